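import numpy as np
import pytest
from scipy import stats

from viromenet.annotation import (
    marker_congruence,
    replication_proximity,
    scan_mtase_motif,
    transfer_functions,
)
from viromenet.io_formats import FeatureRecord
from viromenet.network import EdgeThresholds, build_network, connected_components
from viromenet.similarity_engine import all_vs_all
from viromenet.synthetic_data import FamilySpec, SynthConfig, generate_dataset

from conftest import make_protein


class TestTransferFunctions:
    def test_majority_label_with_support_count(self):
        proteins = [
            make_protein("h1", "MKLV"),
            make_protein("f1", "MKLV", product="holin"),
            make_protein("f2", "MKLV", product="holin"),
        ]
        partition = {"h1": "c1", "f1": "c1", "f2": "c1"}
        (sug,) = transfer_functions(partition, proteins)
        assert (sug.protein_id, sug.suggested_product, sug.n_support) == ("h1", "holin", 2)

    def test_all_hypothetical_component_yields_nothing(self):
        proteins = [make_protein(f"h{i}", "MKLV") for i in range(4)]
        partition = {p.protein_id: "c1" for p in proteins}
        assert transfer_functions(partition, proteins) == []

    def test_tie_broken_lexicographically(self):
        proteins = [
            make_protein("h1", "MKLV"),
            make_protein("f1", "MKLV", product="portal protein"),
            make_protein("f2", "MKLV", product="holin"),
        ]
        partition = {p.protein_id: "c" for p in proteins}
        (sug,) = transfer_functions(partition, proteins)
        assert sug.suggested_product == "holin"

    def test_never_overwrites_existing_annotation(self):
        proteins = [
            make_protein("f1", "MKLV", product="holin"),
            make_protein("f2", "MKLV", product="endolysin"),
        ]
        partition = {"f1": "c", "f2": "c"}
        assert transfer_functions(partition, proteins) == []

    def test_planted_hypotheticals_recover_their_family_label(self):
        """Hypothetical members of labelled families get exactly that label."""
        config = SynthConfig(
            seed=17,
            families=(
                FamilySpec("fa", tuple(f"P{i}" for i in range(6)), 160, 90.0, "holin"),
                FamilySpec("fb", tuple(f"P{i}" for i in range(5)), 180, 90.0, "portal protein"),
            ),
            n_singletons=4,
        )
        proteins, truth = generate_dataset(config)
        # blank out some family members to hypothetical
        planted = {"fa_p00", "fa_p03", "fb_p01"}
        from dataclasses import replace
        proteins = [
            replace(p, product="hypothetical protein") if p.protein_id in planted else p
            for p in proteins
        ]
        net = build_network(all_vs_all(proteins), EdgeThresholds(), proteins)
        suggestions = transfer_functions(connected_components(net), proteins)
        got = {s.protein_id: s.suggested_product for s in suggestions}
        expected_label = {"fa": "holin", "fb": "portal protein"}
        assert got == {pid: expected_label[truth[pid]] for pid in planted}


class TestMarkerCongruence:
    def test_identical_partitions_give_ari_one(self):
        part = {f"t{i}": f"c{i % 2}" for i in range(6)}
        mapping = {f"t{i}": f"ph{i}" for i in range(6)}
        report = marker_congruence(part, dict(part), mapping)
        assert report.adjusted_rand == pytest.approx(1.0)
        assert report.n_shared_phages == 6

    def test_degenerate_partitions_give_zero(self):
        all_in_one = {f"t{i}": "c" for i in range(6)}
        singletons = {f"t{i}": f"c{i}" for i in range(6)}
        mapping = {f"t{i}": f"ph{i}" for i in range(6)}
        report = marker_congruence(all_in_one, singletons, mapping)
        assert report.adjusted_rand == pytest.approx(0.0)

    def test_fewer_than_three_shared_phages_undefined(self):
        a = {"t1": "c1", "t2": "c2"}
        mapping = {"t1": "ph1", "t2": "ph2"}
        report = marker_congruence(a, dict(a), mapping)
        assert report.adjusted_rand is None

    def test_two_proteins_per_phage_is_error(self):
        part = {"t1": "c1", "t2": "c1"}
        mapping = {"t1": "ph1", "t2": "ph1"}
        with pytest.raises(ValueError, match="two proteins"):
            marker_congruence(part, part, mapping)

    def test_random_partitions_have_null_ari_near_zero(self):
        rng = np.random.default_rng(8)
        mapping = {f"t{i}": f"ph{i}" for i in range(20)}
        values = []
        for _ in range(1000):
            a = {f"t{i}": f"a{rng.integers(4)}" for i in range(20)}
            b = {f"t{i}": f"b{rng.integers(4)}" for i in range(20)}
            values.append(marker_congruence(a, b, mapping).adjusted_rand)
        assert abs(np.mean(values)) < 0.05


class TestMtaseMotifScan:
    def test_single_motif_with_position(self):
        (call,) = scan_mtase_motif(make_protein("m", "AANPPYAA"))
        assert (call.motif, call.motif_position) == ("NPPY", 3)

    def test_near_miss_not_called(self):
        assert scan_mtase_motif(make_protein("m", "NPPA")) == []

    @pytest.mark.parametrize("motif", ["NPPY", "NPPF", "NPPW"])
    def test_all_three_catalytic_variants_recognized(self, motif):
        (call,) = scan_mtase_motif(make_protein("m", f"MK{motif}LV"))
        assert call.motif == motif

    def test_planted_family_fully_detected_and_background_rate_analytic(self):
        """Planted NPPW detected in every member; random-sequence hits follow 3/20^4 per site."""
        rng = np.random.default_rng(4)
        spec = FamilySpec("mt", tuple(f"P{i}" for i in range(10)), 300, 70.0,
                          product_label="adenine-specific DNA methyltransferase",
                          plant_motif="NPPW")
        from viromenet.synthetic_data import generate_family
        members = generate_family(spec, rng)
        assert all(any(c.motif == "NPPW" for c in scan_mtase_motif(m)) for m in members)

        aa = list("ACDEFGHIKLMNPQRSTVWY")
        n_seq, length = 1500, 300
        hits = 0
        sites = n_seq * (length - 3)
        for i in range(n_seq):
            seq = "".join(rng.choice(aa, size=length))
            hits += len(scan_mtase_motif(make_protein(f"d{i}", seq)))
        mu = sites * 3 / 20**4
        lo, hi = stats.poisson.ppf([1e-4, 1 - 1e-4], mu)
        assert lo <= hits <= hi


class TestReplicationProximity:
    @staticmethod
    def features(products):
        return [
            FeatureRecord("r", 100 + 1000 * i, 900 + 1000 * i, "+", "CDS",
                          {"protein_id": f"p{i}", "product": prod})
            for i, prod in enumerate(products)
        ]

    def test_adjacent_gene_distance_one(self):
        feats = self.features(["integrase", "methyltransferase", "replication initiation protein"])
        calls = scan_mtase_motif(make_protein("p1", "AANPPYAA"))
        (annotated,) = replication_proximity(calls, feats)
        assert annotated.gene_distance_to_replication == 1

    def test_no_replication_gene_gives_none(self):
        feats = self.features(["integrase", "methyltransferase", "holin"])
        calls = scan_mtase_motif(make_protein("p1", "AANPPYAA"))
        (annotated,) = replication_proximity(calls, feats)
        assert annotated.gene_distance_to_replication is None

    def test_layout_distance_recovered_from_generator(self, rng):
        """The generator plants the MTase at ordinal distance 1 from replication."""
        from viromenet.synthetic_data import ProphagePlantSpec, generate_host_with_prophage

        spec = ProphagePlantSpec(prophage_length=12000)
        _, feats, _ = generate_host_with_prophage(spec, rng)
        mtase_pid = next(
            f.attributes["protein_id"] for f in feats
            if f.kind == "CDS" and "methyltransferase" in f.attributes["product"]
        )
        calls = scan_mtase_motif(make_protein(mtase_pid, "AANPPWAA"))
        (annotated,) = replication_proximity(calls, feats)
        assert annotated.gene_distance_to_replication == 1
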