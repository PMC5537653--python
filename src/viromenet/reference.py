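"""Published summary data of a comparative sinorhizobial virome analysis, as inputs.

These are the printed headline numbers of a comparative analysis of 31
sinorhizobial (pro)phages: the subgraph-size census of the 3688-protein
similarity network built at the 1e-5 / 50% identity / 50% coverage
thresholds, the annotation bookkeeping, and the coordinate/size columns of
the per-prophage summary table.  They serve as worked-example inputs: the
package re-derives the derived quantities (clustered-node count, subgraph
count, percentages, inclusive region lengths) from them rather than
asserting them as constants.

A handful of table rows print a size that does not equal end - start + 1
(they match end - start, or neither); those rows are flagged as known
discrepancies instead of being silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

#: subgraph census: "<size>s:<count>n" comma-joined, sizes descending
SUBGRAPH_CENSUS = "12s:6n, 11s:2n, 9s:5n, 8s:4n, 7s:26n, 6s:7n, 5s:26n, 4s:317n, 3s:98n, 2s:175n"

N_SINGLETONS = 1251
N_EDGES = 3975
N_PROTEINS = 3688
N_PROPHAGES = 31

#: annotation bookkeeping over the 3688 proteins
N_HYPOTHETICAL_INITIAL = 2667
N_REANNOTATED_MANUALLY = 141
N_SUGGESTED_BY_NETWORK = 108


@dataclass(frozen=True)
class ProphageTableRow:
    name: str
    host: str
    accession: str
    start: Optional[int]
    end: Optional[int]
    printed_size_bp: int
    n_genes: int
    integration_site: str


#: per-prophage rows with printed coordinates and sizes (extrachromosomal
#: phages without host coordinates carry start=end=None)
PROPHAGE_TABLE: tuple[ProphageTableRow, ...] = (
    ProphageTableRow("Phi1_CasidaA", "E. adherens Casida A", "NZ_CP015880.1", 2834796, 2878945, 44150, 62, "tRNA-Leu(CAA)"),
    ProphageTableRow("Phi2_CasidaA", "E. adherens Casida A", "NZ_CP015880.1", 2972802, 3012361, 39560, 63, "intergenic"),
    ProphageTableRow("Phi1_CFNEI73", "S. americanum CFNEI73", "NZ_CP013107.1", 1807693, 1861334, 53642, 84, "tRNA-Cys(GCA)"),
    ProphageTableRow("Phi1_WSM419", "S. medicae WSM419", "NC_009636.1", 1392222, 1433999, 41778, 58, "tRNA-Ser(TGA)"),
    ProphageTableRow("Phi2_WSM419", "S. medicae WSM419", "NC_009636.1", 1717421, 1768019, 50599, 66, "DusA"),
    ProphageTableRow("Phi3_WSM419", "S. medicae WSM419", "NC_009636.1", 1934112, 1984910, 50799, 72, "tRNA-Lys(CTT)"),
    ProphageTableRow("Phi1_Rm41", "S. meliloti Rm41", "NC_018700.1", 742114, 794018, 53565, 80, "tRNA-Ser(GCT)"),
    ProphageTableRow("Phi2_Rm41", "S. meliloti Rm41", "NC_018700.1", 1833694, 1887258, 51921, 86, "tRNA-Lys(CTT)"),
    ProphageTableRow("Phi1_RMO17", "S. meliloti RMO17", "NZ_CP009144.1", 2233094, 2285133, 52040, 76, "tRNA-Lys(CTT)"),
    ProphageTableRow("Phi1_BL225C", "S. meliloti BL225C", "NC_017322.1", 1366482, 1418152, 51671, 67, "tRNA-Asn(GTT)"),
    ProphageTableRow("Phi2_BL225C", "S. meliloti BL225C", "NC_017323.1", 1651701, 1686916, 35216, 46, "tRNA-Arg(CCG)"),
    ProphageTableRow("Phi1_SM11", "S. meliloti SM11", "NC_017325.1", 912263, 969433, 57171, 69, "tRNA-Met(CAT)"),
    ProphageTableRow("Phi2_SM11", "S. meliloti SM11", "NC_017325.1", 1084292, 1130096, 45805, 57, ""),
    ProphageTableRow("Phi3_SM11", "S. meliloti SM11", "NC_017325.1", 1453058, 1501481, 48424, 63, "DusA"),
    ProphageTableRow("Phi4_SM11", "S. meliloti SM11", "NC_017325.1", 1795391, 1849554, 54164, 81, "tRNA-Leu(TAA)"),
    ProphageTableRow("Phi5_SM11", "S. meliloti SM11", "NC_017325.1", 1864579, 1915967, 51389, 72, "tRNA-Asn(GTT)"),
    ProphageTableRow("Phi6_SM11", "S. meliloti SM11", "NC_017325.1", 2351730, 2402613, 50865, 76, "tRNA-Pro(GGG)"),
    ProphageTableRow("Phi1_AK83", "S. meliloti AK83", "NC_015590.1", 264329, 313309, 48981, 62, "tRNA-Thr(GGT)"),
    ProphageTableRow("Phi2_AK83", "S. meliloti AK83", "NC_015590.1", 795050, 847939, 52890, 78, "tRNA-Ser(GCT)"),
    ProphageTableRow("Phi3_AK83", "S. meliloti AK83", "NC_015590.1", 2309762, 2355282, 45521, 61, "tRNA-Met(CAT)"),
    ProphageTableRow("Phi2LM21", "Sinorhizobium sp. LM21", "SAMN06765771", 550879, 597478, 46599, 69, "tRNA-Phe(GAA)"),
    ProphageTableRow("Phi3LM21", "Sinorhizobium sp. LM21", "SAMN06765771", 78163, 119610, 41447, 59, "tRNA-Pro(CGG)"),
    ProphageTableRow("pLM21S1", "Sinorhizobium sp. LM21", "KM659098", None, None, 117539, 150, ""),
    ProphageTableRow("PhiLM21", "Sinorhizobium sp. LM21", "KJ743987", None, None, 50827, 72, "tRNA-Pro(GGG)"),
)

#: rows whose printed size does not equal end - start + 1 (most match
#: end - start; Phi1/Phi2_Rm41 appear to have swapped size cells)
KNOWN_SIZE_DISCREPANCIES = frozenset(
    {"Phi1_Rm41", "Phi2_Rm41", "Phi6_SM11", "Phi2LM21", "Phi3LM21"}
)

#: downstream att direct-repeat lengths established for the two LM21 prophages
ATT_REPEAT_LENGTHS = {"Phi2LM21": 17, "Phi3LM21": 57}
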