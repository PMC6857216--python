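"""Published summary statistics of the CHWDIC early-adopter study.

The raw roster and tie data of the 2016 Gombe (Nigeria) study of early
adopters of community health worker-delivered injectable contraceptives were
never deposited; what is public are summary tables.  The machine-readable
copies below are used to cross-check this package's formulas (every quantity
recomputable from a printed input is recomputed and compared) and as
calibration anchors for the synthetic generator.  They are *inputs*, never a
substitute for computation.

``REPORTED_NETWORKS`` carries, per network: the site, the directed-symmetric
tie count (out of 110 possible among 11 actors), the printed density, the
ego's degree, the printed average degree, ego and network-average normalized
betweenness (percent), and the count of injectable-contraceptive users.

Three printed density cells are internally inconsistent with their own tie
counts (SNA-C: 50/110 = 0.4545 printed as 0.46; SNA-D: 94/110 = 0.8545
printed as 0.86; SNA-F: 88/110 = 0.80 printed as 0.98) and are flagged in
``DENSITY_ERRATA``; consistency checks skip them.
"""

from __future__ import annotations

from typing import Dict, List, NamedTuple


class ReportedNetworkRow(NamedTuple):
    label: str
    site: str
    directed_ties: int
    density: float
    ego_degree: int
    average_degree: float
    ego_nbetweenness: float
    average_nbetweenness: float
    cbdic_users: int


REPORTED_NETWORKS: List[ReportedNetworkRow] = [
    ReportedNetworkRow("SNA-A", "A", 84, 0.76, 9, 7.64, 4.37, 2.45, 8),
    ReportedNetworkRow("SNA-B", "A", 96, 0.87, 10, 8.73, 2.14, 1.34, 10),
    ReportedNetworkRow("SNA-C", "A", 50, 0.46, 8, 4.55, 23.07, 4.80, 4),
    ReportedNetworkRow("SNA-D", "A", 94, 0.86, 7, 8.55, 1.56, 1.62, 7),
    ReportedNetworkRow("SNA-E", "A", 108, 0.98, 10, 9.82, 0.25, 0.20, 10),
    ReportedNetworkRow("SNA-F", "A", 88, 0.98, 5, 8.00, 4.58, 1.99, 7),
    ReportedNetworkRow("SNA-G", "A", 86, 0.78, 7, 7.82, 2.56, 2.41, 5),
    ReportedNetworkRow("SNA-H", "A", 92, 0.84, 8, 8.37, 1.60, 2.29, 8),
    ReportedNetworkRow("SNA-I", "A", 92, 0.84, 8, 8.36, 1.15, 1.67, 9),
    ReportedNetworkRow("SNA-J", "A", 74, 0.67, 7, 6.73, 3.11, 2.80, 8),
    ReportedNetworkRow("SNA-K", "B", 74, 0.67, 10, 6.73, 16.41, 2.36, 10),
    ReportedNetworkRow("SNA-L", "B", 110, 1.00, 10, 10.00, 0.0, 0.0, 10),
    ReportedNetworkRow("SNA-M", "B", 110, 1.00, 10, 10.00, 0.0, 0.0, 9),
    ReportedNetworkRow("SNA-N", "B", 76, 0.69, 10, 6.91, 9.78, 2.80, 10),
    ReportedNetworkRow("SNA-O", "B", 82, 0.75, 10, 7.45, 10.63, 2.05, 10),
    ReportedNetworkRow("SNA-P", "B", 56, 0.51, 10, 5.09, 30.56, 2.95, 10),
    ReportedNetworkRow("SNA-Q", "B", 56, 0.51, 2, 5.09, 0.0, 2.89, 3),
    ReportedNetworkRow("SNA-R", "B", 110, 1.00, 10, 10.00, 0.0, 0.0, 3),
    ReportedNetworkRow("SNA-S", "B", 96, 0.87, 10, 8.73, 2.64, 1.30, 10),
    ReportedNetworkRow("SNA-T", "B", 80, 0.73, 10, 7.27, 8.52, 2.48, 9),
]

#: Density cells whose printed value disagrees with the printed tie count.
DENSITY_ERRATA = ("SNA-C", "SNA-D", "SNA-F")

#: Average-degree cells likewise inconsistent: SNA-H prints 8.37 from 92
#: ties, yet 92/11 = 8.36 — exactly what the equal-tie-count row SNA-I prints.
AVERAGE_DEGREE_ERRATA = ("SNA-H",)

#: Reported counts of homophilic egos/alters per attribute (of 20 / 200).
REPORTED_HOMOPHILY_COUNTS: Dict[str, Dict[str, int]] = {
    "ethnicity": {"egos": 20, "alters": 175},
    "cbdic_use": {"egos": 17, "alters": 162},
    "age_group": {"egos": 18, "alters": 158},
    "education": {"egos": 13, "alters": 133},
    "marriage_type": {"egos": 11, "alters": 98},
}

#: Reported actor counts by role for selected descriptive rows.
REPORTED_DESCRIPTIVES: Dict[str, Dict[str, int]] = {
    "egos_age_30_plus": {"count": 15, "denominator": 20},
    "alters_age_30_plus": {"count": 123, "denominator": 200},
    "hausa_total": {"count": 177, "denominator": 220},
    "married_total": {"count": 216, "denominator": 220},
    "cbdic_users_total": {"count": 185, "denominator": 220},
}
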