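"""Published summary statistics of the curated GPCR heteroreceptor network.

The original curated edge list (156 protomers, 260 experimentally supported
heteromer pairs) was distributed through a web resource and is not bundled
here; what the study prints are summary tables — family composition, the
intra/interfamily edge partition, the degree table of the 29 best-connected
protomers, and the disconnected-protomer list.  Those printed numbers are
collected in this module so the synthetic generator can be constrained to
them and simple coverage/share arithmetic can be recomputed.
"""

from __future__ import annotations

NODE_COUNT = 156
EDGE_COUNT = 260

#: Protomers per GPCR class observed in at least one heteromer.
FAMILY_NODE_COUNTS = {"F1": 128, "F2": 15, "F3": 13}

#: Putative human receptor totals per class (orphans included for F1).
FAMILY_PUTATIVE_TOTALS = {"F1": 726, "F2": 46, "F3": 22}

#: Heteromer-pair partition: intrafamily per class plus interfamily.
FAMILY_EDGE_COUNTS = {"F1": 219, "F2": 15, "F3": 17, "interfamily": 9}

#: Degrees of the 29 protomers with more than five interactions,
#: decreasing order (the degree > 5 hub table).
HUB_DEGREES = {
    "DRD2": 17, "OPRM": 17, "ADRB2": 13, "AA2AR": 12, "AA1R": 11,
    "OPRK": 10, "OPRD": 10, "GHSR": 10, "5HT1A": 10,
    "S1PR3": 9, "S1PR1": 9, "CNR1": 9,
    "SCTR": 8, "P2RY1": 8, "LPAR1": 8, "AGTR1": 8,
    "SSR5": 7, "P2RY2": 7, "LPAR3": 7, "LPAR2": 7, "GRM2": 7, "GPR4": 7,
    "DRD1": 7,
    "S1PR2": 6, "P2Y12": 6, "OGR1": 6, "GRM5": 6, "CXCR4": 6, "CCR5": 6,
}

#: The nine protomers with ten or more interactions.
TOP_DEGREES = (17, 17, 13, 12, 11, 10, 10, 10, 10)

#: Protomers reported with no connection to the main network.
ISOLATED_PROTOMERS = (
    "TSHR", "LSHR", "FSHR", "MTR1A", "MTR1B", "MTR1L", "FPR2", "FPR1",
    "FPR3", "CD97", "EMR2", "EMR3", "TS1R2", "TS1R3", "TS1R1", "CLTR1",
    "CLTR2", "CRFR1", "V1BR", "MRGRE", "MRGRD", "RXFP1", "RXFP2",
)

ISOLATED_COUNT = len(ISOLATED_PROTOMERS)  # 23
DEGREE_ONE_COUNT = 57
CLUSTERED_PROTOMER_COUNT = 56


def family_coverage_percent(family: str) -> float:
    """Observed protomers of a class as a percentage of the putative total
    (e.g. 15 of 46 secretin-like receptors)."""
    return 100.0 * FAMILY_NODE_COUNTS[family] / FAMILY_PUTATIVE_TOTALS[family]


def clustered_share_percent() -> float:
    """Percentage of protomers located within dense modules."""
    return 100.0 * CLUSTERED_PROTOMER_COUNT / NODE_COUNT


def round_half_away(x: float, digits: int = 0) -> float:
    """Round half away from zero, the convention used for printed percents."""
    factor = 10 ** digits
    import math

    scaled = abs(x) * factor
    result = math.floor(scaled + 0.5) / factor
    return result if x >= 0 else -result
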