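"""Published summary values from the DGRP virus-injection resistance screen.

Point summaries (posterior means with 95% HPD bounds) of the variance
decomposition for the four viruses assayed on the panel — DCV and FHV
scored as survival time after injection, DMelSV and DAffSV as the CO2
paralysis symptom analysed on a logit scale — together with the
major-effect-locus quantities used by the variance-explained calculus.
These serve as reference inputs for worked examples and consistency
checks; the package recomputes everything else.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VirusSummary:
    virus: str
    natural_host: str
    trait: str  # survival | co2-sensitivity
    scale: str  # observed | logit
    n_flies: int
    n_lines: int
    v_e: tuple[float, float, float]  # mean, hpd_lo, hpd_hi
    v_g: tuple[float, float, float]
    h2: tuple[float, float, float]
    cvg: tuple[float, float, float] | None


VIRUS_SCREEN: dict[str, VirusSummary] = {
    "DCV": VirusSummary(
        "DCV", "D. melanogaster", "survival", "observed",
        14415, 185, (1.15, 1.13, 1.19), (0.61, 0.49, 0.74), (0.34, 0.30, 0.39), (20, 18, 22),
    ),
    "FHV": VirusSummary(
        "FHV", "beetle", "survival", "observed",
        12660, 182, (2.10, 2.03, 2.18), (0.17, 0.13, 0.23), (0.07, 0.05, 0.10), (7, 6, 8),
    ),
    "DMelSV": VirusSummary(
        "DMelSV", "D. melanogaster", "co2-sensitivity", "logit",
        11541, 185, (4.79, 4.50, 5.08), (1.94, 1.47, 2.41), (0.29, 0.24, 0.34), None,
    ),
    "DAffSV": VirusSummary(
        "DAffSV", "D. affinis", "co2-sensitivity", "logit",
        8604, 181, (3.88, 3.69, 4.03), (0.61, 0.43, 0.78), (0.13, 0.10, 0.16), None,
    ),
}

TOTAL_FLIES_INJECTED = 47220

# pastrel 3L:7350895 (DCV resistance): the resistant allele was carried by
# 21 of the 142 lines genotyped at this site and the locus accounts for 47%
# of the DCV heritability on the inbred panel.
PASTREL_SITE = "3L:7350895"
PASTREL_RESISTANT_LINES = 21
PASTREL_GENOTYPED_LINES = 142
PASTREL_FRAC_H2 = 0.47

# heritability shares of the DMelSV loci
REF2P_FRAC_H2 = 0.08
CHKOV1_FRAC_H2 = 0.29
DMELSV_COMBINED_FRAC_H2 = 0.37
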