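"""Observed karyotype distributions of the Seychelles strain.

Karyotype frequencies scored by DNA FISH on larval neuroblast spreads:
48 females (18 XXY, 15 XXY^S, 3 XXYY, 6 XXY^SY^S, 6 XXYY^S) and 50
males.  The printed male percentages (24% XY, 18% XY^S, 16% XYY,
14% XY^SY^S, 26% XYY^S) cover 49 of the 50 scored males and sum to
0.98; they are used as published and renormalized where a proper
distribution is required.  These distributions seed generation 0 of the
simulations.
"""

from __future__ import annotations

from typing import Dict

from .genotypes import KaryoGenotype

__all__ = [
    "OBSERVED_FEMALE_COUNTS",
    "OBSERVED_MALE_COUNTS",
    "OBSERVED_FEMALE_FREQS",
    "OBSERVED_MALE_FREQS",
]

OBSERVED_FEMALE_COUNTS: Dict[KaryoGenotype, int] = {
    KaryoGenotype(2, 1, 0): 18,  # XXY
    KaryoGenotype(2, 0, 1): 15,  # XXY^S
    KaryoGenotype(2, 2, 0): 3,   # XXYY
    KaryoGenotype(2, 0, 2): 6,   # XXY^SY^S
    KaryoGenotype(2, 1, 1): 6,   # XXYY^S
}

OBSERVED_MALE_COUNTS: Dict[KaryoGenotype, int] = {
    KaryoGenotype(1, 1, 0): 12,  # XY
    KaryoGenotype(1, 0, 1): 9,   # XY^S
    KaryoGenotype(1, 2, 0): 8,   # XYY
    KaryoGenotype(1, 0, 2): 7,   # XY^SY^S
    KaryoGenotype(1, 1, 1): 13,  # XYY^S
}

OBSERVED_FEMALE_FREQS: Dict[KaryoGenotype, float] = {
    KaryoGenotype(2, 1, 0): 0.375,
    KaryoGenotype(2, 0, 1): 0.3125,
    KaryoGenotype(2, 2, 0): 0.0625,
    KaryoGenotype(2, 0, 2): 0.125,
    KaryoGenotype(2, 1, 1): 0.125,
}

# As printed; sums to 0.98 (49/50 scored males fall in these five classes).
OBSERVED_MALE_FREQS: Dict[KaryoGenotype, float] = {
    KaryoGenotype(1, 1, 0): 0.24,
    KaryoGenotype(1, 0, 1): 0.18,
    KaryoGenotype(1, 2, 0): 0.16,
    KaryoGenotype(1, 0, 2): 0.14,
    KaryoGenotype(1, 1, 1): 0.26,
}
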