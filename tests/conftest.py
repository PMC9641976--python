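from fractions import Fraction
from itertools import product

import pytest

from karyodyn import KaryoGenotype


def brute_force_male_gametes(genotype: KaryoGenotype, splits: str = "all_nonempty"):
    """Exhaustive oracle for male meiosis: enumerate every labeled
    assignment of the (distinguishably labeled) chromosomes to two poles,
    drop empty-pole cases, optionally keep only balanced splits, then let
    either pole become the sperm with probability 1/2.  Exact rational
    arithmetic throughout."""
    labels = (
        [(0,)] * genotype.n_x + [(1,)] * genotype.n_y + [(2,)] * genotype.n_ys
    )
    n = len(labels)
    dist: dict[KaryoGenotype, Fraction] = {}
    kept = 0
    outcomes = []
    for assignment in product((0, 1), repeat=n):
        sizes = (assignment.count(0), assignment.count(1))
        if 0 in sizes:
            continue
        if splits == "balanced_only" and abs(sizes[0] - sizes[1]) > n % 2:
            continue
        kept += 1
        for pole in (0, 1):
            counts = [0, 0, 0]
            for lab, p in zip(labels, assignment):
                if p == pole:
                    counts[lab[0]] += 1
            outcomes.append(KaryoGenotype(*counts))
    for gamete in outcomes:
        dist[gamete] = dist.get(gamete, Fraction(0)) + Fraction(1, 2 * kept)
    return dist


@pytest.fixture
def male_gamete_oracle():
    return brute_force_male_gametes
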