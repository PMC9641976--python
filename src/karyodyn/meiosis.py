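"""Meiotic segregation of sex chromosomes and gamete distributions.

Females
-------
The two X chromosomes pair and segregate, so every egg carries exactly
one X (rare X nondisjunction is ignored).  A single Y-type chromosome
behaves as a univalent that accompanies one of the two X's at random —
an XXY female makes 50% X and 50% XY eggs.  Two Y-type chromosomes pair
with each other and segregate, so every egg carries exactly one of them;
if they differ (Y vs Y^S) each egg type is equally likely.

Males
-----
A male's single X associates with its 1–3 Y-type chromosomes into a
bivalent, trivalent or quadrivalent at meiosis I, which partitions its
members between the two spindle poles at random: every labeled
assignment of the chromosomes to the two poles with both poles
non-empty is equally likely.  For a trivalent this gives the three
observed, equiprobable 1|2 splits (e.g. for XYY^S males: X vs YY^S,
XY vs Y^S, XY^S vs Y).  Either pole then becomes the sperm content with
probability 1/2 (meiosis II is faithful).  For quadrivalents the same
rule allows 1|3 splits; ``splits="balanced_only"`` restricts them to
2|2 partitions instead.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product
from typing import Dict, List, Tuple

import pandas as pd

from .genotypes import (
    FEMALE,
    MALE,
    KaryoGenotype,
    format_genotype,
    modeled_genotypes,
    sex_of,
)

__all__ = [
    "GameteDistribution",
    "female_gametes",
    "male_gametes",
    "gametes_of",
    "enumerate_mi_splits",
    "gamete_table",
    "write_gamete_table",
]

# A gamete is itself a (possibly X-less) chromosome multiset; probabilities
# over gametes are plain dicts.
GameteDistribution = Dict[KaryoGenotype, float]

_X = KaryoGenotype(1, 0, 0)
_Y = KaryoGenotype(0, 1, 0)
_YS = KaryoGenotype(0, 0, 1)


def _add(dist: GameteDistribution, gamete: KaryoGenotype, p: float) -> None:
    dist[gamete] = dist.get(gamete, 0.0) + p


@lru_cache(maxsize=None)
def female_gametes(genotype: KaryoGenotype) -> GameteDistribution:
    """Egg distribution for a female karyotype (≤ 2 Y-type chromosomes)."""
    if sex_of(genotype) != FEMALE:
        raise ValueError(f"female_gametes called on non-female genotype {genotype}")
    n_y, n_ys = genotype.n_y, genotype.n_ys
    total = n_y + n_ys
    if total > 2:
        raise ValueError(
            f"egg distribution undefined for {genotype}: females with three or "
            "more Y-type chromosomes have fitness 0 and never reproduce"
        )
    dist: GameteDistribution = {}
    if total == 0:
        dist[_X] = 1.0
    elif total == 1:
        # univalent Y-type joins the egg with one of the segregating X's
        carried = _Y if n_y == 1 else _YS
        _add(dist, _X, 0.5)
        _add(dist, _X + carried, 0.5)
    else:
        # the two Y-types pair and segregate: exactly one per egg
        if n_y == 2:
            dist[_X + _Y] = 1.0
        elif n_ys == 2:
            dist[_X + _YS] = 1.0
        else:
            dist[_X + _Y] = 0.5
            dist[_X + _YS] = 0.5
    return dist


Multiset = Tuple[int, int, int]  # (n_x, n_y, n_ys)
Split = Tuple[Multiset, Multiset]  # unordered pole pair, stored sorted


@lru_cache(maxsize=None)
def enumerate_mi_splits(
    chromosomes: Multiset, splits: str = "all_nonempty"
) -> Tuple[Tuple[Split, float], ...]:
    """All meiosis-I pole partitions of a chromosome multiset with probabilities.

    Each of the ``2^n`` labeled assignments of the ``n`` chromosomes to
    two poles is equally likely; assignments leaving a pole empty are
    excluded and the remainder renormalized.  Identical chromosomes are
    treated as distinguishable during enumeration and the resulting
    unordered pole pairs are collapsed with summed multiplicity, which
    yields the correct weights (e.g. {X,Y,Y} → X|YY with weight 1/3 but
    XY|Y with weight 2/3).

    ``splits="balanced_only"`` keeps only assignments splitting the
    chromosomes as evenly as possible (2|2 for four chromosomes; for two
    or three chromosomes the rules coincide with ``all_nonempty``'s
    non-empty requirement on 1|1 and 1|2 splits).
    """
    n = sum(chromosomes)
    if not 2 <= n <= 4:
        raise ValueError(f"MI split enumeration supports 2-4 chromosomes, got {n}")
    if splits not in ("all_nonempty", "balanced_only"):
        raise ValueError(f"unknown splits rule: {splits!r}")
    labels: List[int] = []  # chromosome class index per labeled copy
    for cls, count in enumerate(chromosomes):
        labels.extend([cls] * count)
    weights: Dict[Split, int] = {}
    kept = 0
    for assignment in product((0, 1), repeat=n):
        sizes = (assignment.count(0), assignment.count(1))
        if 0 in sizes:
            continue
        if splits == "balanced_only" and abs(sizes[0] - sizes[1]) > n % 2:
            continue
        poles = [[0, 0, 0], [0, 0, 0]]
        for lab, pole in zip(labels, assignment):
            poles[pole][lab] += 1
        key: Split = tuple(sorted(tuple(p) for p in poles))  # type: ignore[assignment]
        weights[key] = weights.get(key, 0) + 1
        kept += 1
    return tuple((split, w / kept) for split, w in sorted(weights.items()))


@lru_cache(maxsize=None)
def male_gametes(
    genotype: KaryoGenotype, splits: str = "all_nonempty"
) -> GameteDistribution:
    """Sperm distribution for a male karyotype (1-3 Y-type chromosomes)."""
    if sex_of(genotype) != MALE:
        raise ValueError(f"male_gametes called on non-male genotype {genotype}")
    total = genotype.n_ytype
    if total == 0:
        raise ValueError(
            f"sperm distribution undefined for {genotype}: an X-only male has no "
            "rDNA source and never arises as an adult"
        )
    if total >= 4:
        raise ValueError(
            f"sperm distribution undefined for {genotype}: males with four or "
            "more Y-type chromosomes have fitness 0"
        )
    dist: GameteDistribution = {}
    multiset: Multiset = (genotype.n_x, genotype.n_y, genotype.n_ys)
    for (pole_a, pole_b), p in enumerate_mi_splits(multiset, splits):
        _add(dist, KaryoGenotype(*pole_a), p / 2.0)
        _add(dist, KaryoGenotype(*pole_b), p / 2.0)
    return dist


def gametes_of(
    genotype: KaryoGenotype, splits: str = "all_nonempty"
) -> GameteDistribution:
    """Gamete distribution for either sex."""
    if sex_of(genotype) == FEMALE:
        return female_gametes(genotype)
    return male_gametes(genotype, splits)


def gamete_table(splits: str = "all_nonempty") -> pd.DataFrame:
    """Full parent → gamete probability table for every modeled genotype.

    Columns: sex, parent, gamete, probability; one row per gamete class.
    """
    rows = []
    for parent in modeled_genotypes():
        sx = sex_of(parent)
        dist = gametes_of(parent, splits)
        for gamete in sorted(dist):
            rows.append(
                {
                    "sex": sx,
                    "parent": format_genotype(parent),
                    "gamete": format_genotype(gamete),
                    "probability": dist[gamete],
                }
            )
    return pd.DataFrame(rows)


def write_gamete_table(path, splits: str = "all_nonempty") -> None:
    gamete_table(splits).to_csv(path, sep="\t", index=False)
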