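"""Sex-chromosome karyotypes and their fitness values.

The population modeled here is a *Drosophila melanogaster* strain whose X
chromosome has lost its ribosomal DNA (rDNA) locus.  Because rDNA is
essential for viability and the Y chromosome carries the only other rDNA
locus, every individual — female or male — must carry at least one
Y-derived chromosome.  Two Y variants circulate: the full-length Y, which
carries both rDNA and the male fertility factors, and a truncated Y
("Y^S") that retains rDNA but has lost the long-arm fertility factors
(kl-2, kl-3, kl-5) and therefore cannot support male fertility.

A karyotype is the per-individual multiset of sex chromosomes, written
``KaryoGenotype(n_x, n_y, n_ys)``.  Sex follows the X:autosome ratio:
two X's make a female, one X makes a male; any other X count is outside
the model.

Female fitness is parameterized by the cost of carrying Y-type
chromosomes (extra heterochromatin disrupts oogenesis and shortens
lifespan):

* ``s`` — cost of two Y^S chromosomes (XXY^SY^S fitness = 1 − s)
* ``y`` — cost of two full Y chromosomes (XXYY fitness = 1 − y)
* ``h`` — dominance of a single Y^S (XXY^S fitness = 1 − h·s)
* ``h_prime`` — dominance of a single Y (XXY fitness = 1 − h′·y)
* ``h_dblprime`` — interpolation for the YY^S heterozygote:
  XXYY^S fitness = 1 − [(1 − h″)·s + h″·y], so h″ = 0 reproduces the
  Y^SY^S homozygote and h″ = 1 the YY homozygote.

XX females have no rDNA source and fitness 0.  Male fitness is binary —
1 with at least one full Y and at most two Y-type chromosomes, 0 with
only Y^S chromosomes or with the sterile XYYY complement — except the
triple-Y-type genotypes XYYY^S and XYY^SY^S, which get a small fitness
``m3`` (default 0.1).  Negative costs are allowed and make a chromosome
beneficial; fitness is clamped below at 0 but not above 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "KaryoGenotype",
    "FitnessParams",
    "FEMALE",
    "MALE",
    "NON_MODELED",
    "sex_of",
    "female_fitness",
    "male_fitness",
    "fitness",
    "parse_genotype",
    "format_genotype",
    "modeled_genotypes",
    "MODELED_FEMALE_GENOTYPES",
    "MODELED_MALE_GENOTYPES",
]

FEMALE = "female"
MALE = "male"
NON_MODELED = "non_modeled"


@dataclass(frozen=True, order=True)
class KaryoGenotype:
    """A sex-chromosome complement: counts of X, full-length Y, and truncated Y^S."""

    n_x: int
    n_y: int
    n_ys: int

    def __post_init__(self) -> None:
        for name in ("n_x", "n_y", "n_ys"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def n_ytype(self) -> int:
        """Total Y-type chromosomes (full Y plus Y^S)."""
        return self.n_y + self.n_ys

    @property
    def sex(self) -> str:
        return sex_of(self)

    def __str__(self) -> str:
        return format_genotype(self)

    def __add__(self, other: "KaryoGenotype") -> "KaryoGenotype":
        """Componentwise union — zygote formation from an egg and a sperm."""
        return KaryoGenotype(
            self.n_x + other.n_x, self.n_y + other.n_y, self.n_ys + other.n_ys
        )


def sex_of(genotype: KaryoGenotype) -> str:
    """Sex from the X count: 2 X → female, 1 X → male, anything else non-modeled."""
    if genotype.n_x == 2:
        return FEMALE
    if genotype.n_x == 1:
        return MALE
    return NON_MODELED


@dataclass(frozen=True)
class FitnessParams:
    """Selection parameters for karyotype fitness.

    Attributes
    ----------
    s : float
        Female cost of two Y^S chromosomes, in [-1, 1].
    y : float
        Female cost of two full Y chromosomes, in [-1, 1].
    h, h_prime : float
        Dominance of a single Y^S (resp. single Y) relative to two copies,
        in [0, 1]; default 0.5.
    h_dblprime : float
        Y/Y^S heterozygote interpolation weight in [0, 1]; 0 matches the
        Y^SY^S homozygote, 1 the YY homozygote; default 0.5.
    m3 : float
        Fitness of XYYY^S and XYY^SY^S males, in [0, 1]; default 0.1.
    """

    s: float = 0.0
    y: float = 0.0
    h: float = 0.5
    h_prime: float = 0.5
    h_dblprime: float = 0.5
    m3: float = 0.1

    def __post_init__(self) -> None:
        for name in ("s", "y"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")
        for name in ("h", "h_prime", "h_dblprime", "m3"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def female_fitness(genotype: KaryoGenotype, params: FitnessParams) -> float:
    """Fitness of a female karyotype.

    XX females lack any rDNA source and have fitness 0.  Females with one
    or two Y-type chromosomes pay the heterochromatin cost described in
    the module docstring.  Females with three or more Y-type chromosomes
    are assigned fitness 0: the Y-dose burden grows with copy number and
    such individuals are essentially absent from the population.

    The result is clamped below at 0.  Costs may be negative (a beneficial
    chromosome), in which case fitness may exceed 1.
    """
    if sex_of(genotype) != FEMALE:
        raise ValueError(f"female_fitness called on non-female genotype {genotype}")
    n_y, n_ys = genotype.n_y, genotype.n_ys
    total = n_y + n_ys
    if total == 0:
        return 0.0  # XX: no rDNA source
    if total >= 3:
        return 0.0
    if total == 1:
        w = 1.0 - params.h * params.s if n_ys == 1 else 1.0 - params.h_prime * params.y
    else:  # two Y-type chromosomes
        if n_ys == 2:
            w = 1.0 - params.s
        elif n_y == 2:
            w = 1.0 - params.y
        else:  # YY^S heterozygote
            w = 1.0 - ((1.0 - params.h_dblprime) * params.s + params.h_dblprime * params.y)
    return max(w, 0.0)


def male_fitness(genotype: KaryoGenotype, params: FitnessParams) -> float:
    """Fitness of a male karyotype.

    Male fitness is fertility-driven and binary except for the triple-Y
    genotypes: a male needs at least one full-length Y to be fertile
    (Y^S lacks the axonemal dynein fertility factors), so XY^S and
    XY^SY^S are 0; XY, XYY and XYY^S are 1; XYYY is sterile (0); the
    triple genotypes XYYY^S and XYY^SY^S get ``m3``; four or more Y-type
    chromosomes extend the XYYY rule to 0; an X-only male has no rDNA
    source and is 0.
    """
    if sex_of(genotype) != MALE:
        raise ValueError(f"male_fitness called on non-male genotype {genotype}")
    n_y, n_ys = genotype.n_y, genotype.n_ys
    total = n_y + n_ys
    if total == 0:
        return 0.0  # no rDNA source
    if n_y == 0:
        return 0.0  # only Y^S: sterile at any count
    if total >= 4:
        return 0.0
    if total == 3:
        if n_y == 3:
            return 0.0  # XYYY, sterile
        return params.m3  # XYYY^S or XYY^SY^S
    return 1.0


def fitness(genotype: KaryoGenotype, params: FitnessParams) -> float:
    """Fitness of any genotype; non-modeled karyotypes get 0."""
    sx = sex_of(genotype)
    if sx == FEMALE:
        return female_fitness(genotype, params)
    if sx == MALE:
        return male_fitness(genotype, params)
    return 0.0


# --- genotype string format ------------------------------------------------
# "X" repeated, then "Y" for each full Y, then "YS" for each truncated Y;
# e.g. XXYYS is (2, 1, 1) and XYSYS is (1, 0, 2).

_TOKEN_RE = re.compile(r"X|YS|Y", re.IGNORECASE)


def format_genotype(genotype: KaryoGenotype) -> str:
    return "X" * genotype.n_x + "Y" * genotype.n_y + "YS" * genotype.n_ys


def parse_genotype(text: str) -> KaryoGenotype:
    """Parse a genotype string such as ``XXY``, ``XYSYS`` or ``XXYYS``.

    Tokens are X, Y and YS; ``YS`` binds greedily, so the canonical
    ordering (X's, then Y's, then YS's) round-trips.  Case-insensitive;
    a caret/superscript form like ``XY^S`` is accepted.
    """
    cleaned = text.strip().replace("^", "").replace(" ", "")
    if not cleaned:
        raise ValueError("empty genotype string")
    pos = 0
    n_x = n_y = n_ys = 0
    for m in _TOKEN_RE.finditer(cleaned):
        if m.start() != pos:
            break
        tok = m.group(0).upper()
        if tok == "X":
            n_x += 1
        elif tok == "YS":
            n_ys += 1
        else:
            n_y += 1
        pos = m.end()
    if pos != len(cleaned):
        raise ValueError(f"unparseable genotype string: {text!r}")
    return KaryoGenotype(n_x, n_y, n_ys)


# The ten karyotype classes observed in the strain (plus XX, which is
# inviable but representable).  Females carry up to two Y-types; males
# one to three (triple-Y-type males are rare but modeled).

MODELED_FEMALE_GENOTYPES: tuple[KaryoGenotype, ...] = tuple(
    KaryoGenotype(2, n_y, n_ys)
    for n_y in range(3)
    for n_ys in range(3)
    if 1 <= n_y + n_ys <= 2
)

MODELED_MALE_GENOTYPES: tuple[KaryoGenotype, ...] = tuple(
    KaryoGenotype(1, n_y, n_ys)
    for n_y in range(4)
    for n_ys in range(4)
    if 1 <= n_y + n_ys <= 3
)


def modeled_genotypes() -> Iterator[KaryoGenotype]:
    """All viable-sex genotypes with 1–2 (females) or 1–3 (males) Y-types."""
    yield from MODELED_FEMALE_GENOTYPES
    yield from MODELED_MALE_GENOTYPES
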