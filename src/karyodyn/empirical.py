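"""Karyotype count tallies and ddPCR copy-ratio karyotype calling.

``tally`` summarizes karyotype count tables (sex, genotype, count) into
per-sex genotype frequencies and chromosome totals, including the Y^S
share among all Y-type chromosomes.

``call_karyotype`` converts droplet-digital-PCR copy-number ratios into
an integer karyotype.  Three target/reference ratios are used: a Y-arm
locus present on both Y and Y^S (Pp1-Y2, over the autosomal reference
RpL32) measures the total Y-type count; a long-arm locus deleted in Y^S
(PRY/RpL32) measures full-length Y only; an X locus (Upf1/RpL32)
measures the X dose (the autosome:X ratio is 1:1 in females and 2:1 in
males).  Primer efficiency differences depress the Y ratios: a ratio
near 0.8 corresponds to one copy, so ratios are divided by a per-assay
efficiency factor (default 0.8 for the Y assays, 1.0 for X) before
rounding to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .genotypes import (
    FEMALE,
    MALE,
    KaryoGenotype,
    format_genotype,
    parse_genotype,
    sex_of,
)

__all__ = [
    "DEFAULT_Y_EFFICIENCY",
    "DEFAULT_X_EFFICIENCY",
    "DdpcrSample",
    "KaryotypeCall",
    "TallySummary",
    "tally",
    "call_karyotype",
    "read_count_table",
    "write_count_table",
    "read_ddpcr_table",
    "call_ddpcr_table",
]

# Ratio observed for a single copy, attributed to primer efficiency.
DEFAULT_Y_EFFICIENCY = 0.8
DEFAULT_X_EFFICIENCY = 1.0

# Normalized values farther than this from an integer get a low-confidence flag.
_CONFIDENCE_MARGIN = 0.25


@dataclass(frozen=True)
class DdpcrSample:
    """Copy-number ratios of one fly.

    ``r_total_y``: Pp1-Y2/RpL32 (detects Y and Y^S); ``r_full_y``:
    PRY/RpL32 (full-length Y only); ``r_x``: Upf1/RpL32 (X dose).
    """

    sample_id: str
    r_total_y: float
    r_full_y: float
    r_x: float
    efficiency_y: float = DEFAULT_Y_EFFICIENCY
    efficiency_x: float = DEFAULT_X_EFFICIENCY

    def __post_init__(self) -> None:
        for name in ("r_total_y", "r_full_y", "r_x"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("efficiency_y", "efficiency_x"):
            v = getattr(self, name)
            if not 0 < v <= 1.5:
                raise ValueError(f"{name} must lie in (0, 1.5], got {v}")


@dataclass(frozen=True)
class KaryotypeCall:
    """An integer karyotype call plus quality flags."""

    sample_id: str
    genotype: KaryoGenotype
    flags: Tuple[str, ...] = ()

    @property
    def low_confidence(self) -> bool:
        return "low_confidence" in self.flags


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def call_karyotype(sample: DdpcrSample) -> KaryotypeCall:
    """Call an integer karyotype from efficiency-normalized copy ratios.

    Each ratio is divided by its assay efficiency and rounded half-up to
    the nearest integer copy number.  The Y^S count is the total Y-type
    count minus the full-length count, floored at 0 (with a flag) when
    assay noise makes the difference negative.  The X count must come
    out 1 (male) or 2 (female); anything else is an error, as the sample
    is outside the modeled karyotype space.
    """
    z_total = sample.r_total_y / sample.efficiency_y
    z_full = sample.r_full_y / sample.efficiency_y
    z_x = 2.0 * sample.r_x / sample.efficiency_x
    n_total = _round_half_up(z_total)
    n_full = _round_half_up(z_full)
    n_x = _round_half_up(z_x)
    if n_x not in (1, 2):
        raise ValueError(
            f"sample {sample.sample_id}: inferred X count {n_x} outside the "
            "modeled 1 (male) / 2 (female) range"
        )
    flags: List[str] = []
    if any(abs(z - round(z)) > _CONFIDENCE_MARGIN for z in (z_total, z_full, z_x)):
        flags.append("low_confidence")
    n_ys = n_total - n_full
    if n_ys < 0:
        flags.append("negative_ys_floored")
        n_ys = 0
    return KaryotypeCall(sample.sample_id, KaryoGenotype(n_x, n_full, n_ys), tuple(flags))


# --- karyotype count tables ------------------------------------------------


@dataclass
class TallySummary:
    """Chromosome bookkeeping of a karyotype count table."""

    n_individuals: int
    n_by_sex: Dict[str, int]
    frequencies: Dict[str, Dict[KaryoGenotype, float]]  # per sex, sum to 1
    total_y: int
    total_ys: int

    @property
    def total_ytype(self) -> int:
        return self.total_y + self.total_ys

    @property
    def ys_share(self) -> float:
        """Y^S fraction among all Y-type chromosomes (NaN if none)."""
        if self.total_ytype == 0:
            return math.nan
        return self.total_ys / self.total_ytype

    @property
    def y_share(self) -> float:
        if self.total_ytype == 0:
            return math.nan
        return self.total_y / self.total_ytype


def tally(table: pd.DataFrame) -> TallySummary:
    """Summarize a (sex, genotype, count) table.

    Genotype strings must parse to karyotypes whose X count matches the
    stated sex.  Frequencies are computed within each sex; chromosome
    totals are exact integer sums over all rows.
    """
    if table.empty:
        raise ValueError("empty karyotype count table")
    required = {"sex", "genotype", "count"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    counts: Dict[str, Dict[KaryoGenotype, int]] = {}
    total_y = total_ys = 0
    for row in table.itertuples(index=False):
        genotype = parse_genotype(str(row.genotype))
        count = int(row.count)
        if count < 0:
            raise ValueError(f"negative count for {row.genotype}")
        sx = str(row.sex).strip().lower()
        if sex_of(genotype) != sx:
            raise ValueError(
                f"genotype {row.genotype} is {sex_of(genotype)}, table says {sx}"
            )
        counts.setdefault(sx, {})
        counts[sx][genotype] = counts[sx].get(genotype, 0) + count
        total_y += count * genotype.n_y
        total_ys += count * genotype.n_ys
    n_by_sex = {sx: sum(c.values()) for sx, c in counts.items()}
    frequencies = {
        sx: {g: c / n_by_sex[sx] for g, c in per.items()}
        for sx, per in counts.items()
        if n_by_sex[sx] > 0
    }
    return TallySummary(
        n_individuals=sum(n_by_sex.values()),
        n_by_sex=n_by_sex,
        frequencies=frequencies,
        total_y=total_y,
        total_ys=total_ys,
    )


# --- I/O -------------------------------------------------------------------


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV karyotype count table with header (sex, genotype, count)."""
    table = pd.read_csv(path, sep="\t", dtype={"sex": str, "genotype": str})
    table["count"] = table["count"].astype(int)
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ddpcr_table(
    path,
    efficiency_y: float = DEFAULT_Y_EFFICIENCY,
    efficiency_x: float = DEFAULT_X_EFFICIENCY,
) -> List[DdpcrSample]:
    """Read a ddPCR CSV with header (sample_id, pp1y2_rpl32, pry_rpl32, upf1_rpl32)."""
    table = pd.read_csv(path)
    samples = []
    for row in table.itertuples(index=False):
        samples.append(
            DdpcrSample(
                sample_id=str(row.sample_id),
                r_total_y=float(row.pp1y2_rpl32),
                r_full_y=float(row.pry_rpl32),
                r_x=float(row.upf1_rpl32),
                efficiency_y=efficiency_y,
                efficiency_x=efficiency_x,
            )
        )
    return samples


def call_ddpcr_table(samples: List[DdpcrSample]) -> pd.DataFrame:
    """Call every sample; output columns sample_id, genotype, n_y, n_ys, flags."""
    rows = []
    for sample in samples:
        call = call_karyotype(sample)
        rows.append(
            {
                "sample_id": call.sample_id,
                "genotype": format_genotype(call.genotype),
                "n_y": call.genotype.n_y,
                "n_ys": call.genotype.n_ys,
                "flags": ";".join(call.flags),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "n_y", "n_ys", "flags"])
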