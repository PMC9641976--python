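"""Seeded generators of synthetic karyotype tables and ddPCR measurements.

These emulate the two kinds of empirical input the analysis consumes:
karyotype count tables (multinomial draws of individuals from a stated
per-sex karyotype distribution, as a FISH-karyotyping experiment would
produce) and per-fly ddPCR copy-number ratios (true copy numbers scaled
by per-assay efficiency, plus independent additive Gaussian noise per
assay, truncated at 0).  At zero noise, ``simulate_ddpcr`` is the exact
inverse of the karyotype caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd

from .empirical import DEFAULT_X_EFFICIENCY, DEFAULT_Y_EFFICIENCY, DdpcrSample
from .genotypes import KaryoGenotype, format_genotype, sex_of
from .observations import OBSERVED_FEMALE_FREQS, OBSERVED_MALE_FREQS

__all__ = ["SynthConfig", "sample_karyotype_counts", "simulate_ddpcr", "ddpcr_table"]


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic generators.

    Defaults mirror the observed strain: karyotype distributions from
    the FISH tallies, assay efficiencies 0.8 (Y) and 1.0 (X), no noise.
    """

    female_dist: Mapping[KaryoGenotype, float] = field(
        default_factory=lambda: dict(OBSERVED_FEMALE_FREQS)
    )
    male_dist: Mapping[KaryoGenotype, float] = field(
        default_factory=lambda: dict(OBSERVED_MALE_FREQS)
    )
    n_females: int = 48
    n_males: int = 50
    noise_sd: float = 0.0
    efficiency_y: float = DEFAULT_Y_EFFICIENCY
    efficiency_x: float = DEFAULT_X_EFFICIENCY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_females < 0 or self.n_males < 0:
            raise ValueError("sample sizes must be non-negative")


def _draw(
    dist: Mapping[KaryoGenotype, float], n: int, rng: np.random.Generator
) -> Dict[KaryoGenotype, int]:
    if n == 0:
        return {}
    genotypes = list(dist)
    probs = np.fromiter((dist[g] for g in genotypes), dtype=float)
    probs /= probs.sum()
    counts = rng.multinomial(n, probs)
    return {g: int(c) for g, c in zip(genotypes, counts) if c > 0}


def sample_karyotype_counts(
    config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Multinomial karyotype counts per sex, as a (sex, genotype, count) table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for sx_dist, n in (
        (config.female_dist, config.n_females),
        (config.male_dist, config.n_males),
    ):
        for genotype, count in sorted(_draw(sx_dist, n, rng).items()):
            rows.append(
                {
                    "sex": sex_of(genotype),
                    "genotype": format_genotype(genotype),
                    "count": count,
                }
            )
    return pd.DataFrame(rows, columns=["sex", "genotype", "count"])


def simulate_ddpcr(
    genotype: KaryoGenotype,
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "synthetic",
) -> DdpcrSample:
    """Noisy ddPCR ratios for one karyotype.

    ``r_total_y = eff_y·(n_y + n_ys) + ε``, ``r_full_y = eff_y·n_y + ε``,
    ``r_x = eff_x·n_x/2 + ε`` with independent ε ~ N(0, noise_sd²),
    truncated at 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=3) if config.noise_sd > 0 else np.zeros(3)
    return DdpcrSample(
        sample_id=sample_id,
        r_total_y=max(0.0, config.efficiency_y * genotype.n_ytype + noise[0]),
        r_full_y=max(0.0, config.efficiency_y * genotype.n_y + noise[1]),
        r_x=max(0.0, config.efficiency_x * genotype.n_x / 2.0 + noise[2]),
        efficiency_y=config.efficiency_y,
        efficiency_x=config.efficiency_x,
    )


def ddpcr_table(
    genotypes: List[KaryoGenotype],
    config: SynthConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Synthetic ddPCR CSV rows (sample_id, pp1y2_rpl32, pry_rpl32, upf1_rpl32)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for i, genotype in enumerate(genotypes):
        sample = simulate_ddpcr(genotype, config, rng, sample_id=f"fly_{i:04d}")
        rows.append(
            {
                "sample_id": sample.sample_id,
                "pp1y2_rpl32": sample.r_total_y,
                "pry_rpl32": sample.r_full_y,
                "upf1_rpl32": sample.r_x,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "pp1y2_rpl32", "pry_rpl32", "upf1_rpl32"]
    )
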