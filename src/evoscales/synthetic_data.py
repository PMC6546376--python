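"""Synthetic data with known ground truth for every analysis stage.

Two generators:

* :func:`generate_phenotypes` — an individual-level bill/tarsus series over
  calendar years, drawn from a bivariate normal with optional step change
  (level shift from a given year onward) and linear drift.  The defaults
  emulate a 26-year great tit record (1982–2007) in which the first five
  years sit ~0.45 mm below the rest and the trait drifts slowly downward
  (−0.011 mm/yr), so a full-range regression is positive while the
  post-step trend is negative.

* :func:`generate_structured_genotypes` — a two-population diploid SNP panel
  under the Balding–Nichols model: per-SNP subpopulation frequencies are
  Beta-distributed around an ancestral frequency with dispersion set by the
  target FST, optionally with a set of extra-divergent SNPs shifted by
  ±delta_p/2 in opposite directions.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .popgen_stats import GenotypeMatrix

__all__ = [
    "PhenoSimConfig",
    "StructuredPopConfig",
    "generate_phenotypes",
    "generate_structured_genotypes",
    "substream_seeds",
]


def substream_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-stage seeds (< 2^31) from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class PhenoSimConfig:
    """Bivariate-normal phenotype series with optional step and drift.

    Means at year t are ``mean0 + slope*(t - years[0]) + step*[t >= step_year]``
    for each trait; (bill, tarsus) are drawn jointly with correlation ``rho``.
    All length units are mm.
    """

    years: tuple[int, ...] = tuple(range(1982, 2008))
    n_per_year: int = 30
    bill_mean0: float = 13.2
    tarsus_mean0: float = 19.2
    bill_sd: float = 0.45
    tarsus_sd: float = 0.60
    rho: float = 0.5
    step_year: int | None = 1987
    step_bill: float = 0.45
    step_tarsus: float = 0.65
    slope_bill: float = -0.011
    slope_tarsus: float = -0.016
    seed: int = 0
    site: str = "UK"

    def __post_init__(self):
        if len(self.years) == 0:
            raise ValueError("years must be non-empty")
        if any(b >= a for a, b in zip(self.years[1:], self.years[:-1])):
            raise ValueError("years must be strictly increasing")
        if self.n_per_year < 2:
            raise ValueError("n_per_year must be >= 2")
        if not (-1 <= self.rho <= 1):
            raise ValueError("rho must be in [-1, 1]")
        if self.bill_sd < 0 or self.tarsus_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def generate_phenotypes(config: PhenoSimConfig) -> pd.DataFrame:
    """One record per bird-year: id, year, bill_mm, tarsus_mm, sex, site."""
    rng = np.random.default_rng(config.seed)
    cov = np.array(
        [
            [config.bill_sd**2, config.rho * config.bill_sd * config.tarsus_sd],
            [config.rho * config.bill_sd * config.tarsus_sd, config.tarsus_sd**2],
        ]
    )
    y0 = config.years[0]
    frames = []
    uid = 0
    for year in config.years:
        stepped = config.step_year is not None and year >= config.step_year
        mb = (
            config.bill_mean0
            + config.slope_bill * (year - y0)
            + (config.step_bill if stepped else 0.0)
        )
        mt = (
            config.tarsus_mean0
            + config.slope_tarsus * (year - y0)
            + (config.step_tarsus if stepped else 0.0)
        )
        # eigh tolerates the singular covariance of noise-free configs
        draws = rng.multivariate_normal(
            [mb, mt], cov, size=config.n_per_year, method="eigh"
        )
        sex = rng.choice(["F", "M"], size=config.n_per_year)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"bird{uid + i}" for i in range(config.n_per_year)],
                    "year": year,
                    "bill_mm": draws[:, 0],
                    "tarsus_mm": draws[:, 1],
                    "sex": sex,
                    "site": config.site,
                }
            )
        )
        uid += config.n_per_year
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class StructuredPopConfig:
    """Two-population Balding–Nichols genotype panel with target FST."""

    n_per_pop: int = 100
    n_snps: int = 5000
    fst_target: float = 0.1
    anc_freq_range: tuple[float, float] = (0.1, 0.9)
    n_divergent: int = 0
    delta_p: float = 0.3
    spacing_bp: int = 1000
    pop_names: tuple[str, str] = ("UK", "NL")
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must be in [0, 1)")
        if self.n_divergent > self.n_snps:
            raise ValueError("n_divergent cannot exceed n_snps")
        lo, hi = self.anc_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral frequency bounds must satisfy 0 < lo <= hi < 1")
        if self.n_per_pop < 1 or self.n_snps < 1:
            raise ValueError("n_per_pop and n_snps must be positive")


def generate_structured_genotypes(
    config: StructuredPopConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotype matrix with population labels plus the divergent-SNP indices.

    Subpopulation frequencies follow Beta(p (1-F)/F, (1-p)(1-F)/F) around a
    Uniform ancestral frequency p (F = 0 gives p exactly); genotypes are
    Binomial(2, p_pop).  The first ``n_divergent`` SNP indices (chosen at
    random) receive ±delta_p/2 shifts in opposite directions, clipped to
    (0, 1).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.anc_freq_range
    p_anc = rng.uniform(lo, hi, size=config.n_snps)
    f = config.fst_target
    if f == 0:
        p1 = p_anc.copy()
        p2 = p_anc.copy()
    else:
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    divergent = np.sort(rng.choice(config.n_snps, size=config.n_divergent, replace=False))
    eps = 1e-9
    p1[divergent] = np.clip(p1[divergent] + config.delta_p / 2, eps, 1 - eps)
    p2[divergent] = np.clip(p2[divergent] - config.delta_p / 2, eps, 1 - eps)
    g1 = rng.binomial(2, p1, size=(config.n_per_pop, config.n_snps))
    g2 = rng.binomial(2, p2, size=(config.n_per_pop, config.n_snps))
    dosages = np.vstack([g1, g2]).astype(np.int16)
    labels = np.array(
        [config.pop_names[0]] * config.n_per_pop
        + [config.pop_names[1]] * config.n_per_pop
    )
    positions = np.arange(config.n_snps, dtype=np.int64) * config.spacing_bp
    gm = GenotypeMatrix(dosages, positions, chrom="1", pop_labels=labels)
    return gm, divergent
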