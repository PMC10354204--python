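"""Taphonomically corrected community abundance, rarefaction, biomass pyramid.

Skeletal counts from a fossil census under-represent small-bodied species,
because small skeletons are preferentially destroyed and overlooked.  The
Amboseli landscape calibration expresses the ratio of living animals (N) to
skeletons (S) as a power law of body mass W (kg):

    log10(N/S) = 1.96 - 0.45 log10 W,   i.e.  N/S = 91.20 W**-0.45

Multiplying each species' skeletal count by its N/S factor and renormalising
gives corrected relative abundances; weighting those by per-capita mass
gives relative standing-crop biomass, arranged by trophic level into a
biomass pyramid.  Sampling completeness is assessed by individual-based
rarefaction with an unconditional variance (one that does not collapse to
zero at the full census size, acknowledging undetected species via a Chao1
richness estimate).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "NS_LOG_INTERCEPT",
    "NS_LOG_SLOPE",
    "validate_census",
    "retrocalc_counts",
    "ns_ratio",
    "correct_abundance",
    "chao1",
    "RarefactionCurve",
    "rarefy",
    "BiomassPyramid",
    "biomass_pyramid",
]

# Amboseli landscape-to-skeleton calibration, body mass in kg
NS_LOG_INTERCEPT = 1.96
NS_LOG_SLOPE = -0.45

CENSUS_COLUMNS = ("species", "count", "mass_kg", "trophic_level")


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    """Check a census table (species, count, mass_kg, trophic_level)."""
    missing = [c for c in CENSUS_COLUMNS if c not in census.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")
    if census["species"].duplicated().any():
        dupes = census.loc[census["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicated species in census: {dupes}")
    counts = census["count"].to_numpy()
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    if (census["mass_kg"].to_numpy() <= 0).any():
        raise ValueError("per-capita masses must be positive")
    return census


def retrocalc_counts(percentages: Mapping[str, float], total: int) -> dict[str, int]:
    """Convert relative abundances (%) back to integer counts summing to total.

    Uses largest-remainder rounding so the retrocalculated counts sum to the
    published tally exactly.
    """
    if total <= 0 or int(total) != total:
        raise ValueError("total must be a positive integer")
    names = list(percentages)
    p = np.array([percentages[k] for k in names], dtype=float)
    if (p < 0).any():
        raise ValueError("percentages must be nonnegative")
    if p.sum() > 100.0 + 1e-6:
        raise ValueError(f"percentages sum to {p.sum():.6f} > 100")
    exact = p * total / 100.0
    base = np.floor(exact).astype(int)
    short = int(round(exact.sum())) - int(base.sum())
    # hand the leftover units to the largest fractional remainders
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {name: int(c) for name, c in zip(names, base)}


def ns_ratio(mass_kg: float) -> float:
    """Animals-on-landscape to skeletons-observed ratio for body mass W (kg)."""
    W = np.asarray(mass_kg, dtype=float)
    if np.any(W <= 0):
        raise ValueError("mass must be positive")
    out = 10.0 ** (NS_LOG_INTERCEPT + NS_LOG_SLOPE * np.log10(W))
    return float(out) if out.ndim == 0 else out


def correct_abundance(census: pd.DataFrame) -> pd.Series:
    """Taphonomically corrected relative abundance (%), indexed by species."""
    census = validate_census(census)
    counts = census["count"].to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("census has no individuals")
    weights = counts * ns_ratio(census["mass_kg"].to_numpy())
    shares = 100.0 * weights / weights.sum()
    return pd.Series(shares, index=census["species"].to_numpy(), name="corrected_pct")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def chao1(counts: Sequence[int]) -> float:
    """Bias-corrected Chao1 total-richness estimate from abundance counts."""
    c = np.asarray([v for v in counts if v > 0], dtype=int)
    s_obs = len(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


@dataclasses.dataclass
class RarefactionCurve:
    n: np.ndarray  # subsample sizes
    expected: np.ndarray  # E[S_n]
    variance: np.ndarray  # unconditional variance
    low: np.ndarray  # 95% band
    high: np.ndarray
    richness_estimate: float  # Chao1 used by the unconditional variance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n,
                "expected_richness": self.expected,
                "variance": self.variance,
                "low95": self.low,
                "high95": self.high,
            }
        )


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(counts: Sequence[int], n_grid: Sequence[int] | None = None) -> RarefactionCurve:
    """Individual-based rarefaction with unconditional variance.

    E[S_n] = sum_i 1 - C(N - N_i, n) / C(N, n), evaluated with log-gamma
    combinatorics.  The variance is unconditional on the census being the
    complete assemblage: with detection probability p_i = 1 - alpha_i and an
    estimated assemblage richness S~ (Chao1),

        var(S_n) = sum_i p_i**2 - E[S_n]**2 / S~

    which is nonnegative and remains positive at n = N whenever Chao1
    exceeds the observed richness, so the band does not pinch shut at the
    full census.  The 95% band is a normal approximation.
    """
    c = np.asarray(counts, dtype=int)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    c = c[c > 0]
    N = int(c.sum())
    if N == 0:
        raise ValueError("no individuals to rarefy")
    if n_grid is None:
        n_grid = np.unique(np.linspace(1, N, num=min(N, 50)).astype(int))
    n_arr = np.asarray(n_grid, dtype=int)
    if (n_arr < 0).any() or (n_arr > N).any():
        raise ValueError(f"subsample sizes must lie in [0, {N}]")

    s_tilde = chao1(c)
    logCN = _log_choose(N, n_arr)  # per grid point
    # alpha[i, g] = C(N - N_i, n_g) / C(N, n_g), zero when n_g > N - N_i
    expected = np.zeros(len(n_arr))
    sum_p2 = np.zeros(len(n_arr))
    for Ni in c:
        with np.errstate(invalid="ignore"):
            valid = n_arr <= N - Ni
            alpha = np.zeros(len(n_arr))
            alpha[valid] = np.exp(_log_choose(N - Ni, n_arr[valid]) - logCN[valid])
        p = 1.0 - alpha
        expected += p
        sum_p2 += p * p
    variance = np.maximum(sum_p2 - expected**2 / s_tilde, 0.0)
    sd = np.sqrt(variance)
    return RarefactionCurve(
        n=n_arr,
        expected=expected,
        variance=variance,
        low=expected - 1.959963984540054 * sd,
        high=expected + 1.959963984540054 * sd,
        richness_estimate=s_tilde,
    )


# ---------------------------------------------------------------------------
# Biomass pyramid
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BiomassPyramid:
    species_abundance_pct: pd.Series  # corrected relative abundance, sums to 100
    species_biomass_pct: pd.Series  # relative biomass, sums to 100
    level_biomass_pct: pd.Series  # biomass share per trophic level, sums to 100
    within_level_pct: pd.Series  # species' biomass share within its own level

    def to_dict(self) -> dict:
        return {
            "species_abundance_pct": self.species_abundance_pct.to_dict(),
            "species_biomass_pct": self.species_biomass_pct.to_dict(),
            "level_biomass_pct": self.level_biomass_pct.to_dict(),
            "within_level_pct": self.within_level_pct.to_dict(),
        }


def biomass_pyramid(
    census: pd.DataFrame,
    corrected_pct: pd.Series,
    allowed_levels: Sequence[str] | None = None,
) -> BiomassPyramid:
    """Relative standing-crop biomass by species and trophic level.

    ``corrected_pct`` must align with the census species; biomass share of a
    species is its corrected abundance times per-capita mass, renormalised
    to 100%.  ``allowed_levels`` enables strict label checking.
    """
    census = validate_census(census)
    sp = census["species"].to_numpy()
    if set(corrected_pct.index) != set(sp):
        raise ValueError("corrected shares do not align with census species")
    if allowed_levels is not None:
        bad = sorted(set(census["trophic_level"]) - set(allowed_levels))
        if bad:
            raise ValueError(f"unknown trophic levels: {bad}")
    shares = corrected_pct.reindex(sp).to_numpy(dtype=float)
    biomass = shares * census["mass_kg"].to_numpy(dtype=float)
    biomass_pct = pd.Series(100.0 * biomass / biomass.sum(), index=sp)
    levels = census["trophic_level"].to_numpy()
    level_tot = biomass_pct.groupby(levels).sum()
    within = pd.Series(
        [100.0 * biomass_pct[s] / level_tot[l] for s, l in zip(sp, levels)], index=sp
    )
    return BiomassPyramid(
        species_abundance_pct=pd.Series(shares, index=sp),
        species_biomass_pct=biomass_pct,
        level_biomass_pct=pd.Series(100.0 * level_tot / level_tot.sum(), index=level_tot.index),
        within_level_pct=within,
    )
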