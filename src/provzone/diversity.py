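"""Per-population diversity summaries for dominant markers.

Dominant (band presence/absence) markers hide the heterozygote, so allele
frequencies are estimated from the band-absent fraction: under Hardy-Weinberg
equilibrium the null-allele frequency is q = sqrt(n_absent / n_total).  The
species is an obligate outcrosser, which justifies the HWE assumption; an
optional Lynch-Milligan first-order bias correction is available behind a
flag.  Expected heterozygosity uses Nei's small-sample correction with 2n
gene copies, so values can marginally exceed 0.5 at small n.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, MarkerMatrix, ValidationError


def dominant_allele_frequency(
    n_present: int | np.ndarray, n_total: int | np.ndarray, lynch_milligan: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (q, p): null-allele and band-allele frequency at a dominant locus.

    q-hat = sqrt(x) with x the band-absent fraction; with ``lynch_milligan``
    the first-order bias correction q-hat = sqrt(x) / (1 - Var(x)/(8 x^2)) is
    applied where x > 0.
    """
    n_present = np.asarray(n_present, dtype=float)
    n_total = np.asarray(n_total, dtype=float)
    if (n_total < 1).any():
        raise ValidationError("n_total must be >= 1")
    if ((n_present < 0) | (n_present > n_total)).any():
        raise ValidationError("n_present must lie in [0, n_total]")
    x = (n_total - n_present) / n_total
    q = np.sqrt(x)
    if lynch_milligan:
        with np.errstate(divide="ignore", invalid="ignore"):
            var_x = x * (1.0 - x) / n_total
            corr = 1.0 - var_x / (8.0 * x**2)
            q = np.where(x > 0, np.sqrt(x) / np.where(corr > 0, corr, 1.0), 0.0)
    q = np.clip(q, 0.0, 1.0)
    return q, 1.0 - q


def expected_heterozygosity(p: float | np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Unbiased expected heterozygosity 2n/(2n-1) * 2p(1-p) for sample size n."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p outside [0, 1]")
    if (n < 2).any():
        raise ValidationError("n must be >= 2")
    return (2 * n / (2 * n - 1)) * 2 * p * (1 - p)


def _band_counts(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (n_present, n_scored) for one population's rows."""
    scored = rows != MISSING
    present = (rows == 1) & scored
    return present.sum(axis=0).astype(float), scored.sum(axis=0).astype(float)


def locally_common_bands(
    m: MarkerMatrix, freq_min: float = 0.05, pop_fraction_max: float = 0.5
) -> pd.Series:
    """Count, per population, loci locally common there but geographically restricted.

    A locus counts for a population when its band frequency there is at least
    ``freq_min`` while the band occurs in at most ``pop_fraction_max`` of all
    populations.
    """
    if not (0 < freq_min <= 1 and 0 < pop_fraction_max <= 1):
        raise ValidationError("thresholds must lie in (0, 1]")
    pops = m.populations()
    freq = np.zeros((len(pops), m.n_loci))
    occurs = np.zeros_like(freq, dtype=bool)
    for k, pop in enumerate(pops):
        n_present, n_tot = _band_counts(m.population_rows(pop))
        with np.errstate(invalid="ignore"):
            freq[k] = np.where(n_tot > 0, n_present / np.maximum(n_tot, 1), 0.0)
        occurs[k] = n_present > 0
    restricted = occurs.mean(axis=0) <= pop_fraction_max
    counts = ((freq >= freq_min) & restricted[None, :]).sum(axis=1)
    return pd.Series(counts, index=pops, name="f_locally_common")


def private_bands(m: MarkerMatrix) -> pd.Series:
    """Count, per population, loci whose band occurs in that population only."""
    pops = m.populations()
    occurs = np.zeros((len(pops), m.n_loci), dtype=bool)
    for k, pop in enumerate(pops):
        occurs[k] = (m.population_rows(pop) == 1).any(axis=0)
    unique = occurs.sum(axis=0) == 1
    return pd.Series((occurs & unique[None, :]).sum(axis=1), index=pops, name="private_bands")


def aggregate_means(per_population: pd.DataFrame) -> pd.Series:
    """Equally weighted across-population means of the numeric summary columns."""
    return per_population.select_dtypes("number").mean(axis=0)


@dataclasses.dataclass
class DiversityResult:
    """Per-population table plus equally weighted across-population means."""

    per_population: pd.DataFrame  # index population; n, plp, he_mean, he_se, ...
    means: pd.Series


def population_diversity(m: MarkerMatrix, lynch_milligan: bool = False) -> DiversityResult:
    """Sample size, %polymorphic loci, expected heterozygosity and band counts per population.

    A locus is polymorphic in a population when both band states are observed
    there (no frequency cutoff).  He is averaged over all scored loci, with
    its standard error taken across loci.
    """
    pops = m.populations()
    f_common = locally_common_bands(m)
    f_private = private_bands(m)
    rows = []
    for pop in pops:
        sub = m.population_rows(pop)
        n_present, n_tot = _band_counts(sub)
        if (n_tot < 2).any():
            raise ValidationError(f"population {pop!r} has a locus scored in <2 individuals")
        n = int(round(n_tot.mean()))
        poly = (n_present > 0) & (n_present < n_tot)
        plp = 100.0 * poly.sum() / len(n_tot)
        _, p = dominant_allele_frequency(n_present, n_tot, lynch_milligan=lynch_milligan)
        he = expected_heterozygosity(p, n_tot)
        rows.append(
            {
                "population": pop,
                "n": n,
                "plp": plp,
                "he_mean": float(he.mean()),
                "he_se": float(he.std(ddof=1) / np.sqrt(len(he))),
                "f_locally_common": int(f_common[pop]),
                "private_bands": int(f_private[pop]),
            }
        )
    table = pd.DataFrame(rows).set_index("population")
    means = aggregate_means(table)
    return DiversityResult(per_population=table, means=means)


def diversity_size_regression(x, y) -> dict:
    """OLS of a diversity index on sample size: slope, intercept, R^2 and F-test p.

    For simple regression the slope t-test is identical to the F(1, n-2) test,
    so scipy's linregress p-value is reported as the regression p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >=3 paired points")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; regression undefined")
    fit = stats.linregress(x, y)
    r2 = 0.0 if np.ptp(y) == 0 else fit.rvalue**2
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": float(r2),
        "p_value": float(fit.pvalue) if np.ptp(y) != 0 else 1.0,
        "n": int(x.size),
    }
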