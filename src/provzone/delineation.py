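"""Provenance-zone delineation from pairwise differentiation vs distance.

The pairwise ANOSIM R statistics are joined to great-circle distances between
sites, a low-order polynomial is fitted to R as a function of distance, and
three headline quantities are extracted:

* the minimum (and second-minimum) distance at which a significantly
  differentiated pair occurs — the lower bound of a "safe" collection radius;
* the global provenance distance — the smallest distance, inside the sampled
  range, at which the fitted curve crosses the global R value;
* the full-differentiation threshold — the largest distance at which any
  non-significant pair is still found (beyond it, every pair differs).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import DistMatrix, SiteTable, ValidationError, geographic_distance_matrix


def build_pair_table(pairs_genetic: pd.DataFrame, sites: SiteTable) -> pd.DataFrame:
    """Join a pairwise-statistics table (pop_a, pop_b, ...) with distances in km."""
    geo = geographic_distance_matrix(sites)
    idx = {p: i for i, p in enumerate(geo.labels)}
    missing = (set(pairs_genetic["pop_a"]) | set(pairs_genetic["pop_b"])) - set(idx)
    if missing:
        raise ValidationError(f"populations missing from site table: {sorted(missing)}")
    out = pairs_genetic.copy()
    out.insert(
        2,
        "distance_km",
        [
            geo.values[idx[a], idx[b]]
            for a, b in zip(out["pop_a"], out["pop_b"])
        ],
    )
    return out


def fit_R_distance_curve(pairs: pd.DataFrame, degree: int = 2) -> np.polynomial.Polynomial:
    """Least-squares polynomial of pairwise R on distance (km)."""
    if degree < 1:
        raise ValidationError("degree must be >= 1")
    if len(pairs) < degree + 1:
        raise ValidationError("not enough pairs for the requested degree")
    return np.polynomial.Polynomial.fit(
        pairs["distance_km"].to_numpy(float), pairs["R"].to_numpy(float), degree
    ).convert()


def provenance_distance(
    fit: np.polynomial.Polynomial, R_global: float, d_range: tuple[float, float]
) -> float | None:
    """Smallest distance in ``d_range`` where the fitted curve reaches R_global.

    Root-finding on fit(d) - R_global restricted to the sampled range; a grid
    + bisection fallback guards against root-solver misses.  Returns None when
    the curve never crosses inside the range (reported as undefined, never
    extrapolated).
    """
    lo, hi = float(d_range[0]), float(d_range[1])
    if not lo < hi:
        raise ValidationError("empty distance range")
    g = fit - R_global
    candidates = [
        float(r.real)
        for r in g.roots()
        if abs(r.imag) < 1e-9 and lo - 1e-9 <= r.real <= hi + 1e-9
    ]
    if candidates:
        return float(np.clip(min(candidates), lo, hi))
    # bisection fallback on a sign change over a dense grid
    xs = np.linspace(lo, hi, 2049)
    ys = g(xs)
    sign = np.sign(ys)
    change = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if change.size == 0:
        return None
    a, b = xs[change[0]], xs[change[0] + 1]
    for _ in range(80):
        mid = (a + b) / 2
        if g(a) * g(mid) <= 0:
            b = mid
        else:
            a = mid
    return float((a + b) / 2)


def min_significant_distance(
    pairs: pd.DataFrame, rule: str = "sig_perm"
) -> tuple[float | None, float | None]:
    """Smallest and second-smallest distances among significant pairs."""
    d = np.sort(pairs.loc[pairs[rule].astype(bool), "distance_km"].to_numpy(float))
    if d.size == 0:
        return None, None
    if d.size == 1:
        return float(d[0]), None
    return float(d[0]), float(d[1])


def full_differentiation_threshold(pairs: pd.DataFrame, rule: str = "sig_perm") -> tuple[float, bool]:
    """Maximum distance among non-significant pairs; all pairs beyond it differ.

    Returns ``(threshold_km, all_significant)``; when every pair is
    significant the threshold is 0 with the flag set.
    """
    nonsig = pairs.loc[~pairs[rule].astype(bool), "distance_km"]
    if nonsig.empty:
        return 0.0, True
    return float(nonsig.max()), False


def band_summary(
    pairs: pd.DataFrame, d_lo: float, d_hi: float, R_global: float
) -> dict:
    """Fraction of pairs in the distance band [d_lo, d_hi) with R below R_global."""
    if not d_lo < d_hi:
        raise ValidationError("d_lo must be < d_hi")
    band = pairs[(pairs["distance_km"] >= d_lo) & (pairs["distance_km"] < d_hi)]
    if band.empty:
        return {"d_lo": d_lo, "d_hi": d_hi, "n_pairs": 0, "fraction_below": None}
    frac = float((band["R"] < R_global).mean())
    return {"d_lo": d_lo, "d_hi": d_hi, "n_pairs": int(len(band)), "fraction_below": frac}


@dataclasses.dataclass
class ProvenanceResult:
    """Headline distances of the delineation plus the fit they came from."""

    R_global: float
    fit_degree: int
    fit_coefficients: list[float]  # ascending powers
    d_min_sig: float | None
    d_second_sig: float | None
    d_provenance: float | None
    d_full_diff: float
    all_pairs_significant: bool
    rule: str
    band_summaries: list[dict]

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def delineate(
    pairs: pd.DataFrame,
    R_global: float,
    degree: int = 2,
    rule: str = "sig_perm",
    global_p: float | None = None,
    alpha: float = 0.05,
) -> ProvenanceResult:
    """Run the full delineation on a joined pair table (flags already attached).

    When the global R's permutation p is supplied and is not significant at
    ``alpha``, the provenance distance is reported undefined: with no global
    structure, a crossing of the (near-flat) fitted curve with a near-zero
    global R carries no delineation meaning.
    """
    fit = fit_R_distance_curve(pairs, degree=degree)
    d = pairs["distance_km"].to_numpy(float)
    if global_p is not None and global_p >= alpha:
        d_prov = None
    else:
        d_prov = provenance_distance(fit, R_global, (float(d.min()), float(d.max())))
    d_min, d_second = min_significant_distance(pairs, rule=rule)
    d_full, all_sig = full_differentiation_threshold(pairs, rule=rule)
    bands = []
    if d_prov is not None and d_prov < d_full:
        bands.append(band_summary(pairs, d_prov, d_full, R_global))
    return ProvenanceResult(
        R_global=float(R_global),
        fit_degree=int(degree),
        fit_coefficients=[float(c) for c in fit.coef],
        d_min_sig=d_min,
        d_second_sig=d_second,
        d_provenance=d_prov,
        d_full_diff=d_full,
        all_pairs_significant=all_sig,
        rule=rule,
        band_summaries=bands,
    )
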