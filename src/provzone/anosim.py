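"""Analysis of similarities (ANOSIM): rank-based group separation.

R contrasts the mean rank of between-group dissimilarities with the mean rank
of within-group dissimilarities, scaled by M/2 where M = n(n-1)/2 is the
number of dissimilarities.  R is 0 in expectation under exchangeable labels
and 1 when every between-group dissimilarity exceeds every within-group one.
Ties take average ranks.  Significance comes from permuting labels with group
sizes fixed.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .amova import squared_distance_matrix
from .io import DistMatrix, MarkerMatrix, ValidationError


def rank_dissimilarities(d: DistMatrix) -> np.ndarray:
    """Average ranks of the n(n-1)/2 off-diagonal dissimilarities."""
    if d.n < 2:
        raise ValidationError("need >=2 entities")
    return rankdata(d.condensed(), method="average")


def _between_mask(codes: np.ndarray) -> np.ndarray:
    """Condensed-order boolean mask: True where the pair spans two groups."""
    n = codes.size
    iu, ju = np.triu_indices(n, k=1)
    return codes[iu] != codes[ju]


def _r_from_ranks(ranks: np.ndarray, between: np.ndarray) -> float:
    m = ranks.size
    r_between = ranks[between].mean()
    r_within = ranks[~between].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim_R(d: DistMatrix, labels) -> float:
    """The ANOSIM R statistic for a grouping of the distance matrix entities."""
    labels = [str(l) for l in labels]
    if len(labels) != d.n:
        raise ValidationError("label count does not match matrix")
    _, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if codes.max() + 1 < 2:
        raise ValidationError("need >=2 groups")
    if (sizes < 2).any():
        raise ValidationError("every group needs >=2 members")
    ranks = rank_dissimilarities(d)
    return _r_from_ranks(ranks, _between_mask(codes))


@dataclasses.dataclass
class AnosimResult:
    R: float
    p_value: float
    n_perm: int
    group_sizes: dict[str, int]


def anosim_test(
    d: DistMatrix,
    labels,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "sampled",
) -> AnosimResult:
    """ANOSIM with permutation p = (1 + #{R_perm >= R_obs}) / (n_perm + 1).

    ``method="exact"`` enumerates every label ordering instead of sampling
    (feasible for <=9 individuals); the exact p is the fraction of orderings,
    identity included, with R at least the observed one.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = [str(l) for l in labels]
    pops, codes = np.unique(labels, return_inverse=True)
    r_obs = anosim_R(d, labels)
    ranks = rank_dissimilarities(d)
    sizes = {str(p): int(c) for p, c in zip(pops, np.bincount(codes))}
    if method == "exact":
        if len(codes) > 9:
            raise ValidationError("exact enumeration limited to <=9 individuals")
        all_r = [
            _r_from_ranks(ranks, _between_mask(np.asarray(perm)))
            for perm in itertools.permutations(codes)
        ]
        all_r = np.asarray(all_r)
        p = float((all_r >= r_obs - 1e-12).mean())
        return AnosimResult(R=r_obs, p_value=p, n_perm=all_r.size, group_sizes=sizes)
    if method != "sampled":
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _r_from_ranks(ranks, _between_mask(perm)) >= r_obs - 1e-12:
            hits += 1
    return AnosimResult(
        R=r_obs, p_value=(1 + hits) / (n_perm + 1), n_perm=n_perm, group_sizes=sizes
    )


def global_anosim(
    m: MarkerMatrix, n_perm: int = 9999, seed: int | None = None
) -> AnosimResult:
    """Global ANOSIM over all individuals, on binary squared distances."""
    return anosim_test(
        squared_distance_matrix(m), m.population_labels, n_perm=n_perm, seed=seed
    )


def pairwise_anosim(
    m: MarkerMatrix, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """R and permutation p for every unordered population pair."""
    pops = m.populations()
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(pops, 2):
        sub = m.subset_populations([a, b])
        res = anosim_test(
            squared_distance_matrix(sub),
            sub.population_labels,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        rows.append({"pop_a": a, "pop_b": b, "R": res.R, "p_value": res.p_value})
    return pd.DataFrame(rows)


def global_R_rule(pairs: pd.DataFrame, R_global: float, alpha: float = 0.05) -> pd.DataFrame:
    """Attach both pairwise significance flags to a pair table.

    ``sig_globalR``: pairwise R at least the global R (the curve-threshold
    rule); ``sig_perm``: permutation p below ``alpha``.  Both are carried so
    either rule can drive the delineation.
    """
    if not -1 <= R_global <= 1:
        raise ValidationError("R_global outside [-1, 1]")
    out = pairs.copy()
    out["sig_globalR"] = out["R"] >= R_global
    out["sig_perm"] = out["p_value"] < alpha
    return out
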