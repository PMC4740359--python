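"""Climate preparation and (partial) Mantel tests.

Climate variables are pruned for collinearity (|Pearson r| > 0.8 against an
already-retained column), log10(x+1) transformed, z-scored per variable and
turned into Euclidean site-by-site distances.  The Mantel statistic is the
Pearson correlation of the upper-triangle entries of two distance matrices;
its significance comes from jointly permuting rows and columns of the first
matrix.  The partial variant removes the linear effect of a third matrix:

    r_AB.C = (r_AB - r_AC * r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))

with the same permutation scheme, recomputing the partial statistic per
permutation.  P-values are one-tailed (>=) by default, matching directional
isolation-by-distance hypotheses; two-tailed is available by flag.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import ClimateTable, DistMatrix, ValidationError


def prune_correlated(c: ClimateTable, r_max: float = 0.8) -> tuple[ClimateTable, list[str]]:
    """Greedy column-order pruning of highly correlated climate variables.

    Scans variables left to right; drops any whose absolute Pearson
    correlation with an already-retained variable exceeds ``r_max``.  Constant
    columns (undefined correlation) are dropped.  Returns the reduced table
    and the dropped-variable list (auditable: retention is order-dependent).
    """
    if len(c.variables) < 2:
        raise ValidationError("need >=2 variables to prune")
    vals = c.values()
    kept: list[int] = []
    dropped: list[str] = []
    for j, name in enumerate(c.variables):
        col = vals[:, j]
        if np.ptp(col) == 0:
            dropped.append(name)
            continue
        high = any(abs(np.corrcoef(col, vals[:, k])[0, 1]) > r_max for k in kept)
        if high:
            dropped.append(name)
        else:
            kept.append(j)
    reduced = c.table[["population"] + [c.variables[j] for j in kept]].copy()
    return ClimateTable(reduced), dropped


def log_transform(c: ClimateTable) -> ClimateTable:
    """Elementwise log10(x + 1); values below -1 are a domain error."""
    vals = c.values()
    if (vals <= -1).any():
        raise ValidationError("log10(x+1) undefined for x <= -1")
    out = c.table.copy()
    out.iloc[:, 1:] = np.log10(vals + 1.0)
    return ClimateTable(out)


def climate_distance(c: ClimateTable, normalize: bool = True) -> DistMatrix:
    """Euclidean distances between site climate vectors (z-scored per variable)."""
    vals = c.values()
    if vals.shape[0] < 2:
        raise ValidationError("need >=2 sites")
    if normalize:
        sd = vals.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        vals = (vals - vals.mean(axis=0)) / sd
    diff = vals[:, None, :] - vals[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistMatrix(c.populations, d)


@dataclasses.dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    kind: str  # "simple" | "partial"
    controlled: str | None = None
    tail: str = "greater"


def _aligned(*mats: DistMatrix) -> list[np.ndarray]:
    ref = mats[0]
    out = [ref.values]
    for m in mats[1:]:
        if set(m.labels) != set(ref.labels):
            raise ValidationError("distance matrices have different label sets")
        out.append(m.reorder(ref.labels).values)
    return out


def _upper(v: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant distance vector; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _pvalue(r_obs: float, r_perm: np.ndarray, tail: str) -> float:
    if tail == "greater":
        hits = int((r_perm >= r_obs - 1e-12).sum())
    elif tail == "two-sided":
        hits = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return (1 + hits) / (r_perm.size + 1)


def mantel(
    A: DistMatrix,
    B: DistMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "greater",
    method: str = "sampled",
) -> MantelResult:
    """Simple Mantel test of matrix correlation (Pearson, label permutation).

    ``method="exact"`` enumerates all n! joint row/column permutations of A
    (feasible for n <= 8); the exact p is the fraction of permutations,
    identity included, with correlation at least the observed one.
    """
    if A.n < 4:
        raise ValidationError("need >=4 entities")
    a, b = _aligned(A, B)
    ub = _upper(b)
    r_obs = _pearson(_upper(a), ub)
    n = A.n
    if method == "exact":
        if n > 8:
            raise ValidationError("exact enumeration limited to n <= 8")
        import itertools

        r_perm = np.asarray(
            [
                _pearson(_upper(a[np.ix_(perm, perm)]), ub)
                for perm in itertools.permutations(range(n))
            ]
        )
        if tail == "greater":
            p = float((r_perm >= r_obs - 1e-12).mean())
        else:
            p = float((np.abs(r_perm) >= abs(r_obs) - 1e-12).mean())
        return MantelResult(r=r_obs, p_value=p, n_perm=r_perm.size, kind="simple",
                            tail=tail)
    if method != "sampled":
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        r_perm[t] = _pearson(_upper(a[np.ix_(perm, perm)]), ub)
    return MantelResult(
        r=r_obs, p_value=_pvalue(r_obs, r_perm, tail), n_perm=n_perm, kind="simple",
        tail=tail,
    )


def _partial_r(ua: np.ndarray, ub: np.ndarray, uc: np.ndarray) -> float:
    r_ab = _pearson(ua, ub)
    r_ac = _pearson(ua, uc)
    r_bc = _pearson(ub, uc)
    denom = (1 - r_ac**2) * (1 - r_bc**2)
    if denom <= 1e-12:
        raise ValidationError("degenerate partial correlation (|r| = 1 with control)")
    return (r_ab - r_ac * r_bc) / np.sqrt(denom)


def partial_mantel(
    A: DistMatrix,
    B: DistMatrix,
    C: DistMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "greater",
    controlled_label: str = "C",
) -> MantelResult:
    """Partial Mantel: correlation of A and B after removing the effect of C.

    A is permuted and the full partial statistic recomputed per permutation.
    """
    if A.n < 5:
        raise ValidationError("need >=5 entities")
    a, b, c = _aligned(A, B, C)
    ub, uc = _upper(b), _upper(c)
    r_obs = _partial_r(_upper(a), ub, uc)
    rng = np.random.default_rng(seed)
    n = A.n
    r_perm = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        r_perm[t] = _partial_r(_upper(a[np.ix_(perm, perm)]), ub, uc)
    return MantelResult(
        r=float(r_obs), p_value=_pvalue(float(r_obs), r_perm, tail), n_perm=n_perm,
        kind="partial", controlled=controlled_label, tail=tail,
    )


def mantel_table(results: dict[str, MantelResult]) -> pd.DataFrame:
    """Flatten named Mantel results into one tidy table."""
    rows = [
        {
            "comparison": name,
            "kind": res.kind,
            "controlled": res.controlled,
            "r": res.r,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
        }
        for name, res in results.items()
    ]
    return pd.DataFrame(rows)
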