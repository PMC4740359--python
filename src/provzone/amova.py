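"""Analysis of molecular variance (AMOVA) for binary marker phenotypes.

Total squared-distance variation among individuals is partitioned into among-
and within-population components.  For 0/1 band vectors the squared Euclidean
distance is the count of mismatching loci.  The differentiation statistic is
Phi_PT = sigma2_among / (sigma2_among + sigma2_within), an F_ST analogue for
binary phenotype data, with significance from permutation of individuals
among populations holding sample sizes fixed.

Formulas (one-level design, k populations, N individuals, unequal n_k):

    SS_total  = (1/N) * sum_{i<j} d2_ij          over all pairs
    SS_within = sum_k (1/n_k) * sum_{i<j in k} d2_ij
    SS_among  = SS_total - SS_within
    n0        = (N - sum_k n_k^2 / N) / (k - 1)
    sigma2_w  = SS_within / (N - k)
    sigma2_a  = (SS_among/(k-1) - sigma2_w) / n0
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import DistMatrix, MarkerMatrix, ValidationError


def binary_squared_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Number of loci with differing band states (== squared Euclidean for 0/1)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("band vectors differ in length")
    return int((a != b).sum())


def squared_distance_matrix(m: MarkerMatrix) -> DistMatrix:
    """Individual-by-individual squared Euclidean (mismatch-count) distances."""
    if m.has_missing():
        raise ValidationError("distance computation requires complete data")
    d2 = squareform(pdist(m.bands.astype(float), metric="sqeuclidean"))
    return DistMatrix(list(m.individual_ids), np.round(d2))


@dataclasses.dataclass
class AmovaResult:
    df_among: int
    df_within: int
    df_total: int
    ss_among: float
    ss_within: float
    ss_total: float
    ms_among: float
    ms_within: float
    n0: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_pt: float  # truncated at 0 for presentation
    phi_pt_raw: float  # untruncated diagnostic
    p_value: float | None = None
    n_perm: int | None = None

    def as_table(self) -> pd.DataFrame:
        """AMOVA table: df, SS, variance components and % variation per stratum."""
        return pd.DataFrame(
            {
                "source": ["among_populations", "within_populations", "total"],
                "df": [self.df_among, self.df_within, self.df_total],
                "ss": [self.ss_among, self.ss_within, self.ss_total],
                "variance_component": [self.sigma2_among, self.sigma2_within,
                                       self.sigma2_among + self.sigma2_within],
                "pct_variation": [self.pct_among, self.pct_within, 100.0],
            }
        )


def components_from_sums(
    ss_among: float,
    ss_within: float,
    df_among: int,
    df_within: int,
    group_sizes,
) -> AmovaResult:
    """Variance components, n0 and Phi_PT from stratum sums of squares.

    Accepts externally computed df/SS (e.g. a published AMOVA table) together
    with the per-population sample sizes, so the component path can run
    without individual-level data.
    """
    sizes = np.asarray(list(group_sizes), dtype=float)
    k = sizes.size
    n_total = sizes.sum()
    if k < 2 or (sizes < 2).any():
        raise ValidationError("need >=2 populations with >=2 individuals each")
    n0 = (n_total - (sizes**2).sum() / n_total) / (k - 1)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n0
    total = sigma2_among + sigma2_within
    phi_raw = sigma2_among / total if total > 0 else 0.0
    phi = max(phi_raw, 0.0)
    if sigma2_among >= 0 and total > 0:
        pct_among = 100.0 * sigma2_among / total
    else:
        pct_among = 0.0
    return AmovaResult(
        df_among=int(df_among),
        df_within=int(df_within),
        df_total=int(df_among + df_within),
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        ss_total=float(ss_among + ss_within),
        ms_among=float(ms_among),
        ms_within=float(ms_within),
        n0=float(n0),
        sigma2_among=float(sigma2_among),
        sigma2_within=float(sigma2_within),
        pct_among=float(pct_among),
        pct_within=float(100.0 - pct_among),
        phi_pt=float(phi),
        phi_pt_raw=float(phi_raw),
    )


def _sums_of_squares(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * idx.size)
    return ss_total, ss_within


def amova_decompose(d: DistMatrix, labels) -> AmovaResult:
    """One-level AMOVA over an individual distance matrix (no permutation p)."""
    labels = [str(l) for l in labels]
    if len(labels) != d.n:
        raise ValidationError("label count does not match distance matrix")
    pops, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if len(pops) < 2:
        raise ValidationError("need >=2 populations")
    if (sizes < 2).any():
        raise ValidationError("singleton population")
    d2 = d.values  # already squared distances by convention of this pipeline
    ss_total, ss_within = _sums_of_squares(d2, codes, len(pops))
    return components_from_sums(
        ss_total - ss_within, ss_within, len(pops) - 1, int(sizes.sum()) - len(pops), sizes
    )


def phi_pt_test(
    m: MarkerMatrix, labels=None, n_perm: int = 9999, seed: int | None = None
) -> AmovaResult:
    """AMOVA with a permutation test of Phi_PT.

    p = (1 + #{Phi_perm >= Phi_obs}) / (n_perm + 1), permuting individuals
    among populations with sample sizes held fixed.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = list(m.population_labels if labels is None else labels)
    d = squared_distance_matrix(m)
    res = amova_decompose(d, labels)
    _, codes = np.unique(labels, return_inverse=True)
    k = codes.max() + 1
    rng = np.random.default_rng(seed)
    d2 = d.values
    ss_total = d2.sum() / (2.0 * d2.shape[0])

    def _phi(ss_within: float) -> float:
        ms_a = (ss_total - ss_within) / res.df_among
        ms_w = ss_within / res.df_within
        s2a = (ms_a - ms_w) / res.n0
        total = s2a + ms_w
        return s2a / total if total > 0 else 0.0

    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        _, ss_within = _sums_of_squares(d2, perm, k)
        if _phi(ss_within) >= res.phi_pt_raw - 1e-12:
            hits += 1
    res.p_value = (1 + hits) / (n_perm + 1)
    res.n_perm = n_perm
    return res


def pairwise_phi_pt(
    m: MarkerMatrix, n_perm: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Phi_PT, its linearization and permutation p for every unordered population pair.

    ``n_perm=0`` skips the permutation tests (p reported as NaN) — useful when
    only the differentiation matrix is needed.
    """
    pops = m.populations()
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(pops, 2):
        sub = m.subset_populations([a, b])
        if n_perm == 0:
            res = amova_decompose(squared_distance_matrix(sub), sub.population_labels)
            res.p_value = float("nan")
        else:
            res = phi_pt_test(sub, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "phi_pt": res.phi_pt,
                "phi_pt_raw": res.phi_pt_raw,
                "linearized_phi": linearize_phi(res.phi_pt),
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def pairwise_phi_matrix(pairs: pd.DataFrame, pops: list[str], column: str = "linearized_phi") -> DistMatrix:
    """Assemble a symmetric population-level matrix from the pairwise table."""
    n = len(pops)
    mat = np.zeros((n, n))
    idx = {p: i for i, p in enumerate(pops)}
    for _, row in pairs.iterrows():
        i, j = idx[row["pop_a"]], idx[row["pop_b"]]
        mat[i, j] = mat[j, i] = max(float(row[column]), 0.0)
    return DistMatrix(pops, mat)


def linearize_phi(phi: float) -> float:
    """Distance-like transform Phi / (1 - Phi); requires Phi < 1."""
    if phi >= 1:
        raise ValidationError("linearization undefined for Phi >= 1")
    return phi / (1.0 - phi)


def subset_loci(m: MarkerMatrix, loci) -> MarkerMatrix:
    """Restrict a marker matrix to the listed loci (order preserved)."""
    return m.subset_loci(loci)
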