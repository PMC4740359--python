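"""Bayesian F_ST-outlier scan for dominant markers.

Differentiation of locus i in population j is modelled through a
locus-by-population parameter F_ij with

    logit(F_ij) = alpha_i * delta_i + beta_j

where beta_j is a population effect (shared demography), alpha_i a
locus-specific selection effect and delta_i its inclusion indicator.  Local
band-allele frequencies p_ij are drawn from the migration-drift equilibrium
Beta distribution

    p_ij ~ Beta(theta_ij * pi_i, theta_ij * (1 - pi_i)),   theta_ij = 1/F_ij - 1

around the ancestral frequency pi_i, and the observed band counts are
binomial with the dominant-marker presence probability 1 - (1 - p_ij)^2.
A locus is an outlier when the data require alpha_i in addition to the
population effects: the posterior odds PO_i of the inclusion model against
the neutral model carry the evidence, with log10(PO) > 2 conventionally
"decisive".  All loci with positive alpha show excess differentiation
(diversifying selection); negative alpha indicates balancing selection.

Sampling is Metropolis-within-Gibbs with logit-scale random walks for bounded
parameters and spike-and-slab indicator moves that propose alpha from its
prior on inclusion (so prior and proposal cancel in the acceptance ratio) —
posterior-equivalent to reversible jump between the two nested models.
Pilot runs tune each proposal width towards an acceptance rate in
[0.25, 0.45].
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln

from .io import MarkerMatrix, ValidationError

BETA_PRIOR_MEAN = -1.0
BETA_PRIOR_SD = 1.8
ALPHA_PRIOR_SD = 1.0


def band_count_table(m: MarkerMatrix) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per locus x population (n_present, n_total) tables; drops monomorphic loci.

    Loci with the same band state in every scored individual across the whole
    dataset carry no differentiation signal and are excluded, mirroring the
    polymorphic-only convention.  Returns (present, total, dropped_loci).
    """
    pops = m.populations()
    labels = np.asarray(m.population_labels)
    present = np.zeros((m.n_loci, len(pops)), dtype=int)
    total = np.zeros_like(present)
    for k, pop in enumerate(pops):
        rows = m.bands[labels == pop]
        scored = rows != -1
        present[:, k] = ((rows == 1) & scored).sum(axis=0)
        total[:, k] = scored.sum(axis=0)
    tot_present = present.sum(axis=1)
    poly = (tot_present > 0) & (tot_present < total.sum(axis=1))
    dropped = [l for l, keep in zip(m.locus_ids, poly) if not keep]
    kept = [l for l, keep in zip(m.locus_ids, poly) if keep]
    return (
        pd.DataFrame(present[poly], index=kept, columns=pops),
        pd.DataFrame(total[poly], index=kept, columns=pops),
        dropped,
    )


def dominant_likelihood(y, n, p) -> np.ndarray:
    """Binomial log-likelihood of band-present counts with success prob 1-(1-p)^2."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if ((y < 0) | (y > n)).any():
        raise ValidationError("counts outside [0, n]")
    if ((p <= 0) | (p >= 1)).any():
        raise ValidationError("allele frequency must lie in (0, 1)")
    # stable forms: q = p(2-p), 1-q = (1-p)^2
    return (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + y * (np.log(p) + np.log(2.0 - p))
        + (n - y) * 2.0 * np.log1p(-p)
    )


def _beta_logpdf(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a - 1) * np.log(p) + (b - 1) * np.log1p(-p) - betaln(a, b)


def _freq_prior_logpdf(p: np.ndarray, pi: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """log Beta(p; theta*pi, theta*(1-pi)) with theta = exp(-eta), eta = logit F."""
    theta = np.exp(-eta)
    return _beta_logpdf(p, theta * pi, theta * (1.0 - pi))


@dataclasses.dataclass
class MCMCProfile:
    """Sampler schedule; ``default`` follows the standard run configuration."""

    pilot_runs: int = 20
    pilot_length: int = 500
    burn_in: int = 50_000
    iterations: int = 50_000
    thinning: int = 10

    @classmethod
    def fast(cls) -> "MCMCProfile":
        """Desk-scale schedule for tests and small datasets."""
        return cls(pilot_runs=2, pilot_length=300, burn_in=2000, iterations=2000, thinning=5)


@dataclasses.dataclass
class OutlierResult:
    per_locus: pd.DataFrame  # inclusion_prob, po, log10_po, q_value, alpha_mean, fst_mean
    per_population: pd.DataFrame  # beta_mean, fst_mean
    dropped_loci: list[str]
    diagnostics: dict

    def loci(self) -> list[str]:
        return list(self.per_locus.index)


class _Sampler:
    """State and update steps for the outlier-model chain (arrays: loci x pops)."""

    def __init__(self, y: np.ndarray, n: np.ndarray, prior_odds_neutral: float, rng):
        self.y, self.n = y.astype(float), n.astype(float)
        self.I, self.J = y.shape
        self.rng = rng
        self.log_q_ratio = -np.log(prior_odds_neutral)  # log P(delta=1)/P(delta=0)
        # initial state: moment-matched frequencies, neutral loci
        p0 = (self.y + 0.5) / (self.n + 1.0)
        self.p = np.clip(1.0 - np.sqrt(np.clip(1.0 - p0, 1e-6, 1.0)), 1e-4, 1 - 1e-4)
        self.x = _logit(self.p)
        self.pi = np.clip(self.p.mean(axis=1), 1e-3, 1 - 1e-3)
        self.beta = np.full(self.J, BETA_PRIOR_MEAN)
        self.alpha = np.zeros(self.I)
        self.delta = np.zeros(self.I, dtype=bool)
        # proposal widths
        self.s_p = np.full((self.I, self.J), 0.6)
        self.s_pi = np.full(self.I, 0.4)
        self.s_beta = np.full(self.J, 0.25)
        self.s_alpha = np.full(self.I, 0.5)
        self.acc = {k: np.zeros_like(s) for k, s in
                    (("p", self.s_p), ("pi", self.s_pi), ("beta", self.s_beta),
                     ("alpha", self.s_alpha))}
        self.tries = {k: np.zeros_like(v) for k, v in self.acc.items()}

    # -- helpers -----------------------------------------------------------
    def eta(self, alpha=None, delta=None, beta=None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        d = self.delta if delta is None else delta
        b = self.beta if beta is None else beta
        return (a * d)[:, None] + b[None, :]

    def _loglik_counts(self, p: np.ndarray) -> np.ndarray:
        # q = p(2-p); use forms that stay finite as p -> 0 or 1
        return (self.y * (np.log(p) + np.log(2.0 - p))
                + (self.n - self.y) * 2.0 * np.log1p(-p))

    # -- update blocks ------------------------------------------------------
    def update_p(self) -> None:
        eta = self.eta()
        x_new = self.x + self.rng.normal(0.0, self.s_p)
        p_new = expit(x_new)
        ok = (p_new > 1e-12) & (p_new < 1 - 1e-12)
        p_new = np.clip(p_new, 1e-12, 1 - 1e-12)
        pi = self.pi[:, None]
        # logit-scale walk: include the Jacobian p(1-p) of the transform
        cur = (self._loglik_counts(self.p) + _freq_prior_logpdf(self.p, pi, eta)
               + np.log(self.p) + np.log1p(-self.p))
        new = (self._loglik_counts(p_new) + _freq_prior_logpdf(p_new, pi, eta)
               + np.log(p_new) + np.log1p(-p_new))
        accept = ok & (np.log(self.rng.random((self.I, self.J))) < new - cur)
        self.x = np.where(accept, x_new, self.x)
        self.p = np.where(accept, p_new, self.p)
        self.acc["p"] += accept
        self.tries["p"] += 1

    def update_pi(self) -> None:
        eta = self.eta()
        z = _logit(self.pi) + self.rng.normal(0.0, self.s_pi)
        pi_new = np.clip(expit(z), 1e-9, 1 - 1e-9)
        cur = (_freq_prior_logpdf(self.p, self.pi[:, None], eta).sum(axis=1)
               + np.log(self.pi) + np.log1p(-self.pi))
        new = (_freq_prior_logpdf(self.p, pi_new[:, None], eta).sum(axis=1)
               + np.log(pi_new) + np.log1p(-pi_new))
        accept = np.log(self.rng.random(self.I)) < new - cur
        self.pi = np.where(accept, pi_new, self.pi)
        self.acc["pi"] += accept
        self.tries["pi"] += 1

    def update_beta(self) -> None:
        beta_new = self.beta + self.rng.normal(0.0, self.s_beta)
        pi = self.pi[:, None]
        cur = (_freq_prior_logpdf(self.p, pi, self.eta()).sum(axis=0)
               - 0.5 * ((self.beta - BETA_PRIOR_MEAN) / BETA_PRIOR_SD) ** 2)
        new = (_freq_prior_logpdf(self.p, pi, self.eta(beta=beta_new)).sum(axis=0)
               - 0.5 * ((beta_new - BETA_PRIOR_MEAN) / BETA_PRIOR_SD) ** 2)
        accept = np.log(self.rng.random(self.J)) < new - cur
        self.beta = np.where(accept, beta_new, self.beta)
        self.acc["beta"] += accept
        self.tries["beta"] += 1

    def update_alpha(self) -> None:
        if not self.delta.any():
            return
        alpha_new = self.alpha + self.rng.normal(0.0, self.s_alpha)
        pi = self.pi[:, None]
        cur = (_freq_prior_logpdf(self.p, pi, self.eta()).sum(axis=1)
               - 0.5 * (self.alpha / ALPHA_PRIOR_SD) ** 2)
        new = (_freq_prior_logpdf(self.p, pi, self.eta(alpha=alpha_new)).sum(axis=1)
               - 0.5 * (alpha_new / ALPHA_PRIOR_SD) ** 2)
        accept = self.delta & (np.log(self.rng.random(self.I)) < new - cur)
        self.alpha = np.where(accept, alpha_new, self.alpha)
        self.acc["alpha"] += accept & self.delta
        self.tries["alpha"] += self.delta

    def update_delta(self) -> None:
        """Spike-and-slab toggle; alpha proposed from its prior on inclusion."""
        pi = self.pi[:, None]
        alpha_prop = np.where(
            self.delta, 0.0, self.rng.normal(0.0, ALPHA_PRIOR_SD, self.I)
        )
        delta_prop = ~self.delta
        cur = _freq_prior_logpdf(self.p, pi, self.eta()).sum(axis=1)
        new = _freq_prior_logpdf(
            self.p, pi, self.eta(alpha=alpha_prop, delta=delta_prop)
        ).sum(axis=1)
        # prior(alpha) cancels against the proposal; only the indicator prior remains
        log_ratio = new - cur + np.where(self.delta, -1, 1) * self.log_q_ratio
        accept = np.log(self.rng.random(self.I)) < log_ratio
        self.alpha = np.where(accept, alpha_prop, self.alpha)
        self.delta = np.where(accept, delta_prop, self.delta)

    def sweep(self) -> None:
        self.update_p()
        self.update_pi()
        self.update_beta()
        self.update_alpha()
        self.update_delta()

    # -- tuning -------------------------------------------------------------
    def tune(self) -> None:
        for key, s in (("p", self.s_p), ("pi", self.s_pi), ("beta", self.s_beta),
                       ("alpha", self.s_alpha)):
            tries = np.maximum(self.tries[key], 1)
            rate = self.acc[key] / tries
            s *= np.where(rate > 0.45, 1.4, np.where(rate < 0.25, 1 / 1.4, 1.0))
            np.clip(s, 0.02, 10.0, out=s)
            self.acc[key][...] = 0
            self.tries[key][...] = 0

    def acceptance_rates(self) -> dict[str, float]:
        out = {}
        for key in self.acc:
            tries = self.tries[key]
            total = tries.sum()
            out[key] = float(self.acc[key].sum() / total) if total else float("nan")
        return out


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def run_outlier_mcmc(
    present: pd.DataFrame,
    total: pd.DataFrame,
    profile: MCMCProfile | None = None,
    prior_odds_neutral: float = 10.0,
    seed: int | None = None,
    log10_po_threshold: float = 2.0,
) -> OutlierResult:
    """Sample the outlier model over a band-count table and summarize the chain.

    ``present``/``total`` are loci x populations count tables (as produced by
    :func:`band_count_table`).  Returns per-locus posterior inclusion
    probabilities, posterior odds, q-values and alpha summaries, plus
    per-population beta summaries and sampler diagnostics.
    """
    if present.shape != total.shape:
        raise ValidationError("present/total shape mismatch")
    if present.shape[0] < 1 or present.shape[1] < 2:
        raise ValidationError("need >=1 locus and >=2 populations")
    if prior_odds_neutral <= 0:
        raise ValidationError("prior odds must be positive")
    profile = profile or MCMCProfile()
    rng = np.random.default_rng(seed)
    s = _Sampler(present.to_numpy(), total.to_numpy(), prior_odds_neutral, rng)

    for _ in range(profile.pilot_runs):
        for _ in range(profile.pilot_length):
            s.sweep()
        s.tune()
    for _ in range(profile.burn_in):
        s.sweep()
    for key in s.acc:  # count acceptance over the sampling phase only
        s.acc[key][...] = 0
        s.tries[key][...] = 0

    n_samples = max(profile.iterations // profile.thinning, 1)
    delta_sum = np.zeros(s.I)
    alpha_sum = np.zeros(s.I)
    beta_sum = np.zeros(s.J)
    fst_sum = np.zeros((s.I, s.J))
    kept = 0
    for it in range(profile.iterations):
        s.sweep()
        if (it + 1) % profile.thinning == 0:
            delta_sum += s.delta
            alpha_sum += s.alpha * s.delta
            beta_sum += s.beta
            fst_sum += expit(s.eta())
            kept += 1
    kept = max(kept, 1)

    inclusion = delta_sum / kept
    eps = 1.0 / (2.0 * kept)
    p_clip = np.clip(inclusion, eps, 1 - eps)
    po = p_clip / (1 - p_clip)
    log10_po = np.log10(po)
    alpha_mean = np.where(delta_sum > 0, alpha_sum / np.maximum(delta_sum, 1), 0.0)
    q_value = _q_values(inclusion)
    fst_mean = fst_sum / kept

    per_locus = pd.DataFrame(
        {
            "inclusion_prob": inclusion,
            "po": po,
            "log10_po": log10_po,
            "q_value": q_value,
            "alpha_mean": alpha_mean,
            "fst_mean": fst_mean.mean(axis=1),
        },
        index=present.index,
    )
    per_locus["classification"] = _classify(per_locus, log10_po_threshold)
    per_population = pd.DataFrame(
        {"beta_mean": beta_sum / kept, "fst_mean": fst_mean.mean(axis=0)},
        index=present.columns,
    )
    rates = s.acceptance_rates()
    diagnostics = {
        "acceptance_rates": rates,
        "tuning_warning": any(
            not (0.05 <= r <= 0.9) for r in rates.values() if np.isfinite(r)
        ),
        "n_samples": int(kept),
        "profile": dataclasses.asdict(profile),
        "prior_odds_neutral": prior_odds_neutral,
        "seed": seed,
    }
    return OutlierResult(per_locus, per_population, [], diagnostics)


def _q_values(inclusion: np.ndarray) -> np.ndarray:
    """FDR q-values: running mean of (1 - inclusion) down the PO-sorted list.

    A posterior-odds threshold cannot split tied loci, so every locus in a tie
    block gets the FDR of the full block; the reverse cumulative minimum makes
    q nondecreasing along the ranking.
    """
    n = inclusion.size
    order = np.argsort(-inclusion, kind="stable")
    inc_sorted = inclusion[order]
    fdr = np.cumsum(1.0 - inc_sorted) / np.arange(1, n + 1)
    block_fdr = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and inc_sorted[j + 1] == inc_sorted[i]:
            j += 1
        block_fdr[i : j + 1] = fdr[j]
        i = j + 1
    q_sorted = np.minimum.accumulate(block_fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    return q


def _classify(per_locus: pd.DataFrame, threshold: float) -> list[str]:
    out = []
    for _, row in per_locus.iterrows():
        if row["log10_po"] > threshold:
            out.append("diversifying" if row["alpha_mean"] > 0 else "balancing")
        else:
            out.append("neutral")
    return out


def call_outliers(res: OutlierResult, log10_po_threshold: float = 2.0) -> dict:
    """Loci with decisive posterior odds, plus the expected false-positive rate.

    FDR of the call set = mean posterior probability of neutrality among the
    called loci; None when the call set is empty.
    """
    called = res.per_locus[res.per_locus["log10_po"] > log10_po_threshold]
    fdr = float((1.0 - called["inclusion_prob"]).mean()) if len(called) else None
    direction = {
        locus: ("diversifying" if a > 0 else "balancing")
        for locus, a in called["alpha_mean"].items()
    }
    return {
        "loci": list(called.index),
        "fdr": fdr,
        "threshold_log10_po": log10_po_threshold,
        "classification": direction,
    }


def scan_markers(
    m: MarkerMatrix,
    profile: MCMCProfile | None = None,
    prior_odds_neutral: float = 10.0,
    seed: int | None = None,
    log10_po_threshold: float = 2.0,
) -> OutlierResult:
    """Convenience wrapper: counts from a marker matrix, then the MCMC scan."""
    present, total, dropped = band_count_table(m)
    res = run_outlier_mcmc(
        present,
        total,
        profile=profile,
        prior_odds_neutral=prior_odds_neutral,
        seed=seed,
        log10_po_threshold=log10_po_threshold,
    )
    res.dropped_loci = dropped
    return res
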