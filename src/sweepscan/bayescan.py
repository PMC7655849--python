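"""Bayesian FST outlier detection with reversible-jump MCMC.

The model decomposes differentiation on the logit scale into a locus effect
and a population effect,

    logit FST(i, j) = alpha_i + beta_j,

with alpha_i nonzero only when locus i is "selected". Given an ancestral
frequency p_i, the population allele frequency is Beta-distributed with
precision theta_ij = (1 - FST)/FST, and the observed derived counts are
binomial — integrating the frequency out analytically gives a beta-binomial
likelihood per (locus, population) cell. A reversible-jump move toggles
alpha_i between 0 and a free value (independence proposal from its prior, so
proposal and prior densities cancel and only the likelihood ratio times the
prior odds for neutrality enters the acceptance probability). The posterior
probability that alpha_i is in the model ranks loci; q-values are the
Bayesian FDR (cumulative mean of 1 - inclusion probability down the
ranking).

Restricted to biallelic loci (the SNP-chip case): the general
multinomial-Dirichlet cell likelihood reduces to beta-binomial.

Every locus draws its proposal/acceptance randomness from its own
counter-based stream keyed by a hash of the locus identifier, so permuting
the locus order permutes the results identically; cross-locus likelihood
sums are accumulated in sorted order for the same reason.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .datatypes import AlleleCountMatrix

_THETA_FLOOR = 1e-12


@dataclass
class McmcSettings:
    """Run-length and prior settings.

    Defaults follow common practice for this sampler: 20 pilot runs of 5,000
    iterations to adapt proposal widths, 50,000 burn-in iterations, then
    5,000 retained samples at a thinning interval of 10 (100,000 post-burn-in
    iterations), with prior odds of 10 for the neutral model.
    """

    n_pilot: int = 20
    pilot_length: int = 5_000
    burn_in: int = 50_000
    thinning: int = 10
    n_kept: int = 5_000
    prior_odds: float = 10.0
    alpha_prior_sd: float = 1.0
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.0
    p_bounds: tuple = (0.01, 0.99)
    seed: int = 0

    @property
    def sampling_iterations(self) -> int:
        return self.n_kept * self.thinning

    @classmethod
    def reduced(cls, seed: int = 0) -> "McmcSettings":
        """Desk-scale settings: 20,000 total iterations
        (10 x 500 pilot + 5,000 burn-in + 10,000 sampling, 1,000 kept)."""
        return cls(n_pilot=10, pilot_length=500, burn_in=5_000, thinning=10,
                   n_kept=1_000, seed=seed)


@dataclass
class Chains:
    settings: McmcSettings
    locus_ids: list
    pop_ids: list
    alpha: np.ndarray  # (n_kept, n_loci); zero where excluded
    beta: np.ndarray  # (n_kept, n_pops)
    p: np.ndarray  # (n_kept, n_loci)
    included: np.ndarray  # (n_kept, n_loci) bool
    acceptance: dict = field(default_factory=dict)


@dataclass
class OutlierResult:
    table: pd.DataFrame  # locus_id, inclusion_prob, alpha_mean, q_value, outlier

    def outliers(self, q_max: float = 0.05) -> pd.DataFrame:
        sub = self.table[self.table["q_value"] <= q_max]
        return sub.sort_values(["q_value", "locus_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _cell_loglik(derived, total, logit_fst, p):
    """Beta-binomial log likelihood (binomial coefficient dropped) for
    derived counts with precision theta = (1 - FST)/FST = exp(-logit).

    betaln is expanded into gammaln terms: measurably faster on the small
    arrays this sampler updates tens of thousands of times.
    """
    theta = np.exp(-logit_fst)
    a = theta * p
    b = theta * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (gammaln(derived + a) + gammaln(total - derived + b)
              - gammaln(total + theta) - gammaln(a) - gammaln(b)
              + gammaln(theta))
    ll = np.where((a < _THETA_FLOOR) | (b < _THETA_FLOOR), -np.inf, ll)
    return ll


def _sorted_sum(x: np.ndarray) -> float:
    # permutation-invariant accumulation for cross-locus sums
    return float(np.sort(x, kind="stable").sum())


def _locus_keys(locus_ids, seed: int, label: str):
    keys = []
    for lid in locus_ids:
        digest = hashlib.sha256(f"{seed}|{label}|{lid}".encode()).digest()
        keys.append(np.frombuffer(digest[:16], dtype=np.uint64))
    return keys


class _LocusStreams:
    """Per-locus counter-based random streams (Philox keyed by locus id)."""

    def __init__(self, locus_ids, seed: int, n_uniform: int, n_normal: int):
        self._gens = [np.random.Generator(np.random.Philox(key=k))
                      for k in _locus_keys(locus_ids, seed, "locus")]
        self._nu, self._nn = n_uniform, n_normal
        self._u = self._z = None
        self._pos = 0

    def draw(self, chunk: int):
        self._u = np.stack([g.random((chunk, self._nu)) for g in self._gens])
        self._z = np.stack([g.standard_normal((chunk, self._nn))
                            for g in self._gens])
        self._pos = 0

    def next_iter(self):
        u = self._u[:, self._pos, :]
        z = self._z[:, self._pos, :]
        self._pos += 1
        return u, z


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

class _State:
    def __init__(self, counts: AlleleCountMatrix, settings: McmcSettings):
        self.derived = counts.derived.astype(float)
        self.total = counts.total.astype(float)
        self.n_loci, self.n_pops = counts.derived.shape
        freq = (self.derived.sum(axis=1) + 0.5) / (self.total.sum(axis=1) + 1.0)
        lo, hi = settings.p_bounds
        self.p = np.clip(freq, lo + 1e-3, hi - 1e-3)
        self.alpha = np.zeros(self.n_loci)
        self.included = np.zeros(self.n_loci, dtype=bool)
        self.beta = np.full(self.n_pops, settings.beta_prior_mean)
        self.ll = self._loglik_rows(self.alpha, self.p)
        if not np.isfinite(self.ll).all():
            bad = np.flatnonzero(~np.isfinite(self.ll.sum(axis=1)))
            raise ValueError(f"non-finite likelihood at locus "
                             f"{bad[0]} during initialization")

    def _loglik_rows(self, alpha, p):
        logit = alpha[:, None] + self.beta[None, :]
        return _cell_loglik(self.derived, self.total, logit, p[:, None])


def rjmcmc_run(counts: AlleleCountMatrix, settings: Optional[McmcSettings] = None
               ) -> Chains:
    """Sample the posterior over (alpha, beta, p, inclusion indicators).

    Pilot runs adapt the random-walk proposal widths toward acceptance rates
    in [0.25, 0.45]; burn-in samples are discarded; thinned post-burn-in
    samples are returned. Reproducible from settings.seed.
    """
    settings = settings or McmcSettings()
    if counts.n_pops < 2:
        raise ValueError("need at least 2 populations")
    if counts.n_loci < 10:
        raise ValueError("need at least 10 loci")
    state = _State(counts, settings)
    L, P = state.n_loci, state.n_pops

    # proposal widths (adapted in pilots)
    w_p = np.full(L, 0.2)
    w_alpha = np.full(L, 1.0)
    w_beta = np.full(P, 0.4)

    streams = _LocusStreams(counts.locus_ids, settings.seed, n_uniform=4,
                            n_normal=2)
    pop_gens = [np.random.Generator(np.random.Philox(key=k))
                for k in _locus_keys(counts.pop_ids, settings.seed, "pop")]

    lo, hi = settings.p_bounds
    prior_log_odds = np.log(settings.prior_odds)
    acc = {k: np.zeros(L) for k in ("p", "alpha", "rj")}
    try_n = {k: np.zeros(L) for k in ("p", "alpha", "rj")}
    acc_beta = np.zeros(P)
    try_beta = np.zeros(P)

    kept_alpha = np.empty((settings.n_kept, L))
    kept_beta = np.empty((settings.n_kept, P))
    kept_p = np.empty((settings.n_kept, L))
    kept_inc = np.empty((settings.n_kept, L), dtype=bool)
    kept_i = 0

    row_sum = state.ll.sum(axis=1)  # cached per-locus log likelihood

    def one_iteration():
        nonlocal kept_i, row_sum
        u, z = streams.next_iter()

        # --- p random walk with reflection into (lo, hi), per locus -------
        prop = state.p + w_p * (u[:, 0] * 2 - 1)
        prop = np.where(prop < lo, 2 * lo - prop, prop)
        prop = np.where(prop > hi, 2 * hi - prop, prop)
        prop = np.clip(prop, lo, hi)  # double reflection is negligible
        ll_new = state._loglik_rows(state.alpha, prop)
        new_sum = ll_new.sum(axis=1)
        take = np.log(u[:, 1]) < new_sum - row_sum
        state.p[take] = prop[take]
        state.ll[take] = ll_new[take]
        row_sum[take] = new_sum[take]
        acc["p"][take] += 1
        try_n["p"] += 1

        # --- alpha random walk, only the included rows need evaluating ----
        rows = np.flatnonzero(state.included)
        if len(rows):
            prop_a = state.alpha[rows] + w_alpha[rows] * z[rows, 0]
            ll_new = _cell_loglik(state.derived[rows], state.total[rows],
                                  prop_a[:, None] + state.beta[None, :],
                                  state.p[rows, None])
            new_sum = ll_new.sum(axis=1)
            d_prior = (state.alpha[rows]**2 - prop_a**2) \
                / (2 * settings.alpha_prior_sd**2)
            keep = np.log(u[rows, 2]) < new_sum - row_sum[rows] + d_prior
            hit = rows[keep]
            state.alpha[hit] = prop_a[keep]
            state.ll[hit] = ll_new[keep]
            row_sum[hit] = new_sum[keep]
            acc["alpha"][hit] += 1
            try_n["alpha"][rows] += 1

        # --- reversible-jump toggle, independence proposal from the prior -
        prop_a = np.where(state.included, 0.0,
                          z[:, 1] * settings.alpha_prior_sd)
        ll_new = state._loglik_rows(prop_a, state.p)
        new_sum = ll_new.sum(axis=1)
        # birth pays the prior odds for neutrality, death collects them
        delta = new_sum - row_sum \
            + np.where(state.included, prior_log_odds, -prior_log_odds)
        take = np.log(u[:, 3]) < delta
        state.alpha[take] = prop_a[take]
        state.ll[take] = ll_new[take]
        row_sum[take] = new_sum[take]
        state.included[take] = ~state.included[take]
        acc["rj"][take] += 1
        try_n["rj"] += 1

        # --- beta random walks: proposals evaluated in one batch, then
        # accepted per population (each delta depends on its column only) --
        zb = np.array([g.standard_normal() for g in pop_gens])
        ub = np.array([g.random() for g in pop_gens])
        prop_b = state.beta + w_beta * zb
        ll_cols = _cell_loglik(state.derived, state.total,
                               state.alpha[:, None] + prop_b[None, :],
                               state.p[:, None])
        for j in range(P):
            d_prior = ((state.beta[j] - settings.beta_prior_mean) ** 2
                       - (prop_b[j] - settings.beta_prior_mean) ** 2) \
                / (2 * settings.beta_prior_sd**2)
            delta = _sorted_sum(ll_cols[:, j] - state.ll[:, j]) + d_prior
            try_beta[j] += 1
            if np.log(ub[j]) < delta:
                state.beta[j] = prop_b[j]
                row_sum += ll_cols[:, j] - state.ll[:, j]
                state.ll[:, j] = ll_cols[:, j]
                acc_beta[j] += 1

    def run_block(n_iter: int, record: bool):
        nonlocal kept_i
        done = 0
        while done < n_iter:
            chunk = min(1000, n_iter - done)
            streams.draw(chunk)
            for it in range(chunk):
                one_iteration()
                if record:
                    global_it = done + it
                    if (global_it + 1) % settings.thinning == 0 \
                            and kept_i < settings.n_kept:
                        kept_alpha[kept_i] = np.where(state.included,
                                                      state.alpha, 0.0)
                        kept_beta[kept_i] = state.beta
                        kept_p[kept_i] = state.p
                        kept_inc[kept_i] = state.included
                        kept_i += 1
            done += chunk

    # pilots: adapt proposal widths toward acceptance in [0.25, 0.45]
    for _ in range(settings.n_pilot):
        for k in acc:
            acc[k][:] = 0
            try_n[k][:] = 0
        acc_beta[:] = 0
        try_beta[:] = 0
        run_block(settings.pilot_length, record=False)
        for key, w in (("p", w_p), ("alpha", w_alpha)):
            with np.errstate(invalid="ignore"):
                rate = np.where(try_n[key] > 0, acc[key] / np.maximum(try_n[key], 1), 0.35)
            w[rate < 0.25] *= 0.8
            w[rate > 0.45] *= 1.25
        rate_b = acc_beta / np.maximum(try_beta, 1)
        w_beta[rate_b < 0.25] *= 0.8
        w_beta[rate_b > 0.45] *= 1.25
        np.clip(w_p, 1e-3, 0.49, out=w_p)
        np.clip(w_alpha, 1e-2, 10.0, out=w_alpha)
        np.clip(w_beta, 1e-2, 10.0, out=w_beta)

    for k in acc:
        acc[k][:] = 0
        try_n[k][:] = 0
    acc_beta[:] = 0
    try_beta[:] = 0
    run_block(settings.burn_in, record=False)
    run_block(settings.sampling_iterations, record=True)

    rates = {"p": float((acc["p"] / np.maximum(try_n["p"], 1)).mean()),
             "beta": float((acc_beta / np.maximum(try_beta, 1)).mean())}
    if not 0.05 < rates["p"] < 0.9:
        warnings.warn(f"ancestral-frequency acceptance rate {rates['p']:.2f} "
                      "outside (0.05, 0.9) after pilots", stacklevel=2)
    return Chains(settings, list(counts.locus_ids), list(counts.pop_ids),
                  kept_alpha[:kept_i], kept_beta[:kept_i], kept_p[:kept_i],
                  kept_inc[:kept_i], acceptance=rates)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def q_values(inclusion_probs: np.ndarray) -> np.ndarray:
    """Bayesian FDR: loci ranked by decreasing inclusion probability; the
    q-value is the running mean of (1 - P) over all loci at or above each
    locus's probability."""
    probs = np.asarray(inclusion_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty inclusion-probability vector")
    order = np.argsort(-probs, kind="stable")
    sorted_p = probs[order]
    cum = np.cumsum(1.0 - sorted_p) / np.arange(1, probs.size + 1)
    # ties share the q of the last member of their tie group
    q_sorted = cum.copy()
    i = probs.size - 1
    while i > 0:
        if sorted_p[i - 1] == sorted_p[i]:
            q_sorted[i - 1] = q_sorted[i]
        i -= 1
    out = np.empty_like(q_sorted)
    out[order] = q_sorted
    return out


def outlier_result(chains: Chains, q_max: float = 0.05) -> OutlierResult:
    inc = chains.included.mean(axis=0)
    alpha_mean = chains.alpha.mean(axis=0)
    q = q_values(inc)
    return OutlierResult(pd.DataFrame({
        "locus_id": chains.locus_ids,
        "inclusion_prob": inc,
        "alpha_mean": alpha_mean,
        "q_value": q,
        "outlier": q <= q_max}))


def call_outliers(result: OutlierResult, q_max: float = 0.05) -> list:
    """Locus ids with q <= q_max, sorted by q."""
    return list(result.outliers(q_max)["locus_id"])


def posterior_mean_fst(chains: Chains) -> np.ndarray:
    """Posterior mean FST(i, j) = mean over samples of
    logistic(alpha_i + beta_j)."""
    fst = expit(chains.alpha[:, :, None] + chains.beta[:, None, :])
    return fst.mean(axis=0)
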