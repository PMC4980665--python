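"""Hierarchical beta-binomial model of per-category accuracy.

Per subject ``s`` and trial category ``j`` (relation x phase), correct-response
counts are binomial with a subject-level success probability

    y_{j,s} ~ Binomial(N_{j,s}, p_{j,s}),    p_{j,s} ~ Beta(mode omega_{j,s}, conc kappa_j)

and the mode follows a logistic regression with a baseline, a category
deflection and a subject deflection (plus a scene-novelty factor and its
interaction for experiment 3):

    omega_{j,s} = logistic(beta0 + beta_j + beta_s [+ beta_k + beta_{jk}])

``kappa_j`` (> 2) has a vague Gamma prior on ``kappa - 2``; deflection scales
have folded-t priors; ``beta0`` is Normal(0, 10).  The subject-level ``p`` is
marginalized analytically (beta-binomial likelihood) for sampling, and
reconstructed exactly by conjugacy, ``p | omega, kappa, y ~ Beta(a + y,
b + N - y)``, when forming the reported per-category accuracies (the average
of subject-level ``p`` draws).

Deflections are identified by post-hoc recentering (sum-to-zero with
compensation into the baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit
from sklearn.base import BaseEstimator

from ..data import drop_timeouts, exclude_source_trials
from .beta import beta_from_mode
from .diagnostics import PosteriorSummary, contrast, summarize
from .sampler import AdaptiveScales, MCMCConfig, half_t_logpdf, run_chains

__all__ = ["AccuracyModel", "fit_accuracy", "accuracy_counts", "CATEGORY_ORDER"]

logger = logging.getLogger(__name__)

CATEGORY_ORDER = [
    ("choice", "AB"), ("choice", "BC"), ("choice", "AC"),
    ("source", "AB"), ("source", "BC"), ("source", "AC"),
]

KAPPA_PRIOR_SHAPE = 0.01  # vague Gamma on kappa - 2
KAPPA_PRIOR_RATE = 0.01
BETA0_PRIOR_SD = 10.0
RHAT_FLAG = 1.1


def accuracy_counts(dataset: pd.DataFrame, factor: bool = False) -> pd.DataFrame:
    """Per-subject, per-category success counts after the exclusion rules.

    Source trials are retained only when the parent choice was correct; trials
    without a response are dropped.  With ``factor=True`` counts are split by
    the scene condition of the trial's triplet (experiment 3).
    """
    data = exclude_source_trials(drop_timeouts(dataset))
    keys = ["subject", "phase", "relation"]
    if factor:
        keys.append("scene_condition")
    grouped = data.groupby(keys, observed=True)["correct"]
    out = grouped.agg(y="sum", n="count").reset_index()
    return out


@dataclass
class _Cells:
    y: np.ndarray  # (J, K, S)
    n: np.ndarray
    categories: list[tuple[str, str]]
    conditions: list[str]
    subjects: list


def _build_cells(counts: pd.DataFrame) -> _Cells:
    cats = [c for c in CATEGORY_ORDER
            if ((counts["phase"] == c[0]) & (counts["relation"] == c[1])).any()]
    conds = (
        sorted(x for x in counts["scene_condition"].unique())
        if "scene_condition" in counts else [""]
    )
    subjects = sorted(counts["subject"].unique())
    J, K, S = len(cats), len(conds), len(subjects)
    y = np.zeros((J, K, S))
    n = np.zeros((J, K, S))
    cat_idx = {c: i for i, c in enumerate(cats)}
    cond_idx = {c: i for i, c in enumerate(conds)}
    subj_idx = {s: i for i, s in enumerate(subjects)}
    for row in counts.itertuples(index=False):
        j = cat_idx[(row.phase, row.relation)]
        k = cond_idx[getattr(row, "scene_condition", "")]
        s = subj_idx[row.subject]
        y[j, k, s] += row.y
        n[j, k, s] += row.n
    return _Cells(y, n, cats, conds, subjects)


def _normal_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


class AccuracyModel(BaseEstimator):
    """Sklearn-style estimator wrapping the hierarchical accuracy model.

    Parameters mirror :class:`MCMCConfig`; ``factor=True`` adds the
    experiment-3 novelty factor and its interaction with category.

    Fitted attributes
    -----------------
    accuracy_draws_ : dict category -> (chains, draws) array of the average
        subject-level accuracy.
    draws_ : raw parameter draws (recentered deflections).
    summary_ : DataFrame of posterior mean / 95% HDI / rhat / ESS.
    converged_ : False when any reported rhat exceeds 1.1 (also logged).
    """

    def __init__(self, chains: int = 4, draws: int = 5000, burn_in: int = 2000,
                 adapt_steps: int = 1000, thinning: int = 1, seed: int = 0,
                 factor: bool = False, track_subject=None):
        self.chains = chains
        self.draws = draws
        self.burn_in = burn_in
        self.adapt_steps = adapt_steps
        self.thinning = thinning
        self.seed = seed
        self.factor = factor
        self.track_subject = track_subject

    # -- model internals ---------------------------------------------------

    def _loglik(self, y, n, omega, kappa):
        a = omega * (kappa - 2.0)[:, None, None] + 1.0
        b = (1.0 - omega) * (kappa - 2.0)[:, None, None] + 1.0
        # overflowing concentration proposals yield NaN cells, which the
        # Metropolis comparison rejects; keep them quiet
        with np.errstate(invalid="ignore", over="ignore"):
            return betaln(y + a, n - y + b) - betaln(a, b)

    def _run_chain(self, cells: _Cells, rng, n_keep, thin, n_warm):
        y, n = cells.y, cells.n
        J, K, S = y.shape
        has_factor = K > 1

        # empirical initialization, jittered per chain
        p_emp = (y.sum(axis=1) + 0.5) / (n.sum(axis=1) + 1.0)  # (J, S)
        l_emp = logit(np.clip(p_emp, 0.02, 0.98))
        b0 = float(l_emp.mean() + rng.normal(0, 0.2))
        bj = l_emp.mean(axis=1) - l_emp.mean() + rng.normal(0, 0.2, J)
        bs = l_emp.mean(axis=0) - l_emp.mean() + rng.normal(0, 0.2, S)
        bk = rng.normal(0, 0.05, K) if has_factor else np.zeros(K)
        bjk = rng.normal(0, 0.05, (J, K)) if has_factor else np.zeros((J, K))
        z_kap = np.full(J, np.log(10.0)) + rng.normal(0, 0.3, J)  # kappa-2
        sig_j = max(bj.std(), 0.3) * np.exp(rng.normal(0, 0.2))
        sig_s = max(bs.std(), 0.3) * np.exp(rng.normal(0, 0.2))
        sig_k = 0.3
        sig_jk = 0.3

        def omega_of(b0, bj, bk, bjk, bs):
            eta = (
                b0
                + bj[:, None, None]
                + bk[None, :, None]
                + bjk[:, :, None]
                + bs[None, None, :]
            )
            return expit(eta)

        kappa = 2.0 + np.exp(z_kap)
        ll = self._loglik(y, n, omega_of(b0, bj, bk, bjk, bs), kappa)

        sc_b0 = AdaptiveScales.of(1)
        sc_bj = AdaptiveScales.of(J)
        sc_bs = AdaptiveScales.of(S)
        sc_bk = AdaptiveScales.of(K)
        sc_bjk = AdaptiveScales.of(J * K)
        sc_kap = AdaptiveScales.of(J, 0.4)
        sc_sig = AdaptiveScales.of(4, 0.3)

        keep = {
            "beta0": np.empty(n_keep),
            "beta_j": np.empty((n_keep, J)),
            "beta_s": np.empty((n_keep, S)),
            "kappa": np.empty((n_keep, J)),
            "sigma_beta_j": np.empty(n_keep),
            "sigma_beta_s": np.empty(n_keep),
            "accuracy": np.empty((n_keep, J)),
            "omega_mode": np.empty((n_keep, J)),
        }
        if has_factor:
            keep["beta_k"] = np.empty((n_keep, K))
            keep["beta_jk"] = np.empty((n_keep, J, K))
        if self.track_subject is not None:
            keep["p_subject"] = np.empty((n_keep, J))
            track_s = cells.subjects.index(self.track_subject)

        total_iters = n_warm + n_keep * thin
        stored = 0
        for it in range(total_iters):
            if it == n_warm:
                for sc in (sc_b0, sc_bj, sc_bs, sc_bk, sc_bjk, sc_kap, sc_sig):
                    sc.frozen = True
            kappa = 2.0 + np.exp(z_kap)

            # baseline
            prop = b0 + rng.normal(0, sc_b0.scale[0])
            ll_p = self._loglik(y, n, omega_of(prop, bj, bk, bjk, bs), kappa)
            delta = (
                ll_p.sum() - ll.sum()
                + _normal_logpdf(prop, BETA0_PRIOR_SD)
                - _normal_logpdf(b0, BETA0_PRIOR_SD)
            )
            acc = np.log(rng.random()) < delta
            if acc:
                b0, ll = prop, ll_p
            sc_b0.update([acc])

            # category deflections (conditionally independent across j)
            prop = bj + rng.normal(0, sc_bj.scale)
            ll_p = self._loglik(y, n, omega_of(b0, prop, bk, bjk, bs), kappa)
            delta = (
                (ll_p - ll).sum(axis=(1, 2))
                + _normal_logpdf(prop, sig_j)
                - _normal_logpdf(bj, sig_j)
            )
            accs = np.log(rng.random(J)) < delta
            bj = np.where(accs, prop, bj)
            ll = np.where(accs[:, None, None], ll_p, ll)
            sc_bj.update(accs)

            if has_factor:
                prop = bk + rng.normal(0, sc_bk.scale)
                ll_p = self._loglik(y, n, omega_of(b0, bj, prop, bjk, bs), kappa)
                delta = (
                    (ll_p - ll).sum(axis=(0, 2))
                    + _normal_logpdf(prop, sig_k)
                    - _normal_logpdf(bk, sig_k)
                )
                accs = np.log(rng.random(K)) < delta
                bk = np.where(accs, prop, bk)
                ll = np.where(accs[None, :, None], ll_p, ll)
                sc_bk.update(accs)

                prop = bjk + rng.normal(0, sc_bjk.scale.reshape(J, K))
                ll_p = self._loglik(y, n, omega_of(b0, bj, bk, prop, bs), kappa)
                delta = (
                    (ll_p - ll).sum(axis=2)
                    + _normal_logpdf(prop, sig_jk)
                    - _normal_logpdf(bjk, sig_jk)
                )
                accs = np.log(rng.random((J, K))) < delta
                bjk = np.where(accs, prop, bjk)
                ll = np.where(accs[:, :, None], ll_p, ll)
                sc_bjk.update(accs.ravel())

            # subject deflections (conditionally independent across s)
            prop = bs + rng.normal(0, sc_bs.scale)
            ll_p = self._loglik(y, n, omega_of(b0, bj, bk, bjk, prop), kappa)
            delta = (
                (ll_p - ll).sum(axis=(0, 1))
                + _normal_logpdf(prop, sig_s)
                - _normal_logpdf(bs, sig_s)
            )
            accs = np.log(rng.random(S)) < delta
            bs = np.where(accs, prop, bs)
            ll = np.where(accs[None, None, :], ll_p, ll)
            sc_bs.update(accs)

            # concentrations, sampled as log(kappa - 2)
            prop_z = z_kap + rng.normal(0, sc_kap.scale)
            prop_kap = 2.0 + np.exp(prop_z)
            omega = omega_of(b0, bj, bk, bjk, bs)
            ll_p = self._loglik(y, n, omega, prop_kap)
            def kap_logprior(z):
                return KAPPA_PRIOR_SHAPE * z - KAPPA_PRIOR_RATE * np.exp(z)
            delta = (
                (ll_p - ll).sum(axis=(1, 2))
                + kap_logprior(prop_z)
                - kap_logprior(z_kap)
            )
            accs = np.log(rng.random(J)) < delta
            z_kap = np.where(accs, prop_z, z_kap)
            kappa = 2.0 + np.exp(z_kap)
            ll = np.where(accs[:, None, None], ll_p, ll)
            sc_kap.update(accs)

            # translation moves along the redundant beta0 <-> deflection
            # directions: the likelihood is invariant, only priors change,
            # which unsticks the slowly mixing ridge
            for values, sd_of in ((bs, lambda: sig_s), (bj, lambda: sig_j)):
                shift = rng.normal(0, 0.5 * sd_of() / np.sqrt(values.size))
                delta = (
                    _normal_logpdf(values - shift, sd_of()).sum()
                    - _normal_logpdf(values, sd_of()).sum()
                    + _normal_logpdf(b0 + shift, BETA0_PRIOR_SD)
                    - _normal_logpdf(b0, BETA0_PRIOR_SD)
                )
                if np.log(rng.random()) < delta:
                    b0 = b0 + shift
                    values -= shift

            # deflection scales (no data term)
            def scale_step(sig, values, idx):
                z = np.log(sig)
                z_p = z + rng.normal(0, sc_sig.scale[idx])
                sig_p = np.exp(z_p)
                delta = (
                    _normal_logpdf(values, sig_p).sum()
                    - _normal_logpdf(values, sig).sum()
                    + half_t_logpdf(sig_p) - half_t_logpdf(sig)
                    + z_p - z
                )
                acc = np.log(rng.random()) < delta
                return (sig_p if acc else sig), acc

            sig_j, a0 = scale_step(sig_j, bj, 0)
            sig_s, a1 = scale_step(sig_s, bs, 1)
            accs4 = [a0, a1, False, False]
            if has_factor:
                sig_k, a2 = scale_step(sig_k, bk, 2)
                sig_jk, a3 = scale_step(sig_jk, bjk.ravel(), 3)
                accs4[2], accs4[3] = a2, a3
            sc_sig.update(accs4)

            if it >= n_warm and (it - n_warm) % thin == thin - 1:
                i = stored
                # recenter deflections for reporting
                b0_c = b0 + bj.mean() + bs.mean() + bk.mean() + bjk.mean()
                bj_c = bj - bj.mean() + (bjk.mean(axis=1) - bjk.mean())
                bs_c = bs - bs.mean()
                keep["beta0"][i] = b0_c
                keep["beta_j"][i] = bj_c
                keep["beta_s"][i] = bs_c
                keep["kappa"][i] = kappa
                keep["sigma_beta_j"][i] = sig_j
                keep["sigma_beta_s"][i] = sig_s
                if has_factor:
                    keep["beta_k"][i] = bk - bk.mean()
                    keep["beta_jk"][i] = (
                        bjk - bjk.mean(axis=0) - bjk.mean(axis=1)[:, None] + bjk.mean()
                    )
                omega = omega_of(b0, bj, bk, bjk, bs)
                a = omega * (kappa - 2.0)[:, None, None] + 1.0
                b = (1.0 - omega) * (kappa - 2.0)[:, None, None] + 1.0
                # conjugate reconstruction of subject-level accuracies
                p = rng.beta(a + y, b + n - y)
                observed = n > 0
                keep["accuracy"][i] = (
                    (p * observed).sum(axis=(1, 2)) / observed.sum(axis=(1, 2))
                )
                keep["omega_mode"][i] = expit(b0_c + bj_c)
                if self.track_subject is not None:
                    keep["p_subject"][i] = p[:, 0, track_s]
                stored += 1
        return keep

    # -- public API --------------------------------------------------------

    def fit(self, dataset: pd.DataFrame, y=None):
        counts = accuracy_counts(dataset, factor=self.factor)
        cells = _build_cells(counts)
        self.cells_ = cells
        self.categories_ = cells.categories
        config = MCMCConfig(
            chains=self.chains, draws=self.draws, burn_in=self.burn_in,
            adapt_steps=self.adapt_steps, thinning=self.thinning, seed=self.seed,
        )
        draws = run_chains(
            lambda rng, k, t, w: self._run_chain(cells, rng, k, t, w), config
        )
        self.draws_ = draws
        self.accuracy_draws_ = {
            cat: draws["accuracy"][:, :, j] for j, cat in enumerate(cells.categories)
        }
        self.summary_ = self._summaries()
        worst = max(
            (s.rhat for s in self.summaries_.values() if s.rhat is not None),
            default=1.0,
        )
        self.converged_ = worst <= RHAT_FLAG
        if not self.converged_:
            logger.warning("accuracy model: max rhat %.3f exceeds %.2f", worst, RHAT_FLAG)
        return self

    def _summaries(self) -> pd.DataFrame:
        out: dict[str, PosteriorSummary] = {}
        for j, cat in enumerate(self.categories_):
            name = f"accuracy_{cat[0]}_{cat[1]}"
            out[name] = summarize(name, self.draws_["accuracy"][:, :, j])
            mname = f"omega_{cat[0]}_{cat[1]}"
            out[mname] = summarize(mname, self.draws_["omega_mode"][:, :, j])
            kname = f"kappa_{cat[0]}_{cat[1]}"
            out[kname] = summarize(kname, self.draws_["kappa"][:, :, j])
        out["beta0"] = summarize("beta0", self.draws_["beta0"])
        for hyper in ("sigma_beta_j", "sigma_beta_s"):
            out[hyper] = summarize(hyper, self.draws_[hyper])
        if "beta_k" in self.draws_:
            for k in range(self.draws_["beta_k"].shape[-1]):
                cond = self.cells_.conditions[k]
                out[f"beta_k_{cond}"] = summarize(
                    f"beta_k_{cond}", self.draws_["beta_k"][:, :, k]
                )
            for j, cat in enumerate(self.categories_):
                for k, cond in enumerate(self.cells_.conditions):
                    name = f"beta_jk_{cat[0]}_{cat[1]}_{cond}"
                    out[name] = summarize(name, self.draws_["beta_jk"][:, :, j, k])
        self.summaries_ = out
        return pd.DataFrame([s.as_dict() for s in out.values()])

    def accuracy(self, phase: str, relation: str) -> PosteriorSummary:
        return self.summaries_[f"accuracy_{phase}_{relation}"]

    def accuracy_contrast(self, cat_a: tuple[str, str], cat_b: tuple[str, str]
                          ) -> PosteriorSummary:
        """Posterior of the accuracy difference between two categories."""
        return contrast(
            self.accuracy_draws_[cat_a], self.accuracy_draws_[cat_b],
            name=f"{cat_a[0]}_{cat_a[1]}_minus_{cat_b[0]}_{cat_b[1]}",
        )


def fit_accuracy(dataset: pd.DataFrame, mcmc: MCMCConfig | None = None,
                 factor: bool = False, **kwargs) -> AccuracyModel:
    """Fit the hierarchical accuracy model; returns the fitted estimator."""
    mcmc = mcmc or MCMCConfig()
    model = AccuracyModel(
        chains=mcmc.chains, draws=mcmc.draws, burn_in=mcmc.burn_in,
        adapt_steps=mcmc.adapt_steps, thinning=mcmc.thinning, seed=mcmc.seed,
        factor=factor, **kwargs,
    )
    return model.fit(dataset)
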