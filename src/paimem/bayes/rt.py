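"""Robust hierarchical model of reaction times.

Reaction times are log-transformed and modeled with a Student-t likelihood
(robust to the heavy tails of RT distributions):

    log y_i ~ Student-t(nu, mu_i, sigma_j),   mu_i = beta0 + beta_j + beta_s

with a per-category scale ``sigma_j`` (folded-t prior), a broad exponential
prior on the normality parameter ``nu``, category/subject deflections with
folded-t hyperpriors on their scales, and a baseline prior whose sd follows
the spread of the data.  Summaries are reported in seconds by exponentiating
the posterior of the category locations before summarizing.

The model is fitted separately per phase (choice or source trials); the trial
category is the relation (AB, BC, AC).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from ..data import drop_timeouts
from .diagnostics import PosteriorSummary, contrast, summarize
from .sampler import AdaptiveScales, MCMCConfig, half_t_logpdf, run_chains

__all__ = ["RTModel", "fit_rt"]

logger = logging.getLogger(__name__)

NU_PRIOR_MEAN = 30.0  # broad exponential prior on the normality parameter
RHAT_FLAG = 1.1


def _normal_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


class RTModel(BaseEstimator):
    """Hierarchical Student-t regression on log reaction times.

    Fitted attributes include ``rt_seconds_draws_`` (per relation, the
    exponentiated posterior of the category location), ``summary_`` and
    ``converged_``.
    """

    def __init__(self, phase: str = "choice", chains: int = 4, draws: int = 5000,
                 burn_in: int = 2000, adapt_steps: int = 1000, thinning: int = 1,
                 seed: int = 0):
        self.phase = phase
        self.chains = chains
        self.draws = draws
        self.burn_in = burn_in
        self.adapt_steps = adapt_steps
        self.thinning = thinning
        self.seed = seed

    def _run_chain(self, data, rng, n_keep, thin, n_warm):
        y, cat, subj, J, S = data
        n = y.size
        cat_counts = np.bincount(cat, minlength=J).astype(float)
        subj_counts = np.bincount(subj, minlength=S).astype(float)

        cat_means = np.bincount(cat, weights=y, minlength=J) / cat_counts
        subj_means = np.bincount(subj, weights=y, minlength=S) / subj_counts
        grand = float(y.mean())
        sd0 = max(float(y.std()), 0.1)

        b0 = grand + rng.normal(0, 0.1)
        bj = cat_means - grand + rng.normal(0, 0.05, J)
        bs = subj_means - grand + rng.normal(0, 0.05, S)
        log_sig = np.log(np.full(J, sd0 * 0.8)) + rng.normal(0, 0.1, J)
        log_nu = np.log(10.0) + rng.normal(0, 0.3)
        sig_j = max(bj.std(), 0.1)
        sig_s = max(bs.std(), 0.1)

        def loglik_terms(b0, bj, bs, log_sig, log_nu):
            nu = np.exp(log_nu)
            sig = np.exp(log_sig)[cat]
            z = (y - (b0 + bj[cat] + bs[subj])) / sig
            return (
                gammaln((nu + 1) / 2) - gammaln(nu / 2)
                - 0.5 * np.log(nu * np.pi) - np.log(sig)
                - (nu + 1) / 2 * np.log1p(z * z / nu)
            )

        ll = loglik_terms(b0, bj, bs, log_sig, log_nu)

        sc_b0 = AdaptiveScales.of(1, 0.05)
        sc_bj = AdaptiveScales.of(J, 0.05)
        sc_bs = AdaptiveScales.of(S, 0.05)
        sc_sig = AdaptiveScales.of(J, 0.1)
        sc_nu = AdaptiveScales.of(1, 0.3)
        sc_hyp = AdaptiveScales.of(2, 0.3)

        keep = {
            "beta0": np.empty(n_keep),
            "beta_j": np.empty((n_keep, J)),
            "sigma": np.empty((n_keep, J)),
            "nu": np.empty(n_keep),
            "sigma_beta_j": np.empty(n_keep),
            "sigma_beta_s": np.empty(n_keep),
            "mu_cat": np.empty((n_keep, J)),
        }
        stored = 0
        total_iters = n_warm + n_keep * thin
        for it in range(total_iters):
            if it == n_warm:
                for sc in (sc_b0, sc_bj, sc_bs, sc_sig, sc_nu, sc_hyp):
                    sc.frozen = True

            prop = b0 + rng.normal(0, sc_b0.scale[0])
            ll_p = loglik_terms(prop, bj, bs, log_sig, log_nu)
            delta = (
                ll_p.sum() - ll.sum()
                + _normal_logpdf(prop - grand, 5.0 * sd0)
                - _normal_logpdf(b0 - grand, 5.0 * sd0)
            )
            acc = np.log(rng.random()) < delta
            if acc:
                b0, ll = prop, ll_p
            sc_b0.update([acc])

            prop = bj + rng.normal(0, sc_bj.scale)
            ll_p = loglik_terms(b0, prop, bs, log_sig, log_nu)
            delta = (
                np.bincount(cat, weights=ll_p - ll, minlength=J)
                + _normal_logpdf(prop, sig_j) - _normal_logpdf(bj, sig_j)
            )
            accs = np.log(rng.random(J)) < delta
            bj = np.where(accs, prop, bj)
            ll = np.where(accs[cat], ll_p, ll)
            sc_bj.update(accs)

            prop = bs + rng.normal(0, sc_bs.scale)
            ll_p = loglik_terms(b0, bj, prop, log_sig, log_nu)
            delta = (
                np.bincount(subj, weights=ll_p - ll, minlength=S)
                + _normal_logpdf(prop, sig_s) - _normal_logpdf(bs, sig_s)
            )
            accs = np.log(rng.random(S)) < delta
            bs = np.where(accs, prop, bs)
            ll = np.where(accs[subj], ll_p, ll)
            sc_bs.update(accs)

            # per-category scales (log walk; folded-t prior + Jacobian)
            prop = log_sig + rng.normal(0, sc_sig.scale)
            ll_p = loglik_terms(b0, bj, bs, prop, log_nu)
            delta = (
                np.bincount(cat, weights=ll_p - ll, minlength=J)
                + half_t_logpdf(np.exp(prop)) - half_t_logpdf(np.exp(log_sig))
                + prop - log_sig
            )
            accs = np.log(rng.random(J)) < delta
            log_sig = np.where(accs, prop, log_sig)
            ll = np.where(accs[cat], ll_p, ll)
            sc_sig.update(accs)

            # normality parameter (log walk; exponential prior + Jacobian)
            prop = log_nu + rng.normal(0, sc_nu.scale[0])
            ll_p = loglik_terms(b0, bj, bs, log_sig, prop)
            delta = (
                ll_p.sum() - ll.sum()
                - (np.exp(prop) - np.exp(log_nu)) / NU_PRIOR_MEAN
                + prop - log_nu
            )
            acc = np.log(rng.random()) < delta
            if acc:
                log_nu, ll = prop, ll_p
            sc_nu.update([acc])

            # redundant-direction translations (likelihood invariant)
            for values, sd_of in ((bs, lambda: sig_s), (bj, lambda: sig_j)):
                shift = rng.normal(0, 0.5 * sd_of() / np.sqrt(values.size))
                delta = (
                    _normal_logpdf(values - shift, sd_of()).sum()
                    - _normal_logpdf(values, sd_of()).sum()
                    + _normal_logpdf(b0 + shift - grand, 5.0 * sd0)
                    - _normal_logpdf(b0 - grand, 5.0 * sd0)
                )
                if np.log(rng.random()) < delta:
                    b0 = b0 + shift
                    values -= shift

            # deflection-scale hyperparameters
            for idx, (get, set_, values) in enumerate((
                (lambda: sig_j, "j", bj), (lambda: sig_s, "s", bs),
            )):
                z = np.log(get())
                z_p = z + rng.normal(0, sc_hyp.scale[idx])
                delta = (
                    _normal_logpdf(values, np.exp(z_p)).sum()
                    - _normal_logpdf(values, np.exp(z)).sum()
                    + half_t_logpdf(np.exp(z_p)) - half_t_logpdf(np.exp(z))
                    + z_p - z
                )
                acc = np.log(rng.random()) < delta
                if acc:
                    if set_ == "j":
                        sig_j = float(np.exp(z_p))
                    else:
                        sig_s = float(np.exp(z_p))
                # 0.44 leaves the other component's scale untouched
                sc_hyp.update(np.where(np.arange(2) == idx, acc, 0.44))

            if it >= n_warm and (it - n_warm) % thin == thin - 1:
                i = stored
                b0_c = b0 + bj.mean() + bs.mean()
                keep["beta0"][i] = b0_c
                keep["beta_j"][i] = bj - bj.mean()
                keep["sigma"][i] = np.exp(log_sig)
                keep["nu"][i] = np.exp(log_nu)
                keep["sigma_beta_j"][i] = sig_j
                keep["sigma_beta_s"][i] = sig_s
                keep["mu_cat"][i] = b0_c + bj - bj.mean()
                stored += 1
        return keep

    def fit(self, dataset: pd.DataFrame, y=None):
        data = drop_timeouts(dataset)
        data = data[(data["phase"] == self.phase) & (data["rt_seconds"] > 0)]
        if data.empty:
            raise ValueError(f"no {self.phase} trials with positive RTs")
        relations = [r for r in ("AB", "BC", "AC") if (data["relation"] == r).any()]
        subjects = sorted(data["subject"].unique())
        cat = data["relation"].map({r: i for i, r in enumerate(relations)}).to_numpy()
        subj = data["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
        yv = np.log(data["rt_seconds"].to_numpy(dtype=float))
        self.relations_ = relations
        self.subjects_ = subjects

        config = MCMCConfig(
            chains=self.chains, draws=self.draws, burn_in=self.burn_in,
            adapt_steps=self.adapt_steps, thinning=self.thinning, seed=self.seed,
        )
        packed = (yv, cat, subj, len(relations), len(subjects))
        draws = run_chains(
            lambda rng, k, t, w: self._run_chain(packed, rng, k, t, w), config
        )
        self.draws_ = draws
        # back-transform the category locations to the seconds scale
        self.rt_seconds_draws_ = {
            rel: np.exp(draws["mu_cat"][:, :, j]) for j, rel in enumerate(relations)
        }
        self.summary_ = self._summaries()
        worst = max(s.rhat for s in self.summaries_.values() if s.rhat is not None)
        self.converged_ = worst <= RHAT_FLAG
        if not self.converged_:
            logger.warning("RT model: max rhat %.3f exceeds %.2f", worst, RHAT_FLAG)
        return self

    def _summaries(self) -> pd.DataFrame:
        out: dict[str, PosteriorSummary] = {}
        for rel in self.relations_:
            name = f"rt_seconds_{self.phase}_{rel}"
            out[name] = summarize(name, self.rt_seconds_draws_[rel])
        for scalar in ("beta0", "nu", "sigma_beta_j", "sigma_beta_s"):
            out[scalar] = summarize(scalar, self.draws_[scalar])
        for j, rel in enumerate(self.relations_):
            out[f"sigma_{rel}"] = summarize(
                f"sigma_{rel}", self.draws_["sigma"][:, :, j]
            )
        self.summaries_ = out
        return pd.DataFrame([s.as_dict() for s in out.values()])

    def rt_seconds(self, relation: str) -> PosteriorSummary:
        return self.summaries_[f"rt_seconds_{self.phase}_{relation}"]

    def rt_contrast(self, rel_a: str, rel_b: str) -> PosteriorSummary:
        """Seconds-scale posterior of the RT difference between categories."""
        return contrast(
            self.rt_seconds_draws_[rel_a], self.rt_seconds_draws_[rel_b],
            name=f"rt_{rel_a}_minus_{rel_b}",
        )


def fit_rt(dataset: pd.DataFrame, mcmc: MCMCConfig | None = None,
           phase: str = "choice", **kwargs) -> RTModel:
    """Fit the robust hierarchical RT model for one phase."""
    mcmc = mcmc or MCMCConfig()
    model = RTModel(
        phase=phase, chains=mcmc.chains, draws=mcmc.draws, burn_in=mcmc.burn_in,
        adapt_steps=mcmc.adapt_steps, thinning=mcmc.thinning, seed=mcmc.seed,
        **kwargs,
    )
    return model.fit(dataset)
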