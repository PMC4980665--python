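"""Hierarchical logistic regression of inference success on episodic memory.

Per AC choice trial, correctness is Bernoulli with

    logit p = beta0 + b_ABsource x1 + b_BCsource x2 + b_ACsource x3
              + b_BCchoice x4 + beta_s  [+ beta_novel x5, experiment 3]

where the predictors are the same-triplet correctness indicators of the AB,
BC and AC source judgments and the BC choice (the AB-choice predictor is
excluded: collinear with AB source at ceiling performance).  Coefficients get
broad Normal(0, 100) priors; odds ratios are reported as exp(coefficient).
Subject effects beta_s get a hierarchical Normal prior whose scale has a
folded-t hyperprior — this regularizes perfectly-scoring subjects (separation)
instead of letting their effects drift to the prior's edge.

Rows with identical (subject, predictor pattern) are aggregated to binomial
counts for speed; the likelihood is unchanged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ..data import drop_timeouts
from .diagnostics import PosteriorSummary, contrast, summarize
from .sampler import AdaptiveScales, MCMCConfig, half_t_logpdf, run_chains

__all__ = ["LogisticACModel", "fit_logistic", "ac_regression_table"]

logger = logging.getLogger(__name__)

COEF_PRIOR_SD = 100.0
RHAT_FLAG = 1.1

PREDICTORS = ["ab_source", "bc_source", "ac_source", "bc_choice"]


def ac_regression_table(dataset: pd.DataFrame, factor: bool = False) -> pd.DataFrame:
    """One row per AC choice trial with its four same-triplet indicators."""
    data = drop_timeouts(dataset)
    wide = data.pivot_table(
        index=["subject", "triplet_id"],
        columns=["phase", "relation"],
        values="correct",
        aggfunc="first",
        observed=True,
    )
    need = [("choice", "AC"), ("source", "AB"), ("source", "BC"),
            ("source", "AC"), ("choice", "BC")]
    missing = [c for c in need if c not in wide.columns]
    if missing:
        raise ValueError(f"dataset lacks categories required for the regression: {missing}")
    table = pd.DataFrame(
        {
            "subject": wide.index.get_level_values("subject"),
            "triplet_id": wide.index.get_level_values("triplet_id"),
            "y": wide[("choice", "AC")].astype(float),
            "ab_source": wide[("source", "AB")].astype(float),
            "bc_source": wide[("source", "BC")].astype(float),
            "ac_source": wide[("source", "AC")].astype(float),
            "bc_choice": wide[("choice", "BC")].astype(float),
        }
    ).dropna()
    if factor:
        cond = data.drop_duplicates(["subject", "triplet_id"]).set_index(
            ["subject", "triplet_id"]
        )["scene_condition"]
        table["novel"] = (
            cond.reindex(pd.MultiIndex.from_frame(table[["subject", "triplet_id"]]))
            .eq("novel").astype(float).to_numpy()
        )
    return table.reset_index(drop=True)


def _normal_logpdf(x, sd):
    return -0.5 * (x / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def _softplus(x):
    return np.logaddexp(0.0, x)


class LogisticACModel(BaseEstimator):
    """Sklearn-style estimator for the hierarchical Bernoulli-logit model.

    Fitted attributes: ``coef_draws_`` (per predictor), ``odds_ratio_draws_``,
    ``summary_``, ``converged_``.
    """

    def __init__(self, chains: int = 4, draws: int = 5000, burn_in: int = 2000,
                 adapt_steps: int = 1000, thinning: int = 1, seed: int = 0,
                 factor: bool = False):
        self.chains = chains
        self.draws = draws
        self.burn_in = burn_in
        self.adapt_steps = adapt_steps
        self.thinning = thinning
        self.seed = seed
        self.factor = factor

    def _run_chain(self, data, rng, n_keep, thin, n_warm):
        X, succ, tot, subj, S = data
        n, P = X.shape

        beta = rng.normal(0, 0.1, P)
        p0 = (succ.sum() + 0.5) / (tot.sum() + 1.0)
        b0 = float(np.log(p0 / (1 - p0)) + rng.normal(0, 0.2))
        bs = rng.normal(0, 0.1, S)
        sig_s = 0.5 * float(np.exp(rng.normal(0, 0.2)))

        eta = b0 + X @ beta + bs[subj]

        def ll_terms(eta):
            return succ * eta - tot * _softplus(eta)

        ll = ll_terms(eta)

        sc_b0 = AdaptiveScales.of(1, 0.1)
        sc_beta = AdaptiveScales.of(P, 0.1)
        sc_bs = AdaptiveScales.of(S, 0.2)
        sc_sig = AdaptiveScales.of(1, 0.3)

        keep = {
            "beta0": np.empty(n_keep),
            "beta": np.empty((n_keep, P)),
            "sigma_beta_s": np.empty(n_keep),
        }
        stored = 0
        total_iters = n_warm + n_keep * thin
        for it in range(total_iters):
            if it == n_warm:
                for sc in (sc_b0, sc_beta, sc_bs, sc_sig):
                    sc.frozen = True

            d = rng.normal(0, sc_b0.scale[0])
            eta_p = eta + d
            ll_p = ll_terms(eta_p)
            delta = (
                ll_p.sum() - ll.sum()
                + _normal_logpdf(b0 + d, COEF_PRIOR_SD)
                - _normal_logpdf(b0, COEF_PRIOR_SD)
            )
            acc = np.log(rng.random()) < delta
            if acc:
                b0, eta, ll = b0 + d, eta_p, ll_p
            sc_b0.update([acc])

            # coefficients one at a time, eta maintained incrementally
            for kcoef in range(P):
                d = rng.normal(0, sc_beta.scale[kcoef])
                eta_p = eta + X[:, kcoef] * d
                ll_p = ll_terms(eta_p)
                delta = (
                    ll_p.sum() - ll.sum()
                    + _normal_logpdf(beta[kcoef] + d, COEF_PRIOR_SD)
                    - _normal_logpdf(beta[kcoef], COEF_PRIOR_SD)
                )
                acc = np.log(rng.random()) < delta
                if acc:
                    beta[kcoef] += d
                    eta, ll = eta_p, ll_p
                sc_beta.update(np.where(np.arange(P) == kcoef, acc, 0.44))

            # subject effects: conditionally independent given the rest
            d = rng.normal(0, sc_bs.scale)
            eta_p = eta + d[subj]
            ll_p = ll_terms(eta_p)
            delta = (
                np.bincount(subj, weights=ll_p - ll, minlength=S)
                + _normal_logpdf(bs + d, sig_s) - _normal_logpdf(bs, sig_s)
            )
            accs = np.log(rng.random(S)) < delta
            bs = np.where(accs, bs + d, bs)
            eta = np.where(accs[subj], eta_p, eta)
            ll = np.where(accs[subj], ll_p, ll)
            sc_bs.update(accs)

            # translation move along the b0 <-> bs ridge
            shift = rng.normal(0, 0.5 * sig_s / np.sqrt(S))
            delta = (
                _normal_logpdf(bs - shift, sig_s).sum()
                - _normal_logpdf(bs, sig_s).sum()
                + _normal_logpdf(b0 + shift, COEF_PRIOR_SD)
                - _normal_logpdf(b0, COEF_PRIOR_SD)
            )
            if np.log(rng.random()) < delta:
                b0 += shift
                bs = bs - shift

            # subject-scale hyperparameter (no data term)
            z = np.log(sig_s)
            z_p = z + rng.normal(0, sc_sig.scale[0])
            delta = (
                _normal_logpdf(bs, np.exp(z_p)).sum()
                - _normal_logpdf(bs, np.exp(z)).sum()
                + half_t_logpdf(np.exp(z_p)) - half_t_logpdf(np.exp(z))
                + z_p - z
            )
            acc = np.log(rng.random()) < delta
            if acc:
                sig_s = float(np.exp(z_p))
            sc_sig.update([acc])

            if it >= n_warm and (it - n_warm) % thin == thin - 1:
                i = stored
                keep["beta0"][i] = b0 + bs.mean()
                keep["beta"][i] = beta
                keep["sigma_beta_s"][i] = sig_s
                stored += 1
        return keep

    def fit(self, dataset_or_table: pd.DataFrame, y=None):
        if "y" in dataset_or_table.columns and "ab_source" in dataset_or_table.columns:
            table = dataset_or_table
        else:
            table = ac_regression_table(dataset_or_table, factor=self.factor)
        self.predictors_ = list(PREDICTORS)
        if self.factor and "novel" in table.columns:
            self.predictors_ = self.predictors_ + ["novel"]
        # aggregate identical (subject, pattern) rows to binomial counts
        agg = (
            table.groupby(["subject"] + self.predictors_, observed=True)["y"]
            .agg(["sum", "count"])
            .reset_index()
        )
        subjects = sorted(agg["subject"].unique())
        subj = agg["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
        X = agg[self.predictors_].to_numpy(dtype=float)
        succ = agg["sum"].to_numpy(dtype=float)
        tot = agg["count"].to_numpy(dtype=float)
        self.subjects_ = subjects

        perfect = (
            table.groupby("subject")["y"].mean().isin([0.0, 1.0]).sum()
        )
        if perfect:
            logger.info(
                "%d subject(s) with all-or-none AC accuracy (separation); "
                "hierarchical prior regularizes their effects", perfect
            )

        config = MCMCConfig(
            chains=self.chains, draws=self.draws, burn_in=self.burn_in,
            adapt_steps=self.adapt_steps, thinning=self.thinning, seed=self.seed,
        )
        packed = (X, succ, tot, subj, len(subjects))
        draws = run_chains(
            lambda rng, k, t, w: self._run_chain(packed, rng, k, t, w), config
        )
        self.draws_ = draws
        self.coef_draws_ = {
            name: draws["beta"][:, :, k] for k, name in enumerate(self.predictors_)
        }
        self.odds_ratio_draws_ = {
            name: np.exp(d) for name, d in self.coef_draws_.items()
        }
        self.summary_ = self._summaries()
        worst = max(s.rhat for s in self.summaries_.values() if s.rhat is not None)
        self.converged_ = worst <= RHAT_FLAG
        if not self.converged_:
            logger.warning("logistic model: max rhat %.3f exceeds %.2f", worst, RHAT_FLAG)
        return self

    def _summaries(self) -> pd.DataFrame:
        out: dict[str, PosteriorSummary] = {}
        for name in self.predictors_:
            out[f"beta_{name}"] = summarize(f"beta_{name}", self.coef_draws_[name])
            out[f"odds_ratio_{name}"] = summarize(
                f"odds_ratio_{name}", self.odds_ratio_draws_[name]
            )
        out["beta0"] = summarize("beta0", self.draws_["beta0"])
        out["sigma_beta_s"] = summarize("sigma_beta_s", self.draws_["sigma_beta_s"])
        self.summaries_ = out
        return pd.DataFrame([s.as_dict() for s in out.values()])

    def coefficient(self, name: str) -> PosteriorSummary:
        return self.summaries_[f"beta_{name}"]

    def coefficient_contrast(self, name_a: str, name_b: str) -> PosteriorSummary:
        return contrast(
            self.coef_draws_[name_a], self.coef_draws_[name_b],
            name=f"beta_{name_a}_minus_beta_{name_b}",
        )


def fit_logistic(dataset: pd.DataFrame, mcmc: MCMCConfig | None = None,
                 factor: bool = False, **kwargs) -> LogisticACModel:
    """Fit the hierarchical logistic regression of AC-choice correctness."""
    mcmc = mcmc or MCMCConfig()
    model = LogisticACModel(
        chains=mcmc.chains, draws=mcmc.draws, burn_in=mcmc.burn_in,
        adapt_steps=mcmc.adapt_steps, thinning=mcmc.thinning, seed=mcmc.seed,
        factor=factor, **kwargs,
    )
    return model.fit(dataset)
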