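"""Candidate survival models, deviance and WAIC comparison.

Nine candidates span every admissible combination of the two growth
covariates (previous and lagged annual growth) and their elevation
interactions on top of the base covariates, from the base model (no growth
terms) to the full model (both mains and both interactions); an interaction
is only admissible with its main effect. Models are ranked by WAIC,
``-2 * (lppd - p_waic)``, computed from the stored pointwise
log-likelihood matrix whose unit is the tree x interval observation;
``p_waic`` is the variance-form penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import ModelSpec, PosteriorFit


@dataclass(frozen=True)
class WAICResult:
    """WAIC decomposition for one fitted model."""

    mean_deviance: float
    waic_penalty: float
    lppd: float
    waic: float
    delta_waic: float = float("nan")

    def with_delta(self, best_waic: float) -> "WAICResult":
        return WAICResult(
            self.mean_deviance, self.waic_penalty, self.lppd, self.waic,
            self.waic - best_waic,
        )


def build_candidate_set() -> list[tuple[str, ModelSpec]]:
    """The nine candidate specs, base model first, full model last."""

    def spec(prev=False, lag=False, prev_x=False, lag_x=False, name=""):
        return ModelSpec(
            include_prev_growth=prev,
            include_lag_growth=lag,
            include_prev_growth_x_elev=prev_x,
            include_lag_growth_x_elev=lag_x,
            name=name,
        )

    candidates = [
        ("base", spec(name="base")),
        ("base + previous growth", spec(prev=True, name="prev")),
        (
            "base + previous growth + previous growth x elevation",
            spec(prev=True, prev_x=True, name="prev+prevxele"),
        ),
        ("base + lagged growth", spec(lag=True, name="lag")),
        (
            "base + lagged growth + lagged growth x elevation",
            spec(lag=True, lag_x=True, name="lag+lagxele"),
        ),
        ("base + previous growth + lagged growth", spec(prev=True, lag=True, name="prev+lag")),
        (
            "base + previous growth + lagged growth + previous growth x elevation",
            spec(prev=True, lag=True, prev_x=True, name="selected"),
        ),
        (
            "base + previous growth + lagged growth + lagged growth x elevation",
            spec(prev=True, lag=True, lag_x=True, name="prev+lag+lagxele"),
        ),
        (
            "base + previous growth + lagged growth + both elevation interactions",
            spec(prev=True, lag=True, prev_x=True, lag_x=True, name="full"),
        ),
    ]
    assert len(candidates) == 9
    return candidates


def deviance_draws(fit: PosteriorFit) -> np.ndarray:
    """Per-draw deviance: -2x the row sum of the pointwise log-likelihood."""
    return -2.0 * fit.pointwise_loglik.astype(np.float64).sum(axis=1)


def deviance_posterior(fit: PosteriorFit) -> dict:
    """Posterior summary (mean, sd, 2.5%, 97.5%) of the deviance statistic."""
    d = deviance_draws(fit)
    return {
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        "q2.5": float(np.quantile(d, 0.025)),
        "q97.5": float(np.quantile(d, 0.975)),
    }


def compute_waic(fit: PosteriorFit) -> WAICResult:
    """WAIC from the pointwise log-likelihood matrix.

    lppd_i = ln(mean over draws of exp(loglik_i)) via log-sum-exp;
    p_waic_i = variance over draws of loglik_i; WAIC = -2 (lppd - p_waic).
    A degenerate (zero-variance) posterior gives p_waic = 0 and WAIC equal
    to the deviance at that point.
    """
    ll = fit.pointwise_loglik.astype(np.float64)
    n_draws = ll.shape[0]
    if n_draws < 1:
        raise ValueError("need at least one retained draw")
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = ll.var(axis=0, ddof=1) if n_draws > 1 else np.zeros(ll.shape[1])
    if not (np.isfinite(lppd_i).all() and np.isfinite(p_i).all()):
        raise FloatingPointError("non-finite WAIC components")
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    waic = -2.0 * (lppd - p_waic)
    return WAICResult(
        mean_deviance=float(deviance_draws(fit).mean()),
        waic_penalty=p_waic,
        lppd=lppd,
        waic=waic,
    )


def _n_blocks(spec: ModelSpec) -> int:
    return sum(
        (
            spec.include_prev_growth,
            spec.include_lag_growth,
            spec.include_prev_growth_x_elev,
            spec.include_lag_growth_x_elev,
        )
    )


def rank_models(results, specs: dict | None = None) -> pd.DataFrame:
    """Rank ``(name, WAICResult)`` pairs ascending by WAIC.

    Ties (equal WAIC) are broken toward the model with fewer active growth
    blocks (parsimony). The best row has delta_waic exactly 0.00; input
    order does not affect the ranking.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to rank")

    def sort_key(item):
        name, res = item
        parsimony = _n_blocks(specs[name]) if specs and name in specs else 0
        return (res.waic, parsimony, name)

    ordered = sorted(results, key=sort_key)
    best = ordered[0][1].waic
    rows = [
        {
            "model": name,
            "mean_deviance": res.mean_deviance,
            "waic_penalty": res.waic_penalty,
            "waic": res.waic,
            "delta_waic": res.waic - best,
        }
        for name, res in ordered
    ]
    return pd.DataFrame(rows)


def select_models(
    observations: pd.DataFrame,
    mcmc: dict | None = None,
    seed: int | None = None,
    candidates=None,
) -> pd.DataFrame:
    """Fit every candidate independently and return the ranked WAIC table."""
    from .model import BayesianTreeSurvival

    candidates = candidates if candidates is not None else build_candidate_set()
    results, specs = [], {}
    for i, (name, spec) in enumerate(candidates):
        est = BayesianTreeSurvival(
            spec=spec,
            seed=None if seed is None else seed + 1000 * i,
            **(mcmc or {}),
        )
        est.fit(observations)
        results.append((name, compute_waic(est.fit_)))
        specs[name] = spec
    return rank_models(results, specs)
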