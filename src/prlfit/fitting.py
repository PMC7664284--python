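"""Maximum-likelihood fitting and AIC strategy classification.

Each subject's choice sequence is scored under three models:

* **Q-learning** — delta-rule value updates with softmax choice; two free
  parameters (α, β), fitted by multi-start bounded optimisation.
* **WSLS** — win-stay/lose-shift, conditioned only on the previous outcome;
  two free parameters with a closed-form MLE from transition counts.
* **Random** — uniform choice; zero parameters, closed-form likelihood.

The strategy label is the model with the smallest AIC = −2·LL + 2k
(k = 2, 2, 0 respectively).  Missed trials contribute nothing to any
likelihood and break the WSLS one-trial memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .agents import QParams, WSLSParams
from .task import ChoiceSequence

__all__ = [
    "Model",
    "FitOptions",
    "FitResult",
    "StrategyLabel",
    "q_loglik",
    "wsls_loglik",
    "random_loglik",
    "fit_q",
    "fit_wsls",
    "fit_random",
    "classify_strategy",
]

_LN_HALF = math.log(0.5)
_EXP_CLAMP = 700.0


class Model(str, Enum):
    QLEARNING = "qlearning"
    WSLS = "wsls"
    RANDOM = "random"


_K = {Model.QLEARNING: 2, Model.WSLS: 2, Model.RANDOM: 0}

# AIC ties are broken by parsimony then simplicity: random beats WSLS beats
# Q-learning.  Exact ties are measure-zero but the rule must be deterministic.
_TIE_ORDER = (Model.RANDOM, Model.WSLS, Model.QLEARNING)


@dataclass(frozen=True)
class FitOptions:
    """Options for the Q-learning maximum-likelihood fit.

    ``n_restarts`` seeded Latin-hypercube starts over [0,1] × [0, beta_max]
    feed a bounded local optimiser; ``beta_max`` = 50 comfortably covers the
    β range seen empirically (group SDs up to ~7 imply occasional values
    past 20).
    """

    n_restarts: int = 10
    tol: float = 1e-6
    beta_max: float = 50.0
    q_init: float = 0.5
    seed: int = 0


@dataclass(frozen=True)
class FitResult:
    """One model's fit to one subject: parameters, LL, AIC, diagnostics."""

    model: Model
    params: Optional[Union[QParams, WSLSParams]]
    loglik: float
    k: int
    aic: float
    n_valid_trials: int
    converged: bool = True
    n_restarts_used: int = 0
    at_bound: bool = False


@dataclass(frozen=True)
class StrategyLabel:
    """AIC-minimising model for a subject, with the full AIC triple."""

    best_model: Model
    aic_q: float
    aic_wsls: float
    aic_random: float
    fits: dict[Model, FitResult] = field(default_factory=dict, compare=False)

    @property
    def aic_triple(self) -> tuple[float, float, float]:
        return (self.aic_q, self.aic_wsls, self.aic_random)


def _aic(loglik: float, k: int) -> float:
    return -2.0 * loglik + 2.0 * k


def _q_negll_arrays(
    theta: np.ndarray, chosen: np.ndarray, outcome: np.ndarray, q_init: float
) -> float:
    """Negative log-likelihood of a valid-trial sequence under Q-learning.

    Missed trials carry no update and no likelihood term, so they can be
    dropped before calling; the remaining trials are processed in order.
    """
    alpha, beta = float(theta[0]), float(theta[1])
    q1 = q2 = q_init
    ll = 0.0
    log1p, exp = math.log1p, math.exp
    for c, r in zip(chosen, outcome):
        x = beta * (q1 - q2)
        # log P(chosen) = −softplus(∓x), computed saturation-free so the
        # optimiser never sees an infinite objective
        z = -x if c == 1 else x
        ll -= z + log1p(exp(-z)) if z > 0.0 else log1p(exp(z))
        if c == 1:
            q1 += alpha * (r - q1)
        else:
            q2 += alpha * (r - q2)
    return -ll


def q_loglik(params: QParams, seq: ChoiceSequence) -> float:
    """Log-likelihood of a choice sequence under the Q-learning model.

    Applies the softmax choice rule and the delta-rule update sequentially
    over valid trials; missed trials are skipped entirely.
    """
    chosen, outcome = seq.valid_arrays()
    if chosen.size == 0:
        raise ValueError("sequence has no valid trials; Q-learning likelihood undefined")
    return -_q_negll_arrays(
        np.array([params.alpha, params.beta]), chosen, outcome, params.q_init
    )


def _wsls_transitions(seq: ChoiceSequence) -> tuple[int, np.ndarray, np.ndarray]:
    """Extract (n_fresh, prev_outcomes, stayed) over valid trials.

    ``n_fresh`` counts trials with no valid immediate predecessor (first
    trial, or following a miss): each contributes ln ½.  For the remaining
    trials ``prev_outcomes[i]`` is the previous trial's reward and
    ``stayed[i]`` whether the choice repeated.
    """
    n_fresh = 0
    prev: tuple[int, int] | None = None
    prev_outcomes, stayed = [], []
    for rec in seq:
        if rec.missed:
            prev = None
            continue
        if prev is None:
            n_fresh += 1
        else:
            prev_outcomes.append(prev[1])
            stayed.append(rec.chosen == prev[0])
        prev = (rec.chosen, rec.outcome)
    return n_fresh, np.array(prev_outcomes, dtype=np.int64), np.array(stayed, dtype=bool)


def _safe_log(p: float) -> float:
    return math.log(p) if p > 0.0 else -math.inf


def wsls_loglik(params: WSLSParams, seq: ChoiceSequence) -> float:
    """Log-likelihood under win-stay/lose-shift.

    Trials without a valid predecessor contribute ln ½; later trials
    contribute the stay/shift probability implied by the previous outcome.
    A zero-probability observed transition yields −inf.
    """
    n_fresh, prev_outcomes, stayed = _wsls_transitions(seq)
    ll = n_fresh * _LN_HALF
    win = prev_outcomes == 1
    counts = {
        (True, True): params.p_stay_win,
        (True, False): 1.0 - params.p_stay_win,
        (False, False): params.p_shift_lose,
        (False, True): 1.0 - params.p_shift_lose,
    }
    for (is_win, did_stay), p in counts.items():
        n = int(np.sum((win == is_win) & (stayed == did_stay)))
        if n:
            ll += n * _safe_log(p)
    return ll


def random_loglik(seq: ChoiceSequence) -> float:
    """Log-likelihood under uniform random choice: n_valid · ln ½."""
    return seq.n_valid_trials * _LN_HALF


def fit_q(seq: ChoiceSequence, options: FitOptions = FitOptions()) -> FitResult:
    """Maximum-likelihood Q-learning fit via multi-start bounded optimisation.

    L-BFGS-B from ``n_restarts`` Latin-hypercube starts over
    [0,1] × [0, beta_max]; the best local optimum is returned.  ``at_bound``
    flags fits pinned at a parameter bound.
    """
    chosen, outcome = seq.valid_arrays()
    if chosen.size < 2:
        raise ValueError("need at least 2 valid trials to fit the Q-learning model")

    sampler = qmc.LatinHypercube(d=2, seed=options.seed)
    starts = sampler.random(options.n_restarts)
    starts[:, 1] *= options.beta_max
    bounds = [(0.0, 1.0), (0.0, options.beta_max)]

    best_x, best_nll, any_success = None, math.inf, False
    for x0 in starts:
        res = minimize(
            _q_negll_arrays,
            x0,
            args=(chosen, outcome, options.q_init),
            method="L-BFGS-B",
            bounds=bounds,
            tol=options.tol,
        )
        any_success = any_success or bool(res.success)
        if res.fun < best_nll:
            best_nll, best_x = res.fun, res.x
    alpha, beta = float(best_x[0]), float(best_x[1])
    eps = 1e-8
    at_bound = (
        alpha < eps or alpha > 1 - eps or beta < eps or beta > options.beta_max - eps
    )
    ll = -best_nll
    return FitResult(
        model=Model.QLEARNING,
        params=QParams(alpha=alpha, beta=beta, q_init=options.q_init),
        loglik=ll,
        k=_K[Model.QLEARNING],
        aic=_aic(ll, _K[Model.QLEARNING]),
        n_valid_trials=int(chosen.size),
        converged=any_success,
        n_restarts_used=options.n_restarts,
        at_bound=at_bound,
    )


def fit_wsls(seq: ChoiceSequence) -> FitResult:
    """Closed-form WSLS MLE from transition counts.

    P(stay|win) is the fraction of win trials (followed by a valid trial)
    on which the choice repeated, and P(shift|lose) the fraction of loss
    trials followed by a switch; a ratio with no informative transitions
    defaults to 0.5, which leaves the likelihood unchanged.
    """
    _, prev_outcomes, stayed = _wsls_transitions(seq)
    win = prev_outcomes == 1
    n_win, n_lose = int(win.sum()), int((~win).sum())
    p_stay_win = float(stayed[win].sum() / n_win) if n_win else 0.5
    p_shift_lose = float((~stayed[~win]).sum() / n_lose) if n_lose else 0.5
    params = WSLSParams(p_stay_win=p_stay_win, p_shift_lose=p_shift_lose)
    ll = wsls_loglik(params, seq)
    return FitResult(
        model=Model.WSLS,
        params=params,
        loglik=ll,
        k=_K[Model.WSLS],
        aic=_aic(ll, _K[Model.WSLS]),
        n_valid_trials=seq.n_valid_trials,
    )


def fit_random(seq: ChoiceSequence) -> FitResult:
    """The zero-parameter random model: LL = n_valid · ln ½."""
    ll = random_loglik(seq)
    return FitResult(
        model=Model.RANDOM,
        params=None,
        loglik=ll,
        k=_K[Model.RANDOM],
        aic=_aic(ll, _K[Model.RANDOM]),
        n_valid_trials=seq.n_valid_trials,
    )


def classify_strategy(
    seq: ChoiceSequence, options: FitOptions = FitOptions()
) -> StrategyLabel:
    """Fit all three models and label the subject with the AIC minimiser."""
    fits = {
        Model.QLEARNING: fit_q(seq, options),
        Model.WSLS: fit_wsls(seq),
        Model.RANDOM: fit_random(seq),
    }
    best = min(_TIE_ORDER, key=lambda m: (fits[m].aic, _TIE_ORDER.index(m)))
    return StrategyLabel(
        best_model=best,
        aic_q=fits[Model.QLEARNING].aic,
        aic_wsls=fits[Model.WSLS].aic,
        aic_random=fits[Model.RANDOM].aic,
        fits=fits,
    )
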