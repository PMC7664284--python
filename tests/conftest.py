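import numpy as np
import pytest

from prlfit import TaskConfig, make_outcome_schedule
from prlfit.task import ChoiceSequence, TrialRecord


def build_sequence(pairs):
    """Build a ChoiceSequence from (chosen, outcome) pairs; None = missed."""
    records = []
    for i, (chosen, outcome) in enumerate(pairs, start=1):
        records.append(TrialRecord(trial=i, chosen=chosen, outcome=outcome, advantageous=1))
    return ChoiceSequence(tuple(records))


@pytest.fixture
def default_config():
    return TaskConfig()


@pytest.fixture
def default_schedule(default_config):
    return make_outcome_schedule(default_config, seed=0)


# ---------------------------------------------------------------------------
# Independent oracles.  These re-derive quantities by a different route than
# the package (explicit per-trial arithmetic, grids, pairwise counts) so that
# agreement is informative.
# ---------------------------------------------------------------------------


def oracle_q_loglik(alpha, beta, seq, q_init=0.5):
    """Step-by-step Q-learning likelihood: explicit softmax per trial."""
    q = [q_init, q_init]
    ll = 0.0
    for rec in seq:
        if rec.missed:
            continue
        x = np.clip(beta * (q[0] - q[1]), -700, 700)
        p1 = 1.0 / (1.0 + np.exp(-x))
        p = p1 if rec.chosen == 1 else 1.0 - p1
        ll += np.log(p) if p > 0 else -np.inf
        i = rec.chosen - 1
        q[i] = q[i] + alpha * (rec.outcome - q[i])
    return ll


def oracle_q_loglik_grid(alphas, betas, seq, q_init=0.5):
    """Vectorised Q-learning LL over a parameter grid (alphas × betas)."""
    aa, bb = np.meshgrid(alphas, betas, indexing="ij")
    aa, bb = aa.ravel(), bb.ravel()
    q1 = np.full_like(aa, q_init)
    q2 = np.full_like(aa, q_init)
    ll = np.zeros_like(aa)
    for rec in seq:
        if rec.missed:
            continue
        x = np.clip(bb * (q1 - q2), -700, 700)
        p1 = 1.0 / (1.0 + np.exp(-x))
        p = p1 if rec.chosen == 1 else 1.0 - p1
        with np.errstate(divide="ignore"):
            ll += np.log(p)
        if rec.chosen == 1:
            q1 = q1 + aa * (rec.outcome - q1)
        else:
            q2 = q2 + aa * (rec.outcome - q2)
    return ll


def oracle_wsls_loglik(p_stay_win, p_shift_lose, seq):
    """Per-trial WSLS likelihood conditioned on the previous valid trial."""
    ll = 0.0
    prev = None
    for rec in seq:
        if rec.missed:
            prev = None
            continue
        if prev is None:
            p = 0.5
        else:
            stayed = rec.chosen == prev[0]
            if prev[1] == 1:
                p = p_stay_win if stayed else 1.0 - p_stay_win
            else:
                p = (1.0 - p_shift_lose) if stayed else p_shift_lose
        ll += np.log(p) if p > 0 else -np.inf
        prev = (rec.chosen, rec.outcome)
    return ll


def oracle_concordance_auc(scores, labels):
    """Brute-force pairwise Mann-Whitney concordance (ties count 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
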