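"""Trial-by-trial learning models and their observation variables.

Seven models map a discriminant-conditioning trial sequence to a per-trial
observation variable ``z_t`` that is later regressed on autonomic response
amplitudes:

========  ===========================================  ==================  ======
model     observation variable z_t                     learning params     family
========  ===========================================  ==================  ======
RW        associative strength x_t                     eta                 O
HM1       associability eta_t                          k                   S
HM2       associative strength x_t                     k                   O
BM        Beta prior mean E[theta]                     —                   O
BC        prior uncertainty + prior mean, v_t + E      —                   C
UN        pooled prior uncertainty v_t                 —                   N
NL        constant CS difference {1, 0}                —                   N
========  ===========================================  ==================  ======

Families: O = expected outcome, S = surprise / model update, C = combination
of outcome and uncertainty, N = null (no learning).

Indexing convention: on every trial, ``z_t`` reflects the learner's state
*before* that trial's outcome is observed (the prior), so the first trial of
either CS carries the initial value. Learning states are kept separately per
CS and updated only on that CS's trials; the CS- is never reinforced, so its
update always sees ``u = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .design import CS_PLUS, TrialSequence

MODELS: tuple[str, ...] = ("RW", "HM1", "HM2", "BM", "BC", "UN", "NL")

#: free parameters in the learning model (regression weights excluded)
N_LEARNING_PARAMS: Mapping[str, int] = {
    "RW": 1, "HM1": 1, "HM2": 1, "BM": 0, "BC": 0, "UN": 0, "NL": 0,
}

#: default family partition: expected outcome / surprise / combination / null
FAMILIES: Mapping[str, str] = {
    "RW": "O", "HM2": "O", "BM": "O", "HM1": "S", "BC": "C", "UN": "N", "NL": "N",
}

#: initial associative strength for RW and hybrid models (no prior expectation
#: favouring either CS)
X0 = 0.5
#: initial associability of the hybrid model; not a free parameter (the hybrid
#: model has a single fitted learning parameter k), fixed at the midpoint to
#: match the x0 convention
ETA0 = 0.5


class ParameterError(ValueError):
    """Raised for learning parameters outside their admissible range."""


class DispatchError(KeyError):
    """Raised for an unknown model identifier."""


@dataclass
class LearningParams:
    """Learning parameters for one model (empty for the parameter-free ones)."""

    model_id: str
    eta: float | None = None  # RW fixed learning rate
    k: float | None = None    # hybrid scaling parameter
    eta0: float = ETA0        # hybrid initial associability (fixed constant)

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        if self.eta is not None:
            out["eta"] = self.eta
        if self.k is not None:
            out["k"] = self.k
        return out


@dataclass
class ModelTrace:
    """Per-trial latent quantities of one model, aligned with the sequence.

    Arrays not produced by a model are ``None``. ``final_counts`` holds the
    per-CS Beta pseudo-counts after the last trial (beta-binomial models).
    """

    model_id: str
    z: np.ndarray | None = None
    x: np.ndarray | None = None           # associative strength
    eta: np.ndarray | None = None         # associability (hybrid)
    prior_mean: np.ndarray | None = None  # E[theta] before the trial
    v: np.ndarray | None = None           # prior uncertainty -ln(a+b)
    final_counts: dict[str, tuple[float, float]] | None = None


def _check_open_unit(value: float, name: str) -> None:
    if not (0.0 < value < 1.0):
        raise ParameterError(f"{name} must lie in the open interval (0, 1), got {value}")


def rw_trace(seq: TrialSequence, eta: float) -> ModelTrace:
    """Rescorla-Wagner associative strength with fixed learning rate ``eta``.

    Per-CS value ``x`` starts at 0.5 and is updated after each trial of that
    CS by ``x <- x + eta * (u - x)``; ``z_t`` is the value held before the
    trial's outcome.
    """
    _check_open_unit(eta, "eta")
    n = len(seq)
    x = {True: X0, False: X0}
    z = np.empty(n)
    plus = seq.is_cs_plus
    us = seq.us
    for t in range(n):
        p = bool(plus[t])
        z[t] = x[p]
        x[p] += eta * (us[t] - x[p])
    return ModelTrace(model_id="RW", z=z, x=z.copy())


def hybrid_trace(seq: TrialSequence, k: float, eta0: float = ETA0) -> ModelTrace:
    """Hybrid Rescorla-Wagner / Pearce-Hall model.

    Maintains per-CS associative strength ``x`` (x0 = 0.5) and associability
    ``eta`` (eta_0 = ``eta0``), with a single scaling parameter ``k`` shared
    across CS. After a trial with outcome ``u``::

        x   <- x + eta * (u - x)        # value update uses the old eta
        eta <- k * |x_old - u| + (1 - k) * eta

    The trace exposes both observation variables: associability (model HM1)
    and associative strength (model HM2), each as the pre-trial value.
    """
    _check_open_unit(k, "k")
    if not np.isfinite(eta0):
        raise ParameterError("eta0 must be finite")
    n = len(seq)
    x = {True: X0, False: X0}
    a = {True: float(eta0), False: float(eta0)}
    zx = np.empty(n)
    ze = np.empty(n)
    plus = seq.is_cs_plus
    us = seq.us
    for t in range(n):
        p = bool(plus[t])
        zx[t] = x[p]
        ze[t] = a[p]
        x_old, eta_old, u = x[p], a[p], us[t]
        x[p] = x_old + eta_old * (u - x_old)
        a[p] = k * abs(x_old - u) + (1.0 - k) * eta_old
    return ModelTrace(model_id="HM", x=zx, eta=ze)


def beta_trace(seq: TrialSequence) -> ModelTrace:
    """Sequential beta-binomial ideal observer, one Beta(a, b) per CS.

    Counts start at the uninformative prior a = b = 1 and are updated after
    each trial of that CS: ``a <- a + u``, ``b <- b + 1 - u``. Per-trial
    outputs use the counts held before the trial: prior mean
    ``E[theta] = a / (a + b)`` and prior uncertainty ``v = -ln(a + b)``.
    Observation variables: BM uses ``E[theta]``; BC uses ``v + E[theta]``.
    """
    n = len(seq)
    counts = {True: [1.0, 1.0], False: [1.0, 1.0]}
    prior_mean = np.empty(n)
    v = np.empty(n)
    plus = seq.is_cs_plus
    us = seq.us
    for t in range(n):
        p = bool(plus[t])
        a, b = counts[p]
        prior_mean[t] = a / (a + b)
        v[t] = -np.log(a + b)
        u = us[t]
        counts[p][0] = a + u
        counts[p][1] = b + 1 - u
    return ModelTrace(
        model_id="beta",
        prior_mean=prior_mean,
        v=v,
        final_counts={
            CS_PLUS: tuple(counts[True]),
            "CS-": tuple(counts[False]),
        },
    )


def null_traces(seq: TrialSequence, prior_counts: bool = True) -> tuple[ModelTrace, ModelTrace]:
    """The two non-learning models: (UN, NL).

    UN tracks the pooled number of observations regardless of CS identity,
    ``z_t = -ln(a + b)`` with pseudo-counts starting at a + b = 2 and growing
    by one per trial; with ``prior_counts`` (default) the counts held before
    the trial are used, so ``z_t = -ln(t + 1)`` for 1-based ``t``. NL assumes
    learning finished before the session: ``z = 1`` on CS+ trials, 0 on CS-.
    """
    n = len(seq)
    t_index = np.arange(1, n + 1, dtype=float)
    total = t_index + 1.0 if prior_counts else t_index + 2.0
    z_un = -np.log(total)
    un = ModelTrace(model_id="UN", z=z_un, v=z_un.copy())
    nl = ModelTrace(model_id="NL", z=seq.is_cs_plus.astype(float))
    return un, nl


def observation_variable(
    model_id: str,
    seq: TrialSequence,
    params: LearningParams | None = None,
    *,
    eta: float | None = None,
    k: float | None = None,
    eta0: float = ETA0,
) -> np.ndarray:
    """Observation variable ``z_t`` of ``model_id`` over all trials of ``seq``.

    Learning parameters may be supplied as a :class:`LearningParams` or as
    keyword arguments; parameter-free models ignore them.
    """
    if params is not None:
        eta = params.eta if eta is None else eta
        k = params.k if k is None else k
        eta0 = params.eta0
    if model_id == "RW":
        if eta is None:
            raise ParameterError("model RW requires eta")
        return rw_trace(seq, eta).z
    if model_id in ("HM1", "HM2"):
        if k is None:
            raise ParameterError(f"model {model_id} requires k")
        tr = hybrid_trace(seq, k, eta0)
        return tr.eta if model_id == "HM1" else tr.x
    if model_id == "BM":
        return beta_trace(seq).prior_mean
    if model_id == "BC":
        tr = beta_trace(seq)
        return tr.v + tr.prior_mean
    if model_id == "UN":
        return null_traces(seq)[0].z
    if model_id == "NL":
        return null_traces(seq)[1].z
    raise DispatchError(f"unknown model_id {model_id!r}")


# -- vectorized parameter grids (used by the fitting grid search) -----------

def rw_z_grid(seq: TrialSequence, etas: np.ndarray) -> np.ndarray:
    """RW observation variables for many learning rates at once.

    Returns an array of shape ``(len(etas), n_trials)`` whose row ``i`` equals
    ``rw_trace(seq, etas[i]).z``.
    """
    etas = np.asarray(etas, dtype=float)
    n = len(seq)
    xp = np.full(etas.shape, X0)
    xm = np.full(etas.shape, X0)
    out = np.empty((etas.size, n))
    plus = seq.is_cs_plus
    us = seq.us
    for t in range(n):
        if plus[t]:
            out[:, t] = xp
            xp = xp + etas * (us[t] - xp)
        else:
            out[:, t] = xm
            xm = xm - etas * xm
    return out


def hybrid_z_grid(
    seq: TrialSequence, ks: np.ndarray, eta0: float = ETA0
) -> tuple[np.ndarray, np.ndarray]:
    """Hybrid-model observation variables for many ``k`` at once.

    Returns ``(z_eta, z_x)``, each of shape ``(len(ks), n_trials)``: row ``i``
    matches ``hybrid_trace(seq, ks[i], eta0)``'s associability and associative
    strength.
    """
    ks = np.asarray(ks, dtype=float)
    n = len(seq)
    x = {True: np.full(ks.shape, X0), False: np.full(ks.shape, X0)}
    a = {True: np.full(ks.shape, float(eta0)), False: np.full(ks.shape, float(eta0))}
    z_eta = np.empty((ks.size, n))
    z_x = np.empty((ks.size, n))
    plus = seq.is_cs_plus
    us = seq.us
    for t in range(n):
        p = bool(plus[t])
        z_x[:, t] = x[p]
        z_eta[:, t] = a[p]
        x_old, eta_old, u = x[p], a[p], us[t]
        x[p] = x_old + eta_old * (u - x_old)
        a[p] = ks * np.abs(x_old - u) + (1.0 - ks) * eta_old
    return z_eta, z_x
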