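"""Per-participant model fitting by least squares on unreinforced trials.

Each model's observation variable ``z_t`` (computed over *all* trials, since
the learner sees every outcome) is mapped to measured amplitudes through the
linear observation function ``y_t = beta1 * z_t + beta0 + eps_t``. The
residual sum of squares is accumulated only over trials not paired with a US,
to avoid contamination by the evoked outcome response. Model evidence is
approximated by the Gaussian-noise BIC, ``p ln T + T ln(RSS / T)``, where
``T`` is the number of unreinforced trials and ``p`` counts the learning
parameters plus the two regression weights.

For a fixed learning parameter the optimal ``(beta0, beta1)`` have the
closed-form ordinary-least-squares solution, so the regression weights are
profiled out analytically and only the learning parameter (if any) is
searched numerically: a dense grid over the open unit interval followed by
bounded local refinement from the best grid points. The search is
deterministic and seed-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .design import TrialSequence, unreinforced_indices
from .models import (
    ETA0,
    MODELS,
    N_LEARNING_PARAMS,
    LearningParams,
    beta_trace,
    hybrid_z_grid,
    null_traces,
    observation_variable,
    rw_z_grid,
)

__all__ = [
    "AmplitudeSeries",
    "ObservationParams",
    "FitConfig",
    "FitResult",
    "FitError",
    "InsufficientDataError",
    "rss_objective",
    "bic",
    "explained_variance",
    "fit_model",
    "fit_all_models",
    "residualize",
    "fits_to_frame",
]


class FitError(ValueError):
    pass


class InsufficientDataError(FitError):
    pass


@dataclass
class AmplitudeSeries:
    """Per-trial anticipatory response amplitudes for one participant."""

    participant_id: str
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise FitError("amplitudes must be finite")


@dataclass(frozen=True)
class ObservationParams:
    """Linear observation function y = beta1 * z + beta0."""

    beta1: float
    beta0: float


@dataclass(frozen=True)
class FitConfig:
    """Deterministic search contract for the learning parameter.

    101-point grid over (0, 1) with endpoints 0.005 / 0.995, bounded local
    refinement (objective tolerance ``tol``) started from the ``n_starts``
    best grid minima. ``rss_floor_rel`` keeps BIC finite on (near-)noiseless
    data: RSS is clamped at ``rss_floor_rel * TSS``.
    """

    grid_size: int = 101
    bounds: tuple[float, float] = (0.005, 0.995)
    n_starts: int = 3
    tol: float = 1e-8
    rss_floor_rel: float = 1e-12
    eta0: float = ETA0

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.bounds[0], self.bounds[1], self.grid_size)


@dataclass
class FitResult:
    """One model fitted to one participant."""

    model_id: str
    params: LearningParams
    obs: ObservationParams
    rss: float
    T: int
    p: int
    bic: float
    r2: float
    participant_id: str | None = None
    rss_clamped: bool = field(default=False, repr=False)


def _as_y(y: AmplitudeSeries | np.ndarray) -> tuple[np.ndarray, str | None]:
    if isinstance(y, AmplitudeSeries):
        return y.y, y.participant_id
    arr = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise FitError("amplitudes must be finite")
    return arr, None


def rss_objective(
    y: AmplitudeSeries | np.ndarray,
    seq: TrialSequence,
    z: np.ndarray,
    obs: ObservationParams,
) -> float:
    """Sum of squared residuals of ``beta1*z + beta0`` against ``y`` over the
    unreinforced trials of ``seq``. ``z`` and ``y`` cover all trials."""
    arr, _ = _as_y(y)
    z = np.asarray(z, dtype=float)
    if len(arr) != len(seq) or len(z) != len(seq):
        raise FitError(
            f"length mismatch: y={len(arr)}, z={len(z)}, sequence={len(seq)}"
        )
    idx = unreinforced_indices(seq)
    resid = obs.beta1 * z[idx] + obs.beta0 - arr[idx]
    return float(resid @ resid)


def bic(rss: float, T: int, p: int, rss_floor: float = 1e-300) -> float:
    """Gaussian BIC, ``p ln T + T ln(RSS / T)``; ``rss`` is clamped at
    ``rss_floor`` (with a warning) so the result stays finite."""
    if T <= 0:
        raise FitError("T must be positive")
    if p < 2:
        raise FitError("p must be at least 2 (two regression weights)")
    if rss <= rss_floor:
        warnings.warn("RSS at or below floor; BIC clamped", RuntimeWarning, stacklevel=2)
        rss = rss_floor
    return p * np.log(T) + T * np.log(rss / T)


def _ols(z_u: np.ndarray, y_u: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS of y on [1, z]; returns (beta0, beta1, rss)."""
    zm = z_u.mean()
    ym = y_u.mean()
    zc = z_u - zm
    yc = y_u - ym
    szz = float(zc @ zc)
    syy = float(yc @ yc)
    if szz <= 0.0:
        return ym, 0.0, syy
    szy = float(zc @ yc)
    beta1 = szy / szz
    rss = max(syy - beta1 * szy, 0.0)
    return ym - beta1 * zm, beta1, rss


def _ols_grid(Z_u: np.ndarray, y_u: np.ndarray) -> np.ndarray:
    """Profiled-OLS RSS for every row of ``Z_u`` (grid of z series)."""
    zm = Z_u.mean(axis=1)
    Zc = Z_u - zm[:, None]
    yc = y_u - y_u.mean()
    syy = float(yc @ yc)
    szz = np.einsum("ij,ij->i", Zc, Zc)
    szy = Zc @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(szz > 0.0, szy / szz, 0.0)
    return np.maximum(syy - slope * szy, 0.0)


def _local_minima(values: np.ndarray, n: int) -> list[int]:
    """Indices of up to ``n`` best local minima of a 1D array (ends count)."""
    g = len(values)
    cand = [
        i
        for i in range(g)
        if (i == 0 or values[i] <= values[i - 1])
        and (i == g - 1 or values[i] <= values[i + 1])
    ]
    cand.sort(key=lambda i: values[i])
    return cand[:n]


def _refine(
    objective,
    grid: np.ndarray,
    rss_grid: np.ndarray,
    config: FitConfig,
) -> tuple[float, float]:
    """Bounded local refinement from the best grid minima; returns
    (best parameter, best RSS)."""
    best_i = int(np.argmin(rss_grid))
    best_param, best_rss = float(grid[best_i]), float(rss_grid[best_i])
    for i in _local_minima(rss_grid, config.n_starts):
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi <= lo:
            continue
        res = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-7}
        )
        if res.fun < best_rss - config.tol or (
            res.fun < best_rss and abs(res.fun - best_rss) <= config.tol
        ):
            best_param, best_rss = float(res.x), float(res.fun)
    return best_param, best_rss


def _finalize(
    model_id: str,
    params: LearningParams,
    beta0: float,
    beta1: float,
    rss: float,
    T: int,
    syy: float,
    participant_id: str | None,
    config: FitConfig,
) -> FitResult:
    p = 2 + N_LEARNING_PARAMS[model_id]
    floor = max(config.rss_floor_rel * syy, 1e-300)
    clamped = rss < floor
    if clamped:
        warnings.warn(
            f"{model_id}: RSS {rss:.3g} below floor {floor:.3g}; clamped",
            RuntimeWarning,
            stacklevel=3,
        )
        rss = floor
    b = p * np.log(T) + T * np.log(rss / T)
    r2 = 1.0 - rss / syy if syy > 0.0 else np.nan
    return FitResult(
        model_id=model_id,
        params=params,
        obs=ObservationParams(beta1=beta1, beta0=beta0),
        rss=rss,
        T=T,
        p=p,
        bic=float(b),
        r2=float(r2),
        participant_id=participant_id,
        rss_clamped=clamped,
    )


def _fit_parametric(
    model_id: str,
    seq: TrialSequence,
    y_u: np.ndarray,
    idx: np.ndarray,
    syy: float,
    participant_id: str | None,
    config: FitConfig,
    Z_u: np.ndarray | None = None,
) -> FitResult:
    grid = config.grid
    if Z_u is None:
        if model_id == "RW":
            Z_u = rw_z_grid(seq, grid)[:, idx]
        else:
            z_eta, z_x = hybrid_z_grid(seq, grid, config.eta0)
            Z_u = (z_eta if model_id == "HM1" else z_x)[:, idx]
    rss_grid = _ols_grid(Z_u, y_u)

    def objective(theta: float) -> float:
        z = observation_variable(
            model_id,
            seq,
            eta=theta if model_id == "RW" else None,
            k=theta if model_id != "RW" else None,
            eta0=config.eta0,
        )
        return _ols(z[idx], y_u)[2]

    theta, _ = _refine(objective, grid, rss_grid, config)
    z = observation_variable(
        model_id,
        seq,
        eta=theta if model_id == "RW" else None,
        k=theta if model_id != "RW" else None,
        eta0=config.eta0,
    )
    beta0, beta1, rss = _ols(z[idx], y_u)
    params = (
        LearningParams(model_id, eta=theta, eta0=config.eta0)
        if model_id == "RW"
        else LearningParams(model_id, k=theta, eta0=config.eta0)
    )
    return _finalize(model_id, params, beta0, beta1, rss, len(idx), syy, participant_id, config)


def fit_model(
    y: AmplitudeSeries | np.ndarray,
    seq: TrialSequence,
    model_id: str,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one model to one participant's amplitude series.

    Parameter-free models reduce to a single OLS solve; RW and the hybrid
    models search their learning parameter over a dense grid with bounded
    local refinement, with the regression weights profiled out in closed
    form. Deterministic given ``config``.
    """
    if model_id not in MODELS:
        raise FitError(f"unknown model_id {model_id!r}")
    config = config or FitConfig()
    arr, pid = _as_y(y)
    if len(arr) != len(seq):
        raise FitError(f"length mismatch: y={len(arr)}, sequence={len(seq)}")
    idx = unreinforced_indices(seq)
    T = len(idx)
    if T < 3:
        raise InsufficientDataError(f"need at least 3 unreinforced trials, got {T}")
    y_u = arr[idx]
    syy = float(np.sum((y_u - y_u.mean()) ** 2))

    if N_LEARNING_PARAMS[model_id] == 0:
        z = observation_variable(model_id, seq)
        beta0, beta1, rss = _ols(z[idx], y_u)
        return _finalize(
            model_id, LearningParams(model_id), beta0, beta1, rss, T, syy, pid, config
        )
    return _fit_parametric(model_id, seq, y_u, idx, syy, pid, config)


def fit_all_models(
    y: AmplitudeSeries | np.ndarray,
    seq: TrialSequence,
    models: tuple[str, ...] = MODELS,
    config: FitConfig | None = None,
) -> dict[str, FitResult]:
    """Fit every model in ``models`` to one participant.

    Equivalent to calling :func:`fit_model` per model but shares the
    beta-binomial trace between BM and BC and the hybrid parameter grid
    between HM1 and HM2.
    """
    config = config or FitConfig()
    arr, pid = _as_y(y)
    if len(arr) != len(seq):
        raise FitError(f"length mismatch: y={len(arr)}, sequence={len(seq)}")
    idx = unreinforced_indices(seq)
    T = len(idx)
    if T < 3:
        raise InsufficientDataError(f"need at least 3 unreinforced trials, got {T}")
    y_u = arr[idx]
    syy = float(np.sum((y_u - y_u.mean()) ** 2))

    out: dict[str, FitResult] = {}

    simple_z: dict[str, np.ndarray] = {}
    if "BM" in models or "BC" in models:
        bt = beta_trace(seq)
        simple_z["BM"] = bt.prior_mean
        simple_z["BC"] = bt.v + bt.prior_mean
    if "UN" in models or "NL" in models:
        un, nl = null_traces(seq)
        simple_z["UN"] = un.z
        simple_z["NL"] = nl.z
    for m in models:
        if m in simple_z:
            beta0, beta1, rss = _ols(simple_z[m][idx], y_u)
            out[m] = _finalize(
                m, LearningParams(m), beta0, beta1, rss, T, syy, pid, config
            )

    if "RW" in models:
        out["RW"] = _fit_parametric("RW", seq, y_u, idx, syy, pid, config)
    if "HM1" in models or "HM2" in models:
        z_eta, z_x = hybrid_z_grid(seq, config.grid, config.eta0)
        if "HM1" in models:
            out["HM1"] = _fit_parametric(
                "HM1", seq, y_u, idx, syy, pid, config, Z_u=z_eta[:, idx]
            )
        if "HM2" in models:
            out["HM2"] = _fit_parametric(
                "HM2", seq, y_u, idx, syy, pid, config, Z_u=z_x[:, idx]
            )
    return {m: out[m] for m in models}


def explained_variance(
    y: AmplitudeSeries | np.ndarray, seq: TrialSequence, fit: FitResult
) -> float:
    """R^2 of a fit on unreinforced trials: 1 - RSS / TSS, where TSS is the
    total sum of squares of ``y`` about its unreinforced-trial mean. May be
    negative for poor models; NaN when TSS is zero."""
    arr, _ = _as_y(y)
    idx = unreinforced_indices(seq)
    y_u = arr[idx]
    tss = float(np.sum((y_u - y_u.mean()) ** 2))
    if tss == 0.0:
        warnings.warn("zero total sum of squares; R^2 undefined", RuntimeWarning, stacklevel=2)
        return np.nan
    return 1.0 - fit.rss / tss


def residualize(
    y: AmplitudeSeries | np.ndarray, seq: TrialSequence, un_fit: FitResult
) -> AmplitudeSeries | np.ndarray:
    """Subtract a fitted UN model's predictions from ``y`` on every trial.

    The residual series can then be fitted with the standard path, e.g. to
    ask whether a probabilistic or an associability model better explains
    what the pure habituation model leaves over.
    """
    arr, pid = _as_y(y)
    if un_fit.participant_id is not None and pid is not None and un_fit.participant_id != pid:
        raise FitError(
            f"participant mismatch: fit={un_fit.participant_id!r}, y={pid!r}"
        )
    z = observation_variable(un_fit.model_id, seq, params=un_fit.params)
    resid = arr - (un_fit.obs.beta1 * z + un_fit.obs.beta0)
    if isinstance(y, AmplitudeSeries):
        return AmplitudeSeries(participant_id=y.participant_id, y=resid)
    return resid


def fits_to_frame(fits) -> "pd.DataFrame":
    """Tabulate FitResults (mapping, nested mapping, or iterable) as tidy rows."""
    import pandas as pd

    rows = []

    def _collect(obj):
        if isinstance(obj, FitResult):
            rows.append(obj)
        elif isinstance(obj, dict):
            for v in obj.values():
                _collect(v)
        else:
            for v in obj:
                _collect(v)

    _collect(fits)
    return pd.DataFrame(
        {
            "participant": [f.participant_id for f in rows],
            "model": [f.model_id for f in rows],
            "eta": [f.params.eta for f in rows],
            "k": [f.params.k for f in rows],
            "beta0": [f.obs.beta0 for f in rows],
            "beta1": [f.obs.beta1 for f in rows],
            "rss": [f.rss for f in rows],
            "T": [f.T for f in rows],
            "p": [f.p for f in rows],
            "bic": [f.bic for f in rows],
            "r2": [f.r2 for f in rows],
        }
    )
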