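"""Synthetic single-trial amplitude data with known ground truth.

Stands in for the trial-wise anticipatory response amplitudes that upstream
psychophysiological modelling would deliver: a chosen true model's
observation variable ``z_t`` is pushed through the linear observation
function ``y_t = beta1 * z_t + beta0 + eps_t`` with i.i.d. Gaussian noise.
Noise is calibrated per participant so that the true model's population R^2
on unreinforced trials hits a target level (default 0.2, the explained-
variance regime seen in real skin-conductance / pupil data), i.e.

    sigma^2 = beta1^2 * Var(z) * (1 - R*) / R*.

Per-participant learning parameters, regression weights, trial sequences and
noise draws all flow from a single root seed through numpy's SeedSequence
stream splitting, so any subset of participants is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignConfig, TrialSequence, generate_design, unreinforced_indices
from .models import ETA0, MODELS, N_LEARNING_PARAMS, LearningParams, observation_variable

__all__ = [
    "GeneratorConfig",
    "ParticipantTruth",
    "SyntheticDataset",
    "simulate_participant",
    "calibrate_noise",
    "simulate_experiment",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one simulated experiment.

    Learning rates and hybrid scaling parameters are drawn uniformly on
    (0.05, 0.95); the observation slope beta1 is lognormal with median 1 and
    log-sd 0.5; the intercept beta0 is Normal(1, 0.3). ``target_r2`` sets the
    per-participant noise calibration; alternatively a fixed ``sigma``
    overrides it.
    """

    true_model: str = "BC"
    n_participants: int = 20
    design: DesignConfig = field(default_factory=DesignConfig)
    eta_range: tuple[float, float] = (0.05, 0.95)
    k_range: tuple[float, float] = (0.05, 0.95)
    beta1_log_sd: float = 0.5
    beta0_mean: float = 1.0
    beta0_sd: float = 0.3
    target_r2: float = 0.2
    sigma: float | None = None
    eta0: float = ETA0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_model not in MODELS:
            raise SimulationError(f"unknown true_model {self.true_model!r}")
        if self.sigma is None and not (0.0 < self.target_r2 < 1.0):
            raise SimulationError("target_r2 must lie in (0, 1)")
        if self.sigma is not None and self.sigma < 0:
            raise SimulationError("sigma must be non-negative")
        if self.n_participants < 1:
            raise SimulationError("n_participants must be positive")


@dataclass
class ParticipantTruth:
    """Ground truth used to generate one participant's data."""

    participant_id: str
    model_id: str
    params: LearningParams
    beta1: float
    beta0: float
    sigma: float


@dataclass
class SyntheticDataset:
    """Sequences, amplitudes and ground truth for one simulated experiment."""

    config: GeneratorConfig
    sequences: list[TrialSequence]
    amplitudes: list[np.ndarray]
    truths: list[ParticipantTruth]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: participant, trial, cs, us, block, amplitude."""
        frames = []
        for seq, y in zip(self.sequences, self.amplitudes):
            f = seq.to_frame()
            f["amplitude"] = y
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def truth_records(self) -> list[dict]:
        """JSON-serializable ground-truth sidecar."""
        return [
            {
                "participant": t.participant_id,
                "model": t.model_id,
                **t.params.as_dict(),
                "beta1": t.beta1,
                "beta0": t.beta0,
                "sigma": t.sigma,
            }
            for t in self.truths
        ]


def simulate_participant(
    model_id: str,
    params: LearningParams | None,
    seq: TrialSequence,
    beta1: float,
    beta0: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitudes ``y_t = beta1 * z_t + beta0 + eps_t`` for every trial
    (reinforced trials included), ``eps_t ~ N(0, sigma^2)`` i.i.d."""
    if sigma < 0:
        raise SimulationError("sigma must be non-negative")
    z = observation_variable(model_id, seq, params=params)
    return beta1 * z + beta0 + rng.normal(0.0, sigma, size=len(seq))


def calibrate_noise(z_unreinforced: np.ndarray, beta1: float, target_r2: float) -> float:
    """Noise sd giving the true model population R^2 = ``target_r2`` on
    unreinforced trials: sigma^2 = beta1^2 Var(z) (1 - R*) / R*."""
    if not (0.0 < target_r2 < 1.0):
        raise SimulationError("target_r2 must lie in (0, 1)")
    var_z = float(np.var(z_unreinforced))
    if var_z <= 0.0:
        raise SimulationError("z has zero variance on unreinforced trials")
    return float(np.sqrt(beta1**2 * var_z * (1.0 - target_r2) / target_r2))


def _draw_params(
    model_id: str, rng: np.random.Generator, config: GeneratorConfig
) -> LearningParams:
    if model_id == "RW":
        return LearningParams(model_id, eta=rng.uniform(*config.eta_range), eta0=config.eta0)
    if N_LEARNING_PARAMS[model_id] == 1:  # HM1 / HM2
        return LearningParams(model_id, k=rng.uniform(*config.k_range), eta0=config.eta0)
    return LearningParams(model_id, eta0=config.eta0)


def simulate_experiment(
    config: GeneratorConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> SyntheticDataset:
    """Simulate one experiment: fresh design, parameters and noise per
    participant, bit-reproducible given the seed.

    ``seed`` (int or SeedSequence) overrides ``config.seed`` when given,
    letting callers drive many experiments from one root seed.
    """
    if seed is None:
        seed = config.seed
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(config.n_participants)
    sequences: list[TrialSequence] = []
    amplitudes: list[np.ndarray] = []
    truths: list[ParticipantTruth] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"sim{i + 1:03d}"
        seq = generate_design(config.design, seed=rng, participant_id=pid)
        params = _draw_params(config.true_model, rng, config)
        beta1 = float(np.exp(rng.normal(0.0, config.beta1_log_sd)))
        beta0 = float(rng.normal(config.beta0_mean, config.beta0_sd))
        if config.sigma is not None:
            sigma = float(config.sigma)
        else:
            z = observation_variable(config.true_model, seq, params=params)
            sigma = calibrate_noise(z[unreinforced_indices(seq)], beta1, config.target_r2)
        y = simulate_participant(config.true_model, params, seq, beta1, beta0, sigma, rng)
        sequences.append(seq)
        amplitudes.append(y)
        truths.append(
            ParticipantTruth(
                participant_id=pid,
                model_id=config.true_model,
                params=params,
                beta1=beta1,
                beta0=beta0,
                sigma=sigma,
            )
        )
    return SyntheticDataset(
        config=config, sequences=sequences, amplitudes=amplitudes, truths=truths
    )


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of ``config`` with a different root seed."""
    return replace(config, seed=seed)
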