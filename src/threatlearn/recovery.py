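"""Simulated model recovery: can the design tell the models apart a priori?

For each candidate true model, many experiments are simulated (default 64
experiments of 20 participants each, noise calibrated to ~20% explained
variance), every model in the space is fitted to every simulated participant,
and the group-level winner is selected by protected exceedance probability
over -BIC/2 evidences. Tallying winners against the generating model yields a
model-level confusion matrix; mapping both through the family partition
yields the family-level matrix. Row means of the diagonals summarise the
a-priori probability of recovering the true model and the true family.

Each (true model, experiment) cell derives its own SeedSequence from the root
seed by spawn key, so the grid is order-independent and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bms import BMSConfig, evidence_from_bic, family_bms, rfx_bms, winner
from .design import DesignConfig
from .fitting import FitConfig, fit_all_models
from .models import FAMILIES, MODELS
from .simulate import GeneratorConfig, simulate_experiment

__all__ = ["RecoveryConfig", "ConfusionMatrix", "RecoveryResult", "run_recovery", "recovery_summary"]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """Selection counts and proportions, true (rows) x selected (columns).

    Rows cover the models actually simulated from; columns cover the whole
    fitted space, so the matrix need not be square when only a subset of
    true models was run.
    """

    labels_true: list[str]
    labels_selected: list[str]
    counts: np.ndarray

    @property
    def labels(self) -> list[str]:
        if self.labels_true != self.labels_selected:
            raise ValueError("row and column labels differ; use labels_true/labels_selected")
        return self.labels_true

    @property
    def proportions(self) -> np.ndarray:
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, self.counts / row, np.nan)

    @property
    def diagonal(self) -> np.ndarray:
        """Recovery rate of each true model: proportion selected = true."""
        prop = self.proportions
        return np.array(
            [prop[i, self.labels_selected.index(lab)] for i, lab in enumerate(self.labels_true)]
        )

    @property
    def diagonal_mean(self) -> float:
        return float(np.mean(self.diagonal))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.labels_true, columns=self.labels_selected)


@dataclass(frozen=True)
class RecoveryConfig:
    """Scope and conditions of a recovery study.

    ``n_experiments`` defaults to the scaled-down 64 per true model (the full
    study uses 256). ``criterion`` selects the group winner: "rfx" (protected
    exceedance probability) or "ffx" (lowest summed BIC), for sensitivity
    analysis. Monte-Carlo draws for the exceedance probability are reduced to
    2e5 here: the winner is the argmax, which is insensitive to MC noise away
    from exact ties.
    """

    n_experiments: int = 64
    n_participants: int = 20
    models: tuple[str, ...] = MODELS
    true_models: tuple[str, ...] | None = None  # default: every fitted model
    partition: dict[str, str] | None = None
    design: DesignConfig = field(default_factory=DesignConfig)
    target_r2: float = 0.2
    criterion: str = "rfx"
    bms_mc_draws: int = 200_000
    fit_config: FitConfig = field(default_factory=FitConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be at least 1")
        if self.criterion not in ("rfx", "ffx"):
            raise ValueError("criterion must be 'rfx' or 'ffx'")

    def family_of(self, model: str) -> str:
        part = self.partition or FAMILIES
        return part[model]


@dataclass
class RecoveryResult:
    config: RecoveryConfig
    cm_model: ConfusionMatrix
    cm_family: ConfusionMatrix
    winners: pd.DataFrame          # per (true model, experiment) winner log
    n_excluded: int = 0


def _select_winner(
    bic_matrix: np.ndarray, models: tuple[str, ...], criterion: str, bms_config: BMSConfig
) -> str:
    if criterion == "ffx":
        return models[int(np.argmin(bic_matrix.sum(axis=0)))]
    res = rfx_bms(evidence_from_bic(bic_matrix), labels=list(models), config=bms_config)
    return winner(res)[0]


def run_recovery(config: RecoveryConfig | None = None) -> RecoveryResult:
    """Run the full recovery grid and tally model- and family-level winners."""
    config = config or RecoveryConfig()
    models = config.models
    true_models = config.true_models or models
    partition = config.partition or {m: FAMILIES[m] for m in models}
    families = sorted(set(partition.values()))
    true_families = sorted(set(partition[m] for m in true_models))
    k = len(models)
    bms_config = BMSConfig(n_mc=config.bms_mc_draws)

    counts_model = np.zeros((len(true_models), k), dtype=int)
    counts_family = np.zeros((len(true_families), len(families)), dtype=int)
    rows = []
    n_excluded = 0

    for ti, true_model in enumerate(true_models):
        mi = models.index(true_model)  # spawn key tied to position in the model space
        gen = GeneratorConfig(
            true_model=true_model,
            n_participants=config.n_participants,
            design=config.design,
            target_r2=config.target_r2,
        )
        for ei in range(config.n_experiments):
            ss = np.random.SeedSequence(config.seed, spawn_key=(mi, ei))
            try:
                data = simulate_experiment(gen, seed=ss)
                bic_matrix = np.empty((config.n_participants, k))
                for pi, (seq, y) in enumerate(zip(data.sequences, data.amplitudes)):
                    fits = fit_all_models(y, seq, models=models, config=config.fit_config)
                    bic_matrix[pi] = [fits[m].bic for m in models]
                sel = _select_winner(bic_matrix, models, config.criterion, bms_config)
            except Exception:  # noqa: BLE001 - flagged and excluded, never silent
                logger.exception(
                    "experiment excluded: true_model=%s experiment=%d", true_model, ei
                )
                n_excluded += 1
                continue
            counts_model[ti, models.index(sel)] += 1
            counts_family[
                true_families.index(partition[true_model]), families.index(partition[sel])
            ] += 1
            rows.append({"true_model": true_model, "experiment": ei, "selected": sel})

    return RecoveryResult(
        config=config,
        cm_model=ConfusionMatrix(list(true_models), list(models), counts_model),
        cm_family=ConfusionMatrix(true_families, families, counts_family),
        winners=pd.DataFrame(rows),
        n_excluded=n_excluded,
    )


def recovery_summary(cm_model: ConfusionMatrix, cm_family: ConfusionMatrix) -> dict:
    """Diagonal summaries: average probability of recovering the true family
    and the true model, plus per-model and per-family recovery rates."""
    return {
        "family_recovery_mean": cm_family.diagonal_mean,
        "model_recovery_mean": cm_model.diagonal_mean,
        "per_model": dict(zip(cm_model.labels, cm_model.diagonal.tolist())),
        "per_family": dict(zip(cm_family.labels, cm_family.diagonal.tolist())),
    }


def scaled(config: RecoveryConfig, n_experiments: int) -> RecoveryConfig:
    """Copy of ``config`` at a different number of experiments per model."""
    return replace(config, n_experiments=n_experiments)
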