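"""Manipulation-check contrast: CS x Trial linear mixed-effects model.

Before any model comparison it must be established that participants learned
the CS-US contingency at all: CS+ trials should evoke larger anticipatory
amplitudes than CS- trials. The check regresses single-trial amplitudes on
CS identity, trial number and their interaction, with a random intercept per
participant (``amplitude ~ 1 + CS * Trial, random = ~1 | participant``),
fitted by REML on unreinforced trials. F statistics for the three
single-degree-of-freedom fixed effects are the squared Wald statistics;
denominator degrees of freedom follow the within-group residual rule
``N - n_participants - 3``. P values are Bonferroni-corrected for the number
of datasets tested (default 4).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CS_PLUS

__all__ = ["ContrastResult", "cs_trial_contrast"]


class ContrastError(ValueError):
    pass


@dataclass
class ContrastResult:
    """F tests for the CS, Trial and CS x Trial fixed effects."""

    effects: pd.DataFrame  # columns: effect, F, df_num, df_den, p, p_corrected
    dataset: str = ""
    n_participants: int = 0
    n_obs: int = 0

    def effect(self, name: str) -> pd.Series:
        return self.effects.set_index("effect").loc[name]


def _zero_result(dataset: str, n_participants: int, n_obs: int, n_datasets: int) -> ContrastResult:
    effects = pd.DataFrame(
        {
            "effect": ["CS", "Trial", "CS:Trial"],
            "F": 0.0,
            "df_num": 1,
            "df_den": max(n_obs - n_participants - 3, 1),
            "p": 1.0,
            "p_corrected": 1.0,
        }
    )
    return ContrastResult(effects, dataset, n_participants, n_obs)


def cs_trial_contrast(
    data: pd.DataFrame,
    n_datasets: int = 4,
    trial_coding: str = "global",
    dataset: str = "",
) -> ContrastResult:
    """CS x Trial mixed-effects contrast on a long amplitude table.

    ``data`` needs columns participant, trial, cs, amplitude (and optionally
    us; reinforced trials are dropped if present). ``trial_coding`` is
    "global" (session-wide 1..N trial index, shared across CS) or "per_cs"
    (rank of the trial within its own CS).
    """
    import statsmodels.formula.api as smf

    required = {"participant", "trial", "cs", "amplitude"}
    missing = required - set(data.columns)
    if missing:
        raise ContrastError(f"missing columns: {sorted(missing)}")
    if trial_coding not in ("global", "per_cs"):
        raise ContrastError("trial_coding must be 'global' or 'per_cs'")
    df = data.copy()
    if "us" in df.columns:
        df = df[df["us"] == 0]
    if df["participant"].nunique() < 2:
        raise ContrastError("need at least 2 participants")
    if df["cs"].nunique() < 2:
        raise ContrastError("need both CS levels")

    df["cs_plus"] = (df["cs"] == CS_PLUS).astype(float)
    if trial_coding == "global":
        df["trial_c"] = df["trial"].astype(float)
    else:
        df["trial_c"] = df.groupby(["participant", "cs"])["trial"].rank().astype(float)

    n_obs = len(df)
    n_groups = df["participant"].nunique()
    df_den = n_obs - n_groups - 3
    if df_den < 1:
        raise ContrastError("not enough observations for the residual df")
    if float(np.var(df["amplitude"])) == 0.0:
        return _zero_result(dataset, n_groups, n_obs, n_datasets)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("amplitude ~ cs_plus * trial_c", df, groups=df["participant"])
        fit = model.fit(reml=True)

    rows = []
    for label, term in (("CS", "cs_plus"), ("Trial", "trial_c"), ("CS:Trial", "cs_plus:trial_c")):
        coef = fit.params[term]
        se = fit.bse[term]
        f_stat = float((coef / se) ** 2) if se > 0 else 0.0
        p = float(stats.f.sf(f_stat, 1, df_den))
        rows.append(
            {
                "effect": label,
                "F": f_stat,
                "df_num": 1,
                "df_den": df_den,
                "p": p,
                "p_corrected": min(1.0, p * n_datasets),
            }
        )
    return ContrastResult(pd.DataFrame(rows), dataset, n_groups, n_obs)
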