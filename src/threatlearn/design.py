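"""Discriminant-conditioning trial sequences.

A session presents two conditioned stimuli: a CS+ that co-terminates with an
aversive outcome (US) on a fixed fraction of its trials, and a CS- that is
never reinforced. Trials are organised in blocks; the first trial of each
block is a reinforced CS+ and the remaining trials of the block are uniformly
permuted. Only the trial-level structure (CS identity, US occurrence, block)
is modelled here — stimulus timing and modality do not enter trial-level
model fitting, so delay- and trace-conditioning variants share one generator
distinguished only by a metadata tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

CS_PLUS = "CS+"
CS_MINUS = "CS-"


class DesignError(ValueError):
    """Raised when a design configuration violates its invariants."""


class Trial(NamedTuple):
    """One trial: 1-based position, CS identity, US outcome, block number."""

    index: int
    cs: str
    us: int
    block: int


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the discriminant-conditioning design.

    Defaults reproduce the standard session: 80 trials of each CS in two
    blocks, 50% of CS+ trials reinforced, first trial of each block a
    reinforced CS+.
    """

    n_per_cs: int = 80
    reinforcement_rate: float = 0.5
    n_blocks: int = 2
    first_trial_reinforced_csplus: bool = True
    conditioning: str = "delay"  # metadata only: "delay" or "trace"

    def __post_init__(self) -> None:
        if self.n_per_cs <= 0 or self.n_blocks <= 0:
            raise DesignError("n_per_cs and n_blocks must be positive")
        if not 0.0 <= self.reinforcement_rate <= 1.0:
            raise DesignError("reinforcement_rate must lie in [0, 1]")
        n_reinforced = self.n_per_cs * self.reinforcement_rate
        if abs(n_reinforced - round(n_reinforced)) > 1e-9:
            raise DesignError(
                f"n_per_cs * reinforcement_rate = {n_reinforced} is not an integer"
            )
        if self.n_per_cs % self.n_blocks != 0:
            raise DesignError("n_blocks must divide n_per_cs")
        if round(n_reinforced) % self.n_blocks != 0:
            raise DesignError(
                "reinforced CS+ trials cannot be balanced across blocks"
            )
        if self.first_trial_reinforced_csplus and round(n_reinforced) == 0:
            raise DesignError(
                "first-trial rule requires at least one reinforced CS+ per block"
            )

    @property
    def n_trials(self) -> int:
        return 2 * self.n_per_cs

    @property
    def n_reinforced(self) -> int:
        return round(self.n_per_cs * self.reinforcement_rate)


@dataclass
class TrialSequence:
    """Ordered trial-level events for one participant.

    Internally array-backed (``cs``, ``us``, ``block`` aligned 1D arrays);
    :meth:`trials` yields :class:`Trial` records.
    """

    participant_id: str
    cs: np.ndarray  # array of CS_PLUS / CS_MINUS strings
    us: np.ndarray  # int {0, 1}
    block: np.ndarray  # int, 1-based
    config: DesignConfig | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cs = np.asarray(self.cs, dtype=object)
        self.us = np.asarray(self.us, dtype=int)
        self.block = np.asarray(self.block, dtype=int)
        if not (len(self.cs) == len(self.us) == len(self.block)):
            raise DesignError("cs, us and block must have equal length")
        if np.any((self.us == 1) & (self.cs != CS_PLUS)):
            raise DesignError("us = 1 on a non-CS+ trial")

    def __len__(self) -> int:
        return len(self.us)

    @property
    def n_trials(self) -> int:
        return len(self.us)

    @property
    def is_cs_plus(self) -> np.ndarray:
        return np.asarray(self.cs == CS_PLUS)

    def trials(self) -> Iterator[Trial]:
        for i in range(len(self)):
            yield Trial(i + 1, str(self.cs[i]), int(self.us[i]), int(self.block[i]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy representation: participant, trial (1-based), cs, us, block."""
        return pd.DataFrame(
            {
                "participant": self.participant_id,
                "trial": np.arange(1, len(self) + 1),
                "cs": self.cs,
                "us": self.us,
                "block": self.block,
            }
        )


def generate_design(
    config: DesignConfig | None = None,
    seed: int | np.random.Generator | None = None,
    participant_id: str = "sim",
) -> TrialSequence:
    """Generate one randomized trial sequence under ``config``.

    Each block holds ``n_per_cs / n_blocks`` trials of each CS and an equal
    share of the reinforced CS+ trials. When configured, the first trial of
    each block is a reinforced CS+; the order of the remaining trials within
    the block is a uniform random permutation. Reproducible given ``seed``.
    """
    if config is None:
        config = DesignConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    per_block_cs = config.n_per_cs // config.n_blocks
    per_block_reinf = config.n_reinforced // config.n_blocks

    cs_all: list[str] = []
    us_all: list[int] = []
    block_all: list[int] = []
    for b in range(1, config.n_blocks + 1):
        cs_block = [CS_PLUS] * per_block_cs + [CS_MINUS] * per_block_cs
        us_block = [1] * per_block_reinf + [0] * (per_block_cs - per_block_reinf)
        us_block += [0] * per_block_cs
        pairs = list(zip(cs_block, us_block))
        if config.first_trial_reinforced_csplus:
            first = (CS_PLUS, 1)
            pairs.remove(first)
            rest_idx = rng.permutation(len(pairs))
            ordered = [first] + [pairs[i] for i in rest_idx]
        else:
            order = rng.permutation(len(pairs))
            ordered = [pairs[i] for i in order]
        cs_all.extend(p[0] for p in ordered)
        us_all.extend(p[1] for p in ordered)
        block_all.extend([b] * len(ordered))

    return TrialSequence(
        participant_id=participant_id,
        cs=np.array(cs_all, dtype=object),
        us=np.array(us_all),
        block=np.array(block_all),
        config=config,
    )


def unreinforced_indices(seq: TrialSequence) -> np.ndarray:
    """0-based positions of all trials not paired with a US, in trial order.

    These are the trials that enter the fitting objective; the 1-based
    ``trial`` column of the tidy CSV is ``unreinforced_indices(seq) + 1``.
    """
    return np.flatnonzero(seq.us == 0)


def sequence_from_frame(df: pd.DataFrame, participant_id: str | None = None) -> TrialSequence:
    """Rebuild a :class:`TrialSequence` from its tidy-CSV representation."""
    if participant_id is not None:
        df = df[df["participant"] == participant_id]
    elif df["participant"].nunique() > 1:
        raise DesignError("frame holds several participants; pass participant_id")
    else:
        participant_id = str(df["participant"].iloc[0])
    df = df.sort_values("trial")
    block = df["block"].to_numpy() if "block" in df.columns else np.ones(len(df), dtype=int)
    return TrialSequence(
        participant_id=str(participant_id),
        cs=df["cs"].to_numpy(dtype=object),
        us=df["us"].to_numpy(dtype=int),
        block=block,
    )
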