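"""Data model for similarity-judgment trials.

A trial shows a *query* stimulus together with 2-8 *reference* stimuli; the
participant selects the ``n_select`` references most similar to the query,
optionally ranking them.  Judged trials (:class:`Observations`) store the
references with the selected ones first, in rank order; unjudged trials
(:class:`Docket`) impose no ordering.  Stimulus indices are 0-based and
contiguous; unused reference columns are padded with ``-1`` so that every
table carries the maximum of eight reference columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MAX_N_REFERENCE = 8
MIN_N_REFERENCE = 2
PAD = -1

_OBS_COLUMNS = (
    ["query"]
    + [f"ref{i}" for i in range(MAX_N_REFERENCE)]
    + ["n_select", "is_ranked", "group_id"]
)
_DOCKET_COLUMNS = _OBS_COLUMNS[:-1]


class TrialValidationError(ValueError):
    """Raised when a trial table violates a structural invariant."""


@dataclass(frozen=True)
class TrialConfiguration:
    """Shape of a single trial: ``n_reference``-choose-``n_select``.

    ``is_ranked`` is normalized to True when only one selection is made,
    because ranking a single item carries no extra information.
    """

    n_reference: int
    n_select: int = 1
    is_ranked: bool = True

    def __post_init__(self):
        if not MIN_N_REFERENCE <= self.n_reference <= MAX_N_REFERENCE:
            raise TrialValidationError(
                f"n_reference must be in [{MIN_N_REFERENCE}, {MAX_N_REFERENCE}], "
                f"got {self.n_reference}"
            )
        if not 1 <= self.n_select <= self.n_reference - 1:
            raise TrialValidationError(
                f"n_select must be in [1, n_reference - 1], got "
                f"{self.n_select} with n_reference={self.n_reference}"
            )
        if self.n_select == 1 and not self.is_ranked:
            object.__setattr__(self, "is_ranked", True)

    @property
    def n_outcome(self) -> int:
        """Number of distinct response outcomes for this configuration."""
        if self.is_ranked:
            return math.perm(self.n_reference, self.n_select)
        return math.comb(self.n_reference, self.n_select)


def all_configurations() -> list[TrialConfiguration]:
    """Every legal configuration (49 in total, after rank normalization)."""
    configs = []
    for n_ref in range(MIN_N_REFERENCE, MAX_N_REFERENCE + 1):
        for n_sel in range(1, n_ref):
            configs.append(TrialConfiguration(n_ref, n_sel, True))
            if n_sel > 1:
                configs.append(TrialConfiguration(n_ref, n_sel, False))
    return configs


def enumerate_outcomes(config: TrialConfiguration) -> list[tuple[int, ...]]:
    """All possible outcomes of a trial, as tuples of reference positions.

    Outcome 0 is always the recorded-selection convention: positions
    ``(0, 1, ..., n_select - 1)`` in that order.  Remaining outcomes follow
    in lexicographic order of the selected positions.  For ranked
    configurations outcomes are ordered tuples (permutations); for unranked
    they are sorted tuples (combinations).
    """
    positions = range(config.n_reference)
    if config.is_ranked:
        pool = itertools.permutations(positions, config.n_select)
    else:
        pool = itertools.combinations(positions, config.n_select)
    observed = tuple(range(config.n_select))
    rest = sorted(o for o in pool if o != observed)
    return [observed] + rest


def implied_triplets(config: TrialConfiguration) -> int:
    """Number of noisy triplet constraints ``q: a > b`` implied by one trial.

    Each selected/unselected pair contributes one constraint; a ranked
    selection additionally orders the selected references among themselves.
    """
    n_sel, n_ref = config.n_select, config.n_reference
    count = n_sel * (n_ref - n_sel)
    if config.is_ranked:
        count += math.comb(n_sel, 2)
    return count


def _as_matrix(stimulus_set: np.ndarray) -> np.ndarray:
    arr = np.asarray(stimulus_set, dtype=np.int64)
    if arr.ndim != 2:
        raise TrialValidationError("stimulus_set must be a 2-D integer matrix")
    if arr.shape[1] > 1 + MAX_N_REFERENCE:
        raise TrialValidationError(
            f"stimulus_set has {arr.shape[1] - 1} reference columns; "
            f"maximum is {MAX_N_REFERENCE}"
        )
    if arr.shape[1] < 1 + MAX_N_REFERENCE:
        padded = np.full((arr.shape[0], 1 + MAX_N_REFERENCE), PAD, dtype=np.int64)
        padded[:, : arr.shape[1]] = arr
        arr = padded
    return arr


def _broadcast_rowwise(value, n_row: int, dtype) -> np.ndarray:
    arr = np.asarray(value, dtype=dtype)
    if arr.ndim == 0:
        arr = np.full(n_row, arr, dtype=dtype)
    if arr.shape != (n_row,):
        raise TrialValidationError(
            f"per-trial attribute has shape {arr.shape}, expected ({n_row},)"
        )
    return arr


@dataclass(eq=False)
class Docket:
    """A table of unjudged trials.

    ``stimulus_set`` holds one row per trial: column 0 is the query index,
    columns 1..8 the reference indices, padded with ``-1``.  ``n_select``
    and ``is_ranked`` may vary per row, so heterogeneous configurations can
    live in one docket.
    """

    stimulus_set: np.ndarray
    n_select: np.ndarray = field(default=1)
    is_ranked: np.ndarray = field(default=True)

    def __post_init__(self):
        self.stimulus_set = _as_matrix(self.stimulus_set)
        n = self.n_trial
        self.n_select = _broadcast_rowwise(self.n_select, n, np.int64)
        self.is_ranked = _broadcast_rowwise(self.is_ranked, n, bool)
        self.is_ranked[self.n_select == 1] = True

    @property
    def n_trial(self) -> int:
        return self.stimulus_set.shape[0]

    @property
    def n_reference(self) -> np.ndarray:
        """Per-row reference count (number of non-padding reference cells)."""
        return (self.stimulus_set[:, 1:] != PAD).sum(axis=1)

    @property
    def n_stimulus(self) -> int:
        """Size of the stimulus index space, inferred as max index + 1."""
        if self.n_trial == 0:
            return 0
        return int(self.stimulus_set.max()) + 1

    def config(self, i: int) -> TrialConfiguration:
        return TrialConfiguration(
            int(self.n_reference[i]), int(self.n_select[i]), bool(self.is_ranked[i])
        )

    def references(self, i: int) -> np.ndarray:
        row = self.stimulus_set[i, 1:]
        return row[row != PAD]

    def __len__(self) -> int:
        return self.n_trial

    def __eq__(self, other) -> bool:
        if not isinstance(other, type(self)):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in self._fields()
        )

    @classmethod
    def _fields(cls) -> tuple[str, ...]:
        return ("stimulus_set", "n_select", "is_ranked")


@dataclass(eq=False)
class Observations(Docket):
    """A table of judged trials.

    Rows follow the response layout: column 0 the query, then the selected
    references in rank order, then the unselected references.  ``group_id``
    tags each trial with the participant group that produced it (0 when all
    data come from one population).
    """

    group_id: np.ndarray = field(default=0)

    def __post_init__(self):
        super().__post_init__()
        self.group_id = _broadcast_rowwise(self.group_id, self.n_trial, np.int64)

    @property
    def n_group(self) -> int:
        if self.n_trial == 0:
            return 1
        return int(self.group_id.max()) + 1

    def selected(self, i: int) -> np.ndarray:
        return self.stimulus_set[i, 1 : 1 + int(self.n_select[i])]

    def subset(self, rows) -> "Observations":
        return Observations(
            self.stimulus_set[rows],
            self.n_select[rows],
            self.is_ranked[rows],
            self.group_id[rows],
        )

    @classmethod
    def _fields(cls) -> tuple[str, ...]:
        return ("stimulus_set", "n_select", "is_ranked", "group_id")


def validate(obs: Docket) -> Docket:
    """Check structural invariants, returning the input unchanged if valid.

    Raises :class:`TrialValidationError` naming the first offending row.
    """
    ss = obs.stimulus_set
    n_ref = obs.n_reference
    for i in range(obs.n_trial):
        row = ss[i]
        if row[0] < 0:
            raise TrialValidationError(f"row {i}: negative query index {row[0]}")
        refs = row[1:]
        valid = refs[refs != PAD]
        if n_ref[i] < MIN_N_REFERENCE or n_ref[i] > MAX_N_REFERENCE:
            raise TrialValidationError(
                f"row {i}: {n_ref[i]} references, must be in "
                f"[{MIN_N_REFERENCE}, {MAX_N_REFERENCE}]"
            )
        # padding must be a contiguous tail
        if (refs[: n_ref[i]] == PAD).any():
            raise TrialValidationError(
                f"row {i}: padding sentinel before the last valid reference"
            )
        if (valid < 0).any():
            raise TrialValidationError(f"row {i}: negative reference index")
        stimuli = np.concatenate([[row[0]], valid])
        if len(np.unique(stimuli)) != len(stimuli):
            raise TrialValidationError(
                f"row {i}: duplicate stimulus within trial {stimuli.tolist()}"
            )
        if not 1 <= obs.n_select[i] <= n_ref[i] - 1:
            raise TrialValidationError(
                f"row {i}: n_select={obs.n_select[i]} out of range for "
                f"{n_ref[i]} references"
            )
        if isinstance(obs, Observations) and obs.group_id[i] < 0:
            raise TrialValidationError(f"row {i}: negative group_id")
    return obs


def stack(items: Sequence[Docket]) -> Docket:
    """Row-concatenate dockets or observations, preserving per-row configs."""
    if len(items) == 0:
        raise ValueError("nothing to stack")
    first = items[0]
    if not all(type(x) is type(first) for x in items):
        raise TrialValidationError("cannot stack mixed Docket/Observations")
    kwargs = {
        f: np.concatenate([getattr(x, f) for x in items])
        for f in type(first)._fields()
    }
    return type(first)(**kwargs)


def _frame_to_observations(df: pd.DataFrame, with_group: bool):
    missing = [c for c in (_OBS_COLUMNS if with_group else _DOCKET_COLUMNS)
               if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing columns: {missing}")
    ss = df[["query"] + [f"ref{i}" for i in range(MAX_N_REFERENCE)]].to_numpy(
        dtype=np.int64
    )
    n_select = df["n_select"].to_numpy(dtype=np.int64)
    is_ranked = df["is_ranked"].to_numpy(dtype=np.int64).astype(bool)
    if with_group:
        group = (
            df["group_id"].to_numpy(dtype=np.int64)
            if "group_id" in df.columns
            else np.zeros(len(df), dtype=np.int64)
        )
        return Observations(ss, n_select, is_ranked, group)
    return Docket(ss, n_select, is_ranked)


def _to_frame(obs: Docket) -> pd.DataFrame:
    data = {"query": obs.stimulus_set[:, 0]}
    for i in range(MAX_N_REFERENCE):
        data[f"ref{i}"] = obs.stimulus_set[:, 1 + i]
    data["n_select"] = obs.n_select
    data["is_ranked"] = obs.is_ranked.astype(int)
    if isinstance(obs, Observations):
        data["group_id"] = obs.group_id
    return pd.DataFrame(data)


def read_observations(path) -> Observations:
    """Read judged trials from the documented CSV schema."""
    df = pd.read_csv(path)
    if "group_id" not in df.columns:
        df["group_id"] = 0
    obs = _frame_to_observations(df, with_group=True)
    return validate(obs)


def write_observations(obs: Observations, path) -> None:
    _to_frame(obs).to_csv(path, index=False)


def read_docket(path) -> Docket:
    df = pd.read_csv(path)
    docket = _frame_to_observations(df, with_group=False)
    validate(docket)
    return docket


def write_docket(docket: Docket, path) -> None:
    _to_frame(docket).to_csv(path, index=False)
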