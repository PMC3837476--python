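"""Trial tables and epoch containers.

A *trial table* is a plain :class:`pandas.DataFrame`, one row per trial, with
design labels (subject, item, condition, prime type, version), behavioral
outcomes (reaction time in ms, accuracy) and item covariates (word length,
log surface frequency, Albright score).  Epoched source-estimate time
courses live in :class:`EpochSet` (trials x time) and
:class:`SourceEpochSet` (trials x sources x time), aligned to trial-table
rows through ``trial_index``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

CONDITIONS = ("identity", "regular", "irregular", "pseudo_irregular", "nonword")
WORD_CONDITIONS = CONDITIONS[:4]
PRIME_TYPES = ("related", "unrelated")

#: columns every trial table must carry
TRIAL_COLUMNS = (
    "subject_id",
    "item_id",
    "condition",
    "prime_type",
    "version",
    "word_length",
    "log_surface_freq",
    "albright_score",
)


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check trial-table invariants and return the table unchanged.

    Raises ``ValueError`` on a missing column, an unknown condition or prime
    type, a duplicated (subject, item) pair, an Albright score outside
    [0, 1], or a non-positive reaction time.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    bad_cond = set(trials["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
    bad_prime = set(trials["prime_type"].unique()) - set(PRIME_TYPES)
    if bad_prime:
        raise ValueError(f"unknown prime types: {sorted(bad_prime)}")
    if trials.duplicated(subset=["subject_id", "item_id"]).any():
        raise ValueError("duplicated (subject_id, item_id) pairs")
    score = trials["albright_score"].dropna()
    if ((score < 0) | (score > 1)).any():
        raise ValueError("albright_score outside [0, 1]")
    if "rt_ms" in trials.columns:
        rt = trials["rt_ms"].dropna()
        if (rt <= 0).any():
            raise ValueError("non-positive rt_ms")
    return trials


def read_trial_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited trial table and validate it."""
    trials = pd.read_csv(path, sep=sep)
    return validate_trial_table(trials)


def write_trial_table(trials: pd.DataFrame, path, sep: str = "\t") -> None:
    validate_trial_table(trials).to_csv(path, sep=sep, index=True, index_label="trial")


def _check_time_grid(time_ms: np.ndarray, sampling_rate_hz: float) -> None:
    if time_ms.ndim != 1 or len(time_ms) < 1:
        raise ValueError("time_ms must be a 1-D, non-empty array")
    if len(time_ms) > 1:
        dt = np.diff(time_ms)
        step = 1000.0 / sampling_rate_hz
        if (dt <= 0).any() or not np.allclose(dt, step, rtol=1e-6, atol=1e-6):
            raise ValueError(
                "time_ms must be a strictly increasing uniform grid with "
                f"spacing 1000/sampling_rate_hz = {step} ms"
            )


@dataclasses.dataclass
class EpochSet:
    """Signed source-estimate amplitudes, one row per trial.

    Parameters
    ----------
    data : (n_trials, n_times) float array
        Signed amplitude (dSPM-like units, or pT in raw-channel mode).
    time_ms : (n_times,) array
        Uniform time grid, ms relative to target onset.
    trial_index : (n_trials,) int array
        Row labels of the trial table each epoch belongs to.
    sampling_rate_hz : float
    """

    data: np.ndarray
    time_ms: np.ndarray
    trial_index: np.ndarray
    sampling_rate_hz: float = 1000.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.trial_index = np.asarray(self.trial_index)
        if self.data.ndim != 2:
            raise ValueError("EpochSet.data must be 2-D (trials x time)")
        if self.data.shape[1] != len(self.time_ms):
            raise ValueError("data/time_ms length mismatch")
        if self.data.shape[0] != len(self.trial_index):
            raise ValueError("data/trial_index length mismatch")
        _check_time_grid(self.time_ms, self.sampling_rate_hz)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    def window_slice(self, window_ms) -> slice:
        """Index slice of samples with start <= t <= end (inclusive)."""
        start, end = window_ms
        if end < start:
            raise ValueError("window end before start")
        if start < self.time_ms[0] or end > self.time_ms[-1]:
            raise ValueError(
                f"window {window_ms} outside epoch range "
                f"({self.time_ms[0]}, {self.time_ms[-1]})"
            )
        lo = int(np.searchsorted(self.time_ms, start - 1e-9, side="left"))
        hi = int(np.searchsorted(self.time_ms, end + 1e-9, side="right"))
        if hi <= lo:
            raise ValueError(f"window {window_ms} contains no samples")
        return slice(lo, hi)

    def crop(self, window_ms) -> "EpochSet":
        sl = self.window_slice(window_ms)
        return EpochSet(
            self.data[:, sl], self.time_ms[sl], self.trial_index, self.sampling_rate_hz
        )

    def subset(self, trial_ids: Iterable) -> "EpochSet":
        """Rows for the given trial-table labels, in the given order."""
        pos = pd.Index(self.trial_index).get_indexer(np.asarray(list(trial_ids)))
        if (pos < 0).any():
            raise KeyError("trial ids not present in EpochSet.trial_index")
        return EpochSet(
            self.data[pos], self.time_ms, self.trial_index[pos], self.sampling_rate_hz
        )

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.time_ms.copy(),
            self.trial_index.copy(),
            self.sampling_rate_hz,
        )

    # ---- IO ------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset("trial_index", data=np.asarray(self.trial_index, dtype=np.int64))
            f.attrs["sampling_rate_hz"] = self.sampling_rate_hz
            f.attrs["kind"] = "EpochSet"

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            return cls(
                f["data"][()],
                f["time_ms"][()],
                f["trial_index"][()],
                float(f.attrs["sampling_rate_hz"]),
            )

    def to_tsv(self, path) -> None:
        """Small text fixture: one row per trial, columns = time points."""
        df = pd.DataFrame(self.data, index=self.trial_index, columns=self.time_ms)
        df.index.name = "trial"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, sampling_rate_hz: float | None = None) -> "EpochSet":
        df = pd.read_csv(path, sep="\t", index_col=0)
        time_ms = df.columns.to_numpy(dtype=float)
        if sampling_rate_hz is None:
            sampling_rate_hz = 1000.0 / float(np.diff(time_ms).mean()) if len(time_ms) > 1 else 1000.0
        return cls(df.to_numpy(), time_ms, df.index.to_numpy(), sampling_rate_hz)


@dataclasses.dataclass
class SourceEpochSet:
    """Trials x sources x time tensor with an anatomical label per source.

    ``adjacency`` lists undirected source-grid edges (pairs of source
    indices); when omitted, sources are treated as a chain
    (i adjacent to i+1), which is the layout the synthetic grid uses.
    """

    data: np.ndarray
    time_ms: np.ndarray
    trial_index: np.ndarray
    source_labels: Sequence[str]
    sampling_rate_hz: float = 1000.0
    adjacency: Sequence[tuple[int, int]] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.trial_index = np.asarray(self.trial_index)
        self.source_labels = list(self.source_labels)
        if self.data.ndim != 3:
            raise ValueError("SourceEpochSet.data must be 3-D (trials x sources x time)")
        if self.data.shape[2] != len(self.time_ms):
            raise ValueError("data/time_ms length mismatch")
        if self.data.shape[0] != len(self.trial_index):
            raise ValueError("data/trial_index length mismatch")
        if self.data.shape[1] != len(self.source_labels):
            raise ValueError("label map must cover all sources")
        _check_time_grid(self.time_ms, self.sampling_rate_hz)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sources(self) -> int:
        return self.data.shape[1]

    def neighbors(self) -> list[set[int]]:
        """Adjacency as neighbor sets; defaults to the chain layout."""
        nbrs: list[set[int]] = [set() for _ in range(self.n_sources)]
        edges = self.adjacency
        if edges is None:
            edges = [(i, i + 1) for i in range(self.n_sources - 1)]
        for i, j in edges:
            nbrs[i].add(j)
            nbrs[j].add(i)
        return nbrs

    def sources_in_masks(self, masks: Iterable[str]) -> np.ndarray:
        masks = set(masks)
        return np.array([i for i, lab in enumerate(self.source_labels) if lab in masks], dtype=int)

    def window_slice(self, window_ms) -> slice:
        helper = EpochSet(
            self.data[:, 0, :], self.time_ms, self.trial_index, self.sampling_rate_hz
        )
        return helper.window_slice(window_ms)

    def subset(self, trial_ids: Iterable) -> "SourceEpochSet":
        pos = pd.Index(self.trial_index).get_indexer(np.asarray(list(trial_ids)))
        if (pos < 0).any():
            raise KeyError("trial ids not present in SourceEpochSet.trial_index")
        return SourceEpochSet(
            self.data[pos],
            self.time_ms,
            self.trial_index[pos],
            self.source_labels,
            self.sampling_rate_hz,
            self.adjacency,
        )

    def source_mean(self, sources: Iterable[int]) -> EpochSet:
        """Average over the given sources -> trials x time EpochSet."""
        idx = np.asarray(list(sources), dtype=int)
        if idx.size == 0:
            raise ValueError("empty source set")
        return EpochSet(
            self.data[:, idx, :].mean(axis=1),
            self.time_ms,
            self.trial_index,
            self.sampling_rate_hz,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset("trial_index", data=np.asarray(self.trial_index, dtype=np.int64))
            f.create_dataset(
                "source_labels",
                data=np.array(self.source_labels, dtype=h5py.string_dtype()),
            )
            if self.adjacency is not None:
                f.create_dataset("adjacency", data=np.asarray(self.adjacency, dtype=np.int64))
            f.attrs["sampling_rate_hz"] = self.sampling_rate_hz
            f.attrs["kind"] = "SourceEpochSet"

    @classmethod
    def from_hdf5(cls, path) -> "SourceEpochSet":
        with h5py.File(path, "r") as f:
            adjacency = None
            if "adjacency" in f:
                adjacency = [tuple(e) for e in f["adjacency"][()]]
            return cls(
                f["data"][()],
                f["time_ms"][()],
                f["trial_index"][()],
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["source_labels"][()]],
                float(f.attrs["sampling_rate_hz"]),
                adjacency,
            )
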