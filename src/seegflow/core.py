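"""Shared data model and I/O.

The universal currency of the pipeline is the :class:`TrialTensor`: a
(leads x trials x samples) array of trial-aligned voltage traces with an
explicit validity mask, a sampling rate, and the sample index of static
stimulus onset.  Rejected (trial, lead) combinations are marked in the mask
rather than overwritten with sentinel values, which makes the exclusion
contract testable: every downstream stage must treat masked combinations as
absent.

On disk a dataset is an HDF5 container (datasets /data and /mask, scalar
attributes, a /trials label table) with the lead metadata as a TSV sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

REGION_TAGS = ("T", "VL", "Md", "Ds", "outside", "gray-other")

#: columns every trial-label table carries
TRIAL_COLUMNS = ("task", "truncation", "static_duration_ms")


class FormatError(ValueError):
    """Raised when a container file lacks required structure."""


@dataclass
class TrialTensor:
    """Trial-aligned multichannel recording segment.

    Parameters
    ----------
    data : ndarray, shape (n_leads, n_trials, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate, Hz.
    onset_index : int
        Sample index of static stimulus onset (sample 0 = first recorded
        sample).  Latencies are reported in ms relative to this index.
    mask : ndarray of bool, same shape as ``data``
        True marks invalid entries.  After rejection the mask is
        all-or-nothing along the sample axis for each (lead, trial).
    trial_labels : pandas.DataFrame
        One row per trial; columns include ``task`` ('gender'/'action'),
        ``truncation`` ('full'/'truncated'), ``static_duration_ms`` and
        optionally ``response_time_ms``.
    lead_ids : list of str
        Lead labels (clinical convention: shaft letter + contact number).
    """

    data: np.ndarray
    fs: float
    onset_index: int
    mask: np.ndarray = None
    trial_labels: pd.DataFrame = None
    lead_ids: list = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (leads, trials, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.onset_index = int(self.onset_index)
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")
        if self.trial_labels is None:
            self.trial_labels = pd.DataFrame(
                {
                    "task": ["gender"] * self.n_trials,
                    "truncation": ["full"] * self.n_trials,
                    "static_duration_ms": [583.0] * self.n_trials,
                }
            )
        if len(self.trial_labels) != self.n_trials:
            raise ValueError("trial_labels length must equal n_trials")
        if self.lead_ids is None:
            self.lead_ids = [f"L{i}" for i in range(self.n_leads)]
        if len(self.lead_ids) != self.n_leads:
            raise ValueError("lead_ids length must equal n_leads")

    # -- shape helpers -------------------------------------------------
    @property
    def n_leads(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample time in ms relative to static onset."""
        return (np.arange(self.n_samples) - self.onset_index) * 1000.0 / self.fs

    def lead_index(self, lead_id: str) -> int:
        return self.lead_ids.index(lead_id)

    def valid_combination(self) -> np.ndarray:
        """Boolean (lead, trial) matrix: True where wholly unmasked."""
        return ~self.mask.any(axis=2)

    def copy(self) -> "TrialTensor":
        return TrialTensor(
            data=self.data.copy(),
            fs=self.fs,
            onset_index=self.onset_index,
            mask=self.mask.copy(),
            trial_labels=self.trial_labels.copy(),
            lead_ids=list(self.lead_ids),
        )

    def with_mask(self, combo_mask: np.ndarray) -> "TrialTensor":
        """Return a copy whose mask additionally covers the given
        (lead, trial) combinations over all samples."""
        out = self.copy()
        out.mask |= np.asarray(combo_mask, dtype=bool)[:, :, None]
        return out


def validate_baseline(tensor: TrialTensor) -> bool:
    """True iff the tensor offers at least 900 ms of pre-onset baseline.

    The GC baseline window starts 900 ms before static onset, so any
    analysable segment must be aligned at least that far back.
    """
    return tensor.onset_index >= 0.9 * tensor.fs


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def write_trial_tensor(path, tensor: TrialTensor) -> None:
    """Write a TrialTensor to an HDF5 container (bit-exact round trip)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tensor.data)
        f.create_dataset("mask", data=tensor.mask.astype(np.uint8))
        f.attrs["fs"] = float(tensor.fs)
        f.attrs["onset_index"] = int(tensor.onset_index)
        grp = f.create_group("trials")
        for col in tensor.trial_labels.columns:
            vals = tensor.trial_labels[col].to_numpy()
            if vals.dtype.kind in "OU":
                vals = vals.astype("S")
            grp.create_dataset(col, data=vals)
        f.create_dataset(
            "lead_ids", data=np.asarray(tensor.lead_ids, dtype="S")
        )


def read_trial_tensor(path) -> TrialTensor:
    """Read a TrialTensor container written by :func:`write_trial_tensor`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for key in ("data", "mask"):
            if key not in f:
                raise FormatError(f"container missing dataset '{key}'")
        for attr in ("fs", "onset_index"):
            if attr not in f.attrs:
                raise FormatError(f"container missing attribute '{attr}'")
        fs = float(f.attrs["fs"])
        if fs <= 0:
            raise ValueError("fs must be positive")
        cols = {}
        if "trials" in f:
            for col in f["trials"]:
                vals = f["trials"][col][()]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
        labels = pd.DataFrame(cols) if cols else None
        lead_ids = None
        if "lead_ids" in f:
            lead_ids = [s.decode() if isinstance(s, bytes) else str(s)
                        for s in f["lead_ids"][()]]
        return TrialTensor(
            data=f["data"][()],
            fs=fs,
            onset_index=int(f.attrs["onset_index"]),
            mask=f["mask"][()].astype(bool),
            trial_labels=labels,
            lead_ids=lead_ids,
        )


# ---------------------------------------------------------------------------
# lead metadata table
# ---------------------------------------------------------------------------

def read_lead_table(path) -> pd.DataFrame:
    """Read the lead metadata TSV (lead_id, region, patient_id, in_ez)."""
    df = pd.read_csv(path, sep="\t", dtype={"lead_id": str, "patient_id": str})
    required = {"lead_id", "region", "patient_id", "in_ez"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"lead table missing columns: {sorted(missing)}")
    bad = set(df["region"]) - set(REGION_TAGS)
    if bad:
        raise ValueError(f"unknown region tags: {sorted(bad)}")
    for pid, sub in df.groupby("patient_id"):
        if sub["lead_id"].duplicated().any():
            raise ValueError(f"duplicate lead_ids within patient {pid}")
    df["in_ez"] = df["in_ez"].astype(bool)
    return df


def write_lead_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
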