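"""In-memory containers for epoched and averaged ERP data.

`EpochSet` holds fixed-length multi-channel epochs (subjects x blocks x
trials) together with trial-level behavioral annotations and rejection
flags; `AverageSet` holds the per subject x drug x block x condition mean
waveforms (the temporal-PCA input) with accepted-trial counts.

Amplitudes are microvolts throughout; the time axis is seconds relative to
stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .montage import Montage

#: Metadata columns every EpochSet carries.
META_COLUMNS = (
    "subject", "drug", "block", "condition", "trial",
    "onset_s", "tone_hz", "response", "rt_ms",
)

FLAG_COLUMNS = ("reject_artifact", "reject_behavior", "reject_reason")


@dataclass
class EpochSet:
    """Fixed-length multi-channel epochs with behavioral annotations.

    data : (n_epochs, n_channels, n_times) array, microvolts
    meta : one row per epoch (see META_COLUMNS; flag columns are added by
        the preprocessing steps and default to False / "")
    """

    data: np.ndarray
    channels: list[str]
    times: np.ndarray          # seconds, stimulus-locked
    sfreq: float
    meta: pd.DataFrame
    montage: Montage
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_times)")
        if self.data.shape[0] != len(self.meta):
            raise ValueError("meta rows must match epoch count")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis must match channel names")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis must match times")
        for col in FLAG_COLUMNS:
            if col not in self.meta.columns:
                self.meta[col] = "" if col == "reject_reason" else False

    # -- helpers ---------------------------------------------------------

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def scalp_picks(self) -> np.ndarray:
        scalp = set(self.montage.scalp_channels)
        return np.array([i for i, c in enumerate(self.channels) if c in scalp])

    @property
    def eog_picks(self) -> np.ndarray:
        eog = set(self.montage.eog_channels)
        return np.array([i for i, c in enumerate(self.channels) if c in eog])

    @property
    def accepted(self) -> np.ndarray:
        return ~(self.meta["reject_artifact"].to_numpy()
                 | self.meta["reject_behavior"].to_numpy())

    def copy(self, data: np.ndarray | None = None) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy() if data is None else data,
            meta=self.meta.copy(),
        )

    def behavioral_log(self) -> pd.DataFrame:
        """Trial table of the behavioral annotations (no waveforms)."""
        cols = [c for c in META_COLUMNS if c in self.meta.columns]
        return self.meta[cols].copy()


@dataclass
class AverageSet:
    """Per-cell average ERPs: one 19-channel waveform per
    subject x drug x block x condition, with accepted-trial counts.

    data : (n_cells, n_scalp_channels, n_times) array, microvolts
    meta : columns subject, drug, block, condition, n_accepted
    """

    data: np.ndarray
    channels: list[str]
    times: np.ndarray
    sfreq: float
    meta: pd.DataFrame
    montage: Montage
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.meta):
            raise ValueError("meta rows must match cell count")
        bad = self.meta["n_accepted"] > self.meta.get(
            "n_presented", self.meta["n_accepted"])
        if bool(np.any(bad)):
            raise ValueError("accepted-trial count exceeds presented trials")

    @property
    def subjects(self) -> list:
        return sorted(self.meta["subject"].unique().tolist())

    def select(self, drug: str, condition: str) -> "AverageSet":
        mask = ((self.meta["drug"] == drug)
                & (self.meta["condition"] == condition)).to_numpy()
        return AverageSet(
            data=self.data[mask],
            channels=list(self.channels),
            times=self.times,
            sfreq=self.sfreq,
            meta=self.meta.loc[mask].reset_index(drop=True),
            montage=self.montage,
            ground_truth=self.ground_truth,
        )
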