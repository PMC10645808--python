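"""Event table container for mass-cytometry data.

An :class:`EventTable` wraps a per-cell intensity matrix (events x channels,
columns named by marker) together with acquisition quality fields, sample
metadata and — for synthetic data — per-event ground-truth population labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ACQUISITION_CHANNELS, PanelDefinition

#: truth / gate population labels
POPULATIONS = (
    "carrier",
    "control",
    "ctc_epithelial",
    "ctc_early_emt",
    "ctc_advanced_emt",
    "leucocyte",
    "debris",
)

CTC_LABELS = ("ctc_epithelial", "ctc_early_emt", "ctc_advanced_emt")


@dataclass
class EventTable:
    """Events x channels intensity matrix plus metadata.

    Parameters
    ----------
    data:
        Non-negative intensities; columns are marker names plus the
        acquisition channels.
    sample_id, patient_id:
        Identity of the stained sample and of the blood donor.
    truth:
        Optional per-event ground-truth population label (synthetic data
        only); must cover every event when present.
    transformed:
        True once analytical channels carry ArcSinh-transformed values.
    """

    data: pd.DataFrame
    sample_id: str = ""
    patient_id: str = ""
    truth: pd.Series | None = None
    transformed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.truth is not None:
            if len(self.truth) != len(self.data):
                raise ValueError("truth labels must cover every event")
            self.truth = self.truth.reset_index(drop=True)
        self.data = self.data.reset_index(drop=True)

    # -- basics -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def matrix(self, markers: list[str]) -> np.ndarray:
        return self.data.loc[:, markers].to_numpy(dtype=float)

    def validate_against(self, panel: PanelDefinition) -> None:
        """Raise if the table lacks any panel channel."""
        missing = [m for m in panel.markers() if m not in self.data.columns]
        if missing:
            raise KeyError(f"event table missing channels: {missing}")
        vals = self.data[panel.analytical_markers].to_numpy()
        if not self.transformed and (vals < 0).any():
            raise ValueError("raw intensities must be non-negative")

    def subset(self, mask: np.ndarray | pd.Series) -> "EventTable":
        mask = np.asarray(mask, dtype=bool)
        truth = self.truth[mask] if self.truth is not None else None
        return replace(
            self,
            data=self.data.loc[mask].reset_index(drop=True),
            truth=truth.reset_index(drop=True) if truth is not None else None,
        )

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write events (and truth labels, if any) to a single CSV."""
        out = self.data.copy()
        if self.truth is not None:
            out["__truth__"] = self.truth.to_numpy()
        out.insert(0, "__sample_id__", self.sample_id)
        out.insert(1, "__patient_id__", self.patient_id)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path)
        sample_id = str(df.pop("__sample_id__").iloc[0]) if "__sample_id__" in df else ""
        patient_id = str(df.pop("__patient_id__").iloc[0]) if "__patient_id__" in df else ""
        truth = df.pop("__truth__") if "__truth__" in df else None
        return cls(df, sample_id=sample_id, patient_id=patient_id, truth=truth)


def concatenate_events(tables: list[EventTable]) -> EventTable:
    """Stack event tables; patient identity is kept per event.

    The result gains a ``patient_id`` column so per-event provenance
    survives concatenation across samples.
    """
    if not tables:
        raise ValueError("no event tables to concatenate")
    frames = []
    truths = []
    for t in tables:
        df = t.data.copy()
        df["patient_id"] = t.patient_id
        frames.append(df)
        if t.truth is not None:
            truths.append(t.truth)
    data = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True) if len(truths) == len(tables) else None
    return EventTable(
        data,
        sample_id="concatenated",
        patient_id="",
        truth=truth,
        transformed=tables[0].transformed,
    )


def acquisition_columns(table: EventTable) -> list[str]:
    return [c for c in ACQUISITION_CHANNELS if c in table.data.columns]
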