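"""Event-level container for a single cytometry sample."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EventMatrix:
    """Events x channels intensity table for one acquired sample.

    ``data`` holds one column per channel (scatter channels on linear
    scale, markers on the instrument's compensated scale unless a
    transform has been applied).  ``truth_labels``, when present, carries
    the simulator's hidden per-event population tag (including the
    nuisance classes debris / doublet / dead) and travels with every
    subset operation so gating output can be scored against ground truth.
    """

    sample_id: str
    data: pd.DataFrame
    truth_labels: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if len(self.truth_labels) != len(self.data):
                raise ValueError("truth_labels length must match event count")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask: np.ndarray) -> "EventMatrix":
        """Boolean-mask selection preserving truth labels and metadata."""
        mask = np.asarray(mask, dtype=bool)
        labels = self.truth_labels[mask] if self.truth_labels is not None else None
        return EventMatrix(self.sample_id, self.data.loc[mask].reset_index(drop=True),
                           labels, dict(self.metadata))

    def with_data(self, data: pd.DataFrame) -> "EventMatrix":
        return EventMatrix(self.sample_id, data, self.truth_labels, dict(self.metadata))
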