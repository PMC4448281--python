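"""Shared result container for feature-extraction methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FEResult:
    """Outcome of a feature-extraction run.

    ``selected`` holds 0-based feature indices in rank order (best first).
    ``scores`` is the per-feature statistic or P-value the ranking used
    (one entry per feature of the input matrix, not only the selected ones);
    its meaning depends on ``method``.
    """

    selected: np.ndarray
    scores: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.selected.tolist())) != len(self.selected):
            raise ValueError("selected indices contain duplicates")
        if self.selected.size and (
            self.selected.min() < 0 or self.selected.max() >= self.scores.shape[0]
        ):
            raise ValueError("selected indices outside the feature range")

    def selected_set(self) -> frozenset[int]:
        return frozenset(self.selected.tolist())

    def to_frame(self, feature_ids: list[str] | None = None) -> pd.DataFrame:
        """Ranked table of the selected features (id, rank, score)."""
        ids = (
            [feature_ids[i] for i in self.selected]
            if feature_ids is not None
            else [str(i) for i in self.selected]
        )
        return pd.DataFrame(
            {
                "feature_id": ids,
                "feature_index": self.selected,
                "rank": np.arange(1, len(self.selected) + 1),
                "score": self.scores[self.selected],
            }
        )
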