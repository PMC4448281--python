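"""Feature-by-sample expression matrices and their on-disk representation.

The container mirrors the layout used throughout the package: features in
rows, samples in columns, with an optional per-sample categorical label
(class or experimental condition).  On disk it is a tab-delimited table
whose header row holds the sample identifiers, optionally accompanied by a
two-column ``sample -> condition`` map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A real-valued feature-by-sample matrix with identifiers and labels.

    Parameters
    ----------
    values
        Array of shape ``(n_features, n_samples)``.
    feature_ids
        One identifier per row.
    sample_ids
        One identifier per column.
    labels
        Optional per-sample class/condition assignment (categorical; no
        ordering is assumed anywhere in the package).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (features x samples)")
        n, m = self.values.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.feature_ids) != n:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {n} rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} columns")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (m,):
                raise ValueError("labels must assign one class to every sample")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def subset_samples(self, mask_or_idx) -> "ExpressionMatrix":
        """Return a copy restricted to the given sample positions."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.feature_ids),
            [self.sample_ids[i] for i in idx],
            None if self.labels is None else self.labels[idx],
        )

    def write_tsv(self, path: str | Path, label_path: str | Path | None = None) -> None:
        """Write the matrix as TSV (features in rows, header = sample ids).

        If ``label_path`` is given, a two-column ``sample_id<TAB>condition``
        map is written alongside.
        """
        self.to_frame().to_csv(path, sep="\t", index_label="feature_id")
        if label_path is not None:
            if self.labels is None:
                raise ValueError("matrix has no labels to write")
            pd.DataFrame({"sample_id": self.sample_ids, "condition": self.labels}).to_csv(
                label_path, sep="\t", index=False
            )


def read_expression_tsv(path: str | Path, label_path: str | Path | None = None) -> ExpressionMatrix:
    """Read a feature-by-sample TSV, optionally joining a sample->condition map."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = None
    if label_path is not None:
        lab = pd.read_csv(label_path, sep="\t")
        lab = lab.set_index(lab.columns[0])[lab.columns[1]]
        missing = [s for s in df.columns if s not in lab.index]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing[:5]}")
        labels = lab.loc[df.columns].to_numpy()
    return ExpressionMatrix(df.to_numpy(float), list(df.index), list(df.columns), labels)


def labels_to_codes(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Encode categorical labels as 0-based integer codes (sorted unique order)."""
    classes = sorted(pd.unique(np.asarray(labels)).tolist())
    lookup = {c: i for i, c in enumerate(classes)}
    return np.array([lookup[v] for v in labels]), classes
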