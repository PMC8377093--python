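"""Score-matrix container for non-negative psychometric batteries.

The canonical in-memory orientation is items x subjects (p x n), so that a
fitted basis is items x factors and each item's factor assignment can be read
off its basis row.  Tabular I/O uses the conventional subjects-as-rows layout
and transposes on the way in/out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 17 total-achievement variables of the D-KEFS battery, used as default
#: item labels when p == 17.
DKEFS_ITEMS: tuple[str, ...] = (
    "Number-Letter Switching",
    "Letter Fluency",
    "Category Fluency",
    "Category Switching",
    "Design Fluency - Filled Dots",
    "Design Fluency - Empty Dots Only",
    "Design Fluency - Switching",
    "CWI - Inhibition",
    "CWI - Switching",
    "Confirmed Sorts",
    "Free Sorting Description",
    "Sort Recognition",
    "Initial Abstraction Score",
    "20 Questions - Total Achievement",
    "Word Context - Total Achievement",
    "Tower Test - Total Achievement",
    "Proverb Test - Total Achievement",
)


@dataclass
class ScoreMatrix:
    """Items x subjects matrix of non-negative test scores.

    Parameters
    ----------
    values : ndarray of shape (p, n)
        Non-negative, finite scores; rows are items, columns subjects.
    item_labels : list of str
        One label per item (row).
    subject_ids : list of str
        One id per subject (column).
    group_labels : dict, optional
        Mapping subject id -> group label for subgroup analyses.
    metadata : dict
        Free-form provenance (generator parameters, source path, ...).
    """

    values: np.ndarray
    item_labels: list[str]
    subject_ids: list[str]
    group_labels: dict[str, str] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D items x subjects array")
        p, n = self.values.shape
        if p < 2:
            raise ValueError(f"need at least 2 items, got {p}")
        if n < 3:
            raise ValueError(f"need at least 3 subjects, got {n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite with no missing entries")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"scores must be non-negative; item {self.item_labels[i]!r} "
                f"subject {self.subject_ids[j]!r} is {self.values[i, j]}"
            )
        if len(self.item_labels) != p:
            raise ValueError("item_labels length does not match row count")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match column count")
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject ids must be unique")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def subset(self, subject_idx: np.ndarray, name: str | None = None) -> "ScoreMatrix":
        """Return a new ScoreMatrix restricted to the given subject columns."""
        subject_idx = np.asarray(subject_idx)
        ids = [self.subject_ids[i] for i in subject_idx]
        groups = None
        if self.group_labels is not None:
            groups = {s: self.group_labels[s] for s in ids if s in self.group_labels}
        meta = dict(self.metadata)
        if name:
            meta["subset"] = name
        return ScoreMatrix(self.values[:, subject_idx], list(self.item_labels), ids, groups, meta)

    def to_frame(self) -> pd.DataFrame:
        """Subjects x items DataFrame (conventional table layout)."""
        df = pd.DataFrame(self.values.T, index=self.subject_ids, columns=self.item_labels)
        df.index.name = "subject_id"
        if self.group_labels is not None:
            df.insert(0, "group", [self.group_labels.get(s, "") for s in self.subject_ids])
        return df

    def write_csv(self, path, sep: str = ",") -> None:
        # %.17g round-trips float64 exactly
        self.to_frame().to_csv(path, sep=sep, float_format="%.17g")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        id_col: str | None = None,
        metadata_cols: tuple[str, ...] = ("group", "gender", "age", "sex"),
    ) -> "ScoreMatrix":
        """Build a ScoreMatrix from a subjects x items table.

        Non-numeric columns and columns named in ``metadata_cols`` are treated
        as subject metadata, not items.  Subjects with any missing item score
        are dropped (complete-case rule) and the exclusion count is logged.
        """
        df = df.copy()
        if id_col is not None:
            df = df.set_index(id_col)
        elif df.index.name is None and df.columns.size and not pd.api.types.is_numeric_dtype(
            df.iloc[:, 0]
        ):
            df = df.set_index(df.columns[0])
        df.index = df.index.map(str)

        meta_cols = [c for c in df.columns if c.lower() in metadata_cols]
        item_cols = [c for c in df.columns if c not in meta_cols]
        items = df[item_cols].apply(pd.to_numeric, errors="coerce")

        complete = items.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info(
                "complete-case filter: excluded %d of %d subjects with missing scores",
                n_dropped,
                len(df),
            )
        items = items.loc[complete]
        if len(items) < 3:
            raise ValueError("fewer than 3 complete-case subjects after filtering")

        neg = items.lt(0)
        if neg.any().any():
            col = neg.any(axis=0).idxmax()
            row = neg[col].idxmax()
            raise ValueError(
                f"negative score at subject {row!r}, item {col!r}: scores must be non-negative"
            )

        groups = None
        group_col = next((c for c in meta_cols if c.lower() in ("group", "gender", "sex")), None)
        if group_col is not None:
            groups = {str(s): str(v) for s, v in df.loc[complete, group_col].items()}

        meta = {"n_excluded_incomplete": n_dropped}
        for c in meta_cols:
            if c != group_col:
                meta.setdefault("extra_columns", {})[c] = df.loc[complete, c].tolist()
        return cls(items.to_numpy().T, item_cols, items.index.tolist(), groups, meta)


def default_item_labels(p: int) -> list[str]:
    """Battery-style labels: the 17 D-KEFS variables when p == 17, else item_00.."""
    if p == len(DKEFS_ITEMS):
        return list(DKEFS_ITEMS)
    return [f"item_{i:02d}" for i in range(p)]
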