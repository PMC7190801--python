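"""Core data containers shared by every pipeline stage.

The universal input is a cells x TFs activity matrix with per-cell metadata
(condition, timepoint, direction).  Activities are continuous regulon-activity
scores, not counts.  Regulons are per-TF target sets kept separately for the
forward (signal induction) and backward (signal removal) splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The eight-timepoint design: five induction timepoints and three
#: post-removal timepoints.  Day 7 belongs to both transition directions.
TIMEPOINTS = ("0", "8h", "1d", "3d", "7d", "8h_rm", "1d_rm", "3d_rm")
FORWARD_TIMEPOINTS = ("0", "8h", "1d", "3d", "7d")
BACKWARD_TIMEPOINTS = ("7d", "8h_rm", "1d_rm", "3d_rm")

#: Hours since induction start for each design timepoint (removal timepoints
#: are measured from the day-7 removal event).
TIMEPOINT_HOURS = {
    "0": 0.0,
    "8h": 8.0,
    "1d": 24.0,
    "3d": 72.0,
    "7d": 168.0,
    "8h_rm": 176.0,
    "1d_rm": 192.0,
    "3d_rm": 240.0,
}

META_COLUMNS = ("cell_id", "condition", "timepoint", "direction")


@dataclass
class ActivityDataset:
    """Cells x TFs activity matrix with per-cell metadata.

    Parameters
    ----------
    activities
        DataFrame of shape (n_cells, n_tfs) indexed by cell_id.
    cell_meta
        DataFrame indexed by cell_id with columns ``condition``, ``timepoint``
        and ``direction`` (one of ``forward``, ``backward``, ``both``).
    backward_scale
        Optional per-TF (slope, intercept) describing the affine scale on
        which backward-direction measurements live relative to the forward
        scale.  Real data processed separately per direction lands on
        different scales; the synthetic generator records the map it used so
        the rescaling stage has an exactly recoverable target.  ``None``
        means both directions share one scale.
    """

    activities: pd.DataFrame
    cell_meta: pd.DataFrame
    backward_scale: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.activities.index.equals(self.cell_meta.index):
            raise ValueError("activities and cell_meta must share the cell index")
        if self.activities.isna().any().any():
            raise ValueError("activity matrix contains missing values")
        if self.activities.index.has_duplicates:
            raise ValueError("cell_ids must be unique within a dataset")

    @property
    def tf_names(self) -> list[str]:
        return list(self.activities.columns)

    @property
    def n_cells(self) -> int:
        return self.activities.shape[0]

    @property
    def cell_ids(self) -> pd.Index:
        return self.activities.index

    def timepoint_cells(self, timepoint: str) -> pd.Index:
        return self.cell_meta.index[self.cell_meta["timepoint"] == timepoint]

    def subset(self, cell_ids: pd.Index | list[str]) -> "ActivityDataset":
        return ActivityDataset(
            activities=self.activities.loc[cell_ids].copy(),
            cell_meta=self.cell_meta.loc[cell_ids].copy(),
            backward_scale=self.backward_scale,
        )

    def timepoint_means(self, tf: str) -> pd.Series:
        """Mean activity of one TF per timepoint, in design order."""
        grouped = self.activities[tf].groupby(self.cell_meta["timepoint"]).mean()
        order = [t for t in TIMEPOINTS if t in grouped.index]
        return grouped.reindex(order)

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        table = pd.concat(
            [self.cell_meta[["condition", "timepoint", "direction"]], self.activities],
            axis=1,
        )
        table.index.name = "cell_id"
        table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ActivityDataset":
        table = pd.read_csv(path, sep="\t", index_col="cell_id")
        meta_cols = ["condition", "timepoint", "direction"]
        meta = table[meta_cols].astype(str)
        acts = table.drop(columns=meta_cols).astype(float)
        return cls(activities=acts, cell_meta=meta)


@dataclass
class RegulonSet:
    """Per-TF target-gene sets, separately for the two transition directions."""

    forward: dict[str, set[str]]
    backward: dict[str, set[str]]

    @property
    def tfs(self) -> set[str]:
        return set(self.forward) | set(self.backward)

    def targets(self, tf: str) -> set[str]:
        """Union of the forward and backward regulon of one TF."""
        return self.forward.get(tf, set()) | self.backward.get(tf, set())

    def to_tsv(self, forward_path: str | Path, backward_path: str | Path) -> None:
        for mapping, path in ((self.forward, forward_path), (self.backward, backward_path)):
            rows = [(tf, tgt) for tf in sorted(mapping) for tgt in sorted(mapping[tf])]
            pd.DataFrame(rows, columns=["tf", "target"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, forward_path: str | Path, backward_path: str | Path) -> "RegulonSet":
        out: list[dict[str, set[str]]] = []
        for path in (forward_path, backward_path):
            table = pd.read_csv(path, sep="\t")
            mapping: dict[str, set[str]] = {}
            for tf, tgt in zip(table["tf"], table["target"]):
                mapping.setdefault(str(tf), set()).add(str(tgt))
            out.append(mapping)
        return cls(forward=out[0], backward=out[1])


def stack_datasets(datasets: list[ActivityDataset]) -> ActivityDataset:
    """Concatenate datasets with disjoint cell ids into one."""
    acts = pd.concat([d.activities for d in datasets], axis=0)
    meta = pd.concat([d.cell_meta for d in datasets], axis=0)
    return ActivityDataset(activities=acts, cell_meta=meta)


def check_unique_within_condition(meta: pd.DataFrame) -> bool:
    counts = meta.groupby("condition").apply(lambda g: g.index.is_unique, include_groups=False)
    return bool(np.all(counts))
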