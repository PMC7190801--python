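"""Differential TF-activity analysis over the two transition directions.

Each condition's eight-timepoint dataset is split into a forward (signal
induction: 0, 8h, 1d, 3d, 7d) and a backward (signal removal: 7d, 8h_rm,
1d_rm, 3d_rm) dataset, with the day-7 cells shared by both.  Seven pairwise
Wilcoxon rank-sum comparisons are run per condition (four forward against
timepoint 0, three backward against day 7), Bonferroni-adjusted over the TFs
tested and with no fold-change pre-filter.  Common DATFs are TFs that recur
in the per-comparison top-k lists; E/M/I/I2 roles are read off the signs and
significance of the endpoint comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import (
    BACKWARD_TIMEPOINTS,
    FORWARD_TIMEPOINTS,
    TIMEPOINTS,
    ActivityDataset,
    stack_datasets,
)

#: comparison id -> (split, reference timepoint, contrast timepoint)
COMPARISONS: dict[str, tuple[str, str, str]] = {
    "0v8h": ("forward", "0", "8h"),
    "0v1d": ("forward", "0", "1d"),
    "0v3d": ("forward", "0", "3d"),
    "0v7d": ("forward", "0", "7d"),
    "7dv8h_rm": ("backward", "7d", "8h_rm"),
    "7dv1d_rm": ("backward", "7d", "1d_rm"),
    "7dv3d_rm": ("backward", "7d", "3d_rm"),
}

DEFAULT_ALPHA = 0.05
DEFAULT_TOP_K = 100
DEFAULT_MIN_OCCURRENCE = 24


# ---------------------------------------------------------------------------
# Splitting and rescaling


def split_forward_backward(dataset: ActivityDataset) -> tuple[ActivityDataset, ActivityDataset]:
    """Split one condition into forward and backward datasets.

    Day-7 cells appear in both.  If the dataset records a backward affine
    scale (per-TF slope/intercept), it is applied to the backward split —
    including its copy of the day-7 cells — emulating the two directions
    having been processed on different scales.
    """
    present = set(dataset.cell_meta["timepoint"])
    for tp in TIMEPOINTS:
        if tp not in present:
            raise ValueError(f"dataset is missing timepoint {tp!r}")
    fwd_cells = dataset.cell_meta.index[dataset.cell_meta["timepoint"].isin(FORWARD_TIMEPOINTS)]
    bwd_cells = dataset.cell_meta.index[dataset.cell_meta["timepoint"].isin(BACKWARD_TIMEPOINTS)]
    forward = ActivityDataset(
        activities=dataset.activities.loc[fwd_cells].copy(),
        cell_meta=dataset.cell_meta.loc[fwd_cells].copy(),
    )
    bwd_acts = dataset.activities.loc[bwd_cells].copy()
    if dataset.backward_scale is not None:
        scale = dataset.backward_scale
        bwd_acts = bwd_acts * scale["slope"] + scale["intercept"]
    backward = ActivityDataset(
        activities=bwd_acts,
        cell_meta=dataset.cell_meta.loc[bwd_cells].copy(),
        backward_scale=dataset.backward_scale,
    )
    return forward, backward


def scale_backward(forward: ActivityDataset, backward: ActivityDataset) -> ActivityDataset:
    """Map backward activities onto the forward scale via the day-7 anchors.

    Per TF, an ordinary-least-squares line of forward-scale on backward-scale
    activity is fitted over the day-7 cells present in both datasets (matched
    by cell_id) and applied to every backward cell.
    """
    anchors = forward.timepoint_cells("7d").intersection(backward.timepoint_cells("7d"))
    if len(anchors) < 3:
        raise ValueError("insufficient anchor cells")
    fwd = forward.activities.loc[anchors]
    bwd = backward.activities.loc[anchors]
    tfs = [tf for tf in forward.tf_names if tf in backward.tf_names]
    scaled = backward.activities.copy()
    for tf in tfs:
        x = bwd[tf].to_numpy()
        y = fwd[tf].to_numpy()
        vx = np.var(x)
        if vx == 0:
            raise ValueError(f"constant day-7 anchor activities for TF {tf!r}")
        slope = np.cov(x, y, ddof=0)[0, 1] / vx
        intercept = y.mean() - slope * x.mean()
        scaled[tf] = backward.activities[tf] * slope + intercept
    return ActivityDataset(activities=scaled, cell_meta=backward.cell_meta.copy())


def combine_on_forward_scale(dataset: ActivityDataset) -> ActivityDataset:
    """Forward cells plus rescaled backward cells as one dataset on one scale."""
    forward, backward = split_forward_backward(dataset)
    backward_scaled = scale_backward(forward, backward)
    removal = backward_scaled.cell_meta.index[
        backward_scaled.cell_meta["timepoint"] != "7d"]
    return stack_datasets([forward, backward_scaled.subset(removal)])


# ---------------------------------------------------------------------------
# Differential testing


def differential_test(group_a: pd.DataFrame, group_b: pd.DataFrame,
                      comparison_id: str = "") -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per TF with Bonferroni adjustment.

    delta is the difference of group means (B - A); there is no fold-change
    pre-filter.  Ties are handled by the tie-corrected normal approximation;
    small tie-free samples use the exact null distribution.
    """
    if group_a.shape[0] == 0 or group_b.shape[0] == 0:
        raise ValueError("empty group in differential test")
    if group_a.shape[0] < 3 or group_b.shape[0] < 3:
        raise ValueError("each group must have at least 3 cells")
    tfs = list(group_a.columns)
    stat = np.empty(len(tfs))
    pval = np.empty(len(tfs))
    delta = np.empty(len(tfs))
    for j, tf in enumerate(tfs):
        a = group_a[tf].to_numpy()
        b = group_b[tf].to_numpy()
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        stat[j] = res.statistic
        pval[j] = res.pvalue
        delta[j] = b.mean() - a.mean()
    p_adj = multipletests(pval, method="bonferroni")[1]
    return pd.DataFrame(
        {"statistic": stat, "p_value": pval, "p_adjusted": p_adj,
         "delta": delta, "comparison_id": comparison_id},
        index=pd.Index(tfs, name="tf"),
    )


def run_comparisons(dataset: ActivityDataset) -> dict[str, pd.DataFrame]:
    """The seven fixed pairwise comparisons for one condition."""
    forward, backward = split_forward_backward(dataset)
    backward = scale_backward(forward, backward)
    splits = {"forward": forward, "backward": backward}
    results: dict[str, pd.DataFrame] = {}
    for comp_id, (split_name, ref_tp, alt_tp) in COMPARISONS.items():
        split = splits[split_name]
        ref = split.activities.loc[split.timepoint_cells(ref_tp)]
        alt = split.activities.loc[split.timepoint_cells(alt_tp)]
        results[comp_id] = differential_test(ref, alt, comparison_id=comp_id)
    return results


def run_study_comparisons(
    datasets: dict[str, ActivityDataset],
) -> dict[tuple[str, str], pd.DataFrame]:
    """All comparisons of a study: 7 per condition, 84 for the 12-condition design."""
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for label, dataset in datasets.items():
        for comp_id, table in run_comparisons(dataset).items():
            out[(label, comp_id)] = table
    return out


# ---------------------------------------------------------------------------
# Common DATFs and role annotation


def comparison_occurrences(result: pd.DataFrame, top_k: int = DEFAULT_TOP_K,
                           alpha: float = DEFAULT_ALPHA) -> set[str]:
    """TFs 'occurring' in one comparison: top-k by adjusted p AND significant."""
    ranked = result.sort_values("p_adjusted", kind="stable").head(top_k)
    return set(ranked.index[ranked["p_adjusted"] < alpha])


def select_common_datfs(all_results, top_k: int = DEFAULT_TOP_K,
                        min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
                        alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Count per-comparison occurrences and flag TFs recurring often enough.

    ``all_results`` is an iterable (or dict values) of per-comparison result
    tables.  A TF is a common DATF when it occurs in at least
    ``min_occurrence`` of the comparisons.
    """
    if isinstance(all_results, dict):
        all_results = list(all_results.values())
    else:
        all_results = list(all_results)
    if not all_results:
        raise ValueError("no comparison results supplied")
    tfs = sorted({tf for r in all_results for tf in r.index})
    counts = pd.Series(0, index=pd.Index(tfs, name="tf"), dtype=int)
    for result in all_results:
        for tf in comparison_occurrences(result, top_k=top_k, alpha=alpha):
            counts[tf] += 1
    return pd.DataFrame({
        "occurrence_count": counts,
        "is_common": counts >= min_occurrence,
    })


def annotate_em(condition_results: dict[str, pd.DataFrame],
                condition: str = "", alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """E/M role per TF from the endpoint comparisons of one condition.

    Forward rule (0 vs 7d): significant positive delta -> M, negative -> E.
    Backward rule (7d vs 3d_rm): significant negative delta -> M, positive
    -> E (activity reverts on removal).  Conflicting assignments between the
    two directions leave the TF unassigned.
    """
    for needed in ("0v7d", "7dv3d_rm"):
        if needed not in condition_results:
            raise ValueError(f"missing comparison {needed!r}")
    fwd = condition_results["0v7d"]
    bwd = condition_results["7dv3d_rm"]
    rows = []
    for tf in fwd.index:
        f_delta = float(fwd.loc[tf, "delta"])
        f_sig = fwd.loc[tf, "p_adjusted"] < alpha
        fwd_role = ("M" if f_delta > 0 else "E") if f_sig and f_delta != 0 else None
        bwd_role = None
        b_delta = np.nan
        if tf in bwd.index:
            b_delta = float(bwd.loc[tf, "delta"])
            b_sig = bwd.loc[tf, "p_adjusted"] < alpha
            if b_sig and b_delta != 0:
                bwd_role = "M" if b_delta < 0 else "E"
        if fwd_role and bwd_role and fwd_role != bwd_role:
            role = "unassigned"
        else:
            role = fwd_role or bwd_role or "unassigned"
        rows.append((tf, condition, role, f_delta, b_delta))
    return pd.DataFrame(
        rows, columns=["tf", "condition", "role", "forward_delta", "backward_delta"],
    ).set_index("tf")


def classify_dynamics(forward: ActivityDataset, tf: str,
                      alpha: float = DEFAULT_ALPHA) -> str:
    """Temporal class of one TF over the induction timepoints.

    M/E: the day-7 mean is significantly above/below the day-0 mean with no
    intermediate reversal.  I/I2: the intermediate-timepoint extremum
    significantly exceeds (falls below) both endpoints.  Significance is a
    two-sided rank-sum at level ``alpha`` on the corresponding cell groups.
    """
    groups = {tp: forward.activities.loc[forward.timepoint_cells(tp), tf].to_numpy()
              for tp in FORWARD_TIMEPOINTS}
    for tp, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"no cells at timepoint {tp!r}")
    means = {tp: vals.mean() for tp, vals in groups.items()}
    mid = ["8h", "1d", "3d"]
    peak_tp = max(mid, key=lambda t: means[t])
    trough_tp = min(mid, key=lambda t: means[t])

    def sig_greater(tp_hi: str, tp_lo: str) -> bool:
        p = stats.mannwhitneyu(groups[tp_hi], groups[tp_lo],
                               alternative="two-sided", method="auto").pvalue
        return p < alpha and means[tp_hi] > means[tp_lo]

    if sig_greater(peak_tp, "0") and sig_greater(peak_tp, "7d"):
        return "I"
    if sig_greater("0", trough_tp) and sig_greater("7d", trough_tp):
        return "I2"
    if sig_greater("7d", "0"):
        return "M"
    if sig_greater("0", "7d"):
        return "E"
    return "unassigned"


# ---------------------------------------------------------------------------
# Overlap summaries and chronology


@dataclass
class OverlapSummary:
    """Intersection structure of per-condition common-DATF lists."""

    pattern_counts: dict[tuple[str, ...], int]
    pairwise: pd.DataFrame
    same_cell_line_mean: float
    same_signal_mean: float


def _label_parts(label: str) -> tuple[str, str]:
    cell_line, _, signal = label.partition("_")
    return cell_line, signal


def datf_overlap(common_lists: dict[str, set[str]]) -> OverlapSummary:
    """Intersection-pattern counts plus pairwise overlaps grouped by design.

    Condition labels are expected as ``{cell_line}_{signal}``; pairwise
    overlap counts are averaged separately over same-cell-line pairs and
    same-signal pairs.
    """
    if len(common_lists) < 2:
        raise ValueError("need at least 2 conditions")
    conditions = list(common_lists)
    all_tfs = sorted(set().union(*common_lists.values()))
    patterns: dict[tuple[str, ...], int] = {}
    for tf in all_tfs:
        member = tuple(c for c in conditions if tf in common_lists[c])
        patterns[member] = patterns.get(member, 0) + 1
    pairwise = pd.DataFrame(0, index=conditions, columns=conditions, dtype=int)
    for a in conditions:
        for b in conditions:
            pairwise.loc[a, b] = len(common_lists[a] & common_lists[b])
    same_line, same_signal = [], []
    for i, a in enumerate(conditions):
        for b in conditions[i + 1:]:
            la, sa = _label_parts(a)
            lb, sb = _label_parts(b)
            if la == lb:
                same_line.append(pairwise.loc[a, b])
            if sa == sb and la != lb:
                same_signal.append(pairwise.loc[a, b])
    return OverlapSummary(
        pattern_counts=patterns,
        pairwise=pairwise,
        same_cell_line_mean=float(np.mean(same_line)) if same_line else np.nan,
        same_signal_mean=float(np.mean(same_signal)) if same_signal else np.nan,
    )


def group_chronology(dataset: ActivityDataset, group1: list[str],
                     group2: list[str]) -> pd.DataFrame:
    """Per-timepoint mean/SD of the average activity over two TF groups.

    The dataset must hold forward and backward cells on a common scale (see
    :func:`combine_on_forward_scale`).
    """
    if not group1 or not group2:
        raise ValueError("TF groups must be nonempty")
    rows = []
    for tp in TIMEPOINTS:
        cells = dataset.timepoint_cells(tp)
        if len(cells) == 0:
            continue
        g1 = dataset.activities.loc[cells, group1].mean(axis=1)
        g2 = dataset.activities.loc[cells, group2].mean(axis=1)
        rows.append((tp, g1.mean(), g1.std(ddof=0), g2.mean(), g2.std(ddof=0)))
    return pd.DataFrame(rows, columns=["timepoint", "mean1", "sd1", "mean2", "sd2"]
                        ).set_index("timepoint")
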