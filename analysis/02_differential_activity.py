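"""Differential TF-activity analysis across the study.

Loads the condition datasets written by 01_generate_study.py, splits each
into forward/backward directions, rescales the backward activities via the
shared day-7 cells, runs the 7 comparisons per condition (84 in total),
selects the common DATFs, annotates E/M roles per condition and summarizes
the overlap structure.  Writes per-condition role tables, the common-DATF
table and the overlap summary under results/datf/.
"""

import json
from pathlib import Path

import pandas as pd

from emtcircuits import datf
from emtcircuits.datasets import ActivityDataset

STUDY = Path(__file__).resolve().parent.parent / "results" / "study"
OUT = Path(__file__).resolve().parent.parent / "results" / "datf"


def main() -> None:
    datasets = {
        p.stem.removeprefix("activities_"): ActivityDataset.from_tsv(p)
        for p in sorted(STUDY.glob("activities_*.tsv"))
    }
    comparisons = datf.run_study_comparisons(datasets)
    print(f"ran {len(comparisons)} comparisons over {len(datasets)} conditions")

    OUT.mkdir(parents=True, exist_ok=True)
    common = datf.select_common_datfs(comparisons)
    common.to_csv(OUT / "common_datfs.tsv", sep="\t")
    n_common = int(common["is_common"].sum())
    print(f"common DATFs (>= {datf.DEFAULT_MIN_OCCURRENCE} of "
          f"{len(comparisons)} comparisons): {n_common}")

    roles_rows = []
    for label in datasets:
        cond = {cid: comparisons[(label, cid)] for cid in datf.COMPARISONS}
        ann = datf.annotate_em(cond, condition=label)
        roles_rows.append(ann.reset_index())
    roles = pd.concat(roles_rows, ignore_index=True)
    roles.to_csv(OUT / "roles.tsv", sep="\t", index=False)
    counts = roles["role"].value_counts().to_dict()
    print(f"role annotations across conditions: {counts}")

    per_condition = {
        label: set(datf.select_common_datfs(
            [comparisons[(label, cid)] for cid in datf.COMPARISONS],
            min_occurrence=4).query("is_common").index)
        for label in datasets
    }
    overlap = datf.datf_overlap(per_condition)
    overlap.pairwise.to_csv(OUT / "overlap_pairwise.tsv", sep="\t")
    summary = {"same_cell_line_mean": overlap.same_cell_line_mean,
               "same_signal_mean": overlap.same_signal_mean}
    (OUT / "overlap_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"mean pairwise DATF overlap: same cell line "
          f"{overlap.same_cell_line_mean:.2f} vs same signal "
          f"{overlap.same_signal_mean:.2f}")


if __name__ == "__main__":
    main()
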