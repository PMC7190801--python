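"""Differential activity: splitting, rescaling, testing, DATF selection, roles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from emtcircuits import datf
from emtcircuits.datasets import ActivityDataset, TIMEPOINTS
from emtcircuits.synth import ConditionSpec, simulate_timecourse


# ---------------------------------------------------------------------------
# Splitting and rescaling


class TestSplit:
    def test_study_splits_into_24_datasets(self, study):
        splits = [datf.split_forward_backward(ds) for ds in study.datasets.values()]
        flat = [d for pair in splits for d in pair]
        assert len(flat) == 24

    def test_shared_cells_are_exactly_day7(self, study):
        ds = study.datasets["CL1_SIG2"]
        fwd, bwd = datf.split_forward_backward(ds)
        assert set(fwd.cell_ids) & set(bwd.cell_ids) == set(ds.timepoint_cells("7d"))

    def test_cell_conservation(self, study):
        ds = study.datasets["CL4_SIG3"]
        fwd, bwd = datf.split_forward_backward(ds)
        n_7d = len(ds.timepoint_cells("7d"))
        assert fwd.n_cells + bwd.n_cells - n_7d == ds.n_cells

    def test_missing_timepoint_is_named(self, study):
        ds = study.datasets["CL1_SIG1"]
        keep = ds.cell_meta.index[ds.cell_meta["timepoint"] != "3d_rm"]
        with pytest.raises(ValueError, match="3d_rm"):
            datf.split_forward_backward(ds.subset(keep))


class TestScaleBackward:
    def test_identity_when_scales_agree(self, circuit):
        spec = ConditionSpec(cell_line="CL1", signal="SIG1", cells_per_timepoint=30,
                             seed=8)
        ds = simulate_timecourse(circuit, spec)
        ds_plain = ActivityDataset(activities=ds.activities, cell_meta=ds.cell_meta)
        fwd, bwd = datf.split_forward_backward(ds_plain)
        scaled = datf.scale_backward(fwd, bwd)
        anchors = ds_plain.timepoint_cells("7d")
        np.testing.assert_allclose(scaled.activities.loc[anchors].to_numpy(),
                                   fwd.activities.loc[anchors].to_numpy(),
                                   atol=1e-9)

    def test_affine_distortion_inverted_exactly(self, circuit):
        """The generator's known per-TF affine map is recovered to 1e-9."""
        spec = ConditionSpec(cell_line="CL1", signal="SIG1", cells_per_timepoint=30,
                             seed=8)
        ds = simulate_timecourse(circuit, spec)
        fwd, bwd = datf.split_forward_backward(ds)
        scaled = datf.scale_backward(fwd, bwd)
        # after undoing the distortion, backward activities equal the underlying
        # stored (forward-scale) values for every backward cell
        np.testing.assert_allclose(scaled.activities.to_numpy(),
                                   ds.activities.loc[scaled.cell_ids].to_numpy(),
                                   atol=1e-9)

    def test_day7_moments_match_after_scaling(self, circuit):
        spec = ConditionSpec(cell_line="CL2", signal="SIG1", cells_per_timepoint=40,
                             seed=9)
        ds = simulate_timecourse(circuit, spec)
        fwd, bwd = datf.split_forward_backward(ds)
        scaled = datf.scale_backward(fwd, bwd)
        anchors = ds.timepoint_cells("7d")
        f = fwd.activities.loc[anchors]
        s = scaled.activities.loc[anchors]
        np.testing.assert_allclose(s.mean().to_numpy(), f.mean().to_numpy(), atol=1e-6)
        np.testing.assert_allclose(s.var().to_numpy(), f.var().to_numpy(), atol=1e-6)

    def test_too_few_anchor_cells(self, study):
        ds = study.datasets["CL1_SIG1"]
        fwd, bwd = datf.split_forward_backward(ds)
        day7 = fwd.timepoint_cells("7d")
        small = fwd.subset(fwd.cell_ids.difference(day7[2:]))
        with pytest.raises(ValueError, match="anchor"):
            datf.scale_backward(small, bwd)


# ---------------------------------------------------------------------------
# Rank-sum testing


def _exact_ranksum_p(a, b):
    """Independent oracle: exact two-sided rank-sum p by full enumeration."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n_a = len(a)
    observed = ranks[:n_a].sum()
    null = [sum(combo) for combo in itertools.combinations(ranks, n_a)]
    null = np.asarray(null)
    mean = null.mean()
    p = np.mean(np.abs(null - mean) >= np.abs(observed - mean) - 1e-12)
    return p


class TestDifferentialTest:
    def test_identical_groups_give_p_near_one_and_zero_delta(self, rng):
        vals = rng.normal(size=(10, 4))
        frame = pd.DataFrame(vals, columns=list("abcd"))
        res = datf.differential_test(frame, frame.copy())
        assert (res["delta"] == 0).all()
        assert (res["p_value"] > 0.9).all()

    def test_separated_groups_match_exact_enumeration(self):
        a = pd.DataFrame({"tf": [1.0, 2, 3, 4, 5]})
        b = pd.DataFrame({"tf": [6.0, 7, 8, 9, 10]})
        res = datf.differential_test(a, b)
        expected = 2.0 / comb(10, 5)  # 2/252, most extreme assignment
        assert res.loc["tf", "p_value"] == pytest.approx(expected, rel=1e-9)
        assert res.loc["tf", "delta"] == 5.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_samples_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=5)
        b = rng.normal(loc=0.8, size=6)
        res = datf.differential_test(pd.DataFrame({"x": a}), pd.DataFrame({"x": b}))
        assert res.loc["x", "p_value"] == pytest.approx(_exact_ranksum_p(a, b), rel=1e-9)

    def test_bonferroni_multiplies_and_caps(self, rng):
        a = pd.DataFrame(rng.normal(size=(20, 10)))
        b = pd.DataFrame(rng.normal(loc=2.0, size=(20, 10)))
        a.columns = b.columns = [f"t{i}" for i in range(10)]
        res = datf.differential_test(a, b)
        expected = np.minimum(res["p_value"] * 10, 1.0)
        np.testing.assert_allclose(res["p_adjusted"], expected, rtol=1e-12)
        assert (res["p_adjusted"] >= res["p_value"]).all()

    def test_bonferroni_monotone_in_tf_count(self, rng):
        wide = pd.DataFrame(rng.normal(size=(15, 8)),
                            columns=[f"t{i}" for i in range(8)])
        shifted = wide + 1.0
        p_narrow = datf.differential_test(wide[["t0"]], shifted[["t0"]])
        p_wide = datf.differential_test(wide, shifted)
        assert p_wide.loc["t0", "p_adjusted"] >= p_narrow.loc["t0", "p_adjusted"]

    def test_empty_group_rejected(self):
        good = pd.DataFrame({"x": [1.0, 2, 3]})
        with pytest.raises(ValueError):
            datf.differential_test(good, good.iloc[:0])


class TestRunComparisons:
    def test_seven_fixed_labels_per_condition(self, study):
        res = datf.run_comparisons(study.datasets["CL1_SIG1"])
        assert set(res) == set(datf.COMPARISONS)
        for comp_id, table in res.items():
            assert (table["comparison_id"] == comp_id).all()

    def test_study_yields_84_comparisons(self, study_comparisons):
        assert len(study_comparisons) == 84
        per_condition = pd.Series([k[0] for k in study_comparisons]).value_counts()
        assert (per_condition == 7).all()


# ---------------------------------------------------------------------------
# Common DATFs and roles


class TestSelectCommonDatfs:
    def test_boundary_at_min_occurrence(self):
        """A TF present in 23 of 84 comparisons is not common; 24 is."""
        def result(p):
            return pd.DataFrame({"p_adjusted": [p], "p_value": [p],
                                 "delta": [1.0], "statistic": [0.0]},
                                index=pd.Index(["tf1"], name="tf"))
        tables = [result(0.001)] * 23 + [result(0.9)] * 61
        table = datf.select_common_datfs(tables, min_occurrence=24)
        assert not table.loc["tf1", "is_common"]
        tables = [result(0.001)] * 24 + [result(0.9)] * 60
        assert datf.select_common_datfs(tables, min_occurrence=24).loc["tf1", "is_common"]

    def test_driven_tfs_are_exactly_the_common_set(self, circuit, study_comparisons):
        """Strongly-driven TFs recur across comparisons; flat TFs do not."""
        table = datf.select_common_datfs(study_comparisons)
        common = set(table.index[table["is_common"]])
        # TFs that are E/M/I/I2 in (almost) every condition are the driven core
        driven = {tf for tf in circuit.tf_names
                  if sum(circuit.roles[c][tf] != "flat" for c in circuit.conditions) >= 10}
        never_driven = {tf for tf in circuit.tf_names
                        if all(circuit.roles[c][tf] == "flat" for c in circuit.conditions)}
        assert driven <= common
        assert not (never_driven & common)

    def test_occurrence_respects_top_k(self):
        rows = pd.Index([f"t{i}" for i in range(5)], name="tf")
        res = pd.DataFrame({"p_adjusted": [0.001, 0.002, 0.003, 0.004, 0.005],
                            "p_value": 0.001, "delta": 1.0, "statistic": 0.0},
                           index=rows)
        occ = datf.comparison_occurrences(res, top_k=2)
        assert occ == {"t0", "t1"}


class TestAnnotateEM:
    @staticmethod
    def _results(f_delta, f_p, b_delta, b_p):
        def tab(delta, p, comp):
            return pd.DataFrame({"p_adjusted": [p], "p_value": [p], "delta": [delta],
                                 "statistic": [0.0], "comparison_id": comp},
                                index=pd.Index(["tf1"], name="tf"))
        return {"0v7d": tab(f_delta, f_p, "0v7d"),
                "7dv3d_rm": tab(b_delta, b_p, "7dv3d_rm")}

    @pytest.mark.parametrize("f_delta,f_p,b_delta,b_p,expected", [
        (+1.5, 0.001, -1.2, 0.002, "M"),   # both rules agree on M
        (-1.5, 0.001, +1.2, 0.002, "E"),   # both rules agree on E
        (+1.5, 0.001, +1.0, 0.002, "unassigned"),  # forward M, backward E: conflict
        (+1.5, 0.2, +1.0, 0.4, "unassigned"),      # nothing significant
        (+1.5, 0.001, -1.0, 0.4, "M"),     # forward only
    ])
    def test_rule_table(self, f_delta, f_p, b_delta, b_p, expected):
        ann = datf.annotate_em(self._results(f_delta, f_p, b_delta, b_p))
        assert ann.loc["tf1", "role"] == expected

    def test_recovers_ground_truth_em_roles(self, circuit, study_comparisons):
        """>=90% of true E/M roles recovered; flat TFs essentially never labeled."""
        hits = total = 0
        flat_mislabels = flat_total = 0
        for label in circuit.conditions:
            comps = {cid: study_comparisons[(label, cid)] for cid in datf.COMPARISONS}
            ann = datf.annotate_em(comps, condition=label)
            for tf, true_role in circuit.roles[label].items():
                got = ann.loc[tf, "role"]
                if true_role in ("E", "M"):
                    total += 1
                    hits += got == true_role
                elif true_role == "flat":
                    flat_total += 1
                    flat_mislabels += got in ("E", "M")
        assert hits / total >= 0.9
        assert flat_mislabels / max(flat_total, 1) <= 0.05


class TestClassifyDynamics:
    def _forward(self, circuit, **kwargs):
        spec = ConditionSpec(cell_line="CL1", signal="SIG1", cells_per_timepoint=100,
                             noise_sd=0.2, effect_size=2.0, edge_coupling=0.0,
                             seed=6, **kwargs)
        ds = simulate_timecourse(circuit, spec)
        fwd, _ = datf.split_forward_backward(ds)
        return fwd

    def test_roles_recovered_from_trajectories(self, circuit):
        fwd = self._forward(circuit)
        roles = circuit.roles["CL1_SIG1"]
        for tf, role in roles.items():
            got = datf.classify_dynamics(fwd, tf)
            expected = "unassigned" if role == "flat" else role
            assert got == expected, f"{tf}: {role} classified {got}"


class TestOverlapAndChronology:
    def test_identical_lists_single_full_intersection(self):
        lists = {f"CL1_SIG{i}": {"a", "b", "c"} for i in range(1, 4)}
        summary = datf.datf_overlap(lists)
        assert summary.pattern_counts == {tuple(lists): 3}

    def test_disjoint_lists_zero_pairwise(self):
        lists = {"CL1_SIG1": {"a"}, "CL1_SIG2": {"b"}, "CL2_SIG1": {"c"}}
        summary = datf.datf_overlap(lists)
        off_diag = summary.pairwise.to_numpy()[~np.eye(3, dtype=bool)]
        assert (off_diag == 0).all()

    def test_cell_line_structure_shows_in_common_datf_overlap(self, study_comparisons):
        """Same-cell-line conditions share more common DATFs than same-signal ones."""
        per_condition = {}
        conditions = sorted({label for label, _ in study_comparisons})
        for label in conditions:
            tables = [study_comparisons[(label, cid)] for cid in datf.COMPARISONS]
            table = datf.select_common_datfs(tables, min_occurrence=4)
            per_condition[label] = set(table.index[table["is_common"]])
        summary = datf.datf_overlap(per_condition)
        assert summary.same_cell_line_mean > summary.same_signal_mean

    def test_single_tf_group_reduces_to_tf_stats(self, study):
        ds = datf.combine_on_forward_scale(study.datasets["CL1_SIG1"])
        tf1, tf2 = ds.tf_names[0], ds.tf_names[3]
        chron = datf.group_chronology(ds, [tf1], [tf2])
        for tp in TIMEPOINTS:
            cells = ds.timepoint_cells(tp)
            assert chron.loc[tp, "mean1"] == pytest.approx(
                ds.activities.loc[cells, tf1].mean())
            assert chron.loc[tp, "sd2"] == pytest.approx(
                ds.activities.loc[cells, tf2].std(ddof=0))

    def test_forward_backward_loop_does_not_retrace(self, circuit, study):
        """I-group vs M-group trajectory encloses positive area (hysteresis loop)."""
        ds = datf.combine_on_forward_scale(study.datasets["CL1_SIG1"])
        roles = circuit.roles["CL1_SIG1"]
        i_group = [tf for tf, r in roles.items() if r == "I"]
        m_group = [tf for tf, r in roles.items() if r == "M"]
        chron = datf.group_chronology(ds, i_group, m_group)
        x = chron["mean1"].to_numpy()
        y = chron["mean2"].to_numpy()
        # shoelace area of the closed 8-timepoint loop
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        assert area > 0.05

    def test_empty_group_rejected(self, study):
        ds = datf.combine_on_forward_scale(study.datasets["CL1_SIG1"])
        with pytest.raises(ValueError):
            datf.group_chronology(ds, [], ["TF01"])
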