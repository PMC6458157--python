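"""Background thresholding, haemolysis QC, top-100 normalization and the
prevalence filter."""

import numpy as np
import pandas as pd
import pytest

from mirnascreen.data import CountMatrix, ExpressionMatrix, ProbeClass, SampleMeta, Scale, TimePoint, Outcome
from mirnascreen.ncounter import (
    HAEMOLYSIS_MARKERS,
    background_threshold,
    haemolysis_qc,
    prevalence_filter,
    subtract_background,
    top100_normalize,
)


class TestBackgroundThreshold:
    def test_zero_spread(self):
        assert background_threshold([5, 5, 5]).threshold == 5

    def test_mean_plus_two_sample_sd(self):
        # mean 2, sample sd (n-1) = 2 → 2 + 2·2
        assert background_threshold([0, 2, 4]).threshold == pytest.approx(6.0)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 3"):
            background_threshold([1, 3])


class TestSubtractBackground:
    def _matrix(self, endo_counts, neg_counts):
        cols = {f"m{i}": [float(v)] for i, v in enumerate(endo_counts)}
        cols.update({f"NEG_{i}": [float(v)] for i, v in enumerate(neg_counts)})
        ann = {c: (ProbeClass.NEG_CONTROL if c.startswith("NEG")
                   else ProbeClass.ENDOGENOUS) for c in cols}
        counts = pd.DataFrame(cols, index=pd.Index(["s1"], name="sample_id"))
        return CountMatrix(counts=counts, annotation=ann)

    def test_subtracts_and_floors(self):
        m = self._matrix([10, 5], [0, 2, 4])  # threshold 6
        out = subtract_background(m)
        assert out.counts.loc["s1", "m0"] == pytest.approx(4.0)
        assert out.counts.loc["s1", "m1"] == 0.0

    def test_zero_negatives_pass_through(self):
        m = self._matrix([10, 5], [0, 0, 0])
        out = subtract_background(m)
        assert list(out.counts.loc["s1"]) == [10.0, 5.0]

    def test_drops_control_probes(self, toy_counts):
        out = subtract_background(toy_counts)
        assert set(out.counts.columns) == {"mirA", "mirB"}

    def test_idempotent_on_own_output(self, toy_counts):
        once = subtract_background(toy_counts)
        twice = subtract_background(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_per_sample_thresholds(self):
        counts = pd.DataFrame(
            {"m0": [10.0, 10.0], "NEG_0": [0.0, 4.0], "NEG_1": [0.0, 4.0],
             "NEG_2": [0.0, 4.0]},
            index=pd.Index(["s1", "s2"], name="sample_id"))
        ann = {"m0": ProbeClass.ENDOGENOUS,
               **{f"NEG_{i}": ProbeClass.NEG_CONTROL for i in range(3)}}
        out = subtract_background(CountMatrix(counts=counts, annotation=ann))
        assert out.counts.loc["s1", "m0"] == 10.0
        assert out.counts.loc["s2", "m0"] == 6.0


class TestHaemolysisQc:
    def _cohort(self, n=20, outlier=None, factor=100.0):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(n)]
        cols = {m: rng.uniform(900, 1100, n) for m in HAEMOLYSIS_MARKERS}
        cols["other"] = rng.uniform(50, 60, n)
        counts = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
        if outlier is not None:
            counts.loc[outlier, HAEMOLYSIS_MARKERS[0]] *= factor
        ann = {c: ProbeClass.ENDOGENOUS for c in counts.columns}
        return CountMatrix(counts=counts, annotation=ann)

    def test_identical_counts_unflagged(self):
        counts = pd.DataFrame(
            {m: [100.0] * 5 for m in HAEMOLYSIS_MARKERS},
            index=pd.Index([f"s{i}" for i in range(5)], name="sample_id"))
        m = CountMatrix(counts=counts,
                        annotation={c: ProbeClass.ENDOGENOUS for c in counts})
        report = haemolysis_qc(m)
        assert report.flagged.empty
        assert (report.scores.to_numpy() == 0).all()

    def test_hundredfold_outlier_flagged(self):
        report = haemolysis_qc(self._cohort(outlier="s7"))
        assert report.flagged_samples == ["s7"]
        assert report.flagged.loc[0, "marker_id"] == HAEMOLYSIS_MARKERS[0]

    def test_all_markers_absent_is_error(self):
        counts = pd.DataFrame({"other": [1.0, 2.0]},
                              index=pd.Index(["s1", "s2"], name="sample_id"))
        m = CountMatrix(counts=counts,
                        annotation={"other": ProbeClass.ENDOGENOUS})
        with pytest.raises(ValueError, match="haemolysis"):
            haemolysis_qc(m)

    def test_partial_marker_set_warns(self):
        m = self._cohort()
        dropped = m.counts.drop(columns=[HAEMOLYSIS_MARKERS[2]])
        m2 = CountMatrix(counts=dropped,
                         annotation={c: ProbeClass.ENDOGENOUS for c in dropped})
        with pytest.warns(UserWarning, match="absent"):
            report = haemolysis_qc(m2)
        assert set(report.haemolysis_marker_ids) == set(HAEMOLYSIS_MARKERS[:2])


class TestTop100Normalize:
    def _matrix(self, rows: dict):
        counts = pd.DataFrame.from_dict(rows, orient="index")
        counts.columns = [f"m{i}" for i in range(counts.shape[1])]
        counts.index.name = "sample_id"
        ann = {c: ProbeClass.ENDOGENOUS for c in counts.columns}
        return CountMatrix(counts=counts.astype(float), annotation=ann)

    def test_two_sample_worked_example(self):
        m = self._matrix({"X": [10, 20, 30], "Y": [20, 40, 60]})
        out = top100_normalize(m)
        assert np.allclose(out.values.loc["X"], [15, 30, 45])
        assert np.allclose(out.values.loc["Y"], [15, 30, 45])
        assert out.scale is Scale.NORMALIZED_COUNT

    def test_identical_samples_unchanged(self):
        m = self._matrix({"X": [10, 20, 30], "Y": [10, 20, 30]})
        out = top100_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.counts,
                                      check_names=False)

    def test_reference_means_equalized(self, small_cohort):
        _, counts, _, _ = small_cohort
        out = top100_normalize(subtract_background(counts))
        ref = out.values.mean(axis=0).nlargest(100).index
        means = out.values[ref].mean(axis=1)
        assert np.allclose(means, means.iloc[0])

    def test_rescaling_one_sample_cancels_up_to_global_factor(self):
        # a lane-depth factor on one sample leaves all between-sample and
        # between-probe ratios of the normalized matrix unchanged
        m = self._matrix({"X": [10, 20, 30], "Y": [20, 40, 60]})
        scaled = self._matrix({"X": [100, 200, 300], "Y": [20, 40, 60]})
        a = top100_normalize(m).values
        b = top100_normalize(scaled).values
        ratio = b / a
        assert np.allclose(ratio, ratio.iloc[0, 0])

    def test_zero_sample_is_error(self):
        m = self._matrix({"X": [10, 20, 30], "Y": [0, 0, 0]})
        with pytest.raises(ValueError, match="Y"):
            top100_normalize(m)


class TestPrevalenceFilter:
    def _expr(self, marker_cols: dict, samples):
        values = pd.DataFrame(marker_cols,
                              index=pd.Index(samples, name="sample_id"),
                              dtype=float)
        return ExpressionMatrix(values=values, scale=Scale.NORMALIZED_COUNT)

    def _meta(self, groups: dict):
        metas = []
        for outcome, ids in groups.items():
            for s in ids:
                metas.append(SampleMeta(s, s, TimePoint.A, Outcome(outcome)))
        return metas

    def test_exactly_half_is_removed(self):
        samples = [f"s{i}" for i in range(6)]
        expr = self._expr({"m": [1, 1, 1, 0, 0, 0]}, samples)
        meta = self._meta({"TERM": samples})
        assert prevalence_filter(expr, meta) == []

    def test_strict_majority_in_one_group_retained(self):
        samples = [f"t{i}" for i in range(6)] + [f"p{i}" for i in range(6)]
        expr = self._expr(
            {"m": [1, 1, 1, 1, 0, 0] + [0] * 6}, samples)
        meta = self._meta({"TERM": samples[:6], "PRETERM": samples[6:]})
        assert prevalence_filter(expr, meta) == ["m"]

    def test_empty_group_is_error(self):
        samples = ["s0", "s1"]
        expr = self._expr({"m": [1, 1]}, samples)
        meta = self._meta({"TERM": samples})
        with pytest.raises(ValueError, match="empty"):
            prevalence_filter(expr, meta, grouping={"TERM": samples, "X": []})

    def test_invariant_to_order_and_monotone_transform(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(12)]
        values = {f"m{j}": rng.integers(0, 2, 12) * rng.uniform(1, 9, 12)
                  for j in range(8)}
        expr = self._expr(values, samples)
        meta = self._meta({"TERM": samples[:6], "SHORT": samples[6:]})
        base = prevalence_filter(expr, meta)

        shuffled = expr.values.sample(frac=1, random_state=1)
        expr2 = ExpressionMatrix(values=shuffled, scale=Scale.NORMALIZED_COUNT)
        assert prevalence_filter(expr2, meta) == base

        expr3 = ExpressionMatrix(values=np.square(expr.values),
                                 scale=Scale.NORMALIZED_COUNT)
        assert prevalence_filter(expr3, meta) == base
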