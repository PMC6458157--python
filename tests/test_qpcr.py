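"""Replicate collapse, the median normalization chain, relative expression
and the 2^(−ΔG) fold change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirnascreen.data import CtTable, Outcome, SampleMeta, Scale, TimePoint
from mirnascreen.qpcr import (
    collapse_replicates,
    fold_change,
    median_normalize_ct,
    relative_expression,
)


def _table(rows):
    rec = pd.DataFrame(rows, columns=["sample_id", "assay_id", "plate_id",
                                      "replicate", "ct"])
    rec["undetected"] = rec["ct"].isna()
    return CtTable(records=rec, calibrator_assay_id="IPC",
                   spike_in_assay_ids=["cel-254", "UniSp6"])


def _controls(plate, samples, cal=20.0, spike=0.0):
    rows = [("calibrator", "IPC", plate, 1, cal)]
    for s in samples:
        rows += [(s, "cel-254", plate, 1, 18.0 + spike),
                 (s, "UniSp6", plate, 1, 16.0 + spike)]
    return rows


class TestCollapseReplicates:
    def test_tight_replicates_unflagged(self):
        t = _table([("s1", "mirA", "P1", 1, 24.0), ("s1", "mirA", "P1", 2, 24.2)]
                   + _controls("P1", ["s1"]))
        out, qc = collapse_replicates(t)
        cell = out.records.query("assay_id == 'mirA'")
        assert cell["ct"].iloc[0] == pytest.approx(24.1)
        row = qc.query("assay_id == 'mirA'").iloc[0]
        assert row["cv_pct"] == pytest.approx(0.587, abs=1e-3)
        assert not row["flagged"]

    def test_wide_replicates_flagged_but_kept(self):
        t = _table([("s1", "mirA", "P1", 1, 20.0), ("s1", "mirA", "P1", 2, 22.0)]
                   + _controls("P1", ["s1"]))
        out, qc = collapse_replicates(t)
        assert out.records.query("assay_id == 'mirA'")["ct"].iloc[0] == 21.0
        row = qc.query("assay_id == 'mirA'").iloc[0]
        assert row["cv_pct"] == pytest.approx(6.73, abs=0.01)
        assert row["flagged"]

    def test_single_replicate_cv_undefined(self):
        t = _table([("s1", "mirA", "P1", 1, 25.0)] + _controls("P1", ["s1"]))
        out, qc = collapse_replicates(t)
        assert out.records.query("assay_id == 'mirA'")["ct"].iloc[0] == 25.0
        assert not qc.query("assay_id == 'mirA'")["flagged"].iloc[0]

    def test_undetected_replicates_excluded(self):
        t = _table([("s1", "mirA", "P1", 1, 24.0),
                    ("s1", "mirA", "P1", 2, np.nan),
                    ("s1", "mirB", "P1", 1, np.nan),
                    ("s1", "mirB", "P1", 2, np.nan)]
                   + _controls("P1", ["s1"]))
        out, _ = collapse_replicates(t)
        a = out.records.query("assay_id == 'mirA'").iloc[0]
        b = out.records.query("assay_id == 'mirB'").iloc[0]
        assert a["ct"] == 24.0 and not a["undetected"]
        assert b["undetected"]


class TestMedianNormalize:
    def test_plate_offset_from_calibrator(self):
        # spike-ins physically sit on their plate, so they carry its offset
        rows = (_controls("P1", ["s1"], cal=20.0, spike=-1.0)
                + _controls("P2", ["s2"], cal=22.0, spike=1.0)
                + [("s1", "mirA", "P1", 1, 23.0), ("s2", "mirA", "P2", 1, 25.0)])
        out = median_normalize_ct(_table(rows))
        # calibrator median 21 → offsets −1 / +1
        assert out.values.loc["s1", "mirA"] == pytest.approx(24.0)
        assert out.values.loc["s2", "mirA"] == pytest.approx(24.0)

    def test_sample_offset_from_spike_ins(self):
        rows = [("calibrator", "IPC", "P1", 1, 20.0)]
        for s, off in [("s1", 0.0), ("s2", 0.0), ("s3", 1.0)]:
            rows += [(s, "cel-254", "P1", 1, 17.0 + off),
                     (s, "UniSp6", "P1", 1, 15.0 + off),
                     (s, "mirA", "P1", 1, 30.0 if s == "s3" else 29.0)]
        out = median_normalize_ct(_table(rows))
        # s3 spikes sit +1 above the cross-sample medians → offset +1
        assert out.values.loc["s3", "mirA"] == pytest.approx(29.0)
        assert out.values.loc["s1", "mirA"] == pytest.approx(29.0)

    def test_identity_when_no_technical_variation(self):
        rows = _controls("P1", ["s1", "s2"]) + [
            ("s1", "mirA", "P1", 1, 24.0), ("s2", "mirA", "P1", 1, 27.5)]
        out = median_normalize_ct(_table(rows))
        assert out.values.loc["s1", "mirA"] == 24.0
        assert out.values.loc["s2", "mirA"] == 27.5
        assert out.scale is Scale.NORMALIZED_CT


def _meta(groups):
    metas = []
    for outcome, ids in groups.items():
        for s in ids:
            metas.append(SampleMeta(s, s, TimePoint.A, Outcome(outcome)))
    return metas


def _norm_ct(cts: dict):
    rows = _controls("P1", list(cts))
    rows += [(s, "mirA", "P1", 1, ct) for s, ct in cts.items()]
    return median_normalize_ct(_table(rows))


class TestRelativeExpressionAndFold:
    def test_control_group_scaling(self):
        m = _norm_ct({"c1": 25.0, "c2": 27.0})
        rel = relative_expression(m, _meta({"TERM": ["c1", "c2"]}), "mirA")
        assert rel["c1"] == pytest.approx(1.6)
        assert rel["c2"] == pytest.approx(0.4)
        assert rel.mean() == pytest.approx(1.0)

    def test_identical_groups_fold_one(self):
        m = _norm_ct({"c1": 25.0, "c2": 27.0, "e1": 25.0, "e2": 27.0})
        meta = _meta({"TERM": ["c1", "c2"], "PRETERM": ["e1", "e2"]})
        fc = fold_change(m, meta, "mirA", "PRETERM")
        assert fc.fold == pytest.approx(1.0)
        assert fc.group_means["PRETERM"] == pytest.approx(1.0)

    @pytest.mark.parametrize("exp_cts,expected_fold", [
        ((23.0, 25.0), 4.0),   # mean 24 vs 26 → ΔG = −2
        ((27.0, 29.0), 0.25),  # mean 28 vs 26 → ΔG = +2
    ])
    def test_fold_formula(self, exp_cts, expected_fold):
        m = _norm_ct({"c1": 25.0, "c2": 27.0,
                      "e1": exp_cts[0], "e2": exp_cts[1]})
        meta = _meta({"TERM": ["c1", "c2"], "PRETERM": ["e1", "e2"]})
        fc = fold_change(m, meta, "mirA", "PRETERM")
        assert fc.fold == pytest.approx(expected_fold)

    def test_uniform_shift_mean_relative_expression(self):
        # experimental Cts pinned 2 cycles below the control mean: raw r = 4,
        # rescaled by the control mean of r (1.25) → 3.2; fold stays 2^2 = 4
        m = _norm_ct({"c1": 25.0, "c2": 27.0, "e1": 24.0, "e2": 24.0})
        meta = _meta({"TERM": ["c1", "c2"], "PRETERM": ["e1", "e2"]})
        fc = fold_change(m, meta, "mirA", "PRETERM")
        assert fc.fold == pytest.approx(4.0)
        assert fc.group_means["PRETERM"] == pytest.approx(3.2)

    def test_fold_agrees_with_geometric_mean_of_relative_expression(self):
        rng = np.random.default_rng(5)
        cts = {f"c{i}": float(rng.uniform(24, 28)) for i in range(5)}
        cts.update({f"e{i}": float(rng.uniform(22, 26)) for i in range(5)})
        m = _norm_ct(cts)
        meta = _meta({"TERM": [f"c{i}" for i in range(5)],
                      "SHORT": [f"e{i}" for i in range(5)]})
        fc = fold_change(m, meta, "mirA", "SHORT")
        logrel = np.log2(fc.relative_expression)
        geo = 2.0 ** (logrel[[f"e{i}" for i in range(5)]].mean()
                      - logrel[[f"c{i}" for i in range(5)]].mean())
        assert fc.fold == pytest.approx(geo)

    def test_undetected_sample_excluded_with_warning(self):
        rows = _controls("P1", ["c1", "c2", "e1", "e2"])
        rows += [("c1", "mirA", "P1", 1, 25.0), ("c2", "mirA", "P1", 1, 27.0),
                 ("e1", "mirA", "P1", 1, 24.0), ("e2", "mirA", "P1", 1, np.nan)]
        m = median_normalize_ct(_table(rows))
        meta = _meta({"TERM": ["c1", "c2"], "PRETERM": ["e1", "e2"]})
        with pytest.warns(UserWarning, match="e2"):
            fc = fold_change(m, meta, "mirA", "PRETERM")
        assert fc.dg == pytest.approx(24.0 - 26.0)

    def test_empty_group_is_error(self):
        m = _norm_ct({"c1": 25.0, "c2": 27.0})
        meta = _meta({"TERM": ["c1", "c2"]})
        with pytest.raises(ValueError, match="PRETERM"):
            fold_change(m, meta, "mirA", "PRETERM")


@settings(deadline=None, max_examples=40)
@given(
    ctl=st.lists(st.floats(20, 32), min_size=2, max_size=6),
    exp=st.lists(st.floats(20, 32), min_size=2, max_size=6),
)
def test_fold_change_antisymmetry(ctl, exp):
    cts = {f"c{i}": v for i, v in enumerate(ctl)}
    cts.update({f"e{i}": v for i, v in enumerate(exp)})
    m = _norm_ct(cts)
    meta = _meta({"TERM": [f"c{i}" for i in range(len(ctl))],
                  "PRETERM": [f"e{i}" for i in range(len(exp))]})
    ab = fold_change(m, meta, "mirA", "PRETERM", "TERM").fold
    ba = fold_change(m, meta, "mirA", "TERM", "PRETERM").fold
    assert ab * ba == pytest.approx(1.0)
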