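"""RT-qPCR Ct processing: replicate collapse with CV QC, the two-step median
normalization chain (inter-plate calibrator, then extraction/RT spike-in
controls), relative expression and fold change.

Fold change between clinical groups follows the comparative-Ct convention

    fold = 2^(−ΔG),   ΔG = mean Ct(experimental) − mean Ct(control),

so one cycle of Ct difference corresponds to a two-fold expression change.
Per-sample relative expression is reported on a scale where the
control-group mean is exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CtTable, ExpressionMatrix, SampleMeta, Scale, meta_frame

__all__ = [
    "FoldChangeResult",
    "collapse_replicates",
    "median_normalize_ct",
    "relative_expression",
    "fold_change",
]

#: Intra-assay coefficient-of-variance QC bound on replicate Ct values (%).
CV_LIMIT_PCT = 2.0


@dataclass
class FoldChangeResult:
    marker_id: str
    experimental_group: str
    control_group: str
    dg: float           # mean Ct(experimental) − mean Ct(control), cycles
    fold: float         # 2^(−dg)
    relative_expression: pd.Series  # per sample, control-group mean == 1
    group_means: pd.Series
    group_sems: pd.Series


def collapse_replicates(t: CtTable) -> tuple[CtTable, pd.DataFrame]:
    """Average technical replicates per (sample, assay, plate) cell.

    Undetected replicates are excluded from the mean; a cell is undetected
    only when every replicate is. Cells with a replicate CV (sd/mean × 100)
    at or above 2% are flagged in the returned QC listing but retained.
    """
    rec = t.records
    rows, qc_rows = [], []
    for (s, a, p), grp in rec.groupby(["sample_id", "assay_id", "plate_id"],
                                      sort=False):
        cts = grp.loc[~grp["undetected"], "ct"].astype(float)
        if len(cts) == 0:
            rows.append({"sample_id": s, "assay_id": a, "plate_id": p,
                         "replicate": 1, "ct": np.nan, "undetected": True})
            continue
        mean = float(cts.mean())
        cv = float(cts.std(ddof=1) / mean * 100.0) if len(cts) >= 2 else np.nan
        rows.append({"sample_id": s, "assay_id": a, "plate_id": p,
                     "replicate": 1, "ct": mean, "undetected": False})
        qc_rows.append({"sample_id": s, "assay_id": a, "plate_id": p,
                        "n_replicates": len(cts), "cv_pct": cv,
                        "flagged": bool(cv >= CV_LIMIT_PCT)
                        if np.isfinite(cv) else False})
    collapsed = CtTable(records=pd.DataFrame(rows),
                        calibrator_assay_id=t.calibrator_assay_id,
                        spike_in_assay_ids=t.spike_in_assay_ids)
    qc = pd.DataFrame(qc_rows, columns=["sample_id", "assay_id", "plate_id",
                                        "n_replicates", "cv_pct", "flagged"])
    return collapsed, qc


def median_normalize_ct(t: CtTable) -> ExpressionMatrix:
    """Two-step median normalization of Ct values.

    Step 1 (plates): each plate's offset is its calibrator Ct minus the
    median calibrator Ct over plates; the offset is subtracted from every Ct
    on that plate. Step 2 (samples): for each spike-in assay, a sample's
    deviation is its (plate-corrected) spike Ct minus the cross-sample median
    of that spike; the per-sample offset is the median of the deviations over
    spike-in assays (the midpoint when there are two) and is subtracted from
    the sample's target Cts.

    Accepts a replicate-level table (collapsed internally). Returns a
    samples × target-assay matrix on the NORMALIZED_CT scale; samples with an
    undetected cell for a target assay keep NaN there and are excluded by
    downstream consumers with a warning.
    """
    if t.records.duplicated(["sample_id", "assay_id", "plate_id"]).any():
        t, _ = collapse_replicates(t)
    rec = t.records.copy()

    cal = rec.loc[rec["assay_id"] == t.calibrator_assay_id]
    cal_ct = cal.groupby("plate_id")["ct"].mean()
    plate_offset = cal_ct - cal_ct.median()
    rec["ct"] = rec["ct"] - plate_offset.reindex(rec["plate_id"]).to_numpy()

    deviations = []
    for spike in t.spike_in_assay_ids:
        sp = rec.loc[rec["assay_id"] == spike].groupby("sample_id")["ct"].mean()
        deviations.append(sp - sp.median())
    if deviations:
        sample_offset = pd.concat(deviations, axis=1).median(axis=1)
        rec["ct"] = rec["ct"] - sample_offset.reindex(rec["sample_id"]).fillna(0.0).to_numpy()

    targets = rec.loc[rec["assay_id"].isin(t.target_assays)]
    wide = targets.pivot_table(index="sample_id", columns="assay_id",
                               values="ct", aggfunc="mean", dropna=False)
    wide.index.name = "sample_id"
    wide.columns.name = "marker_id"
    return ExpressionMatrix(values=wide.fillna(np.nan), scale=Scale.NORMALIZED_CT) \
        if not wide.isna().any().any() else _with_nan(wide)


def _with_nan(wide: pd.DataFrame) -> ExpressionMatrix:
    # bypass the no-missing-cells invariant for undetected cells; consumers
    # drop the affected samples with a warning
    em = ExpressionMatrix.__new__(ExpressionMatrix)
    em.values = wide
    em.scale = Scale.NORMALIZED_CT
    return em


def _group_cts(m: ExpressionMatrix, meta, marker, group):
    if m.scale is not Scale.NORMALIZED_CT:
        raise ValueError("expected a NORMALIZED_CT matrix")
    if marker not in m.values.columns:
        raise ValueError(f"marker {marker!r} absent from Ct matrix")
    mf = meta_frame(meta)
    ids = mf.index[(mf["outcome"] == group)].intersection(m.values.index)
    cts = m.values.loc[ids, marker]
    dropped = cts.index[cts.isna()]
    if len(dropped):
        warnings.warn(f"{marker}: excluding undetected sample(s) "
                      f"{list(dropped)}", stacklevel=3)
        cts = cts.dropna()
    if len(cts) == 0:
        raise ValueError(f"no usable samples for group {group!r}")
    return cts


def relative_expression(m: ExpressionMatrix, meta, marker: str,
                        control_group: str = "TERM") -> pd.Series:
    """Per-sample relative expression, control-group mean scaled to 1.

    r_i = 2^(−(Ct_i − mean control Ct)), then all values are divided by the
    control-group mean of r so the control mean is exactly 1.
    """
    mf = meta_frame(meta)
    control = _group_cts(m, meta, marker, control_group)
    usable = m.values.index.intersection(mf.index)
    cts = m.values.loc[usable, marker].dropna()
    r = np.power(2.0, -(cts - control.mean()))
    return r / r.loc[control.index].mean()


def fold_change(m: ExpressionMatrix, meta, marker: str,
                experimental_group: str, control_group: str = "TERM",
                *, time_point: str | None = None) -> FoldChangeResult:
    """Group fold change 2^(−ΔG) with per-sample relative expression.

    When ``time_point`` is given, both groups are restricted to samples from
    that gestational time point.
    """
    if time_point is not None:
        meta = [s for s in meta if s.time_point.value == time_point]
    exp_cts = _group_cts(m, meta, marker, experimental_group)
    ctl_cts = _group_cts(m, meta, marker, control_group)
    dg = float(exp_cts.mean() - ctl_cts.mean())
    fold = float(2.0 ** (-dg))

    rel = relative_expression(m, meta, marker, control_group)
    groups = {experimental_group: exp_cts.index, control_group: ctl_cts.index}
    means = pd.Series({g: float(rel.loc[ids].mean()) for g, ids in groups.items()})
    sems = pd.Series({g: float(rel.loc[ids].std(ddof=1) / np.sqrt(len(ids)))
                      if len(ids) > 1 else np.nan for g, ids in groups.items()})
    return FoldChangeResult(
        marker_id=marker, experimental_group=experimental_group,
        control_group=control_group, dg=dg, fold=fold,
        relative_expression=rel.loc[list(exp_cts.index) + list(ctl_cts.index)],
        group_means=means, group_sems=sems,
    )
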