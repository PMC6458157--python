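"""End-to-end orchestration of the two study phases.

**Discovery** (digital counts): haemolysis QC → background subtraction →
top-100 normalization → prevalence filter → per-time-point group comparisons
of each retained marker (PRETERM vs TERM and SHORT vs TERM) →
Benjamini–Hochberg adjustment → candidate panel = markers significant at
one or more time points in either comparison.

**Validation** (independent qPCR cohort): replicate collapse → two-step
median Ct normalization → per-marker fold change / relative expression →
per-marker ROC with specificity at 100% detection rate → multi-marker
logistic combinations, at time points A and C.

Every intermediate table is kept on the report object and written out as a
CSV so each number in the final summary can be traced back to a stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import CountMatrix, CtTable, ExpressionMatrix, SampleMeta, meta_frame
from .diffexpr import bh_fdr, group_compare, welch_log_geomean_test
from .ncounter import (
    QcReport,
    haemolysis_qc,
    prevalence_filter,
    subtract_background,
    top100_normalize,
)
from .qpcr import (
    collapse_replicates,
    fold_change,
    median_normalize_ct,
    relative_expression,
)
from .roc import (
    Direction,
    auc_p_value,
    combine_markers,
    roc_curve,
    specificity_at_full_sensitivity,
)

__all__ = ["PipelineConfig", "DiscoveryReport", "ValidationReport",
           "run_discovery", "run_validation"]

_COMPARISONS = (("PRETERM", "TERM"), ("SHORT", "TERM"))
_TIME_POINTS = ("A", "B", "C")


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    fdr: float = 0.05
    haemolysis_z: float = 3.0
    control_group: str = "TERM"
    candidate_on: str = "q"          # "q" (FDR-adjusted) or "p" (raw)
    #: family for the FDR adjustment behind candidate selection:
    #: "marker" — one p per marker (Bonferroni minimum over its per-phase
    #: tests), BH across markers, controlling the FDR of the discovered
    #: marker set itself; "pooled" — BH over all per-test p-values jointly;
    #: "per_comparison_timepoint" — BH within each comparison × time point.
    fdr_family: str = "marker"
    #: discovery-phase count comparison: the log-geometric-mean Welch test
    #: (the count-screen convention; unequal variances assumed) or the
    #: normality-gated t / Mann-Whitney used for qPCR relative expression.
    discovery_test: str = "welch_log_geomean"
    panel_sizes: tuple[int, ...] = (3, 7)
    n_reference: int = 100
    validation_time_points: tuple[str, ...] = ("A", "C")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.fdr < 1):
            raise ValueError("alpha and fdr must lie in (0, 1)")
        if self.candidate_on not in ("q", "p"):
            raise ValueError("candidate_on must be 'q' or 'p'")
        if self.fdr_family not in ("marker", "pooled",
                                   "per_comparison_timepoint"):
            raise ValueError(f"unknown fdr_family {self.fdr_family!r}")
        if self.discovery_test not in ("welch_log_geomean", "group_compare"):
            raise ValueError(f"unknown discovery_test {self.discovery_test!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "panel_sizes" in raw:
            raw["panel_sizes"] = tuple(raw["panel_sizes"])
        if "validation_time_points" in raw:
            raw["validation_time_points"] = tuple(raw["validation_time_points"])
        return cls(**raw)


@dataclass
class DiscoveryReport:
    qc: QcReport
    excluded_samples: list[str]
    normalized: ExpressionMatrix
    retained_markers: list[str]
    de_table: pd.DataFrame       # marker, time_point, comparison, test, stat, p, q
    candidates: list[str]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.qc.scores.to_csv(outdir / "haemolysis_scores.csv")
        self.qc.flagged.to_csv(outdir / "haemolysis_flagged.csv", index=False)
        self.normalized.values.to_csv(outdir / "normalized_counts.csv")
        pd.Series(self.retained_markers, name="marker_id").to_csv(
            outdir / "retained_markers.csv", index=False)
        self.de_table.to_csv(outdir / "differential_expression.csv", index=False)
        pd.Series(self.candidates, name="marker_id").to_csv(
            outdir / "candidate_panel.csv", index=False)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary())

    def summary(self) -> str:
        lines = [
            f"samples excluded for haemolysis: {len(self.excluded_samples)} "
            f"({', '.join(self.excluded_samples) or '-'})",
            f"markers above background in a strict majority of a group: "
            f"{len(self.retained_markers)}",
            f"differential-expression tests run: {len(self.de_table)}",
            f"candidate markers: {len(self.candidates)} "
            f"({', '.join(self.candidates) or '-'})",
        ]
        return "\n".join(lines) + "\n"


@dataclass
class ValidationReport:
    cv_qc: pd.DataFrame
    normalized_ct: ExpressionMatrix
    fold_table: pd.DataFrame     # Table-3-shaped
    roc_table: pd.DataFrame      # Table-4-shaped
    combined_table: pd.DataFrame
    coefficients: dict[str, pd.Series] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cv_qc.to_csv(outdir / "replicate_cv_qc.csv", index=False)
        self.normalized_ct.values.to_csv(outdir / "normalized_ct.csv")
        self.fold_table.to_csv(outdir / "fold_changes.csv", index=False)
        self.roc_table.to_csv(outdir / "roc_screening.csv", index=False)
        self.combined_table.to_csv(outdir / "combined_panels.csv", index=False)


def run_discovery(counts: CountMatrix, metas: Sequence[SampleMeta],
                  config: PipelineConfig | None = None) -> DiscoveryReport:
    """Run the count-based discovery phase and return its full report."""
    config = config or PipelineConfig()
    qc = haemolysis_qc(counts, z_cutoff=config.haemolysis_z)
    excluded = sorted(qc.flagged_samples)
    kept = [s for s in counts.samples if s not in set(excluded)]
    counts = CountMatrix(counts=counts.counts.loc[kept],
                         annotation=dict(counts.annotation))
    metas = [m for m in metas if m.sample_id in set(kept)]

    background_free = subtract_background(counts)
    normalized = top100_normalize(background_free,
                                  n_reference=config.n_reference)
    retained = prevalence_filter(normalized, metas)

    mf = meta_frame(metas)
    rows = []
    for tp in _TIME_POINTS:
        at_tp = mf.index[mf["time_point"] == tp]
        if len(at_tp) == 0:
            continue
        for exp_group, ctl_group in _COMPARISONS:
            exp_ids = [s for s in at_tp if mf.loc[s, "outcome"] == exp_group]
            ctl_ids = [s for s in at_tp if mf.loc[s, "outcome"] == ctl_group]
            if len(exp_ids) < 2 or len(ctl_ids) < 2:
                continue
            for marker in retained:
                x = normalized.values.loc[exp_ids, marker]
                y = normalized.values.loc[ctl_ids, marker]
                if config.discovery_test == "welch_log_geomean":
                    try:
                        res = welch_log_geomean_test(x, y)
                    except ValueError:
                        # an all-zero group: rank test still applies
                        res = group_compare(x, y, alpha=config.alpha)
                else:
                    res = group_compare(x, y, alpha=config.alpha)
                rows.append({
                    "marker_id": marker, "time_point": tp,
                    "comparison": f"{exp_group}_vs_{ctl_group}",
                    "test_used": res.test_used.value,
                    "statistic": res.statistic, "p_value": res.p_value,
                })
    de = pd.DataFrame(rows)
    if len(de):
        if config.fdr_family == "per_comparison_timepoint":
            de["q_value"] = np.nan
            for _, idx in de.groupby(["time_point", "comparison"]).groups.items():
                de.loc[idx, "q_value"] = bh_fdr(de.loc[idx, "p_value"])
        else:
            de["q_value"] = bh_fdr(de["p_value"])
        if config.candidate_on == "p":
            hits = de.loc[de["p_value"] < config.alpha, "marker_id"]
            candidates = sorted(pd.unique(hits))
        elif config.fdr_family == "marker":
            # marker-level inference: a marker's evidence is its Bonferroni-
            # corrected minimum p over the per-phase tests; BH across markers
            # then controls the FDR of the discovered marker set itself
            per_marker = de.groupby("marker_id")["p_value"].agg(
                lambda p: min(1.0, float(p.min()) * len(p)))
            q_marker = pd.Series(bh_fdr(per_marker.to_numpy()),
                                 index=per_marker.index)
            candidates = sorted(q_marker.index[q_marker < config.fdr])
        else:
            hits = de.loc[de["q_value"] < config.fdr, "marker_id"]
            candidates = sorted(pd.unique(hits))
    else:
        de = pd.DataFrame(columns=["marker_id", "time_point", "comparison",
                                   "test_used", "statistic", "p_value",
                                   "q_value"])
        candidates = []
    return DiscoveryReport(qc=qc, excluded_samples=excluded,
                           normalized=normalized, retained_markers=retained,
                           de_table=de, candidates=candidates)


def run_validation(ct: CtTable, metas: Sequence[SampleMeta],
                   panel: Sequence[str],
                   config: PipelineConfig | None = None) -> ValidationReport:
    """Run the qPCR validation phase over a candidate marker panel."""
    config = config or PipelineConfig()
    if not panel:
        raise ValueError("panel must be non-empty")
    collapsed, cv_qc = collapse_replicates(ct)
    normalized = median_normalize_ct(collapsed)
    missing = [m for m in panel if m not in normalized.values.columns]
    if missing:
        raise ValueError(f"panel marker(s) missing from Ct table: {missing}")

    mf = meta_frame(metas)
    fold_rows, roc_rows = [], []
    rel_store: dict[tuple[str, str], pd.Series] = {}
    for tp in config.validation_time_points:
        tp_metas = [m for m in metas if m.time_point.value == tp
                    and m.sample_id in normalized.values.index]
        if not tp_metas:
            continue
        for marker in panel:
            rel_store[(marker, tp)] = relative_expression(
                normalized, tp_metas, marker, "TERM")
            for exp_group, ctl_group in _COMPARISONS:
                fc = fold_change(normalized, tp_metas, marker, exp_group,
                                 ctl_group)
                exp_ids = [m.sample_id for m in tp_metas
                           if m.outcome.value == exp_group]
                ctl_ids = [m.sample_id for m in tp_metas
                           if m.outcome.value == ctl_group]
                rel = fc.relative_expression
                exp_ids = [s for s in exp_ids if s in rel.index]
                ctl_ids = [s for s in ctl_ids if s in rel.index]
                cmp_res = group_compare(rel.loc[exp_ids], rel.loc[ctl_ids],
                                        alpha=config.alpha)
                fold_rows.append({
                    "marker_id": marker, "time_point": tp,
                    "outcome": exp_group, "fold": fc.fold, "dg": fc.dg,
                    "mean_relative_expression": fc.group_means[exp_group],
                    "sem": fc.group_sems[exp_group],
                    "control_mean": fc.group_means[ctl_group],
                    "p_value": cmp_res.p_value,
                    "test_used": cmp_res.test_used.value,
                })
                scores = pd.concat([rel.loc[exp_ids], rel.loc[ctl_ids]])
                labels = np.r_[np.ones(len(exp_ids)), np.zeros(len(ctl_ids))]
                curve = roc_curve(scores.to_numpy(), labels)
                screen = specificity_at_full_sensitivity(
                    scores.to_numpy(), labels, curve.direction)
                roc_rows.append({
                    "marker_id": marker, "time_point": tp,
                    "outcome": exp_group, "auc": curve.auc,
                    "p_value": auc_p_value(scores.to_numpy(), labels),
                    "specificity_100dr_pct":
                        100.0 * screen.specificity_at_full_sensitivity,
                    "ci95_low_pct": 100.0 * screen.ci95[0],
                    "ci95_high_pct": 100.0 * screen.ci95[1],
                    "case_n": curve.case_n, "control_n": curve.control_n,
                })

    fold_table = pd.DataFrame(fold_rows)
    roc_table = pd.DataFrame(roc_rows)

    combined_rows, coefficients = [], {}
    primary_tp = config.validation_time_points[0]
    for exp_group, ctl_group in _COMPARISONS:
        sub = roc_table.query(
            "time_point == @primary_tp and outcome == @exp_group")
        ranked = sub.sort_values("auc", ascending=False)["marker_id"].tolist()
        for size in config.panel_sizes:
            members = ranked[:size]
            if len(members) < 2:
                continue
            ids = [m.sample_id for m in metas
                   if m.time_point.value == primary_tp
                   and m.outcome.value in (exp_group, ctl_group)]
            log2rel = pd.DataFrame(
                {mk: np.log2(rel_store[(mk, primary_tp)]) for mk in members}
            ).loc[[s for s in ids
                   if all(s in rel_store[(mk, primary_tp)].index
                          for mk in members)]]
            labels = (mf.loc[log2rel.index, "outcome"] == exp_group).astype(int)
            _, curve, coef = combine_markers(log2rel, labels.to_numpy())
            combined_rows.append({
                "outcome": exp_group, "time_point": primary_tp,
                "panel_size": len(members), "markers": "|".join(members),
                "auc": curve.auc,
            })
            coefficients[f"{exp_group}_top{len(members)}"] = coef
    combined_table = pd.DataFrame(combined_rows)
    return ValidationReport(cv_qc=cv_qc, normalized_ct=normalized,
                            fold_table=fold_table, roc_table=roc_table,
                            combined_table=combined_table,
                            coefficients=coefficients)
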