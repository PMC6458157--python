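"""Count-level QC, background handling, normalization and prevalence filtering
for digital hybridization (nCounter-style) miRNA profiling.

The processing chain is:

1. :func:`haemolysis_qc` — flag plasma samples whose red-cell-derived miRNAs
   (hsa-miR-16-5p, hsa-miR-25-3p, hsa-miR-93-5p) are grossly elevated,
   indicating blood-cell contamination.
2. :func:`subtract_background` — the background signal is two standard
   deviations above the mean of the negative-control probes; it is subtracted
   from the endogenous counts and the result floored at zero.
3. :func:`top100_normalize` — counts are scaled so every sample has the same
   mean over the 100 most highly expressed endogenous probes.
4. :func:`prevalence_filter` — markers without expression above background in
   more than half of the samples of any clinical group are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import CountMatrix, ExpressionMatrix, ProbeClass, SampleMeta, Scale

__all__ = [
    "HAEMOLYSIS_MARKERS",
    "BackgroundModel",
    "QcReport",
    "background_threshold",
    "subtract_background",
    "haemolysis_qc",
    "top100_normalize",
    "prevalence_filter",
]

#: Red-cell-derived miRNAs whose elevation marks haemolysed plasma.
HAEMOLYSIS_MARKERS = ("hsa-miR-16-5p", "hsa-miR-25-3p", "hsa-miR-93-5p")

_MAD_SCALE = 1.4826  # MAD → sd consistency factor for a normal distribution


@dataclass(frozen=True)
class BackgroundModel:
    """Per-sample background threshold: mean + 2·sd of negative controls."""

    neg_mean: float
    neg_sd: float

    @property
    def threshold(self) -> float:
        return self.neg_mean + 2.0 * self.neg_sd


@dataclass
class QcReport:
    """Haemolysis QC outcome: robust z-scores and the flagged samples."""

    scores: pd.DataFrame  # samples × markers robust z on log2(count+1)
    flagged: pd.DataFrame  # sample_id, marker_id (trigger), z
    haemolysis_marker_ids: tuple[str, ...] = HAEMOLYSIS_MARKERS

    @property
    def flagged_samples(self) -> list[str]:
        return list(self.flagged["sample_id"])


def background_threshold(neg_counts: Sequence[float]) -> BackgroundModel:
    """Background model from one sample's negative-control counts.

    Uses the arithmetic mean and the n−1 sample standard deviation; at least
    three negative-control values are required.
    """
    x = np.asarray(neg_counts, dtype=float)
    if x.size < 3:
        raise ValueError(
            f"need >= 3 negative-control values, got {x.size}"
        )
    return BackgroundModel(neg_mean=float(x.mean()), neg_sd=float(x.std(ddof=1)))


def subtract_background(m: CountMatrix, *, pooled: bool = False) -> CountMatrix:
    """Threshold-subtract endogenous counts, flooring at zero.

    Each sample's threshold comes from its own negative-control probes by
    default; ``pooled=True`` instead pools the negative-control counts of the
    whole cohort into a single threshold. Control probes are dropped from the
    output.
    """
    neg = m.probe_ids(ProbeClass.NEG_CONTROL)
    endo = m.probe_ids(ProbeClass.ENDOGENOUS)
    if len(neg) == 0:
        # already background-subtracted (controls dropped): nothing to do,
        # which makes the operation idempotent on its own output
        return CountMatrix(counts=m.counts[endo].copy(),
                           annotation={p: ProbeClass.ENDOGENOUS for p in endo})
    if len(neg) < 3:
        raise ValueError("matrix has fewer than 3 negative-control probes")
    counts = m.counts[endo]
    if pooled:
        thr = background_threshold(m.counts[neg].to_numpy().ravel()).threshold
        out = (counts - thr).clip(lower=0.0)
    else:
        thresholds = {}
        for s in m.samples:
            try:
                thresholds[s] = background_threshold(m.counts.loc[s, neg]).threshold
            except ValueError as exc:
                raise ValueError(f"sample {s!r}: {exc}") from None
        out = counts.sub(pd.Series(thresholds)[counts.index], axis=0).clip(lower=0.0)
    annotation = {p: ProbeClass.ENDOGENOUS for p in endo}
    return CountMatrix(counts=out, annotation=annotation)


def haemolysis_qc(m: CountMatrix, *, z_cutoff: float = 3.0) -> QcReport:
    """Flag samples with very high red-cell miRNA signal.

    For each haemolysis marker, a robust z-score is computed across samples
    on log2(count + 1): (x − median) / (1.4826 · MAD). A sample is flagged
    when any marker's z exceeds ``z_cutoff``. Where the MAD is zero, values
    at the median score 0 and values away from it are flagged outright.
    """
    present = [p for p in HAEMOLYSIS_MARKERS if p in m.counts.columns]
    if not present:
        raise ValueError(
            f"none of the haemolysis markers {HAEMOLYSIS_MARKERS} present"
        )
    if len(present) < len(HAEMOLYSIS_MARKERS):
        missing = sorted(set(HAEMOLYSIS_MARKERS) - set(present))
        warnings.warn(f"haemolysis marker(s) absent, QC on remainder: {missing}",
                      stacklevel=2)
    logx = np.log2(m.counts[present] + 1.0)
    med = logx.median(axis=0)
    mad = (logx - med).abs().median(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (logx - med) / (_MAD_SCALE * mad)
    # MAD == 0: deviation from the median is itself the anomaly signal
    for p in present:
        if mad[p] == 0:
            z[p] = np.where(logx[p] == med[p], 0.0, np.inf * np.sign(logx[p] - med[p]))
    rows = []
    for s in m.samples:
        zs = z.loc[s]
        if (zs > z_cutoff).any():
            trigger = zs.idxmax()
            rows.append({"sample_id": s, "marker_id": trigger,
                         "z": float(zs[trigger])})
    flagged = pd.DataFrame(rows, columns=["sample_id", "marker_id", "z"])
    return QcReport(scores=z, flagged=flagged,
                    haemolysis_marker_ids=tuple(present))


def top100_normalize(m: CountMatrix, *, n_reference: int = 100) -> ExpressionMatrix:
    """Scale each sample to the cohort mean of the top-expressed probe set.

    The reference set is the ``n_reference`` endogenous probes with the
    highest mean count across all samples (every probe when fewer exist); the
    per-sample factor is (grand mean over the reference set) / (that sample's
    reference-set mean), so after scaling every sample has an identical
    reference-set mean.
    """
    endo = m.probe_ids(ProbeClass.ENDOGENOUS)
    counts = m.counts[endo]
    ref = counts.mean(axis=0).nlargest(min(n_reference, len(endo))).index
    sample_means = counts[ref].mean(axis=1)
    zero = sample_means[sample_means == 0]
    if len(zero):
        raise ValueError(
            f"reference-set mean is zero for sample(s) {list(zero.index)}"
        )
    grand = float(counts[ref].to_numpy().mean())
    factors = grand / sample_means
    return ExpressionMatrix(values=counts.mul(factors, axis=0),
                            scale=Scale.NORMALIZED_COUNT)


def prevalence_filter(
    m: ExpressionMatrix,
    meta: Sequence[SampleMeta],
    grouping: Mapping[str, Sequence[str]] | None = None,
) -> list[str]:
    """Markers expressed above background in a strict majority of any group.

    ``m`` must hold background-subtracted values, so value > 0 means "above
    background". ``grouping`` maps group label → sample_ids; by default
    samples are partitioned by outcome group. A marker is retained iff in at
    least one group strictly more than half of the samples are above
    background; expression in exactly half the samples of every group does
    not qualify.
    """
    if grouping is None:
        grouping = {}
        for s in meta:
            grouping.setdefault(s.outcome.value, []).append(s.sample_id)
    for label, ids in grouping.items():
        if len(ids) == 0:
            raise ValueError(f"empty group {label!r}")
    retained = []
    for marker in m.values.columns:
        for ids in grouping.values():
            above = int((m.values.loc[list(ids), marker] > 0).sum())
            if above * 2 > len(ids):
                retained.append(marker)
                break
    return retained
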