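"""Synthetic cohorts with the statistical structure of serial plasma-miRNA
profiling in pregnancy, so the whole pipeline is testable without patient
data.

The generator emulates a digital-count (nCounter-style) discovery cohort and
an RT-qPCR validation layout:

* ~800 probes of which ~55 are consistently expressed in plasma; the rest
  sit at or below the negative-control noise floor;
* negative-binomial counts around per-probe baselines, multiplied by a
  group- and time-point-specific fold effect for the true markers and by a
  log-normal patient-level random effect shared across a patient's three
  serial samples — the patient effect dominates, reproducing the
  patient-wise clustering seen in real serial plasma profiles;
* a small fraction of haemolysis-contaminated samples in which the three
  red-cell markers are spiked 20-fold;
* qPCR plates with an inter-plate calibrator, cel-254 and UniSp6 spike-in
  assays that carry each sample's technical offset, and duplicate technical
  replicates with Gaussian cycle noise.

Default group sizes and effect scales follow the discovery-cohort design:
16 TERM / 13 PRETERM / 24 SHORT patients sampled at three gestational time
points, with the nine true markers rising 4–24-fold across time points.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` child streams (one per generation stage), so
every sub-stream is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    CountMatrix,
    CtTable,
    Outcome,
    ProbeClass,
    SampleMeta,
    TimePoint,
)
from .ncounter import HAEMOLYSIS_MARKERS

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "simulate_qpcr",
           "DEFAULT_FOLD_EFFECTS"]

#: Multiplier applied to the red-cell markers of a haemolysed sample.
HAEMOLYSIS_SPIKE = 20.0

#: Fold effects (A, B, C) per outcome group for the nine marker miRNAs,
#: on the scale of the discovery-cohort mean relative expression.
DEFAULT_FOLD_EFFECTS: dict[str, dict[str, tuple[float, float, float]]] = {
    "hsa-miR-150-5p": {"PRETERM": (6.2, 8.8, 15.4), "SHORT": (4.5, 6.2, 9.3)},
    "hsa-miR-374a-5p": {"PRETERM": (6.2, 8.2, 11.4), "SHORT": (5.8, 9.5, 8.6)},
    "hsa-miR-19b-3p": {"PRETERM": (4.1, 4.5, 8.0), "SHORT": (6.1, 5.7, 6.2)},
    "hsa-miR-185-5p": {"PRETERM": (6.2, 4.5, 8.8), "SHORT": (4.9, 6.8, 5.6)},
    "hsa-miR-15b-5p": {"PRETERM": (11.3, 8.1, 17.4), "SHORT": (7.5, 8.0, 11.4)},
    "hsa-miR-191-5p": {"PRETERM": (5.5, 7.0, 6.6), "SHORT": (4.0, 9.2, 10.7)},
    "hsa-miR-93-5p": {"PRETERM": (4.5, 5.3, 6.6), "SHORT": (3.9, 5.1, 5.1)},
    "hsa-let-7a-5p": {"PRETERM": (6.8, 10.5, 24.2), "SHORT": (5.4, 8.6, 14.3)},
    "hsa-miR-23a-3p": {"PRETERM": (14.1, 6.5, 21.2), "SHORT": (8.8, 8.0, 12.8)},
}

_TIME_POINTS = (TimePoint.A, TimePoint.B, TimePoint.C)


@dataclass
class SimConfig:
    """Cohort-generation parameters.

    ``patient_sd`` is the standard deviation (log2 scale) of the per-patient
    multiplicative random effect; ``count_dispersion`` is the
    negative-binomial overdispersion α (variance = μ + αμ²);
    ``qpcr_noise_sd`` is the replicate Ct noise in cycles.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"TERM": 16, "PRETERM": 13, "SHORT": 24})
    n_probes: int = 800
    n_expressed: int = 55
    n_neg_controls: int = 6
    fold_effects: dict[str, dict[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {m: dict(g) for m, g in DEFAULT_FOLD_EFFECTS.items()})
    patient_sd: float = 1.0
    count_dispersion: float = 0.1
    haemolysis_fraction: float = 0.02
    qpcr_noise_sd: float = 0.2
    plate_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} size must be >= 1")
        if self.n_expressed > self.n_probes:
            raise ValueError("n_expressed cannot exceed n_probes")
        if min(self.n_probes, self.n_expressed, self.n_neg_controls,
               self.plate_count) < 1:
            raise ValueError("all sizes must be >= 1")
        for m, groups in self.fold_effects.items():
            for g, folds in groups.items():
                if any(f <= 0 for f in folds):
                    raise ValueError(f"fold effects must be > 0 ({m}, {g})")
        if not 0.0 <= self.haemolysis_fraction <= 1.0:
            raise ValueError("haemolysis_fraction must be in [0, 1]")
        if self.patient_sd < 0 or self.count_dispersion < 0 or self.qpcr_noise_sd < 0:
            raise ValueError("dispersions must be non-negative")


@dataclass
class GroundTruth:
    """What the generator injected, for scoring pipeline output against."""

    markers: set[str]                 # fold effect ≠ 1 somewhere
    haemolysed_samples: set[str]
    log2_rel: pd.DataFrame            # samples × expressed probes, fold +
    #                                   patient effect on log2 scale
    baselines: pd.Series              # expressed-probe baseline counts


def _streams(seed: int, names: Sequence[str]):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean)).astype(float)


def simulate_cohort(config: SimConfig) -> tuple[CountMatrix, list[SampleMeta], GroundTruth]:
    """Generate a serial digital-count cohort plus metadata and ground truth."""
    rngs = _streams(config.seed, ["structure", "patients", "counts",
                                  "haemolysis", "clinical"])

    marker_names = list(config.fold_effects)
    expressed = list(dict.fromkeys(
        marker_names + [m for m in HAEMOLYSIS_MARKERS]))
    if len(expressed) > config.n_expressed:
        raise ValueError("n_expressed smaller than the named marker set")
    expressed += [f"hsa-sim-mir-{i:03d}" for i in
                  range(config.n_expressed - len(expressed))]
    n_background = config.n_probes - config.n_expressed
    background = [f"probe-{i:04d}" for i in range(n_background)]
    negatives = [f"NEG_{chr(65 + i)}" for i in range(config.n_neg_controls)]

    rng = rngs["structure"]
    # Plasma abundance structure: a broad band of consistently expressed
    # miRNAs spans ~2^8-2^13 counts, red-cell miRNAs sit at the top of that
    # band, and the outcome-associated markers are low-abundance species
    # (tens of counts). The top-100 reference mass is therefore spread over
    # many comparable probes — so the per-sample normalization factor is
    # stable — and is dominated by non-differential species, so it is
    # insensitive to the injected group effects, as in real plasma where
    # the most abundant miRNAs are not the disease markers.
    log2_base = pd.Series(rng.uniform(8.0, 13.0, size=len(expressed)),
                          index=expressed)
    for m in expressed:
        if m in config.fold_effects:
            log2_base[m] = rng.uniform(4.0, 6.5)
        elif m in HAEMOLYSIS_MARKERS:
            log2_base[m] = rng.uniform(12.0, 14.0)
    base_expressed = 2.0 ** log2_base
    base_background = pd.Series(
        rng.uniform(0.2, 2.0, size=n_background), index=background)
    neg_mean = 4.0

    # patients and serial samples
    patients: list[tuple[str, str]] = []
    for group in ("TERM", "PRETERM", "SHORT"):
        for i in range(config.n_per_group.get(group, 0)):
            patients.append((f"{group[0]}{i + 1:03d}", group))
    metas: list[SampleMeta] = []
    crng = rngs["clinical"]
    for pid, group in patients:
        if group == "TERM":
            cls = {tp: float(crng.uniform(28, 36)) for tp in _TIME_POINTS}
        else:
            cls = {TimePoint.A: float(crng.uniform(27, 34)),
                   TimePoint.B: float(crng.uniform(24, 28)),
                   TimePoint.C: float(crng.uniform(15, 24))}
        for tp in _TIME_POINTS:
            metas.append(SampleMeta(
                sample_id=f"{pid}-{tp.value}", patient_id=pid,
                time_point=tp, outcome=Outcome(group),
                cervical_length_mm=round(cls[tp], 1)))

    # patient-level multiplicative random effect, shared across time points
    prng = rngs["patients"]
    patient_effect = pd.DataFrame(
        prng.normal(0.0, config.patient_sd,
                    size=(len(patients), len(expressed))),
        index=[p for p, _ in patients], columns=expressed)

    sample_ids = [m.sample_id for m in metas]
    tp_index = {tp: i for i, tp in enumerate(_TIME_POINTS)}
    log2_fold = pd.DataFrame(0.0, index=sample_ids, columns=expressed)
    for marker, groups in config.fold_effects.items():
        for m in metas:
            fold = groups.get(m.outcome.value, (1.0, 1.0, 1.0))[tp_index[m.time_point]]
            log2_fold.loc[m.sample_id, marker] = np.log2(fold)
    log2_rel = log2_fold.add(
        pd.DataFrame(patient_effect.loc[[m.patient_id for m in metas]].to_numpy(),
                     index=sample_ids, columns=expressed))

    mean_expressed = (2.0 ** log2_rel).mul(base_expressed, axis=1)
    cnt_rng = rngs["counts"]
    counts_expressed = _nb_draw(cnt_rng, mean_expressed.to_numpy(),
                                config.count_dispersion)
    counts_background = _nb_draw(
        cnt_rng, np.broadcast_to(base_background.to_numpy(),
                                 (len(sample_ids), n_background)),
        config.count_dispersion)
    counts_neg = _nb_draw(
        cnt_rng, np.full((len(sample_ids), len(negatives)), neg_mean),
        config.count_dispersion)

    counts = pd.DataFrame(
        np.hstack([counts_expressed, counts_background, counts_neg]),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=pd.Index(expressed + background + negatives, name="probe_id"))

    n_haem = int(round(config.haemolysis_fraction * len(sample_ids)))
    haem_ids: set[str] = set()
    if n_haem:
        picks = rngs["haemolysis"].choice(len(sample_ids), size=n_haem,
                                          replace=False)
        haem_ids = {sample_ids[i] for i in picks}
        present = [p for p in HAEMOLYSIS_MARKERS if p in counts.columns]
        counts.loc[sorted(haem_ids), present] *= HAEMOLYSIS_SPIKE

    annotation = {p: ProbeClass.ENDOGENOUS for p in expressed + background}
    annotation.update({p: ProbeClass.NEG_CONTROL for p in negatives})

    truth_markers = {
        m for m, groups in config.fold_effects.items()
        if any(f != 1.0 for folds in groups.values() for f in folds)
    }
    truth = GroundTruth(markers=truth_markers, haemolysed_samples=haem_ids,
                        log2_rel=log2_rel, baselines=base_expressed)
    return CountMatrix(counts=counts, annotation=annotation), metas, truth


#: qPCR assay layout constants (cycles).
CALIBRATOR_ASSAY = "IPC"
SPIKE_IN_ASSAYS = ("cel-254", "UniSp6")
_CAL_BASE_CT = 20.0
_SPIKE_BASE_CT = {"cel-254": 18.0, "UniSp6": 16.0}


def simulate_qpcr(
    config: SimConfig,
    metas: Sequence[SampleMeta],
    truth: GroundTruth,
    markers: Sequence[str] | None = None,
    *,
    plate_offsets: Sequence[float] | None = None,
    sample_offset_sd: float = 0.3,
    sample_offsets: Mapping[str, float] | None = None,
    noise_sd: float | None = None,
    n_replicates: int = 2,
) -> CtTable:
    """Generate an RT-qPCR Ct table for ``markers`` over the cohort.

    Each target Ct is assay baseline − log2(true relative expression) +
    plate offset + per-sample technical offset + replicate noise. The
    calibrator assay sits at a constant Ct plus its plate's offset; the two
    spike-in assays carry the per-sample offset (plus their plate's offset),
    so the two-step median normalization chain can remove both nuisance
    terms exactly in the noiseless limit.
    """
    rngs = _streams(config.seed + 1_000_003, ["layout", "offsets", "noise"])
    if markers is None:
        markers = sorted(truth.markers) or list(truth.log2_rel.columns[:9])
    missing = [m for m in markers if m not in truth.log2_rel.columns]
    if missing:
        raise ValueError(f"marker(s) not in simulated cohort: {missing}")
    noise = config.qpcr_noise_sd if noise_sd is None else noise_sd

    plates = [f"P{i + 1}" for i in range(config.plate_count)]
    if plate_offsets is None:
        plate_off = dict(zip(plates, rngs["offsets"].normal(0.0, 0.5,
                                                            len(plates))))
    else:
        if len(plate_offsets) != len(plates):
            raise ValueError("need one plate offset per plate")
        plate_off = dict(zip(plates, map(float, plate_offsets)))
    sample_plate = {m.sample_id: plates[i % len(plates)]
                    for i, m in enumerate(metas)}
    if sample_offsets is None:
        s_off = {m.sample_id: float(rngs["offsets"].normal(0.0, sample_offset_sd))
                 for m in metas}
    else:
        s_off = {m.sample_id: float(sample_offsets[m.sample_id]) for m in metas}

    base_ct = {m: 22.0 + 8.0 * (i % 5) / 5.0 for i, m in enumerate(markers)}
    nrng = rngs["noise"]

    def _noise() -> float:
        return float(nrng.normal(0.0, noise)) if noise > 0 else 0.0

    rows = []
    for plate in plates:
        for rep in range(1, n_replicates + 1):
            rows.append({"sample_id": "calibrator", "assay_id": CALIBRATOR_ASSAY,
                         "plate_id": plate, "replicate": rep,
                         "ct": _CAL_BASE_CT + plate_off[plate] + _noise(),
                         "undetected": False})
    for m in metas:
        plate = sample_plate[m.sample_id]
        for spike in SPIKE_IN_ASSAYS:
            for rep in range(1, n_replicates + 1):
                rows.append({"sample_id": m.sample_id, "assay_id": spike,
                             "plate_id": plate, "replicate": rep,
                             "ct": _SPIKE_BASE_CT[spike] + plate_off[plate]
                             + s_off[m.sample_id] + _noise(),
                             "undetected": False})
        for marker in markers:
            true_ct = (base_ct[marker]
                       - float(truth.log2_rel.loc[m.sample_id, marker]))
            for rep in range(1, n_replicates + 1):
                rows.append({"sample_id": m.sample_id, "assay_id": marker,
                             "plate_id": plate, "replicate": rep,
                             "ct": true_ct + plate_off[plate]
                             + s_off[m.sample_id] + _noise(),
                             "undetected": False})
    return CtTable(records=pd.DataFrame(rows),
                   calibrator_assay_id=CALIBRATOR_ASSAY,
                   spike_in_assay_ids=list(SPIKE_IN_ASSAYS))


def null_config(config: SimConfig | None = None, **overrides) -> SimConfig:
    """A copy of ``config`` with every fold effect set to 1 (no signal)."""
    cfg = config or SimConfig()
    flat = {m: {g: (1.0, 1.0, 1.0) for g in groups}
            for m, groups in cfg.fold_effects.items()}
    return replace(cfg, fold_effects=flat, **overrides)
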