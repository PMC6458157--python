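"""Domain types and delimited-text IO for the plasma-miRNA screening pipeline.

The pipeline moves between three concrete file formats, all plain delimited
text (comma-separated by default; a tab dialect is auto-detected):

* **counts** — a samples × probes table of non-negative digital counts, plus a
  probe annotation table mapping every probe to a class (endogenous miRNA,
  negative control, positive control, spike-in).
* **Ct table** — long-format qPCR records, one row per
  (sample, assay, plate, replicate) with a cycle-threshold value or an
  "undetected" sentinel (``Undetermined``, ``NA`` or empty).
* **sample metadata** — one row per plasma sample with patient id,
  gestational time point (A/B/C), outcome group (TERM/PRETERM/SHORT) and
  optional cervical lengths (mm) at the three time points.

Counts files may be written samples-in-rows or probes-in-rows; the
orientation is detected from the header: the first header field must be
``sample_id`` (rows are samples) or ``probe_id`` (rows are probes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeClass",
    "TimePoint",
    "Outcome",
    "Scale",
    "ProbeAnnotation",
    "CountMatrix",
    "SampleMeta",
    "CtTable",
    "ExpressionMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "read_ct_table",
    "write_ct_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "derive_outcome",
    "CL_SHORT_MM",
    "UNDETECTED_SENTINELS",
]

#: Diagnostic cervical-length threshold (mm): shortening means CL < 25 mm at
#: time point B or C when the time-point-A measurement exceeded 25 mm.
CL_SHORT_MM = 25.0

#: Instrument-software tokens meaning "no amplification detected".
UNDETECTED_SENTINELS = {"Undetermined", "NA", ""}


class ProbeClass(Enum):
    ENDOGENOUS = "ENDOGENOUS"
    NEG_CONTROL = "NEG_CONTROL"
    POS_CONTROL = "POS_CONTROL"
    SPIKE_IN = "SPIKE_IN"


class TimePoint(Enum):
    """Gestational sampling windows: A 12-14+6, B 15-17+6, C 18-21+6 weeks."""

    A = "A"
    B = "B"
    C = "C"


class Outcome(Enum):
    """Clinical outcome groups.

    TERM: no cervical shortening, delivered at term. PRETERM: spontaneous
    delivery before 34 weeks. SHORT: mid-pregnancy cervical shortening
    (CL < 25 mm at B or C after a normal measurement at A).
    """

    TERM = "TERM"
    PRETERM = "PRETERM"
    SHORT = "SHORT"


class Scale(Enum):
    RAW_COUNT = "RAW_COUNT"
    NORMALIZED_COUNT = "NORMALIZED_COUNT"
    RELATIVE_EXPRESSION = "RELATIVE_EXPRESSION"
    NORMALIZED_CT = "NORMALIZED_CT"


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    probe_class: ProbeClass


@dataclass
class CountMatrix:
    """Probe-level digital counts with probe-class annotation.

    ``counts`` is indexed by sample_id (rows) and probe_id (columns);
    ``annotation`` maps every probe_id in the matrix to its class.
    """

    counts: pd.DataFrame
    annotation: dict[str, ProbeClass]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_id(s): {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate probe_id(s): {dups}")
        missing = [p for p in self.counts.columns if p not in self.annotation]
        if missing:
            raise ValueError(f"probe(s) missing annotation: {missing}")
        if self.counts.isna().any().any():
            raise ValueError("count matrix contains missing cells")
        neg = self.counts.lt(0)
        if neg.any().any():
            s, p = next(zip(*np.nonzero(neg.to_numpy())))
            raise ValueError(
                "negative count at sample "
                f"{self.counts.index[s]!r}, probe {self.counts.columns[p]!r}"
            )

    def probe_ids(self, probe_class: ProbeClass) -> list[str]:
        return [p for p in self.counts.columns if self.annotation[p] == probe_class]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.annotation == other.annotation
            and self.counts.sort_index(axis=0)
            .sort_index(axis=1)
            .equals(other.counts.sort_index(axis=0).sort_index(axis=1))
        )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    time_point: TimePoint
    outcome: Outcome
    cervical_length_mm: float | None = None  # CL at this sample's time point


@dataclass
class CtTable:
    """Replicate-level qPCR cycle-threshold records.

    ``records`` columns: sample_id, assay_id, plate_id, replicate (int >= 1),
    ct (float, NaN when undetected), undetected (bool). The inter-plate
    calibrator assay must appear on every plate and every spike-in assay must
    be measured for every biological sample.
    """

    records: pd.DataFrame
    calibrator_assay_id: str
    spike_in_assay_ids: list[str]

    REQUIRED = ["sample_id", "assay_id", "plate_id", "replicate", "ct", "undetected"]

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing_cols = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing_cols:
            raise ValueError(f"Ct records missing column(s): {missing_cols}")
        r = self.records
        bad = r.loc[~r["undetected"] & ~np.isfinite(r["ct"].astype(float))]
        if len(bad):
            raise ValueError(
                f"non-finite Ct in detected record(s): {bad.index.tolist()[:5]}"
            )
        for plate, grp in r.groupby("plate_id"):
            if not (grp["assay_id"] == self.calibrator_assay_id).any():
                raise ValueError(f"plate {plate!r} lacks calibrator assay "
                                 f"{self.calibrator_assay_id!r}")
        targets = r.loc[~r["assay_id"].isin(
            [self.calibrator_assay_id, *self.spike_in_assay_ids])]
        biological = set(targets["sample_id"])
        for spike in self.spike_in_assay_ids:
            have = set(r.loc[r["assay_id"] == spike, "sample_id"])
            lacking = biological - have
            if lacking:
                raise ValueError(
                    f"sample(s) missing spike-in {spike!r}: {sorted(lacking)}"
                )

    @property
    def target_assays(self) -> list[str]:
        ctrl = {self.calibrator_assay_id, *self.spike_in_assay_ids}
        return [a for a in pd.unique(self.records["assay_id"]) if a not in ctrl]


@dataclass
class ExpressionMatrix:
    """Per-sample expression values (samples × markers) on a stated scale."""

    values: pd.DataFrame
    scale: Scale

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if self.scale is Scale.RELATIVE_EXPRESSION and (self.values <= 0).any().any():
            raise ValueError("relative expression values must be positive")


# ---------------------------------------------------------------------------
# delimited-text helpers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path), dtype=str,
                       keep_default_na=False)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | Path, annotation_path: str | Path) -> CountMatrix:
    """Read a counts file plus its probe-annotation file.

    Orientation is taken from the first header field (``sample_id`` → rows
    are samples, ``probe_id`` → rows are probes and the table is transposed).
    """
    raw = _read_table(path)
    first = raw.columns[0]
    if first not in ("sample_id", "probe_id"):
        raise ValueError(
            f"counts header must start with 'sample_id' or 'probe_id', got {first!r}"
        )
    raw = raw.set_index(first)
    counts = raw.apply(pd.to_numeric)
    if first == "probe_id":
        counts = counts.T
    counts.index.name = "sample_id"
    counts.columns.name = "probe_id"

    ann_raw = _read_table(annotation_path)
    if not {"probe_id", "probe_class"} <= set(ann_raw.columns):
        raise ValueError("annotation file needs columns probe_id, probe_class")
    try:
        annotation = {
            r.probe_id: ProbeClass(r.probe_class) for r in ann_raw.itertuples()
        }
    except ValueError as exc:
        raise ValueError(f"unknown probe class: {exc}") from None
    return CountMatrix(counts=counts.astype(float), annotation=annotation)


def write_count_matrix(m: CountMatrix, path: str | Path,
                       annotation_path: str | Path) -> None:
    out = m.counts.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
    ann = pd.DataFrame(
        {"probe_id": list(m.counts.columns),
         "probe_class": [m.annotation[p].value for p in m.counts.columns]}
    )
    ann.to_csv(annotation_path, index=False)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path, calibrator_assay_id: str,
                  spike_in_assay_ids: Sequence[str]) -> CtTable:
    raw = _read_table(path)
    need = {"sample_id", "assay_id", "plate_id", "replicate", "ct"}
    if not need <= set(raw.columns):
        raise ValueError(f"Ct file needs columns {sorted(need)}")
    undetected = raw["ct"].str.strip().isin(UNDETECTED_SENTINELS)
    ct = pd.to_numeric(raw["ct"].where(~undetected), errors="raise")
    rec = pd.DataFrame(
        {
            "sample_id": raw["sample_id"],
            "assay_id": raw["assay_id"],
            "plate_id": raw["plate_id"],
            "replicate": raw["replicate"].astype(int),
            "ct": ct.astype(float),
            "undetected": undetected.to_numpy(),
        }
    )
    return CtTable(records=rec, calibrator_assay_id=calibrator_assay_id,
                   spike_in_assay_ids=list(spike_in_assay_ids))


def write_ct_table(t: CtTable, path: str | Path) -> None:
    out = t.records.copy()
    out["ct"] = out["ct"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.loc[out["undetected"], "ct"] = "Undetermined"
    out.drop(columns="undetected").to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def derive_outcome(cl_a: float | None, cl_b: float | None, cl_c: float | None,
                   delivery_weeks: float | None = None,
                   sample_id: str = "?") -> Outcome:
    """Classify an outcome group from cervical lengths and delivery week.

    PRETERM: spontaneous delivery before 34 weeks. SHORT: CL < 25 mm at B or
    C when CL at A was > 25 mm. The rule uses strict inequalities; a CL of
    exactly 25 mm triggers neither side and is flagged with a warning, as is
    a shortening pattern whose time-point-A measurement did not exceed 25 mm.
    """
    if delivery_weeks is not None and delivery_weeks < 34:
        return Outcome.PRETERM
    later = [v for v in (cl_b, cl_c) if v is not None]
    short_later = any(v < CL_SHORT_MM for v in later)
    if any(v == CL_SHORT_MM for v in (cl_a, cl_b, cl_c) if v is not None):
        warnings.warn(
            f"sample {sample_id}: cervical length exactly {CL_SHORT_MM:g} mm is on "
            "the diagnostic boundary and triggers neither classification",
            stacklevel=2,
        )
    if short_later:
        if cl_a is not None and cl_a > CL_SHORT_MM:
            return Outcome.SHORT
        warnings.warn(
            f"sample {sample_id}: CL < {CL_SHORT_MM:g} mm at B/C but the "
            f"time-point-A measurement ({cl_a}) does not exceed "
            f"{CL_SHORT_MM:g} mm; ineligible for SHORT derivation",
            stacklevel=2,
        )
    return Outcome.TERM


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata; derives the outcome group when no outcome column
    is present (requires cervical-length columns cl_a/cl_b/cl_c and, for the
    PRETERM call, an optional delivery_weeks column)."""
    raw = _read_table(path)
    need = {"sample_id", "patient_id", "time_point"}
    if not need <= set(raw.columns):
        raise ValueError(f"metadata needs columns {sorted(need)}")

    def _num(row, col):
        v = row.get(col, "")
        return None if v in ("", "NA") else float(v)

    metas: list[SampleMeta] = []
    patient_outcome: dict[str, Outcome] = {}
    for _, row in raw.iterrows():
        try:
            tp = TimePoint(row["time_point"])
        except ValueError:
            raise ValueError(f"unknown time point {row['time_point']!r}") from None
        cls = {c: _num(row, f"cl_{c}") for c in ("a", "b", "c")}
        if "outcome" in raw.columns and row["outcome"] != "":
            try:
                outcome = Outcome(row["outcome"])
            except ValueError:
                raise ValueError(f"unknown outcome {row['outcome']!r}") from None
        else:
            pid = row["patient_id"]
            if pid not in patient_outcome:
                patient_outcome[pid] = derive_outcome(
                    cls["a"], cls["b"], cls["c"],
                    _num(row, "delivery_weeks"), sample_id=row["sample_id"],
                )
            outcome = patient_outcome[pid]
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                time_point=tp,
                outcome=outcome,
                cervical_length_mm=cls[tp.value.lower()],
            )
        )
    _check_meta_invariants(metas)
    return metas


def _check_meta_invariants(metas: Iterable[SampleMeta]) -> None:
    seen: dict[tuple[str, TimePoint], str] = {}
    outcome: dict[str, Outcome] = {}
    for m in metas:
        key = (m.patient_id, m.time_point)
        if key in seen:
            raise ValueError(f"duplicate (patient, time point) {key}")
        seen[key] = m.sample_id
        if m.patient_id in outcome and outcome[m.patient_id] != m.outcome:
            raise ValueError(
                f"patient {m.patient_id!r} has inconsistent outcomes"
            )
        outcome[m.patient_id] = m.outcome


def write_sample_metadata(metas: Sequence[SampleMeta], path: str | Path) -> None:
    by_patient: dict[str, dict[str, float | None]] = {}
    for m in metas:
        by_patient.setdefault(m.patient_id, {})[
            f"cl_{m.time_point.value.lower()}"] = m.cervical_length_mm
    rows = []
    for m in metas:
        cls = by_patient[m.patient_id]
        rows.append(
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "time_point": m.time_point.value,
                "outcome": m.outcome.value,
                "cl_a": cls.get("cl_a"),
                "cl_b": cls.get("cl_b"),
                "cl_c": cls.get("cl_c"),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def meta_frame(metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id (convenience for joins)."""
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in metas],
            "time_point": [m.time_point.value for m in metas],
            "outcome": [m.outcome.value for m in metas],
        },
        index=pd.Index([m.sample_id for m in metas], name="sample_id"),
    )
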