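"""Ingestion and preparation of patient-level adverse-event (AE) data.

Raw inputs are long-format event records (one row per patient, period,
AE name, CTCAE severity grade and occurrence count) plus a trial-design
table mapping each period to its study, treatment, mechanism of action
and cycle count.  This module validates those inputs, applies the
standard pre-processing (stopword AE removal, exclusion of patients
without any AE), builds the shared AE-type vocabulary (an "AE type" is
the pair name + severity, rendered ``NAME_severity``), derives the
severity-adjacency structure used by the smoothing priors, and
assembles the per-period count matrices with per-patient exposures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AEEvent",
    "PeriodMeta",
    "AETypeIndex",
    "AdjacencySets",
    "CountData",
    "ExclusionReport",
    "ValidationError",
    "read_events",
    "apply_filters",
    "build_ae_type_index",
    "build_adjacency",
    "assemble_counts",
]


class ValidationError(ValueError):
    """Raised when an input record violates a structural constraint."""


@dataclass(frozen=True)
class AEEvent:
    """One adverse-event record: a count of occurrences of one AE type
    for one patient during one period."""

    patient_id: str
    period_id: int
    ae_name: str
    severity: int
    count: int

    def __post_init__(self) -> None:
        if self.severity not in (1, 2, 3, 4):
            raise ValidationError(
                f"severity must be in 1..4, got {self.severity!r} "
                f"(patient {self.patient_id}, period {self.period_id}, "
                f"AE {self.ae_name})"
            )
        if self.count < 0:
            raise ValidationError(
                f"count must be >= 0, got {self.count!r} "
                f"(patient {self.patient_id}, period {self.period_id})"
            )

    @property
    def label(self) -> str:
        return f"{self.ae_name}_{self.severity}"


@dataclass
class PeriodMeta:
    """Design metadata for one period of one study arm.

    A baseline period (pre-treatment interval) has no treatment and no
    mechanism; its AEs reflect disease and background only.
    """

    period_id: int
    study_id: int
    treatment_id: int | None
    mechanism_id: int | None
    n_cycles: float | None
    is_baseline: bool
    enrolled_patients: list[str] = field(default_factory=list)
    # optional per-patient exposure override (e.g. mid-period discontinuation)
    exposure_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.is_baseline != (self.treatment_id is None):
            raise ValidationError(
                f"period {self.period_id}: is_baseline must coincide with a "
                "missing treatment_id"
            )
        if self.is_baseline != (self.mechanism_id is None):
            raise ValidationError(
                f"period {self.period_id}: is_baseline must coincide with a "
                "missing mechanism_id"
            )
        if not self.is_baseline and (self.n_cycles is None or self.n_cycles <= 0):
            raise ValidationError(
                f"period {self.period_id}: treatment periods need n_cycles > 0"
            )
        if len(set(self.enrolled_patients)) != len(self.enrolled_patients):
            raise ValidationError(
                f"period {self.period_id}: duplicate patients in enrollment"
            )


class AETypeIndex:
    """Shared vocabulary of AE types (name, severity) -> column index.

    Ordering is deterministic: lexicographic by name, then severity
    ascending.  Labels are rendered ``NAME_severity`` (e.g. ``VOMIT_2``).
    """

    def __init__(self, pairs: list[tuple[str, int]]):
        self.pairs = sorted(set(pairs))
        self.names = [n for n, _ in self.pairs]
        self.severities = np.array([s for _, s in self.pairs], dtype=int)
        self.labels = [f"{n}_{s}" for n, s in self.pairs]
        self._col = {lab: j for j, lab in enumerate(self.labels)}

    @property
    def J(self) -> int:
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def column(self, label: str) -> int:
        return self._col[label]

    def column_of(self, name: str, severity: int) -> int:
        return self._col[f"{name}_{severity}"]

    def __contains__(self, label: str) -> bool:
        return label in self._col

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "ae_name": self.names,
                "severity": self.severities,
                "column": np.arange(self.J),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AETypeIndex":
        idx = cls(list(zip(df["ae_name"], df["severity"].astype(int))))
        if idx.labels != list(df["label"]):
            raise ValidationError("AE type table is not in canonical order")
        return idx


@dataclass
class AdjacencySets:
    """Severity-chain structure over the AE-type columns.

    ``adj_pairs`` holds ordered column pairs (j, j') of the same AE name
    with consecutive *observed* severities and j < j'; ``anchors`` holds
    the column of the lowest observed severity of each name.  The pairs
    drive the Gaussian random-walk (NDLM) smoothing prior across
    severities; the anchors carry the identifiability prior.
    """

    adj_pairs: list[tuple[int, int]]
    anchors: list[int]

    @property
    def pair_lo(self) -> np.ndarray:
        return np.array([a for a, _ in self.adj_pairs], dtype=np.intp)

    @property
    def pair_hi(self) -> np.ndarray:
        return np.array([b for _, b in self.adj_pairs], dtype=np.intp)

    @property
    def anchor_cols(self) -> np.ndarray:
        return np.array(sorted(self.anchors), dtype=np.intp)


@dataclass
class ExclusionReport:
    """What the pre-processing filters removed, and why."""

    removed_names: dict[str, int] = field(default_factory=dict)  # name -> events
    removed_patients: list[str] = field(default_factory=list)
    n_events_in: int = 0
    n_events_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "ae_name", "value": n, "n_events_removed": c}
            for n, c in sorted(self.removed_names.items())
        ]
        rows += [
            {"kind": "patient", "value": p, "n_events_removed": 0}
            for p in self.removed_patients
        ]
        return pd.DataFrame(rows, columns=["kind", "value", "n_events_removed"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CountData:
    """Per-period N_p x J count matrices over a shared AE-type vocabulary.

    ``Y[p]`` has one row per enrolled patient (sorted id order) and one
    column per AE type; ``C[p]`` is the per-patient exposure (number of
    treatment cycles; a configurable constant for baseline periods).
    """

    Y: dict[int, np.ndarray]
    C: dict[int, np.ndarray]
    periods: dict[int, PeriodMeta]
    index: AETypeIndex

    @property
    def total_count(self) -> int:
        return int(sum(int(y.sum()) for y in self.Y.values()))

    def patients(self, period_id: int) -> list[str]:
        return sorted(self.periods[period_id].enrolled_patients)


# ---------------------------------------------------------------------------
# reading


_EVENT_COLS = ["patient_id", "period_id", "ae_name", "severity", "count"]
_DESIGN_COLS = [
    "period_id",
    "study_id",
    "treatment_id",
    "mechanism_id",
    "n_cycles",
    "is_baseline",
]


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} file is missing columns: {missing}")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("1", "true", "yes", "y")


def read_events(
    events_path,
    design_path,
    enrollment_path=None,
) -> tuple[list[AEEvent], list[PeriodMeta]]:
    """Read and validate the events and design CSV tables.

    When ``enrollment_path`` is omitted, each period's enrollment is
    inferred as the set of patients with at least one event in it.  An
    enrollment file (columns ``period_id, patient_id`` and optionally
    ``exposure``) is required to represent patients who reported no AEs
    or to override per-patient exposures.
    """
    ev_df = pd.read_csv(events_path)
    _require_columns(ev_df, _EVENT_COLS, "events")
    de_df = pd.read_csv(design_path)
    _require_columns(de_df, _DESIGN_COLS, "design")

    design: list[PeriodMeta] = []
    for _, row in de_df.iterrows():
        is_base = _parse_bool(row["is_baseline"])
        design.append(
            PeriodMeta(
                period_id=int(row["period_id"]),
                study_id=int(row["study_id"]),
                treatment_id=None if is_base else int(row["treatment_id"]),
                mechanism_id=None if is_base else int(row["mechanism_id"]),
                n_cycles=None if is_base else float(row["n_cycles"]),
                is_baseline=is_base,
            )
        )
    by_period = {pm.period_id: pm for pm in design}
    if len(by_period) != len(design):
        raise ValidationError("duplicate period_id in design")

    # mechanism must be a function of treatment
    mech_of: dict[int, int] = {}
    for pm in design:
        if pm.treatment_id is None:
            continue
        prev = mech_of.setdefault(pm.treatment_id, pm.mechanism_id)
        if prev != pm.mechanism_id:
            raise ValidationError(
                f"treatment {pm.treatment_id} maps to mechanisms "
                f"{prev} and {pm.mechanism_id}"
            )

    events: list[AEEvent] = []
    for i, row in ev_df.iterrows():
        try:
            ev = AEEvent(
                patient_id=str(row["patient_id"]),
                period_id=int(row["period_id"]),
                ae_name=str(row["ae_name"]),
                severity=int(row["severity"]),
                count=int(row["count"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"events row {i}: {exc}") from None
        if ev.period_id not in by_period:
            raise ValidationError(
                f"events row {i}: unknown period_id {ev.period_id}"
            )
        events.append(ev)

    if enrollment_path is not None:
        en_df = pd.read_csv(enrollment_path)
        _require_columns(en_df, ["period_id", "patient_id"], "enrollment")
        for _, row in en_df.iterrows():
            pid = int(row["period_id"])
            if pid not in by_period:
                raise ValidationError(f"enrollment: unknown period_id {pid}")
            pm = by_period[pid]
            pat = str(row["patient_id"])
            pm.enrolled_patients.append(pat)
            if "exposure" in en_df.columns and pd.notna(row.get("exposure")):
                pm.exposure_overrides[pat] = float(row["exposure"])
        for pm in design:
            if len(set(pm.enrolled_patients)) != len(pm.enrolled_patients):
                raise ValidationError(
                    f"period {pm.period_id}: duplicate enrollment rows"
                )
    else:
        for ev in events:
            pm = by_period[ev.period_id]
            if ev.patient_id not in pm.enrolled_patients:
                pm.enrolled_patients.append(ev.patient_id)

    # every event must reference an enrolled patient
    enrolled = {
        (pm.period_id, pat) for pm in design for pat in pm.enrolled_patients
    }
    for ev in events:
        if (ev.period_id, ev.patient_id) not in enrolled:
            raise ValidationError(
                f"event for patient {ev.patient_id} in period {ev.period_id} "
                "references a patient not enrolled in that period"
            )
    return events, design


# ---------------------------------------------------------------------------
# filtering


def apply_filters(
    events: list[AEEvent],
    design: list[PeriodMeta] | None = None,
    stopword_names: set[str] = frozenset(),
    drop_zero_ae_patients: bool = True,
    max_patient_fraction: float | None = None,
) -> tuple[list[AEEvent], list[PeriodMeta] | None, ExclusionReport]:
    """Apply stopword-AE and zero-AE-patient exclusions.

    Stopword removal is name-level: every severity of a stopword AE name
    is dropped.  ``max_patient_fraction`` optionally adds a frequency
    rule, removing any AE name reported (with count > 0) by more than
    that fraction of patients — the rule under which alopecia-like,
    near-universal AEs are excluded before factorization.  Patients left
    without any event are removed from every period's enrollment, since
    their safety profiles would be estimated as zero and they carry no
    information about the patterns.

    Idempotent: filtering an already-filtered dataset is a no-op.
    """
    report = ExclusionReport(n_events_in=len(events))
    stop = set(stopword_names)

    if max_patient_fraction is not None:
        all_patients = {ev.patient_id for ev in events}
        pat_by_name: dict[str, set[str]] = {}
        for ev in events:
            if ev.count > 0:
                pat_by_name.setdefault(ev.ae_name, set()).add(ev.patient_id)
        for name, pats in pat_by_name.items():
            if all_patients and len(pats) / len(all_patients) > max_patient_fraction:
                stop.add(name)

    kept: list[AEEvent] = []
    for ev in events:
        if ev.ae_name in stop:
            report.removed_names[ev.ae_name] = (
                report.removed_names.get(ev.ae_name, 0) + 1
            )
        else:
            kept.append(ev)

    out_design = design
    if drop_zero_ae_patients:
        # a patient counts as "having AEs" only with a positive count
        with_events = {ev.patient_id for ev in kept if ev.count > 0}
        kept = [ev for ev in kept if ev.patient_id in with_events]
        if design is not None:
            all_enrolled = {p for pm in design for p in pm.enrolled_patients}
            report.removed_patients = sorted(all_enrolled - with_events)
            out_design = [
                PeriodMeta(
                    period_id=pm.period_id,
                    study_id=pm.study_id,
                    treatment_id=pm.treatment_id,
                    mechanism_id=pm.mechanism_id,
                    n_cycles=pm.n_cycles,
                    is_baseline=pm.is_baseline,
                    enrolled_patients=[
                        p for p in pm.enrolled_patients if p in with_events
                    ],
                    exposure_overrides={
                        p: c
                        for p, c in pm.exposure_overrides.items()
                        if p in with_events
                    },
                )
                for pm in design
            ]
        else:
            seen = {ev.patient_id for ev in events}
            report.removed_patients = sorted(seen - with_events)

    report.n_events_out = len(kept)
    return kept, out_design, report


# ---------------------------------------------------------------------------
# vocabulary and adjacency


def build_ae_type_index(events: list[AEEvent]) -> AETypeIndex:
    """Build the shared AE-type vocabulary from filtered events."""
    if not events:
        warnings.warn("building an empty AE-type index (no events)")
    return AETypeIndex([(ev.ae_name, ev.severity) for ev in events])


def build_adjacency(index: AETypeIndex) -> AdjacencySets:
    """Derive severity chains and anchors from the vocabulary.

    For each AE name, the observed severities are sorted ascending and
    each consecutive pair becomes an adjacency pair — so severities
    {1, 3} with grade 2 never observed still chain 1 -> 3, keeping the
    name's random-walk prior connected.  The minimum observed severity
    of each name is its anchor.
    """
    by_name: dict[str, list[tuple[int, int]]] = {}
    for j, (name, sev) in enumerate(index.pairs):
        by_name.setdefault(name, []).append((sev, j))
    pairs: list[tuple[int, int]] = []
    anchors: list[int] = []
    for name in sorted(by_name):
        grades = sorted(by_name[name])
        anchors.append(grades[0][1])
        for (_, j), (_, jp) in zip(grades, grades[1:]):
            pairs.append((j, jp))
    return AdjacencySets(adj_pairs=pairs, anchors=anchors)


# ---------------------------------------------------------------------------
# count assembly


def assemble_counts(
    events: list[AEEvent],
    design: list[PeriodMeta],
    index: AETypeIndex,
    baseline_exposure: float = 1.0,
) -> CountData:
    """Summarize events into per-period count matrices with exposures.

    Rows follow each period's enrollment in sorted patient-id order.
    Exposure is the arm's cycle count (per-patient overrides honoured);
    baseline periods use ``baseline_exposure``, treating the
    pre-treatment interval as a single exposure unit by default.
    """
    Y: dict[int, np.ndarray] = {}
    C: dict[int, np.ndarray] = {}
    periods = {pm.period_id: pm for pm in design}
    rowmaps: dict[int, dict[str, int]] = {}
    for pm in design:
        pats = sorted(pm.enrolled_patients)
        rowmaps[pm.period_id] = {p: i for i, p in enumerate(pats)}
        Y[pm.period_id] = np.zeros((len(pats), index.J), dtype=np.int64)
        base = baseline_exposure if pm.is_baseline else float(pm.n_cycles)
        C[pm.period_id] = np.array(
            [pm.exposure_overrides.get(p, base) for p in pats], dtype=float
        )
    for ev in events:
        rm = rowmaps.get(ev.period_id)
        if rm is None or ev.patient_id not in rm:
            raise ValidationError(
                f"event for ({ev.patient_id}, period {ev.period_id}) "
                "is not covered by the enrollment"
            )
        Y[ev.period_id][rm[ev.patient_id], index.column(ev.label)] += ev.count
    return CountData(Y=Y, C=C, periods=periods, index=index)
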