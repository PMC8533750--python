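"""Cohort-level concordance between heterogeneity trends and clinical outcome.

Joins the per-study measures (fractal dimension, averaged multifractal
index, cumulative measure dD) with the PERCIMT outcome of each follow-up
study, classifies the longitudinal trend of each measure, and scores how
often the trend agrees with the clinical reading:

* response (PMR or CMR)  <-> any increase of the measure vs baseline,
* progression (PMD)      <-> any decrease,
* stable disease (SMD)   <-> change inside a small stability band.

Immune-related colitis floods the colon with tracer and mimics a diffuse —
hence "healthier" — distribution, so studies annotated with colitis as an
immune-related finding can be excluded from the statistics.

The packaged fixtures transcribe the published cohort (19 melanoma
patients scanned at baseline / interim / final under PD-1 inhibitor
therapy, plus 8 healthy single-study controls) so the printed matching
percentages are reproducible without access to the raw PET volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import AnalysisError, FixtureLoadError

__all__ = [
    "OUTCOMES",
    "TAU_TREND",
    "TAU_FD",
    "TAU_MFS",
    "StudyRecord",
    "StudyRecords",
    "ConcordanceReport",
    "classify_trend",
    "concordance",
    "cohort_summary",
    "count_colitis_studies",
    "load_fixtures",
]

OUTCOMES = ("CMR", "PMR", "SMD", "PMD")
RESPONSE, PROGRESSION, STABLE_DISEASE = {"CMR", "PMR"}, {"PMD"}, {"SMD"}

#: Stability band on the raw (unrounded) measures, as used in the trend rule.
TAU_TREND = 0.02
#: Default stability bands for the published per-study values, which are
#: rounded to 3 decimals; 0.025 (FD) and 0.13 (dD) reproduce every printed
#: matching annotation, whereas the nominal 0.02 band conflicts with two
#: rows that were evidently classified before rounding.
TAU_FD = 0.025
TAU_MFS = 0.13

_STAGES = ("baseline", "interim", "final", "control")


@dataclass(frozen=True)
class StudyRecord:
    """One PET study of one subject joined across the fixture tables."""

    subject_id: str
    stage: str  # baseline | interim | final | control
    medication: str = ""
    irae_tags: tuple[str, ...] = ()
    outcome: str | None = None
    fd: float | None = None
    mfs: float | None = None
    delta_d: float | None = None
    matching: dict = field(default_factory=dict)  # fixture-only YES/NO per measure

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.outcome is not None and self.outcome not in OUTCOMES:
            raise ValueError(f"unknown PERCIMT outcome {self.outcome!r}")
        if self.stage in ("baseline", "control") and self.outcome is not None:
            raise ValueError("baseline/control studies carry no outcome")
        if self.stage in ("interim", "final") and self.outcome is None:
            raise ValueError(f"follow-up study {self.subject_id}/{self.stage} lacks an outcome")
        for name in ("fd", "mfs"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 3.0):
                raise ValueError(f"{name}={v} outside [0, 3] for {self.subject_id}/{self.stage}")

    @property
    def is_followup(self) -> bool:
        return self.stage in ("interim", "final")

    def mentions_colitis(self) -> bool:
        """Any colitis-related wording in the irAE annotation (census rule)."""
        return any("colitis" in t.lower() for t in self.irae_tags)

    def colitis_irae(self) -> bool:
        """Colitis listed as an immune-related finding in its own right.

        Stricter than :meth:`mentions_colitis`: incidental wording such as
        "signs of colitis in descending colon" is a non-specific finding
        and does not trigger exclusion.
        """
        return any(t.strip().lower() == "colitis" for t in self.irae_tags)


class StudyRecords(Sequence[StudyRecord]):
    """Ordered collection of study records with subject-level lookups."""

    def __init__(self, records: Iterable[StudyRecord]):
        self._records = list(records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i):  # type: ignore[override]
        return self._records[i]

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self._records)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self._records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def patients(self) -> list[str]:
        return [s for s in self.subjects() if any(
            r.subject_id == s and r.stage != "control" for r in self._records)]

    def controls(self) -> list[str]:
        return [s for s in self.subjects() if any(
            r.subject_id == s and r.stage == "control" for r in self._records)]

    def get(self, subject_id: str, stage: str) -> StudyRecord:
        for r in self._records:
            if r.subject_id == subject_id and r.stage == stage:
                return r
        raise KeyError(f"no record for {subject_id}/{stage}")


@dataclass(frozen=True)
class ConcordanceReport:
    """Cohort matching statistics for one measure."""

    measure: str  # FD | MFS
    tau_stable: float
    exclude_colitis: bool
    n_studies: int
    n_excluded: int
    n_concordant: int
    percent_matching: float
    per_study: tuple[dict, ...]

    @property
    def n_included(self) -> int:
        return self.n_studies - self.n_excluded

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "tau_stable": self.tau_stable,
            "exclude_colitis": self.exclude_colitis,
            "n_studies": self.n_studies,
            "n_excluded": self.n_excluded,
            "n_included": self.n_included,
            "n_concordant": self.n_concordant,
            "percent_matching": self.percent_matching,
            "per_study": list(self.per_study),
        }


def classify_trend(delta: float, tau: float = TAU_TREND) -> str:
    """Label a baseline-referenced change of a measure.

    ``|delta| < tau`` is ``"stable"``; at or beyond the band the sign
    decides: an increase of FD/<MFS> means the tracer spreads more
    homogeneously (clinical improvement), a decrease means concentration
    around lesions (deterioration).
    """
    import math

    if not math.isfinite(delta):
        raise ValueError(f"delta must be finite, got {delta}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if abs(delta) < tau:
        return "stable"
    return "improved" if delta > 0 else "deteriorated"


def concordance(delta: float, outcome: str, tau_stable: float) -> bool:
    """Does the measure trend agree with the PERCIMT reading?

    Response categories (PMR, CMR) require any increase, progression (PMD)
    any decrease; only stable disease (SMD) uses the stability band.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be a follow-up PERCIMT category, got {outcome!r}")
    if outcome in RESPONSE:
        return delta > 0
    if outcome in PROGRESSION:
        return delta < 0
    return abs(delta) < tau_stable


def _round_percent(numerator: int, denominator: int) -> float:
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def cohort_summary(
    records: StudyRecords | Iterable[StudyRecord],
    measure: str = "FD",
    exclude_colitis: bool = False,
    tau_stable: float | None = None,
) -> ConcordanceReport:
    """Score trend-vs-outcome concordance over every follow-up study.

    For FD the change is ``fd(j) - fd(baseline)``; for MFS it is the
    cumulative measure dD(j) (taken from the record when present, else
    ``mfs(j) - mfs(baseline)``).  With ``exclude_colitis`` the follow-up
    studies whose irAE annotation lists colitis as an immune-related
    finding are dropped before the percentage is formed.
    """
    measure = measure.upper()
    if measure not in ("FD", "MFS"):
        raise ValueError(f"measure must be 'FD' or 'MFS', got {measure!r}")
    if tau_stable is None:
        tau_stable = TAU_FD if measure == "FD" else TAU_MFS
    if not isinstance(records, StudyRecords):
        records = StudyRecords(records)

    followups = sorted(
        (r for r in records if r.is_followup),
        key=lambda r: (r.subject_id, _STAGES.index(r.stage)),
    )
    if not followups:
        raise AnalysisError("no follow-up studies in the cohort")

    rows = []
    n_excluded = 0
    n_concordant = 0
    for r in followups:
        if exclude_colitis and r.colitis_irae():
            n_excluded += 1
            rows.append({"subject": r.subject_id, "stage": r.stage, "excluded": True})
            continue
        baseline = records.get(r.subject_id, "baseline")
        if measure == "FD":
            if r.fd is None or baseline.fd is None:
                raise AnalysisError(f"missing FD for {r.subject_id}")
            delta = r.fd - baseline.fd
        else:
            if r.delta_d is not None:
                delta = r.delta_d
            elif r.mfs is not None and baseline.mfs is not None:
                delta = r.mfs - baseline.mfs
            else:
                raise AnalysisError(f"missing MFS for {r.subject_id}")
        ok = concordance(delta, r.outcome, tau_stable)
        n_concordant += ok
        rows.append(
            {
                "subject": r.subject_id,
                "stage": r.stage,
                "excluded": False,
                "delta": round(delta, 6),
                "outcome": r.outcome,
                "trend": classify_trend(delta, tau_stable),
                "concordant": bool(ok),
            }
        )
    n_included = len(followups) - n_excluded
    if n_included == 0:
        raise AnalysisError("all follow-up studies were excluded")
    return ConcordanceReport(
        measure=measure,
        tau_stable=tau_stable,
        exclude_colitis=exclude_colitis,
        n_studies=len(followups),
        n_excluded=n_excluded,
        n_concordant=n_concordant,
        percent_matching=_round_percent(n_concordant, n_included),
        per_study=tuple(rows),
    )


def count_colitis_studies(records: StudyRecords | Iterable[StudyRecord]) -> int:
    """Census of studies (all stages, patients and controls) whose irAE
    annotation mentions colitis in any form."""
    return sum(r.mentions_colitis() for r in records)


# ---------------------------------------------------------------------------
# Fixture loading
# ---------------------------------------------------------------------------

_T1, _T2, _T3 = "table1_clinical.csv", "table2_fd.csv", "table3_mfs.csv"
_SCHEMAS = {
    _T1: ["patient", "age_sex", "stage", "medication", "iraes", "outcome"],
    _T2: ["patient", "stage", "fd", "side_effects", "outcome", "matching"],
    _T3: ["patient", "stage", "mfs", "delta_d", "side_effects", "outcome", "matching"],
}
#: printed dD values are consistent with the printed <MFS> values only up
#: to last-digit rounding; the loader enforces this reconciliation bound
_DELTA_D_ROUNDING = 0.007


def _read_fixture(directory: Path, name: str) -> pd.DataFrame:
    path = directory / name
    if not path.is_file():
        raise FixtureLoadError(f"fixture table not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FixtureLoadError(f"fixture table is empty: {path}") from exc
    expected = _SCHEMAS[name]
    if list(df.columns) != expected:
        raise FixtureLoadError(
            f"{path}: schema mismatch; expected columns {expected}, got {list(df.columns)}"
        )
    return df


def _tags(text: str) -> tuple[str, ...]:
    return tuple(t.strip() for t in text.split(";") if t.strip())


def load_fixtures(path: str | Path | None = None) -> StudyRecords:
    """Load and join the packaged cohort tables (or a directory of tables
    with the same schema).

    Validates the expected cohort shape (19 patients x 3 stages plus 8
    controls for the packaged data), the [0, 3] range of the measures and
    the dD(j) = <MFS>_j - <MFS>_1 identity up to printed rounding.
    """
    if path is None:
        directory = Path(str(resources.files("petfract.data")))
    else:
        directory = Path(path)
    t1 = _read_fixture(directory, _T1)
    t2 = _read_fixture(directory, _T2)
    t3 = _read_fixture(directory, _T3)

    clin = {(r.patient, r.stage): r for r in t1.itertuples()}
    fd = {(r.patient, r.stage): r for r in t2.itertuples()}
    mfs = {(r.patient, r.stage): r for r in t3.itertuples()}

    records = []
    for key, c in clin.items():
        patient, stage = key
        f, m = fd.get(key), mfs.get(key)
        matching = {}
        if f is not None and f.matching:
            matching["FD"] = f.matching == "YES"
        if m is not None and m.matching:
            matching["MFS"] = m.matching == "YES"
        records.append(
            StudyRecord(
                subject_id=patient,
                stage=stage,
                medication=c.medication,
                irae_tags=_tags(c.iraes),
                outcome=c.outcome or None,
                fd=float(f.fd) if f is not None and f.fd else None,
                mfs=float(m.mfs) if m is not None and m.mfs else None,
                delta_d=float(m.delta_d) if m is not None and m.delta_d else None,
                matching=matching,
            )
        )
    out = StudyRecords(records)

    # structural validation
    patients = out.patients()
    for p in patients:
        stages = {r.stage for r in out if r.subject_id == p}
        if stages != {"baseline", "interim", "final"}:
            raise FixtureLoadError(f"patient {p} has stages {sorted(stages)}")
    for r in out:
        if r.delta_d is not None:
            base = out.get(r.subject_id, "baseline")
            if base.mfs is None or abs(r.delta_d - (r.mfs - base.mfs)) > _DELTA_D_ROUNDING:
                raise FixtureLoadError(
                    f"dD inconsistent with <MFS> for {r.subject_id}/{r.stage}: "
                    f"{r.delta_d} vs {r.mfs} - {base.mfs}"
                )
    return out
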