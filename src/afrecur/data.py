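"""Core data model and cohort I/O for implantable-cardiac-monitor R-R records.

An implantable cardiac monitor (ICM) stores, for each detected atrial
fibrillation (AF) episode, the R-R intervals of the beats preceding the
onset (the *Flashback*) and of the first ~2 minutes of the episode itself.
One patient record couples those two series with four clinical covariates
(age, AF type, hypertension, ablation extra lesions) and a binary recurrence
label (AF episode longer than 2 minutes after the 3-month blanking period).

Cohorts are serialized as two plain CSV files inside a directory:

* ``rr_intervals.csv`` — long format, columns ``patient_id, segment,
  beat_index, rr_ms`` with ``segment`` in {``flashback``, ``af_episode``};
* ``clinical.csv`` — one row per patient, columns ``patient_id, age,
  af_type, hypertension, extra_lesions, recurrence``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("afrecur")

MIN_FLASHBACK_BEATS = 301
MIN_AF_BEATS = 100

RR_COLUMNS = ("patient_id", "segment", "beat_index", "rr_ms")
CLINICAL_COLUMNS = (
    "patient_id",
    "age",
    "af_type",
    "hypertension",
    "extra_lesions",
    "recurrence",
)
SEGMENTS = ("flashback", "af_episode")


class CohortValidationError(ValueError):
    """A record violates a data-model invariant."""


class CohortParseError(ValueError):
    """A cohort file does not conform to the expected CSV layout."""


@dataclass(frozen=True, eq=False)
class RRSeries:
    """An ordered series of R-R intervals in milliseconds."""

    intervals: np.ndarray
    label: str = "flashback"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=np.float64)
        if arr.ndim != 1:
            raise CohortValidationError("R-R intervals must be one-dimensional")
        if arr.size < 2:
            raise CohortValidationError("R-R series needs at least 2 intervals")
        if not np.all(np.isfinite(arr)):
            raise CohortValidationError("R-R intervals must be finite")
        if np.any(arr <= 0):
            raise CohortValidationError("R-R intervals must be positive")
        object.__setattr__(self, "intervals", arr)

    def __len__(self) -> int:
        return int(self.intervals.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RRSeries):
            return NotImplemented
        return self.label == other.label and np.array_equal(
            self.intervals, other.intervals
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class ClinicalFeatures:
    """Per-patient clinical covariates used by the classifiers.

    ``af_type`` is 1 for non-paroxysmal AF, ``extra_lesions`` is 1 when the
    ablation went beyond pulmonary-vein isolation.
    """

    age: float
    af_type: int
    hypertension: int
    extra_lesions: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age < 0:
            raise CohortValidationError("age must be finite and >= 0")
        for name in ("af_type", "hypertension", "extra_lesions"):
            if getattr(self, name) not in (0, 1):
                raise CohortValidationError(f"{name} must be 0 or 1")


@dataclass(frozen=True)
class ICMRecord:
    """One patient's stored ICM data plus outcome label."""

    patient_id: str
    flashback: RRSeries
    af_episode: RRSeries
    clinical: ClinicalFeatures
    recurrence: int

    def __post_init__(self) -> None:
        if len(self.flashback) < MIN_FLASHBACK_BEATS:
            raise CohortValidationError(
                f"patient {self.patient_id}: flashback length >= "
                f"{MIN_FLASHBACK_BEATS} required, got {len(self.flashback)}"
            )
        if len(self.af_episode) < MIN_AF_BEATS:
            raise CohortValidationError(
                f"patient {self.patient_id}: af_episode length >= "
                f"{MIN_AF_BEATS} required, got {len(self.af_episode)}"
            )
        if self.recurrence not in (0, 1):
            raise CohortValidationError(
                f"patient {self.patient_id}: recurrence must be 0 or 1"
            )


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of ICM records with unique patient ids."""

    records: tuple[ICMRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ICMRecord]:
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.recurrence for r in self.records], dtype=int)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write ``cohort`` to directory ``path`` (created if absent).

    Interval values are written with full ``repr`` precision so that
    :func:`read_cohort` reproduces them bit-identically.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rr_rows = []
    clin_rows = []
    for rec in cohort:
        for segment, series in (("flashback", rec.flashback),
                                ("af_episode", rec.af_episode)):
            for i, v in enumerate(series.intervals):
                rr_rows.append((rec.patient_id, segment, i, repr(float(v))))
        clin_rows.append(
            (
                rec.patient_id,
                repr(float(rec.clinical.age)),
                rec.clinical.af_type,
                rec.clinical.hypertension,
                rec.clinical.extra_lesions,
                rec.recurrence,
            )
        )
    pd.DataFrame(rr_rows, columns=RR_COLUMNS).to_csv(
        path / "rr_intervals.csv", index=False
    )
    pd.DataFrame(clin_rows, columns=CLINICAL_COLUMNS).to_csv(
        path / "clinical.csv", index=False
    )
    logger.info("wrote cohort of %d records to %s", len(cohort), path)
    return path


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort from a directory written by :func:`write_cohort`."""
    path = Path(path)
    rr_file = path / "rr_intervals.csv"
    clin_file = path / "clinical.csv"
    for f in (rr_file, clin_file):
        if not f.exists():
            raise CohortParseError(f"missing cohort file: {f}")
    try:
        rr = pd.read_csv(rr_file, dtype={"patient_id": str},
                         float_precision="round_trip")
        clin = pd.read_csv(clin_file, dtype={"patient_id": str},
                           float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CohortParseError(f"could not parse cohort files under {path}: {exc}")
    for col in RR_COLUMNS:
        if col not in rr.columns:
            raise CohortParseError(f"{rr_file}: missing column '{col}'")
    for col in CLINICAL_COLUMNS:
        if col not in clin.columns:
            raise CohortParseError(f"{clin_file}: missing column '{col}'")
    bad_seg = set(rr["segment"].unique()) - set(SEGMENTS)
    if bad_seg:
        raise CohortParseError(f"{rr_file}: unknown segment values {sorted(bad_seg)}")

    records = []
    grouped = {k: g for k, g in rr.groupby("patient_id", sort=False)}
    for row in clin.itertuples(index=False):
        pid = str(row.patient_id)
        g = grouped.get(pid)
        if g is None:
            raise CohortParseError(f"patient {pid}: no R-R rows in {rr_file}")
        series = {}
        for segment in SEGMENTS:
            seg = g[g["segment"] == segment].sort_values("beat_index")
            if seg.empty:
                raise CohortParseError(f"patient {pid}: no '{segment}' rows")
            series[segment] = RRSeries(seg["rr_ms"].to_numpy(float), label=segment)
        try:
            clinical = ClinicalFeatures(
                age=float(row.age),
                af_type=int(row.af_type),
                hypertension=int(row.hypertension),
                extra_lesions=int(row.extra_lesions),
            )
            records.append(
                ICMRecord(
                    patient_id=pid,
                    flashback=series["flashback"],
                    af_episode=series["af_episode"],
                    clinical=clinical,
                    recurrence=int(row.recurrence),
                )
            )
        except CohortValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise CohortParseError(f"patient {pid}: bad clinical row ({exc})")
    cohort = Cohort(records=tuple(records), provenance=str(path))
    logger.info("read cohort of %d records from %s", len(cohort), path)
    return cohort


@dataclass
class AnalysisConfig:
    """All tunables of the feature-extraction and classification pipeline.

    Defaults follow the study protocol (300-beat / 100-beat areas of
    interest, 8+8 fixed test set, 100 bootstrap repetitions) and, where the
    protocol is silent, the conventional HRV choices (``m`` = 2 and
    ``r`` = 0.2*SDNN for the entropies, DFA box ranges 4-16 and 16-64,
    1/128-s histogram bins).
    """

    # areas of interest
    first_beats: int = 300
    last_beats: int = 100
    flashback_cap: int | None = None

    # HRV feature parameters
    entropy_m: int = 2
    entropy_r_fraction: float = 0.2
    geometric_bin_width_ms: float = 1000.0 / 128.0
    dfa_short_range: tuple[int, int] = (4, 16)
    dfa_long_range: tuple[int, int] = (16, 64)

    # classifier hyperparameters
    svm_c: float = 1.0
    svm_poly_degree: int = 3
    knn_k: int = 5
    cart_min_samples_leaf: int = 1

    # split / evaluation protocol
    test_per_class: tuple[int, int] = (8, 8)  # (no-recurrence, recurrence)
    validation_fraction: float = 1.0 / 3.0
    n_repetitions: int = 100
    redraw_test_per_repetition: bool = False

    # feature selection
    sffs_max_size: int = 20
    n_selection_repetitions: int = 10

    # ensembles
    owv_step: float = 0.1
    owv_per_repetition: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        if self.first_beats < 2 or self.last_beats < 2:
            raise ValueError("area-of-interest sizes must be >= 2 beats")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.n_repetitions < 1 or self.sffs_max_size < 1:
            raise ValueError("repetition counts and sffs_max_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("test_per_class", "dfa_short_range", "dfa_long_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        payload = dataclasses.asdict(self)
        for key, value in payload.items():
            if isinstance(value, tuple):
                payload[key] = list(value)
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
        return path


def config_hash(obj) -> str:
    """Short stable hash of a dataclass config, used as provenance tag."""
    payload = repr(sorted(dataclasses.asdict(obj).items())).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
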