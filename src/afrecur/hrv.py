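"""Heart-rate-variability feature extraction over the four areas of interest.

Fourteen classical HRV features are computed on each of four R-R segments:

* **A** — the whole Flashback (feature group ``fb``),
* **B** — the first 300 beats of the Flashback,
* **C** — the last 100 beats of the Flashback (group ``l100``),
* **D** — the stored AF-episode onset (group ``af``),

plus the *Delta* group: the percentage change of each feature between B and
C, ``100 * (B - C) / B``, excluding pNN50 and pNN20 (whose B value can be 0,
making the relative change undefined). Together with four clinical
covariates this yields the 58-feature vector used by the classifiers.

Feature battery: mean, SDNN, RMSSD, pNN50, pNN20 (time domain); TINN and
the triangular index (interval-histogram geometry); ApEn and SampEn
(complexity); SD1, SD2, SD1/SD2 (Poincare plot); DFA alpha1/alpha2
(short/long-range fractal scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AnalysisConfig, Cohort, ICMRecord, RRSeries

logger = logging.getLogger("afrecur")

#: order of the 14 per-segment features
FEATURE_SET_NAMES = (
    "mean", "pnn50", "pnn20", "rmssd", "sdnn", "tinn", "tri",
    "apen", "sampen", "sd1", "sd2", "sd1sd2_ratio",
    "dfa_alpha1", "dfa_alpha2",
)
#: features excluded from the Delta group
DELTA_EXCLUDED = ("pnn50", "pnn20")
DELTA_SET_NAMES = tuple(n for n in FEATURE_SET_NAMES if n not in DELTA_EXCLUDED)

CLINICAL_NAMES = ("age", "af_type", "hypertension", "extra_lesions")

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"fb_{n}" for n in FEATURE_SET_NAMES)
    + tuple(f"l100_{n}" for n in FEATURE_SET_NAMES)
    + tuple(f"delta_{n}" for n in DELTA_SET_NAMES)
    + tuple(f"af_{n}" for n in FEATURE_SET_NAMES)
    + CLINICAL_NAMES
)

FEATURE_GROUPS: dict[str, str] = (
    {f"fb_{n}": "fb" for n in FEATURE_SET_NAMES}
    | {f"l100_{n}": "l100" for n in FEATURE_SET_NAMES}
    | {f"delta_{n}": "delta" for n in DELTA_SET_NAMES}
    | {f"af_{n}": "af" for n in FEATURE_SET_NAMES}
    | {n: "clinical" for n in CLINICAL_NAMES}
)

GROUP_ORDER = ("fb", "l100", "delta", "af", "clinical")


def _as_array(rr) -> np.ndarray:
    if isinstance(rr, RRSeries):
        return rr.intervals
    arr = np.asarray(rr, dtype=float)
    if arr.ndim != 1:
        raise ValueError("R-R input must be one-dimensional")
    return arr


# ---------------------------------------------------------------------------
# areas of interest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AoISet:
    """The four R-R segments extracted from one patient record."""

    whole_flashback: RRSeries       # A
    first300: RRSeries              # B
    last100: RRSeries               # C
    af_onset: RRSeries              # D


def extract_aois(record: ICMRecord, config: AnalysisConfig | None = None) -> AoISet:
    """Slice a record into the four areas of interest.

    B and C are independent slices of the Flashback (first ``first_beats``,
    last ``last_beats``); for Flashbacks shorter than their sum the two
    overlap, which is allowed. A is the whole stored Flashback (optionally
    capped to the most recent ``flashback_cap`` beats); D is the whole
    stored AF-episode onset.
    """
    config = config or AnalysisConfig()
    fb = record.flashback.intervals
    if len(fb) < config.first_beats + 1:
        raise ValueError(
            f"patient {record.patient_id}: flashback too short for AoI B "
            f"({len(fb)} < {config.first_beats + 1})"
        )
    if len(fb) < config.last_beats:
        raise ValueError(
            f"patient {record.patient_id}: flashback too short for AoI C"
        )
    whole = fb if config.flashback_cap is None else fb[-config.flashback_cap:]
    return AoISet(
        whole_flashback=RRSeries(whole, label="flashback"),
        first300=RRSeries(fb[: config.first_beats], label="flashback"),
        last100=RRSeries(fb[-config.last_beats:], label="flashback"),
        af_onset=RRSeries(record.af_episode.intervals, label="af_episode"),
    )


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def time_domain(rr) -> dict[str, float]:
    """Mean, SDNN (n-1 denominator), RMSSD, pNN50 and pNN20 (strict >)."""
    x = _as_array(rr)
    if x.size < 2:
        raise ValueError("time-domain features need at least 2 intervals")
    d = np.diff(x)
    return {
        "mean": float(np.mean(x)),
        "sdnn": float(np.std(x, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "pnn50": float(100.0 * np.count_nonzero(np.abs(d) > 50.0) / d.size),
        "pnn20": float(100.0 * np.count_nonzero(np.abs(d) > 20.0) / d.size),
    }


# ---------------------------------------------------------------------------
# interval-histogram geometry
# ---------------------------------------------------------------------------

def _histogram(x: np.ndarray, bin_width: float):
    lo = np.floor(x.min() / bin_width) * bin_width
    n_bins = max(int(np.ceil((x.max() - lo) / bin_width)), 1)
    if lo + n_bins * bin_width <= x.max():
        n_bins += 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(x, bins=edges)
    return counts, edges


def geometric(rr, bin_width: float = 1000.0 / 128.0) -> dict[str, float]:
    """Triangular index and TINN of the R-R interval histogram.

    TRI = total beat count / modal bin count. TINN is the baseline width of
    the least-squares best triangular fit to the histogram: with the apex
    fixed at the modal bin, the triangle's feet N and M are searched on the
    bin-edge grid and TINN = M - N. A histogram concentrated in a single bin
    degenerates to TRI = 1, TINN = ``bin_width`` (logged).
    """
    x = _as_array(rr)
    if x.size < 20:
        raise ValueError("geometric features need at least 20 intervals")
    counts, edges = _histogram(x, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = int(np.argmax(counts))
    height = float(counts[peak])
    tri = float(x.size / height)
    occupied = np.nonzero(counts)[0]
    if occupied.size == 1:
        logger.info("degenerate R-R histogram (single bin): TINN = bin width")
        return {"tinn": float(bin_width), "tri": tri}

    # With the apex fixed over the modal bin, the triangle's rising flank
    # only touches bins at or left of the apex and the falling flank only
    # bins right of it, so the squared error separates and the two feet can
    # be optimized independently.
    apex = centers[peak]
    left_feet = edges[: peak + 1]            # N <= left edge of modal bin
    right_feet = edges[peak + 1:]            # M >= right edge of modal bin
    cl, dl = centers[: peak + 1], counts[: peak + 1].astype(float)
    cr, dr = centers[peak + 1:], counts[peak + 1:].astype(float)

    span_l = apex - left_feet                                    # (nl,)
    with np.errstate(divide="ignore", invalid="ignore"):
        rise = height * (cl[None, :] - left_feet[:, None]) / span_l[:, None]
    rise = np.clip(np.nan_to_num(rise, nan=height), 0.0, height)
    rise[cl[None, :] < left_feet[:, None]] = 0.0
    sse_left = np.sum((dl[None, :] - rise) ** 2, axis=1)

    span_r = right_feet - apex                                   # (nr,)
    fall = height * (right_feet[:, None] - cr[None, :]) / span_r[:, None]
    fall = np.clip(fall, 0.0, height)
    fall[cr[None, :] > right_feet[:, None]] = 0.0
    sse_right = np.sum((dr[None, :] - fall) ** 2, axis=1)

    n_pos = float(left_feet[int(np.argmin(sse_left))])
    m_pos = float(right_feet[int(np.argmin(sse_right))])
    return {"tinn": m_pos - n_pos, "tri": tri}


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def _match_matrix(base: np.ndarray, m: int) -> np.ndarray:
    """Boolean matrix of Chebyshev template matches at length ``m``.

    ``base[i, j]`` is ``|x_i - x_j| <= r``; a length-m match is the AND of
    ``m`` diagonal-shifted slices, avoiding the (n, n, m) distance tensor.
    """
    n = base.shape[0]
    k_max = n - m + 1
    out = base[:k_max, :k_max].copy()
    for k in range(1, m):
        out &= base[k:k_max + k, k:k_max + k]
    return out


def _apen_phi(base: np.ndarray, m: int) -> float:
    # Pincus convention: N-m+1 templates, self-matches included
    matches = _match_matrix(base, m)
    c = matches.sum(axis=1) / matches.shape[0]
    return float(np.mean(np.log(c)))


def entropies(rr, m: int = 2, r_fraction: float = 0.2) -> dict[str, float]:
    """Approximate entropy (self-matches included) and sample entropy
    (self-matches excluded), with tolerance ``r = r_fraction * SDNN``.

    A perfectly regular series (SDNN = 0) is assigned ApEn = SampEn = 0.
    SampEn is undefined (NaN) when no template pair matches at length ``m``
    or ``m + 1``.
    """
    x = _as_array(rr)
    if x.size <= m + 1:
        raise ValueError(f"entropy needs more than m+1={m + 1} intervals")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        logger.info("zero-variance series: ApEn and SampEn defined as 0")
        return {"apen": 0.0, "sampen": 0.0}
    r = r_fraction * sd
    base = np.abs(x[:, None] - x[None, :]) <= r

    apen = _apen_phi(base, m) - _apen_phi(base, m + 1)

    # Richman-Moorman: N-m templates at both lengths, i != j
    n_t = x.size - m
    db = _match_matrix(base, m)[:n_t, :n_t]
    da = _match_matrix(base, m + 1)
    b = (np.count_nonzero(db) - n_t) / 2
    a = (np.count_nonzero(da) - n_t) / 2
    if a == 0 or b == 0:
        logger.info("no matching templates: SampEn undefined for this series")
        sampen = float("nan")
    else:
        sampen = float(-np.log(a / b))
    return {"apen": float(apen), "sampen": sampen}


# ---------------------------------------------------------------------------
# Poincare plot
# ---------------------------------------------------------------------------

def poincare(rr) -> dict[str, float]:
    """SD1, SD2 and their ratio.

    SD1 = SD(successive differences)/sqrt(2); SD2 = sqrt(2*SDNN^2 - SD1^2)
    (floored at 0 before the root). The ratio is NaN when SD2 = 0.
    """
    x = _as_array(rr)
    if x.size < 3:
        raise ValueError("Poincare descriptors need at least 3 intervals")
    sdnn = np.std(x, ddof=1)
    sd1 = float(np.std(np.diff(x), ddof=1) / np.sqrt(2.0))
    sd2 = float(np.sqrt(max(2.0 * sdnn**2 - sd1**2, 0.0)))
    if sd2 == 0.0:
        logger.info("SD2 = 0: SD1/SD2 ratio undefined for this series")
        ratio = float("nan")
    else:
        ratio = sd1 / sd2
    return {"sd1": sd1, "sd2": sd2, "sd1sd2_ratio": ratio}


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

def _dfa_fluctuation(profile: np.ndarray, n: int) -> float:
    k = profile.size // n
    if k < 2:
        return float("nan")
    segments = profile[: k * n].reshape(k, n)
    t = np.arange(n, dtype=float)
    coef = np.polyfit(t, segments.T, 1)          # (2, k)
    trend = np.outer(t, coef[0]) + coef[1]       # (n, k)
    resid = segments.T - trend
    return float(np.sqrt(np.mean(resid**2)))


def _dfa_alpha(profile: np.ndarray, lo: int, hi: int) -> float:
    sizes = np.arange(lo, hi + 1)
    f = np.array([_dfa_fluctuation(profile, int(n)) for n in sizes])
    ok = np.isfinite(f) & (f > 0)
    if np.count_nonzero(ok) < 2:
        return float("nan")
    return float(np.polyfit(np.log(sizes[ok]), np.log(f[ok]), 1)[0])


def dfa(rr, short_range: tuple[int, int] = (4, 16),
        long_range: tuple[int, int] = (16, 64)) -> dict[str, float]:
    """First-order DFA scaling exponents alpha1 (short) and alpha2 (long).

    The mean-centred series is integrated, split into non-overlapping boxes
    of each size, linearly detrended per box; F(n) is the RMS residual, and
    each alpha is the least-squares slope of log F(n) against log n over its
    box-size range. Box sizes admitting fewer than two boxes are dropped; an
    exponent with fewer than two usable sizes is NaN (logged).
    """
    x = _as_array(rr)
    if x.size < 2 * short_range[0]:
        raise ValueError("series too short for DFA")
    profile = np.cumsum(x - np.mean(x))
    alpha1 = _dfa_alpha(profile, *short_range)
    alpha2 = _dfa_alpha(profile, *long_range)
    if np.isnan(alpha2):
        logger.info("series too short for the long DFA range: alpha2 missing")
    return {"dfa_alpha1": alpha1, "dfa_alpha2": alpha2}


# ---------------------------------------------------------------------------
# per-segment battery, Delta, and the 58-feature vector
# ---------------------------------------------------------------------------

def hrv_feature_set(rr, config: AnalysisConfig | None = None) -> dict[str, float]:
    """All 14 features of one R-R segment, keyed by :data:`FEATURE_SET_NAMES`."""
    config = config or AnalysisConfig()
    out: dict[str, float] = {}
    out.update(time_domain(rr))
    out.update(geometric(rr, bin_width=config.geometric_bin_width_ms))
    out.update(entropies(rr, m=config.entropy_m,
                         r_fraction=config.entropy_r_fraction))
    out.update(poincare(rr))
    out.update(dfa(rr, short_range=config.dfa_short_range,
                   long_range=config.dfa_long_range))
    return {name: out[name] for name in FEATURE_SET_NAMES}


def delta_group(first300: dict[str, float],
                last100: dict[str, float]) -> tuple[dict[str, float], list[str]]:
    """Percentage change 100*(B - C)/B per feature, pNN50/pNN20 excluded.

    Returns the 12 delta values plus the names of features whose relative
    change could not be computed (B value 0 or non-finite → NaN).
    """
    deltas: dict[str, float] = {}
    flagged: list[str] = []
    for name in DELTA_SET_NAMES:
        b, c = first300[name], last100[name]
        if not np.isfinite(b) or b == 0 or not np.isfinite(c):
            deltas[name] = float("nan")
            flagged.append(name)
        else:
            deltas[name] = float(100.0 * (b - c) / b)
    if flagged:
        logger.info("delta undefined for features %s (baseline 0 or missing)",
                    flagged)
    return deltas, flagged


@dataclass(frozen=True)
class FeatureVector:
    """The 58 named features of one patient plus missing-value flags."""

    patient_id: str
    values: pd.Series
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if tuple(self.values.index) != FEATURE_NAMES:
            raise ValueError("feature vector must carry the 58 canonical names")


def assemble_feature_vector(record: ICMRecord,
                            config: AnalysisConfig | None = None) -> FeatureVector:
    """Compute the full 58-feature vector for one record.

    Missing values (undefined deltas, ratios, exponents) are carried as NaN
    and flagged; imputation is the classification stage's concern.
    """
    config = config or AnalysisConfig()
    aois = extract_aois(record, config)
    fb = hrv_feature_set(aois.whole_flashback, config)
    b = hrv_feature_set(aois.first300, config)
    c = hrv_feature_set(aois.last100, config)
    af = hrv_feature_set(aois.af_onset, config)
    deltas, flagged = delta_group(b, c)

    values: dict[str, float] = {}
    values.update({f"fb_{k}": v for k, v in fb.items()})
    values.update({f"l100_{k}": v for k, v in c.items()})
    values.update({f"delta_{k}": v for k, v in deltas.items()})
    values.update({f"af_{k}": v for k, v in af.items()})
    values["age"] = float(record.clinical.age)
    values["af_type"] = float(record.clinical.af_type)
    values["hypertension"] = float(record.clinical.hypertension)
    values["extra_lesions"] = float(record.clinical.extra_lesions)

    series = pd.Series([values[n] for n in FEATURE_NAMES],
                       index=list(FEATURE_NAMES), dtype=float)
    nan_flags = tuple(sorted(set(f"delta_{n}" for n in flagged)
                             | set(series.index[series.isna()])))
    return FeatureVector(patient_id=record.patient_id, values=series,
                         flags=nan_flags)


def extract_features(cohort: Cohort,
                     config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Feature matrix for a cohort: 58 columns + ``recurrence``, indexed by
    patient id, row order preserved."""
    config = config or AnalysisConfig()
    rows = []
    for record in cohort:
        fv = assemble_feature_vector(record, config)
        row = fv.values.copy()
        row["recurrence"] = float(record.recurrence)
        row.name = record.patient_id
        rows.append(row)
        if fv.flags:
            logger.info("patient %s: missing features %s", record.patient_id,
                        fv.flags)
    frame = pd.DataFrame(rows)
    frame.index.name = "patient_id"
    logger.info("extracted %d features for %d patients", len(FEATURE_NAMES),
                len(frame))
    return frame


class HRVFeatureExtractor:
    """Transformer from ICM records to the 58-column feature matrix.

    Stateless scikit-learn-style transformer: ``fit`` is a no-op; ``transform``
    accepts a :class:`~afrecur.data.Cohort` or a sequence of records and
    returns a DataFrame of the 58 named features (no label column).
    """

    def __init__(self, config: AnalysisConfig | None = None):
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "HRVFeatureExtractor":
        for key, value in params.items():
            if key != "config":
                raise ValueError(f"unknown parameter {key!r}")
            self.config = value
        return self

    def fit(self, X, y=None) -> "HRVFeatureExtractor":
        self.n_features_out_ = len(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        cohort = X if isinstance(X, Cohort) else Cohort(records=tuple(X))
        frame = extract_features(cohort, self.config)
        return frame.drop(columns=["recurrence"])

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
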