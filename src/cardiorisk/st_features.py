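"""ST-segment extraction, slope measurement, and ECG-derived dataset features.

The ST segment — the interval between the QRS complex and the T wave —
normally lasts about 120 ms; its slope and depression carry ischemic-risk
information.  At a 350 Hz sampling rate the default windows reproduce a
42-sample segment starting 20 samples after each R-peak.  The per-segment
slope is ``tan θ = (X - Y) / N`` with X the last sample, Y the first and N
the segment length in samples.

Two tabular features that would otherwise require an exercise test are
completed from the remaining attributes: ``oldpeak`` (ST depression, mV
scale 0–6.2) by support-vector regression and ``restecg`` (resting ECG
class 0/1/2) by a support-vector classifier, each preceded by Pearson
correlation-based feature selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC, SVR

from .ecg import ECGSignal, RPeakSet
from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

#: Default ST window geometry (ms); at 350 Hz these give 20 and 42 samples.
DEFAULT_OFFSET_MS = 57.14
DEFAULT_LENGTH_MS = 120.0

#: Half-band (amplitude-units/sample) inside which a slope counts as flat.
FLAT_SLOPE_BAND = 0.002

#: Hard range of the oldpeak attribute.
OLDPEAK_RANGE = (0.0, 6.2)

RESTECG_DOMAIN = (0, 1, 2)


def _half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class STSegment:
    """A post-R-peak amplitude slice on the raw timeline."""

    start_index: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise InvalidInputError("segment must be a non-empty 1-D slice")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        """Segment length N in samples."""
        return self.samples.size


@dataclass(frozen=True)
class STSlope:
    """Per-beat ST slopes and their summary for one recording."""

    per_beat: np.ndarray
    summary: float
    method: str = "mean"


def extract_st_segments(
    raw: ECGSignal,
    peaks: RPeakSet,
    offset_ms: float = DEFAULT_OFFSET_MS,
    length_ms: float = DEFAULT_LENGTH_MS,
) -> list[STSegment]:
    """One segment per R-peak with enough trailing signal.

    Peaks whose window would run past the end of the signal are skipped
    (logged), never an error.
    """
    if offset_ms <= 0 or length_ms <= 0:
        raise InvalidInputError("offset_ms and length_ms must be > 0")
    offset = _half_up(offset_ms * raw.fs / 1000.0)
    n = _half_up(length_ms * raw.fs / 1000.0)
    segments = []
    skipped = 0
    for r in peaks.indices:
        start = int(r) + offset
        if start + n <= len(raw):
            segments.append(STSegment(start, raw.samples[start : start + n]))
        else:
            skipped += 1
    if skipped:
        logger.info("skipped %d peak(s) too close to the signal end", skipped)
    return segments


def compute_st_slope(segment: STSegment) -> float:
    """Slope tan θ = (X - Y) / N for one segment (units/sample)."""
    if segment.n < 2:
        raise InvalidInputError("segment must contain at least 2 samples")
    return float((segment.samples[-1] - segment.samples[0]) / segment.n)


def summarize_slopes(slopes, method: str = "mean") -> STSlope:
    """Aggregate per-beat slopes into a single per-recording value."""
    per_beat = np.asarray(list(slopes), dtype=float)
    if per_beat.size == 0:
        raise InvalidInputError("no ST segments to summarize")
    if method == "mean":
        value = float(np.mean(per_beat))
    elif method == "median":
        value = float(np.median(per_beat))
    else:
        raise InvalidInputError(f"unknown summary method {method!r}")
    return STSlope(per_beat=per_beat, summary=value, method=method)


def categorize_slope(tan_theta: float, flat_band: float = FLAT_SLOPE_BAND) -> int:
    """Map a continuous slope onto the ordinal attribute.

    1 = upsloping, 2 = flat, 3 = downsloping; the flat band is
    ``|tan θ| <= flat_band`` on normalized signals.
    """
    if not np.isfinite(tan_theta):
        raise InvalidInputError("slope must be finite")
    if tan_theta > flat_band:
        return 1
    if tan_theta < -flat_band:
        return 3
    return 2


def compute_thalach(
    pulse_readings,
    strict: bool = True,
    valid_range: tuple[float, float] = (30.0, 250.0),
) -> float:
    """Maximum of exactly 20 consecutive pulse-rate readings (bpm).

    Out-of-range readings raise when ``strict``; otherwise they are clamped
    into ``valid_range`` with a warning.
    """
    readings = np.asarray(list(pulse_readings), dtype=float)
    if readings.size != 20:
        raise InvalidInputError(
            f"exactly 20 pulse readings are required, got {readings.size}"
        )
    lo, hi = valid_range
    bad = (readings < lo) | (readings > hi)
    if np.any(bad):
        if strict:
            raise InvalidInputError(
                f"{int(bad.sum())} pulse reading(s) outside [{lo}, {hi}] bpm"
            )
        warnings.warn(
            f"clamping {int(bad.sum())} pulse reading(s) into [{lo}, {hi}] bpm",
            stacklevel=2,
        )
        readings = np.clip(readings, lo, hi)
    return float(np.max(readings))


# ---------------------------------------------------------------------------
# Feature-completion models
# ---------------------------------------------------------------------------

def _select_by_correlation(
    table: pd.DataFrame, target: str, threshold: float, exclude=()
) -> list[str]:
    candidates = [
        c for c in table.columns
        if c != target and c not in exclude and pd.api.types.is_numeric_dtype(table[c])
    ]
    corr = {}
    for c in candidates:
        r = table[c].corr(table[target])
        corr[c] = 0.0 if pd.isna(r) else float(r)
    selected = [c for c in candidates if abs(corr[c]) >= threshold]
    if not selected:
        raise ConfigurationError(
            f"no feature reaches |r| >= {threshold} with {target!r}; "
            f"correlations: { {k: round(v, 3) for k, v in corr.items()} }"
        )
    return selected


@dataclass
class OldpeakModel:
    """SVR-based oldpeak completion with correlation feature selection."""

    features: list[str]
    _svr: SVR = field(repr=False)
    clip_range: tuple[float, float] = OLDPEAK_RANGE

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in records.columns]
        if missing:
            raise InvalidInputError(f"records lack selected predictor(s): {missing}")
        raw = self._svr.predict(records[self.features].to_numpy(dtype=float))
        return np.clip(raw, *self.clip_range)


def fit_oldpeak_regressor(
    table: pd.DataFrame,
    correlation_threshold: float = 0.2,
    exclude=("num", "zone"),
    **svr_params,
) -> OldpeakModel:
    """Select |r|-correlated predictors and fit an SVR for oldpeak.

    Predictions are clipped to the overlap of the observed training range
    and the attribute's hard 0–6.2 domain.
    """
    if "oldpeak" not in table.columns:
        raise InvalidInputError("table must contain an 'oldpeak' column")
    data = table.dropna(subset=["oldpeak"])
    features = _select_by_correlation(
        data, "oldpeak", correlation_threshold, exclude=exclude
    )
    svr = SVR(**svr_params)
    svr.fit(data[features].to_numpy(dtype=float), data["oldpeak"].to_numpy(dtype=float))
    lo = max(OLDPEAK_RANGE[0], float(data["oldpeak"].min()))
    hi = min(OLDPEAK_RANGE[1], float(data["oldpeak"].max()))
    return OldpeakModel(features=features, _svr=svr, clip_range=(lo, hi))


@dataclass
class RestecgModel:
    """SVC-based resting-ECG-class completion; output domain {0, 1, 2}."""

    features: list[str]
    _svc: SVC = field(repr=False)

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in records.columns]
        if missing:
            raise InvalidInputError(f"records lack selected predictor(s): {missing}")
        pred = self._svc.predict(records[self.features].to_numpy(dtype=float))
        return pred.astype(int)


def fit_restecg_classifier(
    table: pd.DataFrame,
    correlation_threshold: float = 0.2,
    exclude=("num", "zone"),
    **svc_params,
) -> RestecgModel:
    """Select correlated predictors and fit an SVC for restecg."""
    if "restecg" not in table.columns:
        raise InvalidInputError("table must contain a 'restecg' column")
    data = table.dropna(subset=["restecg"])
    labels = data["restecg"].astype(int)
    if not set(labels.unique()) <= set(RESTECG_DOMAIN):
        raise InvalidInputError(
            f"restecg labels must lie in {RESTECG_DOMAIN}, "
            f"got {sorted(labels.unique())}"
        )
    if labels.nunique() < 2:
        raise InvalidInputError("restecg training labels contain a single class")
    features = _select_by_correlation(
        data, "restecg", correlation_threshold, exclude=exclude
    )
    svc = SVC(**svc_params)
    svc.fit(data[features].to_numpy(dtype=float), labels.to_numpy())
    return RestecgModel(features=features, _svc=svc)
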