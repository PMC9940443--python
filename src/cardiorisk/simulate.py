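"""Synthetic ECG signals and patient cohorts with known ground truth.

Both generators are pure functions of their parameter tuples (seed
included), so fixtures regenerate bit-identically.

The ECG generator sums per-beat Gaussian bumps for the P, Q, R, S and T
waves at fixed fractional offsets of the RR interval, overlays a linear
ramp of configurable slope across the 57–177 ms post-R window (the ST
segment), and adds white noise.  It emits the true R-peak indices and the
injected per-beat ST slope, which makes QRS detection and slope
measurement testable in closed form.  It is deliberately not a
dynamical-system ECG model: no arrhythmias, electrode-motion artifacts or
device noise spectra.

The cohort generator draws zone/severity labels and then features from
class-conditional distributions shaped like the clinical table: continuous
attributes are truncated normals whose class means are separated by a
configurable number of pooled standard deviations; categoricals are
class-tilted multinomials over their domains.  Missingness is
missing-completely-at-random by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecg import ECGSignal
from .errors import InvalidInputError
from .preprocess import (
    CATEGORICAL_DOMAINS,
    CONTINUOUS_RANGES,
    FEATURE_COLUMNS,
    TARGET_COLUMN,
    FeatureTable,
)

#: ST ramp window after each R peak, milliseconds (matches the default
#: ST-segment window: 20–62 samples post-R at 350 Hz).
ST_RAMP_START_MS = 57.14
ST_RAMP_END_MS = 177.14

#: (fractional RR offset, amplitude, fractional RR sigma) per wave.
_WAVES = (
    (-0.22, 0.12, 0.025),   # P
    (-0.03, -0.12, 0.008),  # Q
    (0.00, 1.00, 0.012),    # R
    (0.03, -0.15, 0.008),   # S
    (0.32, 0.28, 0.045),    # T
)

#: Class proportions of the three-zone tally (413/258/249 of 920).
DEFAULT_PROPORTIONS_THREE = (413 / 920, 258 / 920, 249 / 920)
DEFAULT_PROPORTIONS_TWO = (413 / 920, 507 / 920)

#: Marginal mean/SD of the continuous attributes, with the direction in
#: which each shifts as severity rises (thalach falls with risk).
_CONTINUOUS_PROFILE = {
    "age": (54.0, 9.0, +1.0),
    "trestbps": (131.3, 17.9, +1.0),
    "chol": (249.7, 51.7, +1.0),
    "thalach": (149.7, 23.2, -1.0),
    "oldpeak": (1.05, 1.14, +1.0),
}

#: Healthy vs diseased category distributions for each categorical.
_CATEGORICAL_PROFILE = {
    "sex": ((0.55, 0.45), (0.25, 0.75)),
    "cp": ((0.30, 0.35, 0.25, 0.10), (0.05, 0.10, 0.15, 0.70)),
    "fbs": ((0.90, 0.10), (0.75, 0.25)),
    "restecg": ((0.70, 0.15, 0.15), (0.35, 0.30, 0.35)),
    "exang": ((0.85, 0.15), (0.35, 0.65)),
    "slope": ((0.55, 0.35, 0.10), (0.15, 0.50, 0.35)),
}


@dataclass(frozen=True)
class ECGFixture:
    """A simulated ECG with its ground truth."""

    signal: ECGSignal
    true_r_indices: np.ndarray
    true_st_slope: np.ndarray
    params: dict


@dataclass(frozen=True)
class CohortFixture:
    """A simulated patient table with its generating parameters."""

    table: FeatureTable
    params: dict


def simulate_ecg(
    fs: float = 350.0,
    duration: float = 10.0,
    hr_bpm: float = 60.0,
    st_slope: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ECGFixture:
    """Generate a PQRST waveform with a known ST ramp.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz, >= 100.
    duration : float
        Signal length in seconds, >= 2.
    hr_bpm : float
        Heart rate, 30–220 bpm; beats are strictly periodic.
    st_slope : float
        Linear ramp slope in amplitude-units per sample injected across the
        57–177 ms post-R window.
    noise_sd : float
        White-noise standard deviation in amplitude units (R amplitude 1).
    """
    if fs < 100:
        raise InvalidInputError("fs must be >= 100 Hz")
    if duration < 2:
        raise InvalidInputError("duration must be >= 2 s")
    if not 30 <= hr_bpm <= 220:
        raise InvalidInputError("hr_bpm must be in [30, 220]")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")

    n = int(round(duration * fs))
    rr = fs * 60.0 / hr_bpm  # samples per beat
    x = np.zeros(n)
    idx = np.arange(n, dtype=float)

    ramp_start = int(np.floor(ST_RAMP_START_MS * fs / 1000.0 + 0.5))
    ramp_len = int(np.floor((ST_RAMP_END_MS - ST_RAMP_START_MS) * fs / 1000.0 + 0.5))

    r_centers = np.arange(rr / 2.0, n, rr)
    r_indices = []
    for c in r_centers:
        for frac, amp, sig_frac in _WAVES:
            center = c + frac * rr
            sigma = sig_frac * rr
            lo = max(0, int(center - 6 * sigma))
            hi = min(n, int(center + 6 * sigma) + 1)
            if lo < hi:
                x[lo:hi] += amp * np.exp(
                    -0.5 * ((idx[lo:hi] - center) / sigma) ** 2
                )
        r = int(round(c))
        if r < n:
            r_indices.append(r)
            s0 = r + ramp_start
            s1 = min(n, s0 + ramp_len + 1)
            if s0 < n:
                x[s0:s1] += st_slope * np.arange(s1 - s0)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)

    r_indices = np.array(r_indices, dtype=int)
    return ECGFixture(
        signal=ECGSignal(x, fs, "raw"),
        true_r_indices=r_indices,
        true_st_slope=np.full(r_indices.size, float(st_slope)),
        params={
            "fs": fs, "duration": duration, "hr_bpm": hr_bpm,
            "st_slope": st_slope, "noise_sd": noise_sd, "seed": seed,
        },
    )


def _class_proportions_default(n_classes: int):
    if n_classes == 3:
        return DEFAULT_PROPORTIONS_THREE
    if n_classes == 2:
        return (413 / 920, 507 / 920)
    raise InvalidInputError("provide class_proportions for this class count")


def simulate_cohort(
    n: int = 920,
    class_proportions=DEFAULT_PROPORTIONS_THREE,
    effect_size: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    mechanism: str = "mcar",
) -> CohortFixture:
    """Generate a labeled patient table with known class structure.

    Parameters
    ----------
    n : int
        Number of records.
    class_proportions : sequence of float
        Must sum to 1; class k receives the severity label ``num = k``.
    effect_size : float
        Separation between adjacent class means in pooled SDs for the
        continuous attributes; also tilts the categorical distributions
        (0 = no class signal, ~3 = clearly separable).
    missing_rate : float
        Fraction of feature cells masked, 0 <= rate < 0.5.  Exact count,
        never leaving a column fully missing.
    mechanism : str
        ``mcar`` (default) or ``mar`` (mask probability rises with age).
    """
    props = np.asarray(class_proportions, dtype=float)
    if props.ndim != 1 or props.size < 2 or np.any(props <= 0):
        raise InvalidInputError("class_proportions must be >= 2 positive values")
    if not np.isclose(props.sum(), 1.0, atol=1e-8):
        raise InvalidInputError("class_proportions must sum to 1")
    if not 0 <= missing_rate < 0.5:
        raise InvalidInputError("missing_rate must be in [0, 0.5)")
    if mechanism not in ("mcar", "mar"):
        raise InvalidInputError("mechanism must be 'mcar' or 'mar'")
    if n < props.size:
        raise InvalidInputError("n must be at least the number of classes")

    rng = np.random.default_rng(seed)
    k = props.size
    labels = rng.choice(k, size=n, p=props)

    data = {}
    centered = labels - (k - 1) / 2.0
    for col in FEATURE_COLUMNS:
        if col in _CONTINUOUS_PROFILE:
            mean, sd, direction = _CONTINUOUS_PROFILE[col]
            mu = mean + direction * effect_size * sd * centered
            vals = rng.normal(mu, sd)
            lo, hi = CONTINUOUS_RANGES[col]
            vals = np.clip(vals, lo, hi)
            if col != "oldpeak":
                vals = np.round(vals)
            else:
                vals = np.round(vals, 1)
            data[col] = vals
        else:
            healthy, sick = _CATEGORICAL_PROFILE[col]
            healthy = np.asarray(healthy)
            sick = np.asarray(sick)
            domain = np.asarray(CATEGORICAL_DOMAINS[col])
            # mixing weight grows with severity and effect size
            w = (labels / (k - 1)) * min(1.0, effect_size / 3.0)
            probs = (1 - w)[:, None] * healthy[None, :] + w[:, None] * sick[None, :]
            cum = np.cumsum(probs, axis=1)
            u = rng.random(n)
            picks = (u[:, None] > cum).sum(axis=1)
            data[col] = domain[picks].astype(float)

    df = pd.DataFrame(data, columns=list(FEATURE_COLUMNS))
    df[TARGET_COLUMN] = labels.astype(float)

    if missing_rate > 0:
        feat = df[list(FEATURE_COLUMNS)].to_numpy()
        n_cells = feat.size
        n_mask = int(round(missing_rate * n_cells))
        if mechanism == "mcar":
            weights = np.ones(n)
        else:
            age = df["age"].to_numpy()
            weights = 1.0 + (age - age.min()) / max(1e-9, age.max() - age.min())
        cell_w = np.repeat(weights, len(FEATURE_COLUMNS))
        cell_w = cell_w / cell_w.sum()
        flat = rng.choice(n_cells, size=n_mask, replace=False, p=cell_w)
        mask = np.zeros(n_cells, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(feat.shape)
        # never blank out a whole column
        for j in range(mask.shape[1]):
            if mask[:, j].all():
                mask[rng.integers(0, n), j] = False
        feat[mask] = np.nan
        df[list(FEATURE_COLUMNS)] = feat

    table = FeatureTable(df, "raw")
    return CohortFixture(
        table=table,
        params={
            "n": n, "class_proportions": tuple(props.tolist()),
            "effect_size": effect_size, "missing_rate": missing_rate,
            "seed": seed, "mechanism": mechanism,
        },
    )
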