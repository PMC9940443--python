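"""Pan-Tompkins preprocessing chain and R-peak detection.

Single-channel ECG processing: cascaded low-pass and high-pass filters,
five-point derivative, squaring, 150 ms moving-window integration, and
adaptive-threshold QRS detection with delay compensation back onto the raw
signal.  Two coefficient sets are available for the recursive stages:

``canonical``
    The standard Pan-Tompkins difference equations (default).
``paper``
    A variant sign pattern for the high-pass and derivative stages that
    circulates in some transcriptions; kept selectable so both are testable.

All filters are causal with zero initial state; out-of-range history terms
are zero, so transients settle only after the filter memory fills.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

#: Stage order the chain is allowed to traverse.
STAGES = ("raw", "lowpass", "bandpass", "derivative", "squared", "integrated")

#: Default refractory interval between beats, milliseconds.
REFRACTORY_MS = 200.0

#: Native design rate of the integer-coefficient filters, Hz.
DESIGN_FS = 200.0


@dataclass(frozen=True)
class ECGSignal:
    """An amplitude series with its sampling rate and provenance stage.

    Parameters
    ----------
    samples : array-like of float
        Amplitudes in arbitrary units (mV or ADC counts).
    fs : float
        Sampling rate in Hz, > 0.
    stage : str
        Where in the processing chain the signal sits; one of `STAGES`.
    """

    samples: np.ndarray
    fs: float
    stage: str = "raw"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise InvalidInputError("signal must be a non-empty 1-D series")
        if not np.all(np.isfinite(samples)):
            raise InvalidInputError("signal contains non-finite samples")
        if not self.fs > 0:
            raise InvalidInputError(f"sampling rate must be > 0, got {self.fs}")
        if self.stage not in STAGES:
            raise InvalidInputError(f"unknown stage {self.stage!r}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based index / fs)."""
        return np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class RPeakSet:
    """Detected R-peak sample indices on the raw-signal timeline."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise InvalidInputError("peak indices must be 1-D")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise InvalidInputError("peak indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise InvalidInputError("peak indices must be non-negative")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times(self) -> np.ndarray:
        return self.indices / self.fs


# ---------------------------------------------------------------------------
# Filter coefficient sets (b, a) for scipy.signal.lfilter
# ---------------------------------------------------------------------------

def _lowpass_ba() -> tuple[np.ndarray, np.ndarray]:
    # y(n) = 2y(n-1) - y(n-2) + x(n) - 2x(n-6) + x(n-12)
    b = np.zeros(13)
    b[0], b[6], b[12] = 1.0, -2.0, 1.0
    a = np.array([1.0, -2.0, 1.0])
    return b, a


def _highpass_ba(coeffs: str) -> tuple[np.ndarray, np.ndarray]:
    b = np.zeros(33)
    if coeffs == "canonical":
        # y(n) = y(n-1) - x(n)/32 + x(n-16) - x(n-17) + x(n-32)/32
        b[0], b[16], b[17], b[32] = -1 / 32, 1.0, -1.0, 1 / 32
    else:
        # variant sign pattern: y(n) = y(n-1) - x(n)/32 - x(n-16) - x(n-17)
        #                              + x(n-32)/32
        b[0], b[16], b[17], b[32] = -1 / 32, -1.0, -1.0, 1 / 32
    a = np.array([1.0, -1.0])
    return b, a


def _derivative_ba(coeffs: str) -> tuple[np.ndarray, np.ndarray]:
    if coeffs == "canonical":
        # y(n) = (1/8)[2x(n) + x(n-1) - x(n-3) - 2x(n-4)]
        b = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0
    else:
        # variant: y(n) = (1/8)[2x(n) - x(n-1) - x(n-3) + 2x(n-4)]
        b = np.array([2.0, -1.0, 0.0, -1.0, 2.0]) / 8.0
    a = np.array([1.0])
    return b, a


def _check_coeffs(coeffs: str) -> None:
    if coeffs not in ("canonical", "paper"):
        raise InvalidInputError(
            f"coeffs must be 'canonical' or 'paper', got {coeffs!r}"
        )


def _apply(sig: ECGSignal, b, a, in_stage: str, out_stage: str) -> ECGSignal:
    if sig.stage != in_stage:
        raise InvalidInputError(
            f"expected a {in_stage!r}-stage signal, got {sig.stage!r}"
        )
    y = _sig.lfilter(b, a, sig.samples)
    return replace(sig, samples=y, stage=out_stage)


def lowpass_filter(sig: ECGSignal) -> ECGSignal:
    """Second-order recursive low-pass (cutoff ~11 Hz at the 200 Hz design
    rate, DC gain 36); input must be ``raw``."""
    if sig.fs != DESIGN_FS:
        logger.warning(
            "filter coefficients are designed for %g Hz; applying at %g Hz",
            DESIGN_FS, sig.fs,
        )
    return _apply(sig, *_lowpass_ba(), "raw", "lowpass")


def highpass_filter(sig: ECGSignal, coeffs: str = "canonical") -> ECGSignal:
    """32-tap recursive high-pass completing the band-pass; input must be
    ``lowpass``.  DC gain is 0 for the canonical coefficient set."""
    _check_coeffs(coeffs)
    return _apply(sig, *_highpass_ba(coeffs), "lowpass", "bandpass")


def derivative_filter(sig: ECGSignal, coeffs: str = "canonical") -> ECGSignal:
    """Five-point derivative emphasising QRS slope; input must be
    ``bandpass``."""
    _check_coeffs(coeffs)
    return _apply(sig, *_derivative_ba(coeffs), "bandpass", "derivative")


def square_signal(sig: ECGSignal) -> ECGSignal:
    """Element-wise squaring to magnify dominant R-peaks; input must be
    ``derivative``."""
    if sig.stage != "derivative":
        raise InvalidInputError(
            f"expected a 'derivative'-stage signal, got {sig.stage!r}"
        )
    return replace(sig, samples=sig.samples ** 2, stage="squared")


def integration_window_samples(window_ms: float, fs: float) -> int:
    """Window length W = floor(window_ms * fs / 1000 + 0.5) (half-up)."""
    if window_ms <= 0:
        raise InvalidInputError("window_ms must be > 0")
    return int(np.floor(window_ms * fs / 1000.0 + 0.5))


def moving_window_integrate(sig: ECGSignal, window_ms: float = 150.0) -> ECGSignal:
    """Causal moving average over a 150 ms window (53 samples at 350 Hz);
    input must be ``squared``."""
    if sig.stage != "squared":
        raise InvalidInputError(
            f"expected a 'squared'-stage signal, got {sig.stage!r}"
        )
    w = integration_window_samples(window_ms, sig.fs)
    if w > len(sig):
        raise InvalidInputError(
            f"integration window ({w} samples) exceeds signal length {len(sig)}"
        )
    y = _sig.lfilter(np.full(w, 1.0 / w), [1.0], sig.samples)
    return replace(sig, samples=y, stage="integrated")


def preprocess_chain(
    raw: ECGSignal, window_ms: float = 150.0, coeffs: str = "canonical"
) -> ECGSignal:
    """Run lowpass -> highpass -> derivative -> square -> integrate."""
    y = lowpass_filter(raw)
    y = highpass_filter(y, coeffs)
    y = derivative_filter(y, coeffs)
    y = square_signal(y)
    return moving_window_integrate(y, window_ms)


def chain_group_delay(window_ms: float, fs: float) -> int:
    """Cumulative group delay of the linear stages in samples.

    Low-pass contributes 5, high-pass 16, derivative 2, and the integration
    window (W - 1) / 2.
    """
    w = integration_window_samples(window_ms, fs)
    return int(round(5 + 16 + 2 + (w - 1) / 2))


def detect_r_peaks(
    raw: ECGSignal,
    window_ms: float = 150.0,
    coeffs: str = "canonical",
    refractory_ms: float = REFRACTORY_MS,
    init_span_s: float = 2.0,
) -> RPeakSet:
    """Detect R-peaks with the full Pan-Tompkins chain.

    Candidate peaks are local maxima of the integrated signal classified by
    an adaptive two-level threshold T = N + 0.25 (S - N), where the
    signal-level estimate S starts at the maximum and the noise-level
    estimate N at the mean of the integrated signal over the first
    ``init_span_s`` seconds; accepted (rejected) peaks update S (N) with the
    usual 1/8 running average.  Accepted candidates at least one refractory
    interval apart are mapped back to the raw timeline by searching for the
    raw local maximum in a delay-compensated window.

    Returns an empty `RPeakSet` when nothing crosses threshold.
    """
    if raw.stage != "raw":
        raise InvalidInputError(f"expected a 'raw'-stage signal, got {raw.stage!r}")
    n_init = int(round(init_span_s * raw.fs))
    if len(raw) < n_init:
        raise InvalidInputError(
            f"signal too short for threshold initialization "
            f"({len(raw)} < {n_init} samples)"
        )
    integ = preprocess_chain(raw, window_ms, coeffs).samples
    refr = max(1, int(round(refractory_ms * raw.fs / 1000.0)))

    cand, _ = _sig.find_peaks(integ, distance=refr)
    s_level = float(np.max(integ[:n_init]))
    n_level = float(np.mean(integ[:n_init]))

    delay = chain_group_delay(window_ms, raw.fs)
    search_back = delay + int(round(0.060 * raw.fs))
    x = raw.samples

    accepted: list[int] = []
    for p in cand:
        thr = n_level + 0.25 * (s_level - n_level)
        if integ[p] > thr:
            s_level = 0.125 * integ[p] + 0.875 * s_level
            lo = max(0, p - search_back)
            r = lo + int(np.argmax(x[lo : p + 1]))
            if accepted and r - accepted[-1] < refr:
                # two candidates refined to the same neighbourhood: keep the
                # taller raw deflection
                if x[r] > x[accepted[-1]]:
                    accepted[-1] = r
            else:
                accepted.append(r)
        else:
            n_level = 0.125 * integ[p] + 0.875 * n_level

    return RPeakSet(np.array(sorted(set(accepted)), dtype=int), raw.fs)
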