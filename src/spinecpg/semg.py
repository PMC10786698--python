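"""Surface-EMG preprocessing and descriptive left-right activity metrics.

Recordings are four named channels — a left/right paraspinal recording pair
and a left/right upper-thoracic reference pair — sampled at 2000 Hz with
hardware gain 1000 and an analog band of 15-1000 Hz. Preprocessing applies a
zero-phase Butterworth band-pass (the upper edge clipped below Nyquist) and
removes the per-channel mean. ECG contamination is removed by
reference-guided template subtraction: beats are detected on the reference
channel, a beat template is estimated from the contaminated signal at those
lags, and a per-beat least-squares-scaled copy is subtracted. Standing
recordings are normalized by the RMS of the same channel during voluntary
trunk bending toward that channel's side, making channels comparable across
electrode placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from ._util import mad_sigma, rms
from .errors import ParameterError

DEFAULT_BAND = (15.0, 1000.0)
POSTURES = ("standing", "bend_left", "bend_right")


@dataclass
class SemgRecording:
    """Named equal-length channels plus acquisition metadata.

    Channel names start with their side, e.g. ``left_rec``, ``right_ref``.
    """

    channels: dict[str, np.ndarray]
    fs: float
    gain: float = 1000.0
    posture: str = "standing"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if not self.channels:
            raise ParameterError("recording has no channels")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {v.size for v in self.channels.values()}
        if len(lengths) != 1:
            raise ParameterError("all channels must have equal length")
        if 0 in lengths:
            raise ParameterError("channels are empty")
        if self.posture not in POSTURES:
            raise ParameterError(f"posture must be one of {POSTURES}")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def side_of(self, channel: str) -> str:
        side = channel.split("_")[0]
        if side not in ("left", "right"):
            raise ParameterError(f"cannot infer side of channel {channel!r}")
        return side


def preprocess(rec: SemgRecording, band: tuple[float, float] = DEFAULT_BAND,
               order: int = 4) -> SemgRecording:
    """Zero-phase Butterworth band-pass then per-channel mean removal.

    The upper band edge is clipped to 0.45*fs so the filter is realizable
    when the nominal band touches Nyquist (1000 Hz at fs = 2000 Hz).
    """
    low, high = band
    if low >= high:
        raise ParameterError("band is inverted")
    if rec.fs <= 2.0 * low:
        raise ParameterError("sampling rate too low for the requested band")
    high = min(high, 0.45 * rec.fs)
    sos = butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = {}
    for name, x in rec.channels.items():
        y = sosfiltfilt(sos, x)
        out[name] = y - y.mean()
    return replace(rec, channels=out)


@dataclass
class ECGRemovalResult:
    signal: np.ndarray
    applied: bool
    n_beats: int
    beat_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def remove_ecg(signal: np.ndarray, reference: np.ndarray, fs: float,
               min_rr_s: float = 0.4, rr_cv_max: float = 0.25) -> ECGRemovalResult:
    """Reference-guided ECG template subtraction.

    Beats are detected as prominent peaks of the reference channel with a
    physiological minimum RR interval. If fewer than 3 beats are found, or
    the RR intervals are too irregular (CV > ``rr_cv_max``), no detectable
    periodicity is assumed and the input is returned unchanged with
    ``applied=False``. Otherwise the beat template is the beat-locked mean
    segment of the *reference* channel (where EMG contamination is low, so
    the template is nearly clean ECG), each beat's lag in the signal is
    refined by maximizing correlation with the template (EMG noise jitters
    the detected peak by several samples, which would otherwise smear the
    subtraction), and a least-squares-scaled copy of the template is
    subtracted per beat; the scalar fit can only decrease each segment's
    energy, so template-free input is never inflated.
    """
    x = np.asarray(signal, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.size != ref.size:
        raise ParameterError("signal and reference must have equal length")
    not_applied = ECGRemovalResult(signal=x.copy(), applied=False, n_beats=0)
    if not np.any(ref != 0):
        return not_applied
    sigma = mad_sigma(ref)
    height = max(3.0 * sigma, 0.4 * ref.max())
    peaks, _ = find_peaks(ref, height=height, distance=max(1, int(round(min_rr_s * fs))))
    if len(peaks) < 3:
        return not_applied
    rr = np.diff(peaks)
    if rr.std() / rr.mean() > rr_cv_max:
        return not_applied
    half = int(min(0.45 * np.median(rr), round(0.30 * fs)))
    max_shift = int(round(0.02 * fs))
    full = peaks[(peaks - half - max_shift >= 0)
                 & (peaks + half + max_shift < x.size)]
    if len(full) < 3:
        return not_applied

    template = np.stack([ref[p - half:p + half] for p in full]).mean(axis=0)
    denom_full = float(template @ template)
    if denom_full == 0:
        return not_applied
    cleaned = x.copy()
    shifts = np.arange(-max_shift, max_shift + 1)
    refined = []
    for p in peaks:
        # refine the lag in the signal, truncating windows at the edges
        best_s, best_corr = 0, -np.inf
        for s in shifts:
            lo, hi = max(0, p + s - half), min(x.size, p + s + half)
            tmpl = template[(lo - (p + s - half)):(hi - (p + s - half))]
            c = float(x[lo:hi] @ tmpl)
            if c > best_corr:
                best_corr, best_s = c, int(s)
        q = p + best_s
        lo, hi = max(0, q - half), min(x.size, q + half)
        tmpl = template[(lo - (q - half)):(hi - (q - half))]
        denom = float(tmpl @ tmpl)
        if denom == 0:
            continue
        seg = cleaned[lo:hi]
        a = float(seg @ tmpl) / denom
        cleaned[lo:hi] = seg - a * tmpl
        refined.append(q)
    refined = np.asarray(refined, dtype=int)
    return ECGRemovalResult(signal=cleaned, applied=True, n_beats=int(len(refined)),
                            beat_indices=refined)


def remove_ecg_recording(rec: SemgRecording, **kwargs) -> SemgRecording:
    """Apply :func:`remove_ecg` to each recording channel using the same
    side's reference channel."""
    out = dict(rec.channels)
    for name in rec.channels:
        if not name.endswith("_rec"):
            continue
        ref_name = name.replace("_rec", "_ref")
        if ref_name not in rec.channels:
            raise ParameterError(f"no reference channel for {name!r}")
        out[name] = remove_ecg(rec.channels[name], rec.channels[ref_name],
                               rec.fs, **kwargs).signal
    return replace(rec, channels=out)


def bending_normalize(standing: SemgRecording, bend_left: SemgRecording,
                      bend_right: SemgRecording) -> dict[str, np.ndarray]:
    """Divide each standing channel by the RMS of the same channel in the
    bending recording of that channel's side; output is dimensionless."""
    bend = {"left": bend_left, "right": bend_right}
    out = {}
    for name, x in standing.channels.items():
        side = standing.side_of(name)
        ref = bend[side].channels.get(name)
        if ref is None:
            raise ParameterError(f"bending recording lacks channel {name!r}")
        denom = rms(ref)
        if denom == 0:
            raise ParameterError(f"zero bending RMS for channel {name!r}")
        out[name] = x / denom
    return out


@dataclass
class BurstSummary:
    burst_count: int
    burst_fraction: float
    n_windows: int
    window_rms_median: float


def burst_metrics(signal: np.ndarray, fs: float, window_s: float = 0.25,
                  burst_k: float = 3.0) -> BurstSummary:
    """Windowed burst detection on one preprocessed channel.

    The signal is cut into consecutive non-overlapping windows; a window is a
    burst when its RMS exceeds ``burst_k`` times the median window RMS. A
    stationary signal yields a burst fraction near zero; irregular bursts
    (the aberrant-activity signature) inflate it. Exploratory metric — an
    explicit operationalization, not a clinically validated one.
    """
    x = np.asarray(signal, dtype=float)
    win = int(round(window_s * fs))
    if win < 1 or win > x.size:
        raise ParameterError("window must be >= 1 sample and <= signal length")
    n_win = x.size // win
    w = x[: n_win * win].reshape(n_win, win)
    window_rms = np.sqrt(np.mean(w**2, axis=1))
    med = float(np.median(window_rms))
    flags = window_rms > burst_k * med
    return BurstSummary(burst_count=int(flags.sum()),
                        burst_fraction=float(flags.mean()),
                        n_windows=n_win, window_rms_median=med)


@dataclass
class SemgMetrics:
    rms_left: float
    rms_right: float
    lr_rms_ratio: float
    bursts_left: BurstSummary
    bursts_right: BurstSummary


def semg_metrics(rec: SemgRecording, window_s: float = 0.25,
                 burst_k: float = 3.0) -> SemgMetrics:
    """Descriptive left-right metrics of a preprocessed recording pair."""
    left = rec.channels.get("left_rec")
    right = rec.channels.get("right_rec")
    if left is None or right is None:
        raise ParameterError("recording needs left_rec and right_rec channels")
    rl, rr = rms(left), rms(right)
    if rr == 0:
        raise ParameterError("right-side RMS is zero; ratio undefined")
    return SemgMetrics(
        rms_left=rl, rms_right=rr, lr_rms_ratio=rl / rr,
        bursts_left=burst_metrics(left, rec.fs, window_s, burst_k),
        bursts_right=burst_metrics(right, rec.fs, window_s, burst_k),
    )
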