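"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the analyses assume —
antiphase-coupled bilateral calcium event trains, curved fish midlines of
known θ, binomial carrier sampling at stated allele frequencies, multichannel
sEMG with an injected ECG artifact, and uptake-assay plates — so the whole
pipeline is exercisable and testable with no external data. All randomness
flows from one explicit seed per call; equal seeds give identical output.

Event laterality follows a Bernoulli switching process: each event occurs on
the opposite side from the previous one with probability ``switch_prob``, so
the expected left-right alternation index of the ground-truth train equals
``switch_prob`` — an analytic recovery target for the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import ParameterError
from .morpho import BodyAxis
from .neural import EVENT_COLUMNS, BilateralTraceSet, EventTrain
from .semg import SemgRecording
from .uptake import UptakePlate


# ---------------------------------------------------------------------------
# Bilateral calcium traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPGSimParams:
    """Parameters of the bilateral event-train and trace generator.

    event_rate : expected events/s for the whole fish (renewal process with
        refractory gap ``refractory_s`` plus an exponential tail whose mean is
        chosen so the realized rate equals ``event_rate``).
    switch_prob : probability that each event occurs on the opposite side
        from the previous one.
    kernel_tau_rise, kernel_tau_decay : s; double-exponential calcium
        transient, normalized to unit peak.
    amplitude_mean, amplitude_cv : per-event ΔF peak amplitude distribution.
    baseline_level, baseline_drift_slope, noise_sd : fluorescence background.
    """

    event_rate: float = 0.2
    switch_prob: float = 0.85
    kernel_tau_rise: float = 0.2
    kernel_tau_decay: float = 1.5
    amplitude_mean: float = 30.0
    amplitude_cv: float = 0.15
    baseline_level: float = 100.0
    baseline_drift_slope: float = 0.1
    noise_sd: float = 1.0
    fps: float = 10.0
    duration: float = 60.0
    n_rois_per_side: int = 2
    refractory_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ParameterError("switch_prob must be in [0, 1]")
        if self.fps <= 0 or self.duration <= 0:
            raise ParameterError("fps and duration must be positive")
        if self.kernel_tau_rise <= 0 or self.kernel_tau_decay <= 0:
            raise ParameterError("kernel time constants must be positive")
        if self.kernel_tau_rise >= self.kernel_tau_decay:
            raise ParameterError("kernel_tau_rise must be < kernel_tau_decay")
        if self.event_rate < 0:
            raise ParameterError("event_rate must be nonnegative")
        if self.event_rate > 0 and self.event_rate * self.refractory_s >= 1.0:
            raise ParameterError("event_rate incompatible with refractory gap")
        if self.noise_sd < 0 or self.amplitude_cv < 0 or self.amplitude_mean < 0:
            raise ParameterError("noise_sd, amplitude_cv, amplitude_mean must be >= 0")
        if self.n_rois_per_side < 1:
            raise ParameterError("need at least one ROI per side")


def calcium_kernel(tau_rise: float, tau_decay: float, fps: float,
                   tail: float = 1e-3) -> tuple[np.ndarray, int]:
    """Unit-peak double-exponential transient sampled at 1/fps.

    Returns (samples, peak_index); samples run from transient onset until the
    decay falls below ``tail`` of the peak.
    """
    t_peak = (tau_rise * tau_decay / (tau_decay - tau_rise)
              * np.log(tau_decay / tau_rise))
    t_end = t_peak + tau_decay * np.log(1.0 / tail)
    s = np.arange(0.0, t_end, 1.0 / fps)
    raw = np.exp(-s / tau_decay) - np.exp(-s / tau_rise)
    peak_val = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    k = raw / peak_val
    return k, int(np.argmax(k))


def draw_event_train(params: CPGSimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Event times, sides, and amplitudes of the Bernoulli-switching renewal
    process (ground truth, before rendering into traces)."""
    times = []
    if params.event_rate > 0:
        mean_tail = 1.0 / params.event_rate - params.refractory_s
        t = 0.0
        while True:
            t += params.refractory_s + rng.exponential(mean_tail)
            if t >= params.duration:
                break
            times.append(t)
    n = len(times)
    sides = []
    if n:
        side = "left" if rng.random() < 0.5 else "right"
        sides.append(side)
        flips = rng.random(n - 1) < params.switch_prob
        for flip in flips:
            side = ({"left": "right", "right": "left"}[side] if flip else side)
            sides.append(side)
    if params.amplitude_cv > 0:
        amps = rng.normal(params.amplitude_mean,
                          params.amplitude_cv * params.amplitude_mean, n)
        amps = np.clip(amps, 0.05 * params.amplitude_mean, None)
    else:
        amps = np.full(n, params.amplitude_mean)
    return pd.DataFrame({
        "onset_time_s": np.asarray(times, dtype=float),
        "side": sides,
        "peak_amplitude": amps,
        "roi_id": None,
    }, columns=list(EVENT_COLUMNS))


def simulate_bilateral_traces(params: CPGSimParams) -> tuple[BilateralTraceSet, EventTrain]:
    """Render the event train into per-ROI fluorescence traces.

    Each trace is baseline + linear drift + the sum of unit-peak transient
    kernels scaled by event amplitude (events of the ROI's side only, shared
    CPG drive across a side's ROIs) + i.i.d. Gaussian noise. The ground-truth
    event time marks the transient onset (the kernel starts rising at that
    frame; its peak follows ~tau_rise-to-tau_decay later).
    """
    rng = np.random.default_rng(params.seed)
    events = draw_event_train(params, rng)
    n_frames = int(round(params.fps * params.duration))
    t = np.arange(n_frames) / params.fps
    kernel, _ = calcium_kernel(params.kernel_tau_rise, params.kernel_tau_decay,
                               params.fps)
    signal = {side: np.zeros(n_frames) for side in ("left", "right")}
    for _, ev in events.iterrows():
        start = int(round(ev["onset_time_s"] * params.fps))
        ks, ke = max(0, -start), min(len(kernel), n_frames - start)
        if ke > ks:
            sl = slice(start + ks, start + ke)
            signal[ev["side"]][sl] += ev["peak_amplitude"] * kernel[ks:ke]
    columns, sides = {}, {}
    for side, prefix in (("left", "L"), ("right", "R")):
        for j in range(params.n_rois_per_side):
            roi = f"{prefix}{j}"
            noise = (rng.normal(0.0, params.noise_sd, n_frames)
                     if params.noise_sd > 0 else 0.0)
            columns[roi] = (params.baseline_level
                            + params.baseline_drift_slope * t
                            + signal[side] + noise)
            sides[roi] = side
    traces = BilateralTraceSet(values=pd.DataFrame(columns), sides=sides,
                               fps=params.fps)
    return traces, EventTrain(events)


# ---------------------------------------------------------------------------
# Fish midlines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MidlineSimParams:
    """Circular-arc midline of target curvature ``theta_deg`` (central angle
    2θ), arc length ``body_length``, with optional Gaussian coordinate
    noise."""

    theta_deg: float = 0.0
    n_points: int = 51
    body_length: float = 4.0  # mm, ~7 dpf larva
    noise_sd: float = 0.0     # mm
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg < 180.0:
            raise ParameterError("theta_deg must be in [0, 180)")
        if self.n_points < 3:
            raise ParameterError("n_points must be >= 3")
        if self.body_length <= 0:
            raise ParameterError("body_length must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def simulate_midline(params: MidlineSimParams, fish_id: str | None = None,
                     genotype: str | None = None, treatment: str | None = None,
                     age_dpf: float | None = None) -> BodyAxis:
    """Ordered head→tail midline whose noise-free θ equals ``theta_deg``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_points
    if params.theta_deg == 0.0:
        x = np.linspace(0.0, params.body_length, n)
        pts = np.c_[x, np.zeros(n)]
    else:
        half = np.deg2rad(params.theta_deg)        # half the central angle
        radius = params.body_length / (2.0 * half)
        phi = np.linspace(-half, half, n)
        pts = np.c_[radius * np.sin(phi), radius * (1.0 - np.cos(phi))]
        pts -= pts[0]
    if params.noise_sd > 0:
        pts = pts + rng.normal(0.0, params.noise_sd, pts.shape)
    return BodyAxis(points=pts, fish_id=fish_id, genotype=genotype,
                    treatment=treatment, age_dpf=age_dpf)


# ---------------------------------------------------------------------------
# Cohort genotype counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimParams:
    """Binomial sampling of variant alleles in a case and a control group."""

    n_case_alleles: int = 1696
    n_control_alleles: int = 6438
    case_allele_freq: float = 0.00884
    control_allele_freq: float = 0.00109
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case_alleles <= 0 or self.n_control_alleles <= 0:
            raise ParameterError("allele counts must be positive")
        for f in (self.case_allele_freq, self.control_allele_freq):
            if not 0.0 <= f <= 1.0:
                raise ParameterError("allele frequencies must be in [0, 1]")


def simulate_cohort(params: CohortSimParams) -> tuple[CohortTable, CohortTable]:
    """Draw variant-allele counts for the case and control cohorts."""
    rng = np.random.default_rng(params.seed)
    case = CohortTable(group="case",
                       variant_alleles=int(rng.binomial(params.n_case_alleles,
                                                        params.case_allele_freq)),
                       total_alleles=params.n_case_alleles)
    control = CohortTable(group="control",
                          variant_alleles=int(rng.binomial(params.n_control_alleles,
                                                           params.control_allele_freq)),
                          total_alleles=params.n_control_alleles)
    return case, control


# ---------------------------------------------------------------------------
# sEMG
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurstSpec:
    """One-sided burst of paraspinal activity: the EMG noise of ``side``'s
    recording channel is scaled by ``gain`` under a Hann envelope."""

    side: str            # "left" or "right"
    start_s: float
    duration_s: float
    gain: float = 5.0


def ecg_template(fs: float) -> np.ndarray:
    """Stylized PQRST beat (unit R peak), 0.45 s long, sampled at ``fs``."""
    t = np.arange(0.0, 0.45, 1.0 / fs)
    qrs = (1.0 * np.exp(-((t - 0.20) / 0.012) ** 2)
           - 0.25 * np.exp(-((t - 0.165) / 0.015) ** 2)
           - 0.30 * np.exp(-((t - 0.235) / 0.015) ** 2))
    p_wave = 0.15 * np.exp(-((t - 0.08) / 0.025) ** 2)
    t_wave = 0.30 * np.exp(-((t - 0.38) / 0.035) ** 2)
    return qrs + p_wave + t_wave


def simulate_semg(duration_s: float = 5.0, fs: float = 2000.0,
                  ecg_amplitude: float = 8.0,
                  burst_spec: Sequence[BurstSpec] = (),
                  seed: int = 0, emg_sd: float = 1.0, ref_emg_sd: float = 0.3,
                  heart_rate_hz: float = 1.25,
                  posture: str = "standing") -> SemgRecording:
    """Four-channel surface-EMG recording.

    Channels ``left_rec``/``right_rec`` (paraspinal recording pair, curvature
    apex) and ``left_ref``/``right_ref`` (upper-thoracic reference pair, used
    downstream for ECG removal). A periodic ECG template is mixed into all
    channels; optional one-sided burst envelopes model irregular paraspinal
    bursts against an otherwise stationary background.
    """
    if fs <= 0 or duration_s <= 0:
        raise ParameterError("fs and duration_s must be positive")
    if heart_rate_hz <= 0 or fs < 2.0 * 40.0:
        raise ParameterError("invalid sampling setup")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    ecg = np.zeros(n)
    if ecg_amplitude > 0:
        beat = ecg_template(fs)
        period = int(round(fs / heart_rate_hz))
        for start in range(0, n, period):
            seg = beat[: n - start]
            ecg[start:start + len(seg)] += ecg_amplitude * seg

    def bandlimited(sd: float) -> np.ndarray:
        from scipy.signal import butter, sosfiltfilt
        white = rng.normal(0.0, 1.0, n)
        sos = butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
        x = sosfiltfilt(sos, white)
        return sd * x / x.std()

    channels: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        emg = bandlimited(emg_sd)
        env = np.ones(n)
        for spec in burst_spec:
            if spec.side != side:
                continue
            i0 = int(round(spec.start_s * fs))
            i1 = min(n, i0 + int(round(spec.duration_s * fs)))
            if i1 > i0:
                env[i0:i1] += (spec.gain - 1.0) * np.hanning(i1 - i0)
        channels[f"{side}_rec"] = emg * env + ecg
        channels[f"{side}_ref"] = bandlimited(ref_emg_sd) + ecg
    return SemgRecording(channels=channels, fs=fs, posture=posture)


# ---------------------------------------------------------------------------
# Uptake plates
# ---------------------------------------------------------------------------

def simulate_uptake_plate(true_rates_by_genotype: Mapping[str, float],
                          protein_mg: float = 0.05, time_min: float = 10.0,
                          noise_cv: float = 0.1, n_replicates: int = 4,
                          seed: int = 0) -> UptakePlate:
    """Per-well glycine quantities: rate · time · protein · (1 + CV noise)."""
    if protein_mg <= 0 or time_min <= 0:
        raise ParameterError("protein_mg and time_min must be positive")
    if noise_cv < 0 or n_replicates < 1:
        raise ParameterError("noise_cv must be >= 0 and n_replicates >= 1")
    if any(r < 0 for r in true_rates_by_genotype.values()):
        raise ParameterError("uptake rates must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for genotype, rate in true_rates_by_genotype.items():
        for rep in range(n_replicates):
            noise = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
            qty = max(0.0, rate * time_min * protein_mg * (1.0 + noise))
            rows.append({"well": f"W{well:03d}", "genotype": genotype,
                         "nmol": qty, "time_min": time_min,
                         "protein_mg": protein_mg, "replicate": rep})
            well += 1
    return UptakePlate(pd.DataFrame(rows))
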