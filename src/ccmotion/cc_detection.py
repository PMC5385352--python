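"""Jitter and co-confident (CC) motion detection.

The trial is segmented into stimulus half-cycles (turning point to turning
point). For each segment we count response acceleration zero crossings
(AZCs), match them to stimulus AZCs, and compute three similarity metrics
against the stimulus segment after a segment-local lag search:

* ``dT`` — |lag| maximizing the segment-local velocity cross-correlation;
* ``dV`` — RMS velocity error at that lag, relative to the stimulus RMS;
* ``dX`` — RMS position error at that lag, relative to the segment extent.

A segment is CC when it holds exactly one response AZC, that AZC matches a
stimulus AZC (it is the movement's speed peak, not corrective jitter), and
the response is similar enough to the stimulus: dV < 0.95 and dT < 0.15 s.
Response AZCs with no stimulus counterpart are jitter points; the jitter
frequency of an interval between consecutive jitter points is half its
reciprocal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .kinematics import AZCList, RegistrationResult, register, find_azc
from .stimulus import BLEND_HALF_WINDOW, SectionAnnotation
from .types import Trajectory

__all__ = [
    "DV_THRESHOLD",
    "DT_THRESHOLD",
    "UndefinedMetricsError",
    "SegmentWindow",
    "SegmentClassification",
    "JitterProfile",
    "TrialSummary",
    "TrialResult",
    "segment_by_stimulus",
    "match_azc",
    "jitter_frequency",
    "segment_metrics",
    "classify_cc",
    "cc_vector",
    "summarize_trial",
    "analyze_trial",
    "segments_to_frame",
]

#: Relative velocity error ceiling for CC classification (unitless).
DV_THRESHOLD: float = 0.95
#: Timing error ceiling for CC classification (s).
DT_THRESHOLD: float = 0.15
#: Response-to-stimulus AZC matching tolerance (s).
AZC_MATCH_TOLERANCE: float = 0.2


class UndefinedMetricsError(ValueError):
    """Segment metrics undefined (zero-variance stimulus segment)."""


@dataclass
class SegmentWindow:
    """One stimulus half-cycle window."""

    index: int
    t_start: float
    t_end: float
    frequency: float = np.nan         # Hz of the governing stimulus section
    peak_velocity: float = np.nan     # cm/s of the governing section
    section_index: int = -1

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SegmentClassification:
    """Per-half-cycle metrics and CC flag."""

    segment_index: int
    t_start: float
    t_end: float
    stimulus_frequency: float
    stimulus_peak_velocity: float
    section_index: int
    response_azc_count: int
    jitter_point_times: np.ndarray
    dX: float
    dV: float
    dT: float
    is_cc: bool | None                 # None: excluded (insufficient valid data)
    azc_matched: bool = False


@dataclass
class JitterProfile:
    """Interval frequencies between consecutive jitter points."""

    jitter_times: np.ndarray
    interval_frequencies: np.ndarray   # 0.5 / interval, Hz
    peak_jitter_frequency: float       # NaN when < 2 jitter points


@dataclass
class TrialSummary:
    percent_cc: float
    dX_mean: float
    dV_mean: float
    dT_mean: float
    peak_jitter_frequency: float
    n_segments: int
    n_cc: int


@dataclass
class TrialResult:
    """Everything the per-trial pipeline produces."""

    segments: list[SegmentClassification]
    jitter: JitterProfile
    summary: TrialSummary
    registration: RegistrationResult
    windows: list[SegmentWindow]


def segment_by_stimulus(stimulus: Trajectory,
                        sections: list[SectionAnnotation] | None = None,
                        blend_half_window: float = BLEND_HALF_WINDOW,
                        prominence_frac: float = 0.02) -> list[SegmentWindow]:
    """Windows tiling the trial, one per stimulus half-cycle.

    With section annotations the boundaries are analytic: turning points
    within each section, and ``join - blend_half_window`` at section joins
    so the whole blend window belongs to the following half-cycle. Without
    annotations, turning points are detected as velocity zero crossings
    (small-lobe pairs suppressed as in :func:`ccmotion.kinematics.find_azc`),
    and each window is labelled with its measured frequency
    ``0.5 / duration`` and peak speed.
    """
    if sections:
        windows: list[SegmentWindow] = []
        idx = 0
        end_of_trial = stimulus.t0 + stimulus.duration
        for ann in sections:
            bounds = ann.half_cycle_boundaries()
            for j in range(len(bounds) - 1):
                a, b = bounds[j], bounds[j + 1]
                if ann.index > 0 and j == 0:
                    a -= blend_half_window      # blend belongs to this window
                if idx and windows[-1].t_end != a:
                    windows[-1].t_end = a       # keep the tiling exact
                if ann.index == len(sections) - 1 and j == len(bounds) - 2:
                    b = max(b, end_of_trial)
                windows.append(SegmentWindow(
                    index=idx, t_start=a, t_end=b, frequency=ann.frequency,
                    peak_velocity=ann.peak_velocity, section_index=ann.index))
                idx += 1
        return windows

    # Fallback for unannotated traces (e.g., free dyadic motion): turning
    # points from velocity sign changes with a prominence guard.
    v = stimulus.velocity
    if np.all(v == 0) or len(v) < 2:
        raise ValueError("stimulus has no well-defined turning points")
    vel_traj = Trajectory(sample_rate=stimulus.sample_rate, position=v,
                          velocity=v, acceleration=v, t0=stimulus.t0)
    turning = find_azc(vel_traj, prominence_frac=prominence_frac).times
    bounds = np.concatenate(([stimulus.t0], turning,
                             [stimulus.t0 + stimulus.duration]))
    bounds = np.unique(bounds)
    windows = []
    for idx, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        i0, i1 = stimulus.index_range(a, b)
        if i1 - i0 < 2:
            continue
        windows.append(SegmentWindow(
            index=idx, t_start=float(a), t_end=float(b),
            frequency=0.5 / (b - a),
            peak_velocity=float(np.max(np.abs(v[i0:i1])))))
    for idx, w in enumerate(windows):
        w.index = idx
    return windows


def match_azc(response_azc: AZCList, stimulus_azc: AZCList,
              tolerance: float = AZC_MATCH_TOLERANCE
              ) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one matching of response AZCs to stimulus AZCs.

    Optimal assignment: among maximum-cardinality matchings within
    ``tolerance``, the one minimizing the total |time difference|.
    Returns ``(matched_response_times, jitter_point_times)`` — unmatched
    response AZCs are the jitter points.
    """
    tr = np.asarray(response_azc.times, dtype=float)
    ts = np.asarray(stimulus_azc.times, dtype=float)
    if len(tr) == 0:
        return np.array([]), np.array([])
    if len(ts) == 0:
        return np.array([]), tr.copy()
    diff = np.abs(tr[:, None] - ts[None, :])
    big = 1e6
    cost = np.where(diff <= tolerance, diff, big)
    rows, cols = linear_sum_assignment(cost)
    matched_mask = np.zeros(len(tr), dtype=bool)
    for r, c in zip(rows, cols):
        if diff[r, c] <= tolerance:
            matched_mask[r] = True
    return tr[matched_mask], tr[~matched_mask]


def jitter_frequency(jitter_times, bin_width: float = 0.05) -> JitterProfile:
    """Interval frequencies (0.5 / interval) and their histogram peak.

    The peak is the mean of the interval frequencies inside the modal
    ``bin_width`` histogram bin (ties resolved toward the lower bin). With
    fewer than two jitter points the profile is empty and the peak NaN.
    """
    jt = np.sort(np.asarray(jitter_times, dtype=float))
    if len(jt) < 2:
        return JitterProfile(jitter_times=jt, interval_frequencies=np.array([]),
                             peak_jitter_frequency=np.nan)
    freqs = 0.5 / np.diff(jt)
    lo = np.floor(freqs.min() / bin_width) * bin_width
    hi = np.ceil(freqs.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(freqs, bins=edges)
    k = int(np.argmax(counts))
    in_bin = (freqs >= edges[k]) & (freqs < edges[k + 1] if k + 1 < len(edges) - 1
                                    else freqs <= edges[k + 1])
    peak = float(freqs[in_bin].mean()) if in_bin.any() else float(freqs.mean())
    return JitterProfile(jitter_times=jt, interval_frequencies=freqs,
                         peak_jitter_frequency=peak)


def segment_metrics(aligned_response: Trajectory, stimulus: Trajectory,
                    window: SegmentWindow, max_lag: float = 0.5
                    ) -> tuple[float, float, float]:
    """(dX, dV, dT) of one segment against its stimulus half-cycle.

    The segment-local lag maximizing the velocity cross-correlation within
    ``+/- max_lag`` defines dT = |lag|; dV and dX are RMS errors at that
    lag, normalized by the stimulus velocity RMS and the stimulus position
    extent respectively.
    """
    i0, i1 = stimulus.index_range(window.t_start, window.t_end)
    if i1 - i0 < 4:
        raise UndefinedMetricsError("window shorter than 4 samples")
    vs = stimulus.velocity[i0:i1]
    xs = stimulus.position[i0:i1]
    rms_vs = float(np.sqrt(np.mean(vs ** 2)))
    extent = float(xs.max() - xs.min())
    if rms_vs == 0 or extent == 0:
        raise UndefinedMetricsError("zero-variance stimulus segment")

    vr_full = aligned_response.velocity
    n = len(vr_full)
    max_shift = int(round(max_lag * stimulus.sample_rate))
    best_lag, best_score = 0, -np.inf
    for lag in range(-max_shift, max_shift + 1):
        a, b = i0 + lag, i1 + lag
        if a < 0 or b > n:
            continue
        seg = vr_full[a:b]
        denom = np.sqrt(np.sum(seg ** 2) * np.sum(vs ** 2))
        if denom == 0:
            continue
        score = float(np.dot(seg, vs) / denom)
        if score > best_score:
            best_score, best_lag = score, lag

    a, b = i0 + best_lag, i1 + best_lag
    vr = vr_full[a:b]
    xr = aligned_response.position[a:b]
    dV = float(np.sqrt(np.mean((vr - vs) ** 2)) / rms_vs)
    dX = float(np.sqrt(np.mean((xr - xs) ** 2)) / extent)
    dT = abs(best_lag) / stimulus.sample_rate
    return dX, dV, dT


def classify_cc(segment: SegmentClassification,
                dv_threshold: float = DV_THRESHOLD,
                dt_threshold: float = DT_THRESHOLD) -> bool:
    """CC: exactly one response AZC, matched to the stimulus, and similar
    enough (dV < 0.95, dT < 0.15 s)."""
    return bool(segment.response_azc_count == 1
                and segment.azc_matched
                and segment.dV < dv_threshold
                and segment.dT < dt_threshold)


def cc_vector(segments: list[SegmentClassification], time: np.ndarray) -> np.ndarray:
    """Binary per-sample CC membership over a timebase."""
    out = np.zeros(len(time), dtype=np.uint8)
    for seg in segments:
        if seg.is_cc:
            out[(time >= seg.t_start) & (time < seg.t_end)] = 1
    return out


def summarize_trial(segments: list[SegmentClassification],
                    jitter: JitterProfile | None = None) -> TrialSummary:
    """Time-weighted %CC plus metric means over classified segments."""
    used = [s for s in segments if s.is_cc is not None]
    total = sum(s.t_end - s.t_start for s in used)
    cc_time = sum(s.t_end - s.t_start for s in used if s.is_cc)
    percent = 100.0 * cc_time / total if total > 0 else np.nan
    return TrialSummary(
        percent_cc=percent,
        dX_mean=float(np.mean([s.dX for s in used])) if used else np.nan,
        dV_mean=float(np.mean([s.dV for s in used])) if used else np.nan,
        dT_mean=float(np.mean([s.dT for s in used])) if used else np.nan,
        peak_jitter_frequency=(jitter.peak_jitter_frequency
                               if jitter is not None else np.nan),
        n_segments=len(used),
        n_cc=sum(bool(s.is_cc) for s in used),
    )


def analyze_trial(response: Trajectory, stimulus: Trajectory,
                  sections: list[SectionAnnotation] | None = None,
                  max_lag: float = 0.5,
                  azc_tolerance: float = AZC_MATCH_TOLERANCE,
                  prominence_frac: float = 0.02) -> TrialResult:
    """Full per-trial pipeline: register, find AZCs, segment, classify.

    Windows that are not fully inside the registration-valid region are
    excluded from classification (``is_cc = None``) rather than classified
    on edge-padded data.
    """
    reg = register(response, stimulus, max_lag=max_lag)
    aligned = reg.aligned_response
    r_azc = find_azc(aligned, prominence_frac=prominence_frac)
    s_azc = find_azc(stimulus, prominence_frac=prominence_frac)
    matched, jitter_times = match_azc(r_azc, s_azc, tolerance=azc_tolerance)
    windows = segment_by_stimulus(stimulus, sections)

    t_valid_lo = stimulus.t0 + reg.valid_start / stimulus.sample_rate
    t_valid_hi = stimulus.t0 + reg.valid_end / stimulus.sample_rate

    segments: list[SegmentClassification] = []
    for w in windows:
        in_win = r_azc.times[(r_azc.times >= w.t_start) & (r_azc.times < w.t_end)]
        jit_in = jitter_times[(jitter_times >= w.t_start) & (jitter_times < w.t_end)]
        azc_matched = (len(in_win) == 1
                       and bool(np.any(np.isclose(matched, in_win[0], atol=1e-9))))
        valid = w.t_start >= t_valid_lo - 1e-9 and w.t_end <= t_valid_hi + 1e-9
        try:
            dX, dV, dT = segment_metrics(aligned, stimulus, w, max_lag=max_lag)
        except UndefinedMetricsError:
            valid = False
            dX = dV = dT = np.nan
        seg = SegmentClassification(
            segment_index=w.index, t_start=w.t_start, t_end=w.t_end,
            stimulus_frequency=w.frequency,
            stimulus_peak_velocity=w.peak_velocity,
            section_index=w.section_index,
            response_azc_count=len(in_win), jitter_point_times=jit_in,
            dX=dX, dV=dV, dT=dT, is_cc=None, azc_matched=azc_matched)
        seg.is_cc = classify_cc(seg) if valid else None
        segments.append(seg)

    profile = jitter_frequency(jitter_times)
    summary = summarize_trial(segments, profile)
    return TrialResult(segments=segments, jitter=profile, summary=summary,
                       registration=reg, windows=windows)


def segments_to_frame(segments: list[SegmentClassification],
                      **labels) -> pd.DataFrame:
    """Tidy DataFrame of segment classifications; extra columns via labels."""
    rows = []
    for s in segments:
        rows.append({
            "segment_index": s.segment_index,
            "t_start": s.t_start, "t_end": s.t_end,
            "duration": s.t_end - s.t_start,
            "frequency": s.stimulus_frequency,
            "peak_velocity": s.stimulus_peak_velocity,
            "section_index": s.section_index,
            "azc_count": s.response_azc_count,
            "n_jitter": len(s.jitter_point_times),
            "dX": s.dX, "dV": s.dV, "dT": s.dT,
            "is_cc": s.is_cc,
            **labels,
        })
    return pd.DataFrame(rows)
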