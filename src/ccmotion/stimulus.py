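"""Half-sine oscillating stimulus synthesis.

The tracking task uses a virtual leader that oscillates left-right with a
piecewise-constant program of <frequency, peak velocity> pairs. Within a
section each movement (turning point to turning point) has a half-sine
speed profile of duration 1/(2f) that peaks at v_peak, which makes the
position a sinusoid about the workspace center with extent

    D = v_peak / (pi * f)      (cm)

The built-in design is an 11-trial, 31-section program drawing frequencies
from {0.25 ... 0.875} Hz and peak velocities from {20.0 ... 46.6} cm/s, one
minute per trial. Where the program changes (a "join"), position and
velocity over join +/- 250 ms are replaced by the cubic (Hermite) polynomial
matching position and velocity at the window edges, so the assembled trial
is C0/C1 continuous everywhere.

Notes on conventions (free choices of this implementation):

* every trial starts at rest at ``center - D/2`` and first moves rightward;
* concatenation is position-continuous: each section starts at the turning
  point the previous section ended on (its own oscillation center shifts by
  half the extent change), so the blend only has to smooth the C2 break at
  the join rather than absorb a position jump;
* section durations are minimally adjusted so each section holds a whole
  number of half-cycles (for three-section trials the nominal 20 s split
  already does; the two-section trials round to 30/30 s and 28/32 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import ceil, pi

import numpy as np

from .types import Trajectory

__all__ = [
    "DESIGN_FREQUENCIES",
    "DESIGN_PEAK_VELOCITIES",
    "WORKSPACE_WIDTH_CM",
    "StimulusSection",
    "TrialSpec",
    "SectionAnnotation",
    "InvalidSpecError",
    "build_section",
    "blend_join",
    "round_section_durations",
    "build_trial",
    "builtin_design",
]

#: The six oscillation frequencies of the built-in design (Hz).
DESIGN_FREQUENCIES: tuple[float, ...] = (0.25, 0.375, 0.5, 0.625, 0.75, 0.875)
#: The five peak velocities of the built-in design (cm/s).
DESIGN_PEAK_VELOCITIES: tuple[float, ...] = (20.0, 26.7, 33.3, 40.0, 46.6)
#: Width of the 1-D workspace (graphics-tablet track), cm.
WORKSPACE_WIDTH_CM: float = 45.5

#: Half-width of the cubic blend window applied at section joins (s).
BLEND_HALF_WINDOW: float = 0.25


class InvalidSpecError(ValueError):
    """A stimulus specification violates its invariants."""


@dataclass
class StimulusSection:
    """One constant <frequency, peak velocity> stretch of a trial.

    ``duration`` and ``start_time`` may be left unset until
    :func:`round_section_durations` / :func:`build_trial` assign them.
    """

    frequency: float           # Hz; one full left-right-left cycle per 1/f s
    peak_velocity: float       # cm/s
    duration: float | None = None    # s
    start_time: float | None = None  # s from trial onset

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.peak_velocity <= 0:
            raise InvalidSpecError("frequency and peak_velocity must be positive")
        if self.duration is not None and self.duration <= 0:
            raise InvalidSpecError("duration must be positive")

    @property
    def extent(self) -> float:
        """Movement extent D = v_peak / (pi f) in cm."""
        return self.peak_velocity / (pi * self.frequency)

    @property
    def half_cycle_duration(self) -> float:
        return 1.0 / (2.0 * self.frequency)

    @property
    def n_half_cycles(self) -> float:
        if self.duration is None:
            raise InvalidSpecError("section duration not set")
        return 2.0 * self.frequency * self.duration


@dataclass
class TrialSpec:
    """Ordered program of sections for one trial (default one minute)."""

    trial_id: int
    sections: list[StimulusSection]
    total_duration: float = 60.0

    def __post_init__(self) -> None:
        if not self.sections:
            raise InvalidSpecError("a trial needs at least one section")
        if self.total_duration <= 0:
            raise InvalidSpecError("total_duration must be positive")


@dataclass
class SectionAnnotation:
    """Exact placement of one section inside a built trial."""

    index: int                 # 0-based position within the trial
    frequency: float           # Hz
    peak_velocity: float       # cm/s
    t_start: float             # s
    t_end: float               # s
    start_direction: int       # +1 rightward, -1 leftward (first half-cycle)
    start_position: float      # cm (turning point the section starts from)

    @property
    def extent(self) -> float:
        return self.peak_velocity / (pi * self.frequency)

    @property
    def n_half_cycles(self) -> int:
        return int(round(2.0 * self.frequency * (self.t_end - self.t_start)))

    def half_cycle_boundaries(self) -> np.ndarray:
        """Turning-point times t_start, t_start + 1/(2f), ..., t_end."""
        half = 1.0 / (2.0 * self.frequency)
        n = max(int(round((self.t_end - self.t_start) / half)), 1)
        bounds = self.t_start + half * np.arange(n + 1)
        bounds[-1] = self.t_end
        return bounds


def _section_arrays(t_rel: np.ndarray, frequency: float, peak_velocity: float,
                    start_position: float, start_direction: int):
    """Analytic position/velocity/acceleration of a half-sine section.

    ``t_rel`` is time from section onset; the section starts at rest at
    ``start_position`` and first moves in ``start_direction``.
    """
    d = peak_velocity / (pi * frequency)
    omega = 2.0 * pi * frequency
    center = start_position + start_direction * d / 2.0
    phase = omega * t_rel
    pos = center - start_direction * (d / 2.0) * np.cos(phase)
    vel = start_direction * peak_velocity * np.sin(phase)
    acc = start_direction * peak_velocity * omega * np.cos(phase)
    return pos, vel, acc


def build_section(section: StimulusSection, start_position: float = 0.0,
                  start_direction: int = 1, sample_rate: float = 100.0,
                  workspace_width: float = WORKSPACE_WIDTH_CM,
                  strict_workspace: bool = False) -> Trajectory:
    """Generate one constant-program section as a trajectory.

    The section starts at a turning point (zero velocity) at
    ``start_position`` and oscillates with extent ``v_peak / (pi f)``.
    Emits a warning (or raises, with ``strict_workspace``) when the extent
    exceeds the configured workspace width.
    """
    if section.duration is None:
        raise InvalidSpecError("section duration must be set before building")
    if start_direction not in (-1, 1):
        raise InvalidSpecError("start_direction must be +1 or -1")
    if sample_rate < 50.0:
        raise InvalidSpecError("sample_rate must be at least 50 Hz")
    if section.extent > workspace_width:
        msg = (f"section extent {section.extent:.1f} cm exceeds the "
               f"{workspace_width:.1f} cm workspace")
        if strict_workspace:
            raise InvalidSpecError(msg)
        warnings.warn(msg, stacklevel=2)
    n = int(round(section.duration * sample_rate))
    t_rel = np.arange(n) / sample_rate
    pos, vel, acc = _section_arrays(t_rel, section.frequency, section.peak_velocity,
                                    start_position, start_direction)
    return Trajectory(sample_rate=sample_rate, position=pos, velocity=vel,
                      acceleration=acc, t0=0.0)


def _hermite(t: np.ndarray, ta: float, tb: float,
             pa: float, pb: float, va: float, vb: float):
    """Cubic matching position and velocity at both edges, plus derivatives."""
    h = tb - ta
    s = (t - ta) / h
    s2, s3 = s * s, s * s * s
    h00 = 2 * s3 - 3 * s2 + 1
    h10 = s3 - 2 * s2 + s
    h01 = -2 * s3 + 3 * s2
    h11 = s3 - s2
    pos = h00 * pa + h10 * h * va + h01 * pb + h11 * h * vb
    d00 = (6 * s2 - 6 * s) / h
    d10 = 3 * s2 - 4 * s + 1
    d01 = (-6 * s2 + 6 * s) / h
    d11 = 3 * s2 - 2 * s
    vel = d00 * pa + d10 * va + d01 * pb + d11 * vb
    a00 = (12 * s - 6) / (h * h)
    a10 = (6 * s - 4) / h
    a01 = (-12 * s + 6) / (h * h)
    a11 = (6 * s - 2) / h
    acc = a00 * pa + a10 * va + a01 * pb + a11 * vb
    return pos, vel, acc


def blend_join(traj: Trajectory, join_time: float,
               half_window: float = BLEND_HALF_WINDOW) -> Trajectory:
    """Replace traj around ``join_time`` by a position/velocity-matched cubic.

    Position on ``[join - half_window, join + half_window]`` becomes the
    unique cubic whose position and velocity match the trace at the window
    edges; velocity and acceleration inside the window are the cubic's
    derivatives. The result is C0/C1 continuous through the join.
    """
    t = traj.time
    ta = join_time - half_window
    tb = join_time + half_window
    if ta < t[0] - 1e-9 or tb > t[-1] + 1e-9:
        raise ValueError("blend window extends beyond the trace")
    ia = int(np.searchsorted(t, ta - 1e-9))
    ib = int(np.searchsorted(t, tb - 1e-9))
    ib = min(ib, len(t) - 1)
    if ib - ia < 3:
        raise ValueError("blend window too short for the sample rate")
    out = traj.copy()
    pa, pb = traj.position[ia], traj.position[ib]
    va, vb = traj.velocity[ia], traj.velocity[ib]
    seg = slice(ia, ib + 1)
    pos, vel, acc = _hermite(t[seg], t[ia], t[ib], pa, pb, va, vb)
    out.position[seg] = pos
    out.velocity[seg] = vel
    out.acceleration[seg] = acc
    return out


def _candidate_durations(frequency: float, nominal: float, max_shift: float):
    """Durations near nominal holding a whole number of half-cycles."""
    half = 1.0 / (2.0 * frequency)
    lo = max(int(ceil((nominal - max_shift) / half)), 1)
    hi = int((nominal + max_shift) / half)
    return [m * half for m in range(lo, hi + 1)]


def round_section_durations(spec: TrialSpec, max_shift: float = 2.0) -> TrialSpec:
    """Assign section durations holding whole numbers of half-cycles.

    Nominal durations are an even split of the trial; they are shifted
    minimally (total preserved exactly) so that ``2 f d`` is an integer for
    every section. Ties prefer the lexicographically smallest duration
    vector. If no whole-cycle partition exists within ``max_shift`` of
    nominal, the nominal split is kept (the final partial half-cycle is
    simply truncated at the join) with a warning.
    """
    n = len(spec.sections)
    nominal = spec.total_duration / n
    tol = 1e-6

    best: tuple[float, tuple[float, ...]] | None = None
    if n == 1:
        cands = [[d] for d in _candidate_durations(spec.sections[0].frequency,
                                                   nominal, max_shift)
                 if abs(d - spec.total_duration) < tol]
    else:
        # Cartesian search over all but the last section; the last duration
        # is fixed by the 60 s total and checked for integrality.
        from itertools import product

        grids = [_candidate_durations(s.frequency, nominal, max_shift)
                 for s in spec.sections[:-1]]
        last_f = spec.sections[-1].frequency
        cands = []
        for combo in product(*grids):
            d_last = spec.total_duration - sum(combo)
            if d_last <= 0 or abs(d_last - nominal) > max_shift:
                continue
            m = 2.0 * last_f * d_last
            if abs(m - round(m)) > tol:
                continue
            cands.append(list(combo) + [d_last])
    for durations in cands:
        score = sum(abs(d - nominal) for d in durations)
        key = (score, tuple(durations))
        if best is None or key < best:
            best = key
    if best is None:
        warnings.warn(
            f"trial {spec.trial_id}: no whole-half-cycle partition within "
            f"{max_shift} s of nominal; keeping nominal durations (truncated "
            "half-cycles will be blended)", stacklevel=2)
        durations = [nominal] * n
    else:
        durations = list(best[1])
    sections = []
    t = 0.0
    for sec, d in zip(spec.sections, durations):
        sections.append(replace(sec, duration=d, start_time=t))
        t += d
    return replace(spec, sections=sections)


def build_trial(spec: TrialSpec, sample_rate: float = 100.0,
                blend_half_window: float = BLEND_HALF_WINDOW,
                workspace_center: float = 0.0,
                **workspace_kwargs) -> tuple[Trajectory, list[SectionAnnotation]]:
    """Assemble a full trial: concatenated sections with blended joins.

    Returns the trajectory and per-section annotations carrying exact
    section boundaries, start directions and start positions.
    """
    if any(s.duration is None for s in spec.sections):
        spec = round_section_durations(spec)
    n_total = int(round(spec.total_duration * sample_rate))
    time = np.arange(n_total) / sample_rate
    pos = np.empty(n_total)
    vel = np.empty(n_total)
    acc = np.empty(n_total)

    annotations: list[SectionAnnotation] = []
    direction = 1
    t_start = 0.0
    for k, sec in enumerate(spec.sections):
        if sec.extent > workspace_kwargs.get("workspace_width", WORKSPACE_WIDTH_CM):
            warnings.warn(
                f"trial {spec.trial_id} section {k}: extent {sec.extent:.1f} cm "
                "exceeds the workspace", stacklevel=2)
        t_end = t_start + sec.duration
        i0 = int(np.ceil(t_start * sample_rate - 1e-9))
        i1 = int(np.ceil(t_end * sample_rate - 1e-9)) if k < len(spec.sections) - 1 else n_total
        if k == 0:
            start_position = workspace_center - direction * sec.extent / 2.0
        # else: position-continuous — the section starts at the turning
        # point the previous section ended on.
        p, v, a = _section_arrays(time[i0:i1] - t_start, sec.frequency,
                                  sec.peak_velocity, start_position, direction)
        pos[i0:i1], vel[i0:i1], acc[i0:i1] = p, v, a
        annotations.append(SectionAnnotation(
            index=k, frequency=sec.frequency, peak_velocity=sec.peak_velocity,
            t_start=t_start, t_end=t_end, start_direction=direction,
            start_position=start_position))
        n_half = int(round(2.0 * sec.frequency * sec.duration))
        if n_half % 2:
            start_position = start_position + direction * sec.extent
            direction = -direction
        t_start = t_end

    traj = Trajectory(sample_rate=sample_rate, position=pos, velocity=vel,
                      acceleration=acc, t0=0.0)
    for ann in annotations[1:]:
        traj = blend_join(traj, ann.t_start, blend_half_window)
    return traj, annotations


# Built-in 11-trial design: <frequency Hz, peak velocity cm/s> per section.
_BUILTIN_TABLE: tuple[tuple[tuple[float, float], ...], ...] = (
    ((0.25, 40.0), (0.5, 26.7)),
    ((0.5, 20.0), (0.25, 40.0), (0.875, 26.7)),
    ((0.75, 46.6), (0.25, 33.3), (0.25, 46.6)),
    ((0.25, 26.7), (0.875, 40.0), (0.75, 33.3)),
    ((0.625, 46.6), (0.75, 26.7), (0.375, 40.0)),
    ((0.375, 20.0), (0.625, 40.0)),
    ((0.375, 33.3), (0.875, 20.0), (0.375, 46.6)),
    ((0.875, 46.6), (0.75, 20.0), (0.625, 26.7)),
    ((0.5, 33.3), (0.625, 33.3), (0.25, 20.0)),
    ((0.375, 26.7), (0.875, 33.3), (0.5, 46.6)),
    ((0.75, 40.0), (0.5, 33.3), (0.625, 20.0)),
)


def builtin_design(rounded: bool = True) -> list[TrialSpec]:
    """The built-in 11-trial stimulus program (31 sections, 60 s trials).

    With ``rounded=True`` (default) section durations are already assigned
    via :func:`round_section_durations`.
    """
    specs = []
    for i, rows in enumerate(_BUILTIN_TABLE, start=1):
        spec = TrialSpec(
            trial_id=i,
            sections=[StimulusSection(frequency=f, peak_velocity=v) for f, v in rows],
        )
        specs.append(round_section_durations(spec) if rounded else spec)
    return specs
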