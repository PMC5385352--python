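"""Synthetic intermittent-control follower and cohort generator.

No public tracking dataset accompanies the one-player mirror-game design,
so every pipeline stage is exercised against a generative model that
encodes the intermittent-control account of tracking:

* movements are composed of minimum-jerk submovements whose velocities
  superpose linearly;
* a follower can produce a single smooth submovement only up to a
  stochastic duration limit ``T_lim ~ Normal(mu_T, sigma_T)`` (truncated at
  zero); half-cycles longer than the draw are split into
  ``k = ceil(d / T_lim)`` chained submovements, which introduces extra
  acceleration zero crossings — jitter;
* plans are aligned to the (predictable) stimulus turning points, viewed
  through a sensorimotor delay, with endpoint and onset noise;
* corrective submovements fire stochastically in proportion to the
  momentary position error.

Defaults: delay 0.15 s, mu_T = 1.3 s, sigma_T = 0.15 s — a stochastic
generalization of the ~1 s ceiling on smooth movement duration reported in
the motor-control literature, placed so 2 s half-cycles (0.25 Hz) are
essentially never smooth while 1.33 s half-cycles (0.375 Hz) sometimes are.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil, pi

import numpy as np

from .stimulus import SectionAnnotation, TrialSpec, build_trial, builtin_design
from .types import Trajectory

__all__ = [
    "FollowerParams",
    "SubmovementPlan",
    "CohortData",
    "min_jerk",
    "simulate_follower",
    "simulate_cohort",
    "simulate_free_dyad",
]


@dataclass
class FollowerParams:
    """Generative parameters of the simulated follower.

    All durations in seconds; ``endpoint_noise_frac`` scales with the
    half-cycle extent D; ``correction_prob_per_excess_cm`` is the hazard of
    an extra corrective submovement — probability per cm of momentary
    tracking error per second of observing it — so long, slow movements
    accumulate more corrections than short fast ones carrying the same
    instantaneous error.
    """

    delay: float = 0.15
    smooth_limit_mean: float = 1.3        # mu_T
    smooth_limit_sd: float = 0.15         # sigma_T
    endpoint_noise_frac: float = 0.05
    timing_noise_sd: float = 0.03
    correction_prob_per_excess_cm: float = 0.1   # hazard: 1/(cm s)
    correction_duration: float = 0.3
    correction_check_interval: float = 0.25      # s between error checks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delay <= 0 or self.delay >= 0.5:
            raise ValueError("delay must be in (0, 0.5) s")
        for name in ("smooth_limit_mean", "smooth_limit_sd",
                     "endpoint_noise_frac", "timing_noise_sd",
                     "correction_prob_per_excess_cm", "correction_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if (self.smooth_limit_sd > 0
                and self.smooth_limit_mean <= 3 * self.smooth_limit_sd):
            raise ValueError("smooth_limit_mean must exceed 3 * smooth_limit_sd")


@dataclass
class SubmovementPlan:
    """One minimum-jerk submovement: onset, duration, endpoints."""

    onset: float
    duration: float
    start_position: float
    end_position: float

    @property
    def amplitude(self) -> float:
        return self.end_position - self.start_position


def min_jerk(d: float, T: float, sample_rate: float = 100.0) -> Trajectory:
    """Minimum-jerk point-to-point trajectory x(tau) = d(10 tau^3 - 15 tau^4
    + 6 tau^5) over [0, T].

    Starts and ends at rest, velocity has a single peak of 1.875 d/T at
    tau = 0.5, and the acceleration crosses zero exactly once.
    """
    if T <= 0:
        raise ValueError("duration must be positive")
    n = int(round(T * sample_rate)) + 1
    tau = np.linspace(0.0, 1.0, n)
    pos = d * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    vel = d / T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    acc = d / T**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)
    return Trajectory(sample_rate=sample_rate, position=pos, velocity=vel,
                      acceleration=acc, t0=0.0)


def _add_pulse(vel: np.ndarray, acc: np.ndarray, sample_rate: float,
               plan: SubmovementPlan) -> None:
    """Superpose one submovement's velocity/acceleration onto the grid."""
    n = len(vel)
    i0 = max(int(np.ceil(plan.onset * sample_rate - 1e-9)), 0)
    i1 = min(int(np.floor((plan.onset + plan.duration) * sample_rate + 1e-9)) + 1, n)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / sample_rate
    tau = np.clip((t - plan.onset) / plan.duration, 0.0, 1.0)
    d = plan.amplitude
    vel[i0:i1] += d / plan.duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    acc[i0:i1] += d / plan.duration**2 * (60 * tau - 180 * tau**2 + 120 * tau**3)


def _draw_limit(rng: np.random.Generator, mu: float, sd: float) -> float:
    """Normal(mu, sd) truncated at zero (rejection; mu >> sd in practice)."""
    if sd == 0:
        return mu
    for _ in range(100):
        x = rng.normal(mu, sd)
        if x > 0:
            return x
    return mu


def simulate_follower(stimulus: Trajectory,
                      sections: list[SectionAnnotation],
                      params: FollowerParams | None = None,
                      rng: np.random.Generator | None = None) -> Trajectory:
    """Simulate an intermittent-control follower tracking a stimulus.

    Each stimulus half-cycle is planned from the follower's current
    position to the stimulus's next turning point, as one minimum-jerk
    submovement when the duration fits under the smooth-duration draw and
    as a chain of noisy submovements otherwise. Deterministic given
    ``params.seed`` (or an explicit ``rng``).
    """
    if not sections:
        raise ValueError("stimulus must carry section annotations")
    params = params or FollowerParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rate = stimulus.sample_rate
    n = len(stimulus)
    vel = np.zeros(n)
    acc = np.zeros(n)
    stim_t = stimulus.time

    def stim_pos(t: float) -> float:
        return float(np.interp(t, stim_t, stimulus.position))

    plans: list[SubmovementPlan] = []
    start_position = stim_pos(stim_t[0])
    current = start_position

    def plan_position(t: float) -> float:
        """Follower's planned position at time t (integral of pulses so far)."""
        i = min(int(round((t - stimulus.t0) * rate)), n - 1)
        if i <= 0:
            return start_position
        return start_position + float(np.trapezoid(vel[:i + 1], dx=1.0 / rate))

    for ann in sections:
        bounds = ann.half_cycle_boundaries()
        extent = ann.extent
        for j in range(len(bounds) - 1):
            t0, t1 = float(bounds[j]), float(bounds[j + 1])
            d = t1 - t0
            target = stim_pos(min(t1, stim_t[-1]))
            t_lim = _draw_limit(rng, params.smooth_limit_mean,
                                params.smooth_limit_sd)
            onset = t0 + params.delay + rng.normal(0.0, params.timing_noise_sd)
            if d <= t_lim:
                sub = SubmovementPlan(onset=onset, duration=d,
                                      start_position=current,
                                      end_position=target)
                _add_pulse(vel, acc, rate, sub)
                plans.append(sub)
            else:
                k = ceil(d / t_lim)
                sub_d = d / k
                points = [current]
                for m in range(1, k):
                    mid = stim_pos(t0 + m * sub_d)
                    mid += rng.normal(0.0, params.endpoint_noise_frac * extent)
                    points.append(mid)
                points.append(target)
                for m in range(k):
                    jit = rng.normal(0.0, params.timing_noise_sd) if m else 0.0
                    sub = SubmovementPlan(onset=onset + m * sub_d + jit,
                                          duration=sub_d,
                                          start_position=points[m],
                                          end_position=points[m + 1])
                    _add_pulse(vel, acc, rate, sub)
                    plans.append(sub)
            current = target

            # Error-triggered corrections: at a fixed cadence the follower
            # compares its (delayed) plan with the stimulus and patches the
            # drift with a small submovement, with hazard proportional to
            # the momentary error. The plan runs `delay` behind the
            # stimulus, so the observable error is plan(t + delay) - stim(t).
            if params.correction_prob_per_excess_cm > 0:
                step = params.correction_check_interval
                t_check = t0 + step
                # Only patch the ongoing movement: a correction whose onset
                # (one delay after the check) would fall beyond the
                # half-cycle is folded into the next plan instead.
                while t_check < t1 - params.delay:
                    if t_check + params.delay >= stim_t[-1]:
                        break
                    err = (plan_position(t_check + params.delay)
                           - stim_pos(t_check))
                    p_corr = min(params.correction_prob_per_excess_cm
                                 * abs(err) * step, 0.9)
                    if p_corr > 0 and rng.random() < p_corr:
                        dur = min(params.correction_duration, max(d / 2, 0.1))
                        sub = SubmovementPlan(
                            onset=t_check + params.delay, duration=dur,
                            start_position=0.0, end_position=-err)
                        _add_pulse(vel, acc, rate, sub)
                        plans.append(sub)
                    t_check += step

    dt = 1.0 / rate
    pos = start_position + np.concatenate(
        ([0.0], np.cumsum((vel[1:] + vel[:-1]) * dt / 2.0)))
    return Trajectory(sample_rate=rate, position=pos, velocity=vel,
                      acceleration=acc, t0=stimulus.t0)


@dataclass
class CohortData:
    """A simulated cohort: shared stimuli plus one response per trial."""

    stimuli: dict      # trial_id -> (Trajectory, [SectionAnnotation])
    responses: dict    # participant -> trial_id -> Trajectory
    params: dict       # participant -> FollowerParams

    @property
    def participants(self) -> list:
        return sorted(self.responses)

    @property
    def trials(self) -> list:
        return sorted(self.stimuli)


def _draw_participant_params(rng: np.random.Generator,
                             base: FollowerParams) -> FollowerParams:
    """Participant-level variation around the base parameters.

    Bounded uniform draws: mu_T within +/- 0.1 s, delay within +/- 0.03 s
    and endpoint noise within +/- 0.01 of the base values.
    """
    delay = float(np.clip(rng.uniform(base.delay - 0.03, base.delay + 0.03),
                          0.05, 0.45))
    mu = float(max(rng.uniform(base.smooth_limit_mean - 0.1,
                               base.smooth_limit_mean + 0.1),
                   3.2 * base.smooth_limit_sd))
    noise = float(np.clip(rng.uniform(base.endpoint_noise_frac - 0.01,
                                      base.endpoint_noise_frac + 0.01),
                          0.005, 0.2))
    return replace(base, delay=delay, smooth_limit_mean=mu,
                   endpoint_noise_frac=noise,
                   seed=int(rng.integers(0, 2**31 - 1)))


def simulate_cohort(n_participants: int = 18,
                    design: list[TrialSpec] | None = None,
                    base_params: FollowerParams | None = None,
                    master_seed: int = 0,
                    sample_rate: float = 100.0) -> CohortData:
    """Simulate a cohort tracking the built-in design.

    One response per participant per trial; per-participant parameters are
    drawn around the defaults (mu_T +/- 0.1 s, delay +/- 0.03 s, endpoint
    noise +/- 0.01). Fully reproducible from ``master_seed``.
    """
    design = design if design is not None else builtin_design()
    base = base_params or FollowerParams()
    rng = np.random.default_rng(master_seed)
    import warnings as _warnings

    stimuli = {}
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")     # workspace-extent warnings
        for spec in design:
            stimuli[spec.trial_id] = build_trial(spec, sample_rate=sample_rate)

    responses: dict = {}
    params: dict = {}
    for p in range(1, n_participants + 1):
        p_params = _draw_participant_params(rng, base)
        params[p] = p_params
        p_rng = np.random.default_rng(p_params.seed)
        responses[p] = {}
        for trial_id, (traj, anns) in stimuli.items():
            responses[p][trial_id] = simulate_follower(traj, anns, p_params,
                                                       rng=p_rng)
    return CohortData(stimuli=stimuli, responses=responses, params=params)


def simulate_free_dyad(duration: float = 180.0,
                       frequency_range: tuple[float, float] = (0.1, 1.2),
                       velocity_range: tuple[float, float] = (15.0, 45.0),
                       params: FollowerParams | None = None,
                       seed: int = 0,
                       sample_rate: float = 100.0,
                       workspace_half_width: float = 20.0
                       ) -> tuple[Trajectory, Trajectory, list[SectionAnnotation]]:
    """A free-motion dyad: improvising leader plus simulated follower.

    The leader emits a random walk over half-sine movements — frequency and
    peak velocity drawn per half-cycle from the given ranges, direction
    alternating except when a move would leave the workspace. Returns
    ``(leader, follower, annotations)`` where each half-cycle is annotated
    as its own one-half-cycle section, so the CC pipeline and free-motion
    binning apply directly.
    """
    rng = np.random.default_rng(seed)
    params = params or FollowerParams(seed=int(rng.integers(0, 2**31 - 1)))
    n = int(round(duration * sample_rate))
    vel = np.zeros(n)
    acc = np.zeros(n)
    t = 0.0
    position = 0.0
    direction = 1
    annotations: list[SectionAnnotation] = []
    idx = 0
    extent_cap = 1.5 * workspace_half_width
    while t < duration:
        f = float(rng.uniform(*frequency_range))
        v = float(rng.uniform(*velocity_range))
        # Keep strokes on the track: slow movements cap their peak velocity
        # so the extent v/(pi f) stays playable.
        v = min(v, pi * f * extent_cap)
        d = 1.0 / (2.0 * f)
        extent = v / (pi * f)
        if abs(position + direction * extent) > workspace_half_width:
            # Move whichever way keeps the player closer to the center.
            direction = 1 if abs(position + extent) < abs(position - extent) else -1
        i0 = int(np.ceil(t * sample_rate - 1e-9))
        i1 = min(int(np.ceil((t + d) * sample_rate - 1e-9)), n)
        if i1 <= i0:
            break
        tt = np.arange(i0, i1) / sample_rate - t
        omega = 2.0 * pi * f
        vel[i0:i1] = direction * v * np.sin(omega * tt)
        acc[i0:i1] = direction * v * omega * np.cos(omega * tt)
        annotations.append(SectionAnnotation(
            index=idx, frequency=f, peak_velocity=v, t_start=t,
            t_end=min(t + d, duration), start_direction=direction,
            start_position=position))
        position += direction * extent
        direction *= -1
        t += d
        idx += 1
    dt = 1.0 / sample_rate
    pos = np.concatenate(([0.0], np.cumsum((vel[1:] + vel[:-1]) * dt / 2.0)))
    leader = Trajectory(sample_rate=sample_rate, position=pos, velocity=vel,
                        acceleration=acc, t0=0.0)
    follower = simulate_follower(leader, annotations, params)
    return leader, follower, annotations
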