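"""Cohort-level orchestration: responses -> segments, CC vectors, summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cc_detection import TrialResult, analyze_trial, cc_vector, segments_to_frame
from .synthetic_data import CohortData

__all__ = ["CohortAnalysis", "analyze_cohort", "section_cc_vectors"]


@dataclass
class CohortAnalysis:
    """Pooled outputs of the per-trial pipeline over a cohort."""

    segments: pd.DataFrame          # one row per (participant, trial, segment)
    summaries: pd.DataFrame         # one row per (participant, trial)
    cc_vectors: dict                # participant -> trial -> section -> 0/1 array
    trial_results: dict             # participant -> trial -> TrialResult


def section_cc_vectors(result: TrialResult, stimulus) -> dict:
    """Binary CC vectors per stimulus section of one analyzed trial."""
    time = stimulus.time
    full = cc_vector(result.segments, time)
    out = {}
    section_ids = sorted({w.section_index for w in result.windows
                          if w.section_index >= 0})
    for k in section_ids:
        wins = [w for w in result.windows if w.section_index == k]
        t_start = min(w.t_start for w in wins)
        t_end = max(w.t_end for w in wins)
        i0, i1 = stimulus.index_range(t_start, t_end)
        out[k] = full[i0:i1].copy()
    return out


def analyze_cohort(cohort: CohortData, **analyze_kwargs) -> CohortAnalysis:
    """Run the CC pipeline for every (participant, trial) response."""
    seg_frames = []
    summary_rows = []
    cc_vecs: dict = {}
    results: dict = {}
    for p in cohort.participants:
        cc_vecs[p] = {}
        results[p] = {}
        for trial_id in cohort.trials:
            stim, anns = cohort.stimuli[trial_id]
            resp = cohort.responses[p][trial_id]
            res = analyze_trial(resp, stim, anns, **analyze_kwargs)
            results[p][trial_id] = res
            seg_frames.append(segments_to_frame(res.segments, participant=p,
                                                trial=trial_id))
            s = res.summary
            summary_rows.append({
                "participant": p, "trial": trial_id,
                "percent_cc": s.percent_cc, "dX_mean": s.dX_mean,
                "dV_mean": s.dV_mean, "dT_mean": s.dT_mean,
                "peak_jitter_frequency": s.peak_jitter_frequency,
                "n_segments": s.n_segments, "n_cc": s.n_cc,
                "registration_lag": res.registration.lag,
            })
            cc_vecs[p][trial_id] = section_cc_vectors(res, stim)
    return CohortAnalysis(
        segments=pd.concat(seg_frames, ignore_index=True),
        summaries=pd.DataFrame(summary_rows),
        cc_vectors=cc_vecs,
        trial_results=results,
    )
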