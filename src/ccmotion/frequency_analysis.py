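"""CC probability as a function of stimulus frequency and peak velocity.

Each stimulus half-cycle is one Bernoulli trial for CC, so the CC
probability of a bin is the fraction of its segments classified CC. For
design data the bins are exactly the six frequencies / five peak
velocities of the program; free (two-player-style) motion is binned at the
same centers using the measured frequency ``0.5 / half-cycle duration``,
with open-ended outer bins. Per-participant regressions of probability on
bin center feed a one-sample t-test of the slopes (one-sided, greater than
zero), and experiments are compared with a mixed (split-plot) ANOVA plus
Tukey HSD on the between factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .stimulus import DESIGN_FREQUENCIES, DESIGN_PEAK_VELOCITIES

__all__ = [
    "SlopeInference",
    "AnovaResult",
    "cc_probability",
    "participant_slopes",
    "bin_free_motion",
    "mixed_anova",
]


@dataclass
class SlopeInference:
    """Per-participant regression slopes and their one-sample test."""

    slopes: np.ndarray        # probability per Hz (or per cm/s)
    participants: list
    t_statistic: float
    df: int                   # N - 1
    p_value: float            # one-sided, H1: mean slope > 0
    ci95: tuple[float, float]
    degenerate: bool = False


@dataclass
class AnovaResult:
    """Mixed-design ANOVA table plus Tukey pairwise comparisons."""

    anova: pd.DataFrame       # Source, SS, DF1, DF2, F, p-unc ...
    tukey: pd.DataFrame       # pairwise comparisons on the between factor

    def effect(self, source: str) -> pd.Series:
        row = self.anova[self.anova["Source"] == source]
        if row.empty:
            raise KeyError(source)
        return row.iloc[0]


_AXES = {"frequency": "frequency", "peak_velocity": "peak_velocity"}


def cc_probability(segments: pd.DataFrame, axis: str = "frequency",
                   by_participant: bool = False,
                   bin_centers=None) -> pd.DataFrame:
    """Per-bin CC probability table.

    ``segments`` needs columns ``frequency``/``peak_velocity`` and
    ``is_cc`` (True/False/None; None rows are dropped), plus
    ``participant`` when grouping. Bins with no segments are flagged with
    ``probability = NaN`` and ``n_segments = 0``, never zero.
    """
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    col = _AXES[axis]
    if bin_centers is None:
        bin_centers = (DESIGN_FREQUENCIES if axis == "frequency"
                       else DESIGN_PEAK_VELOCITIES)
    df = segments[segments["is_cc"].notna()].copy()
    df["is_cc"] = df["is_cc"].astype(bool)

    group_cols = ["participant", col] if by_participant else [col]
    agg = (df.groupby(group_cols, observed=True)["is_cc"]
             .agg(probability="mean", n_segments="size").reset_index())
    agg = agg.rename(columns={col: "bin"})

    # Materialize empty bins explicitly.
    if by_participant:
        participants = sorted(df["participant"].unique())
        full = pd.MultiIndex.from_product([participants, bin_centers],
                                          names=["participant", "bin"])
        agg = (agg.set_index(["participant", "bin"]).reindex(full)
                  .reset_index())
    else:
        agg = (agg.set_index("bin")
                  .reindex(pd.Index(bin_centers, name="bin")).reset_index())
    agg["n_segments"] = agg["n_segments"].fillna(0).astype(int)
    return agg


def participant_slopes(segments: pd.DataFrame, axis: str = "frequency",
                       min_bins: int = 3) -> SlopeInference:
    """OLS slope of CC probability on bin center, per participant, with a
    one-sided t-test of the slopes against zero."""
    table = cc_probability(segments, axis=axis, by_participant=True)
    slopes, participants = [], []
    for p, sub in table.groupby("participant"):
        sub = sub[sub["n_segments"] > 0]
        if len(sub) < min_bins:
            warnings.warn(f"participant {p!r}: fewer than {min_bins} "
                          "non-empty bins; excluded", stacklevel=2)
            continue
        slope = np.polyfit(sub["bin"].astype(float), sub["probability"], 1)[0]
        slopes.append(float(slope))
        participants.append(p)
    slopes = np.asarray(slopes)
    n = len(slopes)
    if n < 2:
        raise ValueError("need at least two participants with slopes")
    sd = slopes.std(ddof=1)
    mean = slopes.mean()
    dof = n - 1
    if sd == 0:
        warnings.warn("identical slopes; t statistic degenerate", stacklevel=2)
        t = np.inf * np.sign(mean) if mean != 0 else 0.0
        p = 0.0 if t > 0 else 1.0
        ci = (mean, mean)
        return SlopeInference(slopes, participants, float(t), dof, p,
                              (float(ci[0]), float(ci[1])), degenerate=True)
    res = stats.ttest_1samp(slopes, 0.0, alternative="greater")
    half = stats.t.ppf(0.975, dof) * sd / np.sqrt(n)
    return SlopeInference(slopes, participants, float(res.statistic), dof,
                          float(res.pvalue),
                          (float(mean - half), float(mean + half)))


def bin_free_motion(segments: pd.DataFrame,
                    bin_centers=DESIGN_FREQUENCIES) -> pd.DataFrame:
    """Bin free-motion half-cycles at the design frequencies.

    ``segments`` carries a measured ``frequency`` column (0.5 / half-cycle
    duration) and ``is_cc``. Bin edges sit midway between centers; the
    outer bins are open-ended, so every segment lands in some bin.
    """
    centers = np.asarray(bin_centers, dtype=float)
    edges = (centers[:-1] + centers[1:]) / 2.0
    df = segments[segments["is_cc"].notna()].copy()
    df["is_cc"] = df["is_cc"].astype(bool)
    df["bin"] = centers[np.digitize(df["frequency"].to_numpy(), edges)]
    agg = (df.groupby("bin", observed=True)["is_cc"]
             .agg(probability="mean", n_segments="size").reset_index())
    agg = (agg.set_index("bin").reindex(pd.Index(centers, name="bin"))
              .reset_index())
    agg["n_segments"] = agg["n_segments"].fillna(0).astype(int)
    return agg


def mixed_anova(data: pd.DataFrame, dv: str = "probability",
                within: str = "frequency", between: str = "experiment",
                subject: str = "participant") -> AnovaResult:
    """Mixed (split-plot) ANOVA with Tukey HSD on the between factor.

    Subjects missing any within-factor cell are excluded listwise with a
    warning. Effects whose sum of squares is exactly zero report F = 0
    (rather than the 0/0 NaN of a fully degenerate design).
    """
    df = data[[subject, between, within, dv]].dropna().copy()
    levels = sorted(df[within].unique())
    counts = df.groupby(subject)[within].nunique()
    complete = counts[counts == len(levels)].index
    dropped = set(df[subject].unique()) - set(complete)
    if dropped:
        warnings.warn(f"excluding {len(dropped)} subject(s) with missing "
                      f"{within} cells", stacklevel=2)
        df = df[df[subject].isin(complete)]

    if len(levels) == 1:
        # Single within-level: the design collapses to a one-way
        # between-subjects ANOVA on the between factor.
        aov = pg.anova(data=df, dv=dv, between=between, detailed=True)
        aov = aov[aov["Source"] != "Residual"].copy()
        aov["DF1"] = aov.pop("DF")
    else:
        aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                             between=between)
    aov = aov.rename(columns={"p_unc": "p-unc"})
    if "SS" in aov.columns:
        zero_ss = aov["SS"].abs() < 1e-12
        aov.loc[zero_ss, "F"] = 0.0
        aov.loc[zero_ss, "p-unc"] = 1.0

    subj_means = df.groupby([subject, between], observed=True)[dv].mean().reset_index()
    if subj_means[between].nunique() >= 2:
        tk = pairwise_tukeyhsd(subj_means[dv], subj_means[between])
        tukey = pd.DataFrame(tk.summary().data[1:],
                             columns=tk.summary().data[0])
    else:
        tukey = pd.DataFrame()
    return AnovaResult(anova=aov, tukey=tukey)
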