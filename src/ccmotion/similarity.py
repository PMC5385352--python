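"""Cross-participant similarity of CC placement, with a shuffled null.

Every stimulus section yields one binary CC vector per participant (1 where
the sample lies inside a detected CC segment). The distance score of a
section is the mean pairwise Hamming distance over all unordered pairs of
participants (153 pairs for N = 18). Stimulus-locked CC placement makes
real scores low; the null destroys the trial identity while preserving the
section position: for each participant the vector is re-drawn from the same
section index (first/second/final) of a uniformly random trial. Scores are
averaged over shuffles, aggregated to per-trial means, and compared to the
real per-trial means with a matched-pair t-test.

CC vectors are exchanged as a nested mapping
``{participant: {trial: {section_index: 0/1 array}}}``; vectors within a
comparison are cropped to their common prefix (sections at the same index
can differ in length across trials).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SimilarityResult",
    "hamming",
    "distance_score",
    "real_scores",
    "shuffle_null",
    "compare_real_vs_null",
    "similarity_analysis",
]

CCVectors = dict  # participant -> trial -> section_index -> np.ndarray


@dataclass
class SimilarityResult:
    section_keys: list          # (trial, section_index) per score
    real_scores: np.ndarray     # per-section mean pairwise Hamming, in [0, 1]
    null_scores: np.ndarray     # per-section shuffle means
    real_trial_means: pd.Series
    null_trial_means: pd.Series
    t_statistic: float
    df: int
    p_value: float
    ci95: tuple[float, float]   # on the mean (real - null) difference
    degenerate: bool = False    # zero-variance difference


def hamming(a, b) -> float:
    """Fraction of positions that differ between two equal-length binary
    vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("CC vectors must have equal length")
    if len(a) == 0:
        raise ValueError("empty CC vector")
    return float(np.mean(a != b))


def distance_score(matrix) -> float:
    """Mean pairwise Hamming distance over rows (participants x samples)."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two participants")
    n = m.shape[0]
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.mean(m[i] != m[j])
            count += 1
    return float(total / count)


def _layout(cc_vectors: CCVectors):
    """Participants, trials and section indices present in the mapping."""
    participants = sorted(cc_vectors)
    trials = sorted({t for p in participants for t in cc_vectors[p]})
    k_indices = sorted({k for p in participants for t in cc_vectors[p]
                        for k in cc_vectors[p][t]})
    return participants, trials, k_indices


def real_scores(cc_vectors: CCVectors) -> tuple[list, np.ndarray]:
    """Per-section distance scores of the real data.

    Sections are keyed ``(trial, section_index)``; participants missing a
    vector for a section are excluded from that section with a warning.
    """
    participants, trials, k_indices = _layout(cc_vectors)
    keys, scores = [], []
    for t in trials:
        for k in k_indices:
            rows = []
            missing = []
            for p in participants:
                vec = cc_vectors.get(p, {}).get(t, {}).get(k)
                if vec is not None:
                    rows.append(np.asarray(vec, dtype=np.uint8))
                else:
                    missing.append(p)
            if rows and missing:
                # Two-section trials simply lack a final third for everyone;
                # only a partial hole is worth flagging.
                warnings.warn(f"participants {missing!r} missing section "
                              f"(trial {t}, index {k})", stacklevel=2)
            if len(rows) < 2:
                continue
            n = min(len(r) for r in rows)
            keys.append((t, k))
            scores.append(distance_score(np.stack([r[:n] for r in rows])))
    return keys, np.asarray(scores)


def _pair_tables(cc_vectors: CCVectors):
    """Precomputed Hamming fractions for every cross-participant,
    cross-trial vector pair at each section index.

    Returns ``{k: (trials_k, F_k)}`` where ``F_k[p, a, q, b]`` is the
    Hamming fraction between participant p's vector from ``trials_k[a]``
    and participant q's vector from ``trials_k[b]``, cropped to the common
    prefix. Makes each shuffle an exact table lookup.
    """
    participants, trials, k_indices = _layout(cc_vectors)
    n_p = len(participants)
    tables = {}
    for k in k_indices:
        trials_k = [t for t in trials
                    if all(k in cc_vectors[p].get(t, {}) for p in participants)]
        if not trials_k:
            continue
        vecs = [[np.asarray(cc_vectors[p][t][k], dtype=np.float64)
                 for t in trials_k] for p in participants]
        n_t = len(trials_k)
        F = np.zeros((n_p, n_t, n_p, n_t))
        for a in range(n_t):
            for b in range(n_t):
                length = min(len(vecs[0][a]), len(vecs[0][b]))
                A = np.stack([vecs[p][a][:length] for p in range(n_p)])
                B = np.stack([vecs[p][b][:length] for p in range(n_p)])
                # mismatches = a(1-b) + (1-a)b, summed over samples
                mism = A @ (1.0 - B.T) + (1.0 - A) @ B.T
                F[:, a, :, b] = mism / length
        tables[k] = (trials_k, F)
    return participants, trials, tables


def shuffle_null(cc_vectors: CCVectors, n_shuffles: int = 10_000,
                 seed: int = 0) -> tuple[list, np.ndarray]:
    """Mean per-section distance scores under trial shuffling.

    Per shuffle and per section, each participant's CC vector is replaced
    by their vector from a uniformly random trial *at the same section
    index*; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    participants, trials, tables = _pair_tables(cc_vectors)
    n_p = len(participants)
    pairs = [(i, j) for i in range(n_p) for j in range(i + 1, n_p)]
    keys, nulls = [], []
    for t in trials:
        for k in sorted(tables):
            trials_k, F = tables[k]
            if t not in trials_k:
                continue
            draws = rng.integers(0, len(trials_k), size=(n_shuffles, n_p))
            acc = np.zeros(n_shuffles)
            for i, j in pairs:
                acc += F[i, draws[:, i], j, draws[:, j]]
            keys.append((t, k))
            nulls.append(float(np.mean(acc / len(pairs))))
    return keys, np.asarray(nulls)


def compare_real_vs_null(real: np.ndarray, null: np.ndarray,
                         section_keys: list) -> SimilarityResult:
    """Matched-pair t-test of real vs shuffled distance scores.

    Section scores are averaged within trial first (11 matched pairs for
    the built-in design, df = 10), then compared two-sided.
    """
    trials = [t for t, _ in section_keys]
    df_scores = pd.DataFrame({"trial": trials, "real": real, "null": null})
    by_trial = df_scores.groupby("trial").mean()
    diff = by_trial["real"] - by_trial["null"]
    n = len(diff)
    dof = n - 1
    sd = diff.std(ddof=1)
    # A constant difference leaves only floating-point cancellation noise.
    tol = 1e-12 * max(1.0, abs(float(diff.mean())))
    degenerate = bool(sd <= tol or np.isnan(sd))
    if degenerate:
        tstat = 0.0 if np.allclose(diff, 0) else np.inf * np.sign(diff.mean())
        p = 1.0 if tstat == 0 else 0.0
        ci = (float(diff.mean()), float(diff.mean()))
        warnings.warn("zero-variance real-null difference; t undefined",
                      stacklevel=2)
    else:
        res = stats.ttest_rel(by_trial["real"], by_trial["null"])
        tstat, p = float(res.statistic), float(res.pvalue)
        half = stats.t.ppf(0.975, dof) * sd / np.sqrt(n)
        ci = (float(diff.mean() - half), float(diff.mean() + half))
    return SimilarityResult(
        section_keys=section_keys, real_scores=np.asarray(real),
        null_scores=np.asarray(null), real_trial_means=by_trial["real"],
        null_trial_means=by_trial["null"], t_statistic=float(tstat), df=dof,
        p_value=p, ci95=ci, degenerate=degenerate)


def similarity_analysis(cc_vectors: CCVectors, n_shuffles: int = 10_000,
                        seed: int = 0) -> SimilarityResult:
    """Real scores, shuffled null and the matched-pair test, end to end."""
    keys_r, real = real_scores(cc_vectors)
    keys_n, null = shuffle_null(cc_vectors, n_shuffles=n_shuffles, seed=seed)
    if keys_r != keys_n:
        # Align on the common sections (participants with missing sections).
        common = [k for k in keys_r if k in set(keys_n)]
        real = np.array([real[keys_r.index(k)] for k in common])
        null = np.array([null[keys_n.index(k)] for k in common])
        keys_r = common
    return compare_real_vs_null(real, null, keys_r)
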