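"""Blot normalization, significance scoring, discretization, and prizes.

Raw band intensities are background-corrected, normalized to a loading
control (GAPDH in the motivating experiments), and expressed as fold change
from time zero. Evidence of temporal change is scored with paired Student's
t-tests at each time point against both time zero ("firstscores") and the
preceding point ("prevscores"); p <= 0.05 counts as significant, with no
multiple-testing correction. States are discretized per time point and
protein prizes for subnetwork extraction are -log10 of the best p-value.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import (
    ACTIVATED,
    INACTIVE,
    INHIBITED,
    ActivityProfile,
    PhosphoDataset,
    PhosphoTimeSeries,
    SignificanceScores,
)
from .errors import DataError

DEFAULT_THRESHOLD = 0.05
#: Prize assigned when the best p-value is exactly 0 (degenerate t-test).
MAX_PRIZE = 16.0


def normalize_blots(
    raw: np.ndarray,
    loading: np.ndarray,
    background: float | np.ndarray = 0.0,
    protein: str = "protein",
    time_grid: tuple[int, ...] | None = None,
) -> PhosphoTimeSeries:
    """Fold change from basal level after loading-control normalization.

    ``raw`` and ``loading`` are replicate x time intensity matrices sharing
    one layout; ``background`` is subtracted from every band (scalar or a
    matching array). Each replicate is normalized to the loading control,
    then to its own time-zero value, so output[:, 0] == 1 exactly.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    loading = np.atleast_2d(np.asarray(loading, dtype=float))
    if raw.shape != loading.shape:
        raise DataError(f"{protein}: raw and loading shapes differ")
    r = raw - background
    l = loading - background
    if np.any(r <= 0) or np.any(l <= 0):
        rep, t = np.argwhere((r <= 0) | (l <= 0))[0]
        raise DataError(
            f"{protein}: non-positive background-corrected signal "
            f"(replicate {rep}, band {t})"
        )
    ratio = r / l
    fold = ratio / ratio[:, [0]]
    fold[:, 0] = 1.0  # exact, not merely up to rounding
    if time_grid is None:
        time_grid = tuple(range(fold.shape[1]))  # placeholder indices as minutes
    return PhosphoTimeSeries(protein, time_grid, fold)


def paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, str | None]:
    """Two-sided paired Student's t-test; returns (p, flag).

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y, sample (n-1) sd, df = n-1.
    Degenerate cases follow fixed conventions: all differences zero -> p = 1
    (flag 'zero-diff'); zero sd with nonzero mean -> p = 0, the limit of a
    diverging t statistic (flag 'zero-sd').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("paired t-test needs equal-length vectors")
    n = x.size
    if n < 2:
        raise DataError("paired t-test needs n >= 2")
    d = x - y
    if np.all(d == 0):
        return 1.0, "zero-diff"
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, "zero-sd"
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(min(p, 1.0)), None


def compute_significance(
    ts: PhosphoTimeSeries, threshold: float = DEFAULT_THRESHOLD
) -> SignificanceScores:
    """firstscores and prevscores for one protein (T-1 values each)."""
    if ts.n_replicates < 2:
        raise DataError(f"{ts.protein}: significance scoring needs >= 2 replicates")
    T = len(ts.time_grid)
    first = np.empty(T - 1)
    prev = np.empty(T - 1)
    flags: dict[str, list[int]] = {}
    for k in range(1, T):
        p_first, f1 = paired_ttest(ts.values[:, k], ts.values[:, 0])
        p_prev, f2 = paired_ttest(ts.values[:, k], ts.values[:, k - 1])
        first[k - 1] = p_first
        prev[k - 1] = p_prev
        for f in (f1, f2):
            if f:
                flags.setdefault(f, []).append(k)
    return SignificanceScores(ts.protein, first, prev, threshold, flags)


def discretize_activity(
    ts: PhosphoTimeSeries, scores: SignificanceScores
) -> ActivityProfile:
    """Per-time activity state from significance and change direction.

    Time point t > 0 is 'activated' when either test fires (p <= threshold)
    and the mean fold change rose relative to the fired test's reference
    point, 'inhibited' when it fell, 'inactive' otherwise. Time zero is
    always 'inactive' (it is the reference).
    """
    means = ts.values.mean(axis=0)
    states = [INACTIVE]
    thr = scores.threshold
    for k in range(1, len(ts.time_grid)):
        p_first = scores.firstscores[k - 1]
        p_prev = scores.prevscores[k - 1]
        if min(p_first, p_prev) > thr:
            states.append(INACTIVE)
            continue
        ref = 0 if p_first <= p_prev else k - 1  # direction from the stronger test
        if means[k] > means[ref]:
            states.append(ACTIVATED)
        elif means[k] < means[ref]:
            states.append(INHIBITED)
        else:
            states.append(INACTIVE)
    return ActivityProfile(ts.protein, ts.time_grid, tuple(states))


def compute_prizes(
    all_scores: dict[str, SignificanceScores],
    max_prize: float = MAX_PRIZE,
) -> dict[str, float]:
    """Protein prizes: -log10 of the best p-value over both score tracks.

    Monotone in evidence, floored at 0, capped at ``max_prize`` for p = 0.
    Proteins without scores (unmeasured) simply have no entry, which every
    consumer treats as prize 0.
    """
    prizes = {}
    for prot, sc in all_scores.items():
        p = sc.min_p()
        prize = max_prize if p == 0 else min(max(-np.log10(p), 0.0), max_prize)
        prizes[prot] = float(prize)
    return prizes


def preprocess_dataset(
    data: PhosphoDataset, threshold: float = DEFAULT_THRESHOLD
) -> tuple[dict[str, SignificanceScores], dict[str, ActivityProfile], dict[str, float]]:
    """Scores, activity profiles and prizes for every measured protein."""
    scores = {p: compute_significance(data[p], threshold) for p in data.proteins()}
    profiles = {p: discretize_activity(data[p], scores[p]) for p in data.proteins()}
    prizes = compute_prizes(scores)
    return scores, profiles, prizes
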