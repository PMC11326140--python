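"""Validation against independent inhibitor and permeability data.

Two arms mirror the two network strategies. The phospho-network arm scores
each kinase inhibitor by its cumulative inhibition over the network's
kinases (sum of 100 - residual activity) and predicts a permeability
perturbation when that score clears a cutoff equivalent to a quarter of the
network's kinases being half-inhibited; predictions are checked against a
permeability screen. The functional-model arm predicts, per kinase and time
point, whether any associated pathway is active within a closed 10-minute
window centered on the time point, and checks predictions against
differential phosphorylation. Agreement is counted over positive
predictions only (precision); a full confusion matrix is also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import (
    InhibitionMatrix,
    PermeabilityScreen,
    PhosphoDataset,
    TrekingModel,
)
from .errors import ConfigError, DataError


@dataclass
class ValidationConfig:
    """Thresholds of the two detection rules.

    inhibition_threshold: percent inhibition counting a kinase as hit (50);
    network_fraction: fraction of network kinases whose half-inhibition sets
    the perturbation cutoff (0.25); p_threshold: t-test significance (0.05);
    auc_change_threshold: percent AUC change every replicate must exceed
    (10); fold_change_threshold: percent fold change every replicate must
    reach (20); window: minutes, total width of the closed prediction
    window (10); clamp_negative: clamp per-kinase inhibition below 0 (off by
    default — the literal cumulative sum is used).
    """

    inhibition_threshold: float = 50.0
    network_fraction: float = 0.25
    p_threshold: float = 0.05
    auc_change_threshold: float = 10.0
    fold_change_threshold: float = 20.0
    window: float = 10.0
    clamp_negative: bool = False

    def __post_init__(self) -> None:
        for name in ("inhibition_threshold", "p_threshold",
                     "auc_change_threshold", "fold_change_threshold", "window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.network_fraction <= 1:
            raise ConfigError("network_fraction must be in (0,1]")


def cumulative_inhibition(
    network_kinases: set[str],
    matrix: InhibitionMatrix,
    compound: str,
    cfg: ValidationConfig | None = None,
) -> float:
    """Sum of percent inhibition over network kinases present in the matrix.

    Kinases absent from the matrix (or unassayed for this compound) are
    skipped. By default the literal sum is used, so residual activity above
    100 contributes negatively; clamp_negative floors each term at 0.
    """
    cfg = cfg or ValidationConfig()
    if compound not in matrix.compounds:
        raise DataError(f"unknown compound {compound}")
    total = 0.0
    for k in network_kinases:
        r = matrix.residual(k, compound)
        if np.isnan(r):
            continue
        inh = 100.0 - r
        if cfg.clamp_negative:
            inh = max(inh, 0.0)
        total += inh
    return total


def perturbation_cutoff(n_network_kinases: int, cfg: ValidationConfig | None = None) -> float:
    """Cumulative-inhibition cutoff: network_fraction x n x inhibition_threshold.

    A compound is predicted to perturb the phenotype only when its score is
    strictly above this cutoff.
    """
    cfg = cfg or ValidationConfig()
    if n_network_kinases < 1:
        raise ConfigError("need at least one network kinase")
    return cfg.network_fraction * n_network_kinases * cfg.inhibition_threshold


def permeability_differs(
    compound_auc: np.ndarray,
    dmso_auc: np.ndarray,
    cfg: ValidationConfig | None = None,
) -> bool:
    """Does the compound's permeability differ from the DMSO control?

    True when the unpaired two-sample t-test gives p < 0.05 OR every
    replicate's percent AUC change versus the mean DMSO exceeds +10% (all)
    or falls below -10% (all). Mixed directions never satisfy the second
    clause. Degenerate variance falls back to the effect-size clause only.
    """
    cfg = cfg or ValidationConfig()
    x = np.asarray(compound_auc, float)
    y = np.asarray(dmso_auc, float)
    if x.size < 2 or y.size < 2:
        raise DataError("need >= 2 replicates per condition")
    if np.std(x) == 0 and np.std(y) == 0:
        warnings.warn("degenerate variance; using effect-size clause only")
    else:
        p = stats.ttest_ind(x, y).pvalue
        if p < cfg.p_threshold:
            return True
    change = 100.0 * (x - y.mean()) / y.mean()
    thr = cfg.auc_change_threshold
    return bool(np.all(change > thr) or np.all(change < -thr))


def phospho_differs(
    fold_changes: np.ndarray,
    cfg: ValidationConfig | None = None,
) -> bool:
    """Does phosphorylation at this time point differ from the untreated level?

    ``fold_changes`` are the replicates' fold changes versus the untreated
    baseline (so the null value is 1). True when the one-sample t-test
    against 1 gives p < 0.05 OR all replicates are >= 1.2 OR all <= 0.8
    (boundaries inclusive).
    """
    cfg = cfg or ValidationConfig()
    x = np.asarray(fold_changes, float)
    if x.size < 2:
        raise DataError("need >= 2 replicates")
    lo = 1.0 - cfg.fold_change_threshold / 100.0
    hi = 1.0 + cfg.fold_change_threshold / 100.0
    if np.all(x >= hi) or np.all(x <= lo):
        return True
    if np.std(x, ddof=1) == 0:
        return False  # identical replicates inside the band: no evidence
    p = stats.ttest_1samp(x, 1.0).pvalue
    return bool(p < cfg.p_threshold)


def treking_predict_active(
    model: TrekingModel,
    kinase: str,
    t: float,
    cfg: ValidationConfig | None = None,
) -> bool:
    """Is any pathway containing the kinase active in the closed window
    [t - w/2, t + w/2]?"""
    cfg = cfg or ValidationConfig()
    if kinase not in model.intervals:
        warnings.warn(f"kinase {kinase} not in functional model")
        return False
    half = cfg.window / 2.0
    lo, hi = t - half, t + half
    return any(start <= hi and end >= lo for start, end in model.intervals[kinase])


def prediction_accuracy(
    predicted_positive: set, measured_positive: set, universe: set | None = None
) -> dict:
    """Precision of positive predictions, with counts.

    accuracy = |predicted ∩ measured| / |predicted|; None when nothing was
    predicted. When ``universe`` is given a full confusion matrix over it is
    included.
    """
    n_pred = len(predicted_positive)
    n_agree = len(predicted_positive & measured_positive)
    report = {
        "n_predicted": n_pred,
        "n_agree": n_agree,
        "accuracy": (n_agree / n_pred) if n_pred else None,
        "accuracy_pct": (round(100.0 * n_agree / n_pred, 1) if n_pred else None),
    }
    if universe is not None:
        tp = n_agree
        fp = n_pred - n_agree
        fn = len(measured_positive - predicted_positive)
        tn = len(universe) - tp - fp - fn
        report["confusion"] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return report


def validate_tps_arm(
    network_kinases: set[str],
    matrix: InhibitionMatrix,
    screen: PermeabilityScreen,
    cfg: ValidationConfig | None = None,
) -> dict:
    """Compound-level validation of a phospho-derived network.

    Compounds below the cumulative-inhibition cutoff are abstentions: no
    prediction is made and they enter neither numerator nor denominator.
    """
    cfg = cfg or ValidationConfig()
    cutoff = perturbation_cutoff(max(len(network_kinases), 1), cfg)
    scores = {
        c: cumulative_inhibition(network_kinases, matrix, c, cfg)
        for c in matrix.compounds
    }
    predicted = {c for c, s in scores.items() if s > cutoff}
    measured = {
        c for c in screen.compounds()
        if permeability_differs(screen.compound_auc[c], screen.dmso_auc, cfg)
    }
    report = prediction_accuracy(predicted, measured, set(matrix.compounds))
    report.update(
        cutoff=cutoff,
        n_network_kinases=len(network_kinases),
        scores=scores,
        predicted=sorted(predicted),
        measured_positive=sorted(measured),
    )
    return report


def validate_treking_arm(
    model: TrekingModel,
    data: PhosphoDataset,
    cfg: ValidationConfig | None = None,
) -> dict:
    """Kinase x time validation of a functional model against phospho data.

    Instances are (kinase, t) pairs over the measured kinases and the grid
    (t > 0). Predicted-positive instances are checked for differential
    phosphorylation; the accuracy is precision over positive predictions.
    """
    cfg = cfg or ValidationConfig()
    instances = [
        (k, t)
        for k in model.kinases()
        if k in data
        for t in data.time_grid[1:]
    ]
    predicted = {
        (k, t) for k, t in instances if treking_predict_active(model, k, t, cfg)
    }
    measured = set()
    for k, t in instances:
        ts = data[k]
        col = ts.time_grid.index(t)
        if phospho_differs(ts.values[:, col], cfg):
            measured.add((k, t))
    report = prediction_accuracy(predicted, measured, set(instances))
    report.update(
        n_instances=len(instances),
        predicted=sorted(predicted),
        measured_positive=sorted(measured),
    )
    return report
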