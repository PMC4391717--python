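"""Cross-validated model evaluation and decision-threshold selection.

Presence-only models have no true absences, so the background sample acts
as the negative class for every metric here: AUC (the Mann-Whitney
probability that a presence site outscores a background site, ties counted
half), COR (the point-biserial correlation between scores and 0/1 labels),
and Cohen's Kappa of the thresholded prediction against the labels.

Three threshold rules convert the continuous suitability into binary maps,
each selected from the observed scores themselves (exact and scale-free):

* ``T1`` — sensitivity = specificity (minimizes |sens - spec|);
* ``T2`` — Youden's J maximum (maximizes sens + spec - 1);
* ``T3`` — predicted prevalence = observed prevalence.

Ties between candidate thresholds break toward the lower (more inclusive)
candidate.  A score equal to the threshold predicts presence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from .exceptions import InputError
from .io import swd_split
from .maxent import FeatureSet, MaxentModel, fit_maxent

RULES = ("T1_sens_eq_spec", "T2_youden", "T3_prevalence")
_RULE_ALIASES = {"T1": RULES[0], "T2": RULES[1], "T3": RULES[2]}


def canonical_rule(rule: str) -> str:
    rule = _RULE_ALIASES.get(rule, rule)
    if rule not in RULES:
        raise InputError(f"unknown threshold rule {rule!r}")
    return rule


@dataclass(frozen=True)
class MetricValues:
    auc: float
    cor: float
    kappa: float


@dataclass
class EvalMetrics:
    """Per-fold metric values with mean/SD summaries."""

    per_fold: list[MetricValues] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.per_fold)

    def _series(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.per_fold], dtype=float)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self._series(name)))

    def sd(self, name: str) -> float:
        return float(np.nanstd(self._series(name), ddof=1))

    def to_row(self) -> dict[str, str]:
        """Mean (SD) formatting, e.g. ``0.876 (0.05)``."""
        return {
            name.upper(): f"{self.mean(name):.3f} ({self.sd(name):.2f})"
            for name in ("auc", "cor", "kappa")
        }


@dataclass(frozen=True)
class ThresholdChoice:
    rule: str
    value: float


def cv_folds(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random near-equal partition of ``n`` items into ``k`` folds.

    Returns an integer fold id per item; deterministic given ``seed``.
    """
    if n < k:
        raise InputError(f"cannot split {n} presences into {k} folds")
    rng = np.random.default_rng(seed)
    ids = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    return ids[rng.permutation(n)]


def compute_metrics(pres_scores, bg_scores, threshold: float) -> MetricValues:
    """AUC, point-biserial COR and Kappa for presence vs background scores.

    ``score >= threshold`` predicts presence.  COR is NaN when the pooled
    scores have zero variance.
    """
    pres = np.asarray(pres_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise InputError("both score lists must be non-empty")
    labels = np.concatenate([np.ones(pres.size), np.zeros(bg.size)])
    scores = np.concatenate([pres, bg])
    auc = float(roc_auc_score(labels, scores))
    if np.ptp(scores) == 0:
        cor = float("nan")
    else:
        cor = float(stats.pearsonr(scores, labels).statistic)
    predicted = (scores >= threshold).astype(int)
    kappa = float(cohen_kappa_score(labels.astype(int), predicted))
    return MetricValues(auc=auc, cor=cor, kappa=kappa)


def _confusion_counts(pres: np.ndarray, bg: np.ndarray, candidates: np.ndarray):
    """True-positive and false-positive counts at each candidate threshold
    (score >= t predicts presence); integer-exact."""
    ps = np.sort(pres)
    bs = np.sort(bg)
    tp = ps.size - np.searchsorted(ps, candidates, side="left")
    fp = bs.size - np.searchsorted(bs, candidates, side="left")
    return tp, fp


def select_threshold(pres_scores, bg_scores, rule: str) -> ThresholdChoice:
    """Pick a decision threshold from the pooled observed scores.

    Candidates are the sorted unique pooled scores; ties between equally
    good candidates break toward the lower one.
    """
    rule = canonical_rule(rule)
    pres = np.asarray(pres_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise InputError("both score lists must be non-empty")
    candidates = np.unique(np.concatenate([pres, bg]))
    tp, fp = _confusion_counts(pres, bg, candidates)
    n_p, n_b = pres.size, bg.size
    # sens = tp/n_p, spec = 1 - fp/n_b; criteria are rational with fixed
    # denominators, so compare them as exact integers to make tie-breaks
    # immune to floating-point rounding
    if rule == "T1_sens_eq_spec":
        crit = np.abs(tp * n_b - (n_b - fp) * n_p)  # |sens - spec| * n_p*n_b
    elif rule == "T2_youden":
        crit = -(tp * n_b - fp * n_p)  # -(sens + spec - 1) * n_p*n_b
    else:
        crit = np.abs(tp + fp - n_p)  # |pred_prev - obs_prev| * (n_p+n_b)
    best = int(np.argmin(crit))  # argmin takes the first (lowest) candidate
    return ThresholdChoice(rule=rule, value=float(candidates[best]))


def evaluate_run(
    swd: pd.DataFrame,
    fs: FeatureSet,
    rule: str,
    k: int = 5,
    seed: int = 0,
    beta0: float = 0.25,
) -> tuple[MaxentModel, ThresholdChoice, EvalMetrics]:
    """Five-fold cross-validated evaluation plus a final full-data fit.

    Presences are partitioned into ``k`` folds (background rows are shared
    across folds); AUC and COR are computed on each held-out fold.  The
    final model and its threshold come from a fit on all data, and per-fold
    Kappa is evaluated on held-out scores at that final threshold.
    """
    rule = canonical_rule(rule)
    pres, bg = swd_split(swd)
    if len(pres) < k:
        raise InputError(f"{len(pres)} presences cannot fill {k} folds")
    folds = cv_folds(len(pres), k=k, seed=seed)

    full_model = fit_maxent(swd, fs, beta0=beta0)
    full_pres_scores = full_model.score_table(pres, scale="logistic")
    bg_scores_full = full_model.score_table(bg, scale="logistic")
    choice = select_threshold(full_pres_scores, bg_scores_full, rule)

    metrics = EvalMetrics()
    for f in range(k):
        train = pres[folds != f]
        test = pres[folds == f]
        model_f = fit_maxent(pd.concat([train, bg]), fs, beta0=beta0)
        test_scores = model_f.score_table(test, scale="logistic")
        bg_scores = model_f.score_table(bg, scale="logistic")
        metrics.per_fold.append(compute_metrics(test_scores, bg_scores, choice.value))
    return full_model, choice, metrics
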