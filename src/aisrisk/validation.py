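"""Model selection and performance estimation.

Two schemes mirror how surveillance data accrue:

* **True (temporal) validation** — fit the co-kriging model on the
  infestations reported by the first census, then test on the waterbodies
  newly reported by the second census.  Waterbodies already infested at the
  first census are excluded from the test set; negatives are waterbodies
  never reported infested (an assumption — under-reporting makes some of
  them false negatives, but no other convention is computable from
  presence-only surveillance).

* **k-fold cross-validation** — infested locations are partitioned into k
  seeded folds; each fold is withheld from the fitting data and scored by
  the model fit on the remainder (80/20 at k = 5).  Variogram parameters are
  fit once on the full data and held fixed across folds.

Discrimination is summarized by the AUC (Mann–Whitney concordance) and by
sensitivity/specificity at a threshold risk rank (default 3, intermediate).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._rng import stream
from .covariates import VARIABLES
from .errors import EmptyInputError, InsufficientDataError, UndefinedMetricError
from .modeling import KrigingSpec, build_data, fit_model, score_waterbodies
from .ranking import RiskRanking, rank_by_quantiles

__all__ = [
    "ValidationReport",
    "ModelSelectionResult",
    "roc_auc",
    "sens_spec_at_rank",
    "true_validation",
    "kfold_cv",
    "select_model",
]


@dataclass(frozen=True)
class ValidationReport:
    """AUC and threshold-rank sensitivity/specificity for one model."""

    scheme: str  # "true_validation" | "kfold"
    primary: str
    secondaries: tuple[str, ...]
    auc: float
    sensitivity: float
    specificity: float
    threshold_rank: int
    n_test: int
    n_positive: int
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "primary": self.primary,
            "secondaries": list(self.secondaries),
            "auc": self.auc,
            "sensitivity_at_rank": self.sensitivity,
            "specificity_at_rank": self.specificity,
            "threshold_rank": self.threshold_rank,
            "n_test": self.n_test,
            "n_positive": self.n_positive,
            **({"folds": self.details["folds"]} if "folds" in self.details else {}),
        }


@dataclass(frozen=True)
class ModelSelectionResult:
    """AUC of every evaluated secondary pair and the winning pair."""

    primary: str
    evaluated: dict[tuple[str, str], float]
    chosen: tuple[str, str]

    @property
    def chosen_auc(self) -> float:
        return self.evaluated[self.chosen]


def roc_auc(scores, labels) -> float:
    """AUC as the Mann–Whitney concordance probability (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sens_spec_at_rank(
    ranks, labels, rank: int | None = 3
) -> tuple[float, float, int]:
    """Sensitivity and specificity with predicted-positive = rank >= threshold.

    ``rank=None`` scans ranks 1..max and returns the threshold maximizing
    Youden's J = sensitivity + specificity - 1 (ties go to the lower rank).
    Returns (sensitivity, specificity, threshold_rank).
    """
    ranks = np.asarray(ranks).astype(int)
    labels = np.asarray(labels).astype(int)
    if len(ranks) != len(labels):
        raise UndefinedMetricError("ranks and labels must align")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("metrics need both classes present")

    def at(thr: int) -> tuple[float, float]:
        predicted = ranks >= thr
        tp = int((predicted & (labels == 1)).sum())
        tn = int((~predicted & (labels == 0)).sum())
        return tp / n_pos, tn / n_neg

    if rank is not None:
        sens, spec = at(rank)
        return sens, spec, rank
    best = None
    for thr in range(1, int(ranks.max()) + 1):
        sens, spec = at(thr)
        j = sens + spec - 1.0
        if best is None or j > best[0]:
            best = (j, thr, sens, spec)
    _, thr, sens, spec = best
    return sens, spec, thr


def _metrics(scores: pd.Series, labels: pd.Series, threshold_rank: int):
    auc = roc_auc(scores.to_numpy(), labels.to_numpy())
    ranking = rank_by_quantiles(scores.index, scores.to_numpy())
    sens, spec, thr = sens_spec_at_rank(
        ranking.ranks, labels.to_numpy(), threshold_rank
    )
    return auc, sens, spec, thr


def true_validation(
    table_t1: pd.DataFrame,
    table_t2: pd.DataFrame,
    spec: KrigingSpec,
    threshold_rank: int = 3,
) -> ValidationReport:
    """Fit on census-1 reports, test on the waterbodies newly reported by
    census 2.

    The test set is every waterbody *not* infested at census 1; its label is
    its census-2 status.  Each test waterbody is scored leave-one-out (its
    own indicator-0 datum removed), so its own absence of a report cannot
    vote it down.
    """
    t1 = table_t1.set_index("id")
    t2 = table_t2.set_index("id")
    if set(t1.index) != set(t2.index):
        raise UndefinedMetricError("census tables cover different waterbody sets")
    model = fit_model(table_t1, spec)
    test_ids = t1.index[t1[spec.primary] == 0]
    if len(test_ids) == 0:
        raise UndefinedMetricError("no susceptible waterbodies to test on")
    labels = t2.loc[test_ids, spec.primary].astype(int)
    if labels.nunique() < 2:
        raise UndefinedMetricError("no new invasions between censuses")
    scores = score_waterbodies(table_t1, model, spec, target_ids=test_ids)
    scores = scores.loc[labels.index]
    auc, sens, spec_, thr = _metrics(scores, labels, threshold_rank)
    return ValidationReport(
        scheme="true_validation",
        primary=spec.primary,
        secondaries=spec.secondaries,
        auc=auc,
        sensitivity=sens,
        specificity=spec_,
        threshold_rank=thr,
        n_test=len(labels),
        n_positive=int(labels.sum()),
        details={"scores": scores, "labels": labels},
    )


def make_folds(ids, k: int, seed: int) -> list[list]:
    """Seeded uniform shuffle partitioned into k folds (exact partition;
    remainder items go one-per-fold to the first folds)."""
    ids = list(ids)
    if k < 2:
        raise InsufficientDataError("k must be >= 2")
    if len(ids) < k:
        raise InsufficientDataError(f"need >= {k} items for {k} folds")
    rng = stream(seed, "kfold")
    order = rng.permutation(len(ids))
    return [[ids[i] for i in order[f::k]] for f in range(k)]


def kfold_cv(
    table: pd.DataFrame,
    spec: KrigingSpec,
    k: int = 5,
    seed: int = 0,
    threshold_rank: int = 3,
    model=None,
) -> ValidationReport:
    """k-fold cross-validation withholding infested locations.

    Infested waterbodies are split into k seeded folds; each fold's
    indicator-1 data are removed from the fitting data and the withheld
    locations are scored by the remainder.  Never-infested waterbodies are
    scored once, leave-one-out, under the full data.  Variogram/LMC
    parameters (``model``; fit on the full table when not given, e.g. carried
    over from the true validation) are held fixed across folds.
    """
    idx = table.set_index("id")
    pos_ids = list(idx.index[idx[spec.primary] > 0])
    if len(pos_ids) < k:
        raise InsufficientDataError("fewer infested locations than folds")
    folds = make_folds(pos_ids, k, seed)
    if model is None:
        model = fit_model(table, spec)

    xy_all = table[["x", "y"]].to_numpy(float)
    pos_scores = {}
    for fold in folds:
        train_mask = ~(
            table["id"].isin(fold).to_numpy() & (table[spec.primary].to_numpy() > 0)
        )
        data = build_data(table[train_mask], spec)
        # secondaries stay fully observed: rebuild them from the full table
        for sec in spec.secondaries:
            data[sec] = (xy_all, table[sec].to_numpy(float))
        s = score_waterbodies(
            table, model, spec, target_ids=fold, data=data,
            exclude_colocated_primary=True,
        )
        pos_scores.update(s.to_dict())

    neg_ids = list(idx.index[idx[spec.primary] == 0])
    neg_scores = score_waterbodies(table, model, spec, target_ids=neg_ids)
    scores = pd.Series(
        {**pos_scores, **neg_scores.to_dict()}, dtype=float
    )
    labels = pd.Series(
        np.concatenate([np.ones(len(pos_scores), int), np.zeros(len(neg_ids), int)]),
        index=list(pos_scores) + neg_ids,
    )
    scores = scores.loc[labels.index]
    auc, sens, spec_, thr = _metrics(scores, labels, threshold_rank)
    return ValidationReport(
        scheme="kfold",
        primary=spec.primary,
        secondaries=spec.secondaries,
        auc=auc,
        sensitivity=sens,
        specificity=spec_,
        threshold_rank=thr,
        n_test=len(labels),
        n_positive=int(labels.sum()),
        details={"folds": [sorted(f) for f in folds], "k": k, "seed": seed},
    )


def select_model(
    table_t1: pd.DataFrame,
    table_t2: pd.DataFrame,
    candidates: list[str],
    base_spec: KrigingSpec,
    threshold_rank: int = 3,
) -> ModelSelectionResult:
    """Evaluate every two-way secondary combination by temporal-validation AUC.

    Candidates come from the Pearson screen (the other species' status may be
    among them).  The winning pair maximizes AUC; ties break to the
    lexicographically first pair in the fixed covariate order.
    """
    if not candidates:
        raise EmptyInputError("empty candidate set from the correlation screen")
    order = {v: i for i, v in enumerate(VARIABLES)}
    cands = sorted(set(candidates), key=lambda v: order.get(v, len(order)))
    pairs = list(itertools.combinations(cands, 2))
    if not pairs:
        raise EmptyInputError("need at least two screened candidates to form a pair")
    evaluated: dict[tuple[str, str], float] = {}
    best, best_auc = None, -np.inf
    for pair in pairs:
        report = true_validation(
            table_t1, table_t2, base_spec.with_secondaries(pair), threshold_rank
        )
        evaluated[pair] = report.auc
        if report.auc > best_auc:  # strict: earlier (lexicographic) pair wins ties
            best, best_auc = pair, report.auc
    return ModelSelectionResult(
        primary=base_spec.primary, evaluated=evaluated, chosen=best
    )
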