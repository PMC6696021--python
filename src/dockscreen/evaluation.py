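"""Evaluation suite: ROC/AUC, Matthews coefficient, top-k consensus,
threshold-robustness, and the virtual-screening mode.

AUC is computed as the midrank Mann–Whitney statistic — the probability that
a random active outranks a random inactive, with ties counted half — which
equals the trapezoidal area under the ROC curve.  Docking scores rank
*better = lower*, so callers must state the score direction explicitly.

Consensus between two receptor structures is measured on their top-k (k=100)
scored ligands: the overlap count and the Spearman rank correlation of the
shared ligands' within-top-k ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import roc_curve as _sk_roc_curve

from .ensemble_features import EnsembleFeatureMatrix, label_activity
from .models import SplitSpec, TrainedClassifier, fit_classifier, split_dataset

__all__ = [
    "RocResult",
    "OverlapResult",
    "EvaluationError",
    "roc_auc",
    "mcc",
    "confusion_counts",
    "topk_consensus",
    "consensus_frame",
    "ablate_top_k",
    "liminal_robustness",
    "screen_library",
    "evaluate_split",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class OverlapResult:
    """Top-k agreement between two structures' rankings."""

    structure_a: str
    structure_b: str
    n_common: int
    spearman_r: float | None  # None when < 2 common ligands


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[int],
            higher_is_active: bool) -> RocResult:
    """ROC curve and AUC by the midrank Mann–Whitney statistic.

    ``higher_is_active=False`` for docking scores (more negative = better);
    passing the wrong direction silently inverts the AUC, hence the flag is
    mandatory.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise EvaluationError("scores and labels must have the same length")
    classes = np.unique(y)
    if classes.size < 2:
        raise EvaluationError("both classes must be present to compute a ROC")
    if not higher_is_active:
        s = -s
    ranks = rankdata(s)                       # midranks for ties
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = _sk_roc_curve(y, s)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(auc))


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> tuple[int, int, int, int]:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())
    return tp, tn, fp, fn


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    if min(tp, tn, fp, fn) < 0:
        raise EvaluationError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# Top-k consensus across structures
# ---------------------------------------------------------------------------


def _topk(scored: Mapping[str, float], k: int, higher_is_better: bool) -> list[str]:
    """The k best ligand ids, ties broken deterministically by ligand id."""
    sign = -1.0 if higher_is_better else 1.0
    ordered = sorted(scored, key=lambda lig: (sign * scored[lig], lig))
    return ordered[:k]


def topk_consensus(rankings: Mapping[str, Mapping[str, float]], k: int = 100,
                   higher_is_better: bool = False) -> dict[tuple[str, str], OverlapResult]:
    """Pairwise top-k overlap and Spearman rank correlation.

    ``rankings`` maps structure id → {ligand id → score}; every structure
    must cover the same ligand universe.  The Spearman correlation is
    computed on the two within-top-k rank vectors restricted to the common
    ligands; with fewer than two common ligands it is flagged undefined.
    """
    structures = sorted(rankings)
    if not structures:
        raise EvaluationError("no rankings given")
    universe = set(rankings[structures[0]])
    for s in structures[1:]:
        if set(rankings[s]) != universe:
            raise EvaluationError(
                f"structure {s!r} ranks a different ligand universe"
            )
    if k > len(universe):
        raise EvaluationError(
            f"k={k} exceeds the ligand universe size {len(universe)}"
        )
    tops = {s: _topk(rankings[s], k, higher_is_better) for s in structures}
    rank_of = {s: {lig: i + 1 for i, lig in enumerate(tops[s])} for s in structures}

    out: dict[tuple[str, str], OverlapResult] = {}
    for a in structures:
        for b in structures:
            common = sorted(set(tops[a]) & set(tops[b]))
            if len(common) < 2:
                rho = None
            elif a == b:
                rho = 1.0
            else:
                ra = [rank_of[a][lig] for lig in common]
                rb = [rank_of[b][lig] for lig in common]
                rho = float(spearmanr(ra, rb).statistic)
            out[(a, b)] = OverlapResult(a, b, len(common), rho)
    return out


def consensus_frame(results: Mapping[tuple[str, str], OverlapResult]) -> pd.DataFrame:
    """Long-format table of the pairwise consensus matrix."""
    rows = [
        {"structure_a": r.structure_a, "structure_b": r.structure_b,
         "n_common": r.n_common, "spearman_r": r.spearman_r}
        for r in results.values()
    ]
    return pd.DataFrame(rows).sort_values(["structure_a", "structure_b"],
                                          ignore_index=True)


def ablate_top_k(rankings: Mapping[str, Mapping[str, float]], structure: str,
                 k: int = 100, higher_is_better: bool = False) -> set[str]:
    """Ligands in one structure's top k — the set to drop before
    re-evaluating the other structures (suspect-structure ablation)."""
    if structure not in rankings:
        raise EvaluationError(f"unknown structure {structure!r}")
    return set(_topk(rankings[structure], k, higher_is_better))


# ---------------------------------------------------------------------------
# Threshold-robustness
# ---------------------------------------------------------------------------


def _split_train_eval(kind: str, X: np.ndarray, ki: np.ndarray,
                      threshold_uM: float, spec: SplitSpec,
                      mlp_config=None) -> dict:
    y = np.array([label_activity(v, threshold_uM) for v in ki], dtype=int)
    idx_train, idx_test = split_dataset(list(range(len(y))), spec, labels=y)
    tr, te = np.asarray(idx_train), np.asarray(idx_test)
    if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
        raise EvaluationError("train or test partition lost a class")
    model = fit_classifier(kind, X[tr], y[tr], threshold_uM=threshold_uM,
                           mlp_config=mlp_config)
    probs = model.predict_proba(X[te])
    roc = roc_auc(probs, y[te], higher_is_active=True)
    pred = (probs >= 0.5).astype(int)
    return {
        "test_auc": roc.auc,
        "test_mcc": mcc(*confusion_counts(y[te], pred)),
        "n_train": int(tr.size),
        "n_test": int(te.size),
    }


def liminal_robustness(features: np.ndarray, ki_uM: Sequence[float],
                       kind: str = "lda", low_uM: float = 5.0,
                       high_uM: float = 15.0, threshold_uM: float = 10.0,
                       spec: SplitSpec = SplitSpec(), mlp_config=None) -> dict:
    """Compare metrics with and without ligands whose Ki sits near the class
    threshold (inclusive window, default 5–15 µM around 10 µM).

    Sensitivity of the metrics to these liminal ligands indicates a
    threshold-boundary bias in the model.  Both runs use the same seed.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    ki = np.asarray(ki_uM, dtype=float)
    full = _split_train_eval(kind, X, ki, threshold_uM, spec, mlp_config)
    keep = ~((ki >= low_uM) & (ki <= high_uM))
    kept_labels = np.array(
        [label_activity(v, threshold_uM) for v in ki[keep]], dtype=int)
    if np.unique(kept_labels).size < 2:
        raise EvaluationError(
            "removing liminal ligands left a single class; nothing to compare"
        )
    filtered = _split_train_eval(kind, X[keep], ki[keep], threshold_uM, spec,
                                 mlp_config)
    delta = {m: filtered[m] - full[m] for m in ("test_auc", "test_mcc")}
    return {"full": full, "filtered": filtered, "delta": delta,
            "n_removed": int((~keep).sum())}


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


def screen_library(model: TrainedClassifier,
                   library_features: EnsembleFeatureMatrix,
                   cutoff: float = 0.5) -> pd.DataFrame:
    """Rank a screening library by predicted activity probability.

    The library features must come from the same ensemble pipeline; if the
    matrix carries its own fitted scaler it must be the model's (hash check),
    since scoring with a foreign standardisation silently shifts every
    probability.
    """
    if (library_features.scaler is not None and model.scaler is not None
            and library_features.scaler.metadata_hash() != model.scaler.metadata_hash()):
        raise EvaluationError(
            "library feature scaler differs from the model's scaler"
        )
    if not library_features.ligand_ids:
        return pd.DataFrame(columns=["ligand_id", "probability", "predicted_active"])
    probs = model.predict_proba(library_features.features)
    df = pd.DataFrame({
        "ligand_id": library_features.ligand_ids,
        "probability": probs,
        "predicted_active": probs >= cutoff,
    })
    return df.sort_values(["probability", "ligand_id"],
                          ascending=[False, True], ignore_index=True)


# ---------------------------------------------------------------------------
# Composite evaluation used by the CLI and the acceptance pipeline
# ---------------------------------------------------------------------------


def evaluate_split(matrix: EnsembleFeatureMatrix, ki_by_ligand: Mapping[str, float],
                   threshold_uM: float = 10.0, kinds: Sequence[str] = ("lda", "qda", "mlp"),
                   spec: SplitSpec = SplitSpec(), cv_folds: int = 5,
                   mlp_config=None) -> dict:
    """Full per-campaign evaluation: docking-score AUCs (per structure and
    ensemble-averaged), then train/CV/test metrics for each model family."""
    missing = [lig for lig in matrix.ligand_ids if lig not in ki_by_ligand]
    if missing:
        raise EvaluationError(f"no Ki for ligand(s) {missing[:5]}")
    ki = np.array([ki_by_ligand[lig] for lig in matrix.ligand_ids], dtype=float)
    y = np.array([label_activity(v, threshold_uM) for v in ki], dtype=int)
    score_col = matrix.features[:, -1]

    out: dict = {"threshold_uM": threshold_uM, "n_ligands": len(y),
                 "n_active": int(y.sum())}
    out["ensemble_score_auc"] = roc_auc(score_col, y, higher_is_active=False).auc
    if matrix.per_structure is not None:
        out["per_structure_score_auc"] = {
            s: roc_auc(matrix.per_structure[:, i, -1], y, higher_is_active=False).auc
            for i, s in enumerate(matrix.structure_ids)
        }

    idx_train, idx_test = split_dataset(list(range(len(y))), spec, labels=y)
    tr, te = np.asarray(idx_train), np.asarray(idx_test)
    X = matrix.features
    out["models"] = {}
    for kind in kinds:
        from .models import cross_validate  # late import; models imports us too
        model = fit_classifier(kind, X[tr], y[tr], threshold_uM=threshold_uM,
                               mlp_config=mlp_config)
        probs_te = model.predict_proba(X[te])
        pred_te = (probs_te >= 0.5).astype(int)
        cv = cross_validate(kind, X[tr], y[tr], k=cv_folds, seed=spec.seed,
                            mlp_config=mlp_config)
        out["models"][kind] = {
            "test_auc": roc_auc(probs_te, y[te], higher_is_active=True).auc,
            "test_mcc": mcc(*confusion_counts(y[te], pred_te)),
            "cv_mean_auc": cv["mean"],
            "cv_std_auc": cv["std"],
            "n_train": int(tr.size),
            "n_test": int(te.size),
        }
    return out
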