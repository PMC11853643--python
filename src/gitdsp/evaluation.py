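"""Cross-validation harness and ranking metrics for CDA prediction.

Five-fold cross-validation over the known circRNA-disease positives: each
fold's positives are removed from the training graph, the model is refitted,
and every unobserved circRNA-disease pair of the catalog serves as a
negative candidate — the strictest common convention for link prediction,
and the reason AUPR values in this field are small in absolute terms.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold

#: Published five-fold AUC / AUPR of nine prior CDA predictors and GIT-DSP on
#: the three literature benchmark datasets (non-cancer, cancer, multi-source).
#: Used for relative-improvement summaries against the strongest baseline.
PUBLISHED_BENCHMARKS = pd.DataFrame(
    [
        ("KATZHCDA", 0.8033, 0.0103, 0.7539, 0.0129, 0.5608, 0.0056),
        ("RWR", 0.8302, 0.0101, 0.7153, 0.0089, 0.6087, 0.0044),
        ("CD-LNLP", 0.7956, 0.0085, 0.6956, 0.0083, 0.6404, 0.0059),
        ("RWR-KNN", 0.5021, 0.0028, 0.5033, 0.0041, 0.5046, 0.0027),
        ("ICIRCDA", 0.5662, 0.0036, 0.5726, 0.0051, 0.6358, 0.0046),
        ("RNMFLP", 0.8726, 0.0113, 0.7333, 0.0130, 0.5216, 0.0050),
        ("DMFCDA", 0.6367, 0.0034, 0.5883, 0.0047, 0.6258, 0.0050),
        ("GMNN2CD", 0.8705, 0.0106, 0.8109, 0.0145, 0.7084, 0.0069),
        ("KGETCDA", 0.9101, 0.0238, 0.8483, 0.0509, 0.7122, 0.0070),
        ("GIT-DSP", 0.9381, 0.0388, 0.8728, 0.0566, 0.7390, 0.0108),
    ],
    columns=["model", "auc_1", "aupr_1", "auc_2", "aupr_2", "auc_3", "aupr_3"],
).set_index("model")


@dataclass
class FoldSplit:
    folds: list[np.ndarray]   # per-fold row indices into the positive list
    seed: int

    def __post_init__(self):
        all_idx = np.concatenate(self.folds)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("folds overlap")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def kfold_split(positives: np.ndarray, k: int, seed: int) -> FoldSplit:
    """Shuffled k-fold partition of the positive pairs (sizes differ by ≤ 1)."""
    positives = np.asarray(positives)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(positives) < k:
        raise ValueError("fewer positives than folds")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [test for _, test in splitter.split(positives)]
    return FoldSplit(folds=folds, seed=seed)


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Acc / Rec / Pre / F1; metrics with zero denominators are ``None``."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else None
    rec = tp / (tp + fn) if (tp + fn) else None
    pre = tp / (tp + fp) if (tp + fp) else None
    f1 = (2 * pre * rec / (pre + rec)
          if pre is not None and rec is not None and (pre + rec) > 0 else None)
    return {"Acc": acc, "Rec": rec, "Pre": pre, "F1": f1}


def auc_aupr(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """ROC-AUC (ties count 1/2) and step-integrated PR-AUC."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


def topk_hits(scores: np.ndarray, positive_mask: np.ndarray, k: int) -> int:
    """Held-out positives among the global top-k ranked candidate pairs."""
    scores = np.asarray(scores).ravel()
    positive_mask = np.asarray(positive_mask, dtype=bool).ravel()
    if k < 1:
        raise ValueError("K must be at least 1")
    if k > scores.size:
        raise ValueError("K exceeds the number of candidate pairs")
    top = np.argsort(-scores, kind="stable")[:k]
    return int(positive_mask[top].sum())


def relative_improvement(ours: float, best_baseline: float) -> float:
    """Percentage gain over the best baseline, half-up rounded to 2 decimals."""
    if best_baseline <= 0:
        raise ValueError("baseline must be positive")
    pct = decimal.Decimal(ours - best_baseline) / decimal.Decimal(best_baseline) * 100
    return float(pct.quantize(decimal.Decimal("0.01"),
                              rounding=decimal.ROUND_HALF_UP))


def improvement_summary(benchmarks: pd.DataFrame = PUBLISHED_BENCHMARKS,
                        ours: str = "GIT-DSP") -> dict[str, float]:
    """Relative improvement of ``ours`` over the best other model per column."""
    out = {}
    baselines = benchmarks.drop(index=ours)
    for col in benchmarks.columns:
        out[col] = relative_improvement(float(benchmarks.loc[ours, col]),
                                        float(baselines[col].max()))
    return out


@dataclass
class EvaluationReport:
    per_fold: pd.DataFrame   # one row per fold: Acc/Rec/Pre/F1/AUC/AUPR/Top-K
    config_hash: str = ""
    topk_values: tuple[int, ...] = (10, 20, 30, 40)

    @property
    def mean_row(self) -> pd.Series:
        return self.per_fold.mean(numeric_only=True)

    def to_frame(self) -> pd.DataFrame:
        mean = self.mean_row.to_frame().T
        mean.index = ["mean"]
        return pd.concat([self.per_fold, mean])

    def write(self, path: str | Path) -> None:
        path = Path(path)
        frame = self.to_frame()
        frame.to_csv(path.with_suffix(".csv"), index_label="fold")
        with open(path.with_suffix(".txt"), "w") as fh:
            fh.write(f"config_hash: {self.config_hash}\n")
            fh.write(frame.to_string(float_format=lambda v: f"{v:.4f}"))
            fh.write("\n")


def evaluate_fold(scores: np.ndarray, test_mask: np.ndarray,
                  candidate_mask: np.ndarray,
                  topk_values: tuple[int, ...] = (10, 20, 30, 40),
                  threshold: float = 0.5) -> dict[str, float]:
    """Metrics for one fold over the flattened circRNA-disease score grid.

    ``test_mask`` marks held-out positives, ``candidate_mask`` the evaluable
    pairs (everything not used for training).  Classification metrics use the
    fixed operating point ``score ≥ threshold``.
    """
    scores = np.asarray(scores).ravel()
    test_mask = np.asarray(test_mask, dtype=bool).ravel()
    candidate_mask = np.asarray(candidate_mask, dtype=bool).ravel()
    cand_scores = scores[candidate_mask]
    cand_labels = test_mask[candidate_mask].astype(int)
    auc, aupr = auc_aupr(cand_scores, cand_labels)
    pred = cand_scores >= threshold
    counts = ConfusionCounts(
        tp=int((pred & (cand_labels == 1)).sum()),
        tn=int((~pred & (cand_labels == 0)).sum()),
        fp=int((pred & (cand_labels == 0)).sum()),
        fn=int((~pred & (cand_labels == 1)).sum()))
    row: dict[str, float] = {k: (np.nan if v is None else v)
                             for k, v in confusion_metrics(counts).items()}
    row["AUC"] = auc
    row["AUPR"] = aupr
    for k in topk_values:
        row[f"Top-{k}"] = topk_hits(cand_scores, cand_labels, k)
    return row


def cross_validate(tables, catalog, estimator, k: int = 5, seed: int = 0,
                   topk_values: tuple[int, ...] = (10, 20, 30, 40)
                   ) -> EvaluationReport:
    """k-fold CV: refit the estimator per fold with test positives removed.

    ``tables`` are the association frames (namespaced ids), ``catalog`` the
    entity catalog, ``estimator`` an unfitted :class:`~gitdsp.model.GitDsp`
    (cloned per fold).
    """
    from sklearn.base import clone

    from .kg import build_kg

    cd = tables["circ-dis"].reset_index(drop=True)
    positives = np.arange(len(cd))
    split = kfold_split(positives, k=k, seed=seed)

    circ_idx = catalog.indices_of_type("circRNA")
    dis_idx = catalog.indices_of_type("disease")
    circ_local = {int(c): i for i, c in enumerate(circ_idx)}
    dis_local = {int(d): j for j, d in enumerate(dis_idx)}

    def grid_position(row) -> int:
        c = circ_local[catalog.resolve(row.head)]
        d = dis_local[catalog.resolve(row.tail)]
        return c * len(dis_idx) + d

    all_pos = np.array([grid_position(r) for r in cd.itertuples(index=False)])
    rows = []
    for fold_no, test_rows in enumerate(split.folds):
        train_rows = np.setdiff1d(positives, test_rows)
        fold_tables = dict(tables)
        fold_tables["circ-dis"] = cd.iloc[train_rows]
        fold_kg = build_kg(fold_tables, catalog)
        # leakage guard: no test positive may appear in the training triples
        train_grid = set(all_pos[train_rows].tolist())
        test_grid = set(all_pos[test_rows].tolist())
        if train_grid & test_grid:
            raise AssertionError("cross-validation leakage: test positive "
                                 "present in training triples")
        model = clone(estimator).fit(fold_kg)
        scores = model.predict_matrix().scores
        n_pairs = scores.size
        test_mask = np.zeros(n_pairs, dtype=bool)
        test_mask[all_pos[test_rows]] = True
        candidate_mask = np.ones(n_pairs, dtype=bool)
        candidate_mask[all_pos[train_rows]] = False
        row = evaluate_fold(scores, test_mask, candidate_mask, topk_values)
        row["fold"] = fold_no
        rows.append(row)
    per_fold = pd.DataFrame(rows).set_index("fold")
    return EvaluationReport(per_fold=per_fold, topk_values=topk_values)
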