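"""Rare-class-aware evaluation of scored protein pairs.

Balanced (50%-positive) test sets are summarized by accuracy and AUC;
imbalanced sets by average precision and precision at a fixed low recall
(default 3%), the shortlist-quality metric that matters when the positive
class is rare.  Tie handling is deliberate and exact: threshold ties predict
negative, AUC gives tied scores half credit, and average precision /
precision-at-recall treat tied-score blocks atomically — so a constant
(zero-information) scorer lands exactly on the analytic baselines
(accuracy 50 on balanced data, AUC 50, average precision = prevalence)
rather than on seed-dependent values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ScoredPairs:
    """Pairs, binary labels and real-valued prediction scores."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.pairs) == len(self.labels) == len(self.scores)):
            raise ValueError("pairs/labels/scores length mismatch")
        if len(self.scores) and not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean()) if len(self.labels) else 0.0


def accuracy(sp: ScoredPairs, threshold: float = 0.5) -> float:
    """Percent correct with 'predict positive iff score > threshold'
    (threshold ties predict negative)."""
    if len(sp) == 0:
        raise ValueError("empty input")
    pred = (sp.scores > threshold).astype(int)
    return float(np.mean(pred == sp.labels)) * 100.0


def roc_auc(sp: ScoredPairs) -> float:
    """AUC as the Mann-Whitney statistic with half credit for ties, x100."""
    y, s = sp.labels, sp.scores
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for AUC")
    ranks = rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg)) * 100.0


def _tie_blocks(sp: ScoredPairs):
    """Cumulative (rank, TP) at the end of each descending tied-score block."""
    order = np.argsort(-sp.scores, kind="stable")
    s = sp.scores[order]
    y = sp.labels[order]
    cum_tp = np.cumsum(y)
    # block ends: last index of each run of equal scores
    ends = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([ends, [len(s) - 1]])
    ks = ends + 1                       # depth at block end
    tps = cum_tp[ends]
    return ks, tps


def average_precision(sp: ScoredPairs) -> float:
    """AP = sum_k (R_k - R_{k-1}) * P_k over descending-score tie blocks, x100.

    Each tied block is one step, so constant scores give exactly the
    prevalence."""
    if len(sp) == 0:
        raise ValueError("empty input")
    total_pos = int(sp.labels.sum())
    if total_pos == 0:
        raise ValueError("no positive labels")
    ks, tps = _tie_blocks(sp)
    precisions = tps / ks
    recalls = tps / total_pos
    prev = np.concatenate([[0.0], recalls[:-1]])
    return float(np.sum((recalls - prev) * precisions)) * 100.0


def precision_at_recall(sp: ScoredPairs, recall_level: float = 0.03) -> float:
    """Precision of the smallest descending-score prefix whose recall reaches
    the level, x100; tied blocks are included atomically."""
    if len(sp) == 0:
        raise ValueError("empty input")
    total_pos = int(sp.labels.sum())
    if total_pos == 0:
        raise ValueError("no positive labels")
    ks, tps = _tie_blocks(sp)
    recalls = tps / total_pos
    hit = np.flatnonzero(recalls >= recall_level - 1e-12)
    if len(hit) == 0:
        # cannot happen when recall_level <= 1: the final block has recall 1
        raise ValueError("recall level unreachable")
    i = hit[0]
    return float(tps[i] / ks[i]) * 100.0


def pr_curve(sp: ScoredPairs) -> np.ndarray:
    """(recall, precision) points at tie-block boundaries, recall ascending."""
    total_pos = int(sp.labels.sum())
    ks, tps = _tie_blocks(sp)
    return np.column_stack([tps / total_pos, tps / ks])


def roc_curve_points(sp: ScoredPairs) -> np.ndarray:
    """(FPR, TPR) points at tie-block boundaries, FPR ascending."""
    total_pos = int(sp.labels.sum())
    total_neg = len(sp) - total_pos
    ks, tps = _tie_blocks(sp)
    fps = ks - tps
    pts = np.column_stack([fps / max(total_neg, 1), tps / max(total_pos, 1)])
    return np.vstack([[0.0, 0.0], pts])


@dataclass
class EvaluationReport:
    """Metric bundle for one scored dataset (percent scales)."""

    accuracy: float | None = None
    auc: float | None = None
    average_precision: float | None = None
    precision_at_recall: dict[float, float] = field(default_factory=dict)
    pr_points: np.ndarray | None = None
    roc_points: np.ndarray | None = None
    dataset_manifest: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"Acc": self.accuracy, "AUC": self.auc,
               "Avg P": self.average_precision}
        for level, p in sorted(self.precision_at_recall.items()):
            row[f"Prec@{level:g}"] = p
        return {k: (round(v, 1) if v is not None else None)
                for k, v in row.items()}


def evaluate_scored_pairs(sp: ScoredPairs,
                          recall_levels: tuple[float, ...] = (0.03,),
                          manifest: dict | None = None) -> EvaluationReport:
    """Full metric bundle: accuracy, AUC, AP and precision at each recall."""
    return EvaluationReport(
        accuracy=accuracy(sp),
        auc=roc_auc(sp),
        average_precision=average_precision(sp),
        precision_at_recall={lv: precision_at_recall(sp, lv)
                             for lv in recall_levels},
        pr_points=pr_curve(sp),
        roc_points=roc_curve_points(sp),
        dataset_manifest=manifest or {})


# ---------------------------------------------------------------------------
# Proteome-wide hub evaluation
# ---------------------------------------------------------------------------

def hub_cumulative_curve(per_hub: dict[str, ScoredPairs],
                         max_fp: int | None = None) -> np.ndarray:
    """Average cumulative true positives against false-positive count.

    For each hub, candidate partners are sorted by descending score and the
    cumulative TP count recorded at every FP count 0..F; curves are averaged
    pointwise across hubs.  Hubs with no labeled positive partner are
    excluded with a warning.  Returns an array of length F+1 where F is
    ``max_fp`` or the smallest per-hub FP total.
    """
    import logging
    curves = []
    for hub, sp in sorted(per_hub.items()):
        if int(sp.labels.sum()) == 0:
            logging.getLogger("ppibench").warning(
                "hub %s has no labeled positive partner; excluded", hub)
            continue
        order = np.argsort(-sp.scores, kind="stable")
        y = sp.labels[order]
        tp = fp = 0
        curve = [0]
        for lab in y:
            if lab == 1:
                tp += 1
                curve[-1] = tp
            else:
                fp += 1
                curve.append(tp)
        curves.append(np.asarray(curve, dtype=float))
    if not curves:
        raise ValueError("no hub with labeled positives")
    F = min(len(c) - 1 for c in curves)
    if max_fp is not None:
        F = min(F, max_fp)
    return np.mean([c[:F + 1] for c in curves], axis=0)


# ---------------------------------------------------------------------------
# Missing-annotation audit
# ---------------------------------------------------------------------------

def missing_feature_report(datasets: dict[str, "PairDataset"],
                           go_annotations=None, dag=None,
                           domain_annotations=None,
                           domain_databases=("Pfam", "Prosite", "InterPro"),
                           ) -> pd.DataFrame:
    """Percent of pairs missing each annotation family, per dataset x class.

    A pair is missing a family when either protein lacks any annotation in
    it.  Families: each GO namespace, "GO Any" (no GO annotation in any
    namespace on one side), and each domain database.  Percentages are
    rounded to one decimal.
    """
    families: dict[str, callable] = {}
    if go_annotations is not None and dag is not None:
        namespaces = sorted(dag.namespaces())
        for ns in namespaces:
            def has_ns(pid, ns=ns):
                return any(t in dag.terms and dag.namespace.get(t) == ns
                           for t in go_annotations.get(pid))
            families[f"GO {ns}"] = has_ns
        families["GO Any"] = lambda pid: len(go_annotations.get(pid)) > 0
    if domain_annotations is not None:
        for db in domain_databases:
            families[db] = (lambda pid, db=db: any(
                k[0] == db for k in domain_annotations.get(pid)))
    rows = []
    for name, ds in sorted(datasets.items()):
        for cls, label in (("positive", 1), ("negative", 0)):
            sel = [p for p, y in zip(ds.pairs, ds.labels) if y == label]
            row = {"dataset": name, "class": cls, "n_pairs": len(sel)}
            for fam, has in families.items():
                if not sel:
                    row[fam] = float("nan")
                    continue
                miss = sum(1 for a, b in sel if not (has(a) and has(b)))
                row[fam] = round(100.0 * miss / len(sel), 1)
            rows.append(row)
    return pd.DataFrame(rows)


def report_table(reports: dict[str, EvaluationReport]) -> pd.DataFrame:
    """Summary TSV-ready table: one row per dataset, benchmark column order."""
    rows = []
    for name, rep in sorted(reports.items()):
        row = {"dataset": name}
        row.update(rep.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(reports: dict[str, EvaluationReport],
                 path: str | Path) -> None:
    report_table(reports).to_csv(path, sep="\t", index=False)
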