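"""Dataset assembly, seeded training, and the evaluation protocol.

Training minimizes binary cross-entropy on the sigmoid output with Adam
(defaults lr 0.001, batch 32, 50 epochs).  Evaluation reports seven
statistics — accuracy, precision, recall, specificity, F1, AUC, AUPRC —
from the confusion counts at the 0.5 threshold and the score ranking:

    ACC  = (TP + TN) / (TP + FN + FP + TN)
    Prec = TP / (TP + FP)          Recall = TP / (TP + FN)
    Spec = TN / (TN + FP)          F1 = 2 * Prec * Recall / (Prec + Recall)

AUC is the area under the (FPR, TPR) curve and AUPRC the area under the
(recall, precision) curve.  Five-fold cross-validation reports *both* AUC
aggregation conventions in circulation: the mean of per-fold AUCs and the
single AUC over the pooled predictions of all folds — the two can differ,
and results tables citing one are not comparable to curves computed with
the other.

Negative pairs are generated by randomly pairing receptors with peptides
while excluding every listed positive, without duplicates.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .autodiff import Adam, bce_with_logits
from .config import RunConfig
from .model import ChainEncoding, PepPIModel

__all__ = [
    "SamplePair",
    "PairDataset",
    "MetricsReport",
    "sample_negatives",
    "train",
    "compute_metrics",
    "cross_validate",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "write_metrics_csv",
    "write_curves",
]


@dataclass
class SamplePair:
    receptor_id: str
    peptide_id: str
    label: int
    split_fold: int | None = None

    def key(self) -> tuple[str, str]:
        return (self.receptor_id, self.peptide_id)


@dataclass
class PairDataset:
    """Labelled pairs plus the chain and embedding stores they refer to."""

    pairs: list[SamplePair]
    chains: dict = field(default_factory=dict)      # id -> ResidueChain
    embeddings: dict = field(default_factory=dict)  # id -> EmbeddingMatrix

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class MetricsReport:
    """Confusion counts and the seven statistics under one convention."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    prec: float
    recall: float
    spec: float
    f1: float
    auc: float | None
    auprc: float | None
    convention: str = "pooled"  # pooled | per_fold_mean

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {
            "convention": self.convention,
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": self.acc, "Prec": self.prec, "Recall": self.recall,
            "Spec": self.spec, "F1": self.f1, "AUC": self.auc,
            "AUPRC": self.auprc,
        }


# ------------------------------------------------------------------ sampling


def sample_negatives(positives: list[SamplePair], n: int, seed: int,
                     receptor_ids=None, peptide_ids=None) -> list[SamplePair]:
    """Draw n random receptor-peptide pairs absent from the positive list.

    The candidate grid is the Cartesian product of the given (or observed)
    receptor and peptide identifiers minus the positives; sampling is
    without replacement and deterministic given the seed.
    """
    if n == 0:
        return []
    receptor_ids = sorted(receptor_ids
                          or {p.receptor_id for p in positives})
    peptide_ids = sorted(peptide_ids or {p.peptide_id for p in positives})
    taken = {p.key() for p in positives}
    candidates = [
        (r, q) for r in receptor_ids for q in peptide_ids
        if (r, q) not in taken
    ]
    if len(candidates) < n:
        raise ValueError(
            f"cannot draw {n} negatives: only {len(candidates)} "
            f"non-positive combinations exist "
            f"(shortfall {n - len(candidates)})"
        )
    rng = np.random.default_rng(np.random.PCG64(seed))
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [SamplePair(candidates[i][0], candidates[i][1], 0) for i in idx]


def chain_disjoint_split(dataset: PairDataset, test_fraction: float = 0.3,
                         seed: int = 0) -> tuple[PairDataset, PairDataset]:
    """Split pairs so train and test share no chains.

    Receptors and peptides are each partitioned at `test_fraction`; a pair
    lands in train (test) only if both members are in the train (test)
    partition, and straddling pairs are discarded.  Pair-level splits let a
    model score well by memorizing chain identities from their embedding
    fingerprints; a chain-disjoint split measures whether the learned rule
    transfers to unseen chains.
    """
    rng = np.random.default_rng(np.random.PCG64(seed))
    receptors = sorted({p.receptor_id for p in dataset.pairs})
    peptides = sorted({p.peptide_id for p in dataset.pairs})
    test_chains: set[str] = set()
    for ids in (receptors, peptides):
        n_test = max(1, int(round(test_fraction * len(ids))))
        test_chains.update(rng.choice(ids, size=n_test, replace=False))
    train_pairs, test_pairs = [], []
    for p in dataset.pairs:
        in_test = (p.receptor_id in test_chains, p.peptide_id in test_chains)
        if not any(in_test):
            train_pairs.append(p)
        elif all(in_test):
            test_pairs.append(p)
    return (PairDataset(train_pairs, dataset.chains, dataset.embeddings),
            PairDataset(test_pairs, dataset.chains, dataset.embeddings))


# ------------------------------------------------------------------ training


def _encode_dataset(model: PepPIModel, dataset: PairDataset
                    ) -> list[tuple[ChainEncoding, ChainEncoding]]:
    cache: dict[str, ChainEncoding] = {}

    def enc(cid: str) -> ChainEncoding:
        if cid not in cache:
            cache[cid] = model.encode_chain(dataset.chains[cid],
                                            dataset.embeddings[cid])
        return cache[cid]

    return [(enc(p.receptor_id), enc(p.peptide_id)) for p in dataset.pairs]


def train(dataset: PairDataset, config: RunConfig,
          model: PepPIModel | None = None) -> tuple[PepPIModel, dict]:
    """Train a model on the dataset; returns (model, history).

    history carries per-epoch mean loss and the final training accuracy.
    Deterministic given config.seed (initialization and shuffling share the
    seed stream).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    labels = dataset.labels()
    if labels.min() == labels.max():
        raise ValueError("training requires both classes present")
    model = model or PepPIModel(config)
    encodings = _encode_dataset(model, dataset)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.PCG64(config.seed + 1))
    n = len(encodings)
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [encodings[i] for i in idx]
            y = labels[idx].astype(float)[:, None]
            opt.zero_grad()
            logits = model.forward_pairs(batch, training=True)
            loss = bce_with_logits(logits, y)
            loss.backward()
            opt.step()
            epoch_loss += loss.data.item() * len(idx)
        losses.append(epoch_loss / n)
    scores = model.predict_scores(encodings)
    train_acc = float(np.mean((scores >= config.threshold) == (labels == 1)))
    history = {"loss": losses, "final_loss": losses[-1] if losses else None,
               "train_accuracy": train_acc}
    return model, history


# ------------------------------------------------------------------- metrics


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has zero denominator; reporting 0")
        return 0.0
    return num / den


def compute_metrics(labels, scores, threshold: float = 0.5,
                    convention: str = "pooled") -> MetricsReport:
    """Confusion counts at `threshold` plus the seven ranking statistics."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc = _safe_ratio(tp + tn, tp + fn + fp + tn, "ACC")
    prec = _safe_ratio(tp, tp + fp, "Prec")
    recall = _safe_ratio(tp, tp + fn, "Recall")
    spec = _safe_ratio(tn, tn + fp, "Spec")
    f1 = (_safe_ratio(2 * prec * recall, prec + recall, "F1")
          if (prec + recall) > 0 else _safe_ratio(0, 0, "F1"))
    if labels.min() == labels.max():
        warnings.warn("single-class labels: AUC and AUPRC are undefined")
        auc = auprc = None
    else:
        auc = float(roc_auc_score(labels, scores))
        precs, recs, _ = precision_recall_curve(labels, scores)
        # curve is emitted in decreasing-recall order; integrate over recall
        auprc = float(np.trapezoid(precs[::-1], recs[::-1]))
    return MetricsReport(tp, tn, fp, fn, acc, prec, recall, spec, f1,
                         auc, auprc, convention=convention)


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Per-fold-mean convention: average each statistic across folds."""

    def mean_of(attr):
        vals = [getattr(r, attr) for r in reports]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return MetricsReport(
        tp=sum(r.tp for r in reports), tn=sum(r.tn for r in reports),
        fp=sum(r.fp for r in reports), fn=sum(r.fn for r in reports),
        acc=mean_of("acc"), prec=mean_of("prec"), recall=mean_of("recall"),
        spec=mean_of("spec"), f1=mean_of("f1"), auc=mean_of("auc"),
        auprc=mean_of("auprc"), convention="per_fold_mean",
    )


def cross_validate(dataset: PairDataset, config: RunConfig, k: int = 5,
                   seed: int | None = None) -> dict:
    """Stratified k-fold CV; returns per-fold, fold-mean and pooled reports.

    Folds are disjoint and exhaustive; assignment is deterministic given the
    seed.  The 'per_fold_mean' report averages each statistic (including
    AUC) across folds; the 'pooled' report concatenates all folds'
    predictions first.
    """
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    seed = config.seed if seed is None else seed
    labels = dataset.labels()
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[MetricsReport] = []
    pooled_labels: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    fold_assignment = np.full(n, -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(np.zeros(n), labels)
    ):
        fold_assignment[test_idx] = fold
        fold_cfg = RunConfig.from_dict({**config.to_dict(),
                                        "seed": seed + fold})
        sub_train = PairDataset([dataset.pairs[i] for i in train_idx],
                                dataset.chains, dataset.embeddings)
        sub_test = PairDataset([dataset.pairs[i] for i in test_idx],
                               dataset.chains, dataset.embeddings)
        model, _ = train(sub_train, fold_cfg)
        test_enc = _encode_dataset(model, sub_test)
        scores = model.predict_scores(test_enc)
        y = sub_test.labels()
        fold_reports.append(
            compute_metrics(y, scores, config.threshold, convention="pooled")
        )
        pooled_labels.append(y)
        pooled_scores.append(scores)
    for pair, fold in zip(dataset.pairs, fold_assignment):
        pair.split_fold = int(fold)
    pooled_y = np.concatenate(pooled_labels)
    pooled_s = np.concatenate(pooled_scores)
    return {
        "per_fold": fold_reports,
        "per_fold_mean": _mean_report(fold_reports),
        "pooled": compute_metrics(pooled_y, pooled_s, config.threshold,
                                  convention="pooled"),
        "pooled_labels": pooled_y,
        "pooled_scores": pooled_s,
    }


# ---------------------------------------------------------------------- I/O


def read_pairs_tsv(path: str | Path) -> list[SamplePair]:
    df = pd.read_csv(path, sep="\t")
    required = {"receptor_id", "peptide_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair list must have columns {sorted(required)}")
    return [
        SamplePair(str(r.receptor_id), str(r.peptide_id), int(r.label))
        for r in df.itertuples()
    ]


def write_pairs_tsv(path: str | Path, pairs: list[SamplePair]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["receptor_id", "peptide_id", "label"])
        for p in pairs:
            writer.writerow([p.receptor_id, p.peptide_id, p.label])


def write_metrics_csv(path: str | Path, cv_result: dict) -> None:
    """Per-fold rows, then the fold-mean and pooled convention rows."""
    rows = []
    for i, rep in enumerate(cv_result["per_fold"]):
        rows.append({"fold": i, **rep.as_dict()})
    rows.append({"fold": "mean", **cv_result["per_fold_mean"].as_dict()})
    rows.append({"fold": "pooled", **cv_result["pooled"].as_dict()})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curves(prefix: str | Path, labels, scores,
                 plot: bool = False) -> None:
    """ROC and PR curve points as CSV (and optional PNG plots)."""
    prefix = Path(prefix)
    fpr, tpr, _ = roc_curve(labels, scores)
    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
        prefix.with_suffix(".roc.csv"), index=False)
    precs, recs, _ = precision_recall_curve(labels, scores)
    pd.DataFrame({"recall": recs, "precision": precs}).to_csv(
        prefix.with_suffix(".pr.csv"), index=False)
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].plot(fpr, tpr)
        axes[0].set(xlabel="FPR", ylabel="TPR", title="ROC")
        axes[1].plot(recs, precs)
        axes[1].set(xlabel="Recall", ylabel="Precision", title="PR")
        fig.tight_layout()
        fig.savefig(prefix.with_suffix(".curves.png"), dpi=100)
        plt.close(fig)
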