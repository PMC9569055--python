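"""Sampling, cross-validation protocols, metrics, baselines and ranking.

The evaluation protocol mirrors standard practice for bipartite link
prediction: all known associations are positives, an equal number of
unverified (zero) cells is drawn uniformly at random as negatives, and
the balanced set is split into stratified folds.  Similarity matrices
are built once from the full association matrix before splitting — the
interaction-profile kernels therefore see validation positives, a mild
leak inherent to this pipeline order; ``strict=True`` recomputes the
kernels per fold from the training associations only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .dataio import (
    AssociationMatrix,
    DiseaseDAG,
    SequenceSet,
    SimilarityMatrix,
)
from .errors import ParameterError, ValidationError
from .fusion import (
    FlagMatrix,
    build_semantic_flags,
    build_sequence_flags,
    fuse_circrna,
    fuse_disease,
)
from .model import ModelConfig, MspcdModel, predict, train
from .similarity import (
    EditCosts,
    GipParams,
    SemanticParams,
    circ_gip_similarity,
    disease_gip_similarity,
    functional_similarity,
    semantic_similarity_1,
    semantic_similarity_2,
    sequence_similarity_matrix,
)

__all__ = [
    "PairDataset",
    "MetricsRecord",
    "SimilarityBundle",
    "CrossValResult",
    "derive_seed",
    "sample_negatives",
    "kfold_split",
    "independent_split",
    "auc_score",
    "compute_metrics",
    "f1_from_precision_recall",
    "mean_metrics",
    "build_features",
    "run_cross_validation",
    "run_baseline",
    "pair_feature_matrix",
    "rank_candidates",
    "write_metrics_table",
    "write_ranking",
    "roc_points",
]


def derive_seed(seed: int, tag: int) -> int:
    """Deterministically fan a global seed out to stage-specific seeds,
    keeping results below 2**31."""
    return int((seed * 1_000_003 + tag * 7_919 + 12_345) % (2**31))


@dataclass
class PairDataset:
    """Labelled (circRNA index, disease index) samples."""

    pairs: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.labels = np.asarray(self.labels, dtype=np.int8).reshape(-1)
        if self.pairs.shape[0] != self.labels.shape[0]:
            raise ValidationError("pairs and labels lengths differ")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0/1")
        uniq = {tuple(p) for p in self.pairs.tolist()}
        if len(uniq) != self.pairs.shape[0]:
            raise ValidationError("duplicate pairs in dataset")

    def __len__(self) -> int:
        return self.labels.shape[0]

    def subset(self, idx: np.ndarray) -> "PairDataset":
        return PairDataset(self.pairs[idx], self.labels[idx], dict(self.provenance))


@dataclass(frozen=True)
class MetricsRecord:
    """AUC plus thresholded confusion-matrix metrics for one evaluation."""

    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN


def sample_negatives(
    Sd: AssociationMatrix, n: int | None = None, seed: int = 0
) -> PairDataset:
    """All positive cells plus *n* uniformly sampled zero cells (without
    replacement).  Default n equals the positive count, giving the
    balanced dataset the training protocol assumes."""
    pos = np.argwhere(Sd.values == 1)
    zeros = np.argwhere(Sd.values == 0)
    if n is None:
        n = pos.shape[0]
    if n > zeros.shape[0]:
        raise ParameterError(
            f"requested {n} negatives but only {zeros.shape[0]} zero cells exist"
        )
    rng = np.random.default_rng(seed)
    neg = zeros[rng.choice(zeros.shape[0], size=n, replace=False)]
    pairs = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(pos.shape[0]), np.zeros(n)])
    return PairDataset(
        pairs, labels, {"seed": seed, "n_positive": int(pos.shape[0]), "n_negative": int(n)}
    )


def _round_robin_folds(labels: np.ndarray, k: int, rng: np.random.Generator, stratified: bool):
    """Assign samples to k folds round-robin, classes shuffled separately
    when stratified.  Fold sizes differ by at most one overall and per
    class."""
    n = labels.shape[0]
    if stratified:
        order = np.concatenate(
            [rng.permutation(np.flatnonzero(labels == lab)) for lab in (1, 0)]
        )
    else:
        order = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    assign[order] = np.arange(n) % k
    return [np.flatnonzero(assign == f) for f in range(k)]


def kfold_split(
    dataset: PairDataset, k: int = 5, seed: int = 0, stratified: bool = True
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k disjoint folds covering the dataset, sizes differing by <= 1;
    each fold serves as the validation set exactly once."""
    if k < 2:
        raise ParameterError("k must be at least 2")
    if len(dataset) < k:
        raise ParameterError(f"cannot split {len(dataset)} samples into {k} folds")
    rng = np.random.default_rng(seed)
    folds = _round_robin_folds(dataset.labels, k, rng, stratified)
    splits = []
    for f in range(k):
        val = np.sort(folds[f])
        train_idx = np.sort(np.concatenate([folds[g] for g in range(k) if g != f]))
        splits.append((train_idx, val))
    return splits


def independent_split(
    dataset: PairDataset, fraction: float = 0.2, seed: int = 0
) -> tuple[PairDataset, PairDataset]:
    """Hold out ``floor(fraction * n)`` samples, stratified by label;
    returns (working set, holdout set), disjoint by construction."""
    if not (0.0 < fraction < 1.0):
        raise ParameterError("fraction must lie strictly between 0 and 1")
    n = len(dataset)
    n_hold = int(fraction * n)
    if n_hold < 1 or n_hold >= n:
        raise ParameterError(f"degenerate holdout size {n_hold} for n={n}")
    npos = int(dataset.labels.sum())
    hold_pos = int(round(n_hold * npos / n))
    hold_pos = min(max(hold_pos, 0), min(npos, n_hold))
    hold_neg = n_hold - hold_pos
    rng = np.random.default_rng(seed)
    pos_idx = rng.permutation(np.flatnonzero(dataset.labels == 1))
    neg_idx = rng.permutation(np.flatnonzero(dataset.labels == 0))
    if hold_neg > neg_idx.shape[0]:
        raise ParameterError("not enough negatives to stratify the holdout")
    hold = np.sort(np.concatenate([pos_idx[:hold_pos], neg_idx[:hold_neg]]))
    work = np.sort(np.concatenate([pos_idx[hold_pos:], neg_idx[hold_neg:]]))
    return dataset.subset(work), dataset.subset(hold)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC: the probability that a random positive
    outscores a random negative, ties counted one half."""
    labels = np.asarray(labels)
    npos = int((labels == 1).sum())
    nneg = int((labels == 0).sum())
    if npos == 0 or nneg == 0:
        raise ParameterError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg))


def compute_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricsRecord:
    """Confusion counts at ``score >= threshold`` plus rank-based AUC.

    Precision, recall and F1 follow their standard definitions
    (recall = TP / (TP + FN)); undefined ratios fall back to 0.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ParameterError("labels and scores lengths differ")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    total = tp + fp + tn + fn
    acc = (tp + tn) / total if total else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = f1_from_precision_recall(prec, rec)
    return MetricsRecord(auc_score(y, s), acc, prec, rec, f1, (tp, fp, tn, fn))


def mean_metrics(records: Sequence[MetricsRecord]) -> MetricsRecord:
    """Arithmetic mean of each metric; confusion counts are summed."""
    conf = tuple(int(sum(r.confusion[i] for r in records)) for i in range(4))
    return MetricsRecord(
        auc=float(np.mean([r.auc for r in records])),
        accuracy=float(np.mean([r.accuracy for r in records])),
        precision=float(np.mean([r.precision for r in records])),
        recall=float(np.mean([r.recall for r in records])),
        f1=float(np.mean([r.f1 for r in records])),
        confusion=conf,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# pipeline assembly
# ---------------------------------------------------------------------------


@dataclass
class SimilarityBundle:
    """All base similarities, flags, and the fused matrices."""

    CS: SimilarityMatrix
    CF: SimilarityMatrix
    CG: SimilarityMatrix
    DG: SimilarityMatrix
    DS1: SimilarityMatrix
    DS2: SimilarityMatrix
    FQ: FlagMatrix
    FS: FlagMatrix
    CV: SimilarityMatrix
    DV: SimilarityMatrix


def build_features(
    Sd: AssociationMatrix,
    seqs: SequenceSet,
    Sg: AssociationMatrix,
    Sm: AssociationMatrix,
    dag: DiseaseDAG,
    edit_costs: EditCosts = EditCosts(),
    gip_params: GipParams = GipParams(),
    semantic_params: SemanticParams = SemanticParams(),
) -> SimilarityBundle:
    """Compute every base similarity from the inputs and fuse them."""
    CS = sequence_similarity_matrix(seqs, Sd.row_ids, edit_costs)
    CF = functional_similarity(Sd, Sg, Sm)
    CG = circ_gip_similarity(Sd, gip_params)
    DG = disease_gip_similarity(Sd, gip_params)
    DS1 = semantic_similarity_1(dag, Sd.col_ids, semantic_params)
    DS2 = semantic_similarity_2(dag, Sd.col_ids, semantic_params)
    FQ = build_sequence_flags(seqs, Sd.row_ids)
    FS = build_semantic_flags(dag, Sd.col_ids)
    CV = fuse_circrna(CS, CF, CG, FQ)
    DV = fuse_disease(DS1, DS2, DG, FS)
    return SimilarityBundle(CS, CF, CG, DG, DS1, DS2, FQ, FS, CV, DV)


@dataclass
class CrossValResult:
    fold_records: list[MetricsRecord]
    mean: MetricsRecord
    fold_curves: list[tuple[np.ndarray, np.ndarray]]  # (labels, scores) per fold
    loss_traces: list[list[float]]


def _masked_gip_refuse(
    Sd: AssociationMatrix,
    bundle: SimilarityBundle,
    val_pairs: np.ndarray,
    val_labels: np.ndarray,
    gip_params: GipParams,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Strict mode: zero the validation positives out of the association
    matrix, recompute both interaction-profile kernels, and re-fuse."""
    masked = Sd.values.copy()
    for (i, j), lab in zip(val_pairs, val_labels):
        if lab == 1:
            masked[i, j] = 0
    masked_m = AssociationMatrix(masked, list(Sd.row_ids), list(Sd.col_ids))
    CG = circ_gip_similarity(masked_m, gip_params)
    DG = disease_gip_similarity(masked_m, gip_params)
    cv = fuse_circrna(bundle.CS, bundle.CF, CG, bundle.FQ)
    dv = fuse_disease(bundle.DS1, bundle.DS2, DG, bundle.FS)
    return cv, dv


def run_cross_validation(
    Sd: AssociationMatrix,
    seqs: SequenceSet,
    Sg: AssociationMatrix,
    Sm: AssociationMatrix,
    dag: DiseaseDAG,
    model_config: ModelConfig = ModelConfig(),
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    edit_costs: EditCosts = EditCosts(),
    gip_params: GipParams = GipParams(),
    semantic_params: SemanticParams = SemanticParams(),
    strict: bool = False,
    bundle: SimilarityBundle | None = None,
) -> CrossValResult:
    """The full k-fold protocol: build similarities, balance by negative
    sampling, split with stratification, train one network per fold and
    evaluate it on the held-out fold.  A precomputed *bundle* can be
    passed to skip the similarity stage.
    """
    if bundle is None:
        bundle = build_features(Sd, seqs, Sg, Sm, dag, edit_costs, gip_params, semantic_params)
    dataset = sample_negatives(Sd, seed=derive_seed(seed, 1))
    splits = kfold_split(dataset, k=k, seed=derive_seed(seed, 2), stratified=True)
    records: list[MetricsRecord] = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    traces: list[list[float]] = []
    for fold, (train_idx, val_idx) in enumerate(splits):
        cv, dv = bundle.CV, bundle.DV
        if strict:
            cv, dv = _masked_gip_refuse(
                Sd, bundle, dataset.pairs[val_idx], dataset.labels[val_idx], gip_params
            )
        cfg = replace(model_config, seed=derive_seed(seed, 10 + fold))
        fitted = train(cv, dv, dataset.subset(train_idx), cfg)
        scores = predict(fitted, cv, dv, dataset.pairs[val_idx])
        records.append(compute_metrics(dataset.labels[val_idx], scores, threshold))
        curves.append((dataset.labels[val_idx].copy(), scores))
        traces.append(fitted.loss_trace)
    return CrossValResult(records, mean_metrics(records), curves, traces)


def pair_feature_matrix(
    cv: SimilarityMatrix, dv: SimilarityMatrix, pairs: np.ndarray
) -> np.ndarray:
    """Cascaded [circRNA similarity row; disease similarity row] features
    used by the flat baseline classifiers."""
    pairs = np.asarray(pairs, dtype=int)
    return np.hstack([cv.values[pairs[:, 0]], dv.values[pairs[:, 1]]])


def _make_classifier(spec: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    if spec == "forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if spec == "margin":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if spec == "feedforward":
        return MLPClassifier(
            hidden_layer_sizes=(128, 64), max_iter=300, random_state=seed
        )
    raise ParameterError(f"unknown classifier spec {spec!r}")


def run_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    classifier_spec: str,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CrossValResult:
    """Same k-fold protocol with a flat standard classifier (random
    forest, RBF support-vector machine, or a plain feed-forward net) on
    cascaded similarity features."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(derive_seed(seed, 2))
    folds = _round_robin_folds(labels, k, rng, stratified=True)
    records: list[MetricsRecord] = []
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    for fold in range(k):
        val = folds[fold]
        tr = np.concatenate([folds[g] for g in range(k) if g != fold])
        clf = _make_classifier(classifier_spec, derive_seed(seed, 20 + fold))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            clf.fit(features[tr], labels[tr])
            scores = clf.predict_proba(features[val])[:, 1]
        records.append(compute_metrics(labels[val], scores, threshold))
        curves.append((labels[val].copy(), scores))
    return CrossValResult(records, mean_metrics(records), curves, [])


def rank_candidates(
    model: MspcdModel,
    Sd: AssociationMatrix,
    cv: SimilarityMatrix,
    dv: SimilarityMatrix,
    top_k: int = 15,
) -> list[tuple[str, str, float]]:
    """Score every unverified (zero) cell and return the top_k candidate
    associations, ties broken by (row index, column index)."""
    zeros = np.argwhere(Sd.values == 0)
    if top_k > zeros.shape[0]:
        warnings.warn(
            f"top_k={top_k} exceeds the {zeros.shape[0]} unknown pairs; truncating",
            stacklevel=2,
        )
        top_k = zeros.shape[0]
    scores = predict(model, cv, dv, zeros)
    order = np.lexsort((zeros[:, 1], zeros[:, 0], -scores))
    out = []
    for idx in order[:top_k]:
        i, j = zeros[idx]
        out.append((Sd.row_ids[i], Sd.col_ids[j], float(scores[idx])))
    return out


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def write_metrics_table(result: CrossValResult, path: str | Path) -> None:
    """One row per fold plus an average row; columns AUC/accuracy/
    precision/recall/F1."""
    with Path(path).open("w") as fh:
        fh.write("fold\tauc\taccuracy\tprecision\trecall\tf1\n")
        for i, r in enumerate(result.fold_records, 1):
            fh.write(
                f"{i}\t{r.auc:.6f}\t{r.accuracy:.6f}\t{r.precision:.6f}"
                f"\t{r.recall:.6f}\t{r.f1:.6f}\n"
            )
        m = result.mean
        fh.write(
            f"average\t{m.auc:.6f}\t{m.accuracy:.6f}\t{m.precision:.6f}"
            f"\t{m.recall:.6f}\t{m.f1:.6f}\n"
        )


def roc_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """(FPR, TPR) points of the ROC curve, via threshold sweep."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


def write_ranking(rows: list[tuple[str, str, float]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("circRNA\tdisease\tscore\n")
        for cid, did, s in rows:
            fh.write(f"{cid}\t{did}\t{s:.6f}\n")
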