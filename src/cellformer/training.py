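"""Dataset splitting, optimisation and reference→query prediction.

Training is transductive within each forward pass: attention runs over
the cells of the current batch only, so the N in the attention
normaliser is the batch size.  Full-batch training is the special case
of a single batch holding every training cell.  Mini-batches are drawn
as a seeded random partition of the training cells each epoch; batch
index lists are sorted, which makes a batch covering all training cells
reproduce the full-batch computation exactly.

Model selection defaults to the epoch with the best validation accuracy.
The alternative ``paper_test_best`` (best *test* accuracy) is retained
for replication of published protocols but leaks the test set into model
selection; it is off by default and flagged in the history.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import metrics as metrics_mod
from .autodiff import Tensor, softmax_cross_entropy
from .graph import CellGraph, build_knn_graph, normalize_adjacency
from .io_preprocess import (
    DEFAULT_HVG_CAP,
    ExpressionMatrix,
    LabelSet,
    align_genes,
    encode_labels,
    normalize_log,
    qc_filter,
    select_hvg,
)
from .model import ModelConfig, ModelParams, _forward_t, flops, init_params

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "split_dataset",
    "train",
    "train_minibatch",
    "predict",
    "run_replicates",
    "label_transfer",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    ratios : (train, valid, test) fractions, summing to 1.
    batch_size : cells per mini-batch, or "full" for single-batch training;
        512 is the published mini-batch size for large datasets.
    selection : which epoch's parameters to return — "valid_best",
        "paper_test_best" (leaky; replication only) or "last".
    """

    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    epochs: int = 200
    learning_rate: float = 3e-3
    weight_decay: float = 5e-4
    batch_size: int | str = "full"
    selection: str = "valid_best"
    seed: int = 0
    replicates: int = 5

    def __post_init__(self):
        if any(r < 0 for r in self.ratios) or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must be nonnegative and sum to 1")
        if self.batch_size != "full" and int(self.batch_size) < 1:
            raise ValueError("batch_size must be >= 1 or 'full'")
        if self.selection not in ("valid_best", "paper_test_best", "last"):
            raise ValueError(f"unknown selection {self.selection!r}")


@dataclass
class TrainHistory:
    """Per-epoch loss and split accuracies plus the selected epoch."""

    loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    valid_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    selected_epoch: int = -1
    # audit trail: cell indices whose labels entered the loss or the
    # model-selection criterion (test leakage is checkable from these)
    loss_label_indices: set[int] = field(default_factory=set)
    selection_label_indices: set[int] = field(default_factory=set)


def split_dataset(
    n: int,
    ratios: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    labels: Optional[LabelSet] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint train/valid/test indices covering range(n).

    Sizes follow floor allocation with the remainder going to train.
    With labels the split is stratified per class (same floor rule within
    each class); classes too small to stratify fall back to a seeded
    random assignment with a warning.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if abs(sum(ratios) - 1.0) > 1e-9 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)

    def allocate(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = len(idx)
        n_valid = int(np.floor(ratios[1] * m))
        n_test = int(np.floor(ratios[2] * m))
        n_train = m - n_valid - n_test
        perm = rng.permutation(idx)
        return perm[:n_train], perm[n_train : n_train + n_valid], perm[n_train + n_valid :]

    if labels is None:
        tr, va, te = allocate(np.arange(n))
    else:
        if len(labels) != n:
            raise ValueError("labels length does not match n")
        trs, vas, tes = [], [], []
        codes = np.asarray(labels.codes)
        n_splits_needed = sum(1 for r in ratios if r > 0)
        for c in np.unique(codes):
            idx = np.where(codes == c)[0]
            if len(idx) < n_splits_needed:
                warnings.warn(
                    f"class {labels.vocabulary[c]!r} has only {len(idx)} members; "
                    "falling back to non-stratified assignment for it"
                )
                perm = rng.permutation(idx)
                cut = rng.choice(3, size=len(idx), p=list(ratios))
                trs.append(perm[cut == 0]); vas.append(perm[cut == 1]); tes.append(perm[cut == 2])
                continue
            t, v, s = allocate(idx)
            trs.append(t); vas.append(v); tes.append(s)
        tr = np.concatenate(trs); va = np.concatenate(vas); te = np.concatenate(tes)
    return np.sort(tr), np.sort(va), np.sort(te)


class _Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay on the grad."""

    def __init__(self, keys, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd, self.b1, self.b2, self.eps = lr, weight_decay, beta1, beta2, eps
        self.t = 0
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}

    def step(self, pt: dict[str, Tensor]) -> None:
        self.t += 1
        for k, tensor in pt.items():
            g = tensor.grad
            if g is None:
                g = np.zeros_like(tensor.data)
            g = g + self.wd * tensor.data
            if self.m[k] is None:
                self.m[k] = np.zeros_like(tensor.data)
                self.v[k] = np.zeros_like(tensor.data)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            tensor.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_features(x_hat) -> np.ndarray:
    if isinstance(x_hat, ExpressionMatrix):
        return x_hat.dense()
    return np.asarray(x_hat, dtype=np.float64)


def _chunk_logits(arrays_params: ModelParams, config: ModelConfig, x: np.ndarray,
                  graph: Optional[CellGraph], idx: np.ndarray,
                  chunk_size: int) -> np.ndarray:
    """Inference logits for the cells in ``idx``, attention within chunks."""
    pt = arrays_params.as_tensors(requires_grad=False)
    out = np.empty((len(idx), arrays_params.n_classes))
    for start in range(0, len(idx), chunk_size):
        sub = idx[start : start + chunk_size]
        a_norm = None
        if config.use_graph and graph is not None:
            a_norm = normalize_adjacency(graph.induced(sub))
        out[start : start + len(sub)] = _forward_t(
            Tensor(x[sub]), pt, config, a_norm, flops
        ).data
    return out


def train(
    x_hat,
    labels: LabelSet,
    graph: Optional[CellGraph] = None,
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    split: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> tuple[ModelParams, TrainHistory]:
    """Fit the network with Adam on cross-entropy over the training cells.

    The split is stratified by label and seeded; pass ``split`` to reuse
    index sets (e.g. the 0.8/0.2 reference protocol where the test part
    is empty and the query dataset is held elsewhere).  Returns the
    parameters of the epoch chosen by ``train_config.selection`` and the
    full per-epoch history.
    """
    x = _as_features(x_hat)
    n = x.shape[0]
    if len(labels) != n:
        raise ValueError("labels must cover all cells")
    codes = np.asarray(labels.codes)
    if split is None:
        split = split_dataset(n, train_config.ratios, train_config.seed, labels)
    train_idx, valid_idx, test_idx = (np.asarray(s) for s in split)

    params = init_params(model_config, x.shape[1], labels.n_classes)
    history = TrainHistory()
    if train_config.epochs == 0:
        history.selected_epoch = -1
        return params, history

    pt = params.as_tensors(requires_grad=True)
    adam = _Adam(pt.keys(), train_config.learning_rate, train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    batch_size = (
        len(train_idx) if train_config.batch_size == "full" else int(train_config.batch_size)
    )
    if batch_size < labels.n_classes:
        warnings.warn("batch_size below the number of classes; some batches may lack classes")

    best_score, best_epoch, best_arrays = -np.inf, -1, None
    eval_chunk = max(batch_size, 1)
    for epoch in range(train_config.epochs):
        perm = rng.permutation(train_idx)
        batches = [np.sort(perm[s : s + batch_size]) for s in range(0, len(perm), batch_size)]
        epoch_loss = 0.0
        for batch in batches:
            for t in pt.values():
                t.grad = None
            a_norm = None
            if model_config.use_graph and graph is not None:
                a_norm = normalize_adjacency(graph.induced(batch))
            logits_t = _forward_t(Tensor(x[batch]), pt, model_config, a_norm, flops)
            loss_t = softmax_cross_entropy(logits_t, codes[batch])
            if not np.isfinite(loss_t.data):
                raise RuntimeError(f"diverged: non-finite loss at epoch {epoch}")
            loss_t.backward()
            adam.step(pt)
            epoch_loss += float(loss_t.data) * len(batch)
            history.loss_label_indices.update(int(i) for i in batch)
        history.loss.append(epoch_loss / len(train_idx))

        try:
            snapshot = ModelParams(
                {k: t.data for k, t in pt.items()}, params.n_genes, params.n_classes
            )
        except ValueError as exc:
            raise RuntimeError(f"diverged: non-finite parameters at epoch {epoch}") from exc
        accs = {}
        for name, idx in (("train", train_idx), ("valid", valid_idx), ("test", test_idx)):
            if len(idx) == 0:
                accs[name] = float("nan")
                continue
            logits = _chunk_logits(snapshot, model_config, x, graph, idx, eval_chunk)
            accs[name] = float((logits.argmax(axis=1) == codes[idx]).mean())
        history.train_accuracy.append(accs["train"])
        history.valid_accuracy.append(accs["valid"])
        history.test_accuracy.append(accs["test"])

        if train_config.selection == "valid_best":
            score = accs["valid"]
            history.selection_label_indices.update(int(i) for i in valid_idx)
        elif train_config.selection == "paper_test_best":
            score = accs["test"]
            history.selection_label_indices.update(int(i) for i in test_idx)
        else:
            score = epoch  # "last": monotone, final epoch wins
        if np.isnan(score):
            score = epoch
        # ties go to the later epoch: validation accuracy is discrete and
        # plateaus long before the loss converges, and the first epoch of a
        # plateau is systematically under-trained (rare classes are fit late)
        if score >= best_score:
            best_score, best_epoch = score, epoch
            best_arrays = {k: t.data.copy() for k, t in pt.items()}

    history.selected_epoch = best_epoch
    final = ModelParams(best_arrays, params.n_genes, params.n_classes)
    return final, history


def train_minibatch(
    x_hat,
    labels: LabelSet,
    graph: Optional[CellGraph] = None,
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(batch_size=512),
    split: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> tuple[ModelParams, TrainHistory]:
    """Mini-batch variant of :func:`train` (batch_size must be set)."""
    if train_config.batch_size == "full":
        raise ValueError("train_minibatch requires an integer batch_size")
    return train(x_hat, labels, graph, model_config, train_config, split)


def predict(
    params: ModelParams,
    model_config: ModelConfig,
    query_x_hat,
    graph: Optional[CellGraph] = None,
    vocabulary: Optional[Sequence[str]] = None,
    chunk_size: int = 512,
) -> tuple[LabelSet, np.ndarray]:
    """Annotate query cells: argmax labels and row-stochastic probabilities.

    Large query sets are processed in contiguous chunks with attention
    restricted to each chunk, mirroring mini-batch training.
    """
    x = _as_features(query_x_hat)
    if x.shape[1] != params.n_genes:
        raise ValueError(
            f"query has {x.shape[1]} genes but the checkpoint expects {params.n_genes}"
        )
    logits = _chunk_logits(params, model_config, x, graph, np.arange(x.shape[0]), chunk_size)
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    codes = probs.argmax(axis=1)
    vocab = (
        tuple(vocabulary)
        if vocabulary is not None
        else tuple(f"class_{i}" for i in range(params.n_classes))
    )
    labels = tuple(vocab[c] for c in codes)
    return LabelSet(labels, vocab, codes.astype(np.int64)), probs


def run_replicates(
    x_hat,
    labels: LabelSet,
    graph: Optional[CellGraph] = None,
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    replicates: Optional[int] = None,
) -> tuple[list[metrics_mod.MetricsReport], dict[str, dict[str, float]]]:
    """Repeat split→train→test ``replicates`` times with independent seeds.

    Returns per-replicate test-set reports and a mean/sd summary per metric.
    """
    reps = train_config.replicates if replicates is None else replicates
    if reps < 1:
        raise ValueError("replicates must be >= 1")
    x = _as_features(x_hat)
    reports = []
    for r in range(reps):
        seed_r = train_config.seed + 1000 * r
        cfg_r = TrainConfig(
            ratios=train_config.ratios,
            epochs=train_config.epochs,
            learning_rate=train_config.learning_rate,
            weight_decay=train_config.weight_decay,
            batch_size=train_config.batch_size,
            selection=train_config.selection,
            seed=seed_r,
            replicates=train_config.replicates,
        )
        model_r = ModelConfig(**{**_cfg_dict(model_config), "seed": model_config.seed + r})
        split = split_dataset(x.shape[0], cfg_r.ratios, seed_r, labels)
        params, _ = train(x, labels, graph, model_r, cfg_r, split)
        test_idx = split[2]
        pred, _ = predict(
            params, model_r, x[test_idx],
            graph.induced(test_idx) if graph is not None else None,
            vocabulary=labels.vocabulary,
        )
        reports.append(metrics_mod.classification_report(labels.subset(test_idx), pred))
    summary: dict[str, dict[str, float]] = {}
    for name in ("accuracy", "weighted_f1", "macro_f1", "kappa", "nmi", "ari",
                 "balanced_accuracy"):
        vals = np.array([getattr(rep, name) for rep in reports], dtype=float)
        summary[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return reports, summary


def _cfg_dict(cfg: ModelConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def label_transfer(
    reference_raw: ExpressionMatrix,
    reference_labels: LabelSet,
    query_raw: ExpressionMatrix,
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(ratios=(0.8, 0.2, 0.0)),
    n_hvg: int = DEFAULT_HVG_CAP,
    use_graph_k: Optional[int] = None,
) -> tuple[LabelSet, np.ndarray, ModelParams]:
    """Cross-dataset annotation: fit on a labelled reference, predict a query.

    The inter-dataset protocol: QC-filter both datasets, restrict to
    their shared genes, log-normalise each, select HVGs on the reference
    and apply the same gene subset to the query, split the reference
    0.8/0.2 into train/valid (the query is never touched before
    prediction), train, then annotate the query in chunks.  Graphs, when
    requested via ``use_graph_k``, are built per dataset.
    """
    ref_f = qc_filter(reference_raw)
    qry_f = qc_filter(query_raw)
    # labels follow the cells that survived QC
    keep = {c: i for i, c in enumerate(reference_raw.cell_ids)}
    ref_labels = encode_labels(
        [reference_labels.labels[keep[c]] for c in ref_f.cell_ids],
        reference_labels.vocabulary,
    )
    ref_f, qry_f = align_genes(ref_f, qry_f)
    ref_n = normalize_log(ref_f)
    qry_n = normalize_log(qry_f)
    ref_hvg, kept = select_hvg(ref_n, n_top=min(n_hvg, ref_n.n_genes))
    qry_x = qry_n.dense()[:, kept]

    ref_graph = qry_graph = None
    if use_graph_k is not None:
        ref_graph = build_knn_graph(ref_hvg, k=use_graph_k)
        qry_graph = build_knn_graph(qry_x, k=use_graph_k)

    split = split_dataset(ref_hvg.n_cells, train_config.ratios, train_config.seed,
                          ref_labels)
    params, _ = train(ref_hvg, ref_labels, ref_graph, model_config, train_config, split)
    chunk = 512 if train_config.batch_size == "full" else int(train_config.batch_size)
    pred, probs = predict(params, model_config, qry_x, qry_graph,
                          vocabulary=ref_labels.vocabulary, chunk_size=chunk)
    return pred, probs, params
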