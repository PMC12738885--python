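"""Dataset splitting, rebalancing, GCN training and Table-1-style evaluation.

Splits are stratified by class with largest-remainder rounding, reconciled so
the global partition sizes also equal the largest-remainder allocation of the
totals (70/10/20 of 1,053 samples gives exactly 737/105/211).  Random
over-sampling (ROS) equalizes training class counts by duplicating minority
samples and is never applied to validation or test data.  The optimizer is
Adam with decoupled weight decay (AdamW); training keeps the parameters of
the best validation-loss epoch and stops early after ``patience`` epochs
without improvement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import precision_recall_fscore_support

from . import gcnmodel as gm
from .gcnmodel import CLASSES, GCNConfig, GCNParams, GraphBatch
from .graphs import WeightedGraph, normalize_adjacency, random_graph_matched, threshold_ppi
from .dge import RegionDEGSets

logger = logging.getLogger(__name__)

PARTITIONS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.7, 0.1, 0.2)


# ---------------------------------------------------------------------------
# splitting and rebalancing

def largest_remainder(total: int, fractions) -> list:
    """Integer allocation of ``total`` by largest-remainder rounding."""
    quotas = [total * f for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    short = total - sum(base)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - base[i]), i)
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def stratified_split(
    labels: pd.Series, fractions=DEFAULT_FRACTIONS, seed: int = 0
) -> pd.Series:
    """Assign each sample to train/val/test, stratified by label.

    Within each class, counts follow largest-remainder rounding of
    ``class_size * fraction``; leftover units are then distributed so the
    global partition sizes equal the largest-remainder allocation of the
    totals.  Classes with fewer than 3 members go entirely to train.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    assignment = pd.Series("train", index=labels.index, name="partition")

    counts = labels.value_counts()
    small = [c for c in counts.index if counts[c] < 3]
    for c in small:
        warnings.warn(f"class {c!r} has < 3 samples; assigning all to train")
    classes = sorted(c for c in counts.index if c not in small)
    total = int(counts[classes].sum())
    targets = largest_remainder(total, fractions)

    base = {c: [int(np.floor(counts[c] * f)) for f in fractions] for c in classes}
    leftover = {c: counts[c] - sum(base[c]) for c in classes}
    deficit = [targets[p] - sum(base[c][p] for c in classes) for p in range(3)]
    candidates = sorted(
        (
            (-(counts[c] * fractions[p] - base[c][p]), ci, p)
            for ci, c in enumerate(classes)
            for p in range(3)
        ),
    )
    for _negrem, ci, p in candidates:
        c = classes[ci]
        if leftover[c] > 0 and deficit[p] > 0:
            base[c][p] += 1
            leftover[c] -= 1
            deficit[p] -= 1
    for ci, c in enumerate(classes):  # greedy fallback, rarely needed
        while leftover[c] > 0:
            p = int(np.argmax(deficit))
            base[c][p] += 1
            leftover[c] -= 1
            deficit[p] -= 1

    for c in classes:
        idx = labels.index[labels == c].to_numpy()
        rng.shuffle(idx)
        n_tr, n_va, _ = base[c]
        assignment.loc[idx[:n_tr]] = "train"
        assignment.loc[idx[n_tr : n_tr + n_va]] = "val"
        assignment.loc[idx[n_tr + n_va :]] = "test"
    return assignment


def random_oversample(ids, labels, seed: int = 0) -> list:
    """Duplicate minority-class ids (with replacement) until classes balance.

    All original ids are retained; only extra duplicates are sampled.
    """
    ids = list(ids)
    labels = list(labels)
    if len(ids) != len(labels):
        raise ValueError("ids and labels must have equal length")
    by_class: dict = {}
    for i, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(i)
    if any(len(v) == 0 for v in by_class.values()) or not by_class:
        raise ValueError("every class must have >= 1 training sample")
    target = max(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    out = list(ids)
    for lab in sorted(by_class, key=str):
        members = by_class[lab]
        deficit = target - len(members)
        if deficit > 0:
            out.extend(rng.choice(members, size=deficit, replace=True))
    return out


# ---------------------------------------------------------------------------
# feature assembly

@dataclass
class CohortDataset:
    """Per-sample feature matrix over the universal gene list, plus the graph.

    Features are z-scored per gene with training-partition statistics.
    """

    genes: list
    sample_ids: list
    x: np.ndarray  # (n_samples, |G|) standardized
    y: np.ndarray  # integer class indices into CLASSES
    partition: pd.Series
    mask: np.ndarray | None = None  # (n_nodes, |G|) region DEG masks

    def rows(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.partition.loc[self.sample_ids].to_numpy() == part)

    def batch(self, a_hat: np.ndarray, part: str, ids=None) -> GraphBatch:
        rows = self.rows(part) if ids is None else ids
        return GraphBatch(a_hat=a_hat, x=self.x[rows], labels=self.y[rows], mask=self.mask)


def build_dataset(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    region_sets: RegionDEGSets,
    graph: WeightedGraph,
    split: pd.Series | None = None,
    seed: int = 0,
    fractions=DEFAULT_FRACTIONS,
) -> CohortDataset:
    """Assemble standardized per-sample features over G and the region masks."""
    genes = sorted(region_sets.universal)
    if not genes:
        raise ValueError("universal gene list G is empty; nothing to model")
    sample_ids = [s for s in samples["sample_id"] if s in expr.columns]
    meta = samples.set_index("sample_id").loc[sample_ids]
    y = np.array([CLASSES.index(g) for g in meta["group"]])
    labels = pd.Series(meta["group"].to_numpy(), index=sample_ids)
    if split is None:
        split = stratified_split(labels, fractions=fractions, seed=seed)
    x = expr.loc[genes, sample_ids].T.to_numpy(dtype=float)
    train_rows = np.flatnonzero(split.loc[sample_ids].to_numpy() == "train")
    mu = x[train_rows].mean(axis=0)
    sd = x[train_rows].std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    x = (x - mu) / sd
    restricted = region_sets.restricted()
    mask = np.zeros((graph.n_nodes, len(genes)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for i, node in enumerate(graph.nodes):
        for g in restricted.get(node, ()):  # nodes need not all be regions
            if g in gene_pos:
                mask[i, gene_pos[g]] = 1.0
    return CohortDataset(
        genes=genes, sample_ids=sample_ids, x=x, y=y, partition=split, mask=mask
    )


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainRecord:
    """Per-epoch curves plus a subsample of parameter-update values per epoch."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    update_samples: list = field(default_factory=list)  # one array per epoch
    best_epoch: int = -1
    n_epochs: int = 0

    def pooled_updates(self) -> np.ndarray:
        if not self.update_samples:
            return np.empty(0)
        return np.concatenate(self.update_samples)


class _AdamW:
    def __init__(self, params: GCNParams, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.as_dict().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.as_dict().items()}

    def step(self, params: GCNParams, grads: dict) -> dict:
        """Apply one update in place; return the parameter deltas per block."""
        self.t += 1
        deltas = {}
        for k in gm.PARAM_KEYS:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p = getattr(params, k)
            delta = -self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)
            p += delta
            deltas[k] = delta
        return deltas


def train(
    config: GCNConfig,
    a_hat: np.ndarray,
    data: CohortDataset,
    lr: float = 0.00703,
    weight_decay: float = 1.06e-5,
    max_epochs: int = 200,
    patience: int = 20,
    batch_size: int = 64,
    oversample: bool = True,
    seed: int = 0,
    n_update_samples: int = 256,
) -> tuple[GCNParams, TrainRecord]:
    """Train the GCN with AdamW, ROS on train only, and early stopping.

    Returns the parameters of the best validation-loss epoch and the full
    training record.  Deterministic under fixed seeds.
    """
    rng = np.random.default_rng(seed)
    params = gm.init_params(config)
    opt = _AdamW(params, lr=lr, weight_decay=weight_decay)
    record = TrainRecord()

    train_rows = data.rows("train")
    if oversample:
        resampled = random_oversample(
            list(train_rows), list(data.y[train_rows]), seed=seed
        )
        train_rows = np.array(resampled, dtype=int)
    val_batch = data.batch(a_hat, "val")
    if train_rows.size == 0 or val_batch.x.shape[0] == 0:
        raise ValueError("train and validation partitions must be nonempty")

    n_flat = params.flatten().size
    sample_pos = rng.choice(n_flat, size=min(n_update_samples, n_flat), replace=False)

    best_loss = np.inf
    best_params = params.copy()
    bad_epochs = 0
    for epoch in range(max_epochs):
        order = rng.permutation(train_rows)
        losses = []
        deltas = None
        for start in range(0, order.size, batch_size):
            rows = order[start : start + batch_size]
            batch = GraphBatch(a_hat=a_hat, x=data.x[rows], labels=data.y[rows], mask=data.mask)
            probs, cache = gm.forward(params, batch, config, training=True, rng=rng, return_cache=True)
            batch_loss = gm.loss(probs, batch.labels)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}: {batch_loss} (lr={lr}, wd={weight_decay})"
                )
            losses.append(batch_loss)
            grads = gm.backward(params, batch, config, cache)
            deltas = opt.step(params, grads)
        flat_delta = np.concatenate([deltas[k].ravel() for k in gm.PARAM_KEYS])
        record.update_samples.append(flat_delta[sample_pos].copy())
        record.train_loss.append(float(np.mean(losses)))

        val_probs = gm.forward(params, val_batch, config, training=False)
        vloss = gm.loss(val_probs, val_batch.labels)
        vacc = float((val_probs.argmax(axis=1) == val_batch.labels).mean())
        record.val_loss.append(vloss)
        record.val_acc.append(vacc)
        record.n_epochs = epoch + 1

        if vloss < best_loss - 1e-12:
            best_loss = vloss
            best_params = params.copy()
            record.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > patience:
                break
    return best_params, record


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 and overall accuracy."""

    per_class: pd.DataFrame  # index = class label; columns precision, recall, f1
    accuracy: float
    acc_mean: float | None = None
    acc_sd: float | None = None

    def to_row(self, model_name: str) -> dict:
        row = {"model": model_name}
        for cls in self.per_class.index:
            for metric in ("precision", "recall", "f1"):
                row[f"{cls}_{metric[0].upper() if metric != 'f1' else 'F1'}"] = round(
                    float(self.per_class.loc[cls, metric]), 3
                )
        row["accuracy"] = round(self.accuracy, 3)
        if self.acc_mean is not None:
            row["acc_mean"] = round(self.acc_mean, 3)
            row["acc_sd"] = round(self.acc_sd, 3)
        return row


def metrics_from_predictions(y_true, y_pred, n_classes: int = 3) -> MetricsReport:
    """Per-class precision/recall/F1 and accuracy from label/prediction arrays."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    missing = set(range(n_classes)) - set(y_pred)
    if missing:
        warnings.warn(
            f"classes never predicted: {[CLASSES[i] for i in sorted(missing)]}; "
            "their precision is 0 by convention"
        )
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(range(n_classes)), zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": p, "recall": r, "f1": f1}, index=list(CLASSES[:n_classes])
    )
    return MetricsReport(per_class=per_class, accuracy=float((y_pred == y_true).mean()))


def evaluate(
    params: GCNParams, config: GCNConfig, a_hat: np.ndarray, data: CohortDataset,
    part: str = "test",
) -> MetricsReport:
    batch = data.batch(a_hat, part)
    if batch.x.shape[0] == 0:
        raise ValueError(f"partition {part!r} is empty")
    probs = gm.forward(params, batch, config, training=False)
    return metrics_from_predictions(batch.labels, probs.argmax(axis=1), config.n_classes)


# ---------------------------------------------------------------------------
# statsmodels-style facade

class BrainRegionGCN:
    """Graph convolutional classifier over a brain-region interaction graph.

    Parameters
    ----------
    graph : WeightedGraph
        Region graph with self-loops (e.g. the DEG-BRIN).
    data : CohortDataset
        Standardized per-sample features over G with partition assignment.
    hidden_dim, dropout, feature_mode, seed
        Architecture settings (see :class:`degbrin.gcnmodel.GCNConfig`).
    """

    def __init__(
        self,
        graph: WeightedGraph,
        data: CohortDataset,
        hidden_dim: int = 103,
        dropout: float = 0.458,
        feature_mode: str = "broadcast",
        seed: int = 0,
    ):
        self.graph = graph
        self.data = data
        self.a_hat = normalize_adjacency(graph)
        self.config = GCNConfig(
            n_nodes=graph.n_nodes,
            in_dim=1 if feature_mode == "per_node" else len(data.genes),
            hidden_dim=hidden_dim,
            dropout=dropout,
            feature_mode=feature_mode,
            seed=seed,
        )

    @classmethod
    def from_cohort(
        cls, expr, samples, region_sets, graph, seed: int = 0, **kwargs
    ) -> "BrainRegionGCN":
        data = build_dataset(expr, samples, region_sets, graph, seed=seed)
        return cls(graph, data, seed=seed, **kwargs)

    def fit(self, **train_kwargs) -> "GCNResults":
        seed = train_kwargs.pop("seed", self.config.seed)
        params, record = train(self.config, self.a_hat, self.data, seed=seed, **train_kwargs)
        return GCNResults(self, params, record)


class GCNResults:
    """Fitted GCN: parameters, training record, evaluation and summaries."""

    def __init__(self, model: BrainRegionGCN, params: GCNParams, record: TrainRecord):
        self.model = model
        self.params = params
        self.record = record

    def evaluate(self, part: str = "test") -> MetricsReport:
        return evaluate(self.params, self.model.config, self.model.a_hat, self.model.data, part)

    def predict(self, part: str = "test") -> np.ndarray:
        batch = self.model.data.batch(self.model.a_hat, part)
        return gm.forward(self.params, batch, self.model.config, training=False)

    def summary(self) -> pd.DataFrame:
        report = self.evaluate("test")
        out = report.per_class.copy()
        out.attrs["accuracy"] = report.accuracy
        out.attrs["best_epoch"] = self.record.best_epoch
        out.attrs["n_epochs"] = self.record.n_epochs
        return out


# ---------------------------------------------------------------------------
# ablations and comparisons

def compare_models(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    region_sets: RegionDEGSets,
    ppi_edges: pd.DataFrame | None = None,
    ppi_tau: float = 0.4,
    seeds=(0, 1, 2, 3, 4),
    hidden_dim: int = 103,
    dropout: float = 0.458,
    feature_mode: str = "masked",
    external_predictions: dict | None = None,
    **train_kwargs,
) -> pd.DataFrame:
    """Train and evaluate DEG-BRIN-GCN, Random-GCN and PPI-GCN on shared splits.

    One row per model with per-class precision/recall/F1 and accuracy
    mean ± sd over the paired seeds.  ``external_predictions`` may map a
    model name to a per-seed list of predicted class-index arrays for the
    test partition (the hook for off-the-shelf classifier baselines).
    """
    from .graphs import build_degbrin

    brin = build_degbrin(region_sets)
    genes_g = sorted(region_sets.universal)
    accs: dict = {"DEG-BRIN-GCN": [], "Random-GCN": []}
    reports: dict = {}
    if ppi_edges is not None:
        accs["PPI-GCN"] = []
    else:
        warnings.warn("no PPI edge list supplied; comparing BRIN and Random only")

    for seed in seeds:
        data = build_dataset(expr, samples, region_sets, brin, seed=seed)
        specs = {
            "DEG-BRIN-GCN": (brin, feature_mode, data),
            "Random-GCN": (
                random_graph_matched(
                    brin.n_nodes,
                    brin.n_edges,
                    self_loop_weights=np.diag(brin.weights),
                    seed=seed,
                    nodes=brin.nodes,
                ),
                feature_mode,
                None,
            ),
        }
        if ppi_edges is not None:
            ppi = threshold_ppi(ppi_edges, ppi_tau, nodes=genes_g)
            w = ppi.weights.copy()
            np.fill_diagonal(w, 1.0)  # self-loops so normalization is defined
            ppi_graph = WeightedGraph(nodes=ppi.nodes, weights=w)
            specs["PPI-GCN"] = (ppi_graph, "per_node", None)

        for name, (graph, mode, prebuilt) in specs.items():
            if prebuilt is None:
                d = build_dataset(expr, samples, region_sets, graph, split=data.partition, seed=seed)
            else:
                d = prebuilt
            if mode == "per_node":
                d = CohortDataset(
                    genes=d.genes, sample_ids=d.sample_ids,
                    x=d.x[:, :, None], y=d.y, partition=d.partition, mask=None,
                )
            model = BrainRegionGCN(
                graph, d, hidden_dim=hidden_dim, dropout=dropout,
                feature_mode=mode, seed=seed,
            )
            res = model.fit(seed=seed, **train_kwargs)
            report = res.evaluate("test")
            accs[name].append(report.accuracy)
            reports[name] = report

    rows = []
    for name, report in reports.items():
        report.acc_mean = float(np.mean(accs[name]))
        report.acc_sd = float(np.std(accs[name], ddof=1)) if len(accs[name]) > 1 else 0.0
        rows.append(report.to_row(name))
    if external_predictions:
        data0 = build_dataset(expr, samples, region_sets, brin, seed=seeds[0])
        y_test = data0.y[data0.rows("test")]
        for name, preds in external_predictions.items():
            ext_accs = [float((np.asarray(p) == y_test).mean()) for p in preds]
            rows.append(
                {"model": name, "accuracy": round(ext_accs[0], 3),
                 "acc_mean": round(float(np.mean(ext_accs)), 3),
                 "acc_sd": round(float(np.std(ext_accs, ddof=1)) if len(ext_accs) > 1 else 0.0, 3)}
            )
    table = pd.DataFrame(rows)
    table.attrs["accuracies"] = accs
    return table


# ---------------------------------------------------------------------------
# hyperparameter search

@dataclass(frozen=True)
class SearchSpace:
    """Random-search ranges (log-uniform for rates and decay)."""

    hidden_dim: tuple = (64, 256)
    lr: tuple = (1e-4, 1e-3)
    weight_decay: tuple = (1e-6, 1e-3)
    dropout: tuple = (0.3, 0.7)
    n_trials: int = 30
    seed: int = 0


def hyperparameter_search(
    space: SearchSpace,
    graph: WeightedGraph,
    data: CohortDataset,
    feature_mode: str = "broadcast",
    **train_kwargs,
) -> tuple[dict, pd.DataFrame]:
    """Seeded random search maximizing validation accuracy.

    Returns (best config dict, trial log with sampled values and scores).
    """
    rng = np.random.default_rng(space.seed)
    trials = []
    best = None
    for trial in range(space.n_trials):
        cfg = {
            "hidden_dim": int(rng.integers(space.hidden_dim[0], space.hidden_dim[1] + 1)),
            "lr": float(np.exp(rng.uniform(np.log(space.lr[0]), np.log(space.lr[1])))),
            "weight_decay": float(
                np.exp(rng.uniform(np.log(space.weight_decay[0]), np.log(space.weight_decay[1])))
            ),
            "dropout": float(rng.uniform(*space.dropout)),
        }
        model = BrainRegionGCN(
            graph, data, hidden_dim=cfg["hidden_dim"], dropout=cfg["dropout"],
            feature_mode=feature_mode, seed=space.seed,
        )
        res = model.fit(
            seed=space.seed, lr=cfg["lr"], weight_decay=cfg["weight_decay"], **train_kwargs
        )
        score = max(res.record.val_acc) if res.record.val_acc else 0.0
        trials.append({"trial": trial, **cfg, "val_acc": score})
        if best is None or score > best["val_acc"]:
            best = trials[-1]
    return dict(best), pd.DataFrame(trials)


def binomial_above_chance(accuracy: float, n: int, chance: float = 1.0 / 3.0) -> float:
    """One-sided binomial p-value that ``accuracy`` on n trials exceeds chance."""
    k = int(round(accuracy * n))
    return float(sps.binomtest(k, n, chance, alternative="greater").pvalue)
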