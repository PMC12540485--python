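"""Joint next-location / next-emotion prediction from trajectory matrices.

The model follows a Model/Results split: :class:`NextVisitModel` holds
the dataset and configuration, its :meth:`~NextVisitModel.fit` trains the
attention-based BiLSTM and returns a :class:`NextVisitResults` carrying
the trained network, per-epoch history, held-out metrics and a
``summary()`` table.

Architecture: each user history is a chronological stack of vertex
embeddings; a sinusoidal positional encoding is added, then two branches
read the encoded sequence in parallel — multi-head scaled dot-product
attention (global selective focus) and a BiLSTM (local sequential
continuity).  The attention output at the final step and the BiLSTM's
concatenated final states feed a shared fully connected trunk with two
softmax heads, one over stay areas and one over the four emotional
quadrants.  The loss is the sum of the two cross-entropies; an optional
joint head over (area x quadrant) classes replaces the two heads when
``joint_head`` is set.

Sequences are right-aligned: batches are padded at the front and masked,
so prediction always conditions on the most recent steps and padding
never changes the output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .autodiff import Tensor, concat
from .nn import (
    Adam,
    BiLSTM,
    Dropout,
    Linear,
    Module,
    MultiHeadAttention,
    cross_entropy,
    positional_encoding,
    softmax,
)
from .types import GraphVertex, Quadrant, TrajectoryMatrix

N_QUADRANTS = 4


@dataclass
class ModelConfig:
    """Sizes and training profile of the predictor.

    Defaults target roughly half a million trainable parameters at
    n_areas=100 (d_model 64, 4 heads, BiLSTM hidden 64 per direction,
    shared trunk 1024).
    """

    n_areas: int = 100
    d_model: int = 64
    n_heads: int = 4
    lstm_hidden: int = 64
    fc_hidden: int = 1024
    dropout: float = 0.1
    epochs: int = 256
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    max_seq_len: int = 50
    joint_head: bool = False
    attention_pool: str = "final"  # or "mean"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("n_areas", "d_model", "n_heads", "lstm_hidden", "fc_hidden",
                     "epochs", "batch_size", "max_seq_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class PredictionResult:
    """Class probabilities and argmax picks for one history."""

    area_probs: np.ndarray
    quadrant_probs: np.ndarray

    def __post_init__(self) -> None:
        for p in (self.area_probs, self.quadrant_probs):
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
                raise ValueError("probabilities must be non-negative and sum to 1")

    @property
    def top_area(self) -> int:
        return int(np.argmax(self.area_probs))

    @property
    def top_quadrant(self) -> Quadrant:
        return Quadrant(int(np.argmax(self.quadrant_probs)) + 1)


class AttentionBiLSTMNet(Module):
    """The bare network; batches are (padded rows, mask) pairs."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.attention = MultiHeadAttention(c.d_model, c.n_heads, rng)
        self.bilstm = BiLSTM(c.d_model, c.lstm_hidden, rng)
        d_merge = c.d_model + 2 * c.lstm_hidden
        self.trunk = Linear(d_merge, c.fc_hidden, rng)
        if c.joint_head:
            self.head_joint = Linear(c.fc_hidden, c.n_areas * N_QUADRANTS, rng)
            self.head_area = self.head_quadrant = None
        else:
            self.head_area = Linear(c.fc_hidden, c.n_areas, rng)
            self.head_quadrant = Linear(c.fc_hidden, N_QUADRANTS, rng)
            self.head_joint = None
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(c.seed).spawn(1)[0])
        self.drop = Dropout(c.dropout, self._dropout_rng)

    def parameters(self) -> List[Tensor]:
        ps = self.attention.parameters() + self.bilstm.parameters() + self.trunk.parameters()
        if self.head_joint is not None:
            ps += self.head_joint.parameters()
        else:
            ps += self.head_area.parameters() + self.head_quadrant.parameters()
        return ps

    def forward(self, x: np.ndarray, mask: np.ndarray,
                training: bool = False) -> Tuple[Tensor, Tensor]:
        """x: (B, T, d_model) encoded & front-padded; mask: (B, T).

        Returns (area logits, quadrant logits); with a joint head the
        logits are over flattened (area, quadrant) classes and are split
        by marginalisation at prediction time.
        """
        if x.shape[1] < 1:
            raise ValueError("empty sequence")
        xt = Tensor(x)
        attn = self.attention(xt, key_mask=mask)
        if self.config.attention_pool == "mean":
            m = mask[:, :, None]
            attn_vec = (attn * Tensor(m)).sum(axis=1) * Tensor(1.0 / m.sum(axis=1))
        else:
            attn_vec = attn[:, -1, :]  # right-aligned: final step is real
        lstm_vec = self.bilstm(xt, mask)
        merged = concat([attn_vec, lstm_vec], axis=-1)
        h = self.drop(self.trunk(self.drop(merged, training)).relu(), training)
        if self.head_joint is not None:
            logits = self.head_joint(h)
            return logits, logits
        return self.head_area(h), self.head_quadrant(h)


def encode_batch(
    rows_list: Sequence[np.ndarray],
    config: ModelConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Truncate, positionally encode and front-pad a batch of histories."""
    d = config.d_model
    trimmed = []
    for rows in rows_list:
        if rows.shape[0] < 1:
            raise ValueError("empty sequence")
        if rows.shape[1] != d:
            raise ValueError(f"rows have dim {rows.shape[1]}, model expects {d}")
        r = rows[-config.max_seq_len:]
        trimmed.append(r + positional_encoding(r.shape[0], d))
    T = max(r.shape[0] for r in trimmed)
    B = len(trimmed)
    x = np.zeros((B, T, d))
    mask = np.zeros((B, T))
    for b, r in enumerate(trimmed):
        x[b, T - r.shape[0]:] = r
        mask[b, T - r.shape[0]:] = 1.0
    return x, mask


def model_forward(net: AttentionBiLSTMNet, rows: np.ndarray) -> PredictionResult:
    """Run one history through the network and return class probabilities."""
    x, mask = encode_batch([np.asarray(rows, dtype=float)], net.config)
    la, lq = net.forward(x, mask, training=False)
    if net.head_joint is not None:
        joint = softmax(la, axis=-1).data[0].reshape(net.config.n_areas, N_QUADRANTS)
        return PredictionResult(joint.sum(axis=1), joint.sum(axis=0))
    return PredictionResult(softmax(la, axis=-1).data[0], softmax(lq, axis=-1).data[0])


# ---------------------------------------------------------------------------
# metrics


@dataclass
class Metrics:
    """Joint and per-head accuracy with macro P/R/F1 and stratifications."""

    joint_accuracy: float
    area_accuracy: float
    quadrant_accuracy: float
    area_precision: float
    area_recall: float
    area_f1: float
    quadrant_precision: float
    quadrant_recall: float
    quadrant_f1: float
    per_quadrant_area_accuracy: Dict[str, float]
    per_length_accuracy: Dict[str, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "joint_accuracy": self.joint_accuracy,
            "area_accuracy": self.area_accuracy,
            "quadrant_accuracy": self.quadrant_accuracy,
            "area_precision": self.area_precision,
            "area_recall": self.area_recall,
            "area_f1": self.area_f1,
            "quadrant_precision": self.quadrant_precision,
            "quadrant_recall": self.quadrant_recall,
            "quadrant_f1": self.quadrant_f1,
            "per_quadrant_area_accuracy": self.per_quadrant_area_accuracy,
            "per_length_accuracy": self.per_length_accuracy,
            "n": self.n,
        }


_LENGTH_BINS = [(2, 10, "10"), (11, 20, "20"), (21, 30, "30"),
                (31, 40, "40"), (41, 10 ** 9, "50")]


def _macro_prf(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> Tuple[float, float, float]:
    present = np.unique(y_true)
    if len(present) < n_classes:
        warnings.warn(f"{n_classes - len(present)} classes unseen; excluded from macro average")
    p, r, f, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=present, average="macro", zero_division=0)
    return float(p), float(r), float(f)


def compute_metrics(
    area_true: np.ndarray,
    area_pred: np.ndarray,
    quad_true: np.ndarray,
    quad_pred: np.ndarray,
    lengths: np.ndarray,
    n_areas: int,
) -> Metrics:
    """Score predictions; ``lengths`` are full check-in sequence lengths."""
    area_true, area_pred = np.asarray(area_true), np.asarray(area_pred)
    quad_true, quad_pred = np.asarray(quad_true), np.asarray(quad_pred)
    joint = (area_true == area_pred) & (quad_true == quad_pred)
    ap, ar, af = _macro_prf(area_true, area_pred, n_areas)
    qp, qr, qf = _macro_prf(quad_true, quad_pred, N_QUADRANTS)
    per_quadrant = {}
    for q in Quadrant:
        m = quad_true == (q.value - 1)
        if m.any():
            per_quadrant[q.name] = float((area_true[m] == area_pred[m]).mean())
    per_length = {}
    for lo, hi, label in _LENGTH_BINS:
        m = (lengths >= lo) & (lengths <= hi)
        if m.any():
            per_length[label] = float(joint[m].mean())
    return Metrics(
        joint_accuracy=float(joint.mean()),
        area_accuracy=float((area_true == area_pred).mean()),
        quadrant_accuracy=float((quad_true == quad_pred).mean()),
        area_precision=ap, area_recall=ar, area_f1=af,
        quadrant_precision=qp, quadrant_recall=qr, quadrant_f1=qf,
        per_quadrant_area_accuracy=per_quadrant,
        per_length_accuracy=per_length,
        n=int(len(area_true)),
    )


# ---------------------------------------------------------------------------
# Model / Results


class NextVisitModel:
    """Attention-BiLSTM next-visit model over a trajectory-matrix dataset.

    Parameters
    ----------
    dataset : sequence of TrajectoryMatrix
        Training samples (history rows + target vertex).
    config : ModelConfig
        Architecture and training profile; ``config.n_areas`` must cover
        every area id appearing in the targets.
    """

    def __init__(self, dataset: Sequence[TrajectoryMatrix], config: ModelConfig):
        if len(dataset) < 2:
            raise ValueError("need at least 2 samples")
        self.dataset = list(dataset)
        self.config = config
        for s in self.dataset:
            if not 0 <= s.target.area_id < config.n_areas:
                raise ValueError(f"target area {s.target.area_id} outside [0, {config.n_areas})")

    @classmethod
    def from_trajectories(cls, trajectories, table, config: ModelConfig,
                          expand: bool = True, max_history: Optional[int] = None):
        """Build the dataset straight from trajectories + embedding table."""
        from .embedding import expand_trajectory, trajectory_matrix

        samples: List[TrajectoryMatrix] = []
        for tr in trajectories:
            if len(tr) < 2:
                continue
            if expand:
                samples.extend(expand_trajectory(tr, table, max_history=max_history))
            else:
                samples.append(trajectory_matrix(tr, table))
        return cls(samples, config)

    # -- internals -----------------------------------------------------------

    @staticmethod
    def _targets(samples: Sequence[TrajectoryMatrix]) -> Tuple[np.ndarray, np.ndarray]:
        a = np.array([s.target.area_id for s in samples], dtype=int)
        q = np.array([s.target.quadrant.value - 1 for s in samples], dtype=int)
        return a, q

    def _batches(self, samples: Sequence[TrajectoryMatrix],
                 rng: Optional[np.random.Generator]) -> List[List[int]]:
        """Length-sorted batches (less padding), order shuffled per epoch."""
        order = sorted(range(len(samples)), key=lambda i: (samples[i].n_steps, i))
        bs = self.config.batch_size
        batches = [order[i:i + bs] for i in range(0, len(order), bs)]
        if rng is not None:
            rng.shuffle(batches)
        return batches

    def _loss_and_logits(self, net: AttentionBiLSTMNet,
                         samples: Sequence[TrajectoryMatrix], idx: Sequence[int],
                         training: bool) -> Tuple[Tensor, Tensor, Tensor]:
        batch = [samples[i] for i in idx]
        x, mask = encode_batch([s.rows for s in batch], self.config)
        la, lq = net.forward(x, mask, training=training)
        a, q = self._targets(batch)
        if net.head_joint is not None:
            joint_t = a * N_QUADRANTS + q
            loss = cross_entropy(la, joint_t)
        else:
            loss = cross_entropy(la, a) + cross_entropy(lq, q)
        return loss, la, lq

    def _predict_labels(self, net: AttentionBiLSTMNet,
                        samples: Sequence[TrajectoryMatrix]) -> Tuple[np.ndarray, np.ndarray]:
        preds_a, preds_q = [], []
        for idx in self._batches(samples, rng=None):
            batch = [samples[i] for i in idx]
            x, mask = encode_batch([s.rows for s in batch], self.config)
            la, lq = net.forward(x, mask, training=False)
            if net.head_joint is not None:
                joint = la.data.reshape(len(batch), self.config.n_areas, N_QUADRANTS)
                flat = joint.reshape(len(batch), -1).argmax(axis=1)
                pa, pq = flat // N_QUADRANTS, flat % N_QUADRANTS
            else:
                pa, pq = la.data.argmax(axis=1), lq.data.argmax(axis=1)
            for j, i in enumerate(idx):
                preds_a.append((i, pa[j]))
                preds_q.append((i, pq[j]))
        preds_a.sort()
        preds_q.sort()
        return (np.array([p for _, p in preds_a]), np.array([p for _, p in preds_q]))

    def _split(self, rng: np.random.Generator,
               group_by: str = "user") -> Tuple[List[int], List[int]]:
        """80/20 split, grouped by user so no user's prefixes straddle it."""
        n = len(self.dataset)
        if group_by == "user":
            users = sorted({s.user_id for s in self.dataset})
            if len(users) >= 5:
                users = np.array(users, dtype=object)
                rng.shuffle(users)
                cut = max(1, int(round(0.2 * len(users))))
                held = set(users[:cut])
                test = [i for i, s in enumerate(self.dataset) if s.user_id in held]
                test_set = set(test)
                train = [i for i in range(n) if i not in test_set]
                return train, test
        order = rng.permutation(n)
        cut = max(1, int(round(0.2 * n)))
        return list(order[cut:]), list(order[:cut])

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        epochs: Optional[int] = None,
        val_dataset: Optional[Sequence[TrajectoryMatrix]] = None,
        group_by: str = "user",
        verbose: bool = False,
    ) -> "NextVisitResults":
        """Train the network and score it on held-out data.

        When no ``val_dataset`` is supplied, 80% of the samples (grouped
        by user) train the model and the remaining 20% are the holdout.
        """
        cfg = self.config
        n_epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
        if val_dataset is None:
            train_idx, val_idx = self._split(rng, group_by=group_by)
            train = [self.dataset[i] for i in train_idx]
            val = [self.dataset[i] for i in val_idx]
        else:
            train = list(self.dataset)
            val = list(val_dataset)

        a_tr, q_tr = self._targets(train)
        if len(np.unique(a_tr)) < 1 or len(np.unique(q_tr)) < 1:
            raise ValueError("training targets must cover at least one class per head")

        net = AttentionBiLSTMNet(cfg)
        opt = Adam(net.parameters(), lr=cfg.lr)
        history: List[Dict[str, float]] = []
        for epoch in range(n_epochs):
            total, count = 0.0, 0
            for idx in self._batches(train, rng=rng):
                opt.zero_grad()
                loss, _, _ = self._loss_and_logits(net, train, idx, training=True)
                if not math.isfinite(float(loss.data)):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}: {float(loss.data)} "
                        f"(lr={cfg.lr}, batch={cfg.batch_size})")
                loss.backward()
                opt.step()
                total += float(loss.data) * len(idx)
                count += len(idx)
            history.append({"epoch": epoch, "train_loss": total / count})
            if verbose:
                print(f"epoch {epoch}: loss {total / count:.4f}")

        return NextVisitResults(model=self, net=net, history=history,
                                train_set=train, val_set=val)


class NextVisitResults:
    """Fit artefacts: network, history, held-out metrics, summary()."""

    def __init__(self, model: NextVisitModel, net: AttentionBiLSTMNet,
                 history: List[Dict[str, float]],
                 train_set: Sequence[TrajectoryMatrix],
                 val_set: Sequence[TrajectoryMatrix]):
        self.model = model
        self.net = net
        self.history = history
        self.train_set = list(train_set)
        self.val_set = list(val_set)
        self._metrics: Optional[Metrics] = None

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def predict(self, rows: np.ndarray) -> PredictionResult:
        return model_forward(self.net, rows)

    def score(self, dataset: Optional[Sequence[TrajectoryMatrix]] = None) -> Metrics:
        """Metrics on ``dataset`` (default: the held-out split)."""
        data = self.val_set if dataset is None else list(dataset)
        if not data:
            raise ValueError("no samples to score")
        pa, pq = self.model._predict_labels(self.net, data)
        a, q = self.model._targets(data)
        lengths = np.array([s.n_steps + 1 for s in data])
        return compute_metrics(a, pa, q, pq, lengths, self.model.config.n_areas)

    @property
    def metrics(self) -> Metrics:
        if self._metrics is None:
            self._metrics = self.score()
        return self._metrics

    def summary(self) -> str:
        cfg = self.model.config
        m = self.metrics
        lines = [
            "Next-visit model (attention + BiLSTM)",
            "=" * 46,
            f"{'samples (train/val)':28s} {len(self.train_set)}/{len(self.val_set)}",
            f"{'stay-area classes':28s} {cfg.n_areas}",
            f"{'d_model / heads / lstm':28s} {cfg.d_model}/{cfg.n_heads}/{cfg.lstm_hidden}",
            f"{'trainable parameters':28s} {self.n_parameters}",
            f"{'epochs trained':28s} {len(self.history)}",
            f"{'final training loss':28s} {self.history[-1]['train_loss']:.4f}",
            "-" * 46,
            f"{'joint accuracy':28s} {m.joint_accuracy:.4f}",
            f"{'area accuracy':28s} {m.area_accuracy:.4f}",
            f"{'quadrant accuracy':28s} {m.quadrant_accuracy:.4f}",
            f"{'area macro P/R/F1':28s} {m.area_precision:.4f}/{m.area_recall:.4f}/{m.area_f1:.4f}",
            f"{'quadrant macro P/R/F1':28s} "
            f"{m.quadrant_precision:.4f}/{m.quadrant_recall:.4f}/{m.quadrant_f1:.4f}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Training-loss curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot([h["epoch"] for h in self.history],
                [h["train_loss"] for h in self.history])
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss")
        return ax


def save_net(net: AttentionBiLSTMNet, path) -> None:
    """Persist network weights + config as an .npz archive."""
    import dataclasses

    arrays = {f"p{k}": p.data for k, p in enumerate(net.parameters())}
    arrays["config_json"] = np.frombuffer(
        __import__("json").dumps(dataclasses.asdict(net.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_net(path) -> AttentionBiLSTMNet:
    import json as _json

    with np.load(path) as data:
        cfg = ModelConfig(**_json.loads(bytes(data["config_json"]).decode()))
        net = AttentionBiLSTMNet(cfg)
        for k, p in enumerate(net.parameters()):
            p.data[...] = data[f"p{k}"]
    return net


def train_model(dataset: Sequence[TrajectoryMatrix], config: ModelConfig,
                epochs: Optional[int] = None, **kw) -> NextVisitResults:
    """Functional wrapper: build a NextVisitModel and fit it."""
    return NextVisitModel(dataset, config).fit(epochs=epochs, **kw)


def evaluate(
    model: NextVisitModel,
    dataset: Optional[Sequence[TrajectoryMatrix]] = None,
    k_folds: int = 0,
    group_by: str = "user",
    epochs: Optional[int] = None,
) -> Metrics:
    """Holdout (k_folds=0) or k-fold cross-validated metrics.

    With k >= 2 the dataset is partitioned into k disjoint folds (grouped
    by user when ``group_by='user'``); the model is retrained on k-1
    folds and scored on the held-out fold, and the k numeric estimates
    are averaged.
    """
    data = list(model.dataset if dataset is None else dataset)
    if k_folds == 0:
        return model.fit(epochs=epochs, group_by=group_by).metrics
    if k_folds < 2:
        raise ValueError("k_folds must be 0 (holdout) or >= 2")
    from sklearn.model_selection import GroupKFold, KFold

    if group_by == "user" and len({s.user_id for s in data}) >= k_folds:
        splitter = GroupKFold(n_splits=k_folds)
        splits = splitter.split(np.arange(len(data)),
                                groups=[s.user_id for s in data])
    else:
        splitter = KFold(n_splits=k_folds, shuffle=True,
                         random_state=model.config.seed)
        splits = splitter.split(np.arange(len(data)))

    fold_metrics: List[Metrics] = []
    for train_idx, test_idx in splits:
        sub = NextVisitModel([data[i] for i in train_idx], model.config)
        res = sub.fit(epochs=epochs, val_dataset=[data[i] for i in test_idx])
        fold_metrics.append(res.metrics)

    def avg(attr):
        return float(np.mean([getattr(f, attr) for f in fold_metrics]))

    def avg_dict(attr):
        keys = sorted({k for f in fold_metrics for k in getattr(f, attr)})
        return {k: float(np.mean([getattr(f, attr)[k] for f in fold_metrics
                                  if k in getattr(f, attr)])) for k in keys}

    return Metrics(
        joint_accuracy=avg("joint_accuracy"),
        area_accuracy=avg("area_accuracy"),
        quadrant_accuracy=avg("quadrant_accuracy"),
        area_precision=avg("area_precision"),
        area_recall=avg("area_recall"),
        area_f1=avg("area_f1"),
        quadrant_precision=avg("quadrant_precision"),
        quadrant_recall=avg("quadrant_recall"),
        quadrant_f1=avg("quadrant_f1"),
        per_quadrant_area_accuracy=avg_dict("per_quadrant_area_accuracy"),
        per_length_accuracy=avg_dict("per_length_accuracy"),
        n=int(sum(f.n for f in fold_metrics)),
    )
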