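"""Model zoo and training objects for POD prediction.

Seven variants are supported, mirroring the comparison design:

========================  =============================================
``MLP_TAB_P/F/T``         MLP on percentile / signal-feature / vectorized
                          tabular aggregations
``LSTM_SEQ``              stacked LSTM on the sequence tensor
``TRAN_SEQ``              encoder-only transformer (TRAPOD) on sequences
``MLP_LSTM_SEQTAB``       LSTM on sequences fused with an MLP on statics
``MLP_TRAN_SEQTAB``       transformer fused with an MLP on statics
========================  =============================================

Training minimizes either a class-weighted binary cross entropy or the
focal loss ``FL(p_t) = -alpha_t (1 - p_t)^gamma log(p_t)``, which
down-weights easy examples and focuses the gradient on hard minority-class
cases; with ``gamma = 0`` and ``alpha_t`` equal to the class weights it
reduces exactly to weighted cross entropy.

The user-facing surface follows the Model/Results convention:
``PodModel(inputs, labels, config).fit(...)`` returns a :class:`PodResults`
carrying the trained network, the training log, predictions and a
``summary()`` table.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from .aggregate import TabularMatrix
from .nn import Adam, HybridNet, LSTMNet, MLPNet, Tensor, TransformerNet
from .preprocess import SequenceTensor, StaticMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AttentionMatrix",
    "FocalLossParams",
    "ModelConfig",
    "PodModel",
    "PodResults",
    "Prediction",
    "build_hybrid",
    "build_model",
    "extract_attention",
    "focal_loss",
    "predict",
    "weighted_ce",
]

VARIANTS = (
    "MLP_TAB_P",
    "MLP_TAB_F",
    "MLP_TAB_T",
    "LSTM_SEQ",
    "TRAN_SEQ",
    "MLP_LSTM_SEQTAB",
    "MLP_TRAN_SEQTAB",
)

SEQ_VARIANTS = ("LSTM_SEQ", "TRAN_SEQ")
HYBRID_VARIANTS = ("MLP_LSTM_SEQTAB", "MLP_TRAN_SEQTAB")
ATTENTION_VARIANTS = ("TRAN_SEQ", "MLP_TRAN_SEQTAB")


# ---------------------------------------------------------------------------
# Configuration and result containers


@dataclass(frozen=True)
class FocalLossParams:
    gamma: float = 2.0
    alpha: float = 0.25

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "TRAN_SEQ"
    mlp_neurons_per_layer: tuple[int, ...] = (32, 16)
    lstm_hidden: int = 32
    lstm_layers: int = 1
    tran_linear_dim: int | None = None  # default 32 stand-alone, 128 combined
    tran_heads: int = 1
    tran_encoder_layers: int = 1
    tran_ff_dim: int | None = None
    tran_positional: str = "sinusoidal"  # or "learnable"
    tran_pool: str = "mean"  # or "flatten"
    head_neurons: tuple[int, ...] = (8,)
    loss: str = "weighted_ce"  # or "focal"
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.tran_heads < 1:
            raise ValueError("tran_heads must be >= 1")
        if self.loss not in ("weighted_ce", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @property
    def linear_dim(self) -> int:
        if self.tran_linear_dim is not None:
            return self.tran_linear_dim
        return 128 if self.variant == "MLP_TRAN_SEQTAB" else 32


@dataclass
class Prediction:
    surgery_ids: list
    scores: np.ndarray  # O_m in [0, 1], one per surgery

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.surgery_ids) != self.scores.shape[0]:
            raise ValueError("one score per surgery required")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class AttentionMatrix:
    """Attention summaries of a transformer variant.

    ``attention`` is the query x key matrix of the last encoder block
    averaged over surgeries (rows sum to 1); ``saliency`` is the
    feature x time matrix S[f, t] = w_f * a_t with w_f the L1-normalized
    input-projection weight magnitude of channel f and a_t the mean
    attention mass received by time index t.
    """

    attention: np.ndarray  # (n, n)
    saliency: np.ndarray  # (k, n)
    per_time_mean: np.ndarray  # (n,)
    channel_names: list[str]
    per_surgery_received: np.ndarray | None = None  # (m, n)


# ---------------------------------------------------------------------------
# Losses (array form; the autodiff twin lives in _loss_tensor)

_EPS = np.finfo(float).eps


def _p_t(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        logger.warning("probabilities outside (0,1) clipped at machine epsilon")
        p = np.clip(p, _EPS, 1 - _EPS)
    return np.where(y == 1, p, 1 - p)


def focal_loss(p, y, params: FocalLossParams = FocalLossParams()) -> float:
    """Mean focal loss -alpha_t (1-p_t)^gamma log(p_t) over a batch.

    ``alpha`` weights the positive class; the negative class gets
    ``1 - alpha`` unless ``alpha == 1``, in which case both classes get 1
    (the pure focusing form).
    """
    y = np.asarray(y, dtype=float)
    pt = _p_t(p, y)
    if params.alpha == 1.0:
        alpha_t = np.ones_like(pt)
    else:
        alpha_t = np.where(y == 1, params.alpha, 1 - params.alpha)
    return float(np.mean(-alpha_t * (1 - pt) ** params.gamma * np.log(pt)))


def weighted_ce(p, y, pos_weight: float = 1.0) -> float:
    """Mean binary cross entropy with the positive class weighted."""
    if pos_weight <= 0:
        raise ValueError("pos_weight must be > 0")
    y = np.asarray(y, dtype=float)
    pt = _p_t(p, y)
    w = np.where(y == 1, pos_weight, 1.0)
    return float(np.mean(-w * np.log(pt)))


def _loss_tensor(logits: Tensor, y: np.ndarray, config: ModelConfig,
                 pos_weight: float) -> Tensor:
    """Differentiable batch loss on pre-sigmoid logits."""
    p = logits.sigmoid().clip(_EPS, 1 - _EPS)
    y = np.asarray(y, dtype=float)
    pt = p * y + (1.0 - p) * (1.0 - y)
    if config.loss == "focal":
        a = config.focal_alpha
        alpha_t = np.where(y == 1, a, 1 - a) if a < 1 else np.ones_like(y)
        return ((1.0 - pt) ** config.focal_gamma * pt.log() * alpha_t * -1.0).mean()
    w = np.where(y == 1, pos_weight, 1.0)
    return (pt.log() * w * -1.0).mean()


# ---------------------------------------------------------------------------
# Network construction


def _seq_array(data) -> np.ndarray:
    """(m, k, n) tensor -> (m, n, k) network input."""
    if isinstance(data, SequenceTensor):
        return np.transpose(data.values, (0, 2, 1))
    return np.asarray(data, dtype=float)


def _tab_array(data) -> np.ndarray:
    if isinstance(data, (TabularMatrix, StaticMatrix)):
        return data.values
    return np.asarray(data, dtype=float)


def build_model(config: ModelConfig, input_shapes: dict):
    """Instantiate an untrained network for ``config``.

    ``input_shapes`` carries ``n_channels``/``n_steps`` for sequence
    variants, ``n_tabular`` for MLP variants, and both for hybrids.
    """
    rng = np.random.default_rng(config.seed)
    v = config.variant
    if v.startswith("MLP_TAB"):
        return MLPNet(rng, input_shapes["n_tabular"], list(config.mlp_neurons_per_layer))
    if v == "LSTM_SEQ":
        return LSTMNet(rng, input_shapes["n_channels"], config.lstm_hidden,
                       config.lstm_layers, list(config.head_neurons))
    if v == "TRAN_SEQ":
        return TransformerNet(
            rng, input_shapes["n_channels"], input_shapes["n_steps"],
            d_model=config.linear_dim, n_heads=config.tran_heads,
            n_layers=config.tran_encoder_layers, d_ff=config.tran_ff_dim,
            head=list(config.head_neurons), positional=config.tran_positional,
            pool=config.tran_pool,
        )
    # hybrids: sequence branch + tabular MLP branch
    if v == "MLP_LSTM_SEQTAB":
        seq = LSTMNet(rng, input_shapes["n_channels"], config.lstm_hidden,
                      config.lstm_layers, list(config.head_neurons))
    else:
        seq = TransformerNet(
            rng, input_shapes["n_channels"], input_shapes["n_steps"],
            d_model=config.linear_dim, n_heads=config.tran_heads,
            n_layers=config.tran_encoder_layers, d_ff=config.tran_ff_dim,
            head=list(config.head_neurons), positional=config.tran_positional,
            pool=config.tran_pool,
        )
    tab = MLPNet(rng, input_shapes["n_tabular"], list(config.mlp_neurons_per_layer))
    return HybridNet(rng, seq, tab)


def build_hybrid(seq_net, tab_net, seed: int = 0) -> HybridNet:
    """Fuse a configured sequence network and a tabular MLP with a linear
    combiner (two weights + bias) followed by the output sigmoid."""
    return HybridNet(np.random.default_rng(seed), seq_net, tab_net)


def _forward(net, inputs) -> Tensor:
    if isinstance(net, HybridNet):
        x_seq, x_tab = inputs
        return net((Tensor(x_seq, requires_grad=False),
                    Tensor(x_tab, requires_grad=False)))
    return net(Tensor(inputs, requires_grad=False))


def _network_inputs(config: ModelConfig, data):
    """Normalize user data to the network's input arrays."""
    v = config.variant
    if v.startswith("MLP_TAB"):
        return _tab_array(data)
    if v in SEQ_VARIANTS:
        return _seq_array(data)
    seq, tab = data
    return (_seq_array(seq), _tab_array(tab))


def predict(net, config: ModelConfig, data, surgery_ids=None) -> Prediction:
    """Score surgeries with a (trained) network; deterministic in eval."""
    inputs = _network_inputs(config, data)
    logits = _forward(net, inputs)
    scores = 1.0 / (1.0 + np.exp(-logits.data))
    if surgery_ids is None:
        if isinstance(data, tuple):
            data = data[0]
        surgery_ids = getattr(data, "surgery_ids", list(range(len(scores))))
    return Prediction(list(surgery_ids), scores)


def extract_attention(net, config: ModelConfig, data) -> AttentionMatrix:
    """Attention summaries after a forward pass over ``data``.

    Requires a transformer variant.  The per-time profile a_t is the mean
    attention mass received by key/time index t; saliency multiplies it by
    the L1-normalized input-projection weight magnitude per channel.
    """
    if config.variant not in ATTENTION_VARIANTS:
        raise ValueError(f"variant {config.variant!r} has no attention module")
    tran = net.seq if isinstance(net, HybridNet) else net
    inputs = _network_inputs(config, data)
    _forward(net, inputs)
    attn_per_surgery = tran.blocks[-1].last_attention.mean(axis=1)  # (m, n, n)
    attention = attn_per_surgery.mean(axis=0)
    received = attn_per_surgery.mean(axis=1)  # (m, n): mass received per key
    a_t = received.mean(axis=0)
    w = np.abs(tran.input_projection_weights()).sum(axis=1)
    w = w / w.sum() if w.sum() > 0 else w
    saliency = np.outer(w, a_t)
    names = getattr(data[0] if isinstance(data, tuple) else data,
                    "channel_names", [f"ch{i}" for i in range(len(w))])
    return AttentionMatrix(attention, saliency, a_t, list(names), received)


# ---------------------------------------------------------------------------
# Model / Results objects


@dataclass
class TrainingLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


class PodModel:
    """A POD prediction model bound to training data.

    Parameters
    ----------
    inputs : SequenceTensor, TabularMatrix, array, or (seq, tab) tuple
        Training inputs matching ``config.variant``.
    labels : array of {0,1}
        POD labels per surgery, aligned with the inputs.
    config : ModelConfig
    """

    def __init__(self, inputs, labels, config: ModelConfig):
        self.config = config
        self.raw_inputs = inputs
        self.inputs = _network_inputs(config, inputs)
        self.labels = np.asarray(labels, dtype=float)
        n_pos = self.labels.sum()
        self.pos_weight = (
            float((len(self.labels) - n_pos) / n_pos) if n_pos > 0 else 1.0
        )
        self.input_shapes = self._shapes()
        self.net = build_model(config, self.input_shapes)

    def _shapes(self) -> dict:
        shapes = {}
        if isinstance(self.inputs, tuple):
            shapes["n_steps"] = self.inputs[0].shape[1]
            shapes["n_channels"] = self.inputs[0].shape[2]
            shapes["n_tabular"] = self.inputs[1].shape[1]
        elif self.inputs.ndim == 3:
            shapes["n_steps"] = self.inputs.shape[1]
            shapes["n_channels"] = self.inputs.shape[2]
        else:
            shapes["n_tabular"] = self.inputs.shape[1]
        return shapes

    def describe(self) -> dict[str, int]:
        """Parameter counts per component (a pure function of the config)."""
        return self.net.describe()

    def _batches(self, rng, n):
        order = rng.permutation(n)
        bs = self.config.batch_size
        for i in range(0, n, bs):
            yield order[i : i + bs]

    def _take(self, inputs, idx):
        if isinstance(inputs, tuple):
            return (inputs[0][idx], inputs[1][idx])
        return inputs[idx]

    def _eval_loss(self, inputs, labels) -> float:
        logits = _forward(self.net, inputs)
        return _loss_tensor(logits, labels, self.config, self.pos_weight).item()

    def fit(
        self,
        val_inputs=None,
        val_labels=None,
        max_epochs: int = 100,
        patience: int = 10,
        seed: int | None = None,
    ) -> "PodResults":
        """Train with Adam, early stopping on validation loss.

        Stops when the validation loss has not improved for ``patience``
        consecutive epochs and restores the best-epoch weights.  Without a
        validation set the model trains for ``max_epochs``.
        """
        if patience < 1:
            raise ValueError("patience must be >= 1")
        if (val_inputs is None) != (val_labels is None):
            raise ValueError("provide both or neither of val_inputs/val_labels")
        if val_labels is not None and len(np.asarray(val_labels)) == 0:
            raise ValueError("empty validation set")
        val = None
        if val_inputs is not None:
            val = (_network_inputs(self.config, val_inputs),
                   np.asarray(val_labels, dtype=float))
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        opt = Adam(self.net.parameters(), lr=self.config.learning_rate)
        log = TrainingLog()
        best_loss, best_state, since_best = np.inf, self.net.get_state(), 0
        n = len(self.labels)
        for epoch in range(1, max_epochs + 1):
            epoch_loss, n_batches = 0.0, 0
            for idx in self._batches(rng, n):
                self.net.zero_grad()
                logits = _forward(self.net, self._take(self.inputs, idx))
                loss = _loss_tensor(logits, self.labels[idx], self.config,
                                    self.pos_weight)
                loss.backward()
                opt.step()
                epoch_loss += loss.item()
                n_batches += 1
            log.epochs.append(epoch)
            log.train_loss.append(epoch_loss / max(n_batches, 1))
            if val is not None:
                vloss = self._eval_loss(*val)
                log.val_loss.append(vloss)
                if vloss < best_loss - 1e-12:
                    best_loss, best_state, since_best = vloss, self.net.get_state(), 0
                    log.best_epoch = epoch
                else:
                    since_best += 1
                    if since_best >= patience:
                        log.stopped_early = True
                        break
        if val is not None:
            self.net.set_state(best_state)
        else:
            log.best_epoch = max_epochs
        return PodResults(self, log, best_loss if val is not None else None)


class PodResults:
    """Results of a :class:`PodModel` fit: the trained network, the training
    log, and prediction/diagnostic accessors."""

    def __init__(self, model: PodModel, log: TrainingLog,
                 best_val_loss: float | None):
        self.model = model
        self.config = model.config
        self.log = log
        self.best_val_loss = best_val_loss

    def predict(self, data, surgery_ids=None) -> Prediction:
        return predict(self.model.net, self.config, data, surgery_ids)

    def attention(self, data) -> AttentionMatrix:
        return extract_attention(self.model.net, self.config, data)

    def metrics(self, data, labels) -> dict:
        from .evaluate import compute_metrics

        scores = self.predict(data).scores
        return compute_metrics(scores, np.asarray(labels))

    def summary(self) -> str:
        counts = self.model.describe()
        lines = [
            "POD prediction model",
            "====================",
            f"variant:          {self.config.variant}",
            f"loss:             {self.config.loss}",
            f"learning rate:    {self.config.learning_rate:g}",
            f"batch size:       {self.config.batch_size}",
            f"epochs run:       {len(self.log.epochs)}",
            f"best epoch:       {self.log.best_epoch}",
            f"stopped early:    {self.log.stopped_early}",
        ]
        if self.best_val_loss is not None:
            lines.append(f"best val loss:    {self.best_val_loss:.6f}")
        lines.append("parameters:")
        for comp, cnt in counts.items():
            lines.append(f"  {comp:<14} {cnt}")
        return "\n".join(lines)

    # -- checkpointing -------------------------------------------------

    def save(self, path) -> None:
        """Single-file archive: config JSON + weight arrays."""
        state = self.model.net.get_state()
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps(asdict(self.config)))
            zf.writestr("shapes.json", json.dumps(self.model.input_shapes))
            buf = io.BytesIO()
            np.savez(buf, **{k.replace(".", "/"): v for k, v in state.items()})
            zf.writestr("weights.npz", buf.getvalue())

    @staticmethod
    def load_network(path):
        """Rebuild (net, config) from a checkpoint archive."""
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            shapes = json.loads(zf.read("shapes.json"))
            with zf.open("weights.npz") as f:
                npz = np.load(io.BytesIO(f.read()))
                state = {k.replace("/", "."): npz[k] for k in npz.files}
        for key in ("mlp_neurons_per_layer", "head_neurons"):
            cfg[key] = tuple(cfg[key])
        config = ModelConfig(**cfg)
        net = build_model(config, shapes)
        net.set_state(state)
        return net, config
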