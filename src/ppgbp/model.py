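"""Three-stream residual CNN extractors and the channel-attention fusion head.

One extractor per PPG channel maps the input triple (X1, X2, X3) to a
16-dimensional sigmoid latent Z; a scalar head on Z gives the single-channel
BP estimate used to train it (stage 1).  Stage 2 freezes the nine extractors,
scores each channel latent with a shared linear perceptron, softmax-normalizes
the scores into attention weights W, fuses Z' = sum_i W_i Z_i and regresses BP
from Z' through a fresh output layer.  SBP and DBP systems are trained
separately, both minimizing mean squared error with Adam.

Targets are z-scored internally during optimization (statistics from the
training labels, stored with the model); all reported estimates and losses at
the package surface are in mmHg.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .preprocess import PreparedCase

__all__ = [
    "ExtractorConfig",
    "TrainConfig",
    "BPEstimate",
    "Extractor",
    "TrainedExtractor",
    "AttentionHead",
    "BPSystem",
    "mse_loss",
    "build_extractor",
    "attention_score",
    "attention_weights",
    "fuse",
    "train_single_channel",
    "train_attention",
    "train_full_system",
    "ablate_inputs",
    "PreparedDataset",
]

PPG_LEN = 1720
FORCE_LEN = 215
LATENT_DIM = 16
CONCAT_DIM = 96
N_CHANNELS = 9


@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture constants of one per-channel feature extractor."""

    stem_kernel: int = 7
    stem_stride: int = 2
    stem_out: int = 4
    pool_kernel: int = 7
    block_widths: tuple[int, ...] = (8, 16, 32)
    block_kernel: int = 3
    dropout: float = 0.3
    l2: float = 0.005
    latent_dim: int = LATENT_DIM


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings shared by both training stages."""

    target: str = "DBP"  # "SBP" or "DBP"
    stage: str = "extractor"  # "extractor" or "attention"
    learning_rate: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in ("SBP", "DBP"):
            raise ValueError(f"target must be SBP or DBP, got {self.target!r}")
        if self.stage not in ("extractor", "attention"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")


@dataclass
class BPEstimate:
    value: float
    target: str
    weights: np.ndarray | None = None  # per-channel attention weights
    channel_index: int | None = None  # 1-based, for single-channel estimates


class TrainingError(RuntimeError):
    pass


def mse_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error (1/N) sum (y_i - yhat_i)^2."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and y_hat must be equal-length, non-empty")
    return float(np.mean((y - y_hat) ** 2))


class ResBlock(nn.Layer):
    """conv(k3,s1)+BN+ReLU+dropout -> conv(k3,s2)+BN, summed with a
    1x1-conv stride-2 projection of the input, then ReLU.

    The projection is needed because each block both widens the channel
    count and halves the length, so an identity skip cannot connect.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dropout: float,
                 rng: np.random.Generator):
        self.main = nn.Sequential(
            nn.Conv1d(c_in, c_out, kernel, 1, rng),
            nn.BatchNorm1d(c_out),
            nn.ReLU(),
            nn.Dropout(dropout, np.random.default_rng(rng.integers(2**31))),
            nn.Conv1d(c_out, c_out, kernel, 2, rng),
            nn.BatchNorm1d(c_out),
        )
        self.shortcut = nn.Sequential(
            nn.Conv1d(c_in, c_out, 1, 2, rng),
            nn.BatchNorm1d(c_out),
        )
        self.relu = nn.ReLU()

    def children(self):
        return [self.main, self.shortcut, self.relu]

    def params(self):
        return self.main.params() + self.shortcut.params()

    def forward(self, x, train):
        return self.relu.forward(self.main.forward(x, train)
                                 + self.shortcut.forward(x, train), train)

    def backward(self, dy):
        d = self.relu.backward(dy)
        return self.main.backward(d) + self.shortcut.backward(d)


def _tower(c_in: int, cfg: ExtractorConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = [
        nn.Conv1d(c_in, cfg.stem_out, cfg.stem_kernel, cfg.stem_stride, rng),
        nn.BatchNorm1d(cfg.stem_out),
        nn.ReLU(),
        nn.MaxPool1d(cfg.pool_kernel, 1),
    ]
    c = cfg.stem_out
    for width in cfg.block_widths:
        layers.append(ResBlock(c, width, cfg.block_kernel, cfg.dropout, rng))
        c = width
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


class Extractor:
    """Three-stream CNN: (X1, X2, X3) -> 16-d latent Z, plus a scalar head."""

    def __init__(self, config: ExtractorConfig, rng: np.random.Generator):
        self.config = config
        self.tower1 = _tower(3, config, rng)
        self.tower2 = _tower(3, config, rng)
        self.tower3 = _tower(1, config, rng)
        self.fc = nn.Linear(3 * config.block_widths[-1], config.latent_dim, rng)
        self.sigmoid = nn.Sigmoid()
        self.head = nn.Linear(config.latent_dim, 1, rng)
        self._pooled = 3 * config.block_widths[-1]

    # -- plumbing -----------------------------------------------------------
    def children(self):
        return [self.tower1, self.tower2, self.tower3, self.fc, self.sigmoid, self.head]

    def params(self):
        return [p for c in self.children() for p in c.params()]

    def _check_shapes(self, x1, x2, x3):
        if x1.shape[1:] != (3, PPG_LEN) or x2.shape[1:] != (3, PPG_LEN):
            raise ValueError(
                f"PPG streams must be (n, 3, {PPG_LEN}); got {x1.shape}, {x2.shape}"
            )
        if x3.shape[1:] != (1, FORCE_LEN):
            raise ValueError(f"force stream must be (n, 1, {FORCE_LEN}); got {x3.shape}")

    # -- forward / backward -------------------------------------------------
    def features(self, x1, x2, x3, train: bool = False) -> np.ndarray:
        """Latent Z, shape (n, 16), each component in (0, 1)."""
        self._check_shapes(x1, x2, x3)
        z1 = self.tower1.forward(np.asarray(x1, np.float32), train)
        z2 = self.tower2.forward(np.asarray(x2, np.float32), train)
        z3 = self.tower3.forward(np.asarray(x3, np.float32), train)
        cat = np.concatenate([z1, z2, z3], axis=1)
        self._cat_width = z1.shape[1]
        return self.sigmoid.forward(self.fc.forward(cat, train), train)

    def forward(self, x1, x2, x3, train: bool = False) -> np.ndarray:
        """Scalar (standardized-target) prediction per case, shape (n,)."""
        z = self.features(x1, x2, x3, train)
        return self.head.forward(z, train)[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        dz = self.head.backward(dy[:, None])
        dcat = self.fc.backward(self.sigmoid.backward(dz))
        w = self._cat_width
        self.tower1.backward(dcat[:, :w])
        self.tower2.backward(dcat[:, w : 2 * w])
        self.tower3.backward(dcat[:, 2 * w :])

    # -- state --------------------------------------------------------------
    def _flat_layers(self):
        out = []

        def walk(layer):
            kids = layer.children() if hasattr(layer, "children") else (
                layer.layers if isinstance(layer, nn.Sequential) else []
            )
            if isinstance(layer, nn.Sequential):
                kids = layer.layers
            if kids:
                for k in kids:
                    walk(k)
            else:
                out.append(layer)

        for c in self.children():
            walk(c)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            state[f"p{i}"] = p.value.copy()
        for i, layer in enumerate(self._flat_layers()):
            if isinstance(layer, nn.BatchNorm1d):
                state[f"bn{i}_mean"] = layer.running_mean.copy()
                state[f"bn{i}_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]
        for i, layer in enumerate(self._flat_layers()):
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = state[f"bn{i}_mean"]
                layer.running_var[...] = state[f"bn{i}_var"]

    def shape_trace(self, x1, x2, x3) -> dict[str, list[tuple[int, ...]]]:
        """Per-tower output shapes after every layer (structural check)."""
        trace: dict[str, list[tuple[int, ...]]] = {}
        for name, tower, x in (
            ("x1", self.tower1, x1),
            ("x2", self.tower2, x2),
            ("x3", self.tower3, x3),
        ):
            shapes = []
            h = np.asarray(x, np.float32)
            for layer in tower.layers:
                h = layer.forward(h, False)
                shapes.append(h.shape)
            trace[name] = shapes
        return trace


def build_extractor(config: ExtractorConfig | None = None, seed: int = 0) -> Extractor:
    """Freshly initialized extractor + output head with seeded weights."""
    return Extractor(config or ExtractorConfig(), np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Attention primitives (spec-level: Z is a 16 x 9 feature bank)
# ---------------------------------------------------------------------------

def attention_score(Z: np.ndarray, omega: np.ndarray, b: float) -> np.ndarray:
    """Channel scores S_i = omega . Z_i + b with shared weights.

    The score nonlinearity is the identity; softmax follows immediately, so a
    saturating transform would be redundant.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape != (LATENT_DIM, N_CHANNELS):
        raise ValueError(f"feature bank must be ({LATENT_DIM}, {N_CHANNELS})")
    return np.asarray(omega, dtype=float) @ Z + b


def attention_weights(S: np.ndarray) -> np.ndarray:
    """Softmax of the channel scores (max-subtracted for stability)."""
    s = np.asarray(S, dtype=float)
    e = np.exp(s - s.max())
    return e / e.sum()


def fuse(Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Attention-weighted feature Z' = sum_i W_i Z_i (16-vector)."""
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    if Z.shape != (LATENT_DIM, N_CHANNELS) or W.shape != (N_CHANNELS,):
        raise ValueError("fuse expects Z (16, 9) and W (9,)")
    return Z @ W


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

class PreparedDataset:
    """Column-stacked PreparedCases for minibatch training."""

    def __init__(self, cases: list[PreparedCase]):
        if not cases:
            raise ValueError("empty dataset")
        self.case_ids = [c.case_id for c in cases]
        self.subject_ids = np.array([c.subject_id for c in cases])
        self.x1 = np.stack([c.x1 for c in cases])  # (n, 9, 3, 1720)
        self.x2 = np.stack([c.x2 for c in cases])
        self.x3 = np.stack([c.x3 for c in cases])  # (n, 1, 215)
        self.sbp = np.array([c.ref_sbp for c in cases], dtype=float)
        self.dbp = np.array([c.ref_dbp for c in cases], dtype=float)

    def __len__(self) -> int:
        return len(self.case_ids)

    def labels(self, target: str) -> np.ndarray:
        return self.sbp if target == "SBP" else self.dbp

    def channel(self, ch: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X1, X2, X3) arrays for 0-based channel index ch."""
        return self.x1[:, ch], self.x2[:, ch], self.x3

    def subset(self, idx: np.ndarray) -> "PreparedDataset":
        out = object.__new__(PreparedDataset)
        out.case_ids = [self.case_ids[i] for i in idx]
        out.subject_ids = self.subject_ids[idx]
        out.x1, out.x2, out.x3 = self.x1[idx], self.x2[idx], self.x3[idx]
        out.sbp, out.dbp = self.sbp[idx], self.dbp[idx]
        return out


def ablate_inputs(case: PreparedCase, mode: str) -> PreparedCase:
    """Input-combination ablation by zero-masking a stream.

    "P+F" zeroes the envelope streams (X2), "E+F" zeroes the PPG streams
    (X1), "P+E+F" is the identity.  Masking keeps one extractor shape
    serving all modes.
    """
    if mode not in ("P+F", "E+F", "P+E+F"):
        raise ValueError(f"unknown ablation mode {mode!r}")
    out = copy.deepcopy(case)
    if mode == "P+F":
        out.x2[...] = 0.0
    elif mode == "E+F":
        out.x1[...] = 0.0
    return out


# ---------------------------------------------------------------------------
# Stage 1: per-channel extractor training
# ---------------------------------------------------------------------------

@dataclass
class TrainedExtractor:
    extractor: Extractor
    channel_index: int  # 1-based
    target: str
    y_mean: float
    y_std: float
    history: list[dict] = field(default_factory=list)
    val_mse: float | None = None  # mmHg^2, best epoch

    def predict(self, x1, x2, x3, batch_size: int = 64) -> np.ndarray:
        """Single-channel BP estimates in mmHg (inference mode)."""
        return self.y_mean + self.y_std * _batched_forward(
            self.extractor, x1, x2, x3, batch_size
        )

    def features(self, x1, x2, x3, batch_size: int = 64) -> np.ndarray:
        outs = []
        for sl in _batches(len(x1), batch_size):
            outs.append(self.extractor.features(x1[sl], x2[sl], x3[sl], train=False))
        return np.concatenate(outs)


def _batches(n: int, batch_size: int):
    for start in range(0, n, batch_size):
        yield slice(start, min(start + batch_size, n))


def _batched_forward(extractor, x1, x2, x3, batch_size: int) -> np.ndarray:
    outs = []
    for sl in _batches(len(x1), batch_size):
        outs.append(extractor.forward(x1[sl], x2[sl], x3[sl], train=False))
    return np.concatenate(outs)


def train_single_channel(
    dataset: PreparedDataset,
    channel: int,
    cfg: TrainConfig,
    val_dataset: PreparedDataset | None = None,
    y_stats: tuple[float, float] | None = None,
    extractor_config: ExtractorConfig | None = None,
) -> TrainedExtractor:
    """Stage-1 training of one per-channel extractor (channel is 1-based).

    Adam (beta1 0.9, beta2 0.999, lr 0.005), batch 64, dropout 0.3, L2 5e-3
    on weights.  Early stopping on validation MSE when a validation set is
    given; the best-epoch weights are restored.
    """
    if not 1 <= channel <= 9:
        raise ValueError("channel must be in 1..9")
    if cfg.stage != "extractor":
        raise ValueError("cfg.stage must be 'extractor' for stage-1 training")
    ecfg = extractor_config or ExtractorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, channel]))
    model = Extractor(ecfg, rng)

    x1, x2, x3 = dataset.channel(channel - 1)
    y = dataset.labels(cfg.target)
    y_mean, y_std = y_stats if y_stats else (float(y.mean()), float(y.std() + 1e-12))
    ys = ((y - y_mean) / y_std).astype(np.float32)

    opt = nn.Adam(model.params(), lr=cfg.learning_rate, beta1=cfg.beta1,
                  beta2=cfg.beta2, l2=ecfg.l2)
    history: list[dict] = []
    best = {"mse": np.inf, "state": None, "epoch": -1}
    n = len(ys)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for sl in _batches(n, cfg.batch_size):
            idx = order[sl.start : sl.stop]
            yb = ys[idx]
            pred = model.forward(x1[idx], x2[idx], x3[idx], train=True)
            loss = float(np.mean((pred - yb) ** 2))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"channel {channel}: non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward((2.0 / len(yb) * (pred - yb)).astype(np.float32))
            opt.step()
            epoch_loss += loss * len(yb)
        entry = {"epoch": epoch, "train_mse_std": epoch_loss / n}
        if val_dataset is not None:
            v1, v2, v3 = val_dataset.channel(channel - 1)
            vy = val_dataset.labels(cfg.target)
            vpred = y_mean + y_std * _batched_forward(model, v1, v2, v3, cfg.batch_size)
            vmse = mse_loss(vy, vpred)
            entry["val_mse"] = vmse
            if vmse < best["mse"]:
                best = {"mse": vmse, "state": model.state_dict(), "epoch": epoch}
            elif epoch - best["epoch"] >= cfg.patience:
                history.append(entry)
                break
        history.append(entry)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return TrainedExtractor(
        extractor=model,
        channel_index=channel,
        target=cfg.target,
        y_mean=y_mean,
        y_std=y_std,
        history=history,
        val_mse=None if best["epoch"] < 0 else best["mse"],
    )


# ---------------------------------------------------------------------------
# Stage 2: attention head
# ---------------------------------------------------------------------------

@dataclass
class AttentionHead:
    """Shared linear score (omega, b), softmax weights, fused output layer."""

    omega: np.ndarray  # (16,)
    b: float
    v: np.ndarray  # (16,) output layer weights
    c: float  # output layer bias

    def forward(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """features (n, 9, 16) -> (standardized predictions (n,), weights (n, 9))."""
        s = features @ self.omega + self.b  # (n, 9)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        w = e / e.sum(axis=1, keepdims=True)
        fused = np.einsum("ni,nif->nf", w, features)
        return fused @ self.v + self.c, w


def train_attention(
    features: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    y_stats: tuple[float, float],
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[AttentionHead, list[dict]]:
    """Stage-2 training on frozen latent banks.

    ``features`` is (n, 9, 16): the nine per-channel latents per case.  Only
    the score perceptron (omega, b) and the fresh output layer (v, c) are
    trained, with the same optimizer settings as stage 1.
    """
    y_mean, y_std = y_stats
    ys = ((np.asarray(y, float) - y_mean) / y_std).astype(np.float32)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    omega = nn.Param(rng.normal(0, 0.25, LATENT_DIM))
    b = nn.Param(np.zeros(1), decay=False)
    v = nn.Param(rng.normal(0, np.sqrt(2.0 / LATENT_DIM), LATENT_DIM))
    c = nn.Param(np.zeros(1), decay=False)
    opt = nn.Adam([omega, b, v, c], lr=cfg.learning_rate, beta1=cfg.beta1,
                  beta2=cfg.beta2, l2=ExtractorConfig().l2)

    def head() -> AttentionHead:
        return AttentionHead(
            omega.value.astype(float).copy(), float(b.value[0]),
            v.value.astype(float).copy(), float(c.value[0]),
        )

    n = len(ys)
    feats = np.asarray(features, np.float32)
    history: list[dict] = []
    best = {"mse": np.inf, "head": None, "epoch": -1}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for sl in _batches(n, cfg.batch_size):
            idx = order[sl.start : sl.stop]
            Z = feats[idx]  # (B, 9, 16)
            yb = ys[idx]
            s = Z @ omega.value + b.value[0]
            s = s - s.max(axis=1, keepdims=True)
            e = np.exp(s)
            w = e / e.sum(axis=1, keepdims=True)  # (B, 9)
            fused = np.einsum("bi,bif->bf", w, Z)  # (B, 16)
            pred = fused @ v.value + c.value[0]
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingError(f"attention: non-finite loss at epoch {epoch}")
            g = (2.0 / len(yb)) * err  # (B,)
            opt.zero_grad()
            v.grad += fused.T @ g
            c.grad += np.array([g.sum()], np.float32)
            dfused = g[:, None] * v.value  # (B, 16)
            dw = np.einsum("bf,bif->bi", dfused, Z)
            ds = w * (dw - (w * dw).sum(axis=1, keepdims=True))
            omega.grad += np.einsum("bi,bif->f", ds, Z)
            b.grad += np.array([ds.sum()], np.float32)
            opt.step()
            epoch_loss += loss * len(yb)
        entry = {"epoch": epoch, "train_mse_std": epoch_loss / n}
        if val is not None:
            vf, vy = val
            vpred_std, _ = head().forward(np.asarray(vf, np.float32))
            vmse = mse_loss(vy, y_mean + y_std * vpred_std)
            entry["val_mse"] = vmse
            if vmse < best["mse"]:
                best = {"mse": vmse, "head": head(), "epoch": epoch}
            elif epoch - best["epoch"] >= cfg.patience:
                history.append(entry)
                break
        history.append(entry)
    final = best["head"] if best["head"] is not None else head()
    return final, history


# ---------------------------------------------------------------------------
# Full system
# ---------------------------------------------------------------------------

@dataclass
class BPSystem:
    """The full two-stage system: nine frozen extractors + attention head."""

    target: str
    extractors: list[TrainedExtractor]
    attention: AttentionHead
    y_mean: float
    y_std: float
    channel_ranking: list[int] | None = None  # 1-based, best first

    def __post_init__(self) -> None:
        if len(self.extractors) != N_CHANNELS:
            raise ValueError("need exactly 9 trained extractors")
        targets = {e.target for e in self.extractors}
        if targets != {self.target}:
            raise ValueError(
                f"extractors trained for {targets}, system target {self.target}"
            )

    # -- features -----------------------------------------------------------
    def feature_bank(self, dataset: PreparedDataset, batch_size: int = 64) -> np.ndarray:
        """(n, 9, 16) latents from the nine frozen extractors."""
        banks = [
            ext.features(*dataset.channel(i), batch_size=batch_size)
            for i, ext in enumerate(self.extractors)
        ]
        return np.stack(banks, axis=1)

    # -- inference ----------------------------------------------------------
    def predict_batch(self, dataset: PreparedDataset) -> tuple[np.ndarray, np.ndarray]:
        """(estimates mmHg (n,), attention weights (n, 9))."""
        pred_std, w = self.attention.forward(self.feature_bank(dataset))
        return self.y_mean + self.y_std * pred_std, w

    def predict(self, case: PreparedCase) -> BPEstimate:
        yhat, w = self.predict_batch(PreparedDataset([case]))
        return BPEstimate(value=float(yhat[0]), target=self.target, weights=w[0])

    def predict_topk_batch(
        self, dataset: PreparedDataset, k: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Hard channel selection: keep the k channels ranked best on the
        validation set, renormalize their attention weights to sum to 1."""
        if k not in (2, 3):
            raise ValueError("k must be 2 or 3")
        if not self.channel_ranking:
            raise ValueError("no validation channel ranking available")
        keep = np.zeros(N_CHANNELS)
        for ch in self.channel_ranking[:k]:
            keep[ch - 1] = 1.0
        feats = self.feature_bank(dataset)
        _, w = self.attention.forward(feats)
        w = w * keep
        w = w / w.sum(axis=1, keepdims=True)
        fused = np.einsum("ni,nif->nf", w, feats)
        pred_std = fused @ self.attention.v + self.attention.c
        return self.y_mean + self.y_std * pred_std, w

    def predict_topk(self, case: PreparedCase, k: int) -> BPEstimate:
        yhat, w = self.predict_topk_batch(PreparedDataset([case]), k)
        return BPEstimate(value=float(yhat[0]), target=self.target, weights=w[0])


def train_full_system(
    train_set: PreparedDataset,
    cfg: TrainConfig,
    val_set: PreparedDataset | None = None,
    extractor_config: ExtractorConfig | None = None,
    attention_cfg: TrainConfig | None = None,
) -> BPSystem:
    """Both stages end-to-end for one target: nine per-channel extractors,
    then the attention head on their frozen latents.

    The attention stage is cheap (latents are cached), so it may run a
    longer schedule than stage 1 via ``attention_cfg``.
    """
    y = train_set.labels(cfg.target)
    y_stats = (float(y.mean()), float(y.std() + 1e-12))
    stage1 = replace(cfg, stage="extractor")
    extractors = [
        train_single_channel(train_set, ch, stage1, val_set, y_stats, extractor_config)
        for ch in range(1, N_CHANNELS + 1)
    ]
    ranking = None
    if val_set is not None:
        order = np.argsort([e.val_mse for e in extractors])
        ranking = [int(i) + 1 for i in order]

    feats = np.stack(
        [ext.features(*train_set.channel(i)) for i, ext in enumerate(extractors)],
        axis=1,
    )
    val = None
    if val_set is not None:
        vfeats = np.stack(
            [ext.features(*val_set.channel(i)) for i, ext in enumerate(extractors)],
            axis=1,
        )
        val = (vfeats, val_set.labels(cfg.target))
    stage2 = attention_cfg or replace(cfg, stage="attention")
    head, _ = train_attention(feats, y, stage2, y_stats, val)
    return BPSystem(
        target=cfg.target,
        extractors=extractors,
        attention=head,
        y_mean=y_stats[0],
        y_std=y_stats[1],
        channel_ranking=ranking,
    )
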