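"""Supervised stage: shallow CNNs over the low-level feature matrices, a
fully connected predictor, and MSE training.

The drug CNN reads the 64 x d atom-embedding matrix and the target CNN the
K x d fragment-embedding matrix, each as a single-channel 2D image.  Each CNN
is three stride-1 same-padded convolutions (32/64/128 filters, kernels
5/5/3, ReLU), with 2x2 max pooling after the first two layers and a global
max pool per channel after the last, yielding a length-128 vector.  The two
vectors are concatenated (drug first) and a 512-128-1 MLP regresses the
affinity.  Only the CNNs and predictor are trained; the pretrained encoders
stay frozen, so low-level features are computed once up front.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autograd import Tensor, concat, conv2d, global_max_pool, maxpool2d, relu
from .features import LowLevelDrugFeatures, LowLevelTargetFeatures
from .infograph import GINEncoder
from .layers import MLP, Adam, Module
from .metrics import concordance_index, mean_squared_error


@dataclass(frozen=True)
class CNNConfig:
    """Shallow CNN architecture: filters/kernels per layer and the pooling
    applied after each layer ("none", "max2", or "global" for the final
    per-channel spatial max).  ``use_1d`` switches to convolving along the
    fragment/atom axis only (the feature dimension becomes input channels)."""

    n_layers: int = 3
    filters: tuple[int, ...] = (32, 64, 128)
    kernels: tuple[int, ...] = (5, 5, 3)
    pooling: tuple[str, ...] = ("max4", "max2", "global")
    use_1d: bool = False

    def __post_init__(self):
        if not (len(self.filters) == len(self.kernels) == len(self.pooling) == self.n_layers):
            raise ValueError("filters, kernels and pooling must have n_layers entries")
        if self.pooling[-1] != "global":
            raise ValueError("last pooling step must be 'global'")
        for p in self.pooling:
            if p not in ("none", "max2", "max4", "global"):
                raise ValueError(f"unknown pooling {p!r}")


@dataclass(frozen=True)
class PredictorConfig:
    hidden_sizes: tuple[int, ...] = (512, 128, 1)
    activation: str = "relu"

    def __post_init__(self):
        if self.hidden_sizes[-1] != 1:
            raise ValueError("final predictor layer size must be 1")


@dataclass(frozen=True)
class AffinityRecord:
    drug_id: str
    target_id: str
    affinity: float

    def __post_init__(self):
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")


class CNN2D(Module):
    """Single-channel 2D CNN tower producing one vector per input matrix."""

    def __init__(self, cfg: CNNConfig, in_height: int, in_width: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.in_height = int(in_height)
        self.in_width = int(in_width)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        in_ch = self.in_width if cfg.use_1d else 1
        for f, k in zip(cfg.filters, cfg.kernels):
            kh, kw = (k, 1) if cfg.use_1d else (k, k)
            fan_in, fan_out = in_ch * kh * kw, f
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, size=(f, in_ch, kh, kw)).astype(np.float32)
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(f, dtype=np.float32), requires_grad=True))
            in_ch = f

    @property
    def out_dim(self) -> int:
        return self.cfg.filters[-1]

    def params(self):
        out = []
        for w, b in zip(self.weights, self.biases):
            out += [w, b]
        return out

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, 1, H, W) feature matrices -> (B, filters[-1]) vectors."""
        B, C, H, W = x.shape
        if (H, W) != (self.in_height, self.in_width) or C != 1:
            raise ValueError(
                f"CNN input shape mismatch: expected (B, 1, {self.in_height}, "
                f"{self.in_width}), got {tuple(x.shape)}"
            )
        if self.cfg.use_1d:
            # feature dim -> channels; convolve along the row axis only
            x = x.reshape(B, H, W).transpose(0, 2, 1).reshape(B, W, H, 1)
        for w, b, pool in zip(self.weights, self.biases, self.cfg.pooling):
            x = relu(conv2d(x, w, b))
            if pool in ("max2", "max4"):
                k = 2 if pool == "max2" else 4
                x = maxpool2d(x, (k, 1) if self.cfg.use_1d else (k, k))
            elif pool == "global":
                x = global_max_pool(x)
        return x


class Predictor(Module):
    """Fully connected regressor ending in a single linear output."""

    def __init__(self, in_dim: int, cfg: PredictorConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_dim = int(in_dim)
        self.mlp = MLP([in_dim, *cfg.hidden_sizes], rng, activation=cfg.activation)

    def params(self):
        return self.mlp.params()

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_dim:
            raise ValueError(
                f"predictor input length mismatch: expected {self.in_dim}, "
                f"got {x.shape[-1]}"
            )
        return self.mlp(x)


# -- spec-level convenience ops ----------------------------------------------

def cnn_high_level(features, cnn: CNN2D) -> np.ndarray:
    """High-level feature vector of one low-level feature matrix."""
    mat = features.matrix if hasattr(features, "matrix") else np.asarray(features)
    x = Tensor(mat[None, None, :, :])
    return cnn(x).data[0]


def concat_pair(drug_vec: np.ndarray, target_vec: np.ndarray) -> np.ndarray:
    """Drug-target pair features: drug vector first, then target vector."""
    if drug_vec is None or target_vec is None:
        raise ValueError("both drug and target vectors are required")
    return np.concatenate([np.asarray(drug_vec).ravel(), np.asarray(target_vec).ravel()])


def predict_affinity(pair_vec: np.ndarray, predictor: Predictor) -> float:
    x = Tensor(np.asarray(pair_vec, dtype=np.float32)[None, :])
    return float(predictor(x).data[0, 0])


# -- bundle -------------------------------------------------------------------

@dataclass
class ModelBundle:
    """Everything needed to predict: frozen encoders, two CNN towers, the
    predictor, and the configs that reproduce their shapes."""

    drug_encoder: GINEncoder
    target_encoder: GINEncoder
    drug_cnn: CNN2D
    target_cnn: CNN2D
    predictor: Predictor
    drug_cnn_config: CNNConfig
    target_cnn_config: CNNConfig
    predictor_config: PredictorConfig
    metadata: dict = field(default_factory=dict)

    def trainable_params(self):
        return (
            self.drug_cnn.params() + self.target_cnn.params() + self.predictor.params()
        )


def build_bundle(
    drug_encoder: GINEncoder,
    target_encoder: GINEncoder,
    drug_rows: int = 64,
    k: int = 64,
    drug_cnn_config: CNNConfig | None = None,
    target_cnn_config: CNNConfig | None = None,
    predictor_config: PredictorConfig | None = None,
    seed: int = 0,
) -> ModelBundle:
    """Construct the stage-2 networks around two (pre)trained encoders."""
    dcfg = drug_cnn_config or CNNConfig()
    tcfg = target_cnn_config or CNNConfig()
    pcfg = predictor_config or PredictorConfig()
    rng = np.random.default_rng(seed)
    drug_cnn = CNN2D(dcfg, drug_rows, drug_encoder.cfg.hidden_size, rng)
    target_cnn = CNN2D(tcfg, k, target_encoder.out_dim, rng)
    predictor = Predictor(drug_cnn.out_dim + target_cnn.out_dim, pcfg, rng)
    return ModelBundle(
        drug_encoder, target_encoder, drug_cnn, target_cnn, predictor,
        dcfg, tcfg, pcfg, metadata={"seed": seed},
    )


# -- training -----------------------------------------------------------------

@dataclass(frozen=True)
class TrainOptions:
    epochs: int = 80
    batch_size: int = 32
    lr: float = 1e-3
    test_fraction: float = 0.2
    val_fraction: float = 0.1   # carved from the training split
    seed: int = 0


@dataclass
class TrainResult:
    bundle: ModelBundle
    history: pd.DataFrame        # epoch, train_mse, val_mse, val_ci
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    best_epoch: int


def _forward(bundle: ModelBundle, xd: Tensor, xt: Tensor) -> Tensor:
    vd = bundle.drug_cnn(xd)
    vt = bundle.target_cnn(xt)
    return bundle.predictor(concat([vd, vt], axis=1))


def predict_pairs(
    bundle: ModelBundle,
    records: list[AffinityRecord],
    drug_features: dict[str, LowLevelDrugFeatures],
    target_features: dict[str, LowLevelTargetFeatures],
    batch_size: int = 64,
) -> np.ndarray:
    """Predicted affinity per record, in input order."""
    y_mean = float(bundle.metadata.get("y_mean", 0.0))
    y_std = float(bundle.metadata.get("y_std", 1.0))
    preds = np.empty(len(records), dtype=np.float64)
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        xd = Tensor(np.stack(
            [drug_features[r.drug_id].matrix for r in chunk])[:, None, :, :])
        xt = Tensor(np.stack(
            [target_features[r.target_id].matrix for r in chunk])[:, None, :, :])
        preds[i:i + len(chunk)] = _forward(bundle, xd, xt).data[:, 0]
    return preds * y_std + y_mean


def split_records(
    n: int, test_fraction: float, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded random (train, val, test) index split."""
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test = order[:n_test]
    rest = order[n_test:]
    n_val = int(round(len(rest) * val_fraction))
    val = rest[:n_val]
    train = rest[n_val:]
    if not len(train):
        raise ValueError("empty training split")
    return train, val, test


def train_supervised(
    records: list[AffinityRecord],
    bundle: ModelBundle,
    drug_features: dict[str, LowLevelDrugFeatures],
    target_features: dict[str, LowLevelTargetFeatures],
    opts: TrainOptions = TrainOptions(),
) -> TrainResult:
    """Train CNNs + predictor with MSE on a seeded 80/10/10-style split.

    Targets are standardized to zero mean / unit variance on the training
    split (the affine transform is stored in the bundle metadata and undone
    at prediction time), so the optimizer does not spend epochs learning the
    affinity baseline.  Per-epoch train MSE and validation MSE/CI are
    recorded in original affinity units; the returned bundle carries the
    parameters of the epoch with the lowest validation MSE (final epoch if
    there is no validation split).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 labeled records")
    missing = [r.drug_id for r in records if r.drug_id not in drug_features]
    missing += [r.target_id for r in records if r.target_id not in target_features]
    if missing:
        raise KeyError(f"records reference entities without features: {sorted(set(missing))[:5]}")
    rng = np.random.default_rng(opts.seed)
    train_idx, val_idx, test_idx = split_records(
        len(records), opts.test_fraction, opts.val_fraction, rng
    )

    def tensors_for(idx: np.ndarray):
        recs = [records[i] for i in idx]
        xd = np.stack([drug_features[r.drug_id].matrix for r in recs])[:, None, :, :]
        xt = np.stack([target_features[r.target_id].matrix for r in recs])[:, None, :, :]
        y = np.array([r.affinity for r in recs], dtype=np.float32)
        return xd, xt, y

    xd_tr, xt_tr, y_tr = tensors_for(train_idx)
    if len(val_idx):
        xd_va, xt_va, y_va = tensors_for(val_idx)

    y_mean = float(y_tr.mean())
    y_std = float(y_tr.std())
    if y_std < 1e-8:
        y_std = 1.0
    bundle.metadata["y_mean"] = y_mean
    bundle.metadata["y_std"] = y_std
    y_tr_n = (y_tr - y_mean) / y_std

    opt = Adam(bundle.trainable_params(), lr=opts.lr)
    rows = []
    best = (np.inf, None, -1)
    for epoch in range(opts.epochs):
        order = rng.permutation(len(train_idx))
        losses = []
        for i in range(0, len(order), opts.batch_size):
            sel = order[i:i + opts.batch_size]
            pred = _forward(bundle, Tensor(xd_tr[sel]), Tensor(xt_tr[sel]))
            resid = pred.reshape(len(sel)) - Tensor(y_tr_n[sel])
            loss = resid.square().mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item() * len(sel))
        train_mse = float(np.sum(losses) / len(train_idx)) * y_std ** 2
        val_mse = np.nan
        val_ci = np.nan
        if len(val_idx):
            pv = _forward(bundle, Tensor(xd_va), Tensor(xt_va)).data[:, 0] * y_std + y_mean
            val_mse = mean_squared_error(y_va, pv)
            try:
                val_ci = concordance_index(y_va, pv)
            except ValueError:
                val_ci = np.nan
        rows.append({"epoch": epoch, "train_mse": train_mse,
                     "val_mse": val_mse, "val_ci": val_ci})
        score = val_mse if len(val_idx) else train_mse
        if score < best[0]:
            best = (score, [p.data.copy() for p in bundle.trainable_params()], epoch)
    if best[1] is not None:
        for p, a in zip(bundle.trainable_params(), best[1]):
            p.data = a
    history = pd.DataFrame(rows)
    return TrainResult(bundle, history, train_idx, val_idx, test_idx, best[2])


# -- checkpointing ------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path) -> None:
    meta = {
        "format": "fragdta-bundle-v1",
        "drug_encoder": {"config": asdict(bundle.drug_encoder.cfg),
                         "vocab_size": bundle.drug_encoder.vocab_size},
        "target_encoder": {"config": asdict(bundle.target_encoder.cfg),
                           "vocab_size": bundle.target_encoder.vocab_size},
        "drug_cnn": asdict(bundle.drug_cnn_config),
        "target_cnn": asdict(bundle.target_cnn_config),
        "predictor": asdict(bundle.predictor_config),
        "drug_rows": bundle.drug_cnn.in_height,
        "k": bundle.target_cnn.in_height,
        "metadata": bundle.metadata,
    }
    arrays = {}
    for name, mod in [("denc", bundle.drug_encoder), ("tenc", bundle.target_encoder),
                      ("dcnn", bundle.drug_cnn), ("tcnn", bundle.target_cnn),
                      ("pred", bundle.predictor)]:
        for i, a in enumerate(mod.state_arrays()):
            arrays[f"{name}_{i}"] = a
    with open(Path(path), "wb") as fh:
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_bundle(path) -> ModelBundle:
    from .infograph import EncoderConfig

    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format") != "fragdta-bundle-v1":
            raise ValueError(f"{path}: not a fragdta model bundle")
        rng = np.random.default_rng(0)
        denc = GINEncoder(EncoderConfig(**meta["drug_encoder"]["config"]),
                          meta["drug_encoder"]["vocab_size"], rng)
        tenc = GINEncoder(EncoderConfig(**meta["target_encoder"]["config"]),
                          meta["target_encoder"]["vocab_size"], rng)
        dcfg = CNNConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in meta["drug_cnn"].items()})
        tcfg = CNNConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in meta["target_cnn"].items()})
        pcfg = PredictorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in meta["predictor"].items()})
        dcnn = CNN2D(dcfg, meta["drug_rows"], denc.cfg.hidden_size, rng)
        tcnn = CNN2D(tcfg, meta["k"], tenc.out_dim, rng)
        pred = Predictor(dcnn.out_dim + tcnn.out_dim, pcfg, rng)
        for name, mod in [("denc", denc), ("tenc", tenc), ("dcnn", dcnn),
                          ("tcnn", tcnn), ("pred", pred)]:
            mod.load_arrays([data[f"{name}_{i}"] for i in range(len(mod.params()))])
    return ModelBundle(denc, tenc, dcnn, tcnn, pred, dcfg, tcfg, pcfg,
                       metadata=meta.get("metadata", {}))
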