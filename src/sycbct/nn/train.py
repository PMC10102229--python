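"""Training: smooth-L1 loss, Adam with exponential LR decay, early stopping.

The default schedule: Adam at an initial learning
rate of 2.5e-4, decayed by a factor 0.8 every 200 iterations, weight
decay 1e-5, smooth-L1 loss, and early stopping with a patience of 5
validation evaluations without improvement.  Validation is evaluated on
the same 200-iteration cadence as the decay.  Mini-batch sizes are 32
for small (64x64x16) patches and 8 for large (128x128x16) ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .network import NetworkSpec, ResUNet3D, build_network

__all__ = [
    "TrainConfig",
    "smooth_l1",
    "smooth_l1_grad",
    "lr_at_iteration",
    "Adam",
    "train",
    "TrainHistory",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 2.5e-4
    decay_gamma: float = 0.8
    decay_every: int = 200  # iterations
    weight_decay: float = 1e-5
    beta: float = 1.0  # smooth-L1 transition point, normalised units
    patience: int = 5  # validation evaluations without improvement
    batch_size: int = 32
    max_iterations: int = 2000
    eval_every: int = 200  # validation cadence (aligned with decay)
    val_fraction: float = 1 / 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.decay_gamma < 1:
            raise ValueError("decay_gamma must lie in (0, 1)")
        if self.patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch_size must be >= 1")


def smooth_l1(pred: np.ndarray, target: np.ndarray, beta: float = 1.0) -> float:
    """Mean smooth-L1: ``0.5 d^2 / beta`` for ``|d| < beta`` else
    ``|d| - 0.5 beta``, averaged over all elements."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    d = pred - target
    ad = np.abs(d)
    loss = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    return float(loss.mean())


def smooth_l1_grad(pred: np.ndarray, target: np.ndarray, beta: float = 1.0) -> np.ndarray:
    """Gradient of :func:`smooth_l1` with respect to ``pred``."""
    d = np.asarray(pred, dtype=float) - np.asarray(target, dtype=float)
    g = np.where(np.abs(d) < beta, d / beta, np.sign(d))
    return g / d.size


def lr_at_iteration(cfg: TrainConfig, it: int) -> float:
    """Stepwise-exponential schedule ``lr0 * gamma^floor(it / every)``."""
    if it < 0:
        raise ValueError("iteration index must be >= 0")
    return cfg.lr0 * cfg.decay_gamma ** (it // cfg.decay_every)


class Adam:
    """Adam with decoupled-style L2 weight decay on kernels only."""

    def __init__(self, params, weight_decay: float = 0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainHistory:
    """Per-evaluation record of the run."""

    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_iteration: int = 0
    best_val_loss: float = float("inf")
    stopped_early: bool = False


def _eval_loss(model: ResUNet3D, batches: Sequence[tuple[np.ndarray, np.ndarray]], beta: float) -> float:
    losses = []
    for x, y in batches:
        pred = model.forward(x, train=False)
        losses.append(smooth_l1(pred, y[:, None] if y.ndim == 4 else y, beta))
    return float(np.mean(losses))


def train(
    model: ResUNet3D,
    patches: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    val_patches: Sequence[tuple[np.ndarray, np.ndarray]] | None = None,
    verbose: bool = False,
) -> tuple[ResUNet3D, TrainHistory]:
    """Train on (input, target) patch pairs with early stopping.

    ``patches`` is a sequence of normalised ``[-1, 1]`` (mri, cbct) patch
    pairs.  If ``val_patches`` is not given, the last ``val_fraction`` of
    ``patches`` is held out.  Training stops when the validation loss
    fails to improve for ``cfg.patience`` consecutive evaluations, and
    the best-validation weights are restored before returning.
    Deterministic for fixed seeds.
    """
    if len(patches) == 0:
        raise ValueError("empty patch stream")
    if val_patches is None:
        n_val = max(1, int(round(len(patches) * cfg.val_fraction)))
        if n_val >= len(patches):
            raise ValueError("val_fraction leaves no training patches")
        val_patches = patches[-n_val:]
        patches = patches[:-n_val]

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_state = model.state_dict()
    bad_evals = 0

    def make_batch(idx):
        xs = np.stack([np.asarray(patches[i][0], dtype=np.float64) for i in idx])
        ys = np.stack([np.asarray(patches[i][1], dtype=np.float64) for i in idx])
        return xs[:, None], ys[:, None]

    val_batches = []
    for i in range(0, len(val_patches), cfg.batch_size):
        chunk = val_patches[i : i + cfg.batch_size]
        vx = np.stack([np.asarray(c[0], dtype=np.float64) for c in chunk])[:, None]
        vy = np.stack([np.asarray(c[1], dtype=np.float64) for c in chunk])[:, None]
        val_batches.append((vx, vy))

    recent_train: list[float] = []
    for it in range(cfg.max_iterations):
        idx = rng.integers(0, len(patches), size=min(cfg.batch_size, len(patches)))
        x, y = make_batch(idx)
        model.zero_grad()
        pred = model.forward(x, train=True)
        loss = smooth_l1(pred, y, cfg.beta)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        model.backward(smooth_l1_grad(pred, y, cfg.beta))
        lr = lr_at_iteration(cfg, it)
        opt.step(lr)
        recent_train.append(loss)

        if (it + 1) % cfg.eval_every == 0 or it + 1 == cfg.max_iterations:
            val = _eval_loss(model, val_batches, cfg.beta)
            history.iterations.append(it + 1)
            history.train_loss.append(float(np.mean(recent_train)))
            history.val_loss.append(val)
            history.lr.append(lr)
            recent_train = []
            if verbose:
                print(f"iter {it + 1:6d}  lr {lr:.3e}  train {history.train_loss[-1]:.5f}  val {val:.5f}")
            if val < history.best_val_loss:
                history.best_val_loss = val
                history.best_iteration = it + 1
                best_state = model.state_dict()
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= cfg.patience:
                    history.stopped_early = True
                    break

    model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(path: str | Path, model: ResUNet3D, history: TrainHistory | None = None) -> None:
    """NPZ checkpoint: spec, weights, BN running stats, history."""
    path = Path(path)
    arrays = model.state_dict()
    bn_stats = {}
    i = 0
    for layer in _iter_bn(model):
        bn_stats[f"bn{i}_mean"] = layer.running_mean
        bn_stats[f"bn{i}_var"] = layer.running_var
        i += 1
    spec_json = json.dumps(_spec_to_dict(model.spec))
    hist_json = json.dumps(asdict(history)) if history is not None else "{}"
    np.savez(
        path,
        __spec__=np.array(spec_json),
        __history__=np.array(hist_json),
        **arrays,
        **bn_stats,
    )


def load_checkpoint(path: str | Path) -> tuple[ResUNet3D, dict]:
    data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path)
    spec_d = json.loads(str(data["__spec__"]))
    spec = NetworkSpec(
        stem_channels=spec_d["stem_channels"],
        stem_kernel=spec_d["stem_kernel"],
        stem_stride=tuple(spec_d["stem_stride"]),
        stage_repeats=tuple(spec_d["stage_repeats"]),
        stage_mid_channels=tuple(spec_d["stage_mid_channels"]),
        stage_strides=tuple(tuple(s) for s in spec_d["stage_strides"]),
        expansion=spec_d["expansion"],
        decoder_channels=tuple(spec_d["decoder_channels"]),
        kernel_size=spec_d["kernel_size"],
        skip_connections=frozenset(spec_d["skip_connections"]),
    )
    model = build_network(spec)
    model.load_state_dict({k: data[k] for k in data.files if k.startswith("p")})
    for i, layer in enumerate(_iter_bn(model)):
        layer.running_mean = data[f"bn{i}_mean"]
        layer.running_var = data[f"bn{i}_var"]
    history = json.loads(str(data["__history__"]))
    return model, history


def _spec_to_dict(spec: NetworkSpec) -> dict:
    d = asdict(spec)
    d["skip_connections"] = sorted(spec.skip_connections)
    return d


def _iter_bn(model: ResUNet3D):
    from .layers import BatchNorm3d

    seen = []

    def walk(obj):
        if isinstance(obj, BatchNorm3d):
            seen.append(obj)
            return
        if isinstance(obj, (list, tuple)):
            for o in obj:
                walk(o)
            return
        for attr in vars(obj).values() if hasattr(obj, "__dict__") else []:
            if hasattr(attr, "params") or isinstance(attr, (list, BatchNorm3d)):
                walk(attr)

    walk(model.stem)
    for blocks in model.stages:
        walk(blocks)
    walk(model.decoder)
    walk(model.final_conv)
    return seen
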