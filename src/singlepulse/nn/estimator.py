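"""Scikit-learn style estimator wrapping the map-to-map CNN.

``CorrelationMapper`` is a regressor from two-channel difference
off-resonance stacks, shaped (n_samples, n_H, n_offsets, 2), to correlation
maps shaped (n_samples, n_H, n_offsets).  Training minimizes the mean
squared error against noise-free target maps with the ADAM optimizer, L2
weight decay and 30% dropout; ``partial_fit`` supports curriculum rounds in
which the peak-count cap of the generated corpus grows between rounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .model import ArchConfig, UNet

__all__ = ["CorrelationMapper", "TrainConfig", "train_curriculum",
           "evaluate_mse", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Curriculum and optimizer settings.

    ``curriculum`` is an ordered list of ``(n_peaks_max, n_examples)``
    rounds with non-decreasing peak caps; the reduced preset uses
    5 -> 60 over 3,000 examples, the full-scale schedule grows 10 -> 1,500
    over 475,000 examples.
    """

    curriculum: tuple = ((5, 750), (15, 750), (30, 750), (60, 750))
    lr: float = 1e-3
    lr_decay_per_round: float = 0.3
    l2: float = 1e-6
    batch_size: int = 4
    seed: int = 0
    reduced_scale: bool = True

    def __post_init__(self) -> None:
        caps = [c for c, _ in self.curriculum]
        if any(b < a for a, b in zip(caps, caps[1:])):
            raise ValueError("curriculum n_peaks_max must be non-decreasing")
        if caps and caps[-1] > 1500:
            raise ValueError("curriculum n_peaks_max must not exceed 1500")

    @classmethod
    def full_scale(cls) -> "TrainConfig":
        return cls(
            curriculum=(
                (10, 95_000), (50, 95_000), (150, 95_000),
                (500, 95_000), (1500, 95_000),
            ),
            reduced_scale=False,
        )


class _Adam:
    def __init__(self, params: dict, lr: float, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = grads[k]
            if self.l2 and k.endswith(".w"):
                g = g + 2.0 * self.l2 * p
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class CorrelationMapper(BaseEstimator, RegressorMixin):
    """CNN regressor from off-resonance stacks to 1H-13C correlation maps.

    Parameters
    ----------
    arch:
        ``"reduced"``, ``"full"``, or an :class:`ArchConfig`.
    lr, l2, batch_size:
        ADAM learning rate, L2 coefficient and minibatch size.
    n_epochs:
        Passes over the data in a single :meth:`fit`/:meth:`partial_fit`.
    random_state:
        Seeds weight initialization, batch shuffling and dropout masks.

    Attributes
    ----------
    model_ : UNet
        The fitted network.
    n_weights_ : int
        Total trainable parameter count (reported at build time).
    loss_history_ : list of float
        Minibatch MSE in training order.
    """

    def __init__(self, arch="reduced", lr=1e-3, l2=1e-6, batch_size=4,
                 n_epochs=1, shuffle=True, random_state=0):
        self.arch = arch
        self.lr = lr
        self.l2 = l2
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.shuffle = shuffle
        self.random_state = random_state

    # -- internals ------------------------------------------------------------

    def _arch_config(self) -> ArchConfig:
        if isinstance(self.arch, ArchConfig):
            return self.arch
        return ArchConfig.preset(self.arch)

    def _ensure_model(self) -> None:
        if not hasattr(self, "model_"):
            rng = np.random.default_rng(self.random_state)
            self.model_ = UNet(self._arch_config(), rng=rng)
            self.n_weights_ = self.model_.n_weights
            self.loss_history_ = []
            self._opt = _Adam(self.model_.params, lr=self.lr, l2=self.l2)
            self._fit_rng = np.random.default_rng(
                np.random.SeedSequence([self.random_state, 0xF17])
            )

    @staticmethod
    def _to_cbhw(X: np.ndarray) -> np.ndarray:
        """(n, H, W, C) -> channel-major (C, n, H, W) used by the network."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] < 1:
            raise ValueError("X must be (n_samples, n_H, n_offsets, n_channels)")
        if X.shape[1] % 4 or X.shape[2] % 4:
            raise ValueError("spatial dimensions must be divisible by 4")
        return np.ascontiguousarray(X.transpose(3, 0, 1, 2))

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y):
        """Train from scratch on (X, y); use partial_fit for curricula."""
        for attr in ("model_", "n_weights_", "loss_history_", "_opt"):
            if hasattr(self, attr):
                delattr(self, attr)
        for _ in range(self.n_epochs):
            self.partial_fit(X, y)
        return self

    def partial_fit(self, X, y, lr: float | None = None):
        """One pass over (X, y), keeping optimizer state across calls."""
        self._ensure_model()
        if lr is not None:
            self._opt.lr = lr
        Xn = self._to_cbhw(X)
        yn = np.asarray(y, dtype=np.float32)
        if yn.shape != (Xn.shape[1], Xn.shape[2], Xn.shape[3]):
            raise ValueError("y must be (n_samples, n_H, n_offsets)")
        self.model_.check_receptive_field(Xn.shape[3])
        n = Xn.shape[1]
        order = np.arange(n)
        if self.shuffle:
            self._fit_rng.shuffle(order)
        bs = self.batch_size
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            xb, yb = np.ascontiguousarray(Xn[:, idx]), yn[idx]
            pred, cache = self.model_.forward(
                xb, train=True, dropout_rng=self._fit_rng
            )
            err = pred - yb
            loss = float(np.mean(err.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at step {len(self.loss_history_)}; "
                    f"batch indices {idx.tolist()}"
                )
            dy = (2.0 / err.size) * err
            grads = self.model_.backward(dy, cache)
            self._opt.step(self.model_.params, grads)
            self.loss_history_.append(loss)
        return self

    def predict(self, X) -> np.ndarray:
        """Deterministic forward pass (dropout disabled)."""
        check_is_fitted(self, "model_")
        Xn = self._to_cbhw(X)
        n = Xn.shape[1]
        out = np.empty((n, Xn.shape[2], Xn.shape[3]), dtype=np.float32)
        for i in range(0, n, 8):
            out[i:i + 8] = self.model_.forward(
                np.ascontiguousarray(Xn[:, i:i + 8]), train=False
            )
        return out

    def sample_predict(
        self, X, n_passes: int = 20, random_state: int | None = None
    ) -> np.ndarray:
        """Monte-Carlo dropout: (n_passes, n_samples, n_H, n_offsets)."""
        check_is_fitted(self, "model_")
        Xn = self._to_cbhw(X)
        n = Xn.shape[1]
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        out = np.empty((n_passes, n, Xn.shape[2], Xn.shape[3]), dtype=np.float32)
        for p in range(n_passes):
            for i in range(0, n, 8):
                out[p, i:i + 8] = self.model_.forward(
                    np.ascontiguousarray(Xn[:, i:i + 8]),
                    train=False,
                    dropout_rng=rng,
                )
        return out


def evaluate_mse(est: CorrelationMapper, X, y) -> dict:
    """Mean and per-example MSE of deterministic predictions on (X, y)."""
    pred = est.predict(X)
    y = np.asarray(y, dtype=np.float32)
    per_example = np.mean(
        (pred.astype(np.float64) - y.astype(np.float64)) ** 2, axis=(1, 2)
    )
    return {"mse": float(per_example.mean()), "per_example": per_example}


def train_curriculum(
    est: CorrelationMapper,
    cfg: TrainConfig,
    generator_config,
    progress: bool = False,
    checkpoint_dir=None,
) -> CorrelationMapper:
    """Run curriculum rounds, generating examples on the fly.

    Each round draws ``n_examples`` fresh synthetic examples with the
    round's peak cap and makes one pass over them; the learning rate decays
    by ``lr_decay_per_round`` between rounds.  With ``checkpoint_dir`` set,
    a checkpoint is written after every round.
    """
    from ..synth import GeneratorConfig, examples_to_arrays, sample_example

    ss = np.random.SeedSequence([cfg.seed, 0x5EED])
    lr = cfg.lr
    chunk = 50
    for rnd, (cap, n_examples) in enumerate(cfg.curriculum):
        gen_cfg = GeneratorConfig(**{**generator_config.to_dict(),
                                     "n_peaks_max": int(cap)})
        child = np.random.SeedSequence([cfg.seed, 0x5EED, rnd])
        rng = np.random.default_rng(child)
        done = 0
        while done < n_examples:
            k = min(chunk, n_examples - done)
            examples = [sample_example(gen_cfg, rng) for _ in range(k)]
            X, y = examples_to_arrays(examples)
            est.partial_fit(X, y, lr=lr)
            done += k
            if progress:
                print(f"round {rnd} (cap {cap}): {done}/{n_examples} "
                      f"loss {est.loss_history_[-1]:.3e}", flush=True)
        lr *= cfg.lr_decay_per_round
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir)
            path.mkdir(parents=True, exist_ok=True)
            save_checkpoint(
                est, path / f"round_{rnd:02d}.npz",
                extra={"round": rnd, "n_peaks_max": int(cap),
                       "data_config_hash": gen_cfg.content_hash()},
            )
    return est


# -- checkpoints --------------------------------------------------------------


def save_checkpoint(est: CorrelationMapper, path, extra: dict | None = None):
    """Self-describing checkpoint: weights + architecture + training meta."""
    check_is_fitted(est, "model_")
    path = Path(path)
    params = est.get_params()
    params["arch"] = None  # reconstructed from the arch dict on load
    meta = {
        "arch": est.model_.arch.to_dict(),
        "params": params,
        "n_weights": est.n_weights_,
        "loss_history": [float(v) for v in est.loss_history_],
    }
    if extra:
        meta["extra"] = extra
    arrays = {f"param::{k}": v for k, v in est.model_.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> CorrelationMapper:
    path = Path(path)
    with np.load(path) as z:
        meta = json.loads(z["__meta__"].tobytes().decode())
        state = {
            k.removeprefix("param::"): z[k]
            for k in z.files if k.startswith("param::")
        }
    params = meta["params"]
    params["arch"] = ArchConfig.from_dict(meta["arch"])
    est = CorrelationMapper(**params)
    est._ensure_model()
    est.model_.load_state_dict(state)
    est.n_weights_ = meta["n_weights"]
    est.loss_history_ = list(meta["loss_history"])
    return est
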