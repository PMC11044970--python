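"""Targeted discriminant analysis neural collective variables.

A small feed-forward network maps a configuration (or descriptor vector) to a
scalar latent value. Training does not classify: it shapes the latent
distribution so that, for each labelled metastable state k, the batch mean
and standard deviation of the latent values match user-chosen targets,

    L = Σ_k  α (μ_k - μ_k^tg)²  +  β (σ_k - σ_k^tg)² ,

with narrow, well-separated targets for metastable states and broad ones for
transition-state data. After training, the latent output is affinely rescaled
so the training set spans exactly [-1, 1]; that normalized value is the CV
``s(R)`` used for biasing, and its input gradient (needed for bias forces) is
computed by exact backpropagation.

The network, Adam optimizer and backpropagation are implemented here directly
on numpy arrays: the architecture is tiny (default {24, 12, 1} with ReLU) and
the loss couples all samples of a state through batch moments, which rules
out off-the-shelf per-sample regression trainers.

σ_k uses the population convention (divide by n), so a state whose latents
are all equal has σ_k = 0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class StateCountError(ValueError):
    """A labelled state has too few samples for its moments to be defined."""


@dataclass(frozen=True)
class TDATargets:
    """Per-state latent target centers and widths (latent units)."""

    centers: tuple[float, ...]
    widths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.widths):
            raise ValueError("centers and widths must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ValueError("target widths must be positive")
        if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
            raise ValueError("target centers must be strictly increasing")

    @property
    def n_states(self) -> int:
        return len(self.centers)

    @classmethod
    def two_state(cls) -> "TDATargets":
        return cls((-7.0, 7.0), (0.2, 0.2))

    @classmethod
    def three_state(cls) -> "TDATargets":
        return cls((-15.0, 0.0, 15.0), (0.3, 1.0, 0.3))

    @classmethod
    def four_state(cls) -> "TDATargets":
        # transition-state data sits between the first two metastable states,
        # with a deliberately broad target width
        return cls((-30.0, -15.0, 0.0, 15.0), (0.3, 4.0, 1.0, 0.3))


@dataclass
class TrainingConfig:
    """Optimizer and architecture settings for CV training."""

    alpha: float = 1.0        # weight of the mean terms
    beta_loss: float = 250.0  # weight of the std terms
    learning_rate: float = 1e-3
    l2: float = 1e-5
    patience: int = 15        # early-stopping patience, epochs
    max_epochs: int = 2000
    layers: tuple[int, ...] = (24, 12, 1)   # sizes after the input layer
    activation: str = "relu"
    seed: int = 0
    val_fraction: float = 0.2
    batch_size: Optional[int] = None        # None = full batch

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta_loss <= 0:
            raise ValueError("loss weights must be positive")
        if self.layers[-1] != 1:
            raise ValueError("the latent CV is scalar; last layer size must be 1")


@dataclass
class StateDataset:
    """Configurations with one integer state label per row."""

    X: np.ndarray
    labels: np.ndarray
    provenance: str = "unbiased"   # unbiased | trapped | reactive | transition-state

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.X) != len(self.labels):
            raise ValueError("X and labels must have equal length")

    @property
    def state_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @staticmethod
    def concatenate(datasets: Sequence["StateDataset"]) -> "StateDataset":
        X = np.concatenate([d.X for d in datasets])
        y = np.concatenate([d.labels for d in datasets])
        return StateDataset(X, y, provenance="+".join(d.provenance for d in datasets))


def _state_moments(latents: np.ndarray, labels: np.ndarray,
                   n_states: int) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Per-state (mean, population std, index sets); errors on tiny states."""
    mus = np.empty(n_states)
    sigmas = np.empty(n_states)
    idxs = []
    for k in range(n_states):
        idx = np.flatnonzero(labels == k)
        if len(idx) < 2:
            raise StateCountError(
                f"state {k} has {len(idx)} sample(s); need >= 2 for its "
                "standard deviation to be defined")
        z = latents[idx]
        mus[k] = z.mean()
        sigmas[k] = z.std()   # population convention
        idxs.append(idx)
    return mus, sigmas, idxs


def tda_loss(latents: np.ndarray, labels: np.ndarray, targets: TDATargets,
             alpha: float = 1.0, beta_loss: float = 250.0) -> float:
    """Moment-matching loss over per-state batch statistics."""
    latents = np.asarray(latents, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int)
    mus, sigmas, _ = _state_moments(latents, labels, targets.n_states)
    c = np.asarray(targets.centers)
    w = np.asarray(targets.widths)
    return float(np.sum(alpha * (mus - c) ** 2 + beta_loss * (sigmas - w) ** 2))


def _tda_loss_grad(latents: np.ndarray, labels: np.ndarray, targets: TDATargets,
                   alpha: float, beta_loss: float) -> tuple[float, np.ndarray]:
    """Loss and its gradient w.r.t. each latent value."""
    mus, sigmas, idxs = _state_moments(latents, labels, targets.n_states)
    c = np.asarray(targets.centers)
    w = np.asarray(targets.widths)
    loss = float(np.sum(alpha * (mus - c) ** 2 + beta_loss * (sigmas - w) ** 2))
    grad = np.zeros_like(latents)
    for k, idx in enumerate(idxs):
        n_k = len(idx)
        grad[idx] += 2.0 * alpha * (mus[k] - c[k]) / n_k
        if sigmas[k] > 0:
            grad[idx] += (2.0 * beta_loss * (sigmas[k] - w[k])
                          * (latents[idx] - mus[k]) / (n_k * sigmas[k]))
        # at σ_k = 0 the std term is not differentiable; its subgradient 0 is used
    return loss, grad


class _MLP:
    """Minimal dense network with ReLU hidden activations."""

    def __init__(self, n_in: int, layers: Sequence[int], rng: np.random.Generator):
        sizes = [n_in, *layers]
        # uniform ±1/sqrt(fan_in) init: modest first-layer weights keep the
        # map smooth between and beyond the training clusters
        self.W = [rng.uniform(-1.0, 1.0, (a, b)) / np.sqrt(a)
                  for a, b in zip(sizes[:-1], sizes[1:])]
        self.b = [rng.uniform(-1.0, 1.0, b) / np.sqrt(a)
                  for a, b in zip(sizes[:-1], sizes[1:])]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Latent values (n,) and the per-layer pre-activation cache."""
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(z, 0.0)
            else:
                h = z
            acts.append(z)
        return h[:, 0], acts

    def backward(self, acts: list[np.ndarray], dz: np.ndarray):
        """Parameter gradients given dL/d(latent), shape (n,)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dz[:, None]
        for i in reversed(range(len(self.W))):
            h_prev = acts[i] if i == 0 else np.maximum(acts[i], 0.0)
            gW[i] = h_prev.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (acts[i] > 0)
        return gW, gb

    def input_gradient(self, X: np.ndarray) -> np.ndarray:
        """d latent / d input, shape (n, d); exact (piecewise-linear network)."""
        _, acts = self.forward(X)
        delta = np.ones((len(X), 1))
        for i in reversed(range(len(self.W))):
            delta = delta @ self.W[i].T
            if i > 0:
                delta = delta * (acts[i] > 0)
        return delta

    def params(self):
        return self.W + self.b

    def set_params(self, flat):
        k = len(self.W)
        self.W = [p.copy() for p in flat[:k]]
        self.b = [p.copy() for p in flat[k:]]


class TDAModel:
    """Trained CV: network plus a frozen affine normalization to [-1, 1]."""

    def __init__(self, mlp: _MLP, n_in: int, targets: TDATargets,
                 zmin: float = -1.0, zmax: float = 1.0):
        self._mlp = mlp
        self.n_in = n_in
        self.targets = targets
        # s = 2 (z - zmin)/(zmax - zmin) - 1; this form maps the training-set
        # extrema to exactly -1 and 1 in floating point
        self.zmin = zmin
        self.zmax = zmax
        self.state_moments: dict[int, tuple[float, float]] = {}
        self.training_history: dict = {}

    def latent(self, X: np.ndarray) -> np.ndarray:
        """Raw (unnormalized) network output."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_in:
            raise ValueError(f"expected inputs of dimension {self.n_in}, "
                             f"got {X.shape[1]}")
        z, _ = self._mlp.forward(X)
        return z

    @property
    def scale(self) -> float:
        """d s / d z of the normalization map."""
        return 2.0 / (self.zmax - self.zmin)

    def normalize(self, z: np.ndarray) -> np.ndarray:
        return 2.0 * ((z - self.zmin) / (self.zmax - self.zmin)) - 1.0

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Normalized CV values for a batch of configurations."""
        return self.normalize(self.latent(X))

    def value_and_gradient(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        """(s(x), ∇s(x)) for a single configuration."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.shape[0] != self.n_in:
            raise ValueError(f"expected a single configuration of dimension "
                             f"{self.n_in}, got shape {x.shape}")
        X = x[None, :]
        s = self.normalize(self._mlp.forward(X)[0][0])
        grad = self.scale * self._mlp.input_gradient(X)[0]
        return float(s), grad

    def values_and_gradients(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Batched (s, ∇s) for several configurations at once."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = self.normalize(self._mlp.forward(X)[0])
        grads = self.scale * self._mlp.input_gradient(X)
        return s, grads


def evaluate_cv(model: TDAModel, configuration: np.ndarray):
    return model.value_and_gradient(configuration)


class _Adam:
    def __init__(self, params, lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _stratified_split(labels: np.ndarray, frac: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        if len(idx) < 4:
            raise StateCountError(
                f"state {k} has {len(idx)} sample(s); need >= 4 to hold out "
                "a validation split with defined moments")
        idx = rng.permutation(idx)
        n_val = min(max(2, int(round(frac * len(idx)))), len(idx) - 2)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train_cv(dataset: StateDataset, targets: TDATargets,
             config: TrainingConfig = TrainingConfig()) -> TDAModel:
    """Train a TDA CV on labelled configurations.

    Full-batch Adam on the moment-matching loss plus an L2 penalty on the
    weights; early stopping monitors the loss on a stratified held-out split
    and restores the best parameters. The normalization affine map and
    per-state moments (in normalized CV space) are frozen into the model.
    """
    X, y = dataset.X, dataset.labels
    present = set(np.unique(y).tolist())
    needed = set(range(targets.n_states))
    if not needed <= present:
        raise ValueError(f"labels must cover all target states; missing "
                         f"{sorted(needed - present)}")
    rng = np.random.default_rng(config.seed)
    tr, va = _stratified_split(y, config.val_fraction, rng)
    mlp = _MLP(X.shape[1], config.layers, rng)
    opt = _Adam(mlp.params(), config.learning_rate)
    best_val = np.inf
    best_params = [p.copy() for p in mlp.params()]
    best_epoch = 0
    wait = 0
    history = {"train_loss": [], "val_loss": []}

    batch = config.batch_size
    for epoch in range(config.max_epochs):
        if batch is None:
            batches = [tr]
        else:
            perm = rng.permutation(tr)
            batches = [perm[i:i + batch] for i in range(0, len(perm), batch)
                       if len(perm[i:i + batch]) >= 2 * targets.n_states]
        ep_loss = 0.0
        for bidx in batches:
            z, acts = mlp.forward(X[bidx])
            loss, dz = _tda_loss_grad(z, y[bidx], targets,
                                      config.alpha, config.beta_loss)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training loss diverged at epoch {epoch}")
            gW, gb = mlp.backward(acts, dz)
            gW = [g + 2.0 * config.l2 * W for g, W in zip(gW, mlp.W)]
            opt.step(mlp.params(), gW + gb)
            ep_loss += loss
        zv, _ = mlp.forward(X[va])
        val_loss = tda_loss(zv, y[va], targets, config.alpha, config.beta_loss)
        history["train_loss"].append(ep_loss / max(len(batches), 1))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = [p.copy() for p in mlp.params()]
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    mlp.set_params(best_params)

    z_all, _ = mlp.forward(X)
    zmin, zmax = float(z_all.min()), float(z_all.max())
    if zmax - zmin < 1e-12:
        raise FloatingPointError("degenerate latent space: all outputs equal")
    model = TDAModel(mlp, X.shape[1], targets, zmin=zmin, zmax=zmax)
    s_all = model.evaluate(X)
    for k in range(targets.n_states):
        sk = s_all[y == k]
        model.state_moments[k] = (float(sk.mean()), float(sk.std()))
    model.training_history = {"best_epoch": best_epoch, "best_val_loss": best_val,
                              "epochs_run": len(history["val_loss"]),
                              **history}
    return model
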