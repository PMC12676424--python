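"""Trainable volumetric models: weight generators, classifiers, and the
combined curriculum-adaptive re-weighting (CARN) predictor.

All models are small NumPy modules with analytic gradients, sized for
desk-scale volumes (16--48 voxels per axis).  They share three contracts:

* classifiers map a ``(C, D, H, W)`` value array to a pre-sigmoid score
  (the logit) and a probability, are deterministic for fixed parameters,
  and support seeded re-initialization;
* weight generators map the same array to a non-negative voxel-weight grid
  of shape ``(D, H, W)`` (a sigmoid keeps weights in (0, 1), so re-weighting
  can attenuate but never sign-flip image content);
* the CARN predictor computes ``C(G(I) * I)`` with element-wise
  multiplication broadcast across channels, and backpropagates a loss
  jointly through both parts.

Parameters, gradients and Adam moments live in per-module dicts, so a
generic optimizer and (de)serialization work uniformly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Protocol

import numpy as np

__all__ = [
    "Predictor",
    "AffineLogitModel",
    "VoxelGateGenerator",
    "LinearVolumeClassifier",
    "SlabQuadraticClassifier",
    "CarnModel",
    "Adam",
    "air_forward",
    "build_model",
    "save_model",
    "load_model",
]


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class Predictor(Protocol):
    """Anything that scores a ``(C, D, H, W)`` value array."""

    def predict_logit(self, x: np.ndarray) -> float: ...

    def predict_proba(self, x: np.ndarray) -> float: ...


class _Module:
    """Minimal parameter container with seeded init and accumulated grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k, g in self.grads.items():
            g[...] = 0.0

    def _register(self, name: str, value: np.ndarray) -> None:
        self.params[name] = np.asarray(value, dtype=np.float64)
        self.grads[name] = np.zeros_like(self.params[name])

    def initialize(self, seed: int) -> None:  # pragma: no cover - overridden
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Weight generators
# ---------------------------------------------------------------------------

class VoxelGateGenerator(_Module):
    """Voxel-wise gate ``g = sigmoid(v + s * mean_c(x))``.

    ``v`` is a learned spatial bias map and ``s`` a learned input-sensitivity
    map, so the gate can both carve out static anatomy and respond to the
    scan content.  Output shape equals the input spatial shape; values in
    (0, 1).
    """

    def __init__(self, spatial_shape: tuple[int, int, int], seed: int = 0,
                 init_scale: float = 1e-3) -> None:
        super().__init__()
        self.spatial_shape = tuple(spatial_shape)
        self.init_scale = init_scale
        self.initialize(seed)

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self._register("v", rng.normal(0.0, self.init_scale, self.spatial_shape))
        self._register("s", rng.normal(0.0, self.init_scale, self.spatial_shape))

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        if x.shape[1:] != self.spatial_shape:
            raise ValueError(f"input spatial shape {x.shape[1:]} != {self.spatial_shape}")
        xbar = x.mean(axis=0)
        g = _sigmoid(self.params["v"] + self.params["s"] * xbar)
        return g, {"xbar": xbar, "g": g}

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, dg: np.ndarray, cache: dict) -> None:
        """Accumulate parameter gradients given dLoss/dg."""
        g = cache["g"]
        du = dg * g * (1.0 - g)
        self.grads["v"] += du
        self.grads["s"] += du * cache["xbar"]


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class LinearVolumeClassifier(_Module):
    """Affine logit over all voxels: ``logit = mean(w * x) + b``.

    The mean (rather than sum) keeps the logit scale independent of the
    voxel count, so one optimizer step moves the logit by O(learning rate)
    regardless of volume size.  The model is still affine in its input.
    """

    def __init__(self, input_shape: tuple[int, ...], seed: int = 0,
                 init_scale: float = 1e-3) -> None:
        super().__init__()
        self.input_shape = tuple(input_shape)  # (C, D, H, W)
        self.n_features = int(np.prod(input_shape))
        self.init_scale = init_scale
        self.initialize(seed)

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self._register("w", rng.normal(0.0, self.init_scale, self.input_shape))
        self._register("b", np.zeros(()))

    def forward(self, z: np.ndarray) -> tuple[float, dict]:
        if z.shape != self.input_shape:
            raise ValueError(f"input shape {z.shape} != {self.input_shape}")
        logit = float(np.mean(self.params["w"] * z) + self.params["b"])
        return logit, {"z": z}

    def backward(self, dlogit: float, cache: dict) -> np.ndarray:
        n = self.n_features
        self.grads["w"] += dlogit * cache["z"] / n
        self.grads["b"] += dlogit
        return dlogit * self.params["w"] / n

    def predict_logit(self, x: np.ndarray) -> float:
        return self.forward(np.asarray(x, dtype=np.float64))[0]

    def predict_proba(self, x: np.ndarray) -> float:
        return float(_sigmoid(self.predict_logit(x)))


class SlabQuadraticClassifier(_Module):
    """Quadratic logit over depth-slab mean features.

    The volume is average-pooled into ``n_slabs`` equal depth slabs per
    channel (features ``f``), and ``logit = w . f + f' U f + b``.  The
    quadratic form makes the classifier sensitive to pairwise layer
    interactions, which a purely affine model cannot express.

    By default ``U`` carries off-diagonal (cross-feature) terms only:
    omitting per-feature curvature makes a learned pairwise dependence
    identifiable as a cross term rather than representable through
    diagonal curvature, at no cost to linear separability.
    """

    def __init__(self, input_shape: tuple[int, ...], n_slabs: int = 6,
                 seed: int = 0, init_scale: float = 1e-3,
                 include_diagonal: bool = False) -> None:
        super().__init__()
        self.input_shape = tuple(input_shape)
        c, d = self.input_shape[0], self.input_shape[1]
        if d % n_slabs != 0:
            raise ValueError(f"depth {d} not divisible into {n_slabs} slabs")
        self.n_slabs = n_slabs
        self.slab_depth = d // n_slabs
        self.n_features = c * n_slabs
        self.init_scale = init_scale
        self.include_diagonal = include_diagonal
        self.initialize(seed)

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        f = self.n_features
        self._register("w", rng.normal(0.0, self.init_scale, f))
        U = rng.normal(0.0, self.init_scale, (f, f))
        if not self.include_diagonal:
            np.fill_diagonal(U, 0.0)
        self._register("U", U)
        self._register("b", np.zeros(()))

    def _pool(self, z: np.ndarray) -> np.ndarray:
        c, d = self.input_shape[0], self.input_shape[1]
        slabs = z.reshape(c, self.n_slabs, self.slab_depth, *self.input_shape[2:])
        return slabs.mean(axis=(2, 3, 4)).reshape(-1)

    def forward(self, z: np.ndarray) -> tuple[float, dict]:
        if z.shape != self.input_shape:
            raise ValueError(f"input shape {z.shape} != {self.input_shape}")
        f = self._pool(z)
        w, U = self.params["w"], self.params["U"]
        logit = float(w @ f + f @ U @ f + self.params["b"])
        return logit, {"f": f}

    def backward(self, dlogit: float, cache: dict) -> np.ndarray:
        f = cache["f"]
        w, U = self.params["w"], self.params["U"]
        self.grads["w"] += dlogit * f
        dU = dlogit * np.outer(f, f)
        if not self.include_diagonal:
            np.fill_diagonal(dU, 0.0)
        self.grads["U"] += dU
        self.grads["b"] += dlogit
        df = dlogit * (w + (U + U.T) @ f)
        # adjoint of mean-pooling: spread each feature gradient uniformly
        c, d, h, wd = self.input_shape
        per_voxel = df.reshape(c, self.n_slabs) / (self.slab_depth * h * wd)
        dz = np.repeat(per_voxel, self.slab_depth, axis=1)[:, :, None, None]
        return np.broadcast_to(dz, self.input_shape).copy()

    def predict_logit(self, x: np.ndarray) -> float:
        return self.forward(np.asarray(x, dtype=np.float64))[0]

    def predict_proba(self, x: np.ndarray) -> float:
        return float(_sigmoid(self.predict_logit(x)))


class SlabLinearClassifier(_Module):
    """Affine logit over depth-slab mean features: ``logit = w . f + b``.

    The lowest-capacity member of the family: one weight per slab per
    channel.  Because the logit is additive across slabs, each tissue
    layer's occlusion delta depends only on that layer's own content.
    """

    def __init__(self, input_shape: tuple[int, ...], n_slabs: int = 6,
                 seed: int = 0, init_scale: float = 1e-3) -> None:
        super().__init__()
        self.input_shape = tuple(input_shape)
        c, d = self.input_shape[0], self.input_shape[1]
        if d % n_slabs != 0:
            raise ValueError(f"depth {d} not divisible into {n_slabs} slabs")
        self.n_slabs = n_slabs
        self.slab_depth = d // n_slabs
        self.n_features = c * n_slabs
        self.init_scale = init_scale
        self.initialize(seed)

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self._register("w", rng.normal(0.0, self.init_scale, self.n_features))
        self._register("b", np.zeros(()))

    _pool = SlabQuadraticClassifier._pool

    def forward(self, z: np.ndarray) -> tuple[float, dict]:
        if z.shape != self.input_shape:
            raise ValueError(f"input shape {z.shape} != {self.input_shape}")
        f = self._pool(z)
        return float(self.params["w"] @ f + self.params["b"]), {"f": f}

    def backward(self, dlogit: float, cache: dict) -> np.ndarray:
        self.grads["w"] += dlogit * cache["f"]
        self.grads["b"] += dlogit
        df = dlogit * self.params["w"]
        c, d, h, wd = self.input_shape
        per_voxel = df.reshape(c, self.n_slabs) / (self.slab_depth * h * wd)
        dz = np.repeat(per_voxel, self.slab_depth, axis=1)[:, :, None, None]
        return np.broadcast_to(dz, self.input_shape).copy()

    def predict_logit(self, x: np.ndarray) -> float:
        return self.forward(np.asarray(x, dtype=np.float64))[0]

    def predict_proba(self, x: np.ndarray) -> float:
        return float(_sigmoid(self.predict_logit(x)))


class AffineLogitModel:
    """Fixed (non-trainable) affine-logit scorer ``logit = sum(w*x) + b``.

    Serves as an analytically tractable reference: occluding a voxel set
    changes the logit by exactly the sum of ``w * x`` over that set.
    """

    def __init__(self, weights: np.ndarray, bias: float = 0.0) -> None:
        self.weights = np.asarray(weights, dtype=np.float64)
        self.bias = float(bias)

    def predict_logit(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=np.float64)
        if x.shape != self.weights.shape:
            raise ValueError("input shape does not match weights")
        return float(np.sum(self.weights * x) + self.bias)

    def predict_proba(self, x: np.ndarray) -> float:
        return float(_sigmoid(self.predict_logit(x)))


# ---------------------------------------------------------------------------
# CARN: generator + classifier
# ---------------------------------------------------------------------------

def air_forward(generator, classifier, x: np.ndarray) -> float:
    """Adaptive intensity re-weighting forward pass: probability of
    ``C(G(I) * I)``; with ``generator=None`` the weights are identically 1."""
    x = np.asarray(x, dtype=np.float64)
    if generator is None:
        return classifier.predict_proba(x)
    g = generator(x)
    if g.shape != x.shape[1:]:
        raise ValueError("generator output shape must equal input spatial shape")
    return classifier.predict_proba(g[None] * x)


class CarnModel:
    """A weight generator and classifier trained jointly.

    ``predict_logit`` / ``predict_proba`` evaluate ``C(G(I) * I)``;
    ``forward``/``backward`` expose the training path with gradients
    accumulated in both modules.
    """

    def __init__(self, classifier: _Module, generator: _Module | None = None,
                 arch: dict | None = None) -> None:
        self.classifier = classifier
        self.generator = generator
        self.arch = arch or {}

    def forward(self, x: np.ndarray) -> tuple[float, dict]:
        x = np.asarray(x, dtype=np.float64)
        if self.generator is not None:
            g, gcache = self.generator.forward(x)
            z = g[None] * x
        else:
            g, gcache, z = None, None, x
        logit, ccache = self.classifier.forward(z)
        return logit, {"x": x, "g": g, "gcache": gcache, "ccache": ccache}

    def backward(self, dlogit: float, cache: dict) -> None:
        dz = self.classifier.backward(dlogit, cache["ccache"])
        if self.generator is not None:
            dg = np.sum(dz * cache["x"], axis=0)
            self.generator.backward(dg, cache["gcache"])

    def predict_logit(self, x: np.ndarray) -> float:
        return self.forward(x)[0]

    def predict_proba(self, x: np.ndarray) -> float:
        return float(_sigmoid(self.predict_logit(x)))

    # -- parameter plumbing -------------------------------------------------

    def modules(self) -> list[_Module]:
        mods: list[_Module] = [self.classifier]
        if self.generator is not None:
            mods.append(self.generator)
        return mods

    def zero_grad(self) -> None:
        for m in self.modules():
            m.zero_grad()

    def reinitialize(self, seed: int) -> None:
        """Re-draw every parameter from the architecture's seeded
        initialization scheme (the model-randomization sanity operation)."""
        self.classifier.initialize(seed)
        if self.generator is not None:
            self.generator.initialize(seed + 1)


class Adam:
    """Adam with decoupled weight decay over a list of modules.

    The decay (AdamW-style, applied directly to the parameter) shrinks
    weights that stop receiving gradient, which keeps occlusion
    attributions from accumulating on class-uninformative structure.
    """

    def __init__(self, modules: list[_Module], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.modules = modules
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in mod.params.items()} for mod in modules]
        self.v = [{k: np.zeros_like(v) for k, v in mod.params.items()} for mod in modules]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for mod, m, v in zip(self.modules, self.m, self.v):
            for k, p in mod.params.items():
                g = mod.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1 ** self.t)
                vhat = v[k] / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                if self.weight_decay and k != "b":  # never decay the bias
                    p -= self.lr * self.weight_decay * p


# ---------------------------------------------------------------------------
# Construction and persistence
# ---------------------------------------------------------------------------

def build_model(input_shape: tuple[int, ...], classifier: str = "linear",
                generator: str | None = "gate", n_slabs: int = 6,
                seed: int = 0) -> CarnModel:
    """Assemble a CARN model for ``(C, D, H, W)`` inputs.

    ``classifier``: ``"linear"`` (affine logit over voxels) or
    ``"quadratic"`` (depth-slab features with pairwise interaction terms).
    ``generator``: ``"gate"`` or ``None`` (no re-weighting).
    """
    input_shape = tuple(input_shape)
    if classifier == "linear":
        clf: _Module = LinearVolumeClassifier(input_shape, seed=seed)
    elif classifier == "quadratic":
        clf = SlabQuadraticClassifier(input_shape, n_slabs=n_slabs, seed=seed)
    elif classifier == "slab_linear":
        clf = SlabLinearClassifier(input_shape, n_slabs=n_slabs, seed=seed)
    else:
        raise ValueError(f"unknown classifier {classifier!r}")
    if generator == "gate":
        gen: _Module | None = VoxelGateGenerator(input_shape[1:], seed=seed + 1)
    elif generator is None or generator == "none":
        gen = None
    else:
        raise ValueError(f"unknown generator {generator!r}")
    arch = {"input_shape": list(input_shape), "classifier": classifier,
            "generator": generator if generator != "none" else None,
            "n_slabs": n_slabs, "seed": seed}
    return CarnModel(clf, gen, arch)


def save_model(model: CarnModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "arch.json", "w") as fh:
        json.dump(model.arch, fh, indent=1)
    arrays = {}
    for prefix, mod in [("clf", model.classifier), ("gen", model.generator)]:
        if mod is None:
            continue
        for k, v in mod.params.items():
            arrays[f"{prefix}.{k}"] = v
    np.savez(out / "params.npz", **arrays)
    return out


def load_model(model_dir: str | Path) -> CarnModel:
    out = Path(model_dir)
    with open(out / "arch.json") as fh:
        arch = json.load(fh)
    model = build_model(tuple(arch["input_shape"]), arch["classifier"],
                        arch["generator"], arch.get("n_slabs", 6),
                        arch.get("seed", 0))
    with np.load(out / "params.npz") as data:
        for key in data.files:
            prefix, name = key.split(".", 1)
            mod = model.classifier if prefix == "clf" else model.generator
            mod.params[name][...] = data[key]
    return model
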