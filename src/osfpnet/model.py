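"""The four-path plaque classifier.

One network path = a feature-extraction backbone (shared architecture,
independent weights by default) followed by an object-specific pooling
module.  Paths 1 and 3 take the left/right *transverse* ROIs through
spatial pyramid pooling; paths 2 and 4 take the left/right *longitudinal*
ROIs through multilevel strip pooling.  The four fixed-length descriptors
are concatenated — length ``2*14k + 2*6k = 40k`` with the default level
specs — and classified by fully connected layers with dropout inserted
before the last layer.

The network accepts the four views at completely arbitrary sizes (>= the
48-px backbone minimum); nothing is padded or resized, which is why
training runs at batch size 1.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .backbone import Backbone, BackboneConfig
from .pooling import PoolingSpec, pool_backward, _pool_with_cache

__all__ = [
    "ModelConfig",
    "OSFPNet",
    "build_model",
    "apply_dropout",
    "classifier_input_length",
    "save_checkpoint",
    "load_checkpoint",
]

#: quadruple ordering: left/right x transverse/longitudinal, paths 1..4
PATH_KEYS = ("LT", "LL", "RT", "RL")


@dataclass(frozen=True)
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    pooling_T: PoolingSpec = field(default_factory=PoolingSpec.spp_default)
    pooling_L: PoolingSpec = field(default_factory=PoolingSpec.msp_default)
    fc_sizes: tuple[int, ...] = (4096, 4096)
    n_classes: int = 2
    dropout_drop_p: float = 0.5  # probability of *dropping* a unit
    tie_fe_weights: bool = False

    def __post_init__(self):
        if not 0.0 <= self.dropout_drop_p <= 1.0:
            raise ValueError(f"dropout_drop_p must be in [0,1], got {self.dropout_drop_p}")
        if self.pooling_T.kind != "SPP" or self.pooling_L.kind != "MSP":
            raise ValueError("transverse paths use SPP and longitudinal paths use MSP")

    @property
    def path_specs(self) -> tuple[PoolingSpec, ...]:
        return (self.pooling_T, self.pooling_L, self.pooling_T, self.pooling_L)

    @classmethod
    def tiny(cls) -> "ModelConfig":
        """Desk-scale configuration (k=64, 256-wide head) for CPU runs."""
        return cls(backbone=BackboneConfig.tiny(), fc_sizes=(256, 256))


def classifier_input_length(cfg: ModelConfig) -> int:
    """Concatenated descriptor length: k * sum of per-path pooled units."""
    k = cfg.backbone.out_channels
    return k * sum(spec.total_units for spec in cfg.path_specs)


def apply_dropout(y: np.ndarray, p: float, mode: str = "train",
                  seed: int | None = None) -> np.ndarray:
    """Dropout with Bernoulli *retention* probability ``p``.

    Training mode draws a Bernoulli(p) mask per unit and rescales the kept
    units by 1/p (inverted dropout), so inference mode is the identity.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"retention probability p must be in [0, 1], got {p}")
    if mode not in ("train", "inference"):
        raise ValueError(f"mode must be 'train' or 'inference', got {mode!r}")
    y = np.asarray(y)
    if mode == "inference" or p == 1.0:
        return y.copy()
    if p == 0.0:
        return np.zeros_like(y)
    rng = np.random.default_rng(seed)
    mask = (rng.random(y.shape) < p).astype(y.dtype if y.dtype.kind == "f" else np.float64)
    return y * mask / p


class OSFPNet:
    """Four-path network: per-view backbone + SPP/MSP pooling + FC head."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        if cfg.tie_fe_weights:
            fe = Backbone(cfg.backbone, seed=seed, dtype=dtype)
            self.backbones = [fe] * 4
        else:
            # independent weights per path, distinct seeds
            self.backbones = [
                Backbone(cfg.backbone, seed=seed + i, dtype=dtype) for i in range(4)
            ]
        d_in = classifier_input_length(cfg)
        rng = np.random.default_rng(seed + 100)
        self.classifier: list = []
        for d_out in cfg.fc_sizes:
            self.classifier.append(nn.Linear(d_in, d_out, rng, dtype))
            self.classifier.append(nn.ReLU())
            d_in = d_out
        self.dropout = nn.Dropout(1.0 - cfg.dropout_drop_p)
        self.classifier.append(self.dropout)
        self.classifier.append(nn.Linear(d_in, cfg.n_classes, rng, dtype))
        self._cache = None

    # -- parameters ---------------------------------------------------------
    def parameters(self):
        seen, out = set(), []
        for bb in self.backbones:
            for w, g in bb.params():
                if id(w) not in seen:
                    seen.add(id(w))
                    out.append((w, g))
        for l in self.classifier:
            out.extend(l.params())
        return out

    def state(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.parameters()]

    def set_state(self, arrays: list[np.ndarray]):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"state has {len(arrays)} arrays, model has {len(params)}")
        for (w, _), a in zip(params, arrays):
            if w.shape != a.shape:
                raise ValueError(f"shape mismatch {w.shape} vs {a.shape}")
            w[...] = a

    # -- forward/backward ---------------------------------------------------
    def forward(self, quadruple, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class scores (length n_classes) for one subject's four views.

        ``quadruple`` is ordered (LT, LL, RT, RL); views may each have any
        size >= the backbone minimum.
        """
        if len(quadruple) != 4:
            raise ValueError(f"expected 4 views (LT, LL, RT, RL), got {len(quadruple)}")
        descs, path_caches = [], []
        for bb, spec, img in zip(self.backbones, self.cfg.path_specs, quadruple):
            x = bb.prepare(img)
            fmap, caches = bb.forward(x)
            d, pcache = _pool_with_cache(fmap, spec)
            descs.append(d)
            path_caches.append((caches, pcache, spec))
        z = np.concatenate(descs)
        fc_caches = []
        for l in self.classifier:
            if isinstance(l, nn.Dropout):
                z, c = l.forward(z, train=train, rng=rng)
            else:
                z, c = l.forward(z)
            fc_caches.append(c)
        self._cache = (path_caches, [len(d) for d in descs], fc_caches)
        return z

    def backward(self, dlogits: np.ndarray):
        """Backpropagate through the head and all four paths (after forward)."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        path_caches, lengths, fc_caches = self._cache
        d = dlogits.astype(self.dtype)
        for l, c in zip(reversed(self.classifier), reversed(fc_caches)):
            d = l.backward(d, c)
        off = 0
        for bb, (caches, pcache, spec), n in zip(self.backbones, path_caches, lengths):
            dmap = pool_backward(d[off: off + n], spec, pcache)
            bb.backward(dmap, caches)
            off += n
        self._cache = None

    def descriptors(self, quadruple) -> list[np.ndarray]:
        """Per-path fixed-length descriptors in path order (inference mode)."""
        out = []
        for i, (bb, spec, img) in enumerate(
            zip(self.backbones, self.cfg.path_specs, quadruple)
        ):
            x = bb.prepare(img)
            fmap, _ = bb.forward(x)
            d, _ = _pool_with_cache(fmap, spec)
            out.append(d)
        return out

    def predict_proba(self, quadruple) -> np.ndarray:
        return nn.softmax(self.forward(quadruple, train=False).astype(np.float64))


def build_model(cfg: ModelConfig, seed: int = 0, dtype=np.float32) -> OSFPNet:
    d = classifier_input_length(cfg)
    if d <= 0:
        raise ValueError(f"invalid classifier input length {d}")
    return OSFPNet(cfg, seed=seed, dtype=dtype)


# -- checkpointing ----------------------------------------------------------

def _config_to_json(cfg: ModelConfig) -> str:
    d = asdict(cfg)
    return json.dumps(d)


def _config_from_json(s: str) -> ModelConfig:
    d = json.loads(s)
    bb = d.pop("backbone")
    for key in ("convs_per_block", "channels"):
        bb[key] = tuple(bb[key])
    pt = d.pop("pooling_T")
    pl = d.pop("pooling_L")
    for p in (pt, pl):
        p["levels"] = tuple(tuple(l) for l in p["levels"])
    d["fc_sizes"] = tuple(d["fc_sizes"])
    return ModelConfig(
        backbone=BackboneConfig(**bb),
        pooling_T=PoolingSpec(**pt),
        pooling_L=PoolingSpec(**pl),
        **d,
    )


def save_checkpoint(model: OSFPNet, path):
    """Write weights + a config echo to an .npz checkpoint."""
    arrays = {f"p{i}": w for i, (w, _) in enumerate(model.parameters())}
    arrays["config_json"] = np.array(_config_to_json(model.cfg))
    np.savez(path, **arrays)


def load_checkpoint(path, dtype=np.float32) -> OSFPNet:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    data = np.load(path, allow_pickle=False)
    cfg = _config_from_json(str(data["config_json"]))
    model = OSFPNet(cfg, seed=0, dtype=dtype)
    model.set_state([data[f"p{i}"] for i in range(len(model.parameters()))])
    return model
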