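"""The shared-encoder dose/fluence prediction network.

One 3D convolutional encoder (five resolution levels) feeds two decoders
(four levels each): a dose decoder producing a one-channel dose patch, and
a fluence decoder that additionally concatenates the dose decoder's
feature maps at every resolution level and ends in a geometric projection
head.  The head holds one pre-projection feature channel per beam and maps
each through its (patch-restricted) sparse beam's-eye-view projection
``f_b = P_b^T v_b``; because the projection is linear its adjoint
(multiplication by ``P_b``) propagates gradients during training.

All convolutions are 3x3x3 (stride 1, or stride 2 for downsampling) with
instance normalization and ReLU, except the final 1x1x1 output convolution
of each decoder, which is linear.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .geometry import ProjectionOperator
from .nn.layers import (
    Conv3d,
    InstanceNorm3d,
    ReLU,
    TrilinearUpsample,
    concat_backward,
    concat_forward,
)

__all__ = [
    "ModelConfig",
    "SharedEncoderModel",
    "build_model",
    "project_features",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 19
    base_channels: int = 32
    levels: int = 5
    fluence_channels: int = 9  # one pre-projection feature channel per beam
    norm_affine: bool = True
    zero_init_heads: bool = True  # start both output convolutions at zero
    init_seed: int = 0

    @property
    def channels(self) -> list[int]:
        # channel count doubles per encoder level: 32 -> 64 -> ... -> 512
        return [self.base_channels * 2**i for i in range(self.levels)]


class _ConvBlock:
    """conv3x3x3 -> instance norm -> ReLU."""

    def __init__(self, cin, cout, stride, rng, name, affine):
        self.conv = Conv3d(cin, cout, kernel=3, stride=stride, rng=rng, name=f"{name}.conv")
        self.norm = InstanceNorm3d(cout, affine=affine, name=f"{name}.norm")
        self.act = ReLU()

    def params(self):
        return {**self.conv.params(), **self.norm.params()}

    def forward(self, x, train=True):
        return self.act.forward(self.norm.forward(self.conv.forward(x, train), train), train)

    def backward(self, g):
        return self.conv.backward(self.norm.backward(self.act.backward(g)))


class _Encoder:
    def __init__(self, config: ModelConfig, rng):
        ch = config.channels
        aff = config.norm_affine
        self.lvl0 = [
            _ConvBlock(config.in_channels, ch[0], 1, rng, "enc0.a", aff),
            _ConvBlock(ch[0], ch[0], 1, rng, "enc0.b", aff),
        ]
        self.down = []
        for i in range(1, config.levels):
            self.down.append(
                [
                    _ConvBlock(ch[i - 1], ch[i], 2, rng, f"enc{i}.down", aff),
                    _ConvBlock(ch[i], ch[i], 1, rng, f"enc{i}.b", aff),
                ]
            )

    def params(self):
        out = {}
        for blk in self.lvl0:
            out.update(blk.params())
        for lvl in self.down:
            for blk in lvl:
                out.update(blk.params())
        return out

    def forward(self, x, train=True):
        x = self.lvl0[0].forward(x, train)
        x = self.lvl0[1].forward(x, train)
        skips = [x]
        for lvl in self.down:
            x = lvl[0].forward(x, train)
            x = lvl[1].forward(x, train)
            skips.append(x)
        return skips  # skips[-1] is the bottleneck

    def backward(self, gskips):
        # gskips[i]: gradient arriving at the level-i output from the decoders
        g = gskips[-1]
        for i in range(len(self.down) - 1, -1, -1):
            g = self.down[i][0].backward(self.down[i][1].backward(g))
            g = g + gskips[i]
        return self.lvl0[0].backward(self.lvl0[1].backward(g))


class _Decoder:
    """Four-level decoder with skip (and optional cross-decoder) concats."""

    def __init__(self, config: ModelConfig, out_channels: int, cross: bool, rng, name: str):
        ch = config.channels
        aff = config.norm_affine
        self.cross = cross
        self.n_levels = config.levels - 1  # 4 decoder levels
        self.up = [TrilinearUpsample() for _ in range(self.n_levels)]
        self.block1 = []
        self.block2 = []
        self.cat_counts = []
        for i in range(self.n_levels - 1, -1, -1):  # levels 3, 2, 1, 0
            cat = ch[i] + ch[i + 1] + (ch[i] if cross else 0)
            self.cat_counts.append(
                [ch[i], ch[i + 1]] + ([ch[i]] if cross else [])
            )
            self.block1.append(_ConvBlock(cat, ch[i], 1, rng, f"{name}{i}.a", aff))
            if i > 0:
                self.block2.append(_ConvBlock(ch[i], ch[i], 1, rng, f"{name}{i}.b", aff))
        self.out_conv = Conv3d(ch[0], out_channels, kernel=1, rng=rng, name=f"{name}.out")
        if config.zero_init_heads:
            # zero output heads: predictions start at 0 on the normalized
            # scale, avoiding a large early transient through the
            # projection head (which sums many voxels per beamlet)
            self.out_conv.weight.value[...] = 0.0
            self.out_conv.bias.value[...] = 0.0

    def params(self):
        out = {}
        for blk in self.block1 + self.block2:
            out.update(blk.params())
        out.update(self.out_conv.params())
        return out

    def forward(self, skips, cross_feats=None, train=True):
        x = skips[-1]
        feats = [None] * self.n_levels  # per level, after that level's 3x3 convs
        for j, i in enumerate(range(self.n_levels - 1, -1, -1)):
            x = self.up[j].forward(x, skips[i].shape[2:], train)
            parts = [skips[i], x]
            if self.cross:
                parts.append(cross_feats[i])
            x = concat_forward(parts)
            x = self.block1[j].forward(x, train)
            if i > 0:
                x = self.block2[j].forward(x, train)
            feats[i] = x
        out = self.out_conv.forward(x, train)
        return out, feats

    def backward(self, g_out, g_feats=None):
        """Backprop; ``g_feats`` carries extra per-level gradients arriving
        through cross-decoder links.  Returns (gskips, gcross)."""
        n = self.n_levels
        gskips = [None] * (n + 1)
        gcross = [None] * n if self.cross else None
        gx = self.out_conv.backward(g_out)
        # lists were filled for levels n-1 .. 0, so level i lives at index n-1-i;
        # reverse of the forward order processes levels 0, 1, ..., n-1
        for i in range(n):
            idx = n - 1 - i
            if g_feats is not None and g_feats[i] is not None:
                gx = gx + g_feats[i]
            if i > 0:
                gx = self.block2[idx].backward(gx)
            gx = self.block1[idx].backward(gx)
            parts = concat_backward(gx, self.cat_counts[idx])
            gskips[i] = parts[0]
            gup = parts[1]
            if self.cross:
                gcross[i] = parts[2]
            gx = self.up[idx].backward(gup)
        gskips[n] = gx  # gradient into the bottleneck
        return gskips, gcross


def project_features(
    v: np.ndarray, ops: list[ProjectionOperator]
) -> np.ndarray:
    """Project a per-beam feature volume onto the fluence planes.

    ``v`` is ``(n_beams, D, H, W)`` or batched ``(N, n_beams, D, H, W)``;
    channel ``b`` is multiplied by ``P_b^T`` and reshaped to the operator's
    fluence-row window (rows x cols).  Edge rows of a patch-restricted
    operator are produced but under-covered (truncated projection); the
    training loss excludes them.
    """
    batched = v.ndim == 5
    vv = v if batched else v[None]
    if vv.shape[1] != len(ops):
        raise ValueError(f"{vv.shape[1]} feature channels but {len(ops)} operators")
    rows, cols = ops[0].fluence_shape
    out = np.empty((vv.shape[0], len(ops), rows, cols), dtype=vv.dtype)
    for n in range(vv.shape[0]):
        for b, op in enumerate(ops):
            if vv[n, b].size != op.matrix.shape[0]:
                raise ValueError("feature volume does not match operator voxel count")
            out[n, b] = (op.matrix.T @ vv[n, b].astype(np.float64).ravel()).reshape(rows, cols)
    return out if batched else out[0]


def _project_batch(v: np.ndarray, ops_per_sample) -> np.ndarray:
    """Batched projection with per-sample operator lists."""
    return np.stack(
        [project_features(v[n], ops_per_sample[n]) for n in range(v.shape[0])]
    )


def _project_batch_adjoint(gf: np.ndarray, ops_per_sample, vol_shape) -> np.ndarray:
    return np.stack(
        [
            project_features_adjoint(gf[n], ops_per_sample[n], vol_shape)
            for n in range(gf.shape[0])
        ]
    )


def project_features_adjoint(gf: np.ndarray, ops, vol_shape) -> np.ndarray:
    """Adjoint of :func:`project_features` (gradient propagation)."""
    batched = gf.ndim == 4
    gg = gf if batched else gf[None]
    out = np.empty((gg.shape[0], len(ops)) + tuple(vol_shape), dtype=gf.dtype)
    for n in range(gg.shape[0]):
        for b, op in enumerate(ops):
            out[n, b] = (op.matrix @ gg[n, b].astype(np.float64).ravel()).reshape(vol_shape)
    return out if batched else out[0]


class SharedEncoderModel:
    """Dual-output network: dose patch + projected fluence patch."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        self.encoder = _Encoder(config, rng)
        self.dose_decoder = _Decoder(config, 1, cross=False, rng=rng, name="dose")
        self.fluence_decoder = _Decoder(
            config, config.fluence_channels, cross=True, rng=rng, name="flu"
        )
        self.bottleneck_shape: tuple | None = None
        self._cache = None

    # -- parameters -------------------------------------------------------
    def params(self):
        return {
            **{f"encoder.{k}": p for k, p in self.encoder.params().items()},
            **{f"dose.{k}": p for k, p in self.dose_decoder.params().items()},
            **{f"fluence.{k}": p for k, p in self.fluence_decoder.params().items()},
        }

    def count_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params().values()))

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, patch_ops: list[ProjectionOperator] | None = None,
                train: bool = False):
        """Run the network on a ``(N, 19, D, H, W)`` input patch.

        Returns ``(dose_patch, fluence_patch, v)`` where ``dose_patch`` is
        ``(N, 1, D, H, W)``, ``v`` the pre-projection feature volume
        ``(N, n_beams, D, H, W)``, and ``fluence_patch`` the projected
        ``(N, n_beams, rows, cols)`` patch (None when no operators given).
        All outputs are on normalized scales.
        """
        if np.asarray(x).dtype != np.float64:
            x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 5:
            raise ValueError("input must be (N, C, D, H, W)")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}"
            )
        if x.shape[2] % 2 ** (self.config.levels - 1) != 0:
            raise ValueError("slice count must be divisible by 16 for 5 levels")
        skips = self.encoder.forward(x, train)
        self.bottleneck_shape = skips[-1].shape[1:]
        dose, dose_feats = self.dose_decoder.forward(skips, train=train)
        v, _ = self.fluence_decoder.forward(skips, cross_feats=dose_feats, train=train)
        fl = None
        ops_per_sample = None
        if patch_ops is not None:
            if isinstance(patch_ops[0], (list, tuple)):
                ops_per_sample = list(patch_ops)  # one operator list per sample
            else:
                ops_per_sample = [list(patch_ops)] * x.shape[0]
            if len(ops_per_sample) != x.shape[0]:
                raise ValueError("need one operator list per batch sample")
            for ops in ops_per_sample:
                if len(ops) != self.config.fluence_channels:
                    raise ValueError("one projection operator per beam channel required")
            fl = _project_batch(v, ops_per_sample)
        if train:
            self._cache = (ops_per_sample, v.shape[2:])
        return dose, fl, v

    def backward(self, g_dose: np.ndarray, g_fluence: np.ndarray | None = None,
                 g_v: np.ndarray | None = None):
        """Backprop from output gradients; accumulates parameter grads."""
        ops_per_sample, vol_shape = self._cache
        gv = np.zeros(0)
        if g_fluence is not None:
            gv = _project_batch_adjoint(g_fluence, ops_per_sample, vol_shape)
        if g_v is not None:
            gv = gv + g_v if g_fluence is not None else g_v
        gskips_f, gcross = self.fluence_decoder.backward(gv)
        gskips_d, _ = self.dose_decoder.backward(g_dose, g_feats=gcross)
        gskips = [a + b for a, b in zip(gskips_f, gskips_d)]
        gx = self.encoder.backward(gskips)
        self._cache = None
        return gx


def build_model(config: ModelConfig | None = None) -> SharedEncoderModel:
    """Build the network; raises on configs violating the doubling/halving
    channel plan (channel counts are derived, so only sizes can violate)."""
    config = config or ModelConfig()
    if config.levels < 2:
        raise ValueError("need at least 2 resolution levels")
    if config.base_channels < 1 or config.in_channels < 1:
        raise ValueError("invalid channel configuration")
    return SharedEncoderModel(config)


# ---------------------------------------------------------------------------
# checkpoints: config JSON + named parameter arrays in one HDF5 container


def save_checkpoint(path, model: SharedEncoderModel, extra: dict | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "dosefluence-checkpoint"
        f.attrs["config"] = json.dumps(asdict(model.config))
        if extra:
            f.attrs["extra"] = json.dumps(extra)
        g = f.create_group("params")
        for name, p in model.params().items():
            g.create_dataset(name, data=p.value)


def load_checkpoint(path, config: ModelConfig | None = None) -> SharedEncoderModel:
    import h5py

    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "dosefluence-checkpoint":
            raise ValueError("not a dosefluence checkpoint")
        stored = ModelConfig(**json.loads(f.attrs["config"]))
        if config is not None and config != stored:
            raise ValueError(
                f"checkpoint config {stored} does not match requested {config}"
            )
        model = build_model(stored)
        params = model.params()
        names = set(f["params"].keys())
        if names != set(params.keys()):
            raise ValueError("checkpoint parameter names do not match the architecture")
        for name, p in params.items():
            arr = f["params"][name][:]
            if arr.shape != p.value.shape:
                raise ValueError(f"parameter {name} has shape {arr.shape}, expected {p.value.shape}")
            p.value[...] = arr
    return model
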