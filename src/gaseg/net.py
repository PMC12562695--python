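"""The 3D-encoder / 2D-decoder attention U-Net for en face GA segmentation.

The network consumes a subsampled OCT volume ``(z, x, y)`` and emits a 2D
probability mask on the en face plane ``(x, y)``. Its encoder is a standard
3D U-Net encoder (residual double-convolution blocks, 2x average-pool
downsampling); the skip connections *drop the axial dimension*: at every
level a learned softmax attention over ``z`` collapses the 3D feature map to
2D before it is passed to a 2D decoder, whose stages upsample in ``(x, y)``
and merge the collapsed skips through additive attention gates. A final 1x1
convolution with a logistic squashing yields per-pixel GA probability.

With ``use_attention=False`` the axial collapse degrades to a plain mean
over ``z`` and the gates become identities; with ``use_residual=False`` the
blocks are plain double convolutions — together these switches recover a
vanilla 3D-to-2D U-Net for ablations.

An optional near-infrared reflectance image can be supplied as a second
input channel (``in_channels=2``); being natively en face it is injected at
the finest 2D decoder level rather than broadcast into the 3D encoder.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .errors import ConfigError, ShapeError
from .types import EnFaceMask

__all__ = ["NetConfig", "ProbMask", "Net3D2D", "build", "binarize",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``input_dims`` is the subsampled volume grid ``(z, x, y)``; the output
    mask is always ``(x, y)``. ``in_channels=2`` enables the nIR channel.
    """

    input_dims: tuple[int, int, int]
    levels: int = 4
    base_channels: int = 16
    use_attention: bool = True
    use_residual: bool = True
    in_channels: int = 1
    seed: int = 0

    @property
    def mask_dims(self) -> tuple[int, int]:
        return (self.input_dims[1], self.input_dims[2])

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.in_channels not in (1, 2):
            raise ConfigError("in_channels must be 1 (OCT) or 2 (OCT + nIR)")
        z, x, y = self.input_dims
        d = 2 ** self.levels
        if x % d or y % d:
            raise ConfigError(
                f"input (x, y) = ({x}, {y}) must be divisible by 2^levels = {d}"
            )


@dataclass
class ProbMask:
    """A 2D en face probability map, values in [0, 1], indexed (x, y)."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ShapeError(f"probability mask must be 2D, got {self.grid.shape}")
        if self.grid.size and (self.grid.min() < -1e-6 or self.grid.max() > 1 + 1e-6):
            raise ShapeError("probabilities must lie in [0, 1]")
        self.grid = np.clip(self.grid, 0.0, 1.0)


def binarize(p: ProbMask, threshold: float = 0.5,
             pixel_area_mm2: Optional[float] = None) -> EnFaceMask:
    """Threshold a probability mask; ties (p == threshold) map to GA."""
    if not (0.0 < threshold < 1.0):
        raise ConfigError("threshold must lie in (0, 1)")
    grid = (p.grid >= threshold).astype(np.uint8)
    return EnFaceMask(grid=grid, pixel_area_mm2=pixel_area_mm2, binary=True)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

#: negative-side slope of the rectifiers; leaky keeps all units trainable,
#: which matters at the narrow widths used in CPU-scale experiments
LEAK = 0.1


class _Module:
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, _Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for it in v:
                    if isinstance(it, _Module):
                        out.extend(it.parameters())
        return out


def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Conv(_Module):
    """Shared 2D/3D convolution layer wrapper; ndim from kernel length."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: tuple[int, ...],
                 zero_init: bool = False):
        shape = (c_out, c_in) + kernel
        w = np.zeros(shape, np.float32) if zero_init else _he(rng, shape)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(c_out, np.float32), requires_grad=True)
        self._nd = len(kernel)

    def __call__(self, x: Tensor, fuse_relu: bool = False) -> Tensor:
        if self._nd == 3:
            return ag.conv3d(x, self.w, self.b, fuse_relu=fuse_relu, slope=LEAK)
        return ag.conv2d(x, self.w, self.b, fuse_relu=fuse_relu, slope=LEAK)


class _Block(_Module):
    """Residual double-convolution block (3D or 2D by kernel)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: tuple[int, ...],
                 residual: bool):
        self.conv1 = _Conv(rng, c_in, c_out, kernel)
        self.conv2 = _Conv(rng, c_out, c_out, kernel)
        self.residual = residual
        self.short = None
        if residual and c_in != c_out:
            self.short = _Conv(rng, c_in, c_out, (1,) * len(kernel))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x, fuse_relu=True))
        if not self.residual:
            return ag.relu(h, slope=LEAK)
        s = self.short(x) if self.short is not None else x
        return ag.add_relu(h, s, slope=LEAK)


class AxialCollapse(_Module):
    """Collapse (N,C,Z,X,Y) -> (N,C,X,Y) over the axial axis.

    With attention: a 1x1x1 convolution produces per-voxel logits, softmaxed
    over ``z``; the feature map is reduced by the attention-weighted sum and
    channel-mixed by a 1x1 2D convolution. The logit convolution is
    zero-initialized so an untrained collapse is exactly the mean over ``z``.
    Without attention the reduction is a plain mean.
    """

    def __init__(self, rng, channels: int, use_attention: bool):
        self.use_attention = use_attention
        if use_attention:
            self.logit = _Conv(rng, channels, 1, (1, 1, 1), zero_init=True)
        self.mix = _Conv(rng, channels, channels, (1, 1))

    def __call__(self, x: Tensor) -> Tensor:
        z_dim = x.data.shape[2]
        if self.use_attention and z_dim > 1:
            alpha = ag.softmax(self.logit(x), axis=2)  # (N,1,Z,X,Y)
            red = ag.weighted_z_sum(x, alpha)
        elif z_dim == 1:
            red = ag.tsum(x, axis=2)
        else:
            red = ag.mul(ag.tsum(x, axis=2), Tensor(np.float32(1.0 / z_dim)))
        return self.mix(red)


class AttentionGate2D(_Module):
    """Additive attention gate on a 2D skip connection.

    ``alpha = sigmoid(psi(relu(Wg g + Ws s)))`` with per-pixel alpha in
    [0, 1]; output is ``s * alpha``. ``g`` is the coarser decoder feature
    already upsampled to the skip's spatial grid.
    """

    def __init__(self, rng, c_skip: int, c_gate: int):
        c_int = max(1, c_skip // 2)
        self.wg = _Conv(rng, c_gate, c_int, (1, 1))
        self.ws = _Conv(rng, c_skip, c_int, (1, 1))
        self.psi = _Conv(rng, c_int, 1, (1, 1))

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        if skip.data.shape[2:] != gate.data.shape[2:]:
            raise ShapeError(
                f"attention gate spatial mismatch: skip {skip.data.shape} "
                f"vs gate {gate.data.shape}"
            )
        a = ag.sigmoid(self.psi(ag.relu(ag.add(self.wg(gate), self.ws(skip)))))
        return ag.mul(skip, a)


class Net3D2D(_Module):
    """See module docstring. Build with :func:`build` or the constructor."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.levels
        bc = config.base_channels
        widths = [bc * 2 ** i for i in range(L + 1)]  # encoder + bottleneck

        # z pooling schedule: halve z while it is even and > 1
        z = config.input_dims[0]
        self.z_factors: list[int] = []
        for _ in range(L):
            f = 2 if (z > 1 and z % 2 == 0) else 1
            self.z_factors.append(f)
            z //= f

        self.enc: list[_Block] = []
        c_prev = 1
        for i in range(L):
            self.enc.append(_Block(rng, c_prev, widths[i], (3, 3, 3), config.use_residual))
            c_prev = widths[i]
        self.bottleneck = _Block(rng, c_prev, widths[L], (3, 3, 3), config.use_residual)

        self.collapses = [AxialCollapse(rng, widths[i], config.use_attention)
                          for i in range(L)]
        self.collapse_bottom = AxialCollapse(rng, widths[L], config.use_attention)

        self.gates: list[Optional[AttentionGate2D]] = []
        self.dec: list[_Block] = []
        for i in reversed(range(L)):
            c_gate = widths[i + 1]
            gate = AttentionGate2D(rng, widths[i], c_gate) if config.use_attention else None
            self.gates.append(gate)
            c_in = widths[i + 1] + widths[i]
            if i == 0 and config.in_channels == 2:
                c_in += 1  # nIR enters the finest decoder level
            self.dec.append(_Block(rng, c_in, widths[i], (3, 3), config.use_residual))
        self.final = _Conv(rng, widths[0], 1, (1, 1))
        # bias at the foreground-prior logit: GA typically covers ~10-15 %
        # of the field, and starting near that prior shortens the early
        # all-background phase of training considerably
        self.final.b.data[:] = -2.0

    # -- forward -----------------------------------------------------------

    def forward_batch(self, vol: np.ndarray, nir: Optional[np.ndarray] = None) -> Tensor:
        """Forward a batch; returns logits of shape (N, X, Y).

        ``vol``: (N, 1, Z, X, Y) float32; ``nir``: (N, 1, X, Y) or None.
        """
        cfg = self.config
        if vol.ndim != 5 or vol.shape[1] != 1 or vol.shape[2:] != tuple(cfg.input_dims):
            raise ShapeError(
                f"expected volume batch (N, 1, {cfg.input_dims}), got {vol.shape}"
            )
        if (nir is not None) != (cfg.in_channels == 2):
            raise ShapeError("nIR input must be present iff in_channels == 2")
        if nir is not None and nir.shape[2:] != cfg.mask_dims:
            raise ShapeError(
                f"nIR batch must be (N, 1, {cfg.mask_dims}), got {nir.shape}"
            )

        h = Tensor(vol)
        skips2d: list[Tensor] = []
        for i, blk in enumerate(self.enc):
            h = blk(h)
            skips2d.append(self.collapses[i](h))
            h = ag.avg_pool3d(h, (self.z_factors[i], 2, 2))
        h = self.bottleneck(h)
        d = self.collapse_bottom(h)

        L = self.config.levels
        for j, (gate, blk) in enumerate(zip(self.gates, self.dec)):
            i = L - 1 - j
            d = ag.upsample2d(d)
            skip = skips2d[i]
            gated = gate(skip, d) if gate is not None else skip
            parts = [d, gated]
            if i == 0 and nir is not None:
                parts.append(Tensor(nir))
            d = blk(ag.concat(parts, axis=1))
        logits = self.final(d)  # (N, 1, X, Y)
        out_data = logits.data[:, 0]

        def bwd(g):
            logits._accum(g[:, None])

        return Tensor(out_data, _parents=(logits,), _bwd=bwd)

    def predict_proba(self, volume: np.ndarray, nir: Optional[np.ndarray] = None) -> ProbMask:
        """Inference on a single subsampled, normalized volume (z, x, y)."""
        v = np.asarray(volume, np.float32)[None, None]
        n = None if nir is None else np.asarray(nir, np.float32)[None, None]
        logits = self.forward_batch(v, n)
        return ProbMask(grid=1.0 / (1.0 + np.exp(-logits.data[0])))

    # -- utilities ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ConfigError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], np.float32)
            if arr.shape != p.data.shape:
                raise ConfigError(f"checkpoint shape mismatch at parameter {i}")
            p.data = arr.copy()

    def zero_final_layer(self) -> None:
        """Zero the output convolution, forcing probability 0.5 everywhere."""
        self.final.w.data[:] = 0.0
        self.final.b.data[:] = 0.0

    def checksum(self) -> float:
        """Sum of all parameter values — cheap identity fingerprint."""
        return float(sum(float(p.data.sum()) for p in self.parameters()))


def build(config: NetConfig) -> Net3D2D:
    """Construct the network with deterministic initialization under config.seed."""
    return Net3D2D(config)


def save_checkpoint(net: Net3D2D, path: Union[str, Path]) -> None:
    """Single-file checkpoint: NetConfig JSON header + parameter arrays."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(net.config)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(cfg))
        buf = _stdio.BytesIO()
        np.savez(buf, **net.state_dict())
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path: Union[str, Path]) -> Net3D2D:
    path = Path(path)
    with zipfile.ZipFile(path, "r") as zf:
        cfg = json.loads(zf.read("config.json"))
        cfg["input_dims"] = tuple(cfg["input_dims"])
        with zf.open("params.npz") as fh:
            state = dict(np.load(_stdio.BytesIO(fh.read())))
    net = Net3D2D(NetConfig(**cfg))
    net.load_state_dict(state)
    return net
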