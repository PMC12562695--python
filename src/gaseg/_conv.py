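"""Convolution compute kernels.

Three interchangeable execution paths for 3D 'same' convolution with 3x3x3
kernels, selected per call site by shape:

* a direct numba kernel that keeps the weight tensor in L1 and vectorizes
  along the contiguous B-scan axis — best at full-resolution stages, where
  channel counts are small and rows are long;
* a shifted-GEMM path: the padded volume is flattened with a zeroed guard
  margin so that each of the 27 kernel offsets is a plain contiguous view,
  and the convolution becomes 27 accumulated (O x C) @ (C x P) matmuls —
  best at deep stages, whose feature maps are small enough to stay
  cache-resident across the 27 passes;
* a batched-matmul path for 1x1 kernels.

All kernels operate on float32 and implement stride-1, zero-padded ('same')
convolution; the network only ever uses kernel sizes 1 and 3.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# shift-GEMM is used when one sample's padded in+out feature maps fit here
_SHIFT_MAX_BYTES = 8 * 1024 * 1024


@njit(cache=True, fastmath=True)
def _nb_conv3d_k3(xp, w, out):  # pragma: no cover - compiled
    """out[n,o,z,x,y] += sum_{c,dz,dx,dy} w[o,c,dz,dx,dy] * xp[n,c,z+dz,x+dx,y+dy].

    xp is pre-padded by 1 voxel per spatial axis; out must be zero-filled.
    """
    N, O, Z, X, Y = out.shape
    C = w.shape[1]
    acc = np.empty((O, Y), np.float32)
    for n in range(N):
        for z in range(Z):
            for x in range(X):
                acc[:] = 0.0
                for c in range(C):
                    for dz in range(3):
                        for dx in range(3):
                            row = xp[n, c, z + dz, x + dx]
                            for o in range(O):
                                w0 = w[o, c, dz, dx, 0]
                                w1 = w[o, c, dz, dx, 1]
                                w2 = w[o, c, dz, dx, 2]
                                a = acc[o]
                                for y in range(Y):
                                    a[y] += w0 * row[y] + w1 * row[y + 1] + w2 * row[y + 2]
                for o in range(O):
                    out[n, o, z, x, :] = acc[o]


@njit(cache=True, fastmath=True)
def _nb_conv3d_dw_k3(xp, go, dw):  # pragma: no cover - compiled
    """dw[o,c,dz,dx,dy] += sum_{n,z,x,y} go[n,o,z,x,y] * xp[n,c,z+dz,x+dx,y+dy]."""
    N, O, Z, X, Y = go.shape
    C = xp.shape[1]
    for n in range(N):
        for z in range(Z):
            for x in range(X):
                for c in range(C):
                    for dz in range(3):
                        for dx in range(3):
                            row = xp[n, c, z + dz, x + dx]
                            for o in range(O):
                                g = go[n, o, z, x]
                                s0 = np.float32(0.0)
                                s1 = np.float32(0.0)
                                s2 = np.float32(0.0)
                                for y in range(Y):
                                    s0 += g[y] * row[y]
                                    s1 += g[y] * row[y + 1]
                                    s2 += g[y] * row[y + 2]
                                dw[o, c, dz, dx, 0] += s0
                                dw[o, c, dz, dx, 1] += s1
                                dw[o, c, dz, dx, 2] += s2


def _pad_spatial(x: np.ndarray, pad: int = 1) -> np.ndarray:
    """Zero padding of the spatial axes of (N, C, *S); faster than np.pad."""
    N, C = x.shape[:2]
    S = x.shape[2:]
    out = np.zeros((N, C) + tuple(s + 2 * pad for s in S), np.float32)
    inner = (slice(None), slice(None)) + (slice(pad, -pad),) * len(S)
    out[inner] = x
    return out


def _matmul_1x1(w2: np.ndarray, x: np.ndarray) -> np.ndarray:
    """(O, C) applied channel-wise to (N, C, *S) via batched matmul."""
    N, C = x.shape[:2]
    S = x.shape[2:]
    out = np.matmul(w2[None], x.reshape(N, C, -1))
    return out.reshape((N, w2.shape[0]) + S)


# -- shift-GEMM helpers ------------------------------------------------------


def _shift_geometry(S: tuple[int, ...]):
    Zp, Xp, Yp = (s + 2 for s in S)
    Pp = Zp * Xp * Yp
    guard = Xp * Yp + Yp + 1  # largest |offset|
    shifts = [
        (dz * Xp + dx) * Yp + dy
        for dz in (-1, 0, 1) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
    ]
    return (Zp, Xp, Yp), Pp, guard, shifts


def _pack_guarded(x: np.ndarray) -> np.ndarray:
    """(N, C, *S) -> (N, C, G + Pp + G) flat, zero pad and guard."""
    N, C = x.shape[:2]
    S = x.shape[2:]
    (Zp, Xp, Yp), Pp, G, _ = _shift_geometry(S)
    xg = np.zeros((N, C, G + Pp + G), np.float32)
    view = xg[:, :, G:G + Pp].reshape(N, C, Zp, Xp, Yp)
    view[:, :, 1:-1, 1:-1, 1:-1] = x
    return xg


def _shift_conv(xg: np.ndarray, w: np.ndarray, S: tuple[int, ...]) -> np.ndarray:
    """Convolution of a guarded flat input with w (O, C, 3, 3, 3)."""
    N, C = xg.shape[0], xg.shape[1]
    O = w.shape[0]
    _, Pp, G, shifts = _shift_geometry(S)
    wk = np.ascontiguousarray(w.reshape(O, C, 27).transpose(2, 0, 1))
    outp = np.zeros((N, O, Pp), np.float32)
    tmp = np.empty((O, Pp), np.float32)
    for n in range(N):
        xn = xg[n]
        on = outp[n]
        for k, s in enumerate(shifts):
            np.matmul(wk[k], xn[:, G + s:G + s + Pp], out=tmp)
            on += tmp
    Zp, Xp, Yp = (s + 2 for s in S)
    out = outp.reshape(N, O, Zp, Xp, Yp)[:, :, 1:-1, 1:-1, 1:-1]
    return np.ascontiguousarray(out)


def _shift_conv_dw(xg: np.ndarray, go: np.ndarray, w_shape) -> np.ndarray:
    """dW for the shift-GEMM path; go is the unpadded upstream gradient."""
    O, C = w_shape[0], w_shape[1]
    S = go.shape[2:]
    N = go.shape[0]
    _, Pp, G, shifts = _shift_geometry(S)
    gop = _pack_guarded(go)[:, :, G:G + Pp]  # padded grid, no guard needed
    dwk = np.zeros((27, O, C), np.float32)
    for n in range(N):
        gn = gop[n]
        xn = xg[n]
        for k, s in enumerate(shifts):
            dwk[k] += gn @ xn[:, G + s:G + s + Pp].T
    return np.ascontiguousarray(dwk.transpose(1, 2, 0)).reshape(w_shape)


def _mode_3d(C: int, O: int, S: tuple[int, ...]) -> str:
    _, Pp, _, _ = _shift_geometry(S)
    if C >= 2 and (C + O) * Pp * 4 <= _SHIFT_MAX_BYTES:
        return "shift"
    return "direct"


def conv3d_forward(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, dict]:
    """3D 'same' convolution; returns (out, cache-for-backward)."""
    N, C = x.shape[:2]
    S = x.shape[2:]
    O = w.shape[0]
    if w.shape[2:] == (1, 1, 1):
        return _matmul_1x1(w.reshape(O, C), x), {"mode": "gemm1"}
    assert w.shape[2:] == (3, 3, 3), "only 1x1x1 and 3x3x3 kernels supported"
    mode = _mode_3d(C, O, S)
    if mode == "direct":
        xp = _pad_spatial(x)
        out = np.zeros((N, O) + S, np.float32)
        _nb_conv3d_k3(xp, w, out)
        return out, {"mode": "direct", "xp": xp}
    xg = _pack_guarded(x)
    out = _shift_conv(xg, w, S)
    return out, {"mode": "shift", "xg": xg}


def conv3d_backward(
    x: np.ndarray, w: np.ndarray, go: np.ndarray, cache: dict, need_dx: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    """Gradients (dw, dx) of conv3d_forward given upstream gradient go."""
    N, C = x.shape[:2]
    S = x.shape[2:]
    O = w.shape[0]
    go = np.ascontiguousarray(go, dtype=np.float32)
    mode = cache["mode"]
    if mode == "gemm1":
        gof = go.reshape(N, O, -1)
        xf = x.reshape(N, C, -1)
        dw = np.einsum("nop,ncp->oc", gof, xf, optimize=True).reshape(w.shape)
        dx = None
        if need_dx:
            dx = _matmul_1x1(w.reshape(O, C).T, go).reshape(x.shape)
        return dw, dx
    # transposed convolution = convolution with channel-swapped, flipped kernel
    wt = None
    if need_dx:
        wt = np.ascontiguousarray(w.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1])
    if mode == "direct":
        dw = np.zeros_like(w)
        _nb_conv3d_dw_k3(cache["xp"], go, dw)
        dx = None
        if need_dx:
            gop = _pad_spatial(go)
            dx = np.zeros_like(x)
            _nb_conv3d_k3(gop, wt, dx)
        return dw, dx
    # shift-GEMM
    xg = cache["xg"]
    dw = _shift_conv_dw(xg, go, w.shape)
    dx = None
    if need_dx:
        gog = _pack_guarded(go)
        dx = _shift_conv(gog, wt, S)
    return dw, dx


# -- fused axial attention-collapse kernels ---------------------------------


@njit(cache=True, fastmath=True)
def _nb_wsum_fwd(xd, a, out):  # pragma: no cover - compiled
    """out[n,c,x,y] = sum_z xd[n,c,z,x,y] * a[n,z,x,y]."""
    N, C, Z, X, Y = xd.shape
    for n in range(N):
        for c in range(C):
            for x in range(X):
                acc = out[n, c, x]
                acc[:] = 0.0
                for z in range(Z):
                    row = xd[n, c, z, x]
                    arow = a[n, z, x]
                    for y in range(Y):
                        acc[y] += row[y] * arow[y]


@njit(cache=True, fastmath=True)
def _nb_wsum_dx(a, g, dx):  # pragma: no cover - compiled
    """dx[n,c,z,x,y] = g[n,c,x,y] * a[n,z,x,y]."""
    N, C, Z, X, Y = dx.shape
    for n in range(N):
        for c in range(C):
            for z in range(Z):
                for x in range(X):
                    grow = g[n, c, x]
                    arow = a[n, z, x]
                    drow = dx[n, c, z, x]
                    for y in range(Y):
                        drow[y] = grow[y] * arow[y]


@njit(cache=True, fastmath=True)
def _nb_wsum_da(xd, g, da):  # pragma: no cover - compiled
    """da[n,z,x,y] = sum_c xd[n,c,z,x,y] * g[n,c,x,y]."""
    N, C, Z, X, Y = xd.shape
    for n in range(N):
        for z in range(Z):
            for x in range(X):
                acc = da[n, z, x]
                acc[:] = 0.0
                for c in range(C):
                    row = xd[n, c, z, x]
                    grow = g[n, c, x]
                    for y in range(Y):
                        acc[y] += row[y] * grow[y]


# ---------------------------------------------------------------------------
# 2D convolution (decoder path): pure NumPy offset-loop; cost is negligible
# next to the 3D encoder, so clarity wins over speed here.
# ---------------------------------------------------------------------------


def conv2d_forward(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    N, C = x.shape[:2]
    S = x.shape[2:]
    O = w.shape[0]
    K = w.shape[2:]
    if K == (1, 1):
        return _matmul_1x1(w.reshape(O, C), x)
    xf = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(C, -1)
    G = w.reshape(O, C, -1)
    opad = np.zeros((O, N) + tuple(s + k - 1 for s, k in zip(S, K)), np.float32)
    for fi, kk in enumerate(np.ndindex(*K)):
        y = (G[:, :, fi] @ xf).reshape((O, N) + S)
        sl = (slice(None), slice(None)) + tuple(
            slice(k - 1 - o, k - 1 - o + s) for k, o, s in zip(K, kk, S)
        )
        opad[sl] += y
    ctr = (slice(None), slice(None)) + tuple(
        slice(k // 2, k // 2 + s) for k, s in zip(K, S)
    )
    return np.ascontiguousarray(opad[ctr].transpose(1, 0, 2, 3))


def conv2d_backward(
    x: np.ndarray, w: np.ndarray, go: np.ndarray, need_dx: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    N, C = x.shape[:2]
    S = x.shape[2:]
    O = w.shape[0]
    K = w.shape[2:]
    go = np.ascontiguousarray(go, dtype=np.float32)
    if K == (1, 1):
        gof = go.reshape(N, O, -1)
        xf = x.reshape(N, C, -1)
        dw = np.einsum("nop,ncp->oc", gof, xf, optimize=True).reshape(w.shape)
        dx = None
        if need_dx:
            dx = _matmul_1x1(w.reshape(O, C).T, go).reshape(x.shape)
        return dw, dx
    pads = [(k // 2, k // 2) for k in K]
    xp = np.pad(x, [(0, 0), (0, 0)] + pads)
    gof = np.ascontiguousarray(go.transpose(1, 0, 2, 3)).reshape(O, -1)
    dw = np.empty_like(w)
    for fi, kk in enumerate(np.ndindex(*K)):
        sl = (slice(None), slice(None)) + tuple(
            slice(o, o + s) for o, s in zip(kk, S)
        )
        xsl = np.ascontiguousarray(xp[sl].transpose(1, 0, 2, 3)).reshape(C, -1)
        dw.reshape(O, C, -1)[:, :, fi] = gof @ xsl.T
    dx = None
    if need_dx:
        wflip = np.ascontiguousarray(w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dx = conv2d_forward(go, wflip)
    return dw, dx
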