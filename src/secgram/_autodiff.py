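"""Minimal tape-based reverse-mode autodiff over numpy arrays.

Just enough machinery to train the recurrent and convolutional secretion
classifiers on CPU and to expose input gradients for saliency: broadcasting
elementwise ops, 2-D matmul, the gate nonlinearities, time-slicing, 1-D
unfold (im2col) and width-2 max pooling, plus Adam with Xavier init and
L1+L2 weight penalties.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce a broadcast gradient back to the original shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad", "is_weight")

    def __init__(self, data, requires_grad: bool = False, is_weight: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.requires_grad = requires_grad
        self.is_weight = is_weight

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + (other * -1.0)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = _node(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    # -- reductions / shape -------------------------------------------------

    def sum(self) -> "Tensor":
        out = _node(self.data.sum(), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def reshape(self, *shape) -> "Tensor":
        out = _node(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


# ---------------------------------------------------------------------------
# Nonlinearities
# ---------------------------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = _node(s, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = _node(t, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - t * t))

    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    m = x.data > 0
    out = _node(x.data * m, (x,))

    def bw(g):
        if x.requires_grad:
            x._accumulate(g * m)

    out._backward = bw
    return out


def weighted_bce_with_logits(logits: Tensor, y: np.ndarray, w: np.ndarray) -> Tensor:
    """Mean weighted binary cross-entropy on raw logits (numerically stable).

    loss_i = w_i * (softplus(z_i) - y_i * z_i); dL/dz_i = w_i (sigma(z_i) - y_i) / n.
    """
    z = logits.data.ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    w = np.asarray(w, dtype=np.float64).ravel()
    n = z.size
    softplus = np.logaddexp(0.0, z)
    val = float(np.mean(w * (softplus - y * z)))
    out = _node(np.asarray(val), (logits,))

    def bw(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accumulate((g * w * (p - y) / n).reshape(logits.data.shape))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Structured ops
# ---------------------------------------------------------------------------

def select_time(x: Tensor, t: int) -> Tensor:
    """x[:, t, :] with gradient scatter back into the 3-D input."""
    out = _node(x.data[:, t, :], (x,))

    def bw(g):
        if x.requires_grad:
            if x.grad is None:
                x.grad = np.zeros_like(x.data)
            x.grad[:, t, :] += g

    out._backward = bw
    return out


def unfold1d(x: Tensor, k: int, pad: int) -> Tensor:
    """im2col for 1-D convolution: (B, L, C) -> (B, L_out, k*C)."""
    B, L, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (0, 0)))
    L_out = L + 2 * pad - k + 1
    cols = np.concatenate([xp[:, i : i + L_out, :] for i in range(k)], axis=2)
    out = _node(cols, (x,))

    def bw(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                gxp[:, i : i + L_out, :] += g[:, :, i * C : (i + 1) * C]
            x._accumulate(gxp[:, pad : pad + L, :] if pad else gxp)

    out._backward = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """Width-2 max pooling along the length axis of (B, L, C); odd tails drop."""
    B, L, C = x.data.shape
    L2 = L // 2
    xr = x.data[:, : 2 * L2, :].reshape(B, L2, 2, C)
    arg = xr.argmax(axis=2)
    out = _node(xr.max(axis=2), (x,))

    def bw(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gr = gx[:, : 2 * L2, :].reshape(B, L2, 2, C)
            b_idx, l_idx, c_idx = np.ogrid[:B, :L2, :C]
            gr[b_idx, l_idx, arg, c_idx] = g
            x._accumulate(gx)

    out._backward = bw
    return out


def gru_layer(X: Tensor, mask: np.ndarray, params: dict, layer: int) -> Tensor:
    """Full GRU layer over a (B, T, d) input: fused forward + analytic BPTT.

    Implements, per step,
        z = sigmoid(x W_z + h U_z + b_z)
        r = sigmoid(x W_r + h U_r + b_r)
        h' = tanh(x W_h + (r * h) U_h + b_h)
        h_new = (1 - z) * h + z * h'
    with the state held (h_out = h) wherever mask is 0, and returns the whole
    hidden sequence (B, T, H). One tape node per layer keeps the graph small
    enough to train at scale on CPU.
    """
    Wz, Uz, bz = params[f"W_z{layer}"], params[f"U_z{layer}"], params[f"b_z{layer}"]
    Wr, Ur, br = params[f"W_r{layer}"], params[f"U_r{layer}"], params[f"b_r{layer}"]
    Wh, Uh, bh = params[f"W_h{layer}"], params[f"U_h{layer}"], params[f"b_h{layer}"]
    Xd = X.data
    B, T, d = Xd.shape
    H = Wz.data.shape[1]
    h = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    Zs = np.empty((B, T, H)); Rs = np.empty((B, T, H)); Ts = np.empty((B, T, H))
    Hprev = np.empty((B, T, H))
    # precompute all input projections in one big matmul each
    Xf = Xd.reshape(B * T, d)
    AZx = (Xf @ Wz.data).reshape(B, T, H) + bz.data
    ARx = (Xf @ Wr.data).reshape(B, T, H) + br.data
    AHx = (Xf @ Wh.data).reshape(B, T, H) + bh.data
    for t in range(T):
        m = mask[:, t : t + 1]
        z = 1.0 / (1.0 + np.exp(-np.clip(AZx[:, t] + h @ Uz.data, -60, 60)))
        r = 1.0 / (1.0 + np.exp(-np.clip(ARx[:, t] + h @ Ur.data, -60, 60)))
        ht = np.tanh(AHx[:, t] + (r * h) @ Uh.data)
        h_new = (1.0 - z) * h + z * ht
        Hprev[:, t] = h
        h = m * h_new + (1.0 - m) * h
        Zs[:, t], Rs[:, t], Ts[:, t] = z, r, ht
        Hs[:, t] = h

    parents = (X, Wz, Uz, bz, Wr, Ur, br, Wh, Uh, bh)
    out = _node(Hs, parents)

    def bw(G):
        dWz = np.zeros_like(Wz.data); dUz = np.zeros_like(Uz.data); dbz = np.zeros_like(bz.data)
        dWr = np.zeros_like(Wr.data); dUr = np.zeros_like(Ur.data); dbr = np.zeros_like(br.data)
        dWh = np.zeros_like(Wh.data); dUh = np.zeros_like(Uh.data); dbh = np.zeros_like(bh.data)
        dX = np.zeros_like(Xd) if X.requires_grad else None
        carry = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            m = mask[:, t : t + 1]
            g = G[:, t] + carry
            dh_new = g * m
            dh = g * (1.0 - m)  # held-state path
            z, r, ht, hp = Zs[:, t], Rs[:, t], Ts[:, t], Hprev[:, t]
            x = Xd[:, t]
            dz = dh_new * (ht - hp)
            dht = dh_new * z
            dh += dh_new * (1.0 - z)
            da_h = dht * (1.0 - ht * ht)
            dWh += x.T @ da_h; dbh += da_h.sum(axis=0); dUh += (r * hp).T @ da_h
            drh = da_h @ Uh.data.T
            dh += drh * r
            da_r = (drh * hp) * r * (1.0 - r)
            dWr += x.T @ da_r; dUr += hp.T @ da_r; dbr += da_r.sum(axis=0)
            dh += da_r @ Ur.data.T
            da_z = dz * z * (1.0 - z)
            dWz += x.T @ da_z; dUz += hp.T @ da_z; dbz += da_z.sum(axis=0)
            dh += da_z @ Uz.data.T
            if dX is not None:
                dX[:, t] = da_z @ Wz.data.T + da_r @ Wr.data.T + da_h @ Wh.data.T
            carry = dh
        for p, dp in ((Wz, dWz), (Uz, dUz), (bz, dbz), (Wr, dWr), (Ur, dUr),
                      (br, dbr), (Wh, dWh), (Uh, dUh), (bh, dbh)):
            if p.requires_grad:
                p._accumulate(dp.reshape(p.data.shape))
        if dX is not None:
            X._accumulate(dX)

    out._backward = bw
    return out


def lstm_layer(X: Tensor, mask: np.ndarray, params: dict, layer: int) -> Tensor:
    """Full LSTM layer over (B, T, d), fused like ``gru_layer``."""
    Wi, Ui, bi = params[f"W_i{layer}"], params[f"U_i{layer}"], params[f"b_i{layer}"]
    Wf, Uf, bf = params[f"W_f{layer}"], params[f"U_f{layer}"], params[f"b_f{layer}"]
    Wo, Uo, bo = params[f"W_o{layer}"], params[f"U_o{layer}"], params[f"b_o{layer}"]
    Wc, Uc, bc = params[f"W_c{layer}"], params[f"U_c{layer}"], params[f"b_c{layer}"]
    Xd = X.data
    B, T, d = Xd.shape
    H = Wi.data.shape[1]

    def sig(a):
        return 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))

    h = np.zeros((B, H)); c = np.zeros((B, H))
    Hs = np.empty((B, T, H))
    Is = np.empty((B, T, H)); Fs = np.empty((B, T, H)); Os = np.empty((B, T, H))
    Gs = np.empty((B, T, H)); Cn = np.empty((B, T, H))
    Hp = np.empty((B, T, H)); Cp = np.empty((B, T, H))
    Xf = Xd.reshape(B * T, d)
    AI = (Xf @ Wi.data).reshape(B, T, H) + bi.data
    AF = (Xf @ Wf.data).reshape(B, T, H) + bf.data
    AO = (Xf @ Wo.data).reshape(B, T, H) + bo.data
    AC = (Xf @ Wc.data).reshape(B, T, H) + bc.data
    for t in range(T):
        m = mask[:, t : t + 1]
        i = sig(AI[:, t] + h @ Ui.data)
        f = sig(AF[:, t] + h @ Uf.data)
        o = sig(AO[:, t] + h @ Uo.data)
        g = np.tanh(AC[:, t] + h @ Uc.data)
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        Hp[:, t], Cp[:, t] = h, c
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
        Is[:, t], Fs[:, t], Os[:, t], Gs[:, t], Cn[:, t] = i, f, o, g, c_new
        Hs[:, t] = h

    parents = (X, Wi, Ui, bi, Wf, Uf, bf, Wo, Uo, bo, Wc, Uc, bc)
    out = _node(Hs, parents)

    def bw(G):
        grads = {name: np.zeros_like(p.data) for name, p in
                 (("Wi", Wi), ("Ui", Ui), ("bi", bi), ("Wf", Wf), ("Uf", Uf), ("bf", bf),
                  ("Wo", Wo), ("Uo", Uo), ("bo", bo), ("Wc", Wc), ("Uc", Uc), ("bc", bc))}
        dX = np.zeros_like(Xd) if X.requires_grad else None
        dh_carry = np.zeros((B, H)); dc_carry = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            m = mask[:, t : t + 1]
            gh = G[:, t] + dh_carry
            dh_new = gh * m
            dh_prev = gh * (1.0 - m)
            dc_new = dc_carry * m
            dc_prev = dc_carry * (1.0 - m)
            i, f, o, g, c_new = Is[:, t], Fs[:, t], Os[:, t], Gs[:, t], Cn[:, t]
            hp, cp = Hp[:, t], Cp[:, t]
            x = Xd[:, t]
            tc = np.tanh(c_new)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
            df = dc_new * cp
            dc_prev += dc_new * f
            di = dc_new * g
            dg = dc_new * i
            da_i = di * i * (1.0 - i)
            da_f = df * f * (1.0 - f)
            da_o = do * o * (1.0 - o)
            da_c = dg * (1.0 - g * g)
            for name_W, name_U, name_b, U, W, da in (
                ("Wi", "Ui", "bi", Ui, Wi, da_i), ("Wf", "Uf", "bf", Uf, Wf, da_f),
                ("Wo", "Uo", "bo", Uo, Wo, da_o), ("Wc", "Uc", "bc", Uc, Wc, da_c),
            ):
                grads[name_W] += x.T @ da
                grads[name_U] += hp.T @ da
                grads[name_b] += da.sum(axis=0)
                dh_prev += da @ U.data.T
                if dX is not None:
                    dX[:, t] += da @ W.data.T
            dh_carry, dc_carry = dh_prev, dc_prev
        for (p, name) in ((Wi, "Wi"), (Ui, "Ui"), (bi, "bi"), (Wf, "Wf"), (Uf, "Uf"),
                          (bf, "bf"), (Wo, "Wo"), (Uo, "Uo"), (bo, "bo"), (Wc, "Wc"),
                          (Uc, "Uc"), (bc, "bc")):
            if p.requires_grad:
                p._accumulate(grads[name].reshape(p.data.shape))
        if dX is not None:
            X._accumulate(dX)

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference) or p <= 0."""
    if rng is None or p <= 0:
        return x
    m = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(m)


# ---------------------------------------------------------------------------
# Initialization and optimization
# ---------------------------------------------------------------------------

def xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    """Glorot uniform: U(-a, a) with a = sqrt(6 / (fan_in + fan_out))."""
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape if shape is not None else (fan_in, fan_out))


class Adam:
    """Adam with optional L1+L2 penalties applied to weight tensors only."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, l1: float = 0.0,
                 l2: float = 0.0, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.l1 = l1
        self.l2 = l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if p.is_weight and (self.l1 or self.l2):
                g = g + self.l1 * np.sign(p.data) + 2.0 * self.l2 * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def regularization_value(params: list[Tensor], l1: float, l2: float) -> float:
    """lambda * (||theta||_1 + ||theta||_2^2) over weight tensors, for reporting."""
    tot = 0.0
    for p in params:
        if p.is_weight:
            tot += l1 * np.abs(p.data).sum() + l2 * (p.data ** 2).sum()
    return float(tot)


__all__ = [
    "Tensor",
    "sigmoid",
    "tanh",
    "relu",
    "weighted_bce_with_logits",
    "select_time",
    "unfold1d",
    "maxpool2",
    "xavier",
    "Adam",
    "regularization_value",
]
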