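"""Numpy kernels for banks of small GRU branches with analytic backprop.

A "bank" is a set of ``m`` recurrent branches trained jointly: branch j
consumes its own ``p``-channel input series, runs a standard GRU over T steps,
feeds the final hidden state through a one-hidden-layer tanh head to a scalar
branch output u_j, and the bank combines the branches additively,

    z = b + sum_j w_j * u_j,       e_j = w_j * u_j.

All three architecture variants reduce to this kernel:

* independent branches: m = n_features, p = 1 (per-feature GRUs and heads);
* shared head: as above but one head parameter set reused across branches;
* pooled GRU: m = 1, p = n_features (one GRU over the full feature vector).

GRU gate equations (update z, reset r, candidate n; biases split as in the
common "v3" formulation so the reset gate multiplies the recurrent candidate
term including its bias):

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)
    n_t = tanh(x_t Wn + bnx + r_t * (h_{t-1} Un + bnh))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

Gradients are derived by hand and verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "init_bank",
    "forward_bank",
    "backward_bank",
    "bank_logits",
    "composite_loss",
    "composite_grads",
    "AdamState",
    "sigmoid",
    "bce_with_logits",
]

GATE_KEYS = ("Wz", "Wr", "Wn", "Uz", "Ur", "Un", "bz", "br", "bnx", "bnh")


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Numerically stable mean binary cross-entropy from logits."""
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


def init_bank(
    m: int, p: int, hidden: int, head: int, seed: int, shared_head: bool = False
) -> dict:
    """Glorot-style initialization of an m-branch GRU bank; deterministic in seed."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6121]))

    def glorot(*shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    params = {
        "Wz": glorot(m, p, hidden, fan_in=p, fan_out=hidden),
        "Wr": glorot(m, p, hidden, fan_in=p, fan_out=hidden),
        "Wn": glorot(m, p, hidden, fan_in=p, fan_out=hidden),
        "Uz": glorot(m, hidden, hidden, fan_in=hidden, fan_out=hidden),
        "Ur": glorot(m, hidden, hidden, fan_in=hidden, fan_out=hidden),
        "Un": glorot(m, hidden, hidden, fan_in=hidden, fan_out=hidden),
        "bz": np.zeros((m, hidden)),
        "br": np.zeros((m, hidden)),
        "bnx": np.zeros((m, hidden)),
        "bnh": np.zeros((m, hidden)),
        # combining layer starts small so no branch dominates at init
        "w": rng.normal(0.0, 0.1, size=m),
        "b": np.zeros(1),
    }
    if shared_head:
        params["V1"] = glorot(hidden, head, fan_in=hidden, fan_out=head)
        params["c1"] = np.zeros(head)
        params["V2"] = glorot(head, fan_in=head, fan_out=1)
        params["c2"] = np.zeros(1)
    else:
        params["V1"] = glorot(m, hidden, head, fan_in=hidden, fan_out=head)
        params["c1"] = np.zeros((m, head))
        params["V2"] = glorot(m, head, fan_in=head, fan_out=1)
        params["c2"] = np.zeros(m)
    params["_shared_head"] = shared_head
    return params


def forward_bank(params: dict, X: np.ndarray, want_cache: bool = False):
    """Run the bank over X of shape (N, T, m, p).

    Returns ``(logit, u, cache)`` where ``logit`` is (N,), ``u`` is (N, m)
    branch outputs, and ``cache`` (if requested) holds what backprop needs.
    Internally states are laid out (m, N, h) so the recurrent updates are
    batched matrix products over the branch axis.
    """
    N, T, m, p = X.shape
    h = params["bz"].shape[1]
    shared = params["_shared_head"]
    Xm = np.ascontiguousarray(X.transpose(2, 1, 0, 3))  # (m, T, N, p)

    # project inputs through all gates in one shot per gate: (m, T, N, h)
    bz = params["bz"][:, None, None, :]
    xz = np.matmul(Xm, params["Wz"][:, None]) + bz
    xr = np.matmul(Xm, params["Wr"][:, None]) + params["br"][:, None, None, :]
    xn = np.matmul(Xm, params["Wn"][:, None]) + params["bnx"][:, None, None, :]

    UzT = params["Uz"].transpose(0, 2, 1)
    UrT = params["Ur"].transpose(0, 2, 1)
    UnT = params["Un"].transpose(0, 2, 1)
    bnh = params["bnh"][:, None, :]

    hs = np.zeros((T + 1, m, N, h))
    zs = np.empty((T, m, N, h))
    rs = np.empty((T, m, N, h))
    ns = np.empty((T, m, N, h))
    ss = np.empty((T, m, N, h))
    for t in range(T):
        h_prev = hs[t]
        z = sigmoid(xz[:, t] + np.matmul(h_prev, UzT))
        r = sigmoid(xr[:, t] + np.matmul(h_prev, UrT))
        s = np.matmul(h_prev, UnT) + bnh
        n = np.tanh(xn[:, t] + r * s)
        hs[t + 1] = (1.0 - z) * n + z * h_prev
        zs[t], rs[t], ns[t], ss[t] = z, r, n, s

    hT = hs[T]  # (m, N, h)
    if shared:
        a = np.tanh(np.matmul(hT, params["V1"]) + params["c1"])      # (m, N, d)
        u = a @ params["V2"] + params["c2"]                          # (m, N)
    else:
        a = np.tanh(np.matmul(hT, params["V1"]) + params["c1"][:, None, :])
        u = np.matmul(a, params["V2"][:, :, None])[:, :, 0] + params["c2"][:, None]
    u = u.T  # (N, m)
    logit = params["b"][0] + u @ params["w"]

    cache = None
    if want_cache:
        cache = {"X": Xm, "hs": hs, "zs": zs, "rs": rs, "ns": ns, "ss": ss, "a": a, "u": u}
    return logit, u, cache


def bank_logits(params: dict, X: np.ndarray):
    """Forward pass without cache; returns (logit, effects) with e_j = w_j u_j."""
    logit, u, _ = forward_bank(params, X)
    return logit, u * params["w"]


def backward_bank(params: dict, cache: dict, dlogit: np.ndarray, deffects=None) -> dict:
    """Gradients of a scalar loss with upstream grads dL/dz (N,) and
    optionally dL/de_j (N, m) for the per-branch effect terms."""
    Xm, hs = cache["X"], cache["hs"]          # Xm: (m, T, N, p); hs: (T+1, m, N, h)
    m, T, N, p = Xm.shape
    u, a = cache["u"], cache["a"]             # u: (N, m); a: (m, N, d)
    w = params["w"]
    shared = params["_shared_head"]

    de_total = np.repeat(dlogit[:, None], m, axis=1)
    if deffects is not None:
        de_total = de_total + deffects
    grads = {"w": np.einsum("nm,nm->m", de_total, u), "b": np.array([dlogit.sum()])}
    du = (de_total * w).T  # (m, N)

    if shared:
        grads["V2"] = np.einsum("mnd,mn->d", a, du)
        grads["c2"] = np.array([du.sum()])
        da_pre = (du[:, :, None] * params["V2"]) * (1.0 - a**2)
        grads["V1"] = np.einsum("mnh,mnd->hd", hs[T], da_pre)
        grads["c1"] = da_pre.sum(axis=(0, 1))
        dh = np.matmul(da_pre, params["V1"].T)
    else:
        grads["V2"] = np.einsum("mnd,mn->md", a, du)
        grads["c2"] = du.sum(axis=1)
        da_pre = (du[:, :, None] * params["V2"][:, None, :]) * (1.0 - a**2)
        grads["V1"] = np.matmul(hs[T].transpose(0, 2, 1), da_pre)
        grads["c1"] = da_pre.sum(axis=1)
        dh = np.matmul(da_pre, params["V1"].transpose(0, 2, 1))

    h = hs.shape[-1]
    dxz = np.empty((m, T, N, h))
    dxr = np.empty_like(dxz)
    dxn = np.empty_like(dxz)
    ds_all = np.empty_like(dxz)
    Uz, Ur, Un = params["Uz"], params["Ur"], params["Un"]
    for t in range(T - 1, -1, -1):
        z, r, n, s = cache["zs"][t], cache["rs"][t], cache["ns"][t], cache["ss"][t]
        h_prev = hs[t]
        dn_pre = dh * (1.0 - z) * (1.0 - n**2)
        dz_pre = dh * (h_prev - n) * z * (1.0 - z)
        dr_pre = dn_pre * s * r * (1.0 - r)
        ds = dn_pre * r
        dxz[:, t], dxr[:, t], dxn[:, t], ds_all[:, t] = dz_pre, dr_pre, dn_pre, ds
        dh = (
            dh * z
            + np.matmul(dz_pre, Uz)
            + np.matmul(dr_pre, Ur)
            + np.matmul(ds, Un)
        )
    # weight/bias gradients accumulated over all steps in single contractions;
    # hs[:T] reshaped to (m, T, N, h) time-major to align with the dx buffers
    Hprev = hs[:T].transpose(1, 0, 2, 3).reshape(m, T * N, h)
    grads["Uz"] = np.matmul(dxz.reshape(m, T * N, h).transpose(0, 2, 1), Hprev)
    grads["Ur"] = np.matmul(dxr.reshape(m, T * N, h).transpose(0, 2, 1), Hprev)
    grads["Un"] = np.matmul(ds_all.reshape(m, T * N, h).transpose(0, 2, 1), Hprev)
    grads["bz"] = dxz.sum(axis=(1, 2))
    grads["br"] = dxr.sum(axis=(1, 2))
    grads["bnx"] = dxn.sum(axis=(1, 2))
    grads["bnh"] = ds_all.sum(axis=(1, 2))
    Xflat = Xm.reshape(m, T * N, p)
    grads["Wz"] = np.matmul(Xflat.transpose(0, 2, 1), dxz.reshape(m, T * N, h))
    grads["Wr"] = np.matmul(Xflat.transpose(0, 2, 1), dxr.reshape(m, T * N, h))
    grads["Wn"] = np.matmul(Xflat.transpose(0, 2, 1), dxn.reshape(m, T * N, h))
    return grads


def composite_loss(logit, effects, y, lam: float) -> float:
    """BCE on the combined logit plus lam * mean per-branch BCE on effects.

    With lam = 0 this is plain binary cross-entropy on the combined logit;
    the branch terms couple the sub-classifiers only through the shared label.
    """
    loss = bce_with_logits(logit, y)
    if lam > 0:
        m = effects.shape[1]
        branch = np.mean(np.logaddexp(0.0, effects) - y[:, None] * effects)
        loss += lam * branch
    return float(loss)


def composite_grads(logit, effects, y, lam: float):
    """Upstream gradients (dL/dz, dL/de) of :func:`composite_loss`."""
    N, m = effects.shape
    dlogit = (sigmoid(logit) - y) / N
    deff = None
    if lam > 0:
        deff = lam * (sigmoid(effects) - y[:, None]) / (N * m)
    return dlogit, deff


def clip_grads(grads: dict, max_norm: float) -> None:
    """Scale gradients in place so their global L2 norm is at most max_norm."""
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] *= scale


# decay applies to weight matrices only, never to biases or the combining layer
_DECAYED = ("Wz", "Wr", "Wn", "Uz", "Ur", "Un", "V1", "V2")


class AdamState:
    """Adam with decoupled weight decay over a dict of parameter arrays."""

    def __init__(
        self, params: dict, lr: float = 0.01, beta1=0.9, beta2=0.999, eps=1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items() if k != "_shared_head"}
        self.v = {k: np.zeros_like(v) for k, v in params.items() if k != "_shared_head"}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k in _DECAYED:
                params[k] -= self.lr * self.weight_decay * params[k]
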