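"""Gated recurrent response models: LSTM/GRU cells, two-layer trunk, per-voxel readout.

The recurrent family predicts a voxel group's response sequence from the
feature sequence through two stacked recurrent layers followed by a linear
readout of the second layer's hidden states:

    y_hat[t] = h2[t] @ W_out.T

All voxels in a group share the recurrent trunk but own a readout row each.
Because the hidden state integrates the stimulus history, the network can
learn hemodynamic-like temporal dependencies (and voxel-specific variations
of them) that a fixed convolution kernel cannot.

Cell equations (per time step, sigmoid gates):

    LSTM:  o = s(U_o h' + W_o x + b_o)      GRU:  z = s(U_z h' + W_z x + b_z)
           f = s(U_f h' + W_f x + b_f)            r = s(U_r h' + W_r x + b_r)
           i = s(U_i h' + W_i x + b_i)            hb = tanh(U_h (r*h') + W_h x + b_h)
           cb = s(U_c h' + W_c x + b_c)           h = (1-z)*h' + z*hb
           c = f*c' + i*cb;  h = o*tanh(c)

The LSTM candidate ``cb`` uses a sigmoid by default (``candidate_tanh=True``
switches to the conventional tanh candidate). Training is truncated
backpropagation through time with Adam on the mean-squared-error loss,
dropout on both hidden layers' outputs, and early stopping on the validation
median correlation. Gradients are computed by hand in numpy and are verified
against finite differences in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GateParams",
    "RNNLayer",
    "RNNResponseModel",
    "TrainConfig",
    "init_model",
    "lstm_step",
    "gru_step",
    "forward",
    "train",
    "RNNDivergenceError",
]

LSTM_GATES = ("o", "f", "i", "c")
GRU_GATES = ("z", "r", "h")


class RNNDivergenceError(RuntimeError):
    """Raised when training or a forward pass produces non-finite values."""


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GateParams:
    """One gate's recurrent weights U (h x h), input weights W (h x d), bias b (h)."""

    U: np.ndarray
    W: np.ndarray
    b: np.ndarray


@dataclass
class RNNLayer:
    """A recurrent layer: cell type, size, and one GateParams per gate."""

    cell_type: str  # "LSTM" or "GRU"
    size: int
    input_dim: int
    gates: dict[str, GateParams]
    candidate_tanh: bool = False  # LSTM candidate nonlinearity: sigmoid unless set

    def __post_init__(self):
        expected = LSTM_GATES if self.cell_type == "LSTM" else GRU_GATES
        if self.cell_type not in ("LSTM", "GRU"):
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if tuple(self.gates) != expected:
            raise ValueError(f"{self.cell_type} layer needs gates {expected}, got {tuple(self.gates)}")


@dataclass
class RNNResponseModel:
    """Two recurrent layers shared by a voxel group, plus a per-voxel linear readout."""

    layer1: RNNLayer
    layer2: RNNLayer
    W_out: np.ndarray  # (m x h2)
    group: str = "all"

    def __post_init__(self):
        if self.layer2.input_dim != self.layer1.size:
            raise ValueError("layer2 input_dim must equal layer1 size")
        if self.W_out.shape[1] != self.layer2.size:
            raise ValueError("readout width must equal layer2 size")

    @property
    def n_voxels(self) -> int:
        return self.W_out.shape[0]

    def simulate(self, features: np.ndarray) -> np.ndarray:
        """Run the model on one feature block (T x p) -> predictions (T x m)."""
        return forward(self, features)[0]


def init_model(
    cell_type: str,
    size: int,
    n_features: int,
    n_voxels: int,
    seed: int = 0,
    candidate_tanh: bool = False,
    group: str = "all",
) -> RNNResponseModel:
    """Initialise a two-layer model: uniform(+-1/sqrt(fan_in)) weights, zero biases.

    The LSTM forget-gate bias starts at +1 so memory is open at the outset.
    """
    rng = np.random.default_rng(seed)

    def _layer(input_dim: int) -> RNNLayer:
        names = LSTM_GATES if cell_type == "LSTM" else GRU_GATES
        gates = {}
        for name in names:
            su = 1.0 / np.sqrt(size)
            sw = 1.0 / np.sqrt(input_dim)
            b = np.zeros(size)
            if cell_type == "LSTM" and name == "f":
                b += 1.0
            gates[name] = GateParams(
                U=rng.uniform(-su, su, (size, size)),
                W=rng.uniform(-sw, sw, (size, input_dim)),
                b=b,
            )
        return RNNLayer(cell_type, size, input_dim, gates, candidate_tanh)

    layer1 = _layer(n_features)
    layer2 = _layer(size)
    W_out = rng.uniform(-1.0 / np.sqrt(size), 1.0 / np.sqrt(size), (n_voxels, size))
    return RNNResponseModel(layer1, layer2, W_out, group=group)


# -- single-step cells (public, validated) -----------------------------------


def _check_finite(name: str, value: np.ndarray) -> None:
    if not np.all(np.isfinite(value)):
        raise RNNDivergenceError(f"non-finite activation in gate {name!r}")


def lstm_step(
    layer: RNNLayer, h_prev: np.ndarray, c_prev: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update; inputs may be (h,) vectors or (B, h) batches."""
    g = layer.gates
    o = _sigmoid(h_prev @ g["o"].U.T + x @ g["o"].W.T + g["o"].b)
    f = _sigmoid(h_prev @ g["f"].U.T + x @ g["f"].W.T + g["f"].b)
    i = _sigmoid(h_prev @ g["i"].U.T + x @ g["i"].W.T + g["i"].b)
    a_c = h_prev @ g["c"].U.T + x @ g["c"].W.T + g["c"].b
    cbar = np.tanh(a_c) if layer.candidate_tanh else _sigmoid(a_c)
    for name, val in (("o", o), ("f", f), ("i", i), ("c", cbar)):
        _check_finite(name, val)
    c = f * c_prev + i * cbar
    h = o * np.tanh(c)
    return h, c


def gru_step(layer: RNNLayer, h_prev: np.ndarray, x: np.ndarray) -> np.ndarray:
    """One GRU update; inputs may be (h,) vectors or (B, h) batches."""
    g = layer.gates
    z = _sigmoid(h_prev @ g["z"].U.T + x @ g["z"].W.T + g["z"].b)
    r = _sigmoid(h_prev @ g["r"].U.T + x @ g["r"].W.T + g["r"].b)
    hbar = np.tanh((r * h_prev) @ g["h"].U.T + x @ g["h"].W.T + g["h"].b)
    for name, val in (("z", z), ("r", r), ("h", hbar)):
        _check_finite(name, val)
    return (1.0 - z) * h_prev + z * hbar


# -- batched unroll with caches (training internals) -------------------------


def _layer_forward(layer: RNNLayer, X: np.ndarray, h0: np.ndarray, c0: np.ndarray | None):
    """Unroll a layer over time-major input X (K, B, d); returns H, final state, cache."""
    K, B, _ = X.shape
    g = layer.gates
    H = np.empty((K, B, layer.size))
    cache = []
    h, c = h0, c0
    if layer.cell_type == "LSTM":
        for t in range(K):
            x = X[t]
            o = _sigmoid(h @ g["o"].U.T + x @ g["o"].W.T + g["o"].b)
            f = _sigmoid(h @ g["f"].U.T + x @ g["f"].W.T + g["f"].b)
            i = _sigmoid(h @ g["i"].U.T + x @ g["i"].W.T + g["i"].b)
            a_c = h @ g["c"].U.T + x @ g["c"].W.T + g["c"].b
            cbar = np.tanh(a_c) if layer.candidate_tanh else _sigmoid(a_c)
            c_new = f * c + i * cbar
            tc = np.tanh(c_new)
            cache.append((x, h, c, o, f, i, cbar, tc))
            h, c = o * tc, c_new
            H[t] = h
        return H, (h, c), cache
    for t in range(K):
        x = X[t]
        z = _sigmoid(h @ g["z"].U.T + x @ g["z"].W.T + g["z"].b)
        r = _sigmoid(h @ g["r"].U.T + x @ g["r"].W.T + g["r"].b)
        rh = r * h
        hbar = np.tanh(rh @ g["h"].U.T + x @ g["h"].W.T + g["h"].b)
        h_new = (1.0 - z) * h + z * hbar
        cache.append((x, h, z, r, rh, hbar))
        h = h_new
        H[t] = h
    return H, (h, None), cache


def _layer_backward(layer: RNNLayer, dH: np.ndarray, cache) -> tuple[dict, np.ndarray]:
    """Backprop a layer over one window. dH is (K, B, h) upstream gradient.

    Returns (parameter gradients keyed like the layer's gates, dX (K, B, d)).
    Gradients do not flow across window boundaries (truncated BPTT).
    """
    K = dH.shape[0]
    g = layer.gates
    grads = {name: GateParams(np.zeros_like(gp.U), np.zeros_like(gp.W), np.zeros_like(gp.b))
             for name, gp in g.items()}
    dX = np.empty((K, dH.shape[1], layer.input_dim))
    dh_carry = np.zeros_like(dH[0])
    if layer.cell_type == "LSTM":
        dc_carry = np.zeros_like(dH[0])
        for t in range(K - 1, -1, -1):
            x, h_prev, c_prev, o, f, i, cbar, tc = cache[t]
            dh = dH[t] + dh_carry
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_carry
            df = dc * c_prev
            di = dc * cbar
            dcbar = dc * i
            dc_carry = dc * f
            da = {
                "o": do * o * (1.0 - o),
                "f": df * f * (1.0 - f),
                "i": di * i * (1.0 - i),
                "c": dcbar * (1.0 - cbar * cbar) if layer.candidate_tanh
                     else dcbar * cbar * (1.0 - cbar),
            }
            dh_carry = np.zeros_like(dh)
            dx = np.zeros_like(dX[t])
            for name, d in da.items():
                grads[name].U += d.T @ h_prev
                grads[name].W += d.T @ x
                grads[name].b += d.sum(axis=0)
                dh_carry += d @ g[name].U
                dx += d @ g[name].W
            dX[t] = dx
        return grads, dX
    for t in range(K - 1, -1, -1):
        x, h_prev, z, r, rh, hbar = cache[t]
        dh = dH[t] + dh_carry
        dz = dh * (hbar - h_prev)
        dhbar = dh * z
        dh_carry = dh * (1.0 - z)
        da_h = dhbar * (1.0 - hbar * hbar)
        grads["h"].U += da_h.T @ rh
        grads["h"].W += da_h.T @ x
        grads["h"].b += da_h.sum(axis=0)
        drh = da_h @ g["h"].U
        dr = drh * h_prev
        dh_carry += drh * r
        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        for name, d in (("z", da_z), ("r", da_r)):
            grads[name].U += d.T @ h_prev
            grads[name].W += d.T @ x
            grads[name].b += d.sum(axis=0)
            dh_carry += d @ g[name].U
        dX[t] = da_z @ g["z"].W + da_r @ g["r"].W + da_h @ g["h"].W
    return grads, dX


def forward(model: RNNResponseModel, features: np.ndarray):
    """Run the model over one block (states start at zero at the block onset).

    Returns ``(predictions (T x m), h1 (T x h1), h2 (T x h2))``; the hidden
    state trajectories feed the representational analyses. Dropout is never
    applied at inference.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.layer1.input_dim:
        raise ValueError(
            f"expected (T x {model.layer1.input_dim}) features, got {X.shape}"
        )
    Xtb = X[:, None, :]  # batch of one
    h0 = np.zeros((1, model.layer1.size))
    c0 = np.zeros((1, model.layer1.size)) if model.layer1.cell_type == "LSTM" else None
    H1, _, _ = _layer_forward(model.layer1, Xtb, h0, c0)
    h0b = np.zeros((1, model.layer2.size))
    c0b = np.zeros((1, model.layer2.size)) if model.layer2.cell_type == "LSTM" else None
    H2, _, _ = _layer_forward(model.layer2, H1, h0b, c0b)
    h1 = H1[:, 0, :]
    h2 = H2[:, 0, :]
    if not np.all(np.isfinite(h2)):
        raise RNNDivergenceError("non-finite hidden states during forward pass")
    return h2 @ model.W_out.T, h1, h2


# -- training ----------------------------------------------------------------


@dataclass
class TrainConfig:
    """Hyperparameters for truncated-BPTT training with Adam.

    ``truncation`` is the BPTT window in samples; gradients never cross
    windows, but hidden states are carried forward through them. ``dropout``
    is applied to both hidden layers' outputs during training only. Batches
    are whole blocks: equal-length training blocks are stacked and advance in
    lockstep.
    """

    truncation: int = 60
    learning_rate: float = 3e-3
    dropout: float = 0.2
    max_epochs: int = 500
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    grad_clip: float = 5.0


def _named_params(model: RNNResponseModel):
    for li, layer in ((1, model.layer1), (2, model.layer2)):
        for name, gp in layer.gates.items():
            yield f"l{li}.{name}.U", gp.U
            yield f"l{li}.{name}.W", gp.W
            yield f"l{li}.{name}.b", gp.b
    yield "out.W", model.W_out


def _validation_median_r(model: RNNResponseModel, val_blocks) -> float:
    preds, obs = [], []
    for X, Y in val_blocks:
        preds.append(forward(model, X)[0])
        obs.append(np.asarray(Y, dtype=float))
    P = np.concatenate(preds)
    O = np.concatenate(obs)
    Pc = P - P.mean(axis=0)
    Oc = O - O.mean(axis=0)
    denom = np.linalg.norm(Pc, axis=0) * np.linalg.norm(Oc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->j", Pc, Oc) / denom
    r = np.where(denom > 0, r, 0.0)
    return float(np.median(r))


def train(
    model: RNNResponseModel,
    train_blocks,
    val_blocks,
    config: TrainConfig | None = None,
    seed: int = 0,
):
    """Truncated-BPTT training with Adam, dropout and early stopping.

    ``train_blocks`` / ``val_blocks`` are sequences of ``(X (T x p), Y (T x m))``
    pairs. Equal-length training blocks are stacked into one batch so the
    recurrence is advanced for all of them in lockstep. After each epoch the
    validation median Pearson correlation over voxels is recorded, and the
    parameter snapshot from the best epoch is returned (dropout off at
    inference). Raises :class:`RNNDivergenceError` if the loss becomes
    non-finite, naming the epoch.

    Returns ``(best_model, history)`` where ``history`` is a list of
    ``{"epoch", "train_loss", "val_median_r"}`` records.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(seed)
    train_blocks = [(np.asarray(X, float), np.asarray(Y, float)) for X, Y in train_blocks]
    val_blocks = [(np.asarray(X, float), np.asarray(Y, float)) for X, Y in val_blocks]

    # group equal-length blocks into time-major batches
    by_len: dict[int, list] = {}
    for X, Y in train_blocks:
        by_len.setdefault(X.shape[0], []).append((X, Y))
    batches = []
    for T in sorted(by_len):
        Xs = np.stack([X for X, _ in by_len[T]], axis=1)  # (T, B, p)
        Ys = np.stack([Y for _, Y in by_len[T]], axis=1)  # (T, B, m)
        batches.append((Xs, Ys))

    adam_m = {k: np.zeros_like(v) for k, v in _named_params(model)}
    adam_v = {k: np.zeros_like(v) for k, v in _named_params(model)}
    step = 0
    keep = 1.0 - config.dropout

    best = copy.deepcopy(model)
    best_score = -np.inf
    history = []

    for epoch in range(config.max_epochs):
        epoch_loss = 0.0
        n_windows = 0
        for Xs, Ys in batches:
            T, B, _ = Xs.shape
            h1 = np.zeros((B, model.layer1.size))
            c1 = np.zeros((B, model.layer1.size)) if model.layer1.cell_type == "LSTM" else None
            h2 = np.zeros((B, model.layer2.size))
            c2 = np.zeros((B, model.layer2.size)) if model.layer2.cell_type == "LSTM" else None
            for start in range(0, T, config.truncation):
                Xw = Xs[start : start + config.truncation]
                Yw = Ys[start : start + config.truncation]
                K = Xw.shape[0]
                H1, (h1, c1), cache1 = _layer_forward(model.layer1, Xw, h1, c1)
                if config.dropout > 0:
                    mask1 = (rng.random(H1.shape) < keep) / keep
                    D1 = H1 * mask1
                else:
                    mask1 = None
                    D1 = H1
                H2, (h2, c2), cache2 = _layer_forward(model.layer2, D1, h2, c2)
                if config.dropout > 0:
                    mask2 = (rng.random(H2.shape) < keep) / keep
                    D2 = H2 * mask2
                else:
                    mask2 = None
                    D2 = H2
                pred = D2 @ model.W_out.T  # (K, B, m)
                resid = pred - Yw
                loss = float(np.mean(resid * resid))
                if not np.isfinite(loss):
                    raise RNNDivergenceError(f"training loss diverged at epoch {epoch}")
                epoch_loss += loss
                n_windows += 1

                dpred = 2.0 * resid / resid.size
                flatD2 = D2.reshape(-1, model.layer2.size)
                dW_out = dpred.reshape(-1, model.n_voxels).T @ flatD2
                dD2 = dpred @ model.W_out
                dH2 = dD2 * mask2 if mask2 is not None else dD2
                grads2, dD1 = _layer_backward(model.layer2, dH2, cache2)
                dH1 = dD1 * mask1 if mask1 is not None else dD1
                grads1, _ = _layer_backward(model.layer1, dH1, cache1)

                grad_map = {"out.W": dW_out}
                for li, gs in ((1, grads1), (2, grads2)):
                    for name, gp in gs.items():
                        grad_map[f"l{li}.{name}.U"] = gp.U
                        grad_map[f"l{li}.{name}.W"] = gp.W
                        grad_map[f"l{li}.{name}.b"] = gp.b

                if config.grad_clip is not None:
                    total = np.sqrt(sum(float(np.sum(v * v)) for v in grad_map.values()))
                    if total > config.grad_clip:
                        scale = config.grad_clip / total
                        for v in grad_map.values():
                            v *= scale

                step += 1
                lr_t = config.learning_rate * (
                    np.sqrt(1.0 - config.beta2**step) / (1.0 - config.beta1**step)
                )
                for key, param in _named_params(model):
                    gradv = grad_map[key]
                    adam_m[key] = config.beta1 * adam_m[key] + (1 - config.beta1) * gradv
                    adam_v[key] = config.beta2 * adam_v[key] + (1 - config.beta2) * gradv**2
                    param -= lr_t * adam_m[key] / (np.sqrt(adam_v[key]) + config.eps)

        score = _validation_median_r(model, val_blocks) if val_blocks else -epoch_loss
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_windows, 1),
                "val_median_r": score if val_blocks else np.nan,
            }
        )
        if score > best_score:
            best_score = score
            best = copy.deepcopy(model)

    return best, history
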