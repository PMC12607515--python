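"""Small numpy neural networks for spectral regression.

Two architectures sized for 3-148 input wavelengths and ~160 calibration
samples: a 1-D convolutional net (one conv block, kernel 3, ReLU, flatten,
linear head; dense-only fallback below 3 features) and a bidirectional LSTM
reading the wavelength axis as a sequence in both directions, final hidden
states concatenated into a linear head.

Training follows a fixed recipe: Adam, initial learning rate 0.01 with a
piecewise decay of x0.2 every 100 epochs, L2 coefficient 0.01 on the
weights, global gradient-norm clipping at 1, at most 5000 epochs with
early stopping on a training-loss plateau.  Everything is seeded and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrainConfig", "learning_rate_at", "CnnRegressor", "BiLstmRegressor"]


@dataclass
class TrainConfig:
    max_epochs: int = 5000
    lr0: float = 0.01
    decay_factor: float = 0.2
    decay_every: int = 100
    l2: float = 0.01
    grad_clip: float = 1.0
    patience: int = 200
    seed: int = 0


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-constant schedule: lr0 * decay^floor(epoch / decay_every)."""
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_global(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for k in grads:
            grads[k] *= scale


class _BaseNet:
    """Shared trainer: standardizes X per feature and y, runs Adam with the
    configured schedule, early-stops on a training-loss plateau and restores
    the best parameters."""

    weight_keys: tuple[str, ...] = ()  # keys subject to L2

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        self.params: dict[str, np.ndarray] = {}
        self.epochs_run = 0

    # subclasses: _init_params(rng, n_features), _forward(X) -> (yhat, cache),
    # _backward(cache, dyhat) -> grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaseNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one feature")
        self._x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._x_sd = np.where(sd == 0, 1.0, sd)
        self._y_mean = y.mean()
        ysd = y.std()
        self._y_sd = ysd if ysd > 0 else 1.0
        Xs = (X - self._x_mean) / self._x_sd
        ys = (y - self._y_mean) / self._y_sd

        rng = np.random.default_rng(self.cfg.seed)
        self._init_params(rng, X.shape[1])
        opt = _Adam(self.params)
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stale = 0
        n = X.shape[0]
        for epoch in range(self.cfg.max_epochs):
            yhat, cache = self._forward(Xs)
            resid = yhat - ys
            loss = float((resid**2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            if loss < best_loss - 1e-12:
                best_loss = loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= self.cfg.patience:
                    break
            dyhat = 2.0 * resid / n
            grads = self._backward(cache, dyhat)
            for k in self.weight_keys:
                grads[k] = grads[k] + self.cfg.l2 * self.params[k]
            _clip_global(grads, self.cfg.grad_clip)
            opt.step(self.params, grads, learning_rate_at(epoch, self.cfg))
            self.epochs_run = epoch + 1
        self.params = best_params
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self._x_mean) / self._x_sd
        yhat, _ = self._forward(Xs)
        return yhat * self._y_sd + self._y_mean


class CnnRegressor(_BaseNet):
    """1-D CNN: conv(1 -> channels, kernel 3, valid) -> ReLU -> flatten ->
    linear head.  Below 3 features the conv is replaced by a dense ReLU
    layer of the same width."""

    def __init__(self, cfg: TrainConfig, channels: int = 8):
        super().__init__(cfg)
        self.channels = channels

    def _init_params(self, rng: np.random.Generator, p: int) -> None:
        C = self.channels
        self.p = p
        self.conv_mode = p >= 3
        if self.conv_mode:
            L = p - 2
            self.params = {
                "Wc": rng.normal(0, np.sqrt(2.0 / 3), size=(C, 3)),
                "bc": np.zeros(C),
                "Wo": np.zeros(C * L),
                "bo": np.zeros(1),
            }
        else:
            self.params = {
                "Wc": rng.normal(0, np.sqrt(2.0 / p), size=(p, C)),
                "bc": np.zeros(C),
                "Wo": np.zeros(C),
                "bo": np.zeros(1),
            }
        self.weight_keys = ("Wc", "Wo")

    def _forward(self, X: np.ndarray):
        P = self.params
        if self.conv_mode:
            n, p = X.shape
            L = p - 2
            # windows: (n, L, 3)
            win = np.lib.stride_tricks.sliding_window_view(X, 3, axis=1)
            z = np.einsum("nlk,ck->nlc", win, P["Wc"]) + P["bc"]  # (n, L, C)
            a = np.maximum(z, 0.0)
            flat = a.reshape(n, -1)  # (n, L*C)
            yhat = flat @ P["Wo"] + P["bo"][0]
            return yhat, (X, win, z, a, flat)
        z = X @ P["Wc"] + P["bc"]
        a = np.maximum(z, 0.0)
        yhat = a @ P["Wo"] + P["bo"][0]
        return yhat, (X, None, z, a, a)

    def _backward(self, cache, dyhat: np.ndarray):
        P = self.params
        X, win, z, a, flat = cache
        dflat = np.outer(dyhat, P["Wo"])
        gWo = flat.T @ dyhat
        gbo = np.array([dyhat.sum()])
        if self.conv_mode:
            n = X.shape[0]
            da = dflat.reshape(a.shape)  # (n, L, C)
            dz = da * (z > 0)
            gWc = np.einsum("nlc,nlk->ck", dz, win)
            gbc = dz.sum(axis=(0, 1))
        else:
            dz = dflat * (z > 0)
            gWc = X.T @ dz
            gbc = dz.sum(axis=0)
        return {"Wc": gWc, "bc": gbc, "Wo": gWo, "bo": gbo}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LstmDirection:
    """One scalar-input LSTM direction with full BPTT (batch-vectorized)."""

    def __init__(self, hidden: int):
        self.H = hidden

    def init_params(self, rng: np.random.Generator, prefix: str) -> dict:
        H = self.H
        scale = 1.0 / np.sqrt(H)
        params = {
            f"{prefix}Wx": rng.normal(0, scale, size=(4 * H, 1)),
            f"{prefix}Wh": rng.normal(0, scale, size=(4 * H, H)),
            f"{prefix}b": np.zeros(4 * H),
        }
        # forget-gate bias 1: standard recipe for gradient flow at init
        params[f"{prefix}b"][H : 2 * H] = 1.0
        return params

    def forward(self, X: np.ndarray, params: dict, prefix: str):
        """X: (n, T) scalar sequence.  Returns final hidden (n, H), cache."""
        n, T = X.shape
        H = self.H
        Wx, Wh, b = params[f"{prefix}Wx"], params[f"{prefix}Wh"], params[f"{prefix}b"]
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        cache = []
        for t in range(T):
            x_t = X[:, t : t + 1]  # (n, 1)
            z = x_t @ Wx.T + h @ Wh.T + b  # (n, 4H)
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x_t, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        return h, cache

    def backward(self, dh_final: np.ndarray, cache, params: dict, prefix: str):
        H = self.H
        Wh = params[f"{prefix}Wh"]
        gWx = np.zeros_like(params[f"{prefix}Wx"])
        gWh = np.zeros_like(Wh)
        gb = np.zeros(4 * H)
        dh = dh_final
        dc = np.zeros_like(dh_final)
        for t in range(len(cache) - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            do = dh * tanh_c
            dct = dh * o * (1 - tanh_c**2) + dc
            di = dct * g
            dg = dct * i
            df = dct * c_prev
            dc = dct * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )  # (n, 4H)
            gWx += dz.T @ x_t
            gWh += dz.T @ h_prev
            gb += dz.sum(axis=0)
            dh = dz @ Wh
        return {f"{prefix}Wx": gWx, f"{prefix}Wh": gWh, f"{prefix}b": gb}


class BiLstmRegressor(_BaseNet):
    """Bidirectional LSTM over the wavelength axis.

    The forward and backward directions read the spectrum left-to-right and
    right-to-left; their final hidden states are concatenated and mapped to
    the target by a linear head.
    """

    def __init__(self, cfg: TrainConfig, hidden: int = 8):
        super().__init__(cfg)
        self.hidden = hidden
        self._fwd = _LstmDirection(hidden)
        self._bwd = _LstmDirection(hidden)

    def _init_params(self, rng: np.random.Generator, p: int) -> None:
        H = self.hidden
        self.params = {}
        self.params.update(self._fwd.init_params(rng, "f_"))
        self.params.update(self._bwd.init_params(rng, "b_"))
        self.params["Wo"] = np.zeros(2 * H)
        self.params["bo"] = np.zeros(1)
        self.weight_keys = ("f_Wx", "f_Wh", "b_Wx", "b_Wh", "Wo")

    def _forward(self, X: np.ndarray):
        hf, cache_f = self._fwd.forward(X, self.params, "f_")
        hb, cache_b = self._bwd.forward(X[:, ::-1], self.params, "b_")
        feats = np.concatenate([hf, hb], axis=1)  # (n, 2H)
        yhat = feats @ self.params["Wo"] + self.params["bo"][0]
        return yhat, (cache_f, cache_b, feats)

    def _backward(self, cache, dyhat: np.ndarray):
        cache_f, cache_b, feats = cache
        H = self.hidden
        gWo = feats.T @ dyhat
        gbo = np.array([dyhat.sum()])
        dfeats = np.outer(dyhat, self.params["Wo"])
        grads = {"Wo": gWo, "bo": gbo}
        grads.update(self._fwd.backward(dfeats[:, :H], cache_f, self.params, "f_"))
        grads.update(self._bwd.backward(dfeats[:, H:], cache_b, self.params, "b_"))
        return grads
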