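"""Trajectory gap filling with a six-layer recurrent sequence model.

The imputer is a stacked recurrent network — LSTM → dropout(0.3) → LSTM →
dropout(0.3) → dense → activation — that maps a window of the last
``window_len`` (latitude, longitude) fixes, min-max normalized to [0, 1],
to the next fix.  It is trained with an MSE loss by backpropagation
through time with Adam, implemented directly on NumPy arrays; gradients
are verified against numerical differentiation in the test suite.

Gaps are filled forward-only: a multi-hour gap is completed hour by hour,
each prediction feeding back into the input window.  Predictions are
clipped to the normalized [0, 1] box, so filled fixes can never leave the
training bounding box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import haversine_distance, EARTH_RADIUS_M

HOUR = pd.Timedelta(hours=1)


@dataclass
class ImputerConfig:
    window_len: int = 12
    hidden_units: int = 64
    dropout_p: float = 0.3
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 5e-3
    lr_decay: float = 0.97  # per-epoch multiplicative decay
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_len < 2:
            raise ValueError("window_len must be at least 2")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1 or self.hidden_units < 1:
            raise ValueError("epochs, batch_size and hidden_units must be positive")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must lie in (0, 1]")


@dataclass
class NormalizerState:
    """Per-coordinate min/max (degrees) fitted on the training fixes."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("degenerate coordinate range: max must exceed min")

    #: half-width (degrees, ~11 m) used to open up a degenerate axis
    _PAD = 1e-4

    @classmethod
    def fit(cls, fixes: pd.DataFrame) -> "NormalizerState":
        """Fit min/max per coordinate; a constant axis (e.g. a stationary
        track) is padded by ±1e-4 degrees so the mapping stays invertible."""
        lo_la, hi_la = float(fixes["lat"].min()), float(fixes["lat"].max())
        lo_lo, hi_lo = float(fixes["lon"].min()), float(fixes["lon"].max())
        if hi_la <= lo_la:
            lo_la, hi_la = lo_la - cls._PAD, hi_la + cls._PAD
        if hi_lo <= lo_lo:
            lo_lo, hi_lo = lo_lo - cls._PAD, hi_lo + cls._PAD
        return cls(lat_min=lo_la, lat_max=hi_la, lon_min=lo_lo, lon_max=hi_lo)

    def transform(self, latlon: np.ndarray) -> np.ndarray:
        out = np.empty_like(latlon, dtype=float)
        out[..., 0] = (latlon[..., 0] - self.lat_min) / (self.lat_max - self.lat_min)
        out[..., 1] = (latlon[..., 1] - self.lon_min) / (self.lon_max - self.lon_min)
        return out

    def inverse(self, z: np.ndarray) -> np.ndarray:
        out = np.empty_like(z, dtype=float)
        out[..., 0] = z[..., 0] * (self.lat_max - self.lat_min) + self.lat_min
        out[..., 1] = z[..., 1] * (self.lon_max - self.lon_min) + self.lon_min
        return out


# ---------------------------------------------------------------------------
# layers


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


class LSTMLayer:
    """Single LSTM layer over (batch, time, features) inputs.

    Gate order in the packed weight matrices is input, forget, cell, output;
    the forget-gate bias starts at 1 (standard remember-by-default init).
    """

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-k, k, size=(input_dim, 4 * hidden))
        self.Wh = rng.uniform(-k, k, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0
        self.hidden = hidden
        self._cache = None

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            a = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = cache
        return hs

    def backward(self, dh_out: np.ndarray):
        B, T, H = dh_out.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty((B, T, self.Wx.shape[0]))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dh_out[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x_t.T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        return dx, [dWx, dWh, db]


class DropoutLayer:
    """Inverted dropout, active only during training.

    On sequence inputs (batch, time, units) one mask per sequence is drawn
    and broadcast across time (variational dropout): an independent mask
    per timestep would corrupt the step-to-step differences the next
    recurrent layer needs to estimate velocity.
    """

    def __init__(self, p: float):
        self.p = p
        self._mask = None

    @property
    def params(self):
        return []

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None or self.p == 0.0:
            self._mask = None
            return x
        shape = (x.shape[0], 1, x.shape[2]) if x.ndim == 3 else x.shape
        self._mask = (rng.random(shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class DenseLayer:
    def __init__(self, input_dim: int, output_dim: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(input_dim)
        self.W = rng.uniform(-k, k, size=(input_dim, output_dim))
        self.b = np.zeros(output_dim)
        self._x = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray):
        dW = self._x.T @ dout
        db = dout.sum(axis=0)
        return dout @ self.W.T, [dW, db]


class ActivationLayer:
    """Linear output activation; predictions are clipped to [0, 1] at
    inference (normalized coordinates), keeping fills inside the training
    bounding box."""

    @property
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            mhat = m / (1.0 - self.b1**self.t)
            vhat = v / (1.0 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TrajectoryImputer:
    """The six-layer sequence model: LSTM, dropout, LSTM, dropout, dense,
    activation; input (window_len, 2), output (2,)."""

    def __init__(self, config: ImputerConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H = config.hidden_units
        self.lstm1 = LSTMLayer(2, H, rng)
        self.drop1 = DropoutLayer(config.dropout_p)
        self.lstm2 = LSTMLayer(H, H, rng)
        self.drop2 = DropoutLayer(config.dropout_p)
        self.dense = DenseLayer(H, 2, rng)
        self.act = ActivationLayer()
        self.layers = [self.lstm1, self.drop1, self.lstm2, self.drop2, self.dense, self.act]
        self._train_rng = np.random.default_rng(config.seed + 1)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        rng = self._train_rng if train else None
        h = self.lstm1.forward(x)
        h = self.drop1.forward(h, rng)
        h = self.lstm2.forward(h)
        h = self.drop2.forward(h, rng)
        out = self.dense.forward(h[:, -1])
        return self.act.forward(out)

    def _backward(self, dout: np.ndarray) -> list[np.ndarray]:
        dout = self.act.backward(dout)
        dlast, dense_grads = self.dense.backward(dout)
        B, T = dout.shape[0], self.config.window_len
        dh2 = np.zeros((B, T, self.config.hidden_units))
        dh2[:, -1] = dlast
        dh2 = self.drop2.backward(dh2)
        dh1, lstm2_grads = self.lstm2.backward(dh2)
        dh1 = self.drop1.backward(dh1)
        _, lstm1_grads = self.lstm1.backward(dh1)
        return lstm1_grads + lstm2_grads + dense_grads

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, train: bool = True):
        pred = self.forward(x, train=train)
        resid = pred - y
        loss = float(np.mean(resid**2))
        grads = self._backward(2.0 * resid / resid.size)
        return loss, grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference on normalized windows; outputs clipped to [0, 1]."""
        return np.clip(self.forward(x, train=False), 0.0, 1.0)

    # ---- persistence -----------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, **{f"p{i}": p for i, p in enumerate(self.params)})

    def load(self, path) -> None:
        data = np.load(path)
        for i, p in enumerate(self.params):
            p[...] = data[f"p{i}"]


def build_imputer(config: ImputerConfig) -> TrajectoryImputer:
    """Construct the (untrained) six-layer sequence model."""
    return TrajectoryImputer(config)


# ---------------------------------------------------------------------------
# training data assembly


def _contiguous_stretches(fixes: pd.DataFrame) -> list[np.ndarray]:
    """(n, 2) lat/lon arrays of hourly-contiguous runs, per individual."""
    stretches = []
    for _, grp in fixes.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        ts = pd.to_datetime(grp["timestamp"])
        coords = grp[["lat", "lon"]].to_numpy(dtype=float)
        breaks = np.flatnonzero(ts.diff().iloc[1:].to_numpy() != HOUR.to_timedelta64()) + 1
        for part in np.split(coords, breaks):
            if len(part) > 0:
                stretches.append(part)
    return stretches


def _windows(stretches: list[np.ndarray], norm: NormalizerState, window_len: int):
    xs, ys = [], []
    for s in stretches:
        if len(s) < window_len + 1:
            continue
        z = norm.transform(s)
        for i in range(len(s) - window_len):
            xs.append(z[i : i + window_len])
            ys.append(z[i + window_len])
    if not xs:
        raise ValueError(
            f"no contiguous stretch of at least window_len+1={window_len + 1} fixes"
        )
    return np.stack(xs), np.stack(ys)


def fit_imputer(
    model: TrajectoryImputer, fixes: pd.DataFrame, config: ImputerConfig | None = None
) -> tuple[TrajectoryImputer, NormalizerState, list[float]]:
    """Train on (window → next fix) pairs from gap-free stretches.

    Returns the trained model, the fitted min-max normalizer and the
    per-epoch mean training loss (length = epochs).  Deterministic for a
    fixed config seed.
    """
    config = config or model.config
    norm = NormalizerState.fit(fixes)
    X, Y = _windows(_contiguous_stretches(fixes), norm, config.window_len)
    n = len(X)
    rng = np.random.default_rng(config.seed + 2)
    optimizer = _Adam(model.params, lr=config.learning_rate)
    history: list[float] = []
    for epoch in range(config.epochs):
        optimizer.lr = config.learning_rate * config.lr_decay**epoch
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = model.loss_and_grads(X[idx], Y[idx], train=True)
            optimizer.step(grads)
            total += loss * len(idx)
        history.append(total / n)
    return model, norm, history


# ---------------------------------------------------------------------------
# gap filling


def fill_gaps(
    model: TrajectoryImputer,
    gapped: pd.DataFrame,
    mask: pd.DataFrame,
    normalizer: NormalizerState,
) -> pd.DataFrame:
    """Predict every missing (individual, timestamp); forward-only, iterative.

    Each missing hour is predicted from the ``window_len`` fixes
    immediately preceding it (observed or previously filled) and fed back
    for the next hour.  Gaps whose history is incomplete (e.g. at the
    sequence start) are skipped with a warning and remain missing.
    Observed rows pass through untouched.
    """
    W = model.config.window_len
    if len(mask) == 0:
        return gapped.copy()
    out_parts = []
    skipped = 0
    for ind, grp in gapped.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        known: dict[pd.Timestamp, tuple[float, float, bool]] = {
            pd.Timestamp(t): (la, lo, bool(im))
            for t, la, lo, im in zip(grp["timestamp"], grp["lat"], grp["lon"], grp["imputed"])
        }
        missing = sorted(
            pd.Timestamp(t) for t in mask.loc[mask["individual_id"] == ind, "timestamp"]
        )
        for ts in missing:
            hist_ts = [ts - HOUR * k for k in range(W, 0, -1)]
            if not all(h in known for h in hist_ts):
                skipped += 1
                continue
            window = np.array([[known[h][0], known[h][1]] for h in hist_ts])
            z = normalizer.transform(window)[None, :, :]
            pred = normalizer.inverse(model.predict(z)[0])
            known[ts] = (float(pred[0]), float(pred[1]), True)
        rows = [
            (ind, ts, la, lo, im) for ts, (la, lo, im) in sorted(known.items())
        ]
        out_parts.append(
            pd.DataFrame(rows, columns=["individual_id", "timestamp", "lat", "lon", "imputed"])
        )
    if skipped:
        warnings.warn(f"{skipped} missing fixes skipped: insufficient history", stacklevel=2)
    return pd.concat(out_parts).reset_index(drop=True)


def fill_gaps_locf(gapped: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Last-observation-carried-forward baseline filler (comparison only)."""
    out_parts = []
    for ind, grp in gapped.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        missing = mask.loc[mask["individual_id"] == ind]
        add = []
        obs_ts = grp["timestamp"].to_numpy()
        for ts in pd.to_datetime(missing["timestamp"]):
            prev = grp[grp["timestamp"] < ts]
            if len(prev) == 0:
                continue
            last = prev.iloc[-1]
            add.append((ind, ts, last["lat"], last["lon"], True))
        filled = pd.concat(
            [grp, pd.DataFrame(add, columns=["individual_id", "timestamp", "lat", "lon", "imputed"])]
        ).sort_values("timestamp", kind="stable")
        out_parts.append(filled)
    return pd.concat(out_parts).reset_index(drop=True)


def evaluate_imputation(
    completed: pd.DataFrame, truth: pd.DataFrame, radius: float = EARTH_RADIUS_M
) -> dict[str, float]:
    """Great-circle error (metres) of imputed rows against the true fixes.

    Tables are aligned on (individual_id, timestamp); only rows flagged
    ``imputed`` in ``completed`` are scored.
    """
    imputed = completed[completed["imputed"]]
    if len(imputed) == 0:
        raise ValueError("no imputed rows to evaluate")
    merged = imputed.merge(
        truth[["individual_id", "timestamp", "lat", "lon"]],
        on=["individual_id", "timestamp"],
        suffixes=("", "_true"),
        validate="one_to_one",
    )
    if len(merged) != len(imputed):
        raise ValueError("truth table does not cover all imputed timestamps")
    err = haversine_distance(
        merged["lat"].to_numpy(),
        merged["lon"].to_numpy(),
        merged["lat_true"].to_numpy(),
        merged["lon_true"].to_numpy(),
        radius=radius,
    )
    err = np.atleast_1d(err)
    return {
        "n": int(len(err)),
        "mean_m": float(err.mean()),
        "median_m": float(np.median(err)),
        "max_m": float(err.max()),
    }
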