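"""Cross-body-part velocity mapping with an anti-identity regularized MLP.

A three-layer feed-forward network maps a window of one body part's angular
velocity (e.g. thorax) to the sine/cosine encoding of the other part's
velocity (e.g. head) at a possibly shifted instant. The loss

    L = Σ_t |head_enc(t) − O(t)|² / (λ |thorax_enc(t) − O(t)|² + ϵ)

penalizes the trivial identity solution (predicting the source from itself):
the denominator shrinks — and the loss blows up — exactly when the output
reproduces the source's own encoding. λ = 0.5, ϵ = 0.1.

Temporal-shift scans probe predictive causality: with shift τ < 0 the whole
observation window precedes the predicted instant (forecasting); with τ > 0
it follows it (backcasting); τ = 0 uses the centered window. Where the
correlation r(τ) between decoded prediction and target stays high tells in
which direction information flows between head and thorax.

The network, its backprop and the Adam optimizer are implemented in numpy so
training is deterministic and dependency-free.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .classifier import WindowSpec, split_flights
from .series import VelocitySeries

__all__ = [
    "MapperConfig", "MapperModel", "MapperResults", "VelocityMapper",
    "default_velocity_scale", "encode_velocity", "decode_velocity",
    "mlp_forward", "anti_identity_loss", "shift_pairs", "train_mapper",
    "unsigned_error_angle", "grid_search_mapper", "correlation_vs_shift",
    "N_GRID", "DELTA_T_GRID",
]

N_GRID = (1, 2, 4, 8, 16, 32, 64, 128)
DELTA_T_GRID = tuple(range(1, 54, 2))  # ms


def default_velocity_scale(fps: float) -> float:
    """Radians of turn per sample interval per (deg/s): the natural data-free
    way to fold a velocity into (−π, π) for the sine/cosine encoding.

    At 500 fps even 5000 deg/s maps to ≈0.17 rad, far from the ±π wrap.
    """
    return (np.pi / 180.0) / fps


@dataclass
class MapperConfig:
    """Hyper- and training parameters of the velocity mapper."""

    n_hidden: int = 32
    window_ms: float = 29.0
    fps: float = 500.0
    tau_ms: float = 0.0          # <0 forecasting, >0 backcasting
    lambda_reg: float = 0.5
    epsilon: float = 0.1
    epochs: int = 30
    seed: int = 0
    # with the radians-per-sample encoding the targets live on a ~1e-2 scale;
    # 1e-2 lets Adam traverse that landscape within the 30 training epochs
    learning_rate: float = 1e-2
    batch_size: int = 64
    velocity_scale: float | None = None  # rad-per-sample per (deg/s)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.velocity_scale is None:
            self.velocity_scale = default_velocity_scale(self.fps)

    @property
    def window(self) -> WindowSpec:
        return WindowSpec(delta_t_ms=self.window_ms, fps=self.fps)

    @property
    def tau_samples(self) -> int:
        exact = self.tau_ms * self.fps / 1000.0
        k = int(round(exact))
        if abs(exact - k) > 1e-6:
            raise ValueError(
                f"tau={self.tau_ms} ms is not a whole number of samples at "
                f"{self.fps} fps")
        return k


def encode_velocity(omega, scale: float):
    """(cos θ, sin θ) with θ = ω·scale; requires |θ| < π."""
    theta = np.asarray(omega, float) * scale
    if np.any(np.abs(theta) >= np.pi):
        bad = int(np.argmax(np.abs(theta) >= np.pi))
        raise ValueError(f"velocity out of encodable range at frame {bad}")
    return np.stack([np.cos(theta), np.sin(theta)], axis=-1)


def decode_velocity(enc, scale: float):
    """Inverse of :func:`encode_velocity`: ω = atan2(s, c)/scale (deg/s);
    insensitive to a common positive rescaling of (c, s)."""
    enc = np.asarray(enc, float)
    c, s = enc[..., 0], enc[..., 1]
    if np.any((c == 0) & (s == 0)):
        raise ValueError("cannot decode the zero vector")
    return np.arctan2(s, c) / scale


@dataclass
class MapperModel:
    """Trained network weights plus their configuration.

    Layers: input (n_samples + bias) → N relu units + bias → 2 tanh outputs
    (the (cos, sin) encoding of the predicted velocity).
    """

    config: MapperConfig
    W1: np.ndarray = field(repr=False)
    b1: np.ndarray = field(repr=False)
    W2: np.ndarray = field(repr=False)
    b2: np.ndarray = field(repr=False)
    loss_history: list = field(default_factory=list, repr=False)

    def forward(self, X: np.ndarray) -> np.ndarray:
        return mlp_forward(self, X)

    def predict_velocity(self, X: np.ndarray) -> np.ndarray:
        return decode_velocity(self.forward(X), self.config.velocity_scale)


def mlp_forward(model: MapperModel, X: np.ndarray) -> np.ndarray:
    """affine → relu → affine → tanh; returns (rows, 2) = (O_c, O_s)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.W1.shape[0]:
        raise ValueError(
            f"window length {X.shape[1]} != expected {model.W1.shape[0]}")
    H = np.maximum(X @ model.W1 + model.b1, 0.0)
    return np.tanh(H @ model.W2 + model.b2)


def anti_identity_loss(target_enc, source_enc, outputs,
                       lambda_reg: float = 0.5, epsilon: float = 0.1) -> float:
    """Σ_t |target_enc − O|² / (λ|source_enc − O|² + ϵ)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    target_enc, source_enc, outputs = (np.atleast_2d(np.asarray(a, float))
                                       for a in (target_enc, source_enc, outputs))
    if not target_enc.shape == source_enc.shape == outputs.shape:
        raise ValueError("encoding batches must share a shape")
    num = np.sum((target_enc - outputs) ** 2, axis=1)
    den = lambda_reg * np.sum((source_enc - outputs) ** 2, axis=1) + epsilon
    return float(np.sum(num / den))


def shift_pairs(source: VelocitySeries, target: VelocitySeries,
                tau_ms: float, window: WindowSpec):
    """Training pairs for a temporal shift of τ ms.

    Returns ``(X, target_omega, source_at_target)`` where row i of X is a
    source window, ``target_omega[i]`` the target velocity at the predicted
    instant and ``source_at_target[i]`` the source velocity at that same
    instant (needed by the anti-identity denominator).

    τ = 0: window centered on the predicted instant. τ < 0 (forecasting): the
    window ends |τ| samples *before* the predicted instant. τ > 0
    (backcasting): the window starts τ samples *after* it.
    """
    if len(source) != len(target):
        raise ValueError("source and target series must be aligned")
    cfg_tau = MapperConfig(window_ms=window.delta_t_ms, fps=window.fps,
                           tau_ms=tau_ms)
    k = cfg_tau.tau_samples
    n = window.n_samples
    L = len(source)
    if L < n + abs(k):
        warnings.warn("series shorter than window + shift: no pairs",
                      RuntimeWarning, stacklevel=2)
        e = np.empty(0)
        return np.empty((0, n)), e, e
    Xall = sliding_window_view(source.omega_z, n)      # start index a = row
    if k == 0:
        starts = np.arange(0, L - n + 1)
        pred = starts + window.half_width
    elif k < 0:  # forecasting: window [a, a+n-1], predict at a+n-1+|k|
        starts = np.arange(0, L - n + 1 - abs(k))
        pred = starts + n - 1 + abs(k)
    else:        # backcasting: window [a, a+n-1], predict at a-k
        starts = np.arange(k, L - n + 1)
        pred = starts - k
    return (Xall[starts].copy(), target.omega_z[pred].copy(),
            source.omega_z[pred].copy())


def unsigned_error_angle(pred_enc, target_enc) -> np.ndarray:
    """Absolute angle in [0, π] between prediction and target encodings."""
    a = np.atleast_2d(np.asarray(pred_enc, float))
    b = np.atleast_2d(np.asarray(target_enc, float))
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero vector has no direction")
    cosang = np.clip(np.sum(a * b, axis=1) / (na * nb), -1.0, 1.0)
    return np.arccos(cosang)


def _init_params(cfg: MapperConfig, n_in: int, rng: np.random.Generator):
    lim1 = 1.0 / np.sqrt(n_in)
    lim2 = 1.0 / np.sqrt(cfg.n_hidden)
    W1 = rng.uniform(-lim1, lim1, size=(n_in, cfg.n_hidden))
    b1 = rng.uniform(-lim1, lim1, size=cfg.n_hidden)
    W2 = rng.uniform(-lim2, lim2, size=(cfg.n_hidden, 2))
    b2 = rng.uniform(-lim2, lim2, size=2)
    return W1, b1, W2, b2


def train_mapper(source_flights, target_flights,
                 config: MapperConfig | None = None) -> MapperModel:
    """Train the mapper with Adam on the anti-identity loss.

    ``source_flights``/``target_flights`` are aligned lists of
    VelocitySeries; pairs are built per flight (no window crosses a flight
    boundary) with the configured τ. Deterministic given ``config.seed``.
    """
    cfg = config or MapperConfig()
    Xs, ts, ss = [], [], []
    for sv, tv in zip(source_flights, target_flights, strict=True):
        X, t_om, s_om = shift_pairs(sv, tv, cfg.tau_ms, cfg.window)
        Xs.append(X); ts.append(t_om); ss.append(s_om)
    X = np.vstack(Xs)
    if X.shape[0] == 0:
        raise ValueError("no training pairs")
    scale = cfg.velocity_scale
    T = encode_velocity(np.concatenate(ts), scale)
    S = encode_velocity(np.concatenate(ss), scale)
    Xn = X * scale  # feed encoded-scale inputs; keeps init ranges sensible

    rng = np.random.default_rng(cfg.seed)
    W1, b1, W2, b2 = _init_params(cfg, X.shape[1], rng)
    params = [W1, b1, W2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    step = 0
    history = []
    n_rows = X.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n_rows)
        epoch_loss = 0.0
        for i0 in range(0, n_rows, cfg.batch_size):
            idx = order[i0:i0 + cfg.batch_size]
            xb, tb, sb = Xn[idx], T[idx], S[idx]
            pre = xb @ params[0] + params[1]
            H = np.maximum(pre, 0.0)
            z = H @ params[2] + params[3]
            O = np.tanh(z)
            num = np.sum((tb - O) ** 2, axis=1)
            den = cfg.lambda_reg * np.sum((sb - O) ** 2, axis=1) + cfg.epsilon
            batch_loss = float(np.sum(num / den))
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite loss at step {step}: diverged "
                    f"(lr={cfg.learning_rate}, seed={cfg.seed})")
            epoch_loss += batch_loss
            # dL/dO, averaged over the batch for a size-free learning rate
            g = (2 * (O - tb) * den[:, None]
                 - num[:, None] * cfg.lambda_reg * 2 * (O - sb)) / den[:, None] ** 2
            g /= idx.size
            dz = g * (1.0 - O ** 2)
            grads = [xb.T @ ((dz @ params[2].T) * (pre > 0)),
                     np.sum((dz @ params[2].T) * (pre > 0), axis=0),
                     H.T @ dz,
                     np.sum(dz, axis=0)]
            step += 1
            for j, (p, gr) in enumerate(zip(params, grads)):
                m[j] = beta1 * m[j] + (1 - beta1) * gr
                v[j] = beta2 * v[j] + (1 - beta2) * gr * gr
                mh = m[j] / (1 - beta1 ** step)
                vh = v[j] / (1 - beta2 ** step)
                p -= cfg.learning_rate * mh / (np.sqrt(vh) + eps_adam)
        history.append(epoch_loss)
    return MapperModel(config=cfg, W1=params[0], b1=params[1],
                       W2=params[2], b2=params[3], loss_history=history)


def _predict_on(model: MapperModel, source: VelocitySeries,
                target: VelocitySeries):
    cfg = model.config
    X, t_om, s_om = shift_pairs(source, target, cfg.tau_ms, cfg.window)
    O = model.forward(X * cfg.velocity_scale)
    return O, t_om, s_om


def _eval_pairs(model, flight_pairs):
    Os, toms = [], []
    for sv, tv in flight_pairs:
        O, t_om, _ = _predict_on(model, sv, tv)
        Os.append(O); toms.append(t_om)
    O = np.vstack(Os)
    t_om = np.concatenate(toms)
    scale = model.config.velocity_scale
    err = unsigned_error_angle(O, encode_velocity(t_om, scale))
    pred_om = decode_velocity(O, scale)
    if np.std(pred_om) < 1e-12 or np.std(t_om) < 1e-12:
        r = np.nan
    else:
        r = float(np.corrcoef(pred_om, t_om)[0, 1])
    return {"median_error_angle": float(np.median(err)), "r": r,
            "n": int(t_om.size)}


def grid_search_mapper(source_flights, target_flights,
                       N_grid=N_GRID, delta_t_grid=DELTA_T_GRID,
                       base: MapperConfig | None = None):
    """(N, Δt) grid search minimizing the validation median unsigned error
    angle; ties break toward smaller N, then smaller Δt.

    Returns ``(best_config, table)``.
    """
    N_grid = list(N_grid)
    delta_t_grid = list(delta_t_grid)
    if not N_grid or not delta_t_grid:
        raise ValueError("grids must be non-empty")
    base = base or MapperConfig()
    flights = list(zip(source_flights, target_flights))
    train, val, _ = split_flights(flights)
    rows = []
    best = None
    for dt in delta_t_grid:
        for N in N_grid:
            cfg = replace(base, n_hidden=N, window_ms=dt)
            model = train_mapper([f[0] for f in train], [f[1] for f in train],
                                 cfg)
            metrics = _eval_pairs(model, val)
            rows.append({"n_hidden": N, "delta_t_ms": dt, **metrics})
            key = (metrics["median_error_angle"], N, dt)
            if best is None or key < best[0]:
                best = (key, cfg)
    return best[1], pd.DataFrame(rows)


def correlation_vs_shift(source_flights, target_flights, tau_grid_ms,
                         config: MapperConfig | None = None) -> pd.DataFrame:
    """Pearson r(τ) between decoded prediction and target on the held-out
    flight, retraining a fresh model (same seed) per τ.

    Columns: tau_ms (requested), tau_samples (realized), r,
    median_error_angle.
    """
    base = config or MapperConfig()
    flights = list(zip(source_flights, target_flights))
    train, _, test = split_flights(flights)
    rows = []
    for tau in tau_grid_ms:
        cfg = replace(base, tau_ms=tau)
        model = train_mapper([f[0] for f in train], [f[1] for f in train], cfg)
        metrics = _eval_pairs(model, test)
        if np.isnan(metrics["r"]):
            warnings.warn(f"degenerate variance at tau={tau} ms: r undefined",
                          RuntimeWarning, stacklevel=2)
        rows.append({"tau_ms": tau, "tau_samples": cfg.tau_samples, **metrics})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results façade

class VelocityMapper:
    """Model object: map one body part's velocity to another's.

    ``source_flights`` and ``target_flights`` are aligned lists of
    VelocitySeries (e.g. thorax → head). The last flight is held out; the
    first K−1 are split 70/30 into train/validation.
    """

    def __init__(self, source_flights, target_flights,
                 config: MapperConfig | None = None):
        if len(source_flights) != len(target_flights):
            raise ValueError("source and target flight lists must align")
        self.source_flights = list(source_flights)
        self.target_flights = list(target_flights)
        self.config = config or MapperConfig()

    @classmethod
    def from_flights(cls, flights, direction: str = "thorax2head",
                     config: MapperConfig | None = None):
        if direction == "thorax2head":
            src = [f.thorax_v for f in flights]
            tgt = [f.head_v for f in flights]
        elif direction == "head2thorax":
            src = [f.head_v for f in flights]
            tgt = [f.thorax_v for f in flights]
        else:
            raise ValueError("direction must be 'thorax2head' or 'head2thorax'")
        return cls(src, tgt, config)

    def fit(self) -> "MapperResults":
        flights = list(zip(self.source_flights, self.target_flights))
        train, val, test = split_flights(flights)
        model = train_mapper([f[0] for f in train], [f[1] for f in train],
                             self.config)
        return MapperResults(model=model,
                             validation=_eval_pairs(model, val),
                             test=_eval_pairs(model, test))

    def shift_scan(self, tau_grid_ms) -> pd.DataFrame:
        return correlation_vs_shift(self.source_flights, self.target_flights,
                                    tau_grid_ms, self.config)


@dataclass
class MapperResults:
    """Trained mapper with its validation/test scores."""

    model: MapperModel
    validation: dict
    test: dict

    def predict(self, source: VelocitySeries, target: VelocitySeries):
        """Decoded velocity prediction (deg/s) and the paired target values."""
        O, t_om, _ = _predict_on(self.model, source, target)
        return self.model.config, decode_velocity(
            O, self.model.config.velocity_scale), t_om

    def summary(self) -> str:
        c = self.model.config
        lines = [
            "Velocity mapper (anti-identity MLP)",
            "=" * 45,
            f"hidden units  : {c.n_hidden}",
            f"window        : {c.window_ms} ms ({c.window.n_samples} samples)",
            f"tau           : {c.tau_ms} ms ({c.tau_samples} samples)",
            f"lambda / eps  : {c.lambda_reg} / {c.epsilon}",
            f"epochs        : {c.epochs}",
            f"final loss    : {self.model.loss_history[-1]:.4g}",
            "-" * 45,
        ]
        for name, d in (("validation", self.validation), ("test", self.test)):
            lines.append(
                f"{name:<11} median dOmega {d['median_error_angle']:.4f} rad"
                f"  r {d['r']:.4f}  (n={d['n']})")
        return "\n".join(lines)
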