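"""The recurrent survival network, its time-window training loop, prediction,
probability calibration, and cross-validated hyperparameter selection.

Architecture (default, 8 layers): a 28-node input (26 encoded covariates plus
2 latent survival channels fed back from the previous window's estimate),
a fully connected ReLU layer, two gated recurrent (LSTM) layers, three more
fully connected ReLU layers with gradually decreasing widths, and a 2-node
linear output representing (risk, time) — no softmax, since the two output
nodes live on different scales.  An optional dropout stage sits between the
first fully connected layer and the recurrent stack; a "bignode" multiplier
widens every hidden layer.

Training walks the windows in chronological order: at window i the targets
are the vectors ``(alpha * E_i, t_i)``, the loss is the masked cosine
proximity, and parameters are updated by RMSProp once per window per batch
(truncated backpropagation — the recurrent state and the latent feedback are
carried forward as constants).  Covariates are first-visit only and repeat
unchanged at every window.

Everything is plain NumPy in float64; problems of registry scale (a few
thousand patients, ~30 windows) train in seconds on one CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .red import CENSORED_OUT, NORM_FLOOR, WindowTargets, cosine_loss, cosine_loss_grad

__all__ = [
    "NetworkConfig",
    "Hyperparameters",
    "RedSNN",
    "PredictionCurve",
    "survival_probability",
    "SurvivalCalibrator",
    "tune_hyperparameters",
]

_ALLOWED_DROPOUT = (0.0, 0.3, 0.5, 0.7)


@dataclass(frozen=True)
class NetworkConfig:
    """Layer plan and initialization seed.

    ``hidden`` lists the six hidden widths (gradually decreasing);
    ``recurrent`` gives the indices into ``hidden`` that are LSTM layers.
    Input width defaults to 28 = 26 features + 2 latent survival channels;
    the output is always 2 linear nodes.
    """

    input_width: int = 28
    hidden: tuple[int, ...] = (24, 20, 16, 12, 8, 4)
    recurrent: tuple[int, ...] = (1, 2)
    dropout: float = 0.3
    bignode: float = 1.0
    seed: int = 0
    init_output_bias: tuple[float, float] = (1.0, 30.0)

    def validate(self) -> None:
        if self.input_width < 3:
            raise ValueError("input width must be at least 3 (features + 2 latent)")
        if self.dropout not in _ALLOWED_DROPOUT:
            raise ValueError(f"dropout must be one of {_ALLOWED_DROPOUT}")
        if self.bignode <= 0:
            raise ValueError("bignode multiplier must be positive")
        if any(i < 0 or i >= len(self.hidden) for i in self.recurrent):
            raise ValueError("recurrent layer indices out of range")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(max(2, int(round(w * self.bignode))) for w in self.hidden)


@dataclass(frozen=True)
class Hyperparameters:
    """Training-time knobs.  ``m`` is the window length in months, ``alpha``
    the death weight of the survival vector, ``horizon`` the last month the
    network is trained to (W = floor(horizon/m) windows)."""

    m: float = 2.0
    alpha: float = 10.0
    epochs: int = 2
    horizon: float = 62.0
    learning_rate: float = 1e-3
    batch_size: int = 64

    def validate(self) -> None:
        for name in ("m", "alpha", "epochs", "horizon", "learning_rate", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_windows(self) -> int:
        return int(np.floor(self.horizon / self.m + 1e-9))


@dataclass
class PredictionCurve:
    """Per patient, per window: estimated time t̂ (months), estimated risk ê
    (on the alpha*E scale), the scale-free risk score ê/|Ŷ| in [-1, 1], and
    window boundaries."""

    t_hat: np.ndarray
    e_hat: np.ndarray
    boundaries: np.ndarray

    @property
    def risk_score(self) -> np.ndarray:
        norm = np.maximum(np.hypot(self.e_hat, self.t_hat), NORM_FLOOR)
        return self.e_hat / norm


def survival_probability(curve: PredictionCurve, alpha: float) -> np.ndarray:
    """Direct probability readout S_i = 1 - clamp(ê_i / alpha, 0, 1).

    Because the cumulative event target is alpha*E_i, ê_i/alpha reads as an
    estimate of P(death by window i) — but only if the estimate's magnitude is
    on the target scale, which the scale-invariant cosine loss does not
    enforce.  Pipelines therefore default to the Kaplan-Meier-calibrated
    readout (:class:`SurvivalCalibrator`); this direct form is kept as the
    naive mapping.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return 1.0 - np.clip(curve.e_hat / alpha, 0.0, 1.0)


# --------------------------------------------------------------------------
# network


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class RedSNN:
    """The network state plus its one-window forward/backward machinery."""

    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        widths = config.widths
        self.layers: list[dict] = []
        prev = config.input_width
        for idx, w in enumerate(widths):
            if idx in config.recurrent:
                layer = {
                    "type": "lstm",
                    "Wx": _glorot(rng, prev, 4 * w),
                    "Wh": _glorot(rng, w, 4 * w),
                    "b": np.zeros(4 * w),
                    "size": w,
                }
                layer["b"][w : 2 * w] = 1.0  # forget-gate bias
            else:
                layer = {"type": "fc", "W": _glorot(rng, prev, w), "b": np.zeros(w)}
            self.layers.append(layer)
            prev = w
        self.out_W = _glorot(rng, prev, 2)
        self.out_b = np.array(config.init_output_bias, dtype=float)
        self._rms: dict[int, np.ndarray] | None = None

    # -- parameter bookkeeping -------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        params = []
        for layer in self.layers:
            if layer["type"] == "fc":
                params += [layer["W"], layer["b"]]
            else:
                params += [layer["Wx"], layer["Wh"], layer["b"]]
        params += [self.out_W, self.out_b]
        return params

    def init_states(self, batch: int) -> list:
        states = []
        for layer in self.layers:
            if layer["type"] == "lstm":
                w = layer["size"]
                states.append((np.zeros((batch, w)), np.zeros((batch, w))))
            else:
                states.append(None)
        return states

    # -- one window -------------------------------------------------------
    def forward_window(self, x, states, training=False, dropout_rng=None):
        """One pass through the stack for a single time window.

        Returns (y, new_states, cache); the incoming recurrent states are
        treated as constants for the backward pass (truncated BPTT).
        """
        cache = []
        h = np.asarray(x, dtype=float)
        new_states = list(states)
        first_fc_done = False
        for li, layer in enumerate(self.layers):
            if layer["type"] == "fc":
                z = h @ layer["W"] + layer["b"]
                a = np.maximum(z, 0.0)
                drop_mask = None
                if (
                    training
                    and not first_fc_done
                    and self.config.dropout > 0
                    and dropout_rng is not None
                ):
                    keep = 1.0 - self.config.dropout
                    drop_mask = (dropout_rng.uniform(size=a.shape) < keep) / keep
                    a = a * drop_mask
                cache.append({"h_in": h, "z": z, "drop": drop_mask})
                first_fc_done = True
                h = a
            else:
                h_prev, c_prev = states[li]
                gates = h @ layer["Wx"] + h_prev @ layer["Wh"] + layer["b"]
                w = layer["size"]
                i_g = _sigmoid(gates[:, :w])
                f_g = _sigmoid(gates[:, w : 2 * w])
                g_g = np.tanh(gates[:, 2 * w : 3 * w])
                o_g = _sigmoid(gates[:, 3 * w :])
                c = f_g * c_prev + i_g * g_g
                tanh_c = np.tanh(c)
                h_new = o_g * tanh_c
                cache.append(
                    {
                        "x_in": h,
                        "h_prev": h_prev,
                        "c_prev": c_prev,
                        "i": i_g,
                        "f": f_g,
                        "g": g_g,
                        "o": o_g,
                        "tanh_c": tanh_c,
                    }
                )
                new_states[li] = (h_new, c)
                h = h_new
        y = h @ self.out_W + self.out_b
        cache.append({"h_out": h})
        return y, new_states, cache

    def backward_window(self, dy, cache) -> list[np.ndarray]:
        """Gradients of the window loss w.r.t. every parameter (same order as
        :meth:`parameters`), with incoming recurrent states held fixed."""
        grads: list[np.ndarray | None] = [None] * len(self.parameters())
        h_out = cache[-1]["h_out"]
        gi = len(grads)
        grads[gi - 2] = h_out.T @ dy
        grads[gi - 1] = dy.sum(axis=0)
        dh = dy @ self.out_W.T
        pi = gi - 2
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            c = cache[li]
            if layer["type"] == "fc":
                da = dh
                if c["drop"] is not None:
                    da = da * c["drop"]
                dz = da * (c["z"] > 0)
                pi -= 2
                grads[pi] = c["h_in"].T @ dz
                grads[pi + 1] = dz.sum(axis=0)
                dh = dz @ layer["W"].T
            else:
                w = layer["size"]
                do = dh * c["tanh_c"]
                dc = dh * c["o"] * (1.0 - c["tanh_c"] ** 2)
                di = dc * c["g"]
                df = dc * c["c_prev"]
                dg = dc * c["i"]
                dgates = np.concatenate(
                    [
                        di * c["i"] * (1.0 - c["i"]),
                        df * c["f"] * (1.0 - c["f"]),
                        dg * (1.0 - c["g"] ** 2),
                        do * c["o"] * (1.0 - c["o"]),
                    ],
                    axis=1,
                )
                pi -= 3
                grads[pi] = c["x_in"].T @ dgates
                grads[pi + 1] = c["h_prev"].T @ dgates
                grads[pi + 2] = dgates.sum(axis=0)
                dh = dgates @ layer["Wx"].T
        return grads  # type: ignore[return-value]

    def rmsprop_step(self, grads, lr, rho=0.9, eps=1e-8) -> None:
        params = self.parameters()
        if self._rms is None or len(self._rms) != len(params):
            self._rms = {i: np.zeros_like(p) for i, p in enumerate(params)}
        for i, (p, g) in enumerate(zip(params, grads)):
            self._rms[i] = rho * self._rms[i] + (1.0 - rho) * g * g
            p -= lr * g / (np.sqrt(self._rms[i]) + eps)

    def reset_optimizer(self) -> None:
        self._rms = None

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Single-archive persistence: config JSON + flat parameter arrays."""
        cfg = json.dumps(
            {
                "input_width": self.config.input_width,
                "hidden": self.config.hidden,
                "recurrent": self.config.recurrent,
                "dropout": self.config.dropout,
                "bignode": self.config.bignode,
                "seed": self.config.seed,
                "init_output_bias": self.config.init_output_bias,
            }
        )
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        with open(path, "wb") as fh:
            np.savez(fh, config=np.frombuffer(cfg.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "RedSNN":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config"]).decode())
            model = cls(
                NetworkConfig(
                    input_width=cfg["input_width"],
                    hidden=tuple(cfg["hidden"]),
                    recurrent=tuple(cfg["recurrent"]),
                    dropout=cfg["dropout"],
                    bignode=cfg["bignode"],
                    seed=cfg["seed"],
                    init_output_bias=tuple(cfg["init_output_bias"]),
                )
            )
            for i, p in enumerate(model.parameters()):
                p[...] = data[f"p{i}"]
        return model


# --------------------------------------------------------------------------
# training / prediction


def _latent_feedback(y, alpha, horizon):
    """Previous-window estimate, rescaled onto the standardized-feature scale
    before re-entering the input layer."""
    return np.column_stack([y[:, 0] / alpha, y[:, 1] / horizon])


def train(
    model: RedSNN,
    features: np.ndarray,
    targets: WindowTargets,
    hp: Hyperparameters,
    rng: np.random.Generator | None = None,
) -> list[float]:
    """Fit in place; returns the per-epoch mean masked loss trace.

    Each epoch reshuffles patients into batches; each batch walks the windows
    chronologically, taking one RMSProp step on the masked cosine loss per
    window.  Censored-out elements never contribute.
    """
    hp.validate()
    features = np.asarray(features, dtype=float)
    if features.shape[0] != targets.status.shape[0]:
        raise ValueError("features and targets are not row-aligned")
    if features.shape[1] + 2 != model.config.input_width:
        raise ValueError(
            f"feature width {features.shape[1]} does not match network input "
            f"{model.config.input_width} (= features + 2 latent channels)"
        )
    if not targets.loss_mask()[:, 0].any():
        raise ValueError("every patient is censored out at the first window")
    rng = rng or np.random.default_rng(0)
    n = features.shape[0]
    n_windows = targets.n_windows
    Y = targets.target_vectors(hp.alpha)
    mask = targets.loss_mask()

    trace: list[float] = []
    for _ in range(int(hp.epochs)):
        perm = rng.permutation(n)
        loss_sum = 0.0
        loss_cnt = 0
        for start in range(0, n, int(hp.batch_size)):
            idx = perm[start : start + int(hp.batch_size)]
            xb = features[idx]
            states = model.init_states(len(idx))
            latent = np.zeros((len(idx), 2))
            for wi in range(n_windows):
                x_in = np.column_stack([xb, latent])
                y, states, cache = model.forward_window(
                    x_in, states, training=True, dropout_rng=rng
                )
                mb = mask[idx, wi]
                if mb.any():
                    yb = Y[idx, wi]
                    loss = cosine_loss(yb, y, mb)
                    dy = cosine_loss_grad(yb, y, mb)
                    grads = model.backward_window(dy, cache)
                    model.rmsprop_step(grads, hp.learning_rate)
                    loss_sum += loss * mb.sum()
                    loss_cnt += int(mb.sum())
                latent = _latent_feedback(y, hp.alpha, hp.horizon)
        trace.append(loss_sum / max(loss_cnt, 1))
    if not all(np.isfinite(trace)):
        raise FloatingPointError("non-finite training loss")
    return trace


def predict_curves(model: RedSNN, features: np.ndarray, hp: Hyperparameters) -> PredictionCurve:
    """Deterministic evaluation-mode forward pass over all windows.

    The two latent input channels are zero at window 1 and carry the previous
    window's (rescaled) estimate thereafter.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[1] + 2 != model.config.input_width:
        raise ValueError("feature width does not match the network input")
    n = features.shape[0]
    n_windows = hp.n_windows
    states = model.init_states(n)
    latent = np.zeros((n, 2))
    e_hat = np.empty((n, n_windows))
    t_hat = np.empty((n, n_windows))
    for wi in range(n_windows):
        x_in = np.column_stack([features, latent])
        y, states, _ = model.forward_window(x_in, states, training=False)
        e_hat[:, wi] = y[:, 0]
        t_hat[:, wi] = y[:, 1]
        latent = _latent_feedback(y, hp.alpha, hp.horizon)
    boundaries = hp.m * np.arange(1, n_windows + 1)
    return PredictionCurve(t_hat=t_hat, e_hat=e_hat, boundaries=boundaries)


# --------------------------------------------------------------------------
# probability calibration


class _WindowLink:
    """Monotone score -> survival-probability link for one window.

    The risk score is first rank-normalized against the training score
    distribution (probit of the empirical CDF), then survival status at the
    window boundary is fitted by a complementary-log-log binomial GLM, cubic
    in the normalized score, with inverse-probability-of-censoring weights.
    Under a proportional-hazards data law with a roughly Gaussian linear
    predictor, log(-log S(b)) is approximately polynomial in the score's
    normal rank, which is why this link family calibrates well while staying
    smooth.  The fitted curve is projected onto the decreasing cone (pool
    adjacent violators on a dense grid) so the link is monotone by
    construction; degenerate windows (all alive or all dead) fall back to a
    constant.
    """

    def __init__(self, sorted_train_scores, grid_z, grid_S):
        self._sorted = sorted_train_scores
        self._grid_z = grid_z
        self._grid_S = grid_S

    def _to_z(self, s: np.ndarray) -> np.ndarray:
        n = len(self._sorted)
        lo = np.searchsorted(self._sorted, s, side="left")
        hi = np.searchsorted(self._sorted, s, side="right")
        u = (lo + hi) / 2.0 / n
        return stats.norm.ppf(np.clip(u, 0.5 / n, 1.0 - 0.5 / n))

    def predict(self, s: np.ndarray) -> np.ndarray:
        z = self._to_z(np.asarray(s, dtype=float))
        # grid_S is decreasing in z; np.interp needs ascending x
        return np.interp(z, self._grid_z, self._grid_S)


class SurvivalCalibrator:
    """Maps the scale-free per-window risk score to survival probability.

    The cosine loss pins down only the direction of the estimate vector, so
    the raw risk output carries no probability scale; the calibrator learns
    the score -> P(survive past window boundary) mapping on the training set
    with one :class:`_WindowLink` per window.  Censoring is handled by
    inverse-probability-of-censoring weighting: a patient observed past the
    boundary counts as alive with weight 1/G(b), a patient dead by the
    boundary counts with weight 1/G(T-), a patient censored earlier gets
    weight zero, where G is the Kaplan-Meier estimate of the censoring
    survival function.  Weights are truncated at ``max_weight``.
    """

    def __init__(self, max_weight: float = 20.0, degree: int = 3):
        self.max_weight = max_weight
        self.degree = degree
        self._links: list[_WindowLink] = []
        self.boundaries: np.ndarray | None = None

    def _fit_window(self, s, alive, weights) -> _WindowLink:
        import statsmodels.api as sm

        sorted_scores = np.sort(s)
        grid_z = np.linspace(-3.5, 3.5, 201)
        used = weights > 0
        mean_alive = float(np.average(alive[used], weights=weights[used]))
        if mean_alive <= 0.0 or mean_alive >= 1.0:
            return _WindowLink(sorted_scores, grid_z, np.full_like(grid_z, mean_alive))
        link = _WindowLink(sorted_scores, grid_z, None)
        z = link._to_z(s)
        basis = np.column_stack([z**k for k in range(self.degree + 1)])
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                glm = sm.GLM(
                    alive,
                    basis,
                    family=sm.families.Binomial(sm.families.links.CLogLog()),
                    freq_weights=weights,
                ).fit(maxiter=200)
                grid_basis = np.column_stack([grid_z**k for k in range(self.degree + 1)])
                fitted = np.clip(np.asarray(glm.predict(grid_basis)), 0.0, 1.0)
        except Exception:  # separation / non-convergence: constant fallback
            fitted = np.full_like(grid_z, mean_alive)
        # project onto the decreasing-in-z cone, weighting by the rank-normal
        # density so sparse tails cannot drag the dense center
        iso = IsotonicRegression(increasing=False).fit(
            grid_z, fitted, sample_weight=stats.norm.pdf(grid_z)
        )
        link._grid_S = np.clip(iso.predict(grid_z), 0.0, 1.0)
        return link

    def fit(self, scores: np.ndarray, time: np.ndarray, event: np.ndarray,
            boundaries: np.ndarray) -> "SurvivalCalibrator":
        scores = np.asarray(scores, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        n = len(time)
        if scores.shape != (n, len(boundaries)):
            raise ValueError("scores must be (n_patients, n_windows)")
        self.boundaries = np.asarray(boundaries, dtype=float)

        cens_km = KaplanMeierFitter().fit(time, 1 - event)
        eps = 1e-9
        g_at_death = np.maximum(
            cens_km.predict((time - eps).clip(min=0.0)).to_numpy(dtype=float), eps
        )
        self._links = []
        for wi, b in enumerate(self.boundaries):
            observed_past = time > b
            dead_by_b = (time <= b) & (event == 1)
            alive = observed_past.astype(float)
            g_b = max(float(cens_km.predict(b)), eps)
            weights = np.zeros(n)
            weights[observed_past] = 1.0 / g_b
            weights[dead_by_b] = 1.0 / g_at_death[dead_by_b]
            weights = np.minimum(weights, self.max_weight)
            self._links.append(self._fit_window(scores[:, wi], alive, weights))
        return self

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """(n, W) survival probabilities in [0, 1]."""
        if not self._links:
            raise RuntimeError("calibrator is not fitted")
        scores = np.asarray(scores, dtype=float)
        S = np.column_stack(
            [self._links[wi].predict(scores[:, wi]) for wi in range(scores.shape[1])]
        )
        return np.clip(S, 0.0, 1.0)


# --------------------------------------------------------------------------
# hyperparameter tuning


def _cindex_from_curve(curve: PredictionCurve, time, event) -> float:
    """Concordance of the final-window risk score against (time, event)."""
    risk = curve.risk_score[:, -1]
    return float(_lifelines_cindex(time, -risk, event))


def tune_hyperparameters(
    grid: list[Hyperparameters],
    folds: list[tuple[np.ndarray, np.ndarray]],
    X_raw: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    net_config: NetworkConfig,
    n_neighbors: int = 5,
    seed: int = 0,
) -> tuple[Hyperparameters, list[dict]]:
    """Median validation c-index over the folds for every grid point; returns
    the argmax setting (ties broken by grid order) and the per-setting record.

    ``X_raw`` is the encoded feature matrix with missing cells still NaN;
    imputation and scaling are re-fitted inside every fold so no validation
    information leaks into the preprocessing statistics.
    """
    from .preprocessing import knn_impute, standardize
    from .red import build_window_targets

    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    X_raw = np.asarray(X_raw, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)

    records = []
    best_idx, best_score = 0, -np.inf
    for gi, hp in enumerate(grid):
        hp.validate()
        fold_scores = []
        for fi, (fit_idx, val_idx) in enumerate(folds):
            fit_imp = knn_impute(X_raw[fit_idx], X_raw[fit_idx], k=n_neighbors)
            val_imp = knn_impute(X_raw[fit_idx], X_raw[val_idx], k=n_neighbors)
            fit_X = standardize(fit_imp, fit_imp)
            val_X = standardize(fit_imp, val_imp)
            targets = build_window_targets(time[fit_idx], event[fit_idx], hp.m, hp.horizon)
            model = RedSNN(net_config)
            train(model, fit_X, targets, hp, rng=np.random.default_rng(seed + fi))
            curve = predict_curves(model, val_X, hp)
            fold_scores.append(_cindex_from_curve(curve, time[val_idx], event[val_idx]))
        median_c = float(np.median(fold_scores))
        records.append(
            {"hyperparameters": hp, "fold_c_indexes": fold_scores, "median_c_index": median_c}
        )
        if median_c > best_score:
            best_idx, best_score = gi, median_c
    return grid[best_idx], records
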