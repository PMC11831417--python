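"""Specific-productivity modelling: derive qp from titer, train an MLP,
integrate titer back, and rank feature influence.

Specific productivity qp (product per viable cell per day) is not measured
directly; it is recovered by inverting the reactor product balance
``dIgG/dt = qp*Xv - (Fh+Fb)/V * IgG`` on smoothed titer measurements.  A
small feed-forward network (two hidden layers, 16 and 10 logistic units,
Adam-trained on standardized features) then learns qp as a function of the
mechanistic model's states and the process inputs, closing the hybrid loop:
the mechanistic states supply unmeasurable features (lysed cells,
biomaterial) to the data-driven sub-model, whose prediction drives the
titer state in simulation.  Permutation importance ranks which features the
trained network actually relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .io import BatchRecord
from .simulate import Trajectory

__all__ = [
    "FEATURES",
    "MlpConfig",
    "derive_qp",
    "SpecificProductivityModel",
    "QpModelResults",
    "integrate_titer",
    "permutation_importance",
    "diameter_correlation",
]

#: feature order used by every qp predictor in the package
FEATURES = ("xv", "xl", "phib", "temp_c", "ph", "volume_ml", "feed_ml_d")


@dataclass(frozen=True)
class MlpConfig:
    hidden: tuple[int, int] = (16, 10)
    activation: str = "logistic"
    max_epochs: int = 4000
    learning_rate: float = 1e-3
    seed: int = 0
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if len(self.hidden) < 1 or min(self.hidden) < 1:
            raise ValueError("need at least one hidden layer of size >= 1")


def derive_qp(
    record: BatchRecord,
    trajectory: Trajectory,
    smooth_window: int = 3,
    xv_floor: float = 1.0,
) -> pd.DataFrame:
    """Invert the product balance into per-sample qp training data.

    Titer is smoothed with a centered moving average before centered
    differencing; the washout term uses the measured feed (constant volume,
    so ``(Fh+Fb)/V = Ff/V``).  Features come from the simulated trajectory
    at the sample times — that is the point of the hybrid model: lysed cells
    and biomaterial are not measurable.  Samples where simulated VCD falls
    below ``xv_floor`` are dropped (the inversion divides by Xv).
    """
    if record.titer_norm is None or record.time_d.size < 3:
        raise ValueError("record needs titer at >= 3 sample times")
    t = record.time_d
    titer = np.asarray(record.titer_norm, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(titer, pad, mode="edge")
        titer = np.convolve(padded, kernel, mode="valid")
    d_titer = np.gradient(titer, t)
    washout = record.feed_ml_d / record.volume_ml

    xv = trajectory.at(t, "Xv")
    qp = (d_titer + washout * titer) / np.maximum(xv, 1e-12)

    df = pd.DataFrame(
        {
            "time_d": t,
            "xv": xv,
            "xl": trajectory.at(t, "xl_total"),
            "phib": trajectory.at(t, "phib_total"),
            "temp_c": trajectory.at(t, "temp"),
            "ph": trajectory.at(t, "ph"),
            "volume_ml": record.volume_ml,
            "feed_ml_d": record.feed_ml_d,
            "qp": qp,
            "batch_id": record.batch_id,
        }
    )
    kept = df[df["xv"] >= xv_floor].reset_index(drop=True)
    return kept


class QpModelResults:
    """Fitted qp predictor with portable weights.

    Calling the results object on a feature array of shape ``(..., 7)``
    (ordered as :data:`FEATURES`) evaluates the network with a plain NumPy
    forward pass, so it can sit inside the vectorized simulation loop.
    """

    def __init__(self, weights, biases, x_mean, x_scale, y_mean, y_scale,
                 loss_curve=None):
        self.weights = [np.asarray(w, dtype=float) for w in weights]
        self.biases = [np.asarray(b, dtype=float) for b in biases]
        self.x_mean = np.asarray(x_mean, dtype=float)
        self.x_scale = np.asarray(x_scale, dtype=float)
        self.y_mean = float(y_mean)
        self.y_scale = float(y_scale)
        self.loss_curve = (
            np.asarray(loss_curve, dtype=float)
            if loss_curve is not None else None
        )

    def __call__(self, features) -> np.ndarray:
        x = (np.asarray(features, dtype=float) - self.x_mean) / self.x_scale
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            x = 1.0 / (1.0 + np.exp(-(x @ w + b)))  # logistic hidden units
        x = x @ self.weights[-1] + self.biases[-1]
        return x[..., 0] * self.y_scale + self.y_mean

    predict = __call__

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        return self(df[list(FEATURES)].to_numpy(dtype=float))

    def mse(self, samples: pd.DataFrame) -> float:
        pred = self.predict_frame(samples)
        return float(np.mean((samples["qp"].to_numpy() - pred) ** 2))

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "features": list(FEATURES),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "QpModelResults":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["weights"], d["biases"], d["x_mean"], d["x_scale"],
            d["y_mean"], d["y_scale"],
        )


class SpecificProductivityModel:
    """MLP regression of qp on mechanistic states and process inputs."""

    def __init__(self, samples: pd.DataFrame, config: MlpConfig | None = None):
        missing = [c for c in FEATURES + ("qp",) if c not in samples.columns]
        if missing:
            raise ValueError(f"samples missing column(s) {missing}")
        if len(samples) < 50:
            raise ValueError(
                f"need >= 50 qp samples to train, got {len(samples)}"
            )
        self.samples = samples.reset_index(drop=True)
        self.config = config or MlpConfig()

    def fit(self) -> QpModelResults:
        cfg = self.config
        X = self.samples[list(FEATURES)].to_numpy(dtype=float)
        y = self.samples["qp"].to_numpy(dtype=float)
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite feature or target values")
        xs = StandardScaler().fit(X)
        # constant features (e.g. volume within one campaign) get unit scale
        xs.scale_ = np.where(xs.scale_ == 0, 1.0, xs.scale_)
        y_mean, y_std = float(y.mean()), float(y.std())
        if y_std == 0:
            y_std = 1.0
        mlp = MLPRegressor(
            hidden_layer_sizes=cfg.hidden,
            activation=cfg.activation,
            solver="adam",
            learning_rate_init=cfg.learning_rate,
            max_iter=cfg.max_epochs,
            tol=cfg.tol,
            n_iter_no_change=50,
            random_state=cfg.seed,
        )
        mlp.fit(xs.transform(X), (y - y_mean) / y_std)
        if not np.all(np.isfinite(mlp.loss_curve_)):
            raise RuntimeError("training diverged to a non-finite loss")
        return QpModelResults(
            weights=mlp.coefs_,
            biases=mlp.intercepts_,
            x_mean=xs.mean_,
            x_scale=xs.scale_,
            y_mean=y_mean,
            y_scale=y_std,
            loss_curve=mlp.loss_curve_,
        )


def integrate_titer(
    trajectory: Trajectory,
    qp_model,
    igg0: float = 0.0,
):
    """Integrate the product balance along a simulated trajectory.

    Returns a DataFrame with columns ``time_d``, ``qp``, ``igg``,
    ``volumetric_rate`` (qp*Xv) and ``harvested`` (cumulative integral of
    IgG*Fh, i.e. product captured in the harvest stream).  The titer ODE is
    linear given the trajectory, and is advanced with RK4 on the trajectory
    grid with the qp prediction held over each interval.
    """
    t = trajectory.t
    xv = trajectory.states[..., 0]
    if xv.ndim != 1:
        raise ValueError("use .select() on vectorized trajectories")
    feats = np.stack(
        [
            xv,
            trajectory.xl_total,
            trajectory.phib_total,
            trajectory.temp,
            trajectory.ph,
            np.full_like(xv, trajectory.volume),
            trajectory.ff,
        ],
        axis=-1,
    )
    qp = np.maximum(np.asarray(qp_model(feats), dtype=float), 0.0)
    d = (trajectory.fh + trajectory.fb) / trajectory.volume

    igg = np.empty_like(t)
    igg[0] = igg0
    for k in range(t.size - 1):
        h = t[k + 1] - t[k]

        def f(x, frac):
            xv_i = xv[k] + frac * (xv[k + 1] - xv[k])
            d_i = d[k] + frac * (d[k + 1] - d[k])
            return qp[k] * xv_i - d_i * x

        k1 = f(igg[k], 0.0)
        k2 = f(igg[k] + 0.5 * h * k1, 0.5)
        k3 = f(igg[k] + 0.5 * h * k2, 0.5)
        k4 = f(igg[k] + h * k3, 1.0)
        igg[k + 1] = igg[k] + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    rate = igg * trajectory.fh
    harvested = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(t))]
    )
    return pd.DataFrame(
        {
            "time_d": t,
            "qp": qp,
            "igg": igg,
            "volumetric_rate": qp * xv,
            "harvested": harvested,
        }
    )


def permutation_importance(
    qp_model,
    samples: pd.DataFrame,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean MSE increase when each feature column is shuffled.

    Returns a frame sorted by importance with columns ``feature``,
    ``importance`` (mean MSE increase over repeats) and ``std``.
    """
    rng = np.random.default_rng(seed)
    X = samples[list(FEATURES)].to_numpy(dtype=float)
    y = samples["qp"].to_numpy(dtype=float)
    base = float(np.mean((y - qp_model(X)) ** 2))
    rows = []
    for j, name in enumerate(FEATURES):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            deltas.append(np.mean((y - qp_model(Xp)) ** 2) - base)
        rows.append(
            {"feature": name, "importance": float(np.mean(deltas)),
             "std": float(np.std(deltas))}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )


def diameter_correlation(record: BatchRecord, trajectory: Trajectory) -> float:
    """Pearson correlation between simulated lysed cells and measured mean
    cell diameter — a diagnostic of the debris/cell-size link."""
    if record.diameter_um is None:
        raise ValueError("record has no diameter measurements")
    xl = trajectory.at(record.time_d, "xl_total")
    return float(np.corrcoef(xl, record.diameter_um)[0, 1])
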