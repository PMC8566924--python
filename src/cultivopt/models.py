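"""Surrogate model families with a uniform fit/predict contract.

Three families predict a single growth trait from the five culture inputs:

* **GRNN** — generalized regression neural network, a Nadaraya–Watson
  kernel-weighted average of stored training targets,
  ``ŷ(x) = Σ yᵢ exp(−Dᵢ²/2σ²) / Σ exp(−Dᵢ²/2σ²)`` with squared Euclidean
  distance on min–max-scaled inputs. Predictions are convex combinations of
  training targets, hence always within ``[min y, max y]``.
* **MLP** — one hidden layer of tanh units with a linear output, trained by
  Levenberg–Marquardt (damped Gauss–Newton) on the sum-of-squares loss.
* **ANFIS** — first-order Takagi–Sugeno rule base on a grid partition of
  Gaussian memberships ``μ(x) = exp[−((x−c)/a)²]``, trained by hybrid
  learning: ridge least squares for rule consequents alternated with
  gradient steps on the premise parameters.

Every fitted model is wrapped in :class:`SurrogateModel`, which owns the
input scaler and the optional Box-Cox target transform and always predicts
in original trait units.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from cultivopt.metrics import MetricError, compute_metrics
from cultivopt.preprocessing import (
    BoxCoxTransform,
    FoldPlan,
    MinMaxScaler1,
    boxcox_apply,
    boxcox_fit,
    boxcox_invert,
)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# GRNN


@dataclass(frozen=True)
class GRNNCore:
    """Stored training set plus kernel width σ (scaled-input distance units)."""

    X: np.ndarray
    y: np.ndarray
    sigma: float

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        D2 = cdist(Xq, self.X, "sqeuclidean")
        logw = -D2 / (2.0 * self.sigma**2)
        logw -= logw.max(axis=1, keepdims=True)  # σ→0 stays finite
        w = np.exp(logw)
        return w @ self.y / w.sum(axis=1)


# ---------------------------------------------------------------------------
# MLP


@dataclass(frozen=True)
class MLPConfig:
    max_iter: int = 200
    gtol: float = 1e-9
    ftol: float = 1e-12
    mu0: float = 1e-3
    mu_max: float = 1e12


@dataclass(frozen=True)
class MLPCore:
    """tanh hidden layer + linear output; targets standardized internally."""

    W1: np.ndarray  # (p, k)
    b1: np.ndarray  # (p,)
    w2: np.ndarray  # (p,)
    b2: float
    y_mean: float
    y_std: float

    def _forward_std(self, Xq: np.ndarray) -> np.ndarray:
        H = np.tanh(Xq @ self.W1.T + self.b1)
        return H @ self.w2 + self.b2

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        return self._forward_std(Xq) * self.y_std + self.y_mean


def _mlp_pack(W1, b1, w2, b2):
    return np.concatenate([W1.ravel(), b1, w2, [b2]])


def _mlp_unpack(theta, p, k):
    W1 = theta[: p * k].reshape(p, k)
    b1 = theta[p * k : p * k + p]
    w2 = theta[p * k + p : p * k + 2 * p]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _train_mlp(
    X: np.ndarray, y: np.ndarray, hidden_size: int, seed: int, cfg: MLPConfig
) -> MLPCore:
    n, k = X.shape
    p = hidden_size
    y_mean, y_std = float(y.mean()), float(y.std())
    y_std = y_std if y_std > 0 else 1.0
    t = (y - y_mean) / y_std

    rng = np.random.default_rng(seed)
    theta = rng.normal(scale=1.0 / np.sqrt(k + 1), size=p * k + 2 * p + 1)

    def residual_and_jac(th):
        W1, b1, w2, b2 = _mlp_unpack(th, p, k)
        A = X @ W1.T + b1
        H = np.tanh(A)
        r = H @ w2 + b2 - t
        dH = 1.0 - H**2  # (n, p)
        J = np.empty((n, th.size))
        # d r / d W1[j, i] = w2[j] * dH[:, j] * X[:, i]
        G = dH * w2  # (n, p)
        J[:, : p * k] = (G[:, :, None] * X[:, None, :]).reshape(n, p * k)
        J[:, p * k : p * k + p] = G
        J[:, p * k + p : p * k + 2 * p] = H
        J[:, -1] = 1.0
        return r, J

    r, J = residual_and_jac(theta)
    loss = float(r @ r)
    mu = cfg.mu0
    for it in range(cfg.max_iter):
        if not np.isfinite(loss):
            raise ModelError(f"MLP training diverged at iteration {it}")
        g = J.T @ r
        if np.abs(g).max() < cfg.gtol:
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= cfg.mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(theta.size), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            r_new, J_new = residual_and_jac(theta + delta)
            loss_new = float(r_new @ r_new)
            if np.isfinite(loss_new) and loss_new < loss:
                improvement = loss - loss_new
                theta, r, J = theta + delta, r_new, J_new
                loss = loss_new
                mu = max(mu / 10.0, 1e-15)
                accepted = True
                if improvement < cfg.ftol * max(loss, 1.0):
                    mu = cfg.mu_max * 10  # signal convergence
                break
            mu *= 10.0
        if not accepted or mu > cfg.mu_max:
            break
    W1, b1, w2, b2 = _mlp_unpack(theta, p, k)
    return MLPCore(
        W1=W1, b1=b1, w2=w2, b2=float(b2), y_mean=y_mean, y_std=y_std
    )


# ---------------------------------------------------------------------------
# ANFIS


@dataclass(frozen=True)
class ANFISCore:
    """Grid-partition first-order Takagi–Sugeno system.

    ``centers``/``widths`` hold per-input premise parameters with shape
    (n_inputs, m); ``rules`` maps each rule to one membership index per
    input; ``theta`` holds (d+1) consequent coefficients per rule.
    ``conventional=True`` switches the membership to
    ``exp(−(x−c)²/2a²)`` instead of the default ``exp(−((x−c)/a)²)``.
    """

    centers: np.ndarray
    widths: np.ndarray
    rules: np.ndarray
    theta: np.ndarray
    conventional: bool = False

    @property
    def n_rules(self) -> int:
        return self.rules.shape[0]

    def memberships(self, Xq: np.ndarray) -> np.ndarray:
        z = (Xq[:, :, None] - self.centers[None]) / self.widths[None]
        if self.conventional:
            return np.exp(-0.5 * z**2)
        return np.exp(-(z**2))

    def firing(self, Xq: np.ndarray) -> np.ndarray:
        mu = self.memberships(Xq)  # (n, d, m)
        n, d, _ = mu.shape
        w = np.ones((n, self.n_rules))
        for i in range(d):
            w *= mu[:, i, self.rules[:, i]]
        return w

    def normalized_firing(self, Xq: np.ndarray) -> np.ndarray:
        w = self.firing(Xq)
        s = w.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        return w / s

    def design(self, Xq: np.ndarray) -> np.ndarray:
        wbar = self.normalized_firing(Xq)
        Xa = np.hstack([Xq, np.ones((Xq.shape[0], 1))])
        return (wbar[:, :, None] * Xa[:, None, :]).reshape(Xq.shape[0], -1)

    def predict(self, Xq: np.ndarray) -> np.ndarray:
        return self.design(Xq) @ self.theta


def _anfis_ls(core: ANFISCore, X, t, ridge: float) -> np.ndarray:
    Phi = core.design(X)
    n, P = Phi.shape
    # dimensionless penalty: scale by the mean squared row norm of the
    # design so the regularization strength is invariant to rule count
    # and input scale
    lam = ridge * float(np.sum(Phi**2)) / n
    lam = max(lam, 1e-12)
    if P <= n:
        A = Phi.T @ Phi + lam * np.eye(P)
        return np.linalg.solve(A, Phi.T @ t)
    # dual form: with more consequent parameters than samples solve the
    # n×n system instead ((ΦᵀΦ+λI)⁻¹Φᵀ = Φᵀ(ΦΦᵀ+λI)⁻¹)
    K = Phi @ Phi.T + lam * np.eye(n)
    return Phi.T @ np.linalg.solve(K, t)


def _anfis_premise_step(
    core: ANFISCore, X, t, lr: float, width_floor: float
) -> ANFISCore:
    """One gradient-descent step on squared error w.r.t. centers and widths."""
    n, d = X.shape
    mu = core.memberships(X)
    w = core.firing(X)
    s = w.sum(axis=1)
    s[s == 0] = 1.0
    wbar = w / s[:, None]
    Xa = np.hstack([X, np.ones((n, 1))])
    F = Xa @ core.theta.reshape(core.n_rules, d + 1).T  # (n, R) rule outputs
    yhat = (wbar * F).sum(axis=1)
    e = yhat - t
    # dE/dw_r = 2e * (F_r − ŷ)/s ; dw_r/dμ_{i,j} = w_r/μ_{i,j} for rules using (i,j)
    dE_dw = 2.0 * e[:, None] * (F - yhat[:, None]) / s[:, None]
    gc = np.zeros_like(core.centers)
    ga = np.zeros_like(core.widths)
    z = (X[:, :, None] - core.centers[None]) / core.widths[None]
    fac = 1.0 if core.conventional else 2.0
    for i in range(d):
        mu_i = mu[:, i, core.rules[:, i]]
        mu_i = np.where(mu_i == 0, 1e-300, mu_i)
        dE_dmu_rule = dE_dw * w / mu_i  # (n, R)
        for j in range(core.centers.shape[1]):
            mask = core.rules[:, i] == j
            dE_dmu = dE_dmu_rule[:, mask].sum(axis=1)
            zij = z[:, i, j]
            mu_ij = mu[:, i, j]
            # dμ/dc = μ·fac·z/a ; dμ/da = μ·fac·z²/a
            gc[i, j] = np.sum(dE_dmu * mu_ij * fac * zij / core.widths[i, j])
            ga[i, j] = np.sum(dE_dmu * mu_ij * fac * zij**2 / core.widths[i, j])
    scale = max(np.abs(gc).max(), np.abs(ga).max(), 1e-12)
    centers = core.centers - lr * gc / scale
    widths = np.maximum(core.widths - lr * ga / scale, width_floor)
    return replace(core, centers=centers, widths=widths)


def _train_anfis(
    X: np.ndarray,
    y: np.ndarray,
    mf_per_input: int,
    epochs: int,
    seed: int,
    ridge: float,
    rule_cap: int,
    lr: float,
    conventional: bool,
) -> ANFISCore:
    n, d = X.shape
    if not 3 <= mf_per_input <= 5:
        raise ModelError("mf_per_input must be between 3 and 5")
    n_rules = mf_per_input**d
    if n_rules > rule_cap:
        raise ModelError(
            f"grid partition yields {n_rules} rules (> cap {rule_cap}); "
            "use fewer membership functions per input or raise rule_cap"
        )
    centers = np.empty((d, mf_per_input))
    widths = np.empty((d, mf_per_input))
    for i in range(d):
        lo, hi = X[:, i].min(), X[:, i].max()
        if hi == lo:
            hi = lo + 1.0
        centers[i] = np.linspace(lo, hi, mf_per_input)
        widths[i] = (hi - lo) / (mf_per_input - 1)
    rules = np.array(
        list(itertools.product(range(mf_per_input), repeat=d)), dtype=int
    )
    core = ANFISCore(
        centers=centers,
        widths=widths,
        rules=rules,
        theta=np.zeros(n_rules * (d + 1)),
        conventional=conventional,
    )
    # train on standardized targets so the ridge does not shrink the
    # response level; fold mean/scale back into the consequents at the end
    y_mean, y_std = float(y.mean()), float(y.std())
    y_std = y_std if y_std > 0 else 1.0
    t = (y - y_mean) / y_std
    width_floor = 1e-3
    for _ in range(epochs):
        core = replace(core, theta=_anfis_ls(core, X, t, ridge))
        core = _anfis_premise_step(core, X, t, lr, width_floor)
    theta = _anfis_ls(core, X, t, ridge).reshape(n_rules, d + 1)
    theta = theta * y_std
    theta[:, -1] += y_mean  # normalized firing strengths sum to 1
    return replace(core, theta=theta.ravel())


# ---------------------------------------------------------------------------
# SurrogateModel wrapper


@dataclass(frozen=True)
class SurrogateModel:
    """A fitted trait predictor: core model + preprocessing transforms.

    ``predict`` scales query inputs with the training scaler, evaluates the
    core model and back-transforms predictions to original trait units. For
    Box-Cox targets the transformed predictions are winsorized to the
    transformed training-target range (±10 % of its span) before inversion:
    an extrapolating core (MLP/ANFIS) would otherwise leave the invertible
    domain of the power transform, where the back-transform diverges.
    """

    family: str
    core: GRNNCore | MLPCore | ANFISCore
    scaler: MinMaxScaler1
    boxcox: BoxCoxTransform | None
    hyperparams: dict
    t_range: tuple[float, float] | None = None

    def predict(self, Xq) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        z = self.core.predict(self.scaler.transform(Xq))
        if self.boxcox is None:
            return z
        if self.t_range is not None:
            lo, hi = self.t_range
            margin = 0.1 * (hi - lo)
            z = np.clip(z, lo - margin, hi + margin)
        lam = self.boxcox.lambda_
        if lam != 0.0:
            dlo = -1.0 / lam + 1e-12 if lam > 0 else -np.inf
            dhi = np.inf if lam > 0 else -1.0 / lam - 1e-12
            z = np.clip(z, dlo, dhi)
        return boxcox_invert(self.boxcox, z)

    # -- JSON serialization (versioned container) ---------------------------

    def to_json(self) -> str:
        def arr(a):
            return np.asarray(a).tolist()

        core: dict = {}
        if self.family == "grnn":
            core = {"X": arr(self.core.X), "y": arr(self.core.y),
                    "sigma": self.core.sigma}
        elif self.family == "mlp":
            core = {"W1": arr(self.core.W1), "b1": arr(self.core.b1),
                    "w2": arr(self.core.w2), "b2": self.core.b2,
                    "y_mean": self.core.y_mean, "y_std": self.core.y_std}
        elif self.family == "anfis":
            core = {"centers": arr(self.core.centers),
                    "widths": arr(self.core.widths),
                    "rules": arr(self.core.rules),
                    "theta": arr(self.core.theta),
                    "conventional": self.core.conventional}
        payload = {
            "format": "cultivopt-surrogate",
            "version": 1,
            "family": self.family,
            "hyperparams": self.hyperparams,
            "core": core,
            "scaler": {"mins": arr(self.scaler.mins),
                       "ranges": arr(self.scaler.ranges)},
            "boxcox": None if self.boxcox is None else
                      {"lambda": self.boxcox.lambda_, "shift": self.boxcox.shift},
            "t_range": None if self.t_range is None else list(self.t_range),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        d = json.loads(text)
        if d.get("format") != "cultivopt-surrogate":
            raise ModelError("not a cultivopt surrogate container")
        c = d["core"]
        family = d["family"]
        if family == "grnn":
            core = GRNNCore(np.array(c["X"]), np.array(c["y"]), c["sigma"])
        elif family == "mlp":
            core = MLPCore(np.array(c["W1"]), np.array(c["b1"]),
                           np.array(c["w2"]), c["b2"], c["y_mean"], c["y_std"])
        elif family == "anfis":
            core = ANFISCore(np.array(c["centers"]), np.array(c["widths"]),
                             np.array(c["rules"], dtype=int),
                             np.array(c["theta"]), c["conventional"])
        else:
            raise ModelError(f"unknown family '{family}'")
        bc = d["boxcox"]
        return cls(
            family=family,
            core=core,
            scaler=MinMaxScaler1(np.array(d["scaler"]["mins"]),
                                 np.array(d["scaler"]["ranges"])),
            boxcox=None if bc is None else
                   BoxCoxTransform(bc["lambda"], bc["shift"]),
            hyperparams=d["hyperparams"],
            t_range=None if d.get("t_range") is None else tuple(d["t_range"]),
        )


def _prepare(X, y, use_boxcox):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scaler = MinMaxScaler1.fit(X)
    Xs = scaler.transform(X)
    if use_boxcox:
        bc = boxcox_fit(y)
        t = boxcox_apply(bc, y)
        t_range = (float(t.min()), float(t.max()))
    else:
        bc, t, t_range = None, y, None
    return Xs, t, scaler, bc, t_range


def fit_grnn(X, y, sigma: float, *, use_boxcox: bool = False) -> SurrogateModel:
    """Fit a GRNN; training cost is storage only."""
    if sigma <= 0:
        raise ModelError(f"sigma must be positive, got {sigma}")
    Xs, t, scaler, bc, t_range = _prepare(X, y, use_boxcox)
    return SurrogateModel(
        family="grnn",
        core=GRNNCore(X=Xs, y=t, sigma=float(sigma)),
        scaler=scaler,
        boxcox=bc,
        hyperparams={"sigma": float(sigma), "use_boxcox": use_boxcox},
        t_range=t_range,
    )


def fit_mlp(
    X,
    y,
    hidden_size: int,
    seed: int = 0,
    config: MLPConfig = MLPConfig(),
    *,
    use_boxcox: bool = False,
) -> SurrogateModel:
    """Fit a one-hidden-layer tanh MLP by Levenberg–Marquardt."""
    if hidden_size < 1:
        raise ModelError(f"hidden_size must be >= 1, got {hidden_size}")
    Xs, t, scaler, bc, t_range = _prepare(X, y, use_boxcox)
    core = _train_mlp(Xs, t, hidden_size, seed, config)
    return SurrogateModel(
        family="mlp",
        core=core,
        scaler=scaler,
        boxcox=bc,
        hyperparams={"hidden_size": hidden_size, "seed": seed,
                     "use_boxcox": use_boxcox},
        t_range=t_range,
    )


def fit_anfis(
    X,
    y,
    mf_per_input: int = 3,
    epochs: int = 10,
    seed: int = 0,
    *,
    ridge: float = 1e-7,
    rule_cap: int = 256,
    lr: float = 0.01,
    conventional_mf: bool = False,
    use_boxcox: bool = False,
) -> SurrogateModel:
    """Fit a grid-partition ANFIS by hybrid LS/gradient learning.

    With 5 inputs and 3 memberships each the rule base has 243 rules —
    far more consequent parameters than the 66 treatment means — so the
    consequent least squares is solved as a minimum-norm ridge problem.
    The dimensionless ``ridge`` penalty (scaled by the mean squared design
    row norm) is a numerical stabilizer: small enough that exactly
    representable targets (e.g. linear functions) are recovered to
    near-machine precision.
    """
    Xs, t, scaler, bc, t_range = _prepare(X, y, use_boxcox)
    core = _train_anfis(
        Xs, t, mf_per_input, epochs, seed, ridge, rule_cap, lr, conventional_mf
    )
    return SurrogateModel(
        family="anfis",
        core=core,
        scaler=scaler,
        boxcox=bc,
        hyperparams={"mf_per_input": mf_per_input, "epochs": epochs,
                     "ridge": ridge, "use_boxcox": use_boxcox},
        t_range=t_range,
    )


_FITTERS = {
    "grnn": fit_grnn,
    "mlp": fit_mlp,
    "anfis": fit_anfis,
}


def fit_family(family: str, X, y, params: dict) -> SurrogateModel:
    """Dispatch to a family fitter by name."""
    if family not in _FITTERS:
        raise ModelError(
            f"unknown family '{family}'; valid: {sorted(_FITTERS)}"
        )
    return _FITTERS[family](X, y, **params)


# ---------------------------------------------------------------------------
# Cross-validated evaluation and hyperparameter selection


@dataclass(frozen=True)
class CVReport:
    """Per-fold train/test metrics for one model family on one target."""

    family: str
    frame: pd.DataFrame  # pair, repeat, fold, partition, r2, rmse, mbe, n

    def summary(self) -> pd.DataFrame:
        return self.frame.groupby("partition")[["r2", "rmse", "mbe"]].mean()

    def mean(self, metric: str, partition: str = "test") -> float:
        sel = self.frame[self.frame["partition"] == partition]
        return float(sel[metric].mean())

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def evaluate_cv(
    family: str,
    X,
    y,
    fold_plan: FoldPlan,
    params: dict | None = None,
    *,
    use_boxcox: bool = True,
) -> CVReport:
    """Repeated-k-fold evaluation of one family.

    Transforms (input scaler, target Box-Cox) are fit on the training
    partition of each fold only; metrics are computed in original trait
    units on both partitions. Folds whose fit fails are skipped with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    params = dict(params or {})
    rows = []
    for pid, (train, test) in enumerate(fold_plan):
        repeat, fold = divmod(pid, fold_plan.k)
        fold_params = dict(params)
        if family == "mlp":
            fold_params.setdefault("seed", fold_plan.seed + pid)
        try:
            model = fit_family(
                family, X[train], y[train],
                {**fold_params, "use_boxcox": use_boxcox},
            )
            for partition, idx in (("train", train), ("test", test)):
                m = compute_metrics(y[idx], model.predict(X[idx]))
                rows.append(
                    (pid, repeat, fold, partition, m.r2, m.rmse, m.mbe, m.n)
                )
        except (ModelError, MetricError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"{family}: fold pair {pid} skipped ({exc})", stacklevel=2
            )
    frame = pd.DataFrame(
        rows,
        columns=["pair", "repeat", "fold", "partition", "r2", "rmse", "mbe", "n"],
    )
    return CVReport(family=family, frame=frame)


DEFAULT_SIGMA_GRID = tuple(np.geomspace(0.02, 2.0, 20))


def select_sigma(
    X,
    y,
    fold_plan: FoldPlan,
    grid: Sequence[float] = DEFAULT_SIGMA_GRID,
    *,
    use_boxcox: bool = True,
) -> float:
    """Pick the GRNN width minimizing mean CV test RMSE (ties → smaller σ)."""
    grid = sorted(float(s) for s in grid)
    if not grid:
        raise ModelError("empty sigma grid")
    best_sigma, best_rmse = None, np.inf
    for s in grid:
        report = evaluate_cv(
            "grnn", X, y, fold_plan, {"sigma": s}, use_boxcox=use_boxcox
        )
        rmse = report.mean("rmse", "test")
        if rmse < best_rmse:
            best_sigma, best_rmse = s, rmse
    return best_sigma


def select_hidden_size(
    X,
    y,
    fold_plan: FoldPlan,
    candidates: Sequence[int] = (2, 4, 8, 12),
    *,
    use_boxcox: bool = True,
) -> int:
    """Pick the MLP hidden size maximizing mean CV test R² (ties → smaller)."""
    candidates = sorted(int(c) for c in candidates)
    if not candidates:
        raise ModelError("empty candidate list")
    if candidates[0] < 1 or candidates[-1] > 20:
        raise ModelError("hidden-size candidates must lie in [1, 20]")
    best_size, best_r2 = None, -np.inf
    for c in candidates:
        report = evaluate_cv(
            "mlp", X, y, fold_plan, {"hidden_size": c}, use_boxcox=use_boxcox
        )
        r2 = report.mean("r2", "test")
        if r2 > best_r2:
            best_size, best_r2 = c, r2
    return best_size
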