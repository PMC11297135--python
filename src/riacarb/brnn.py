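"""Bayesian-regularized feed-forward regression ensembles.

Implements MacKay-style Bayesian regularization trained with
Levenberg-Marquardt, the classic ``trainbr`` recipe: the objective is

    F(w) = beta * E_D + alpha * E_W,

with ``E_D`` the sum of squared errors on the (standardized) training
targets and ``E_W`` the sum of squared weights.  After every accepted
Levenberg-Marquardt step the hyperparameters are re-estimated from the
evidence framework:

    gamma = N_w - 2 * alpha * tr(H^-1)
    alpha = gamma / (2 * E_W)
    beta  = (N - gamma) / (2 * E_D)

where ``H = 2*beta*J'J + 2*alpha*I`` is the Gauss-Newton approximation
to the Hessian of F, ``N_w`` the number of weights and ``gamma`` the
effective number of well-determined parameters.  Hidden layers use
tanh, the output is linear, and inputs/targets are standardized on the
training split (the scalers travel with the model).

A proxy model for one target (pH or total alkalinity) is an ensemble
of ten such networks differing only in their weight initialization;
the ensemble prediction is the arithmetic mean of the members, whose
squared error never exceeds the members' average squared error.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fixed feature order fed to the networks
FEATURE_NAMES = [
    "latitude",
    "longitude",
    "depth",
    "temperature",
    "salinity",
    "phosphate",
    "nitrate",
    "silicate",
    "year",
    "week_sin",
    "week_cos",
]

#: table column backing each non-derived feature
_FEATURE_COLUMNS = {
    "latitude": "latitude",
    "longitude": "longitude",
    "depth": "depth_m",
    "temperature": "temperature_c",
    "salinity": "salinity",
    "phosphate": "phosphate_umol_kg",
    "nitrate": "nitrate_umol_kg",
    "silicate": "silicate_umol_kg",
    "year": "year_decimal",
}

TARGET_COLUMNS = {"ph": "ph", "ta": "ta_umol_kg"}

WEEK_PERIOD = 52.0  # weeks; integer ISO week 53 is folded to 52 upstream

ENSEMBLE_SIZE = 10


class EncodingError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


def encode_features(table: pd.DataFrame) -> np.ndarray:
    """Encode table rows as the (n, 11) feature matrix.

    The week-of-year is mapped onto the unit circle,
    ``sin(2*pi*week/52), cos(2*pi*week/52)``, so that week 52 is
    adjacent to week 1; all other predictors pass through unchanged.
    """
    cols = {}
    for feat, col in _FEATURE_COLUMNS.items():
        if col not in table.columns:
            raise EncodingError(f"missing predictor column {col!r}")
        x = np.asarray(table[col], float)
        if not np.all(np.isfinite(x)):
            i = int(np.flatnonzero(~np.isfinite(x))[0])
            raise EncodingError(f"non-finite value for predictor {feat!r} at row {i}")
        cols[feat] = x
    if "week" not in table.columns:
        raise EncodingError("missing predictor column 'week'")
    week = np.asarray(table["week"], float)
    if not np.all(np.isfinite(week)):
        raise EncodingError("non-finite value for predictor 'week'")
    ang = 2.0 * np.pi * week / WEEK_PERIOD
    cols["week_sin"] = np.sin(ang)
    cols["week_cos"] = np.cos(ang)
    return np.column_stack([cols[f] for f in FEATURE_NAMES])


def split_train_test(table: pd.DataFrame, fraction_test: float = 0.10,
                     seed: int = 0):
    """Random disjoint, exhaustive train/test partition of the rows.

    The test-set size is ``round(fraction_test * N)`` with halves
    rounded away from zero (so N = 5755 gives 576 test rows).
    """
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    n_test = int(math.floor(fraction_test * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return table.iloc[train_idx].reset_index(drop=True), table.iloc[test_idx].reset_index(drop=True)


# ----------------------------------------------------------------------
# network plumbing

def _layer_shapes(n_in: int, hidden: list[int]) -> list[tuple[int, int]]:
    sizes = [n_in] + list(hidden) + [1]
    return [(sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]


def _n_weights(n_in: int, hidden: list[int]) -> int:
    return sum(a * b + b for a, b in _layer_shapes(n_in, hidden))


def _unpack(w: np.ndarray, n_in: int, hidden: list[int]):
    params, k = [], 0
    for a, b in _layer_shapes(n_in, hidden):
        W = w[k:k + a * b].reshape(a, b); k += a * b
        c = w[k:k + b]; k += b
        params.append((W, c))
    return params


def _init_weights(n_in: int, hidden: list[int], rng) -> np.ndarray:
    chunks = []
    for a, b in _layer_shapes(n_in, hidden):
        r = math.sqrt(6.0 / (a + b))
        chunks.append(rng.uniform(-r, r, a * b))
        chunks.append(np.zeros(b))
    return np.concatenate(chunks)


def _forward(X: np.ndarray, w: np.ndarray, n_in: int, hidden: list[int]):
    """Forward pass; returns (yhat, activations per hidden layer)."""
    params = _unpack(w, n_in, hidden)
    a = X
    acts = []
    for (W, c) in params[:-1]:
        a = np.tanh(a @ W + c)
        acts.append(a)
    W, c = params[-1]
    y = (a @ W + c).ravel()
    return y, acts


def _jacobian(X: np.ndarray, w: np.ndarray, n_in: int, hidden: list[int]):
    """Network output and its Jacobian d yhat / d w, shape (n, N_w)."""
    params = _unpack(w, n_in, hidden)
    n = X.shape[0]
    acts = [X]
    a = X
    for (W, c) in params[:-1]:
        a = np.tanh(a @ W + c)
        acts.append(a)
    W_out, c_out = params[-1]
    y = (a @ W_out + c_out).ravel()

    # backward pass: delta[l] = d y / d z_l  (pre-activation sensitivities)
    blocks = [None] * len(params)
    blocks[-1] = np.concatenate([acts[-1], np.ones((n, 1))], axis=1)  # dW_out, db_out
    delta = np.ones((n, 1))
    W_next = W_out
    for l in range(len(params) - 2, -1, -1):
        delta = (delta @ W_next.T) * (1.0 - acts[l + 1] ** 2)
        dW = np.einsum("ni,nj->nij", acts[l], delta).reshape(n, -1)
        blocks[l] = np.concatenate([dW, delta], axis=1)
        W_next = params[l][0]
    return y, np.concatenate(blocks, axis=1)


# ----------------------------------------------------------------------

@dataclass
class Metrics:
    """Held-out evaluation metrics, in target units."""
    mae: float
    mse: float
    rmse: float
    r2: float

    def to_dict(self):
        return dataclasses.asdict(self)


def evaluate(predictions, observations) -> Metrics:
    """MAE, MSE, RMSE and r2 = 1 - SS_res/SS_tot about the observation mean.

    Zero observation variance makes r2 undefined; it is flagged as NaN
    rather than raising.
    """
    p = np.asarray(predictions, float)
    o = np.asarray(observations, float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 points to evaluate")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise ValueError("non-finite values in predictions or observations")
    err = p - o
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(err ** 2)) / ss_tot
    return Metrics(mae=mae, mse=mse, rmse=math.sqrt(mse), r2=r2)


@dataclass
class NetworkMember:
    """One trained network plus its scalers and regularization state."""
    hidden: list
    weights: np.ndarray          # flat parameter vector (scaled space)
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    alpha_reg: float             # weight-decay hyperparameter
    beta_reg: float              # noise-precision hyperparameter
    gamma: float                 # effective number of parameters
    seed: int
    n_iter: int
    converged: bool
    gamma_history: list = field(default_factory=list)

    @property
    def n_weights(self) -> int:
        return int(self.weights.size)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.x_center) / self.x_scale
        y, _ = _forward(Xs, self.weights, X.shape[1], list(self.hidden))
        return self.y_center + self.y_scale * y

    def to_dict(self):
        return {
            "hidden": list(self.hidden),
            "weights": self.weights.tolist(),
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_center": self.y_center,
            "y_scale": self.y_scale,
            "alpha_reg": self.alpha_reg,
            "beta_reg": self.beta_reg,
            "gamma": self.gamma,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "gamma_history": list(self.gamma_history),
        }

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["weights"] = np.asarray(d["weights"], float)
        d["x_center"] = np.asarray(d["x_center"], float)
        d["x_scale"] = np.asarray(d["x_scale"], float)
        return cls(**d)


def train_member(X: np.ndarray, y: np.ndarray, hidden, seed: int = 0,
                 max_iter: int = 150, tol: float = 1e-6,
                 mu0: float = 5e-3, mu_max: float = 1e10,
                 log=None) -> NetworkMember:
    """Train one Bayesian-regularized network by Levenberg-Marquardt.

    ``hidden`` is the list of hidden-layer widths; an empty list trains
    a plain linear-in-features model under the same evidence updates
    (used for cross-checking the optimizer against a closed-form ridge
    evidence).  Hyperparameters start at ``alpha=0, beta=1`` and are
    re-estimated every epoch (Foresee-Hagan convention).  Training
    stops at ``max_iter``, when the damping parameter overflows
    ``mu_max``, or when the objective and gamma both stabilize below
    ``tol``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
        raise ValueError("X must be (n, d) with matching non-empty y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    hidden = list(hidden)
    n, d = X.shape

    x_center = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_center = float(y.mean())
    y_scale = float(y.std()) or 1.0
    Xs = (X - x_center) / x_scale
    ys = (y - y_center) / y_scale

    rng = np.random.default_rng(seed)
    w = _init_weights(d, hidden, rng)
    nw = w.size
    alpha, beta = 0.0, 1.0
    mu = mu0
    gamma = float(nw)
    gamma_hist = []
    converged = False
    I = np.eye(nw)

    yhat, J = _jacobian(Xs, w, d, hidden)
    r = ys - yhat
    e_d = float(r @ r)
    e_w = float(w @ w)
    f_obj = beta * e_d + alpha * e_w

    it = 0
    for it in range(1, max_iter + 1):
        if not np.isfinite(f_obj):
            raise TrainingError(f"non-finite objective at epoch {it}")
        g = -2.0 * beta * (J.T @ r) + 2.0 * alpha * w
        JJ = J.T @ J
        # Levenberg-Marquardt inner loop: grow damping until F decreases
        stepped = False
        while mu <= mu_max:
            H_damped = 2.0 * beta * JJ + (2.0 * alpha + mu) * I
            try:
                dw = np.linalg.solve(H_damped, -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            w_new = w + dw
            yhat_new, _ = _forward(Xs, w_new, d, hidden)
            r_new = ys - yhat_new
            e_d_new = float(r_new @ r_new)
            e_w_new = float(w_new @ w_new)
            f_new = beta * e_d_new + alpha * e_w_new
            if np.isfinite(f_new) and f_new < f_obj:
                mu = max(mu * 0.1, 1e-20)
                stepped = True
                break
            mu *= 10.0
        if not stepped:
            converged = True  # damping overflow: no downhill step exists
            break

        e_d_prev, e_w_prev = e_d, e_w
        w = w_new
        yhat, J = _jacobian(Xs, w, d, hidden)
        r = ys - yhat
        e_d = float(r @ r)
        e_w = float(w @ w)

        # evidence re-estimation of (alpha, beta) via the eigenvalues of J'J
        lam = np.linalg.eigvalsh(J.T @ J)
        lam = np.maximum(lam, 0.0)
        tr_hinv = float(np.sum(1.0 / (2.0 * beta * lam + 2.0 * alpha + 1e-300)))
        gamma_new = nw - 2.0 * alpha * tr_hinv
        gamma_new = min(max(gamma_new, 0.0), float(nw))
        alpha_new = gamma_new / max(2.0 * e_w, 1e-300)
        beta_new = max(n - gamma_new, 1e-12) / max(2.0 * e_d, 1e-300)

        d_gamma = abs(gamma_new - gamma)
        # progress is measured on E_D and E_W, not on F: at the evidence
        # fixed point F = beta*E_D + alpha*E_W equals N/2 identically
        rel_de = abs(e_d - e_d_prev) / max(e_d_prev, 1e-300)
        rel_dw = abs(e_w - e_w_prev) / max(e_w_prev, 1e-300)
        gamma, alpha, beta = gamma_new, alpha_new, beta_new
        f_obj = beta * e_d + alpha * e_w
        gamma_hist.append(gamma)
        if log is not None:
            log(epoch=it, f=f_obj, e_d=e_d, e_w=e_w, gamma=gamma,
                alpha=alpha, beta=beta)
        grad_inf = float(np.max(np.abs(-2.0 * beta * (J.T @ r) + 2.0 * alpha * w)))
        if (rel_de < tol and rel_dw < tol
                and d_gamma < max(tol * nw, 1e-6)) or grad_inf < tol:
            converged = True
            break

    return NetworkMember(
        hidden=hidden, weights=w, x_center=x_center, x_scale=x_scale,
        y_center=y_center, y_scale=y_scale, alpha_reg=alpha, beta_reg=beta,
        gamma=gamma, seed=seed, n_iter=it, converged=converged,
        gamma_history=gamma_hist,
    )


def log_evidence(X: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float,
                 beta: float, hidden) -> float:
    """Log model evidence log p(D | alpha, beta) in the Laplace
    approximation around ``w``, in the sum-of-squares convention
    ``F = beta*E_D + alpha*E_W`` (prior precision 2*alpha, noise
    precision 2*beta)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    nw = w.size
    yhat, J = _jacobian(X, w, X.shape[1], list(hidden))
    r = y - yhat
    e_d = float(r @ r)
    e_w = float(w @ w)
    lam = np.maximum(np.linalg.eigvalsh(J.T @ J), 0.0)
    logdet_h = float(np.sum(np.log(2.0 * beta * lam + 2.0 * alpha)))
    return (-beta * e_d - alpha * e_w - 0.5 * logdet_h
            + 0.5 * nw * math.log(2.0 * alpha)
            + 0.5 * n * math.log(beta / math.pi))


# ----------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Ten-member committee for one target variable."""
    target: str                      # "ph" or "ta"
    members: list                    # list[NetworkMember]
    split_seed: int
    member_metrics: list             # list[Metrics], held-out test set
    ensemble_metrics: Metrics
    test_predictions: np.ndarray     # ensemble predictions on the test set
    test_observations: np.ndarray

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        X = encode_features(records)
        return predict_members(self.members, X)

    def to_dict(self):
        return {
            "target": self.target,
            "split_seed": self.split_seed,
            "members": [m.to_dict() for m in self.members],
            "member_metrics": [m.to_dict() for m in self.member_metrics],
            "ensemble_metrics": self.ensemble_metrics.to_dict(),
            "test_predictions": np.asarray(self.test_predictions).tolist(),
            "test_observations": np.asarray(self.test_observations).tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d):
        return cls(
            target=d["target"], split_seed=d["split_seed"],
            members=[NetworkMember.from_dict(m) for m in d["members"]],
            member_metrics=[Metrics(**m) for m in d["member_metrics"]],
            ensemble_metrics=Metrics(**d["ensemble_metrics"]),
            test_predictions=np.asarray(d["test_predictions"], float),
            test_observations=np.asarray(d["test_observations"], float),
        )

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict_members(members, X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the members' de-scaled outputs."""
    preds = np.stack([m.predict(X) for m in members])
    return preds.mean(axis=0)


def train_ensemble(table: pd.DataFrame, target: str, hidden=None,
                   seed: int = 0, n_members: int = ENSEMBLE_SIZE,
                   fraction_test: float = 0.10, max_iter: int = 150,
                   tol: float = 1e-6, log=None) -> EnsembleModel:
    """Train a committee for ``target`` on the labeled rows of ``table``.

    One 90/10 split is shared by all members; the members differ only
    in their weight-initialization seeds, which are fanned out
    deterministically from ``seed``.  Default architectures follow the
    proxy-model design: two hidden layers [28, 10] for pH, one hidden
    layer [40] for TA.
    """
    if target not in TARGET_COLUMNS:
        raise ValueError(f"unknown target {target!r}; expected one of {sorted(TARGET_COLUMNS)}")
    if hidden is None:
        hidden = [28, 10] if target == "ph" else [40]
    col = TARGET_COLUMNS[target]
    labeled = table.loc[np.isfinite(np.asarray(table[col], float))].reset_index(drop=True)
    if len(labeled) < 10:
        raise ValueError(f"too few labeled rows for target {target!r}: {len(labeled)}")

    ss = np.random.SeedSequence(seed)
    split_seed, *member_seeds = [int(s) % (2 ** 31) for s in ss.generate_state(1 + n_members)]
    train_tab, test_tab = split_train_test(labeled, fraction_test, split_seed)
    X_train = encode_features(train_tab)
    y_train = np.asarray(train_tab[col], float)
    X_test = encode_features(test_tab)
    y_test = np.asarray(test_tab[col], float)

    members, member_metrics = [], []
    for i, mseed in enumerate(member_seeds):
        try:
            m = train_member(X_train, y_train, hidden, seed=mseed,
                             max_iter=max_iter, tol=tol, log=log)
        except Exception as exc:
            raise TrainingError(f"member {i + 1}/{n_members} failed: {exc}") from exc
        members.append(m)
        member_metrics.append(evaluate(m.predict(X_test), y_test))

    y_pred = predict_members(members, X_test)
    ens_metrics = evaluate(y_pred, y_test)
    return EnsembleModel(
        target=target, members=members, split_seed=split_seed,
        member_metrics=member_metrics, ensemble_metrics=ens_metrics,
        test_predictions=y_pred, test_observations=y_test,
    )


def predict_ensemble(model: EnsembleModel, records: pd.DataFrame) -> np.ndarray:
    """Ensemble prediction for every row of ``records`` (order preserved)."""
    return model.predict(records)
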