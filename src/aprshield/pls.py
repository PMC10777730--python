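"""Single-response PLS (NIPALS) with LOO-CV component selection, repeated
train/test-split validation, and VIP scores.

Preprocessing is autoscaling (column mean 0, unit variance with ddof=1) of
both X and y; all cross-validation refits the scaling inside each fold.
Coefficients are reported back on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 1000
DEFAULT_PARSIMONY_TOL = 0.02


class ZeroVarianceError(ValueError):
    pass


def autoscale(
    X: np.ndarray, y: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Centre and scale columns of X (and optionally y) to unit variance.

    Returns scaled arrays plus a ``scaler`` dict with the centring/scaling
    vectors; :func:`autoscale_inverse_y` and the stored vectors undo it.
    Raises :class:`ZeroVarianceError` naming the first constant column.
    """
    X = np.asarray(X, dtype=float)
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(x_std == 0)
    if zero.size:
        raise ZeroVarianceError(f"column {zero[0]} has zero variance; remove constant columns")
    Xs = (X - x_mean) / x_std
    scaler = {"x_mean": x_mean, "x_std": x_std}
    ys = None
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        y_mean = float(y.mean())
        y_std = float(y.std(ddof=1))
        if y_std == 0:
            raise ZeroVarianceError("response has zero variance")
        ys = (y - y_mean) / y_std
        scaler["y_mean"] = y_mean
        scaler["y_std"] = y_std
    return Xs, ys, scaler


@dataclass(frozen=True)
class PLSModel:
    """Fitted single-response PLS model.

    Weights/loadings/scores live in the autoscaled space; ``coefficients``
    and ``intercept`` are back-transformed to the original scale so that
    ``predict(X) = X @ coefficients + intercept``.
    """

    n_components: int
    x_weights: np.ndarray      # (p, k)
    x_loadings: np.ndarray     # (p, k)
    y_loadings: np.ndarray     # (k,)
    scores: np.ndarray         # (n, k) training scores
    x_rotations: np.ndarray    # (p, k): W (P'W)^-1
    coefficients: np.ndarray   # (p,) original scale
    intercept: float
    scaler: dict = field(compare=False)
    r2_train: float = 0.0
    feature_names: tuple[str, ...] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.intercept

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Latent scores of (possibly new) samples."""
        X = np.asarray(X, dtype=float)
        Xs = (X - self.scaler["x_mean"]) / self.scaler["x_std"]
        return Xs @ self.x_rotations


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    feature_names: tuple[str, ...] | None = None,
) -> PLSModel:
    """Fit a PLS model by NIPALS with autoscaled X and y.

    For a single response the per-component weight vector has the closed form
    w = X'y / ||X'y||; the NIPALS iteration is retained for generality and
    converges in one pass.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match number of rows of X")
    Xs, ys, scaler = autoscale(X, y)
    rank = np.linalg.matrix_rank(Xs)
    if not (1 <= n_components <= rank):
        raise ValueError(f"n_components must be in 1..rank(X)={rank}, got {n_components}")

    Xd = Xs.copy()
    yd = ys.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = Xd.T @ yd
        for _ in range(NIPALS_MAX_ITER):
            w_norm = np.linalg.norm(w)
            if w_norm == 0:
                raise ValueError("weight vector collapsed to zero; reduce n_components")
            w = w / w_norm
            t = Xd @ w
            tt = float(t @ t)
            q = float(yd @ t) / tt
            w_new = Xd.T @ (yd * q)
            if np.linalg.norm(w_new / np.linalg.norm(w_new) - w) < NIPALS_TOL:
                break
            w = w_new
        t = Xd @ w
        tt = float(t @ t)
        p_vec = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p_vec)
        yd = yd - q * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_vec, q, t

    rotations = W @ np.linalg.inv(P.T @ W)
    b_scaled = rotations @ Q
    coefficients = b_scaled * scaler["y_std"] / scaler["x_std"]
    intercept = scaler["y_mean"] - float(scaler["x_mean"] @ coefficients)
    y_hat = X @ coefficients + intercept
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return PLSModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        x_rotations=rotations,
        coefficients=coefficients,
        intercept=intercept,
        scaler=scaler,
        r2_train=1.0 - ss_res / ss_tot,
        feature_names=feature_names,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Cross-validation summary for one descriptor/response dataset."""

    rmsep_by_components: dict[int, float]
    chosen_k: int
    loo_rmsep: float
    mrep: float | None = None
    split_q2_median: float | None = None
    split_rmse_train_median: float | None = None
    split_rmse_test_median: float | None = None
    n_repetitions: int | None = None
    seed: int | None = None
    n_degenerate_resampled: int = 0
    parameters: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "rmsep_by_components": {str(k): v for k, v in self.rmsep_by_components.items()},
            "chosen_k": self.chosen_k,
            "loo_rmsep": self.loo_rmsep,
            "mrep": self.mrep,
            "split_q2_median": self.split_q2_median,
            "split_rmse_train_median": self.split_rmse_train_median,
            "split_rmse_test_median": self.split_rmse_test_median,
            "n_repetitions": self.n_repetitions,
            "seed": self.seed,
            "n_degenerate_resampled": self.n_degenerate_resampled,
            "parameters": dict(self.parameters),
        }


def _loo_predictions(X: np.ndarray, y: np.ndarray, k_max: int) -> np.ndarray:
    """(n, k_max) matrix of held-out predictions; fold i row predicted by a
    model fit (scaling included) on all other samples, at 1..k_max components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    preds = np.empty((n, k_max))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_pls(X[mask], y[mask], k_max)
        # per-component predictions via sequential deflation of the new sample
        x_def = (X[i] - model.scaler["x_mean"]) / model.scaler["x_std"]
        cumulative = 0.0
        for a in range(k_max):
            t_a = float(x_def @ model.x_weights[:, a])
            x_def = x_def - t_a * model.x_loadings[:, a]
            cumulative += t_a * model.y_loadings[a]
            preds[i, a] = cumulative * model.scaler["y_std"] + model.scaler["y_mean"]
    return preds


def choose_k(rmsep_by_components: dict[int, float], parsimony_tol: float) -> int:
    """Smallest k whose RMSEP is within ``parsimony_tol`` (relative) of the
    global minimum."""
    best = min(rmsep_by_components.values())
    for k in sorted(rmsep_by_components):
        if rmsep_by_components[k] <= best * (1.0 + parsimony_tol):
            return k
    raise AssertionError("unreachable")


def loo_select(
    X: np.ndarray,
    y: np.ndarray,
    k_max: int,
    parsimony_tol: float = DEFAULT_PARSIMONY_TOL,
    *,
    compute_mrep: bool = True,
    mrep_mode: str = "per_observation",
) -> ValidationReport:
    """LOO-CV over 1..k_max components with the parsimony selection rule.

    MREP at the chosen k is mean(|y_hat - y| / y) over folds
    (``mrep_mode='per_observation'``) or mean(|y_hat - y|) / mean(y)
    (``'pooled'``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for LOO-CV")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    # cap so every LOO fold (n-1 samples, centred) can support k components
    k_max = min(k_max, int(np.linalg.matrix_rank(autoscale(X)[0])), n - 2, X.shape[1])
    preds = _loo_predictions(X, y, k_max)
    rmsep = {
        k: float(np.sqrt(((preds[:, k - 1] - y) ** 2).mean())) for k in range(1, k_max + 1)
    }
    chosen = choose_k(rmsep, parsimony_tol)
    mrep = None
    if compute_mrep:
        residuals = np.abs(preds[:, chosen - 1] - y)
        if mrep_mode == "per_observation":
            if np.any(y == 0):
                raise ValueError("MREP per observation undefined: y contains zeros")
            mrep = float((residuals / np.abs(y)).mean())
        elif mrep_mode == "pooled":
            mrep = float(residuals.mean() / np.abs(y).mean())
        else:
            raise ValueError(f"unknown mrep_mode {mrep_mode!r}")
    return ValidationReport(
        rmsep_by_components=rmsep,
        chosen_k=chosen,
        loo_rmsep=rmsep[chosen],
        mrep=mrep,
        parameters={"parsimony_tol": parsimony_tol, "k_max": k_max, "mrep_mode": mrep_mode},
    )


def repeated_split(
    X: np.ndarray,
    y: np.ndarray,
    k_max: int,
    n_reps: int = 1000,
    train_fraction: float = 0.8,
    parsimony_tol: float = DEFAULT_PARSIMONY_TOL,
    seed: int = 0,
    fixed_k: int | None = None,
) -> ValidationReport:
    """Repeated random 0.8/0.2 split validation.

    Per repetition: split, choose k by LOO-CV on the training portion (or use
    ``fixed_k``), fit, predict the held-out portion, and record
    Q^2 = 1 - SS_res / SS_tot with the training mean in the denominator.
    Medians over repetitions are reported.  Degenerate partitions (constant
    training response) are resampled and counted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    n_train = int(round(train_fraction * n))
    if n - n_train < 2:
        raise ValueError("test partition must have at least 2 members")
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(n_reps)
    q2s = np.empty(n_reps)
    rmse_train = np.empty(n_reps)
    rmse_test = np.empty(n_reps)
    n_degenerate = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(children[rep])
        for _ in range(100):
            perm = rng.permutation(n)
            train_idx, test_idx = perm[:n_train], perm[n_train:]
            if np.std(y[train_idx]) > 0:
                break
            n_degenerate += 1
        else:
            raise RuntimeError("could not draw a non-degenerate partition")
        X_train, y_train = X[train_idx], y[train_idx]
        X_test, y_test = X[test_idx], y[test_idx]
        if fixed_k is None:
            report = loo_select(
                X_train, y_train, k_max, parsimony_tol, compute_mrep=False
            )
            k = report.chosen_k
        else:
            k = fixed_k
        model = fit_pls(X_train, y_train, k)
        y_hat_test = model.predict(X_test)
        y_hat_train = model.predict(X_train)
        ss_res = float(((y_test - y_hat_test) ** 2).sum())
        ss_tot = float(((y_test - y_train.mean()) ** 2).sum())
        q2s[rep] = 1.0 - ss_res / ss_tot
        rmse_train[rep] = float(np.sqrt(((y_train - y_hat_train) ** 2).mean()))
        rmse_test[rep] = float(np.sqrt(((y_test - y_hat_test) ** 2).mean()))
    return ValidationReport(
        rmsep_by_components={},
        chosen_k=fixed_k if fixed_k is not None else 0,
        loo_rmsep=float("nan"),
        split_q2_median=float(np.median(q2s)),
        split_rmse_train_median=float(np.median(rmse_train)),
        split_rmse_test_median=float(np.median(rmse_test)),
        n_repetitions=n_reps,
        seed=seed,
        n_degenerate_resampled=n_degenerate,
        parameters={
            "train_fraction": train_fraction,
            "k_max": k_max,
            "parsimony_tol": parsimony_tol,
            "fixed_k": fixed_k,
            "q2_convention": "training-set mean in denominator",
        },
    )


def vip(model: PLSModel) -> dict[str, float] | np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 t_a' t_a.  Squared scores sum to p.
    """
    W = model.x_weights
    T = model.scores
    q = model.y_loadings
    p = W.shape[0]
    ssy = q**2 * (T**2).sum(axis=0)
    w_norm2 = (W**2).sum(axis=0)
    contrib = (W**2 / w_norm2) @ ssy
    scores = np.sqrt(p * contrib / ssy.sum())
    if model.feature_names is not None:
        return dict(zip(model.feature_names, scores.tolist()))
    return scores


def latent_export(
    model: PLSModel,
    X: np.ndarray,
    compound_ids: list[str] | None = None,
) -> dict:
    """Per-compound latent coordinates plus per-descriptor loadings."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.x_weights.shape[0]:
        raise ValueError(
            f"descriptor mismatch: model has {model.x_weights.shape[0]} descriptors, "
            f"input has {X.shape[1]}"
        )
    scores = model.transform(X)
    out = {
        "scores": scores,
        "loadings": model.x_loadings,
        "n_components": model.n_components,
    }
    if compound_ids is not None:
        out["compound_ids"] = list(compound_ids)
    if model.feature_names is not None:
        out["feature_names"] = list(model.feature_names)
    return out
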