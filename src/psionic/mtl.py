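"""Multitask inference of TF activities with shared latent regulatory programs.

Each sample (task) t has a linear model w_t mapping TF motif features to
expression; the models are tied through a factorization W = L S, where the
columns of L (TF × K) are latent regulatory programs and s_t weights them
per sample. The joint cost is

    min_{L,S}  sum_t (1/N) ||y_t - X L s_t||^2  +  mu ||S||_1  +  lambda ||L||_F^2

minimized by alternating exact sub-problem solves: the S-step is T
independent lasso problems (cyclic coordinate descent), the L-step a
closed-form ridge system. The single-task baseline (STL) fits one ridge
model per sample with no sharing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso


class FitDivergenceError(RuntimeError):
    """The alternating objective increased; indicates a solver bug."""


@dataclass
class PsionicModel:
    """Fitted latent-program model: W = L S."""

    L: np.ndarray                      # d x K latent regulatory programs
    S: np.ndarray                      # K x T sample weights
    mu: float
    lam: float
    tf_ids: list[str]
    sample_ids: list[str]
    n_iter: int = 0
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int | None = None

    @property
    def K(self) -> int:
        return self.L.shape[1]

    @property
    def T(self) -> int:
        return self.S.shape[1]

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def activities(self) -> pd.DataFrame:
        """Inferred TF activity matrix W = L S (TF × sample)."""
        return pd.DataFrame(self.L @ self.S, index=self.tf_ids, columns=self.sample_ids)

    # serialization hooks used by psionic.io
    def params_dict(self) -> dict:
        return {"mu": self.mu, "lam": self.lam, "K": self.K}

    def metadata_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "final_objective": self.final_objective,
            "seed": self.seed,
        }

    def arrays_dict(self) -> dict:
        return {"L": self.L, "S": self.S, "objective_trace": self.objective_trace}

    @classmethod
    def from_serialized(cls, manifest: dict, arrays: dict) -> "PsionicModel":
        return cls(
            L=arrays["L"],
            S=arrays["S"],
            mu=manifest["params"]["mu"],
            lam=manifest["params"]["lam"],
            tf_ids=manifest["tf_ids"],
            sample_ids=manifest["sample_ids"],
            n_iter=manifest["metadata"]["n_iter"],
            objective_trace=arrays["objective_trace"],
            seed=manifest["metadata"]["seed"],
        )


@dataclass
class StlModel:
    """Per-sample ridge baseline: independent w_t, no sharing."""

    W: np.ndarray                      # d x T ridge coefficients
    lam_ridge: float
    tf_ids: list[str]
    sample_ids: list[str]

    def activities(self) -> pd.DataFrame:
        return pd.DataFrame(self.W, index=self.tf_ids, columns=self.sample_ids)

    def params_dict(self) -> dict:
        return {"lam_ridge": self.lam_ridge}

    def metadata_dict(self) -> dict:
        return {}

    def arrays_dict(self) -> dict:
        return {"W": self.W}

    @classmethod
    def from_serialized(cls, manifest: dict, arrays: dict) -> "StlModel":
        return cls(
            W=arrays["W"],
            lam_ridge=manifest["params"]["lam_ridge"],
            tf_ids=manifest["tf_ids"],
            sample_ids=manifest["sample_ids"],
        )


def _as_arrays(X, Y) -> tuple[np.ndarray, np.ndarray]:
    Xa = np.asarray(X, dtype=float)
    Ya = np.asarray(Y, dtype=float)
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError(f"X has {Xa.shape[0]} gene rows but Y has {Ya.shape[0]}")
    return Xa, Ya


def objective(L, S, X, Y, mu: float, lam: float) -> float:
    """Joint cost: sum_t (1/N)||y_t - X L s_t||^2 + mu||S||_1 + lam||L||_F^2."""
    X, Y = _as_arrays(X, Y)
    L = np.asarray(L, dtype=float)
    S = np.asarray(S, dtype=float)
    for name, arr in (("L", L), ("S", S), ("X", X), ("Y", Y)):
        if not np.isfinite(arr).all():
            raise ValueError(f"non-finite values in {name}")
    N = X.shape[0]
    resid = Y - X @ (L @ S)
    loss = float(np.sum(resid ** 2)) / N
    return loss + mu * float(np.abs(S).sum()) + lam * float(np.sum(L ** 2))


def update_S(L, X, Y, mu: float, tol: float = 1e-12, max_iter: int = 100_000) -> np.ndarray:
    """Exact S-step: per task, s_t = argmin (1/N)||y_t - (XL)s||^2 + mu||s||_1.

    Solved by cyclic coordinate descent (scikit-learn Lasso; its
    (1/2N)-scaled loss maps onto this cost with alpha = mu/2). mu = 0 falls
    back to least squares.
    """
    if mu < 0:
        raise ValueError("mu must be nonnegative")
    X, Y = _as_arrays(X, Y)
    A = X @ np.asarray(L, dtype=float)
    K, T = A.shape[1], Y.shape[1]
    S = np.empty((K, T))
    if mu == 0:
        S[:] = np.linalg.lstsq(A, Y, rcond=None)[0]
        return S
    model = Lasso(alpha=mu / 2.0, fit_intercept=False, tol=tol, max_iter=max_iter,
                  selection="cyclic")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny tol
        for t in range(T):
            model.fit(A, Y[:, t])
            S[:, t] = model.coef_
    return S


def update_L(S, X, Y, lam: float) -> np.ndarray:
    """Exact L-step: minimizer of sum_t (1/N)||y_t - X L s_t||^2 + lam||L||_F^2.

    The stationarity condition is the Sylvester-type system
    G L M + lam L = B with G = X'X/N, M = S S', B = X'Y S'/N; solved in
    closed form through the eigendecomposition of M (one d×d ridge solve
    per latent program).
    """
    X, Y = _as_arrays(X, Y)
    S = np.asarray(S, dtype=float)
    N, d = X.shape
    G = X.T @ X / N
    M = S @ S.T
    B = X.T @ Y @ S.T / N
    evals, Q = np.linalg.eigh(M)
    evals = np.clip(evals, 0.0, None)
    Bt = B @ Q
    Lt = np.empty_like(Bt)
    eye = np.eye(d)
    for k in range(S.shape[0]):
        A = evals[k] * G + lam * eye
        if lam <= 0:
            if np.linalg.matrix_rank(A) < d:
                raise np.linalg.LinAlgError(
                    "L-step system is rank deficient; use lambda > 0"
                )
        Lt[:, k] = np.linalg.solve(A, Bt[:, k]) if lam > 0 or evals[k] > 0 else 0.0
    return Lt @ Q.T


def fit_stl_ridge(X, Y, lam_ridge: float,
                  tf_ids: Sequence[str] | None = None,
                  sample_ids: Sequence[str] | None = None) -> StlModel:
    """Per-task ridge: w_t = argmin (1/N)||y_t - X w||^2 + lam ||w||^2.

    Closed form (X'X/N + lam I)^-1 X'Y/N, shared across tasks.
    """
    if lam_ridge < 0:
        raise ValueError("lam_ridge must be nonnegative")
    if isinstance(X, pd.DataFrame) and tf_ids is None:
        tf_ids = list(X.columns)
    if isinstance(Y, pd.DataFrame) and sample_ids is None:
        sample_ids = list(Y.columns)
    Xa, Ya = _as_arrays(X, Y)
    N, d = Xa.shape
    G = Xa.T @ Xa / N + lam_ridge * np.eye(d)
    if lam_ridge == 0 and np.linalg.matrix_rank(G) < d:
        raise np.linalg.LinAlgError("X'X singular and lam_ridge = 0; increase lam_ridge")
    W = np.linalg.solve(G, Xa.T @ Ya / N)
    return StlModel(
        W=W,
        lam_ridge=lam_ridge,
        tf_ids=list(tf_ids) if tf_ids is not None else [f"tf_{j}" for j in range(d)],
        sample_ids=list(sample_ids) if sample_ids is not None
        else [f"s_{t}" for t in range(Ya.shape[1])],
    )


def init_from_stl(X, Y, lam_ridge: float, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Initialize (L, S) from the rank-K SVD of the single-task solution.

    W_stl = U Sigma V'; L = U_K Sigma_K^{1/2}, S = Sigma_K^{1/2} V_K', so
    L S is the best rank-K approximation of W_stl. K beyond the rank pads
    zero programs with a warning.
    """
    W = fit_stl_ridge(X, Y, lam_ridge).W
    U, sv, Vt = np.linalg.svd(W, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size else 0
    k_eff = min(K, len(sv))
    if K > rank:
        warnings.warn(f"K={K} exceeds rank {rank} of the STL solution; padding with zeros")
    root = np.sqrt(sv[:k_eff])
    L = np.zeros((W.shape[0], K))
    S = np.zeros((K, W.shape[1]))
    L[:, :k_eff] = U[:, :k_eff] * root
    S[:k_eff, :] = root[:, None] * Vt[:k_eff, :]
    return L, S


def fit_psionic(
    X,
    Y,
    K: int,
    mu: float = 1e-3,
    lam: float = 1e-3,
    init: str | tuple[np.ndarray, np.ndarray] = "stl",
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    init_ridge: float = 0.01,
) -> PsionicModel:
    """Fit the joint model by alternating S- and L-steps.

    Stops when the relative objective change drops below ``tol`` or after
    ``max_iter`` outer iterations. The objective trace is recorded and must
    be non-increasing; a repeated increase raises :class:`FitDivergenceError`.
    """
    tf_ids = list(X.columns) if isinstance(X, pd.DataFrame) else None
    sample_ids = list(Y.columns) if isinstance(Y, pd.DataFrame) else None
    Xa, Ya = _as_arrays(X, Y)
    N, d = Xa.shape
    T = Ya.shape[1]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > min(d, T):
        warnings.warn(f"K={K} exceeds min(d, T)={min(d, T)}; clipping")
        K = min(d, T)

    if isinstance(init, tuple):
        L, S = (np.array(init[0], dtype=float), np.array(init[1], dtype=float))
    elif init == "stl":
        L, S = init_from_stl(Xa, Ya, init_ridge, K)
    elif init == "random":
        rng = np.random.default_rng(seed)
        L = rng.standard_normal((d, K)) / np.sqrt(d)
        S = rng.standard_normal((K, T)) / np.sqrt(K)
    else:
        raise ValueError(f"unknown init {init!r}")

    trace = [objective(L, S, Xa, Ya, mu, lam)]
    increases = 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        S = update_S(L, Xa, Ya, mu)
        L = update_L(S, Xa, Ya, lam)
        obj = objective(L, S, Xa, Ya, mu, lam)
        prev = trace[-1]
        trace.append(obj)
        rel = (obj - prev) / max(abs(prev), 1e-300)
        if rel > 1e-8:
            increases += 1
            if increases >= 2:
                raise FitDivergenceError(
                    f"objective increased at iteration {n_iter} (rel {rel:.2e})"
                )
        if abs(prev - obj) <= tol * max(abs(prev), 1e-300):
            break
    return PsionicModel(
        L=L, S=S, mu=mu, lam=lam,
        tf_ids=tf_ids if tf_ids is not None else [f"tf_{j}" for j in range(d)],
        sample_ids=sample_ids if sample_ids is not None else [f"s_{t}" for t in range(T)],
        n_iter=n_iter,
        objective_trace=np.array(trace),
        seed=seed,
    )


def predict(X_new, model) -> pd.DataFrame | np.ndarray:
    """Predicted expression Y_hat = X_new W for a fitted model (either kind)."""
    W = model.L @ model.S if isinstance(model, PsionicModel) else model.W
    if isinstance(X_new, pd.DataFrame):
        missing = [t for t in model.tf_ids if t not in X_new.columns]
        extra = [c for c in X_new.columns if c not in set(model.tf_ids)]
        if missing or extra:
            raise ValueError(
                f"feature labels do not match model TFs (missing {missing[:5]}, "
                f"unexpected {extra[:5]})"
            )
        Xa = X_new[model.tf_ids].to_numpy(dtype=float)
        return pd.DataFrame(Xa @ W, index=X_new.index, columns=model.sample_ids)
    Xa = np.asarray(X_new, dtype=float)
    if Xa.shape[1] != W.shape[0]:
        raise ValueError(f"X_new has {Xa.shape[1]} features; model expects {W.shape[0]}")
    return Xa @ W


def infer_activities(model) -> pd.DataFrame:
    """TF activity matrix W (TF × sample) with labels attached."""
    return model.activities()


def grid_search_hyperparams(
    X,
    Y,
    K: int,
    mu_grid: Sequence[float] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0),
    lam_grid: Sequence[float] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0),
    val_frac: float = 0.2,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[float, float]:
    """Pick (mu, lam) by held-out-gene validation inside the training genes.

    A seeded gene split is shared across the grid; the pair with the lowest
    mean validation squared error wins (ties to the sparser, then smoother,
    choice).
    """
    Xa, Ya = _as_arrays(X, Y)
    rng = np.random.default_rng(seed)
    n = Xa.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n)))
    val, train = perm[:n_val], perm[n_val:]
    best = None
    for mu in sorted(mu_grid, reverse=True):
        for lam in sorted(lam_grid, reverse=True):
            model = fit_psionic(Xa[train], Ya[train], K, mu=mu, lam=lam,
                                seed=seed, **fit_kwargs)
            err = float(np.mean((Ya[val] - Xa[val] @ (model.L @ model.S)) ** 2))
            if best is None or err < best[0] - 1e-15:
                best = (err, mu, lam)
    return best[1], best[2]
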