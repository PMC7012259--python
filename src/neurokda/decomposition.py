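"""Dictionary decomposition of feature matrices via augmented Lagrangians.

Training features ``X`` (M x N, columns = subjects) are split into a
class-specific part ``A``, a non-class-specific part ``B @ beta`` and a
sparse error ``E`` by solving

    min  ||A||_* + mu ||B||_* + gamma ||beta||_F^2 + tau ||E||_1
    s.t. X = A + B beta + E

with an inexact augmented Lagrange multiplier (ALM) scheme: one proximal
pass per variable per outer iteration, a multiplier update, and geometric
growth of the penalty.  The class-specific dictionary ``A`` keeps one
column per training subject (the training codes over ``A`` are pinned to
the identity), so each column of ``A`` inherits its subject's label.

A test vector ``y`` is then coded against the learned dictionaries by

    min  ||alpha||_1 + gamma ||beta||_2^2 + tau ||eps||_1
    s.t. y = A alpha + B beta + eps

again by ALM with soft-threshold steps for ``alpha``/``eps`` and a
closed-form ridge step for ``beta``.  The class-specific reconstruction
``A alpha`` is what the downstream classifier consumes; ``B beta``
(shared acquisition/processing variation) and ``eps`` are discarded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .features import FeatureMatrix

__all__ = [
    "DecompParams",
    "DecompModel",
    "TestCode",
    "soft_threshold",
    "svt",
    "train_decompose",
    "test_decompose",
    "class_component",
    "objective_value",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class DecompParams:
    """Balance and solver parameters of the decomposition program.

    ``mu`` weights the nuclear norm of B, ``gamma`` the squared Frobenius
    norm of the confound codes, ``tau`` the L1 norm of the sparse error
    (default ``1/sqrt(max(M, N))``, resolved at fit time).  ``n_atoms``
    is the number of columns of B (default ``min(M, N)``).
    """

    mu: float = 1.0
    gamma: float = 1.0
    tau: float | None = None
    n_atoms: int | None = None
    rho_init: float | None = None
    rho_scale: float = 1.2
    rho_max: float = 1e7
    tol: float = 1e-7
    max_iter: int = 500
    seed: int = 0
    init: str = "svd"

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.gamma <= 0:
            raise ValueError(f"mu and gamma must be > 0, got mu={self.mu}, gamma={self.gamma}")
        if self.tau is not None and self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.rho_scale <= 1:
            raise ValueError(f"rho_scale must be > 1, got {self.rho_scale}")
        if self.tol <= 0:
            raise ValueError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")

    def resolve(self, M: int, N: int) -> "DecompParams":
        """Fill shape-dependent defaults for an M x N problem."""
        tau = self.tau if self.tau is not None else 1.0 / np.sqrt(max(M, N))
        d = self.n_atoms if self.n_atoms is not None else min(M, N)
        if not (1 <= d):
            raise ValueError(f"n_atoms must be >= 1, got {d}")
        return DecompParams(
            mu=self.mu, gamma=self.gamma, tau=float(tau), n_atoms=int(d),
            rho_init=self.rho_init, rho_scale=self.rho_scale, rho_max=self.rho_max,
            tol=self.tol, max_iter=self.max_iter, seed=self.seed, init=self.init,
        )


@dataclass
class DecompModel:
    """Learned dictionaries, training codes, sparse error and history."""

    A: np.ndarray               # M x N class-specific dictionary
    B: np.ndarray               # M x d non-class-specific dictionary
    beta_train: np.ndarray      # d x N training confound codes
    E: np.ndarray               # M x N sparse training error
    labels: np.ndarray          # per-column labels of A
    params: DecompParams
    history: dict[str, list[float]]
    converged: bool
    residual: float

    @property
    def n_features(self) -> int:
        return self.A.shape[0]

    @property
    def n_train(self) -> int:
        return self.A.shape[1]


@dataclass
class TestCode:
    """Sparse code of one test sample against a fitted model."""

    alpha: np.ndarray           # length-N code over class-specific atoms
    beta: np.ndarray            # length-d confound code
    eps: np.ndarray             # length-M sparse residual
    objective: float
    residual: float
    converged: bool
    history: dict[str, list[float]] = field(default_factory=dict)


def soft_threshold(x: np.ndarray | float, t: float) -> np.ndarray | float:
    """Elementwise soft threshold ``sign(x) * max(|x| - t, 0)``."""
    if t < 0:
        raise ValueError(f"threshold must be >= 0, got {t}")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - t, 0.0)
    return out if out.ndim else float(out)


def svt(Mx: np.ndarray, t: float) -> np.ndarray:
    """Singular value thresholding, the proximal operator of ``t * ||.||_*``."""
    if t < 0:
        raise ValueError(f"threshold must be >= 0, got {t}")
    Mx = np.asarray(Mx, dtype=float)
    if not np.all(np.isfinite(Mx)):
        raise ValueError("svt requires a finite matrix")
    U, s, Vt = linalg.svd(Mx, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    keep = s > 0
    if not np.any(keep):
        return np.zeros_like(Mx)
    return (U[:, keep] * s[keep]) @ Vt[keep]


def nuclear_norm(Mx: np.ndarray) -> float:
    return float(linalg.svdvals(Mx).sum())


def objective_value(
    A: np.ndarray, B: np.ndarray, beta: np.ndarray, E: np.ndarray, params: DecompParams
) -> float:
    """Value of the training objective at an arbitrary point."""
    p = params.resolve(A.shape[0], A.shape[1])
    return (
        nuclear_norm(A)
        + p.mu * nuclear_norm(B)
        + p.gamma * float(np.sum(beta**2))
        + p.tau * float(np.abs(E).sum())
    )


def _prox_factored_product(s: np.ndarray, c: float, rho: float) -> np.ndarray:
    """Prox of ``t -> c * t**(2/3)`` at ``s`` under penalty ``rho``.

    Solves ``min_{t >= 0} c t^(2/3) + (rho/2)(t - s)^2`` per entry.  The
    stationarity condition ``rho (t - s) + (2c/3) t^(-1/3) = 0`` has its
    local minimum at the larger root, bracketed between the inflection
    point ``(2c/(9 rho))^(3/4)`` and ``s``; we bisect and compare against
    the boundary candidate t = 0.
    """
    out = np.zeros_like(s)
    if c <= 0:
        return np.maximum(s, 0.0)
    t_inf = (2.0 * c / (9.0 * rho)) ** 0.75
    for i, si in enumerate(s):
        if si <= 0:
            continue
        def phi(t: float) -> float:
            return rho * (t - si) + (2.0 * c / 3.0) * t ** (-1.0 / 3.0)
        if t_inf >= si or phi(t_inf) >= 0:
            continue  # no interior stationary point below s: t = 0
        lo, hi = t_inf, si
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if phi(mid) > 0:
                hi = mid
            else:
                lo = mid
        t = 0.5 * (lo + hi)
        if c * t ** (2.0 / 3.0) + 0.5 * rho * (t - si) ** 2 < 0.5 * rho * si**2:
            out[i] = t
    return out


def _split_product(
    U: np.ndarray, t: np.ndarray, Vt: np.ndarray, mu: float, gamma: float, d: int
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal factorization of ``Z = U diag(t) Vt`` into ``B @ beta``.

    Per direction with product amplitude t, the cheapest split under
    ``mu ||B||_* + gamma ||beta||_F^2`` puts ``b = (2 gamma t^2 / mu)^(1/3)``
    into B and ``t / b`` into beta.  Directions beyond the atom budget d
    are dropped (t is sorted descending by the SVD).
    """
    M = U.shape[0]
    N = Vt.shape[1]
    B = np.zeros((M, d))
    beta = np.zeros((d, N))
    nz = np.flatnonzero(t)
    if nz.size > d:  # keep the d largest product amplitudes
        nz = nz[np.argsort(t[nz])[::-1][:d]]
    if nz.size:
        tk = t[nz]
        b = (2.0 * gamma * tk**2 / mu) ** (1.0 / 3.0)
        B[:, : nz.size] = U[:, nz] * b
        beta[: nz.size] = (tk / b)[:, None] * Vt[nz]
    return B, beta


def _spectral_resplit(
    A: np.ndarray, B: np.ndarray, beta: np.ndarray, p: DecompParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reassign the low-rank part ``L = A + B beta`` along its own SVD.

    Each singular direction of L is placed wholly in A (cost sigma) or
    wholly in ``B beta`` (cost ``c sigma^(2/3)``), whichever is cheaper;
    the split is all-or-nothing because the mixed cost is concave in the
    transferred amplitude.  Feasibility is untouched (L is preserved), so
    this exit polish can only lower the objective -- it undoes unlucky
    assignments made while the ALM penalty was still small.
    """
    d = int(p.n_atoms)  # type: ignore[arg-type]
    L = A + B @ beta
    if not np.any(L):
        return A, B, beta
    U, s, Vt = linalg.svd(L, full_matrices=False)
    crossover = 27.0 / 4.0 * p.mu**2 * p.gamma
    to_B = s > crossover
    if to_B.sum() > d:  # atom budget: keep only the d largest in B
        cut = np.sort(s[to_B])[::-1][d - 1]
        to_B &= s >= cut
    t = np.where(to_B, s, 0.0)
    B_new, beta_new = _split_product(U, t, Vt, p.mu, p.gamma, d)
    A_new = (U * np.where(to_B, 0.0, s)) @ Vt
    return A_new, B_new, beta_new


def train_decompose(X: FeatureMatrix | np.ndarray, params: DecompParams | None = None) -> DecompModel:
    """Learn class-specific and confound dictionaries by inexact ALM.

    The bilinear term ``B beta`` is updated jointly: for a fixed product
    ``Z = B beta`` the best factorization costs
    ``c * sum_i sigma_i(Z)^(2/3)`` with ``c = 3 mu^(2/3) gamma^(1/3) / 2^(2/3)``,
    so the (B, beta) step is a spectral prox of that penalty on the
    residual (solved per singular value), followed by the closed-form
    split of each retained direction between B and beta.  Joint updates
    avoid the degenerate absorbing state of naive alternating steps,
    where an early all-zero B can never regrow.  Deterministic given the
    parameters; if the relative constraint residual does not reach
    ``tol`` within ``max_iter`` the model is returned flagged
    non-converged.
    """
    if params is None:
        params = DecompParams()
    if isinstance(X, FeatureMatrix):
        labels = X.labels
        X = X.X
    else:
        X = np.asarray(X, dtype=float)
        labels = np.zeros(X.shape[1], dtype=int)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("training matrix must be 2D with at least 2 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("training matrix contains non-finite values")
    M, N = X.shape
    p = params.resolve(M, N)
    d = int(p.n_atoms)  # type: ignore[arg-type]

    norm_fro = linalg.norm(X)
    if norm_fro == 0.0:
        zero_hist = {"objective": [0.0], "residual": [0.0]}
        return DecompModel(
            A=np.zeros((M, N)), B=np.zeros((M, d)), beta_train=np.zeros((d, N)),
            E=np.zeros((M, N)), labels=labels, params=p, history=zero_hist,
            converged=True, residual=0.0,
        )
    spectral = linalg.svdvals(X)[0]
    rho = p.rho_init if p.rho_init is not None else 1.0 / spectral

    # deterministic warm start: B from the leading singular subspace of X
    if p.init == "random":
        rng = np.random.default_rng(p.seed)
        B = rng.normal(0.0, 1.0 / np.sqrt(M), size=(M, d))
        beta = linalg.lstsq(B, X, lapack_driver="gelsd")[0]
    else:
        U, s, Vt = linalg.svd(X, full_matrices=False)
        B, beta = _split_product(U, s, Vt, p.mu, p.gamma, d)
    A = np.zeros((M, N))
    E = np.zeros((M, N))
    Y = np.zeros((M, N))
    c_split = 3.0 * p.mu ** (2.0 / 3.0) * p.gamma ** (1.0 / 3.0) / 2.0 ** (2.0 / 3.0)

    history: dict[str, list[float]] = {"objective": [], "residual": []}
    converged = False
    rel = np.inf
    for _ in range(p.max_iter):
        # A step: full nuclear prox of the residual
        A = svt(X - B @ beta - E + Y / rho, 1.0 / rho)
        # joint (B, beta) step: spectral prox of the factored-product
        # penalty on the residual, then the optimal split
        G = X - A - E + Y / rho
        U, s, Vt = linalg.svd(G, full_matrices=False)
        t = _prox_factored_product(s, c_split, rho)
        B, beta = _split_product(U, t, Vt, p.mu, p.gamma, d)
        # E step: elementwise soft threshold
        E = soft_threshold(X - A - B @ beta + Y / rho, p.tau / rho)  # type: ignore[arg-type]
        resid = X - A - B @ beta - E
        Y = Y + rho * resid
        rho = min(rho * p.rho_scale, p.rho_max)
        rel = float(linalg.norm(resid) / norm_fro)
        history["residual"].append(rel)
        history["objective"].append(objective_value(A, B, beta, E, p))
        if rel <= p.tol:
            converged = True
            break

    A, B, beta = _spectral_resplit(A, B, beta, p)
    history["objective"].append(objective_value(A, B, beta, E, p))
    resid = X - A - B @ beta - E
    rel = float(linalg.norm(resid) / norm_fro)
    history["residual"].append(rel)
    converged = converged and rel <= p.tol

    return DecompModel(
        A=A, B=B, beta_train=beta, E=E, labels=labels, params=p,
        history=history, converged=converged, residual=rel,
    )


def test_decompose(
    y: np.ndarray,
    model: DecompModel,
    tol: float = 1e-8,
    max_iter: int = 5000,
    rho: float | None = None,
) -> TestCode:
    """Code a test sample against fitted dictionaries by ALM.

    Alternates a linearized soft-threshold step on ``alpha`` (proximal
    gradient through ``A``), a closed-form ridge step on ``beta`` and an
    exact soft-threshold step on ``eps``, with multiplier updates at a
    fixed penalty ``rho`` (the coding problem is jointly convex, so the
    fixed-penalty iteration converges to the global optimum; growing the
    penalty would freeze the iterate at a merely feasible point).  Stops
    once the relative equality residual is below ``tol`` and the
    objective has stabilized.
    """
    y = np.asarray(y, dtype=float).ravel()
    A, B = model.A, model.B
    M, N = A.shape
    d = B.shape[1]
    if y.shape[0] != M:
        raise ValueError(f"test vector length {y.shape[0]} does not match feature dim {M}")
    p = model.params
    gamma, tau = p.gamma, float(p.tau)  # type: ignore[arg-type]

    ynorm = float(np.linalg.norm(y))
    if ynorm == 0.0:
        return TestCode(
            alpha=np.zeros(N), beta=np.zeros(d), eps=np.zeros(M),
            objective=0.0, residual=0.0, converged=True,
        )

    AtA = A.T @ A
    La = max(float(linalg.svdvals(AtA)[0]) if AtA.size else 0.0, 1e-12)
    BtB = B.T @ B
    if rho is None:
        rho = np.sqrt(M) / ynorm
    ridge = linalg.cho_factor(BtB + (2.0 * gamma / rho) * np.eye(d))

    alpha = np.zeros(N)
    beta = np.zeros(d)
    eps = np.zeros(M)
    lam = np.zeros(M)
    history: dict[str, list[float]] = {"objective": [], "residual": []}
    converged = False
    rel = np.inf
    denom = max(ynorm, 1.0)
    prev_obj = np.inf
    for _ in range(max_iter):
        q = y - B @ beta - eps + lam / rho
        grad = A.T @ (A @ alpha - q)
        alpha = soft_threshold(alpha - grad / La, 1.0 / (rho * La))  # type: ignore[assignment]
        r = y - A @ alpha - eps + lam / rho
        beta = linalg.cho_solve(ridge, B.T @ r)
        eps = soft_threshold(y - A @ alpha - B @ beta + lam / rho, tau / rho)  # type: ignore[assignment]
        resid = y - A @ alpha - B @ beta - eps
        lam = lam + rho * resid
        rel = float(np.linalg.norm(resid) / denom)
        obj = float(np.abs(alpha).sum() + gamma * np.dot(beta, beta) + tau * np.abs(eps).sum())
        history["residual"].append(rel)
        history["objective"].append(obj)
        if rel <= tol and abs(obj - prev_obj) <= 1e-10 * max(obj, 1.0):
            converged = True
            break
        prev_obj = obj

    obj = float(np.abs(alpha).sum() + gamma * np.dot(beta, beta) + tau * np.abs(eps).sum())
    return TestCode(
        alpha=alpha, beta=beta, eps=eps, objective=obj,
        residual=rel, converged=converged, history=history,
    )


def class_component(code: TestCode, model: DecompModel) -> np.ndarray:
    """Class-specific reconstruction ``A @ alpha`` of a coded test sample.

    For training subjects the class-specific component is, by
    construction, the corresponding column of ``A`` itself.
    """
    return model.A @ code.alpha


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def save_model(model: DecompModel, path: str | Path) -> None:
    """Serialize a fitted model (matrices + params + history) to one archive."""
    meta = {
        "schema": SCHEMA_VERSION,
        "params": asdict(model.params),
        "history": model.history,
        "converged": bool(model.converged),
        "residual": model.residual,
    }
    np.savez_compressed(
        str(path), A=model.A, B=model.B, beta_train=model.beta_train, E=model.E,
        labels=model.labels, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> DecompModel:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        if meta["schema"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {meta['schema']}")
        return DecompModel(
            A=z["A"], B=z["B"], beta_train=z["beta_train"], E=z["E"],
            labels=z["labels"], params=DecompParams(**meta["params"]),
            history=meta["history"], converged=meta["converged"],
            residual=meta["residual"],
        )
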