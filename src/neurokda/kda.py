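"""Kernel discriminant analysis in spectral-regression form, plus NN.

Given class-specific components of training subjects, a Gaussian-kernel
discriminant projection is fitted by spectral regression: the
discriminant directions of the regularized kernel Rayleigh quotient

    max_a  (a^T K W K a) / (a^T (K K + delta K) a)

are recovered by (1) solving a small C x C eigenproblem for the response
vectors, which live in the span of the class indicators (W is the
block-constant class-graph matrix with entries 1/N_l inside class l),
then (2) a ridge-regularized kernel regression ``(K + delta I) a = v``.
Because the nonzero spectrum of the pencil (KWK, K(K + delta I)) is
confined to the indicator span, this two-step procedure attains the
dense generalized-eigensolver optimum exactly, for any delta >= 0 with
K nonsingular.  Test samples are embedded through the kernel projective
function ``f(x) = sum_i a_i K(x_i, x)`` and classified by one nearest
neighbor in the embedded space.

A cardinality-constrained variant (restrict the coefficient vector to k
nonzeros) is provided with greedy forward selection plus one backward
sweep, and exhaustive search for small problems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "KernelSpec",
    "KDAModel",
    "SparseKDAResult",
    "gaussian_kernel",
    "resolve_sigma",
    "class_graph",
    "srkda_fit",
    "sparse_kda",
    "project",
    "nn_classify",
]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel with a fixed bandwidth or the median heuristic."""

    kind: str = "gaussian"
    sigma: float | str = "median"

    def __post_init__(self) -> None:
        if self.kind != "gaussian":
            raise ValueError(f"unsupported kernel kind {self.kind!r}")
        if isinstance(self.sigma, str):
            if self.sigma != "median":
                raise ValueError(f"sigma must be a positive number or 'median', got {self.sigma!r}")
        elif self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class KDAModel:
    """Fitted spectral-regression KDA model.

    ``coeffs`` holds the C-1 discriminant coefficient vectors (columns);
    ``coeffs_all`` additionally includes the non-discriminative direction
    dominated by the all-ones response, whose quotient is the global
    optimum of the regularized Rayleigh quotient.
    """

    kernel: KernelSpec
    sigma: float
    train_points: np.ndarray        # M x N (feature columns)
    K: np.ndarray                   # N x N kernel matrix
    W: np.ndarray                   # N x N class-graph matrix
    coeffs: np.ndarray              # N x (C-1) discriminant directions
    coeffs_all: np.ndarray          # N x C all spectral directions
    quotients: np.ndarray           # length-C Rayleigh quotients (desc order)
    delta: float
    embedded_train: np.ndarray      # (C-1) x N projected training points
    labels: np.ndarray

    @property
    def n_train(self) -> int:
        return self.train_points.shape[1]


@dataclass
class SparseKDAResult:
    """Cardinality-constrained discriminant direction on a support."""

    support: np.ndarray
    coeffs_on_support: np.ndarray
    quotient: float
    skipped_supports: int = 0


def gaussian_kernel(P: np.ndarray, Q: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix ``exp(-||p_i - q_j||^2 / (2 sigma^2))``.

    ``P`` and ``Q`` hold points as columns (feature dim x count).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if P.shape[0] != Q.shape[0]:
        raise ValueError(f"feature dims differ: {P.shape[0]} vs {Q.shape[0]}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    d2 = cdist(P.T, Q.T, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def resolve_sigma(P: np.ndarray, spec: KernelSpec) -> float:
    """Resolve a kernel bandwidth: fixed value or median pairwise distance."""
    if not isinstance(spec.sigma, str):
        return float(spec.sigma)
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[1] < 2:
        raise ValueError("median bandwidth needs at least 2 points")
    dists = pdist(P.T)
    med = float(np.median(dists))
    if med > 0:
        return med
    positive = dists[dists > 0]
    if positive.size == 0:
        raise ValueError("all points identical; median bandwidth undefined")
    return float(np.median(positive))


def class_graph(labels: np.ndarray) -> np.ndarray:
    """Block-constant class-graph matrix: W_ij = 1/N_l iff i,j in class l."""
    labels = np.asarray(labels, dtype=int)
    N = labels.shape[0]
    W = np.zeros((N, N))
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        W[np.ix_(idx, idx)] = 1.0 / idx.size
    return W


def srkda_fit(
    components: np.ndarray,
    labels: np.ndarray,
    kernel: KernelSpec | None = None,
    delta: float | None = None,
) -> KDAModel:
    """Fit spectral-regression KDA on training class-specific components.

    ``components`` is M x N with one column per subject.  ``delta``
    defaults to ``0.01 * trace(K) / N`` (scale-aware ridge).  Responses
    are the eigenvectors of the class-indicator-restricted pencil
    operator; coefficients solve ``(K + delta I) a = v``.  Embeddings are
    sign-fixed (higher class label => higher mean) and scaled to unit
    variance so they are invariant to response normalization.
    """
    components = np.atleast_2d(np.asarray(components, dtype=float))
    labels = np.asarray(labels, dtype=int)
    N = components.shape[1]
    if labels.shape != (N,):
        raise ValueError("labels length must match number of component columns")
    classes = np.unique(labels)
    C = classes.size
    if C < 2:
        raise ValueError(f"KDA needs at least 2 classes, got {C}")
    if kernel is None:
        kernel = KernelSpec()
    sigma = resolve_sigma(components, kernel)
    K = gaussian_kernel(components, components, sigma)
    if delta is None:
        delta = 0.01 * float(np.trace(K)) / N
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    W = class_graph(labels)

    # reduced C x C symmetric eigenproblem on the class-indicator span
    U = np.zeros((N, C))
    counts = np.zeros(C)
    for j, lab in enumerate(classes):
        U[labels == lab, j] = 1.0
        counts[j] = np.sum(labels == lab)
    try:
        KinvU = linalg.solve(K + delta * np.eye(N), U, assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - needs degenerate K
        raise ValueError(
            "kernel system (K + delta I) is singular; increase delta"
        ) from exc
    Q = U.T @ (K @ KinvU)                       # U^T K (K+dI)^{-1} U, symmetric
    Q = 0.5 * (Q + Q.T)
    Dhalf = np.sqrt(counts)
    T = Q / np.outer(Dhalf, Dhalf)
    evals, evecs = linalg.eigh(T)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    ones = np.ones(N)
    responses = U @ (evecs / Dhalf[:, None])    # eigen responses, class-constant
    coeffs_all = linalg.solve(K + delta * np.eye(N), responses, assume_a="pos")
    # drop the trivial direction: the response most aligned with all-ones
    cos = np.abs(ones @ responses) / (np.linalg.norm(responses, axis=0) * np.sqrt(N) + 1e-300)
    trivial = int(np.argmax(cos))
    keep = [j for j in range(C) if j != trivial][: C - 1]
    coeffs = coeffs_all[:, keep].copy()

    embedded = coeffs.T @ K                     # (C-1) x N
    # scale-free normalization: unit variance, higher class => higher mean
    for r in range(embedded.shape[0]):
        sd = embedded[r].std()
        if sd > 0:
            embedded[r] /= sd
            coeffs[:, r] /= sd
        hi = embedded[r][labels == classes[-1]].mean()
        lo = embedded[r][labels == classes[0]].mean()
        if hi < lo:
            embedded[r] *= -1.0
            coeffs[:, r] *= -1.0

    quotients = np.array([
        _rayleigh_quotient(coeffs_all[:, j], K, W, delta) for j in range(C)
    ])
    return KDAModel(
        kernel=kernel, sigma=sigma, train_points=components, K=K, W=W,
        coeffs=coeffs, coeffs_all=coeffs_all, quotients=quotients,
        delta=float(delta), embedded_train=embedded, labels=labels,
    )


def _rayleigh_quotient(a: np.ndarray, K: np.ndarray, W: np.ndarray, delta: float) -> float:
    Ka = K @ a
    num = float(Ka @ (W @ Ka))
    den = float(Ka @ Ka + delta * (a @ Ka))
    return num / den if den > 0 else 0.0


def project(model: KDAModel, components: np.ndarray) -> np.ndarray:
    """Embed test components via ``f(x) = sum_i a_i K(x_i, x)``.

    Returns a ``(C-1) x n_test`` array; projecting the training points
    reproduces ``embedded_train`` exactly.
    """
    components = np.atleast_2d(np.asarray(components, dtype=float))
    if components.shape[0] != model.train_points.shape[0]:
        raise ValueError(
            f"component dim {components.shape[0]} does not match "
            f"training dim {model.train_points.shape[0]}"
        )
    Kcross = gaussian_kernel(model.train_points, components, model.sigma)
    return model.coeffs.T @ Kcross


def nn_classify(
    model: KDAModel,
    embedded_test: np.ndarray,
    positive_label: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One-nearest-neighbor classification with a margin ranking score.

    Predictions use Euclidean distance in the embedded space, ties broken
    by lowest training index.  For binary problems the score is
    ``d(nearest negative) - d(nearest positive)`` (large = positive-like),
    the continuous output used for AUC; for >2 classes scores are NaN.
    """
    embedded_test = np.atleast_2d(np.asarray(embedded_test, dtype=float))
    if embedded_test.shape[0] != model.embedded_train.shape[0]:
        raise ValueError("embedded dimension mismatch with training embedding")
    n_test = embedded_test.shape[1]
    if n_test == 0:
        return np.empty(0, dtype=int), np.empty(0)
    D = cdist(embedded_test.T, model.embedded_train.T)
    nearest = np.argmin(D, axis=1)              # argmin takes the lowest index on ties
    pred = model.labels[nearest]

    classes = np.unique(model.labels)
    if classes.size == 2:
        pos = positive_label if positive_label is not None else int(classes.max())
        pos_cols = model.labels == pos
        d_pos = D[:, pos_cols].min(axis=1)
        d_neg = D[:, ~pos_cols].min(axis=1)
        scores = d_neg - d_pos
    else:
        scores = np.full(n_test, np.nan)
    return pred, scores


# ---------------------------------------------------------------------------
# cardinality-constrained (sparse) KDA
# ---------------------------------------------------------------------------

def _support_quotient(Akwk: np.ndarray, Bkk: np.ndarray, support: tuple[int, ...]):
    """Max generalized eigenpair of the support's principal submatrices."""
    idx = np.asarray(support, dtype=int)
    Ak = Akwk[np.ix_(idx, idx)]
    Bk = Bkk[np.ix_(idx, idx)]
    try:
        evals, evecs = linalg.eigh(Ak, Bk)
    except linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(evals)):
        return None
    j = int(np.argmax(evals))
    return float(evals[j]), evecs[:, j]


def sparse_kda(K: np.ndarray, W: np.ndarray, k: int, mode: str = "greedy") -> SparseKDAResult:
    """Maximize the kernel discriminant Rayleigh quotient under card(a)=k.

    The quotient ``(a^T KWK a) / (a^T KK a)`` restricted to a support S
    equals the top generalized eigenvalue of the principal submatrices
    ``(KWK)_S, (KK)_S``.  ``greedy`` grows the support by forward
    selection and applies one backward-elimination (swap) sweep; ``exact``
    enumerates all supports (N <= 20 only).  Supports with a singular
    metric submatrix are skipped and counted.
    """
    K = np.asarray(K, dtype=float)
    W = np.asarray(W, dtype=float)
    N = K.shape[0]
    if not (1 <= k <= N):
        raise ValueError(f"cardinality k={k} out of range [1, {N}]")
    Akwk = K @ W @ K
    Bkk = K @ K
    skipped = 0

    if mode == "exact":
        if N > 20:
            raise ValueError(f"exact mode limited to N <= 20, got N={N}")
        best = None
        for support in itertools.combinations(range(N), k):
            res = _support_quotient(Akwk, Bkk, support)
            if res is None:
                skipped += 1
                continue
            if best is None or res[0] > best[0]:
                best = (res[0], support, res[1])
        if best is None:
            raise ValueError("every candidate support had a singular metric submatrix")
        quot, support, vec = best
        return SparseKDAResult(np.asarray(support), vec, quot, skipped)

    if mode != "greedy":
        raise ValueError(f"mode must be 'greedy' or 'exact', got {mode!r}")

    support: list[int] = []
    best_vec = None
    best_quot = -np.inf
    for _ in range(k):
        cand_best = None
        for j in range(N):
            if j in support:
                continue
            res = _support_quotient(Akwk, Bkk, tuple(support + [j]))
            if res is None:
                skipped += 1
                continue
            if cand_best is None or res[0] > cand_best[0]:
                cand_best = (res[0], j, res[1])
        if cand_best is None:
            raise ValueError("forward selection found no nonsingular support extension")
        best_quot, j, best_vec = cand_best
        support.append(j)

    # one backward-elimination sweep: try swapping each member for an outsider
    for i in list(support):
        improved = None
        for j in range(N):
            if j in support:
                continue
            trial = tuple(sorted(s for s in support if s != i)) + (j,)
            res = _support_quotient(Akwk, Bkk, tuple(sorted(trial)))
            if res is None:
                skipped += 1
                continue
            if res[0] > best_quot + 1e-12 and (improved is None or res[0] > improved[0]):
                improved = (res[0], j, res[1])
        if improved is not None:
            best_quot, j, best_vec = improved
            support.remove(i)
            support.append(j)

    order = np.argsort(support)
    support_arr = np.asarray(support)[order]
    res = _support_quotient(Akwk, Bkk, tuple(support_arr))
    assert res is not None
    return SparseKDAResult(support_arr, res[1], res[0], skipped)
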