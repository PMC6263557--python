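"""Signature extraction from a spectra matrix: NMF, PCA, and matching.

The spectra matrix M (N samples x 96 subtypes) is modeled as a
non-negative linear combination of K mutational signatures:
``M ~ W H`` with loadings W (N x K) and signatures H (K x 96), both
non-negative.  The factorization minimizes the Frobenius reconstruction
error ``||M - WH||_F`` by the classic multiplicative update rules from
seeded random initialization; the objective is provably non-increasing
under these updates, which the fit diagnostics record and downstream
tests assert.  After convergence each signature is normalized to a
probability distribution over the 96 subtypes (row sum 1) and loadings
are rescaled so the product is unchanged.

PCA (column-centered, via scikit-learn) is offered as an exploratory
complement; its components are not non-negative and so lack the direct
mutational-process interpretation of NMF signatures.

``match_signatures`` pairs inferred with reference signatures greedily
by descending cosine similarity, the standard way recovered signatures
are compared against a known catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .spectra import SpectraMatrix
from .subtypes import N_SUBTYPES

_EPS = 1e-9


class DecompositionError(ValueError):
    pass


@dataclass
class SignatureSet:
    """K signatures, each a probability distribution over 96 subtypes."""

    labels: list[str]
    matrix: np.ndarray  # (K, 96), rows sum to 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_SUBTYPES:
            raise DecompositionError(
                f"signature matrix must be K x {N_SUBTYPES}, got {self.matrix.shape}"
            )
        if len(self.labels) != self.matrix.shape[0]:
            raise DecompositionError("signature label count mismatch")
        if (self.matrix < 0).any():
            raise DecompositionError("signatures must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise DecompositionError("each signature row must sum to 1")

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


@dataclass
class LoadingsMatrix:
    """Per-sample non-negative signature contributions (N x K)."""

    row_labels: list[str]
    signature_labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.row_labels), len(self.signature_labels)):
            raise DecompositionError("loadings shape does not match labels")
        if (self.matrix < 0).any():
            raise DecompositionError("loadings must be non-negative")


@dataclass
class NmfDiagnostics:
    objective: list[float]  # per-iteration Frobenius error of the kept run
    converged: bool
    n_iter: int
    restart_objectives: list[float] = field(default_factory=list)

    @property
    def final_objective(self) -> float:
        return self.objective[-1]


@dataclass
class PcaResult:
    components: np.ndarray  # (n_components, 96) subtype weights
    scores: np.ndarray  # (N, n_components)
    explained_variance_ratio: np.ndarray
    row_labels: list[str]


def _frobenius(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    return float(np.linalg.norm(V - W @ H))


def _mu_run(
    V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    n, s = V.shape
    # uniform (0,1] init; the epsilon floor in the updates keeps entries
    # from being absorbed at exactly zero
    W = 1.0 - rng.random((n, k))
    H = 1.0 - rng.random((k, s))
    objective = [_frobenius(V, W, H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = _frobenius(V, W, H)
        objective.append(obj)
        prev = objective[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
    return W, H, objective, converged, it


def nmf(
    M: SpectraMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    restarts: int = 1,
) -> tuple[SignatureSet, LoadingsMatrix, NmfDiagnostics]:
    """Factor a spectra matrix into K signatures and per-sample loadings.

    Multiplicative-update NMF under the Frobenius objective, from seeded
    uniform random initialization.  ``restarts`` independent runs are
    performed (seeds derived from ``seed``) and the best final objective
    kept — the updates only find local minima.  Deterministic: the same
    matrix, ``k`` and ``seed`` give bitwise-identical factors.
    """
    V = np.asarray(M.counts, dtype=float)
    n = V.shape[0]
    if not 1 <= k <= min(n, N_SUBTYPES):
        raise DecompositionError(
            f"rank k={k} outside valid range [1, {min(n, N_SUBTYPES)}]"
        )
    if not V.any():
        raise DecompositionError("cannot factor an all-zero spectra matrix")
    if restarts < 1:
        raise DecompositionError("restarts must be >= 1")

    best = None
    restart_objectives = []
    for r in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        W, H, objective, converged, n_iter = _mu_run(V, k, rng, max_iter, tol)
        restart_objectives.append(objective[-1])
        if best is None or objective[-1] < best[2][-1]:
            best = (W, H, objective, converged, n_iter)
    W, H, objective, converged, n_iter = best

    # normalize signatures to probability rows; fold the scale into W
    row_sums = H.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    H = H / row_sums[:, None]
    W = W * row_sums[None, :]

    labels = [f"S{i + 1}" for i in range(k)]
    signatures = SignatureSet(labels, H)
    loadings = LoadingsMatrix(list(M.row_labels), labels, W)
    diagnostics = NmfDiagnostics(
        objective=objective,
        converged=converged,
        n_iter=n_iter,
        restart_objectives=restart_objectives,
    )
    return signatures, loadings, diagnostics


def rank_scan(
    M: SpectraMatrix, ks: list[int], seed: int = 0, **kwargs
) -> dict[int, float]:
    """Relative reconstruction error per candidate rank, to guide the
    user's choice of K (no automatic selection is attempted)."""
    norm = float(np.linalg.norm(np.asarray(M.counts, dtype=float)))
    out = {}
    for k in ks:
        _, _, diag = nmf(M, k, seed=seed, **kwargs)
        out[k] = diag.final_objective / norm if norm else 0.0
    return out


def pca(
    M: SpectraMatrix, n_components: int | None = None, proportions: bool = False
) -> PcaResult:
    """Column-centered PCA of the spectra matrix.

    ``proportions`` first normalizes each row to sum 1, removing
    per-sample mutation-burden differences before looking for structure.
    """
    X = np.asarray(M.counts, dtype=float)
    if X.shape[0] < 2:
        raise DecompositionError("PCA needs at least two samples")
    if proportions:
        sums = X.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        X = X / sums
    max_comp = min(X.shape)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise DecompositionError(
            f"n_components={n_components} outside [1, {max_comp}]"
        )
    fit = PCA(n_components=n_components, svd_solver="full")
    scores = fit.fit_transform(X)
    ratios = fit.explained_variance_ratio_
    # an all-identical-rows matrix has zero total variance; report zeros
    ratios = np.where(np.isfinite(ratios), ratios, 0.0)
    if np.allclose(fit.explained_variance_, 0.0):
        ratios = np.zeros_like(ratios)
    return PcaResult(
        components=fit.components_,
        scores=scores,
        explained_variance_ratio=ratios,
        row_labels=list(M.row_labels),
    )


@dataclass
class Matching:
    """Greedy pairing of inferred to reference signatures."""

    pairs: list[tuple[int, int, float]]  # (inferred idx, reference idx, cosine)

    @property
    def mean_similarity(self) -> float:
        return float(np.mean([s for _, _, s in self.pairs]))

    def as_labels(
        self, inferred: SignatureSet, reference: SignatureSet
    ) -> list[tuple[str, str, float]]:
        return [
            (inferred.labels[i], reference.labels[j], s) for i, j, s in self.pairs
        ]


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), _EPS)
    return An @ Bn.T


def match_signatures(inferred: SignatureSet, reference: SignatureSet) -> Matching:
    """Assign each inferred signature to a distinct reference signature,
    greedily by descending cosine similarity (ties broken by inferred
    index, then reference index — deterministic)."""
    if inferred.matrix.shape[1] != reference.matrix.shape[1]:
        raise DecompositionError("signature sets have different subtype dimensions")
    sims = cosine_similarity_matrix(inferred.matrix, reference.matrix)
    order = sorted(
        ((i, j) for i in range(sims.shape[0]) for j in range(sims.shape[1])),
        key=lambda ij: (-sims[ij], ij[0], ij[1]),
    )
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs = []
    for i, j in order:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j, float(sims[i, j])))
        if len(used_i) == min(sims.shape):
            break
    pairs.sort(key=lambda p: p[0])
    return Matching(pairs)
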