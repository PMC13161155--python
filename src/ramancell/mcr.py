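"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Resolves a spectra matrix X (cells × channels) into non-negative
concentrations C (cells × k) and pure-component spectra S (k × channels)
under the bilinear model X ≈ C·S.  The rank is suggested from the elbow of
the singular-value spectrum, initial pure spectra come from SIMPLISMA
pure-variable selection (Windig determinant formulation, 10% noise default),
and the ALS alternates exact non-negative least-squares subproblem solves
(max 50 iterations, 0.1% relative change of the residual standard deviation).

Scale ambiguity is fixed by max-normalizing each S row and absorbing the
scale into C; components are reported in descending total-concentration
order.  Permutation ambiguity is resolved for testing by
:func:`match_components`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .errors import DataError, LabelError, ParameterError


@dataclass
class MCRModel:
    C: np.ndarray                # samples × k, >= 0
    S: np.ndarray                # k × channels, >= 0, rows max-normalized
    explained_variance: float
    lack_of_fit: float
    n_iter: int
    converged: bool
    rsd_history: np.ndarray | None = None


@dataclass
class RankDiagnostics:
    singular_values: np.ndarray
    suggested_rank: int
    method: str = "elbow"


@dataclass
class ComponentGroupStats:
    component: int
    means: dict[str, float]
    sds: dict[str, float]
    p_value: float
    test_used: str
    stars: str


def select_rank_svd(matrix: np.ndarray) -> RankDiagnostics:
    """Suggest the chemical rank at the largest elbow of the log singular values.

    The elbow is the index maximizing the second difference of the log
    singular-value spectrum — the point where signal singular values give
    way to the noise floor.  The full spectrum is returned for inspection
    and the suggestion is overridable downstream.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if X.size == 0:
        raise DataError("cannot rank an empty matrix")
    s = np.linalg.svd(X, compute_uv=False)
    if s.size < 3:
        return RankDiagnostics(s, 1)
    floor = max(s[0], 1.0) * np.finfo(float).eps
    logs = np.log(np.maximum(s, floor))
    d2 = logs[:-2] - 2.0 * logs[1:-1] + logs[2:]
    rank = int(np.argmax(d2)) + 1  # d2[i] is curvature at singular value i+1
    return RankDiagnostics(s, max(rank, 1))


def simplisma(
    matrix: np.ndarray,
    n_components: int,
    noise_percent: float = 10.0,
) -> np.ndarray:
    """SIMPLISMA pure-variable initial estimate of the pure spectra.

    Channels are the variables (spectral-direction mode).  The purity of
    channel j is σⱼ/(μⱼ + α) with the noise offset α = (noise_percent/100)·
    max(μ); after each selection the purity is deflated by the
    determinant-based independence weight of the candidate against the
    already-chosen pure variables, so successive selections are mutually
    independent.  The chosen channels' intensity columns act as the initial
    concentration profiles, and the returned S_init (k × channels) is their
    least-squares spectral estimate clipped at zero.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = X.shape
    if n_components > p:
        raise ParameterError(
            f"n_components={n_components} exceeds channel count {p}"
        )
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    alpha = (noise_percent / 100.0) * mu.max()
    purity = sigma / (mu + alpha)
    # scaled data for the correlation-around-origin (COO) matrix
    lam = np.sqrt(mu**2 + (sigma + alpha) ** 2)
    lam[lam == 0] = 1.0
    D = X / (np.sqrt(n) * lam)
    coo = D.T @ D  # p × p, built lazily below via selected columns only

    selected: list[int] = []
    for _ in range(n_components):
        weights = np.empty(p)
        if not selected:
            weights[:] = 1.0
        else:
            sub = coo[np.ix_(selected, selected)]
            cols = coo[np.ix_(selected, range(p))]
            for j in range(p):
                m = np.empty((len(selected) + 1, len(selected) + 1))
                m[0, 0] = coo[j, j]
                m[0, 1:] = cols[:, j]
                m[1:, 0] = cols[:, j]
                m[1:, 1:] = sub
                weights[j] = max(np.linalg.det(m), 0.0)
        score = weights * purity
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))

    C_init = X[:, selected]
    S_init, *_ = np.linalg.lstsq(C_init, X, rcond=None)
    S_init = np.clip(S_init, 0.0, None)
    for r in range(n_components):
        m = S_init[r].max()
        if m <= 0:  # degenerate direction: fall back to the pure channel itself
            S_init[r] = 0.0
            S_init[r, selected[r]] = 1.0
        else:
            S_init[r] /= m
    return S_init


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x_i - b_i|| s.t. x_i >= 0 for every column b_i of B.

    Fast path: unconstrained least squares first; only columns with negative
    entries are re-solved exactly with NNLS (identical solution where the
    unconstrained optimum is already feasible).
    """
    sol, *_ = np.linalg.lstsq(A, B, rcond=None)
    bad = np.nonzero((sol < 0).any(axis=0))[0]
    for j in bad:
        sol[:, j], _ = nnls(A, B[:, j])
    return sol


def mcr_als_fit(
    matrix: np.ndarray,
    S_init: np.ndarray,
    max_iter: int = 50,
    tol: float = 0.001,
) -> MCRModel:
    """Alternating exact non-negative least squares from an initial S.

    Stops when the relative change of the residual standard deviation
    ``||X − C·S||_F / sqrt(#elements)`` drops below ``tol`` (default 0.1%)
    or after ``max_iter`` iterations.  Because every subproblem is solved
    exactly, the residual is monotone non-increasing.
    """
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    S = np.atleast_2d(np.asarray(S_init, dtype=float)).copy()
    if S.shape[1] != X.shape[1]:
        raise ParameterError(
            f"S_init has {S.shape[1]} channels, matrix has {X.shape[1]}"
        )
    if np.any(S.max(axis=1) <= 0):
        raise ParameterError("S_init contains an all-zero (or non-positive) row")
    n_el = X.size
    prev_rsd = None
    converged = False
    history = []
    C = np.zeros((X.shape[0], S.shape[0]))
    it = 0
    for it in range(1, max_iter + 1):
        C = _nnls_rows(S.T, X.T).T          # C-update, rows of X
        S = _nnls_rows(C, X)                 # S-update, columns of X
        if np.all(S.max(axis=1) <= 0) or np.all(C.max(axis=0) <= 0):
            break
        rsd = float(np.linalg.norm(X - C @ S) / np.sqrt(n_el))
        history.append(rsd)
        if prev_rsd is not None and prev_rsd > 0:
            if abs(prev_rsd - rsd) / prev_rsd < tol:
                converged = True
                prev_rsd = rsd
                break
        prev_rsd = rsd
    # fix scale: S rows max-normalized, scale absorbed into C
    for r in range(S.shape[0]):
        m = S[r].max()
        if m > 0:
            S[r] /= m
            C[:, r] *= m
    # report components in descending total-concentration order
    order = np.argsort(-C.sum(axis=0), kind="stable")
    C, S = C[:, order], S[order]
    ev = explained_variance(X, C, S)
    lof = float(np.sqrt(max(0.0, 1.0 - ev)))
    return MCRModel(C, S, ev, lof, it, converged, np.array(history))


def explained_variance(matrix: np.ndarray, C_or_model, S: np.ndarray | None = None) -> float:
    """Fraction of the data's total sum of squares captured: 1 − ‖X−CS‖²/‖X‖²."""
    X = np.atleast_2d(np.asarray(matrix, dtype=float))
    if S is None:
        model: MCRModel = C_or_model
        C, S = model.C, model.S
    else:
        C = np.asarray(C_or_model, dtype=float)
    denom = float(np.sum(X**2))
    if denom == 0:
        return float("nan")
    resid = float(np.sum((X - C @ S) ** 2))
    return 1.0 - resid / denom


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-300)
    return An @ Bn.T


def match_components(S_est: np.ndarray, S_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign estimated to reference components by maximal total cosine similarity.

    Exhaustive over permutations for k ≤ 6 (guaranteed optimum), Hungarian
    assignment beyond.  Returns ``perm`` with ``S_est[perm[r]]`` matching
    ``S_ref[r]``, plus the per-pair cosine similarities.
    """
    S_est = np.atleast_2d(S_est)
    S_ref = np.atleast_2d(S_ref)
    if S_est.shape[0] != S_ref.shape[0]:
        raise ParameterError(
            f"component count mismatch: {S_est.shape[0]} vs {S_ref.shape[0]}"
        )
    sim = _cosine_matrix(S_ref, S_est)  # ref × est
    k = sim.shape[0]
    if k <= 6:
        best, best_total = None, -np.inf
        for perm in itertools.permutations(range(k)):
            total = sum(sim[r, perm[r]] for r in range(k))
            if total > best_total:
                best, best_total = perm, total
        perm = np.array(best)
    else:
        from scipy.optimize import linear_sum_assignment

        _, cols = linear_sum_assignment(-sim)
        perm = cols
    sims = np.array([sim[r, perm[r]] for r in range(k)])
    return perm, sims


def compare_component_scores(model: MCRModel, meta) -> list[ComponentGroupStats]:
    """Per-component group comparison of the resolved concentrations.

    ``meta`` is a list of SampleMeta (or an array of group labels) aligned
    with the rows of ``model.C``.  Uses the normality/variance test-selection
    rule from :mod:`ramancell.peaks`.
    """
    from .peaks import group_compare, significance_stars

    groups = np.array([m.group if hasattr(m, "group") else str(m) for m in meta])
    present = sorted(set(groups.tolist()) - {"UNKNOWN"})
    if len(present) != 2:
        raise LabelError(f"need exactly two groups, got {present}")
    a, b = present
    out = []
    for r in range(model.C.shape[1]):
        va, vb = model.C[groups == a, r], model.C[groups == b, r]
        p, test = group_compare(va, vb)
        out.append(
            ComponentGroupStats(
                component=r,
                means={a: float(va.mean()), b: float(vb.mean())},
                sds={a: float(va.std(ddof=1)), b: float(vb.std(ddof=1))},
                p_value=p,
                test_used=test,
                stars=significance_stars(p),
            )
        )
    return out
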