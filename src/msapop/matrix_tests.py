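"""Permutation tests on distance matrices and small contingency tables.

The Mantel test correlates the off-diagonal entries of two distance
matrices over the same individuals and assesses significance by jointly
permuting rows and columns of the second matrix.  The partial Mantel
variant first residualizes both matrices' off-diagonals on a third
(control) matrix by simple linear regression and permutes the
residualized first matrix (the Smouse-Long-Sokal scheme), which gives
better type-I control under confounding than raw-matrix permutation.

Soil-difference matrices translate a site-level environmental variable
into an individual-level distance matrix (each individual carries its
site mean), the form in which habitat enters the Mantel analyses.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .band import SoilTable

__all__ = [
    "MantelResult",
    "ContingencyResult",
    "mantel",
    "partial_mantel",
    "soil_difference_matrix",
    "offdiag_correlation",
    "chi2_2x2",
]

log = logging.getLogger(__name__)

EXACT_ENUMERATION_MAX_N = 7


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str
    exact: bool = False
    degenerate: bool = False


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    p: float
    method: str


def _square(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return np.asarray(d.data, dtype=float)
    a = np.asarray(d, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    return a


def _check_same_ids(*mats) -> None:
    ids = [tuple(m.ids) for m in mats if isinstance(m, DistanceMatrix)]
    if ids and any(i != ids[0] for i in ids):
        raise ValueError("distance matrices must share the same ids in the same order")


def _offdiag(A: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(A.shape[0], 1)
    return A[iu]


def _tail_count(r_perm: float, r_obs: float, tail: str) -> bool:
    if tail == "upper":
        return r_perm >= r_obs
    if tail == "lower":
        return r_perm <= r_obs
    if tail == "two":
        return abs(r_perm) >= abs(r_obs)
    raise ValueError(f"unknown tail {tail!r}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    return float(np.clip(xc @ yc / denom, -1.0, 1.0))


def mantel(
    A,
    B,
    n_perm: int = 10000,
    tail: str = "upper",
    seed: int | None = None,
    exact: bool | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the n(n-1)/2 off-diagonal pairs; the
    null distribution jointly permutes rows and columns of ``B``.  For
    n <= 7 an exhaustive enumeration over all n! permutations is used when
    ``exact`` is None or True; otherwise Monte-Carlo with the add-one rule.
    """
    _check_same_ids(*(m for m in (A, B) if isinstance(m, DistanceMatrix)))
    a = _square(A)
    b = _square(B)
    n = a.shape[0]
    if b.shape[0] != n:
        raise ValueError("matrices must have the same size")
    if n < 4:
        raise ValueError("mantel needs n >= 4")
    va = _offdiag(a)
    if np.allclose(va, va[0]) or np.allclose(_offdiag(b), _offdiag(b)[0]):
        raise ValueError("constant off-diagonal: Mantel r undefined")
    r_obs = _pearson(va, _offdiag(b))
    use_exact = exact if exact is not None else n <= EXACT_ENUMERATION_MAX_N
    if use_exact:
        if n > EXACT_ENUMERATION_MAX_N:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_ENUMERATION_MAX_N}")
        count = total = 0
        for perm in itertools.permutations(range(n)):
            bp = b[np.ix_(perm, perm)]
            if _tail_count(_pearson(va, _offdiag(bp)), r_obs, tail):
                count += 1
            total += 1
        return MantelResult(r_obs, count / total, total, tail, exact=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _tail_count(_pearson(va, _offdiag(b[np.ix_(perm, perm)])), r_obs, tail):
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm, tail)


def _residual_matrix(y: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    """Residuals of off-diagonal vector y on x, reshaped to a square matrix."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    res = y - X @ beta
    M = np.zeros((n, n))
    M[np.triu_indices(n, 1)] = res
    return M + M.T


def partial_mantel(
    A,
    B,
    C,
    n_perm: int = 100000,
    tail: str = "upper",
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel correlation of A and B controlling for C.

    Off-diagonals of A and of B are each residualized on C by simple
    linear regression; r is the correlation of the residuals (the partial
    correlation r_AB.C).  The null permutes the residualized A matrix.
    """
    _check_same_ids(*(m for m in (A, B, C) if isinstance(m, DistanceMatrix)))
    a, b, c = _square(A), _square(B), _square(C)
    n = a.shape[0]
    if n < 5:
        raise ValueError("partial mantel needs n >= 5")
    vc = _offdiag(c)
    if np.allclose(vc, vc[0]):
        log.warning("control matrix constant: partial Mantel degenerates to simple Mantel")
        simple = mantel(A, B, n_perm=n_perm, tail=tail, seed=seed, exact=False)
        return MantelResult(simple.r, simple.p, simple.n_perm, tail, degenerate=True)
    ra_mat = _residual_matrix(_offdiag(a), vc, n)
    rb = _offdiag(_residual_matrix(_offdiag(b), vc, n))
    ra = _offdiag(ra_mat)
    if np.allclose(ra, 0, atol=1e-12) or np.allclose(rb, 0, atol=1e-12):
        return MantelResult(0.0, 1.0, 0, tail, degenerate=True)
    r_obs = _pearson(ra, rb)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = _offdiag(ra_mat[np.ix_(perm, perm)])
        if _tail_count(_pearson(rp, rb), r_obs, tail):
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm, tail)


def soil_difference_matrix(s: SoilTable, variable: str, assignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise absolute differences of a site-level soil variable.

    ``assignment`` maps each sample id to its site; every sample receives
    its site mean, so within-site entries are zero.
    """
    values = s.values_for(variable)
    samples = list(assignment)
    missing = sorted({site for site in assignment.values() if site not in values.index})
    if missing:
        raise ValueError(f"sites absent from soil table: {missing}")
    v = np.asarray([values[assignment[i]] for i in samples], dtype=float)
    M = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(M, ids=samples)


def offdiag_correlation(A, B) -> tuple[float, float, float]:
    """Plain Pearson correlation of two matrices' off-diagonal entries.

    Returns (r, R^2, two-sided t-test p); no permutation is involved.
    Accepts symmetric matrices of pairwise statistics (e.g. pairwise Phi).
    """
    if isinstance(A, pd.DataFrame):
        A, B = A.to_numpy(), (B.to_numpy() if isinstance(B, pd.DataFrame) else B)
    a, b = _square(A), _square(B)
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    va, vb = _offdiag(a), _offdiag(b)
    if np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        raise ValueError("constant off-diagonal vector")
    res = stats.pearsonr(va, vb)
    r = float(res.statistic)
    return r, r * r, float(res.pvalue)


def chi2_2x2(counts, method: str = "pearson") -> ContingencyResult:
    """Chi-square test of independence on a 2x2 table.

    ``pearson`` is the classical sum (O-E)^2/E without continuity
    correction; ``likelihood_ratio`` is the G statistic 2 sum O ln(O/E).
    Both are referred to a chi-square distribution with 1 df.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    lambda_ = {"pearson": "pearson", "likelihood_ratio": "log-likelihood"}.get(method)
    if lambda_ is None:
        raise ValueError(f"unknown method {method!r}")
    res = stats.chi2_contingency(t, correction=False, lambda_=lambda_)
    return ContingencyResult(float(res.statistic), 1, float(res.pvalue), method)
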