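"""Distance-based ordination and model selection.

Principal coordinate analysis (PCoA), distance-based linear models
(DistLM / dbRDA) with marginal and forward-selection permutation tests,
Storey q-values for false-discovery-rate control, redundancy analysis of
a centered binary matrix on soil variables, and UPGMA clustering with
locus-bootstrap support.

All DistLM machinery works on the Gower-centered inner-product matrix
G = -1/2 J A J, where A holds squared distances (pass ``squared=True``
when the input matrix already contains squared distances, as produced by
:func:`msapop.amova.squared_distance_matrix`) and J = I - 11'/n.  For a
hat matrix H projecting onto [1, X], pseudo-F uses the trace identities
tr(HGH) = tr(GH) and tr((I-H)G(I-H)) = tr(G) - tr(GH).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .band import BandMatrix, SoilTable

__all__ = [
    "PcoaResult",
    "DistlmRecord",
    "pcoa",
    "gower_center",
    "distlm_marginal",
    "distlm_forward",
    "storey_qvalues",
    "rda_forward",
    "upgma",
]

log = logging.getLogger(__name__)


def _square(d) -> np.ndarray:
    a = np.asarray(d.data if isinstance(d, DistanceMatrix) else d, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    return a


def gower_center(d, squared: bool = False) -> np.ndarray:
    """Gower-centered inner-product matrix -1/2 J D2 J."""
    D = _square(d)
    A = D if squared else D**2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ A @ J


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    negative_eigenvalues: np.ndarray


def pcoa(d, squared: bool = False, lingoes: bool = False) -> PcoaResult:
    """Classical (Gower) principal coordinate analysis.

    Coordinates are eigenvectors scaled by the square root of their
    (positive) eigenvalues; negative eigenvalues are reported but not
    corrected unless ``lingoes=True``, which adds the smallest constant to
    all squared off-diagonal distances that makes the form positive
    semi-definite.
    """
    D = _square(d)
    n = D.shape[0]
    if n < 3:
        raise ValueError("pcoa needs n >= 3")
    ids = list(d.ids) if isinstance(d, DistanceMatrix) else [str(i) for i in range(n)]
    G = gower_center(D, squared=squared)
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    if lingoes and eigval.min() < -1e-12:
        c = -eigval.min()
        A = (D if squared else D**2) + 2 * c * (1 - np.eye(n))
        G = gower_center(A, squared=True)
        eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(abs(eigval).max(), 1.0)
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    prop = eigval[pos] / eigval[pos].sum() if pos.any() else np.empty(0)
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
        ),
        eigenvalues=eigval,
        proportion_explained=prop,
        negative_eigenvalues=eigval[eigval < -tol],
    )


@dataclass
class DistlmRecord:
    predictor: str
    pseudo_f: float
    p: float
    proportion: float
    q: float | None = None
    flag: str = ""


def _hat(X: np.ndarray) -> np.ndarray:
    Xd = np.column_stack([np.ones(X.shape[0]), X])
    return Xd @ np.linalg.pinv(Xd)


def _predictor_frame(predictors) -> pd.DataFrame:
    df = pd.DataFrame(predictors).astype(float)
    const = [c for c in df.columns if np.allclose(df[c], df[c].iloc[0])]
    if const:
        raise ValueError(f"constant predictors: {const}")
    return df


def distlm_marginal(
    d,
    predictors,
    n_perm: int = 9999,
    seed: int | None = None,
    squared: bool = False,
) -> list[DistlmRecord]:
    """Marginal (single-predictor) DistLM permutation tests.

    For each predictor x (with intercept), pseudo-F =
    tr(HGH) / [tr((I-H)G(I-H)) / (n - 2)]; the null permutes the units of
    the distance matrix.  Proportion explained is tr(HGH) / tr(G).
    """
    G = gower_center(d, squared=squared)
    n = G.shape[0]
    df = _predictor_frame(predictors)
    if len(df) != n:
        raise ValueError("predictor rows must match distance-matrix units")
    trG = np.trace(G)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(n_perm)]
    out = []
    for name in df.columns:
        H = _hat(df[name].to_numpy()[:, None])
        num = float((G * H).sum())  # tr(GH)
        f_obs = num / ((trG - num) / (n - 2))
        count = 0
        for perm in perms:
            Gp = G[np.ix_(perm, perm)]
            nump = float((Gp * H).sum())
            if nump / ((trG - nump) / (n - 2)) >= f_obs:
                count += 1
        out.append(
            DistlmRecord(
                predictor=str(name),
                pseudo_f=f_obs,
                p=(count + 1) / (n_perm + 1),
                proportion=num / trG,
            )
        )
    return out


def distlm_forward(
    d,
    predictors,
    n_perm: int = 9999,
    stop_alpha: float = 0.05,
    seed: int | None = None,
    squared: bool = False,
    max_steps: int | None = None,
) -> list[DistlmRecord]:
    """Greedy forward selection maximizing added proportion of total SS.

    At each step the candidate adding the largest proportion of the total
    sum of squares (conditional on the selected set) is tested with a
    sequential pseudo-F whose null permutes the residual inner-product
    matrix under the reduced model; selection stops when the best
    candidate's p >= ``stop_alpha``.  Candidates adding < 1e-12 proportion
    are skipped as collinear.
    """
    G = gower_center(d, squared=squared)
    n = G.shape[0]
    df = _predictor_frame(predictors)
    trG = np.trace(G)
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    path: list[DistlmRecord] = []
    remaining = list(df.columns)
    while remaining:
        if max_steps is not None and len(selected) >= max_steps:
            break
        X_sel = df[selected].to_numpy() if selected else np.empty((n, 0))
        H_sel = _hat(X_sel)
        r_sel = float((G * H_sel).sum())
        best = None
        for name in remaining:
            H_full = _hat(np.column_stack([X_sel, df[name].to_numpy()]))
            added = float((G * H_full).sum()) - r_sel
            if best is None or added > best[1]:
                best = (name, added, H_full)
        name, added, H_full = best
        if added / trG < 1e-12:
            path.append(DistlmRecord(str(name), 0.0, 1.0, 0.0, flag="collinear_skip"))
            remaining.remove(name)
            continue
        m = len(selected) + 1
        resid_df = n - m - 1
        r_full = r_sel + added
        f_obs = added / ((trG - r_full) / resid_df)
        # Freedman-Lane: permute the reduced-model residual matrix
        G_res = (np.eye(n) - H_sel) @ G @ (np.eye(n) - H_sel)
        r_res_sel = float((G_res * H_sel).sum())
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G_res[np.ix_(perm, perm)]
            added_p = float((Gp * H_full).sum()) - float((Gp * H_sel).sum())
            denom = (np.trace(Gp) - r_res_sel - added_p) / resid_df
            if denom <= 0:
                continue
            if added_p / denom >= f_obs:
                count += 1
        p = (count + 1) / (n_perm + 1)
        rec = DistlmRecord(str(name), f_obs, p, added / trG)
        if p >= stop_alpha:
            break
        path.append(rec)
        selected.append(name)
        remaining.remove(name)
    return path


def storey_qvalues(pvals, lambdas=None) -> np.ndarray:
    """Storey-Tibshirani q-values with smoothed pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on a
    lambda grid (0.05 ... 0.95), smoothed by a cubic polynomial and read
    off at the largest lambda, clamped to (0, 1].  For m < 20 the grid is
    unreliable and pi0 is fixed at 1 (Benjamini-Hochberg fallback).
    q(p_(i)) = min over j >= i of pi0 * m * p_(j) / j, monotone in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D array")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m < 20:
        log.warning("storey_qvalues: m < 20, fixing pi0 = 1 (BH fallback)")
        pi0 = 1.0
    else:
        lam = np.arange(0.05, 0.951, 0.05) if lambdas is None else np.asarray(lambdas)
        pi0_lam = np.array([(p > l).sum() / (m * (1 - l)) for l in lam])
        coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
        pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p)
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class RdaResult:
    global_f: float
    global_p: float
    r2: float
    adj_r2: float
    selected: list[DistlmRecord]


def rda_forward(
    b: BandMatrix,
    s: SoilTable,
    assignment: dict[str, str] | None = None,
    n_perm: int = 999,
    stop_alpha: float = 0.05,
    seed: int | None = None,
) -> RdaResult:
    """Redundancy analysis of the centered band matrix on soil variables.

    For a column-centered response matrix Y the RDA explained variance
    equals the DistLM decomposition of the Euclidean inner-product matrix
    G = Y Y', which is exploited here.  A global Monte-Carlo test over all
    variables precedes forward selection with a double stopping rule
    (per-step alpha and the global adjusted R^2 ceiling).  Missing band
    scores are mean-imputed per locus before centering.
    """
    if assignment is None:
        assignment = dict(zip(b.sample_ids, b.site))
    X = pd.DataFrame(
        {
            v: [s.values_for(v)[assignment[i]] for i in b.sample_ids]
            for v in s.variables
        },
        index=b.sample_ids,
    )
    X = X.loc[:, [c for c in X.columns if not np.allclose(X[c], X[c].iloc[0])]]
    if X.shape[1] < 1:
        raise ValueError("no non-constant soil variables: use pcoa for unconstrained ordination")
    Y = b.values.copy()
    col_mean = np.nanmean(Y, axis=0)
    inds = np.where(np.isnan(Y))
    Y[inds] = np.take(col_mean, inds[1])
    Y = Y - Y.mean(axis=0)
    G = Y @ Y.T
    n, m = Y.shape[0], X.shape[1]
    trG = np.trace(G)
    H = _hat(X.to_numpy())
    r_full = float((G * H).sum())
    r2 = r_full / trG
    f_obs = (r_full / m) / ((trG - r_full) / (n - m - 1))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        rp = float((Gp * H).sum())
        if (rp / m) / ((trG - rp) / (n - m - 1)) >= f_obs:
            count += 1
    global_p = (count + 1) / (n_perm + 1)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    dm = DistanceMatrix(np.sqrt(np.maximum(_sqdist_from_gram(G), 0.0)), ids=b.sample_ids)
    path = distlm_forward(
        dm, X, n_perm=n_perm, stop_alpha=stop_alpha, seed=seed, squared=False
    )
    kept: list[DistlmRecord] = []
    cum = 0.0
    for rec in path:
        prop_adj = 1.0 - (1.0 - (cum + rec.proportion)) * (n - 1) / (n - len(kept) - 2)
        # adjusted-R2 ceiling applies from the second variable on: the first
        # admissible variable is always kept when the global test passed
        if kept and prop_adj > adj_r2:
            rec.flag = "adjR2_stop"
            break
        kept.append(rec)
        cum += rec.proportion
    return RdaResult(f_obs, global_p, r2, adj_r2, kept)


def _sqdist_from_gram(G: np.ndarray) -> np.ndarray:
    g = np.diag(G)
    return g[:, None] + g[None, :] - 2 * G


# -- UPGMA -----------------------------------------------------------------


class _Node:
    __slots__ = ("members", "height", "children", "rep")

    def __init__(self, members, height, children, rep):
        self.members = members  # frozenset of leaf ids
        self.height = height
        self.children = children  # [] for leaves
        self.rep = rep  # lexicographically smallest member, for tie-breaks


def _upgma_tree(D: np.ndarray, ids: list[str]) -> _Node:
    nodes = {i: _Node(frozenset([ids[i]]), 0.0, [], ids[i]) for i in range(len(ids))}
    dist = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            dist[(i, j)] = D[i, j]
    sizes = {i: 1 for i in nodes}
    next_id = len(ids)
    while len(nodes) > 1:
        # deterministic tie-break: smallest distance, then lexicographic reps
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((nodes[kv[0][0]].rep, nodes[kv[0][1]].rep)))),
        )
        (i, j), dij = best
        a, b_ = nodes.pop(i), nodes.pop(j)
        new = _Node(a.members | b_.members, dij / 2.0, [a, b_], min(a.rep, b_.rep))
        ni, nj = sizes.pop(i), sizes.pop(j)
        del dist[(i, j)]
        for k in list(nodes):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        nodes[next_id] = new
        sizes[next_id] = ni + nj
        next_id += 1
    return next(iter(nodes.values()))


def _bipartitions(root: _Node) -> set[frozenset]:
    out = set()

    def walk(node: _Node):
        for ch in node.children:
            if ch.children and ch.members != root.members:
                out.add(ch.members)
            walk(ch)

    walk(root)
    return out


def _newick(node: _Node, parent_height: float, supports: dict[frozenset, float] | None) -> str:
    bl = parent_height - node.height
    if not node.children:
        return f"{next(iter(node.members))}:{bl:.6g}"
    inner = ",".join(_newick(c, node.height, supports) for c in node.children)
    label = ""
    if supports is not None and node.members in supports:
        label = f"{supports[node.members]:.0f}"
    return f"({inner}){label}:{bl:.6g}"


def upgma(
    d,
    b: BandMatrix | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[str, dict[frozenset, float]]:
    """UPGMA dendrogram with optional locus-bootstrap support values.

    ``d`` holds plain (not squared) distances.  When a band matrix is
    supplied, loci are resampled with replacement ``n_boot`` times, the
    distance matrix and tree rebuilt, and each internal bipartition's
    support is the percentage of replicates containing it.  Returns the
    Newick string (supports as internal labels) and the support map.
    Merge ties are broken by the lexicographically smaller id pair.
    """
    from .amova import _sqdist_array

    D = _square(d)
    ids = list(d.ids) if isinstance(d, DistanceMatrix) else [str(i) for i in range(D.shape[0])]
    if D.shape[0] < 3:
        raise ValueError("upgma needs n >= 3")
    root = _upgma_tree(D, ids)
    supports: dict[frozenset, float] | None = None
    if b is not None:
        if list(b.sample_ids) != ids:
            raise ValueError("band matrix samples must match distance-matrix ids")
        rng = np.random.default_rng(seed)
        target = _bipartitions(root)
        hits = {bp: 0 for bp in target}
        for _ in range(n_boot):
            cols = rng.integers(0, b.n_loci, b.n_loci)
            Db = np.sqrt(_sqdist_array(b.values[:, cols], ids))
            bps = _bipartitions(_upgma_tree(Db, ids))
            for bp in target:
                if bp in bps:
                    hits[bp] += 1
        supports = {bp: 100.0 * h / n_boot for bp, h in hits.items()}
    newick = _newick(root, root.height, supports).rsplit(":", 1)[0] + ";"
    return newick, (supports or {})
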