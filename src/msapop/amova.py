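"""Analysis of molecular variance (AMOVA) for dominant binary profiles.

Variance in pairwise squared Euclidean distances between individual band
profiles is partitioned across a one-level (among groups / within groups)
or two-level nested design (among habitats / among populations within
habitats / within populations), following the classical sums-of-squares
identities for distance matrices.  Phi statistics are the Fst analogues
built from the resulting variance components:

* one level: PhiPT = s2_among / (s2_among + s2_within)
* two levels: PhiCT = s2_a / s2_total, PhiSC = s2_b / (s2_b + s2_c),
  PhiST = (s2_a + s2_b) / s2_total

Significance is assessed by permutation with the add-one rule
p = (count >= observed + 1) / (n_perm + 1).  Permutation schemes follow
the hierarchy: individuals among all units for PhiPT/PhiST, individuals
among populations within groups for PhiSC, and whole populations among
groups for PhiCT.

Distance-matrix entries are interpreted as *squared* distances throughout,
which is what :func:`squared_distance_matrix` produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .band import BandMatrix

__all__ = [
    "AmovaResult",
    "squared_distance_matrix",
    "amova",
    "pairwise_amova",
    "locus_by_locus_amova",
]


def _sqdist_array(values: np.ndarray, ids=None) -> np.ndarray:
    O = np.isfinite(values).astype(float)
    X = np.where(np.isfinite(values), values, 0.0)
    L_ij = O @ O.T
    if (L_ij == 0).any():
        i, j = np.argwhere(L_ij == 0)[0]
        a, b = (ids[i], ids[j]) if ids is not None else (i, j)
        raise ValueError(f"samples {a!r} and {b!r} share no observed locus")
    # binary data: (xi - xj)^2 over co-observed = xi(1-xj) + xj(1-xi)
    mism = X @ (O - X).T
    mism = mism + mism.T
    d2 = values.shape[1] / L_ij * mism
    np.fill_diagonal(d2, 0.0)
    return (d2 + d2.T) / 2.0  # enforce exact symmetry against float noise


def squared_distance_matrix(b: BandMatrix) -> DistanceMatrix:
    """Pairwise squared Euclidean distances with missing-data rescaling.

    d2(i, j) = (L / L_ij) * sum over mutually observed loci of (x_i - x_j)^2,
    where L_ij counts mutually observed loci and L the total.  A pair with
    no mutually observed locus is an error.
    """
    if b.n_samples < 2:
        raise ValueError("need at least two samples")
    return DistanceMatrix(_sqdist_array(b.values, b.sample_ids), ids=b.sample_ids)


@dataclass
class AmovaResult:
    """Hierarchical variance decomposition with Phi statistics.

    ``table`` has one row per stratum (df, SS, MS, variance component,
    raw and truncated % variation); ``phi`` and ``p_values`` map statistic
    names (PhiPT / PhiCT / PhiSC / PhiST) to values and permutation
    p-values.  ``degenerate`` flags an all-zero total variance.
    """

    table: pd.DataFrame
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    degenerate: bool = False
    flags: list[str] = field(default_factory=list)


def _labels_array(d: DistanceMatrix, labels) -> np.ndarray:
    if isinstance(labels, dict):
        missing = [i for i in d.ids if i not in labels]
        if missing:
            raise ValueError(f"ids without group assignment: {missing}")
        return np.asarray([labels[i] for i in d.ids])
    arr = np.asarray(labels)
    if arr.shape != (len(d.ids),):
        raise ValueError("labels must give one value per distance-matrix id")
    return arr


def _onehot(labels: np.ndarray) -> tuple[np.ndarray, list]:
    cats = list(dict.fromkeys(labels))
    B = np.zeros((labels.size, len(cats)))
    for k, c in enumerate(cats):
        B[labels == c, k] = 1.0
    return B, cats


def _ss_within(D: np.ndarray, B: np.ndarray) -> float:
    """Sum over units of (1/n_k) * sum of pairwise entries within unit."""
    sizes = B.sum(axis=0)
    within = (B * (D @ B)).sum(axis=0)  # per unit: full double sum
    return float((within / (2.0 * sizes)).sum())


def _one_level_components(D, B):
    N = D.shape[0]
    sizes = B.sum(axis=0)
    K = B.shape[1]
    ss_t = D.sum() / (2.0 * N)
    ss_w = _ss_within(D, B)
    ss_a = ss_t - ss_w
    df_a, df_w = K - 1, N - K
    ms_a, ms_w = ss_a / df_a, ss_w / df_w
    n0 = (N - (sizes**2).sum() / N) / (K - 1)
    s2_w = ms_w
    s2_a = (ms_a - ms_w) / n0
    return ss_t, ss_a, ss_w, df_a, df_w, s2_a, s2_w


def _phi_pt(D, B) -> float:
    *_, s2_a, s2_w = _one_level_components(D, B)
    tot = s2_a + s2_w
    return s2_a / tot if tot > 0 else 0.0


def _two_level_components(D, labels_g, labels_s):
    N = D.shape[0]
    Bs, sites = _onehot(labels_s)
    Bg, groups = _onehot(labels_g)
    site_group = {}
    for s, g in zip(labels_s, labels_g):
        site_group[s] = g
    ss_t = D.sum() / (2.0 * N)
    ss_wp = _ss_within(D, Bs)
    ss_wg = _ss_within(D, Bg)
    ss_ag = ss_t - ss_wg
    ss_ap = ss_wg - ss_wp
    G, P = len(groups), len(sites)
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_ag, ms_ap, ms_wp = ss_ag / df_ag, ss_ap / df_ap, ss_wp / df_wp
    n_p = {s: (labels_s == s).sum() for s in sites}
    n_g = {g: (labels_g == g).sum() for g in groups}
    sum_np2_over_ng = sum(
        sum(n_p[s] ** 2 for s in sites if site_group[s] == g) / n_g[g] for g in groups
    )
    n1 = (N - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - sum(v**2 for v in n_p.values()) / N) / (G - 1)
    n3 = (N - sum(v**2 for v in n_g.values()) / N) / (G - 1)
    s2_c = ms_wp
    s2_b = (ms_ap - ms_wp) / n1
    s2_a = (ms_ag - ms_wp - n2 * s2_b) / n3
    return {
        "ss": (ss_ag, ss_ap, ss_wp, ss_t),
        "df": (df_ag, df_ap, df_wp),
        "sigma": (s2_a, s2_b, s2_c),
    }


def _two_level_phis(D, labels_g, labels_s) -> dict[str, float]:
    c = _two_level_components(D, labels_g, labels_s)
    s2_a, s2_b, s2_c = c["sigma"]
    tot = s2_a + s2_b + s2_c
    if tot <= 0:
        return {"PhiCT": 0.0, "PhiSC": 0.0, "PhiST": 0.0}
    return {
        "PhiCT": s2_a / tot,
        "PhiSC": s2_b / (s2_b + s2_c) if (s2_b + s2_c) > 0 else 0.0,
        "PhiST": (s2_a + s2_b) / tot,
    }


def _pct_rows(sigmas: list[float]) -> tuple[list[float], list[float]]:
    tot = sum(sigmas)
    raw = [100.0 * s / tot if tot != 0 else 0.0 for s in sigmas]
    clipped = [max(s, 0.0) for s in sigmas]
    ctot = sum(clipped)
    trunc = [100.0 * s / ctot if ctot > 0 else 0.0 for s in clipped]
    return raw, trunc


def amova(
    d: DistanceMatrix,
    groups,
    subgroups=None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> AmovaResult:
    """One- or two-level AMOVA on a matrix of squared distances.

    ``groups`` assigns every id to a top-level group; the optional
    ``subgroups`` adds a nested population level.  Both accept a mapping
    id -> label or a label sequence in id order.
    """
    D = np.asarray(d.data, dtype=float)
    N = D.shape[0]
    g = _labels_array(d, groups)
    if len(dict.fromkeys(g)) < 2:
        raise ValueError("AMOVA needs at least two groups")
    flags = []
    sizes = pd.Series(g).value_counts()
    if (sizes == 1).any():
        flags.append(f"groups with a single individual: {list(sizes[sizes == 1].index)}")
    rng = np.random.default_rng(seed)
    degenerate = bool(D.max() == 0)

    if subgroups is None:
        B, _ = _onehot(g)
        ss_t, ss_a, ss_w, df_a, df_w, s2_a, s2_w = _one_level_components(D, B)
        tot = s2_a + s2_w
        phi = s2_a / tot if tot > 0 else 0.0
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            if _phi_pt(D[np.ix_(perm, perm)], B) >= phi:
                count += 1
        p = (count + 1) / (n_perm + 1)
        raw, trunc = _pct_rows([s2_a, s2_w])
        table = pd.DataFrame(
            {
                "df": [df_a, df_w, df_a + df_w],
                "SS": [ss_a, ss_w, ss_t],
                "MS": [ss_a / df_a, ss_w / df_w, np.nan],
                "variance": [s2_a, s2_w, s2_a + s2_w],
                "pct_variation_raw": raw + [100.0],
                "pct_variation": trunc + [100.0],
            },
            index=["among_groups", "within_groups", "total"],
        )
        return AmovaResult(table, {"PhiPT": phi}, {"PhiPT": p}, n_perm, degenerate, flags)

    s = _labels_array(d, subgroups)
    site_group = {}
    for si, gi in zip(s, g):
        if site_group.setdefault(si, gi) != gi:
            raise ValueError(f"population {si!r} spans multiple groups")
    comp = _two_level_components(D, g, s)
    phis = _two_level_phis(D, g, s)
    counts = {k: 0 for k in phis}
    sites = list(dict.fromkeys(s))
    group_of = np.asarray([site_group[si] for si in sites])
    site_index = {si: i for i, si in enumerate(sites)}
    site_codes = np.asarray([site_index[si] for si in s])
    for _ in range(n_perm):
        # PhiST / PhiPT: individuals permuted among all units
        perm = rng.permutation(N)
        Dp = D[np.ix_(perm, perm)]
        if _two_level_phis(Dp, g, s)["PhiST"] >= phis["PhiST"]:
            counts["PhiST"] += 1
        # PhiSC: individuals permuted among populations within their group
        perm2 = np.arange(N)
        for gg in dict.fromkeys(g):
            idx = np.flatnonzero(g == gg)
            perm2[idx] = rng.permutation(idx)
        Dp2 = D[np.ix_(perm2, perm2)]
        if _two_level_phis(Dp2, g, s)["PhiSC"] >= phis["PhiSC"]:
            counts["PhiSC"] += 1
        # PhiCT: whole populations permuted among groups
        g_perm_sites = group_of[rng.permutation(len(sites))]
        g_perm = g_perm_sites[site_codes]
        if _two_level_phis(D, g_perm, s)["PhiCT"] >= phis["PhiCT"]:
            counts["PhiCT"] += 1
    p = {k: (counts[k] + 1) / (n_perm + 1) for k in counts}
    ss_ag, ss_ap, ss_wp, ss_t = comp["ss"]
    df_ag, df_ap, df_wp = comp["df"]
    s2 = comp["sigma"]
    raw, trunc = _pct_rows(list(s2))
    table = pd.DataFrame(
        {
            "df": [df_ag, df_ap, df_wp, df_ag + df_ap + df_wp],
            "SS": [ss_ag, ss_ap, ss_wp, ss_t],
            "MS": [ss_ag / df_ag, ss_ap / df_ap, ss_wp / df_wp, np.nan],
            "variance": list(s2) + [sum(s2)],
            "pct_variation_raw": raw + [100.0],
            "pct_variation": trunc + [100.0],
        },
        index=[
            "among_habitats",
            "among_populations_within_habitats",
            "within_populations",
            "total",
        ],
    )
    return AmovaResult(table, phis, p, n_perm, degenerate, flags)


def pairwise_amova(
    d: DistanceMatrix, groups, n_perm: int = 9999, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-level AMOVA restricted to every pair of groups.

    Returns symmetric (Phi, p) matrices indexed by group label.
    """
    g = _labels_array(d, groups)
    cats = list(dict.fromkeys(g))
    if len(cats) < 2:
        raise ValueError("need at least two groups")
    phi = pd.DataFrame(0.0, index=cats, columns=cats)
    pval = pd.DataFrame(1.0, index=cats, columns=cats)
    rng = np.random.default_rng(seed)
    ids = np.asarray(d.ids)
    for a in range(len(cats)):
        for b in range(a + 1, len(cats)):
            sel = np.flatnonzero((g == cats[a]) | (g == cats[b]))
            sub = DistanceMatrix(d.data[np.ix_(sel, sel)], ids=list(ids[sel]))
            res = amova(sub, g[sel], n_perm=n_perm, seed=int(rng.integers(2**31 - 1)))
            phi.iloc[a, b] = phi.iloc[b, a] = res.phi["PhiPT"]
            pval.iloc[a, b] = pval.iloc[b, a] = res.p_values["PhiPT"]
    return phi, pval


def _phi_from_counts(ones, obs):
    """Vectorized one-level PhiPT for binary loci from per-group counts.

    ``ones``/``obs`` have shape (K, L): per group, counts of band-present
    and of observed individuals.  Returns (phi, valid) arrays of length L.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        N = obs.sum(axis=0).astype(float)
        A = ones.sum(axis=0).astype(float)
        Kl = (obs > 0).sum(axis=0).astype(float)
        ss_t = A * (N - A) / N
        ss_w = np.where(obs > 0, ones * (obs - ones) / np.maximum(obs, 1), 0.0).sum(axis=0)
        ss_a = ss_t - ss_w
        df_a = Kl - 1
        df_w = N - Kl
        n0 = (N - (obs.astype(float) ** 2).sum(axis=0) / N) / np.maximum(df_a, 1e-12)
        ms_a = ss_a / np.maximum(df_a, 1e-12)
        ms_w = ss_w / np.maximum(df_w, 1e-12)
        s2_w = ms_w
        s2_a = (ms_a - ms_w) / n0
        tot = s2_a + s2_w
        phi = np.where(tot > 0, s2_a / np.maximum(np.abs(tot), 1e-300), 0.0)
    valid = (A > 0) & (A < N) & (df_a >= 1) & (df_w >= 1)
    return phi, valid


def locus_by_locus_amova(
    b: BandMatrix,
    groups,
    n_perm: int = 999,
    alpha: float = 0.01,
    seed: int | None = None,
) -> pd.DataFrame:
    """Single-locus AMOVA per locus with a shared permutation scheme.

    Each locus contributes a 0/1 squared distance between observed
    individuals; monomorphic loci are excluded with a flag.  One set of
    individual permutations is shared across loci.
    """
    labels = np.asarray(groups) if not isinstance(groups, str) else b.labels(groups)
    if labels.shape != (b.n_samples,):
        raise ValueError("groups must give one label per sample")
    if len(dict.fromkeys(labels)) < 2:
        raise ValueError("need at least two groups")
    B, _ = _onehot(labels)
    V = b.values
    Obs = b.observed.astype(float)
    ones = (np.nan_to_num(V) * Obs).T @ B  # (L, K) -> transpose later
    obs = Obs.T @ B
    phi_obs, valid = _phi_from_counts(ones.T, obs.T)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(b.n_loci)
    for _ in range(n_perm):
        perm = rng.permutation(b.n_samples)
        ones_p = (np.nan_to_num(V[perm]) * Obs[perm]).T @ B
        obs_p = Obs[perm].T @ B
        phi_p, _ = _phi_from_counts(ones_p.T, obs_p.T)
        exceed += phi_p >= phi_obs
    p = (exceed + 1) / (n_perm + 1)
    out = pd.DataFrame(
        {
            "locus": b.locus_ids,
            "phi": np.where(valid, phi_obs, np.nan),
            "p": np.where(valid, p, np.nan),
            "significant": valid & (p < alpha),
            "excluded_monomorphic": ~valid,
        }
    )
    return out
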