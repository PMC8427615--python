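"""Diversity statistics and Nei distance for dominant markers.

Dominant markers (AFLP bands, MSAP epialleles in their binary encoding)
only distinguish band presence from absence, so the recessive (band-absent)
allele frequency q must be estimated from the band-absent phenotype
fraction x0.  Three estimators are provided:

``sqrt``
    q = sqrt(x0), the classical estimator assuming Hardy-Weinberg
    proportions (POPGENE's convention); the default.
``lynch_milligan``
    Taylor-corrected estimator q = sqrt(x0) / (1 + Var(x0) / (8 x0^2)),
    applied only when x0 > 3/n (its recommended validity region), with
    Var(x0) = x0 (1 - x0) / n.
``bayes_uniform``
    q = sqrt of the posterior mean of the band-absent phenotype frequency
    q^2 under a uniform prior, i.e. q = sqrt((a0 + 1) / (n + 2)) with a0
    band-absent individuals of n observed.  Never returns a fixed estimate
    from a polymorphic sample, which motivates its use for percentage-
    polymorphism criteria.

All diversity indices use natural logarithms.  Shannon's index I is
computed on band-state (phenotype) frequencies, not on estimated allele
frequencies, so methylation-susceptible and nonmethylated loci can be
compared on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .band import BandMatrix

__all__ = [
    "AlleleFreqTable",
    "DiversityTable",
    "estimate_allele_frequencies",
    "diversity_indices",
    "nei_distance",
    "shannon_per_locus",
    "rank_sum_compare",
]


def _resolve_grouping(b: BandMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, str):
        return b.labels(grouping)
    labels = np.asarray(grouping)
    if labels.shape != (b.n_samples,):
        raise ValueError("grouping must give one label per sample")
    return labels


@dataclass
class AlleleFreqTable:
    """Per-population recessive (band-absent) allele frequencies.

    ``q`` has shape (n_populations, n_loci); NaN marks loci with no
    observed individual in a population.
    """

    populations: list[str]
    locus_ids: list[str]
    q: np.ndarray
    n_obs: np.ndarray
    method: str

    @property
    def p(self) -> np.ndarray:
        return 1.0 - self.q


@dataclass
class DiversityTable:
    """Across-locus mean diversity per population plus Gst/Nm overall."""

    per_population: pd.DataFrame  # index population; Na, Ne, P, P5, He, I
    gst: float | None
    nm: float | None


def _estimate_q(x0: np.ndarray, n: np.ndarray, method: str) -> np.ndarray:
    """Estimate q from band-absent fraction x0 with n observed individuals."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if method == "sqrt":
            return np.sqrt(x0)
        if method == "lynch_milligan":
            q0 = np.sqrt(x0)
            var = x0 * (1 - x0) / np.maximum(n, 1)
            corr = 1.0 + var / (8.0 * x0**2)
            q = np.where(x0 > 3.0 / np.maximum(n, 1), q0 / corr, q0)
            return q
        if method == "bayes_uniform":
            a0 = x0 * n
            return np.sqrt((a0 + 1.0) / (n + 2.0))
    raise ValueError(f"unknown allele-frequency estimator {method!r}")


def estimate_allele_frequencies(
    b: BandMatrix, grouping="site", method: str = "sqrt"
) -> AlleleFreqTable:
    """Estimate per-population recessive allele frequencies per locus."""
    labels = _resolve_grouping(b, grouping)
    pops = list(dict.fromkeys(labels))
    obs = b.observed
    q = np.full((len(pops), b.n_loci), np.nan)
    n_obs = np.zeros((len(pops), b.n_loci), dtype=int)
    for k, pop in enumerate(pops):
        sel = labels == pop
        n = obs[sel].sum(axis=0)
        absent = ((b.values[sel] == 0) & obs[sel]).sum(axis=0)
        with np.errstate(invalid="ignore"):
            x0 = np.where(n > 0, absent / np.maximum(n, 1), np.nan)
        q[k] = _estimate_q(x0, n.astype(float), method)
        q[k, n == 0] = np.nan
        n_obs[k] = n
    return AlleleFreqTable(
        populations=[str(p) for p in pops],
        locus_ids=list(b.locus_ids),
        q=q,
        n_obs=n_obs,
        method=method,
    )


def _entropy(f: np.ndarray) -> np.ndarray:
    """Shannon information of a two-state frequency; 0 when monomorphic."""
    f = np.asarray(f, dtype=float)
    out = np.zeros_like(f)
    inner = (f > 0) & (f < 1)
    fi = f[inner]
    out[inner] = -(fi * np.log(fi) + (1 - fi) * np.log(1 - fi))
    out[~np.isfinite(f)] = np.nan
    return out


def shannon_per_locus(b: BandMatrix, grouping=None) -> np.ndarray:
    """Per-locus Shannon index on pooled band-state frequencies.

    With ``grouping=None`` frequencies are pooled over all individuals;
    otherwise a (n_groups, n_loci) array of within-group values is returned.
    """
    if grouping is None:
        obs = b.observed
        n = obs.sum(axis=0).astype(float)
        f = np.where(n > 0, ((b.values == 1) & obs).sum(axis=0) / np.maximum(n, 1), np.nan)
        return _entropy(f)
    labels = _resolve_grouping(b, grouping)
    return np.vstack([
        shannon_per_locus(b.select_samples(labels == g)) for g in dict.fromkeys(labels)
    ])


def diversity_indices(
    b: BandMatrix, grouping="site", method: str = "sqrt"
) -> DiversityTable:
    """POPGENE-style dominant-marker diversity per population.

    Per locus within each population: He = 2 p q from the estimated allele
    frequencies, I from the band-state frequency, Na = number of observed
    band states, Ne = 1 / (p^2 + q^2); population values are across-locus
    means.  P is the percentage of loci with both band states observed,
    P5 the percentage with estimated minor allele frequency >= 0.05.
    Across populations, Gst = (Ht - Hs) / Ht with Hs and Ht summed over
    loci, and Nm = 0.5 (1 - Gst) / Gst.
    """
    freqs = estimate_allele_frequencies(b, grouping, method)
    labels = _resolve_grouping(b, grouping)
    q, p = freqs.q, freqs.p
    he = 2.0 * p * q
    with np.errstate(invalid="ignore", divide="ignore"):
        ne = 1.0 / (p**2 + q**2)
    rows = []
    for k, pop in enumerate(freqs.populations):
        sel = labels == pop
        obs = b.observed[sel]
        n = obs.sum(axis=0).astype(float)
        present = ((b.values[sel] == 1) & obs).sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(n > 0, present / np.maximum(n, 1), np.nan)
        have = n > 0
        both_states = have & (present > 0) & (present < n)
        na = np.where(both_states, 2.0, 1.0)
        maf = np.minimum(p[k], q[k])
        rows.append(
            {
                "population": pop,
                "n": int(sel.sum()),
                "Na": float(np.mean(na[have])),
                "Ne": float(np.nanmean(ne[k, have])),
                "P": 100.0 * float(both_states.sum() / have.sum()),
                "P5": 100.0 * float(np.nanmean((maf[have] >= 0.05).astype(float))),
                "He": float(np.nanmean(he[k, have])),
                "I": float(np.nanmean(_entropy(f[have]))),
            }
        )
    table = pd.DataFrame(rows).set_index("population")
    gst = nm = None
    if len(freqs.populations) >= 2:
        pbar = np.nanmean(p, axis=0)
        ht = 2.0 * pbar * (1.0 - pbar)
        hs = np.nanmean(he, axis=0)
        ok = np.isfinite(ht) & np.isfinite(hs) & (ht > 0)
        ht_sum, hs_sum = ht[ok].sum(), hs[ok].sum()
        if ht_sum > 0:
            gst = float((ht_sum - hs_sum) / ht_sum)
            nm = float(0.5 * (1.0 - gst) / gst) if gst > 0 else np.inf
    return DiversityTable(per_population=table, gst=gst, nm=nm)


def nei_distance(freqs: AlleleFreqTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nei (1972) genetic identity and distance between populations.

    Per pair, Jxy is the across-locus mean of (px py + qx qy), and the
    identity is I = Jxy / sqrt(Jx Jy) with D = -ln I.  Degenerate pairs
    with I <= 0 get D = +inf.
    """
    K = len(freqs.populations)
    if K < 2:
        raise ValueError("nei_distance needs at least two populations")
    p, q = freqs.p, freqs.q
    ident = np.ones((K, K))
    dist = np.zeros((K, K))
    for x in range(K):
        for y in range(x + 1, K):
            ok = np.isfinite(q[x]) & np.isfinite(q[y])
            if not ok.any():
                raise ValueError(
                    f"no shared loci between {freqs.populations[x]} and {freqs.populations[y]}"
                )
            jxy = np.mean(p[x, ok] * p[y, ok] + q[x, ok] * q[y, ok])
            jx = np.mean(p[x, ok] ** 2 + q[x, ok] ** 2)
            jy = np.mean(p[y, ok] ** 2 + q[y, ok] ** 2)
            i_xy = jxy / np.sqrt(jx * jy)
            ident[x, y] = ident[y, x] = i_xy
            dist[x, y] = dist[y, x] = -np.log(i_xy) if i_xy > 0 else np.inf
    pops = freqs.populations
    return (
        pd.DataFrame(ident, index=pops, columns=pops),
        pd.DataFrame(dist, index=pops, columns=pops),
    )


def rank_sum_compare(a, b) -> dict:
    """Wilcoxon rank-sum comparison of two sets of per-locus values.

    Returns the minimal rank sum W, a two-sided p-value (exact enumeration
    for small tie-free samples, otherwise the tie-corrected normal
    approximation with continuity correction), and mean +/- sd of both
    samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    w_a = float(ranks[: a.size].sum())
    w_b = float(ranks[a.size:].sum())
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        p = 1.0
    else:
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (not has_ties and min(a.size, b.size) <= 8) else "asymptotic"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    return {
        "W": min(w_a, w_b),
        "p": p,
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)) if a.size > 1 else 0.0,
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)) if b.size > 1 else 0.0,
    }
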