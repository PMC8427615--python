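"""Outlier-locus detection and environmental association for dominant markers.

Two complementary scans:

1. An Fst-outlier scan in the FDIST tradition: per-locus differentiation
   (Fst analogue from dominant-marker allele-frequency estimates) is
   compared against a simulated neutral envelope of Fst conditional on
   heterozygosity.  The neutral model is a Balding-Nichols beta island
   model: group allele frequencies are Beta-distributed around an
   ancestral frequency with variance set by the target Fst, dominant
   phenotypes are sampled under Hardy-Weinberg proportions, and Fst/het
   are recomputed through the very same estimator applied to the data, so
   estimator bias cancels between observation and null.  Loci above the
   upper envelope quantile are directional-selection candidates; below
   the lower quantile, balancing-selection candidates.

2. Univariate logistic regressions of band presence on each environmental
   variable (the landscape-genomics "SAM" approach), declaring a model
   significant only when both the likelihood-ratio G test and the Wald
   test pass a Bonferroni-corrected threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .band import BandMatrix, SoilTable
from .diversity import estimate_allele_frequencies

__all__ = [
    "LocusFstRecord",
    "EnvAssociation",
    "fst_het_per_locus",
    "multilocus_fst",
    "fdist_null_envelope",
    "fdist_outliers",
    "fdist_scan",
    "env_logistic_scan",
]

log = logging.getLogger(__name__)


@dataclass
class LocusFstRecord:
    locus_id: str
    fst: float
    het: float
    flag: str = "none"  # directional_candidate | balancing_candidate | none
    outside_het_range: bool = False


@dataclass
class EnvAssociation:
    locus_id: str
    variable: str
    beta: float
    g_statistic: float
    wald_statistic: float
    p_g: float
    p_wald: float
    significant: bool
    separation: bool = False


def _fst_het_from_freqs(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Fst and total heterozygosity from (K, L) frequencies.

    Fst = (Ht - Hs)/Ht with Hs the mean within-group He and Ht from the
    pooled mean frequency; returns (fst, het, valid) where invalid marks
    monomorphic loci (Ht == 0) or loci missing in some group.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        hs = np.nanmean(2.0 * p * (1.0 - p), axis=0)
        pbar = np.nanmean(p, axis=0)
        ht = 2.0 * pbar * (1.0 - pbar)
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    valid = np.isfinite(fst) & (ht > 0)
    return fst, ht, valid


def fst_het_per_locus(
    b: BandMatrix, groups="habitat", freq_method: str = "sqrt"
) -> list[LocusFstRecord]:
    """Empirical per-locus Fst and heterozygosity across groups.

    Monomorphic loci (pooled Ht = 0) are excluded.
    """
    freqs = estimate_allele_frequencies(b, groups, freq_method)
    if len(freqs.populations) < 2:
        raise ValueError("need at least two groups")
    fst, het, valid = _fst_het_from_freqs(freqs.p)
    return [
        LocusFstRecord(freqs.locus_ids[j], float(fst[j]), float(het[j]))
        for j in np.flatnonzero(valid)
    ]


def multilocus_fst(records: list[LocusFstRecord]) -> float:
    """Het-weighted multilocus Fst (ratio of summed components)."""
    het = np.array([r.het for r in records])
    fst = np.array([r.fst for r in records])
    num = (fst * het).sum()
    return float(num / het.sum())


def fdist_null_envelope(
    n_groups: int,
    group_sizes,
    target_fst: float,
    n_sim: int = 20000,
    quantiles: tuple[float, float] = (0.005, 0.995),
    het_bins: int = 20,
    seed: int | None = None,
    freq_method: str = "sqrt",
    min_per_bin: int = 200,
) -> pd.DataFrame:
    """Simulated neutral Fst envelope conditional on heterozygosity.

    Each simulated locus draws an ancestral frequency uniform on
    (0.01, 0.99), group frequencies from the Balding-Nichols Beta island
    model at ``target_fst``, samples dominant phenotypes per group under
    Hardy-Weinberg proportions, and recomputes Fst/het through the same
    dominant-marker estimator as the observed scan.  Bins with fewer than
    ``min_per_bin`` simulated loci are merged with a warning.
    """
    if not 0 < target_fst < 1:
        raise ValueError("target_fst must be in (0, 1)")
    sizes = np.asarray(group_sizes, dtype=int)
    if sizes.size != n_groups:
        raise ValueError("group_sizes must list one size per group")
    if (sizes < 2).any():
        raise ValueError("group sizes must be >= 2")
    rng = np.random.default_rng(seed)
    theta = target_fst
    fst_all = np.empty(0)
    het_all = np.empty(0)
    remaining = n_sim
    while remaining > 0:
        m = int(remaining * 1.4) + 16
        pbar = rng.uniform(0.01, 0.99, m)
        a = pbar * (1 - theta) / theta
        bpar = (1 - pbar) * (1 - theta) / theta
        pk = rng.beta(a[None, :], bpar[None, :], size=(n_groups, m))
        f_band = 1.0 - (1.0 - pk) ** 2  # dominant phenotype frequency under HWE
        x1 = rng.binomial(sizes[:, None], f_band)
        x0 = 1.0 - x1 / sizes[:, None]
        if freq_method == "sqrt":
            qhat = np.sqrt(x0)
        else:
            from .diversity import _estimate_q

            qhat = _estimate_q(x0, np.broadcast_to(sizes[:, None].astype(float), x0.shape), freq_method)
        fst, het, valid = _fst_het_from_freqs(1.0 - qhat)
        keep = valid  # resample until polymorphic in sample
        take = min(int(keep.sum()), remaining)
        idx = np.flatnonzero(keep)[:take]
        fst_all = np.concatenate([fst_all, fst[idx]])
        het_all = np.concatenate([het_all, het[idx]])
        remaining -= take
    # equal-count het bins, merged until every bin holds >= min_per_bin
    order = np.argsort(het_all)
    het_s, fst_s = het_all[order], fst_all[order]
    n_bins = max(1, min(het_bins, n_sim // max(min_per_bin, 1)))
    if n_bins < het_bins:
        log.warning("fdist envelope: widened het bins from %d to %d", het_bins, n_bins)
    edges = np.quantile(het_s, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = 0.0, 0.5 + 1e-9
    rows = []
    lo_q, hi_q = quantiles
    for i in range(n_bins):
        sel = (het_s >= edges[i]) & (het_s < edges[i + 1] if i < n_bins - 1 else het_s <= edges[i + 1])
        vals = fst_s[sel]
        if vals.size == 0:
            continue
        rows.append(
            {
                "het_lo": edges[i],
                "het_hi": edges[i + 1],
                "n_sim": int(vals.size),
                "fst_lower": float(np.quantile(vals, lo_q)),
                "fst_median": float(np.quantile(vals, 0.5)),
                "fst_upper": float(np.quantile(vals, hi_q)),
            }
        )
    env = pd.DataFrame(rows)
    env.attrs["target_fst"] = target_fst
    env.attrs["quantiles"] = quantiles
    env.attrs["mean_fst"] = float((fst_all * het_all).sum() / het_all.sum())
    return env


def fdist_outliers(
    records: list[LocusFstRecord], envelope: pd.DataFrame
) -> list[LocusFstRecord]:
    """Flag loci outside the neutral envelope for their het bin.

    Records with heterozygosity outside the envelope's range use the
    nearest bin and carry ``outside_het_range=True``.
    """
    lo = envelope["het_lo"].to_numpy()
    hi = envelope["het_hi"].to_numpy()
    out = []
    for r in records:
        i = np.searchsorted(lo, r.het, side="right") - 1
        outside = r.het < lo[0] or r.het > hi[-1]
        i = int(np.clip(i, 0, len(envelope) - 1))
        row = envelope.iloc[i]
        flag = "none"
        if r.fst > row["fst_upper"]:
            flag = "directional_candidate"
        elif r.fst < row["fst_lower"]:
            flag = "balancing_candidate"
        out.append(LocusFstRecord(r.locus_id, r.fst, r.het, flag, outside))
    return out


def _simulated_mean_fst(theta, n_groups, sizes, n_sim, seed, freq_method) -> float:
    env = fdist_null_envelope(
        n_groups, sizes, theta, n_sim, seed=seed, freq_method=freq_method,
        het_bins=1, min_per_bin=1,
    )
    return float(env.attrs["mean_fst"])


def calibrate_target_fst(
    observed_fst: float,
    n_groups: int,
    group_sizes,
    seed: int | None = None,
    n_sim: int = 3000,
    n_iter: int = 6,
    freq_method: str = "sqrt",
) -> float:
    """Find the Balding-Nichols theta whose *measured* mean Fst matches.

    With few individuals per group, the dominant-marker Fst estimator is
    inflated by sampling variance, so the observed multilocus Fst cannot be
    used directly as the neutral theta.  This multiplicative fixed-point
    iteration tunes theta until the simulated loci, pushed through the same
    estimator, reproduce the observed mean.
    """
    rng = np.random.default_rng(seed)
    theta = float(np.clip(observed_fst, 1e-4, 0.95))
    for _ in range(n_iter):
        sim = _simulated_mean_fst(
            theta, n_groups, group_sizes, n_sim, int(rng.integers(2**31 - 1)), freq_method
        )
        if sim <= 0:
            break
        theta = float(np.clip(theta * observed_fst / sim, 1e-4, 0.95))
    return theta


def fdist_scan(
    b: BandMatrix,
    groups="habitat",
    n_sim: int = 20000,
    quantiles: tuple[float, float] = (0.005, 0.995),
    seed: int | None = None,
    freq_method: str = "sqrt",
    target_fst: float | None = None,
) -> tuple[list[LocusFstRecord], pd.DataFrame]:
    """Full outlier scan: calibrate target Fst, simulate envelope, flag loci.

    The neutral target is the Balding-Nichols theta whose simulated loci
    reproduce the observed multilocus Fst through the same estimator
    (see :func:`calibrate_target_fst`), re-estimated once after a trimming
    pass that drops provisional outliers - the standard FDIST practice.
    """
    labels = b.labels(groups) if isinstance(groups, str) else np.asarray(groups)
    cats = list(dict.fromkeys(labels))
    sizes = [int((labels == c).sum()) for c in cats]
    records = fst_het_per_locus(b, groups, freq_method)
    rng = np.random.default_rng(seed)
    if target_fst is None:
        theta0 = calibrate_target_fst(
            multilocus_fst(records), len(cats), sizes,
            seed=int(rng.integers(2**31 - 1)), freq_method=freq_method,
        )
        env0 = fdist_null_envelope(
            len(cats), sizes, theta0, n_sim, quantiles,
            seed=int(rng.integers(2**31 - 1)), freq_method=freq_method,
        )
        provisional = fdist_outliers(records, env0)
        trimmed = [r for r in provisional if r.flag == "none"]
        target_fst = calibrate_target_fst(
            multilocus_fst(trimmed or records), len(cats), sizes,
            seed=int(rng.integers(2**31 - 1)), freq_method=freq_method,
        )
    envelope = fdist_null_envelope(
        len(cats), sizes, target_fst, n_sim, quantiles,
        seed=int(rng.integers(2**31 - 1)), freq_method=freq_method,
    )
    return fdist_outliers(records, envelope), envelope


# -- environmental association --------------------------------------------


def _logistic_fit(y: np.ndarray, x: np.ndarray):
    """Univariate ML logistic fit; returns (beta, se, ll_full, separation)."""
    import statsmodels.api as sm

    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return np.nan, np.nan, np.nan, True
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    converged = bool(getattr(fit, "mle_retvals", {}).get("converged", True))
    separation = not np.isfinite(se) or se > 1e4 or not converged
    return beta, se, float(fit.llf), separation


def env_logistic_scan(
    b: BandMatrix,
    s: SoilTable,
    assignment: dict[str, str] | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    threshold: float | None = None,
) -> list[EnvAssociation]:
    """Univariate logistic association of each locus with each soil variable.

    Individuals carry their site means of the environmental variables.  A
    locus x variable model is significant when both the likelihood-ratio G
    test and the Wald test fall below the corrected threshold
    (``alpha / (n_loci * n_variables)`` for Bonferroni, overridable via
    ``threshold``).  Perfect separation suppresses the Wald test and flags
    the record.
    """
    if assignment is None:
        assignment = dict(zip(b.sample_ids, b.site))
    variables = [v for v in s.variables]
    env = {
        v: np.asarray([s.values_for(v)[assignment[i]] for i in b.sample_ids], dtype=float)
        for v in variables
    }
    const = [v for v in variables if np.allclose(env[v], env[v][0])]
    if const:
        raise ValueError(f"environmental variables constant across samples: {const}")
    n_tests = b.n_loci * len(variables)
    if threshold is None:
        if correction == "bonferroni":
            threshold = alpha / n_tests
        elif correction == "none":
            threshold = alpha
        else:
            raise ValueError(f"unknown correction {correction!r}")
    out = []
    chi2_sf = stats.chi2(1).sf
    for j, locus in enumerate(b.locus_ids):
        col = b.values[:, j]
        ok = np.isfinite(col)
        y = col[ok]
        n1 = int(y.sum())
        if n1 == 0 or n1 == y.size:
            continue  # monomorphic locus: no association model
        pi = n1 / y.size
        ll_null = n1 * np.log(pi) + (y.size - n1) * np.log(1 - pi)
        for v in variables:
            x = env[v][ok]
            beta, se, ll_full, sep = _logistic_fit(y, x)
            if sep or not np.isfinite(ll_full):
                out.append(
                    EnvAssociation(locus, v, beta, max(0.0, 2 * (ll_full - ll_null)) if np.isfinite(ll_full) else np.nan,
                                   np.nan, np.nan, np.nan, False, separation=True)
                )
                continue
            g = max(0.0, 2.0 * (ll_full - ll_null))
            wald = (beta / se) ** 2
            p_g = float(chi2_sf(g))
            p_w = float(chi2_sf(wald))
            out.append(
                EnvAssociation(
                    locus, v, beta, g, wald, p_g, p_w,
                    significant=(p_g < threshold) and (p_w < threshold),
                )
            )
    return out
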