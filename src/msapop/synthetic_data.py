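"""Synthetic AFLP + MSAP datasets with known ground truth.

The generator emulates the sampling design of a four-habitat, three-sites-
per-habitat field survey (80 individuals by default) and produces:

* an AFLP band matrix with nested neutral structure (Balding-Nichols
  island model at the habitat level, then at the site level within
  habitats) plus a configurable number of planted selection outliers
  simulated at an elevated theta;
* a paired HpaII/MspI MSAP assay in which a configurable fraction of loci
  are methylation-susceptible (MSL).  Each MSL's methylation indicator is
  drawn from a mixture of *obligate* (deterministic in an underlying
  genotype), *facilitated* (probabilistic given genotype) and *pure*
  (logistic in a soil variable) epiloci; the indicator is rendered as
  (1,0) or (0,1) with equal probability when methylated and (1,1) when
  unmethylated, then per-cell scoring errors are flipped independently
  into both matrices;
* a site-level soil table drawn around habitat-specific means;
* a :class:`SyntheticTruth` record of everything planted, for recovery
  tests.

By default the island model is placed directly on band-presence
frequencies, so the planted theta is the quantity that distance-based
Phi statistics estimate; ``band_model="hwe_dominant"`` instead treats the
Balding-Nichols frequency as a presence-allele frequency and samples
dominant diploid phenotypes, which makes Phi overshoot theta by the
classical dominant-marker bias.

A single integer seed drives everything; independent sub-streams are
spawned per component so, e.g., adding loci does not reshuffle soil draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .band import CANONICAL_SOIL_VARIABLES, BandMatrix, MsapPair, SoilTable

__all__ = ["SimParams", "SyntheticTruth", "simulate_dataset", "render_replicates", "simulate_phenotypes"]

# per-habitat soil means for the default four habitats
# (wet low-lying meadow / bare saline-alkaline patch / meadow steppe / sandy)
_DEFAULT_SOIL_MEANS = {
    "moisture": (25.0, 12.0, 18.0, 10.0),
    "pH": (8.2, 10.3, 8.8, 8.3),
    "EC": (0.4, 2.5, 0.8, 0.3),
    "total_P": (0.45, 0.30, 0.40, 0.35),
    "total_N": (1.8, 0.9, 1.5, 1.0),
    "organic_matter": (35.0, 15.0, 28.0, 16.0),
    "NO3_N": (12.0, 6.0, 10.0, 5.0),
    "NH4_N": (8.0, 5.0, 7.0, 4.0),
    "Cl": (60.0, 400.0, 120.0, 40.0),
    "SO4": (80.0, 350.0, 150.0, 60.0),
    "Na": (120.0, 900.0, 250.0, 90.0),
    "K": (40.0, 70.0, 50.0, 35.0),
    "Mg": (30.0, 20.0, 25.0, 28.0),
    "Ca": (90.0, 60.0, 80.0, 100.0),
}
_DEFAULT_SOIL_SD_FRAC = 0.08  # within-habitat between-site sd as fraction of mean

#: Site sizes of the default survey design (three sites in each of four habitats).
DEFAULT_SITE_SIZES = (6, 7, 7, 7, 6, 7, 7, 6, 7, 6, 6, 8)


@dataclass
class SimParams:
    """Generator settings; defaults match the emulated survey design."""

    n_habitats: int = 4
    sites_per_habitat: int = 3
    individuals_per_site: tuple | int = DEFAULT_SITE_SIZES
    n_aflp: int = 2478
    n_msap: int = 2884
    msl_fraction: float = 2.0 / 3.0
    theta_habitat: float = 0.10
    theta_site: float = 0.05
    n_outliers: int = 24
    outlier_theta: float = 0.50
    env_effect: float = 2.0  # logistic slope per sd of the driving soil variable
    facilitation: float = 0.8  # P(methylated | genotype carrier) for facilitated epiloci
    error_rate: float = 0.02  # per-cell flip probability in each MSAP matrix
    band_model: str = "band_bernoulli"  # or "hwe_dominant"
    epilocus_class_probs: tuple = (0.3, 0.3, 0.4)  # obligate, facilitated, pure
    env_variable: str = "total_N"
    phenotype_coefficients: dict | None = None
    soil_means: dict | None = None
    soil_sd_frac: float = _DEFAULT_SOIL_SD_FRAC
    seed: int = 0

    def site_sizes(self) -> list[int]:
        n_sites = self.n_habitats * self.sites_per_habitat
        if isinstance(self.individuals_per_site, int):
            return [self.individuals_per_site] * n_sites
        sizes = list(self.individuals_per_site)
        if len(sizes) != n_sites:
            raise ValueError(
                f"individuals_per_site must list {n_sites} sizes, got {len(sizes)}"
            )
        return [int(s) for s in sizes]

    def validate(self) -> None:
        for name in ("msl_fraction", "facilitation", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("theta_habitat", "theta_site", "outlier_theta"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if min(self.n_aflp, self.n_msap, self.n_habitats, self.sites_per_habitat) < 1:
            raise ValueError("counts must be positive")
        if self.n_outliers > self.n_aflp:
            raise ValueError("more outliers than AFLP loci")
        if self.band_model not in ("band_bernoulli", "hwe_dominant"):
            raise ValueError(f"unknown band_model {self.band_model!r}")
        if abs(sum(self.epilocus_class_probs) - 1.0) > 1e-9:
            raise ValueError("epilocus_class_probs must sum to 1")


@dataclass
class SyntheticTruth:
    """Planted effects, for recovery testing."""

    params: SimParams
    aflp_habitat_freqs: np.ndarray  # (n_habitats, n_aflp)
    aflp_site_freqs: np.ndarray  # (n_sites, n_aflp)
    outlier_locus_ids: list[str]
    msl_locus_ids: list[str]
    epilocus_class: dict[str, str]  # MSL id -> obligate | facilitated | pure
    env_slopes: dict[str, float]  # pure epilocus id -> logistic slope
    env_variable: str
    clean_hpa: np.ndarray = field(repr=False, default=None)
    clean_msp: np.ndarray = field(repr=False, default=None)
    methylation_truth: np.ndarray = field(repr=False, default=None)  # (n, n_msl)
    phenotype_coefficients: dict | None = None


def _nested_freqs(rng, n_loci, thetas_by_locus, theta_site, n_habitats, sites_per_habitat):
    """Ancestral -> habitat -> site frequencies under the Beta island model."""
    u = rng.uniform(0.05, 0.95, n_loci)
    th = np.asarray(thetas_by_locus)
    hab = rng.beta(u * (1 - th) / th, (1 - u) * (1 - th) / th, size=(n_habitats, n_loci))
    hab = np.clip(hab, 1e-6, 1 - 1e-6)
    site = rng.beta(
        hab[:, None, :] * (1 - theta_site) / theta_site,
        (1 - hab[:, None, :]) * (1 - theta_site) / theta_site,
        size=(n_habitats, sites_per_habitat, n_loci),
    )
    return u, hab, site.reshape(n_habitats * sites_per_habitat, n_loci)


def _sample_bands(rng, site_freqs, sizes, band_model):
    rows = []
    for k, n in enumerate(sizes):
        f = site_freqs[k]
        if band_model == "hwe_dominant":
            f = 1.0 - (1.0 - f) ** 2
        rows.append(rng.random((n, site_freqs.shape[1])) < f)
    return np.vstack(rows).astype(float)


def simulate_dataset(p: SimParams) -> tuple[BandMatrix, MsapPair, SoilTable, SyntheticTruth]:
    """Generate one complete synthetic dataset; byte-identical per seed."""
    p.validate()
    sizes = p.site_sizes()
    n_total = sum(sizes)
    n_sites = len(sizes)
    streams = np.random.SeedSequence(p.seed).spawn(6)
    rng_aflp, rng_msap, rng_soil, rng_err, rng_meth, _ = (
        np.random.default_rng(s) for s in streams
    )

    habitats = [f"H{h + 1}" for h in range(p.n_habitats)]
    site_names = [
        f"H{h + 1}S{s + 1}" for h in range(p.n_habitats) for s in range(p.sites_per_habitat)
    ]
    sample_ids, hab_labels, site_labels = [], [], []
    for k, n in enumerate(sizes):
        h = k // p.sites_per_habitat
        for i in range(n):
            sample_ids.append(f"{site_names[k]}_{i + 1:02d}")
            hab_labels.append(habitats[h])
            site_labels.append(site_names[k])

    # ---- soil ------------------------------------------------------------
    means = p.soil_means or _DEFAULT_SOIL_MEANS
    soil_rows = {}
    for var in CANONICAL_SOIL_VARIABLES:
        mu = np.asarray(means[var], dtype=float)
        mu = mu[np.arange(p.n_habitats) % mu.size]  # tile beyond four habitats
        per_site = np.repeat(mu, p.sites_per_habitat)
        sd = np.abs(per_site) * p.soil_sd_frac
        soil_rows[var] = per_site + rng_soil.normal(0.0, sd, n_sites)
    soil = SoilTable(pd.DataFrame(soil_rows, index=site_names))

    # ---- AFLP with planted outliers -------------------------------------
    thetas = np.full(p.n_aflp, p.theta_habitat)
    outlier_idx = rng_aflp.choice(p.n_aflp, size=p.n_outliers, replace=False)
    thetas[outlier_idx] = p.outlier_theta
    _, hab_f, site_f = _nested_freqs(
        rng_aflp, p.n_aflp, thetas, p.theta_site, p.n_habitats, p.sites_per_habitat
    )
    aflp_vals = _sample_bands(rng_aflp, site_f, sizes, p.band_model)
    aflp_ids = [f"A{j + 1:04d}" for j in range(p.n_aflp)]
    aflp_sizes = rng_aflp.integers(150, 501, p.n_aflp).astype(float)
    aflp = BandMatrix(
        values=aflp_vals, sample_ids=sample_ids, habitat=hab_labels,
        site=site_labels, locus_ids=aflp_ids, fragment_size_bp=aflp_sizes,
    )

    # ---- MSAP ------------------------------------------------------------
    n_msl = int(round(p.msl_fraction * p.n_msap))
    n_nml = p.n_msap - n_msl
    msap_ids = [f"E{j + 1:04d}" for j in range(p.n_msap)]
    msl_ids, nml_ids = msap_ids[:n_msl], msap_ids[n_msl:]

    # NML loci: ordinary dominant bands, identical in both enzyme profiles
    _, _, nml_site_f = _nested_freqs(
        rng_msap, n_nml, np.full(n_nml, p.theta_habitat), p.theta_site,
        p.n_habitats, p.sites_per_habitat,
    ) if n_nml else (None, None, np.empty((n_sites, 0)))
    nml_bands = _sample_bands(rng_msap, nml_site_f, sizes, p.band_model)

    # MSL loci: an underlying fragment must exist before methylation shows
    frag_u = rng_msap.uniform(0.7, 0.98, n_msl)
    frag_present = np.vstack([
        rng_msap.random((n, n_msl)) < frag_u for n in sizes
    ]).astype(bool)
    # linked genotype for obligate/facilitated classes, with the same
    # nested structure as neutral loci
    _, _, geno_site_f = _nested_freqs(
        rng_meth, n_msl, np.full(n_msl, p.theta_habitat), p.theta_site,
        p.n_habitats, p.sites_per_habitat,
    )
    genotype = _sample_bands(rng_meth, geno_site_f, sizes, "band_bernoulli").astype(bool)
    classes = rng_meth.choice(
        ["obligate", "facilitated", "pure"], size=n_msl, p=p.epilocus_class_probs
    )
    z_env = soil.values_for(p.env_variable).to_numpy()
    z_env = (z_env - z_env.mean()) / z_env.std()
    z_ind = np.concatenate([np.full(n, z_env[k]) for k, n in enumerate(sizes)])
    slopes = rng_meth.normal(p.env_effect, 0.2 * abs(p.env_effect), n_msl)
    intercepts = rng_meth.normal(0.0, 0.5, n_msl)
    meth = np.zeros((n_total, n_msl), dtype=bool)
    is_obl = classes == "obligate"
    is_fac = classes == "facilitated"
    is_pure = classes == "pure"
    meth[:, is_obl] = genotype[:, is_obl]
    pm = np.where(genotype[:, is_fac], p.facilitation, 1.0 - p.facilitation)
    meth[:, is_fac] = rng_meth.random(pm.shape) < pm
    prob_pure = expit(intercepts[is_pure] + slopes[is_pure] * z_ind[:, None])
    meth[:, is_pure] = rng_meth.random(prob_pure.shape) < prob_pure

    # rendering: methylated -> (1,0)/(0,1) equiprobably, unmethylated -> (1,1),
    # fragment absent -> (0,0)
    hpa_msl = np.zeros((n_total, n_msl))
    msp_msl = np.zeros((n_total, n_msl))
    unmeth = frag_present & ~meth
    hpa_msl[unmeth] = 1.0
    msp_msl[unmeth] = 1.0
    shown = frag_present & meth
    pick_hpa = rng_meth.random((n_total, n_msl)) < 0.5
    hpa_msl[shown & pick_hpa] = 1.0
    msp_msl[shown & ~pick_hpa] = 1.0

    clean_hpa = np.hstack([hpa_msl, nml_bands])
    clean_msp = np.hstack([msp_msl, nml_bands])

    def flip(mat, rng):
        f = rng.random(mat.shape) < p.error_rate
        return np.abs(mat - f.astype(float))

    hpa_vals = flip(clean_hpa, rng_err)
    msp_vals = flip(clean_msp, rng_err)
    msap_sizes = rng_msap.integers(150, 501, p.n_msap).astype(float)

    def bm(vals):
        return BandMatrix(
            values=vals, sample_ids=sample_ids, habitat=hab_labels,
            site=site_labels, locus_ids=msap_ids, fragment_size_bp=msap_sizes,
        )

    msap = MsapPair(hpa=bm(hpa_vals), msp=bm(msp_vals))

    truth = SyntheticTruth(
        params=p,
        aflp_habitat_freqs=hab_f,
        aflp_site_freqs=site_f,
        outlier_locus_ids=[aflp_ids[j] for j in sorted(outlier_idx)],
        msl_locus_ids=list(msl_ids),
        epilocus_class={msl_ids[j]: classes[j] for j in range(n_msl)},
        env_slopes={msl_ids[j]: float(slopes[j]) for j in np.flatnonzero(is_pure)},
        env_variable=p.env_variable,
        clean_hpa=clean_hpa,
        clean_msp=clean_msp,
        methylation_truth=meth,
        phenotype_coefficients=p.phenotype_coefficients,
    )
    return aflp, msap, soil, truth


def render_replicates(
    truth: SyntheticTruth,
    n_individuals: int = 6,
    seed: int | None = None,
) -> list[tuple[BandMatrix, BandMatrix]]:
    """Re-render a subset of individuals twice with fresh scoring errors.

    Emulates the duplicate assays used to estimate the genotyping error
    rate: both members of each returned pair come from the same clean
    banding truth, independently corrupted at the planted error rate.
    Returns [(hpa_run1, hpa_run2), (msp_run1, msp_run2)].
    """
    p = truth.params
    rng = np.random.default_rng(seed if seed is not None else p.seed + 1)
    sizes = p.site_sizes()
    n_total = sum(sizes)
    idx = rng.choice(n_total, size=n_individuals, replace=False)
    site_names = [
        f"H{h + 1}S{s + 1}" for h in range(p.n_habitats) for s in range(p.sites_per_habitat)
    ]
    sample_ids, habs, sites_l = [], [], []
    for k, n in enumerate(sizes):
        h = k // p.sites_per_habitat
        for i in range(n):
            sample_ids.append(f"{site_names[k]}_{i + 1:02d}")
            habs.append(f"H{h + 1}")
            sites_l.append(site_names[k])
    msap_ids = [f"E{j + 1:04d}" for j in range(p.n_msap)]

    def corrupt(clean):
        f = rng.random(clean.shape) < p.error_rate
        return np.abs(clean - f.astype(float))

    out = []
    for clean in (truth.clean_hpa, truth.clean_msp):
        sub = clean[idx]
        run1, run2 = corrupt(sub), corrupt(sub)
        mats = [
            BandMatrix(
                values=v,
                sample_ids=[sample_ids[i] for i in idx],
                habitat=[habs[i] for i in idx],
                site=[sites_l[i] for i in idx],
                locus_ids=msap_ids,
            )
            for v in (run1, run2)
        ]
        out.append((mats[0], mats[1]))
    return out


def simulate_phenotypes(
    truth: SyntheticTruth,
    methylation_binary: BandMatrix,
    noise_sd: float = 1.0,
    coefficients: dict[str, float] | None = None,
    intercept: float = 10.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-individual trait driven by methylation at chosen epiloci.

    trait = intercept + sum over epiloci of coef * methylated(individual)
    + Normal(0, noise_sd).  Missing methylation scores contribute the
    locus mean, so traits stay defined for every individual.
    """
    coefs = coefficients if coefficients is not None else (truth.phenotype_coefficients or {})
    rng = np.random.default_rng(seed if seed is not None else truth.params.seed + 2)
    n = methylation_binary.n_samples
    trait = np.full(n, float(intercept))
    for locus, c in coefs.items():
        j = methylation_binary.locus_ids.index(locus)
        col = methylation_binary.values[:, j]
        fill = np.nanmean(col) if np.isfinite(col).any() else 0.0
        trait = trait + c * np.where(np.isfinite(col), col, fill)
    if noise_sd > 0:
        trait = trait + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"sample": methylation_binary.sample_ids, "trait": trait}).set_index("sample")
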