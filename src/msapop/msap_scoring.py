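"""Methylation-state scoring of paired *Hpa*II/*Msp*I MSAP profiles.

The two isoschizomers differ in sensitivity to cytosine methylation at CCGG
sites, so the joint (HpaII, MspI) band pattern of an individual at a locus
encodes a methylation state:

==========  =======================  ==============
(hpa, msp)  state                    binary view
==========  =======================  ==============
(1, 1)      type 1, unmethylated     0
(1, 0)      type 2, hemimethylated   1
(0, 1)      type 3, internal-C       1
(0, 0)      type 4, uninformative    missing
==========  =======================  ==============

Pattern (0,0) is uninformative because it may reflect either fragment
absence or hypermethylation of both strands, and is treated as a missing
binary score.  Loci are split into methylation-susceptible loci (MSL) and
nonmethylated loci (NML) by whether the observed fraction of discordant
(hpa != msp) scores exceeds an error-based threshold; NML are then analysed
as ordinary dominant bands, MSL as methylated/unmethylated epialleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .band import AlignmentError, BandMatrix, MsapPair

__all__ = [
    "TYPE1_UNMETHYLATED",
    "TYPE2_HEMIMETHYLATED",
    "TYPE3_INTERNAL_METHYLATED",
    "TYPE4_UNINFORMATIVE",
    "MethylationMatrix",
    "LocusClassification",
    "ErrorRateEstimate",
    "DEFAULT_EPSILON",
    "score_methylation_states",
    "estimate_error_rate",
    "classify_loci",
    "classification_frame",
    "split_msl_nml",
    "apply_band_filters",
    "state_proportions",
]

log = logging.getLogger(__name__)

TYPE1_UNMETHYLATED = 1
TYPE2_HEMIMETHYLATED = 2
TYPE3_INTERNAL_METHYLATED = 3
TYPE4_UNINFORMATIVE = 4

STATE_NAMES = {
    TYPE1_UNMETHYLATED: "unmethylated",
    TYPE2_HEMIMETHYLATED: "hemimethylated",
    TYPE3_INTERNAL_METHYLATED: "internal_methylated",
    TYPE4_UNINFORMATIVE: "uninformative",
}

#: Fallback per-individual mismatch threshold when no replicate assays are
#: available to estimate one.
DEFAULT_EPSILON = 0.05


@dataclass
class MethylationMatrix:
    """Per-individual, per-locus methylation state of an MSAP assay.

    ``state`` holds codes 1-4 (see module docstring).  ``observed`` marks
    cells where both enzyme scores were non-missing; a type-4 cell can
    therefore be an *observed* (0,0) pattern (informative but uninformative
    as to state) or a missing-input cell.
    """

    state: np.ndarray  # (n, L) int codes 1..4
    observed: np.ndarray  # (n, L) bool: both enzyme scores present
    sample_ids: list[str]
    habitat: list[str]
    site: list[str]
    locus_ids: list[str]
    fragment_size_bp: np.ndarray | None = None

    @property
    def binary_view(self) -> np.ndarray:
        """0 = unmethylated, 1 = methylated, NaN = uninformative/missing."""
        out = np.full(self.state.shape, np.nan)
        out[self.state == TYPE1_UNMETHYLATED] = 0.0
        out[(self.state == TYPE2_HEMIMETHYLATED) | (self.state == TYPE3_INTERNAL_METHYLATED)] = 1.0
        return out

    def binary_band_matrix(self) -> BandMatrix:
        """The methylated/unmethylated encoding as a :class:`BandMatrix`."""
        return BandMatrix(
            values=self.binary_view,
            sample_ids=self.sample_ids,
            habitat=self.habitat,
            site=self.site,
            locus_ids=self.locus_ids,
            fragment_size_bp=self.fragment_size_bp,
        )


@dataclass
class LocusClassification:
    locus_id: str
    discordance: float
    n_informative: int
    label: str  # "MSL" | "NML"
    threshold_used: float
    no_informative_flag: bool = False


@dataclass
class ErrorRateEstimate:
    """Pooled per-cell mismatch probability between replicate assays."""

    epsilon: float
    n_duplicate_pairs: int
    n_comparisons: int


def score_methylation_states(pair: MsapPair) -> MethylationMatrix:
    """Map each (hpa, msp) score pair to a methylation state code.

    Cellwise and order-invariant; any missing input score yields type 4
    with ``observed`` False.
    """
    if not isinstance(pair, MsapPair):
        raise AlignmentError("score_methylation_states requires an aligned MsapPair")
    h, m = pair.hpa.values, pair.msp.values
    observed = np.isfinite(h) & np.isfinite(m)
    state = np.full(h.shape, TYPE4_UNINFORMATIVE, dtype=np.int8)
    state[observed & (h == 1) & (m == 1)] = TYPE1_UNMETHYLATED
    state[observed & (h == 1) & (m == 0)] = TYPE2_HEMIMETHYLATED
    state[observed & (h == 0) & (m == 1)] = TYPE3_INTERNAL_METHYLATED
    return MethylationMatrix(
        state=state,
        observed=observed,
        sample_ids=pair.sample_ids,
        habitat=pair.hpa.habitat,
        site=pair.hpa.site,
        locus_ids=pair.locus_ids,
        fragment_size_bp=pair.hpa.fragment_size_bp,
    )


def estimate_error_rate(replicate_pairs: list[tuple[BandMatrix, BandMatrix]]) -> ErrorRateEstimate:
    """Pooled genotyping error rate from repeated assays of the same samples.

    ``epsilon`` is the fraction of discordant cells among all cells compared
    (missing scores excluded) across every replicate pair.
    """
    discordant = 0
    compared = 0
    for a, b in replicate_pairs:
        if a.sample_ids != b.sample_ids or a.locus_ids != b.locus_ids:
            raise AlignmentError("replicate pair has mismatched sample or locus ids")
        mask = np.isfinite(a.values) & np.isfinite(b.values)
        compared += int(mask.sum())
        discordant += int((a.values[mask] != b.values[mask]).sum())
    if compared == 0:
        raise ValueError("no comparable cells across replicate pairs")
    return ErrorRateEstimate(
        epsilon=discordant / compared,
        n_duplicate_pairs=len(replicate_pairs),
        n_comparisons=compared,
    )


def classify_loci(m: MethylationMatrix, epsilon: float | None = None) -> list[LocusClassification]:
    """Split loci into MSL and NML by their HpaII/MspI discordance rate.

    Per locus the discordance is the fraction of type-2/type-3 individuals
    among individuals with both enzyme scores observed (an observed (0,0)
    pattern counts as informative but concordant).  A locus is MSL iff
    discordance is strictly greater than ``epsilon``; loci with no
    informative individual are labelled NML with a flag.
    """
    if epsilon is None:
        epsilon = DEFAULT_EPSILON
        log.warning(
            "classify_loci: no error-rate estimate supplied; using default "
            "mismatch threshold epsilon=%.3f", epsilon,
        )
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must be in [0, 1)")
    discordant = (
        (m.state == TYPE2_HEMIMETHYLATED) | (m.state == TYPE3_INTERNAL_METHYLATED)
    ) & m.observed
    n_inf = m.observed.sum(axis=0)
    n_dis = discordant.sum(axis=0)
    out = []
    for j, locus in enumerate(m.locus_ids):
        if n_inf[j] == 0:
            out.append(LocusClassification(locus, 0.0, 0, "NML", epsilon, True))
            continue
        d = n_dis[j] / n_inf[j]
        out.append(
            LocusClassification(locus, float(d), int(n_inf[j]), "MSL" if d > epsilon else "NML", epsilon)
        )
    return out


def classification_frame(classifications: list[LocusClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [c.locus_id for c in classifications],
            "discordance": [c.discordance for c in classifications],
            "n_informative": [c.n_informative for c in classifications],
            "label": [c.label for c in classifications],
            "threshold": [c.threshold_used for c in classifications],
            "no_informative": [c.no_informative_flag for c in classifications],
        }
    )


def split_msl_nml(
    m: MethylationMatrix,
    classifications: list[LocusClassification],
    pair: MsapPair | None = None,
    msl_source: str = "binary_view",
) -> tuple[BandMatrix, BandMatrix | None]:
    """Return (MSL matrix, NML matrix) for downstream analyses.

    MSL loci are scored as methylated/unmethylated (the binary view) by
    default, or as the raw *Hpa*II banding with ``msl_source="hpa"``.  NML
    loci are ordinary dominant bands taken from the *Msp*I profile when the
    original pair is supplied (else from the binary view, where type 1 = 1).
    """
    is_msl = np.array([c.label == "MSL" for c in classifications])
    if is_msl.size != len(m.locus_ids):
        raise ValueError("classification list does not match loci")
    if msl_source == "binary_view":
        msl = m.binary_band_matrix().select_loci(is_msl)
    elif msl_source == "hpa":
        if pair is None:
            raise ValueError("msl_source='hpa' requires the original MsapPair")
        msl = pair.hpa.select_loci(is_msl)
    else:
        raise ValueError(f"unknown msl_source {msl_source!r}")
    nml = None
    if (~is_msl).any():
        if pair is not None:
            nml = pair.msp.select_loci(~is_msl)
        else:
            v = np.where(m.observed, (m.state != TYPE4_UNINFORMATIVE).astype(float), np.nan)
            nml = BandMatrix(
                values=v, sample_ids=m.sample_ids, habitat=m.habitat,
                site=m.site, locus_ids=m.locus_ids,
            ).select_loci(~is_msl)
    return msl, nml


def apply_band_filters(
    b: BandMatrix,
    min_carriers: int = 4,
    size_range: tuple[float, float] | None = (150, 500),
    drop_singleton_nonconsensus: bool = True,
) -> tuple[BandMatrix, dict[str, str]]:
    """Apply the standard reliability filters to a scored band matrix.

    Removes loci carried by fewer than ``min_carriers`` individuals, loci
    with fragment sizes outside ``size_range`` (skipped with a warning when
    sizes are unknown), and loci where exactly one individual deviates from
    the consensus state.  Returns the filtered matrix and a log mapping each
    removed locus id to the first filter that removed it.
    """
    removed: dict[str, str] = {}
    keep = np.ones(b.n_loci, dtype=bool)
    vals = b.values
    carriers = (vals == 1).sum(axis=0)
    for j, locus in enumerate(b.locus_ids):
        if carriers[j] < min_carriers:
            removed[locus] = "min_carriers"
            keep[j] = False
    if size_range is not None:
        if b.fragment_size_bp is None:
            log.warning("apply_band_filters: fragment sizes unknown; size filter skipped")
        else:
            lo, hi = size_range
            for j, locus in enumerate(b.locus_ids):
                if keep[j] and not (lo <= b.fragment_size_bp[j] <= hi):
                    removed[locus] = "size_range"
                    keep[j] = False
    if drop_singleton_nonconsensus:
        for j, locus in enumerate(b.locus_ids):
            if not keep[j]:
                continue
            col = vals[:, j]
            col = col[np.isfinite(col)]
            n1 = int((col == 1).sum())
            n0 = int((col == 0).sum())
            if (n1 == 1 and n0 >= 1) or (n0 == 1 and n1 >= 1):
                removed[locus] = "singleton"
                keep[j] = False
    if not keep.any():
        raise ValueError("band filters removed every locus")
    return b.select_loci(keep), removed


def state_proportions(m: MethylationMatrix, by: str = "habitat") -> pd.DataFrame:
    """Proportion of the four methylation states per group (observed cells)."""
    labels = np.asarray(m.habitat if by == "habitat" else m.site)
    rows = []
    for g in dict.fromkeys(labels):
        sel = labels == g
        st = m.state[sel][m.observed[sel]]
        total = st.size
        rows.append(
            {"group": g, "n_scores": total}
            | {
                STATE_NAMES[k]: (st == k).sum() / total if total else np.nan
                for k in STATE_NAMES
            }
        )
    return pd.DataFrame(rows).set_index("group")
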