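"""Core in-memory containers for dominant-marker data.

A :class:`BandMatrix` is the universal unit of analysis: an individuals-by-loci
matrix of band presence/absence calls (0/1, ``NaN`` for missing) carrying the
nested sampling design (habitat > site > individual) plus optional per-locus
fragment sizes in base pairs.  An :class:`MsapPair` holds the two aligned
profiles of a methylation-sensitive AFLP assay (*Eco*RI/*Hpa*II and
*Eco*RI/*Msp*I digests of the same individuals).  A :class:`SoilTable` holds
site-level means of the measured soil variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "MsapPair",
    "SoilTable",
    "CANONICAL_SOIL_VARIABLES",
    "FormatError",
    "AlignmentError",
]

#: The canonical soil variables assayed per site, in reporting order.
CANONICAL_SOIL_VARIABLES = (
    "moisture",
    "pH",
    "EC",
    "total_P",
    "total_N",
    "organic_matter",
    "NO3_N",
    "NH4_N",
    "Cl",
    "SO4",
    "Na",
    "K",
    "Mg",
    "Ca",
)


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


class AlignmentError(ValueError):
    """Raised when paired inputs cannot be aligned on sample or locus ids."""


def _as_str_list(x) -> list[str]:
    return [str(v) for v in x]


@dataclass
class BandMatrix:
    """Individuals x loci binary band matrix with sampling-design labels.

    Parameters
    ----------
    values
        ``(n_samples, n_loci)`` float array with entries in ``{0.0, 1.0, nan}``;
        ``nan`` encodes a missing score.
    sample_ids, habitat, site
        Per-sample identifiers and design labels.  Site labels must nest
        within habitats (each site maps to exactly one habitat).
    locus_ids
        Unique per-locus identifiers.
    fragment_size_bp
        Optional per-locus fragment length in base pairs; filters that need
        sizes are skipped when this is absent.
    """

    values: np.ndarray
    sample_ids: list[str]
    habitat: list[str]
    site: list[str]
    locus_ids: list[str]
    fragment_size_bp: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _as_str_list(self.sample_ids)
        self.habitat = _as_str_list(self.habitat)
        self.site = _as_str_list(self.site)
        self.locus_ids = _as_str_list(self.locus_ids)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D array")
        n, L = self.values.shape
        if n == 0 or L == 0:
            raise FormatError("empty band matrix")
        if len(self.sample_ids) != n:
            raise FormatError("sample_ids length does not match values")
        if len(self.habitat) != n or len(self.site) != n:
            raise FormatError("habitat/site labels must be given per sample")
        if len(self.locus_ids) != L:
            raise FormatError("locus_ids length does not match values")
        if len(set(self.sample_ids)) != n:
            dups = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise FormatError(f"duplicate sample ids: {dups}")
        if len(set(self.locus_ids)) != L:
            raise FormatError("duplicate locus ids")
        site_to_hab: dict[str, str] = {}
        for s, h in zip(self.site, self.habitat):
            if site_to_hab.setdefault(s, h) != h:
                raise FormatError(f"site {s!r} assigned to multiple habitats")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            bad = sorted(set(finite) - {0.0, 1.0})
            raise FormatError(f"band values must be 0/1/missing; found {bad}")
        if self.fragment_size_bp is not None:
            self.fragment_size_bp = np.asarray(self.fragment_size_bp, dtype=float)
            if self.fragment_size_bp.shape != (L,):
                raise FormatError("fragment_size_bp must be one value per locus")

    # -- basic shape -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing cells."""
        return np.isfinite(self.values)

    # -- subsetting --------------------------------------------------------

    def select_loci(self, index) -> "BandMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        sizes = None
        if self.fragment_size_bp is not None:
            sizes = self.fragment_size_bp[index]
        return replace(
            self,
            values=self.values[:, index],
            locus_ids=[self.locus_ids[i] for i in index],
            fragment_size_bp=sizes,
        )

    def select_samples(self, index) -> "BandMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            values=self.values[index],
            sample_ids=[self.sample_ids[i] for i in index],
            habitat=[self.habitat[i] for i in index],
            site=[self.site[i] for i in index],
        )

    def reorder_samples(self, sample_ids: list[str]) -> "BandMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing or len(sample_ids) != self.n_samples:
            raise AlignmentError(f"cannot reorder: ids not matching {missing}")
        return self.select_samples([pos[s] for s in sample_ids])

    def labels(self, level: str) -> np.ndarray:
        """Per-sample grouping labels for ``level`` in {'habitat', 'site'}."""
        if level == "habitat":
            return np.asarray(self.habitat)
        if level == "site":
            return np.asarray(self.site)
        raise ValueError(f"unknown grouping level {level!r}")

    def to_frame(self) -> pd.DataFrame:
        """Wide data frame with sample/habitat/site metadata columns first."""
        df = pd.DataFrame(self.values, columns=self.locus_ids)
        df.insert(0, "site", self.site)
        df.insert(0, "habitat", self.habitat)
        df.insert(0, "sample", self.sample_ids)
        return df


@dataclass
class MsapPair:
    """Aligned *Hpa*II / *Msp*I band matrices of one MSAP assay."""

    hpa: BandMatrix
    msp: BandMatrix

    def __post_init__(self) -> None:
        if self.hpa.sample_ids != self.msp.sample_ids:
            raise AlignmentError("MsapPair sample ids differ or are out of order")
        if self.hpa.locus_ids != self.msp.locus_ids:
            raise AlignmentError("MsapPair locus ids differ or are out of order")

    @property
    def sample_ids(self) -> list[str]:
        return self.hpa.sample_ids

    @property
    def locus_ids(self) -> list[str]:
        return self.hpa.locus_ids

    def select_loci(self, index) -> "MsapPair":
        return MsapPair(self.hpa.select_loci(index), self.msp.select_loci(index))


@dataclass
class SoilTable:
    """Site-level means of soil variables (one row per site)."""

    data: pd.DataFrame  # index: site ids, columns: variable names

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        if self.data.index.has_duplicates:
            raise FormatError("duplicate site ids in soil table")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise FormatError("soil table contains non-finite values")

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, variable: str) -> pd.Series:
        if variable not in self.data.columns:
            raise KeyError(f"unknown soil variable {variable!r}")
        return self.data[variable]
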