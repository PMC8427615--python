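"""Readers and writers for scored marker tables and soil data.

Two dialects of band-matrix files are supported:

``wide-csv``
    Samples as rows; the first three columns are ``sample,habitat,site``
    and every further column is a locus.  An optional reserved row whose
    sample id is ``#size_bp`` carries per-locus fragment sizes.  This is
    also the output format of :func:`write_band_matrix`.
``genalex-csv``
    GenAlEx-style export with two numeric/title header rows followed by a
    ``sample,pop,<loci...>`` header.  Read-only.  The ``pop`` label doubles
    as the site label; a habitat prefix separated by ``_`` or ``-``
    (e.g. ``H1_S2``) is split off when present, otherwise habitat == site.

Missing scores are accepted as ``?``, ``NA``, ``NaN`` or an empty cell and
stored as a single canonical missing code (NaN).
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .band import (
    CANONICAL_SOIL_VARIABLES,
    AlignmentError,
    BandMatrix,
    FormatError,
    MsapPair,
    SoilTable,
)

__all__ = [
    "read_band_matrix",
    "write_band_matrix",
    "read_msap_pair",
    "read_soil_table",
    "write_soil_table",
]

log = logging.getLogger(__name__)

MISSING_TOKENS = {"?", "na", "nan", ""}
SIZE_ROW_ID = "#size_bp"


def _parse_cell(tok: str, row: str, col: str) -> float:
    t = str(tok).strip()
    if t.lower() in MISSING_TOKENS:
        return np.nan
    if t in ("0", "1"):
        return float(t)
    # tolerate float renderings of 0/1 (e.g. "1.0") from spreadsheet exports
    try:
        v = float(t)
    except ValueError:
        v = None
    if v in (0.0, 1.0):
        return v
    raise FormatError(f"invalid band score {tok!r} at sample {row!r}, locus {col!r}")


def _parse_values(raw: pd.DataFrame, sample_ids: list[str]) -> np.ndarray:
    out = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy(dtype=object)
    cols = list(raw.columns)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            out[i, j] = _parse_cell(arr[i, j], sample_ids[i], cols[j])
    return out


def read_band_matrix(path, dialect: str = "wide-csv") -> BandMatrix:
    """Read a scored 0/1 band matrix.

    Raises
    ------
    FormatError
        On duplicate sample ids, ragged rows, empty matrices, or cell
        tokens outside ``{0, 1, missing codes}``.
    """
    if dialect == "wide-csv":
        return _read_wide(path)
    if dialect == "genalex-csv":
        return _read_genalex(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_csv_checked(path, **kw) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, **kw)
    except pd.errors.ParserError as e:  # ragged rows etc.
        raise FormatError(f"malformed CSV {path}: {e}") from e
    return df


def _read_wide(path) -> BandMatrix:
    df = _read_csv_checked(path)
    required = ["sample", "habitat", "site"]
    if list(df.columns[:3]) != required:
        raise FormatError(
            f"{path}: wide-csv must start with columns {required}, got {list(df.columns[:3])}"
        )
    if df.shape[1] == 3 or df.shape[0] == 0:
        raise FormatError(f"{path}: empty band matrix")
    sizes = None
    size_rows = df.index[df["sample"] == SIZE_ROW_ID]
    if len(size_rows):
        sizes = df.loc[size_rows[0]].iloc[3:].astype(float).to_numpy()
        df = df.drop(index=size_rows)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: empty band matrix")
    samples = df["sample"].tolist()
    values = _parse_values(df.iloc[:, 3:], samples)
    return BandMatrix(
        values=values,
        sample_ids=samples,
        habitat=df["habitat"].tolist(),
        site=df["site"].tolist(),
        locus_ids=list(df.columns[3:]),
        fragment_size_bp=sizes,
    )


def _split_pop_label(pop: str) -> tuple[str, str]:
    m = re.match(r"^([^_\-]+)[_\-](.+)$", pop)
    if m:
        return m.group(1), pop
    return pop, pop


def _read_genalex(path) -> BandMatrix:
    df = _read_csv_checked(path, header=None)
    if df.shape[0] < 4:
        raise FormatError(f"{path}: too short for a GenAlEx file")
    header = df.iloc[2].tolist()
    if str(header[0]).strip().lower() not in ("sample", "ind", "individual", "id"):
        raise FormatError(f"{path}: third row must be the 'sample,pop,...' header")
    loci = [str(c) for c in header[2:] if str(c).strip() != ""]
    body = df.iloc[3:, : 2 + len(loci)]
    body = body[body.iloc[:, 0].astype(str).str.strip() != ""]
    if body.empty or not loci:
        raise FormatError(f"{path}: empty band matrix")
    samples = body.iloc[:, 0].astype(str).tolist()
    pops = body.iloc[:, 1].astype(str).tolist()
    habs, sites = zip(*(_split_pop_label(p) for p in pops))
    raw = body.iloc[:, 2:]
    raw.columns = loci
    values = _parse_values(raw, samples)
    return BandMatrix(
        values=values,
        sample_ids=samples,
        habitat=list(habs),
        site=list(sites),
        locus_ids=loci,
    )


def write_band_matrix(b: BandMatrix, path) -> None:
    """Write a band matrix as wide CSV (round-trips through the reader)."""
    df = b.to_frame()
    out = df.copy()
    for c in b.locus_ids:
        col = out[c]
        out[c] = np.where(np.isfinite(col.to_numpy(dtype=float)),
                          col.astype(float).astype("Int64").astype(str), "?")
    if b.fragment_size_bp is not None:
        size_row = {"sample": SIZE_ROW_ID, "habitat": "", "site": ""}
        size_row.update({c: format(s, "g") for c, s in zip(b.locus_ids, b.fragment_size_bp)})
        out = pd.concat([pd.DataFrame([size_row]), out], ignore_index=True)
    out.to_csv(path, index=False)


def read_msap_pair(hpa_path, msp_path, dialect: str = "wide-csv") -> MsapPair:
    """Read the two enzyme profiles of an MSAP assay and align them.

    Samples and loci are matched by id (order-independent); the sample and
    locus order of the *Hpa*II file is preserved.
    """
    hpa = read_band_matrix(hpa_path, dialect)
    msp = read_band_matrix(msp_path, dialect)
    only_h = sorted(set(hpa.sample_ids) - set(msp.sample_ids))
    only_m = sorted(set(msp.sample_ids) - set(hpa.sample_ids))
    if only_h or only_m:
        raise AlignmentError(
            f"samples present in one file only: HpaII-only={only_h}, MspI-only={only_m}"
        )
    if set(hpa.locus_ids) != set(msp.locus_ids):
        diff = set(hpa.locus_ids) ^ set(msp.locus_ids)
        raise AlignmentError(f"locus sets differ between files: {sorted(diff)[:10]}")
    msp = msp.reorder_samples(hpa.sample_ids)
    if hpa.locus_ids != msp.locus_ids:
        order = [msp.locus_ids.index(l) for l in hpa.locus_ids]
        msp = msp.select_loci(order)
    return MsapPair(hpa=hpa, msp=msp)


# -- soil tables -----------------------------------------------------------

_SOIL_ALIASES = {
    "moisture": "moisture", "soilmoisture": "moisture", "water": "moisture",
    "ph": "pH",
    "ec": "EC", "conductivity": "EC", "electricalconductivity": "EC",
    "soilconductivity": "EC",
    "totalp": "total_P", "totalphosphorus": "total_P", "p": "total_P",
    "totaln": "total_N", "totalnitrogen": "total_N", "n": "total_N",
    "organicmatter": "organic_matter", "om": "organic_matter",
    "no3n": "NO3_N", "no3nitrogen": "NO3_N", "no3": "NO3_N",
    "nh4n": "NH4_N", "nh4nitrogen": "NH4_N", "nh4": "NH4_N",
    "cl": "Cl", "so4": "SO4", "na": "Na", "k": "K", "mg": "Mg", "ca": "Ca",
}


def _canon_soil_name(name: str) -> str:
    key = re.sub(r"\(.*?\)", "", str(name))  # strip unit annotations
    key = re.sub(r"[^a-z0-9]", "", key.lower())
    if key in _SOIL_ALIASES:
        return _SOIL_ALIASES[key]
    log.warning("soil variable %r not recognized; retained under given name", name)
    return str(name)


def read_soil_table(path) -> SoilTable:
    """Read a site x soil-variable table, averaging replicate rows per site.

    Variable names are normalized to the canonical set where recognized;
    unknown names are retained with a warning.
    """
    df = _read_csv_checked(path)
    site_col = next((c for c in df.columns if c.strip().lower() == "site"), None)
    if site_col is None:
        raise FormatError(f"{path}: soil table lacks a 'site' column")
    df = df.rename(columns={site_col: "site"})
    value_cols = [c for c in df.columns if c != "site"]
    if not value_cols or df.empty:
        raise FormatError(f"{path}: empty soil table")
    for c in value_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    means = df.groupby("site", sort=False)[value_cols].mean()
    means.columns = [_canon_soil_name(c) for c in means.columns]
    ordered = [v for v in CANONICAL_SOIL_VARIABLES if v in means.columns]
    extra = [c for c in means.columns if c not in ordered]
    return SoilTable(data=means[ordered + extra])


def write_soil_table(s: SoilTable, path) -> None:
    s.data.rename_axis("site").to_csv(path)
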