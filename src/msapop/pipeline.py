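"""Config-driven orchestration of the full analysis.

A single YAML config drives: load -> band filters -> methylation scoring
and MSL/NML classification -> diversity -> AMOVA suite (one- and
two-level, pairwise by habitat and by site) -> Mantel suite (genetic vs
epigenetic, partial Mantel against soil-difference matrices) -> outlier
and environmental scans -> ordination (PCoA, UPGMA).  Stages that need a
missing optional input (e.g. the soil table) are skipped with a logged
reason; any stage failure halts the run, with earlier outputs preserved
on disk.  The run manifest (versions, seeds, parameters, per-stage
timing) suffices to reproduce a run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, amova, diversity, marker_io, matrix_tests, msap_scoring, ordination, selection_scan

log = logging.getLogger("msapop.pipeline")

DEFAULT_PERMUTATIONS = {
    "amova": 9999,
    "mantel": 10000,
    "partial_mantel": 100000,
    "locus_amova": 999,
    "rda": 999,
    "upgma_boot": 1000,
}
DEFAULT_ALPHA = {"locus_amova": 0.01, "env_scan": 0.05}
DEFAULT_ENVELOPE_QUANTILES = (0.005, 0.995)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see :func:`load_config`."""

    output_dir: Path
    seed: int
    aflp_path: Path | None = None
    hpa_path: Path | None = None
    msp_path: Path | None = None
    soil_path: Path | None = None
    dialect: str = "wide-csv"
    epsilon: float | None = None
    filters: dict = field(default_factory=dict)
    permutations: dict = field(default_factory=lambda: dict(DEFAULT_PERMUTATIONS))
    alpha: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    envelope_quantiles: tuple = DEFAULT_ENVELOPE_QUANTILES
    fdist_sims: int = 20000

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        for name in ("aflp_path", "hpa_path", "msp_path", "soil_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        if self.aflp_path is None and self.hpa_path is None:
            raise ConfigError("need at least an AFLP matrix or an MSAP pair")
        if (self.hpa_path is None) != (self.msp_path is None):
            raise ConfigError("MSAP input needs both hpa and msp paths")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    inputs = raw.get("inputs", {})
    perms = dict(DEFAULT_PERMUTATIONS)
    perms.update(raw.get("permutations", {}))
    alpha = dict(DEFAULT_ALPHA)
    alpha.update(raw.get("alpha", {}))
    cfg = PipelineConfig(
        output_dir=Path(raw.get("output_dir", "msapop_out")),
        seed=raw.get("seed"),
        aflp_path=inputs.get("aflp"),
        hpa_path=inputs.get("hpa"),
        msp_path=inputs.get("msp"),
        soil_path=inputs.get("soil"),
        dialect=inputs.get("dialect", "wide-csv"),
        epsilon=raw.get("epsilon"),
        filters=raw.get("filters", {}),
        permutations=perms,
        alpha=alpha,
        envelope_quantiles=tuple(raw.get("envelope_quantiles", DEFAULT_ENVELOPE_QUANTILES)),
        fdist_sims=raw.get("fdist_sims", 20000),
    )
    cfg.validate()
    return cfg


def _seed_for(cfg: PipelineConfig, stage: str) -> int:
    # deterministic per-stage sub-seed below 2**31 (crc32 is process-stable)
    import zlib

    tag = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence([cfg.seed, tag]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "permutations": cfg.permutations,
        "alpha": cfg.alpha,
        "stages": [],
        "skipped": [],
    }
    t_all = time.perf_counter()

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception:
                log.error("stage %s failed", name)
                manifest["failed_stage"] = name
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
                raise
            manifest["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        if cfg.aflp_path:
            state["aflp"] = marker_io.read_band_matrix(cfg.aflp_path, cfg.dialect)
        if cfg.hpa_path:
            state["msap"] = marker_io.read_msap_pair(cfg.hpa_path, cfg.msp_path, cfg.dialect)
        if cfg.soil_path:
            state["soil"] = marker_io.read_soil_table(cfg.soil_path)

    @stage("filter")
    def _filter():
        f = cfg.filters
        kwargs = dict(
            min_carriers=f.get("min_carriers", 4),
            size_range=tuple(f["size_range"]) if f.get("size_range") else (150, 500),
            drop_singleton_nonconsensus=f.get("drop_singleton", True),
        )
        logrows = []
        if "aflp" in state:
            state["aflp"], removed = msap_scoring.apply_band_filters(state["aflp"], **kwargs)
            logrows += [{"matrix": "aflp", "locus": k, "reason": v} for k, v in removed.items()]
        if "msap" in state:
            pair = state["msap"]
            keep = np.ones(len(pair.locus_ids), dtype=bool)
            for mat in (pair.hpa, pair.msp):
                try:
                    _, removed = msap_scoring.apply_band_filters(mat, **kwargs)
                except ValueError:
                    removed = {}
                for k, v in removed.items():
                    keep[pair.locus_ids.index(k)] = False
                    logrows.append({"matrix": "msap", "locus": k, "reason": v})
            state["msap"] = pair.select_loci(keep)
        pd.DataFrame(logrows).to_csv(out / "filter_log.csv", index=False)

    @stage("score")
    def _score():
        if "msap" not in state:
            manifest["skipped"].append({"stage": "score", "reason": "no MSAP input"})
            return
        m = msap_scoring.score_methylation_states(state["msap"])
        cls = msap_scoring.classify_loci(m, cfg.epsilon)
        state["meth"] = m
        state["classes"] = cls
        msl, nml = msap_scoring.split_msl_nml(m, cls, state["msap"])
        state["msl"], state["nml"] = msl, nml
        msap_scoring.classification_frame(cls).to_csv(out / "msl_classification.csv", index=False)
        marker_io.write_band_matrix(msl, out / "msl_binary.csv")
        msap_scoring.state_proportions(m).to_csv(out / "state_proportions.csv")

    @stage("diversity")
    def _diversity():
        for key in ("aflp", "msl", "nml"):
            if key not in state or state[key] is None:
                continue
            table = diversity.diversity_indices(state[key], "site")
            df = table.per_population.copy()
            df["Gst"] = table.gst
            df["Nm"] = table.nm
            df.to_csv(out / f"diversity_{key}.csv")

    @stage("amova")
    def _amova():
        seed = _seed_for(cfg, "amova")
        nper = cfg.permutations["amova"]
        rows = {}
        for key in ("aflp", "msl", "nml"):
            if key not in state or state[key] is None:
                continue
            b = state[key]
            d = amova.squared_distance_matrix(b)
            one = amova.amova(d, b.habitat, n_perm=nper, seed=seed)
            two = amova.amova(d, b.habitat, b.site, n_perm=nper, seed=seed)
            one.table.to_csv(out / f"amova_{key}_one_level.csv")
            two.table.to_csv(out / f"amova_{key}_two_level.csv")
            phi_h, p_h = amova.pairwise_amova(d, b.habitat, n_perm=nper, seed=seed)
            phi_h.to_csv(out / f"pairwise_phi_habitat_{key}.csv")
            p_h.to_csv(out / f"pairwise_p_habitat_{key}.csv")
            rows[key] = {
                "PhiPT_one_level": one.phi["PhiPT"],
                "p_one_level": one.p_values["PhiPT"],
                **{k: two.phi[k] for k in two.phi},
            }
            state[f"d_{key}"] = d
            state[f"pairphi_{key}"] = phi_h
        pd.DataFrame(rows).T.to_csv(out / "amova_summary.csv")

    @stage("mantel")
    def _mantel():
        if "d_aflp" not in state or "d_msl" not in state:
            manifest["skipped"].append({"stage": "mantel", "reason": "need both AFLP and MSL distances"})
            return
        seed = _seed_for(cfg, "mantel")
        res = matrix_tests.mantel(
            state["d_aflp"], state["d_msl"], n_perm=cfg.permutations["mantel"],
            seed=seed, exact=False,
        )
        records = [{"test": "mantel_genetic_epigenetic", "r": res.r, "p": res.p, "n_perm": res.n_perm}]
        if "soil" in state:
            b = state["aflp"]
            assignment = dict(zip(b.sample_ids, b.site))
            for var in state["soil"].variables:
                sd = matrix_tests.soil_difference_matrix(state["soil"], var, assignment)
                for label, dmat, ctrl in (
                    ("genetic", state["d_aflp"], state["d_msl"]),
                    ("epigenetic", state["d_msl"], state["d_aflp"]),
                ):
                    pm = matrix_tests.partial_mantel(
                        dmat, sd, ctrl, n_perm=cfg.permutations["partial_mantel"], seed=seed
                    )
                    records.append(
                        {"test": f"partial_mantel_{label}", "variable": var, "r": pm.r, "p": pm.p,
                         "n_perm": pm.n_perm}
                    )
        pd.DataFrame(records).to_csv(out / "mantel_results.csv", index=False)

    @stage("scan")
    def _scan():
        if "aflp" not in state:
            manifest["skipped"].append({"stage": "scan", "reason": "no AFLP matrix"})
            return
        seed = _seed_for(cfg, "scan")
        records, envelope = selection_scan.fdist_scan(
            state["aflp"], "habitat", n_sim=cfg.fdist_sims,
            quantiles=cfg.envelope_quantiles, seed=seed,
        )
        pd.DataFrame(
            {
                "locus": [r.locus_id for r in records],
                "fst": [r.fst for r in records],
                "het": [r.het for r in records],
                "flag": [r.flag for r in records],
            }
        ).to_csv(out / "fdist_outliers.csv", index=False)
        envelope.to_csv(out / "fdist_envelope.csv", index=False)
        state["outliers"] = [r.locus_id for r in records if r.flag == "directional_candidate"]
        if "soil" in state:
            assoc = selection_scan.env_logistic_scan(
                state["aflp"], state["soil"], alpha=cfg.alpha["env_scan"]
            )
            pd.DataFrame([a.__dict__ for a in assoc]).to_csv(out / "env_scan.csv", index=False)
        else:
            manifest["skipped"].append({"stage": "scan.env", "reason": "no soil table"})
        if "msl" in state and state["msl"] is not None:
            loc = amova.locus_by_locus_amova(
                state["msl"], state["msl"].habitat,
                n_perm=cfg.permutations["locus_amova"],
                alpha=cfg.alpha["locus_amova"], seed=seed,
            )
            loc.to_csv(out / "locus_amova_msl.csv", index=False)

    @stage("ordinate")
    def _ordinate():
        seed = _seed_for(cfg, "ordinate")
        for key in ("aflp", "msl"):
            if f"d_{key}" not in state:
                continue
            res = ordination.pcoa(state[f"d_{key}"], squared=True)
            res.coordinates.iloc[:, :4].to_csv(out / f"pcoa_{key}.csv")
            pd.DataFrame({"eigenvalue": res.eigenvalues}).to_csv(out / f"pcoa_{key}_eigenvalues.csv", index=False)
            b = state[key]
            from skbio import DistanceMatrix

            dmat = DistanceMatrix(np.sqrt(state[f"d_{key}"].data), ids=state[f"d_{key}"].ids)
            newick, _ = ordination.upgma(
                dmat, b, n_boot=cfg.permutations["upgma_boot"], seed=seed
            )
            (out / f"upgma_{key}.nwk").write_text(newick + "\n")

    manifest["seconds_total"] = round(time.perf_counter() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
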