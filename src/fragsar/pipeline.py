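"""End-to-end orchestration of the fragmentation analysis.

Stages: (optional) synthetic archipelago -> species classification ->
stratified landscape ensemble -> null-model replicates -> z-series per
incidence view -> breakpoints and phase split -> rank correlations ->
variation partitioning.  All intermediate tables are written as CSV next
to a JSON manifest (seeds, config echo, stage timings) that suffices to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breakpoint import BreakpointFit, fit_piecewise
from .core_data import (
    Archipelago,
    classify_species,
    read_incidence,
    read_island_table,
    subset_incidence,
    write_incidence,
    write_island_table,
)
from .lsar import compute_richness, null_z_series, z_series
from .null_models import NullConfig, randomize
from .sampler import SamplerConfig, build_ensemble, ensemble_to_frame
from .stats import (
    FRAGMENTATION_SET,
    attach_z,
    landscape_table,
    partial_spearman,
    run_phase_varpart,
    spearman_matrix,
)
from .synthetic import SynthConfig, generate_archipelago

__all__ = ["RunConfig", "run_all", "stage_seed"]

logger = logging.getLogger(__name__)

DEFAULT_VIEWS = ("observed", "RDM", "OWRDM", "rare", "common")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: adding a view never perturbs another's draws."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    islands_path: str | None = None
    incidence_path: str | None = None
    synth: SynthConfig | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    null_replicates: int = 100
    views: tuple[str, ...] = DEFAULT_VIEWS
    outdir: str = "fragsar_out"
    seed: int = 0

    def __post_init__(self) -> None:
        have_files = self.islands_path is not None and self.incidence_path is not None
        if have_files == (self.synth is not None):
            raise ValueError("provide either input paths or synthetic settings, not both")


def _load_archipelago(cfg: RunConfig, outdir: Path) -> Archipelago:
    if cfg.synth is not None:
        synth = replace(cfg.synth, seed=stage_seed(cfg.seed, "synth"))
        arch = generate_archipelago(synth)
        write_island_table(arch.islands, outdir / "islands.csv")
        write_incidence(arch, outdir / "incidence.csv")
        return arch
    islands = read_island_table(cfg.islands_path)
    return read_incidence(cfg.incidence_path, islands)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns a summary dict (also written as the manifest)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "fragsar_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {},
        "timings_s": {},
        "config": {
            "sampler": asdict(cfg.sampler),
            "synth": asdict(cfg.synth) if cfg.synth else None,
            "islands_path": cfg.islands_path,
            "incidence_path": cfg.incidence_path,
            "null_replicates": cfg.null_replicates,
            "views": list(cfg.views),
        },
    }

    def _stage(name: str):
        manifest["stage_seeds"][name] = stage_seed(cfg.seed, name)
        logger.info("stage %s", name)
        return time.perf_counter()

    def _done(name: str, t0: float) -> None:
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)

    try:
        t0 = _stage("synth")
        arch = _load_archipelago(cfg, outdir)
        _done("synth", t0)

        t0 = _stage("classify")
        occ = classify_species(arch)
        pd.DataFrame(
            {
                "species_id": [o.species_id for o in occ],
                "n_islands": [o.n_islands for o in occ],
                "proportion": [o.proportion for o in occ],
                "class": [o.species_class for o in occ],
            }
        ).to_csv(outdir / "species_classes.csv", index=False)
        manifest["n_species"] = arch.n_species
        manifest["n_rare"] = sum(o.species_class == "rare" for o in occ)
        manifest["n_common"] = arch.n_species - manifest["n_rare"]
        _done("classify", t0)

        t0 = _stage("ensemble")
        sampler = replace(cfg.sampler, seed=stage_seed(cfg.seed, "ensemble"))
        ensemble = build_ensemble(arch, sampler)
        manifest["n_landscapes"] = len(ensemble)
        _done("ensemble", t0)

        t0 = _stage("zseries")
        zseries: dict[str, pd.DataFrame] = {}
        for view in cfg.views:
            if view in ("RDM", "OWRDM"):
                null_seed = stage_seed(cfg.seed, f"null_{view}")
                manifest["stage_seeds"][f"null_{view}"] = null_seed
                null_cfg = NullConfig(
                    model=view,
                    n_replicates=cfg.null_replicates,
                    seed=null_seed,
                )
                zseries[view] = null_z_series(ensemble, randomize(arch, null_cfg), view)
            else:
                view_arch = arch if view == "observed" else subset_incidence(arch, view)
                compute_richness(ensemble, view_arch, view)
                zseries[view] = z_series(ensemble, view)
            zseries[view].to_csv(outdir / f"zseries_{view}.csv", index=False)
        ensemble_to_frame(ensemble).to_csv(outdir / "landscapes.csv", index=False)
        _done("zseries", t0)

        t0 = _stage("breakpoint")
        fits: dict[str, BreakpointFit] = {}
        bp_rows = []
        phase_rows = []
        for view, series in zseries.items():
            fit = fit_piecewise(series["pn_level"].to_numpy(), series["z"].to_numpy())
            fits[view] = fit
            bp_rows.append(
                {"view": view, "psi": fit.psi, "beta0": fit.beta0, "beta1": fit.beta1,
                 "beta2": fit.beta2, "r2": fit.r2, "p": fit.p,
                 "no_threshold": fit.no_threshold}
            )
            for pn in series["pn_level"]:
                phase_rows.append({"view": view, "pn_level": int(pn),
                                   "phase": fit.phase_of(pn)})
        pd.DataFrame(bp_rows).to_csv(outdir / "breakpoints.csv", index=False)
        pd.DataFrame(phase_rows).to_csv(outdir / "phases.csv", index=False)
        _done("breakpoint", t0)

        t0 = _stage("correlate")
        base_view = "observed" if "observed" in zseries else cfg.views[0]
        table = attach_z(landscape_table(ensemble, base_view), zseries[base_view])
        attr_cols = ["area", "pn", "psv", "lsi", "mdm", "richness"]
        t1 = pd.DataFrame(
            [
                {"var_x": r.var_x, "var_y": r.var_y, "rho": r.rho,
                 "p_raw": r.p_raw, "p_adj": r.p_adj, "n": r.n}
                for r in spearman_matrix(table, attr_cols)
            ]
        )
        t1.to_csv(outdir / "table1.csv", index=False)
        t2_rows = []
        for control in ("pn", "area"):
            xs = [a for a in ("area", "pn", "psv", "lsi", "mdm") if a != control]
            for response in ("richness", "z"):
                for xcol in xs:
                    r = partial_spearman(table, xcol, response, (control,),
                                         family_size=len(xs))
                    t2_rows.append(
                        {"response": response, "attribute": xcol, "control": control,
                         "rho": r.rho, "p_raw": r.p_raw, "p_adj": r.p_adj, "n": r.n}
                    )
        pd.DataFrame(t2_rows).to_csv(outdir / "table2.csv", index=False)
        _done("correlate", t0)

        t0 = _stage("varpart")
        vp_views = [v for v in ("observed", "rare", "common") if v in fits]
        vp = run_phase_varpart(
            ensemble,
            {v: zseries[v] for v in vp_views},
            {v: fits[v] for v in vp_views},
        )
        pd.DataFrame(
            [
                {"view": view, "phase": phase, "frac_a": r.frac_a, "frac_b": r.frac_b,
                 "frac_c": r.frac_c, "frac_d": r.frac_d}
                for (view, phase), r in vp.items()
            ]
        ).to_csv(outdir / "varpart.csv", index=False)
        _done("varpart", t0)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
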