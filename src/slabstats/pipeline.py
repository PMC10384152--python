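"""Reproducible analysis pipeline: one YAML config, one run directory.

A config names its input (either a synthetic-generator spec or a GRO file
plus annotation sidecar), the stages to run, and per-stage parameters.
Every numeric default actually applied is echoed to the log and recorded in
the JSON summary, so no convention stays silent. Identical config + seed
reproduce the summary byte-identically for deterministic stages.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import yaml

from .conformation import chain_length_distribution, gauche_profile, tilt_angles
from .core import Trajectory
from .cube import write_cube_nm
from .exceptions import ConfigError, SlabstatsError
from .hbond import (HBondCriterion, correlation_lifetime, hbond_count_per_head,
                    hbond_time_series, intermittent_acf, water_head_selections)
from .io import apply_annotation, load_annotation, read_gro, write_gro, dump_annotation
from .profiles import area_per_surfactant, density_profile, thickness_10_90
from .rdf import compute_rdf, coordination_number, find_first_valley
from .rdg import rdg_scan
from .sdf import GridSpec, compute_sdf
from .synth import MonolayerSpec, build_monolayer, default_annotation

log = logging.getLogger("slabstats")

KNOWN_STAGES = ("generate", "area", "profile", "thickness", "rdf", "sdf",
                "hbond", "tilt", "gauche", "chainlen", "rdg")


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping")
    return cfg


def _load_input(cfg: dict, seed: int | None, outdir: Path):
    inp = cfg.get("input", {})
    if "generate" in inp:
        params = dict(inp["generate"])
        if seed is not None:
            params["seed"] = seed
        spec = MonolayerSpec.from_dict(params)
        log.info("generate: spec %s", spec.to_dict())
        topology, traj = build_monolayer(spec)
        write_gro(topology, traj, outdir / "system.gro")
        dump_annotation(default_annotation(), outdir / "annotation.yaml")
        yaml.safe_dump(spec.to_dict(), (outdir / "spec.yaml").open("w"))
        return topology, traj, spec
    if "gro" in inp:
        topology, data = read_gro(inp["gro"])
        traj = data if isinstance(data, Trajectory) else Trajectory.from_frame(
            topology, data)
        if "annotation" in inp:
            apply_annotation(topology, load_annotation(inp["annotation"]))
        topology.infer_water_bonds()
        return topology, traj, None
    raise ConfigError("config input must provide 'generate' or 'gro'")


def run_pipeline(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Execute the configured stages in dependency order; returns and writes
    the machine-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", [])
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    params = cfg.get("params", {})
    topology, traj, spec = _load_input(cfg, seed, outdir)
    summary: dict = {"stages": {}, "defaults_applied": {}}

    def note_defaults(stage, applied: dict):
        summary["defaults_applied"][stage] = applied
        log.info("%s: defaults %s", stage, applied)

    for stage in stages:
        p = dict(params.get(stage, {}))
        result: dict = {}
        if stage == "generate":
            result = {"n_atoms": topology.n_atoms, "n_frames": len(traj)}
        elif stage == "area":
            n = p.get("n_surfactant_total")
            if n is None:
                n = 2 * spec.n_surfactant_per_leaflet if spec else None
            if n is None:
                raise ConfigError("area stage needs n_surfactant_total")
            result = {"area_per_surfactant_nm2":
                      area_per_surfactant(traj[0].box, int(n))}
        elif stage == "profile":
            bw = p.get("bin_width", 0.02)
            note_defaults(stage, {"bin_width": bw})
            sel = topology.require_role(p.get("role", "OW"))
            prof = density_profile(traj, sel, bw, species=p.get("role", "OW"))
            (outdir / "profile.dat").write_text(prof.to_text())
            result = {"mean_count": prof.integral_count(), "file": "profile.dat"}
        elif stage == "thickness":
            bw = p.get("bin_width", 0.02)
            note_defaults(stage, {"bin_width": bw, "smooth_window": 5,
                                  "bulk_window": "central 25% of slab"})
            sel = topology.require_role("OW")
            prof = density_profile(traj, sel, bw, species="OW")
            th = thickness_10_90(prof)
            (outdir / "thickness.json").write_text(json.dumps(th.to_dict(),
                                                              indent=1))
            result = th.to_dict()
        elif stage == "rdf":
            ref_role = p.get("ref_role", "N1")
            bw = p.get("bin_width", 0.01)
            r_max = p.get("r_max", 1.2)
            note_defaults(stage, {"ref_role": ref_role, "bin_width": bw,
                                  "r_max": r_max})
            ref = topology.require_role(ref_role)
            tgt = topology.require_role(p.get("target_role", "OW"))
            bulk = p.get("bulk_region_z")
            rdf = compute_rdf(traj, ref, tgt, r_max, bw,
                              tuple(bulk) if bulk else None)
            (outdir / f"rdf_{ref_role}.dat").write_text(rdf.to_text())
            result = {"file": f"rdf_{ref_role}.dat"}
            try:
                rv = find_first_valley(rdf)
                result["first_valley_nm"] = rv
                result["coordination_number"] = coordination_number(rdf, rv)
            except SlabstatsError as exc:
                result["first_valley_nm"] = None
                result["note"] = str(exc)
        elif stage == "sdf":
            center = p.get("center_role", "C16")
            shell = p.get("shell_r_max", 0.5)
            note_defaults(stage, {"center_role": center, "shell_r_max": shell})
            grid = GridSpec(spacing=p.get("spacing", 0.05))
            sdf = compute_sdf(traj, center, grid=grid, shell_r_max=shell)
            write_cube_nm(outdir / f"sdf_{center}.cube", sdf.counts,
                          sdf.grid_origin, sdf.grid_spacing)
            result = {"file": f"sdf_{center}.cube",
                      "total_occupancy": float(sdf.counts.sum())}
        elif stage == "hbond":
            crit = HBondCriterion(
                r_cut=p.get("r_cut", 0.35),
                angle_mode=p.get("angle_mode", "HDA"),
                angle_cut=p.get("angle_cut"))
            n_terms = p.get("n_terms", 2)
            note_defaults(stage, {"r_cut": crit.r_cut,
                                  "angle_mode": crit.angle_mode,
                                  "angle_cut": crit.angle_cut,
                                  "n_terms": n_terms})
            mean, sd = hbond_count_per_head(traj, crit)
            result = {"bonds_per_head_mean": mean, "bonds_per_head_sd": sd}
            if len(traj) >= 8:
                donors, donor_h, acceptors = water_head_selections(topology)
                series = hbond_time_series(traj, donors, donor_h, acceptors,
                                           crit)
                if series.h.size and series.h.any():
                    acf = intermittent_acf(series, max_lag=len(traj) // 2)
                    life = correlation_lifetime(acf, n_terms=n_terms)
                    result["lifetime_ps"] = life.tau
                    result["plateau"] = life.plateau
        elif stage == "tilt":
            report = tilt_angles(traj)
            result = {"mean_a_tail_deg": report.mean_a_tail,
                      "mean_a_whole_deg": report.mean_a_whole,
                      "mean_a_polar_deg": report.mean_a_polar}
        elif stage == "gauche":
            prof = gauche_profile(traj)
            (outdir / "gauche.dat").write_text(prof.to_text())
            result = {"p_gauche": [float(v) for v in prof.p_gauche],
                      "file": "gauche.dat"}
        elif stage == "chainlen":
            bw = p.get("bin_width", 0.01)
            note_defaults(stage, {"bin_width": bw})
            cl = chain_length_distribution(traj, bw)
            result = {"mean_length_nm": cl.mean}
        elif stage == "rdg":
            spacing = p.get("spacing_bohr", 0.25)
            note_defaults(stage, {"spacing_bohr": spacing, "margin_bohr": 3.0,
                                  "rho_max_cut": 0.05})
            res_idx = p.get("residue", topology.residue_indices()[0])
            sel = topology.atoms_in_residue(res_idx)
            elements = [topology.atoms[i].element for i in sel]
            coords = traj[0].positions[sel]
            field = rdg_scan(elements, coords, spacing_bohr=spacing)
            (outdir / "rdg_scatter.dat").write_text(field.scatter_text())
            s, g = field.scatter()
            result = {"file": "rdg_scatter.dat", "n_scatter": int(len(s)),
                      "min_rdg_in_window": float(g.min()) if len(g) else None}
        summary["stages"][stage] = result

    text = json.dumps(summary, indent=1, sort_keys=True)
    (outdir / "summary.json").write_text(text)
    return summary
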