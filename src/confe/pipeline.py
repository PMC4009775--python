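"""End-to-end workflows driven by a YAML-style configuration dict.

Two workflows mirror how ensemble free-energy studies are organized:

* :func:`run_state_compare` — two conformational states, several replicate
  ensembles each, per-replicate G1/G2, a replicate table per state and a
  significance-flagged comparison.
* :func:`run_pathway` — two endpoint conformations, a geometric morph
  between them, PCA projection of the path, equal-arc-length waypoints,
  small-amplitude torsion resampling around each waypoint to form
  replicate ensembles, and the G1/G2 free-energy profile.

Outputs are CSV files stamped with a deterministic configuration hash;
every default that the science does not pin down (contact cutoff, surface
tension, entropy mode, radii) is recorded in the run log.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import free_energy as fe
from . import gbsa, pathway, synthetic
from .entropy import bin_sensitivity
from .exceptions import ConfigError
from .geometry import dihedrals, enumerate_torsions
from .structure import (
    ConformationEnsemble,
    assign_parameters,
    config_hash,
    read_structure,
    read_topology,
    select,
    strip_solvent,
)


def _require(cfg: dict, key: str, where: str):
    if key not in cfg:
        raise ConfigError(f"missing config field {where}.{key}")
    return cfg[key]


def _gb_sa_params(cfg: dict) -> tuple[gbsa.GBParameters, gbsa.SASAParameters]:
    gb = gbsa.GBParameters(**cfg.get("gb", {}))
    sa = gbsa.SASAParameters(**cfg.get("sasa", {}))
    return gb, sa


def _spec_from_config(dist_cfg, n_torsions: int
                      ) -> synthetic.TorsionDistributionSpec:
    if dist_cfg == "uniform":
        return synthetic.TorsionDistributionSpec.uniform(n_torsions)
    if isinstance(dist_cfg, dict) and "vonmises" in dist_cfg:
        vm = dist_cfg["vonmises"]
        return synthetic.TorsionDistributionSpec.von_mises(
            vm.get("mu", 0.0), vm["kappa"], n_torsions)
    if isinstance(dist_cfg, dict) and "fixed" in dist_cfg:
        return synthetic.TorsionDistributionSpec.fixed(
            [dist_cfg["fixed"]] * n_torsions)
    raise ConfigError(f"unrecognized torsion distribution {dist_cfg!r}")


def _state_ensembles(state: dict, n_replicates: int, seeds: list[int],
                     log: list[str]) -> list[ConformationEnsemble]:
    """Replicate ensembles for one state, synthetic or file-based."""
    label = state.get("label", "?")
    if ("synthetic" in state) == ("structure" in state):
        raise ConfigError(
            f"state {label!r} must define exactly one of "
            "'synthetic' or 'structure'")
    out = []
    if "synthetic" in state:
        syn = state["synthetic"]
        n_torsions = _require(syn, "n_torsions", f"states[{label}].synthetic")
        n_frames = _require(syn, "n_frames", f"states[{label}].synthetic")
        topo = synthetic.make_toy_topology(
            n_torsions + 3, atoms_per_residue=1,
            interacting=syn.get("interacting", False))
        topo.energy_offset = float(syn.get("energy_offset", 0.0))
        spec = _spec_from_config(
            syn.get("distribution", "uniform"), n_torsions)
        for r in range(n_replicates):
            out.append(synthetic.sample_ensemble(
                topo, spec, n_frames, seeds[r], run_id=r + 1))
        log.append(f"state {label}: synthetic, {n_torsions} torsions, "
                   f"{n_frames} frames x {n_replicates} replicates, "
                   f"seeds {seeds}")
    else:
        ens = read_structure(state["structure"])
        if "topology" in state:
            par = read_topology(state["topology"])
            ens = ConformationEnsemble(
                assign_parameters(ens.topology, par), ens.coordinates,
                ens.metadata)
        ens, removed = strip_solvent(ens)
        log.append(f"state {label}: {state['structure']}, "
                   f"{ens.n_frames} frames, {removed} solvent atoms removed")
        if n_replicates > 1:
            # split frames into replicate blocks
            blocks = np.array_split(np.arange(ens.n_frames), n_replicates)
            for b in blocks:
                out.append(ens.with_coordinates(ens.coordinates[b]))
        else:
            out.append(ens)
    return out


def run_state_compare(config: dict, output_dir=None) -> dict:
    """Two-state stability comparison; returns summaries and the comparison.

    Writes per-state replicate tables (run, G2, -TS, G1 with Average and
    sigma rows), a comparison summary and a provenance log when
    ``output_dir`` is given.
    """
    states = _require(config, "states", "config")
    if len(states) != 2:
        raise ConfigError("config.states must list exactly two states")
    temperature = config.get("temperature", 300.0)
    mode = config.get("entropy_mode", "differential")
    bin_width = config.get("bin_width", 30.0)
    stride = config.get("energy_stride", 1)
    n_replicates = config.get("replicates", 2)
    master_seed = config.get("seed", 0)
    gb, sa = _gb_sa_params(config)
    chash = config_hash(config)
    log = [f"config_hash {chash}",
           f"defaults: entropy_mode={mode} bin_width={bin_width} "
           f"T={temperature} gamma={sa.gamma} probe={sa.probe_radius} "
           f"eps_solvent={gb.solvent_dielectric} "
           f"energy_stride={stride}"]

    rng = np.random.default_rng(master_seed)
    summaries = []
    for state in states:
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, n_replicates)]
        ensembles = _state_ensembles(state, n_replicates, seeds, log)
        records = []
        for k, ens in enumerate(ensembles):
            records.append(fe.EnsembleFreeEnergy(
                ens, gb=gb, sa=sa, bin_width=bin_width, entropy_mode=mode,
                temperature=temperature, energy_stride=stride,
                label=state.get("label", f"state{len(summaries)}"),
                run_id=k + 1).fit().record)
        summaries.append(fe.ReplicateSummary(
            records, state.get("label", ""), allow_single=True))
    comparison = fe.compare_states(summaries[0], summaries[1])

    result = {"summaries": summaries, "comparison": comparison,
              "config_hash": chash, "log": log}
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for summ in summaries:
            df = summ.to_frame()
            df.insert(0, "config_hash", chash)
            df.to_csv(outdir / f"free_energy_{summ.label}.csv", index=False)
        comp = {k: getattr(comparison, k) for k in
                ("label_a", "label_b", "dg1", "dg2", "dts", "sigma_g1",
                 "sigma_g2", "sigma_ts", "g1_significant", "g2_significant")}
        comp["config_hash"] = chash
        with open(outdir / "comparison.json", "w") as fh:
            json.dump(comp, fh, indent=2, default=str)
        (outdir / "run.log").write_text("\n".join(log) + "\n")
    return result


def run_pathway(config: dict, output_dir=None) -> dict:
    """Pathway free-energy profile between two endpoint conformations.

    Endpoints are defined by fixed torsion vectors on a shared synthetic
    chain (or read from files); the path is a linear morph, projected with
    PCA; waypoints are picked at equal arc length; replicate ensembles per
    waypoint come from von Mises torsion resampling centered on the
    waypoint's torsions (a documented stand-in for restrained sampling).
    """
    pcfg = _require(config, "pathway", "config")
    n_torsions = pcfg.get("n_torsions", 10)
    n_morph = pcfg.get("n_morph_frames", 101)
    n_waypoints = pcfg.get("n_waypoints", 10)
    n_rep = pcfg.get("replicates", 2)
    n_frames_wp = pcfg.get("frames_per_waypoint", 300)
    kappa_resample = pcfg.get("kappa_resample", 200.0)
    temperature = config.get("temperature", 300.0)
    mode = config.get("entropy_mode", "differential")
    bin_width = config.get("bin_width", 30.0)
    stride = config.get("energy_stride", 1)
    master_seed = config.get("seed", 0)
    gb, sa = _gb_sa_params(config)
    chash = config_hash(config)
    rng = np.random.default_rng(master_seed)

    topo = synthetic.make_toy_topology(
        n_torsions + 3, atoms_per_residue=1,
        interacting=pcfg.get("interacting", False))
    torsions = enumerate_torsions(topo)
    if "endpoint_torsions" in pcfg:
        tors_a = np.asarray(pcfg["endpoint_torsions"][0], dtype=float)
        tors_b = np.asarray(pcfg["endpoint_torsions"][1], dtype=float)
    else:
        tors_a = rng.uniform(-170, 170, n_torsions)
        tors_b = rng.uniform(-170, 170, n_torsions)
    conf_a = synthetic.build_coordinates_from_torsions(topo, tors_a)
    conf_b = synthetic.build_coordinates_from_torsions(topo, tors_b)

    path = pathway.morph(conf_a, conf_b, n_morph, topology=topo)
    all_sel = select(topo, "all")
    aligned = pathway.align_ensemble(path, all_sel)
    model = pathway.pca(aligned, all_sel)
    wp_idx = pathway.select_waypoints(model.projections, n_waypoints)

    waypoint_ensembles = []
    for w, idx in enumerate(wp_idx):
        frame = aligned.coordinates[idx]
        center = dihedrals(frame, torsions.quads)
        replicates = []
        for r in range(n_rep):
            seed = int(rng.integers(0, 2**31 - 1))
            spec = synthetic.TorsionDistributionSpec(
                [("vonmises", float(c), kappa_resample) for c in center])
            replicates.append(synthetic.sample_ensemble(
                topo, spec, n_frames_wp, seed, run_id=r + 1))
        waypoint_ensembles.append((f"wp{w + 1}", replicates))
    profile = fe.build_profile(
        waypoint_ensembles, direction=pcfg.get("direction", "A->B"),
        gb=gb, sa=sa, bin_width=bin_width, entropy_mode=mode,
        temperature=temperature, energy_stride=stride)

    result = {"profile": profile, "pca": model, "waypoints": wp_idx,
              "config_hash": chash}
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        proj = model.to_frame()
        proj["waypoint"] = [int(i in set(wp_idx.tolist()))
                            for i in range(len(proj))]
        proj.insert(0, "config_hash", chash)
        proj.to_csv(outdir / "projections.csv", index=False)
        pd.DataFrame({"eigenvalue": model.eigenvalues}).to_csv(
            outdir / "eigenvalues.csv", index=False)
        prof = profile.to_frame()
        prof.insert(0, "config_hash", chash)
        prof.to_csv(outdir / "profile.csv", index=False)
    return result


def run_bin_sensitivity(ensemble: ConformationEnsemble,
                        widths=(12.0, 30.0, 60.0, 120.0),
                        mode: str = "differential",
                        temperature: float = 300.0) -> pd.DataFrame:
    """Convenience wrapper over :func:`confe.entropy.bin_sensitivity`."""
    torsions = enumerate_torsions(ensemble.topology)
    return bin_sensitivity(ensemble, torsions, tuple(widths), mode,
                           temperature)
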