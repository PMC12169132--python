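"""End-to-end two-state comparison: orchestration and report bundle.

``run_comparison`` executes, in order: load/generate → window + stride →
per-state RMSD/RMSF/Rg → differential RMSF → SASA + differential SASA →
per-state PCA, subspace comparison, projections, modevectors → domain
rotation + significance → per-state tunnels (detection, clustering,
statistics, bottleneck residues) → residue interaction networks,
exclusivity classification and the focal neighbourhood → manifest.  All
tabular outputs are TSV, structured summaries JSON; the run is
deterministic given the config (including the master seed of a synthetic
spec).

Per-state profiles pool the windowed frames of all replicates (RMSD means
are additionally reported per replicate); differential quantities are
always state2 − state1, i.e. deoxygenated-like minus oxygenated-like.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ComparisonConfig
from .ensemble import Ensemble
from .geometry import (differential_profile, gyration_series, rmsd_series,
                       rmsf_profile, sidechain_conformation_series)
from .networks import classify_edges, contact_frequencies, extract_neighborhood
from .pca import (compare_subspaces, components_for_variance, compute_subspace,
                  modevectors, project_density)
from .pdbio import read_pdb_models
from .rotation import compare_rotation, rotation_series
from .sasa import differential_sasa, sasa_ensemble
from .synthetic import build_toy_topology, sample_ensemble
from .tunnels import bottleneck_residues, cluster_tunnels, detect_tunnels

__all__ = ["ReportBundle", "run_comparison", "pool_ensembles"]

logger = logging.getLogger("hemodyn")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ReportBundle:
    manifest: dict
    rmsd: dict = field(default_factory=dict)
    rmsf: dict = field(default_factory=dict)
    differential_rmsf: object = None
    rg: dict = field(default_factory=dict)
    sasa: dict = field(default_factory=dict)
    differential_sasa: object = None
    subspaces: dict = field(default_factory=dict)
    overlap: object = None
    variance_counts: dict = field(default_factory=dict)
    projections: dict = field(default_factory=dict)
    modevector_fields: dict = field(default_factory=dict)
    rotation: dict = field(default_factory=dict)
    rotation_comparison: object = None
    tunnels: dict = field(default_factory=dict)
    tunnel_clusters: dict = field(default_factory=dict)
    bottleneck_reports: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    edge_classification: object = None
    neighborhood: object = None
    gate_sidechain: dict = field(default_factory=dict)
    outdir: Path = None


def pool_ensembles(ensembles) -> Ensemble:
    """Concatenate replicate ensembles (same topology) into one."""
    ensembles = list(ensembles)
    first = ensembles[0]
    return Ensemble(
        topology=first.topology,
        coords=np.concatenate([e.coords for e in ensembles], axis=0),
        frame_labels=np.concatenate([e.frame_labels for e in ensembles]),
        state=first.state,
        replicate=-1,
    )


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_comparison(config: ComparisonConfig) -> ReportBundle:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state_a, state_b = config.states  # oxy-like, deoxy-like

    manifest = {
        "software": "hemodyn",
        "version": __version__,
        "states": list(config.states),
        "parameters": {k: v for k, v in config.to_dict().items()
                       if k not in ("synthetic", "ensemble_files")},
    }
    bundle = ReportBundle(manifest=manifest, outdir=outdir)
    stage = "load"
    try:
        # ---- load or generate -------------------------------------------
        _stage(stage)
        replicates: dict = {}
        if config.synthetic is not None:
            spec = config.synthetic
            toy = build_toy_topology(spec)
            manifest["input"] = {"synthetic_seed": spec.seed,
                                 "n_frames": spec.n_frames,
                                 "n_replicates": spec.n_replicates}
            for state in config.states:
                replicates[state] = [sample_ensemble(spec, state, r, structure=toy)
                                     for r in range(spec.n_replicates)]
            seed_point = toy.seed_point
            tunnel_sel_name = config.tunnel_selection or "tunnel"
        else:
            manifest["input"] = {s: [str(p) for p in config.ensemble_files[s]]
                                 for s in config.states}
            for state in config.states:
                replicates[state] = [read_pdb_models(p)
                                     for p in config.ensemble_files[state]]
                for r, ens in enumerate(replicates[state]):
                    ens.state, ens.replicate = state, r
            seed_point = None
            tunnel_sel_name = config.tunnel_selection
        topology = replicates[state_a][0].topology
        if config.tunnel_seed_point is not None:
            seed_point = np.asarray(config.tunnel_seed_point, dtype=float)
        elif config.tunnel_seed_atoms is not None:
            i, j = config.tunnel_seed_atoms
            ref = replicates[state_a][0].coords[0]
            seed_point = 0.5 * (ref[i] + ref[j])

        def sel(name_or_expr):
            return topology.select(name_or_expr)

        core = sel(config.core_selection)
        windowed = {s: [e.window(*config.window, stride=config.stride)
                        for e in replicates[s]] for s in config.states}
        pooled = {s: pool_ensembles(windowed[s]) for s in config.states}

        # ---- fluctuation metrics ----------------------------------------
        stage = "fluctuations"
        _stage(stage)
        for state in config.states:
            ref = replicates[state][0].coords[0]
            per_rep = [rmsd_series(w, ref, core) for w in windowed[state]]
            series = np.concatenate([v for v, _, _ in per_rep])
            bundle.rmsd[state] = {
                "per_replicate_mean": [m for _, m, _ in per_rep],
                "mean": float(series.mean()), "sd": float(series.std(ddof=0)),
                "series": series,
            }
            rg, rg_mean, rg_sd = gyration_series(pooled[state], core)
            bundle.rg[state] = {"mean": rg_mean, "sd": rg_sd, "series": rg}
            bundle.rmsf[state] = rmsf_profile(pooled[state], core)
        bundle.differential_rmsf = differential_profile(
            bundle.rmsf[state_b], bundle.rmsf[state_a], config.rmsf_threshold)

        # ---- solvent accessibility --------------------------------------
        stage = "sasa"
        _stage(stage)
        sasa_sel = sel(config.sasa_selection)
        for state in config.states:
            bundle.sasa[state] = sasa_ensemble(
                pooled[state], sasa_sel, probe=config.sasa_probe,
                n_points=config.sasa_points)
        bundle.differential_sasa = differential_sasa(
            bundle.sasa[state_b], bundle.sasa[state_a], config.dsasa_threshold)

        # ---- essential dynamics -----------------------------------------
        stage = "pca"
        _stage(stage)
        for state in config.states:
            sub = compute_subspace(pooled[state], core, exclude=config.pca_exclude)
            bundle.subspaces[state] = sub
            bundle.variance_counts[state] = {
                "with_exclusion": components_for_variance(sub),
                "without_exclusion": components_for_variance(
                    compute_subspace(pooled[state], core, exclude=())),
            }
            bundle.projections[state] = project_density(
                pooled[state], sub, components=config.pca_projection)
            bundle.modevector_fields[state] = modevectors(
                sub, config.pca_projection[0])
        bundle.overlap = compare_subspaces(
            bundle.subspaces[state_a], bundle.subspaces[state_b], m=config.pca_modes)

        # ---- domain rotation --------------------------------------------
        stage = "rotation"
        _stage(stage)
        d1, d2 = sel(config.domain1_selection), sel(config.domain2_selection)
        rot_ref = replicates[state_b][0].coords[0]  # deoxy-like reference
        for state in config.states:
            series = [rotation_series(w, rot_ref, d1, d2, stride=1)
                      for w in windowed[state]]
            merged = series[0]
            merged.angles = np.concatenate([s.angles for s in series])
            merged.frame_labels = np.concatenate([s.frame_labels for s in series])
            bundle.rotation[state] = merged
        bundle.rotation_comparison = compare_rotation(
            bundle.rotation[state_b], bundle.rotation[state_a],
            test=config.rotation_test)

        # ---- tunnels ------------------------------------------------------
        stage = "tunnels"
        _stage(stage)
        if seed_point is not None:
            tunnel_sel = sel(tunnel_sel_name) if tunnel_sel_name else None
            for state in config.states:
                paths, frames = [], {}
                fid = 0
                for rep, w in enumerate(windowed[state]):
                    for f in range(w.n_frames):
                        found = detect_tunnels(
                            w.coords[f], topology, seed_point,
                            probe=config.tunnel_probe,
                            spacing=config.tunnel_spacing,
                            max_tunnels=config.tunnel_max_per_frame,
                            selection=tunnel_sel, frame_id=fid)
                        for p in found:
                            p.replicate, p.state = rep, state
                        if found:
                            frames[fid] = w.coords[f]
                        paths.extend(found)
                        fid += 1
                bundle.tunnels[state] = {"paths": paths, "frames": frames,
                                         "n_frames_analysed": fid}
                clusters = cluster_tunnels(
                    paths, threshold=config.tunnel_cluster_threshold,
                    n_replicates=len(windowed[state]))
                bundle.tunnel_clusters[state] = clusters
                if clusters:
                    bundle.bottleneck_reports[state] = bottleneck_residues(
                        clusters[0], topology, frames)

        # ---- residue interaction networks -------------------------------
        stage = "networks"
        _stage(stage)
        rin_sel = sel(config.rin_selection)
        for state in config.states:
            bundle.networks[state] = contact_frequencies(
                windowed[state], selection=rin_sel)
        bundle.edge_classification = classify_edges(
            bundle.networks[state_a], bundle.networks[state_b],
            threshold=config.rin_threshold)
        if any(config.rin_focal in bundle.networks[s].nodes for s in config.states):
            bundle.neighborhood = extract_neighborhood(
                [bundle.networks[s] for s in config.states], config.rin_focal,
                max_steps=config.rin_steps, threshold=config.rin_threshold,
                classification=bundle.edge_classification)
        for state in config.states:
            try:
                bundle.gate_sidechain[state] = sidechain_conformation_series(
                    pooled[state], config.rin_focal)
            except ValueError:
                pass  # focal residue without side-chain atoms: skip rotamers

        # ---- write outputs ----------------------------------------------
        stage = "write"
        _stage(stage)
        _write_outputs(bundle, config)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return bundle


def _write_outputs(bundle: ReportBundle, config: ComparisonConfig) -> None:
    out = bundle.outdir
    state_a, state_b = config.states

    for state in config.states:
        pd.DataFrame({
            "frame": np.arange(len(bundle.rmsd[state]["series"])),
            "rmsd_A": bundle.rmsd[state]["series"],
        }).to_csv(out / f"rmsd_{state}.tsv", sep="\t", index=False)
        pd.DataFrame({
            "frame": np.arange(len(bundle.rg[state]["series"])),
            "rg_A": bundle.rg[state]["series"],
        }).to_csv(out / f"rg_{state}.tsv", sep="\t", index=False)

    prof_a, prof_b = bundle.rmsf[state_a], bundle.rmsf[state_b]
    pd.DataFrame({
        "residue": prof_a.resids,
        f"rmsf_{state_a}_A": prof_a.rmsf,
        f"rmsf_{state_b}_A": prof_b.rmsf,
    }).to_csv(out / "rmsf.tsv", sep="\t", index=False)
    diff = bundle.differential_rmsf
    pd.DataFrame({
        "residue": diff.resids, "delta_A": diff.delta,
        "flagged": np.isin(diff.resids, diff.flagged),
    }).to_csv(out / "differential_rmsf.tsv", sep="\t", index=False)

    dsasa = bundle.differential_sasa
    pd.DataFrame({
        "residue": dsasa.residue_ids,
        "delta_nm2": dsasa.delta_nm2,
        "increased": np.isin(dsasa.residue_ids, dsasa.increased),
        "decreased": np.isin(dsasa.residue_ids, dsasa.decreased),
    }).to_csv(out / "differential_sasa.tsv", sep="\t", index=False)
    for state in config.states:
        profile = bundle.sasa[state]
        pd.DataFrame({
            "residue": profile.residue_ids,
            "mean_A2": profile.residue_mean,
            "sd_A2": profile.residue_sd,
        }).to_csv(out / f"sasa_residues_{state}.tsv", sep="\t", index=False)

    for state in config.states:
        sub = bundle.subspaces[state]
        pd.DataFrame({
            "component": np.arange(1, len(sub.eigenvalues) + 1),
            "eigenvalue_A2": sub.eigenvalues,
            "variance_fraction": sub.variance_fractions,
        }).head(50).to_csv(out / f"pca_spectrum_{state}.tsv", sep="\t", index=False)
    ov = bundle.overlap
    (out / "subspace_overlap.json").write_text(json.dumps({
        "m": ov.m, "rmsip": ov.rmsip,
        "subspace_overlap_pct": ov.subspace_overlap_pct,
        "hess_covariance_overlap": ov.hess_overlap,
        "mean_max_dot_a": ov.mean_max_dot_a,
        "mean_max_dot_b": ov.mean_max_dot_b,
        "mean_max_dot_both": ov.mean_max_dot_both,
        "best_pairs": ov.best_pairs,
        "variance_counts": bundle.variance_counts,
    }, indent=2))

    for state in config.states:
        series = bundle.rotation[state]
        pd.DataFrame({
            "frame": series.frame_labels, "angle_deg": series.angles,
        }).to_csv(out / f"rotation_{state}.tsv", sep="\t", index=False)
    rc = bundle.rotation_comparison
    (out / "rotation_comparison.json").write_text(json.dumps({
        "deoxy_like_mean_deg": rc.mean_a, "deoxy_like_sd_deg": rc.sd_a,
        "oxy_like_mean_deg": rc.mean_b, "oxy_like_sd_deg": rc.sd_b,
        "oxy_minus_deoxy_mean_deg": rc.mean_b - rc.mean_a,
        "statistic": rc.statistic, "p_value": rc.p_value, "test": rc.test_name,
    }, indent=2))

    for state, clusters in bundle.tunnel_clusters.items():
        rows = [{
            "ID": c.rank, "No_snaps": c.n_snapshots,
            "Avg_BR": c.avg_bottleneck, "SD": c.sd_bottleneck,
            "Max_BR": c.max_bottleneck, "Avg_L": c.avg_length,
            "SD_L": c.sd_length, "Avg_thru": c.avg_throughput,
            "SD_thru": c.sd_throughput,
        } for c in clusters]
        pd.DataFrame(rows).to_csv(out / f"tunnel_clusters_{state}.tsv",
                                  sep="\t", index=False)
    for state, report in bundle.bottleneck_reports.items():
        rows = [{"chain": k[0], "residue": k[1], "fraction": f,
                 "crucial": f >= report.crucial_fraction}
                for k, f in sorted(report.fractions.items(),
                                   key=lambda kv: -kv[1])]
        pd.DataFrame(rows).to_csv(out / f"bottleneck_residues_{state}.tsv",
                                  sep="\t", index=False)

    cls = bundle.edge_classification
    keys = sorted(set(bundle.networks[state_a].frequencies)
                  | set(bundle.networks[state_b].frequencies))
    pd.DataFrame([{
        "resA": a, "resB": b, "type": t,
        f"freq_{state_a}": bundle.networks[state_a].frequencies.get((a, b, t), 0.0),
        f"freq_{state_b}": bundle.networks[state_b].frequencies.get((a, b, t), 0.0),
        "class": cls.classify((a, b, t)),
    } for a, b, t in keys]).to_csv(out / "rin_edges.tsv", sep="\t", index=False)
    if bundle.neighborhood is not None:
        g = bundle.neighborhood
        (out / "rin_neighborhood.json").write_text(json.dumps({
            "focal": g.graph["focal"],
            "nodes": [{"residue": n, "depth": d["depth"]}
                      for n, d in g.nodes(data=True)],
            "edges": [{"resA": a, "resB": b, "type": k, **attrs}
                      for a, b, k, attrs in g.edges(keys=True, data=True)],
        }, indent=2))

    bundle.manifest["outputs"] = sorted(p.name for p in bundle.outdir.iterdir()
                                        if p.name != "manifest.json")
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
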