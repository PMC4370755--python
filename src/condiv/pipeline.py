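"""End-to-end pipeline orchestration and tabular output writers.

``run_contrast_pipeline`` chains alignment reading, sequence weighting,
foreground/background contrast scoring, per-node subfamily contrasts, insert
detection and (when a structure is supplied) column-to-structure mapping and
interaction analysis. ``run_traj_pipeline`` produces the trajectory summary
statistics. Both write TSV/JSON outputs plus a manifest recording every
threshold, input digest and the seed, so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .config import RunConfig
from .contrast import (ContrastResult, InsertCall, detect_inserts, freq_to_tenths,
                       henikoff_weights, score_contrast, subfamily_contrasts,
                       weighted_profile)
from .msa_io import (build_hyperpartition, make_reference_numbering, read_alignment,
                     write_reference_numbering)
from .structmap import (build_contact_graph, default_regions, detect_interactions,
                        map_columns_to_structure, read_structure)
from .trajstats import HBondSpec, compute_stats, read_trajectory_pdb, read_trajectory_xyz

logger = logging.getLogger("condiv.pipeline")


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_contrast_tsv(result: ContrastResult, fg_prof, bg_prof, numbering, path: str) -> None:
    """Per-column contrast table, one row per scored column."""
    significant = set(result.ranked_positions)
    fg_freq = fg_prof.frequencies()
    bg_freq = bg_prof.frequencies()
    with open(path, "w") as fh:
        fh.write("column\trefnum\tpattern_set\tk_F\tN_F\tk_B\tN_B\t"
                 "fg_tenths\tbg_tenths\tneglog10_p\tsignificant\n")
        from .config import AMINO_ACIDS
        for pc in sorted(result.columns, key=lambda c: c.column):
            i = pc.column - 1
            idxs = [AMINO_ACIDS.index(c) for c in sorted(pc.pattern_set)]
            fgf = float(fg_freq[i, idxs].sum())
            bgf = float(bg_freq[i, idxs].sum())
            refnum = numbering.refnum(pc.column) if numbering else ""
            fh.write(
                f"{pc.column}\t{refnum if refnum is not None else ''}\t"
                f"{''.join(sorted(pc.pattern_set))}\t"
                f"{pc.k_F:.3f}\t{pc.N_F:.3f}\t{pc.k_B:.3f}\t{pc.N_B:.3f}\t"
                f"{freq_to_tenths(min(fgf, 1.0))}\t{freq_to_tenths(min(bgf, 1.0))}\t"
                f"{pc.height:.4f}\t{int(pc.column in significant)}\n"
            )


def write_inserts_tsv(calls: List[InsertCall], numbering, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tstart_refnum\tend_refnum\tfg_occ\tbg_gap\tp\n")
        for c in calls:
            srn = numbering.refnum(c.start) if numbering else ""
            ern = numbering.refnum(c.end) if numbering else ""
            fh.write(f"{c.start}\t{c.end}\t{srn if srn is not None else ''}\t"
                     f"{ern if ern is not None else ''}\t"
                     f"{c.fg_occupancy:.4f}\t{c.bg_gap_fraction:.4f}\t{c.p_value:.4g}\n")


def write_interactions_tsv(records, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("type\tchain1\tres1\tname1\tatom1\tchain2\tres2\tname2\tatom2\t"
                 "distance\tgeometry\n")
        for r in records:
            geom = f"{r.geometry:.2f}" if r.geometry is not None else ""
            fh.write(f"{r.type}\t{r.res1[0]}\t{r.res1[1]}\t{r.res1[2]}\t{r.atom1}\t"
                     f"{r.res2[0]}\t{r.res2[1]}\t{r.res2[2]}\t{r.atom2}\t"
                     f"{r.distance:.3f}\t{geom}\n")


def run_contrast_pipeline(config: RunConfig) -> Dict:
    """Run the full sequence-analysis pipeline from a RunConfig.

    Foreground/background is taken from the hyperpartition tree: the first
    level below the root supplies the family contrasts; deeper nodes get
    within-parent subfamily contrasts. Aborts with the failing stage named.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: Dict = {
        "tool": "condiv", "version": __version__, "kind": "contrast",
        "config": config.to_dict(), "stages": {}, "inputs": {},
    }
    t0 = time.time()
    stage = "msa_io"
    try:
        if not config.alignment:
            raise ValueError("config.alignment is required")
        manifest["inputs"]["alignment"] = _digest(config.alignment)
        if config.labels:
            manifest["inputs"]["labels"] = _digest(config.labels)
        aln = read_alignment(config.alignment, config.labels)
        numbering = None
        if config.ref_id:
            numbering = make_reference_numbering(aln, config.ref_id, config.first_residue)
            write_reference_numbering(numbering, os.path.join(config.out_dir, "numbering.tsv"))
        tree = build_hyperpartition(aln)
        manifest["stages"][stage] = "ok"

        stage = "weighting"
        weights = henikoff_weights(aln)
        manifest["stages"][stage] = "ok"

        stage = "contrast"
        results = subfamily_contrasts(
            aln, weights, tree, alpha=config.alpha, top_k=config.top_k,
            min_fg_coverage=config.min_fg_coverage,
        )
        parent_of = {}
        stack = [tree.root]
        while stack:
            node = stack.pop()
            for child in node.children:
                parent_of[child.name] = node
                stack.append(child)
        for name, result in sorted(results.items()):
            safe = name.replace("/", "_") or "root"
            node = tree.node(name)
            fg_ids = node.members
            bg_ids = [s for s in parent_of[name].members if s not in set(fg_ids)]
            fg_prof = weighted_profile(aln, weights, fg_ids)
            bg_prof = weighted_profile(aln, weights, bg_ids)
            write_contrast_tsv(result, fg_prof, bg_prof, numbering,
                               os.path.join(config.out_dir, f"contrast_{safe}.tsv"))
        manifest["stages"][stage] = "ok"

        stage = "inserts"
        top = sorted(tree.root.children, key=lambda n: n.name)
        inserts_out = {}
        for node in top:
            background = [s for s in tree.root.members if s not in set(node.members)]
            if not background:
                continue
            calls = detect_inserts(
                aln, weights, node.members, background,
                min_len=config.insert_min_len, occ_min=config.insert_occ_min,
                gap_min=config.insert_gap_min, merge_gap=config.insert_merge_gap,
            )
            safe = node.name.replace("/", "_")
            write_inserts_tsv(calls, numbering,
                              os.path.join(config.out_dir, f"inserts_{safe}.tsv"))
            inserts_out[node.name] = [(c.start, c.end) for c in calls]
        manifest["stages"][stage] = "ok"

        structure_summary = None
        if config.pdb:
            stage = "struct_map"
            manifest["inputs"]["pdb"] = _digest(config.pdb)
            model = read_structure(config.pdb, keep_ligands=config.keep_ligands)
            chain = config.chain or model.chains()[0]
            col_map = {}
            if numbering is not None:
                col_map = map_columns_to_structure(aln, numbering, model, chain)
            records = detect_interactions(
                model,
                salt_bridge_cutoff=config.salt_bridge_cutoff,
                hbond_dist_cutoff=config.hbond_dist_cutoff,
                hbond_angle_cutoff=config.hbond_angle_cutoff,
                vdw_cutoff=config.vdw_cutoff,
                ch_pi_cutoff=config.ch_pi_cutoff,
                min_seq_separation=config.min_seq_separation,
            )
            write_interactions_tsv(records, os.path.join(config.out_dir, "interactions.tsv"))
            structure_summary = {"chain": chain, "mapped_columns": len(col_map),
                                 "interactions": len(records)}
            manifest["stages"][stage] = "ok"

        summary = {
            "n_sequences": aln.n_sequences,
            "n_columns": aln.n_columns,
            "nodes_contrasted": sorted(results),
            "significant_per_node": {k: len(v.ranked_positions) for k, v in results.items()},
            "inserts_per_node": inserts_out,
            "structure": structure_summary,
            "seed": config.seed,
            "elapsed_s": round(time.time() - t0, 3),
        }
        with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary


def run_traj_pipeline(config: RunConfig, hbond_specs: Optional[List[HBondSpec]] = None) -> Dict:
    """Trajectory statistics run: RMSD, RMSF, DCCM, occupancies + manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: Dict = {
        "tool": "condiv", "version": __version__, "kind": "trajstats",
        "config": config.to_dict(), "stages": {}, "inputs": {},
    }
    stage = "read_trajectory"
    try:
        if not config.trajectory:
            raise ValueError("config.trajectory is required")
        manifest["inputs"]["trajectory"] = _digest(config.trajectory)
        if config.trajectory.endswith((".pdb", ".ent")):
            traj = read_trajectory_pdb(config.trajectory)
        else:
            traj = read_trajectory_xyz(config.trajectory)
        manifest["stages"][stage] = "ok"

        stage = "stats"
        stats = compute_stats(
            traj, selection=config.selection,
            exclude_residues=[tuple(r) for r in config.exclude_residues],
            hbond_specs=hbond_specs or [],
        )
        manifest["stages"][stage] = "ok"

        stage = "write"
        out = config.out_dir
        idx = stats.selection_indices
        with open(os.path.join(out, "rmsd.tsv"), "w") as fh:
            fh.write("frame\trmsd_A\n")
            for f, v in enumerate(stats.rmsd_series):
                fh.write(f"{f}\t{v:.4f}\n")
        with open(os.path.join(out, "rmsf.tsv"), "w") as fh:
            fh.write("resnum\tatom\trmsf_A\n")
            for k, i in enumerate(idx):
                fh.write(f"{traj.resnums[i]}\t{traj.atom_names[i]}\t{stats.rmsf[k]:.4f}\n")
        np.savetxt(os.path.join(out, "dccm.tsv"), stats.dccm, fmt="%.6f", delimiter="\t")
        with open(os.path.join(out, "occupancy.tsv"), "w") as fh:
            fh.write("spec\toccupancy\n")
            for label, occ in stats.hbond_occupancy.items():
                fh.write(f"{label}\t{occ:.4f}\n")
        manifest["stages"][stage] = "ok"
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "n_frames": traj.n_frames,
        "n_selected": int(len(stats.selection_indices)),
        "mean_rmsd": float(np.mean(stats.rmsd_series)),
        "occupancy": stats.hbond_occupancy,
    }
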