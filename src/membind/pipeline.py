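"""End-to-end analysis pipeline: time filter -> contacts/distances ->
bound partition -> 2D FEL + basins -> per-basin FELs + microstates ->
binding-model classification -> depths, H-bonds, secondary structure,
contact maps -> deterministic report files.

Outputs are TSV/JSON only, every table carries the config hash, and no
timestamps are written, so identical inputs produce byte-identical report
directories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fel, geometry, hbond, secstruct
from .core import AnalysisConfig, MembindError, TrajectoryEnsemble, filter_time_window
from .io import read_pdb_multimodel, write_table

logger = logging.getLogger("membind.pipeline")


@dataclass
class PipelineReport:
    out_dir: Path
    config: AnalysisConfig
    per_frame: pd.DataFrame
    per_residue: pd.DataFrame
    basin_summary: pd.DataFrame
    files: list[Path]


def _stage(name):
    logger.info("stage: %s", name)


def run_full_pipeline(
    traj_path: str | Path | TrajectoryEnsemble,
    config: AnalysisConfig | str | Path | None = None,
    out_dir: str | Path = "membind-report",
) -> PipelineReport:
    """Run every analysis stage on an ensemble and write the report.

    ``traj_path`` may be a multi-model PDB path or an in-memory ensemble.
    Any stage failure aborts with the stage name in the error message.
    """
    if config is None:
        config = AnalysisConfig()
    elif not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_file(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    files: list[Path] = []

    def emit(records, name, comment=None):
        path = out_dir / name
        write_table(
            records, path,
            comment=f"config={chash}" + (f" {comment}" if comment else ""),
        )
        files.append(path)
        return path

    stage = "read"
    try:
        if isinstance(traj_path, TrajectoryEnsemble):
            traj = traj_path
        else:
            traj = read_pdb_multimodel(
                traj_path, region_map=config.regions,
                frame_spacing=config.frame_spacing,
            )
        _stage(stage)

        stage = "time-filter"
        traj = filter_time_window(
            traj, config.equilibration_discard, float("inf")
        )
        if len(traj) == 0:
            raise MembindError(
                "no frames remain after discarding the equilibration window "
                f"({config.equilibration_discard} ns)"
            )
        _stage(stage)
        system = traj.topology
        n_frames = len(traj)

        stage = "contacts-distances"
        contacts = [
            geometry.count_contacts(system, f, config) for f in traj.frames
        ]
        n_contacts = np.array([c.n_contacts for c in contacts])
        distances = np.array(
            [geometry.peptide_bilayer_distance(system, f) for f in traj.frames]
        )
        bound = fel.partition_bound(n_contacts)
        _stage(stage)

        stage = "secondary-structure"
        assignments = secstruct.assign_secstruct_series(traj)
        betas = np.array([secstruct.beta_content(a) for a in assignments])
        _stage(stage)

        stage = "rmsd"
        rmsds = geometry.peptide_rmsd_series(traj)
        _stage(stage)

        stage = "fel-2d"
        grid = fel.compute_fel_2d(distances, n_contacts, config)
        basins = fel.find_basins(grid, config)
        basin_labels = basins.frame_labels(n_frames)
        _stage(stage)

        stage = "microstates"
        micro_rows = []
        frame_micro = np.full(n_frames, "", dtype=object)
        for basin in basins.basins:
            if len(basin.member_frames) == 0:
                continue
            _, microstates = fel.per_basin_fel(rmsds, betas, basin, config)
            for ms in microstates:
                micro_rows.append(
                    {
                        "microstate": ms.label,
                        "basin": basin.label,
                        "group": ms.group,
                        "mean_beta": ms.mean_beta,
                        "population": len(ms.member_frames),
                        "G_min_kT": ms.G_min,
                    }
                )
                frame_micro[ms.member_frames] = ms.label
        _stage(stage)

        stage = "classification"
        model_labels = []
        for i, frame in enumerate(traj.frames):
            feats = fel.extract_features(
                system, frame, config, ss=assignments[i], contact=contacts[i]
            )
            model_labels.append(fel.classify_binding_model(feats, config))
        _stage(stage)

        stage = "depths"
        depth_stack = np.stack(
            [
                geometry.residue_depths(system, f, config).depths
                for f in traj.frames
            ]
        )
        _stage(stage)

        stage = "hbonds"
        hsum = hbond.hbond_summaries(traj, config)
        _stage(stage)

        stage = "contact-maps"
        bound_idx = np.flatnonzero(bound)
        unbound_idx = np.flatnonzero(~bound)
        cmap_all = geometry.residue_contact_map(traj, config)
        _stage(stage)

        stage = "report"
        resids = system.peptide_residues
        per_frame = pd.DataFrame(
            {
                "frame": np.arange(n_frames),
                "time_ns": traj.times,
                "distance_nm": distances,
                "n_contacts": n_contacts,
                "n_contact_residues": [
                    c.n_contact_residues for c in contacts
                ],
                "bound": bound.astype(int),
                "beta_fraction": betas,
                "rmsd_nm": rmsds,
                "basin": basin_labels,
                "microstate": frame_micro,
                "model": model_labels,
            }
        )
        emit(per_frame, "per_frame.tsv")

        _, frac_all, _ = geometry.contact_fractions(
            traj, config, contacts=contacts
        )
        if len(bound_idx):
            bound_contacts = [contacts[i] for i in bound_idx]
            frac_bound = np.stack(
                [c.per_residue_contact for c in bound_contacts]
            ).mean(axis=0)
        else:
            frac_bound = np.zeros(len(resids))
        grouped = secstruct.grouped_fractions(assignments)
        per_residue = pd.DataFrame(
            {
                "residue": resids,
                "region": [system.region_of(int(r)) for r in resids],
                "contact_fraction": frac_all,
                "contact_fraction_bound": frac_bound,
                "mean_depth_nm": depth_stack.mean(axis=0),
                "hbond_membrane": hsum.per_residue["membrane"].to_numpy(),
                "hbond_water": hsum.per_residue["water"].to_numpy(),
                "ss_unstructured": grouped["unstructured"].to_numpy(),
                "ss_beta": grouped["beta"].to_numpy(),
                "ss_helix": grouped["helix"].to_numpy(),
            }
        )
        emit(per_residue, "per_residue.tsv")

        pops = np.array(
            [len(b.member_frames) for b in basins.basins], dtype=float
        )
        rel_g = fel.basin_relative_free_energy(pops, config)
        basin_summary = pd.DataFrame(
            {
                "basin": [b.label for b in basins.basins],
                "distance_nm": [b.min_coords[0] for b in basins.basins],
                "contacts": [b.min_coords[1] for b in basins.basins],
                "G_min_kT": [b.G_min for b in basins.basins],
                "population": pops.astype(int),
                "delta_G_kT": rel_g,
            }
        )
        emit(basin_summary, "basins.tsv")
        if micro_rows:
            emit(micro_rows, "microstates.tsv")

        fel_rows = []
        cx = grid.centers(0)
        cy = grid.centers(1)
        for i in range(len(cx)):
            for j in range(len(cy)):
                if grid.occupied[i, j]:
                    fel_rows.append(
                        {
                            "distance_nm": cx[i],
                            "contacts": cy[j],
                            "P": grid.P[i, j],
                            "G_kT": grid.G[i, j],
                        }
                    )
        emit(fel_rows, "fel2d.tsv")

        prof = fel.project_fel_1d(grid, axis=0)
        emit(
            [
                {"distance_nm": c, "P": p, "G_kT": g}
                for c, p, g in zip(prof.centers, prof.P, prof.G)
                if p > 0
            ],
            "fel1d_distance.tsv",
        )

        def map_rows(matrix):
            return [
                {
                    "residue_i": int(resids[i]),
                    "residue_j": int(resids[j]),
                    "probability": float(matrix[i, j]),
                }
                for i in range(len(resids))
                for j in range(i + 1, len(resids))
                if matrix[i, j] > 0
            ]

        emit(map_rows(cmap_all), "contact_map.tsv")
        for name, idx in (
            ("contact_map_bound.tsv", bound_idx),
            ("contact_map_unbound.tsv", unbound_idx),
        ):
            if len(idx):
                emit(
                    map_rows(
                        geometry.residue_contact_map(
                            traj, config, frame_indices=idx
                        )
                    ),
                    name,
                )

        pairs = geometry.top_longrange_pairs(cmap_all, 10, config)
        emit(
            [
                {"residue_i": i, "residue_j": j, "probability": p}
                for i, j, p in pairs
            ],
            "longrange_pairs.tsv",
        )

        if hsum.records:
            emit(
                [
                    {
                        "donor_atom": d,
                        "acceptor_atom": a,
                        "partner_class": c,
                        "count": n,
                    }
                    for (d, a, c), n in hbond.top_hbond_types(
                        hsum.records, 10
                    )
                ],
                "hbond_types.tsv",
            )

        meta = {
            "config_hash": chash,
            "config": config.to_dict(),
            "n_frames": int(n_frames),
            "n_atoms": int(system.n_atoms),
            "bound_fraction": float(bound.mean()),
            "versions": {"membind": __version__},
        }
        meta_path = out_dir / "report.json"
        meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
        files.append(meta_path)
        _stage(stage)
    except MembindError as exc:
        raise MembindError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineReport(
        out_dir=out_dir,
        config=config,
        per_frame=per_frame,
        per_residue=per_residue,
        basin_summary=basin_summary,
        files=files,
    )
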