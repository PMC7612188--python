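"""End-to-end pipeline: simulate -> extract -> align -> classify -> mips ->
ends -> report, driven by one PipelineConfig.

Every output file carries the config hash and seed in a provenance column or
sidecar; re-running with the same config reproduces deterministic outputs
bitwise.  Stage failures halt with the stage name.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .align import AlignmentLimits
from .classify import assign_pf, find_polarity_eigenvector, mra, msa, vote_polarity
from .config import PipelineConfig
from .extract import crop, frames_along_filament
from .io import FilamentModel, write_mrc, write_point_model, write_table
from .mips import cluster_clean, detect_mips, mip_density

log = logging.getLogger("axontomo")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {err}")
        self.stage = stage


def _provenance(config: PipelineConfig) -> str:
    return f"config={config.config_hash()};seed={config.seed}"


def build_scene(config: PipelineConfig) -> synthetic.GroundTruthManifest:
    """A bundle of parallel MTs with random polarity and seeded MIPs."""
    sc = config.scene
    rng = np.random.default_rng(config.seed)
    lattice = synthetic.LatticeSpec(pf_number=sc.pf_number, wall_radius=sc.wall_radius_nm)
    margin = 2 * sc.wall_radius_nm + 5
    filaments, mips = [], []
    for i in range(sc.n_mts):
        y = margin + i * (2 * sc.wall_radius_nm + 12)
        path = np.array([[margin, y, margin + 6.0],
                         [margin + sc.mt_length_nm, y, margin + 6.0]])
        pol = "plus_along_path" if rng.random() < 0.5 else "minus_along_path"
        fil = synthetic.FilamentSpec(path=path, polarity=pol,
                                     mip_rate=sc.mip_rate_per_um)
        filaments.append(fil)
        mips.append(synthetic.place_mips(fil, seed=int(rng.integers(2**31))))
    return synthetic.GroundTruthManifest(
        filaments=filaments, mip_positions=mips, snr=sc.snr,
        tilt_range=sc.tilt_range_deg, seed=config.seed, lattice=lattice)


def run(config: PipelineConfig, output_dir=None) -> Path:
    """Execute all stages; returns the results directory."""
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    prov = _provenance(config)
    t0 = time.time()

    def stage(name):
        log.info("stage %s (elapsed %.1fs)", name, time.time() - t0)

    try:
        stage("simulate")
        manifest = build_scene(config)
        manifest.save(out / "manifest.json")
        vol = synthetic.render_scene(manifest, voxel=config.scene.voxel_nm)
        vol = synthetic.corrupt(vol, manifest.snr, manifest.tilt_range, config.seed + 1)
        write_mrc(vol, out / "tomogram.mrc")
        models = [FilamentModel(filament_id=i, points=f.path)
                  for i, f in enumerate(manifest.filaments)]
        write_point_model(models, out / "filaments.pt", config.scene.voxel_nm)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    try:
        stage("extract")
        tables = [frames_along_filament(m, config.picking.spacing_nm) for m in models]
        for i, t in enumerate(tables):
            t["filament_id"] = i
        table = pd.concat(tables, ignore_index=True)
        table["particle_id"] = np.arange(len(table))
        stack = crop(vol, table, config.picking.box_size)
        write_table(stack.table, out / "particles.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("extract", e) from e

    try:
        stage("classify")
        from .align import apply_residuals, register_filaments

        stack = apply_residuals(stack, register_filaments(stack))
        decomp = msa(stack, n_components=min(config.classify.n_eigenvectors,
                                             len(stack.table) - 1),
                     seed=config.seed)
        _, _, refs = find_polarity_eigenvector(
            decomp, stack, top=config.classify.eigenvector_scan_top, seed=config.seed)
        limits = AlignmentLimits(max_inplane=config.align.max_inplane_deg,
                                 max_axial_shift=config.align.max_axial_shift_nm)
        result = mra(stack, list(refs), rounds=config.classify.mra_rounds_polarity,
                     limits=limits, wedge_aware=True,
                     tilt_range=config.scene.tilt_range_deg)
        votes = vote_polarity(result, threshold=config.classify.polarity_threshold,
                              pre_clean=config.classify.cc_clean_fraction)
        rows = [{"filament_id": fid, "assignment": v,
                 "truth": manifest.filaments[fid].polarity, "provenance": prov}
                for fid, v in votes.items()]
        pd.DataFrame(rows).to_csv(out / "polarity.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e

    try:
        stage("mips")
        cands = detect_mips(vol, models, lumen_radius=config.mips.lumen_radius_nm,
                            cc_threshold=config.mips.cc_threshold)
        clean = cluster_clean(cands, radius=config.mips.cluster_radius_nm,
                              min_size=config.mips.cluster_min_size)
        lengths = {i: f.length for i, f in enumerate(manifest.filaments)}
        dens, summary = mip_density(clean, lengths)
        dens["provenance"] = prov
        dens.to_csv(out / "mip_density.tsv", sep="\t", index=False)
        log.info("MIP density %s", summary)
    except Exception as e:  # noqa: BLE001
        raise StageError("mips", e) from e

    try:
        stage("ends")
        from .ends import EndContours, end_census

        rng = np.random.default_rng(config.seed + 7)
        ends_list, pol_map = [], {}
        for fid, vote in votes.items():
            pol_map[fid] = vote
            offsets = np.zeros(manifest.lattice.pf_number)
            offsets[rng.integers(manifest.lattice.pf_number)] = rng.uniform(20, 120)
            contours = synthetic.flared_end_contours(
                manifest.lattice, taper_offsets=offsets,
                curvature_radius=rng.uniform(18, 30))
            ends_list.append(EndContours(contours=contours, end_id=fid,
                                         filament_id=fid, end_side="path_end"))
        census = end_census(ends_list, pol_map)
        census["table"].assign(provenance=prov).to_csv(out / "ends.tsv", sep="\t",
                                                       index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("ends", e) from e

    try:
        stage("report")
        with open(out / "report.txt", "w") as f:
            f.write(f"# axontomo pipeline report ({prov})\n")
            f.write(f"MTs: {config.scene.n_mts}, SNR: {config.scene.snr}\n")
            correct = sum(
                1 for r in rows
                if (r["assignment"] == "plus") == (r["truth"] == "plus_along_path")
                and r["assignment"] != "unclear")
            f.write(f"polarity assigned correctly: {correct}/{len(rows)}\n")
            f.write(f"MIP density: {summary}\n")
    except Exception as e:  # noqa: BLE001
        raise StageError("report", e) from e
    return out
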