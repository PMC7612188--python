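"""Reproducible end-to-end experiments on synthetic ground truth.

Each function builds its own scenes from a single integer seed, runs the
full analysis path under the study conditions used throughout the package
(1-um transition MTs at SNR 0.5 with the +-60 degree wedge, 0.8-1.2-um MTs
seeded at 72 luminal particles per micrometre, 20-MT polarity cohorts), and
returns plain dictionaries of results.  They back both the acceptance test
suite and scripts/acceptance.py.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import synthetic as syn
from .align import AlignmentLimits, apply_residuals, average, register_filaments
from .classify import (
    assign_pf,
    count_pfs,
    find_polarity_eigenvector,
    mra,
    msa,
    polarity_from_slew,
    register_to_references,
    slew_sign,
    vote_polarity,
)
from .extract import SubtomogramStack, crop, frames_along_filament
from .mips import cluster_clean, detect_mips, mip_density

BOX = 33


def _crop_mt(vol, model, spacing=8.0, filament_id=0):
    table = frames_along_filament(model, spacing)
    table["filament_id"] = filament_id
    return crop(vol, table, BOX)


def transition_localization(n_seeds: int = 20, seed: int = 0, length: float = 1000.0,
                            snr: float = 0.5) -> dict:
    """12->13-pf transition detection on 1-um MTs: localization errors (nm).

    Each replicate renders an MT switching pf number at a known arclength,
    picks every 8 nm, runs the register + 3-round MRA + patch-rule pipeline
    and records |detected - true| where a transition is reported.
    """
    rng = np.random.default_rng(seed)
    errors, assignments = [], []
    for k in range(n_seeds):
        true_pos = float(rng.uniform(0.3, 0.7) * length)
        rep_seed = int(rng.integers(2**31))
        vol, _, model = syn.make_mt_tomogram(
            length=length, snr=snr, seed=rep_seed,
            pf_segments=[(0.0, true_pos, 12), (true_pos, length, 13)],
            tilt_max_deg=4.0)
        stack = _crop_mt(vol, model)
        refs = [syn.render_reference(12, BOX), syn.render_reference(13, BOX)]
        refs = register_to_references(stack, refs)
        result = mra(stack, refs, rounds=3, limits=AlignmentLimits(), wedge_aware=True)
        out = assign_pf(result, stack, class_pf={0: 12, 1: 13})
        row = out.iloc[0]
        assignments.append(row.assignment)
        if row.assignment == "transition":
            errors.append(abs(row.transition_nm - true_pos))
    errors = np.asarray(errors)
    return {
        "n": n_seeds,
        "n_detected": len(errors),
        "errors_nm": errors,
        "median_error_nm": float(np.median(errors)) if len(errors) else np.nan,
        "frac_within_20nm": float(np.mean(errors <= 20.0) * len(errors) / n_seeds),
        "assignments": assignments,
    }


def mip_density_recovery(n_mts: int = 150, seed: int = 0, rate: float = 72.0,
                         snr: float = 1.0) -> dict:
    """Detect -> cluster-clean -> density on MTs seeded at ``rate`` per um."""
    rng = np.random.default_rng(seed)
    per_um, planted = [], []
    for k in range(n_mts):
        length = float(rng.uniform(800.0, 1200.0))
        rep_seed = int(rng.integers(2**31))
        vol, manifest, model = syn.make_mt_tomogram(
            length=length, snr=snr, seed=rep_seed, mip_rate=rate, tilt_max_deg=0.0)
        cands = detect_mips(vol, [model])
        clean = cluster_clean(cands, radius=5.0, min_size=2)
        df, _ = mip_density(clean, {0: manifest.filaments[0].length})
        per_um.append(df["per_um"].iloc[0])
        planted.append(len(manifest.mip_positions[0]) / (length / 1000.0))
    per_um = np.asarray(per_um)
    return {
        "n": n_mts,
        "mean_per_um": float(per_um.mean()),
        "sd_per_um": float(per_um.std(ddof=1)),
        "se_per_um": float(per_um.std(ddof=1) / np.sqrt(n_mts)),
        "planted_mean_per_um": float(np.mean(planted)),
        "rate": rate,
    }


def pf_counting(n_mts: int = 20, seed: int = 0, pf_number: int = 13,
                length: float = 200.0) -> dict:
    """Noiseless randomly oriented MTs through extract-align-average-count."""
    rng = np.random.default_rng(seed)
    counts = []
    for k in range(n_mts):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        ctr = np.full(3, length / 2.0 + 40.0)
        fil = syn.FilamentSpec(path=np.array([ctr - d * length / 2,
                                              ctr + d * length / 2]),
                               polarity="plus_along_path",
                               phase_deg=float(rng.uniform(0, 360)))
        lattice = syn.LatticeSpec(pf_number=pf_number)
        manifest = syn.GroundTruthManifest([fil], [[]], snr=None, tilt_range=90.0,
                                           seed=k, lattice=lattice)
        n = int(length + 80)
        vol = syn.render_scene(manifest, shape=(n, n, n))
        from .io import FilamentModel

        stack = _crop_mt(vol, FilamentModel(0, fil.path))
        table = stack.table
        from .align import align

        table = align(stack, average(stack), AlignmentLimits(max_inplane=6.0))
        avg = average(stack, table)
        counts.append(count_pfs(avg))
    modal = max(set(counts), key=counts.count)
    return {"counts": counts, "modal": modal,
            "frac_correct": counts.count(pf_number) / n_mts}


def polarity_recovery(n_mts: int = 20, seed: int = 0, snr: float = 0.5,
                      length: float = 250.0) -> dict:
    """The full MSA -> polarity eigenvector -> MRA -> vote pipeline.

    Half the cohort runs plus-along-path, half minus.  Returns per-route
    agreement with ground truth and between the classification vote and the
    per-MT slew reading.
    """
    rng = np.random.default_rng(seed)
    stacks, truth = [], {}
    for i in range(n_mts):
        pol = "plus_along_path" if i < n_mts // 2 else "minus_along_path"
        rep_seed = int(rng.integers(2**31))
        vol, _, model = syn.make_mt_tomogram(length=length, polarity=pol, snr=snr,
                                             seed=rep_seed, tilt_max_deg=4.0)
        stacks.append(_crop_mt(vol, model, filament_id=i))
        truth[i] = pol
    boxes = np.concatenate([s.boxes for s in stacks])
    table = pd.concat([s.table for s in stacks], ignore_index=True)
    table["particle_id"] = np.arange(len(table))
    stack = SubtomogramStack(boxes, stacks[0].voxel_size, table)
    stack = apply_residuals(stack, register_filaments(stack))

    decomp = msa(stack, n_components=40, seed=seed)
    _, _, refs = find_polarity_eigenvector(decomp, stack, seed=seed)
    result = mra(stack, list(refs), rounds=1, limits=AlignmentLimits(),
                 wedge_aware=True)
    votes = vote_polarity(result)

    slew_calls = {}
    for i in range(n_mts):
        sub = stack.table[stack.table["filament_id"] == i]
        avg = average(SubtomogramStack(stack.boxes[sub.index.to_numpy()], 1.0,
                                       sub.reset_index(drop=True)))
        slew_calls[i] = polarity_from_slew(slew_sign(avg)[0])

    correct = wrong = unclear = 0
    agree = both = 0
    for i in range(n_mts):
        v = votes[i]
        if v == "unclear":
            unclear += 1
        elif (v == "plus") == (truth[i] == "plus_along_path"):
            correct += 1
        else:
            wrong += 1
        s = slew_calls[i]
        if v != "unclear" and s != "unclear":
            both += 1
            agree += (s == "plus_along_path") == (v == "plus")
    return {"n": n_mts, "correct": correct, "wrong": wrong, "unclear": unclear,
            "frac_correct": correct / n_mts,
            "route_agreement": (agree, both), "votes": votes, "truth": truth}
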