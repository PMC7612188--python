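"""Shared fixtures: rendered references and small synthetic stacks.

Everything is generated at test time from seeded code; nothing is read from
disk.  Session-scoped fixtures hold the expensive renders.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from axontomo import synthetic as syn
from axontomo.extract import SubtomogramStack, crop, frames_along_filament

warnings.filterwarnings("ignore", category=UserWarning)

BOX = 33


@pytest.fixture(scope="session")
def ref13():
    return syn.render_reference(13, BOX)


@pytest.fixture(scope="session")
def ref12():
    return syn.render_reference(12, BOX)


def build_mt_stack(length=250.0, polarity="plus_along_path", snr=0.5, seed=0,
                   filament_id=0, tilt_max_deg=4.0, **kw):
    """One MT tomogram cropped into a particle stack (8-nm dimer picking)."""
    vol, manifest, model = syn.make_mt_tomogram(
        length=length, polarity=polarity, snr=snr, seed=seed,
        tilt_max_deg=tilt_max_deg, **kw)
    table = frames_along_filament(model, 8.0)
    table["filament_id"] = filament_id
    stack = crop(vol, table, BOX)
    return stack, manifest, model


def pool_stacks(stacks):
    boxes = np.concatenate([s.boxes for s in stacks])
    table = pd.concat([s.table for s in stacks], ignore_index=True)
    table["particle_id"] = np.arange(len(table))
    return SubtomogramStack(boxes, stacks[0].voxel_size, table)


@pytest.fixture(scope="session")
def noiseless_mt_stack():
    stack, manifest, model = build_mt_stack(snr=None, tilt_max_deg=4.0, seed=11)
    return stack, manifest


@pytest.fixture(scope="session")
def polarity_cohort():
    """Eight MTs (4 plus, 4 minus) at SNR 1, registered: the MSA workbench."""
    from axontomo.align import apply_residuals, register_filaments

    stacks, truth = [], {}
    for i in range(8):
        pol = "plus_along_path" if i < 4 else "minus_along_path"
        s, _, _ = build_mt_stack(polarity=pol, snr=1.0, seed=40 + i, filament_id=i)
        stacks.append(s)
        truth[i] = pol
    stack = pool_stacks(stacks)
    stack = apply_residuals(stack, register_filaments(stack))
    return stack, truth
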