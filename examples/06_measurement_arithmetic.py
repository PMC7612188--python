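"""The quantification layer: densities, spectra and statistics.

Shows the measurement arithmetic used in reports: plus-end densities per
axon length and area, filament layer-line spectra, and the Student t-tests
behind group comparisons.
"""

import numpy as np

from axontomo import synthetic as syn
from axontomo.stats import (densities, diameter_peak_to_peak,
                            layer_line_spectrum, round_sig, summarize, ttest)

# 11 plus ends over 75 um of axon, axons ~0.3 um wide
d = densities(11, 75.0, 0.3)
print(f"plus ends: {round_sig(d['per_um'], 2)} per um, "
      f"{round_sig(d['per_um2'], 2)} per um^2")

# MT wall diameter from a rendered cross-section profile
from axontomo.align import project

ref = syn.render_reference(13, 33)
img = project(ref, 5, "z")
print(f"rendered MT wall peak-to-peak: {diameter_peak_to_peak(img[16, :], 1.0):.1f} nm")

# actin-like filament: 6-nm axial repeat from the Fourier layer lines
fil = syn.FilamentSpec(path=np.array([[30.0, 30.0, 10.0], [30.0, 30.0, 240.0]]),
                       kind="actin")
man = syn.GroundTruthManifest([fil], [[]], snr=None, tilt_range=90, seed=3)
vol = syn.render_scene(man, shape=(256, 60, 60))
_, spacing = layer_line_spectrum(vol.data[:, 30, :], 1.0, axial_axis=0)
print(f"actin layer-line spacing: {spacing:.1f} nm")

# unpaired two-tailed t-test between two diameter samples
rng = np.random.default_rng(0)
mts = rng.normal(21.2, 1.0, 40)
actin = rng.normal(6.1, 1.1, 40)
r = ttest(mts, actin)
print(f"MT vs actin diameters: {summarize(mts)} vs {summarize(actin)}, "
      f"t={r['t']:.1f}, p={r['p']:.2g}")
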