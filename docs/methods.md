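# Methods

## Coordinate and data conventions

Physical coordinates are nanometres in a right-handed (x, y, z) frame;
volumes are stored (z, y, x) with the centre of voxel (0, 0, 0) at the
origin. Orientations are intrinsic Z-X-Z Euler triplets in degrees; the
rotation matrix maps box-frame vectors to tomogram-frame vectors and the
box z-axis follows the local filament tangent. The in-plane (spin) angle is
the third angle. Internally protein is positive density; MRC export inverts
the sign by default so files look like conventional cryo-EM maps. Particle
tables are TSV motive lists; alignment results live in residual-transform
columns (rphi, rtheta, rpsi, sx, sy, sz) meaning "box content equals the
reference rotated by the residual rotation, then shifted".

## The synthetic scene model

A microtubule is a Gaussian-blob lattice on a cylinder:

* 13 pf by default, wall radius 10.6 nm (scaled as `10.6 * pf/13` for other
  pf numbers, since the pf spacing along the wall is conserved — this
  radial difference is also the physical cue separating 12- from 13-pf MTs);
* tubulin dimers repeat every 8 nm along each pf with the β monomer 4 nm
  above the α (both rendered identically, so the axial repeat of the wall
  is 4 nm);
* **helical rise 0.92 nm per pf** (the 3-start helix implied by the
  27.69°/0.92-nm helical parameters of the 13-pf MT). This is the dominant
  polarity cue: the winding handedness of the lattice reverses when the MT
  is viewed from the other end;
* each monomer is drawn as a radially oriented blob pair (separation
  2 nm, sub-blob σ 1.5 nm) tilted tangentially by 15° with handedness tied
  to polarity — a minimal parametric surrogate for the tubulin slew seen in
  projections. The physical origin of the slew in real data is not modelled;
  the helical rise plus this tilt suffice to exercise the method;
* lattice breaks remove monomers inside stated arclength intervals; per-pf
  end tapers remove monomers beyond per-pf terminal arclengths; pf-number
  transitions tile the path with per-segment pf counts;
* luminal particles are rings of six blobs (ring radius 3.2 nm, blob σ
  1.2 nm, ~9-nm outer diameter with a central pore), randomly oriented,
  placed along the lumen with a Poisson-drawn count and an exact hard-core
  construction (uniform order statistics plus cumulative 9-nm offsets), so
  the realized density equals the requested rate while respecting the
  particle diameter;
* actin-like filaments are double-stranded blob chains with a 6-nm axial
  repeat and a slow (72-nm period) twist.

Corruption adds white Gaussian noise scaled so that variance on the signal
support mask (voxels above 10% of max) over noise variance equals the
requested SNR, then zeroes Fourier amplitudes in the missing wedge
(|arctan(kz/kx)| > tilt range, tilt axis y, default ±60°). Everything is
seeded; the manifest round-trips losslessly through JSON.

### What the generator does and does not emulate

It reproduces the geometry and statistics the pipeline quantifies: lattice
periodicity and helicity, pf-number geometry, breaks/tapers/transitions,
luminal-particle placement, SNR, and the anisotropy of a single-axis tilt
series. It does not model the contrast transfer function, dose weighting,
reconstruction artifacts other than the ideal wedge, crowding by other
cellular material, or the internal structure of tubulin. Passing tests
therefore demonstrate the correctness and noise/wedge robustness of the
estimators under a faithful geometric model, not performance on raw
experimental tomograms.

## Wedge-aware cross-sections: the repeat-layer trick

For an MT lying roughly perpendicular to the beam, the ±60° wedge removes
nearly all cross-sectional information at kz_axial ≈ 0: a plain 5-slice
projection shows only the wall sectors whose normals stay inside the
sampled region. The 4-nm monomer repeat, however, puts a full copy of the
wall's angular structure on the Fourier plane kz_axial = 1/(4 nm), which
lies outside the wedge for any filament orientation. Cross-sections for pf
counting and slew reading are therefore taken as the 2D inverse transform
of that plane: its magnitude shows the pf ring; its phase winds with the
helical start number, with a sign given by polarity. A plain projection
mode remains available, including least-squares harmonic fitting with
missing-wedge visibility weights.

## Detectors and their calibrations (fixed once, on noiseless renders)

* **pf counting**: the wall annulus (r_wall ± 3 nm) of the cross-section is
  unwrapped; the pf count is the harmonic in 11..15 with maximal fitted
  power; 'ND' when the peak-to-runner-up power ratio is below 1.5 or the
  peak is under 3× the spectral background.
* **slew/polarity from a volume**: the phase winding of the repeat-layer
  ring (conjugate-product phase accumulation around the wall circle);
  accepted when the step coherence is ≥ 0.2 and the winding magnitude lies
  in [0.5, 4.5]; the sign-to-handedness mapping was calibrated once on
  rendered references of known polarity and frozen. Anti-clockwise slew
  (viewer on the path-forward side) means the plus end faces the viewer.
* **slew from a 2D image**: phase of the dominant pf harmonic fitted at six
  radii between 8 and 13 nm and regressed against radius; undetermined when
  the harmonic power is below 8× background, the radial phase residual
  exceeds 3°, or the integrated lag is below 0.5°.
* **MIP detection**: whole-volume normalized cross-correlation against the
  rotation-averaged ring template (with a spherically symmetric template
  the free-rotation search is degenerate, so translation-only refinement is
  exact). Candidate positions are taken from a difference-of-Gaussians
  sharpened correlation map (σ 2 nm): near the 9-nm packing limit two
  particles fuse into one ridge of the raw map, which would merge their
  clusters and undercount. Samples every 2 voxels refine to the best
  sharpened-map voxel within 4 nm (non-converged, window-boundary argmaxes
  are dropped), constrained to 4 nm of the axis; acceptance requires raw
  NCC ≥ 0.03 at that voxel, a threshold chosen on a synthetic
  receiver-operating sweep (precision ≥ 0.99, recall ≥ 0.98 at SNR 1 and
  ≥ 0.97 at SNR 0.5, zero detections on particle-free MTs) and frozen.

## Registration before MSA

Particles within one filament share a picking frame; across filaments the
azimuthal lattice phase and axial register are arbitrary, and that
structured variance would bury the polarity contrast in the eigenspectrum.
Both registers are measured in closed form on per-filament averages — the
pf-harmonic phase of the layer-plane magnitude for spin, and the global
layer-plane phase relative to the pooled average for the axial shift (a
z-shift multiplies the whole plane by a unit phasor; opposite-polarity
layers are near-orthogonal, so each filament effectively registers against
its own class). Picking frames also standardize the in-plane angle so the
missing wedge sits identically in every box; since spin freedom is a
lattice symmetry this costs nothing.

Because the helical lattice phase is defined modulo 360° (not modulo one pf
spacing), classification against *external* references first aligns the
pooled per-MT average to each reference over the full in-plane range and
pre-rotates the references into the data's register; the subsequent MRA
then works within the constrained limits (28° in-plane, 2.2 nm axial,
2° / half-voxel steps).

## Statistics

Summaries are mean ± SD (n−1); group comparisons are classic Student
t-tests (pooled variance unpaired, or paired), two-tailed, via scipy, with
an explicit p = 1 convention for the zero-variance equal-mean corner.
Report-layer rounding is 2–3 significant figures; internals keep full
precision. The expected-vs-observed density analysis truncates adjacent
100-nm windows at MT ends and excludes zero-length breaks with a flag.

## Problem sizes and numerical choices

Synthetic cohorts use 1-µm MTs for transition detection (20 replicates,
SNR 0.5), 0.8–1.2-µm MTs for luminal-particle recovery (planted at
72/µm, SNR 1), 250-nm MTs for the 20-MT polarity cohort (SNR 0.5), and
200-nm randomly oriented MTs for noiseless pf counting — sizes chosen so
each experiment carries enough particles per MT (≥ 25) for stable per-MT
averages while a full acceptance run stays in the tens of minutes on one
core. Boxes are 33 voxels at 1 nm; interpolation is trilinear everywhere;
missing-wedge compensation in averaging divides by summed per-particle
coverage floored at 10% of its maximum. k-means and PCA are seeded;
rendering and corruption are bit-reproducible given the manifest seed.

## Known limitations

* The slew surrogate's absolute handedness convention is a generator
  definition; only its internal consistency (mirror antisymmetry, agreement
  between the winding and radial-lag routes) is meaningful.
* MSA-based polarity classification needs several MTs per cohort for the
  eigenvector scan; single-MT polarity is available through the per-MT slew
  reading instead.
* Real-data use of the break/end density analysis requires user-supplied
  break boundaries (defined by the shortest pf on either side); synthetic
  breaks carry exact boundaries.
* Contours whose pf tips would leave the reconstructed volume are not
  modelled; taper assumes every traced contour ends inside the volume.
* No CTF, dose weighting, or reconstruction pipeline is simulated; the
  wedge is applied directly in Fourier space.
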