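# Methods

## Conventions

Volumes are cubic arrays indexed `[z, y, x]` with the real-space origin at
voxel `N // 2` on each axis; images are `[y, x]` with 0-based pixel
coordinates, origin top-left.  Euler angles are ZYZ intrinsic
`(rot, tilt, psi)` in degrees with rotation matrix
`R = Rz(rot) · Ry(tilt) · Rz(psi)`; a projection samples the volume at
`R·u` and integrates along z, so for a C2 volume (two-fold about z)
`(rot, tilt, psi)` and `(rot+180°, tilt, psi)` produce the same image, and
angular errors are always reported modulo the C2 operation.  Defocus is in
μm, positive for underfocus, with `defocus_u ≥ defocus_v` and the
astigmatism azimuth in [0°, 180°).  Spatial frequency is in Å⁻¹.

## The phantom

The phantom emulates a barrel-shaped protease core of four stacked
pseudo-seven-fold rings with C2 symmetry.  Because the package fixes the
C2 axis to z, the barrel's long axis lies along x (in the real complex the
two-fold likewise relates the two halves across the ring stack).  Each
half carries an outer ring (radius 42 Å, axial centre 55 Å) and an inner
ring (radius 45 Å, centre 20 Å) of seven Gaussian blobs (σ = 6.5 Å); the
second half is the exact 180° copy about z, so the rendered density is
invariant under the grid-exact rotation `rot180_z` to machine precision.
The seven blobs of a ring carry distinct weights (0.6–1.4) and the inner
ring is staggered by 25.7°.  This is deliberate: rings of seven
*identical* subunits would make orientation recovery ill-posed modulo
2π/7, whereas the real complex has seven distinct subunits per ring.

Three ligand sites per half sit adjacent to inner-ring blobs, inset 15 Å
radially into the solvent cavity and 8 Å axially (compact blobs,
σ = 3 Å, weight 0.6 × occupancy).  Defaults: 64-voxel box at 2.8 Å/voxel,
large enough that every blob's rendered support (±4.5 σ) is interior to
the grid — a requirement for the exact C2 invariance.  A coarse 32-voxel
variant at 5.6 Å/voxel serves the reconstruction oracles.

Gaussian rendering uses `w·(2πσ²)^{−3/2}·exp(−r²/2σ²)·v³` on a ±4.5 σ
window, so each atom's plain grid sum equals its weight to <0.1 %.

## Imaging model

Default acquisition: 300 keV (λ = 0.0197 Å), Cs = 2.7 mm, amplitude
contrast A = 0.07, 1.04 Å/px at the instrument scale (desk-scale stages
use the phantom's 2.8 Å voxel), 17 frames of 2.8 e⁻ Å⁻² at 0.056 s in a
1 s exposure.  The CTF is the weak-phase model given in the README;
CTF(0) = −A for every parameter set.  The sampled 2D CTF grid is
symmetrized under k → −k (this only touches the aliased Nyquist
row/column) so that applying or phase-flipping the CTF keeps real images
exactly real.

Noise is additive white Gaussian.  For particle stacks the level is set
by an SNR parameter (clean-image variance over noise variance, measured
over the whole box on the CTF-modulated image); for movies the per-frame
noise variance is proportional to the per-frame dose.  No detector
MTF/DQE, no ice or support modelling, no amplitude-decay envelopes: the
generator reproduces the *geometry and dose structure* of real data, so
passing tests demonstrate correctness of the algorithms under this model,
not performance on real micrographs, whose noise is neither white nor
Gaussian and whose particles deform.

Thon-ring work uses an amorphous-specimen stand-in: unit-variance white
noise filtered by the CTF plus white noise of variance 1/SNR.

## CTF estimation and screening

The estimator computes a tile-averaged periodogram (512-px tiles, 50 %
overlap), removes a smooth radial baseline (median + Gaussian-smoothed
log-power profile) and lightly smooths the residual (isotropic, so ring
positions are unbiased).  It then maximizes the correlation between
|CTF|² and the residual over a fitting band, by a 0.05 μm defocus grid, a
coarse astigmatism scan, and Nelder–Mead refinement.  The band's upper
edge is capped where the spectral sampling stops resolving rings at the
maximum search defocus (phase step ≤ π/3 per spectral pixel) — beyond
that, undersampled rings only add noise.  A best correlation below 0.2
raises an estimation-failure error rather than returning a default (pure
noise reliably fails).  On the standard simulated micrographs at SNR 0.5
the recovery is ≲0.5 % in defocus and ≲3° in angle, comfortably inside
the 2 %/5° acceptance bands.

Thon-ring isotropy splits the Friedel-unique azimuth range into sectors,
builds per-sector radial profiles of *linear* power, and scores each
radial window by the worst concordance correlation between a sector
segment and the all-sector mean segment.  Concordance (not Pearson) is
essential: directional drift damps ring *contrast* in some sectors, a
scale change that position-only correlation cannot see.  Bins below 6 %
of Nyquist are excluded (too few pixels per sector, no ring content).
The returned frequency is the end of the contiguous passing run from low
frequency, which is monotone in the threshold by construction.

Phase flipping multiplies Fourier coefficients by sign(CTF); amplitudes
are untouched, the raw operation is an involution, and a `phase_flipped`
flag guards against double application.

## Movie handling

Frame indices are 1-based at the interface.  Window selection takes the
maximal contiguous run whose *preceding* accumulated dose reaches the
skip threshold and whose own accumulated dose stays under the cap; with
the default ledger, (skip 5.6, cap 28) gives frames 3–10, 0.448 s of
exposure.  Drift is measured (not auto-applied) by phase cross-correlation
of consecutive frames with a normalized-correlation confidence; the
"negligible" threshold defaults to 1 px and is a configuration choice.

## Picking and extraction

The picker is a matched filter — normalized cross-correlation against a
template, or a Laplacian-of-Gaussian response at the configured diameter
(threshold in SD units) — with greedy non-maximum suppression (score
descending, ties to lower (y, x)).  Each surviving peak is then recentred
by two mean-shift iterations on the smoothed intensity, because the raw
response maximum sits on the strongest density lobe, ~3 px off the
particle centroid for this phantom.  Curation flags removals (provenance
preserved) and appends manual additions.  Extraction crops even-sized
boxes centred on each active pick, inheriting the micrograph CTF; the
`skip` edge policy drops and reports out-of-bounds picks, `clamp-pad`
pads with the field mean.

## Refinement and reconstruction

Each round builds a projection library of the current reference on a
quasi-uniform (rot, tilt) grid over the C2 asymmetric unit (tilt rings,
rot samples ∝ sin tilt, rot ∈ [0°, 180°)), rotates every projection
through a discrete psi grid, and matches every particle against every
template by FFT cross-correlation over a ±8 px shift window.  Images and
templates are normalized to zero mean and unit norm under a circular
mask, so a perfect self-match scores 1.  Two matched-filtering choices
matter at low SNR: matching is band-limited to 15 Å by default (the
phantom's information lives below ~20 Å while the noise is white), and
each particle's |CTF| enters the filter — applied once to the image
transform, with template norms corrected by Parseval — because CTF zeros
cut through the discriminating band.  Round 1 searches the full
asymmetric unit; later rounds restrict each particle's direction search
to twice the previous angular step around its previous assignment
(standard local projection matching); psi and shift stay exhaustive.  The
schedule defaults to 3 rounds at 15°/10°/7.5°, starting from the
reference low-pass filtered to 20 Å.

Reconstruction is direct Fourier inversion: each particle's transform
(shift-corrected by phase ramps) is inserted into its central slice at
`K = R·(kx, ky, 0)` with trilinear spreading and per-voxel weight
accumulation, once per symmetry element (Fourier-space C2 averaging).
Because rotations are about the box centre rather than the FFT origin,
the 2D transform is re-centred by a phase checkerboard before insertion
and the 3D transform un-centred afterwards.  With amplitude correction
the map is `Σ CTFᵢFᵢ / (Σ CTFᵢ² + c)` with `c = 0.01 × mean(Σ CTF²)`;
phase-flipped particles contribute |CTF| in the numerator.  On 500
noiseless projections of the coarse phantom the result matches both the
phantom and a naive periodic real-space back-projection oracle at
FSC ≥ 0.95 up to 0.8 × Nyquist (per-shell normalization divides out the
back-projection's radial weighting; the smear must be periodic because
the Fourier method is).

At the standard noisy condition (500 particles, SNR 0.1, CTF applied and
phase-flipped, 64-px boxes) the median angular error after three rounds
is ~5–6°, within the 7.5° final step; a minority of particles (roughly a
quarter to a third) land far from truth, which is expected at this SNR
for a smooth blob phantom where distinct views genuinely resemble one
another.  The median, not the tail, is the specified recovery statistic.

## Postprocessing

FSC uses one-Fourier-voxel shells with per-shell normalized complex
correlation; the DC shell is reported but flagged.  Resolution at a
threshold interpolates the first crossing linearly between shell centres;
a shell exactly on the threshold is itself the crossing; without a
crossing the Nyquist-shell resolution is returned with a flag.  Default
thresholds: 0.5 map-vs-model, 0.143 half-map.  Sharpening scales
amplitudes by `exp(−B·k²/4)`; low-pass filtering uses a cosine edge
(default 3 Fourier voxels), preserves DC exactly and never adds power.
Local resolution is a windowed-FSC stand-in for likelihood-based tools:
Hann-apodized cubes (default 16 px, step 8) are scored by
`resolution_at_threshold` and interpolated back to voxels, with NaN
outside coverage.  It is a relative map-quality indicator — windowed
spectral leakage biases absolute values — and is validated as such (a
uniformly band-limited pair is homogeneous; a deliberately blurred region
scores strictly worse).

Grey-scale sections partition the map into slabs by nearest-voxel
assignment (`floor(i·voxel/thickness)`), average each slab, and normalize
the grey scale globally over the stack so densities are comparable across
sections.  A thickness slightly below the voxel size (≥ half a voxel) is
allowed and yields one single-voxel section per plane — this is how 1 Å
sections of a 1.04 Å-sampled map are to be read; thinner requests are
rejected.

## Ligand-site scoring

The density at a designated site is summarized as
`z = (mean_in_mask − mean_shell) / sd_shell` with a spherical mask
(default 4 Å) and a disjoint background shell (default 7–14 Å).  The
statistic is invariant under global affine rescaling of the map and its
expectation increases with occupancy.  The background shell rather than
the whole solvent makes the score robust to map-wide gradients, at the
price of sensitivity to nearby protein tails — the default mask/shell
geometry keeps the shell clear of the nearest subunit blob.  The standard
experiment simulates maps at occupancies 1.0/0.6/0.3 with white map noise
of σ = 0.1 × the ligand blob's peak density (a map in which ligand
density is clearly visible has noise well below the ligand peak) and
ranks the three sites per half by z; full occupancy scores z > 5, the
zero-occupancy null stays within |z| < 2, and the ladder ranks correctly
in ≥ 18 of 20 replicates.

## Problem sizes

The test-suite and acceptance-script workloads are sized for a single
CPU: 1024² micrographs for CTF work, 640–768² fields of ~20 particles for
picking, 32³/500-projection reconstructions for the oracles, and a
500-particle, 64²-box, 3-round refinement as the largest single job
(a few minutes).  The full experimental-scale problem
(76,500 particles in 256² boxes) is orders of magnitude beyond desk
scale and is deliberately out of scope; nothing in the implementation is
specific to the reduced sizes.

## Known limitations

White Gaussian noise, no detector envelope and no structural
heterogeneity make the synthetic task easier than real data in some ways
(no model bias between independent half-sets, no orientation bias) and
harder in others (the smooth blob phantom offers less high-frequency
discrimination than secondary structure).  The local-resolution mapper is
a windowed-FSC approximation, not a likelihood method.  The picker is a
classical matched filter; crowded or contaminated fields would need the
curation hooks.  C2 symmetry is hard-wired to the z axis; externally
supplied maps must be pre-oriented.
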