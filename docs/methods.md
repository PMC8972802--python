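# Methods

This note records the models, conventions, numerical choices and known
limitations behind `biaslab`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external measurements.

## The observation model

A particle image is simulated as

    I = a · ( CTF ⊛ P_φ(V) + n ) + b

where `P_φ` is the line-integral projection of the ground-truth volume `V`
at pose φ = (rot, tilt, psi, Δx, Δy), `CTF` the contrast transfer
modulation applied multiplicatively in Fourier space, `n` zero-mean
Gaussian noise, and `(a, b)` a per-image linear normalization perturbation.
Euler angles follow the intrinsic ZYZ convention used by STAR-file
metadata: `A = Rz(rot)·Ry(tilt)·Rz(psi)`, with the projection taken along
the rotated z axis and shifts applied after rotation via Fourier phase
ramps, in pixels. The volume/image origin is the voxel at index
`box // 2` (0-based); shell `i` maps to frequency `R = i/(N·Ts)` in 1/Å.

**SNR definition.** The paper-style SNR range (0.1–0.01) is ambiguous
without a support convention; here SNR = (signal variance inside the
projected support disk of radius 0.4·box) / (noise variance). Restricting
to the support avoids diluting the signal statistics with empty background.
A 1000-image Monte-Carlo check confirms the realized ratio to within 5%.

**CTF.** `CTF(R) = −[√(1−Q²)·sin χ + Q·cos χ]`, with
`χ = πλΔf R² − (π/2)Cs λ³R⁴` and
`λ[Å] = 12.2639/√(V + 0.97845·10⁻⁶·V²)` (V in volts). Spherical
aberration Cs and amplitude contrast Q default to zero in `CTFParams`,
reducing to the plain `sin(πλΔf R²)` oscillation; the *dataset generator*
defaults to Q = 0.1, a typical experimental value, so that low frequencies
are not completely extinguished. Underfocus is positive. The first zero
(Cs = Q = 0) sits at `R = (λΔf)^(−1/2)` and is verified against a
high-resolution grid evaluation.

**Phantoms.** Sums of 14 Gaussian blobs inside a support sphere of radius
0.4·box, placed deterministically from a seed. `class2` displaces three
blobs by 0.08·box and deletes one, giving a localized, known structural
difference; `pseudo_sym` is two 7-blob subunits related by a 180° rotation
about z plus one symmetry-breaking blob (rotated-self correlation ≈ 0.98).

**Mixture allocation** is deterministic rounding (contaminants, class 2,
then class 1 fills the remainder), so mixture predictions can be checked
exactly. Contaminants are random 2-D blob clutter scaled to the projection
variance. Defoci are drawn per micrograph (50 images each) from
10 000–25 000 Å at 300 kV. Pixel size is 2 Å/voxel throughout the desk
profile: a 48-voxel box then spans 96 Å, a small protein.

## Projection and reconstruction

Projection is Fourier central-slice extraction on a 2× zero-padded grid
with cubic-spline interpolation of the (prefiltered) transform; a
brute-force real-space rotate-and-sum oracle is kept in the package and
the two agree to <2% below ⅔ Nyquist (measured ≈0.05%).

Reconstruction is direct Fourier inversion: each image's padded 2-D
transform is spread as a central slice at each of its weighted orientations
with trilinear gridding; accumulated values are divided by accumulated
interpolation (+CTF², in Wiener mode) weights with a Tikhonov floor
ε = 10⁻³·max-weight, followed by a sinc⁻² gridding correction on the
cropped box. Two numerical choices deserve note:

- **2× oversampling is structural, not cosmetic.** On an unpadded grid a
  constant image is exactly a Fourier-domain delta, and the normalization
  "sphere" artifact cannot be represented by slice insertion at all; with
  padding the constant image has spectral width and the artifact emerges
  with the correct increasing-with-radius profile.
- **Reprojection correction.** Single-pass gridding carries a ~3%
  broadband systematic error. In the CTF-free mode one Richardson pass —
  re-grid the residual between the data and the reprojected estimate —
  reduces this to ≈0.3%, which is what the mixture-law oracle requires.
  CTF-handling modes keep single-pass gridding, the field's standard
  practice, and the experiments that model "what a standard reconstruction
  shows" (the normalization sphere, halos) use single-pass gridding
  explicitly.

Wiener correction uses a fixed constant (0.1) against CTF²; with amplitude
contrast ~0.1 this deliberately under-restores the lowest frequencies, as
real pipelines with conservative SSNR estimates do.

`refine` is plain projection matching: per iteration the images are split
(fixed seeded partition for gold; fresh partition each iteration for
interleaved), each half is assigned against a Fibonacci-lattice gallery of
its own current map (gold) or the common previous map (interleaved), the
halves are reconstructed and their FSC recorded. Half-membership history
is logged so interleaved image sharing can be audited. A common initial
volume is allowed in gold mode, mirroring common practice (and its known
insufficiency for true independence).

## Alignment, classification, consensus

`assign_pose` searches a gallery (Fibonacci directions with in-plane psi at
the same step; ~46 directions at 30°) exhaustively with integer shift
search (default radius 5 px) under correlation or Euclidean metrics; ties
break on the lowest gallery index. For mean-zero equal-norm references the
two metrics provably pick the same reference, which the tests verify.

`classify2d` is the classic align-and-average loop with seeded random
initial labels and reseeding of empty classes from worst-fitting images.
Class averages are *not* renormalized, so the Euclidean metric sees the
smaller background norm of better-averaged classes — the mechanism behind
the attraction instability, which duly appears at SNR 0.05 and not at
SNR 1.

`consensus` clusters each particle's pose estimates across runs by single
linkage under the SO(3) geodesic metric at θ = 10° (≈ one coarse sampling
bin); a particle "agrees" when the top cluster holds a strict majority,
and its consensus pose is the chordal quaternion mean of that cluster.

## Diagnostics

FSC uses integer-rounded voxel-radius shells, the real part of the
cross-spectrum in the numerator, and reports zero for zero-energy shells;
threshold crossings are linearly interpolated, first crossing only (no
regime-change detection is attempted). The B-factor weight
`exp(−B·R²/4)` is evaluated at the binned shell radius — constant within
each FSC shell — so FSC invariance under it is exact rather than
approximate; at desk-scale boxes the difference from the continuous weight
is far below one shell width. Phase randomization replaces phases beyond
the cutoff with those of a white Gaussian field's transform, preserving
per-voxel amplitudes exactly and Hermitian symmetry automatically; corner
samples beyond the Nyquist sphere count as "at Nyquist" so a cutoff at
Nyquist is the identity. The tight-mask recipe is: low-pass to ~15 Å,
threshold at the 85th percentile of in-support values, 3-voxel dilation,
raised-cosine edge (5 voxels). The halo annulus is [1.05r, 1.3r], just
outside the particle. The BIC is scored as `loglik − (k/2)·ln N`; the
penalty constant is isolated in one line should a different convention be
preferred.

## The experiments and their study conditions

Desk profile: boxes 32–48, 60–500 particles, SNR 0.1 for realistic runs
(the favourable end of the experimental range, so effects are visible at
small n); stochastic claims aggregate 10 seeds; all thresholds live in the
experiment registry and are echoed in reports. Choices worth explaining:

- **mixture_bias** verifies the linear mixture law with equal class counts
  (250 + 250) on quasi-uniform pose sets: a sparsely sampled contaminant
  class leaves angular gaps where no linear-mixture behavior is possible at
  high frequency, which is a real property of sparse contamination, not an
  implementation artifact. The contamination sweep (N2/N1 up to 0.5) then
  shows the bias magnitude growing monotonically.
- **missing_directions**: depleting a polar *cap of viewing directions*
  leaves every Fourier shell covered (equatorial and antipodal views fill
  it) — measured elongation ratio ≈ 1.0 — so the experiment demonstrates
  the empty-cone artifact with the geometry that actually produces it:
  views concentrated near the pole (top views only), which leave an empty
  double cone around the z axis and a measured z/x second-moment ratio
  ≈ 3× the uniform control. Both numbers are reported.
- **defocus_bias / pixel_size_bias** compare matched phase-flip correction
  against correction with a +1000 Å defocus offset or a 2% pixel-size
  error, at 10 paired seeds. The sign matters: an *overestimated* phase
  (positive defocus offset; pixel size underestimated by 2%) darkens the
  halo annulus, the opposite sign brightens it; the experiments use the
  darkening direction, matching the dark-halo phenomenology. The matched
  control itself has a negative baseline score because phase flipping
  preserves |CTF| attenuation at low frequency; only the paired difference
  is interpreted.
- **normalization_bias** backprojects constant images over a deterministic
  Fibonacci coverage (eliminating orientation-sampling jitter) and checks
  the radial profile is non-decreasing with an edge/center ratio > 1.5.
- **einstein_from_noise**: refining pure-noise images against a structured
  reference yields a map correlated with the reference (≈0.09 vs ≈0.01
  unrelated-map null). Projection matching reaches an exact self-consistent
  fixed point after one iteration at this scale, so the correlation is
  retained rather than growing across iterations; the experiment asserts
  emergence and retention.
- **interleaved_split** runs the same noisy dataset through gold and
  per-iteration-resplit refinements (4 iterations, 24° sampling) and
  compares FSC-to-truth areas; the difference is well under 5%.
- **attraction_2d** uses 60 images (classes of ~30) so that the
  background-norm difference between classes is large relative to the
  signal term; at larger n the instability weakens at fixed iteration
  count.

## What the synthetic data does and does not emulate

The generator produces pre-extracted, perfectly centered (unless shifted),
white-noise particles of a rigid phantom with an idealized CTF — no ice
gradients, motion blur, detector DQE, beam tilt, structural flexibility,
or per-particle defocus variation within a micrograph. Passing tests
therefore demonstrate the *mechanisms* of bias and the correctness of the
diagnostics, not quantitative agreement with any real dataset; real-data
effect sizes (e.g. how many particles two algorithms disagree on) are
dataset-dependent and outside what a synthetic desk-scale model can pin
down.

## Numerical details and degenerate inputs

Seeded `numpy` Generators everywhere; every operation taking a seed is
bit-reproducible. Empty stacks, singleton ensembles, inconsistent
fractions, zero pixel sizes, out-of-range thresholds and cutoffs raise
`ValueError` with the offending quantity named. Reconstruction accepts
weights summing to anything positive per image (renormalized); all-zero
weights are an error. Volumes must be cubic with even box ≥ 16;
experiments use ≥ 32.
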