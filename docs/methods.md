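# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic validation does and does not
show.

## Digital phantom

The phantom is a 2D single-slice (default) or small-3D torso: an elliptic
muscle body with a fat ring, a myocardial shell with a blood pool, and two
cylindrical aorta-like vessels (AAo, DAo) running along the through-plane
axis. In 2D mode the image plane is (y, z) — a plane containing the
superior–inferior axis — so that respiratory motion (predominantly SI) is
in-plane and identifiable from in-plane k-space, while flow is
through-plane (v_x), matching the flow-quantification geometry. The
through-plane displacement coefficient is unobservable in this mode
(k_x = 0) and is fixed at zero by the motion fit.

Tissue signal is a lookup per contrast mechanism: the bright-blood
anatomical contrast has blood/myocardium = 3.0/2.0 = 1.5 with fat at 0
(inherent fat suppression); the PC contrast has blood/myocardium =
1.4/2.0 = 0.7 with fat visible. These ratios are chosen to reproduce the
direction and scale of the contrast dichotomy the combination method
exploits; they are generator inputs, so the end-to-end contrast
measurements on reconstructed magnitudes are a consistency check of the
measurement chain, not independent evidence about in-vivo contrast.

Dynamics:

* Cardiac cycle: a raised-cosine systolic pulse w(τ) occupying the first
  35% of the RR interval drives both the flow waveform and a distensible
  vessel radius R(τ) = R₀(1 + 0.08·w(τ)); the blood pool contracts by 10%
  at peak systole. Heart rate 1.2 Hz (72 bpm).
* Flow: parabolic (Poiseuille) profile v(ρ) = v_max(τ)(1 − ρ²/R²) along
  the vessel axis. The peak amplitude is calibrated at construction (4096-
  point quadrature) so that ∫_beat Q dt equals the configured stroke
  volume exactly; with the defaults (SV 30 mL per vessel, R₀ 10 mm) the
  peak on-axis velocity is ≈ 117 cm/s, safely below venc = 150 cm/s. The
  defaults are deliberately on the small side of physiological so that no
  wrap occurs at the published venc.
* Respiration: r(t) = −cos(2π·0.25·t), a bounded unitless curve; the
  rigid displacement is c_true·r(t) with default c_true = (0, 0, 8) mm.
* Pilot tone: each of 12 channels mixes a cardiac source (smooth periodic
  dips of width σ = 0.15·RR whose minima mark beat onsets — sharp minima,
  flat maxima, which is what the polarity heuristic keys on) and the
  respiratory curve with seeded Gaussian weights, plus per-channel linear
  drift, a step offset at the inter-sequence gap, and Gaussian noise.
  Sources are unit-variance, so noise_sd = 0.1 means SNR 10. The dip
  width keeps ~96% of the source energy in the fundamental, so a
  narrow-band extraction can correlate > 0.9 with the source; no
  quantitative PT signal model is published, and these defaults are
  chosen for testability, not hardware fidelity.

Rasterization is 4x supersampled and box-averaged (partial volume), with
the supersample boxes centered on the voxel centers (i − n/2)·Δx used by
the NUDFT — the two conventions must agree or every geometric comparison
inherits a half-voxel bias.

## Forward model and operators

The simulator and the reconstruction share one operator: a direct
non-uniform DFT of the rasterized frame along radial spokes
(k = kmax(2i−N)/N·d, cycles/mm, iso-center origin), with the exact
conjugate-transpose adjoint. Spoke matrices are built by a multiplicative
recursion along the uniformly spaced radial offsets (one complex exp per
voxel instead of one per entry) and cached as complex64 for iterative
work; oracle tests use complex128. Motion enters simulation as the linear
k-space phase of a rigid translation — identical, by construction, to
what the correction removes; non-rigid realism is explicitly out of
scope. Velocity encoding uses the balanced 4-point Hadamard matrix
H = [(−1,−1,−1),(1,1,−1),(1,−1,1),(−1,1,1)] with φ_s = (π/2venc)(h_s·v);
the published protocol names the scheme but not the matrix, so any
full-rank balanced realization is equivalent as long as encode and decode
share it.

Velocity decoding is the pseudo-inverse v = (2venc/π)(Hᵀ/4)φ on the raw
segment phases; a common background phase cancels exactly because
Hᵀ1 = 0. Voxels where any pairwise segment-phase difference exceeds π are
flagged as potentially wrapped. The flag is conservative: with
|v|₂ < venc no segment phase wraps (√3·|v| < 2·venc) and decoding is
exact, yet pairwise differences can still exceed π. True unambiguous
decoding for arbitrary component-wise |v| < venc is impossible in
principle when a background phase is unknown (v and v + venc·(1,1,1)
produce identical wrapped phases), which is why the accuracy contract is
stated for velocity magnitudes inside the venc ball.

## Physiological signal extraction

"Physiologically plausible ranges" are fixed at 0.5–3.0 Hz (30–180 bpm)
for cardiac and 0.05–0.7 Hz (3–42 breaths/min) for respiration. Component
selection requires the Welch-PSD peak inside the band to exceed 10x the
median PSD — pure noise fails this and raises an explicit error rather
than returning garbage. ICA polarity is canonicalized before filtering by
comparing the mean second difference at minima vs maxima of the smoothed
component (the trigger convention lives at the minima); the band-pass
(±0.3 Hz around the component's own peak, zero-phase Butterworth) would
otherwise erase the asymmetry that disambiguates the sign.

The respiratory curve is processed per sequence window (split at the
acquisition gap): low-pass at peak + 0.1 Hz with padding extended to ~3
respiratory periods (edge transients on 30 s windows otherwise dominate
the normalization), linear detrend fitted on a central span covering an
integer number of respiratory periods (so the oscillation cannot leak
into the trend estimate), then a residual step removal matching medians
over integer-period windows adjacent to the gap, and finally
normalization to max |r| = 1. The extracted curve's sign and scale are
arbitrary; downstream only the product c·r(t) matters, so the motion fit
absorbs both.

Binning is linear within each RR interval (floor((t−T_k)/(T_{k+1}−T_k)·P),
clipped), with readouts before the first or after the last trigger
discarded and flagged rather than raised.

## Focused-navigation motion correction

The objective is the Shannon entropy (natural log) of the normalized
gradient-magnitude image over a central ROI of half the FOV, computed on
a density-compensated, cardiac-pooled adjoint reconstruction of the
corrected anatomical data — the standard autofocus surrogate: correct
coefficients cancel the motion phase, the pooled image sharpens, entropy
drops. An all-zero gradient returns +inf so degenerate inputs are ordered
deterministically. The optimizer is a derivative-free coordinate search:
per axis a coarse 2 mm grid over ±25 mm followed by golden-section
refinement to 0.1 mm, two sweeps. The coarse grid is re-run every sweep
(locally after the first) because the landscape along one axis changes
once the other axes are corrected; a single initial coarse pass can strand
the refinement in a stale basin 2 mm from the optimum. Only improving
steps are accepted, so the recorded trace is non-increasing by
construction. On the default phantom the fit recovers c to ≈ 0.15 mm.

## Reconstruction

k-t sparse SENSE is solved per sequence (and per encoding segment) over
all cardiac phases jointly: data term ½Σ_p‖E_p x_p − y_p‖², total
variation along the cyclic cardiac dimension (λ_t) and along each spatial
axis (λ_s), TV smoothed as √(|d|² + ε²) with ε = 1e-6. Published weights
are used unchanged: 0.03/0.015 (anatomical) and 0.0075/0.015 (flow),
applied after normalizing each acquisition to the maximum of a pooled
gridded reconstruction. The solver is L-BFGS on the real view of the
complex unknowns (Wolfe line search → monotone objective trace), warm
started by density-compensated conjugate gradients on the weighted normal
equations EᴴWE x = EᴴWy with the |k|-ramp weights W. The warm start
matters: the unweighted data term is ill-conditioned (radial sampling
never observes the Cartesian k-space corners; cond(E) ~ 5·10⁴ on a 16²
test), while EᴴWE ≈ I, so a handful of CG iterations lands near the
least-squares solution and the L-BFGS phase spends its budget on the TV
trade-off. For consistent (well-sampled, noiseless) data the weighted CG
limit *is* the least-squares solution, which is what the λ=0 oracle
equivalence rests on. Density compensation uses the |k| ramp with the k=0
sample capped at half the first nonzero weight (deterministic center
handling). Iterations default to 30 with relative tolerance 1e-5. No
background-phase (eddy-current) correction is applied; none is described
for the original protocol, and the simulation introduces no such phase.

The SyNAPS combination is deliberately trivial — magnitude from the
anatomical reconstruction, velocity from the flow reconstruction, bitwise,
with an explicit error on any phase-count or grid mismatch — because the
method's claim is that synchronization makes this voxel-for-voxel
combination valid.

## Flow quantification

Dynamic segmentation thresholds each phase at τ = 0.6 x the median
intensity of the phase-0 seed component and keeps the connected component
containing the seed, propagated between phases as the previous mask's
centroid. τ = 0.6 (rather than the half-intensity 0.5) keeps
partial-volume rim pixels (< 40% blood fill) out of the mask at 2 mm
voxels, which is what the Dice ≥ 0.9 fidelity against center-based truth
masks requires; on the low-contrast PC magnitude the threshold falls below
the muscle intensity and the component floods — reproducing, by mechanism
rather than by tuning, the in-vivo finding that native PC magnitudes do
not support dynamic vessel tracing. Flow conversion:
Q [mL/s] = 0.01 Σ v[cm/s]·A[mm²]; net volume Σ_p Q_p·RR/P; peak flow
max_p Q_p. Plane normals are oriented so physiologic systolic flow is
positive (+x for AAo, −x for DAo). Flow curves are circularly aligned at
peak systole before agreement statistics (Pearson, regression, Bland-
Altman a−b with 1.96·SD limits, Wilcoxon signed-rank; the Bonferroni
divisor is reported alongside, applied at the reporting layer).

## Desk-scale study conditions

Reconstructions of the published protocol run for hours on server
hardware; this package's validation scale is minutes on one core. The
end-to-end configuration is a 64² single-slice grid (2 mm voxels), 4
coils, 8 cardiac phases, 25 anatomical interleaves (600 readouts) and 40
flow interleaves (840 readouts), with the TR stretched to 50/40 ms so the
reduced spoke counts still span ~36 heartbeats and ~15 breaths — the
physiological sampling regime of the free-running acquisition at 1/80 the
data volume. The schedule *structure* (24 = 6x4; 21 = 1 SI + 5x4) is
never reduced. K-space noise (sd 0.5 a.u. against a k-space center of
~10³) gives a magnitude-image SNR of roughly 20 in the blood pool —
visible noise without burying the PC contrast. SI projections are
generated and stored for format fidelity but consumed by no stage.

Two deliberate measurement-design choices:

* Net volume is validated on the dynamic 8-phase run because bin-averaging
  preserves the time integral of Q(t) exactly, regardless of phase count.
* Peak velocity is validated on a cardiac-frozen peak-systole phantom,
  fully sampled and noiseless: averaging a 35%-of-RR systolic pulse into 8
  bins attenuates its peak by ~10% for *any* correct reconstruction, so a
  binned comparison against the instantaneous programmed v_max would
  measure the binning, not the reconstruction. The frozen-systole test
  isolates encoding + reconstruction + decoding fidelity (≈ 1.7% error).

## What passing tests show — and what they do not

Ground truth here is generated by the same rigid-translation, discrete-
image model the correction and reconstruction assume, so the parameter-
recovery results demonstrate internal correctness and identifiability, not
robustness to non-rigid motion, through-plane motion, relaxation effects,
off-resonance, trajectory errors or flow displacement artifacts — all of
which exist in vivo and are out of scope. In-vivo magnitudes of the
published comparison statistics (Dice ≈ 0.8 against a different modality,
Pearson ≈ 0.7 between modalities) are not reproducible from a phantom;
what the phantom reproduces is their *ordering*: the bright-blood
magnitude supports segmentation and the PC magnitude does not. The
pilot-tone model is a linear mixture chosen for testability; real PT
amplitude modulation is unpublished.

## Known limitations

Rigid translation only (no rotation, no non-rigid correction);
respiratory-resolved (5D) reconstruction not implemented; 3D mode is
exercised at small matrix sizes only; the HDF5 container is
ISMRMRD-inspired but not ISMRMRD-compliant (no public raw data exists to
interoperate with); no DICOM export; no background-phase correction; the
proprietary contouring software used for the in-vivo analyses cannot be
replicated, so segmentation conformance is defined against phantom truth.
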