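# Methods

This note records the model as implemented, the defaults and why they were
chosen, the numerical choices, and what the synthetic test conditions do and
do not demonstrate. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Light transport

The medium is a four-species particle mixture under a per-node majorant
σmaj: absorbing (σa), volumetric-scattering, surface-scattering (together
σs, split by the particle-type probability Pfs + Pρ = 1) and fictitious
"null" particles (σn = σmaj − σt). Free-flight distances are drawn from the
majorant exponential, restarted per traversal segment (distance sampling is
memoryless, so per-segment restarts are exact). Event selection uses the
history-aware weighted probabilities

    p_x = Σ_c w_c σ_x,c / Σ_c w_c σmaj,   x ∈ {a, n, vs, fs},

with per-channel weight updates w_c ← w_c · σ_x,c / (σmaj p_x). In
single-channel mode all σ_x,c are channel-uniform, the weights cancel and
this reduces to the scalar probabilities σa/σmaj, σn/σmaj, Pρσs/σmaj,
Pfsσs/σmaj.

**Where the albedo is applied.** The surface albedo A (per unit area) and
the volumetric single-scattering albedo S multiply the path throughput *at
the scattering event, before* next-event estimation, so NEE weights contain
only the angular density, light radiance and shadow transmittance. This is
forced by consistency between the two channel modes: in spectral
single-path tracking the albedo is unavoidably carried in the per-channel
event weights, so the single-channel estimator must apply it at the same
point for the two configurations to share an expectation. Per-channel
expected survival at a real collision is exactly Pρ·S_c + Pfs·A_c in both
modes.

**σa/σs split.** The transfer functions produce an opacity scale (→ σt =
opacity × density_scale) and albedos, but no explicit scattering fraction.
We set w = max over channels of (S, and A where Pfs > 0), σs = w·σt,
σa = (1 − w)·σt, with volume/surface event multipliers S/w and A/w. This
keeps every event weight ≤ 1 (no throughput amplification) while preserving
the exact per-channel survival above. In multi-channel mode the same medium
is expressed as σ_vs,c = Pρ S_c σt, σ_fs,c = Pfs A_c σt,
σ_a,c = σt − σ_vs,c − σ_fs,c; σt itself stays channel-uniform (the
coefficient schema has no chromatic-extinction field; colour lives in the
albedos in both configurations).

**Environment handling.** Environment radiance is added on escape only for
paths with no prior real scattering event; after a scattering event the
environment contributes exclusively through NEE. Adding both would count
the environment twice. Uniform environments are importance-sampled through
the phase function / PSF (the densities cancel, so each event's
contribution is bounded by throughput × E); lat-long maps use
uniform-sphere sampling with equirectangular bilinear lookup (+y up);
point lights are sampled deterministically with inverse-square falloff.

**Energy conservation** holds at the estimator-mean level: with zero
emission and A, S ≤ 1, the *mean* radiance cannot exceed the environment
radiance, and the suite gates on that (3 SE). A strict per-sample bound is
not attainable for an NEE estimator — a near-boundary event contributes
≈ E and the path may still collect more — so per-sample checks are
finiteness and non-negativity tripwires (non-finite radiance is a hard
error, as is any σt above a stored majorant).

**Self-occlusion.** Shadow-ray transmittance scales σt by a user factor
a ∈ (0, 1] (default 0.8; sensible range 0.75–0.85). Smaller a brightens
shadowed surfaces monotonically (E[T] = e^(−a·τ) is decreasing in a);
camera-path transmittance always uses a = 1. The factor is heuristic
realism tuning and never changes structure.

**BSDFs.** Two families pass through the PSF construction: diffuse
(f = A/π; PSF = cos⁺/π, spherical integral exactly 1, cosine-sampled with
unit weight) and a powered-cosine specular lobe for metal/dielectric kinds
with exponent e = max(1, 2/roughness² − 2). For the lobe the PSF integral
falls below 1; the residual is treated as surface absorption (lobe samples
landing under the horizon terminate the path). The shading normal is −Ĝ:
CT-like data is denser inside structures, so the outward normal is the
negative gradient; the public `eval_psf` keeps the Ĝ·ωo > 0 convention and
the renderer passes G = −∇f into it. Back-side incidence is fully absorbed.

**Particle-type probability.** By default Pfs = min(1, (|G|/g_ref)^γ) with
g_ref the 98th percentile of the gradient-magnitude proxy (computed from
the primary volume when no proxy is loaded) and γ = 1 — strong gradients
shade like surfaces, homogeneous interiors like media. Materials can pin it
(metal/dielectric/highlight → 1, emissive → 0, diffuse → gradient-driven),
and Pfs is forced to 0 wherever |G| vanishes (no normal, no surface event).

**Russian roulette** starts at bounce 3 with survival
clamp(max throughput channel, 0.05, 0.95); max_bounces defaults to 32.

## Transfer-function manager

Opacity maps to extinction via σt = opacity × density_scale
(default 100 per world unit): artistic opacity stays separate from physical
units. Combination semantics:

* *multiply*: opacity, both albedos and emission multiply component-wise
  across bindings; roughness/metallic/phase-g average weighted by each
  binding's opacity; the material identity comes from the highest-priority
  material-form binding (else the first binding). Multiplying emission is a
  choice — a binding that never sets emission leaves the product at the
  other bindings' values only if it sets 1; in practice emissive media use
  priority mode or a single binding.
* *priority*: bindings sorted by descending priority; the first whose
  opacity exceeds 0 supplies the entire coefficient vector (no leakage).

Piecewise intervals are half-open [b_i, b_{i+1}) — a query exactly at a
breakpoint takes the right interval. CCTF queries clamp to the control
range (standard DVR editor behaviour). Unmapped labels of the discrete
forms return the unclassified entry (opacity 0), never an exception.
Control points may specify any subset of coefficients; absent entries
resolve against the binding's material defaults and ultimately the global
defaults (opacity 1, albedos 0.8, roughness 0.3). Material forms never
interpolate identities.

## Accelerator

The octree is complete and stored level-major in a flat array; the node
covering any point at any level is direct arithmetic (row-major cell within
the level plus the level offset). Leaves hold an inclusive voxel range from
proportional splitting (non-power-of-two volumes round; construction errors
if a leaf would cover less than one voxel), dilated by a one-voxel margin so
interpolation near node faces stays inside the leaf's bound.

**Update.** Per leaf, the majorant is the supremum of the
post-classification extinction over the leaf's margin-dilated region: for a
continuous binding, the opacity curve evaluated at the endpoints of the
value interval [vmin, vmax] spanned by the leaf's voxels, plus the curve's
own critical values (CCTF control points; breakpoint levels) strictly
inside the interval. Trilinear interpolation cannot leave that interval and
attains every value in it, so for a single binding this is the exact
supremum — a per-voxel-centre maximum alone would *underbound* σt wherever
a transfer-function peak falls between two adjacent voxel values, which the
majorant-violation tripwire turns into a hard error. Discrete bindings have
no intermediate values and reduce to an exact per-label maximum. Multiple
bindings combine conservatively (product of per-binding suprema in multiply
mode, max in priority mode). Interior nodes take the max of their children,
bottom-up; the update is a few milliseconds at 64³ with leaf level 4, so
interactive transfer-function editing re-runs it per edit.

**Traversal** advances per-level with ray/cell exits (slab method; exit
advanced by 1e-5 of the cell edge to avoid re-entry) and applies, per
probed node: (1) invalid → climb to the highest invalid ancestor whose
parent is valid and skip its whole box; (2) max < hd → climb, unless the
parent's max exceeds hu; max > hu → descend toward the leaves; (3)
otherwise (or at root/leaf) emit the node as a sampling segment carrying
its own majorant, then continue at the same level. hd = 0.2 / hu = 0.6 are
interpreted as fractions of the root's max extinction by default
(`normalized_thresholds=False` switches to absolute units). A
`global_majorant` flag collapses traversal to one root-majorant segment —
delta tracking is unbiased under any valid majorant, which the suite
verifies by comparing mean images.

## Synthetic phantoms

Three families over [-0.5, 0.5]³, each yielding a continuous primary, its
gradient-magnitude proxy and a discrete mask: `nested_shells` (three
concentric smooth-stepped shells; mimics layered anatomy and gives an
analytic inner-sphere volume for oracle checks), `gaussian_blobs` (random
soft masses with an argmax-label mask), `engine_like_block` (a housing with
two denser bores; industrial-CT-like straight edges). A low-amplitude
band-limited cosine texture keeps gradients non-degenerate. Generation is a
pure function of (spec, seed) via counter-based Philox streams.

What they do not emulate: acquisition noise, partial-volume and beam-
hardening artifacts, anisotropic spacing, 12/16-bit integer quantization,
and anatomical complexity. Tests passing on phantoms therefore validate the
*estimators and data structures* (unbiasedness, majorant soundness,
determinism, channel-mode equivalence), not clinical image quality.

## Numerical choices and test conditions

* Voxel (i,j,k) is centred at origin + (i,j,k)·spacing; the support box is
  [origin − spacing/2, origin + (dims − 1/2)·spacing]. Outside-support
  queries return 0 (or label 0): the renderer clips rays to the bound, so
  this path is rare by construction.
* Gradients: central differences with a one-voxel step, degrading to
  one-sided within half a voxel of the boundary (stencil points clamp onto
  the support).
* RNG: splitmix64 streams keyed by (seed, pixel, sample); renders are
  bit-reproducible for fixed seeds regardless of execution order, and
  accumulating sample ranges [0, N) + [N, 2N) reproduces a 2N-sample render
  exactly. Library-level samplers take numpy Generators.
* Default problem sizes in the suite: 32³ phantoms for oracle equivalence,
  32×32 at 64 spp for estimator-consistency renders, 10⁵ replicates for
  transmittance means, 10⁶ samples for spherical integrals — sizes at which
  the 3-standard-error gates are decisive while the whole suite stays quick
  on one core.
* Statistical gates use 3 standard errors computed from the same run
  (per-pixel sample variances for renders); exact contracts (determinism,
  label sets, probability sums, σ decompositions) are asserted exactly.

## Known limitations

* No refraction (the transport is non-refractive), no denoising, no
  photon-map/VPL approximations; images at low spp are noisy by design.
* Lat-long environment sampling is uniform-sphere (high variance for
  concentrated maps); importance sampling the map is future work.
* The multiply-mode majorant (product of per-binding suprema) is an upper
  bound, not a supremum; heavily multiplicative managers trade some
  traversal efficiency, never correctness.
* Per-channel extinction tints are expressible only through albedo, not
  through a chromatic σt field.
* The CPU path is numba-compiled and single-threaded; first use in a fresh
  environment pays a one-time JIT cost.
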