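# Methods

`kdnatools` quantifies the internal organisation and mechanics of
kinetoplast DNA (kDNA) — the chainmail-like network of thousands of
catenated DNA circles in trypanosomatid mitochondria — along two
complementary routes: image/tracking analysis of quantum-dot (QD) labelled
sequences, and coarse-grained simulation of catenated-ring ("Olympic")
networks. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data do and do not establish.

## Radial enrichment statistic

A kDNA network imaged in fluorescence is segmented from the DNA-stain
channel by Gaussian smoothing (default σ = 2 px), Otsu thresholding, and
keeping the largest connected component with holes filled. Otsu is used
because it is parameter-free and reproducible; `yen`, `mean` and `triangle`
are available where staining is very uneven. The boundary is the set of
foreground pixels with a 4-neighbour background pixel (mask minus its
4-connected erosion): this gives a thin 8-connected ring whose pixel count
tracks the digital perimeter, and it is the set against which all distances
are measured.

Each QD localisation inside the mask contributes its Euclidean distance r
to the nearest boundary pixel, normalised by r0, the maximum distance of
any boundary pixel from the mask centroid — so r/r0 = 0 at the rim and ≈ 1
at the centre. The binary (not intensity-weighted) centroid is used for
robustness to uneven staining. For non-convex masks r/r0 can marginally
exceed 1; such values are clipped into the last bin with a warning.

The null model is random deposition: uniformly chosen foreground pixels
plus uniform sub-pixel jitter, by default 100× the observed spot count,
passed through the identical distance metric. The enrichment profile is the
per-bin ratio of the two unit-mass histograms on r/r0 ∈ [0, 1] (default 10
bins, matching the granularity at which peripheral effects are typically
reported); bins with zero null mass are reported as NaN rather than
infinite. Profiles from several networks are aggregated as the per-bin mean
± SD of the per-network ratios.

Pixelation bias: distances are measured to boundary pixel centres, so area
fractions derived from the profile carry an O(1 px / r0) bias; for the
~30 px-radius structures of the default synthetic geometry this is a few
percent, and the test suite checks area-law predictions on finer grids
where the bias is negligible.

## Tracking statistics and equipartition stiffness

Spots are linked frame-to-frame by optimal (Hungarian) nearest-neighbour
assignment with a hard displacement cap (default 5 px/frame equivalent) and
gap closing across up to 3 missing frames, chosen for QD blinking at 8 fps.
The structure's centre of mass (COM) is tracked by segmenting every frame
of the DNA channel; unsegmentable frames are interpolated.

Two MSD observables are computed with overlapping time origins (variance
reduction; origins are correlated but the estimator is unbiased):

* `g2(t)` — the MSD of each label's position *relative to the COM*,
  averaged over origins and labels. It removes rigid translation but not
  rotation.
* `dMSD(t)` — the MSD of the pair separation vector d_ij = r_i − r_j,
  averaged over origins and pairs, optionally normalised per pair by ⟨d⟩².
  It is exactly invariant under any rigid-body motion, which the tests
  assert to machine precision.

Power-law exponents are least-squares slopes on log10–log10 within a stated
window (default 0.125–2 s at 8 fps, i.e. the shortest decade available);
the fit refuses windows with fewer than 4 lags or non-positive values. The
long-time plateau is the mean of g2 over lags beyond t_min (default 10 s)
with a reliability guard: if the residual log-log slope in the window
exceeds 0.1 the curve is still rising (e.g. free diffusion) and the plateau
is flagged unreliable.

Stiffness follows from equipartition, κ = 2 k_B T / ⟨fluctuation²⟩, with
the fluctuation either the g2 plateau (μm²) or the squared mean per-pair
distance SD σ⟨d⟩². Temperature defaults to 298 K (k_B T = 4.11 × 10⁻³
pN·μm). Note the convention: applied to a 2D harmonic trap of per-axis
stiffness k, whose g2 plateau is 4 k_B T/k, this definition returns κ =
k/2 — κ is an *effective 2D network stiffness*, not a per-axis spring
constant, and the recovery tests are written against the analytic plateau.

## Synthetic data generator

No raw imaging data ships with the package; every estimator is tested
against generated data with known ground truth.

* **Images.** The DNA channel is a filled ellipse (default diameter 4 μm,
  axis ratio 0.85, 70 nm pixels — the imaged networks are ~4 μm across)
  with a brighter soft rim, since real kDNA shows an intense outer ring.
  The QD channel renders point emitters under a Gaussian PSF (σ = 1.5 px)
  with Poisson noise on both channels. Emitters follow a radial placement
  law on r/r0 — uniform, peripheral(p_outer, shell_fraction), or central —
  applied at pixel resolution (membership decided by the pixel centre, then
  jittered within the pixel).
* **Confined motion.** Overdamped Ornstein–Uhlenbeck springs with per-axis
  stiffness κ and drag γ (default 0.02 pN·s/μm), discretised exactly, so
  the stationary variance k_B T/κ and correlation time γ/κ are closed-form
  targets; κ = 0 gives free diffusion with D = k_B T/γ. An optional common
  drift checks COM-frame invariance.
* **Subdiffusion.** Fractional Brownian motion per axis via exact
  Davies–Harte circulant embedding with Hurst index α/2, so the ensemble
  MSD is a pure power law t^α.
* **Blinking.** i.i.d. per-frame removal of localisations with the
  ground-truth identity retained for scoring the linker.

These generators share the statistical structure the estimators assume but
not the physics of real kDNA: no photobleaching, no z-drift, no
rotation of the structure, Gaussian (not Airyscan) PSF, and OU/fBm rather
than true network dynamics. Passing tests therefore establish estimator
correctness, not that real kDNA follows these models. Acquisition-shaped
defaults (70 nm pixels, 8 fps, ≥500 frames) are used throughout; SNR and
emitter counts are plausible choices, not measured values.

## Olympic network construction

Minicircle-only (MO) networks are honeycomb patches: ring centres on a
valence-3 lattice (interior nodes have exactly 3 neighbours), the patch
taken as the n nearest nodes to the lattice centre. Each minicircle is a
circle of radius 0.6·spacing with an out-of-plane modulation z =
±h·cos(3θ) (h = 0.2·spacing), the sign alternating between the two
honeycomb sublattices. At each of the six rim crossings with its three
neighbours the modulation places the two strands on opposite sides of the
plane, so every lattice edge is a Hopf link. Chirality is randomised by
drawing each ring's traversal orientation; because reversing a ring's
orientation flips the sign of all its links at once, per-edge signs are
random but correlated within a ring — an unavoidable property of any fixed
geometric embedding. The recorded chirality of an edge is its *realised*
Gauss linking number, verified numerically at build time; `verify="full"`
additionally scans all geometrically-possible pairs for spurious
catenations. The default spacing (≈12.5σ for 60-bead rings) gives an
initial bond length of ~0.95σ.

Maxicircles are closed waypoint curves that travel above (+z0) and below
(−z0) the disk and cross its plane only through the holes of the
minicircles they thread, alternating dive direction so the curve closes;
this makes every intended maxi–mini link a clean ±1 and provably creates no
others. Linked-border (LB) threads the boundary cycle of the patch;
linked-diffuse (LD) threads an even-sized uniform sample of all
minicircles, ordered by angle to keep the loop simple. Mutual maxi–maxi
linking is guaranteed by wrap clasps in a rendezvous region outside the
disk, added only for pairs whose discretised loops are not already linked
by their interior dives (in LD the dives alone often link the loops, with
|Lk| occasionally > 1 — "interlinked between themselves" without a fixed
multiplicity). All realised linking numbers are verified; failed
constructions retry with a fresh seed.

The Gauss linking number of two closed polylines is the exact
Klenin–Langowski segment-pair double sum (numba-compiled), rounded to the
nearest integer with tolerance 0.2; near-degenerate geometries are
resampled at double resolution and retried before erroring.

Slit compression runs the Langevin engine with harmonic walls whose gap
narrows in stages to the target, then re-verifies every intended link.

## Langevin engine

Kremer–Grest bead-spring model in reduced units: FENE bonds (K = 30 ε/σ²,
R0 = 1.5σ — the standard constants for this model class, which the source
protocol references but does not print), WCA repulsion between all pairs
(ε = 1, cutoff 2^{1/6}σ), and a cosine bending potential U = κ_bend(1 +
cos θ). FENE + WCA together prevent strand crossing, so catenation topology
is conserved by construction; the tests verify the full linking matrix
across a 10⁶-step run. The bending constant is calibrated to the model's
defining property, a persistence length of 4σ: for the discrete
Kratky–Porod chain ⟨cos φ⟩ = coth(κ/T) − T/κ and l_p = −b/ln⟨cos φ⟩, so the
continuum identification κ_bend = l_p·k_BT/σ = 4ε actually yields
l_p ≈ 3.4σ; inverting the discrete relation gives the default
κ_bend = 4.661ε (`bend_constant_for_lp`), and the measured
tangent-correlation decay of an isolated ring then sits at 4σ.

Integration is Grønbech-Jensen–Farago velocity-Verlet Langevin with γ =
0.1/τ_LJ, dt = 0.01 τ_LJ, bead mass 1. Gaussian noise comes from an
in-kernel xorshift64* generator with Box–Muller (numpy's generator is not
available inside the compiled loop at the required throughput); moments and
bitwise reproducibility are tested. Kinetic temperature is reported from
the half-step (2GJ) velocity statistic, which is exact at finite dt,
whereas the on-site velocity underestimates T by ~1.5% at these settings.
Pair interactions use a cell list with a 0.4σ skin rebuilt on a
half-skin displacement criterion. Freshly built networks are first relaxed
by capped-displacement (0.05σ) steepest descent to remove construction
overlaps without threading changes.

Equilibration is diagnosed on the radius-of-gyration series: pass requires
≥95% of samples within 2 SD of the mean and no drift (|slope| × duration ≤
0.5 SD). Desk-scale protocols default to 5×10⁶ steps; the matched
MO-versus-LB comparison in the test suite uses 48-ring disks with 10⁵
equilibration and 1.5×10⁵ production steps (dumps every 2×10³) — the
burn-in is deliberately longer than production because shorter burn-ins
leave a visible relaxation transient in the Rg trend diagnostic. At this scale
the networks are not fully equilibrated — the comparison probes the
qualitative ordering of curvature and ring mobility under identical
protocols, not converged equilibrium averages. The complementary check that
the minicircle-only disk is flat on time average uses the longer 10⁶-step
run instead, because a zero-consistency test needs far more effective
samples than an ordering comparison; full-scale runs (604 rings,
10⁸ + 1.5×10⁹ steps) are cluster-scale and supported only through the
LAMMPS data-file export.

## Curvature analysis

Each frame's minicircle centres of mass are projected onto their best-fit
plane (total least squares), Delaunay-triangulated in 2D and lifted.
Per-frame re-triangulation tolerates in-plane rearrangement; orientation is
kept continuous by flipping each frame's plane normal to match the
previous frame's. Mean curvature uses the cotangent-Laplacian
mean-curvature normal with Meyer mixed-Voronoi areas; the sign is the dot
product with the (area-weighted) vertex normal, so H̄ > 0 means bowing
toward the reference normal. Boundary vertices are excluded from all
averages — discrete curvature operators are unreliable on the boundary —
and the surface average is mixed-area-weighted over interior vertices.
Because only |H̄| is physically comparable across runs (the buckling
direction is spontaneous), the summary reports both |⟨H̄⟩| and ⟨|H̄|⟩,
plus the sign-flip count; the standard error of the time average uses a
moving-block bootstrap whose block length is set from the series' own
integrated autocorrelation time (max(√n, 3τ_int)) — fixed-√n blocks
underestimate the error of slowly decorrelating shape modes.
Oracles: H = 1/R on a sphere, H̄ = 0 on a plane, H = 0 with K < 0 at a
saddle point, exact mirror antisymmetry, and monotone refinement
convergence.

## Known limitations

* The enrichment statistic is 2D (single slice or max projection); axial
  structure is ignored.
* g2 removes translation only; rotation of a real network inflates its
  plateau. dMSD is the rotation-proof alternative and both are reported.
* The OU/fBm generators have closed-form targets but are not models of
  entangled-network dynamics; recovery tests validate estimators, nothing
  more.
* Scaled-down simulations cannot reproduce full-scale exponents or
  absolute curvatures; only ordering statements are tested.
* The curvature units are 1/σ with no physical mapping (the σ→nm scale of
  the coarse-grained model is not fixed by anything in the package).
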