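# Methods

`protonpath` implements the analysis chain used to characterize
hydration-coupled proton transfer (PT) through a water-containing protein
channel — the setting is the E-channel of respiratory Complex I, where a
weakly hydrated segment between two acidic residues gates the proton's
passage — and a synthetic collective-variable-space sampler that lets the
entire chain run, and be validated against known ground truth, without any
external simulation engine.  Units are fixed throughout: lengths in
Angstrom, energies in kcal/mol, temperatures in Kelvin.

## Pathway construction (`path_geometry`)

The PT pathway is a smooth curve through the channel's water density,
represented as N ordered, arc-length-equidistant nodes (default N = 25).
It is fitted as a principal curve in the Hastie–Stuetzle style: starting
from the first principal axis of the water-oxygen cloud, the algorithm
alternates (i) projection of every point onto the current polyline
(ties between segments break toward the lower segment index, for
determinism) and (ii) local-linear kernel smoothing of the point
coordinates against the projected arc length, evaluated at the node arc
positions, followed by equidistant resampling.  Local-*linear* (rather
than Nadaraya–Watson) smoothing is used because it is free of boundary
bias: a cloud lying exactly on a straight segment reproduces that segment
including its endpoints, so node spacing is exact in that limit.  The
kernel bandwidth is `smoothing` × total arc length (default 0.1);
iteration stops when the mean node displacement falls below `tol`
(default 1e-4 Å) or after `max_iter` sweeps.

Equidistance is defined on arc length along the polyline — nodes sit at
k·L/(N−1) — which the resampler satisfies exactly by construction.  Node
frame metadata (`origin_index`, `orientation`) is user-supplied, not
inferred: which residue anchors progress zero and which channel end is
"positive" is a modelling statement about the system, not a geometric
property of the cloud.

## Collective variables (`colvars`)

**Node occupancy.** The occupancy of node *i* is a sum of rational
switching functions over water oxygens,
σ(r) = (1 − (r/r₀)ⁿ)/(1 − (r/r₀)ᵐ) with defaults n = 6, m = 12,
r₀ = 2.5 Å (σ(0) = 1, σ(r₀) = n/m, long-range decay (r/r₀)^(n−m)),
capped at 1.  The default cap is the hard `min(1, ·)`; a smooth soft-min
cap `s − ln(1 + e^{k(s−1)})/k` (k = 20) is available via `cap="soft"` for
uses that need differentiability through the cap.  The hard cap keeps the
identity "one water exactly at the node ⇒ occupancy 1" exact.  When a
frame carries an orthorhombic box, water–node distances use the
minimum-image convention; otherwise they are plain Euclidean.

**Water-wire connectivity.** Adjacent node pairs are scored by their mean
occupancy f_{i,i+1} = (o_i + o_{i+1})/2 and the connectivity is their
geometric mean,

    phi = ( prod_{i=1}^{N-1} f_{i,i+1} )^{1/(N-1)},

computed in log space; a single dry pair sends phi to zero, which is what
makes phi sharply sensitive to the few bridging waters of a weakly
hydrated gap where a mean-occupancy descriptor would barely move.  The
proton-localized variant phi* replaces the uniform geometric mean with a
weighted one, weighting pair *i* by a Gaussian in the distance d_i from
the excess-charge probe to the pair midpoint, w_i = exp(−d_i²/2σ_loc²)
(default σ_loc = 3 Å).  phi* → phi as σ_loc → ∞ (verified to 1e-6); a
probe whose largest weight underflows (below 1e-12) is reported as
off-path rather than silently renormalized.

**Path progress.** With i₁ the node closest to the probe, i₂ the adjacent
node nearer the probe (at a terminus, the only neighbor), v₁ and v₂ the
vectors from the probe to nodes i₁ and i₂, and v₃ the vector from node i₁
to node i₂, the continuous node index is

    xi' = i2 − sign(i2 − i1) · sqrt(D) / |v3|²,
    D   = (v1·v3)² − |v3|² (|v1|² − |v2|²).

With this vector convention D = |v₃|⁴(1 − t)² on a straight path, where t
is the fractional progress from i₁ toward i₂, so xi' reduces exactly to
the signed arc-length projection in node-spacing units; the discriminant
form keeps the estimate well-behaved on curved paths, where it coincides
with the standard adaptive path-CV construction restricted to adjacent
nodes.  Restricting i₂ to a neighbor of i₁ (rather than the globally
second-closest node, which on a strongly curved path may not be adjacent)
guarantees continuity of xi' as the probe crosses node mid-planes; D is
clamped at zero against round-off at exact node hits.  The rescaled form
xi* = (xi' − origin_index) · spacing · orientation is numerically
comparable to Å of arc length, zero at the origin node.

## Synthetic sampling (`sampling`)

**Model surface.** The coupled landscape is

    F(xi, phi) = g(u) + kappa_phi (phi − phi_min(u))²,
    u = (xi − xi_R)/(xi_P − xi_R),

with g(u) = 16a·u²(1−u)² + ΔG·u²(3−2u), whose interior maximum sits at
the closed-form u_s = 1/2 + 3ΔG/32a; the amplitude a is calibrated by
root-finding so that g(u_s) equals the requested barrier ΔF‡ exactly.
phi_min(u) is the quadratic through (0, φ_R), (u_s, φ_S), (1, φ_P).
Because ∂F/∂phi vanishes exactly on the valley floor, the surface's
stationary points sit at the requested locations with the requested free
energies — reactant (xi_R, φ_R) at 0, saddle (xi_s, φ_S) at ΔF‡, product
(xi_P, φ_P) at ΔG — making the surface an analytic oracle for every
downstream stage.  The `e_channel` preset places the reactant minimum at
(0, 0.75), the saddle near (5.6, 0.92) and an endergonic product at
(10, 0.85) with ΔF‡ = 6 and ΔG = 3 kcal/mol: a desk-scale landscape with
the same topology and hydration-coupling signature as the channel's PT
surface (hydration rises toward the transition state), scaled down so
that converged sampling takes seconds rather than CPU-years.  κ_phi
defaults to 60 kcal/mol per φ², giving thermal hydration fluctuations of
about 0.07 at 310 K.

**Dynamics.** Overdamped Langevin (Euler–Maruyama),
x ← x − (∇F)Δt/γ + √(2k_BT Δt/γ)·η, with Δt = 2×10⁻⁵ reduced time.  The
step-size criterion is the stiffest restraint (κ = 2500 kcal/mol per φ²):
κΔt/γ = 0.05 biases the stationary variance of that mode by ≈2.6%, well
inside every tolerance used here.  `friction` may be per-CV: the
stationary distribution is γ-independent, so a small γ on the softly
restrained, slowly relaxing xi mode (0.05 vs 1.0 for phi in the umbrella
presets) shortens its correlation time ~20-fold without touching any
equilibrium average — the synthetic analogue of choosing a well-mixing
thermostat.  phi reflects at [0, 1] (it is bounded by construction); xi
has an error guard half a basin-separation beyond each minimum, so a
diverging trajectory fails loudly with the offending step number.

**Umbrella protocol.** The 1D preset is 24 windows along xi*; the 2D
preset is 130 windows with the strong hydration restraint
(2500 kcal/mol per φ²) and 10 kcal/mol (the soft end of the 10–30 range)
on xi*.  With κ_phi = 2500 a window confines phi* to a band of width
~0.016, so a regular rectangular grid would spend most of its windows on
hydration states tens of kT uphill and leave the phi rows mutually
disconnected; the 130 windows are instead laid out as 26 xi columns × 5
phi rows centered on the valley floor phi_min(xi) at offsets of 0.033,
tiling the corridor the MFEP can actually explore.  Columns are ordered
along xi with serpentine phi ordering, so each window is initialized from
the final configuration of an adjacent one ("dragging" the system along
the path); production then runs all windows as one batched integration.

**Metadynamics.** Multiple walkers step synchronously; every `pace` steps
each walker deposits a Gaussian hill with the well-tempered height
w₀·exp(−V(s)/((γ−1)k_BT)) evaluated from the bias it currently sees, and
the shared bias (held on a grid with analytically accumulated value and
gradient, queried by (bi)linear interpolation) is refreshed every
`share_interval` steps — mirroring walkers that re-read a shared hills
file.  With the published protocol (pace 1000 > share 100) a deposited
hill is stale for at most one refresh interval.  γ = ∞ reduces the
heights to constant w₀ (standard metadynamics).

**Hydration frames.** `generate_hydration_frames` places waters uniformly
along a straight channel with lateral Gaussian jitter and relocates each
water that falls inside a declared gap with probability
1 − gap_occupancy_factor, thinning the gap without changing the water
count; the default gap width of 4.5 Å mirrors the weakly hydrated
separation between the channel's two acidic residues.  The excess-charge
probe sits on the axis at a chosen arc position.  All generators are
bit-reproducible given (seed, config).

## Free-energy estimation (`free_energy`)

**WHAM.** Standard discrete WHAM on half-open bins [lo, hi), bias
evaluated at bin centers: the self-consistent equations for the window
offsets f_k and unbiased bin probabilities are iterated to
max|Δf_k| < 1e-7 kcal/mol.  Because those equations are the stationarity
conditions of a convex objective, the solver first runs a quasi-Newton
(L-BFGS) descent on that objective and then polishes with direct
iteration to the requested fixed-point tolerance — orders of magnitude
faster than plain iteration for a hundred stiff windows, and verified
against a brute-force plain-loop iteration to 1e-8 on small instances.
Unsampled bins are masked, never interpolated or zero-filled.  Before
solving, the windows' sampled-bin sets must form a single connected
component of the pairwise-overlap graph (otherwise the relative offsets
of the components are undetermined and the run fails naming the split);
a window sharing fewer than 10 counts with every other window triggers a
warning.  Bin widths should keep the bias variation across one bin well
under k_BT — for the κ = 2500 hydration restraint this means phi bins of
~0.006, which the presets use.  Statistical-inefficiency weighting is
deliberately absent; convergence is judged by block averaging instead.

**Block averaging.** Every window's series is split into `n_blocks` equal
time blocks (defaults 8 for the 2D protocol, 6 for 1D), WHAM runs per
block, and the PMF is the bin-wise mean of the last `keep_last` blocks
(4 and 3 respectively) after aligning the blocks' arbitrary additive
constants on their common sampled bins; the spread across retained blocks
gives the per-bin standard error.  Early blocks, which still carry the
relaxation transient of the dragged initialization, are thereby
discarded.

**Metadynamics inversion.** F(s) = −(γ/(γ−1))·V(s) on a grid, where V is
the sum of deposited Gaussians; γ = ∞ gives F = −V.  With a large bias
factor the hill heights decay slowly and the instantaneous V oscillates
around the converged profile by roughly one hill height, so V is averaged
over the final fraction of the deposition history (default: the last
half, computed in one pass as a per-hill weighted sum).  This is still a
pure bias-inversion estimate — no time-dependent reweighting is
performed.  Walker logs merge into a single time-ordered log with a
stable tie-break on walker id, so the result is independent of input
order.

## MFEP and rates (`mfep_rates`)

The minimum free energy path between two basins is defined by the min–max
(lowest highest point / watershed) criterion, tie-broken by the minimal
path integral of F, and computed exactly on the 8-connected graph of
sampled bins by a Dijkstra-style sweep with lexicographic cost — a
deterministic, globally optimal alternative to string-method local
optimization, verified against an exhaustive threshold-connectivity
oracle on small grids.  Masked bins are never crossed.  The reported path
coordinates are smoothed by a width-3 moving average; barrier and ΔG are
read from the raw bin values.  Projection onto xi* takes the per-bin
minimum of F where the path doubles back in xi*, preserving the barrier a
reader would take from the projected plot.

Rates use the Eyring/transition-state expression
k = (k_BT/h)·exp(−ΔF‡/RT) with CODATA-2018 constants pinned in one table
(R = 1.987204×10⁻³ kcal/(mol·K); k_BT/h = 6.459×10¹² s⁻¹ at 310 K); the
forward/reverse rate ratio equals exp(−ΔG/RT) identically.  Energy
conversions (meV, eV, kcal/mol, kJ/mol, k_BT) go through the same table
(1 eV = 23.060548 kcal/mol).  No transmission coefficients or
friction-dependent (Kramers/Grote–Hynes) corrections are applied: these
rates are order-of-magnitude TST estimates by design.

## What the synthetic generators do and do not establish

The samplers emulate the statistics of biased CV-space exploration —
harmonically restrained windows with realistic relaxation-time
separation between a stiff and a soft CV, well-tempered hill deposition
with shared multiple walkers, hydration frames with a tunable dry gap —
and they reproduce the published protocol constants (310 K; 130/24
windows; force constants 2500 and 10–30 kcal/mol; hills of 0.6 kcal/mol,
σ = 0.02, γ = 35, pace 1000, 8 walkers sharing every 100 steps; 8/4 and
6/3 block averaging).  They do not emulate a reactive Hamiltonian, real
water exchange kinetics, protein conformational gating, or the true
magnitudes of the channel's barriers: passing tests demonstrate that the
estimators recover known landscapes from realistic biased statistics at
desk scale (barriers of 4–6 kcal/mol, 10⁵–10⁶ steps), not that the
published barrier heights themselves are reproduced — those require the
reactive MD engine this package deliberately post-processes rather than
replaces.

## Problem sizes and numerical defaults

The shipped analyses use: 130 windows × 2×10⁵ Langevin steps (recorded
every 5) for the 2D pipeline on a 96 × 70 grid; 8 walkers × 10⁶ steps for
metadynamics on an 801-point bias grid read out on 50 output bins;
exact-sampling WHAM checks with 12 windows × 4000 draws; 1000-profile
randomized property checks for the connectivity identities.  WHAM
tolerance 1e-7 kcal/mol on the window offsets; principal-curve tolerance
1e-4 Å; discriminant clamping at 0; equal-distance tie-breaks always to
the lower index.  Degenerate inputs (coincident point clouds, zero-length
polylines, empty hill logs, non-overlapping windows, probes off the path)
raise errors naming the defect rather than returning silently degraded
results.

## Known limitations

- The occupancy switching function and the phi* weighting are explicit
  config rather than a single canonical definition; results are reported
  with their parameters.
- 2D umbrella coverage follows the hydration corridor; free energies far
  off the valley floor are masked, and the MFEP cannot leave the sampled
  region (by design — no invented free energies).
- Metadynamics free energies come from bias inversion; histogram
  reweighting is out of scope.
- Grids are limited to 1D/2D; no MBAR generalization; block averaging is
  the only error model.
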