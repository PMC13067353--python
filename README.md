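# protonpath

Analysis tools for **hydration-coupled proton transfer through protein
channels**, built around the water wires of the respiratory Complex I
E-channel: a weakly hydrated stretch between two acidic residues that a
proton can only cross when the intervening water network transiently
connects.  The package is for computational biophysicists who have (or
simulate) biased trajectories in collective-variable space and want the
full chain from raw coordinates to a rate estimate:

* **Pathway construction** — a principal curve fitted through the
  channel's water-oxygen positions, resampled to N equidistant nodes
  (default 25).
* **Collective variables** — per-node water occupancies from a rational
  switching function; the water-wire connectivity

  φ = ( ∏ᵢ f_{i,i+1} )^{1/(N−1)},  f_{i,i+1} = (oᵢ + oᵢ₊₁)/2,

  its proton-localized variant φ* (pairs Gaussian-weighted by distance
  from the excess-charge probe), and the continuous path-progress CV ξ*
  locating the probe along the nodes in Å-comparable units.
* **Free-energy reconstruction** — umbrella sampling combined by
  self-consistent WHAM (1D/2D) with block-averaged convergence control,
  and multiple-walker well-tempered metadynamics inverted via
  F(s) = −(γ/(γ−1))·V(s).
* **Minimum free energy paths and rates** — the exact min–max (lowest
  saddle) path through a 2D PMF, its projection onto ξ*, barrier ΔF‡ and
  reaction free energy ΔG, and Eyring rates k = (k_BT/h)·e^(−ΔF‡/RT).
* **A synthetic sampler** — overdamped Langevin dynamics on a closed-form
  coupled (ξ*, φ*) surface with exactly placed minima and saddle, plus a
  hydration-frame generator with a tunable dry gap, so every stage runs
  and is validated against analytic ground truth with no external data.

## Worked example

`examples/04_mfep_and_rates.py` evaluates the coupled model surface on a
grid, extracts the MFEP and converts barriers to rates:

```text
MFEP barrier dF* = 6.00 kcal/mol, dG = 3.00
saddle at xi* = 5.65, phi* = 0.92 (hydration peaks at the transition state)
Eyring rate at 310 K: 3.81e+08 1/s (prefactor kBT/h = 6.46e+12 1/s)

published-style numbers, recomputed:
  22 kcal/mol barrier  -> k = 0.002 1/s
  17.1 kcal/mol barrier-> k = 5.69 1/s
  800 meV              -> 18.45 kcal/mol
```

The first block is the desk-scale model landscape: the path's highest
point sits at elevated hydration (φ* = 0.92 vs 0.75 in the reactant
basin) — proton progress and wetting are coupled, and the barrier read
off the projected profile feeds the Eyring expression.  The second block
re-evaluates reference numbers for the real channel: a 22 kcal/mol
barrier (proton transfer in a poorly hydrated channel) corresponds to
one event every ~8 minutes, and the 800 meV quinone redox energy is
18.45 kcal/mol on the same scale.

The other examples cover path fitting + connectivity scoring
(`01_path_and_connectivity.py`), the 24-window umbrella/WHAM protocol
with 6/3 block averaging (`02_umbrella_wham.py`) and shared-walker
well-tempered metadynamics (`03_metadynamics.py`).  A thin CLI wraps the
same library:

```bash
protonpath rate --barrier 22 --temperature 310
protonpath demo --seed 1          # full umbrella→WHAM→MFEP→rate pipeline
```

File formats are plain text throughout: minimal PDB / XYZ frames,
COLVAR- and HILLS-style tables with `#`-prefixed headers, and a
round-trippable free-energy grid format.  See `docs/methods.md` for the
model definitions, estimator details and numerical choices.

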