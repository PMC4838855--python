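# Methods

## Scope and assumptions

polymsm estimates discrete-state Markov models from pooled trajectory
swarms and extracts metastable structure, equilibrium thermodynamics,
kinetics with bootstrap uncertainty, and transition-path-theory (TPT)
mechanism decompositions. The core assumptions are the usual MSM ones:
the discretized dynamics are approximately Markovian at the chosen lag
time (checked via implied-timescale plateaus and residence-probability
self-consistency), the pooled trajectories sample every microstate
transition of interest (enforced by trimming to the largest strongly
connected set), and equilibrium properties are meaningful because the
estimator satisfies detailed balance by construction.

All quantitative kinetics are computed at the microstate level and only
*reported* per macrostate; the lumped (macrostate) chain itself is never
propagated, because a coarse-grained chain of a weakly metastable system
is generally not Markovian at the same lag.

## Estimators and numerical choices

* **Counting.** Sliding-window counts at lag L frames (every pair
  `(s_t, s_{t+L})`) are the default; strided counting is available.
  Sliding counting treats the pool as one estimate and matches how large
  swarm datasets are normally used.
* **Trimming.** The largest strongly connected component of the directed
  count graph is kept (ties: larger total counts, then lower state
  index); the kept-state mapping is preserved in every artifact.
* **Transition matrix.** Default estimator symmetrizes counts,
  `C' = (C + Cᵀ)/2`, then row-normalizes. This guarantees reversibility
  (real spectrum, required by PCCA+) and makes the stationary
  distribution equal to the normalized symmetrized row sums. The plain
  row-normalized non-reversible estimator is available for sensitivity
  checks; both are exposed because the convention differs between
  historical MSM packages.
* **Spectral decomposition.** For reversible models, eigenpairs come
  from the symmetrized matrix `diag(√π) T diag(1/√π)` via `eigh`, giving
  π-orthonormal left/right eigenvectors. Implied timescales
  `t_k = −τ/ln λ_{k+1}`; complex or non-positive eigenvalues yield NaN
  entries that are reported, never interpolated — they are the
  diagnostic for non-Markovian lags.
* **PCCA+.** Inner-simplex variant: find m extreme rows of the top-m
  right-eigenvector matrix, invert the vertex matrix, clip memberships to
  [0, 1] and renormalize rows. Vertex candidates are restricted to
  microstates with stationary weight ≥ 0.1/n: greedy farthest-point
  clustering deliberately places centers on outlier frames, and such
  near-empty microstates otherwise capture simplex vertices and produce
  degenerate macrostates. A degenerate eigenvalue pair at the cut
  (|λ_m − λ_{m+1}| < 1e-10) is rejected with advice to change m.
  Macrostates are relabeled S1…Sm along a pathway coordinate (the
  well-polyline progression for landscape data; the state index for
  chain data) so labels are reproducible.
* **MFPT.** Linear solve of `(I − T_rest) m = τ·1`; macrostate MFPTs are
  stationary-weighted averages over the source macrostate (uniform
  weighting available). The defining residual and Kac's formula
  (mean return time `= τ/π_i`) are verified in tests to 1e-9 and 1e-8.
* **Bootstrap.** Whole trajectories are resampled with replacement
  (replicate size = original trajectory count), per-trajectory count
  matrices are precomputed once and summed per replicate, and the
  *lumping is frozen* from the full-data model so replicate labels cannot
  switch. Replicates that lose ergodic connection to a macrostate are
  excluded and counted, not patched. Reported as mean ± SD (ddof = 1).
* **TPT.** Committors by direct linear solve of the boundary-value
  problem; backward committor `1 − q⁺` for reversible chains, otherwise
  via the time-reversed chain. Pathway decomposition iteratively removes
  the widest (maximum-bottleneck) path; ties break to the shorter path,
  then lexicographic state order, implemented as a bottleneck-value
  Dijkstra followed by a BFS-shortest lexicographic walk in the
  thresholded subgraph — this makes the decomposition exactly
  reproducible and equal to exhaustive simple-path enumeration on small
  instances. A pathway is "stepwise" if it visits any microstate of the
  designated intermediate macrostates, else "concerted"; classification
  requires ≥ 99.9% flux coverage.
* **k-centers.** Greedy farthest-point clustering, first center = frame 0
  (deterministic; a seeded random option exists). Euclidean metric for
  low-dimensional landscape/feature data; pairwise Kabsch-RMSD metric for
  coordinate frames. The covering radius is a 2-approximation of the
  optimal k-center radius (verified against brute force on small
  instances).

## Synthetic generators: what they emulate, and what they do not

**Four-well Langevin landscape** (`build_four_well`). Four inverted
Gaussian wells (depths 5/4/4.5/6 kT, widths 0.25 nm) on a 120° arc with
consecutive chord spacing 1 nm emulate a linear S1↔S2↔S3↔S4 topology
with the endpoint state deepest (the backtracked-like state most stable)
and shallow intermediates. Two additional terms are physically necessary
and were arrived at by explicit design iteration:

* a quartic confining wall hugging the well region — bare Gaussian wells
  are non-confining, and any flat plateau between wells and wall forms a
  spurious *entropic* metastable state that corrupts the slow spectrum;
* an *arc corridor*: everything farther than ~1.2 well widths from the
  arc is raised by `direct_barrier` (default 8 kT), so the straight
  1↔4 chord and every other off-pathway route is blocked and the only
  low-energy channel is the stepwise one. This is what "suppressing the
  direct channel" means here, and it is why the TPT stepwise flux
  fraction is 1.0 on this landscape.

Dynamics are overdamped Euler–Maruyama,
`p ← p − ∇U Δt/γ + √(2 kT Δt/γ) η`, stable for
`Δt ≤ width²γ/(4·max depth)`; the reference protocol uses Δt = 0.002,
γ = 1, kT = 0.8 (at kT = 1 the basin boundaries are soft enough that
crisp four-state metastability degrades). Swarms are seeded along the
polyline through the well centers (14 interpolants per segment × 3
segments × 5000 steps ≈ 2.1·10⁵ frames), emulating pathway-seeded rounds
of short unbiased simulations; per-member seeds derive from
`SeedSequence([master_seed, start_index])`. Each landscape frame is also
emitted as six labeled pseudo-particles (RNA 3′-end, DNA transition
nucleotide, T831/T827/Y836/Y769 analogues) by fixed affine maps plus
0.02 nm seeded isotropic noise, so the transition index, DCCM and
distance observables operate on realistic-shaped inputs.

What this does *not* emulate: real force fields, solvent, actual Pol II
geometry, per-atom masses (centers of mass use unit masses), adaptive
reseeding between simulation rounds (one seeding generation only, rounds
are a config loop), or the dimensionality of real conformation spaces.
Passing tests on this data show the *estimation pipeline* is correct and
well-conditioned, not that any particular molecular system has four
states.

**Block ground-truth chain** (`build_block_chain`). 20 states in four
blocks of five; symmetric weight matrix (complete within-block graphs,
single bridge edges between consecutive blocks), row-normalized, hence
reversible with exact stationary vector. Block strengths are
proportional to 0.105/0.224/0.040/0.631, matching the equilibrium
pattern of the emulated system (pre-translocation ≪ frayed >
intermediate ≪ backtracked), and the weakest coupling (0.008) sits on
the 3↔4 bond so the final transition is rate-limiting (slowest
relaxation ≈ 1.4·10³ chain steps, next ≈ 10² — well inside the
12,500-step trajectories of the recovery test). Couplings are kept well
below the weakest block's within-block weights; otherwise the bridge
microstate kinetically belongs to its neighbour block and the
construction labels would not be the true metastable sets (verified:
PCCA+ of the exact matrix reproduces the construction blocks). A ±15%
seeded jitter on within-block weights avoids accidental spectral
degeneracies. Recovery tests start trajectories from the exact
stationary distribution — the equilibrium-sampling condition under which
occupancy-based population estimates are unbiased.

**Correlated displacements.** Zero-mean Gaussian positions with a
prescribed particle-particle correlation (matrix square root applied to
iid normals, identically per spatial component); the DCCM of the
ensemble converges to the requested matrix, and per-particle RMSF
converges to √3 for unit component variance.

## Observables

* **Transition index** `x = (d_i · d_ref)/|d_ref|²` with
  `d_i = r − r_pre`, `d_ref = r_frayed − r_pre`, where r is the
  probe-group (DNA transition-nucleotide analogue) center of mass. This
  normalized scalar projection is the unique linear form with x = 0 at
  the pre-translocation reference and x = 1 at the frayed reference; it
  is unbounded outside [0, 1] by design and rigid-motion equivariant.
  Destination classification of transition-state-seeded runs uses the
  symmetric midpoint threshold x = 0.5 (only destination fractions are
  reported, so the cut is a convention).
* **DCCM** `C_ab = ⟨Δr_a·Δr_b⟩ / √(⟨|Δr_a|²⟩⟨|Δr_b|²⟩)` on group
  center-of-mass displacements from the subset mean, computed per
  metastable state by restricting the frame subset; symmetric, unit
  diagonal, clipped to [−1, 1] at 1e-12.
* **RMSD/RMSF.** Kabsch superposition (proper rotations only, via
  least-squares rotation fitting) with degenerate (collinear) fit groups
  rejected; RMSF about the once-iterated mean structure.
* **Distance to reference**: per-frame Euclidean distance of group
  centers of mass to the same groups in a reference conformation,
  optionally averaged over groups (the convention for profiling several
  upstream nucleotide positions at once) and summarized per state as
  mean ± SD.

## Pipeline

One content-addressed run directory per configuration (SHA-256 of the
canonical config), containing every intermediate as CSV/JSON text plus a
run log with stage timings; every number in `report.json` is
recomputable from persisted intermediates. Times are stored in ns
internally; the human-readable kinetics table converts MFPTs to the
configured unit and prints `mean±SD` with one decimal. `validate`
re-checks: populations sum to 100 ± 0.1%, slowest implied timescale at
the chosen lag within 20% of the next larger candidate lag,
residence-probability mismatch ≤ 0.1, and net-flux conservation at
intermediate states ≤ 1e-10 of total flux.

Reference protocol sizes (chosen to keep a desk-scale run in minutes):
k = 100 microstates and lag = 20 frames for the four-well tutorial
(k = 800, lag 8 ns mirror the emulated study's scale and are plain
config values); 4 macrostates; B = 100 bootstrap resamples.

## Known limitations

* The reversible estimator is the symmetrized-count convention, not the
  maximum-likelihood reversible estimator; for strongly non-equilibrium
  sampling the two differ.
* Frozen-lumping bootstrap ignores lumping uncertainty; it quantifies
  count-matrix noise only.
* PCCA+ is the deterministic inner-simplex variant without the
  constrained-optimization refinement; adequate for well-separated
  metastable systems, which is the regime this package targets.
* k-centers with the RMSD metric scales linearly per center in frames
  and is intended for small coordinate sets; large datasets should be
  clustered on reduced features.
* The Langevin integrator is Euler–Maruyama; its discretization bias is
  irrelevant to testing the inference pipeline but makes the sampled
  landscape distribution only approximately Boltzmann at large Δt.
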