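# Methods

This note records the models, estimators, conventions and numerical
choices behind `tailmsm`, and what the synthetic benchmarks do and do not
establish about real data.

## The modelling problem

A disordered protein tail explores a rugged conformational landscape with
a few long-lived ("metastable") states. Given trajectories sampled at
spacing Δt, the pipeline estimates a discrete-state kinetic model:

1. **Featurization.** Internal coordinates only: backbone torsions and
   pairwise Cα distances. Torsions are encoded as (sin θ, cos θ) pairs by
   default so the ±π seam does not break the linear-correlation structure
   tICA relies on; raw angles are available for comparison
   (`FeatureSetDefinition(encoding="raw")`).
2. **VAMP-2 feature scoring.** Candidate feature sets are compared by the
   VAMP-2 score, the sum of squared singular values of the half-weighted
   propagator C₀₀^{-1/2} C₀τ Cττ^{-1/2}. The constant singular function is
   counted, so the score lower bound is 1 and a process with one slow mode
   of eigenvalue λ₂ scores → 1 + λ₂². Scores are cross-validated over
   contiguous-block splits (default 3) rather than shuffled frames, which
   would destroy the temporal correlations the score measures.
3. **tICA.** Generalized eigenproblem C_τ v = λ C₀ v on mean-free
   covariances accumulated over trajectories (lagged pairs never span
   trajectory boundaries). Covariances are symmetrized
   (C_τ ← (C_τ + C_τᵀ)/2, and both time directions enter C₀ and the mean),
   the standard remedy for finite-sampling non-reversibility and the
   estimator consistent with the reversible MSM downstream. The number of
   retained components defaults to the smallest m with cumulative kinetic
   variance Σλ² ≥ 95%, overridable.
4. **Microstates.** k-means (k-means++ seeding, Lloyd iterations to a
   1e-6 center-shift tolerance, cap 500) on the pooled projected data; the
   per-iteration inertia history is recorded and asserted non-increasing.
   Empty clusters are re-seeded from the point farthest from its assigned
   center; nearest-center assignment breaks ties toward the lowest center
   index, so fixtures are bit-reproducible. Fitting may subsample frames
   (`cluster_stride`) with assignment of every frame afterwards.
5. **Reversible MSM.** Transition counts at lag τ (sliding window by
   default; strided available), trimmed to the largest strongly connected
   component (ties broken by total counts), then maximum-likelihood
   estimation under detailed balance by the fixed-point iteration on
   symmetric auxiliary variables x_ij:
   x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j), converged when the implied
   stationary vector moves < 1e-10 (∞-norm). Symmetric count matrices are
   the fixed point immediately (T = row-normalized counts); the estimator
   is checked against an independent constrained optimizer in the tests.
   The spectrum is computed on the π-symmetrized matrix, so eigenvalues
   are exactly real.
6. **Validation.** Implied timescales t_i = −τ/ln λ_i across a lag list
   (eigenvalues clipped to (−1, 1) before the log; non-positive
   eigenvalues are reported as NaN — below the resolution of the lag).
   The Chapman–Kolmogorov test compares set-aggregated probabilities of a
   freshly estimated model at lag kτ with T(τ)^k propagation, with error
   bars from a trajectory-level bootstrap (a single trajectory is split
   into 10 contiguous chunks first). A multiple whose re-estimation loses
   a set entirely is flagged, not fatal.
7. **Macrostates.** PCCA+ on the top-m right eigenvectors: inner-simplex
   vertex initialization, then optimization of the feasible linear
   transform maximizing the crispness objective trace(diag(1/A₀) AᵀA)
   (Nelder–Mead on the free block of A, feasibility reconstructed each
   step; infeasible proposals are rejected and the initialization kept).
   Crisp states are argmax memberships with lowest-index tie-break;
   macrostate populations are π aggregated through the memberships.
   The macrostate count is user-chosen; `choose_macrostate_count` reports
   spectral gaps, minimal crispness and optional CK discrepancy per
   candidate, without auto-selecting.
8. **Kinetics.** MFPT into a set solves (I − T_C) m = 1 outside the sink,
   π-weighted over the source set (the convention for single-number
   set-to-set MFPTs), in ns via the model lag; rates are inverse MFPTs.
   TPT: forward committors from the discrete boundary-value problem,
   backward committors from the time-reversed chain (= 1 − q⁺ for
   reversible models), gross fluxes f_ij = π_i q⁻_i T_ij q⁺_j, net fluxes
   f⁺ = max(0, f − fᵀ), all converted to per-ns. Dominant pathways are
   extracted strongest-bottleneck-first (widest-path search, subtract the
   bottleneck, repeat until the flux is exhausted or `max_paths` reached);
   shares are percentages of the total net source→sink flux, and the
   subtraction order is part of the definition. For few-state reporting
   the microstate flux is first aggregated onto the crisp macrostate sets
   and decomposed there, which is what the pathway percentages in the
   report refer to.

Default settings follow standard practice for tail kinetics: τ = 5 ns for
tICA and the MSM, k = 200 microstates (smaller k is appropriate at desk
scale and used in the bundled fixtures), 4 macrostates, free-energy
surfaces at T = 310 K with R = 0.0019872 kcal/(mol·K), all times in ns.

## Synthetic benchmarks and their oracles

The generators provide data whose kinetics are known exactly; one explicit
integer seed (numpy PCG64) makes every dataset bit-reproducible.

- **Markov chains + Gaussian emissions.** `GroundTruthChain` validates row
  sums (1e-12) and stores the stationary vector (left Perron eigenvector,
  residual < 1e-10). `oracle_kinetics` gives exact MFPTs (absorbing-chain
  linear solve, π-weighted over the source), the exact spectrum and
  implied timescales; unreachable sinks are flagged as infinite.
  Emissions draw one Gaussian vector per frame from the frame's hidden
  state; (sin, cos) angle pairs are radially clipped to the unit disk.
- **Langevin walkers.** Overdamped Euler–Maruyama on a sum of inverted
  Gaussian wells plus a flat-bottom harmonic wall (zero inside the
  confining radius), so the analysis region keeps an exactly known
  potential while the walker cannot escape to free diffusion. The step
  constraint √(2kTΔt/γ) < min(width)/5 is validated at construction.
  Euler–Maruyama carries an O(k·Δt) stationary-variance bias (for an
  Ornstein–Uhlenbeck mode, var = (kT/k)/(1 − kΔt/2)); equilibrium checks
  therefore run at k·Δt ≲ 0.03. The bundled double well uses depths
  (3.0, 2.0) kT at centers (±1, 0), width 0.55: deep enough for two
  clearly separated basins, shallow enough that a 10⁶-step walk crosses
  several hundred times, which is what makes the basin free-energy
  difference resolvable to a few hundredths of a kcal/mol by Boltzmann
  inversion of the histogram.
- **Toy tail.** A bead chain with fixed bond length, fixed 90° planar bond
  angles, and torsions drawn from per-hidden-state von Mises
  distributions; construction is the standard internal-coordinate (NeRF)
  placement, so consecutive-bead distances are exact and the hidden-state
  record is returned for parameter-recovery tests. The bundled 4-state
  tail uses a reversible chain (built from symmetric counts) with
  stationary populations (34.7, 28.1, 22.1, 15.1)%, relaxation times of
  roughly 20–50 steps, torsion means (−2.5, −0.9, 0.7, 2.3) rad and
  concentration 25 — separations and noise chosen so the states are
  distinct in feature space but overlap enough that the pipeline, not the
  generator, does the work.

What the benchmarks do **not** show: real tails have many more degrees of
freedom than the slow ones (solvent, side chains), non-Gaussian emissions,
state-dependent noise, and no guarantee that a Markovian lag exists.
Passing the synthetic suite demonstrates estimator correctness (the
implementations converge to the right answers when the model class is
right), not that a 5 ns lag or 4 macrostates are right for any particular
protein — that is what the ITS/CK diagnostics are for on real data.

## Numerical choices

- Covariance regularization: eigenvalues below 1e-10 of the largest are
  truncated, plus an absolute floor of 1e-12 × the largest feature second
  moment — without the floor, exactly constant features leave O(machine
  epsilon) covariance residue that a purely relative cutoff would whiten
  into spurious unit singular values.
- tICA/MSM eigenvalues are clipped to (−1+1e-12, 1−1e-12) before any
  log-timescale conversion; symmetrized tICA estimates are capped at 1.
- The reversible fixed point caps at 10⁶ iterations and raises with
  diagnostics on non-convergence (typical convergence: a few hundred
  iterations at n ≤ 200).
- PCCA+ refuses top-m eigenvalue gaps below 1e-10 (degenerate simplex) and
  suggests changing m; m = n yields the identity membership matrix.
- Pathway decomposition stops when the remaining flux is below 1e-12 of
  the total; shares then sum to 100% within 1e-6.
- Dihedrals of collinear triples are NaN with a warning by default
  (configurable to raise); the angle range is (−π, π] with −π mapped to π.
- Free-energy surfaces are probability-mass histograms (sum to 1); empty
  bins are NaN and ΔG is exactly 0 at the most populated bin.
- HDF5 outputs are written with `track_times=False`, so identical runs
  produce byte-identical files; the pipeline records SHA-256 hashes of
  every output in `run_record.json`.

## Problem sizes

The test suite and `scripts/acceptance.py` run chains of 10⁵–10⁶ steps,
toy-tail datasets of 8 × 125 000 frames, and Langevin walks of 10⁶ steps —
sizes at which the analytic recovery targets (populations within ±3%
absolute, set MFPTs within 10–15%, implied timescales within 5%) are
comfortably inside sampling error on a single CPU core in about a minute
per benchmark.

## Known limitations

- No Bayesian/posterior sampling of transition matrices; uncertainty comes
  from trajectory-level bootstraps only.
- No hidden Markov refinement, milestoning, kinetic-map scalings, or
  nonlinear dimensionality reduction; k-means is the only discretizer.
- The CLI reads multi-model PDB, CSV and HDF5 only — no compressed binary
  MD formats, no solvent/ion handling.
- Set-to-set MFPT and pathway-share conventions (π-weighted sources,
  net-flux percentages, strongest-first subtraction) are choices; numbers
  are comparable across runs of this package but only comparable to other
  software using the same conventions.
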