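# Methods

This note documents the models and estimators implemented in `fespath`,
the parameters that matter, what the synthetic generators emulate, and the
numerical choices made where the design was genuinely open.

## CV-space dynamics surrogate

The sampling engine propagates a walker directly in collective-variable
space with the overdamped (Brownian) update

    x ← x − (Δt/η) ∇(U + V_bias) + sqrt(2 k_B T Δt / η) ξ,   ξ ~ N(0, 1)

rather than integrating atomistic equations of motion. The target is
sampling statistics — hill-height decay, bias convergence, reweighting
behaviour — not kinetics, so a first-order integrator on a model potential
is the appropriate level of description. Parameters and defaults:

| parameter | default | units | meaning |
|---|---|---|---|
| height *w₀* | 0.5 | kcal/mol | initial Gaussian kernel height |
| sigma *σ* | 0.25 | Å | kernel width per CV |
| pace | 100 | steps | steps between depositions |
| timestep | 0.5 | fs | integrator step |
| bias factor γ | 34.77 | — | tempering (γ = 1 + E/k_BT; 20 kcal/mol at 298 K) |
| temperature | 298 | K | thermal energy of the walker |
| friction η | 1.0 | ps⁻¹ | mobility of the overdamped walker |
| seed | 0 | — | reproducibility; same seed ⇒ bit-identical runs |

The kernel protocol values are the deposition protocol of the study this
toolkit mirrors. The friction is a property of the surrogate, not of any
physical system: it sets the walker's diffusivity D = k_B T/η and thereby
how many independent basin sweeps fit into a run. The default η = 1 ps⁻¹
makes the standard 2×10⁶-step (1 ns) run a deeply converged regime
(hundreds of barrier recrossings on the reference double well), which is
the premise of every downstream convergence diagnostic; at η = 10 ps⁻¹
the same run length leaves seed-level scatter of order the hill height in
the recovered barriers.

Implementation: the model potential's gradient and the growing bias (and
its gradient) are tabulated on regular grids and linearly interpolated
inside a numba-compiled loop; grid spacing is σ/5, so interpolation error
is far below sampling noise (exact for harmonic wells). Domain boundaries
reflect the walker; kernels are not mirrored at the walls, so FES
estimates within ~2σ of a boundary are distorted — analyses use interior
windows.

## FES estimators

Two independent routes to the free energy are provided:

1. **Hill sum**: F(s) = −γ/(γ−1) · V(s, t_end), min-shifted to 0. The
   instantaneous estimate carries a kernel-scale ripple in time; an
   optional variant averages the estimate over *n* checkpoints spanning
   the second half of the deposition record, which suppresses the ripple
   at no extra assumption (the default remains the instantaneous form).
2. **Reweighted histogram**: per-frame weights
   w_t ∝ exp(+[V(s_t, t) − c(t)]/k_B T) with the time-dependent offset

       c(t) = (1/β) ln [ ∫ exp(β γ V/(γ−1)) ds / ∫ exp(β V/(γ−1)) ds ],

   evaluated incrementally on a bias grid as hills are replayed. A frame
   recorded at the same step as a deposition is weighted with the bias
   *before* that hill — the sample was generated under the earlier bias,
   and including the synchronous kernel (always centred on the frame)
   systematically overweights early frames. A simpler final-bias scheme
   (w ∝ exp(+V(s, t_end)/k_B T)) is available for cross-checking.

On the analytic double well both estimators recover the barrier to within
a few tenths of kcal/mol and agree with each other to ≲0.15 kcal/mol
averaged over bins (defaults, 1 ns run).

## Landscape analysis

Minima are interior grid nodes strictly below all neighbours, refined by a
Newton step on the local quadratic model from central finite differences
(step clamped to one cell) and accepted only with a positive-definite
Hessian. Saddles (2D) are nodes whose Newton step stays within the cell
and whose Hessian has exactly one negative eigenvalue; candidates within
two grid spacings merge keeping the lowest, and nodes whose smallest
|eigenvalue| is below 10⁻³ kcal/mol/Å² are rejected — on featureless
plateaus the finite-difference Hessian signature is noise. The default
0.02 Å spacing resolves the two decimals to which stationary-point
coordinates are quoted.

The minimum-energy path between two minima is the **minimax path** on the
8-connected node graph — the path whose highest node is as low as possible,
found by a Dijkstra variant ordered on the running maximum. It is
deterministic and exact on the grid (verified against a flood-fill oracle:
the minimax level equals the lowest level at which the basins join), with
no string/NEB-style tuning. The reported path is optionally rebuilt by
steepest-descent relaxation from the path maximum toward both endpoints.
Barrier = max(F along path) − F(a); reaction free energy = F(b) − F(a);
basin values are refined point values, not basin integrals.

## Reference surface calibration

`reference_mechanism_surface` builds a smooth 2D stand-in for the
first-step free-energy landscape of the phosphoryl transfer: CV1 = d(S–P),
CV2 = d(O–P), reactant channel at (3.38–4.28, 1.68) Å with ΔG_r = 5.7
kcal/mol, index-1 saddle at (3.05, 2.40) with ΔG_t = 12.8, product
global minimum at (2.20, 3.51–4.68) with ΔG_p = 0. Range-valued targets
are collapsed to midpoints — R at (3.83, 1.68), P at (2.20, 4.10) — and
basin elongation is reproduced by anisotropic widths.

The functional form is a 20 kcal/mol plateau minus four anisotropic
Gaussian wells: one per basin plus two "channel" wells centred on the
R→TS and TS→P segments that carve the curved reaction valley (two basin
wells alone cannot place a 12.8 kcal/mol saddle between basins ~3 Å
apart). The 24 well parameters are fitted by deterministic least squares
whose residuals are the located stationary points (positions, relative
energies, Hessian signatures, found by nested local optimisation from the
target points) plus hinge penalties keeping the energy along the
R→TS→P line below the saddle level, and a weak pull toward the designed
initial layout. The fit reproduces all targets to ~10⁻⁶; failure to reach
the spec tolerances (0.1 kcal/mol on energies, 0.1 Å on basin locations,
0.15 Å on the saddle) raises a calibration error with the residual report.
An independent dense-grid check (0.01 Å tabulation, neighbourhood minima
search, flood-fill saddle level) confirms the calibrated surface has
exactly two minima and one saddle at the target values.

## Block-average error and crossings

The trajectory is split into equal contiguous blocks; each block yields a
weighted marginal probability profile per CV. Per bin, the block
probabilities (zero when a block misses the bin — a legitimate
observation, not a missing one) are combined with block-weight-weighted
mean and standard error, propagated to the free energy as
δF = k_B T · δp/p̄, and averaged over occupied bins; bins holding less
than 10⁻⁵ of the peak probability are excluded as pure shot noise. For
i.i.d. samples the resulting error is flat in the number of blocks (the
independence signature); for correlated trajectories it plateaus once
blocks exceed the correlation time.

Barrier crossings are counted with a hysteresis filter: a crossing
registers only when the series penetrates at least one kernel width
(default 0.25 Å) beyond the dividing value on the far side, suppressing
grazing recrossings. Several filtered crossings are the diffusivity
criterion for calling a run converged.

## Consensus clustering

Pairwise pose dissimilarity is the heavy-atom RMSD after least-squares
superposition (Kabsch, proper rotations only — mirror images are never
matched) on the receptor selection; fit and measurement selections are
configurable, defaulting to receptor fit / all-atom RMSD. Agglomeration
uses average linkage (the convention associated with the Kelley
criterion); assignments are materialised for every cut level. The Kelley
penalty rescales the average spread — mean over multi-member clusters of
their mean intra-cluster pairwise RMSD — onto [1, n−2] across levels and
adds the cluster count; the minimum over k = 2..n−1 picks k*, ties toward
smaller k, and uniform RMSD rescaling provably leaves the choice
unchanged. The consensus model is the member of the most populated
cluster minimising mean RMSD to the rest of that cluster; size ties
resolve toward the more compact cluster, member ties toward the lower
index. The mean-pairwise spread definition is the default; a
centroid-based variant was considered and rejected for its sensitivity to
cluster shape.

## Synthetic generators

All generators are deterministic given their seed.

- **Double well** U(x) = b·((x/a)² − 1)²: the oracle potential with exact
  barrier b and minima ±a used to validate the entire sampling →
  reconstruction → reweighting chain.
- **Planted pose ensemble**: one fixed receptor cloud; ten rigid ligand
  placements (random rotation, translations ≥ 10 Å apart) with cluster
  sizes (95, 80, 70, 60, 50, 40, 35, 30, 25, 15) summing to 500 — the
  total and the top-cluster size follow the pooled docking study, the
  remaining sizes are fixture choices; members jitter the placement by
  i.i.d. 0.5 Å Gaussian atomic displacements. With ≥ 10 Å separation and
  0.5 Å jitter the within/between RMSD ratio is < 0.2, so exact recovery
  is the designed outcome; the generator errs if the separation
  constraint cannot be placed in three attempts.
- **Toy active site**: nine atoms with PDB-style addressing (chain,
  residue, atom name) at configurable distances — collinear S···P···O for
  the in-line attack, the Asp proton between donor and acceptor oxygens,
  three terminal phosphate oxygens perpendicular to the S–P axis. Every
  CV operation has a hand-checkable value on it.

What the generators do **not** emulate: atomistic force fields, realistic
decoy geometries, CV-space anisotropic diffusion, or the slow orthogonal
degrees of freedom of a real enzyme. Passing tests demonstrate the
correctness of the estimators and procedures, not the physical accuracy
of any particular simulation.

## CV definitions

The reweighting CV for proton transfer is a signed combination of
coordination numbers of the Asp proton with its donor and acceptor
oxygens, CN(O_Asp) − CN(O_Tyr) − CN(O_P), under the exponential-decay
switching function (value 1 for d ≤ d₀, exp(−(d−d₀)/r₀) beyond; d₀ = 1.0 Å,
r₀ = 0.5 Å). The clamp at d ≤ d₀ keeps each term in (0, 1] and the
coordination number bounded by the partner count. The combination's exact
coefficients are configurable; the default separates donor-bound
(positive) from acceptor-bound (negative) proton states. No cutoff radius
is applied to the switching function; contributions decay to < 10⁻⁷
within ~9 Å of d₀ and a cutoff would only complicate the clamp semantics.

## Units, constants, degenerate inputs

Å, kcal/mol, ps, Kelvin package-wide; k_B = 0.0019872041 kcal/mol/K;
Planck constant per molecule 1.5836687×10⁻³⁷ kcal·s; transmission
coefficient fixed at 1 in all Eyring conversions. Empty hill series give
uniform weights (no bias, nothing to undo); empty histogram bins are
non-finite and excluded from minima searches; a missing basin at a
convergence checkpoint yields NaN rather than an error; the Kelley
criterion is undefined (error) when every member is identical.

## Problem sizes

Default analyses run on: 2×10⁶-step (1 ns) 1D double-well runs (2×10⁴
hills and frames), FES grids of ~200×240 nodes at 0.02 Å, and the
500-pose ensemble (1.25×10⁵ RMSD pairs). These sizes give comfortable
statistical margins for every tolerance used in the tests while keeping
a full suite run in the low minutes on one CPU.

## Known limitations

- The engine is 1D/2D only, matching the CV spaces it emulates; no
  multi-walker or replica schemes.
- Reflecting walls distort the FES within ~2σ of the domain boundary.
- The reweighting offset c(t) assumes the quasi-static (well-tempered)
  bias regime; the violent early filling phase is handled by the offset
  but contributes little effective weight.
- Saddle search is 2D; in 1D the path maximum is the barrier.
- Kelley selection assumes the dissimilarity scales meaningfully; it is
  undefined for all-identical ensembles and can be shallow when clusters
  overlap heavily.
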