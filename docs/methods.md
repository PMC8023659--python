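# Methods

This note documents the models, conventions and design choices behind
`chelafix`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordination model

A phosphate group g ∈ {α, β, γ} counts as coordinated when the minimum
distance from Mg²⁺ to any of g's **non-bridging** oxygens (α: O1A, O2A;
β: O1B, O2B; γ: O1G, O2G, O3G) is at most the cutoff (default 3.0 Å, the
same distance used for the mining selection rule). Bridging O3A/O3B are
excluded by default — bridging coordination is chemically rare and the
grouping is by phosphate group — but can be included via a flag. The
composite labels are:

* **C3** — coordinated groups exactly {α, β, γ};
* **C2** — coordinated groups exactly {β, γ} *and* Mg–Pα > 3.75 Å;
* **OTHER** — everything else.

For per-frame reweighting masks of simulation ensembles, the pure
distance rule (Mg–Pα > 3.75 Å ⇒ C2) is exposed separately
(`distance_only_c2`), because group-membership tests are needlessly
strict on continuous trajectories.

Mining conventions: every model of a multi-model file and every
nucleotide copy yields an independent instance; redundant/homologous
entries are deliberately *not* deduplicated (each is an independent
observation of binding-site flexibility); altloc ties resolve to the
first highest-occupancy record; the divalent-cation list for the 8 Å
exclusion rule is residue-name based (MG, CA, MN, ZN, FE2, CO, NI, CU,
CD, SR, BA) and configurable. ATP analogues (ANP, ACP, AGS) are mapped
onto ATP atom naming via an alias table but are off the default
whitelist.

## Tail PCA

The six-atom representation (Pα, O3α, Pβ, O3β, Pγ, Mg²⁺) isolates
metal–phosphate coordination variance from nucleotide conformational
diversity. Frames are first superposed by unweighted 6-atom Kabsch fits
onto an iterated mean reference (converged when the mean moves by
< 1e-6 Å RMSD); superposition precedes PCA because rigid-body variance
would otherwise dominate a coordinate PCA. The PCA itself
eigendecomposes the sample covariance (ddof = 1) of the flattened
18-vectors with uniform weights and no mass weighting. Eigenvector signs
are arbitrary; when C2/C3 labels are available the convention is fixed so
the mean C3 projection on EV2 is negative and the mean C2 projection on
EV1 is positive, which matches the usual map orientation. Projections
are reported in nm although coordinates are Å internally.

Free-energy surfaces are F(bin) = −kT ln(Σ weights in bin), min-shifted
to zero over finite bins; empty bins and bins above a cap (default
18 kcal/mol) are flagged inaccessible. kT defaults to 0.59616 kcal/mol
(300 K). Density maps use a Gaussian KDE (Silverman bandwidth by
default) on a 100×100 grid spanning the data range ±5%, with clusters
defined as connected components above a fraction of the density maximum,
labelled I, II, … by decreasing mass.

`select_diverse_subset` maximizes the summed pairwise distance with a
greedy construction plus pairwise-exchange refinement. Exact
maximization is NP-hard; on small instances the exchange step recovers
the brute-force optimum (asserted in the tests), and the procedure is
deterministic for a given input order.

## Alchemical states and restraints

The reduced-charge intermediate lowers the cation from +2 to +0.5 and
spreads the removed +1.5 e uniformly (+1.5/13 each) over the 13
triphosphate P/O atoms, preserving net charge exactly. Intermediate
charges interpolate linearly in λ; no soft-core is needed because no
atoms appear or vanish. Coordination restraints are flat-bottom
half-harmonics: zero inside the window, (k/2)(d − wall)² outside.
Defaults: upper wall 3.0 Å on each coordinated group's minimum Mg–O
distance, lower wall 3.75 Å on uncoordinated groups, k = 1000
kcal/mol/Å² (matching the selection and C2-mask distances; in the
surrogate the walls act on the r coordinate directly with k = 100).
Eleven additional named barrier-region restraints are supported
structurally but ship without defaults.

Schedule equalization measures neighbour exchange acceptances, converts
them to per-gap resistances (1 − a), and re-spaces λ by inverse
interpolation of the cumulative resistance so each gap carries an equal
share; iteration stops when the coefficient of variation of the
acceptances reaches the tolerance (default 0.05). The chain length
defaults to 21 states (20 intermediates plus the native endpoint).

## MBAR

Reduced potentials are dimensionless (β and restraints folded in); kT
enters only at reporting. The solver runs self-consistent iteration as a
warm start, then Newton on the convex maximum-likelihood objective with
f₀ ≡ 0; the reported residual is the maximum deviation of f from one
further self-consistent update, and non-convergence flags the result
rather than raising. All accumulations go through log-sum-exp.

Uncertainties use a circular moving-block bootstrap within each state's
time-ordered sample block (default block length: one twentieth of the
series). For replica-exchange archives the `synchronized` mode reuses
the same block positions in every state; replica exchange correlates the
states' series (configurations physically migrate between replicas), and
independent per-state resampling would destroy that correlation and
understate the variance of well-population-sensitive quantities.
Decorrelation thinning of input series is available but off by default —
the surrogate sampler controls its own thinning.

## The surrogate ensemble

The surrogate stands in for the MD engine. Its configuration space is
(r, θ): r is a Mg–Pα-like distance with a double well (C3-like minimum
at 3.3 Å, C2-like at 4.2 Å, each −2 kcal/mol deep, Gaussian width
0.18 Å), separated by a Gaussian barrier at 3.75 Å whose height scales
with λ from 8 kcal/mol (native) to 1 kcal/mol (reduced charge), i.e.
B(λ) = 8·(1 − λ·s) with s = 7/8 the effective charge-reduction factor.
θ is the α–β–γ phosphate angle, harmonically tethered
(k = 0.004 kcal/mol/deg²) to a well centre that switches smoothly from
112° (compact, C3 side) to 155° (extended, C2 side) across the barrier.
A steep polynomial wall confines r. These constants were chosen once so
that native-charge sampling stalls (the 8 kcal/mol ≈ 13.4 kT barrier is
uncrossable in 10⁴ Metropolis steps) while the reduced-charge state
mixes freely — the structure of the real sampling problem.

A third coordinate h is a harmonic "solvent bath" of fixed unit
stiffness whose centre shifts linearly with λ (total shift 19.1 σ).
Physically it stands in for the solvent degrees of freedom that respond
to charge scaling and that, in the real system, carry most of the
thermodynamic length of the λ path. With only (r, θ), neighbouring
states of a 21-state chain would overlap almost completely and exchange
acceptances would sit near 1; the bath restores a realistic overlap
structure. Because its stiffness is identical in every state, a shifted
centre leaves the partition function unchanged: the bath contributes
**exactly zero** to every free-energy difference, so the 2D quadrature
oracle remains exact. The shift was calibrated analytically — for two
equal-width Gaussians displaced by d the swap acceptance is
2Φ(−d/(σ√2)), which equals 0.5 at d = 0.954 σ; at 20 gaps that gives a
total shift of 19.1 σ — so a 21-state chain lands at ≈ 0.5 mean
acceptance by construction.

Sampling is Hamiltonian replica exchange: per sweep, one Gaussian
Metropolis move per replica, then neighbour swap attempts over a
conflict-free partition of the pair list (the λ chain in order, plus
each restrained native state attached to the λ = 0 state), repeated
`swap_rounds` (default 3) times per sweep to speed replica diffusion
along the ladder. Replica exchange is essential, not cosmetic: without
it the native states cannot cross the barrier and the restrained-C2
end state would be disconnected from the estimator's overlap network.
Chains start from alternating wells to halve the equilibration burden;
the default burn-in is 2000 sweeps. u_kn is recomputed from stored
coordinates for every state (an archive invariant asserts the recompute
matches to 1e-10).

The quadrature oracle evaluates f_k = −ln Σ exp(−u_k) ΔA on a 2D
midpoint grid (default 801×601 over r ∈ [2.0, 6.2] Å,
θ ∈ [20°, 260°]), errors if the Boltzmann density fails to vanish at the
grid boundary (relative 1e-12), and can verify itself by resolution
doubling (Richardson-style, 1e-6 agreement). It is cross-checked in the
tests against `scipy.integrate.dblquad` as an independent integration
path, and the two-state solver is cross-checked against an independent
BAR root-finder.

## Offset correction

Conventions are fixed by the published arithmetic: corrected
ΔG(C3→C2) = uncorrected + offset (6.4 − 7.1 = −0.7;
−5.3 + 3.3 = −2.0), and at the weight level a positive offset multiplies
C2-frame weights by exp(−offset/kT). Prediction accuracy as a function
of the offset is piecewise constant with breakpoints at −ΔG_i, so the
fit is exact: accuracy is evaluated on every open segment between sorted
breakpoints and at the breakpoints themselves (exact zeros tie-break to
C3 with a flag; they occur with probability zero on real data), all
maximal optimal open intervals are returned, and the widest is chosen
with ties going to the interval whose midpoint is smallest in absolute
value — the single-interval-plus-midpoint convention of the published
analysis. Unbounded optimal intervals get a pseudo-midpoint 1 kcal/mol
beyond their finite endpoint. An uncertainty-aware accuracy variant
(counting near-boundary mispredictions within the record's own error bar
as correct) exists but is off by default.

The ΔG dataset generator emulates the 30-complex test-set design
(13 C2 / 17 C3 by deterministic rounding): label-consistent base values
±margin with margin ~ U(0.5, 8) kcal/mol, plus the injected bias and
Gaussian noise (σ = 1 kcal/mol by default). Fitting the offset on such
data should recover ≈ −bias; the acceptance suite measures the recovery
rate over 50 seeds.

## What the synthetic layer does and does not show

The toy structures use idealized tetrahedral phosphate geometry (P–O
1.5/1.6 Å, target Mg–O 2.05 Å, mode-dependent backbone angles:
112° for the tridentate template, 155° for extended β–γ); they exercise
parsing, filtering, classification and PCA geometry, not real
crystallographic diversity. The surrogate exercises every estimator
(MBAR, reweighting, FES construction, schedule equalization) against
exact references, but its energetics are schematic: passing tests
demonstrates the correctness of the machinery, not the accuracy of any
force field. Quantities that require the live PDB or microsecond MD —
census fractions, the real 30-complex free energies, unbiased transition
counts — are outside what this package can reproduce and are represented
by the synthetic recovery analyses instead.

## Numerical choices and limitations

* Problem sizes: the shipped analyses use 21+2 states × 4000–5000
  samples/state (thinning 15–20 sweeps), 10⁴ samples/state for the
  Gaussian pair, 50 bootstrap replicates for ensemble uncertainties and
  200 for the cheap Gaussian pair, and 50 seeds for recovery rates —
  sizes at which the estimators' error bands are a few hundredths of a
  kcal/mol.
* The equalizer equalizes overlap; the *mean* acceptance is a property
  of the system and chain length, not of the spacing.
* `fit_offset` is exact but O(n²) in the number of breakpoints;
  irrelevant at n ≤ a few thousand.
* The PDB reader handles PDB-format files only (no mmCIF) and does not
  fetch from the network.
* Bootstrap SEs inherit the usual caveats of block bootstraps: block
  length must exceed the correlation time; the defaults are tuned to the
  shipped sampler settings.
* Free-energy surfaces are only validated on bins the sampling plan can
  estimate: the exact expected sample count of a bin under the sampled
  mixture is computable by quadrature, and bins below ~30 expected counts
  (a handful of effective draws once serial correlation is accounted for)
  are in the Poisson regime where a histogram free energy is undefined or
  dominated by a single sample. The low-free-energy comparison region is
  therefore intersected with that estimability condition.
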