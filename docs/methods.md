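# Methods

## The problem

Relative binding free energy (RBFE) calculations rank congeneric
ligands — or single-point mutants of a peptide ligand — by the
difference in standard binding free energy to a common receptor,
ΔΔG°_b = ΔG°_b(B) − ΔG°_b(A).  Alchemical-transfer methods express the
RBFE as a one-sided exponential average over a *coordinate
transformation* of the simulated system rather than over a topology
change:

    exp(−β ΔΔG°_b) = ⟨ exp(−β u(r)) ⟩_{RA+B} ,

where the average runs over the ensemble in which ligand A is bound to
the receptor R and ligand B floats in the bulk, β = 1/(k_B T), and the
perturbation energy u(r) = U(T r) − U(r) is the change of the potential
energy under the transformation T that carries the system to the state
with B bound and A in the bulk.

`atswap` implements two such transformations:

* **Whole-ligand transfer** (`mode="atm"`): ligand A translates by a
  fixed displacement **d** and ligand B by −**d**, exchanging the bound
  and unbound positions.
* **Swap-and-displace** (`mode="ats"`): the coordinates of the mapped
  atoms of the two ligands' *common regions* are swapped, and only the
  variable R-groups translate — A's by the instantaneous anchor-anchor
  displacement **d**_BA = r_anchorB − r_anchorA, B's by −**d**_BA.
  The common region, however large, drops out of the perturbation
  energy; the magnitude and variance of u scale with the size of the
  *difference* between the ligands.  The swap keeps every covalent term
  between an R-group and its own anchor exactly unchanged, because the
  anchor's image (its mapped partner's old position) is displaced by
  exactly **d**_BA, the same shift the R-group receives.

The swap transform is an involution when **d**_BA is recomputed from
the instantaneous coordinates, which is why it is recomputed at every
energy evaluation and never cached.

## Alchemical potential

Sampling interpolates between the two end states through

    U_λ(r) = U0(r) + W_λ( u_sc(u(r)) ) ,

with a soft-core cap and a softplus coupling:

* `softcore(u)`: identity for u ≤ u_c; for u > u_c,
  u_sc = u_c + (u_max − u_c)·(z^a − 1)/(z^a + 1) with
  z = 1 + 2y/a + 2(y/a)², y = (u − u_c)/(u_max − u_c).  C¹ at u_c
  (slope 1), strictly increasing, asymptote u_max.  Defaults
  u_max = 200, u_c = 100 kcal/mol, a = 1/16.  Note the cap is
  approached only logarithmically at this exponent — u_sc reaches
  199 kcal/mol only around u ~ 10¹⁵.
* `softplus_w(u_sc)`: W = (λ2 − λ1)/α · ln(1 + e^{−α(u_sc − u0)}) +
  λ2·u_sc — slope λ1 in the low-energy tail, λ2 in the high-energy
  tail, exactly λ·u when λ1 = λ2 = λ.  Evaluated through
  `logaddexp` so both tails are stable.

The shipped 22-state schedule uses λ_k = k/21 with the two-leg
convention λ2 = min(1, 2λ), λ1 = max(0, 2λ − 1), α = 0.1 (kcal/mol)⁻¹,
u0 = 110 kcal/mol.  The endpoints are exactly linear (λ1 = λ2 ∈ {0, 1}),
so state 0 samples the physical RA+B ensemble and state 21 the RB+A
ensemble whenever u ≤ u_c.  The grid is mirror-symmetric about λ = 1/2
(λ_k + λ_{21−k} = 1); a 22-point strictly-increasing symmetric grid
cannot contain λ = 1/2 itself, so the λ = 1/2 "annealing target" is an
interpolated parameter set (`lambda_params(0.5)`), not a schedule
member.  The schedule is a plain TSV and fully user-replaceable; the
functional forms above are conventions, not contracts — only the
endpoint and symmetry properties are relied on.

## Restraints

All restraints are flat-bottom: zero within a tolerance, (k/2)(d−tol)²
beyond it.  **Convention: the printed force constant k multiplies the
half-squared excursion**, so published values in kcal/mol/Å² transfer
directly; comparisons against an implementation without the ½ must
rescale.  Provided forms: per-atom positional restraints (default
tol 3.0 Å, k 25 kcal/mol/Å²), a binding-site indicator on the two
anchor atoms (default tol 5 Å, k 25; the unbound ligand is evaluated
after subtracting the setup displacement, i.e. as if moved into the
site), and a simplified alignment restraint (distance between displaced
frame origins plus harmonic angle penalties between corresponding frame
axes).  The alignment form is a stand-in of our own design — published
alignment restraints are defined elsewhere and not re-derived here — and
is off by default in toy runs.  Restraints bias the sampled ensemble but
are *not* part of the perturbation energy u; the setups keep them
identical in the two end states so they cancel from ΔΔG.

## Sampling

Conformational sampling is single-atom Gaussian-displacement
Metropolis on exp(−β[U0 + W_λ(u_sc) + restraints]), with synchronous
nearest-neighbor Hamiltonian replica exchange across the λ ladder.
Design points that matter:

* **Per-atom move sizes**, tuned per replica and per atom toward
  30–50% acceptance during the equilibration phase (aggressively at
  first: ×1.5 every 10 sweeps, then ×1.3), frozen afterwards.  Atom
  stiffnesses in these systems span two orders of magnitude; a single
  global step size quasi-freezes the stiffly restrained anchors, whose
  frozen fluctuations then bias the anchor-anchor displacement
  coherently for an entire run.
* **Eight exchange phases per sweep** (alternating even/odd pairing).
  Exchange acceptance needs no energy re-evaluation — the decision
  variable Δ = [W_i(u_j) + W_j(u_i)] − [W_i(u_i) + W_j(u_j)] uses
  cached u_sc — so extra phases are nearly free, and replica flow
  through the ladder was the dominant slow mode of the estimate.
* An optional annealing pre-phase ramps λ from 0 to 1/2 linearly
  (default 250 sweeps); the final configuration and the tuned move
  sizes seed all replicas.
* One spawned RNG stream per replica plus separate streams for
  exchange and annealing; every run is a pure function of its seed.

Samples (sweep index, u_sc, U0 per state) are recorded every
`sample_interval` sweeps; the first third is marked as equilibration
and discarded by the estimators by default.

## Estimation

* `exp_estimator`: −(1/β) ln(mean e^{−βu}) with a log-sum-exp guard.
* `uwham`: the unbinned WHAM (= MBAR) self-consistent equations over
  all states.  Each state's reduced energy is β·W_k(u_sc) — U0 is
  shared by construction and cancels.  Solved by L-BFGS on the convex
  likelihood followed by self-consistent polishing to
  max|ΔF| < 10⁻¹⁰ kcal/mol; F is pinned at state 0 and
  ΔΔG = F_last − F_first.
* `bar`: a two-state Bennett acceptance-ratio solver (Brent root of the
  Fermi-weight balance), kept as an independent code path; tests
  require UWHAM and BAR to agree to 10⁻⁶ kcal/mol on shared samples.
* `bootstrap_sigma`: moving-block bootstrap.  Replica-exchange output
  is time-aligned across states (one sample per state per sweep) and
  the same configurations migrate between states, so time blocks are
  resampled *jointly* — the same block indices for every state —
  preserving the estimator's cross-state covariance.  The default
  block length is 4× the largest Sokal-windowed integrated
  autocorrelation time over the per-state series and two aggregate
  series (cross-state mean, first-minus-last state), capped so at
  least ten blocks remain.  This calibration was checked against
  across-seed scatter of independent runs and is mildly conservative.

## Synthetic systems and their closed forms

`make_toy_pair(k_bond, k_siteA, k_siteB)` builds a five-bead system:
one fixed receptor bead at the binding site; two two-bead ligands, each
an anchor plus an R-group bead joined by a zero-rest-length harmonic
bond (k_bond); ligand A bound at the site, ligand B displaced 40 Å
along y.  Binding-site interactions are *occupancy-switched* harmonic
wells centered on the site that act on whichever candidate bead lies
within 20 Å — with the spring constant belonging to that bead
(k_siteA for A's R-group, k_siteB for B's; a common k for the two
anchors).  This is how a toy expresses that site interactions follow
the transformation: after the swap, B's R-group image is in the site
and automatically feels *its* constant.  Anchors carry stiff positional
restraints (1000 kcal/mol/Å²) so the partition functions factor;
ligand-ligand interactions are excluded.

Every coupled degree of freedom is Gaussian, so the RBFE is exact:

    ΔΔG = (3/(2β)) · ln[(k_bond + k_siteB)/(k_bond + k_siteA)] ,

because a bound R-group bead is a 3-D Gaussian of total stiffness
k_bond + k_site (bond and well are concentric), an unbound bead one of
stiffness k_bond, and the unbound factors cancel between ligands.  The
sign follows the ΔG(B) − ΔG(A) convention: a *stiffer* site well costs
configurational entropy, so k_siteB > k_siteA gives ΔΔG > 0 (for the
reference constants 10/10/40 at 300 K, +0.819 kcal/mol).
`analytic_rbfe_restrained` keeps the anchor stiffness finite (the exact
2×2 Gaussian determinant), shifting the answer by +0.003 kcal/mol at
the defaults — below the statistical resolution of the runs.

What the toys do **not** emulate: real intermolecular chemistry,
internal ligand flexibility beyond one bond, solvent, periodic
boundaries, and common regions with internal structure (the common
region is a single anchor bead, so the swap-vs-transfer comparison
probes bookkeeping and anchor fluctuations, not conformational-swap
effects).  Passing the toy recovery therefore validates the
transformation algebra, the sampling stack, and the estimators — not
force-field realism.

## Problem sizes and numerical choices

The shipped validation runs use 22 states × 3000 sweeps (first third
discarded, samples every sweep, ~2000 production samples per state),
250 annealing sweeps, and 30 bootstrap resamples; a residual
equilibration transient of ~+0.01 kcal/mol is measurable at 2000
sweeps on the self-transform null and decays away by 3000.  The test
suite uses 1200-sweep runs, whose larger uncertainties are reported by
the same bootstrap.  Degenerate inputs are rejected with named
invariant violations (`ValidationError`) rather than silently patched;
soft-core/softplus values are cross-checked against arbitrary-precision
symbolic evaluation; the involution property of the swap holds to
floating-point roundoff (≤ 10⁻¹⁰ Å on toy coordinates, exactly for the
swapped rows).

## Known limitations

* Metropolis single-atom moves stand in for molecular dynamics; the
  estimators consume equilibrium samples regardless of the sampler,
  but sampling efficiency on anything larger than the toys would be
  poor.
* Synchronous nearest-neighbor exchange replaces asynchronous
  scheduling; free energies are scheduler-independent at equilibrium.
* One R-group per ligand; the partition format reserves no group
  column yet.
* No periodic boundaries: displaced ligands are never wrapped through
  images.
* The occupancy-switched well is discontinuous at its radius; the
  shipped systems keep all occupants far from the boundary.
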