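# Methods

`gofold` bundles the computational machinery used to dissect how a
C-terminal segment stabilizes a small globular protein — the motivating
case is human frataxin, whose mature domain (residues 90–210) carries a
non-canonical C-terminal region (CTR, residues 196–210) that packs
against the core, and whose CTR-truncated variant (90–195) folds but is
strongly destabilized.  Four layers of analysis are implemented: a Cα
structure-based folding model, WHAM thermodynamics over its trajectories,
landscape decomposition by contact region, and two-state analysis of
equilibrium unfolding experiments, plus small analytic hydrodynamic
calculators.

## The Cα structure-based (Gō) model

Each residue is a unit-mass bead at its Cα position.  The potential is
the standard funneled form

    V = Σ K_r (r − r0)² + Σ K_θ (θ − θ0)²
      + Σ [K_Φ1(1 − cos(Φ − Φ0)) + K_Φ3(1 − cos 3(Φ − Φ0))]
      + Σ_native ε [5 (r0ij/rij)¹² − 6 (r0ij/rij)¹⁰]
      + Σ_non-native ε (σ0/rij)¹²

with all reference values (r0, θ0, Φ0, r0ij) measured on the input
structure, so that structure is the global minimum.  Force constants are
K_r = 100ε, K_θ = 20ε, K_Φ(1) = ε, K_Φ(3) = 0.5ε; native contacts share a
uniform depth ε in a 10–12 well with its minimum at the native distance.

**Contact map.**  A native contact is a Cα pair at 4.0–6.0 Å with chain
separation ≥ 4; closer-in-sequence pairs are already restrained by the
bonded terms.  Contact distances are Cα–Cα; no all-atom shadow map is
used.  Non-native pairs (separation ≥ 4, not in the map) carry an r⁻¹²
excluded volume with σ0 = 4.0 Å.  Two deliberate edge-case rules:

* a long-range pair *closer* than 4.0 Å in the native reference is
  excluded from the repulsion list — giving it the 4 Å repulsion would
  push the native state off the potential minimum, against the Gō
  construction.  Real Cα traces essentially never produce such pairs;
  synthetic desk fixtures can.
* a dihedral whose flanking virtual bond angle is collinear in the native
  structure has no defined reference Φ0; its torsional term is masked
  (weight 0).  At such a geometry the dihedral is discontinuous and its
  gradient unbounded, so keeping the term would both corrupt energies and
  destabilize integration.

**Units.**  Lengths in Å, energies in ε (ε = 1), k_B = 1, masses 1, time
in the intrinsic unit τ.  Temperatures are reduced (ε/k_B); no mapping to
Kelvin is attempted for simulation outputs.

**Dynamics.**  BAOAB-split Langevin integration: deterministic half-kick
and half-drift around an exact Ornstein–Uhlenbeck velocity refresh.  With
the friction sent to zero the scheme reduces to velocity Verlet, which is
how the energy-conservation test exercises the integrator.  Defaults:
timestep 0.0005 τ (conservative for the stiff K_r = 100ε bonds;
thermostatted production on the toy systems is stable at 0.005 τ, which
the test-scale runs use), friction 1.0 τ⁻¹.  A single integer seed feeds
a numpy `SeedSequence`; ladder runs receive spawned child streams, and
random normals are drawn outside the compiled kernels, so every
trajectory is bit-reproducible.  Q uses the γ = 1.2 formation threshold:
a contact is formed when its distance is below γ times its native value.
A topology without contacts reports Q = 1 by convention (logged) rather
than 0/0.

## WHAM

Constant-temperature runs are pooled into a shared 2-D histogram over
(E, Q) — 60 energy bins spanning the pooled range; Q bins of width
1/N_contacts, capped at 50.  The self-consistent equations for the
density of states Ω(E, Q) and per-run shifts f_k are iterated on a log
scale (log-sum-exp) until the largest shift change falls below 10⁻⁷
(default), anchoring f_1 = 0 during iteration and normalizing ΣΩ = 1 at
the end so results are independent of run order.  Each bin's energy is
represented by the pooled within-bin sample mean rather than the bin
centre, which removes most discretization bias (this matters for the
two-level validation, where all samples sit at exactly two energies).
Adjacent-temperature energy histograms overlapping by less than 1% draw a
warning.

Reweighting gives Cv(T) = (⟨E²⟩−⟨E⟩²)/T² on a 2001-point grid across the
simulated bracket (ties at the argmax break toward lower T); temperatures
beyond a ±20% guard around the bracket are refused.  F(Q|T) = −T ln P(Q|T)
is reported with its minimum at zero; Q bins backed by fewer than 5
pooled samples are masked (NaN) because their reweighted probabilities
are shot-noise.  The barrier ΔF‡ is located by a prominence-based minimum
search (default prominence 0.1 ε) — the saddle is the maximum between the
outermost pair of basins, measured from the lower-Q (unfolded) basin and
reported in kT.  With a single basin the barrier is `None`, never a
number.

**Validation oracle.**  A two-level system (ground state degeneracy 1 at
E = 0, excited degeneracy g at E = ΔE) has closed-form occupation
p(T) = g·e^(−ΔE/T)/(1 + g·e^(−ΔE/T)) and Schottky heat capacity
Cv = p(1−p)·ΔE²/T².  Exact Bernoulli samples of this system at several
temperatures are the independent check that WHAM recovers both the
degeneracy ratio and Cv.

## Landscape decomposition

Contacts split by a residue region (for frataxin, the CTR 196–210): a
contact belongs to the region iff at least one partner does.  Q_core and
Q_region are each normalized by their own contact count and carried with
the integer formed counts, so the identity
n_core·Q_core + n_region·Q_region = n_total·Q is exact per frame.
Substate labels operationalize the joint-map clusters: N1 (core folded,
region bound): Q_core ≥ 0.7 ∧ Q_region ≥ 0.5; N2 (core folded, region
unbound): Q_core ≥ 0.7 ∧ Q_region < 0.5; U: Q_core ≤ 0.3; else "other".
These thresholds are declared defaults, exposed in the API and recorded
in outputs — they are not fitted.  The transition-state ensemble is
selected as frames with |Q − 0.5| ≤ 0.05 at the melting temperature
(window configurable).  Joint (Q_core, Q_region) maps default to 25×25
bins over [0,1]²; both axes are fractions, with counts recoverable from
the stored histogram.

## Two-state unfolding fits

**Chemical (Santoro–Bolen / linear extrapolation).**
ΔG(x) = ΔG° − m·x; the observed signal is
S(x) = [(S0_N + a_N x) + (S0_U + a_U x)·K]/(1+K) with
K = e^(−ΔG/RT).  R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹; the default fit
temperature is 293.15 K (isothermal experiments at 20 °C).  The m-value
can be held fixed (the practice followed for the frataxin data, which
used surface-area-predicted m values) or floated.  Baseline slopes are
fitted but initialized at zero.  Cm = ΔG°/m is derived, never fitted, so
Cm·m = ΔG° holds to round-off.

**Thermal (Gibbs–Helmholtz).**
ΔG(T) = ΔH(1 − T/Tm) − ΔCp[(Tm − T) + T ln(T/Tm)], f_U = K/(1+K), and
S(T) = (S0_N + l_N T)f_N + (S0_U + l_U T)f_U with baselines linear in
Kelvin.  ΔCp can be fixed or floated.  The stability curve ΔG(T) is
evaluated on a 0.1 K grid; with ΔCp > 0 its unique maximum satisfies
ln(Tm/T*) = ΔH/(Tm·ΔCp) and the grid answer matches that closed form to
one grid step; with ΔCp ≤ 0 the maximum is reported as `None`.

**Initialization (deterministic).**  The transition midpoint is guessed
from the mid-crossing of the apparent unfolded fraction (baselines from
the outer 20% of points); the enthalpy from a logistic pre-fit slope via
dH ≈ 4RTm²·(df_U/dT at Tm).  Data that a single straight line explains,
or whose signal change is within baseline noise, raise a no-transition
error instead of returning a meaningless fit.  Optimization is
Levenberg–Marquardt least squares; fits are invariant to row order of the
input table.

## Hydrodynamics

Stokes radius from mass: log10(Rs[Å]) = −0.254 + 0.369·log10(MW[Da]),
coefficients at their central values, result in nm.  Note one internal
inconsistency in the motivating data: the published table predicts
1.86 nm for MW 13,605.1 Da, but direct evaluation of the printed
coefficients gives 1.87 nm (possibly a Met-cleaved mass was used); the
package reproduces the self-consistent 1.78 nm value for 11,923.2 Da and
documents the other.  Polydispersity is the mass-weighted SD of the size
distribution over its mass-weighted mean, ×100; weights not summing to 1
are renormalized with a warning.  Svedberg
(M = s0·R·T/(D0(1 − v̄ρ))) and Stokes–Einstein (Rs = k_BT/6πηD0)
conversions run in cgs with results in Da and nm; a vanishing buoyancy
factor (v̄ρ ≥ 1) is an error.

## Synthetic fixtures and what they do (and do not) show

* **U-chain** (6 beads, two contacts of 3.8√2 Å): every contact-map rule
  is provable by hand; its long-range (1,6) pair at 3.8 Å exercises the
  sub-window exclusion, and its collinear first segment exercises the
  degenerate-dihedral mask.
* **Helix-hairpin toy** (20–60 beads): two antiparallel zigzag strands
  (bond 3.8 Å, midlines 5.6 Å apart) with the last ⌈0.15n⌉ residues
  packing back against the first strand in a contact-dense third layer
  (4.6 Å), an analytic stand-in for a core-plus-lock topology.  The
  geometry is closed-form, so the contact map is verifiable by
  enumeration.  The default n = 30 gives 35 contacts, 14 of them to the
  tail; truncating the tail leaves 21.
* **Denaturation curves** generate from exactly the signal models the
  fitters assume, with additive Gaussian noise — so round-trip tests
  probe the optimizer, not model misspecification.  Real curves carry
  correlated baselines drifts and non-two-state artefacts these fixtures
  deliberately lack.
* **Two-level samples** are exact Bernoulli draws; they validate the
  WHAM solver against closed forms but not its behaviour under
  correlated time series (trajectory frames are treated as independent
  counts; no autocorrelation correction is attempted).

The toy full-vs-truncated comparison reproduces the *qualitative*
signatures of deleting a contact-dense terminal segment — lower melting
temperature, broader heat-capacity peak, smaller folding barrier — at
desk scale (minutes).  Three study-condition choices behind it:

* the "truncated" construct removes the whole appendage — connector
  linker plus packed tail (residues 23–30 of the 30-mer) — not the tail
  beads alone.  Truncating only the tail leaves a floppy two-bead arm
  whose residual contacts blur the truncated chain's transition into a
  nearly flat Cv; removing the complete segment mirrors deleting a full
  C-terminal region and leaves a clean hairpin.
* each variant's temperature ladder brackets its own transition (the
  truncated chain melts lower), since a Cv peak at a ladder edge cannot
  be located.
* the truncated chain is only weakly cooperative (its Cv hump is low and
  broad), so it gets roughly twice the sampling of the full chain; the
  exact step counts are stated in the test and acceptance scripts.

Profiles and barriers are evaluated at the coexistence temperature
(where the folded and unfolded basins of F(Q) balance) rather than at
the Cv argmax: for finite systems the two differ slightly, and barrier
heights are only well defined near coexistence.

One signature deliberately does *not* carry over to desk scale: the
barrier ordering.  In the full-size frataxin models, deleting the CTR
*lowers* the folding barrier (the lock region raises it through
backtracking-type topological frustration while contributing only ~10%
of the contacts).  In a 30-bead toy the tail must carry ~40% of the
contact energy before its deletion shifts Tm resolvably, and an
appendage of that share folds by staged post-saddle docking — which
dilutes the Q axis and raises the full variant's coexistence
temperature, leaving the *truncated* chain with the larger barrier in
kT (measured ~1.0–1.2 vs ~0.5–0.8 across seeds and tail geometries).
A resolvable Tm shift and a small tail-contact share are mutually
exclusive at this scale, so the toy reproduces the melting-temperature
and cooperativity signatures but inverts the barrier one; the published
~2.3 kT barrier difference belongs to 121- and 106-residue models built
from the crystal structure with hour-scale sampling.  All sizes are
stated in the scripts and configurable.

## Known limitations

* No replica exchange, constraints, electrostatics or solvent; the model
  is strictly topological, as intended.
* WHAM error bars are not estimated (no autocorrelation analysis, no
  bootstrap); peak positions on small toys carry a few-percent
  stochastic scatter between seeds.
* The thermal and chemical fitters treat each probe separately; no global
  multi-probe fit.
* Substate thresholds and the TSE window are operational definitions,
  chosen once and exposed, not inferred from data.
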