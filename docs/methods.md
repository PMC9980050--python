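# Methods

## Microstate model

A binding site is a potential graph over 2^(R+1) microstates (R titratable
residues × one metal-occupancy flag; R ≤ 12). States are indexed
canonically — proton occupancy bits little-endian in residue-list order,
metal-free block first — and labelled S0…S(2^R−1) per block, S0 being the
fully deprotonated state. Edge parameters are the field's natural
microscopic quantities:

* protonation step of residue r in a fixed context (occupancy of the other
  residues plus the metal flag): microscopic pKa, full free energy
  ln10·(pH − pKa) in kBT;
* metal-binding step at a fixed protonation pattern: standard-state
  binding free energy βΔG⁰ = ln(K_D/c0) at c0 = 1 M, full free energy
  βΔG⁰ − ln(X/c0).

Measured edge values from heterogeneous sources are generally not
mutually consistent (cycles do not close). We therefore store per-state
intrinsic potentials βg_i obtained by minimizing the weighted sum of
squared deviations between supplied edge values and implied potential
differences — the maximum-likelihood projection onto thermodynamically
consistent models, solved through the normal equations of the edge
incidence matrix (dense Cholesky up to 1024 states, sparse factorization
above; the factorization is cached per topology so re-projection inside a
Monte Carlo step costs one matrix–vector product and two triangular
solves). The reference state (S0, unbound) is pinned at βg = 0; all
observables are invariant to this gauge choice. Edge weights default to
equal. After projection, every cycle closes exactly (< 1e−10 kBT
numerically), and observables computed from potentials coincide with the
stationary distribution of any rate assignment satisfying the same edge
free energies.

pH and concentration enter analytically per evaluation,
βG_i(pH, X) = βg_i + n_H(i)·ln10·pH − b(i)·ln(X/c0), so a single
projection serves the whole (pH, X) plane. Probabilities are evaluated in
log space (log-sum-exp), making partition sums overflow-safe at any
condition. The apparent K_d at a given pH is the free-ligand
concentration at half saturation, found by bisection on log10 X to a
relative tolerance of 1e−6.

Builders construct complete edge sets from a pairwise Hamiltonian:
per-residue intrinsic pKa's (separately for the metal-free and
metal-bound branches) plus pairwise coupling energies W (pKa units;
W > 0 anti-cooperative, W < 0 cooperative), and a single binding ΔG⁰ at
the fully deprotonated pattern — the remaining binding edges follow from
cycle closure. Energies are kept in kBT throughout; temperature
(default 298.15 K) only enters when converting to J/mol.

## Titration analysis

Constant-pH simulation output is consumed as per-residue, per-replica-pH
λ series (CSV contract; no engine-native parsing). Frames classify as
deprotonated (λ > 0.8) or protonated (λ < 0.2); intermediate frames are
excluded from both the deprotonation fraction S = N_deprot/(N_deprot +
N_prot) and the joint microstate histograms, where a frame is dropped
unless *all* residues classify. Protomer series are concatenated for
histograms (doubling the sampling) but fitted per protomer for pKa's,
reported as mean ± half absolute difference.

Per-residue pKa's come from bounded least-squares fits of the
generalized Henderson–Hasselbalch (Hill) equation
S(pH) = 1/(1 + 10^{n(pKa−pH)}), started at the pH whose S is nearest 0.5
with n = 1 and re-started on a fixed 3×3 grid if the first residual
exceeds tolerance — the procedure is fully deterministic. Saturated
curves (all S near 0 or 1) raise an unidentifiability error rather than
returning an extrapolated number; when effective pKa's are generated from
a *model* (where any pH can be evaluated), such residues are refit on a
ladder centered on their model-generated midpoint.

Strongly coupled pairs are not Hill-fittable individually. Their joint
proton count N_prot = (1−S_r) + (1−S_s) is fitted with the two-proton
coupled titration model in stepwise-association form,

    N_prot(pH) = (10^{pK1−pH} + 2·10^{pK1+pK2−2pH}) /
                 (1 + 10^{pK1−pH} + 10^{pK1+pK2−2pH}),

pK1 binding the first proton to the empty pair and pK2 the second. For
two independent identical sites with microscopic pKa p the statistical
factors give pK1 − pK2 = 2·log10 2 exactly; in the strongly
anti-cooperative limit pK1 and pK2 are the pair's two separated effective
pKa's (the assignment of pK1/pK2 to the two residue names is a labeling
convention, not physics). The coupled-model fallback triggers when a
designated pair's individual Hill residual exceeds a threshold (default
RMS 0.02); pairs default to residues sharing a tie group.

Effective pKa's of a site model are computed at X = 10⁻²⁰ M to represent
metal-free conditions. The coupling energy between residues r and s,
W = pKa(r | s deprotonated) − pKa(r | s protonated) at fixed occupancy of
the remaining residues, is read off the consistent potentials; its two
defining path decompositions agree identically by cycle closure.

## Isotherm analysis

Binding signals are fitted either with the law of mass action including
ligand depletion by the protein (the quadratic form in C_Zn, C_P and K_d)
or with the Hill equation F = F_u + (F_b − F_u)/(1 + (EC50/C)^n). Both
use bounded least squares on log-scaled concentration parameters with
deterministic restarts; plateaus F_u/F_b are free. Replicates are fitted
jointly with shared parameters by default (per-replicate fits optional).
When the fitted K_d falls below the protein concentration the assay is in
the titration rather than binding regime: the estimate carries a
tight-binding flag and its (linearized) standard error widens
accordingly. Fitted plateaus also rescale the signal to a bound fraction
in [0, 1] for downstream inference; this rescaling is our choice, as the
normalized-fluorescence-to-bound-fraction conversion is not otherwise
pinned down. As C_P → 0 the quadratic form converges to the Langmuir
isotherm (verified numerically).

Free Zn²⁺ set by a 1:1 chelator (nitrilotriacetate K_d = 14 nM, citrate
K_d = 12 µM) is the positive root of f² + f(L_T − Zn_T + K_d) − K_d·Zn_T
= 0, evaluated in the numerically stable branch; the inverse map (total
zinc required for a desired free concentration) is analytic.

## Monte Carlo inference

The inverse problem — microscopic pKa's and ΔG⁰ from macroscopic
observables — is solved by Metropolis Monte Carlo on the full edge
parameter set. Targets are either bound fractions on a (pH, X) grid or
metal-free microstate distributions over a pH ladder; the objective is
the RMSD over all target entries, equally weighted, with microstate
targets concatenating all state probabilities over all pH points (an
alternative per-pH averaging would rescale, not reorder, the objective).

Each step adds one independent draw from U(−0.2, +0.2) (pKa units or kBT
by parameter kind) to every free parameter; residues in a tie group form
edge-equivalence classes under the group's permutations and share a
single draw, so tied parameters are exactly equal in every visited state.
The trial model is re-projected to consistency before evaluation, so the
objective only ever sees thermodynamically valid models. Acceptance is
min(1, e^{−ΔRMSD/r}) with fictional temperature r = 10⁻⁴, chosen on the
order of typical per-step objective changes. Finite-temperature runs
terminate when the RMSD drops below a cutoff (defaults 0.0382/0.0447 for
microstate targets and 0.0760/0.0995 for bound-fraction targets,
according to target kind and site, all overridable); the zero-temperature
variant (accept only improvements) stops once no proposal was accepted
within a trailing 100-step window, or at 2000 steps, and is the tool for
calibrating cutoffs. Non-convergence is returned as a flag, never
silently. Ensembles of independent runs (default 50, sub-seeded
deterministically from one master seed) are summarized by per-parameter
mean and sample standard deviation — a variability indicator across runs,
not a rigorous statistical error.

Binding isotherms under-determine the microscopic model even across
several pH values; with a single target point the ensemble scatter makes
this visible rather than hiding it. Refinement therefore needs physically
sensible starting values — titration-derived pKa's and a ΔG⁰ initialized
from a measured K_d — and should be read as a data-guided correction of
those values. Initializing ΔG⁰ from an apparent K_d can be done exactly:
at fixed pKa's the apparent K_d scales as e^{ΔG⁰}, so shifting ΔG⁰ by
ln(K_d,measured/K_d,apparent(model)) matches the measurement at the
measurement pH, folding in the model's own proton-competition factor.

## Synthetic data and fixtures

The binding-data generator emulates a thermophoresis titration: per pH, a
16-point 2-fold dilution series auto-centered to bracket the ground-truth
apparent K_d by about two decades on the high side, signal from the
mass-action quadratic with plateaus 0/1, protein at 50 nM, Gaussian noise
(σ = 0.02) on the signal, three replicates, all driven by one mandatory
seed. It does not emulate thermophoresis physics, capillary artifacts,
pipetting correlations, or plateau drift — so passing recovery tests show
the estimators and inference are correct under the assumed signal model,
not that real instrument systematics are handled.

The titration generator draws a microstate per frame from the
ground-truth metal-free Boltzmann distribution on the 30-replica pH
ladder (1.5–11.5) and emits λ = 0.9 + 0.1·U(0,1) for deprotonated,
0.1·U(0,1) for protonated residues; the emission distribution is a
package invention (only the classification thresholds are physically
meaningful) placing mass firmly in the classified regions, with an
optional fraction of intermediate-λ entries to exercise the exclusion
rule. Frames are independent draws, so autocorrelation of real
trajectories is not represented.

Three documented fixtures serve tests and examples. "Site A"
(transport-site-like; D47, D51, H155, D159) carries a cooperative
His/Asp pair (microscopic pKa 5.3 for the first proton, 10.3 for the
second; W = −5) giving a steep joint titration with midpoint ≈7.8, D51
at 6.51, D47 at −0.20, a fully deprotonation-favoring bound branch, and
ΔG⁰ = −21.94 kBT calibrated so the apparent K_d at pH 7 is ≈16 nM.
"Site B" (loop-site-like; D70, H73, H77) has a symmetric, tie-constrained
histidine pair (microscopic pKa 12.07, W = +6.5) whose effective pKa's
separate to ≈12.4 and ≈5.3, D70 at 1.12, and ΔG⁰ = −26.04 kBT for an
apparent K_d ≈1.2 µM at pH 7. These parameter values are inputs taken
from published refinement results for a bacterial zinc/proton antiporter
and serve as qualitative anchors (e.g., the dominant metal-free state of
site A at pH 7.5 carries exactly two protons, on the pair); the
underlying experimental affinities and simulation pKa's cannot be
re-derived here. The "two-residue" fixture (pKa 7.0 and 6.0, both inside
the experimental pH window 5.6–7.4; bound-branch pKa 2.0; ΔG⁰ = −18.4)
is the ground truth for parameter-recovery studies.

## Recovery study design

`run_recovery_study` generates noisy binding data from the two-residue
truth (5 pH × 12 concentrations, σ = 0.02), rescales to bound fractions
via per-pH mass-action fits, and refines from a deliberately perturbed
start: pKa's offset by ±0.3 units — representative of the accuracy of
simulation-derived starting values — and ΔG⁰ initialized from the fitted
apparent K_d at pH 7 through the initial model. Fifty finite-temperature
runs at cutoff 0.0760 recover per-pH apparent K_d within ±0.3 log10
units and effective pKa's within ±0.5. Because runs halt at the cutoff,
the attainable resolution is set by the cutoff's acceptance tube, not by
the noise floor; with grossly wrong starting values the method is a
search, not a refinement, and these tolerances would not hold — which is
precisely the documented operating regime of the approach.

## Transport energetics

One antiport cycle, m H⁺ in for n Zn²⁺ out, exports net charge
z = 2n − m. With V_m = ψ_in − ψ_out (inside-negative physiological
default −80 mV),

    ΔG = RT·ln10·[m(pH_out − pH_in) + n·log10([Zn]_out/[Zn]_in)] − zFV_m,

zero exactly at the equilibrium gradient log10([Zn]_out/[Zn]_in) =
(m/n)·ΔpH + zFV_m/(nRT·ln10), ΔpH = pH_in − pH_out. The sign conventions
are pinned so that a pure pH gradient yields the 10^(m/n) rule, the 1:2
cycle is potential-independent (electroneutral), and an inside-negative
potential boosts the 1:3 cycle (10^4.35 ≈ 10^4.4 at ΔpH = 1, −80 mV,
298.15 K) while opposing 1:1. Temperature defaults to 298.15 K; the
10^4.4 figure is insensitive to the 293–303 K range at one-decimal
precision.

## Numerical choices and limitations

* Probabilities, bound fractions, and the MC objective all evaluate in
  log space; no partition sum is formed in linear scale.
* Curve fits use `scipy.optimize.least_squares` with box bounds,
  log-parameterized concentrations, fixed starting rules and fixed
  restart grids; identical inputs give identical outputs.
* Ensemble runs are scheduled sequentially with `SeedSequence.spawn`
  sub-seeds, making whole ensembles bitwise reproducible.
* Equilibrium only: no kinetics, rates, or conformational-cycle
  modeling; the transport-energetics module deliberately excludes
  rate-enhancement arguments.
* The pairwise-coupling builders cannot express three-body protonation
  couplings; arbitrary couplings can still be supplied as explicit
  edge lists.
* Tie groups assume full permutation symmetry of their members'
  microscopic parameters, including mirrored contexts.
* Model extrapolations outside the pH/concentration range of the data
  used for refinement inherit no experimental constraint and should be
  treated as such.
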