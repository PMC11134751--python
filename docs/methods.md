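# Methods

This note documents the models, numerical choices and design decisions
behind `tubigem`, and what the synthetic study conditions do and do not
establish about organism-scale data.

## Model representation

A metabolic model is a list of compartmentalised metabolites (four
compartments: extracellular `e`, cytosol `c`, mitochondria `m`,
peroxisome `x`), reactions with signed stoichiometries and flux bounds in
mmol gDW⁻¹ h⁻¹, a gene set, Boolean GPR rules and one objective reaction.
Structural invariants (unique ids, declared metabolites, `lb ≤ ub`,
resolvable objective) are enforced at construction. Classification rules:
a reaction is a *transporter* iff its participants span ≥ 2 compartments;
an *exchange* iff it has a single extracellular participant; a *boundary*
iff it has a single participant of any compartment (demands/sinks). In
the compartment statistics a reaction is counted in every compartment it
touches, so transporters contribute to both endpoints ("reactions in X +
transport reactions"); metabolites belong to exactly one compartment, so
those counts are additive. Enzyme complexes are counted as the distinct
all-of gene sets of the DNF of each GPR, deduplicated model-wide — the
conservative set-level reading of "complexes included in the network".
Where a model's declared metabolite total and the per-compartment sum
disagree (as happens in published model tables), both numbers are
reported side by side; nothing is reconciled silently.

GPR grammar: gene ids, `and`/`or` (case-insensitive), parentheses; `and`
binds tighter than `or`. Evaluation is plain Boolean semantics over a
gene-presence set; tests verify the parser and evaluator against
exhaustive truth tables for trees up to 10 leaves.

## Curation procedures

*Dead ends.* A metabolite is a dead end if, considering reversibility, it
can only be produced or only consumed. A reversible reaction counts as
both producer and consumer; boundary reactions count as both. One
refinement: a metabolite whose only connection is a single internal
reaction is a dead end even when that reaction is reversible, because a
lone reversible connection has no net sink at steady state. Pruning
removes every reaction touching a dead end, iterating to a fixed point;
the objective and all boundary reactions are never removed, and the
procedure refuses (with a diagnostic) if the objective itself touches a
dead end, since that indicates a gap to fill rather than content to
delete. Because a dead-end reaction can carry no steady-state flux,
pruning provably never changes the FBA optimum; the test suite checks
this and checks equivalence with a brute-force remove-one-recheck oracle
on 50 random networks. Cofactor-specificity curation (e.g. dropping the
NADH variant of a reductase) is data-level editing — a reaction-id patch
list — not an algorithm, and is out of scope here.

*Generic reactions.* A metabolite without a formula, or with an
R-group/asterisk placeholder, has no exact mass; every reaction touching
one is flagged for replacement with specific chemistry.

*Balance and producibility.* Elemental balance is checked per reaction
from parsed formulas; boundary and biomass reactions are intentionally
unbalanced and listed as skipped rather than failed. Biomass-precursor
producibility opens a temporary demand per biomass substrate on a given
medium and calls a precursor producible when its maximal demand flux
exceeds 10⁻⁶ mmol gDW⁻¹ h⁻¹ (the LP noise floor). Blocked reactions are
those whose FVA range is {0} on the medium.

## Biomass objective

Measured bulk fractions (g/gDW) of seven components — DNA, protein,
lipid, cell wall, RNA, ash, soluble pool — are combined with a monomer
table (monomer ids, molar fractions summing to 1 per macromolecule,
residue masses in g/mmol) into consumption coefficients
`fraction × molfrac / residue_mass` (mmol gDW⁻¹), producing one unit of
biomass. Both measured morphologies (filamentous and pelleted) ship as
data; the pelleted column is the default because pelleted growth is the
relevant morphology for citric-acid production. Growth-associated ATP
hydrolysis is a configurable coefficient (default 30 mmol gDW⁻¹, the
usual magnitude for filamentous fungi; the reference equation's value is
not published, so this is an explicit config value). Ash is modelled as a
phosphate drain and the pool as a glucose-equivalent drain — single
pseudo-metabolite drains with configurable composition. Vitamins and
trace cofactors are excluded: they do not contribute measurably to dry
weight. Monomer-level splits are a user-editable table; the default
single-pseudo-monomer table is deliberately minimal and is what the toy
network uses. Phosphorus content of the biomass (mmol P gDW⁻¹) is the
negated signed sum of coefficient × P-atoms, so the GAM currency cycle
(ATP → ADP + Pi) cancels exactly.

## FBA layer

The LP `max c·v` s.t. `S·v = 0`, `lb ≤ v ≤ ub` is solved through
cobra/optlang with GLPK. Only the objective value is treated as unique;
flux vectors are one optimal vertex and are never asserted unique.
Infeasibility and unboundedness are reported in the solution status,
never raised from `optimize`. Gene deletions close (0, 0) every reaction
whose GPR evaluates false without the gene, using this package's GPR
semantics rather than the solver's. Phenotype simulation closes all
carbon exchanges (identified by carbon-containing formulas), opens one
source at 10 mmol gDW⁻¹ h⁻¹ and calls growth at μ > 10⁻³ h⁻¹; both
numbers are configurable since assay-matched uptake rates are rarely
known. A source without an exchange reaction yields a `no_exchange`
category, not an error — missing uptake routes are themselves a finding
in model validation.

## Dynamic FBA

The integrator is the static-optimisation approach: at each step the
extracellular state sets uptake bounds, one LP is solved, and explicit
Euler updates the state (default dt = 0.1 h, with a refinement check in
the tests: halving dt moves endpoints by < 1 %).

Kinetic rules, with units:

| parameter | meaning | default |
|---|---|---|
| `vmax_glc_high`, `km_glc_high` | high-affinity glucose uptake (mmol gDW⁻¹ h⁻¹, g/L) | 2.0, 0.1 |
| `vmax_glc_low`, `km_glc_low` | low-affinity term, active above the threshold | 1.0, 15 |
| `glc_low_affinity_threshold` | g/L | 75 |
| `vmax_xyl`, `km_xyl` | transporter-mediated xylose uptake | 1.0, 1.0 |
| `xyl_repression_threshold` | mM glucose above which the transporter is off | 5 |
| `k_passive_xyl` | passive xylose influx per g/L | 0.005 |
| `ngam` | maintenance ATP, mmol gDW⁻¹ h⁻¹ | 1.9 |
| `t_start` | simulation start after inoculation, h | 10 |
| `vmax_pi` | phosphate uptake cap while P > 0 | 0.3 |

The thresholds (5 mM, 75 g/L), NGAM (1.9) and start offset (10 h) are the
published switching rules; the remaining Vmax/Km values are config-driven
defaults chosen once to give realistic *Aspergillus* fermentation
time-scales (glucose uptake ≈ 2 mmol gDW⁻¹ h⁻¹, slow passive xylose
leakage), since the source kinetic table is supplementary-only. Passive
xylose uptake is assumed linear in concentration and is configurable.
Phosphate uptake is demand-driven under a Vmax cap until depletion —
no published kinetics exist for it in this context. Unit conventions are
centralised: sugars and citrate in g/L, phosphate in mM, the glucose
threshold compared in mM via M = 180.16 g/mol (5 mM ≈ 0.90 g/L).

Objective policy: maximise growth; when optimal μ < 10⁻⁴ h⁻¹ (phosphate
exhausted) switch to maximising citrate secretion under the same uptake
bounds. The two-phase policy is configurable (`"growth"` disables the
switch) and the active phase is logged per step. An infeasible LP (NGAM
unsatisfiable after substrate exhaustion) truncates the trajectory
cleanly with the reason recorded — never zero-padding, never negative
concentrations. Euler overshoot past zero is clamped at zero and logged;
the carbon-recovery diagnostic reports NaN on clamped steps because the
truncated delta is not a conservation statement there. States before
`t_start` are reported as constant at the initial values by the plotting
helper, so figures span from inoculation.

`FermentationModel.fit` estimates selected kinetic parameters by
nonlinear least squares on concentration time series, normalising each
species by its data range. Discrete events (phase switches, depletion
crossings) make the objective piecewise smooth, so a coarse
multiplicative grid (7 log-spaced points per parameter, factor 2 each
way) locates the basin before the derivative-based polish; the fit
integrates at dt = 0.25 h, which removes event-quantisation bumps that a
coarser step introduces. Standard errors come from the Gauss–Newton
covariance `(JᵀJ)⁻¹·2·cost/dof`.

## Synthetic study conditions

The toy network (~60 reactions, 4 compartments) lumps glycolysis,
pentose catabolism (3 xylose → 5 pyruvate), TCA (pyruvate → 5 NADH +
3 CO₂), oxidative phosphorylation (P/O = 2), citrate synthesis
(2 pyruvate + ½ O₂ → citrate), a peroxisomal β-oxidation branch, and
monomer syntheses feeding a measured-composition biomass equation. All
coefficients are small integers and every non-boundary, non-biomass
reaction is elementally balanced, so LP optima are hand-checkable and
carbon recovery in dFBA is exact to integration tolerance. The fixture
deliberately contains substrates that are transported and interconverted
but never catabolised (blocked but not dead ends), a false-positive and a
false-negative phenotype source, and optional decoy dead-end appendages,
so each QC procedure has designed positives and negatives.

The default fermentation condition is 80 g/L glucose + 40 g/L xylose,
2 mM phosphate (the level of a 0.27 g/L KH₂PO₄ medium) and a
0.05 gDW/L inoculum, simulated from 10 h to 130 h. Synthetic datasets
subsample ~10 time points, 3 replicates, multiplicative Gaussian noise
(CV-parameterised, truncated at 0), all seeded.

What passing tests show: the machinery is internally consistent, agrees
with independent oracles, conserves mass, and recovers known parameters
from clean synthetic data. What they do not show: predictive accuracy on
organism-scale models (thousands of reactions, extensive blocked
subnetworks, annotation noise), identifiability of multi-parameter
kinetic fits from real, sparse, heteroscedastic fermentation data, or the
biological correctness of any specific lumped pathway. Statistics checks
against a published organism-scale SBML activate automatically when such
a file is placed next to the repository.

## Known limitations

* Euler integration only; no adaptive step, though dt is a config value
  with a convergence check in the tests.
* No pH, dissolved-oxygen or morphology modelling in the fermentation.
* Dead-end pruning is topological; it does not attempt MILP gap-filling.
* The tabular dialect assumes `name[compartment]` tokens and will not
  parse arbitrary published workbook layouts without adjustment.
* The phenotype medium is a single generic minimal-salts assumption; no
  assay-specific media compositions are modelled.
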