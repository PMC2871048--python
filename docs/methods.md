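# Methods

This note records the models implemented by the package, the parameter
choices that matter, and what the synthetic studies do and do not
demonstrate.

## Network model and SBML exchange

A network holds typed molecular species (gene, transcript, protein,
protein complex, metabolite) and typed interactions (transcription,
translation, metabolic reaction, complex assembly, transport, exchange).
Interactions carry physical stoichiometry (substrates/products, positive
coefficients) and a separate controller list for species that are
required but not consumed — the gene of a transcription, the transcript
of a translation, the catalyzing enzyme of a reaction. Internal ids are
namespaced (`g:`, `tr:`, `p:`, `cx:`, `m:`, `ix:`) so the species and
interaction id spaces cannot collide.

SBML export uses Level 3 Version 1, fixed for deterministic round trips.
Plain SBML does not distinguish the five layers, so each species carries
a controlled annotation attribute with its layer type (plus its sequence
and verbatim internal id); controllers are encoded as modifier species
references, never as reactants, so stoichiometry stays physical.
Database cross-references are emitted as MIRIAM-style `identifiers.org`
URIs in CV terms. On import, foreign documents without layer annotations
are mapped to metabolites, one warning per species; non-identifiers.org
resources are retained as opaque xrefs. A finalized network contains no
reversible interactions; the flag exists only for pre-split inputs.

The source literature reports two slightly different totals for the
deposited yeast reconstruction (67,228 objects in its summary table,
67,288 variables before classification preprocessing); the discrepancy
is unexplained there and is not reconciled here — `read_sbml` simply
reports what it finds.

## Reconstruction rules

* Sequence identity is exact string equality after uppercasing and
  whitespace removal; there is no alignment or tolerance. Gene identity
  uses the first-to-last-exon nucleotide sequence, transcript identity
  the coding sequence, protein identity the amino-acid sequence; fixture
  files supply these sequences directly.
* One transcription per (gene, transcript) link — a transcript merged
  from k genes receives k transcriptions — and one translation per
  transcript. Proteins documented without any transcript are retained as
  orphan species with no producing interaction.
* EC matching treats trailing-dash fields as wildcards (database exports
  contain partial ECs). A separate reaction interaction is created per
  (reaction record, capable protein) pair; records matching no protein
  are kept as uncatalyzed interactions by default (`include_uncatalyzed`
  selects the alternative of dropping them, since the source account is
  ambiguous on whether such reactions entered the Boolean analysis).
* Protein complexes never catalyze reactions. Duplicate PPI records are
  deduplicated by the sorted tuple of member ids; no containment-based
  merging of member subsets is attempted. Assemblies are irreversible
  (no disassembly interaction).
* Reversible reactions are split into `:fwd`/`:rev` copies sharing
  controllers.

## Boolean damage semantics

The rule system (interaction = AND over required species, species = OR
over producing interactions) is evaluated as the greatest fixed point
below the all-feasible state: a knockout clamps the listed genes
infeasible, everything else starts feasible, and only blockage
propagates. This matches the initialization "all others feasible",
guarantees a unique order-independent result, and prevents
self-sustaining metabolic loops from being spuriously blocked. Root
species (genes, medium-like metabolites without producers, orphan
proteins) remain feasible unless explicitly knocked.

The implementation is a worklist algorithm (O(edges) per knockout); a
quadratic full-sweep reference implementation with shuffled evaluation
order exists alongside it and the test suite asserts both reach the same
fixed point on random networks, together with monotonicity in the
knockout set.

Ubiquitous currency metabolites (water, ATP, ...) are *not* removed from
requirement sets by default; `compile_boolean_model` exposes an opt-in
exclusion list, visible in the compiled model, because the appropriate
treatment is data-dependent and silent exemption would change damage
sizes invisibly.

Structural consequences used as checks: every single-gene knockout
blocks the gene and its transcriptions (probability 1, one each); at
most one protein can be blocked per single knockout (proteins are
produced only by translations, one protein each); the minimum possible
damage is 4 objects (gene, transcription, transcript, translation) and
occurs exactly when the protein survives through a second production
route. A gene sharing its coding sequence with another gene has damage
of size 2 (gene + transcription — the merged transcript survives via the
OR rule), so the four-object floor is exhibited on networks whose
redundancy is at the protein level, not the transcript level; the
minimum-damage check therefore generates with `p_duplicate_cds = 0`.

## Flux-balance damage

Blocked-reaction detection follows the standard reading of "cannot carry
flux": per reaction, maximize then minimize its flux subject to
steady state (S·v = 0) and bounds; blocked iff both optima are within
1e-9 of zero. Open bounds use magnitude 1000. The zero flux vector is
always admissible, so the base LP is feasible by construction. LPs are
solved with scipy's HiGHS interface; the test suite cross-checks the
blocked sets against cobrapy's independent FVA-based finder on random
toy models.

Exchange reactions are written with their single metabolite as
substrate: positive flux secretes, negative flux takes up; "open for
uptake" means a negative lower bound. Unconditional damage opens every
exchange in both directions (this subsumes aerobic conditions — oxygen
uptake is open like everything else), disables GPR-false reactions, and
computes blocked reactions and then blocked metabolites with every
exchange counted as an uptake route. Reactions blocked with no knockout
at all (pathway dead-ends) form a constitutive baseline, reported
separately; knockout damage is net of this baseline, so it captures only
the *additional* blockage. Compartments are labels on metabolites;
unique-object counting collapses compartment copies.

## Essentiality scoring

Variables with identical feasibility columns over all N knockouts are
merged before scoring (no phenotype information is used); the merge is
lossless via the recorded groups, and a merged variable's score equals
the score any member would get individually. Scores of never-blocked
variables are reported as missing, never zero — zero would falsely
assert evidence of dispensability. `unconditionally_essential` filters
on score = 1 with a `min_support` knob (default 1) because scores backed
by few blocking experiments are biased toward 1.

Conflicting phenotype labels for one strain id are resolved by majority
vote; ties keep viable with a warning (discarding weak lethality
evidence rather than inventing it). Synthetic-rescue style annotations,
where fixtures include them, map to the viable class; fixtures must
declare their convention.

## Classification

The classifier is scikit-learn compatible: feature selection (training
essentiality score strictly greater than 0.5) followed by an SVM with a
linear kernel and soft-margin constant C = 1. The source account
specifies only "maximum margin"; a soft margin is required for noisy
real data and C is exposed. Samples exactly on the hyperplane are
predicted viable (conservative toward the majority class). If no
variable passes selection the classifier predicts the training majority
class with a warning. Hold-out evaluation draws fixed class counts
without replacement into training (class-count control, not
proportion-preserving stratification, matching the fixed
lethal/non-lethal training design), tests on the remainder, and is fully
reproducible from its seed. Omics-ablation experiments are pipeline
configurations, not code: rebuild the feasibility matrix from a network
generated without the metabolic or protein-interaction layer (set the
corresponding generator counts to zero) and rerun the evaluation.

## Synthetic data: what it emulates and what it does not

Defaults approximate the proportions of the yeast network: ~0.12
metabolites and ~0.35 reaction records per gene, two PPI records per
protein, complex sizes with median 2 and a geometric tail capped at 99,
hub-skewed (Pareto-weighted) complex membership, 88% of reactions
enzyme-catalyzed, 2.5% orphan proteins, 1% duplicate coding sequences
and 1% redundant protein routes (the latter reproducing the observed
0.99 protein damage probability). A default study plants 25 essential
objects (drawn uniformly over all blockable objects, hence across
types) and contains 5,000 strains: one single knockout per gene plus
4,500 doubles and 250 triples — the single/double/triple mix of the
experimental compendia, scaled to desk size.

Phenotypes are generated by the rule "inviable iff the Boolean damage
intersects the planted set", optionally flipped with probability
`label_noise`. This makes the noiseless study exactly separable and is
deliberately the inverse of the inference the scoring stage performs, so
ground-truth recovery (every reachable planted object scores 1.0;
hold-out TPR 1, FPR 0) is a meaningful end-to-end check. It does *not*
emulate condition-dependent lethality, partial growth defects, or
epistasis beyond damage-set union, so passing these tests demonstrates
correctness of the machinery, not predictive performance on real mutant
compendia; with realistic label noise the measured TPR/FPR trends (TPR
rising with training-set size; TPR and FPR rising with the inviable
training fraction) are qualitative, not calibrated.

Problem sizes used in the checked experiments — 250-gene networks
(~2,400 objects), 5,000-strain studies, 3,000-sample training sets, toy
stoichiometric models of 8 metabolites and 12 reactions — were chosen so
a full analysis runs in seconds to minutes on one CPU while keeping
every structural feature (merging, redundancy, hubs, exchanges)
represented.

## Known limitations

* Sequence identity only; no alignment, so near-identical isoforms stay
  distinct.
* The Boolean model has no notion of quantity, kinetics or regulation;
  transcriptional regulation is absent by design.
* Blocked-reaction analysis is per-reaction LP probing — exact but
  quadratic in model size; genome-scale models are tractable only with
  batching or warm starts, which are not implemented.
* The deposited-model object-count check requires an external download
  and cannot run offline.
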