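# Methods

## The model

A virtual cell carries a circular genome of genes in three functional
categories: transcription factors (TFs), metabolic enzymes and membrane
pumps. Metabolism involves two molecules: a resource A, present outside the
cell at concentration `A_ext`, and an energy carrier X produced from A.
Five protein-mediated processes and passive diffusion define the
intracellular dynamics (concentrations `A`, `X`, protein levels `P_i`):

    dA/dt = permeability * (A_ext - A) + sum(v_pump) - sum(v_cat) - sum(v_ana)
    dX/dt = conversion_rate * sum(v_cat) - sum(energy_cost * v_pump) - sum(v_ana)
    dP_i/dt = expression_i - degradation * P_i

with saturating kinetics

    v_cat  = k_cat * P * A/(K_A + A)                      (catabolic, A -> X)
    v_ana  = k_cat * P * A/(K_A + A) * X/(K_X + X)        (anabolic, A + X -> sink)
    v_pump = k_cat * P * A_ext/(K_Aext + A_ext) * X/(K_X + X)   (import, costs X)

These single- and bi-substrate Michaelis–Menten forms are the minimal
kinetics consistent with the described reactions; the anabolic product is a
sink (no explicit building-block pool), there is no cell volume or growth
dilution, and protein synthesis itself consumes nothing. One consequence
worth knowing: because expression is thermodynamically free, large genomes
carry no direct expression cost — selection against genome size acts only
through mutational load, which is what makes long-term streamlining a
population-genetic effect rather than a physiological one.

### Regulation

Binding is discrete: a TF regulates exactly the genes whose promoter
operator is identical to its binding motif (no mismatch tolerance). Motifs
are length-L words over an S-letter alphabet; the data structures default to
L=12, S=2, while the genome generators default to L=5 so that random
15–60-gene genomes start with a handful of regulatory edges (match
probability 2^-L per TF–promoter pair) and single-symbol flips can rewire
the network on evolutionary timescales. Exact matching is a deliberate
model property, not a simplification: graded partial matching would permit
subfunctionalization of TF target sets, which this model intentionally
excludes.

Ligand binding (a TF senses internal A or X) and TF–promoter binding are
fast and treated in quasi-steady state. A regulator contributes

    w = occ * (b * effect_bound + (1 - b) * effect_free),
    b = ligand/(ligand + K_ligand),
    occ = P_tf / (K_op + sum of P over the promoter's regulators)

to the log-expression of its targets: `rate = basal * exp(sum w)`. The
exponential form keeps rates positive and lets effects be signed and
state-dependent (a TF can activate when ligand-free and repress when bound).
The occupancy is competitive: a promoter carries exactly one operator, so
all TFs matching it share one binding site and one saturation denominator
(K_op = 1 concentration unit by default); with a single regulator this is
the familiar P/(P + K_op). Competition is not a detail — under an additive
independent-occupancy form a WGD would double every regulatory input, so
deleting one copy of a strongly connected TF pair would *restore* tuned
regulation and be selected for, inverting the dosage-balance retention this
model is meant to exhibit. With shared-site occupancy a WGD leaves
saturated regulatory inputs nearly unchanged (both copies share the site)
while still doubling enzyme and pump dosage, which is the regime in which
dosage balance can act on gene loss.

### Fitness

Homeostasis is the only criterion. At steady state the relative deviations
`dev_A = |A - target_A|/target_A` (likewise X) give a per-environment score
`1/(1 + dev_A + dev_X)` in (0, 1]; cells whose dynamics do not converge
(oscillation, divergence) score 0, since failing to settle is failing
homeostasis. A cell experiences 1–3 external-resource conditions per
lifetime; its fitness is the geometric mean of the scores — non-decreasing
in each score and severe on failure in any single condition, which is what
selects for regulation rather than a fixed compromise phenotype.

The standard environment is `A_ext=1.0, permeability=0.3, degradation=0.5,
conversion_rate=1.0, target_A=0.3, target_X=0.3` (arbitrary concentration /
time units). Targets below the external resource level make regulated
import-and-burn metabolism non-trivial at both low and high resource.

### Numerical integration

Every state variable has the form `dy/dt = production - loss_rate * y` with
state-dependent coefficients, so the integrator uses exponential
(linearly-implicit) relaxation steps toward the local equilibrium
`production/loss_rate` for A, X and all proteins. The scheme is
unconditionally stable, and its fixed points are exactly the fixed points of
the ODEs, so converged steady states do not depend on the step size (the
test suite checks agreement at 1e-6 relative between step sizes). Default
step cap 0.2 time units, time cap 1000, convergence when the largest
relative derivative falls below 1e-9. The evolutionary loop uses a cheaper
profile (step cap 1.0, time cap 150 ≈ 75 protein half-lives, tolerance 1e-6)
and warm-starts each offspring from its parent's converged state — again
only speed, not the fixed point, depends on these choices. Genuinely
oscillating cells never meet the tolerance and score 0.

## Mutation

Rates per cell per generation at the reference genome size G_ref = 50,
scaling linearly with gene count (constant per-gene rates):

| event          | probability | notes                                   |
|----------------|-------------|-----------------------------------------|
| duplication    | 0.024       | tandem copy of a circular segment       |
| deletion       | 0.024       | segment removed                         |
| translocation  | 0.048       | segment excised, reinserted uniformly   |
| WGD            | 0.003       | per cell, size-independent              |
| point          | 0.0096/gene | = 5 x large-scale events at G_ref       |

Segment lengths are uniform on [1, ceil(n/4)] ("up to a quarter of the
genome"). The quoted duplication/deletion rate is taken as 0.024 each, and
the large-scale rates as per-cell probabilities at G_ref — this is the one
reading that reconciles the fixed quoted numbers with constant per-gene
rates. At most one attempt per operator per generation (Bernoulli); at
these rates multi-event corrections are negligible and replay stays simple.

A point hit picks one mutable attribute of the gene uniformly: continuous
parameters take a log-normal step (sigma 0.3), motifs/operators flip one
random symbol, the TF ligand toggles, and TF effect values take an additive
Gaussian step (sigma 0.5) so regulation signs can change. Pump energy cost
is fixed at 0.5 X per imported A (with conversion 1.0 this makes
pump-then-catabolize a net energy source, a prerequisite for viable
metabolism; evolving the cost itself is out of scope).

Every event logs a payload sufficient for exact deterministic replay of the
child from the parent; lines of descent are reconstructed from snapshots
plus replay and verified against stored snapshots.

### Ancestry bookkeeping

Two tag systems ride on genes. `ancestry_tag` marks descent from a stamped
reference genome; it is copied to every duplicate, and analyses apply the
"one random copy is the original" rule so duplicates never inflate conserved
content. `wgd_tag = (pair, member)` is assigned at WGD — both copies of a
gene share a pair id and get member 0/1 — and is likewise copied by later
segmental duplications, so post-WGD duplicates are attributed to their
member without counting as extra WGD genes. A pair is an intact ohnolog
while both member lineages survive; a member whose partner's lineage has
died is a single, permanently (lost tags are never re-created).

## Populations and protocol

Wright–Fisher with fitness-proportional sampling: each generation all N
cells are scored on their own lifetime resource draws, N parents are drawn
with replacement proportionally to fitness, and each offspring is a mutated
copy. If every cell scores 0 (as can happen right after a harsh
environmental change) parents are drawn uniformly, avoiding extinction
deadlock. Population size never changes (full-scale default N=1024).

Lifetime resource draws use a symmetric log-spaced 5-level grid spanning the
fluctuation range (default 0.1–10x standard). A discrete grid rather than
continuous log-uniform sampling is the package's choice: it preserves the
log-mean and the selective pressure for regulation while making
steady-state evaluations cacheable per (genome, level) — the difference
this makes to the evolutionary dynamics is the granularity of the
environment distribution, not its range or symmetry. Continuous sampling
remains available (`n_levels=None`). The high-fitness cutoff (0.85) is
evaluated on a fixed three-level reference subset (standardized fitness), so
the protocol trigger is deterministic given the genome.

The perturbation panel takes five global parameters (permeability,
degradation, conversion rate, both targets), assigns each a low and a high
level (defaults: degradation x4 and /4, the others x2 and /2 — inside the
stated 2–4x bracket, with the severest change on degradation), and
enumerates all C(5,3) x 2^3 = 80 ways of setting exactly three parameters
to non-standard levels.

## Post-WGD analyses

Lines of descent are traced from one individual of the final population —
the fittest by default (configurable) — back to generation zero through the
stored parent pointers, with genomes reconstructed by event replay and
checked against snapshots. Retention fractions are intact-ohnolog genes
over all surviving ancestral WGD genes, per category, in 1000-generation
bins. The uniform null model
replays the per-bin, per-category loss counts observed on the matched line
of descent, deleting members uniformly at random without selection; the
connectivity-binned variant weights TF deletions by the per-bin loss
likelihood of the member's ancestral relative-outdegree bin (quintiles by
default), estimated from the evolutionary runs themselves. Binding-site
conservation scores a surviving TF member 1 if a randomly chosen surviving
copy kept the ancestral motif, else 0; relative outdegree is the mean
ancestral outdegree of retained TFs over the mean of all ancestral TFs.
Group comparisons use two-sided (or one-sided where a direction is
pre-specified) Mann–Whitney rank-sum tests over per-run scores, exact null
distribution when there are no ties.

## Desk-scale campaign

The full-scale experiments (100 populations x 1024 cells x 15000
generations, plus 800 perturbation runs) are reproduced in scaled-down form
by `virtualcell.experiments.run_campaign`: 10 replicates of N=100 cells,
founding genomes of 12–18 genes, resource fluctuation 3.16x either way
(narrower than the full default range, chosen to keep scaled runs in the
regime where regulation evolves within hundreds of generations), stage-1
adaptation of 600 generations, then three arms of continued evolution from
the same adapted population: a 3000-generation neutral continuation (one
fifth of the full-scale 15000-generation neutral horizon, for streamlining
and long-run gene-content turnover), a 1000-generation re-adaptation arm
with an environmental change (degradation and both targets high — the
dosage-sensitive regime) and a WGD fixed in every cell at the change point
(providing a clean WGD reference for the retention analyses), and a
500-generation re-adaptation arm with an environmental change but no
imposed WGD, in which each replicate draws a *different* member of the
80-environment panel — spontaneous WGD fixation frequency is a property of
the whole change set, not of one favourable environment. Bin width stays
at 1000 generations.

Because expression is cost-free, adaptive genome expansion is unbounded in
this model and occasionally runs into the hundreds of genes; the scaled
campaign therefore imposes an explicit carrying constraint of 60 genes
(genomes above it are inviable), doubled to 120 in the post-change arms so
the per-ploidy limit is unchanged after a WGD. This keeps the scaled runs
in the small-genome regime the analyses target; it truncates the upper tail
of the expansion dynamic, which is the main thing the scaled campaign gives
up relative to an uncapped run.

What the scaled campaign does and does not show: trend-level reproductions
(fitness increase, streamlining after expansion, over-retention of TF
ohnologs versus the uniform null, connectivity bias of retained TFs,
minority spontaneous WGD fixation, majority ancestral-content loss) are
meaningful at this size; the full-scale headline figures (≈30% WGD lineages,
≈two-thirds content loss) emerge from 15000-generation runs at N=1024 and
are only expected to match in direction here, and the carrying constraint
above additionally truncates the expansion phase that precedes streamlining
at full scale.

## Known limitations

* No hybridization/allopolyploidy (WGD is strict autopolyploidization), no
  biased fractionation, no spatial structure, no mutation-rate evolution.
* Text-level supplementary material of the original model (exact ODE forms
  and the standard-environment table) was not available; the kinetic forms
  and parameter values above are this package's own calibration, chosen once
  and fixed. Quantities that depend on them (absolute fitness values,
  adaptation speeds) are therefore not comparable number-for-number with
  full-scale results, while the combinatorial and bookkeeping results (panel
  size, WGD doubling, replay, null expectations, rank-sum comparisons) are
  exact reimplementations.
* The random-genome generator seeds category proportions 40/40/20 and
  log-uniform kinetic parameters; real runs of the original model started
  from different random ensembles, so early-generation dynamics are only
  qualitatively comparable.
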