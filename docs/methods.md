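# Methods

## Data model and coordinates

All positions are 1-based indices into the protein sequence, so "S33"
means serine at position 33.  Accessions are treated literally: isoform
suffixes ("P04637-2") denote distinct proteins and are never collapsed,
and PTM sites annotated to protein groups (peptides shared by homologs)
stay attached to the representative accession given in the input table.
Mutation records are missense only — synonymous rows, nonsense (`*`) and
non-standard residues are dropped at parse time with a reasoned rejection
report, and duplicate (protein, position, wt, mut, sample) rows collapse
to one so that downstream counts are per-sample, never per-call.

## Hotspot mutation score

A protein with n mutations over k distinct mutation types — exact
(position, wt, mut) triples, so R248W and R248Q are different types — has
type frequencies fᵢ = nᵢ/n, Shannon entropy S = −Σ fᵢ ln fᵢ, uniform
reference S₀ = ln k, and hotspot score ΔS = S₀ − S, reported in nats.
Properties relied on throughout: 0 ≤ ΔS ≤ ln k; ΔS = 0 iff the
distribution is uniform; ΔS is Schur-convex, i.e. concentrating counts
never lowers it.  Scores with |ΔS| < 1e−12 are clamped to exactly 0 to
absorb float noise, which makes the k = 1 and uniform cases exact.

Two deliberate readings of under-specified conventions: occurrences nᵢ
count *distinct samples* (a tumor contributes at most once per type), and
S₀ uses the *observed* k, not a theoretical alphabet of possible changes.
A protein with a single highly recurrent mutation type has ΔS = 0 by the
formula; driver enrichment is therefore gated not by ΔS but by the
recurrence filter, which keeps mutation types seen in ≥ `min_tumors`
distinct samples (default 3).  Per-cancer-type scores are the same
pipeline run on records grouped by context label.  Mutation density is
n/length with its natural log for plotting; a generic two-sided
Mann-Whitney utility supports recurrence-vs-score comparisons without
claiming any bespoke statistic.

## Mutation–PTM intersection

Position-coincident (mutation, site) pairs partition into `direct_loss`
and `mimic`; flank hits (1 ≤ |offset| ≤ 5 by default) are a disjoint
relation, so site destruction is never double-counted as rewiring.  The
mimic rule is restricted to phosphorylation: S/T/Y phosphosite with
mutant residue D or E.  Acidic substitutions at acetyl/methyl/ubiquityl
sites have no mimic interpretation and remain direct losses.  A mutation
landing on a residue with several PTM annotations fans out into one
record per site.  Wild-type residues disagreeing with the site table at
the same position raise a data-inconsistency error rather than being
silently reconciled.

Expected mutated sites per (residue, PTM type) category are the product
of the number of mutations observed on that residue letter anywhere and
the proportion of that letter's proteome residues that carry a site of
the category.  Significance uses a two-tailed Fisher exact test on a 2×2
table counted over distinct proteome residue positions: rows = site vs
non-site residues of the letter, columns = carrying ≥ 1 mutation vs none.
The exact construction of this table was a genuinely open design choice;
this one mirrors the residue-proportion logic of the expected-value
formula.  The two-tailed p sums hypergeometric point probabilities not
exceeding the observed table's probability, with a relative tie tolerance
of 1e−12; it is validated against an exhaustive exact-rational oracle and
against `scipy.stats.fisher_exact`.  Raw p-values are reported by
default; Benjamini–Hochberg adjustment across categories is optional and
off by default.

## Kinase-motif rewiring (delta scores)

For each flank hit the ±7-residue window around the phosphosite is
extracted, padding beyond the termini with 'X' which scores a neutral 0,
so truncated flanks are comparable to full ones.  The mutant flank is the
wild-type flank with the single substitution applied at index
`half_width + offset`.  Scoring is additive over offsets:
score = Σ weights[offset, residue].  delta = score(mut) − score(wt), so
only the matrix column at the mutated offset contributes — the algebraic
identities (antisymmetry under wt/mut swap, invariance to perturbations
at unmutated offsets) are property-tested.

Orientation: higher score = stronger predicted binding.  Matrices
exported from tools with the opposite convention (lower score = better)
must be imported with `score_orientation=-1`.  "Minimum stringency" is
implemented as: no percentile threshold — every (site, mutation, kinase)
triple is scored.  An empirical background calibrator (score percentile
over all candidate-site flanks in the proteome) exists for optional
stringency filtering at user-chosen percentiles.

Sign agreement between two predictors inner-joins on (site protein, site
position, mutation type, kinase) and counts same-sign deltas.  Zero
deltas are neither gain nor loss: they are excluded from numerator and
denominator and reported separately.

## Substitution spectra

Counts of each missense change are grouped by wild-type residue (every
record counted exactly once — conservation is asserted) or by impacted
PTM class, where a mutation on a residue bearing two PTM classes
contributes to both rows and the fan-out count is reported.  Rows are
normalized to proportions; zero rows are flagged, not divided.  Rows and
columns of the one normalized matrix are clustered independently with
complete-linkage agglomeration on Euclidean distances (the common heatmap
default); leaf order is deterministic with ties broken by input order.
Output is the ordered matrix plus linkage trees serialized as
nested-bracket text; rendering is left to plotting tools.

## Synthetic data

The generators emulate the statistical shape of the real inputs rather
than their content.  Defaults, chosen once as desk-scale study
conditions:

* proteome: 120 proteins, lengths ~ Normal(400, 100) clipped at 50,
  i.i.d. residues (uniform by default; a human-like composition preset
  exists for enrichment tests where residue abundance matters);
* PTM sites: per-residue Bernoulli rates with phosphoserine most common
  (S 0.08, T 0.03, Y 0.03 phospho; K 0.05 ubiquityl, 0.02 acetyl, 0.01
  methyl; R 0.01 methyl), mirroring the relative class abundances of
  large PTM repositories; 6.5 % of sites are flagged as protein-group
  sites;
* somatic cohort: 50 tumors; passenger mutations Poisson-scattered at
  0.02 expected mutations per residue per cohort, dense enough that
  essentially every protein has a mutation profile while specific-type
  recurrence by chance stays negligible; planted hotspots are inserted
  with an exact distinct-tumor count;
* germline variants: 300 by default, 25 % targeted onto or within ±5 of
  a PTM site (disease variants cluster near functional residues), and a
  5 % phosphomimetic fraction (S/T/Y→D/E on phosphosites);
* PSSMs: anchor weights planted (e.g. R at −3 = 3.0 for the basophilic
  matrix) over Gaussian noise (sd 0.25 by default); noise is keyed by
  (seed, spec) so renaming a matrix does not change its weights.

Every planted signal is recorded exactly once in a manifest, and all
randomness flows from the single config seed through named substreams,
giving byte-identical regeneration.  What the generator does *not*
emulate: trinucleotide mutational signatures, cohort-size heterogeneity
across cancer types, homology between proteins, and sequence motifs
around real PTM sites.  Passing tests therefore demonstrate correctness
of the computations and recoverability of planted structure, not
biological performance on real cohorts.

## Numerical and determinism choices

Entropy and delta scores are plain float arithmetic with a 1e−12 clamp at
exact-zero boundaries.  Fisher ties use a 1e−12 relative gate.  Output
tables carry a provenance comment line; its timestamp can be suppressed
(`--deterministic-headers`) to make whole output trees byte-comparable.
Sorting is total everywhere user-visible (hotspots by count then type;
intersections by protein, site position, offset), so results are
invariant to input record order.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen as
the package's own reference conditions: 1000 random count vectors for the
entropy oracle, exhaustive 2×2 tables to total 16 plus 400 random tables
with margins ≤ 30 for the Fisher oracle, 20 seeded cohorts for the
recurrence gate, 100 replicates of 110 proteins for top-decile hotspot
recovery, 50 random matrices for the clustering oracle, and 8 planted
rewiring events per run.

## Known limitations

Mutations reported on isoforms are not mapped to canonical sequences —
accessions are matched literally.  The enrichment contingency table is
one defensible construction among several the expected-value formula
admits.  Whether the ±5 compile window should include offset 0 is
ambiguous; here offset 0 is a direct hit, never a flank.  The rewiring
engine is a generic additive PSSM scorer: it does not reproduce any
proprietary matrix set, and percentile stringency beyond "minimum" is
left to the user.
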