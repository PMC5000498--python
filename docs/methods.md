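# Methods

`locusforge` implements an evidence-weighted consensus approach to gene-set
construction: given many competing gene models for the same genome (from
different predictors, parameter settings and transcript assemblers), it
scores each model against independent evidence tracks, partitions the
candidates into loci, and keeps the best-supported non-redundant model per
locus. Around that core it provides the downstream apparatus a gene-set
release needs: locus typing and naming, whole-set quality reports,
cross-annotation comparison, completeness counting, lineage-specific
expansion detection, clade-relative protein-divergence analysis, and the
contingency/model-averaging statistics used to analyse alternative
splicing. Everything is testable offline through a seeded synthetic-fixture
generator.

## Evidence scoring

Each candidate model is a chain of exons with an optional CDS chain
(1-based inclusive coordinates throughout; BED inputs are converted on
read). Four evidence classes are scored per model:

* **Expression** (`expr_overlap`): the fraction of the model's exon bases
  covered by the union of expression coverage spans (RNA-seq depth runs,
  tiling-array TARs, ESTs). Overlaps are computed on merged interval
  unions, so duplicated evidence never counts twice.
* **Intron support** (`splices_hit`): the fraction of the model's introns
  that coincide *exactly* (seq, start, end, strand) with splice junctions
  supported by ≥ 3 splice-mapped reads. Splice sites are
  nucleotide-resolution evidence, so no fuzz window is applied. Intronless
  models score 1 — no junction can contradict them. At the set level the
  same statistic is reported in the opposite direction (fraction of
  validated junction locations recovered by the set).
* **Structure agreement**: each model is graded against independently
  assembled or aligned structures (EST assemblies, protein-to-genome
  structures, RNA assemblies) as `perfect` (identical internal splice
  chain, terminal ends within a 50 bp tolerance — UTR ends vary between
  assemblies; set 0 for strict end-to-end matching), `equal66` (exon-base
  Jaccard ≥ 2/3; the Jaccard formulation is this package's concrete
  definition of "two-thirds equal"), `some` (any exon-base overlap) or
  `none`. Counts at the three levels are cumulative, hence nested.
* **Homology**: from precomputed protein alignments (the toolkit never
  runs BLAST), filtered at e-value < 1e-5: best non-transposon bitscore,
  bitscore per amino acid of the model's own protein, number of reference
  species hit, best same-species (paralog) bitscore, and best transposon
  bitscore kept separately.

The selection score is a weighted sum of the components, each normalized
to [0, 1] (bits/aa is divided by a cap, default 2.0 bits/aa ≈ a self-hit
density, and clipped). Transposon overlap of the exon bases enters as a
*subtractive* penalty — transposon evidence demotes a model, it never
supports one. Negative sums are clamped to 0. The default weight vector
(expression 1, intron 1, structure 0.5 per source, homology 1, transposon
penalty 1, minimum threshold 0.1) is a declared toolkit default: published
selection runs of this kind tuned weights iteratively against expert
review, and no canonical vector exists. Support tiers used in reports are
`strong` (> 2/3 overlap) and `medium` (> 1/3), with strict inequalities at
both boundaries.

## Locus selection

Loci are single-linkage clusters of candidates under same-strand CDS base
overlap (≥ 1 bp): overlap chains transitively, which is the only closure
consistent with "the same CDS locations" on one strand. CDS-less
(non-coding) candidates become singleton loci. Per locus one primary model
is selected iff its score clears the minimum threshold and is maximal
among members; ties break by a fixed documented cascade (homology
bitscore, then expression overlap, then configured source priority, then
model id) for reproducibility.

Two error patterns are flagged, never auto-repaired (resolving them is a
curation decision):

* **Join (chimera) suspects.** A model whose CDS bridges ≥ 2 of the CDS
  clusters formed by the *other* members of its locus, while its best
  bitscore does not exceed the best bitscore in any bridged cluster. The
  rationale: a true join of two genes has a larger coding span but aligns
  to each component protein no better than the un-joined models do. The
  detection deliberately examines all candidates, not just selected ones —
  a chimera merges its two victim genes into a single locus, so at most
  one of them can be selected and the chimera itself usually is not.
* **Fragment suspects.** A selected model whose best hit covers < 1/3 of a
  reference protein, where an adjacent selected model hits the same
  protein and covers most of the remainder (within a 0.1 slack).

Alternate isoforms come exclusively from read-derived transcript
assemblies, never from predictor output (predictor-generated alternates
are rarely assembly-supported). A candidate isoform is accepted iff its
intron chain is novel for the locus, every intron distinguishing it from
the primary is a validated junction, and it shares ≥ 1 bp CDS with the
primary. Candidates are processed in model-id order so the accepted set is
order-independent.

`iterate_selection` re-runs score → cluster → select with updated weights
and expert overrides (`force_keep` / `force_drop`, always honored;
conflicting keeps in one locus are an error), supporting the
negative-feedback refinement workflow.

## Locus typing and naming

Coding potential combines homology with ORF statistics from the longest
ATG-initiated ORF over the three forward frames (ORFs that run off the
transcript end are flagged partial; with no ATG, the longest stop-free
stretch is reported). Typing priority: `transposon` when transposon
homology dominates and expression is at most the medium tier; `expressTE`
when transposon homology coexists with real expression *and* non-transposon
insect homology (kept as an indeterminate class rather than discarded);
`coding` on significant non-transposon homology or a substantial ORF
(defaults: ≥ 300 bp and ≥ 30 % of the transcript — declared defaults, both
configurable, since no canonical cutoffs exist for "weak coding
potential"); `noncoding` on expression without either; `unclassifiable`
with no evidence at all.

Names come from the best significant protein hit with coverage-stepped
qualifiers on half-open bins: ≥ 66 % plain name, [33 %, 66 %) "putative",
[10 %, 33 %) "-like", below 10 % "uncharacterized protein". The sources
this convention descends from print the boundaries inconsistently
(">" vs "<"); this package fixes lower-bound-inclusive bins and tests the
breakpoints exactly.

## Gene-set evaluation

The evaluation report computes, for a whole gene set: per-evidence-class
recovery (of-evidence direction), the set-level splices-hit fraction,
nested structure-agreement counts per evidence source, homolog match and
group counts, mean bits/aa, and coding/exon base totals. Cross-set
equivalence classifies each query gene by its best coding-exon base
overlap against the other set — asymmetric by design, as a fraction of the
query gene's own coding bases — binned at ≥ 95 % / ≥ 66 % / > 0 / 0 with
cumulative upper bins. Universal single-copy ortholog completeness is a
partition of group copy counts into missing / single / multi.

Ortholog-group protein metrics take, per group, the cross-species median
protein size; each species' representative is its maximal-bitscore member,
contributing its bitscore and its size deviation from the median; an
outlier is a representative shorter than median − 2 SD (population SD by
default; sample SD available). Partial gene models surface as negative
mean deviations and elevated outlier percentages.

All report percentages use decimal half-up rounding — the single rounding
mode for printed output. Duplication and singleton loads divide
(species-specific paralogs + duplicated ortholog genes) and
(species-specific genes + single-copy ortholog genes) by reference insect
medians of 5000 and 10000 respectively.

## Protein divergence analysis

Pairwise amino-acid distances are maximum-likelihood estimates under the
JTT empirical substitution model (Jones, Taylor & Thornton 1992;
exchangeabilities and frequencies packaged as data). The rate matrix is
normalized to one expected substitution per site per unit time, so
distances are expected substitutions per site; the symmetric
π^½Qπ^-½ parameterization is eigendecomposed once and P(t) = exp(Qt)
costs a single triple-product per evaluation. The 1-D likelihood is
maximized by bounded scalar optimization on [0, 10]; estimates pinned at
the cap are flagged saturated. Columns with a gap in either sequence are
excluded pairwise (not listwise per group), maximizing usable columns;
fewer than 10 comparable columns is an error. At the divergence depths
this analysis targets, synonymous sites are saturated, which is why the
toolkit works at the amino-acid level and offers no dN/dS statistics.

For each ortholog group containing at least one focal, one ant and one bee
gene, the per-focal-gene medians AN (focal–ant) and BN (focal–bee) and the
per-group median AB (ant–bee, computed once per group) give

    R = (AN + BN) / (AN + BN + AB),   R_A = AN / (·),   R_B = BN / (·)

with R = R_A + R_B exactly, and R = 2/3 under equal rates. R is clamped to
[1e-6, 1 − 1e-6], logit-transformed, and regressed on nuisance covariates
(group median divergence, paralog presence, transposon-associated
expression). The ortholog-group ("random") effect is a two-stage
approximation to a mixed model: a method-of-moments variance partition
shrinks group-mean residuals toward zero before removal, falling back to
fixed effects only when ≥ 90 % of groups are singletons — the common case
of one focal gene per group, where a group effect is unidentifiable. An
exact mixed-model fitter can be substituted externally; model-averaging
over thousands of exact mixed fits is out of scope and the analysis'
conclusions rest on coefficient signs and importances.

Fast/slow genes are the residuals strictly beyond the 95th/5th
empirical percentiles (linear-interpolation definition; "exceeds" is read
strictly, so an all-ties vector selects nothing). The stricter
intersection mode applies an 80/20 rule separately to the focal–ant and
focal–bee ratio models and intersects the selections.

Lineage-specific expansions are ortholog groups with ≥ 2 focal copies,
presence (≥ 1 copy) in strictly more than 80 % of the other species
(other hymenopterans count among the arthropods for presence), and no
duplicate (≥ 2 copies) in any other hymenopteran.

## Association statistics

Fisher's exact test (two-sided by the point-probability convention) and
Benjamini–Hochberg FDR control are delegated to scipy and statsmodels
behind the module surface; the test suite checks the exact test against an
independent full hypergeometric enumeration for every 2×2 table with
margins ≤ 12. The splicing factor table is complete-case, restricted by
default to genes with *strong* expression and intron support (isoform
detection scales with coverage; weaker genes would bias every factor),
with counts and lengths log-then-z transformed (the CDS/transcript ratio
log-transformed and centered only; zero-based counts shifted by +1 before
the log).

Model averaging fits a logistic regression for every subset of ≤ 12
factors, ranks them by AICc = AIC + 2k(k+1)/(n−k−1), weights them by
exp(−ΔAICc/2) normalized over the candidate set, and reports per-factor
relative importance (summed weight of models containing the factor) plus
model-averaged coefficients with unconditional standard errors. Fits that
diverge (separation) are excluded with a warning. Overdispersion (Pearson
χ²/df of the full model) is reported, not acted on.

## Synthetic fixtures

The annotation fixture emulates the study conditions end to end: ~4
introns per gene (Poisson), exons 120–400 bp, introns 80–400 bp with GT–AG
dinucleotides forced in the generated genome, intergenic gaps 300–900 bp,
all genes on the forward strand of one scaffold. Evidence derives from the
truth: negative-binomial junction read counts (mean ≈ 20, so essentially
every true intron clears the 3-read bar), lognormal coverage over exons
plus a coarser whole-span TAR track, RNA/EST assembly structures for
80 %/50 % of genes, exon-skipping isoform assemblies (with their skip
junction validated) for 15 %, and alignment records whose bitscores scale
with the truth-CDS amino acids a model recovers, decaying over three
reference species.

Corruption is applied per gene at 5 % per mode by default — split at an
intron, join with the downstream neighbour, drop an internal exon, overrun
a UTR by 100–300 bp, or absorb a transposon span — with the flawed variant
placed in one predictor run while the faithful copy survives in the other.
This isolates the one failure the selection algebra cannot undo: a
chimeric join merges two true loci into one selection cluster, costing one
gene, which is precisely the error the join flag is built to catch
(chimera bitscores are set just below the weaker component, as homology
does not grow with a spliced-together coding span). Expected exact-CDS
locus recovery under the defaults is therefore ≈ 1 − p(join) ≈ 95 %, with
join flagging at ~100 %.

The protein-family simulator evolves an aligned family site-independently
on a star topology from a stationary ancestral sequence, recording true
additive path lengths, so distance estimates can be checked for
calibration and the divergence ratio for directional response to an
inflated focal branch.

What the fixtures do *not* model — and hence what green tests do not
establish about real data: overlapping or nested genes, alternative
strands within a locus, non-canonical splice sites, sequencing error and
read-level noise, biased genome composition, alignment errors in the
evidence itself, and fragmented assemblies. The fixtures exercise the
selection algebra and statistics, not the upstream mappers and assemblers.

All randomness flows from one explicit seed through purpose-keyed child
streams (`numpy` `SeedSequence` spawn keys), so sub-generators are
order-independent and outputs are byte-identical across runs.

## Numerical and degenerate-input choices

* Overlap fractions with an empty denominator side return NaN, distinct
  from a true 0.
* An empty validated-junction set makes set-level splices-hit 0 with a
  warning.
* Distances are capped at 10 substitutions/site and flagged saturated.
* `percent_of` and the load ratios round half-up at the printed precision;
  no other rounding mode is used for report output.
* Selection within a locus is fully deterministic given inputs (fixed
  tie-break cascade); candidate isoforms are processed in id order.
* Sequences > 50 % ambiguous are rejected by the ORF scanner; constant
  responses are rejected by the residual regression; percentile selection
  requires ≥ 20 genes.

## Problem sizes used in the shipped benchmarks

The bundled acceptance computation uses a 500-gene fixture for the
selection benchmark, 10,000-site alignments for distance calibration at
t ∈ {0.1, 0.3, 0.6}, the full enumeration of 2×2 tables with margins ≤ 12
for the exact-test check, and 100 replicates of n = 500 logistic data for
the model-averaging study. These sizes give Monte-Carlo error comfortably
inside the documented tolerances while keeping a full run under a minute.

## Known limitations

* The evidence weights and selection threshold are package defaults, not
  a reconstruction of any historical configuration; results on real data
  will depend on tuning them against expert review.
* The group-effect approximation is not an exact GLMM; with few, large
  groups and strong group structure an external mixed-model fitter should
  be preferred.
* Join/fragment detection flags candidates; it does not split or merge
  models, and flagged loci still require curation.
* `expressTE` typing requires all three conditions simultaneously
  (transposon homology, expression above the medium tier, non-transposon
  insect homology); an expressed transposon without the third condition
  remains `transposon`.
* The ORF scanner considers the forward strand of the supplied mRNA only.
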