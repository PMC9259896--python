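# Methods

## The triage model

`uvtriage` operationalizes a cohort-level rare-variant prioritization
procedure for diagnostic exome series in autism spectrum disorder and
related neurodevelopmental disorders (NDD). Its central premise is that in
a modest cohort (~150 probands), causative variants are *ultrarare*: a
variant observed in one patient, or a gene harboring a single distinct
variant across the whole cohort ("single event"), is a stronger candidate
than anything recurrent. The pipeline therefore (i) discards what is
common in reference populations, (ii) discards what is recurrent within
the cohort itself — recurrence at this scale is far more likely a
pipeline artifact than a shared pathogenic allele — and (iii) ranks what
remains by ACMG class, panel membership and segregation.

The two rarity notions are deliberately kept distinct, because the
literature conflates them: `ultrarare` is variant-level (carrier count
exactly 1), `single_event` is gene-level (exactly 1 distinct non-artifact
variant cohort-wide). Both flags are computed and reported on every
triage record.

## Filter thresholds and boundary conventions

| rule | predicate | boundary |
|---|---|---|
| depth | read depth > `min_depth_exclusive` (10×) | strict: 10 excluded, 11 kept |
| vaf | alt fraction ≥ `min_alt_fraction` (0.30) | inclusive: 0.30 kept |
| popfreq | max AF over databases ≤ `max_pop_freq_exclusive` (0.01) | exclusive: 0.010 kept, >0.01 excluded |
| consequence | not in excluded set, or canonical splice site | synonymous at a canonical splice site is rescued |

The allele fraction is AD_alt / DP where both FORMAT fields are present
(the convention chosen for "altered variant frequency", which callers do
not standardize); a FORMAT AF is accepted directly otherwise. The
population-frequency rule takes the **maximum** across databases: a
variant common in any reference population is not ultrarare. Whether the
1% cutoff should apply per-database or to the maximum is genuinely open;
max-across is the conservative choice and is config-overridable, as are
all three numeric thresholds. A population frequency absent from every
database is treated as 0 — absence from reference panels is precisely the
rare-variant signal. The kept/excluded decision is a conjunction and
order-independent; the fixed rule order (depth, vaf, popfreq,
consequence) exists only for the `failed_rules` report and the VCF FILTER
column.

## Cohort catalog and recurrence artifacts

Recurrence counts **distinct carrier patients**, not alleles: a
homozygote is one carrier, and siblings or twins each count (a true
variant shared by a twin pair has carrier count 2, far below the
threshold). Variants carried by more than `max_recurrence` (5) patients
are flagged as artifacts — retained in the catalog file for audit,
excluded from every downstream stage. A `count_families` switch collapses
family members to one carrier before the comparison, default off.

The "no more than three variants per gene" expansion cap is applied to
**class 3–5 variants only**, computed after classification; the
extension-panel tier requires the gene to pass it, the primary panel does
not (the primary panel is a positive gene list, the cap exists to keep
the panel-free expansion tractable).

## ACMG combination

Only the combining algebra is implemented; which criteria a variant earns
is an upstream interpretation step consumed as input. The default rule
table transcribes the 2015 ACMG/AMP combinations as lower-bound threshold
rows over evidence-strength counts (after optional per-tag strength
overrides, default off). Each side — pathogenic, benign — takes the
strongest class among its fired rules; upper-bounded guideline phrasings
("1 strong and 1–2 moderate") need no upper bounds under max-class
semantics. Contradictory evidence resolves to class 3 `conflict`: both
sides fire, or one side fires while the other holds strong-or-stronger
evidence (e.g. PVS1 against BA1). Nothing firing is class 3
`default_vus`. The engine is checked exhaustively against
`enumerate_oracle`, an independent literal transcription of the rule text
as nested boolean conditions, over full power sets of up to 12-tag
alphabets.

## Segregation

Inheritance is a total function of (child call, mother genotype, father
genotype, child sex, contig), genotypes taken at face value — no
mosaicism, non-paternity or genotyping-error modelling. With both parents
genotyped: absent in both → de novo; in exactly one → maternal/paternal;
in both → biparental. With one parent: present → that parent's category;
absent → excluded-in-that-parent (the "not inh mat" pattern). No parents →
not tested. For a hemizygous male child on X the father is irrelevant, so
a genotyped non-carrier mother suffices for a de novo call even without
the father; Y and mitochondrial contigs are rejected. Compound-het calls
are always *presumed* (no read-backed phasing): within a gene, pairs of
class-3–5 heterozygous variants whose origins are trans-compatible —
different parental categories, de novo plus inherited, or unresolved
origin — are emitted; two variants from the same parent are presumed cis
and suppressed.

## Yield arithmetic

Diagnostic yield counts **patients**, not variants: a patient with ≥ 1
class-4–5 variant in a tiered gene counts once per (tier, P/LP) cell, and
the overall yield is the union of P/LP-positive patients over tiers. VUS
carriers are reported separately and never added to yield; P/LP takes
precedence *across* tiers, so a patient with an extension-panel P/LP and
a primary-panel VUS appears only in the P/LP cell (their VUS variant is
still listed in the variant counts). Multi-variant patients are
attributed to the primary column when all their tiered variants are
primary-panel, otherwise to the extension column. Percentages are rounded
half-up to one decimal, in the consistent "n/total (x%)" form.

## Over-representation analysis and clustering

The ORA is the standard one-sided upper-tail hypergeometric test
P(X ≥ k) for overlap k between a query gene list (size n) and a term's
gene set (size K) in a universe of N genes (default: all genes in the
term table), corrected by Benjamini–Hochberg (default) or Bonferroni over
all tested terms. This is a deliberate desk-scale stand-in for hosted
enrichment services: their p-values depend on the annotation-database
release and on proprietary corrections (g:SCS) and are not reproducible
locally, so no attempt is made to match them. Gene clustering is plain
k-means (k = 4 by default, k-means++ seeding, deterministic given the
seed) on binary term-membership rows; when duplicate rows collapse
clusters below k, surplus genes are reassigned deterministically in gene
order with a warning, honouring the exactly-k contract. No GO-graph
propagation or network kernel is applied.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults matching the study conditions the pipeline targets:
147 patients (male fraction 110/147), ~268 kept variants per patient,
a 1,031-gene primary panel and 242-gene extension panel drawn disjointly
from 5,000 synthetic genes across 22 autosomes and X, 20 recurrence
artifacts carried by 6–40 patients, 30 common polymorphisms
(AF ∈ (0.011, 0.5)), causative P/LP plans of 20% (primary) and 3%
(extension) of patients with VUS plans of 6% and 4%, a trio fraction of
32/147, 10 sibling pairs of which 2 are twin pairs, a de novo fraction of
0.5 among planted variants, and ~15 decoy calls per patient failing the
depth or allele-fraction filter. Plans may be given as exact counts
instead of rates. Per-patient kept-variant counts are Poisson around the
configured mean (no per-patient variance is published for real cohorts,
so Poisson is the recorded assumption), with the planted and expected
artifact load subtracted from the background mean so the realized mean
matches the configuration.

Every planted causative/VUS variant occupies its own panel gene (drawn
without replacement), which makes it single-event by construction and
guarantees the expansion cap is satisfied; evidence tags are chosen to
combine to the intended class (P: PVS1+PS2; LP: PS1+PM2; VUS: PM2+PP3;
background: BS1+BP4 → likely benign; polymorphisms: BA1). Trio families
receive parental genotypes consistent with the true origin (de novo →
both parents reference; X-male → father hemizygous reference). Identical
twins share their entire germline variant set (planted, background,
decoys, polymorphisms) but *not* artifacts, which are per-sample pipeline
noise; non-twin siblings share half of the first sibling's background,
counted toward (not on top of) their own draw. Genotype observations are
noise-free by default; an optional parental-allele-dropout rate exercises
the excluded-one-parent path.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: realistic allele-frequency spectra and
mutation-rate heterogeneity, linkage disequilibrium, genotyping error,
incomplete penetrance, evidence-assignment noise (tags always combine to
the intended class), and the long tail of VUS that real background
variants would produce (background evidence is benign-leaning so that
ground truth stays exact). Recovery on this generator validates the
*plumbing and boundary logic* of the pipeline, not the clinical
sensitivity of the strategy.

## Numerical and problem-size choices

Hypergeometric tails are computed through the scipy survival function
(log-space internally) and are verified against exact integer draw
counting for every universe up to N = 25 at 1e-12. K-means runs 10
restarts, ≤ 300 iterations, tolerance 1e-6. Yield percentages use decimal
half-up rounding to one decimal. The end-to-end recovery suite runs ten
seeds at the full default cohort size (147 patients, ~40,000 catalog
variants) in memory; file round-trips (VCF/PED byte-identity given a
seed) are exercised on a 20-patient cohort, a size chosen to keep the
default test run fast while covering every code path. All randomness in a
run flows from a single integer seed through one `numpy` generator.

## Known limitations

* The bundled demonstration cohort records inheritance as printed in its
  source records; two of its primary-panel VUS are excluded-in-mother,
  which is faithfully reported even though summary tables in the
  literature sometimes fold one such case into "not tested".
* Evidence assignment (which ACMG criteria a variant earns) is out of
  scope by design; the engine's classes are only as good as the tags
  supplied.
* No joint genotyping, IBD checks, imprinting logic or genome-build
  conversion; Y and mitochondrial segregation is rejected rather than
  modelled.
* The per-gene expansion cap interacts with cohort composition: a gene
  made noisy by coincidental VUS can evict a true extension-panel
  candidate. The simulator avoids this by construction; real data may
  not.
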