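# Methods

## The problem

A T-box transcription factor (Tbx3/TBX3) regulates alternative splicing:
conditional ablation in the embryonic mouse limb changes the inclusion of
cassette exons in a compartment-specific way — the same exon can be lost in
the anterior compartment and gained in the posterior.  `tbxsplice`
implements the informatics around that finding as a reusable pipeline:
calling differential cassette-exon usage from exon-level RNA-Seq counts,
scanning candidate exons and their intronic flanks for T-box binding
elements (TBEs), filtering an IP-MS interactome, and modelling the
splicing-reporter (minigene) constructs used for validation.  A
synthetic-data generator with recorded ground truth makes every stage
testable without external downloads.

## Differential exon usage: the four-filter cascade

Candidate events are annotated cassette exons: an internal exon (or a pair
of adjacent internal exons, included or skipped as a unit) between two
constitutive neighbours.  For each event and compartment, replicate counts
are pooled by summation into a 2x2 table

|            | alternative-exon reads | gene-remainder reads |
|------------|------------------------|----------------------|
| control    | a                      | b                    |
| mutant     | c                      | d                    |

where the gene remainder is `gene_count - exon_count`.  Pooling is a
deliberate choice at n = 2 replicates per group: with two replicates there
is no usable within-group variance estimate, so the exact conditional test
on pooled counts is the honest option.  The cost — biological replicate
variability is not modelled, so p-values are calibrated against counting
noise only — is stated here as a known limitation.

Four conjunctive filters define a significant event (defaults overridable):

1. **Fisher's exact test, two-sided, p <= 0.05.**  Implemented by direct
   enumeration of the conditional hypergeometric support with the
   point-probability rule: the p-value sums the probabilities of all
   tables with the observed margins whose point probability does not
   exceed the observed one, ties admitted within relative tolerance 1e-7
   (to absorb floating-point representation of mathematically equal
   probabilities).  Degenerate margins (an all-zero row or column) return
   p = 1 and the event is flagged uninformative.
2. **Bayesian error rate <= 0.1.**  The original study's per-event error
   estimator is not publicly defined; this package substitutes a
   q-value-style posterior error bound and says so.  The null fraction is
   estimated as `pi0 = min(1, mean(p > 0.5) / 0.5)` (Storey's estimator at
   lambda = 0.5) and the rate at event i is
   `min over thresholds t >= p_i of pi0 * t * M / rank(t)`, capped at 1 —
   i.e. a pi0-corrected Benjamini–Hochberg step-up quantity, monotone in
   p.  It is computed separately within each compartment, across all
   events of that comparison.  On all-null simulations, thresholding at
   0.1 admits essentially no events; on mixed simulations the empirical
   false discovery proportion stays below ~0.15.
3. **Fold change >= 1.5**, taken on the exon-usage ratio, not on raw exon
   RPKM, so a gene-level expression change does not masquerade as a
   splicing change.  A raw-RPKM mode exists behind a flag.
4. **Support >= 15 reads**: total alternative-exon reads summed over all
   samples of the comparison (the filter is one number per event, not per
   sample).

### PSI via the RPKM usage ratio

RPKM = count / ((length/1000) * (library/1e6)).  The usage ratio is
`(exon_RPKM + eps) / (gene_RPKM + eps)` with the half-read pseudocount
`eps = 0.5 / (library/1e6)` in RPKM units.  Because RPKM divides by
feature length, the ratio cancels the alternative exon's length share of
the gene and estimates the inclusion level (PSI): under the generator's
model, exon reads are a `share * psi` fraction of gene reads with
`share = alt_length / gene_length`, and the ratio recovers `psi` exactly
in expectation.  A 0/0 event yields ratio 1 and is flagged uninformative.

### Direction

Directions are stated as what the factor does in the wild type, from a
loss-of-function comparison: mutant PSI below control (by more than
`min_delta`, default 0.05) means the factor promotes inclusion; above,
skipping.  Anterior and posterior compartments are called independently,
which is what lets one event carry opposite directions — the
compartment-reversal pattern of the validated in-vivo events.

## TBE motif scanning

Fixed degenerate patterns (no de-novo discovery):

| name          | pattern        | strands    |
|---------------|----------------|------------|
| TBE_DNA       | (T/A)GGTG(T/A/G) | both     |
| TBE_CONSENSUS | (A/T)GGTGTG    | both       |
| TBE_CORE      | GGTG (complement CACC) | both |
| RNA_TBE       | UGGUGU         | sense only |
| RELAXED       | (G/T)(G/C)TG N | both       |

Overlapping matches all count (multiplicity matters for probes carrying
tandem elements); reverse-strand hits are reported in forward coordinates
with strand "-"; RNA motifs are scanned sense-only since RNA has one
strand.  T and U are interchangeable on input.

Expected-by-chance counts for an i.i.d. background are closed-form:
`(L - k + 1) * P(match)`, with the reverse-strand match probability added
for both-strand motifs whose match set is not reverse-complement-closed
(under a uniform background this doubles the count).  Over-representation
is tested with an upper-tail binomial on positions.  Flanks for the
presence summary are intronic only — clipped at the neighbouring
constitutive exons and at the 1 kb window — because the biological claim
concerns TBEs in the introns flanking the alternative exons; on the minus
strand, flanks and exon are reverse-complemented into transcript
orientation.

## IP-MS interactome filter

A protein is an interactor iff detected in at least `min_datasets = 2`
non-control IP-MS experiments and in zero negative-control IPs.  Peptide
evidence is reduced to boolean detection (the rule is presence-based).
"Independent datasets" pools experiments across species by default, with
a within-single-species mode exposed, since either reading of the rule is
defensible.  Cross-species overlap matches identifiers case-insensitively
(mouse/human symbol casing).  Category fold-enrichment is
`(k/n) / (K/N)` with an upper-tail hypergeometric p — identical, by
construction, to a one-sided Fisher test on the corresponding 2x2 table,
which the tests verify against the splicing caller's hypergeometric core.

## Minigene model

A reporter construct is an alternating exon/intron segment list (three
exons and two introns for the pRHCglo-style reporter).  Observable
products: the unspliced pre-mRNA, each single-intron-removed intermediate,
the fully spliced mRNA, and the mature cassette-skip mRNA (all introns out
and the internal exon excluded with its flanking introns).  Only
whole-intron removal and cassette skipping are modelled; cryptic splice
sites and splice-site strength are out of scope.  Published product sizes
for the MS2-site reporter are not arithmetically reconcilable with the
control reporter's sizes under a shared backbone, so no printed size is a
bit-exact target; constructs are user-specified and checked through
length-conservation invariants instead.  The default worked example uses
exons of 50/32/108 bp with introns 700/856 bp, giving an 1746 bp
pre-mRNA, a 190 bp fully spliced product and a 158 bp skip product, and a
32 -> 31 bp test-exon swap that shortens the construct by exactly 1 bp.

## The synthetic-data generator

What it emulates: a 2-genotype x 2-compartment design with 2 replicates
per group; one cassette event per gene (each gene on its own chromosome
`chrS<i>`, exons 80-250 bp, introns 600-1400 bp so a 1 kb flank fits);
20% of events span two adjacent alternative exons with perfectly
correlated inclusion; gene counts NegBin(mean = `mean_gene_depth`,
overdispersion `dispersion`, variance mean + dispersion*mean^2);
alternative-exon counts Binomial(gene_count, share * psi); library size =
per-sample sum of gene counts; genomes i.i.d. from a background
composition with motif instances planted verbatim at recorded
non-overlapping positions on the gene strand; Bernoulli IP-MS detection
with sticky contaminants that also appear in controls.

Defaults and why:

* `mean_gene_depth = 200` reads/gene/sample, `dispersion = 0.1`: moderate
  bulk RNA-Seq depth and overdispersion giving the exact test realistic
  counting noise at desk scale; the original libraries' depths are not
  published, so these are the package's own choice.
* Baseline PSI 0.5 for unplanted events (maximally variable null).
* Planted effects for recovery studies are switch-like, PSI 0.75 <-> 0.25:
  the validated in-vivo events are near-complete isoform switches visible
  as band reversals on gels, and this is what the standard
  `plant_study_events` layout models (30 anterior effects of alternating
  direction, the first event reversed between compartments).
* IP-MS: 7 assays (3 mouse + 4 human) with 2 negative controls; true
  interactors detected per assay with probability 0.8 and never in
  controls; background proteins at 0.05 per assay but 0.5 in controls
  (contaminants are enriched in control IPs, which is what the control
  veto exploits).

What it does not emulate — and hence what passing tests do not show about
real data: read-level effects (mappability, positional bias, junction
reads), biological replicate variability beyond NB counting noise,
correlated expression changes between genotypes, realistic genome
composition (repeats, SINEs, GC structure), isoform complexity beyond a
single cassette per gene, and peptide-level MS error.  Results on real
libraries additionally depend on alignment and annotation quality, which
are out of scope.

## Numerical choices

* Coordinates 0-based half-open everywhere; GTF converted on read; a read
  overlaps an exon at >= 1 bp overlap; junction logic out of scope.
* Fisher tie tolerance 1e-7 relative; a full-support sum snaps to exactly
  1.0.
* All randomness through `numpy.random.default_rng`; generators salt the
  design seed per stage so annotation, genome and counts are independent
  streams but byte-reproducible.
* Degenerate inputs: all-zero tables are flagged uninformative (p = 1);
  0/0 usage ratio is 1; `mean_gene_depth = 0` yields an all-zero table
  without error; an empty p-value vector is an error.

## Problem sizes for the shipped studies

Null calibration uses 2000 events (5 seeds x 400 genes); recovery uses
200 genes with 30 planted events; the Fisher oracle check enumerates all
~164,000 tables with margins <= 30; Monte-Carlo motif checks use 500
replicates of 300 bp; the reporter invariants use 1000 random constructs.
These sizes give stable statistics at interactive runtimes.

## Known limitations

* The Bayesian error rate is a documented stand-in, not the study's exact
  estimator.
* Pooled replicates mean no biological-variance modelling (see above).
* PSI from exon-body RPKM only; junction-based PSI would be more direct
  but is out of scope.
* The motif scanner counts fixed patterns; it neither discovers motifs
  nor scores position weight matrices or conservation.
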