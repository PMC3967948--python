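# tbxsplice

Tools for studying how a T-box transcription factor (Tbx3/TBX3) shapes
alternative splicing.  Loss of Tbx3 in the embryonic mouse limb changes
the inclusion of cassette exons — and does so with opposite sign in the
anterior and posterior compartments of the same limb bud.  `tbxsplice`
implements the informatics of that study as a tested, reusable pipeline
for anyone analysing compartment-resolved exon-level RNA-Seq, scanning
for T-box binding elements (TBEs), or filtering an IP-MS interactome:

* **`exon_quant`** — read counting over cassette events, RPKM, and the
  exon-usage ratio that estimates PSI (percent spliced in).
* **`as_caller`** — the four-filter cascade for differential exon usage:
  two-sided Fisher's exact test p <= 0.05, Bayesian error rate <= 0.1,
  usage-ratio fold change >= 1.5, and >= 15 reads supporting the event,
  applied per compartment, plus direction classification
  (factor-promotes-inclusion vs -skipping).
* **`motif_scan`** — degenerate TBE-family motif scanning (DNA core GGTG
  / complement CACC; conservative (T/A)GGTG(T/A/G); consensus
  (A/T)GGTGTG; RNA element UGGUGU) over alternative exons and their 1 kb
  intronic flanks, with closed-form expected counts and binomial
  over-representation tests.
* **`interactome_filter`** — the IP-MS presence rule (detected in >= 2
  independent datasets, never in negative controls), cross-species
  overlap, and hypergeometric category fold-enrichment.
* **`minigene_model`** — splicing-reporter constructs as exon/intron
  segment lists: segment replacement, isoform enumeration, RT-PCR
  product sizes.
* **`synthetic_data`** — generators for all of the above with recorded
  ground truth (planted PSI shifts, planted motif positions, labelled
  true interactors), so the whole pipeline is testable offline.

## The statistics in brief

For each event and compartment, replicate counts are pooled into a 2x2
table of {control, mutant} x {alternative-exon reads, gene-remainder
reads} and tested with a two-sided Fisher's exact test (point-probability
rule, enumerated over the conditional hypergeometric support).  PSI is
estimated by the RPKM usage ratio (exon RPKM / gene RPKM, pseudocounted),
which cancels the exon's length share of the gene.  The Bayesian error
rate is a q-value-style posterior error bound with
pi0 = min(1, mean(p > 0.5)/0.5), computed across the compartment's
events.  An event is significant only if all four filters pass.  See
`docs/methods.md` for the full model, defaults and limitations.

## Worked example

Simulate a 50-gene compartment study with one event planted to flip
direction between compartments (PSI 0.75 -> 0.25 anterior, 0.25 -> 0.75
posterior) and two TBEs planted in its upstream intron, then call events
and scan flanks:

```python
import tbxsplice as tx

design = tx.SimulationDesign(n_genes=50, mean_gene_depth=200, seed=1)
annotation = tx.generate_annotation(design)
planted = [tx.PlantedEvent(
    annotation[0].gene_id, annotation[0].event_id,
    {("control", "anterior"): 0.75, ("mutant", "anterior"): 0.25,
     ("control", "posterior"): 0.25, ("mutant", "posterior"): 0.75},
    motif_plan=(("TBE_DNA", "upstream", 2),),
)]
genome, record = tx.generate_genome(annotation, planted=planted, seed=1)
counts, truth = tx.simulate_counts(annotation, design, planted)

for c in tx.call_events(counts, annotation):
    if c.significant:
        print(f"{c.event_id} {c.comparison:9s} p={c.p:.2e} ber={c.ber:.3f} "
              f"fc={c.fc:.2f} support={c.support} "
              f"psi {c.psi_ctl:.2f}->{c.psi_mut:.2f} {c.direction}")

summary = tx.presence_summary([annotation[0]], genome, tx.BUILTIN_MOTIFS["TBE_DNA"])
print("TBE in intronic flanks:", summary.label)
```

prints

```
ev0001 anterior  p=1.78e-07 ber=0.000 fc=3.57 support=83 psi 0.70->0.20 factor-promotes-inclusion
ev0001 posterior p=5.44e-06 ber=0.000 fc=3.10 support=74 psi 0.26->0.80 factor-promotes-skipping
ev0005 posterior p=1.74e-03 ber=0.044 fc=2.15 support=65 psi 0.72->0.33 factor-promotes-inclusion
TBE in intronic flanks: 1/1
```

The planted event is recovered in both compartments with opposite
directions — the compartment-reversal pattern — and its estimated PSI
values track the planted 0.75/0.25 truth.  The third line is a false
positive of this small 50-gene run: a reminder that the error-rate filter
bounds, but does not abolish, false discoveries.  `ev0005` was not
planted, yet an unlucky draw produced a convincing usage shift.

A thin CLI mirrors the library for shell use
(`tbxsplice simulate counts --seed 1 --n-genes 200 --out-dir out/`,
`tbxsplice call --counts out/counts.tsv --events out/events.json --out calls.tsv`,
`tbxsplice scan --fasta flanks.fa --motif TBE_DNA --out hits.tsv`, ...).

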