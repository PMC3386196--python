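# barcodetax

Integrated DNA-barcoding taxonomy for mitochondrial barcode datasets.

Surveys that identify animals from a short mitochondrial marker (typically
5′ *coxI*) face two coupled problems: choosing the divergence cutoff that
best separates within-species from between-species variation, and deciding
what the resulting molecular clusters *are* taxonomically. `barcodetax`
implements the full workflow for researchers running such surveys —
bat inventories, cryptic-species screens, reference-library curation:

1. **QC** — screen a trimmed, pre-aligned barcode matrix for the classic
   nuclear-pseudogene (NUMT) symptoms: internal indels and in-frame stop
   codons under the vertebrate mitochondrial code.
2. **Distances** — Kimura 2-parameter (K2P) distances under pairwise
   deletion,

   *d* = −½ ln(1 − 2*P* − *Q*) − ¼ ln(1 − 2*Q*),

   with *P* and *Q* the transition and transversion proportions over the
   sites comparable for each pair, plus within/between-species summaries.
3. **Optimum threshold (OT)** — scan candidate cutoffs *t*; a conspecific
   pair with *d* > *t* is a Type I error, a heterospecific pair with
   *d* < *t* a Type II error, both as percentages of all compared pairs.
   The OT sits at the minimum of their sum, the minimum cumulative error
   (MCE); ties resolve to the midpoint of the first optimal run.
4. **Entities and ranks** — single-linkage clusters at the OT become
   molecular entities; each is ranked:
   - `SPECIES_MATCH` — one entity, one nominal species;
   - `MT_MOTU` — one entity fusing several nominal species (marker failure);
   - `IOTU` — a divergent lineage corroborated by a second, congruent
     character (here geography: disjoint locality groups);
   - `UCS` — a divergent lineage (mean K2P above 2%) with molecular
     evidence only.
   Divergent intraspecific lineages are detected at a 2% mean-K2P
   criterion with bootstrap support from a neighbour-joining tree
   (column resampling, bipartition frequencies).
5. **Identification** — unknown queries are assigned to the reference
   species with the smallest minimum K2P distance when it falls below the
   OT and beats the runner-up by a tie margin.

A synthetic-data generator (`simulate_dataset`) evolves star-phylogeny
datasets under the K2P substitution process with injectable MT-MOTU /
IOTU / UCS structures and known ground truth, so the entire pipeline is
testable without sequence downloads.

## Worked example

Simulate a 6-species dataset (556 bp, ~1% within- and ~20%
between-species divergence) with two injected structures — a pair of
nominal species sharing one gene pool, and a species split into two
geographically disjoint 6%-divergent lineages — then run the pipeline:

```sh
barcodetax simulate --n-species 6 --samples 6:6 \
    --scenario mt_motu --scenario iotu --seed 11 \
    --out-fasta bats.fa --out-metadata bats.tsv
barcodetax qc bats.fa --metadata bats.tsv
barcodetax run --fasta bats.fa --metadata bats.tsv \
    --output-dir out --seed 11 --replicates 200
```

prints

```
36 records x 556 columns, frame 0, all passed
base frequencies: pi_A=0.255  pi_C=0.254  pi_G=0.250  pi_T=0.241
OT = 12.10%  MCE = 1.4286%  6 entities: {'MT_MOTU': 1, 'IOTU': 1, 'SPECIES_MATCH': 4}
```

Reading the output: the QC screen found a stop-free reading frame (no
NUMT suspects). The threshold scan could not reach zero error — the fused
species pair leaves heterospecific pairs near 1% divergence below any
sensible cutoff, and 1.43% of all compared pairs remain misclassified at
the optimum (the MCE). At the 12.1% OT the 36 samples collapse into six
molecular entities: the fused pair is flagged `MT_MOTU`, the split
species is recovered as an `IOTU` (its two lineages are allopatric), and
the four clean species match one-to-one. `out/` holds the distance
matrix, error curve, Newick tree with bootstrap supports, entity and
assignment reports, and a run log with every parameter and seed.

Each stage also runs standalone (`dist`, `ot`, `tree`, `classify`,
`identify`) on FASTA + TSV inputs, and the same functionality is
available as a library (`import barcodetax`).

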