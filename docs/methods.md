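# Methods

## Model and procedure

`barcodetax` operationalises threshold-based DNA-barcoding taxonomy as a
deterministic pipeline over a pre-aligned mitochondrial protein-coding
matrix. The stages, in execution order:

**NUMT screen.** Nuclear copies of mitochondrial genes betray themselves
through indels and in-frame stop codons. The screen reports, per record,
internal gap characters (a gap strictly between the first and last
non-gap position) and the stop-codon count in a single reading frame
chosen globally: the frame (0/1/2) minimising total stops over all
records, ties to the lowest index. A genuine coding alignment has a
stop-free frame, so the global choice is both deterministic and robust to
a few contaminated records; per-record frame fitting would let a real
NUMT pick a frame that hides its stops. The genetic code defaults to the
vertebrate mitochondrial table (NCBI table 2), appropriate for chiropteran
and other vertebrate *coxI*, and is configurable. Codons containing gaps
or ambiguity codes never count as stops. Base composition is tallied over
unambiguous A/C/G/T only, consistent with pairwise deletion downstream.

**K2P distances.** For each pair, alignment columns where either sequence
has a gap or IUPAC ambiguity are dropped (pairwise deletion); transitions
*P* and transversions *Q* are proportions over the remaining sites, and

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q).

When an argument of a log is non-positive (saturated pairs) or no
comparable sites remain, the distance is undefined; it is stored as NaN,
excluded from all summaries and counted in the report. Exclusion is the
conservative choice — an undefined distance carries no usable signal for
threshold placement. Distances are kept in substitutions/site internally;
every user-facing figure is ×100 with a percent sign, following field
convention. Divergence summaries report the standard deviation of the
pairwise values labelled "dispersion": the conventional "mean ± x%"
headline figures in barcoding surveys have the magnitude of this SD, not
of a standard error of the mean.

**Threshold optimisation.** Candidate thresholds run from 0 to
⌈max distance⌉ in 0.1-point steps (configurable; 0.1 matches the
one-decimal precision thresholds are conventionally reported at). At each
candidate *t*, Type I errors are conspecific pairs with *d* > *t* and
Type II errors heterospecific pairs with *d* < *t* — strict inequalities,
so a pair exactly at *t* is neither. Both are percentages of **all**
compared pairs (intra- and interspecific pooled). A per-class denominator
is available as an option, but the pooled denominator is the default: it
makes the cumulative error a single misclassification rate over the
dataset, and reported MCE values of a few hundredths of a percent on
reference sets of ~10⁴ pairs are only consistent with pooling. Samples
labelled UNKNOWN, and any species configured as excluded (e.g. one with
known taxonomic uncertainty), stay out of the scan. The minimum of the
cumulative error usually extends over a run of candidates; the default
tie rule returns the midpoint of the first such contiguous run, which
maximises the margin between the cutoff and the nearest misclassified
pairs ("smallest" is available).

**Trees.** Neighbour-joining on the Q-criterion, made fully
deterministic: among tied minimal-Q pairs, the pair whose representative
labels (a cluster is represented by its lexicographically smallest leaf)
sort first is joined. Negative branch-length estimates are clamped to
zero with the deficit moved to the sibling branch, preserving path
lengths through the joined node. Bootstrap support resamples alignment
columns with replacement, rebuilds the K2P + NJ tree per replicate, and
maps bipartition frequencies onto the full-data tree; replicates whose
resampled matrix contains undefined distances are skipped and counted,
with a warning past 10%. The seed is a required argument and is written
to the run log. Per-replicate pair counts are computed as matrix–vector
products of fixed per-pair column-category indicators against the
replicate's column-multiplicity vector, so resampling cost does not scale
with a Python-level pair loop.

**Lineages.** Within each species, lineages are the single-linkage
connected components at a mean-divergence criterion (default 2% K2P); the
species is flagged when ≥2 components exist and every between-component
mean exceeds the criterion. Single linkage makes the published
"lineages separated by a mean K2P distance greater than X%" phrasing
reproducible without manual tree inspection; the NJ tree is then used
only to annotate each lineage with the bootstrap support of its smallest
containing clade and whether it meets the support threshold (default
95%). Lineages are reported at any support, with the criterion met/not
met marked, since real surveys report supports ranging below the nominal
cutoff.

**Ranks.** Molecular entities are single-linkage components at the OT.
Rules, in order of precedence per entity: (1) two or more nominal species
fused → `MT_MOTU`; (2) a nominal species split across entities → each
such entity is `IOTU` when its locality-group set is disjoint from every
sibling entity of that species, else `UCS`; (3) a single-species entity
containing flagged internal lineages → `IOTU` when the lineages' locality
sets are pairwise disjoint, else `UCS`; (4) otherwise `SPECIES_MATCH`.
The unifying principle is that IOTU status requires molecular divergence
*plus* at least one independent congruent character — geography in this
data model — regardless of whether the divergence happens to exceed the
OT; the OT split (rule 2) and the sub-OT lineage route (rule 3) are the
same test applied at different divergence depths. Geographic congruence
means strict disjointness of locality-group sets; any overlap demotes to
UCS. Evidence codes record which route fired (`DIVERGENCE_GT_OT`,
`DIVERGENCE_2_TO_5`, `DIVERGENCE_GT_5`, `GEOGRAPHY_CONGRUENT`). `DCL` and
`CCS` ranks exist as manual-override labels only: both require evidence
types (morphological diagnosis, formal description) outside this data
model, so the classifier never auto-assigns them.

**Identification.** A query is assigned to the reference species with the
smallest minimum K2P distance when that distance is below the OT and the
runner-up species is at least `tie_margin` (default 0.3 percentage
points, absolute) further; two species below the OT within the margin
give `AMBIGUOUS`, none below the OT gives `UNASSIGNED`. In two-pass mode
(default) assigned queries re-enter the comprehensive dataset under their
assigned labels before partitioning; unassigned and ambiguous queries
stay out.

## Synthetic data

The generator emulates the statistical shape of a curated barcode survey
of a morphologically sorted fauna: a star phylogeny of species ancestors
(each evolved `inter_divergence/2` from a shared root, so every
between-species expectation equals `inter_divergence`), conspecific
samples evolved `intra_divergence/2` from their ancestor, sequences under
the K2P substitution process with uniform stationary frequencies, and a
stop-free frame-0 coding constraint maintained by redrawing offending
codons. Defaults follow the study conditions the package targets: ~30
species, 1–22 samples per species, 556 bp, κ = 4 (typical for mammalian
mtDNA), intraspecific divergence 1%, interspecific 20%. The star is the
default because the analysis consumes only pairwise distances and a star
makes configured divergences exact in expectation; a random-depth
("coalescent") option exists for stress testing.

Scenario injections create the structures the classifier must name:
`MTMotuPair` labels one gene pool as two nominal species; `IotuSplit`
grows lineage sub-ancestors with disjoint locality sets; `UcsSplit` grows
them with one shared locality set, cycled across samples so every lineage
realises the full overlap (sympatry by construction, not by chance). For
the lineage-defining branches the substitution count is fixed to its
expectation round(L·t) via the embedded jump chain (under K2P every site
carries the same total rate, so events land uniformly on sites): the
injected divergence **is** the ground truth, and leaving it
Poisson-distributed would silently falsify the ground-truth labels in a
noticeable fraction of draws at the 556-bp scale — a 2.5% split carries
roughly ±0.7 points of count noise, enough to cross the 2% detection
criterion. All other branches, and everything else in the simulation,
remain fully stochastic.

What the generator does **not** emulate: unequal base composition (real
*coxI* is AT-rich; the simulator is stationary-uniform, so base-frequency
outputs on synthetic data hover near 0.25), rate variation across sites
and codon positions, a non-star species tree with correlated divergences,
saturation at deep distances, missing data and ambiguity codes, and
selection on the protein beyond stop-codon avoidance. Passing tests
therefore demonstrate correctness of the algorithms under the model's
assumptions, not robustness to every property of field data.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open everywhere; trimming is by explicit
  window (or "to shortest"), never auto-detected.
- Distance matrices are validated symmetric within 1e-12 with an exactly
  zero diagonal; undefined entries are NaN and must be resolved (by
  exclusion) before tree building.
- Species with fewer than two samples report NA intraspecific statistics,
  never 0, and still contribute interspecific pairs.
- The threshold grid is generated as integer multiples of the step to
  avoid floating-point drift; optimal-run detection tolerates 1e-12.
- NJ ties and the all-equal matrix resolve deterministically via label
  order; bootstrap replicate streams depend only on the seed and the
  alignment dimensions, so supports are invariant to leaf relabelling.
- An empty FASTA yields an empty record list with a logged warning;
  duplicate sample ids, conflicting metadata rows, non-IUPAC characters
  and window/length mismatches are hard errors naming the offender.

## Problem sizes

The shipped test suite and acceptance script run entirely on simulated
data: clean-gap recovery uses 5 species × 6 samples; scenario recovery
uses 6 species × 6 samples over 20 seeds per scenario; the study-shaped
run uses 30 species with 1–22 samples (~300 sequences) and a 100-replicate
bootstrap. These sizes give stable statistics while keeping a full run in
the minutes range on one CPU; all of them are configuration, not limits —
the implementation handles the multi-hundred-sequence, 1000-replicate
setting of real surveys.

## Known limitations

- The threshold scan assumes the reference labels are correct;
  misidentified reference specimens bias both error curves.
- Single-linkage entities can chain through intermediate samples, so a
  low OT on dense sampling may merge distinct clusters connected by one
  intermediate pair.
- Geographic congruence is a set-disjointness test on coarse locality
  groups; it neither models sampling effort nor distinguishes parapatry
  from allopatry.
- Bootstrap support is mapped onto the full-data topology only; splits
  absent from that topology are not reported.
- The real-data regression test requires the original accession
  sequences, which are not bundled.
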