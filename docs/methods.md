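# Methods

`rnadx` implements a diagnostic RNA-seq analysis for rare-disease cohorts:
given one patient sample and a tissue-matched control cohort, it detects
aberrant splice junctions and expression outliers, quantifies allelic
skew, infers the splicing event and its coding consequence, and codes the
clinical outcome of the analysis. This note documents the model, the
parameters that matter, the synthetic-data generator, and the numerical
and design choices.

## Junction usage score

Splice junctions are taken from STAR `SJ.out.tab` tables (1-based closed
intron coordinates). Junctions with at least `min_unique = 5` uniquely
mapped reads are reported; multi-mapped reads are parsed but never enter
any statistic. The usage score of junction *j* is

```
score_donor(j)    = u_j / Σ u_k  over junctions k sharing j's donor site
score_acceptor(j) = u_j / Σ u_k  over junctions k sharing j's acceptor site
score(j)          = min(score_donor, score_acceptor)
```

where `u_j` is the unique-read count. Two normalizations are computed
because "reads sharing a donor or acceptor site" admits either; the
minimum is the conservative choice — a junction counts as low-usage as
soon as either of its splice sites has a dominant competitor, which is
what matters when screening for reduced or increased usage. Denominators
are always computed on the *unfiltered* junction set; the 5-read filter
only gates reporting, because filtering the denominator would inflate the
scores of weak junctions. The donor is the `intron_start` side on the +
strand, the `intron_end` side on the − strand; strand-undefined junctions
are treated like + and are matched to genes by coordinates alone, so
non-canonical (motif 0) junctions are never silently discarded.

Degenerate cases: a side whose site total is zero has an undefined score
for that side; a junction with both sides undefined (possible only at
zero reads) is dropped with a warning.

## Cohort reference and Z-scores

For every junction seen in any control or present in the annotation, the
control cohort supplies mean and standard deviation of the usage score
and a detection fraction. A control that does not report a junction
contributes a true zero only when the junction's donor or acceptor site
carries at least `min_site_reads = 10` reads in that control — otherwise
the junction was unmeasurable there and the sample is excluded from that
junction's statistics. This separates "the junction is not used" from
"the gene is not expressed", a distinction the source protocol resolves
by manual IGV review.

The patient Z-score is

```
z = (score_patient − mean_control) / max(sd_control, sd_floor)
```

with `sd_floor = 0.01`. Scores live in [0, 1], so the floor bounds |z| by
roughly 100·|Δscore| and keeps z finite at junctions whose usage is
invariant across controls (common: most constitutive junctions score
exactly 1 in every sample). The standard deviation is the sample sd
(ddof 1); with the floor sent to zero the statistic reduces to the
textbook z-score. Annotated junctions absent from the patient — but with
patient site coverage ≥ `min_site_reads` — are emitted with patient score
0, so "missing" junctions become visible. Control samples are admitted by
five QC predicates evaluated strictly: RIN > 7, autolysis less than
severe, mapping rate > 80%, intergenic rate < 0.15, rRNA < 10%. Reference
cohort sizes of roughly 120–290 samples per tissue are typical for this
design; no computation depends on the cohort size beyond requiring at
least two contributing samples per junction.

## Aberrant-junction classes

Junctions with |z| ≥ 3 are classified exclusively and exhaustively:

| class   | annotated | cohort detection | direction  |
|---------|-----------|------------------|------------|
| novel   | no        | < 5% of samples  | increased  |
| missing | yes       | —                | decreased  |
| outlier | everything else at \|z\| ≥ 3              |

"Detected in the cohort" needed an operational cutoff; detection in
fewer than 5% of control samples counts as undetected, which tolerates
rare mapping artifacts in controls. An annotated junction with increased
usage is an outlier, not novel (it exists in the transcriptome); an
unannotated junction that controls do use also goes to outlier, keeping
"novel" strictly for patient-specific junctions.

Hypothesis-driven review collects, for a candidate region ± a 500-bp
flank (configurable; splice effects of a variant can land one exon away),
every aberrant junction, every junction Z including sub-threshold ones
(for manual review), the gene's expression-outlier status and the
downstream event calls.

## Expression outliers

Per-gene Z of the patient TPM against the control cohort, on the raw TPM
scale by default (a `log2(TPM+1)` switch exists because raw-scale Z is
heavy-tailed); |z| > 2 flags an outlier. The control sd is floored at
`max(0.1 TPM, 5% of the cohort mean)` per gene so that invariant
low-expression genes cannot dominate the ranking. Outliers are ranked by
|z| (ties broken by gene id) after optional restriction to
phenotype-relevant genes.

## Splicing events and coding consequences

Events are inferred on the gene's canonical transcript — the longest CDS,
overridable by transcript id; a deterministic default is required where a
human analyst would review isoforms by hand. Pattern rules, in match
order: an exact annotated intron (an intron-retention candidate when the
junction is *missing* and the intron's coverage ratio exceeds the
threshold); a tandem-duplication back-junction (ends one base outside
exon boundaries, inverted); an exon skip (both ends on annotated splice
sites of different introns); an extension or truncation (one end
annotated, the other inside the intron or an exon); a novel exon (both
ends inside one intron); otherwise unclassified with a note.

The coding-length change `delta_nt` counts CDS-overlapping bases only and
is computed by reconstructing the edited transcript's retained genomic
blocks: the novel junction removes its own interval; canonical introns
disjoint from it are spliced normally; the parts of overlapping introns
outside the junction are retained (that is what an exon extension is).
The mod-3 rule on `delta_nt` gives in-frame vs frameshift; events that
never touch the CDS are noncoding. When a genome sequence is available
the premature termination codon is located by scanning codons of the
edited spliced CDS; the 55-nt rule then predicts nonsense-mediated decay
when the PTC lies more than 55 nt upstream of the last exon–exon
junction. The 55-nt rule is adopted as an explicit convention — in
clinical practice NMD is usually inferred indirectly from allelic skew
and read loss.

A tandem duplication of exons *a..b* is confirmed by its back-junction:
the split-read junction joining the donor of the last duplicated exon to
the acceptor of the first. In genomic coordinates this junction runs
backwards, and is represented as the interval
`[first dup exon start − 1, last dup exon end + 1]`, which is identical
for + and − strand genes. `in_tandem` requires ≥ `min_support = 5`
split reads; `in_frame` is the mod-3 rule on the duplicated CDS length.
This junction-table lookup replaces realignment to a customized
reference genome carrying the duplicated segment — the same information
with no realignment step; BAM-level analysis is out of scope.

Intron retention is quantified from per-base coverage as the median
intron coverage over the mean of the two flanking exons' medians,
truncated to [0, 1]; zero exon coverage leaves the ratio undefined
(logged). Isoform switches are screened from isoform-percentage matrices:
a gene is a candidate when at least one isoform falls below −3 cohort
sds and another rises above +3.

## Allelic skew

At a heterozygous site, skew = dominant-allele reads / total, in
[0.5, 1], with an exact two-sided binomial test against 0.5 — depths at
single sites are small, so no normal approximation. The default depth
requirement is 20 reads. Skew is reported toward whichever allele
dominates; the caller annotates which allele carries the candidate
variant.

## Hypothesis-independent screen

Without a candidate variant, aberrant junctions are filtered by usage:
novel junctions need patient score > 0.2 and cohort mean < 0.2;
missing/outlier junctions need patient score < 0.75, cohort mean ≥ 0.6
and detection in ≥ 80% of controls. The 80%-of-cohort condition is
attached to the missing/outlier branch only — novel junctions are by
definition near-absent from controls. Survivors are restricted to genes
mapped from the patient's HPO terms (an empty mapping triggers a
genome-wide screen with a prominent warning rather than a failure) and
ranked by aberration count, then max |z|, then gene id — genes with
multiple splicing aberrations rank first because splice-altering variants
frequently disrupt more than one junction.

## Outcome coding

The outcome coder is a total, deterministic rule engine over adjudicated
inputs: analysis failed → Unsuccessful; a significant transcript effect →
Diagnostic (PS3); an effect of uncertain significance → RNA VUS; no
effect (or a judged-minor one) → Transcript-effect Ruled Out when a
protein-level mechanism such as missense remains possible, else Diagnosis
Ruled Out (both BS3). The judgment "is the impact significant" is an
input field, never inferred — an advisory helper suggests it from
aberrant fraction and frame, but its output is not used for the packaged
cohort. Percentages are reported raw and rounded to the nearest integer;
the combined Diagnostic + Ruled-Out share (~69.7%) is rounding-sensitive
and is therefore also kept raw.

The packaged fixture (`data/cohort_cases.tsv`) encodes a 53-proband
cohort: 33 probands with candidate DNA variants across four clinical
scenarios (non-canonical splice variants, canonical splice-site variants
with atypical phenotypes, intragenic CNVs, regulatory/UTR variants) and
20 probands with uninformative genome sequencing. Every row carries a
citation string so failing tests can print their provenance anchor.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
beginning at the junction-count level — the pipeline's inputs start at
`SJ.out.tab`, so read-level simulation would add nothing. Genes
(default 20, 4–10 exons of 60–300 nt, introns 200–2000 nt, alternating
strands) are coding with codon-multiple CDS lengths; about half carry an
annotated skip isoform whose usage varies across samples as
Beta(c·μ, c·(1−μ)) with concentration c = 200 and mean μ = 0.2 — a tight
cohort (score sd of a few percent) so that |z| ≥ 3 corresponds to
biologically large shifts, mirroring a manual-review regime. Per sample
and gene, total junction depth is Poisson(500) and reads split
multinomially across isoforms.

Injections re-route a stated fraction of reads through an aberration;
the fraction is defined against the junction reads at the shared splice
sites, which is exactly what the usage score estimates. Exon-skip
injections are kept unannotated by construction (the alt isoform never
skips the injected exon). TPM matrices are log-normal per gene
(log2 means uniform on [1, 7], sd 0.25); expression outliers are planted
at a stated true z. Allele counts are binomial at a stated true skew.
Intron-retention coverage is written as Poisson-noisy bedGraph segments.
All randomness flows from one `numpy` generator seeded from the config,
and equal configs produce byte-identical bundles.

What the generator does **not** model: mapping artifacts and soft-clip
noise, correlated technical variation across junctions and samples,
tissue composition, library-depth imbalance, and annotation errors.
Passing recovery tests therefore demonstrates the statistical behaviour
of the method under its assumptions, not its performance on patient data.

## Problem sizes used in the test suite

The packaged simulations use 6–20 genes, 20–50 controls and junction
depth 300–1000; seeded recovery runs use 20 seeds. These sizes give
stable statistics (binomial sd of a usage-score estimate at depth 500 is
≈ 0.022) while keeping the whole suite fast. At depth 500 a per-run
fraction-recovery tolerance of ±0.05 is a ≈2.2σ event, so recovery
accuracy is asserted on the mean absolute error over seeded runs, with
detection (novel class at |z| ≥ 3) asserted per run.

## Known limitations

- A fully retained intron removes its own junction and, with it, the
  site coverage needed to call the junction "missing" from the junction
  table alone; retention is therefore detected from coverage ratios, not
  junction scores.
- Raw-TPM Z-scores are heavy-tailed; the log-scale switch is provided
  but is not the default.
- The canonical-transcript default (longest CDS) can mis-assign events
  in genes whose clinically relevant isoform is shorter; use the
  transcript-id override.
- Junction Z-scores treat junctions independently; no multiple-testing
  correction is applied because downstream review is manual and
  candidate-driven.
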