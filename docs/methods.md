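# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic data does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## F2 cross and bulk-sequencing simulator

**Model.** Two fully inbred parents differ at every marker site; the
recessive ("dwarf") parent allele is written `A` and emitted as ALT. Each F2
individual is the union of two independent gametes. Gametes follow the
Haldane model: crossovers form a Poisson process on genetic distance with no
interference, implemented by drawing independent Poisson counts for each
inter-marker interval (rate = distance in Morgans) and tracking the parity
of their cumulative sum; the haplotype at the first site of a chromosome is
a fair coin. The phenotype is fully penetrant: dwarf iff the individual is
`AA` at the causal locus, which is simulated jointly with the markers even
when it is not itself a marker.

**Map density.** The default is 4 cM/Mb (1 cM ≙ 250 kb), a typical
plant-genome-scale figure; it is a settable parameter of `GenomeSpec`, not a
claim about any particular genome. An 8-Mb simulated chromosome is then
~32 cM, long enough that a locus at one end is effectively unlinked from the
other.

**Bulks and sequencing.** The dwarf bulk pools the first `n_dwarf` dwarf
individuals (default 25) and the vine bulk the first `n_vine` vine
individuals (default 25) — phenotype classes, not genotyped classes, so the
vine bulk naturally mixes heterozygotes and dominant homozygotes 2:1. At
each marker the pooled ALT frequency is the mean allele dosage / 2; read
depth per site per bulk is Poisson(`depth_mean`, default 50) and ALT reads
are Binomial(depth, p) with p adjusted by a symmetric per-read error
(`error_rate`, default 0.001): p' = p(1−e) + (1−p)e. Expected values at a
fully linked site: dwarf-bulk index → 1, vine-bulk index → 1/3, so
Δ_alt → −2/3 and ED → √2·2/3 ≈ 0.943.

**What the simulator does not emulate.** Sequence-level reads (no FASTQ, no
mapping artefacts), depth overdispersion beyond Poisson, segregation
distortion, selfing generations beyond F2, variant-calling error structure,
and linked-site LD decay within a bulk beyond what the shared individuals
induce. Tests passing on this generator therefore validate the statistical
logic of the scan, not robustness to alignment or calling artefacts.

**Determinism.** All randomness flows from user-supplied seeds through
`numpy.random.default_rng`; identical seeds give byte-identical outputs.

## BSA scan

Per-site statistics are exactly the index/Δ/ED formulas given in the README;
`ED = √2·|Δ_alt|` is an algebraic identity of the two-term definition for
biallelic sites and is asserted in tests to machine precision.

**Depth filter.** Total depth ≥ `min_reads` (default 5) in *each* bulk.
Requiring it per bulk (rather than summed) is the stricter reading and
guarantees both indices are defined.

**Windows.** Default 1-Mb window advanced in 1-kb steps, starting at
position 1 of each chromosome, 1-based inclusive ends clipped at the
chromosome end. The alternative reading ("1-kb windows averaged over 1 Mb")
produces the same smooth curve family; the window and step are both
parameters. Empty windows are emitted with `n_sites = 0` and missing means
so downstream consumers see the full grid.

**99% threshold.** The published style of "99% smooth fitting" threshold
lines is not an algorithm, so the package calibrates empirically: for each
distinct window site-count `n`, simulate `n_null` (default 2,000) windows of
`n` sites under the no-linkage null — per-bulk depths resampled with
replacement from the observed filtered depth distribution, allele frequency
0.5 in both bulks — and take the 99th percentile of the window-mean
statistic (ED by default, Δ optionally). Flagging uses strict `>`. Windows
sharing a site count share a null distribution, which makes calibration
cheap and exact in distribution. By construction ≈1% of null windows exceed
the threshold; the calibration test uses non-overlapping windows because
heavily overlapping windows are correlated and a binomial tolerance on the
flagged fraction would otherwise be meaningless.

**Regions.** Maximal runs of above-threshold windows, merging gaps up to
`merge_gap_bp`, reported as (first window start, last window end), then
optionally intersected across variant classes (e.g. SNP-derived ∩
InDel-derived), mirroring the practice of combining the two scans.

**Sizes used in the checks.** Parameter recovery runs 20 seeded simulations
of one 8-Mb chromosome with 500 marker sites, 160 F2 plants, 25+25 bulks at
depth 50, window 1 Mb stepped 10 kb; the top-ED window midpoint must fall
within 1 Mb of the true locus in ≥ 18/20 runs. Null calibration uses ~2,000
no-linkage sites at depth ~50 and 2,000 null replicates. These sizes are the
package's chosen test conditions; the defaults for real scans are the 1-kb
step and full `n_null`.

## Segregation testing

Plain Pearson χ² against an arbitrary two-class ratio (default 3:1), df = 1,
with the Yates continuity correction available (|O−E| reduced by 0.5,
floored at 0). The worked 72:26 example gives 0.1224 plain and 0.0544 with
Yates — both far below the 5% critical value 3.841, hence consistent with a
single recessive gene. Neither value equals the 0.683 previously reported
for the same counts; that figure is not reproducible from the standard
formula and is documented here rather than targeted. Plain Pearson is the default because no correction was stated.

## Fine mapping

Within recessive-class individuals, any marker call that is not the
recessive-parent homozygote (`H` or `B`) is a recombinant between marker and
locus; missing calls are ignored, not imputed, and `H` and `B` both count
one recombinant individual (individuals, not chromosomes, are counted). The
interval is delimited by the nearest marker with ≥ 1 recombinant on each
side of the zero-recombinant core; degenerate panels (no zero-recombinant
marker, or no flanking recombinant on one side) fall back to the widest
bracket with an explicit warning and an `ambiguous` flag. Interval lengths
are reported in kb truncated (floored) to the integer, matching the
convention that a 541,590-bp span is a "541-kb" interval.

## Splice-acceptor consequence prediction

A variant in the last two intron bases that destroys the acceptor `AG`
is classified `acceptor_disruption` (first two bases / `GT` analogously for
donors; the acceptor semantics — last 2 nt of the intron — are used even
though annotation-tool footnotes sometimes describe the class with donor
wording). Two isoforms are enumerated for an acceptor loss, the two outcomes
observed for this gene: full retention of the affected intron, and splicing
to the nearest downstream `AG` within `cryptic_scan_limit` nt (default 50)
of the next exon's start, which truncates that exon by the scan distance.
No exon skipping, splice-strength scoring or NMD modelling is attempted.
Translation runs codon-by-codon from the start codon to the first in-frame
stop (standard nuclear code via Biopython); the protein length includes the
initiator Met, so `3·protein_length + 3` equals the stop codon's end
coordinate. Domains given in protein coordinates are `retained` when wholly
within the translated protein, `lost` when wholly beyond it, `truncated`
when straddling.

**The bundled example gene** (`build_example_gene`) is a synthetic 1,257-nt
two-exon gene constructed to satisfy, simultaneously, every reported
coordinate of the real GA3ox case: exon 1 at nt 1–503, a 123-nt intron at 504–626
opening `GTAG` (donor GT, then an in-frame TAG at nt 505–507 once the intron
is retained) and closing `AG`, exon 2 at 627–1,257; a 1,134-nt canonical CDS
(377 aa); an `AG` at exon-2 nt 12–13 as the nearest cryptic acceptor, so the
mutant cryptic isoform carries a 13-nt deletion and a frameshifted TGA at
transcript nt 520–522 (173 aa), while the retention isoform stops at 505–507
(168 aa); and a Fe2OG-dioxygenase-like domain at aa 200–350, wholly distal
to both truncation points, so both mutant isoforms lose it. This exon/intron
layout is the unique small solution to those joint constraints; free bases
are drawn from a fixed-seed generator codon-wise under no-early-stop
constraints (with rejection on the doubly-framed segment and on spurious
upstream `AG`s), and the finished gene is re-verified end to end through the
public API at build time. It is a synthetic stand-in consistent with the
printed coordinates, not the real genomic sequence, whose full exon/intron
structure is not public.

## Quantitative screening

Analytes measured in two groups are compared as log2(b/a) of the group
means plus a two-sided t-test; the significance call requires both
|log2FC| ≥ `fold_thresh` (default 1) and p < `p_thresh` (default 0.05), with
the direction from the fold-change sign. Hormone panels printed as
mean ± SD (n = 3) use the summary-statistic Welch test (Satterthwaite df;
pooled-variance available by flag, since the original analysis did not state
which was used); replicate lists are reduced to the same summaries, so both
input forms agree to machine precision. `n.d.` / `n.q.` statuses propagate
to `no_call` rather than being zero-imputed. Degenerate zero-variance input
follows t = 0, p = 1 (equal means) / |t| = ∞, p = 0 (unequal).

FPKM triplicates get a fold-change-only screen with pseudocount 0.001
(the constant used for log-FPKM heatmaps) to guard all-zero rows; the output
carries an explicit "screening only — FDR not computed" note because a
proper differential-expression call needs count-based dispersion modelling
and multiple-testing control, which are out of scope. Gibberellin species
are classified into the two parallel branches of the GA biosynthetic/
metabolic network (the GA53 pathway: GA53→GA44→GA19→GA20→{GA1→GA8, GA29,
GA5→{GA3, GA6}}; the GA12 pathway: GA12→GA15→GA24→GA9→{GA4→GA34, GA51,
GA7}).

Bundled worked-example tables (`dwarfmap.datasets`) carry the hormone panel
(18 GAs × 4 groups, ng/g fresh weight, mean ± SD of three UPLC-MS/MS runs)
and the FPKM triplicates of the 20 expressed GA pathway genes, so every
screening operation runs end to end out of the box.

## Known limitations

* The scan's threshold is an empirical null calibration, not a re-derivation
  of any specific published smoothing procedure.
* The simulator's Poisson/binomial read model understates the overdispersion
  of real pooled sequencing; thresholds calibrated on real data inherit the
  observed depth distribution but still assume binomial allele sampling.
* Multi-intron genes are handled by straightforward generalization (one
  affected intron, canonical splicing elsewhere); complex re-splicing is not
  modelled.
* The hormone screen applies no multiple-testing correction across analytes,
  matching the original single-analyte t-test convention.
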