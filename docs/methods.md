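# Methods

This note records the models implemented in `retmap`, their assumptions,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions a maintainer needs.

## Coordinates and gene models

All internal coordinates are 1-based inclusive (VCF convention); BED12
input is converted at the parsing boundary. Exons are stored in
*transcript* order, so on a minus-strand gene exon 1 has the highest
genomic coordinates and intron *i* (between exons *i* and *i+1*) lies
genomically *above* exon *i+1*. This is the convention under which an
HGVS-style intronic offset such as c.1047−9 — nine bases upstream of the
acceptor of the exon whose first coding base is CDS position 1047 —
resolves by walking the pre-mRNA in the transcript direction, respecting
strand. Resolution errors out if the landing base is not intronic (anchor
not at the appropriate exon boundary, or offset beyond the adjacent
intron).

Interval sizes in kb are computed as (end − start)/1000, rounded half-up.
Whether the inclusive (+1 bp) or difference convention is meant by a
printed interval size is immaterial at kb rounding and both reproduce the
published sizes; the difference convention is used and documented here
once.

The demonstration gene is an 8-exon minus-strand transcript constructed so
the published coordinate arithmetic is reproduced exactly: 1046 CDS nt
before the 109-bp focal intron 6, a 1701-nt CDS (566 residues), an
in-frame stop beginning at intron base 53, and a near-acceptor variant at
c.1047−9 (genomic 21:33,582,064, T>C on the plus strand). A second small
plus-strand gene outside the candidate interval hosts the fixture's rare
coding variants and exercises plus-strand coordinate paths.

## Homozygosity mapping

`detect_roh` emits maximal runs of homozygous calls. Defaults:
`min_markers=25`, `min_length_kb=500`, heterozygote tolerance 0 (array
heterozygote calls are treated as run breakers, as is standard for
array-based ROH), up to `max_missing_run=2` consecutive missing calls
skipped without breaking the run — missing markers never count toward
`min_markers`. These thresholds are conventional array-ROH practice; they
are configuration, not biology.

The LOD is an explicitly *singlepoint* homozygosity statistic in the
Lander–Botstein tradition: per affected individual, log₁₀ of
P(genotype | autozygous) / P(genotype | random mating), with
P(hom for allele a | autozygous) = (1−ε)·q_a, P(het | autozygous) = ε
(genotyping error), and Hardy–Weinberg under the alternative. It is *not*
a multipoint pedigree likelihood: recombination fraction, pedigree loops
and linkage disequilibrium are not modelled, so a published multipoint LOD
value is not a target for this statistic. Because a single chance
all-homozygous marker can rival any in-segment marker, single-marker
argmax is an unreliable localiser — the motivation for multipoint methods.
`lod_profile(window=k)` therefore offers a centred rolling *sum* over k
markers (default pipeline setting 11), which captures the run-level nature
of autozygosity; the windowed peak localises the truth segment reliably in
simulation.

## Variant triage

Category precedence is coding > canonical splice > UTR > intronic >
intergenic, with the most severe category across transcripts. Canonical
splice sites are the two intronic bases adjacent to an exon; distances to
splice junctions are signed (positive downstream of a donor, negative
upstream of an acceptor), so the focal variant reports −9. UTR ranks above
intronic by the usual severity convention. Coding SNVs are split
synonymous/nonsynonymous by codon translation; multi-base events are
classified by every touched reference base, most severe wins, and coding
indels are conservatively called nonsynonymous. The rarity rule is: common
iff allele frequency ≥ threshold (default 1%, inclusive) in *any*
database; absent frequencies are treated as 0. "Noncoding" in summaries
means intronic + intergenic; UTR is reported separately. Conservation
scores are deliberately not used for ranking — a causal regulatory allele
need not be conserved.

## Intron retention

A read is *spanning* for intron *i* when it has ≥ `min_anchor` contiguous
aligned bases on both sides of either intron boundary with no splice gap
there, and *spliced* when its alignment gap coincides exactly with the
intron and both exonic anchors reach `min_anchor`. Everything else —
including reads wholly inside the intron — is uninformative: the estimator
uses junction evidence only. `min_anchor` defaults to 6 bp, a standard
junction-confidence setting. A read spanning both boundaries of a short
intron counts once. Counts are pooled across the samples of each genotype
group before testing (per-sample tables are also emitted for inspection).

R = spanning/(spanning+spliced); the 95% interval is Wilson score by
default (Clopper–Pearson via `ci_method="beta"`). Zero informative reads
is an error, not a zero estimate. The three pairwise group comparisons use
two-sided Fisher exact tests with Holm step-down over exactly that
three-test family. Allelic association counts reads by their base at the
variant position (bases other than ref/alt are excluded and reported) and
applies a two-sided exact binomial test against 0.5. In TSV mode there are
no base qualities and no quality filter; SAM input is supported for the
same read schema. FPKM = fragments / (exonic kb × millions of mapped
fragments).

## Consequence of a retained intron

The mutant coding sequence is the wild-type CDS with the intron inserted
at its junction; translation proceeds from the annotated start.
Conventions, chosen once for self-consistency and because they reproduce
the demonstration gene's arithmetic exactly ((1046+52)/3 = 366;
366 − ⌈1046/3⌉ = 17):

* `stop_offset_bp` = number of retained-intron bases translated into
  protein before termination; the stop codon begins at intron base
  `stop_offset_bp`+1.
* `aberrant_residues` counts residues whose codon's *first* base is
  intronic; the chimeric junction codon is not counted.
* Identity: 3 × mutant length + 3 equals the mutant-CDS position of the
  stop codon's last base (property-tested against a brute-force
  translation oracle on random toy genes).

A frame-preserving, stop-free intron yields no premature stop and an
in-frame insertion of length/3 residues. The wild-type CDS must pass
sanity checks (ATG start, terminal stop, length divisible by 3, no
internal stop).

NMD uses the 50-nt exon-junction rule with strict inequality, evaluated on
the *mutant* transcript's junction set (retaining intron *i* removes the
*i*/(*i*+1) junction and shifts downstream junctions by the intron
length). A stop in a retained final intron has no downstream junction and
is not flagged. The rule threshold is configurable (`rule_nt`).

RT-PCR product lengths for a primer pair flanking the intron are computed
in spliced-transcript coordinates; the unspliced product exceeds the
spliced one by exactly the intron length.

## RT-PCR and qPCR quantification

Percent-unspliced is a *relative* splicing measure (amplification
efficiency differs between amplicons); it is scale-invariant in the areas.
Group summaries use the sample SD (n−1). Pairwise tests are two-tailed
unpaired Student t (pooled variance) by default with Welch via
`equal_var=False` — the choice is ambiguous in common practice and does
not affect any acceptance-grade conclusion; Holm is applied over the
three-test family. Groups with fewer than two samples are summarised but
excluded from testing with a warning.

ΔΔCt assumes perfect doubling per cycle; the CI is a Welch t-interval on
the difference of group mean ΔCt, exponentiated endpoint-wise, hence
asymmetric around 2^(−ΔΔCt). The reference group reports exactly 1.

## Synthetic generators: what they emulate and what they do not

All generators draw from one seeded `numpy` Generator per call; the seed
is a required, explicit argument, and identical seed + configuration gives
byte-identical outputs. Every generator returns its latent truth.

*Genotypes* (`gen_genotypes`): 7 affected / 15 parents / 10 controls by
default, 1000 markers over a 10-Mb map with the autozygous segment equal
to the published minimal interval; affecteds are homozygous for one
founder haplotype across the segment (ε flips a call to heterozygous,
a missing rate masks calls); parents and controls are Hardy–Weinberg.
Not modelled: linkage disequilibrium, parental carrier haplotypes,
genotyping batch structure.

*Variant fixture* (`gen_variant_fixture`): by construction, 18 rare
intronic (one being the focal variant) and 20 rare intergenic variants
inside the candidate interval, zero rare coding/canonical-splice inside,
plus common variants inside and rare coding variants in the second gene
outside. Intergenic positions keep a 50-kb margin from the interval edges
so a marker-resolution interval estimate still contains them. Allele
frequencies are drawn per database below/above the 1% threshold.

*Junction reads* (`gen_junction_reads`): per fragment, an allele is chosen
per the sample's genotype, retained vs spliced with that allele's
retention probability, and the read is placed uniformly among
junction-informative placements — boundary-spanning for retained
molecules, valid-anchor splices for spliced molecules — so the configured
probability *is* the expected informative-read proportion and estimator
recovery is unbiased. Optional uninformative background reads are
available via `uninformative_fraction`. Default retention: 0.66 per mutant
allele in homozygotes and 0.07 per wild-type allele; the heterozygote
mutant-allele value is solved from the pooled heterozygote value 0.12
under equal allelic output (pooled = mean of allele rates), giving 0.17
and an expected mutant-base fraction among variant-covering reads of
0.17/0.24 ≈ 71%. Mutant-base tags appear only on mutant-allele retained
reads covering the variant; allelic purity is property-tested. Reads are
single-end fixed-length (100 bp); no sequencing errors, qualities,
duplicates or fragment-length distribution. Per-sample depth defaults
(400 fragments/intron) are free parameters chosen for desk-scale runs.

*Splice quantification* (`gen_splice_quant`): per-sample true
fraction-unspliced ~ Normal per group — defaults 0.85±0.05 / 0.38±0.13 /
0.24±0.10 for affected/parent/control — truncated to [0,1], with lognormal
total-area scale; Ct pairs consistent with the configured relative
expression (default 56% of wild type in mutation carriers) plus Gaussian
cycle noise. Not modelled: amplification-efficiency differences,
plate/batch effects.

Passing tests on these simulations demonstrates the estimators and their
statistical machinery, and internal consistency of the generator/estimator
pair — not performance on real sequencing data with alignment artefacts,
duplicate structure or mapping bias.

## Problem sizes and determinism

The test and acceptance runs use desk-scale sizes chosen as the package's
defaults: ≈11,000 junction-informative reads per genotype group for
retention recovery (binomial SE ≈ 0.5 percentage points), ≥5,000
variant-covering reads for the heterozygote allelic fraction, 20
samples/group for fragment-area recovery, and the packaged variant fixture
for triage counts. The end-to-end pipeline is byte-deterministic given the
config and seed.

## Known limitations

Single transcript per gene model (most-severe-across-models only);
no cryptic-splice-site discovery or novel-isoform assembly; no multipoint
linkage or IBD HMM; no CNV/SV handling; the homozygosity LOD is a
simplified statistic (see above); the ΔΔCt model ignores efficiency
calibration; published cohort-dependent values (the multipoint LOD of the
original study, its exact interval boundaries, FPKM group means, real
p-values) depend on restricted-access genotypes and are out of scope —
the statistical machinery behind them is verified against brute-force
oracles instead.
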