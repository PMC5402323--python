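# Methods

`alemut` analyses mutation accumulation in serial-passage (adaptive
laboratory evolution, ALE) experiments: replicate bacterial lineages are
propagated for thousands of generations with or without an antibiotic,
sequenced at regular intervals, and phenotyped by minimum inhibitory
concentration (MIC). The package covers the analysis from pileup allele
counts onward — read mapping is upstream and out of scope — plus a
synthetic-data generator that stands in for sequencing so every stage is
testable without any download.

## The synthetic ALE generator

**Genome.** A random sequence of configurable length and GC content is
tiled with non-overlapping CDS on both strands (uniform lengths between
`min_cds_length` and `max_cds_length`, rounded to codons) until roughly
`cds_fraction` of the genome is coding. Every CDS starts with ATG, ends
with a stop codon, and contains no internal in-frame stop. A numerical
subtlety: sampling sense-strand codons while rejecting stops removes
AT-rich codons and would inflate the realised GC by about 1.5 percentage
points at GC 0.46. The per-base GC used inside CDS is therefore solved
(Brent's method) so that the stop-conditioned expectation equals the
target; the realised genome GC then lands within the 1% construction
contract. The default genome is desk-scale — 100 kb at 46.4% GC, ~80%
coding — standing in for a ~2.9 Mb *Lactobacillus casei* chromosome. The
fixed-mutation supply is parameterised per genome per generation, not per
bp, so event counts stay realistic at any genome size.

**Population model.** The analysis only consumes per-timepoint allele
frequencies, so the simulator uses the minimal population model that
produces them: origin-fixation. De novo fixed mutations arrive as a
Poisson process with the arm's rate (default 0.01/generation for
antibiotic arms, 0.003 for the control); each event takes a uniform random
position (resampled on within-lineage collision) and, with probability
`indel_fraction` (default 5%), is a 1–3 bp indel instead of an SNV. SNV
alternate alleles follow a configurable distribution over the six
strand-collapsed substitution classes (`uniform` default; an
`lcasei_zhang` preset enriched for CG→AT and AT→CG transversions).
Neutral events fix instantly at their origin generation; events in
designated resistance-target genes of selected arms sweep logistically
from 1/N (N = `population_size`, default 10⁶) to fixation over
`sweep_generations` (default 200). Explicit bottleneck drift between
transfers is deliberately not modelled: under origin-fixation the sampled
population is monomorphic between events, and drift would only jitter the
sweep trajectories the downstream analysis never fits. A configurable
number of pre-existing SNVs is planted identically, at frequency 1 from
generation 0, in every lineage of every arm — the signature the
cross-lineage filter must exploit.

**Sequencing.** Pileups at each sampled generation draw site coverage from
Poisson(`coverage_mean`, default 200); each read reports the true local
allele and is then miscalled to a uniform other base with probability
`sequencing_error_rate` (default 0.003). Error never fabricates indels.
The pileup TSV carries two trailing columns (`ins_allele`, `del_allele`)
with the observed indel allele so that indel calls keep an exact
(position, ref, alt) identity; files without those columns still load.

**MIC.** Each resistance fixation doubles the arm's MIC from `mic_initial`
(default 2 µg/mL), capped at `mic_plateau_cap` (default 32 µg/mL); control
arms give a constant row. This reproduces the stepwise-doubling,
plateauing trajectories of broth-macrodilution series.

**Seeding.** One master seed; every stream is a numpy `default_rng` keyed
by `[seed, stream-tag, ...]` counters (genome 101, pre-existing variants
202, per-arm-per-lineage 303, per-lineage-per-generation pileups 404), so
any lineage or timepoint regenerates independently and byte-identically.

What the generator does *not* emulate: read-level errors correlated along
reads or by base quality, mapping artefacts, coverage waves, strand bias,
contamination, clonal interference, recombination and horizontal transfer.
Passing the recovery tests therefore shows the analysis chain is correct
under its own assumptions, not that it is robust to every artefact of real
short-read data.

## Two-tier variant calling

The two detector parameter sets are re-embodied as transparent rules on
allele counts (the original commercial detector's internals are
proprietary; this formulation is a declared stand-in that keeps the same
parameters).

*Fixed (high-quality) tier*: coverage strictly greater than `min_coverage`
(default >20) and posterior probability ≥ `fixed_probability` (default
90%) that the haploid consensus equals the top non-reference allele, under
a two-hypothesis model (true allele is ref or alt, symmetric miscall rate
`error_rate` spread uniformly over the three wrong bases, uniform prior).
Reads matching neither hypothesis cancel, so the log-likelihood ratio is
`(n_alt − n_ref)·log((1−e)/(e/3))`.

*Lenient tier*: same coverage bound, allele frequency ≥ `min_frequency`
(default 1%), and one-sided binomial tail P(X ≥ n_alt | n = coverage,
p = e/3) ≤ `significance` (default 1%) — the standard per-site
low-frequency caller test against the error rate of one specific wrong
base.

`error_rate` defaults to 0.003 and is configurable; e = 0 is handled as a
limit (any non-reference read is decisive). Ploidy is fixed at 1 and not
exposed. Indels are gated on the ins/del count columns: the lenient tier
applies the same frequency/significance gates; the fixed tier requires the
indel frequency to reach `fixed_probability`, a frequency criterion
standing in for the posterior, which is defined only for substitutions.
These rules make the fixed tier a strict subset of the lenient tier in
practice, and both are monotone in the alternate count — both properties
are under test.

## De novo identification and tracing

A fixed-tier variant identity (position, ref, alt — exact match, no fuzzy
indel matching) is removed as pre-existing when it appears in ≥2 lineages
from *different* arms; sharing between replicates of the same arm is kept,
because identical selection can legitimately fix the same mutation twice.
Anything present in a lineage's generation-0 baseline is removed as well —
on clean data this is equivalent to the cross-arm rule (the planted
ancestral SNVs satisfy both) but it also catches stock variants when only
one arm is analysed deeply. Removals are returned as an audit table, never
silently dropped.

Each retained variant is then dated from the lenient call set of its own
lineage only: `first_seen`/`last_seen` are the earliest/latest sampled
generations with a matching lenient call, `fixed_at` the earliest
fixed-tier call. Detection dropouts at intermediate timepoints are
reported as observed, without interpolation; a variant with no lenient
support at all keeps its fixed-tier dates and raises an audit warning.

## Statistics

- **Rates**: `rate_per_generation = mean count / generations`;
  `rate_per_bp_per_generation` divides by the genome length (chromosome
  length only, by default). Raw values throughout; rounding to 2
  significant figures (rates) and 2 decimals (ratios) happens only in the
  report layer.
- **Spectrum / Ti-Tv**: the 12 ordered substitutions collapse to 6 classes
  by strand complementarity, labelled with the reference pair first
  (AT→CG, AT→GC, AT→TA, CG→AT, CG→GC, CG→TA); transitions are AT→GC and
  CG→TA. Ti/Tv is flagged undefined when there are no transversions.
- **Consequences**: NCBI translation table 11, internal codons only, so
  alternative starts are irrelevant; stop gain/loss folds into
  "non-synonymous". Variants are classified strictly CDS vs intergenic.
- **Ka/Ks**: Nei–Gojobori site counting — each codon position contributes
  f/3 synonymous sites, f being the number of its three single-base
  changes that preserve the amino acid. Site totals are computed
  genome-wide over all CDS (standard for mutation-accumulation data with
  at most a few hits per gene), optionally re-weighted by an external
  codon-usage table over a genome-length-equivalent codon pool. Ka =
  non-synonymous SNVs per non-synonymous site, Ks likewise; no multiple-hit
  correction is applied at ~20 SNVs/genome, and the ratio is flagged
  undefined when no synonymous SNV was seen.
- **Non-synonymous enrichment**: one-tailed two-proportion z-test with
  pooled variance (statsmodels `proportions_ztest`, cross-checked against
  the closed form); degenerate pooled proportions are an error, not a NaN.
- **COG tallies**: a supplied gene→COG table is consumed, never fetched;
  replicate occurrences of the same gene accumulate, unmapped genes count
  as "unassigned", multi-letter assignments count once per letter.

Arm summaries average counts over lineages and pool SNVs for spectrum and
Ka/Ks.

## MIC fitness analysis

Per replicate, the plateau is the maximum MIC and the earliest sampled
generation attaining it (cumulative maximum, so a transient dip cannot
postpone it). The arm-level plateau MIC is the modal replicate maximum,
ties broken toward the lower (more conservative) MIC. Two dating rules are
maintained because doubling-dilution replicates genuinely disagree — one
tube can jump a dilution step 200 generations before the others: `all`
(default; earliest generation by which every replicate has attained the
consensus) and `first` (earliest generation any replicate attains it).
Both datings and the per-replicate table are always carried in the
summary, and disagreement is flagged rather than resolved. The adaptation
rate is 1/time-to-plateau, so the relative adaptation rate of two arms is
the inverse ratio of their plateau generations.

## Problem sizes used in the test and acceptance runs

Tests run on desk-scale genomes (20–50 kb; 200 kb for the false-positive
and recovery studies), chosen so the whole suite completes in well under a
minute of simulation time while keeping every statistical check at its
stated tolerance (2–3 SE, or exact where the quantity is deterministic).
The end-to-end recovery experiment simulates 50 treated lineages plus 2
controls for 2000 generations at 0.01 fixed mutations/generation on a
200 kb genome with error-free coverage-200 pileups. At that genome size
the chance that two independent lineages draw the same (position, alt)
event — which the cross-arm filter would then wrongly remove — is
negligible relative to the 2-SE acceptance band.

## Known limitations

- The fixed-tier posterior is a stand-in for an undocumented commercial
  detector; with deep coverage it calls any site whose top allele exceeds
  ~50%, so a mid-sweep variant can enter the "fixed" set before true
  fixation.
- Circularity is ignored: features spanning the origin of a circular
  chromosome are unsupported.
- Overlapping CDS are rejected at load (first-wins under an explicit
  escape hatch); consequence calling assumes one gene per position.
- Indel consequences are not classified beyond "indel" (no frameshift
  annotation), matching the SNV-focused downstream statistics.
- Lenient-set tracing cannot see below `min_frequency` or outside sampled
  generations, so `first_seen` is an upper bound on the origin generation.
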