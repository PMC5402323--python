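"""Summary statistics for mutation-accumulation experiments.

Covers per-arm mutation rates (per generation and per bp per generation),
the six-class mutation spectrum with the transition/transversion ratio,
Nei-Gojobori synonymous/non-synonymous site counting and the Ka/Ks ratio,
a one-tailed two-proportion z-test for enrichment of non-synonymous
changes, and COG functional-category tallies of mutated genes.

No multiple-hit or Jukes-Cantor correction is applied to Ka/Ks: at the
divergence these experiments reach (tens of SNVs per genome) each observed
SNV is a single mutational step.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Iterable, Mapping, Sequence

from .annotate import CODON_TO_AA, SPECTRUM_LABELS, spectrum_class
from .io_formats import ReferenceGenome

_BASES = ("A", "C", "G", "T")


@dataclass
class EvolutionStats:
    """Per-arm summary of the identified de novo mutations."""

    arm: str
    mean_denovo_count: float
    rate_per_generation: float
    rate_per_bp_per_generation: float
    spectrum_proportions: dict[str, float] = field(default_factory=dict)
    ti_tv: float | None = None
    n_synonymous: int = 0
    n_nonsynonymous: int = 0
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None
    nonsyn_fraction: float | None = None
    site_counts: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class ZTestResult:
    p1: float
    n1: int
    p2: float
    n2: int
    z: float
    p_one_tailed: float


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float | None
    ratio: float | None
    n_synonymous: int
    n_nonsynonymous: int

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def mutation_rate(mean_count: float, generations: int,
                  genome_length: int) -> tuple[float, float]:
    """(rate per generation, rate per bp per generation) from a mean
    per-lineage mutation count.  Raw values; presentation rounding (2
    significant figures) happens in the report layer."""
    if generations <= 0 or genome_length <= 0:
        raise ValueError("generations and genome_length must be positive")
    per_gen = mean_count / generations
    return per_gen, per_gen / genome_length


def spectrum_proportions(snvs: Iterable) -> tuple[dict[str, float], float | None]:
    """Per-class fractions of the six substitution classes, plus Ti/Tv.

    Accepts annotated mutations or (ref, alt) pairs; indels must have been
    excluded upstream.  Ti/Tv is None (undefined) when there are no
    transversions; an empty input gives an empty map.
    """
    counts: Counter[str] = Counter()
    transitions = 0
    total = 0
    for s in snvs:
        if hasattr(s, "ref_allele"):
            if getattr(s, "variant_type", "SNV") != "SNV":
                raise ValueError("spectrum is defined for SNVs only; filter indels first")
            sc = spectrum_class(s.ref_allele, s.alt_allele)
        else:
            sc = spectrum_class(s[0], s[1])
        counts[sc.label] += 1
        transitions += int(sc.is_transition)
        total += 1
    if total == 0:
        return {}, None
    props = {lab: counts.get(lab, 0) / total for lab in SPECTRUM_LABELS}
    transversions = total - transitions
    ti_tv = (transitions / transversions) if transversions > 0 else None
    return props, ti_tv


@lru_cache(maxsize=1)
def _per_codon_sites() -> dict[str, tuple[float, float]]:
    """Nei-Gojobori fractional site counts for all 64 codons.

    Each codon position contributes f/3 synonymous sites, f being the number
    of its three possible single-base changes that preserve the encoded
    amino acid (stop codons translate to '*', so stop<->stop is preserving).
    """
    table: dict[str, tuple[float, float]] = {}
    for codon_tuple in product(_BASES, repeat=3):
        codon = "".join(codon_tuple)
        aa = CODON_TO_AA[codon]
        syn = 0.0
        for i in range(3):
            preserving = 0
            for b in _BASES:
                if b == codon[i]:
                    continue
                if CODON_TO_AA[codon[:i] + b + codon[i + 1:]] == aa:
                    preserving += 1
            syn += preserving / 3.0
        table[codon] = (syn, 3.0 - syn)
    return table


def count_sites(ref: ReferenceGenome,
                codon_usage: Mapping[str, float] | None = None,
                ) -> tuple[float, float]:
    """(synonymous_sites, nonsynonymous_sites) over all CDS codons.

    Without a usage table the genome's own codons are counted.  With one,
    per-codon site counts are weighted by the supplied frequencies over a
    codon pool of the same total size (a genome-length-equivalent pool),
    which substitutes the species' genome-wide codon usage for the local
    annotation.
    """
    per_codon = _per_codon_sites()
    codon_counter: Counter[str] = Counter()
    for f in ref.features:
        seq = ref.sequence[f.start - 1: f.end]
        if f.strand == "-":
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            seq = "".join(comp[b] for b in reversed(seq))
        for i in range(0, len(seq), 3):
            codon = seq[i:i + 3]
            if set(codon) - set(_BASES):
                raise ValueError(f"CDS {f.gene_id} contains ambiguous bases")
            codon_counter[codon] += 1
    total_codons = sum(codon_counter.values())
    if codon_usage is not None:
        weights = {c.upper().replace("U", "T"): v for c, v in codon_usage.items()}
        wsum = sum(weights.values())
        if wsum <= 0:
            raise ValueError("codon usage frequencies must sum to a positive value")
        syn = total_codons * sum(w / wsum * per_codon[c][0] for c, w in weights.items())
        nonsyn = total_codons * sum(w / wsum * per_codon[c][1] for c, w in weights.items())
    else:
        syn = sum(n * per_codon[c][0] for c, n in codon_counter.items())
        nonsyn = sum(n * per_codon[c][1] for c, n in codon_counter.items())
    return syn, nonsyn


def ka_ks(snvs: Iterable, site_counts: tuple[float, float]) -> KaKsResult:
    """Ka/Ks from consequence-annotated CDS SNVs and NG site counts.

    ka = non-synonymous SNVs per non-synonymous site, ks = synonymous SNVs
    per synonymous site; the ratio is flagged undefined (None) when no
    synonymous SNV was observed.
    """
    syn_sites, nonsyn_sites = site_counts
    if syn_sites <= 0 or nonsyn_sites <= 0:
        raise ValueError("site counts must be positive")
    n_syn = sum(1 for s in snvs if s.consequence == "synonymous")
    n_nonsyn = sum(1 for s in snvs if s.consequence == "non-synonymous")
    ka = n_nonsyn / nonsyn_sites
    ks = n_syn / syn_sites if n_syn > 0 else None
    ratio = (ka / ks) if ks else None
    return KaKsResult(ka=ka, ks=ks, ratio=ratio,
                      n_synonymous=n_syn, n_nonsynonymous=n_nonsyn)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int,
                     tail: str = "greater") -> ZTestResult:
    """One-tailed two-proportion z-test with pooled variance.

    z = (p1 - p2) / sqrt(p_hat (1 - p_hat) (1/n1 + 1/n2)) with the pooled
    p_hat = (x1+x2)/(n1+n2); the p-value is the upper-tail normal
    probability.  Degenerate pooled proportions (0 or 1) are an error.
    """
    if tail != "greater":
        raise ValueError("only the upper-tailed test is defined here")
    if n1 <= 0 or n2 <= 0 or not (0 <= x1 <= n1) or not (0 <= x2 <= n2):
        raise ValueError("invalid counts")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion: variance is zero")
    from statsmodels.stats.proportion import proportions_ztest
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="larger")
    return ZTestResult(p1=x1 / n1, n1=n1, p2=x2 / n2, n2=n2,
                       z=float(z), p_one_tailed=float(p))


def cog_tally(denovo_genes: Iterable[tuple[str, str, str]],
              cog_map: Mapping[str, str | Sequence[str]],
              ) -> dict[str, Counter]:
    """Arm x COG-letter counts of mutated-gene occurrences.

    ``denovo_genes`` yields (arm, lineage_id, gene_id).  The same gene
    mutated in two replicate lineages counts twice — replicate occurrences
    accumulate.  Genes missing from the map land under "unassigned"; a gene
    mapped to several letters counts once per letter (documented
    multi-assignment).
    """
    tally: dict[str, Counter] = defaultdict(Counter)
    for arm, _lineage, gene in denovo_genes:
        letters = cog_map.get(gene)
        if letters is None or letters == "":
            tally[arm]["unassigned"] += 1
            continue
        if isinstance(letters, str):
            letters = list(letters)
        for letter in letters:
            tally[arm][letter] += 1
    return dict(tally)


def summarize_arm(arm: str, denovo: Sequence, n_lineages: int,
                  generations_total: int, ref: ReferenceGenome,
                  genome_length: int | None = None,
                  codon_usage: Mapping[str, float] | None = None,
                  ) -> EvolutionStats:
    """Pool one arm's annotated de novo mutations into an EvolutionStats.

    The mean count averages over lineages; the spectrum, Ti/Tv, Ka/Ks and
    non-synonymous fraction pool all of the arm's SNVs.
    """
    if n_lineages <= 0:
        raise ValueError("n_lineages must be positive")
    L = genome_length if genome_length is not None else len(ref.sequence)
    mean_count = len(denovo) / n_lineages
    per_gen, per_bp = mutation_rate(mean_count, generations_total, L)
    snvs = [m for m in denovo if m.variant_type == "SNV"]
    props, ti_tv = spectrum_proportions(snvs)
    sites = count_sites(ref, codon_usage)
    cds_snvs = [m for m in snvs if m.consequence in ("synonymous", "non-synonymous")]
    kk = ka_ks(cds_snvs, sites) if cds_snvs else None
    n_syn = kk.n_synonymous if kk else 0
    n_nonsyn = kk.n_nonsynonymous if kk else 0
    total_cds = n_syn + n_nonsyn
    return EvolutionStats(
        arm=arm, mean_denovo_count=mean_count, rate_per_generation=per_gen,
        rate_per_bp_per_generation=per_bp, spectrum_proportions=props,
        ti_tv=ti_tv, n_synonymous=n_syn, n_nonsynonymous=n_nonsyn,
        ka=kk.ka if kk else None, ks=kk.ks if kk else None,
        ka_ks=kk.ratio if kk else None,
        nonsyn_fraction=(n_nonsyn / total_cds) if total_cds else None,
        site_counts=sites)
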