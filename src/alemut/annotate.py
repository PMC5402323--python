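"""Coding consequence and strand-collapsed substitution-class annotation.

The 12 ordered single-base substitutions collapse to six classes by strand
complementarity (a change and its reverse complement are the same mutational
event on double-stranded DNA).  Class labels put the reference base pair
first: A:T pairs render as "AT", G:C pairs as "CG".  Transitions are the
purine<->purine / pyrimidine<->pyrimidine classes AT→GC and CG→TA.

Consequences are called against the bacterial genetic code (NCBI table 11);
only internal codons are compared, so alternative start codons are
irrelevant, and stop gain/loss counts as non-synonymous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data import CodonTable

from .io_formats import ReferenceGenome, VariantCall

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SPECTRUM_LABELS = ("AT→CG", "AT→GC", "AT→TA", "CG→AT", "CG→GC", "CG→TA")
TRANSITION_LABELS = frozenset({"AT→GC", "CG→TA"})

_table = CodonTable.unambiguous_dna_by_id[11]
#: codon -> amino acid, stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
CODON_TO_AA.update({c: "*" for c in _table.stop_codons})
del _table


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SpectrumClass:
    label: str
    is_transition: bool


def spectrum_class(ref_base: str, alt_base: str) -> SpectrumClass:
    """Collapse an ordered substitution to one of the six strand-symmetric classes."""
    if ref_base not in _COMPLEMENT or alt_base not in _COMPLEMENT:
        raise ValueError(f"bases must be A/C/G/T, got {ref_base!r}->{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError(f"ref and alt base are identical ({ref_base})")
    # normalise so the reference base is the A-or-C representative of its pair
    if ref_base in ("T", "G"):
        ref_base, alt_base = complement(ref_base), complement(alt_base)
    ref_pair = "AT" if ref_base == "A" else "CG"
    alt_pair = {"A": "AT", "T": "TA", "C": "CG", "G": "GC"}[alt_base]
    label = f"{ref_pair}→{alt_pair}"
    if label not in SPECTRUM_LABELS:
        raise AssertionError(f"unmapped substitution {ref_base}->{alt_base}")
    return SpectrumClass(label=label, is_transition=label in TRANSITION_LABELS)


def classify_consequence(variant: VariantCall | tuple[int, str, str],
                         ref: ReferenceGenome) -> tuple[str, str | None]:
    """Return (consequence, gene_id) for an SNV against the reference.

    consequence is "synonymous", "non-synonymous" or "intergenic".  The
    affected codon is translated before and after the change, reading through
    the reverse complement for '-'-strand genes.
    """
    if isinstance(variant, VariantCall):
        pos, ref_base, alt_base = variant.position, variant.ref_allele, variant.alt_allele
    else:
        pos, ref_base, alt_base = variant
    if len(ref_base) != 1 or len(alt_base) != 1:
        raise ValueError("consequence calling is defined for SNVs only")
    if not 1 <= pos <= len(ref.sequence):
        raise ValueError(f"position {pos} outside genome bounds")
    genome_base = ref.base_at(pos)
    if genome_base != ref_base:
        raise ValueError(
            f"ref allele {ref_base} does not match genome base {genome_base} at {pos}")

    feature = ref.feature_at(pos)
    if feature is None:
        return "intergenic", None

    if feature.strand == "+":
        offset = pos - feature.start          # 0-based offset into the CDS
    else:
        offset = feature.end - pos
    codon_index = offset // 3
    within = offset % 3
    if feature.strand == "+":
        codon_start = feature.start + 3 * codon_index
        codon = ref.sequence[codon_start - 1: codon_start + 2]
        new_codon = codon[:within] + alt_base + codon[within + 1:]
    else:
        codon_end = feature.end - 3 * codon_index
        codon_fwd = ref.sequence[codon_end - 3: codon_end]
        codon = reverse_complement(codon_fwd)
        new_codon = codon[:within] + complement(alt_base) + codon[within + 1:]
    aa_before = CODON_TO_AA[codon]
    aa_after = CODON_TO_AA[new_codon]
    consequence = "synonymous" if aa_before == aa_after else "non-synonymous"
    return consequence, feature.gene_id


def annotate_denovo(mutations: Iterable, ref: ReferenceGenome) -> None:
    """Fill consequence, gene_id and spectrum fields of DeNovoMutation records.

    Indels get consequence "indel" (gene assignment still reported when the
    anchor position falls in a CDS) and no spectrum class.
    """
    for m in mutations:
        if m.variant_type == "SNV":
            sc = spectrum_class(m.ref_allele, m.alt_allele)
            m.spectrum_class = sc.label
            m.is_transition = sc.is_transition
            m.consequence, m.gene_id = classify_consequence(
                (m.position, m.ref_allele, m.alt_allele), ref)
        else:
            m.spectrum_class = None
            m.is_transition = None
            m.consequence = "indel"
            feature = ref.feature_at(m.position)
            m.gene_id = feature.gene_id if feature is not None else None
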