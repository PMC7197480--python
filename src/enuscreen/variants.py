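"""ENU variant filtering, consequence annotation, and spectrum summaries.

Whole-exome candidate lesions from mutagenized founders are cleaned by
subtracting inbred-strain polymorphisms (sites seen in the parental
strains), catalogued SNPs, and sites shared across founder males
(recurrent artifacts), and by dropping lesions predicted to be tolerated.
Surviving single-nucleotide variants are annotated codon-by-codon against
a minimal transcript model, and the resulting set is summarized as a
consequence spectrum, a 12-class substitution spectrum, and a per-gene
allele tally (how many genes carry lesions in 1, 2, 3, ... founder lines).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .scoring import InvalidInputError

CONSEQUENCES = (
    "missense",
    "nonsense",
    "splice",
    "frameshift",
    "stop_loss",
    "synonymous",
    "noncoding",
)
PREDICTIONS = ("damaging", "tolerated", "unknown")
BASES = ("A", "C", "G", "T")
# the 12 ordered substitution classes, as sequenced (no strand collapsing)
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in BASES for a in BASES if r != a
)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

Site = Tuple[str, int, str, str]


class TranscriptModelError(ValueError):
    """Raised when a transcript model is internally inconsistent."""


@dataclass(frozen=True)
class Variant:
    """A single candidate ENU lesion in one founder line."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    line: str = ""
    consequence: Optional[str] = None
    prediction: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidInputError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise InvalidInputError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise InvalidInputError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise InvalidInputError(f"unknown consequence {self.consequence!r}")
        if self.prediction not in PREDICTIONS:
            raise InvalidInputError(f"unknown prediction {self.prediction!r}")

    @property
    def site(self) -> Site:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class TranscriptModel:
    """Minimal coding transcript: CDS exon intervals plus the CDS sequence.

    ``cds_exons`` are 1-based inclusive genomic intervals in genomic order;
    ``cds_sequence`` is the spliced coding-strand sequence (for '-' strand
    transcripts this is the reverse complement of the genomic sequence).
    """

    gene: str
    chrom: str
    strand: str
    cds_exons: Tuple[Tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_exons:
            raise TranscriptModelError("at least one CDS exon required")
        prev_end = 0
        for start, end in self.cds_exons:
            if start < 1 or end < start:
                raise TranscriptModelError(f"bad exon interval ({start}, {end})")
            if start <= prev_end:
                raise TranscriptModelError("exons must be disjoint and sorted")
            prev_end = end
        length = sum(end - start + 1 for start, end in self.cds_exons)
        seq = self.cds_sequence.upper()
        if len(seq) != length:
            raise TranscriptModelError(
                f"CDS length {len(seq)} != summed exon length {length}"
            )
        if length % 3 != 0:
            raise TranscriptModelError(f"CDS length {length} not divisible by 3")
        if not seq.startswith("ATG"):
            raise TranscriptModelError("CDS must begin with ATG")
        if seq[-3:] not in standard_dna_table.stop_codons:
            raise TranscriptModelError("CDS must end with a stop codon")

    @property
    def span(self) -> Tuple[int, int]:
        return self.cds_exons[0][0], self.cds_exons[-1][1]

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """0-based CDS index for a genomic position, or None if intronic/outside."""
        offset = 0
        if self.strand == "+":
            for start, end in self.cds_exons:
                if start <= pos <= end:
                    return offset + (pos - start)
                offset += end - start + 1
        else:
            for start, end in reversed(self.cds_exons):
                if start <= pos <= end:
                    return offset + (end - pos)
                offset += end - start + 1
        return None

    def distance_to_exon_boundary(self, pos: int) -> Optional[int]:
        """For an intronic position, distance (bp) to the nearest exon edge."""
        for (s1, e1), (s2, _) in zip(self.cds_exons, self.cds_exons[1:]):
            if e1 < pos < s2:
                return min(pos - e1, s2 - pos)
        return None


@dataclass
class VariantPanels:
    """Exclusion panels keyed by (chrom, pos, ref, alt)."""

    parental_strain_variants: Set[Site] = field(default_factory=set)
    known_catalogue: Set[Site] = field(default_factory=set)
    founder_site_matrix: Dict[Site, Set[str]] = field(default_factory=dict)

    @classmethod
    def from_variant_lists(
        cls,
        parental: Iterable[Variant] = (),
        known: Iterable[Variant] = (),
        founders: Iterable[Variant] = (),
    ) -> "VariantPanels":
        matrix: Dict[Site, Set[str]] = {}
        for v in founders:
            matrix.setdefault(v.site, set()).add(v.line)
        return cls(
            parental_strain_variants={v.site for v in parental},
            known_catalogue={v.site for v in known},
            founder_site_matrix=matrix,
        )


@dataclass(frozen=True)
class SpectrumSummary:
    """Counts/percentages by consequence, substitution class, and gene recurrence."""

    total: int
    consequence_counts: Mapping[str, int]
    consequence_percent: Mapping[str, int]
    substitution_counts: Mapping[str, int]
    allele_tally: Mapping[int, int]


def substitution_class(ref: str, alt: str) -> str:
    """One of the 12 ordered base changes, reported as sequenced.

    No strand collapsing: A>G and T>C are distinct classes (ENU spectra
    report them separately).
    """
    if ref not in BASES or alt not in BASES:
        raise InvalidInputError(f"non-ACGT substitution ({ref!r}, {alt!r})")
    if ref == alt:
        raise InvalidInputError(f"ref == alt ({ref})")
    return f"{ref}>{alt}"


def filter_candidates(
    variants: Sequence[Variant],
    panels: VariantPanels,
    sharing_threshold: int = 2,
) -> List[Variant]:
    """Subtract panel sites, cross-founder recurrences, and tolerated calls.

    A variant is removed if its site appears in the parental-strain panel,
    the known-variant catalogue, or in >= ``sharing_threshold`` *other*
    founder lines, or if its tolerance prediction is "tolerated".
    Order-stable and idempotent; the subtractive stages commute.
    """
    if sharing_threshold < 1:
        raise InvalidInputError("sharing_threshold must be >= 1")
    kept = []
    for v in variants:
        if v.site in panels.parental_strain_variants:
            continue
        if v.site in panels.known_catalogue:
            continue
        others = panels.founder_site_matrix.get(v.site, set()) - {v.line}
        if len(others) >= sharing_threshold:
            continue
        if v.prediction == "tolerated":
            continue
        kept.append(v)
    return kept


def classify_consequence(
    variant: Variant,
    model: TranscriptModel,
    splice_window: int = 2,
) -> str:
    """Consequence of a variant against a transcript model.

    SNVs in the CDS get a codon-level call through the standard genetic
    code (strand-aware); intronic positions within ``splice_window`` bp of
    an exon boundary are splice; length-changing indels in the CDS are
    frameshift unless the length change is a multiple of 3 (treated as
    missense at the protein level); anything outside the transcript span
    is noncoding.
    """
    if variant.chrom != model.chrom:
        return "noncoding"
    start, end = model.span
    pos = variant.pos
    if not variant.is_snv:
        delta = abs(len(variant.ref) - len(variant.alt))
        if model.genomic_to_cds(pos) is None:
            dist = model.distance_to_exon_boundary(pos)
            if dist is not None and dist <= splice_window:
                return "splice"
            return "noncoding"
        if delta % 3 != 0:
            return "frameshift"
        return "missense"
    if pos < start or pos > end:
        return "noncoding"
    idx = model.genomic_to_cds(pos)
    if idx is None:
        dist = model.distance_to_exon_boundary(pos)
        if dist is not None and dist <= splice_window:
            return "splice"
        return "noncoding"
    # codon-level call on the coding strand
    ref_c = variant.ref if model.strand == "+" else _COMPLEMENT[variant.ref]
    alt_c = variant.alt if model.strand == "+" else _COMPLEMENT[variant.alt]
    seq = model.cds_sequence.upper()
    if seq[idx] != ref_c:
        raise TranscriptModelError(
            f"reference mismatch at {variant.chrom}:{pos}: model has "
            f"{seq[idx]} on the coding strand, variant ref implies {ref_c}"
        )
    codon_start = (idx // 3) * 3
    ref_codon = seq[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: idx % 3] + alt_c + ref_codon[idx % 3 + 1 :]
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    if ref_aa == "*":
        return "stop_loss"
    return "missense"


def summarize_spectrum(variants: Sequence[Variant]) -> SpectrumSummary:
    """Consequence counts/percentages, substitution counts, and allele tally.

    Percentages are rounded to the nearest integer (as printed in screen
    reports).  The allele tally counts, per gene, the number of distinct
    (gene, line) lesions, i.e. how many founder lines carry an allele of
    that gene; the tally maps k alleles -> number of genes with k.
    """
    total = len(variants)
    cons = Counter(v.consequence for v in variants if v.consequence is not None)
    subs = Counter(
        substitution_class(v.ref, v.alt) for v in variants if v.is_snv
    )
    pairs: Set[Tuple[str, str]] = {
        (v.gene, v.line) for v in variants if v.gene
    }
    per_gene = Counter(gene for gene, _ in pairs)
    tally = Counter(per_gene.values())
    percent = (
        {c: round(100 * n / total) for c, n in cons.items()} if total else {}
    )
    return SpectrumSummary(
        total=total,
        consequence_counts=dict(cons),
        consequence_percent=percent,
        substitution_counts=dict(subs),
        allele_tally=dict(tally),
    )


def genome_equivalents(
    n_gametes: int, gametes_per_equivalent: float = 655.0
) -> float:
    """Genome equivalents screened: gametes / gametes-per-equivalent.

    At the standard 3 x 100 mg/kg ENU dose, roughly one new mutation
    arises per gene in every 655 gametes screened, so 655 gametes amount
    to one genome's equivalent of mutagenized gene copies.
    """
    if n_gametes < 0:
        raise InvalidInputError(f"n_gametes must be >= 0, got {n_gametes}")
    if gametes_per_equivalent <= 0:
        raise InvalidInputError("gametes_per_equivalent must be positive")
    return n_gametes / gametes_per_equivalent
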