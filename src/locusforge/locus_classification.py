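"""Locus typing (coding / noncoding / transposon / expressTE) and gene naming.

Coding potential combines protein homology with open-reading-frame
statistics (ORF length, ORF fraction of the transcript, introns in the
coding span).  Loci resembling transposons but showing genuine expression
plus non-transposon insect homology are kept as the indeterminate
"expressTE" class rather than being discarded.  Gene names are taken from
the best significant protein hit, with qualifiers stepping down with
alignment coverage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .evidence_scoring import EvidenceScores, SupportTier, support_tier
from .io_formats import AlignmentRecord, TranscriptModel

STOP_CODONS = {"TAA", "TAG", "TGA"}


class LocusType(enum.Enum):
    CODING = "coding"
    NONCODING = "noncoding"
    TRANSPOSON = "transposon"
    EXPRESS_TE = "expressTE"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class OrfStats:
    orf_length_bp: int
    transcript_length_bp: int
    introns_in_cds: int = 0
    complete: bool = True

    @property
    def orf_fraction(self) -> float:
        if self.transcript_length_bp == 0:
            return 0.0
        return self.orf_length_bp / self.transcript_length_bp


@dataclass
class ClassifyThresholds:
    """Defaults for the ORF-based coding-potential rules.

    An ORF of >= 300 bp covering >= 30 % of the transcript is treated as
    evidence of coding potential even without homology; the expression
    minimum separating bare transposons from expressTE loci reuses the
    medium support tier (> 1/3 overlap)."""

    min_orf_bp: int = 300
    min_orf_fraction: float = 0.3
    expr_min: float = 1.0 / 3.0
    evalue_max: float = 1e-5


@dataclass(frozen=True)
class NamingRecord:
    gene_id: str
    name: str
    qualifier: str  # none | putative | like | uncharacterized
    target_name: str = ""
    e_value: float | None = None
    aligned_fraction: float | None = None


def find_orf(sequence: str) -> OrfStats:
    """Longest ATG-initiated ORF across the three forward frames.

    The mRNA sequence is scanned 5'->3'; an ORF runs from ATG to the first
    in-frame stop.  If an ATG never reaches a stop before the transcript
    end the open stretch still counts but is flagged partial; with no ATG
    at all, the longest stop-free frame stretch is reported (partial).
    Sequences that are > 50 % ambiguous are rejected.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if n == 0:
        return OrfStats(0, 0, complete=False)
    ambiguous = sum(1 for c in seq if c not in "ACGT")
    if ambiguous / n > 0.5:
        raise ValueError("sequence is more than 50% ambiguous")

    best_len, best_complete = 0, False
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, n - 2, 3)]
        i = 0
        while i < len(codons):
            if codons[i] == "ATG":
                j = i
                while j < len(codons) and codons[j] not in STOP_CODONS:
                    j += 1
                complete = j < len(codons)
                length = (j - i + (1 if complete else 0)) * 3
                if (complete, length) > (best_complete, best_len) or (
                    complete == best_complete and length > best_len
                ):
                    best_len, best_complete = length, complete
                i = j + 1
            else:
                i += 1
    if best_len > 0:
        return OrfStats(best_len, n, complete=best_complete)

    # no ATG-initiated ORF: report longest stop-free stretch, flagged partial
    longest = 0
    for frame in range(3):
        run = 0
        for i in range(frame, n - 2, 3):
            if seq[i : i + 3] in STOP_CODONS:
                run = 0
            else:
                run += 3
                longest = max(longest, run)
    return OrfStats(longest, n, complete=False)


def classify_locus(
    model: TranscriptModel,
    scores: EvidenceScores,
    orf: OrfStats | None = None,
    thresholds: ClassifyThresholds | None = None,
) -> LocusType:
    """Assign the locus type from homology, expression and ORF evidence.

    Priority order (mutually exclusive, exhaustive given any evidence):

    1. transposon — transposon homology dominates non-transposon homology
       and expression is at most the ``expr_min`` tier;
    2. expressTE — transposon homology, but with real expression *and*
       non-transposon reference homology (kept as indeterminate);
    3. coding — significant non-transposon homology, or a substantial ORF;
    4. noncoding — expression support without homology or ORF evidence;
    5. unclassifiable — no evidence at all (excluded from the good set).
    """
    th = thresholds or ClassifyThresholds()
    h = scores.homology
    te_dominant = h.best_transposon_bits > h.best_bits and (
        h.best_transposon_bits > 0
    )
    if te_dominant:
        if scores.expr_overlap > th.expr_min and h.best_bits > 0:
            return LocusType.EXPRESS_TE
        if scores.expr_overlap <= th.expr_min:
            return LocusType.TRANSPOSON
        # expressed TE without supporting insect homology stays a transposon
        return LocusType.TRANSPOSON
    orf_ok = (
        orf is not None
        and orf.orf_length_bp >= th.min_orf_bp
        and orf.orf_fraction >= th.min_orf_fraction
    )
    if h.best_bits > 0 or orf_ok:
        return LocusType.CODING
    if scores.expr_overlap > 0 or scores.splices_hit > 0:
        return LocusType.NONCODING
    if h.best_transposon_bits > 0:
        return LocusType.TRANSPOSON
    return LocusType.UNCLASSIFIABLE


def assign_name(
    gene_id: str,
    best_alignment: AlignmentRecord | None,
    evalue_max: float = 1e-5,
) -> NamingRecord:
    """Name a gene from its best significant protein hit.

    Alignment coverage (aligned fraction of the target protein) steps the
    name through half-open bins: >= 66 % plain name, [33, 66) % "putative",
    [10, 33) % "-like", below 10 % (or no significant hit)
    "uncharacterized protein".
    """
    if best_alignment is None or best_alignment.e_value >= evalue_max:
        return NamingRecord(gene_id, "uncharacterized protein", "uncharacterized")
    frac = best_alignment.aligned_fraction
    base = best_alignment.target_name or best_alignment.target_id
    if frac >= 0.66:
        return NamingRecord(
            gene_id, base, "none", base, best_alignment.e_value, frac
        )
    if frac >= 0.33:
        return NamingRecord(
            gene_id, f"putative {base}", "putative", base,
            best_alignment.e_value, frac,
        )
    if frac >= 0.10:
        return NamingRecord(
            gene_id, f"{base}-like", "like", base, best_alignment.e_value, frac
        )
    return NamingRecord(
        gene_id, "uncharacterized protein", "uncharacterized", base,
        best_alignment.e_value, frac,
    )
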