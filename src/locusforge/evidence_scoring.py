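"""Per-model evidence scores and their weighted combination.

Each candidate gene model is annotated with four classes of evidence
support:

(a) expression — fraction of its exon bases covered by RNA-seq / tiling /
    EST coverage spans;
(b) intron support — fraction of its introns that coincide exactly with
    splice junctions validated by >= 3 spliced reads;
(c) structure agreement — how well an independently assembled or aligned
    structure (EST assembly, protein alignment, RNA assembly) matches the
    model, graded perfect / equal66 / some / none;
(d) protein homology — best bitscore, bitscore per amino acid, number of
    reference species hit, and best same-species (paralog) bitscore.

Transposon overlap enters as a subtractive penalty.  The weighted sum of
the normalized components is the model's selection score S.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import (
    GenomicInterval,
    intersection_bases,
    merge_intervals,
    total_bases,
)
from .io_formats import (
    MIN_JUNCTION_READS,
    AlignmentRecord,
    EvidenceBundle,
    JunctionRecord,
    TranscriptModel,
)


class StructureClass(enum.IntEnum):
    """Agreement between a model and one evidence structure.

    Ordered so that better agreement compares greater; the count of models
    at >= a given level is therefore nested (perfect <= equal66 <= some).
    """

    NONE = 0
    SOME = 1
    EQUAL66 = 2
    PERFECT = 3


class SupportTier(enum.Enum):
    NONE = "none"
    MEDIUM = "medium"
    STRONG = "strong"


class Direction(enum.Enum):
    OF_SUBJECT = "of_subject"    # fraction of subject bases covered
    OF_EVIDENCE = "of_evidence"  # fraction of evidence bases recovered


@dataclass
class WeightConfig:
    """Weights and normalization caps for the evidence sum.

    The published selection runs tuned weights iteratively against expert
    review; the defaults here are declared toolkit defaults, not a claim
    about any particular historical configuration.  ``transposon`` is a
    penalty weight (subtracted).  ``bits_per_aa_cap`` rescales the homology
    component onto [0, 1]; 2.0 bits/aa is a typical self-hit density.
    """

    expression: float = 1.0
    intron: float = 1.0
    structure_est: float = 0.5
    structure_protein: float = 0.5
    structure_rna: float = 0.5
    homology: float = 1.0
    transposon: float = 1.0
    min_threshold: float = 0.1
    bits_per_aa_cap: float = 2.0
    end_tolerance: int = 50
    evalue_max: float = 1e-5
    min_reads: int = MIN_JUNCTION_READS
    source_priority: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "expression",
            "intron",
            "structure_est",
            "structure_protein",
            "structure_rna",
            "homology",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name} must be >= 0")
        if self.min_threshold < 0:
            raise ValueError("min_threshold must be >= 0")


@dataclass
class HomologyScore:
    best_bits: float = 0.0
    bits_per_aa: float = 0.0
    n_ref_species: int = 0
    paralog_bits: float = 0.0
    best_transposon_bits: float = 0.0
    bits_per_aa_undefined: bool = False


@dataclass
class EvidenceScores:
    """All component scores for one model plus the weighted total."""

    model_id: str
    expr_overlap: float = 0.0
    splices_hit: float = 0.0
    structure: dict[str, StructureClass] = field(default_factory=dict)
    homology: HomologyScore = field(default_factory=HomologyScore)
    transposon_overlap: float = 0.0
    total: float = 0.0


def base_overlap_fraction(
    subject_intervals: Sequence[GenomicInterval],
    evidence_intervals: Sequence[GenomicInterval],
    direction: Direction = Direction.OF_SUBJECT,
) -> float:
    """Base-level overlap between two interval collections.

    Both sides are merged to deduplicated unions first, so the result is
    |intersection| / |denominator side| in distinct genome bases.  An empty
    denominator side makes the fraction undefined and returns NaN (distinct
    from a true 0.0).
    """
    denom_side = (
        subject_intervals
        if direction is Direction.OF_SUBJECT
        else evidence_intervals
    )
    denom = total_bases(denom_side) if denom_side else 0
    if denom == 0:
        return math.nan
    if not subject_intervals or not evidence_intervals:
        return 0.0
    inter = intersection_bases(subject_intervals, evidence_intervals)
    return inter / denom


def splices_hit(
    models: Sequence[TranscriptModel],
    junctions: Sequence[JunctionRecord],
    min_reads: int = MIN_JUNCTION_READS,
    direction: Direction = Direction.OF_EVIDENCE,
) -> float:
    """Set-level intron validation statistic.

    ``OF_EVIDENCE`` (the reporting direction): fraction of validated
    junction locations recovered by the model set's introns.
    ``OF_SUBJECT``: fraction of the model set's intron locations that are
    validated junctions.
    """
    validated = {
        j.key for j in junctions if j.is_validated(min_reads)
    }
    model_introns = {
        (i.seq_id, i.start, i.end, i.strand)
        for m in models
        for i in m.introns
    }
    if direction is Direction.OF_EVIDENCE:
        if not validated:
            warnings.warn("no validated junctions; splices_hit is 0")
            return 0.0
        return len(validated & model_introns) / len(validated)
    if not model_introns:
        return 0.0
    return len(validated & model_introns) / len(model_introns)


def model_intron_support(
    model: TranscriptModel,
    junction_index: Mapping[tuple[str, int, int, str], int],
    min_reads: int = MIN_JUNCTION_READS,
) -> tuple[float, list[bool]]:
    """Per-model intron support: fraction of introns matching validated
    junctions, plus a per-intron flag list.  Intron-less models score 1.0
    (no splice evidence can contradict them)."""
    flags = [
        junction_index.get((i.seq_id, i.start, i.end, i.strand), 0) >= min_reads
        for i in model.introns
    ]
    if not flags:
        return 1.0, []
    return sum(flags) / len(flags), flags


def _exon_jaccard(a: TranscriptModel, b: TranscriptModel) -> float:
    inter = intersection_bases(a.exons, b.exons)
    union = total_bases(list(a.exons) + list(b.exons))
    return inter / union if union else 0.0


def structure_agreement(
    model: TranscriptModel,
    evidence_structure: TranscriptModel,
    end_tolerance: int = 50,
) -> StructureClass:
    """Grade how closely an evidence structure matches a model.

    * PERFECT — identical internal splice-site chain (same introns) and
      terminal transcript ends within ``end_tolerance`` bp (UTR ends vary
      between assemblies; 0 gives strict end-to-end matching).
    * EQUAL66 — exon-base Jaccard >= 2/3.
    * SOME — any exon-base overlap.
    * NONE — different seq_id/strand or no overlap.
    """
    if (
        model.seq_id != evidence_structure.seq_id
        or model.strand != evidence_structure.strand
    ):
        return StructureClass.NONE
    inter = intersection_bases(model.exons, evidence_structure.exons)
    if inter == 0:
        return StructureClass.NONE
    same_introns = model.introns == evidence_structure.introns
    ends_ok = (
        abs(model.span.start - evidence_structure.span.start) <= end_tolerance
        and abs(model.span.end - evidence_structure.span.end) <= end_tolerance
    )
    if same_introns and ends_ok:
        return StructureClass.PERFECT
    if _exon_jaccard(model, evidence_structure) >= 2.0 / 3.0:
        return StructureClass.EQUAL66
    return StructureClass.SOME


def best_structure_class(
    model: TranscriptModel,
    structures: Iterable[TranscriptModel],
    end_tolerance: int = 50,
) -> StructureClass:
    best = StructureClass.NONE
    for s in structures:
        best = max(best, structure_agreement(model, s, end_tolerance))
        if best is StructureClass.PERFECT:
            break
    return best


def homology_score(
    model_id: str,
    protein_length: int | None,
    alignments: Sequence[AlignmentRecord],
    evalue_max: float = 1e-5,
    self_species: str = "self",
) -> HomologyScore:
    """Summarize significant protein hits for one model.

    Only alignments with e-value < ``evalue_max`` count.  The headline
    bitscore excludes transposon targets (kept separately) and same-species
    paralog hits (reported as ``paralog_bits``).
    """
    hits = [
        a
        for a in alignments
        if a.query_id == model_id and a.e_value < evalue_max
    ]
    hs = HomologyScore()
    ref_species: set[str] = set()
    for a in hits:
        if a.is_transposon_target:
            hs.best_transposon_bits = max(hs.best_transposon_bits, a.bitscore)
        elif a.target_species == self_species:
            hs.paralog_bits = max(hs.paralog_bits, a.bitscore)
        else:
            hs.best_bits = max(hs.best_bits, a.bitscore)
            ref_species.add(a.target_species)
    hs.n_ref_species = len(ref_species)
    if hs.best_bits > 0:
        if not protein_length:
            hs.bits_per_aa_undefined = True
        else:
            hs.bits_per_aa = hs.best_bits / protein_length
    return hs


_STRUCTURE_COMPONENT = {
    StructureClass.NONE: 0.0,
    StructureClass.SOME: 1.0 / 3.0,
    StructureClass.EQUAL66: 2.0 / 3.0,
    StructureClass.PERFECT: 1.0,
}


def score_model(scores: EvidenceScores, weights: WeightConfig) -> float:
    """Weighted evidence sum S for one model.

    Every component is normalized to [0, 1] (bits/aa is divided by its cap
    and clipped); transposon overlap is subtracted.  Negative totals are
    clamped to 0 so S remains comparable to the selection threshold.
    """
    homol = min(scores.homology.bits_per_aa / weights.bits_per_aa_cap, 1.0)
    components = {
        "expression": (weights.expression, scores.expr_overlap),
        "intron": (weights.intron, scores.splices_hit),
        "homology": (weights.homology, homol),
    }
    for src, wname in (
        ("est", "structure_est"),
        ("protein", "structure_protein"),
        ("rna", "structure_rna"),
    ):
        cls = scores.structure.get(src, StructureClass.NONE)
        components[wname] = (
            getattr(weights, wname),
            _STRUCTURE_COMPONENT[cls],
        )
    total = 0.0
    for name, (w, s) in components.items():
        if math.isnan(s):
            s = 0.0
        if s < 0:
            raise ValueError(f"negative component {name} after normalization")
        total += w * s
    total -= weights.transposon * scores.transposon_overlap
    return max(total, 0.0)


def support_tier(fraction: float) -> SupportTier:
    """Evidence tier: strong iff overlap > 2/3, medium iff > 1/3 (strict)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction out of range: {fraction}")
    if fraction > 2.0 / 3.0:
        return SupportTier.STRONG
    if fraction > 1.0 / 3.0:
        return SupportTier.MEDIUM
    return SupportTier.NONE


def compute_scores(
    models: Sequence[TranscriptModel],
    bundle: EvidenceBundle,
    weights: WeightConfig | None = None,
    self_species: str = "self",
) -> dict[str, EvidenceScores]:
    """Score every model against the evidence bundle.

    Returns a ``model_id -> EvidenceScores`` map with the weighted total
    filled in.  Structure agreement is graded separately for EST
    assemblies, protein-to-genome structures and RNA assemblies
    (transcript structures carry ``source`` labels starting with ``est``
    or ``rna``).
    """
    from .intervals import MergedIndex, SpanIndex

    weights = weights or WeightConfig()
    junction_index = {j.key: j.read_count for j in bundle.junctions}
    cov_index = MergedIndex(c.span for c in bundle.coverage)
    te_index = MergedIndex(bundle.transposon_spans)
    struct_indexes = {
        "est": SpanIndex(
            (s.span, s)
            for s in bundle.transcript_structures
            if s.source.startswith("est")
        ),
        "protein": SpanIndex((s.span, s) for s in bundle.protein_structures),
        "rna": SpanIndex(
            (s.span, s)
            for s in bundle.transcript_structures
            if not s.source.startswith("est")
        ),
    }
    align_by_query: dict[str, list[AlignmentRecord]] = {}
    for a in bundle.alignments:
        align_by_query.setdefault(a.query_id, []).append(a)

    out: dict[str, EvidenceScores] = {}
    for m in models:
        es = EvidenceScores(model_id=m.model_id)
        exon_bases = sum(e.length for e in m.exons)  # exons are disjoint
        es.expr_overlap = cov_index.intersection_bases(m.exons) / exon_bases
        es.splices_hit, _ = model_intron_support(
            m, junction_index, weights.min_reads
        )
        span = m.span
        es.structure = {
            src: best_structure_class(
                m,
                idx.window(m.seq_id, m.strand, span.start, span.end),
                weights.end_tolerance,
            )
            for src, idx in struct_indexes.items()
        }
        es.homology = homology_score(
            m.model_id,
            m.protein_length,
            align_by_query.get(m.model_id, ()),
            weights.evalue_max,
            self_species,
        )
        es.transposon_overlap = (
            te_index.intersection_bases(m.exons) / exon_bases
        )
        es.total = score_model(es, weights)
        out[m.model_id] = es
    return out
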