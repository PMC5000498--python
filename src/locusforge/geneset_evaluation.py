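"""Gene-set quality reports and cross-set comparison statistics.

Covers the whole-set evidence-recovery report (how much of each evidence
class the final models recover), ortholog-group protein-size metrics,
single-copy-ortholog completeness counting, equivalence classes between
two annotations of the same assembly, and the half-up percentage
arithmetic used for all printed report numbers.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence_scoring import (
    Direction,
    StructureClass,
    base_overlap_fraction,
    best_structure_class,
    homology_score,
    splices_hit,
)
from .intervals import GenomicInterval, intersection_bases, total_bases
from .io_formats import EvidenceBundle, TranscriptModel


# ---------------------------------------------------------------------------
# Rounding / proportions
# ---------------------------------------------------------------------------


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up — the single rounding mode for report output."""
    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def percent_of(numerator: float, denominator: float, decimals: int = 0) -> float:
    """``100 * numerator / denominator`` rounded half-up to *decimals*."""
    if denominator == 0:
        raise ZeroDivisionError("percent_of: denominator is zero")
    return round_half_up(100.0 * numerator / denominator, decimals)


def table4_proportions(
    species_specific_paralogs: int,
    duplicated_ortholog_genes: int,
    species_specific_genes: int,
    single_ortholog_genes: int,
    dupl_median: int = 5000,
    singl_median: int = 10000,
) -> tuple[float, float]:
    """Duplication and singleton load relative to the insect medians.

    ``dupl`` = (species-specific paralogs + duplicated ortholog genes) /
    median duplicated count; ``singl`` = (species-specific genes + single
    ortholog genes) / median singleton count; each rounded half-up to one
    decimal.
    """
    for v in (
        species_specific_paralogs,
        duplicated_ortholog_genes,
        species_specific_genes,
        single_ortholog_genes,
    ):
        if v < 0:
            raise ValueError("counts must be non-negative")
    dupl = (species_specific_paralogs + duplicated_ortholog_genes) / dupl_median
    singl = (species_specific_genes + single_ortholog_genes) / singl_median
    return round_half_up(dupl, 1), round_half_up(singl, 1)


def independence_expectation(p1: float, p2: float) -> float:
    """Expected joint proportion under independence: p1 * p2."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must be in [0, 1]")
    return p1 * p2


# ---------------------------------------------------------------------------
# Evidence-recovery report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Whole-set evidence recovery, structure-agreement counts and totals."""

    recovered: dict[str, float] = field(default_factory=dict)
    splices_hit: float = 0.0
    structure_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    homolog_matches: int = 0
    homolog_groups_found: int = 0
    mean_bits_per_aa: float = 0.0
    coding_bases: int = 0
    exon_bases: int = 0
    gene_count: int = 0


def evaluation_report(
    models: Sequence[TranscriptModel],
    bundle: EvidenceBundle,
    end_tolerance: int = 50,
    evalue_max: float = 1e-5,
    min_reads: int = 3,
) -> EvaluationReport:
    """Compute the evidence-recovery report for a gene set.

    Recovery fractions run in the of-evidence direction: how much of each
    evidence base set the models recover.  Structure counts are cumulative
    (a perfect match also counts at the equal66 and some levels), so the
    three levels are nested by construction.
    """
    rep = EvaluationReport(gene_count=len({m.gene_id for m in models}))
    if not models:
        rep.recovered = {"est": 0.0, "rna": 0.0, "protein": 0.0, "transposon": 0.0}
        return rep
    exon_union = [e for m in models for e in m.exons]
    rep.exon_bases = total_bases(exon_union)
    rep.coding_bases = total_bases([c for m in models for c in m.cds])

    cov = {"est": [], "rna": [], "tar": []}
    for c in bundle.coverage:
        cov.setdefault(c.source, []).append(c.span)
    for src in ("est", "rna", "tar"):
        spans = cov.get(src) or cov.get("rnaseq" if src == "rna" else src, [])
        if src == "rna":
            spans = spans or cov.get("rnaseq", [])
        if spans:
            rep.recovered[src] = base_overlap_fraction(
                exon_union, spans, Direction.OF_EVIDENCE
            )
    prot_exons = [e for s in bundle.protein_structures for e in s.exons]
    if prot_exons:
        rep.recovered["protein"] = base_overlap_fraction(
            exon_union, prot_exons, Direction.OF_EVIDENCE
        )
    if bundle.transposon_spans:
        rep.recovered["transposon"] = base_overlap_fraction(
            exon_union, bundle.transposon_spans, Direction.OF_EVIDENCE
        )
    if bundle.junctions:
        rep.splices_hit = splices_hit(
            models, bundle.junctions, min_reads, Direction.OF_EVIDENCE
        )

    sources = {
        "ESTgene": [
            s for s in bundle.transcript_structures if s.source.startswith("est")
        ],
        "Progene": list(bundle.protein_structures),
        "RNAgene": [
            s
            for s in bundle.transcript_structures
            if not s.source.startswith("est")
        ],
    }
    for label, structs in sources.items():
        counts = {"perfect": 0, "equal66": 0, "some": 0}
        if structs:
            for m in models:
                cls = best_structure_class(m, structs, end_tolerance)
                if cls >= StructureClass.PERFECT:
                    counts["perfect"] += 1
                if cls >= StructureClass.EQUAL66:
                    counts["equal66"] += 1
                if cls >= StructureClass.SOME:
                    counts["some"] += 1
        rep.structure_counts[label] = counts

    bits = []
    groups: set[str] = set()
    for m in models:
        hs = homology_score(
            m.model_id, m.protein_length, bundle.alignments, evalue_max
        )
        if hs.best_bits > 0:
            rep.homolog_matches += 1
            if hs.bits_per_aa > 0:
                bits.append(hs.bits_per_aa)
            groups.update(
                a.target_id
                for a in bundle.alignments
                if a.query_id == m.model_id
                and a.e_value < evalue_max
                and not a.is_transposon_target
            )
    rep.homolog_groups_found = len(groups)
    rep.mean_bits_per_aa = float(np.mean(bits)) if bits else 0.0
    return rep


# ---------------------------------------------------------------------------
# Set equivalence
# ---------------------------------------------------------------------------

EQUIV_ORDER = ("ge95", "ge66", "some", "none")


def set_equivalence(
    set_a: Sequence[TranscriptModel],
    set_b: Sequence[TranscriptModel],
    use_cds: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every gene of *set_b* by its best coding-exon base overlap
    with *set_a*.

    The overlap fraction is asymmetric: intersection bases divided by the
    B gene's own coding bases (the query set is the one being audited).
    Classes: >= 0.95 -> ge95, >= 0.66 -> ge66, > 0 -> some, else none.
    Aggregate counts are cumulative for the two upper classes so that
    ge95 <= ge66 <= some.
    """

    def gene_intervals(ms: Sequence[TranscriptModel]) -> dict[str, list]:
        by_gene: dict[str, list] = {}
        for m in ms:
            ivs = m.cds if (use_cds and m.cds) else m.exons
            by_gene.setdefault(m.gene_id, []).extend(ivs)
        return by_gene

    a_by_strand: dict[tuple[str, str], list[GenomicInterval]] = {}
    for m in set_a:
        ivs = m.cds if (use_cds and m.cds) else m.exons
        a_by_strand.setdefault((m.seq_id, m.strand), []).extend(ivs)

    rows = []
    b_strand: dict[str, tuple[str, str]] = {}
    for m in set_b:
        b_strand[m.gene_id] = (m.seq_id, m.strand)
    for gene_id, ivs in sorted(gene_intervals(set_b).items()):
        own = total_bases(ivs)
        key = b_strand[gene_id]
        inter = (
            intersection_bases(ivs, a_by_strand.get(key, []))
            if own
            else 0
        )
        frac = inter / own if own else 0.0
        if frac >= 0.95:
            cls = "ge95"
        elif frac >= 0.66:
            cls = "ge66"
        elif frac > 0:
            cls = "some"
        else:
            cls = "none"
        rows.append({"gene_id": gene_id, "overlap_fraction": frac, "class": cls})
    table = pd.DataFrame(rows, columns=["gene_id", "overlap_fraction", "class"])
    counts = {
        "ge95": int((table["overlap_fraction"] >= 0.95).sum()),
        "ge66": int((table["overlap_fraction"] >= 0.66).sum()),
        "some": int((table["overlap_fraction"] > 0).sum()),
        "none": int((table["overlap_fraction"] == 0).sum()),
        "total": len(table),
    }
    return table, counts


# ---------------------------------------------------------------------------
# Single-copy ortholog completeness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BuscoSummary:
    total: int
    missing: int
    single: int
    multi: int

    def __post_init__(self) -> None:
        assert self.missing + self.single + self.multi == self.total


def busco_summary(group_copy_counts: Mapping[str, int]) -> BuscoSummary:
    """Count missing / single-copy / multi-copy universal ortholog groups."""
    missing = single = multi = 0
    for count in group_copy_counts.values():
        if count < 0:
            raise ValueError("copy counts must be non-negative")
        if count == 0:
            missing += 1
        elif count == 1:
            single += 1
        else:
            multi += 1
    return BuscoSummary(len(group_copy_counts), missing, single, multi)


# ---------------------------------------------------------------------------
# Ortholog-group protein metrics
# ---------------------------------------------------------------------------


def orthogroup_protein_metrics(
    genes: pd.DataFrame,
    population_sd: bool = True,
) -> pd.DataFrame:
    """Per-species protein quality metrics within ortholog groups.

    *genes* columns: ``group``, ``species``, ``gene_id``, ``protein_size``,
    ``bitscore``.  For every group the cross-species median protein size is
    taken; per species the member with the maximal bitscore is the
    representative, contributing (1) its bitscore and (2) its size
    deviation from the group median.  A representative is a size outlier
    when it is shorter than median minus two standard deviations of the
    group's sizes.  Averages are over the groups in which the species is
    present.  Partial gene models show up as negative mean deviations and
    elevated outlier percentages.
    """
    required = {"group", "species", "protein_size", "bitscore"}
    if not required.issubset(genes.columns):
        raise ValueError(f"missing columns: {required - set(genes.columns)}")
    records: dict[str, list] = {}
    ddof = 0 if population_sd else 1
    for _, grp in genes.groupby("group"):
        if grp["species"].nunique() < 2:
            continue
        median = float(grp["protein_size"].median())
        sd = float(grp["protein_size"].std(ddof=ddof))
        cutoff = median - 2.0 * sd
        for species, sub in grp.groupby("species"):
            rep = sub.loc[sub["bitscore"].idxmax()]
            records.setdefault(species, []).append(
                (
                    float(rep["bitscore"]),
                    float(rep["protein_size"]) - median,
                    bool(rep["protein_size"] < cutoff),
                )
            )
    rows = []
    for species in sorted(records):
        vals = records[species]
        rows.append(
            {
                "species": species,
                "avg_max_bitscore": float(np.mean([v[0] for v in vals])),
                "avg_size_deviation": float(np.mean([v[1] for v in vals])),
                "pct_short_outliers": 100.0
                * sum(v[2] for v in vals)
                / len(vals),
                "n_groups": len(vals),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "avg_max_bitscore",
            "avg_size_deviation",
            "pct_short_outliers",
            "n_groups",
        ],
    )
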