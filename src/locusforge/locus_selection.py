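"""Locus clustering, best-model selection, and join/fragment flagging.

Competing gene models are partitioned into loci by single-linkage
clustering over same-strand CDS base overlap; within each locus the model
with the highest weighted evidence score that also clears the minimum
threshold is selected.  Chimeric (joined) and fragmented models are
flagged — never edited — since resolving them is a curation decision.
Alternate isoforms are accepted only from read-derived transcript
assemblies, never from predictor output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .evidence_scoring import (
    EvidenceScores,
    WeightConfig,
    compute_scores,
)
from .intervals import GenomicInterval, intervals_overlap_any, merge_intervals
from .io_formats import (
    AlignmentRecord,
    EvidenceBundle,
    JunctionRecord,
    TranscriptModel,
)

JOIN_SUSPECT = "join_suspect"
FRAGMENT_SUSPECT = "fragment_suspect"
BELOW_THRESHOLD = "below_threshold"


@dataclass
class Locus:
    locus_id: str
    seq_id: str
    strand: str
    members: list[str]
    cds_span: list[GenomicInterval]


@dataclass
class LocusSelection:
    locus_id: str
    selected: str | None = None
    alternates: list[str] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)


@dataclass
class SelectionResult:
    loci: list[Locus]
    selections: dict[str, LocusSelection]
    model_flags: dict[str, set[str]] = field(default_factory=dict)

    def selected_ids(self) -> list[str]:
        return [
            s.selected
            for s in self.selections.values()
            if s.selected is not None
        ]


def cluster_loci(models: Sequence[TranscriptModel]) -> list[Locus]:
    """Partition models into loci by same-strand CDS overlap (>= 1 bp).

    Single-linkage: overlap is chained transitively, so A-B and B-C
    overlaps place A, B, C in one locus even if A and C are disjoint.
    CDS-less models cannot anchor a protein locus and become singletons.
    """
    loci: list[Locus] = []
    singletons = [m for m in models if not m.cds]
    coding = [m for m in models if m.cds]

    by_group: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in coding:
        by_group.setdefault((m.seq_id, m.strand), []).append(m)

    clusters: list[list[TranscriptModel]] = []
    for (seq_id, strand), group in sorted(by_group.items()):
        # sweep over individual CDS intervals; chaining by sorted sweep is
        # exactly the connected components of the interval-overlap graph
        events = sorted(
            (c.start, c.end, i)
            for i, m in enumerate(group)
            for c in m.cds
        )
        parent = list(range(len(group)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        cur_end = -1
        cur_rep = -1
        for start, end, idx in events:
            if start <= cur_end:
                union(cur_rep, idx)
                cur_end = max(cur_end, end)
            else:
                cur_rep, cur_end = idx, end
        comp: dict[int, list[TranscriptModel]] = {}
        for i, m in enumerate(group):
            comp.setdefault(find(i), []).append(m)
        clusters.extend(comp.values())

    def locus_sort_key(ms: list[TranscriptModel]):
        return (ms[0].seq_id, min(m.span.start for m in ms), ms[0].strand)

    for ms in sorted(clusters, key=locus_sort_key):
        cds_union = merge_intervals([c for m in ms for c in m.cds])
        loci.append(
            Locus(
                locus_id=f"LOC{len(loci) + 1:05d}",
                seq_id=ms[0].seq_id,
                strand=ms[0].strand,
                members=sorted(m.model_id for m in ms),
                cds_span=cds_union,
            )
        )
    for m in sorted(singletons, key=lambda m: (m.seq_id, m.span.start)):
        loci.append(
            Locus(
                locus_id=f"LOC{len(loci) + 1:05d}",
                seq_id=m.seq_id,
                strand=m.strand,
                members=[m.model_id],
                cds_span=[],
            )
        )
    return loci


def _selection_key(
    mid: str,
    scores: Mapping[str, EvidenceScores],
    models: Mapping[str, TranscriptModel],
    weights: WeightConfig,
):
    """Sort key implementing the documented tie-break cascade:
    total score, then homology bitscore, then expression overlap, then
    configured source priority, then lexicographic model id."""
    es = scores[mid]
    src = models[mid].source
    prio = (
        weights.source_priority.index(src)
        if src in weights.source_priority
        else len(weights.source_priority)
    )
    return (-es.total, -es.homology.best_bits, -es.expr_overlap, prio, mid)


def select_best(
    loci: Sequence[Locus],
    scores: Mapping[str, EvidenceScores],
    models: Sequence[TranscriptModel],
    weights: WeightConfig | None = None,
) -> SelectionResult:
    """Pick the highest-scoring member per locus, subject to the minimum
    evidence threshold; loci where no member clears it yield no selection
    and a ``below_threshold`` flag."""
    weights = weights or WeightConfig()
    model_map = {m.model_id: m for m in models}
    selections: dict[str, LocusSelection] = {}
    for locus in loci:
        if not locus.members:
            raise RuntimeError(f"locus {locus.locus_id} has no members")
        sel = LocusSelection(locus_id=locus.locus_id)
        ranked = sorted(
            locus.members,
            key=lambda mid: _selection_key(mid, scores, model_map, weights),
        )
        best = ranked[0]
        if scores[best].total >= weights.min_threshold:
            sel.selected = best
        else:
            sel.flags.add(BELOW_THRESHOLD)
        selections[locus.locus_id] = sel
    return SelectionResult(loci=list(loci), selections=selections)


def flag_join_candidates(
    result: SelectionResult,
    models: Sequence[TranscriptModel],
    scores: Mapping[str, EvidenceScores],
) -> SelectionResult:
    """Flag putative chimeric joins and fragments.

    A model is a join suspect when its CDS bridges >= 2 CDS clusters formed
    by the *other* models of its locus, while its best homology bitscore
    does not exceed the best bitscore found in any bridged cluster: a true
    join of two genes has a larger coding span but aligns no better than
    its components.

    A selected model is a fragment suspect when its best protein hit covers
    < 1/3 of the target and an adjacent selected model (next selected locus
    on the same seq/strand) hits the same target covering most of the
    remainder.
    """
    model_map = {m.model_id: m for m in models}
    by_locus = {loc.locus_id: loc for loc in result.loci}
    for locus_id, sel in result.selections.items():
        locus = by_locus[locus_id]
        if len(locus.members) < 2:
            continue
        for mid in locus.members:
            m = model_map[mid]
            if not m.cds:
                continue
            others = [model_map[o] for o in locus.members if o != mid]
            comps = _cds_components(others)
            bridged = [
                comp
                for comp in comps
                if intervals_overlap_any(
                    m.cds, [c for om in comp for c in om.cds]
                )
            ]
            if len(bridged) < 2:
                continue
            comp_best = max(
                scores[om.model_id].homology.best_bits
                for comp in bridged
                for om in comp
            )
            if scores[mid].homology.best_bits <= comp_best:
                result.model_flags.setdefault(mid, set()).add(JOIN_SUSPECT)
                if sel.selected == mid:
                    sel.flags.add(JOIN_SUSPECT)

    _flag_fragments(result, model_map, scores)
    return result


def _cds_components(
    models: Sequence[TranscriptModel],
) -> list[list[TranscriptModel]]:
    """Connected components of the CDS-overlap graph among *models*."""
    comps: list[list[TranscriptModel]] = []
    remaining = list(models)
    while remaining:
        seed = remaining.pop()
        comp = [seed]
        changed = True
        while changed:
            changed = False
            for m in list(remaining):
                if any(
                    intervals_overlap_any(m.cds, c.cds) for c in comp
                ):
                    comp.append(m)
                    remaining.remove(m)
                    changed = True
        comps.append(comp)
    return comps


def _flag_fragments(
    result: SelectionResult,
    model_map: Mapping[str, TranscriptModel],
    scores: Mapping[str, EvidenceScores],
    coverage_slack: float = 0.1,
) -> None:
    selected = [
        (model_map[s.selected], s)
        for s in result.selections.values()
        if s.selected is not None
    ]
    selected.sort(key=lambda t: (t[0].seq_id, t[0].strand, t[0].span.start))
    # best significant alignment per selected model (from score annotations
    # we only have bitscores; fragment detection needs fractions, so it is
    # driven by the alignment-derived fields when provided via scores)
    for (m1, s1), (m2, s2) in zip(selected, selected[1:]):
        if m1.seq_id != m2.seq_id or m1.strand != m2.strand:
            continue
        a1 = getattr(scores[m1.model_id], "best_alignment", None)
        a2 = getattr(scores[m2.model_id], "best_alignment", None)
        if a1 is None or a2 is None:
            continue
        if a1.target_id != a2.target_id:
            continue
        for frag, other, sel in ((a1, a2, s1), (a2, a1, s2)):
            if (
                frag.aligned_fraction < 1.0 / 3.0
                and other.aligned_fraction
                >= 1.0 - frag.aligned_fraction - coverage_slack
            ):
                sel.flags.add(FRAGMENT_SUSPECT)


def attach_best_alignments(
    scores: Mapping[str, EvidenceScores],
    alignments: Sequence[AlignmentRecord],
    evalue_max: float = 1e-5,
) -> None:
    """Annotate each score record with its best non-transposon alignment
    (needed by fragment detection, which compares aligned fractions)."""
    best: dict[str, AlignmentRecord] = {}
    for a in alignments:
        if a.e_value >= evalue_max or a.is_transposon_target:
            continue
        cur = best.get(a.query_id)
        if cur is None or a.bitscore > cur.bitscore:
            best[a.query_id] = a
    for mid, es in scores.items():
        setattr(es, "best_alignment", best.get(mid))


def validate_alt_transcripts(
    locus: Locus,
    selected_model: TranscriptModel,
    transcript_structures: Sequence[TranscriptModel],
    junctions: Sequence[JunctionRecord],
    min_reads: int = 3,
) -> list[TranscriptModel]:
    """Accept alternate isoforms for a selected locus.

    Candidates come exclusively from read-derived transcript assemblies.
    An isoform is accepted iff (i) its intron chain differs from the
    primary model and every already-accepted isoform, (ii) every intron
    that distinguishes it from the primary is a validated junction, and
    (iii) it shares >= 1 bp of CDS overlap with the primary model.
    Candidates are examined in model_id order so the accepted set is
    deterministic.
    """
    validated = {
        j.key for j in junctions if j.is_validated(min_reads)
    }
    primary_introns = set(
        (i.seq_id, i.start, i.end, i.strand) for i in selected_model.introns
    )
    accepted: list[TranscriptModel] = []
    seen_chains = {tuple(sorted(primary_introns))}
    for cand in sorted(transcript_structures, key=lambda m: m.model_id):
        if cand.seq_id != selected_model.seq_id or (
            cand.strand != selected_model.strand
        ):
            continue
        chain = set(
            (i.seq_id, i.start, i.end, i.strand) for i in cand.introns
        )
        if tuple(sorted(chain)) in seen_chains:
            continue
        distinguishing = chain - primary_introns
        if any(key not in validated for key in distinguishing):
            continue
        if not cand.cds or not intervals_overlap_any(
            cand.cds, selected_model.cds
        ):
            continue
        accepted.append(cand)
        seen_chains.add(tuple(sorted(chain)))
    return accepted


class OverrideConflictError(ValueError):
    pass


def iterate_selection(
    models: Sequence[TranscriptModel],
    bundle: EvidenceBundle,
    weights: WeightConfig | None = None,
    overrides: Mapping[str, str] | None = None,
    self_species: str = "self",
) -> SelectionResult:
    """One pass of the negative-feedback loop: score, cluster, select,
    flag — with expert overrides honored (``force_keep`` / ``force_drop``).

    Deterministic given inputs; re-running with the same weights and no
    overrides reproduces the same result.
    """
    weights = weights or WeightConfig()
    overrides = dict(overrides or {})
    kept = [
        m for m in models if overrides.get(m.model_id) != "force_drop"
    ]
    scores = compute_scores(kept, bundle, weights, self_species)
    attach_best_alignments(scores, bundle.alignments, weights.evalue_max)
    loci = cluster_loci(kept)
    result = select_best(loci, scores, kept, weights)
    for locus in loci:
        forced = [
            mid
            for mid in locus.members
            if overrides.get(mid) == "force_keep"
        ]
        if len(forced) > 1:
            raise OverrideConflictError(
                f"conflicting force_keep overrides in {locus.locus_id}: "
                f"{forced}"
            )
        if forced:
            sel = result.selections[locus.locus_id]
            sel.selected = forced[0]
            sel.flags.discard(BELOW_THRESHOLD)
    flag_join_candidates(result, kept, scores)
    return result
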