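"""Seeded generators for toy genomes, gene structures, evidence tracks,
corrupted prediction sets, and simulated protein families.

The annotation fixture emulates the situation the selection machinery is
built for: a set of true genes, evidence tracks derived from those genes
(splice junctions with read counts, expression coverage, protein
alignments, transposon spans, transcript assemblies), and competing
predictor outputs in which known error modes have been injected —
splitting a gene at an intron, joining two neighbours into a chimera,
dropping an internal exon, over-running a UTR into intergenic sequence,
or absorbing a transposon span.  Every corrupted model is labelled with
its source gene(s) and error mode, so tests can score recovery exactly.

All randomness flows from one seed through independent, purpose-keyed
child streams (``numpy`` SeedSequence spawn keys), so adding a new
sub-generator never perturbs the output of existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._jtt_data import AA_ORDER
from .comparative_evolution import SubstitutionModel, jtt_model
from .intervals import GenomicInterval
from .io_formats import (
    AlignmentRecord,
    CoverageSpan,
    EvidenceBundle,
    JunctionRecord,
    TranscriptModel,
    write_alignment_tsv,
    write_coverage_bed,
    write_gff3,
    write_junction_tsv,
    write_transposon_bed,
)

ERROR_MODES = (
    "split_at_intron",
    "join_with_neighbor",
    "drop_internal_exon",
    "utr_overrun",
    "transposon_insert",
)

_STREAMS = {
    "structure": 1,
    "junctions": 2,
    "coverage": 3,
    "corruption": 4,
    "alignments": 5,
    "genome": 6,
    "isoforms": 7,
    "protein_family": 8,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named sub-stream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class FixtureParams:
    """Study conditions for the annotation fixture.

    Defaults describe a small but structurally realistic insect-like
    region: ~4 introns per gene (Poisson), exons of 120-400 bp, introns of
    80-400 bp, and mild corruption (5 % per error mode, so roughly a
    quarter of genes carry one flawed variant somewhere).  Junction read
    counts are negative-binomial with mean ~20, matching deep short-read
    splice coverage where nearly every true intron clears the 3-read
    validation bar.
    """

    seed: int = 0
    n_genes: int = 100
    seq_id: str = "chr1"
    intron_mean: float = 4.0
    exon_len_range: tuple[int, int] = (120, 400)
    intron_len_range: tuple[int, int] = (80, 400)
    intergenic_range: tuple[int, int] = (300, 900)
    utr_len_range: tuple[int, int] = (30, 100)
    corruption: dict[str, float] = field(
        default_factory=lambda: {m: 0.05 for m in ERROR_MODES}
    )
    nb_reads_n: float = 5.0
    nb_reads_p: float = 0.2  # mean n(1-p)/p = 20
    assembly_fraction: float = 0.8  # genes with an RNA assembly structure
    est_fraction: float = 0.5
    isoform_fraction: float = 0.15
    ref_species: tuple[str, ...] = ("apis", "harpegnathos", "drosophila")
    species_bit_scale: tuple[float, ...] = (1.0, 0.85, 0.6)
    bits_per_aa: float = 2.0
    join_bit_factor: float = 0.9  # join bitscore = factor * min(components)
    utr_overrun_range: tuple[int, int] = (100, 300)
    n_transposon_spans: int = 5
    genome_length: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.corruption.values())
        if total > 1.0 or any(p < 0 or p > 1 for p in self.corruption.values()):
            raise ValueError("corruption probabilities must be in [0,1], sum <= 1")


@dataclass
class FixtureTruth:
    """Ground truth: true models, per-corruption provenance, and evidence."""

    truth_models: list[TranscriptModel]
    corrupted: dict[str, tuple[str, tuple[str, ...]]]  # model -> (mode, genes)
    isoform_truth: dict[str, str] = field(default_factory=dict)


@dataclass
class AnnotationFixture:
    params: FixtureParams
    genome: dict[str, str]
    truth: FixtureTruth
    predictor_sets: dict[str, list[TranscriptModel]]
    bundle: EvidenceBundle

    @property
    def all_candidates(self) -> list[TranscriptModel]:
        return [m for ms in self.predictor_sets.values() for m in ms]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fasta", "w") as fh:
            for seq_id, seq in self.genome.items():
                fh.write(f">{seq_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_gff3(self.truth.truth_models, out / "truth.gff3")
        for name, models in self.predictor_sets.items():
            write_gff3(models, out / f"{name}.gff3")
        write_junction_tsv(self.bundle.junctions, out / "junctions.tsv")
        write_coverage_bed(self.bundle.coverage, out / "coverage.bed")
        write_alignment_tsv(self.bundle.alignments, out / "alignments.tsv")
        write_transposon_bed(self.bundle.transposon_spans, out / "transposons.bed")
        write_gff3(
            self.bundle.transcript_structures, out / "transcript_structures.gff3"
        )
        with open(out / "fixture.toml", "w") as fh:
            fh.write("[paths]\n")
            for key, fname in (
                ("junctions", "junctions.tsv"),
                ("coverage", "coverage.bed"),
                ("alignments", "alignments.tsv"),
                ("transposons", "transposons.bed"),
                ("transcript_structures", "transcript_structures.gff3"),
            ):
                fh.write(f'{key} = "{fname}"\n')
            fh.write(f"\nseed = {self.params.seed}\n")


def _sample_gene_structure(
    rng: np.random.Generator, params: FixtureParams, cursor: int, idx: int
) -> TranscriptModel:
    n_introns = int(rng.poisson(params.intron_mean))
    n_exons = n_introns + 1
    exon_lens = rng.integers(
        params.exon_len_range[0], params.exon_len_range[1] + 1, n_exons
    )
    intron_lens = rng.integers(
        params.intron_len_range[0], params.intron_len_range[1] + 1, n_introns
    )
    utr5 = int(rng.integers(*params.utr_len_range))
    utr3 = int(rng.integers(*params.utr_len_range))
    # keep >= 30 bp of CDS in each terminal exon (single-exon genes carry
    # both UTRs on the same exon)
    utr5 = min(utr5, int(exon_lens[0]) - 30)
    if n_exons == 1:
        utr3 = min(utr3, int(exon_lens[0]) - utr5 - 30)
    else:
        utr3 = min(utr3, int(exon_lens[-1]) - 30)
    utr5, utr3 = max(utr5, 0), max(utr3, 0)
    exons = []
    pos = cursor
    for i in range(n_exons):
        exons.append(
            GenomicInterval(params.seq_id, pos, pos + int(exon_lens[i]) - 1, "+")
        )
        pos += int(exon_lens[i])
        if i < n_introns:
            pos += int(intron_lens[i])
    # CDS trims UTRs off the terminal exons (exons are > utr + 20 long)
    cds = []
    for i, e in enumerate(exons):
        start, end = e.start, e.end
        if i == 0:
            start += utr5
        if i == len(exons) - 1:
            end -= utr3
        cds.append(GenomicInterval(params.seq_id, start, end, "+"))
    gid = f"g{idx:04d}"
    return TranscriptModel(
        model_id=f"{gid}.t1",
        gene_id=gid,
        source="truth",
        exons=tuple(exons),
        cds=tuple(cds),
        protein_length=max(sum(c.length for c in cds) // 3, 1),
    )


def _copy_as(model: TranscriptModel, model_id: str, source: str) -> TranscriptModel:
    return dataclasses.replace(model, model_id=model_id, source=source)


def _corrupt(
    mode: str,
    gene: TranscriptModel,
    neighbor: TranscriptModel | None,
    rng: np.random.Generator,
    params: FixtureParams,
    te_spans: list[GenomicInterval],
    set_name: str,
) -> list[tuple[TranscriptModel, tuple[str, ...]]] | None:
    """Build the corrupted variant(s) for one gene; None if inapplicable."""
    gid = gene.gene_id
    seq = gene.seq_id
    if mode == "split_at_intron" and len(gene.exons) >= 2:
        k = int(rng.integers(1, len(gene.exons)))
        left_e, right_e = gene.exons[:k], gene.exons[k:]
        cut = left_e[-1].end
        left_c = tuple(c for c in gene.cds if c.end <= cut)
        right_c = tuple(c for c in gene.cds if c.start > cut)
        if not left_c or not right_c:
            return None
        mk = lambda sfx, ex, cd: TranscriptModel(
            f"{gid}.{set_name}.split{sfx}", f"{gid}.{set_name}.split{sfx}",
            set_name, ex, cd,
            protein_length=max(sum(c.length for c in cd) // 3, 1),
        )
        return [(mk("A", left_e, left_c), (gid,)), (mk("B", right_e, right_c), (gid,))]
    if mode == "join_with_neighbor" and neighbor is not None:
        if neighbor.strand != gene.strand:
            return None
        exons = tuple(gene.exons) + tuple(neighbor.exons)
        cds = tuple(gene.cds) + tuple(neighbor.cds)
        m = TranscriptModel(
            f"{gid}.{set_name}.join", f"{gid}.{set_name}.join", set_name,
            exons, cds, protein_length=max(sum(c.length for c in cds) // 3, 1),
        )
        return [(m, (gid, neighbor.gene_id))]
    if mode == "drop_internal_exon" and len(gene.exons) >= 3:
        k = int(rng.integers(1, len(gene.exons) - 1))
        dropped = gene.exons[k]
        exons = gene.exons[:k] + gene.exons[k + 1 :]
        cds = tuple(
            c for c in gene.cds if not (c.start >= dropped.start and c.end <= dropped.end)
        )
        if not cds:
            return None
        m = TranscriptModel(
            f"{gid}.{set_name}.dropx", f"{gid}.{set_name}.dropx", set_name,
            exons, cds, protein_length=max(sum(c.length for c in cds) // 3, 1),
        )
        return [(m, (gid,))]
    if mode == "utr_overrun":
        overrun = int(rng.integers(*params.utr_overrun_range))
        last = gene.exons[-1]
        exons = gene.exons[:-1] + (
            GenomicInterval(seq, last.start, last.end + overrun, gene.strand),
        )
        m = TranscriptModel(
            f"{gid}.{set_name}.utr", f"{gid}.{set_name}.utr", set_name,
            exons, gene.cds,
            protein_length=gene.protein_length,
        )
        return [(m, (gid,))]
    if mode == "transposon_insert" and te_spans:
        te = te_spans[int(rng.integers(len(te_spans)))]
        if te.start <= gene.span.end:
            return None
        exons = gene.exons + (
            GenomicInterval(seq, te.start, te.end, gene.strand),
        )
        m = TranscriptModel(
            f"{gid}.{set_name}.te", f"{gid}.{set_name}.te", set_name,
            exons, gene.cds, protein_length=gene.protein_length,
        )
        return [(m, (gid,))]
    return None


def _model_alignments(
    model: TranscriptModel,
    source_genes: Sequence[TranscriptModel],
    params: FixtureParams,
    bit_factor: float = 1.0,
) -> list[AlignmentRecord]:
    """Alignment records against each source gene's reference protein.

    Bitscores scale with the number of truth-CDS amino acids the model
    recovers for that gene, decreasing with simulated species divergence;
    a chimeric model therefore never aligns better than its components.
    """
    from .intervals import intersection_bases

    out = []
    for truth in source_genes:
        overlap_aa = intersection_bases(model.cds, truth.cds) // 3
        if overlap_aa == 0:
            continue
        for sp, scale in zip(params.ref_species, params.species_bit_scale):
            bits = params.bits_per_aa * overlap_aa * scale * bit_factor
            out.append(
                AlignmentRecord(
                    query_id=model.model_id,
                    target_id=f"ref_{truth.gene_id}_{sp}",
                    target_species=sp,
                    target_length=truth.protein_length or 1,
                    bitscore=round(bits, 1),
                    e_value=1e-40,
                    aligned_fraction=min(
                        overlap_aa / (truth.protein_length or 1), 1.0
                    ),
                    target_name=f"protein {truth.gene_id}",
                )
            )
    return out


def simulate_annotation_fixture(params: FixtureParams) -> AnnotationFixture:
    """Generate the full fixture: genome, truth, evidence, predictor sets.

    Deterministic given ``params.seed``.  Candidate models comprise one
    faithful predictor run plus a second run in which, per gene, at most
    one error mode has been applied (each with its configured
    probability); the faithful copy of every gene is always present, so
    recovery failures isolate genuine selection mistakes — with one
    exception: a chimeric join merges two true loci into one selection
    cluster, which is exactly the error the join flag exists to catch.
    """
    s_rng = stream_rng(params.seed, "structure")
    j_rng = stream_rng(params.seed, "junctions")
    cov_rng = stream_rng(params.seed, "coverage")
    cor_rng = stream_rng(params.seed, "corruption")
    iso_rng = stream_rng(params.seed, "isoforms")
    g_rng = stream_rng(params.seed, "genome")

    truth: list[TranscriptModel] = []
    cursor = 1 + int(s_rng.integers(*params.intergenic_range))
    for i in range(params.n_genes):
        gene = _sample_gene_structure(s_rng, params, cursor, i)
        truth.append(gene)
        cursor = gene.span.end + 1 + int(s_rng.integers(*params.intergenic_range))

    # transposon spans in intergenic gaps past the last gene region used for
    # te insertion, plus a couple inside early intergenic gaps
    te_spans = []
    te_cursor = cursor + 500
    for _ in range(params.n_transposon_spans):
        length = int(cor_rng.integers(300, 900))
        te_spans.append(
            GenomicInterval(params.seq_id, te_cursor, te_cursor + length - 1)
        )
        te_cursor += length + int(cor_rng.integers(200, 600))

    genome_len = params.genome_length or te_cursor + 1000
    if genome_len < te_cursor:
        raise ValueError("genome too short for requested gene count")
    bases = g_rng.choice(list("ACGT"), size=genome_len)
    genome = {params.seq_id: "".join(bases)}
    gl = list(genome[params.seq_id])
    for gene in truth:
        for intron in gene.introns:
            gl[intron.start - 1 : intron.start + 1] = ["G", "T"]
            gl[intron.end - 2 : intron.end] = ["A", "G"]
    genome[params.seq_id] = "".join(gl)

    # evidence: junctions over true introns
    junctions = []
    for gene in truth:
        for intron in gene.introns:
            reads = int(j_rng.negative_binomial(params.nb_reads_n, params.nb_reads_p))
            junctions.append(JunctionRecord(intron, max(reads, 0)))

    # coverage: one span per exon, rnaseq plus a coarser tar track
    coverage = []
    for gene in truth:
        for e in gene.exons:
            coverage.append(
                CoverageSpan(
                    GenomicInterval(e.seq_id, e.start, e.end),
                    float(np.round(cov_rng.lognormal(2.0, 0.5), 3)),
                    "rnaseq",
                )
            )
        span = gene.span
        coverage.append(
            CoverageSpan(
                GenomicInterval(span.seq_id, span.start, span.end),
                float(np.round(cov_rng.lognormal(1.5, 0.5), 3)),
                "tar",
            )
        )

    # transcript structures: RNA assemblies (mirroring truth) and isoforms
    structures: list[TranscriptModel] = []
    isoform_truth: dict[str, str] = {}
    extra_junctions: list[JunctionRecord] = []
    for gene in truth:
        if cov_rng.random() < params.assembly_fraction:
            structures.append(
                _copy_as(gene, f"{gene.gene_id}.rna", "rna_assembly")
            )
        if cov_rng.random() < params.est_fraction:
            structures.append(
                _copy_as(gene, f"{gene.gene_id}.est", "est_assembly")
            )
        if len(gene.exons) >= 3 and iso_rng.random() < params.isoform_fraction:
            k = int(iso_rng.integers(1, len(gene.exons) - 1))
            dropped = gene.exons[k]
            exons = gene.exons[:k] + gene.exons[k + 1 :]
            cds = tuple(
                c
                for c in gene.cds
                if not (c.start >= dropped.start and c.end <= dropped.end)
            )
            if not cds:
                continue
            iso = TranscriptModel(
                f"{gene.gene_id}.iso", f"{gene.gene_id}.iso", "rna_assembly",
                exons, cds,
            )
            structures.append(iso)
            isoform_truth[iso.model_id] = gene.gene_id
            # the skipping junction is genuinely expressed -> validated
            skip = GenomicInterval(
                gene.seq_id, exons[k - 1].end + 1, exons[k].start - 1, gene.strand
            )
            extra_junctions.append(
                JunctionRecord(skip, int(j_rng.negative_binomial(
                    params.nb_reads_n, params.nb_reads_p)) + 3)
            )
    junctions.extend(extra_junctions)

    # predictor sets: one faithful run, one with per-gene injected errors
    modes = list(params.corruption.keys())
    probs = np.array([params.corruption[m] for m in modes])
    corrupted: dict[str, tuple[str, tuple[str, ...]]] = {}
    set_a = [_copy_as(g, f"{g.gene_id}.augA", "augA") for g in truth]
    set_b: list[TranscriptModel] = []
    alignments: list[AlignmentRecord] = []
    truth_by_gid = {g.gene_id: g for g in truth}

    for i, gene in enumerate(truth):
        u = cor_rng.random()
        mode = None
        acc = 0.0
        for m, p in zip(modes, probs):
            acc += p
            if u < acc:
                mode = m
                break
        made = None
        if mode is not None:
            neighbor = truth[i + 1] if i + 1 < len(truth) else None
            made = _corrupt(
                mode, gene, neighbor, cor_rng, params, te_spans, "augB"
            )
        if made is None:
            set_b.append(_copy_as(gene, f"{gene.gene_id}.augB", "augB"))
        else:
            for model, src in made:
                set_b.append(model)
                corrupted[model.model_id] = (mode, src)

    # alignments for every candidate, scored against its source gene(s)
    for model in set_a:
        alignments.extend(
            _model_alignments(model, [truth_by_gid[model.gene_id]], params)
        )
    for model in set_b:
        if model.model_id in corrupted:
            mode, src = corrupted[model.model_id]
            sources = [truth_by_gid[g] for g in src]
            factor = params.join_bit_factor if mode == "join_with_neighbor" else 1.0
            if mode == "join_with_neighbor":
                # a chimera aligns to each component protein no better than
                # the weaker component does on its own
                min_aa = min(
                    sum(c.length for c in s.cds) // 3 for s in sources
                )
                for sp, scale in zip(params.ref_species, params.species_bit_scale):
                    bits = params.bits_per_aa * min_aa * scale * factor
                    alignments.append(
                        AlignmentRecord(
                            query_id=model.model_id,
                            target_id=f"ref_{sources[0].gene_id}_{sp}",
                            target_species=sp,
                            target_length=sources[0].protein_length or 1,
                            bitscore=round(bits, 1),
                            e_value=1e-40,
                            aligned_fraction=min(
                                min_aa / (sources[0].protein_length or 1), 1.0
                            ),
                            target_name=f"protein {sources[0].gene_id}",
                        )
                    )
            else:
                alignments.extend(_model_alignments(model, sources, params))
        else:
            gid = model.gene_id.split(".")[0]
            alignments.extend(
                _model_alignments(model, [truth_by_gid[gid]], params)
            )

    bundle = EvidenceBundle(
        junctions=junctions,
        coverage=coverage,
        transcript_structures=structures,
        transposon_spans=te_spans,
        alignments=alignments,
    )
    return AnnotationFixture(
        params=params,
        genome=genome,
        truth=FixtureTruth(truth, corrupted, isoform_truth),
        predictor_sets={"augA": set_a, "augB": set_b},
        bundle=bundle,
    )


# ---------------------------------------------------------------------------
# Protein family simulation
# ---------------------------------------------------------------------------


@dataclass
class ProteinFamily:
    sequences: dict[str, str]
    clades: dict[str, str]
    true_distances: dict[tuple[str, str], float]


def _evolve(
    ancestor: np.ndarray, t: float, model: SubstitutionModel,
    rng: np.random.Generator,
) -> np.ndarray:
    if t == 0:
        return ancestor.copy()
    P = model.transition_matrix(t)
    child = np.empty_like(ancestor)
    for state in range(20):
        mask = ancestor == state
        if mask.any():
            child[mask] = rng.choice(20, size=int(mask.sum()), p=P[state])
    return child


def simulate_protein_family(
    n_ant: int = 2,
    n_bee: int = 2,
    n_focal: int = 1,
    branch_lengths: Mapping[str, float] | None = None,
    n_sites: int = 300,
    model: SubstitutionModel | None = None,
    seed: int = 0,
) -> ProteinFamily:
    """Evolve an aligned protein family on a star topology.

    Each tip descends independently from a stationary ancestral sequence
    along its clade's branch length (expected substitutions per site), so
    the true pairwise path length of tips i, j is b_i + b_j — symmetric
    and additive by construction.  Branch lengths default to 0.3 per
    clade; inflate the focal branch to plant accelerated evolution.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    model = model or jtt_model()
    bl = {"focal": 0.3, "ant": 0.3, "bee": 0.3}
    if branch_lengths:
        bl.update(branch_lengths)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS["protein_family"],))
    )
    ancestor = rng.choice(20, size=n_sites, p=model.pi)
    tips: list[tuple[str, str]] = (
        [(f"focal{i}", "focal") for i in range(n_focal)]
        + [(f"ant{i}", "ant") for i in range(n_ant)]
        + [(f"bee{i}", "bee") for i in range(n_bee)]
    )
    seqs: dict[str, str] = {}
    clades: dict[str, str] = {}
    for name, clade in tips:
        states = _evolve(ancestor, bl[clade], model, rng)
        seqs[name] = "".join(AA_ORDER[s] for s in states)
        clades[name] = clade
    dists: dict[tuple[str, str], float] = {}
    for a, ca in tips:
        for b, cb in tips:
            if a < b:
                dists[(a, b)] = bl[ca] + bl[cb]
    return ProteinFamily(seqs, clades, dists)
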