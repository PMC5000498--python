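"""Readers and writers for the external formats the toolkit consumes.

Gene models travel as GFF3 (parsed with :mod:`gffutils`), splice junctions
and protein alignments as TSV, expression coverage and transposon spans as
BED-like files, and run configuration as TOML.  All coordinates are 1-based
inclusive externally and internally (see :mod:`locusforge.intervals`); BED
inputs are converted from their native 0-based half-open convention on read
and back on write.
"""

from __future__ import annotations

import csv
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .intervals import GenomicInterval, IntervalError, merge_intervals

MIN_JUNCTION_READS = 3  # reads required to call an intron location validated


class GffParseError(ValueError):
    """Malformed GFF3 input, annotated with the offending line number."""


class ModelValidationError(ValueError):
    """A transcript model violating a structural invariant, named in message."""


@dataclass(frozen=True)
class TranscriptModel:
    """One candidate gene model: an exon chain with an optional CDS chain.

    ``exons`` must be sorted, pairwise disjoint intervals on a single
    seq_id/strand; every ``cds`` interval must lie within exactly one exon.
    Models without CDS are legal (non-coding candidates).
    """

    model_id: str
    gene_id: str
    source: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    protein_length: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "cds", tuple(self.cds))
        if not self.exons:
            raise ModelValidationError(f"model {self.model_id}: no exons")
        seq_ids = {e.seq_id for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seq_ids) != 1 or len(strands) != 1:
            raise ModelValidationError(
                f"model {self.model_id}: exons span multiple seq_ids/strands"
            )
        if self.strand not in ("+", "-"):
            raise ModelValidationError(
                f"model {self.model_id}: models require explicit strand"
            )
        prev_end = 0
        for e in sorted(self.exons, key=lambda x: x.start):
            if e.start <= prev_end:
                raise ModelValidationError(
                    f"model {self.model_id}: overlapping/unsorted exons"
                )
            prev_end = e.end
        object.__setattr__(
            self, "exons", tuple(sorted(self.exons, key=lambda x: x.start))
        )
        cds_sorted = tuple(sorted(self.cds, key=lambda x: x.start))
        for c in cds_sorted:
            if not any(
                c.seq_id == e.seq_id and e.start <= c.start and c.end <= e.end
                for e in self.exons
            ):
                raise ModelValidationError(
                    f"model {self.model_id}: CDS {c.start}-{c.end} "
                    "not contained in any exon"
                )
        object.__setattr__(self, "cds", cds_sorted)

    @property
    def seq_id(self) -> str:
        return self.exons[0].seq_id

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, each of length >= 1."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(
                GenomicInterval(self.seq_id, a.end + 1, b.start - 1, self.strand)
            )
        return tuple(out)

    @property
    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(c.length for c in self.cds)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass(frozen=True)
class JunctionRecord:
    """An intron location with the number of splice-mapped reads crossing it."""

    intron: GenomicInterval
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if self.intron.strand not in ("+", "-"):
            raise ValueError("junctions require explicit strand")

    def is_validated(self, min_reads: int = MIN_JUNCTION_READS) -> bool:
        return self.read_count >= min_reads

    @property
    def key(self) -> tuple[str, int, int, str]:
        iv = self.intron
        return (iv.seq_id, iv.start, iv.end, iv.strand)


@dataclass(frozen=True)
class CoverageSpan:
    """An expressed region (RNA-seq depth run, tiling-array TAR, or EST)."""

    span: GenomicInterval
    intensity: float
    source: str = "rnaseq"  # rnaseq | tar | est

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass(frozen=True)
class AlignmentRecord:
    """A precomputed protein alignment (the toolkit never runs BLAST)."""

    query_id: str
    target_id: str
    target_species: str
    target_length: int
    bitscore: float
    e_value: float
    aligned_fraction: float
    is_transposon_target: bool = False
    target_name: str = ""

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction must be in [0, 1]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")


@dataclass
class EvidenceBundle:
    """All evidence tracks for one genome, as parsed from configured files."""

    junctions: list[JunctionRecord] = field(default_factory=list)
    coverage: list[CoverageSpan] = field(default_factory=list)
    protein_structures: list[TranscriptModel] = field(default_factory=list)
    transcript_structures: list[TranscriptModel] = field(default_factory=list)
    transposon_spans: list[GenomicInterval] = field(default_factory=list)
    alignments: list[AlignmentRecord] = field(default_factory=list)
    reference_models: list[TranscriptModel] = field(default_factory=list)

    def validated_junctions(
        self, min_reads: int = MIN_JUNCTION_READS
    ) -> list[JunctionRecord]:
        return [j for j in self.junctions if j.is_validated(min_reads)]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _precheck_gff3(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GffParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc


def read_gff3(path: str | Path, source: str | None = None) -> list[TranscriptModel]:
    """Parse a GFF3 file into one :class:`TranscriptModel` per mRNA feature.

    Exons and CDS rows are grouped by their ``Parent`` attribute; the mRNA's
    ``Parent`` gene (or the mRNA itself when orphaned) supplies ``gene_id``.
    ``source`` overrides column 2 as the model's provenance label.
    """
    _precheck_gff3(path)
    with open(path) as fh:
        if not any(
            line.strip() and not line.startswith("#") for line in fh
        ):
            return []
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        exons, cds = [], []
        for child in db.children(mrna, featuretype=("exon", "CDS")):
            iv = GenomicInterval(
                child.seqid, child.start, child.end, child.strand
            )
            (exons if child.featuretype == "exon" else cds).append(iv)
        gene_id = (mrna.attributes.get("Parent") or [mrna.id])[0]
        plen_attr = mrna.attributes.get("protein_length")
        models.append(
            TranscriptModel(
                model_id=mrna.id,
                gene_id=gene_id,
                source=source or mrna.source,
                exons=tuple(exons),
                cds=tuple(cds),
                protein_length=int(plen_attr[0]) if plen_attr else None,
            )
        )
    return models


def write_gff3(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write models as GFF3 with stable ordering (seq_id, start, model_id)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    def gene_key(gid: str) -> tuple:
        ms = by_gene[gid]
        return (ms[0].seq_id, min(m.span.start for m in ms), gid)

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(by_gene, key=gene_key):
            ms = sorted(by_gene[gid], key=lambda m: (m.span.start, m.model_id))
            g_start = min(m.span.start for m in ms)
            g_end = max(m.span.end for m in ms)
            first = ms[0]
            # a model that is its own gene is written as a standalone mRNA
            # (a gene feature with the same ID would collide)
            standalone = len(ms) == 1 and ms[0].model_id == gid
            if not standalone:
                fh.write(
                    f"{first.seq_id}\t{first.source}\tgene\t{g_start}\t{g_end}"
                    f"\t.\t{first.strand}\t.\tID={gid}\n"
                )
            for m in ms:
                attrs = (
                    f"ID={m.model_id}"
                    if standalone
                    else f"ID={m.model_id};Parent={gid}"
                )
                if m.protein_length is not None:
                    attrs += f";protein_length={m.protein_length}"
                fh.write(
                    f"{m.seq_id}\t{m.source}\tmRNA\t{m.span.start}"
                    f"\t{m.span.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )
                for i, e in enumerate(m.exons, 1):
                    fh.write(
                        f"{m.seq_id}\t{m.source}\texon\t{e.start}\t{e.end}"
                        f"\t.\t{m.strand}\t.\tID={m.model_id}.exon{i};"
                        f"Parent={m.model_id}\n"
                    )
                for i, c in enumerate(m.cds, 1):
                    fh.write(
                        f"{m.seq_id}\t{m.source}\tCDS\t{c.start}\t{c.end}"
                        f"\t.\t{m.strand}\t0\tID={m.model_id}.cds{i};"
                        f"Parent={m.model_id}\n"
                    )


# ---------------------------------------------------------------------------
# TSV / BED evidence tracks
# ---------------------------------------------------------------------------

_JUNCTION_COLS = ["seq_id", "start", "end", "strand", "read_count"]
_ALIGNMENT_COLS = [
    "query_id",
    "target_id",
    "target_species",
    "target_length",
    "bitscore",
    "e_value",
    "aligned_fraction",
    "is_transposon_target",
    "target_name",
]


def _require_columns(header: Sequence[str], required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def read_junction_tsv(path: str | Path) -> list[JunctionRecord]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return out
        _require_columns(reader.fieldnames, _JUNCTION_COLS, path)
        for row in reader:
            count = int(row["read_count"])
            if count < 0:
                raise ValueError(f"{path}: negative read_count {count}")
            out.append(
                JunctionRecord(
                    GenomicInterval(
                        row["seq_id"],
                        int(row["start"]),
                        int(row["end"]),
                        row["strand"],
                    ),
                    count,
                )
            )
    return out


def write_junction_tsv(junctions: Iterable[JunctionRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_JUNCTION_COLS)
        for j in sorted(junctions, key=lambda j: j.key):
            iv = j.intron
            w.writerow([iv.seq_id, iv.start, iv.end, iv.strand, j.read_count])


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return out
        _require_columns(reader.fieldnames, _ALIGNMENT_COLS, path)
        for row in reader:
            out.append(
                AlignmentRecord(
                    query_id=row["query_id"],
                    target_id=row["target_id"],
                    target_species=row["target_species"],
                    target_length=int(row["target_length"]),
                    bitscore=float(row["bitscore"]),
                    e_value=float(row["e_value"]),
                    aligned_fraction=float(row["aligned_fraction"]),
                    is_transposon_target=row["is_transposon_target"]
                    in ("1", "true", "True"),
                    target_name=row["target_name"],
                )
            )
    return out


def write_alignment_tsv(alignments: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_ALIGNMENT_COLS)
        for a in sorted(alignments, key=lambda a: (a.query_id, a.target_id)):
            w.writerow(
                [
                    a.query_id,
                    a.target_id,
                    a.target_species,
                    a.target_length,
                    f"{a.bitscore:g}",
                    f"{a.e_value:g}",
                    f"{a.aligned_fraction:g}",
                    int(a.is_transposon_target),
                    a.target_name,
                ]
            )


def read_coverage_bed(path: str | Path) -> list[CoverageSpan]:
    """BED: chrom, chromStart (0-based), chromEnd, source, intensity, strand."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}: line {lineno}: expected >= 5 columns")
            strand = cols[5] if len(cols) > 5 else "."
            out.append(
                CoverageSpan(
                    GenomicInterval(
                        cols[0], int(cols[1]) + 1, int(cols[2]), strand
                    ),
                    float(cols[4]),
                    cols[3],
                )
            )
    return out


def write_coverage_bed(spans: Iterable[CoverageSpan], path) -> None:
    with open(path, "w") as fh:
        for s in sorted(spans, key=lambda s: (s.span.seq_id, s.span.start)):
            iv = s.span
            fh.write(
                f"{iv.seq_id}\t{iv.start - 1}\t{iv.end}\t{s.source}"
                f"\t{s.intensity:g}\t{iv.strand}\n"
            )


def read_transposon_bed(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 columns")
            out.append(GenomicInterval(cols[0], int(cols[1]) + 1, int(cols[2])))
    return out


def write_transposon_bed(spans: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(spans, key=lambda i: (i.seq_id, i.start)):
            fh.write(f"{iv.seq_id}\t{iv.start - 1}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ToolConfig:
    """Run configuration: evidence file paths plus thresholds and the seed.

    Mirrors a single TOML file with ``[paths]``, ``[weights]`` and
    ``[thresholds]`` sections; weights are handed to
    :class:`locusforge.evidence_scoring.WeightConfig`.
    """

    paths: dict[str, str] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "ToolConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(
            paths={k: str(v) for k, v in raw.get("paths", {}).items()},
            weights=dict(raw.get("weights", {})),
            thresholds=dict(raw.get("thresholds", {})),
            seed=int(raw.get("seed", 0)),
        )
        for name, w in cfg.weights.items():
            if name != "transposon" and w < 0:
                raise ValueError(f"weight {name} must be >= 0")
        return cfg

    def resolve(self, key: str, base: Path | None = None) -> Path | None:
        if key not in self.paths:
            return None
        p = Path(self.paths[key])
        if base is not None and not p.is_absolute():
            p = base / p
        return p


def read_evidence_bundle(
    config: ToolConfig, base_dir: str | Path | None = None
) -> EvidenceBundle:
    """Assemble an :class:`EvidenceBundle` from the files named in *config*.

    Missing path entries yield empty tracks; junctions below the read
    threshold are retained (they are merely flagged non-validated on use).
    """
    base = Path(base_dir) if base_dir is not None else None
    bundle = EvidenceBundle()
    p = config.resolve("junctions", base)
    if p:
        bundle.junctions = read_junction_tsv(p)
    p = config.resolve("coverage", base)
    if p:
        bundle.coverage = read_coverage_bed(p)
    p = config.resolve("alignments", base)
    if p:
        bundle.alignments = read_alignment_tsv(p)
    p = config.resolve("transposons", base)
    if p:
        bundle.transposon_spans = read_transposon_bed(p)
    p = config.resolve("protein_structures", base)
    if p:
        bundle.protein_structures = read_gff3(p)
    p = config.resolve("transcript_structures", base)
    if p:
        bundle.transcript_structures = read_gff3(p)
    p = config.resolve("reference_models", base)
    if p:
        bundle.reference_models = read_gff3(p)
    return bundle
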