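"""Pillar data model and file I/O.

A *pillar* is one ancestral locus that was triplicated by the hexaploidy: for
every extant polyploid genome it carries up to three candidate gene slots
("tracks"), each either empty or holding a syntenic gene.  An ordered set of
pillars approximates the ancestral gene order; runs of pillars between
contiguity breaks form the blocks over which the orthology HMM operates.

All coordinates are 0-based, half-open.  GFF3 input (1-based, closed) is
converted on ingest and back on output.

The pillar table dialect is TSV, one row per pillar::

    pillar_id  reference_gene  <genome>.1  <genome>.2  <genome>.3  ...

where each track field is ``gene_id:chrom:start:end:strand`` or ``-`` for an
empty slot.  A line consisting of ``#BREAK`` declares an explicit contiguity
break before the next pillar row.  Adjacency flags are *derived*: a track's
gene is flagged adjacent when the same track in the previous pillar holds a
gene on the same chromosome with no other pillar gene of that genome strictly
between the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "Genome",
    "Track",
    "Pillar",
    "PillarSet",
    "AnnotationSet",
    "PillarFormatError",
    "read_pillars",
    "write_pillars",
    "read_annotation",
]

N_TRACKS = 3


class PillarFormatError(ValueError):
    """Raised for malformed pillar tables, with the offending line number."""


@dataclass(frozen=True)
class Genome:
    name: str
    chromosomes: tuple[str, ...] = ()


@dataclass(frozen=True)
class Track:
    """One occupied gene slot of a pillar."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"track {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )


@dataclass
class Pillar:
    """One triplicated ancestral locus.

    ``tracks[genome]`` is a length-3 list of ``Track | None``;
    ``adjacency[genome]`` is a length-3 list of bools (derived, see module
    docstring).
    """

    pillar_id: int
    reference_gene: str | None = None
    tracks: dict[str, list[Track | None]] = field(default_factory=dict)
    adjacency: dict[str, list[bool]] = field(default_factory=dict)

    def tracks_for(self, genome: str) -> list[Track | None]:
        return self.tracks.get(genome, [None] * N_TRACKS)

    def presence(self, genome: str) -> tuple[bool, bool, bool]:
        return tuple(t is not None for t in self.tracks_for(genome))

    def n_genes(self) -> int:
        return sum(t is not None for slots in self.tracks.values() for t in slots)


@dataclass
class PillarSet:
    genomes: list[Genome]
    pillars: list[Pillar]
    #: positions i such that the chain re-initialises *before* pillars[i]
    breaks: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def genome_names(self) -> list[str]:
        return [g.name for g in self.genomes]

    def __len__(self) -> int:
        return len(self.pillars)

    def validate(self) -> None:
        names = self.genome_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate genome names")
        prev = None
        for p in self.pillars:
            if prev is not None and p.pillar_id <= prev:
                raise ValueError(f"pillar_ids not strictly increasing at {p.pillar_id}")
            prev = p.pillar_id
            if p.n_genes() == 0:
                raise ValueError(f"pillar {p.pillar_id} has no genes in any genome")
            for g in p.tracks:
                if g not in names:
                    raise ValueError(f"pillar {p.pillar_id}: unknown genome {g!r}")
                if len(p.tracks[g]) != N_TRACKS:
                    raise ValueError(f"pillar {p.pillar_id}: genome {g} needs {N_TRACKS} slots")

    def derive_adjacency(self) -> None:
        """Populate per-track adjacency flags and structural contiguity breaks."""
        flags_per_pillar, derived = _adjacency(self, self.breaks)
        for p, flags in zip(self.pillars, flags_per_pillar):
            p.adjacency = flags
        self.breaks = set(self.breaks) | derived


@dataclass
class AnnotationSet:
    """Per-genome gene records with 0-based half-open coordinates."""

    genes: dict[str, dict[str, Track]] = field(default_factory=dict)

    def add(self, genome: str, record: Track) -> None:
        table = self.genes.setdefault(genome, {})
        if record.gene_id in table:
            raise ValueError(f"duplicate gene_id {record.gene_id!r} in genome {genome}")
        table[record.gene_id] = record

    def get(self, genome: str, gene_id: str) -> Track | None:
        return self.genes.get(genome, {}).get(gene_id)


def _adjacency(
    ps: "PillarSet", explicit: set[int]
) -> tuple[list[dict[str, list[bool]]], set[int]]:
    """Adjacency flags per pillar and the derived contiguity breaks (pure)."""
    rank: dict[tuple[str, str], int] = {}
    for g in ps.genome_names:
        per_chrom: dict[str, list[tuple[int, str]]] = {}
        for p in ps.pillars:
            for t in p.tracks_for(g):
                if t is not None:
                    per_chrom.setdefault(t.chromosome, []).append((t.start, t.gene_id))
        for items in per_chrom.values():
            for r, (_, gid) in enumerate(sorted(items)):
                rank[(g, gid)] = r
    all_flags: list[dict[str, list[bool]]] = []
    derived: set[int] = set()
    for i, p in enumerate(ps.pillars):
        any_adjacent = False
        flags_g: dict[str, list[bool]] = {}
        for g in ps.genome_names:
            flags = [False] * N_TRACKS
            if i > 0 and i not in explicit:
                prev_tracks = ps.pillars[i - 1].tracks_for(g)
                for k, t in enumerate(p.tracks_for(g)):
                    pt = prev_tracks[k]
                    if (
                        t is not None
                        and pt is not None
                        and t.chromosome == pt.chromosome
                        and abs(rank[(g, t.gene_id)] - rank[(g, pt.gene_id)]) == 1
                    ):
                        flags[k] = True
                        any_adjacent = True
            flags_g[g] = flags
        all_flags.append(flags_g)
        if i > 0 and not any_adjacent:
            derived.add(i)
    return all_flags, derived


def _parse_track(fieldtext: str, lineno: int) -> Track | None:
    if fieldtext == "-":
        return None
    parts = fieldtext.split(":")
    if len(parts) != 5:
        raise PillarFormatError(f"line {lineno}: malformed track field {fieldtext!r}")
    gid, chrom, start, end, strand = parts
    try:
        return Track(gid, chrom, int(start), int(end), strand)
    except ValueError as exc:
        raise PillarFormatError(f"line {lineno}: {exc}") from exc


def read_pillars(path) -> PillarSet:
    """Read a pillar TSV (dialect in the module docstring) into a PillarSet."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = None
    genomes: list[str] = []
    pillars: list[Pillar] = []
    breaks: set[int] = set()
    pending_break = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.strip() == "#BREAK":
            pending_break = True
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if header[:2] != ["pillar_id", "reference_gene"]:
                raise PillarFormatError(f"line {lineno}: bad header {header[:2]}")
            track_cols = header[2:]
            if len(track_cols) % N_TRACKS:
                raise PillarFormatError(f"line {lineno}: track columns not a multiple of 3")
            for j in range(0, len(track_cols), N_TRACKS):
                base = track_cols[j].rsplit(".", 1)[0]
                expect = [f"{base}.{k + 1}" for k in range(N_TRACKS)]
                if track_cols[j : j + N_TRACKS] != expect:
                    raise PillarFormatError(f"line {lineno}: expected columns {expect}")
                genomes.append(base)
            continue
        if len(fields) != 2 + N_TRACKS * len(genomes):
            raise PillarFormatError(
                f"line {lineno}: expected {2 + N_TRACKS * len(genomes)} fields, got {len(fields)}"
            )
        try:
            pid = int(fields[0])
        except ValueError as exc:
            raise PillarFormatError(f"line {lineno}: bad pillar_id {fields[0]!r}") from exc
        ref = fields[1] if fields[1] != "-" else None
        tracks: dict[str, list[Track | None]] = {}
        for j, g in enumerate(genomes):
            slots = [
                _parse_track(fields[2 + j * N_TRACKS + k], lineno) for k in range(N_TRACKS)
            ]
            tracks[g] = slots
        if pending_break:
            breaks.add(len(pillars))
            pending_break = False
        pillars.append(Pillar(pid, ref, tracks))
    if header is None:
        raise PillarFormatError("empty pillar file")
    ps = PillarSet([Genome(g) for g in genomes], pillars, breaks)
    ps.derive_adjacency()
    return ps


def _format_track(t: Track | None) -> str:
    if t is None:
        return "-"
    return f"{t.gene_id}:{t.chromosome}:{t.start}:{t.end}:{t.strand}"


def write_pillars(ps: PillarSet, path) -> None:
    """Write the canonical TSV form; read/write round-trips are identity."""
    cols = ["pillar_id", "reference_gene"]
    for g in ps.genome_names:
        cols += [f"{g}.{k + 1}" for k in range(N_TRACKS)]
    out = ["\t".join(cols)]
    # breaks that adjacency alone would not re-derive must be written out
    _, rederivable = _adjacency(ps, set())
    explicit = {i for i in ps.breaks if i not in rederivable and 0 < i < len(ps.pillars)}
    for i, p in enumerate(ps.pillars):
        if i in explicit:
            out.append("#BREAK")
        row = [str(p.pillar_id), p.reference_gene or "-"]
        for g in ps.genome_names:
            row += [_format_track(t) for t in p.tracks_for(g)]
        out.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_annotation(path, genome: str) -> AnnotationSet:
    """Read gene features from a GFF3 file for one genome.

    GFF3's 1-based closed coordinates become 0-based half-open.  Records with
    end < start are rejected; duplicate gene IDs are an error.
    """
    import gffutils

    ann = AnnotationSet()
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
    except Exception as exc:  # gffutils raises plain ValueError on empty input
        with open(path) as fh:
            if not any(ln.strip() and not ln.startswith("#") for ln in fh):
                warnings.warn(f"empty GFF3 file {path}; empty annotation set")
                return ann
        raise exc
    for feat in db.features_of_type("gene"):
        if feat.end < feat.start:
            raise ValueError(f"gene {feat.id}: end < start in GFF3 record")
        ann.add(genome, Track(feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand or "+"))
    return ann
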