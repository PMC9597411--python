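"""Subgenome-assigned intergenic regions (SAIRs).

A SAIR group is the set of orthologous intergenic intervals, one per
genome, lying between two neighbouring pillars at which one subgenome has a
gene present in every genome, the flanking gene pairs are syntenic
neighbours in every genome, and the joint orthology state is inferred with
high confidence (posterior >= threshold at both pillars).  Such intervals
are orthologous *and* of known subgenome of origin, which is what makes
them usable for comparing repeat content between subgenomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .hmm import HMMResult
from .models import SUBGENOMES
from .pillars import AnnotationSet, PillarSet

__all__ = ["SAIRMember", "SAIRGroup", "find_sairs", "extract_sequences", "load_fasta"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SAIRMember:
    """One genome's interval of a SAIR group (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    left_gene: str
    right_gene: str
    sequence: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SAIRGroup:
    sair_id: str
    subgenome: str
    left_pillar: int
    right_pillar: int
    confidence: float  # min joint-state posterior over the two pillars
    members: dict[str, SAIRMember] = field(default_factory=dict)


def _gene_ranks(pillars: PillarSet) -> dict[tuple[str, str], int]:
    rank: dict[tuple[str, str], int] = {}
    for g in pillars.genome_names:
        per_chrom: dict[str, list[tuple[int, str]]] = {}
        for p in pillars.pillars:
            for t in p.tracks_for(g):
                if t is not None:
                    per_chrom.setdefault(t.chromosome, []).append((t.start, t.gene_id))
        for items in per_chrom.values():
            for r, (_, gid) in enumerate(sorted(items)):
                rank[(g, gid)] = r
    return rank


def find_sairs(
    pillars: PillarSet,
    result: HMMResult,
    annotation: AnnotationSet | None = None,
    threshold: float = 0.95,
    max_gap: int = 0,
) -> list[SAIRGroup]:
    """Identify SAIR groups from pillar pairs with confident orthology.

    Pillar pairs at ancestral distance up to ``1 + max_gap`` are examined
    (``max_gap=0`` is strict adjacency).  For each subgenome the pair
    qualifies when: the MAP joint state at both pillars has posterior >=
    threshold and maps the same track of each genome to the subgenome; that
    track holds a gene in every genome at both pillars; and each genome's
    two genes are syntenic neighbours (same chromosome, no other pillar
    gene between them).  ``annotation``, when given, overrides the gene
    coordinates stored in the pillar tracks.
    """
    rank = _gene_ranks(pillars)
    genomes = result.genomes
    out: list[SAIRGroup] = []
    n = len(pillars.pillars)
    for i in range(n):
        for j in range(i + 1, min(i + 2 + max_gap, n)):
            if any(b in pillars.breaks for b in range(i + 1, j + 1)):
                continue
            pi_, pj = pillars.pillars[i], pillars.pillars[j]
            conf = min(float(result.map_posterior[i]), float(result.map_posterior[j]))
            if conf < threshold:
                continue
            perms_i = result.state_perms(int(result.map_states[i]))
            perms_j = result.state_perms(int(result.map_states[j]))
            for s, subg in enumerate(SUBGENOMES):
                members: dict[str, SAIRMember] = {}
                ok = True
                for k, g in enumerate(genomes):
                    t_i = perms_i[k].index(s)
                    t_j = perms_j[k].index(s)
                    if t_i != t_j:
                        ok = False
                        break
                    a = pi_.tracks_for(g)[t_i]
                    b = pj.tracks_for(g)[t_j]
                    if a is None or b is None:
                        ok = False
                        break
                    if annotation is not None:
                        a = annotation.get(g, a.gene_id) or a
                        b = annotation.get(g, b.gene_id) or b
                    if (
                        a.chromosome != b.chromosome
                        or abs(rank[(g, a.gene_id)] - rank[(g, b.gene_id)]) != 1
                    ):
                        ok = False  # not syntenic neighbours
                        break
                    lo, hi = (a, b) if a.start <= b.start else (b, a)
                    if lo.end >= hi.start:
                        log.info(
                            "SAIR %s_%d_%d dropped: flanking genes overlap/abut in %s",
                            subg,
                            pi_.pillar_id,
                            pj.pillar_id,
                            g,
                        )
                        ok = False
                        break
                    members[g] = SAIRMember(
                        a.chromosome, lo.end, hi.start, lo.gene_id, hi.gene_id
                    )
                if ok:
                    out.append(
                        SAIRGroup(
                            f"{subg}_{pi_.pillar_id}_{pj.pillar_id}",
                            subg,
                            pi_.pillar_id,
                            pj.pillar_id,
                            conf,
                            members,
                        )
                    )
    return out


def load_fasta(path) -> dict[str, str]:
    """Sequence name -> uppercase sequence string."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_sequences(
    groups: list[SAIRGroup], fasta: dict[str, dict[str, str]]
) -> list[SAIRGroup]:
    """Attach interval sequences sliced from per-genome FASTA dictionaries.

    ``fasta[genome][chromosome]`` must cover every member interval; the
    strand is ignored (intervals are reported on the forward strand).
    """
    out = []
    for grp in groups:
        members = {}
        for g, m in grp.members.items():
            seqs = fasta[g]
            if m.chromosome not in seqs:
                raise KeyError(f"chromosome {m.chromosome!r} missing from {g} FASTA")
            chrom = seqs[m.chromosome]
            if m.end > len(chrom):
                raise ValueError(
                    f"interval [{m.start}, {m.end}) exceeds {g}:{m.chromosome} "
                    f"length {len(chrom)}"
                )
            members[g] = replace(m, sequence=chrom[m.start : m.end])
        out.append(replace_group(grp, members))
    return out


def replace_group(grp: SAIRGroup, members: dict[str, SAIRMember]) -> SAIRGroup:
    return SAIRGroup(
        grp.sair_id, grp.subgenome, grp.left_pillar, grp.right_pillar, grp.confidence, members
    )
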