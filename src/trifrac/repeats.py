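"""Repetitive-element analysis over SAIRs.

Ingests repeat-search hit tables (BLASTN outfmt-6 or nhmmer tblout), merges
hits into regions, calls *ancestral* repeats either by parsimony (a hit to
the same element in every genome's member of a SAIR group) or by conserved
local alignment of a region against the orthologous SAIRs, computes
per-subgenome repeat densities (hits per kilobase of SAIR sequence), and
assesses density differences with a placement randomization test.

The randomization follows the no-reuse scheme: hits are shuffled, each hit
is dropped uniformly among the positions left in SAIRs at least as long as
the hit (a SAIR has length - hit_length positions), and a SAIR that has
received a hit is removed for the remaining hits, so placed hits can never
overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .sairs import SAIRGroup

__all__ = [
    "REHit",
    "RERegion",
    "SAIRInterval",
    "RandomizationResult",
    "load_hits",
    "merge_regions",
    "local_align",
    "call_ancestral_parsimony",
    "call_ancestral_regions",
    "re_density",
    "randomization_test",
    "sair_intervals",
]

log = logging.getLogger(__name__)

DEFAULT_E_CUTOFF = 1e-5
MIN_ALIGN_LEN = 80
MIN_ALIGN_SCORE = 200


@dataclass(frozen=True)
class REHit:
    """One repeat match within a SAIR (0-based half-open coordinates)."""

    element_id: str
    sair_id: str
    genome: str
    start: int
    end: int
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")
        if self.evalue < 0:
            raise ValueError("negative E-value")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RERegion:
    sair_id: str
    start: int
    end: int
    elements: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SAIRInterval:
    sair_id: str
    subgenome: str
    length: int


def sair_intervals(groups: list[SAIRGroup], genome: str) -> list[SAIRInterval]:
    """One genome's SAIR lengths, labelled by subgenome of origin."""
    return [
        SAIRInterval(g.sair_id, g.subgenome, g.members[genome].length)
        for g in groups
        if genome in g.members
    ]


# ------------------------------------------------------------------ ingest
_BLAST6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def load_hits(
    path,
    dialect: str,
    e_cutoff: float = DEFAULT_E_CUTOFF,
    genome: str = "",
    query_is_sair: bool = True,
) -> list[REHit]:
    """Parse a repeat-search table, keeping hits with E-value <= cutoff.

    ``blast6``: tab-separated BLASTN ``-outfmt 6``.  ``query_is_sair``
    selects whether the query (default) or the subject column names the
    SAIR.  ``nhmmer``: nhmmer ``--tblout`` format, target = SAIR, query =
    element; alignment coordinates are used.  1-based inclusive input
    coordinates become 0-based half-open, normalised so start < end.
    """
    hits: list[REHit] = []
    if dialect == "blast6":
        tab = pd.read_csv(path, sep="\t", names=_BLAST6_COLS, comment="#")
        for row in tab.itertuples(index=False):
            if row.evalue > e_cutoff:
                continue
            if query_is_sair:
                sair, elem, a, b = row.qseqid, row.sseqid, row.qstart, row.qend
            else:
                sair, elem, a, b = row.sseqid, row.qseqid, row.sstart, row.send
            lo, hi = (a, b) if a <= b else (b, a)
            hits.append(REHit(str(elem), str(sair), genome, int(lo) - 1, int(hi),
                              float(row.bitscore), float(row.evalue)))
    elif dialect == "nhmmer":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.split()
                if len(f) < 15:
                    raise ValueError(f"short nhmmer tblout line: {line!r}")
                sair, elem = f[0], f[2]
                a, b = int(f[6]), int(f[7])  # alifrom, alito
                ev, score = float(f[12]), float(f[13])
                if ev > e_cutoff:
                    continue
                lo, hi = (a, b) if a <= b else (b, a)
                hits.append(REHit(elem, sair, genome, lo - 1, hi, score, ev))
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'blast6' or 'nhmmer'")
    return hits


# ------------------------------------------------------------------ regions
def merge_regions(hits: list[REHit]) -> list[RERegion]:
    """Union hits into regions, merging any overlap of >= 1 base.

    Abutting hits (zero overlap) stay separate.  Idempotent and
    order-invariant.
    """
    by_sair: dict[str, list[REHit]] = {}
    for h in hits:
        by_sair.setdefault(h.sair_id, []).append(h)
    out: list[RERegion] = []
    for sair_id in sorted(by_sair):
        items = sorted(by_sair[sair_id], key=lambda h: (h.start, h.end))
        cur_start, cur_end = items[0].start, items[0].end
        cur_elems = {items[0].element_id}
        for h in items[1:]:
            if h.start < cur_end:  # >= 1 base of overlap
                cur_end = max(cur_end, h.end)
                cur_elems.add(h.element_id)
            else:
                out.append(RERegion(sair_id, cur_start, cur_end, tuple(sorted(cur_elems))))
                cur_start, cur_end, cur_elems = h.start, h.end, {h.element_id}
        out.append(RERegion(sair_id, cur_start, cur_end, tuple(sorted(cur_elems))))
    return out


# ------------------------------------------------------------------ alignment
def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            m[x, y] = 4.0 if (x == y and x != "N") else -5.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -4.0
    return aligner


_ALIGNER = _make_aligner()


def local_align(query: str, target: str) -> tuple[float, int]:
    """Best Smith-Waterman local alignment (score, alignment columns).

    Scoring: match +4, mismatch -5, gap open (first gapped base) -8, gap
    extend -4; N matches nothing, scoring as a mismatch.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    q, t = query.upper(), target.upper()
    for s in (q, t):
        if set(s) - set("ACGTN"):
            raise ValueError(f"sequence contains non-ACGTN symbols: {set(s) - set('ACGTN')}")
    alns = _ALIGNER.align(q, t)
    best = alns[0]
    return float(best.score), int(best.length)


# ------------------------------------------------------------------ ancestral calls
def call_ancestral_parsimony(
    hits: list[REHit], groups: list[SAIRGroup]
) -> list[tuple[str, str]]:
    """Elements present in every genome's member of a group.

    Returns (sair_id, element_id) pairs called ancestral: a passing hit to
    the same element exists in all genomes of the group.
    """
    index: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        index.setdefault((h.sair_id, h.element_id), set()).add(h.genome)
    calls = []
    for grp in groups:
        genomes = set(grp.members)
        elems = {e for (sid, e) in index if sid == grp.sair_id}
        for e in sorted(elems):
            if genomes <= index[(grp.sair_id, e)]:
                calls.append((grp.sair_id, e))
    return calls


def call_ancestral_regions(
    regions: list[RERegion],
    groups: list[SAIRGroup],
    reference_genome: str,
    min_length: int = MIN_ALIGN_LEN,
    min_score: float = MIN_ALIGN_SCORE,
) -> list[RERegion]:
    """Regions of the reference genome conserved in all other genomes.

    Each region (in the reference member's SAIR coordinates) is locally
    aligned against the orthologous SAIR sequence of every other genome;
    it is ancestral iff every genome yields an alignment of at least
    ``min_length`` columns scoring at least ``min_score``.
    """
    by_id = {g.sair_id: g for g in groups}
    ancestral = []
    for region in regions:
        grp = by_id.get(region.sair_id)
        if grp is None:
            log.info("region %s skipped: unknown SAIR", region.sair_id)
            continue
        ref = grp.members.get(reference_genome)
        if ref is None or ref.sequence is None:
            log.info("region %s skipped: reference sequence missing", region.sair_id)
            continue
        qseq = ref.sequence[region.start : region.end]
        ok = True
        for g, member in grp.members.items():
            if g == reference_genome:
                continue
            if member.sequence is None:
                log.info("region %s skipped: %s sequence missing", region.sair_id, g)
                ok = False
                break
            score, length = local_align(qseq, member.sequence)
            if length < min_length or score < min_score:
                ok = False
                break
        if ok:
            ancestral.append(region)
    return ancestral


# ------------------------------------------------------------------ density & test
def re_density(hits_or_regions, sairs: list[SAIRInterval]) -> pd.DataFrame:
    """Hits per kilobase of SAIR sequence, by subgenome.

    ``hits_or_regions`` may be REHits or RERegions; each is attributed to
    the subgenome of its SAIR.
    """
    sub_of = {s.sair_id: s.subgenome for s in sairs}
    length = {}
    for s in sairs:
        length[s.subgenome] = length.get(s.subgenome, 0) + s.length
    counts = dict.fromkeys(length, 0)
    for h in hits_or_regions:
        sub = sub_of.get(h.sair_id)
        if sub is not None:
            counts[sub] += 1
    rows = []
    for sub in sorted(length):
        total = length[sub]
        if total == 0:
            raise ValueError(f"subgenome {sub} has zero total SAIR length")
        rows.append(
            {"subgenome": sub, "hits": counts[sub], "length_bp": total,
             "density_per_kb": 1000.0 * counts[sub] / total}
        )
    return pd.DataFrame(rows).set_index("subgenome")


@dataclass(frozen=True)
class RandomizationResult:
    pair: tuple[str, str]
    observed_diff: float  # density(A) - density(B), hits/kB
    replicates: int
    exceedances: int
    p_value: float
    alternative: str


@njit(cache=True)
def _place_replicates(lengths, is_a, hit_lens, uniforms, orders, len_a, len_b):
    reps, nh = orders.shape
    ns = lengths.shape[0]
    diffs = np.empty(reps)
    avail = np.empty(ns, dtype=np.bool_)
    for r in range(reps):
        for s in range(ns):
            avail[s] = True
        ca = 0
        cb = 0
        for k in range(nh):
            hl = hit_lens[orders[r, k]]
            t = 0.0
            for s in range(ns):
                if avail[s] and lengths[s] > hl:
                    t += lengths[s] - hl
            if t <= 0.0:
                diffs[r] = np.nan
                break
            x = uniforms[r, k] * t
            cum = 0.0
            chosen = -1
            for s in range(ns):
                if avail[s] and lengths[s] > hl:
                    cum += lengths[s] - hl
                    if x < cum:
                        chosen = s
                        break
            if chosen < 0:
                chosen = ns - 1
            avail[chosen] = False
            if is_a[chosen]:
                ca += 1
            else:
                cb += 1
        else:
            diffs[r] = 1000.0 * ca / len_a - 1000.0 * cb / len_b
    return diffs


def random_placement(
    sairs: list[SAIRInterval], hit_lengths: list[int], seed: int = 0
) -> list[REHit]:
    """Place hypothetical hits by the null scheme; returns synthetic hits.

    Each hit of the given length is dropped uniformly among the positions
    remaining in unused SAIRs (no-reuse rule), exactly as inside the
    randomization test; useful for generating datasets that are true draws
    from the null.
    """
    rng = np.random.default_rng(seed)
    available = list(range(len(sairs)))
    out: list[REHit] = []
    for k, hl in enumerate(hit_lengths):
        weights = [(i, sairs[i].length - hl) for i in available if sairs[i].length > hl]
        total = sum(w for _, w in weights)
        if total <= 0:
            raise RuntimeError("ran out of placeable positions")
        x = rng.random() * total
        for i, w in weights:
            if x < w:
                chosen = i
                offset = int(x)
                break
            x -= w
        available.remove(chosen)
        out.append(
            REHit(
                f"E{k}", sairs[chosen].sair_id, "", offset, offset + hl, 0.0, 1e-20
            )
        )
    return out


def randomization_test(
    hits: list[REHit],
    sairs: list[SAIRInterval],
    pair: tuple[str, str],
    replicates: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> RandomizationResult:
    """Placement randomization test of the density difference between two
    subgenomes.

    The observed difference density(A) - density(B) is compared to the null
    distribution obtained by shuffling the pooled hits of both subgenomes
    and placing them at random (no-reuse scheme, module docstring) across
    the pooled SAIRs.  p = (exceedances + 1) / (replicates + 1);
    ``alternative`` is ``two-sided``, ``greater`` or ``less`` on A - B.
    """
    a, b = pair
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pool = [s for s in sairs if s.subgenome in (a, b)]
    sub_of = {s.sair_id: s.subgenome for s in pool}
    used = [h for h in hits if sub_of.get(h.sair_id) in (a, b)]
    if not pool:
        raise ValueError("no SAIRs for the requested subgenome pair")
    if len(used) > len(pool):
        raise ValueError(
            f"{len(used)} hits cannot be placed without reuse in {len(pool)} SAIRs"
        )
    len_a = sum(s.length for s in pool if s.subgenome == a)
    len_b = sum(s.length for s in pool if s.subgenome == b)
    if len_a == 0 or len_b == 0:
        raise ValueError("zero total SAIR length in one subgenome")
    ca = sum(1 for h in used if sub_of[h.sair_id] == a)
    cb = len(used) - ca
    observed = 1000.0 * ca / len_a - 1000.0 * cb / len_b
    rng = np.random.default_rng(seed)
    nh = len(used)
    uniforms = rng.random((replicates, nh))
    orders = np.empty((replicates, nh), dtype=np.int64)
    for r in range(replicates):
        orders[r] = rng.permutation(nh)
    diffs = _place_replicates(
        np.array([s.length for s in pool], dtype=np.float64),
        np.array([s.subgenome == a for s in pool]),
        np.array([h.length for h in used], dtype=np.float64),
        uniforms,
        orders,
        float(len_a),
        float(len_b),
    )
    if np.isnan(diffs).any():
        raise RuntimeError("a replicate ran out of placeable positions")
    if alternative == "two-sided":
        exceed = int(np.sum(np.abs(diffs) >= abs(observed)))
    elif alternative == "greater":
        exceed = int(np.sum(diffs >= observed))
    else:
        exceed = int(np.sum(diffs <= observed))
    p = (exceed + 1) / (replicates + 1)
    return RandomizationResult((a, b), observed, replicates, exceed, p, alternative)
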