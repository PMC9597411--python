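"""Synthetic pillar datasets and RE-bearing SAIR sequences with known truth.

The pillar generator is the exact generative counterpart of the inference
machinery: pillars start from the model's root distribution, evolve down
the species tree by the loss-process transition matrices, and each genome's
track permutation follows the HMM's switch kernel (probability theta of
jumping to a uniformly chosen alternative between adjacent pillars, a
synteny break).  A break starts a fresh chromosome segment, so the
adjacency flags derived from coordinates reflect the simulated breaks.

The SAIR generator draws ancestral intergenic sequences, plants repeat
copies from a small bundled element library at per-subgenome densities,
evolves each genome's copy by substitutions and indels, and emits both the
sequences and a perfect-knowledge hit table, so the repeat stage can be
tested end to end without running any external search.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .hmm import PERMS
from .models import LossModel, root_distribution, transition_matrix
from .pillars import Genome, Pillar, PillarSet, Track
from .repeats import REHit
from .sairs import SAIRGroup, SAIRMember
from .trees import SpeciesTree

__all__ = [
    "SimulationConfig",
    "PillarTruth",
    "SAIRTruth",
    "simulate_pillars",
    "simulate_sairs",
    "toy_re_library",
    "write_fasta",
    "write_hits_blast6",
]

_SURVIVORS = (
    (0, 1, 2), (0, 1), (0, 2), (1, 2), (0,), (1,), (2,),
)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
SUBGENOMES = ("LF", "IF", "MF")


@dataclass
class SimulationConfig:
    """Study conditions for the generators.

    Pillar side: ``tree`` carries branch lengths in alpha*t units; ``model``
    is the true loss model; ``theta`` the per-pillar synteny-break
    probability; ``block_size`` optionally inserts an explicit contiguity
    break (and chain restart) every so many pillars.

    SAIR side: ancestral repeat densities are per subgenome in elements per
    kilobase; ``recent_density`` adds genome-private insertions emulating
    post-speciation repeat turnover; ``divergence`` is the per-site
    substitution probability applied independently on each genome's copy,
    with small indels at ``indel_rate`` per site (geometric lengths, mean
    ``indel_mean``).
    """

    tree: SpeciesTree
    model: LossModel
    seed: int
    n_pillars: int = 5000
    theta: float = 0.02
    block_size: int | None = None
    n_sairs: dict[str, int] = field(
        default_factory=lambda: {"LF": 200, "IF": 150, "MF": 150}
    )
    sair_length_range: tuple[int, int] = (800, 3000)
    ancestral_density: dict[str, float] = field(
        default_factory=lambda: {"LF": 1.0, "IF": 3.0, "MF": 3.0}
    )
    recent_density: float = 2.0
    divergence: float = 0.10
    indel_rate: float = 0.01
    indel_mean: float = 3.0


@dataclass
class PillarTruth:
    genomes: list[str]
    perms: np.ndarray  # (n_pillars, n_genomes) permutation index per genome
    leaf_states: np.ndarray  # (n_pillars, n_genomes) loss state at each leaf
    root_states: np.ndarray  # (n_pillars,) state at the polyploidy event

    def survivor_counts(self) -> np.ndarray:
        """(n_genomes, 3) true surviving-gene counts per subgenome."""
        out = np.zeros((len(self.genomes), 3))
        for k in range(len(self.genomes)):
            for s in self.leaf_states[:, k]:
                for sub in _SURVIVORS[s]:
                    out[k, sub] += 1
        return out


def simulate_pillars(config: SimulationConfig) -> tuple[PillarSet, PillarTruth]:
    """Sample a pillar dataset under the loss model and break kernel."""
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    model = config.model
    n = config.n_pillars
    genomes = tree.leaf_names
    ng = len(genomes)

    # --- loss states down the tree (vectorised over pillars per branch)
    pi = root_distribution(model)
    top = rng.choice(7, size=n, p=pi)
    states: dict[int, np.ndarray] = {}

    def sample_branch(parent_states: np.ndarray, node) -> np.ndarray:
        P = transition_matrix(model, node.length, root=(node is tree.root))
        child = np.empty_like(parent_states)
        for s in np.unique(parent_states):
            idx = np.nonzero(parent_states == s)[0]
            child[idx] = rng.choice(7, size=len(idx), p=P[s])
        return child

    states[tree.root.index] = sample_branch(top, tree.root)  # stem
    for node in reversed(tree.nodes[:-1]):  # pre-order below the crown
        states[node.index] = sample_branch(states[node.parent], node)
    leaf_states = np.empty((n, ng), dtype=np.int64)
    for node in tree.leaves:
        leaf_states[:, genomes.index(node.name)] = states[node.index]

    # --- per-genome permutation chains with synteny breaks
    perms = np.empty((n, ng), dtype=np.int64)
    segment = np.zeros((n, ng), dtype=np.int64)
    breaks: set[int] = set()
    seg_counter = np.zeros(ng, dtype=np.int64)
    for i in range(n):
        new_block = i == 0 or (config.block_size and i % config.block_size == 0)
        if new_block and i > 0:
            breaks.add(i)
        for k in range(ng):
            if new_block:
                perms[i, k] = rng.integers(6)
                seg_counter[k] += 1
            elif rng.random() < config.theta:
                alts = [q for q in range(6) if q != perms[i - 1, k]]
                perms[i, k] = alts[rng.integers(5)]
                seg_counter[k] += 1
            else:
                perms[i, k] = perms[i - 1, k]
            segment[i, k] = seg_counter[k]

    # --- emit pillars: gene on track t iff its subgenome survived
    gene_len, spacing = 200, 1000
    cursors: dict[str, int] = {}
    pillars = []
    for i in range(n):
        tracks = {}
        for k, g in enumerate(genomes):
            perm = PERMS[perms[i, k]]
            surv = set(_SURVIVORS[leaf_states[i, k]])
            slots = []
            for t in range(3):
                if perm[t] in surv:
                    chrom = f"{g}_s{segment[i, k]}_t{t}"
                    pos = cursors.get(chrom, 0)
                    cursors[chrom] = pos + spacing
                    slots.append(Track(f"{g}_p{i}_t{t}", chrom, pos, pos + gene_len))
                else:
                    slots.append(None)
            tracks[g] = slots
        pillars.append(Pillar(i, None, tracks))
    ps = PillarSet([Genome(g) for g in genomes], pillars, breaks)
    ps.derive_adjacency()
    return ps, PillarTruth(list(genomes), perms, leaf_states, top)


# ---------------------------------------------------------------- sequences
def toy_re_library() -> dict[str, str]:
    """The bundled 12-element toy repeat library (lengths 60-400 b)."""
    from .sairs import load_fasta

    with importlib.resources.as_file(
        importlib.resources.files("trifrac") / "data" / "toy_re_library.fasta"
    ) as p:
        return load_fasta(p)


def _rand_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, length).astype(np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _from_str(s: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[np.frombuffer(s.encode(), dtype=np.uint8)]


def _evolve(
    seq: np.ndarray, rng: np.random.Generator, sub: float, indel: float, mean: float
) -> tuple[np.ndarray, np.ndarray]:
    """Substitutions + indels; returns (new sequence, old->new offset map).

    The offset map has length len(seq)+1: old interval [a, b) maps to
    [map[a] + ins_len(a), map[b]) in the new coordinates.
    """
    L = len(seq)
    s = seq.copy()
    mask = rng.random(L) < sub
    s[mask] = (s[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    keep = np.ones(L, dtype=bool)
    insertions: dict[int, np.ndarray] = {}
    for p in np.nonzero(rng.random(L) < indel)[0]:
        ln = int(rng.geometric(1.0 / mean))
        if rng.random() < 0.5:
            keep[p : p + ln] = False
        else:
            insertions[int(p)] = _rand_seq(rng, ln)
    contrib = keep.astype(np.int64)
    for p, ins in insertions.items():
        contrib[p] += len(ins)
    offsets = np.concatenate([[0], np.cumsum(contrib)])
    parts = []
    last = 0
    for p in sorted(insertions):
        parts.append(s[last:p][keep[last:p]])
        parts.append(insertions[p])
        last = p
    parts.append(s[last:][keep[last:]])
    return np.concatenate(parts), offsets


@dataclass(frozen=True)
class PlantedRE:
    element_id: str
    sair_id: str
    genome: str
    start: int
    end: int
    ancestral: bool


@dataclass
class SAIRTruth:
    planted: list[PlantedRE]

    def ancestral_pairs(self) -> set[tuple[str, str]]:
        return {(p.sair_id, p.element_id) for p in self.planted if p.ancestral}


def simulate_sairs(
    config: SimulationConfig,
) -> tuple[list[SAIRGroup], list[REHit], SAIRTruth]:
    """Generate SAIR groups with sequences, perfect-knowledge hits and truth.

    Hits report each surviving planted copy (ancestral copies in every
    genome, recent ones in their own genome) with a nominal E-value of
    1e-20, standing in for an external BLASTN/nhmmer search with no false
    negatives.
    """
    rng = np.random.default_rng(config.seed + 1)
    library = {k: _from_str(v) for k, v in toy_re_library().items()}
    elem_ids = sorted(library)
    mean_len = float(np.mean([len(v) for v in library.values()]))
    for sub, dens in config.ancestral_density.items():
        if dens * mean_len >= 900.0:  # > ~90% expected occupancy per kB
            raise ValueError(
                f"ancestral RE density too high for subgenome {sub}: "
                f"{dens}/kB of ~{mean_len:.0f} b elements cannot be placed "
                "without overlap"
            )
    genomes = config.tree.leaf_names
    groups: list[SAIRGroup] = []
    hits: list[REHit] = []
    planted: list[PlantedRE] = []
    lo, hi = config.sair_length_range
    for sub in SUBGENOMES:
        for i in range(config.n_sairs.get(sub, 0)):
            sair_id = f"{sub}_{i:04d}"
            L = int(rng.integers(lo, hi + 1))
            anc = _rand_seq(rng, L)
            n_anc = rng.poisson(config.ancestral_density.get(sub, 0.0) * L / 1000.0)
            anc_plants: list[tuple[str, int, int]] = []
            occupied: list[tuple[int, int]] = []
            for _ in range(n_anc):
                # draw an element that still fits; place it uniformly among
                # the positions left free by earlier plants
                elem = None
                order = rng.permutation(len(elem_ids))
                for j in order:
                    cand = elem_ids[j]
                    el = library[cand]
                    gaps = []
                    prev = 0
                    for a, b in sorted(occupied) + [(L, L)]:
                        if a - prev >= len(el):
                            gaps.append((prev, a - prev - len(el) + 1))
                        prev = max(prev, b)
                    total = sum(npos for _, npos in gaps)
                    if total > 0:
                        elem = cand
                        break
                if elem is None:
                    break  # this SAIR is saturated; plant the rest nowhere
                x = int(rng.integers(total))
                for gap_start, npos in gaps:
                    if x < npos:
                        p = gap_start + x
                        break
                    x -= npos
                anc[p : p + len(el)] = el
                occupied.append((p, p + len(el)))
                anc_plants.append((elem, p, p + len(el)))
            members: dict[str, SAIRMember] = {}
            for g in genomes:
                seq, offsets = _evolve(
                    anc, rng, config.divergence, config.indel_rate, config.indel_mean
                )
                coords = [
                    (elem, int(offsets[a]), int(offsets[b]), True)
                    for elem, a, b in anc_plants
                ]
                # recent, genome-private insertions
                n_rec = rng.poisson(config.recent_density * L / 1000.0)
                for _ in range(n_rec):
                    elem = elem_ids[rng.integers(len(elem_ids))]
                    el = library[elem]
                    q = int(rng.integers(0, len(seq) + 1))
                    seq = np.concatenate([seq[:q], el, seq[q:]])
                    coords = [
                        (e, a + len(el) if a >= q else a, b + len(el) if b > q else b, anc_flag)
                        for e, a, b, anc_flag in coords
                    ]
                    coords.append((elem, q, q + len(el), False))
                for e, a, b, anc_flag in coords:
                    if b - a < 20:  # copy effectively deleted
                        continue
                    hits.append(REHit(e, sair_id, g, a, b, 2.0 * (b - a), 1e-20))
                    planted.append(PlantedRE(e, sair_id, g, a, b, anc_flag))
                members[g] = SAIRMember(
                    f"{sair_id}|{g}", 0, len(seq), f"{sair_id}_L", f"{sair_id}_R",
                    _to_str(seq),
                )
            groups.append(SAIRGroup(sair_id, sub, -1, -1, 1.0, members))
    return groups, hits, SAIRTruth(planted)


# ---------------------------------------------------------------- writers
def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_hits_blast6(hits: list[REHit], path) -> None:
    """Emit hits as BLASTN outfmt-6 rows (query = SAIR, subject = element)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.sair_id, h.element_id, "100.00", str(h.length), "0", "0",
                        str(h.start + 1), str(h.end), "1", str(h.length),
                        f"{h.evalue:.2g}", f"{h.score:.1f}",
                    ]
                )
                + "\n"
            )
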