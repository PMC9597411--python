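"""Per-gene subgenome assignment and surviving-gene counts.

Genes are assigned from the per-genome marginal posterior that their track
maps to each subgenome; since every track permutation is a bijection, the
expected counts per genome always sum to that genome's total gene count in
the pillars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import PERMS, HMMResult
from .models import SUBGENOMES
from .pillars import N_TRACKS, PillarSet

__all__ = ["GeneAssignment", "assign_genes", "count_surviving"]


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    genome: str
    pillar_id: int
    track: int
    subgenome: str
    confidence: float


def assign_genes(
    result: HMMResult,
    pillars: PillarSet,
    threshold: float = 0.95,
) -> tuple[list[GeneAssignment], list[GeneAssignment]]:
    """Assign every present gene to its most probable subgenome.

    Returns ``(assigned, low_confidence)``: genes whose marginal posterior
    meets the threshold (>=), and the rest.  Confidence is the per-genome
    marginal P(track -> subgenome), not the joint-state posterior.
    """
    gi = {g: k for k, g in enumerate(result.genomes)}
    assigned: list[GeneAssignment] = []
    low: list[GeneAssignment] = []
    for i, p in enumerate(pillars.pillars):
        for g in result.genomes:
            for t, track in enumerate(p.tracks_for(g)):
                if track is None:
                    continue
                marg = result.track_subgenome[i, gi[g], t]
                s = int(np.argmax(marg))
                rec = GeneAssignment(
                    track.gene_id, g, p.pillar_id, t, SUBGENOMES[s], float(marg[s])
                )
                (assigned if rec.confidence >= threshold else low).append(rec)
    return assigned, low


def count_surviving(
    result: HMMResult, pillars: PillarSet, mode: str = "expected"
) -> pd.DataFrame:
    """Surviving-gene counts per genome and subgenome.

    ``mode="expected"`` sums the marginal posteriors over occupied tracks;
    ``mode="map"`` counts under each pillar's MAP joint state.  Either way a
    genome's row sums to its total gene count in the pillars.
    """
    if mode not in ("expected", "map"):
        raise ValueError("mode must be 'expected' or 'map'")
    gi = {g: k for k, g in enumerate(result.genomes)}
    counts = np.zeros((len(result.genomes), 3))
    for i, p in enumerate(pillars.pillars):
        map_perms = result.state_perms(int(result.map_states[i])) if mode == "map" else None
        for g in result.genomes:
            k = gi[g]
            for t, track in enumerate(p.tracks_for(g)):
                if track is None:
                    continue
                if mode == "expected":
                    counts[k] += result.track_subgenome[i, k, t]
                else:
                    counts[k, map_perms[k][t]] += 1.0
    return pd.DataFrame(counts, index=result.genomes, columns=list(SUBGENOMES))
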