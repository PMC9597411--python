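"""Shared fixtures and independent oracles.

The oracles here (exhaustive path enumeration, quadratic Smith-Waterman DP)
are deliberately written against the mathematical definitions, independent
of the package's vectorised/JIT implementations they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import trifrac as tf
from trifrac.models import TRANSITION_NAMES

ARB_RATES = {
    "rho_T>D_LF.MF": 0.8,
    "rho_T>D_IF.MF": 0.45,
    "rho_D_LF.IF>S_LF": 1.3,
    "rho_D_LF.IF>S_IF": 0.6,
    "rho_D_LF.MF>S_LF": 1.6,
    "rho_D_LF.MF>S_MF": 0.5,
    "rho_D_IF.MF>S_IF": 1.1,
    "rho_D_IF.MF>S_MF": 0.7,
}


def make_pillar(pid: int, presence: dict[str, tuple[int, int, int]]) -> tf.Pillar:
    """Pillar with each track on its own per-genome chromosome, genes laid
    out consecutively so derived adjacency holds within a run of pillars."""
    tracks = {}
    for g, bits in presence.items():
        slots = []
        for t in range(3):
            if bits[t]:
                slots.append(
                    tf.Track(f"{g}_p{pid}_t{t}", f"{g}_c{t}", 1000 * pid, 1000 * pid + 200)
                )
            else:
                slots.append(None)
        tracks[g] = slots
    return tf.Pillar(pid, None, tracks)


def make_pillarset(patterns: list[dict[str, tuple[int, int, int]]]) -> tf.PillarSet:
    genomes = sorted({g for pat in patterns for g in pat})
    ps = tf.PillarSet(
        [tf.Genome(g) for g in genomes],
        [make_pillar(i, pat) for i, pat in enumerate(patterns)],
    )
    ps.derive_adjacency()
    return ps


def arb_model(**extra) -> tf.LossModel:
    return tf.build_model("arb", ARB_RATES, **extra)


def brute_force_loglik(E: np.ndarray, theta: float, n_genomes: int,
                       breaks: np.ndarray | None = None) -> float:
    """ln-likelihood by exhaustive summation over all joint state paths."""
    n, S = E.shape
    K1 = np.full((6, 6), theta / 5.0)
    np.fill_diagonal(K1, 1.0 - theta)
    K = K1
    for _ in range(n_genomes - 1):
        K = np.kron(K, K1)
    if breaks is None:
        breaks = np.zeros(n, dtype=bool)
    total = 0.0
    chunk = 1_000_000
    n_paths = S**n
    for lo in range(0, n_paths, chunk):
        hi = min(lo + chunk, n_paths)
        idx = np.unravel_index(np.arange(lo, hi), (S,) * n)
        p = E[0, idx[0]] / S
        for i in range(1, n):
            step = np.where(breaks[i], 1.0 / S, K[idx[i - 1], idx[i]])
            p = p * step * E[i, idx[i]]
        total += p.sum()
    return float(np.log(total))


def brute_force_posterior(E: np.ndarray, theta: float, n_genomes: int,
                          pillar: int) -> np.ndarray:
    """Posterior over joint states at one pillar by path enumeration."""
    n, S = E.shape
    K1 = np.full((6, 6), theta / 5.0)
    np.fill_diagonal(K1, 1.0 - theta)
    K = K1
    for _ in range(n_genomes - 1):
        K = np.kron(K, K1)
    post = np.zeros(S)
    chunk = 1_000_000
    for lo in range(0, S**n, chunk):
        hi = min(lo + chunk, S**n)
        idx = np.unravel_index(np.arange(lo, hi), (S,) * n)
        p = E[0, idx[0]] / S
        for i in range(1, n):
            p = p * K[idx[i - 1], idx[i]] * E[i, idx[i]]
        post += np.bincount(idx[pillar], weights=p, minlength=S)
    return post / post.sum()


def sw_oracle(q: str, t: str) -> float:
    """Quadratic-space affine-gap Smith-Waterman score (match +4, mismatch
    -5, first gap base -8, extension -4; N mismatches everything)."""
    nq, nt = len(q), len(t)
    NEG = -1e18
    H = np.zeros((nq + 1, nt + 1))
    Eg = np.full((nq + 1, nt + 1), NEG)
    Fg = np.full((nq + 1, nt + 1), NEG)
    best = 0.0
    for i in range(1, nq + 1):
        for j in range(1, nt + 1):
            s = 4.0 if (q[i - 1] == t[j - 1] and q[i - 1] != "N") else -5.0
            Eg[i, j] = max(H[i, j - 1] - 8.0, Eg[i, j - 1] - 4.0)
            Fg[i, j] = max(H[i - 1, j] - 8.0, Fg[i - 1, j] - 4.0)
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, Eg[i, j], Fg[i, j])
            best = max(best, H[i, j])
    return best


@pytest.fixture(scope="session")
def two_genome_tree() -> tf.SpeciesTree:
    return tf.SpeciesTree.from_newick("(A:0.3,B:0.25):0.2;")


@pytest.fixture(scope="session")
def four_genome_tree() -> tf.SpeciesTree:
    return tf.SpeciesTree.from_newick(
        "((tom:0.12,egg:0.10):0.06,(pep:0.14,pet:0.22):0.03):0.35;"
    )


@pytest.fixture(scope="session")
def small_sim(four_genome_tree):
    """A modest 4-genome simulated dataset with posterior decoding."""
    cfg = tf.SimulationConfig(
        tree=four_genome_tree, model=arb_model(), seed=7, n_pillars=400, theta=0.02
    )
    ps, truth = tf.simulate_pillars(cfg)
    res = tf.posterior_decode(
        ps, arb_model(), four_genome_tree, tf.HMMParameters(0.02)
    )
    return ps, truth, res


def all_free_params(family: str) -> dict[str, float]:
    from trifrac.models import free_param_names

    return dict.fromkeys(free_param_names(family), 1.0)
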