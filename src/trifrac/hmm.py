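"""Orthology inference: per-pillar emissions, the HMM over joint track
permutations, posterior decoding and maximum-likelihood fitting.

For each genome a hidden *orthology state* is one of the 3! = 6 ways its
three syntenic tracks can map onto the subgenomes {LF, IF, MF}; jointly the
HMM has 6^n states for n genomes.  A pillar's emission under a joint state
is the phylogenetic likelihood (Felsenstein pruning over the 7 loss states)
of the observed presence/absence pattern, with each genome's leaf vector the
indicator of the loss state implied by which subgenomes its occupied tracks
map to.  Between adjacent pillars each genome keeps its permutation with
probability 1 - theta and switches to each alternative with probability
theta/5 (a synteny break); the chain re-initialises to uniform at contiguity
breaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import _kernels
from .models import (
    LossModel,
    free_param_names,
    loss_flux,
    model_from_vector,
    relabel,
    root_distribution,
    transition_matrix,
)
from .pillars import N_TRACKS, Pillar, PillarSet
from .trees import SpeciesTree

__all__ = [
    "PERMS",
    "HMMParameters",
    "HMMResult",
    "FitResult",
    "EmissionEngine",
    "leaf_state",
    "emission_likelihood",
    "forward_loglik",
    "posterior_decode",
    "fit",
]

MAX_FULL_GENOMES = 5  # 6^5 = 7776 joint states; larger sets are unsupported

#: the 6 track -> subgenome permutations, lexicographic
PERMS = tuple(itertools.permutations(range(3)))
_PERM_ARRAY = np.array(PERMS, dtype=np.int64)

_STATE_OF_SURVIVORS = {
    frozenset({0, 1, 2}): 0,
    frozenset({0, 1}): 1,
    frozenset({0, 2}): 2,
    frozenset({1, 2}): 3,
    frozenset({0}): 4,
    frozenset({1}): 5,
    frozenset({2}): 6,
}


def _leaf_tables() -> tuple[np.ndarray, np.ndarray]:
    """Reduced leaf-vector classes per presence bitmask.

    For a given presence pattern the 6 permutations yield at most 3 distinct
    leaf vectors; LEAF[c] holds them (padded) and EXPAND[c, p] maps each
    permutation to its class.
    """
    leaf = np.zeros((8, 3, 7))
    expand = np.zeros((8, 6), dtype=np.int64)
    for c in range(8):
        tracks = [t for t in range(N_TRACKS) if (c >> t) & 1]
        classes: dict[int, int] = {}
        vecs: list[np.ndarray] = []
        for p_i, perm in enumerate(PERMS):
            if not tracks:
                key = -1
            else:
                key = _STATE_OF_SURVIVORS[frozenset(perm[t] for t in tracks)]
            if key not in classes:
                classes[key] = len(vecs)
                if key == -1:
                    vecs.append(np.ones(7))
                else:
                    v = np.zeros(7)
                    v[key] = 1.0
                    vecs.append(v)
            expand[c, p_i] = classes[key]
        for k in range(3):
            leaf[c, k] = vecs[min(k, len(vecs) - 1)]
    return leaf, expand


_LEAF, _EXPAND = _leaf_tables()

# indicator M[p, t, s] = 1 iff permutation p maps track t to subgenome s
_TRACK_SUB = np.zeros((6, 3, 3))
for _p, _perm in enumerate(PERMS):
    for _t in range(3):
        _TRACK_SUB[_p, _t, _perm[_t]] = 1.0


@dataclass(frozen=True)
class HMMParameters:
    """theta: probability per adjacent pillar pair that a genome's track
    permutation changes (shared across genomes)."""

    theta: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must be in [0, 1)")


def leaf_state(pillar: Pillar, genome: str, permutation: tuple[int, int, int]) -> np.ndarray:
    """Partial-likelihood leaf vector over the 7 loss states.

    The indicator of the unique loss state whose surviving-subgenome set is
    the image of the occupied tracks; an all-empty genome is missing data
    (all-ones vector).
    """
    present = pillar.presence(genome)
    surv = frozenset(permutation[t] for t in range(N_TRACKS) if present[t])
    if not surv:
        return np.ones(7)
    v = np.zeros(7)
    v[_STATE_OF_SURVIVORS[surv]] = 1.0
    return v


def emission_likelihood(
    pillar: Pillar,
    state: tuple[tuple[int, int, int], ...],
    model: LossModel,
    tree: SpeciesTree,
    genome_order: list[str] | None = None,
) -> float:
    """Pruning likelihood of one pillar under one joint orthology state.

    ``state`` gives one permutation per genome, in ``genome_order`` (default:
    tree leaf order).  Plain recursive reference implementation; the
    vectorised :class:`EmissionEngine` must agree with it.
    """
    if genome_order is None:
        genome_order = tree.leaf_names
    perm_of = dict(zip(genome_order, state))

    def cond(node) -> np.ndarray:
        if node.is_leaf:
            below = leaf_state(pillar, node.name, perm_of[node.name])
        else:
            below = np.ones(7)
            for c in node.children:
                below = below * cond(tree.nodes[c])
        P = transition_matrix(model, node.length, root=(node is tree.root))
        return P @ below

    pi = root_distribution(model)
    return float(pi @ cond(tree.root))


class EmissionEngine:
    """Vectorised pillar emissions over all 6^n joint states.

    Pillars are grouped by their joint presence signature (one bitmask per
    genome); emissions are computed once per unique signature with a reduced
    per-genome class axis (<= 3 distinct leaf vectors per genome) and then
    expanded to the full 6^n state axis.
    """

    CHUNK = 2048

    def __init__(self, pillars: PillarSet, tree: SpeciesTree):
        tree.validate_leaves(pillars.genome_names)
        self.genomes = pillars.genome_names
        self.n = len(self.genomes)
        if self.n > MAX_FULL_GENOMES:
            raise NotImplementedError(
                f"full 6^n state enumeration supports at most {MAX_FULL_GENOMES} genomes"
            )
        self.n_states = 6**self.n
        self.tree = tree
        gi = {g: i for i, g in enumerate(self.genomes)}
        codes = np.zeros((len(pillars), self.n), dtype=np.int64)
        for i, p in enumerate(pillars.pillars):
            for g in self.genomes:
                mask = 0
                for t, occupied in enumerate(p.presence(g)):
                    if occupied:
                        mask |= 1 << t
                codes[i, gi[g]] = mask
        self.unique, self.inverse = np.unique(codes, axis=0, return_inverse=True)
        self.breaks = np.zeros(len(pillars), dtype=np.bool_)
        for b in pillars.breaks:
            if 0 < b < len(pillars):
                self.breaks[b] = True
        self._leaf_genome = {
            node.index: gi[node.name] for node in tree.nodes if node.is_leaf
        }
        # joint state -> reduced leaf-class index, per unique presence pattern
        U = len(self.unique)
        self.n_reduced = 3**self.n
        idx = np.zeros((U,) + (6,) * self.n, dtype=np.int32)
        for g in range(self.n):
            shape = (U,) + tuple(6 if k == g else 1 for k in range(self.n))
            idx = idx + (
                _EXPAND[self.unique[:, g]].reshape(shape) * 3 ** (self.n - 1 - g)
            ).astype(np.int32)
        self.reduced_index = np.ascontiguousarray(idx.reshape(U, self.n_states))

    def _branch_matrices(self, model: LossModel, u: np.ndarray | None) -> list[np.ndarray]:
        tree = self.tree if u is None else self.tree.with_branch_lengths(u)
        return [
            transition_matrix(model, node.length, root=(node.index == tree.root.index))
            for node in tree.nodes
        ]

    def emissions_reduced(
        self, model: LossModel, u: np.ndarray | None = None
    ) -> np.ndarray:
        """(U, 3^n) emissions over the reduced per-genome leaf classes."""
        return self.emissions_reduced_batch([(model, u)])[0]

    def emissions_reduced_batch(
        self, models: list[tuple[LossModel, np.ndarray | None]]
    ) -> np.ndarray:
        """(B, U, 3^n) reduced emissions for a batch of (model, lengths)."""
        B = len(models)
        Ps = np.empty((B, len(self.tree.nodes), 7, 7))
        r = np.empty((B, 7))
        for b, (model, u) in enumerate(models):
            mats = self._branch_matrices(model, u)
            for k, P in enumerate(mats):
                Ps[b, k] = P
            r[b] = root_distribution(model) @ mats[self.tree.root.index]
        U = len(self.unique)
        out = np.empty((B, U, self.n_reduced))
        for lo in range(0, U, self.CHUNK):
            hi = min(lo + self.CHUNK, U)
            out[:, lo:hi, :] = self._emit_chunk(self.unique[lo:hi], Ps, r)
        return out

    def emissions(self, model: LossModel, u: np.ndarray | None = None) -> np.ndarray:
        """(U, 6^n) emission matrix for the unique presence signatures."""
        red = self.emissions_reduced(model, u)
        return np.take_along_axis(red, self.reduced_index, axis=1)

    def _emit_chunk(self, codes: np.ndarray, Ps: np.ndarray, r: np.ndarray) -> np.ndarray:
        """(B, C, 3^n) reduced emissions for one chunk of patterns."""
        B = Ps.shape[0]
        C = codes.shape[0]

        def up(arr: np.ndarray, node_index: int) -> np.ndarray:
            shape = arr.shape
            flat = arr.reshape(B, -1, 7)
            res = np.matmul(flat, np.transpose(Ps[:, node_index], (0, 2, 1)))
            return res.reshape(shape)

        def prune(node) -> tuple[np.ndarray, list[int]]:
            if node.is_leaf:
                g = self._leaf_genome[node.index]
                A = np.broadcast_to(_LEAF[codes[:, g]], (B, C, 3, 7))
                return up(A, node.index), [g]
            arrs, orders = zip(*(prune(self.tree.nodes[c]) for c in node.children))
            k_total = sum(len(o) for o in orders)
            prod = None
            seen = 0
            for arr, order in zip(arrs, orders):
                k = len(order)
                shape = (
                    (B, C) + (1,) * seen + arr.shape[2:-1] + (1,) * (k_total - seen - k) + (7,)
                )
                arr = arr.reshape(shape)
                prod = arr if prod is None else prod * arr
                seen += k
            order = [g for o in orders for g in o]
            if node.index == self.tree.root.index:
                return prod, order  # stem handled via the root prior r
            return up(prod, node.index), order

        root = self.tree.root
        if len(root.children) == 2:
            # contract the root prior early: em = sum_k A_ik r_k B_jk
            (arr_a, ord_a), (arr_b, ord_b) = (
                prune(self.tree.nodes[c]) for c in root.children
            )
            ka = int(np.prod(arr_a.shape[2:-1]))
            kb = int(np.prod(arr_b.shape[2:-1]))
            r_bc = r.reshape((B,) + (1,) * (arr_a.ndim - 2) + (7,))
            a_flat = (arr_a * r_bc).reshape(B * C, ka, 7)
            b_flat = arr_b.reshape(B * C, kb, 7)
            red = np.matmul(a_flat, np.transpose(b_flat, (0, 2, 1)))
            red = red.reshape((B, C) + (3,) * self.n)
            order = ord_a + ord_b
        else:
            red, order = prune(root)
            red = np.matmul(red.reshape(B, -1, 7), r[:, :, None]).reshape(
                (B, C) + (3,) * self.n
            )
        # genome axes into canonical order
        axes = [0, 1] + [2 + order.index(g) for g in range(self.n)]
        red = np.transpose(red, axes)
        return red.reshape(B, C, self.n_reduced)


@dataclass
class HMMResult:
    """Posterior decoding of the orthology HMM."""

    loglik: float
    genomes: list[str]
    map_states: np.ndarray  # (n,) joint state index, lexicographic tie-break
    map_posterior: np.ndarray  # (n,)
    perm_marginals: np.ndarray  # (n, n_genomes, 6)
    track_subgenome: np.ndarray  # (n, n_genomes, 3, 3): P(track t -> subgenome s)
    sparse: list[dict[int, float]]  # per pillar, joint states above the floor

    def state_perms(self, state_index: int) -> tuple[tuple[int, int, int], ...]:
        """Decode a joint state index into one permutation per genome."""
        n = len(self.genomes)
        out = []
        for g in range(n):
            digit = (state_index // 6 ** (n - 1 - g)) % 6
            out.append(PERMS[digit])
        return tuple(out)


def _prepare(pillars: PillarSet, tree: SpeciesTree) -> EmissionEngine:
    return EmissionEngine(pillars, tree)


def forward_loglik(
    pillars: PillarSet,
    model: LossModel,
    tree: SpeciesTree,
    hmm: HMMParameters,
    engine: EmissionEngine | None = None,
) -> float:
    """Total ln-likelihood of the pillar data under the joint HMM."""
    eng = engine or _prepare(pillars, tree)
    em = eng.emissions(model)
    return float(
        _kernels.forward_ll(em, eng.inverse, eng.breaks, hmm.theta, eng.n)
    )


def posterior_decode(
    pillars: PillarSet,
    model: LossModel,
    tree: SpeciesTree,
    hmm: HMMParameters,
    floor: float = 1e-6,
    engine: EmissionEngine | None = None,
) -> HMMResult:
    """Forward-backward posteriors, MAP states and per-genome marginals."""
    eng = engine or _prepare(pillars, tree)
    em = eng.emissions(model)
    ll, gamma = _kernels.forward_backward(em, eng.inverse, eng.breaks, hmm.theta, eng.n)
    n = gamma.shape[0]
    map_states = np.argmax(gamma, axis=1)
    map_post = gamma[np.arange(n), map_states]
    shaped = gamma.reshape((n,) + (6,) * eng.n)
    marg = np.empty((n, eng.n, 6))
    for g in range(eng.n):
        axes = tuple(1 + k for k in range(eng.n) if k != g)
        marg[:, g, :] = shaped.sum(axis=axes)
    track_sub = np.einsum("ngp,pts->ngts", marg, _TRACK_SUB)
    sparse = []
    for i in range(n):
        keep = np.nonzero(gamma[i] >= floor)[0]
        sparse.append({int(s): float(gamma[i, s]) for s in keep})
    return HMMResult(
        float(ll), list(eng.genomes), map_states, map_post, marg, track_sub, sparse
    )


def write_posteriors(result: HMMResult, path) -> None:
    """TSV posterior table: MAP state plus all joint states above the floor."""
    with open(path, "w") as fh:
        fh.write(f"#loglik\t{result.loglik:.10g}\n")
        fh.write("#genomes\t" + ",".join(result.genomes) + "\n")
        fh.write("index\tmap_state\tmap_posterior\tstates\n")
        for i in range(len(result.map_states)):
            cell = ";".join(
                f"{s}:{p:.10g}" for s, p in sorted(result.sparse[i].items())
            )
            fh.write(
                f"{i}\t{int(result.map_states[i])}\t{result.map_posterior[i]:.10g}\t{cell}\n"
            )


def read_posteriors(path) -> tuple[float, list[str], np.ndarray, np.ndarray, list[dict[int, float]]]:
    """Inverse of :func:`write_posteriors` (loglik, genomes, map, map_p, sparse)."""
    loglik = np.nan
    genomes: list[str] = []
    maps, map_p, sparse = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#loglik"):
                loglik = float(line.split("\t")[1])
            elif line.startswith("#genomes"):
                genomes = line.rstrip("\n").split("\t")[1].split(",")
            elif line.startswith("index"):
                continue
            else:
                idx, ms, mp, cell = line.rstrip("\n").split("\t")
                maps.append(int(ms))
                map_p.append(float(mp))
                sparse.append(
                    {
                        int(kv.split(":")[0]): float(kv.split(":")[1])
                        for kv in cell.split(";")
                        if kv
                    }
                )
    return float(loglik), genomes, np.array(maps), np.array(map_p), sparse


@dataclass
class FitResult:
    model: LossModel
    tree: SpeciesTree
    hmm: HMMParameters
    loglik: float
    converged: bool
    n_iterations: int
    n_starts: int
    family: str
    arrival_last: str | None = None
    root_variant: bool = False

    def free_parameters(self) -> int:
        from .models import count_free_parameters

        return count_free_parameters(self.model)


_U_BOUNDS = (np.log(1e-4), np.log(20.0))
_RATE_BOUNDS = (np.log(1e-3), np.log(1e3))
_TAU_BOUNDS = (np.log(1e-4), np.log(10.0))
_THETA_BOUNDS = (logit(1e-5), logit(0.5))


def fit(
    pillars: PillarSet,
    family: str,
    tree: SpeciesTree,
    arrival_last: str | None = None,
    root_variant: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    maxfun: int = 4000,
    ftol: float = 1e-8,
    standardize: bool = True,
    engine: EmissionEngine | None = None,
    init: dict | None = None,
) -> FitResult:
    """Maximise the HMM likelihood over branch lengths, loss rates and theta.

    Bounded quasi-Newton (L-BFGS-B) on log-transformed rates and branch
    lengths (logit for theta), with ``n_starts`` seeded starts: a neutral
    default plus random log-normal perturbations, guarding against the
    label-switching multimodality of the likelihood surface.  For arb-family
    fits the labels are standardised afterwards: the subgenome with the
    lowest total loss flux becomes LF, the highest MF, and rates are
    renormalised so the T->D_LF.IF rate is 1 (branch lengths absorb the
    scale).
    """
    eng = engine or _prepare(pillars, tree)
    nb = tree.n_branches
    rate_names = free_param_names(family, arrival=arrival_last is not None, root_variant=root_variant)
    nr = len(rate_names)

    def unpack(x):
        u = np.exp(x[:nb])
        vals = np.exp(x[nb : nb + nr])
        theta = float(expit(x[-1]))
        model = model_from_vector(family, vals, arrival_last, root_variant)
        return model, u, theta

    npar = nb + nr + 1
    fd_step = 1e-6

    def objective(x):
        """Value and forward-difference gradient, one batched likelihood pass."""
        X = np.repeat(x[None, :], npar + 1, axis=0)
        X[1:] += np.eye(npar) * fd_step
        batch = []
        thetas = np.empty(npar + 1)
        for b in range(npar + 1):
            model, u, theta = unpack(X[b])
            batch.append((model, u))
            thetas[b] = theta
        red = eng.emissions_reduced_batch(batch)
        ll = _kernels.forward_ll_batch(
            red, eng.reduced_index, eng.inverse, eng.breaks, thetas, eng.n
        )
        if not np.isfinite(ll[0]):
            return 1e12, np.zeros(npar)
        grad = -(ll[1:] - ll[0]) / fd_step
        grad[~np.isfinite(grad)] = 0.0
        return -float(ll[0]), grad

    init = init or {}
    u0 = np.asarray(init.get("u", np.full(nb, 0.3)), dtype=float)
    rates0 = [
        float(init.get(name, 0.05 if name == "tau" else 1.0)) for name in rate_names
    ]
    theta0 = float(init.get("theta", 0.02))
    x0 = np.concatenate([np.log(u0), np.log(rates0), [logit(theta0)]])
    bounds = (
        [_U_BOUNDS] * nb
        + [(_TAU_BOUNDS if name == "tau" else _RATE_BOUNDS) for name in rate_names]
        + [_THETA_BOUNDS]
    )
    rng = np.random.default_rng(seed)
    best = None
    total_iter = 0
    for s in range(max(1, n_starts)):
        start = x0 if s == 0 else x0 + rng.normal(0.0, 0.7, size=x0.shape)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxfun": maxfun, "ftol": ftol},
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    model, u, theta = unpack(best.x)
    loglik = -best.fun
    if standardize and family == "arb":
        model, u = _standardize_labels(model, u)
    fitted_tree = tree.with_branch_lengths(u)
    return FitResult(
        model,
        fitted_tree,
        HMMParameters(theta),
        float(loglik),
        bool(best.success),
        int(total_iter),
        max(1, n_starts),
        family,
        arrival_last,
        root_variant,
    )


def init_from_fit(
    res: FitResult,
    family: str,
    arrival_last: str | None = None,
    root_variant: bool = False,
) -> dict:
    """Warm-start dictionary for a richer model from a completed fit.

    Shared parameters carry over; parameters new to the richer family start
    at their neutral values (rates 1, a short tetraploid phase for tau), so
    the staged fit begins at (essentially) the simpler model's optimum.
    """
    from .models import TRANSITION_NAMES

    init: dict = {"u": res.tree.branch_lengths(), "theta": res.hmm.theta}
    src = res.model.params or {}
    for name in free_param_names(family, arrival_last is not None, root_variant):
        if name in src:
            init[name] = float(src[name])
        elif name.startswith("root_rho_"):
            tn = name[len("root_rho_") :]
            source = res.model.root_rho or res.model.rho
            init[name] = float(source[TRANSITION_NAMES.index(tn)])
        elif name.startswith("rho_"):
            init[name] = float(res.model.rho[TRANSITION_NAMES.index(name[4:])])
        elif name == "sigma":
            init[name] = float(np.mean(res.model.rho[3:]))
    return init


def _standardize_labels(model: LossModel, u: np.ndarray) -> tuple[LossModel, np.ndarray]:
    """Relabel so LF has the lowest loss flux, then renormalise rho[0] to 1."""
    flux = loss_flux(model.rho)
    order = np.argsort(flux, kind="stable")
    perm = [0, 0, 0]
    for new, old in enumerate(order):
        perm[old] = new
    model = relabel(model, tuple(perm))
    c = model.rho[0]
    if c > 0 and not np.isclose(c, 1.0):
        rho = tuple(r / c for r in model.rho)
        root_rho = (
            tuple(r / c for r in model.root_rho) if model.root_rho is not None else None
        )
        arrival = model.arrival
        if arrival is not None:
            from dataclasses import replace

            arrival = replace(arrival, tau=arrival.tau * c)
        model = LossModel(model.family, rho, None, arrival, root_rho)
        u = u * c
    return model, u
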