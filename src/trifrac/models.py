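"""Continuous-time Markov models of homoeologue loss after a triplication.

State space (7 states)::

    T          all three homoeologues survive
    D_LF.IF    the MF copy has been lost, LF and IF survive
    D_LF.MF    the IF copy has been lost
    D_IF.MF    the LF copy has been lost
    S_LF       only the LF copy survives          (absorbing)
    S_IF       only the IF copy survives          (absorbing)
    S_MF       only the MF copy survives          (absorbing)

Nine loss transitions are possible (3 from T, 2 from each D state).  All
rates are *relative*: the base loss rate alpha is absorbed into the branch
lengths u = alpha*t, and the rate of T -> D_LF.IF is the unit.

Model families, from simplest to richest:

``null``  one shared T->D rate (1) and one shared D->S rate sigma; the
          subgenomes are exchangeable and cannot be told apart.
``1d``    one subgenome (LF) may be lost at its own rates: f_T scales the
          T->D transition that removes the LF copy, f_D scales the two D->S
          transitions that remove it.
``3g``    additionally distinguishes IF from MF via the analogous pair
          (g_T, g_D) on transitions that remove the IF copy.
``arb``   every one of the 9 transitions has its own rate (8 free).

Each family nests in the next, so likelihood-ratio tests between
consecutive fits have 2, 2 and 3 degrees of freedom.

*Arrival* variants model the two-step origin of a hexaploid: two founder
subgenomes first form a tetraploid that evolves for a phase of length tau
(in u units, D->S rates scaled by kappa) before the last-arriving subgenome
joins; the second merger is instantaneous.  Arrival adds 2 free parameters.
The *root variant* gives the root (stem) branch its own full set of 9
relative rates (8 extra parameters), which lets the preference among T->D
transitions differ between the immediate post-triplication period and the
later branches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm

__all__ = [
    "STATE_NAMES",
    "SUBGENOMES",
    "TRANSITIONS",
    "TRANSITION_NAMES",
    "FAMILIES",
    "Arrival",
    "LossModel",
    "build_model",
    "free_param_names",
    "model_from_vector",
    "count_free_parameters",
    "rate_matrix",
    "transition_matrix",
    "root_distribution",
    "loss_flux",
    "relabel",
]

SUBGENOMES = ("LF", "IF", "MF")
STATE_NAMES = ("T", "D_LF.IF", "D_LF.MF", "D_IF.MF", "S_LF", "S_IF", "S_MF")
N_STATES = 7

#: (from_state, to_state, lost_subgenome_index)
TRANSITIONS = (
    (0, 1, 2),  # T -> D_LF.IF        loses MF
    (0, 2, 1),  # T -> D_LF.MF        loses IF
    (0, 3, 0),  # T -> D_IF.MF        loses LF
    (1, 4, 1),  # D_LF.IF -> S_LF     loses IF
    (1, 5, 0),  # D_LF.IF -> S_IF     loses LF
    (2, 4, 2),  # D_LF.MF -> S_LF     loses MF
    (2, 6, 0),  # D_LF.MF -> S_MF     loses LF
    (3, 5, 2),  # D_IF.MF -> S_IF     loses MF
    (3, 6, 1),  # D_IF.MF -> S_MF     loses IF
)
TRANSITION_NAMES = tuple(
    f"{STATE_NAMES[a]}>{STATE_NAMES[b]}" for a, b, _ in TRANSITIONS
)

FAMILIES = ("null", "1d", "3g", "arb")
_FAMILY_PARAMS = {
    "null": ("sigma",),
    "1d": ("sigma", "f_T", "f_D"),
    "3g": ("sigma", "f_T", "f_D", "g_T", "g_D"),
    "arb": tuple(f"rho_{name}" for name in TRANSITION_NAMES[1:]),
}

# survivor sets per state, used for consistent relabeling
_STATE_SURVIVORS = (
    frozenset({0, 1, 2}),
    frozenset({0, 1}),
    frozenset({0, 2}),
    frozenset({1, 2}),
    frozenset({0}),
    frozenset({1}),
    frozenset({2}),
)


@dataclass(frozen=True)
class Arrival:
    """Two-step hexaploid formation: ``last`` joins after a tetraploid phase."""

    last: str  # "LF" | "IF" | "MF"
    tau: float  # tetraploid-phase length in u = alpha*t units
    kappa: float = 1.0  # loss-rate modifier during the phase

    def __post_init__(self) -> None:
        if self.last not in SUBGENOMES:
            raise ValueError(f"unknown subgenome {self.last!r}")
        if self.tau < 0 or self.kappa < 0:
            raise ValueError("tau and kappa must be >= 0")


@dataclass(frozen=True)
class LossModel:
    family: str
    rho: tuple[float, ...]  # 9 materialised relative rates, TRANSITIONS order
    params: dict | None = None  # the family's free parameters by name
    arrival: Arrival | None = None
    root_rho: tuple[float, ...] | None = None  # separate rates on the stem

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.rho) != len(TRANSITIONS):
            raise ValueError("rho must have 9 entries")
        if any(r < 0 for r in self.rho):
            raise ValueError("negative relative rate")
        if self.root_rho is not None:
            if self.family != "arb":
                raise ValueError("root_variant is only defined for the arb family")
            if len(self.root_rho) != len(TRANSITIONS) or any(r < 0 for r in self.root_rho):
                raise ValueError("invalid root-branch rate set")

    @property
    def has_root_variant(self) -> bool:
        return self.root_rho is not None


def _materialise(family: str, params: dict) -> tuple[float, ...]:
    missing = [k for k in _FAMILY_PARAMS[family] if k not in params]
    if missing:
        raise ValueError(f"family {family!r} missing parameters {missing}")
    s = params.get("sigma", 1.0)
    if family == "null":
        f_T = f_D = g_T = g_D = 1.0
    elif family == "1d":
        f_T, f_D = params["f_T"], params["f_D"]
        g_T = g_D = 1.0
    elif family == "3g":
        f_T, f_D = params["f_T"], params["f_D"]
        g_T, g_D = params["g_T"], params["g_D"]
    else:  # arb
        return (1.0,) + tuple(float(params[f"rho_{n}"]) for n in TRANSITION_NAMES[1:])
    return (
        1.0,  # T > D_LF.IF
        g_T,  # T > D_LF.MF   (loses IF)
        f_T,  # T > D_IF.MF   (loses LF)
        s * g_D,  # D_LF.IF > S_LF (loses IF)
        s * f_D,  # D_LF.IF > S_IF (loses LF)
        s,  # D_LF.MF > S_LF (loses MF)
        s * f_D,  # D_LF.MF > S_MF (loses LF)
        s,  # D_IF.MF > S_IF (loses MF)
        s * g_D,  # D_IF.MF > S_MF (loses IF)
    )


def build_model(
    family: str,
    params: dict,
    arrival: Arrival | None = None,
    root_params: dict | None = None,
) -> LossModel:
    """Materialise a loss model from its family's free parameters.

    ``root_params`` (arb only) gives the stem branch its own rate set; its
    keys follow the arb layout.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    rho = _materialise(family, params)
    root_rho = None
    if root_params is not None:
        if family != "arb":
            raise ValueError("root_variant is only defined for the arb family")
        root_rho = _materialise("arb", root_params)
    return LossModel(family, rho, dict(params), arrival, root_rho)


def free_param_names(
    family: str, arrival: bool = False, root_variant: bool = False
) -> tuple[str, ...]:
    names = _FAMILY_PARAMS[family]
    if root_variant:
        if family != "arb":
            raise ValueError("root_variant is only defined for the arb family")
        names = names + tuple(f"root_{n}" for n in _FAMILY_PARAMS["arb"])
    if arrival:
        names = names + ("tau", "kappa")
    return names


def model_from_vector(
    family: str,
    values,
    arrival_last: str | None = None,
    root_variant: bool = False,
) -> LossModel:
    """Build a model from a flat vector laid out as ``free_param_names``."""
    names = free_param_names(family, arrival=arrival_last is not None, root_variant=root_variant)
    if len(values) != len(names):
        raise ValueError(f"expected {len(names)} values, got {len(values)}")
    d = dict(zip(names, (float(v) for v in values)))
    arrival = None
    if arrival_last is not None:
        arrival = Arrival(arrival_last, d.pop("tau"), d.pop("kappa"))
    root_params = None
    if root_variant:
        root_params = {k[len("root_") :]: d.pop(k) for k in list(d) if k.startswith("root_")}
    return build_model(family, d, arrival, root_params)


def count_free_parameters(model: LossModel) -> int:
    """Independently estimable rate parameters, with rho(T>D_LF.IF) := 1.

    Branch lengths and the HMM synteny-break rate are not counted.
    """
    n = len(_FAMILY_PARAMS[model.family])
    if model.arrival is not None:
        n += 2
    if model.root_rho is not None:
        n += len(_FAMILY_PARAMS["arb"])
    return n


def rate_matrix(model: LossModel, root: bool = False) -> np.ndarray:
    """7x7 generator Q; upper triangular, absorbing S rows all zero."""
    rho = model.root_rho if (root and model.root_rho is not None) else model.rho
    Q = np.zeros((N_STATES, N_STATES))
    for (a, b, _), r in zip(TRANSITIONS, rho):
        Q[a, b] = r
    Q[np.diag_indices(N_STATES)] = -Q.sum(axis=1)
    return Q


def transition_matrix(model: LossModel, u: float, root: bool = False) -> np.ndarray:
    """P(u) = exp(Q u) for a branch of length u (alpha*t units)."""
    if u < 0:
        raise ValueError("branch length must be >= 0")
    P = expm(rate_matrix(model, root=root) * u)
    np.clip(P, 0.0, 1.0, out=P)
    # renormalise away round-off so rows are exactly stochastic
    P /= P.sum(axis=1, keepdims=True)
    return P


def root_distribution(model: LossModel) -> np.ndarray:
    """State distribution at the polyploidy event, before the stem branch.

    Without an arrival scenario every pillar starts triplicated.  With one,
    the two founder subgenomes evolve as a duplicated pair for the
    tetraploid phase (length tau, rates scaled by kappa); the second merger
    then maps the surviving founder states onto the 7-state space:
    D(founders) -> T and S(founder) -> D(founder, last).
    """
    pi = np.zeros(N_STATES)
    if model.arrival is None:
        pi[0] = 1.0
        return pi
    last = SUBGENOMES.index(model.arrival.last)
    founders = tuple(i for i in range(3) if i != last)
    d_state = _STATE_SURVIVORS.index(frozenset(founders))
    rho = model.root_rho if model.root_rho is not None else model.rho
    # loss rates out of the founder-pair duplicated state, per lost founder
    rates = {}
    for (a, b, lost), r in zip(TRANSITIONS, rho):
        if a == d_state:
            surviving = next(iter(_STATE_SURVIVORS[b]))
            rates[surviving] = r * model.arrival.kappa
    total = sum(rates.values())
    tau = model.arrival.tau
    p_stay = np.exp(-total * tau) if total > 0 else 1.0
    pi[0] = p_stay
    for f in founders:
        p_f = (rates[f] / total) * (1.0 - p_stay) if total > 0 else 0.0
        pi[_STATE_SURVIVORS.index(frozenset({f, last}))] = p_f
    return pi


def loss_flux(rho) -> np.ndarray:
    """Total relative loss rate borne by each subgenome (LF, IF, MF order)."""
    flux = np.zeros(3)
    for (_, _, lost), r in zip(TRANSITIONS, rho):
        flux[lost] += r
    return flux


def relabel(model: LossModel, perm: tuple[int, int, int]) -> LossModel:
    """Consistently relabel subgenomes: old index i becomes ``perm[i]``.

    Used both for post-hoc naming (lowest loss flux -> LF) and for the
    label-symmetry property of the likelihood.
    """

    def permute(rho):
        new = [0.0] * len(TRANSITIONS)
        for (a, b, _), r in zip(TRANSITIONS, rho):
            na = _STATE_SURVIVORS.index(frozenset(perm[i] for i in _STATE_SURVIVORS[a]))
            nb = _STATE_SURVIVORS.index(frozenset(perm[i] for i in _STATE_SURVIVORS[b]))
            idx = next(
                k for k, (x, y, _) in enumerate(TRANSITIONS) if (x, y) == (na, nb)
            )
            new[idx] = r
        return tuple(new)

    arrival = model.arrival
    if arrival is not None:
        arrival = replace(arrival, last=SUBGENOMES[perm[SUBGENOMES.index(arrival.last)]])
    return LossModel(
        model.family,
        permute(model.rho),
        None,
        arrival,
        permute(model.root_rho) if model.root_rho is not None else None,
    )


def model_to_dict(model: LossModel) -> dict:
    """Plain-dict form of a model (YAML/JSON-friendly)."""
    d: dict = {
        "family": model.family,
        "rho": {name: float(r) for name, r in zip(TRANSITION_NAMES, model.rho)},
    }
    if model.params:
        d["params"] = {k: float(v) for k, v in model.params.items()}
    if model.arrival is not None:
        d["arrival"] = {
            "last": model.arrival.last,
            "tau": float(model.arrival.tau),
            "kappa": float(model.arrival.kappa),
        }
    if model.root_rho is not None:
        d["root_rho"] = {
            name: float(r) for name, r in zip(TRANSITION_NAMES, model.root_rho)
        }
    return d


def model_from_dict(d: dict) -> LossModel:
    arrival = None
    if "arrival" in d:
        a = d["arrival"]
        arrival = Arrival(a["last"], float(a["tau"]), float(a.get("kappa", 1.0)))
    rho = tuple(float(d["rho"][name]) for name in TRANSITION_NAMES)
    root_rho = None
    if "root_rho" in d:
        root_rho = tuple(float(d["root_rho"][name]) for name in TRANSITION_NAMES)
    return LossModel(d["family"], rho, d.get("params"), arrival, root_rho)


def write_rates_tsv(model: LossModel, path) -> None:
    """Flat TSV of named relative rates (plus arrival/root entries)."""
    with open(path, "w") as fh:
        fh.write("parameter\tvalue\n")
        fh.write(f"family\t{model.family}\n")
        for name, r in zip(TRANSITION_NAMES, model.rho):
            fh.write(f"{name}\t{r:.10g}\n")
        if model.arrival is not None:
            fh.write(f"arrival_last\t{model.arrival.last}\n")
            fh.write(f"tau\t{model.arrival.tau:.10g}\n")
            fh.write(f"kappa\t{model.arrival.kappa:.10g}\n")
        if model.root_rho is not None:
            for name, r in zip(TRANSITION_NAMES, model.root_rho):
                fh.write(f"root:{name}\t{r:.10g}\n")


def state_permutation(perm: tuple[int, int, int]) -> np.ndarray:
    """Index map on the 7 states induced by a subgenome relabeling."""
    out = np.empty(N_STATES, dtype=np.int64)
    for s, surv in enumerate(_STATE_SURVIVORS):
        out[s] = _STATE_SURVIVORS.index(frozenset(perm[i] for i in surv))
    return out
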