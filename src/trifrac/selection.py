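"""Model selection: nested likelihood-ratio tests, rooted-topology
comparison, and the subgenome arrival-order analysis.

The model families form a nested chain (null < 1d < 3g < arb) and the two
structural extensions (arrival phase, root-branch rate set) each nest the
plain model they extend, so twice the log-likelihood gain is compared to a
chi-square with the difference in free rate parameters as degrees of
freedom.  Arrival models place tau on the boundary of its range under the
null; the chi-square reference is used regardless and the boundary issue is
flagged in the result rather than corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .hmm import FitResult, fit, init_from_fit
from .models import SUBGENOMES, count_free_parameters
from .pillars import PillarSet
from .trees import SpeciesTree

__all__ = [
    "LRTResult",
    "ArrivalComparison",
    "lrt",
    "compare_topologies",
    "compare_arrival_models",
    "root_branch_contrast",
]

COLLAPSE_TOL = 1e-3  # |delta lnL| below this is a structural collapse
_FAMILY_ORDER = {"null": 0, "1d": 1, "3g": 2, "arb": 3}


@dataclass(frozen=True)
class LRTResult:
    lnl_null: float
    lnl_alt: float
    statistic: float
    df: int
    p_value: float
    boundary_note: str | None = None


def _is_nested(a: FitResult, b: FitResult) -> bool:
    """True if a's model is nested within b's."""
    if a.arrival_last is not None and b.arrival_last != a.arrival_last:
        return False
    if a.root_variant and not b.root_variant:
        return False
    if _FAMILY_ORDER[a.family] > _FAMILY_ORDER[b.family]:
        return False
    return count_free_parameters(a.model) < count_free_parameters(b.model)


def lrt(fit_null: FitResult, fit_alt: FitResult) -> LRTResult:
    """Likelihood-ratio test of a nested pair of fits on the same data."""
    if not _is_nested(fit_null, fit_alt):
        raise ValueError(
            f"{fit_null.family}(arrival={fit_null.arrival_last}, root={fit_null.root_variant}) "
            f"is not nested in {fit_alt.family}(arrival={fit_alt.arrival_last}, "
            f"root={fit_alt.root_variant})"
        )
    df = count_free_parameters(fit_alt.model) - count_free_parameters(fit_null.model)
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < 0:
        warnings.warn(
            f"negative LRT statistic {stat:.3g} clipped to 0 (optimizer tolerance)"
        )
        stat = 0.0
    note = None
    if fit_alt.arrival_last is not None and fit_null.arrival_last is None:
        note = (
            "tau lies on the boundary of its range under the null; the "
            "chi-square reference is conservative here"
        )
    return LRTResult(fit_null.loglik, fit_alt.loglik, stat, df, float(chi2.sf(stat, df)), note)


def compare_topologies(
    pillars: PillarSet,
    topologies: list[SpeciesTree],
    family: str = "arb",
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit each candidate rooted topology independently; rank by lnL.

    Returns a DataFrame (newick, lnL, delta_lnl, converged) sorted by lnL
    descending; the input order does not influence the ranking.
    """
    if len(topologies) < 2:
        raise ValueError("need at least two topologies to compare")
    leafsets = {tuple(sorted(t.leaf_names)) for t in topologies}
    if len(leafsets) != 1:
        raise ValueError("topologies have mismatched leaf sets")
    rows = []
    for i, tree in enumerate(topologies):
        res = fit(pillars, family, tree, **fit_kwargs)
        rows.append(
            {
                "input_index": i,
                "newick": tree.to_newick(),
                "lnl": res.loglik,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("lnl", ascending=False, ignore_index=True)
    table["delta_lnl"] = table["lnl"].max() - table["lnl"]
    return table


@dataclass
class ArrivalComparison:
    """Arrival-order analysis: which subgenome joined the polyploid last.

    The arrival family is symmetric under consistent subgenome relabeling,
    so the three nominal candidates are three labeled modes of one model;
    an optimizer started in one mode can migrate to another with permuted
    rates.  Each fitted candidate is therefore *canonicalised* (labels
    re-anchored by loss flux: lowest -> LF, highest -> MF) and judged by
    its effective last-arriving subgenome, recorded in ``effective_last``.
    """

    arb: FitResult
    candidates: dict[str, FitResult] = field(default_factory=dict)
    lrts: dict[str, LRTResult] = field(default_factory=dict)
    collapsed: dict[str, bool] = field(default_factory=dict)
    effective_last: dict[str, str] = field(default_factory=dict)

    @property
    def best_last(self) -> str:
        """Effective last-arriving subgenome of the best-likelihood candidate
        (equivalent-complexity candidates compared by raw likelihood)."""
        best = max(self.candidates, key=lambda k: self.candidates[k].loglik)
        return self.effective_last[best]

    def ranking(self) -> list[str]:
        return sorted(self.candidates, key=lambda k: -self.candidates[k].loglik)


def compare_arrival_models(
    pillars: PillarSet,
    tree: SpeciesTree,
    arb_fit: FitResult | None = None,
    **fit_kwargs,
) -> ArrivalComparison:
    """Fit the three last-arriving-subgenome variants of the arb model.

    Each candidate is tested against plain arb by a 2-d.f. LRT; a candidate
    whose likelihood gain is below ``COLLAPSE_TOL`` has collapsed back into
    the arb model (its tetraploid phase fits at zero length).
    """
    if arb_fit is None:
        arb_fit = fit(pillars, "arb", tree, **fit_kwargs)
    cmp = ArrivalComparison(arb=arb_fit)
    for last in SUBGENOMES:
        res = fit(
            pillars,
            "arb",
            tree,
            arrival_last=last,
            standardize=False,
            init=init_from_fit(arb_fit, "arb", arrival_last=last),
            **fit_kwargs,
        )
        cmp.candidates[last] = res
        cmp.lrts[last] = lrt(arb_fit, res)
        cmp.collapsed[last] = abs(res.loglik - arb_fit.loglik) < COLLAPSE_TOL
        cmp.effective_last[last] = _effective_last(res)
    return cmp


def _effective_last(res: FitResult) -> str:
    """Arrival label after canonicalising subgenomes by loss flux."""
    from .models import loss_flux

    flux = np.asarray(loss_flux(res.model.rho))
    order = np.argsort(flux, kind="stable")
    perm = [0, 0, 0]
    for new, old in enumerate(order):
        perm[old] = new
    return SUBGENOMES[perm[SUBGENOMES.index(res.arrival_last)]]


@dataclass(frozen=True)
class RootBranchContrast:
    root_order: tuple[str, ...]
    later_order: tuple[str, ...]
    pair_reversed: dict[str, bool]
    tied: bool
    reversal: bool
    mf_last_signature: bool


def root_branch_contrast(res: FitResult, tol: float = 1e-6) -> RootBranchContrast:
    """Compare the T->D rate preferences on the root branch vs later branches.

    A *reversal* means some pair of T->D transitions is ordered one way on
    the root branch and the opposite way on the later branches.  The
    MF-last signature is the specific pattern where the root branch favours
    T->D_LF.MF over T->D_LF.IF (the newly arrived MF subgenome has had less
    time to lose genes) while the later branches reverse that preference.
    """
    if res.model.root_rho is None:
        raise ValueError("fit has no root-branch rate set")
    names = ("T>D_LF.IF", "T>D_LF.MF", "T>D_IF.MF")
    root = np.array(res.model.root_rho[:3])
    later = np.array(res.model.rho[:3])
    tied = bool(
        np.all(np.abs(root[:, None] - root[None, :]) < tol)
        and np.all(np.abs(later[:, None] - later[None, :]) < tol)
    )
    pair_reversed = {}
    for i in range(3):
        for j in range(i + 1, 3):
            dr = root[i] - root[j]
            dl = later[i] - later[j]
            pair_reversed[f"{names[i]} vs {names[j]}"] = bool(
                abs(dr) > tol and abs(dl) > tol and np.sign(dr) != np.sign(dl)
            )
    order = lambda v: tuple(names[k] for k in np.argsort(-v, kind="stable"))
    mf_sig = bool(root[1] > root[0] + tol and later[1] < later[0] - tol)
    return RootBranchContrast(
        order(root), order(later), pair_reversed, tied, any(pair_reversed.values()), mf_sig
    )
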