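"""Production-demand scoring of exchangeable metabolites under two conditions.

For each scored metabolite the engine asks the network two questions per
condition:

1. *Capability* — the FBA maximum of the metabolite's secretion exchange flux
   subject to steady state (``S v = 0``) and the condition's bounds.
2. *Demand* — the minimum weighted total flux ``sum_j w_j |v_j|`` the whole
   network must carry while secreting the metabolite at a required rate.

The demand is a parsimonious-FBA-style LP solved by splitting every flux into
nonnegative forward/reverse parts. The two demands are combined into a raw
score ``X_raw = (X_early - X_late) / (X_early + X_late)`` in ``[-1, 1]`` and
z-transformed across all scored metabolites (population mean 0, SD 1). A
positive final score means production becomes cheaper as fasting progresses
and the metabolite is predicted to rise in plasma; negative, to fall.

The required secretion rate is a configurable fraction (default 0.9) of the
maximum capability. By default the *same* target is used in both conditions
(the fraction is taken of the smaller of the two capabilities), so the two
demands compare the cost of equal output; ``v_opt_mode="per_condition"``
instead targets each condition's own capability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .constraints import ConditionBounds, apply_condition
from .errors import DegenerateScoreError, InfeasibleError, ValidationError
from .netmodel import DEFAULT_BOUND, NetworkModel, Reaction

log = logging.getLogger(__name__)

#: statuses recorded per metabolite in a ScoreTable
STATUS_OK = "ok"
STATUS_ZERO = "zero_capability"
STATUS_INFEASIBLE = "infeasible"

_CAP_TOL = 1e-9  # capability below this counts as "cannot produce"


@dataclass
class DemandProblem:
    """One minimum-weighted-total-flux query against a conditioned model."""

    model: NetworkModel
    target_metabolite: str
    v_opt_fraction: float = 0.9
    weights: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.v_opt_fraction <= 1.0:
            raise ValidationError("v_opt_fraction must lie in (0, 1]")


@dataclass
class ScoreTable:
    """Per-metabolite demands, raw scores and z-scores with (mu, sigma)."""

    table: pd.DataFrame  # metabolite_id, X_early, X_late, X_raw, X_s, status
    mu: float
    sigma: float

    COLUMNS = ["metabolite_id", "X_early", "X_late", "X_raw", "X_s", "status"]

    def ok(self) -> pd.DataFrame:
        return self.table[self.table["status"] == STATUS_OK]

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mu={self.mu!r}\tsigma={self.sigma!r}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "ScoreTable":
        with open(path) as fh:
            meta = fh.readline().lstrip("# ").split("\t")
            mu = float(meta[0].split("=")[1])
            sigma = float(meta[1].split("=")[1])
            table = pd.read_csv(fh, sep="\t")
        return cls(table, mu, sigma)


# ---------------------------------------------------------------------------
# LP plumbing
# ---------------------------------------------------------------------------


def _solve(c, A_eq, b_eq, bounds, what: str):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        raise InfeasibleError(
            f"{what}: LP solver returned status {res.status} ({res.message})",
            solver_status=str(res.status),
        )
    return res


def _secretion_exchange(model: NetworkModel, met_id: str) -> Tuple[NetworkModel, str]:
    """Model plus the id of an exchange able to carry positive secretion.

    If the metabolite has no exchange, a temporary one with bounds
    ``(0, DEFAULT_BOUND)`` is added (convention: stoichiometry ``{met: -1}``,
    positive flux = secretion into plasma).
    """
    model.metabolite(met_id)
    # most-permissive secretion route first; ties broken by id for determinism
    candidates = sorted(
        (
            ex_id
            for ex_id in model.exchanges_of(met_id)
            if model.reaction(ex_id).stoichiometry[met_id] < 0
        ),
        key=lambda ex_id: (-model.reaction(ex_id).upper_bound, ex_id),
    )
    if candidates:
        return model, candidates[0]
    tmp_id = f"EX_{met_id}_demand_tmp"
    if model.has_reaction(tmp_id):
        return model, tmp_id
    augmented = model.copy()
    augmented.reactions.append(Reaction(tmp_id, {met_id: -1.0}, 0.0, DEFAULT_BOUND))
    return NetworkModel(
        augmented.metabolites, augmented.reactions, augmented.compartments, model.id
    ), tmp_id


def max_production_capability(model: NetworkModel, met_id: str) -> float:
    """FBA maximum of the metabolite's secretion flux (clipped at 0)."""
    model, ex_id = _secretion_exchange(model, met_id)
    j = model.reaction_index(ex_id)
    n = len(model.reactions)
    c = np.zeros(n)
    c[j] = -1.0  # maximize secretion flux
    lb, ub = model.bounds_arrays()
    res = _solve(
        c, model.S, np.zeros(len(model.metabolites)), np.column_stack([lb, ub]),
        f"max capability of {met_id!r}",
    )
    return max(0.0, -res.fun)


def minimum_total_flux(
    model: NetworkModel,
    target_exchange: str,
    required_flux: float,
    weights: Optional[Mapping[str, float]] = None,
) -> Tuple[float, np.ndarray]:
    """Min of ``sum_j w_j |v_j|`` with the target exchange flux >= required.

    Implemented by splitting each flux into forward/reverse nonnegative
    parts; returns the optimal objective and the recombined flux vector.
    """
    j = model.reaction_index(target_exchange)
    lb, ub = model.bounds_arrays()
    lb[j] = max(lb[j], required_flux)
    if lb[j] > ub[j] + 1e-12:
        raise InfeasibleError(
            f"required secretion {required_flux} exceeds upper bound {ub[j]} "
            f"of {target_exchange!r}"
        )
    w = model.weights_array()
    if weights is not None:
        for rxn_id, wt in weights.items():
            if wt < 0:
                raise ValidationError(f"negative weight for reaction {rxn_id!r}")
            w[model.reaction_index(rxn_id)] = wt
    n = len(model.reactions)
    S = model.S
    # v = v_plus - v_minus with v_plus in [max(0,lb), max(0,ub)],
    # v_minus in [max(0,-ub), max(0,-lb)]; positive weights drive the
    # optimizer to v_plus*v_minus = 0, so the objective equals sum w|v|.
    bounds_plus = np.column_stack([np.maximum(0.0, lb), np.maximum(0.0, ub)])
    bounds_minus = np.column_stack([np.maximum(0.0, -ub), np.maximum(0.0, -lb)])
    A_eq = sparse.hstack([S, -S], format="csc")
    c = np.concatenate([w, w])
    res = _solve(
        c,
        A_eq,
        np.zeros(S.shape[0]),
        np.vstack([bounds_plus, bounds_minus]),
        f"demand for {target_exchange!r} at {required_flux:g}",
    )
    v = res.x[:n] - res.x[n:]
    return res.fun, v


def production_demand(dp: DemandProblem) -> Tuple[float, str]:
    """Demand for one conditioned model; returns ``(X_met, status)``.

    The required secretion is ``v_opt_fraction`` of this model's own maximum
    capability (single-condition query; :func:`run_timbr` handles the
    two-condition shared-target logic).
    """
    model, ex_id = _secretion_exchange(dp.model, dp.target_metabolite)
    cap = max_production_capability(model, dp.target_metabolite)
    if cap <= _CAP_TOL:
        return math.nan, STATUS_ZERO
    try:
        x_met, _ = minimum_total_flux(
            model, ex_id, dp.v_opt_fraction * cap, dp.weights
        )
    except InfeasibleError:
        return math.nan, STATUS_INFEASIBLE
    return x_met, STATUS_OK


def raw_score(x_early: float, x_late: float) -> float:
    """Normalized demand difference, in ``[-1, 1]``; antisymmetric in its args."""
    if x_early < 0 or x_late < 0:
        raise ValidationError("demands must be nonnegative")
    total = x_early + x_late
    if total <= 0:
        raise ValidationError("raw score undefined when both demands are zero")
    return (x_early - x_late) / total


def z_transform(raw_scores: Sequence[float]) -> Tuple[np.ndarray, float, float]:
    """Population z-scores of the raw scores; returns ``(X_s, mu, sigma)``."""
    arr = np.asarray(raw_scores, dtype=float)
    if arr.size < 2:
        raise ValidationError("z-transform needs at least 2 scores")
    mu = float(arr.mean())
    sigma = float(arr.std())  # population SD
    # identical inputs leave only rounding noise in sigma
    if sigma <= 1e-12 * max(1.0, abs(mu)):
        raise DegenerateScoreError("all raw scores identical; z-transform undefined")
    return (arr - mu) / sigma, mu, sigma


def run_timbr(
    model: NetworkModel,
    cb_early: ConditionBounds,
    cb_late: ConditionBounds,
    metabolites: Optional[Sequence[str]] = None,
    v_opt_fraction: float = 0.9,
    weights: Optional[Mapping[str, float]] = None,
    v_opt_mode: str = "shared",
) -> ScoreTable:
    """Score metabolites under early vs. late fasting bound sets.

    ``metabolites`` defaults to every exchangeable metabolite of the model.
    Metabolites with zero capability or an infeasible demand in either
    condition are flagged and excluded from the z-transform population.
    """
    if not 0.0 < v_opt_fraction <= 1.0:
        raise ValidationError("v_opt_fraction must lie in (0, 1]")
    if v_opt_mode not in ("shared", "per_condition"):
        raise ValidationError(f"unknown v_opt_mode {v_opt_mode!r}")
    m_early = apply_condition(model, cb_early)
    m_late = apply_condition(model, cb_late)
    if metabolites is None:
        metabolites = sorted(
            {
                met_id
                for r in model.reactions
                if r.is_exchange
                for met_id in r.stoichiometry
            }
        )

    rows = []
    for met_id in metabolites:
        me, ex_e = _secretion_exchange(m_early, met_id)
        ml, ex_l = _secretion_exchange(m_late, met_id)
        cap_e = max_production_capability(me, met_id)
        cap_l = max_production_capability(ml, met_id)
        if min(cap_e, cap_l) <= _CAP_TOL:
            log.info("metabolite %s: zero capability (early=%g late=%g)", met_id, cap_e, cap_l)
            rows.append((met_id, math.nan, math.nan, math.nan, STATUS_ZERO))
            continue
        if v_opt_mode == "shared":
            req_e = req_l = v_opt_fraction * min(cap_e, cap_l)
        else:
            req_e, req_l = v_opt_fraction * cap_e, v_opt_fraction * cap_l
        try:
            x_e, _ = minimum_total_flux(me, ex_e, req_e, weights)
            x_l, _ = minimum_total_flux(ml, ex_l, req_l, weights)
        except InfeasibleError as exc:
            log.warning("metabolite %s: demand infeasible (%s)", met_id, exc)
            rows.append((met_id, math.nan, math.nan, math.nan, STATUS_INFEASIBLE))
            continue
        rows.append((met_id, x_e, x_l, raw_score(x_e, x_l), STATUS_OK))

    table = pd.DataFrame(
        rows, columns=["metabolite_id", "X_early", "X_late", "X_raw", "status"]
    )
    ok_mask = table["status"] == STATUS_OK
    if ok_mask.sum() < 2:
        raise ValidationError(
            "fewer than 2 metabolites with feasible demand in both conditions"
        )
    xs, mu, sigma = z_transform(table.loc[ok_mask, "X_raw"].to_numpy())
    table["X_s"] = math.nan
    table.loc[ok_mask, "X_s"] = xs
    return ScoreTable(table[ScoreTable.COLUMNS].copy(), mu, sigma)
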