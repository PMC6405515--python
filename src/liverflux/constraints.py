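"""Per-condition flux bound sets for the fasting time points.

A :class:`ConditionBounds` carries two override maps for one physiological
condition (e.g. ``early_5-7h`` vs ``late_10-13h``): exchange-reaction bounds
(uptake/secretion rates between hepatocyte and plasma) and measured
central-carbon bounds from isotope-tracer flux estimates. Applying a
condition to a model intersects each override with the model's declared
bounds — the tighter interval wins — and leaves every other reaction alone.

:func:`fractions_to_bounds` converts fractional precursor contributions to
liver glucose output (glycogen / glycerol / lactate-and-amino-acids summing
to ~100%) into absolute bounds, given the total glucose output in model flux
units and a relative tolerance.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

from .errors import InfeasibleError, ValidationError
from .netmodel import NetworkModel

PRECURSOR_NAMES = ("glycogen", "glycerol", "lactate_and_amino_acids")


@dataclass
class ConditionBounds:
    """Bound overrides for one condition, keyed by reaction id."""

    condition_label: str
    exchange_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    mfa_bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for source, table in (
            ("exchange", self.exchange_bounds),
            ("mfa", self.mfa_bounds),
        ):
            for rxn_id, (lo, hi) in table.items():
                if lo > hi:
                    raise ValidationError(
                        f"{self.condition_label}/{source}: reaction {rxn_id!r} "
                        f"has lower {lo} > upper {hi}"
                    )

    def items(self):
        yield from self.exchange_bounds.items()
        yield from self.mfa_bounds.items()


@dataclass
class PrecursorFractions:
    """Fractional contributions of gluconeogenic precursors to glucose output."""

    total_output: float
    fractions: Dict[str, float]

    #: tolerated deviation of the fraction sum from 1 (table rows sum to ~100%)
    SUM_TOLERANCE = 0.01

    def __post_init__(self) -> None:
        if self.total_output <= 0:
            raise ValidationError("total_output must be positive")
        for name, frac in self.fractions.items():
            if name not in PRECURSOR_NAMES:
                raise ValidationError(
                    f"unknown precursor name {name!r}; expected one of {PRECURSOR_NAMES}"
                )
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"fraction for {name!r} outside [0, 1]: {frac}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > self.SUM_TOLERANCE:
            raise ValidationError(
                f"precursor fractions sum to {total:.4f}, not 1 within "
                f"{self.SUM_TOLERANCE}"
            )


def fractions_to_bounds(
    pf: PrecursorFractions,
    mapping: Mapping[str, str],
    tolerance_fraction: float = 0.0,
    output_reaction: Optional[str] = None,
    condition_label: str = "",
) -> ConditionBounds:
    """Turn precursor fractions into absolute bound intervals.

    Each precursor's reaction is bounded at ``fraction * total_output`` with
    relative half-width ``tolerance_fraction``; the glucose-output reaction
    (if given) is bounded at ``total_output`` with the same relative
    tolerance. The intervals land in ``mfa_bounds`` — they constrain pathway
    throughputs, not plasma exchange rates.
    """
    if tolerance_fraction < 0:
        raise ValidationError("tolerance_fraction must be nonnegative")
    missing = [p for p in pf.fractions if p not in mapping]
    if missing:
        raise ValidationError(f"mapping lacks reaction ids for precursor(s): {missing}")

    def band(center: float) -> Tuple[float, float]:
        return (center * (1 - tolerance_fraction), center * (1 + tolerance_fraction))

    mfa = {mapping[p]: band(frac * pf.total_output) for p, frac in pf.fractions.items()}
    if output_reaction is not None:
        mfa[output_reaction] = band(pf.total_output)
    return ConditionBounds(condition_label or "condition", {}, mfa)


def apply_condition(model: NetworkModel, cb: ConditionBounds) -> NetworkModel:
    """Return a copy of ``model`` with the condition's bounds applied.

    Each override is intersected with the model's declared bounds; an empty
    intersection raises :class:`InfeasibleError`. Idempotent for a fixed
    ``cb``.
    """
    overrides = dict(cb.items())
    unknown = sorted(r for r in overrides if not model.has_reaction(r))
    if unknown:
        raise ValidationError(
            f"condition {cb.condition_label!r} references unknown reaction id(s): {unknown}"
        )
    out = model.copy()
    for rxn_id, (lo, hi) in overrides.items():
        rxn = out.reaction(rxn_id)
        new_lo = max(rxn.lower_bound, lo)
        new_hi = min(rxn.upper_bound, hi)
        if new_lo > new_hi:
            raise InfeasibleError(
                f"condition {cb.condition_label!r}: bounds ({lo}, {hi}) for "
                f"{rxn_id!r} do not intersect model bounds "
                f"({rxn.lower_bound}, {rxn.upper_bound})"
            )
        rxn.lower_bound = new_lo
        rxn.upper_bound = new_hi
    return out


# ---------------------------------------------------------------------------
# TSV dialect: condition, reaction_id, lower, upper, source
# ---------------------------------------------------------------------------

_HEADER = ["condition", "reaction_id", "lower", "upper", "source"]


def read_bounds_tsv(path: str) -> Dict[str, ConditionBounds]:
    conditions: Dict[str, Dict[str, Dict[str, Tuple[float, float]]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HEADER:
            raise ValidationError(f"{path}: expected header {_HEADER}, found {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValidationError(f"{path}:{lineno}: expected 5 columns")
            cond, rxn_id, lo_s, hi_s, source = parts
            if source not in ("exchange", "mfa"):
                raise ValidationError(
                    f"{path}:{lineno}: source must be 'exchange' or 'mfa', got {source!r}"
                )
            try:
                lo, hi = float(lo_s), float(hi_s)
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-numeric bound") from None
            conditions.setdefault(cond, {"exchange": {}, "mfa": {}})[source][rxn_id] = (lo, hi)
    return {
        cond: ConditionBounds(cond, tables["exchange"], tables["mfa"])
        for cond, tables in conditions.items()
    }


def write_bounds_tsv(conditions: Mapping[str, ConditionBounds], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for cond in conditions.values():
            for source, table in (
                ("exchange", cond.exchange_bounds),
                ("mfa", cond.mfa_bounds),
            ):
                for rxn_id, (lo, hi) in table.items():
                    fh.write(
                        f"{cond.condition_label}\t{rxn_id}\t{lo!r}\t{hi!r}\t{source}\n"
                    )
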