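"""Data model and I/O for constraint-based metabolic networks.

A :class:`NetworkModel` holds an ordered list of metabolites and reactions,
builds the stoichiometric matrix ``S`` (rows = metabolites, columns =
reactions), and flags exchange reactions — boundary reactions touching a
single metabolite, through which the cell takes up (negative flux) or
secretes (positive flux) a metabolite.

Three dialects are supported:

* ``cobra-json`` — the COBRA community JSON schema, read/written through
  :mod:`cobra`;
* ``sbml`` — SBML Level 3 FBC, read through :mod:`cobra` (read-only);
* ``tsv-triplet`` — a plain-text fixture dialect: a directory holding
  ``metabolites.tsv``, ``reactions.tsv`` and ``stoich.tsv``.

Bounds are plain floats in one model-level flux unit; strict inequalities of
the mathematical formulation are represented as non-strict LP bounds
``lb <= v <= ub``. Missing bounds default to +/-``DEFAULT_BOUND``.
Identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse

from .errors import FormatError, ValidationError

#: Default magnitude used for unspecified bounds (COBRA convention).
DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A reaction with a signed stoichiometry map and flux bounds.

    ``weight`` is the nonnegative coefficient of this reaction in the
    weighted-total-flux objective of the demand LP (default 1).
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.weight < 0:
            raise ValidationError(f"reaction {self.id!r}: negative weight")

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1


class NetworkModel:
    """An ordered, validated collection of metabolites and reactions."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        compartments: Optional[Sequence[str]] = None,
        id: str = "model",
    ):
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        for label, ids in (("metabolite", met_ids), ("reaction", rxn_ids)):
            if len(set(ids)) != len(ids):
                dups = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {label} id(s): {dups}")
        self.compartments: List[str] = (
            list(compartments)
            if compartments is not None
            else sorted({m.compartment for m in self.metabolites})
        )
        bad_comp = [m.id for m in self.metabolites if m.compartment not in self.compartments]
        if bad_comp:
            raise ValidationError(
                f"metabolite(s) {bad_comp} use undeclared compartments "
                f"(declared: {self.compartments})"
            )
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        for r in self.reactions:
            unknown = [m for m in r.stoichiometry if m not in self._met_index]
            if unknown:
                raise ValidationError(
                    f"reaction {r.id!r} references undeclared metabolite(s): {sorted(unknown)}"
                )

    # -- indexed access ----------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise ValidationError(f"unknown metabolite id {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise ValidationError(f"unknown reaction id {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def reaction_index(self, rxn_id: str) -> int:
        self.reaction(rxn_id)
        return self._rxn_index[rxn_id]

    # -- matrix and bounds -------------------------------------------------
    @property
    def S(self) -> sparse.csc_matrix:
        return build_stoich_matrix(self.reactions, self.metabolites)

    def bounds_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def weights_array(self) -> np.ndarray:
        return np.array([r.weight for r in self.reactions], dtype=float)

    # -- misc ---------------------------------------------------------------
    def copy(self) -> "NetworkModel":
        mets = [Metabolite(m.id, m.name, m.compartment) for m in self.metabolites]
        rxns = [
            Reaction(r.id, dict(r.stoichiometry), r.lower_bound, r.upper_bound, r.weight)
            for r in self.reactions
        ]
        return NetworkModel(mets, rxns, list(self.compartments), id=self.id)

    def exchanges_of(self, met_id: str) -> List[str]:
        """Exchange reactions whose single metabolite is ``met_id``."""
        return [
            r.id for r in self.reactions if r.is_exchange and met_id in r.stoichiometry
        ]

    def is_exchangeable(self, met_id: str) -> bool:
        return bool(self.exchanges_of(met_id))

    def summary(self) -> Dict[str, int]:
        return {
            "n_metabolites": len(self.metabolites),
            "n_reactions": len(self.reactions),
            "n_exchanges": len(identify_exchange_reactions(self)),
        }


def build_stoich_matrix(
    reactions: Sequence[Reaction], metabolites: Sequence[Metabolite]
) -> sparse.csc_matrix:
    """Sparse stoichiometric matrix; column j reproduces reaction j exactly."""
    met_index = {m.id: i for i, m in enumerate(metabolites)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(reactions):
        for met_id, coef in r.stoichiometry.items():
            if met_id not in met_index:
                raise ValidationError(
                    f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                )
            rows.append(met_index[met_id])
            cols.append(j)
            vals.append(float(coef))
    return sparse.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
    )


def identify_exchange_reactions(model: NetworkModel) -> List[str]:
    """Ids of reactions with exactly one metabolite, ordered by id."""
    return sorted(r.id for r in model.reactions if r.is_exchange)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_FILES = ("metabolites.tsv", "reactions.tsv", "stoich.tsv")


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "tsv-triplet"
    lower = path.lower()
    if lower.endswith(".json"):
        return "cobra-json"
    if lower.endswith((".xml", ".sbml")):
        return "sbml"
    raise FormatError(f"cannot infer model format from path {path!r}")


def load_model(path: str, format: Optional[str] = None) -> NetworkModel:
    """Load a model from ``cobra-json``, ``sbml`` or ``tsv-triplet`` input."""
    fmt = format or _infer_format(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "tsv-triplet":
        return _load_tsv_triplet(path)
    if fmt == "cobra-json":
        return _load_via_cobra(path, "json")
    if fmt == "sbml":
        return _load_via_cobra(path, "sbml")
    raise FormatError(f"unknown model format {fmt!r}")


def save_model(model: NetworkModel, path: str, format: Optional[str] = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "tsv-triplet":
        _save_tsv_triplet(model, path)
    elif fmt == "cobra-json":
        _save_cobra_json(model, path)
    else:
        raise FormatError(f"saving format {fmt!r} not supported")


def _load_via_cobra(path: str, kind: str) -> NetworkModel:
    import cobra.io

    try:
        if kind == "json":
            cm = cobra.io.load_json_model(path)
        else:
            cm = cobra.io.read_sbml_model(path)
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise FormatError(f"failed to parse {path!r} as {kind}: {exc}") from exc
    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "c") for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        weight = 1.0
        if isinstance(r.notes, dict) and "weight" in r.notes:
            weight = float(r.notes["weight"])
        rxns.append(
            Reaction(
                r.id,
                {m.id: float(c) for m, c in r.metabolites.items()},
                float(r.lower_bound) if r.lower_bound is not None else -DEFAULT_BOUND,
                float(r.upper_bound) if r.upper_bound is not None else DEFAULT_BOUND,
                weight,
            )
        )
    return NetworkModel(mets, rxns, id=cm.id or "model")


def _save_cobra_json(model: NetworkModel, path: str) -> None:
    doc = {
        "id": model.id,
        "version": "1",
        "compartments": {c: c for c in model.compartments},
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.id,
                "metabolites": {k: v for k, v in sorted(r.stoichiometry.items())},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": "",
                "notes": {"weight": r.weight},
            }
            for r in model.reactions
        ],
        "genes": [],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)


def _load_tsv_triplet(path: str) -> NetworkModel:
    for fname in _TSV_FILES:
        if not os.path.exists(os.path.join(path, fname)):
            raise FormatError(f"tsv-triplet model at {path!r} is missing {fname}")

    def read_rows(fname: str, expected: Sequence[str]) -> List[Dict[str, str]]:
        fpath = os.path.join(path, fname)
        with open(fpath) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != list(expected):
                raise FormatError(
                    f"{fpath}: expected header {list(expected)}, found {header}"
                )
            rows = []
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(expected):
                    raise FormatError(f"{fpath}:{lineno}: expected {len(expected)} columns")
                rows.append(dict(zip(expected, parts)))
        return rows

    def as_float(text: str, where: str) -> float:
        try:
            return float(text)
        except ValueError:
            raise FormatError(f"{where}: not a number: {text!r}") from None

    mets = [
        Metabolite(row["id"], row["name"], row["compartment"])
        for row in read_rows("metabolites.tsv", ("id", "name", "compartment"))
    ]
    rxn_rows = read_rows(
        "reactions.tsv", ("id", "lower_bound", "upper_bound", "weight")
    )
    stoich: Dict[str, Dict[str, float]] = {row["id"]: {} for row in rxn_rows}
    for row in read_rows("stoich.tsv", ("reaction_id", "metabolite_id", "coefficient")):
        if row["reaction_id"] not in stoich:
            raise ValidationError(
                f"stoich.tsv references undeclared reaction {row['reaction_id']!r}"
            )
        stoich[row["reaction_id"]][row["metabolite_id"]] = as_float(
            row["coefficient"], f"stoich.tsv ({row['reaction_id']})"
        )
    rxns = [
        Reaction(
            row["id"],
            stoich[row["id"]],
            as_float(row["lower_bound"], f"reactions.tsv ({row['id']})"),
            as_float(row["upper_bound"], f"reactions.tsv ({row['id']})"),
            as_float(row["weight"], f"reactions.tsv ({row['id']})"),
        )
        for row in rxn_rows
    ]
    return NetworkModel(mets, rxns, id=os.path.basename(os.path.normpath(path)))


def _save_tsv_triplet(model: NetworkModel, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "metabolites.tsv"), "w") as fh:
        fh.write("id\tname\tcompartment\n")
        for m in model.metabolites:
            fh.write(f"{m.id}\t{m.name}\t{m.compartment}\n")
    with open(os.path.join(path, "reactions.tsv"), "w") as fh:
        fh.write("id\tlower_bound\tupper_bound\tweight\n")
        for r in model.reactions:
            fh.write(
                f"{r.id}\t{r.lower_bound!r}\t{r.upper_bound!r}\t{r.weight!r}\n"
            )
    with open(os.path.join(path, "stoich.tsv"), "w") as fh:
        fh.write("reaction_id\tmetabolite_id\tcoefficient\n")
        for r in model.reactions:
            for met_id, coef in r.stoichiometry.items():
                fh.write(f"{r.id}\t{met_id}\t{coef!r}\n")
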