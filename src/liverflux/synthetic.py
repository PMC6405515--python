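"""Desk-scale fixtures with known ground truth.

Two generators:

* :func:`make_toy_liver_network` — a ~35-reaction liver-like network
  (glycogenolysis, gluconeogenesis from glycerol and from lactate/amino
  acids, a lumped TCA cycle, ketogenesis, and a urea stub) together with an
  early-fasting and a late-fasting bound set and a table of planted
  production-direction truths that follow constructively from the bounds.

* :func:`make_ms_counts` — multi-study lognormal MS count tables with
  planted fold changes, per-study baseline shifts (vehicle proxies) and
  left-censored missingness below a per-study detection floor.

Flux bookkeeping of the toy network: hexose units for glycogen/G6P/glucose
and their products; three-carbon units for glycerol, lactate, alanine and
pyruvate (two required per hexose, carried by the 2:1 stoichiometry of the
lumped aldolase/FBPase step). The early condition allots 48% of a total
glucose output capacity of 100 units to glycogenolysis and the late
condition 2.3% of 70 units, with glycerol and lactate/amino-acid allowances
filling the remainder in the same published proportions, so the fasting
trajectory (collapsing glycogen stores, rising lipolysis and proteolysis)
is encoded entirely in the bounds.

Planted truths are not assertions about the real liver; they are
consequences of the construction. Each sentinel product has a cheap
synthesis route gated by a condition-dependent uptake allowance plus an
always-open expensive fallback, so the minimum-total-flux demand provably
drops (elevated) or rises (depressed) from the early to the late bound set:

========  ==========  ======================================================
sentinel  direction   mechanism
========  ==========  ======================================================
glc       depressed   output band falls 100 -> 70; extra glucose late must
                      come from the 11-reaction lactate route once glycogen
                      (4-reaction route) is exhausted
mlt       depressed   maltose released 1:1 from the glycogen store; late the
                      store allowance collapses and the fallback (2 G6P per
                      maltose via gluconeogenesis) is expensive
ket       elevated    ketone bodies cost 3 flux units each from fatty acids
                      (allowance 1 -> 20) vs. ~10 via pyruvate dehydrogenase
acrn      elevated    acylcarnitine 1:1 from fatty acids vs. 8 acetyl-CoA
                      fallback
c4ac      elevated    short-chain acylcarnitine, 2 per fatty acid vs.
                      2 acetyl-CoA fallback
ba        elevated    bile-acid-like product, 10 acetyl-CoA each; acetyl-CoA
                      is ~6x cheaper from fatty acids than from lactate
========  ==========  ======================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constraints import ConditionBounds
from .errors import ValidationError
from .metabolomics import MSCountTable, StudyPair
from .netmodel import DEFAULT_BOUND, Metabolite, NetworkModel, Reaction

ALL_PATHWAYS = frozenset(
    {
        "glycogenolysis",
        "gluconeogenesis_glycerol",
        "gluconeogenesis_lactate",
        "tca",
        "ketogenesis",
        "urea_stub",
    }
)


@dataclass
class ToyNetworkSpec:
    include_pathways: FrozenSet[str] = ALL_PATHWAYS
    n_extra_exchanges: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.include_pathways) - ALL_PATHWAYS
        if unknown:
            raise ValidationError(f"unknown pathway name(s): {sorted(unknown)}")
        if self.n_extra_exchanges < 0:
            raise ValidationError("n_extra_exchanges must be nonnegative")


@dataclass
class ToyNetwork:
    model: NetworkModel
    cb_early: ConditionBounds
    cb_late: ConditionBounds
    truths: Dict[str, str]  # sentinel metabolite -> planted direction
    scored_metabolites: List[str]
    pathway_map: Dict[str, str]


# (reaction id, stoichiometry, pathway tag); all irreversible 0..DEFAULT_BOUND
# except LDH (reversible, near-equilibrium)
_INTERNAL = [
    ("PYGL", {"glycogen": -1, "g6p": 1}, "glycogenolysis"),
    ("MLT_REL", {"glycogen": -1, "mlt": 1}, "glycogenolysis"),
    ("MLT_SYN", {"g6p": -2, "mlt": 1}, "glycogenolysis"),
    ("G6PC", {"g6p": -1, "glc": 1}, "core"),
    ("FBP_GNG", {"gap": -2, "g6p": 1}, "core"),
    ("GK", {"glyc": -1, "gap": 1}, "gluconeogenesis_glycerol"),
    ("LDH", {"lac": -1, "pyr": 1}, "gluconeogenesis_lactate"),
    ("ALT", {"ala": -1, "pyr": 1, "nh3": 1}, "gluconeogenesis_lactate"),
    ("PC", {"pyr": -1, "co2": -1, "oaa": 1}, "tca"),
    ("PCK", {"oaa": -1, "gap": 1, "co2": 1}, "tca"),
    ("PDH", {"pyr": -1, "accoa": 1, "co2": 1}, "tca"),
    ("CS", {"accoa": -1, "oaa": -1, "cit": 1}, "tca"),
    ("TCA_OX", {"cit": -1, "oaa": 1, "co2": 2}, "tca"),
    ("BOX", {"ffa": -1, "accoa": 4}, "ketogenesis"),
    ("HMGS_KET", {"accoa": -2, "ket": 1}, "ketogenesis"),
    ("CACT", {"ffa": -1, "acrn": 1}, "ketogenesis"),
    ("ACRN_ACCOA", {"accoa": -8, "acrn": 1}, "ketogenesis"),
    ("C4AC_FFA", {"ffa": -1, "c4ac": 2}, "ketogenesis"),
    ("C4AC_ACCOA", {"accoa": -2, "c4ac": 1}, "ketogenesis"),
    ("BA_SYN", {"accoa": -10, "ba": 1}, "ketogenesis"),
    ("UREA_SYN", {"nh3": -2, "co2": -1, "urea": 1}, "urea_stub"),
]

# exchange id -> (metabolite, base lower, base upper, pathway)
_EXCHANGES = [
    ("EX_glycogen", "glycogen", -DEFAULT_BOUND, 0.0, "glycogenolysis"),
    ("EX_mlt", "mlt", 0.0, DEFAULT_BOUND, "glycogenolysis"),
    ("EX_glc", "glc", -DEFAULT_BOUND, DEFAULT_BOUND, "core"),
    ("EX_co2", "co2", -DEFAULT_BOUND, DEFAULT_BOUND, "core"),
    ("EX_glyc", "glyc", -DEFAULT_BOUND, 0.0, "gluconeogenesis_glycerol"),
    ("EX_lac", "lac", -DEFAULT_BOUND, 0.0, "gluconeogenesis_lactate"),
    ("EX_ala", "ala", -DEFAULT_BOUND, 0.0, "gluconeogenesis_lactate"),
    ("EX_ffa", "ffa", -DEFAULT_BOUND, 0.0, "ketogenesis"),
    ("EX_ket", "ket", 0.0, DEFAULT_BOUND, "ketogenesis"),
    ("EX_acrn", "acrn", 0.0, DEFAULT_BOUND, "ketogenesis"),
    ("EX_c4ac", "c4ac", 0.0, DEFAULT_BOUND, "ketogenesis"),
    ("EX_ba", "ba", 0.0, DEFAULT_BOUND, "ketogenesis"),
    ("EX_nh3", "nh3", -DEFAULT_BOUND, 0.0, "urea_stub"),
    ("EX_urea", "urea", 0.0, DEFAULT_BOUND, "urea_stub"),
]

_MET_NAMES = {
    "glycogen": "glycogen (hepatic store)",
    "g6p": "glucose 6-phosphate",
    "glc": "glucose",
    "gap": "triose phosphate pool",
    "glyc": "glycerol",
    "lac": "lactate",
    "pyr": "pyruvate",
    "ala": "alanine (amino-acid pool)",
    "nh3": "ammonia",
    "oaa": "oxaloacetate",
    "cit": "citrate",
    "accoa": "acetyl-CoA",
    "ffa": "non-esterified fatty acids",
    "ket": "ketone bodies",
    "co2": "carbon dioxide",
    "mlt": "maltose (glycogen-derived)",
    "acrn": "long-chain acylcarnitine",
    "c4ac": "short-chain acylcarnitine",
    "urea": "urea",
    "ba": "bile acid pool",
}

_MET_PATHWAY = {
    "glc": "carbohydrate",
    "mlt": "carbohydrate",
    "ket": "lipid",
    "acrn": "lipid",
    "c4ac": "lipid",
    "ba": "lipid",
    "urea": "amino acid",
}

# condition tables (see module docstring for the unit conventions):
# total glucose output capacity 100 (early, 5-7 h) vs 70 (late, 10-13 h);
# uptake allowances follow the published precursor fractions
# (glycogen 48% / glycerol 15% / lactate 33% / amino acids 4% early;
#  2.3% / 23.4% / 59% / 15.3% late), three-carbon precursors doubled.
_EARLY_EXCHANGE = {
    "EX_glycogen": (-60.0, 0.0),  # store allowance; PYGL cap limits glucose use
    "EX_glyc": (-30.0, 0.0),
    "EX_lac": (-66.0, 0.0),
    "EX_ala": (-8.0, 0.0),
    "EX_ffa": (-1.0, 0.0),
    "EX_nh3": (-1.0, 0.0),
    "EX_glc": (70.0, 130.0),  # obligatory systemic glucose supply, 100 +/- 30%
}
_EARLY_MFA = {"PYGL": (0.0, 48.0)}
_LATE_EXCHANGE = {
    "EX_glycogen": (-2.0, 0.0),
    "EX_glyc": (-32.8, 0.0),
    "EX_lac": (-82.6, 0.0),
    "EX_ala": (-21.4, 0.0),
    "EX_ffa": (-20.0, 0.0),
    "EX_nh3": (-10.0, 0.0),
    "EX_glc": (49.0, 91.0),  # 70 +/- 30%
}
_LATE_MFA = {"PYGL": (0.0, 1.61)}

_SENTINEL_TRUTHS = {
    "glc": "depressed",
    "mlt": "depressed",
    "ket": "elevated",
    "acrn": "elevated",
    "c4ac": "elevated",
    "ba": "elevated",
}

# sentinel -> pathways its mechanism needs (beyond core)
_SENTINEL_NEEDS = {
    "glc": {"glycogenolysis", "gluconeogenesis_lactate", "tca"},
    "mlt": {"glycogenolysis", "gluconeogenesis_lactate", "tca"},
    "ket": {"ketogenesis", "gluconeogenesis_lactate", "tca"},
    "acrn": {"ketogenesis", "gluconeogenesis_lactate", "tca"},
    "c4ac": {"ketogenesis", "gluconeogenesis_lactate", "tca"},
    "ba": {"ketogenesis", "gluconeogenesis_lactate", "tca"},
}


def make_toy_liver_network(spec: Optional[ToyNetworkSpec] = None) -> ToyNetwork:
    """Build the toy network, both bound sets and the planted-truth table.

    Deterministic: the same spec always yields the same network. Raises if
    the requested pathway subset cannot carry the forced glucose output
    (gluconeogenesis from lactate requires the TCA pathway for the
    pyruvate-carboxylase/PEPCK route).
    """
    spec = spec or ToyNetworkSpec()
    pathways = set(spec.include_pathways) | {"core"}
    if "gluconeogenesis_lactate" in pathways and "tca" not in pathways:
        raise ValidationError(
            "gluconeogenesis from lactate needs the tca pathway: without "
            "PC/PCK there is no route from pyruvate to triose phosphate"
        )
    # the forced glucose output band must be coverable by the included routes
    early_capacity = 0.0
    if "glycogenolysis" in pathways:
        early_capacity += 48.0
    if "gluconeogenesis_glycerol" in pathways:
        early_capacity += 15.0
    if "gluconeogenesis_lactate" in pathways:
        early_capacity += 37.0
    if early_capacity < _EARLY_EXCHANGE["EX_glc"][0]:
        raise ValidationError(
            f"included pathways supply at most {early_capacity} glucose units "
            f"but the early output bound requires {_EARLY_EXCHANGE['EX_glc'][0]}"
        )

    internal = [
        Reaction(rid, dict(stoich), 0.0, DEFAULT_BOUND)
        for rid, stoich, tag in _INTERNAL
        if tag in pathways
    ]
    for r in internal:
        if r.id == "LDH":
            r.lower_bound = -DEFAULT_BOUND  # near-equilibrium, reversible
    exchanges = [
        Reaction(rid, {met: -1.0}, lo, hi)
        for rid, met, lo, hi, tag in _EXCHANGES
        if tag in pathways
    ]
    extra_mets, extra_rxns = [], []
    for i in range(spec.n_extra_exchanges):
        met = f"xf{i + 1}"
        extra_mets.append(Metabolite(met, f"filler metabolite {i + 1}", "c"))
        extra_rxns.append(Reaction(f"XF_SYN{i + 1}", {"gap": -1, met: 1}, 0.0, DEFAULT_BOUND))
        extra_rxns.append(Reaction(f"EX_{met}", {met: -1.0}, 0.0, DEFAULT_BOUND))

    used_mets = sorted(
        {m for r in internal + exchanges for m in r.stoichiometry}
    )
    mets = [Metabolite(m, _MET_NAMES.get(m, m), "c") for m in used_mets] + extra_mets
    model = NetworkModel(mets, internal + exchanges + extra_rxns, id="toy_liver")

    def trim(bounds: Dict[str, Tuple[float, float]]) -> Dict[str, Tuple[float, float]]:
        return {rid: b for rid, b in bounds.items() if model.has_reaction(rid)}

    cb_early = ConditionBounds("early_5-7h", trim(_EARLY_EXCHANGE), trim(_EARLY_MFA))
    cb_late = ConditionBounds("late_10-13h", trim(_LATE_EXCHANGE), trim(_LATE_MFA))

    truths = {
        met: direction
        for met, direction in _SENTINEL_TRUTHS.items()
        if model.has_metabolite(met) and _SENTINEL_NEEDS[met] <= pathways
    }
    scored = sorted(
        set(truths)
        | ({"urea"} if model.has_metabolite("urea") else set())
        | {m.id for m in extra_mets}
    )
    pathway_map = {m: _MET_PATHWAY[m] for m in _MET_PATHWAY if model.has_metabolite(m)}
    return ToyNetwork(model, cb_early, cb_late, truths, scored, pathway_map)


# ---------------------------------------------------------------------------
# MS count simulator
# ---------------------------------------------------------------------------


@dataclass
class CountSimSpec:
    """Lognormal multi-study count simulation with planted fold changes.

    Defaults mirror the real study designs: three studies with 8, 8 and 9
    animals per time point; lognormal biological+technical noise with log
    scale 0.3; per-study baseline shifts standing in for the different
    vehicles; and 10% left-censoring below a per-study detection floor.
    """

    n_metabolites: int = 50
    planted_fc: Dict[str, float] = field(default_factory=dict)
    n_animals: Tuple[int, ...] = (8, 8, 9)
    noise_sigma: float = 0.3
    study_shift_sigma: float = 0.25
    missing_rate: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_metabolites < 1 and not self.planted_fc:
            raise ValidationError("need at least one metabolite")
        if any(fc <= 0 for fc in self.planted_fc.values()):
            raise ValidationError("planted fold changes must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if self.noise_sigma < 0 or self.study_shift_sigma < 0:
            raise ValidationError("noise scales must be nonnegative")
        if self.seed is None:
            raise ValidationError("a seed is required (counts are stochastic)")


def make_ms_counts(spec: CountSimSpec) -> Tuple[List[StudyPair], pd.DataFrame]:
    """Simulate count tables; returns (study pairs, truth table).

    Early counts are LogNormal(mu_m + d_s, sigma); late counts multiply the
    location by the planted fold change. Entries below the study's detection
    floor (the ``missing_rate`` quantile of all values generated for that
    study) are masked missing — left-censoring, the mechanism that makes
    minimum-value imputation sensible. The truth table records each
    metabolite's fold change, nominal direction and whether censoring wiped
    it out entirely.
    """
    planted = dict(spec.planted_fc)
    met_ids = list(planted)
    filler = spec.n_metabolites - len(met_ids)
    met_ids += [f"m{i + 1:04d}" for i in range(max(0, filler))]
    fc = np.array([planted.get(m, 1.0) for m in met_ids])

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x6C69]))
    mu = rng.uniform(math.log(1e4), math.log(1e6), size=len(met_ids))
    shifts = rng.normal(0.0, spec.study_shift_sigma, size=len(spec.n_animals))

    studies: List[StudyPair] = []
    observed_any = np.zeros(len(met_ids), dtype=bool)
    for s, n in enumerate(spec.n_animals):
        study_id = f"study{s + 1}"
        loc = mu + shifts[s]
        early = np.exp(
            rng.normal(loc[:, None], spec.noise_sigma, size=(len(met_ids), n))
        )
        late = np.exp(
            rng.normal(
                (loc + np.log(fc))[:, None], spec.noise_sigma, size=(len(met_ids), n)
            )
        )
        if spec.missing_rate > 0:
            floor = np.quantile(
                np.concatenate([early, late], axis=1), spec.missing_rate
            )
            early = np.where(early < floor, np.nan, early)
            late = np.where(late < floor, np.nan, late)
        observed_any |= ~np.all(
            np.isnan(np.concatenate([early, late], axis=1)), axis=1
        )
        animals_e = [f"{study_id}_e{a + 1}" for a in range(n)]
        animals_l = [f"{study_id}_l{a + 1}" for a in range(n)]
        studies.append(
            (
                MSCountTable(
                    study_id, "early",
                    pd.DataFrame(early, index=met_ids, columns=animals_e),
                ),
                MSCountTable(
                    study_id, "late",
                    pd.DataFrame(late, index=met_ids, columns=animals_l),
                ),
            )
        )

    truth = pd.DataFrame(
        {
            "metabolite_id": met_ids,
            "fc": fc,
            "direction": np.where(
                fc > 1.0, "elevated", np.where(fc < 1.0, "depressed", "unchanged")
            ),
            "fully_censored": ~observed_any,
        }
    )
    return studies, truth


def write_truth_tsv(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)
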