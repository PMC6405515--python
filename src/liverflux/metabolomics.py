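"""Direction calling for multi-study plasma MS count tables.

The observed data are MS ion counts per metabolite per animal, at an early
and a late fasting time point in each study (different animals at the two
time points). The procedure:

1. *Min-imputation* — missing counts (left-censored below each study's
   detection floor) are replaced by the minimum observed value of that
   metabolite within the imputation scope (default: per study).
2. *Pooled percentile bootstrap* — for each of ``B`` replicates and each
   study with ``n_s`` animals, ``n_s`` late and ``n_s`` early counts are
   resampled with replacement and ratioed elementwise into ``n_s``
   fold-change values; the fold values of all studies are pooled and
   averaged, giving ``B`` pooled mean fold changes (late/early).
3. *99% percentile CI* — the interval between the 0.5th and 99.5th
   percentiles (linear interpolation) of the replicate means.
4. *Call* — elevated iff the whole CI lies above 1, depressed iff below 1,
   otherwise unchanged.

The elementwise-ratio estimator (``paired_ratio``) is the default; note that
the mean of ratios of lognormal counts is biased above the median fold
change by ``exp(sigma^2)``, which inflates elevated calls under the null for
noisy data. The ``ratio_of_means`` estimator (per-study ratio of resampled
means, pooled with study-size weights) is available as an alternative.

Randomness is reproducible: each metabolite gets a substream derived from
the master seed and a hash of its id, so results do not depend on metabolite
order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

TIME_POINTS = ("early", "late")
DIRECTIONS = ("elevated", "depressed", "unchanged")


@dataclass
class MSCountTable:
    """Counts for one study at one time point: metabolites x animals.

    ``counts`` has metabolite ids as the index and animal ids as columns;
    NaN marks a missing (censored) entry.
    """

    study_id: str
    time_point: str
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValidationError(
                f"time_point must be one of {TIME_POINTS}, got {self.time_point!r}"
            )
        vals = self.counts.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError(
                f"{self.study_id}/{self.time_point}: negative counts present"
            )

    @property
    def n_animals(self) -> int:
        return self.counts.shape[1]


StudyPair = Tuple[MSCountTable, MSCountTable]  # (early, late)


@dataclass
class BootstrapConfig:
    B: int = 100_000
    ci_level: float = 0.99
    seed: Optional[int] = None
    estimator: str = "paired_ratio"
    impute_scope: str = "per_study"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if not 0.0 < self.ci_level <= 1.0:
            raise ValidationError("ci_level must lie in (0, 1]")
        if self.estimator not in ("paired_ratio", "ratio_of_means"):
            raise ValidationError(f"unknown estimator {self.estimator!r}")
        if self.impute_scope not in ("per_study", "pooled"):
            raise ValidationError(f"unknown impute_scope {self.impute_scope!r}")
        if self.seed is None:
            raise ValidationError("a seed is required for the bootstrap")


def _check_pair(pair: StudyPair) -> None:
    early, late = pair
    if early.time_point != "early" or late.time_point != "late":
        raise ValidationError("study pair must be ordered (early, late)")
    if early.study_id != late.study_id:
        raise ValidationError("study pair mixes study ids")
    if early.n_animals != late.n_animals:
        raise ValidationError(
            f"study {early.study_id}: early and late animal counts differ "
            f"({early.n_animals} vs {late.n_animals})"
        )


def impute_missing(
    studies: Sequence[StudyPair], scope: str = "per_study"
) -> Tuple[List[StudyPair], List[Tuple[str, str]]]:
    """Min-impute missing counts; returns (imputed studies, dropped records).

    The imputation value is the minimum observed count of the metabolite
    within the scope — both time points of the study for ``per_study``, all
    studies for ``pooled``. Metabolites with no observed value anywhere in
    scope are dropped from that scope and reported as ``(study_id | '*',
    metabolite_id)`` records.
    """
    if scope not in ("per_study", "pooled"):
        raise ValidationError(f"unknown imputation scope {scope!r}")
    for pair in studies:
        _check_pair(pair)
    dropped: List[Tuple[str, str]] = []

    if scope == "pooled":
        stacked = pd.concat(
            [t.counts.min(axis=1) for pair in studies for t in pair], axis=1
        )
        pooled_min = stacked.min(axis=1)
        fully_missing = set(pooled_min.index[pooled_min.isna()])
        dropped.extend(("*", m) for m in sorted(fully_missing))

    out: List[StudyPair] = []
    for early, late in studies:
        both = pd.concat([early.counts, late.counts], axis=1)
        study_min = both.min(axis=1)
        if scope == "per_study":
            fill = study_min
            gone = set(fill.index[fill.isna()])
            dropped.extend((early.study_id, m) for m in sorted(gone))
        else:
            fill = pooled_min.reindex(both.index)
            gone = fully_missing & set(both.index)
        keep = [m for m in both.index if m not in gone]
        if gone:
            log.info(
                "impute_missing: dropping %d fully-missing metabolite(s) from %s",
                len(gone), early.study_id,
            )
        pair_out = tuple(
            MSCountTable(
                t.study_id,
                t.time_point,
                t.counts.loc[keep].T.fillna(fill.loc[keep]).T,
            )
            for t in (early, late)
        )
        out.append(pair_out)  # type: ignore[arg-type]
    return out, dropped


def _metabolite_rng(seed: int, met_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(met_id.encode("utf8"))])
    )


def _studies_with(met_id: str, studies: Sequence[StudyPair]) -> List[StudyPair]:
    present = []
    for early, late in studies:
        if met_id in early.counts.index and met_id in late.counts.index:
            e = early.counts.loc[met_id]
            l = late.counts.loc[met_id]
            if e.notna().any() and l.notna().any():
                present.append((early, late))
    return present


def _bootstrap_one(
    met_id: str, studies: Sequence[StudyPair], cfg: BootstrapConfig
) -> np.ndarray:
    """B pooled mean fold changes for one metabolite (imputed inputs)."""
    rng = _metabolite_rng(cfg.seed, met_id)
    per_study: List[Tuple[int, np.ndarray, np.ndarray]] = []
    for early, late in studies:
        e = early.counts.loc[met_id].to_numpy(dtype=float)
        l = late.counts.loc[met_id].to_numpy(dtype=float)
        if np.isnan(e).any() or np.isnan(l).any():
            raise ValidationError(
                f"{met_id}: missing values remain in study {early.study_id}; "
                "run impute_missing first"
            )
        if (e == 0).all():
            raise ValidationError(
                f"{met_id}: all early counts are zero in study {early.study_id}; "
                "fold changes are undefined"
            )
        per_study.append((len(e), e, l))

    fold_blocks, weights = [], []
    redraws = 0
    for n, e, l in per_study:
        il = rng.integers(0, n, size=(cfg.B, n))
        ie = rng.integers(0, n, size=(cfg.B, n))
        denom = e[ie]
        # zero denominators are normally impossible after min-imputation of
        # positive counts; redraw the offending rows if raw zeros slipped in
        bad = (denom == 0).any(axis=1)
        while bad.any():
            redraws += int(bad.sum())
            ie[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
            denom = e[ie]
            bad = (denom == 0).any(axis=1)
        if cfg.estimator == "paired_ratio":
            fold_blocks.append(l[il] / denom)
        else:
            fold_blocks.append((l[il].mean(axis=1) / denom.mean(axis=1))[:, None])
        weights.append(n)
    if redraws:
        log.warning("%s: redrew %d replicate rows with zero denominators", met_id, redraws)

    if cfg.estimator == "paired_ratio":
        return np.concatenate(fold_blocks, axis=1).mean(axis=1)
    ratios = np.concatenate(fold_blocks, axis=1)  # (B, n_studies)
    w = np.asarray(weights, dtype=float)
    return ratios @ (w / w.sum())


def bootstrap_fold_changes(
    studies: Sequence[StudyPair],
    cfg: BootstrapConfig,
    metabolites: Optional[Sequence[str]] = None,
) -> Dict[str, np.ndarray]:
    """Replicate vectors of pooled mean fold changes, keyed by metabolite."""
    for pair in studies:
        _check_pair(pair)
    if metabolites is None:
        metabolites = sorted(
            {m for early, _ in studies for m in early.counts.index}
        )
    out = {}
    for met_id in metabolites:
        present = _studies_with(met_id, studies)
        if not present:
            log.info("bootstrap: %s observed in no study; skipped", met_id)
            continue
        out[met_id] = _bootstrap_one(met_id, present, cfg)
    return out


def percentile_ci(samples: Sequence[float], ci_level: float) -> Tuple[float, float]:
    """Equal-tailed percentile interval (linear-interpolation percentiles)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty sample vector")
    if not 0.0 < ci_level <= 1.0:
        raise ValidationError("ci_level must lie in (0, 1]")
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(arr, [100 * alpha, 100 * (1 - alpha)], method="linear")
    return float(lo), float(hi)


def classify_direction(ci: Tuple[float, float]) -> str:
    lo, hi = ci
    if lo > hi:
        raise ValidationError("invalid CI: lower > upper")
    if lo > 1.0:
        return "elevated"
    if hi < 1.0:
        return "depressed"
    return "unchanged"


def call_directions(
    studies: Sequence[StudyPair],
    cfg: BootstrapConfig,
    metabolites: Optional[Sequence[str]] = None,
    impute: bool = True,
) -> pd.DataFrame:
    """Full chain: impute -> bootstrap -> CI -> direction, one row per metabolite."""
    if impute:
        studies, _ = impute_missing(studies, cfg.impute_scope)
    if metabolites is None:
        metabolites = sorted(
            {m for early, _ in studies for m in early.counts.index}
        )
    rows = []
    for met_id in metabolites:
        present = _studies_with(met_id, studies)
        if not present:
            continue
        reps = _bootstrap_one(met_id, present, cfg)
        lo, hi = percentile_ci(reps, cfg.ci_level)
        rows.append(
            {
                "metabolite_id": met_id,
                "mean_fc": float(reps.mean()),
                "ci_lower": lo,
                "ci_upper": hi,
                "direction": classify_direction((lo, hi)),
                "studies_present": ";".join(e.study_id for e, _ in present),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite_id", "mean_fc", "ci_lower", "ci_upper",
            "direction", "studies_present",
        ],
    )


# ---------------------------------------------------------------------------
# TSV dialect: study_id, time_point, animal_id, metabolite_id, count
# (a missing measurement is simply an absent row)
# ---------------------------------------------------------------------------


def read_counts_tsv(path: str) -> List[StudyPair]:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "animal_id": str})
    expected = ["study_id", "time_point", "animal_id", "metabolite_id", "count"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    pairs: List[StudyPair] = []
    for study_id, study_df in df.groupby("study_id", sort=True):
        tables = {}
        met_ids = sorted(study_df["metabolite_id"].unique())
        for tp in TIME_POINTS:
            sub = study_df[study_df["time_point"] == tp]
            if sub.empty:
                raise ValidationError(f"{path}: study {study_id} lacks {tp} rows")
            wide = sub.pivot_table(
                index="metabolite_id", columns="animal_id", values="count",
                aggfunc="first",
            ).reindex(met_ids)
            wide.columns.name = None
            wide.index.name = None
            tables[tp] = MSCountTable(str(study_id), tp, wide)
        pairs.append((tables["early"], tables["late"]))
    return pairs


def write_counts_tsv(studies: Sequence[StudyPair], path: str) -> None:
    records = []
    for pair in studies:
        for t in pair:
            for met_id, row in t.counts.iterrows():
                for animal_id, val in row.items():
                    if pd.notna(val):
                        records.append(
                            (t.study_id, t.time_point, animal_id, met_id, repr(float(val)))
                        )
    with open(path, "w") as fh:
        fh.write("study_id\ttime_point\tanimal_id\tmetabolite_id\tcount\n")
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")
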