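"""Concordance of predicted score signs with observed plasma directions.

A metabolite with an observed direction (elevated or depressed) and a
production score is *concordant* when the score's sign points the same way:
positive score with an elevated metabolite, negative with a depressed one.
A score of exactly zero, or a metabolite without a usable score, yields no
prediction and is counted discordant by default (configurable to exclude).

Significance of a group's accuracy against coin-flipping is assessed with
the exact binomial test: one-sided (``greater``) for the overall accuracy,
doubled-tail two-sided for pathway subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .timbr import STATUS_OK, ScoreTable

OBSERVABLE = ("elevated", "depressed")


@dataclass
class ConcordanceReport:
    """Per-metabolite comparison rows plus the metabolites left unmapped."""

    rows: pd.DataFrame  # metabolite_id, pathway, observed, predicted_sign, concordant
    unmapped: List[str] = field(default_factory=list)

    def counts(self, subset: Optional[pd.DataFrame] = None) -> Dict[str, int]:
        df = self.rows if subset is None else subset
        elev = df[df["observed"] == "elevated"]
        depr = df[df["observed"] == "depressed"]
        out = {
            "n_elevated": len(elev),
            "n_elevated_concordant": int(elev["concordant"].sum()),
            "n_depressed": len(depr),
            "n_depressed_concordant": int(depr["concordant"].sum()),
        }
        out["n_total"] = out["n_elevated"] + out["n_depressed"]
        out["n_concordant"] = (
            out["n_elevated_concordant"] + out["n_depressed_concordant"]
        )
        return out


def _scores_frame(scores: Union[ScoreTable, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(scores, ScoreTable):
        return scores.table
    return scores


def compare(
    scores: Union[ScoreTable, pd.DataFrame],
    calls: pd.DataFrame,
    pathway_map: Optional[Mapping[str, str]] = None,
    zero_policy: str = "discordant",
) -> ConcordanceReport:
    """Match direction calls against score signs.

    Only metabolites called elevated or depressed are compared; calls with
    no score row are listed as unmapped and excluded from the counts.
    ``zero_policy`` controls metabolites with a zero score or a non-ok
    status: ``"discordant"`` (default, conservative) or ``"exclude"``.
    """
    if zero_policy not in ("discordant", "exclude"):
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    sdf = _scores_frame(scores).set_index("metabolite_id")
    pathway_map = pathway_map or {}
    rows, unmapped = [], []
    for _, call in calls.iterrows():
        met = call["metabolite_id"]
        observed = call["direction"]
        if observed not in OBSERVABLE:
            continue
        if met not in sdf.index:
            unmapped.append(met)
            continue
        srow = sdf.loc[met]
        xs = srow["X_s"]
        if srow["status"] != STATUS_OK or not np.isfinite(xs) or xs == 0.0:
            sign = "none"
        else:
            sign = "+" if xs > 0 else "-"
        if sign == "none" and zero_policy == "exclude":
            continue
        concordant = (sign == "+" and observed == "elevated") or (
            sign == "-" and observed == "depressed"
        )
        rows.append(
            {
                "metabolite_id": met,
                "pathway": pathway_map.get(met, ""),
                "observed": observed,
                "predicted_sign": sign,
                "concordant": bool(concordant),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["metabolite_id", "pathway", "observed", "predicted_sign", "concordant"]
    )
    return ConcordanceReport(frame, unmapped)


def exact_binomial_p(
    k: int, n: int, p0: float = 0.5, alternative: str = "greater"
) -> float:
    """Exact binomial tail probability for k successes in n trials.

    ``greater``: P(X >= k). ``two_sided``: doubled smaller tail,
    ``2 * min(P(X >= k), P(X <= k))`` capped at 1 (equals the usual
    minimum-likelihood two-sided test when p0 = 0.5).
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValidationError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError("p0 must lie in (0, 1)")
    if alternative not in ("greater", "two_sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    upper = float(stats.binom.sf(k - 1, n, p0))  # P(X >= k)
    if alternative == "greater":
        return upper
    lower = float(stats.binom.cdf(k, n, p0))  # P(X <= k)
    return min(1.0, 2.0 * min(upper, lower))


def _group_summary(
    counts: Dict[str, int], alternative: str, p0: float = 0.5
) -> Dict[str, object]:
    n, k = counts["n_total"], counts["n_concordant"]
    return {
        **counts,
        "accuracy_pct": round(100.0 * k / n) if n else None,
        "accuracy": (100.0 * k / n) if n else None,
        "p_value": exact_binomial_p(k, n, p0, alternative) if n else None,
    }


def accuracy_summary(
    report: ConcordanceReport,
    overall_alternative: str = "greater",
    pathway_alternative: str = "two_sided",
) -> Dict[str, object]:
    """Integer-percent accuracies and binomial p-values per group.

    Groups: overall, elevated, depressed, and one entry per pathway present.
    Empty groups report ``None`` (not applicable).
    """
    counts = report.counts()

    def class_group(observed: str) -> Dict[str, object]:
        n = counts[f"n_{observed}"]
        k = counts[f"n_{observed}_concordant"]
        return {
            "n_total": n,
            "n_concordant": k,
            "accuracy_pct": round(100.0 * k / n) if n else None,
            "accuracy": (100.0 * k / n) if n else None,
            "p_value": exact_binomial_p(k, n, 0.5, overall_alternative) if n else None,
        }

    summary: Dict[str, object] = {
        "overall": _group_summary(counts, overall_alternative),
        "elevated": class_group("elevated"),
        "depressed": class_group("depressed"),
        "pathways": {},
    }
    for pathway, sub in report.rows.groupby("pathway"):
        if not pathway:
            continue
        summary["pathways"][pathway] = _group_summary(
            report.counts(sub), pathway_alternative
        )
    return summary


def concordance_from_counts(
    n_elevated: int,
    k_elevated: int,
    n_depressed: int,
    k_depressed: int,
    overall_alternative: str = "greater",
) -> Dict[str, object]:
    """Accuracy arithmetic and overall binomial test from confusion counts.

    Entry point for published confusion tables where only the group counts
    (measured vs. concordant) are available.
    """
    for name, (k, n) in {
        "elevated": (k_elevated, n_elevated),
        "depressed": (k_depressed, n_depressed),
    }.items():
        if not 0 <= k <= n:
            raise ValidationError(f"{name}: need 0 <= concordant <= measured")
    n = n_elevated + n_depressed
    k = k_elevated + k_depressed
    return {
        "overall_accuracy_pct": round(100.0 * k / n) if n else None,
        "elevated_accuracy_pct": round(100.0 * k_elevated / n_elevated)
        if n_elevated else None,
        "depressed_accuracy_pct": round(100.0 * k_depressed / n_depressed)
        if n_depressed else None,
        "overall_p_value": exact_binomial_p(k, n, 0.5, overall_alternative)
        if n else None,
        "n_total": n,
        "n_concordant": k,
    }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_pathway_map(path: str) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    expected = ["metabolite_id", "pathway"]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: expected columns {expected}")
    return dict(zip(df["metabolite_id"], df["pathway"]))


def write_report(report: ConcordanceReport, path: str) -> None:
    report.rows.to_csv(path, sep="\t", index=False)
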