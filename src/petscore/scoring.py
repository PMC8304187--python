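"""The integrated tumor + host PET/CT prognostic score.

Three dichotomized predictors feed a 0-4 score: the two tumor factors
(TLG and first-order entropy, 1 point each when above their cutoffs) and the
host factor (bone-marrow SUV, 2 points when above its cutoff). Totals are
pooled into three prognostic groups: "0-2", "3" and "4". Default cutoffs
(TLG > 41.40 g, entropy > 3.40, BM SUV > 1.53) can be replaced by cutpoints
derived from a cohort via the maximally selected chi-square test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import CutoffResult, cox_fit, harrell_c, km_estimate, maxstat_cutoff

__all__ = [
    "ScoringRule",
    "RiskScore",
    "StratificationReport",
    "default_rule",
    "assign_score",
    "derive_rule",
    "score_cohort",
    "evaluate_stratification",
]

TUMOR_WEIGHT = 1  # per tumor factor (TLG, entropy)
HOST_WEIGHT = 2  # host factor (BM SUV)
GROUP_LABELS = ("0-2", "3", "4")


@dataclass(frozen=True)
class ScoringRule:
    """Cutoffs and fixed weights of the 0-4 tumor+host score."""

    tlg_cutoff: float = 41.40
    entropy_cutoff: float = 3.40
    bm_suv_cutoff: float = 1.53
    derived_from: tuple[CutoffResult, ...] = ()

    @staticmethod
    def group_of(total: int) -> str:
        if total not in (0, 1, 2, 3, 4):
            raise ValueError(f"total score must be 0..4, got {total}")
        return "0-2" if total <= 2 else str(total)


def default_rule() -> ScoringRule:
    """The published cutoffs: TLG 41.40 g, first-order entropy 3.40, BM SUV 1.53."""
    return ScoringRule()


@dataclass(frozen=True)
class RiskScore:
    """Per-factor points, 0-4 total and prognostic group of one patient."""

    tlg_points: int
    entropy_points: int
    bm_points: int
    total: int
    group: str


def _check_present(name: str, value: float) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"cannot score patient: {name} is missing")
    return float(value)


def assign_score(tlg: float, entropy: float, bm_suv: float, rule: ScoringRule) -> RiskScore:
    """Score one patient; comparisons are strict '>' (boundary values score 0)."""
    tlg = _check_present("TLG", tlg)
    entropy = _check_present("first-order entropy", entropy)
    bm_suv = _check_present("BM SUV", bm_suv)
    tlg_points = TUMOR_WEIGHT if tlg > rule.tlg_cutoff else 0
    entropy_points = TUMOR_WEIGHT if entropy > rule.entropy_cutoff else 0
    bm_points = HOST_WEIGHT if bm_suv > rule.bm_suv_cutoff else 0
    total = tlg_points + entropy_points + bm_points
    return RiskScore(
        tlg_points=tlg_points,
        entropy_points=entropy_points,
        bm_points=bm_points,
        total=total,
        group=ScoringRule.group_of(total),
    )


def derive_rule(
    cohort: pd.DataFrame,
    manual_cutoffs: tuple[float, float, float] | None = None,
    time_col: str = "time_months",
    event_col: str = "event",
) -> ScoringRule:
    """Build a scoring rule from a cohort, or from manual cutoffs.

    With ``manual_cutoffs=(tlg, entropy, bm_suv)`` the cutoffs are taken as
    given (``None`` means the published defaults). Otherwise each of the
    three predictors is dichotomized at its maximally selected chi-square
    cutpoint; the 1/1/2 weights are fixed either way.
    """
    if manual_cutoffs is not None:
        tlg_c, ent_c, bm_c = manual_cutoffs
        return ScoringRule(tlg_cutoff=tlg_c, entropy_cutoff=ent_c, bm_suv_cutoff=bm_c)
    results = []
    for col in ("tlg_g", "firstorder_entropy", "bm_suv"):
        results.append(
            maxstat_cutoff(
                cohort[col].to_numpy(),
                cohort[time_col].to_numpy(),
                cohort[event_col].to_numpy(),
                variable=col,
            )
        )
    return ScoringRule(
        tlg_cutoff=results[0].cutoff,
        entropy_cutoff=results[1].cutoff,
        bm_suv_cutoff=results[2].cutoff,
        derived_from=tuple(results),
    )


def score_cohort(cohort: pd.DataFrame, rule: ScoringRule) -> pd.DataFrame:
    """Append score columns (per-factor points, total, group) to a cohort table."""
    scores = [
        assign_score(row.tlg_g, row.firstorder_entropy, row.bm_suv, rule)
        for row in cohort.itertuples()
    ]
    out = cohort.copy()
    out["score_tlg"] = [s.tlg_points for s in scores]
    out["score_entropy"] = [s.entropy_points for s in scores]
    out["score_bm"] = [s.bm_points for s in scores]
    out["score_total"] = [s.total for s in scores]
    out["score_group"] = pd.Categorical(
        [s.group for s in scores], categories=list(GROUP_LABELS), ordered=True
    )
    return out


@dataclass(frozen=True)
class StratificationReport:
    """Group-wise survival evaluation of the scoring system.

    ``group_summary`` has one row per prognostic group (n, events, mean and
    median survival with CI, hazard ratio vs the "0-2" reference). Missing
    hazard ratios (empty group) are NaN with a note in ``notes``.
    ``subgroups`` maps each split (stage I-II / III-IV, surgery / other) to
    the analogous summary table, or to a note when the model is not
    estimable in that subgroup.
    """

    group_summary: pd.DataFrame
    c_index: float
    c_index_ci: tuple[float, float] | None
    subgroups: dict[str, pd.DataFrame | str]
    notes: tuple[str, ...] = ()


def _group_table(scored: pd.DataFrame, time_col: str, event_col: str):
    """Per-group KM summaries plus Cox HRs vs the '0-2' reference group."""
    rows = []
    notes = []
    for g in GROUP_LABELS:
        sub = scored[scored["score_group"] == g]
        if len(sub) == 0:
            rows.append(
                {"group": g, "n": 0, "events": 0, "mean_time": float("nan"),
                 "median": float("nan"), "median_ci_lower": float("nan"),
                 "median_ci_upper": float("nan")}
            )
            notes.append(f"group {g} is empty; no survival summary")
            continue
        km = km_estimate(sub[time_col], sub[event_col])
        rows.append(
            {
                "group": g,
                "n": int(len(sub)),
                "events": int(sub[event_col].sum()),
                "mean_time": float(sub[time_col].mean()),
                "median": km.median,
                "median_ci_lower": km.median_ci[0],
                "median_ci_upper": km.median_ci[1],
            }
        )
    table = pd.DataFrame(rows).set_index("group")

    table["hazard_ratio"] = float("nan")
    table["hr_ci_lower"] = float("nan")
    table["hr_ci_upper"] = float("nan")
    table["p_value"] = float("nan")
    table.loc["0-2", "hazard_ratio"] = 1.0  # reference
    design = scored[[time_col, event_col]].copy()
    design["group_3"] = (scored["score_group"] == "3").astype(float)
    design["group_4"] = (scored["score_group"] == "4").astype(float)
    estimable = (table.loc[["3", "4"], "n"] > 0).all() and table.loc["0-2", "n"] > 0
    if estimable:
        try:
            fit = cox_fit(
                design, ["group_3", "group_4"], time_col=time_col,
                event_col=event_col, label="score group",
            )
            for g, term in (("3", "group_3"), ("4", "group_4")):
                table.loc[g, "hazard_ratio"] = fit.summary.loc[term, "hazard_ratio"]
                table.loc[g, "hr_ci_lower"] = fit.summary.loc[term, "ci_lower"]
                table.loc[g, "hr_ci_upper"] = fit.summary.loc[term, "ci_upper"]
                table.loc[g, "p_value"] = fit.summary.loc[term, "p_value"]
        except RuntimeError as exc:
            notes.append(f"group-wise Cox model not estimable: {exc}")
    else:
        notes.append("group-wise Cox model skipped: at least one group is empty")
    return table, notes


def evaluate_stratification(
    cohort: pd.DataFrame,
    rule: ScoringRule,
    time_col: str = "time_months",
    event_col: str = "event",
    c_index_boot: int = 0,
    seed: int | None = None,
) -> StratificationReport:
    """Score a cohort and evaluate the prognostic stratification.

    Produces per-group Kaplan-Meier and Cox summaries (reference group
    "0-2"), Harrell's C of the total score, and subgroup tables split by
    stage (I-II vs III-IV) and treatment (surgery vs other).
    """
    scored = score_cohort(cohort, rule)
    table, notes = _group_table(scored, time_col, event_col)

    c_index, c_ci = harrell_c(
        scored["score_total"].to_numpy(dtype=float),
        scored[time_col].to_numpy(dtype=float),
        scored[event_col].to_numpy(),
        n_boot=c_index_boot,
        seed=seed,
    )

    subgroups: dict[str, pd.DataFrame | str] = {}
    splits = {
        "stage_I-II": scored["stage"].isin(["I", "II"]),
        "stage_III-IV": scored["stage"].isin(["III", "IV"]),
        "treatment_surgery": scored["treatment"] == "surgery",
        "treatment_other": scored["treatment"] != "surgery",
    }
    for name, mask in splits.items():
        sub = scored[mask]
        if len(sub) == 0:
            subgroups[name] = "empty subgroup"
            continue
        try:
            sub_table, sub_notes = _group_table(sub, time_col, event_col)
            subgroups[name] = sub_table
            notes.extend(f"{name}: {n}" for n in sub_notes)
        except (RuntimeError, ValueError) as exc:
            subgroups[name] = f"not estimable: {exc}"

    return StratificationReport(
        group_summary=table,
        c_index=c_index,
        c_index_ci=c_ci,
        subgroups=subgroups,
        notes=tuple(notes),
    )
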