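"""Competing-cost-pair (CCP) analysis.

A participant facing a choice between crouch walking and incline walking
at increasing grade eventually transitions to the crouch. The steepest
grade still chosen over crouch is the *pre-transition* incline; the
shallowest grade rejected in favour of crouch is the *post-transition*
incline. A competing-cost pair exists when, comparing the (mean) crouch
trial to the pre-transition incline, metabolic power decreased while the
activation cost increased — i.e. the two costs could not be reduced
simultaneously and one had to be traded against the other.

All percentage summaries express each cost as a percentage of the
participant's level-walking (0% incline) value, and percent changes use
the pre-transition incline value as denominator:

    advantage_X  = 100 * (crouch_X - incline_X) / incline_X
    penalty_met  = 100 * (incline_met - crouch_met) / incline_met

so a positive activation "advantage" is what the participant avoided by
choosing the incline, and the metabolic "penalty" is what that choice
cost them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costs import TrialCosts
from .exceptions import ConfigurationError, DataError

__all__ = [
    "ChoiceSequence",
    "TransitionResult",
    "CcpResult",
    "identify_transitions",
    "evaluate_ccp",
    "ccp_from_percent",
    "ccp_summary",
    "compare_conditions",
    "ConditionComparison",
]

PROTOCOL_GRADES: tuple[int, ...] = (0, 6, 12, 18, 24)

_METRICS = ("c_met_p", "c_a2", "c_a_max", "c_a_vol")


@dataclass(frozen=True)
class ChoiceSequence:
    """Per-grade crouch-vs-incline selections for one participant."""

    participant_id: str
    choices: Mapping[int, str]  # grade % -> "incline" | "crouch"

    def __post_init__(self) -> None:
        for g, sel in self.choices.items():
            if sel not in ("incline", "crouch"):
                raise ConfigurationError(f"unknown selection {sel!r} at grade {g}")


@dataclass(frozen=True)
class TransitionResult:
    """Pre-/post-transition grades derived from a choice sequence.

    ``monotone`` is True when no incline selection occurs at a steeper
    grade than any crouch selection — i.e. the sequence is consistent
    with a single transition.
    """

    pre_transition_grade: Optional[int]
    post_transition_grade: Optional[int]
    monotone: bool


def identify_transitions(
    choices: ChoiceSequence, protocol_grades: Sequence[int] = PROTOCOL_GRADES
) -> TransitionResult:
    """Locate the transition grades in a choice sequence.

    pre  = steepest grade where the incline was selected over crouch;
    post = shallowest grade where crouch was preferred. Either may be
    absent (None) when the respective set is empty.
    """
    missing = [g for g in protocol_grades if g not in choices.choices]
    if missing:
        raise ConfigurationError(
            f"choices for participant {choices.participant_id} missing grades {missing}"
        )
    incline_grades = [g for g in protocol_grades if choices.choices[g] == "incline"]
    crouch_grades = [g for g in protocol_grades if choices.choices[g] == "crouch"]
    pre = max(incline_grades) if incline_grades else None
    post = min(crouch_grades) if crouch_grades else None
    if pre is None or post is None:
        monotone = True
    else:
        monotone = pre < post
    return TransitionResult(
        pre_transition_grade=pre, post_transition_grade=post, monotone=monotone
    )


@dataclass(frozen=True)
class CcpResult:
    """CCP booleans and percent summaries for one participant.

    ``crouch_pct`` and ``incline_pct`` hold each cost as a percentage of
    the participant's 0%-incline value; activation entries are NaN when
    the participant's EMG was excluded. CCP flags are None in that case.
    """

    participant_id: str
    pre_transition_grade: Optional[int]
    crouch_pct: Mapping[str, float]
    incline_pct: Mapping[str, float]
    ccp_a2: Optional[bool]
    ccp_a_max: Optional[bool]
    ccp_a_vol: Optional[bool]
    advantage_a2: float
    advantage_a_max: float
    advantage_a_vol: float
    penalty_met: float

    @property
    def has_activation(self) -> bool:
        return self.ccp_a2 is not None


def _pct_change(new: float, ref: float) -> float:
    return 100.0 * (new - ref) / ref


def ccp_from_percent(
    participant_id: str,
    crouch_pct: Mapping[str, float],
    incline_pct: Mapping[str, float],
    pre_transition_grade: Optional[int] = None,
) -> CcpResult:
    """Apply the CCP rule to costs already expressed as % of level walking.

    The rule uses strict inequalities: a CCP for activation cost X holds
    iff crouch metabolic power is strictly below the pre-transition
    incline's AND crouch X is strictly above it. Ties yield no CCP.
    """
    for m in ("c_met_p",):
        for d in (crouch_pct, incline_pct):
            if m not in d or not math.isfinite(d[m]):
                raise DataError(f"participant {participant_id}: missing {m}")
    cm_c, cm_i = crouch_pct["c_met_p"], incline_pct["c_met_p"]
    if cm_i == 0:
        raise DataError(f"participant {participant_id}: degenerate incline denominator")
    met_decreases = cm_c < cm_i
    penalty_met = 100.0 * (cm_i - cm_c) / cm_i

    flags: dict[str, Optional[bool]] = {}
    adv: dict[str, float] = {}
    for m in ("c_a2", "c_a_max", "c_a_vol"):
        c = crouch_pct.get(m, float("nan"))
        i = incline_pct.get(m, float("nan"))
        if not (math.isfinite(c) and math.isfinite(i)):
            flags[m] = None
            adv[m] = float("nan")
            continue
        if i == 0:
            raise DataError(f"participant {participant_id}: degenerate incline denominator")
        flags[m] = bool(met_decreases and c > i)
        adv[m] = _pct_change(c, i)

    return CcpResult(
        participant_id=participant_id,
        pre_transition_grade=pre_transition_grade,
        crouch_pct=dict(crouch_pct),
        incline_pct=dict(incline_pct),
        ccp_a2=flags["c_a2"],
        ccp_a_max=flags["c_a_max"],
        ccp_a_vol=flags["c_a_vol"],
        advantage_a2=adv["c_a2"],
        advantage_a_max=adv["c_a_max"],
        advantage_a_vol=adv["c_a_vol"],
        penalty_met=penalty_met,
    )


def evaluate_ccp(
    crouch_costs: TrialCosts,
    pre_incline_costs: TrialCosts,
    baseline_costs: TrialCosts,
    pre_transition_grade: Optional[int] = None,
) -> CcpResult:
    """Express costs as % of the 0%-incline trial and apply the CCP rule.

    ``crouch_costs`` should be the mean of the initial and final crouch
    trials. Raises when the pre-transition incline is absent upstream
    (call sites must not pass None) or any baseline cost is non-positive.
    """
    base = {m: getattr(baseline_costs, m) for m in _METRICS}
    for m, v in base.items():
        if math.isfinite(v) and v <= 0:
            raise DataError(f"baseline cost {m} must be strictly positive; got {v}")

    def to_pct(tc: TrialCosts) -> dict[str, float]:
        out = {}
        for m in _METRICS:
            v = getattr(tc, m)
            b = base[m]
            out[m] = 100.0 * v / b if math.isfinite(v) and math.isfinite(b) else float("nan")
        return out

    return ccp_from_percent(
        crouch_costs.participant_id or pre_incline_costs.participant_id,
        to_pct(crouch_costs),
        to_pct(pre_incline_costs),
        pre_transition_grade=pre_transition_grade,
    )


_SUMMARY_FIELDS = {
    "advantage_a2": "advantage_a2",
    "advantage_a_max": "advantage_a_max",
    "advantage_a_vol": "advantage_a_vol",
    "penalty_met": "penalty_met",
}


def ccp_summary(
    results: Iterable[CcpResult], restrict_to_ccp: bool = True
) -> pd.DataFrame:
    """Group means and ranges of the advantage/penalty percentages.

    With ``restrict_to_ccp`` the selection is the participants for whom
    a metabolic-vs-C̄a² CCP was established; otherwise all participants
    with complete activation data. Returns a DataFrame indexed by
    measure with columns ``mean``, ``min``, ``max``, ``n``.
    """
    results = list(results)
    if not results:
        raise DataError("empty result list")
    if restrict_to_ccp:
        sel = [r for r in results if r.ccp_a2 is True]
    else:
        sel = [r for r in results if r.has_activation]
    if not sel:
        raise DataError("no participants in the requested selection")

    rows = {}
    for name, attr in _SUMMARY_FIELDS.items():
        vals = np.array([getattr(r, attr) for r in sel], dtype=float)
        vals = vals[np.isfinite(vals)]
        rows[name] = {
            "mean": vals.mean(),
            "min": vals.min(),
            "max": vals.max(),
            "n": vals.size,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class ConditionComparison:
    """Decision report for one cost variable across the three conditions."""

    variable: str
    branch: str  # "parametric" | "nonparametric" | "degenerate"
    normality_p: Mapping[str, float]
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    significant: bool
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def compare_conditions(
    values: pd.DataFrame,
    alpha: float = 0.05,
    posthoc_alpha: float = 0.017,
    variable: str = "",
) -> ConditionComparison:
    """Compare crouch vs pre- vs post-transition values across participants.

    ``values`` must have the matched columns ``crouch``, ``pre``,
    ``post`` (one row per participant, no missing entries). Each
    condition is screened for normality (Shapiro–Wilk at 0.05); if all
    pass, the parametric branch runs a one-way repeated-measures ANOVA
    with paired t-test post-hocs, otherwise a Friedman test with
    Wilcoxon signed-rank post-hocs. Post-hocs run only when the omnibus
    test is significant at ``alpha`` and are judged against the
    Bonferroni-adjusted ``posthoc_alpha``.
    """
    required = ["crouch", "pre", "post"]
    missing_cols = [c for c in required if c not in values.columns]
    if missing_cols:
        raise ConfigurationError(f"values missing columns {missing_cols}")
    bad = values[required].isna().any(axis=1)
    if bad.any():
        raise DataError(f"incomplete triples for participants {list(values.index[bad])}")
    if len(values) < 3:
        raise DataError("need at least 3 complete triples")

    arr = {c: values[c].to_numpy(dtype=float) for c in required}

    if all(np.ptp(arr[c]) == 0 for c in required) and (
        np.ptp(values[required].to_numpy()) == 0
    ):
        return ConditionComparison(
            variable=variable,
            branch="degenerate",
            normality_p={c: float("nan") for c in required},
            omnibus_test="none",
            omnibus_stat=float("nan"),
            omnibus_p=1.0,
            significant=False,
        )

    normality_p = {}
    normal = True
    for c in required:
        x = arr[c]
        if np.ptp(x) == 0:
            # constant condition: Shapiro undefined; treat as non-normal
            normality_p[c] = float("nan")
            normal = False
        else:
            p = float(stats.shapiro(x).pvalue)
            normality_p[c] = p
            normal = normal and p >= 0.05

    if normal:
        branch = "parametric"
        omnibus_test = "repeated-measures ANOVA"
        long = values[required].reset_index(names="participant").melt(
            id_vars="participant", var_name="condition", value_name="y"
        )
        from statsmodels.stats.anova import AnovaRM

        res = AnovaRM(long, depvar="y", subject="participant", within=["condition"]).fit()
        omnibus_stat = float(res.anova_table["F Value"].iloc[0])
        omnibus_p = float(res.anova_table["Pr > F"].iloc[0])
    else:
        branch = "nonparametric"
        omnibus_test = "Friedman"
        stat, p = stats.friedmanchisquare(arr["crouch"], arr["pre"], arr["post"])
        omnibus_stat, omnibus_p = float(stat), float(p)

    significant = omnibus_p < alpha
    posthoc_rows = []
    if significant:
        for a, b in itertools.combinations(required, 2):
            if branch == "parametric":
                t = stats.ttest_rel(arr[a], arr[b])
                test, s, p = "paired t", float(t.statistic), float(t.pvalue)
            else:
                d = arr[a] - arr[b]
                if np.all(d == 0):
                    test, s, p = "Wilcoxon signed-rank", float("nan"), 1.0
                else:
                    w = stats.wilcoxon(arr[a], arr[b])
                    test, s, p = "Wilcoxon signed-rank", float(w.statistic), float(w.pvalue)
            posthoc_rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "test": test,
                    "stat": s,
                    "p": p,
                    "significant": p < posthoc_alpha,
                }
            )
    posthoc = pd.DataFrame(posthoc_rows)

    return ConditionComparison(
        variable=variable,
        branch=branch,
        normality_p=normality_p,
        omnibus_test=omnibus_test,
        omnibus_stat=omnibus_stat,
        omnibus_p=omnibus_p,
        significant=significant,
        posthoc=posthoc,
    )
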