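"""End-to-end orchestration: signals → costs → choices → CCP report.

``run_experiment`` chains the stages in protocol order: stride detection
from the GRF, EMG linear envelopes and per-stride activations
(normalized to the participant's own 0%-incline trial), final-minute
metabolic power, the three activation cost functionals, simulated (or
supplied) crouch-vs-incline choices, transition identification, and the
competing-cost-pair analysis with its group summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .ccp import (
    PROTOCOL_GRADES,
    CcpResult,
    ChoiceSequence,
    ConditionComparison,
    ccp_summary,
    compare_conditions,
    evaluate_ccp,
    identify_transitions,
)
from .costs import TrialCosts, trial_costs
from .emg import MUSCLES, ActivationTable, compute_activation_table, compute_envelope
from .energetics import MetabolicResult, metabolic_power
from .exceptions import ConfigurationError, GaitCostsError
from .gait_events import StrideWindows, detect_strides
from .io import write_cohort
from .synthetic import (
    TrialRecording,
    default_profiles,
    generate_cohort,
    simulate_choice,
)

__all__ = [
    "RunConfig",
    "TrialAnalysis",
    "CohortAnalysis",
    "analyze_trial",
    "run_cohort_analysis",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable pipeline settings, with the study's processing defaults.

    Defaults: 2000 Hz sampling, 20–350 Hz band-pass and 6 Hz low-pass
    fourth-order zero-phase Butterworth filters, 2% GRF contact
    threshold, 5 analysed strides, 60 s final-minute metabolic window,
    α = 0.05 with Bonferroni-adjusted post-hoc α = 0.017.
    """

    sampling_rate: float = 2000.0
    band: tuple[float, float] = (20.0, 350.0)
    lowpass: float = 6.0
    filter_order: int = 4
    threshold_fraction: float = 0.02
    refractory: float = 0.2
    n_strides: int = 5
    saturation: Optional[float] = None
    metabolic_window: float = 60.0
    grades: tuple[int, ...] = PROTOCOL_GRADES
    choice_weights: tuple[float, float] = (1.0, 2.0)  # (w_met, w_act)
    alpha: float = 0.05
    posthoc_alpha: float = 0.017
    crouch_aggregate: str = "mean"  # "mean" | "initial" | "final"
    # simulation-mode settings
    n_participants: int = 10
    trial_duration: float = 300.0
    carrier: str = "noise"
    breath_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ConfigurationError(f"invalid band {self.band}")
        if self.sampling_rate <= 2 * hi:
            raise ConfigurationError(
                f"sampling rate {self.sampling_rate} Hz incompatible with band "
                f"edge {hi} Hz"
            )
        if self.crouch_aggregate not in ("mean", "initial", "final"):
            raise ConfigurationError(
                f"crouch_aggregate must be mean/initial/final, got {self.crouch_aggregate!r}"
            )
        if self.n_strides < 1:
            raise ConfigurationError("n_strides must be >= 1")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        for key in ("band", "choice_weights", "grades"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TrialAnalysis:
    """Derived quantities for one trial."""

    strides: StrideWindows
    activation: ActivationTable
    metabolic: MetabolicResult
    costs: TrialCosts


def analyze_trial(
    rec: TrialRecording,
    baseline: Optional[ActivationTable] = None,
    config: Optional[RunConfig] = None,
) -> TrialAnalysis:
    """Run the signal stages on one trial.

    ``baseline`` is the 0%-incline trial's activation table for this
    participant; pass None when analysing that trial itself.
    """
    cfg = config or RunConfig()
    strides = detect_strides(
        rec.grf,
        rec.sampling_rate,
        threshold_fraction=cfg.threshold_fraction,
        refractory=cfg.refractory,
    )
    envelopes = {
        m: compute_envelope(
            rec.emg[m].to_numpy(),
            rec.sampling_rate,
            muscle=m,
            band=cfg.band,
            lowpass=cfg.lowpass,
            order=cfg.filter_order,
        )
        for m in MUSCLES
        if m not in rec.excluded_channels
    }
    activation = compute_activation_table(
        envelopes,
        strides,
        baseline=baseline,
        stride_count=cfg.n_strides,
        saturation=cfg.saturation,
    )
    metabolic = metabolic_power(
        rec.breaths, rec.mass, trial_duration=rec.duration, window=cfg.metabolic_window
    )
    costs = trial_costs(
        activation, metabolic, condition=rec.condition, participant_id=rec.participant_id
    )
    return TrialAnalysis(
        strides=strides, activation=activation, metabolic=metabolic, costs=costs
    )


def _mean_costs(a: TrialCosts, b: TrialCosts) -> TrialCosts:
    return TrialCosts(
        c_met_p=0.5 * (a.c_met_p + b.c_met_p),
        c_a2=0.5 * (a.c_a2 + b.c_a2),
        c_a_max=0.5 * (a.c_a_max + b.c_a_max),
        c_a_vol=0.5 * (a.c_a_vol + b.c_a_vol),
        condition="crouch",
        participant_id=a.participant_id,
    )


@dataclass
class CohortAnalysis:
    """Bundle of per-trial costs, choices and group-level CCP results."""

    costs: pd.DataFrame  # long: participant, condition, c_met_p, c_a2, ...
    choices: dict[str, ChoiceSequence]
    transitions: pd.DataFrame
    ccp_results: list[CcpResult]
    summary_ccp: pd.DataFrame
    summary_all: pd.DataFrame
    comparisons: dict[str, ConditionComparison]
    trial_analyses: dict[str, dict[str, TrialAnalysis]] = field(default_factory=dict)


def run_cohort_analysis(
    cohort: Mapping[str, Mapping[str, TrialRecording]],
    config: Optional[RunConfig] = None,
    choices: Optional[Mapping[str, ChoiceSequence]] = None,
) -> CohortAnalysis:
    """Analyse every trial of a cohort and run the CCP pipeline.

    When ``choices`` is None the composite-objective agent of
    ``simulate_choice`` supplies the crouch-vs-incline selections using
    the configured (w_met, w_act) weights.
    """
    cfg = config or RunConfig()
    cost_rows = []
    all_choices: dict[str, ChoiceSequence] = {}
    transitions_rows = []
    ccp_results: list[CcpResult] = []
    analyses: dict[str, dict[str, TrialAnalysis]] = {}

    for pid, trials in cohort.items():
        if "incline_0" not in trials:
            raise ConfigurationError(f"participant {pid}: missing 0% incline trial")
        per: dict[str, TrialAnalysis] = {}
        try:
            base_an = analyze_trial(trials["incline_0"], baseline=None, config=cfg)
        except GaitCostsError as e:
            raise type(e)(f"stage failure in incline_0 of {pid}: {e}") from e
        per["incline_0"] = base_an
        for label, rec in trials.items():
            if label == "incline_0":
                continue
            try:
                per[label] = analyze_trial(rec, baseline=base_an.activation, config=cfg)
            except GaitCostsError as e:
                raise type(e)(f"stage failure in {label} of {pid}: {e}") from e
        analyses[pid] = per

        costs_by_label = {lab: an.costs for lab, an in per.items()}
        if cfg.crouch_aggregate == "mean":
            crouch_costs = _mean_costs(
                costs_by_label["crouch_initial"], costs_by_label["crouch_final"]
            )
        elif cfg.crouch_aggregate == "initial":
            crouch_costs = costs_by_label["crouch_initial"]
        else:
            crouch_costs = costs_by_label["crouch_final"]

        for lab, tc in {**costs_by_label, "crouch": crouch_costs}.items():
            cost_rows.append(
                {
                    "participant": pid,
                    "condition": lab,
                    "c_met_p": tc.c_met_p,
                    "c_a2": tc.c_a2,
                    "c_a_max": tc.c_a_max,
                    "c_a_vol": tc.c_a_vol,
                }
            )

        choice_costs = {"crouch": crouch_costs}
        for g in cfg.grades:
            choice_costs[f"incline_{g}"] = costs_by_label[f"incline_{g}"]
        if choices is not None:
            seq = choices[pid]
        else:
            seq = simulate_choice(
                choice_costs,
                weights=cfg.choice_weights,
                grades=cfg.grades,
                participant_id=pid,
            )
        all_choices[pid] = seq

        tr = identify_transitions(seq, cfg.grades)
        transitions_rows.append(
            {
                "participant": pid,
                "pre_transition_grade": tr.pre_transition_grade,
                "post_transition_grade": tr.post_transition_grade,
                "monotone": tr.monotone,
            }
        )
        if tr.pre_transition_grade is not None and tr.monotone:
            ccp_results.append(
                evaluate_ccp(
                    crouch_costs,
                    costs_by_label[f"incline_{tr.pre_transition_grade}"],
                    costs_by_label["incline_0"],
                    pre_transition_grade=tr.pre_transition_grade,
                )
            )
        else:
            logger.info(
                "participant %s: no evaluable CCP (pre-transition %s, monotone %s)",
                pid,
                tr.pre_transition_grade,
                tr.monotone,
            )

    costs_df = pd.DataFrame(cost_rows)
    transitions = pd.DataFrame(transitions_rows).set_index("participant")

    summary_ccp = ccp_summary(ccp_results, restrict_to_ccp=True) if ccp_results else pd.DataFrame()
    summary_all = ccp_summary(ccp_results, restrict_to_ccp=False) if ccp_results else pd.DataFrame()

    comparisons = _condition_comparisons(costs_df, transitions, cfg)

    return CohortAnalysis(
        costs=costs_df,
        choices=all_choices,
        transitions=transitions,
        ccp_results=ccp_results,
        summary_ccp=summary_ccp,
        summary_all=summary_all,
        comparisons=comparisons,
        trial_analyses=analyses,
    )


def _condition_comparisons(
    costs_df: pd.DataFrame, transitions: pd.DataFrame, cfg: RunConfig
) -> dict[str, ConditionComparison]:
    """Crouch vs pre- vs post-transition comparison per cost metric."""
    out: dict[str, ConditionComparison] = {}
    wide = costs_df.set_index(["participant", "condition"])
    for metric in ("c_met_p", "c_a2", "c_a_max", "c_a_vol"):
        rows = {}
        for pid, tr in transitions.iterrows():
            pre, post = tr["pre_transition_grade"], tr["post_transition_grade"]
            if pd.isna(pre) or pd.isna(post) or not tr["monotone"]:
                continue
            try:
                rows[pid] = {
                    "crouch": wide.loc[(pid, "crouch"), metric],
                    "pre": wide.loc[(pid, f"incline_{int(pre)}"), metric],
                    "post": wide.loc[(pid, f"incline_{int(post)}"), metric],
                }
            except KeyError:
                continue
        df = pd.DataFrame.from_dict(rows, orient="index").dropna()
        if len(df) >= 3:
            out[metric] = compare_conditions(
                df, alpha=cfg.alpha, posthoc_alpha=cfg.posthoc_alpha, variable=metric
            )
    return out


def _comparison_to_dict(c: ConditionComparison) -> dict:
    return {
        "branch": c.branch,
        "normality_p": dict(c.normality_p),
        "omnibus_test": c.omnibus_test,
        "omnibus_stat": c.omnibus_stat,
        "omnibus_p": c.omnibus_p,
        "significant": c.significant,
        "posthoc": c.posthoc.to_dict(orient="records") if len(c.posthoc) else [],
    }


def ccp_results_frame(results: Sequence[CcpResult]) -> pd.DataFrame:
    """One row per participant mirroring the worked-example table layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "participant": r.participant_id,
                "pre_transition_grade": r.pre_transition_grade,
                "cmet_crouch": r.crouch_pct["c_met_p"],
                "cmet_pre": r.incline_pct["c_met_p"],
                "ca2_crouch": r.crouch_pct["c_a2"],
                "ca2_pre": r.incline_pct["c_a2"],
                "ccp_a2": {True: "Y", False: "N", None: ""}[r.ccp_a2],
                "camax_crouch": r.crouch_pct["c_a_max"],
                "camax_pre": r.incline_pct["c_a_max"],
                "ccp_amax": {True: "Y", False: "N", None: ""}[r.ccp_a_max],
                "cavol_crouch": r.crouch_pct["c_a_vol"],
                "cavol_pre": r.incline_pct["c_a_vol"],
                "ccp_avol": {True: "Y", False: "N", None: ""}[r.ccp_a_vol],
                "advantage_a2": r.advantage_a2,
                "advantage_a_max": r.advantage_a_max,
                "advantage_a_vol": r.advantage_a_vol,
                "penalty_met": r.penalty_met,
            }
        )
    return pd.DataFrame(rows)


def ccp_from_frames(
    costs_df: pd.DataFrame,
    choices_df: pd.DataFrame,
    grades: Sequence[int] = PROTOCOL_GRADES,
) -> tuple[list[CcpResult], pd.DataFrame]:
    """CCP analysis from persisted ``costs.csv`` / ``choices.csv`` tables.

    ``costs_df`` is the long cost table (one row per participant ×
    condition, including the aggregated ``crouch`` row); ``choices_df``
    has columns participant, grade, selected.
    """
    wide = costs_df.set_index(["participant", "condition"])
    results: list[CcpResult] = []
    transitions_rows = []

    def tc(pid: str, cond: str) -> TrialCosts:
        row = wide.loc[(pid, cond)]
        return TrialCosts(
            c_met_p=float(row["c_met_p"]),
            c_a2=float(row["c_a2"]),
            c_a_max=float(row["c_a_max"]),
            c_a_vol=float(row["c_a_vol"]),
            condition=cond,
            participant_id=str(pid),
        )

    for pid, grp in choices_df.groupby("participant"):
        seq = ChoiceSequence(
            participant_id=str(pid),
            choices={int(r["grade"]): str(r["selected"]) for _, r in grp.iterrows()},
        )
        tr = identify_transitions(seq, grades)
        transitions_rows.append(
            {
                "participant": pid,
                "pre_transition_grade": tr.pre_transition_grade,
                "post_transition_grade": tr.post_transition_grade,
                "monotone": tr.monotone,
            }
        )
        if tr.pre_transition_grade is None or not tr.monotone:
            continue
        results.append(
            evaluate_ccp(
                tc(pid, "crouch"),
                tc(pid, f"incline_{tr.pre_transition_grade}"),
                tc(pid, "incline_0"),
                pre_transition_grade=tr.pre_transition_grade,
            )
        )
    transitions = pd.DataFrame(transitions_rows).set_index("participant")
    return results, transitions


def plot_condition_costs(costs_df: pd.DataFrame, grades: Sequence[int], path: Path) -> None:
    """Line plots of cohort mean ± s.d. of each cost across grade, with crouch."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [
        ("c_met_p", "Metabolic power (W kg$^{-1}$)"),
        ("c_a2", "Mean squared activation"),
        ("c_a_max", "Max activation"),
        ("c_a_vol", "Volume-weighted activation"),
    ]
    fig, axes = plt.subplots(1, 4, figsize=(16, 3.6))
    for ax, (metric, label) in zip(axes, metrics):
        means, sds = [], []
        for g in grades:
            v = costs_df.loc[costs_df["condition"] == f"incline_{g}", metric]
            means.append(v.mean())
            sds.append(v.std())
        ax.errorbar(list(grades), means, yerr=sds, marker="o", capsize=3, label="incline")
        cr = costs_df.loc[costs_df["condition"] == "crouch", metric]
        ax.axhline(cr.mean(), color="tab:red", ls="--", label="crouch mean")
        ax.fill_between(
            [min(grades), max(grades)],
            cr.mean() - cr.std(),
            cr.mean() + cr.std(),
            color="tab:red",
            alpha=0.15,
        )
        ax.set_xlabel("incline grade (%)")
        ax.set_title(label, fontsize=10)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_experiment(
    config: RunConfig,
    outdir: Path,
    cohort: Optional[Mapping[str, Mapping[str, TrialRecording]]] = None,
    write_raw: bool = False,
) -> CohortAnalysis:
    """Simulation-mode end-to-end run, writing the artifact bundle.

    Generates a cohort from the config seed (unless one is supplied),
    analyses it, and writes ``costs.csv``, ``choices.csv``,
    ``ccp_results.csv``, ``group_summary.json``, ``report.png`` and a
    ``run_manifest.json`` recording the full configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        logger.info("generating cohort: n=%d, seed=%d", config.n_participants, config.seed)
        profiles = default_profiles(config.n_participants, seed=config.seed)
        cohort = generate_cohort(
            profiles,
            grades=config.grades,
            duration=config.trial_duration,
            seed=config.seed,
            carrier=config.carrier,
            breath_noise_cv=config.breath_noise_cv,
        )
        if write_raw:
            write_cohort(cohort, outdir / "cohort")

    analysis = run_cohort_analysis(cohort, config=config)

    analysis.costs.to_csv(outdir / "costs.csv", index=False, float_format="%.10g")
    choice_rows = [
        {"participant": pid, "grade": g, "selected": sel}
        for pid, seq in analysis.choices.items()
        for g, sel in sorted(seq.choices.items())
    ]
    pd.DataFrame(choice_rows).to_csv(outdir / "choices.csv", index=False)
    ccp_results_frame(analysis.ccp_results).to_csv(
        outdir / "ccp_results.csv", index=False, float_format="%.6g"
    )
    summary = {
        "ccp_subset": analysis.summary_ccp.to_dict(orient="index"),
        "all_participants": analysis.summary_all.to_dict(orient="index"),
        "n_ccp": int(sum(r.ccp_a2 is True for r in analysis.ccp_results)),
        "n_evaluable": int(sum(r.has_activation for r in analysis.ccp_results)),
        "comparisons": {k: _comparison_to_dict(v) for k, v in analysis.comparisons.items()},
    }
    (outdir / "group_summary.json").write_text(json.dumps(summary, indent=1))
    plot_condition_costs(analysis.costs, config.grades, outdir / "report.png")
    manifest = {"package_version": _pkg_version, "config": config.to_dict()}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("experiment artifacts written to %s", outdir)
    return analysis
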