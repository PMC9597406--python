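"""Plain-text persistence for trials and derived artifacts.

One directory per trial: ``emg.csv`` (time_s + seven muscle columns,
volts), ``grf.csv`` (time_s, fz_n), ``breaths.csv`` (time_s, vo2_l_s,
vco2_l_s) and ``meta.json``. A cohort directory holds one trial
directory per (participant, condition) plus a ``cohort.json`` manifest.
Derived artifacts are ``strides.json``, ``activation.csv``,
``energetics.json``, ``costs.csv`` and ``ccp_results.csv`` /
``group_summary.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .emg import MUSCLES, ActivationTable
from .energetics import MetabolicResult
from .gait_events import StrideWindows
from .synthetic import TrialRecording

__all__ = [
    "write_trial",
    "read_trial",
    "write_cohort",
    "read_cohort",
    "write_strides",
    "read_strides",
    "write_activation",
    "write_energetics",
]


def write_trial(rec: TrialRecording, path: Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    emg = rec.emg.copy()
    emg.insert(0, "time_s", rec.time)
    emg.to_csv(path / "emg.csv", index=False, float_format="%.8g")
    pd.DataFrame({"time_s": rec.time, "fz_n": rec.grf}).to_csv(
        path / "grf.csv", index=False, float_format="%.8g"
    )
    rec.breaths.to_csv(path / "breaths.csv", index=False, float_format="%.8g")
    meta = {
        "participant_id": rec.participant_id,
        "condition": rec.condition,
        "mass_kg": rec.mass,
        "speed_m_s": rec.belt_speed,
        "duration_s": rec.duration,
        "sampling_rate_hz": rec.sampling_rate,
        "excluded_channels": sorted(rec.excluded_channels),
    }
    if rec.truth is not None:
        meta["truth"] = {
            "gains_v": rec.truth.gains.to_dict(),
            "contact_times_s": rec.truth.contact_times.tolist(),
            "vo2_target_l_s": rec.truth.vo2_target,
            "vco2_target_l_s": rec.truth.vco2_target,
            "c_met_target_w_kg": rec.truth.c_met_target,
            "stance_duration_s": rec.truth.stance_duration,
        }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_trial(path: Path) -> TrialRecording:
    from .synthetic import TrialTruth

    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    emg = pd.read_csv(path / "emg.csv")
    grf = pd.read_csv(path / "grf.csv")["fz_n"].to_numpy()
    breaths = pd.read_csv(path / "breaths.csv")
    truth = None
    if "truth" in meta:
        tr = meta["truth"]
        truth = TrialTruth(
            gains=pd.Series(tr["gains_v"]),
            contact_times=np.asarray(tr["contact_times_s"]),
            stride_times=np.diff(np.asarray(tr["contact_times_s"])),
            vo2_target=tr["vo2_target_l_s"],
            vco2_target=tr["vco2_target_l_s"],
            c_met_target=tr["c_met_target_w_kg"],
            stance_duration=tr["stance_duration_s"],
        )
    return TrialRecording(
        participant_id=meta["participant_id"],
        condition=meta["condition"],
        emg=emg[list(MUSCLES)],
        grf=grf,
        breaths=breaths,
        duration=meta["duration_s"],
        belt_speed=meta["speed_m_s"],
        mass=meta["mass_kg"],
        sampling_rate=meta["sampling_rate_hz"],
        excluded_channels=frozenset(meta.get("excluded_channels", ())),
        truth=truth,
    )


def write_cohort(cohort: Mapping[str, Mapping[str, TrialRecording]], path: Path) -> None:
    path = Path(path)
    manifest: dict[str, list[str]] = {}
    for pid, trials in cohort.items():
        manifest[pid] = list(trials)
        for label, rec in trials.items():
            write_trial(rec, path / pid / label)
    (path / "cohort.json").write_text(json.dumps(manifest, indent=1))


def read_cohort(path: Path) -> dict[str, dict[str, TrialRecording]]:
    path = Path(path)
    manifest = json.loads((path / "cohort.json").read_text())
    return {
        pid: {label: read_trial(path / pid / label) for label in labels}
        for pid, labels in manifest.items()
    }


def write_strides(sw: StrideWindows, path: Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "contact_indices": sw.contact_indices.tolist(),
                "stride_durations_s": sw.stride_durations.tolist(),
                "sampling_rate_hz": sw.sampling_rate,
                "threshold_n": sw.threshold_value,
            },
            indent=1,
        )
    )


def read_strides(path: Path) -> StrideWindows:
    d = json.loads(Path(path).read_text())
    return StrideWindows(
        contact_indices=np.asarray(d["contact_indices"], dtype=np.intp),
        stride_durations=np.asarray(d["stride_durations_s"]),
        sampling_rate=d["sampling_rate_hz"],
        threshold_value=d["threshold_n"],
    )


def write_activation(table: ActivationTable, path: Path) -> None:
    rows = []
    for m in table.muscles:
        for k, col in enumerate(table.a.columns, start=1):
            rows.append(
                {
                    "muscle": m,
                    "stride": k,
                    "a": table.a.loc[m, col],
                    "A": table.A.loc[m, col],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def write_energetics(res: MetabolicResult, path: Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "vo2_mean_l_s": res.vo2_mean,
                "vco2_mean_l_s": res.vco2_mean,
                "c_met_p_w_kg": res.c_met_p,
                "window_s": list(res.window),
                "n_breaths": res.n_breaths,
            },
            indent=1,
        )
    )
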