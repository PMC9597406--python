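"""Steady-state metabolic power from breath-by-breath gas exchange.

Mass-specific whole-body metabolic power is computed from the rates of
oxygen uptake and carbon dioxide production (L s⁻¹), averaged over the
final minute of a trial, via the stoichiometric relation

    C_met,P = 1000 * (16.89 * V̇O₂ + 4.82 * V̇CO₂) / M      [W kg⁻¹]

with M the participant's body mass in kg. Because belt speed is constant
across the conditions compared, no conversion to cost per distance is
applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

__all__ = ["MetabolicResult", "metabolic_power", "VO2_COEFF_W", "VCO2_COEFF_W"]

logger = logging.getLogger(__name__)

# stoichiometric coefficients, W per (L s^-1), before the /M and x1000
VO2_COEFF_W = 16.89
VCO2_COEFF_W = 4.82

MIN_BREATHS = 5


@dataclass(frozen=True)
class MetabolicResult:
    """Final-minute gas-exchange means and the derived metabolic power."""

    vo2_mean: float  # L s^-1
    vco2_mean: float  # L s^-1
    c_met_p: float  # W kg^-1
    window: tuple[float, float]  # (start s, end s)
    n_breaths: int

    @property
    def rer(self) -> float:
        """Respiratory exchange ratio V̇CO₂/V̇O₂ over the window."""
        return self.vco2_mean / self.vo2_mean if self.vo2_mean > 0 else float("nan")


def metabolic_power(
    breaths: pd.DataFrame,
    mass: float,
    trial_duration: float,
    window: float = 60.0,
    units: str = "L/s",
) -> MetabolicResult:
    """Average gas-exchange rates over the final window and apply Eq. above.

    Parameters
    ----------
    breaths : DataFrame
        Columns ``time_s``, ``vo2``, ``vco2`` (aliases ``vo2_l_s`` /
        ``vco2_l_s`` accepted). Timestamps in seconds from trial start.
    mass : float
        Body mass, kg.
    trial_duration : float
        Trial length in seconds; the averaging window is
        ``[trial_duration - window, trial_duration]``, closed at both
        ends.
    window : float
        Averaging window length, seconds (default 60, the final minute).
    units : {"L/s", "mL/min"}
        Units of the rate columns; ``"mL/min"`` values are divided by
        60000.

    Raises
    ------
    DataError
        If fewer than 5 breaths fall in the window, or any rate is
        negative.
    ConfigurationError
        For non-positive mass/window or unknown units.
    """
    if mass <= 0:
        raise ConfigurationError("mass must be positive")
    if window <= 0 or trial_duration <= 0:
        raise ConfigurationError("window and trial_duration must be positive")

    df = breaths.rename(columns={"vo2_l_s": "vo2", "vco2_l_s": "vco2"})
    missing = {"time_s", "vo2", "vco2"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"breath table missing columns {sorted(missing)}")

    vo2 = df["vo2"].to_numpy(dtype=float)
    vco2 = df["vco2"].to_numpy(dtype=float)
    t = df["time_s"].to_numpy(dtype=float)
    if units == "mL/min":
        vo2 = vo2 / 60000.0
        vco2 = vco2 / 60000.0
    elif units != "L/s":
        raise ConfigurationError(f"unknown units {units!r}; use 'L/s' or 'mL/min'")
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise DataError("negative gas-exchange rates")

    start = trial_duration - window
    sel = (t >= start) & (t <= trial_duration)
    n = int(sel.sum())
    if n < MIN_BREATHS:
        raise DataError(
            f"insufficient steady-state data: {n} breaths in the final "
            f"{window:g} s window (need >= {MIN_BREATHS})"
        )

    vo2_mean = float(vo2[sel].mean())
    vco2_mean = float(vco2[sel].mean())
    c_met_p = 1000.0 * (VO2_COEFF_W * vo2_mean + VCO2_COEFF_W * vco2_mean) / mass

    if vo2_mean > 0 and vco2_mean / vo2_mean > 1.05:
        logger.warning(
            "window-mean RER %.3f exceeds 1.05; steady aerobic state questionable",
            vco2_mean / vo2_mean,
        )

    return MetabolicResult(
        vo2_mean=vo2_mean,
        vco2_mean=vco2_mean,
        c_met_p=c_met_p,
        window=(start, trial_duration),
        n_breaths=n,
    )
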