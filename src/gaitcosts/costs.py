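"""Weighted muscle-activation cost functions.

All three trial-level activation costs are instances of one generic
per-stride form: a weighted average of normalized activations raised to
an exponent p,

    C̄_j = (Σ_i w_i A_ij^p) / (Σ_i w_i),

averaged over the five analysed strides (cost per stride first, then the
stride mean — for the max cost this means max-then-average).

* ``C̄a²`` — w_i = 1, p = 2. "Fatigue-like": penalizes large activations
  in any muscle regardless of its size.
* ``C̄a,max`` — w_i = 1, p → ∞, i.e. the per-stride maximum over
  muscles. The most extreme fatigue-like form: only the maximally
  activated muscle contributes.
* ``C̄a,vol`` — w_i = muscle volume fraction, p = 1. "Effort-like":
  tracks active muscle volume, a key determinant of muscle energy use,
  so it is most sensitive to the large muscles.

The volume weights are the seven muscles' volumes as proportions of
their sum, fixed at two decimals so the arithmetic is exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .emg import ActivationTable
from .energetics import MetabolicResult
from .exceptions import ConfigurationError, IncompleteActivationError

__all__ = [
    "VOLUME_WEIGHTS",
    "CostFunctionSpec",
    "TrialCosts",
    "generic_cost",
    "trial_costs",
]

#: Muscle volume fractions (Gmax, BF, RF, VM, MG, SOL, TA); sum to 1.00.
VOLUME_WEIGHTS = pd.Series(
    {"Gmax": 0.33, "BF": 0.08, "RF": 0.10, "VM": 0.17, "MG": 0.10, "SOL": 0.17, "TA": 0.05}
)


@dataclass(frozen=True)
class CostFunctionSpec:
    """Weights and exponent defining one activation cost.

    ``exponent`` may be ``math.inf``, selecting the per-stride maximum
    over muscles exactly (not a large-p approximation). ``weights`` may
    be a scalar (equal weights) or a per-muscle Series; weights are
    ignored at p = ∞.
    """

    weights: Union[float, pd.Series] = 1.0
    exponent: float = 1.0

    def __post_init__(self) -> None:
        w = self.weights
        if isinstance(w, pd.Series):
            if (w < 0).any():
                raise ConfigurationError("weights must be non-negative")
            if not (w > 0).any():
                raise ConfigurationError("at least one weight must be positive")
        elif w <= 0:
            raise ConfigurationError("scalar weight must be positive")
        if not (self.exponent >= 1):
            raise ConfigurationError("exponent must be >= 1 (or math.inf)")


@dataclass(frozen=True)
class TrialCosts:
    """The four per-trial cost scalars.

    ``c_met_p`` is mass-specific metabolic power (W kg⁻¹); the three
    activation costs are unitless (activations are baseline-normalized).
    For any one activation table the Jensen/max bounds
    ``c_a_vol <= c_a_max`` and ``c_a2 <= c_a_max**2`` hold.
    """

    c_met_p: float
    c_a2: float
    c_a_max: float
    c_a_vol: float
    condition: str = ""
    participant_id: str = ""

    def activation_costs(self) -> dict[str, float]:
        return {"c_a2": self.c_a2, "c_a_max": self.c_a_max, "c_a_vol": self.c_a_vol}


def _complete_A(table: ActivationTable) -> pd.DataFrame:
    A = table.A
    bad = A.isna().any(axis=1)
    if bad.any():
        raise IncompleteActivationError(
            f"incomplete activation table: missing channels {list(A.index[bad])}"
        )
    return A


def generic_cost(
    table: ActivationTable, spec: CostFunctionSpec
) -> tuple[np.ndarray, float]:
    """Evaluate the generic weighted activation cost on a table.

    Returns
    -------
    per_stride : ndarray
        ``C̄_j`` for each analysed stride.
    mean : float
        Their unweighted mean over the strides.

    Raises
    ------
    IncompleteActivationError
        If any muscle row is missing — the cost is defined over all
        seven muscles and is never silently renormalized.
    """
    A = _complete_A(table)

    if math.isinf(spec.exponent):
        per_stride = A.max(axis=0).to_numpy(dtype=float)
    else:
        if isinstance(spec.weights, pd.Series):
            w = spec.weights.reindex(A.index)
            if w.isna().any():
                raise ConfigurationError(
                    f"weights missing for muscles {list(A.index[w.isna()])}"
                )
            w = w.to_numpy(dtype=float)
        else:
            w = np.full(A.shape[0], float(spec.weights))
        Ap = A.to_numpy(dtype=float) ** spec.exponent
        per_stride = (w @ Ap) / w.sum()
    return per_stride, float(per_stride.mean())


def trial_costs(
    table: ActivationTable,
    metabolic: Optional[MetabolicResult] = None,
    condition: str = "",
    participant_id: str = "",
) -> TrialCosts:
    """Compute the three activation costs (and attach metabolic power).

    ``c_a2`` uses equal weights and p = 2; ``c_a_max`` is the exact
    per-stride maximum (p = ∞); ``c_a_vol`` uses the volume weights and
    p = 1. Each is the mean of its per-stride values over the five
    strides. ``c_met_p`` is copied from ``metabolic`` (NaN if absent,
    e.g. when only activation data are being processed).
    """
    _, c_a2 = generic_cost(table, CostFunctionSpec(weights=1.0, exponent=2.0))
    _, c_a_max = generic_cost(table, CostFunctionSpec(weights=1.0, exponent=math.inf))
    _, c_a_vol = generic_cost(table, CostFunctionSpec(weights=VOLUME_WEIGHTS, exponent=1.0))
    return TrialCosts(
        c_met_p=metabolic.c_met_p if metabolic is not None else float("nan"),
        c_a2=c_a2,
        c_a_max=c_a_max,
        c_a_vol=c_a_vol,
        condition=condition,
        participant_id=participant_id,
    )
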