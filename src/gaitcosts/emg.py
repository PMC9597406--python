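"""Surface-EMG linear envelopes and per-stride activation rates.

The processing chain is the standard linear-envelope recipe: remove the
DC offset, band-pass 20–350 Hz (movement artefact and high-frequency
noise), full-wave rectify, low-pass at 6 Hz. Filters are fourth-order
Butterworth applied forward–backward (zero phase), so burst timing is
preserved relative to the GRF-derived stride boundaries.

Per stride ``j`` and muscle ``i`` the activation rate is the
time-averaged envelope

    a_ij = (1 / T_j) * integral over stride j of EMG_env,

a quantity with the units of the envelope itself, reflecting both how
much of the muscle is active (the integral) and how often it is recruited
(the 1/T_j rate factor). Normalizing by the muscle's mean activation in
the level-walking trial gives the unitless A_ij used by the cost
functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .exceptions import (
    ConfigurationError,
    DataError,
    DegenerateBaselineError,
    InsufficientStridesError,
)
from .gait_events import StrideWindows

__all__ = [
    "MUSCLES",
    "EnvelopeSeries",
    "ActivationTable",
    "compute_envelope",
    "compute_activation_table",
]

#: Recorded muscles, in canonical order: gluteus maximus, biceps femoris,
#: rectus femoris, vastus medialis, medial gastrocnemius, soleus,
#: tibialis anterior.
MUSCLES: tuple[str, ...] = ("Gmax", "BF", "RF", "VM", "MG", "SOL", "TA")

DEFAULT_STRIDE_COUNT = 5


@dataclass(frozen=True)
class EnvelopeSeries:
    """Linear envelope of one EMG channel.

    Samples are non-negative (rectification; low-pass ringing is clipped
    at zero) and share the raw channel's length and sampling rate.
    """

    muscle: str
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if np.any(s < 0):
            raise ValueError("envelope samples must be non-negative")


def compute_envelope(
    raw_emg: np.ndarray,
    sampling_rate: float,
    muscle: str = "",
    band: tuple[float, float] = (20.0, 350.0),
    lowpass: float = 6.0,
    order: int = 4,
) -> EnvelopeSeries:
    """Compute the linear envelope of a raw EMG channel.

    Pipeline: subtract the channel mean (DC offset) → zero-phase
    Butterworth band-pass (``band``, nominal order ``order``) → absolute
    value → zero-phase Butterworth low-pass (``lowpass``) → clip negatives
    to zero. Every stage is positively homogeneous, so scaling the input
    by k > 0 scales the envelope by k.

    Raises
    ------
    ConfigurationError
        If the upper band edge is at or above the Nyquist frequency.
    DataError
        If the channel contains non-finite samples.
    """
    x = np.asarray(raw_emg, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("raw_emg must be one-dimensional")
    lo, hi = band
    if not 0 < lo < hi:
        raise ConfigurationError(f"invalid band edges {band}")
    if sampling_rate <= 2 * hi:
        raise ConfigurationError(
            f"sampling rate {sampling_rate} Hz too low for band edge {hi} Hz "
            "(must exceed twice the upper band edge)"
        )
    if not np.all(np.isfinite(x)):
        label = muscle or "EMG channel"
        raise DataError(f"non-finite samples in {label}")
    if x.size < int(2 * sampling_rate):
        raise DataError("record shorter than 2 s; filter transients would dominate")

    x = x - x.mean()
    sos_bp = butter(order, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    x = sosfiltfilt(sos_bp, x)
    x = np.abs(x)
    sos_lp = butter(order, lowpass, btype="lowpass", fs=sampling_rate, output="sos")
    env = sosfiltfilt(sos_lp, x)
    np.clip(env, 0.0, None, out=env)
    return EnvelopeSeries(muscle=muscle, samples=env, sampling_rate=float(sampling_rate))


@dataclass(frozen=True)
class ActivationTable:
    """Per-stride activation rates for the seven muscles.

    Attributes
    ----------
    a : DataFrame, muscles × strides
        Activation rates ``a_ij`` (envelope units). Excluded channels are
        rows of NaN.
    A : DataFrame, muscles × strides
        Baseline-normalized activations ``A_ij = a_ij / baseline_means_i``
        (unitless).
    baseline_means : Series
        Per-muscle 5-stride mean activation of the level (0% incline)
        trial used for normalization.
    muscles : tuple of str
    stride_count : int
    """

    a: pd.DataFrame
    A: pd.DataFrame
    baseline_means: pd.Series
    muscles: tuple[str, ...] = MUSCLES
    stride_count: int = DEFAULT_STRIDE_COUNT

    @property
    def excluded(self) -> tuple[str, ...]:
        """Muscles whose rows are missing (NaN)."""
        bad = self.a.isna().any(axis=1)
        return tuple(self.a.index[bad])

    def mean_A(self) -> pd.Series:
        """Per-muscle mean normalized activation across the strides."""
        return self.A.mean(axis=1)


def _stride_integral_mean(
    env: np.ndarray, start: int, stop: int, sampling_rate: float
) -> float:
    # trapezoid on [start, stop] inclusive of both boundary samples;
    # divided by T = (stop - start)/fs this is the stride time-average
    seg = env[start : stop + 1]
    integral = np.trapezoid(seg) / sampling_rate
    duration = (stop - start) / sampling_rate
    return integral / duration


def compute_activation_table(
    envelopes: Mapping[str, EnvelopeSeries],
    strides: StrideWindows,
    baseline: Optional[ActivationTable] = None,
    stride_count: int = DEFAULT_STRIDE_COUNT,
    saturation: Optional[float] = None,
    muscles: Sequence[str] = MUSCLES,
) -> ActivationTable:
    """Integrate envelopes over strides to build an activation table.

    The first ``stride_count`` artifact-free complete strides are used,
    where a stride is artifact-free when no channel's envelope exceeds
    ``saturation`` within it (``None`` disables the screen). ``a_ij`` is
    the trapezoidal time-average of the envelope over stride ``j``.

    When ``baseline`` is None this trial is itself the level-walking
    reference: ``baseline_means`` are computed from its own ``a`` and the
    per-muscle mean of ``A`` over the strides is 1 by construction.
    Otherwise the supplied baseline's means are used.

    Channels absent from ``envelopes`` are carried as NaN rows and any
    cost computed over them fails loudly rather than silently
    renormalizing.

    Raises
    ------
    InsufficientStridesError
        If fewer than ``stride_count`` usable strides are available.
    DegenerateBaselineError
        If any baseline mean needed for normalization is zero.
    """
    if strides.n_strides < stride_count:
        raise InsufficientStridesError(
            f"{strides.n_strides} complete strides < required {stride_count}"
        )
    fs = strides.sampling_rate
    for name, env in envelopes.items():
        if env.sampling_rate != fs:
            raise ConfigurationError(
                f"envelope {name} sampling rate {env.sampling_rate} != GRF rate {fs}"
            )

    # select the first `stride_count` artifact-free strides
    chosen: list[int] = []
    for j in range(strides.n_strides):
        start = int(strides.contact_indices[j])
        stop = int(strides.contact_indices[j + 1])
        ok = True
        if saturation is not None:
            for env in envelopes.values():
                if np.any(env.samples[start : stop + 1] > saturation):
                    ok = False
                    break
        if ok:
            chosen.append(j)
        if len(chosen) == stride_count:
            break
    if len(chosen) < stride_count:
        raise InsufficientStridesError(
            f"only {len(chosen)} artifact-free strides of {stride_count} required"
        )

    cols = [f"stride_{k + 1}" for k in range(stride_count)]
    a = pd.DataFrame(np.nan, index=list(muscles), columns=cols, dtype=float)
    for name in muscles:
        if name not in envelopes:
            continue
        env = envelopes[name].samples
        for k, j in enumerate(chosen):
            start = int(strides.contact_indices[j])
            stop = int(strides.contact_indices[j + 1])
            if stop >= env.size:
                raise DataError(f"stride {j} extends past the end of channel {name}")
            a.iloc[a.index.get_loc(name), k] = _stride_integral_mean(env, start, stop, fs)

    if baseline is None:
        baseline_means = a.mean(axis=1)
    else:
        baseline_means = baseline.baseline_means.reindex(a.index)

    present = a.notna().all(axis=1)
    degenerate = present & (baseline_means.fillna(1.0) == 0.0)
    if degenerate.any():
        raise DegenerateBaselineError(
            f"zero baseline mean for {list(baseline_means.index[degenerate])}"
        )

    A = a.div(baseline_means, axis=0)
    return ActivationTable(
        a=a,
        A=A,
        baseline_means=baseline_means,
        muscles=tuple(muscles),
        stride_count=stride_count,
    )
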