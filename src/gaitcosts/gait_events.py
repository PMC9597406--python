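"""Foot-contact detection from the vertical ground reaction force.

Initial contacts are upward crossings of a relative force threshold
(default 2% of the record's peak force). A stride spans two consecutive
contacts of the same foot; its duration ``T_j`` normalizes the per-stride
activation integrals downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, InsufficientStridesError

__all__ = ["StrideWindows", "detect_strides"]


@dataclass(frozen=True)
class StrideWindows:
    """Detected initial contacts and the strides between them.

    Attributes
    ----------
    contact_indices : ndarray of int
        Sample indices of initial foot contacts, strictly increasing.
    stride_durations : ndarray of float
        ``T_j = (contact[j+1] - contact[j]) / sampling_rate`` in seconds;
        one entry per complete stride.
    sampling_rate : float
        Hz.
    threshold_value : float
        Absolute force threshold used for detection (N), recorded for audit.
    """

    contact_indices: np.ndarray
    stride_durations: np.ndarray
    sampling_rate: float
    threshold_value: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.contact_indices, dtype=np.intp)
        dur = np.asarray(self.stride_durations, dtype=float)
        object.__setattr__(self, "contact_indices", idx)
        object.__setattr__(self, "stride_durations", dur)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("contact_indices must be strictly increasing")
        if np.any(dur <= 0):
            raise ValueError("stride_durations must be positive")

    @property
    def n_strides(self) -> int:
        return int(self.stride_durations.size)

    @property
    def contact_times(self) -> np.ndarray:
        """Contact times in seconds."""
        return self.contact_indices / self.sampling_rate


def detect_strides(
    grf: np.ndarray,
    sampling_rate: float,
    threshold_fraction: float = 0.02,
    refractory: float = 0.2,
) -> StrideWindows:
    """Detect initial contacts as threshold crossings of the vertical GRF.

    A contact is the first sample at or above ``threshold_fraction *
    max(grf)`` following a sample below it (0-based indexing). After each
    contact, crossings within ``refractory`` seconds are ignored; this
    suppresses chatter from force noise around the threshold without
    affecting physiological stride times (well above 0.8 s in walking).

    Parameters
    ----------
    grf : array_like
        Non-negative vertical force samples (N).
    sampling_rate : float
        Hz.
    threshold_fraction : float
        Fraction of the record's peak force, in (0, 1). Default 0.02.
    refractory : float
        Dead time after each detected contact, seconds.

    Returns
    -------
    StrideWindows

    Raises
    ------
    ConfigurationError
        If ``threshold_fraction`` is outside (0, 1) or the sampling rate
        is not positive.
    InsufficientStridesError
        If fewer than two contacts are found (no complete stride), which
        includes the all-zero signal.
    """
    grf = np.asarray(grf, dtype=float)
    if not 0.0 < threshold_fraction < 1.0:
        raise ConfigurationError(
            f"threshold_fraction must be in (0, 1); got {threshold_fraction}"
        )
    if sampling_rate <= 0:
        raise ConfigurationError("sampling_rate must be positive")
    if grf.ndim != 1:
        raise ConfigurationError("grf must be one-dimensional")
    if np.any(grf < 0):
        raise ConfigurationError("grf must be non-negative")

    peak = float(grf.max(initial=0.0))
    if peak <= 0:
        raise InsufficientStridesError("GRF signal is identically zero")
    threshold = threshold_fraction * peak

    above = grf >= threshold
    # upward crossings: below at i-1, at-or-above at i
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        # record starts mid-stance; that contact is incomplete, skip it
        pass

    refractory_samples = int(round(refractory * sampling_rate))
    contacts: list[int] = []
    last = -np.inf
    for c in crossings:
        if c - last > refractory_samples:
            contacts.append(int(c))
            last = c

    if len(contacts) < 2:
        raise InsufficientStridesError(
            f"found {len(contacts)} contact(s); need at least 2 for one stride"
        )

    idx = np.asarray(contacts, dtype=np.intp)
    durations = np.diff(idx) / sampling_rate
    return StrideWindows(
        contact_indices=idx,
        stride_durations=durations,
        sampling_rate=float(sampling_rate),
        threshold_value=threshold,
    )
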