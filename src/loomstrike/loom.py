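"""Angular-size kinematics of a looming (virtually approaching) object.

A dark disk expanding on a screen mimics an object of radius ``r``
approaching the viewer at constant speed ``v``.  The visual angle it
subtends ``t`` milliseconds before (virtual) contact is

    theta(t) = 2 * atan((r/v) / t)

so the whole expansion profile depends on the size-to-speed ratio ``r/v``
(in ms) alone: a large object approaching fast looks the same as a small
object approaching slowly.  Small ``r/v`` therefore means a fast-seeming
approach.  The stimulus starts at an onset angle and stops expanding at a
fixed maximum angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoomStimulus",
    "FractionEscaped",
    "angular_size",
    "time_to_reach",
    "theoretical_contact_time",
    "fraction_escaped_before_contact",
    "expansion_profile",
]


@dataclass(frozen=True)
class LoomStimulus:
    """A virtual constant-velocity approach stimulus.

    Parameters
    ----------
    r_over_v:
        Size-to-speed ratio of the virtual object, in ms.  Fully
        determines the expansion kinematics.
    theta_onset:
        Angular size (deg) at which the stimulus appears.
    theta_max:
        Fixed angular size (deg) at which expansion stops.
    onset_time:
        Experiment-clock time (ms) of stimulus onset.
    """

    r_over_v: float
    theta_onset: float = 10.0
    theta_max: float = 90.0
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.r_over_v > 0:
            raise ValueError(f"r_over_v must be positive, got {self.r_over_v}")
        if not (0 < self.theta_onset < self.theta_max <= 180):
            raise ValueError(
                "require 0 < theta_onset < theta_max <= 180, got "
                f"theta_onset={self.theta_onset}, theta_max={self.theta_max}"
            )


def angular_size(stim: LoomStimulus, t_before_contact: float) -> float:
    """Angular size (deg) of the virtual object ``t_before_contact`` ms before contact.

    Monotonically non-increasing in ``t_before_contact``; the expansion is
    clipped at ``stim.theta_max`` (the stimulus stops growing there).

    Raises
    ------
    ValueError
        If ``t_before_contact`` is not strictly positive (virtual contact
        already reached).
    """
    if not t_before_contact > 0:
        raise ValueError(
            f"t_before_contact must be > 0 (contact reached at 0), got {t_before_contact}"
        )
    theta = 2.0 * math.atan(stim.r_over_v / t_before_contact)
    return min(math.degrees(theta), stim.theta_max)


def time_to_reach(stim: LoomStimulus, theta: float) -> float:
    """Time before virtual contact (ms) at which the stimulus subtends ``theta`` degrees.

    Inverse of :func:`angular_size` on the open expansion domain:
    ``t = (r/v) / tan(theta/2)``.

    Raises
    ------
    ValueError
        If ``theta`` is outside (0, 180) degrees.
    """
    if not (0 < theta < 180):
        raise ValueError(f"theta must lie in (0, 180) degrees, got {theta}")
    return stim.r_over_v / math.tan(math.radians(theta) / 2.0)


def theoretical_contact_time(stim: LoomStimulus) -> float:
    """Experiment-clock time (ms) of hypothetical contact with the virtual object.

    Contact occurs ``time_to_reach(stim, theta_onset)`` ms after stimulus
    onset, since the expansion starts at ``theta_onset``.
    """
    return stim.onset_time + time_to_reach(stim, stim.theta_onset)


@dataclass(frozen=True)
class FractionEscaped:
    """Proportion of flies that took off before hypothetical contact.

    ``denominator`` records whether the proportion is over all sequences or
    over responders (sequences with a take-off) only.
    """

    value: float
    denominator: str
    n_denominator: int
    n_before_contact: int
    contact_time: float


def fraction_escaped_before_contact(
    seqs: Sequence,
    stim: LoomStimulus,
    denominator: str = "responders",
) -> FractionEscaped:
    """Likelihood that flies took off before the hypothetical time-of-contact.

    Parameters
    ----------
    seqs:
        Escape sequences with ``took_off`` and ``escape_time`` attributes;
        ``escape_time`` is on the same experiment clock as ``stim``.
    denominator:
        ``"responders"`` counts only sequences that took off; ``"all"``
        counts every sequence (non-responders trivially did not escape
        before contact).
    """
    if len(seqs) == 0:
        raise ValueError("no escape sequences given")
    if denominator not in ("responders", "all"):
        raise ValueError(f"unknown denominator choice {denominator!r}")
    contact = theoretical_contact_time(stim)
    responders = [s for s in seqs if s.took_off]
    n_before = sum(1 for s in responders if s.escape_time < contact)
    if denominator == "responders":
        if not responders:
            raise ValueError("no take-offs among sequences (responders denominator empty)")
        n_den = len(responders)
    else:
        n_den = len(seqs)
    return FractionEscaped(
        value=n_before / n_den,
        denominator=denominator,
        n_denominator=n_den,
        n_before_contact=n_before,
        contact_time=contact,
    )


def expansion_profile(stim: LoomStimulus, step_ms: float = 1.0) -> pd.DataFrame:
    """Tabulate the expansion time course from onset to (just before) contact.

    Returns a DataFrame with columns ``t_ms`` (time since stimulus onset) and
    ``theta_deg``.  The final row is one step before virtual contact; the
    angle column saturates at ``theta_max``.
    """
    t_contact = time_to_reach(stim, stim.theta_onset)
    t = np.arange(0.0, t_contact, step_ms)
    countdown = t_contact - t
    theta = np.degrees(2.0 * np.arctan(stim.r_over_v / countdown))
    theta = np.minimum(theta, stim.theta_max)
    return pd.DataFrame({"t_ms": t, "theta_deg": theta})
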