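"""Escape take-off timing and mode classification.

A fly's escape take-off sequence runs from the first frame of wing raising
(the *reaction time*, latency from stimulus onset) to the first frame the
middle jumping legs leave the ground (the *escape time*).  The sequence
duration separates two motor programmes: a fast *short mode* (< 7 ms,
driven by the giant-fibre pathway) and a slower *long mode* (> 7 ms,
driven by other descending pathways).  The 7 ms boundary is the
intersection point of the two duration-distribution modes; it can be
re-estimated from data with a two-component Gaussian mixture on
log-durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .competition import two_sample_t, wilson_interval

__all__ = [
    "EscapeSequence",
    "ModeBoundary",
    "UnimodalDurationsError",
    "DEFAULT_BOUNDARY_MS",
    "duration",
    "classify_mode",
    "estimate_mode_boundary",
    "takeoff_rate",
    "short_mode_percentage",
    "timing_summaries",
    "downsample_to_match",
    "read_ethograms",
]

DEFAULT_BOUNDARY_MS = 7.0


@dataclass(frozen=True)
class EscapeSequence:
    """Per-fly take-off annotation on the stimulus clock (ms since onset)."""

    took_off: bool
    wing_raise_time: float = math.nan
    legs_leave_time: float = math.nan
    frame_rate: float = 6000.0
    genotype_label: str = ""
    stimulus_rv: float = math.nan
    fly_id: str = ""

    def __post_init__(self) -> None:
        if self.took_off:
            if not self.legs_leave_time > self.wing_raise_time:
                raise ValueError(
                    "take-off requires legs_leave_time > wing_raise_time, got "
                    f"raise={self.wing_raise_time}, leave={self.legs_leave_time}"
                )
            if self.wing_raise_time < 0:
                raise ValueError("times must be non-negative")

    @property
    def reaction_time(self) -> float:
        """Latency to the start of the take-off sequence (wing raise)."""
        return self.wing_raise_time

    @property
    def escape_time(self) -> float:
        """Latency to the end of the take-off sequence (legs leave ground)."""
        return self.legs_leave_time


@dataclass(frozen=True)
class ModeBoundary:
    """Duration threshold (ms) separating short- and long-mode take-offs."""

    boundary: float = DEFAULT_BOUNDARY_MS
    method: str = "fixed"

    def __post_init__(self) -> None:
        if not self.boundary > 0:
            raise ValueError(f"boundary must be positive, got {self.boundary}")
        if self.method not in ("fixed", "mixture_intersection"):
            raise ValueError(f"unknown boundary method {self.method!r}")


class UnimodalDurationsError(ValueError):
    """Raised when a two-mode fit degenerates (no separable short/long modes)."""


def duration(seq: EscapeSequence) -> float:
    """Take-off sequence duration (ms): wing raise to loss of ground contact."""
    if not seq.took_off:
        raise ValueError("sequence has no take-off; duration undefined")
    return seq.legs_leave_time - seq.wing_raise_time


def classify_mode(duration_ms: float, boundary: ModeBoundary | float = DEFAULT_BOUNDARY_MS) -> str:
    """Classify a take-off as ``"short"`` or ``"long"`` mode.

    Short iff duration < boundary; a duration exactly at the boundary is
    classified long (conservative for short-mode claims, since the modes
    are defined by strict < and > inequalities).
    """
    if not duration_ms > 0:
        raise ValueError(f"duration must be positive, got {duration_ms}")
    b = boundary.boundary if isinstance(boundary, ModeBoundary) else float(boundary)
    return "short" if duration_ms < b else "long"


def estimate_mode_boundary(
    durations: Sequence[float],
    seed: int = 0,
    min_n: int = 30,
    min_separation: float = 1.3,
) -> ModeBoundary:
    """Estimate the short/long boundary as the intersection of two duration modes.

    Fits a 2-component Gaussian mixture to log-durations (durations are
    positive and right-skewed) with 10 EM restarts, then finds the point
    between the component means where the posterior responsibilities are
    equal — the intersection of the two weighted mode densities.

    Raises
    ------
    UnimodalDurationsError
        If the fitted components merge (mean ratio below ``min_separation``)
        or no posterior-equality point lies between the means.
    """
    d = np.asarray(list(durations), dtype=float)
    if len(d) < min_n:
        raise ValueError(f"need >= {min_n} durations, got {len(d)}")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    x = np.log(d).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, n_init=10, tol=1e-8, random_state=seed, covariance_type="full"
    ).fit(x)
    means = gm.means_.ravel()
    lo, hi = np.sort(means)
    if math.exp(hi - lo) < min_separation:
        raise UnimodalDurationsError(
            f"mixture components merged (mode ratio {math.exp(hi - lo):.3f}); "
            "duration distribution looks unimodal"
        )
    # a genuinely bimodal fit has a density dip between the component means;
    # a unimodal sample split into left/right halves does not
    dip_grid = np.linspace(lo, hi, 2001).reshape(-1, 1)
    dens = np.exp(gm.score_samples(dip_grid))
    if dens.min() >= 0.95 * min(dens[0], dens[-1]):
        raise UnimodalDurationsError(
            "no density dip between fitted components; duration distribution "
            "looks unimodal"
        )
    # posterior-equality point on a dense grid between the component means
    grid = np.linspace(lo, hi, 20001).reshape(-1, 1)
    resp = gm.predict_proba(grid)
    diff = resp[:, 0] - resp[:, 1]
    crossings = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if len(crossings) == 0:
        raise UnimodalDurationsError("no posterior-equality point between component means")
    i = crossings[0]
    # linear interpolation of the sign change
    x0, x1 = grid[i, 0], grid[i + 1, 0]
    y0, y1 = diff[i], diff[i + 1]
    x_star = x0 if y1 == y0 else x0 - y0 * (x1 - x0) / (y1 - y0)
    return ModeBoundary(boundary=float(math.exp(x_star)), method="mixture_intersection")


def takeoff_rate(seqs: Sequence[EscapeSequence], conf: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Proportion of flies that took off, with a Wilson score confidence interval."""
    if len(seqs) == 0:
        raise ValueError("no sequences")
    k = sum(1 for s in seqs if s.took_off)
    n = len(seqs)
    return k / n, wilson_interval(k, n, conf)


def short_mode_percentage(
    seqs: Sequence[EscapeSequence],
    boundary: ModeBoundary | float = DEFAULT_BOUNDARY_MS,
) -> float:
    """Fraction of take-offs classified short mode (among take-offs only)."""
    tookoff = [s for s in seqs if s.took_off]
    if not tookoff:
        raise ValueError("no take-offs among sequences")
    n_short = sum(1 for s in tookoff if classify_mode(duration(s), boundary) == "short")
    return n_short / len(tookoff)


def _group_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(len(values)),
        "mean": float(np.mean(values)),
        "median": float(med),
        "iqr": (float(q1), float(q3)),
    }


def timing_summaries(
    group_a: Sequence[EscapeSequence],
    group_b: Sequence[EscapeSequence],
    labels: tuple[str, str] = ("a", "b"),
) -> dict:
    """Compare reaction times and escape times between two groups of take-offs.

    For each timing quantity, reports per-group median, interquartile range
    and mean, plus a two-sided two-sample Student t-test.  The central
    comparison of the assay: silencing the giant fibres removes the short
    take-off mode and so lengthens escape times without changing reaction
    times.
    """
    a = [s for s in group_a if s.took_off]
    b = [s for s in group_b if s.took_off]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 take-offs")
    out: dict = {"labels": labels}
    for name, attr in (("reaction_time", "reaction_time"), ("escape_time", "escape_time")):
        va = np.array([getattr(s, attr) for s in a])
        vb = np.array([getattr(s, attr) for s in b])
        t, p = two_sample_t(va, vb)
        out[name] = {
            labels[0]: _group_stats(va),
            labels[1]: _group_stats(vb),
            "t": t,
            "p": p,
        }
    return out


def downsample_to_match(
    group_a: Sequence[EscapeSequence],
    group_b: Sequence[EscapeSequence],
    seed: int = 0,
) -> tuple[list[EscapeSequence], list[EscapeSequence]]:
    """Randomly downsample the larger group to the smaller group's n.

    Used when pooling across stimulus speeds, so neither speed dominates
    the pooled sample.  Seeded for reproducibility.
    """
    rng = np.random.default_rng(seed)
    a, b = list(group_a), list(group_b)
    if len(a) > len(b):
        a = [a[i] for i in sorted(rng.choice(len(a), size=len(b), replace=False))]
    elif len(b) > len(a):
        b = [b[i] for i in sorted(rng.choice(len(b), size=len(a), replace=False))]
    return a, b


def read_ethograms(path) -> list[EscapeSequence]:
    """Read an ethogram CSV: fly_id,genotype,rv_ms,took_off,wing_raise_ms,legs_leave_ms."""
    df = pd.read_csv(path)
    required = {"fly_id", "genotype", "rv_ms", "took_off", "wing_raise_ms", "legs_leave_ms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    seqs = []
    for row in df.itertuples(index=False):
        took_off = bool(row.took_off)
        seqs.append(
            EscapeSequence(
                took_off=took_off,
                wing_raise_time=float(row.wing_raise_ms) if took_off else math.nan,
                legs_leave_time=float(row.legs_leave_ms) if took_off else math.nan,
                genotype_label=str(row.genotype),
                stimulus_rv=float(row.rv_ms),
                fly_id=str(row.fly_id),
            )
        )
    return seqs
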