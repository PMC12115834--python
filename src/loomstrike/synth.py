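"""Synthetic predation and escape data with known ground truth.

Generators emulate the statistical structure of the three assay data
streams so every analysis stage is testable without videography, and so
parameter-recovery tests can compare estimates against programmed truth:

* hover-then-dart 3D attack trajectories at 1000 fps with digitization
  noise — a damselfly hovers near the prey, then darts along a straight
  approach with either a constant-speed or an accelerating speed profile
  whose peak occurs a programmed time before contact;
* per-fly escape ethograms — Bernoulli take-off, a reaction-time draw,
  a short/long mode draw, and a log-normal sequence duration per mode
  (silencing the giant fibres removes the short mode but leaves reaction
  times untouched);
* competition-trial eaten counts — binomial per group per trial.

All randomness flows through numpy Generators; a single scenario seed
fans out to independent substreams via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .competition import CompetitionTrial
from .ethogram import EscapeSequence
from .kinematics import TrackedTrajectory

__all__ = [
    "AttackGenParams",
    "EthoGenParams",
    "TrialGenParams",
    "gen_attack",
    "gen_ethograms",
    "gen_trials",
    "generate_scenario",
    "NULL_SCENARIO",
    "PAPER_SHAPED",
]


def _as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# attack trajectories


@dataclass(frozen=True)
class AttackGenParams:
    """Parameters of one synthetic hover-then-dart attack.

    Distances mm, speeds m/s, times ms, angles degrees.  The approach runs
    along a straight line toward the prey at (``approach_elevation``,
    ``approach_azimuth``) and is truncated at ``end_distance`` (contact
    proximity for captures, take-off distance for escapes).  The
    ``accelerating`` profile cruises at ``start_speed_fraction *
    peak_speed``, then executes a terminal burst: a raised-cosine speed
    bump, symmetric about its peak, that tops out at ``peak_speed``
    exactly ``peak_time_before_contact`` ms before the end of the event
    and falls back to cruise speed at contact.  The symmetric peak keeps
    the programmed peak time identifiable after zero-phase smoothing.
    """

    peak_speed: float = 0.2
    profile: str = "constant_speed"  # or "accelerating"
    peak_time_before_contact: float = 30.0
    start_speed_fraction: float = 0.3
    hover_distance: float = 40.0
    hover_duration: float = 100.0
    hover_jitter_sd: float = 0.05
    end_distance: float = 1.0
    approach_elevation: float = 0.0
    approach_azimuth: float = 0.0
    digitization_noise_sd: float = 0.1
    frame_rate: float = 1000.0
    tail_length: float = 25.0
    outcome: str = "capture"

    def __post_init__(self) -> None:
        if self.hover_distance <= self.end_distance:
            raise ValueError("hover_distance must exceed end_distance")
        if self.peak_speed <= 0:
            raise ValueError("peak_speed must be positive")
        if self.digitization_noise_sd < 0 or self.hover_jitter_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.profile not in ("constant_speed", "accelerating"):
            raise ValueError(f"unknown profile {self.profile!r}")


def _approach_distance_travelled(p: AttackGenParams, t: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Distance travelled (mm) at time t (s) since dart onset, plus (T_total, t_peak).

    Closed-form integrals of the piecewise raised-cosine speed profile.
    """
    D = (p.hover_distance - p.end_distance) * 1e-3  # m
    vp = p.peak_speed
    if p.profile == "constant_speed":
        T = D / vp
        x = vp * np.clip(t, 0.0, T)
        return x * 1e3, T, T  # flat profile: peak time pinned to the end by tie-break
    vc = p.start_speed_fraction * vp
    w = p.peak_time_before_contact * 1e-3  # bump half-width; peak w before contact
    # v(s) = vc + (vp - vc) * cos^2(pi (s - w) / (2 w)) over the 2w-long bump
    bump_dist = 2.0 * w * vc + (vp - vc) * w
    cruise_dist = D - bump_dist
    if cruise_dist <= 0:
        raise ValueError(
            "peak_time_before_contact too long: the terminal speed bump alone covers "
            "the whole approach distance"
        )
    Tc = cruise_dist / vc
    T = Tc + 2.0 * w
    t = np.clip(t, 0.0, T)
    x = np.empty_like(t)
    cruise = t <= Tc
    x[cruise] = vc * t[cruise]
    s = t[~cruise] - Tc
    # integral of the cos^2 bump: cos^2(pi(s-w)/(2w)) = sin^2(pi s/(2w))
    x[~cruise] = cruise_dist + vc * s + (vp - vc) * (
        s / 2.0 - w / (2.0 * math.pi) * np.sin(math.pi * s / w)
    )
    return x * 1e3, T, Tc + w


def gen_attack(
    params: AttackGenParams, rng: int | np.random.Generator | None = None
) -> tuple[TrackedTrajectory, dict]:
    """Generate one attack trajectory and its ground-truth record.

    The prey sits at the origin; the damselfly head starts
    ``hover_distance`` mm away along the programmed approach direction,
    jitters in place for ``hover_duration`` ms, then closes in along the
    straight approach line.  I.i.d. Gaussian digitization noise is added
    to every coordinate of every label.  Truth records the programmed peak
    speed, peak time (ms before the end frame, negative), approach angles
    and end distance.
    """
    rng = _as_rng(rng)
    fr = params.frame_rate
    el = math.radians(params.approach_elevation)
    az = math.radians(params.approach_azimuth)
    u = np.array([math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)])

    n_hover = int(round(params.hover_duration * fr / 1000.0))
    # approach sampled on the frame grid; the final grid point clips to the
    # exact approach duration so the event ends at end_distance
    _, T, t_peak = _approach_distance_travelled(params, np.array([0.0]))
    n_app = max(1, int(round(T * fr)))
    t_app = np.arange(1, n_app + 1) / fr
    travelled, _, _ = _approach_distance_travelled(params, t_app)
    dist = np.concatenate([np.full(n_hover, params.hover_distance), params.hover_distance - travelled])
    n = len(dist)
    head = dist[:, None] * u[None, :]
    if params.hover_jitter_sd > 0 and n_hover > 0:
        head[:n_hover] += rng.normal(0.0, params.hover_jitter_sd, size=(n_hover, 3))
    tail = head + params.tail_length * u[None, :]
    fly = np.zeros((n, 3))
    points = {"damselfly_head": head, "damselfly_tail": tail, "fly_centroid": fly}
    if params.digitization_noise_sd > 0:
        for k in points:
            points[k] = points[k] + rng.normal(0.0, params.digitization_noise_sd, size=(n, 3))
    end_frame = n - 1
    t_end = min(t_app[-1], T)
    truth = {
        "peak_speed": params.peak_speed,
        "time_of_peak_speed_ms": (min(t_peak, t_end) - t_end) * 1e3,
        "dart_onset_frame": n_hover,
        "elevation_deg": params.approach_elevation,
        "azimuth_deg": abs(params.approach_azimuth),
        "end_distance_mm": params.hover_distance - travelled[-1],
        "outcome": params.outcome,
        "approach_duration_s": T,
    }
    traj = TrackedTrajectory(
        frame_rate=fr, points=points, outcome=params.outcome, end_frame=end_frame
    )
    return traj, truth


# ---------------------------------------------------------------------------
# escape ethograms


@dataclass(frozen=True)
class EthoGenParams:
    """Parameters of a synthetic escape-ethogram population (times ms).

    Take-off is Bernoulli; reaction time is Gaussian (truncated at 1 ms);
    take-off mode is Bernoulli with weight ``short_mode_weight`` on short;
    sequence durations are log-normal per mode.  Defaults place the modes
    near 4 ms and 15 ms so the populations straddle the 7 ms boundary.
    """

    takeoff_prob: float = 0.85
    reaction_mean: float = 60.0
    reaction_sd: float = 10.0
    short_mode_weight: float = 0.7
    short_log_mu: float = math.log(4.0)
    short_log_sigma: float = 0.15
    long_log_mu: float = math.log(15.0)
    long_log_sigma: float = 0.25
    genotype_label: str = ""
    stimulus_rv: float = 40.0

    def __post_init__(self) -> None:
        for name in ("takeoff_prob", "short_mode_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def gen_ethograms(
    params: EthoGenParams, n: int, rng: int | np.random.Generator | None = None
) -> tuple[list[EscapeSequence], dict]:
    """Generate ``n`` escape sequences plus a per-fly ground-truth record."""
    rng = _as_rng(rng)
    seqs: list[EscapeSequence] = []
    modes: list[str | None] = []
    for i in range(n):
        if rng.random() >= params.takeoff_prob:
            seqs.append(
                EscapeSequence(
                    took_off=False,
                    genotype_label=params.genotype_label,
                    stimulus_rv=params.stimulus_rv,
                    fly_id=f"{params.genotype_label}_{i:04d}",
                )
            )
            modes.append(None)
            continue
        reaction = max(1.0, rng.normal(params.reaction_mean, params.reaction_sd))
        if rng.random() < params.short_mode_weight:
            mode = "short"
            dur = rng.lognormal(params.short_log_mu, params.short_log_sigma)
        else:
            mode = "long"
            dur = rng.lognormal(params.long_log_mu, params.long_log_sigma)
        seqs.append(
            EscapeSequence(
                took_off=True,
                wing_raise_time=reaction,
                legs_leave_time=reaction + dur,
                genotype_label=params.genotype_label,
                stimulus_rv=params.stimulus_rv,
                fly_id=f"{params.genotype_label}_{i:04d}",
            )
        )
        modes.append(mode)
    truth = {
        "takeoff_prob": params.takeoff_prob,
        "short_mode_weight": params.short_mode_weight,
        "reaction_mean": params.reaction_mean,
        "modes": modes,
    }
    return seqs, truth


# ---------------------------------------------------------------------------
# competition trials


@dataclass(frozen=True)
class TrialGenParams:
    """Parameters of synthetic competition trials.

    Each trial releases ``n_per_group`` flies per group with
    ``n_damselflies`` predators; eaten counts per group are binomial with
    the per-group consumption probabilities.
    """

    p_a: float = 0.3
    p_b: float = 0.15
    n_trials: int = 8
    n_per_group: int = 100
    n_damselflies: int = 10
    group_a_label: str = "silenced"
    group_b_label: str = "control"

    def __post_init__(self) -> None:
        for name in ("p_a", "p_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def gen_trials(
    params: TrialGenParams, rng: int | np.random.Generator | None = None
) -> tuple[list[CompetitionTrial], dict]:
    """Generate competition trials with binomial per-group eaten counts."""
    rng = _as_rng(rng)
    trials = [
        CompetitionTrial(
            group_a_label=params.group_a_label,
            group_b_label=params.group_b_label,
            n_a_eaten=int(rng.binomial(params.n_per_group, params.p_a)),
            n_b_eaten=int(rng.binomial(params.n_per_group, params.p_b)),
            trial_id=f"trial_{i:03d}",
        )
        for i in range(params.n_trials)
    ]
    denom = params.p_a + params.p_b
    truth = {
        "p_a": params.p_a,
        "p_b": params.p_b,
        "expected_index": (params.p_a - params.p_b) / denom if denom > 0 else math.nan,
    }
    return trials, truth


# ---------------------------------------------------------------------------
# scenarios

#: No genotype effect anywhere: identical outcome models, mode weights and
#: consumption probabilities.  Calibration baseline.
NULL_SCENARIO: dict = {
    "name": "null_scenario",
    "genotypes": ["control", "silenced"],
    "attacks": {
        "n_per_genotype": 60,
        "speed_log_median": 0.15,
        "speed_log_sigma": 0.45,
        "peak_time_mean_ms": 30.0,
        "peak_time_sd_ms": 7.0,
        "outcome_model": {
            "v_ref": 0.167,
            "intercept": {"control": -1.0, "silenced": -1.0},
            "slope": {"control": 10.0, "silenced": 10.0},
        },
        "capture_end_distance": {"control": 2.0, "silenced": 2.0},
        "escape_distance": 4.0,
    },
    "ethograms": {
        "n": {"control": 80, "silenced": 80},
        "takeoff_prob": {"control": 0.85, "silenced": 0.85},
        "reaction_mean_ms": 60.0,
        "reaction_sd_ms": 6.0,
        "short_mode_weight": {"control": 0.7, "silenced": 0.7},
        "stimulus_rv": 10.0,
    },
    "trials": {
        "n_trials": 8,
        "n_per_group": 100,
        "p_eaten": {"control": 0.2, "silenced": 0.2},
        "wcb_n_trials": 10,
    },
}

#: The study-shaped scenario: silencing the giant fibres removes the short
#: take-off mode (leaving reaction times untouched), roughly halves the
#: escape proportion, lets the predator approach closer before capture
#: (past the ~40 degree retinal-size threshold), and makes silenced flies
#: eaten preferentially in competition.
PAPER_SHAPED: dict = {
    "name": "paper_shaped",
    "genotypes": ["control", "silenced"],
    "attacks": {
        "n_per_genotype": 60,
        "speed_log_median": 0.15,
        "speed_log_sigma": 0.45,
        "peak_time_mean_ms": 30.0,
        "peak_time_sd_ms": 7.0,
        "outcome_model": {
            "v_ref": 0.167,
            "intercept": {"control": -2.9, "silenced": 0.2},
            "slope": {"control": 20.0, "silenced": 0.0},
        },
        "capture_end_distance": {"control": 3.2, "silenced": 1.5},
        "escape_distance": 4.0,
    },
    "ethograms": {
        "n": {"control": 80, "silenced": 29},
        "takeoff_prob": {"control": 0.85, "silenced": 0.55},
        "reaction_mean_ms": 60.0,
        "reaction_sd_ms": 6.0,
        "short_mode_weight": {"control": 0.7, "silenced": 0.02},
        "stimulus_rv": 10.0,
    },
    "trials": {
        "n_trials": 8,
        "n_per_group": 100,
        "p_eaten": {"control": 0.15, "silenced": 0.3},
        "wcb_n_trials": 10,
    },
}


def _gen_scenario_attacks(cfg: Mapping, genotypes: Sequence[str], rng: np.random.Generator) -> dict:
    om = cfg["outcome_model"]
    out: dict = {}
    for g in genotypes:
        events = []
        for _ in range(cfg["n_per_genotype"]):
            v = float(rng.lognormal(math.log(cfg["speed_log_median"]), cfg["speed_log_sigma"]))
            v = float(np.clip(v, 0.04, 0.45))
            p_cap = float(expit(om["intercept"][g] + om["slope"][g] * (v - om["v_ref"])))
            capture = rng.random() < p_cap
            if capture:
                t_peak = float(
                    np.clip(rng.normal(cfg["peak_time_mean_ms"], cfg["peak_time_sd_ms"]), 10.0, 60.0)
                )
                params = AttackGenParams(
                    peak_speed=v,
                    profile="accelerating",
                    peak_time_before_contact=t_peak,
                    end_distance=cfg["capture_end_distance"][g],
                    approach_elevation=float(rng.normal(0.0, 10.0)),
                    approach_azimuth=float(rng.uniform(0.0, 60.0)),
                    outcome="capture",
                )
            else:
                params = AttackGenParams(
                    peak_speed=v,
                    profile="constant_speed",
                    end_distance=cfg["escape_distance"],
                    approach_elevation=float(rng.normal(0.0, 10.0)),
                    approach_azimuth=float(rng.uniform(0.0, 60.0)),
                    outcome="escape",
                )
            events.append(gen_attack(params, rng))
        out[g] = events
    return out


def generate_scenario(scenario: Mapping, seed: int) -> dict:
    """Generate the full data bundle of a scenario, reproducibly.

    The single ``seed`` fans out to one independent substream per data
    stream (attacks, ethograms, trials) via ``SeedSequence.spawn``, so the
    streams can be regenerated independently.  Returns a dict with keys
    ``attacks`` (genotype -> list of (trajectory, truth)), ``ethograms``
    (genotype -> (sequences, truth)) and ``trials``
    ((trials, truth) with group a = silenced).
    """
    ss = np.random.SeedSequence(seed)
    rng_att, rng_eth, rng_tri = (np.random.default_rng(s) for s in ss.spawn(3))
    genotypes = list(scenario["genotypes"])

    attacks = _gen_scenario_attacks(scenario["attacks"], genotypes, rng_att)

    eth_cfg = scenario["ethograms"]
    ethograms = {}
    for g in genotypes:
        params = EthoGenParams(
            takeoff_prob=eth_cfg["takeoff_prob"][g],
            reaction_mean=eth_cfg["reaction_mean_ms"],
            reaction_sd=eth_cfg["reaction_sd_ms"],
            short_mode_weight=eth_cfg["short_mode_weight"][g],
            genotype_label=g,
            stimulus_rv=eth_cfg["stimulus_rv"],
        )
        ethograms[g] = gen_ethograms(params, eth_cfg["n"][g], rng_eth)

    tri_cfg = scenario["trials"]
    trials = gen_trials(
        TrialGenParams(
            p_a=tri_cfg["p_eaten"]["silenced"],
            p_b=tri_cfg["p_eaten"]["control"],
            n_trials=tri_cfg["n_trials"],
            n_per_group=tri_cfg["n_per_group"],
        ),
        rng_tri,
    )
    # same-genotype wing-clip control trials: no real asymmetry between sides
    p_ctrl = tri_cfg["p_eaten"]["control"]
    wcb_trials = gen_trials(
        TrialGenParams(
            p_a=p_ctrl,
            p_b=p_ctrl,
            n_trials=tri_cfg.get("wcb_n_trials", 10),
            n_per_group=tri_cfg["n_per_group"],
            group_a_label="left_clipped",
            group_b_label="right_clipped",
        ),
        rng_tri,
    )
    return {
        "name": scenario.get("name", "scenario"),
        "attacks": attacks,
        "ethograms": ethograms,
        "trials": trials,
        "wcb_trials": wcb_trials,
    }
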