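"""Synthetic seated-reaching trials and cohorts with known ground truth.

The generator emulates the study task: 45 approximately periodic, slightly
asymmetric reaching cycles at a self-selected pace near 0.38 cycles/s, with
flexion-extension as the primary axis (~20 deg amplitude) and lateral bending /
axial rotation as secondary axes (~8 deg).  Three independent noise sources are
controllable:

* ``temporal_jitter_sd`` — SD of the per-cycle (peak-to-peak) duration,
  producing temporal variability (CyclSD);
* ``spatial_noise_sd`` — SD of additive, low-pass-filtered kinematic noise per
  axis, producing spatial variability (MeanSD);
* ``process_noise_sd`` — multiplicative noise on the instantaneous phase
  velocity, producing genuine trajectory divergence that the local divergence
  exponent detects (unlike purely additive measurement noise).

Cycle durations are defined peak-to-peak (peaks sit at integer phase), matching
how the analysis pipeline segments cycles at the detected sagittal peaks, so the
drawn durations are directly comparable with the pipeline's CyclSD.

Cohorts are generated at the metric level: per participant, a random baseline
for each movement metric plus configured condition (threat) and group-by-EBS
interaction effects, mirroring the 2 (group) x 2 (EBS) between-subjects, 2
(condition) within-subjects design with 15 participants per between cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .kinematics import (
    AngleSeries,
    MarkerTrial,
    THORAX_MARKERS,
    PELVIS_MARKERS,
    cluster_orientation,
    euler_compose,
)

__all__ = [
    "TrialConfig",
    "TrialGroundTruth",
    "ClusterGeometry",
    "CohortConfig",
    "generate_angle_trial",
    "generate_marker_trial",
    "generate_cohort",
    "GROUP_LBP",
    "GROUP_CONTROL",
    "CONDITION_THREAT",
    "CONDITION_REFERENCE",
]

GROUP_LBP = "LBP"
GROUP_CONTROL = "back-healthy"
CONDITION_THREAT = "threat"
CONDITION_REFERENCE = "reference"


@dataclass
class TrialConfig:
    """Parameters of one synthetic reaching trial."""

    n_cycles: int = 45
    mean_period: float = 2.6          # s per reaching cycle (~0.38 cycles/s)
    amp_fe: float = 20.0              # deg, flexion-extension
    amp_lb: float = 8.0               # deg, lateral bending
    amp_ar: float = 8.0               # deg, axial rotation
    spatial_noise_sd: float = 0.0     # deg, per-axis additive noise SD
    temporal_jitter_sd: float = 0.0   # s, SD of per-cycle duration
    process_noise_sd: float = 0.0     # dimensionless phase-velocity noise
    sample_rate: float = 100.0        # Hz
    seed: int = 0
    rise_fraction: float = 0.45       # asymmetry: fraction of cycle spent flexing
    noise_cutoff_hz: float | None = 10.0  # low-pass cutoff of additive noise
    secondary_phase_lag: float = 0.06     # cycles; offsets lb/ar from fe

    def validate(self) -> None:
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        if self.mean_period <= 0:
            raise ValueError("mean_period must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for name in ("spatial_noise_sd", "temporal_jitter_sd", "process_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.05 <= self.rise_fraction <= 0.95:
            raise ValueError("rise_fraction must be in [0.05, 0.95]")


@dataclass
class TrialGroundTruth:
    """What was injected into a synthetic trial."""

    durations: np.ndarray    # drawn peak-to-peak durations, s (n_cycles - 1)
    peak_times: np.ndarray   # realized peak times, s (n_cycles)
    spatial_noise_sd: float
    temporal_jitter_sd: float
    process_noise_sd: float
    config: TrialConfig


def _waveform(phase: np.ndarray, rise: float) -> np.ndarray:
    """Asymmetric raised cosine on [0, 1): 0 (upright) -> 1 (peak at ``rise``) -> 0."""
    p = np.mod(phase, 1.0)
    out = np.empty_like(p)
    up = p < rise
    out[up] = 0.5 * (1.0 - np.cos(np.pi * p[up] / rise))
    out[~up] = 0.5 * (1.0 + np.cos(np.pi * (p[~up] - rise) / (1.0 - rise)))
    return out


def _filtered_noise(rng, n: int, sd: float, fs: float, cutoff: float | None) -> np.ndarray:
    """Additive noise of exact SD ``sd``; low-pass filtered to resemble kinematic noise."""
    x = rng.standard_normal(n)
    if cutoff is not None and 0 < cutoff < fs / 2:
        b, a = butter(4, cutoff / (fs / 2))
        x = filtfilt(b, a, x)
    s = x.std()
    if s > 0:
        x = x / s
    return sd * x


def generate_angle_trial(config: TrialConfig) -> tuple[AngleSeries, TrialGroundTruth]:
    """Simulate one trial's lumbar angle series with known injected noise.

    The trajectory follows a phase variable advanced sample by sample at rate
    ``(1 + process_noise_sd * xi_t) / T_k`` where ``T_k`` is the drawn duration
    of the current peak-to-peak segment; the three angle channels are
    asymmetric raised cosines of that phase (secondary axes lag/lead by
    ``secondary_phase_lag`` cycles).  Identical seed => identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cycles
    r = config.rise_fraction
    # n+1 draws: lead-in (upright -> peak 1), n-1 peak-to-peak segments, tail
    durations = config.mean_period + config.temporal_jitter_sd * rng.standard_normal(n + 1)
    if np.any(durations <= 0):
        raise ValueError(
            "temporal_jitter_sd too large: a drawn cycle duration is <= 0"
        )
    dt = 1.0 / config.sample_rate
    theta_end = (n - 1) + (1.0 - r)
    # phase runs from -r (upright) through peaks at 0, 1, ..., n-1, to upright
    cap = int(np.ceil((durations.sum() * 2 + 10) * config.sample_rate))
    theta = np.empty(cap)
    th = -r
    i = 0
    noisy = config.process_noise_sd > 0
    while th < theta_end and i < cap:
        theta[i] = th
        seg = min(int(np.floor(th)) + 1, n) if th >= 0 else 0
        rate = 1.0 / durations[seg]
        if noisy:
            rate *= 1.0 + config.process_noise_sd * rng.standard_normal()
            rate = max(rate, 1e-6)
        th += dt * rate
        i += 1
    theta = theta[:i]
    n_samples = i

    # realized peak times: crossings of integer phase (theta is monotone)
    peaks = []
    for k in range(n):
        j = int(np.searchsorted(theta, k))
        if j >= n_samples:
            break
        if j == 0:
            peaks.append(0.0)
        else:
            frac = (k - theta[j - 1]) / (theta[j] - theta[j - 1])
            peaks.append((j - 1 + frac) * dt)
    peak_times = np.asarray(peaks)

    base_phase = theta + r
    fe = config.amp_fe * _waveform(base_phase, r)
    lb = config.amp_lb * _waveform(base_phase - config.secondary_phase_lag, r)
    ar = config.amp_ar * _waveform(base_phase + config.secondary_phase_lag, r)
    angles = np.column_stack([fe, lb, ar])
    if config.spatial_noise_sd > 0:
        for axis in range(3):
            angles[:, axis] += _filtered_noise(
                rng, n_samples, config.spatial_noise_sd,
                config.sample_rate, config.noise_cutoff_hz,
            )
    series = AngleSeries(angles=angles, sample_rate=config.sample_rate)
    truth = TrialGroundTruth(
        durations=durations[1:n],
        peak_times=peak_times,
        spatial_noise_sd=config.spatial_noise_sd,
        temporal_jitter_sd=config.temporal_jitter_sd,
        process_noise_sd=config.process_noise_sd,
        config=config,
    )
    return series, truth


def _default_offsets() -> np.ndarray:
    # canonical: cluster_orientation(these three points) is the identity
    return np.array([
        [-0.03, -0.02, 0.0],
        [0.03, -0.02, 0.0],
        [0.00, 0.04, 0.0],
    ])


@dataclass
class ClusterGeometry:
    """Marker offsets (m) of both clusters in their segment frames.

    The defaults are canonical: the frame constructed from the offsets is the
    identity, so the forward model and the kinematics chain are exact mutual
    inverses.  Non-canonical offsets are allowed; the recovered angles then
    differ by the fixed cluster-to-segment rotations.
    """

    thorax_markers: np.ndarray = field(default_factory=_default_offsets)
    pelvis_markers: np.ndarray = field(default_factory=_default_offsets)
    thorax_origin: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.25]))
    pelvis_origin: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.00]))

    def validate(self) -> None:
        for name in ("thorax_markers", "pelvis_markers"):
            pts = np.asarray(getattr(self, name), dtype=float)
            if pts.shape != (3, 3):
                raise ValueError(f"{name} must be three 3-D offsets")
            area = np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
            if area < 1e-8:
                raise ValueError(f"{name} are collinear")
        cluster_orientation(*np.asarray(self.thorax_markers, dtype=float))
        cluster_orientation(*np.asarray(self.pelvis_markers, dtype=float))


def generate_marker_trial(angles: AngleSeries, geometry: ClusterGeometry | None = None) -> MarkerTrial:
    """Forward model: place both clusters from a lumbar angle series.

    The pelvis cluster keeps a fixed global orientation; the thorax cluster is
    rotated by the composition of the Euler angles in the analysis order.
    Rigid-body distances within each cluster are constant over time.
    """
    geometry = geometry or ClusterGeometry()
    geometry.validate()
    R = euler_compose(angles.angles)  # (n, 3, 3)
    positions: dict[str, np.ndarray] = {}
    thorax_off = np.asarray(geometry.thorax_markers, dtype=float)
    pelvis_off = np.asarray(geometry.pelvis_markers, dtype=float)
    for j, label in enumerate(THORAX_MARKERS):
        positions[label] = geometry.thorax_origin + R @ thorax_off[j]
    for j, label in enumerate(PELVIS_MARKERS):
        positions[label] = np.broadcast_to(
            geometry.pelvis_origin + pelvis_off[j], (angles.n_samples, 3)
        ).copy()
    t = np.arange(angles.n_samples) / angles.sample_rate
    return MarkerTrial(timestamps=t, positions=positions, nominal_rate=angles.sample_rate)


# reference-condition scale of each movement metric (medians / means of the
# seated-reaching task); lognormal metrics are generated on the log scale
_METRIC_SCALE = {
    "meansd_fe": 1.66,
    "meansd_ar": 0.86,
    "meansd_lb": 0.87,
    "cyclsd": 0.10,
    "amplitude_fe": 20.4,
    "amplitude_ar": 8.2,
    "amplitude_lb": 7.9,
    "velocity": 0.38,
}
_LDE_SCALE = 3.86

LOGNORMAL_METRICS = tuple(_METRIC_SCALE)
METRIC_COLUMNS = LOGNORMAL_METRICS + ("lde",)


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort (metric-level generation).

    Effects default to the magnitudes of the threat condition in the study
    design this package targets: ~22% increase of flexion-extension MeanSD
    and ~10% of CyclSD-scale metrics under threat, +0.10 LDE, +5% amplitude,
    -3% velocity; the group-by-EBS interaction inflates secondary-axis MeanSD
    in the LBP & high-EBS cell.
    """

    n_per_group: int = 15                 # per group x EBS cell (4 cells)
    threat_effect: float = 1.22           # x on meansd_fe and cyclsd under threat
    interaction_effect: float = 1.25      # x on meansd_lb/ar for LBP & high EBS
    between_subject_sd: float = 0.22      # log-scale SD of participant baselines
    within_subject_sd: float = 0.25       # log-scale SD of per-condition residuals
    threat_lde_shift: float = 0.10        # additive LDE shift under threat
    lde_between_sd: float = 0.25
    lde_within_sd: float = 0.18
    threat_amplitude_factor: float = 1.05
    threat_velocity_factor: float = 0.97
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("threat_effect", "interaction_effect",
                     "threat_amplitude_factor", "threat_velocity_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("between_subject_sd", "within_subject_sd",
                     "lde_between_sd", "lde_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _draw_ebs(rng, level: str) -> int:
    if level == "low":
        return int(rng.choice([0, 1, 2, 3], p=[0.15, 0.25, 0.35, 0.25]))
    return int(rng.choice([4, 5, 6, 7, 8], p=[0.40, 0.30, 0.15, 0.10, 0.05]))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Cohort table: one row per participant x condition, long format.

    The between design is 2 (group: LBP / back-healthy) x 2 (EBS: low <= 3 /
    high >= 4) with ``n_per_group`` participants per cell; every participant
    has a reference and a threat row.  EBS integers are drawn to respect the
    fixed split; clinical covariates are drawn at the scale of the study
    sample and carried along as data.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    pid = 0
    for group in (GROUP_CONTROL, GROUP_LBP):
        for ebs_level in ("low", "high"):
            for _ in range(config.n_per_group):
                pid += 1
                ebs_threat = _draw_ebs(rng, ebs_level)
                ebs_reference = int(np.clip(
                    ebs_threat - rng.choice([0, 1, 2], p=[0.45, 0.40, 0.15]), 0, 10))
                base = {
                    m: np.log(_METRIC_SCALE[m]) + config.between_subject_sd * rng.standard_normal()
                    for m in LOGNORMAL_METRICS
                }
                lde_base = _LDE_SCALE + config.lde_between_sd * rng.standard_normal()
                if group == GROUP_LBP and ebs_level == "high":
                    base["meansd_lb"] += np.log(config.interaction_effect)
                    base["meansd_ar"] += np.log(config.interaction_effect)
                covar = {
                    "sex": rng.choice(["M", "F"], p=[11 / 30, 19 / 30]),
                    "age": float(np.clip(rng.normal(32.0, 13.5), 18, 65)),
                    "height": float(rng.normal(1.79, 0.09)),
                    "weight": float(rng.normal(74.7, 12.0)),
                    "odi": float(np.clip(rng.normal(15.7, 12.7), 0, 50)) if group == GROUP_LBP else 0.0,
                    "sbst": float(np.clip(rng.normal(1.6, 1.5), 0, 9)) if group == GROUP_LBP else 0.0,
                    "nrs": float(np.clip(rng.normal(2.4, 2.1), 0, 10)) if group == GROUP_LBP else 0.0,
                    "pcs": float(np.clip(rng.normal(13.0, 6.0), 0, 52)),
                    "pass": float(np.clip(rng.normal(48.0, 20.0), 0, 200)),
                }
                for condition in (CONDITION_REFERENCE, CONDITION_THREAT):
                    threat = condition == CONDITION_THREAT
                    vals = {}
                    for m in LOGNORMAL_METRICS:
                        x = base[m] + config.within_subject_sd * rng.standard_normal()
                        if threat:
                            if m in ("meansd_fe", "cyclsd"):
                                x += np.log(config.threat_effect)
                            elif m == "amplitude_fe":
                                x += np.log(config.threat_amplitude_factor)
                            elif m == "velocity":
                                x += np.log(config.threat_velocity_factor)
                        vals[m] = float(np.exp(x))
                    vals["lde"] = float(
                        lde_base
                        + (config.threat_lde_shift if threat else 0.0)
                        + config.lde_within_sd * rng.standard_normal()
                    )
                    rows.append({
                        "participant": f"P{pid:03d}",
                        "group": group,
                        "condition": condition,
                        "ebs_threat": ebs_threat,
                        "ebs_reference": ebs_reference,
                        **vals,
                        **covar,
                    })
    return pd.DataFrame(rows)
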