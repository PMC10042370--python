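"""End-to-end orchestration: raw trial -> metrics row; cohort table -> report.

``run_trial_pipeline`` composes the full per-trial chain: resample markers to
100 Hz -> cluster orientations -> relative lumbar Euler angles -> cycle
detection at the sagittal peaks -> keep the final 40 cycles -> variability,
amplitude and velocity metrics + the local divergence exponent on the
300-samples-per-cycle resampled series.  ``run_cohort`` applies the
statistical stage (log transforms, EBS split, both MANOVAs, univariate
follow-ups and the nonparametric suite) to a metrics-plus-metadata table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cycles as cyc
from . import lds as lds_mod
from . import stats as st
from .kinematics import AngleSeries, MarkerTrial, markers_to_angles, resample_to_rate
from .lds import EmbeddingConfig

__all__ = ["RunConfig", "CohortReport", "run_trial_pipeline", "run_cohort"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All analysis parameters, with the study protocol's values as defaults."""

    sample_rate: float = 100.0
    expected_cycles: int | None = None   # protocol expects 45 peaks; None = don't check
    n_analysis_cycles: int = 40          # final cycles kept (transients discarded)
    max_gap: float = 0.1                 # s, longest marker dropout bridged by spline
    min_separation_frac: float = 0.5     # peak detection: x dominant period
    prominence_frac: float = 0.25        # peak detection: x signal IQR
    align_max_shift: int = 10            # phase samples
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    compute_lde: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        emb = d.pop("embedding", None)
        cfg = cls(**d)
        if emb:
            cfg.embedding = EmbeddingConfig(**emb)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_trial_pipeline(trial: MarkerTrial | AngleSeries, config: RunConfig | None = None,
                       trial_id: str = "") -> cyc.MovementMetrics:
    """Compute the per-trial movement metrics from markers or angles.

    Angle-series input skips the kinematics stage; downstream results are
    identical to the equivalent marker input.  Any stage error is re-raised
    with the trial identity attached.
    """
    config = config or RunConfig()
    tag = f"trial {trial_id}: " if trial_id else ""
    try:
        if isinstance(trial, MarkerTrial):
            logger.info("%sresampling markers to %.0f Hz", tag, config.sample_rate)
            uniform = resample_to_rate(trial, config.sample_rate, config.max_gap)
            angles = markers_to_angles(uniform)
        elif isinstance(trial, AngleSeries):
            angles = trial
        else:
            raise TypeError(f"unsupported trial input: {type(trial)!r}")

        peaks = cyc.detect_cycles(
            angles.flexion_extension,
            expected_count=config.expected_cycles,
            min_separation_frac=config.min_separation_frac,
            prominence_frac=config.prominence_frac,
        )
        logger.info("%s%d peaks detected", tag, peaks.size)
        boundaries = cyc.select_analysis_cycles(peaks, config.n_analysis_cycles)
        # integer sample differences first: equal spacings give exactly equal durations
        durations = np.diff(boundaries) / angles.sample_rate
        cyclsd = cyc.cycl_sd(durations)

        normalized = cyc.normalize_cycles(angles.angles, boundaries)
        aligned, shifts = cyc.align_cycles(normalized, max_shift=config.align_max_shift)
        msd = cyc.mean_sd(aligned)
        amp = cyc.amplitude(normalized)
        vel = cyc.velocity(
            config.n_analysis_cycles,
            float(boundaries[-1] - boundaries[0]) / angles.sample_rate,
        )

        lde_val = slope = float("nan")
        if config.compute_lde:
            span = angles.angles[int(boundaries[0]): int(boundaries[-1]) + 1]
            lde_val, slope, _ = lds_mod.compute_lde(
                span, config.n_analysis_cycles, config.embedding
            )
        logger.info("%smetrics computed (%d cycles analyzed)", tag, config.n_analysis_cycles)
        return cyc.MovementMetrics(
            meansd_fe=float(msd[0]), meansd_lb=float(msd[1]), meansd_ar=float(msd[2]),
            cyclsd=float(cyclsd),
            amplitude_fe=float(amp[0]), amplitude_lb=float(amp[1]), amplitude_ar=float(amp[2]),
            velocity=float(vel), lde=float(lde_val), lde_slope_per_sample=float(slope),
        )
    except Exception as exc:
        if trial_id and not getattr(exc, "_trial_tagged", False):
            exc.args = (f"trial {trial_id}: {exc}",) + exc.args[1:]
            exc._trial_tagged = True
        raise


@dataclass
class CohortReport:
    """Outputs of the cohort statistical stage."""

    manova_variability: list[st.ManovaResult]
    manova_amplitude: list[st.ManovaResult]
    univariate: pd.DataFrame
    nonparametric: dict

    def results_table(self) -> pd.DataFrame:
        """Flat effect x DV table (F, p, partial eta squared) plus MANOVA rows."""
        rows = []
        for label, results in (("variability/stability", self.manova_variability),
                               ("amplitude/velocity", self.manova_amplitude)):
            for r in results:
                rows.append({
                    "analysis": label, "effect": r.effect, "dv": "(multivariate)",
                    "wilks_lambda": r.wilks_lambda, "F": r.F,
                    "df_num": r.df_num, "df_den": r.df_den, "p": r.p,
                    "partial_eta_sq": np.nan,
                })
        manova = pd.DataFrame(rows)
        uni = self.univariate.copy()
        uni.insert(0, "analysis", "univariate")
        uni["wilks_lambda"] = np.nan
        return pd.concat([manova, uni], ignore_index=True)[
            ["analysis", "effect", "dv", "wilks_lambda", "F", "df_num", "df_den",
             "p", "partial_eta_sq"]
        ]

    def summary(self, alpha: float = 0.05) -> str:
        lines = ["Cohort analysis summary", "======================="]
        for label, results in (("Variability/stability MANOVA", self.manova_variability),
                               ("Amplitude/velocity MANOVA", self.manova_amplitude)):
            lines.append(label)
            for r in results:
                flag = " *" if r.p <= alpha else ""
                lines.append(
                    f"  {r.effect:<24s} Wilks L={r.wilks_lambda:.3f} "
                    f"F({r.df_num},{r.df_den})={r.F:.3f} p={r.p:.3f}{flag}"
                )
        lines.append("Univariate follow-ups (significant effects)")
        for _, row in self.univariate.iterrows():
            if row["p"] <= alpha:
                lines.append(
                    f"  {row['effect']:<24s} {row['dv']:<14s} "
                    f"F({row['df_num']:.0f},{row['df_den']:.0f})={row['F']:.3f} "
                    f"p={row['p']:.3f} eta2={row['partial_eta_sq']:.3f}"
                )
        return "\n".join(lines)


def run_cohort(table: pd.DataFrame, followup_alpha: float = 0.05) -> CohortReport:
    """Statistical stage on a long cohort table of metrics + metadata.

    Log transforms the skewed metrics, runs both predefined MANOVAs,
    univariate follow-ups for every DV whose analysis has at least one
    significant multivariate effect, and the nonparametric descriptive suite.
    """
    transformed = st.transform_skewed(table)
    res_var = st.mixed_manova(transformed, st.VARIABILITY_DVS)
    res_amp = st.mixed_manova(transformed, st.AMPLITUDE_DVS)
    uni_rows = []
    for results, dvs in ((res_var, st.VARIABILITY_DVS), (res_amp, st.AMPLITUDE_DVS)):
        if any(r.p <= followup_alpha for r in results):
            for dv in dvs:
                for eff in st.univariate_followup(transformed, dv):
                    uni_rows.append(asdict(eff))
    uni = pd.DataFrame(
        uni_rows,
        columns=["dv", "effect", "F", "p", "partial_eta_sq", "df_num", "df_den"],
    )
    nonpar = st.nonparametric_suite(table)
    return CohortReport(
        manova_variability=res_var, manova_amplitude=res_amp,
        univariate=uni, nonparametric=nonpar,
    )
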