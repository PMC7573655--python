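"""Synthetic multi-scanner cohorts with known ground truth.

Each scanner s carries a latent quality q_s in [-1, 1]. Per ROI g the
scanner distorts the true relative volume v with an additive effect
gamma_{s,g} = A_g(q_s) and a multiplicative effect delta_{s,g} =
M_g(q_s), both smooth and monotone in q_s by default. IQMs are noisy
monotone functions of q_s, so the distortion is recoverable from the
IQMs alone — the property the learner module exploits. An optional
random-effect mode breaks that link to probe failure behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import CohortTable

AGE_MID = 44.0


@dataclass
class SimConfig:
    n_scanners: int = 10
    subjects_per_scanner: int | Sequence[int] = 80
    n_rois: int = 20
    n_iqms: int = 10
    age_range: tuple[float, float] = (18.0, 70.0)
    age_jitter: float = 5.0            # per-scanner shift of the age window midpoint
    sex_imbalance: float | Sequence[float] | None = None  # P(male); None -> drawn in [0.3, 0.7]
    roi_mean_range: tuple[float, float] = (0.002, 0.02)
    roi_cv_range: tuple[float, float] = (0.08, 0.15)
    age_slope_scale: float = 0.8       # max |total age effect| across the window, in ROI SDs
    sex_offset_scale: float = 0.5      # max |sex offset|, in ROI SDs
    gamma_scale: float = 1.0           # additive scanner effect magnitude, in ROI SDs
    log_delta_scale: float = 0.15      # multiplicative effect: delta = exp(+-scale * q)
    measurement_noise_sd: float = 0.0  # additive observation noise, in ROI SDs
    iqm_noise_sd: float = 0.05         # subject-level IQM noise (IQM signal has unit scale)
    effect_mode: str = "latent"        # 'latent' (q-driven) | 'random' (IQM-independent)
    tiv_mean: float = 1.5e6
    tiv_sd: float = 1.0e5
    seed: int = 0

    def sizes(self) -> np.ndarray:
        if np.isscalar(self.subjects_per_scanner):
            return np.full(self.n_scanners, int(self.subjects_per_scanner))
        sizes = np.asarray(self.subjects_per_scanner, int)
        if len(sizes) != self.n_scanners:
            raise ValueError("subjects_per_scanner length != n_scanners")
        return sizes

    def validate(self) -> None:
        if self.n_scanners < 1 or self.n_rois < 1 or self.n_iqms < 1:
            raise ValueError("n_scanners, n_rois, n_iqms must be positive")
        if (self.sizes() < 2).any():
            raise ValueError("every scanner needs at least 2 subjects")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("invalid age_range")
        if self.effect_mode not in ("latent", "random"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")


@dataclass
class GroundTruth:
    true_relative: pd.DataFrame      # subject-indexed true relative volumes
    gamma: pd.DataFrame              # scanner x ROI additive effects
    delta: pd.DataFrame              # scanner x ROI multiplicative effects (> 0)
    quality: pd.Series               # latent q_s per scanner
    age_slope: pd.Series             # per ROI
    sex_offset: pd.Series            # per ROI
    roi_sd: pd.Series = field(default=None)


def simulate_cohort(config: SimConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort; observed = delta * true + gamma + noise, by construction."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.sizes()
    scanners = [f"S{i+1:02d}" for i in range(config.n_scanners)]
    rois = [f"roi_{g+1:02d}" for g in range(config.n_rois)]
    iqms = [f"iqm_{j+1:02d}" for j in range(config.n_iqms)]

    # per-ROI population parameters
    roi_mean = rng.uniform(*config.roi_mean_range, config.n_rois)
    roi_sd = roi_mean * rng.uniform(*config.roi_cv_range, config.n_rois)
    half_span = (config.age_range[1] - config.age_range[0]) / 2.0
    age_slope = roi_sd * rng.uniform(-config.age_slope_scale, config.age_slope_scale, config.n_rois) / half_span
    sex_offset = roi_sd * rng.uniform(-config.sex_offset_scale, config.sex_offset_scale, config.n_rois)

    # scanner effects
    quality = rng.uniform(-1.0, 1.0, config.n_scanners)
    if config.effect_mode == "latent":
        a_coef = rng.uniform(0.5, 1.5, config.n_rois) * rng.choice([-1.0, 1.0], config.n_rois)
        d_coef = rng.uniform(0.5, 1.5, config.n_rois) * rng.choice([-1.0, 1.0], config.n_rois)
        gamma = config.gamma_scale * roi_sd[None, :] * a_coef[None, :] * quality[:, None]
        delta = np.exp(config.log_delta_scale * d_coef[None, :] * quality[:, None])
    else:  # scanner effects independent of q (and hence of the IQMs)
        gamma = config.gamma_scale * roi_sd[None, :] * rng.normal(size=(config.n_scanners, config.n_rois))
        delta = np.exp(config.log_delta_scale * rng.normal(size=(config.n_scanners, config.n_rois)))

    # IQM model: monotone in q with per-IQM offset/slope/curvature
    iqm_b0 = rng.uniform(-1, 1, config.n_iqms)
    iqm_b1 = rng.uniform(0.5, 2.0, config.n_iqms) * rng.choice([-1.0, 1.0], config.n_iqms)
    iqm_b2 = rng.uniform(-0.3, 0.3, config.n_iqms)

    if config.sex_imbalance is None:
        p_male = rng.uniform(0.3, 0.7, config.n_scanners)
    elif np.isscalar(config.sex_imbalance):
        p_male = np.full(config.n_scanners, float(config.sex_imbalance))
    else:
        p_male = np.asarray(config.sex_imbalance, float)

    rows = []
    true_rows = []
    sid = 0
    for i, s in enumerate(scanners):
        n_i = sizes[i]
        lo = max(config.age_range[0], config.age_range[0] + rng.uniform(0, config.age_jitter))
        hi = min(config.age_range[1], config.age_range[1] - rng.uniform(0, config.age_jitter))
        age = rng.uniform(lo, hi, n_i)
        sex = (rng.uniform(size=n_i) < p_male[i]).astype(int)
        true = (
            roi_mean[None, :]
            + age_slope[None, :] * (age[:, None] - AGE_MID)
            + sex_offset[None, :] * sex[:, None]
            + rng.normal(size=(n_i, config.n_rois)) * roi_sd[None, :]
        )
        observed = delta[i][None, :] * true + gamma[i][None, :]
        if config.measurement_noise_sd > 0:
            observed = observed + rng.normal(size=observed.shape) * (
                config.measurement_noise_sd * roi_sd[None, :]
            )
        iqm_vals = (
            iqm_b0[None, :]
            + iqm_b1[None, :] * quality[i]
            + iqm_b2[None, :] * quality[i] ** 2
            + rng.normal(size=(n_i, config.n_iqms)) * config.iqm_noise_sd
        )
        tiv = np.maximum(rng.normal(config.tiv_mean, config.tiv_sd, n_i), 1e5)
        for k in range(n_i):
            row = {
                "subject_id": f"sub-{sid:05d}",
                "scanner": s,
                "age": age[k],
                "sex": int(sex[k]),
                "tiv": tiv[k],
            }
            row.update({rois[g]: observed[k, g] * tiv[k] for g in range(config.n_rois)})
            row.update({CohortTable.rel_col(rois[g]): observed[k, g] for g in range(config.n_rois)})
            row.update({iqms[j]: iqm_vals[k, j] for j in range(config.n_iqms)})
            rows.append(row)
            true_rows.append({"subject_id": f"sub-{sid:05d}", **{rois[g]: true[k, g] for g in range(config.n_rois)}})
            sid += 1

    data = pd.DataFrame(rows)
    table = CohortTable(data, tuple(rois), tuple(iqms), meta={"sim_seed": config.seed})
    table.validate()
    truth = GroundTruth(
        true_relative=pd.DataFrame(true_rows).set_index("subject_id"),
        gamma=pd.DataFrame(gamma, index=scanners, columns=rois),
        delta=pd.DataFrame(delta, index=scanners, columns=rois),
        quality=pd.Series(quality, index=scanners, name="q"),
        age_slope=pd.Series(age_slope, index=rois),
        sex_offset=pd.Series(sex_offset, index=rois),
        roi_sd=pd.Series(roi_sd, index=rois),
    )
    return table, truth


def make_validation_split(
    table: CohortTable,
    n_holdout_scanners: int,
    seed: int = 0,
    quality: pd.Series | None = None,
) -> tuple[CohortTable, CohortTable]:
    """Scanner-level train/holdout split with zero subject overlap.

    With ``quality`` given, holdout scanners are drawn from the interior
    of the quality range (never the extremes), keeping the held-out
    latent quality inside the training envelope.
    """
    scanners = table.scanners()
    if n_holdout_scanners >= len(scanners):
        raise ValueError("n_holdout_scanners must be smaller than the number of scanners")
    rng = np.random.default_rng(seed)
    if quality is not None:
        q = quality.loc[scanners]
        interior = q.sort_values().index[1:-1].tolist()
        if len(interior) < n_holdout_scanners:
            raise ValueError("not enough interior scanners for an in-envelope holdout")
        holdout = sorted(rng.choice(interior, n_holdout_scanners, replace=False).tolist())
    else:
        holdout = sorted(rng.choice(scanners, n_holdout_scanners, replace=False).tolist())
    mask = table.data["scanner"].isin(holdout).to_numpy()
    return table.subset(~mask), table.subset(mask)
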