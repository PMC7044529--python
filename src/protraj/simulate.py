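"""Seeded synthetic cohorts with the statistical structure the models assume.

A latent, non-negative disease severity drives everything else:

* three correlated cognitive composites (memory, executive function, a
  depression sum score) are linear in severity plus independent noise;
* amyloid burden rises with severity and APOE4 carriage becomes more likely;
* voxelwise grey-matter density equals a smooth baseline field minus a
  severity-scaled deficit confined to a contiguous planted region, plus
  spatially smooth noise;
* longitudinal memory series decline with subject-specific slopes that
  are linear in severity (steeper decline at higher severity);
* conversion from MCI to dementia follows an exponential hazard whose log
  rate is linear in severity, labelled with a fixed observation window;
* three regional tau burdens increase with the planted-region deficit.

Ground-truth severity, slopes and the planted region are retained so that
recovery can be verified.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .pls_rfe import VoxelMatrix

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort",
           "assign_labels", "InfeasibleConfigError",
           "STABLE", "PROGRESSIVE", "EXCLUDED"]

STABLE = "stable"
PROGRESSIVE = "progressive"
EXCLUDED = "excluded"


class InfeasibleConfigError(ValueError):
    """The configured parameters produce impossible data (e.g. negative density)."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Feature loadings are (intercept, slope on severity, noise sd).  Units:
    cognitive composites are z-like scores, amyloid is SUVR, times are
    years.  The memory decline model is slope = a + b*severity + noise with
    b < 0 (higher severity, faster decline); conversion hazard is
    exp(h0 + h1*severity) per year with h1 > 0.
    """

    n_subjects: int = 300
    normal_fraction: float = 1.0 / 3.0
    grid_shape: tuple[int, int, int] = (22, 22, 22)
    region_center: tuple[int, int, int] = (11, 11, 11)
    region_radius: float = 3.0
    baseline_density: float = 0.60
    baseline_field_sd: float = 0.02
    deficit_scale: float = 0.05
    voxel_noise_sd: float = 0.04
    smooth_sigma: float = 1.0
    # latent severity: gamma distributed, MCI shifted above normals
    severity_shape: float = 2.0
    severity_scale: float = 0.5
    normal_severity_scale: float = 0.15
    mci_severity_shift: float = 0.3
    feature_loadings: dict = field(default_factory=lambda: {
        "adni_mem": (0.5, -0.8, 0.30),
        "adni_ef": (0.3, -0.5, 0.35),
        "gds": (1.0, 0.8, 1.00),
        "amyloid_suvr": (1.05, 0.25, 0.10),
    })
    apoe4_intercept: float = -1.0
    apoe4_slope: float = 1.2
    visit_times: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0)
    visit_jitter_sd: float = 0.05
    slope_intercept: float = 0.02
    slope_on_severity: float = -0.12
    slope_noise_sd: float = 0.05
    memory_visit_noise_sd: float = 0.10
    hazard_intercept: float = -4.0
    hazard_slope: float = 1.5
    followup_min_years: float = 3.5
    followup_max_years: float = 6.0
    observation_window: float = 3.0
    tau_loadings: dict = field(default_factory=lambda: {
        "tau_braak12": (1.20, 4.0, 0.15),
        "tau_braak34": (1.15, 2.5, 0.15),
        "tau_braak56": (1.10, 1.5, 0.15),
    })
    seed: int = 0

    def validate(self) -> None:
        for name, (_, _, sd) in {**self.feature_loadings, **self.tau_loadings}.items():
            if sd <= 0:
                raise InfeasibleConfigError(f"noise sd for {name!r} must be > 0")
        if self.voxel_noise_sd <= 0 or self.baseline_field_sd <= 0:
            raise InfeasibleConfigError("voxel noise sds must be > 0")
        if self.slope_on_severity >= 0:
            raise InfeasibleConfigError("slope_on_severity must be negative")
        center = np.asarray(self.region_center)
        if np.any(center - self.region_radius < 0) or \
           np.any(center + self.region_radius >= np.asarray(self.grid_shape)):
            raise InfeasibleConfigError("planted region extends outside the grid")
        if len(self.visit_times) < 3:
            raise InfeasibleConfigError("need at least 3 visits")


@dataclass
class SyntheticCohort:
    table: pd.DataFrame             # one row per subject
    voxels: VoxelMatrix             # grey-matter density
    longitudinal: pd.DataFrame      # subject_id, time_years, adni_mem
    tau: pd.DataFrame               # subject_id, tau per Braak composite
    region_mask: np.ndarray         # (m, 3) planted voxel coordinates
    config: SimulationConfig

    @property
    def mci(self) -> pd.DataFrame:
        return self.table[self.table.baseline_dx == "MCI"]

    @property
    def labelled(self) -> pd.DataFrame:
        """MCI subjects with a usable stable/progressive outcome."""
        return self.table[self.table.label.isin([STABLE, PROGRESSIVE])]


def assign_labels(conversion_times, followup_years, window: float = 3.0) -> np.ndarray:
    """Dichotomise outcomes within a clinical observation window.

    Progressive: conversion within the window.  Stable: no conversion and
    follow-up beyond the window.  Excluded: conversion after the window, or
    insufficient observation (no conversion, follow-up shorter than the
    window).  ``inf`` conversion time means never converts.
    """
    conversion_times = np.asarray(conversion_times, dtype=float)
    followup_years = np.asarray(followup_years, dtype=float)
    if np.any(conversion_times < 0):
        raise ValueError("conversion times must be nonnegative")
    observed_conv = conversion_times <= followup_years
    labels = np.full(conversion_times.shape, EXCLUDED, dtype=object)
    labels[observed_conv & (conversion_times <= window)] = PROGRESSIVE
    labels[~observed_conv & (followup_years > window)] = STABLE
    return labels.astype(str)


def _sphere_mask(grid_shape, center, radius) -> np.ndarray:
    grids = np.indices(grid_shape)
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.argwhere(dist2 <= radius ** 2)


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate one seeded cohort; byte-identical across runs of one config."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    n_normal = int(round(cfg.normal_fraction * n))
    n_mci = n - n_normal
    dx = np.array(["normal"] * n_normal + ["MCI"] * n_mci)

    severity = np.empty(n)
    severity[:n_normal] = rng.gamma(cfg.severity_shape, cfg.normal_severity_scale,
                                    size=n_normal)
    severity[n_normal:] = cfg.mci_severity_shift + rng.gamma(
        cfg.severity_shape, cfg.severity_scale, size=n_mci)

    # cross-sectional features
    cols = {}
    for name, (a, b, sd) in cfg.feature_loadings.items():
        cols[name] = a + b * severity + rng.normal(0.0, sd, size=n)
    # depression sum score: small nonnegative integer, capped at the study
    # entry criterion (GDS <= 5)
    cols["gds"] = np.clip(np.round(cols["gds"]), 0, 5).astype(int)
    p_apoe = 1.0 / (1.0 + np.exp(-(cfg.apoe4_intercept + cfg.apoe4_slope * severity)))
    cols["apoe4"] = (rng.uniform(size=n) < p_apoe).astype(int)

    # voxel data: shared smooth baseline field minus a planted deficit
    mask = _sphere_mask(cfg.grid_shape, cfg.region_center, cfg.region_radius)
    deficit_vol = np.zeros(cfg.grid_shape)
    deficit_vol[tuple(mask.T)] = 1.0
    # smoothing attenuates white noise; rescale so the stated sds are the
    # per-voxel sds of the smooth fields actually added
    delta = np.zeros(cfg.grid_shape)
    delta[tuple(d // 2 for d in cfg.grid_shape)] = 1.0
    atten = float(np.sqrt(np.sum(ndimage.gaussian_filter(delta, cfg.smooth_sigma) ** 2)))
    base_field = cfg.baseline_density + (cfg.baseline_field_sd / atten) * \
        ndimage.gaussian_filter(rng.standard_normal(cfg.grid_shape), cfg.smooth_sigma)
    vox = np.empty((n, int(np.prod(cfg.grid_shape))))
    for i in range(n):
        noise = ndimage.gaussian_filter(rng.standard_normal(cfg.grid_shape),
                                        cfg.smooth_sigma)
        vol = base_field - cfg.deficit_scale * severity[i] * deficit_vol \
            + (cfg.voxel_noise_sd / atten) * noise
        vox[i] = vol.ravel()
    if vox.min() <= 0.0:
        raise InfeasibleConfigError(
            "configured deficit/noise produce non-positive grey-matter density")
    voxel_index = np.argwhere(np.ones(cfg.grid_shape, dtype=bool))
    voxels = VoxelMatrix(vox, voxel_index, cfg.grid_shape)

    # longitudinal memory series
    true_slope = cfg.slope_intercept + cfg.slope_on_severity * severity \
        + rng.normal(0.0, cfg.slope_noise_sd, size=n)
    long_rows = []
    for i in range(n):
        times = np.asarray(cfg.visit_times) + rng.normal(
            0.0, cfg.visit_jitter_sd, size=len(cfg.visit_times))
        times[0] = 0.0  # baseline anchored at the first amyloid scan
        scores = cols["adni_mem"][i] + true_slope[i] * times \
            + rng.normal(0.0, cfg.memory_visit_noise_sd, size=len(times))
        for t, s in zip(times, scores):
            long_rows.append((f"S{i:04d}", float(t), float(s)))
    longitudinal = pd.DataFrame(long_rows, columns=["subject_id", "time_years", "adni_mem"])

    # conversion model and labels (MCI only)
    rate = np.exp(cfg.hazard_intercept + cfg.hazard_slope * severity)
    conversion = rng.exponential(1.0 / rate)
    conversion[dx == "normal"] = np.inf
    followup = rng.uniform(cfg.followup_min_years, cfg.followup_max_years, size=n)
    labels = np.full(n, "", dtype=object)
    labels[dx == "MCI"] = assign_labels(conversion[dx == "MCI"],
                                        followup[dx == "MCI"],
                                        cfg.observation_window)
    labels[dx == "normal"] = "normal"

    # regional tau tracks the planted-region deficit
    region_cols = np.ravel_multi_index(mask.T, cfg.grid_shape)
    region_deficit = base_field.ravel()[region_cols].mean() \
        - vox[:, np.searchsorted(voxels.linear_index(), region_cols)].mean(axis=1)
    tau_cols = {"subject_id": [f"S{i:04d}" for i in range(n)]}
    for name, (a, b, sd) in cfg.tau_loadings.items():
        tau_cols[name] = a + b * region_deficit + rng.normal(0.0, sd, size=n)
    tau = pd.DataFrame(tau_cols)

    table = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "baseline_dx": dx,
        "gds": cols["gds"],
        "adni_mem": cols["adni_mem"],
        "adni_ef": cols["adni_ef"],
        "amyloid_suvr": cols["amyloid_suvr"],
        "apoe4": cols["apoe4"],
        "label": labels.astype(str),
        "conversion_time": conversion,
        "followup_years": followup,
        "severity": severity,
        "true_slope": true_slope,
    })
    return SyntheticCohort(table=table, voxels=voxels, longitudinal=longitudinal,
                           tau=tau, region_mask=mask, config=cfg)
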