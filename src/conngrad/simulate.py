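"""Synthetic resting-state cohorts with planted connectivity gradients.

The generator emulates the data-generating assumptions of the gradient
analysis at desk scale: each subject's 4D image contains an ellipsoidal
ROI whose voxels mix two "cortical" latent signals with weights varying
smoothly (logistically) along a spatial axis, plus a set of out-of-ROI
voxels carrying the latent signals themselves. A group manipulation
steepens or flattens the gradient (sigmoid slope k), continuous trait
scores are linearly coupled to each subject's k, and per-subject motion
summaries are drawn from a log-normal.

The planted per-voxel gradient field g(v) in [0, 1] is stored for
ground-truth recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "make_masks",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
]

#: subject-table columns, in file order
TABLE_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "meanFD",
    "dvars",
    "bprs_total",
    "bprs_pos",
    "sans_total",
    "schizo_general",
    "schizo_pos",
    "schizo_neg",
]

# clinical anchor scales for symptom outcomes: (location, scale)
_OUTCOME_ANCHORS = {
    "bprs_total": (57.3, 10.0),
    "bprs_pos": (16.1, 4.3),
    "sans_total": (34.6, 17.2),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Cohort sizes default to 27 controls and 56 patients. Group gradient
    steepness defaults to 6 (controls) vs 3 (patients): patients show a
    more gradual change in gradient organization. ``steepness_sd`` is
    the between-subject SD of k (a free parameter of the generator);
    ``trait_coupling`` sets trait = a*k + noise.
    """

    n_controls: int = 27
    n_patients: int = 56
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    roi_shape: tuple[float, float, float] = (4.0, 3.0, 3.0)  # semi-axes, voxels
    n_outside_voxels: int = 240
    n_latent_signals: int = 4
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    gradient_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    steepness_control: float = 6.0
    steepness_patient: float = 3.0
    steepness_sd: float = 0.5
    noise_sd: float = 0.5
    trait_coupling: float = 2.0
    trait_noise_sd: float = 1.0
    ar_coefficient: float = 0.4
    voxel_size_mm: float = 3.0
    age_range: tuple[float, float] = (18.0, 50.0)
    female_prob: float = 0.5
    mean_fd_log_mu: float = -2.9  # median meanFD ~ 0.055 mm
    mean_fd_log_sd: float = 0.5
    motion_contaminated: bool = False
    motion_coupling: float = 0.8
    confound_age_by_group: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_latent_signals < 2:
            raise ValueError("n_latent_signals must be >= 2")
        # enough time points for the richest (degree-5) spatial basis
        if self.n_timepoints <= 16:
            raise ValueError("n_timepoints must exceed the TSM basis size (16)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.noise_sd < 0 or self.trait_noise_sd < 0 or self.steepness_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.steepness_control <= 0 or self.steepness_patient <= 0:
            raise ValueError("gradient steepness must be positive")
        if not np.any(np.asarray(self.gradient_axis)):
            raise ValueError("gradient_axis must be a nonzero vector")
        if not 0 <= self.female_prob <= 1:
            raise ValueError("female_prob must be in [0, 1]")

    @property
    def affine(self) -> np.ndarray:
        """RAS affine placing the grid center at the origin."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        center = (np.asarray(self.grid_shape) - 1) / 2.0
        aff[:3, 3] = -center * self.voxel_size_mm
        return aff


@dataclass
class SyntheticCohort:
    """A simulated cohort: images, masks, table and planted ground truth."""

    images: list[np.ndarray]
    roi_mask: np.ndarray
    brain_mask: np.ndarray
    affine: np.ndarray
    subject_table: pd.DataFrame
    planted_gradients: np.ndarray  # (n_subjects, n_roi_voxels)
    steepness: np.ndarray  # per-subject realized k
    config: SimulationConfig

    @property
    def n_subjects(self) -> int:
        return len(self.images)


def make_masks(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Build the ellipsoidal ROI mask and the disjoint out-of-ROI mask.

    The ROI is the voxel set inside an ellipsoid with ``roi_shape``
    semi-axes centered on the grid; the out-of-ROI ("brain") mask holds
    ``n_outside_voxels`` voxels sampled outside a one-voxel guard zone
    around the ROI, deterministically given the config seed.
    """
    config.validate()
    shape = tuple(config.grid_shape)
    semi = np.asarray(config.roi_shape, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("empty ROI: all semi-axes must be positive")
    center = (np.asarray(shape) - 1) / 2.0
    if np.any(center - semi < -0.5) or np.any(center + semi > np.asarray(shape) - 0.5):
        raise ValueError("ROI ellipsoid does not fit inside the image grid")

    idx = np.indices(shape, dtype=float)
    dist2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    roi = dist2 <= 1.0
    if not roi.any():
        raise ValueError("empty ROI")
    n_labels = ndimage.label(roi)[1]
    if n_labels != 1:
        raise ValueError("ROI is disconnected")

    guard = ndimage.binary_dilation(roi, iterations=2)
    candidates = np.argwhere(~guard)
    if len(candidates) < config.n_outside_voxels:
        raise ValueError("grid too small for the requested number of outside voxels")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA5]))
    pick = rng.choice(len(candidates), size=config.n_outside_voxels, replace=False)
    brain = np.zeros(shape, dtype=bool)
    brain[tuple(candidates[np.sort(pick)].T)] = True
    if (roi & brain).any():  # pragma: no cover - guard zone prevents this
        raise ValueError("masks must be disjoint")
    return roi.astype(np.uint8), brain.astype(np.uint8)


def _ar1_series(rng: np.random.Generator, n_series: int, n_t: int, phi: float) -> np.ndarray:
    """Stationary AR(1) Gaussian series with unit marginal variance, (n_t, n_series)."""
    x = np.empty((n_t, n_series))
    x[0] = rng.standard_normal(n_series)
    innov_sd = np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal((n_t - 1, n_series))
    for t in range(1, n_t):
        x[t] = phi * x[t - 1] + innov_sd * eps[t - 1]
    return x


def _planted_gradient(config: SimulationConfig, roi_mask: np.ndarray, k: float) -> np.ndarray:
    """Logistic gradient field over ROI voxels for slope k.

    The projection of voxel millimeter coordinates onto the gradient
    axis is rescaled to [-1, 1] over the ROI, so k is a dimensionless
    slope: g = logistic(k * u), u in [-1, 1].
    """
    vox = np.argwhere(roi_mask.astype(bool))
    coords = (np.c_[vox, np.ones(len(vox))] @ config.affine.T)[:, :3]
    w = np.asarray(config.gradient_axis, dtype=float)
    w = w / np.linalg.norm(w)
    proj = coords @ w
    lo, hi = proj.min(), proj.max()
    theta = (lo + hi) / 2.0
    half_range = (hi - lo) / 2.0
    if half_range == 0:
        raise ValueError("gradient axis degenerate over the ROI")
    u = (proj - theta) / half_range
    return expit(k * u)


def simulate_subject(
    config: SimulationConfig,
    group_label: str,
    rng: np.random.Generator,
    roi_mask: np.ndarray | None = None,
    brain_mask: np.ndarray | None = None,
    steepness: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate one subject's 4D image.

    Returns ``(image4d, planted_gradient, trait_raw)`` where
    ``trait_raw = trait_coupling * k + noise``. Latent signals are AR(1)
    Gaussian series; out-of-ROI voxels carry their zone's latent signal
    plus white noise; each ROI voxel mixes latent signals 1 and 2 as
    ``(1 - g) s1 + g s2`` plus white noise, with the logistic field g.
    """
    config.validate()
    if roi_mask is None or brain_mask is None:
        roi_mask, brain_mask = make_masks(config)
    roi_b = roi_mask.astype(bool)
    brain_b = brain_mask.astype(bool)

    if steepness is None:
        base = (
            config.steepness_control
            if group_label == "control"
            else config.steepness_patient
        )
        steepness = max(base + config.steepness_sd * rng.standard_normal(), 0.2)

    g = _planted_gradient(config, roi_mask, steepness)
    signals = _ar1_series(
        rng, config.n_latent_signals, config.n_timepoints, config.ar_coefficient
    )

    out_idx = np.argwhere(brain_b)
    zones = np.array_split(np.arange(len(out_idx)), config.n_latent_signals)

    T = config.n_timepoints
    image = np.zeros((*config.grid_shape, T), dtype=np.float32)

    out_ts = np.empty((T, len(out_idx)))
    for z, members in enumerate(zones):
        out_ts[:, members] = signals[:, [z]]
    out_ts = out_ts + config.noise_sd * rng.standard_normal(out_ts.shape)
    image[brain_b] = out_ts.T.astype(np.float32)

    roi_ts = (1.0 - g)[None, :] * signals[:, [0]] + g[None, :] * signals[:, [1]]
    roi_ts = roi_ts + config.noise_sd * rng.standard_normal(roi_ts.shape)
    image[roi_b] = roi_ts.T.astype(np.float32)

    trait_raw = config.trait_coupling * steepness + config.trait_noise_sd * rng.standard_normal()

    if not np.all(np.isfinite(image)):
        raise FloatingPointError("non-finite values in simulated image")
    return image, g, float(trait_raw)


def _outcome_scores(
    config: SimulationConfig, k: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Trait scores linearly coupled to per-subject gradient steepness.

    Each score is ``a*k + noise`` mapped onto its clinical anchor scale
    through the theoretical SD ``sqrt(a^2 sd_k^2 + sd_eps^2)`` (a fixed,
    data-independent standardization). Symptom scales are anchored at
    published clinical means/SDs; schizotypy factors are zero-mean,
    unit-variance by construction.
    """
    a = config.trait_coupling
    k_nominal = (config.steepness_control + config.steepness_patient) / 2.0
    sd_theory = np.sqrt(a**2 * config.steepness_sd**2 + config.trait_noise_sd**2)
    if sd_theory == 0:
        sd_theory = 1.0

    def _score() -> np.ndarray:
        raw = a * k + config.trait_noise_sd * rng.standard_normal(len(k))
        return (raw - a * k_nominal) / sd_theory

    scores: dict[str, np.ndarray] = {}
    for name, (loc, scale) in _OUTCOME_ANCHORS.items():
        scores[name] = loc + scale * _score()
    for name in ("schizo_general", "schizo_pos", "schizo_neg"):
        scores[name] = _score()
    return scores


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a full cohort: images, masks, subject table, ground truth."""
    config.validate()
    group_effect = config.steepness_control != config.steepness_patient
    if group_effect and (config.n_controls == 0 or config.n_patients == 0):
        raise ValueError("group effect requested but one group has zero subjects")
    n = config.n_controls + config.n_patients
    if n == 0:
        raise ValueError("cohort must contain at least one subject")

    roi_mask, brain_mask = make_masks(config)
    groups = ["control"] * config.n_controls + ["patient"] * config.n_patients

    ss = np.random.SeedSequence([config.seed, 0x5EED])
    child_seeds = ss.spawn(n + 1)
    table_rng = np.random.default_rng(child_seeds[-1])

    base_k = np.where(
        np.array(groups) == "control",
        config.steepness_control,
        config.steepness_patient,
    )
    k = np.maximum(base_k + config.steepness_sd * table_rng.standard_normal(n), 0.2)

    images: list[np.ndarray] = []
    gradients = []
    for i in range(n):
        rng_i = np.random.default_rng(child_seeds[i])
        img, g, _ = simulate_subject(
            config, groups[i], rng_i, roi_mask, brain_mask, steepness=float(k[i])
        )
        images.append(img)
        gradients.append(g)

    age = table_rng.uniform(*config.age_range, size=n)
    if config.confound_age_by_group:
        age = age - 3.0 * (np.array(groups) == "patient")
        age = np.clip(age, config.age_range[0] - 3.0, config.age_range[1])
    gender = (table_rng.random(n) < config.female_prob).astype(int)

    mean_fd = np.exp(
        config.mean_fd_log_mu + config.mean_fd_log_sd * table_rng.standard_normal(n)
    )
    if config.motion_contaminated:
        k_nominal = (config.steepness_control + config.steepness_patient) / 2.0
        mean_fd = mean_fd * np.exp(config.motion_coupling * (k - k_nominal))
    dvars = 20.0 * mean_fd * np.exp(0.2 * table_rng.standard_normal(n))

    scores = _outcome_scores(config, k, table_rng)
    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "group": groups,
            "age": age,
            "gender": gender,
            "meanFD": mean_fd,
            "dvars": dvars,
            **scores,
        }
    )[TABLE_COLUMNS]
    # symptom scales are clinician-rated in patients only
    table.loc[table["group"] == "control", ["bprs_total", "bprs_pos", "sans_total"]] = np.nan

    return SyntheticCohort(
        images=images,
        roi_mask=roi_mask,
        brain_mask=brain_mask,
        affine=config.affine,
        subject_table=table,
        planted_gradients=np.asarray(gradients),
        steepness=k,
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort to disk: NIfTI images/masks, TSV table, ground truth."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = cohort.affine
    nib.save(nib.Nifti1Image(cohort.roi_mask.astype(np.uint8), aff), out / "roi_mask.nii.gz")
    nib.save(
        nib.Nifti1Image(cohort.brain_mask.astype(np.uint8), aff), out / "brain_mask.nii.gz"
    )
    for sid, img in zip(cohort.subject_table["subject_id"], cohort.images):
        nii = nib.Nifti1Image(img.astype(np.float32), aff)
        nii.header.set_zooms((*np.diag(aff)[:3], cohort.config.tr_seconds))
        nib.save(nii, out / f"{sid}_bold.nii.gz")
    cohort.subject_table.to_csv(out / "subject_table.tsv", sep="\t", index=False)
    np.savez_compressed(
        out / "ground_truth.npz",
        planted_gradients=cohort.planted_gradients,
        steepness=cohort.steepness,
    )
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(cohort.config), indent=2, default=list)
    )
    return out
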