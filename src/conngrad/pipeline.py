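"""End-to-end study replica: simulate/load -> map -> TSM -> inference.

Stages: motion QC on the subject table, per-subregion connectopic
mapping, sign alignment against a within-sample group reference,
spatial-correlation QC, subregion combination, trend-surface fitting
with scree degree selection, 3-SD coefficient outlier exclusion, and the
group/association statistics with Bonferroni gates and contamination
checks. Every exclusion is recorded with a reason in the ledger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import inference, mapping, trend_surface
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "apply_exclusion_ledger",
    "map_subject",
]

#: Bonferroni families: family-wise alpha 0.05 over the printed test counts
ALPHA_FAMILIES = {"group": 4, "symptoms": 3, "schizotypy": 12}

SYMPTOM_OUTCOMES = ["bprs_total", "bprs_pos", "sans_total"]
SCHIZOTYPY_OUTCOMES = ["schizo_general", "schizo_pos", "schizo_neg"]


@dataclass
class PipelineConfig:
    """Analysis plan and QC thresholds for a pipeline run."""

    simulation: SimulationConfig | None = None
    n_modes: int = 1
    degrees: tuple[int, ...] = (1, 2, 3, 4, 5)
    fixed_degree: int | None = None  # None -> scree-selected
    spatial_corr_threshold: float = 0.5
    outlier_n_sd: float = 3.0
    mean_fd_max: float = 0.2
    family_alpha: float = 0.05
    n_neighbors: int | None = None
    out_dir: str | None = None
    seed: int = 0

    def alpha(self, family: str) -> float:
        return inference.bonferroni_alpha(ALPHA_FAMILIES[family], self.family_alpha)


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    stage_counts: dict[str, int]
    exclusions: pd.DataFrame
    chosen_degree: int
    scree: pd.DataFrame
    coefficients: pd.DataFrame
    variance_explained: dict[str, float]
    group_tests: dict[str, inference.GroupTestResult]
    associations: dict[str, dict[str, inference.AssociationResult]]
    partials: dict[str, pd.DataFrame]
    contamination: dict[str, dict]
    config: dict

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, pd.DataFrame):
                return x.to_dict(orient="records")
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, dict):
                return {str(k): conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        return {
            "stage_counts": conv(self.stage_counts),
            "exclusions": conv(self.exclusions),
            "chosen_degree": self.chosen_degree,
            "scree": conv(self.scree),
            "variance_explained": conv(self.variance_explained),
            "group_tests": conv(self.group_tests),
            "associations": conv(self.associations),
            "partial_correlations": conv(self.partials),
            "contamination": conv(self.contamination),
            "config": conv(self.config),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def map_subject(
    image4d: np.ndarray,
    roi_mask: np.ndarray,
    brain_mask: np.ndarray,
    affine: np.ndarray,
    n_modes: int = 1,
    n_neighbors: int | None = None,
) -> tuple[list[mapping.ConnectivityMode], np.ndarray]:
    """Run the connectopic-mapping chain for one subject.

    Returns the extracted modes (unsigned, unaligned) and the ROI voxel
    coordinates.
    """
    ds = mapping.extract_timeseries(image4d, roi_mask, brain_mask, affine=affine)
    reduced = mapping.svd_reduce(ds.B)
    C = mapping.compute_fingerprints(ds.A, reduced)
    S = mapping.eta_squared_matrix(C)
    modes = mapping.laplacian_eigenmaps(S, n_modes=n_modes, n_neighbors=n_neighbors)
    return modes, ds.roi_coords


def apply_exclusion_ledger(
    subject_table: pd.DataFrame,
    qc_results: list[tuple[str, str, str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove flagged subjects and record (subject, stage, reason) rows.

    A subject flagged more than once is removed once, with every reason
    recorded. Unknown subject ids are an error.
    """
    known = set(subject_table["subject_id"])
    for sid, _, _ in qc_results:
        if sid not in known:
            raise ValueError(f"unknown subject id in QC results: {sid}")
    ledger = pd.DataFrame(qc_results, columns=["subject_id", "stage", "reason"])
    flagged = set(ledger["subject_id"])
    filtered = subject_table[~subject_table["subject_id"].isin(flagged)].reset_index(
        drop=True
    )
    return filtered, ledger


def run_pipeline(
    config: PipelineConfig, cohort: SyntheticCohort | None = None
) -> RunReport:
    """Execute the full analysis and return a machine-readable report."""
    if cohort is None:
        if config.simulation is None:
            raise ValueError("config must carry a SimulationConfig or pass a cohort")
        cohort = simulate_cohort(config.simulation)

    table = cohort.subject_table.reset_index(drop=True)
    stage_counts = {"input": len(table)}
    all_exclusions: list[tuple[str, str, str]] = []

    # ---- stage 1: motion QC on the summary table -------------------------
    motion_flags = [
        (sid, "motion_qc", f"meanFD > {config.mean_fd_max:g}")
        for sid, fd in zip(table["subject_id"], table["meanFD"])
        if fd > config.mean_fd_max
    ]
    all_exclusions += motion_flags
    table, _ = apply_exclusion_ledger(table, motion_flags)
    stage_counts["post_motion_qc"] = len(table)

    sid_to_idx = {
        sid: i for i, sid in enumerate(cohort.subject_table["subject_id"])
    }

    # ---- stage 2: connectopic mapping per subject ------------------------
    subject_modes: dict[str, list[mapping.ConnectivityMode]] = {}
    coords = None
    for sid in table["subject_id"]:
        modes, coords = map_subject(
            cohort.images[sid_to_idx[sid]],
            cohort.roi_mask,
            cohort.brain_mask,
            cohort.affine,
            n_modes=config.n_modes,
            n_neighbors=config.n_neighbors,
        )
        subject_modes[sid] = modes

    # ---- stage 3: group reference, alignment, spatial QC -----------------
    aligned: dict[int, dict[str, mapping.ConnectivityMode]] = {}
    spatial_flags: list[tuple[str, str, str]] = []
    references: dict[int, np.ndarray] = {}
    for mode_idx in range(1, config.n_modes + 1):
        maps = [subject_modes[sid][mode_idx - 1].values for sid in table["subject_id"]]
        ref = mapping.group_reference(maps)
        references[mode_idx] = ref
        aligned[mode_idx] = {}
        for sid in table["subject_id"]:
            m = mapping.align_sign(subject_modes[sid][mode_idx - 1], ref)
            aligned[mode_idx][sid] = m
            if not mapping.qc_spatial_corr(
                m, threshold=config.spatial_corr_threshold
            ):
                spatial_flags.append(
                    (
                        sid,
                        "spatial_corr_qc",
                        f"mode {mode_idx} spatial correlation "
                        f"{m.qc_spatial_r:.3f} < {config.spatial_corr_threshold:g}",
                    )
                )
    all_exclusions += spatial_flags
    table, _ = apply_exclusion_ledger(table, spatial_flags)
    stage_counts["post_spatial_corr_qc"] = len(table)

    # ---- stage 4: trend surface fitting ----------------------------------
    mode1 = {sid: aligned[1][sid] for sid in table["subject_id"]}
    fits_by_degree: dict[int, list[trend_surface.TSMFit]] = {}
    for d in config.degrees:
        basis = trend_surface.build_basis(coords, d)
        fits_by_degree[d] = [
            trend_surface.fit_tsm(basis, mode1[sid].values, subject_id=sid)
            for sid in table["subject_id"]
        ]
    scree = trend_surface.select_degree_scree(fits_by_degree)
    degree = (
        config.fixed_degree if config.fixed_degree is not None else scree.chosen_degree
    )
    basis = trend_surface.build_basis(coords, degree)
    fits = (
        fits_by_degree[degree]
        if degree in fits_by_degree
        else [
            trend_surface.fit_tsm(basis, mode1[sid].values, subject_id=sid)
            for sid in table["subject_id"]
        ]
    )

    # ---- stage 5: coefficient outlier exclusion --------------------------
    outliers = trend_surface.detect_outlier_subjects(fits, n_sd=config.outlier_n_sd)
    outlier_flags = [
        (row.subject_id, "tsm_outlier", f"coefficient beyond {config.outlier_n_sd:g} SD")
        for row in outliers.itertuples()
        if row.outlier
    ]
    all_exclusions += outlier_flags
    table, _ = apply_exclusion_ledger(table, outlier_flags)
    stage_counts["post_outlier"] = len(table)

    kept = set(table["subject_id"])
    fits = [f for f in fits if f.subject_id in kept]
    coef_names = [f"b_{name}" for name in basis.names]
    coef_df = pd.DataFrame(
        np.vstack([f.beta for f in fits]),
        columns=coef_names,
    )
    coef_df.insert(0, "subject_id", [f.subject_id for f in fits])
    ve = {
        "mode1_mean": float(np.mean([f.variance_explained for f in fits])),
        "mode1_sd": float(np.std([f.variance_explained for f in fits], ddof=1)),
    }

    # ---- stage 6: statistics ---------------------------------------------
    X = coef_df[coef_names]
    cov = table[["age", "gender"]].to_numpy(dtype=float)
    group_tests: dict[str, inference.GroupTestResult] = {}
    associations: dict[str, dict[str, inference.AssociationResult]] = {}
    partials: dict[str, pd.DataFrame] = {}
    contamination: dict[str, dict] = {}

    has_groups = (
        table["group"].nunique() == 2 and len(table) > X.shape[1] + cov.shape[1] + 2
    )
    if has_groups:
        group_tests["mode1"] = inference.omnibus_group_lrt(
            X, table["group"], cov, alpha=config.alpha("group")
        )

    for family, outcomes in (
        ("symptoms", SYMPTOM_OUTCOMES),
        ("schizotypy", SCHIZOTYPY_OUTCOMES),
    ):
        fam_alpha = config.alpha(family)
        fam_results: dict[str, inference.AssociationResult] = {}
        for out in outcomes:
            if out not in table.columns or table[out].notna().sum() < X.shape[1] + 4:
                continue
            res = inference.association_glm(
                X, table[out], cov, outcome_name=out, alpha=fam_alpha
            )
            if res.significant:
                mask = table[out].notna().to_numpy()
                res.partials = inference.partial_correlations(
                    X[mask], table[out][mask], cov[mask]
                )
                partials[out] = res.partials
            fam_results[out] = res
        if fam_results:
            associations[family] = fam_results

    if has_groups:
        contamination["mode1"] = inference.contamination_checks(
            X,
            table,
            outcomes=[o for fam in associations.values() for o in fam],
            alpha_group=config.alpha("group"),
        )

    exclusions = pd.DataFrame(
        all_exclusions, columns=["subject_id", "stage", "reason"]
    )
    report = RunReport(
        stage_counts=stage_counts,
        exclusions=exclusions,
        chosen_degree=degree,
        scree=scree.table,
        coefficients=coef_df,
        variance_explained=ve,
        group_tests=group_tests,
        associations=associations,
        partials=partials,
        contamination=contamination,
        config={
            "pipeline": {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "simulation"
            },
            "simulation": dataclasses.asdict(config.simulation)
            if config.simulation
            else None,
        },
    )

    if config.out_dir is not None:
        _write_outputs(report, references, aligned, cohort, Path(config.out_dir))
    return report


def _write_outputs(
    report: RunReport,
    references: dict[int, np.ndarray],
    aligned: dict[int, dict[str, mapping.ConnectivityMode]],
    cohort: SyntheticCohort,
    out: Path,
) -> None:
    import nibabel as nib

    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    report.coefficients.to_csv(out / "tsm_coefficients.tsv", sep="\t", index=False)
    report.scree.to_csv(out / "scree.tsv", sep="\t", index=False)
    report.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)

    roi = cohort.roi_mask.astype(bool)
    for mode_idx, ref in references.items():
        vol = np.zeros(cohort.roi_mask.shape, dtype=np.float32)
        vol[roi] = ref
        nib.save(
            nib.Nifti1Image(vol, cohort.affine),
            out / f"group_reference_mode{mode_idx}.nii.gz",
        )
    grad_dir = out / "gradients"
    grad_dir.mkdir(exist_ok=True)
    for mode_idx, per_subject in aligned.items():
        for sid, mode in per_subject.items():
            vol = np.zeros(cohort.roi_mask.shape, dtype=np.float32)
            vol[roi] = mode.values
            nib.save(
                nib.Nifti1Image(vol, cohort.affine),
                grad_dir / f"{sid}_mode{mode_idx}.nii.gz",
            )
    logger.info("pipeline outputs written to %s", out)
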