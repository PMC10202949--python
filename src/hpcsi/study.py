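"""End-to-end study orchestration: simulate, quantify, compare, correlate.

``run_study`` turns a :class:`~hpcsi.cohort.StudySpec` into the full
result bundle of a four-arm metabolic-imaging experiment: the
per-animal study table, group comparisons for every imaging and ex vivo
endpoint, the association matrix between MR readouts and disease
markers, and (optionally) rendered heatmaps and NIfTI maps.  Everything
derives deterministically from the spec's master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from . import __version__ as _pkg_version
from .ce_mri import (brain_ellipse_mask, enhancement_volume,
                     lesion_blobs_for_volume, simulate_t1_pair)
from .cohort import MARKER_NAMES, Study, StudySpec, generate_study
from .pipeline import AnalysisMaps, ZScoreMaps, analyze_dataset, \
    compute_zscores, render_heatmap, roi_mean
from .stats import GroupComparison, anova_tukey, kruskal_bky, linreg, \
    pearson_corr

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResults", "run_study"]

MR_READOUTS = ("lacpyr_roi", "nurea_roi", "t1_volume_mm3")


@dataclass(frozen=True)
class StudyConfig:
    """Analysis choices of a study run.

    ``test_family`` maps endpoint names to "anova" (ANOVA + Tukey HSD)
    or "kruskal" (Kruskal-Wallis + BKY); unlisted endpoints use
    ``default_family``.  The ordinal clinical score defaults to the
    rank-based family.
    """

    default_family: str = "anova"
    test_family: dict[str, str] = field(
        default_factory=lambda: {"eae_score": "kruskal"})
    zero_fill_factor: int = 2
    apodization_hz: float = 10.0
    heatmap_shape: tuple[int, int] = (256, 256)
    write_maps: bool = True

    def family_for(self, endpoint: str) -> str:
        fam = self.test_family.get(endpoint, self.default_family)
        if fam not in ("anova", "kruskal"):
            raise ValueError(f"unknown test family {fam!r}")
        return fam


@dataclass
class StudyResults:
    """Bundle returned by :func:`run_study`."""

    study: Study
    table: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    associations: pd.DataFrame
    zscores: dict[str, ZScoreMaps]
    maps: list[AnalysisMaps]

    def comparisons_frame(self) -> pd.DataFrame:
        rows = []
        for endpoint, comp in self.comparisons.items():
            for _, c in comp.contrasts.iterrows():
                rows.append({
                    "endpoint": endpoint, "test": comp.test,
                    "statistic": comp.statistic, "p_omnibus": comp.pvalue,
                    "group_a": c.group_a, "group_b": c.group_b,
                    "p_raw": c.p_raw, "p_adj": c.p_adj,
                    "fold_change": c.fold_change,
                })
        return pd.DataFrame(rows)

    def fold(self, endpoint: str, group_a: str, group_b: str) -> float:
        """Fold-change mean(group_a)/mean(group_b) for one endpoint."""
        t = self.table
        a = t.loc[t.group == group_a, endpoint].mean()
        b = t.loc[t.group == group_b, endpoint].mean()
        return float(a / b)

    def summary(self) -> str:
        lines = [f"Synthetic study: {len(self.table)} animals, "
                 f"{self.table.group.nunique()} groups"]
        for comp in self.comparisons.values():
            lines.append(comp.summary())
        return "\n".join(lines)


def _t1_endpoint(record, spec: StudySpec) -> float:
    """Simulate the pre/post T1 pair of one animal and segment it."""
    lesions = lesion_blobs_for_volume(
        record.lesion_volume_mm3,
        enhancement_fraction=spec.t1_enhancement_fraction)
    pair = simulate_t1_pair(lesions, noise_sigma=spec.t1_noise_sigma,
                            seed=record.seed + 2)
    brain = brain_ellipse_mask(pair.pre.shape)
    lesion_mask = np.zeros(pair.pre.shape, dtype=bool)
    for blob in lesions:
        lesion_mask |= blob.mask(pair.pre.shape)
    normal = brain & ~binary_dilation(lesion_mask, iterations=3)
    result = enhancement_volume(pair, normal, k_sd=spec.t1_k_sd,
                                analysis_mask=brain)
    return result.volume_mm3


def _associations_table(table: pd.DataFrame) -> pd.DataFrame:
    """MR readouts x disease markers, in the layout of an association table.

    Clinical-score and enhancement-volume rows are per-animal Pearson
    correlations; enzyme/immunofluorescence rows are simple linear
    regressions on group means (marker assays come from separate animal
    subsets in the emulated design, so only group-level pairing exists).
    """
    group_means = table.groupby("group", sort=False).mean(numeric_only=True)
    rows = []
    for readout in MR_READOUTS:
        for var, method in ([("eae_score", "pearson")]
                            + [(m, "linreg") for m in MARKER_NAMES
                               if m in table.columns]
                            + [("t1_volume_mm3", "pearson")]):
            if var == readout:
                continue
            try:
                if method == "pearson":
                    res = pearson_corr(table[readout], table[var],
                                       x_name=readout, y_name=var)
                else:
                    res = linreg(group_means[readout], group_means[var],
                                 x_name=readout, y_name=var)
            except ValueError as exc:
                logger.warning("association %s ~ %s skipped: %s",
                               var, readout, exc)
                continue
            rows.append({
                "mr_readout": readout, "variable": var, "method": res.method,
                "n": res.n, "r": res.r, "r2": res.r2, "slope": res.slope,
                "intercept": res.intercept, "pvalue": res.pvalue,
            })
    return pd.DataFrame(rows)


def run_study(
    spec: StudySpec,
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
    study: Study | None = None,
) -> StudyResults:
    """Run the complete analysis of a (generated or supplied) study.

    Steps: simulate each animal's dynamic CSI acquisition; quantify it
    (zero-fill, reconstruct, sum, fit, ratio, urea normalization, ROI
    averages); build per-voxel cohort z-score maps; simulate and segment
    the contrast-enhanced T1 endpoint; assemble the study table; run
    group comparisons and the association matrix.  With ``out_dir`` the
    tables, maps and a run log are written to disk.
    """
    config = config or StudyConfig()
    if study is None:
        study = generate_study(spec, simulate=True)

    rows = []
    all_maps: list[AnalysisMaps] = []
    for a in study.animals:
        maps = analyze_dataset(
            a.dataset,
            zero_fill_factor=config.zero_fill_factor,
            apodization_hz=config.apodization_hz,
        )
        all_maps.append(maps)
        r = a.record
        row = {
            "animal_id": r.animal_id, "group": r.group,
            "eae_score": r.eae_score, "censored": r.censored,
            "lacpyr_roi": maps.roi_lacpyr(), "nurea_roi": maps.roi_nurea(),
            "t1_volume_mm3": _t1_endpoint(r, spec),
            "kpl_true": r.kpl_brain, "burden_true": r.burden,
        }
        row.update(r.markers)
        rows.append(row)
    table = pd.DataFrame(rows)

    # per-voxel cohort z-scores of pyruvate, lactate and their ratio
    zscores = {}
    for name, attr in (("pyr", "auc_pyr"), ("lac", "auc_lac"),
                       ("lacpyr", "lacpyr")):
        stack = np.stack([getattr(m, attr) for m in all_maps])
        zmaps = compute_zscores(stack)
        zscores[name] = zmaps
        roi = all_maps[0].roi_mask
        table[f"{name}_z_roi"] = [roi_mean(zmaps.z[i], roi)
                                  for i in range(len(all_maps))]

    missing = table.isna().sum()
    for col, n_missing in missing.items():
        if n_missing:
            logger.warning("column %s has %d missing values", col, n_missing)

    endpoints = ["lacpyr_roi", "nurea_roi", "t1_volume_mm3", "eae_score",
                 "lacpyr_z_roi"] + [m for m in MARKER_NAMES
                                    if m in table.columns]
    comparisons = {}
    for endpoint in endpoints:
        named = {g: table.loc[table.group == g, endpoint].to_numpy()
                 for g in table.group.unique()}
        try:
            if config.family_for(endpoint) == "kruskal":
                comparisons[endpoint] = kruskal_bky(named, endpoint=endpoint)
            else:
                comparisons[endpoint] = anova_tukey(named, endpoint=endpoint)
        except ValueError as exc:
            logger.warning("comparison for %s skipped: %s", endpoint, exc)

    associations = _associations_table(table)

    results = StudyResults(study=study, table=table, comparisons=comparisons,
                           associations=associations, zscores=zscores,
                           maps=all_maps)
    if out_dir is not None:
        _write_outputs(results, spec, config, Path(out_dir))
    return results


def _write_outputs(results: StudyResults, spec: StudySpec,
                   config: StudyConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results.table.to_csv(out / "study_table.csv", index=False)
    results.comparisons_frame().to_csv(out / "group_comparisons.csv",
                                       index=False)
    results.associations.to_csv(out / "associations.csv", index=False)
    results.study.ground_truth_table().to_csv(out / "ground_truth.csv",
                                              index=False)
    log = {
        "package_version": _pkg_version,
        "master_seed": spec.master_seed,
        "n_animals": int(len(results.table)),
        "groups": {g.name: g.n_animals for g in spec.groups},
        "csi_noise_sigma": spec.csi_noise_sigma,
        "failed_fits": int(sum(m.n_failed for m in results.maps)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))

    if not config.write_maps:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import nibabel as nib

    table = results.table
    groups = list(table.group.unique())
    fig, axes = plt.subplots(1, len(groups), figsize=(4 * len(groups), 4))
    axes = np.atleast_1d(axes)
    for ax, g in zip(axes, groups):
        idx = np.nonzero((table.group == g).to_numpy())[0]
        mean_map = np.nanmean(
            np.stack([results.maps[i].lacpyr for i in idx]), axis=0)
        filled = np.where(np.isfinite(mean_map), mean_map, 0.0)
        hm = render_heatmap(filled, config.heatmap_shape)
        im = ax.imshow(hm, cmap="inferno")
        ax.set_title(f"{g} lac/pyr")
        ax.axis("off")
        fig.colorbar(im, ax=ax, shrink=0.7)
        nib.save(nib.Nifti1Image(filled.astype(np.float32), affine=np.eye(4)),
                 out / f"lacpyr_{g}.nii.gz")
    fig.tight_layout()
    fig.savefig(out / "lacpyr_heatmaps.png", dpi=120)
    plt.close(fig)
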