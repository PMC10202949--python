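"""Synthetic multi-animal cohorts with a shared latent inflammation burden.

Every per-animal quantity — the brain pyruvate-to-lactate conversion
rate, the ordinal clinical disability (EAE) score, the contrast-enhancing
lesion volume, and nine ex vivo markers (enzyme activities and
immunofluorescence read-outs) — derives from one latent Gaussian
"inflammation burden" b per animal.  That one-factor construction is the
minimal structure producing the pairwise associations the analysis
expects, and its implied correlations are analytically checkable: for
two linear read-outs  X = a + alpha*b + e1, Y = c + gamma*b + e2,

    corr(X, Y) = alpha*gamma*sd_b^2 /
                 sqrt((alpha^2 sd_b^2 + s1^2)(gamma^2 sd_b^2 + s2^2)).

Group contrasts enter through each group's burden distribution and
per-group link intercepts; within-group correlation through the shared
slopes.  ``cpz_eae_preset`` loads a four-arm neuroinflammation
study (control / disease / two treated arms) whose designed fold-changes
are documented in the packaged YAML config.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .acquisition import AcquisitionParams
from .csi import DynamicCSIDataset, generate_dynamic_csi
from .phantom import PhantomGrid, default_phantom

__all__ = [
    "MARKER_NAMES",
    "MARKER_UNITS",
    "MarkerLink",
    "EAELink",
    "GroupSpec",
    "StudySpec",
    "AnimalRecord",
    "SampledAnimal",
    "Study",
    "sample_animal",
    "generate_study",
    "cpz_eae_preset",
]

MARKER_NAMES = ("pdh", "ldh", "iba1", "cd68", "cd3", "pdk1", "gfap",
                "fibrinogen", "myelin")

MARKER_UNITS = {
    "pdh": "nmol/min/mg", "ldh": "nmol/min/mg",
    "iba1": "% area", "cd68": "% area", "cd3": "cells/mm^2",
    "pdk1": "% area", "gfap": "% area", "fibrinogen": "% area",
    "myelin": "% area",
}

MAX_EAE_SCORE = 6
EUTHANASIA_SCORE = 4


@dataclass(frozen=True)
class MarkerLink:
    """Linear link value = max(0, intercept + slope*b + N(0, noise_sd))."""

    intercept: float
    slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def mean(self, b: float) -> float:
        return self.intercept + self.slope * b

    def sample(self, b: float, rng: np.random.Generator) -> float:
        return max(0.0, self.mean(b) + rng.normal(0.0, self.noise_sd))


@dataclass(frozen=True)
class EAELink:
    """Ordered-categorical link from burden to the 0-6 disability scale.

    P(score <= k | b) = expit(cutpoints[k] - (slope*b + offset)).  A
    fixed category law (``probs``) overrides the logit — used for groups
    whose clinical presentation is designed, e.g. an all-mass-at-zero
    law for a treatment that completely prevents physical impairment.
    """

    cutpoints: tuple[float, ...] = (0.0, 1.2, 2.4, 3.6, 4.8, 6.0)
    slope: float = 1.5
    offset: float = 0.0
    probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.probs is not None:
            p = np.asarray(self.probs, dtype=float)
            if p.size != MAX_EAE_SCORE + 1 or np.any(p < 0) \
                    or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("probs must be 7 non-negative values summing to 1")
        else:
            if len(self.cutpoints) != MAX_EAE_SCORE:
                raise ValueError("need 6 cutpoints for a 0-6 scale")
            if np.any(np.diff(self.cutpoints) <= 0):
                raise ValueError("cutpoints must be strictly increasing")

    @classmethod
    def all_zero(cls) -> "EAELink":
        return cls(probs=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0))

    def category_probs(self, b: float) -> np.ndarray:
        if self.probs is not None:
            return np.asarray(self.probs, dtype=float)
        eta = self.slope * b + self.offset
        cdf = expit(np.asarray(self.cutpoints) - eta)
        p = np.empty(MAX_EAE_SCORE + 1)
        p[0] = cdf[0]
        p[1:MAX_EAE_SCORE] = np.diff(cdf)
        p[MAX_EAE_SCORE] = 1.0 - cdf[-1]
        return p

    def sample(self, b: float, rng: np.random.Generator) -> int:
        return int(rng.choice(MAX_EAE_SCORE + 1, p=self.category_probs(b)))

    def expected_score(self, burden_mean: float, burden_sd: float,
                       censor: bool = True, n_nodes: int = 31) -> float:
        """E[score] over the burden distribution (Gauss-Hermite).

        With the euthanasia rule active, scores above 4 are recorded
        as 4, so the expectation uses min(score, 4).
        """
        nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
        scores = np.arange(MAX_EAE_SCORE + 1)
        if censor:
            scores = np.minimum(scores, EUTHANASIA_SCORE)
        total = 0.0
        for x, w in zip(nodes, weights):
            b = burden_mean + math.sqrt(2.0) * burden_sd * x
            total += w * float(self.category_probs(b) @ scores)
        return total / math.sqrt(math.pi)


@dataclass(frozen=True)
class GroupSpec:
    """One experimental arm: burden distribution and all link functions."""

    name: str
    n_animals: int
    burden_mean: float
    burden_sd: float = 0.25
    kpl_log_slope: float = 0.0
    eae: EAELink = field(default_factory=EAELink.all_zero)
    lesion: MarkerLink = field(default_factory=lambda: MarkerLink(0.0))
    markers: dict[str, MarkerLink] = field(default_factory=dict)
    urea_link: MarkerLink = field(default_factory=lambda: MarkerLink(1.0))
    delivery_scale_sd: float = 0.0
    censor_at_4: bool = True

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.burden_sd < 0 or self.delivery_scale_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        unknown = set(self.markers) - set(MARKER_NAMES)
        if unknown:
            raise ValueError(f"unknown markers: {sorted(unknown)}")


@dataclass(frozen=True)
class StudySpec:
    """Full study design: arms, acquisition, phantom template, seed."""

    groups: tuple[GroupSpec, ...]
    acq: AcquisitionParams = field(default_factory=AcquisitionParams)
    phantom_template: PhantomGrid = field(default_factory=default_phantom)
    master_seed: int = 0
    csi_noise_sigma: float = 0.0
    t1_noise_sigma: float = 0.02
    t1_enhancement_fraction: float = 0.5
    t1_k_sd: float = 3.0

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        if not self.groups:
            raise ValueError("at least one group required")

    @property
    def n_animals(self) -> int:
        return sum(g.n_animals for g in self.groups)

    def group(self, name: str) -> GroupSpec:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass
class AnimalRecord:
    """One synthetic animal: design ground truth plus drawn outcomes."""

    animal_id: str
    group: str
    burden: float
    eae_score: int
    censored: bool
    kpl_brain: float
    delivery_scale: float
    urea_factor: float
    lesion_volume_mm3: float
    markers: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.eae_score <= MAX_EAE_SCORE):
            raise ValueError("EAE score must be in 0..6")
        if self.censored and self.eae_score < EUTHANASIA_SCORE:
            raise ValueError("censored implies score >= 4")


@dataclass
class SampledAnimal:
    record: AnimalRecord
    phantom: PhantomGrid
    dataset: DynamicCSIDataset | None = None


@dataclass
class Study:
    spec: StudySpec
    animals: list[SampledAnimal]

    def ground_truth_table(self) -> pd.DataFrame:
        rows = []
        for a in self.animals:
            r = a.record
            row = {
                "animal_id": r.animal_id, "group": r.group,
                "burden": r.burden, "eae_score": r.eae_score,
                "censored": r.censored, "kpl_brain": r.kpl_brain,
                "delivery_scale": r.delivery_scale,
                "lesion_volume_mm3": r.lesion_volume_mm3,
                "seed": r.seed,
            }
            row.update(r.markers)
            rows.append(row)
        return pd.DataFrame(rows)


def sample_animal(
    spec: GroupSpec,
    phantom_template: PhantomGrid,
    seed: int,
    animal_id: str = "a0",
) -> SampledAnimal:
    """Draw one animal: latent burden, then every linked outcome.

    Brain-mask voxels get kPL scaled by exp(kpl_log_slope * b); vascular
    voxels are untouched.  The delivery scale (lognormal, unit mean)
    multiplies both injected-compound amplitudes, emulating
    polarization/transfer variability.
    """
    rng = np.random.default_rng(seed)
    b = float(rng.normal(spec.burden_mean, spec.burden_sd))

    kpl_factor = math.exp(spec.kpl_log_slope * b)
    phantom = phantom_template.with_scaled_kpl(kpl_factor)
    sd = spec.delivery_scale_sd
    delivery_scale = float(np.exp(rng.normal(-0.5 * sd ** 2, sd))) if sd > 0 else 1.0
    urea_factor = spec.urea_link.sample(b, rng)
    phantom = phantom.with_scaled_delivery(delivery_scale,
                                           delivery_scale * urea_factor)

    raw_score = spec.eae.sample(b, rng)
    censored = spec.censor_at_4 and raw_score >= EUTHANASIA_SCORE
    score = min(raw_score, EUTHANASIA_SCORE) if spec.censor_at_4 else raw_score

    markers = {name: link.sample(b, rng) for name, link in spec.markers.items()}
    lesion_volume = spec.lesion.sample(b, rng)

    brain_kpl = [k.kpl for row, mrow in zip(phantom.kinetics, phantom.brain_mask)
                 for k, m in zip(row, mrow) if m]
    record = AnimalRecord(
        animal_id=animal_id, group=spec.name, burden=b,
        eae_score=score, censored=censored,
        kpl_brain=float(np.mean(brain_kpl)) if brain_kpl else 0.0,
        delivery_scale=delivery_scale, urea_factor=urea_factor,
        lesion_volume_mm3=lesion_volume, markers=markers, seed=seed,
    )
    return SampledAnimal(record=record, phantom=phantom)


def generate_study(spec: StudySpec, simulate: bool = True) -> Study:
    """Sample every animal of the study; optionally simulate its CSI data.

    Per-animal seeds derive deterministically from the master seed, so a
    fixed master seed reproduces the full bundle bit for bit.
    """
    seed_rng = np.random.default_rng(spec.master_seed)
    animals: list[SampledAnimal] = []
    for g in spec.groups:
        seeds = seed_rng.integers(0, 2 ** 31 - 1, size=g.n_animals)
        for i, s in enumerate(seeds):
            a = sample_animal(g, spec.phantom_template, int(s),
                              animal_id=f"{g.name}_{i:02d}")
            if simulate:
                a.dataset = generate_dynamic_csi(
                    a.phantom, spec.acq, noise_sigma=spec.csi_noise_sigma,
                    seed=int(s) + 1,
                )
            animals.append(a)
    return Study(spec=spec, animals=animals)


# ---------------------------------------------------------------------------
# Calibrated preset
# ---------------------------------------------------------------------------


def _load_preset_config() -> dict:
    ref = importlib.resources.files("hpcsi") / "presets" / "cpz_eae.yaml"
    with ref.open("r") as f:
        return yaml.safe_load(f)


def _calibrate_eae_offset(target_mean: float, cutpoints, slope: float,
                          burden_mean: float, burden_sd: float) -> float:
    """Solve the logit offset so the expected (censored) score hits target."""

    def f(offset: float) -> float:
        link = EAELink(cutpoints=tuple(cutpoints), slope=slope, offset=offset)
        return link.expected_score(burden_mean, burden_sd) - target_mean

    return brentq(f, -40.0, 40.0, xtol=1e-10)


def cpz_eae_preset(
    seed: int = 0,
    n_override: dict[str, int] | None = None,
) -> StudySpec:
    """Four-arm neuroinflammation study with designed fold-changes.

    All tuned constants live in the packaged ``presets/cpz_eae.yaml``;
    this builder only converts group means into link intercepts
    (intercept = mean - slope * group burden mean) and calibrates the
    ordinal-score offsets by root finding.  ``n_override`` replaces
    per-group animal counts, e.g. for large Monte-Carlo runs.
    """
    cfg = _load_preset_config()
    burden_sd = float(cfg["burden_sd"])
    kpl_slope = float(cfg["kpl_log_slope"])
    m_cfg = cfg["markers"]
    within_slope = float(m_cfg["within_slope"])
    within_noise = float(m_cfg["within_noise"])
    l_cfg = cfg["lesion"]
    eae_cfg = cfg["eae"]
    cutpoints = tuple(float(c) for c in eae_cfg["cutpoints"])
    eae_slope = float(eae_cfg["slope"])

    groups = []
    for name, g_cfg in cfg["groups"].items():
        n = int(g_cfg["n_animals"])
        if n_override and name in n_override:
            n = int(n_override[name])
        b_mean = float(g_cfg["burden_mean"])

        markers = {}
        for marker, (direction, *means) in m_cfg["table"].items():
            mean_g = float(means[list(cfg["groups"]).index(name)])
            slope = direction * within_slope * mean_g
            markers[marker] = MarkerLink(
                intercept=mean_g - slope * b_mean,
                slope=slope,
                noise_sd=within_noise * mean_g,
            )

        lesion_mean = float(l_cfg["means"][name])
        lesion_slope = float(l_cfg["within_slope"]) * lesion_mean
        lesion = MarkerLink(
            intercept=lesion_mean - lesion_slope * b_mean,
            slope=lesion_slope,
            noise_sd=float(l_cfg["within_noise"]) * lesion_mean,
        )

        target = eae_cfg["target_means"][name]
        if target == "zero":
            eae = EAELink.all_zero()
        else:
            offset = _calibrate_eae_offset(float(target), cutpoints, eae_slope,
                                           b_mean, burden_sd)
            eae = EAELink(cutpoints=cutpoints, slope=eae_slope, offset=offset)

        groups.append(GroupSpec(
            name=name, n_animals=n, burden_mean=b_mean, burden_sd=burden_sd,
            kpl_log_slope=kpl_slope, eae=eae, lesion=lesion, markers=markers,
            delivery_scale_sd=float(cfg["delivery_scale_sd"]),
        ))

    return StudySpec(
        groups=tuple(groups),
        phantom_template=default_phantom(kpl=float(cfg["kpl_base"])),
        master_seed=seed,
        csi_noise_sigma=float(cfg["csi_noise_sigma"]),
        t1_noise_sigma=float(cfg["t1_noise_sigma"]),
        t1_enhancement_fraction=float(cfg["t1_enhancement_fraction"]),
        t1_k_sd=float(cfg["t1_k_sd"]),
    )


def designed_fold_changes(spec: StudySpec, control: str = "control",
                          disease: str = "cpz_eae") -> dict[str, float]:
    """Designed group contrasts implied by a spec's links (no sampling).

    The lactate/pyruvate fold between two groups is
    exp(kpl_log_slope * (b1 - b2)) because the AUC-ratio map is linear
    in kPL (see :func:`hpcsi.kinetics.auc_ratio_theory`).
    """
    g_ctl = spec.group(control)
    g_dis = spec.group(disease)
    folds = {
        "lacpyr_disease_vs_control":
            math.exp(g_dis.kpl_log_slope * (g_dis.burden_mean - g_ctl.burden_mean)),
    }
    for g in spec.groups:
        if g.name in (control, disease):
            continue
        folds[f"lacpyr_decrease_{g.name}"] = math.exp(
            g.kpl_log_slope * (g_dis.burden_mean - g.burden_mean))
    folds["lesion_disease_vs_control"] = (
        g_dis.lesion.mean(g_dis.burden_mean) / g_ctl.lesion.mean(g_ctl.burden_mean))
    return folds
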