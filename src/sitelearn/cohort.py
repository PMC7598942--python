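"""Synthetic multi-site case-control cohort generator.

The generator emulates the statistical structure of a pooled consortium
FreeSurfer ROI table so that every downstream stage (preprocessing, fold
construction, classification, confound control, importance inference,
subgroup analysis) is testable without private data:

* ~46 site blocks of log-uniformly varying size (consortium site sizes are
  heavily skewed);
* per-site additive feature offsets and multiplicative scale factors
  (scanner/protocol effects), shared by all subjects of a site;
* a small, spatially distributed diagnosis effect and a larger distributed
  medication effect, both expressed in within-site SD units;
* a fraction of sites that are exclusively medicated or exclusively
  unmedicated (medication status partially aligned with site);
* a weak negative medication-illness-duration coupling (point-biserial
  r = -0.094 by default), realized by a closed-form mean gap between the
  duration distributions of medicated and unmedicated patients;
* MCAR missingness plus a subset of subjects with >10% of cells missing.

The feature model for subject i at site s is

    x_ij = offset_sj + scale_sj * (age_i*a_j + male_i*b_j
                                   + dx_i*d_j + med_i*m_j + eps_ij)

with eps ~ N(0, 1), so within a site the noise SD is scale_sj and the
injected effects d_j, m_j are in within-site SD units by construction.
The generator emits a :class:`GroundTruth` sidecar sufficient to recompute
every expected group difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .table import META_COLUMNS, SubjectTable
from ._seeds import derive_rng

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "canonical_feature_names",
    "generate_cohort",
    "inject_missingness",
]

_DK_REGIONS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
]

_SUBCORTICAL = [
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala",
    "accumbens",
]


def canonical_feature_names() -> list[str]:
    """157 FreeSurfer-style feature names.

    2x34 cortical thickness + 2x34 surface area (Desikan-Killiany),
    2 whole-hemisphere mean thickness + 2 whole-hemisphere total area,
    2x7 subcortical volumes, 2 lateral ventricles, total intracranial
    volume.
    """
    names: list[str] = []
    for hemi in ("lh", "rh"):
        names += [f"{hemi}_{r}_thickavg" for r in _DK_REGIONS]
    for hemi in ("lh", "rh"):
        names += [f"{hemi}_{r}_surfavg" for r in _DK_REGIONS]
    names += ["lh_MeanThickness_thickavg", "rh_MeanThickness_thickavg"]
    names += ["lh_TotalSurfArea_surfavg", "rh_TotalSurfArea_surfavg"]
    for hemi in ("L", "R"):
        names += [f"{hemi}{s}_vol" for s in _SUBCORTICAL]
    names += ["LLatVent_vol", "RLatVent_vol", "ICV_vol"]
    assert len(names) == 157
    return names


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic cohort generator.

    Effect sizes are (n_affected_features, d) pairs with d in within-site
    SD units.  ``site_medication_purity`` is the fraction of sites whose
    patients are exclusively medicated or exclusively unmedicated.
    """

    n_sites: int = 46
    site_size_range: tuple[int, int] = (12, 250)
    case_fraction: float = 0.527
    n_features: int = 157
    site_offset_sd: float = 0.5
    site_scale_sd: float = 0.1
    diagnosis_effect: tuple[int, float] = (20, 0.2)
    medication_effect: tuple[int, float] = (30, 0.5)
    medicated_fraction: float = 0.5
    site_medication_purity: float = 0.5
    medication_duration_target_r: float = -0.094
    duration_mean: float = 9.0
    duration_sd: float = 5.0
    age_range: tuple[float, float] = (8.0, 65.0)
    sex_ratio: float = 0.5
    age_slope_sd: float = 0.01
    sex_effect_sd: float = 0.1
    missing_rate: float = 0.01
    heavy_missing_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "case_fraction", "medicated_fraction", "site_medication_purity",
            "missing_rate", "heavy_missing_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.site_size_range[0] < 4:
            raise ValidationError("site_size_range min must be >= 4")
        for k, _ in (self.diagnosis_effect, self.medication_effect):
            if k > self.n_features:
                raise ValidationError("more affected features than features")
        if abs(self.medication_duration_target_r) >= 1.0:
            raise ValidationError("correlation target must lie in (-1, 1)")
        if self.medication_duration_target_r != 0.0 and (
            self.medicated_fraction in (0.0, 1.0) and self.site_medication_purity == 0.0
        ):
            raise ContractError(
                "medication-duration correlation target is infeasible when "
                "all or no patients are medicated"
            )


@dataclass
class GroundTruth:
    """Everything needed to recompute the injected structure exactly."""

    feature_names: list[str]
    dx_affected: list[int]
    dx_effect: list[float]
    med_affected: list[int]
    med_effect: list[float]
    site_offsets: dict[str, list[float]]
    site_scales: dict[str, float]
    age_slopes: list[float]
    sex_effects: list[float]
    duration_mean_gap: float
    clean_features: np.ndarray = field(repr=False)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["clean_features"] = np.asarray(self.clean_features).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["clean_features"] = np.asarray(d["clean_features"], dtype=float)
        return cls(**d)


def _site_sizes(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.site_size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_sites))
    return np.maximum(np.round(sizes).astype(int), 4)


def _duration_mean_gap(cfg: CohortConfig) -> float:
    """Closed-form mean gap giving the requested point-biserial correlation.

    With medicated fraction p, within-group SD s and mean gap D, the
    point-biserial correlation of the medication flag with duration is
    r = D*sqrt(p*q) / sqrt(s^2 + p*q*D^2), hence
    D = r*s / sqrt(p*q*(1-r^2)).
    """
    r = cfg.medication_duration_target_r
    p = cfg.medicated_fraction
    q = 1.0 - p
    if r == 0.0:
        return 0.0
    if p <= 0.0 or q <= 0.0:
        raise ContractError(
            "cannot realize a nonzero medication-duration correlation when "
            f"medicated_fraction={p}"
        )
    return r * cfg.duration_sd / np.sqrt(p * q * (1.0 - r**2))


def generate_cohort(config: CohortConfig) -> tuple[SubjectTable, GroundTruth]:
    """Generate one synthetic multi-site cohort plus its ground truth.

    Deterministic under ``config.seed``.  Missingness is applied last, via
    :func:`inject_missingness`; the pre-missingness feature matrix is kept
    in the ground truth.
    """
    config.validate()
    cfg = config
    rng = derive_rng(cfg.seed, "cohort")

    if cfg.n_features == 157:
        feature_names = canonical_feature_names()
    else:
        feature_names = [f"feat{i:03d}" for i in range(cfg.n_features)]
    p = cfg.n_features

    sizes = _site_sizes(cfg, rng)
    n = int(sizes.sum())
    site_labels = [f"site{i:02d}" for i in range(cfg.n_sites)]
    site_of = np.repeat(np.arange(cfg.n_sites), sizes)

    # diagnosis: every site hosts both classes
    dx = np.zeros(n, dtype=int)
    start = 0
    for s, m in enumerate(sizes):
        n_cases = int(np.clip(round(m * cfg.case_fraction), 1, m - 1))
        idx = start + rng.permutation(m)[:n_cases]
        dx[idx] = 1
        start += m
    case = dx == 1

    # medication: pure sites are all-medicated or all-unmedicated
    n_pure = int(round(cfg.site_medication_purity * cfg.n_sites))
    pure_sites = rng.permutation(cfg.n_sites)[:n_pure]
    pure_medicated = {int(s): bool(i % 2 == 0) for i, s in enumerate(pure_sites)}
    med = np.zeros(n, dtype=float)
    med[:] = np.nan
    for i in range(n):
        if not case[i]:
            continue
        s = int(site_of[i])
        if s in pure_medicated:
            med[i] = float(pure_medicated[s])
        else:
            med[i] = float(rng.random() < cfg.medicated_fraction)

    # covariates
    age = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    male = (rng.random(n) < cfg.sex_ratio).astype(int)
    sex = np.where(male == 1, "M", "F")

    # clinical fields (cases only).  Duration draws are centered exactly on
    # the analytic per-group means so the realized medication-duration gap
    # carries no Monte-Carlo error (only the physiological-range clipping
    # perturbs the correlation slightly).
    gap = _duration_mean_gap(cfg)
    duration = np.full(n, np.nan)
    onset = np.full(n, np.nan)
    ybocs = np.full(n, np.nan)
    case_idx = np.flatnonzero(case)
    base_mean = cfg.duration_mean - cfg.medicated_fraction * gap  # keep overall mean fixed
    med_case = med[case_idx] == 1.0
    raw = rng.normal(0.0, cfg.duration_sd, size=len(case_idx))
    for grp, mu in ((med_case, base_mean + gap), (~med_case, base_mean)):
        if grp.sum() > 1:
            raw[grp] += mu - raw[grp].mean()
        elif grp.any():
            raw[grp] = mu
    dur_case = np.clip(raw, 0.25, np.maximum(age[case_idx] - 4.0, 0.25))
    duration[case_idx] = dur_case
    onset[case_idx] = age[case_idx] - dur_case
    ybocs[case_idx] = np.clip(np.round(rng.normal(25.0, 6.0, len(case_idx))), 0, 40)

    # site effects
    offsets = rng.normal(0.0, cfg.site_offset_sd, size=(cfg.n_sites, p))
    scales = np.exp(rng.normal(0.0, cfg.site_scale_sd, size=cfg.n_sites))

    # effect supports: disjoint by default so the two effects are separable
    perm = rng.permutation(p)
    k_dx, d_dx = cfg.diagnosis_effect
    k_med, d_med = cfg.medication_effect
    dx_affected = np.sort(perm[:k_dx])
    med_affected = np.sort(perm[k_dx:k_dx + k_med]) if k_dx + k_med <= p else np.sort(
        rng.permutation(p)[:k_med]
    )
    dx_vec = np.zeros(p)
    dx_vec[dx_affected] = d_dx
    med_vec = np.zeros(p)
    med_vec[med_affected] = d_med

    age_slopes = rng.normal(0.0, cfg.age_slope_sd, size=p)
    sex_effects = rng.normal(0.0, cfg.sex_effect_sd, size=p)

    age_c = age - age.mean()
    eps = rng.normal(0.0, 1.0, size=(n, p))
    latent = (
        age_c[:, None] * age_slopes[None, :]
        + male[:, None] * sex_effects[None, :]
        + dx[:, None] * dx_vec[None, :]
        + np.nan_to_num(med)[:, None] * med_vec[None, :]
        + eps
    )
    X = offsets[site_of] + scales[site_of, None] * latent

    meta = pd.DataFrame(
        {
            "subject_id": [f"sub{i:05d}" for i in range(n)],
            "site_id": [site_labels[s] for s in site_of],
            "diagnosis": dx,
            "age": age,
            "sex": sex,
            "medicated": med,
            "ybocs": ybocs,
            "age_of_onset": onset,
            "illness_duration": duration,
        },
        columns=META_COLUMNS,
    )
    features = pd.DataFrame(X, columns=feature_names)
    table = SubjectTable(meta, features)

    gt = GroundTruth(
        feature_names=feature_names,
        dx_affected=[int(i) for i in dx_affected],
        dx_effect=[float(v) for v in dx_vec[dx_affected]],
        med_affected=[int(i) for i in med_affected],
        med_effect=[float(v) for v in med_vec[med_affected]],
        site_offsets={site_labels[s]: offsets[s].tolist() for s in range(cfg.n_sites)},
        site_scales={site_labels[s]: float(scales[s]) for s in range(cfg.n_sites)},
        age_slopes=age_slopes.tolist(),
        sex_effects=sex_effects.tolist(),
        duration_mean_gap=float(gap),
        clean_features=X.copy(),
    )

    if cfg.missing_rate > 0 or cfg.heavy_missing_fraction > 0:
        table = inject_missingness(
            table, cfg.missing_rate, cfg.heavy_missing_fraction,
            seed=cfg.seed,
        )
    return table, gt


def inject_missingness(
    table: SubjectTable,
    missing_rate: float,
    heavy_missing_fraction: float,
    seed: int,
) -> SubjectTable:
    """Mask feature cells: MCAR at ``missing_rate`` plus heavy-missing rows.

    Heavy-missing subjects get a masked fraction drawn uniformly in
    (0.12, 0.30), i.e. strictly above the 10% exclusion threshold applied
    downstream.  Deterministic under ``seed``.
    """
    for v in (missing_rate, heavy_missing_fraction):
        if not 0.0 <= v <= 1.0:
            raise ValidationError("rates must be in [0, 1]")
    rng = derive_rng(seed, "missingness")
    n, p = table.features.shape
    mask = rng.random((n, p)) < missing_rate
    n_heavy = int(round(heavy_missing_fraction * n))
    heavy = rng.permutation(n)[:n_heavy]
    for i in heavy:
        frac = rng.uniform(0.12, 0.30)
        k = max(int(np.ceil(frac * p)), int(np.floor(0.10 * p)) + 1)
        cols = rng.permutation(p)[:k]
        mask[i, cols] = True
    feats = table.features.copy()
    arr = feats.to_numpy()
    arr[mask] = np.nan
    out = pd.DataFrame(arr, columns=feats.columns)
    return SubjectTable(table.meta.copy(), out, _validated=True)
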