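"""Synthetic cohorts with the structure the normative model assumes.

The generator draws a multi-group cohort (a large 3 T normal-control
reference, a smaller 1.5 T normal-control set, and 1.5 T sMCI/pMCI/AD
evaluation groups, with the demographic structure of a typical mixed-site
aging study) and produces ROI volumes from the same log-linear generative
form the model fits:

    log10 V = intercept + b_age*age + b_field*field + b_sex*sex
              + b_etiv*log10(eTIV) + group_shift + N(0, residual_sd)

Every generative parameter is retained in a truth record so that fitting,
QC and evaluation can be tested for parameter recovery and calibration
without any data download. Group sizes, age distributions and sex ratios
default to the cohort structure described in the package documentation;
the per-ROI coefficients are plausible invented defaults (no published
values exist for them).
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from .containers import Group, SubjectRecord, VolumeTable

__all__ = [
    "GroupConfig",
    "RoiConfig",
    "SimulationConfig",
    "default_config",
    "default_roi_catalog",
    "simulate_cohort",
    "inject_disease_effect",
    "z_effect_to_log10_shift",
]


@dataclass
class GroupConfig:
    """One diagnostic/scanner stratum of the simulated cohort."""

    size: int
    age_mean: float
    age_sd: float
    male_fraction: float
    field_strength: int  # 0 = 3 T, 1 = 1.5 T
    diagnosis: Group

    def validate(self) -> None:
        if self.size < 0:
            raise ValueError(f"group size must be >= 0, got {self.size}")
        if self.age_sd <= 0:
            raise ValueError(f"age SD must be > 0, got {self.age_sd}")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError(f"male fraction must be in [0, 1], got {self.male_fraction}")
        if self.field_strength not in (0, 1):
            raise ValueError(f"field_strength must be 0 or 1, got {self.field_strength}")


@dataclass
class RoiConfig:
    """Generative coefficients for one ROI.

    ``typical_log10_volume`` anchors the surface at a reference subject
    (age 65, female, 3 T, eTIV 1.5e6 mm^3); the intercept is derived from
    it. ``disease_shift`` maps group label -> additive log10 shift
    (negative = atrophy).
    """

    name: str
    typical_log10_volume: float
    age_slope: float = -0.001  # log10 units per year
    field_offset: float = -0.02  # 1.5 T relative to 3 T, log10 units
    sex_offset: float = 0.01  # male relative to female, log10 units
    etiv_slope: float = 0.7  # log10 volume per log10 eTIV
    disease_shift: dict[Group, float] = field(default_factory=dict)

    _REF_AGE = 65.0
    _REF_LOG10_ETIV = np.log10(1.5e6)

    @property
    def intercept(self) -> float:
        return (
            self.typical_log10_volume
            - self.age_slope * self._REF_AGE
            - self.etiv_slope * self._REF_LOG10_ETIV
        )


@dataclass
class SimulationConfig:
    """Full cohort recipe: strata, eTIV model, ROI coefficients, noise."""

    groups: dict[str, GroupConfig]
    rois: list[RoiConfig]
    etiv_mean_female: float = 1.45e6
    etiv_sd_female: float = 1.1e5
    etiv_mean_male: float = 1.60e6
    etiv_sd_male: float = 1.2e5
    residual_sd: float = 0.05  # log10 units
    age_floor: float = 40.0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for g in self.groups.values():
            g.validate()
        if not self.rois:
            raise ValueError("at least one ROI required")
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names in config")
        if self.residual_sd < 0:
            raise ValueError("residual SD must be >= 0")
        for v in (self.etiv_sd_female, self.etiv_sd_male):
            if v <= 0:
                raise ValueError("eTIV SDs must be > 0")


def z_effect_to_log10_shift(delta_z: float, residual_sd: float) -> float:
    """Convert a target Z-scale effect size to a log10-volume shift.

    A disease group shifted by ``delta_z * residual_sd`` log10 units sits
    ``delta_z`` standard deviations below the normative surface, so the
    binormal AUC limit Phi(delta_z / sqrt(2)) applies when the Z variance
    is ~1 in both groups.
    """
    return delta_z * residual_sd


# Anatomically plausible typical volumes (mm^3) for the named default ROIs.
_NAMED_ROIS: list[tuple[str, float]] = [
    ("Right Hippocampus", 3500.0),
    ("Left Hippocampus", 3400.0),
    ("Right Amygdala", 1600.0),
    ("Left Amygdala", 1550.0),
    ("Right Parahippocampal Gyrus", 4100.0),
    ("Left Parahippocampal Gyrus", 4000.0),
    ("Right Inferior Temporal Gyrus", 11000.0),
    ("Left Inferior Temporal Gyrus", 10800.0),
    ("Right Middle Temporal Gyrus", 14000.0),
    ("Left Middle Temporal Gyrus", 13800.0),
    ("Left Thalamus Proper", 7000.0),
    ("Right Thalamus Proper", 7100.0),
    ("Left Entorhinal Area", 1800.0),
    ("Right Entorhinal Area", 1850.0),
]

# Default Z-scale disease effects (multiples of the residual SD, applied as
# negative/atrophic shifts); invented to mirror the usual ordering of
# medial-temporal involvement: strongest in AD hippocampus, weak in sMCI.
_DISEASE_Z_EFFECTS: dict[str, dict[Group, float]] = {
    "Hippocampus": {Group.AD: 2.5, Group.PMCI: 0.9, Group.SMCI: 0.35},
    "Amygdala": {Group.AD: 2.0, Group.PMCI: 0.7, Group.SMCI: 0.25},
    "Parahippocampal": {Group.AD: 1.5, Group.PMCI: 0.5, Group.SMCI: 0.2},
    "Entorhinal": {Group.AD: 1.5, Group.PMCI: 0.5, Group.SMCI: 0.2},
    "Temporal Gyrus": {Group.AD: 1.2, Group.PMCI: 0.35, Group.SMCI: 0.1},
    "Thalamus": {Group.AD: 0.8, Group.PMCI: 0.2, Group.SMCI: 0.1},
}


def default_roi_catalog(n_rois: int = 20, residual_sd: float = 0.05) -> list[RoiConfig]:
    """Named medial-temporal/limbic ROIs first, generic filler ROIs after.

    Disease shifts are attached to the named ROIs; filler ROIs carry no
    disease effect (they act as null regions in discrimination tests).
    """
    rois: list[RoiConfig] = []
    for name, vol in _NAMED_ROIS[:n_rois]:
        shifts: dict[Group, float] = {}
        for key, effects in _DISEASE_Z_EFFECTS.items():
            if key in name:
                shifts = {
                    g: -z_effect_to_log10_shift(dz, residual_sd) for g, dz in effects.items()
                }
                break
        rois.append(RoiConfig(name=name, typical_log10_volume=float(np.log10(vol)), disease_shift=shifts))
    for k in range(len(rois), n_rois):
        # generic gray-matter ROI volumes spread over ~1.5 decades
        vol = 10 ** (3.2 + 1.4 * (k - len(_NAMED_ROIS)) / max(n_rois - len(_NAMED_ROIS), 1))
        rois.append(RoiConfig(name=f"ROI_{k + 1:03d}", typical_log10_volume=float(np.log10(vol))))
    return rois


def default_config(n_rois: int = 20, residual_sd: float = 0.05) -> SimulationConfig:
    """Default cohort recipe.

    Group sizes, age distributions and sex ratios follow the mixed
    1.5 T / 3 T aging-cohort structure documented in docs/methods.md:
    a 3 T NC reference of 1089 (mean age 58.5, SD 14.3, 375 male), a
    1.5 T NC set of 146 (67.6 +- 5.66, 68 male), and 1.5 T evaluation
    groups sMCI 102 (72.8 +- 6.10, 57 male), pMCI 112 (73.0 +- 5.54,
    47 male), AD 147 (73.5 +- 6.60, 63 male).
    """
    groups = {
        "NC_3T": GroupConfig(1089, 58.5, 14.3, 375 / 1089, 0, Group.NC),
        "NC_1.5T": GroupConfig(146, 67.6, 5.66, 68 / 146, 1, Group.NC),
        "sMCI": GroupConfig(102, 72.8, 6.10, 57 / 102, 1, Group.SMCI),
        "pMCI": GroupConfig(112, 73.0, 5.54, 47 / 112, 1, Group.PMCI),
        "AD": GroupConfig(147, 73.5, 6.60, 63 / 147, 1, Group.AD),
    }
    cfg = SimulationConfig(
        groups=groups,
        rois=default_roi_catalog(n_rois=n_rois, residual_sd=residual_sd),
        residual_sd=residual_sd,
    )
    cfg.validate()
    return cfg


def _truncated_normal(rng: np.random.Generator, mean, sd, floor, size) -> np.ndarray:
    a = (floor - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(
    config: SimulationConfig, seed: int
) -> tuple[list[SubjectRecord], VolumeTable, dict]:
    """Draw a cohort and its ROI volume table.

    Ages are truncated-normal (floor ``config.age_floor``); sex is
    Bernoulli(male_fraction); eTIV is sex-conditional normal; volumes
    follow the log-linear generative surface plus Gaussian residual noise.
    Identical (config, seed) pairs produce bitwise-identical output. The
    returned truth record retains every generative parameter.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    rows: list[np.ndarray] = []
    ids: list[str] = []

    intercepts = np.array([r.intercept for r in config.rois])
    age_slopes = np.array([r.age_slope for r in config.rois])
    field_offsets = np.array([r.field_offset for r in config.rois])
    sex_offsets = np.array([r.sex_offset for r in config.rois])
    etiv_slopes = np.array([r.etiv_slope for r in config.rois])

    for gname, g in config.groups.items():
        if g.size == 0:
            continue
        ages = _truncated_normal(rng, g.age_mean, g.age_sd, config.age_floor, g.size)
        sexes = (rng.random(g.size) < g.male_fraction).astype(int)
        etiv_mean = np.where(sexes == 1, config.etiv_mean_male, config.etiv_mean_female)
        etiv_sd = np.where(sexes == 1, config.etiv_sd_male, config.etiv_sd_female)
        etiv = np.maximum(rng.normal(etiv_mean, etiv_sd), 8e5)
        shifts = np.array(
            [r.disease_shift.get(g.diagnosis, 0.0) for r in config.rois]
        )
        noise = rng.normal(0.0, config.residual_sd, size=(g.size, len(config.rois)))
        log10v = (
            intercepts[None, :]
            + age_slopes[None, :] * ages[:, None]
            + field_offsets[None, :] * g.field_strength
            + sex_offsets[None, :] * sexes[:, None]
            + etiv_slopes[None, :] * np.log10(etiv)[:, None]
            + shifts[None, :]
            + noise
        )
        rows.append(10.0 ** log10v)
        tag = gname.replace(".", "p").replace(" ", "_")
        for i in range(g.size):
            sid = f"{tag}_{i + 1:04d}"
            ids.append(sid)
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    age=float(ages[i]),
                    sex=int(sexes[i]),
                    field_strength=g.field_strength,
                    etiv=float(etiv[i]),
                    group=g.diagnosis,
                )
            )

    table = VolumeTable(
        subject_ids=ids,
        roi_names=[r.name for r in config.rois],
        volumes=np.vstack(rows),
    )
    truth = {
        "seed": seed,
        "residual_sd": config.residual_sd,
        "rois": {
            r.name: {
                "intercept": r.intercept,
                "age_slope": r.age_slope,
                "field_offset": r.field_offset,
                "sex_offset": r.sex_offset,
                "etiv_slope": r.etiv_slope,
                "disease_shift": {g.value: s for g, s in r.disease_shift.items()},
            }
            for r in config.rois
        },
        "groups": {
            name: {k: (v.value if isinstance(v, Group) else v) for k, v in asdict(g).items()}
            for name, g in config.groups.items()
        },
    }
    return subjects, table, truth


def inject_disease_effect(
    table: VolumeTable,
    subjects: list[SubjectRecord],
    roi_set: list[str],
    shift: float,
    group: str | Group,
) -> VolumeTable:
    """Return a copy of the table with volumes of one group reduced by
    ``shift`` log10 units (positive shift = atrophy) in the named ROIs.

    Cells outside the named group x ROI block are bit-identical to the
    input.
    """
    g = group if isinstance(group, Group) else Group.parse(group)
    by_id = {s.subject_id: s for s in subjects}
    for roi in roi_set:
        if roi not in table.roi_names:
            raise KeyError(f"ROI {roi!r} not in volume table")
    group_rows = [
        i for i, sid in enumerate(table.subject_ids) if by_id[sid].group == g
    ]
    if not group_rows:
        raise ValueError(f"no subjects with group label {g.value!r} in the table")
    volumes = table.volumes.copy()
    cols = [table.column_index(r) for r in roi_set]
    idx = np.ix_(group_rows, cols)
    if shift != 0.0:  # keep shift-0 calls bit-identical (no log/exp round trip)
        volumes[idx] = 10.0 ** (np.log10(volumes[idx]) - shift)
    return VolumeTable(
        subject_ids=copy.copy(table.subject_ids),
        roi_names=copy.copy(table.roi_names),
        volumes=volumes,
    )
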