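"""Configuration blocks for the virtual-implantation pipeline.

Every tunable constant of the pipeline lives here: the population
calibration used by the cohort sampler, the parametric shape family of the
synthetic distal tibia, the resection-plane parameters (proximal offset and
posterior inclination) and the implant-fitting tolerances.  The defaults
describe the adult reference population the package is calibrated to
(137 women / 182 men; sex-specific resection-area and body-height
distributions) and a five-size modular tibial-component system.

A full :class:`RunConfig` can be round-tripped through a single YAML file so
that every pipeline run is reproducible from ``(config, seed)`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import CalibrationError

__all__ = [
    "SexCalibration",
    "PopulationCalibration",
    "AnatomyParams",
    "ResectionParams",
    "FitParams",
    "RunConfig",
    "default_calibration",
    "default_config",
    "load_config",
    "save_config",
]


@dataclass
class SexCalibration:
    """Marginal distributions for one sex.

    Heights, areas, BMI and age are modelled as truncated normals; the
    centre is the published median (height/BMI/age) or mean (area), the
    spread is the published SD where available and otherwise one quarter of
    the published range width, and truncation is at the published observed
    range.
    """

    area_mean: float  # mm^2
    area_sd: float  # mm^2
    area_range: tuple[float, float]  # mm^2, observed min/max
    height_center: float  # cm
    height_spread: float  # cm
    height_range: tuple[float, float]  # cm
    area_height_corr: float  # latent Gaussian-copula correlation
    bmi_center: float  # kg/m^2
    bmi_spread: float
    bmi_range: tuple[float, float]
    age_center: float  # years
    age_spread: float
    age_range: tuple[float, float]

    def validate(self) -> None:
        for name in ("area_sd", "height_spread", "bmi_spread", "age_spread"):
            if getattr(self, name) <= 0:
                raise CalibrationError(f"{name} must be > 0")
        for name in ("area_range", "height_range", "bmi_range", "age_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise CalibrationError(f"{name} must be ordered (lo < hi)")
        if self.area_range[0] <= 0:
            raise CalibrationError("area_range must be positive")
        if not -1 < self.area_height_corr < 1:
            raise CalibrationError("area_height_corr must lie in (-1, 1)")


@dataclass
class PopulationCalibration:
    """Sex-stratified population model for cohort simulation."""

    female: SexCalibration
    male: SexCalibration
    sex_fraction_female: float = 137.0 / 319.0

    def validate(self) -> None:
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise CalibrationError("sex_fraction_female must lie in [0, 1]")
        self.female.validate()
        self.male.validate()

    def for_sex(self, sex: str) -> SexCalibration:
        if sex == "female":
            return self.female
        if sex == "male":
            return self.male
        raise CalibrationError(f"unknown sex {sex!r}")


@dataclass
class AnatomyParams:
    """Shape family of the synthetic distal tibia.

    The resection-level contour is a rounded oval (medio-lateral semi-axis
    ``aspect_ratio`` times the antero-posterior one), tapered posteriorly,
    flattened anteriorly over ``anterior_flat_fraction`` of its half-width
    (the anterior cortical flat), carrying a medial-malleolus bump and
    low-order Fourier perturbations.  All lengths in mm.
    """

    aspect_ratio: float = 1.35  # medial-lateral / anterior-posterior
    taper: float = 0.25  # posterior narrowing fraction
    anterior_flat_fraction: float = 0.45
    malleolus_bump_amplitude: float = 0.95  # mm, centre of per-subject draw
    malleolus_bump_width: float = 0.20  # radians, angular half-width
    contour_irregularity: float = 0.008  # relative Fourier scale
    dome_depth: float = 7.0  # mm, articular concavity depth
    shaft_length: float = 60.0  # mm, modelled segment above the rim
    n_circumference: int = 128  # mesh vertices per ring
    subject_variability: float = 0.35  # relative spread of bump draws

    def validate(self) -> None:
        from .errors import GenerationError

        if self.aspect_ratio <= 0:
            raise GenerationError("aspect_ratio must be > 0")
        if not 0.0 <= self.taper < 1.0:
            raise GenerationError("taper must lie in [0, 1)")
        if not 0.0 <= self.anterior_flat_fraction < 1.0:
            raise GenerationError("anterior_flat_fraction must lie in [0, 1)")
        if self.malleolus_bump_amplitude < 0:
            raise GenerationError("malleolus_bump_amplitude must be >= 0")
        if self.dome_depth <= 2.0:
            raise GenerationError("dome_depth must exceed 2 mm")
        if self.shaft_length <= self.dome_depth + 10.0:
            raise GenerationError("shaft_length too short for the dome + cut")
        if self.n_circumference < 32:
            raise GenerationError("n_circumference must be >= 32")


@dataclass
class ResectionParams:
    """Osteotomy definition: cut height above the dome apex and slope."""

    proximal_offset: float = 2.0  # mm proximal to the dome apex
    posterior_inclination: float = 4.0  # degrees of posterior slope

    def validate(self) -> None:
        from .errors import LandmarkError

        if self.proximal_offset <= 0:
            raise LandmarkError("proximal_offset must be > 0")
        if not 0.0 <= self.posterior_inclination < 90.0:
            raise LandmarkError("posterior_inclination must lie in [0, 90)")


@dataclass
class FitParams:
    """Implant footprint family and placement tolerances.

    ``nominal_areas`` are the five tray surface areas of the modular system.
    ``overhang_tol_mm2`` is the uncovered-footprint area tolerated before a
    placement is declared infeasible; the default is calibrated so that the
    smallest resections observed in the reference population remain
    fittable with size 2 (see docs/methods.md).
    """

    nominal_areas: tuple[float, ...] = (884.40, 1028.60, 1178.50, 1403.60, 1600.80)
    aspect_ratio: float = 1.35
    taper: float = 0.25
    anterior_flat_fraction: float = 0.45
    contact_distance: float = 1.5  # mm, perimeter-to-cortex contact band
    overhang_tol_mm2: float = 60.0  # mm^2, absolute overhang tolerance
    rotation_tol_deg: float = 2.0  # allowed deviation from shield alignment
    coarse_step: float = 1.0  # mm, translation grid
    coarse_halfspan: float = 4.0  # mm
    fine_step: float = 0.1  # mm
    fine_halfspan: float = 0.5  # mm
    contact_tie_tol: float = 0.01  # contact-score tie window for size choice

    def validate(self) -> None:
        if len(self.nominal_areas) < 1 or any(a <= 0 for a in self.nominal_areas):
            raise CalibrationError("nominal_areas must be positive")
        if list(self.nominal_areas) != sorted(self.nominal_areas):
            raise CalibrationError("nominal_areas must be increasing")
        if self.overhang_tol_mm2 < 0 or self.contact_distance <= 0:
            raise CalibrationError("fit tolerances must be positive")


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the seed and output path."""

    calibration: PopulationCalibration
    anatomy: AnatomyParams = field(default_factory=AnatomyParams)
    resection: ResectionParams = field(default_factory=ResectionParams)
    fitting: FitParams = field(default_factory=FitParams)
    n_subjects: int = 319
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise CalibrationError("n_subjects must be >= 1")
        self.calibration.validate()
        self.anatomy.validate()
        self.resection.validate()
        self.fitting.validate()


def default_calibration() -> PopulationCalibration:
    """Reference-population calibration (137 F / 182 M healthy adults)."""
    female = SexCalibration(
        area_mean=1064.0,
        area_sd=102.9,
        area_range=(810.3, 1335.3),
        height_center=165.0,
        height_spread=(180.0 - 146.0) / 4.0,
        height_range=(146.0, 180.0),
        area_height_corr=0.49,
        bmi_center=23.4,
        bmi_spread=(43.2 - 13.3) / 4.0,
        bmi_range=(13.3, 43.2),
        age_center=54.0,
        age_spread=(81.0 - 15.0) / 4.0,
        age_range=(15.0, 81.0),
    )
    male = SexCalibration(
        area_mean=1341.2,
        area_sd=153.0,
        area_range=(997.3, 1856.7),
        height_center=180.0,
        height_spread=(203.0 - 162.0) / 4.0,
        height_range=(162.0, 203.0),
        area_height_corr=0.42,
        bmi_center=23.7,
        bmi_spread=(38.8 - 15.6) / 4.0,
        bmi_range=(15.6, 38.8),
        age_center=43.5,
        age_spread=(89.0 - 16.0) / 4.0,
        age_range=(16.0, 89.0),
    )
    return PopulationCalibration(female=female, male=male)


def default_config(n_subjects: int = 319, seed: int = 0) -> RunConfig:
    return RunConfig(
        calibration=default_calibration(), n_subjects=n_subjects, seed=seed
    )


def _tuples_to_lists(obj):
    if isinstance(obj, tuple):
        return [_tuples_to_lists(x) for x in obj]
    if isinstance(obj, list):
        return [_tuples_to_lists(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig verbatim to one YAML file."""
    payload = _tuples_to_lists(asdict(config))
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _sex_from_dict(d: dict) -> SexCalibration:
    d = dict(d)
    for key in ("area_range", "height_range", "bmi_range", "age_range"):
        d[key] = tuple(d[key])
    return SexCalibration(**d)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML and validate it."""
    raw = yaml.safe_load(Path(path).read_text())
    calib = PopulationCalibration(
        female=_sex_from_dict(raw["calibration"]["female"]),
        male=_sex_from_dict(raw["calibration"]["male"]),
        sex_fraction_female=raw["calibration"]["sex_fraction_female"],
    )
    fit_raw = dict(raw["fitting"])
    fit_raw["nominal_areas"] = tuple(fit_raw["nominal_areas"])
    config = RunConfig(
        calibration=calib,
        anatomy=AnatomyParams(**raw["anatomy"]),
        resection=ResectionParams(**raw["resection"]),
        fitting=FitParams(**fit_raw),
        n_subjects=raw["n_subjects"],
        seed=raw["seed"],
    )
    config.validate()
    return config
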