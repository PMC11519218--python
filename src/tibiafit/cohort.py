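"""Cohort sampling: anthropometrics and per-subject target resection areas.

Subjects are drawn sex-stratified; within each sex, (height, resection
area) follow a Gaussian copula whose latent correlation is the published
height-area Pearson coefficient and whose marginals are truncated normals
calibrated to the reference population (centre = published median/mean,
spread = published SD or quarter range width, truncated to the published
observed range).  BMI is sampled independently of area — in the reference
data the resection area is essentially unrelated to BMI — and weight is
derived from BMI and height so the BMI identity holds exactly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .config import PopulationCalibration, SexCalibration
from .errors import ParseError

__all__ = ["SubjectProfile", "CohortRecord", "sample_cohort", "write_cohort", "read_cohort"]

_MAX_SEED = 2**31 - 1


@dataclass
class SubjectProfile:
    subject_id: str
    sex: str  # "female" | "male"
    age: float  # years
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2


@dataclass
class CohortRecord:
    profile: SubjectProfile
    target_area: float  # mm^2, ground-truth resection-level area
    seed: int  # per-subject anatomy seed


def _truncnorm(center: float, spread: float, lo: float, hi: float):
    a = (lo - center) / spread
    b = (hi - center) / spread
    return stats.truncnorm(a, b, loc=center, scale=spread)


def _sample_sex(
    rng: np.random.Generator, n: int, calib: SexCalibration
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw (height, area, bmi, age) for n subjects of one sex."""
    rho = calib.area_height_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n, method="cholesky")
    u = stats.norm.cdf(z)
    height = _truncnorm(
        calib.height_center, calib.height_spread, *calib.height_range
    ).ppf(u[:, 0])
    area = _truncnorm(calib.area_mean, calib.area_sd, *calib.area_range).ppf(u[:, 1])
    bmi = _truncnorm(calib.bmi_center, calib.bmi_spread, *calib.bmi_range).ppf(
        rng.random(n)
    )
    age = _truncnorm(calib.age_center, calib.age_spread, *calib.age_range).ppf(
        rng.random(n)
    )
    return height, area, bmi, age


def sample_cohort(
    n: int, calibration: PopulationCalibration, seed: int
) -> list[CohortRecord]:
    """Sample ``n`` subjects with target resection areas; fully deterministic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    calibration.validate()
    rng = np.random.default_rng(seed)
    sexes = np.where(
        rng.random(n) < calibration.sex_fraction_female, "female", "male"
    )
    subject_seeds = rng.integers(0, _MAX_SEED, size=n)

    records: list[CohortRecord | None] = [None] * n
    for sex in ("female", "male"):
        idx = np.flatnonzero(sexes == sex)
        if idx.size == 0:
            continue
        height, area, bmi, age = _sample_sex(rng, idx.size, calibration.for_sex(sex))
        for k, i in enumerate(idx):
            h, b = float(height[k]), float(bmi[k])
            weight = b * (h / 100.0) ** 2
            profile = SubjectProfile(
                subject_id=f"S{i:04d}",
                sex=sex,
                age=float(age[k]),
                height=h,
                weight=weight,
                bmi=b,
            )
            records[i] = CohortRecord(
                profile=profile,
                target_area=float(area[k]),
                seed=int(subject_seeds[i]),
            )
    return records  # type: ignore[return-value]


_COLUMNS = ["subject_id", "sex", "age_y", "height_cm", "weight_kg", "bmi", "target_area_mm2", "seed"]


def write_cohort(records: list[CohortRecord], path: str | Path) -> None:
    """Write cohort records to CSV (comma separated, dot decimal, header)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in records:
            p = rec.profile
            writer.writerow(
                [
                    p.subject_id,
                    p.sex,
                    repr(p.age),
                    repr(p.height),
                    repr(p.weight),
                    repr(p.bmi),
                    repr(rec.target_area),
                    rec.seed,
                ]
            )


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort CSV back; raises ParseError with the offending line."""
    records: list[CohortRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty cohort file", line=1) from None
        if header != _COLUMNS:
            raise ParseError(f"unexpected header {header!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(_COLUMNS):
                raise ParseError(
                    f"expected {len(_COLUMNS)} fields, got {len(row)}", line=lineno
                )
            sid, sex, age_s, height_s, weight_s, bmi_s, area_s, seed_s = row
            if sex not in ("female", "male"):
                raise ParseError(f"unknown sex {sex!r}", line=lineno)
            try:
                age = float(age_s)
                height = float(height_s)
                weight = float(weight_s)
                bmi = float(bmi_s)
                area = float(area_s)
                seed = int(seed_s)
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", line=lineno) from None
            profile = SubjectProfile(
                subject_id=sid, sex=sex, age=age, height=height, weight=weight, bmi=bmi
            )
            records.append(CohortRecord(profile=profile, target_area=area, seed=seed))
    return records
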