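"""Synthetic four-view screening cohorts with a known aging signal.

Real screening mammograms are restricted data, so the package ships a
phantom generator that reproduces the *structure* the age model consumes:
four views per examination (bilateral CC/MLO), an age-dependent
fibroglandular-density signal, ACR-like density categories correlated with
age, longitudinal exams per patient, a cancer subgroup whose breasts appear
older than their chronological age, and follow-up outcomes whose hazard
depends on the true aging offset.

The aging signal is deliberately multi-cue so that no single pixel
statistic trivially solves the task: the fibroglandular tissue fraction
decays linearly with apparent age, the skin line thickens, and the count of
bright calcification-like speckles grows.  The fibroglandular fraction of
the rendered foreground follows the closed-form curve
``fibroglandular_fraction(age)`` exactly (up to pixel rounding), which is
what makes the generator testable.

Every source of randomness flows from ``CohortConfig.seed``; identical
config + seed yields byte-identical manifests and pixels.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "CohortConfig",
    "ExamRecord",
    "VIEW_KEYS",
    "DENSITY_THRESHOLDS",
    "fibroglandular_fraction",
    "render_exam",
    "assign_density_category",
    "simulate_followup",
    "generate_cohort",
    "MANIFEST_COLUMNS",
]

VIEW_KEYS = ("R-CC", "R-MLO", "L-CC", "L-MLO")

#: Quartile thresholds on the fibroglandular-fraction scale mapping to the
#: four-level ACR-style density scheme (A = mostly fatty ... D = extremely
#: dense).
DENSITY_THRESHOLDS = (0.25, 0.50, 0.75)

MANIFEST_COLUMNS = [
    "patient_id", "exam_id", "age", "density", "cancer",
    "followup_time", "event", "path_RCC", "path_RMLO", "path_LCC", "path_LMLO",
]

# rendering intensity palette (fraction of full scale)
_FATTY = 0.30
_PECTORAL = 0.40
_SKIN = 0.45
_FIBRO = 0.75
_SPECKLE = 0.95
#: intensity separating dense (fibroglandular/speckle) from non-dense tissue
DENSE_INTENSITY_THRESHOLD = 0.60


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults describe the desk-scale cohort used throughout the test-suite:
    an adult screening age range, a small per-patient aging offset
    (sd 3 years) creating nonzero healthy gap variance, and a cancer
    subgroup whose apparent age is shifted by ``acceleration_delta`` years.
    """

    n_patients: int = 60
    exams_per_patient: tuple[int, int] = (1, 2)
    age_range: tuple[float, float] = (18.0, 98.0)
    image_shape: tuple[int, int] = (256, 128)  # H, W
    density_age_slope: float = 0.0075  # fibroglandular fraction lost per year
    noise_sd: float = 0.01            # additive Gaussian, intensity units
    cancer_fraction: float = 0.0
    acceleration_delta: float = 5.0   # years of apparent aging in cancer group
    patient_offset_sd: float = 3.0    # years, healthy apparent-age spread
    appearance_jitter_sd: float = 8.0  # years, per-exam density variability at fixed age
    hazard_log_hr: float = float(np.log(1.02))  # per year of true gap
    baseline_hazard: float = 0.05     # events per year at gap 0
    followup_horizon: float = 10.0    # years, administrative censoring
    unknown_density_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.age_range
        if not (1.0 <= lo < hi <= 100.0):
            raise ValueError("age_range must be within [1, 100] with min < max")
        if not 0.0 <= self.cancer_fraction <= 1.0:
            raise ValueError("cancer_fraction must be in [0, 1]")
        if self.exams_per_patient[0] < 1 or self.exams_per_patient[0] > self.exams_per_patient[1]:
            raise ValueError("exams_per_patient must be a nondecreasing range of counts >= 1")
        if min(self.image_shape) < 8:
            raise ValueError("image_shape too small to render a phantom")


@dataclass
class ExamRecord:
    """One examination: four view images plus labels and outcomes.

    ``true_apparent_age`` is the generator's hidden ground truth (the age
    the images were rendered from); it is never written to the manifest the
    model reads.
    """

    patient_id: str
    exam_id: str
    exam_index: int
    views: dict[str, str]           # view key -> image path
    chronological_age: float
    density_category: str           # A/B/C/D/unknown
    cancer_label: bool
    followup_time: float
    event: bool
    true_apparent_age: float

    def __post_init__(self):
        if set(self.views) != set(VIEW_KEYS):
            raise ValueError(f"exam must have exactly the four views {VIEW_KEYS}")
        if self.followup_time <= 0:
            raise ValueError("followup_time must be positive")


def fibroglandular_fraction(age: float, slope: float = 0.0075) -> float:
    """Analytic fibroglandular tissue fraction at a given apparent age.

    Linear decay from 0.85 at age 1, clipped away from {0, 1}; strictly
    decreasing over [1, 100] at the default slope.
    """
    return float(np.clip(0.85 - slope * (age - 1.0), 0.02, 0.98))


def _foreground(view: str, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Breast-shaped foreground mask (right-breast orientation, chest wall
    at the left edge) and the pectoral sub-mask (MLO only)."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    pect = np.zeros(shape, dtype=bool)
    if view == "CC":
        # half disc against the chest wall
        r = 0.46 * H
        mask = ((rr - H / 2.0) ** 2 + cc ** 2) <= r ** 2
    elif view == "MLO":
        # oblique half-ellipse with a pectoral wedge in the upper corner
        mask = ((rr - 0.5 * H) / (0.48 * H)) ** 2 + (cc / (0.92 * W)) ** 2 <= 1.0
        pect = mask & (cc / (0.45 * W) + rr / (0.5 * H) <= 1.0)
    else:
        raise ValueError(f"unknown projection {view!r}")
    return mask, pect


def render_exam(apparent_age: float, view_key: str, rng: np.random.Generator,
                shape: tuple[int, int] = (256, 128),
                density_age_slope: float = 0.0075,
                noise_sd: float = 0.01) -> np.ndarray:
    """Render one 16-bit grayscale view at the given apparent age.

    The left-breast views are exact horizontal mirrors of the right-breast
    rendering under the same generator state.
    """
    if not 1.0 <= apparent_age <= 100.0:
        raise ValueError("apparent_age must lie in [1, 100]")
    if min(shape) <= 0:
        raise ValueError("image shape must be positive")
    laterality, view = view_key.split("-")
    if laterality not in ("R", "L"):
        raise ValueError(f"unknown laterality in view key {view_key!r}")

    H, W = shape
    mask, pect = _foreground(view, shape)
    n_fg = int(mask.sum())

    img = np.zeros(shape, dtype=np.float64)
    img[mask] = _FATTY
    img[pect] = _PECTORAL

    # skin line thickens with age
    skin_t = 1 + int(apparent_age // 25)
    interior = ndimage.binary_erosion(mask, iterations=skin_t)
    img[mask & ~interior] = _SKIN

    # fibroglandular tissue: top-k pixels of a centrality field inside the
    # interior, with k chosen so the dense fraction of the *whole*
    # foreground follows the analytic curve
    frac = fibroglandular_fraction(apparent_age, density_age_slope)
    k = min(int(round(frac * n_fg)), int(interior.sum()))
    if k > 0:
        rr, cc = np.mgrid[0:H, 0:W]
        centrality = -((rr - 0.5 * H) ** 2 + (cc - 0.35 * W) ** 2)
        cand = np.where(interior.ravel())[0]
        order = np.argpartition(-centrality.ravel()[cand], k - 1)[:k]
        img.ravel()[cand[order]] = _FIBRO

    # calcification-like speckles, more with age
    n_speck = int(apparent_age // 10)
    fg_idx = np.where(mask.ravel())[0]
    if n_speck > 0 and fg_idx.size:
        pos = rng.choice(fg_idx, size=n_speck, replace=False)
        prr, pcc = np.unravel_index(pos, shape)
        for r0, c0 in zip(prr, pcc):
            img[r0:r0 + 2, c0:c0 + 2] = _SPECKLE

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)

    if laterality == "L":
        img = img[:, ::-1]
    return np.round(img * 65535.0).astype(np.uint16)


def assign_density_category(fibroglandular_frac: float,
                            thresholds: tuple[float, float, float] = DENSITY_THRESHOLDS,
                            unknown_prob: float = 0.0,
                            rng: np.random.Generator | None = None) -> str:
    """Map a fibroglandular fraction to an ACR-style category A-D.

    Optionally masks the label to ``unknown`` with probability
    ``unknown_prob``, emulating datasets without density annotations.
    """
    if not 0.0 <= fibroglandular_frac <= 1.0:
        raise ValueError("fibroglandular fraction must be in [0, 1]")
    if unknown_prob > 0.0:
        if rng is None:
            raise ValueError("rng required when unknown_prob > 0")
        if rng.random() < unknown_prob:
            return "unknown"
    for cat, thr in zip("ABC", thresholds):
        if fibroglandular_frac < thr:
            return cat
    return "D"


def simulate_followup(true_gap: float, horizon: float, baseline_hazard: float,
                      log_hr: float, rng: np.random.Generator) -> tuple[float, bool]:
    """Exponential event time with hazard ``baseline_hazard * exp(log_hr * gap)``,
    administratively censored at ``horizon``."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rate = baseline_hazard * np.exp(log_hr * true_gap)
    t = rng.exponential(1.0 / rate)
    if t >= horizon:
        return horizon, False
    return float(t), True


def generate_cohort(config: CohortConfig, out_dir: str | os.PathLike,
                    ) -> tuple[list[ExamRecord], pd.DataFrame]:
    """Generate a cohort: view images on disk plus a CSV manifest.

    Per patient a latent trajectory ``apparent_age(t) = chronological_age(t)
    + patient_offset`` is drawn (offset ~ Normal(0, patient_offset_sd));
    patients in the cancer subgroup additionally age by
    ``acceleration_delta`` years in appearance.  Images are rendered from
    the apparent age; density categories derive from the rendered
    fibroglandular fraction via fixed quartile thresholds; follow-up is
    simulated per exam from the true aging offset.

    Returns the exam records (which keep the hidden ``true_apparent_age``)
    and the manifest frame written to ``out_dir/manifest.csv``.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    os.makedirs(img_dir, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    records: list[ExamRecord] = []

    n_cancer = int(round(config.cancer_fraction * config.n_patients))
    cancer_ids = set(rng.choice(config.n_patients, size=n_cancer, replace=False).tolist())

    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        is_cancer = p in cancer_ids
        offset = rng.normal(0.0, config.patient_offset_sd)
        if is_cancer:
            offset += config.acceleration_delta
        n_exams = int(rng.integers(config.exams_per_patient[0],
                                   config.exams_per_patient[1] + 1))
        age0 = rng.uniform(lo, hi - 2.0 * (n_exams - 1)) if hi - 2.0 * (n_exams - 1) > lo \
            else rng.uniform(lo, hi)
        for e in range(n_exams):
            age = float(np.clip(age0 + rng.uniform(1.0, 2.0) * e, lo, hi))
            apparent = float(np.clip(age + offset, 1.0, 100.0))
            # what the images show: apparent age plus between-woman density
            # variability at fixed age (no hazard consequence of its own)
            rendered = float(np.clip(
                apparent + rng.normal(0.0, config.appearance_jitter_sd), 1.0, 100.0))
            eid = f"{pid}_E{e:02d}"
            paths: dict[str, str] = {}
            for vk in VIEW_KEYS:
                img = render_exam(rendered, vk, rng, shape=config.image_shape,
                                  density_age_slope=config.density_age_slope,
                                  noise_sd=config.noise_sd)
                fname = f"{pid}_E{e:02d}_{vk.replace('-', '')}.png"
                fpath = os.path.join(img_dir, fname)
                Image.fromarray(img).save(fpath)
                paths[vk] = fpath
            frac = fibroglandular_fraction(rendered, config.density_age_slope)
            density = assign_density_category(frac, unknown_prob=config.unknown_density_prob,
                                              rng=rng)
            t, ev = simulate_followup(apparent - age, config.followup_horizon,
                                      config.baseline_hazard, config.hazard_log_hr, rng)
            records.append(ExamRecord(
                patient_id=pid, exam_id=eid, exam_index=e, views=paths,
                chronological_age=age, density_category=density,
                cancer_label=is_cancer, followup_time=t, event=ev,
                true_apparent_age=apparent))

    manifest = records_to_manifest(records)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return records, manifest


def records_to_manifest(records: list[ExamRecord]) -> pd.DataFrame:
    rows = [{
        "patient_id": r.patient_id, "exam_id": r.exam_id,
        "age": r.chronological_age, "density": r.density_category,
        "cancer": int(r.cancer_label), "followup_time": r.followup_time,
        "event": int(r.event),
        "path_RCC": r.views["R-CC"], "path_RMLO": r.views["R-MLO"],
        "path_LCC": r.views["L-CC"], "path_LMLO": r.views["L-MLO"],
    } for r in records]
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def manifest_to_records(manifest: pd.DataFrame) -> list[ExamRecord]:
    """Rebuild exam records from a manifest (true apparent age unknown: NaN)."""
    recs = []
    for _, row in manifest.iterrows():
        recs.append(ExamRecord(
            patient_id=row.patient_id, exam_id=row.exam_id,
            exam_index=int(str(row.exam_id).rsplit("E", 1)[-1]) if "E" in str(row.exam_id) else 0,
            views={"R-CC": row.path_RCC, "R-MLO": row.path_RMLO,
                   "L-CC": row.path_LCC, "L-MLO": row.path_LMLO},
            chronological_age=float(row.age), density_category=str(row.density),
            cancer_label=bool(row.cancer), followup_time=float(row.followup_time),
            event=bool(row.event), true_apparent_age=float("nan")))
    return recs


def config_to_dict(config: CohortConfig) -> dict:
    return dataclasses.asdict(config)
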