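"""Synthetic longitudinal screening-cohort simulator.

The simulator produces cohorts with the statistical structure the risk model
assumes, so the entire pipeline is testable without any clinical data:

* a discrete annual hazard ``h = logistic(b0 + beta . riskf + gamma * u)``
  with a per-patient latent frailty ``u ~ N(0, 1)``; the event year is the
  first success of a per-year Bernoulli draw, so event years are geometric
  given covariates (which gives an analytic target for goodness-of-fit
  checks);
* roughly annual screening exams with jittered spacing; exams on/after the
  diagnosis date are dropped; independent censoring from an exponential
  follow-up drawn after the last exam;
* four-view 16-bit images per exam: a half-ellipse breast against a black
  background, a per-patient static parenchymal texture whose amplitude scales
  with ACR density, static bright blobs (benign structures that *look* like
  masses), and — on the future event side only — a Gaussian lesion whose
  radius and contrast grow linearly as the exam date approaches the diagnosis
  within the growth horizon ``T_g``.  With lesion amplitude ``alpha = 0`` the
  images carry no outcome information at all.

Because benign blob brightness overlaps early-lesion brightness, a single
exam is deliberately ambiguous; the *growth* across exams is the reliable
signal, which is exactly what a multi-time-point model can exploit and a
single-time-point model cannot.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .cohort import (
    MISSING,
    PatientTimeline,
    RiskFactorVector,
    ScreeningExam,
    SIDES,
    TumorRecord,
    VIEWS,
)

SCHEMA_VERSION = "1"


def _json_default(o):
    import numpy as _np
    if isinstance(o, (_np.integer,)):
        return int(o)
    if isinstance(o, (_np.floating,)):
        return float(o)
    if isinstance(o, (_np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort (desk scale by default)."""

    n_patients: int = 600
    image_size: tuple[int, int] = (64, 32)      # (H, W)
    exam_count_range: tuple[int, int] = (1, 6)  # uniform inclusive, support 1..11
    spacing_months: float = 12.0
    spacing_jitter_months: float = 2.0
    base_hazard_logit: float = -3.6             # per-year baseline log-odds
    beta_density: float = 0.45                  # per ACR level above 1
    beta_family_history: float = 1.0
    beta_gene: float = 1.5
    beta_personal_history: float = 1.0
    beta_age: float = 0.04                      # per year above 55
    gamma_latent: float = 0.6
    lesion_alpha: float = 2.5                   # lesion contrast scale (alpha)
    lesion_growth_years: float = 4.0            # T_g
    recurrence_fraction: float = 0.12
    censor_mean_years: float = 5.0
    censor_max_years: float = 12.0
    texture_amp: float = 0.06
    blob_amp_range: tuple[float, float] = (0.20, 1.20)
    intensity_ceiling: float = 2.2                  # clip level before 16-bit scaling
    noise_amp: float = 0.02
    density_missing_rate: float = 0.10
    max_event_years: int = 40
    with_images: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.lesion_alpha < 0:
            raise ValueError("lesion_alpha must be non-negative")
        if not 1 <= self.exam_count_range[0] <= self.exam_count_range[1] <= 11:
            raise ValueError("exam counts must lie in 1..11")
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.lesion_growth_years <= 0:
            raise ValueError("lesion growth horizon must be positive")


@dataclass
class PatientTruth:
    latent: float
    hazard: float
    raw_event_year: int | None      # first-success year, pre-censoring
    event_time_years: float | None  # continuous time from first exam
    event_side: str | None
    observed_event: bool
    lesion_amp: float
    lesion_sigma_max: float


@dataclass
class SimTruth:
    config: SimConfig
    patients: dict[str, PatientTruth] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> tuple[list[PatientTimeline], SimTruth]:
    config.validate()
    root = np.random.SeedSequence(config.seed)
    child_seeds = root.spawn(config.n_patients)
    timelines: list[PatientTimeline] = []
    truth = SimTruth(config=config)
    for i, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        pid = f"P{i:05d}"
        tl, pt = _simulate_patient(pid, rng, config)
        timelines.append(tl)
        truth.patients[pid] = pt
    return timelines, truth


def _simulate_patient(pid: str, rng: np.random.Generator, cfg: SimConfig):
    # --- risk factors -------------------------------------------------------
    age0 = float(rng.uniform(40, 74))
    menarche = float(np.clip(rng.normal(13, 1.5), 9, 17))
    density = int(rng.choice([1, 2, 3, 4], p=[0.10, 0.40, 0.35, 0.15]))
    fam_bc = int(rng.random() < 0.12)
    fam_ov = int(rng.random() < 0.03)
    gene = int(rng.random() < 0.03)
    personal = int(rng.random() < cfg.recurrence_fraction)
    menop = 2 if age0 > 55 else (0 if age0 < 48 else 1)
    rf = RiskFactorVector(
        age=round(age0, 1), age_at_menarche=round(menarche, 1),
        menopausal_status=menop, family_history_bc=fam_bc,
        family_history_ovarian=fam_ov, density_acr=density,
        race=int(rng.integers(0, 4)), gene_mutation=gene,
        personal_history_bc=personal, personal_history_ovarian=0,
    )

    prior_tumors: list[TumorRecord] = []
    prior_side = None
    if personal:
        prior_side = str(rng.choice(SIDES))
        prior_tumors.append(TumorRecord(
            laterality=prior_side,
            location_c50=int(rng.integers(0, 6)),
            pT=int(rng.integers(0, 5)), pN=int(rng.integers(0, 4)),
            er=int(rng.random() < 0.7), pr=int(rng.random() < 0.6),
            her2=int(rng.random() < 0.2),
            surgery_type=int(rng.integers(0, 3)),
            adjuvant_chemo=int(rng.integers(0, 2)),
            adjuvant_radio=int(rng.integers(0, 2)),
            anti_hormonal=int(rng.integers(0, 2)),
            antibody_therapy=int(rng.integers(0, 2)),
            pcr=int(rng.random() < 0.3),
        ))

    # --- hazard and event time ---------------------------------------------
    latent = float(rng.normal())
    eta = (cfg.base_hazard_logit
           + cfg.beta_density * (density - 1)
           + cfg.beta_family_history * fam_bc
           + cfg.beta_gene * gene
           + cfg.beta_personal_history * personal
           + cfg.beta_age * (age0 - 55)
           + cfg.gamma_latent * latent)
    hazard = float(1.0 / (1.0 + np.exp(-eta)))
    raw_year = None
    for year in range(1, cfg.max_event_years + 1):
        if rng.random() < hazard:
            raw_year = year
            break
    event_time = None
    event_side = None
    if raw_year is not None:
        event_time = raw_year - 1 + float(rng.uniform(0.05, 1.0))
        if personal and prior_side is not None and rng.random() < 0.6:
            event_side = prior_side
        else:
            event_side = str(rng.choice(SIDES))

    # --- exam schedule ------------------------------------------------------
    n_exams = int(rng.integers(cfg.exam_count_range[0], cfg.exam_count_range[1] + 1))
    gaps = rng.normal(cfg.spacing_months, cfg.spacing_jitter_months, size=n_exams - 1)
    gaps = np.clip(gaps, 4.0, 24.0)
    exam_months = np.concatenate([[0.0], np.cumsum(gaps)])
    start = date(2010, 1, 1) + timedelta(days=int(rng.integers(0, 3650)))
    exam_times_years = exam_months * 30.4375 / 365.25
    if event_time is not None:
        keep = exam_times_years < event_time - 1e-9
        exam_times_years = exam_times_years[keep]
        if exam_times_years.size == 0:
            exam_times_years = np.array([0.0])  # entry exam always exists
    exam_dates = [start + timedelta(days=round(t * 365.25)) for t in exam_times_years]
    # de-duplicate any collisions from rounding
    for k in range(1, len(exam_dates)):
        if exam_dates[k] <= exam_dates[k - 1]:
            exam_dates[k] = exam_dates[k - 1] + timedelta(days=1)

    # --- censoring ----------------------------------------------------------
    followup_after_last = min(float(rng.exponential(cfg.censor_mean_years)),
                              cfg.censor_max_years)
    censor_time = exam_times_years[-1] + followup_after_last
    observed_event = event_time is not None and event_time <= censor_time

    diagnosis_date = None
    diagnosis_lat = None
    last_fu = None
    future_tumor = None
    if observed_event:
        diagnosis_date = start + timedelta(days=round(event_time * 365.25))
        if diagnosis_date <= exam_dates[-1]:
            diagnosis_date = exam_dates[-1] + timedelta(days=1)
        diagnosis_lat = event_side
        future_tumor = TumorRecord(
            laterality=event_side,
            location_c50=int(rng.integers(0, 6)),
            er=int(rng.random() < 0.7), pr=int(rng.random() < 0.6),
            her2=int(rng.random() < 0.2),
        )
    else:
        last_fu = start + timedelta(days=round(censor_time * 365.25))
        if last_fu <= exam_dates[-1]:
            last_fu = exam_dates[-1] + timedelta(days=1)

    # --- image model --------------------------------------------------------
    h, w = cfg.image_size
    lesion_amp = cfg.lesion_alpha * float(rng.uniform(0.35, 0.55))
    lesion_sigma_max = float(rng.uniform(0.055, 0.080)) * h
    anatomy = _patient_anatomy(rng, cfg) if cfg.with_images else None

    exams: list[ScreeningExam] = []
    for k, (d, t) in enumerate(zip(exam_dates, exam_times_years)):
        lesion_frac = 0.0
        if event_time is not None:
            dt = event_time - t
            if dt <= cfg.lesion_growth_years:
                lesion_frac = float(np.clip(1.0 - dt / cfg.lesion_growth_years, 0.0, 1.0))
        images = {}
        if cfg.with_images:
            images = _render_exam(rng, cfg, anatomy, event_side, lesion_frac,
                                  lesion_amp, lesion_sigma_max)
        birads, biopsy = _assessment(rng, lesion_frac)
        dens = MISSING if rng.random() < cfg.density_missing_rate else density
        exams.append(ScreeningExam(
            exam_date=d, images=images, birads=birads, density_acr=dens,
            manufacturer=int(rng.integers(0, 3)),
            biopsy_benign_within_90d=biopsy,
        ))

    tl = PatientTimeline(
        patient_id=pid, exams=exams, risk_factors=rf,
        prior_tumors=prior_tumors, diagnosis_date=diagnosis_date,
        diagnosis_laterality=diagnosis_lat, last_followup_date=last_fu,
        future_tumor=future_tumor,
    )
    pt = PatientTruth(
        latent=latent, hazard=hazard, raw_event_year=raw_year,
        event_time_years=event_time, event_side=event_side,
        observed_event=observed_event, lesion_amp=lesion_amp,
        lesion_sigma_max=lesion_sigma_max,
    )
    return tl, pt


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def _patient_anatomy(rng: np.random.Generator, cfg: SimConfig) -> dict:
    """Static per-patient structures, fixed across all of her exams."""
    h, w = cfg.image_size
    anatomy: dict = {}
    for side in SIDES:
        for view in VIEWS:
            ry = 0.42 * h * rng.uniform(0.9, 1.1)
            rx = 0.80 * w * rng.uniform(0.9, 1.1)
            cy = h / 2 + rng.uniform(-0.03, 0.03) * h
            texture = gaussian_filter(rng.normal(size=(h, w)), sigma=3.0)
            texture /= max(texture.std(), 1e-9)
            n_blobs = int(rng.integers(1, 4))
            blobs = []
            for _ in range(n_blobs):
                blobs.append((
                    rng.uniform(0.2, 0.8) * h,           # y
                    rng.uniform(0.1, 0.6) * w,           # x
                    rng.uniform(*cfg.blob_amp_range),    # amplitude
                    rng.uniform(0.04, 0.09) * h,         # sigma
                ))
            lesion_center = (rng.uniform(0.25, 0.75) * h, rng.uniform(0.12, 0.55) * w)
            anatomy[(side, view)] = dict(ry=ry, rx=rx, cy=cy, texture=texture,
                                         blobs=blobs, lesion_center=lesion_center)
    return anatomy


def _render_exam(rng, cfg: SimConfig, anatomy, event_side, lesion_frac,
                 lesion_amp, lesion_sigma_max) -> dict:
    h, w = cfg.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    images = {}
    for side in SIDES:
        for view in VIEWS:
            a = anatomy[(side, view)]
            mask = ((xx / a["rx"]) ** 2 + ((yy - a["cy"]) / a["ry"]) ** 2) <= 1.0
            img = np.zeros((h, w))
            dens_scale = cfg.texture_amp
            img[mask] = 0.45 + dens_scale * a["texture"][mask]
            for by, bx, bamp, bsig in a["blobs"]:
                img += bamp * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2)
                                       / (2 * bsig ** 2)))
            if side == event_side and lesion_frac > 0 and lesion_amp > 0:
                ly, lx = a["lesion_center"]
                sig = 1.0 + (lesion_sigma_max - 1.0) * lesion_frac
                amp = lesion_amp * (0.15 + 0.85 * lesion_frac)
                img += amp * np.exp(-(((yy - ly) ** 2 + (xx - lx) ** 2)
                                      / (2 * sig ** 2)))
            img += cfg.noise_amp * rng.normal(size=(h, w))
            img[~mask] = 0.0
            img = np.clip(img, 0.0, cfg.intensity_ceiling) / cfg.intensity_ceiling
            # mirror left-side views so raw files face opposite directions,
            # like real CC/MLO pairs; preprocessing undoes this
            if side == "left":
                img = img[:, ::-1]
            images[(side, view)] = (img * 65535).astype(np.uint16)
    return images


def _assessment(rng: np.random.Generator, lesion_frac: float) -> tuple[int, bool]:
    """BI-RADS score and benign-biopsy flag, loosely tracking lesion visibility."""
    if lesion_frac > 0.55 and rng.random() < 0.5:
        birads = int(rng.choice([0, 3, 4], p=[0.45, 0.35, 0.20]))
    else:
        birads = int(rng.choice([0, 1, 2, 3], p=[0.04, 0.56, 0.36, 0.04]))
    biopsy = bool(rng.random() < (0.5 if birads >= 3 else 0.02))
    return birads, biopsy


# ---------------------------------------------------------------------------
# fixture round trip
# ---------------------------------------------------------------------------

def _tumor_to_json(rec: TumorRecord | None):
    return None if rec is None else asdict(rec)


def _tumor_from_json(obj) -> TumorRecord | None:
    return None if obj is None else TumorRecord(**obj)


def write_fixture(timelines: list[PatientTimeline], truth: SimTruth | None,
                  out_dir: str | Path) -> Path:
    """Persist a cohort: 16-bit PNG images, CSV exam table, JSON records,
    and a manifest with checksums.  Inverse of :func:`read_fixture`."""
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    exam_rows = []
    patients = {}
    files: list[Path] = []
    for tl in timelines:
        for k, exam in enumerate(tl.exams):
            row = {
                "patient_id": tl.patient_id, "exam_index": k,
                "exam_date": exam.exam_date.isoformat(),
                "birads": exam.birads, "density_acr": exam.density_acr,
                "manufacturer": exam.manufacturer,
                "biopsy_benign_within_90d": int(exam.biopsy_benign_within_90d),
            }
            for (side, view), img in sorted(exam.images.items()):
                name = f"{tl.patient_id}_e{k}_{side}_{view}.png"
                arr = np.asarray(img)
                if arr.dtype != np.uint16:
                    raise ValueError("fixture images must be 16-bit")
                iio.imwrite(img_dir / name, arr)
                files.append(img_dir / name)
                row[f"image_{side}_{view}"] = f"images/{name}"
            exam_rows.append(row)
        patients[tl.patient_id] = {
            "risk_factors": asdict(tl.risk_factors),
            "prior_tumors": [asdict(r) for r in tl.prior_tumors],
            "diagnosis_date": tl.diagnosis_date.isoformat() if tl.diagnosis_date else None,
            "diagnosis_laterality": tl.diagnosis_laterality,
            "last_followup_date": tl.last_followup_date.isoformat() if tl.last_followup_date else None,
            "future_tumor": _tumor_to_json(tl.future_tumor),
        }

    import pandas as pd
    exams_csv = out / "exams.csv"
    pd.DataFrame(exam_rows).to_csv(exams_csv, index=False)
    files.append(exams_csv)
    patients_json = out / "patients.json"
    patients_json.write_text(json.dumps(
        {"schema_version": SCHEMA_VERSION, "patients": patients}, indent=1,
        default=_json_default))
    files.append(patients_json)
    if truth is not None:
        tj = out / "truth.json"
        tj.write_text(json.dumps({
            "schema_version": SCHEMA_VERSION,
            "config": asdict(truth.config),
            "patients": {k: asdict(v) for k, v in truth.patients.items()},
        }, indent=1, default=_json_default))
        files.append(tj)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "files": {str(f.relative_to(out)): _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_fixture(in_dir: str | Path, load_images: bool = True
                 ) -> tuple[list[PatientTimeline], SimTruth | None]:
    """Load a cohort written by :func:`write_fixture` (the same reader path
    a real-data adapter would feed)."""
    import pandas as pd
    root = Path(in_dir)
    pj = json.loads((root / "patients.json").read_text())
    if pj.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported fixture schema {pj.get('schema_version')!r}")
    exams_df = pd.read_csv(root / "exams.csv")
    timelines = []
    for pid, rec in pj["patients"].items():
        rows = exams_df[exams_df.patient_id == pid].sort_values("exam_index")
        exams = []
        for _, row in rows.iterrows():
            images = {}
            for side in SIDES:
                for view in VIEWS:
                    col = f"image_{side}_{view}"
                    if col in row and isinstance(row[col], str):
                        path = root / row[col]
                        images[(side, view)] = (
                            iio.imread(path).astype(np.uint16) if load_images else str(path)
                        )
            exams.append(ScreeningExam(
                exam_date=date.fromisoformat(row["exam_date"]),
                images=images, birads=int(row["birads"]),
                density_acr=int(row["density_acr"]),
                manufacturer=int(row["manufacturer"]),
                biopsy_benign_within_90d=bool(row["biopsy_benign_within_90d"]),
            ))
        timelines.append(PatientTimeline(
            patient_id=pid, exams=exams,
            risk_factors=RiskFactorVector(**rec["risk_factors"]),
            prior_tumors=[TumorRecord(**r) for r in rec["prior_tumors"]],
            diagnosis_date=date.fromisoformat(rec["diagnosis_date"]) if rec["diagnosis_date"] else None,
            diagnosis_laterality=rec["diagnosis_laterality"],
            last_followup_date=date.fromisoformat(rec["last_followup_date"]) if rec["last_followup_date"] else None,
            future_tumor=_tumor_from_json(rec.get("future_tumor")),
        ))
    truth = None
    tj = root / "truth.json"
    if tj.exists():
        obj = json.loads(tj.read_text())
        cfg_obj = obj["config"]
        for key in ("image_size", "exam_count_range", "blob_amp_range"):
            cfg_obj[key] = tuple(cfg_obj[key])
        truth = SimTruth(config=SimConfig(**cfg_obj),
                         patients={k: PatientTruth(**v) for k, v in obj["patients"].items()})
    return timelines, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
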