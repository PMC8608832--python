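"""Synthetic four-chamber cine phantoms, LGE phantoms, and survival simulation.

The phantom renders four elliptical chambers (LV, RV, LA, RA) as bright
blood pools with mid-gray walls on a dark background.  Ventricular areas
contract along a raised-cosine curve between end-diastole and end-systole;
atrial areas follow the reciprocal (reservoir) curve, in anti-phase with
the ventricles.  Chamber function is parameterised by volume ejection
fractions: a single-view area is mapped to a volume proxy as area^1.5
(isotropic scaling of one 2D cross-section), so the *area* ejection
fraction used for rendering is ``1 - (1 - ef)^(2/3)``.

Event times are simulated from an exponential proportional-hazards model
whose log-hazard is linear in the population-standardized phantom
parameters, with an optional independent exponential competing death and
administrative censoring — the censoring structure the downstream risk
models assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import CineSequence, CohortTable, SurvivalRecord, write_cine, write_survival_table

__all__ = [
    "PhantomParams",
    "SurvivalSimConfig",
    "DEFAULT_POPULATION",
    "generate_phantom_sequence",
    "render_phantom_frame",
    "sample_cohort",
    "simulate_survival",
    "generate_lge_phantom",
    "save_cohort",
]

_BACKGROUND_SI = 0.05
_WALL_SI = 0.5
_BLOOD_SI = 1.0
_SUPERSAMPLE = 3  # sub-pixel sampling per axis for partial-volume edges


@dataclass(frozen=True)
class PhantomParams:
    """Ground-truth generative parameters of one synthetic heart.

    Areas are end-diastolic (ventricles) / maximal (atria) four-chamber
    cross-sections in mm^2; ejection/emptying fractions are volume
    fractions strictly in (0, 1).
    """

    lv_edv_area: float = 3800.0
    lv_ef: float = 0.26
    rv_ef: float = 0.35
    la_max_area: float = 2200.0
    la_total_ef: float = 0.38
    wall_thickness_mm: float = 8.0
    noise_sd: float = 0.02
    n_frames: int = 8

    def __post_init__(self) -> None:
        for name in ("lv_ef", "rv_ef", "la_total_ef"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be strictly in (0, 1); got {v}")
        for name in ("lv_edv_area", "la_max_area", "wall_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")

    _FLOAT_FIELDS = (
        "lv_edv_area",
        "lv_ef",
        "rv_ef",
        "la_max_area",
        "la_total_ef",
        "wall_thickness_mm",
    )

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class SurvivalSimConfig:
    """Exponential proportional-hazards simulation settings.

    ``log_hazard_coeffs`` maps PhantomParams field names to log-hazard
    slopes per standard deviation of that parameter in the cohort.
    """

    # default calibrated so that, with a unit log-hazard slope on standardized
    # LVEF and 10-year administrative censoring, ~27% of subjects have the
    # primary event — the censoring regime the pipeline is meant to face
    baseline_hazard: float = 0.0235  # events / year
    log_hazard_coeffs: Mapping[str, float] = field(default_factory=dict)
    admin_censor_years: float = 10.0
    competing_hazard: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be > 0")
        if self.competing_hazard < 0:
            raise ValueError("competing_hazard must be >= 0")


def area_ef_from_volume_ef(volume_ef: float) -> float:
    """Area fraction ejected so that the area^1.5 volume proxy gives volume_ef."""
    return 1.0 - (1.0 - volume_ef) ** (2.0 / 3.0)


def volume_ef_from_areas(area_ed: float, area_es: float) -> float:
    """Implied volume EF of a chamber from its extreme single-view areas."""
    return 1.0 - (area_es / area_ed) ** 1.5


def _ellipse_coverage(
    size_px: int,
    spacing_mm: float,
    center_mm: tuple[float, float],
    semi_axes_mm: tuple[float, float],
) -> np.ndarray:
    """Fraction of each pixel covered by an axis-aligned ellipse (supersampled)."""
    s = _SUPERSAMPLE
    n = size_px * s
    # supersample coordinates of sub-pixel centres, mm, origin at image centre
    half_fov = size_px * spacing_mm / 2.0
    coords = (np.arange(n) + 0.5) * (spacing_mm / s) - half_fov
    rr = (coords - center_mm[0])[:, None] / semi_axes_mm[0]
    cc = (coords - center_mm[1])[None, :] / semi_axes_mm[1]
    inside = (rr**2 + cc**2) <= 1.0
    return inside.reshape(size_px, s, size_px, s).mean(axis=(1, 3))


@dataclass(frozen=True)
class _Chamber:
    center_frac: tuple[float, float]  # of the field of view, (row, col)
    aspect: float  # semi-minor / semi-major (major axis along rows)
    area_ed: float  # mm^2 at phase 0
    area_es: float  # mm^2 at phase 0.5
    ventricular: bool  # contracts (True) vs fills (False) toward phase 0.5
    wall_scale: float  # wall thickness multiplier


def _chambers(params: PhantomParams) -> list[_Chamber]:
    lv_es = params.lv_edv_area * (1.0 - area_ef_from_volume_ef(params.lv_ef))
    rv_ed = 0.80 * params.lv_edv_area
    rv_es = rv_ed * (1.0 - area_ef_from_volume_ef(params.rv_ef))
    la_min = params.la_max_area * (1.0 - area_ef_from_volume_ef(params.la_total_ef))
    ra_max = 0.9 * params.la_max_area
    ra_min = ra_max * (1.0 - area_ef_from_volume_ef(params.la_total_ef))
    return [
        _Chamber((-0.16, +0.16), 0.60, params.lv_edv_area, lv_es, True, 1.0),
        _Chamber((-0.16, -0.17), 0.50, rv_ed, rv_es, True, 0.5),
        # atria: area_ed slot holds the *minimum* (phase-0) area, area_es the maximum
        _Chamber((+0.21, +0.16), 0.80, la_min, params.la_max_area, False, 0.4),
        _Chamber((+0.21, -0.17), 0.80, ra_min, ra_max, False, 0.4),
    ]


def render_phantom_frame(
    params: PhantomParams, phase: float, spacing_mm: float = 2.2, size_px: int = 128
) -> np.ndarray:
    """Render one noise-free frame at cardiac phase ``phase`` (period 1).

    Phase 0 is end-diastole; ventricular area reaches its minimum at
    phase 0.5 along a raised-cosine curve, atria their maximum.
    """
    fov = size_px * spacing_mm
    c = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))  # 0 at ED, 1 at ES
    img = np.full((size_px, size_px), _BACKGROUND_SI, dtype=np.float64)
    for ch in _chambers(params):
        area = ch.area_ed + (ch.area_es - ch.area_ed) * c
        a = np.sqrt(area / (np.pi * ch.aspect))  # semi-major, along rows
        b = ch.aspect * a
        wall = params.wall_thickness_mm * ch.wall_scale
        center = (ch.center_frac[0] * fov, ch.center_frac[1] * fov)
        outer_a, outer_b = a + wall, b + wall
        if abs(center[0]) + outer_a > fov / 2 or abs(center[1]) + outer_b > fov / 2:
            raise ValueError(
                f"chamber geometry exceeds the {fov:.0f} mm field of view "
                f"(semi-axes {outer_a:.0f}x{outer_b:.0f} mm at offset {center})"
            )
        blood = _ellipse_coverage(size_px, spacing_mm, center, (a, b))
        outer = _ellipse_coverage(size_px, spacing_mm, center, (outer_a, outer_b))
        wall_cov = np.clip(outer - blood, 0.0, 1.0)
        img += wall_cov * (_WALL_SI - _BACKGROUND_SI) + blood * (_BLOOD_SI - _BACKGROUND_SI)
    return img


def generate_phantom_sequence(
    params: PhantomParams,
    spacing_mm: float = 2.2,
    size_px: int = 128,
    seed: int = 0,
    subject_id: str = "phantom",
) -> CineSequence:
    """Render a full cardiac cycle as a cine sequence; pure in (params, seed).

    Frame k sits at phase k / n_frames, so one further frame would close
    the cycle exactly.  Gaussian noise with sd ``params.noise_sd`` is added
    and intensities clipped at 0.
    """
    rng = np.random.default_rng(seed)
    frames = np.stack(
        [
            render_phantom_frame(params, k / params.n_frames, spacing_mm, size_px)
            for k in range(params.n_frames)
        ]
    )
    if params.noise_sd > 0:
        frames = frames + rng.normal(0.0, params.noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)
    return CineSequence(
        frames=frames,
        pixel_spacing_mm=(spacing_mm, spacing_mm),
        frame_interval_ms=1000.0 / params.n_frames,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

# (mean, sd, lower bound, upper bound) truncated normals per parameter;
# centres mirror a dilated-cardiomyopathy ICD-candidate population
# (median LVEF ~26%, LA emptying ~38%).
DEFAULT_POPULATION: dict[str, tuple[float, float, float, float]] = {
    "lv_edv_area": (3800.0, 700.0, 2200.0, 6000.0),
    "lv_ef": (0.26, 0.08, 0.05, 0.60),
    "rv_ef": (0.35, 0.10, 0.10, 0.65),
    "la_max_area": (2200.0, 450.0, 1100.0, 3800.0),
    "la_total_ef": (0.38, 0.12, 0.05, 0.80),
    "wall_thickness_mm": (8.0, 1.0, 5.0, 12.0),
}


def _draw_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, n: int
) -> np.ndarray:
    if not (low <= mean <= high):
        raise ValueError(f"infeasible distribution: mean {mean} outside [{low}, {high}]")
    if sd == 0:
        return np.full(n, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_cohort(
    n: int,
    population: Mapping[str, tuple[float, float, float, float]] | None = None,
    seed: int = 0,
    spacing_mm: float = 2.2,
    size_px: int = 128,
    noise_sd: float = 0.02,
    n_frames: int = 8,
    render: bool = True,
) -> list[tuple[str, PhantomParams, CineSequence | None]]:
    """Draw ``n`` independent phantom subjects from a truncated-normal population.

    Returns ``(subject_id, ground-truth params, cine sequence)`` triples;
    pass ``render=False`` to skip image rendering when only the parameter
    table is needed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    pop = dict(DEFAULT_POPULATION)
    if population:
        pop.update(population)
    rng = np.random.default_rng(seed)
    draws = {name: _draw_truncnorm(rng, *spec_, n) for name, spec_ in pop.items()}
    base = PhantomParams(noise_sd=noise_sd, n_frames=n_frames)
    out: list[tuple[str, PhantomParams, CineSequence | None]] = []
    for i in range(n):
        sid = f"S{i:04d}"
        params = replace(base, **{name: float(v[i]) for name, v in draws.items()})
        seq = None
        if render:
            seq = generate_phantom_sequence(
                params, spacing_mm=spacing_mm, size_px=size_px,
                seed=int(rng.integers(2**31)), subject_id=sid,
            )
        out.append((sid, params, seq))
    return out


def simulate_survival(
    cohort: pd.DataFrame | list[tuple[str, PhantomParams, CineSequence | None]],
    config: SurvivalSimConfig,
    outcome_label: str = "VA",
) -> CohortTable:
    """Simulate right-censored event times from the phantom ground truth.

    Primary-event time is exponential with rate
    ``baseline_hazard * exp(sum_k beta_k z_k)`` where z_k is the cohort-
    standardized parameter named by ``log_hazard_coeffs``; an independent
    exponential competing death (code 2) and administrative censoring
    (code 0) truncate it.  Ground-truth parameters are carried along as
    covariates.
    """
    if isinstance(cohort, pd.DataFrame):
        df = cohort.copy()
    else:
        df = pd.DataFrame(
            [{"subject_id": sid, **params.as_dict()} for sid, params, _ in cohort]
        )
    unknown = set(config.log_hazard_coeffs) - set(df.columns)
    if unknown:
        raise ValueError(f"log_hazard_coeffs name unknown parameters: {sorted(unknown)}")

    eta = np.zeros(len(df))
    for name, beta in config.log_hazard_coeffs.items():
        col = df[name].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        eta += beta * z

    rng = np.random.default_rng(config.seed)
    lam = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / lam)
    if config.competing_hazard > 0:
        t_death = rng.exponential(1.0 / config.competing_hazard, size=len(df))
    else:
        t_death = np.full(len(df), np.inf)
    t_admin = config.admin_censor_years

    records = []
    cov_cols = [c for c in df.columns if c != "subject_id"]
    for i, row in enumerate(df.itertuples(index=False)):
        t_obs = min(t_event[i], t_death[i], t_admin)
        if t_obs == t_event[i]:
            code = 1
        elif t_obs == t_death[i]:
            code = 2
        else:
            code = 0
        records.append(
            SurvivalRecord(
                subject_id=str(getattr(row, "subject_id")),
                time=float(t_obs),
                event_code=code,
                covariates={c: float(getattr(row, c)) for c in cov_cols},
            )
        )
    return CohortTable(records=records, outcome_label=outcome_label)


# ---------------------------------------------------------------------------
# LGE phantom
# ---------------------------------------------------------------------------


def generate_lge_phantom(
    scar_core_px: int,
    scar_gray_px: int,
    normal_peak_si: float = 100.0,
    max_si: float = 400.0,
    seed: int = 0,
    size_px: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build an LGE still with a known core / gray-zone pixel decomposition.

    Returns ``(image, myocardium_mask, hyperenhanced_mask)``.  The annular
    myocardium has normal signal <= ``normal_peak_si`` (one pixel exactly at
    the peak); a contiguous scar patch holds exactly ``scar_core_px`` pixels
    with SI > 0.5 * max_si (one exactly at ``max_si``) and ``scar_gray_px``
    pixels strictly between the normal peak and half-maximal SI.  The
    hyperenhanced mask is the scar patch.
    """
    if scar_core_px < 0 or scar_gray_px < 0:
        raise ValueError("pixel counts must be >= 0")
    if scar_gray_px > 0 and scar_core_px == 0:
        raise ValueError("a gray zone needs a core to anchor the half-maximal threshold")
    if not (max_si > 2 * normal_peak_si):
        raise ValueError("max_si must exceed 2 * normal_peak_si so the gray band is non-empty")

    rng = np.random.default_rng(seed)
    r_out, r_in = 0.42 * size_px, 0.30 * size_px
    center = (size_px - 1) / 2.0
    rows, cols = np.mgrid[0:size_px, 0:size_px]
    rr = np.hypot(rows - center, cols - center)
    myo = (rr >= r_in) & (rr <= r_out)
    n_scar = scar_core_px + scar_gray_px
    n_myo = int(myo.sum())
    if n_scar >= n_myo:
        raise ValueError(f"requested {n_scar} scar pixels but the annulus has only {n_myo}")

    image = np.zeros((size_px, size_px))
    # normal myocardium below its peak, with the peak attained exactly once
    idx_myo = np.flatnonzero(myo.ravel())
    image.ravel()[idx_myo] = rng.uniform(0.3 * normal_peak_si, 0.95 * normal_peak_si, n_myo)
    image.ravel()[idx_myo[rng.integers(n_myo)]] = normal_peak_si

    he_mask = np.zeros_like(myo)
    if n_scar > 0:
        # contiguous angular wedge of the annulus around a random direction
        theta = np.arctan2(rows - center, cols - center).ravel()[idx_myo]
        theta0 = rng.uniform(-np.pi, np.pi)
        ang_dist = np.abs(np.angle(np.exp(1j * (theta - theta0))))
        wedge = idx_myo[np.argsort(ang_dist, kind="stable")[:n_scar]]
        he_mask.ravel()[wedge] = True
        wedge = rng.permutation(wedge)
        core_idx, gray_idx = wedge[:scar_core_px], wedge[scar_core_px:]
        half = 0.5 * max_si
        core_si = rng.uniform(half * 1.05, max_si * 0.98, scar_core_px)
        core_si[0] = max_si  # anchor the maximal SI
        image.ravel()[core_idx] = core_si
        if scar_gray_px:
            lo, hi = normal_peak_si * 1.02, half * 0.98
            image.ravel()[gray_idx] = rng.uniform(lo, hi, scar_gray_px)

    return image, myo, he_mask


# ---------------------------------------------------------------------------
# Disk emission (formats of cinerisk.io)
# ---------------------------------------------------------------------------


def save_cohort(
    out_dir: str | Path,
    cohort: list[tuple[str, PhantomParams, CineSequence | None]],
    survival: CohortTable,
) -> Path:
    """Write NIfTI sequences, the ground-truth parameter table, and the survival table."""
    out_dir = Path(out_dir)
    img_dir = out_dir / "cine"
    for sid, _, seq in cohort:
        if seq is not None:
            write_cine(seq, img_dir / f"{sid}.nii.gz")
    params_df = pd.DataFrame([{"subject_id": sid, **p.as_dict()} for sid, p, _ in cohort])
    out_dir.mkdir(parents=True, exist_ok=True)
    params_df.to_csv(out_dir / "ground_truth_params.csv", index=False)
    write_survival_table(survival, out_dir / "survival.csv")
    return out_dir
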