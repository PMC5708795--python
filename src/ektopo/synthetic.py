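"""Seeded generator of synthetic corneal geometries and visual outcomes.

The generator emulates three study arms:

* **control** — smooth conicoid surfaces with small higher-order
  perturbations; posterior power sits around the cool/yellow boundary.
* **DMEK** — near-normal geometry plus a central stromal-dehydration
  steepening of the posterior surface: curvature change concentrates in an
  annulus at the margin of the central dehydration zone, so the map shows a
  yellow/orange ring that fades over follow-up.
* **DSAEK** — a meniscus-shaped posterior lenticule (donor stroma), thickest
  centrally, which steepens the central posterior surface into the orange
  and red bands and raises spherical aberration.

Each eye draws its latent geometry once; follow-up timepoints reuse the
latents with multiplicative decay factors, so recovery is monotone per eye.
Per-group parameters are calibration constructs tuned once (see
scripts/calibrate.py) so that the full map->metrics->grade pipeline
reproduces the published group-level summaries; they are not biophysical
measurements, and the preset Q values in particular absorb the difference
between the thin-phase OPD model and device ray tracing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import zernike
from .grading import GradeResult
from .wavefront import (
    DELTA_N_ANTERIOR,
    DELTA_N_POSTERIOR,
    AberrationSet,
    CorneaModel,
    ElevationMap,
)

GROUPS = ("control", "DMEK", "DSAEK")
TIMEPOINTS = ("pre", "1m", "3m", "6m")
POSTOP_TIMEPOINTS = ("1m", "3m", "6m")

DEFAULT_GRID_SPACING = 0.05  # mm
DEFAULT_HALF_WIDTH = 3.5  # mm
NOISE_ZONE_RADIUS = 3.0  # mm; perturbations are expanded over the 6-mm zone

__all__ = [
    "GROUPS",
    "TIMEPOINTS",
    "POSTOP_TIMEPOINTS",
    "GroupPreset",
    "BscvaModel",
    "EyeRecord",
    "CohortConfig",
    "make_conicoid",
    "dmek_dehydration",
    "dsaek_meniscus",
    "bscva_from_metrics",
    "sample_cohort",
    "default_config",
    "CONTROL_PRESET",
    "DMEK_PRESET",
    "DSAEK_PRESET",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def make_conicoid(
    R: float,
    Q: float,
    grid_spacing: float = DEFAULT_GRID_SPACING,
    half_width: float = DEFAULT_HALF_WIDTH,
) -> ElevationMap:
    """Vertex-referenced conicoid sag map (µm).

    ``z(r) = r^2 / (R (1 + sqrt(1 - (1+Q) r^2 / R^2)))`` with apical radius
    R (mm) and asphericity Q (Q = 0 sphere, Q < 0 prolate, Q = -1
    paraboloid). Raises if the conic is not defined over the whole grid.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    n = int(round(2 * half_width / grid_spacing)) + 1
    if n % 2 == 0:
        n += 1
    ax = np.linspace(-half_width, half_width, n)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    disc = 1.0 - (1.0 + Q) * r2 / R**2
    if np.any(disc <= 0):
        raise ValueError("conicoid undefined over the requested grid")
    sag_mm = r2 / (R * (1.0 + np.sqrt(disc)))
    return ElevationMap(sag=sag_mm * 1000.0, grid_spacing=grid_spacing, half_width=half_width)


def _raised_cosine_ramp(r: np.ndarray, r_lo: float, r_hi: float) -> np.ndarray:
    """Smooth 0->1 ramp between r_lo and r_hi (raised cosine)."""
    t = np.clip((r - r_lo) / max(r_hi - r_lo, 1e-9), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def dmek_dehydration(
    posterior: ElevationMap,
    amplitude: float,
    zone_radius: float = 2.05,
    transition: float = 1.3,
) -> ElevationMap:
    """Central dehydration of the posterior stroma after DMEK.

    The central ``zone_radius`` (mm) deturgesces first, displacing the
    central posterior surface anteriorly by ``amplitude`` (µm) relative to
    the still-edematous periphery. In vertex-referenced sag this adds a
    raised-cosine annular ramp at the zone margin, steepening the posterior
    power map there. ``amplitude = 0`` is the identity.
    """
    if amplitude == 0:
        return posterior
    rr = posterior.radius()
    ramp = _raised_cosine_ramp(rr, zone_radius - transition / 2.0, zone_radius + transition / 2.0)
    return replace(posterior, sag=posterior.sag + amplitude * ramp)


def dsaek_meniscus(
    posterior: ElevationMap,
    amplitude: float,
    edge_radius: float = 3.2,
    smoothness: float = 1.0,
) -> ElevationMap:
    """Meniscus-shaped posterior lenticule after DSAEK.

    The donor stromal lenticule is thickest centrally and tapers to zero at
    ``edge_radius`` (mm), protruding into the anterior chamber. Relative to
    the vertex the sag gains ``amplitude * ramp(r)`` (µm), a center-steep
    dome: central posterior power becomes strictly more negative (steeper)
    for any positive amplitude. ``smoothness`` is an exponent shaping the
    taper (1 = raised cosine).
    """
    if amplitude == 0:
        return posterior
    if edge_radius <= 0:
        raise ValueError("edge_radius must be positive")
    rr = posterior.radius()
    ramp = _raised_cosine_ramp(rr, 0.0, edge_radius) ** smoothness
    return replace(posterior, sag=posterior.sag + amplitude * ramp)


# ---------------------------------------------------------------------------
# higher-order surface perturbations
# ---------------------------------------------------------------------------

_HOA_JS = [j for j in range(zernike.N_TERMS) if zernike.single_index_to_nm(j).n >= 3]


def _hoa_weights() -> np.ndarray:
    """Per-coefficient RMS weight profile over orders 3-8 (unit total variance).

    Coma-dominant, matching the composition of corneal HOA after
    keratoplasty: most variance in the order-3 comas, a deliberate share on
    Z(4,0) (so surface noise feeds spherical aberration), the remainder
    decaying as 1/n^2 over orders 5-8.
    """
    var = np.zeros(zernike.N_TERMS)
    var[zernike.nm_to_single_index(3, -1)] = 0.25
    var[zernike.nm_to_single_index(3, 1)] = 0.25
    var[zernike.nm_to_single_index(3, -3)] = 0.075
    var[zernike.nm_to_single_index(3, 3)] = 0.075
    var[zernike.nm_to_single_index(4, 0)] = 0.05
    for m in (-4, -2, 2, 4):
        var[zernike.nm_to_single_index(4, m)] = 0.025
    high = {n: 1.0 / n**2 for n in range(5, 9)}
    total_high = sum(high.values())
    for n in range(5, 9):
        js = [j for j in _HOA_JS if zernike.single_index_to_nm(j).n == n]
        for j in js:
            var[j] = 0.20 * high[n] / total_high / len(js)
    var /= var.sum()
    return np.sqrt(var)


_HOA_W = _hoa_weights()

_BASIS_CACHE: dict[tuple, np.ndarray] = {}


def _grid_basis(grid_spacing: float, half_width: float) -> np.ndarray:
    """Zernike basis over the full map grid, rho normalized to the 6-mm zone."""
    key = (round(grid_spacing, 9), round(half_width, 9))
    if key not in _BASIS_CACHE:
        n = int(round(2 * half_width / grid_spacing)) + 1
        ax = np.linspace(-half_width, half_width, n)
        xx, yy = np.meshgrid(ax, ax)
        rho = np.hypot(xx, yy) / NOISE_ZONE_RADIUS
        theta = np.arctan2(yy, xx)
        _BASIS_CACHE[key] = zernike.zernike_basis(rho, theta)
    return _BASIS_CACHE[key]


def _perturbation(
    direction: np.ndarray, amplitude_opd: float, delta_n: float, grid_spacing: float, half_width: float
) -> np.ndarray:
    """Surface perturbation (µm) whose OPD has HOA RMS = amplitude_opd.

    ``direction`` is a 45-vector supported on orders 3-8 with unit norm.
    """
    coeffs = direction * (amplitude_opd / abs(delta_n))
    basis = _grid_basis(grid_spacing, half_width)
    pert = np.tensordot(coeffs, basis, axes=(0, 0))
    c = pert.shape[0] // 2
    return pert - pert[c, c]


def _hoa_direction(rng: np.random.Generator) -> np.ndarray:
    g = np.zeros(zernike.N_TERMS)
    g[_HOA_JS] = rng.standard_normal(len(_HOA_JS)) * _HOA_W[_HOA_JS]
    return g / np.linalg.norm(g)


# ---------------------------------------------------------------------------
# outcome model and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BscvaModel:
    """Linear response of visual acuity to posterior grade and total HOA.

    ``bscva = max(floor, intercept + beta_grade * grade
    + beta_hoa * totalHOA(6 mm) + N(0, noise_sd))`` in logMAR (lower is
    better); the floor is the best acuity the chart resolves.
    """

    intercept: float = -0.255
    beta_grade: float = 0.13
    beta_hoa: float = 0.12
    noise_sd: float = 0.21
    floor: float = -0.08

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def bscva_from_metrics(
    metrics: AberrationSet,
    grade: GradeResult | int,
    model: BscvaModel,
    rng: np.random.Generator,
) -> float:
    """Draw one BSCVA (logMAR) from the calibrated response model."""
    g = grade.grade if isinstance(grade, GradeResult) else int(grade)
    hoa6 = metrics.get("total", 6.0).hoa
    value = model.intercept + model.beta_grade * g + model.beta_hoa * hoa6
    value += model.noise_sd * rng.standard_normal()
    return float(max(model.floor, value))


@dataclass(frozen=True)
class GroupPreset:
    """Generative parameters of one study arm.

    Radii/asphericities are (mean, sd) of per-eye Gaussians; perturbation
    and bump amplitudes are preoperative medians with log-normal per-eye
    spread (``gsd`` = geometric sd); ``time_decay`` holds per-perturbation
    multiplicative factors in (0, 1] for each timepoint.
    """

    group: str
    anterior_R: tuple[float, float]
    anterior_Q: tuple[float, float]
    posterior_R: tuple[float, float]
    posterior_Q: tuple[float, float]
    anterior_q_shift: float  # preoperative disease-state offset on anterior Q
    posterior_steepening: float  # preoperative global posterior radius decrease, mm
    hoa_anterior: float  # preoperative anterior OPD HOA RMS, µm
    hoa_posterior: float  # preoperative posterior OPD HOA RMS, µm
    hoa_gsd: float
    bump_kind: str  # "none" | "dehydration" | "meniscus"
    bump_amplitude: tuple[float, float]  # (preoperative median µm, gsd)
    bump_radius: float  # dehydration zone radius / meniscus edge radius, mm
    bump_transition: float  # dehydration ramp width, mm (unused for meniscus)
    time_decay: dict  # {"bump"|"hoa"|"q_shift": {timepoint: factor}}
    cct: dict  # {timepoint: (mean µm, sd µm)}
    preop_bscva: tuple[float, float] | None  # logMAR (mean, sd); None -> model
    timepoints: tuple[str, ...]
    sex_p_female: float = 0.7
    eye_p_right: float = 0.65

    def __post_init__(self) -> None:
        if self.anterior_R[0] <= 0 or self.posterior_R[0] <= 0:
            raise ValueError("radii must be positive")
        for pert in self.time_decay.values():
            for f in pert.values():
                if not 0.0 < f <= 1.0:
                    raise ValueError("decay factors must lie in (0, 1]")
        if self.bump_kind not in ("none", "dehydration", "meniscus"):
            raise ValueError(f"unknown bump_kind {self.bump_kind!r}")


def _flat_decay(value: float = 1.0) -> dict:
    return {t: value for t in TIMEPOINTS}


CONTROL_PRESET = GroupPreset(
    group="control",
    anterior_R=(7.80, 0.15),
    anterior_Q=(-0.72, 0.08),
    posterior_R=(6.268, 0.07),
    posterior_Q=(-0.70, 0.04),
    anterior_q_shift=0.0,
    posterior_steepening=0.0,
    hoa_anterior=0.17,
    hoa_posterior=0.055,
    hoa_gsd=1.30,
    bump_kind="none",
    bump_amplitude=(0.0, 1.0),
    bump_radius=0.0,
    bump_transition=0.0,
    time_decay={"bump": _flat_decay(), "hoa": _flat_decay(), "q_shift": _flat_decay()},
    cct={"pre": (527.0, 27.0)},
    preop_bscva=None,
    timepoints=("pre",),
    sex_p_female=12 / 18,
    eye_p_right=14 / 18,
)

DMEK_PRESET = GroupPreset(
    group="DMEK",
    anterior_R=(7.80, 0.15),
    anterior_Q=(-0.73, 0.08),
    posterior_R=(6.33, 0.08),
    posterior_Q=(-0.30, 0.05),
    anterior_q_shift=0.30,
    posterior_steepening=0.35,
    hoa_anterior=0.67,
    hoa_posterior=0.21,
    hoa_gsd=1.45,
    bump_kind="dehydration",
    bump_amplitude=(70.0, 1.6),
    bump_radius=1.85,
    bump_transition=1.5,
    time_decay={
        "bump": {"pre": 1.0, "1m": 0.50, "3m": 0.22, "6m": 0.15},
        "hoa": {"pre": 1.0, "1m": 0.70, "3m": 0.58, "6m": 0.52},
        "q_shift": {"pre": 1.0, "1m": 0.42, "3m": 0.42, "6m": 0.34},
        "steepen": {"pre": 1.0, "1m": 0.50, "3m": 0.15, "6m": 0.08},
    },
    cct={"pre": (714.0, 99.0), "1m": (520.0, 50.0), "3m": (480.0, 40.0), "6m": (460.0, 35.0)},
    preop_bscva=(1.01, 0.55),
    timepoints=TIMEPOINTS,
    sex_p_female=15 / 19,
    eye_p_right=13 / 19,
)

DSAEK_PRESET = GroupPreset(
    group="DSAEK",
    anterior_R=(7.80, 0.15),
    anterior_Q=(-0.73, 0.08),
    posterior_R=(6.22, 0.08),
    posterior_Q=(-0.20, 0.05),
    anterior_q_shift=0.31,
    posterior_steepening=0.0,
    hoa_anterior=0.92,
    hoa_posterior=0.26,
    hoa_gsd=1.45,
    bump_kind="meniscus",
    bump_amplitude=(260.0, 1.5),
    bump_radius=3.2,
    bump_transition=0.0,
    time_decay={
        "bump": {"pre": 1.0, "1m": 0.60, "3m": 0.31, "6m": 0.20},
        "hoa": {"pre": 1.0, "1m": 0.90, "3m": 0.82, "6m": 0.82},
        "q_shift": {"pre": 1.0, "1m": 0.45, "3m": 0.38, "6m": 0.36},
    },
    cct={"pre": (759.0, 130.0), "1m": (640.0, 70.0), "3m": (620.0, 60.0), "6m": (610.0, 60.0)},
    preop_bscva=(1.28, 0.43),
    timepoints=TIMEPOINTS,
    sex_p_female=18 / 23,
    eye_p_right=14 / 23,
)

PRESETS = {"control": CONTROL_PRESET, "DMEK": DMEK_PRESET, "DSAEK": DSAEK_PRESET}


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

@dataclass
class EyeRecord:
    """One synthetic eye at one timepoint.

    ``metrics``/``grade``/``bscva`` for postoperative records are filled by
    the pipeline (BSCVA responds to the computed grade and aberrations);
    preoperative BSCVA of surgical eyes is drawn directly from the preset.
    """

    eye_id: str
    group: str
    timepoint: str
    cornea: CorneaModel
    sex: str
    eye_side: str
    bscva: float | None = None
    bscva_seed: int = 0
    metrics: AberrationSet | None = None
    grade: GradeResult | None = None

    @property
    def cct(self) -> float:
        return self.cornea.central_thickness


@dataclass
class CohortConfig:
    """Study-cohort specification: group sizes, presets, seed, grid."""

    sizes: dict = field(default_factory=lambda: {"control": 18, "DMEK": 19, "DSAEK": 23})
    seed: int = 20170
    presets: dict = field(default_factory=lambda: dict(PRESETS))
    timepoints: dict | None = None  # optional per-group override
    bscva_model: BscvaModel = field(default_factory=BscvaModel)
    grid_spacing: float = DEFAULT_GRID_SPACING
    half_width: float = DEFAULT_HALF_WIDTH

    def group_timepoints(self, group: str) -> tuple[str, ...]:
        if self.timepoints and group in self.timepoints:
            return tuple(self.timepoints[group])
        return self.presets[group].timepoints


def _lognormal_mult(rng: np.random.Generator, gsd: float) -> float:
    return float(np.exp(np.log(gsd) * rng.standard_normal())) if gsd > 1.0 else 1.0


def _sample_eye(
    preset: GroupPreset,
    eye_id: str,
    timepoints: Sequence[str],
    rng: np.random.Generator,
    cfg: CohortConfig,
) -> list[EyeRecord]:
    """Draw one eye's latents and expand them over its timepoints."""
    r_ant = rng.normal(*preset.anterior_R)
    q_ant = rng.normal(*preset.anterior_Q)
    r_post = rng.normal(*preset.posterior_R)
    q_post = rng.normal(*preset.posterior_Q)
    dir_ant = _hoa_direction(rng)
    dir_post = _hoa_direction(rng)
    amp_mult_ant = _lognormal_mult(rng, preset.hoa_gsd)
    amp_mult_post = _lognormal_mult(rng, preset.hoa_gsd)
    bump_mult = _lognormal_mult(rng, preset.bump_amplitude[1])
    z_cct = rng.standard_normal()
    sex = "F" if rng.random() < preset.sex_p_female else "M"
    side = "R" if rng.random() < preset.eye_p_right else "L"
    preop_draw = rng.normal(*preset.preop_bscva) if preset.preop_bscva else None
    bscva_seeds = {t: int(rng.integers(0, 2**31 - 1)) for t in TIMEPOINTS}

    records = []
    for t in timepoints:
        decay = preset.time_decay
        q_t = q_ant + preset.anterior_q_shift * decay["q_shift"].get(t, 1.0)
        steepen = preset.posterior_steepening * decay.get("steepen", {}).get(t, 1.0)
        ant = make_conicoid(r_ant, q_t, cfg.grid_spacing, cfg.half_width)
        post = make_conicoid(max(r_post - steepen, 4.5), q_post, cfg.grid_spacing, cfg.half_width)

        hoa_f = decay["hoa"].get(t, 1.0)
        ant_noise = _perturbation(
            dir_ant, preset.hoa_anterior * hoa_f * amp_mult_ant,
            DELTA_N_ANTERIOR, cfg.grid_spacing, cfg.half_width,
        )
        post_noise = _perturbation(
            dir_post, preset.hoa_posterior * hoa_f * amp_mult_post,
            DELTA_N_POSTERIOR, cfg.grid_spacing, cfg.half_width,
        )
        ant = replace(ant, sag=ant.sag + ant_noise)
        post = replace(post, sag=post.sag + post_noise)

        amp = preset.bump_amplitude[0] * bump_mult * decay["bump"].get(t, 1.0)
        if preset.bump_kind == "dehydration":
            post = dmek_dehydration(post, amp, preset.bump_radius, preset.bump_transition)
        elif preset.bump_kind == "meniscus":
            post = dsaek_meniscus(post, amp, preset.bump_radius)

        cct_mean, cct_sd = preset.cct.get(t, next(iter(preset.cct.values())))
        cct = max(350.0, cct_mean + cct_sd * z_cct)
        cornea = CorneaModel(anterior=ant, posterior=post, central_thickness=cct)

        bscva = None
        if t == "pre" and preop_draw is not None:
            bscva = float(max(cfg.bscva_model.floor, preop_draw))
        records.append(
            EyeRecord(
                eye_id=eye_id,
                group=preset.group,
                timepoint=t,
                cornea=cornea,
                sex=sex,
                eye_side=side,
                bscva=bscva,
                bscva_seed=bscva_seeds[t],
            )
        )
    return records


def sample_cohort(config: CohortConfig) -> list[EyeRecord]:
    """Generate the full synthetic cohort, deterministic under config.seed.

    Longitudinal records of one eye share its latent draws, with the
    preset's decay factors applied per timepoint. Group sizes default to
    the study's 18 / 19 / 23 eyes.
    """
    root = np.random.SeedSequence(config.seed)
    group_seqs = root.spawn(len(GROUPS))
    records: list[EyeRecord] = []
    for gi, group in enumerate(GROUPS):
        n = config.sizes.get(group, 0)
        if n == 0:
            continue
        preset = config.presets[group]
        timepoints = config.group_timepoints(group)
        eye_seqs = group_seqs[gi].spawn(n)
        for i in range(n):
            rng = np.random.default_rng(eye_seqs[i])
            records.extend(
                _sample_eye(preset, f"{group}-{i + 1:03d}", timepoints, rng, config)
            )
    return records


def default_config(**overrides) -> CohortConfig:
    """The shipped study configuration (study-sized groups, fixed seed)."""
    return CohortConfig(**overrides)
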