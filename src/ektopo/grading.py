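"""Posterior refractive power (PRP) maps and the 0-5 posterior color grade.

The posterior corneal surface refracts from stroma (n = 1.376) into aqueous
(n = 1.336), so its dioptric power is negative: PRP = (1.336 - 1.376) / R_a
with the axial (sagittal) radius R_a in meters. Clinical devices render the
PRP map with a discrete color scale; here the scale is reduced to four
bands around the printed thresholds:

* cool (green/blue): PRP above the yellow band (flat),
* yellow: a band of configurable width centered at -6.3 D,
* orange: between the yellow band and -6.9 D,
* red: below -6.9 D (steep).

The 0-5 grade mirrors how a clinician scores the rendered map — cool
background 0, yellow 1, orange 2/3/4 as the red area crosses 1/4 and 1/2,
red background 5 — implemented as a monotone decision rule: red-area tiers
(>= 3/4 -> 5, >= 1/2 -> 4, >= 1/4 -> 3, boundaries closed on the higher
grade), otherwise the band of the area-median PRP value over the zone
(cool -> 0, yellow -> 1, orange -> 2). The median-band reading of
"background" coincides with the modal band on typical corneal maps and,
unlike it, guarantees that steepening a map everywhere can never lower the
grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wavefront import N_AQUEOUS, N_CORNEA, ElevationMap

BANDS = ("cool", "yellow", "orange", "red")

__all__ = [
    "BANDS",
    "BandConfig",
    "PRPMap",
    "GradeResult",
    "axial_radius_map",
    "prp_map",
    "classify_band",
    "band_fractions",
    "red_fraction",
    "background_band",
    "grade",
]


@dataclass(frozen=True)
class BandConfig:
    """Color-band thresholds of the posterior power scale (diopters).

    The printed scale places yellow exactly at -6.3 D; a measure-zero band
    is useless for classification, so yellow is widened to ``yellow_width``
    centered on -6.3 D (the device's discrete color step). A map counts as
    red-background once the red area fraction reaches
    ``red_background_fraction``.
    """

    yellow_center: float = -6.3
    yellow_width: float = 0.3
    red_threshold: float = -6.9
    red_background_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.yellow_width <= 0:
            raise ValueError("yellow_width must be positive")
        if self.red_threshold >= self.yellow_center:
            raise ValueError("red_threshold must lie below yellow_center")


@dataclass
class PRPMap:
    """Posterior refractive power map (diopters) over an analysis zone."""

    prp: np.ndarray
    grid_spacing: float  # mm
    half_width: float  # mm
    zone_diameter: float = 6.0
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.prp = np.asarray(self.prp, dtype=float)
        if self.zone_diameter <= 0:
            raise ValueError("zone_diameter must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.prp)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def n(self) -> int:
        return self.prp.shape[0]

    def zone_mask(self) -> np.ndarray:
        ax = np.linspace(-self.half_width, self.half_width, self.n)
        xx, yy = np.meshgrid(ax, ax)
        return np.hypot(xx, yy) <= self.zone_diameter / 2.0 + 1e-12

    @classmethod
    def uniform(
        cls,
        value: float,
        grid_spacing: float = 0.05,
        half_width: float = 3.5,
        zone_diameter: float = 6.0,
    ) -> "PRPMap":
        n = int(round(2 * half_width / grid_spacing)) + 1
        return cls(
            prp=np.full((n, n), float(value)),
            grid_spacing=grid_spacing,
            half_width=half_width,
            zone_diameter=zone_diameter,
        )


@dataclass
class GradeResult:
    """Outcome of the automated posterior color grading."""

    grade: int
    background_band: str
    red_fraction: float
    band_fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.grade <= 5:
            raise ValueError("grade must be in 0..5")
        if not 0.0 <= self.red_fraction <= 1.0:
            raise ValueError("red_fraction must be a fraction")
        if self.band_fractions:
            total = sum(self.band_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("band fractions must sum to 1")

    def to_dict(self) -> dict:
        return {
            "grade": self.grade,
            "background_band": self.background_band,
            "red_fraction": self.red_fraction,
            "band_fractions": dict(self.band_fractions),
        }


def axial_radius_map(posterior: ElevationMap, mode: str = "axial") -> np.ndarray:
    """Axial (sagittal) radius map R_a in mm; NaN where degenerate.

    For a meridian with sag z(r) (z in mm), the axial radius is
    ``R_a = r * sqrt(1 + z'^2) / z'``, the distance from the surface point
    to the optical axis along the surface normal. At the vertex the limit
    is the apical radius ``1 / z''(0)``, estimated from a small central
    neighborhood. ``mode="tangential"`` returns the instantaneous
    (meridional) radius of curvature instead.
    """
    if mode not in ("axial", "tangential"):
        raise ValueError("mode must be 'axial' or 'tangential'")
    z_mm = posterior.sag / 1000.0  # µm -> mm
    h = posterior.grid_spacing
    xx, yy = posterior.coords()
    rr = np.hypot(xx, yy)
    gy, gx = np.gradient(z_mm, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        dzdr = (xx * gx + yy * gy) / rr
    if mode == "axial":
        with np.errstate(invalid="ignore", divide="ignore"):
            ra = rr * np.sqrt(1.0 + dzdr**2) / dzdr
    else:
        # meridional curvature via second radial derivative
        gyy, gyx = np.gradient(gy, h)
        gxy, gxx = np.gradient(gx, h)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = (xx**2 * gxx + 2 * xx * yy * 0.5 * (gxy + gyx) + yy**2 * gyy) / rr**2
            ra = (1.0 + dzdr**2) ** 1.5 / d2
    ra = np.where(posterior.valid_mask, ra, np.nan)
    # off-vertex degenerate (flat or inverted) meridians -> invalid
    ra = np.where(ra > 0, ra, np.nan)

    # vertex limit: apical radius from a central quadratic fit z ~ (k/2) r^2
    c = posterior.n // 2
    near = (rr > 0) & (rr <= 2.5 * h) & posterior.valid_mask
    if near.sum() >= 4:
        r2 = rr[near] ** 2
        kappa = 2.0 * float(np.sum(z_mm[near] * r2) / np.sum(r2 * r2))
        ra[c, c] = 1.0 / kappa if kappa > 0 else np.nan
    else:
        ra[c, c] = np.nan
    return ra


def prp_map(
    posterior: ElevationMap,
    n_cornea: float = N_CORNEA,
    n_aqueous: float = N_AQUEOUS,
    zone_diameter: float = 6.0,
    mode: str = "axial",
) -> PRPMap:
    """Posterior refractive power map: (n_aqueous - n_cornea) / R_a, in diopters."""
    ra_mm = axial_radius_map(posterior, mode=mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        prp = (n_aqueous - n_cornea) / (ra_mm / 1000.0)
    return PRPMap(
        prp=prp,
        grid_spacing=posterior.grid_spacing,
        half_width=posterior.half_width,
        zone_diameter=zone_diameter,
        valid_mask=np.isfinite(prp),
    )


def _classify(values: np.ndarray, cfg: BandConfig) -> np.ndarray:
    """Vectorized band classification -> integer codes into BANDS.

    Gapless partition: red below red_threshold (strict); orange up to the
    yellow band; yellow closed on both edges; cool above. Nested selection
    keeps boundary values consistent under floating point.
    """
    half = cfg.yellow_width / 2.0
    lo, hi = cfg.yellow_center - half, cfg.yellow_center + half
    return np.where(
        values < cfg.red_threshold, 3,
        np.where(values < lo, 2, np.where(values <= hi, 1, 0)),
    ).astype(int)


def classify_band(prp_value: float, cfg: BandConfig | None = None) -> str:
    """Band of a single finite PRP value."""
    cfg = cfg or BandConfig()
    if not np.isfinite(prp_value):
        raise ValueError("PRP value must be finite")
    return BANDS[int(_classify(np.asarray([prp_value]), cfg)[0])]


def _zone_bands(m: PRPMap, cfg: BandConfig) -> np.ndarray:
    zone = m.zone_mask()
    valid = zone & m.valid_mask
    if valid.sum() < 0.5 * zone.sum():
        raise ValueError("fewer than 50% of zone samples are valid")
    return _classify(m.prp[valid], cfg)


def band_fractions(m: PRPMap, cfg: BandConfig | None = None) -> dict[str, float]:
    """Area fraction of each band over the valid analysis zone (sums to 1)."""
    cfg = cfg or BandConfig()
    codes = _zone_bands(m, cfg)
    counts = np.bincount(codes, minlength=4)
    return {band: float(c) / codes.size for band, c in zip(BANDS, counts)}


def red_fraction(m: PRPMap, cfg: BandConfig | None = None) -> float:
    """Area fraction of the zone classified red (PRP below the red threshold)."""
    cfg = cfg or BandConfig()
    return band_fractions(m, cfg)["red"]


def _median_band(fractions: dict[str, float], among_non_red: bool) -> str:
    """Band holding the area-median sample, counting from the steep side."""
    bands = ("red", "orange", "yellow", "cool")
    total = 1.0 - (fractions["red"] if among_non_red else 0.0)
    if total <= 0:
        return "red"
    half = total / 2.0
    cum = 0.0
    for b in bands:
        if among_non_red and b == "red":
            continue
        cum += fractions[b]
        if cum >= half:
            return b
    return "cool"


def background_band(m: PRPMap, cfg: BandConfig | None = None) -> str:
    """Background color of the map.

    Red once the red area reaches ``red_background_fraction``; otherwise
    the band of the area-median non-red sample — the color a rater reads
    off the bulk of the map.
    """
    cfg = cfg or BandConfig()
    fr = band_fractions(m, cfg)
    if fr["red"] >= cfg.red_background_fraction:
        return "red"
    return _median_band(fr, among_non_red=True)


def grade(m: PRPMap, cfg: BandConfig | None = None) -> GradeResult:
    """Posterior color grade 0-5 of a PRP map.

    Monotone decision rule: red fraction >= 3/4 -> 5 (red background);
    >= 1/2 -> 4; >= 1/4 -> 3 (boundaries closed on the higher grade);
    otherwise the area-median band of the zone decides — cool -> 0,
    yellow -> 1, orange -> 2. Steepening a map everywhere (any uniform
    negative PRP offset) can only raise both the red fraction and the
    warmth of the median band, so the grade never decreases.
    """
    cfg = cfg or BandConfig()
    fr = band_fractions(m, cfg)
    rf = fr["red"]
    if rf >= cfg.red_background_fraction:
        g = 5
    elif rf >= 0.5:
        g = 4
    elif rf >= 0.25:
        g = 3
    else:
        g = {"cool": 0, "yellow": 1, "orange": 2, "red": 3}[_median_band(fr, among_non_red=False)]
    bg = "red" if rf >= cfg.red_background_fraction else _median_band(fr, among_non_red=True)
    return GradeResult(grade=g, background_band=bg, red_fraction=rf, band_fractions=fr)


def render_prp(m: PRPMap, path: str, cfg: BandConfig | None = None) -> None:
    """Write a color rendering of the PRP map (green/blue-yellow-orange-red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    cfg = cfg or BandConfig()
    half = cfg.yellow_width / 2.0
    cmap = ListedColormap(["#d62728", "#ff7f0e", "#ffdf00", "#2ca02c"])
    bounds = [-12.0, cfg.red_threshold, cfg.yellow_center - half, cfg.yellow_center + half, -2.0]
    norm = BoundaryNorm(bounds, cmap.N)
    fig, ax = plt.subplots(figsize=(4, 4))
    extent = [-m.half_width, m.half_width, -m.half_width, m.half_width]
    im = ax.imshow(m.prp, cmap=cmap, norm=norm, origin="lower", extent=extent)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.colorbar(im, ax=ax, label="PRP (D)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
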