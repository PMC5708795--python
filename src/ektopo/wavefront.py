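"""Corneal surface geometry to optical path difference (OPD) maps.

A cornea is modelled as two refracting surfaces. Each surface's wavefront
contribution is taken in the thin-phase (paraxial) approximation as
``OPD(x, y) = delta_n * sag(x, y)`` with the refractive index steps used in
clinical corneal aberrometry: air→stroma 1.000→1.376 for the anterior
surface and stroma→aqueous 1.376→1.336 for the posterior surface. The total
corneal OPD is the pointwise sum of the two. Piston/tilt/defocus are fit
but excluded from every reported metric, so no reference-sphere subtraction
is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import zernike
from .zernike import ZernikeCoefficients, coma_rms, fit_coefficients, hoa_rms, sa_rms

N_CORNEA = 1.376
N_AQUEOUS = 1.336
N_AIR = 1.000
DELTA_N_ANTERIOR = N_CORNEA - N_AIR  # 0.376
DELTA_N_POSTERIOR = N_AQUEOUS - N_CORNEA  # -0.040

SURFACE_LABELS = ("anterior", "posterior", "total")

__all__ = [
    "N_CORNEA",
    "N_AQUEOUS",
    "DELTA_N_ANTERIOR",
    "DELTA_N_POSTERIOR",
    "ElevationMap",
    "CorneaModel",
    "OPDMap",
    "AberrationTriple",
    "AberrationSet",
    "surface_opd",
    "total_opd",
    "aberration_profile",
]


@dataclass
class ElevationMap:
    """Gridded surface sag on a square Cartesian grid.

    ``sag`` is in µm, positive toward the retina, vertex-referenced so
    sag(0, 0) = 0. The grid has an odd sample count per axis so the vertex
    is a sample. ``valid_mask`` flags measured samples.
    """

    sag: np.ndarray
    grid_spacing: float  # mm
    half_width: float  # mm
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sag = np.asarray(self.sag, dtype=float)
        if self.sag.ndim != 2 or self.sag.shape[0] != self.sag.shape[1]:
            raise ValueError("sag must be a square matrix")
        if self.sag.shape[0] % 2 != 1:
            raise ValueError("sample count per axis must be odd (vertex on grid)")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.sag)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.sag.shape:
                raise ValueError("valid_mask shape mismatch")
        c = self.sag.shape[0] // 2
        if self.valid_mask[c, c] and abs(self.sag[c, c]) > 1e-6:
            raise ValueError("sag must be vertex-referenced: sag(0,0) = 0")

    @property
    def n(self) -> int:
        return self.sag.shape[0]

    def axis(self) -> np.ndarray:
        return np.linspace(-self.half_width, self.half_width, self.n)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        ax = self.axis()
        return np.meshgrid(ax, ax)

    def radius(self) -> np.ndarray:
        xx, yy = self.coords()
        return np.hypot(xx, yy)

    def same_grid(self, other: "ElevationMap | OPDMap") -> bool:
        return (
            self.n == getattr(other, "n", None)
            and abs(self.grid_spacing - other.grid_spacing) < 1e-12
            and abs(self.half_width - other.half_width) < 1e-12
        )


@dataclass
class CorneaModel:
    """One eye's corneal geometry: both surfaces plus central thickness (µm)."""

    anterior: ElevationMap
    posterior: ElevationMap
    central_thickness: float

    def __post_init__(self) -> None:
        if self.central_thickness <= 0:
            raise ValueError("central_thickness must be positive")
        if not self.anterior.same_grid(self.posterior):
            raise ValueError("anterior and posterior maps must share grid geometry")


@dataclass
class OPDMap:
    """Optical path difference map (µm) over a circular pupil."""

    opd: np.ndarray
    grid_spacing: float
    half_width: float
    surface_label: str
    pupil_diameter: float
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.opd = np.asarray(self.opd, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.opd)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not np.all(np.isfinite(self.opd[self.valid_mask])):
            raise ValueError("OPD must be finite on valid samples")

    @property
    def n(self) -> int:
        return self.opd.shape[0]


def surface_opd(
    surface: ElevationMap,
    delta_n: float,
    pupil_diameter: float,
    surface_label: str = "anterior",
) -> OPDMap:
    """Thin-phase OPD of one refracting surface: ``delta_n * sag``, masked to the pupil."""
    if delta_n == 0:
        raise ValueError("delta_n must be nonzero")
    rr = surface.radius()
    in_pupil = rr <= pupil_diameter / 2.0 + 1e-12
    if pupil_diameter / 2.0 > surface.half_width + 1e-9:
        raise ValueError("pupil exceeds the map extent")
    if not np.all(surface.valid_mask[in_pupil]):
        raise ValueError("pupil exceeds the valid region of the map")
    opd = np.where(in_pupil, delta_n * surface.sag, np.nan)
    return OPDMap(
        opd=opd,
        grid_spacing=surface.grid_spacing,
        half_width=surface.half_width,
        surface_label=surface_label,
        pupil_diameter=pupil_diameter,
        valid_mask=in_pupil,
    )


def total_opd(anterior_opd: OPDMap, posterior_opd: OPDMap) -> OPDMap:
    """Total corneal OPD as the pointwise sum of the two surface OPDs."""
    if (
        anterior_opd.opd.shape != posterior_opd.opd.shape
        or abs(anterior_opd.grid_spacing - posterior_opd.grid_spacing) > 1e-12
        or abs(anterior_opd.pupil_diameter - posterior_opd.pupil_diameter) > 1e-12
    ):
        raise ValueError("grid or pupil mismatch between surface OPDs")
    mask = anterior_opd.valid_mask & posterior_opd.valid_mask
    opd = np.where(mask, anterior_opd.opd + posterior_opd.opd, np.nan)
    return OPDMap(
        opd=opd,
        grid_spacing=anterior_opd.grid_spacing,
        half_width=anterior_opd.half_width,
        surface_label="total",
        pupil_diameter=anterior_opd.pupil_diameter,
        valid_mask=mask,
    )


@dataclass(frozen=True)
class AberrationTriple:
    """HOA / SA / Coma RMS values (µm) for one surface at one zone."""

    hoa: float
    sa: float
    coma: float


@dataclass
class AberrationSet:
    """Aberration metrics for each surface label x pupil diameter."""

    values: dict = field(default_factory=dict)  # (label, diameter) -> AberrationTriple

    def get(self, surface_label: str, pupil_diameter: float) -> AberrationTriple:
        return self.values[(surface_label, float(pupil_diameter))]

    def set(self, surface_label: str, pupil_diameter: float, triple: AberrationTriple) -> None:
        if min(triple.hoa, triple.sa, triple.coma) < 0:
            raise ValueError("aberration metrics are non-negative")
        self.values[(surface_label, float(pupil_diameter))] = triple


def surface_coefficients(
    cornea: CorneaModel, pupil_diameter: float
) -> dict[str, ZernikeCoefficients]:
    """Zernike coefficients of anterior, posterior and total OPD at one zone."""
    ant = surface_opd(cornea.anterior, DELTA_N_ANTERIOR, pupil_diameter, "anterior")
    post = surface_opd(cornea.posterior, DELTA_N_POSTERIOR, pupil_diameter, "posterior")
    tot = total_opd(ant, post)
    return {
        "anterior": fit_coefficients(ant),
        "posterior": fit_coefficients(post),
        "total": fit_coefficients(tot),
    }


def aberration_profile(
    cornea: CorneaModel, pupil_diameters: tuple[float, ...] = (4.0, 6.0)
) -> AberrationSet:
    """HOA/SA/Coma for anterior, posterior and total OPD at each analysis zone."""
    out = AberrationSet()
    for d in pupil_diameters:
        for label, c in surface_coefficients(cornea, d).items():
            out.set(label, d, AberrationTriple(hoa=hoa_rms(c), sa=sa_rms(c), coma=coma_rms(c)))
    return out
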