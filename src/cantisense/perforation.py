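"""Perforation geometry, porosity, and the effective-modulus power law.

Drilling a regular grid of through-holes into the cantilever lowers its
stiffness and therefore amplifies the deflection produced by a given
contractile stress.  The perforated plate is homogenized as a porous
material whose effective Young's modulus follows the power law

    E = Es * (1 - a * p) ** b

where ``p`` is the porosity (area fraction of holes; through-thickness
holes make area and volume fraction identical) and ``a``, ``b`` are
constants fitted to finite-element data.  The default constants are
``a = 0.49`` and ``b = 5.86``.

Hole-layout convention
----------------------
The layout rule places an interior grid of ``n1 x n2`` hole centres with

    n1 = floor(L / q1) - 1,   n2 = floor(b / q2) - 1

rows at pitch ``q1`` along the length and columns at pitch ``q2`` across
the width, centred on the plate so no hole touches the boundary.  With
``q1 = 300 um``, ``q2 = 100 um`` on a 3000 x 1000 um plate this gives
81 holes and porosities 0.053 / 0.076 / 0.104 / 0.136 for apertures of
50 / 60 / 70 / 80 um.  ``porosity_value`` inputs are also accepted
everywhere so layouts that follow a different counting rule can be run
by supplying their porosity directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import (
    CantileverGeometry,
    CellGeometry,
    ContractileLoad,
    DeflectionResult,
    ElasticMaterial,
    InvalidGeometryError,
    curvature_radius_from_tip_deflection,
)

__all__ = [
    "PerforationPattern",
    "PorosityLaw",
    "DEFAULT_POROSITY_LAW",
    "FitDataset",
    "PorosityLawFit",
    "PorosityDomainError",
    "FitConvergenceError",
    "hole_layout",
    "porosity",
    "effective_modulus",
    "tip_deflection_perforated",
    "fit_porosity_law",
    "generate_fit_fixture",
    "layout_to_csv",
    "layout_to_svg",
]


class PorosityDomainError(ValueError):
    """Porosity outside the validity domain of the power law (a*p >= 1)."""


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge."""

    def __init__(self, message: str, residual_history: Sequence[float] = ()):
        super().__init__(message)
        self.residual_history = list(residual_history)


@dataclass(frozen=True)
class PerforationPattern:
    """Regular grid of circular through-holes.

    Parameters
    ----------
    aperture : float
        Hole diameter d in um.
    spacing_long : float
        Centre-to-centre pitch q1 along the cantilever length, um.
    spacing_trans : float
        Pitch q2 across the width, um.

    The aperture must be smaller than both pitches so neighbouring holes
    cannot merge.
    """

    aperture: float
    spacing_long: float
    spacing_trans: float

    def __post_init__(self) -> None:
        if self.aperture <= 0:
            raise InvalidGeometryError("aperture must be positive")
        if self.aperture >= min(self.spacing_long, self.spacing_trans):
            raise InvalidGeometryError(
                "aperture must be smaller than both hole spacings"
            )

    def check_cell_assumption(self, cell: CellGeometry = CellGeometry()) -> None:
        """Warn when holes are as large as the cells themselves.

        The homogenized model assumes the perforation does not disturb the
        arrangement or contraction of the cell layer, which holds only
        while the aperture stays below the size of the self-organized
        cells, i.e. their length along the contraction axis.
        """
        if self.aperture >= cell.cell_length:
            warnings.warn(
                f"aperture {self.aperture} um is not smaller than the cell "
                f"dimensions ({cell.cell_length} x {cell.cell_width} um); the "
                "assumption that perforation leaves the cell layer "
                "undisturbed may not hold",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class PorosityLaw:
    """Constants of the effective-modulus power law ``E = Es (1 - a p)^b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("power-law constants a and b must be positive")

    def ratio(self, p: float | np.ndarray) -> float | np.ndarray:
        """Modulus ratio ``E/Es`` at porosity ``p`` (requires ``a*p < 1``)."""
        arg = 1.0 - self.a * np.asarray(p, dtype=float)
        if np.any(arg <= 0):
            raise PorosityDomainError(
                f"porosity law invalid where a*p >= 1 (a={self.a})"
            )
        out = arg**self.b
        return float(out) if np.isscalar(p) or np.ndim(p) == 0 else out


#: Constants fitted to finite-element stiffness data for circular-hole grids.
DEFAULT_POROSITY_LAW = PorosityLaw(a=0.49, b=5.86)


@dataclass(frozen=True)
class FitDataset:
    """Paired (porosity, modulus-ratio) observations for fitting the law."""

    porosities: np.ndarray
    modulus_ratios: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.porosities, dtype=float)
        r = np.asarray(self.modulus_ratios, dtype=float)
        if p.shape != r.shape or p.ndim != 1:
            raise ValueError("porosities and modulus_ratios must be equal-length 1-D")
        if np.any(p < 0) or np.any(p >= 1):
            raise ValueError("porosities must lie in [0, 1)")
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError("modulus ratios must lie in (0, 1]")
        object.__setattr__(self, "porosities", p)
        object.__setattr__(self, "modulus_ratios", r)

    def __len__(self) -> int:
        return len(self.porosities)


@dataclass(frozen=True)
class PorosityLawFit:
    """Fitted law plus diagnostics from the nonlinear least squares."""

    law: PorosityLaw
    residual_norm: float
    a_confidence: tuple[float, float]
    b_confidence: tuple[float, float]
    n_observations: int


def hole_layout(
    pattern: PerforationPattern, geometry: CantileverGeometry
) -> np.ndarray:
    """Hole-centre coordinates for the interior-grid layout convention.

    Returns an ``(n, 2)`` array of ``(x, y)`` centres in um, ordered
    row-major from the clamped end (x increasing, then y).  ``x`` runs
    along the length from the clamped edge, ``y`` across the width.  An
    empty layout (with a warning) results when the plate is too small to
    host even one interior hole at the requested pitch.
    """
    n1 = math.floor(geometry.length / pattern.spacing_long + 1e-9) - 1
    n2 = math.floor(geometry.width / pattern.spacing_trans + 1e-9) - 1
    if n1 < 1 or n2 < 1:
        warnings.warn(
            "hole spacing leaves no interior grid position; empty layout",
            UserWarning,
            stacklevel=2,
        )
        return np.empty((0, 2))
    x0 = (geometry.length - (n1 - 1) * pattern.spacing_long) / 2.0
    y0 = (geometry.width - (n2 - 1) * pattern.spacing_trans) / 2.0
    xs = x0 + pattern.spacing_long * np.arange(n1)
    ys = y0 + pattern.spacing_trans * np.arange(n2)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def porosity(pattern: PerforationPattern, geometry: CantileverGeometry) -> float:
    """Porosity (hole area fraction) of the interior-grid layout.

    Through-thickness holes make the area fraction equal to the volume
    fraction, so the thickness does not enter.
    """
    centers = hole_layout(pattern, geometry)
    hole_area = len(centers) * math.pi * pattern.aperture**2 / 4.0
    return hole_area / (geometry.length * geometry.width)


def effective_modulus(
    young_modulus: float, p: float, law: PorosityLaw = DEFAULT_POROSITY_LAW
) -> float:
    """Homogenized Young's modulus ``Es (1 - a p)^b`` in kPa."""
    if young_modulus <= 0:
        raise ValueError("young_modulus must be positive")
    if p < 0:
        raise PorosityDomainError("porosity must be non-negative")
    return young_modulus * law.ratio(p)


def tip_deflection_perforated(
    geometry: CantileverGeometry,
    substrate: ElasticMaterial,
    load: ContractileLoad,
    p: float,
    law: PorosityLaw = DEFAULT_POROSITY_LAW,
) -> DeflectionResult:
    """Tip deflection of a perforated cantilever via the homogenized modulus.

        delta = 3 (1 - nu^2) L^2 tf sigma_f / (Es (1 - a p)^b ts^2)

    i.e. the plain-cantilever formula with the dense modulus replaced by
    the effective one; the gain over the plain cantilever is exactly
    ``(1 - a p)^-b`` regardless of geometry, load and substrate modulus.
    """
    e_eff = effective_modulus(substrate.young_modulus, p, law)
    nu = substrate.poisson_ratio
    delta = (
        3.0
        * (1.0 - nu**2)
        * geometry.length**2
        * geometry.film_thickness
        * load.film_stress
        / (e_eff * geometry.substrate_thickness**2)
    )
    radius = curvature_radius_from_tip_deflection(geometry.length, delta)
    return DeflectionResult(
        tip_deflection=delta,
        curvature_radius=radius,
        effective_modulus=e_eff,
    )


def fit_porosity_law(data: FitDataset) -> PorosityLawFit:
    """Fit the power-law constants to (porosity, modulus-ratio) data.

    Nonlinear least squares on ``E/Es = (1 - a p)^b`` with the fixed
    starting point ``(a, b) = (0.5, 5.0)`` and bounds ``a in (0, 1]``,
    ``b in (0, 50]``, so the fit is deterministic for a given dataset.
    Approximate 95% confidence intervals per constant come from the
    Jacobian-based covariance estimate.

    Raises
    ------
    ValueError
        Fewer than 3 observations (two constants need at least three).
    FitConvergenceError
        The optimizer did not converge; carries the residual history.
    """
    if len(data) < 3:
        raise ValueError("at least 3 (porosity, ratio) records are required")

    p, r = data.porosities, data.modulus_ratios
    residual_history: list[float] = []

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b = theta
        res = np.clip(1.0 - a * p, 1e-12, None) ** b - r
        residual_history.append(float(np.linalg.norm(res)))
        return res

    result = least_squares(
        residuals,
        x0=(0.5, 5.0),
        bounds=((1e-9, 1e-9), (1.0, 50.0)),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=5000,
    )
    if not result.success:
        raise FitConvergenceError(
            f"porosity-law fit failed: {result.message}", residual_history
        )

    dof = max(len(data) - 2, 1)
    s2 = 2.0 * result.cost / dof
    jtj = result.jac.T @ result.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    a_hat, b_hat = result.x
    halfwidth = 1.96 * se
    return PorosityLawFit(
        law=PorosityLaw(a=float(a_hat), b=float(b_hat)),
        residual_norm=float(np.sqrt(2.0 * result.cost)),
        a_confidence=(float(a_hat - halfwidth[0]), float(a_hat + halfwidth[0])),
        b_confidence=(float(b_hat - halfwidth[1]), float(b_hat + halfwidth[1])),
        n_observations=len(data),
    )


def generate_fit_fixture(
    law: PorosityLaw,
    n: int = 10,
    p_range: tuple[float, float] | Sequence[float] = (0.02, 0.15),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> FitDataset:
    """Synthetic (porosity, modulus-ratio) dataset drawn from a known law.

    Emulates the kind of finite-element stiffness-ratio data the power
    law is fitted to in practice.  ``p_range`` is either a ``(lo, hi)``
    pair expanded to ``n`` equispaced porosities or an explicit sequence
    (then ``n`` is ignored).  Gaussian noise of standard deviation
    ``noise_sd`` is added to the ratios, which are then clipped back into
    ``(0, 1]``.  Reproducible for a fixed ``seed``.
    """
    if len(p_range) == 2 and not isinstance(p_range, np.ndarray):
        lo, hi = float(p_range[0]), float(p_range[1])
        if n < 3:
            raise ValueError("n must be at least 3")
        p = np.linspace(lo, hi, n)
    else:
        p = np.asarray(p_range, dtype=float)
    ratios = np.asarray(law.ratio(p), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratios = ratios + rng.normal(0.0, noise_sd, size=ratios.shape)
    ratios = np.clip(ratios, 1e-6, 1.0)
    return FitDataset(porosities=p, modulus_ratios=ratios)


def layout_to_csv(
    pattern: PerforationPattern, geometry: CantileverGeometry, path
) -> None:
    """Write hole centres as CSV with columns ``x_um, y_um, d_um``."""
    centers = hole_layout(pattern, geometry)
    with open(path, "w") as fh:
        fh.write("x_um,y_um,d_um\n")
        for x, y in centers:
            fh.write(f"{x:.6g},{y:.6g},{pattern.aperture:.6g}\n")


def layout_to_svg(
    pattern: PerforationPattern, geometry: CantileverGeometry, path
) -> None:
    """Write a simple SVG sketch of the plate outline and hole layout."""
    centers = hole_layout(pattern, geometry)
    L, b = geometry.length, geometry.width
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {L} {b}" '
        f'width="{L}" height="{b}">',
        f'<rect x="0" y="0" width="{L}" height="{b}" fill="none" '
        'stroke="black" stroke-width="2"/>',
        f'<line x1="0" y1="0" x2="0" y2="{b}" stroke="red" stroke-width="4"/>',
    ]
    r = pattern.aperture / 2.0
    for x, y in centers:
        lines.append(
            f'<circle cx="{x:.4g}" cy="{y:.4g}" r="{r:.4g}" fill="white" '
            'stroke="black"/>'
        )
    lines.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
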