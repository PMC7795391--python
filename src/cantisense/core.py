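"""Closed-form Stoney-type relations for a film-stressed cantilever.

A thin contracting cell layer (the "film") cultured on a soft elastomer
cantilever (the "substrate") exerts an in-plane stress that bends the
cantilever.  Treating the cell layer as a residually stressed thin film,
the curvature of the substrate follows the Stoney relation; substituting
the plate modulus ``Es/(1 - nu**2)`` for the biaxial modulus gives the
wide-plate ("plate") convention used throughout this package:

    sigma_f = Es * ts**2 / (6 * (1 - nu**2) * tf) * (1/r - 1/r0)

together with the shallow-arc geometric identity ``r ~ L**2 / (2 delta)``,
which combine into the tip-deflection formula

    delta = 3 * (1 - nu**2) * L**2 * tf * sigma_f / (Es * ts**2)

Unit system
-----------
All quantities use a consistent micromechanics unit system: lengths in
micrometres, moduli and stresses in kilopascal.  Note the identity
``1 nN/um^2 == 1 kPa``, so contractile stresses quoted in nN/um^2 can be
passed directly as kPa.  Deflections come out in micrometres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "FLAT",
    "ElasticMaterial",
    "CantileverGeometry",
    "ContractileLoad",
    "CellGeometry",
    "DeflectionResult",
    "InvalidGeometryError",
    "ThinFilmAssumptionWarning",
    "curvature_radius_from_tip_deflection",
    "film_stress_from_curvature",
    "tip_deflection_plain",
]

#: Sentinel curvature radius of an unbent (flat) cantilever.
FLAT = math.inf


class InvalidGeometryError(ValueError):
    """Geometry or material parameters outside the model's domain."""


class ThinFilmAssumptionWarning(UserWarning):
    """The thin-film assumption behind the Stoney relation is degrading."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidGeometryError(msg)


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic material.

    Parameters
    ----------
    young_modulus : float
        Young's modulus in kPa.  PDMS at a 10:1 base:curing-agent ratio is
        about 750 kPa; a cardiomyocyte monolayer about 188 kPa.
    poisson_ratio : float
        Poisson's ratio, in ``[0, 0.5)``.  Soft elastomers and cell layers
        are nearly incompressible (0.49).
    """

    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        _require(self.young_modulus > 0, "young_modulus must be positive")
        _require(
            0 <= self.poisson_ratio < 0.5,
            "poisson_ratio must lie in [0, 0.5)",
        )

    @property
    def plate_modulus(self) -> float:
        """``E / (1 - nu**2)`` in kPa."""
        return self.young_modulus / (1.0 - self.poisson_ratio**2)

    @property
    def biaxial_modulus(self) -> float:
        """``E / (1 - nu)`` in kPa."""
        return self.young_modulus / (1.0 - self.poisson_ratio)


#: PDMS substrate, 10:1 base to curing agent.
PDMS = ElasticMaterial(young_modulus=750.0, poisson_ratio=0.49)

#: Self-organized cardiomyocyte monolayer.
CM_FILM = ElasticMaterial(young_modulus=188.0, poisson_ratio=0.49)


@dataclass(frozen=True)
class CantileverGeometry:
    """Rectangular cantilever plate with a full-face film on top.

    All lengths in micrometres.  ``length`` runs from the clamped edge to
    the free end, ``width`` is transverse, ``substrate_thickness`` is the
    elastomer plate and ``film_thickness`` the cell layer on its surface.
    A warning (not an error) is raised when the film is thicker than ~20%
    of the substrate, where the thin-film assumption starts to degrade.
    """

    length: float
    width: float
    substrate_thickness: float
    film_thickness: float = 10.0

    def __post_init__(self) -> None:
        for name in ("length", "width", "substrate_thickness", "film_thickness"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        if self.film_thickness / self.substrate_thickness > 0.2:
            warnings.warn(
                "film_thickness exceeds 20% of substrate_thickness; the "
                "thin-film (Stoney) assumption degrades in this regime",
                ThinFilmAssumptionWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ContractileLoad:
    """Contractile stress exerted by the cell layer, treated as film stress.

    ``film_stress`` is in nN/um^2 (identically kPa).  Beating
    cardiomyocyte monolayers generate roughly 2-5 nN/um^2.  The dominant
    component acts along the cantilever's long axis when the cells align
    longitudinally, hence the default direction.
    """

    film_stress: float
    direction: str = "longitudinal_uniaxial"

    _DIRECTIONS = ("longitudinal_uniaxial", "equibiaxial")

    def __post_init__(self) -> None:
        _require(self.film_stress >= 0, "film_stress must be non-negative")
        if self.direction not in self._DIRECTIONS:
            raise ValueError(
                f"direction must be one of {self._DIRECTIONS}, got {self.direction!r}"
            )


@dataclass(frozen=True)
class CellGeometry:
    """Idealized box model of a single cardiomyocyte (informational).

    Used only to check that perforation apertures stay smaller than the
    cells, so the hole pattern does not disturb their arrangement.
    Defaults are typical for cultured ventricular cardiomyocytes.
    """

    cell_length: float = 100.0
    cell_width: float = 30.0
    cell_thickness: float = 10.0

    def __post_init__(self) -> None:
        for name in ("cell_length", "cell_width", "cell_thickness"):
            _require(getattr(self, name) > 0, f"{name} must be positive")


@dataclass(frozen=True)
class DeflectionResult:
    """Outcome of a deflection computation.

    Attributes
    ----------
    tip_deflection : float
        Free-end deflection magnitude in um, toward the film side.
    curvature_radius : float
        Bent curvature radius in um (``FLAT`` i.e. ``inf`` when unbent).
    initial_curvature_radius : float
        Pre-load curvature radius; ``FLAT`` unless stated otherwise.
    effective_modulus : float
        The substrate modulus actually used (kPa); equals the dense
        modulus for a plain cantilever, the homogenized one when
        perforated.
    """

    tip_deflection: float
    curvature_radius: float
    effective_modulus: float
    initial_curvature_radius: float = field(default=FLAT)

    def __post_init__(self) -> None:
        _require(self.tip_deflection >= 0, "tip_deflection must be >= 0")
        if self.tip_deflection == 0:
            _require(
                math.isinf(self.curvature_radius),
                "zero deflection must come with a flat (infinite) radius",
            )
        else:
            _require(self.curvature_radius > 0, "curvature_radius must be positive")


def curvature_radius_from_tip_deflection(length: float, deflection: float) -> float:
    """Curvature radius from tip deflection via the shallow-arc relation.

    ``r ~ L**2 / (2 delta)``; valid for deflections small against the
    length.  Returns ``FLAT`` (infinity) for zero deflection.

    Parameters
    ----------
    length : float
        Cantilever length L in um, > 0.
    deflection : float
        Tip deflection in um, >= 0.
    """
    _require(length > 0, "length must be positive")
    _require(deflection >= 0, "deflection must be non-negative")
    if deflection == 0:
        return FLAT
    return length**2 / (2.0 * deflection)


def film_stress_from_curvature(
    substrate: ElasticMaterial,
    geometry: CantileverGeometry,
    curvature_radius: float,
    initial_curvature_radius: float = FLAT,
    convention: str = "plate",
) -> float:
    """Film stress implied by a curvature change (inverse Stoney relation).

    Parameters
    ----------
    substrate : ElasticMaterial
    geometry : CantileverGeometry
    curvature_radius, initial_curvature_radius : float
        Bent and initial curvature radii in um; ``FLAT`` for an unbent
        state.  An unbent initial state contributes ``1/r0 = 0``.
    convention : {"plate", "biaxial"}
        "plate" uses the wide-plate modulus ``Es/(1-nu**2)`` (the default
        and the recommended form for cantilever plates); "biaxial" the
        classical ``Es/(1-nu)``.

    Returns
    -------
    float
        Film stress sigma_f in nN/um^2 (kPa).
    """
    _require(curvature_radius > 0, "curvature_radius must be positive")
    _require(initial_curvature_radius > 0, "initial_curvature_radius must be positive")
    if geometry.film_thickness <= 0:
        raise InvalidGeometryError("film_thickness must be positive")
    exponent = {"plate": 2, "biaxial": 1}.get(convention)
    if exponent is None:
        raise ValueError(f"convention must be 'plate' or 'biaxial', got {convention!r}")
    nu = substrate.poisson_ratio
    modulus_factor = substrate.young_modulus / (1.0 - nu**exponent)
    inv_r = 0.0 if math.isinf(curvature_radius) else 1.0 / curvature_radius
    inv_r0 = 0.0 if math.isinf(initial_curvature_radius) else 1.0 / initial_curvature_radius
    return (
        modulus_factor
        * geometry.substrate_thickness**2
        / (6.0 * geometry.film_thickness)
        * (inv_r - inv_r0)
    )


def tip_deflection_plain(
    geometry: CantileverGeometry,
    substrate: ElasticMaterial,
    load: ContractileLoad,
    convention: str = "plate",
) -> DeflectionResult:
    """Tip deflection of a plain (unperforated) cantilever.

    Combines the Stoney curvature with the shallow-arc identity:

        delta = 3 * (1 - nu**2) * L**2 * tf * sigma_f / (Es * ts**2)

    (plate convention; the biaxial convention replaces ``1 - nu**2`` by
    ``1 - nu``).  The deflection is toward the cell-layer side and is
    reported as a positive magnitude.  Independent of the width.
    """
    exponent = {"plate": 2, "biaxial": 1}.get(convention)
    if exponent is None:
        raise ValueError(f"convention must be 'plate' or 'biaxial', got {convention!r}")
    nu = substrate.poisson_ratio
    delta = (
        3.0
        * (1.0 - nu**exponent)
        * geometry.length**2
        * geometry.film_thickness
        * load.film_stress
        / (substrate.young_modulus * geometry.substrate_thickness**2)
    )
    radius = curvature_radius_from_tip_deflection(geometry.length, delta)
    return DeflectionResult(
        tip_deflection=delta,
        curvature_radius=radius,
        effective_modulus=substrate.young_modulus,
    )
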