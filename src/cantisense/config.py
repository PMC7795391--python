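"""YAML/JSON configuration handling.

A config document carries ``material``, ``geometry``, ``load``,
``perforation``, ``law`` and ``sweep`` blocks, e.g.::

    material:   {young_modulus_kPa: 750, poisson_ratio: 0.49}
    geometry:   {L_um: 9000, b_um: 3000, ts_um: 100, tf_um: 10}
    load:       {sigma_nN_per_um2: 2}
    perforation: {d_um: 60, q1_um: 300, q2_um: 100}   # or {porosity: 0.068}
    law:        {a: 0.49, b: 5.86}

CLI flags override config entries.  JSON documents parse too (YAML is a
superset).
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .core import CantileverGeometry, ContractileLoad, ElasticMaterial
from .perforation import DEFAULT_POROSITY_LAW, PerforationPattern, PorosityLaw

__all__ = [
    "load_config",
    "material_from_config",
    "geometry_from_config",
    "load_from_config",
    "perforation_from_config",
    "law_from_config",
]


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Parse a YAML/JSON config file; ``None`` gives an empty config."""
    if path is None:
        return {}
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ValueError(f"config root must be a mapping, got {type(doc).__name__}")
    return doc


def _merged(block: dict | None, overrides: dict[str, Any]) -> dict[str, Any]:
    out = dict(block or {})
    out.update({k: v for k, v in overrides.items() if v is not None})
    return out


def material_from_config(cfg: dict, **overrides) -> ElasticMaterial:
    blk = _merged(cfg.get("material"), overrides)
    return ElasticMaterial(
        young_modulus=float(blk.get("young_modulus_kPa", blk.get("Es", 750.0))),
        poisson_ratio=float(blk.get("poisson_ratio", blk.get("nu", 0.49))),
    )


def geometry_from_config(cfg: dict, **overrides) -> CantileverGeometry:
    blk = _merged(cfg.get("geometry"), overrides)
    return CantileverGeometry(
        length=float(blk.get("L_um", blk.get("L", 9000.0))),
        width=float(blk.get("b_um", blk.get("b", 3000.0))),
        substrate_thickness=float(blk.get("ts_um", blk.get("ts", 100.0))),
        film_thickness=float(blk.get("tf_um", blk.get("tf", 10.0))),
    )


def load_from_config(cfg: dict, **overrides) -> ContractileLoad:
    blk = _merged(cfg.get("load"), overrides)
    return ContractileLoad(
        film_stress=float(blk.get("sigma_nN_per_um2", blk.get("sigma", 2.0))),
        direction=blk.get("direction", "longitudinal_uniaxial"),
    )


def perforation_from_config(
    cfg: dict, **overrides
) -> tuple[PerforationPattern | None, float | None]:
    """Return ``(pattern, porosity)``; either may be None.

    A direct ``porosity`` entry wins over a ``d/q1/q2`` pattern so that
    layouts following a different counting convention can be specified
    by their porosity alone.
    """
    blk = _merged(cfg.get("perforation"), overrides)
    if not blk:
        return None, None
    p = blk.get("porosity")
    pattern = None
    if all(k in blk and blk[k] is not None for k in ("d_um", "q1_um", "q2_um")):
        pattern = PerforationPattern(
            aperture=float(blk["d_um"]),
            spacing_long=float(blk["q1_um"]),
            spacing_trans=float(blk["q2_um"]),
        )
    return pattern, (None if p is None else float(p))


def law_from_config(cfg: dict, **overrides) -> PorosityLaw:
    blk = _merged(cfg.get("law"), overrides)
    return PorosityLaw(
        a=float(blk.get("a", DEFAULT_POROSITY_LAW.a)),
        b=float(blk.get("b", DEFAULT_POROSITY_LAW.b)),
    )
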