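"""Parameter sweeps and figure-style report campaigns.

`run_sweep` evaluates the deflection model over one swept parameter and
returns a tidy table with one row per value; `figure_campaign` bundles
the study's standard sweep definitions (size, contractile force,
substrate modulus, substrate thickness, aperture, hole spacing,
transient) into reproducible CSV (and optional PNG) artifacts.  CSV
output is deterministic: re-running a campaign produces byte-identical
files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .core import (
    CantileverGeometry,
    ContractileLoad,
    ElasticMaterial,
    tip_deflection_plain,
)
from .perforation import (
    DEFAULT_POROSITY_LAW,
    PerforationPattern,
    PorosityLaw,
    porosity as porosity_of,
    tip_deflection_perforated,
)
from . import fem as fem_mod
from .transient import ContractileWaveform, response_timeseries

__all__ = ["SweepSpec", "run_sweep", "figure_campaign", "CAMPAIGNS"]

logger = logging.getLogger("cantisense.sweeps")

MODELS = ("analytic_plain", "analytic_perforated", "fem")

#: Standard result-table columns shared by the CLI and campaign writers.
COLUMNS = [
    "L_um", "b_um", "ts_um", "tf_um", "Es_kPa", "nu",
    "sigma_nN_per_um2", "porosity", "delta_um", "r_um", "method",
]


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep over the deflection model.

    ``parameter`` is one of ``L, b, ts, tf, Es, nu, sigma, porosity, d,
    q1, q2, size`` (``size`` sets L and keeps the width at L/aspect,
    default aspect 3).  ``fixed`` holds the remaining parameters; a
    perforated run takes either a direct ``porosity`` or a hole pattern
    ``d, q1, q2`` from which the porosity is computed.
    """

    parameter: str
    values: Sequence[float]
    fixed: dict[str, Any] = field(default_factory=dict)
    model: str = "analytic_plain"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        vals = np.asarray(list(self.values), dtype=float)
        if vals.size == 0 or not np.all(np.isfinite(vals)):
            raise ValueError("swept values must be non-empty and finite")

    def spec_hash(self) -> str:
        payload = repr((self.parameter, tuple(self.values), sorted(self.fixed.items()), self.model))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_DEFAULTS = {
    "L": 9000.0, "b": 3000.0, "ts": 100.0, "tf": 10.0,
    "Es": 750.0, "nu": 0.49, "sigma": 2.0, "aspect": 3.0,
    "a": DEFAULT_POROSITY_LAW.a, "b_exp": DEFAULT_POROSITY_LAW.b,
    "h": 50.0, "load_mode": "cylindrical",
}


def _row(params: dict[str, Any], model: str) -> dict[str, Any]:
    geom = CantileverGeometry(
        length=params["L"], width=params["b"],
        substrate_thickness=params["ts"], film_thickness=params["tf"],
    )
    substrate = ElasticMaterial(params["Es"], params["nu"])
    load = ContractileLoad(params["sigma"])
    law = PorosityLaw(params["a"], params["b_exp"])

    pattern = None
    if all(k in params for k in ("d", "q1", "q2")):
        pattern = PerforationPattern(params["d"], params["q1"], params["q2"])
    if "porosity" in params:
        p = float(params["porosity"])
    elif pattern is not None:
        p = porosity_of(pattern, geom)
    else:
        p = 0.0

    if model == "analytic_plain":
        res = tip_deflection_plain(geom, substrate, load)
        p = 0.0
    elif model == "analytic_perforated":
        res = tip_deflection_perforated(geom, substrate, load, p=p, law=law)
    else:  # fem
        mesh = fem_mod.build_mesh(geom, pattern, target_h=params["h"])
        section = fem_mod.LayeredSection(
            substrate=substrate,
            substrate_thickness=geom.substrate_thickness,
            film=ElasticMaterial(188.0, 0.49),
            film_thickness=geom.film_thickness,
            film_stress=load.film_stress,
        )
        fr = fem_mod.solve_bilayer(mesh, section, load_mode=params["load_mode"])
        return {
            "L_um": geom.length, "b_um": geom.width,
            "ts_um": geom.substrate_thickness, "tf_um": geom.film_thickness,
            "Es_kPa": substrate.young_modulus, "nu": substrate.poisson_ratio,
            "sigma_nN_per_um2": load.film_stress, "porosity": p,
            "delta_um": fr.tip_deflection, "r_um": np.nan, "method": "fem",
        }
    return {
        "L_um": geom.length, "b_um": geom.width,
        "ts_um": geom.substrate_thickness, "tf_um": geom.film_thickness,
        "Es_kPa": substrate.young_modulus, "nu": substrate.poisson_ratio,
        "sigma_nN_per_um2": load.film_stress, "porosity": p,
        "delta_um": res.tip_deflection, "r_um": res.curvature_radius,
        "method": model,
    }


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the sweep; one row per swept value, in given order.

    Any row failure aborts the sweep with the offending value named.
    Provenance (spec hash, package version) is logged per row and stored
    in ``DataFrame.attrs``.
    """
    try:
        version = metadata.version("cantisense")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    shash = spec.spec_hash()
    rows = []
    for value in spec.values:
        params = dict(_DEFAULTS)
        params.update(spec.fixed)
        if spec.parameter == "size":
            params["L"] = float(value)
            params["b"] = float(value) / params["aspect"]
        else:
            params[spec.parameter] = float(value)
        try:
            row = _row(params, spec.model)
        except Exception as exc:
            raise RuntimeError(
                f"sweep failed at {spec.parameter}={value}: {exc}"
            ) from exc
        logger.info(
            "sweep %s v%s %s=%g -> delta=%.6g um",
            shash, version, spec.parameter, value, row["delta_um"],
        )
        rows.append(row)
    df = pd.DataFrame(rows, columns=COLUMNS)
    df.attrs["spec_hash"] = shash
    df.attrs["package_version"] = version
    return df


# --- figure campaigns ------------------------------------------------------

_SIZES = [1500.0, 3000.0, 6000.0, 9000.0]
_FORCES = [2.0, 3.0, 4.0, 5.0]
#: Porosities of the fixed hole pattern (d=60, q1=300, q2=100) realized on
#: the four standard plate sizes; slightly size-dependent because the hole
#: grid must stay interior.
_SIZE_POROSITIES = {1500.0: 0.094, 3000.0: 0.076, 6000.0: 0.068, 9000.0: 0.065}
#: Porosities of the spacing sweep (d=50, q2=100, q1 = 100..400 um).
_SPACING_POROSITIES = {100.0: 0.147, 200.0: 0.076, 300.0: 0.053, 400.0: 0.041}


def _campaign_fig2() -> pd.DataFrame:
    frames = []
    for sigma in _FORCES:
        spec = SweepSpec("size", _SIZES, fixed={"sigma": sigma, "ts": 100.0})
        frames.append(run_sweep(spec))
    return pd.concat(frames, ignore_index=True)


def _campaign_fig3() -> pd.DataFrame:
    frames = []
    for L in _SIZES:
        spec = SweepSpec(
            "Es", np.arange(500.0, 1001.0, 100.0),
            fixed={"L": L, "b": L / 3.0, "ts": 100.0},
        )
        df = run_sweep(spec)
        df.insert(0, "panel", "a")
        frames.append(df)
    df = run_sweep(SweepSpec("ts", np.arange(70.0, 131.0, 10.0), fixed={"L": 9000.0}))
    df.insert(0, "panel", "b")
    frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _campaign_fig4() -> pd.DataFrame:
    frames = []
    for sigma in _FORCES:
        for L in _SIZES:
            spec = SweepSpec(
                "L", [L], model="analytic_perforated",
                fixed={
                    "b": L / 3.0, "ts": 100.0, "sigma": sigma,
                    "porosity": _SIZE_POROSITIES[L],
                },
            )
            frames.append(run_sweep(spec))
    return pd.concat(frames, ignore_index=True)


def _campaign_fig5() -> pd.DataFrame:
    a = run_sweep(
        SweepSpec(
            "Es", np.arange(500.0, 1001.0, 100.0), model="analytic_perforated",
            fixed={"L": 6000.0, "b": 2000.0, "ts": 100.0, "porosity": 0.068},
        )
    )
    a.insert(0, "panel", "a")
    b = run_sweep(
        SweepSpec(
            "ts", np.arange(70.0, 131.0, 10.0), model="analytic_perforated",
            fixed={"L": 9000.0, "porosity": 0.068},
        )
    )
    b.insert(0, "panel", "b")
    return pd.concat([a, b], ignore_index=True)


def _campaign_fig6() -> pd.DataFrame:
    frames = []
    for sigma in _FORCES:
        df = run_sweep(
            SweepSpec(
                "d", [50.0, 60.0, 70.0, 80.0], model="analytic_perforated",
                fixed={
                    "L": 3000.0, "b": 1000.0, "ts": 100.0, "sigma": sigma,
                    "q1": 300.0, "q2": 100.0,
                },
            )
        )
        df.insert(0, "panel", "a")
        df.insert(1, "swept", df["porosity"])
        frames.append(df)
    for sigma in _FORCES:
        for q1, p in _SPACING_POROSITIES.items():
            df = run_sweep(
                SweepSpec(
                    "porosity", [p], model="analytic_perforated",
                    fixed={"L": 3000.0, "b": 1000.0, "ts": 100.0, "sigma": sigma},
                )
            )
            df.insert(0, "panel", "b")
            df.insert(1, "swept", q1)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _campaign_fig7() -> pd.DataFrame:
    geom = CantileverGeometry(3000.0, 1000.0, 100.0, 10.0)
    substrate = ElasticMaterial(750.0, 0.49)
    wave = ContractileWaveform(amplitude=5.0, period=1.0)
    pattern = PerforationPattern(80.0, 300.0, 100.0)
    p = porosity_of(pattern, geom)
    plain = response_timeseries(geom, substrate, wave, p=0.0)
    perf = response_timeseries(geom, substrate, wave, p=p)
    return pd.DataFrame(
        {
            "t_s": plain.times,
            "sigma_nN_per_um2": plain.stresses,
            "delta_plain_um": plain.deflections,
            "delta_perforated_um": perf.deflections,
        }
    )


CAMPAIGNS = {
    "fig2": _campaign_fig2,
    "fig3": _campaign_fig3,
    "fig4": _campaign_fig4,
    "fig5": _campaign_fig5,
    "fig6": _campaign_fig6,
    "fig7": _campaign_fig7,
}


def figure_campaign(name: str, outdir, make_plot: bool = True) -> list[Path]:
    """Run one bundled sweep campaign; write ``<name>.csv`` (+ ``.png``).

    CSV bytes are identical across re-runs.  Raises ``ValueError``
    listing the valid names when ``name`` is unknown.
    """
    if name not in CAMPAIGNS:
        raise ValueError(
            f"unknown campaign {name!r}; valid names: {sorted(CAMPAIGNS)}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = CAMPAIGNS[name]()
    csv_path = outdir / f"{name}.csv"
    df.to_csv(csv_path, index=False, float_format="%.9g", lineterminator="\n")
    written = [csv_path]
    if make_plot:
        written.append(_plot_campaign(name, df, outdir))
    return written


def _plot_campaign(name: str, df: pd.DataFrame, outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if name == "fig7":
        ax.plot(df["t_s"], df["delta_plain_um"], label="plain")
        ax.plot(df["t_s"], df["delta_perforated_um"], label="perforated")
        ax.set_xlabel("t (s)")
        ax.set_ylabel("tip deflection (um)")
    else:
        x = "L_um"
        for key in ("ts_um", "Es_kPa", "sigma_nN_per_um2"):
            if df[key].nunique() > 1:
                x = key
        for sig, grp in df.groupby("sigma_nN_per_um2"):
            ax.plot(grp[x], grp["delta_um"], "o-", label=f"sigma={sig:g}")
        ax.set_xlabel(x)
        ax.set_ylabel("delta (um)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    png_path = outdir / f"{name}.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return png_path
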