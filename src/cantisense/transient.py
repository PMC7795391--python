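"""Quasi-static time response to a periodic contractile waveform.

A beating cardiomyocyte layer loads the cantilever with a time-varying
contractile stress, modelled as a sine ``sigma(t) = A sin(2 pi t / T)``
(default amplitude 5 nN/um^2, period 1 s).  The lowest bending resonance
of these millimetre-scale PDMS plates sits far above the ~1 Hz beating
frequency, so inertia is neglected and the deflection at each instant is
simply the static deflection at that instant's stress magnitude:

    delta(t) = delta_static(|sigma(t)|)

Contraction magnitude drives the bending regardless of sign, which is
why the response shows two equal peaks per period (at T/4 and 3T/4 for
zero phase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import CantileverGeometry, ContractileLoad, ElasticMaterial
from .perforation import DEFAULT_POROSITY_LAW, PorosityLaw, tip_deflection_perforated

__all__ = [
    "ContractileWaveform",
    "ResponseSeries",
    "waveform_value",
    "response_timeseries",
    "peak_times",
]


@dataclass(frozen=True)
class ContractileWaveform:
    """Sinusoidal contractile stress ``A sin(2 pi t / T + phase)``.

    ``amplitude`` in nN/um^2, ``period`` in seconds, ``phase`` in rad.
    """

    amplitude: float = 5.0
    period: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")


@dataclass(frozen=True)
class ResponseSeries:
    """Deflection time series on a uniform grid.

    ``times`` in s (strictly increasing), ``deflections`` in um,
    ``stresses`` the signed waveform values in nN/um^2, and ``metadata``
    records the geometry/material/porosity the series was computed for.
    """

    times: np.ndarray
    deflections: np.ndarray
    stresses: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.deflections, dtype=float)
        s = np.asarray(self.stresses, dtype=float)
        if not (t.shape == d.shape == s.shape) or t.ndim != 1:
            raise ValueError("times, deflections, stresses must be equal-length 1-D")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "deflections", d)
        object.__setattr__(self, "stresses", s)

    def __len__(self) -> int:
        return len(self.times)


def waveform_value(waveform: ContractileWaveform, t: float | np.ndarray):
    """Signed contractile stress at time ``t`` (array-friendly)."""
    return waveform.amplitude * np.sin(
        2.0 * math.pi * np.asarray(t, dtype=float) / waveform.period + waveform.phase
    )


def response_timeseries(
    geometry: CantileverGeometry,
    substrate: ElasticMaterial,
    waveform: ContractileWaveform,
    p: float = 0.0,
    law: PorosityLaw = DEFAULT_POROSITY_LAW,
    t_grid: np.ndarray | None = None,
    dt: float = 1e-3,
) -> ResponseSeries:
    """Quasi-static deflection series ``delta(t)`` for a beating layer.

    ``p = 0`` gives the plain cantilever.  By default the grid spans one
    full period at 1 ms resolution; pass ``t_grid`` for a custom grid
    (it should cover at least one period for peak analysis to be
    meaningful).
    """
    if t_grid is None:
        n = int(round(waveform.period / dt))
        t_grid = np.linspace(0.0, waveform.period, n + 1)
    t_grid = np.asarray(t_grid, dtype=float)
    sigma = np.asarray(waveform_value(waveform, t_grid), dtype=float)
    # Static deflection is linear in stress: one unit solve scales the series.
    unit = tip_deflection_perforated(
        geometry, substrate, ContractileLoad(film_stress=1.0), p=p, law=law
    ).tip_deflection
    deflections = unit * np.abs(sigma)
    return ResponseSeries(
        times=t_grid,
        deflections=deflections,
        stresses=sigma,
        metadata={
            "geometry": geometry,
            "substrate": substrate,
            "porosity": p,
            "law": law,
            "waveform": waveform,
        },
    )


def peak_times(series: ResponseSeries) -> list[float]:
    """Grid times of the local maxima of the deflection series.

    A grid point counts as a peak when it strictly exceeds its left
    neighbour and is no smaller than its right neighbour, so a plateau of
    equal maxima reports its earliest time.  A constant series has no
    peaks.  Grid endpoints are not candidates.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    d = series.deflections
    peaks = []
    for i in range(1, len(d) - 1):
        if d[i] > d[i - 1] and d[i] >= d[i + 1]:
            peaks.append(float(series.times[i]))
    return peaks
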