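"""Steady-state physical model of a single OECT unit.

An organic electrochemical transistor (OECT) used as an electrochemical
sensor couples two capacitors in series: the gate/electrolyte double layer
(C_G-E) and the volumetric capacitance of the PEDOT:PSS channel
(C_volumetric).  Electro-oxidation of a catecholamine at the platinum gate
(catechol -> quinone, two electrons) injects a Faradaic current that lowers
the potential drop at the gate/electrolyte interface and therefore raises
the effective gate voltage seen by the channel.  For a p-type depletion
device the drain current falls monotonically with gate voltage, so evoked
release appears as a downward drain-current transient.

The per-decade (Nernstian) gate-voltage response scales with
``(1 + gamma) * k*T / (n*q)`` where ``gamma = C_volumetric / C_G-E``; at
sub-micromolar analyte levels the response is instead described by the
empirical power law ``dV_geff = A * C**beta``.

Units: SI throughout (A, V, s, K, F) except where a field name says
otherwise (geometry in µm, capacitance densities in F/cm³ and µF/cm²,
concentrations in nM) — those are the units the quantities are quoted in
experimentally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Union

import numpy as np
from scipy import constants as _const

from .errors import CharacterizationError, DomainError, InvalidParameterError

__all__ = [
    "BOLTZMANN_K",
    "ELEMENTARY_CHARGE_Q",
    "PhysicalConstants",
    "DeviceParams",
    "TransferCurve",
    "CurveSource",
    "CapacitanceSummary",
    "channel_volumetric_capacitance",
    "gate_interface_capacitance",
    "capacitance_ratio",
    "nernstian_shift",
    "powerlaw_shift",
    "transfer_current",
    "transconductance",
    "optimal_operating_point",
]

#: CODATA value of the Boltzmann constant, J/K.
BOLTZMANN_K: float = _const.k
#: CODATA value of the elementary charge, C.
ELEMENTARY_CHARGE_Q: float = _const.e

_UM3_PER_CM3 = 1e-12  # (1 µm = 1e-4 cm)³


@dataclass(frozen=True)
class PhysicalConstants:
    """Fixed physical constants (CODATA); immutable."""

    boltzmann_k: float = BOLTZMANN_K
    elementary_charge_q: float = ELEMENTARY_CHARGE_Q


class CurveSource(str, Enum):
    PARAMETRIC = "parametric"
    MEASURED = "measured"


@dataclass
class DeviceParams:
    """Physical, geometric and transfer-curve parameters of one OECT unit.

    Geometry is in µm, the volumetric capacitance density in F/cm³, the gate
    areal capacitance in µF/cm², the gate area in cm².  ``transfer_imax``,
    ``transfer_v0`` and ``transfer_slope_s`` parameterize the falling-sigmoid
    transfer curve ``I_DS(V_GS) = imax / (1 + exp((V_GS - v0) / s))``.

    Defaults reflect the reference device: channel 40 x 10 x 0.03 µm³ of
    PEDOT:PSS at 39 F/cm³, a 0.08 x 0.06 cm² platinum gate at 10 µF/cm²,
    body temperature, and a two-electron catechol oxidation.  The sigmoid
    scale ``transfer_imax`` is set so that evoked in vivo transients of a
    few tens of mV effective-gate shift produce drain-current deflections of
    order 10 nA against a ~1 nA peak-to-peak noise floor, i.e. the
    signal-to-noise regime reported for in vivo recordings.
    """

    channel_width: float = 40.0  # µm
    channel_length: float = 10.0  # µm
    channel_thickness: float = 0.03  # µm
    volumetric_capacitance_density: float = 39.0  # F/cm³
    gate_area: float = 0.08 * 0.06  # cm²
    gate_areal_capacitance: float = 10.0  # µF/cm²
    temperature_T: float = 310.0  # K (in vivo); use 298.15 for bench work
    electrons_transferred_n: int = 2
    transfer_imax: float = 3.5e-7  # A
    transfer_v0: float = 0.6  # V
    transfer_slope_s: float = 0.15  # V
    v_ds: float = 0.06  # V

    def __post_init__(self) -> None:
        positive = {
            "channel_width": self.channel_width,
            "channel_length": self.channel_length,
            "channel_thickness": self.channel_thickness,
            "volumetric_capacitance_density": self.volumetric_capacitance_density,
            "gate_area": self.gate_area,
            "gate_areal_capacitance": self.gate_areal_capacitance,
            "temperature_T": self.temperature_T,
            "transfer_imax": self.transfer_imax,
            "transfer_slope_s": self.transfer_slope_s,
            "v_ds": self.v_ds,
        }
        for name, value in positive.items():
            if not value > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {value!r}")
        if self.electrons_transferred_n < 1:
            raise InvalidParameterError(
                f"electrons_transferred_n must be >= 1, got {self.electrons_transferred_n!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceParams":
        return cls(**d)

    def capacitance_summary(self) -> "CapacitanceSummary":
        cv = channel_volumetric_capacitance(
            self.volumetric_capacitance_density,
            self.channel_width,
            self.channel_length,
            self.channel_thickness,
        )
        cg = gate_interface_capacitance(self.gate_areal_capacitance, self.gate_area)
        return CapacitanceSummary(cv, cg, capacitance_ratio(cv, cg))


@dataclass
class TransferCurve:
    """A sampled V_GS -> I_DS map at fixed V_DS."""

    v_gs_grid: np.ndarray
    i_ds_values: np.ndarray
    v_ds: float
    source: CurveSource = CurveSource.MEASURED

    def __post_init__(self) -> None:
        self.v_gs_grid = np.asarray(self.v_gs_grid, dtype=float)
        self.i_ds_values = np.asarray(self.i_ds_values, dtype=float)
        self.source = CurveSource(self.source)
        if self.v_gs_grid.shape != self.i_ds_values.shape or self.v_gs_grid.ndim != 1:
            raise InvalidParameterError("v_gs_grid and i_ds_values must be 1-D and equal length")
        if self.v_gs_grid.size and not np.all(np.diff(self.v_gs_grid) > 0):
            raise InvalidParameterError("v_gs_grid must be strictly increasing")
        if np.any(self.i_ds_values < 0):
            raise InvalidParameterError("i_ds_values must be non-negative")
        # p-type depletion: a noise-free parametric curve must fall strictly.
        if self.source is CurveSource.PARAMETRIC and self.v_gs_grid.size > 1:
            if not np.all(np.diff(self.i_ds_values) < 0):
                raise InvalidParameterError("parametric curve must be strictly decreasing")

    def __len__(self) -> int:
        return int(self.v_gs_grid.size)


@dataclass(frozen=True)
class CapacitanceSummary:
    """C_volumetric, C_G-E and their ratio gamma for one device."""

    c_volumetric: float
    c_gate_electrolyte: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.c_volumetric > 0 and self.c_gate_electrolyte > 0):
            raise InvalidParameterError("capacitances must be > 0")


def channel_volumetric_capacitance(
    density: float, width: float, length_: float, thickness: float
) -> float:
    """Channel capacitance in farads from a volumetric density.

    Parameters
    ----------
    density : float
        Volumetric capacitance density in F/cm³.
    width, length_, thickness : float
        Channel dimensions in µm (any may be 0, giving zero volume).

    The reference 39 F/cm³ channel of 40 x 10 x 0.03 µm³ gives 0.468 nF.
    """
    if density <= 0:
        raise InvalidParameterError(f"density must be > 0, got {density!r}")
    for name, v in (("width", width), ("length_", length_), ("thickness", thickness)):
        if v < 0:
            raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")
    volume_cm3 = width * length_ * thickness * _UM3_PER_CM3
    return density * volume_cm3


def gate_interface_capacitance(areal_density: float, area: float) -> float:
    """Gate/electrolyte double-layer capacitance in farads.

    ``areal_density`` in µF/cm², ``area`` in cm².  Note that the plain
    arithmetic for a 10 µF/cm² double layer over 0.08 x 0.06 cm² gives
    48 nF; see the methods note for the discrepancy with the commonly
    quoted 4.8 nF figure for this geometry.
    """
    if areal_density <= 0:
        raise InvalidParameterError(f"areal_density must be > 0, got {areal_density!r}")
    if area < 0:
        raise InvalidParameterError(f"area must be >= 0, got {area!r}")
    return areal_density * 1e-6 * area


def capacitance_ratio(c_volumetric: float, c_gate_electrolyte: float) -> float:
    """gamma = C_volumetric / C_G-E (both in farads, both > 0)."""
    if c_volumetric <= 0 or c_gate_electrolyte <= 0:
        raise InvalidParameterError("capacitances must be > 0")
    return c_volumetric / c_gate_electrolyte


def nernstian_shift(
    c_ratio_decades: float,
    gamma: float,
    T: float = 298.15,
    n: int = 2,
) -> float:
    """Nernstian effective-gate-voltage shift for a concentration change.

    Returns ``ln(10) * (1 + gamma) * k*T / (n*q) * c_ratio_decades`` volts,
    where ``c_ratio_decades = log10(C2/C1)``.  The absolute reference
    concentration is a calibration offset and does not appear; only the
    per-decade change is physical here.  At 298.15 K with gamma = 0 and a
    two-electron reaction the slope is 29.6 mV/decade.
    """
    if T <= 0:
        raise InvalidParameterError(f"T must be > 0, got {T!r}")
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n!r}")
    if gamma < 0:
        raise InvalidParameterError(f"gamma must be >= 0, got {gamma!r}")
    return math.log(10.0) * (1.0 + gamma) * BOLTZMANN_K * T / (n * ELEMENTARY_CHARGE_Q) * c_ratio_decades


def powerlaw_shift(concentration: float, A: float, beta: float) -> float:
    """Empirical low-concentration response ``dV_geff = A * C**beta``.

    ``concentration`` in nM, ``A`` in V·nM^-beta (so A = 2e-3 means
    2 mV·nM^-beta); returns volts.
    """
    if A <= 0 or beta <= 0:
        raise InvalidParameterError("A and beta must be > 0")
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0):
        raise InvalidParameterError("concentration must be >= 0")
    out = A * conc**beta
    return float(out) if np.isscalar(concentration) else out


def transfer_current(v_gs, params: DeviceParams):
    """Falling-sigmoid steady-state transfer curve ``I_DS(V_GS)``.

    ``imax / (1 + exp((v_gs - v0)/s))``: tends to ``imax`` at deeply
    negative gate voltage, to 0 at full depletion, and passes through
    ``imax/2`` at ``v0`` where the transconductance peaks.
    """
    v = np.asarray(v_gs, dtype=float)
    z = (v - params.transfer_v0) / params.transfer_slope_s
    out = params.transfer_imax / (1.0 + np.exp(z))
    return float(out) if np.isscalar(v_gs) else out


def _sampled_gm(curve: TransferCurve) -> np.ndarray:
    """|dI/dV| of a sampled curve by central finite differences."""
    return np.abs(np.gradient(curve.i_ds_values, curve.v_gs_grid))


def transconductance(curve_or_params: Union[TransferCurve, DeviceParams], v_gs):
    """Transconductance g_m = |dI_DS/dV_GS| at ``v_gs`` in siemens.

    Analytic derivative for a parametric device, central finite differences
    (interpolated) for a sampled curve.
    """
    v = np.asarray(v_gs, dtype=float)
    if isinstance(curve_or_params, DeviceParams):
        p = curve_or_params
        z = (v - p.transfer_v0) / p.transfer_slope_s
        ez = np.exp(z)
        out = p.transfer_imax / p.transfer_slope_s * ez / (1.0 + ez) ** 2
    else:
        curve = curve_or_params
        grid = curve.v_gs_grid
        if np.any(v < grid[0]) or np.any(v > grid[-1]):
            raise DomainError(
                f"v_gs outside curve domain [{grid[0]:g}, {grid[-1]:g}] V"
            )
        out = np.interp(v, grid, _sampled_gm(curve))
    return float(out) if np.isscalar(v_gs) else out


def optimal_operating_point(curve: Union[TransferCurve, DeviceParams]) -> float:
    """V_GS maximizing the transconductance (the recording operating point).

    For the parametric sigmoid this is exactly ``transfer_v0``.  For a
    sampled curve the finite-difference g_m is maximized on the grid; ties
    break toward the smaller V_GS.
    """
    if isinstance(curve, DeviceParams):
        return curve.transfer_v0
    if len(curve) < 5:
        raise CharacterizationError("need at least 5 samples to locate the g_m peak")
    i = curve.i_ds_values
    if i[-1] >= i[0] or np.ptp(i) == 0:
        raise CharacterizationError("curve is not overall decreasing; cannot characterize")
    gm = _sampled_gm(curve)
    return float(curve.v_gs_grid[int(np.argmax(gm))])  # argmax -> earliest tie
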