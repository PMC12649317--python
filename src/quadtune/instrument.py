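"""A virtual quadrupole mass spectrometer.

The simulator stands in for a real triple-quadrupole platform during tuning
experiments.  It is an explicit stand-in, not a physical model: the
dependence of peak intensity on the ion-source/ion-optics tuning parameters
(curtain gas CUR, nebulizer gas GS1, de-clustering potential DP, entrance
potential EP) is a Gaussian response surface with a known optimum, optionally
with a rotated covariance between DP and EP so that univariate
parameter-at-a-time search is provably suboptimal.  The mass axis follows a
linear mass-to-DAC table and the peak width (FWHM) a linear
mass-to-OFFSET table, mimicking the near-linear factory calibration curves
of real instruments.  Measurement noise is multiplicative on intensity with
a configurable coefficient of variation; centroid and FWHM readings carry a
proportional additive jitter.  With the CV set to zero the instrument is
fully deterministic.

Intensities are reported as MCA (multiple channel acquisition)
accumulations: the sum of ``mca`` independent single-scan readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParameterDef",
    "TuningParameterSet",
    "PeakMeasurement",
    "VirtualInstrument",
    "gaussian_profile",
    "fwhm_of_profile",
    "export_spectrum",
    "FWHM_FACTOR",
]

#: FWHM of a Gaussian of standard deviation sigma is FWHM_FACTOR * sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ParameterDef:
    name: str
    lower: float
    upper: float

    @property
    def mid(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def span(self) -> float:
        return self.upper - self.lower


@dataclass
class TuningParameterSet:
    """Named tuning-parameter values validated against their bounds."""

    values: dict[str, float]

    def validate(self, defs: Sequence[ParameterDef]) -> None:
        for d in defs:
            if d.name not in self.values:
                raise ValueError(f"missing tuning parameter {d.name!r}")
            v = self.values[d.name]
            if not d.lower <= v <= d.upper:
                raise ValueError(
                    f"parameter {d.name} = {v} outside bounds [{d.lower}, {d.upper}]"
                )

    def as_array(self, defs: Sequence[ParameterDef]) -> np.ndarray:
        return np.array([self.values[d.name] for d in defs])


@dataclass(frozen=True)
class PeakMeasurement:
    centroid: float  # measured peak position, u
    fwhm: float  # full width at half maximum, u
    intensity: float  # MCA-accumulated counts per second
    nominal_mass: float

    @property
    def mass_error(self) -> float:
        return self.centroid - self.nominal_mass


_DEFAULT_PARAMS = (
    ParameterDef("CUR", 5.0, 40.0),
    ParameterDef("GS1", 5.0, 40.0),
    ParameterDef("DP", 50.0, 200.0),
    ParameterDef("EP", 2.0, 15.0),
)

# ground-truth optimum and sensitivity width per parameter (synthetic fixture)
_DEFAULT_OPTIMUM = {"CUR": 20.229, "GS1": 15.573, "DP": 163.03, "EP": 11.413}
_DEFAULT_SIGMA = {"CUR": 6.0, "GS1": 6.0, "DP": 30.0, "EP": 2.5}

#: NaI/CsI calibrant cluster peaks (u) spanning the low/mid/high mass range
DEFAULT_MASSES = (172.88, 622.57, 922.36)
#: single-scan peak maxima (cps); an MCA-5 reading is five times larger
_DEFAULT_IMAX = (5.28e6, 5.22e6, 1.578e6)

_INIT_MASS_ERROR = (0.103, 0.15, 0.25)
_INIT_FWHM = (1.239, 1.313, 1.945)


@dataclass
class VirtualInstrument:
    """Simulated plant with a known intensity optimum and linear axis models.

    Parameters
    ----------
    interaction
        When true (the default for comparative experiments) DP and EP are
        coupled through a rotated Gaussian covariance with correlation
        ``interaction_rho``, so their joint optimum cannot be located by
        optimizing one of them at a time.
    noise_cv
        Coefficient of variation of single-scan intensity noise
        (multiplicative, zero-mean Gaussian, clipped at zero intensity).
        Centroid and FWHM readings jitter with sd = 0.2 * noise_cv (u).
    """

    params: tuple[ParameterDef, ...] = _DEFAULT_PARAMS
    optimum: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_OPTIMUM))
    sigma: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_SIGMA))
    interaction: bool = True
    interaction_pair: tuple[str, str] = ("DP", "EP")
    interaction_rho: float = 0.6
    peak_masses: tuple[float, ...] = DEFAULT_MASSES
    peak_max_intensity: tuple[float, ...] = _DEFAULT_IMAX
    noise_cv: float = 0.06
    mca: int = 5
    # linear factory tables (synthetic): DAC(m) = dac_intercept + dac_slope * m
    dac_slope: float = 35.0  # counts per u
    dac_intercept: float = 500.0
    offset_slope: float = 0.004  # V per u along the factory OFFSET table
    offset_intercept: float = 1.5
    res_slope: float = 0.05  # u of FWHM per V of OFFSET
    fwhm_at_line: float = 0.7
    # weak couplings from tuning parameters into the axis models (u per unit
    # of parameter, relative to the parameter midpoint)
    mass_coupling: dict[str, float] = field(default_factory=lambda: {"DP": 0.0008})
    fwhm_coupling: dict[str, float] = field(default_factory=lambda: {"EP": 0.008})
    init_mass_error: tuple[float, ...] = _INIT_MASS_ERROR
    init_fwhm: tuple[float, ...] = _INIT_FWHM
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        for name in names:
            if not self.params[names.index(name)].lower < self.optimum[name] < self.params[names.index(name)].upper:
                raise ValueError(f"ground-truth optimum of {name} must lie strictly inside bounds")
        self.current_params: dict[str, float] = {p.name: p.mid for p in self.params}
        self.current_dac = [self.dac_true(m) + e * self.dac_slope
                            for m, e in zip(self.peak_masses, self.init_mass_error)]
        self.current_offset = [self.offset_true(m) + (f - self.fwhm_at_line) / self.res_slope
                               for m, f in zip(self.peak_masses, self.init_fwhm)]
        self.measurement_count = 0
        self._rng = np.random.default_rng(self.seed)

    # -- configuration ----------------------------------------------------
    @property
    def n_peaks(self) -> int:
        return len(self.peak_masses)

    @property
    def param_names(self) -> list[str]:
        return [p.name for p in self.params]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.array([p.lower for p in self.params]),
                np.array([p.upper for p in self.params]))

    def dac_true(self, mass: float) -> float:
        """Factory DAC table: the DAC count that centres the peak at ``mass``."""
        return self.dac_intercept + self.dac_slope * mass

    def offset_true(self, mass: float) -> float:
        """Factory OFFSET table: the offset voltage giving the nominal FWHM."""
        return self.offset_intercept + self.offset_slope * mass

    # -- state ------------------------------------------------------------
    def apply_parameters(self, params: Mapping[str, float]) -> None:
        pset = TuningParameterSet(dict(params))
        pset.validate(self.params)
        self.current_params.update({p.name: float(params[p.name]) for p in self.params})

    def apply_settings(self, peak: int, dac: float | None = None,
                       offset: float | None = None) -> None:
        """Set the per-peak DAC and/or OFFSET; other peaks are untouched."""
        if dac is not None:
            if not math.isfinite(dac):
                raise ValueError("DAC setting must be finite")
            self.current_dac[peak] = float(dac)
        if offset is not None:
            if not math.isfinite(offset):
                raise ValueError("OFFSET setting must be finite")
            self.current_offset[peak] = float(offset)

    def get_settings(self, peak: int) -> tuple[float, float]:
        return self.current_dac[peak], self.current_offset[peak]

    # -- physics stand-in -------------------------------------------------
    def _log_response(self, params: Mapping[str, float]) -> float:
        names = self.param_names
        z = {n: (params[n] - self.optimum[n]) / self.sigma[n] for n in names}
        expo = 0.0
        a, b = self.interaction_pair
        coupled = self.interaction and a in z and b in z
        for n in names:
            if coupled and n in (a, b):
                continue
            expo -= 0.5 * z[n] ** 2
        if coupled:
            rho = self.interaction_rho
            expo -= 0.5 * (z[a] ** 2 - 2.0 * rho * z[a] * z[b] + z[b] ** 2) / (1.0 - rho ** 2)
        return expo

    def peak_intensity_response(
        self,
        params: Mapping[str, float],
        peak: int,
        rng: np.random.Generator | None = None,
    ) -> float:
        """Single-scan intensity at ``params`` for one peak (cps, >= 0)."""
        pset = TuningParameterSet(dict(params))
        pset.validate(self.params)
        intensity = self.peak_max_intensity[peak] * math.exp(self._log_response(params))
        if self.noise_cv > 0.0:
            rng = self._rng if rng is None else rng
            intensity *= 1.0 + rng.normal(0.0, self.noise_cv)
        return max(intensity, 0.0)

    def _true_centroid(self, peak: int) -> float:
        mass = self.peak_masses[peak]
        # invert the factory line at the current DAC setting
        centroid = mass + (self.current_dac[peak] - self.dac_true(mass)) / self.dac_slope
        for name, coeff in self.mass_coupling.items():
            pdef = next((p for p in self.params if p.name == name), None)
            if pdef is not None:
                centroid += coeff * (self.current_params[name] - pdef.mid)
        return centroid

    def _true_fwhm(self, peak: int) -> float:
        mass = self.peak_masses[peak]
        fwhm = self.fwhm_at_line + self.res_slope * (
            self.current_offset[peak] - self.offset_true(mass)
        )
        for name, coeff in self.fwhm_coupling.items():
            pdef = next((p for p in self.params if p.name == name), None)
            if pdef is not None:
                fwhm += coeff * (self.current_params[name] - pdef.mid)
        return max(fwhm, 0.05)

    def measure_peak(self, peak: int, rng: np.random.Generator | None = None) -> PeakMeasurement:
        """Acquire one MCA-accumulated measurement of a peak."""
        rng = self._rng if rng is None else rng
        self.measurement_count += 1
        centroid = self._true_centroid(peak)
        fwhm = self._true_fwhm(peak)
        if self.noise_cv > 0.0:
            jitter = 0.2 * self.noise_cv
            centroid += rng.normal(0.0, jitter)
            fwhm = max(fwhm + rng.normal(0.0, jitter), 0.01)
        intensity = sum(
            self.peak_intensity_response(self.current_params, peak, rng)
            for _ in range(self.mca)
        )
        return PeakMeasurement(
            centroid=centroid, fwhm=fwhm, intensity=intensity,
            nominal_mass=self.peak_masses[peak],
        )


def gaussian_profile(mz: np.ndarray, centroid: float, fwhm: float,
                     intensity: float) -> np.ndarray:
    """Render a peak as an area-normalized Gaussian: the profile integrates
    (trapezoid, on a sufficiently wide grid) to ``intensity``."""
    sigma = fwhm / FWHM_FACTOR
    return intensity * np.exp(-0.5 * ((mz - centroid) / sigma) ** 2) / (
        sigma * math.sqrt(2.0 * math.pi)
    )


def fwhm_of_profile(mz: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a single-peak profile, with linear
    interpolation of the half-maximum crossings."""
    y = np.asarray(y, dtype=float)
    mz = np.asarray(mz, dtype=float)
    peak = int(np.argmax(y))
    half = y[peak] / 2.0

    def _cross(lo_side: bool) -> float:
        idx = range(peak, 0, -1) if lo_side else range(peak, len(y) - 1)
        for j in idx:
            k = j - 1 if lo_side else j + 1
            if (y[j] - half) * (y[k] - half) <= 0.0 and y[j] != y[k]:
                t = (half - y[j]) / (y[k] - y[j])
                return mz[j] + t * (mz[k] - mz[j])
        raise ValueError("profile does not cross half maximum on both sides")

    return _cross(False) - _cross(True)


def export_spectrum(path: str, mz: np.ndarray, y: np.ndarray) -> None:
    """Write a spectrum as two-column text (m/z, intensity)."""
    np.savetxt(path, np.column_stack([mz, y]), fmt="%.6f\t%.6e",
               header="mz\tintensity")
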