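"""Iterative linear calibration of the mass axis (DAC) and resolution (OFFSET).

Both loops share one proportional update rule: with e_m the remaining error
(target minus measurement) after m updates,

    setting_m = setting_{m-1} + k * e_{m-1},

iterated until |e_m| <= tolerance (0.1 u for both the mass axis and the
FWHM target of 0.7 u) or a maximum number of iterations.  On a noiseless
linear plant with measurement slope s (measured units per setting unit) the
error contracts geometrically, e_m = (1 - k s) e_{m-1}; a matched
coefficient k = 1/s converges in a single step.

When no coefficient is supplied it is estimated at the start of the loop by
a two-point probe: perturb the setting, re-measure, fit the slope and
invert it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "CalibrationResult",
    "calibrate_linear",
    "calibrate_mass_axis",
    "calibrate_resolution",
    "RESOLUTION_TARGET",
]

#: conventional FWHM target for unit resolution, u
RESOLUTION_TARGET = 0.7
#: termination tolerance for both calibration loops, u
DEFAULT_TOLERANCE = 0.1


@dataclass
class CalibrationModel:
    """Configuration of one calibration loop.

    ``coefficient`` is the proportional gain k (setting units per u of
    error); ``None`` requests a two-point probe estimate at startup.
    """

    target: float | None = None
    coefficient: float | None = None
    tolerance: float = DEFAULT_TOLERANCE
    max_iterations: int = 20
    probe_step: float = 1.0
    averaging: int = 1

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.coefficient == 0:
            raise ValueError("coefficient must be nonzero (or None for auto-probe)")


@dataclass
class CalibrationResult:
    converged: bool
    diverged: bool
    iterations: int
    final_value: float
    final_setting: float
    coefficient: float
    history: list[tuple[float, float, float]] = field(default_factory=list)
    # history rows: (setting, measured, error)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history, columns=["setting", "measured", "error"]
                            ).rename_axis("iteration").reset_index()


def calibrate_linear(
    get_setting: Callable[[], float],
    set_setting: Callable[[float], None],
    measure: Callable[[], float],
    target: float,
    model: CalibrationModel,
) -> CalibrationResult:
    """Generic proportional calibration loop over an opaque plant."""

    def _measure() -> float:
        if model.averaging > 1:
            return float(np.mean([measure() for _ in range(model.averaging)]))
        return measure()

    setting = get_setting()
    measured = _measure()
    error = target - measured
    history = [(setting, measured, error)]

    k = model.coefficient
    if k is None:
        set_setting(setting + model.probe_step)
        probed = _measure()
        set_setting(setting)
        slope = (probed - measured) / model.probe_step
        if slope == 0.0:
            raise ValueError("two-point probe measured zero slope; cannot calibrate")
        k = 1.0 / slope

    if abs(error) <= model.tolerance:
        return CalibrationResult(True, False, 0, measured, setting, k, history)

    grow_streak = 0
    converged = diverged = False
    iterations = 0
    for _ in range(model.max_iterations):
        setting = setting + k * error
        set_setting(setting)
        measured = _measure()
        new_error = target - measured
        iterations += 1
        history.append((setting, measured, new_error))
        if abs(new_error) > abs(error):
            grow_streak += 1
        else:
            grow_streak = 0
        error = new_error
        if abs(error) <= model.tolerance:
            converged = True
            break
        if grow_streak >= 3:
            diverged = True
            break

    return CalibrationResult(converged, diverged, iterations, measured, setting, k, history)


def calibrate_mass_axis(
    instrument,
    peak: int,
    model: CalibrationModel | None = None,
    rng: np.random.Generator | None = None,
) -> CalibrationResult:
    """Steer the peak centroid onto its nominal mass by adjusting the DAC.

    Only the per-peak DAC setting is touched; tuning parameters
    (gases/voltages) are never modified by calibration.
    """
    model = model or CalibrationModel(probe_step=10.0)
    target = model.target if model.target is not None else instrument.peak_masses[peak]
    return calibrate_linear(
        get_setting=lambda: instrument.get_settings(peak)[0],
        set_setting=lambda v: instrument.apply_settings(peak, dac=v),
        measure=lambda: instrument.measure_peak(peak, rng).centroid,
        target=target,
        model=model,
    )


def calibrate_resolution(
    instrument,
    peak: int,
    model: CalibrationModel | None = None,
    rng: np.random.Generator | None = None,
) -> CalibrationResult:
    """Steer the peak FWHM onto the resolution target by adjusting OFFSET."""
    model = model or CalibrationModel(probe_step=4.0)
    target = model.target if model.target is not None else RESOLUTION_TARGET
    return calibrate_linear(
        get_setting=lambda: instrument.get_settings(peak)[1],
        set_setting=lambda v: instrument.apply_settings(peak, offset=v),
        measure=lambda: instrument.measure_peak(peak, rng).fwhm,
        target=target,
        model=model,
    )
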