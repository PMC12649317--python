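"""Automatic tuning orchestration.

Each candidate parameter vector proposed by an optimizer is pushed to the
instrument, the mass axis and resolution are re-calibrated per peak, the
peak intensities are measured, and the multi-objective reciprocal-intensity
fitness

    f(x) = sum_k lambda_k / I_k(x)         (lower is better)

is fed back to the optimizer.  The same evaluation path serves the
parameter-at-a-time univariate-search baseline, so fitness values of the
two methods are directly comparable.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    RESOLUTION_TARGET,
    CalibrationModel,
    CalibrationResult,
    calibrate_mass_axis,
    calibrate_resolution,
)
from .instrument import PeakMeasurement, VirtualInstrument
from .optimizers import OptimizerConfig, Strategy, run

__all__ = [
    "EvaluationSpec",
    "TuningResult",
    "evaluation_function",
    "CandidateEvaluator",
    "univariate_search",
    "autotune",
    "repeatability_report",
]

DEFAULT_WEIGHT = 1.0e6


@dataclass
class EvaluationSpec:
    """Peaks entering the fitness and their reciprocal-intensity weights."""

    peaks: tuple[int, ...] = (0, 1, 2)
    weights: tuple[float, ...] | None = None
    intensity_floor: float = 1.0  # cps; guards the reciprocal at dead peaks

    def __post_init__(self) -> None:
        if len(self.peaks) < 1:
            raise ValueError("at least one peak is required")
        if self.weights is None:
            self.weights = tuple(DEFAULT_WEIGHT for _ in self.peaks)
        if len(self.weights) != len(self.peaks):
            raise ValueError("one weight per peak is required")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        if self.intensity_floor <= 0:
            raise ValueError("intensity floor must be positive")


def evaluation_function(intensities: Sequence[float], spec: EvaluationSpec) -> float:
    """Weighted sum of reciprocal intensities; the single-peak case reduces
    to lambda/I."""
    if len(intensities) != len(spec.peaks):
        raise ValueError(f"expected {len(spec.peaks)} intensities")
    total = 0.0
    for w, i in zip(spec.weights, intensities):
        if i < 0:
            raise ValueError("intensities must be non-negative")
        total += w / max(i, spec.intensity_floor)
    return total


@dataclass
class TuningResult:
    parameters: dict[str, float]
    peaks: list[PeakMeasurement]
    fitness: float
    fitness_history: np.ndarray  # best-so-far, monotone non-increasing
    candidate_evaluations: int
    measurement_count: int
    algorithm: str = ""
    calibration_failures: int = 0

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mass": [p.nominal_mass for p in self.peaks],
                "intensity": [p.intensity for p in self.peaks],
                "fwhm": [p.fwhm for p in self.peaks],
                "mass_error": [p.mass_error for p in self.peaks],
            }
        )


class CandidateEvaluator:
    """Shared evaluation path: apply parameters, calibrate, measure, score.

    ``calibrate_every`` is "candidate" (default: every candidate triggers
    per-peak mass-axis and resolution calibration) or "generation" (economy
    mode: calibrate on the first candidate of each block of N).  Calibration
    coefficients are probed once at startup and then held fixed.
    """

    def __init__(
        self,
        instrument: VirtualInstrument,
        spec: EvaluationSpec,
        rng: np.random.Generator,
        mass_model: CalibrationModel | None = None,
        res_model: CalibrationModel | None = None,
        calibrate_every: str = "candidate",
        generation_size: int = 20,
    ) -> None:
        if calibrate_every not in ("candidate", "generation"):
            raise ValueError("calibrate_every must be 'candidate' or 'generation'")
        self.instrument = instrument
        self.spec = spec
        self.rng = rng
        self.calibrate_every = calibrate_every
        self.generation_size = generation_size
        self.n_candidates = 0
        self.calibration_failures = 0
        self.mass_models = {
            p: dataclasses.replace(mass_model) if mass_model is not None
            else CalibrationModel(probe_step=10.0)
            for p in spec.peaks
        }
        self.res_models = {
            p: dataclasses.replace(res_model) if res_model is not None
            else CalibrationModel(probe_step=4.0)
            for p in spec.peaks
        }

    def _calibrate(self) -> bool:
        ok = True
        for p in self.spec.peaks:
            res_m: CalibrationResult = calibrate_mass_axis(
                self.instrument, p, self.mass_models[p], self.rng
            )
            self.mass_models[p].coefficient = res_m.coefficient  # probe once
            res_r = calibrate_resolution(self.instrument, p, self.res_models[p], self.rng)
            self.res_models[p].coefficient = res_r.coefficient
            ok = ok and res_m.converged and res_r.converged
        return ok

    def measure(self) -> list[PeakMeasurement]:
        return [self.instrument.measure_peak(p, self.rng) for p in self.spec.peaks]

    def __call__(self, params: Mapping[str, float]) -> tuple[float, list[PeakMeasurement]]:
        self.instrument.apply_parameters(params)
        need_cal = (
            self.calibrate_every == "candidate"
            or self.n_candidates % self.generation_size == 0
        )
        self.n_candidates += 1
        if need_cal and not self._calibrate():
            self.calibration_failures += 1
            return math.inf, []
        peaks = self.measure()
        return evaluation_function([m.intensity for m in peaks], self.spec), peaks


def _final_result(
    evaluator: CandidateEvaluator,
    params: dict[str, float],
    history: np.ndarray,
    algorithm: str,
) -> TuningResult:
    """Re-apply the winning parameters, calibrate, and re-measure."""
    evaluator.instrument.apply_parameters(params)
    evaluator._calibrate()
    peaks = evaluator.measure()
    fitness = evaluation_function([m.intensity for m in peaks], evaluator.spec)
    return TuningResult(
        parameters=dict(params),
        peaks=peaks,
        fitness=fitness,
        fitness_history=history,
        candidate_evaluations=evaluator.n_candidates,
        measurement_count=evaluator.instrument.measurement_count,
        algorithm=algorithm,
        calibration_failures=evaluator.calibration_failures,
    )


def univariate_search(
    instrument: VirtualInstrument,
    spec: EvaluationSpec | None = None,
    levels: int = 10,
    order: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
    evaluator: CandidateEvaluator | None = None,
) -> TuningResult:
    """Parameter-at-a-time baseline: one pass over the parameters in
    ``order``, each evaluated on a uniform grid of ``levels`` values
    (endpoints included) with the other parameters held at their current
    values; the best level is locked in before moving on."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    spec = spec or EvaluationSpec(peaks=tuple(range(instrument.n_peaks)))
    rng = rng if rng is not None else np.random.default_rng(0)
    evaluator = evaluator or CandidateEvaluator(instrument, spec, rng)
    defs = {p.name: p for p in instrument.params}
    order = list(order) if order is not None else ["GS1", "CUR", "DP", "EP"]
    order = [n for n in order if n in defs] + [n for n in defs if n not in order]

    current = {p.name: p.mid for p in instrument.params}
    best_so_far: list[float] = []
    for name in order:
        pdef = defs[name]
        grid = np.linspace(pdef.lower, pdef.upper, levels)
        best_level, best_fit = current[name], math.inf
        for level in grid:
            candidate = dict(current)
            candidate[name] = float(level)
            fit, _ = evaluator(candidate)
            best_so_far.append(min(best_so_far[-1], fit) if best_so_far else fit)
            if fit < best_fit:
                best_level, best_fit = float(level), fit
        current[name] = best_level
    return _final_result(evaluator, current, np.array(best_so_far), "univariate")


def autotune(
    instrument: VirtualInstrument,
    config: OptimizerConfig | None = None,
    spec: EvaluationSpec | None = None,
    rng: np.random.Generator | None = None,
    evaluator: CandidateEvaluator | None = None,
    calibrate_every: str = "candidate",
) -> TuningResult:
    """Optimizer-in-the-loop tuning with embedded per-peak calibration.

    Candidate vectors are clipped to the instrument bounds before being
    applied; a candidate whose calibration fails scores +inf and is skipped
    by selection.  The returned result re-measures the winning candidate, so
    every reported peak satisfies both calibration tolerances.
    """
    spec = spec or EvaluationSpec(peaks=tuple(range(instrument.n_peaks)))
    lower, upper = instrument.bounds
    if config is None:
        config = OptimizerConfig(D=len(lower), lower=lower, upper=upper,
                                 strategy=Strategy.DE_IMPROVED)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    evaluator = evaluator or CandidateEvaluator(
        instrument, spec, rng, calibrate_every=calibrate_every,
        generation_size=config.N,
    )
    names = instrument.param_names

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, lower, upper)
        fit, _ = evaluator(dict(zip(names, (float(v) for v in x))))
        return fit

    result = run(objective, config, rng)
    best_params = dict(zip(names, (float(v) for v in np.clip(result.best_x, lower, upper))))
    out = _final_result(evaluator, best_params, result.convergence, config.strategy.value)
    return out


def repeatability_report(results: Sequence[TuningResult]) -> pd.DataFrame:
    """Per-peak repeatability of final intensities across tuning runs.

    CV is the sample standard deviation (n-1) over the mean, in percent.
    """
    if len(results) < 2:
        raise ValueError("at least 2 tuning results are required")
    n_peaks = len(results[0].peaks)
    rows = []
    for p in range(n_peaks):
        intensities = np.array([r.peaks[p].intensity for r in results])
        mean = float(np.mean(intensities))
        if mean == 0.0:
            raise ValueError(f"zero mean intensity for peak {p}")
        rows.append(
            {
                "mass": results[0].peaks[p].nominal_mass,
                "mean_intensity": mean,
                "cv_percent": float(np.std(intensities, ddof=1) / mean * 100.0),
                "n_runs": len(results),
            }
        )
    return pd.DataFrame(rows)
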