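"""Shifted/rotated multimodal test functions and a repeated-trial harness.

Two formula-defined members of the CEC-2017 suite are provided: the shifted
and rotated Rastrigin function (F5) and the shifted and rotated Lunacek
bi-Rastrigin function (F7).  Instances (shift vector, rotation matrix) are
self-generated from a seed rather than loaded from the official data files,
so statistics obtained on them agree with published tables only up to
instance-to-instance variability.

The hybrid and composition functions of the suite (F16, F20, F26, F29) are
defined through external per-instance data and are deliberately rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .optimizers import OptimizerConfig, OptimizationResult, run

__all__ = [
    "BenchmarkFunction",
    "BenchmarkInstance",
    "TrialStats",
    "make_instance",
    "evaluate",
    "evaluate_f5",
    "evaluate_f7",
    "rastrigin",
    "run_trials",
    "SEARCH_LOWER",
    "SEARCH_UPPER",
    "SHRINK",
]

SEARCH_LOWER = -100.0
SEARCH_UPPER = 100.0
#: native Rastrigin domain is [-5.12, 5.12]; the search domain is [-100, 100]
SHRINK = 5.12 / 100.0
#: the Lunacek bi-Rastrigin member of the suite uses a 10/100 domain shrink
SHRINK_F7 = 10.0 / 100.0

_MU0 = 2.5
_D_LUNACEK = 1.0

_UNSUPPORTED = {"F16", "F20", "F26", "F29"}


class BenchmarkFunction(str, Enum):
    F5 = "F5"  # shifted and rotated Rastrigin
    F7 = "F7"  # shifted and rotated Lunacek bi-Rastrigin


_BIAS = {BenchmarkFunction.F5: 500.0, BenchmarkFunction.F7: 700.0}


@dataclass(frozen=True)
class BenchmarkInstance:
    """One concrete test-function instance (shift, rotation, bias)."""

    function: BenchmarkFunction
    dimension: int
    shift: np.ndarray
    rotation: np.ndarray
    bias: float
    lower: float = SEARCH_LOWER
    upper: float = SEARCH_UPPER
    shrink: float = SHRINK
    seed: int = 0

    def __call__(self, x: Sequence[float]) -> float:
        return evaluate(self, x)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        d = self.dimension
        return np.full(d, self.lower), np.full(d, self.upper)


def _coerce_function(function_id: "BenchmarkFunction | str") -> BenchmarkFunction:
    name = str(getattr(function_id, "value", function_id)).upper()
    if name in _UNSUPPORTED:
        raise ValueError(
            f"{name} is a hybrid/composition function whose internals are defined "
            "by external per-instance data; it is out of scope here "
            "(supported: F5, F7)."
        )
    try:
        return BenchmarkFunction(name)
    except ValueError:
        raise ValueError(f"unknown benchmark function {name!r} (supported: F5, F7)") from None


def _random_orthogonal(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random orthogonal matrix from the QR decomposition of a
    standard-normal matrix, sign-fixed for determinism."""
    a = rng.standard_normal((dim, dim))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q


def make_instance(
    function_id: "BenchmarkFunction | str", dimension: int, seed: int
) -> BenchmarkInstance:
    """Deterministically generate a shifted/rotated instance.

    The shift is uniform over the inner 80% of the search domain; the
    rotation is a random orthogonal matrix.
    """
    function = _coerce_function(function_id)
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    fn_tag = 5 if function is BenchmarkFunction.F5 else 7
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, fn_tag]))
    shift = rng.uniform(0.8 * SEARCH_LOWER, 0.8 * SEARCH_UPPER, size=dimension)
    rotation = _random_orthogonal(dimension, rng)
    return BenchmarkInstance(
        function=function,
        dimension=dimension,
        shift=shift,
        rotation=rotation,
        bias=_BIAS[function],
        shrink=SHRINK if function is BenchmarkFunction.F5 else SHRINK_F7,
        seed=int(seed),
    )


def rastrigin(z: np.ndarray) -> float:
    """Base Rastrigin value: sum of z_i^2 - 10 cos(2 pi z_i) + 10."""
    z = np.asarray(z, dtype=float)
    return float(np.sum(z * z - 10.0 * np.cos(2.0 * np.pi * z) + 10.0))


def _check_dim(instance: BenchmarkInstance, x: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (instance.dimension,):
        raise ValueError(
            f"expected a vector of length {instance.dimension}, got shape {x.shape}"
        )
    return x


def evaluate_f5(instance: BenchmarkInstance, x: Sequence[float]) -> float:
    """Shifted and rotated Rastrigin: bias + rastrigin(M (shrink (x - o)))."""
    x = _check_dim(instance, x)
    z = instance.rotation @ (instance.shrink * (x - instance.shift))
    return instance.bias + rastrigin(z)


def evaluate_f7(instance: BenchmarkInstance, x: Sequence[float]) -> float:
    """Shifted and rotated Lunacek bi-Rastrigin.

    Uses the standard constants mu0 = 2.5, d = 1,
    s = 1 - 1/(2 sqrt(D + 20) - 8.2), mu1 = -sqrt((mu0^2 - d)/s).  The
    transformation x_hat = 2 sign(o) y + mu0 (y the shrunken shift-relative
    coordinates) places the global minimum exactly at the shift vector.
    """
    x = _check_dim(instance, x)
    d = instance.dimension
    # the standard scale is positive only for D >= 2; clamp so the D = 1
    # degenerate case stays well-defined with its minimum at the shift
    s = max(1.0 - 1.0 / (2.0 * np.sqrt(d + 20.0) - 8.2), 0.2)
    mu1 = -np.sqrt((_MU0 * _MU0 - _D_LUNACEK) / s)

    y = instance.shrink * (x - instance.shift)
    sign = np.where(instance.shift >= 0.0, 1.0, -1.0)
    x_hat = 2.0 * sign * y + _MU0

    t1 = float(np.sum((x_hat - _MU0) ** 2))
    t2 = _D_LUNACEK * d + s * float(np.sum((x_hat - mu1) ** 2))
    z = instance.rotation @ (x_hat - _MU0)
    cos_term = 10.0 * (d - float(np.sum(np.cos(2.0 * np.pi * z))))
    return instance.bias + min(t1, t2) + cos_term


def evaluate(instance: BenchmarkInstance, x: Sequence[float]) -> float:
    if instance.function is BenchmarkFunction.F5:
        return evaluate_f5(instance, x)
    return evaluate_f7(instance, x)


@dataclass
class TrialStats:
    """Summary of repeated optimizer trials on one benchmark function."""

    algorithm: str
    function: str
    n_trials: int
    best_values: np.ndarray
    convergence_curves: np.ndarray  # (n_trials, G + 1) best-so-far values
    trial_seeds: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def mean(self) -> float:
        return float(np.mean(self.best_values))

    @property
    def std(self) -> float:
        # sample std (ddof=1), the convention for n-trial benchmark tables
        if self.n_trials < 2:
            return 0.0
        return float(np.std(self.best_values, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        """One row per trial: algorithm, function, seed, best value."""
        return pd.DataFrame(
            {
                "algorithm": self.algorithm,
                "function": self.function,
                "trial": np.arange(self.n_trials),
                "seed": self.trial_seeds,
                "best_value": self.best_values,
            }
        )

    def curves_frame(self) -> pd.DataFrame:
        """Long-format convergence curves: trial, generation, best_so_far."""
        n, g1 = self.convergence_curves.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(np.arange(n), g1),
                "generation": np.tile(np.arange(g1), n),
                "best_so_far": self.convergence_curves.ravel(),
            }
        )


InstanceFactory = Callable[[int, int], BenchmarkInstance]


def run_trials(
    function_id: "BenchmarkFunction | str",
    config: OptimizerConfig,
    n_trials: int = 30,
    instance_factory: InstanceFactory | None = None,
    label: str | None = None,
) -> TrialStats:
    """Run ``n_trials`` independent optimizer runs, one fresh instance each.

    Sub-seeds for the per-trial instance and the optimizer RNG are derived
    from ``config.seed``, so a fixed master seed reproduces the statistics
    bit-for-bit.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    function = _coerce_function(function_id)
    if instance_factory is None:
        instance_factory = lambda trial, seed: make_instance(function, config.D, seed)  # noqa: E731

    children = np.random.SeedSequence(config.seed).spawn(n_trials)
    bests = np.empty(n_trials)
    curves = np.empty((n_trials, config.G + 1))
    seeds = np.empty(n_trials, dtype=np.int64)
    for t, child in enumerate(children):
        inst_seed, opt_seed = (int(s) & 0x7FFFFFFF for s in child.generate_state(2))
        seeds[t] = inst_seed
        instance = instance_factory(t, inst_seed)
        lower, upper = instance.bounds
        cfg = dataclasses.replace(
            config, D=instance.dimension, lower=lower, upper=upper, seed=opt_seed
        )
        try:
            result: OptimizationResult = run(instance, cfg)
        except Exception as exc:  # pragma: no cover - propagation path
            raise RuntimeError(f"optimizer failed in trial {t}") from exc
        bests[t] = result.best_fitness
        curves[t] = result.convergence
    return TrialStats(
        algorithm=label or config.strategy.value,
        function=function.value,
        n_trials=n_trials,
        best_values=bests,
        convergence_curves=curves,
        trial_seeds=seeds,
    )
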