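"""Nelder-Mead simplex search over the four decision-tree parameters.

The simplex engine is written out explicitly so that the four scalar moves
(reflection rho=1, expansion chi=2, contraction gamma=0.5, shrinkage
alpha=0.5) are configurable and the full per-iteration trace is available.
The decision-tree objective rounds parameters to integers at evaluation
time (block length clamped to >= 2, triggers to >= 0), keeping the simplex
continuous while honoring epoch-granular parameters, and maximizes epoch
accuracy against the reference labels, pooled over the development set by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dt import DTParams, detect_bedrest
from .metrics import confusion
from .model import ConfigurationError, EpochSeries, LabelSequence

__all__ = [
    "SimplexConfig",
    "OptimizeResult",
    "nelder_mead",
    "default_initial_vertices",
    "objective",
    "optimize_dt_params",
]


@dataclass(frozen=True)
class SimplexConfig:
    rho: float = 1.0  # reflection
    chi: float = 2.0  # expansion
    gamma: float = 0.5  # contraction
    alpha_shrink: float = 0.5  # shrinkage
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if min(self.rho, self.chi, self.gamma, self.alpha_shrink) <= 0:
            raise ConfigurationError("simplex coefficients must be positive")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass
class OptimizeResult:
    best_vertex: np.ndarray
    best_value: float  # minimized objective at the best-ever evaluated point
    trace: list[dict] = field(default_factory=list)


def default_initial_vertices() -> np.ndarray:
    """Shipped 5-vertex starting simplex for the 4 DT parameters.

    A documented spread over (block_length, threshold, start trigger, end
    trigger) spanning the plausible preschool-to-youth activity regimes,
    plus the centroid of the four as the fifth vertex.
    """
    base = np.array(
        [
            [60.0, 400.0, 500.0, 1500.0],
            [24.0, 150.0, 200.0, 800.0],
            [48.0, 300.0, 600.0, 2000.0],
            [12.0, 100.0, 400.0, 600.0],
        ]
    )
    return np.vstack([base, base.mean(axis=0)])


def nelder_mead(
    f,
    initial_vertices: np.ndarray,
    config: SimplexConfig = SimplexConfig(),
) -> OptimizeResult:
    """Minimize ``f`` with the Nelder-Mead simplex method.

    ``initial_vertices`` must be an (n+1, n) array.  Ties in the vertex
    ordering are broken toward the lexicographically smaller vertex so the
    search is fully deterministic.  The returned best vertex/value is the
    best point *ever evaluated*, and the trace records, per iteration, the
    current best vertex and the running best-so-far value (non-decreasing
    in quality by construction).
    """
    vertices = np.array(initial_vertices, dtype=float)
    n_vert, dim = vertices.shape
    if n_vert != dim + 1:
        raise ConfigurationError(
            f"need {dim + 1} vertices for a {dim}-dimensional simplex, got {n_vert}"
        )
    best_ever_x: np.ndarray | None = None
    best_ever_f = np.inf

    def evaluate(x: np.ndarray) -> float:
        nonlocal best_ever_x, best_ever_f
        v = float(f(x))
        if v < best_ever_f or (
            v == best_ever_f and best_ever_x is not None and tuple(x) < tuple(best_ever_x)
        ):
            best_ever_f, best_ever_x = v, x.copy()
        return v

    values = np.array([evaluate(v) for v in vertices])

    def order() -> None:
        nonlocal vertices, values
        keys = [(values[i], tuple(vertices[i])) for i in range(n_vert)]
        idx = sorted(range(n_vert), key=lambda i: keys[i])
        vertices, values = vertices[idx], values[idx]

    trace: list[dict] = []
    for iteration in range(config.max_iterations):
        order()
        centroid = vertices[:-1].mean(axis=0)
        worst = vertices[-1]
        xr = centroid + config.rho * (centroid - worst)
        fr = evaluate(xr)
        if fr < values[0]:
            xe = centroid + config.chi * (xr - centroid)
            fe = evaluate(xe)
            if fe < fr:
                vertices[-1], values[-1] = xe, fe
            else:
                vertices[-1], values[-1] = xr, fr
        elif fr < values[-2]:
            vertices[-1], values[-1] = xr, fr
        else:
            if fr < values[-1]:  # outside contraction
                xc = centroid + config.gamma * (xr - centroid)
                fc = evaluate(xc)
                accept = fc <= fr
            else:  # inside contraction
                xc = centroid - config.gamma * (centroid - worst)
                fc = evaluate(xc)
                accept = fc < values[-1]
            if accept:
                vertices[-1], values[-1] = xc, fc
            else:  # shrink toward the best vertex
                for i in range(1, n_vert):
                    vertices[i] = vertices[0] + config.alpha_shrink * (
                        vertices[i] - vertices[0]
                    )
                    values[i] = evaluate(vertices[i])
        trace.append(
            {
                "iteration": iteration,
                "best_value": float(min(values)),
                "best_so_far": float(best_ever_f),
                "best_vertex": vertices[int(np.argmin(values))].copy(),
            }
        )
    order()
    return OptimizeResult(best_vertex=best_ever_x, best_value=best_ever_f, trace=trace)


def _round_params(x: np.ndarray, min_bedrest_min: int) -> DTParams:
    return DTParams(
        block_length=max(2, int(round(x[0]))),
        threshold=max(0.0, float(round(x[1]))),
        bedrest_start_trigger=max(0.0, float(round(x[2]))),
        bedrest_end_trigger=max(0.0, float(round(x[3]))),
        min_bedrest_min=min_bedrest_min,
    )


def objective(
    params: DTParams,
    dataset: list[tuple[EpochSeries, LabelSequence]],
    mode: str = "pooled",
    signal: str = "vm",
) -> float:
    """Epoch accuracy of the decision tree against reference labels.

    ``pooled`` accumulates the confusion counts over every recording (each
    epoch weighs equally); ``per_recording_mean`` averages per-recording
    accuracies.  Non-wear/excluded epochs in the reference are skipped.
    """
    if not dataset:
        raise ConfigurationError("dataset must be non-empty")
    if mode not in ("pooled", "per_recording_mean"):
        raise ConfigurationError(f"unknown objective mode {mode!r}")
    tp = tn = fp = fn = 0
    accs = []
    for series, reference in dataset:
        labels, _ = detect_bedrest(series, params, nonwear=reference, signal=signal)
        c = confusion(labels, reference)
        tp, tn, fp, fn = tp + c.tp, tn + c.tn, fp + c.fp, fn + c.fn
        accs.append((c.tp + c.tn) / c.total)
    if mode == "pooled":
        return (tp + tn) / (tp + tn + fp + fn)
    return float(np.mean(accs))


def optimize_dt_params(
    dataset: list[tuple[EpochSeries, LabelSequence]],
    config: SimplexConfig = SimplexConfig(),
    initial_vertices: np.ndarray | None = None,
    mode: str = "pooled",
    signal: str = "vm",
    min_bedrest_min: int = 30,
) -> tuple[DTParams, OptimizeResult]:
    """Maximize decision-tree accuracy on a development set.

    Returns the best-ever evaluated parameter vector (rounded to the
    integer grid actually evaluated) together with the full iteration
    trace.  Deterministic given the inputs.
    """
    if initial_vertices is None:
        initial_vertices = default_initial_vertices()
    vertices = np.asarray(initial_vertices, dtype=float)
    if vertices.shape != (5, 4):
        raise ConfigurationError("DT optimization needs 5 initial vertices of dimension 4")

    cache: dict[tuple, float] = {}

    def neg_accuracy(x: np.ndarray) -> float:
        p = _round_params(x, min_bedrest_min)
        key = (p.block_length, p.threshold, p.bedrest_start_trigger, p.bedrest_end_trigger)
        if key not in cache:
            cache[key] = -objective(p, dataset, mode=mode, signal=signal)
        return cache[key]

    result = nelder_mead(neg_accuracy, vertices, config)
    best = _round_params(result.best_vertex, min_bedrest_min)
    return best, result
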