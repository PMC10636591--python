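"""Restricted cubic spline (natural spline) bases in the truncated-power form.

A restricted cubic spline with K knots is a piecewise cubic, continuous in
value, first and second derivative, and constrained to be *linear* beyond the
boundary knots. It contributes K - 1 degrees of freedom: one linear column
plus K - 2 restricted cubic columns. Knots default to Harrell's percentile
placements. Nonlinear columns are normalised by the squared boundary-knot
span for numerical conditioning; fits are invariant to this affine scaling.

The same basis serves covariate transforms and the log-time baseline of the
flexible parametric survival model, where the analytic derivative with
respect to log time enters the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Harrell's default knot percentiles, keyed by spline degrees of freedom.
HARRELL_PERCENTILES: dict[int, tuple[float, ...]] = {
    2: (10.0, 50.0, 90.0),
    3: (5.0, 35.0, 65.0, 95.0),
    4: (5.0, 27.5, 50.0, 72.5, 95.0),
}


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations of a restricted cubic spline; df = len(knots) - 1."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(k) for k in self.knots)
        object.__setattr__(self, "knots", knots)
        if len(knots) < 3:
            raise ValueError(f"restricted cubic spline needs >=3 knots, got {len(knots)}")
        if not all(np.isfinite(knots)):
            raise ValueError("knots must be finite")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing, got {knots}")

    @property
    def df(self) -> int:
        return len(self.knots) - 1


def default_knots(x: np.ndarray, df: int) -> SplineSpec:
    """Place knots at Harrell's default percentiles of ``x`` for the given df.

    Quantiles use linear interpolation between order statistics. Raises if the
    data cannot support distinct knots (advice: use fewer df).
    """
    if df not in HARRELL_PERCENTILES:
        raise ValueError(f"df must be one of {sorted(HARRELL_PERCENTILES)}, got {df}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < df + 1:
        raise ValueError("not enough observations to place knots")
    knots = np.percentile(x, HARRELL_PERCENTILES[df], method="linear")
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"duplicate knots {knots.tolist()} at df={df}; too few distinct values - use fewer df"
        )
    return SplineSpec(tuple(knots))


def _check_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return x


def rcs_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic basis: columns [x, f_1(x), ..., f_{K-2}(x)].

    f_j is the restricted truncated-power term anchored at internal/boundary
    knot j, scaled by 1/(k_K - k_1)^2 so all columns share the scale of x.
    The implied spline is linear for x outside the boundary knots.
    """
    x = _check_x(x)
    k = np.asarray(spec.knots)
    K = len(k)
    out = np.empty((x.size, K - 1), dtype=float)
    out[:, 0] = x
    norm = (k[-1] - k[0]) ** 2
    for j in range(K - 2):
        lam = (k[-1] - k[j]) / (k[-1] - k[-2])
        mu = (k[-2] - k[j]) / (k[-1] - k[-2])
        out[:, j + 1] = (
            np.maximum(x - k[j], 0.0) ** 3
            - lam * np.maximum(x - k[-2], 0.0) ** 3
            + mu * np.maximum(x - k[-1], 0.0) ** 3
        ) / norm
    return out


def rcs_derivative(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Analytic d/dx of :func:`rcs_basis`, column for column."""
    x = _check_x(x)
    k = np.asarray(spec.knots)
    K = len(k)
    out = np.empty((x.size, K - 1), dtype=float)
    out[:, 0] = 1.0
    norm = (k[-1] - k[0]) ** 2
    for j in range(K - 2):
        lam = (k[-1] - k[j]) / (k[-1] - k[-2])
        mu = (k[-2] - k[j]) / (k[-1] - k[-2])
        out[:, j + 1] = (
            3.0 * np.maximum(x - k[j], 0.0) ** 2
            - 3.0 * lam * np.maximum(x - k[-2], 0.0) ** 2
            + 3.0 * mu * np.maximum(x - k[-1], 0.0) ** 2
        ) / norm
    return out


def time_basis(
    log_t: np.ndarray, spec: SplineSpec | None
) -> tuple[np.ndarray, np.ndarray]:
    """Spline basis of log time and its analytic derivative d/d(log t).

    ``spec=None`` denotes the 1-df (Weibull) case: basis ``[log t]`` with
    constant unit derivative. Knots are expected on the log-time scale.
    """
    log_t = _check_x(log_t)
    if spec is None:
        return log_t[:, None].copy(), np.ones((log_t.size, 1))
    return rcs_basis(log_t, spec), rcs_derivative(log_t, spec)


def time_knots_from_events(time: np.ndarray, event: np.ndarray, df: int) -> SplineSpec | None:
    """Baseline-hazard knots: boundary at min/max uncensored log event times,
    internal knots at event-time quantiles. ``df=1`` returns None (Weibull)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if np.any(time <= 0):
        raise ValueError("event/censoring times must be > 0")
    if df == 1:
        return None
    lt = np.log(time[event == 1])
    if lt.size < df + 1:
        raise ValueError("too few events for requested baseline df")
    internal = np.percentile(lt, np.linspace(0, 100, df + 1)[1:-1], method="linear")
    knots = np.concatenate([[lt.min()], internal, [lt.max()]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate event-time distribution: duplicate baseline knots")
    return SplineSpec(tuple(knots))
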