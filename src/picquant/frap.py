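"""FRAP recovery-curve normalization and single-exponential fitting.

Raw bleached/reference/background traces are double-normalized (after
background subtraction the bleached trace is divided by the reference and
both are scaled by their pre-bleach means) and then full-scale transformed
so the first post-bleach point maps to 0 and the pre-bleach plateau to 1.
The normalized recovery is fitted with

    I(t) = I0 - a * exp(-beta * t)

where ``I0`` is the mobile fraction and ``beta`` the recovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, FitError, ParameterError
from .morph import GroupSummary, summarize


@dataclass
class FrapTrace:
    """Recovery time series; bleach at t = 0, pre-bleach points at t < 0.

    ``reference`` and ``background`` may be None for traces that are
    already normalized (generator bypass / external normalization)."""

    t_s: np.ndarray
    bleached: np.ndarray
    reference: np.ndarray | None = None
    background: np.ndarray | None = None
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        if np.any(np.diff(self.t_s) <= 0):
            raise ParameterError("time grid must be strictly increasing")
        for name in ("reference", "background", "normalized"):
            value = getattr(self, name)
            if value is not None:
                value = np.asarray(value, dtype=float)
                if value.shape != self.t_s.shape:
                    raise ParameterError(f"{name} must be aligned with t")
                setattr(self, name, value)


@dataclass
class FrapFit:
    """Fitted recovery parameters with covariance and diagnostics."""

    I0: float
    a: float
    beta: float
    covariance: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        return np.sqrt(np.diag(self.covariance))


def normalize_fullscale(trace: FrapTrace) -> FrapTrace:
    """Background subtraction, double normalization, full-scale transform.

    Requires pre-bleach (t < 0) and post-bleach (t >= 0) points.  The
    transform is idempotent: renormalizing the output is a no-op.
    """
    pre = trace.t_s < 0
    post = trace.t_s >= 0
    if not pre.any():
        raise DataError("no pre-bleach (t < 0) points for normalization")
    if not post.any():
        raise DataError("no post-bleach (t >= 0) points")

    bleached = trace.bleached.astype(float)
    if trace.background is not None:
        bleached = bleached - trace.background
    if trace.reference is not None:
        reference = trace.reference.astype(float)
        if trace.background is not None:
            reference = reference - trace.background
        if np.any(reference <= 0):
            raise DataError("reference signal non-positive after background subtraction")
        ratio = bleached / reference
    else:
        ratio = bleached

    pre_mean = ratio[pre].mean()
    if pre_mean <= 0:
        raise DataError("non-positive pre-bleach plateau")
    double_norm = ratio / pre_mean  # pre-bleach plateau -> 1
    first_post = double_norm[np.flatnonzero(post)[0]]
    if first_post >= 1.0:
        raise DataError("no bleach depth: first post-bleach point at/above plateau")
    fullscale = (double_norm - first_post) / (1.0 - first_post)
    return FrapTrace(
        t_s=trace.t_s.copy(),
        bleached=trace.bleached.copy(),
        reference=None if trace.reference is None else trace.reference.copy(),
        background=None if trace.background is None else trace.background.copy(),
        normalized=fullscale,
    )


def _recovery_model(t, i0, a, beta):
    return i0 - a * np.exp(-beta * t)


def fit_recovery(
    trace: FrapTrace,
    flat_amplitude_tol: float = 1e-6,
) -> FrapFit:
    """Nonlinear least-squares fit of I0 - a exp(-beta t) on t >= 0 points.

    Initialization: I0 from the last-decile mean, a from the bleach depth,
    beta from the time to half recovery.  Bounds keep the estimates in the
    physically meaningful region (0 <= I0 <= 1.2, a >= 0, beta > 0).  A
    flat trace (a ~ 0) leaves beta unidentifiable and is flagged instead of
    fitted.
    """
    y_all = trace.normalized if trace.normalized is not None else trace.bleached
    post = trace.t_s >= 0
    t = trace.t_s[post]
    y = np.asarray(y_all, dtype=float)[post]
    if t.size < 5:
        raise ParameterError("need at least 5 post-bleach points")

    n_tail = max(1, t.size // 10)
    i0_init = float(y[-n_tail:].mean())
    a_init = i0_init - float(y[0])
    if abs(a_init) < flat_amplitude_tol and np.ptp(y) < flat_amplitude_tol:
        return FrapFit(I0=float(y.mean()), a=0.0, beta=np.nan,
                       flags=["beta_unidentifiable_flat_trace"])
    a_init = max(a_init, 1e-6)
    half_level = y[0] + 0.5 * a_init
    above = np.flatnonzero(y >= half_level)
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] / 2 or 1.0)
    beta_init = 1.0 / t_half

    bounds = ([0.0, 0.0, 1e-12], [1.2, np.inf, np.inf])
    p0 = [min(max(i0_init, 0.0), 1.2), a_init, beta_init]
    try:
        popt, pcov = curve_fit(
            _recovery_model, t, y, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"recovery fit did not converge: {exc}") from exc
    flags = []
    if popt[0] >= 1.2 - 1e-9:
        flags.append("I0_at_bound")
    if popt[2] <= 1e-9:
        flags.append("beta_at_bound")
    if t[-1] < 2.0 / popt[2]:
        flags.append("short_time_window")
    return FrapFit(I0=float(popt[0]), a=float(popt[1]), beta=float(popt[2]),
                   covariance=pcov, flags=flags)


def mobile_fraction_compare(
    fits_a: list[FrapFit],
    fits_b: list[FrapFit],
    labels: tuple[str, str] = ("A", "B"),
) -> GroupSummary:
    """Boxplot summary + significance of mobile fractions of two groups."""
    return summarize(
        {labels[0]: [f.I0 for f in fits_a], labels[1]: [f.I0 for f in fits_b]}
    )
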