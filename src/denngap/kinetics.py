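"""Quantitative GAP and GEF kinetics from fluorescence time courses.

GTP hydrolysis stimulated by a GAP is followed in real time through a
fluorescence signal (native tryptophan fluorescence for Arf-family
substrates, mantGDP for exchange assays).  Under pseudo-first-order
conditions the trace decays as a single exponential

    F(t) = F_inf + (F_0 − F_inf) · exp(−k_obs · t)

and the observed rate constant k_obs (the assay's k_GAP, s⁻¹) divided
by the GAP concentration gives the second-order GAP rate in M⁻¹s⁻¹.
Endpoint (malachite-green) assays quantify released phosphate against
a linear absorbance standard curve; GEF activity is judged as a fold
change of the exchange rate over the intrinsic (buffer-only) rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

K_BOUNDS = (1e-6, 10.0)  # s^-1, search bounds for the observed rate


class TraceError(ValueError):
    """Raised for degenerate traces or failed fits."""


@dataclass(frozen=True)
class FluorescenceTrace:
    """A fluorescence time course; times in s, values in arbitrary units."""

    times: np.ndarray
    values: np.ndarray
    gap_conc: float | None = None  # molar
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size < 8:
            raise TraceError(f"trace {self.label!r}: need at least 8 samples")
        if t.size != v.size:
            raise TraceError("times and values differ in length")
        if not np.all(np.diff(t) > 0):
            raise TraceError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise TraceError("non-finite trace data")


@dataclass(frozen=True)
class ExponentialFit:
    f0: float
    f_inf: float
    k_obs: float
    rmse: float
    converged: bool

    @property
    def span(self) -> float:
        return self.f0 - self.f_inf


@dataclass(frozen=True)
class GapRate:
    rate: float          # M^-1 s^-1
    gap_conc: float      # M
    k_obs: float         # s^-1
    condition_id: str

    @property
    def rate_1e4(self) -> float:
        """The rate in the display unit ×10⁴ M⁻¹s⁻¹."""
        return self.rate / 1e4


@dataclass(frozen=True)
class StandardCurve:
    slope: float      # absorbance per uM
    intercept: float  # absorbance
    r_squared: float


@dataclass(frozen=True)
class EndpointResult:
    p_enzyme: float       # uM
    p_mock: float         # uM
    reaction_time: float  # min
    activity: float       # uM / min
    negative: bool


@dataclass(frozen=True)
class GefAssessment:
    k_intrinsic: float
    k_with_gef: float
    fold: float
    detectable: bool


def _tail(values: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    n = max(2, int(round(values.size * fraction)))
    return values[-n:]


def normalize_trace(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Span-normalise a trace to start near 1 and decay toward 0.

    F_0 is estimated from the first sample and F_inf from the mean of
    the final 10 % of samples.  A trace whose span does not exceed five
    tail standard deviations is considered degenerate.
    """
    tail = _tail(trace.values)
    f_inf_est = float(tail.mean())
    f0_est = float(trace.values[0])
    span = f0_est - f_inf_est
    noise = float(tail.std(ddof=1))
    if abs(span) < 5.0 * noise or span == 0.0:
        raise TraceError(
            f"trace {trace.label!r}: span {span:.3g} below noise floor "
            f"(5 x tail sd = {5 * noise:.3g})"
        )
    return replace(trace, values=(trace.values - f_inf_est) / span)


def _initial_guess(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    f0 = float(v[0])
    f_inf = float(_tail(v).mean())
    mid = f_inf + 0.5 * (f0 - f_inf)
    crossing = np.nonzero((v - mid) * np.sign(f0 - f_inf) <= 0)[0]
    if crossing.size and t[crossing[0]] > 0:
        k0 = float(np.log(2.0) / t[crossing[0]])
    else:
        k0 = 1.0 / max(t[-1], 1e-6)
    k0 = float(np.clip(k0, *K_BOUNDS))
    return f0, f_inf, k0


def fit_single_exponential(trace: FluorescenceTrace) -> ExponentialFit:
    """Nonlinear least-squares fit of a single-exponential decay.

    Initialisation uses the first sample (F_0), the tail mean (F_inf)
    and a half-life read off the midpoint crossing; k_obs is bounded to
    (1e-6, 10) s⁻¹.  A rising trace is fit with negative span and
    flagged in the log rather than rejected.
    """
    t, v = trace.times, trace.values
    f0_0, f_inf_0, k0 = _initial_guess(t, v)
    if f0_0 - f_inf_0 < 0:
        logger.warning("trace %r increases over time; fitting negative span", trace.label)
    tail_sd = float(_tail(v).std(ddof=1))
    if abs(f0_0 - f_inf_0) < 5.0 * tail_sd or f0_0 == f_inf_0:
        raise TraceError(f"trace {trace.label!r} is degenerate (flat)")

    def model(tt, f_inf, span, k):
        return f_inf + span * np.exp(-k * tt)

    lo = [-np.inf, -np.inf, K_BOUNDS[0]]
    hi = [np.inf, np.inf, K_BOUNDS[1]]
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            v,
            p0=[f_inf_0, f0_0 - f_inf_0, k0],
            bounds=(lo, hi),
            maxfev=20000,
        )
        converged = True
    except RuntimeError as exc:
        raise TraceError(
            f"exponential fit failed for trace {trace.label!r}: {exc}"
        ) from exc
    f_inf, span, k = map(float, popt)
    resid = v - model(t, f_inf, span, k)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return ExponentialFit(
        f0=f_inf + span, f_inf=f_inf, k_obs=k, rmse=rmse, converged=converged
    )


def gap_rate(fit: ExponentialFit, gap_conc: float, condition_id: str = "") -> GapRate:
    """Second-order GAP rate: k_obs divided by the GAP concentration (M)."""
    if gap_conc is None or gap_conc <= 0:
        raise ValueError(f"gap_conc must be positive, got {gap_conc}")
    if not fit.converged:
        raise TraceError("cannot derive a rate from an unconverged fit")
    return GapRate(
        rate=fit.k_obs / gap_conc,
        gap_conc=gap_conc,
        k_obs=fit.k_obs,
        condition_id=condition_id,
    )


def fit_standard_curve(
    known_concs: np.ndarray, absorbances: np.ndarray
) -> StandardCurve:
    """Ordinary least-squares phosphate standard curve (A = m·C + b)."""
    c = np.asarray(known_concs, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size < 3:
        raise ValueError("need at least 3 phosphate standards")
    if np.unique(c).size < 2:
        raise ValueError("standard concentrations are all equal; singular design")
    res = stats.linregress(c, a)
    if res.slope == 0:
        raise ValueError("standard curve has zero slope")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def invert_standard_curve(curve: StandardCurve, absorbance: float) -> float:
    """Phosphate concentration (μM) for a measured absorbance."""
    return (absorbance - curve.intercept) / curve.slope


def endpoint_activity(
    p_enzyme: float, p_mock: float, reaction_time: float = 5.0
) -> EndpointResult:
    """Endpoint activity (μM·min⁻¹) = (P_enzyme − P_mock) / time.

    Negative activities (mock above enzyme) are reported and flagged,
    not rejected.
    """
    if reaction_time <= 0:
        raise ValueError(f"reaction_time must be positive, got {reaction_time}")
    activity = (p_enzyme - p_mock) / reaction_time
    if activity < 0:
        logger.warning(
            "negative endpoint activity %.4g uM/min (enzyme %.4g < mock %.4g)",
            activity, p_enzyme, p_mock,
        )
    return EndpointResult(
        p_enzyme=p_enzyme,
        p_mock=p_mock,
        reaction_time=reaction_time,
        activity=activity,
        negative=activity < 0,
    )


def assess_gef(
    intrinsic_trace: FluorescenceTrace,
    gef_trace: FluorescenceTrace,
    detection_fold: float = 2.0,
) -> GefAssessment:
    """Compare nucleotide exchange with and without a candidate GEF.

    Both traces are fit as single exponentials; the assessment reports
    the fold change k_with_gef / k_intrinsic and whether it reaches the
    detection threshold.
    """
    k_int = fit_single_exponential(intrinsic_trace).k_obs
    k_gef = fit_single_exponential(gef_trace).k_obs
    fold = k_gef / k_int
    return GefAssessment(
        k_intrinsic=k_int,
        k_with_gef=k_gef,
        fold=fold,
        detectable=fold >= detection_fold,
    )
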