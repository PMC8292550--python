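"""Global nonlinear fitting of a referenced concentration series.

All curves in a series share one set of kinetic parameters
(k_on, k_off, Rmax and, for the two-compartment model, k_t); each curve
additionally carries a local bulk-offset nuisance parameter, since residual
refractive-index jumps routinely survive double referencing.

Kinetic parameters are optimized in log10 space inside physically plausible
bounds with a trust-region least-squares minimizer, multi-started from
log-spaced k_on initializations to guard against local minima.  Standard
errors come from the Jacobian at the solution.  Residuals are screened for
systematic divergence from the model with a Wald-Wolfowitz runs test and the
lag-1 autocorrelation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from ._fastmodel import fast_two_compartment
from .errors import (
    DegenerateDataWarning,
    FitError,
    IdentifiabilityWarning,
    InvalidParameterError,
)
from .kinetics import RateConstants, Sensorgram, kd_from_rates, langmuir_response
from .referencing import ReferencedSeries

__all__ = [
    "GlobalFitResult",
    "ReplicateSummary",
    "fit_global",
    "residual_diagnostics",
    "aggregate_replicates",
    "concentration_independence_check",
    "runs_test_z",
    "lag1_autocorrelation",
]

# physically plausible biosensor ranges; fits are constrained inside these
BOUNDS = {
    "k_on": (1e2, 1e8),    # 1/(M*s)
    "k_off": (1e-6, 1.0),  # 1/s
    "r_max": (1e-2, 1e6),  # RU
    "k_t": (1e6, 1e13),    # RU/(M*s)
}

#: flag thresholds for "systematic divergence" of residuals
RUNS_Z_THRESHOLD = 3.0
LAG1_THRESHOLD = 0.5


@dataclass
class CurveDiagnostics:
    runs_test_z: float
    lag1_autocorr: float
    flagged: bool
    degenerate: bool = False
    skipped: bool = False


@dataclass
class GlobalFitResult:
    """Converged global fit: shared kinetics plus per-curve nuisance terms."""

    params: RateConstants
    per_curve_offsets: np.ndarray
    k_d: float
    param_sd: dict[str, float]
    chi2: float
    residuals: list[np.ndarray]
    diagnostics: list[CurveDiagnostics] = field(default_factory=list)
    model: str = "two_compartment"
    concentrations: tuple[float, ...] = ()
    n_points: int = 0
    at_bounds: tuple[str, ...] = ()
    cov_log10: np.ndarray | None = None
    n_starts_used: int = 1

    def __post_init__(self):
        assert self.chi2 >= 0
        expected = kd_from_rates(self.params.k_on, self.params.k_off)
        assert math.isclose(self.k_d, expected, rel_tol=1e-12)


@dataclass
class ReplicateSummary:
    """Mean and sample SD of kinetic parameters over independent series."""

    n: int
    k_on_mean: float
    k_off_mean: float
    k_d_mean: float
    k_on_sd: float | None
    k_off_sd: float | None
    k_d_sd: float | None

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "k_on_mean": self.k_on_mean,
            "k_off_mean": self.k_off_mean,
            "k_d_mean": self.k_d_mean,
            "k_on_sd": self.k_on_sd,
            "k_off_sd": self.k_off_sd,
            "k_d_sd": self.k_d_sd,
        }


# ---------------------------------------------------------------------------
# model evaluation


def _model_trace(
    theta_log: np.ndarray, curve: Sensorgram, t_assoc: float, model: str
) -> np.ndarray:
    k_on, k_off, r_max = 10.0 ** theta_log[:3]
    if model == "two_compartment":
        k_t = 10.0 ** theta_log[3]
        return fast_two_compartment(
            curve.time, k_on, k_off, r_max, k_t, curve.concentration, t_assoc
        )
    # closed-form Langmuir path
    from .kinetics import InjectionSchedule

    sched = InjectionSchedule(
        t_assoc=t_assoc,
        t_dissoc=max(float(curve.time[-1]) - t_assoc, 0.0),
        concentration=curve.concentration,
        dt=1.0,
    )
    params = RateConstants(k_on=k_on, k_off=k_off, r_max=r_max)
    return langmuir_response(curve.time, params, sched)


def _n_kin(model: str) -> int:
    return 4 if model == "two_compartment" else 3


def _residual_vector(
    x: np.ndarray, curves: list[Sensorgram], t_assoc: float, model: str
) -> np.ndarray:
    nk = _n_kin(model)
    theta_log, offsets = x[:nk], x[nk:]
    res = [
        _model_trace(theta_log, c, t_assoc, model) + off - c.response
        for c, off in zip(curves, offsets)
    ]
    return np.concatenate(res)


# ---------------------------------------------------------------------------
# initialization


def _estimate_koff(curve: Sensorgram, t_assoc: float) -> float | None:
    """Tail mono-exponential estimate of k_off from the dissociation phase."""
    mask = curve.time > t_assoc
    if mask.sum() < 10:
        return None
    t = curve.time[mask]
    r = curve.response[mask]
    r0 = r[: max(3, len(r) // 20)].mean()
    if r0 <= 0:
        return None
    keep = r > 0.05 * r0
    if keep.sum() < 10:
        return None
    with np.errstate(invalid="ignore"):
        fit = linregress(t[keep], np.log(r[keep]))
    k = -fit.slope
    return float(k) if np.isfinite(k) and k > 0 else None


def _estimate_kobs(curve: Sensorgram, t_assoc: float) -> float | None:
    """Observed association rate from the linearized early association phase.

    Uses d/dt log(Req - R) = -k_obs with Req approximated by the response at
    the end of association (biased low for non-equilibrated curves, good
    enough as an initializer).
    """
    mask = (curve.time >= 0) & (curve.time <= t_assoc)
    t = curve.time[mask]
    r = curve.response[mask]
    if len(r) < 10:
        return None
    r_eq = r[-max(3, len(r) // 20):].mean() * 1.05
    if r_eq <= 0:
        return None
    y = r_eq - r
    keep = y > 0.05 * r_eq
    if keep.sum() < 10:
        return None
    fit = linregress(t[keep], np.log(y[keep]))
    k = -fit.slope
    return float(k) if np.isfinite(k) and k > 0 else None


def auto_initialize(curves: list[Sensorgram], t_assoc: float) -> RateConstants:
    """Heuristic starting parameters from the data themselves.

    k_off from a tail mono-exponential fit of the highest-concentration
    dissociation; k_on from the slope of observed rate k_obs vs C; Rmax from
    the maximal response scaled by expected fractional occupancy.
    """
    by_conc = sorted(curves, key=lambda c: c.concentration)
    top = by_conc[-1]
    k_off = _estimate_koff(top, t_assoc)
    if k_off is None:
        k_off = 1e-3

    kobs, concs = [], []
    for c in by_conc:
        if c.concentration <= 0:
            continue
        k = _estimate_kobs(c, t_assoc)
        if k is not None:
            kobs.append(k)
            concs.append(c.concentration)
    if len(kobs) >= 2:
        fit = linregress(concs, kobs)
        k_on = float(fit.slope)
    elif kobs:
        k_on = max((kobs[0] - k_off), kobs[0] * 0.5) / concs[0]
    else:
        k_on = 1e4
    k_on = float(np.clip(k_on, *BOUNDS["k_on"]))
    k_off = float(np.clip(k_off, *BOUNDS["k_off"]))

    k_d = k_off / k_on
    occupancy = top.concentration / (top.concentration + k_d)
    r_top = float(np.max(top.response))
    r_max = r_top / occupancy if occupancy > 1e-6 and r_top > 0 else max(r_top, 1.0)
    r_max = float(np.clip(r_max, *BOUNDS["r_max"]))
    return RateConstants(k_on=k_on, k_off=k_off, r_max=r_max, k_t=1e9)


# ---------------------------------------------------------------------------
# fitting


def fit_global(
    series: ReferencedSeries,
    model: str = "two_compartment",
    init: RateConstants | None = None,
    t_assoc: float | None = None,
    n_starts: int = 3,
    fix_k_t: float | None = None,
    fix_r_max: float | None = None,
    with_diagnostics: bool = True,
) -> GlobalFitResult:
    """Fit all curves of ``series`` jointly to the chosen binding model.

    Parameters
    ----------
    series : ReferencedSeries
        Referenced curves at distinct concentrations.
    model : {"two_compartment", "langmuir"}
        Kinetic model; "langmuir" drops the mass-transport step.
    init : RateConstants, optional
        Starting parameters; estimated from the data when omitted.
    t_assoc : float, optional
        Dissociation start time; taken from the curves' phase marks when
        omitted.
    n_starts : int
        Number of log-spaced k_on starting points (local-minimum guard).
    fix_k_t, fix_r_max : float, optional
        Freeze the corresponding parameter instead of fitting it.

    Raises
    ------
    FitError
        On degenerate input (all-zero curves) or optimizer failure.
    """
    if model not in ("two_compartment", "langmuir"):
        raise InvalidParameterError(f"unknown model {model!r}")
    curves = list(series.curves)
    if not curves:
        raise FitError("empty series")
    if len(curves) < 2:
        warnings.warn(
            "single-concentration series: kinetic parameters may not be "
            "identifiable",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    max_abs = max(float(np.max(np.abs(c.response))) for c in curves)
    if max_abs == 0.0:
        raise FitError("degenerate input: all curves identically zero")

    if t_assoc is None:
        marked = [c.t_dissoc_start for c in curves if c.phase_marks is not None]
        if not marked:
            raise FitError("t_assoc not given and no phase marks on curves")
        t_assoc = float(marked[0])

    if init is None:
        init = auto_initialize(curves, t_assoc)

    nk = _n_kin(model)
    lo = np.array(
        [np.log10(BOUNDS[k][0]) for k in ("k_on", "k_off", "r_max", "k_t")[:nk]]
        + [-np.inf] * len(curves)
    )
    hi = np.array(
        [np.log10(BOUNDS[k][1]) for k in ("k_on", "k_off", "r_max", "k_t")[:nk]]
        + [np.inf] * len(curves)
    )
    if fix_k_t is not None and model == "two_compartment":
        lo[3] = hi[3] = np.log10(fix_k_t)
    if fix_r_max is not None:
        lo[2] = hi[2] = np.log10(fix_r_max)
    # least_squares needs lb < ub strictly; nudge frozen params
    frozen = lo == hi
    hi[frozen] = lo[frozen] + 1e-12

    base = np.array(
        [
            np.log10(np.clip(init.k_on, *BOUNDS["k_on"])),
            np.log10(np.clip(init.k_off, *BOUNDS["k_off"])),
            np.log10(np.clip(init.r_max, *BOUNDS["r_max"])),
            np.log10(np.clip(init.k_t if np.isfinite(init.k_t) else 1e9, *BOUNDS["k_t"])),
        ][:nk]
    )

    starts = [base]
    for shift in np.linspace(-1.0, 1.0, n_starts)[np.linspace(-1.0, 1.0, n_starts) != 0]:
        s = base.copy()
        s[0] = np.clip(s[0] + shift, lo[0], hi[0] - 1e-12)
        starts.append(s)
    starts = starts[:n_starts] if n_starts >= 1 else [base]

    best = None
    for s in starts:
        x0 = np.concatenate([np.clip(s, lo[:nk], hi[:nk]), np.zeros(len(curves))])
        sol = least_squares(
            _residual_vector,
            x0,
            bounds=(lo, hi),
            args=(curves, t_assoc, model),
            method="trf",
            x_scale="jac",
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None or not best.success:
        state = None if best is None else best.x
        raise FitError("global fit did not converge", best_state=state)

    x = best.x
    theta = 10.0 ** x[:nk]
    k_t = float(theta[3]) if model == "two_compartment" else math.inf
    params = RateConstants(
        k_on=float(theta[0]), k_off=float(theta[1]), r_max=float(theta[2]), k_t=k_t
    )
    offsets = x[nk:]
    residuals = []
    pos = 0
    for c in curves:
        residuals.append(best.fun[pos : pos + len(c)].copy())
        pos += len(c)
    chi2 = float(np.sum(best.fun**2))

    # covariance in log10 space from the Jacobian at the solution
    m, n = best.jac.shape
    dof = max(m - n, 1)
    param_sd: dict[str, float] = {}
    cov = None
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * (chi2 / dof)
        sd_log = np.sqrt(np.clip(np.diag(cov)[:nk], 0, None))
        names = ("k_on", "k_off", "r_max", "k_t")[:nk]
        ln10 = math.log(10.0)
        for i, name in enumerate(names):
            param_sd[name] = float(theta[i] * ln10 * sd_log[i])
        # K_D = k_off/k_on: propagate in log space including covariance
        var_kd_log = cov[1, 1] + cov[0, 0] - 2 * cov[0, 1]
        k_d = params.k_d
        param_sd["k_d"] = float(k_d * ln10 * math.sqrt(max(var_kd_log, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass

    names = ("k_on", "k_off", "r_max", "k_t")[:nk]
    at_bounds = tuple(
        name
        for i, name in enumerate(names)
        if not frozen[i]
        and (x[i] - lo[i] < 1e-6 or hi[i] - x[i] < 1e-6)
    )

    result = GlobalFitResult(
        params=params,
        per_curve_offsets=offsets.copy(),
        k_d=params.k_d,
        param_sd=param_sd,
        chi2=chi2,
        residuals=residuals,
        model=model,
        concentrations=tuple(c.concentration for c in curves),
        n_points=sum(len(c) for c in curves),
        at_bounds=at_bounds,
        cov_log10=cov,
        n_starts_used=len(starts),
    )
    if with_diagnostics:
        result.diagnostics = residual_diagnostics(result)
    return result


# ---------------------------------------------------------------------------
# residual diagnostics


def runs_test_z(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs-test z statistic on residual signs.

    Zeros are dropped. Returns 0.0 for degenerate sequences (fewer than two
    distinct signs).
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0])
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    n = n1 + n2
    if n1 == 0 or n2 == 0 or n < 2:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 0.0
    return (runs - mu) / math.sqrt(var)


def lag1_autocorrelation(residuals: np.ndarray) -> float:
    """Lag-1 autocorrelation; 0.0 (with a warning) for constant residuals."""
    r = np.asarray(residuals, dtype=float)
    if len(r) < 3 or np.allclose(r, r[0]):
        warnings.warn(
            "degenerate residuals: lag-1 autocorrelation undefined, reporting 0",
            DegenerateDataWarning,
            stacklevel=2,
        )
        return 0.0
    x = r - r.mean()
    denom = float(np.sum(x**2))
    if denom == 0:
        return 0.0
    return float(np.sum(x[1:] * x[:-1]) / denom)


def residual_diagnostics(
    result: GlobalFitResult, min_points: int = 10
) -> list[CurveDiagnostics]:
    """Per-curve runs-test z and lag-1 autocorrelation.

    A curve is flagged as showing systematic divergence from the model when
    |z| exceeds 3 or |lag-1 autocorrelation| exceeds 0.5.  Traces shorter
    than ``min_points`` are skipped with a warning.
    """
    out = []
    for res in result.residuals:
        if len(res) < min_points:
            warnings.warn(
                f"residual trace of length {len(res)} < {min_points}: "
                "diagnostics skipped",
                DegenerateDataWarning,
                stacklevel=2,
            )
            out.append(
                CurveDiagnostics(
                    runs_test_z=float("nan"),
                    lag1_autocorr=float("nan"),
                    flagged=False,
                    skipped=True,
                )
            )
            continue
        degenerate = bool(np.allclose(res, res[0] if len(res) else 0.0))
        z = runs_test_z(res)
        if degenerate:
            ac = 0.0
        else:
            ac = lag1_autocorrelation(res)
        flagged = abs(z) > RUNS_Z_THRESHOLD or abs(ac) > LAG1_THRESHOLD
        out.append(
            CurveDiagnostics(
                runs_test_z=z,
                lag1_autocorr=ac,
                flagged=flagged,
                degenerate=degenerate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# replicate aggregation and concentration-independence check


def aggregate_replicates(results: list[GlobalFitResult]) -> ReplicateSummary:
    """Arithmetic mean and sample SD of k_on, k_off, K_D over replicates.

    SD is reported only for n >= 2.
    """
    if not results:
        raise InvalidParameterError("need at least one fit result")
    k_on = np.array([r.params.k_on for r in results])
    k_off = np.array([r.params.k_off for r in results])
    k_d = np.array([r.k_d for r in results])
    n = len(results)
    sd = (lambda v: float(np.std(v, ddof=1))) if n >= 2 else (lambda v: None)
    return ReplicateSummary(
        n=n,
        k_on_mean=float(k_on.mean()),
        k_off_mean=float(k_off.mean()),
        k_d_mean=float(k_d.mean()),
        k_on_sd=sd(k_on),
        k_off_sd=sd(k_off),
        k_d_sd=sd(k_d),
    )


def concentration_independence_check(
    series: ReferencedSeries,
    model: str = "two_compartment",
    global_result: GlobalFitResult | None = None,
    t_assoc: float | None = None,
):
    """Per-curve individual fits vs the global fit.

    Each curve is fit on its own with Rmax (and k_t, for the two-compartment
    model) frozen at the global estimates — single curves cannot constrain
    them — and the per-concentration K_D is compared to the global K_D.

    Returns a pandas DataFrame with columns ``concentration_M``, ``k_d_M``
    and ``ratio_to_global``.
    """
    import pandas as pd

    if global_result is None:
        global_result = fit_global(
            series, model=model, t_assoc=t_assoc, with_diagnostics=False
        )
    rows = []
    for curve in series.curves:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentifiabilityWarning)
            single = fit_global(
                ReferencedSeries(curves=[curve]),
                model=model,
                init=global_result.params,
                t_assoc=t_assoc,
                n_starts=1,
                fix_r_max=global_result.params.r_max,
                fix_k_t=(
                    global_result.params.k_t
                    if model == "two_compartment"
                    else None
                ),
                with_diagnostics=False,
            )
        rows.append(
            {
                "concentration_M": curve.concentration,
                "k_d_M": single.k_d,
                "ratio_to_global": single.k_d / global_result.k_d,
            }
        )
    return pd.DataFrame(rows)
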