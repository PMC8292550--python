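"""Binding models and forward simulation of biosensor sensorgrams.

Two model variants are provided:

* a closed-form reversible 1:1 surface-binding (Langmuir) model, valid when
  analyte delivery to the surface is not rate limiting;
* a two-compartment variant in which the analyte concentration at the surface
  ``Cs`` differs from the bulk concentration ``C`` because diffusive transport
  (coefficient ``k_t``) competes with binding:

      dR/dt = k_on * Cs * (Rmax - R) - k_off * R
      k_t * (C - Cs) = k_on * Cs * (Rmax - R) - k_off * R

  which gives the quasi-steady surface concentration

      Cs = (k_t * C + k_off * R) / (k_t + k_on * (Rmax - R)).

  As ``k_t`` grows the two-compartment trace converges to the closed form.

Units follow biosensor practice: responses in RU, concentrations in M,
``k_on`` in 1/(M*s), ``k_off`` in 1/s, ``k_t`` in RU/(M*s).  Note that
``k_t`` conflates the RU and M scales (surface capacity is expressed in RU);
this is the conventional single-channel formulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidParameterError, SimulationError

__all__ = [
    "RateConstants",
    "InjectionSchedule",
    "Sensorgram",
    "kd_from_rates",
    "simulate_langmuir",
    "simulate_two_compartment",
]


@dataclass(frozen=True)
class RateConstants:
    """Kinetic parameters of a 1:1 surface binding reaction.

    Attributes
    ----------
    k_on : float
        Association rate constant, 1/(M*s). Must be positive.
    k_off : float
        Dissociation rate constant, 1/s. Must be non-negative.
    r_max : float
        Maximal analyte binding capacity of the surface, RU. Must be positive.
    k_t : float
        Mass-transport coefficient, RU/(M*s). ``math.inf`` marks the
        transport-unlimited limit.
    """

    k_on: float
    k_off: float
    r_max: float
    k_t: float = math.inf

    def __post_init__(self):
        if not (self.k_on > 0):
            raise InvalidParameterError(f"k_on must be > 0, got {self.k_on}")
        if not (self.k_off >= 0):
            raise InvalidParameterError(f"k_off must be >= 0, got {self.k_off}")
        if not (self.r_max > 0):
            raise InvalidParameterError(f"r_max must be > 0, got {self.r_max}")
        if not (self.k_t > 0):
            raise InvalidParameterError(f"k_t must be > 0 (or inf), got {self.k_t}")

    @property
    def k_d(self) -> float:
        """Equilibrium dissociation constant, M."""
        return kd_from_rates(self.k_on, self.k_off)

    @property
    def transport_unlimited(self) -> bool:
        return math.isinf(self.k_t)

    def with_kt(self, k_t: float) -> "RateConstants":
        return replace(self, k_t=k_t)


@dataclass(frozen=True)
class InjectionSchedule:
    """One injection cycle: association then buffer-wash dissociation.

    ``t_assoc`` and ``t_dissoc`` in seconds, ``concentration`` in M (bulk
    analyte concentration during the association phase; zero during
    dissociation), ``dt`` the sampling interval in seconds.
    """

    t_assoc: float
    t_dissoc: float
    concentration: float
    dt: float = 1.0

    def __post_init__(self):
        if not (self.t_assoc > 0):
            raise InvalidParameterError(f"t_assoc must be > 0, got {self.t_assoc}")
        if not (self.t_dissoc >= 0):
            raise InvalidParameterError(f"t_dissoc must be >= 0, got {self.t_dissoc}")
        if not (self.dt > 0):
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if not (self.concentration >= 0):
            raise InvalidParameterError(
                f"concentration must be >= 0, got {self.concentration}"
            )

    def time_grid(self, lead_in: float = 0.0) -> np.ndarray:
        """Sampling times; injection start is t = 0.

        ``lead_in`` seconds of pre-injection baseline are prepended when
        positive (times negative up to -lead_in).
        """
        n_pre = int(round(lead_in / self.dt))
        n_total = int(round((self.t_assoc + self.t_dissoc) / self.dt))
        return np.arange(-n_pre, n_total + 1) * self.dt


@dataclass
class Sensorgram:
    """A single injection cycle's time/response trace.

    ``phase_marks`` are the indices of injection start and dissociation start
    in ``time``.  After preprocessing the response at injection start is zero
    by convention.
    """

    time: np.ndarray
    response: np.ndarray
    concentration: float
    phase_marks: tuple[int, int] | None = None
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise InvalidParameterError(
                "time and response must have the same length, got "
                f"{self.time.shape} vs {self.response.shape}"
            )
        if self.time.ndim != 1:
            raise InvalidParameterError("time must be one-dimensional")
        if len(self.time) > 1 and not np.all(np.diff(self.time) > 0):
            raise InvalidParameterError("time must be strictly increasing")
        if self.phase_marks is not None:
            i0, i1 = self.phase_marks
            if not (0 <= i0 <= i1 < len(self.time)):
                raise InvalidParameterError(
                    f"phase_marks {self.phase_marks} out of range for "
                    f"{len(self.time)} samples"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def t_inject(self) -> float:
        """Time of injection start (0.0 when phase marks are absent)."""
        return self.time[self.phase_marks[0]] if self.phase_marks else 0.0

    @property
    def t_dissoc_start(self) -> float | None:
        return self.time[self.phase_marks[1]] if self.phase_marks else None


def kd_from_rates(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on, in M.

    Raises
    ------
    InvalidParameterError
        If ``k_on`` is not positive.
    """
    if not (k_on > 0):
        raise InvalidParameterError(f"k_on must be > 0, got {k_on}")
    if k_off < 0:
        raise InvalidParameterError(f"k_off must be >= 0, got {k_off}")
    return k_off / k_on


def _phase_marks(time: np.ndarray, t_assoc: float) -> tuple[int, int]:
    i0 = int(np.argmin(np.abs(time - 0.0)))
    i1 = int(np.argmin(np.abs(time - t_assoc)))
    return i0, i1


def langmuir_response(
    time: np.ndarray, params: RateConstants, schedule: InjectionSchedule
) -> np.ndarray:
    """Closed-form 1:1 Langmuir trace evaluated on ``time`` (injection at 0).

    Association (0 <= t <= t_assoc):
        R(t) = Req * (1 - exp(-(k_on*C + k_off) * t)),
        Req  = Rmax * C / (C + K_D)
    Dissociation (t > t_assoc):
        R(t) = R(t_assoc) * exp(-k_off * (t - t_assoc))
    R = 0 before injection.
    """
    time = np.asarray(time, dtype=float)
    c = schedule.concentration
    k_obs = params.k_on * c + params.k_off
    denom = c + params.k_d
    r_eq = params.r_max * c / denom if denom > 0 else 0.0

    out = np.zeros_like(time)
    assoc = (time >= 0) & (time <= schedule.t_assoc)
    out[assoc] = r_eq * -np.expm1(-k_obs * time[assoc])
    r_end = r_eq * -np.expm1(-k_obs * schedule.t_assoc)
    dissoc = time > schedule.t_assoc
    out[dissoc] = r_end * np.exp(-params.k_off * (time[dissoc] - schedule.t_assoc))
    return out


def simulate_langmuir(
    params: RateConstants, schedule: InjectionSchedule, lead_in: float = 0.0
) -> Sensorgram:
    """Simulate a sensorgram under the closed-form 1:1 Langmuir model."""
    time = schedule.time_grid(lead_in)
    response = langmuir_response(time, params, schedule)
    return Sensorgram(
        time=time,
        response=response,
        concentration=schedule.concentration,
        phase_marks=_phase_marks(time, schedule.t_assoc),
        label="langmuir",
    )


def two_compartment_rhs(
    r: float, params: RateConstants, c_bulk: float
) -> float:
    """dR/dt of the two-compartment model at response ``r``."""
    if params.transport_unlimited:
        cs = c_bulk
    else:
        cs = (params.k_t * c_bulk + params.k_off * r) / (
            params.k_t + params.k_on * (params.r_max - r)
        )
    return params.k_on * cs * (params.r_max - r) - params.k_off * r


def simulate_two_compartment(
    params: RateConstants,
    schedule: InjectionSchedule,
    lead_in: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Sensorgram:
    """Simulate a sensorgram under the 1:1 + mass-transport model.

    The ODE is integrated with an adaptive stiffness-switching method
    (LSODA); the model can be stiff when ``k_t`` is small relative to
    ``k_on * Rmax``.

    Raises
    ------
    SimulationError
        If the integrator fails to converge.
    """
    time = schedule.time_grid(lead_in)
    pos = time[time >= 0]
    response = np.zeros_like(time)

    def rhs(_t, y, c_bulk):
        return [two_compartment_rhs(y[0], params, c_bulk)]

    # association phase
    t_a = schedule.t_assoc
    eval_a = pos[pos <= t_a]
    r_end = 0.0
    if len(eval_a) > 0 and t_a > 0:
        sol = solve_ivp(
            rhs,
            (0.0, t_a),
            [0.0],
            t_eval=eval_a,
            args=(schedule.concentration,),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"association integration failed: {sol.message}")
        response[np.searchsorted(time, eval_a)] = sol.y[0]
        r_end = float(sol.y[0][-1]) if sol.t[-1] == t_a else float(
            solve_ivp(
                rhs, (0.0, t_a), [0.0], args=(schedule.concentration,),
                method="LSODA", rtol=rtol, atol=atol,
            ).y[0][-1]
        )

    # dissociation phase (bulk concentration drops to zero exactly)
    eval_d = pos[pos > t_a]
    if len(eval_d) > 0:
        sol = solve_ivp(
            rhs,
            (t_a, float(eval_d[-1])),
            [r_end],
            t_eval=eval_d,
            args=(0.0,),
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"dissociation integration failed: {sol.message}")
        response[np.searchsorted(time, eval_d)] = sol.y[0]

    return Sensorgram(
        time=time,
        response=response,
        concentration=schedule.concentration,
        phase_marks=_phase_marks(time, schedule.t_assoc),
        label="two_compartment",
    )
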