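"""Target-controlled infusion: plasma and effect-site targeting plus the
sedation/anaesthesia dosing scenarios.

The effect-site controller is a discrete-time, no-overshoot strategy: at each
control tick it administers the largest pump-admissible rate such that the
predicted future peak of the effect-site concentration does not exceed the
target.  Because the system is linear, the predicted future Ce under a
candidate rate r for one tick is ``a(t) + r * g(t)`` where ``a`` is the free
evolution of the current state and ``g`` the (precomputed) Ce response to a
one-tick unit-rate infusion, so the admissible rate is found in closed form
each tick.  Once Ce reaches the target the same rule automatically holds it
there (plasma and effect-site concentrations then coincide at the target).
The MOAA/S effect-site rate constant drives the controller; BIS is evaluated
as a passive output with its own ke0.

Plasma targeting pins the central amount at ``target * V1`` exactly at every
tick boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logit

from .covariates import SubjectModel
from .effects import moaas_probabilities, tolerance_drift
from .system import (
    IDX,
    N_STATES,
    DoseEvent,
    InfusionSchedule,
    Timecourse,
    build_system,
)

__all__ = [
    "TCITarget",
    "TCIPlan",
    "plan_tci",
    "find_sedation_target",
    "dosing_vs_age",
    "DEFAULT_RATE_CAP",
]

DEFAULT_RATE_CAP = 600.0 / 60.0  # pump maximum, mg min^-1 (600 mg h^-1)


@dataclass(frozen=True)
class TCITarget:
    """A constant concentration target held for ``duration`` minutes."""

    target: float  # ug ml^-1
    mode: Literal["plasma", "effect_site"] = "effect_site"
    signal: Literal["moaas_ce", "bis_ce"] = "moaas_ce"
    duration: float = 60.0  # min
    control_interval: float = 1.0  # s
    overshoot_tol: float = 0.01  # fractional Ce overshoot allowed

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise ValueError("target must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.control_interval <= 0:
            raise ValueError("control interval must be > 0")


@dataclass(frozen=True)
class TCIPlan:
    """Controller output: dosing, predicted trajectories and summaries."""

    target: TCITarget
    schedule: InfusionSchedule
    timecourse: Timecourse
    rates: np.ndarray  # mg min^-1 per control tick
    tick_min: float
    induction_dose_mg: float | None  # cumulative dose to 99% target attainment
    induction_time_min: float | None
    maintenance_rate_mg_min: float  # mean rate over the late window
    maintenance_window: tuple[float, float]
    target_attained: bool
    weight: float | None = None
    pd_summary: pd.DataFrame | None = None

    @property
    def induction_dose_mg_per_kg(self) -> float | None:
        if self.induction_dose_mg is None or not self.weight:
            return None
        return self.induction_dose_mg / self.weight

    @property
    def maintenance_rate_mg_kg_h(self) -> float | None:
        if not self.weight:
            return None
        return self.maintenance_rate_mg_min * 60.0 / self.weight

    @property
    def total_dose_mg(self) -> float:
        return float(self.rates.sum() * self.tick_min)


def _ce_row(signal: str) -> int:
    return IDX["Ce_moaas"] if signal == "moaas_ce" else IDX["Ce_bis"]


def plan_tci(
    model: SubjectModel,
    target: TCITarget,
    rate_cap: float = DEFAULT_RATE_CAP,
    horizon_min: float = 15.0,
    maintenance_window: tuple[float, float] = (30.0, 60.0),
    evaluate_pd: bool = True,
) -> TCIPlan:
    """Run the TCI controller for one subject at a constant target.

    ``rate_cap`` is the pump maximum in mg min^-1.  In effect-site mode the
    controller never lets predicted Ce exceed the target (no overshoot beyond
    ``target.overshoot_tol``); if the target cannot be attained within the
    simulated duration under the rate cap the plan is flagged unattained.
    """
    if rate_cap <= 0:
        raise ValueError("rate_cap must be > 0")
    system = build_system(model.remi, model.metab,
                          model.moaas.ke0, model.bis.ke0)
    dt = target.control_interval / 60.0
    n = int(round(target.duration / dt))
    P, q = system.propagator(dt)
    ce_i = _ce_row(target.signal)

    if target.mode == "effect_site":
        # free-evolution map of Ce over the prediction horizon: Cmat[j] = e_ce' P^j
        h = max(2, int(round(horizon_min / dt)))
        cmat = np.empty((h + 1, N_STATES))
        row = np.zeros(N_STATES)
        row[ce_i] = 1.0
        cmat[0] = row
        for j in range(1, h + 1):
            row = row @ P
            cmat[j] = row
        # Ce response (j ticks ahead) to a unit rate held for one tick
        g = cmat[:h] @ q  # g[j] = Ce after j+1 ticks
        pos = g > 1e-300

    v1_target = target.target * model.remi.V1
    x = np.zeros(N_STATES)
    rates = np.empty(n)
    states = np.empty((n + 1, N_STATES))
    states[0] = x
    for k in range(n):
        if target.mode == "plasma":
            r = (v1_target - (P @ x)[IDX["A1"]]) / q[IDX["A1"]]
        else:
            a = cmat[1:] @ x  # free Ce at 1..h ticks ahead
            room = target.target - a
            r = np.min(room[pos] / g[pos])
        rates[k] = min(max(r, 0.0), rate_cap)
        x = P @ x + q * rates[k]
        states[k + 1] = x

    t_grid = np.arange(n + 1) * dt
    sig = system.outputs(states)
    cum = np.concatenate(([0.0], np.cumsum(rates * dt)))
    tc = Timecourse(
        time=t_grid,
        cp_art=sig["cp_art"], cven=sig["cven"],
        ce_moaas=sig["ce_moaas"], ce_bis=sig["ce_bis"],
        ca_metab=sig["ca_metab"], cven_metab=sig["cven_metab"],
        cum_dose=cum, states=states,
    )

    ctrl = sig["cp_art"] if target.mode == "plasma" else states[:, ce_i]
    attained_idx = np.flatnonzero(ctrl >= 0.99 * target.target)
    attained = attained_idx.size > 0
    if attained:
        k0 = int(attained_idx[0])
        induction_dose = float(cum[k0])
        induction_time = float(t_grid[k0])
    else:
        induction_dose = None
        induction_time = None

    w0, w1 = maintenance_window
    w1 = min(w1, target.duration)
    sel = (t_grid[:-1] >= w0) & (t_grid[:-1] < w1)
    maint = float(rates[sel].mean()) if sel.any() else float("nan")

    # compress per-tick rates into dose events
    events = []
    start = 0
    for k in range(1, n + 1):
        if k == n or rates[k] != rates[start]:
            if rates[start] > 0:
                dur = (k - start) * dt
                events.append(DoseEvent(time=start * dt,
                                        amount=rates[start] * dur, duration=dur))
            start = k
    schedule = InfusionSchedule(events)

    pd_summary = None
    if evaluate_pd:
        pd_summary = tolerance_drift(tc, model.moaas, model.bis,
                                     opioids=model.cov.opioids_present)

    return TCIPlan(
        target=target, schedule=schedule, timecourse=tc, rates=rates,
        tick_min=dt, induction_dose_mg=induction_dose,
        induction_time_min=induction_time, maintenance_rate_mg_min=maint,
        maintenance_window=(w0, w1), target_attained=attained,
        weight=model.cov.weight, pd_summary=pd_summary,
    )


@dataclass(frozen=True)
class TargetResult:
    target: float  # ug ml^-1
    multiple_of_ce50: float
    criterion: str
    criterion_value: float


def _p0_at_attainment(model: SubjectModel, tgt: float, rate_cap: float,
                      control_interval: float) -> float:
    plan = plan_tci(
        model,
        TCITarget(target=tgt, duration=20.0, control_interval=control_interval),
        rate_cap=rate_cap, evaluate_pd=False,
    )
    if not plan.target_attained:
        return 0.0
    k = int(np.flatnonzero(plan.timecourse.ce_moaas >= 0.99 * tgt)[0])
    dist = moaas_probabilities(
        plan.timecourse.ce_moaas[k], plan.timecourse.ca_metab[k],
        model.moaas, opioids=model.cov.opioids_present,
    )
    return float(dist.p(0))


def _p23_at(model: SubjectModel, tgt: float, at_min: float, rate_cap: float,
            control_interval: float) -> float:
    plan = plan_tci(
        model,
        TCITarget(target=tgt, duration=at_min, control_interval=control_interval),
        rate_cap=rate_cap, evaluate_pd=False,
    )
    tc = plan.timecourse
    dist = moaas_probabilities(tc.ce_moaas[-1], tc.ca_metab[-1],
                               model.moaas, opioids=model.cov.opioids_present)
    return float(dist.p(2) + dist.p(3))


def find_sedation_target(
    model: SubjectModel,
    criterion: Literal["sedation", "anaesthesia"] = "sedation",
    rate_cap: float = DEFAULT_RATE_CAP,
    tol: float = 1e-3,
    control_interval: float = 2.0,
) -> TargetResult:
    """Constant effect-site target for a clinical criterion.

    sedation -- the target maximising P(MOAA/S in {2, 3}) at 10 min;
    anaesthesia -- the minimal target achieving P(MOAA/S = 0) >= 0.90 at
    first target attainment.  Both are solved on the simulated PD criterion
    to ``tol`` ug ml^-1; the result also reports the target as a multiple of
    the subject's MOAA/S Ce50.
    """
    p = model.moaas
    b0 = p.b0_op if model.cov.opioids_present else p.b0
    ce50 = p.ce50
    if criterion == "anaesthesia":
        # closed-form seed ignoring the metabolite: expit(b0 + DEFF*f) = 0.9
        fmax = 1.0  # sup of the drug-effect fraction
        if 1.0 / (1.0 + np.exp(-(b0 + p.deff * fmax))) < 0.90:
            raise ValueError("P(MOAA/S=0) >= 0.90 unattainable for this subject")
        f_req = (logit(0.90) - b0) / p.deff
        seed = ce50 * (f_req / (1.0 - f_req)) ** (1.0 / p.gamma)
        fun = lambda t: _p0_at_attainment(model, t, rate_cap, control_interval) - 0.90
        lo, hi = 0.7 * seed, 1.5 * seed
        while fun(lo) > 0 and lo > 1e-3:
            lo *= 0.7
        while fun(hi) < 0:
            hi *= 1.5
            if hi > 100 * seed:
                raise ValueError("anaesthesia criterion unattainable under rate cap")
        tgt = float(brentq(fun, lo, hi, xtol=tol))
        val = fun(tgt) + 0.90
    else:
        span = (0.2 * ce50, 20.0 * ce50)
        res = minimize_scalar(
            lambda t: -_p23_at(model, t, 10.0, rate_cap, control_interval),
            bounds=span, method="bounded", options={"xatol": tol},
        )
        tgt = float(res.x)
        val = -float(res.fun)
    return TargetResult(target=tgt, multiple_of_ce50=tgt / ce50,
                        criterion=criterion, criterion_value=val)


def dosing_vs_age(
    scenario: Literal["sedation", "anaesthesia"],
    ages: Sequence[float],
    weight: float = 70.0,
    sex: str = "male",
    opioids: bool = True,
    rate_cap: float = DEFAULT_RATE_CAP,
    control_interval: float = 1.0,
    return_plans: bool = False,
):
    """Targets, induction doses and maintenance rates across age.

    Simulates 60 min of effect-site TCI at the criterion-derived target for
    each age (opioids present and normal organ function by default, matching
    the published simulation conditions).  Returns a DataFrame with one row
    per age; with ``return_plans`` also the full plans.
    """
    if scenario not in ("sedation", "anaesthesia"):
        raise ValueError("scenario must be 'sedation' or 'anaesthesia'")
    from .covariates import SubjectCovariates, individual_parameters

    rows = []
    plans = []
    for age in ages:
        cov = SubjectCovariates(age=age, weight=weight, sex=sex,
                                opioids_present=opioids)
        model = individual_parameters(cov)
        tr = find_sedation_target(model, scenario, rate_cap=rate_cap)
        plan = plan_tci(
            model,
            TCITarget(target=tr.target, duration=60.0,
                      control_interval=control_interval),
            rate_cap=rate_cap,
        )
        rows.append({
            "age": age,
            "target_ugml": tr.target,
            "target_over_ce50": tr.multiple_of_ce50,
            "criterion_value": tr.criterion_value,
            "induction_dose_mg": plan.induction_dose_mg,
            "induction_dose_mg_kg": plan.induction_dose_mg_per_kg,
            "maintenance_mg_kg_h": plan.maintenance_rate_mg_kg_h,
            "bis_at_60": float(plan.pd_summary["BIS"].iloc[-1]),
            "ews_at_60": float(plan.pd_summary["EWS"].iloc[-1]),
        })
        if return_plans:
            plans.append(plan)
    table = pd.DataFrame(rows)
    return (table, plans) if return_plans else table
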