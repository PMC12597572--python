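import numpy as np
import pytest
from scipy.integrate import solve_ivp

from remipkpd import (
    DoseEvent,
    InfusionSchedule,
    SubjectCovariates,
    ThetaTable,
    build_system,
    individual_parameters,
)


@pytest.fixture(scope="session")
def theta():
    return ThetaTable()


@pytest.fixture(scope="session")
def ref_cov():
    """The reference individual: 70 kg, 35 yr, male, no opioids, normal
    hepatic and renal function."""
    return SubjectCovariates(age=35.0, weight=70.0, sex="male")


@pytest.fixture(scope="session")
def ref_model(ref_cov, theta):
    return individual_parameters(ref_cov, theta)


@pytest.fixture(scope="session")
def ref_system(ref_model):
    return build_system(ref_model.remi, ref_model.metab,
                        ref_model.moaas.ke0, ref_model.bis.ke0)


def random_covariates(rng, opioids=None):
    """Covariates over the modelled demographic envelope, normal organ function."""
    return SubjectCovariates(
        age=float(rng.uniform(6.0, 93.0)),
        weight=float(rng.uniform(21.0, 171.0)),
        sex="female" if rng.random() < 0.5 else "male",
        opioids_present=bool(rng.random() < 0.5) if opioids is None else opioids,
    )


def random_schedule(rng, t_max=40.0):
    """A random mixture of boluses and infusions for simulator stress tests."""
    events = []
    for _ in range(rng.integers(1, 4)):
        t = float(rng.uniform(0.0, t_max * 0.5))
        if rng.random() < 0.4:
            events.append(DoseEvent(time=t, amount=float(rng.uniform(1, 20))))
        else:
            dur = float(rng.uniform(0.5, 15.0))
            events.append(DoseEvent(time=t, amount=float(rng.uniform(1, 30)),
                                    duration=dur))
    return InfusionSchedule(events)


def ode_oracle(system, schedule, times, rtol=1e-9, atol=1e-12):
    """Independent adaptive-ODE integration of the same dosing problem.

    Integrates segment-by-segment between dose events with solve_ivp so the
    piecewise-constant input is exact; entirely independent of the
    matrix-exponential path under test.
    """
    boluses = {}
    deltas = {}
    for ev in schedule:
        if ev.duration > 0:
            deltas[ev.time] = deltas.get(ev.time, 0.0) + ev.rate
            t1 = ev.time + ev.duration
            deltas[t1] = deltas.get(t1, 0.0) - ev.rate
        elif ev.amount > 0:
            boluses[ev.time] = boluses.get(ev.time, 0.0) + ev.amount
    times = np.asarray(times, dtype=float)
    points = np.union1d(times, np.array(sorted(set(boluses) | set(deltas))))
    A, b = system.A, system.b
    x = np.zeros(A.shape[0])
    rate = 0.0
    t_cur = 0.0
    out = np.empty((times.size, A.shape[0]))
    oi = 0
    for t in points:
        if t > t_cur:
            sol = solve_ivp(lambda tt, xx: A @ xx + b * rate, (t_cur, t), x,
                            rtol=rtol, atol=atol, method="LSODA")
            x = sol.y[:, -1]
            t_cur = t
        if t in boluses:
            x = x.copy()
            x[0] += boluses.pop(t)
        while oi < times.size and times[oi] <= t + 1e-12:
            out[oi] = x
            oi += 1
        rate += deltas.pop(t, 0.0)
    return out
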