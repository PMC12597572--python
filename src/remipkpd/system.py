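"""Linear compartmental system for remimazolam and CNS7054, with exact solver.

The state couples a three-compartment mammillary model for remimazolam
(amounts A1-A3, mg) with a mass-less first-order venous-delay tracer, two
effect sites (MOAA/S and BIS, concentrations ug ml^-1), and a
depot + two-compartment chain for the metabolite CNS7054 (all remimazolam
eliminated by CL is converted to metabolite and appears in the depot).  Two
bookkeeping states accumulate eliminated remimazolam and metabolite mass so
mass balance is checkable to machine precision.

Because the system is linear and time-invariant with piecewise-constant
infusion input, trajectories are propagated exactly with matrix exponentials
of the input-augmented rate matrix; an adaptive ODE solver is used only as an
independent oracle in the test-suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .covariates import MetabPKParams, RemiPKParams

__all__ = [
    "DoseEvent",
    "InfusionSchedule",
    "CompartmentSystem",
    "Timecourse",
    "build_system",
    "simulate",
    "time_to_peak_effect",
    "merge_dose_records",
    "N_STATES",
    "IDX",
]

# state layout
N_STATES = 12
IDX = {
    "A1": 0, "A2": 1, "A3": 2,      # remimazolam amounts, mg
    "Cdel": 3,                       # venous delay tracer, ug ml^-1
    "Ce_moaas": 4, "Ce_bis": 5,      # effect sites, ug ml^-1
    "Adepot": 6, "Am1": 7, "Am2": 8,  # metabolite amounts, mg
    "Cdel_m": 9,                     # metabolite venous delay tracer
    "Elim": 10, "Elim_m": 11,        # cumulative eliminated mass, mg
}


@dataclass(frozen=True)
class DoseEvent:
    """One dosing record: a bolus (duration 0) or a constant-rate infusion.

    ``amount`` is the total dose in mg; infusions run at ``amount/duration``
    mg min^-1 into the remimazolam central compartment.
    """

    time: float  # min
    amount: float  # mg
    duration: float = 0.0  # min; 0 for bolus

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if self.duration < 0:
            raise ValueError("dose duration must be >= 0")

    @property
    def rate(self) -> float:
        """Infusion rate in mg min^-1 (0 for a bolus record)."""
        return self.amount / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class InfusionSchedule:
    """Ordered list of dose events; overlapping infusion rates add."""

    events: tuple[DoseEvent, ...]

    def __init__(self, events: Iterable[DoseEvent] = ()):
        object.__setattr__(self, "events", tuple(sorted(events, key=lambda e: e.time)))

    @property
    def total_dose(self) -> float:
        return sum(e.amount for e in self.events)

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class CompartmentSystem:
    """Constant-coefficient rate matrix plus output maps."""

    A: np.ndarray  # (12, 12) rate matrix, min^-1
    b: np.ndarray  # (12,) input map: infusion rate (mg min^-1) -> dA1/dt
    remi: RemiPKParams
    metab: MetabPKParams
    ke0_moaas: float
    ke0_bis: float
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def propagator(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """Exact discrete-time propagator over ``dt`` under constant input.

        Returns ``(P, q)`` with ``x(t+dt) = P @ x(t) + q * rate`` from the
        exponential of the input-augmented matrix [[A, b], [0, 0]].
        """
        key = round(float(dt), 12)
        hit = self._cache.get(key)
        if hit is None:
            m = np.zeros((N_STATES + 1, N_STATES + 1))
            m[:N_STATES, :N_STATES] = self.A
            m[:N_STATES, N_STATES] = self.b
            e = expm(m * dt)
            hit = (np.ascontiguousarray(e[:N_STATES, :N_STATES]),
                   e[:N_STATES, N_STATES].copy())
            self._cache[key] = hit
        return hit

    def outputs(self, states: np.ndarray) -> dict[str, np.ndarray]:
        """Concentration signals from a (n, 12) state array."""
        x = np.atleast_2d(states)
        cp = x[:, IDX["A1"]] / self.remi.V1
        cdel = x[:, IDX["Cdel"]]
        ca = x[:, IDX["Am1"]] / self.metab.V1m
        cdel_m = x[:, IDX["Cdel_m"]]
        fv = self.remi.fven
        return {
            "cp_art": cp,
            "cven": fv * cp + (1.0 - fv) * cdel,
            "ce_moaas": x[:, IDX["Ce_moaas"]],
            "ce_bis": x[:, IDX["Ce_bis"]],
            "ca_metab": ca,
            "cven_metab": fv * ca + (1.0 - fv) * cdel_m,
        }


@dataclass(frozen=True)
class Timecourse:
    """Simulated concentration trajectories on a time grid (min, ug ml^-1)."""

    time: np.ndarray
    cp_art: np.ndarray
    cven: np.ndarray
    ce_moaas: np.ndarray
    ce_bis: np.ndarray
    ca_metab: np.ndarray
    cven_metab: np.ndarray
    cum_dose: np.ndarray  # mg administered up to and including t
    states: np.ndarray | None = None  # (n, 12), optional

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "TIME": self.time,
                "CP_ART": self.cp_art,
                "CVEN": self.cven,
                "CE_MOAAS": self.ce_moaas,
                "CE_BIS": self.ce_bis,
                "CA_METAB": self.ca_metab,
                "CVEN_METAB": self.cven_metab,
                "CUM_DOSE": self.cum_dose,
            }
        )


def build_system(
    remi: RemiPKParams,
    metab: MetabPKParams,
    ke0_moaas: float,
    ke0_bis: float,
) -> CompartmentSystem:
    """Assemble the full 12-state rate matrix.

    Remimazolam: standard mammillary rates; the venous signal is the convex
    combination ``Cven = fven * Cp + (1 - fven) * Cdel`` with
    ``dCdel/dt = kdelay * (Cp - Cdel)``.  Effect sites follow
    ``dCe/dt = ke0 * (Cp - Ce)`` and carry no mass.  Eliminated remimazolam
    mass (times ``mass_conversion``) feeds the metabolite depot, which
    transfers into the CNS7054 central compartment at ``kdepot``; the
    metabolite reuses the remimazolam venous-delay model.
    """
    if ke0_moaas <= 0 or ke0_bis <= 0:
        raise ValueError("ke0 values must be > 0")
    A = np.zeros((N_STATES, N_STATES))
    i = IDX
    V1, V2, V3 = remi.V1, remi.V2, remi.V3
    CL, Q2, Q3 = remi.CL, remi.Q2, remi.Q3
    kd = remi.kdelay
    # remimazolam mammillary
    A[i["A1"], i["A1"]] = -(CL + Q2 + Q3) / V1
    A[i["A1"], i["A2"]] = Q2 / V2
    A[i["A1"], i["A3"]] = Q3 / V3
    A[i["A2"], i["A1"]] = Q2 / V1
    A[i["A2"], i["A2"]] = -Q2 / V2
    A[i["A3"], i["A1"]] = Q3 / V1
    A[i["A3"], i["A3"]] = -Q3 / V3
    # venous delay tracer and effect sites (driven by Cp = A1/V1)
    A[i["Cdel"], i["A1"]] = kd / V1
    A[i["Cdel"], i["Cdel"]] = -kd
    A[i["Ce_moaas"], i["A1"]] = ke0_moaas / V1
    A[i["Ce_moaas"], i["Ce_moaas"]] = -ke0_moaas
    A[i["Ce_bis"], i["A1"]] = ke0_bis / V1
    A[i["Ce_bis"], i["Ce_bis"]] = -ke0_bis
    # metabolite chain: eliminated remi mass -> depot -> 2-compartment
    mc = metab.mass_conversion
    V1m, V2m = metab.V1m, metab.V2m
    CLm, Q2m = metab.CLm, metab.Q2m
    A[i["Adepot"], i["A1"]] = mc * CL / V1
    A[i["Adepot"], i["Adepot"]] = -metab.kdepot
    A[i["Am1"], i["Adepot"]] = metab.kdepot
    A[i["Am1"], i["Am1"]] = -(CLm + Q2m) / V1m
    A[i["Am1"], i["Am2"]] = Q2m / V2m
    A[i["Am2"], i["Am1"]] = Q2m / V1m
    A[i["Am2"], i["Am2"]] = -Q2m / V2m
    A[i["Cdel_m"], i["Am1"]] = kd / V1m
    A[i["Cdel_m"], i["Cdel_m"]] = -kd
    # cumulative elimination bookkeeping
    A[i["Elim"], i["A1"]] = CL / V1
    A[i["Elim_m"], i["Am1"]] = CLm / V1m
    b = np.zeros(N_STATES)
    b[i["A1"]] = 1.0
    return CompartmentSystem(A=A, b=b, remi=remi, metab=metab,
                             ke0_moaas=ke0_moaas, ke0_bis=ke0_bis)


def _rate_profile(schedule: InfusionSchedule):
    """Bolus map and sorted rate-change breakpoints from a schedule."""
    boluses: dict[float, float] = {}
    deltas: dict[float, float] = {}
    for ev in schedule:
        if ev.duration > 0:
            deltas[ev.time] = deltas.get(ev.time, 0.0) + ev.rate
            t1 = ev.time + ev.duration
            deltas[t1] = deltas.get(t1, 0.0) - ev.rate
        elif ev.amount > 0:
            boluses[ev.time] = boluses.get(ev.time, 0.0) + ev.amount
    return boluses, deltas


def simulate(
    system: CompartmentSystem,
    schedule: InfusionSchedule,
    times: Sequence[float],
    x0: np.ndarray | None = None,
    keep_states: bool = False,
) -> Timecourse:
    """Exact piecewise trajectory of the system under a dosing schedule.

    Boluses are instantaneous state increments applied before outputs at the
    same time stamp (so a time grid containing the bolus time reports the
    post-bolus concentration).  Between breakpoints the infusion rate is
    constant and the state is advanced with the cached matrix-exponential
    propagator, so the result carries no discretisation error.
    """
    t_out = np.asarray(times, dtype=float)
    if t_out.ndim != 1 or t_out.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t_out) < 0):
        raise ValueError("times must be sorted ascending")
    if t_out[0] < 0:
        raise ValueError("times must be >= 0")

    boluses, deltas = _rate_profile(schedule)
    critical = sorted(set(boluses) | set(deltas))
    points = np.union1d(t_out, np.asarray(critical, dtype=float))

    x = np.zeros(N_STATES) if x0 is None else np.asarray(x0, dtype=float).copy()
    rate = 0.0
    cum = 0.0
    t_cur = 0.0
    # events at t = 0
    states_out = np.empty((t_out.size, N_STATES))
    cum_out = np.empty(t_out.size)
    out_i = 0

    def emit(t: float) -> None:
        nonlocal out_i
        while out_i < t_out.size and t_out[out_i] <= t + 1e-12:
            states_out[out_i] = x
            cum_out[out_i] = cum
            out_i += 1

    for t in points:
        dt = t - t_cur
        if dt > 0:
            P, q = system.propagator(dt)
            x = P @ x + q * rate
            cum += rate * dt
            t_cur = t
        amt = boluses.pop(t, 0.0)
        if amt:
            x = x.copy()
            x[IDX["A1"]] += amt
            cum += amt
        emit(t)
        rate += deltas.pop(t, 0.0)
        rate = 0.0 if abs(rate) < 1e-15 else rate
    emit(np.inf)

    sig = system.outputs(states_out)
    return Timecourse(
        time=t_out,
        cp_art=sig["cp_art"], cven=sig["cven"],
        ce_moaas=sig["ce_moaas"], ce_bis=sig["ce_bis"],
        ca_metab=sig["ca_metab"], cven_metab=sig["cven_metab"],
        cum_dose=cum_out,
        states=states_out if keep_states else None,
    )


def time_to_peak_effect(
    remi: RemiPKParams,
    ke0: float,
    tol: float = 1e-4,
) -> float:
    """Time (min) of maximum effect-site concentration after an IV bolus.

    Dose-independent for a linear system; located by a coarse grid scan
    followed by bounded golden-section refinement to ``tol`` minutes.
    """
    if ke0 <= 0:
        raise ValueError("ke0 must be > 0")
    V1, V2, V3 = remi.V1, remi.V2, remi.V3
    CL, Q2, Q3 = remi.CL, remi.Q2, remi.Q3
    A = np.array([
        [-(CL + Q2 + Q3) / V1, Q2 / V2, Q3 / V3, 0.0],
        [Q2 / V1, -Q2 / V2, 0.0, 0.0],
        [Q3 / V1, 0.0, -Q3 / V3, 0.0],
        [ke0 / V1, 0.0, 0.0, -ke0],
    ])
    x0 = np.array([1.0, 0.0, 0.0, 0.0])

    # eigendecomposition => vectorised Ce(t); generic PK systems are diagonalisable
    lam, V = np.linalg.eig(A)
    w = np.linalg.solve(V, x0)
    c = V[3, :] * w

    def ce(t):
        t = np.asarray(t, dtype=float)
        return np.real(np.exp(np.multiply.outer(t, lam)) @ c)

    tmax = 30.0
    while True:
        grid = np.linspace(0.0, tmax, 1501)
        vals = ce(grid)
        k = int(np.argmax(vals))
        if k < 1500 or tmax > 2000:
            break
        tmax *= 4
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, 1500)]
    res = minimize_scalar(lambda t: -float(ce(t)), bounds=(lo, hi),
                          method="bounded", options={"xatol": tol})
    return float(res.x)


# dose-record merging thresholds (Methods rule for TCI infusion profiles)
MERGE_MAX_GAP = 1.0 / 60.0  # min  (< 1 s apart)
MERGE_MAX_RATE_DIFF = 0.05  # mg min^-1  (< 50 ug min^-1)
MERGE_MAX_DURATION = 2.0  # min


def merge_dose_records(schedule: InfusionSchedule) -> InfusionSchedule:
    """Iteratively combine near-contiguous, near-equal-rate short infusions.

    Two consecutive infusion records merge when the gap between them is under
    1 s, their rates differ by less than 50 ug min^-1 and each lasts under
    2 min; the merged record delivers the summed dose over the combined span.
    Repeats until no further records combine.  Total dose is preserved
    exactly; bolus records are never merged.
    """
    events = list(schedule)
    changed = True
    while changed:
        changed = False
        out: list[DoseEvent] = []
        j = 0
        while j < len(events):
            cur = events[j]
            if (
                j + 1 < len(events)
                and cur.duration > 0
                and events[j + 1].duration > 0
            ):
                nxt = events[j + 1]
                gap = nxt.time - (cur.time + cur.duration)
                if (
                    abs(gap) < MERGE_MAX_GAP
                    and abs(cur.rate - nxt.rate) < MERGE_MAX_RATE_DIFF
                    and cur.duration < MERGE_MAX_DURATION
                    and nxt.duration < MERGE_MAX_DURATION
                ):
                    merged = DoseEvent(
                        time=cur.time,
                        amount=cur.amount + nxt.amount,
                        duration=(nxt.time + nxt.duration) - cur.time,
                    )
                    out.append(merged)
                    j += 2
                    changed = True
                    continue
            out.append(cur)
            j += 1
        events = out
    return InfusionSchedule(events)
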