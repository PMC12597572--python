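"""Virtual-cohort generation with the statistical structure of the analysis.

Covariates are drawn over the demographic envelope of the modelled
population (ages 6-93 yr, weights 21-171 kg), interindividual variability is
log-normal with the published omega^2 values (remimazolam CL variance
inflated 1.86-fold for venous-only subjects), PK observations carry
multiplicative log-normal residual error (the transform-both-sides
proportional model), MOAA/S observations are categorical draws from the
proportional-odds model, and BIS observations are produced as a 1-Hz stream
with a 15-s signal-processing delay, additive Gaussian noise and a
per-subject noisy baseline, then median-filtered in 10-s epochs.
Remimazolam / metabolite concentration rows within the first 2 / 3 min of
drug administration are excluded, mirroring the front-end data-cleaning rule
the analysis assumes.

Residual-error magnitudes are not part of the published estimates; the
defaults here (sigma 0.20 on the log scale for PK, 4 BIS units) are
field-realistic stand-ins and are recorded in the dataset metadata.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .covariates import (
    DEFAULT_IIV,
    DEFAULT_THETA,
    IIVSpec,
    SubjectCovariates,
    SubjectModel,
    ThetaTable,
    individual_parameters,
)
from .effects import bis_predict, drug_effect_fraction, moaas_probabilities
from .system import DoseEvent, InfusionSchedule, build_system, simulate

__all__ = [
    "PopulationSpec",
    "Subject",
    "SyntheticDataset",
    "sample_population",
    "generate_observations",
    "default_dosing",
]

#: front-end exclusion windows after start of administration (min)
REMI_EXCLUSION_MIN = 2.0
METAB_EXCLUSION_MIN = 3.0
BIS_DELAY_MIN = 15.0 / 60.0
BIS_EPOCH_S = 10.0

TYPE_CMT = {"dose": 1, "remi_art": 1, "remi_ven": 2,
            "metab_art": 3, "metab_ven": 4, "MOAAS": 5, "BIS": 6}


def default_dosing(weight: float) -> InfusionSchedule:
    """Induction + maintenance template: 0.1 mg/kg over 1 min, then 1 mg/kg/h
    until 30 min."""
    return InfusionSchedule([
        DoseEvent(time=0.0, amount=0.1 * weight, duration=1.0),
        DoseEvent(time=1.0, amount=weight * (29.0 / 60.0), duration=29.0),
    ])


@dataclass(frozen=True)
class PopulationSpec:
    """Virtual-cohort definition: covariate distributions, IIV, residuals,
    sampling design and dosing template."""

    n: int = 20
    seed: int = 0
    age_range: tuple[float, float] = (6.0, 93.0)  # yr
    weight_range: tuple[float, float] = (21.0, 171.0)  # kg
    female_fraction: float = 0.39
    opioid_prevalence: float = 0.5
    pugh_prevalence: float = 0.0
    esrd_prevalence: float = 0.0
    venous_only_fraction: float = 0.0
    sigma_pk: float = 0.20  # SD of log-scale multiplicative PK error
    sigma_bis: float = 4.0  # SD of additive BIS error (BIS units)
    pk_sample_times: tuple[float, ...] = (3.0, 5.0, 8.0, 12.0, 20.0, 30.0, 45.0, 60.0, 90.0)
    moaas_sample_times: tuple[float, ...] = tuple(float(t) for t in range(0, 62, 4))
    bis_duration: float = 30.0  # min of 1-Hz BIS streaming (0 disables BIS)
    include_metab: bool = True
    include_moaas: bool = True
    include_bis: bool = True
    dosing: Callable[[float], InfusionSchedule] = default_dosing
    iiv: IIVSpec = field(default_factory=IIVSpec)
    theta: ThetaTable = field(default_factory=ThetaTable)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma_pk < 0 or self.sigma_bis < 0:
            raise ValueError("residual SDs must be >= 0")
        for lo, hi in (self.age_range, self.weight_range):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")


@dataclass(frozen=True)
class Subject:
    """One virtual subject: covariates, true etas, individualised model and
    a private random stream for observation noise."""

    id: int
    cov: SubjectCovariates
    etas: dict[str, np.ndarray]
    model: SubjectModel
    seedseq: np.random.SeedSequence


def sample_population(spec: PopulationSpec) -> list[Subject]:
    """Draw covariates and log-normal etas for ``spec.n`` subjects.

    Etas are independent Normal(0, omega^2) per parameter; the remimazolam CL
    eta of venous-only subjects is drawn with variance inflated by the
    published multiplier.  Reproducible bit-for-bit under a fixed seed, with
    disjoint random streams per subject.
    """
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.n + 1)
    rng = np.random.default_rng(children[0])
    iiv = spec.iiv
    subjects = []
    for sid in range(spec.n):
        cov = SubjectCovariates(
            age=float(rng.uniform(*spec.age_range)),
            weight=float(rng.uniform(*spec.weight_range)),
            sex="female" if rng.random() < spec.female_fraction else "male",
            opioids_present=bool(rng.random() < spec.opioid_prevalence),
            pugh_gt8=bool(rng.random() < spec.pugh_prevalence),
            esrd=bool(rng.random() < spec.esrd_prevalence),
            venous_only=bool(rng.random() < spec.venous_only_fraction),
        )
        w2_remi = iiv.remi_omega2().copy()
        if cov.venous_only:
            w2_remi[3] *= iiv.venous_cl_variance_multiplier
        etas = {
            "remi": rng.normal(0.0, np.sqrt(w2_remi)),
            "metab": rng.normal(0.0, np.sqrt(iiv.metab_omega2())),
            "moaas": rng.normal(0.0, np.sqrt([iiv.moaas_ce50])),
            "bis": rng.normal(0.0, np.sqrt([iiv.bis_ke0, iiv.bis_ce50])),
        }
        model = individual_parameters(cov, spec.theta, etas)
        subjects.append(Subject(id=sid + 1, cov=cov, etas=etas, model=model,
                                seedseq=children[sid + 1]))
    return subjects


@dataclass(frozen=True)
class SyntheticDataset:
    """Long-format dataset plus a sidecar of ground truth."""

    table: pd.DataFrame
    truth: dict

    def write(self, csv_path, sidecar_path=None) -> None:
        from .dataset import write_dataset
        write_dataset(self.table, csv_path)
        if sidecar_path is not None:
            import json
            with open(sidecar_path, "w") as fh:
                json.dump(self.truth, fh, indent=1)


def _median_filter_epochs(t_s: np.ndarray, y: np.ndarray,
                          epoch_s: float = BIS_EPOCH_S):
    """Median per consecutive epoch; stamps each epoch at its end time."""
    n_ep = int(len(t_s) // epoch_s)
    tt, yy = [], []
    for k in range(n_ep):
        sl = slice(int(k * epoch_s), int((k + 1) * epoch_s))
        tt.append(t_s[sl][-1])
        yy.append(float(np.median(y[sl])))
    return np.array(tt), np.array(yy)


def _covariate_columns(cov: SubjectCovariates) -> dict:
    return {
        "AGE": cov.age, "WGT": cov.weight,
        "SEX": 1 if cov.sex == "male" else 2,
        "OPI": int(cov.opioids_present), "PUGH": int(cov.pugh_gt8),
        "ESRD": int(cov.esrd), "ECMO": int(cov.ecmo_subject),
        "ECMOACT": int(cov.ecmo_active), "ICU": int(cov.icu_subject),
        "ICU24": int(cov.icu_gt24h), "VENOUS": int(cov.venous_only),
    }


def generate_observations(
    subjects: Sequence[Subject], spec: PopulationSpec
) -> SyntheticDataset:
    """Simulate each subject under the dosing template and emit observations.

    Produces a NONMEM-style long table (ID, TIME, EVID, AMT, RATE, CMT, DV,
    MDV, TYPE + covariates) and a JSON-ready sidecar with each subject's
    covariates, true etas and individualised parameters.
    """
    rows = []
    truth_subjects = []
    for s in subjects:
        rng = np.random.default_rng(s.seedseq.spawn(1)[0])
        schedule = spec.dosing(s.cov.weight)
        t_start = min(e.time for e in schedule)
        system = build_system(s.model.remi, s.model.metab,
                              s.model.moaas.ke0, s.model.bis.ke0)
        covcols = _covariate_columns(s.cov)

        for ev in schedule:
            rows.append({"ID": s.id, "TIME": ev.time, "EVID": 1,
                         "AMT": ev.amount, "RATE": ev.rate, "CMT": 1,
                         "DV": 0.0, "MDV": 1, "TYPE": "dose", **covcols})

        pk_times = np.asarray(spec.pk_sample_times, dtype=float)
        early = pk_times < t_start
        if early.any():
            warnings.warn("PK design times before first dose were excluded")
            pk_times = pk_times[~early]
        moaas_times = np.asarray(spec.moaas_sample_times, dtype=float)
        moaas_times = moaas_times[moaas_times >= t_start]

        grids = [pk_times, moaas_times]
        if spec.include_bis and spec.bis_duration > 0:
            bis_stream_t = np.arange(0.0, spec.bis_duration * 60.0 + 1) / 60.0
            grids.append(bis_stream_t)
        all_times = np.unique(np.concatenate(grids))
        tc = simulate(system, schedule, all_times)
        at = dict(zip(np.round(all_times, 9), range(all_times.size)))

        def sig_at(name, times):
            idx = [at[round(float(t), 9)] for t in times]
            return getattr(tc, name)[idx]

        site = "remi_ven" if s.cov.venous_only else "remi_art"
        sitem = "metab_ven" if s.cov.venous_only else "metab_art"

        keep = pk_times >= t_start + REMI_EXCLUSION_MIN
        conc = sig_at("cven" if s.cov.venous_only else "cp_art", pk_times[keep])
        dv = conc * np.exp(rng.normal(0.0, spec.sigma_pk, conc.size))
        for t, v in zip(pk_times[keep], dv):
            rows.append({"ID": s.id, "TIME": t, "EVID": 0, "AMT": 0.0,
                         "RATE": 0.0, "CMT": TYPE_CMT[site], "DV": v,
                         "MDV": 0, "TYPE": site, **covcols})

        if spec.include_metab:
            keep = pk_times >= t_start + METAB_EXCLUSION_MIN
            conc = sig_at("cven_metab" if s.cov.venous_only else "ca_metab",
                          pk_times[keep])
            dv = conc * np.exp(rng.normal(0.0, spec.sigma_pk, conc.size))
            for t, v in zip(pk_times[keep], dv):
                rows.append({"ID": s.id, "TIME": t, "EVID": 0, "AMT": 0.0,
                             "RATE": 0.0, "CMT": TYPE_CMT[sitem], "DV": v,
                             "MDV": 0, "TYPE": sitem, **covcols})

        if spec.include_moaas and moaas_times.size:
            ce = sig_at("ce_moaas", moaas_times)
            ca = sig_at("ca_metab", moaas_times)
            probs = moaas_probabilities(ce, ca, s.model.moaas,
                                        opioids=s.cov.opioids_present).probs
            for t, p in zip(moaas_times, probs):
                score = int(rng.choice(6, p=p / p.sum()))
                rows.append({"ID": s.id, "TIME": t, "EVID": 0, "AMT": 0.0,
                             "RATE": 0.0, "CMT": TYPE_CMT["MOAAS"],
                             "DV": float(score), "MDV": 0, "TYPE": "MOAAS",
                             **covcols})

        if spec.include_bis and spec.bis_duration > 0:
            baseline = s.model.bis.baseline + rng.normal(0.0, spec.sigma_bis)
            # 15-s signal-processing delay: the monitor reports the effect
            # that held 15 s earlier (drug-free baseline before that)
            ce = sig_at("ce_bis", bis_stream_t)
            ca = sig_at("ca_metab", bis_stream_t)
            shift = int(round(BIS_DELAY_MIN * 60))
            if shift:
                ce = np.concatenate([np.zeros(shift), ce[:-shift]])
                ca = np.concatenate([np.zeros(shift), ca[:-shift]])
            f = drug_effect_fraction(ce, ca, s.model.bis.ce50,
                                     s.model.bis.ca50, s.model.bis.gamma)
            stream = baseline * (1.0 - f) + rng.normal(0.0, spec.sigma_bis,
                                                       ce.size)
            t_ep, y_ep = _median_filter_epochs(bis_stream_t * 60.0, stream)
            for t, v in zip(t_ep / 60.0, y_ep):
                rows.append({"ID": s.id, "TIME": t, "EVID": 0, "AMT": 0.0,
                             "RATE": 0.0, "CMT": TYPE_CMT["BIS"], "DV": v,
                             "MDV": 0, "TYPE": "BIS", **covcols})

        truth_subjects.append({
            "id": s.id,
            "covariates": asdict(s.cov),
            "etas": {k: list(map(float, v)) for k, v in s.etas.items()},
            "params": {
                "remi": asdict(s.model.remi),
                "metab": asdict(s.model.metab),
                "moaas": asdict(s.model.moaas),
                "bis": asdict(s.model.bis),
            },
        })

    table = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"],
                                           kind="stable").reset_index(drop=True)
    truth = {
        "seed": spec.seed,
        "sigma_pk": spec.sigma_pk,
        "sigma_bis": spec.sigma_bis,
        "n": spec.n,
        "subjects": truth_subjects,
    }
    return SyntheticDataset(table=table, truth=truth)
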