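"""Covariate model mapping subject characteristics to individual PK/PD parameters.

Fixed effects are expressed relative to a reference individual: a 70-kg,
35-yr-old male without concomitant opioids and with normal hepatic and renal
function.  Weight enters through allometric size scaling (linear for volumes,
exponent 0.75 for clearances; the metabolite volumes use an estimated
exponent), age through exponential factors ``exp(K/1000 * (AGE - 35))`` and
binary covariates through factors ``exp(K/100)``.  Peripheral distribution
clearances use compartmental allometry, ``Q = Q_ref * (V/V_ref)**0.75``, so
covariate effects on a peripheral volume propagate into its clearance.

Interindividual variability is log-normal: each parameter with an omega^2
entry accepts a log-scale deviation eta, applied as ``exp(eta)``.  Subjects
receiving ECMO or treated in the ICU carry additional direct multiplicative
adjustments on the PK parameters.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

Sex = Literal["male", "female"]

__all__ = [
    "SubjectCovariates",
    "ThetaTable",
    "IIVSpec",
    "RemiPKParams",
    "MetabPKParams",
    "MOAASParams",
    "BISParams",
    "SubjectModel",
    "REFERENCE_AGE",
    "REFERENCE_WEIGHT",
    "REMI_ETA_ORDER",
    "METAB_ETA_ORDER",
    "remi_pk_params",
    "metab_pk_params",
    "moaas_params",
    "bis_params",
    "derive_opioid_cutpoints",
    "apply_ecmo_icu",
    "cv_from_omega2",
    "omega2_from_cv",
    "simplified_remi_params",
    "SIMPLIFIED_KE0",
    "individual_parameters",
]

REFERENCE_AGE = 35.0  # yr
REFERENCE_WEIGHT = 70.0  # kg

#: canonical ordering of the eta vectors accepted by the parameter builders
REMI_ETA_ORDER = ("v1", "v2", "v3", "cl", "q2", "q3")
METAB_ETA_ORDER = ("kdepot", "v1", "v2", "cl", "q2")
MOAAS_ETA_ORDER = ("ce50",)
BIS_ETA_ORDER = ("ke0", "ce50")


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographic and clinical covariates driving parameter individualisation.

    ``ecmo_active`` and ``icu_gt24h`` are time-varying in principle; here they
    describe the state that holds during the simulated episode.
    ``venous_only`` marks subjects whose drug levels are sampled only from
    venous blood, which inflates the variance of remimazolam clearance.
    """

    age: float  # yr
    weight: float  # kg, total body weight
    sex: Sex = "male"
    opioids_present: bool = False
    pugh_gt8: bool = False  # Pugh-Child score > 8 (severe hepatic dysfunction)
    esrd: bool = False  # end-stage renal disease
    ecmo_subject: bool = False
    ecmo_active: bool = False
    icu_subject: bool = False
    icu_gt24h: bool = False
    venous_only: bool = False

    def __post_init__(self) -> None:
        if not (self.age > 0):
            raise ValueError(f"age must be positive, got {self.age}")
        if not (self.weight > 0):
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.icu_gt24h and not self.icu_subject:
            raise ValueError("icu_gt24h implies icu_subject")
        if self.ecmo_active and not self.ecmo_subject:
            raise ValueError("ecmo_active implies ecmo_subject")


@dataclass(frozen=True)
class ThetaTable:
    """Fixed-effect estimates of the final model (plus ECMO/ICU adjustments).

    Units: volumes L, clearances L min^-1, rate constants min^-1,
    concentrations ug ml^-1.  Covariate coefficients named ``k_*`` are on the
    scales used in the published equations (divided by 1000 for age effects
    and by 100 for binary effects before exponentiation); the ECMO/ICU
    adjustments are direct multipliers.
    """

    # --- remimazolam PK ---
    # the remimazolam structural estimates are published twice: rounded to
    # 3 s.f. in the estimates table and at full precision in the simplified
    # population code; the full-precision printing is used here
    remi_v1_ref: float = 4.30730
    remi_v2_ref: float = 12.2994
    remi_v3_ref: float = 18.6411
    remi_cl_ref: float = 1.11977
    remi_q2_ref: float = 1.45260
    remi_q3_ref: float = 0.297838
    fven_pct: float = 13.2  # venous fraction, percent
    kdelay_ref: float = 0.0144
    k_v3_age: float = 7.30817
    k_cl_sex: float = 16.2802
    k_v3_sex: float = 28.7037
    k_cl_opiates: float = -13.9340
    k_v3_pugh: float = 82.4
    k_omega2_cl_ven: float = 1.86
    # --- CNS7054 (metabolite) PK ---
    m_kdepot: float = 0.215
    m_v1_ref: float = 6.85
    m_v2_ref: float = 5.12
    m_cl_ref: float = 0.0665
    m_q2_ref: float = 0.141
    m_k_cl_renal: float = -218.0
    m_kscale: float = 0.518
    m_k_cl_opiates: float = -32.8
    m_k_q2_pugh: float = 188.0
    m_k_q2_age: float = 15.7
    mass_conversion: float = 1.0  # remimazolam -> CNS7054 mass factor
    # --- MOAA/S PD ---
    moaas_deff: float = 19.9
    moaas_ke0: float = 0.298269  # full-precision printing; table rounds to 0.298
    moaas_b0: float = -16.6
    moaas_d01: float = 2.65
    moaas_d12: float = 0.942
    moaas_d23: float = 1.47
    moaas_d34: float = 2.54
    moaas_ce50_ref: float = 0.182
    moaas_ca50: float = 11.9
    moaas_k_ce50_age: float = -7.63
    moaas_k_d01_opiates: float = 1.67
    moaas_gamma: float = 1.0  # Hill exponent (not reported; configurable)
    # --- BIS PD ---
    bis_ke0_ref: float = 0.145
    bis_ce50_ref: float = 0.982
    bis_baseline: float = 93.7
    bis_ca50: float = 8.41
    bis_k_ce50_age: float = -16.4
    bis_k_ke0_age: float = -10.6
    bis_gamma: float = 1.0
    # --- ECMO / ICU adjustments (direct multipliers) ---
    k_v1_ecmo: float = 46.1  # remi V1 while ECMO is running
    k_v_iecmo: float = 0.189  # remi V1 and V2 for ECMO subjects
    k_v2m_iecmo: float = 2.03  # metabolite V2 for ECMO subjects
    k_v3_iecmo: float = 0.722  # remi V3 for ECMO subjects
    k_v3_icu: float = 1.59  # remi V3 for ICU subjects
    k_cl_iecmo: float = 0.815  # remi and metabolite CL for ECMO subjects
    k_cl_24h: float = 0.264  # remi CL for ICU treatment > 24 h
    k_cl_icu: float = 0.426  # metabolite CL for ICU subjects

    def __post_init__(self) -> None:
        positive = (
            "remi_v1_ref remi_v2_ref remi_v3_ref remi_cl_ref remi_q2_ref "
            "remi_q3_ref kdelay_ref m_kdepot m_v1_ref m_v2_ref m_cl_ref "
            "m_q2_ref m_kscale mass_conversion moaas_ke0 moaas_ce50_ref "
            "moaas_ca50 moaas_gamma bis_ke0_ref bis_ce50_ref bis_baseline "
            "bis_ca50 bis_gamma k_v1_ecmo k_v_iecmo k_v2m_iecmo k_v3_iecmo "
            "k_v3_icu k_cl_iecmo k_cl_24h k_cl_icu"
        ).split()
        for name in positive:
            if not (getattr(self, name) > 0):
                raise ValueError(f"theta field {name} must be > 0")
        for name in ("moaas_d01", "moaas_d12", "moaas_d23", "moaas_d34"):
            if getattr(self, name) < 0:
                raise ValueError(f"theta field {name} must be >= 0")
        if not (0.0 <= self.fven_pct <= 100.0):
            raise ValueError("fven_pct must lie in [0, 100]")

    @property
    def fven(self) -> float:
        """Venous fraction as a number in [0, 1]."""
        return self.fven_pct / 100.0

    def replace(self, **changes: float) -> "ThetaTable":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class IIVSpec:
    """Log-domain variances (omega^2) of the parameters carrying IIV."""

    remi_v1: float = 0.0631
    remi_v2: float = 0.203
    remi_v3: float = 0.138
    remi_cl: float = 0.0297
    remi_q2: float = 0.105
    remi_q3: float = 0.118
    m_kdepot: float = 0.257
    m_v1: float = 0.0888
    m_v2: float = 0.443
    m_cl: float = 0.145
    m_q2: float = 0.989
    moaas_ce50: float = 0.195
    bis_ke0: float = 0.549
    bis_ce50: float = 0.228
    venous_cl_variance_multiplier: float = 1.86

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "venous_cl_variance_multiplier":
                if not v > 0:
                    raise ValueError("variance multiplier must be > 0")
            elif v < 0:
                raise ValueError(f"omega^2 {f.name} must be >= 0")

    def remi_omega2(self) -> np.ndarray:
        return np.array(
            [self.remi_v1, self.remi_v2, self.remi_v3, self.remi_cl,
             self.remi_q2, self.remi_q3]
        )

    def metab_omega2(self) -> np.ndarray:
        return np.array(
            [self.m_kdepot, self.m_v1, self.m_v2, self.m_cl, self.m_q2]
        )

    def replace(self, **changes: float) -> "IIVSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class RemiPKParams:
    V1: float  # L
    V2: float  # L
    V3: float  # L
    CL: float  # L min^-1
    Q2: float  # L min^-1
    Q3: float  # L min^-1
    fven: float  # fraction in [0, 1]
    kdelay: float  # min^-1

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "V3", "CL", "Q2", "Q3", "kdelay"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.fven <= 1.0):
            raise ValueError("fven must lie in [0, 1]")


@dataclass(frozen=True)
class MetabPKParams:
    kdepot: float  # min^-1
    V1m: float  # L
    V2m: float  # L
    CLm: float  # L min^-1
    Q2m: float  # L min^-1
    mass_conversion: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kdepot", "V1m", "V2m", "CLm", "Q2m", "mass_conversion"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class MOAASParams:
    """Proportional-odds MOAA/S parameters with opioid-adjusted cut-points.

    The cumulative logit of score 0 is ``b0 + DEFF * f(Ce, Ca)`` where the
    drug-effect fraction ``f`` is the competitive-interaction Hill kernel;
    successive cumulative logits add the (strictly positive) cut-point
    differences d01, d12, d23, d34.  When opioids are present the (b0, d01)
    pair is replaced by (b0_op, d01_op), shifting probability mass from score
    1 to score 0 while leaving P(S<=1) unchanged.
    """

    ke0: float  # min^-1
    b0: float
    d01: float
    d12: float
    d23: float
    d34: float
    b0_op: float
    d01_op: float
    deff: float
    ce50: float  # ug ml^-1
    ca50: float  # ug ml^-1
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ke0", "ce50", "ca50", "gamma"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        for name in ("d01", "d12", "d23", "d34", "d01_op"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (monotone cumulative logits)")


@dataclass(frozen=True)
class BISParams:
    ke0: float  # min^-1
    ce50: float  # ug ml^-1
    ca50: float  # ug ml^-1
    baseline: float  # BIS units
    gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ke0", "ce50", "ca50", "baseline", "gamma"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if not (self.baseline <= 100.0):
            raise ValueError("baseline must be <= 100")


def _f_age(k: float, age: float) -> float:
    return math.exp(k / 1000.0 * (age - REFERENCE_AGE))


def _f_bin(k: float, flag: bool) -> float:
    return math.exp(k / 100.0) if flag else 1.0


def _eta(eta, n: int, what: str) -> np.ndarray:
    if eta is None:
        return np.zeros(n)
    arr = np.asarray(eta, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{what} eta vector must have length {n}, got shape {arr.shape}")
    return arr


def remi_pk_params(
    cov: SubjectCovariates,
    theta: ThetaTable | None = None,
    eta: Sequence[float] | None = None,
) -> RemiPKParams:
    """Individualised remimazolam PK parameters.

    ``eta`` follows :data:`REMI_ETA_ORDER` (V1, V2, V3, CL, Q2, Q3); omit it
    (or pass zeros) for the population prediction.
    """
    t = theta or DEFAULT_THETA
    e = _eta(eta, 6, "remimazolam")
    female = cov.sex == "female"
    fsize = cov.weight / REFERENCE_WEIGHT
    v1 = t.remi_v1_ref * fsize * math.exp(e[0])
    v2 = t.remi_v2_ref * fsize * math.exp(e[1])
    v3 = (
        t.remi_v3_ref * fsize
        * _f_age(t.k_v3_age, cov.age)
        * _f_bin(t.k_v3_sex, female)
        * _f_bin(t.k_v3_pugh, cov.pugh_gt8)
        * math.exp(e[2])
    )
    cl = (
        t.remi_cl_ref * fsize ** 0.75
        * _f_bin(t.k_cl_sex, female)
        * _f_bin(t.k_cl_opiates, cov.opioids_present)
        * math.exp(e[3])
    )
    q2 = t.remi_q2_ref * (v2 / t.remi_v2_ref) ** 0.75 * math.exp(e[4])
    q3 = t.remi_q3_ref * (v3 / t.remi_v3_ref) ** 0.75 * math.exp(e[5])
    return RemiPKParams(V1=v1, V2=v2, V3=v3, CL=cl, Q2=q2, Q3=q3,
                        fven=t.fven, kdelay=t.kdelay_ref)


def metab_pk_params(
    cov: SubjectCovariates,
    theta: ThetaTable | None = None,
    eta: Sequence[float] | None = None,
) -> MetabPKParams:
    """Individualised CNS7054 PK parameters (eta order: Kdepot, V1, V2, CL, Q2)."""
    t = theta or DEFAULT_THETA
    e = _eta(eta, 5, "CNS7054")
    fsize_v = (cov.weight / REFERENCE_WEIGHT) ** t.m_kscale
    kdepot = t.m_kdepot * math.exp(e[0])
    v1m = t.m_v1_ref * fsize_v * math.exp(e[1])
    v2m = t.m_v2_ref * fsize_v * math.exp(e[2])
    clm = (
        t.m_cl_ref * (cov.weight / REFERENCE_WEIGHT) ** 0.75
        * _f_bin(t.m_k_cl_renal, cov.esrd)
        * _f_bin(t.m_k_cl_opiates, cov.opioids_present)
        * math.exp(e[3])
    )
    q2m = (
        t.m_q2_ref * (v2m / t.m_v2_ref) ** 0.75
        * _f_age(t.m_k_q2_age, cov.age)
        * _f_bin(t.m_k_q2_pugh, cov.pugh_gt8)
        * math.exp(e[4])
    )
    return MetabPKParams(kdepot=kdepot, V1m=v1m, V2m=v2m, CLm=clm, Q2m=q2m,
                         mass_conversion=t.mass_conversion)


def derive_opioid_cutpoints(b0: float, d01: float, k_d01_opiates: float) -> tuple[float, float]:
    """Opioid-adjusted MOAA/S intercept and first cut-point difference.

    The adjustment shrinks the 0/1 cut-point difference,
    ``d01_op = d01 * exp(-K)``, and raises the intercept by the difference so
    the cumulative logit for scores <= 1 is unchanged:
    ``b0_op + d01_op = b0 + d01`` exactly.  P(S=0) therefore increases while
    P(S<=1) is invariant to opioid status.
    """
    if d01 < 0:
        raise ValueError("d01 must be >= 0")
    d01_op = d01 * math.exp(-k_d01_opiates)
    b0_op = b0 + d01 - d01_op
    return b0_op, d01_op


def moaas_params(
    cov: SubjectCovariates,
    theta: ThetaTable | None = None,
    eta: Sequence[float] | None = None,
) -> MOAASParams:
    """Individualised MOAA/S PD parameters (single eta on Ce50; ke0 has no IIV)."""
    t = theta or DEFAULT_THETA
    e = _eta(eta, 1, "MOAA/S")
    ce50 = t.moaas_ce50_ref * _f_age(t.moaas_k_ce50_age, cov.age) * math.exp(e[0])
    b0_op, d01_op = derive_opioid_cutpoints(t.moaas_b0, t.moaas_d01, t.moaas_k_d01_opiates)
    return MOAASParams(
        ke0=t.moaas_ke0, b0=t.moaas_b0, d01=t.moaas_d01, d12=t.moaas_d12,
        d23=t.moaas_d23, d34=t.moaas_d34, b0_op=b0_op, d01_op=d01_op,
        deff=t.moaas_deff, ce50=ce50, ca50=t.moaas_ca50, gamma=t.moaas_gamma,
    )


def bis_params(
    cov: SubjectCovariates,
    theta: ThetaTable | None = None,
    eta: Sequence[float] | None = None,
) -> BISParams:
    """Individualised BIS PD parameters (eta order: ke0, Ce50)."""
    t = theta or DEFAULT_THETA
    e = _eta(eta, 2, "BIS")
    ke0 = t.bis_ke0_ref * _f_age(t.bis_k_ke0_age, cov.age) * math.exp(e[0])
    ce50 = t.bis_ce50_ref * _f_age(t.bis_k_ce50_age, cov.age) * math.exp(e[1])
    return BISParams(ke0=ke0, ce50=ce50, ca50=t.bis_ca50,
                     baseline=t.bis_baseline, gamma=t.bis_gamma)


def apply_ecmo_icu(
    remi: RemiPKParams,
    metab: MetabPKParams,
    cov: SubjectCovariates,
    theta: ThetaTable | None = None,
) -> tuple[RemiPKParams, MetabPKParams]:
    """Apply the ECMO/ICU adjustments as direct multiplicative factors.

    With all flags false the parameters are returned unchanged ("otherwise 1").
    """
    t = theta or DEFAULT_THETA
    v1 = remi.V1
    if cov.ecmo_active:
        v1 *= t.k_v1_ecmo
    v2, v3, cl = remi.V2, remi.V3, remi.CL
    if cov.ecmo_subject:
        v1 *= t.k_v_iecmo
        v2 *= t.k_v_iecmo
        v3 *= t.k_v3_iecmo
        cl *= t.k_cl_iecmo
    if cov.icu_subject:
        v3 *= t.k_v3_icu
    if cov.icu_gt24h:
        cl *= t.k_cl_24h
    v2m, clm = metab.V2m, metab.CLm
    if cov.ecmo_subject:
        v2m *= t.k_v2m_iecmo
        clm *= t.k_cl_iecmo
    if cov.icu_subject:
        clm *= t.k_cl_icu
    remi_adj = dataclasses.replace(remi, V1=v1, V2=v2, V3=v3, CL=cl)
    metab_adj = dataclasses.replace(metab, V2m=v2m, CLm=clm)
    return remi_adj, metab_adj


def cv_from_omega2(omega2: float) -> float:
    """Coefficient of variation (%) implied by a log-normal variance.

    ``CV = 100 * sqrt(exp(omega^2) - 1)``.
    """
    w = np.asarray(omega2, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega^2 must be >= 0")
    out = 100.0 * np.sqrt(np.expm1(w))
    return float(out) if out.ndim == 0 else out


def omega2_from_cv(cv_pct: float) -> float:
    """Inverse of :func:`cv_from_omega2`."""
    c = np.asarray(cv_pct, dtype=float)
    if np.any(c < 0):
        raise ValueError("CV must be >= 0")
    out = np.log1p((c / 100.0) ** 2)
    return float(out) if out.ndim == 0 else out


#: effect-site rate constant printed alongside the simplified population code
SIMPLIFIED_KE0 = 0.298269


def simplified_remi_params(
    age: float, weight: float, sex: Sex, opioids: bool
) -> RemiPKParams:
    """Bit-faithful transcription of the published simplified population code.

    Population prediction for normal hepatic function; serves as an internal
    oracle for :func:`remi_pk_params` (agreement limited only by the rounding
    of the published fixed effects).
    """
    m1f2 = 1 if sex == "male" else 2
    oa1p2 = 2 if opioids else 1
    kocl = -0.139340 * (oa1p2 - 1)
    ksv3 = 0.287037 * (m1f2 - 1)
    kscl = 0.162802 * (m1f2 - 1)
    kav3 = 0.00730817 * (age - 35)
    vsiz = weight / 70
    csiz = (weight / 70.0) ** 0.75
    v1 = vsiz * 4.30730
    v2 = vsiz * 12.2994
    v3 = vsiz * 18.6411 * math.exp(kav3 + ksv3)
    cl = csiz * 1.11977 * math.exp(kscl + kocl)
    q2 = (vsiz ** 0.75) * 1.45260
    q3 = ((v3 / 18.6411) ** 0.75) * 0.297838
    return RemiPKParams(V1=v1, V2=v2, V3=v3, CL=cl, Q2=q2, Q3=q3,
                        fven=DEFAULT_THETA.fven, kdelay=DEFAULT_THETA.kdelay_ref)


@dataclass(frozen=True)
class SubjectModel:
    """Complete individualised parameter set for one subject."""

    cov: SubjectCovariates
    remi: RemiPKParams
    metab: MetabPKParams
    moaas: MOAASParams
    bis: BISParams


def individual_parameters(
    cov: SubjectCovariates,
    theta: ThetaTable | None = None,
    etas: Mapping[str, Sequence[float]] | None = None,
    adjust_ecmo_icu: bool = True,
) -> SubjectModel:
    """Build all individualised parameters for one subject.

    ``etas`` maps block names {'remi', 'metab', 'moaas', 'bis'} to eta vectors
    in canonical order; missing blocks default to zero (population prediction).
    ECMO/ICU multipliers are applied according to the subject's flags unless
    ``adjust_ecmo_icu`` is false.
    """
    etas = etas or {}
    remi = remi_pk_params(cov, theta, etas.get("remi"))
    metab = metab_pk_params(cov, theta, etas.get("metab"))
    if adjust_ecmo_icu:
        remi, metab = apply_ecmo_icu(remi, metab, cov, theta)
    return SubjectModel(
        cov=cov,
        remi=remi,
        metab=metab,
        moaas=moaas_params(cov, theta, etas.get("moaas")),
        bis=bis_params(cov, theta, etas.get("bis")),
    )


DEFAULT_THETA = ThetaTable()
DEFAULT_IIV = IIVSpec()
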