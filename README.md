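# remipkpd

A population pharmacokinetic–pharmacodynamic (PK–PD) toolkit for the
intravenous benzodiazepine **remimazolam** and its pharmacologically inactive
metabolite **CNS7054**, for anaesthesia researchers and pharmacometricians
who need individualised concentration and effect predictions, effect-site
target-controlled infusion (TCI) planning, virtual clinical trials, or a
testbed for estimation workflows.

## The model

**Pharmacokinetics.** Remimazolam follows a three-compartment mammillary
model (V1, V2, V3; elimination clearance CL; distribution clearances Q2, Q3).
Arterial concentration is Cp = A1/V1; venous concentration mixes the central
signal with a first-order delay compartment, Cven = F·Cp + (1−F)·Cdel,
dCdel/dt = k_delay (Cp − Cdel). All eliminated remimazolam is converted to
CNS7054, which enters a depot compartment and transfers at first order
(k_depot) into its own two-compartment model. Fixed effects are relative to
a 70-kg, 35-yr-old male without opioids and with normal hepatic and renal
function; weight scales volumes linearly (remimazolam) or with an estimated
exponent of 0.518 (CNS7054) and clearances with exponent 0.75; age enters as
exp(K/1000·(AGE−35)) and binary covariates (sex, opioids, Pugh–Child > 8,
end-stage renal disease) as exp(K/100). Distribution clearances use
compartmental allometry, Q = Q_ref (V/V_ref)^0.75. Separate multiplicative
adjustments describe subjects on ECMO or treated in the ICU.
Interindividual variability is log-normal, with the remimazolam CL variance
inflated 1.86× for venous-only sampling.

**Pharmacodynamics.** Both drug effects are driven by an effect site,
dCe/dt = ke0 (Cp − Ce), and share a competitive-interaction kernel in which
arterial CNS7054 (Ca) antagonises the remimazolam effect:

    f(Ce, Ca) = (Ce/Ce50)^γ / (1 + (Ce/Ce50)^γ + (Ca/Ca50)^γ)

The MOAA/S sedation score (0–5) is a proportional-odds model whose score-0
cumulative logit is b0 + DEFF·f, with positive cut-point differences d01,
d12, d23, d34 building the remaining logits; with opioids present, (b0, d01)
are replaced by an adjusted pair that leaves P(S ≤ 1) unchanged while moving
probability from score 1 to 0. BIS is the sigmoid BIS = baseline·(1 − f).
Because CNS7054 is cleared ~20-fold more slowly than remimazolam, Ca
accumulates during long infusions and predicted effect drifts toward lighter
levels at constant Ce — the model's account of apparent tolerance.

## Worked example

Effect-site TCI for anaesthesia (≥ 90 % probability of MOAA/S 0 at target
attainment) in a 45-yr-old, 70-kg male with opioids:

```python
from remipkpd import SubjectCovariates, individual_parameters
from remipkpd.tci import TCITarget, find_sedation_target, plan_tci

cov = SubjectCovariates(age=45, weight=70, sex="male", opioids_present=True)
model = individual_parameters(cov)
tr = find_sedation_target(model, "anaesthesia")
plan = plan_tci(model, TCITarget(target=tr.target, duration=60.0))
```

prints (via the summary fields):

```
target          0.881 ug/ml (5.22 x Ce50)
induction dose  15.4 mg (0.219 mg/kg) in 3.0 min
maintenance     0.86 mg/kg/h (min 30-60)
at 60 min       P(MOAA/S=0) = 0.79, BIS = 55.1
```

The target is the constant effect-site concentration meeting the clinical
criterion; the induction dose is the cumulative dose until Ce first reaches
99 % of it (0.219 mg/kg sits inside the 0.14–0.37 mg/kg envelope reported
across clinical induction studies); the maintenance rate is the mean pump
rate over minutes 30–60. The drop of P(MOAA/S = 0) from 0.90 at induction to
0.79 at 60 min, at a constant remimazolam effect-site concentration, is the
metabolite-mediated tolerance drift.

The same is available from the shell:

```
remipkpd tci --age 45 --weight 70 --sex m --opioids --scenario anaesthesia
remipkpd params --age 35 --weight 70 --sex m
remipkpd cohort --n 20 --seed 1 --out cohort.csv --sidecar truth.json
remipkpd recover --data cohort.csv --sidecar truth.json --out recovery.json
```

## Layout

| module | contents |
| --- | --- |
| `remipkpd.covariates` | covariate → parameter engine, ECMO/ICU adjustments, CV↔ω² |
| `remipkpd.system` | compartmental system, matrix-exponential simulator, peak-effect timing, dose-record merging |
| `remipkpd.effects` | MOAA/S proportional-odds and BIS models, tolerance evaluation |
| `remipkpd.tci` | plasma / effect-site TCI controller, clinical target search, dosing-by-age tables |
| `remipkpd.cohort` | virtual-cohort generator (NONMEM-style long format + truth sidecar) |
| `remipkpd.fit` | MdPE/MdAPE metrics, MAP eta recovery, pooled fixed-effect ML |
| `remipkpd.dataset`, `remipkpd.config`, `remipkpd.cli` | dataset I/O, YAML/JSON configuration, command line |

See `docs/methods.md` for modelling assumptions, parameter provenance,
numerical choices and known limitations.
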