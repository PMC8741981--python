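"""Seedable synthetic cohorts with the study's two-group structure.

The source cohort (130 prolonged-ventilated, tracheotomized patients; 100
successful and 30 failed first spontaneous breathing trials) is not public,
so this module generates cohorts whose group-wise distributions of the
ventilatory primitives, blood gases, demographics and comorbidity
prevalences match the published group summaries.  Primitives are drawn
first (tidal volume, respiratory rate, PEEP, Pmax, PaCO2, ...) and every
derived index is always recomputed from them through :mod:`.indices`, so
the algebraic identities between indices hold on generated data exactly as
they would on real records.

Post-SBT observations are constructed so that the outcome classifier
reproduces the intended group label: failure records present hypercapnia
(PaCO2 > 45 mmHg) or, for the configurable number of records with a
missing end-of-trial blood gas, an overt vital-sign violation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .indices import (DomainError, FAILURE, PACO2_LIMIT, PatientRecord,
                      PostSbtObservation, SUCCESS, classify_sbt_outcome)

MAX_REDRAWS = 1000


@dataclass(frozen=True)
class TruncNorm:
    """Truncated-normal draw parameters: mean, sd and truncation bounds."""

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self):
        if self.sd < 0:
            raise DomainError(f"sd must be non-negative, got {self.sd}")
        if not self.lo < self.hi:
            raise DomainError(f"empty truncation interval [{self.lo}, {self.hi}]")

    @classmethod
    def around(cls, mean: float, sd: float, n_sd: float = 3.0,
               lo: float = -math.inf, hi: float = math.inf) -> "TruncNorm":
        """Symmetric mean +/- n_sd truncation, tightened by optional bounds."""
        return cls(mean, sd, max(lo, mean - n_sd * sd), min(hi, mean + n_sd * sd))

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        for _ in range(MAX_REDRAWS):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return x
        raise DomainError(f"could not draw within [{self.lo}, {self.hi}] "
                          f"from N({self.mean}, {self.sd}^2)")

    def expected_mean(self) -> float:
        """Mean of the truncated distribution (for convergence checks)."""
        if self.sd == 0:
            return self.mean
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return float(stats.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class GroupParams:
    """Per-group primitive distributions and prevalences."""

    tidal_volume: TruncNorm        # mL
    respiratory_rate: TruncNorm    # breaths/min
    peep: TruncNorm                # cmH2O
    pmax: TruncNorm                # cmH2O
    paco2_mv: TruncNorm            # mmHg
    pao2_mv: TruncNorm             # mmHg
    ph_mv: TruncNorm
    fio2: TruncNorm                # fraction
    age: TruncNorm                 # years
    height_male: TruncNorm         # cm
    height_female: TruncNorm       # cm
    bmi: TruncNorm                 # kg/m^2; truncation refined by obesity flag
    male_prevalence: float
    copd_prevalence: float
    smoking_prevalence: float
    malignancy_prevalence: float
    obesity_prevalence: float
    post_paco2_shift: TruncNorm    # mmHg, post minus pre SBT
    post_bf: TruncNorm             # breaths/min (non-violating range)
    post_hr: TruncNorm             # bpm
    post_sbp: TruncNorm            # mmHg
    post_spo2: TruncNorm           # %
    post_ph_shift: TruncNorm
    post_pao2_shift: TruncNorm     # mmHg


def _default_success() -> GroupParams:
    return GroupParams(
        tidal_volume=TruncNorm.around(547, 83, lo=200),
        respiratory_rate=TruncNorm.around(16.5, 2.7, lo=8),
        peep=TruncNorm.around(6.0, 0.9, lo=3, hi=8.0),
        pmax=TruncNorm.around(22.8, 4.1, lo=10),
        paco2_mv=TruncNorm.around(33.9, 4.8, lo=20),
        pao2_mv=TruncNorm.around(85.0, 15.9, lo=45),
        ph_mv=TruncNorm.around(7.50, 0.05),
        fio2=TruncNorm.around(0.27, 0.05, lo=0.21, hi=0.40),
        age=TruncNorm.around(68, 12, lo=18, hi=95),
        height_male=TruncNorm.around(175, 7),
        height_female=TruncNorm.around(165, 7),
        bmi=TruncNorm.around(26.5, 5.0, lo=15, hi=55),
        male_prevalence=0.66,
        copd_prevalence=0.16,
        smoking_prevalence=0.29,
        malignancy_prevalence=0.05,
        obesity_prevalence=0.28,
        post_paco2_shift=TruncNorm.around(2.4, 4.4),
        post_bf=TruncNorm.around(24, 5, lo=8, hi=35),
        post_hr=TruncNorm.around(92, 14, lo=45, hi=130),
        post_sbp=TruncNorm.around(124, 14, lo=80, hi=160),
        post_spo2=TruncNorm.around(95, 2, lo=92, hi=100),
        post_ph_shift=TruncNorm.around(-0.02, 0.05),
        post_pao2_shift=TruncNorm.around(-7.6, 22.2),
    )


def _default_failure() -> GroupParams:
    return replace(
        _default_success(),
        tidal_volume=TruncNorm.around(547, 97, lo=200),
        respiratory_rate=TruncNorm.around(16.5, 2.0, lo=8),
        peep=TruncNorm.around(6.0, 0.8, lo=3, hi=8.0),
        pmax=TruncNorm.around(26.3, 3.5, lo=10),
        paco2_mv=TruncNorm.around(38.8, 4.5, lo=20),
        pao2_mv=TruncNorm.around(79.4, 15.5, lo=45),
        ph_mv=TruncNorm.around(7.48, 0.05),
        fio2=TruncNorm.around(0.28, 0.04, lo=0.21, hi=0.40),
        age=TruncNorm.around(69, 8, lo=18, hi=95),
        bmi=TruncNorm.around(29.0, 6.0, lo=15, hi=55),
        male_prevalence=0.533,
        copd_prevalence=0.467,
        smoking_prevalence=0.633,
        malignancy_prevalence=0.167,
        obesity_prevalence=0.40,
        post_paco2_shift=TruncNorm.around(10.2, 7.2),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults reproduce the published group summaries: 100 successful and 30
    failed trials (23.1% failure), group-wise ventilatory and blood-gas
    moments, comorbidity prevalences, post-SBT PaCO2 shifts, and 7 failure
    records with a missing end-of-trial blood gas.
    """

    n_success: int = 100
    n_failure: int = 30
    success: GroupParams = field(default_factory=_default_success)
    failure: GroupParams = field(default_factory=_default_failure)
    n_missing_post_abg: int = 7
    outcome_mechanism: str = "group_label"
    seed: int = 0

    def __post_init__(self):
        if self.n_success <= 0 or self.n_failure <= 0:
            raise DomainError("group sizes must be positive")
        if not 0 <= self.n_missing_post_abg <= self.n_failure:
            raise DomainError("n_missing_post_abg must fit in the failure group")
        if self.outcome_mechanism != "group_label":
            raise DomainError(
                f"unsupported outcome mechanism {self.outcome_mechanism!r}; "
                "use generate_logistic_cohort for a known logistic mechanism")
        for g in (self.success, self.failure):
            for name in ("male_prevalence", "copd_prevalence",
                         "smoking_prevalence", "malignancy_prevalence",
                         "obesity_prevalence"):
                p = getattr(g, name)
                if not 0 <= p <= 1:
                    raise DomainError(f"{name} must be in [0, 1], got {p}")


def _draw_record(rng: np.random.Generator, params: GroupParams, label: str,
                 patient_id: str, missing_abg: bool) -> PatientRecord:
    gender = "male" if rng.random() < params.male_prevalence else "female"
    height = (params.height_male if gender == "male"
              else params.height_female).draw(rng)
    obese = rng.random() < params.obesity_prevalence
    # BMI drawn conditional on the obesity flag so flag and value agree.
    bmi_dist = (replace(params.bmi, lo=max(params.bmi.lo, 30.0)) if obese
                else replace(params.bmi, hi=min(params.bmi.hi, 29.999)))
    bmi = bmi_dist.draw(rng)
    body_mass = bmi * (height / 100.0) ** 2

    peep = params.peep.draw(rng)
    pmax = None
    for _ in range(MAX_REDRAWS):
        candidate = params.pmax.draw(rng)
        if candidate > peep + 2.0:
            pmax = candidate
            break
    if pmax is None:
        raise DomainError("could not draw Pmax exceeding PEEP + 2 cmH2O")

    paco2_mv = params.paco2_mv.draw(rng)

    comorbidities = set()
    if rng.random() < params.copd_prevalence:
        comorbidities.add("COPD")
    if rng.random() < params.smoking_prevalence:
        comorbidities.add("smoking")
    if rng.random() < params.malignancy_prevalence:
        comorbidities.add("malignancy")
    if obese:
        comorbidities.add("obesity")

    if label == SUCCESS:
        post = _success_post(rng, params, paco2_mv)
        duration = 30.0
    else:
        post = _failure_post(rng, params, paco2_mv, missing_abg)
        duration = float(rng.uniform(8.0, 30.0))

    return PatientRecord(
        patient_id=patient_id,
        gender=gender,
        age=params.age.draw(rng),
        height=height,
        body_mass=body_mass,
        tidal_volume=params.tidal_volume.draw(rng),
        respiratory_rate=params.respiratory_rate.draw(rng),
        peep=peep,
        pmax=pmax,
        fio2=params.fio2.draw(rng),
        paco2_mv=paco2_mv,
        pao2_mv=params.pao2_mv.draw(rng),
        ph_mv=params.ph_mv.draw(rng),
        minute_ventilation=None,  # derived as RR x VT
        post_sbt=post,
        comorbidities=frozenset(comorbidities),
        sbt_outcome=label,
        sbt_duration=duration,
    )


def _success_post(rng: np.random.Generator, params: GroupParams,
                  paco2_mv: float) -> PostSbtObservation:
    for _ in range(MAX_REDRAWS):
        paco2 = paco2_mv + params.post_paco2_shift.draw(rng)
        if 0 < paco2 <= PACO2_LIMIT:
            break
    else:
        raise DomainError("could not draw a normocapnic post-SBT PaCO2")
    return PostSbtObservation(
        breathing_frequency=params.post_bf.draw(rng),
        heart_rate=params.post_hr.draw(rng),
        systolic_bp=params.post_sbp.draw(rng),
        spo2=params.post_spo2.draw(rng),
        paco2=paco2,
        ph=params.ph_mv.mean + params.post_ph_shift.draw(rng),
        pao2=max(40.0, params.pao2_mv.mean + params.post_pao2_shift.draw(rng)),
    )


def _failure_post(rng: np.random.Generator, params: GroupParams,
                  paco2_mv: float, missing_abg: bool) -> PostSbtObservation:
    if missing_abg:
        # Severe distress: trial aborted on tachypnoea before the blood gas.
        return PostSbtObservation(
            breathing_frequency=TruncNorm.around(42, 4, lo=35.5, hi=60).draw(rng),
            heart_rate=params.post_hr.draw(rng),
            systolic_bp=params.post_sbp.draw(rng),
            spo2=params.post_spo2.draw(rng),
        )
    for _ in range(MAX_REDRAWS):
        paco2 = paco2_mv + params.post_paco2_shift.draw(rng)
        if paco2 > PACO2_LIMIT:
            break
    else:
        raise DomainError("could not draw a hypercapnic post-SBT PaCO2")
    return PostSbtObservation(
        breathing_frequency=params.post_bf.draw(rng),
        heart_rate=params.post_hr.draw(rng),
        systolic_bp=params.post_sbp.draw(rng),
        spo2=params.post_spo2.draw(rng),
        paco2=paco2,
        ph=params.ph_mv.mean - 0.09 + params.post_ph_shift.sd * rng.normal(),
        pao2=max(40.0, params.pao2_mv.mean + params.post_pao2_shift.draw(rng)),
    )


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a label-consistent synthetic cohort, reproducible per seed.

    Every returned record passes its invariants and the outcome classifier
    applied to its post-SBT observation reproduces the group label.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    plan = ([(SUCCESS, False)] * spec.n_success
            + [(FAILURE, i < spec.n_missing_post_abg)
               for i in range(spec.n_failure)])
    for i, (label, missing) in enumerate(plan):
        for _ in range(MAX_REDRAWS):
            rec = _draw_record(rng, spec.success if label == SUCCESS
                               else spec.failure, label,
                               patient_id=f"P{i + 1:04d}", missing_abg=missing)
            rec.validate()
            if classify_sbt_outcome(rec.post_sbt) == label:
                records.append(rec)
                break
        else:
            raise DomainError(
                f"could not generate a label-consistent {label} record "
                f"in {MAX_REDRAWS} redraws")
    return records


def generate_logistic_cohort(n: int, beta0: float, beta1: float,
                             pi_mean: float, pi_sd: float,
                             seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Index values and outcomes from an exactly known logistic mechanism.

    Draws the index from N(pi_mean, pi_sd^2) and the binary outcome from
    Bernoulli(expit(beta0 + beta1 * index)).  Used for odds-ratio recovery
    tests where the true effect must be known, unlike :func:`generate_cohort`
    where separation arises from the printed group means.

    Returns (values, outcomes) as aligned arrays.
    """
    if n <= 0:
        raise DomainError(f"n must be positive, got {n}")
    if pi_sd <= 0:
        raise DomainError(f"pi_sd must be positive, got {pi_sd}")
    rng = np.random.default_rng(seed)
    x = rng.normal(pi_mean, pi_sd, size=n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.random(n) < p).astype(int)
    return x, y


def calibrate_intercept(beta1: float, pi_mean: float, pi_sd: float,
                        prevalence: float) -> float:
    """Intercept giving a target marginal outcome prevalence.

    Solves E_X[expit(beta0 + beta1 X)] = prevalence for X ~ N(pi_mean,
    pi_sd^2) by Gauss-Hermite quadrature and bisection.
    """
    if not 0 < prevalence < 1:
        raise DomainError("prevalence must be in (0, 1)")
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    x = pi_mean + pi_sd * nodes
    w = weights / weights.sum()

    def marginal(beta0: float) -> float:
        return float(w @ (1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))))

    return float(optimize.brentq(
        lambda b0: marginal(b0) - prevalence, -60.0, 60.0))
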