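"""Per-patient ventilator-derived weaning predictors.

All candidate predictors are computed from a one-time pre-SBT measurement of
ventilator settings (pressure-controlled ventilation) and an arterial blood
gas: dynamic driving pressure, dynamic lung-thorax compliance, mechanical
power by the simplified pressure-controlled formula, its normalizations to
predicted body weight and to compliance, the PaCO2-corrected Power index of
the respiratory system, and the ventilatory ratio.  The spontaneous breathing
trial (SBT) outcome is classified from post-trial vital signs and blood gas.

Units follow bedside convention: pressures in cmH2O, tidal volume in mL at
the record boundary (litres inside the power formula), PaCO2 in mmHg, power
in J/min.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

#: J per (cmH2O x L); fixed at 0.098 so the mechanical-power and
#: compliance-normalized routes cancel exactly in the algebraic identity.
POWER_CONVERSION = 0.098

#: Isocapnic PaCO2 target for the Power index (mmHg).
TARGET_PACO2 = 45.0

#: Ideal-lung normalization constants of the ventilatory ratio:
#: predicted minute ventilation = PBW x 100 mL/min at PaCO2 37.5 mmHg.
VR_PREDICTED_MV_PER_KG = 100.0
VR_PREDICTED_PACO2 = 37.5

SUCCESS = "success"
FAILURE = "failure"

#: SBT failure cut-offs (strict inequalities).
BF_LIMIT = 35.0      # breaths/min
HR_LIMIT = 130.0     # bpm
SBP_LIMIT = 160.0    # mmHg
SPO2_LIMIT = 88.0    # %, failure below
PACO2_LIMIT = 45.0   # mmHg


class DomainError(ValueError):
    """A physical/physiological precondition was violated."""


@dataclass(frozen=True)
class PostSbtObservation:
    """Vitals and optional arterial blood gas at the end of the SBT.

    The blood gas may be absent when severe distress forced immediate
    resumption of mechanical ventilation.
    """

    breathing_frequency: Optional[float] = None  # breaths/min
    heart_rate: Optional[float] = None           # bpm
    systolic_bp: Optional[float] = None          # mmHg
    spo2: Optional[float] = None                 # %
    paco2: Optional[float] = None                # mmHg
    ph: Optional[float] = None
    pao2: Optional[float] = None                 # mmHg

    def validate(self) -> None:
        for name in ("breathing_frequency", "heart_rate", "systolic_bp",
                     "spo2", "paco2", "ph", "pao2"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"post-SBT {name} must be positive, got {v}")
        if self.spo2 is not None and self.spo2 > 100:
            raise DomainError(f"SpO2 cannot exceed 100%, got {self.spo2}")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's pre-SBT measurement, demographics and trial outcome."""

    patient_id: str
    gender: str                    # "male" | "female"
    age: float                     # years
    height: float                  # cm
    body_mass: float               # kg
    tidal_volume: float            # mL
    respiratory_rate: float        # breaths/min
    peep: float                    # cmH2O
    pmax: float                    # cmH2O, pre-set inspiratory pressure
    fio2: float                    # fraction
    paco2_mv: float                # mmHg, on ventilator pre-SBT
    pao2_mv: float                 # mmHg
    ph_mv: float
    minute_ventilation: Optional[float] = None  # L/min; RR x VT/1000 if absent
    post_sbt: Optional[PostSbtObservation] = None
    comorbidities: frozenset = field(default_factory=frozenset)
    sbt_outcome: Optional[str] = None  # "success" | "failure"
    sbt_duration: Optional[float] = None  # min

    def validate(self) -> None:
        if self.gender not in ("male", "female"):
            raise DomainError(f"unknown gender code {self.gender!r}")
        if not self.tidal_volume > 0:
            raise DomainError(f"tidal volume must be positive, got {self.tidal_volume}")
        if not self.respiratory_rate > 0:
            raise DomainError(f"respiratory rate must be positive, got {self.respiratory_rate}")
        if not self.peep >= 0:
            raise DomainError(f"PEEP must be non-negative, got {self.peep}")
        if not self.pmax > self.peep:
            raise DomainError(
                f"Pmax ({self.pmax}) must exceed PEEP ({self.peep})")
        if not 0.21 <= self.fio2 <= 1.0:
            raise DomainError(f"FiO2 must be in [0.21, 1.0], got {self.fio2}")
        if not self.paco2_mv > 0:
            raise DomainError(f"PaCO2 must be positive, got {self.paco2_mv}")
        if self.post_sbt is not None:
            self.post_sbt.validate()

    @property
    def minute_ventilation_effective(self) -> float:
        """Measured minute ventilation, or RR x VT when not recorded (L/min)."""
        if self.minute_ventilation is not None:
            return self.minute_ventilation
        return self.respiratory_rate * self.tidal_volume / 1000.0


@dataclass(frozen=True)
class IndexPanel:
    """All derived candidate predictors for one patient."""

    delta_paw: float    # cmH2O
    ltc_dyn: float      # mL/cmH2O
    mp: float           # J/min
    pbw: float          # kg
    pbw_mp: float       # J/min/kg
    ltcdyn_mp: float    # cmH2O^2/min
    pi_1: float         # cmH2O^2/min, exponent 1.0
    pi_2: float         # cmH2O^2/min, exponent 2.0
    vr: float           # dimensionless


def dynamic_driving_pressure(pmax: float, peep: float) -> float:
    """Dynamic driving pressure ΔPaw = Pmax − PEEP (cmH2O), PCV mode."""
    if not peep >= 0:
        raise DomainError(f"PEEP must be non-negative, got {peep}")
    if not pmax > peep:
        raise DomainError(
            f"driving pressure must be positive: Pmax {pmax} <= PEEP {peep}")
    return pmax - peep


def dynamic_compliance(tidal_volume: float, delta_paw: float) -> float:
    """Dynamic lung-thorax compliance LTCdyn = VT / ΔPaw (mL/cmH2O)."""
    if not tidal_volume > 0:
        raise DomainError(f"tidal volume must be positive, got {tidal_volume}")
    if not delta_paw > 0:
        raise DomainError(f"driving pressure must be positive, got {delta_paw}")
    return tidal_volume / delta_paw


def mechanical_power(respiratory_rate: float, tidal_volume_l: float,
                     pmax: float) -> float:
    """Mechanical power by the simplified PCV formula (J/min).

    MP = 0.098 x RR x VT x Pmax, with VT in litres and Pmax the total
    inspiratory pressure (PEEP + inspiratory driving pressure).  Equivalently
    0.098 x minute ventilation x Pmax.
    """
    if not (respiratory_rate > 0 and tidal_volume_l > 0 and pmax > 0):
        raise DomainError("mechanical power inputs must all be positive")
    if tidal_volume_l > 3.0:
        warnings.warn(
            f"tidal volume {tidal_volume_l} L looks like mL passed as litres",
            stacklevel=2)
    return POWER_CONVERSION * respiratory_rate * tidal_volume_l * pmax


def predicted_body_weight(gender: str, height: float) -> float:
    """Predicted body weight (kg), a surrogate of healthy total lung capacity.

    Standard height/gender formula: 50.0 (male) / 45.5 (female)
    + 0.91 x (height − 152.4 cm).
    """
    if gender not in ("male", "female"):
        raise DomainError(f"unknown gender code {gender!r}")
    if not 120 <= height <= 220:
        warnings.warn(f"height {height} cm outside plausible adult range",
                      stacklevel=2)
    base = 50.0 if gender == "male" else 45.5
    return base + 0.91 * (height - 152.4)


def pbw_normalized_mp(mp: float, pbw: float) -> float:
    """Mechanical power per kg predicted body weight (J/min/kg)."""
    if not (mp > 0 and pbw > 0):
        raise DomainError("PBW-MP inputs must be positive")
    return mp / pbw


def ltc_normalized_mp(mp: float, ltc_dyn: float) -> float:
    """Mechanical power normalized to compliance, LTCdyn-MP (cmH2O^2/min).

    MP / (0.098 x LTCdyn/1000): the pressure-volume conversion factors cancel,
    so when MP comes from the simplified formula this equals
    RR x Pmax x ΔPaw exactly — a stress-intensity surrogate independent of
    absolute lung size.
    """
    if not (mp > 0 and ltc_dyn > 0):
        raise DomainError("LTCdyn-MP inputs must be positive")
    return mp / (POWER_CONVERSION * ltc_dyn / 1000.0)


def power_index(ltcdyn_mp: float, paco2_mv: float, exponent: float = 1.0,
                target_paco2: float = TARGET_PACO2) -> float:
    """Power index of the respiratory system (cmH2O^2/min).

    LTCdyn-MP rescaled by (PaCO2/target)^exponent to simulate isocapnic
    conditions at the target (default 45 mmHg): patients ventilated to a low
    PaCO2 are doing more work than strictly required to normalize CO2, and
    the rescaling removes that operator-chosen component.
    """
    if not (ltcdyn_mp > 0 and paco2_mv > 0 and target_paco2 > 0):
        raise DomainError("power index inputs must be positive")
    if exponent < 0:
        raise DomainError(f"exponent must be non-negative, got {exponent}")
    return ltcdyn_mp * (paco2_mv / target_paco2) ** exponent


def ventilatory_ratio(minute_ventilation: float, paco2_mv: float,
                      pbw: float) -> float:
    """Ventilatory ratio, a dead-space surrogate (dimensionless).

    (MV[mL/min] x PaCO2) / (PBW x 100 x 37.5): measured CO2 clearance demand
    relative to that of an ideal lung of the same predicted size.
    """
    if not (minute_ventilation > 0 and paco2_mv > 0 and pbw > 0):
        raise DomainError("ventilatory ratio inputs must be positive")
    mv_ml = 1000.0 * minute_ventilation
    return (mv_ml * paco2_mv) / (pbw * VR_PREDICTED_MV_PER_KG * VR_PREDICTED_PACO2)


def compute_panel(record: PatientRecord) -> IndexPanel:
    """Compute all nine indices for one patient record (pure, deterministic)."""
    try:
        record.validate()
        delta_paw = dynamic_driving_pressure(record.pmax, record.peep)
        ltc = dynamic_compliance(record.tidal_volume, delta_paw)
        mp = mechanical_power(record.respiratory_rate,
                              record.tidal_volume / 1000.0, record.pmax)
        pbw = predicted_body_weight(record.gender, record.height)
        pbw_mp = pbw_normalized_mp(mp, pbw)
        ltcdyn_mp = ltc_normalized_mp(mp, ltc)
        pi_1 = power_index(ltcdyn_mp, record.paco2_mv, 1.0)
        pi_2 = power_index(ltcdyn_mp, record.paco2_mv, 2.0)
        vr = ventilatory_ratio(record.minute_ventilation_effective,
                               record.paco2_mv, pbw)
    except DomainError as exc:
        raise DomainError(f"patient {record.patient_id}: {exc}") from exc
    return IndexPanel(delta_paw=delta_paw, ltc_dyn=ltc, mp=mp, pbw=pbw,
                      pbw_mp=pbw_mp, ltcdyn_mp=ltcdyn_mp, pi_1=pi_1,
                      pi_2=pi_2, vr=vr)


def classify_sbt_outcome(obs: PostSbtObservation) -> str:
    """Classify the SBT as success or failure from end-of-trial observations.

    Failure on any objective sign of respiratory distress (breathing
    frequency > 35/min, heart rate > 130 bpm, systolic BP > 160 mmHg,
    SpO2 < 88%) or ventilatory failure (PaCO2 > 45.0 mmHg when a blood gas
    is available).  All cut-offs are strict; pH is recorded but never an
    independent trigger (acidosis accompanies hypercapnia, with or without).
    """
    obs.validate()
    decision_fields = (obs.breathing_frequency, obs.heart_rate,
                       obs.systolic_bp, obs.spo2, obs.paco2)
    if all(v is None for v in decision_fields):
        raise DomainError("no post-SBT vital or blood-gas value to classify on")
    if obs.breathing_frequency is not None and obs.breathing_frequency > BF_LIMIT:
        return FAILURE
    if obs.heart_rate is not None and obs.heart_rate > HR_LIMIT:
        return FAILURE
    if obs.systolic_bp is not None and obs.systolic_bp > SBP_LIMIT:
        return FAILURE
    if obs.spo2 is not None and obs.spo2 < SPO2_LIMIT:
        return FAILURE
    if obs.paco2 is not None and obs.paco2 > PACO2_LIMIT:
        return FAILURE
    return SUCCESS
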