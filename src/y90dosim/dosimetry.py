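"""MIRD partition-model dose engine and activity prescription policy.

Three compartments share the administered :sup:`90`Y activity: the tumor,
the injected healthy liver (IHL), and the lungs (via the shunt fraction SF).
With TLR the tumor-to-liver activity concentration ratio and masses in
grams,

    liver uptake = (1 − SF) · m_liver / (m_tumor·TLR + m_liver)
    tumor uptake = (1 − SF) · TLR·m_tumor / (m_tumor·TLR + m_liver)

The activity to administer for a prescribed liver dose and the resulting
tumor dose use the MIRD constant 184,000 rad·g/mCi for 90Y; the lung dose
uses the companion constant 49.33 Gy·kg/GBq,

    A_admin (mCi) = dose_liver (rad) · m_liver (g) / (184000 · liver uptake)
    D_tumor (rad) = A_total (mCi) · 184000 · tumor uptake / m_tumor (g)
    D_lung  (Gy)  = A_admin (GBq) · SF · 49.33 / M_lung (kg)

The two constants are not mutually consistent (184,000 rad·g/mCi is
49.73 Gy·kg/GBq); each is used inside its own equation as published, both
are exposed, and every dose function accepts an override to force a single
constant.

Prescription policy for resin microspheres: full activity for SF < 10%,
reduced by 20% for 10-15%, by 40% for 15-20%, contraindicated above 20%;
a single session is limited to 30 Gy lung dose and the cumulative lung
dose to ~50 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PartitionInput",
    "DoseReport",
    "Prescription",
    "liver_uptake",
    "tumor_uptake",
    "activity_for_liver_dose",
    "tumor_dose",
    "lung_dose",
    "prescribe",
    "activity_deviation",
    "lung_dose_deviation",
    "plan_treatment",
    "MIRD_RAD_G_PER_MCI",
    "LUNG_GY_KG_PER_GBQ",
    "MIRD_GY_KG_PER_GBQ",
]

#: 90Y equilibrium dose constant as used in the activity/tumor-dose equations.
MIRD_RAD_G_PER_MCI = 184_000.0
#: 90Y lung-dose constant in Gy·kg/GBq as used in the lung-dose equation.
LUNG_GY_KG_PER_GBQ = 49.33
RAD_PER_GY = 100.0
GBQ_PER_MCI = 0.037

#: The Gy·kg/GBq value implied by 184,000 rad·g/mCi (≈49.73; reference/override).
MIRD_GY_KG_PER_GBQ = MIRD_RAD_G_PER_MCI / RAD_PER_GY / GBQ_PER_MCI / 1000.0

SINGLE_SESSION_LUNG_LIMIT_GY = 30.0
CUMULATIVE_LUNG_LIMIT_GY = 50.0


@dataclass(frozen=True)
class PartitionInput:
    """Masses, uptake ratio and shunt fraction feeding the partition model."""

    m_liver: float  # injected healthy liver mass, g
    m_tumor: float  # g
    tlr: float  # tumor-to-liver activity concentration ratio
    sf: float  # lung shunt fraction
    lung_mass_kg: float = 1.0

    def __post_init__(self) -> None:
        if self.m_liver <= 0 or self.m_tumor <= 0:
            raise ValueError("masses must be positive")
        if self.tlr < 0:
            raise ValueError("TLR must be non-negative")
        if not 0.0 <= self.sf < 1.0:
            raise ValueError("shunt fraction must lie in [0, 1)")
        if self.lung_mass_kg <= 0:
            raise ValueError("lung mass must be positive")


@dataclass
class DoseReport:
    """Administered activity and per-compartment absorbed doses."""

    activity_admin_gbq: float
    activity_admin_mci: float
    dose_liver_gy: float
    dose_tumor_gy: float
    dose_lung_gy: float
    uptake_liver: float
    uptake_tumor: float


@dataclass
class Prescription:
    """LSF-banded activity prescription with lung-dose limit flags."""

    requested_activity_gbq: float
    reduction_factor: float
    delivered_activity_gbq: float
    contraindicated: bool
    single_session_lung_dose_gy: float
    cumulative_lung_dose_gy: float
    exceeds_single_session_limit: bool
    exceeds_cumulative_limit: bool


def liver_uptake(p: PartitionInput) -> float:
    """Fraction of the administered activity taken up by the healthy liver."""
    return (1.0 - p.sf) * p.m_liver / (p.m_tumor * p.tlr + p.m_liver)


def tumor_uptake(p: PartitionInput) -> float:
    """Fraction of the administered activity taken up by the tumor.

    ``liver_uptake + tumor_uptake == 1 - sf`` exactly.
    """
    return (1.0 - p.sf) * (p.tlr * p.m_tumor) / (p.m_tumor * p.tlr + p.m_liver)


def activity_for_liver_dose(
    dose_liver_gy: float,
    p: PartitionInput,
    mird_constant: float = MIRD_RAD_G_PER_MCI,
) -> tuple[float, float]:
    """Activity to administer for a prescribed healthy-liver dose.

    Returns ``(mCi, GBq)``.  Raises if the liver fractional uptake is zero
    (no finite activity can deliver the dose).
    """
    if dose_liver_gy < 0:
        raise ValueError("dose must be non-negative")
    uptake = liver_uptake(p)
    if uptake == 0.0:
        raise ValueError("liver fractional uptake is zero: prescription infeasible")
    mci = dose_liver_gy * RAD_PER_GY * p.m_liver / (mird_constant * uptake)
    return mci, mci * GBQ_PER_MCI


def tumor_dose(
    activity_total_mci: float,
    p: PartitionInput,
    mird_constant: float = MIRD_RAD_G_PER_MCI,
) -> float:
    """Tumor absorbed dose in Gy for a given total administered activity."""
    if activity_total_mci < 0:
        raise ValueError("activity must be non-negative")
    rad = activity_total_mci * mird_constant * tumor_uptake(p) / p.m_tumor
    return rad / RAD_PER_GY


def lung_dose(
    activity_admin_gbq: float,
    sf: float,
    lung_mass_kg: float = 1.0,
    gy_kg_per_gbq: float = LUNG_GY_KG_PER_GBQ,
) -> float:
    """Lung absorbed dose in Gy.

    The shunted activity ``activity_admin_gbq * sf`` is assumed uniformly
    distributed in a lung mass of ``lung_mass_kg`` kilograms.
    """
    if activity_admin_gbq < 0:
        raise ValueError("activity must be non-negative")
    if not 0.0 <= sf < 1.0:
        raise ValueError("shunt fraction must lie in [0, 1)")
    if lung_mass_kg <= 0:
        raise ValueError("lung mass must be positive")
    return activity_admin_gbq * sf * gy_kg_per_gbq / lung_mass_kg


def _reduction_factor(sf: float) -> float:
    # Band edges: a boundary value belongs to the higher-reduction band.
    if sf < 0.10:
        return 1.0
    if sf < 0.15:
        return 0.8
    if sf <= 0.20:
        return 0.6
    return 0.0


def prescribe(
    requested_activity_gbq: float,
    sf: float,
    lung_mass_kg: float = 1.0,
    prior_lung_dose_gy: float = 0.0,
) -> Prescription:
    """Apply the LSF-banded resin-microsphere prescription policy.

    Full activity below 10% shunt, 20% reduction for 10-15%, 40% reduction
    for 15-20%, contraindicated above 20%.  Flags are raised when the
    single-session lung dose exceeds 30 Gy or the cumulative (prior +
    session) lung dose exceeds 50 Gy.
    """
    if requested_activity_gbq < 0 or prior_lung_dose_gy < 0:
        raise ValueError("activity and prior dose must be non-negative")
    factor = _reduction_factor(sf)
    delivered = requested_activity_gbq * factor
    session_dose = lung_dose(delivered, sf, lung_mass_kg)
    cumulative = prior_lung_dose_gy + session_dose
    return Prescription(
        requested_activity_gbq=requested_activity_gbq,
        reduction_factor=factor,
        delivered_activity_gbq=delivered,
        contraindicated=(factor == 0.0),
        single_session_lung_dose_gy=session_dose,
        cumulative_lung_dose_gy=cumulative,
        exceeds_single_session_limit=(session_dose > SINGLE_SESSION_LUNG_LIMIT_GY),
        exceeds_cumulative_limit=(cumulative > CUMULATIVE_LUNG_LIMIT_GY),
    )


def activity_deviation(lsf_ref: float, lsf_alt: float) -> float:
    """Fractional change in the suggested activity when only the LSF changes.

    With masses, TLR and the prescribed liver dose fixed, the administered
    activity scales as 1/(1 − SF), so switching the shunt estimate from
    ``lsf_ref`` to ``lsf_alt`` changes the activity by
    ``(1 − lsf_ref)/(1 − lsf_alt) − 1``.
    """
    for name, v in (("lsf_ref", lsf_ref), ("lsf_alt", lsf_alt)):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    return (1.0 - lsf_ref) / (1.0 - lsf_alt) - 1.0


def lung_dose_deviation(lsf_ref: float, lsf_alt: float) -> float:
    """Fractional change in the lung dose when only the LSF changes.

    The lung dose scales as A·SF ∝ SF/(1 − SF), so the change is
    ``lsf_alt(1 − lsf_ref) / (lsf_ref(1 − lsf_alt)) − 1``.
    """
    for name, v in (("lsf_ref", lsf_ref), ("lsf_alt", lsf_alt)):
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    if lsf_ref == 0.0:
        raise ZeroDivisionError("lung dose deviation undefined for lsf_ref = 0")
    return lsf_alt * (1.0 - lsf_ref) / (lsf_ref * (1.0 - lsf_alt)) - 1.0


def plan_treatment(
    dose_liver_gy: float,
    p: PartitionInput,
    mird_constant: float = MIRD_RAD_G_PER_MCI,
    lung_constant: float = LUNG_GY_KG_PER_GBQ,
) -> DoseReport:
    """Full partition-model plan for a prescribed healthy-liver dose."""
    mci, gbq = activity_for_liver_dose(dose_liver_gy, p, mird_constant)
    return DoseReport(
        activity_admin_gbq=gbq,
        activity_admin_mci=mci,
        dose_liver_gy=dose_liver_gy,
        dose_tumor_gy=tumor_dose(mci, p, mird_constant),
        dose_lung_gy=lung_dose(gbq, p.sf, p.lung_mass_kg, lung_constant),
        uptake_liver=liver_uptake(p),
        uptake_tumor=tumor_uptake(p),
    )


def tlr_from_counts(
    tumor_counts: float, m_tumor_g: float, ihl_counts: float, m_ihl_g: float
) -> float:
    """Tumor-to-liver ratio from image counts and compartment masses."""
    if min(tumor_counts, ihl_counts) < 0 or min(m_tumor_g, m_ihl_g) <= 0:
        raise ValueError("counts must be non-negative and masses positive")
    if ihl_counts == 0:
        raise ZeroDivisionError("IHL counts are zero; TLR undefined")
    return (tumor_counts / m_tumor_g) / (ihl_counts / m_ihl_g)
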