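"""Synthetic-cohort generator emulating the ECMO meropenem study design.

The clinical dataset behind the model is not publicly deposited, so this
module reproduces its design: 30 adult ECMO patients (10 on CRRT), a single
0.5 or 1 g meropenem dose infused over 3 h, and 7 plasma samples per subject
drawn on one of three fixed sampling schemes (predose plus six post-infusion
times).  Covariates are drawn from independent log-normal marginals whose
median and IQR match the reported cohort summaries, separately for the CRRT
and non-CRRT strata.  True concentrations come from the closed-form
two-compartment model; combined additive + proportional residual error is then
applied and values below the 1 mg/L assay quantitation limit are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import PKDataset
from .pk_core import DosingRegimen, concentration_single_dose
from .popmodel import CovariateVector, PopulationModel, individual_params

__all__ = [
    "SAMPLING_SCHEMES",
    "LognormalSpec",
    "CohortSpec",
    "sample_covariates",
    "cockcroft_gault",
    "simulate_dataset",
]

#: Fixed sampling schemes: hours after start of the 3-h infusion (7 samples each).
SAMPLING_SCHEMES: dict[int, tuple[float, ...]] = {
    1: (0.0, 3.33, 3.67, 4.0, 5.0, 6.0, 8.0),
    2: (0.0, 3.33, 3.67, 4.0, 5.0, 8.0, 10.0),
    3: (0.0, 3.33, 3.67, 4.0, 6.0, 11.0, 14.0),
}

_Z75 = norm.ppf(0.75)  # 0.6744897...


@dataclass(frozen=True)
class LognormalSpec:
    """A log-normal marginal parameterised by its median and quartiles.

    mu = log(median); sigma = log(q75/q25) / (2 * z_0.75), so the fitted
    distribution reproduces the median exactly and the IQR *ratio* exactly
    (log-normal quartiles are symmetric about the median on the log scale).
    """

    median: float
    q25: float
    q75: float

    def __post_init__(self) -> None:
        if not (0 < self.q25 <= self.median <= self.q75):
            raise ValueError(f"need 0 < q25 <= median <= q75, got {self}")

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        return float(np.log(self.q75 / self.q25) / (2 * _Z75))

    def quantile(self, q) -> np.ndarray:
        return np.exp(self.mu + self.sigma * norm.ppf(q))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.exp(self.mu + self.sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class CohortSpec:
    """Study-design and covariate-distribution settings for one cohort.

    Defaults reproduce the study conditions: n=30 with a 10/30 CRRT fraction,
    1000 mg infused over 3 h (one subject receives 500 mg), cyclic assignment
    of the three sampling schemes, and stratum-specific covariate marginals
    matching the reported medians/IQRs.
    """

    n_subjects: int = 30
    dose_mg: float = 1000.0
    alt_dose_mg: float = 500.0
    n_alt_dose: int = 1          # number of subjects on the alternative dose
    t_inf: float = 3.0           # h
    crrt_fraction: float = 10 / 30
    # CRCL (Cockcroft-Gault, ml/min) and ECMO flow (L/min) marginals per stratum
    crcl_non_crrt: LognormalSpec = LognormalSpec(69.6, 42.2, 115.0)
    crcl_crrt: LognormalSpec = LognormalSpec(43.4, 31.8, 51.0)
    lpm_non_crrt: LognormalSpec = LognormalSpec(3.62, 2.62, 4.08)
    lpm_crrt: LognormalSpec = LognormalSpec(3.83, 3.47, 4.17)
    lpm_floor: float = 0.8       # L/min; draws below are resampled (admissibility)
    # demographics (carried but unused by the final model)
    age: LognormalSpec = LognormalSpec(63.0, 54.4, 74.7)
    weight: LognormalSpec = LognormalSpec(67.4, 57.9, 80.3)
    height: LognormalSpec = LognormalSpec(164.0, 160.0, 173.0)
    male_fraction: float = 17 / 30
    scheme_assignment: str = "cyclic"   # "cyclic" or "random"
    lloq: float = 1.0            # mg/L
    censor_blq: bool = False     # True: drop BLQ rows instead of flagging

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.crrt_fraction <= 1:
            raise ValueError("crrt_fraction must be in [0, 1]")
        if self.n_alt_dose > self.n_subjects:
            raise ValueError("n_alt_dose exceeds n_subjects")
        if self.scheme_assignment not in ("cyclic", "random"):
            raise ValueError(f"unknown scheme_assignment {self.scheme_assignment!r}")


def cockcroft_gault(age: float, weight: float, scr: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance, ml/min.

    (140 - age) * weight / (72 * Scr), times 0.85 for females.  Age in years,
    weight in kg, serum creatinine in mg/dl; ``sex`` is "M" or "F".
    """
    if age < 0 or age > 140 or weight <= 0 or scr <= 0:
        raise ValueError("age must be in [0, 140]; weight and scr must be positive")
    crcl = (140.0 - age) * weight / (72.0 * scr)
    if sex.upper().startswith("F"):
        crcl *= 0.85
    return crcl


def _crrt_flags(n: int, fraction: float) -> np.ndarray:
    """Deterministic evenly-spread CRRT assignment with round(fraction*n) flags."""
    n_crrt = int(round(fraction * n))
    counts = (np.arange(n + 1) * n_crrt) // n
    return np.diff(counts).astype(bool)


def sample_covariates(spec: CohortSpec, rng) -> list[CovariateVector]:
    """Draw one covariate vector per subject.

    CRCL and ECMO flow come from the stratum-specific log-normal marginals;
    flow draws below ``spec.lpm_floor`` are resampled so every subject sits in
    the admissible region of the covariate model.
    """
    rng = np.random.default_rng(rng)
    flags = _crrt_flags(spec.n_subjects, spec.crrt_fraction)
    out = []
    for crrt in flags:
        crcl_dist = spec.crcl_crrt if crrt else spec.crcl_non_crrt
        lpm_dist = spec.lpm_crrt if crrt else spec.lpm_non_crrt
        crcl = float(crcl_dist.sample(1, rng)[0])
        lpm = float(lpm_dist.sample(1, rng)[0])
        while lpm < spec.lpm_floor:
            lpm = float(lpm_dist.sample(1, rng)[0])
        sex = "M" if rng.random() < spec.male_fraction else "F"
        age = float(spec.age.sample(1, rng)[0])
        weight = float(spec.weight.sample(1, rng)[0])
        height = float(spec.height.sample(1, rng)[0])
        # serum creatinine back-solved from the CG formula so the demographic
        # fields are mutually consistent with the sampled CRCL
        scr = (140.0 - min(age, 139.0)) * weight / (72.0 * crcl)
        if sex == "F":
            scr *= 0.85
        out.append(CovariateVector(
            crcl=crcl, lpm=lpm, age=age, weight=weight, height=height,
            sex=sex, scr=scr, crrt=bool(crrt),
            ecmo_type="VV" if rng.random() < 23 / 30 else "VA",
        ))
    return out


def simulate_dataset(spec: CohortSpec, m: PopulationModel, seed) -> PKDataset:
    """Simulate a full cohort dataset under the study design.

    For each subject: draw covariates and random effects, assign a sampling
    scheme (cyclic by default), compute true concentrations with the
    closed-form two-compartment model, apply residual error (negative values
    truncated at 0) and flag observations below the LLOQ.  The predose sample
    is reported as 0 (no drug on board in a single-dose design).

    Returns a :class:`PKDataset`; with default settings it contains exactly
    ``n_subjects * 7`` observation rows.
    """
    rng = np.random.default_rng(seed)
    covs = sample_covariates(spec, rng)
    scheme_ids = list(SAMPLING_SCHEMES)
    rows = []
    for i, cov in enumerate(covs):
        sid = i + 1
        if spec.scheme_assignment == "cyclic":
            scheme = scheme_ids[i % len(scheme_ids)]
        else:
            scheme = scheme_ids[rng.integers(len(scheme_ids))]
        times = SAMPLING_SCHEMES[scheme]
        dose = spec.alt_dose_mg if i < spec.n_alt_dose else spec.dose_mg
        eta = rng.standard_normal(3) * m.omegas
        try:
            p = individual_params(m, cov, eta)
        except ValueError as exc:
            raise ValueError(f"subject {sid}: {exc}") from exc
        regimen = DosingRegimen(dose=dose, t_inf=spec.t_inf, tau=max(times) + spec.t_inf)
        base = dict(ID=sid, CRCL=cov.crcl, LPM=cov.lpm, AGE=cov.age,
                    WT=cov.weight, HT=cov.height, SEX=1 if cov.sex == "M" else 0,
                    SCR=cov.scr, CRRT=int(cov.crrt), SCHEME=scheme)
        for t in times:
            if t == 0.0:
                dv, blq = 0.0, 1  # predose: no drug on board, below LLOQ
                rows.append(dict(base, TIME=0.0, AMT=0.0, RATE=0.0, EVID=0,
                                 MDV=0, DV=dv, BLQ=blq))
                rows.append(dict(base, TIME=0.0, AMT=dose, RATE=dose / spec.t_inf,
                                 EVID=1, MDV=1, DV=np.nan, BLQ=0))
            else:
                ipred = concentration_single_dose(p, regimen, t)
                eps = rng.standard_normal(2)
                dv = ipred * (1.0 + m.sigma_prop * eps[0]) + m.sigma_add * eps[1]
                dv = max(dv, 0.0)  # concentrations are non-negative
                blq = int(dv < spec.lloq)
                rows.append(dict(base, TIME=t, AMT=0.0, RATE=0.0, EVID=0,
                                 MDV=0, DV=dv, BLQ=blq))
    df = pd.DataFrame(rows)
    lead = ["ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "CRCL", "LPM", "BLQ"]
    df = df[lead + [c for c in df.columns if c not in lead]]
    data = PKDataset(df)
    if spec.censor_blq:
        data = data.without_blq()
    return data
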