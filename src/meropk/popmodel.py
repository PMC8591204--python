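"""Population PK model: covariates, between-subject variability, residual error.

The final covariate model for meropenem during ECMO is

    CL = theta1 * (1 + theta2 * (CRCL - cg_ref))        [L/h]
    Vc = theta3 * (1 + theta4 * (LPM  - lpm_ref))       [L]
    Q  = Q_pop,  Vp = Vp_pop

where CRCL is Cockcroft-Gault creatinine clearance (ml/min) and LPM the ECMO
circuit flow rate (L/min); ``cg_ref``/``lpm_ref`` are the covariate centering
constants (cohort medians).  Between-subject variability is log-normal,
``P_i = P_typ * exp(eta_P)`` with independent eta ~ N(0, omega^2) on CL, Vc and
Vp (none on Q).  Observed concentrations carry combined additive + proportional
residual error,

    y = ipred * (1 + eps_prop) + eps_add.

Omega values are log-scale standard deviations; the conventional "%CV" display
is 100*omega (e.g. 39.6% <-> omega = 0.396).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .pk_core import StructuralParams

__all__ = [
    "PopulationModel",
    "CovariateVector",
    "CovariateDomainError",
    "typical_params",
    "individual_params",
    "sample_etas",
    "apply_residual_error",
    "default_model",
]

# Serialization key order for the flat config format.
_CONFIG_KEYS = (
    "theta1", "theta2", "theta3", "theta4", "Q", "Vp",
    "omega_CL", "omega_Vc", "omega_Vp", "sigma_add", "sigma_prop",
    "cg_ref", "lpm_ref",
)


class CovariateDomainError(ValueError):
    """Raised when the linear covariate model leaves the admissible region.

    The linear parameterisation can extrapolate to non-physiological (<= 0)
    clearances or volumes; such covariate values are a hard error rather than
    being clipped, because silently clipping would bias downstream simulation.
    """


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, BSV and residual-error parameters of the population model."""

    theta1: float  # typical CL at CRCL = cg_ref, L/h
    theta2: float  # CRCL slope on CL, per (ml/min)
    theta3: float  # typical Vc at LPM = lpm_ref, L
    theta4: float  # ECMO-flow slope on Vc, per (L/min)
    Q: float       # intercompartmental clearance, L/h
    Vp: float      # peripheral volume, L
    omega_CL: float = 0.0   # log-scale SD of BSV on CL
    omega_Vc: float = 0.0
    omega_Vp: float = 0.0
    sigma_add: float = 0.0  # additive residual SD, mg/L
    sigma_prop: float = 0.0  # proportional residual SD, fraction
    cg_ref: float = 49.7    # CRCL centering constant, ml/min
    lpm_ref: float = 3.7    # ECMO flow centering constant, L/min

    def __post_init__(self) -> None:
        for name in ("theta1", "theta3", "Q", "Vp"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("omega_CL", "omega_Vc", "omega_Vp", "sigma_add", "sigma_prop"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    @property
    def omegas(self) -> np.ndarray:
        """BSV SDs as an array ordered (CL, Vc, Vp)."""
        return np.array([self.omega_CL, self.omega_Vc, self.omega_Vp])

    def replace(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)

    # -- flat config round trip -------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: float(d[k]) for k in _CONFIG_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        unknown = set(d) - set(_CONFIG_KEYS)
        if unknown:
            raise ValueError(f"unknown model parameter keys: {sorted(unknown)}")
        missing = set(_CONFIG_KEYS) - set(d)
        if missing:
            raise ValueError(f"missing model parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PopulationModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class CovariateVector:
    """Covariates of one (virtual) subject.

    Only ``crcl`` and ``lpm`` enter the final model; the demographic fields are
    carried so datasets can expose them to covariate search.
    """

    crcl: float  # Cockcroft-Gault creatinine clearance, ml/min
    lpm: float   # ECMO flow rate, L/min
    age: float | None = None     # yr
    weight: float | None = None  # kg
    height: float | None = None  # cm
    sex: str | None = None       # "M" / "F"
    scr: float | None = None     # serum creatinine, mg/dl
    crrt: bool = False
    ecmo_type: str | None = None  # "VV" / "VA"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.crcl) and self.crcl >= 0):
            raise ValueError(f"crcl must be >= 0, got {self.crcl!r}")
        if not (np.isfinite(self.lpm) and self.lpm > 0):
            raise ValueError(f"lpm must be > 0, got {self.lpm!r}")


def typical_params(m: PopulationModel, cov: CovariateVector) -> StructuralParams:
    """Typical-value disposition parameters for a covariate vector.

    Raises
    ------
    CovariateDomainError
        If the linear covariate model yields CL <= 0 or Vc <= 0 (covariate
        outside the admissible region; e.g. ECMO flow at or below the root of
        ``1 + theta4*(LPM - lpm_ref)``).
    """
    cl = m.theta1 * (1.0 + m.theta2 * (cov.crcl - m.cg_ref))
    vc = m.theta3 * (1.0 + m.theta4 * (cov.lpm - m.lpm_ref))
    if cl <= 0:
        raise CovariateDomainError(
            f"CRCL = {cov.crcl:g} ml/min gives non-positive clearance CL = {cl:g} L/h"
        )
    if vc <= 0:
        raise CovariateDomainError(
            f"ECMO flow = {cov.lpm:g} L/min gives non-positive central volume Vc = {vc:g} L"
        )
    return StructuralParams(CL=cl, Vc=vc, Vp=m.Vp, Q=m.Q)


def individual_params(m: PopulationModel, cov: CovariateVector, eta) -> StructuralParams:
    """Individual parameters: typical values times exp(eta) on (CL, Vc, Vp).

    ``eta`` is a length-3 sequence ordered (eta_CL, eta_Vc, eta_Vp);
    Q carries no random effect.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite length-3 vector (CL, Vc, Vp)")
    typ = typical_params(m, cov)
    return StructuralParams(
        CL=typ.CL * float(np.exp(eta[0])),
        Vc=typ.Vc * float(np.exp(eta[1])),
        Vp=typ.Vp * float(np.exp(eta[2])),
        Q=typ.Q,
    )


def sample_etas(m: PopulationModel, n: int, rng) -> np.ndarray:
    """Draw ``n`` independent random-effect triples, shape (n, 3).

    Zero-mean normals with SDs (omega_CL, omega_Vc, omega_Vp); the covariance
    is diagonal (no eta correlations in the model).

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(rng)
    return rng.standard_normal((n, 3)) * m.omegas


def apply_residual_error(m: PopulationModel, ipred, eps) -> np.ndarray | float:
    """Apply combined additive + proportional residual error.

    ``eps`` is a pair (eps_prop, eps_add) of standard-normal draws (scalars or
    arrays matching ``ipred``); they are scaled by (sigma_prop, sigma_add) here,
    so callers pass unit-variance noise:

        y = ipred * (1 + sigma_prop * eps_prop) + sigma_add * eps_add
    """
    ipred_arr = np.asarray(ipred, dtype=float)
    if np.any(ipred_arr < 0):
        raise ValueError("ipred must be non-negative")
    eps_prop, eps_add = eps
    y = ipred_arr * (1.0 + m.sigma_prop * np.asarray(eps_prop, float)) \
        + m.sigma_add * np.asarray(eps_add, float)
    return float(y) if np.ndim(ipred) == 0 and np.ndim(eps_prop) == 0 else y


def default_model() -> PopulationModel:
    """Population estimates for meropenem in adults on ECMO.

    Two-compartment disposition with creatinine clearance (Cockcroft-Gault) as
    a covariate on CL and ECMO circuit flow rate on Vc, log-normal BSV on CL,
    Vc and Vp, and combined additive + proportional residual error.
    """
    return PopulationModel(
        theta1=7.35, theta2=0.0104,
        theta3=17.3, theta4=0.337,
        Q=14.5, Vp=12.8,
        omega_CL=0.396, omega_Vc=0.485, omega_Vp=0.388,
        sigma_add=0.370, sigma_prop=0.0473,
        cg_ref=49.7, lpm_ref=3.7,
    )
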