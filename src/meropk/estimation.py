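"""Nonlinear mixed-effects estimation: FOCE-I objective, fitting, covariate
search and nonparametric bootstrap.

The marginal likelihood of each subject's concentration vector is approximated
by first-order conditional estimation with interaction (FOCE-I): the inner
problem finds the posterior mode ``eta_hat`` of the subject's random effects,
the model is linearised there, and the residual variance is evaluated at the
individual predictions (the interaction term).  With ``f_i(eta)`` the model
prediction vector, ``G_i = df_i/deta`` at the mode, ``R_i`` the diagonal
residual variance at ``f_i(eta_hat)`` and ``Omega`` the BSV covariance,

    C_i   = G_i Omega G_i' + R_i
    r_i   = y_i - f_i(eta_hat) + G_i eta_hat
    OFV_i = n_i log(2 pi) + log|C_i| + r_i' C_i^{-1} r_i

and the objective function value is ``OFV = sum_i OFV_i`` (-2 log approximate
marginal likelihood, 2-pi terms included; the additive constant therefore
differs from NONMEM's convention, which is harmless for the nested-model
differences used in model selection).

The inner mode search minimises the conditional objective

    q_i(eta) = sum_j [ (y_ij - f_ij)^2 / R_ij(eta) + log R_ij(eta) ]
               + eta' Omega^{-1} eta

by a damped Newton iteration with finite-difference Jacobians, run
simultaneously for all subjects on stacked arrays.  Observations recorded
before any dose (predose samples of a single-dose design) carry no structural
information and are excluded from the likelihood, as are rows with MDV=1 and
— when BLQ censoring is enabled — rows below the quantitation limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import PKDataset
from .popmodel import PopulationModel

__all__ = [
    "CovariateEffect",
    "ModelStructure",
    "FitResult",
    "CovariateSearchTrace",
    "EstimationError",
    "InnerConvergenceError",
    "final_structure",
    "foce_objective",
    "fit",
    "compare_nested",
    "stepwise_covariate_search",
    "bootstrap",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_PENALTY = 1e12
_OMEGA_ACTIVE = 1e-10  # BSV below this is treated as a fixed zero random effect

#: model-selection thresholds on delta-OFV (chi-square quantiles)
NESTED_THRESHOLDS = {1: 3.84, 2: 5.99}
FORWARD_THRESHOLD = 6.63    # p < 0.01, 1 df
BACKWARD_THRESHOLD = 10.8   # p < 0.001, 1 df


class EstimationError(RuntimeError):
    """Estimation failed in a way that cannot be reported as a result."""


class InnerConvergenceError(EstimationError):
    """The inner (empirical-Bayes) optimisation failed for some subjects."""

    def __init__(self, subject_ids):
        self.subject_ids = list(subject_ids)
        super().__init__(
            f"inner eta optimisation did not converge for subjects {self.subject_ids}"
        )


# ---------------------------------------------------------------------------
# model structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateEffect:
    """A linear covariate term ``P = P_base * (1 + slope * (x - ref))``."""

    column: str
    parameter: str  # one of "CL", "Vc", "Vp", "Q"
    ref: float

    def __post_init__(self) -> None:
        if self.parameter not in ("CL", "Vc", "Vp", "Q"):
            raise ValueError(f"unknown parameter {self.parameter!r}")

    @property
    def name(self) -> str:
        return f"beta_{self.column}_{self.parameter}"


@dataclass(frozen=True)
class ModelStructure:
    """Which covariate effects enter the fixed-effect model."""

    effects: tuple[CovariateEffect, ...] = ()

    def with_effect(self, e: CovariateEffect) -> "ModelStructure":
        return ModelStructure(self.effects + (e,))

    def without_effect(self, e: CovariateEffect) -> "ModelStructure":
        return ModelStructure(tuple(x for x in self.effects if x != e))

    def parameter_names(self) -> list[str]:
        return (["CL", "Vc", "Q", "Vp"]
                + [e.name for e in self.effects]
                + ["omega_CL", "omega_Vc", "omega_Vp", "sigma_add", "sigma_prop"])


def final_structure(cg_ref: float = 49.7, lpm_ref: float = 3.7) -> ModelStructure:
    """The final two-covariate structure: CRCL on CL and ECMO flow on Vc."""
    return ModelStructure((
        CovariateEffect("CRCL", "CL", cg_ref),
        CovariateEffect("LPM", "Vc", lpm_ref),
    ))


def _params_from_model(m: PopulationModel) -> dict[str, float]:
    return {
        "CL": m.theta1, "Vc": m.theta3, "Q": m.Q, "Vp": m.Vp,
        "beta_CRCL_CL": m.theta2, "beta_LPM_Vc": m.theta4,
        "omega_CL": m.omega_CL, "omega_Vc": m.omega_Vc, "omega_Vp": m.omega_Vp,
        "sigma_add": m.sigma_add, "sigma_prop": m.sigma_prop,
    }


def _model_from_params(params: dict[str, float], structure: ModelStructure) -> PopulationModel | None:
    """Map estimates back onto a PopulationModel when the structure matches the
    final two-covariate model (otherwise returns None)."""
    cols = {(e.column, e.parameter): e for e in structure.effects}
    if set(cols) != {("CRCL", "CL"), ("LPM", "Vc")}:
        return None
    e_cl = cols[("CRCL", "CL")]
    e_vc = cols[("LPM", "Vc")]
    return PopulationModel(
        theta1=params["CL"], theta2=params[e_cl.name],
        theta3=params["Vc"], theta4=params[e_vc.name],
        Q=params["Q"], Vp=params["Vp"],
        omega_CL=params["omega_CL"], omega_Vc=params["omega_Vc"],
        omega_Vp=params["omega_Vp"],
        sigma_add=params["sigma_add"], sigma_prop=params["sigma_prop"],
        cg_ref=e_cl.ref, lpm_ref=e_vc.ref,
    )


# ---------------------------------------------------------------------------
# cohort preparation (stacked arrays)
# ---------------------------------------------------------------------------

@dataclass
class _Cohort:
    ids: np.ndarray         # (n,)
    times: np.ndarray       # (n, m) observation times, padded
    y: np.ndarray           # (n, m) observed DV, padded
    mask: np.ndarray        # (n, m) True where a real observation sits
    dose_time: np.ndarray   # (n, d)
    dose_amt: np.ndarray    # (n, d)
    dose_tinf: np.ndarray   # (n, d)
    dose_mask: np.ndarray   # (n, d)
    covs: dict[str, np.ndarray]  # column -> (n,)

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    def dose_geometry(self):
        """Parameter-independent infusion geometry per dose column, cached.

        Returns a list of (pos, te, td, r0) tuples: exposure/decay times and
        the infusion rate, which depend only on the design, not on the PK
        parameters — so concentration evaluation inside the optimiser reduces
        to exponentials.
        """
        cache = getattr(self, "_dose_geom", None)
        if cache is None:
            cache = []
            for j in range(self.dose_time.shape[1]):
                t = self.times - self.dose_time[:, [j]]
                tinf = self.dose_tinf[:, [j]]
                te = np.clip(t, 0.0, tinf)
                td = np.maximum(t - tinf, 0.0)
                pos = (t > 0) & self.dose_mask[:, [j]]
                r0 = (self.dose_amt[:, j] / self.dose_tinf[:, j])[:, None]
                cache.append((pos, te, td, r0))
            object.__setattr__(self, "_dose_geom", cache)
        return cache


def _prepare(data: PKDataset, use_blq: bool = True) -> _Cohort:
    df = data.df
    ids = df["ID"].unique()
    obs_list, dose_list = [], []
    for sid in ids:
        g = df[df["ID"] == sid]
        doses = g[(g["EVID"] == 1) & (g["AMT"] > 0)]
        if doses.empty:
            raise EstimationError(f"subject {sid} has no dose record")
        first_dose = doses["TIME"].min()
        obs = g[(g["EVID"] == 0) & (g["MDV"] != 1)]
        # predose rows carry no structural information (prediction identically 0)
        obs = obs[obs["TIME"] > first_dose]
        if not use_blq:
            obs = obs[obs["BLQ"] != 1]
        if obs.empty:
            raise EstimationError(f"subject {sid} has no usable observations")
        obs_list.append(obs)
        dose_list.append(doses)
    n = len(ids)
    m = max(len(o) for o in obs_list)
    d = max(len(dl) for dl in dose_list)
    times = np.zeros((n, m)); y = np.zeros((n, m)); mask = np.zeros((n, m), bool)
    dtime = np.zeros((n, d)); damt = np.zeros((n, d))
    dtinf = np.ones((n, d)); dmask = np.zeros((n, d), bool)
    for i, (o, dl) in enumerate(zip(obs_list, dose_list)):
        times[i, : len(o)] = o["TIME"].to_numpy()
        y[i, : len(o)] = o["DV"].to_numpy()
        mask[i, : len(o)] = True
        dtime[i, : len(dl)] = dl["TIME"].to_numpy()
        damt[i, : len(dl)] = dl["AMT"].to_numpy()
        dtinf[i, : len(dl)] = (dl["AMT"] / dl["RATE"]).to_numpy()
        dmask[i, : len(dl)] = True
    covs = {}
    first_rows = df.groupby("ID", sort=False).first()
    for col in df.columns:
        if col in ("ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "BLQ"):
            continue
        vals = first_rows[col]
        if pd.api.types.is_numeric_dtype(vals):
            covs[col] = vals.to_numpy(dtype=float)
    return _Cohort(np.asarray(ids), times, y, mask, dtime, damt, dtinf, dmask, covs)


def _conc_multi(c: _Cohort, CL, Vc, Vp, Q) -> np.ndarray:
    """Concentrations for a stack of parameter sets, shape (K, n, m).

    Same closed form as :func:`_conc_cohort`, evaluated for K parameter
    variants per subject in one pass — used to build finite-difference
    Jacobians without per-variant call overhead.
    """
    k10 = CL / Vc
    k12 = Q / Vc
    k21 = Q / Vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 1e-300))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    ca = ((alpha - k21) / (disc * alpha) / Vc)[:, :, None]
    cb = ((k21 - beta) / (disc * beta) / Vc)[:, :, None]
    al = alpha[:, :, None]
    be = beta[:, :, None]
    f = None
    for pos, te, td, r0 in c.dose_geometry():
        contrib = r0 * (ca * -np.expm1(-al * te) * np.exp(-al * td)
                        + cb * -np.expm1(-be * te) * np.exp(-be * td))
        contrib = np.where(pos, contrib, 0.0)
        f = contrib if f is None else f + contrib
    return f


def _conc_cohort(c: _Cohort, CL, Vc, Vp, Q) -> np.ndarray:
    """Batched closed-form concentrations, (n, m), for per-subject parameters."""
    k10 = CL / Vc
    k12 = Q / Vc
    k21 = Q / Vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 1e-300))
    alpha = (s + disc) / 2.0
    beta = (s - disc) / 2.0
    ca = ((alpha - k21) / (disc * alpha) / Vc)[:, None]
    cb = (((k21 - beta) / disc) / beta / Vc)[:, None]
    al = alpha[:, None]
    be = beta[:, None]
    f = None
    for pos, te, td, r0 in c.dose_geometry():
        contrib = r0 * (ca * -np.expm1(-al * te) * np.exp(-al * td)
                        + cb * -np.expm1(-be * te) * np.exp(-be * td))
        contrib = np.where(pos, contrib, 0.0)
        f = contrib if f is None else f + contrib
    return f


# ---------------------------------------------------------------------------
# FOCE-I objective
# ---------------------------------------------------------------------------

def _typical_arrays(params: dict[str, float], structure: ModelStructure,
                    c: _Cohort) -> dict[str, np.ndarray] | None:
    n = c.n_subjects
    typ = {p: np.full(n, params[p]) for p in ("CL", "Vc", "Vp", "Q")}
    factors = {p: np.ones(n) for p in ("CL", "Vc", "Vp", "Q")}
    for e in structure.effects:
        if e.column not in c.covs:
            raise EstimationError(f"covariate column {e.column!r} not in dataset")
        factors[e.parameter] = factors[e.parameter] + params[e.name] * (c.covs[e.column] - e.ref)
    for p in typ:
        typ[p] = typ[p] * factors[p]
        if np.any(typ[p] <= 1e-8):
            return None  # inadmissible covariate region for these slopes
    return typ


def _newton_polish(qfun, gfun, eta, max_iter=20):
    """Damped Newton minimisation of a single subject's conditional objective.

    The Hessian comes from forward differences of the (analytic-given-Jacobian)
    gradient, so convergence near the mode is quadratic; warm starts typically
    finish in one or two iterations.
    """
    qv = qfun(eta)
    k = len(eta)
    for _ in range(max_iter):
        g = gfun(eta)
        if np.linalg.norm(g) < 1e-7:
            break
        h = 1e-6
        H = np.empty((k, k))
        for j in range(k):
            e = eta.copy()
            e[j] += h
            H[:, j] = (gfun(e) - g) / h
        H = (H + H.T) / 2.0
        lam = 1e-10
        moved = False
        for _try in range(12):
            try:
                step = np.linalg.solve(H + lam * np.eye(k), -g)
            except np.linalg.LinAlgError:
                lam = max(lam * 10.0, 1e-6)
                continue
            if np.linalg.norm(step) < 1e-9:
                moved = False
                break
            qn = qfun(eta + step)
            if qn <= qv:
                eta = eta + step
                qv = qn
                moved = True
                break
            lam = max(lam * 10.0, 1e-6)
        if not moved:
            break
    return eta, qv


def _ofv_core(params: dict[str, float], structure: ModelStructure, c: _Cohort,
              eta0: np.ndarray | None = None, inner_gtol: float = 1e-8,
              inner_accept: float = 1e-5, max_inner: int = 16):
    """Compute the FOCE-I objective.

    Returns (ofv, etas, converged_mask, J, f_hat) or (PENALTY, ..., None) on an
    inadmissible parameter set.
    """
    typ = _typical_arrays(params, structure, c)
    if typ is None:
        return _PENALTY, eta0, None, None, None
    omegas = np.array([params["omega_CL"], params["omega_Vc"], params["omega_Vp"]])
    sig_a = params["sigma_add"]
    sig_p = params["sigma_prop"]
    if sig_a <= 0 and sig_p <= 0:
        raise EstimationError("residual error model is degenerate (both sigmas zero)")
    n, m = c.y.shape
    active = omegas > _OMEGA_ACTIVE
    omegas_safe = np.where(active, omegas, 1.0)
    winv = np.where(active, 1.0 / omegas_safe ** 2, 0.0)
    y, mask = c.y, c.mask

    CLt, Vct, Vpt, Qt = typ["CL"], typ["Vc"], typ["Vp"], typ["Q"]

    def conc(etas):
        return _conc_cohort(
            c,
            CLt * np.exp(etas[:, 0]),
            Vct * np.exp(etas[:, 1]),
            Vpt * np.exp(etas[:, 2]),
            Qt,
        )

    def resvar(f):
        return np.maximum(sig_a ** 2 + (sig_p * f) ** 2, 1e-30)

    def qval(f, etas):
        R = resvar(f)
        terms = ((y - f) ** 2 / R + np.log(R)) * mask
        return terms.sum(axis=1) + (etas ** 2 * winv).sum(axis=1)

    act_idx = np.flatnonzero(active)

    def jac(etas, f):
        # central differences, all perturbations evaluated in one stacked
        # kernel call: truncation error ~h^2 keeps the gradient noise floor
        # far below the inner tolerance even at high concentrations
        J = np.zeros((n, m, 3))
        if len(act_idx) == 0:
            return J
        h = 1e-5
        K = len(act_idx)
        pert = np.repeat(etas[None, :, :], 2 * K, axis=0)
        for kk, k in enumerate(act_idx):
            pert[2 * kk, :, k] += h
            pert[2 * kk + 1, :, k] -= h
        F = _conc_multi(
            c,
            CLt[None, :] * np.exp(pert[:, :, 0]),
            Vct[None, :] * np.exp(pert[:, :, 1]),
            Vpt[None, :] * np.exp(pert[:, :, 2]),
            np.broadcast_to(Qt, (2 * K, n)),
        )
        for kk, k in enumerate(act_idx):
            J[:, :, k] = (F[2 * kk] - F[2 * kk + 1]) / (2 * h)
        return J

    etas = np.zeros((n, 3)) if eta0 is None else np.array(eta0, float)
    etas[:, ~active] = 0.0
    errstate = np.errstate(over="ignore", invalid="ignore", divide="ignore")
    errstate.__enter__()
    f = conc(etas)
    q = qval(f, etas)
    lam = np.full(n, 1e-6)
    gnorm = np.full(n, np.inf)
    stagnant = np.zeros(n, int)
    # ``done`` is sticky: a subject counts as converged once its gradient
    # meets the target, or once the (undamped) Newton step becomes negligible
    # — the mode is then located far more precisely than the objective needs,
    # even if the raw gradient norm sits on its finite-difference noise floor.
    done = np.zeros(n, bool)
    for _it in range(max_inner):
        J = jac(etas, f)
        R = resvar(f)
        resid = y - f
        dRdf = 2.0 * sig_p ** 2 * f
        dq_df = (-2.0 * resid / R - resid ** 2 * dRdf / R ** 2 + dRdf / R) * mask
        g = np.einsum("nm,nmk->nk", dq_df, J) + 2.0 * etas * winv
        g[:, ~active] = 0.0
        gnorm = np.sqrt((g * g).sum(axis=1))
        done |= gnorm < inner_gtol
        if (done | (stagnant >= 2)).all():
            break
        # when only a few stragglers remain, hand them to the per-subject
        # polisher rather than churning the whole batch
        if _it >= 6 and (~done).sum() <= 3:
            break
        # Newton Hessian of q in the predictions (second derivatives of f
        # itself are dropped; the interaction-curvature terms from R(f) are
        # kept, which restores fast convergence when sigma_prop dominates)
        u = resid
        d2Rdf2 = 2.0 * sig_p ** 2
        d2q_df2 = (2.0 / R + 4.0 * u * dRdf / R ** 2
                   - u ** 2 * d2Rdf2 / R ** 2 + 2.0 * u ** 2 * dRdf ** 2 / R ** 3
                   + d2Rdf2 / R - dRdf ** 2 / R ** 2)
        # floor the per-observation curvature at a fraction of its
        # Gauss-Newton value so the Hessian stays positive definite and every
        # damped step is a descent direction
        d2q_df2 = np.maximum(d2q_df2, 0.2 / R) * mask
        H = np.einsum("nmk,nm,nml->nkl", J, d2q_df2, J)
        H[:, np.arange(3), np.arange(3)] += 2.0 * winv
        for k in range(3):
            if not active[k]:
                H[:, k, k] = 1.0
        Hd = H + lam[:, None, None] * np.eye(3)
        try:
            step = np.linalg.solve(Hd, -g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            return _PENALTY, etas, None, None, None
        step[:, ~active] = 0.0
        # trust region: BSV is log-normal with omega < 1, so an eta move of 2
        # is already extreme; larger proposals only overflow the exponentials
        raw_norm = np.sqrt((step * step).sum(axis=1))
        step *= np.where(raw_norm > 2.0, 2.0 / raw_norm, 1.0)[:, None]
        step_norm = np.sqrt((step * step).sum(axis=1))
        done |= (step_norm < 1e-8) & (lam < 1.0)
        if done.all():
            break
        # backtracking line search along the damped Newton direction; only
        # subjects that keep failing inflate their damping parameter
        improved = np.zeros(n, bool)
        gain = np.zeros(n)
        t_step = np.ones(n)
        remaining = ~done
        for _bt in range(4):
            trial = np.where(remaining[:, None], etas + t_step[:, None] * step, etas)
            f_t = conc(trial)
            q_t = qval(f_t, trial)
            accept = remaining & (q_t <= q - 1e-14)
            gain = np.where(accept, q - q_t, gain)
            etas = np.where(accept[:, None], trial, etas)
            f = np.where(accept[:, None], f_t, f)
            q = np.where(accept, q_t, q)
            improved |= accept
            remaining &= ~accept
            if not remaining.any():
                break
            t_step = np.where(remaining, t_step * 0.3, t_step)
        stagnant = np.where(done | (gain > 1e-8), 0, stagnant + 1)
        lam = np.where(improved, np.maximum(lam * 0.25, 1e-10), lam)
        lam = np.where(~improved & ~done, lam * 8.0, lam)
    # final acceptance: the undamped Newton step estimates the remaining
    # distance to the mode directly, which is the quantity that matters for
    # the objective (a raw gradient norm is scale-dependent and can sit on
    # the finite-difference noise floor for high-concentration subjects)
    J = jac(etas, f)
    R = resvar(f)
    resid = y - f
    dRdf = 2.0 * sig_p ** 2 * f
    dq_df = (-2.0 * resid / R - resid ** 2 * dRdf / R ** 2 + dRdf / R) * mask
    g = np.einsum("nm,nmk->nk", dq_df, J) + 2.0 * etas * winv
    g[:, ~active] = 0.0
    H = 2.0 * np.einsum("nmk,nm,nml->nkl", J, mask / R, J)
    H[:, np.arange(3), np.arange(3)] += 2.0 * winv
    for k in range(3):
        if not active[k]:
            H[:, k, k] = 1.0
    try:
        newton = np.linalg.solve(H, -g[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        newton = np.full_like(etas, np.inf)
    mode_err = np.linalg.norm(newton, axis=1)

    # subjects the batched phase leaves short of their mode (typically
    # near-LLOQ tails bending the conditional objective into a curved valley)
    # are polished individually with BFGS, using the exact gradient given a
    # central-difference Jacobian; this keeps the objective smooth in the
    # outer parameters, which the outer finite-difference optimiser needs
    far = np.flatnonzero(~done & (mode_err > inner_accept))
    if len(far) and active.any():
        for i in far:
            ti = c.times[i][c.mask[i]]
            yi = c.y[i][c.mask[i]]
            # lean closed-form evaluator (single-infusion fast path; the
            # generic multi-dose route goes through the batched evaluator)
            single = c.dose_mask[i].sum() == 1
            if single:
                dj = int(np.flatnonzero(c.dose_mask[i])[0])
                t_rel = ti - c.dose_time[i, dj]
                tinf = c.dose_tinf[i, dj]
                r0 = c.dose_amt[i, dj] / tinf
                te = np.clip(t_rel, 0.0, tinf)
                td = np.maximum(t_rel - tinf, 0.0)
                pos = t_rel > 0

                def fi_of(eta_full, te=te, td=td, pos=pos, r0=r0, tinf=tinf):
                    cl = CLt[i] * np.exp(eta_full[0])
                    vc = Vct[i] * np.exp(eta_full[1])
                    vp = Vpt[i] * np.exp(eta_full[2])
                    qq = Qt[i]
                    k10 = cl / vc; k12 = qq / vc; k21 = qq / vp
                    ss = k10 + k12 + k21
                    disc = np.sqrt(max(ss * ss - 4.0 * k10 * k21, 1e-300))
                    al = (ss + disc) / 2.0; be = (ss - disc) / 2.0
                    A = (al - k21) / disc; B = (k21 - be) / disc
                    fv = (r0 / vc) * (
                        (A / al) * -np.expm1(-al * te) * np.exp(-al * td)
                        + (B / be) * -np.expm1(-be * te) * np.exp(-be * td))
                    return np.where(pos, fv, 0.0)
            else:
                ci = _Cohort(c.ids[i:i + 1], c.times[i:i + 1], c.y[i:i + 1],
                             c.mask[i:i + 1], c.dose_time[i:i + 1], c.dose_amt[i:i + 1],
                             c.dose_tinf[i:i + 1], c.dose_mask[i:i + 1], {})

                def fi_of(eta_full, ci=ci):
                    return _conc_cohort(
                        ci,
                        np.array([CLt[i] * np.exp(eta_full[0])]),
                        np.array([Vct[i] * np.exp(eta_full[1])]),
                        np.array([Vpt[i] * np.exp(eta_full[2])]),
                        np.array([Qt[i]]))[0][ci.mask[0]]

            def qi(eta_act):
                eta_full = np.zeros(3)
                eta_full[act_idx] = eta_act
                fi = fi_of(eta_full)
                Ri = np.maximum(sig_a ** 2 + (sig_p * fi) ** 2, 1e-30)
                return float(np.sum((yi - fi) ** 2 / Ri + np.log(Ri))
                             + (eta_full ** 2 * winv).sum())

            def qi_grad(eta_act):
                eta_full = np.zeros(3)
                eta_full[act_idx] = eta_act
                fi = fi_of(eta_full)
                h = 1e-5
                Ji = np.empty((len(fi), len(act_idx)))
                for kk, k in enumerate(act_idx):
                    up = eta_full.copy(); up[k] += h
                    dn = eta_full.copy(); dn[k] -= h
                    Ji[:, kk] = (fi_of(up) - fi_of(dn)) / (2 * h)
                Ri = np.maximum(sig_a ** 2 + (sig_p * fi) ** 2, 1e-30)
                ui = yi - fi
                dRi = 2.0 * sig_p ** 2 * fi
                dq_dfi = -2.0 * ui / Ri - ui ** 2 * dRi / Ri ** 2 + dRi / Ri
                return dq_dfi @ Ji + 2.0 * eta_full[act_idx] * winv[act_idx]

            eta_i, q_i = _newton_polish(qi, qi_grad, etas[i, act_idx].copy())
            if q_i <= q[i] + 1e-12:
                etas[i, act_idx] = eta_i
                q[i] = q_i
                mode_err[i] = 0.0
                done[i] = True
        f = conc(etas)
        J = jac(etas, f)
    converged = done | (mode_err < inner_accept)
    errstate.__exit__(None, None, None)
    # marginal covariance with interaction: residual variance at IPRED
    R = resvar(f)
    Om = np.zeros((3, 3))
    Om[np.arange(3), np.arange(3)] = omegas ** 2
    C = np.einsum("nmk,kl,njl->nmj", J, Om, J)
    C[:, np.arange(m), np.arange(m)] += np.where(mask, R, 1.0)
    # zero out padded cross terms
    outer = mask[:, :, None] & mask[:, None, :]
    offdiag = ~np.eye(m, dtype=bool)
    C[np.broadcast_to(offdiag, C.shape) & ~outer] = 0.0
    r = (y - f + np.einsum("nmk,nk->nm", J, etas)) * mask
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return _PENALTY, etas, None, None, None
    logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    sol = np.linalg.solve(C, r[:, :, None])[:, :, 0]
    quad = (r * sol).sum(axis=1)
    ofv_i = mask.sum(axis=1) * _LOG2PI + logdet + quad
    return float(ofv_i.sum()), etas, converged, J, f


def foce_objective(m: PopulationModel, data: PKDataset, use_blq: bool = True) -> float:
    """FOCE-I objective function value for a population model on a dataset.

    Raises :class:`InnerConvergenceError` when the empirical-Bayes mode search
    fails for any subject (rather than returning a silently wrong number).
    """
    c = _prepare(data, use_blq=use_blq)
    structure = final_structure(m.cg_ref, m.lpm_ref)
    ofv, _, converged, _, _ = _ofv_core(_params_from_model(m), structure, c)
    if converged is None:
        raise EstimationError("objective not computable at these parameters")
    if not converged.all():
        raise InnerConvergenceError(c.ids[~converged])
    return ofv


# ---------------------------------------------------------------------------
# outer fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a population fit."""

    estimates: dict[str, float]
    structure: ModelStructure
    ofv: float
    converged: bool
    message: str
    model: PopulationModel | None = None
    rse: dict[str, float] | None = None
    ebes: np.ndarray | None = None           # (n_subjects, 3) posterior-mode etas
    subject_ids: np.ndarray | None = None
    shrinkage: dict[str, float] | None = None
    n_obs: int = 0
    n_function_evals: int = 0

    def __repr__(self) -> str:
        est = ", ".join(f"{k}={v:.4g}" for k, v in self.estimates.items())
        return f"FitResult(OFV={self.ofv:.3f}, converged={self.converged}, {est})"


_POSITIVE = ("CL", "Vc", "Q", "Vp", "omega_CL", "omega_Vc", "omega_Vp",
             "sigma_add", "sigma_prop")


def _pack(params: dict[str, float], names: list[str], scales: dict[str, float]) -> np.ndarray:
    return np.array([np.log(params[k]) if k in _POSITIVE else params[k] * scales[k]
                     for k in names])


def _unpack(x: np.ndarray, names: list[str], scales: dict[str, float]) -> dict[str, float]:
    # cap the exponent: a wildly exploratory optimizer step lands in the
    # penalty region either way, without overflow warnings
    return {k: float(np.exp(min(v, 700.0))) if k in _POSITIVE else float(v) / scales[k]
            for k, v in zip(names, x)}


def _recenter(params: dict[str, float], src: ModelStructure, dst: ModelStructure) -> dict[str, float]:
    """Exactly reparameterise covariate effects from the centering constants of
    ``src`` to those of ``dst`` (same effects, different refs).

    With a linear factor ``1 + sum_k s_k (x_k - r_k)`` on parameter P, moving
    the refs multiplies the base typical value by ``c = 1 + sum_k s_k (r'_k -
    r_k)`` and divides every slope on P by the same ``c``; the fitted curve is
    unchanged.
    """
    out = dict(params)
    by_param: dict[str, list[tuple[CovariateEffect, CovariateEffect]]] = {}
    for e_s, e_d in zip(src.effects, dst.effects):
        if (e_s.column, e_s.parameter) != (e_d.column, e_d.parameter):
            raise ValueError("structures differ in effects, cannot recenter")
        by_param.setdefault(e_s.parameter, []).append((e_s, e_d))
    for pname, pairs in by_param.items():
        c = 1.0 + sum(params[e_s.name] * (e_d.ref - e_s.ref) for e_s, e_d in pairs)
        if c <= 0:
            raise EstimationError(f"recentering leaves {pname} non-positive")
        out[pname] = params[pname] * c
        for e_s, e_d in pairs:
            out[e_s.name] = params[e_s.name] / c
    return out


def _slope_scales_bounds(structure: ModelStructure, c: _Cohort):
    """Covariate-SD scaling and admissibility bounds for slope parameters.

    A slope on parameter P must keep ``1 + slope*(x - ref) > 0`` for every
    observed covariate value x, i.e. slope in (-1/(xmax-ref), 1/(ref-xmin));
    the optimizer is boxed slightly inside that interval so line searches
    never cross into the penalised inadmissible region.  Scaling by the
    covariate SD puts slope gradients on a footing comparable with the
    log-transformed positive parameters.
    """
    scales: dict[str, float] = {}
    bounds: dict[str, tuple[float, float]] = {}
    for e in structure.effects:
        x = c.covs[e.column]
        sd = float(np.std(x))
        scales[e.name] = sd if sd > 0 else 1.0
        xmin, xmax = float(np.min(x)), float(np.max(x))
        lo = -0.999 / (xmax - e.ref) if xmax > e.ref else -np.inf
        hi = 0.999 / (e.ref - xmin) if xmin < e.ref else np.inf
        bounds[e.name] = (lo, hi)
    return scales, bounds


def fit(
    data: PKDataset,
    init: PopulationModel | dict[str, float],
    structure: ModelStructure | None = None,
    compute_rse: bool = True,
    use_blq: bool = True,
    maxiter: int = 60,
) -> FitResult:
    """Fit the population model by minimising the FOCE-I objective.

    Positive parameters (typical values, omegas, sigmas) are log-transformed
    for the outer quasi-Newton optimisation; covariate slopes stay on their
    natural scale and may be negative.  Relative standard errors come from the
    inverse of the finite-difference Hessian of the objective (covariance
    ``2 H^{-1}`` since OFV is -2 log L); a singular Hessian reports RSEs as
    unavailable instead of failing the fit.
    """
    c = _prepare(data, use_blq=use_blq)
    if isinstance(init, PopulationModel):
        if structure is None:
            structure = final_structure(init.cg_ref, init.lpm_ref)
        params0 = _params_from_model(init)
    else:
        if structure is None:
            raise ValueError("structure must be given when init is a plain dict")
        params0 = dict(init)
    names = structure.parameter_names()
    missing = [k for k in names if k not in params0]
    if missing:
        params0 = dict(params0)
        for k in missing:
            params0[k] = 0.0 if k.startswith("beta_") else None
        still = [k for k, v in params0.items() if v is None]
        if still:
            raise ValueError(f"no initial value for parameters {still}")
    # floors keep log-transform finite when a variance component starts near 0
    for k in _POSITIVE:
        if k in names and params0[k] < 1e-6:
            params0 = dict(params0)
            params0[k] = 1e-3 if k.startswith(("omega", "sigma")) else 1e-2

    # optimise on a covariate parameterisation centred at the cohort medians:
    # an exact reparameterisation that decorrelates base typical values from
    # their slopes and conditions the outer problem far better than distant
    # reference covariate values would
    internal = ModelStructure(tuple(
        CovariateEffect(e.column, e.parameter, float(np.median(c.covs[e.column])))
        for e in structure.effects
    ))
    params0_int = _recenter(params0, structure, internal)

    state = {"nev": 0, "start": np.zeros((c.n_subjects, 3))}
    scales, slope_bounds = _slope_scales_bounds(internal, c)

    # The inner mode search starts from per-subject etas that are FROZEN for
    # the duration of each outer iteration and refreshed in the optimiser
    # callback.  A start varying call-by-call would make the objective
    # path-dependent — the conditional objective can be multimodal for
    # sparse subjects, and different starts can settle in different basins —
    # which poisons finite-difference gradients; a start frozen per
    # iteration keeps all evaluations of one gradient cluster mutually
    # consistent while retaining warm-start speed.
    state["best"] = (np.inf, None)

    def objective(x):
        state["nev"] += 1
        p = _unpack(x, names, scales)
        ofv, _, converged, _, _ = _ofv_core(p, internal, c, eta0=state["start"])
        if converged is None:
            return _PENALTY
        if ofv < state["best"][0]:
            state["best"] = (ofv, x.copy())
        return ofv

    def refresh_start(xk):
        p = _unpack(xk, names, scales)
        _, etas, converged, _, _ = _ofv_core(p, internal, c, eta0=state["start"])
        if converged is not None:
            state["start"] = etas

    x0 = _pack(params0_int, names, scales)
    bounds = []
    for k in names:
        if k in slope_bounds:
            lo, hi = slope_bounds[k]
            bounds.append((lo * scales[k], hi * scales[k]))
        else:
            bounds.append((None, None))
    x0 = np.array([np.clip(v, lo if lo is not None else -np.inf,
                           hi if hi is not None else np.inf)
                   for v, (lo, hi) in zip(x0, bounds)])
    res = minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        callback=refresh_start,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 5e-4, "eps": 1e-5},
    )
    est = _recenter(_unpack(res.x, names, scales), internal, structure)
    ofv, etas, converged_mask, J, f = _ofv_core(est, structure, c)
    # an "abnormal" line-search exit at the finite-difference noise floor
    # still counts as converged when the remaining gradient is small relative
    # to the objective's curvature scale
    small_grad = res.jac is not None and np.max(np.abs(res.jac)) < 0.5
    ok = (bool(res.success) or small_grad) and converged_mask is not None \
        and bool(converged_mask.all()) and ofv < _PENALTY / 2
    if converged_mask is None or ofv >= _PENALTY / 2:
        # a failed line search can leave the optimiser's final point inside
        # the penalised region; fall back to the best admissible iterate
        best_ofv, best_x = state["best"]
        if best_x is None:
            raise EstimationError(
                f"fit left the admissible region (best OFV so far {res.fun:.3f})")
        est = _recenter(_unpack(best_x, names, scales), internal, structure)
        ofv, etas, converged_mask, J, f = _ofv_core(est, structure, c)
        if converged_mask is None:
            raise EstimationError(
                f"fit left the admissible region (best OFV so far {best_ofv:.3f})")
        ok = bool(converged_mask.all()) and ofv < _PENALTY / 2

    omegas = np.array([est["omega_CL"], est["omega_Vc"], est["omega_Vp"]])
    shrink = {}
    for k, nm in enumerate(("omega_CL", "omega_Vc", "omega_Vp")):
        if omegas[k] > _OMEGA_ACTIVE and c.n_subjects > 1:
            sd = float(np.std(etas[:, k], ddof=1))
            shrink[nm] = float(np.clip(100.0 * (1.0 - sd / omegas[k]), 0.0, 100.0))
        else:
            shrink[nm] = float("nan")

    rse = None
    if compute_rse:
        rse = _rse_from_hessian(est, names, structure, c)

    return FitResult(
        estimates=est, structure=structure, ofv=float(ofv), converged=ok,
        message=str(res.message), model=_model_from_params(est, structure),
        rse=rse, ebes=etas, subject_ids=c.ids, shrinkage=shrink,
        n_obs=c.n_obs, n_function_evals=state["nev"],
    )


def _rse_from_hessian(est, names, structure, c) -> dict[str, float] | None:
    """RSE% from the inverse FD Hessian of the OFV on the natural scale."""
    x = np.array([est[k] for k in names])
    steps = np.maximum(np.abs(x) * 1e-3, 1e-6)

    def f_at(dx):
        p = {k: float(v) for k, v in zip(names, x + dx)}
        if any(p[k] <= 0 for k in _POSITIVE if k in p):
            return None
        ofv, _, conv, _, _ = _ofv_core(p, structure, c)
        return None if conv is None else ofv

    k = len(x)
    H = np.zeros((k, k))
    f0 = f_at(np.zeros(k))
    if f0 is None:
        return None
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            vals = [f_at(ei + ej), f_at(ei - ej), f_at(-ei + ej), f_at(-ei - ej)]
            if any(v is None for v in vals):
                return None
            H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * steps[i] * steps[j])
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    if np.any(var <= 0):
        return None
    return {nm: float(100.0 * np.sqrt(v) / abs(xv)) if xv != 0 else float("inf")
            for nm, v, xv in zip(names, var, x)}


# ---------------------------------------------------------------------------
# model comparison and covariate search
# ---------------------------------------------------------------------------

def compare_nested(fit_full: FitResult, fit_reduced: FitResult, df: int) -> tuple[float, bool]:
    """Likelihood-ratio comparison of nested fits.

    Returns (delta_ofv, significant) with delta_ofv = OFV_reduced - OFV_full;
    significance thresholds are 3.84 for 1 df and 5.99 for 2 df.
    """
    if df not in NESTED_THRESHOLDS:
        raise ValueError(f"no threshold tabulated for df={df}")
    delta = fit_reduced.ofv - fit_full.ofv
    return float(delta), bool(delta > NESTED_THRESHOLDS[df])


@dataclass
class CovariateSearchTrace:
    """Ordered record of forward-selection / backward-elimination steps."""

    steps: list[dict] = field(default_factory=list)

    def record(self, phase: str, effect: CovariateEffect, delta_ofv: float, action: str):
        self.steps.append(dict(phase=phase, column=effect.column,
                               parameter=effect.parameter,
                               delta_ofv=float(delta_ofv), action=action))

    def included(self) -> list[tuple[str, str]]:
        kept = []
        for s in self.steps:
            key = (s["column"], s["parameter"])
            if s["action"] == "included":
                kept.append(key)
            elif s["action"] == "removed" and key in kept:
                kept.remove(key)
        return kept


def _screen_slope(c: _Cohort, params: dict[str, float], ofv0: float,
                  structure: ModelStructure, e: CovariateEffect) -> tuple[float, float]:
    """OFV drop (and optimal slope) from optimising only the candidate's
    slope with all other parameters fixed.  A cheap lower bound on the
    full-refit OFV drop, used to rank candidates before confirming the best
    one with a full refit — which is then started at the screened slope, so
    it begins near the joint optimum instead of at zero."""
    from scipy.optimize import minimize_scalar

    x = c.covs[e.column]
    xmin, xmax = float(np.min(x)), float(np.max(x))
    lo = -0.95 / (xmax - e.ref) if xmax > e.ref else -10.0
    hi = 0.95 / (e.ref - xmin) if xmin < e.ref else 10.0
    st2 = structure.with_effect(e)

    def f1(b):
        p = dict(params)
        p[e.name] = float(b)
        ofv, _, conv, _, _ = _ofv_core(p, st2, c)
        return _PENALTY if conv is None else ofv

    r = minimize_scalar(f1, bounds=(lo, hi), method="bounded",
                        options={"xatol": (hi - lo) * 1e-3})
    return float(ofv0 - r.fun), float(r.x)


def stepwise_covariate_search(
    data: PKDataset,
    candidates: list[tuple[str, str]],
    init: PopulationModel | dict[str, float],
    base_structure: ModelStructure = ModelStructure(),
    refs: dict[str, float] | None = None,
    forward_threshold: float = FORWARD_THRESHOLD,
    backward_threshold: float = BACKWARD_THRESHOLD,
    use_blq: bool = True,
) -> tuple[FitResult, CovariateSearchTrace]:
    """Stepwise forward-selection / backward-elimination covariate search.

    ``candidates`` are (dataset column, PK parameter) pairs tested as linear
    effects ``P_base * (1 + slope * (x - ref))`` centred at ``refs[column]``
    (dataset median when not given).

    Each forward step first scores every remaining candidate by optimising
    its slope alone (a cheap lower bound on the refit OFV drop), then refits
    the full model for the top-scoring candidate; it is included when the
    full-refit OFV drop reaches ``forward_threshold`` (p < 0.01, 1 df).  The
    backward phase refits without each retained effect and removes any whose
    removal costs <= ``backward_threshold`` OFV units (retention demands
    p < 0.001).  Ties break by candidate order.
    """
    if isinstance(init, PopulationModel):
        base_params = {
            "CL": init.theta1, "Vc": init.theta3, "Q": init.Q, "Vp": init.Vp,
            "omega_CL": max(init.omega_CL, 1e-3), "omega_Vc": max(init.omega_Vc, 1e-3),
            "omega_Vp": max(init.omega_Vp, 1e-3),
            "sigma_add": max(init.sigma_add, 1e-3), "sigma_prop": max(init.sigma_prop, 1e-3),
        }
    else:
        base_params = dict(init)
    refs = dict(refs or {})
    obs = data.df[data.df["EVID"] == 0]
    for col, _ in candidates:
        if col not in data.df.columns:
            raise EstimationError(f"candidate covariate column {col!r} not in dataset")
        refs.setdefault(col, float(obs.groupby(obs["ID"]).first()[col].median()))

    cohort = _prepare(data, use_blq=use_blq)
    trace = CovariateSearchTrace()
    structure = base_structure
    fit_cache: dict[frozenset, FitResult] = {}

    def cached_fit(init_params, st):
        key = frozenset(st.effects)
        if key not in fit_cache:
            fit_cache[key] = fit(data, init_params, st, compute_rse=False,
                                 use_blq=use_blq, maxiter=40)
        return fit_cache[key]

    current = cached_fit(base_params, structure)
    remaining = [CovariateEffect(col, par, refs[col]) for col, par in candidates]

    while remaining:
        scored = []
        for e in remaining:
            params = dict(current.estimates)
            params[e.name] = 0.0
            delta, b_opt = _screen_slope(cohort, params, current.ofv, structure, e)
            scored.append((delta, b_opt, e))
        scored.sort(key=lambda t: -t[0])
        best_screen, best_b, best_e = scored[0]
        for delta, _, e in scored[1:]:
            trace.record("forward", e, delta, "not selected")
        cand_init = dict(current.estimates)
        cand_init[best_e.name] = best_b
        cand_fit = cached_fit(cand_init, structure.with_effect(best_e))
        best_delta = current.ofv - cand_fit.ofv
        if best_delta >= forward_threshold:
            trace.record("forward", best_e, best_delta, "included")
            structure = structure.with_effect(best_e)
            current = cand_fit
            remaining = [e for e in remaining if e is not best_e]
        else:
            trace.record("forward", best_e, best_delta, "rejected")
            break

    removable = [e for e in structure.effects if e not in base_structure.effects]
    changed = True
    while changed and removable:
        changed = False
        scored = []
        for e in removable:
            red_init = {k: v for k, v in current.estimates.items() if k != e.name}
            red_fit = cached_fit(red_init, structure.without_effect(e))
            scored.append((red_fit.ofv - current.ofv, e, red_fit))
        worst_delta, worst_e, worst_fit = min(scored, key=lambda s: s[0])
        if worst_delta <= backward_threshold:
            trace.record("backward", worst_e, worst_delta, "removed")
            structure = structure.without_effect(worst_e)
            current = worst_fit
            removable = [e for e in removable if e is not worst_e]
            changed = True
        else:
            for delta, e, _ in scored:
                trace.record("backward", e, delta, "retained")
    return current, trace


# ---------------------------------------------------------------------------
# nonparametric bootstrap
# ---------------------------------------------------------------------------

def bootstrap(
    data: PKDataset,
    final: FitResult,
    n_boot: int,
    seed,
    resample: bool = True,
    use_blq: bool = True,
) -> pd.DataFrame:
    """Nonparametric bootstrap of the final model: resample subjects with
    replacement and refit each replicate (warm-started at the point estimates).

    Returns a DataFrame indexed by parameter with columns ``median``, ``ci_low``
    and ``ci_high`` (2.5/50/97.5 percentiles over converged replicates) plus a
    ``failed_fraction`` attribute in ``DataFrame.attrs``.  With
    ``resample=False`` every replicate is the identity resample, so the CI
    collapses onto the point estimates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    ids = data.df["ID"].unique()
    names = final.structure.parameter_names()
    draws, failures = [], 0
    for _ in range(n_boot):
        chosen = rng.choice(ids, size=len(ids), replace=True) if resample else ids
        parts = []
        for new_id, sid in enumerate(chosen, start=1):
            part = data.df[data.df["ID"] == sid].copy()
            part["ID"] = new_id
            parts.append(part)
        boot_data = PKDataset(pd.concat(parts, ignore_index=True))
        try:
            res = fit(boot_data, final.estimates, final.structure,
                      compute_rse=False, use_blq=use_blq)
        except EstimationError:
            failures += 1
            continue
        if not res.converged:
            failures += 1
            continue
        draws.append([res.estimates[k] for k in names])
    if not draws:
        raise EstimationError("all bootstrap replicates failed to converge")
    arr = np.array(draws)
    lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5], axis=0)
    out = pd.DataFrame({"median": med, "ci_low": lo, "ci_high": hi}, index=names)
    out.attrs["failed_fraction"] = failures / n_boot
    out.attrs["n_converged"] = len(draws)
    return out
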