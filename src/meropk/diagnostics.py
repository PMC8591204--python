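"""Model-evaluation diagnostics: conditional weighted residuals and the
prediction- and variability-corrected visual predictive check (pcVPC).

CWRES follow the FOCE linearisation: with ``G_i`` the Jacobian of the model at
the subject's posterior-mode etas, the approximate marginal distribution of
``y_i`` is ``N(f_i(eta_hat) - G_i eta_hat, C_i)`` with
``C_i = G_i Omega G_i' + R_i``, and

    CWRES_i = L_i^{-1} (y_i - f_i(eta_hat) + G_i eta_hat),   C_i = L_i L_i'.

Under a correctly specified model these are approximately standard normal.

The pcVPC corrects each observed and simulated concentration for the
within-bin spread of population predictions before comparing percentile
bands (binning is one bin per nominal sampling time):

    pcY_ij  = Y_ij * PRED_bin / PRED_ij                    (prediction corr.)
    pvcY_ij = PRED_bin + (pcY_ij - PRED_bin) * W_bin/W_ij  (variability corr.)

where PRED_bin and W_bin are the bin medians of the population prediction and
of the model's approximate marginal SD ``W_ij = sqrt((G0 Omega G0' + R)_jj)``
evaluated at eta=0.  Predose bins (PRED = 0) are left uncorrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import EstimationError, FitResult, _conc_cohort, _ofv_core, _params_from_model, _prepare
from .io import PKDataset
from .popmodel import PopulationModel

__all__ = ["VPCResult", "conditional_residuals", "pc_vpc", "gof_plots", "vpc_plot"]


def _model_of(fit: FitResult | PopulationModel) -> PopulationModel:
    if isinstance(fit, PopulationModel):
        return fit
    if fit.model is None:
        raise EstimationError("fit does not map onto the final covariate model")
    return fit.model


def conditional_residuals(fit: FitResult | PopulationModel, data: PKDataset) -> pd.DataFrame:
    """Per-observation diagnostics: PRED, IPRED and CWRES.

    Returns a DataFrame with one row per likelihood observation (predose rows
    carry no information and are excluded) and columns ID, TIME, DV, PRED,
    IPRED, CWRES.

    Raises
    ------
    EstimationError
        If both residual-error components and all BSV terms are zero (the
        residual covariance is singular and CWRES are undefined).
    """
    m = _model_of(fit)
    if m.sigma_add == 0 and m.sigma_prop == 0:
        raise EstimationError("degenerate variance model: CWRES undefined")
    c = _prepare(data)
    params = _params_from_model(m)
    ofv, etas, converged, J, f_hat = _ofv_core(params, _final_structure(m), c)
    if converged is None or not converged.all():
        raise EstimationError("linearisation failed: inner optimisation did not converge")
    omegas = m.omegas
    R = np.maximum(m.sigma_add ** 2 + (m.sigma_prop * f_hat) ** 2, 1e-30)
    n, mm = c.y.shape
    Om = np.diag(omegas ** 2)
    C = np.einsum("nmk,kl,njl->nmj", J, Om, J)
    C[:, np.arange(mm), np.arange(mm)] += np.where(c.mask, R, 1.0)
    outer = c.mask[:, :, None] & c.mask[:, None, :]
    offdiag = ~np.eye(mm, dtype=bool)
    C[np.broadcast_to(offdiag, C.shape) & ~outer] = 0.0
    r = (c.y - f_hat + np.einsum("nmk,nk->nm", J, etas)) * c.mask
    L = np.linalg.cholesky(C)
    cwres = np.linalg.solve(L, r[:, :, None])[:, :, 0]
    pred = _conc_cohort(c, *_typ_arrays(m, c))
    rows = []
    for i in range(n):
        for j in range(mm):
            if c.mask[i, j]:
                rows.append(dict(ID=c.ids[i], TIME=c.times[i, j], DV=c.y[i, j],
                                 PRED=pred[i, j], IPRED=f_hat[i, j], CWRES=cwres[i, j]))
    return pd.DataFrame(rows)


def _final_structure(m: PopulationModel):
    from .estimation import final_structure
    return final_structure(m.cg_ref, m.lpm_ref)


def _typ_arrays(m: PopulationModel, c):
    cl = m.theta1 * (1.0 + m.theta2 * (c.covs["CRCL"] - m.cg_ref))
    vc = m.theta3 * (1.0 + m.theta4 * (c.covs["LPM"] - m.lpm_ref))
    return cl, vc, np.full(len(cl), m.Vp), np.full(len(cl), m.Q)


@dataclass
class VPCResult:
    """Numeric pcVPC output.

    ``table`` has one row per (bin, percentile) with the corrected observed
    percentile and the 95% CI of the same percentile across simulated
    replicates; ``inside_fraction`` is the fraction of corrected observations
    inside the pooled simulated 80% prediction interval (10th-90th).
    """

    table: pd.DataFrame
    inside_fraction: float
    n_sim: int

    def __post_init__(self) -> None:
        if not 0 <= self.inside_fraction <= 1:
            raise ValueError("inside_fraction must be in [0, 1]")


def pc_vpc(
    fit: FitResult | PopulationModel,
    data: PKDataset,
    n_sim: int = 1000,
    seed=None,
    percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0),
    min_bin_size: int = 2,
) -> VPCResult:
    """Prediction- and variability-corrected visual predictive check.

    Simulates ``n_sim`` replicate datasets under the original design (same
    subjects, covariates, doses and sampling times; fresh BSV and residual
    draws, negative observations truncated at 0 and predose samples fixed at
    0), applies the pc/pvc correction to both observed and simulated values,
    and summarises percentile bands per nominal-time bin.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for stable percentile CIs")
    m = _model_of(fit)
    rng = np.random.default_rng(seed)
    c = _prepare(data)
    n, mm = c.y.shape
    CLt, Vct, Vpt, Qt = _typ_arrays(m, c)
    pred = _conc_cohort(c, CLt, Vct, Vpt, Qt)

    # marginal SD at eta=0 for the variability correction
    h = 1e-6
    J0 = np.zeros((n, mm, 3))
    base_args = [CLt, Vct, Vpt]
    for k in range(3):
        pert = [a.copy() for a in base_args]
        pert[k] = pert[k] * np.exp(h)
        J0[:, :, k] = (_conc_cohort(c, pert[0], pert[1], pert[2], Qt) - pred) / h
    var_pop = (J0 ** 2 * (m.omegas ** 2)).sum(axis=2) \
        + m.sigma_add ** 2 + (m.sigma_prop * pred) ** 2
    W = np.sqrt(np.maximum(var_pop, 1e-30))

    # simulate replicates (stacked: (n_sim, n, mm))
    etas = rng.standard_normal((n_sim, n, 3)) * m.omegas
    sims = np.empty((n_sim, n, mm))
    for s in range(n_sim):
        CLi = CLt * np.exp(etas[s, :, 0])
        Vci = Vct * np.exp(etas[s, :, 1])
        Vpi = Vpt * np.exp(etas[s, :, 2])
        ipred = _conc_cohort(c, CLi, Vci, Vpi, Qt)
        eps = rng.standard_normal((2, n, mm))
        sims[s] = np.maximum(ipred * (1.0 + m.sigma_prop * eps[0]) + m.sigma_add * eps[1], 0.0)

    # bin by nominal time
    times = np.round(c.times, 6)
    bins = np.unique(times[c.mask])
    obs_corr = np.full((n, mm), np.nan)
    sim_corr = np.full((n_sim, n, mm), np.nan)
    bin_of = np.full((n, mm), -1)
    merged = []
    for b, tval in enumerate(bins):
        sel = (times == tval) & c.mask
        if sel.sum() < min_bin_size and b > 0:
            merged.append(tval)
        bin_of[sel] = b
        pred_bin = np.median(pred[sel])
        w_bin = np.median(W[sel])
        if pred_bin <= 0:
            obs_corr[sel] = c.y[sel]
            sim_corr[:, sel] = sims[:, sel]
            continue
        pc_obs = c.y[sel] * pred_bin / pred[sel]
        obs_corr[sel] = pred_bin + (pc_obs - pred_bin) * (w_bin / W[sel])
        pc_sim = sims[:, sel] * pred_bin / pred[sel]
        sim_corr[:, sel] = pred_bin + (pc_sim - pred_bin) * (w_bin / W[sel])
    if merged:
        warnings.warn(f"bins at t={merged} below {min_bin_size} observations", stacklevel=2)

    rows = []
    inside = 0
    total = 0
    for b, tval in enumerate(bins):
        sel = bin_of == b
        if not sel.any():
            continue
        o = obs_corr[sel]
        s = sim_corr[:, sel]                    # (n_sim, n_in_bin)
        lo_b, hi_b = np.percentile(s, [10.0, 90.0])
        inside += int(np.sum((o >= lo_b) & (o <= hi_b)))
        total += len(o)
        sim_pcts = np.percentile(s, percentiles, axis=1)   # (3, n_sim)
        for p, obs_p, sim_p in zip(percentiles, np.percentile(o, percentiles), sim_pcts):
            ci_lo, ci_hi = np.percentile(sim_p, [2.5, 97.5])
            rows.append(dict(bin_time=float(tval), percentile=float(p),
                             observed=float(obs_p), sim_median=float(np.median(sim_p)),
                             ci_low=float(ci_lo), ci_high=float(ci_hi)))
    table = pd.DataFrame(rows)
    return VPCResult(table=table, inside_fraction=inside / total, n_sim=n_sim)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def gof_plots(resid: pd.DataFrame, path) -> None:
    """Four-panel goodness-of-fit figure: CWRES vs time, CWRES vs PRED,
    DV vs PRED, DV vs IPRED."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    axes[0, 0].scatter(resid["TIME"], resid["CWRES"], s=12, alpha=0.6)
    axes[0, 0].axhline(0, ls="--", c="gray")
    axes[0, 0].set(xlabel="time (h)", ylabel="CWRES")
    axes[0, 1].scatter(resid["PRED"], resid["CWRES"], s=12, alpha=0.6)
    axes[0, 1].axhline(0, ls="--", c="gray")
    axes[0, 1].set(xlabel="PRED (mg/L)", ylabel="CWRES")
    for ax, col in ((axes[1, 0], "PRED"), (axes[1, 1], "IPRED")):
        ax.scatter(resid[col], resid["DV"], s=12, alpha=0.6)
        lim = max(resid["DV"].max(), resid[col].max()) * 1.05
        ax.plot([0, lim], [0, lim], ls="--", c="gray")
        ax.set(xlabel=f"{col} (mg/L)", ylabel="observed (mg/L)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def vpc_plot(vpc: VPCResult, path) -> None:
    """Percentile bands of the pcVPC with simulated 95% CIs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for p, style in zip(sorted(vpc.table["percentile"].unique()), ("--", "-", "--")):
        sub = vpc.table[vpc.table["percentile"] == p].sort_values("bin_time")
        ax.fill_between(sub["bin_time"], sub["ci_low"], sub["ci_high"], alpha=0.25)
        ax.plot(sub["bin_time"], sub["observed"], style, marker="o", ms=3,
                label=f"observed {p:g}th")
    ax.set(xlabel="time (h)", ylabel="corrected concentration (mg/L)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
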