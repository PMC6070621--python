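"""Fitting the negative binomial mixed model by IWLS, per-taxon scans,
and the arcsine-square-root LMM comparator.

For one taxon with counts y_ij the NBMM is

    y_ij ~ NB(mu_ij, theta)
    log(mu_ij) = log(T_ij) + X_ij beta + Z_ij b_i,    b_i ~ N(0, Psi)

with fixed design X_ij = (1, X_i, t_ij, X_i t_ij) (group, time and their
interaction, plus any extra covariates) and random design Z_ij = (1) or
(1, t_ij).  The IWLS algorithm alternates (a) a Newton-Raphson update of
the dispersion theta on the NB likelihood at the current conditional means
(linear predictor including the predicted random effects) with (b) a
weighted linear mixed model fit of the PQL working response, optionally
with AR(1)/CAR(1) within-subject residual correlation.  At convergence the
fixed effects are tested with Wald t-tests from the final working LMM.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import LongitudinalDataset, ScanResult
from .lmm_engine import LMMFit, fit_lmm, predict_re_loo, wald_inference
from .nb_core import estimate_dispersion, nb_glm_irls, pseudo_data

__all__ = [
    "ModelSpec",
    "FitControl",
    "FittedNBMM",
    "fit_nbmm",
    "scan_taxa",
    "fit_lmm_arcsine",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Model layout for one longitudinal differential-abundance fit.

    Parameters
    ----------
    group_var : str
        Host variable of interest (binary group indicator or numeric).
    time_var : str
        Time column; enters as a linear trend unless ``time_basis`` maps
        the raw times to several columns (polynomial/spline hook).
    extra_covariates : sequence of str
        Additional fixed-effect covariates.
    include_interaction : bool
        Include group x time interaction columns.
    random : {"intercept_only", "intercept_and_time"}
        Subject-level random design Z_ij = (1) or (1, t_ij).
    correlation : {"independent", "ar1", "car1"}
        Within-subject residual correlation of the working model.
    psi_structure : {"general_pd", "diagonal"}
        Random-effects covariance parameterization.
    """

    group_var: str
    time_var: str = "time"
    extra_covariates: Sequence[str] = ()
    include_interaction: bool = True
    random: str = "intercept_only"
    correlation: str = "independent"
    psi_structure: str = "general_pd"
    time_basis: Callable | None = None

    def __post_init__(self):
        if self.random not in ("intercept_only", "intercept_and_time"):
            raise ValueError(f"unknown random structure {self.random!r}")
        if self.correlation not in ("independent", "ar1", "car1"):
            raise ValueError(f"unknown correlation kind {self.correlation!r}")

    @property
    def tested_terms(self) -> list:
        terms = [self.group_var]
        if self.include_interaction:
            terms.append(f"{self.group_var}:{self.time_var}")
        return terms


@dataclass
class FitControl:
    """IWLS tolerances and variants.

    The loop stops when the largest absolute change in the linear
    predictor drops below ``tol`` (parameterization-invariant), or after
    ``max_outer`` iterations.  ``dispersion_means`` selects the means at
    which the NB likelihood is maximized in the theta step:
    ``"conditional"`` (default) uses the fitted conditional means
    including the predicted random effects; ``"loo"`` replaces each
    subject's prediction with its leave-one-observation-out counterpart —
    a diagnostic for the shrinkage-overfitting bias of the plug-in, which
    trades that upward bias for a downward one from prediction error.
    ``final_reml`` re-fits the working LMM of the last iteration by REML
    and reports inference from that fit (the loop itself always uses ML,
    whose profiled likelihood is cheap and comparable across iterations).
    """

    tol: float = 1e-6
    max_outer: int = 50
    theta_init: float = 1.0
    dispersion_means: str = "conditional"
    final_reml: bool = False

    def __post_init__(self):
        if self.dispersion_means not in ("loo", "conditional"):
            raise ValueError("dispersion_means must be 'loo' or 'conditional'")


@dataclass
class FittedNBMM:
    """Converged (or flagged) NBMM fit for one taxon."""

    lmm: LMMFit
    theta: float
    n_iter: int
    converged: bool
    history: list  # per outer iteration: (theta, max |delta eta|)
    wald: pd.DataFrame
    method: str = "nbmm"

    @property
    def coef(self) -> pd.Series:
        return pd.Series(self.lmm.beta, index=self.lmm.beta_names)

    @property
    def pvalues(self) -> pd.Series:
        return self.wald["p"]


def _encode_column(values: pd.Series, name: str) -> np.ndarray:
    """Numeric columns pass through; two-level factors become 0/1 by
    sorted level order."""
    if pd.api.types.is_numeric_dtype(values) and not isinstance(
        values.dtype, pd.CategoricalDtype
    ):
        return values.to_numpy(dtype=float)
    levels = sorted(pd.unique(values.astype(str)))
    if len(levels) != 2:
        raise ValueError(
            f"covariate {name!r} must be numeric or binary; levels: {levels}"
        )
    return (values.astype(str) == levels[1]).to_numpy(dtype=float)


def build_design(ds: LongitudinalDataset, spec: ModelSpec):
    """Fixed/random design matrices, offset, groups and times for a fit.

    Returns ``(X, names, Z, groups, times, offset)`` with rows in the
    dataset's (subject, time) order.
    """
    df = ds.samples
    for v in (spec.group_var, spec.time_var, *spec.extra_covariates):
        if v not in df.columns:
            raise ValueError(f"model variable {v!r} not found in the metadata")
    g = _encode_column(df[spec.group_var], spec.group_var)
    t = df[spec.time_var].to_numpy(dtype=float)

    if spec.time_basis is not None:
        tcols = np.atleast_2d(np.asarray(spec.time_basis(t), dtype=float))
        if tcols.shape[0] != len(t):
            tcols = tcols.T
        tnames = [f"{spec.time_var}{k + 1}" for k in range(tcols.shape[1])]
    else:
        tcols = t[:, None]
        tnames = [spec.time_var]

    cols = [np.ones(len(df)), g]
    names = ["Intercept", spec.group_var]
    for v in spec.extra_covariates:
        cols.append(_encode_column(df[v], v))
        names.append(v)
    for j, nm in enumerate(tnames):
        cols.append(tcols[:, j])
        names.append(nm)
    if spec.include_interaction:
        for j, nm in enumerate(tnames):
            cols.append(g * tcols[:, j])
            names.append(f"{spec.group_var}:{nm}")
    X = np.column_stack(cols)

    if spec.random == "intercept_and_time":
        Z = np.column_stack([np.ones(len(df)), t])
    else:
        Z = np.ones((len(df), 1))

    offset = np.log(ds.total_reads.astype(float))
    return X, names, Z, ds.subjects, ds.times, offset


def fit_nbmm(
    ds: LongitudinalDataset,
    taxon: str,
    spec: ModelSpec,
    control: FitControl | None = None,
) -> FittedNBMM:
    """Fit the NBMM for one taxon by the alternating IWLS algorithm.

    Initialization is a fixed-effects-only NB regression (IRLS at
    theta=1); each outer iteration then re-estimates theta at the current
    conditional means, rebuilds the working response/weights, and refits
    the weighted LMM (warm-starting its variance-parameter search).
    Non-convergence yields a usable fit flagged ``converged=False`` with a
    warning; an all-zero taxon is an error (filter such taxa first).
    """
    control = control or FitControl()
    y = ds.taxon_counts(taxon).astype(float)
    if np.all(y == 0):
        raise ValueError(
            f"taxon {taxon!r} has zero counts in every sample; "
            "apply filter_taxa before fitting"
        )
    X, names, Z, groups, times, offset = build_design(ds, spec)
    if ds.n_subjects < 2:
        raise ValueError("at least two subjects are required")

    _, eta, *_ = nb_glm_irls(y, X, offset, theta=control.theta_init)

    history = []
    converged = False
    theta = control.theta_init
    phi = None
    lmm = None
    eta_disp = eta  # means for the theta update
    codes = pd.factorize(groups)[0]
    it = 0
    for it in range(1, control.max_outer + 1):
        disp = estimate_dispersion(y, np.exp(eta_disp), theta_init=theta)
        theta = disp.theta
        work = pseudo_data(y, eta, theta)
        lmm = fit_lmm(
            work.z - offset,
            work.w,
            X,
            Z,
            groups,
            times,
            re_structure=spec.psi_structure,
            correlation=spec.correlation,
            beta_names=names,
            start=phi,
        )
        phi = lmm.opt_params
        re_part = np.einsum("nq,nq->n", Z, lmm.blups[codes])
        eta_new = offset + X @ lmm.beta + re_part
        if control.dispersion_means == "loo":
            b_loo = predict_re_loo(
                lmm, work.z - offset, work.w, X, Z, groups, times
            )
            eta_disp = offset + X @ lmm.beta + np.einsum("nq,nq->n", Z, b_loo)
        else:
            eta_disp = eta_new
        delta = float(np.max(np.abs(eta_new - eta)))
        eta = eta_new
        history.append((theta, delta))
        if delta < control.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"IWLS did not converge for taxon {taxon!r} within "
            f"{control.max_outer} iterations (last max |delta eta| = "
            f"{history[-1][1]:.2e})",
            stacklevel=2,
        )
    if control.final_reml:
        # inference from a REML refit of the final working model
        work = pseudo_data(y, eta, theta)
        lmm = fit_lmm(
            work.z - offset,
            work.w,
            X,
            Z,
            groups,
            times,
            re_structure=spec.psi_structure,
            correlation=spec.correlation,
            beta_names=names,
            start=phi,
            reml=True,
        )
    return FittedNBMM(
        lmm=lmm,
        theta=theta,
        n_iter=it,
        converged=converged and lmm.converged,
        history=history,
        wald=wald_inference(lmm),
    )


def fit_lmm_arcsine(
    ds: LongitudinalDataset,
    taxon: str,
    spec: ModelSpec,
) -> FittedNBMM:
    """Comparator: linear mixed model on arcsine(sqrt(y/T)) proportions.

    The classical transformation approach — the response is
    arcsin(sqrt(y_ij / T_ij)) (0 at y=0, pi/2 at y=T), fitted with the
    same fixed/random/correlation structure, unit weights and no offset.
    """
    y = ds.taxon_counts(taxon).astype(float)
    T = ds.total_reads.astype(float)
    if np.any(y > T):
        raise ValueError("counts exceed total reads; cannot form proportions")
    resp = np.arcsin(np.sqrt(y / T))
    X, names, Z, groups, times, _ = build_design(ds, spec)
    lmm = fit_lmm(
        resp,
        np.ones_like(resp),
        X,
        Z,
        groups,
        times,
        re_structure=spec.psi_structure,
        correlation=spec.correlation,
        beta_names=names,
    )
    return FittedNBMM(
        lmm=lmm,
        theta=float("nan"),
        n_iter=1,
        converged=lmm.converged,
        history=[],
        wald=wald_inference(lmm),
        method="lmm_arcsine",
    )


def scan_taxa(
    ds: LongitudinalDataset,
    spec: ModelSpec,
    taxa: Sequence[str] | None = None,
    adjust: str = "none",
    control: FitControl | None = None,
    method: str = "nbmm",
) -> ScanResult:
    """Fit every taxon independently and collect the tested coefficients.

    Records the group main effect and (when present) the group-by-time
    interaction for each taxon.  Per-taxon failures are captured as rows
    with NA statistics, never raised; non-converged fits keep their
    estimates but report NA p-values.  ``adjust="BH"`` appends
    Benjamini-Hochberg adjusted p-values across taxa, separately per term.
    """
    if taxa is None:
        taxa = ds.taxa
    if len(taxa) == 0:
        raise ValueError("no taxa to scan")
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    fitter = {"nbmm": fit_nbmm, "lmm_arcsine": fit_lmm_arcsine}[method]

    rows = []
    for taxon in taxa:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if method == "nbmm":
                    fit = fitter(ds, taxon, spec, control)
                else:
                    fit = fitter(ds, taxon, spec)
        except Exception as err:  # per-taxon failures are data, not bugs
            logger.warning("taxon %s failed: %s", taxon, err)
            for term in spec.tested_terms:
                rows.append(
                    dict(
                        taxon=taxon,
                        term=term,
                        estimate=np.nan,
                        se=np.nan,
                        t=np.nan,
                        df=np.nan,
                        p=np.nan,
                        theta=np.nan,
                        converged=False,
                    )
                )
            continue
        for term in spec.tested_terms:
            w = fit.wald.loc[term]
            rows.append(
                dict(
                    taxon=taxon,
                    term=term,
                    estimate=w["estimate"],
                    se=w["se"],
                    t=w["t"],
                    df=w["df"],
                    p=w["p"] if fit.converged else np.nan,
                    theta=fit.theta,
                    converged=fit.converged,
                )
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    if adjust == "BH":
        for term in table["term"].unique():
            mask = (table["term"] == term) & table["p"].notna()
            if mask.any():
                table.loc[mask, "p_adj"] = multipletests(
                    table.loc[mask, "p"].to_numpy(), method="fdr_bh"
                )[1]
    table = table[list(ScanResult.COLUMNS)]
    return ScanResult(table)
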