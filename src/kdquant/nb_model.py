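"""Negative-binomial offset model for pseudobulk knockdown quantification.

The model: for pseudobulk row *i* (one animal x cell type), target UMI
counts are NB2-distributed,

    y_i ~ NB(mu_i, theta),   Var(y_i) = mu_i + mu_i^2 / theta,
    log mu_i = beta_ct(i) + beta_ct(i):trt(i) * [trt(i) != reference]
               + log(total_umi_i),

i.e. one free baseline log-rate per cell type, one interaction coefficient
per cell type x non-reference treatment, and the log of total UMIs as an
exposure offset with coefficient fixed at 1. The exponentiated interaction
coefficient is the mean residual-target fraction in that cell type —
exp(beta_int) = 0.5 means 50% of control expression remains — with a 95% CI
obtained as exp(beta_int ± 1.96 SE).

Estimation alternates IRLS for beta given theta with a 1-D profile-
likelihood search (Brent, on log theta) for theta given beta, to joint
convergence. Standard errors come from the observed information matrix at
the optimum, conditional on the fitted theta (a single dispersion shared
across cell types).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln, polygamma

LOG_THETA_BOUNDS = (-10.0, 15.0)
CONV_TOL = 1e-8
MAX_OUTER = 200


@dataclass
class DesignSpec:
    """Model structure: ordered cell types and treatments, with a declared
    reference (control) treatment."""

    reference_treatment: str
    cell_types: list[str]
    treatments: list[str]

    def __post_init__(self) -> None:
        if self.reference_treatment not in self.treatments:
            raise ValueError(
                f"reference {self.reference_treatment!r} not among treatments "
                f"{self.treatments}"
            )

    @classmethod
    def from_table(cls, table: pd.DataFrame, reference_treatment: str) -> "DesignSpec":
        return cls(
            reference_treatment=reference_treatment,
            cell_types=sorted(table["cell_type"].unique().tolist()),
            treatments=sorted(table["treatment"].unique().tolist()),
        )

    @property
    def non_reference(self) -> list[str]:
        return [t for t in self.treatments if t != self.reference_treatment]

    def coef_names(self) -> list[str]:
        names = [f"ct[{c}]" for c in self.cell_types]
        names += [
            f"ct[{c}]:trt[{t}]" for c in self.cell_types for t in self.non_reference
        ]
        return names


@dataclass
class NBFit:
    """Fitted coefficients (natural-log scale), their SEs, the shared NB
    dispersion and bookkeeping."""

    beta: np.ndarray
    se: np.ndarray
    coef_names: list[str]
    theta: float
    loglik: float
    converged: bool
    n_iter: int
    flags: dict[str, list[str]] = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.beta[self.coef_names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.coef_names.index(name)])


@dataclass
class ResidualEstimate:
    """Residual-target fraction for one cell type under one treatment."""

    cell_type: str
    treatment: str
    residual: float
    ci_low: float
    ci_high: float
    n_cells: int = 0
    per_animal: list[tuple[str, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def build_design(
    table: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Return (X, y, offset, coefficient names) for the pseudobulk table."""
    missing_ct = set(table["cell_type"]) - set(design.cell_types)
    if missing_ct:
        raise ValueError(f"cell types not in design: {sorted(missing_ct)}")
    missing_trt = set(table["treatment"]) - set(design.treatments)
    if missing_trt:
        raise ValueError(f"treatments not in design: {sorted(missing_trt)}")
    if (table["total_umi"] <= 0).any():
        raise ValueError("total_umi must be positive (offset is log total)")

    names = design.coef_names()
    col = {n: j for j, n in enumerate(names)}
    n, p = len(table), len(names)
    X = np.zeros((n, p))
    ct = table["cell_type"].to_numpy()
    trt = table["treatment"].to_numpy()
    for i in range(n):
        X[i, col[f"ct[{ct[i]}]"]] = 1.0
        if trt[i] != design.reference_treatment:
            X[i, col[f"ct[{ct[i]}]:trt[{trt[i]}]"]] = 1.0
    y = table["target_umi"].to_numpy(dtype=float)
    offset = np.log(table["total_umi"].to_numpy(dtype=float))
    return X, y, offset, names


def _nb2_logpmf(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 log-PMF via gamma functions; tolerates non-integer y (used for
    continuity-corrected counts) and mu = 0 (point mass at zero)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.full(y.shape, -np.inf)
    pos = mu > 0
    if pos.any():
        m, yy = mu[pos], y[pos]
        out[pos] = (
            gammaln(yy + theta)
            - gammaln(theta)
            - gammaln(yy + 1.0)
            + theta * np.log(theta / (theta + m))
            + yy * np.log(m / (theta + m))
        )
    zero_mu = ~pos
    out[zero_mu & (y == 0)] = 0.0
    return out


def nb_loglik(
    table: pd.DataFrame, beta: np.ndarray, theta: float, design: DesignSpec
) -> float:
    """Exact NB2 log-likelihood of the pseudobulk table at (beta, theta)."""
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("nonfinite beta")
    if theta <= 0:
        raise ValueError("theta must be positive")
    X, y, offset, _ = build_design(table, design)
    mu = np.exp(X @ beta + offset)
    return float(_nb2_logpmf(y, mu, theta).sum())


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    theta: float,
    beta0: np.ndarray,
    tol: float = CONV_TOL,
    max_iter: int = 100,
) -> np.ndarray:
    """IRLS for NB2 beta at fixed theta (log link, exposure offset)."""
    beta = beta0.copy()
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -700, 700))
        w = mu / (1.0 + mu / theta)  # expected-information weight
        z = (eta - offset) + (y - mu) / np.maximum(mu, 1e-300)
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX + 1e-12 * np.eye(X.shape[1]), WX.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            break
    return beta


def _theta_score_info(y: np.ndarray, mu: np.ndarray, theta: float) -> tuple[float, float]:
    """First and second derivatives of the NB2 log-likelihood w.r.t. theta."""
    g = float(
        np.sum(
            digamma(y + theta)
            - digamma(theta)
            + np.log(theta / (theta + mu))
            + (mu - y) / (theta + mu)
        )
    )
    h = float(
        np.sum(
            polygamma(1, y + theta)
            - polygamma(1, theta)
            + 1.0 / theta
            - 1.0 / (theta + mu)
            - (mu - y) / (theta + mu) ** 2
        )
    )
    return g, h


def _profile_log_theta(
    y: np.ndarray,
    mu: np.ndarray,
    lt0: float | None = None,
    bounds: tuple[float, float] = LOG_THETA_BOUNDS,
) -> float:
    """Profile-likelihood maximizer of log theta at fixed mu.

    A bounded Brent search locates the optimum; analytic Newton steps (in
    log theta, via digamma/trigamma) then polish it, which keeps the value
    deterministic where the profile is numerically flat.
    """
    def neg(lt: float) -> float:
        return -float(_nb2_logpmf(y, mu, np.exp(lt)).sum())

    if lt0 is None:
        res = minimize_scalar(neg, bounds=bounds, method="bounded",
                              options={"xatol": 1e-6})
        lt = float(res.x)
    else:
        lt = float(np.clip(lt0, *bounds))
    for _ in range(100):
        theta = np.exp(lt)
        g, h = _theta_score_info(y, mu, theta)
        # d/dlt = theta*g ; d2/dlt2 = theta*g + theta^2*h
        f, fp = theta * g, theta * g + theta**2 * h
        if fp >= 0 or not np.isfinite(fp):
            break  # not locally concave; keep the Brent answer
        step = f / fp
        lt_new = float(np.clip(lt - step, *bounds))
        if abs(lt_new - lt) < 1e-12:
            lt = lt_new
            break
        lt = lt_new
    return lt


def _moment_init(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments starting value for log theta."""
    excess = np.mean(((y - mu) ** 2 - mu) / np.maximum(mu, 1e-300) ** 2)
    if excess <= 0:
        return LOG_THETA_BOUNDS[1]
    return float(np.clip(np.log(1.0 / excess), *LOG_THETA_BOUNDS))


def fit_nb_offset_model(
    table: pd.DataFrame, design: DesignSpec | None = None,
    reference_treatment: str | None = None,
) -> NBFit:
    """Fit the NB offset model by alternating IRLS (beta) and Brent profile
    likelihood on log theta, to joint convergence.

    A cell type x arm whose target counts are all zero makes the
    corresponding coefficient unbounded below (separation); those groups
    get a 0.5 continuity correction, the coefficient is flagged
    ``separation`` and its SE reported infinite.
    """
    if design is None:
        if reference_treatment is None:
            raise ValueError("provide a DesignSpec or a reference_treatment")
        design = DesignSpec.from_table(table, reference_treatment)
    X, y, offset, names = build_design(table, design)

    # pre: at least one control row per cell type
    ctrl = table[table["treatment"] == design.reference_treatment]
    missing = set(design.cell_types) & set(table["cell_type"]) - set(ctrl["cell_type"])
    if missing:
        raise ValueError(f"no control rows for cell types: {sorted(missing)}")

    flags: dict[str, list[str]] = {}
    # separation: any coefficient whose supporting rows have all-zero counts
    y_work = y.copy()
    separated: list[int] = []
    for j, name in enumerate(names):
        rows = X[:, j] > 0
        if rows.any() and y[rows].sum() == 0:
            separated.append(j)
            flags.setdefault(name, []).append("separation")
    if separated:
        corrected = np.zeros(len(y), dtype=bool)
        for j in separated:
            corrected |= X[:, j] > 0
        y_work[corrected] += 0.5
        for j in separated:
            flags.setdefault(names[j], []).append("continuity_corrected")

    # init: log-linear regression of log((y + 0.5)/exposure)
    z0 = np.log((y_work + 0.5)) - offset
    beta = np.linalg.lstsq(X, z0, rcond=None)[0]
    mu = np.exp(X @ beta + offset)
    log_theta = _moment_init(y_work, mu)

    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_OUTER + 1):
        theta = np.exp(log_theta)
        beta_new = _irls(X, y_work, offset, theta, beta)
        mu = np.exp(X @ beta_new + offset)
        log_theta_new = _profile_log_theta(
            y_work, mu, lt0=None if n_iter == 1 else log_theta
        )
        d_beta = np.max(np.abs(beta_new - beta))
        d_lt = abs(log_theta_new - log_theta)
        beta, log_theta = beta_new, log_theta_new
        if d_beta < CONV_TOL and d_lt < CONV_TOL:
            converged = True
            break
    theta = float(np.exp(log_theta))
    if log_theta >= LOG_THETA_BOUNDS[1] - 1e-6:
        flags.setdefault("theta", []).append("at_upper_bound")

    mu = np.exp(X @ beta + offset)
    # observed information for beta given theta:
    # -d2l/deta2 = theta * mu * (theta + y) / (theta + mu)^2
    w_obs = theta * mu * (y_work + theta) / (theta + mu) ** 2
    info = X.T @ (X * w_obs[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.inf)
    for j in separated:
        se[j] = np.inf

    ll = float(_nb2_logpmf(y_work, mu, theta).sum())
    return NBFit(
        beta=beta,
        se=se,
        coef_names=names,
        theta=theta,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        flags=flags,
    )


def residual_fractions(
    fit: NBFit, design: DesignSpec, table: pd.DataFrame | None = None
) -> list[ResidualEstimate]:
    """Exponentiate interaction coefficients into residual-target fractions.

    The 95% CI is exp(beta_int ± 1.96 SE): computed on the log scale and
    exponentiated, so ci_low <= residual <= ci_high always holds. n_cells
    is filled from *table* when provided.
    """
    out: list[ResidualEstimate] = []
    for ct in design.cell_types:
        for trt in design.non_reference:
            name = f"ct[{ct}]:trt[{trt}]"
            if name not in fit.coef_names:
                raise KeyError(f"missing interaction term {name}")
            b = fit.coef(name)
            s = fit.coef_se(name)
            n_cells = 0
            if table is not None:
                sel = (table["cell_type"] == ct) & (table["treatment"] == trt)
                n_cells = int(table.loc[sel, "n_cells"].sum())
            out.append(
                ResidualEstimate(
                    cell_type=ct,
                    treatment=trt,
                    residual=float(np.exp(b)),
                    ci_low=float(np.exp(b - 1.96 * s)),
                    ci_high=float(np.exp(b + 1.96 * s)),
                    n_cells=n_cells,
                    flags=list(fit.flags.get(name, [])),
                )
            )
    return out


def per_animal_estimates(
    fit: NBFit, table: pd.DataFrame, design: DesignSpec
) -> pd.DataFrame:
    """Per-animal residual fractions: exp(beta_int + rho_i) with rho_i the
    log-ratio residual log(y_i / mu_hat_i) of that animal's treated row.

    Rows with y_i = 0 use y_i + 0.5 and are flagged. Returns a DataFrame
    with columns animal, cell_type, treatment, residual, flag.
    """
    X, y, offset, names = build_design(table, design)
    mu = np.exp(X @ fit.beta + offset)
    recs = []
    trt_arr = table["treatment"].to_numpy()
    ct_arr = table["cell_type"].to_numpy()
    an_arr = table["animal"].to_numpy()
    for i in range(len(table)):
        if trt_arr[i] == design.reference_treatment:
            continue
        b_int = fit.coef(f"ct[{ct_arr[i]}]:trt[{trt_arr[i]}]")
        yi, flag = y[i], ""
        if yi == 0:
            yi, flag = 0.5, "zero_count_corrected"
        rho = np.log(yi / mu[i])
        recs.append(
            {
                "animal": an_arr[i],
                "cell_type": ct_arr[i],
                "treatment": trt_arr[i],
                "residual": float(np.exp(b_int + rho)),
                "flag": flag,
            }
        )
    return pd.DataFrame.from_records(
        recs, columns=["animal", "cell_type", "treatment", "residual", "flag"]
    )


def pool_cell_types(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a pseudobulk table across cell types: one all-cells row per
    animal (cell_type label 'all')."""
    pooled = (
        table.groupby(["animal", "treatment"], sort=True, observed=True)
        .agg(
            target_umi=("target_umi", "sum"),
            total_umi=("total_umi", "sum"),
            n_cells=("n_cells", "sum"),
        )
        .reset_index()
    )
    pooled["cell_type"] = "all"
    return pooled[["animal", "cell_type", "treatment", "target_umi", "total_umi", "n_cells"]]


def overall_residual(table: pd.DataFrame, reference_treatment: str) -> ResidualEstimate:
    """Overall (all-cells) residual-target fraction: the same NB offset
    model fit to the single pooled pseudobulk across cell types."""
    pooled = pool_cell_types(table)
    design = DesignSpec.from_table(pooled, reference_treatment)
    if not design.non_reference:
        raise ValueError("control-only table has no residual to estimate")
    fit = fit_nb_offset_model(pooled, design)
    return residual_fractions(fit, design, pooled)[0]


def estimates_to_frame(estimates: list[ResidualEstimate]) -> pd.DataFrame:
    """Tabulate ResidualEstimates (percent scale columns are the caller's
    job; this keeps fractions)."""
    return pd.DataFrame(
        [
            {
                "cell_type": e.cell_type,
                "treatment": e.treatment,
                "residual": e.residual,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_cells": e.n_cells,
                "flags": ";".join(e.flags),
            }
            for e in estimates
        ]
    )
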