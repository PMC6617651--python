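"""Covariate-adjusted differential methylation with empirical-Bayes
variance moderation.

Per probe g, beta values are regressed on a design matrix X (intercept,
case/control indicator, age, sex, estimated monocyte proportion) by ordinary
least squares, giving the group coefficient b_g, residual variance s2_g and
residual degrees of freedom d = n - rank(X). The per-probe variances are then
shrunk toward a common prior by the scaled-F empirical-Bayes model

    s2_g | sigma2_g ~ sigma2_g * chi2_d / d,     1/sigma2_g ~ chi2_d0 / (d0 * s0^2),

whose hyperparameters (d0, s0^2) are estimated by matching the first two
moments of log s2 (numeric inversion of the trigamma function). The
moderated variance is the weighted average

    s2_tilde_g = (d0 * s0^2 + d * s2_g) / (d0 + d)

and the moderated t statistic b_g / (se_g * sqrt(s2_tilde_g / s2_g)) is
referred to a t distribution with d0 + d degrees of freedom. Two-sided
p-values are Benjamini-Hochberg adjusted across probes, and the signature is
the set of probes with adjusted p < alpha and raw-scale |delta beta| >
min_abs_delta (both strict), where delta beta is the unadjusted difference
of case and control group means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import BetaMatrix, SampleSheet


class DesignError(ValueError):
    """The design matrix is rank deficient or misaligned."""


class ModerationError(ValueError):
    """Variance moderation cannot proceed (degenerate variances)."""


def build_design(
    sheet: SampleSheet,
    sample_ids: list[str] | pd.Index,
    monocyte: pd.Series | None = None,
) -> pd.DataFrame:
    """Design matrix with intercept, group indicator (case=1), age, sex and,
    when supplied, estimated monocyte proportion."""
    t = sheet.table.loc[sample_ids]
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "group": (t["group"] == "case").astype(float),
            "age": t["age"].astype(float),
            "sex": t["sex"].astype(float),
        },
        index=pd.Index(sample_ids),
    )
    if monocyte is not None:
        design["monocyte"] = monocyte.loc[design.index].astype(float)
    return design


def _check_full_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a culprit: a column whose removal restores rank
        for j, name in enumerate(columns):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise DesignError(f"design matrix is rank deficient; column '{name}' is collinear")
        raise DesignError("design matrix is rank deficient")


def fit_probe_models(beta: BetaMatrix | pd.DataFrame, design: pd.DataFrame, coef: str = "group") -> pd.DataFrame:
    """Per-probe OLS of beta on the design; vectorized across probes.

    Returns a DataFrame indexed by probe with columns ``b`` (the ``coef``
    coefficient), ``s2`` (residual mean square), ``d`` (residual df) and
    ``se_unscaled`` (standard error per unit residual sd).
    """
    Y = beta.beta if isinstance(beta, BetaMatrix) else beta
    if list(design.index) != list(Y.columns):
        design = design.loc[Y.columns]
    X = design.to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise DesignError(f"need more samples ({n}) than design columns ({p})")
    _check_full_rank(X, design.columns)
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y.to_numpy() @ X @ xtx_inv          # probes x p
    fitted = B @ X.T
    resid = Y.to_numpy() - fitted
    d = n - p
    s2 = (resid**2).sum(axis=1) / d
    j = design.columns.get_loc(coef)
    return pd.DataFrame(
        {
            "b": B[:, j],
            "s2": s2,
            "d": float(d),
            "se_unscaled": np.sqrt(xtx_inv[j, j]),
        },
        index=Y.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(
    s2: np.ndarray | pd.Series,
    d: float,
    b: np.ndarray | pd.Series | None = None,
    se_unscaled: np.ndarray | float | None = None,
    d0_override: float | None = None,
) -> dict:
    """Estimate the scaled-F prior (d0, s0^2) and moderate the variances.

    Returns a dict with ``d0``, ``s0_2``, ``s2_tilde`` and, when ``b`` and
    ``se_unscaled`` are given, ``t_mod`` and two-sided ``p`` on d0 + d
    degrees of freedom. ``d0_override`` injects a prior df (0, finite, or
    ``inf``) instead of estimating it.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10 and d0_override is None:
        raise ModerationError("need >= 10 probes to estimate the variance prior")
    if np.all(s2 <= 0):
        raise ModerationError("all residual variances are zero: moderation is degenerate")
    pos = s2 > 0
    e = np.log(s2[pos])
    ebar = e.mean()

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0:
            s0_2 = float(np.exp(ebar))
            s2_tilde = s2.copy()
        elif np.isinf(d0):
            s0_2 = float(np.exp(ebar))
            s2_tilde = np.full_like(s2, s0_2)
        else:
            s0_2 = float(np.exp(ebar + special.digamma(d0 / 2) - np.log(d0 / 2)
                                 - special.digamma(d / 2) + np.log(d / 2)))
            s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
    else:
        evar = e.var(ddof=1) if e.size > 1 else 0.0
        evar_resid = evar - special.polygamma(1, d / 2)
        if np.isfinite(evar_resid) and evar_resid > 0:
            x = _trigamma_inverse(evar_resid)
            d0 = 2.0 * x
            s0_2 = float(np.exp(ebar + special.digamma(x) - np.log(x)
                                 - special.digamma(d / 2) + np.log(d / 2)))
            s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
        else:
            # homogeneous limit: infinite prior df, prior variance at the
            # geometric mean so identical s2 are returned unchanged
            d0 = np.inf
            uniq = np.unique(s2[pos])
            s0_2 = float(uniq[0]) if uniq.size == 1 else float(np.exp(ebar))
            s2_tilde = np.full_like(s2, s0_2)

    out = {"d0": d0, "s0_2": s0_2, "s2_tilde": s2_tilde, "df_total": d0 + d}
    if b is not None and se_unscaled is not None:
        b = np.asarray(b, dtype=float)
        se = np.asarray(se_unscaled, dtype=float) * np.sqrt(s2_tilde)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = b / se
        df = d if (d0_override is not None and d0_override == 0) else d0 + d
        p = 2.0 * stats.t.sf(np.abs(t_mod), df)
        out["t_mod"] = t_mod
        out["p"] = np.clip(p, 0.0, 1.0)
    return out


def adjust_bh(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def delta_beta(beta: BetaMatrix | pd.DataFrame, case_ids, control_ids) -> pd.Series:
    """Raw-scale mean(case beta) - mean(control beta) per probe."""
    Y = beta.beta if isinstance(beta, BetaMatrix) else beta
    return (Y[list(case_ids)].mean(axis=1) - Y[list(control_ids)].mean(axis=1)).rename("delta_beta")


def select_signature(stats_table: pd.DataFrame, alpha: float = 0.05, min_abs_delta: float = 0.10) -> list[str]:
    """Signature probes: p_adj < alpha AND |delta beta| > min_abs_delta
    (strict), ordered by p_adj, then |delta beta| descending, then probe id."""
    keep = (stats_table["p_adj"] < alpha) & (stats_table["delta_beta"].abs() > min_abs_delta)
    sel = stats_table.loc[keep].copy()
    sel["_absd"] = -sel["delta_beta"].abs()
    sel = sel.sort_values(["p_adj", "_absd"], kind="mergesort")
    # stable final tie-break on probe id
    sel["_pid"] = sel.index
    sel = sel.sort_values(["p_adj", "_absd", "_pid"], kind="mergesort")
    return sel.index.tolist()


# ---------------------------------------------------------------------------
# Model / Results presentation


class DifferentialMethylation:
    """Moderated differential-methylation model for a case/control study.

    Parameters
    ----------
    beta : BetaMatrix or DataFrame
        Probes x samples methylation fractions.
    design : DataFrame
        Samples x covariates design (see :func:`build_design`); must contain
        a ``group`` column coding cases as 1.
    case_ids, control_ids : sequences of sample ids used for delta beta.
    """

    def __init__(self, beta, design: pd.DataFrame, case_ids, control_ids):
        Y = beta.beta if isinstance(beta, BetaMatrix) else beta
        Y = Y[design.index.tolist()]
        # probes with missing values cannot share the common residual df
        complete = Y.notna().all(axis=1)
        self.n_dropped_incomplete = int((~complete).sum())
        self.beta = Y.loc[complete]
        self.design = design
        self.case_ids = list(case_ids)
        self.control_ids = list(control_ids)

    @classmethod
    def from_sample_sheet(
        cls, beta, sheet: SampleSheet, monocyte: pd.Series | None = None, min_age: float = 2.0
    ) -> "DifferentialMethylation":
        """Build the derivation model: cases vs controls older than
        ``min_age`` years, with age, sex and monocyte covariates."""
        t = sheet.table
        keep = t["group"].isin(["case", "control"]) & (t["age"].astype(float) > min_age)
        ids = t.index[keep]
        design = build_design(sheet, ids, monocyte)
        case_ids = ids[t.loc[ids, "group"] == "case"]
        control_ids = ids[t.loc[ids, "group"] == "control"]
        return cls(beta, design, case_ids, control_ids)

    def fit(self, d0_override: float | None = None) -> "DiffMethResults":
        ols = fit_probe_models(self.beta, self.design)
        mod = moderate_variances(
            ols["s2"].to_numpy(),
            float(ols["d"].iloc[0]),
            b=ols["b"].to_numpy(),
            se_unscaled=ols["se_unscaled"].to_numpy(),
            d0_override=d0_override,
        )
        table = ols.copy()
        table["s2_tilde"] = mod["s2_tilde"]
        table["t_mod"] = mod["t_mod"]
        table["p"] = mod["p"]
        table["p_adj"] = adjust_bh(mod["p"])
        table["delta_beta"] = delta_beta(self.beta, self.case_ids, self.control_ids)
        return DiffMethResults(self, table, d0=mod["d0"], s0_2=mod["s0_2"])


class DiffMethResults:
    """Fitted per-probe statistics plus the moderation hyperparameters."""

    def __init__(self, model: DifferentialMethylation, table: pd.DataFrame, d0: float, s0_2: float):
        self.model = model
        self.table = table
        self.d0 = d0
        self.s0_2 = s0_2

    def select_signature(self, alpha: float = 0.05, min_abs_delta: float = 0.10) -> list[str]:
        return select_signature(self.table, alpha, min_abs_delta)

    def summary(self, alpha: float = 0.05, min_abs_delta: float = 0.10) -> str:
        n_sig = len(self.select_signature(alpha, min_abs_delta))
        d = self.table["d"].iloc[0]
        lines = [
            "Moderated differential methylation",
            "==================================",
            f"probes:                {len(self.table)}",
            f"samples (case/ctrl):   {len(self.model.case_ids)}/{len(self.model.control_ids)}",
            f"residual df per probe: {d:g}",
            f"prior df (d0):         {self.d0:.4g}",
            f"prior variance (s0^2): {self.s0_2:.4g}",
            f"signature probes (p_adj < {alpha:g}, |delta beta| > {min_abs_delta:g}): {n_sig}",
        ]
        if self.model.n_dropped_incomplete:
            lines.append(f"probes dropped (missing values): {self.model.n_dropped_incomplete}")
        return "\n".join(lines)
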