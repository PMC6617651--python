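"""Reference-based blood cell-type deconvolution.

Bulk whole-blood methylation is modelled as a nonnegative mixture of
sorted-cell reference profiles (the Houseman approach): for a sample's beta
vector ``y`` over marker probes and a reference matrix ``R`` (cell types x
markers), the proportion estimate is

    c_hat = argmin ||y - R' c||^2   subject to  c >= 0,  sum(c) <= 1.

The inequality on the sum leaves room for unmodelled cell types; the
unexplained mass ``1 - sum(c)`` and the fit residual norm are reported.
The constrained problem is solved exactly by nonnegative least squares on a
design augmented with a slack component and a heavily weighted sum-to-one
row, which is equivalent to the usual quadratic program and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .containers import ValidationError

_SUM_WEIGHT = 1e6


class EstimationError(ValueError):
    """Deconvolution could not be performed on the given input."""


@dataclass
class CellTypePanel:
    """Sorted-cell mean beta profiles over marker probes (types x markers)."""

    reference: pd.DataFrame

    def __post_init__(self) -> None:
        if self.reference.shape[0] < 2:
            raise ValidationError("panel needs >= 2 cell types")
        if self.reference.columns.has_duplicates:
            raise ValidationError("duplicate marker probes in panel")
        vals = self.reference.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("panel reference values outside [0, 1]")

    @property
    def cell_type_names(self) -> list[str]:
        return self.reference.index.tolist()

    @property
    def marker_probe_ids(self) -> pd.Index:
        return self.reference.columns

    def to_json(self) -> dict:
        return {
            "cell_types": self.cell_type_names,
            "marker_probes": self.marker_probe_ids.tolist(),
            "reference": self.reference.to_numpy().tolist(),
        }

    @classmethod
    def from_json(cls, doc: dict) -> "CellTypePanel":
        ref = pd.DataFrame(doc["reference"], index=doc["cell_types"], columns=doc["marker_probes"])
        return cls(ref)


@dataclass
class CellProportions:
    """Estimated proportions per sample plus fit residual norms."""

    proportions: pd.DataFrame   # samples x cell types
    residual_norm: pd.Series

    def __post_init__(self) -> None:
        vals = self.proportions.to_numpy()
        if (vals < -1e-9).any():
            raise ValidationError("negative estimated proportions")
        if (vals.sum(axis=1) > 1 + 1e-8).any():
            raise ValidationError("estimated proportions sum above 1")


def select_discriminating_probes(
    panel_source: pd.DataFrame, cell_labels: pd.Series, n_per_type: int
) -> list[str]:
    """Pick marker probes per cell type by one-vs-rest t statistic.

    For each type, the ``n_per_type/2`` most hypermethylated and most
    hypomethylated probes (largest positive / negative t) are taken; the
    union over types is returned. ``panel_source`` is probes x sorted cells.
    """
    if n_per_type % 2:
        raise ValueError("n_per_type must be even (half hyper-, half hypomethylated)")
    labels = cell_labels.loc[panel_source.columns]
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("need >= 2 sorted cells per type for one-vs-rest t statistics")
    selected: list[str] = []
    max_abs_t = 0.0
    vals = panel_source.to_numpy()
    for ct in counts.index:
        in_type = (labels == ct).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            t, _ = stats.ttest_ind(vals[:, in_type], vals[:, ~in_type], axis=1, equal_var=True)
        t = np.nan_to_num(t)
        max_abs_t = max(max_abs_t, float(np.max(np.abs(t))) if t.size else 0.0)
        order = np.argsort(t)
        half = n_per_type // 2
        for idx in np.concatenate([order[:half], order[-half:]]):
            pid = panel_source.index[idx]
            if pid not in selected:
                selected.append(pid)
    if max_abs_t < 1e-8:
        warnings.warn("cell types are indistinguishable: all one-vs-rest |t| ~ 0", stacklevel=2)
    return selected


def _estimate_one(y: np.ndarray, R: np.ndarray) -> tuple[np.ndarray, float]:
    k, m = R.shape
    # columns: k proportions + 1 slack; heavy last row enforces sum + slack = 1
    A = np.zeros((m + 1, k + 1))
    A[:m, :k] = R.T
    A[m, :] = _SUM_WEIGHT
    b = np.concatenate([y, [_SUM_WEIGHT]])
    x, _ = nnls(A, b)
    c = x[:k]
    resid = float(np.linalg.norm(y - R.T @ c))
    return np.clip(c, 0.0, None), resid


def estimate_proportions(sample_beta: pd.DataFrame | pd.Series, panel: CellTypePanel) -> CellProportions:
    """Estimate cell-type proportions for one or more samples.

    ``sample_beta`` is a Series (one sample) or probes x samples DataFrame
    covering the panel's marker probes; up to 20% of marker values may be
    missing per sample.
    """
    if isinstance(sample_beta, pd.Series):
        sample_beta = sample_beta.to_frame()
    markers = panel.marker_probe_ids
    present = markers.intersection(sample_beta.index)
    if len(present) < 0.8 * len(markers):
        raise EstimationError(
            f"only {len(present)}/{len(markers)} marker probes present (>20% missing)"
        )
    Y = sample_beta.reindex(markers)
    R_full = panel.reference.to_numpy()
    rows, resids = [], []
    for col in Y.columns:
        y = Y[col].to_numpy(float)
        ok = np.isfinite(y)
        if ok.sum() < 0.8 * len(markers):
            raise EstimationError(f"sample {col}: >20% marker values missing")
        c, r = _estimate_one(y[ok], R_full[:, ok])
        rows.append(c)
        resids.append(r)
    props = pd.DataFrame(rows, index=Y.columns, columns=panel.cell_type_names)
    return CellProportions(props, pd.Series(resids, index=Y.columns, name="residual_norm"))


def compare_cell_proportions(props: CellProportions, groups: pd.Series) -> pd.DataFrame:
    """Equal-variance two-sample t-test of case vs control per cell type."""
    groups = groups.loc[props.proportions.index]
    case = props.proportions.loc[groups == "case"]
    ctrl = props.proportions.loc[groups == "control"]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need >= 2 samples per group to compare proportions")
    rows = []
    for ct in props.proportions.columns:
        t, p = stats.ttest_ind(case[ct], ctrl[ct], equal_var=True)
        if not np.isfinite(t):  # zero variance in both groups, identical means
            t, p = 0.0, 1.0
        rows.append({
            "cell_type": ct,
            "mean_case": case[ct].mean(),
            "mean_control": ctrl[ct].mean(),
            "t": float(t),
            "p": float(p),
        })
    return pd.DataFrame(rows).set_index("cell_type")
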