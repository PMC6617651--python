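"""Signature reference profiles, correlation-difference scoring, evaluation
and clustering.

A fitted :class:`SignatureModel` stores, for each signature CpG, the median
beta over derivation cases and over derivation controls (the two reference
profiles) together with the per-group observed [min, max] beta ranges. A
query sample's beta vector ``B_sig`` over the signature CpGs is scored as

    score = r(B_sig, case profile) - r(B_sig, control profile)

with r the Pearson correlation; a positive score classifies the sample as
"pathogenic" (more similar to the case profile), a negative score as
"benign". Scores lie in [-2, 2] by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import BetaMatrix, ValidationError


class ScoringError(ValueError):
    """Scoring is undefined (too few probes, zero variance, missing data)."""


@dataclass
class SignatureModel:
    """Median reference profiles and per-group beta ranges at signature CpGs."""

    probe_ids: pd.Index
    case_profile: pd.Series
    control_profile: pd.Series
    case_range: pd.DataFrame      # columns: min, max
    control_range: pd.DataFrame
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.probe_ids = pd.Index(self.probe_ids)
        for name, prof, rng in [
            ("case", self.case_profile, self.case_range),
            ("control", self.control_profile, self.control_range),
        ]:
            if len(prof) != len(self.probe_ids):
                raise ValidationError(f"{name} profile length != signature size")
            if ((rng["min"] > prof + 1e-12) | (rng["max"] < prof - 1e-12)).any():
                raise ValidationError(f"{name} profile falls outside its own range")
            if ((rng["min"] < 0) | (rng["max"] > 1)).any():
                raise ValidationError(f"{name} range outside [0, 1]")

    def __len__(self) -> int:
        return len(self.probe_ids)

    # -- scoring -----------------------------------------------------------

    def score(self, sample_beta: pd.Series) -> "ScoreResult":
        return score_sample(sample_beta, self)

    def score_many(self, beta: BetaMatrix | pd.DataFrame) -> pd.DataFrame:
        Y = beta.beta if isinstance(beta, BetaMatrix) else beta
        rows = [score_sample(Y[c], self).as_dict() for c in Y.columns]
        return pd.DataFrame(rows).set_index("sample_id")

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "probe_ids": self.probe_ids.tolist(),
            "case_profile": self.case_profile.tolist(),
            "control_profile": self.control_profile.tolist(),
            "case_range": self.case_range[["min", "max"]].to_numpy().tolist(),
            "control_range": self.control_range[["min", "max"]].to_numpy().tolist(),
            "threshold": self.threshold,
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    @classmethod
    def from_json(cls, doc: dict | str | Path) -> "SignatureModel":
        if not isinstance(doc, dict):
            doc = json.loads(Path(doc).read_text())
        pid = pd.Index(doc["probe_ids"], name="probe_id")
        def _rng(key):
            arr = np.asarray(doc[key], dtype=float)
            return pd.DataFrame(arr, index=pid, columns=["min", "max"])
        return cls(
            probe_ids=pid,
            case_profile=pd.Series(doc["case_profile"], index=pid),
            control_profile=pd.Series(doc["control_profile"], index=pid),
            case_range=_rng("case_range"),
            control_range=_rng("control_range"),
            threshold=float(doc.get("threshold", 0.0)),
        )


@dataclass
class ScoreResult:
    sample_id: str
    r_case: float
    r_control: float
    score: float
    label: str
    boundary: bool = False

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "r_case": self.r_case,
            "r_control": self.r_control,
            "score": self.score,
            "label": self.label,
        }


def build_reference_profiles(
    beta: BetaMatrix | pd.DataFrame, signature_probes, case_ids, control_ids
) -> SignatureModel:
    """Per-probe group medians and observed [min, max] ranges at signature CpGs."""
    Y = beta.beta if isinstance(beta, BetaMatrix) else beta
    signature_probes = pd.Index(signature_probes)
    missing = signature_probes.difference(Y.index)
    if len(missing):
        raise ValidationError(f"signature probes absent from beta matrix: {missing[:3].tolist()}")
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValidationError("need >= 2 samples per group to build reference profiles")
    case = Y.loc[signature_probes, list(case_ids)]
    ctrl = Y.loc[signature_probes, list(control_ids)]
    return SignatureModel(
        probe_ids=signature_probes,
        case_profile=case.median(axis=1),
        control_profile=ctrl.median(axis=1),
        case_range=pd.DataFrame({"min": case.min(axis=1), "max": case.max(axis=1)}),
        control_range=pd.DataFrame({"min": ctrl.min(axis=1), "max": ctrl.max(axis=1)}),
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0:
        raise ScoringError("undefined correlation: zero-variance vector")
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


def score_sample(sample_beta: pd.Series, model: SignatureModel) -> ScoreResult:
    """Correlation-difference score of one query sample.

    Missing beta at signature probes is tolerated up to 10% (pairwise-complete
    correlation); below that coverage, scoring refuses.
    """
    if len(model) < 3:
        raise ScoringError(f"signature has {len(model)} probes; need >= 3 for a meaningful correlation")
    v = sample_beta.reindex(model.probe_ids)
    ok = v.notna().to_numpy()
    if ok.sum() < 0.9 * len(model):
        raise ScoringError(
            f"sample covers {int(ok.sum())}/{len(model)} signature probes (<90%)"
        )
    x = v.to_numpy(float)[ok]
    r_case = _pearson(x, model.case_profile.to_numpy()[ok])
    r_control = _pearson(x, model.control_profile.to_numpy()[ok])
    score = r_case - r_control
    label = "pathogenic" if score > model.threshold else "benign"
    boundary = score == model.threshold
    if boundary:
        import warnings

        warnings.warn(
            f"sample {sample_beta.name}: score exactly at the decision boundary; labelled benign",
            stacklevel=2,
        )
    return ScoreResult(
        sample_id=str(sample_beta.name), r_case=r_case, r_control=r_control,
        score=score, label=label, boundary=boundary,
    )


def evaluate(scores: pd.DataFrame, truth_labels: pd.Series) -> dict:
    """Sensitivity/specificity of predicted labels against truth.

    ``truth_labels`` uses the same vocabulary: pathogenic (positive class)
    and benign (negative class).
    """
    truth = truth_labels.loc[scores.index]
    bad = set(truth.unique()) - {"pathogenic", "benign"}
    if bad:
        raise ValueError(f"truth labels must be pathogenic/benign, got {sorted(bad)}")
    pred = scores["label"]
    tp = int(((pred == "pathogenic") & (truth == "pathogenic")).sum())
    fn = int(((pred == "benign") & (truth == "pathogenic")).sum())
    tn = int(((pred == "benign") & (truth == "benign")).sum())
    fp = int(((pred == "pathogenic") & (truth == "benign")).sum())
    out = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
    out["specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
    if (tp + fn) == 0 or (tn + fp) == 0:
        out["undefined_metric"] = True
    return out


def cluster_samples(
    beta: BetaMatrix | pd.DataFrame, signature_probes=None, linkage_method: str = "complete"
) -> tuple[np.ndarray, pd.Series]:
    """Agglomerative clustering of samples on signature-probe beta values.

    Euclidean distances; returns (scipy linkage matrix, 2-cluster cut labels
    per sample).
    """
    Y = beta.beta if isinstance(beta, BetaMatrix) else beta
    if signature_probes is not None:
        Y = Y.loc[pd.Index(signature_probes)]
    if Y.shape[1] < 2:
        raise ValidationError("need >= 2 samples to cluster")
    X = Y.to_numpy().T
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage_method)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return Z, pd.Series(labels, index=Y.columns, name="cluster")
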