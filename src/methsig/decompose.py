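"""Four-way range-overlap partition of a query sample at signature CpGs.

For an intermediate (mosaic / partial-signature) sample, each signature CpG
is categorized by where its beta value falls relative to the closed
[min, max] beta ranges observed in the derivation groups:

- ``case_typical``    — inside the case range and outside the control range
- ``control_typical`` — inside the control range and outside the case range
- ``both``            — inside both ranges (uninformative)
- ``neither``         — outside both ranges

Probes with missing beta are categorized ``missing`` and excluded from all
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signature import SignatureModel

CATEGORIES = ("case_typical", "control_typical", "neither", "both")


@dataclass
class PartitionResult:
    sample_id: str
    per_probe: pd.DataFrame   # category, beta, hyper (vs control profile)
    counts: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        cats = self.per_probe.loc[self.per_probe["category"] != "missing", "category"]
        self.counts = cats.value_counts().reindex(CATEGORIES, fill_value=0)

    @property
    def n_scored(self) -> int:
        return int(self.counts.sum())

    def fraction(self, category: str) -> float:
        return float(self.counts[category] / self.n_scored) if self.n_scored else float("nan")


def partition_sites(sample_beta: pd.Series, model: SignatureModel) -> PartitionResult:
    """Assign every signature probe of one sample to a range-overlap category.

    Ranges are closed intervals: a beta exactly at a group's observed min or
    max counts as inside that group's range.
    """
    v = sample_beta.reindex(model.probe_ids).to_numpy(float)
    ok = np.isfinite(v)
    in_case = ok & (v >= model.case_range["min"].to_numpy()) & (v <= model.case_range["max"].to_numpy())
    in_ctrl = ok & (v >= model.control_range["min"].to_numpy()) & (v <= model.control_range["max"].to_numpy())
    category = np.full(len(model), "missing", dtype=object)
    category[ok & in_case & ~in_ctrl] = "case_typical"
    category[ok & ~in_case & in_ctrl] = "control_typical"
    category[ok & in_case & in_ctrl] = "both"
    category[ok & ~in_case & ~in_ctrl] = "neither"
    per_probe = pd.DataFrame(
        {
            "category": category,
            "beta": v,
            "hyper": np.where(ok, v > model.control_profile.to_numpy(), False),
        },
        index=model.probe_ids,
    )
    return PartitionResult(sample_id=str(sample_beta.name), per_probe=per_probe)


def summarize_partition(
    partition: PartitionResult, probe_genes: dict[str, list[str]] | None = None
) -> dict[str, pd.DataFrame]:
    """Counts, percentages and hyper/hypo splits per category; optionally a
    gene-level majority category for probes sharing a gene.

    ``hyper`` means the sample's beta lies above the control median profile
    at that probe.
    """
    pp = partition.per_probe
    scored = pp[pp["category"] != "missing"]
    n = len(scored)
    rows = []
    for cat in CATEGORIES:
        sub = scored[scored["category"] == cat]
        rows.append({
            "category": cat,
            "n": len(sub),
            "percent": 100.0 * len(sub) / n if n else float("nan"),
            "n_hyper": int(sub["hyper"].sum()),
            "n_hypo": int((~sub["hyper"]).sum()),
        })
    summary = pd.DataFrame(rows).set_index("category")

    out = {"summary": summary}
    if probe_genes is not None:
        gene_cats: dict[str, list[str]] = {}
        for pid, row in scored.iterrows():
            for gene in probe_genes.get(pid, []):
                gene_cats.setdefault(gene, []).append(row["category"])
        grows = []
        for gene, cats in sorted(gene_cats.items()):
            vc = pd.Series(cats).value_counts()
            top = vc.index[0]
            grows.append({
                "gene": gene,
                "n_probes": len(cats),
                "majority_category": top,
                "majority_fraction": vc.iloc[0] / len(cats),
            })
        out["genes"] = pd.DataFrame(grows).set_index("gene") if grows else pd.DataFrame()
    return out
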