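"""Probe-level quality-control filters for methylation beta matrices.

Filters are applied in a fixed order, and each reported count is the number
of probes removed at that step among the survivors of earlier steps, so the
per-filter counts sum to the total removed:

1. detection flaws    — detection p > cutoff in at least one sample
2. SNP-adjacent       — interfering SNP with minor-allele frequency > 1%
3. cross-reactive     — probe flagged as mapping to multiple loci
4. extreme raw beta   — beta exactly 0 or 1 in more than ``raw_extreme_frac``
                        of samples (default 0.25%)
5. non-CpG            — probes not interrogating a CpG dinucleotide
6. sex chromosomes    — probes on chrX or chrY
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix, PipelineConfig, ProbeManifest, ValidationError

FILTER_ORDER = (
    "detection_flawed",
    "snp_adjacent",
    "cross_reactive",
    "extreme_raw_beta",
    "non_cpg",
    "sex_chromosome",
)


class AnnotationError(KeyError):
    """A probe in the beta matrix has no manifest annotation."""


@dataclass
class QCReport:
    """Per-filter removal counts, in application order."""

    filters: list[tuple[str, int]]
    n_input: int
    n_remaining: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(n for _, n in self.filters)
        assert self.n_input - total == self.n_remaining, "QC counts do not balance"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": name, "n_removed": n} for name, n in self.filters]
        rows.append({"filter": "remaining", "n_removed": self.n_remaining})
        return pd.DataFrame(rows)


def _filter_masks(beta: BetaMatrix, manifest: ProbeManifest, config: PipelineConfig) -> dict[str, np.ndarray]:
    """Boolean removal mask per filter, each over the full input probe set."""
    ann = manifest.table.loc[beta.probe_ids]
    vals = beta.beta.to_numpy()
    n_samples = vals.shape[1]

    if beta.detection_p is not None:
        det = (beta.detection_p.to_numpy() > config.detection_p_cutoff).any(axis=1)
    else:
        det = np.zeros(len(beta.probe_ids), dtype=bool)

    extreme_frac = ((vals == 0.0) | (vals == 1.0)).sum(axis=1) / n_samples
    return {
        "detection_flawed": det,
        "snp_adjacent": ann["snp_maf"].to_numpy(float) > 0.01,
        "cross_reactive": ann["cross_reactive"].to_numpy(int) != 0,
        "extreme_raw_beta": extreme_frac > config.raw_extreme_frac,
        "non_cpg": ann["probe_class"].to_numpy() != "CpG",
        "sex_chromosome": ann["chrom"].isin(["chrX", "chrY", "X", "Y"]).to_numpy(),
    }


def apply_probe_filters(
    beta: BetaMatrix, manifest: ProbeManifest, config: PipelineConfig | None = None
) -> tuple[BetaMatrix, QCReport]:
    """Apply the probe-removal rules and report sequential per-filter counts."""
    config = config or PipelineConfig()
    missing = beta.probe_ids.difference(manifest.probe_ids)
    if len(missing):
        raise AnnotationError(
            f"{len(missing)} probes in beta matrix absent from manifest, e.g. {missing[:3].tolist()}"
        )
    masks = _filter_masks(beta, manifest, config)

    alive = np.ones(len(beta.probe_ids), dtype=bool)
    counts: list[tuple[str, int]] = []
    for name in FILTER_ORDER:
        hit = masks[name] & alive
        counts.append((name, int(hit.sum())))
        alive &= ~hit

    kept = beta.probe_ids[alive]
    report = QCReport(
        filters=counts,
        n_input=len(beta.probe_ids),
        n_remaining=int(alive.sum()),
        metadata={
            "detection_rule": f"detection_p > {config.detection_p_cutoff} in any sample "
            "(operational choice; the removal rule is not fully specified upstream)",
            "raw_extreme_frac": config.raw_extreme_frac,
        },
    )
    return beta.subset_probes(kept), report
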