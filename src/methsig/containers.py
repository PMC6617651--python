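"""Core data containers and tabular I/O for methylation-array analysis.

All tables are tab-separated UTF-8 with a header row; ``NA`` encodes missing
values. Genomic coordinates are 1-based and fully closed, following the
Illumina manifest convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

NA_REP = "NA"

GROUP_VOCABULARY = frozenset({"case", "control", "test"})
PROBE_CLASSES = frozenset({"CpG", "non-CpG", "control"})


class ValidationError(ValueError):
    """Input data violates a container invariant."""


class SchemaError(ValueError):
    """A required column is missing or a header is malformed."""


def _check_unique(values: Iterable[str], what: str) -> None:
    values = pd.Index(values)
    if values.has_duplicates:
        dups = values[values.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions (beta values).

    beta values are fractions of methylated signal, in [0, 1]. An optional
    companion matrix of per-measurement detection p-values (same shape) marks
    measurements that could not be distinguished from background.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.beta = self.beta.astype(float)
        _check_unique(self.beta.index, "probe ids")
        _check_unique(self.beta.columns, "sample ids")
        vals = self.beta.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            pr, sc = np.nonzero(bad)
            cells = [
                f"({self.beta.index[i]}, {self.beta.columns[j]})={vals[i, j]:g}"
                for i, j in zip(pr[:5], sc[:5])
            ]
            raise ValidationError(
                f"beta values outside [0, 1] at {int(bad.sum())} cells: " + ", ".join(cells)
            )
        if self.detection_p is not None:
            self.detection_p = self.detection_p.astype(float)
            if not self.detection_p.index.equals(self.beta.index) or not (
                self.detection_p.columns.equals(self.beta.columns)
            ):
                raise ValidationError("detection_p matrix does not align with beta matrix")
            dp = self.detection_p.to_numpy()
            if ((dp < 0) | (dp > 1)).any():
                raise ValidationError("detection p-values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta.shape

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        dp = self.detection_p.loc[probe_ids] if self.detection_p is not None else None
        return BetaMatrix(self.beta.loc[probe_ids], dp)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        dp = self.detection_p[sample_ids] if self.detection_p is not None else None
        return BetaMatrix(self.beta[sample_ids], dp)


@dataclass
class ProbeManifest:
    """Per-probe annotation: position, class, artifact flags and gene map.

    Columns: ``probe_id`` (index), ``chrom``, ``pos`` (1-based cytosine
    coordinate), ``probe_class`` (CpG / non-CpG / control), ``snp_maf``
    (minor-allele frequency of the nearest interfering SNP; 0 if none),
    ``cross_reactive`` (0/1), ``genes`` (``;``-separated ``GENE:region``
    entries, region in {promoter, 5'UTR, body}; NA if unannotated).
    Unknown extra columns are carried through untouched.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "pos", "probe_class", "snp_maf", "cross_reactive", "genes")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"manifest missing required columns: {missing}")
        _check_unique(self.table.index, "probe ids")
        t = self.table
        if (t["pos"].astype(int) < 1).any():
            raise ValidationError("manifest positions must be >= 1 (1-based)")
        maf = t["snp_maf"].astype(float)
        if ((maf < 0) | (maf > 0.5)).any():
            raise ValidationError("snp_maf must lie in [0, 0.5]")
        bad_class = set(t["probe_class"].unique()) - PROBE_CLASSES
        if bad_class:
            raise ValidationError(f"unknown probe_class values: {sorted(bad_class)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def gene_map(self) -> dict[str, list[str]]:
        """probe_id -> deduplicated gene symbols (region annotation stripped)."""
        out: dict[str, list[str]] = {}
        for pid, entry in self.table["genes"].items():
            if not isinstance(entry, str) or entry in ("", NA_REP):
                out[pid] = []
                continue
            genes = []
            for token in entry.split(";"):
                gene = token.split(":")[0].strip()
                if gene and gene not in genes:
                    genes.append(gene)
            out[pid] = genes
        return out


@dataclass
class SampleSheet:
    """Per-sample phenotype table: group, age (years), sex code, replicate."""

    table: pd.DataFrame

    REQUIRED = ("group", "age", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"sample sheet missing required columns: {missing}")
        _check_unique(self.table.index, "sample ids")
        bad = set(self.table["group"].unique()) - GROUP_VOCABULARY
        if bad:
            raise ValidationError(
                f"unknown group labels {sorted(bad)}; allowed: {sorted(GROUP_VOCABULARY)}"
            )
        ages = self.table["age"].astype(float)
        if not np.isfinite(ages).all() or (ages < 0).any():
            raise ValidationError("ages must be finite and nonnegative")
        if "replicate_of" not in self.table.columns:
            self.table = self.table.assign(replicate_of=pd.NA)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def ids_in_group(self, group: str) -> list[str]:
        return self.table.index[self.table["group"] == group].tolist()


@dataclass
class PipelineConfig:
    """Thresholds and tuning knobs for the full signature workflow.

    Defaults follow the published protocol: signature CpGs at BH-adjusted
    p < 0.05 with |delta beta| > 0.10, derivation restricted to samples older
    than ``min_age`` years, DMRs from probe clusters with inter-probe gaps
    < 500 bp, kept at bootstrap p < 0.01 with >= 4 CpGs.
    """

    alpha: float = 0.05
    min_abs_delta: float = 0.10
    min_age: float = 2.0
    max_gap: int = 500
    dmr_p: float = 0.01
    dmr_min_len: int = 4
    n_boot: int = 1000
    detection_p_cutoff: float = 0.01
    raw_extreme_frac: float = 0.0025
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("alpha", 0.0, 1.0),
            ("min_abs_delta", 0.0, 1.0),
            ("dmr_p", 0.0, 1.0),
            ("detection_p_cutoff", 0.0, 1.0),
            ("raw_extreme_frac", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.max_gap < 1 or self.dmr_min_len < 1 or self.n_boot < 1:
            raise ValidationError("max_gap, dmr_min_len and n_boot must be >= 1")
        if self.min_age < 0:
            raise ValidationError("min_age must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Tabular readers / writers


def read_beta_matrix(path: str | Path, detection_p_path: str | Path | None = None) -> BetaMatrix:
    """Read a probes x samples beta TSV (first column probe ids, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
    if df.columns.size == 0:
        raise SchemaError(f"{path}: no sample columns found in header")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric beta values ({exc})") from exc
    dp = None
    if detection_p_path is not None:
        dp = pd.read_csv(detection_p_path, sep="\t", index_col=0, na_values=[NA_REP])
    return BetaMatrix(df, dp)


def write_beta_matrix(bm: BetaMatrix, path: str | Path, detection_p_path: str | Path | None = None) -> None:
    bm.beta.to_csv(path, sep="\t", na_rep=NA_REP, index_label="probe_id", float_format="%.10g")
    if bm.detection_p is not None and detection_p_path is not None:
        bm.detection_p.to_csv(
            detection_p_path, sep="\t", na_rep=NA_REP, index_label="probe_id", float_format="%.10g"
        )


def read_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_REP], keep_default_na=False, dtype={"genes": str}
    )
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", na_rep=NA_REP, index_label="probe_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", na_rep=NA_REP, index_label="sample_id")
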