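"""Bumphunter-style differentially methylated region (DMR) detection.

Probes are grouped into clusters of neighbours with inter-probe gaps below
``max_gap`` (strict, default 500 bp). Within a cluster, maximal runs of
consecutive probes whose covariate-adjusted group coefficient exceeds the
candidate cutoff (default |coef| > 0.10) with a common sign form candidate
regions; each candidate is summarized by its area (sum of |coef| over member
probes). Significance comes from a residual bootstrap under the null model
(the design without the group column): residual vectors are resampled across
samples with replacement, added back to the null fitted values, the group
coefficients refitted, and candidate areas pooled over iterations into a
null distribution. The add-one empirical p-value

    p = (1 + #{null areas >= observed area}) / (1 + #null areas)

is attached to each candidate; reported DMRs satisfy p < dmr_p and
n_probes >= dmr_min_len.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ProbeManifest, ValidationError


@dataclass
class DMRecord:
    chrom: str
    start: int
    end: int
    n_probes: int
    value: float      # mean group coefficient over member probes
    area: float       # sum of |coefficient|
    p: float
    probe_ids: tuple[str, ...] = ()


def cluster_probes(manifest: ProbeManifest, max_gap: int = 500) -> pd.Series:
    """Cluster id per probe: consecutive probes on one chromosome join a
    cluster iff their positional gap is strictly below ``max_gap``."""
    t = manifest.table[["chrom", "pos"]].copy()
    if t.duplicated(["chrom", "pos"]).any():
        dup = t[t.duplicated(["chrom", "pos"], keep=False)].head(4)
        raise ValidationError(f"duplicate (chrom, pos) in manifest:\n{dup}")
    t = t.sort_values(["chrom", "pos"], kind="mergesort")
    new_chrom = t["chrom"].ne(t["chrom"].shift())
    gap = t["pos"].diff()
    breaks = new_chrom | (gap >= max_gap)
    ids = breaks.cumsum() - 1
    return ids.reindex(manifest.probe_ids).rename("cluster")


def _runs(c: np.ndarray, clu: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Start/stop (half-open) index pairs of maximal same-sign passing runs
    within clusters, over position-sorted arrays. Vectorized."""
    passing = np.abs(c) > cutoff
    sign = np.sign(c)
    brk = np.ones(c.size, dtype=bool)
    if c.size > 1:
        brk[1:] = (clu[1:] != clu[:-1]) | (sign[1:] != sign[:-1])
    starts = np.flatnonzero(passing & (brk | ~np.concatenate([[False], passing[:-1]])))
    if starts.size == 0:
        return starts, starts
    ends_mask = np.concatenate([(~passing[1:]) | brk[1:], [True]])
    run_end = np.flatnonzero(passing & ends_mask)
    # pair each start with the first run end at or after it
    stops = run_end[np.searchsorted(run_end, starts)] + 1
    return starts, stops


def find_candidate_regions(
    coefs: pd.Series, manifest: ProbeManifest, clusters: pd.Series, cutoff: float = 0.10
) -> pd.DataFrame:
    """Maximal same-sign runs of consecutive probes with |coef| > cutoff.

    Returns a DataFrame with chrom/start/end/n_probes/value/area and the
    member probe ids, one row per candidate region.
    """
    t = manifest.table[["chrom", "pos"]].copy()
    t["coef"] = coefs.reindex(manifest.probe_ids)
    t["cluster"] = clusters.reindex(manifest.probe_ids)
    t = t.sort_values(["chrom", "pos"], kind="mergesort")
    return _candidates_sorted(
        t["coef"].to_numpy(float), t["cluster"].to_numpy(), t["chrom"].to_numpy(),
        t["pos"].to_numpy(int), t.index.to_numpy(), cutoff,
    )


def _candidates_sorted(c, clu, chrom, pos, pids, cutoff) -> pd.DataFrame:
    starts, stops = _runs(c, clu, cutoff)
    absum = np.concatenate([[0.0], np.cumsum(np.abs(c))])
    csum = np.concatenate([[0.0], np.cumsum(c)])
    rows = {
        "chrom": chrom[starts],
        "start": pos[starts],
        "end": pos[stops - 1],
        "n_probes": stops - starts,
        "value": (csum[stops] - csum[starts]) / (stops - starts) if starts.size else np.array([]),
        "area": absum[stops] - absum[starts],
        "probe_ids": [";".join(pids[a:b]) for a, b in zip(starts, stops)],
    }
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes", "value", "area", "probe_ids"])


def _group_coefs(Y: np.ndarray, X: np.ndarray, group_col: int) -> np.ndarray:
    xtx_inv = np.linalg.inv(X.T @ X)
    return (Y @ X @ xtx_inv)[:, group_col]


def bootstrap_null(
    beta: BetaMatrix | pd.DataFrame,
    design: pd.DataFrame,
    manifest: ProbeManifest,
    clusters: pd.Series,
    cutoff: float = 0.10,
    n_boot: int = 1000,
    seed: int = 0,
    group_col: str = "group",
) -> np.ndarray:
    """Pooled null candidate areas from a residual bootstrap of the null
    (group-free) model."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    Y = (beta.beta if isinstance(beta, BetaMatrix) else beta)
    Y = Y[design.index.tolist()].to_numpy()
    X = design.to_numpy(float)
    X0 = design.drop(columns=[group_col]).to_numpy(float)
    j = design.columns.get_loc(group_col)
    n = X.shape[0]

    fitted0 = (Y @ X0 @ np.linalg.inv(X0.T @ X0)) @ X0.T
    resid0 = Y - fitted0
    rng = np.random.default_rng(seed)
    probe_index = (beta.beta if isinstance(beta, BetaMatrix) else beta).index

    # position-sorted view computed once; bootstrap only permutes residuals
    t = manifest.table[["chrom", "pos"]].copy()
    t["cluster"] = clusters.reindex(manifest.probe_ids)
    t = t.sort_values(["chrom", "pos"], kind="mergesort")
    order = probe_index.get_indexer(t.index)
    clu_sorted = t["cluster"].to_numpy()

    hat = X @ np.linalg.inv(X.T @ X)[:, j]  # Yb @ hat = group coefficients
    null_areas: list[np.ndarray] = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cb = (fitted0 + resid0[:, idx]) @ hat
        c_sorted = cb[order]
        starts, stops = _runs(c_sorted, clu_sorted, cutoff)
        if starts.size:
            absum = np.concatenate([[0.0], np.cumsum(np.abs(c_sorted))])
            null_areas.append(absum[stops] - absum[starts])
    if not null_areas:
        return np.array([], dtype=float)
    return np.concatenate(null_areas)


def call_dmrs(
    candidates: pd.DataFrame, null_areas: np.ndarray, p_cut: float = 0.01, min_len: int = 4
) -> list[DMRecord]:
    """Attach add-one bootstrap p-values and post-filter candidates."""
    null_areas = np.asarray(null_areas, dtype=float)
    records = []
    for _, row in candidates.iterrows():
        p = (1.0 + float((null_areas >= row["area"]).sum())) / (1.0 + null_areas.size)
        if p < p_cut and row["n_probes"] >= min_len:
            records.append(DMRecord(
                chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                n_probes=int(row["n_probes"]), value=float(row["value"]),
                area=float(row["area"]), p=float(p),
                probe_ids=tuple(str(row["probe_ids"]).split(";")),
            ))
    records.sort(key=lambda r: -r.area)
    return records


def dmrs_to_frame(records: list[DMRecord]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_probes", "value", "area", "p"]
    rows = [{c: getattr(r, c) for c in cols} | {"probe_ids": ";".join(r.probe_ids)} for r in records]
    return pd.DataFrame(rows, columns=cols + ["probe_ids"])


def write_bed(records: list[DMRecord], path) -> None:
    """Export reported DMRs as BED (0-based half-open; converted from the
    internal 1-based closed coordinates at export)."""
    with open(path, "w") as fh:
        for i, r in enumerate(records):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tDMR_{i+1}\t{r.area:.4f}\n")


class DMRAnalysis:
    """Bumphunter model: candidate regions plus a bootstrap null.

    Parameters mirror the region-detection protocol: clusters from gaps
    < ``max_gap``, candidate cutoff on the adjusted group coefficient,
    ``n_boot`` bootstrap iterations, post-filter at ``p_cut`` /
    ``min_len``.
    """

    def __init__(self, beta, design: pd.DataFrame, manifest: ProbeManifest,
                 max_gap: int = 500, cutoff: float = 0.10):
        self.beta = beta
        self.design = design
        self.manifest = manifest
        self.max_gap = max_gap
        self.cutoff = cutoff
        self.clusters = cluster_probes(manifest, max_gap)

    def fit(self, n_boot: int = 1000, seed: int = 0, p_cut: float = 0.01, min_len: int = 4) -> "DMRResults":
        Y = (self.beta.beta if isinstance(self.beta, BetaMatrix) else self.beta)
        coefs = pd.Series(
            _group_coefs(Y[self.design.index.tolist()].to_numpy(),
                         self.design.to_numpy(float),
                         self.design.columns.get_loc("group")),
            index=Y.index,
        )
        candidates = find_candidate_regions(coefs, self.manifest, self.clusters, self.cutoff)
        null_areas = bootstrap_null(
            self.beta, self.design, self.manifest, self.clusters,
            cutoff=self.cutoff, n_boot=n_boot, seed=seed,
        )
        records = call_dmrs(candidates, null_areas, p_cut=p_cut, min_len=min_len)
        return DMRResults(self, coefs, candidates, null_areas, records)


class DMRResults:
    def __init__(self, model, coefs, candidates, null_areas, records):
        self.model = model
        self.coefs = coefs
        self.candidates = candidates
        self.null_areas = null_areas
        self.records = records

    def to_frame(self) -> pd.DataFrame:
        return dmrs_to_frame(self.records)

    def summary(self) -> str:
        return "\n".join([
            "Bootstrap DMR detection",
            "=======================",
            f"probes:             {len(self.coefs)}",
            f"clusters:           {self.model.clusters.nunique()}",
            f"candidate regions:  {len(self.candidates)}",
            f"null areas pooled:  {self.null_areas.size}",
            f"reported DMRs:      {len(self.records)}",
        ])
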