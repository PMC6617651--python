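"""Gene-set enrichment of signature probes and 2x2 overlap testing.

Foreground and background probe sets are mapped to deduplicated gene lists
through the manifest's probe->gene annotations; each gene set is tested with
an upper-tail hypergeometric p-value (probability of observing at least the
seen number of foreground genes in the set, given the background
composition). Terms with fewer than ``min_hits`` foreground genes are not
reported; reported p-values are Benjamini-Hochberg adjusted across terms.

The 2x2 chi-square (1 df, no continuity correction) covers overlap tests of
a gene list against an external panel such as the SFARI autism genes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffmeth import adjust_bh


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse GMT gene sets: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:80]}")
        sets[parts[0]] = [g for g in dict.fromkeys(parts[2:]) if g]
    return sets


def _genes_of(probes, probe_to_genes: dict[str, list[str]]) -> set[str]:
    out: set[str] = set()
    for p in probes:
        out.update(probe_to_genes.get(p, []))
    return out


def hypergeom_enrich(
    foreground_probes,
    background_probes,
    probe_to_genes: dict[str, list[str]],
    gene_sets: dict[str, list[str]],
    min_hits: int = 2,
) -> pd.DataFrame:
    """Foreground/background hypergeometric enrichment over probe-mapped genes."""
    fg_probes = set(foreground_probes)
    bg_probes = set(background_probes)
    extra = fg_probes - bg_probes
    if extra:
        raise ValueError(f"foreground probes absent from background: {sorted(extra)[:3]}")
    bg_genes = _genes_of(bg_probes, probe_to_genes)
    fg_genes = _genes_of(fg_probes, probe_to_genes)
    N, n_fg = len(bg_genes), len(fg_genes)
    rows = []
    for name, members in gene_sets.items():
        in_bg = bg_genes.intersection(members)
        K = len(in_bg)
        hits = len(fg_genes.intersection(in_bg))
        if hits < min_hits:
            continue
        p = float(stats.hypergeom.sf(hits - 1, N, K, n_fg))
        fold = (hits / n_fg) / (K / N) if K and n_fg else float("nan")
        rows.append({
            "set_name": name, "n_hits": hits, "n_set": K,
            "n_foreground": n_fg, "n_background": N,
            "fold": fold, "p": p,
        })
    out = pd.DataFrame(rows, columns=["set_name", "n_hits", "n_set", "n_foreground",
                                      "n_background", "fold", "p"])
    if len(out):
        out["p_adj"] = adjust_bh(out["p"].to_numpy())
        out = out.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
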