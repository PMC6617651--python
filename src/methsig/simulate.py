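"""Synthetic EPIC-style methylation datasets with known ground truth.

The generator emulates the statistical structure of a small case/control
whole-blood methylation study: a bimodal genome-wide beta distribution, bulk
samples formed as cell-type-proportion-weighted mixtures of sorted-cell
profiles, a planted CpG signature with ~10-15% beta effects in cases,
group-correlated shifts in blood composition (monocytes up, CD4+ T cells down
in cases), age- and sex-associated probes, probe-level artifacts that the QC
stage must remove, and clustered probe positions supporting multi-probe DMRs.

Planted effects and measurement noise are applied on the logit scale and
mapped back through the inverse logit, so beta never leaves (0, 1). The
logit-scale noise sd and the signature logit offsets are solved numerically
(Gauss-Hermite quadrature plus bisection) so that, probe by probe, the
induced beta-scale measurement sd equals ``noise_sd`` and the induced
beta-scale group-mean shift equals ``effect_delta`` — the nominal study
conditions hold on the beta scale at any baseline methylation level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import BetaMatrix, ProbeManifest, SampleSheet, ValidationError
from .celltype import CellTypePanel

DEFAULT_CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")

# Whole-blood composition means; cases shift mass from CD4+ T to monocytes.
_CONTROL_MEANS = np.array([0.15, 0.10, 0.06, 0.07, 0.07, 0.55])
_CASE_MEANS = np.array([0.09, 0.10, 0.06, 0.07, 0.13, 0.55])
_CONCENTRATION = 150.0  # Dirichlet precision: proportion sd ~1-2% per type

DEFAULT_ARTIFACT_RATES = {
    "snp": 0.010,
    "cross_reactive": 0.010,
    "detection_failure": 0.001,
    "non_cpg": 0.005,
    "sex_chromosome": 0.020,
}


class ParameterError(ValueError):
    """Simulation parameters are infeasible or out of range."""


@dataclass
class SimulationParams:
    """Knobs controlling one synthetic study.

    Defaults reproduce the study conditions the analysis was designed for:
    8 cases vs 23 controls, 300 signature CpGs at |delta beta| = 0.15 among
    20,000 probes, beta-scale noise sd 0.03, six blood cell types with a
    monocyte/CD4T shift in cases, and three planted 6-probe DMRs.
    """

    n_probes: int = 20_000
    n_cases: int = 8
    n_controls: int = 23
    n_signature: int = 300
    effect_delta: float = 0.15
    hyper_fraction: float = 0.5
    noise_sd: float = 0.03
    n_celltypes: int = 6
    dirichlet_case: np.ndarray | None = None
    dirichlet_control: np.ndarray | None = None
    n_discriminating: int = 50
    n_dmrs: int = 3
    dmr_len: int = 6
    artifact_rates: dict = field(default_factory=lambda: dict(DEFAULT_ARTIFACT_RATES))
    n_age_probes: int = 100
    n_sex_probes: int = 50
    age_range: tuple[float, float] = (3.0, 40.0)
    max_gap: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.effect_delta < 1:
            raise ParameterError("effect_delta must lie in [0, 1)")
        if self.dmr_len < 4:
            raise ParameterError("dmr_len must be >= 4 to support reportable DMRs")
        if self.n_dmrs * self.dmr_len > self.n_probes:
            raise ParameterError("infeasible layout: n_dmrs * dmr_len exceeds n_probes")
        if self.n_signature > self.n_probes:
            raise ParameterError("n_signature exceeds n_probes")
        if self.n_signature < self.n_dmrs * self.dmr_len:
            raise ParameterError("n_signature must cover the planted DMR probes")
        if self.dirichlet_case is None:
            self.dirichlet_case = self._default_concentration(case=True)
        if self.dirichlet_control is None:
            self.dirichlet_control = self._default_concentration(case=False)
        self.dirichlet_case = np.asarray(self.dirichlet_case, dtype=float)
        self.dirichlet_control = np.asarray(self.dirichlet_control, dtype=float)
        if len(self.dirichlet_case) != self.n_celltypes or len(self.dirichlet_control) != self.n_celltypes:
            raise ParameterError("Dirichlet concentration length must equal n_celltypes")
        if (self.dirichlet_case <= 0).any() or (self.dirichlet_control <= 0).any():
            raise ParameterError("Dirichlet concentrations must be positive")

    def _default_concentration(self, case: bool) -> np.ndarray:
        if self.n_celltypes == 6:
            means = _CASE_MEANS if case else _CONTROL_MEANS
            return means * _CONCENTRATION
        return np.full(self.n_celltypes, _CONCENTRATION / self.n_celltypes)

    @property
    def cell_type_names(self) -> list[str]:
        if self.n_celltypes <= len(DEFAULT_CELL_TYPES):
            return list(DEFAULT_CELL_TYPES[: self.n_celltypes])
        extra = [f"CT{k}" for k in range(len(DEFAULT_CELL_TYPES), self.n_celltypes)]
        return list(DEFAULT_CELL_TYPES) + extra


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for parameter-recovery tests."""

    signature: pd.DataFrame          # probe_id index; effect (signed, beta scale), in_dmr
    true_proportions: pd.DataFrame   # samples x cell types, rows sum to 1
    planted_dmrs: pd.DataFrame       # chrom, start, end, n_probes, effect
    artifact_labels: pd.Series       # per probe: none/snp/cross_reactive/...
    mosaic_masks: dict = field(default_factory=dict)  # sample_id -> mask Series
    # internal generator state needed to synthesize further samples
    baseline: pd.Series | None = None
    logit_effect: pd.Series | None = None        # over signature probes
    logit_noise_sd: pd.Series | None = None
    logit_noise_sd_case: pd.Series | None = None  # over signature probes
    profiles: pd.DataFrame | None = None    # cell types x probes
    control_concentration: np.ndarray | None = None

    @property
    def signature_probe_ids(self) -> pd.Index:
        return self.signature.index


class SimulatedDataset(NamedTuple):
    beta: BetaMatrix
    manifest: ProbeManifest
    samples: SampleSheet
    truth: SyntheticTruth


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(21)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _noisy_mean_beta(mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """E[expit(mu + sd*Z)] for Z ~ N(0,1), by Gauss-Hermite quadrature."""
    z = mu[:, None] + sd[:, None] * _GH_NODES[None, :]
    return expit(z) @ _GH_WEIGHTS


def _noisy_sd_beta(mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """SD of expit(mu + sd*Z) for Z ~ N(0,1), by quadrature."""
    z = expit(mu[:, None] + sd[:, None] * _GH_NODES[None, :])
    m = z @ _GH_WEIGHTS
    return np.sqrt(np.maximum((z**2) @ _GH_WEIGHTS - m**2, 0.0))


def _solve_logit_sd(mu: np.ndarray, target_sd: float) -> np.ndarray:
    """Per-probe logit-scale noise sd whose induced beta-scale sd equals
    ``target_sd`` (bisection; the induced sd is increasing in the logit sd)."""
    if target_sd <= 0:
        return np.zeros_like(mu)
    lo = np.zeros_like(mu)
    hi = np.full_like(mu, 20.0)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        too_low = _noisy_sd_beta(mu, mid) < target_sd
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def _solve_logit_offset(mu0: np.ndarray, sd: np.ndarray, target_mean: np.ndarray) -> np.ndarray:
    """Offset e with E[expit(mu0 + e + sd*Z)] = target_mean (bisection; the
    noisy mean is strictly increasing in the offset)."""
    lo = np.full_like(mu0, -30.0)
    hi = np.full_like(mu0, 30.0)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _noisy_mean_beta(mu0 + mid, sd) < target_mean
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def _architecture(params: SimulationParams, seed: int):
    """Probe-level layout shared by the dataset and the reference panel.

    Deterministic given (params, seed): baselines, role assignment (DMR,
    signature, cell-type marker, age/sex, artifact), cell-type profiles,
    manifest coordinates and planted logit effects.
    """
    root = np.random.SeedSequence(seed)
    s_layout, s_samples, s_noise = root.spawn(3)
    rng = np.random.default_rng(s_layout)
    n = params.n_probes

    # bimodal baseline: low-methylated and high-methylated modes
    low = rng.random(n) < 0.5
    baseline = np.where(low, rng.beta(2.0, 18.0, n), rng.beta(17.0, 3.0, n))
    baseline = np.clip(baseline, 0.02, 0.98)

    probe_ids = np.array([f"cg{i:07d}" for i in range(n)])

    # --- roles -------------------------------------------------------------
    role = np.full(n, "none", dtype=object)
    dmr_blocks: list[np.ndarray] = []
    if params.n_dmrs:
        starts = np.linspace(0, n - params.dmr_len, params.n_dmrs + 2)[1:-1].astype(int)
        for st in starts:
            block = np.arange(st, st + params.dmr_len)
            dmr_blocks.append(block)
            role[block] = "signature"
    dmr_members = np.concatenate(dmr_blocks) if dmr_blocks else np.array([], dtype=int)
    free = np.flatnonzero(role == "none")
    n_rest = params.n_signature - dmr_members.size
    sig_rest = rng.choice(free, size=n_rest, replace=False)
    role[sig_rest] = "signature"

    free = np.flatnonzero(role == "none")
    n_markers = params.n_celltypes * params.n_discriminating
    marker_idx = rng.choice(free, size=min(n_markers, free.size), replace=False)
    role[marker_idx] = "marker"
    marker_by_type = np.array_split(marker_idx, params.n_celltypes)

    free = np.flatnonzero(role == "none")
    n_age = min(params.n_age_probes, free.size)
    age_idx = rng.choice(free, size=n_age, replace=False)
    role[age_idx] = "age"
    free = np.flatnonzero(role == "none")
    n_sex = min(params.n_sex_probes, free.size)
    sex_idx = rng.choice(free, size=n_sex, replace=False)
    role[sex_idx] = "sex"

    # --- artifacts (only on role-free probes) ------------------------------
    artifact = np.full(n, "none", dtype=object)
    free = np.flatnonzero(role == "none")
    u = rng.random(free.size)
    edges = np.cumsum([params.artifact_rates.get(k, 0.0) for k in DEFAULT_ARTIFACT_RATES])
    labels = list(DEFAULT_ARTIFACT_RATES)
    which = np.searchsorted(edges, u)
    for j, lab in enumerate(labels):
        artifact[free[which == j]] = lab

    # --- DMR baselines away from the boundary so effects stay coherent -----
    if dmr_members.size:
        baseline[dmr_members] = rng.uniform(0.25, 0.65, dmr_members.size)

    # --- cell-type profiles -------------------------------------------------
    profiles = np.tile(baseline, (params.n_celltypes, 1))
    for k, idx in enumerate(marker_by_type):
        half = idx.size // 2
        hyper, hypo = idx[:half], idx[half:]
        baseline[hyper] = np.clip(rng.normal(0.12, 0.02, hyper.size), 0.03, 0.3)
        baseline[hypo] = np.clip(rng.normal(0.85, 0.02, hypo.size), 0.7, 0.97)
        profiles[:, hyper] = baseline[hyper]
        profiles[:, hypo] = baseline[hypo]
        profiles[k, hyper] = np.clip(rng.normal(0.90, 0.02, hyper.size), 0.75, 0.98)
        profiles[k, hypo] = np.clip(rng.normal(0.10, 0.02, hypo.size), 0.02, 0.25)

    # --- signature effects ---------------------------------------------------
    logit_sd = _solve_logit_sd(logit(baseline), params.noise_sd)
    sig_idx = np.flatnonzero(role == "signature")
    sign = np.where(rng.random(sig_idx.size) < params.hyper_fraction, 1.0, -1.0)
    # coherent sign within a DMR block
    for block in dmr_blocks:
        block_sign = 1.0 if rng.random() < params.hyper_fraction else -1.0
        sign[np.isin(sig_idx, block)] = block_sign
    mu0 = logit(baseline[sig_idx])
    sd_sig = logit_sd[sig_idx]
    m0 = _noisy_mean_beta(mu0, sd_sig)
    target = m0 + sign * params.effect_delta
    infeasible = (target < 0.02) | (target > 0.98)
    sign[infeasible] *= -1.0
    target = np.clip(m0 + sign * params.effect_delta, 1e-4, 1 - 1e-4)
    # jointly solve the case-group logit offset and noise sd so that, at
    # signature probes, the case mean is shifted by exactly effect_delta and
    # the case beta-scale sd still equals noise_sd (the inverse logit both
    # compresses means and rescales noise, so the two must be solved together)
    sd_case = sd_sig.copy()
    logit_effect = np.zeros_like(mu0)
    if params.effect_delta > 0:
        for _ in range(8):
            logit_effect = _solve_logit_offset(mu0, sd_case, target)
            sd_case = _solve_logit_sd(mu0 + logit_effect, params.noise_sd)
        logit_effect = _solve_logit_offset(mu0, sd_case, target)

    # --- age / sex effects ---------------------------------------------------
    age_slope = np.zeros(n)
    age_slope[age_idx] = rng.choice([-1, 1], n_age) * 0.003 / (baseline[age_idx] * (1 - baseline[age_idx]))
    sex_offset = np.zeros(n)
    sex_offset[sex_idx] = rng.choice([-1, 1], n_sex) * 0.05 / (baseline[sex_idx] * (1 - baseline[sex_idx]))

    # --- manifest ------------------------------------------------------------
    chrom = np.empty(n, dtype=object)
    autosomal = np.flatnonzero(artifact != "sex_chromosome")
    sexed = np.flatnonzero(artifact == "sex_chromosome")
    chrom[autosomal] = [f"chr{1 + (r * 22) // autosomal.size}" for r in range(autosomal.size)]
    half = sexed.size // 2
    chrom[sexed[:half]] = "chrX"
    chrom[sexed[half:]] = "chrY"
    for block in dmr_blocks:  # a block never straddles two chromosomes
        chrom[block] = chrom[block[0]]
    in_dmr_follow = np.zeros(n, dtype=bool)
    for block in dmr_blocks:
        in_dmr_follow[block[1:]] = True
    gaps = rng.integers(params.max_gap + 100, params.max_gap * 4, n).astype(int)
    gaps[in_dmr_follow] = rng.integers(50, min(300, params.max_gap), int(in_dmr_follow.sum()))
    pos = np.empty(n, dtype=int)
    order = pd.Series(np.arange(n)).groupby(pd.Series(chrom), sort=False)
    for _, members in order.groups.items():
        members = np.sort(np.asarray(members))
        pos[members] = 1 + np.cumsum(gaps[members]) - gaps[members][0]
    pos += 1

    probe_class = np.where(artifact == "non_cpg", "non-CpG", "CpG")
    snp_maf = np.where(artifact == "snp", rng.uniform(0.02, 0.4, n), 0.0)
    cross = (artifact == "cross_reactive").astype(int)
    gene_id = np.arange(n) // 10
    regions = rng.choice(["promoter", "5'UTR", "body"], n, p=[0.3, 0.1, 0.6])
    genes = np.array([f"GENE{g}:{r}" for g, r in zip(gene_id, regions)], dtype=object)

    manifest = ProbeManifest(pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "probe_class": probe_class,
            "snp_maf": np.round(snp_maf, 4),
            "cross_reactive": cross,
            "genes": genes,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    ))

    dmr_rows = []
    for block, s in zip(dmr_blocks, [sign[np.isin(sig_idx, b)][0] for b in dmr_blocks] if dmr_blocks else []):
        dmr_rows.append({
            "chrom": chrom[block[0]],
            "start": int(pos[block[0]]),
            "end": int(pos[block[-1]]),
            "n_probes": int(block.size),
            "effect": float(s * params.effect_delta),
            "probe_ids": ";".join(probe_ids[block]),
        })
    planted_dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "n_probes", "effect", "probe_ids"])

    return dict(
        probe_ids=probe_ids, baseline=baseline, profiles=profiles, role=role,
        artifact=artifact, manifest=manifest, sig_idx=sig_idx, sign=sign,
        logit_effect=logit_effect, age_slope=age_slope, sex_offset=sex_offset,
        logit_sd=logit_sd, logit_sd_case=sd_case, planted_dmrs=planted_dmrs,
        dmr_members=dmr_members, s_samples=s_samples, s_noise=s_noise,
    )


def generate_dataset(params: SimulationParams | None = None, seed: int | None = None) -> SimulatedDataset:
    """Simulate one case/control study with ground truth.

    Returns a 4-tuple ``(beta, manifest, samples, truth)``.
    """
    params = params or SimulationParams()
    seed = params.seed if seed is None else seed
    arch = _architecture(params, seed)
    rng_s = np.random.default_rng(arch["s_samples"])
    rng_n = np.random.default_rng(arch["s_noise"])

    n_case, n_ctrl = params.n_cases, params.n_controls
    n_samples = n_case + n_ctrl
    sample_ids = [f"case_{i+1:02d}" for i in range(n_case)] + [f"ctrl_{i+1:02d}" for i in range(n_ctrl)]
    groups = ["case"] * n_case + ["control"] * n_ctrl

    props = np.vstack([
        rng_s.dirichlet(params.dirichlet_case, n_case),
        rng_s.dirichlet(params.dirichlet_control, n_ctrl),
    ])
    ages = rng_s.uniform(*params.age_range, n_samples)
    sexes = rng_s.integers(0, 2, n_samples)

    m = props @ arch["profiles"]                      # samples x probes bulk means
    z = logit(np.clip(m, 1e-6, 1 - 1e-6))
    is_case = np.array([g == "case" for g in groups])
    z[np.ix_(is_case, arch["sig_idx"])] += arch["logit_effect"]
    z += np.outer(ages - np.mean(params.age_range), arch["age_slope"])
    z += np.outer(sexes, arch["sex_offset"])
    sd = np.tile(arch["logit_sd"], (n_samples, 1))
    sd[np.ix_(is_case, arch["sig_idx"])] = arch["logit_sd_case"]
    z += rng_n.normal(0.0, 1.0, z.shape) * sd
    beta_vals = expit(z).T                            # probes x samples

    dp = rng_n.uniform(0.0, 1e-4, beta_vals.shape)
    fail_idx = np.flatnonzero(arch["artifact"] == "detection_failure")
    for j in fail_idx:
        k = rng_n.integers(1, 4)
        cols = rng_n.choice(n_samples, size=k, replace=False)
        dp[j, cols] = rng_n.uniform(0.05, 0.5, k)

    pid = pd.Index(arch["probe_ids"], name="probe_id")
    sid = pd.Index(sample_ids, name="sample_id")
    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=pid, columns=sid),
        pd.DataFrame(dp, index=pid, columns=sid),
    )
    samples = SampleSheet(pd.DataFrame(
        {"group": groups, "age": np.round(ages, 1), "sex": sexes}, index=sid,
    ))

    sig_ids = arch["probe_ids"][arch["sig_idx"]]
    truth = SyntheticTruth(
        signature=pd.DataFrame(
            {
                "effect": arch["sign"] * params.effect_delta,
                "in_dmr": np.isin(arch["sig_idx"], arch["dmr_members"]),
            },
            index=pd.Index(sig_ids, name="probe_id"),
        ),
        true_proportions=pd.DataFrame(props, index=sid, columns=params.cell_type_names),
        planted_dmrs=arch["planted_dmrs"],
        artifact_labels=pd.Series(arch["artifact"], index=pid, name="artifact"),
        baseline=pd.Series(arch["baseline"], index=pid, name="baseline"),
        logit_effect=pd.Series(arch["logit_effect"], index=pd.Index(sig_ids, name="probe_id")),
        logit_noise_sd=pd.Series(arch["logit_sd"], index=pid),
        logit_noise_sd_case=pd.Series(arch["logit_sd_case"], index=pd.Index(sig_ids, name="probe_id")),
        profiles=pd.DataFrame(arch["profiles"], index=params.cell_type_names, columns=pid),
        control_concentration=params.dirichlet_control,
    )
    return SimulatedDataset(beta, arch["manifest"], samples, truth)


def generate_mosaic_sample(
    dataset: SimulatedDataset, fraction: float, seed: int, sample_id: str | None = None
) -> tuple[pd.Series, pd.Series]:
    """Synthesize one sample carrying the case effect at a random subset of
    signature probes (the partial-signature / mosaic scenario).

    Each signature probe independently carries the case effect with
    probability ``fraction``; elsewhere the sample is drawn from the control
    distribution. Returns ``(beta_vector, mask)`` where ``mask`` is a boolean
    Series over signature probes, and records the mask in the dataset truth.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"mosaic fraction {fraction} outside [0, 1]")
    truth = dataset.truth
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(truth.control_concentration)
    m = props @ truth.profiles.to_numpy()
    z = logit(np.clip(m, 1e-6, 1 - 1e-6))
    sig_ids = truth.signature_probe_ids
    sig_pos = truth.profiles.columns.get_indexer(sig_ids)
    mask = rng.random(len(sig_ids)) < fraction
    z[sig_pos[mask]] += truth.logit_effect.to_numpy()[mask]
    sd = truth.logit_noise_sd.to_numpy().copy()
    sd[sig_pos[mask]] = truth.logit_noise_sd_case.to_numpy()[mask]
    z += rng.normal(0.0, 1.0, z.size) * sd
    name = sample_id or f"mosaic_f{fraction:g}_s{seed}"
    beta_vec = pd.Series(expit(z), index=truth.profiles.columns, name=name)
    mask = pd.Series(mask, index=sig_ids, name=name)
    truth.mosaic_masks[name] = mask
    return beta_vec, mask


def generate_reference_panel(params: SimulationParams | None = None, seed: int | None = None) -> CellTypePanel:
    """Sorted-cell reference panel consistent with :func:`generate_dataset`.

    The per-cell-type mean beta profiles over marker probes equal, bit for
    bit, the profiles used to mix the bulk samples for the same (params,
    seed), emulating an external FACS-sorted reference dataset.
    """
    params = params or SimulationParams()
    seed = params.seed if seed is None else seed
    arch = _architecture(params, seed)
    marker_idx = np.sort(np.flatnonzero(arch["role"] == "marker"))
    marker_ids = arch["probe_ids"][marker_idx]
    ref = pd.DataFrame(
        arch["profiles"][:, marker_idx],
        index=params.cell_type_names,
        columns=pd.Index(marker_ids, name="probe_id"),
    )
    return CellTypePanel(reference=ref)


def generate_sorted_cell_data(
    params: SimulationParams, seed: int, n_per_type: int = 3, noise_sd: float | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate sorted-cell methylation (probes x cells) with cell labels,
    as input for marker selection. Noise defaults to params.noise_sd."""
    arch = _architecture(params, seed)
    noise = params.noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9151]))
    cols, labels, vecs = [], [], []
    for k, name in enumerate(params.cell_type_names):
        prof = arch["profiles"][k]
        z = logit(np.clip(prof, 1e-6, 1 - 1e-6))
        sd = _solve_logit_sd(z, noise)
        for r in range(n_per_type):
            vecs.append(expit(z + rng.normal(0.0, 1.0, z.size) * sd))
            cols.append(f"{name}_{r+1}")
            labels.append(name)
    df = pd.DataFrame(
        np.column_stack(vecs),
        index=pd.Index(arch["probe_ids"], name="probe_id"),
        columns=cols,
    )
    return df, pd.Series(labels, index=df.columns, name="cell_type")
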