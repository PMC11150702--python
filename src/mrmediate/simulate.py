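"""Synthetic GWAS summary statistics with a known mediation structure.

The generator emulates the summary-level inputs of a two-sample MR
mediation study: an exposure GWAS, a mediator GWAS and a binary-outcome
GWAS over a shared SNP panel, generated directly at the summary level with
asymptotic normal errors (no individual-level cohorts).

Per SNP j the true effects are

    exposure   bx_j = γ_j                      γ_j ~ N(gamma_mean, gamma_sd)
    mediator   bm_j = α γ_j + η_j              η_j ~ N(0, mediator_gamma_sd)
    outcome    by_j = θ_d γ_j + θ_m bm_j + π_j (log-odds scale)

where η_j is the SNP's mediator-specific effect — without it the exposure
and mediator effect columns are exactly collinear and the multivariable
direct effect is unidentified — and π_j is a direct (pleiotropic) SNP →
outcome path present for a configurable fraction of SNPs. Observed effects
are drawn Normal(truth, se) with per-trait SE scales.

The analytic truth record carries the total effect θ_total = θ_d + θ_m·α
and the proportion mediated on both the log-odds scale
(100·θ_m·α/θ_total) and the OR scale the PERM formula uses.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .sumstats import (
    AssociationRecord,
    LdPanel,
    SummaryDataset,
    write_ld_panel,
    write_sumstats,
)

# Non-palindromic allele pairs only, so harmonization keeps every SNP.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]

#: Separation between independent loci; larger than the clumping window.
_LOCUS_SPACING_BP = 25_000_000


@dataclass
class SimConfig:
    """Generating parameters for one synthetic study.

    Defaults emulate a large-consortium setting: a strongly instrumented
    continuous exposure (SE scale 0.002 ≈ a ~700k-sample GWAS), a mediator
    measured in a mid-size sample (SE 0.004) and a common binary outcome
    (log-odds SE 0.008 ≈ a case-control GWAS with tens of thousands of
    cases).
    """

    n_snps: int = 100
    ld_blocks: list[tuple[int, float]] | None = None  # (size, within_r2)
    gamma_mean: float = 0.0
    gamma_sd: float = 0.05
    mediator_gamma_sd: float = 0.05
    alpha: float = 0.6
    theta_direct: float = 0.15
    theta_mediator: float = 0.3
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    se_x: float = 0.002
    se_m: float = 0.004
    se_y: float = 0.008
    n_x: int = 700_000
    n_m: int = 57_000
    n_y: int = 1_030_000
    exposure_name: str = "exposure"
    mediator_name: str = "mediator"
    outcome_name: str = "outcome"
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 4:
            raise ValueError("n_snps must be >= 4")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        for name in ("gamma_sd", "mediator_gamma_sd", "pleiotropy_sd", "se_x", "se_m", "se_y"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Generating parameters and the analytic quantities they imply."""

    alpha: float
    theta_direct: float
    theta_mediator: float
    theta_total: float
    or_total: float
    or_direct: float
    perm_log: float  # 100·θ_m·α/θ_total on the log-odds scale
    perm_or: float  # PERM formula applied to the analytic ORs
    gamma: list[float]
    eta: list[float]
    pleiotropy: list[float]
    pleiotropic_snps: list[str]
    config: dict = field(default_factory=dict)


def _positions(cfg: SimConfig) -> list[tuple[str, int]]:
    """Chromosome/position layout: LD blocks packed within one clumping
    window, independent loci separated beyond it."""
    out: list[tuple[str, int]] = []
    blocks = cfg.ld_blocks or [(1, 1.0)] * cfg.n_snps
    total = sum(size for size, _ in blocks)
    if total != cfg.n_snps:
        raise ValueError(
            f"ld_blocks sizes sum to {total}, expected n_snps = {cfg.n_snps}"
        )
    locus = 0
    for size, _ in blocks:
        chrom = str(locus % 22 + 1)
        base = 1_000_000 + (locus // 22) * _LOCUS_SPACING_BP
        for k in range(size):
            out.append((chrom, base + 10_000 * k))
        locus += 1
    return out


def _dataset(
    cfg: SimConfig,
    name: str,
    trait_type: str,
    true_beta: np.ndarray,
    se: float,
    n: int,
    eafs: np.ndarray,
    alleles: list[tuple[str, str]],
    positions: list[tuple[str, int]],
    rng: np.random.Generator,
) -> SummaryDataset:
    obs = rng.normal(true_beta, se)
    z = obs / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    records = [
        AssociationRecord(
            snp_id=f"rs{j + 1}",
            chrom=positions[j][0],
            pos=positions[j][1],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            beta=float(obs[j]),
            se=se,
            pvalue=float(max(pvals[j], 1e-300)),
            eaf=float(eafs[j]),
            n=n,
        )
        for j in range(cfg.n_snps)
    ]
    return SummaryDataset(name, trait_type, records)


def simulate_summary(
    cfg: SimConfig,
) -> tuple[SummaryDataset, list[SummaryDataset], SummaryDataset, SimTruth, LdPanel]:
    """Generate the (exposure, [mediator], outcome) trio plus truth and LD.

    Deterministic: the same config (including seed) reproduces the datasets
    bitwise.
    """
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps

    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=j)
    eta = rng.normal(0.0, cfg.mediator_gamma_sd, size=j)
    pleio = np.zeros(j)
    n_pleio = int(round(cfg.pleiotropy_frac * j))
    pleio_idx = rng.choice(j, size=n_pleio, replace=False) if n_pleio else np.array([], int)
    if n_pleio:
        pleio[pleio_idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_pleio)

    bm_true = cfg.alpha * gamma + eta
    # Pleiotropy acts in the exposure-increasing orientation (the frame MR
    # estimators analyse after instrument orientation), so a non-zero mean
    # is genuinely directed rather than cancelling across allele codings.
    by_true = (
        cfg.theta_direct * gamma
        + cfg.theta_mediator * bm_true
        + pleio * np.sign(gamma)
    )

    eafs = rng.uniform(0.05, 0.95, size=j)
    alleles = [_ALLELE_PAIRS[int(rng.integers(len(_ALLELE_PAIRS)))] for _ in range(j)]
    positions = _positions(cfg)

    exposure = _dataset(
        cfg, cfg.exposure_name, "continuous", gamma, cfg.se_x, cfg.n_x,
        eafs, alleles, positions, rng,
    )
    mediator = _dataset(
        cfg, cfg.mediator_name, "continuous", bm_true, cfg.se_m, cfg.n_m,
        eafs, alleles, positions, rng,
    )
    outcome = _dataset(
        cfg, cfg.outcome_name, "binary", by_true, cfg.se_y, cfg.n_y,
        eafs, alleles, positions, rng,
    )

    panel = LdPanel(window_bp=10_000_000)
    blocks = cfg.ld_blocks or [(1, 1.0)] * j
    idx = 0
    snp_of = lambda i: f"rs{i + 1}"
    for size, r2 in blocks:
        members = list(range(idx, idx + size))
        for a in members:
            for b in members:
                if a < b:
                    panel.set_r2(snp_of(a), snp_of(b), r2)
        idx += size
    # Cross-locus independence within the panel's window is explicit zero.
    # Loci are laid out farther apart than the clumping window, so only
    # within-block pairs need storing.

    theta_total = cfg.theta_direct + cfg.theta_mediator * cfg.alpha
    or_total = math.exp(theta_total)
    or_direct = math.exp(cfg.theta_direct)
    perm_log = (
        100.0 * cfg.theta_mediator * cfg.alpha / theta_total if theta_total != 0 else float("nan")
    )
    perm_or = (
        100.0 * (or_total - or_direct) / (or_total - 1.0) if or_total != 1.0 else float("nan")
    )
    truth = SimTruth(
        alpha=cfg.alpha,
        theta_direct=cfg.theta_direct,
        theta_mediator=cfg.theta_mediator,
        theta_total=theta_total,
        or_total=or_total,
        or_direct=or_direct,
        perm_log=perm_log,
        perm_or=perm_or,
        gamma=gamma.tolist(),
        eta=eta.tolist(),
        pleiotropy=pleio.tolist(),
        pleiotropic_snps=[snp_of(i) for i in sorted(pleio_idx.tolist())],
        config=asdict(cfg),
    )
    return exposure, [mediator], outcome, truth, panel


def simulate_region_pair(
    n_snps: int,
    shared: bool,
    seed: int,
    causal_z: float = 10.0,
    se_1: float = 0.01,
    se_2: float = 0.01,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    region_tag: str = "r",
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """One colocalization region for two traits.

    One SNP is causal with |z| ≈ ``causal_z`` for trait 1; when ``shared``
    the same SNP is causal for trait 2, otherwise trait 2 is null
    everywhere. Non-causal SNPs carry pure noise (z ~ N(0, 1)). Returns the
    per-trait association records over the region's shared SNP panel.
    """
    rng = np.random.default_rng(seed)
    causal = int(rng.integers(n_snps))
    z1 = rng.normal(0.0, 1.0, size=n_snps)
    z2 = rng.normal(0.0, 1.0, size=n_snps)
    sign = rng.choice([-1.0, 1.0])
    z1[causal] += sign * causal_z
    if shared:
        z2[causal] += sign * causal_z

    def build(zs: np.ndarray, se: float) -> list[AssociationRecord]:
        out = []
        for k in range(n_snps):
            beta = float(zs[k] * se)
            p = float(max(2.0 * stats.norm.sf(abs(zs[k])), 1e-300))
            out.append(
                AssociationRecord(
                    snp_id=f"{region_tag}_snp{k + 1}",
                    chrom=chrom,
                    pos=start_pos + 5_000 * k,
                    effect_allele="A",
                    other_allele="G",
                    beta=beta,
                    se=se,
                    pvalue=p,
                    eaf=0.3,
                )
            )
        return out

    return build(z1, se_1), build(z2, se_2)


def write_fixture_trio(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Emit the trio, LD panel and truth JSON in the reader's TSV dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, mediators, outcome, truth, panel = simulate_summary(cfg)
    paths = {}
    for ds in [exposure, *mediators, outcome]:
        p = outdir / f"{ds.trait_name}.tsv"
        write_sumstats(ds, p)
        paths[ds.trait_name] = p
    ld_path = outdir / "ld_panel.tsv"
    write_ld_panel(panel, ld_path)
    paths["ld"] = ld_path
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=1))
    paths["truth"] = truth_path
    return paths
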