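"""MR-PRESSO: pleiotropy residual sum of squares and outlier detection.

Three simulation-based tests on a single-exposure harmonized set:

* **global test** — the observed leave-one-out weighted residual sum of
  squares is ranked against a null distribution simulated from the
  no-pleiotropy model (both exposure and outcome effects re-drawn from
  their sampling normals); p < 0.05 signals horizontal pleiotropy.
* **outlier test** — each SNP's observed weighted squared residual is
  ranked against its own simulated distribution; Bonferroni-adjusted
  p-values below the significance level flag the SNP as an outlier.
* **distortion test** — compares the raw IVW estimate with the
  outlier-corrected one against the distortion expected from removing
  equally many randomly chosen SNPs.

Deterministic given (inputs, seed): same seed reproduces the result bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateSetError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet
from .univariable import MrEstimate, ivw


@dataclass
class PressoResult:
    rss_obs: float
    global_p: float
    outlier_p: dict[str, float]
    outliers: list[str]
    beta_raw: float
    beta_corrected: float | None
    distortion_p: float | None
    n_sim: int
    seed: int
    raw: MrEstimate = field(repr=False, default=None)
    corrected: MrEstimate | None = field(repr=False, default=None)


def _loo_betas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """IVW slope excluding each SNP in turn, via sum updates (O(J))."""
    w = bx**2 / sy**2
    num = bx * by / sy**2
    s_num, s_den = num.sum(), w.sum()
    return (s_num - num) / (s_den - w)


def _weighted_loo_residuals(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> np.ndarray:
    beta_loo = _loo_betas(bx, by, sy)
    return (by - beta_loo * bx) ** 2 / sy**2


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_sig: float = 0.05,
) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    Rank p-values use the add-one convention p = (1 + #{sim ≥ obs}) /
    (n_sim + 1), so p never reaches zero. Outlier p-values are Bonferroni
    adjusted over the J instruments; note the adjusted p cannot fall below
    J/(n_sim + 1), so detecting outliers at level ``outlier_sig`` needs
    n_sim > J/outlier_sig. The corrected estimate is IVW on the
    non-outlier SNPs; the distortion p is two-sided against the distortion
    obtained by removing random same-size SNP subsets.
    """
    if h.n_snp < 4:
        raise InsufficientInstrumentsError(
            f"presso requires at least 4 instruments, got {h.n_snp}"
        )
    bx, sx, by, sy = h.single()
    j = h.n_snp
    rng = np.random.default_rng(seed)

    obs_res = _weighted_loo_residuals(bx, by, sy)
    rss_obs = float(obs_res.sum())
    beta_loo = _loo_betas(bx, by, sy)

    # Null: re-draw both sides from their sampling distributions around the
    # leave-one-out fitted values (exposure around its observed effect).
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(beta_loo * bx, sy, size=(n_sim, j))
    w_sim = bx_sim**2 / sy**2
    num_sim = bx_sim * by_sim / sy**2
    loo_sim = (num_sim.sum(axis=1, keepdims=True) - num_sim) / (
        w_sim.sum(axis=1, keepdims=True) - w_sim
    )
    res_sim = (by_sim - loo_sim * bx_sim) ** 2 / sy**2
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_raw = (1 + (res_sim >= obs_res).sum(axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * j)
    outlier_p = {s: float(p) for s, p in zip(h.snp_ids, p_adj)}
    out_mask = p_adj < outlier_sig
    outliers = [s for s, m in zip(h.snp_ids, out_mask) if m]

    raw_est, _ = ivw(h)
    if out_mask.all():
        raise DegenerateSetError("every instrument flagged as a PRESSO outlier")

    corrected = None
    distortion_p = None
    if outliers:
        keep = np.flatnonzero(~out_mask)
        corrected, _ = ivw(h.subset(keep))
        d_obs = 100.0 * (raw_est.beta - corrected.beta) / abs(corrected.beta)
        n_out = int(out_mask.sum())
        d_null = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            mask = np.ones(j, bool)
            mask[drop] = False
            b = float(
                np.sum(bx[mask] * by[mask] / sy[mask] ** 2)
                / np.sum(bx[mask] ** 2 / sy[mask] ** 2)
            )
            d_null[i] = 100.0 * (raw_est.beta - b) / abs(b) if b != 0 else np.inf
        distortion_p = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
        )

    return PressoResult(
        rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        beta_raw=raw_est.beta,
        beta_corrected=None if corrected is None else corrected.beta,
        distortion_p=distortion_p,
        n_sim=n_sim,
        seed=seed,
        raw=raw_est,
        corrected=corrected,
    )
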