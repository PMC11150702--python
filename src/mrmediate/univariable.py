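"""Univariable two-sample MR estimators and diagnostics.

The primary estimator is inverse-variance weighting (IVW): the weighted
average of per-SNP Wald ratios, equivalently a zero-intercept weighted
regression of outcome effects on exposure effects with weights 1/se_y².
Alternative estimators with weaker identifying assumptions (MR-Egger,
weighted median, mode-based) and the Cochran Q heterogeneity statistic and
leave-one-out analysis support sensitivity analysis.

All effects are on the additive scale (log odds for binary outcomes); odds
ratios are exponentiated at the reporting boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError
from .harmonize import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MrEstimate:
    """One estimator's causal-effect estimate.

    ``beta``/``se`` are on the log-odds (or linear) scale; ``or_`` fields
    are the exponentiated mirror used when the outcome is binary.
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    df: int | None = None  # t reference when set, normal otherwise

    def __post_init__(self):
        crit = Z95 if self.df is None else stats.t.ppf(0.975, self.df)
        self.ci_low = self.beta - crit * self.se
        self.ci_high = self.beta + crit * self.se

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_ci_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass
class HeterogeneityResult:
    """Cochran Q heterogeneity test for the per-SNP ratio estimates."""

    q: float
    df: int
    pvalue: float


@dataclass
class LooEntry:
    """One leave-one-out re-estimate and its influence flag."""

    snp_id: str
    estimate: MrEstimate
    flagged: bool


def _require(h: HarmonizedSet, j_min: int, what: str) -> None:
    if h.n_snp < j_min:
        raise InsufficientInstrumentsError(
            f"{what} requires at least {j_min} instruments, got {h.n_snp}"
        )


def _normal_p(beta: float, se: float) -> float:
    return 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float("nan")


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MrEstimate:
    """Single-SNP causal estimate by/bx.

    First-order standard error sy/|bx|: the exposure-side uncertainty is
    ignored, the usual approximation when the instrument is strong.
    """
    if bx == 0:
        raise UndefinedRatioError("wald_ratio undefined for bx = 0")
    beta = by / bx
    se = sy / abs(bx)
    return MrEstimate("wald_ratio", beta, se, _normal_p(beta, se), n_snp=1)


def cochran_q(bx, by, sy, beta: float) -> float:
    """Weighted sum of squared ratio residuals around ``beta``."""
    bx = np.asarray(bx, float)
    w = bx**2 / np.asarray(sy, float) ** 2
    return float(np.sum(w * (np.asarray(by, float) / bx - beta) ** 2))


def ivw(
    h: HarmonizedSet, model: str = "auto"
) -> tuple[MrEstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with Cochran Q.

    ``model``: ``"fixed"`` uses the fixed-effect SE; ``"multiplicative_random"``
    inflates it by sqrt(max(1, Q/df)); ``"auto"`` (default) applies the
    inflation only when Q/df > 1.
    """
    _require(h, 1, "ivw")
    bx, sx, by, sy = h.single()
    j = h.n_snp
    if j == 1:
        est = wald_ratio(bx[0], sx[0], by[0], sy[0])
        return est, HeterogeneityResult(0.0, 0, float("nan"))
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    q = cochran_q(bx, by, sy, beta)
    df = j - 1
    q_p = float(stats.chi2.sf(q, df))
    scale = math.sqrt(max(1.0, q / df))
    if model == "multiplicative_random" or (model == "auto" and q / df > 1.0):
        se *= scale
    elif model not in ("fixed", "auto"):
        raise ValueError(f"unknown ivw model {model!r}")
    est = MrEstimate("ivw", beta, se, _normal_p(beta, se), n_snp=j)
    return est, HeterogeneityResult(q, df, q_p)


def egger(
    h: HarmonizedSet,
) -> tuple[MrEstimate, MrEstimate, HeterogeneityResult]:
    """MR-Egger regression: slope (causal effect) and pleiotropy intercept.

    Weighted regression of by on bx *with* intercept, weights 1/sy², after
    orienting every instrument to a positive exposure effect. The intercept
    estimates the average directional pleiotropy; p < 0.05 on the intercept
    flags horizontal pleiotropy. Inference uses t with J − 2 df and
    multiplicative overdispersion scaling sqrt(max(1, Q/df)).
    """
    _require(h, 3, "egger")
    bx, sx, by, sy = h.single()
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    # Closed-form weighted normal equations for [intercept, slope].
    sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = sw * swx2 - swx**2
    a = (swx2 * swy - swx * swxy) / det
    b = (sw * swxy - swx * swy) / det
    resid = y - a - b * x
    j = h.n_snp
    df = j - 2
    q = float(np.sum(w * resid**2))
    scale2 = max(1.0, q / df)
    var_a = swx2 / det * scale2
    var_b = sw / det * scale2
    se_a, se_b = math.sqrt(var_a), math.sqrt(var_b)
    p_a = 2.0 * stats.t.sf(abs(a) / se_a, df)
    p_b = 2.0 * stats.t.sf(abs(b) / se_b, df)
    slope = MrEstimate("egger_slope", float(b), se_b, float(p_b), n_snp=j, df=df)
    intercept = MrEstimate(
        "egger_intercept", float(a), se_a, float(p_a), n_snp=j, df=df
    )
    het = HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))
    return slope, intercept, het


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with cumulative-weight interpolation."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _ratio_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    bx, sx, by, sy = h.single()
    return by / bx, bx**2 / sy**2


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median estimator, consistent when valid instruments carry
    more than half the weight; SE by parametric bootstrap."""
    _require(h, 3, "weighted_median")
    bx, sx, by, sy = h.single()
    ratios, w = _ratio_weights(h)
    beta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    j = h.n_snp
    boots = np.empty(n_boot)
    bx_s = rng.normal(bx, sx, size=(n_boot, j))
    by_s = rng.normal(by, sy, size=(n_boot, j))
    for i in range(n_boot):
        bxi = np.where(bx_s[i] == 0, np.finfo(float).tiny, bx_s[i])
        boots[i] = _weighted_median(by_s[i] / bxi, bxi**2 / sy**2)
    se = float(boots.std(ddof=1))
    return MrEstimate("weighted_median", beta, se, _normal_p(beta, se), n_snp=j)


def _mad_bandwidth(ratios: np.ndarray, factor: float) -> float:
    """Modified Silverman rule on the ratio scale, MAD-based for robustness."""
    s = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    if s == 0:
        s = float(np.std(ratios)) or 1e-6
    return factor * 0.9 * s * len(ratios) ** (-0.2)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth: float) -> float:
    w = weights / weights.sum()
    lo, hi = ratios.min() - 3 * bandwidth, ratios.max() + 3 * bandwidth
    grid = np.unique(np.concatenate([np.linspace(lo, hi, 2048), ratios]))
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bandwidth) ** 2)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimators(
    h: HarmonizedSet,
    mode: str = "weighted",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    """Mode-based estimator: the kernel-density mode of per-SNP ratios.

    Consistent when the largest group of instruments sharing a ratio is
    valid (ZEMPA). ``mode="weighted"`` weights each kernel by the inverse-
    variance weight; ``"simple"`` weights equally. The normal-kernel
    bandwidth is ``bandwidth_factor`` times a MAD-based Silverman rule.
    """
    _require(h, 3, "mode_estimators")
    if mode not in ("weighted", "simple"):
        raise ValueError(f"unknown mode {mode!r}")
    bx, sx, by, sy = h.single()
    ratios, ivw_w = _ratio_weights(h)
    weights = ivw_w if mode == "weighted" else np.ones_like(ratios)
    bw = _mad_bandwidth(ratios, bandwidth_factor)
    beta = _kde_mode(ratios, weights, bw)
    rng = np.random.default_rng(seed)
    j = h.n_snp
    boots = np.empty(n_boot)
    bx_s = rng.normal(bx, sx, size=(n_boot, j))
    by_s = rng.normal(by, sy, size=(n_boot, j))
    for i in range(n_boot):
        bxi = np.where(bx_s[i] == 0, np.finfo(float).tiny, bx_s[i])
        r = by_s[i] / bxi
        wgt = bxi**2 / sy**2 if mode == "weighted" else np.ones(j)
        boots[i] = _kde_mode(r, wgt, _mad_bandwidth(r, bandwidth_factor))
    se = float(boots.std(ddof=1))
    method = "weighted_mode" if mode == "weighted" else "simple_mode"
    return MrEstimate(method, beta, se, _normal_p(beta, se), n_snp=j)


def leave_one_out(h: HarmonizedSet, model: str = "auto") -> list[LooEntry]:
    """IVW re-estimates omitting each SNP in turn.

    An omission is flagged when the re-estimate changes sign relative to
    the full-set estimate, or when dropping the SNP moves a significant
    full-set result across the null (the reduced CI includes 0 while the
    full CI does not).
    """
    _require(h, 3, "leave_one_out")
    full, _ = ivw(h, model=model)
    full_sig = full.ci_low > 0 or full.ci_high < 0
    out: list[LooEntry] = []
    for i, snp in enumerate(h.snp_ids):
        est, _ = ivw(h.subset([k for k in range(h.n_snp) if k != i]), model=model)
        sign_change = np.sign(est.beta) != np.sign(full.beta) and est.beta != 0
        crosses_null = full_sig and (est.ci_low <= 0 <= est.ci_high)
        out.append(LooEntry(snp, est, bool(sign_change or crosses_null)))
    return out
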