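"""Multivariable MR: joint direct effects of several exposures on one outcome.

Zero-intercept weighted regression of per-SNP outcome effects on the J×K
matrix of exposure effects, weights 1/se_y². Each coefficient is the direct
effect of its exposure conditional on the others — the quantity a mediation
analysis adjusts the total effect by.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, IdentifiabilityError
from .harmonize import HarmonizedSet
from .univariable import HeterogeneityResult, MrEstimate, _normal_p


@dataclass
class MvmrResult:
    """Per-exposure direct effects plus instrument-strength diagnostics."""

    estimates: list[MrEstimate]
    exposures: list[str]
    conditional_f: dict[str, float]
    het: HeterogeneityResult

    def __getitem__(self, exposure: str) -> MrEstimate:
        return self.estimates[self.exposures.index(exposure)]


def _conditional_f(h: HarmonizedSet, w: np.ndarray, k: int) -> float:
    """Residual-based conditional instrument-strength approximation.

    Regress exposure k's effects on the other exposures' effects (weights
    w); the mean residual chi-square against that exposure's standard
    errors approximates the conditional F-statistic.
    """
    x_k = h.beta_x[:, k]
    others = np.delete(h.beta_x, k, axis=1)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(others * sw[:, None], x_k * sw, rcond=None)
    resid = x_k - others @ coef
    j, kk = h.beta_x.shape
    return float(np.sum(resid**2 / h.se_x[:, k] ** 2) / (j - kk + 1))


def mvmr_ivw(h: HarmonizedSet, overdispersion: str = "auto") -> MvmrResult:
    """Multivariable IVW regression.

    ``overdispersion``: ``"auto"`` scales SEs by sqrt(max(1, Q/(J−K)));
    ``"fixed"`` never scales.

    Raises
    ------
    IdentifiabilityError
        When J ≤ K (fewer instruments than exposures plus one).
    CollinearityError
        When the exposure-effect matrix is rank deficient.
    """
    x = h.beta_x
    y = h.beta_y
    j, k = x.shape
    if k < 2:
        raise ValueError("mvmr_ivw requires K >= 2 exposures; use ivw for K = 1")
    if j <= k:
        raise IdentifiabilityError(
            f"MVMR needs J >= K + 1 instruments (J={j}, K={k})"
        )
    # An identically-zero column carries no identifying variation at all:
    # estimate on the remaining columns and report a null placeholder for
    # it, rather than failing the whole fit.
    zero_cols = [c for c in range(k) if np.all(x[:, c] == 0)]
    if zero_cols and k - len(zero_cols) >= 1:
        keep = [c for c in range(k) if c not in zero_cols]
        if len(keep) == 1:
            from .univariable import ivw as _ivw

            sub = HarmonizedSet(
                exposures=[h.exposures[keep[0]]],
                outcome=h.outcome,
                snp_ids=list(h.snp_ids),
                beta_x=x[:, keep],
                se_x=h.se_x[:, keep],
                beta_y=y,
                se_y=h.se_y,
            )
            est, het = _ivw(sub, model="fixed" if overdispersion == "fixed" else "auto")
            estimates = []
            for c in range(k):
                if c in zero_cols:
                    estimates.append(
                        MrEstimate("mvmr_ivw", 0.0, float("inf"), 1.0, n_snp=j)
                    )
                else:
                    estimates.append(est)
            cond_f = {h.exposures[c]: float("nan") for c in range(k)}
            return MvmrResult(estimates, list(h.exposures), cond_f, het)
        sub = HarmonizedSet(
            exposures=[h.exposures[c] for c in keep],
            outcome=h.outcome,
            snp_ids=list(h.snp_ids),
            beta_x=x[:, keep],
            se_x=h.se_x[:, keep],
            beta_y=y,
            se_y=h.se_y,
        )
        reduced = mvmr_ivw(sub, overdispersion=overdispersion)
        estimates, cond_f = [], {}
        for c in range(k):
            if c in zero_cols:
                estimates.append(MrEstimate("mvmr_ivw", 0.0, float("inf"), 1.0, n_snp=j))
                cond_f[h.exposures[c]] = float("nan")
            else:
                est = reduced[h.exposures[c]]
                estimates.append(est)
                cond_f[h.exposures[c]] = reduced.conditional_f[h.exposures[c]]
        return MvmrResult(estimates, list(h.exposures), cond_f, reduced.het)

    rank = np.linalg.matrix_rank(x)
    if rank < k:
        # name the offending exposures: columns whose removal restores rank
        bad = [
            h.exposures[c]
            for c in range(k)
            if np.linalg.matrix_rank(np.delete(x, c, axis=1)) == rank
        ]
        raise CollinearityError(
            f"exposure-effect matrix rank deficient; involved exposures: {bad}"
        )
    w = 1.0 / h.se_y**2
    xtw = x.T * w
    a = xtw @ x
    beta = np.linalg.solve(a, xtw @ y)
    resid = y - x @ beta
    q = float(np.sum(w * resid**2))
    df = j - k
    phi = max(1.0, q / df) if overdispersion == "auto" else 1.0
    cov = np.linalg.inv(a) * phi
    ses = np.sqrt(np.diag(cov))
    estimates = [
        MrEstimate("mvmr_ivw", float(b), float(s), _normal_p(float(b), float(s)), n_snp=j)
        for b, s in zip(beta, ses)
    ]
    cond_f = {
        h.exposures[c]: _conditional_f(h, w, c) for c in range(k)
    }
    het = HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))
    return MvmrResult(estimates, list(h.exposures), cond_f, het)
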