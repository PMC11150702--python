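"""Mediator screening and the percentage of excess risk mediated (PERM).

A candidate mediates the exposure→outcome relation when it is causally
downstream of the exposure *and* causally upstream of the outcome; the
screen keeps candidates whose univariable MR is significant in both
directions. For a retained mediator set, the mediated share of the excess
risk is

    PERM = 100 × (OR_total − OR_adjusted) / (OR_total − 1)

where OR_total is the unadjusted exposure→outcome odds ratio and
OR_adjusted the multivariable-MR direct effect after conditioning on the
mediators. The formula presumes a harmful exposure (OR_total > 1); callers
with a protective exposure must re-orient it first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .exceptions import OrientationError
from .univariable import MrEstimate


@dataclass
class ScreenEntry:
    candidate: str
    exposure_to_mediator_p: float | None
    mediator_to_outcome_p: float | None
    exposure_to_mediator_sig: bool | None
    mediator_to_outcome_sig: bool | None
    status: str  # retained | excluded | untested


@dataclass
class MediationResult:
    mediator_set: list[str]
    or_total: float
    or_adjusted: float
    perm_pct: float
    adjusted_ci: tuple[float, float] | None = None
    attenuated_to_null: bool | None = None
    screen_table: list[ScreenEntry] = field(default_factory=list)


def perm(or_total: float, or_adjusted: float) -> float:
    """Percentage of excess risk mediated, unrounded.

    Raises :class:`OrientationError` when ``or_total`` ≤ 1 (no excess risk
    to apportion); warns without capping when the adjusted OR is protective,
    which yields PERM > 100%.
    """
    if or_total <= 1.0:
        raise OrientationError(
            "PERM requires OR_total > 1; re-orient the exposure so the total "
            "effect is harmful"
        )
    if or_adjusted < 1.0:
        warnings.warn(
            "adjusted OR < 1: PERM exceeds 100% and is reported uncapped",
            stacklevel=2,
        )
    return 100.0 * (or_total - or_adjusted) / (or_total - 1.0)


def screen_mediators(
    uni_results: pd.DataFrame,
    exposure: str,
    outcome: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
) -> list[ScreenEntry]:
    """Screen candidates for causal association with both exposure and outcome.

    ``uni_results`` must contain columns ``exposure``, ``outcome``,
    ``pvalue`` with one row per univariable contrast. A candidate is
    retained when exposure→candidate and candidate→outcome p-values are
    both below ``alpha``; a candidate missing either contrast is marked
    ``"untested"`` rather than silently excluded. No multiplicity
    correction is applied across candidates.
    """
    entries: list[ScreenEntry] = []
    for cand in candidates:
        fwd = uni_results[
            (uni_results["exposure"] == exposure) & (uni_results["outcome"] == cand)
        ]
        rev = uni_results[
            (uni_results["exposure"] == cand) & (uni_results["outcome"] == outcome)
        ]
        p_fwd = float(fwd["pvalue"].iloc[0]) if len(fwd) else None
        p_rev = float(rev["pvalue"].iloc[0]) if len(rev) else None
        sig_fwd = None if p_fwd is None else p_fwd < alpha
        sig_rev = None if p_rev is None else p_rev < alpha
        if p_fwd is None or p_rev is None:
            status = "untested"
        elif sig_fwd and sig_rev:
            status = "retained"
        else:
            status = "excluded"
        entries.append(ScreenEntry(cand, p_fwd, p_rev, sig_fwd, sig_rev, status))
    return entries


def retained(entries: Sequence[ScreenEntry]) -> list[str]:
    return [e.candidate for e in entries if e.status == "retained"]


def mediation_report(
    total: MrEstimate,
    adjusted: Mapping[tuple[str, ...], MrEstimate],
    screen_table: Sequence[ScreenEntry] = (),
) -> list[MediationResult]:
    """One MediationResult per adjustment set.

    ``total`` is the unadjusted exposure→outcome estimate; ``adjusted``
    maps each adjustment set (tuple of mediator names) to the exposure's
    direct-effect estimate from the corresponding multivariable model. A
    set is flagged ``attenuated_to_null`` when its adjusted 95% CI includes
    OR = 1.
    """
    results = []
    for med_set, est in adjusted.items():
        results.append(
            MediationResult(
                mediator_set=list(med_set),
                or_total=total.or_,
                or_adjusted=est.or_,
                perm_pct=perm(total.or_, est.or_),
                adjusted_ci=(est.or_ci_low, est.or_ci_high),
                attenuated_to_null=est.or_ci_low <= 1.0 <= est.or_ci_high,
                screen_table=list(screen_table),
            )
        )
    return results


def report_frame(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Tabular mediation report; PERM rounded to 2 decimals here only."""
    rows = [
        {
            "adjustment_set": "+".join(r.mediator_set),
            "or_total": r.or_total,
            "or_adjusted": r.or_adjusted,
            "or_adj_ci_low": None if r.adjusted_ci is None else r.adjusted_ci[0],
            "or_adj_ci_high": None if r.adjusted_ci is None else r.adjusted_ci[1],
            "perm_pct": round(r.perm_pct, 2),
            "attenuated_to_null": r.attenuated_to_null,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "adjustment_set",
            "or_total",
            "or_adjusted",
            "or_adj_ci_low",
            "or_adj_ci_high",
            "perm_pct",
            "attenuated_to_null",
        ],
    )
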