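"""Colocalization by approximate Bayes factors under one causal variant.

For each instrument, a region of ±500 kb is examined. Within a region the
per-SNP evidence for association with each trait is the Wakefield
approximate Bayes factor computed from (beta, se) and a prior effect
standard deviation; the five single-causal-variant hypotheses

    H0 no association, H1 trait-1 only, H2 trait-2 only,
    H3 two distinct causal variants, H4 one shared causal variant

are enumerated, weighted by per-SNP priors (p1, p2, p12), and normalized
into posterior probabilities PPH0..PPH4. The study-level call averages
PPH4 across regions; a mean above 0.75 is taken as evidence of a shared
causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import NoEvaluableRegionError
from .sumstats import AssociationRecord, SummaryDataset

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
SD_PRIOR_CONTINUOUS = 0.15
SD_PRIOR_BINARY = 0.2
PPH4_SHARED_RULE = 0.75
COLOC_HALF_WINDOW_BP = 500_000


@dataclass
class Region:
    region_id: str
    chrom: str | None
    start: int
    end: int


@dataclass
class RegionSummary:
    region_id: str
    snp_ids: list[str]
    log_abf_1: np.ndarray
    log_abf_2: np.ndarray
    pph: np.ndarray  # PPH0..PPH4

    @property
    def pph4(self) -> float:
        return float(self.pph[4])


@dataclass
class ColocResult:
    regions: list[RegionSummary]
    skipped: list[tuple[str, str]]
    mean_pph4: float
    shared_flag: bool

    def region_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region_id": r.region_id,
                "n_snps": len(r.snp_ids),
                **{f"PPH{i}": r.pph[i] for i in range(5)},
            }
            for r in self.regions
        ]
        return pd.DataFrame(
            rows, columns=["region_id", "n_snps"] + [f"PPH{i}" for i in range(5)]
        )


def make_regions(
    instruments: SummaryDataset, half_window_bp: int = COLOC_HALF_WINDOW_BP
) -> tuple[list[Region], list[tuple[str, str]]]:
    """One closed interval [pos − hw, pos + hw] per instrument.

    Overlapping intervals are kept separate — one region per instrument.
    Instruments without a position are skipped with an audit entry.
    """
    regions, skipped = [], []
    for rec in instruments:
        if rec.pos is None:
            skipped.append((rec.snp_id, "no_position"))
            continue
        regions.append(
            Region(rec.snp_id, rec.chrom, max(0, rec.pos - half_window_bp), rec.pos + half_window_bp)
        )
    return regions, skipped


def wakefield_log_abf(beta: float, se: float, sd_prior: float) -> float:
    """Log approximate Bayes factor for one SNP-trait association."""
    r = sd_prior**2 / (sd_prior**2 + se**2)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z * z


def coloc_abf(
    region_records_1: Sequence[AssociationRecord],
    region_records_2: Sequence[AssociationRecord],
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    sd_prior_1: float = SD_PRIOR_CONTINUOUS,
    sd_prior_2: float = SD_PRIOR_BINARY,
    region_id: str = "",
) -> RegionSummary | None:
    """Posterior hypothesis probabilities for one region.

    Records are intersected on shared SNP ids; records with a non-finite z
    are dropped. Returns None when no shared SNP remains (caller audits the
    skip). Hypothesis sums are accumulated in log space with log-sum-exp.
    """
    by_id_2 = {r.snp_id: r for r in region_records_2}
    pairs = [
        (r1, by_id_2[r1.snp_id])
        for r1 in region_records_1
        if r1.snp_id in by_id_2
    ]
    pairs = [
        (a, b)
        for a, b in pairs
        if np.isfinite(a.beta / a.se) and np.isfinite(b.beta / b.se)
    ]
    if not pairs:
        return None
    snp_ids = [a.snp_id for a, _ in pairs]
    l1 = np.array([wakefield_log_abf(a.beta, a.se, sd_prior_1) for a, _ in pairs])
    l2 = np.array([wakefield_log_abf(b.beta, b.se, sd_prior_2) for _, b in pairs])

    p1, p2, p12 = priors
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # H3: sum over ordered distinct pairs = (Σ1)(Σ2) − Σ same-SNP products.
    both = s1 + s2
    if len(pairs) > 1 and s12 < both:
        h3_core = both + np.log1p(-np.exp(s12 - both))
    else:
        h3_core = -np.inf
    log_h = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + h3_core,
            np.log(p12) + s12,
        ]
    )
    pph = np.exp(log_h - logsumexp(log_h))
    return RegionSummary(region_id, snp_ids, l1, l2, pph)


def _records_in(ds: SummaryDataset, region: Region) -> list[AssociationRecord]:
    return [
        r
        for r in ds
        if r.pos is not None
        and (region.chrom is None or r.chrom == region.chrom)
        and region.start <= r.pos <= region.end
    ]


def coloc_pipeline(
    trait1: SummaryDataset,
    trait2: SummaryDataset,
    instruments: SummaryDataset,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    sd_prior_1: float | None = None,
    sd_prior_2: float | None = None,
    half_window_bp: int = COLOC_HALF_WINDOW_BP,
    shared_rule: float = PPH4_SHARED_RULE,
) -> ColocResult:
    """Colocalize a trait pair across all instrument-centred regions.

    The study-level summary is the unweighted arithmetic mean of region
    PPH4 values; ``shared_flag`` is True when the mean exceeds the 75%
    rule. Raises when every region is skipped.
    """

    def default_sd(ds: SummaryDataset) -> float:
        return SD_PRIOR_BINARY if ds.trait_type == "binary" else SD_PRIOR_CONTINUOUS

    sd1 = default_sd(trait1) if sd_prior_1 is None else sd_prior_1
    sd2 = default_sd(trait2) if sd_prior_2 is None else sd_prior_2
    regions, skipped = make_regions(instruments, half_window_bp)
    summaries: list[RegionSummary] = []
    for region in regions:
        summary = coloc_abf(
            _records_in(trait1, region),
            _records_in(trait2, region),
            priors=priors,
            sd_prior_1=sd1,
            sd_prior_2=sd2,
            region_id=region.region_id,
        )
        if summary is None:
            skipped.append((region.region_id, "no_shared_snps"))
        else:
            summaries.append(summary)
    if not summaries:
        raise NoEvaluableRegionError(
            f"no evaluable region for {trait1.trait_name} vs {trait2.trait_name}"
        )
    mean_pph4 = float(np.mean([s.pph4 for s in summaries]))
    return ColocResult(summaries, skipped, mean_pph4, mean_pph4 > shared_rule)
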