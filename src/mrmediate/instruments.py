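"""Instrument selection: significance thresholding and greedy LD clumping.

Instruments are SNPs that pass genome-wide significance for the exposure
(default p < 5e-8) and are approximately independent: greedy clumping keeps
the strongest association and discards any remaining candidate in linkage
disequilibrium (r² above threshold, default 0.001) with an accepted SNP
within the window (default 10,000 kb). When the LD of an in-window pair is
unknown, the pair is treated as correlated — a conservative choice that
never admits a dependent pair.
"""

from __future__ import annotations

from .exceptions import NoInstrumentsError
from .sumstats import AssociationRecord, LdPanel, SummaryDataset

GWAS_P_THRESHOLD = 5e-8
CLUMP_R2 = 0.001
CLUMP_WINDOW_BP = 10_000_000


def _in_window(a: AssociationRecord, b: AssociationRecord, window_bp: int) -> bool:
    # Unplaced SNPs cannot be cleared by distance; treat them as in-window.
    if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
        return True
    return a.chrom == b.chrom and abs(a.pos - b.pos) <= window_bp


def conflicts(
    a: AssociationRecord,
    b: AssociationRecord,
    ld: LdPanel | None,
    r2_threshold: float,
    window_bp: int,
) -> bool:
    """Whether two candidates violate the independence constraint.

    A pair conflicts when it lies inside the window and its r² exceeds the
    threshold or is unknown.
    """
    if not _in_window(a, b, window_bp):
        return False
    r2 = None if ld is None else ld.r2(a.snp_id, b.snp_id)
    return r2 is None or r2 > r2_threshold


def select_instruments(
    ds: SummaryDataset,
    p_threshold: float = GWAS_P_THRESHOLD,
    ld: LdPanel | None = None,
    r2_threshold: float = CLUMP_R2,
    window_bp: int = CLUMP_WINDOW_BP,
) -> SummaryDataset:
    """Select independent genome-wide-significant instruments.

    Candidates with p < ``p_threshold`` are clumped greedily: sort by
    ascending p (ties broken by genomic position, then SNP id, for
    determinism), accept the best, discard every remaining candidate that
    conflicts with an accepted SNP, repeat. Returns accepted records in
    genomic order.

    Raises
    ------
    NoInstrumentsError
        If no SNP passes the significance threshold.
    """
    candidates = [r for r in ds if r.pvalue < p_threshold]
    if not candidates:
        raise NoInstrumentsError(ds.trait_name, p_threshold)

    def order(rec: AssociationRecord):
        return (rec.pvalue, rec.chrom or "", rec.pos or 0, rec.snp_id)

    pending = sorted(candidates, key=order)
    accepted: list[AssociationRecord] = []
    while pending:
        best = pending.pop(0)
        accepted.append(best)
        pending = [
            r for r in pending if not conflicts(best, r, ld, r2_threshold, window_bp)
        ]
    return SummaryDataset(
        ds.trait_name, ds.trait_type, accepted
    ).in_genomic_order()
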