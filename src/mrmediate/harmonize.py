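"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR combines per-SNP effects estimated in different samples, so
every trait's effect must be expressed on the same effect allele. The first
exposure dataset fixes the convention per SNP; other traits are aligned by
direct match, allele swap (sign flip), strand complement, or both.
Palindromic SNPs (A/T, C/G) cannot be resolved from alleles alone and are
either dropped or inferred from allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats import AssociationRecord, SummaryDataset

#: Half-width of the frequency band around 0.5 inside which a palindromic
#: SNP's orientation cannot be inferred from EAF.
EAF_AMBIGUITY_BAND = 0.08


@dataclass
class HarmonizedSet:
    """Instrument-aligned effects for K exposures and one outcome.

    ``beta_x``/``se_x`` are J×K arrays of exposure effects, ``beta_y``/
    ``se_y`` length-J outcome effects, all on one effect-allele convention
    per SNP. ``dropped`` audits every excluded SNP with its reason;
    ``actions`` records the per-trait alignment applied to each retained SNP.
    """

    exposures: list[str]
    outcome: str
    snp_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)
    actions: dict[str, dict[str, str]] = field(default_factory=dict)
    outcome_type: str = "binary"

    def __post_init__(self):
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, dtype=float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, dtype=float))
        if self.beta_x.shape[0] == 1 and len(self.snp_ids) != 1:
            self.beta_x = self.beta_x.T
            self.se_x = self.se_x.T
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposure(self) -> int:
        return self.beta_x.shape[1]

    def single(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """1-D views (bx, sx, by, sy) for the K = 1 case."""
        if self.n_exposure != 1:
            raise ValueError("single() requires exactly one exposure")
        return self.beta_x[:, 0], self.se_x[:, 0], self.beta_y, self.se_y

    def subset(self, keep: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HarmonizedSet(
            exposures=list(self.exposures),
            outcome=self.outcome,
            snp_ids=[self.snp_ids[i] for i in keep],
            beta_x=self.beta_x[keep],
            se_x=self.se_x[keep],
            beta_y=self.beta_y[keep],
            se_y=self.se_y[keep],
            outcome_type=self.outcome_type,
        )

    def drop_snp(self, snp_id: str) -> "HarmonizedSet":
        keep = [i for i, s in enumerate(self.snp_ids) if s != snp_id]
        return self.subset(keep)

    def audit_frame(self) -> pd.DataFrame:
        """Harmonization audit: one row per SNP with action or drop reason."""
        rows = [
            {"snp_id": s, "action": "kept", "reason": "; ".join(
                f"{t}:{a}" for t, a in self.actions.get(s, {}).items())}
            for s in self.snp_ids
        ]
        rows += [{"snp_id": s, "action": "dropped", "reason": r} for s, r in self.dropped]
        return pd.DataFrame(rows, columns=["snp_id", "action", "reason"])


def _align(
    ref: AssociationRecord,
    rec: AssociationRecord,
    palindrome_policy: str,
    band: float,
) -> tuple[AssociationRecord | None, str]:
    """Express ``rec`` on ``ref``'s effect-allele convention.

    Returns (aligned record, action tag); the record is None when the SNP
    must be dropped, with the tag carrying the reason.
    """
    ra, ro = ref.effect_allele, ref.other_allele
    if ref.is_palindromic():
        # For A/T and C/G variants 'same' and 'complement-swapped' are
        # indistinguishable; orientation must come from allele frequency.
        if palindrome_policy == "drop":
            return None, "palindromic"
        if {rec.effect_allele, rec.other_allele} != {ra, ro}:
            return None, "allele_mismatch"
        if ref.eaf is None or rec.eaf is None:
            return None, "palindromic_no_eaf"
        if abs(ref.eaf - 0.5) <= band or abs(rec.eaf - 0.5) <= band:
            return None, "palindromic_ambiguous"
        nominal = rec if rec.effect_allele == ra else rec.flipped()
        if (ref.eaf - 0.5) * (nominal.eaf - 0.5) > 0:
            return nominal, "eaf_aligned"
        return nominal.flipped(), "eaf_flipped"

    pairs = {
        (rec.effect_allele, rec.other_allele): ("same", rec),
        (rec.other_allele, rec.effect_allele): ("swapped", rec.flipped()),
    }
    comp = rec.complemented()
    pairs.setdefault((comp.effect_allele, comp.other_allele), ("complemented", comp))
    pairs.setdefault(
        (comp.other_allele, comp.effect_allele), ("comp_swapped", comp.flipped())
    )
    hit = pairs.get((ra, ro))
    if hit is None:
        return None, "allele_mismatch"
    action, aligned = hit
    return aligned, action


def harmonize(
    exposure_sets: Sequence[SummaryDataset],
    outcome_set: SummaryDataset,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: float = EAF_AMBIGUITY_BAND,
) -> HarmonizedSet:
    """Align one or more exposure datasets with an outcome dataset.

    The SNP universe is the first exposure set's instruments, in its stored
    order; a SNP missing from any other set is dropped with reason
    ``"missing"``. Allele swaps flip the effect sign and replace EAF by
    1 − EAF; strand complements are aligned after complementing. Palindromic
    SNPs follow ``palindrome_policy``: ``"drop"`` removes them, while
    ``"infer_by_eaf"`` orients by allele frequency unless either EAF falls
    inside 0.5 ± ``eaf_ambiguity_band``.
    """
    if not exposure_sets:
        raise ValueError("exposure_sets must be non-empty")
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")

    ref_set = exposure_sets[0]
    others = list(exposure_sets[1:]) + [outcome_set]
    snp_ids: list[str] = []
    rows_x: list[list[tuple[float, float]]] = []
    rows_y: list[tuple[float, float]] = []
    dropped: list[tuple[str, str]] = []
    actions: dict[str, dict[str, str]] = {}

    for ref in ref_set:
        if ref.is_palindromic() and palindrome_policy == "drop":
            dropped.append((ref.snp_id, "palindromic"))
            continue
        per_trait: list[tuple[float, float]] = [(ref.beta, ref.se)]
        acts = {ref_set.trait_name: "reference"}
        reason = None
        for ds in others:
            rec = ds.get(ref.snp_id)
            if rec is None:
                reason = f"missing:{ds.trait_name}"
                break
            aligned, action = _align(ref, rec, palindrome_policy, eaf_ambiguity_band)
            if aligned is None:
                reason = f"{action}:{ds.trait_name}"
                break
            per_trait.append((aligned.beta, aligned.se))
            acts[ds.trait_name] = action
        if reason is not None:
            dropped.append((ref.snp_id, reason))
            continue
        if any(not np.isfinite(v) for pair in per_trait for v in pair):
            dropped.append((ref.snp_id, "non_finite"))
            continue
        snp_ids.append(ref.snp_id)
        rows_x.append(per_trait[:-1])
        rows_y.append(per_trait[-1])
        actions[ref.snp_id] = acts

    k = len(exposure_sets)
    beta_x = np.array([[p[0] for p in row] for row in rows_x], dtype=float).reshape(-1, k)
    se_x = np.array([[p[1] for p in row] for row in rows_x], dtype=float).reshape(-1, k)
    beta_y = np.array([p[0] for p in rows_y], dtype=float)
    se_y = np.array([p[1] for p in rows_y], dtype=float)
    return HarmonizedSet(
        exposures=[ds.trait_name for ds in exposure_sets],
        outcome=outcome_set.trait_name,
        snp_ids=snp_ids,
        beta_x=beta_x,
        se_x=se_x,
        beta_y=beta_y,
        se_y=se_y,
        dropped=dropped,
        actions=actions,
        outcome_type=outcome_set.trait_type,
    )
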