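"""GWAS summary-statistic containers and delimited-text I/O.

A trait's summary statistics are held as a :class:`SummaryDataset` — an
ordered collection of per-SNP :class:`AssociationRecord` objects keyed by
SNP identifier. Binary-trait effects are stored as log odds ratios; readers
log-transform an odds-ratio column at load time so every downstream module
works on an additive scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Complementary base for strand flips.
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column map mirroring common GWAS summary-statistic headers.
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "eaf": "EAF",
    "n": "N",
}

_MANDATORY = ("snp_id", "effect_allele", "other_allele", "se", "pvalue")


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait
    scale (log odds for binary traits). ``eaf`` is the effect-allele
    frequency, ``n`` the sample size; both may be missing (``None``).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def is_valid(self) -> bool:
        """Whether the record satisfies the container invariants."""
        ok = (
            self.effect_allele in VALID_ALLELES
            and self.other_allele in VALID_ALLELES
            and self.effect_allele != self.other_allele
            and math.isfinite(self.beta)
            and math.isfinite(self.se)
            and self.se > 0
            and 0 < self.pvalue <= 1
        )
        if ok and self.eaf is not None:
            ok = 0 < self.eaf < 1
        return ok

    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is ambiguous."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "AssociationRecord":
        """Record re-expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def complemented(self) -> "AssociationRecord":
        """Record with both alleles mapped to the opposite strand."""
        return replace(
            self,
            effect_allele=COMPLEMENT[self.effect_allele],
            other_allele=COMPLEMENT[self.other_allele],
        )


class SummaryDataset:
    """Summary statistics for one trait, keyed by unique SNP id."""

    def __init__(
        self,
        trait_name: str,
        trait_type: str,
        records: Iterable[AssociationRecord],
        n_dropped: int = 0,
    ):
        if trait_type not in ("binary", "continuous"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'continuous', got {trait_type!r}"
            )
        self.trait_name = trait_name
        self.trait_type = trait_type
        self.n_dropped = n_dropped
        self._records: dict[str, AssociationRecord] = {}
        for rec in records:
            if rec.snp_id in self._records:
                raise DataError(
                    f"duplicate SNP id {rec.snp_id!r} in trait {trait_name!r}"
                )
            self._records[rec.snp_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self._records.values())

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._records

    def __getitem__(self, snp_id: str) -> AssociationRecord:
        return self._records[snp_id]

    def get(self, snp_id: str) -> AssociationRecord | None:
        return self._records.get(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return list(self._records)

    def subset(self, snp_ids: Iterable[str]) -> "SummaryDataset":
        return SummaryDataset(
            self.trait_name,
            self.trait_type,
            (self._records[s] for s in snp_ids),
        )

    def in_genomic_order(self) -> "SummaryDataset":
        """Records sorted by (chromosome, position); unplaced SNPs last."""

        def key(rec: AssociationRecord):
            if rec.chrom is None or rec.pos is None:
                return (1, "", 0, rec.snp_id)
            return (0, _chrom_key(rec.chrom), rec.pos, rec.snp_id)

        return SummaryDataset(
            self.trait_name, self.trait_type, sorted(self, key=key)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the bundled default column names."""
        rows = [
            {
                "SNP": r.snp_id,
                "CHR": r.chrom,
                "BP": r.pos,
                "A1": r.effect_allele,
                "A2": r.other_allele,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pvalue,
                "EAF": r.eaf,
                "N": r.n,
            }
            for r in self
        ]
        return pd.DataFrame(
            rows, columns=["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "EAF", "N"]
        )


def _chrom_key(chrom: str) -> tuple:
    c = str(chrom).removeprefix("chr")
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass
class LdPanel:
    """Pairwise LD (r-squared) lookup over a bounded window.

    Pairs absent from the panel are *unknown*, not independent; the clumping
    step treats unknown in-window pairs as correlated (conservative).
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    window_bp: int = 10_000_000

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise DataError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
        self.pairs[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float | None:
        """r² for a pair, 1.0 on the diagonal, None if unknown."""
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b))

    @classmethod
    def from_pair_table(cls, frame: pd.DataFrame, window_bp: int = 10_000_000) -> "LdPanel":
        panel = cls(window_bp=window_bp)
        for a, b, r2 in frame.itertuples(index=False):
            panel.set_r2(str(a), str(b), float(r2))
        return panel

    @classmethod
    def read(cls, path, window_bp: int = 10_000_000) -> "LdPanel":
        """Read LD as a 3-column pair list or a square matrix with header.

        A pair list has columns (snp_a, snp_b, r2); a square matrix has a
        SNP-id header row and one row per SNP.
        """
        frame = pd.read_csv(path, sep=None, engine="python")
        # A pair list has (snp_a, snp_b, r2): exactly 3 columns with a
        # non-numeric second column. Anything else is read as a square
        # matrix whose header row names the SNPs.
        if frame.shape[1] == 3 and frame.iloc[:, 1].dtype == object:
            return cls.from_pair_table(frame, window_bp=window_bp)
        if frame.shape[1] == len(frame) + 1:
            ids = [str(c) for c in frame.columns[1:]]
        else:
            ids = [str(c) for c in frame.columns]
        mat = frame.iloc[:, -len(ids):].to_numpy(dtype=float)
        if mat.shape[0] != mat.shape[1]:
            raise ConfigurationError("LD matrix is not square")
        panel = cls(window_bp=window_bp)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                panel.set_r2(a, ids[j], mat[i, j])
        return panel


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_name: str | None = None,
    effect_is_or: bool = False,
) -> SummaryDataset:
    """Read and validate a delimited summary-statistic table.

    Parameters
    ----------
    path
        TSV or CSV file (gzip transparent), with a header row.
    column_map
        Maps record fields to source column names; defaults to the bundled
        GWAS preset (SNP, CHR, BP, A1, A2, BETA, SE, P, EAF, N). An ``"or"``
        entry may replace ``"beta"``, in which case effects are
        log-transformed at read time.
    trait_type
        ``"binary"`` or ``"continuous"``.
    effect_is_or
        Treat the effect column as an odds ratio even when mapped as beta.

    Rows violating the record invariants (non-ACGT or identical alleles,
    non-positive SE, p outside (0, 1], EAF outside (0, 1)) are dropped and
    counted; alleles are upper-cased.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    # An explicit "or" mapping takes precedence over the beta preset; either
    # way the stored effect is log-transformed to the additive scale.
    effect_field = "or" if "or" in (column_map or {}) else "beta"
    log_transform = effect_is_or or effect_field == "or"

    frame = pd.read_csv(path, sep=None, engine="python")
    needed = list(_MANDATORY) + [effect_field]
    missing = [f for f in needed if cmap.get(f) not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"missing mandatory column(s) {missing} in {path} "
            f"(mapped names: {[cmap.get(f) for f in missing]})"
        )

    def col(fieldname, default=None):
        name = cmap.get(fieldname)
        if name is not None and name in frame.columns:
            return frame[name]
        return pd.Series([default] * len(frame))

    records: list[AssociationRecord] = []
    n_dropped = 0
    effects = col(effect_field)
    for i in range(len(frame)):
        try:
            beta = float(effects.iloc[i])
            if log_transform:
                if beta <= 0:
                    n_dropped += 1
                    continue
                beta = math.log(beta)
            eaf_v = col("eaf").iloc[i]
            n_v = col("n").iloc[i]
            pos_v = col("pos").iloc[i]
            chrom_v = col("chrom").iloc[i]
            rec = AssociationRecord(
                snp_id=str(col("snp_id").iloc[i]),
                effect_allele=str(col("effect_allele").iloc[i]).upper(),
                other_allele=str(col("other_allele").iloc[i]).upper(),
                beta=beta,
                se=float(col("se").iloc[i]),
                pvalue=float(col("pvalue").iloc[i]),
                chrom=None if pd.isna(chrom_v) else str(chrom_v),
                pos=None if pd.isna(pos_v) else int(pos_v),
                eaf=None if pd.isna(eaf_v) else float(eaf_v),
                n=None if pd.isna(n_v) else int(float(n_v)),
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if rec.is_valid():
            records.append(rec)
        else:
            n_dropped += 1

    if not records:
        raise DataError(f"no valid rows in {path}")
    name = trait_name or str(path)
    if n_dropped:
        logger.info(
            "read_sumstats(%s): %d records kept, %d dropped", name, len(records), n_dropped
        )
    return SummaryDataset(name, trait_type, records, n_dropped=n_dropped)


def write_sumstats(ds: SummaryDataset, path) -> None:
    """Write a dataset in the same TSV dialect the readers consume."""
    ds.to_frame().to_csv(path, sep="\t", index=False)


def write_ld_panel(panel: LdPanel, path) -> None:
    """Write the LD panel as a 3-column (snp_a, snp_b, r2) pair list."""
    rows = [(a, b, r2) for (a, b), r2 in sorted(panel.pairs.items())]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(path, sep="\t", index=False)
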