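import numpy as np
import pytest

from mrmediate import AssociationRecord, SimConfig, SummaryDataset, simulate_summary
from mrmediate.harmonize import HarmonizedSet


def hset(bx, by, sy, sx=None, exposures=("x",), outcome="y", snp_ids=None,
         outcome_type="binary"):
    """Build a HarmonizedSet directly from effect arrays (test shorthand)."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    if sx is None:
        sx = np.full_like(bx, 1e-3)
    j = len(by)
    if snp_ids is None:
        snp_ids = [f"s{i}" for i in range(j)]
    return HarmonizedSet(
        exposures=list(exposures),
        outcome=outcome,
        snp_ids=snp_ids,
        beta_x=bx,
        se_x=np.asarray(sx, float),
        beta_y=by,
        se_y=sy,
        outcome_type=outcome_type,
    )


def record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01, p=1e-10,
           chrom="1", pos=1_000_000, eaf=0.3, n=1000):
    return AssociationRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=p, chrom=chrom, pos=pos, eaf=eaf, n=n,
    )


def dataset(records, name="trait", trait_type="continuous"):
    return SummaryDataset(name, trait_type, records)


@pytest.fixture(scope="session")
def sim_trio():
    """One default-parameter synthetic study, shared across tests."""
    cfg = SimConfig(seed=7)
    exposure, mediators, outcome, truth, panel = simulate_summary(cfg)
    return {
        "cfg": cfg,
        "exposure": exposure,
        "mediator": mediators[0],
        "outcome": outcome,
        "truth": truth,
        "ld": panel,
    }
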