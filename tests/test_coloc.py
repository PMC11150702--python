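"""Colocalization: Wakefield ABFs, hypothesis enumeration, averaging."""

import numpy as np
import pytest

from mrmediate import (
    NoEvaluableRegionError,
    coloc_abf,
    coloc_pipeline,
    make_regions,
    simulate_region_pair,
)
from mrmediate.coloc import wakefield_log_abf
from tests.conftest import dataset, record


def region_records(zs, se=0.01, tag="r"):
    return [
        record(
            f"{tag}_snp{k}",
            beta=float(z * se),
            se=se,
            p=0.5,
            pos=1_000_000 + 1_000 * k,
        )
        for k, z in enumerate(zs)
    ]


def test_make_regions_interval_arithmetic():
    inst = dataset([record("rs1", pos=1_000_000)])
    regions, skipped = make_regions(inst, half_window_bp=500_000)
    assert len(regions) == 1 and not skipped
    assert (regions[0].start, regions[0].end) == (500_000, 1_500_000)
    assert regions[0].region_id == "rs1"


def test_overlapping_regions_not_merged():
    inst = dataset([record("rs1", pos=1_000_000), record("rs2", pos=1_100_000)])
    regions, _ = make_regions(inst)
    assert len(regions) == 2


def test_no_instruments_no_regions_and_missing_pos_audited():
    regions, skipped = make_regions(dataset([]))
    assert regions == [] and skipped == []
    regions, skipped = make_regions(dataset([record("rs1", pos=None)]))
    assert regions == [] and skipped == [("rs1", "no_position")]


def test_single_strong_shared_snp_forces_pph4():
    s = coloc_abf(region_records([12.0]), region_records([11.0]))
    assert s.pph[4] > 0.99
    assert s.pph.sum() == pytest.approx(1.0, abs=1e-9)


def test_null_region_prefers_pph0():
    zs = [0.05, -0.1, 0.02, 0.08]
    s = coloc_abf(region_records(zs), region_records([-z for z in zs]))
    assert np.argmax(s.pph) == 0


def linear_space_oracle(rec1, rec2, priors=(1e-4, 1e-4, 1e-5),
                        sd1=0.15, sd2=0.2):
    """Brute-force enumeration of hypothesis configurations, no log tricks."""
    ids = [r.snp_id for r in rec1 if r.snp_id in {x.snp_id for x in rec2}]
    b2 = {r.snp_id: r for r in rec2}
    a1 = np.array([np.exp(wakefield_log_abf(r.beta, r.se, sd1)) for r in rec1 if r.snp_id in ids])
    a2 = np.array([np.exp(wakefield_log_abf(b2[s].beta, b2[s].se, sd2)) for s in ids])
    p1, p2, p12 = priors
    n = len(ids)
    h0 = 1.0
    h1 = p1 * a1.sum()
    h2 = p2 * a2.sum()
    h3 = p1 * p2 * sum(a1[i] * a2[j] for i in range(n) for j in range(n) if i != j)
    h4 = p12 * float(np.dot(a1, a2))
    h = np.array([h0, h1, h2, h3, h4])
    return h / h.sum()


@pytest.mark.parametrize("seed", range(5))
def test_log_space_matches_linear_space_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 26))
    z1 = rng.normal(0, 3, n)
    z2 = rng.normal(0, 3, n)
    rec1 = region_records(z1)
    rec2 = region_records(z2)
    s = coloc_abf(rec1, rec2)
    expected = linear_space_oracle(rec1, rec2)
    np.testing.assert_allclose(s.pph, expected, atol=1e-10)
    assert s.pph.sum() == pytest.approx(1.0, abs=1e-9)
    assert (s.pph >= 0).all()


def test_pph4_monotone_in_shared_prior():
    rng = np.random.default_rng(3)
    rec1 = region_records(rng.normal(0, 2, 10))
    rec2 = region_records(rng.normal(0, 2, 10))
    last = -1.0
    for p12 in (1e-6, 1e-5, 1e-4):
        s = coloc_abf(rec1, rec2, priors=(1e-4, 1e-4, p12))
        assert s.pph[4] >= last
        last = s.pph[4]


def test_zero_shared_snps_region_skipped():
    assert coloc_abf(region_records([1.0], tag="a"), region_records([1.0], tag="b")) is None


def make_pair_datasets(region_specs):
    """region_specs: list of (shared: bool, seed). Builds trait datasets,
    one instrument per region, regions 10 Mb apart."""
    rec1_all, rec2_all, inst = [], [], []
    for k, (shared, seed) in enumerate(region_specs):
        r1, r2 = simulate_region_pair(
            15, shared, seed=seed, start_pos=1_000_000 + 10_000_000 * k,
            region_tag=f"reg{k}",
        )
        rec1_all += r1
        rec2_all += r2
        lead = max(r1, key=lambda r: abs(r.beta / r.se))
        inst.append(lead)
    t1 = dataset(rec1_all, name="t1")
    t2 = dataset(rec2_all, name="t2", trait_type="binary")
    return t1, t2, dataset(inst, name="inst")


def test_pipeline_mean_is_unweighted_average_of_regions():
    t1, t2, inst = make_pair_datasets([(True, 1), (False, 2)])
    res = coloc_pipeline(t1, t2, inst)
    assert len(res.regions) == 2
    assert res.mean_pph4 == pytest.approx(
        np.mean([r.pph4 for r in res.regions]), abs=1e-12
    )
    # one shared, one null region: strong disagreement, no shared call
    assert res.shared_flag is False


def test_pipeline_single_region_mean_is_that_region():
    t1, t2, inst = make_pair_datasets([(True, 5)])
    res = coloc_pipeline(t1, t2, inst)
    assert res.mean_pph4 == pytest.approx(res.regions[0].pph4)
    assert res.shared_flag is True


def test_all_regions_skipped_raises():
    t1 = dataset([record("rs1", pos=1_000_000)], name="t1")
    t2 = dataset([record("zzz", pos=99_000_000)], name="t2")
    inst = dataset([record("rs1", pos=1_000_000)], name="inst")
    with pytest.raises(NoEvaluableRegionError):
        coloc_pipeline(t1, t2, inst)


def test_shared_and_null_simulations_separate_cleanly():
    shared = [(True, 100 + i) for i in range(8)]
    null = [(False, 200 + i) for i in range(8)]
    t1, t2, inst = make_pair_datasets(shared)
    assert coloc_pipeline(t1, t2, inst).mean_pph4 > 0.75
    t1, t2, inst = make_pair_datasets(null)
    assert coloc_pipeline(t1, t2, inst).mean_pph4 < 0.75
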