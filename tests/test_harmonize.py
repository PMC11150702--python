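"""Allele harmonization: flips, strand complements, palindromes, audit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate import AssociationRecord, harmonize
from tests.conftest import dataset, record


def pair(exposure_recs, outcome_recs, **kwargs):
    return harmonize(
        [dataset(exposure_recs, name="x")],
        dataset(outcome_recs, name="y", trait_type="binary"),
        **kwargs,
    )


def test_swapped_alleles_flip_outcome_sign():
    h = pair(
        [record("rs1", "A", "G", beta=0.1)],
        [record("rs1", "G", "A", beta=-0.2)],
    )
    assert h.snp_ids == ["rs1"]
    assert h.beta_y[0] == pytest.approx(0.2)
    assert h.beta_x[0, 0] == pytest.approx(0.1)


def test_strand_complement_aligned_without_flip():
    # exposure A/G, outcome reported on the other strand as T/C
    h = pair(
        [record("rs1", "A", "G", beta=0.1)],
        [record("rs1", "T", "C", beta=0.3)],
    )
    assert h.beta_y[0] == pytest.approx(0.3)
    assert h.actions["rs1"]["y"] == "complemented"


def test_strand_complement_swapped_flips():
    h = pair(
        [record("rs1", "A", "G", beta=0.1)],
        [record("rs1", "C", "T", beta=0.3)],
    )
    assert h.beta_y[0] == pytest.approx(-0.3)


def test_palindromic_ambiguous_eaf_dropped():
    h = pair(
        [record("rs1", "A", "T", eaf=0.5)],
        [record("rs1", "A", "T", eaf=0.5)],
        palindrome_policy="infer_by_eaf",
    )
    assert h.snp_ids == []
    assert h.dropped[0][1].startswith("palindromic_ambiguous")


def test_palindromic_policy_drop():
    h = pair(
        [record("rs1", "A", "T", eaf=0.2)],
        [record("rs1", "A", "T", eaf=0.2)],
        palindrome_policy="drop",
    )
    assert h.dropped == [("rs1", "palindromic")]


def test_palindromic_inferred_by_eaf():
    # same minor-allele side: keep orientation
    h = pair(
        [record("rs1", "A", "T", beta=0.1, eaf=0.2)],
        [record("rs1", "A", "T", beta=0.3, eaf=0.25)],
    )
    assert h.beta_y[0] == pytest.approx(0.3)
    # opposite sides: flip
    h = pair(
        [record("rs1", "A", "T", beta=0.1, eaf=0.2)],
        [record("rs1", "A", "T", beta=0.3, eaf=0.75)],
    )
    assert h.beta_y[0] == pytest.approx(-0.3)


def test_irreconcilable_alleles_dropped_with_reason():
    h = pair(
        [record("rs1", "A", "G", beta=0.1)],
        [record("rs1", "A", "C", beta=0.3)],
    )
    assert h.snp_ids == []
    assert h.dropped[0][1].startswith("allele_mismatch")


def test_snp_missing_from_outcome_dropped():
    h = pair(
        [record("rs1"), record("rs2", pos=2_000_000)],
        [record("rs1")],
    )
    assert h.snp_ids == ["rs1"]
    assert ("rs2", "missing:y") in h.dropped


_alleles = st.sampled_from(["A", "C", "G", "T"])


@st.composite
def random_records(draw):
    ea = draw(_alleles)
    oa = draw(_alleles.filter(lambda a: a != ea))
    return record(
        snp_id=f"rs{draw(st.integers(0, 10_000))}",
        ea=ea,
        oa=oa,
        beta=draw(st.floats(-1, 1, allow_nan=False)),
        eaf=draw(st.floats(0.05, 0.95)),
    )


@given(st.lists(random_records(), min_size=1, max_size=100,
                unique_by=lambda r: r.snp_id))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_harmonization_is_involutive(recs):
    """Re-harmonizing an already-harmonized pair changes nothing."""
    exp = dataset(recs, name="x")
    out = dataset([r for r in recs], name="y", trait_type="binary")
    h1 = harmonize([exp], out)
    # rebuild datasets from the harmonized rows (aligned to the reference)
    exp2 = dataset([exp[s] for s in h1.snp_ids], name="x")
    out_aligned = [
        AssociationRecord(
            snp_id=s,
            effect_allele=exp[s].effect_allele,
            other_allele=exp[s].other_allele,
            beta=float(h1.beta_y[i]),
            se=float(h1.se_y[i]),
            pvalue=exp[s].pvalue,
            eaf=exp[s].eaf,
            chrom=exp[s].chrom,
            pos=exp[s].pos,
        )
        for i, s in enumerate(h1.snp_ids)
    ]
    h2 = harmonize([exp2], dataset(out_aligned, name="y", trait_type="binary"))
    assert h2.snp_ids == h1.snp_ids
    np.testing.assert_allclose(h2.beta_y, h1.beta_y)
    np.testing.assert_allclose(h2.beta_x, h1.beta_x)


@given(st.lists(random_records(), min_size=1, max_size=50,
                unique_by=lambda r: r.snp_id))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_strand_flip_invariance(recs):
    """Complementing both outcome alleles (beta unchanged) gives an
    identical harmonized set, palindromic drops aside."""
    exp = dataset(recs, name="x")
    out1 = dataset(recs, name="y", trait_type="binary")
    out2 = dataset([r.complemented() for r in recs], name="y", trait_type="binary")
    h1 = harmonize([exp], out1)
    h2 = harmonize([exp], out2)
    assert h1.snp_ids == h2.snp_ids
    np.testing.assert_allclose(h1.beta_y, h2.beta_y)


def test_no_retained_row_has_missing_values(sim_trio):
    h = harmonize(
        [sim_trio["exposure"], sim_trio["mediator"]], sim_trio["outcome"]
    )
    assert h.n_snp > 0
    assert np.isfinite(h.beta_x).all() and np.isfinite(h.se_x).all()
    assert np.isfinite(h.beta_y).all() and np.isfinite(h.se_y).all()
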