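"""Colocalization of two traits around instrument regions.

Builds regions that do or do not share a causal variant and shows how the
posterior probability of a shared causal variant (PPH4), averaged across
regions, separates the two situations at the 75% rule.
"""

import numpy as np

from mrmediate import SummaryDataset, coloc_pipeline, simulate_region_pair


def build_study(shared: bool, n_regions: int = 6, seed0: int = 0):
    """Trait pair with one instrument-centred region per locus."""
    rec1_all, rec2_all, leads = [], [], []
    for k in range(n_regions):
        r1, r2 = simulate_region_pair(
            20, shared, seed=seed0 + k,
            start_pos=1_000_000 + 10_000_000 * k, region_tag=f"locus{k}",
        )
        rec1_all += r1
        rec2_all += r2
        leads.append(max(r1, key=lambda r: abs(r.beta / r.se)))
    return (
        SummaryDataset("trait1", "continuous", rec1_all),
        SummaryDataset("trait2", "binary", rec2_all),
        SummaryDataset("instruments", "continuous", leads),
    )


for shared in (True, False):
    t1, t2, inst = build_study(shared, seed0=100 if shared else 200)
    res = coloc_pipeline(t1, t2, inst)
    label = "shared causal variants" if shared else "distinct/no causal variants"
    pph4s = np.array([r.pph4 for r in res.regions])
    print(f"{label}:")
    print(f"  per-region PPH4: {np.round(pph4s, 3)}")
    print(f"  mean PPH4 = {res.mean_pph4:.3f}  -> shared_flag = {res.shared_flag}")

print("\nmean PPH4 > 0.75 is read as evidence that the two traits are "
      "driven by the same causal variants in these regions.")
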