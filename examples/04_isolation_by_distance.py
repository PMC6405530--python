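"""Isolation by distance in the native vs the invasive range.

In the native range, demes sit on a spatial gradient, so genetic and
geographic distance correlate (positive Rousset slope, significant Mantel
test).  Invasive populations all descend from one recent founder pool, so
their differentiation carries no spatial signal.
"""

from invadepop import (
    SimConfig,
    detect_clones,
    ibd_analysis,
    simulate_dataset,
    wc_fst,
)
from invadepop.io import metadata_for

gm, meta, _ = simulate_dataset(SimConfig(seed=3))
_, clone_free = detect_clones(gm, meta)
mcf = metadata_for(clone_free, meta)

for rng_label in ("native", "invasive"):
    ids = mcf.loc[mcf.range_label == rng_label, "individual_id"].tolist()
    sub = clone_free.subset(individuals=ids)
    fst = wc_fst(sub, meta, n_boot=100, seed=1, pairwise=True)
    res = ibd_analysis(fst.pairwise_FST, sub, meta, n_perm=9999, seed=11)
    print(f"[{rng_label}] {res.n_populations} populations")
    print(f"  Rousset regression: r = {res.pearson_r:.3f} (p = {res.pearson_p:.2g}), "
          f"slope = {res.slope:.4f} per ln(km)")
    print(f"  Mantel test (chord distance vs km): r = {res.mantel_r:.3f}, "
          f"p = {res.mantel_p:.4g} ({res.n_perm} permutations)")
print("\nA positive, significant correlation only in the native range mirrors")
print("long-term spatial equilibrium there and human-mediated spread elsewhere.")
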