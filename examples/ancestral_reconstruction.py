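"""Reconstruct ancestral states of a continuous character (a log2 expression
fold change) under Brownian motion on a small rooted tree."""

import expevo as ev

tree = ev.parse_newick("((Fgram:0.3,Fneo:0.3)Hypocreaceae:0.7,(Moryzae:0.8,Ncrassa:0.8):0.2,Cglob:1.0);")
tips = {"Fgram": 3.2, "Fneo": 1.1, "Moryzae": -0.4, "Ncrassa": 0.2, "Cglob": 0.5}

root, var = ev.bm_root_estimate(tree, tips)
print(f"tip fold changes: {tips}")
print(f"root (MRCA) estimate: {root:.4f}  (estimator variance {var:.4f})")

est = ev.bm_internal_states(tree, tips)
print("\nall internal nodes:")
for name, vals in est.node_values.items():
    print(f"  {name:>14}: {vals[0]: .4f}")

hypo = ev.node_lookup(est, "MRCA:Fgram,Fneo", tree=tree)[0]
print(
    f"\nancestor of the two Fusarium-like lineages: {hypo:.4f} — closer to "
    "their tip values than the root is, because only 0.3 units of drift "
    "separate them from it."
)
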