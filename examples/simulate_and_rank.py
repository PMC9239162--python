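"""Generate a synthetic five-species developmental transcriptome and rank
genes by fold-change differential (FCD) against the reconstructed ancestor.

The generator plants 25 genes with a +4 log2 activation shift on the focal
terminal branch; a good ranking puts those at the top.
"""

import expevo as ev

ds = ev.emit_dataset(ev.SimConfig(seed=42))
print(f"species tree: {ds.tree.to_newick()}")
print(f"focal species (carries the planted shifts): {ds.focal_species}\n")

result = ev.run_priority_pipeline(ds.matrices, ds.tree, ds.scog_map, ds.focal_species)
print(
    f"{len(ds.scog_map)} clusters; {len(result.excluded)} excluded as not "
    f"actively transcribed; {len(result.retained)} ranked"
)

planted = set(ds.truth.planted_clusters())
print("\nrank  cluster    FCD(log2)  linear  transition  planted?")
for r in ev.top_k(result.records, 10):
    mark = "*" if r.cluster_id in planted else ""
    print(
        f"{r.rank:>4}  {r.cluster_id}  {r.fcd_max:>9.2f}  {r.fcd_linear:>6.1f}"
        f"  {r.transition_label:>9}  {mark}"
    )

top50 = {r.cluster_id for r in ev.top_k(result.records, 50)}
print(
    f"\n{len(planted & top50)} of {len(planted)} planted genes in the top 50 — "
    "FCD is the log2 excess of the extant fold change over the ancestral one, "
    "so a value near 4 recovers the planted shift minus what leaked into the "
    "root estimate."
)
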