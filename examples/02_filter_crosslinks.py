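"""Filter simulated cross-link replicates the way real identifications are.

Three replicate tables with planted true links and dropout are pushed
through the all-replicates + 5 ppm mass-accuracy filter, then chemistry
validation and the dynamic-region exclusion.
"""
import beltlink as bl

ref = bl.make_toy_reference(120, "random-walk", seed=11)
chem = bl.builtin_chemistries()["FM"].with_max_span(26.0)
sim = bl.simulate_crosslinks(
    ref, chem, n_true=20, fp_rate=0.1, n_replicates=3, dropout_rate=0.15, seed=1
)
for i, rep in enumerate(sim.replicates, 1):
    print(f"replicate {i}: {len(rep)} identifications")

survivors = bl.filter_reproducible(sim.replicates, ppm_tol=5.0)
print(f"reproducible in all 3 replicates within 5 ppm: {len(survivors)}")

seqs = {ref.name: ref.sequence}
valid = [x for x in survivors if bl.validate_reactivity(x, chem, seqs)]
kept, excluded = bl.exclude_dynamic_regions(valid, regions=((ref.name, 1, 1),))
print(f"chemically valid: {len(valid)}; after N-terminus exclusion: {len(kept)}")
print("-> only links seen in every replicate, chemically formable and outside "
      "dynamic regions go forward as distance restraints.")
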