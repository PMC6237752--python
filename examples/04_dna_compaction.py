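"""DNA-compaction signature: maximum intensity rises, mean does not.

Two simulated arms carry identical per-cell total Hoechst (DNA) intensity;
in the treated arm each cell's signal is concentrated into 20% of its
area.  Per-cell mean intensity is therefore statistically indistinguishable
between the arms, while the maximum localized intensity separates them
sharply — the intensity signature of nucleoid compaction at constant DNA
content.
"""

from halofoci.experiments import compaction_experiment

out = compaction_experiment(n_cells_per_arm=100, compaction_fraction=0.2, seed=33)
print(f"cells per arm: {out['n_per_arm']}")
print(f"Welch p, per-cell MEAN DNA intensity: {out['p_mean']:.3f}  (expect > 0.05)")
print(f"Welch p, per-cell MAX  DNA intensity: {out['p_max']:.2e} (expect < 0.01)")
print(f"max-intensity ratio treated/control: {out['max_ratio']:.1f}x")
# Conserved integrated intensity with a higher localized maximum is what
# distinguishes compaction from a change in DNA content.
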