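"""Sample-level tumor infiltration phenotypes with grid-shift averaging.

Builds a synthetic tissue sample whose tiles are 60% inflamed, 25% excluded
and 15% deserted, trains a tile classifier on separately simulated labeled
tiles, and computes the sample's TIP: the proportions of tiles classified
into each phenotype, averaged over the original grid placement and four
placements shifted by 10% of the tile edge.  The recovered proportions
should track the planted ones.
"""

from tipmap import Config, sample_tips
from tipmap.simulate import simulate_sample
from tipmap.validation import train_synthetic_classifier

config = Config()
print("training tile classifier on simulated labeled tiles ...")
model = train_synthetic_classifier(seed=0, config=config, n_per_class=20)

cells, window, truth = simulate_sample((0.60, 0.25, 0.15), grid=(6, 6), seed=3)
print(f"sample: {len(cells)} cells, region {window.area / 1e6:.1f} mm^2, "
      f"planted proportions {truth.tip_proportions}")

result = sample_tips(cells, window, {"CD8": model}, config)
props = result.proportions["tumor:CD8"]
print("shift-averaged TIP (tumor, CD8):")
for phenotype, value in props.items():
    print(f"  {phenotype:9s} {value:.3f}")
print("per-placement classifiable tile counts:",
      [d.n_classifiable for d in result.per_shift["tumor:CD8"]])
print("note: tiles clipped at the region border hold fewer immune cells, so "
      "a share of border tiles reads as deserted; interior-dominated samples "
      "track the planted proportions more closely")
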