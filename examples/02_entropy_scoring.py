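"""Entropy-weight composite scores from a raw indicator panel.

A tiny worked cross-section (3 provinces x 2 indicators) shows each step:
min–max normalisation with the 0.01 floor, per-indicator entropy, weights
proportional to information content (1 - entropy), and weighted-sum
scores.  Then the same machinery scores a full synthetic panel per year.
"""

import numpy as np

from vetcoord import preset_regimes, simulate_panel, score_panel
from vetcoord.entropy import score_cross_section

X = np.array([[1.0, 10.0],
              [2.0, 20.0],
              [3.0, 40.0]])
scores, weights, entropies = score_cross_section(X, ["+", "+"])
print("raw 3x2 cross-section:\n", X)
print(f"entropies:  {entropies.round(4)}   (lower = more informative)")
print(f"weights:    {weights.round(3)}     (sum to 1)")
print(f"scores:     {scores.round(3)}      (weighted normalised values)")
print("Indicator 2 spreads provinces more unevenly, so it carries slightly "
      "more weight (0.538 vs 0.462).\n")

spec = preset_regimes("unidirectional_vhr_to_paaw", seed=7)
panel, _ = simulate_panel(spec)
weight_table, score_table = score_panel(panel, index_spec=spec.index_spec())
print("full panel: per-year weights and per-province scores")
print(weight_table.head(4).to_string(index=False))
print("...")
print(score_table.head(4).to_string(index=False))
print(f"\nscores span ({score_table['score'].min():.3f}, "
      f"{score_table['score'].max():.3f}] — always within (0, 1] by "
      "construction of the normalisation and the weight simplex.")
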