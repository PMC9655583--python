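"""Attribution-based motif discovery on a trained model.

Integrated Gradients assigns each input position a signed contribution
to the positive-class score. High-weight subsequences (seqlets) from
confidently predicted positives are clustered and aligned into position
frequency matrices; on the synthetic benchmark the recovered consensus
can be checked against the planted motif.
"""

import numpy as np

from seqdsn.experiments import run_transfer_experiment
from seqdsn.interpretation import (cluster_and_align, extract_seqlets,
                                   integrated_gradients)

small = dict(n_source_pos=600, n_source_neg=600,
             n_target_pos=120, n_target_neg=1200)
result = run_transfer_experiment(seed=3, preset="easy", run_mode1=False,
                                 synth_overrides=small, restarts=2)
model = result.model2
model.eval()
score_fn = model.score_fn("target")

pos_idx = np.flatnonzero(result.target_test.labels == 1)
maps = [integrated_gradients(score_fn, result.target_test.encoded[i],
                             steps=50) for i in pos_idx]
print(f"attributed {len(maps)} positive windows "
      f"(mean completeness gap {np.mean([m.convergence_gap for m in maps]):.4f})")

seqlets = extract_seqlets(maps, k=6)
motifs = cluster_and_align(seqlets, min_support=5)
print(f"{len(seqlets)} seqlets -> {len(motifs)} motif(s)\n")
for i, m in enumerate(motifs[:3]):
    print(f"motif {i + 1}: consensus {m.consensus}  "
          f"support {m.support}  mean weight {m.mean_weight:.3f}")
print("\nThe generator planted GUUCGA in every positive of this preset; "
      "a consensus\ncontaining it means the network's prediction is "
      "driven by the planted signal,\nnot by background composition.")
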