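"""Simulate a D-KEFS-like score battery with planted factor structure.

Generates a 17-item, 334-subject table of non-negative scores whose items
fall into two planted factors, plus a hierarchical variant where five fine
item blocks nest inside two coarse factors.
"""

import numpy as np

from opnmfkit import generate_hierarchical, generate_scores

sm, truth = generate_scores(p=17, k=2, n=334, noise_sd=0.3, seed=1)
print(f"flat battery: {sm.n_items} items x {sm.n_subjects} subjects, min score "
      f"{sm.values.min():.3f} (non-negative by construction)")
print("planted item->factor partition:", truth.partition_true.tolist())
print("first items:", sm.item_labels[:3])

hsm, htruth = generate_hierarchical(
    p=17, k_fine=5, k_coarse=2, within_corr=0.7, n=334, noise_sd=0.3, seed=1
)
print("\nhierarchical battery: fine partition ", htruth.partition_true.tolist())
print("                      coarse partition", htruth.partition_coarse.tolist())
R = np.corrcoef(hsm.values)
same = R[np.equal.outer(htruth.partition_coarse, htruth.partition_coarse)
         & ~np.eye(17, dtype=bool)].mean()
diff = R[~np.equal.outer(htruth.partition_coarse, htruth.partition_coarse)].mean()
print(f"mean item correlation within a coarse block {same:.2f} vs across {diff:.2f}"
      " -- the coarse split dominates shared variance")
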