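"""Grow a single perfect tree on an interleaved one-feature toy problem.

The labels along the feature are 0,1,1,0: no single threshold separates the
classes, so the tree must peel error-free extremes step by step until an
admissible neuron splits what remains.
"""

import numpy as np

from rfpt import Dataset, TreeConfig, grow_tree, verify_perfect

data = Dataset(np.array([[1.0], [2.0], [3.0], [4.0]]), [0, 1, 1, 0])
config = TreeConfig(n_features_per_neuron=1)

tree = grow_tree(data, features=[0], config=config)

print(f"perfect: {tree.is_perfect}, neurons used: {tree.neurons_used}")
for i, (neuron, (idx, labels)) in enumerate(zip(tree.neurons, tree.finalized), 1):
    print(
        f"  neuron {i}: c={neuron.coefficients} t={neuron.threshold:+.2f} "
        f"policy={neuron.policy.value} finalizes samples {idx.tolist()} as {labels.tolist()}"
    )
print(f"sign profile: {tree.sign_profile.value}")
print(f"solution class: {tree.solution_class.value} "
      f"(multiplicity {tree.solution_multiplicity:g})")
print(f"independent verification: {verify_perfect(tree, data.y)}")

# The first neuron peels the high extreme (a true negative) without error;
# the second classifies the remaining three samples perfectly, so the tree
# reaches 100% sensitivity and specificity with two ternary-weight neurons.
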