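"""Quantify PSI for one local splicing variation (LSV) from read counts.

An LSV with J elements and per-element read counts r_j gets the conjugate
posterior Psi_j ~ Beta(1/J + r_j, 1 - 1/J + sum of the other counts); the
prior Beta(1/J, 1 - 1/J) favours extreme inclusion values.
"""

from spliceunion import psi_posterior

for counts in ([7, 3], [0, 0, 0], [30, 10, 2]):
    post = psi_posterior(counts)
    J = len(counts)
    print(f"counts={counts}  (J={J})")
    for j, (a, b, m) in enumerate(zip(post.alpha, post.beta, post.means)):
        print(f"  element {j}: Beta({a:.3f}, {b:.3f})  E[PSI]={m:.4f}")
    print(f"  sum of posterior means = {post.means.sum():.12f}")

# With no reads the posterior equals the prior (mean 1/J); with reads the
# means approach the count fractions, and they always sum to exactly 1.
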