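"""Strength and relevance of a single observed expression pair.

For one individual, the standardized expression values (z_i, z_j) of two genes
are a single draw from a bivariate normal.  The *strength* is the correlation
that maximizes the density at that point; the *relevance* is the probability
that a chance pairing would have produced a smaller strength.
"""

from wigamine import relevance, strength

pairs = [(2.0, 1.9), (2.0, 1.0), (1.0, -1.2), (0.3, 0.2), (2.0, -2.0)]

print(f"{'z_i':>6} {'z_j':>6} {'strength':>9} {'relevance':>10}")
for zi, zj in pairs:
    score = relevance(zi, zj)
    print(f"{zi:6.1f} {zj:6.1f} {score.strength:9.4f} {score.relevance:10.4f}")

print()
print("Agreement of the standardized values drives the strength: z_i ~ z_j")
print("gives strength near +1, opposition near -1.  Relevance separates them:")
print("large co-deviations are hard to produce by a chance pairing (relevance")
print("near 1), opposed pairs have relevance near 0, and an edge enters an")
print("individual's network only when relevance > tau_r.")
print(f"\nExample: strength(2, 1) = {strength(2.0, 1.0):.4f} is the root of the")
print("stationarity cubic r^3 - 2 r^2 + 4 r - 2 in (-1, 1).")
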