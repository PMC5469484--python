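"""The exact statistics used throughout the pipeline, on small inputs.

Each call below prints a value that can be checked by hand: the
hypergeometric overlap tail, the two-sided Fisher test with the
point-probability criterion, the exact Mann-Whitney test, and a
BH-adjusted gene-set enrichment against user-supplied reference sets.
"""

from profileclust.stats import (
    bh_adjust,
    fisher_exact_two_sided,
    gene_set_enrichment,
    hypergeometric_tail,
    mann_whitney_u,
)

# overlap of two gene sets of sizes 5 and 2 in a 10-gene universe
p = hypergeometric_tail(k=2, K=5, n=2, N=10)
print(f"hypergeometric P(X >= 2) = {p:.5f}   (exactly C(5,2)/C(10,2) = 10/45)")

# perfectly associated 2x2 table: only the two extreme tables qualify
p = fisher_exact_two_sided([[5, 0], [0, 5]])
print(f"two-sided Fisher p = {p:.7f}   (exactly 2/252)")

# fully separated small samples: one extreme ordering out of C(6,3) = 20
u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
print(f"Mann-Whitney U = {u:.0f}, exact two-sided p = {p:.3f}   (2 * 1/20)")

adjusted = bh_adjust([0.01, 0.02, 0.03])
print("BH-adjusted (0.01, 0.02, 0.03) ->", [round(float(q), 3) for q in adjusted])

universe = {f"g{i}" for i in range(200)}
muscle = {f"g{i}" for i in range(30)}          # reference set
query = {f"g{i}" for i in range(20)} | {"g100", "g101"}  # mostly inside it
table = gene_set_enrichment(query, {"muscle_development": muscle}, universe, alpha=0.01)
row = table.iloc[0]
print(
    f"enrichment of the query in '{row.set_name}': overlap {row.overlap}/{row.set_size}, "
    f"adjusted p = {row.p_adjusted:.2e}, significant: {bool(row.significant)}"
)
print("a significant set means the query shares more genes with it than expected")
print("for random draws from the universe, after BH control across all sets.")
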