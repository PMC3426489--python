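"""Do dysregulated pairs coincide with physical protein interactions?

Counts, over the tested pathways, how many gene pairs could have been both
tested and physically interacting (the urn), how many dysregulated pairs
were drawn, and how many of those are physical, then computes the exact
upper-tail hypergeometric probability of seeing at least that much
overlap by chance.
"""

from giena import (
    GeneSetCollection, PhysicalInteractionNetwork, hypergeom_upper_tail,
    run_overlap,
)

pathways = GeneSetCollection({
    "CELL_CYCLE": ("demo", frozenset({"CDK2", "CDK4", "TP53", "MDM2", "E2F1"})),
    "APOPTOSIS": ("demo", frozenset({"TP53", "BAX", "BCL2", "FAS", "CASP3"})),
})
ppi = PhysicalInteractionNetwork({
    ("CDK2", "TP53"), ("TP53", "MDM2"), ("TP53", "BAX"),
    ("BCL2", "BAX"), ("FAS", "CASP3"), ("E2F1", "TP53"), ("CDK4", "CDK2"),
})
dysregulated = [("TP53", "MDM2"), ("BCL2", "BAX"), ("CDK2", "E2F1"), ("TP53", "CASP3")]

test = run_overlap(pathways, dysregulated, ppi, mode="literal")
print(f"urn: N={test.N} testable pairs, m={test.m} physical; "
      f"drew n={test.n} dysregulated pairs, k={test.k} physical")
print(f"P(X >= {test.k}) = {test.p_value:.4f}")
# A small p-value says the dysregulated pairs are physically connected
# more often than random pairs of the same tested pathways would be.

print("sanity: P(X >= 0) =", hypergeom_upper_tail(test.N, test.n, test.m, 0))
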