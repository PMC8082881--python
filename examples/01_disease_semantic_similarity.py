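"""Disease semantic similarity from a small ontology DAG.

Builds a toy disease hierarchy, computes decayed ancestor contributions for
one term, and the pairwise similarity matrix for three diseases.
"""

from smalf import DiseaseDAG, disease_similarity_matrix, semantic_contributions

# root -> {cancer, metabolic}; cancer -> {liver cancer, colon cancer}
dag = DiseaseDAG.from_edges(
    [
        ("disease", "cancer"),
        ("disease", "metabolic"),
        ("cancer", "liver cancer"),
        ("cancer", "colon cancer"),
        ("metabolic", "diabetes"),
    ]
)

cm = semantic_contributions(dag, "liver cancer", delta=0.5)
print("ancestor contributions to 'liver cancer':")
for term, value in sorted(cm.contributions.items(), key=lambda kv: -kv[1]):
    print(f"  {term:15s} {value:.3f}")
print(f"semantic value DV = {cm.semantic_value:.3f}")
# the focus term contributes 1; each step up the hierarchy halves the
# contribution, and DV sums them.

sm = disease_similarity_matrix(dag, ["liver cancer", "colon cancer", "diabetes"])
print("\npairwise semantic similarity:")
for i, row_id in enumerate(sm.ids):
    row = "  ".join(f"{v:.3f}" for v in sm.values[i])
    print(f"  {row_id:15s} {row}")
# sibling cancers share most of their ancestry (high similarity); diabetes
# shares only the root (low similarity).
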