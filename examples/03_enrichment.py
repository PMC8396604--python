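"""Hypergeometric term enrichment of a small query set.

Builds a toy annotation map over a 50-gene background, queries a gene set
concentrated in one term, and prints the enrichment table.
"""
from chptools.enrichment import AnnotationMap, hypergeom_enrich

background = {f"g{i:02d}" for i in range(50)}
annotations = AnnotationMap.build(
    {
        "adhesion": {f"g{i:02d}" for i in range(0, 10)},
        "splicing": {f"g{i:02d}" for i in range(10, 18)},
        "transport": {f"g{i:02d}" for i in range(18, 30)},
    },
    background,
)
query = {"g00", "g01", "g02", "g03", "g04", "g20", "g45"}

result = hypergeom_enrich(query, annotations)
print(result.to_string(index=False, float_format=lambda x: f"{x:.4g}"))
# k of K annotated genes hit by the n-gene query against N background genes;
# p is the upper-tail hypergeometric probability, p_bh its BH adjustment.
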