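"""Hypergeometric term enrichment with BH correction.

A study set enriched for one term out of three: the enriched term gets a
small p and q value, the others stay near 1.
"""

import cosplice as cs

universe = [f"g{i}" for i in range(50)]
term_map = {
    "GO:splicing": set(universe[:10]),
    "GO:photosynthesis": set(universe[10:25]),
    "GO:transport": set(universe[25:]),
}
study = universe[:8] + universe[30:32]  # 8 of 10 splicing genes

res = cs.hypergeom_enrich(study, universe, term_map)
print(res.round(5).to_string(index=False))
print("k of K annotated genes fell in the n-gene study set out of N; the "
      "p-value is the upper hypergeometric tail, q the BH-adjusted FDR.")
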