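"""Place species without reference sequences into a 16S tree.

Two placements are shown: a species whose genus has a single leaf in the
tree (midpoint mechanism: the anchor's branch is split in half) and one
whose genus has several leaves (maximization mechanism: every node is
scored by clade purity + inclusiveness of the congeners and the best
node above the 60% inclusiveness floor receives the new leaf).
"""

import taxdiv as td
from taxdiv.graft import reports_to_tsv

# taxonomy: genus A with 4 species, genus B with 2; the tree only knows
# three of genus A's species and one of genus B's
tax, by_genus = td.random_taxonomy([4, 2], seed=2)
genus_a, genus_b = by_genus
tree = td.read_newick(
    f"(({genus_a[0]}:0.05,{genus_a[1]}:0.06,{genus_a[2]}:0.04):0.9,"
    f"{genus_b[0]}:0.95);"
)

missing = [genus_a[3], genus_b[1]]
augmented, reports = td.augment_tree(tree, tax, missing)

print("leaves before:", sorted(tree.leaf_labels()))
print("grafted      :", [str(m) for m in missing])
print(reports_to_tsv(reports))
print("augmented tree:", augmented.to_newick().strip())

# genus_b's second species lands by the midpoint rule next to its lone
# congener; genus_a's fourth species attaches under the genus-A clade,
# whose score (purity 1, inclusiveness 1) dominates every other node,
# with a branch equal to the mean congener depth within that clade.
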