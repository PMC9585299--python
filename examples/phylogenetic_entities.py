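"""Branch-abundance aggregation and phylogenetic Hill numbers, step by step.

Uses a hand-checkable 3-tip tree: every quantity printed here can be
verified with pencil and paper.
"""

from divgrad import branch_abundances, hill_phylo, parse_newick, prune_to

tree = parse_newick("((A:1,B:1):1,C:2);")
abund = {"A": 0.25, "B": 0.25, "C": 0.5}

bas = branch_abundances(tree, abund)
print("branch (length, descendant abundance) pairs:")
for L, a in sorted(zip(bas.lengths, bas.abundances)):
    print(f"  L={L:.1f}  a={a:.2f}")
print(f"abundance-weighted depth T-bar = {bas.T_bar:.1f}")

for q in (0, 1, 2):
    mean, total = hill_phylo(bas, q)
    print(f"q={q}: mean diversity {mean:.4f} lineages, "
          f"total PD {total:.4f} branch-length units")
print()
print("At q=0 total PD (5.0) is Faith's PD: the summed length of all")
print("branches leading to present taxa. Higher q discounts rare lineages.")

pruned = prune_to(tree, {"A", "C"})
print("\npruned to {A, C}:", pruned.as_string(schema="newick").strip())
print("(the unbranched node above A collapsed; root-to-tip depths kept)")
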