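"""Organize sibling pairs into Distinct Parent Groups (DPGs).

Each larva has two unobserved parents; full-sib edges force both to
coincide, half-sib edges exactly one.  The assignment minimizes the
number of distinct parents subject to the pairwise constraints and to a
consistent sexing of the parent labels.
"""

import networkx as nx

from larvkin import sibgraph

g = nx.Graph()
# a chain: A,B full sibs; C half-sib of both; C-D half sibs; E isolated
for i, j, cls in [("A", "B", "FSP"), ("A", "C", "HSP"), ("B", "C", "HSP"), ("C", "D", "HSP")]:
    g.add_edge(i, j, kin_class=cls)
g.add_node("E")

assignment = sibgraph.assign_parents(g)
print("parent labels per larva:", assignment.slots)
print("groups:", {k: v for k, v in assignment.groups.items()})
tab = sibgraph.tabulate_dpgs(assignment, cohort=2024)
print(f"\ng_s (groups of size 1, 2, ...): {[int(x) for x in tab.g_s]}")
print(f"m_J={tab.m_J}  PotNP=2*m_J={tab.pot_np}  NDP=sum(g_s)={tab.ndp}")
# PotNP is the parent count if every larva were unrelated; NDP < PotNP
# measures how much sibship has collapsed the parent pool.
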