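"""Distinct Parent Groups (DPGs) from pairwise sibling calls.

Each larva has exactly two (unobserved) parents, i.e. two "parent slots".
A full-sibling edge forces both slots of the two larvae to coincide, a
half-sibling edge exactly one, and an unrelated pair none.  Organizing
pairwise FSP/HSP calls into DPGs therefore amounts to merging slots into
groups subject to those constraints; among all feasible merge patterns we
return one minimizing the number of distinct parents (parsimony), which
is the right resolution when the adult population is vastly larger than
the number of coincidental co-parentages.

The search is exact (branch and bound over larvae in deterministic
order) for components up to ``max_exact`` larvae and greedy first-feasible
above; observed sibship components are small, so the exact path is the
one that runs in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SibshipConflictError",
    "ParentAssignment",
    "DPGTabulation",
    "build_sibgraph",
    "assign_parents",
    "tabulate_dpgs",
    "tabulate_from_parent_map",
    "chain_summary",
]


class SibshipConflictError(ValueError):
    """Pairwise kin calls admit no consistent parent assignment."""

    def __init__(self, message: str, edges: list):
        super().__init__(message)
        self.edges = edges


@dataclass
class ParentAssignment:
    """Map from each larva to its two abstract parent labels.

    ``slots[larva] = (label_a, label_b)`` with distinct labels;
    ``groups[label]`` lists the member larvae of that distinct parent.
    """

    slots: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)

    def shared_parents(self, i, j) -> int:
        return len(set(self.slots[i]) & set(self.slots[j]))

    @property
    def n_distinct_parents(self) -> int:
        return len(self.groups)


@dataclass
class DPGTabulation:
    """Counts ``g_s`` of distinct-parent groups by size ``s``.

    Identities: ``sum(s * g_s) = 2 * m_J`` (each larva contributes two
    parent slots), ``PotNP = 2 * m_J``, ``NDP = sum(g_s)``.
    """

    cohort: object
    g_s: np.ndarray  # g_s[k] = number of groups of size k+1
    m_J: int

    def __post_init__(self) -> None:
        self.g_s = np.asarray(self.g_s, dtype=np.int64)
        if (self.g_s < 0).any():
            raise ValueError("group-size counts must be non-negative")
        s = np.arange(1, len(self.g_s) + 1)
        if int((s * self.g_s).sum()) != 2 * self.m_J:
            raise ValueError(
                f"sum s*g_s = {(s * self.g_s).sum()} != 2*m_J = {2 * self.m_J}"
            )

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, len(self.g_s) + 1)

    @property
    def pot_np(self) -> int:
        return 2 * self.m_J

    @property
    def ndp(self) -> int:
        return int(self.g_s.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cohort": self.cohort, "s": self.sizes, "g_s": self.g_s})


KIN_EDGE_CLASSES = ("FSP", "HSP")


def build_sibgraph(
    kin_pairs: pd.DataFrame, sample_meta: pd.DataFrame
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Per-cohort sibship graphs plus the cross-cohort HSP list.

    Within-cohort FSP/HSP calls become edges of that cohort's graph
    (every retained sample is a node, so isolated larvae are counted);
    cross-cohort HSPs are returned separately; cross-cohort FSP calls are
    biologically anomalous and returned as a third table rather than
    silently accepted.
    """
    cohort = sample_meta.set_index("sample_id")["cohort_year"].to_dict()
    graphs: dict = {}
    for sid, cy in cohort.items():
        graphs.setdefault(cy, nx.Graph()).add_node(sid)

    seen: dict = {}
    cross_hsp, anomalies = [], []
    kin = kin_pairs[kin_pairs["kin_class"].isin(KIN_EDGE_CLASSES)]
    for row in kin.itertuples(index=False):
        i, j, cls = row.sample_i, row.sample_j, row.kin_class
        key = (i, j) if i <= j else (j, i)
        if key in seen and seen[key] != cls:
            raise ValueError(f"conflicting duplicate kin records for pair {key}")
        seen[key] = cls
        ci, cj = cohort[i], cohort[j]
        if ci == cj:
            graphs[ci].add_edge(i, j, kin_class=cls, plod=getattr(row, "plod", np.nan))
        elif cls == "HSP":
            cross_hsp.append({"sample_i": i, "sample_j": j, "cohort_i": ci, "cohort_j": cj})
        else:
            anomalies.append(
                {"sample_i": i, "sample_j": j, "cohort_i": ci, "cohort_j": cj, "kin_class": cls}
            )
    cross_cols = ["sample_i", "sample_j", "cohort_i", "cohort_j"]
    return (
        graphs,
        pd.DataFrame(cross_hsp, columns=cross_cols),
        pd.DataFrame(anomalies, columns=cross_cols + ["kin_class"]),
    )


def _two_colorable(edges) -> bool:
    """Can the groups be assigned sexes so each larva has one of each?

    ``edges`` are the (group_a, group_b) slot pairs of placed larvae; the
    two groups of a larva must take opposite sexes, so the group graph
    must be bipartite.
    """
    color: dict = {}
    adj: dict = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    for start in adj:
        if start in color:
            continue
        color[start] = 0
        stack = [start]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in color:
                    color[w] = 1 - color[u]
                    stack.append(w)
                elif color[w] == color[u]:
                    return False
    return True


def _component_assign(graph: nx.Graph, nodes: list, max_exact: int):
    """Minimum-NDP slot assignment for one connected component.

    Returns ``(slots, n_groups)`` or ``None`` when infeasible.  Exact
    branch-and-bound up to ``max_exact`` larvae; greedy first-feasible
    with cheapest merges first (no inter-larva backtracking) above.
    Candidates must respect the pairwise shared-slot counts *and* keep
    the group graph two-colorable (every larva has one mother and one
    father, so group labels must admit a consistent sexing).
    """
    order = list(nx.bfs_tree(graph.subgraph(nodes), min(nodes)))
    exact = len(nodes) <= max_exact

    best: list = [None, np.inf]  # [slots, n_groups]
    budget = [500_000]  # consistency-check budget; exhaustion => give up

    members: dict = {}  # group label -> list of larvae owning a slot in it

    def req(v, u) -> int:
        data = graph.get_edge_data(v, u)
        return {"FSP": 2, "HSP": 1}.get(data["kin_class"], 0) if data else 0

    def consistent(v, pair, slotg):
        budget[0] -= 1
        # shared-slot count per placed larva owning a candidate group; any
        # larva not owning one shares 0, which only neighbours can violate
        cnt: dict = {}
        for g in pair:
            for u in members.get(g, ()):
                cnt[u] = cnt.get(u, 0) + 1
        for u, c in cnt.items():
            if req(v, u) != c:
                return False
        for u in graph[v]:
            if u in slotg and u not in cnt:
                return False  # placed sibling must share at least one group
        return _two_colorable(list(slotg.values()) + [pair])

    def candidates_for(v, k, slotg, n_groups):
        placed_nbrs = [u for u in graph[v] if u in slotg]
        fsp_nbrs = [u for u in placed_nbrs if graph[v][u]["kin_class"] == "FSP"]
        existing = sorted({g for u in placed_nbrs for g in slotg[u]})
        if fsp_nbrs:
            return [tuple(sorted(slotg[fsp_nbrs[0]]))], existing
        # a candidate group shared with any non-neighbour is inconsistent, so
        # only groups of placed neighbours (or fresh labels) can appear
        cands = []
        for a_i in range(len(existing)):
            for b_i in range(a_i + 1, len(existing)):
                cands.append((existing[a_i], existing[b_i]))
        new1, new2 = n_groups + 10**9, n_groups + 10**9 + 1  # fresh labels
        for a in existing:
            cands.append((a, new1))
        cands.append((new1, new2))
        # cheaper merges (fewer new groups) first
        cands.sort(key=lambda pr: sum(g not in existing for g in pr))
        return cands, existing

    def place(v, pair):
        for g in pair:
            members.setdefault(g, []).append(v)

    def unplace(v, pair):
        for g in pair:
            members[g].remove(v)
            if not members[g]:
                del members[g]

    def recurse(k, slotg, n_groups):
        if n_groups >= best[1] or budget[0] <= 0:
            return
        if k == len(order):
            best[0] = dict(slotg)
            best[1] = n_groups
            return
        v = order[k]
        cands, existing = candidates_for(v, k, slotg, n_groups)
        for pair in cands:
            if pair[0] == pair[1] or not consistent(v, pair, slotg):
                continue
            cost = sum(g not in existing for g in pair)
            slotg[v] = pair
            place(v, pair)
            recurse(k + 1, slotg, n_groups + cost)
            unplace(v, pair)
            del slotg[v]

    def greedy():
        slotg: dict = {}
        n_groups = 0
        for k, v in enumerate(order):
            cands, existing = candidates_for(v, k, slotg, n_groups)
            placed_ok = False
            for pair in cands:
                if pair[0] == pair[1] or not consistent(v, pair, slotg):
                    continue
                slotg[v] = pair
                place(v, pair)
                n_groups += sum(g not in existing for g in pair)
                placed_ok = True
                break
            if not placed_ok:
                return  # dead end: surface as a conflict
        best[0] = slotg
        best[1] = n_groups

    if exact:
        recurse(0, {}, 0)
    else:
        greedy()
    if best[0] is None:
        return None
    # relabel groups compactly and deterministically
    labels: dict = {}
    slots = {}
    for v in order:
        pair = []
        for g in best[0][v]:
            labels.setdefault(g, len(labels))
            pair.append(labels[g])
        slots[v] = tuple(pair)
    return slots, best[1]


def assign_parents(graph: nx.Graph, max_exact: int = 12) -> ParentAssignment:
    """Parsimonious parent labels for every larva in the graph.

    FSP edges merge both slot pairs, HSP edges exactly one slot of each
    endpoint, absent (UP) pairs share no label, and each larva's two
    slots map to distinct labels.  Among feasible assignments one with
    the minimum number of distinct parents is returned (exact for
    components up to ``max_exact`` larvae).  Raises
    :class:`SibshipConflictError` listing the component's edges when no
    feasible assignment exists.
    """
    assignment = ParentAssignment()
    next_label = 0
    for nodes in sorted(nx.connected_components(graph), key=lambda c: min(c)):
        nodes = sorted(nodes)
        if len(nodes) == 1:
            v = nodes[0]
            assignment.slots[v] = (next_label, next_label + 1)
            next_label += 2
            continue
        res = _component_assign(graph, nodes, max_exact)
        if res is None:
            edges = [
                (u, w, graph[u][w]["kin_class"])
                for u, w in graph.subgraph(nodes).edges
            ]
            raise SibshipConflictError(
                f"no consistent parent assignment for component {nodes}", edges
            )
        slots, _ = res
        for v in sorted(slots):
            a, b = slots[v]
            assignment.slots[v] = (a + next_label, b + next_label)
        next_label += 1 + max(g for pr in slots.values() for g in pr)
    for v, (a, b) in assignment.slots.items():
        assignment.groups.setdefault(a, []).append(v)
        assignment.groups.setdefault(b, []).append(v)
    return assignment


def resolve_conflicts(graph: nx.Graph, reference=None, max_exact: int = 12) -> nx.Graph:
    """Drop the weakest edge (smallest |PLOD - cutoff| margin) of a
    conflicting component until assignment becomes feasible.

    Only applied when explicitly called: conflicts normally indicate
    upstream misclassification and should surface, not be hidden.
    """
    g = graph.copy()
    while True:
        try:
            assign_parents(g, max_exact=max_exact)
            return g
        except SibshipConflictError as err:
            def margin(e):
                plod = g[e[0]][e[1]].get("plod", np.nan)
                return abs(plod) if np.isfinite(plod) else np.inf

            weakest = min(err.edges, key=lambda e: (margin(e), e[:2]))
            g.remove_edge(weakest[0], weakest[1])


def tabulate_dpgs(assignment: ParentAssignment, cohort) -> DPGTabulation:
    """Group-size tabulation ``g_s`` for one cohort's assignment."""
    sizes = np.array([len(v) for v in assignment.groups.values()], dtype=int)
    m_j = len(assignment.slots)
    if len(sizes) == 0:
        return DPGTabulation(cohort, np.zeros(0, dtype=int), 0)
    g = np.bincount(sizes, minlength=sizes.max() + 1)[1:]
    return DPGTabulation(cohort, g, m_j)


def tabulate_from_parent_map(parent_map: dict, cohort) -> DPGTabulation:
    """Tabulation computed directly from true (mother, father) identities.

    ``parent_map[larva] = (mother_id, father_id)``; the ground-truth
    counterpart of :func:`tabulate_dpgs` for simulation recovery tests.
    """
    counts: dict = {}
    for larva, (m, f) in parent_map.items():
        counts[("M", m)] = counts.get(("M", m), 0) + 1
        counts[("F", f)] = counts.get(("F", f), 0) + 1
    sizes = np.array(list(counts.values()), dtype=int)
    g = np.bincount(sizes, minlength=sizes.max() + 1)[1:] if len(sizes) else np.zeros(0, int)
    return DPGTabulation(cohort, g, len(parent_map))


def chain_summary(graph: nx.Graph) -> pd.DataFrame:
    """Connected-component summary: larvae, edges and class mix per chain."""
    rows = []
    for nodes in sorted(nx.connected_components(graph), key=lambda c: min(c)):
        sub = graph.subgraph(nodes)
        classes = [d["kin_class"] for _, _, d in sub.edges(data=True)]
        rows.append(
            {
                "component": min(nodes),
                "n_larvae": len(nodes),
                "n_edges": sub.number_of_edges(),
                "n_fsp": classes.count("FSP"),
                "n_hsp": classes.count("HSP"),
            }
        )
    return pd.DataFrame(rows, columns=["component", "n_larvae", "n_edges", "n_fsp", "n_hsp"])
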