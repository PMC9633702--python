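"""Independent brute-force oracles used by the test suite.

These deliberately re-derive pair-genotype probabilities by enumerating
pedigree structures (parent genotypes and transmitted gametes) rather
than using the IBD-mixture formula, so that agreement with the library
is a genuine cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np


def hwe(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def _allele_probs(g: int) -> list[tuple[int, float]]:
    """Probability of transmitting each allele given a parent genotype."""
    return [(0, 1 - g / 2), (1, g / 2)]


def _pop_allele(p: float) -> list[tuple[int, float]]:
    return [(0, 1 - p), (1, p)]


def enum_pair_table(relationship: str, p: float) -> np.ndarray:
    """Joint genotype table for a pair, by explicit pedigree enumeration."""
    tab = np.zeros((3, 3))
    H = hwe(p)
    if relationship == "UP":
        tab = np.outer(H, H)
    elif relationship == "HSP":
        # one shared parent; each child: one gamete from it + one from the
        # population
        for gp in range(3):
            for (a1, pa1), (b1, pb1), (a2, pa2), (b2, pb2) in itertools.product(
                _allele_probs(gp), _pop_allele(p), _allele_probs(gp), _pop_allele(p)
            ):
                tab[a1 + b1, a2 + b2] += H[gp] * pa1 * pb1 * pa2 * pb2
    elif relationship == "FSP":
        # both parents shared; each child draws one gamete from each
        for gm in range(3):
            for gf in range(3):
                w = H[gm] * H[gf]
                for (a1, pa1), (b1, pb1), (a2, pa2), (b2, pb2) in itertools.product(
                    _allele_probs(gm), _allele_probs(gf), _allele_probs(gm), _allele_probs(gf)
                ):
                    tab[a1 + b1, a2 + b2] += w * pa1 * pb1 * pa2 * pb2
    elif relationship == "POP":
        # parent and its child: child gets one of the parent's alleles
        for gp in range(3):
            for (a, pa), (b, pb) in itertools.product(_allele_probs(gp), _pop_allele(p)):
                tab[gp, a + b] += H[gp] * pa * pb
    elif relationship == "DUP":
        # the same individual genotyped twice
        for g in range(3):
            tab[g, g] += H[g]
    else:
        raise ValueError(relationship)
    return tab


def flip_channel(e: float) -> np.ndarray:
    """P(observed | true) by enumerating independent per-allele miscalls."""
    out = np.zeros((3, 3))
    for t in range(3):
        alleles = [1] * t + [0] * (2 - t)
        for f1 in (0, 1):
            for f2 in (0, 1):
                pr = (e if f1 else 1 - e) * (e if f2 else 1 - e)
                obs = (alleles[0] ^ f1) + (alleles[1] ^ f2)
                out[t, obs] += pr
    return out


def enum_pair_table_with_error(relationship: str, p: float, e: float) -> np.ndarray:
    true = enum_pair_table(relationship, p)
    E = flip_channel(e)
    return E.T @ true @ E


def min_ndp_exhaustive(edges: dict, nodes: list, node_cap: int = 2_000_000) -> int:
    """Minimum number of distinct parents by exhaustive slot partitioning.

    ``edges[(i, j)]`` (i < j) is "FSP" or "HSP"; missing pairs are
    unrelated.  Every larva contributes two slots; a feasible partition
    gives each larva two distinct blocks, pairwise shared-block counts
    matching the edge classes, and a two-colorable (sexable) block
    graph.  Enumerates restricted-growth partitions of the slot list
    with early pruning; independent of the library's search strategy.
    """
    n = len(nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    req = np.zeros((n, n), dtype=int)
    for (i, j), cls in edges.items():
        a, b = idx[i], idx[j]
        req[a, b] = req[b, a] = {"FSP": 2, "HSP": 1}[cls]

    best = [2 * n]
    counter = [0]

    def colorable(pairs):
        color, adj = {}, {}
        for a, b in pairs:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
        for s in adj:
            if s in color:
                continue
            color[s] = 0
            stack = [s]
            while stack:
                u = stack.pop()
                for w in adj[u]:
                    if w not in color:
                        color[w] = 1 - color[u]
                        stack.append(w)
                    elif color[w] == color[u]:
                        return False
        return True

    def rec(slot, blocks, owner_pairs):
        counter[0] += 1
        if counter[0] > node_cap:
            raise RuntimeError("exhaustive oracle budget exceeded")
        if len(blocks) >= best[0]:
            return
        if slot == 2 * n:
            if colorable(owner_pairs):
                best[0] = len(blocks)
            return
        larva = slot // 2
        second = slot % 2 == 1
        options = list(range(len(blocks) + 1))
        for choice in options:
            if choice == len(blocks):
                new_blocks = blocks + [[larva]]
            else:
                new_blocks = [list(b) for b in blocks]
                new_blocks[choice].append(larva)
            # a larva's two slots must land in different blocks
            if second:
                first_block = my_block[larva]
                if choice == first_block:
                    continue
            # pairwise constraint check against fully-placed larvae
            ok = True
            if second:
                pair = (my_block[larva], choice if choice < len(blocks) else len(blocks))
                for other in range(larva):
                    shared = sum(
                        1
                        for b in pair
                        for ob in (my_block[other], my_block2[other])
                        if b == ob
                    )
                    if shared != req[larva, other]:
                        ok = False
                        break
            else:
                # partial check: sharing with a non-sib already violates
                if choice < len(blocks):
                    for other in range(larva):
                        shared = sum(
                            1 for ob in (my_block[other], my_block2[other]) if ob == choice
                        )
                        if shared > req[larva, other]:
                            ok = False
                            break
            if not ok:
                continue
            if second:
                my_block2[larva] = choice if choice < len(blocks) else len(blocks)
                rec(slot + 1, new_blocks, owner_pairs + [(my_block[larva], my_block2[larva])])
                my_block2[larva] = -1
            else:
                my_block[larva] = choice if choice < len(blocks) else len(blocks)
                rec(slot + 1, new_blocks, owner_pairs)
                my_block[larva] = -1

    my_block = [-1] * n
    my_block2 = [-1] * n
    rec(0, [], [])
    return best[0]
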