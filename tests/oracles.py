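"""Independent brute-force oracles used by the test suite.

These enumerate every internal-state assignment explicitly — no pruning, no
shared code with the engine under test — so they are exponentially slow and
only run on tiny trees and alignments.
"""

from itertools import product

import numpy as np

from bdmshift.engine import encode_states
from bdmshift.models import N_STATES


def _node_transition_cache(tree, model, rates):
    return {
        node.index: [model.transition_matrix(node.length, r) for r in rates.rates]
        for node in tree.postorder()
        if node.parent is not None
    }


def enumerate_site_likelihoods(aln, tree, model, rates):
    """Per-site likelihoods by exhaustive summation over internal states."""
    states = encode_states(aln)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    order = [n for n in tree.postorder() if n.parent is not None]
    P = _node_transition_cache(tree, model, rates)
    root = tree.root.index
    site_liks = []
    for site in range(aln.L):
        site_total = 0.0
        for cat in range(rates.k):
            cat_total = 0.0
            for assignment in product(range(N_STATES), repeat=len(internals)):
                amap = {n.index: s for n, s in zip(internals, assignment)}
                for leaf in tree.leaves:
                    amap[leaf.index] = states[leaf.name][site]
                p = model.pi[amap[root]] if not tree.root.is_leaf else model.pi[
                    states[tree.root.name][site]
                ]
                for node in order:
                    s = amap[node.index]
                    if s < 0:  # gap/missing: sums to 1 over all states
                        continue
                    p *= P[node.index][cat][amap[node.parent.index], s]
                cat_total += p
            site_total += cat_total / rates.k
        site_liks.append(site_total)
    return np.array(site_liks)


def enumerate_marginal_posteriors(aln, tree, model, rates, node_index):
    """Posterior state distribution at one internal node per site, by
    exhaustive Bayes over all internal-state assignments."""
    states = encode_states(aln)
    internals = [n for n in tree.postorder() if not n.is_leaf]
    order = [n for n in tree.postorder() if n.parent is not None]
    P = _node_transition_cache(tree, model, rates)
    root = tree.root.index
    posts = np.zeros((aln.L, N_STATES))
    for site in range(aln.L):
        joint = np.zeros(N_STATES)
        for cat in range(rates.k):
            for assignment in product(range(N_STATES), repeat=len(internals)):
                amap = {n.index: s for n, s in zip(internals, assignment)}
                for leaf in tree.leaves:
                    amap[leaf.index] = states[leaf.name][site]
                p = model.pi[amap[root]]
                for node in order:
                    s = amap[node.index]
                    if s < 0:
                        continue
                    p *= P[node.index][cat][amap[node.parent.index], s]
                joint[amap[node_index]] += p / rates.k
        posts[site] = joint / joint.sum()
    return posts


def fisher_tail_exact(a, b, c, d):
    """P(X >= a), X ~ Hypergeom, by exact integer arithmetic."""
    from math import comb

    n = a + b + c + d
    row1, col1 = a + b, a + c
    num = sum(
        comb(col1, x) * comb(n - col1, row1 - x)
        for x in range(a, min(row1, col1) + 1)
        if row1 - x <= n - col1
    )
    return num / comb(n, row1)


def reroot_newick(newick_text, edge_index):
    """Reroot an unrooted tree along one of its edges via dendropy."""
    import dendropy

    tree = dendropy.Tree.get(data=newick_text, schema="newick")
    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node]
    edge = edges[edge_index % len(edges)]
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    return tree.as_string(schema="newick", suppress_rooting=True)
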