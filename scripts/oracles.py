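"""Brute-force oracles shared by the acceptance script.

Kept independent of the package implementations they check: average
linkage is recomputed naively from the original distance matrix at every
merge instead of via Lance-Williams updates.
"""

import numpy as np


def naive_upgma_heights(D, ids):
    clusters = [[i] for i in range(len(ids))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                lab = tuple(sorted((min(ids[i] for i in clusters[a]),
                                    min(ids[j] for j in clusters[b]))))
                if best is None or (d, lab) < best[0]:
                    best = ((d, lab), a, b)
        (d, _), a, b = best
        heights.append(d / 2.0)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def tree_heights(node, acc=None):
    acc = [] if acc is None else acc
    if not node.is_leaf:
        acc.append(node.height)
        for c in node.children:
            tree_heights(c, acc)
    return acc
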