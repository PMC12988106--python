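"""The molecular relatedness tree.

All-pairs composite similarity over aligned features, conversion to a
distance matrix (d = 1 - s), hierarchical clustering (UPGMA by default,
neighbour joining as an alternative), a k-stage cut mirroring the three
hydrothermal transformation stages, per-stage clade profiles by compound
family / vent activity / vent field, and Newick plus ring-annotation
export. The tree is phylogeny-inspired — a statistical clustering of
fragmentation fingerprints, not a biological phylogeny — so the default
method is distance-based average linkage.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AlignedFeature, AnnotationConfig, Spectrum, total_similarity
from .errors import ConfigurationError, NewickParseError

RING_COLUMNS = ("feature_id", "stage", "activity", "vent_field",
                "class_label", "annotation")


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal
    n_pairs: int


def pairwise_matrix(
    features: list[AlignedFeature] | list[tuple[str, Spectrum]],
    cfg: AnnotationConfig | None = None,
) -> SimilarityMatrix:
    """Composite total similarity for every unordered feature pair."""
    cfg = cfg or AnnotationConfig()
    items: list[tuple[str, Spectrum]] = []
    for f in features:
        if isinstance(f, AlignedFeature):
            if f.representative is None:
                raise ConfigurationError(f"feature {f.feature_id} lacks a representative")
            items.append((f.feature_id, f.representative))
        else:
            items.append(f)
    n = len(items)
    if n < 2:
        raise ConfigurationError("need at least two features")
    S = np.eye(n)
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = total_similarity(items[i][1], items[j][1], cfg).total
            S[i, j] = S[j, i] = s
            n_pairs += 1
    return SimilarityMatrix([i for i, _ in items], S, n_pairs)


def to_distance(S: SimilarityMatrix) -> np.ndarray:
    """d = 1 - s elementwise; zero diagonal."""
    D = 1.0 - S.values
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """A rooted (binary for UPGMA) merge-tree node.

    ``height`` is the merge height (distance from this node down to any of
    its leaves for an ultrametric tree); leaves have height 0.
    """

    name: str | None = None
    children: list["Node"] = field(default_factory=list)
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def internal_nodes(self) -> list["Node"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out


@dataclass
class RelatednessTree:
    root: Node
    method: str = "upgma"

    def leaves(self) -> list[str]:
        return self.root.leaves()


def _check_distance(D: np.ndarray, n: int):
    D = np.asarray(D, dtype=float)
    if D.shape != (n, n):
        raise ConfigurationError("distance matrix shape mismatch")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ConfigurationError("distance matrix must be symmetric")
    return D


def upgma(D: np.ndarray, ids: list[str]) -> Node:
    """Average-linkage agglomeration; merge height = distance / 2.

    Ties are broken by the lexicographically smallest pair of cluster
    labels, a cluster being labelled by its smallest member id, which
    makes the tree invariant to input order.
    """
    n = len(ids)
    D = _check_distance(D, n).copy()
    nodes = {i: Node(name=ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    labels = {i: ids[i] for i in range(n)}
    active = set(range(n))
    dist = {(min(i, j), max(i, j)): D[i, j]
            for i in range(n) for j in range(i + 1, n)}
    nxt = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = dist[(i, j)]
                pair_label = tuple(sorted((labels[i], labels[j])))
                key = (d, pair_label)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _), i, j = best
        d = dist[(i, j)]
        child_a, child_b = sorted((nodes[i], nodes[j]),
                                  key=lambda nd: min(nd.leaves()))
        merged = Node(children=[child_a, child_b], height=d / 2.0)
        nodes[nxt] = merged
        sizes[nxt] = sizes[i] + sizes[j]
        labels[nxt] = min(labels[i], labels[j])
        active.discard(i)
        active.discard(j)
        for k in active:
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(k, nxt), max(k, nxt))] = dnew
        active.add(nxt)
        nxt += 1
    return nodes[next(iter(active))]


def _nj(D: np.ndarray, ids: list[str]) -> Node:
    """Neighbour joining via scikit-bio, re-rooted at its top node."""
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    tree = skbio_nj(DistanceMatrix(_check_distance(D, len(ids)), ids))
    return _from_skbio(tree)


def _from_skbio(t) -> Node:
    if t.is_tip():
        return Node(name=t.name)
    children = [_from_skbio(c) for c in t.children]
    # height of an internal node: max child height + child branch length
    height = 0.0
    for c, cc in zip(t.children, children):
        height = max(height, cc.height + (c.length or 0.0))
    return Node(children=children, height=height)


def build_tree(D: np.ndarray, ids: list[str], method: str = "upgma") -> RelatednessTree:
    """Hierarchical tree over features (UPGMA default, NJ alternative)."""
    if method == "upgma":
        return RelatednessTree(upgma(D, ids), "upgma")
    if method == "nj":
        return RelatednessTree(_nj(D, ids), "nj")
    raise ConfigurationError(f"unknown tree method: {method!r}")


# ---------------------------------------------------------------------------
# stages and profiles
# ---------------------------------------------------------------------------

@dataclass
class StageAssignment:
    stages: dict[str, int]  # leaf -> 1..k
    clades: list[list[str]]  # leaves per stage, stage order


def cut_stages(
    tree: RelatednessTree,
    k: int = 3,
    metadata: pd.DataFrame | None = None,
    anchor_class: str = "alkane",
) -> StageAssignment:
    """Cut into exactly k subtrees at the k-1 highest merges.

    Stages are numbered in circular leaf order starting from the clade
    richest in ``anchor_class`` compounds (Stage 1 of the published tree
    is the alkane-dominated clade); without metadata, numbering starts at
    the first clade in leaf order.
    """
    leaves = tree.leaves()
    n = len(leaves)
    if not 1 <= k <= n:
        raise ConfigurationError("k must lie in [1, n]")
    frontier: list[Node] = [tree.root]
    while len(frontier) < k:
        # split the internal node with the greatest height; tie: leftmost
        cand = [nd for nd in frontier if not nd.is_leaf]
        if not cand:
            break
        top = max(cand, key=lambda nd: nd.height)
        pos = frontier.index(top)
        frontier[pos:pos + 1] = top.children
    clades = [nd.leaves() for nd in frontier]

    start = 0
    if metadata is not None and len(clades) > 1:
        cls = metadata.set_index("feature_id")["class_label"]
        richness = []
        for c in clades:
            labels = [cls.get(leaf) for leaf in c]
            richness.append(sum(1 for x in labels if x == anchor_class) / len(c))
        start = int(np.argmax(richness))
    ordered = clades[start:] + clades[:start]
    stages = {}
    for s, clade in enumerate(ordered, start=1):
        for leaf in clade:
            stages[leaf] = s
    return StageAssignment(stages, ordered)


@dataclass
class CladeProfile:
    clade_id: int
    size: int
    class_counts: dict[str, int]
    activity_counts: dict[str, int]
    field_counts: dict[str, int]

    def proportions(self, which: str) -> dict[str, float]:
        counts = getattr(self, f"{which}_counts")
        total = sum(counts.values())
        return {k: v / total for k, v in counts.items()} if total else {}


def clade_profiles(
    tree: RelatednessTree,
    stages: StageAssignment,
    metadata: pd.DataFrame,
) -> list[CladeProfile]:
    """Per-stage counts and proportions by class, activity and vent field.

    ``metadata`` needs columns feature_id, class_label, activity, vent_field.
    """
    meta = metadata.set_index("feature_id")
    missing = [leaf for leaf in tree.leaves() if leaf not in meta.index]
    if missing:
        raise ConfigurationError(f"metadata missing for leaf {missing[0]!r}")
    profiles = []
    for s, clade in enumerate(stages.clades, start=1):
        sub = meta.loc[clade]
        profiles.append(CladeProfile(
            s, len(clade),
            sub["class_label"].value_counts().to_dict(),
            sub["activity"].value_counts().to_dict(),
            sub["vent_field"].value_counts().to_dict(),
        ))
    return profiles


# ---------------------------------------------------------------------------
# Newick I/O and ring annotations
# ---------------------------------------------------------------------------

def _escape(name: str) -> str:
    if any(ch in name for ch in " ,():;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: RelatednessTree) -> str:
    """Serialize with branch lengths = parent height - child height."""
    def render(node: Node, parent_height: float | None) -> str:
        if node.is_leaf:
            body = _escape(node.name)
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - node.height:.12g}"

    return render(tree.root, None) + ";"


def read_newick(text: str) -> RelatednessTree:
    """Parse Newick (via scikit-bio) back into a height-annotated tree."""
    from skbio import TreeNode

    try:
        t = TreeNode.read(_io.StringIO(text))
    except Exception as exc:  # skbio raises several parse error types
        pos = getattr(exc, "pos", None)
        raise NewickParseError(str(exc), pos) from exc
    return RelatednessTree(_from_skbio(t))


def export_ring_annotations(
    tree: RelatednessTree,
    stages: StageAssignment,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """One row per leaf, in tree leaf order, for concentric-ring displays."""
    meta = metadata.set_index("feature_id")
    rows = []
    for leaf in tree.leaves():
        if leaf not in meta.index:
            raise ConfigurationError(f"metadata missing for leaf {leaf!r}")
        m = meta.loc[leaf]
        rows.append({
            "feature_id": leaf,
            "stage": stages.stages[leaf],
            "activity": m["activity"],
            "vent_field": m["vent_field"],
            "class_label": m["class_label"],
            "annotation": m.get("annotation", ""),
        })
    return pd.DataFrame(rows, columns=RING_COLUMNS)
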