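"""Gene trees, monophyly tests and Dollo ancestral domain reconstruction.

Desk-scale phylogenetics for the comparative stage: Poisson-corrected
distances from pairwise alignments, neighbor-joining gene trees, an unrooted
monophyly test for the SMP-vs-non-SMP question, and parsimony reconstruction
of ancestral domain presence on the fixed five-taxon conchiferan species
tree (Nautilus,((Lottia,Euhadra),(Crassostrea,Pinctada))). Dollo parsimony
— a single gain per character, losses free — is the default model behind the
"ancestral conchiferan" domain set; unweighted Fitch parsimony is available
as an alternative.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .homology_coresets import PresenceMatrix, local_align

MAX_DISTANCE = 10.0  # cap when the Poisson correction diverges (p >= 19/20)

SPECIES = ("Nautilus", "Lottia", "Euhadra", "Crassostrea", "Pinctada")
MARINE_SPECIES = ("Nautilus", "Lottia", "Crassostrea", "Pinctada")
ROOT_LABEL = "Ancestral_Conchiferan"


def load_species_tree(path=None) -> TreeNode:
    """The fixed conchiferan species tree, rooted between Nautilus and the rest."""
    if path is None:
        ref = resources.files("conchicore.fixtures") / "conchifera.nwk"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return TreeNode.read(io.StringIO(text), convert_underscores=False)


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), convert_underscores=False)


def poisson_distance(p: float) -> float:
    """Poisson-corrected amino-acid distance d = -ln(1 - p * 20/19)."""
    if p < 0:
        raise ValueError("p-distance must be >= 0")
    if p >= 19 / 20:
        warnings.warn(f"p-distance {p:.3f} saturated; capping at {MAX_DISTANCE}")
        return MAX_DISTANCE
    return -math.log(1.0 - p * 20.0 / 19.0)


def distance_matrix(
    sequences: Mapping[str, str],
    aligned: Optional[bool] = None,
) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances.

    With ``aligned`` (default: auto-detected from equal lengths) the
    p-distance is the mismatch fraction over columns where neither sequence
    has a gap. Otherwise each pair is locally aligned and p = 1 - identity
    over aligned columns.
    """
    ids = list(sequences)
    if len(ids) < 3:
        raise ValueError("need at least 3 sequences")
    seqs = [sequences[i] for i in ids]
    if aligned is None:
        aligned = len({len(s) for s in seqs}) == 1
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = seqs[i], seqs[j]
        if aligned:
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not pairs:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            p = sum(x != y for x, y in pairs) / len(pairs)
        else:
            hit = local_align(a, b)
            p = 1.0 - hit.percent_identity / 100.0
        mat[i, j] = mat[j, i] = poisson_distance(p)
    return DistanceMatrix(mat, ids)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; deterministic given input order."""
    arr = distances.data
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if len(distances.ids) == 3:
        # unique star resolution
        a, b, c = distances.ids
        return read_newick(f"({a},{b},{c});")
    return nj(distances)


def _bipartitions(tree: TreeNode) -> list[frozenset]:
    """Leaf set on one side of every internal edge of the unrooted tree."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts = []
    for node in tree.traverse(include_self=False):
        side = frozenset(t.name for t in node.tips()) or frozenset([node.name])
        if 0 < len(side) < len(all_tips):
            parts.append(side)
    return parts


def is_monophyletic(tree: TreeNode, tip_subset: Iterable[str]) -> bool:
    """True iff the subset forms a clade under some rooting of the tree,
    i.e. some edge bipartition separates exactly the subset."""
    subset = frozenset(tip_subset)
    if not subset:
        raise ValueError("tip subset must be non-empty")
    all_tips = frozenset(t.name for t in tree.tips())
    unknown = subset - all_tips
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if len(subset) in (1, len(all_tips)):
        return True
    complement = all_tips - subset
    return any(side == subset or side == complement for side in _bipartitions(tree))


@dataclass
class AncestralStates:
    """Per-node presence states plus gain/loss events per feature."""

    states: dict[str, dict[str, bool]]  # feature -> node name -> present
    gains: dict[str, Optional[str]]  # feature -> node above whose edge the gain sits
    losses: dict[str, list[str]]  # feature -> nodes whose parent edge carries a loss
    root_name: str

    def root_present(self, feature: str) -> bool:
        return self.states[feature][self.root_name]

    def root_present_features(self) -> list[str]:
        return [f for f in self.states if self.root_present(f)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states).T


def _label_internals(tree: TreeNode) -> None:
    k = 0
    for node in tree.traverse(include_self=True):
        if node.name is None:
            node.name = ROOT_LABEL if node.is_root() else f"node_{k}"
            k += 1


def dollo_ancestral(tree: TreeNode, presence: PresenceMatrix) -> AncestralStates:
    """Dollo parsimony on a rooted species tree.

    For each feature the single gain is placed on the edge above the MRCA of
    the leaves where it is present; within that clade a node is present
    unless all its descendant leaves are absent (which minimizes losses, one
    loss per maximal absent subtree). The root is present iff the gain sits
    on the root edge.
    """
    tree = tree.copy()
    _label_internals(tree)
    leaves = {t.name for t in tree.tips()}
    if set(presence.species) != leaves:
        raise ValueError("matrix species must equal tree leaves")
    states: dict[str, dict[str, bool]] = {}
    gains: dict[str, Optional[str]] = {}
    losses: dict[str, list[str]] = {}
    for feat in presence.features:
        present_leaves = {sp for sp in presence.species if presence.cell(feat, sp)}
        node_state = {n.name: False for n in tree.traverse(include_self=True)}
        if not present_leaves:
            states[feat], gains[feat], losses[feat] = node_state, None, []
            continue
        if len(present_leaves) == 1:
            mrca = tree.find(next(iter(present_leaves)))
        else:
            mrca = tree.lca(list(present_leaves))
        feat_losses = []
        for node in mrca.traverse(include_self=True):
            desc = {t.name for t in node.tips()} or {node.name}
            node_state[node.name] = bool(desc & present_leaves)
        for node in mrca.traverse(include_self=False):
            if not node_state[node.name] and node_state[node.parent.name]:
                feat_losses.append(node.name)
        states[feat] = node_state
        gains[feat] = mrca.name
        losses[feat] = sorted(feat_losses)
    return AncestralStates(states, gains, losses, tree.root().name)


def fitch_ancestral(tree: TreeNode, presence: PresenceMatrix) -> AncestralStates:
    """Unweighted Fitch parsimony (two-state), resolving root ambiguity to
    'present' and ambiguous descendants by inheritance from the parent."""
    tree = tree.copy()
    _label_internals(tree)
    leaves = {t.name for t in tree.tips()}
    if set(presence.species) != leaves:
        raise ValueError("matrix species must equal tree leaves")
    states: dict[str, dict[str, bool]] = {}
    gains: dict[str, Optional[str]] = {}
    losses: dict[str, list[str]] = {}
    for feat in presence.features:
        sets: dict[str, set] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                sets[node.name] = {presence.cell(feat, node.name)}
            else:
                inter = set.intersection(*(sets[c.name] for c in node.children))
                sets[node.name] = inter or set.union(*(sets[c.name] for c in node.children))
        node_state: dict[str, bool] = {}
        feat_gains, feat_losses = [], []
        for node in tree.preorder(include_self=True):
            s = sets[node.name]
            if node.is_root():
                node_state[node.name] = True in s
            else:
                parent = node_state[node.parent.name]
                node_state[node.name] = parent if parent in s else next(iter(s))
                if node_state[node.name] and not parent:
                    feat_gains.append(node.name)
                if parent and not node_state[node.name]:
                    feat_losses.append(node.name)
        states[feat] = node_state
        gains[feat] = feat_gains[0] if feat_gains else (
            tree.root().name if node_state[tree.root().name] else None
        )
        losses[feat] = sorted(feat_losses)
    return AncestralStates(states, gains, losses, tree.root().name)
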