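"""Light distance-based phylogenetics for checking clade structure.

This module exists to verify that a labelled family really falls into its
claimed clades and to place unlabelled sequences: p-distances under complete
deletion, a neighbor-joining tree (via scikit-bio), a monophyly test, and a
nearest-clade assignment with a margin score.  It deliberately does not do
maximum-likelihood inference or bootstrapping.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .alignment import GAP, LabeledAlignment, strip_gap_columns
from .errors import NoComparableColumnsError, UnknownLeafError

#: Returned by assign_clade when two clades are exactly tied.
AMBIGUOUS = "AMBIGUOUS"


def p_distance_matrix(aln: LabeledAlignment) -> DistanceMatrix:
    """Pairwise p-distances under complete deletion.

    All gap-containing columns are removed globally first; each pairwise
    distance is then the proportion of remaining columns at which the two
    sequences differ.  Raises when no gap-free column remains.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    arr = aln.to_array()
    keep = ~(arr == GAP).any(axis=0)
    if not keep.any():
        raise NoComparableColumnsError("no gap-free columns under complete deletion")
    arr = arr[:, keep]
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i + 1:] != arr[i]).mean(axis=1)
        d[i, i + 1:] = diff
        d[i + 1:, i] = diff
    return DistanceMatrix(d, ids=list(aln.seq_ids))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero.

    Deterministic for a given distance matrix (scikit-bio's implementation).
    Requires at least 3 taxa.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(dm, neg_as_zero=True)


def is_monophyletic(tree: TreeNode, members: set[str]) -> bool:
    """True iff some edge of the unrooted tree splits ``members`` from the rest.

    ``members`` must be a proper nonempty subset of the leaf labels.
    """
    leaves = {t.name for t in tree.tips()}
    unknown = set(members) - leaves
    if unknown:
        raise UnknownLeafError(f"labels not in tree: {sorted(unknown)}")
    if not 1 <= len(members) < len(leaves):
        raise ValueError("members must be a proper nonempty subset of the leaves")
    members = set(members)
    complement = leaves - members
    # Each internal node of the (arbitrarily rooted) TreeNode induces the
    # bipartition {tips below} vs {rest}; checking both orientations covers
    # every edge of the unrooted tree.
    for node in tree.non_tips(include_self=True):
        below = {t.name for t in node.tips()}
        if below == members or below == complement:
            return True
    # Single leaves and leaf-parent edges:
    return len(members) == 1 or len(complement) == 1


def assign_clade(
    query_id: str,
    query_row: str,
    aln: LabeledAlignment,
) -> tuple[str, float]:
    """Assign an aligned query sequence to its nearest clade.

    The query must live in the same column space as ``aln``.  The winning
    clade minimises the mean p-distance (complete deletion over the combined
    alignment) to its members; the margin is the gap to the second-best
    clade mean.  An exact tie returns :data:`AMBIGUOUS` with margin 0.
    """
    if query_id in aln.seq_ids:
        raise ValueError(f"query id {query_id!r} collides with an alignment id")
    if len(query_row) != aln.n_columns:
        raise ValueError("query not in the alignment's column space")
    clade_of = dict(aln.clade_of)
    clade_of[query_id] = "__query__"
    # Temporary second pseudo-clade label not needed: LabeledAlignment wants
    # >= 2 clades, which the real clades already provide.
    combined = LabeledAlignment(
        records=tuple(aln.records) + ((query_id, query_row),),
        clade_of=clade_of,
    )
    stripped = strip_gap_columns(combined)
    if stripped.n_columns == 0 or all(ch == GAP for ch in stripped.row(query_id)):
        raise NoComparableColumnsError("query is all-gaps after complete deletion")
    dm = p_distance_matrix(stripped)
    means = {
        clade: float(np.mean([dm[query_id, m] for m in aln.members(clade)]))
        for clade in aln.clades
    }
    ranked = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    best_clade, best = ranked[0]
    second = ranked[1][1] if len(ranked) > 1 else float("inf")
    margin = second - best
    if margin == 0.0:
        return AMBIGUOUS, 0.0
    return best_clade, margin


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """Square labelled TSV."""
    import pandas as pd

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
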