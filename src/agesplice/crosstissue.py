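"""Cross-tissue sharing of age-associated spliced genes.

Tissue similarity is the Jaccard index of the per-tissue sets of genes with
at least one age-associated splicing event; tissues are then clustered by
average-linkage hierarchical clustering on the distance 1 - J.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode


def jaccard_index(set_a: Iterable, set_b: Iterable) -> float:
    """|A intersect B| / |A union B|; defined as 0 when both sets are empty."""
    a, b = frozenset(set_a), frozenset(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class TissueSimilarity:
    """Pairwise Jaccard matrix plus the hierarchical clustering built on it."""

    matrix: pd.DataFrame
    linkage_matrix: np.ndarray
    newick: str

    def cut(self, k: int) -> pd.Series:
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.matrix.index, name="cluster")


def tissue_similarity(
    gene_sets: Mapping[str, Iterable], method: str = "average"
) -> TissueSimilarity:
    """Jaccard matrix over tissues and its 1 - J hierarchical clustering."""
    tissues = list(gene_sets)
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    sets = {t: frozenset(gene_sets[t]) for t in tissues}
    n = len(tissues)
    jac = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            jac[i, j] = jac[j, i] = jaccard_index(sets[tissues[i]], sets[tissues[j]])
        # the diagonal of an empty tissue is still 1 by convention J(A, A)=1
        # only for nonempty A; keep 0 for empty sets to avoid fake similarity
        if not sets[tissues[i]]:
            jac[i, i] = 0.0
    dist = 1.0 - jac
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method=method)
    tree = TreeNode.from_linkage_matrix(z, tissues)
    newick = str(tree).strip()
    matrix = pd.DataFrame(jac, index=tissues, columns=tissues)
    return TissueSimilarity(matrix, z, newick)
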