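"""Pairwise identity/similarity matrices and neighbor-joining trees.

Identity is computed either from a gapped global alignment (terminal-gap
columns excluded from the denominator, internal gaps included) or as a
gapless positional comparison of equal-length sequences.  "Similar" pairs
are those with a positive substitution-matrix score.  Identity matrices are
converted to per-residue distances (p-distance by default, Poisson
correction optionally) and handed to a Saitou-Nei neighbor-joining
implementation with a fixed tie rule, so tree construction is fully
deterministic; trees serialise to newick via scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .features import AlignParams, DEFAULT_ALIGN
from .io import ProteinRecord


@dataclass(frozen=True)
class IdentityResult:
    identity_percent: float
    similarity_percent: float
    aligned_columns: int
    identical_columns: int
    gap_columns: int
    mode: str


def pairwise_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    mode: str = "gapped-global",
    params: AlignParams = DEFAULT_ALIGN,
) -> IdentityResult:
    """Percent identity and similarity between two sequences.

    ``gapped-global``: align globally, trim columns where a terminal gap of
    either sequence runs, and use every remaining column (internal gaps
    included) as the denominator.  ``gapless-positional``: compare the two
    equal-length sequences column by column with no alignment, the
    convention used for structure-wrap comparisons of complete peptides.
    """
    if mode == "gapless-positional":
        if len(a) != len(b):
            raise ValueError(
                f"gapless mode requires equal lengths ({len(a)} vs {len(b)})"
            )
        sa, sb = a.residues, b.residues
    elif mode == "gapped-global":
        aln = params.make_aligner().align(a.residues, b.residues)[0]
        sa, sb = str(aln[0]), str(aln[1])
        start, end = _trim_terminal_gaps(sa, sb)
        sa, sb = sa[start:end], sb[start:end]
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    matrix = params.make_aligner().substitution_matrix
    cols = len(sa)
    identical = gaps = similar = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            identical += 1
            similar += 1
        elif matrix[x, y] > 0:
            similar += 1
    if cols == 0:
        raise ValueError("no aligned columns")
    return IdentityResult(
        identity_percent=100.0 * identical / cols,
        similarity_percent=100.0 * similar / cols,
        aligned_columns=cols,
        identical_columns=identical,
        gap_columns=gaps,
        mode=mode,
    )


def _trim_terminal_gaps(sa: str, sb: str) -> tuple[int, int]:
    start = 0
    while sa[start] == "-" or sb[start] == "-":
        start += 1
        if start == len(sa):
            return 0, 0
    end = len(sa)
    while sa[end - 1] == "-" or sb[end - 1] == "-":
        end -= 1
    return start, end


def identity_matrix(
    records: list[ProteinRecord],
    mode: str = "gapped-global",
    params: AlignParams = DEFAULT_ALIGN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric identity and similarity matrices (percent, diagonal 100)."""
    if len(records) < 2:
        raise ValueError("need >=2 records for a matrix")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in matrix input")
    n = len(records)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = pairwise_identity(records[i], records[j], mode, params)
            ident[i, j] = ident[j, i] = res.identity_percent
            simil[i, j] = simil[j, i] = res.similarity_percent
    return (pd.DataFrame(ident, index=ids, columns=ids),
            pd.DataFrame(simil, index=ids, columns=ids))


def to_distance(
    identity: pd.DataFrame, correction: str = "p-distance"
) -> DistanceMatrix:
    """Convert a percent-identity matrix to a per-residue distance matrix.

    ``p-distance`` is 1 - identity/100 (the scale of "changes per amino
    acid residue"); ``poisson`` applies -ln(identity/100) and rejects zero
    identity.
    """
    vals = identity.to_numpy(dtype=float)
    if (vals < 0).any() or (vals > 100).any():
        raise ValueError("identities must lie in [0, 100]")
    frac = vals / 100.0
    if correction == "p-distance":
        d = 1.0 - frac
    elif correction == "poisson":
        if (frac <= 0).any():
            raise ValueError("Poisson correction undefined at identity 0")
        d = -np.log(frac)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float round-off
    return DistanceMatrix(d, ids=list(identity.index))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with a deterministic tie rule.

    Iteratively joins the pair minimising the Q criterion
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; ties are broken by the smallest
    (i, j) index pair under input order.  Branch lengths use the standard
    rate-corrected formula; negative estimates are clamped to zero and the
    returned tree carries ``negative_branches_clamped`` with the count.
    The final three-taxon closure leaves an unrooted (trifurcating) tree.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs >=3 taxa")
    d = dm.data.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=str(i)) for i in dm.ids]
    clamped = 0

    def _attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        child.length = float(length)
        parent.append(child)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        _attach(parent, nodes[i], li)
        _attach(parent, nodes[j], lj)
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = du[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    root = TreeNode()
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    _attach(root, nodes[0], 0.5 * (d01 + d02 - d12))
    _attach(root, nodes[1], 0.5 * (d01 + d12 - d02))
    _attach(root, nodes[2], 0.5 * (d02 + d12 - d01))
    root.negative_branches_clamped = clamped
    return root


def tree_to_newick(tree: TreeNode) -> str:
    import io as _stdio

    buf = _stdio.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tree_distance_matrix(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    tip_dm = tree.tip_tip_distances()
    return pd.DataFrame(tip_dm.data, index=list(tip_dm.ids),
                        columns=list(tip_dm.ids))
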