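"""Pairwise percent identity and single-linkage clade grouping.

Stage 3.  Candidate proteins in this virus group share very little identity
overall (mostly under 10%), but subgroups with markedly higher intra-group
identity exist; single-linkage clustering of the identity matrix at a
threshold between the inter- and intra-group levels recovers them.

Identity convention: for a pair of aligned rows,

    identity = 100 * (# columns with identical residues)
                   / (# columns where BOTH rows are non-gap)

A pair with zero co-occupied columns scores 0 with a warning.  When no MSA
is available, an end-to-end (global) affine-gap alignment with BLOSUM62 is
computed per pair; a gap of length k costs ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix (diagonal exactly 100)."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("identity matrix shape does not match id count")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix is not symmetric")
        if v.min() < 0 or v.max() > 100:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _make_aligner(matrix_name: str, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # Biopython charges open_gap_score for the first gapped position; our
    # convention charges open + extend for it.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                 gap_open: float = 11.0,
                 gap_extend: float = 1.0) -> tuple[str, str, float]:
    """Optimal global alignment of two proteins (affine gaps, BLOSUM62).

    Returns the two gapped rows and the alignment score.  Ties are broken
    deterministically by taking the first optimal alignment in Biopython's
    enumeration order (match/mismatch preferred over gap).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def _pair_identity(row_a: str, row_b: str, pair_label: str = "") -> float:
    both = matches = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                matches += 1
    if both == 0:
        logger.warning("pair %s shares no co-occupied columns; identity set to 0",
                       pair_label)
        return 0.0
    return 100.0 * matches / both


def pairwise_identity(records: list[tuple[str, str]],
                      aligned: bool = True) -> IdentityMatrix:
    """Percent-identity matrix over proteins.

    With ``aligned=True`` the inputs are MSA rows and must share one column
    count (ragged input is a hard error).  Otherwise each pair is globally
    aligned first via :func:`global_align`.
    """
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in identity-matrix input")
    seqs = [s for _, s in records]
    n = len(ids)
    if aligned and len({len(s) for s in seqs}) > 1:
        raise ValueError("MSA rows have unequal lengths")
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            if aligned:
                ra, rb = seqs[i], seqs[j]
            else:
                ra, rb, _ = global_align(seqs[i].replace("-", ""),
                                         seqs[j].replace("-", ""))
            ident = _pair_identity(ra, rb, f"{ids[i]}/{ids[j]}")
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(ids=ids, values=values)


def cluster_clades(matrix: IdentityMatrix,
                   threshold_pct: float = 15.0) -> dict[str, str]:
    """Single-linkage clades: connected components of the >= threshold graph.

    Labels are ``clade_1..clade_k`` ordered by descending clade size, ties
    broken by the lexicographically smallest member id.  Singletons are
    allowed.
    """
    n = len(matrix.ids)
    if n == 0:
        return {}
    adjacency = csr_matrix(matrix.values >= threshold_pct)
    _, labels = connected_components(adjacency, directed=False)
    groups: dict[int, list[str]] = {}
    for idx, comp in enumerate(labels):
        groups.setdefault(int(comp), []).append(matrix.ids[idx])
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    assignment: dict[str, str] = {}
    for rank, members in enumerate(ordered, start=1):
        for member in members:
            assignment[member] = f"clade_{rank}"
    return assignment


def plot_identity_heatmap(matrix: IdentityMatrix, path: str) -> None:
    """Render the identity matrix as a simple heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(matrix.ids)),) * 2)
    im = ax.imshow(matrix.values, vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(len(matrix.ids)), matrix.ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.ids)), matrix.ids, fontsize=7)
    fig.colorbar(im, ax=ax, label="% identity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
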