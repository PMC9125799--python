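"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths they verify: the ORF oracle
enumerates codons per frame from scratch, the alignment oracle is a plain
three-matrix Gotoh DP, the component oracle is a hand-written BFS, and the
Pearson oracle is the textbook sum formula.
"""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
_STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def orf_scan_oracle(seq: str, require_atg: bool = True,
                    min_aa: int = 1) -> set[tuple]:
    """Enumerate ORFs over all six frames of the standard genetic code.

    Returns tuples ``(strand, start, end, protein, complete5, complete3)``
    with plus-strand 0-based half-open coordinates including the stop codon.
    Codons containing N act as run breakers that never translate.
    """
    L = len(seq)
    found: set[tuple] = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [s[i:i + 3] for i in range(frame, L - 2, 3)]
            # split codon indices into runs between stop/N codons
            runs: list[tuple[int, int, bool]] = []   # (first, last_excl, stopped)
            first = 0
            for idx, codon in enumerate(codons):
                if codon in _STOPS or "N" in codon:
                    runs.append((first, idx, codon in _STOPS))
                    first = idx + 1
            runs.append((first, len(codons), False))
            for first, last, stopped in runs:
                run = codons[first:last]
                if require_atg:
                    starts = [i for i, c in enumerate(run) if c == "ATG"]
                    if starts:
                        offset, complete5 = starts[0], True
                    elif first == 0:
                        offset, complete5 = 0, False
                    else:
                        continue
                else:
                    offset = 0
                    complete5 = bool(run) and run[0] == "ATG"
                coding = run[offset:]
                if not coding:
                    continue
                protein = "".join(_STANDARD_CODE[c] for c in coding)
                if len(protein) < min_aa:
                    continue
                nt_start = frame + 3 * (first + offset)
                nt_end = frame + 3 * last + (3 if stopped else 0)
                if strand == "+":
                    start, end = nt_start, nt_end
                else:
                    start, end = L - nt_end, L - nt_start
                found.add((strand, start, end, protein, complete5, stopped))
    return found


def gotoh_score_oracle(a: str, b: str, submat, gap_open: float,
                       gap_extend: float) -> float:
    """Optimal global affine-gap alignment score by the three-matrix DP.

    A gap of length k costs ``gap_open + k * gap_extend``.
    """
    neg = -math.inf
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in b (a consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = submat[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def bfs_components_oracle(ids: list[str], values, threshold: float) -> list[set[str]]:
    """Connected components of the >= threshold graph by plain BFS."""
    n = len(ids)
    seen = [False] * n
    components: list[set[str]] = []
    for start in range(n):
        if seen[start]:
            continue
        queue, comp = [start], {start}
        seen[start] = True
        while queue:
            u = queue.pop()
            for v in range(n):
                if not seen[v] and values[u][v] >= threshold:
                    seen[v] = True
                    comp.add(v)
                    queue.append(v)
        components.append({ids[i] for i in comp})
    return components


def pearson_oracle(x: list[float], y: list[float]) -> float:
    """Textbook Pearson correlation from raw sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(u * v for u, v in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den
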