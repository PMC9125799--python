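"""Palm-domain motif anchoring and catalytic-triad extraction.

Stage 4.  Viral RNA-dependent RNA polymerases carry three conserved palm
motifs: motif A with a conserved aspartate (D), motif B with two conserved
glycines (G), and motif C whose central aspartate coordinates the catalytic
metal.  The three residues around the motif-C aspartate form the *catalytic
triad*, canonically GDD, with rare natural variants such as SDD (many
negative-sense RNA viruses) and GDN.  The viruses this pipeline targets show
NDD most commonly plus ADD, SDD, HDD, and the previously unreported GDQ.

Anchors are located by a conservation heuristic over MSA columns: a column
is D- (or G-) conserved when the residue frequency over *all* rows (gaps
count against) reaches ``min_frac``.  Users reproducing a published,
structure-guided alignment can instead pass explicit anchor columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

TRIAD_CANONICAL = "GDD"
DEFAULT_RARE_TRIADS = frozenset({"SDD", "GDN"})

STATUS_CANONICAL = "canonical"
STATUS_KNOWN_RARE = "known_rare"
STATUS_NOVEL = "novel"
STATUS_INCOMPLETE = "incomplete"


@dataclass(frozen=True)
class MotifAnchors:
    """MSA column indices of the conserved palm-motif residues."""

    col_a: int                    # motif-A aspartate column
    col_b: tuple[int, int]        # the two motif-B glycine columns
    col_c: int                    # motif-C central aspartate column
    support: dict[int, float]     # conservation fraction per anchor column


@dataclass(frozen=True)
class TriadCall:
    """Catalytic triad of one sequence: residues at columns C-1, C, C+1."""

    seq_id: str
    triad: str
    status: str


@dataclass
class TriadResult:
    calls: list[TriadCall]
    tally: Counter
    mode: str | None


def _check_msa(msa: list[tuple[str, str]]) -> int:
    if len(msa) < 2:
        raise ValueError("an MSA of at least 2 sequences is required")
    lengths = {len(s) for _, s in msa}
    if len(lengths) != 1:
        raise ValueError("ragged MSA: rows have unequal lengths")
    return lengths.pop()


def _column_freq(msa: list[tuple[str, str]], col: int, residue: str) -> float:
    return sum(1 for _, s in msa if s[col] == residue) / len(msa)


def locate_motif_anchors(msa: list[tuple[str, str]], min_frac: float = 0.7,
                         min_ab_gap: int = 20, min_bc_gap: int = 5,
                         max_b_span: int = 3) -> MotifAnchors | None:
    """Find the A/B/C motif anchor columns in an RdRP-like MSA.

    The motif-C column is the D-conserved column of maximal D frequency that
    has, upstream, a pair of G-conserved columns (the motif-B glycines, at
    most ``max_b_span`` columns apart, adjacent preferred) at least
    ``min_bc_gap`` columns before it, and a D-conserved motif-A column at
    least ``min_ab_gap`` columns before the first glycine.  Ties break
    toward the smallest column index.  Returns ``None`` when no column
    arrangement satisfies ``min_frac`` (a no-anchor result, not an error).
    """
    ncol = _check_msa(msa)
    d_cols = [(c, _column_freq(msa, c, "D")) for c in range(ncol)]
    d_cols = [(c, f) for c, f in d_cols if f >= min_frac]
    g_cols = [c for c in range(ncol) if _column_freq(msa, c, "G") >= min_frac]
    if not d_cols or len(g_cols) < 2:
        return None
    g_pairs = [(g1, g2) for i, g1 in enumerate(g_cols)
               for g2 in g_cols[i + 1:] if g2 - g1 <= max_b_span]
    best: tuple[float, int] | None = None   # (-freq, col_c) for min() ordering
    chosen: tuple[int, tuple[int, int], int] | None = None
    for col_c, freq_c in d_cols:
        valid: list[tuple[int, tuple[int, int]]] = []
        for g1, g2 in g_pairs:
            if col_c - g2 < min_bc_gap:
                continue
            for col_a, _ in d_cols:
                if col_a < g1 and g1 - col_a >= min_ab_gap and col_a != col_c:
                    valid.append((col_a, (g1, g2)))
        if not valid:
            continue
        key = (-freq_c, col_c)
        if best is None or key < best:
            best = key
            # deterministic choice: tightest, earliest glycine pair; then the
            # most D-conserved (earliest on ties) motif-A column for it
            pair = min({p for _, p in valid}, key=lambda p: (p[1] - p[0], p[0]))
            a_candidates = [a for a, p in valid if p == pair]
            col_a = min(a_candidates,
                        key=lambda a: (-dict(d_cols)[a], a))
            chosen = (col_a, pair, col_c)
    if chosen is None:
        return None
    col_a, (g1, g2), col_c = chosen
    support = {
        col_a: _column_freq(msa, col_a, "D"),
        g1: _column_freq(msa, g1, "G"),
        g2: _column_freq(msa, g2, "G"),
        col_c: _column_freq(msa, col_c, "D"),
    }
    return MotifAnchors(col_a=col_a, col_b=(g1, g2), col_c=col_c,
                        support=support)


def classify_triad(triad: str, canonical: str = TRIAD_CANONICAL,
                   rare: frozenset[str] = DEFAULT_RARE_TRIADS) -> str:
    """Classify one triad against the catalog (fully configurable)."""
    if len(triad) != 3:
        raise ValueError(f"a catalytic triad has exactly 3 residues: {triad!r}")
    if "-" in triad:
        return STATUS_INCOMPLETE
    if triad == canonical:
        return STATUS_CANONICAL
    if triad in rare:
        return STATUS_KNOWN_RARE
    return STATUS_NOVEL


def extract_triads(msa: list[tuple[str, str]], anchors: MotifAnchors,
                   canonical: str = TRIAD_CANONICAL,
                   rare: frozenset[str] = DEFAULT_RARE_TRIADS) -> TriadResult:
    """Read each sequence's triad at columns (C-1, C, C+1) and tally.

    Gap characters are preserved in the triad string; a triad containing a
    gap is ``incomplete`` and excluded from the tally.  The mode is the most
    frequent complete triad (lexicographic tie-break).
    """
    ncol = _check_msa(msa)
    if anchors.col_c - 1 < 0 or anchors.col_c + 1 >= ncol:
        raise ValueError("motif-C anchor column at the alignment edge")
    calls: list[TriadCall] = []
    tally: Counter = Counter()
    for seq_id, row in msa:
        triad = row[anchors.col_c - 1:anchors.col_c + 2]
        status = classify_triad(triad, canonical=canonical, rare=rare)
        calls.append(TriadCall(seq_id=seq_id, triad=triad, status=status))
        if status != STATUS_INCOMPLETE:
            tally[triad] += 1
    mode = min(tally, key=lambda t: (-tally[t], t)) if tally else None
    return TriadResult(calls=calls, tally=tally, mode=mode)


def summarize_by_clade(calls: list[TriadCall],
                       clades: dict[str, str]) -> dict[str, Counter]:
    """Cross-tabulate triads by clade (e.g. to see a clade-exclusive triad)."""
    out: dict[str, Counter] = {}
    for call in calls:
        clade = clades.get(call.seq_id, "unassigned")
        out.setdefault(clade, Counter())[call.triad] += 1
    return out


def write_annotated_alignment(msa: list[tuple[str, str]],
                              anchors: MotifAnchors, path: str) -> None:
    """Write the MSA as text with a ruler line marking motif columns A/B/C."""
    ncol = _check_msa(msa)
    ruler = [" "] * ncol
    ruler[anchors.col_a] = "A"
    for g in anchors.col_b:
        ruler[g] = "B"
    ruler[anchors.col_c] = "C"
    width = max(len(seq_id) for seq_id, _ in msa) + 2
    with open(path, "w") as fh:
        fh.write(" " * width + "".join(ruler) + "\n")
        for seq_id, row in msa:
            fh.write(seq_id.ljust(width) + row + "\n")
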