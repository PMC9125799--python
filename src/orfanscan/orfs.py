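"""ORFan candidate selection: six-frame ORF calling, protein mass, filters.

Stage 1 of the discovery pipeline.  A contig is an *ORFan candidate* when it
has no similarity-search hit, is longer than a nucleotide-length threshold
(1,000 bp by default, a common lower bound for mycovirus genomic segments),
and encodes a protein heavier than a mass threshold (15 kDa by default --
segments above 1 kb that code for anything conserved rarely encode less).
Both thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import Contig

logger = logging.getLogger(__name__)

# Average (not monoisotopic) residue masses in Daltons, Expasy convention.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.0513, "A": 71.0779, "S": 87.0773, "P": 97.1152, "V": 99.1311,
    "T": 101.1039, "C": 103.1429, "L": 113.1576, "I": 113.1576, "N": 114.1026,
    "D": 115.0874, "Q": 128.1292, "K": 128.1723, "E": 129.1155, "M": 131.1961,
    "H": 137.1393, "F": 147.1739, "R": 156.1857, "Y": 163.1733, "W": 186.2099,
}
WATER_MASS = 18.0153
#: X (unknown residue) contributes the unweighted mean of the 20 residues.
_X_MASS = sum(AVERAGE_RESIDUE_MASS.values()) / len(AVERAGE_RESIDUE_MASS)


def protein_mass(protein: str) -> float:
    """Average molecular mass of a protein in Daltons.

    Sum of standard average residue masses plus one water (18.0153 Da).
    ``X`` contributes the mean residue mass; any other character outside the
    20-letter alphabet is a hard error, as is an empty protein.
    """
    if not protein:
        raise ValueError("cannot compute the mass of an empty protein")
    total = WATER_MASS
    for ch in protein:
        if ch == "X":
            total += _X_MASS
        else:
            try:
                total += AVERAGE_RESIDUE_MASS[ch]
            except KeyError:
                raise ValueError(f"illegal amino-acid character {ch!r}") from None
    return total


@dataclass(frozen=True)
class OrfCall:
    """A predicted open reading frame.

    Coordinates are 0-based half-open on the contig *plus* strand and include
    the stop codon when ``complete3``.  ``frame`` is the scanning frame
    (0..2) on the strand the ORF was read from.
    """

    contig_id: str
    strand: str               # '+' or '-'
    frame: int
    start: int
    end: int
    protein: str
    mass_da: float
    complete5: bool           # has an initiator ATG
    complete3: bool           # ends at a stop codon


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _frame_segments(s: str, frame: int, stop_codons: frozenset[str]):
    """Split one reading frame into maximal stop-free, N-free codon runs.

    Yields ``(seg_start, seg_end, stop_end)`` where ``[seg_start, seg_end)``
    is the translatable span and ``stop_end`` is the end of the terminating
    stop codon, or ``None`` when the run ends at the contig edge or at a
    codon containing N (which never translates).
    """
    L = len(s)
    seg_start = frame
    j = frame
    while j + 3 <= L:
        codon = s[j:j + 3]
        if "N" in codon:
            yield seg_start, j, None
            seg_start = j + 3
        elif codon in stop_codons:
            yield seg_start, j, j + 3
            seg_start = j + 3
        j += 3
    yield seg_start, frame + 3 * ((L - frame) // 3), None


def find_orfs(contig: Contig, genetic_code_id: int = 1,
              require_atg: bool = True, min_aa: int = 1) -> list[OrfCall]:
    """Scan all six frames of a contig for open reading frames.

    An ORF runs from its initiator to the next stop codon in frame.  With
    ``require_atg`` the initiator is the first ATG of the stop-free run,
    except that a run open at the contig terminus (no upstream stop in that
    frame) is reported from the frame start with ``complete5=False`` --
    assemblies routinely truncate 5' ends, and the downstream mass filter
    must see those proteins.  Runs truncated by the contig end (or broken by
    an N-containing codon) are reported with ``complete3=False``.

    Results are sorted by protein length descending (ties: strand then
    start).
    """
    if not contig.seq:
        raise ValueError(f"contig {contig.id!r} has an empty sequence")
    try:
        table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    except KeyError:
        raise ValueError(f"unknown genetic code id {genetic_code_id}") from None
    stops = frozenset(table.stop_codons)
    L = contig.length
    calls: list[OrfCall] = []
    for strand, s in (("+", contig.seq), ("-", revcomp(contig.seq))):
        for frame in range(3):
            for seg_start, seg_end, stop_end in _frame_segments(s, frame, stops):
                if seg_end <= seg_start:
                    continue
                if require_atg:
                    orf_start = None
                    k = seg_start
                    while k + 3 <= seg_end:
                        if s[k:k + 3] == "ATG":
                            orf_start = k
                            break
                        k += 3
                    if orf_start is not None:
                        complete5 = True
                    elif seg_start == frame:
                        # run open at the contig 5' terminus on this strand
                        orf_start, complete5 = seg_start, False
                    else:
                        continue
                else:
                    orf_start = seg_start
                    complete5 = s[seg_start:seg_start + 3] == "ATG"
                coding = s[orf_start:seg_end]
                if len(coding) < 3:
                    continue
                protein = str(Seq(coding).translate(table=genetic_code_id))
                if len(protein) < min_aa:
                    continue
                span_end = stop_end if stop_end is not None else seg_end
                if strand == "+":
                    start, end = orf_start, span_end
                else:
                    start, end = L - span_end, L - orf_start
                calls.append(OrfCall(
                    contig_id=contig.id, strand=strand, frame=frame,
                    start=start, end=end, protein=protein,
                    mass_da=protein_mass(protein.replace("*", "")),
                    complete5=complete5, complete3=stop_end is not None,
                ))
    calls.sort(key=lambda c: (-len(c.protein), c.strand, c.start))
    return calls


@dataclass(frozen=True)
class OrfanCandidate:
    """A contig that passed every ORFan filter, with its heaviest ORF."""

    contig: Contig
    best_orf: OrfCall
    reasons: tuple[str, ...] = ("no_hit", "length", "protein_mass")


@dataclass
class OrfanScreen:
    """Outcome of the candidate screen: survivors plus rejection reasons."""

    candidates: list[OrfanCandidate] = field(default_factory=list)
    rejections: dict[str, str] = field(default_factory=dict)

    @property
    def candidate_ids(self) -> list[str]:
        return [c.contig.id for c in self.candidates]


def select_orfan_candidates(contigs: list[Contig], hit_queries: set[str],
                            min_len: int = 1000, min_mass: float = 15000.0,
                            genetic_code_id: int = 1,
                            require_atg: bool = True) -> OrfanScreen:
    """Apply the three ORFan filters in order: hit, length, protein mass.

    A contig survives iff it is absent from ``hit_queries``, strictly longer
    than ``min_len`` nucleotides, and carries an ORF whose encoded protein is
    strictly heavier than ``min_mass`` Daltons.  The heaviest qualifying ORF
    becomes ``best_orf``.  Rejected contigs are recorded with the first
    failed filter ("database hit", "length", or "protein mass").
    """
    screen = OrfanScreen()
    for contig in contigs:
        if contig.id in hit_queries:
            screen.rejections[contig.id] = "database hit"
            continue
        if contig.length <= min_len:
            screen.rejections[contig.id] = "length"
            continue
        orfs = find_orfs(contig, genetic_code_id=genetic_code_id,
                         require_atg=require_atg)
        heavy = [o for o in orfs if o.mass_da > min_mass]
        if not heavy:
            screen.rejections[contig.id] = "protein mass"
            continue
        best = max(heavy, key=lambda o: o.mass_da)
        screen.candidates.append(OrfanCandidate(contig=contig, best_orf=best))
    return screen
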