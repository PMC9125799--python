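"""RNA1-RNA2 segment association.

Stage 5.  Bisegmented viruses in this group pair an RdRP-encoding segment
(RNA1) with a companion segment of unknown function (RNA2).  Three evidence
streams link candidate pairs:

* **terminal conservation** -- genome segments of one virus share nearly
  identical 5' and 3' termini (for the founding case, a single mismatch in
  the first twenty nucleotides);
* **co-occurrence** -- across an isolate panel screened by qPCR, the two
  segments are present in exactly the same individuals (Ct above the cutoff,
  38 by default, or a blank cell scores as absent);
* **abundance correlation** -- per-library read counts of the two segments
  correlate quantitatively (Pearson on log10(count+1); raw counts span
  orders of magnitude).

The decision rule combining them is explicit and configurable: terminal
conservation alone is STRONG evidence; exact co-occurrence (MODERATE) and
high correlation (WEAK) only associate a pair together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GRADE_STRONG = "STRONG"
GRADE_MODERATE = "MODERATE"
GRADE_WEAK = "WEAK"


@dataclass(frozen=True)
class TerminalDistance:
    """Ungapped mismatch counts over the first/last ``k`` nt of two segments."""

    k: int
    mism5: int
    mism3: int


def terminal_conservation(seq_a: str, seq_b: str, k: int = 20) -> TerminalDistance:
    """Position-by-position mismatches over the 5'- and 3'-terminal k nt.

    Both sequences must be given in plus-sense (coding) orientation; no
    alignment or shifting is attempted.  Sequences shorter than ``k`` are a
    hard error.
    """
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError(f"both sequences must be at least k={k} nt long")
    mism5 = sum(1 for x, y in zip(seq_a[:k], seq_b[:k]) if x != y)
    mism3 = sum(1 for x, y in zip(seq_a[-k:], seq_b[-k:]) if x != y)
    return TerminalDistance(k=k, mism5=mism5, mism3=mism3)


def binarize_ct(table: pd.DataFrame, cutoff: float = 38.0) -> pd.DataFrame:
    """Presence/absence from a Ct table: present iff Ct <= cutoff.

    Missing (NaN) cells score absent, mirroring the blank-equals-negative
    convention of qPCR screening tables.
    """
    return table.le(cutoff).fillna(False).astype(bool)


def cooccurrence_score(pres_a: pd.Series,
                       pres_b: pd.Series) -> tuple[float, bool, int]:
    """Jaccard index, exact-match flag and shared-positive count.

    Both rows must cover the same sample set.  The Jaccard index over the
    present-sample sets is defined as 0 (with a warning) when both sets are
    empty.
    """
    if set(pres_a.index) != set(pres_b.index):
        raise ValueError("presence rows cover different sample sets")
    pres_b = pres_b.reindex(pres_a.index)
    set_a = set(pres_a.index[pres_a.astype(bool)])
    set_b = set(pres_b.index[pres_b.astype(bool)])
    union = set_a | set_b
    shared = set_a & set_b
    if not union:
        logger.warning("both presence sets empty; Jaccard set to 0")
        jaccard = 0.0
    else:
        jaccard = len(shared) / len(union)
    return jaccard, set_a == set_b, len(shared)


def abundance_correlation(counts_a: pd.Series,
                          counts_b: pd.Series) -> tuple[float | None, int]:
    """Pearson r on log10(count+1) over libraries where either segment has reads.

    Libraries where both counts are zero are dropped.  Returns ``(None, n)``
    when fewer than 3 libraries remain or either log-vector is constant.
    """
    if set(counts_a.index) != set(counts_b.index):
        raise ValueError("count rows cover different library sets")
    counts_b = counts_b.reindex(counts_a.index)
    a = counts_a.to_numpy(dtype=float)
    b = counts_b.to_numpy(dtype=float)
    mask = (a > 0) | (b > 0)
    a, b = a[mask], b[mask]
    n = int(mask.sum())
    if n < 3:
        logger.warning("fewer than 3 informative libraries; correlation undefined")
        return None, n
    la, lb = np.log10(a + 1.0), np.log10(b + 1.0)
    if np.allclose(la, la[0]) or np.allclose(lb, lb[0]):
        logger.warning("constant count vector; correlation undefined")
        return None, n
    r, _ = stats.pearsonr(la, lb)
    return float(r), n


@dataclass(frozen=True)
class AssociationRules:
    """Thresholds of the association decision rule (echoed in reports)."""

    terminal_k: int = 20
    max_mism5: int = 2
    max_mism3: int = 2
    min_shared_positive: int = 2
    min_r: float = 0.9
    min_libraries: int = 3


@dataclass
class AssociationEvidence:
    """All evidence linking one candidate RNA1 to one candidate RNA2."""

    rna1_id: str
    rna2_id: str
    terminal: TerminalDistance | None = None
    jaccard: float | None = None
    exact_cooccurrence: bool | None = None
    n_shared_positive: int = 0
    abundance_r: float | None = None
    n_libraries: int = 0
    grades: list[str] = field(default_factory=list)
    call: str = "unresolved"


def call_association(rna1_id: str, rna2_id: str,
                     terminal: TerminalDistance | None = None,
                     cooccurrence: tuple[float, bool, int] | None = None,
                     abundance: tuple[float | None, int] | None = None,
                     rules: AssociationRules = AssociationRules()
                     ) -> AssociationEvidence:
    """Combine the evidence streams into an associated/unresolved call.

    STRONG: both termini within the mismatch budget.  MODERATE: exact
    co-occurrence over at least ``min_shared_positive`` shared positives.
    WEAK: r >= ``min_r`` over at least ``min_libraries`` libraries.  The
    pair is ``associated`` iff STRONG holds, or both MODERATE and WEAK do.
    """
    ev = AssociationEvidence(rna1_id=rna1_id, rna2_id=rna2_id,
                             terminal=terminal)
    if terminal is not None and (terminal.mism5 <= rules.max_mism5
                                 and terminal.mism3 <= rules.max_mism3):
        ev.grades.append(GRADE_STRONG)
    if cooccurrence is not None:
        ev.jaccard, ev.exact_cooccurrence, ev.n_shared_positive = cooccurrence
        if ev.exact_cooccurrence and ev.n_shared_positive >= rules.min_shared_positive:
            ev.grades.append(GRADE_MODERATE)
    if abundance is not None:
        ev.abundance_r, ev.n_libraries = abundance
        if (ev.abundance_r is not None and ev.abundance_r >= rules.min_r
                and ev.n_libraries >= rules.min_libraries):
            ev.grades.append(GRADE_WEAK)
    supporting = set(ev.grades)
    if GRADE_STRONG in supporting or len(supporting & {GRADE_MODERATE,
                                                       GRADE_WEAK}) >= 2:
        ev.call = "associated"
    return ev


def associate_all(segments: dict[str, str],
                  ct_table: pd.DataFrame | None = None,
                  counts: pd.DataFrame | None = None,
                  ct_cutoff: float = 38.0,
                  rules: AssociationRules = AssociationRules()
                  ) -> list[AssociationEvidence]:
    """Evaluate every unordered candidate pair with all available evidence.

    ``segments`` maps segment id to its plus-sense nucleotide sequence.
    Ct and count tables contribute only for pairs whose ids they contain.
    """
    presence = binarize_ct(ct_table, cutoff=ct_cutoff) if ct_table is not None else None
    evidence: list[AssociationEvidence] = []
    for id_a, id_b in combinations(sorted(segments), 2):
        terminal = None
        seq_a, seq_b = segments[id_a], segments[id_b]
        if len(seq_a) >= rules.terminal_k and len(seq_b) >= rules.terminal_k:
            terminal = terminal_conservation(seq_a, seq_b, k=rules.terminal_k)
        cooc = None
        if presence is not None and id_a in presence.index and id_b in presence.index:
            cooc = cooccurrence_score(presence.loc[id_a], presence.loc[id_b])
        abund = None
        if counts is not None and id_a in counts.index and id_b in counts.index:
            abund = abundance_correlation(counts.loc[id_a], counts.loc[id_b])
        evidence.append(call_association(id_a, id_b, terminal=terminal,
                                         cooccurrence=cooc, abundance=abund,
                                         rules=rules))
    return evidence
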