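"""Stranded read tallies and polarity classification.

Stage 2.  A replicating RNA virus produces both a plus (coding) and a minus
(template) strand, so a genuinely viral contig in a stranded RNA-seq library
attracts reads from both orientations; host mRNA contigs attract sense reads
only.  This module decodes each alignment's RNA of origin from its SAM flag
under a declared library protocol, tallies plus/minus per contig, applies
the both-strand keep rule, and classifies polarity dominance (one virus
clade in this system accumulates predominantly minus-strand RNA).

Protocol conventions:

``fr_firststrand``
    dUTP / TruSeq-stranded chemistry.  A single-end or first-in-pair read
    aligning *forward* derives from RNA antisense to the contig (minus);
    aligning *reverse* derives from the plus strand.  Second-in-pair reads
    follow the opposite rule.
``fr_secondstrand``
    the inverse convention.

Misconfiguring the protocol silently inverts the biology, which is why it is
an explicit required argument rather than a guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

from .io import AlignedRead

logger = logging.getLogger(__name__)

PROTOCOLS = ("fr_firststrand", "fr_secondstrand")

POLARITY_PLUS = "plus_dominant"
POLARITY_MINUS = "minus_dominant"
POLARITY_BALANCED = "balanced"
POLARITY_INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class StrandProfile:
    """Per-contig (per-library) plus/minus read tally with a polarity call."""

    contig_id: str
    library_id: str = ""
    plus_count: int = 0
    minus_count: int = 0
    polarity: str | None = None
    keep: bool | None = None

    @property
    def total(self) -> int:
        return self.plus_count + self.minus_count


@dataclass
class TallyResult:
    """Outcome of a tally pass over one alignment stream."""

    profiles: dict[str, StrandProfile] = field(default_factory=dict)
    n_unmapped: int = 0
    n_unknown_ref: int = 0

    @property
    def n_counted(self) -> int:
        return sum(p.total for p in self.profiles.values())


def read_origin_is_plus(read: AlignedRead, protocol: str) -> bool:
    """Decode the RNA-of-origin strand for one mapped read."""
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown stranded protocol {protocol!r}")
    effective_reverse = bool(read.is_reverse)
    if read.is_first_in_pair is False:      # second in pair: flipped rule
        effective_reverse = not effective_reverse
    if protocol == "fr_firststrand":
        return effective_reverse
    return not effective_reverse


def tally_strand(reads: Iterable[AlignedRead], protocol: str,
                 library_id: str = "",
                 contig_ids: set[str] | None = None) -> TallyResult:
    """Tally plus/minus-origin reads per contig.

    Unmapped reads are ignored (counted in ``n_unmapped``).  When a contig
    set is supplied, reads aligned to references outside it are warned about
    and counted separately rather than silently dropped.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown stranded protocol {protocol!r}")
    plus: dict[str, int] = {}
    minus: dict[str, int] = {}
    result = TallyResult()
    if contig_ids is not None:
        for cid in contig_ids:
            plus[cid] = 0
            minus[cid] = 0
    for read in reads:
        if not read.is_mapped:
            result.n_unmapped += 1
            continue
        if contig_ids is not None and read.ref_id not in contig_ids:
            result.n_unknown_ref += 1
            continue
        bucket = plus if read_origin_is_plus(read, protocol) else minus
        bucket[read.ref_id] = bucket.get(read.ref_id, 0) + 1
        if read.ref_id not in (minus if bucket is plus else plus):
            (minus if bucket is plus else plus).setdefault(read.ref_id, 0)
    if result.n_unknown_ref:
        logger.warning("%d reads aligned to references outside the contig set",
                       result.n_unknown_ref)
    for cid in sorted(set(plus) | set(minus)):
        result.profiles[cid] = StrandProfile(
            contig_id=cid, library_id=library_id,
            plus_count=plus.get(cid, 0), minus_count=minus.get(cid, 0))
    return result


def classify_profile(profile: StrandProfile, min_each: int = 1,
                     min_total: int = 10,
                     dominance_ratio: float = 1.0) -> StrandProfile:
    """Fill in the polarity class and the both-strand keep decision.

    ``keep`` is False when either strand has fewer than ``min_each`` reads
    (contigs with only sense or only antisense reads are discarded -- the
    viral hallmark is two-strand support).  Polarity is ``insufficient``
    below ``min_total`` reads, otherwise minus/plus dominant when one strand
    exceeds ``dominance_ratio`` times the other, else ``balanced``.
    """
    keep = profile.plus_count >= min_each and profile.minus_count >= min_each
    if profile.total < min_total:
        polarity = POLARITY_INSUFFICIENT
    elif profile.minus_count > dominance_ratio * profile.plus_count:
        polarity = POLARITY_MINUS
    elif profile.plus_count > dominance_ratio * profile.minus_count:
        polarity = POLARITY_PLUS
    else:
        polarity = POLARITY_BALANCED
    return replace(profile, polarity=polarity, keep=keep)


def merge_profiles(profiles: Iterable[StrandProfile],
                   library_id: str = "pooled") -> dict[str, StrandProfile]:
    """Sum per-library profiles into pooled per-contig tallies."""
    pooled: dict[str, StrandProfile] = {}
    for p in profiles:
        cur = pooled.get(p.contig_id)
        if cur is None:
            pooled[p.contig_id] = StrandProfile(
                contig_id=p.contig_id, library_id=library_id,
                plus_count=p.plus_count, minus_count=p.minus_count)
        else:
            pooled[p.contig_id] = StrandProfile(
                contig_id=p.contig_id, library_id=library_id,
                plus_count=cur.plus_count + p.plus_count,
                minus_count=cur.minus_count + p.minus_count)
    return pooled
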