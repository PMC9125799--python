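"""Seeded synthetic datasets with ground truth for every pipeline stage.

The generator emulates the statistical structure the discovery analysis
relies on:

* **host contigs** have a database hit and sense-only reads (mRNA);
* **viral segment pairs** (an RdRP-encoding RNA1 with planted palm motifs
  A/B/C and a companion RNA2) have no hit, reads on both strands at a
  configurable plus:minus ratio, identical k-nt termini within a pair, and
  co-segregating presence across samples with correlated read abundances.

Everything is driven by one integer seed through a single
``numpy.random.Generator``; identical parameters and seed give a
byte-identical file bundle.  What this emulates -- and what it does not
(no indels, no quality-value error model, no chimeras, no assembly) -- is
documented in the package methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .io import Contig
from .orfs import protein_mass

NT = np.array(list("ACGT"))
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codon choices per amino acid (standard genetic code), sorted for determinism
_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(_aa, []).append(_codon)
for _codons in _BACK_TABLE.values():
    _codons.sort()
_STOP_CODONS = sorted(CodonTable.unambiguous_dna_by_id[1].stop_codons)

#: padding kept free of planted features at each contig end, so that shared
#: termini can be overwritten without touching the ORF
TERMINAL_PAD = 25


@dataclass
class SyntheticParams:
    """Study-condition knobs of the generator.

    Defaults mirror the kind of dataset the analysis was designed for:
    150-bp stranded single-end reads, a handful of bisegmented viruses
    whose plus:minus read ratio departs from 1, host contigs with
    sense-only reads, and a small qPCR isolate panel.
    """

    n_host: int = 8
    n_viruses: int = 3
    contig_len_range: tuple[int, int] = (1500, 3200)
    read_len: int = 150
    depth_per_contig: float = 300.0
    plus_fraction: float | list[float] = 0.7
    host_plus_fraction: float = 1.0
    substitution_error_rate: float = 0.005
    triads: list[str] = field(default_factory=lambda: ["NDD", "GDQ", "SDD"])
    terminal_k: int = 20
    n_samples: int = 6
    paired: bool = False
    protocol: str = "fr_firststrand"
    seed: int = 0

    def validate(self) -> None:
        if self.n_host < 0 or self.n_viruses < 0 or self.n_samples < 1:
            raise ValueError("counts must be non-negative and n_samples >= 1")
        fracs = self.virus_plus_fractions()
        if any(not 0 < f < 1 for f in fracs):
            raise ValueError("plus_fraction must lie in (0, 1)")
        if any(len(t) != 3 or any(c not in AA20 for c in t) for t in self.triads):
            raise ValueError("triads must be 3-mers over the amino-acid alphabet")
        if self.contig_len_range[0] < 1200:
            raise ValueError("contigs shorter than 1200 nt cannot host the ORF")
        if self.substitution_error_rate < 0:
            raise ValueError("substitution_error_rate must be >= 0")
        if self.terminal_k > TERMINAL_PAD:
            raise ValueError(f"terminal_k must be <= {TERMINAL_PAD}")

    def virus_plus_fractions(self) -> list[float]:
        if isinstance(self.plus_fraction, (int, float)):
            return [float(self.plus_fraction)] * self.n_viruses
        if len(self.plus_fraction) != self.n_viruses:
            raise ValueError("plus_fraction list length must equal n_viruses")
        return [float(f) for f in self.plus_fraction]


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[rng.integers(0, 4, size=n)])


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_BACK_TABLE[aa][rng.integers(0, len(_BACK_TABLE[aa]))]
                   for aa in protein)


def make_orf_contig(contig_id: str, length: int, rng: np.random.Generator,
                    triad: str | None = None) -> tuple[Contig, dict]:
    """Build a contig carrying one long ATG..stop ORF, optionally with motifs.

    When ``triad`` is given, the translated ORF contains, in order, a
    conserved motif-A aspartate, the two motif-B glycines, and the requested
    motif-C triad, at recorded protein positions.  The encoded protein always
    weighs more than 15 kDa (a too-short ``length`` is a hard error).  An
    in-frame stop is planted just upstream of the initiator so the annotated
    ORF is exactly what a six-frame scan reports.
    """
    utr5 = TERMINAL_PAD + 5 + int(rng.integers(0, 30))
    utr3 = TERMINAL_PAD + 5 + int(rng.integers(0, 30))
    orf_nt = ((length - utr5 - utr3) // 3) * 3
    n_aa = orf_nt // 3 - 2            # minus initiator M and stop codon
    if n_aa < 160:
        raise ValueError(
            f"length {length} too short to encode a >15 kDa protein")
    body = "".join(AA20[i] for i in rng.integers(0, 20, size=n_aa))
    protein = list("M" + body)
    annotations: dict = {}
    if triad is not None:
        pos_a = 30 + int(rng.integers(0, 20))
        pos_b = pos_a + 25 + int(rng.integers(0, 15))
        pos_c = pos_b + 12 + int(rng.integers(0, 10))     # triad center
        protein[pos_a] = "D"
        protein[pos_b], protein[pos_b + 1] = "G", "G"
        protein[pos_c - 1:pos_c + 2] = list(triad)
        annotations.update(motif_a=pos_a, motif_b=(pos_b, pos_b + 1),
                           motif_c=pos_c, triad=triad)
    protein_str = "".join(protein)
    coding = ("ATG" + _back_translate(protein_str[1:], rng)
              + _STOP_CODONS[rng.integers(0, 3)])
    utr5_seq = _random_nt(rng, utr5)
    # in-frame stop immediately upstream of the ORF start
    utr5_seq = utr5_seq[:-3] + "TAA"
    seq = utr5_seq + coding + _random_nt(rng, length - utr5 - len(coding))
    annotations.update(orf_start=utr5, orf_end=utr5 + len(coding),
                       protein=protein_str,
                       mass_da=protein_mass(protein_str))
    if annotations["mass_da"] <= 15000:
        raise ValueError("generated protein unexpectedly below 15 kDa")
    return Contig(id=contig_id, seq=seq), annotations


def make_rdrp_contig(contig_id: str, length: int, triad: str,
                     seed: int | np.random.Generator) -> tuple[Contig, dict]:
    """RdRP-like segment: one long ORF with planted A/B/C motifs."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if len(triad) != 3:
        raise ValueError("triad must be a 3-mer")
    return make_orf_contig(contig_id, length, rng, triad=triad)


def make_rdrp_msa(n_rows: int, n_cols: int, seed: int,
                  triads: list[str] | str = "NDD",
                  conservation: float = 1.0,
                  col_a: int | None = None, col_b: int | None = None,
                  col_c: int | None = None) -> tuple[list[tuple[str, str]], dict]:
    """Synthetic protein MSA with planted motif columns.

    Columns ``col_a`` (D), ``col_b``/``col_b``+1 (G,G) and the triad around
    ``col_c`` are planted in every row, then hit by per-column substitution
    noise ``1 - conservation``; all other columns are uniform random.  The
    truth dict records the planted columns and the *emitted* per-row triads
    (i.e. after noise), which is what a faithful extractor must recover.
    """
    rng = np.random.default_rng(seed)
    if col_a is None:
        col_a = n_cols // 6
    if col_b is None:
        col_b = col_a + max(21, n_cols // 4)
    if col_c is None:
        col_c = col_b + max(7, n_cols // 6)
    if not (col_a < col_b < col_b + 1 < col_c - 1 and col_c + 1 < n_cols):
        raise ValueError("motif columns do not fit the alignment width")
    if isinstance(triads, str):
        triads = [triads]
    rows: list[tuple[str, str]] = []
    emitted: dict[str, str] = {}
    for i in range(n_rows):
        row = [AA20[k] for k in rng.integers(0, 20, size=n_cols)]
        triad = triads[i % len(triads)]
        row[col_a] = "D"
        row[col_b], row[col_b + 1] = "G", "G"
        row[col_c - 1:col_c + 2] = list(triad)
        for col in (col_a, col_b, col_b + 1, col_c - 1, col_c, col_c + 1):
            if rng.random() > conservation:
                row[col] = AA20[rng.integers(0, 20)]
        seq_id = f"seq_{i + 1}"
        rows.append((seq_id, "".join(row)))
        emitted[seq_id] = "".join(row[col_c - 1:col_c + 2])
    truth = {"col_a": col_a, "col_b": (col_b, col_b + 1), "col_c": col_c,
             "planted_triads": emitted}
    return rows, truth


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    chars = np.array(list(seq))
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        options = [c for c in "ACGT" if c != chars[i]]
        chars[i] = options[rng.integers(0, 3)]
    return "".join(chars)


def simulate_stranded_reads(contig: Contig, depth: float, plus_fraction: float,
                            protocol: str = "fr_firststrand",
                            error_rate: float = 0.0, read_len: int = 150,
                            rng: np.random.Generator | int = 0,
                            paired: bool = False,
                            qname_prefix: str = "read"
                            ) -> tuple[list[str], int, int]:
    """Simulate stranded reads from one contig as SAM body lines.

    The read count is Poisson(``depth``); each read's RNA of origin is
    Bernoulli(``plus_fraction``).  Flags are set so that the strand tally
    under the same ``protocol`` recovers the origin exactly (dUTP
    convention: a plus-origin single-end read aligns reverse).  Returns the
    records plus the ground-truth plus/minus counts.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if contig.length < read_len:
        raise ValueError("contig shorter than the read length")
    if protocol not in ("fr_firststrand", "fr_secondstrand"):
        raise ValueError(f"unknown stranded protocol {protocol!r}")
    n = int(rng.poisson(depth))
    lines: list[str] = []
    n_plus = n_minus = 0
    for i in range(n):
        origin_plus = bool(rng.random() < plus_fraction)
        n_plus += origin_plus
        n_minus += not origin_plus
        pos = int(rng.integers(0, contig.length - read_len + 1))
        seq = _mutate(contig.seq[pos:pos + read_len], error_rate, rng)
        qual = "I" * read_len
        r1_reverse = origin_plus if protocol == "fr_firststrand" else not origin_plus
        qname = f"{qname_prefix}_{contig.id}_{i}"
        if not paired:
            flag = 0x10 if r1_reverse else 0
            lines.append("\t".join([qname, str(flag), contig.id, str(pos + 1),
                                    "60", f"{read_len}M", "*", "0", "0",
                                    seq, qual]))
        else:
            f1 = 0x1 | 0x2 | 0x40 | (0x10 if r1_reverse else 0x20)
            f2 = 0x1 | 0x2 | 0x80 | (0x20 if r1_reverse else 0x10)
            for flag in (f1, f2):
                lines.append("\t".join([qname, str(flag), contig.id,
                                        str(pos + 1), "60", f"{read_len}M",
                                        "=", str(pos + 1), "0", seq, qual]))
    return lines, n_plus, n_minus


def sam_header(contigs: list[Contig]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{c.id}\tLN:{c.length}" for c in contigs]
    return lines


def generate_dataset(params: SyntheticParams,
                     out_dir: str | Path) -> tuple[dict[str, Path], dict]:
    """Emit a complete input bundle plus its truth manifest.

    Files written under ``out_dir``: ``contigs.fasta``, ``hits.tsv``
    (every host contig with a strong hit, never a viral one), one
    ``reads_<sample>.sam`` per sample, ``ct.tsv`` (Ct ~ Uniform(20, 30)
    where present, blank otherwise), ``counts.tsv`` (segments x samples),
    and ``manifest.json`` with labels, RNA1/RNA2 pairings, planted ORF and
    motif coordinates, per-virus plus fractions, per-sample presence and
    per-(contig, sample) true strand tallies.
    """
    from .io import write_fasta

    params.validate()
    rng = np.random.default_rng(params.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lo, hi = params.contig_len_range
    samples = [f"S{i + 1}" for i in range(params.n_samples)]
    fracs = params.virus_plus_fractions()

    contigs: list[Contig] = []
    manifest: dict = {"labels": {}, "pairs": [], "orfs": {},
                      "plus_fraction": {}, "presence": {},
                      "strand_truth": {}, "params": {
                          "seed": params.seed, "n_host": params.n_host,
                          "n_viruses": params.n_viruses,
                          "n_samples": params.n_samples,
                          "protocol": params.protocol,
                          "error_rate": params.substitution_error_rate}}

    for h in range(params.n_host):
        cid = f"host_{h + 1}"
        length = int(rng.integers(lo, hi + 1))
        contigs.append(Contig(id=cid, seq=_random_nt(rng, length)))
        manifest["labels"][cid] = "host"

    depth_factor: dict[tuple[str, str], float] = {}
    for v in range(params.n_viruses):
        rna1_id, rna2_id = f"virus{v + 1}_rna1", f"virus{v + 1}_rna2"
        triad = params.triads[v % len(params.triads)]
        rna1_lo = min(max(lo, 1800), hi)
        rna1, ann1 = make_orf_contig(rna1_id, int(rng.integers(rna1_lo, hi + 1)),
                                     rng, triad=triad)
        rna2, ann2 = make_orf_contig(rna2_id, int(rng.integers(lo, max(lo + 1, hi - 500))),
                                     rng)
        # a segment pair shares its first/last k nucleotides
        k = params.terminal_k
        rna2 = Contig(id=rna2_id,
                      seq=rna1.seq[:k] + rna2.seq[k:-k] + rna1.seq[-k:])
        contigs += [rna1, rna2]
        manifest["labels"][rna1_id] = "viral_rna1"
        manifest["labels"][rna2_id] = "viral_rna2"
        manifest["pairs"].append([rna1_id, rna2_id])
        manifest["orfs"][rna1_id] = _jsonable(ann1)
        manifest["orfs"][rna2_id] = _jsonable(ann2)
        manifest["plus_fraction"][rna1_id] = fracs[v]
        manifest["plus_fraction"][rna2_id] = fracs[v]
        # each virus infects a distinct subset of samples (>=2, so that
        # co-occurrence is informative); distinct patterns are what make
        # cross-virus pairs distinguishable, as in a real isolate panel
        seen = {frozenset(manifest["presence"][cid])
                for cid in manifest["presence"]}
        for _ in range(1000):
            n_pos = int(rng.integers(2, params.n_samples + 1))
            pos_idx = sorted(rng.choice(params.n_samples, size=n_pos,
                                        replace=False))
            present = [samples[i] for i in pos_idx]
            if frozenset(present) not in seen:
                break
        else:
            raise ValueError(
                "cannot draw distinct presence patterns: too many viruses "
                f"for {params.n_samples} samples")
        manifest["presence"][rna1_id] = present
        manifest["presence"][rna2_id] = present
        rna2_scale = float(rng.uniform(0.6, 1.6))
        for s in present:
            shared = float(rng.lognormal(0.0, 0.6))
            depth_factor[(rna1_id, s)] = shared
            depth_factor[(rna2_id, s)] = shared * rna2_scale

    fasta_path = out_dir / "contigs.fasta"
    write_fasta(contigs, fasta_path)

    hits_path = out_dir / "hits.tsv"
    with open(hits_path, "w") as fh:
        for c in contigs:
            if manifest["labels"][c.id] != "host":
                continue
            fh.write("\t".join([c.id, f"nr|{c.id}_protein", "92.3", "250",
                                "10", "0", "1", "750", "1", "250",
                                "1e-80", "310.5"]) + "\n")

    counts: dict[str, dict[str, int]] = {
        c.id: {s: 0 for s in samples} for c in contigs
        if manifest["labels"][c.id] != "host"}
    sam_paths: list[Path] = []
    header = sam_header(contigs)
    for s in samples:
        lines: list[str] = list(header)
        for c in contigs:
            label = manifest["labels"][c.id]
            if label == "host":
                depth = params.depth_per_contig * float(rng.lognormal(0.0, 0.4))
                frac = params.host_plus_fraction
                # sense-only hosts: clamp the Bernoulli off the open interval
                frac = min(max(frac, 1e-12), 1 - 1e-12)
            else:
                if s not in manifest["presence"][c.id]:
                    continue
                depth = params.depth_per_contig * depth_factor[(c.id, s)]
                frac = manifest["plus_fraction"][c.id]
            recs, n_plus, n_minus = simulate_stranded_reads(
                c, depth=depth, plus_fraction=frac, protocol=params.protocol,
                error_rate=params.substitution_error_rate,
                read_len=params.read_len, rng=rng, paired=params.paired,
                qname_prefix=f"{s}")
            lines += recs
            manifest["strand_truth"].setdefault(c.id, {})[s] = [n_plus, n_minus]
            if c.id in counts:
                counts[c.id][s] = n_plus + n_minus
        path = out_dir / f"reads_{s}.sam"
        path.write_text("\n".join(lines) + "\n")
        sam_paths.append(path)

    ct_path = out_dir / "ct.tsv"
    with open(ct_path, "w") as fh:
        fh.write("segment\t" + "\t".join(samples) + "\n")
        for cid in sorted(counts):
            cells = []
            for s in samples:
                if s in manifest["presence"][cid]:
                    cells.append(f"{rng.uniform(20.0, 30.0):.2f}")
                else:
                    cells.append("")
            fh.write(cid + "\t" + "\t".join(cells) + "\n")

    counts_path = out_dir / "counts.tsv"
    with open(counts_path, "w") as fh:
        fh.write("segment\t" + "\t".join(samples) + "\n")
        for cid in sorted(counts):
            fh.write(cid + "\t"
                     + "\t".join(str(counts[cid][s]) for s in samples) + "\n")

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths = {"contigs": fasta_path, "hits": hits_path, "ct": ct_path,
             "counts": counts_path, "manifest": manifest_path,
             "alignments": sam_paths}
    return paths, manifest


def _jsonable(ann: dict) -> dict:
    out = {}
    for key, value in ann.items():
        out[key] = list(value) if isinstance(value, tuple) else value
    return out
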