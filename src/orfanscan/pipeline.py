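"""End-to-end orchestration of the discovery stages.

Order of operations: ORFan filtering -> strand profiling (both-strand keep
rule on tallies pooled across libraries) -> clade clustering on the kept
candidates' best proteins -> optional motif/triad scan (when a curated MSA
is supplied) -> segment association over all kept-candidate pairs.  Every
stage writes a TSV; ``summary.json`` collects the headline numbers together
with the full effective configuration, and re-running with identical inputs
is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import BaseModel

from . import clades as clades_mod
from . import io, motifs as motifs_mod, orfs, segments as seg_mod, strand

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one discovery run."""

    contigs: str = ""
    hits: str = ""
    alignments: list[str] = field(default_factory=list)
    ct: str | None = None
    counts: str | None = None
    msa: str | None = None
    out_dir: str = "orfanscan_out"

    evalue_max: float = 1e-3
    min_len: int = 1000
    min_mass: float = 15000.0
    genetic_code_id: int = 1
    require_atg: bool = True

    protocol: str = "fr_firststrand"
    min_each: int = 1
    min_total: int = 10
    dominance_ratio: float = 1.0

    identity_threshold: float = 15.0

    motif_min_frac: float = 0.7
    motif_min_ab_gap: int = 20
    motif_min_bc_gap: int = 5

    ct_cutoff: float = 38.0
    terminal_k: int = 20
    max_mism5: int = 2
    max_mism3: int = 2
    min_shared_positive: int = 2
    min_r: float = 0.9
    min_libraries: int = 3

    seed: int = 0
    log_level: str = "INFO"

    def association_rules(self) -> seg_mod.AssociationRules:
        return seg_mod.AssociationRules(
            terminal_k=self.terminal_k, max_mism5=self.max_mism5,
            max_mism3=self.max_mism3,
            min_shared_positive=self.min_shared_positive,
            min_r=self.min_r, min_libraries=self.min_libraries)

    def as_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


class AssociationRow(BaseModel):
    rna1_id: str
    rna2_id: str
    call: str
    grades: list[str]
    mism5: int | None = None
    mism3: int | None = None
    jaccard: float | None = None
    abundance_r: float | None = None


class DiscoveryReport(BaseModel):
    """Machine-readable run summary; its JSON schema ships with the package."""

    n_contigs: int
    n_candidates: int
    n_kept: int
    rejection_counts: dict[str, int]
    n_clades: int
    clades: dict[str, str]
    polarity: dict[str, str]
    triad_tally: dict[str, int] | None
    triad_mode: str | None
    motif_stage: str
    n_associated: int
    associations: list[AssociationRow]
    config: dict


def run_discovery(config: PipelineConfig) -> DiscoveryReport:
    """Run every stage, write per-stage TSVs plus summary.json, return summary.

    Missing input files raise ``FileNotFoundError`` (the CLI converts that
    to a non-zero exit).  An empty contig FASTA yields an empty report with
    success status.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in [config.contigs, config.hits, *config.alignments,
                 config.ct, config.counts, config.msa]:
        if path and not Path(path).exists():
            raise FileNotFoundError(f"input file not found: {path}")

    contigs = io.read_fasta(config.contigs)
    hit_queries = io.read_hits_table(config.hits, evalue_max=config.evalue_max)

    # stage 1: ORFan candidate screen
    screen = orfs.select_orfan_candidates(
        contigs, hit_queries, min_len=config.min_len,
        min_mass=config.min_mass, genetic_code_id=config.genetic_code_id,
        require_atg=config.require_atg)
    _write_candidates(screen, out)

    # stage 2: stranded tallies per library, pooled for the keep rule
    candidate_ids = set(screen.candidate_ids)
    per_library: list[strand.StrandProfile] = []
    for sam_path in config.alignments:
        library = Path(sam_path).stem
        tally = strand.tally_strand(io.read_alignments(sam_path),
                                    protocol=config.protocol,
                                    library_id=library,
                                    contig_ids=candidate_ids or None)
        per_library += list(tally.profiles.values())
    pooled = strand.merge_profiles(per_library)
    classified = {cid: strand.classify_profile(
                      p, min_each=config.min_each, min_total=config.min_total,
                      dominance_ratio=config.dominance_ratio)
                  for cid, p in pooled.items()}
    if config.alignments:
        kept = [c for c in screen.candidates
                if classified.get(c.contig.id) is not None
                and classified[c.contig.id].keep]
    else:                      # no read evidence supplied: keep rule inapplicable
        kept = list(screen.candidates)
    _write_strand_table(per_library, classified, config, out)

    # stage 3: clades over kept candidates' best proteins (pairwise fallback)
    proteins = [(c.contig.id, c.best_orf.protein) for c in kept]
    if len(proteins) >= 2:
        matrix = clades_mod.pairwise_identity(proteins, aligned=False)
        assignment = clades_mod.cluster_clades(
            matrix, threshold_pct=config.identity_threshold)
        matrix.to_dataframe().round(1).to_csv(out / "identity_matrix.tsv",
                                              sep="\t")
    else:
        assignment = {pid: "clade_1" for pid, _ in proteins}
    with open(out / "clades.tsv", "w") as fh:
        fh.write("id\tclade\n")
        for cid in sorted(assignment):
            fh.write(f"{cid}\t{assignment[cid]}\n")

    # stage 4: motif scan, only on a supplied curated MSA
    triad_tally = triad_mode = None
    motif_stage = "skipped (no MSA supplied)"
    if config.msa:
        msa = io.read_protein_fasta(config.msa, require_equal_length=True)
        anchors = motifs_mod.locate_motif_anchors(
            msa, min_frac=config.motif_min_frac,
            min_ab_gap=config.motif_min_ab_gap,
            min_bc_gap=config.motif_min_bc_gap)
        if anchors is None:
            motif_stage = "no anchors found"
        else:
            result = motifs_mod.extract_triads(msa, anchors)
            triad_tally = dict(sorted(result.tally.items()))
            triad_mode = result.mode
            motif_stage = "completed"
            with open(out / "triads.tsv", "w") as fh:
                fh.write("seq_id\ttriad\tstatus\tclade\n")
                for call in result.calls:
                    fh.write(f"{call.seq_id}\t{call.triad}\t{call.status}\t"
                             f"{assignment.get(call.seq_id, 'unassigned')}\n")
            motifs_mod.write_annotated_alignment(msa, anchors,
                                                 str(out / "alignment_annotated.txt"))

    # stage 5: association over kept-candidate pairs
    ct_table = io.read_ct_table(config.ct) if config.ct else None
    counts = io.read_counts_table(config.counts) if config.counts else None
    segment_seqs = {c.contig.id: c.contig.seq for c in kept}
    evidence = seg_mod.associate_all(segment_seqs, ct_table=ct_table,
                                     counts=counts, ct_cutoff=config.ct_cutoff,
                                     rules=config.association_rules())
    _write_evidence(evidence, out)

    report = DiscoveryReport(
        n_contigs=len(contigs),
        n_candidates=len(screen.candidates),
        n_kept=len(kept),
        rejection_counts=_count_values(screen.rejections),
        n_clades=len(set(assignment.values())),
        clades=dict(sorted(assignment.items())),
        polarity={cid: p.polarity for cid, p in sorted(classified.items())
                  if p.polarity is not None},
        triad_tally=triad_tally,
        triad_mode=triad_mode,
        motif_stage=motif_stage,
        n_associated=sum(e.call == "associated" for e in evidence),
        associations=[AssociationRow(
            rna1_id=e.rna1_id, rna2_id=e.rna2_id, call=e.call,
            grades=e.grades,
            mism5=e.terminal.mism5 if e.terminal else None,
            mism3=e.terminal.mism3 if e.terminal else None,
            jaccard=e.jaccard, abundance_r=e.abundance_r)
            for e in evidence],
        config=config.as_dict(),
    )
    (out / "summary.json").write_text(
        json.dumps(report.model_dump(), indent=1, sort_keys=True))
    (out / "summary.schema.json").write_text(
        json.dumps(DiscoveryReport.model_json_schema(), indent=1, sort_keys=True))
    return report


def _count_values(rejections: dict[str, str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for reason in rejections.values():
        counts[reason] = counts.get(reason, 0) + 1
    return dict(sorted(counts.items()))


def _write_candidates(screen: orfs.OrfanScreen, out: Path) -> None:
    with open(out / "candidates.tsv", "w") as fh:
        fh.write("contig_id\tlength\torf_start\torf_end\tstrand\t"
                 "protein_aa\tmass_kda\treasons\n")
        for c in screen.candidates:
            o = c.best_orf
            # 1-based inclusive coordinates in reports
            fh.write(f"{c.contig.id}\t{c.contig.length}\t{o.start + 1}\t{o.end}\t"
                     f"{o.strand}\t{len(o.protein)}\t{o.mass_da / 1000:.2f}\t"
                     f"{','.join(c.reasons)}\n")
        for cid in sorted(screen.rejections):
            fh.write(f"# rejected\t{cid}\t{screen.rejections[cid]}\n")
    io.write_fasta([(c.contig.id, c.contig.seq) for c in screen.candidates],
                   out / "candidates.fasta")
    io.write_fasta([(c.contig.id, c.best_orf.protein) for c in screen.candidates],
                   out / "candidates_protein.fasta")


def _write_strand_table(per_library: list[strand.StrandProfile],
                        classified: dict[str, strand.StrandProfile],
                        config: PipelineConfig, out: Path) -> None:
    with open(out / "strand_profiles.tsv", "w") as fh:
        fh.write("contig_id\tlibrary\ttotal\tpos\tneg\tpolarity\tkeep\n")
        for p in sorted(per_library, key=lambda p: (p.contig_id, p.library_id)):
            fh.write(f"{p.contig_id}\t{p.library_id}\t{p.total}\t"
                     f"{p.plus_count}\t{p.minus_count}\t\t\n")
        for cid in sorted(classified):
            p = classified[cid]
            fh.write(f"{p.contig_id}\tpooled\t{p.total}\t{p.plus_count}\t"
                     f"{p.minus_count}\t{p.polarity}\t{p.keep}\n")


def _write_evidence(evidence: list[seg_mod.AssociationEvidence],
                    out: Path) -> None:
    with open(out / "associations.tsv", "w") as fh:
        fh.write("id_a\tid_b\tmism5\tmism3\tjaccard\texact\t"
                 "n_shared\tr\tn_libraries\tgrades\tcall\n")
        for e in evidence:
            fh.write("\t".join([
                e.rna1_id, e.rna2_id,
                str(e.terminal.mism5) if e.terminal else "",
                str(e.terminal.mism3) if e.terminal else "",
                f"{e.jaccard:.3f}" if e.jaccard is not None else "",
                str(e.exact_cooccurrence) if e.exact_cooccurrence is not None else "",
                str(e.n_shared_positive),
                f"{e.abundance_r:.4f}" if e.abundance_r is not None else "",
                str(e.n_libraries),
                ",".join(e.grades), e.call]) + "\n")
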