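import json

import numpy as np
import pytest

from orfanscan.io import read_alignments, read_ct_table, read_fasta
from orfanscan.orfs import find_orfs, protein_mass
from orfanscan.segments import binarize_ct
from orfanscan.simulate import (SyntheticParams, generate_dataset,
                                make_rdrp_contig, simulate_stranded_reads)
from conftest import noise_free_params


class TestRdrpContig:
    @pytest.mark.parametrize("seed", range(20))
    def test_planted_orf_and_mass_constraint(self, seed):
        contig, ann = make_rdrp_contig("r1", 2400, "GDQ", seed)
        assert ann["mass_da"] > 15000
        protein = ann["protein"]
        assert protein[ann["motif_c"] - 1:ann["motif_c"] + 2] == "GDQ"
        assert protein[ann["motif_a"]] == "D"
        b1, b2 = ann["motif_b"]
        assert protein[b1] + protein[b2] == "GG"

    def test_six_frame_scan_reports_planted_orf(self):
        contig, ann = make_rdrp_contig("r1", 2400, "NDD", 7)
        best = find_orfs(contig)[0]
        assert (best.start, best.end) == (ann["orf_start"], ann["orf_end"])
        assert best.protein == ann["protein"]
        assert best.strand == "+" and best.complete5 and best.complete3

    def test_determinism(self):
        a, _ = make_rdrp_contig("r1", 1800, "SDD", 42)
        b, _ = make_rdrp_contig("r1", 1800, "SDD", 42)
        assert a == b

    def test_too_short_is_error(self):
        with pytest.raises(ValueError, match="too short"):
            make_rdrp_contig("r1", 550, "NDD", 0)


class TestStrandedReads:
    def _contig(self, n=1500, seed=0):
        rng = np.random.default_rng(seed)
        from orfanscan.io import Contig
        return Contig("v", "".join(np.array(list("ACGT"))[
            rng.integers(0, 4, size=n)]))

    def test_pure_plus_decodes_pure_plus(self):
        from orfanscan.strand import tally_strand
        contig = self._contig()
        lines, n_plus, n_minus = simulate_stranded_reads(
            contig, depth=80, plus_fraction=1 - 1e-12,
            rng=np.random.default_rng(1))
        assert n_minus == 0

    def test_error_free_reads_are_substrings(self):
        contig = self._contig()
        lines, *_ = simulate_stranded_reads(contig, depth=50,
                                            plus_fraction=0.5, error_rate=0.0,
                                            rng=np.random.default_rng(2))
        for line in lines:
            seq = line.split("\t")[9]
            assert seq in contig.seq

    def test_errors_perturb_but_preserve_length(self):
        contig = self._contig()
        lines, *_ = simulate_stranded_reads(contig, depth=60,
                                            plus_fraction=0.5, error_rate=0.1,
                                            rng=np.random.default_rng(3))
        seqs = [line.split("\t")[9] for line in lines]
        assert all(len(s) == 150 for s in seqs)
        assert any(s not in contig.seq for s in seqs)

    def test_binomial_concentration_across_seeds(self):
        # decoded plus fraction within 3*sqrt(p(1-p)/n) in >= 19/20 runs
        contig = self._contig(2000)
        p, depth = 0.1, 1000
        ok = 0
        for seed in range(20):
            _, n_plus, n_minus = simulate_stranded_reads(
                contig, depth=depth, plus_fraction=p,
                rng=np.random.default_rng(seed))
            n = n_plus + n_minus
            ok += abs(n_plus / n - p) <= 3 * np.sqrt(p * (1 - p) / n)
        assert ok >= 19


class TestBundle:
    def test_manifest_structure(self, synthetic_bundle):
        _, manifest = synthetic_bundle
        rna1 = [c for c, l in manifest["labels"].items() if l == "viral_rna1"]
        rna2 = [c for c, l in manifest["labels"].items() if l == "viral_rna2"]
        assert len(rna1) == len(rna2) == 3
        assert {frozenset(p) for p in manifest["pairs"]} == \
               {frozenset((a, b)) for a, b in zip(sorted(rna1), sorted(rna2))}

    def test_hits_cover_hosts_and_never_virus(self, synthetic_bundle):
        paths, manifest = synthetic_bundle
        from orfanscan.io import read_hits_table
        hit_ids = read_hits_table(paths["hits"], evalue_max=1e-3)
        hosts = {c for c, l in manifest["labels"].items() if l == "host"}
        viral = set(manifest["labels"]) - hosts
        assert hit_ids == hosts
        assert not hit_ids & viral

    def test_sam_parseable_and_matches_truth(self, synthetic_bundle):
        paths, manifest = synthetic_bundle
        from orfanscan.strand import tally_strand
        sam = paths["alignments"][0]
        sample = sam.stem.replace("reads_", "")
        tally = tally_strand(read_alignments(sam), "fr_firststrand")
        for cid, profile in tally.profiles.items():
            truth = manifest["strand_truth"][cid][sample]
            assert [profile.plus_count, profile.minus_count] == truth

    def test_ct_presence_matches_manifest(self, synthetic_bundle):
        paths, manifest = synthetic_bundle
        presence = binarize_ct(read_ct_table(paths["ct"]))
        for cid in presence.index:
            present = set(presence.columns[presence.loc[cid]])
            assert present == set(manifest["presence"][cid])

    def test_pair_termini_shared(self, synthetic_bundle):
        paths, manifest = synthetic_bundle
        seqs = {c.id: c.seq for c in read_fasta(paths["contigs"])}
        k = 20
        for rna1, rna2 in manifest["pairs"]:
            assert seqs[rna1][:k] == seqs[rna2][:k]
            assert seqs[rna1][-k:] == seqs[rna2][-k:]

    def test_byte_identical_regeneration(self, tmp_path):
        params = noise_free_params(seed=5)
        paths_a, _ = generate_dataset(params, tmp_path / "a")
        paths_b, _ = generate_dataset(noise_free_params(seed=5), tmp_path / "b")
        for key in ("contigs", "hits", "ct", "counts", "manifest"):
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes()
        for sam_a, sam_b in zip(paths_a["alignments"], paths_b["alignments"]):
            assert sam_a.read_bytes() == sam_b.read_bytes()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SyntheticParams(n_samples=0).validate()
        with pytest.raises(ValueError):
            SyntheticParams(plus_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SyntheticParams(triads=["GDDD"]).validate()
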