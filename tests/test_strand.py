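import numpy as np
import pytest

from orfanscan.io import AlignedRead, Contig, read_alignments
from orfanscan.simulate import simulate_stranded_reads
from orfanscan.strand import (StrandProfile, TallyResult, classify_profile,
                              merge_profiles, tally_strand)


def _read(ref="c", reverse=False, mapped=True, first=None, name="r"):
    return AlignedRead(read_id=name, ref_id=ref, is_mapped=mapped,
                       is_reverse=reverse if mapped else None,
                       is_first_in_pair=first)


class TestTally:
    def test_firststrand_convention_single_end(self):
        # dUTP chemistry: a forward single-end read comes from antisense RNA
        result = tally_strand([_read(reverse=True), _read(reverse=False)],
                              protocol="fr_firststrand")
        profile = result.profiles["c"]
        assert (profile.plus_count, profile.minus_count) == (1, 1)

    def test_second_in_pair_flips_rule(self):
        reads = [_read(reverse=False, first=True),
                 _read(reverse=False, first=False)]
        profiles = tally_strand(reads, protocol="fr_firststrand").profiles
        assert (profiles["c"].plus_count, profiles["c"].minus_count) == (1, 1)

    def test_protocol_flip_swaps_counts_exactly(self):
        rng = np.random.default_rng(3)
        reads = [_read(reverse=bool(rng.integers(2)), name=f"r{i}")
                 for i in range(200)]
        first = tally_strand(reads, "fr_firststrand").profiles["c"]
        second = tally_strand(reads, "fr_secondstrand").profiles["c"]
        assert (first.plus_count, first.minus_count) == \
               (second.minus_count, second.plus_count)

    def test_unmapped_ignored_and_counted(self):
        result = tally_strand([_read(mapped=False), _read(reverse=True)],
                              protocol="fr_firststrand")
        assert result.n_unmapped == 1
        assert result.n_counted == 1

    def test_unknown_ref_counted_separately(self, caplog):
        with caplog.at_level("WARNING"):
            result = tally_strand([_read(ref="other"), _read(ref="c")],
                                  protocol="fr_firststrand",
                                  contig_ids={"c"})
        assert result.n_unknown_ref == 1
        assert set(result.profiles) == {"c"}

    def test_conservation_of_read_count(self):
        rng = np.random.default_rng(9)
        refs = [f"c{i}" for i in range(5)]
        reads = [_read(ref=refs[rng.integers(5)], reverse=bool(rng.integers(2)),
                       name=f"r{i}") for i in range(500)]
        result = tally_strand(reads, "fr_firststrand")
        assert result.n_counted == 500

    def test_unknown_protocol(self):
        with pytest.raises(ValueError, match="protocol"):
            tally_strand([], protocol="unstranded")


class TestClassify:
    @pytest.mark.parametrize("plus,minus,polarity,keep", [
        (3360, 1450, "plus_dominant", True),    # ElaOMV1 RNA1 tallies
        (518, 3262, "minus_dominant", True),    # ElaOMV2 RNA1 tallies
        (0, 500, "minus_dominant", False),      # one-strand contig: discarded
        (5, 5, "balanced", True),
        (4, 3, "insufficient", True),
    ])
    def test_rules(self, plus, minus, polarity, keep):
        profile = StrandProfile("c", "lib", plus_count=plus, minus_count=minus)
        out = classify_profile(profile)
        assert (out.polarity, out.keep) == (polarity, keep)
        assert out.total == plus + minus

    def test_dominance_ratio_configurable(self):
        profile = StrandProfile("c", plus_count=60, minus_count=40)
        assert classify_profile(profile, dominance_ratio=2.0).polarity == "balanced"
        assert classify_profile(profile, dominance_ratio=1.0).polarity == "plus_dominant"


class TestSimulatedRoundTrip:
    def test_generator_truth_recovered(self, tmp_path, rng):
        contig = Contig("v", "".join(np.array(list("ACGT"))[
            rng.integers(0, 4, size=2000)]))
        lines, n_plus, n_minus = simulate_stranded_reads(
            contig, depth=100, plus_fraction=0.7, rng=rng)
        sam = tmp_path / "sim.sam"
        sam.write_text("\n".join(lines) + "\n")
        profile = tally_strand(read_alignments(sam),
                               "fr_firststrand").profiles["v"]
        assert (profile.plus_count, profile.minus_count) == (n_plus, n_minus)

    @pytest.mark.parametrize("protocol", ["fr_firststrand", "fr_secondstrand"])
    def test_paired_reads_decode_consistently(self, tmp_path, rng, protocol):
        contig = Contig("v", "".join(np.array(list("ACGT"))[
            rng.integers(0, 4, size=1000)]))
        lines, n_plus, n_minus = simulate_stranded_reads(
            contig, depth=50, plus_fraction=0.3, protocol=protocol,
            rng=rng, paired=True)
        sam = tmp_path / "sim.sam"
        sam.write_text("\n".join(lines) + "\n")
        profile = tally_strand(read_alignments(sam), protocol).profiles["v"]
        # both mates decode to the fragment's origin strand
        assert (profile.plus_count, profile.minus_count) == \
               (2 * n_plus, 2 * n_minus)

    def test_plus_fraction_converges(self):
        # binomial concentration: |p_hat - p| <= 3*sqrt(p(1-p)/n) at n >= 1000
        p, n = 0.7, 2000
        contig_rng = np.random.default_rng(0)
        contig = Contig("v", "".join(np.array(list("ACGT"))[
            contig_rng.integers(0, 4, size=2000)]))
        failures = 0
        for seed in range(10):
            _, n_plus, n_minus = simulate_stranded_reads(
                contig, depth=n, plus_fraction=p,
                rng=np.random.default_rng(seed))
            total = n_plus + n_minus
            if abs(n_plus / total - p) > 3 * np.sqrt(p * (1 - p) / total):
                failures += 1
        assert failures <= 1


def test_merge_profiles_sums_libraries():
    profiles = [StrandProfile("c", "lib1", 10, 2),
                StrandProfile("c", "lib2", 5, 8),
                StrandProfile("d", "lib1", 0, 1)]
    pooled = merge_profiles(profiles)
    assert (pooled["c"].plus_count, pooled["c"].minus_count) == (15, 10)
    assert pooled["d"].total == 1
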