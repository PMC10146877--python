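"""Quality filtering, demultiplexing, anchor extraction and counting,
checked against naive brute-force oracles on small fixtures."""

import random

import pytest

import ptcscape as P
from ptcscape.designs import reverse_complement, rna_to_dna
from ptcscape.reads import (
    ReadPair,
    extract_variant_detail,
    iter_fastq_pairs,
    mean_phred,
)

from conftest import toy_design


def make_pair(design, scheme, condition, variant_rna, rid="r1", q="I"):
    """Handcrafted error-free read pair with the simulator's amplicon layout."""
    amplicon = (
        scheme.forward(condition)
        + design.upstream_anchor
        + rna_to_dna(variant_rna)
        + design.downstream_anchor
        + reverse_complement(scheme.reverse(condition))
    )
    s1 = amplicon[:150]
    s2 = reverse_complement(amplicon)[:150]
    return ReadPair(rid, s1, q * len(s1), s2, q * len(s2))


class TestQualityFilter:
    def test_high_quality_kept(self):
        pair = ReadPair("r", "ACGT", "IIII", "ACGT", "IIII")  # Q40
        assert P.quality_filter(pair, 20.0)

    def test_low_quality_discarded(self):
        pair = ReadPair("r", "ACGT", "####", "ACGT", "IIII")  # Q2 mate
        assert not P.quality_filter(pair, 20.0)

    def test_threshold_is_inclusive(self):
        q20 = chr(33 + 20)
        pair = ReadPair("r", "ACGT", q20 * 4, "ACGT", q20 * 4)
        assert P.quality_filter(pair, 20.0)

    def test_mean_phred_values(self):
        assert mean_phred("II") == 40.0
        assert mean_phred(chr(33) + chr(33 + 40)) == 20.0

    def test_malformed_quality_raises(self):
        with pytest.raises(ValueError):
            mean_phred(chr(20) * 4)


class TestDemultiplex:
    def test_published_barcodes_route_to_conditions(self, scheme):
        filler = "ACGT" * 30
        for cond in ("positive", "negative", "unselected"):
            pair = ReadPair(
                "r",
                scheme.forward(cond) + filler,
                "I" * 150,
                scheme.reverse(cond) + filler,
                "I" * 150,
            )
            assert P.demultiplex(pair, scheme) == cond

    def test_random_prefix_unassigned(self, scheme):
        rng = random.Random(0)
        filler = "".join(rng.choice("ACGT") for _ in range(150))
        pair = ReadPair("r", filler, "I" * 150, filler, "I" * 150)
        assert P.demultiplex(pair, scheme) is None

    def test_one_mismatch_tolerated_two_rejected(self, scheme):
        fwd = scheme.forward("positive")
        rev = scheme.reverse("positive")
        filler = "ACGT" * 30
        one_mm = "G" + fwd[1:] if fwd[0] != "G" else "C" + fwd[1:]
        pair = ReadPair("r", one_mm + filler, "I" * 150, rev + filler, "I" * 150)
        assert P.demultiplex(pair, scheme, max_mismatch=1) == "positive"
        two_mm = one_mm[:5] + ("G" if one_mm[5] != "G" else "C") + one_mm[6:]
        pair2 = ReadPair("r", two_mm + filler, "I" * 150, rev + filler, "I" * 150)
        assert P.demultiplex(pair2, scheme, max_mismatch=1) is None

    def test_mates_must_agree_on_condition(self, scheme):
        filler = "ACGT" * 30
        pair = ReadPair(
            "r",
            scheme.forward("positive") + filler,
            "I" * 150,
            scheme.reverse("negative") + filler,
            "I" * 150,
        )
        assert P.demultiplex(pair, scheme) is None


class TestExtractVariant:
    def test_round_trip_with_simulated_layout(self, design_2058, scheme):
        pair = make_pair(design_2058, scheme, "positive", "GGAUC")
        assert P.extract_variant(pair, design_2058) == "GGAUC"

    def test_missing_anchor_returns_none(self, design_2058):
        pair = ReadPair("r", "ACGT" * 37, "I" * 148, "ACGT" * 37, "I" * 148)
        variant, status = extract_variant_detail(pair, design_2058)
        assert variant is None and status == "no_anchor"

    def test_disagreeing_mates_are_ambiguous(self, design_2058, scheme):
        pair = make_pair(design_2058, scheme, "positive", "GGAUC")
        # corrupt one window base on R1 only
        pos = len(scheme.forward("positive")) + len(design_2058.upstream_anchor)
        s1 = pair.seq1[:pos] + "A" + pair.seq1[pos + 1:]
        assert pair.seq1[pos] != "A"
        corrupted = pair._replace(seq1=s1)
        variant, status = extract_variant_detail(corrupted, design_2058)
        assert variant is None and status == "ambiguous"

    def test_single_covering_mate_suffices(self, design_2058, scheme):
        pair = make_pair(design_2058, scheme, "positive", "CCCCC")
        no_r2 = pair._replace(seq2="ACGT" * 37, qual2="I" * 148)
        assert P.extract_variant(no_r2, design_2058) == "CCCCC"

    def test_anchor_mismatch_tolerance(self, design_2058, scheme):
        pair = make_pair(design_2058, scheme, "positive", "GGAUC")
        start = len(scheme.forward("positive"))
        s1 = list(pair.seq1)
        s1[start] = "A" if s1[start] != "A" else "G"  # 1 mm in upstream anchor
        broken = pair._replace(seq1="".join(s1))
        variant, status = extract_variant_detail(broken, design_2058, 1)
        assert status == "ok" and variant == "GGAUC"


class TestCountVariants:
    def test_handcrafted_reads_match_brute_force_oracle(self, design_2058, scheme):
        """30 error-free reads tallied independently by a naive dict loop."""
        rng = random.Random(7)
        variants = ["".join(rng.choice("ACGU") for _ in range(5)) for _ in range(10)]
        expected = {c: {} for c in ("positive", "negative", "unselected")}
        pairs = []
        i = 0
        for cond in expected:
            for v in variants:
                # naive oracle: direct tally of what we put in
                expected[cond][v] = expected[cond].get(v, 0) + 1
                pairs.append(make_pair(design_2058, scheme, cond, v, rid=f"r{i}"))
                i += 1
        rng.shuffle(pairs)
        table = P.count_variants(pairs, design_2058, scheme)
        assert table.counts == expected
        assert table.reads_in == 30
        assert table.accounting_ok()

    def test_empty_stream(self, design_2058, scheme):
        table = P.count_variants([], design_2058, scheme)
        assert table.reads_in == 0
        assert table.totals == {c: 0 for c in table.counts}

    def test_permutation_invariance(self, design_2058, scheme):
        exp = P.SimulatedExperiment(
            design_2058, P.benchmark_truth(design_2058), 2000,
            error_rate=0.01, seed=9,
        )
        reads = list(P.sample_reads(exp, "positive", scheme))
        t1 = P.count_variants(reads, design_2058, scheme)
        random.Random(1).shuffle(reads)
        t2 = P.count_variants(reads, design_2058, scheme)
        assert t1.counts == t2.counts and t1.tallies == t2.tallies

    def test_error_free_simulation_loses_nothing(self, design_2058, scheme):
        exp = P.SimulatedExperiment(
            design_2058, P.benchmark_truth(design_2058), 5000, seed=4
        )
        def stream():
            for cond in ("positive", "negative", "unselected"):
                yield from P.sample_reads(exp, cond, scheme)
        table = P.count_variants(stream(), design_2058, scheme)
        assert table.totals == {c: 5000 for c in table.totals}
        assert sum(table.tallies.values()) == 0

    def test_accounting_identity_with_errors(self, design_2058, scheme):
        exp = P.SimulatedExperiment(
            design_2058, P.benchmark_truth(design_2058), 4000,
            error_rate=0.03, seed=13,
        )
        def stream():
            for cond in ("positive", "negative", "unselected"):
                yield from P.sample_reads(exp, cond, scheme)
        table = P.count_variants(stream(), design_2058, scheme)
        assert table.reads_in == 12000
        assert table.accounting_ok()
        assert table.tallies["no_barcode"] > 0  # errors do land in barcodes

    def test_swap_mates_recovers_swapped_input(self, design_2058, scheme):
        pair = make_pair(design_2058, scheme, "positive", "GGAUC")
        swapped = ReadPair(pair.id, pair.seq2, pair.qual2, pair.seq1, pair.qual1)
        assert P.count_variants([swapped], design_2058, scheme).totals["positive"] == 0
        table = P.count_variants([swapped], design_2058, scheme, swap_mates=True)
        assert table.counts["positive"] == {"GGAUC": 1}

    def test_oracle_equivalence_small_toy_library(self, scheme):
        """Counts on a k=2 fixture equal an independent quadratic tally."""
        d = toy_design(2)
        rng = random.Random(3)
        all_v = ["".join(p) for p in __import__("itertools").product("ACGU", repeat=2)]
        draws = [(rng.choice(("positive", "negative", "unselected")),
                  rng.choice(all_v)) for _ in range(500)]
        pairs = [make_pair(d, scheme, c, v, rid=f"x{i}")
                 for i, (c, v) in enumerate(draws)]
        table = P.count_variants(pairs, d, scheme)
        for cond in ("positive", "negative", "unselected"):
            for v in all_v:
                naive = sum(1 for c, vv in draws if c == cond and vv == v)
                assert table.counts[cond].get(v, 0) == naive


class TestFastqIO:
    def test_fastq_round_trip(self, design_2058, scheme, tmp_path):
        exp = P.SimulatedExperiment(
            design_2058, P.benchmark_truth(design_2058), 1500,
            error_rate=0.005, seed=21,
        )
        paths = P.write_fastq(exp, scheme, tmp_path)
        in_memory = P.count_variants(
            (r for cond in ("positive", "negative", "unselected")
             for r in P.sample_reads(exp, cond, scheme)),
            design_2058, scheme,
        )
        from_disk = P.count_fastq(paths.values(), design_2058, scheme)
        assert from_disk.counts == in_memory.counts
        assert (tmp_path / "truth.tsv").exists()
        assert (tmp_path / "experiment.json").exists()

    def test_gzip_fastq_supported(self, design_2058, scheme, tmp_path):
        exp = P.SimulatedExperiment(
            design_2058, P.benchmark_truth(design_2058), 300, seed=2
        )
        paths = P.write_fastq(exp, scheme, tmp_path, compress=True)
        p1, p2 = paths["positive"]
        assert str(p1).endswith(".gz")
        n = sum(1 for _ in iter_fastq_pairs(p1, p2))
        assert n == 300

    def test_desynchronized_pair_raises(self, design_2058, scheme, tmp_path):
        exp = P.SimulatedExperiment(
            design_2058, P.benchmark_truth(design_2058), 50, seed=2
        )
        paths = P.write_fastq(exp, scheme, tmp_path)
        p1, _ = paths["positive"]
        short = tmp_path / "short.fastq"
        lines = p1.read_text().splitlines(keepends=True)
        short.write_text("".join(lines[:-4]))
        with pytest.raises(ValueError):
            list(iter_fastq_pairs(p1, short))
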