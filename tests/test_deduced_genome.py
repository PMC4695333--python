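import pytest

from deducemeth.genome import (
    BuilderParams,
    FragmentGroup,
    PreConsensus,
    build_deduced_genome,
    cluster_fragments,
    concatenate_genome,
    merge_reverse_complements,
    mismatch_ratio,
    prefilter_reads,
    preliminary_grouping,
    refine_consensus,
)
from deducemeth.io_formats import RRBSRead, convert_c2t
from deducemeth.simulate import library_molecules, simulate_rrbs_reads
from .oracles import expected_consensus


def _read(seq, sample="s1", rid="r"):
    return RRBSRead(rid, sample, seq)


def _pre(seq, count=1):
    key = convert_c2t(seq)
    return PreConsensus(
        converted_key=key,
        member_count=count,
        c_fraction=tuple(1.0 if c == "C" else 0.0 for c in seq),
        sequence=seq,
    )


PARAMS = BuilderParams()


class TestPrefilter:
    def test_single_occurrence_discarded(self):
        out = prefilter_reads({"s1": [_read("ACGTACGT")]}, PARAMS)
        assert out == {}

    def test_same_sequence_in_two_samples_retained(self):
        out = prefilter_reads(
            {"s1": [_read("ACGTACGT")], "s2": [_read("ACGTACGT", "s2")]}, PARAMS
        )
        key = convert_c2t("ACGTACGT")
        assert key in out
        assert sum(c for _, c in out[key]) == 2

    def test_conversion_variants_share_key(self):
        # TCGGA and TTGGA only differ at a C -> same converted key TTGGA
        out = prefilter_reads({"s1": [_read("TCGGA"), _read("TTGGA")]}, PARAMS)
        assert list(out) == ["TTGGA"]
        assert len(out["TTGGA"]) == 2

    def test_duplicates_within_sample_collapse_but_keep_copy_count(self):
        out = prefilter_reads(
            {"s1": [_read("TCGGA")] * 5, "s2": [_read("TCGGA", "s2")]}, PARAMS
        )
        assert sorted(c for _, c in out["TTGGA"]) == [1, 5]

    def test_reads_with_n_excluded(self):
        out = prefilter_reads(
            {"s1": [_read("ANGTA"), _read("ANGTA")], "s2": [_read("ACGTA", "s2")]},
            PARAMS,
        )
        assert out == {}

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no reads"):
            prefilter_reads({"s1": []}, PARAMS)

    def test_raising_multiplicity_never_increases_fragments(self, fully_methylated_reads):
        counts = []
        for mult in (1, 2, 4):
            params = BuilderParams(min_multiplicity=mult)
            genome = build_deduced_genome(fully_methylated_reads, params)
            counts.append(len(genome.fragments))
        assert counts == sorted(counts, reverse=True)


class TestPreliminaryGrouping:
    def test_five_percent_rule_restores_c(self):
        filtered = {"TTGGATTGA": [("TCGGATTGA", 1), ("TTGGATTGA", 1)]}
        (pre,) = preliminary_grouping(filtered, PARAMS)
        assert pre.sequence == "TCGGATTGA"  # C fraction 0.5 >= 0.05

    def test_exact_threshold_boundary(self):
        members_at_4pct = [("TCGGA", 4), ("TTGGA", 96)]
        (pre,) = preliminary_grouping({"TTGGA": members_at_4pct}, PARAMS)
        assert pre.sequence == "TTGGA"  # 0.04 < 0.05 stays T
        members_at_5pct = [("TCGGA", 5), ("TTGGA", 95)]
        (pre,) = preliminary_grouping({"TTGGA": members_at_5pct}, PARAMS)
        assert pre.sequence == "TCGGA"  # 0.05 >= 0.05 restores C

    def test_single_member_is_its_own_consensus(self):
        (pre,) = preliminary_grouping({"TTGGA": [("TCGGA", 1)]}, PARAMS)
        assert pre.sequence == "TCGGA"
        assert pre.member_count == 1


class TestClustering:
    def test_mismatch_over_eight_percent_stays_separate(self):
        # 1/9 = 11.1% > 8%
        groups = cluster_fragments([_pre("TTGGATTGA"), _pre("TTGGATTTA")], PARAMS)
        assert len(groups) == 2

    def test_mismatch_under_eight_percent_merges(self):
        # 1/13 = 7.7% < 8%
        a = "TTGGATTGATTGA"
        b = "TTGGATTGATTGT"
        groups = cluster_fragments([_pre(a, 2), _pre(b, 1)], PARAMS)
        assert len(groups) == 1

    def test_exact_eight_percent_not_merged(self):
        # 2/25 = 8% exactly -> strictly-less rule keeps them apart
        a = "T" * 25
        b = "T" * 23 + "AA"
        groups = cluster_fragments([_pre(a), _pre(b)], PARAMS)
        assert len(groups) == 2

    def test_identical_keys_single_group(self):
        groups = cluster_fragments([_pre("TCGGATTGA", 2), _pre("TCGGATTGA", 1)], PARAMS)
        assert len(groups) == 1
        assert groups[0].representative == "TCGGATTGA"

    def test_mismatch_ratio_uses_shorter_length(self):
        assert mismatch_ratio("TTGGATTGA", "TTGG") == 0.0
        assert mismatch_ratio("ATGG", "TTGGATTGA") == 0.25


class TestRefinement:
    def test_fixed_point_when_all_members_close(self):
        # 1 mismatch over 21 bases = 4.8%, within both thresholds
        a = "TTGGATTGATTGATTGATTGA"
        b = a[:-1] + "T"
        groups = cluster_fragments([_pre(a, 2), _pre(b, 1)], PARAMS)
        refined = refine_consensus(groups, PARAMS)
        assert len(refined) == 1
        assert sorted(m.converted_key for m in refined[0].members) == sorted(
            m.converted_key for m in groups[0].members
        )

    def test_divergent_members_split(self):
        # force two 10%-divergent members into one group, then refine
        a = _pre("TTGGATTGAT", 2)
        b = _pre("TTGGTTTGTT", 1)
        group = FragmentGroup(members=[a, b], representative=a.sequence)
        refined = refine_consensus([group], PARAMS)
        assert len(refined) == 2
        assert all(len(g.members) == 1 for g in refined)

    def test_singleton_group_is_fixed_point(self):
        group = FragmentGroup(members=[_pre("TTGGA")], representative="TTGGA")
        refined = refine_consensus([group], PARAMS)
        assert len(refined) == 1
        assert refined[0].representative == "TTGGA"

    def test_exact_five_percent_member_kept(self):
        # 1/20 = 5% mismatch: only *more than* 5% splits
        a = "T" * 20
        b = "T" * 19 + "A"
        group = FragmentGroup(members=[_pre(a, 2), _pre(b, 1)], representative=a)
        refined = refine_consensus([group], PARAMS)
        assert len(refined) == 1
        assert len(refined[0].members) == 2


class TestStrandMerge:
    def test_spec_worked_example(self):
        # two strands of a duplex whose CpGs are methylated
        fwd = _pre("CGGTATATCG", 1)
        rev = _pre("CGGTGTATCG", 1)
        merged = merge_reverse_complements(
            [
                FragmentGroup([fwd], fwd.sequence),
                FragmentGroup([rev], rev.sequence),
            ],
            PARAMS,
        )
        assert len(merged) == 1
        assert merged[0].sequence == "CGGTACACCG"
        assert merged[0].strand_merged

    def test_pattern_gate_excludes_non_restriction_ends(self):
        a = _pre("AGGTATATCG", 1)  # does not start with [CT]GG
        b = _pre("CGGTGTATCG", 1)
        merged = merge_reverse_complements(
            [FragmentGroup([a], a.sequence), FragmentGroup([b], b.sequence)], PARAMS
        )
        assert len(merged) == 2
        assert not any(f.strand_merged for f in merged)

    def test_merge_without_c_evidence_keeps_sequence(self):
        # self-reverse-complementary sequence: the partner adds no C evidence
        a = _pre("CGGTATACCG", 1)
        b = _pre("CGGTATACCG", 2)
        merged = merge_reverse_complements(
            [FragmentGroup([a], a.sequence), FragmentGroup([b], b.sequence)], PARAMS
        )
        assert len(merged) == 1
        assert merged[0].sequence == "CGGTATACCG"


class TestConcatenation:
    def test_spacer_arithmetic(self):
        frags = merge_reverse_complements(
            [
                FragmentGroup([_pre("T" * 10, 5)], "T" * 10),
                FragmentGroup([_pre("A" * 20, 1)], "A" * 20),
            ],
            PARAMS,
        )
        genome = concatenate_genome(frags, PARAMS)
        spans = sorted(genome.coordinate_index.values())
        assert spans == [(0, 10), (60, 80)]
        assert len(genome.sequence) == 80
        assert genome.sequence[10:60] == "N" * 50

    def test_single_fragment_no_spacer(self):
        frags = merge_reverse_complements(
            [FragmentGroup([_pre("TGTGA", 1)], "TGTGA")], PARAMS
        )
        genome = concatenate_genome(frags, PARAMS)
        assert genome.sequence == "TGTGA"

    def test_zero_spacer_override(self):
        params = BuilderParams(spacer_length=0)
        frags = merge_reverse_complements(
            [
                FragmentGroup([_pre("TGTGA", 2)], "TGTGA"),
                FragmentGroup([_pre("AAAAA", 1)], "AAAAA"),
            ],
            params,
        )
        genome = concatenate_genome(frags, params)
        assert genome.sequence == "TGTGAAAAAA"

    def test_empty_fragment_list_errors(self):
        with pytest.raises(ValueError):
            concatenate_genome([], PARAMS)


class TestReconstruction:
    def test_error_free_simulation_recovers_every_molecule(
        self, sim_genome, four_sample_sheet, fully_methylated_reads
    ):
        """Fully covered, fully methylated fragments are reconstructed exactly
        (both-strand merging restores every genomic cytosine)."""
        genome = build_deduced_genome(fully_methylated_reads)
        molecules = library_molecules(sim_genome, (30, 50))
        expected = sorted(
            expected_consensus(
                mol, {i: True for i in range(len(mol) - 1) if mol[i : i + 2] == "CG"}
            )
            for _, mol in molecules
        )
        got = sorted(f.sequence for f in genome.fragments)
        assert got == expected
        assert all(f.strand_merged for f in genome.fragments)

    def test_mixed_methylation_recovers_molecules(self, sim_genome, four_sample_sheet):
        """With some CpGs fully unmethylated, opposite-strand coverage still
        restores the converted cytosines."""
        truth = {}
        for group in ("g1", "g2"):
            for j, p in enumerate(sim_genome.cpg_positions):
                truth[(group, p)] = 1.0 if j % 2 == 0 else 0.0
        reads, _ = simulate_rrbs_reads(
            sim_genome, truth, four_sample_sheet, depth=20, read_length=50,
            size_range=(30, 50), seed=21, paired_strands=True,
        )
        genome = build_deduced_genome(reads)
        molecules = library_molecules(sim_genome, (30, 50))
        expected = sorted(
            expected_consensus(
                mol,
                {
                    i: truth[("g1", frag.start + i)] == 1.0
                    for i in range(len(mol) - 1)
                    if mol[i : i + 2] == "CG"
                },
            )
            for frag, mol in molecules
        )
        assert sorted(f.sequence for f in genome.fragments) == expected

    def test_idempotence_on_own_output(self, fully_methylated_reads, four_sample_sheet):
        """Reads regenerated from the deduced fragments reproduce the same set."""
        from deducemeth.io_formats import RRBSRead, reverse_complement

        genome = build_deduced_genome(fully_methylated_reads)
        reads = {}
        for sid in four_sample_sheet.sample_ids:
            rs = []
            for k, f in enumerate(genome.fragments):
                rs.append(RRBSRead(f"f{k}", sid, f.sequence))
                rs.append(RRBSRead(f"r{k}", sid, reverse_complement(f.sequence)))
            reads[sid] = rs
        again = build_deduced_genome(reads)
        assert sorted(f.sequence for f in again.fragments) == sorted(
            f.sequence for f in genome.fragments
        )
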