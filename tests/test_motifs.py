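"""Cysteine-framework detection, window extraction, compensation, grouping."""

import pytest

from toxkit.motifs import (
    C_WINDOW,
    DEFAULT_EXPOSED_POSITIONS,
    N_WINDOW,
    ClassProfile,
    CompensationVerdict,
    KunitzAlignment,
    MotifError,
    ResidueClass,
    ToxinRecord,
    UnclassifiableResidueError,
    build_class_profiles,
    classify_residue,
    dendrotoxin_records,
    detect_compensation,
    exposure_filter,
    extract_windows,
    find_cysteine_framework,
    group_specificities,
    map_key_residues,
    reference_alignment,
    synthetic_kalicludine_alignment,
)
from toxkit.synth import gen_kunitz_msa


def _toy_alignment(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    records = tuple(
        ToxinRecord(id=i, sequence=r.replace("-", "")) for i, r in zip(ids, rows)
    )
    return KunitzAlignment(records=records, aligned_rows=tuple(rows))


# A minimal 6-cysteine scaffold: C at 1-based 3, 8, 14, 20, 26, 30.
_TOY = "AACAKLGCAKLGACAKLGACAKLGACKKLCAA"


def _toy_rows(n=3):
    return [_TOY] * n


class TestClassifyResidue:
    def test_partition_sizes_are_2_3_6_9(self):
        from collections import Counter
        counts = Counter(classify_residue(a) for a in "ACDEFGHIKLMNPQRSTVWY")
        assert counts[ResidueClass.negative] == 2
        assert counts[ResidueClass.positive] == 3
        assert counts[ResidueClass.polar_uncharged] == 6
        assert counts[ResidueClass.hydrophobic] == 9

    @pytest.mark.parametrize("aa,cls", [
        ("H", ResidueClass.positive),        # histidine counted as charged
        ("P", ResidueClass.hydrophobic),
        ("E", ResidueClass.negative),
        ("G", ResidueClass.hydrophobic),
        ("C", ResidueClass.polar_uncharged),
    ])
    def test_documented_assignments(self, aa, cls):
        assert classify_residue(aa) is cls

    def test_unknown_residue_never_silently_classified(self):
        with pytest.raises(UnclassifiableResidueError):
            classify_residue("X")


class TestFrameworkDetection:
    def test_six_aligned_cysteines_labeled_in_order(self):
        aln = _toy_alignment(_toy_rows())
        fw = find_cysteine_framework(aln)
        assert len(fw.framework_columns) == 6
        assert list(fw.framework_columns) == sorted(fw.framework_columns)
        # per-record ungapped 0-based positions
        assert fw.per_record_positions["s0"] == (2, 7, 13, 19, 25, 29)

    def test_record_missing_one_cysteine_is_flagged_not_fatal(self):
        rows = _toy_rows(10)
        rows[0] = _TOY[:7] + "S" + _TOY[8:]  # Cys II -> Ser in one record
        aln = _toy_alignment(rows)
        fw = find_cysteine_framework(aln, conservation_threshold=0.9)
        assert "s0" in fw.flagged_records
        assert fw.per_record_positions["s0"][1] is None
        assert fw.per_record_positions["s1"] == (2, 7, 13, 19, 25, 29)

    def test_subthreshold_cysteine_column_excluded(self):
        rows = _toy_rows(10)
        # plant a 7th Cys column in 60% of records only
        rows = [
            (r[:4] + "C" + r[5:]) if i < 6 else r for i, r in enumerate(rows)
        ]
        aln = _toy_alignment(rows)
        fw = find_cysteine_framework(aln, conservation_threshold=0.9)
        assert len(fw.framework_columns) == 6
        assert 4 not in fw.framework_columns

    def test_seventh_fully_conserved_cysteine_is_an_error(self):
        rows = [(r[:4] + "C" + r[5:]) for r in _toy_rows(3)]
        with pytest.raises(MotifError, match="non-canonical framework"):
            find_cysteine_framework(_toy_alignment(rows))

    def test_invariant_to_appended_non_cys_columns_and_record_order(self):
        aln1 = _toy_alignment(_toy_rows())
        fw1 = find_cysteine_framework(aln1)
        aln2 = _toy_alignment([r + "AGL" for r in _toy_rows()])
        fw2 = find_cysteine_framework(aln2)
        assert fw1.framework_columns == fw2.framework_columns
        aln3 = _toy_alignment(_toy_rows(), ids=["s2", "s0", "s1"])
        fw3 = find_cysteine_framework(aln3)
        assert fw3.per_record_positions["s2"] == fw1.per_record_positions["s0"]


class TestWindowExtraction:
    def test_dtx_k_window_residues_match_published_numbering(self):
        """DTX-K: Lys25 at Xa-2, Lys28 at Xa+1, Pro30 at Xa+3; Arg74 at
        Xb+1 and Arg75 at Xb+2."""
        aln = reference_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        w = mw.window("DTX-K")
        assert (w["Xa-2"].residue, w["Xa-2"].published_number) == ("K", 25)
        assert (w["Xa+1"].residue, w["Xa+1"].published_number) == ("K", 28)
        assert (w["Xa+3"].residue, w["Xa+3"].published_number) == ("P", 30)
        assert (w["Xb+1"].residue, w["Xb+1"].published_number) == ("R", 74)
        assert (w["Xb+2"].residue, w["Xb+2"].published_number) == ("R", 75)

    def test_alpha_dtx_window_residues(self):
        """alpha-DTX: Lys5 at Xa-2 and Ile8 at Xa+1."""
        aln = reference_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        w = mw.window("alpha-DTX")
        assert (w["Xa-2"].residue, w["Xa-2"].published_number) == ("K", 5)
        assert (w["Xa+1"].residue, w["Xa+1"].published_number) == ("I", 8)
        assert w["Xa+3"].residue == "H"  # the dendrotoxin His at Xa+3

    def test_cys_slots_hold_cysteine(self):
        aln = reference_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        for rid in ("DTX-K", "alpha-DTX"):
            w = mw.window(rid)
            assert w["CysI"].residue == "C"
            assert w["CysV"].residue == "C"
            assert w["CysVI"].residue == "C"
            assert not mw.record_flags[rid]

    def test_truncated_n_terminus_flagged(self):
        # Cys I at position 2: no room for Xa-2.
        rows = ["ACAKLGACAKLGACAKLGACAKLGACKKLCAA"] * 2
        aln = _toy_alignment(rows)
        mw = extract_windows(find_cysteine_framework(aln), aln)
        assert any("truncated" in f for f in mw.record_flags["s0"])
        assert mw.window("s0")["Xa-2"].residue is None

    def test_insertion_between_cys_v_and_vi_is_non_canonical(self):
        # One record with 4 residues between Cys V and Cys VI.
        good = _TOY[:28] + "-" + _TOY[28:]  # gap keeps CysVI aligned
        bad = _TOY[:28] + "K" + _TOY[28:]  # now CysVI - CysV = 5
        rows = [good, bad]
        aln = _toy_alignment(rows)
        fw = find_cysteine_framework(aln, conservation_threshold=1.0)
        mw = extract_windows(fw, aln)
        assert any("non-canonical C-window" in f for f in mw.record_flags["s1"])

    def test_planted_windows_recovered_over_seeded_alignments(self):
        """Window extraction returns exactly the planted residues across many
        generated alignments."""
        for seed in range(20):
            pm = gen_kunitz_msa(seed=seed)
            fw = find_cysteine_framework(pm.alignment)
            mw = extract_windows(fw, pm.alignment)
            c1, c5 = pm.cys_positions[0], pm.cys_positions[4]
            for rec in pm.alignment.records:
                w = mw.window(rec.id)
                assert w["CysI"].published_number == c1
                assert w["Xa-2"].residue == rec.sequence[c1 - 3]
                assert w["Xb+2"].residue == rec.sequence[c5 + 1]


class TestExposureFilter:
    def test_no_asa_table_defaults_to_fully_exposed_set(self):
        aln = reference_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        out = exposure_filter(mw, None)
        assert out.exposed_positions == DEFAULT_EXPOSED_POSITIONS
        assert out.provenance == "fold-default"

    def test_threshold_is_strict_and_per_position(self):
        aln = reference_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        asa = {}
        for rid in ("DTX-K", "alpha-DTX"):
            for wp in mw.per_record[rid]:
                if wp.label == "Xa-2":
                    asa[(rid, wp.published_number)] = 60.0
                elif wp.label == "Xa-1":
                    asa[(rid, wp.published_number)] = 30.0
                elif wp.label == "Xa+1":
                    asa[(rid, wp.published_number)] = 50.0  # exactly 50: buried
        out = exposure_filter(mw, asa)
        assert out.provenance == "asa-table"
        assert "Xa-2" in out.exposed_positions
        assert "Xa-1" not in out.exposed_positions
        assert "Xa+1" not in out.exposed_positions  # strict inequality
        assert "Xb+1" in out.unknown_positions


class TestCompensation:
    def test_dendrotoxin_pair_is_compensated_via_xa1_xa3_swap(self):
        """alpha-DTX vs DTX-K: hydrophobic/positive classes swap between
        Xa+1 and Xa+3 while the C-window is identical."""
        aln = reference_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        profiles = {p.toxin_id: p for p in build_class_profiles(mw)}
        rep = detect_compensation(profiles["alpha-DTX"], profiles["DTX-K"])
        assert rep.verdict is CompensationVerdict.compensated
        assert ("Xa+1", "Xa+3") in rep.compensated_pairs
        assert rep.window_verdicts["C"] is CompensationVerdict.identical

    def test_identical_profiles(self):
        p = ClassProfile(
            toxin_id="a",
            n_window=(("Xa-2", ResidueClass.positive),),
            c_window=(("Xb+1", ResidueClass.positive),),
        )
        q = ClassProfile(toxin_id="b", n_window=p.n_window, c_window=p.c_window)
        assert detect_compensation(p, q).verdict is CompensationVerdict.identical

    def test_single_class_change_is_non_compensated(self):
        base = dict(n_window=(
            ("Xa-2", ResidueClass.positive),
            ("Xa+1", ResidueClass.hydrophobic),
            ("Xa+3", ResidueClass.positive),
        ), c_window=(("Xb+1", ResidueClass.positive),))
        p = ClassProfile(toxin_id="a", **base)
        changed = dict(base)
        changed["n_window"] = (
            ("Xa-2", ResidueClass.negative),) + base["n_window"][1:]
        q = ClassProfile(toxin_id="b", **changed)
        assert detect_compensation(p, q).verdict is CompensationVerdict.non_compensated

    def test_symmetric_in_its_arguments(self):
        aln = reference_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        pa, pb = build_class_profiles(mw)
        ab = detect_compensation(pa, pb)
        ba = detect_compensation(pb, pa)
        assert ab.verdict is ba.verdict
        assert set(ab.compensated_pairs) == set(ba.compensated_pairs)

    def test_mismatched_position_sets_rejected(self):
        p = ClassProfile(toxin_id="a",
                         n_window=(("Xa-2", ResidueClass.positive),),
                         c_window=())
        q = ClassProfile(toxin_id="b",
                         n_window=(("Xa+1", ResidueClass.positive),),
                         c_window=())
        with pytest.raises(MotifError, match="different position sets"):
            detect_compensation(p, q)

    def test_three_cycle_of_classes_is_not_a_swap(self):
        # Changes P->H, H->N, N->P preserve the multiset but cannot be
        # decomposed into pairwise swaps.
        P, H, N = (ResidueClass.positive, ResidueClass.hydrophobic,
                   ResidueClass.negative)
        p = ClassProfile(toxin_id="a", c_window=(),
                         n_window=(("Xa-2", P), ("Xa+1", H), ("Xa+3", N)))
        q = ClassProfile(toxin_id="b", c_window=(),
                         n_window=(("Xa-2", H), ("Xa+1", N), ("Xa+3", P)))
        rep = detect_compensation(p, q)
        assert rep.verdict is CompensationVerdict.non_compensated
        assert rep.cross_window_multiset_preserving  # multiset equal overall


def _profile(tid, n_classes):
    labels = ("Xa-2", "Xa+1", "Xa+3")
    return ClassProfile(
        toxin_id=tid,
        n_window=tuple(zip(labels, n_classes)),
        c_window=(("Xb+1", ResidueClass.positive),
                  ("Xb+2", ResidueClass.positive)),
    )


class TestGrouping:
    def test_synthetic_kalicludines_group_as_reported(self):
        """AsKC1 and AsKC2 share predicted specificity; AsKC3 differs."""
        aln = synthetic_kalicludine_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        profiles = build_class_profiles(mw)
        for mode in ("strict", "compensated"):
            grouping = group_specificities(profiles, mode=mode)
            groups = {frozenset(g) for g in grouping.groups}
            assert groups == {
                frozenset({"AsKC1-syn", "AsKC2-syn"}),
                frozenset({"AsKC3-syn"}),
            }

    def test_single_profile_is_a_singleton_group(self):
        p = _profile("only", (ResidueClass.positive, ResidueClass.hydrophobic,
                              ResidueClass.positive))
        grouping = group_specificities([p])
        assert grouping.groups == (("only",),)

    def test_nontransitive_chain_merged_by_closure_with_warning(self):
        """A~B and B~C compensated but A~C a 3-cycle: closure merges all
        three and flags the non-transitivity."""
        P, H, N = (ResidueClass.positive, ResidueClass.hydrophobic,
                   ResidueClass.negative)
        a = _profile("A", (P, H, N))
        b = _profile("B", (H, P, N))  # swap Xa-2/Xa+1 vs A
        c = _profile("C", (H, N, P))  # swap Xa+1/Xa+3 vs B; 3-cycle vs A
        assert detect_compensation(a, b).verdict is CompensationVerdict.compensated
        assert detect_compensation(b, c).verdict is CompensationVerdict.compensated
        assert detect_compensation(a, c).verdict is CompensationVerdict.non_compensated
        grouping = group_specificities([a, b, c], mode="compensated")
        assert grouping.groups == (("A", "B", "C"),)
        assert any("non-transitive" in w for w in grouping.warnings)

    def test_strict_groups_refine_compensated_groups(self):
        for seed in range(10):
            pm = gen_kunitz_msa(seed=seed, n_compensated_pairs=2,
                                n_noncompensated=2, n_seqs=8)
            mw = extract_windows(
                find_cysteine_framework(pm.alignment), pm.alignment
            )
            profiles = build_class_profiles(mw)
            strict = group_specificities(profiles, "strict").groups
            comp = group_specificities(profiles, "compensated").groups
            comp_sets = [set(g) for g in comp]
            for g in strict:
                assert any(set(g) <= cg for cg in comp_sets)


class TestKeyResidueMapping:
    def test_dendrotoxin_key_residues_located(self):
        """DTX-K K28 maps to Xa+1 in the N-window, R75 to Xb+2 in the
        C-window, and the K46-K50 cluster falls outside both."""
        aln = reference_alignment()
        mw = extract_windows(find_cysteine_framework(aln), aln)
        report = map_key_residues(list(dendrotoxin_records()), mw)
        where = {(t, n): loc for t, n, _, loc in report.per_residue}
        assert where[("DTX-K", 28)] == "N-window at Xa+1"
        assert where[("DTX-K", 75)] == "C-window at Xb+2"
        assert where[("DTX-K", 46)] == "outside"
        assert where[("alpha-DTX", 5)] == "N-window at Xa-2"
        assert where[("alpha-DTX", 9)] == "N-window at Xa+2"  # dyad Leu9
        assert where[("alpha-DTX", 3)] == "outside"
        assert not report.errors

    def test_out_of_range_annotation_reported_per_residue(self):
        rec = ToxinRecord(id="t", sequence="AACAKLGCAKLGACAKLGACAKLGACKKLCAA",
                          key_residues=((99, "phantom"),))
        aln = KunitzAlignment(records=(rec,), aligned_rows=(rec.sequence,))
        mw = extract_windows(find_cysteine_framework(
            aln, conservation_threshold=1.0), aln)
        report = map_key_residues([rec], mw)
        assert any("outside sequence range" in e for e in report.errors)
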