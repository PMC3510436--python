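import random

import pytest

from trnapanel.conservation import (
    column_profile,
    expected_tally,
    largest_identical_group,
    pct_conserved_columns,
    project_variant,
    reference_is_major,
    sample_sequences,
    tally_stem_loop_variation,
    variant_profile,
)
from trnapanel.io_formats import GeneAnnotation, SequenceRecord, parse_variant
from trnapanel.msa import Alignment
from trnapanel.structure import Domain, PairClass, StructureAnnotation
from trnapanel.synth import SynthParams, evolve_panel, make_structured_trna


def _aln(rows):
    return Alignment([f"s{i}" for i in range(len(rows))], rows)


class TestColumnProfile:
    def test_monomorphic_column(self):
        aln = _aln(["ACG"] * 10)
        prof = column_profile(aln, 2, "s0")
        assert prof.n_changes == 0
        assert prof.reference_residue == "C"

    def test_single_change(self):
        aln = _aln(["ACG"] * 9 + ["ATG"])
        assert column_profile(aln, 2, "s0").n_changes == 1

    def test_gap_policy(self):
        aln = _aln(["ACG", "ACG", "A-G"])
        assert column_profile(aln, 2, "s0", gap_is_change=True).n_changes == 1
        assert column_profile(aln, 2, "s0", gap_is_change=False).n_changes == 0

    def test_reference_gap_flagged(self):
        aln = _aln(["A-G", "ACG", "ACG"])
        prof = column_profile(aln, 2, "s0")
        assert prof.reference_gapped

    def test_missing_reference_row(self):
        with pytest.raises(KeyError):
            column_profile(_aln(["ACG"]), 1, "nope")

    def test_invariant_under_row_permutation(self, rng):
        rows = ["ACGT", "ACTT", "AGGT", "AC-T", "ACGT"]
        base = column_profile(_aln(rows), 3, "s0").n_changes
        ids = [f"s{i}" for i in range(len(rows))]
        for _ in range(10):
            order = list(range(1, len(rows)))
            rng.shuffle(order)
            perm = [rows[0]] + [rows[i] for i in order]
            assert column_profile(_aln(perm), 3, "s0").n_changes == base


class TestIntraSpeciesMetrics:
    def test_pct_conserved_all_identical(self):
        assert pct_conserved_columns(_aln(["ACGTACGTAC"] * 4)) == 100.0

    def test_pct_conserved_one_variable_of_ten(self):
        rows = ["ACGTACGTAC", "ACGTACGTAC", "ACGTACTTAC"]
        assert pct_conserved_columns(_aln(rows)) == 90.0

    def test_pct_conserved_all_variable(self):
        assert pct_conserved_columns(_aln(["AC", "CA"])) == 0.0

    def test_pct_conserved_needs_two_rows(self):
        with pytest.raises(ValueError):
            pct_conserved_columns(_aln(["ACGT"]))

    def test_gap_counts_as_fifth_state(self):
        assert pct_conserved_columns(_aln(["AC-T", "ACGT"])) == 75.0

    @pytest.mark.parametrize(
        "seqs,expect",
        [
            (["AAAA"] * 5, 100.0),
            (["AAAA", "AAAA", "AAAA", "CCCC"], 75.0),
            (["AAAA", "CCCC", "GGGG", "TTTT"], 25.0),
        ],
    )
    def test_largest_identical_group(self, seqs, expect):
        recs = [SequenceRecord(id=f"i{k}", sequence=s) for k, s in enumerate(seqs)]
        assert largest_identical_group(recs) == expect

    def test_largest_group_lower_bound(self, rng):
        recs = [
            SequenceRecord(id=f"i{k}",
                           sequence="".join(rng.choice("ACGT") for _ in range(8)))
            for k in range(7)
        ]
        assert largest_identical_group(recs) >= 100.0 / len(recs)

    def test_conserved_iff_single_group(self):
        """pct_conserved_columns is 100 exactly when every sequence is
        identical, i.e. the largest identical group is 100%."""
        for seqs in (["ACGT"] * 3, ["ACGT", "ACGT", "ACTT"]):
            recs = [SequenceRecord(id=f"i{k}", sequence=s)
                    for k, s in enumerate(seqs)]
            aln = _aln(seqs)
            assert (pct_conserved_columns(aln) == 100.0) == (
                largest_identical_group(recs) == 100.0
            )


class TestReferenceIsMajor:
    def _split_alignment(self, n_ref, n_alt):
        """One polymorphic column: n_ref rows carry the reference G,
        n_alt rows carry A (the documented 68/32-style split)."""
        rows = ["GAC"] * n_ref + ["AAC"] * n_alt
        return _aln(rows)

    def test_vacuous_when_monomorphic(self):
        assert reference_is_major(_aln(["ACG"] * 3), "s0")

    def test_major_at_68_percent(self):
        assert reference_is_major(self._split_alignment(68, 32), "s0")

    def test_minor_at_32_percent(self):
        aln = self._split_alignment(32, 68)
        assert reference_is_major(aln, "s0") is False

    def test_tied_mode_counts_as_major(self):
        assert reference_is_major(self._split_alignment(50, 50), "s0")


class TestVariantProfile:
    def _setup(self, seed=3):
        params = SynthParams(seed=seed)
        rng = random.Random(seed)
        root, ann = make_structured_trna(params, gene_name="synth", rng=rng)
        panel, truth = evolve_panel(root, ann, params, rng=rng)
        gene_ann = GeneAnnotation("Homo sapiens", "synth", 1001,
                                  1000 + ann.length, "+")
        return root, ann, panel, truth, gene_ann

    def test_conserved_loop_position(self):
        root, ann, panel, truth, gene_ann = self._setup()
        loop_pos = next(
            p for p in ann.loop_positions()
            if all(p not in truth[sp] for sp in truth)
        )
        var = parse_variant(
            f"m.{1000 + loop_pos}{root.sequence[loop_pos - 1]}>"
            f"{'A' if root.sequence[loop_pos - 1] != 'A' else 'G'}"
        )
        trivial = Alignment([r.id for r in panel], [r.sequence for r in panel])
        prof, domain, is_stem, pairs = variant_profile(
            panel, gene_ann, ann, var, alignment=trivial
        )
        assert prof.n_changes == 0
        assert not is_stem
        assert pairs is None

    def test_change_count_matches_truth_log(self):
        root, ann, panel, truth, gene_ann = self._setup()
        trivial = Alignment([r.id for r in panel], [r.sequence for r in panel])
        for pos in ann.positions:
            expected = sum(1 for sp in truth if pos in truth[sp])
            ref = root.sequence[pos - 1]
            var = parse_variant(
                f"m.{1000 + pos}{ref}>{'A' if ref != 'A' else 'G'}"
            )
            prof, domain, is_stem, pairs = variant_profile(
                panel, gene_ann, ann, var, alignment=trivial
            )
            assert prof.n_changes == expected
            assert is_stem == (pos in ann.stem_positions())
            if is_stem:
                assert set(pairs) == {r.id for r in panel}

    def test_ref_mismatch_rejected(self):
        root, ann, panel, truth, gene_ann = self._setup()
        pos = 1
        actual = root.sequence[0]
        wrong = "A" if actual != "A" else "C"
        other = "G" if wrong != "G" else "T"
        var = parse_variant(f"m.{1001}{wrong}>{other}")
        with pytest.raises(ValueError, match=f"has '{actual}'"):
            variant_profile(panel, gene_ann, ann, var)

    def test_variant_outside_gene_rejected(self):
        root, ann, panel, truth, gene_ann = self._setup()
        var = parse_variant("m.500A>G")
        with pytest.raises(ValueError, match="outside gene"):
            variant_profile(panel, gene_ann, ann, var)

    def test_minus_strand_projection(self):
        """An rCRS heavy-strand variant on a light-strand gene maps to the
        complemented base at the mirrored offset."""
        ann = GeneAnnotation("Homo sapiens", "mirror", 101, 104, "-")
        # genome heavy strand 101..104 = ATGC -> sense gene = GCAT
        var = parse_variant("m.102T>C")
        offset, ref, alt = project_variant(var, ann)
        assert (offset, ref, alt) == (3, "A", "G")


class TestTally:
    def _gene(self, rows, domains):
        aln = _aln(rows)
        ann_domains = {i + 1: d for i, d in enumerate(domains)}
        partners = {}
        # pair stem positions left-to-right with right-to-left of same domain
        for dom in set(domains):
            if dom not in (Domain.ACCEPTOR_STEM, Domain.D_STEM,
                           Domain.ANTICODON_STEM, Domain.T_STEM):
                continue
            ps = [p for p, d in ann_domains.items() if d == dom]
            half = len(ps) // 2
            for a, b in zip(ps[:half], reversed(ps[half:])):
                partners[a] = b
                partners[b] = a
        partners = {p: partners.get(p) for p in ann_domains}
        return aln, StructureAnnotation("g", ann_domains, partners)

    def test_no_polymorphism(self):
        aln, ann = self._gene(["ACGT"] * 3, [Domain.T_LOOP] * 4)
        tally = tally_stem_loop_variation({"g": aln}, {"g": ann})
        assert (tally.stem_variants, tally.loop_variants) == (0, 0)
        assert tally.n_loop_positions == 4

    def test_planted_counts_recovered(self):
        # columns: 1-2 stem (paired), 3-6 loop; variants at 2 (stem), 4, 5
        rows = ["AT" + "CCGG",
                "AT" + "CTGG",
                "AA" + "CTCG"]
        doms = [Domain.ACCEPTOR_STEM, Domain.ACCEPTOR_STEM,
                Domain.T_LOOP, Domain.T_LOOP, Domain.T_LOOP, Domain.T_LOOP]
        aln, ann = self._gene(rows, doms)
        tally = tally_stem_loop_variation({"g": aln}, {"g": ann})
        assert (tally.stem_variants, tally.loop_variants) == (1, 2)
        assert tally.total_variants == 3

    def test_all_loop_single_variant(self):
        aln, ann = self._gene(["AAAA", "AAAT"], [Domain.D_LOOP] * 4)
        tally = tally_stem_loop_variation({"g": aln}, {"g": ann})
        assert (tally.stem_variants, tally.loop_variants) == (0, 1)

    def test_length_mismatch_rejected(self):
        aln, ann = self._gene(["ACGT"] * 2, [Domain.D_LOOP] * 4)
        short = StructureAnnotation("g", {1: Domain.D_LOOP}, {1: None})
        with pytest.raises(ValueError, match="does not match"):
            tally_stem_loop_variation({"g": aln}, {"g": short})

    def test_accumulates_over_genes(self):
        a1, s1 = self._gene(["AAAA", "AAAT"], [Domain.D_LOOP] * 4)
        a2, s2 = self._gene(["GT", "AC"], [Domain.T_STEM, Domain.T_STEM])
        tally = tally_stem_loop_variation({"g1": a1, "g2": a2},
                                          {"g1": s1, "g2": s2})
        assert (tally.stem_variants, tally.loop_variants) == (2, 1)
        assert (tally.n_stem_positions, tally.n_loop_positions) == (2, 4)


class TestExpectedTally:
    def test_proportional_split(self):
        assert expected_tally(100, 60, 40) == (60.0, 40.0)

    def test_zero_total(self):
        assert expected_tally(0, 60, 40) == (0.0, 0.0)

    def test_zero_positions_rejected(self):
        with pytest.raises(ValueError):
            expected_tally(10, 0, 0)

    def test_sum_conserved(self, rng):
        for _ in range(50):
            total = rng.randint(0, 500)
            ns, nl = rng.randint(1, 300), rng.randint(1, 300)
            e_stem, e_loop = expected_tally(total, ns, nl)
            assert e_stem + e_loop == pytest.approx(total)
            assert 0 <= e_stem <= total

    def test_published_position_split(self):
        """With the published observed/expected stem counts (78 observed,
        139 expected of 207), the implied stem share of positions is about
        two thirds, and the proportional expectation reproduces 139 when
        fed that share."""
        e_stem, e_loop = expected_tally(207, 139, 68)
        assert round(e_stem) == 139
        assert round(e_loop) == 68


class TestSampleSequences:
    def _recs(self, n):
        return [SequenceRecord(id=f"i{k}", sequence="ACGT") for k in range(n)]

    def test_under_cap_all_retained(self):
        recs = self._recs(10)
        assert sample_sequences(recs, cap=34, seed=1) == recs

    def test_cap_yields_reference_plus_cap(self):
        out = sample_sequences(self._recs(100), cap=34, seed=1)
        assert len(out) == 35
        assert out[0].id == "i0"

    def test_deterministic(self):
        recs = self._recs(80)
        a = sample_sequences(recs, cap=10, seed=42)
        b = sample_sequences(recs, cap=10, seed=42)
        assert a == b
        c = sample_sequences(recs, cap=10, seed=43)
        assert [r.id for r in a] != [r.id for r in c]
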