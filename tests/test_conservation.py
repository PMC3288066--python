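import numpy as np
import pytest

from paccmit.conservation import (
    ColumnMap,
    ConservationConfig,
    column_map,
    conserved_window_mask,
    conserved_window_total,
    is_conserved,
    selected_species,
    species_has_site,
)
from paccmit.seedmatch import total_windows
from paccmit.seqio import AlignedUTR, UTRRecord


class TestColumnMap:
    def test_ref_with_gap(self):
        aln = AlignedUTR("g", "human", {"human": "AC-GT", "chimp": "ACCGT"})
        assert column_map(aln).ref_pos_to_col.tolist() == [0, 1, 3, 4]

    def test_gapless_identity(self):
        aln = AlignedUTR("g", "human", {"human": "ACGT", "chimp": "AGGT"})
        assert column_map(aln).ref_pos_to_col.tolist() == [0, 1, 2, 3]

    def test_nonref_rows_do_not_affect_map(self):
        a = AlignedUTR("g", "human", {"human": "AC-GT", "chimp": "-----"})
        b = AlignedUTR("g", "human", {"human": "AC-GT", "chimp": "CCCCC"})
        assert column_map(a).ref_pos_to_col.tolist() == column_map(b).ref_pos_to_col.tolist()


class TestSpeciesHasSite:
    def test_identical_row_carries_site(self, toy_alignment):
        utr, aln = toy_alignment
        cmap = column_map(aln)
        assert species_has_site(aln, cmap, "chimp", 0, "CTACCTC") is True

    def test_substitution_breaks_site(self, toy_alignment):
        utr, aln = toy_alignment
        cmap = column_map(aln)
        assert species_has_site(aln, cmap, "mouse", 0, "CTACCTC") is False

    def test_ref_gap_column_skipped_species_matches_ref_bearing_columns(self):
        # Insertion in chimp: ref gap at column 3; the site occupies ref
        # positions 0..6 whose columns are 0,1,2,4,5,6,7.
        aln = AlignedUTR(
            "g", "human",
            {
                "human": "CTA-CCTC",
                "chimp": "CTAGCCTC",
                "mouse": "CTA-CCTG",
            },
        )
        cmap = column_map(aln)
        assert species_has_site(aln, cmap, "chimp", 0, "CTACCTC") is True
        assert species_has_site(aln, cmap, "mouse", 0, "CTACCTC") is False

    def test_gap_in_species_window_breaks_site(self):
        aln = AlignedUTR("g", "human", {"human": "CTACCTC", "chimp": "CTA-CTC"})
        cmap = column_map(aln)
        assert species_has_site(aln, cmap, "chimp", 0, "CTACCTC") is False

    def test_missing_species_is_all_gap(self, toy_alignment):
        utr, aln = toy_alignment
        cmap = column_map(aln)
        assert species_has_site(aln, cmap, "dog", 0, "CTACCTC") is False

    def test_ref_must_carry_word(self, toy_alignment):
        utr, aln = toy_alignment
        cmap = column_map(aln)
        with pytest.raises(ValueError, match="reference"):
            species_has_site(aln, cmap, "chimp", 1, "CTACCTC")


class TestIsConserved:
    def test_any_1_always_true(self, toy_alignment):
        utr, aln = toy_alignment
        cmap = column_map(aln)
        cfg = ConservationConfig(mode="any", S=1)
        assert is_conserved(aln, cmap, 0, "CTACCTC", cfg) is True

    def test_any_count_thresholds(self, toy_alignment):
        utr, aln = toy_alignment
        cmap = column_map(aln)
        # human + chimp carry the site at 0; mouse is mutated inside it
        assert is_conserved(aln, cmap, 0, "CTACCTC",
                            ConservationConfig(mode="any", S=2)) is True
        assert is_conserved(aln, cmap, 0, "CTACCTC",
                            ConservationConfig(mode="any", S=3)) is False

    def test_selected_with_all_gap_species_false(self, toy_alignment, selected4):
        utr, aln = toy_alignment
        cmap = column_map(aln)
        # rhesus absent entirely -> treated as all-gap -> false
        assert is_conserved(aln, cmap, 0, "CTACCTC", selected4) is False

    def test_selected_ladder_prefixes(self):
        assert selected_species(2) == ("human", "chimp")
        assert selected_species(4) == ("human", "chimp", "rhesus", "mouse")
        assert selected_species(7)[-1] == "chicken"
        with pytest.raises(ValueError):
            selected_species(1)


class TestConservedWindowTotal:
    def test_fully_conserved_equals_total_windows(self):
        seq = "ACGTACGTACGT"
        aln = AlignedUTR("g", "human", {"human": seq, "chimp": seq, "mouse": seq})
        cmap = column_map(aln)
        cfg = ConservationConfig(mode="any", S=3)
        utr = UTRRecord("g", seq)
        assert conserved_window_total(seq, aln, cmap, 7, cfg) == total_windows(utr, 7)

    def test_single_mutated_column_removes_covering_windows(self):
        seq = "ACGTACGTACGT"  # 12 nt, 6 windows of 7
        mutated = seq[:5] + "G" + seq[6:]  # position 5 (C) differs in all non-ref
        aln = AlignedUTR("g", "human", {"human": seq, "chimp": mutated, "mouse": mutated})
        cmap = column_map(aln)
        cfg = ConservationConfig(mode="any", S=2)
        # windows covering position 5: starts 0..5 -> all 6 windows
        assert conserved_window_total(seq, aln, cmap, 7, cfg) == 0
        mutated_tail = seq[:11] + "G"
        aln2 = AlignedUTR("g", "human",
                          {"human": seq, "chimp": mutated_tail, "mouse": mutated_tail})
        # windows covering position 11: starts 5 only
        assert conserved_window_total(seq, aln2, column_map(aln2), 7, cfg) == 5

    def test_selected_with_missing_species_zero(self, selected4):
        seq = "ACGTACGTACGT"
        aln = AlignedUTR("g", "human", {"human": seq, "chimp": seq})
        cmap = column_map(aln)
        assert conserved_window_total(seq, aln, cmap, 7, selected4) == 0


def _random_alignment(rng, n=60, n_species=6, mut=0.15, gap=0.05):
    bases = np.array(list("ACGT"))
    ref = "".join(rng.choice(bases, size=n))
    ladder = ["human", "chimp", "rhesus", "mouse", "dog", "cow"]
    rows = {"human": ref}
    for sp in ladder[1:n_species]:
        row = list(ref)
        for i in range(n):
            r = rng.random()
            if r < gap:
                row[i] = "-"
            elif r < gap + mut:
                row[i] = str(rng.choice(bases))
        rows[sp] = "".join(row)
    return UTRRecord("g", ref), AlignedUTR("g", "human", rows)


class TestPropertiesOnRandomAlignments:
    def test_any_s_nesting_and_brute_force_oracle(self, rng):
        utr, aln = _random_alignment(rng)
        cmap = column_map(aln)
        prev = None
        for S in range(1, 7):
            cfg = ConservationConfig(mode="any", S=S)
            mask = conserved_window_mask(utr.sequence, aln, cmap, 7, cfg)
            brute = np.array([
                is_conserved(aln, cmap, s, utr.sequence[s : s + 7], cfg)
                for s in range(utr.length - 6)
            ])
            assert np.array_equal(mask, brute)
            if prev is not None:
                assert np.all(mask <= prev)  # Any-(S+1) subset of Any-S
            prev = mask

    def test_selected_ladder_nesting(self, rng):
        utr, aln = _random_alignment(rng)
        cmap = column_map(aln)
        prev = None
        for S in range(2, 7):
            cfg = ConservationConfig(mode="selected", species_list=selected_species(S)[:S])
            mask = conserved_window_mask(utr.sequence, aln, cmap, 7, cfg)
            if prev is not None:
                assert np.all(mask <= prev)
            prev = mask

    def test_gapped_reference_brute_force_agreement(self, rng):
        # Insert ref gap columns (insertions in other species)
        utr, aln = _random_alignment(rng, n=40)
        cols = list(range(40))
        rows = {sp: list(row) for sp, row in aln.rows.items()}
        for pos in [7, 19, 33]:
            for sp in rows:
                rows[sp].insert(pos, "-" if sp == "human" else "A")
        aln2 = AlignedUTR("g", "human", {sp: "".join(r) for sp, r in rows.items()})
        cmap = column_map(aln2)
        assert aln2.ungapped_ref() == utr.sequence
        cfg = ConservationConfig(mode="any", S=3)
        mask = conserved_window_mask(utr.sequence, aln2, cmap, 7, cfg)
        brute = np.array([
            is_conserved(aln2, cmap, s, utr.sequence[s : s + 7], cfg)
            for s in range(utr.length - 6)
        ])
        assert np.array_equal(mask, brute)
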