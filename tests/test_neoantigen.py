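import numpy as np
import pytest

from repairimmune.cohort_io import AffinityTable
from repairimmune.neoantigen import (
    AMINO_ACIDS,
    PeptidePair,
    ToyPredictor,
    call_neoantigens,
    mutant_windows,
    neoantigen_burden,
)

PROTEIN20 = "ACDEFGHIKLMNPQRSTVWY"  # length 20, all residues distinct


class TestMutantWindows:
    def test_interior_position_full_window_set(self):
        pairs = mutant_windows(PROTEIN20, 10, "L", "A")
        assert len(pairs) == 9
        assert [p.window_start for p in pairs] == list(range(2, 11))

    def test_first_position_single_window(self):
        pairs = mutant_windows(PROTEIN20, 1, "A", "G")
        assert len(pairs) == 1 and pairs[0].window_start == 1

    def test_protein_equal_to_window(self):
        protein = PROTEIN20[:9]
        pairs = mutant_windows(protein, 5, "F", "W")
        assert len(pairs) == 1
        assert pairs[0].wt_peptide == protein

    def test_ref_mismatch_names_gene_and_position(self):
        with pytest.raises(ValueError, match="MYGENE.*position 10"):
            mutant_windows(PROTEIN20, 10, "W", "A", gene="MYGENE")

    def test_out_of_range_position(self):
        with pytest.raises(ValueError, match="outside"):
            mutant_windows(PROTEIN20, 21, "A", "G")

    def test_pairs_differ_at_exactly_one_residue(self):
        rng = np.random.default_rng(5)
        aa = list(AMINO_ACIDS)
        for _ in range(50):
            length = int(rng.integers(9, 40))
            protein = "".join(rng.choice(aa, size=length))
            pos = int(rng.integers(1, length + 1))
            ref = protein[pos - 1]
            alt = aa[(aa.index(ref) + 1) % 20]
            for pair in mutant_windows(protein, pos, ref, alt):
                diffs = [i for i, (a, b) in enumerate(zip(pair.wt_peptide, pair.mut_peptide)) if a != b]
                assert len(diffs) == 1
                assert pair.window_start + diffs[0] == pos


def make_pair(mut="ACDEFGHIK", wt="ACDEFGHIR", gene="G1", sample="S1"):
    return PeptidePair(
        sample_id=sample, gene=gene, protein_pos=9, window_start=1, wt_peptide=wt, mut_peptide=mut
    )


class TestNeoantigenFilter:
    @pytest.mark.parametrize(
        "mut_ic50, wt_ic50, expr, expected",
        [
            (400.0, 600.0, 5.2, True),  # strong mutant, weak wild-type, expressed
            (400.0, 450.0, 5.2, False),  # parental peptide also binds
            (400.0, 600.0, 0.0, False),  # gene not expressed
            (500.0, 600.0, 5.2, False),  # mutant boundary fails strict <
            (400.0, 500.0, 5.2, False),  # wild-type boundary fails strict >
        ],
    )
    def test_filter_conjunction(self, mut_ic50, wt_ic50, expr, expected):
        pair = make_pair()
        table = AffinityTable({(pair.mut_peptide, "A1"): mut_ic50, (pair.wt_peptide, "A1"): wt_ic50})
        calls = call_neoantigens([pair], ["A1"], table, {"G1": expr})
        assert calls[0].is_neoantigen is expected

    def test_missing_affinity_entry_is_an_error(self):
        pair = make_pair()
        table = AffinityTable({(pair.mut_peptide, "A1"): 100.0})
        with pytest.raises(KeyError, match="A1"):
            call_neoantigens([pair], ["A1"], table, {"G1": 1.0})

    def test_missing_expression_is_an_error(self):
        pair = make_pair()
        table = AffinityTable({(pair.mut_peptide, "A1"): 100.0, (pair.wt_peptide, "A1"): 900.0})
        with pytest.raises(KeyError, match="G1"):
            call_neoantigens([pair], ["A1"], table, {})

    def test_raising_wt_cut_only_reduces_calls(self):
        rng = np.random.default_rng(2)
        aa = list(AMINO_ACIDS)
        pairs = []
        for i in range(60):
            wt = "".join(rng.choice(aa, size=9))
            j = int(rng.integers(0, 9))
            mut = wt[:j] + aa[(aa.index(wt[j]) + 1) % 20] + wt[j + 1 :]
            pairs.append(PeptidePair("S1", "G1", j + 1, 1, wt, mut))
        predictor = ToyPredictor(seed_constant=3)
        calls_500 = call_neoantigens(pairs, ["A1", "A2"], predictor, {"G1": 1.0}, wt_cut=500.0)
        calls_1000 = call_neoantigens(pairs, ["A1", "A2"], predictor, {"G1": 1.0}, wt_cut=1000.0)
        n500 = sum(c.is_neoantigen for c in calls_500)
        n1000 = sum(c.is_neoantigen for c in calls_1000)
        assert n1000 <= n500
        passing_1000 = {(c.pair.mut_peptide, c.allele) for c in calls_1000 if c.is_neoantigen}
        passing_500 = {(c.pair.mut_peptide, c.allele) for c in calls_500 if c.is_neoantigen}
        assert passing_1000 <= passing_500


class TestBurden:
    def _calls(self):
        pair = make_pair()
        table = AffinityTable(
            {
                (pair.mut_peptide, "A1"): 100.0,
                (pair.wt_peptide, "A1"): 900.0,
                (pair.mut_peptide, "A2"): 200.0,
                (pair.wt_peptide, "A2"): 800.0,
            }
        )
        return pair, table

    def test_counting_units(self):
        pair, table = self._calls()
        calls = call_neoantigens([pair], ["A1", "A2"], table, {"G1": 3.0})
        assert neoantigen_burden(calls, unit="peptide") == 1
        assert neoantigen_burden(calls, unit="peptide_allele") == 2

    def test_no_passing_calls(self):
        pair, table = self._calls()
        calls = call_neoantigens([pair], ["A1", "A2"], table, {"G1": 0.0})
        assert neoantigen_burden(calls) == 0

    def test_adding_an_allele_never_decreases_burden(self):
        pair, table = self._calls()
        one = call_neoantigens([pair], ["A1"], table, {"G1": 3.0})
        two = call_neoantigens([pair], ["A1", "A2"], table, {"G1": 3.0})
        for unit in ("peptide", "peptide_allele"):
            assert neoantigen_burden(two, unit=unit) >= neoantigen_burden(one, unit=unit)


class TestToyPredictor:
    def test_deterministic(self):
        p = ToyPredictor(seed_constant=9)
        assert p("ACDEFGHIK", "HLA-A*02:01") == p("ACDEFGHIK", "HLA-A*02:01")
        assert ToyPredictor(seed_constant=9)("ACDEFGHIK", "X") == p("ACDEFGHIK", "X")

    def test_single_residue_change_changes_score(self):
        p = ToyPredictor()
        assert p("ACDEFGHIK", "A1") != p("ACDEFGHIR", "A1")

    def test_rejects_non_9mer(self):
        with pytest.raises(ValueError):
            ToyPredictor()("ACDEFG", "A1")

    def test_scores_span_binding_threshold(self):
        rng = np.random.default_rng(0)
        aa = list(AMINO_ACIDS)
        peptides = ["".join(rng.choice(aa, size=9)) for _ in range(200)]
        scores = ToyPredictor().score_many(peptides, "HLA-A*01:01")
        assert (scores < 500).any() and (scores > 500).any()
        assert (scores > 0).all()

    def test_vectorized_matches_scalar(self):
        p = ToyPredictor(seed_constant=4)
        peptides = ["ACDEFGHIK", "YWVTSRQPN"]
        np.testing.assert_allclose(
            p.score_many(peptides, "B1"), [p(x, "B1") for x in peptides], rtol=1e-12
        )
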