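import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from catchscan.degron_annotation import (
    AMINO_ACIDS,
    HYDROPHOBICITY_PH7,
    assign_facing,
    background_frequencies,
    flanking_frequencies,
    hydrophobicity_contrast,
    paired_ttest,
    plddt_contrast,
    positional_enrichment,
    reconcile_parity,
)
from catchscan.strand_capture import CapturedStrand, detect_captured_strand
from catchscan.structure_io import ChainModel, ComplexModel, ResidueRecord, StructureError
from catchscan.synthetic_data import SheetSpec, build_capture_complex, build_monomer, plant_plddt


def _strand(start, end, residues=None):
    return CapturedStrand(
        start=start, end=end, residues=residues or "V" * (end - start + 1)
    )


class TestAssignFacing:
    def test_fixture_inward_set_matches_geometric_truth(self, capture_fixture):
        model = capture_fixture.as_model()
        strand = detect_captured_strand(model)
        facing = assign_facing(strand, model)
        assert facing.inward == set(capture_fixture.truth["inward_residues"])
        assert facing.parity == capture_fixture.truth["inward_parity"]

    def test_missing_reference_residue_is_error(self, capture_fixture):
        model = capture_fixture.as_model()
        strand = detect_captured_strand(model)
        with pytest.raises(StructureError, match="909"):
            assign_facing(strand, model, ref_residue=909)

    def test_all_glycine_strand_is_parity_tie_error(self):
        # glycines have no C-beta: no raw calls, odd and even tie at 0
        residues = [
            ResidueRecord(
                author_number=n,
                aa="G",
                atoms={"CA": np.array([3.5 * n, 0.0, 0.0])},
                plddt=90.0,
            )
            for n in range(1, 7)
        ]
        ref = ResidueRecord(
            author_number=309,
            aa="I",
            atoms={"CA": np.zeros(3)},
            plddt=90.0,
        )
        model = ComplexModel(
            receptor=ChainModel(chain_id="A", residues=[ref]),
            substrate=ChainModel(chain_id="B", residues=residues),
        )
        with pytest.raises(ValueError, match="parity"):
            assign_facing(_strand(1, 6, "G" * 6), model)

    def test_equidistant_cbeta_called_outward(self):
        # strict less-than: a CB exactly as far as its CA from the
        # reference is an outward raw call; were the rule <=, all four
        # residues here would be raw-inward and parity would tie
        residues = []
        for n in range(1, 5):
            ca = np.array([3.5 * n, 5.0, 0.0])
            cb = ca * 0.5 if n % 2 == 1 else ca.copy()  # even: equidistant
            residues.append(
                ResidueRecord(
                    author_number=n, aa="V", atoms={"CA": ca, "CB": cb}, plddt=90.0
                )
            )
        model = ComplexModel(
            receptor=ChainModel(
                chain_id="A",
                residues=[
                    ResidueRecord(
                        author_number=309, aa="I", atoms={"CA": np.zeros(3)}, plddt=90.0
                    )
                ],
            ),
            substrate=ChainModel(chain_id="B", residues=residues),
        )
        facing = assign_facing(_strand(1, 4), model)
        assert facing.parity == "odd"
        assert facing.inward == {1, 3}


class TestReconcileParity:
    def test_perfect_odd_set_kept(self):
        facing = reconcile_parity({1, 3, 5}, _strand(1, 6))
        assert facing.inward == {1, 3, 5}
        assert facing.parity == "odd"

    def test_majority_odd_adopts_full_odd_set(self):
        facing = reconcile_parity({1, 2, 5}, _strand(1, 6))
        assert facing.inward == {1, 3, 5}

    def test_even_set_adopted_wholesale(self):
        facing = reconcile_parity({2, 4}, _strand(1, 6))
        assert facing.inward == {2, 4, 6}
        assert facing.parity == "even"

    def test_exact_tie_is_error(self):
        with pytest.raises(ValueError, match="tie"):
            reconcile_parity({1, 2}, _strand(1, 6))

    @pytest.mark.parametrize("length", range(2, 9))
    def test_output_is_always_a_pure_parity_class(self, length):
        strand = _strand(1, length)
        numbers = set(range(1, length + 1))
        odd = {n for n in numbers if n % 2 == 1}
        even = numbers - odd
        for raw in itertools.chain.from_iterable(
            itertools.combinations(sorted(numbers), k)
            for k in range(length + 1)
        ):
            try:
                facing = reconcile_parity(set(raw), strand)
            except ValueError:
                continue
            assert facing.inward in (odd, even)
            assert facing.outward == numbers - facing.inward


class TestPositionalEnrichment:
    def test_balanced_cohort_has_unit_ratios(self):
        # every amino acid appears once per position: observed == background
        seqs = ["ACDE", "CDEA", "DEAC", "EACD"]
        strands = [_strand(1, 4, s) for s in seqs]
        background = {aa: 0.0 for aa in AMINO_ACIDS}
        background.update({"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25})
        table = positional_enrichment(strands, background)
        observed = table[table["observed"] > 0]
        assert np.allclose(observed["ratio"], 1.0)

    def test_single_strand_uniform_background(self):
        table = positional_enrichment(
            [_strand(1, 4, "VVVV")], {aa: 0.05 for aa in AMINO_ACIDS}
        )
        v_rows = table[table["aa"] == "V"]
        assert set(v_rows["depth"]) == {1, 2}
        assert np.allclose(v_rows["ratio"], 20.0)
        others = table[(table["aa"] != "V")]
        assert np.allclose(others["ratio"], 0.0)

    def test_length_three_strand_contributes_to_depth_one_only(self):
        # length >= 2n rule: a 3-residue strand supports n=1 but not n=2
        strands = [_strand(1, 3, "VLK"), _strand(10, 17, "AAAAAAAA")]
        table = positional_enrichment(
            strands, {aa: 0.05 for aa in AMINO_ACIDS}
        )
        n1 = table[(table["side"] == "N") & (table["depth"] == 1)]
        n2 = table[(table["side"] == "N") & (table["depth"] == 2)]
        assert n1.set_index("aa")["observed"]["V"] == pytest.approx(0.5)
        assert n2.set_index("aa")["observed"]["V"] == 0.0
        assert n2.set_index("aa")["observed"]["A"] == pytest.approx(1.0)

    def test_conservation_identity(self):
        rng = np.random.default_rng(5)
        aas = list(AMINO_ACIDS)
        strands = [
            _strand(1, L, "".join(rng.choice(aas, size=L)))
            for L in rng.integers(4, 12, size=25)
        ]
        background = background_frequencies([s.residues for s in strands])
        table = positional_enrichment(strands, background)
        for (_, _), group in table.groupby(["side", "depth"]):
            total = sum(
                r["ratio"] * background[r["aa"]]
                for _, r in group.iterrows()
                if np.isfinite(r["ratio"])
            )
            assert total == pytest.approx(1.0)

    def test_flanking_excludes_protein_termini(self):
        # strand at the very N terminus has no preceding flank
        cohort = [
            ("VVVVAAAA", _strand(1, 4), 1),      # starts at N terminus
            ("KVVVVAAA", _strand(2, 5), 1),      # preceded by K
        ]
        bg = {aa: 0.05 for aa in AMINO_ACIDS}
        table = flanking_frequencies(cohort, bg)
        prec = table[table["side"] == "preceding"].set_index("aa")
        assert prec.loc["K", "observed"] == pytest.approx(1.0)
        foll = table[table["side"] == "following"].set_index("aa")
        assert foll.loc["A", "observed"] == pytest.approx(1.0)


class TestPairedTTest:
    def test_matches_scipy_oracle(self):
        a = np.array([3.1, 2.4, 5.9, 4.4, 3.3])
        b = np.array([2.8, 2.9, 4.1, 4.6, 2.0])
        t, p = paired_ttest(a, b)
        ref = sstats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_all_equal_pairs(self):
        t, p = paired_ttest(np.ones(5), np.ones(5))
        assert t == 0.0 and p == 1.0

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            paired_ttest(np.array([1.0]), np.array([2.0]))


class TestHydrophobicityContrast:
    def test_null_cohort(self):
        cohort = [("VVVVVV", _strand(2, 4), 1) for _ in range(5)]
        result = hydrophobicity_contrast(cohort)
        assert result.t == 0.0 and result.p == 1.0

    def test_planted_hydrophobic_strands_detected(self):
        rng = np.random.default_rng(12)
        hydro = [aa for aa, v in HYDROPHOBICITY_PH7.items() if v > 60]
        polar = [aa for aa, v in HYDROPHOBICITY_PH7.items() if v < 0]
        cohort = []
        for _ in range(30):
            flank1 = "".join(rng.choice(polar, size=10))
            flank2 = "".join(rng.choice(polar, size=10))
            core = "".join(rng.choice(hydro, size=6))
            cohort.append((flank1 + core + flank2, _strand(11, 16), 1))
        result = hydrophobicity_contrast(cohort)
        assert result.mean_difference > 0
        assert result.p < 0.01

    def test_three_pairs_match_closed_form(self):
        cohort = [
            ("VAVAK", _strand(1, 2), 1),
            ("KKVVA", _strand(3, 4), 1),
            ("AVKAV", _strand(2, 3), 1),
        ]
        scale = HYDROPHOBICITY_PH7
        a, b = [], []
        for seq, s, off in cohort:
            inside = seq[s.start - off : s.end - off + 1]
            outside = seq[: s.start - off] + seq[s.end - off + 1 :]
            a.append(np.mean([scale[x] for x in inside]))
            b.append(np.mean([scale[x] for x in outside]))
        ref = sstats.ttest_rel(a, b)
        result = hydrophobicity_contrast(cohort)
        assert result.t == pytest.approx(ref.statistic, rel=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        aas = list(AMINO_ACIDS)
        cohort = [
            ("".join(rng.choice(aas, size=30)), _strand(10, 15), 1)
            for _ in range(8)
        ]
        r1 = hydrophobicity_contrast(cohort)
        r2 = hydrophobicity_contrast(cohort[::-1])
        assert r1.t == pytest.approx(r2.t)


class TestPlddtContrast:
    def test_uniform_plddt_gives_zero_difference(self):
        monomers = [build_monomer("VIKVEVTFAL", plddt=70.0) for _ in range(4)]
        result = plddt_contrast(monomers, [(3, 6)] * 4)
        assert result.mean_difference == 0.0
        assert result.t == 0.0

    def test_planted_disorder_contrast_recovered(self):
        monomers = []
        for k in range(20):
            m = build_monomer("V" * 40)
            monomers.append(
                plant_plddt(m, (15, 24), in_region=(50, 5), elsewhere=(85, 5), seed=k)
            )
        result = plddt_contrast(monomers, [(15, 24)] * 20)
        assert result.mean_difference == pytest.approx(-35.0, abs=3.0)
        assert result.p < 1e-6

    def test_single_substrate_is_error(self):
        with pytest.raises(ValueError):
            plddt_contrast([build_monomer("VVVVVV")], [(2, 4)])

    def test_unresolvable_interval_dropped_and_counted(self):
        monomers = [build_monomer("V" * 20) for _ in range(3)]
        result = plddt_contrast(monomers, [(5, 10), (5, 10), (50, 60)])
        assert result.n == 2
        assert result.dropped == 1
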