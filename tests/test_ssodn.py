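"""ssODN templates, combined-score arithmetic, matrices and codon reversion."""

import itertools

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from trimology.predictor import OutcomeDistribution, RepairOutcome
from trimology.seqcore import context_window, nucleotide_at
from trimology.ssodn import (
    DesignError,
    EditSpec,
    GenomeMismatchError,
    Substitution,
    build_ssodn,
    codon_revert,
    diff_against_genome,
    display_score,
    editing_window_scan,
    junction_score,
    optimal_ssodn,
    parse_edit,
    pythia_matrix,
    pythia_score,
    score_design,
)


def _simple_edit(site, position=-6):
    ref = nucleotide_at(site, position)
    alt = "A" if ref != "A" else "C"
    return EditSpec((Substitution(position, ref, alt),))


class TestBuildSsodn:
    def test_template_length_is_l_plus_r(self, planted_site):
        design = build_ssodn(planted_site, _simple_edit(planted_site), L=24, R=17)
        assert len(design.seq) == 41

    def test_empty_edit_reproduces_genome_window(self, planted_site):
        design = build_ssodn(planted_site, EditSpec(()), L=10, R=10)
        left, right = context_window(planted_site, 10, 10)
        assert design.seq == left + right

    def test_diff_recovers_editspec(self, planted_site, rng):
        for _ in range(20):
            L, R = int(rng.integers(8, 25)), int(rng.integers(8, 25))
            positions = rng.choice(range(-L + 3 - 3, R - 3 - 1), size=2, replace=False)
            subs = []
            for pos in sorted(int(p) for p in positions):
                ref = nucleotide_at(planted_site, pos)
                subs.append(Substitution(pos, ref, "ACGT"[("ACGT".index(ref) + 1) % 4]))
            edits = EditSpec(tuple(subs))
            design = build_ssodn(planted_site, edits, L, R)
            assert diff_against_genome(design) == edits

    def test_edit_outside_arms_names_minimal_coverage(self, planted_site):
        edits = _simple_edit(planted_site, position=-14)  # cut offset -11
        with pytest.raises(DesignError, match=r"L=11"):
            build_ssodn(planted_site, edits, L=5, R=5)

    def test_ref_mismatch_rejected(self, planted_site):
        ref = nucleotide_at(planted_site, -6)
        wrong = "A" if ref != "A" else "C"
        edits = EditSpec((Substitution(-6, wrong, "G" if wrong != "G" else "T"),))
        with pytest.raises(GenomeMismatchError):
            build_ssodn(planted_site, edits, 10, 10)


class TestCombinedScore:
    def test_worked_example_94_times_46(self):
        assert display_score(pythia_score(94, 46)) == 43
        assert pythia_score(94, 46) == pytest.approx(43.24)

    def test_identity_and_annihilation(self):
        assert pythia_score(100, 77.5) == pytest.approx(77.5)
        assert pythia_score(0, 50) == 0.0

    def test_commutative_monotone_bounded(self, rng):
        for _ in range(50):
            a, b, c = rng.uniform(0, 100, size=3)
            assert pythia_score(a, b) == pythia_score(b, a)
            assert pythia_score(a, b) <= min(a, b) + 1e-12
            lo, hi = sorted((b, c))
            assert pythia_score(a, lo) <= pythia_score(a, hi)

    def test_mock_predictor_left_score_is_46(self, planted_site):
        design = build_ssodn(planted_site, _simple_edit(planted_site), L=10, R=10)

        def mock_predictor(left, right):
            x = left + right
            cut = len(left)
            intended = x[: cut - 10] + x[cut:]
            other = x[: cut - 1] + x[cut + 1 :]
            return OutcomeDistribution(
                junction=x, cut=cut, params_id="mock",
                outcomes=(
                    RepairOutcome(category="deletion", product=intended, frequency=0.46, del_len=10),
                    RepairOutcome(category="deletion", product=other, frequency=0.54, del_len=2),
                ),
            )

        assert junction_score(mock_predictor, planted_site, design, "left") == pytest.approx(46.0)

    def test_score_decreases_with_edit_distance(self, surrogate, planted_site):
        scores = []
        for pos in (-5, -9, -13, -17):
            design, _ = optimal_ssodn(
                surrogate, planted_site, _simple_edit(planted_site, pos)
            )
            scores.append(design.pythia_score_pct)
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestMatrix:
    def test_full_grid_has_576_cells(self, surrogate, planted_site):
        mat = pythia_matrix(
            surrogate, planted_site, _simple_edit(planted_site),
            range(1, 25), range(1, 25),
        )
        assert mat.scores.size == 576

    def test_cells_match_independent_recomputation(self, surrogate, planted_site):
        edits = _simple_edit(planted_site)
        mat = pythia_matrix(surrogate, planted_site, edits, range(1, 13), range(1, 13))
        for L, R in [(4, 7), (8, 3), (12, 12)]:
            design = score_design(surrogate, build_ssodn(planted_site, edits, L, R))
            assert mat.cell(L, R) == pytest.approx(design.pythia_score_pct)
            # combined score recomputable from the two junction scores
            i, j = mat.L_range.index(L), mat.R_range.index(R)
            assert mat.cell(L, R) == pytest.approx(
                pythia_score(mat.score_left[i, j], mat.score_right[i, j])
            )

    def test_uncovered_cells_are_invalid_not_zero(self, surrogate, planted_site):
        edits = _simple_edit(planted_site, position=-10)  # needs L >= 7
        mat = pythia_matrix(surrogate, planted_site, edits, range(1, 13), range(1, 13))
        assert np.isnan(mat.cell(3, 5))
        assert not np.isnan(mat.cell(8, 5))

    def test_empty_valid_region_raises(self, surrogate, planted_site):
        edits = _simple_edit(planted_site, position=-14)
        with pytest.raises(DesignError):
            pythia_matrix(surrogate, planted_site, edits, range(1, 5), range(1, 5))

    def test_decile_binning_three_sites_yields_90_designs(self):
        from trimology.ssodn import PythiaMatrix, sample_by_decile

        # three guides whose matrices cover every decile: 3 per bin x 10
        # bins x 3 sites = 90 templates
        total = 0
        for seed in range(3):
            scores = np.linspace(0, 99.9, 144).reshape(12, 12)
            mat = PythiaMatrix(
                tuple(range(1, 13)), tuple(range(1, 13)), scores, scores, scores
            )
            picks = sample_by_decile(mat, per_bin=3, seed=seed)
            assert (picks.groupby("decile").size() == 3).all()
            total += len(picks)
        assert total == 90


class TestOptimal:
    def test_single_cell_region_forced(self, surrogate, planted_site):
        edits = _simple_edit(planted_site, position=-10)  # needs L >= 7
        design, mat = optimal_ssodn(
            surrogate, planted_site, edits, range(7, 8), range(5, 6)
        )
        assert (design.L, design.R) == (7, 5)

    def test_argmax_matches_exhaustive_scan(self, surrogate, planted_site):
        edits = _simple_edit(planted_site)
        design, mat = optimal_ssodn(
            surrogate, planted_site, edits, range(1, 13), range(1, 13)
        )
        best = np.nanmax(mat.scores)
        assert design.pythia_score_pct == pytest.approx(best)
        # repeated runs are byte-identical
        again, _ = optimal_ssodn(surrogate, planted_site, edits, range(1, 13), range(1, 13))
        assert (again.L, again.R, again.seq) == (design.L, design.R, design.seq)

    def test_tie_breaks_prefer_short_then_balanced_then_small_l(self, planted_site):
        def flat_predictor(left, right):
            x = left + right
            cut = len(left)
            outcomes = tuple(
                RepairOutcome(category="deletion", product=x[: cut - d] + x[cut:],
                              frequency=0.5 if d == 1 else 0.5, del_len=d)
                for d in (1, 2)
            )
            return OutcomeDistribution(junction=x, cut=cut, params_id="flat", outcomes=outcomes)

        # constant-score predictor: every cell ties, so the tie-break decides
        edits = EditSpec(())
        design, mat = optimal_ssodn(
            flat_predictor, planted_site, edits, range(10, 13), range(10, 13)
        )
        finite = mat.scores[~np.isnan(mat.scores)]
        assert np.allclose(finite, finite[0])
        assert (design.L, design.R) == (10, 10)


class TestWindowScan:
    def test_three_alt_rows_per_position(self, surrogate, planted_site):
        table = editing_window_scan(
            surrogate, planted_site, positions=range(-6, -3),
            L_range=range(1, 9), R_range=range(1, 9),
        )
        assert (table.groupby("position").size() == 3).all()

    def test_rows_equal_single_optimal_runs(self, surrogate, planted_site):
        table = editing_window_scan(
            surrogate, planted_site, positions=[-5],
            L_range=range(1, 9), R_range=range(1, 9),
        )
        for row in table.itertuples():
            edits = EditSpec((Substitution(row.position, row.ref, row.alt),))
            design, _ = optimal_ssodn(
                surrogate, planted_site, edits, range(1, 9), range(1, 9)
            )
            assert row.max_score_pct == pytest.approx(design.pythia_score_pct)
            assert (row.optimal_L, row.optimal_R) == (design.L, design.R)

    def test_cut_adjacent_beats_distal(self, surrogate, planted_site):
        table = editing_window_scan(surrogate, planted_site, positions=[-5, -20])
        near = table[table.position == -5].max_score_pct.max()
        far = table[table.position == -20].max_score_pct.max()
        assert near >= far


class TestCodonRevert:
    def test_printed_conversion_needs_two_changes(self):
        # the eGFP -> eBFP assay conversion CCT -> GCC differs at two bases
        edit = codon_revert("CCT", "A")  # GCC encodes Ala
        assert sum(a != b for a, b in zip("CCT", "GCC")) == 2
        # the minimal reversion to Ala needs only one change (GCT)
        assert edit.chosen_codon == "GCT"
        assert edit.n_changes == 1

    def test_identity_when_codon_already_encodes_target(self):
        edit = codon_revert("GAT", "D")
        assert edit.n_changes == 0 and edit.chosen_codon == "GAT"

    def test_equals_exhaustive_oracle_for_all_codon_aa_pairs(self):
        aas = sorted(set(standard_dna_table.forward_table.values())) + ["*"]
        codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
        for codon in codons:
            for aa in aas:
                edit = codon_revert(codon, aa)
                best = min(
                    (
                        (sum(a != b for a, b in zip(codon, cand)), cand)
                        for cand in codons
                        if str(Seq(cand).translate()) == aa
                    ),
                )
                assert (edit.n_changes, edit.chosen_codon) == best
                assert edit.n_changes <= 3
                assert str(Seq(edit.chosen_codon).translate()) == aa

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            codon_revert("ATG", "B")


def test_parse_edit_round_trip():
    sub = parse_edit("-6C>G")
    assert (sub.position, sub.ref, sub.alt) == (-6, "C", "G")
    with pytest.raises(ValueError):
        parse_edit("x>y")
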