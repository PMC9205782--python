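import numpy as np
import pytest

from larkszip.io import read_variant_table, write_variant_table
from larkszip.synth import (LCD_PROFILE, SyntheticSpec,
                            generate_synthetic_proteome,
                            generate_synthetic_variants,
                            make_ideal_zipper_structure)


@pytest.fixture(scope="module")
def small_spec():
    return SyntheticSpec(seed=5, n_proteins=6, protein_length=60,
                         windows_per_protein=2, pathogenic_per_window=2,
                         n_benign=20)


@pytest.fixture(scope="module")
def proteome(small_spec):
    return generate_synthetic_proteome(small_spec)


class TestProteomeGenerator:
    def test_seeded_runs_are_identical(self, small_spec):
        r1, t1 = generate_synthetic_proteome(small_spec)
        r2, t2 = generate_synthetic_proteome(small_spec)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1.equals(t2)

    def test_ground_truth_bookkeeping(self, proteome, small_spec):
        records, truth = proteome
        assert len(records) == small_spec.n_proteins
        assert len(truth) == small_spec.n_proteins * small_spec.windows_per_protein
        by_id = {r.id: r for r in records}
        for _, row in truth.iterrows():
            rec = by_id[row.protein_id]
            window = rec.sequence[row.start - 1:row.end]
            assert window == row.motif
            for pos in row.kink_positions:
                assert rec.residue_at(pos) == "G"

    def test_composition_within_sampling_error(self):
        spec = SyntheticSpec(seed=3, n_proteins=30, protein_length=80,
                             windows_per_protein=1)
        records, truth = generate_synthetic_proteome(spec)
        planted = {(row.protein_id, p)
                   for _, row in truth.iterrows()
                   for p in range(row.start, row.end + 1)}
        residues = [r.sequence[p - 1] for r in records
                    for p in range(1, len(r) + 1) if (r.id, p) not in planted]
        gsy = np.mean([c in "GSY" for c in residues])
        target = LCD_PROFILE["G"] + LCD_PROFILE["S"] + LCD_PROFILE["Y"]
        sigma = np.sqrt(target * (1 - target) / len(residues))
        assert abs(gsy - target) <= 3 * sigma

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(protein_length=4)


class TestVariantGenerator:
    def test_rows_survive_table_validation(self, proteome, small_spec, tmp_path):
        records, truth = proteome
        variants, vtruth = generate_synthetic_variants(records, truth, small_spec)
        path = tmp_path / "v.tsv"
        write_variant_table(variants, path)
        assert len(read_variant_table(path)) == len(variants)

    def test_wild_types_consistent_with_sequences(self, proteome, small_spec):
        records, truth = proteome
        by_id = {r.id: r for r in records}
        variants, _ = generate_synthetic_variants(records, truth, small_spec)
        for v in variants:
            assert by_id[v.protein_id].residue_at(v.position) == v.wt_aa

    def test_pathogenic_rows_sit_inside_planted_windows(self, proteome, small_spec):
        records, truth = proteome
        variants, vtruth = generate_synthetic_variants(records, truth, small_spec)
        in_window = {(row.protein_id, p)
                     for _, row in truth.iterrows()
                     for p in range(row.start, row.end + 1)}
        path = [v for v in variants if v.significance == "pathogenic"]
        ben = [v for v in variants if v.significance == "benign"]
        assert all((v.protein_id, v.position) in in_window for v in path)
        assert all((v.protein_id, v.position) not in in_window for v in ben)

    def test_truth_flags_only_acv_substitutions(self, proteome, small_spec):
        records, truth = proteome
        variants, vtruth = generate_synthetic_variants(records, truth, small_spec)
        flagged = {r.label for _, r in vtruth.iterrows() if r.planted_converted}
        for v in variants:
            if v.label in flagged:
                assert v.wt_aa == "G" and v.mut_aa in "ACV"

    def test_seeded_reproducibility(self, proteome, small_spec):
        records, truth = proteome
        v1, t1 = generate_synthetic_variants(records, truth, small_spec)
        v2, t2 = generate_synthetic_variants(records, truth, small_spec)
        assert [x.label for x in v1] == [x.label for x in v2]
        assert t1.equals(t2)


class TestIdealZipperGenerator:
    def test_planted_attributes_by_construction(self):
        st, truth = make_ideal_zipper_structure(1, "SGMGGI", 0)
        assert truth["within_sheet"] == "parallel"
        assert truth["class_number"] == 1
        assert len(st.chain_ids()) == 8  # 2 sheets x 4 strands

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            make_ideal_zipper_structure(9, "SGMGGI", 0)

    def test_seeded_rigid_transform_determinism(self):
        s1, _ = make_ideal_zipper_structure(3, "SGMGGI", 42)
        s2, _ = make_ideal_zipper_structure(3, "SGMGGI", 42)
        a = [(x.x, x.y, x.z) for x in s1.atoms]
        b = [(x.x, x.y, x.z) for x in s2.atoms]
        assert a == b
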