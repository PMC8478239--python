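"""Feature assembly: ligand proximity, domain membership, contact
profiles, the PSSM reader, and the full feature table."""

import numpy as np
import pandas as pd
import pytest

from pctopo.datasets import load_gaucher_variants
from pctopo.features import (
    AA_ALPHABET, DomainConfig, VariantRecord,
    binds_ligand, build_feature_table, contact_profile, in_catalytic_domain, read_pssm,
)
from pctopo.structure import Atom, Residue, Structure
from pctopo.synthetic import SyntheticStructureSpec, make_structure
from pctopo.topology import Contact, ContactMap, compute_contacts
from pctopo.structure import read_pdb


def _structure_with_ligand(residue_to_ligand_distance):
    res = Residue("A", 1, "", "ALA", [Atom("CA", "C", np.zeros(3), 15.0)])
    lig = Residue("B", 101, "", "GOL",
                  [Atom("C1", "C", np.array([residue_to_ligand_distance, 0.0, 0.0]), 20.0)],
                  is_polymer=False)
    return Structure(chains={"A": [res]}, het_groups=[lig])


class TestBindsLigand:
    @pytest.mark.parametrize("distance, expected", [
        (4.9, True), (5.1, False), (5.0, True),  # inclusive boundary
    ])
    def test_cutoff_boundary(self, distance, expected):
        s = _structure_with_ligand(distance)
        assert binds_ligand(s, 1, "GOL", cutoff=5.0) is expected

    def test_monotone_in_cutoff(self):
        s = _structure_with_ligand(4.0)
        assert binds_ligand(s, 1, "GOL", cutoff=4.0)
        assert binds_ligand(s, 1, "GOL", cutoff=7.5)

    def test_absent_residue_raises(self):
        with pytest.raises(Exception):
            binds_ligand(_structure_with_ligand(3.0), 42, "GOL")


class TestCatalyticDomain:
    def test_containment_and_inclusive_ends(self):
        cfg = DomainConfig([(30, 400)])
        assert in_catalytic_domain(cfg, 370)
        assert in_catalytic_domain(cfg, 400)
        assert not in_catalytic_domain(cfg, 444)  # L444 outside the catalytic domain
        assert not in_catalytic_domain(cfg, 29)

    def test_missing_config_raises(self):
        with pytest.raises(ValueError):
            in_catalytic_domain(None, 370)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            DomainConfig([(1, 10), (5, 20)])


class TestContactProfile:
    def test_counts_by_residue_type(self, nested_structure):
        structure, expected = nested_structure
        cmap = compute_contacts(structure, "methods")
        # residue 5 contacts residue 8 only (types cycle A,L,G,S,V,T,K,D,F,R)
        profile = contact_profile(structure, cmap, 5)
        assert profile["D"] == 1  # residue 8 is ASP in the synthetic type cycle
        assert sum(profile.values()) == 1

    def test_isolated_residue_all_zero(self, nested_structure):
        structure, _ = nested_structure
        cmap = compute_contacts(structure, "methods")
        profile = contact_profile(structure, cmap, 2)
        assert sum(profile.values()) == 0

    def test_profile_sums_equal_contact_count_everywhere(self, tmp_path):
        from pctopo.topology import contact_count
        text, _ = make_structure(SyntheticStructureSpec(16, "hairpin", seed=5))
        path = tmp_path / "h.pdb"
        path.write_text(text)
        structure = read_pdb(path)
        cmap = compute_contacts(structure, "methods")
        for res in structure.residues():
            profile = contact_profile(structure, cmap, res.seq_number)
            assert sum(profile.values()) == contact_count(cmap, res.seq_number)


PSSM_TEXT = """
Last position-specific scoring matrix computed, weighted, observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M    -2  -3  -4  -5  -3  -2  -4  -5  -3   1   2  -3   8   0  -4  -3  -2  -3  -2   0    0   0   0   0   0   0   0   0   0   4   9   0  79   1   0   0   0   0   0   5  0.95 0.12
    2 K    -1   2   0  -1  -4   1   1  -2   0  -3  -3   5  -2  -4  -2   0  -1  -4  -2  -3    4  12   3   2   0   5   7   2   1   0   1  55   0   0   1   4   2   0   0   1  0.52 0.10
    3 V     0  -3  -4  -4  -2  -3  -3  -4  -4   2   1  -3   1  -1  -3  -2   0  -4  -2   4    6   0   0   0   1   0   1   0   0  13  10   0   3   2   0   2   4   0   1  57  0.48 0.11

                      K         Lambda
Standard Ungapped    0.1347     0.3179
"""


class TestReadPssm:
    def test_round_trip_values(self, tmp_path):
        path = tmp_path / "query.pssm"
        path.write_text(PSSM_TEXT)
        mat = read_pssm(path)
        assert mat.shape == (3, 20)
        assert list(mat.index) == [1, 2, 3]
        assert mat.at[1, "M"] == 8
        assert mat.at[2, "K"] == 5
        assert mat.at[3, "V"] == 4
        assert mat.at[1, "A"] == -2

    def test_trailing_statistics_block_ignored(self, tmp_path):
        path = tmp_path / "query.pssm"
        path.write_text(PSSM_TEXT)
        assert read_pssm(path).shape == (3, 20)

    def test_truncated_row_is_parse_error_with_line(self, tmp_path):
        lines = PSSM_TEXT.strip().splitlines()
        lines[3] = "    2 K    -1   2   0"
        path = tmp_path / "trunc.pssm"
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="line"):
            read_pssm(path)

    def test_non_pssm_file_rejected(self, tmp_path):
        path = tmp_path / "x.pssm"
        path.write_text("nothing to see\n")
        with pytest.raises(ValueError):
            read_pssm(path)


class TestVariantRecord:
    @pytest.mark.parametrize("name, wt, pos, mut", [
        ("N370S", "N", 370, "S"),
        ("p.Asn370Ser", "N", 370, "S"),
        ("L444P", "L", 444, "P"),
    ])
    def test_name_parsing(self, name, wt, pos, mut):
        v = VariantRecord.from_string("GBA", name, 0.5)
        assert (v.wt_aa, v.position, v.mut_aa) == (wt, pos, mut)

    def test_synonymous_rejected(self):
        with pytest.raises(ValueError):
            VariantRecord("GBA", "N", 370, "N", 0.0)


class TestBuildFeatureTable:
    def test_published_features_pass_through_verbatim(self):
        """Supplying the published Gaucher feature rows as records keeps
        every printed column value intact in the assembled table."""
        ref = load_gaucher_variants()
        variants = [VariantRecord.from_string(r.protein_id, r.variant, r.ddg,
                                              r.observed_responsive)
                    for r in ref.itertuples()]
        table = build_feature_table(variants)
        assert list(table["variant"]) == list(ref["variant"])
        assert list(table["ddg"]) == list(ref["ddg"])
        # structural columns are explicit missing values without a structure
        assert table["n_contacts"].isna().all()
        assert table["binds_ligand"].isna().all()

    def test_empty_variant_list_gives_empty_table_with_header(self):
        table = build_feature_table([])
        assert len(table) == 0
        assert "ddg" in table.columns and "p_inv" in table.columns

    def test_structure_derived_columns(self, nested_structure, tmp_path):
        structure, _ = nested_structure
        cmap = compute_contacts(structure, "methods")
        # residue 5 is VAL in the synthetic type cycle
        v = VariantRecord("SYN", "V", 5, "A", 1.0)
        table = build_feature_table([v], structure, cmap)
        row = table.iloc[0]
        assert row["n_contacts"] == 1
        assert row["p_inv"] == 2  # two enclosing loops around contact (5, 8)
        assert row["ca_b_factor"] == pytest.approx(20.0)

    def test_wt_mismatch_names_found_residue(self, nested_structure):
        structure, _ = nested_structure
        cmap = compute_contacts(structure, "methods")
        with pytest.raises(ValueError, match="position 5"):
            build_feature_table([VariantRecord("SYN", "W", 5, "A", 1.0)],
                                structure, cmap)

    def test_unresolved_position_skip_policy(self, nested_structure):
        structure, _ = nested_structure
        with pytest.warns(UserWarning, match="skipped"):
            table = build_feature_table(
                [VariantRecord("SYN", "A", 999, "G", 1.0)],
                structure, on_unresolved="skip")
        assert len(table) == 0

    def test_permutation_invariance(self):
        ref = load_gaucher_variants()
        variants = [VariantRecord.from_string(r.protein_id, r.variant, r.ddg)
                    for r in ref.itertuples()]
        fwd = build_feature_table(variants)
        rev = build_feature_table(variants[::-1])
        assert list(rev["variant"]) == list(fwd["variant"])[::-1]
        merged = rev.sort_values("variant").reset_index(drop=True)
        assert merged.equals(fwd.sort_values("variant").reset_index(drop=True))
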