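import pandas as pd
import pytest

from chirdelta import chem
from chirdelta.errors import (
    MultiCenterError,
    NoStereocenterError,
    ParseError,
)

ALANINE_S = "C[C@H](N)C(=O)O"


class TestCanonicalize:
    def test_matches_toolkit_canonical_form(self):
        assert chem.canonicalize("OCC") == "CCO"

    @pytest.mark.parametrize(
        "smiles", ["OCC", ALANINE_S, "c1ccccc1[C@@H](O)C", "N[C@@H](Br)Cl"]
    )
    def test_idempotent(self, smiles):
        once = chem.canonicalize(smiles)
        assert chem.canonicalize(once) == once

    def test_strips_typeset_whitespace(self):
        # published strings often carry spaces inside "(= O)" groups
        spaced = "COC(= O)[C@]1(c2ccc(Cl)cc2)OC(= O)c2cc3ccccc3n21"
        can = chem.canonicalize(spaced)
        assert can.count("[C@]") + can.count("[C@@]") == 1

    def test_rejects_garbage(self):
        with pytest.raises(ParseError):
            chem.canonicalize("this is not a molecule")
        with pytest.raises(ParseError):
            chem.canonicalize("")


class TestInvertEnantiomer:
    def test_known_pair(self):
        assert chem.invert_enantiomer(ALANINE_S) == "C[C@@H](N)C(=O)O"

    def test_flips_cip_label(self):
        inv = chem.invert_enantiomer(ALANINE_S)
        assert {chem.assign_cip(ALANINE_S), chem.assign_cip(inv)} == {"R", "S"}

    def test_involution(self, small_library):
        records, _ = small_library
        for rec in records:
            s = rec.smiles_canonical
            assert chem.invert_enantiomer(chem.invert_enantiomer(s)) == s

    def test_achiral_input_rejected(self):
        with pytest.raises(NoStereocenterError):
            chem.invert_enantiomer("CCO")


class TestStripStereo:
    def test_removes_parity_tag(self):
        assert chem.strip_stereo(ALANINE_S) == "CC(N)C(=O)O"

    def test_idempotent_and_commutes_with_inversion(self, small_library):
        records, _ = small_library
        for rec in records:
            s = rec.smiles_canonical
            stripped = chem.strip_stereo(s)
            assert chem.strip_stereo(stripped) == stripped
            assert chem.strip_stereo(chem.invert_enantiomer(s)) == stripped

    def test_pair_members_share_stripped_form(self, small_library):
        records, pairs = small_library
        for pair in pairs:
            a = records[pair.member_first_index]
            b = records[pair.member_second_index]
            assert chem.strip_stereo(a.smiles_canonical) == chem.strip_stereo(
                b.smiles_canonical
            )


class TestAssignCip:
    def test_single_center_gets_r_or_s(self):
        assert chem.assign_cip(ALANINE_S) in ("R", "S")

    def test_antisymmetric_under_inversion(self, small_library):
        records, _ = small_library
        for rec in records:
            assert chem.assign_cip(rec.smiles_canonical) != chem.assign_cip(
                chem.invert_enantiomer(rec.smiles_canonical)
            )

    def test_achiral_and_multicenter_rejected(self):
        with pytest.raises(NoStereocenterError):
            chem.assign_cip("CC(N)C(=O)O")
        with pytest.raises(MultiCenterError):
            chem.assign_cip("C[C@H](O)[C@H](N)C(=O)O")


class TestRelabelCipAligned:
    def test_aligned_input_is_fixed_point(self, small_library):
        records, _ = small_library
        for rec in records:
            if chem.CIP_ALIGNED_TAG[rec.cip_label] == rec.stereo_tag:
                assert chem.relabel_cip_aligned(rec.smiles_canonical) == (
                    rec.smiles_canonical
                )

    def test_misaligned_input_gets_rewritten_same_molecule(self, small_library):
        records, _ = small_library
        checked = 0
        for rec in records:
            if chem.CIP_ALIGNED_TAG[rec.cip_label] == rec.stereo_tag:
                continue
            out = chem.relabel_cip_aligned(rec.smiles_canonical)
            # tag now follows the convention @=S / @@=R ...
            assert chem.stereo_tag_of(out) == chem.CIP_ALIGNED_TAG[rec.cip_label]
            # ... but the molecule (and hence its CIP label) is unchanged
            assert chem.canonicalize(out) == rec.smiles_canonical
            assert chem.assign_cip(out) == rec.cip_label
            checked += 1
        assert checked > 0, "library should contain misaligned molecules"

    def test_achiral_input_rejected(self):
        with pytest.raises(NoStereocenterError):
            chem.relabel_cip_aligned("CCO")


class TestStereoTag:
    def test_classes(self):
        assert chem.stereo_tag_of("C[C@H](N)C(=O)O") == "AT"
        assert chem.stereo_tag_of("C[C@@H](N)C(=O)O") == "ATAT"

    def test_tag_free_rejected(self):
        with pytest.raises(NoStereocenterError):
            chem.stereo_tag_of("CCO")


def _frame(rows):
    return pd.DataFrame(rows)


class TestCurate:
    def test_valid_pair_survives_with_shared_pair_key(self):
        records, rejections = chem.curate(
            _frame([{"smiles": ALANINE_S}, {"smiles": "C[C@@H](N)C(=O)O"}])
        )
        assert len(records) == 2 and len(rejections) == 0
        assert records[0].pair_key == records[1].pair_key
        assert {r.cip_label for r in records} == {"R", "S"}
        assert {r.stereo_tag for r in records} == {"AT", "ATAT"}

    def test_disallowed_element_dropped(self):
        _, rejections = chem.curate(
            _frame([{"smiles": "C[C@H](N)C[Si](C)(C)C"}])
        )
        assert list(rejections.reason) == ["element"]

    def test_unparseable_dropped(self):
        _, rejections = chem.curate(_frame([{"smiles": "xyz("}]))
        assert list(rejections.reason) == ["parse"]

    def test_stereo_filters(self):
        frame = _frame(
            [
                {"smiles": "CCO"},  # no stereocenter
                {"smiles": "C[C@H](O)[C@H](N)C(=O)O"},  # two centers
                {"smiles": "C/C=C/C[C@H](N)O"},  # double-bond stereo alongside
            ]
        )
        _, rejections = chem.curate(frame)
        assert list(rejections.reason) == [
            "no_stereocenter",
            "multi_stereocenter",
            "stereo_type",
        ]

    def test_conflicting_duplicates_all_dropped(self):
        frame = _frame(
            [
                {"smiles": ALANINE_S, "elution_label": "First"},
                {"smiles": ALANINE_S, "elution_label": "Last"},
                {"smiles": "C[C@@H](N)C(=O)O", "elution_label": "Last"},
            ]
        )
        records, rejections = chem.curate(frame)
        assert (rejections.reason == "inconsistent_duplicate").sum() == 2
        # the surviving partner becomes an orphan and is dropped too
        assert (rejections.reason == "orphan").sum() == 1
        assert records == []

    def test_consistent_duplicates_deduplicated(self):
        frame = _frame(
            [
                {"smiles": ALANINE_S},
                {"smiles": "C[CH](N)C(=O)O ".replace("[CH]", "[C@H]")},
                {"smiles": "C[C@@H](N)C(=O)O"},
            ]
        )
        records, rejections = chem.curate(frame)
        assert len(records) == 2
        assert list(rejections.reason) == ["duplicate"]

    def test_orphan_enantiomer_dropped(self):
        records, rejections = chem.curate(_frame([{"smiles": ALANINE_S}]))
        assert records == [] and list(rejections.reason) == ["orphan"]

    def test_drop_flag_hook(self):
        frame = _frame(
            [
                {"smiles": ALANINE_S, "suspect": True},
                {"smiles": "C[C@@H](N)C(=O)O", "suspect": False},
            ]
        )
        records, rejections = chem.curate(frame, drop_flag_column="suspect")
        assert set(rejections.reason) == {"flagged", "orphan"}
        assert records == []

    def test_curated_set_pairs_cleanly(self, small_library):
        records, pairs = small_library
        assert len(records) % 2 == 0
        assert len(pairs) == len(records) // 2
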