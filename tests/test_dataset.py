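import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

import chirdelta as cd
from chirdelta import chem, dataset
from chirdelta.errors import MissingDataError, TieError


def _record(smiles, rt=None, exp=None):
    can = chem.canonicalize(smiles)
    return chem.MoleculeRecord(
        smiles_raw=smiles,
        smiles_canonical=can,
        stereo_tag=chem.stereo_tag_of(can),
        cip_label=chem.assign_cip(can),
        pair_key=chem.strip_stereo(can),
        retention_time=rt,
        experiment_id=exp,
    )


class TestBuildPairs:
    def test_groups_into_pairs(self):
        records = [
            _record("C[C@H](N)C(=O)O"),
            _record("C[C@@H](N)C(=O)O"),
            _record("N[C@@H](Br)Cl"),
            _record("N[C@H](Br)Cl"),
        ]
        pairs, rejected = cd.build_pairs(records)
        assert len(pairs) == 2 and len(rejected) == 0
        for pair in pairs:
            a, b = pair.indices()
            assert records[a].pair_key == records[b].pair_key == pair.pair_key
            assert records[a].cip_label != records[b].cip_label

    def test_bad_group_size_rejected(self):
        records = [
            _record("C[C@H](N)C(=O)O"),
            _record("C[C@@H](N)C(=O)O"),
            _record("C[C@H](N)C(=O)O"),
        ]
        pairs, rejected = cd.build_pairs(records)
        assert pairs == []
        assert set(rejected.reason) == {"group_size"}
        assert len(rejected) == 3

    def test_synthetic_library_yields_exactly_n_pairs(self, small_library):
        records, pairs = small_library
        assert len(pairs) == len(records) // 2 == 20


class TestLabelElution:
    def _pair(self, rt_a, rt_b, exp_a="E1", exp_b="E1"):
        records = [
            _record("C[C@H](N)C(=O)O", rt_a, exp_a),
            _record("C[C@@H](N)C(=O)O", rt_b, exp_b),
        ]
        pairs, _ = cd.build_pairs(records)
        return records, pairs[0]

    def test_smaller_time_elutes_first(self):
        records, pair = self._pair(3.2, 5.5)
        labels = dataset.label_elution(pair, records)
        by_rt = sorted(
            (records[i] for i in pair.indices()), key=lambda r: r.retention_time
        )
        assert by_rt[0].elution_label == "First"
        assert by_rt[1].elution_label == "Last"
        assert set(labels) == {"First", "Last"}

    def test_equal_times_raise_tie(self):
        records, pair = self._pair(4.0, 4.0)
        with pytest.raises(TieError):
            dataset.label_elution(pair, records)

    def test_missing_time_or_experiment_mismatch(self):
        records, pair = self._pair(3.0, None)
        with pytest.raises(MissingDataError):
            dataset.label_elution(pair, records)
        records, pair = self._pair(3.0, 4.0, exp_a="E1", exp_b="E2")
        with pytest.raises(MissingDataError):
            dataset.label_elution(pair, records)

    def test_bulk_labeling_drops_bad_pairs_with_reasons(self):
        records = [
            _record("C[C@H](N)C(=O)O", 3.0, "E1"),
            _record("C[C@@H](N)C(=O)O", 5.0, "E1"),
            _record("N[C@@H](Br)Cl", 2.0, "E2"),
            _record("N[C@H](Br)Cl", 2.0, "E2"),
        ]
        pairs, _ = cd.build_pairs(records)
        kept, dropped = cd.label_all_elution(records, pairs)
        assert len(kept) == 1
        assert list(dropped.reason) == ["tie"]


class TestSplitPairs:
    def test_pair_integrity_across_seeds(self, small_library):
        _, pairs = small_library
        for seed in range(5):
            split = cd.split_pairs(pairs, test_fraction=0.1, seed=seed)
            assert not (split.train_pair_keys & split.test_pair_keys)
            assert split.train_pair_keys | split.test_pair_keys == {
                p.pair_key for p in pairs
            }
            assert len(split.test_pair_keys) == 2

    def test_explicit_test_count_overrides_fraction(self, small_library):
        _, pairs = small_library
        split = cd.split_pairs(pairs, test_fraction=0.5, test_count=3, seed=0)
        assert len(split.test_pair_keys) == 3
        assert len(split.train_pair_keys) == 17

    def test_reproducible_and_seed_sensitive(self, small_library):
        _, pairs = small_library
        a = cd.split_pairs(pairs, seed=1)
        b = cd.split_pairs(pairs, seed=1)
        c = cd.split_pairs(pairs, seed=2)
        assert a.test_pair_keys == b.test_pair_keys
        assert a.test_pair_keys != c.test_pair_keys

    @given(test_count=st.integers(min_value=-3, max_value=30))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_invalid_counts_rejected(self, small_library, test_count):
        _, pairs = small_library
        if 0 < test_count < len(pairs):
            split = cd.split_pairs(pairs, test_count=test_count, seed=0)
            assert len(split.test_pair_keys) == test_count
        else:
            with pytest.raises(ValueError):
                cd.split_pairs(pairs, test_count=test_count, seed=0)

    def test_split_file_round_trip(self, small_library, tmp_path):
        _, pairs = small_library
        split = cd.split_pairs(pairs, seed=3)
        path = tmp_path / "split.csv"
        split.to_csv(path)
        back = dataset.SplitAssignment.from_csv(path)
        assert back == split


class TestLeakOneEnantiomer:
    def test_counts_and_membership(self, small_library):
        records, pairs = small_library
        split = cd.split_pairs(pairs, test_fraction=0.5, seed=0)
        leaked = cd.leak_one_enantiomer(split, pairs, records)
        n_test_pairs = len(split.test_pair_keys)
        assert len(leaked.test_smiles) == n_test_pairs
        n_train_molecules = 2 * len(split.train_pair_keys) + n_test_pairs
        assert len(leaked.train_smiles) == n_train_molecules
        # each former test pair contributes one member to each side
        for p in pairs:
            if p.pair_key not in split.test_pair_keys:
                continue
            a, b = (records[i].smiles_canonical for i in p.indices())
            assert (a in leaked.train_smiles) != (b in leaked.train_smiles)
            assert (a in leaked.test_smiles) != (b in leaked.test_smiles)

    def test_idempotent(self, small_library):
        records, pairs = small_library
        split = cd.split_pairs(pairs, seed=0)
        once = cd.leak_one_enantiomer(split, pairs, records)
        twice = cd.leak_one_enantiomer(once, pairs, records)
        assert twice is once

    def test_seed_changes_choice_not_counts(self, small_library):
        records, pairs = small_library
        split = cd.split_pairs(pairs, test_fraction=0.5, seed=0)
        default = cd.leak_one_enantiomer(split, pairs, records)
        seeded = cd.leak_one_enantiomer(split, pairs, records, seed=5)
        assert len(default.test_smiles) == len(seeded.test_smiles)
        assert len(default.train_smiles) == len(seeded.train_smiles)
        assert set(default.test_smiles) != set(seeded.test_smiles)
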