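"""Feature multisets, difference fingerprints, and key canonicalization.

The independent oracle enumerates circular environments structurally
(canonical substructure SMILES) and must agree with the hashed Morgan
multisets on counts and on the induced grouping.
"""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from fppairs.chem_io import standardize_molecule
from fppairs.fingerprints import (
    FeatureMultiset,
    TransformationKey,
    canonical_orientation,
    compute_feature_multiset,
    difference_fingerprint,
    feature_environments,
    key_string,
    reverse_key,
)
from oracles import enumerate_environment_classes, environment_class_difference

CORPUS = [
    "C",
    "CC",
    "CCO",
    "c1ccccc1",
    "Cc1ccccc1",
    "CCN(C)CCc1ccc(F)cc1",
    "CC(=O)Oc1ccccc1C(=O)O",
    "c1ccncc1",
    "CC(C)(C)c1ccc(O)cc1",
    "C1CCCCC1",
    "CC1CCCC1C",
    "N#Cc1ccccc1",
    "OCC(O)CO",
    "CN1CCC[C@H]1c1cccnc1",
    "OCCN(C)CCc1ccc(Br)cc1",
    "CC(=O)Nc1ccc(O)cc1",
    "c1cn[nH]c1",
    "FC(F)(F)c1ccccc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
]


def mol(smiles: str) -> Chem.Mol:
    return Chem.MolFromSmiles(smiles)


class TestFeatureMultiset:
    @pytest.mark.parametrize("diameter", [0, 2, 4, 6])
    def test_methane_single_feature(self, diameter):
        """One heavy atom: every radius collapses onto the lone atom."""
        fp = compute_feature_multiset(mol("C"), diameter)
        assert len(fp.features) == 1
        assert fp.total_count == 1

    def test_benzene_symmetry(self):
        """All six atoms are equivalent; at diameter 6 the radius-3
        environments all cover the whole ring and collapse to one."""
        fp = compute_feature_multiset(mol("c1ccccc1"), 6)
        assert sorted(fp.features.values()) == [1, 6, 6, 6]
        oracle = enumerate_environment_classes(mol("c1ccccc1"), 6)
        assert sorted(oracle.values()) == sorted(fp.features.values())

    def test_smiles_form_invariance(self):
        a = compute_feature_multiset(standardize_molecule("OCC"), 6)
        b = compute_feature_multiset(standardize_molecule("CCO"), 6)
        assert a == b

    @pytest.mark.parametrize("smiles", CORPUS)
    @pytest.mark.parametrize("diameter", [2, 4, 6])
    def test_counts_match_structural_enumeration(self, smiles, diameter):
        """The hashed multiset induces the same class sizes as a
        structural enumeration of the circular environments."""
        fp = compute_feature_multiset(mol(smiles), diameter)
        oracle = enumerate_environment_classes(mol(smiles), diameter)
        assert sorted(fp.features.values()) == sorted(oracle.values())
        assert fp.total_count == sum(oracle.values())

    def test_total_count_bound(self):
        for smiles in CORPUS:
            m = mol(smiles)
            fp = compute_feature_multiset(m, 6)
            assert fp.total_count <= m.GetNumHeavyAtoms() * 4

    @pytest.mark.parametrize("diameter", [-2, 1, 3, 10])
    def test_invalid_diameter_rejected(self, diameter):
        with pytest.raises(ValueError):
            compute_feature_multiset(mol("CC"), diameter)

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            FeatureMultiset(features={1: 0}, diameter=2)


class TestDifferenceFingerprint:
    def test_identity_is_empty(self):
        fp = compute_feature_multiset(mol("CCO"), 6)
        key = difference_fingerprint(fp, fp)
        assert key.is_empty
        assert key_string(key) == "removed:{}|added:{}"

    @pytest.mark.parametrize("a,b", [("CC", "CCO"), ("c1ccccc1", "Cc1ccccc1")])
    def test_antisymmetry(self, a, b):
        fa, fb = (compute_feature_multiset(mol(s), 6) for s in (a, b))
        fwd, rev = difference_fingerprint(fa, fb), difference_fingerprint(fb, fa)
        assert fwd.removed == rev.added and fwd.added == rev.removed
        assert reverse_key(fwd) == rev

    def test_ethane_to_ethanol_counts(self):
        """Count deltas match the independent structural enumeration."""
        fa = compute_feature_multiset(mol("CC"), 2)
        fb = compute_feature_multiset(mol("CCO"), 2)
        key = difference_fingerprint(fa, fb)
        removed_o, added_o = environment_class_difference(mol("CC"), mol("CCO"), 2)
        assert sorted(c for _, c in key.removed) == sorted(removed_o.values())
        assert sorted(c for _, c in key.added) == sorted(added_o.values())
        # the unchanged methyl radius-0 carbon partially cancels: one of
        # two equivalent carbons remains shared
        assert sum(c for _, c in key.removed) == 2
        assert sum(c for _, c in key.added) == 5

    def test_mismatched_diameters_rejected(self):
        fa = compute_feature_multiset(mol("CC"), 2)
        fb = compute_feature_multiset(mol("CCO"), 4)
        with pytest.raises(ValueError, match="diameter"):
            difference_fingerprint(fa, fb)

    @given(st.integers(0, len(CORPUS) - 1), st.integers(0, len(CORPUS) - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_common_features_always_cancel(self, i, j):
        """No feature id appears on both sides of a key, and features
        with equal counts in both molecules never appear at all."""
        fa = compute_feature_multiset(mol(CORPUS[i]), 4)
        fb = compute_feature_multiset(mol(CORPUS[j]), 4)
        key = difference_fingerprint(fa, fb)
        removed_ids = {f for f, _ in key.removed}
        added_ids = {f for f, _ in key.added}
        assert not removed_ids & added_ids
        for fid, count in fa.features.items():
            if fb.features.get(fid) == count:
                assert fid not in removed_ids and fid not in added_ids


class TestOrientation:
    def _key(self):
        fa = compute_feature_multiset(mol("CC"), 6)
        fb = compute_feature_multiset(mol("CCO"), 6)
        return difference_fingerprint(fa, fb)

    def test_negative_mean_keeps_orientation(self):
        key = self._key()
        oriented, direction = canonical_orientation(key, -0.5)
        assert oriented == key and direction == +1

    def test_positive_mean_flips(self):
        key = self._key()
        oriented, direction = canonical_orientation(key, +0.5)
        assert oriented == reverse_key(key) and direction == -1

    def test_zero_mean_tie_is_deterministic(self):
        key = self._key()
        oriented, _ = canonical_orientation(key, 0.0)
        again, _ = canonical_orientation(reverse_key(key), 0.0)
        assert oriented == again  # same winner from either starting orientation
        assert key_string(oriented) <= key_string(reverse_key(oriented))

    def test_empty_key_rejected(self):
        empty = TransformationKey(removed=(), added=(), diameter=6)
        with pytest.raises(ValueError, match="empty"):
            canonical_orientation(empty, -1.0)


class TestKeyString:
    def test_equal_keys_equal_strings_and_distinct_keys_distinct(self):
        strings = {}
        for a in CORPUS:
            for b in CORPUS:
                fa = compute_feature_multiset(mol(a), 4)
                fb = compute_feature_multiset(mol(b), 4)
                key = difference_fingerprint(fa, fb)
                s = key_string(key)
                assert strings.setdefault(s, key) == key  # no collisions
        assert len(strings) > len(CORPUS)  # plenty of distinct keys scanned

    def test_order_independent(self):
        key = TransformationKey(removed=((2, 1), (1, 3)), added=((5, 2),), diameter=6)
        same = TransformationKey(removed=((1, 3), (2, 1)), added=((5, 2),), diameter=6)
        assert key == same
        assert key_string(key) == key_string(same)

    def test_shared_ids_rejected(self):
        with pytest.raises(ValueError, match="share"):
            TransformationKey(removed=((1, 1),), added=((1, 2),), diameter=6)


def test_environment_legend_covers_all_features():
    m = mol("CCN(C)CCc1ccc(F)cc1")
    fp = compute_feature_multiset(m, 6)
    legend = feature_environments(m, 6)
    assert set(legend) == set(fp.features)
    assert all(isinstance(s, str) and s for s in legend.values())
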