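"""Circular-fingerprint feature multisets and difference fingerprints.

A molecule is represented as a multiset of hashed circular atom
environments (ECFP-style Morgan features with counts, not folded to a
bitvector). A chemical transformation between two molecules is the
"difference fingerprint": the multiset of features that disappear from
the initial molecule together with the multiset that appear in the
final one. Features present in both with equal counts cancel, so the
key captures the changed substructures plus their nearby context.

Two compound pairs belong to the same transformation if and only if
their difference fingerprints are equal — that equality is the
aggregation relation used downstream.

Feature hashes come from the toolkit's Morgan algorithm; they are
stable within a run and across runs of the same toolkit version, but
they are opaque, so :func:`feature_environments` provides a
human-readable SMILES legend per feature id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "DEFAULT_DIAMETER",
    "FeatureMultiset",
    "TransformationKey",
    "compute_feature_multiset",
    "feature_environments",
    "difference_fingerprint",
    "reverse_key",
    "canonical_orientation",
    "key_string",
]

#: Default maximum environment diameter (bonds). Diameter 6 (radius 3)
#: is tight enough that aggregated pairs share the same chemical change;
#: diameters 0 and 2 conflate chemically different transformations
#: (diameter 0 is equivalent to the molecular formula).
DEFAULT_DIAMETER = 6

_VALID_DIAMETERS = (0, 2, 4, 6, 8)


def _check_diameter(diameter: int) -> None:
    if diameter not in _VALID_DIAMETERS:
        raise ValueError(f"diameter must be one of {_VALID_DIAMETERS}, got {diameter}")


@dataclass(frozen=True)
class FeatureMultiset:
    """Counted circular-fingerprint features of one molecule.

    ``features`` maps the integer feature hash of each distinct atom
    environment (all radii up to ``diameter/2``) to its occurrence
    count in the molecule.
    """

    features: Mapping[int, int]
    diameter: int

    def __post_init__(self) -> None:
        _check_diameter(self.diameter)
        if any(c < 1 for c in self.features.values()):
            raise ValueError("feature counts must be >= 1")

    @property
    def total_count(self) -> int:
        return sum(self.features.values())

    def counter(self) -> Counter[int]:
        return Counter(self.features)


@dataclass(frozen=True)
class TransformationKey:
    """The (removed, added) feature-count deltas defining a transformation.

    ``removed`` and ``added`` are sorted ``(feature_id, count)`` tuples
    and never share a feature id: common features cancel in the
    difference. The key of a molecule with itself is empty.
    """

    removed: tuple[tuple[int, int], ...]
    added: tuple[tuple[int, int], ...]
    diameter: int

    def __post_init__(self) -> None:
        _check_diameter(self.diameter)
        # normalize ordering so keys built in any order compare equal
        object.__setattr__(self, "removed", tuple(sorted(self.removed)))
        object.__setattr__(self, "added", tuple(sorted(self.added)))
        shared = {f for f, _ in self.removed} & {f for f, _ in self.added}
        if shared:
            raise ValueError(f"removed and added share feature ids {sorted(shared)}")

    @property
    def is_empty(self) -> bool:
        return not self.removed and not self.added

    @property
    def n_changed_features(self) -> int:
        """Total count of removed plus added feature occurrences."""
        return sum(c for _, c in self.removed) + sum(c for _, c in self.added)


def compute_feature_multiset(
    mol: Chem.Mol, diameter: int = DEFAULT_DIAMETER, use_chirality: bool = False
) -> FeatureMultiset:
    """Morgan/circular feature counts for all radii up to ``diameter/2``.

    Environments that stop growing (their bond set repeats an earlier
    radius) or coincide with another atom's environment at the same
    radius contribute once, following the standard Morgan duplicate
    removal; identical molecules give identical multisets regardless of
    the input SMILES form.
    """
    _check_diameter(diameter)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=diameter // 2, includeChirality=use_chirality
    )
    sfp = gen.GetSparseCountFingerprint(mol)
    return FeatureMultiset(features=dict(sfp.GetNonzeroElements()), diameter=diameter)


def feature_environments(
    mol: Chem.Mol, diameter: int = DEFAULT_DIAMETER, use_chirality: bool = False
) -> dict[int, str]:
    """Map each feature id to a canonical SMILES of one of its environments.

    Radius-0 features map to the bare atom; larger radii to the rooted
    substructure SMILES. Used for the human-readable report legend.
    """
    _check_diameter(diameter)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=diameter // 2, includeChirality=use_chirality
    )
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    legend: dict[int, str] = {}
    for bit, occurrences in ao.GetBitInfoMap().items():
        atom_idx, radius = occurrences[0]
        if radius == 0:
            legend[bit] = Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx])
            continue
        env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx)
        atoms = {atom_idx}
        for bond_idx in env:
            bond = mol.GetBondWithIdx(bond_idx)
            atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        legend[bit] = Chem.MolFragmentToSmiles(
            mol, atomsToUse=sorted(atoms), bondsToUse=list(env), rootedAtAtom=atom_idx
        )
    return legend


def _sorted_items(counter: Counter[int]) -> tuple[tuple[int, int], ...]:
    return tuple(sorted(counter.items()))


def difference_fingerprint(
    initial: FeatureMultiset, final: FeatureMultiset
) -> TransformationKey:
    """Per-feature count deltas between two molecules' multisets.

    ``removed`` holds counts lost going initial→final, ``added`` counts
    gained; a feature with equal counts in both is absent from the key.
    """
    if initial.diameter != final.diameter:
        raise ValueError(
            f"diameter mismatch: {initial.diameter} vs {final.diameter}"
        )
    ci, cf = initial.counter(), final.counter()
    return TransformationKey(
        removed=_sorted_items(ci - cf),
        added=_sorted_items(cf - ci),
        diameter=initial.diameter,
    )


def reverse_key(key: TransformationKey) -> TransformationKey:
    """The same transformation run in the opposite direction."""
    return TransformationKey(removed=key.added, added=key.removed, diameter=key.diameter)


def canonical_orientation(
    key: TransformationKey, mean_delta: float
) -> tuple[TransformationKey, int]:
    """Orient a key so its aggregate's mean Δlog10 IC50 is ≤ 0.

    Every transformation occurs in both directions (each unordered pair
    is counted once per direction), so aggregates come in mirror pairs;
    reporting uses the inhibition-reducing direction. Returns the
    oriented key and +1 if the input orientation was kept, −1 if it was
    flipped. A mean of exactly 0 is broken by lexicographic order of
    the serialized key, which is deterministic across runs.
    """
    if key.is_empty:
        raise ValueError("empty transformation key has no orientation")
    if mean_delta < 0:
        return key, +1
    if mean_delta > 0:
        return reverse_key(key), -1
    rev = reverse_key(key)
    return (key, +1) if key_string(key) <= key_string(rev) else (rev, -1)


def _part_string(part: tuple[tuple[int, int], ...]) -> str:
    return "{" + ",".join(f"{fid}x{count}" for fid, count in part) + "}"


def key_string(key: TransformationKey) -> str:
    """Stable sortable serialization; equal keys ⇔ equal strings."""
    return f"removed:{_part_string(key.removed)}|added:{_part_string(key.added)}"
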