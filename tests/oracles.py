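"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they validate: environments
are enumerated structurally (canonical substructure SMILES instead of
Morgan hashes), and the signed-rank null is built by explicit
enumeration of all 2^n sign assignments.
"""

from __future__ import annotations

from collections import Counter
from itertools import product

from rdkit import Chem


def atom_invariant(atom) -> tuple:
    """The connectivity invariant a circular fingerprint starts from."""
    return (
        atom.GetAtomicNum(),
        atom.GetDegree(),
        atom.GetTotalNumHs(),
        atom.GetFormalCharge(),
        atom.GetIsotope(),
        int(atom.IsInRing()),
    )


def enumerate_environment_classes(mol: Chem.Mol, diameter: int) -> Counter:
    """Structurally keyed circular-environment counts for one molecule.

    Keys are (radius, canonical submol SMILES with the center marked
    and parent atom invariants encoded as atom maps); radius-0 keys are
    the bare atom invariants. Duplicate bond sets contribute once, and
    an environment that stops growing is not recounted at larger radii
    — mirroring Morgan duplicate removal without using its hashes.
    """
    counts: Counter = Counter()
    inv_class: dict[tuple, int] = {}
    for atom in mol.GetAtoms():
        inv = atom_invariant(atom)
        inv_class.setdefault(inv, len(inv_class) + 1)
        counts[(0, inv)] += 1
    seen_bond_sets: set = set()
    for radius in range(1, diameter // 2 + 1):
        for atom in mol.GetAtoms():
            env = tuple(sorted(Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom.GetIdx())))
            if not env:
                continue
            if radius > 1 and env == tuple(
                sorted(Chem.FindAtomEnvironmentOfRadiusN(mol, radius - 1, atom.GetIdx()))
            ):
                continue  # environment stopped growing
            if env in seen_bond_sets:
                continue  # same substructure already counted
            seen_bond_sets.add(env)
            amap: dict[int, int] = {}
            sub = Chem.PathToSubmol(mol, list(env), atomMap=amap)
            for parent_idx, sub_idx in amap.items():
                a = sub.GetAtomWithIdx(sub_idx)
                a.SetAtomMapNum(inv_class[atom_invariant(mol.GetAtomWithIdx(parent_idx))])
                if parent_idx == atom.GetIdx():
                    a.SetIsotope(99)  # mark the center atom
            counts[(radius, Chem.MolToSmiles(sub))] += 1
    return counts


def environment_class_difference(
    mol_a: Chem.Mol, mol_b: Chem.Mol, diameter: int
) -> tuple[Counter, Counter]:
    """(removed, added) structural-class count deltas going a → b."""
    ca = enumerate_environment_classes(mol_a, diameter)
    cb = enumerate_environment_classes(mol_b, diameter)
    return ca - cb, cb - ca


def signed_rank_distribution(ranks) -> Counter:
    """Null distribution of the positive-rank sum over all 2^n assignments."""
    dist: Counter = Counter()
    for signs in product((0, 1), repeat=len(ranks)):
        dist[sum(r for r, s in zip(ranks, signs) if s)] += 1
    return dist


def signed_rank_p_brute(deltas, sided: str = "two") -> float:
    """Exact signed-rank p-value by full 2^n enumeration (average ranks)."""
    from scipy.stats import rankdata

    d = list(deltas)
    ranks = rankdata([abs(x) for x in d])
    w_plus = sum(r for r, x in zip(ranks, d) if x > 0)
    w_minus = sum(r for r, x in zip(ranks, d) if x < 0)
    w_min = min(w_plus, w_minus)
    dist = signed_rank_distribution(list(ranks))
    tail = sum(c for w, c in dist.items() if w <= w_min + 1e-9) / 2 ** len(d)
    return tail if sided == "one" else min(1.0, 2.0 * tail)


def sign_test_p_brute(n_increase: int, n_decrease: int, sided: str = "two") -> float:
    """Exact sign-test p-value by enumerating all 2^n direction patterns."""
    n = n_increase + n_decrease
    k = min(n_increase, n_decrease)
    tail_hits = sum(1 for signs in product((0, 1), repeat=n) if sum(signs) <= k)
    one = tail_hits / 2**n
    return one if sided == "one" else min(1.0, 2.0 * one)
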