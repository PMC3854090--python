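"""Wildman–Crippen atom-contribution logP ("SlogP") and pair deltas.

SlogP estimates the octanol–water partition coefficient as a sum of
per-atom contributions determined by SMARTS atom typing. Because the
contribution of an atom depends only on its local type, every pair in
an aggregated transformation shares the same ΔSlogP — a property the
aggregation step asserts on congeneric data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import Crippen
from rdkit.Chem.rdMolDescriptors import _CalcCrippenContribs

log = logging.getLogger(__name__)

__all__ = ["SlogPValue", "slogp", "delta_slogp"]


@dataclass(frozen=True)
class SlogPValue:
    """A logP estimate with its per-atom decomposition.

    ``per_atom`` lists ``(atom_index, contribution)`` over the molecule
    with explicit hydrogens (hydrogen contributions are part of the
    model); ``value`` is their sum.
    """

    value: float
    per_atom: tuple[tuple[int, float], ...]


def slogp(mol: Chem.Mol) -> SlogPValue:
    """Wildman–Crippen logP of a standardized molecule.

    Atoms no published type matches fall back to the scheme's wildcard
    contribution (the toolkit handles this internally); deterministic
    for a given molecule.
    """
    molh = Chem.AddHs(mol)
    contribs = _CalcCrippenContribs(molh)
    per_atom = tuple((i, c[0]) for i, c in enumerate(contribs))
    value = Crippen.MolLogP(mol)
    total = sum(c for _, c in per_atom)
    if abs(total - value) > 1e-9:  # pragma: no cover - would indicate a typing bug
        log.warning("SlogP per-atom sum %.12f != total %.12f", total, value)
    return SlogPValue(value=value, per_atom=per_atom)


def delta_slogp(initial: Chem.Mol, final: Chem.Mol) -> float:
    """SlogP(final) − SlogP(initial); antisymmetric under reversal."""
    return slogp(final).value - slogp(initial).value
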