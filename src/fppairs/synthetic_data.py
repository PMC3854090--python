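"""Synthetic congeneric-series activity tables with planted effects.

Real structure–activity archives of hERG dofetilide-displacement IC50s
are proprietary, so every pipeline stage is exercised on generated
data instead: a set of scaffolds, each carrying one attachment point,
is combined with a panel of substituents. The log10 IC50 of a
scaffold–substituent molecule is

    base + scaffold offset + substituent effect + Normal(0, noise_sd)

so that swapping substituent a for b on any scaffold plants an
additive shift of ``effect[b] − effect[a]`` log units, the quantity
the analysis should recover. Values above the assay ceiling are
emitted as censored strings (``">30"``), exercising the clamping and
exclusion rules downstream.

Scaffolds share a common stalk of at least six bonds around the
attachment point, so at fingerprint diameter ≤ 6 the same substituent
swap produces the identical difference fingerprint on every scaffold
and the planted pairs aggregate together — emulating a congeneric
lead-optimization series. Distal scaffold decorations differ, keeping
the molecules distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "SyntheticSpec",
    "default_spec",
    "attach",
    "generate_dataset",
    "write_dataset",
    "load_spec",
    "recovery_report",
]

# ten scaffolds: a phenethyl-amine stalk ending in the attachment
# point, with varying distal aryl decoration >6 bonds away
_DEFAULT_SCAFFOLDS = [
    "c1ccc(CCN(C)CC[*:1])cc1",
    "Cc1ccc(CCN(C)CC[*:1])cc1",
    "CCc1ccc(CCN(C)CC[*:1])cc1",
    "COc1ccc(CCN(C)CC[*:1])cc1",
    "Fc1ccc(CCN(C)CC[*:1])cc1",
    "Clc1ccc(CCN(C)CC[*:1])cc1",
    "Brc1ccc(CCN(C)CC[*:1])cc1",
    "N#Cc1ccc(CCN(C)CC[*:1])cc1",
    "FC(F)(F)c1ccc(CCN(C)CC[*:1])cc1",
    "Cc1cc(CCN(C)CC[*:1])ccc1C",
]

# six substituents spanning H, alkyl, polar and heteroaromatic groups
_DEFAULT_SUBSTITUENTS = {
    "H": "[H][*:1]",
    "Me": "C[*:1]",
    "Et": "CC[*:1]",
    "OH": "O[*:1]",
    "OMe": "CO[*:1]",
    "Imid": "c1nccn1[*:1]",
}

# per-substituent additive shifts on log10 IC50 (μM); a swap a→b plants
# effect[b] − effect[a]. Polar groups raise IC50 (reduce inhibition) by
# a few-fold, the magnitude typical of consistent hERG-reducing
# transformations; alkyl growth lowers it slightly.
_DEFAULT_EFFECTS = {
    "H": 0.0,
    "Me": -0.1,
    "Et": -0.2,
    "OH": 0.7,
    "OMe": 0.5,
    "Imid": 0.4,
}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic congeneric dataset.

    ``substituent_effects`` are additive log10-IC50 shifts per
    substituent; the planted effect of any swap is their difference
    (see :meth:`planted_effects`), which keeps all swap effects
    mutually consistent. ``scaffold_offset_sd`` spreads baseline
    potency across series; ``noise_sd`` is per-measurement assay noise,
    both in log10 units.
    """

    scaffolds: Sequence[str] = field(default_factory=lambda: list(_DEFAULT_SCAFFOLDS))
    substituents: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_SUBSTITUENTS)
    )
    substituent_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    base_log_ic50: float = 0.5  # ~3 μM baseline, mid assay range
    scaffold_offset_sd: float = 0.3
    noise_sd: float = 0.2
    upper_limit_um: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.scaffold_offset_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if len(self.scaffolds) < 1 or len(self.substituents) < 2:
            raise ValueError("need >= 1 scaffold and >= 2 substituents")
        missing = set(self.substituents) - set(self.substituent_effects)
        if missing:
            raise ValueError(f"substituents without an effect value: {sorted(missing)}")

    def planted_effects(self) -> dict[tuple[str, str], float]:
        """Planted Δlog10 IC50 for every ordered substituent swap."""
        labels = list(self.substituents)
        return {
            (a, b): self.substituent_effects[b] - self.substituent_effects[a]
            for a in labels
            for b in labels
            if a != b
        }


def default_spec(**overrides) -> SyntheticSpec:
    """The standard 10-scaffold × 6-substituent fixture."""
    return SyntheticSpec(**overrides)


def attach(scaffold_smiles: str, substituent_smiles: str) -> Chem.Mol:
    """Join a scaffold and a substituent at their ``[*:1]`` points."""
    RDLogger.DisableLog("rdApp.warning")  # hydrogen-substituent parse is noisy
    try:
        scaffold = Chem.MolFromSmiles(scaffold_smiles)
        substituent = Chem.MolFromSmiles(substituent_smiles)
        if scaffold is None or substituent is None:
            raise ValueError("unparsable fragment SMILES")
        mol = Chem.molzip(Chem.CombineMols(scaffold, substituent))
        Chem.SanitizeMol(mol)
        mol = Chem.RemoveHs(mol)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(
            f"cannot attach {substituent_smiles!r} to {scaffold_smiles!r}: {exc}"
        ) from None
    finally:
        RDLogger.EnableLog("rdApp.warning")
    return mol


def generate_dataset(spec: SyntheticSpec) -> pd.DataFrame:
    """Enumerate scaffold×substituent molecules with noisy, censored IC50s.

    Returns an activity table with columns ``compound_id``, ``smiles``,
    ``ic50`` (string, μM, ``">limit"`` when censored) plus bookkeeping
    columns ``scaffold_idx`` and ``substituent`` naming the ground
    truth. Fully reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    offsets = rng.normal(0.0, spec.scaffold_offset_sd, size=len(spec.scaffolds))
    rows = []
    for s_idx, scaffold in enumerate(spec.scaffolds):
        for label, frag in spec.substituents.items():
            mol = attach(scaffold, frag)
            log_ic50 = (
                spec.base_log_ic50
                + offsets[s_idx]
                + spec.substituent_effects[label]
                + rng.normal(0.0, spec.noise_sd)
            )
            ic50 = 10.0**log_ic50
            if ic50 > spec.upper_limit_um:
                ic50_str = f">{spec.upper_limit_um:g}"
            else:
                ic50_str = f"{ic50:.10g}"
            rows.append(
                {
                    "compound_id": f"S{s_idx:02d}-{label}",
                    "smiles": Chem.MolToSmiles(mol),
                    "ic50": ic50_str,
                    "scaffold_idx": s_idx,
                    "substituent": label,
                }
            )
    return pd.DataFrame(rows)


def write_dataset(spec: SyntheticSpec, path: str | Path) -> pd.DataFrame:
    """Generate and write the activity CSV consumed by the reader."""
    frame = generate_dataset(spec)
    frame.to_csv(path, index=False)
    return frame


def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(SyntheticSpec.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown spec keys: {sorted(unknown)}")
    return SyntheticSpec(**data)


def recovery_report(
    spec: SyntheticSpec,
    aggregates,
    min_examples: int = 5,
    diameter: int = 6,
) -> dict:
    """Compare recovered aggregates against the planted swap effects.

    For each unordered substituent swap, the expected transformation
    key is computed on the first scaffold; the matching reported
    aggregate (either orientation) is then scored: detected (present
    with ``n >= min_examples``), sign correct, and absolute error of
    the estimated mean Δlog versus the planted shift. Aggregates whose
    keys match no planted swap and still pass the size threshold are
    counted as false positives.
    """
    from .fingerprints import (
        compute_feature_multiset,
        difference_fingerprint,
        key_string,
        reverse_key,
    )

    by_key = {key_string(a.key): a for a in aggregates}
    planted = spec.planted_effects()
    scaffold = spec.scaffolds[0]

    swap_rows = []
    planted_key_strings: set[str] = set()
    seen_unordered: set[frozenset] = set()
    for (a, b), effect in planted.items():
        if frozenset((a, b)) in seen_unordered:
            continue
        seen_unordered.add(frozenset((a, b)))
        fp_a = compute_feature_multiset(attach(scaffold, spec.substituents[a]), diameter)
        fp_b = compute_feature_multiset(attach(scaffold, spec.substituents[b]), diameter)
        key = difference_fingerprint(fp_a, fp_b)
        ks_fwd, ks_rev = key_string(key), key_string(reverse_key(key))
        planted_key_strings.update((ks_fwd, ks_rev))
        agg = by_key.get(ks_fwd)
        sign_flip = 1.0
        if agg is None:
            agg = by_key.get(ks_rev)
            sign_flip = -1.0
        row = {"swap": f"{a}->{b}", "planted_delta": effect}
        if agg is None or agg.n < min_examples:
            row.update(detected=False, sign_correct=None, abs_error=None, n=0 if agg is None else agg.n)
        else:
            estimate = sign_flip * agg.mean_delta_log
            row.update(
                detected=True,
                sign_correct=(effect == 0) or (math.copysign(1, estimate) == math.copysign(1, effect)),
                abs_error=abs(estimate - effect),
                n=agg.n,
            )
        swap_rows.append(row)

    false_positives = sum(
        1
        for ks, agg in by_key.items()
        if ks not in planted_key_strings and agg.n >= min_examples
    )
    detected = [r for r in swap_rows if r["detected"]]
    return {
        "swaps": swap_rows,
        "n_planted": len(swap_rows),
        "n_detected": len(detected),
        "n_sign_correct": sum(1 for r in detected if r["sign_correct"]),
        "false_positives": false_positives,
    }
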