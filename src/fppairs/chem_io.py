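"""Reading and standardizing molecule–activity tables with censored IC50 values.

Activity tables are delimited text files with one row per measurement:
a compound identifier, a SMILES string, and an IC50 that may carry a
censoring qualifier (``">30"`` meaning "beyond the upper assay limit").
The internal concentration unit is μM; nM input is converted on read.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from rdkit import Chem

log = logging.getLogger(__name__)

__all__ = [
    "Qualifier",
    "CensoredValue",
    "ActivityRecord",
    "TableConfig",
    "parse_censored_value",
    "standardize_molecule",
    "read_activity_table",
    "records_from_frame",
    "write_activity_table",
    "load_table_config",
]


class Qualifier(enum.Enum):
    """Censoring status of a concentration measurement."""

    EXACT = "exact"
    ABOVE_LIMIT = "above_limit"
    BELOW_LIMIT = "below_limit"


@dataclass(frozen=True)
class CensoredValue:
    """A possibly censored IC50 in μM.

    ``value_um`` is the numeric value used in analysis: off-scale
    measurements are clamped to the assay limit, so an ``ABOVE_LIMIT``
    value always equals the configured upper limit.
    """

    value_um: float
    qualifier: Qualifier = Qualifier.EXACT

    def __post_init__(self) -> None:
        if not (self.value_um > 0):
            raise ValueError(f"IC50 must be positive, got {self.value_um}")

    @property
    def log10(self) -> float:
        return math.log10(self.value_um)

    def as_string(self) -> str:
        """Serialize back to the table form (``">30"`` etc.), μM scale."""
        prefix = {
            Qualifier.EXACT: "",
            Qualifier.ABOVE_LIMIT: ">",
            Qualifier.BELOW_LIMIT: "<",
        }[self.qualifier]
        return f"{prefix}{self.value_um:.10g}"


@dataclass(frozen=True)
class ActivityRecord:
    """One compound: identifier, standardized structure, censored IC50."""

    compound_id: str
    mol: Chem.Mol
    smiles: str  # canonical SMILES of the standardized structure
    ic50: CensoredValue

    @property
    def log_ic50(self) -> float:
        return self.ic50.log10


_VALUE_RE = re.compile(r"^\s*(?P<qual>[<>])?\s*(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?)\s*$")

_UNIT_FACTORS = {"um": 1.0, "μm": 1.0, "µm": 1.0, "nm": 1e-3}


def parse_censored_value(
    raw: str | float,
    unit: str = "uM",
    upper_limit_um: float = 30.0,
    lower_limit_um: float = 0.0,
) -> CensoredValue:
    """Parse an IC50 cell such as ``"5"``, ``">30"`` or ``"<0.1"``.

    Values are converted to μM. A ``>`` qualifier, or an exact value above
    ``upper_limit_um``, is clamped to the upper limit and marked
    ``ABOVE_LIMIT``. A ``<`` qualifier is clamped up to ``lower_limit_um``
    when that limit is positive; the default of 0 applies no lower clamp.
    """
    key = unit.strip().lower()
    if key not in _UNIT_FACTORS:
        raise ValueError(f"unsupported concentration unit {unit!r} (use uM or nM)")
    factor = _UNIT_FACTORS[key]

    m = _VALUE_RE.match(str(raw))
    if m is None:
        raise ValueError(f"cannot parse IC50 value {raw!r}")
    value = float(m.group("num")) * factor
    if value <= 0:
        raise ValueError(f"IC50 must be positive, got {raw!r}")
    qual = m.group("qual")

    if qual == ">" or value > upper_limit_um:
        return CensoredValue(min(value, upper_limit_um), Qualifier.ABOVE_LIMIT)
    if qual == "<":
        if lower_limit_um > 0:
            value = max(value, lower_limit_um)
        return CensoredValue(value, Qualifier.BELOW_LIMIT)
    return CensoredValue(value, Qualifier.EXACT)


def standardize_molecule(smiles: str) -> Chem.Mol:
    """Parse SMILES and keep the largest covalently bonded fragment.

    Salt/counter-ion stripping keeps the fragment with the most heavy
    atoms (ties broken by canonical SMILES order for determinism).
    Charges are preserved; no tautomer canonicalization is applied.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        raise ValueError(f"invalid SMILES {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return mol


@dataclass
class TableConfig:
    """Column names and unit handling for an activity table."""

    id_col: str = "compound_id"
    smiles_col: str = "smiles"
    ic50_col: str = "ic50"
    unit: str = "uM"  # used when unit_col is None
    unit_col: str | None = None
    upper_limit_um: float = 30.0
    lower_limit_um: float = 0.0
    # how to collapse several measurements of one compound:
    # geometric_mean | first | error
    duplicate_policy: str = "geometric_mean"


def load_table_config(path: str | Path) -> TableConfig:
    """Load a :class:`TableConfig` from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in TableConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TableConfig(**data)


def _collapse_duplicates(
    records: list[ActivityRecord], policy: str, upper_limit_um: float
) -> list[ActivityRecord]:
    by_id: dict[str, list[ActivityRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.compound_id not in by_id:
            order.append(rec.compound_id)
        by_id.setdefault(rec.compound_id, []).append(rec)

    out: list[ActivityRecord] = []
    for cid in order:
        group = by_id[cid]
        if len(group) == 1:
            out.append(group[0])
            continue
        if policy == "error":
            raise ValueError(f"duplicate measurements for compound {cid!r}")
        if policy == "first":
            out.append(group[0])
            continue
        if policy != "geometric_mean":
            raise ValueError(f"unknown duplicate policy {policy!r}")
        mean_log = sum(r.log_ic50 for r in group) / len(group)
        value = 10.0**mean_log
        # the geometric mean of clamped values can itself sit at the limit
        if value >= upper_limit_um or all(
            r.ic50.qualifier is Qualifier.ABOVE_LIMIT for r in group
        ):
            cv = CensoredValue(min(value, upper_limit_um), Qualifier.ABOVE_LIMIT)
        else:
            cv = CensoredValue(value)
        out.append(replace(group[0], ic50=cv))
    return out


def records_from_frame(frame: pd.DataFrame, config: TableConfig) -> list[ActivityRecord]:
    """Build activity records from a DataFrame, skipping invalid rows.

    Rows with unparsable SMILES or IC50 cells are logged and dropped;
    duplicated compound ids are collapsed per ``config.duplicate_policy``.
    Raises if a required column is missing or no valid rows remain.
    """
    required = [config.id_col, config.smiles_col, config.ic50_col]
    if config.unit_col:
        required.append(config.unit_col)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise KeyError(f"missing required column(s) {missing}; have {list(frame.columns)}")

    records: list[ActivityRecord] = []
    n_skipped = 0
    for idx, row in frame.iterrows():
        unit = str(row[config.unit_col]) if config.unit_col else config.unit
        try:
            ic50 = parse_censored_value(
                row[config.ic50_col], unit, config.upper_limit_um, config.lower_limit_um
            )
            mol = standardize_molecule(str(row[config.smiles_col]))
        except ValueError as exc:
            log.warning("skipping row %s (compound %r): %s", idx, row.get(config.id_col), exc)
            n_skipped += 1
            continue
        records.append(
            ActivityRecord(
                compound_id=str(row[config.id_col]),
                mol=mol,
                smiles=Chem.MolToSmiles(mol),
                ic50=ic50,
            )
        )
    if n_skipped:
        log.info("skipped %d invalid row(s) of %d", n_skipped, len(frame))
    if not records:
        raise ValueError("no valid rows in activity table")
    return _collapse_duplicates(records, config.duplicate_policy, config.upper_limit_um)


def read_activity_table(
    path: str | Path, config: TableConfig | None = None
) -> list[ActivityRecord]:
    """Read a CSV/TSV activity table into standardized records."""
    config = config or TableConfig()
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    return records_from_frame(frame, config)


def write_activity_table(
    records: Iterable[ActivityRecord], path: str | Path, config: TableConfig | None = None
) -> None:
    """Write records back to CSV (μM scale, qualifiers re-emitted)."""
    config = config or TableConfig()
    rows = [
        {
            config.id_col: r.compound_id,
            config.smiles_col: r.smiles,
            config.ic50_col: r.ic50.as_string(),
        }
        for r in records
    ]
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
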