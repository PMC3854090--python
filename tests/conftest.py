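import sys
from pathlib import Path

import pytest
from rdkit import Chem

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from fppairs.chem_io import ActivityRecord, CensoredValue, Qualifier, standardize_molecule
from fppairs.synthetic_data import SyntheticSpec, generate_dataset


def make_record(compound_id: str, smiles: str, ic50_um: float,
                qualifier: Qualifier = Qualifier.EXACT) -> ActivityRecord:
    mol = standardize_molecule(smiles)
    return ActivityRecord(
        compound_id=compound_id,
        mol=mol,
        smiles=Chem.MolToSmiles(mol),
        ic50=CensoredValue(ic50_um, qualifier),
    )


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """5 scaffolds × 3 substituents: fast but exercises every stage."""
    return SyntheticSpec(
        scaffolds=[
            "c1ccc(CCN(C)CC[*:1])cc1",
            "Cc1ccc(CCN(C)CC[*:1])cc1",
            "COc1ccc(CCN(C)CC[*:1])cc1",
            "Fc1ccc(CCN(C)CC[*:1])cc1",
            "Clc1ccc(CCN(C)CC[*:1])cc1",
        ],
        substituents={"H": "[H][*:1]", "Me": "C[*:1]", "OH": "O[*:1]"},
        substituent_effects={"H": 0.0, "Me": -0.1, "OH": 0.7},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_frame(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_records(small_frame):
    from fppairs.chem_io import TableConfig, records_from_frame

    return records_from_frame(small_frame, TableConfig())


@pytest.fixture(scope="session")
def small_pairs(small_records):
    from fppairs.pairing import enumerate_pairs

    return enumerate_pairs(small_records)


@pytest.fixture(scope="session")
def small_aggregates(small_pairs):
    from fppairs.stats_aggregation import aggregate_pairs

    return aggregate_pairs(small_pairs)
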