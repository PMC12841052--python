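import logging

import numpy as np
import pytest
from rdkit import RDLogger

from delforge.curation import (BBClass, BuildingBlock, morgan_fp,
                               ro2_profile)

RDLogger.DisableLog("rdApp.*")
logging.getLogger("delforge").setLevel(logging.ERROR)


def make_blocks(smiles_list, bb_class, prefix="bb"):
    """Build BuildingBlock records directly from SMILES (test helper)."""
    return [
        BuildingBlock(
            bb_id=f"{prefix}{i:03d}", smiles=s, bb_class=bb_class,
            ro2=ro2_profile(s), fp=morgan_fp(s))
        for i, s in enumerate(smiles_list)
    ]


@pytest.fixture(scope="session")
def acid_blocks():
    return make_blocks(
        ["CC(=O)O", "CCC(=O)O", "OC(=O)C1CC1", "OC(=O)c1ccccc1"],
        BBClass.CARBOXYLIC_ACID, prefix="ca")


@pytest.fixture(scope="session")
def alkyne_blocks():
    return make_blocks(
        ["C#CC", "C#Cc1ccccc1", "C#CCO", "C#CC1CC1"],
        BBClass.TERMINAL_ALKYNE, prefix="ta")


@pytest.fixture(scope="session")
def methylene_blocks():
    return make_blocks(
        ["CC(=O)CC(=O)OC(C)(C)C", "CC(=O)CC(=O)OCC", "CC(=O)CC#N",
         "O=C(Cc1ccccc1)c1ccccc1"],
        BBClass.ACTIVE_METHYLENE, prefix="am")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
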