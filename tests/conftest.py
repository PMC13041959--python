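"""Shared fixtures: small synthetic study systems and hand-built PDB text."""

import numpy as np
import pytest

from xlstruct import (SyntheticSpec, dedupe_crosslinks, make_structure,
                      map_crosslink, plant_crosslinks)
from xlstruct.synthetic import chain_map_for

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   LYS A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  LYS A   2       3.988   2.839   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA ALYS A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BLYS A   1       0.300   0.000   0.000  0.40  0.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def trimer(spec):
    return make_structure(spec)


@pytest.fixture(scope="session")
def trimer_pdb(tmp_path_factory, trimer):
    from xlstruct import write_pdb
    p = tmp_path_factory.mktemp("models") / "trimer.pdb"
    write_pdb(trimer, p)
    return p


@pytest.fixture(scope="session")
def planted(spec, trimer):
    csms, truth = plant_crosslinks(trimer, spec)
    return csms, truth


@pytest.fixture(scope="session")
def mapped(spec, trimer, planted):
    csms, _ = planted
    uniques = dedupe_crosslinks(csms)
    cmap = chain_map_for(trimer)
    return [map_crosslink(u, cmap, trimer) for u in uniques]


def helix_chain_model(n=30, chain="A", model_id="helix"):
    """Single ideal-helix chain as a StructureModel."""
    return make_structure(SyntheticSpec(
        chains=[(chain, n, 1.0)], inter_chain_offsets={}, seed=0), model_id)
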