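import numpy as np
import pandas as pd
import pytest

from foldability import DomainCatalog

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      5  HA  SER A   3       8.100   0.500   0.000  1.00  0.00           H
HETATM    6  O   HOH A   4      20.000  20.000  20.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.70  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


def make_catalog(families, seed=0):
    """Small hand-specified catalog: families = [(family, smco, age, n_domains)]."""
    rng = np.random.default_rng(seed)
    rows = []
    for fam, smco_val, age, n in families:
        letter = fam.split(".")[0]
        for k in range(n):
            rows.append(
                {
                    "domain_id": f"{fam}_{k}",
                    "sccs": fam,
                    "class_letter": letter,
                    "family": fam,
                    "superfamily": fam.rsplit(".", 1)[0],
                    "length": int(rng.integers(60, 200)),
                    "smco": smco_val,
                    "tightness": np.nan,
                    "age": age,
                }
            )
    return DomainCatalog.from_frame(pd.DataFrame(rows))
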