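import io

import pandas as pd
import pytest

from evostrata import model_io as mio


@pytest.fixture(scope="session")
def tree23():
    return mio.load_default_tree()


def make_tree(newick: str, strata: dict[str, str], focal: str) -> mio.SpeciesTree:
    rows = [
        {"species_code": sp, "stratum_name": name, "is_focal": int(sp == focal)}
        for sp, name in strata.items()
    ]
    return mio.parse_species_tree(newick, pd.DataFrame(rows))


@pytest.fixture(scope="session")
def toy_tree_abc():
    """Three species ((A,B),C) with A focal; C is the basal outgroup."""
    return make_tree(
        "((A,B),C);",
        {"A": "Vertebrata", "B": "Metazoa", "C": "Filozoa"},
        focal="A",
    )


@pytest.fixture(scope="session")
def toy_tree_5sp():
    """Five species ((((A,B),C),D),E), one off-path clade per stratum."""
    return make_tree(
        "((((A,B),C),D),E);",
        {
            "A": "Vertebrata",
            "B": "Deuterostomia",
            "C": "Bilateria",
            "D": "Metazoa",
            "E": "Filozoa",
        },
        focal="A",
    )


@pytest.fixture()
def stratum_table_23():
    pkg = __import__("importlib.resources", fromlist=["files"]).files("evostrata.data")
    return mio.read_stratum_table(io.StringIO((pkg / "phylostrata.tsv").read_text()))
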