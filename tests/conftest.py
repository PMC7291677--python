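"""Shared fixtures: small synthetic corpora generated at test time."""

from __future__ import annotations

import pytest

from pinot.fixtures import FixtureSpec, generate_fixtures, generate_worm_dump
from pinot.idmap import MappingTable, load_mapping_table
from pinot.methods import load_method_table

import pandas as pd


@pytest.fixture(scope="session")
def method_table():
    return load_method_table()


@pytest.fixture(scope="session")
def bundled_mapping():
    return load_mapping_table()


@pytest.fixture(scope="session")
def tiny_mapping():
    """A handful of rows, including one deliberately ambiguous accession."""
    return MappingTable(
        pd.DataFrame(
            {
                "symbol": ["CYCS", "SNCA", "PRKN", "DUPA", "DUPB"],
                "uniprot": ["P99999", "P37840", "O60260", "P88888", "P88888"],
                "entrez": ["54205", "6622", "5071", "900001", "900002"],
            }
        )
    )


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Default synthetic corpus: manifest + on-disk offline layout."""
    out = tmp_path_factory.mktemp("corpus")
    manifest = generate_fixtures(FixtureSpec(random_seed=7), out)
    return {"dir": out, "manifest": manifest}


@pytest.fixture(scope="session")
def worm_dump(tmp_path_factory):
    path = tmp_path_factory.mktemp("worm") / "worm_interactions.tsv"
    manifest = generate_worm_dump(path, n_pairs=10, n_defective=2, random_seed=3)
    return {"path": path, "manifest": manifest}
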