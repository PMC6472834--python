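import pathlib

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import decontax as dx
from decontax.scored_tree import FoldParams, ScoredNode, build_tree, default_mintaxa, fold

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


MINI_NODES = """\
1\t|\t1\t|\tno rank\t|
2\t|\t1\t|\tsuperkingdom\t|
1224\t|\t2\t|\tphylum\t|
1236\t|\t1224\t|\tclass\t|
91347\t|\t1236\t|\torder\t|
543\t|\t91347\t|\tfamily\t|
191675\t|\t543\t|\tno rank\t|
561\t|\t191675\t|\tgenus\t|
562\t|\t561\t|\tspecies\t|
83333\t|\t562\t|\tno rank\t|
620\t|\t543\t|\tgenus\t|
623\t|\t620\t|\tspecies\t|
590\t|\t543\t|\tgenus\t|
28901\t|\t590\t|\tspecies\t|
570\t|\t543\t|\tgenus\t|
573\t|\t570\t|\tspecies\t|
613\t|\t543\t|\tgenus\t|
615\t|\t613\t|\tspecies\t|
"""

MINI_NAMES = """\
1\t|\troot\t|\t\t|\tscientific name\t|
2\t|\tBacteria\t|\t\t|\tscientific name\t|
1224\t|\tProteobacteria\t|\t\t|\tscientific name\t|
1236\t|\tGammaproteobacteria\t|\t\t|\tscientific name\t|
91347\t|\tEnterobacterales\t|\t\t|\tscientific name\t|
543\t|\tEnterobacteriaceae\t|\t\t|\tscientific name\t|
191675\t|\tEscherichia group\t|\t\t|\tscientific name\t|
561\t|\tEscherichia\t|\t\t|\tscientific name\t|
562\t|\tEscherichia coli\t|\t\t|\tscientific name\t|
562\t|\tE. coli\t|\t\t|\tsynonym\t|
83333\t|\tEscherichia coli K-12\t|\t\t|\tscientific name\t|
620\t|\tShigella\t|\t\t|\tscientific name\t|
623\t|\tShigella flexneri\t|\t\t|\tscientific name\t|
590\t|\tSalmonella\t|\t\t|\tscientific name\t|
28901\t|\tSalmonella enterica\t|\t\t|\tscientific name\t|
570\t|\tKlebsiella\t|\t\t|\tscientific name\t|
573\t|\tKlebsiella pneumoniae\t|\t\t|\tscientific name\t|
613\t|\tSerratia\t|\t\t|\tscientific name\t|
615\t|\tSerratia marcescens\t|\t\t|\tscientific name\t|
"""

MINI_MERGED = "666\t|\t562\t|\n"


@pytest.fixture(scope="session")
def mini_taxdump(tmp_path_factory) -> pathlib.Path:
    path = tmp_path_factory.mktemp("taxdump")
    (path / "nodes.dmp").write_text(MINI_NODES)
    (path / "names.dmp").write_text(MINI_NAMES)
    (path / "merged.dmp").write_text(MINI_MERGED)
    return path


@pytest.fixture(scope="session")
def mini_tax(mini_taxdump) -> dx.Taxonomy:
    return dx.load_taxdump(mini_taxdump / "nodes.dmp", mini_taxdump / "names.dmp",
                           mini_taxdump / "merged.dmp")


@pytest.fixture(scope="session")
def ranks():
    return dx.DEFAULT_RANKS


def fig1_tree(ranks) -> ScoredNode:
    """Family F1 (2 reads @ 100) over genus G1 with three species leaves
    (4 @ 60, 2 @ 35, 2 @ 45)."""
    g1 = ScoredNode(10, ranks["genus"], 0, 0.0, [
        ScoredNode(101, ranks["species"], 4, 60.0),
        ScoredNode(102, ranks["species"], 2, 35.0),
        ScoredNode(103, ranks["species"], 2, 45.0),
    ])
    return ScoredNode(5, ranks["family"], 2, 100.0, [g1])


@pytest.fixture
def fig1(ranks) -> ScoredNode:
    return fig1_tree(ranks)


# ---------------------------------------------------------------- mock data

@pytest.fixture(scope="session")
def mock_tax() -> dx.Taxonomy:
    return dx.mock_taxonomy()


@pytest.fixture(scope="session")
def mock_design() -> dx.MockDesign:
    return dx.default_design(seed=7)


@pytest.fixture(scope="session")
def mock_paths(tmp_path_factory, mock_tax, mock_design):
    out = tmp_path_factory.mktemp("mock")
    paths = dx.generate(mock_design, out, mock_tax, seed=7)
    taxdump = out / "taxdump"
    taxdump.mkdir()
    dx.write_taxdump(mock_tax, taxdump / "nodes.dmp", taxdump / "names.dmp")
    paths["taxdump"] = taxdump
    paths["dir"] = out
    return paths


@pytest.fixture(scope="session")
def mock_truth(mock_paths) -> pd.DataFrame:
    return pd.read_csv(mock_paths["truth"], sep="\t", index_col="taxid")


@pytest.fixture(scope="session")
def mock_profiles(mock_paths, mock_tax, mock_design):
    return {
        sample: dx.parse_sample(mock_paths[sample], dx.Format.CENTRIFUGE,
                                mock_tax,
                                is_control=sample in mock_design.control_samples)
        for sample in mock_design.samples
    }


@pytest.fixture(scope="session")
def species_rank(mock_tax):
    return mock_tax.rank_order["species"]


@pytest.fixture(scope="session")
def mock_folded(mock_profiles, mock_tax, species_rank):
    return {
        name: fold(build_tree(profile, mock_tax),
                   FoldParams(rank_floor=species_rank,
                              mintaxa=default_mintaxa(profile.n_passing)))
        for name, profile in mock_profiles.items()
    }


@pytest.fixture(scope="session")
def mock_decontam(mock_folded, mock_design, species_rank):
    ctrl, report = dx.subtract_controls(mock_folded, mock_design.n_controls,
                                        species_rank, dx.DecontamParams())
    return ctrl, report
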