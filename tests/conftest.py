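import io

import numpy as np
import pandas as pd
import pytest
import skbio

from microbiome_cc import Lineage, TaxonTable, simulate_dataset, SimulationConfig

OTU_TSV = """\
# Constructed from a rarefied table
#OTU ID\tS1\tS2\tS3\ttaxonomy
OTU1\t5000\t2500\t100\tk__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Roseburia;s__
OTU2\t5000\t2500\t200\tk__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__;s__
OTU3\t0\t2500\t300\tk__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella;s__copri
OTU4\t0\t2500\t9400\tk__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pasteurellales;f__Pasteurellaceae;g__Haemophilus;s__influenzae
"""


@pytest.fixture
def otu_tsv(tmp_path):
    path = tmp_path / "otu.tsv"
    path.write_text(OTU_TSV)
    return path


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        [[5000, 5000, 0, 0], [2500, 2500, 2500, 2500], [100, 200, 300, 9400]],
        index=["S1", "S2", "S3"],
        columns=["OTU1", "OTU2", "OTU3", "OTU4"],
    )
    lineages = {
        "OTU1": Lineage.parse("k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Roseburia;s__"),
        "OTU2": Lineage.parse("k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__;s__"),
        "OTU3": Lineage.parse("k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella;s__copri"),
        "OTU4": Lineage.parse("k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pasteurellales;f__Pasteurellaceae;g__Haemophilus;s__influenzae"),
    }
    return TaxonTable(data, lineages, mode="counts")


@pytest.fixture
def toy_metadata():
    """Ten clean fecal samples with full covariates."""
    n = 10
    return pd.DataFrame(
        {
            "AGE": [30, 40, 50, 25, 60, 35, 45, 55, 28, 33],
            "SEX": ["male", "female"] * 5,
            "RACE": ["Caucasian"] * 10,
            "BMI": [24.0] * 10,
            "BODY_SITE": ["UBERON:feces"] * 10,
            "ANTIBIOTIC_SELECT": ["None in past year"] * 10,
            "DIABETES": ["no"] * 10,
            "IBD": ["no"] * 10,
            "CSECTION": ["yes", "no"] * 5,
            "APPENDIX_REMOVED": ["no"] * 10,
            "HOST_SUBJECT_ID": [f"P{i}" for i in range(n)],
        },
        index=[f"S{i}" for i in range(n)],
    )


@pytest.fixture
def ultrametric_tree():
    """Four-leaf ultrametric tree with unit branches everywhere."""
    return skbio.TreeNode.read(io.StringIO("((a:1,b:1):1,(c:1,d:1):1);"))


@pytest.fixture(scope="session")
def null_dataset():
    return simulate_dataset(SimulationConfig(n_cases=20, n_controls=20, n_taxa=50, seed=11))


def random_compositions(rng, n, k, alpha=0.5):
    return rng.dirichlet(np.full(k, alpha), size=n)
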