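import numpy as np
import pandas as pd
import pytest

from phyloexpr import (
    SampleMetadata,
    balanced_species_tree,
    label_species_branches,
    read_newick,
)


@pytest.fixture(scope="session")
def st7():
    """Seven-species ladder species tree, root age 1, branches labeled A-L."""
    return balanced_species_tree(7)


@pytest.fixture(scope="session")
def st4():
    """Four-species species tree (((A,B),C),D), root age 1."""
    st = read_newick(
        "(((A:0.25,B:0.25):0.25,C:0.5):0.5,D:1.0);", kind="species", is_path=False
    )
    return label_species_branches(st)


@pytest.fixture
def gene_tree():
    """Builder for gene trees from inline newick (tips 'species@gene')."""

    def build(newick, **kwargs):
        return read_newick(newick, kind="gene", is_path=False, **kwargs)

    return build


def congruent_newick(st, gene_index=1, separator="@"):
    """Single-copy gene tree newick congruent with a species tree, with
    branch lengths equal to the species-tree time lengths."""

    def rec(node):
        if node.is_leaf:
            return f"{node.name}{separator}g{gene_index}:{node.length:.10f}"
        inner = ",".join(rec(c) for c in node.children)
        if node.is_root:
            return f"({inner})"
        return f"({inner}):{node.length:.10f}"

    return rec(st.root) + ";"


@pytest.fixture
def congruent_gt(st7):
    return read_newick(congruent_newick(st7), kind="gene", is_path=False,
                       tree_id="congruent")


def make_metadata(species, tissues, n_replicates):
    rows = []
    for sp in species:
        for tis in tissues:
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "library": f"{sp}_{tis}_r{rep}",
                        "species": sp,
                        "tissue": tis,
                        "stage": "mature",
                        "replicate": rep,
                    }
                )
    return SampleMetadata(pd.DataFrame(rows).set_index("library"))
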