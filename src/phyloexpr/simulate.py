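"""Synthetic data generation: BM traits on trees, duplication-loss gene
trees inside a species tree, counting-efficiency factors, and multinomial
read counts.

These generators define the study conditions for the whole test surface:
log-expression evolves by Brownian motion along gene trees, expected read
counts couple true expression to an unknown per-(gene, species) counting
efficiency, and sequencing is multinomial per library (exact library-size
conservation).  Every generator is reproducible under a seed and returns
its full latent history (true node values, true events) so tests can use
the truth as an oracle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .norm import CountMatrix, SampleMetadata
from .trees import (
    GeneTree,
    Node,
    SpeciesTree,
    Tree,
    label_species_branches,
    read_newick,
)

logger = logging.getLogger(__name__)


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Brownian motion
# ---------------------------------------------------------------------------

def simulate_bm(
    tree: Tree,
    root_value: float,
    sigma2: float,
    seed: Union[int, np.random.Generator, None] = None,
) -> dict[int, float]:
    """Simulate a BM trait along a tree; returns node-id -> value for every
    node (tips and internals), root included.

    Increments along a branch of length t are Normal(0, sigma2 * t); with
    sigma2 = 0 every node equals the root value.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = _rng(seed)
    values: dict[int, float] = {}
    for node in tree.preorder():
        if node.is_root:
            values[node.id] = float(root_value)
        else:
            t = max(node.length or 0.0, 0.0)
            values[node.id] = values[node.parent.id] + rng.normal(
                0.0, math.sqrt(sigma2 * t)
            )
    return values


def empirical_bm_params(tree: Tree, tip_values: Mapping[str, float]) -> tuple[float, float]:
    """Moment-matched BM parameters from observed tip values.

    root value = mean of tip values; sigma2 = sample variance (n-1) of tip
    values divided by the mean root-to-tip path length.  A convention for
    seeding simulations from data, not an ML fit.
    """
    tips = [leaf for leaf in tree.leaves() if leaf.name in tip_values]
    if len(tips) < 2:
        raise ValueError("need at least 2 valued tips")
    vals = np.array([tip_values[t.name] for t in tips], dtype=float)
    depths = np.array([t.depth() for t in tips], dtype=float)
    mean_depth = depths.mean()
    if mean_depth <= 0:
        raise ValueError("zero mean tip depth")
    return float(vals.mean()), float(vals.var(ddof=1) / mean_depth)


# ---------------------------------------------------------------------------
# duplication-loss gene trees
# ---------------------------------------------------------------------------

def simulate_gene_tree(
    st: SpeciesTree,
    dup_rate: float,
    loss_rate: float,
    seed: Union[int, np.random.Generator, None] = None,
    subst_gamma_shape: Optional[float] = 3.0,
    separator: str = "@",
    tree_id: str = "",
) -> Optional[GeneTree]:
    """One gene tree evolved by a birth-death process inside the species tree.

    A single gene lineage enters at the species-tree root; along each
    species-tree branch it duplicates at ``dup_rate`` and dies at
    ``loss_rate`` (per unit time, species root age = 1); at each species
    split every surviving lineage speciates into both daughters.  Lost
    subtrees are pruned and unary nodes suppressed.

    Each surviving node's true history is kept in ``node.extra``:
    ``true_event`` (speciation/duplication), ``true_species_node`` (id in
    ``st``) for speciations, and ``true_species_branch`` (letter label of
    the species branch the *branch above the node* runs in, when labeled).
    Tips are named ``species<sep>g<k>``.  Returns None if every lineage
    dies.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = _rng(seed)
    counter = {"tip": 0}
    prefix = f"{tree_id}." if tree_id else ""
    total_rate = dup_rate + loss_rate

    def evolve(snode: Node, t_top: float) -> Optional[Node]:
        """Evolve one lineage from age t_top down to species node ``snode``
        (age snode.age), then across it.  Returns the subtree root whose
        .length is the *time* from t_top to the node, or None if lost."""
        t = t_top
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            if t - wait <= snode.age:
                break
            t -= wait
            if rng.random() < (dup_rate / total_rate):
                left = evolve(snode, t)
                right = evolve(snode, t)
                if left is None and right is None:
                    return None
                if left is None or right is None:
                    survivor = left or right
                    survivor.length += t_top - t
                    return survivor
                node = Node()
                node.extra["true_event"] = "duplication"
                node.extra["age"] = t
                node.length = t_top - t
                node.add_child(left)
                node.add_child(right)
                node.extra["true_species_branch"] = snode.branch_label
                return node
            else:
                return None  # loss
        # reached the bottom of the branch: species node snode at snode.age
        if snode.is_leaf:
            counter["tip"] += 1
            tip = Node(name=f"{snode.name}{separator}{prefix}g{counter['tip']}")
            tip.length = t_top - snode.age
            tip.extra["true_event"] = "tip"
            tip.extra["true_species_node"] = snode.id
            tip.extra["true_species_branch"] = snode.branch_label
            tip.extra["age"] = 0.0
            return tip
        kids = [evolve(child, snode.age) for child in snode.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            survivor = kids[0]
            survivor.length += t_top - snode.age
            survivor.extra.setdefault("suppressed_speciation", []).append(snode.id)
            return survivor
        node = Node()
        node.extra["true_event"] = "speciation"
        node.extra["true_species_node"] = snode.id
        node.extra["true_species_branch"] = snode.branch_label
        node.extra["age"] = snode.age
        node.length = t_top - snode.age
        for k in kids:
            node.add_child(k)
        return node

    # the root lineage: a speciation at the species root (age 1)
    root_snode = st.root
    kids = [evolve(child, root_snode.age) for child in root_snode.children]
    kids = [k for k in kids if k is not None]
    if not kids:
        logger.info("gene tree %s: all lineages lost", tree_id)
        return None
    if len(kids) == 1:
        root = kids[0]
        root.length = None
    else:
        root = Node()
        root.extra["true_event"] = "speciation"
        root.extra["true_species_node"] = root_snode.id
        root.extra["age"] = root_snode.age
        for k in kids:
            root.add_child(k)

    # substitution lengths: time length scaled by a unit-mean gamma factor
    for node in root.preorder():
        if node.parent is None or node.length is None:
            continue
        node.extra["time_length"] = node.length
        if subst_gamma_shape is None:
            continue
        factor = rng.gamma(subst_gamma_shape, 1.0 / subst_gamma_shape)
        node.length = node.length * factor
    return GeneTree(root, separator=separator, tree_id=tree_id)


def simulate_gene_trees(
    st: SpeciesTree,
    dup_rate: float,
    loss_rate: float,
    n_trees: int,
    seed: Union[int, np.random.Generator, None] = None,
    **kwargs,
) -> list[GeneTree]:
    """A forest of duplication-loss gene trees; lost families are skipped."""
    rng = _rng(seed)
    forest = []
    for i in range(n_trees):
        gt = simulate_gene_tree(
            st, dup_rate, loss_rate, seed=rng, tree_id=f"tree{i}", **kwargs
        )
        if gt is not None:
            forest.append(gt)
    return forest


# ---------------------------------------------------------------------------
# counting efficiencies and read counts
# ---------------------------------------------------------------------------

def simulate_efficiencies(
    genes: Sequence[str],
    species: Sequence[str],
    sd_log: float = 1.0,
    seed: Union[int, np.random.Generator, None] = None,
) -> pd.DataFrame:
    """Log-normal per-(gene, species) counting-efficiency factors e_gs > 0."""
    rng = _rng(seed)
    return pd.DataFrame(
        np.exp(rng.normal(0.0, sd_log, size=(len(genes), len(species)))),
        index=pd.Index(genes, name="gene"),
        columns=pd.Index(species, name="species"),
    )


def simulate_counts(
    true_expression: pd.DataFrame,
    efficiencies: pd.DataFrame,
    meta: SampleMetadata,
    effective_length: Union[pd.Series, pd.DataFrame, float] = 1000.0,
    library_size: int = 1_000_000,
    seed: Union[int, np.random.Generator, None] = None,
    exact: bool = False,
) -> CountMatrix:
    """Multinomial read counts from true expression and efficiency factors.

    ``true_expression`` is genes x libraries on the linear scale; each
    library's expected count for gene g is proportional to
    ``e[g, species(lib)] * x[g, lib] * length[g]``; reads are then drawn
    multinomially with the library size fixed (``exact=True`` returns the
    expectations instead, for noise-free pipelines).
    """
    rng = _rng(seed)
    genes = true_expression.index
    meta.validate_against(true_expression.columns)
    if isinstance(effective_length, (int, float)):
        lengths = pd.Series(float(effective_length), index=genes)
    elif isinstance(effective_length, pd.DataFrame):
        lengths = None
    else:
        lengths = effective_length.reindex(genes)
    counts = {}
    for lib in true_expression.columns:
        sp = meta.species_of(lib)
        e = efficiencies[sp].reindex(genes).to_numpy()
        x = true_expression[lib].to_numpy(dtype=float)
        lg = (
            effective_length[lib].reindex(genes).to_numpy()
            if lengths is None
            else lengths.to_numpy()
        )
        expected = e * x * lg
        total = expected.sum()
        if total <= 0:
            raise ValueError(f"library {lib!r} has zero total expectation")
        p = expected / total
        if exact:
            counts[lib] = p * library_size
        else:
            counts[lib] = rng.multinomial(library_size, p).astype(float)
    counts_df = pd.DataFrame(counts, index=genes)
    length_df = (
        effective_length
        if lengths is None
        else pd.DataFrame(
            np.tile(lengths.to_numpy()[:, None], (1, counts_df.shape[1])),
            index=genes,
            columns=counts_df.columns,
        )
    )
    flags = pd.DataFrame(
        {"is_rRNA": False, "is_protein_coding": True}, index=genes
    )
    return CountMatrix(counts=counts_df, effective_length=length_df, gene_flags=flags)


# ---------------------------------------------------------------------------
# scenario: a full synthetic study
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A complete synthetic study configuration.

    Defaults emulate the shape of a siphonophore-style design: 7 species on
    an ultrametric tree (root age 1), 5 tissues (zooid types) with the
    denominator tissue sampled in every species, 3 replicates, moderate
    duplication/loss, BM log-expression, log-normal counting efficiencies
    and multinomial libraries of 1e6 reads.
    """

    n_species: int = 7
    tissues: tuple = ("gastrozooid", "nectophore", "palpon", "pneumatophore", "gonodendron")
    denominator_tissue: str = "gastrozooid"
    n_replicates: int = 3
    n_trees: int = 30
    dup_rate: float = 0.3
    loss_rate: float = 0.2
    sigma2: float = 0.25
    root_log_expression: float = 3.0
    efficiency_sd_log: float = 1.0
    tissue_effect_sd: float = 0.5
    library_size: int = 1_000_000
    replicate_noise_sd: float = 0.05
    seed: int = 0


def balanced_species_tree(n_species: int = 7) -> SpeciesTree:
    """A deterministic ladder-shaped ultrametric species tree, root age 1."""
    names = [f"sp{i+1}" for i in range(n_species)]
    # ladder (pectinate) topology with evenly spaced split ages
    ages = np.linspace(1.0, 1.0 / n_species, n_species - 1)

    def build(i: int) -> str:
        if i == n_species - 2:
            inner = f"{names[i]}:{ages[i]:.10f},{names[i+1]}:{ages[i]:.10f}"
        else:
            sub = build(i + 1)
            inner = (
                f"{names[i]}:{ages[i]:.10f},"
                f"({sub}):{ages[i]-ages[i+1]:.10f}"
            )
        return inner

    newick = f"({build(0)});"
    st = read_newick(newick, kind="species", is_path=False)
    return label_species_branches(st)


def time_copy(gt: GeneTree) -> GeneTree:
    """Copy of a simulated gene tree with branch lengths set to true time
    (the ``time_length`` recorded before gamma rate noise was applied)."""
    ct = gt.copy()
    for node in ct.preorder():
        if not node.is_root and "time_length" in node.extra:
            node.length = node.extra["time_length"]
        if "age" in node.extra:
            node.age = node.extra["age"]
    return ct


@dataclass
class ScenarioData:
    """Everything one synthetic study produces, latent truth included."""

    scenario: Scenario
    species_tree: SpeciesTree
    gene_trees: list
    true_traits: dict          # (tree_id, tissue) -> {node_id: log value}
    tissue_offsets: dict       # (tree_id, tissue) -> additive offset
    counts: dict               # species -> CountMatrix
    meta: SampleMetadata
    efficiencies: pd.DataFrame # genes x species (own species column filled)
    n_reference: dict          # species -> reference gene count


def generate_scenario(sc: Scenario) -> ScenarioData:
    """Simulate a full study: gene trees, BM log-expression per tissue,
    counting efficiencies and multinomial libraries, one count matrix per
    species (each species has its own reference).

    Log-expression for each (gene tree, tissue) evolves by an independent BM
    along the tree's true time lengths, rooted at the scenario's root value
    plus a tissue offset; replicate libraries add i.i.d. log-normal noise.
    """
    rng = _rng(sc.seed)
    st = balanced_species_tree(sc.n_species)
    forest = simulate_gene_trees(
        st, sc.dup_rate, sc.loss_rate, sc.n_trees, seed=rng
    )

    true_traits: dict = {}
    tissue_offsets: dict = {}
    for gt in forest:
        tc = time_copy(gt)
        for tissue in sc.tissues:
            offset = float(rng.normal(0.0, sc.tissue_effect_sd))
            tissue_offsets[(gt.tree_id, tissue)] = offset
            true_traits[(gt.tree_id, tissue)] = simulate_bm(
                tc, sc.root_log_expression + offset, sc.sigma2, seed=rng
            )

    species = st.species()
    tips_by_species: dict[str, list] = {sp: [] for sp in species}
    tip_tree: dict[str, str] = {}
    tip_node_id: dict[str, int] = {}
    for gt in forest:
        for leaf in gt.leaves():
            sp = gt.tip_species(leaf)
            tips_by_species[sp].append(leaf.name)
            tip_tree[leaf.name] = gt.tree_id
            tip_node_id[leaf.name] = leaf.id

    # library layout: every (species, tissue) x replicates
    meta_rows = []
    for sp in species:
        for tissue in sc.tissues:
            for rep in range(1, sc.n_replicates + 1):
                meta_rows.append(
                    {
                        "library": f"{sp}_{tissue}_r{rep}",
                        "species": sp,
                        "tissue": tissue,
                        "stage": "mature",
                        "replicate": rep,
                    }
                )
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("library"))

    all_genes = [g for sp in species for g in tips_by_species[sp]]
    efficiencies = simulate_efficiencies(
        all_genes, species, sd_log=sc.efficiency_sd_log, seed=rng
    )

    counts: dict[str, CountMatrix] = {}
    n_reference: dict[str, int] = {}
    for sp in species:
        genes = tips_by_species[sp]
        n_reference[sp] = len(genes)
        if not genes:
            continue
        libs = [lib for lib in meta.table.index if meta.species_of(lib) == sp]
        expr = {}
        for lib in libs:
            tissue = meta.tissue_of(lib)
            log_vals = np.array(
                [
                    true_traits[(tip_tree[g], tissue)][tip_node_id[g]]
                    for g in genes
                ]
            )
            noise = rng.normal(0.0, sc.replicate_noise_sd, size=len(genes))
            expr[lib] = np.exp(log_vals + noise)
        expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"))
        sp_meta = SampleMetadata(meta.table.loc[libs])
        counts[sp] = simulate_counts(
            expr_df,
            efficiencies.loc[genes],
            sp_meta,
            library_size=sc.library_size,
            seed=rng,
        )

    return ScenarioData(
        scenario=sc,
        species_tree=st,
        gene_trees=forest,
        true_traits=true_traits,
        tissue_offsets=tissue_offsets,
        counts=counts,
        meta=meta,
        efficiencies=efficiencies,
        n_reference=n_reference,
    )
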