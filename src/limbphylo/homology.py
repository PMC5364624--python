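"""Ortholog core-set construction and phylostratigraphic age assignment.

The core set is built reference-outward: a reference-species gene survives
iff, in every other species, it matches exactly one subject gene at or below
the E-value cutoff (multiple matches in any species exclude the gene, as do
missing matches).  Phylostrata are assigned per focal species as the leaf
count of the most recent common ancestor spanning the focal species and its
most distant homolog-bearing species: species-specific genes get ps 1, genes
shared by all K species get ps K.  A clustering of pairwise homolog counts
against the species tree validates the homolog calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import trees
from .io import HOMOLOGY_COLUMNS

CORE_E_MAX = 1e-20
PS_E_MAX = 1e-5


def _check_hits(hits: pd.DataFrame) -> None:
    missing = set(HOMOLOGY_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"homology table missing columns: {sorted(missing)}")
    if (hits["evalue"] < 0).any():
        raise ValueError("E-values must be >= 0")


def build_core_orthologs(
    hits: pd.DataFrame,
    species: list[str],
    reference: str,
    e_max: float = CORE_E_MAX,
) -> pd.DataFrame:
    """Ortholog groups with exactly one gene per species.

    Returns a DataFrame indexed by reference gene with one column per
    species.  Reference genes matching zero or more than one subject gene
    in any non-reference species are excluded; groups that would reuse a
    subject gene are dropped with a warning so no gene appears twice.
    """
    _check_hits(hits)
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if reference not in species:
        raise ValueError(f"reference species {reference!r} not in species list")
    others = [sp for sp in species if sp != reference]
    sub = hits[
        (hits["qspecies"] == reference)
        & (hits["sspecies"].isin(others))
        & (hits["evalue"] <= e_max)
    ]
    if reference not in set(hits["qspecies"]):
        if len(hits):
            raise ValueError(f"no hits with query species {reference!r}")

    rows = {}
    per_gene = sub.groupby("qseqid")
    for qgene, block in per_gene:
        subjects = {}
        ok = True
        for sp in others:
            hits_sp = block.loc[block["sspecies"] == sp, "sseqid"].unique()
            if len(hits_sp) != 1:
                ok = False  # absent or ambiguous in this species
                break
            subjects[sp] = hits_sp[0]
        if ok:
            rows[qgene] = {reference: qgene, **subjects}

    groups = pd.DataFrame.from_dict(rows, orient="index", columns=species)
    groups = groups.sort_index()
    # enforce one-group-per-gene: drop every group sharing a subject gene
    for sp in others:
        dup = groups[sp].duplicated(keep=False)
        if dup.any():
            warnings.warn(
                f"{int(dup.sum())} groups share subject genes in {sp}; dropped",
                stacklevel=2,
            )
            groups = groups[~dup]
    return groups


def assign_phylostrata(
    hits: pd.DataFrame,
    tree_newick: str,
    focal: str,
    genes: list[str] | None = None,
    e_max: float = PS_E_MAX,
) -> pd.Series:
    """Phylostratum (evolutionary age class) per focal-species gene.

    ps = number of leaves under the MRCA of the focal species and the most
    distant species holding a homolog at E <= e_max; 1 when no homolog is
    detected anywhere.  ``genes`` extends the result to genes with no hits
    at all (they get ps 1); by default only genes present in the hit table
    are returned.
    """
    _check_hits(hits)
    tree = trees.load_tree(tree_newick)
    leaves = set(trees.leaf_names(tree))
    if focal not in leaves:
        raise ValueError(f"focal species {focal!r} not on tree")
    hit_species = set(hits["qspecies"]) | set(hits["sspecies"])
    unknown = hit_species - leaves
    if unknown:
        raise ValueError(f"species in hits not on tree: {sorted(unknown)}")

    sub = hits[
        (hits["qspecies"] == focal)
        & (hits["sspecies"] != focal)
        & (hits["evalue"] <= e_max)
    ]
    # rank of each possible partner = leaf count of MRCA(focal, partner)
    rank = {
        sp: len(trees.mrca_clade(tree, {focal, sp}))
        for sp in leaves
        if sp != focal
    }
    per_gene = sub.groupby("qseqid")["sspecies"].agg(
        lambda s: max(rank[sp] for sp in set(s))
    )
    ps = per_gene.astype(int)
    if genes is not None:
        ps = ps.reindex(genes, fill_value=1).astype(int)
    ps.name = "ps"
    return ps


@dataclass
class HomologClusteringResult:
    counts: pd.DataFrame  # pairwise homolog-bearing gene counts
    linkage: np.ndarray
    labels: list[str]
    newick: str
    rf_distance: int
    matches_tree: bool
    tie_warning: bool


def _linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def render(i: int) -> str:
        if i < n:
            return labels[i]
        left, right = int(linkage[i - n, 0]), int(linkage[i - n, 1])
        return f"({render(left)},{render(right)})"

    return render(n + len(linkage) - 1) + ";"


def homolog_count_clustering(
    hits: pd.DataFrame,
    tree_newick: str,
    e_max: float = PS_E_MAX,
) -> HomologClusteringResult:
    """Average-linkage clustering of pairwise homolog counts vs. the tree.

    N[i, j] = number of genes of species i with >= 1 homolog in species j;
    the distance is max(N) - (N + N') / 2 (symmetrized).  The resulting
    dendrogram is compared to the species tree by Robinson-Foulds distance.
    """
    _check_hits(hits)
    tree = trees.load_tree(tree_newick)
    species = sorted(trees.leaf_names(tree))
    if len(species) < 3:
        raise ValueError("need >= 3 species for topology comparison")
    sub = hits[hits["evalue"] <= e_max]
    counts = pd.DataFrame(0, index=species, columns=species, dtype=float)
    grouped = sub.groupby(["qspecies", "sspecies"])["qseqid"].nunique()
    for (qs, ss), n in grouped.items():
        if qs != ss:
            counts.loc[qs, ss] = float(n)

    sym = (counts.values + counts.values.T) / 2.0
    dist = sym.max() - sym
    np.fill_diagonal(dist, 0.0)
    iu = np.triu_indices(len(species), k=1)
    condensed = dist[iu]
    tie = bool(len(condensed) > 1 and np.allclose(condensed, condensed[0]))
    if tie:
        warnings.warn(
            "all pairwise homolog counts are equal; clustering is arbitrary",
            stacklevel=2,
        )
    linkage = hierarchy.average(condensed)
    newick = _linkage_to_newick(linkage, species)
    rf = trees.robinson_foulds(newick, tree_newick)
    return HomologClusteringResult(
        counts=counts,
        linkage=linkage,
        labels=species,
        newick=newick,
        rf_distance=int(rf),
        matches_tree=bool(rf == 0) and not tie,
        tie_warning=tie,
    )
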