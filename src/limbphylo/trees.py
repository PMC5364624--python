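"""Small rooted-species-tree utilities on top of dendropy."""

from __future__ import annotations

import dendropy


def load_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick string with unique, named leaves."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    names = leaf_names(tree)
    if len(names) < 2:
        raise ValueError("species tree must have at least 2 leaves")
    if len(set(names)) != len(names):
        raise ValueError("species tree leaf names must be unique")
    return tree


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def clades(tree: dendropy.Tree) -> list[frozenset[str]]:
    """All proper internal clades (leaf-name sets), smallest first, root last."""
    out = []
    for node in tree.postorder_internal_node_iter():
        out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    out.sort(key=lambda s: (len(s), sorted(s)))
    return out


def mrca_clade(tree: dendropy.Tree, species: set[str]) -> frozenset[str]:
    """Leaf set of the MRCA of ``species``."""
    taxa = [t for t in tree.taxon_namespace if t.label in species]
    if len(taxa) != len(species):
        missing = species - {t.label for t in tree.taxon_namespace}
        raise ValueError(f"species not on tree: {sorted(missing)}")
    if len(taxa) == 1:
        return frozenset(species)
    node = tree.mrca(taxa=taxa)
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unrooted symmetric-difference (Robinson-Foulds) distance."""
    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(ta, tb)
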