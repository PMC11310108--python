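"""Readers and writers for standard phylogenetic formats.

Alignments are parsed with Biopython (FASTA, NEXUS); trees with dendropy
(Newick, NEXUS).  Unrooted trees are serialised with an arbitrary
trifurcating root, so a write/read round trip preserves the unrooted
topology (Robinson-Foulds distance 0) and the branch lengths.

Taxon matching between alignments and trees is by exact label string
throughout the package; a mismatch is an error, never silent pruning.
"""

from __future__ import annotations

import os

import dendropy
import numpy as np
from Bio import SeqIO
from dendropy.calculate import treecompare

from .models import Alignment
from .soft_nj import PhyloTree

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "tree_to_newick",
    "tree_from_newick",
    "rf_distance",
]

_ALN_FORMATS = ("fasta", "nexus")
_TREE_FORMATS = ("newick", "nexus")


def _infer_format(path: str, choices, kind: str) -> str:
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    by_ext = {
        "fa": "fasta", "fasta": "fasta", "fna": "fasta",
        "nex": "nexus", "nexus": "nexus", "nxs": "nexus",
        "nwk": "newick", "newick": "newick", "tree": "newick", "tre": "newick",
    }
    fmt = by_ext.get(ext)
    if fmt not in choices:
        raise ValueError(
            f"cannot infer {kind} format from extension {ext!r}; pass format= one of {choices}"
        )
    return fmt


def read_alignment(path, format: str | None = None) -> Alignment:
    """Read a multiple sequence alignment from FASTA or NEXUS.

    Case-insensitive; RNA U is normalised to T by the Alignment itself.
    Ragged sequences, duplicate labels, and empty files raise ValueError
    naming the problem.
    """
    fmt = format or _infer_format(path, _ALN_FORMATS, "alignment")
    if fmt not in _ALN_FORMATS:
        raise ValueError(f"unsupported alignment format {fmt!r}; use one of {_ALN_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"no sequences found in {path!r} (empty or not {fmt})")
    taxa = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return Alignment(taxa=taxa, sequences=seqs)


def write_alignment(aln: Alignment, path, format: str | None = None) -> None:
    """Write an alignment as FASTA or a NEXUS data block."""
    fmt = format or _infer_format(path, _ALN_FORMATS, "alignment")
    if fmt not in _ALN_FORMATS:
        raise ValueError(f"unsupported alignment format {fmt!r}; use one of {_ALN_FORMATS}")
    if fmt == "fasta":
        with open(path, "w") as fh:
            for t, s in zip(aln.taxa, aln.sequences):
                fh.write(f">{t}\n{s}\n")
        return
    # NEXUS data block
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBegin data;\n")
        fh.write(f"  Dimensions ntax={aln.n_taxa} nchar={aln.n_sites};\n")
        fh.write("  Format datatype=dna missing=? gap=-;\n  Matrix\n")
        for t, s in zip(aln.taxa, aln.sequences):
            fh.write(f"    {t}  {s}\n")
        fh.write("  ;\nEnd;\n")


def tree_to_newick(tree: PhyloTree, precision: int = 12) -> str:
    """Serialise a PhyloTree as Newick with a trifurcating root.

    The (arbitrary) serialisation root is the last internal node; the
    unrooted topology and branch lengths are exactly preserved.
    """
    n = tree.n_tips
    adj = tree.adjacency()
    bl = tree.lengths_value()
    root = tree.n_nodes - 1

    def rec(v, parent):
        if v < n:
            return tree.taxon_labels[v]
        kids = [(w, e) for w, e in adj[v] if w != parent]
        return "(" + ",".join(f"{rec(w, v)}:{bl[e]:.{precision}g}" for w, e in kids) + ")"

    kids = [(w, e) for w, e in adj[root]]
    return "(" + ",".join(f"{rec(w, root)}:{bl[e]:.{precision}g}" for w, e in kids) + ");"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    dtree = dtree.clone(depth=1)
    dtree.deroot()  # trifurcating seed node; unrooted reading
    leaves = [nd for nd in dtree.leaf_node_iter()]
    n = len(leaves)
    if n < 3:
        raise ValueError("tree must have at least 3 tips")
    labels = []
    for nd in leaves:
        if nd.taxon is None or not nd.taxon.label:
            raise ValueError("every tip must carry a taxon label")
        labels.append(nd.taxon.label)
    if len(set(labels)) != n:
        raise ValueError("duplicate tip labels in tree")
    node_id = {id(nd): i for i, nd in enumerate(leaves)}
    next_internal = n
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf():
            continue
        node_id[id(nd)] = next_internal
        next_internal += 1
    edges = []
    lengths = []
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        edges.append((node_id[id(nd.parent_node)], node_id[id(nd)]))
        lengths.append(0.0 if nd.edge.length is None else float(nd.edge.length))
    tree = PhyloTree(n_tips=n, taxon_labels=labels, edges=edges, branch_lengths=np.asarray(lengths))
    tree.validate()
    return tree


def tree_from_newick(newick: str) -> PhyloTree:
    """Parse a Newick string into an unrooted PhyloTree."""
    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree(path, format: str | None = None) -> PhyloTree:
    """Read a tree from a Newick or NEXUS file."""
    fmt = format or _infer_format(path, _TREE_FORMATS, "tree")
    if fmt not in _TREE_FORMATS:
        raise ValueError(f"unsupported tree format {fmt!r}; use one of {_TREE_FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        dtree = dendropy.Tree.get(path=str(path), schema=fmt,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"could not parse {fmt} tree {path!r}: {exc}") from exc
    return _from_dendropy(dtree)


def write_tree(tree: PhyloTree, path, format: str | None = None) -> None:
    """Write a tree as Newick or NEXUS (trees block)."""
    fmt = format or _infer_format(path, _TREE_FORMATS, "tree")
    if fmt not in _TREE_FORMATS:
        raise ValueError(f"unsupported tree format {fmt!r}; use one of {_TREE_FORMATS}")
    nwk = tree_to_newick(tree)
    if fmt == "newick":
        with open(path, "w") as fh:
            fh.write(nwk + "\n")
        return
    dtree = dendropy.Tree.get(data=nwk, schema="newick")
    dtree.write(path=str(path), schema="nexus", suppress_rooting=False)


def _to_dendropy_pair(t1: PhyloTree, t2: PhyloTree):
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=tree_to_newick(t1), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=tree_to_newick(t2), schema="newick", taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return d1, d2


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds (symmetric bipartition) distance between two trees."""
    if set(t1.taxon_labels) != set(t2.taxon_labels):
        raise ValueError("trees must share the same tip label set")
    d1, d2 = _to_dendropy_pair(t1, t2)
    return int(treecompare.symmetric_difference(d1, d2))
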