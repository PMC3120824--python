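"""Phylogenetic likelihood of codon site patterns under the site-class mixture.

Implements Felsenstein pruning over the 61 sense-codon states, vectorized
across site patterns and batched across the four site classes.  Per-pattern
rescaling keeps partial likelihoods in range on deep trees.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from ._codons import N_SENSE
from .codonmodel import (
    CLASS_OMEGA_KEYS,
    BranchSiteParams,
    CodonFrequencies,
    class_operators,
)
from .seqio import CodonAlignment, PhyloTree

N_CLASSES = 4


class PackedTree:
    """Array-indexed postorder view of a PhyloTree for pruning.

    Nodes are numbered in postorder with the root last; branch attributes
    (length, foreground) belong to the branch above each non-root node.
    """

    def __init__(self, tree: PhyloTree, taxa_order):
        nodes = tree.postorder()
        index = {id(n): i for i, n in enumerate(nodes)}
        taxon_index = {t: i for i, t in enumerate(taxa_order)}
        self.n_nodes = len(nodes)
        self.root = self.n_nodes - 1
        self.children: list[list[int]] = [
            [index[id(c)] for c in n.children] for n in nodes
        ]
        self.lengths = np.array([n.length for n in nodes], dtype=float)
        self.foreground = np.array([n.foreground for n in nodes], dtype=bool)
        self.is_leaf = np.array([n.is_leaf for n in nodes], dtype=bool)
        leaf_taxon = np.full(self.n_nodes, -1, dtype=np.intp)
        for i, n in enumerate(nodes):
            if n.is_leaf:
                if n.label not in taxon_index:
                    raise ValueError(f"tree leaf {n.label!r} missing from alignment")
                leaf_taxon[i] = taxon_index[n.label]
        self.leaf_taxon = leaf_taxon
        # postorder positions of non-root nodes = branch ordering used by
        # PhyloTree.branch_lengths()
        self.branch_nodes = np.arange(self.n_nodes - 1)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        return self.lengths[: self.n_nodes - 1].copy()


def encode_alignment(aln: CodonAlignment, taxa_order=None) -> np.ndarray:
    """(n_taxa, n_sites) sense-codon state matrix in the given taxon order."""
    mat = aln.state_matrix()
    if taxa_order is None:
        return mat
    order = [aln.taxa.index(t) for t in taxa_order]
    return mat[order]


def compress_patterns(states: np.ndarray):
    """Collapse identical columns; returns (patterns, counts, inverse)."""
    patterns, inverse, counts = np.unique(
        states.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts.astype(float), inverse


def class_site_log_likelihoods(
    ptree: PackedTree,
    patterns: np.ndarray,
    params: BranchSiteParams,
    freqs: CodonFrequencies,
    lengths: np.ndarray | None = None,
    class_keys=CLASS_OMEGA_KEYS,
    operators=None,
    rate_scale: float | None = None,
) -> np.ndarray:
    """Per-class, per-pattern log-likelihoods, shape (n_classes, n_patterns).

    ``class_keys`` gives each class's (background, foreground) omega key
    into the operator dict; the default is the 4-class branch-site scheme.
    ``operators``/``rate_scale`` may be supplied to reuse decompositions.
    """
    if operators is None or rate_scale is None:
        operators, rate_scale = class_operators(freqs, params)
    if rate_scale <= 0:
        raise ValueError("nonpositive rate scale")
    if lengths is None:
        lengths = ptree.lengths
    else:
        lengths = np.concatenate([np.asarray(lengths, float), [0.0]])
    n_classes = len(class_keys)
    n_pat = patterns.shape[1]

    # per-branch transition matrices for each distinct omega key
    pmat_cache: dict[tuple[str, int], np.ndarray] = {}

    def branch_pmats(node: int) -> np.ndarray:
        fg = ptree.foreground[node]
        out = np.empty((n_classes, N_SENSE, N_SENSE))
        for c, (bg_key, fg_key) in enumerate(class_keys):
            key = fg_key if fg else bg_key
            cached = pmat_cache.get((key, node))
            if cached is None:
                cached = operators[key].transition_matrix(lengths[node] / rate_scale)
                pmat_cache[(key, node)] = cached
            out[c] = cached
        return out

    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros((n_classes, n_pat))

    for node in range(ptree.n_nodes):
        if ptree.is_leaf[node]:
            continue
        acc = np.ones((n_classes, n_pat, N_SENSE))
        for child in ptree.children[node]:
            pmats = branch_pmats(child)
            if ptree.is_leaf[child]:
                states = patterns[ptree.leaf_taxon[child]]
                safe = np.where(states < 0, 0, states)
                contrib = pmats[:, :, safe].transpose(0, 2, 1).copy()
                contrib[:, states < 0, :] = 1.0
            else:
                contrib = np.matmul(partials.pop(child), pmats.transpose(0, 2, 1))
            acc *= contrib
        peak = acc.max(axis=2)
        np.clip(peak, 1e-300, None, out=peak)
        acc /= peak[:, :, None]
        logscale += np.log(peak)
        partials[node] = acc

    root_partial = partials[ptree.root]
    site_lik = root_partial @ freqs.pi
    np.clip(site_lik, 1e-300, None, out=site_lik)
    return np.log(site_lik) + logscale


def mixture_log_likelihood(
    class_loglik: np.ndarray, proportions: np.ndarray, counts: np.ndarray | None = None
):
    """Total (and per-pattern) log mixture likelihood.

    Classes with zero proportion are excluded rather than contributing
    log(0) terms.
    """
    props = np.asarray(proportions, dtype=float)
    with np.errstate(divide="ignore"):
        logw = np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)
    per_pattern = logsumexp(class_loglik + logw[:, None], axis=0)
    if counts is None:
        return float(per_pattern.sum()), per_pattern
    return float(per_pattern @ counts), per_pattern


def tree_log_likelihood(
    aln: CodonAlignment,
    tree: PhyloTree,
    params: BranchSiteParams,
    freqs: CodonFrequencies,
    lengths: np.ndarray | None = None,
) -> float:
    """Convenience wrapper: total branch-site mixture log-likelihood."""
    ptree = PackedTree(tree, aln.taxa)
    states = encode_alignment(aln)
    patterns, counts, _ = compress_patterns(states)
    class_ll = class_site_log_likelihoods(ptree, patterns, params, freqs, lengths)
    total, _ = mixture_log_likelihood(class_ll, params.proportions, counts)
    return total
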