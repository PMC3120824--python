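"""Input/output for alignments, labeled trees, coordinates and annotations.

File dialects
-------------
* alignments: plain FASTA (in-frame nucleotide for codon data, single-letter
  residues for amino-acid data);
* trees: Newick, with the ``#1`` suffix on a leaf or internal-node label
  marking the subtending branch as *foreground*;
* taxon groups and binding sites: two-column TSV.

All coordinates exposed to users are 1-based and inclusive; alignment column
indices inside the package are 0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _codons
from ._codons import GAP_CHARS, codon_state

#: Residues crucial for botrocetin binding, mature-peptide numbering of the
#: Mus reference sequence.
DEFAULT_BINDING_SITES = frozenset(
    {628, 629, 632, 635, 636, 639, 643, 660, 661, 664, 667, 668}
)
A1_DOMAIN_BOUNDS = (478, 728)
SEQUENCED_REGION_BOUNDS = (524, 843)

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class StopCodonError(ValueError):
    """Internal stop codon in a coding sequence."""


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    """In-frame codon alignment.

    ``sequences[i]`` is the aligned nucleotide string for ``taxa[i]``; all
    strings have equal length divisible by three.  Gap or IUPAC-ambiguous
    codons are treated as missing data.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    code: int = 1

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        for taxon, seq in zip(self.taxa, self.sequences):
            if len(seq) % 3 != 0:
                raise FrameError(
                    f"sequence for {taxon!r} has length {len(seq)}, "
                    "not divisible by 3"
                )
            for k in range(0, len(seq), 3):
                codon = seq[k : k + 3].upper()
                if codon in _codons.STOP_CODONS:
                    raise StopCodonError(
                        f"internal stop codon {codon} in {taxon!r} at codon "
                        f"index {k // 3}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        """Number of codon columns."""
        return len(self.sequences[0]) // 3 if self.sequences else 0

    def codon(self, taxon_index: int, site: int) -> str:
        return self.sequences[taxon_index][3 * site : 3 * site + 3].upper()

    def state_matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) sense-codon indices; -1 marks missing codons."""
        mat = np.empty((self.n_taxa, self.n_sites), dtype=np.intp)
        for i in range(self.n_taxa):
            for h in range(self.n_sites):
                mat[i, h] = codon_state(self.codon(i, h))
        return mat

    def translate(self) -> "AminoAlignment":
        """Translate codon columns to residues (missing codons become X)."""
        rows = []
        for seq in self.sequences:
            residues = []
            for k in range(0, len(seq), 3):
                state = codon_state(seq[k : k + 3])
                residues.append("X" if state < 0 else _codons.AMINO_ACID[state])
            rows.append("".join(residues))
        return AminoAlignment(self.taxa, tuple(rows))


@dataclass(frozen=True)
class AminoAlignment:
    """Aligned amino-acid sequences (20 residues plus gap and X)."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        for taxon, seq in zip(self.taxa, self.sequences):
            for col, ch in enumerate(seq.upper()):
                if ch not in AMINO_ALPHABET and ch not in GAP_CHARS and ch != "X":
                    raise ValueError(
                        f"unknown residue {ch!r} for {taxon!r} at column {col + 1}"
                    )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def row(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)].upper()
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None


def _read_fasta(path_or_handle):
    return list(SeqIO.parse(path_or_handle, "fasta"))


def read_codon_alignment(path) -> CodonAlignment:
    """Read and validate an in-frame codon alignment from FASTA."""
    records = _read_fasta(path)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return CodonAlignment(
        taxa=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
    )


def read_amino_alignment(path) -> AminoAlignment:
    records = _read_fasta(path)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return AminoAlignment(
        taxa=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
    )


def write_alignment(aln, path) -> None:
    """Write a codon or amino-acid alignment as FASTA."""
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of a rooted tree representation used for pruning."""

    label: str | None = None
    length: float = 0.0
    foreground: bool = False
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Tree topology with branch lengths and per-branch foreground flags.

    Branch attributes (length, foreground) are stored on the child node of
    each branch; attributes on the root are ignored by the likelihood.
    """

    root: TreeNode

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode):
            for child in node.children:
                walk(child)
            out.append(node)

        walk(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(n.label for n in self.leaves())

    @property
    def n_foreground(self) -> int:
        return sum(n.foreground for n in self.postorder() if n is not self.root)

    def branch_lengths(self) -> np.ndarray:
        """Branch lengths in postorder (root excluded)."""
        return np.array(
            [n.length for n in self.postorder() if n is not self.root], dtype=float
        )

    def with_branch_lengths(self, lengths) -> "PhyloTree":
        tree = self.copy()
        nodes = [n for n in tree.postorder() if n is not tree.root]
        if len(lengths) != len(nodes):
            raise ValueError("branch-length vector has wrong size")
        for node, t in zip(nodes, lengths):
            node.length = float(t)
        return tree

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            return TreeNode(
                label=node.label,
                length=node.length,
                foreground=node.foreground,
                children=[clone(c) for c in node.children],
            )

        return PhyloTree(clone(self.root))

    def newick(self, precision: int = 6) -> str:
        def fmt(node: TreeNode, is_root: bool) -> str:
            tag = "#1" if node.foreground and not is_root else ""
            if node.is_leaf:
                body = f"{node.label}{tag}"
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                body = f"({inner}){node.label or ''}{tag}"
            if is_root:
                return body
            return f"{body}:{node.length:.{precision}g}"

        return fmt(self.root, True) + ";"


def parse_labeled_tree(newick: str) -> PhyloTree:
    """Parse a Newick string with optional ``#1`` foreground branch tags."""
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        raw = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        raw = raw or ""
        foreground = raw.endswith("#1")
        label = raw[:-2].strip() if foreground else raw
        length = dnode.edge.length
        if length is not None and length < 0:
            raise ValueError(f"negative branch length {length} on {raw!r}")
        node = TreeNode(
            label=label or None,
            length=float(length) if length is not None else 0.0,
            foreground=foreground,
            children=[convert(c) for c in dnode.child_nodes()],
        )
        return node

    tree = PhyloTree(convert(dtree.seed_node))
    labels = [leaf.label for leaf in tree.leaves()]
    if any(lbl is None for lbl in labels):
        raise ValueError("tree has an unlabeled leaf")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def read_labeled_tree(path) -> PhyloTree:
    if hasattr(path, "read"):
        return parse_labeled_tree(path.read())
    with open(path) as fh:
        return parse_labeled_tree(fh.read())


def write_labeled_tree(tree: PhyloTree, path, precision: int = 6) -> None:
    text = tree.newick(precision=precision) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def check_tree_alignment(tree: PhyloTree, aln) -> None:
    """Raise if tree leaves and alignment taxa are not the same set."""
    tree_taxa = set(tree.taxa)
    aln_taxa = set(aln.taxa)
    if tree_taxa != aln_taxa:
        missing = sorted(aln_taxa - tree_taxa)
        extra = sorted(tree_taxa - aln_taxa)
        raise ValueError(
            f"tree/alignment taxon mismatch: missing from tree {missing}, "
            f"extra in tree {extra}"
        )


# ---------------------------------------------------------------------------
# coordinates and annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoordinateMap:
    """Mapping from alignment columns to reference residue positions.

    ``positions[col]`` is the 1-based reference (Mus mature-peptide)
    coordinate of column ``col``, or -1 where the reference row is gapped.
    """

    reference_taxon: str
    positions: tuple[int, ...]
    a1_bounds: tuple[int, int] = A1_DOMAIN_BOUNDS
    sequenced_bounds: tuple[int, int] = SEQUENCED_REGION_BOUNDS

    def position_of_column(self, col: int) -> int | None:
        pos = self.positions[col]
        return None if pos < 0 else pos

    def column_of_position(self, pos: int) -> int:
        try:
            return self.positions.index(pos)
        except ValueError:
            raise KeyError(f"reference position {pos} not mapped") from None

    @property
    def mapped_positions(self) -> tuple[int, ...]:
        return tuple(p for p in self.positions if p >= 0)

    def in_a1(self, pos: int) -> bool:
        lo, hi = self.a1_bounds
        return lo <= pos <= hi

    def to_tsv(self, path) -> None:
        lines = ["column\treference_position\n"]
        for col, pos in enumerate(self.positions):
            lines.append(f"{col + 1}\t{pos if pos >= 0 else 'NA'}\n")
        _write_text(path, "".join(lines))


def build_coordinate_map(
    aln: AminoAlignment, reference_taxon: str, start_pos: int
) -> CoordinateMap:
    """Assign reference coordinates from the reference row of an alignment.

    Non-gap reference columns receive ``start_pos, start_pos + 1, ...``;
    columns where the reference is gapped carry no reference position.
    """
    if start_pos < 1:
        raise ValueError("start_pos must be >= 1")
    row = aln.row(reference_taxon)
    positions = []
    nxt = start_pos
    for ch in row:
        if ch in GAP_CHARS:
            positions.append(-1)
        else:
            positions.append(nxt)
            nxt += 1
    return CoordinateMap(reference_taxon=reference_taxon, positions=tuple(positions))


@dataclass(frozen=True)
class BindingSiteSet:
    """Reference positions of the ligand-binding residues under study."""

    positions: frozenset[int] = DEFAULT_BINDING_SITES

    def __post_init__(self):
        if not self.positions:
            raise ValueError("binding-site set is empty")
        lo, hi = A1_DOMAIN_BOUNDS
        if self.positions == DEFAULT_BINDING_SITES:
            bad = [p for p in self.positions if not lo <= p <= hi]
            if bad:
                raise ValueError(f"binding sites outside A1 bounds: {bad}")

    def __contains__(self, pos: int) -> bool:
        return pos in self.positions

    def sorted(self) -> list[int]:
        return sorted(self.positions)


@dataclass(frozen=True)
class TaxonGroups:
    """Partition of analysis taxa into resistant and non-resistant groups."""

    resistant: frozenset[str]
    non_resistant: frozenset[str]

    def __post_init__(self):
        overlap = self.resistant & self.non_resistant
        if overlap:
            raise ValueError(f"taxa in both groups: {sorted(overlap)}")
        if not self.resistant or not self.non_resistant:
            raise ValueError("both groups must be non-empty")

    def check_covers(self, taxa) -> None:
        uncovered = set(taxa) - self.resistant - self.non_resistant
        if uncovered:
            raise ValueError(f"taxa not assigned to a group: {sorted(uncovered)}")


def read_taxon_groups(path) -> TaxonGroups:
    """Read a two-column TSV ``taxon<TAB>resistant|non_resistant``."""
    resistant, non_resistant = set(), set()
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        taxon, group = parts[0].strip(), parts[1].strip().lower()
        if group in {"resistant", "1", "true"}:
            resistant.add(taxon)
        elif group in {"non_resistant", "nonresistant", "0", "false"}:
            non_resistant.add(taxon)
        else:
            raise ValueError(f"{path}:{lineno}: unknown group {parts[1]!r}")
    return TaxonGroups(frozenset(resistant), frozenset(non_resistant))


def write_taxon_groups(groups: TaxonGroups, path) -> None:
    lines = [f"{t}\tresistant\n" for t in sorted(groups.resistant)]
    lines += [f"{t}\tnon_resistant\n" for t in sorted(groups.non_resistant)]
    _write_text(path, "".join(lines))


def read_binding_sites(path) -> BindingSiteSet:
    """Read binding sites from TSV; first column is the reference position."""
    positions = set()
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        first = line.rstrip("\n").split("\t")[0].strip()
        try:
            positions.add(int(first))
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: non-integer position {first!r}"
            ) from None
    return BindingSiteSet(frozenset(positions))


def write_binding_sites(sites: BindingSiteSet, path) -> None:
    _write_text(path, "".join(f"{p}\tbinding\n" for p in sites.sorted()))


def _read_lines(path):
    if hasattr(path, "read"):
        return io.StringIO(path.read()).readlines()
    with open(path) as fh:
        return fh.readlines()


def _write_text(path, text: str) -> None:
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


__all__ = [
    "CodonAlignment",
    "AminoAlignment",
    "PhyloTree",
    "TreeNode",
    "CoordinateMap",
    "BindingSiteSet",
    "TaxonGroups",
    "FrameError",
    "StopCodonError",
    "DEFAULT_BINDING_SITES",
    "A1_DOMAIN_BOUNDS",
    "SEQUENCED_REGION_BOUNDS",
    "read_codon_alignment",
    "read_amino_alignment",
    "write_alignment",
    "read_labeled_tree",
    "parse_labeled_tree",
    "write_labeled_tree",
    "check_tree_alignment",
    "build_coordinate_map",
    "read_taxon_groups",
    "write_taxon_groups",
    "read_binding_sites",
    "write_binding_sites",
]
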