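"""Synthetic inputs with the statistical structure the analyses assume.

Two generators:

* ``simulate_codon_alignment`` evolves codon columns along a labeled tree
  under the branch-site site-class mixture (exact transition-matrix
  sampling, or an event-recording jump-chain mode for substitution-count
  oracles);
* ``simulate_property_alignment`` builds an amino-acid alignment in which a
  "resistant" group carries charge/hydropathy shifts concentrated at and
  near annotated binding sites over a noisy background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import AMINO_ACID, N_SENSE, SENSE_CODONS
from .codonmodel import (
    CLASS_OMEGA_KEYS,
    BranchSiteParams,
    CodonFrequencies,
    build_rate_matrix,
    class_operators,
)
from .physchem import CHARGE, KYTE_DOOLITTLE
from .seqio import (
    AminoAlignment,
    BindingSiteSet,
    CodonAlignment,
    CoordinateMap,
    PhyloTree,
    TaxonGroups,
    parse_labeled_tree,
)

# ---------------------------------------------------------------------------
# default simulation tree
# ---------------------------------------------------------------------------

# 26-leaf didelphid-shaped topology: a resistant clade of four genera
# (Chironectes, Lutreolina, Didelphis, Philander) nested among non-resistant
# opossums, Metachirus as its sister lineage.  Branch lengths are arbitrary
# but fixed.
RESISTANT_CLADE_LEAVES = (
    "Chironectes",
    "Lutreolina",
    "Didelphis_virginiana",
    "Didelphis_albiventris",
    "Didelphis_marsupialis",
    "Philander_opossum",
    "Philander_frater",
)

DEFAULT_TREE_NEWICK = (
    "((Glironia:0.09,(Caluromys_philander:0.05,Caluromys_lanatus:0.06):0.05):0.04,"
    "(Hyladelphys:0.12,((((Marmosa_mexicana:0.05,Marmosa_murina:0.04):0.03,"
    "Tlacuatzin:0.07):0.03,(Monodelphis_brevicaudata:0.06,Monodelphis_emiliae:0.05"
    "):0.06):0.02,((Marmosops_incanus:0.05,Marmosops_noctivagus:0.05):0.04,"
    "((Thylamys_pallidior:0.05,Thylamys_venustus:0.04):0.04,(Cryptonanus:0.06,"
    "(Gracilinanus_agilis:0.05,Chacodelphys:0.07):0.02):0.03):0.03):0.02):0.02"
    "):0.02,((Metachirus:0.09,((Chironectes:0.07,Lutreolina:0.06):0.015,"
    "((Didelphis_virginiana:0.02,(Didelphis_albiventris:0.015,"
    "Didelphis_marsupialis:0.015):0.01):0.025,(Philander_opossum:0.02,"
    "Philander_frater:0.02):0.03):0.02):0.03):0.03,(Caenolestes:0.1,"
    "Dromiciops:0.11):0.05):0.02);"
)


def label_foreground(
    tree: PhyloTree, clade_leaves, include_stem: bool = True, exclude=()
) -> PhyloTree:
    """Return a copy with every branch inside the clade spanned by
    ``clade_leaves`` flagged foreground.

    ``include_stem`` also flags the clade's stem branch; terminal branches
    of taxa in ``exclude`` are left in the background.
    """
    clade = set(clade_leaves)
    excluded = set(exclude)
    out = tree.copy()

    def walk(node) -> set:
        if node.is_leaf:
            return {node.label}
        below = set()
        for child in node.children:
            below |= walk(child)
        return below

    def mark(node, inside: bool):
        if node.is_leaf:
            leaves_below = {node.label}
        else:
            leaves_below = walk(node)
        is_clade_root = leaves_below == clade
        if inside or (is_clade_root and include_stem):
            node.foreground = True
        for child in node.children:
            mark(child, inside or is_clade_root)
        if node.is_leaf and node.label in excluded:
            node.foreground = False

    mark(out.root, False)
    out.root.foreground = False
    return out


def default_tree(include_all_resistant: bool = True) -> PhyloTree:
    """The fixture tree with one of the two foreground labelings applied.

    ``include_all_resistant=False`` drops the terminal branch of
    Chironectes (the taxon of unknown resistance status) from the
    foreground, mirroring the two tested schemes.
    """
    tree = parse_labeled_tree(DEFAULT_TREE_NEWICK)
    exclude = () if include_all_resistant else ("Chironectes",)
    return label_foreground(
        tree, RESISTANT_CLADE_LEAVES, include_stem=True, exclude=exclude
    )


def default_taxon_groups() -> TaxonGroups:
    tree = parse_labeled_tree(DEFAULT_TREE_NEWICK)
    resistant = frozenset(RESISTANT_CLADE_LEAVES)
    return TaxonGroups(
        resistant=resistant,
        non_resistant=frozenset(set(tree.taxa) - resistant),
    )


# ---------------------------------------------------------------------------
# codon simulation
# ---------------------------------------------------------------------------


@dataclass
class CodonSimSpec:
    """Specification of a branch-site codon-alignment simulation."""

    tree: PhyloTree
    params: BranchSiteParams
    n_sites: int
    seed: int = 2011
    freqs: CodonFrequencies = field(default_factory=CodonFrequencies.uniform)

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def _sample_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical sample per row of a stochastic matrix."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])
    return np.minimum((cum < u[:, None]).sum(axis=1), prob_rows.shape[1] - 1)


def simulate_codon_alignment(spec: CodonSimSpec):
    """Evolve codon sites along the tree under the site-class mixture.

    Each site draws a latent class from (p0, p1, p2a, p2b); the root codon
    comes from the equilibrium frequencies; branches apply the class- and
    branch-appropriate transition matrix.  Returns ``(alignment,
    site_classes)`` with classes coded 0, 1, 2, 3 for 0, 1, 2a, 2b.
    """
    rng = np.random.default_rng(spec.seed)
    params, freqs = spec.params, spec.freqs
    operators, scale = class_operators(freqs, params)
    classes = rng.choice(4, size=spec.n_sites, p=params.proportions)
    root_states = rng.choice(N_SENSE, size=spec.n_sites, p=freqs.pi)

    nodes = spec.tree.postorder()
    states = {id(nodes[-1]): root_states}
    leaf_states: dict[str, np.ndarray] = {}

    def evolve(node, parent_states):
        if id(node) not in states:
            child_states = np.empty(spec.n_sites, dtype=np.intp)
            for c, (bg_key, fg_key) in enumerate(CLASS_OMEGA_KEYS):
                mask = classes == c
                if not np.any(mask):
                    continue
                key = fg_key if node.foreground else bg_key
                pmat = operators[key].transition_matrix(node.length / scale)
                child_states[mask] = _sample_rows(pmat[parent_states[mask]], rng)
            states[id(node)] = child_states
        if node.is_leaf:
            leaf_states[node.label] = states[id(node)]
        for child in node.children:
            evolve(child, states[id(node)])

    for child in spec.tree.root.children:
        evolve(child, root_states)

    taxa = spec.tree.taxa
    sequences = tuple(
        "".join(SENSE_CODONS[s] for s in leaf_states[t]) for t in taxa
    )
    return CodonAlignment(taxa=tuple(taxa), sequences=sequences), classes


def simulate_codon_history(spec: CodonSimSpec):
    """Jump-chain (Gillespie) simulation recording every substitution event.

    Returns ``(alignment, site_classes, events)`` where ``events`` is a
    DataFrame with one row per substitution: site, branch (postorder index
    of the child node), foreground flag, from/to codons and a
    nonsynonymous flag.  Needed by substitution-count oracles; slower than
    the exact-sampling simulator.
    """
    rng = np.random.default_rng(spec.seed)
    params, freqs = spec.params, spec.freqs
    _, scale = class_operators(freqs, params)
    omega_of = {"w0": params.omega0, "w1": 1.0, "w2": params.omega2}
    qmats = {
        key: build_rate_matrix(freqs, params.kappa, omega_of[key], scale=False) / scale
        for key in ("w0", "w1", "w2")
    }
    classes = rng.choice(4, size=spec.n_sites, p=params.proportions)
    root_states = rng.choice(N_SENSE, size=spec.n_sites, p=freqs.pi)

    nodes = spec.tree.postorder()
    node_index = {id(n): i for i, n in enumerate(nodes)}
    events = []
    leaf_states: dict[str, np.ndarray] = {}

    def evolve(node, parent_states):
        child_states = parent_states.copy()
        for h in range(spec.n_sites):
            key = CLASS_OMEGA_KEYS[classes[h]][1 if node.foreground else 0]
            q = qmats[key]
            state = child_states[h]
            t_remaining = node.length
            while True:
                rate = -q[state, state]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait > t_remaining:
                    break
                t_remaining -= wait
                jump_probs = q[state].copy()
                jump_probs[state] = 0.0
                jump_probs /= jump_probs.sum()
                new_state = rng.choice(N_SENSE, p=jump_probs)
                events.append(
                    {
                        "site": h,
                        "branch": node_index[id(node)],
                        "foreground": bool(node.foreground),
                        "site_class": int(classes[h]),
                        "from_codon": SENSE_CODONS[state],
                        "to_codon": SENSE_CODONS[new_state],
                        "nonsynonymous": AMINO_ACID[state] != AMINO_ACID[new_state],
                    }
                )
                state = new_state
            child_states[h] = state
        if node.is_leaf:
            leaf_states[node.label] = child_states
        for child in node.children:
            evolve(child, child_states)

    for child in spec.tree.root.children:
        evolve(child, root_states)

    taxa = spec.tree.taxa
    sequences = tuple(
        "".join(SENSE_CODONS[s] for s in leaf_states[t]) for t in taxa
    )
    columns = [
        "site",
        "branch",
        "foreground",
        "site_class",
        "from_codon",
        "to_codon",
        "nonsynonymous",
    ]
    return (
        CodonAlignment(taxa=tuple(taxa), sequences=sequences),
        classes,
        pd.DataFrame(events, columns=columns),
    )


# ---------------------------------------------------------------------------
# amino-acid property simulation
# ---------------------------------------------------------------------------

_RESIDUES = tuple(sorted(KYTE_DOOLITTLE))


@dataclass
class PropertySimSpec:
    """Specification of a resistant-vs-non-resistant property simulation."""

    n_resistant: int = 4
    n_non_resistant: int = 8
    n_sites: int = 120
    region_start: int = 524
    binding_positions: tuple[int, ...] = (628, 629, 632, 635, 636, 639, 643)
    effect_size_charge: float = 2.0
    effect_size_hydropathy: float = 4.0
    decay_length: float = 0.0
    background_noise: float = 0.01
    seed: int = 2011

    def __post_init__(self):
        if self.n_resistant < 2 or self.n_non_resistant < 2:
            raise ValueError("need at least 2 taxa per group")
        if self.decay_length < 0:
            raise ValueError("decay_length must be >= 0")
        if not 0 <= self.background_noise <= 1:
            raise ValueError("background_noise must be a probability")
        if not self.binding_positions:
            raise ValueError("binding_positions must be non-empty")
        lo = self.region_start
        hi = self.region_start + self.n_sites - 1
        bad = [p for p in self.binding_positions if not lo <= p <= hi]
        if bad:
            raise ValueError(f"binding positions outside simulated region: {bad}")


def _shift_residue(anc: str, d_charge: float, d_hyd: float) -> str:
    """Residue whose property change from ``anc`` best matches the target."""
    best, best_score = anc, np.inf
    for res in _RESIDUES:
        score = abs((CHARGE[res] - CHARGE[anc]) - d_charge) + (
            abs((KYTE_DOOLITTLE[res] - KYTE_DOOLITTLE[anc]) - d_hyd) / 4.5
        )
        if score < best_score - 1e-12:
            best, best_score = res, score
    return best


def simulate_property_alignment(spec: PropertySimSpec):
    """Generate the resistant-vs-non-resistant amino-acid contrast.

    Both groups derive from one ancestral sequence with i.i.d. background
    substitution noise; the resistant group additionally receives, at each
    binding site (always) and at neighboring sites (with probability
    decaying as exp(-distance/decay_length)), a group-wide residue
    replacement whose charge/hydropathy change approximates the stated
    effect sizes.

    Returns ``(alignment, groups, binding_sites, coordinate_map, truth)``
    where ``truth`` lists, per site, whether a systematic shift was applied.
    """
    rng = np.random.default_rng(spec.seed)
    positions = np.arange(spec.region_start, spec.region_start + spec.n_sites)
    binding = np.asarray(sorted(spec.binding_positions))
    dist = np.min(np.abs(positions[:, None] - binding[None, :]), axis=1)

    ancestral = rng.choice(_RESIDUES, size=spec.n_sites)

    has_effect = spec.effect_size_charge != 0 or spec.effect_size_hydropathy != 0
    shifted = np.zeros(spec.n_sites, dtype=bool)
    resistant_consensus = ancestral.copy()
    for h in range(spec.n_sites):
        if not has_effect:
            break
        if dist[h] == 0:
            p_shift = 1.0
        elif spec.decay_length > 0:
            p_shift = float(np.exp(-dist[h] / spec.decay_length))
        else:
            p_shift = 0.0
        if rng.random() < p_shift:
            sign_c = rng.choice([-1.0, 1.0])
            sign_h = rng.choice([-1.0, 1.0])
            replacement = _shift_residue(
                ancestral[h],
                sign_c * spec.effect_size_charge,
                sign_h * spec.effect_size_hydropathy,
            )
            if replacement != ancestral[h]:
                resistant_consensus[h] = replacement
                shifted[h] = True

    def noisy(base: np.ndarray) -> str:
        seq = base.copy()
        noise_mask = rng.random(spec.n_sites) < spec.background_noise
        if np.any(noise_mask):
            seq[noise_mask] = rng.choice(_RESIDUES, size=int(noise_mask.sum()))
        return "".join(seq)

    taxa, sequences = [], []
    for i in range(spec.n_non_resistant):
        taxa.append(f"nonres_{i + 1}")
        sequences.append(noisy(ancestral))
    for i in range(spec.n_resistant):
        taxa.append(f"res_{i + 1}")
        sequences.append(noisy(resistant_consensus))

    aln = AminoAlignment(taxa=tuple(taxa), sequences=tuple(sequences))
    groups = TaxonGroups(
        resistant=frozenset(t for t in taxa if t.startswith("res_")),
        non_resistant=frozenset(t for t in taxa if t.startswith("nonres_")),
    )
    coord = CoordinateMap(
        reference_taxon=taxa[0],
        positions=tuple(int(p) for p in positions),
    )
    truth = pd.DataFrame(
        {
            "site": positions,
            "binding": dist == 0,
            "distance": dist,
            "shifted": shifted,
            "ancestral": ancestral,
            "resistant_consensus": resistant_consensus,
        }
    )
    return aln, groups, BindingSiteSet(frozenset(int(p) for p in binding)), coord, truth
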