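"""Independent oracles used by the test suite.

Everything here is deliberately brute-force and shares no code path with
the implementations it checks.
"""

from __future__ import annotations

import itertools
from itertools import product

import numpy as np

from venomscan._codons import N_SENSE
from venomscan.codonmodel import CLASS_OMEGA_KEYS, class_operators

_NUCS = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
SENSE = tuple(
    c for c in ("".join(p) for p in product(_NUCS, repeat=3)) if c not in _STOPS
)


def classify_pair(ci: str, cj: str):
    """(is_neighbor, is_transition, is_nonsynonymous) for an ordered pair."""
    diffs = [k for k in range(3) if ci[k] != cj[k]]
    if len(diffs) != 1:
        return False, False, False
    k = diffs[0]
    transition = {ci[k], cj[k]} in ({"A", "G"}, {"C", "T"})
    return True, transition, _CODE[ci] != _CODE[cj]


def series_expm(q: np.ndarray, t: float, terms: int = 60) -> np.ndarray:
    """Taylor series matrix exponential with scaling and squaring."""
    n = q.shape[0]
    squarings = max(0, int(np.ceil(np.log2(max(1.0, np.abs(q).max() * t)))) + 4)
    a = q * (t / 2**squarings)
    out = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms):
        term = term @ a / k
        out = out + term
    for _ in range(squarings):
        out = out @ out
    return out


def brute_force_class_log_likelihoods(tree, states_by_taxon, params, freqs):
    """Class log-likelihoods of one codon column by enumerating all
    internal-node codon assignments (exponential; tiny trees only)."""
    ops, scale = class_operators(freqs, params)
    root = tree.root
    nodes = tree.postorder()
    non_root_internal = [n for n in nodes if not n.is_leaf and n is not root]
    out = []
    for bg_key, fg_key in CLASS_OMEGA_KEYS:
        pmats = {}
        for n in nodes:
            if n is root:
                continue
            key = fg_key if n.foreground else bg_key
            pmats[id(n)] = ops[key].transition_matrix(n.length / scale)
        total = 0.0
        for root_state in range(N_SENSE):
            for assign in itertools.product(
                range(N_SENSE), repeat=len(non_root_internal)
            ):
                state_of = {id(root): root_state}
                for n, s in zip(non_root_internal, assign):
                    state_of[id(n)] = s
                prob = freqs.pi[root_state]

                def walk(node):
                    nonlocal prob
                    s_par = state_of[id(node)]
                    for child in node.children:
                        if child.is_leaf:
                            s = states_by_taxon[child.label]
                            if s >= 0:
                                prob *= pmats[id(child)][s_par, s]
                        else:
                            prob *= pmats[id(child)][s_par, state_of[id(child)]]
                            walk(child)

                walk(root)
                total += prob
        out.append(np.log(total))
    return np.array(out)


def enumerate_rank_sum(values_a, values_b):
    """Exact U statistic (first sample, midranks) and two-sided p-value by
    enumerating every group assignment of the pooled observations."""
    from itertools import combinations

    pooled = np.concatenate([np.asarray(values_a, float), np.asarray(values_b, float)])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j < pooled.size and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n1 = len(values_a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mean_u = n1 * (pooled.size - n1) / 2
    n_extreme = 0
    n_total = 0
    for idx in combinations(range(pooled.size), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        n_total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            n_extreme += 1
    return float(u_obs), n_extreme / n_total
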