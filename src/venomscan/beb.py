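"""Site posteriors for the positively-selected class (empirical Bayes).

``beb_site_posteriors`` integrates over a discrete prior grid on the
mixture proportions and both omega parameters (10 equal-weight categories
per dimension: omega0 uniform on (0,1), omega2 uniform on (1,11), and
(p0, p1) on a uniform lattice over the simplex), holding kappa and branch
lengths at their MLEs.  A plug-in ("neb") variant that conditions on the
MLEs of all parameters is provided as a documented fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .codonmodel import (
    BranchSiteParams,
    CodonFrequencies,
    RateOperator,
    class_operators,
    estimate_f3x4,
)
from .fit import FitResult
from .likelihood import (
    PackedTree,
    class_site_log_likelihoods,
    compress_patterns,
    encode_alignment,
)
from .seqio import BindingSiteSet, CodonAlignment, CoordinateMap, PhyloTree

CLASS_NAMES = ("0", "1", "2a", "2b")


@dataclass(frozen=True)
class SitePosteriors:
    """Per-site posterior probabilities over the four site classes."""

    probs: np.ndarray  # (n_sites, 4), rows sum to 1
    method: str

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (n_sites, 4)")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("site posteriors must sum to 1")
        object.__setattr__(self, "probs", probs)

    @property
    def n_sites(self) -> int:
        return self.probs.shape[0]

    @property
    def p_selected(self) -> np.ndarray:
        """P(class 2a) + P(class 2b) per site."""
        return self.probs[:, 2] + self.probs[:, 3]

    def selected_sites(self, threshold: float) -> np.ndarray:
        """0-based column indices with P_selected >= threshold."""
        return np.flatnonzero(self.p_selected >= threshold)


def _proportion_grid(grid_size: int) -> np.ndarray:
    """Equal-weight (p0, p1) lattice over the simplex p0 + p1 <= 1."""
    pts = []
    for i in range(grid_size):
        for j in range(grid_size):
            p0 = (i + 0.5) / grid_size
            p1 = (j + 0.5) / grid_size
            if p0 + p1 <= 1.0 + 1e-12:
                pts.append((p0, p1))
    return np.array(pts)


def _log_props(p0: float, p1: float) -> np.ndarray:
    params = BranchSiteParams(kappa=1.0, p0=p0, p1=p1, omega0=0.5, omega2=2.0)
    props = params.proportions
    with np.errstate(divide="ignore"):
        return np.where(props > 0, np.log(np.maximum(props, 1e-300)), -np.inf)


def beb_site_posteriors(
    aln: CodonAlignment,
    tree: PhyloTree,
    fit_alt: FitResult,
    freqs: CodonFrequencies | None = None,
    grid_size: int = 10,
    method: str = "beb",
) -> SitePosteriors:
    """Posterior probability per site of each branch-site class.

    Requires a converged alternative-model fit; kappa, branch lengths and
    the mixture rate scaling are fixed at the fit's values.  ``method``
    selects full grid integration ("beb") or the plug-in MLE ("neb").
    """
    if fit_alt.model != "alternative":
        raise ValueError("site posteriors require an alternative-model fit")
    if not fit_alt.converged:
        raise ValueError("refusing site posteriors from a non-converged fit")
    if method not in {"beb", "neb"}:
        raise ValueError("method must be 'beb' or 'neb'")
    if freqs is None:
        freqs = estimate_f3x4(aln)

    mle = fit_alt.params
    ptree = PackedTree(tree, aln.taxa)
    states = encode_alignment(aln)
    patterns, counts, inverse = compress_patterns(states)
    # fix the rate scaling (hence branch-length meaning) at the MLE
    _, rate_scale = class_operators(freqs, mle)
    lengths = fit_alt.branch_lengths

    if method == "neb":
        class_ll = class_site_log_likelihoods(
            ptree, patterns, mle, freqs, lengths=lengths
        )
        logw = np.log(np.maximum(mle.proportions, 1e-300))
        log_joint = class_ll + logw[:, None]
        log_m = logsumexp(log_joint, axis=0)
        probs = np.exp(log_joint - log_m).T
        return SitePosteriors(probs=probs[inverse], method="neb")

    d = grid_size
    w0_grid = (np.arange(d) + 0.5) / d
    w2_grid = 1.0 + 10.0 * (np.arange(d) + 0.5) / d
    p_grid = _proportion_grid(d)

    # one pruning pass per distinct (background, foreground) omega pair:
    # class 0 -> (w0_i, w0_i); class 1 -> (1, 1); class 2a -> (w0_i, w2_j);
    # class 2b -> (1, w2_j).  All are evaluated in a single batched call.
    operators: dict[str, RateOperator] = {"w1": RateOperator(freqs, mle.kappa, 1.0)}
    for i, w0 in enumerate(w0_grid):
        operators[f"w0_{i}"] = RateOperator(freqs, mle.kappa, w0)
    for j, w2 in enumerate(w2_grid):
        operators[f"w2_{j}"] = RateOperator(freqs, mle.kappa, w2)

    class_keys: list[tuple[str, str]] = []
    class_keys += [(f"w0_{i}", f"w0_{i}") for i in range(d)]  # class 0
    class_keys += [("w1", "w1")]  # class 1
    class_keys += [(f"w0_{i}", f"w2_{j}") for i in range(d) for j in range(d)]  # 2a
    class_keys += [("w1", f"w2_{j}") for j in range(d)]  # class 2b

    all_ll = class_site_log_likelihoods(
        ptree,
        patterns,
        mle,
        freqs,
        lengths=lengths,
        class_keys=tuple(class_keys),
        operators=operators,
        rate_scale=rate_scale,
    )
    n_pat = patterns.shape[1]
    ll0 = all_ll[:d]  # (d, n_pat)
    ll1 = all_ll[d]  # (n_pat,)
    ll2a = all_ll[d + 1 : d + 1 + d * d].reshape(d, d, n_pat)
    ll2b = all_ll[d + 1 + d * d :]  # (d, n_pat)

    # class log-likelihood stack per (w0_i, w2_j) combination
    cl = np.empty((d * d, 4, n_pat))
    for i in range(d):
        for j in range(d):
            g = i * d + j
            cl[g, 0] = ll0[i]
            cl[g, 1] = ll1
            cl[g, 2] = ll2a[i, j]
            cl[g, 3] = ll2b[j]

    n_p = p_grid.shape[0]
    log_props = np.stack([_log_props(p0, p1) for p0, p1 in p_grid])  # (n_p, 4)

    log_m = np.empty((n_p, d * d, n_pat))
    for k in range(n_p):
        log_m[k] = logsumexp(cl + log_props[k][None, :, None], axis=1)
    log_data = log_m @ counts  # (n_p, d*d): full-data log-likelihood per grid point
    log_z = logsumexp(log_data)

    posterior = np.zeros((4, n_pat))
    for k in range(n_p):
        w_k = np.exp(log_data[k] - log_z)
        if not np.any(w_k > 0):
            continue
        t = np.exp(cl + log_props[k][None, :, None] - log_m[k][:, None, :])
        posterior += np.einsum("g,gch->ch", w_k, t)
    posterior /= posterior.sum(axis=0, keepdims=True)
    return SitePosteriors(probs=posterior.T[inverse], method="beb")


def count_selected_sites(
    p_selected,
    positions,
    threshold: float,
    binding: BindingSiteSet,
    region: tuple[int, int] | None = None,
) -> dict:
    """2x2 enrichment counts of selected sites at binding vs other positions.

    ``p_selected`` and ``positions`` are parallel sequences (posterior
    probability of positive selection, 1-based reference position).  Sites
    outside ``region`` (inclusive bounds) are dropped.
    """
    p_selected = np.asarray(p_selected, dtype=float)
    positions = np.asarray(positions, dtype=int)
    if p_selected.shape != positions.shape:
        raise ValueError("p_selected and positions must be parallel")
    if region is not None:
        lo, hi = region
        keep = (positions >= lo) & (positions <= hi)
        p_selected, positions = p_selected[keep], positions[keep]
    if positions.size == 0:
        raise ValueError("no sites fall inside the requested region")
    is_binding = np.array([p in binding for p in positions])
    selected = p_selected >= threshold
    return {
        "binding_selected": int(np.sum(is_binding & selected)),
        "binding_total": int(np.sum(is_binding)),
        "nonbinding_selected": int(np.sum(~is_binding & selected)),
        "nonbinding_total": int(np.sum(~is_binding)),
    }


def posterior_table(
    posteriors: SitePosteriors,
    coord: CoordinateMap,
    aln: CodonAlignment,
    min_p: float = 0.5,
):
    """Plain records mirroring a published-style selected-sites table.

    One row per alignment column with P_selected > ``min_p``: reference
    position, reference residue, the four class posteriors and P_selected.
    """
    import pandas as pd

    amino = aln.translate()
    ref_row = amino.row(coord.reference_taxon)
    rows = []
    for col in range(posteriors.n_sites):
        p_sel = float(posteriors.p_selected[col])
        if p_sel <= min_p:
            continue
        pos = coord.position_of_column(col)
        rows.append(
            {
                "column": col + 1,
                "reference_position": pos if pos is not None else np.nan,
                "reference_residue": ref_row[col],
                "p_class0": posteriors.probs[col, 0],
                "p_class1": posteriors.probs[col, 1],
                "p_class2a": posteriors.probs[col, 2],
                "p_class2b": posteriors.probs[col, 3],
                "p_selected": p_sel,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "column",
            "reference_position",
            "reference_residue",
            "p_class0",
            "p_class1",
            "p_class2a",
            "p_class2b",
            "p_selected",
        ],
    )
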