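"""Codon substitution model: equilibrium frequencies and rate matrices.

The substitution process is the standard codon model in which the rate from
codon *i* to codon *j* is zero unless the codons differ at exactly one
nucleotide, and otherwise proportional to the target codon's equilibrium
frequency, multiplied by kappa for transitions and by omega for
nonsynonymous changes.  Equilibrium frequencies come from position-specific
nucleotide frequencies (F3x4) renormalized over the 61 sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, expm

from ._codons import (
    CODON_NUC,
    N_SENSE,
    NEIGHBOR_I,
    NEIGHBOR_J,
    NEIGHBOR_NS,
    NEIGHBOR_TS,
    NUC_INDEX,
    SENSE_CODONS,
)
from .seqio import CodonAlignment


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium frequencies over the 61 sense codons."""

    pi: np.ndarray

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (N_SENSE,):
            raise ValueError(f"expected {N_SENSE} frequencies, got {pi.shape}")
        if np.any(pi < 0):
            raise ValueError("negative codon frequency")
        if not np.isclose(pi.sum(), 1.0, atol=1e-9):
            raise ValueError(f"frequencies sum to {pi.sum()}, not 1")
        object.__setattr__(self, "pi", pi)

    @classmethod
    def uniform(cls) -> "CodonFrequencies":
        return cls(np.full(N_SENSE, 1.0 / N_SENSE))

    def of(self, codon: str) -> float:
        return float(self.pi[SENSE_CODONS.index(codon.upper())])


def estimate_f3x4(aln: CodonAlignment) -> CodonFrequencies:
    """Estimate F3x4 codon frequencies from observed nucleotide counts.

    Counts unambiguous ACGT characters separately at the three codon
    positions, forms products over positions for every sense codon, and
    renormalizes after dropping the stop codons.
    """
    counts = np.zeros((3, 4), dtype=float)
    for seq in aln.sequences:
        s = seq.upper()
        for k, ch in enumerate(s):
            idx = NUC_INDEX.get(ch)
            if idx is not None:
                counts[k % 3, idx] += 1
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = [k + 1 for k in range(3) if totals[k] == 0]
        raise ValueError(f"no unambiguous nucleotides at codon position(s) {bad}")
    freq = counts / totals[:, None]
    pi = freq[0, CODON_NUC[:, 0]] * freq[1, CODON_NUC[:, 1]] * freq[2, CODON_NUC[:, 2]]
    total = pi.sum()
    if total == 0:
        raise ValueError("all sense codons have zero F3x4 frequency")
    return CodonFrequencies(pi / total)


def build_rate_matrix(
    freqs: CodonFrequencies, kappa: float, omega: float, scale: bool = True
) -> np.ndarray:
    """Build the 61x61 codon rate matrix Q.

    Off-diagonal entries are pi_j, multiplied by ``kappa`` for transitions
    and ``omega`` for nonsynonymous changes; rows sum to zero.  With
    ``scale=True`` the matrix is normalized so the expected substitution
    rate at equilibrium, ``-sum_i pi_i q_ii``, equals 1.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    q = np.zeros((N_SENSE, N_SENSE), dtype=float)
    rates = freqs.pi[NEIGHBOR_J].copy()
    rates[NEIGHBOR_TS] *= kappa
    rates[NEIGHBOR_NS] *= omega
    q[NEIGHBOR_I, NEIGHBOR_J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        rate = expected_rate(freqs, q)
        if rate > 0:
            q /= rate
    return q


def expected_rate(freqs: CodonFrequencies, q: np.ndarray) -> float:
    """Expected substitutions per unit time at equilibrium, -sum pi_i q_ii."""
    return float(-(freqs.pi * np.diag(q)).sum())


def transition_probabilities(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1 for any t >= 0."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    if t == 0:
        return np.eye(q.shape[0])
    return expm(q * t)


class RateOperator:
    """Spectral form of a reversible codon rate matrix for fast P(t).

    For a time-reversible Q with stationary distribution pi, the symmetric
    matrix ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is eigendecomposed once;
    each transition matrix then costs two 61x61 matrix products.
    """

    def __init__(self, freqs: CodonFrequencies, kappa: float, omega: float):
        self.freqs = freqs
        self.kappa = kappa
        self.omega = omega
        q = build_rate_matrix(freqs, kappa, omega, scale=False)
        self.rate = expected_rate(freqs, q)
        # zero-frequency codons break the similarity transform; guard them
        pi = np.maximum(freqs.pi, 1e-300)
        sqrt_pi = np.sqrt(pi)
        sym = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        sym = 0.5 * (sym + sym.T)
        self._eigvals, self._eigvecs = eigh(sym)
        self._left = self._eigvecs / sqrt_pi[:, None]
        self._right = (self._eigvecs * sqrt_pi[:, None]).T

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for the *unscaled* Q; callers pre-scale t as needed."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        p = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        # renormalize tiny numerical drift so rows are exactly stochastic
        p /= p.sum(axis=1, keepdims=True)
        return p


@dataclass(frozen=True)
class BranchSiteParams:
    """Free parameters of the branch-site site-class mixture.

    Site classes and their (background, foreground) omega pairs:

    ========  ===========  ===========
    class     background   foreground
    ========  ===========  ===========
    0         omega0       omega0
    1         1            1
    2a        omega0       omega2
    2b        1            omega2
    ========  ===========  ===========

    The null model fixes ``omega2 = 1``.  Class proportions are
    ``(p0, p1, p2a, p2b)`` with ``p2a = (1-p0-p1) p0/(p0+p1)`` and
    ``p2b = (1-p0-p1) p1/(p0+p1)``.
    """

    kappa: float
    p0: float
    p1: float
    omega0: float
    omega2: float = 1.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 <= self.p0 <= 1 and 0 <= self.p1 <= 1):
            raise ValueError("p0, p1 must lie in [0, 1]")
        if self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("p0 + p1 must not exceed 1")
        if self.p0 + self.p1 <= 0:
            raise ValueError("p0 + p1 must be positive")
        if not (0 < self.omega0 < 1):
            raise ValueError("omega0 must lie in (0, 1)")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")

    @property
    def p2a(self) -> float:
        rest = max(0.0, 1.0 - self.p0 - self.p1)
        return rest * self.p0 / (self.p0 + self.p1)

    @property
    def p2b(self) -> float:
        rest = max(0.0, 1.0 - self.p0 - self.p1)
        return rest * self.p1 / (self.p0 + self.p1)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2a, self.p2b])

    @property
    def is_null(self) -> bool:
        return self.omega2 == 1.0

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "p0": self.p0,
            "p1": self.p1,
            "p2a": self.p2a,
            "p2b": self.p2b,
            "omega0": self.omega0,
            "omega2": self.omega2,
        }


#: (background omega key, foreground omega key) for classes 0, 1, 2a, 2b.
CLASS_OMEGA_KEYS = (
    ("w0", "w0"),
    ("w1", "w1"),
    ("w0", "w2"),
    ("w1", "w2"),
)


def class_operators(
    freqs: CodonFrequencies, params: BranchSiteParams
) -> tuple[dict[str, RateOperator], float]:
    """Rate operators for the distinct omegas plus the mixture rate scale.

    The scale is the expected rate averaged over the four site classes using
    the *background* omega assignment, so one unit of branch length is one
    expected substitution per codon under the background mixture.
    """
    ops = {
        "w0": RateOperator(freqs, params.kappa, params.omega0),
        "w1": RateOperator(freqs, params.kappa, 1.0),
    }
    ops["w2"] = (
        ops["w1"]
        if params.omega2 == 1.0
        else RateOperator(freqs, params.kappa, params.omega2)
    )
    props = params.proportions
    scale = (props[0] + props[2]) * ops["w0"].rate + (props[1] + props[3]) * ops[
        "w1"
    ].rate
    return ops, float(scale)
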