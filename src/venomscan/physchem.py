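"""Physicochemical divergence between taxon groups along a protein alignment.

Per-residue charge (K/R = +1, D/E = -1, others including H = 0 at
physiological pH) and Kyte-Doolittle hydropathy are averaged within the
resistant and non-resistant groups at every site; the analyses operate on
the absolute between-group difference |delta|:

* rank-sum comparison of binding vs non-binding sites,
* G-test of 2x2 enrichment counts,
* sliding-window smoothing of the per-site profile,
* ordinary-least-squares slope of |delta| against distance to the nearest
  binding site, with a permutation null obtained by shuffling |delta|
  across sites while holding distances fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2, mannwhitneyu

from .seqio import GAP_CHARS, AminoAlignment, BindingSiteSet, CoordinateMap, TaxonGroups

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Charge at physiological pH; histidine is scored 0 (configurable below).
CHARGE = {aa: 0.0 for aa in KYTE_DOOLITTLE}
CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0})


@dataclass(frozen=True)
class PropertyScale:
    """Named residue -> value map (charge or hydropathy)."""

    name: str
    values: dict

    def __post_init__(self):
        missing = set(KYTE_DOOLITTLE) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")


def charge_scale(histidine_positive: bool = False) -> PropertyScale:
    values = dict(CHARGE)
    if histidine_positive:
        values["H"] = 1.0
    return PropertyScale("charge", values)


def hydropathy_scale() -> PropertyScale:
    return PropertyScale("hydropathy", dict(KYTE_DOOLITTLE))


def property_values(aln: AminoAlignment, scale: PropertyScale) -> np.ndarray:
    """(n_taxa, n_sites) numeric matrix; gap and X become NaN."""
    out = np.full((aln.n_taxa, aln.n_sites), np.nan)
    for i, (taxon, seq) in enumerate(zip(aln.taxa, aln.sequences)):
        for j, ch in enumerate(seq.upper()):
            if ch in GAP_CHARS or ch == "X":
                continue
            try:
                out[i, j] = scale.values[ch]
            except KeyError:
                raise ValueError(
                    f"unknown residue {ch!r} for taxon {taxon!r} at column {j + 1}"
                ) from None
    return out


def group_delta_profile(
    values: np.ndarray,
    taxa,
    groups: TaxonGroups,
    coord: CoordinateMap,
    binding: BindingSiteSet,
) -> pd.DataFrame:
    """Per-site group means and |delta| with binding annotation.

    Returns one row per alignment column with columns ``site`` (reference
    position, NaN where unmapped), ``mean_resistant``,
    ``mean_non_resistant``, ``delta`` (resistant minus non-resistant),
    ``abs_delta``, per-group informative counts, and ``binding``.  Sites
    where either group has no informative residue carry NaN deltas and are
    excluded from downstream tests.
    """
    taxa = list(taxa)
    res_idx = [i for i, t in enumerate(taxa) if t in groups.resistant]
    non_idx = [i for i, t in enumerate(taxa) if t in groups.non_resistant]
    if not res_idx or not non_idx:
        raise ValueError("both groups must be represented in the alignment")

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        mean_res = np.nanmean(values[res_idx], axis=0)
        mean_non = np.nanmean(values[non_idx], axis=0)
    n_res = np.sum(~np.isnan(values[res_idx]), axis=0)
    n_non = np.sum(~np.isnan(values[non_idx]), axis=0)
    delta = mean_res - mean_non
    uninformative = (n_res == 0) | (n_non == 0)
    delta[uninformative] = np.nan

    sites = np.array(
        [p if p >= 0 else np.nan for p in coord.positions], dtype=float
    )
    is_binding = np.array(
        [p in binding if p >= 0 else False for p in coord.positions]
    )
    return pd.DataFrame(
        {
            "column": np.arange(1, values.shape[1] + 1),
            "site": sites,
            "mean_resistant": np.where(n_res > 0, mean_res, np.nan),
            "mean_non_resistant": np.where(n_non > 0, mean_non, np.nan),
            "delta": delta,
            "abs_delta": np.abs(delta),
            "n_resistant": n_res,
            "n_non_resistant": n_non,
            "binding": is_binding,
        }
    )


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample, midranks for ties
    p_value: float
    n1: int
    n2: int
    method: str
    ties_present: bool

    def __post_init__(self):
        if not (0 <= self.statistic <= self.n1 * self.n2 + 1e-9):
            raise ValueError("rank-sum statistic outside [0, n1*n2]")


def rank_sum_test(values_a, values_b, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon/Mann-Whitney rank-sum test on two samples.

    Reports the U statistic of the first sample using midranks for ties.
    The p-value uses exact enumeration when ``n1 * n2 <= 10000`` and there
    are no ties, otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray([v for v in np.ravel(values_a) if not np.isnan(v)], dtype=float)
    b = np.asarray([v for v in np.ravel(values_b) if not np.isnan(v)], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty after NA removal")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < pooled.size
    exact = (a.size * b.size <= 10_000) and not ties
    method = "exact" if exact else "asymptotic"
    res = mannwhitneyu(
        a,
        b,
        alternative=alternative,
        method=method,
        use_continuity=not exact,
    )
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=a.size,
        n2=b.size,
        method=method,
        ties_present=bool(ties),
    )


@dataclass(frozen=True)
class GTestResult:
    statistic: float
    df: int
    p_value: float
    table: tuple

    def __post_init__(self):
        if self.statistic < -1e-12:
            raise ValueError("G statistic must be nonnegative")


def g_test(table) -> GTestResult:
    """Log-likelihood-ratio (G) test of independence on a 2x2 table.

    ``G = 2 sum O ln(O/E)`` with expectations from the margins; zero cells
    contribute nothing.  No Williams correction is applied; the p-value
    comes from chi-square with 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("g_test expects a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all table margins must be positive")
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(max(0.0, 2.0 * terms.sum()))
    return GTestResult(
        statistic=g,
        df=1,
        p_value=float(chi2.sf(g, df=1)),
        table=tuple(tuple(int(x) if float(x).is_integer() else float(x) for x in r) for r in obs),
    )


def sliding_window(profile, window: int) -> np.ndarray:
    """Centered moving average ignoring NaN; truncated windows at the edges."""
    values = np.asarray(profile, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be an odd positive integer")
    if window > values.size:
        raise ValueError("window exceeds profile length")
    half = window // 2
    out = np.full(values.size, np.nan)
    for i in range(values.size):
        chunk = values[max(0, i - half) : i + half + 1]
        good = chunk[~np.isnan(chunk)]
        if good.size:
            out[i] = good.mean()
    return out


def distance_to_binding(positions, binding: BindingSiteSet) -> np.ndarray:
    """Residue-unit distance from each reference position to the nearest
    binding site (0 at binding sites themselves)."""
    sites = np.asarray(binding.sorted(), dtype=float)
    pos = np.asarray(positions, dtype=float)
    return np.min(np.abs(pos[:, None] - sites[None, :]), axis=1)


@dataclass(frozen=True)
class PermutationRegressionResult:
    """Observed |delta|-vs-distance OLS slope against a permutation null."""

    observed_slope: float
    null_slopes: np.ndarray
    include_binding: bool
    seed: int
    n_perm: int = field(default=0)

    def __post_init__(self):
        object.__setattr__(
            self, "null_slopes", np.asarray(self.null_slopes, dtype=float)
        )
        object.__setattr__(self, "n_perm", int(self.null_slopes.size))

    @property
    def interval95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.null_slopes, [2.5, 97.5])
        return float(lo), float(hi)

    @property
    def significant(self) -> bool:
        lo, hi = self.interval95
        return self.observed_slope < lo or self.observed_slope > hi

    def to_dict(self) -> dict:
        lo, hi = self.interval95
        return {
            "observed_slope": self.observed_slope,
            "null_interval95": [lo, hi],
            "significant": self.significant,
            "n_perm": self.n_perm,
            "include_binding": self.include_binding,
            "seed": self.seed,
        }


def _ols_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """OLS slopes of each row of ``y`` on ``x`` (shared predictor)."""
    xc = x - x.mean()
    denom = float(xc @ xc)
    return (y - y.mean(axis=-1, keepdims=True)) @ xc / denom


def permutation_slope_test(
    abs_delta,
    distances,
    n_perm: int = 1000,
    include_binding: bool = True,
    seed: int = 2011,
    is_binding=None,
) -> PermutationRegressionResult:
    """Permutation test of the regression of |delta| on binding-site distance.

    The null distribution shuffles the |delta| values across sites while
    the distances stay fixed.  With ``include_binding=False`` the
    binding-site rows (``is_binding`` mask required) are dropped before both
    the observed and the permuted fits.  NaN sites are removed pairwise.
    """
    y = np.asarray(abs_delta, dtype=float)
    x = np.asarray(distances, dtype=float)
    if y.shape != x.shape:
        raise ValueError("abs_delta and distances must be parallel")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    keep = ~(np.isnan(y) | np.isnan(x))
    if not include_binding:
        if is_binding is None:
            raise ValueError("include_binding=False requires an is_binding mask")
        keep &= ~np.asarray(is_binding, dtype=bool)
    y, x = y[keep], x[keep]
    if y.size < 3:
        raise ValueError("need at least 3 non-NA sites for the regression")
    if np.ptp(x) == 0:
        raise ValueError("all distances equal; slope undefined")

    observed = float(_ols_slopes(x, y[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    null_slopes = _ols_slopes(x, perms)
    return PermutationRegressionResult(
        observed_slope=observed,
        null_slopes=null_slopes,
        include_binding=include_binding,
        seed=seed,
    )


def exact_rank_sum_reference(values_a, values_b):
    """Brute-force U statistic and exact two-sided p by full enumeration.

    Independent oracle used in tests; enumerates all C(n1+n2, n1) group
    assignments of the pooled sample (midranks for ties).
    """
    from itertools import combinations

    from scipy.stats import rankdata

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n1 = a.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    total = comb(pooled.size, n1)
    mean_u = n1 * b.size / 2
    extreme = sum(
        1
        for idx in combinations(range(pooled.size), n1)
        if abs(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2 - mean_u)
        >= abs(u_obs - mean_u) - 1e-12
    )
    return float(u_obs), extreme / total
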