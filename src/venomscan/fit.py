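"""Maximum-likelihood fitting of the branch-site models and the LRT.

The alternative model frees omega2 >= 1 on foreground branches; the null
fixes omega2 = 1.  Optimization runs bounded L-BFGS-B on transformed
parameters (log kappa, simplex logits for the class proportions, a logistic
map for omega0, log(omega2 - 1) for the alternative, and log branch lengths
when those are free), with one default start plus seeded random restarts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import chi2

from .codonmodel import BranchSiteParams, CodonFrequencies, estimate_f3x4
from .likelihood import (
    PackedTree,
    class_site_log_likelihoods,
    compress_patterns,
    encode_alignment,
    mixture_log_likelihood,
)
from .seqio import CodonAlignment, PhyloTree, check_tree_alignment

_W0_FLOOR = 1e-4
_W2_CAP = 999.0
_BLEN_FLOOR = 1e-8
_BLEN_CAP = 50.0
DEFAULT_SEED = 2011


@dataclass
class FitResult:
    """Outcome of one branch-site model fit."""

    params: BranchSiteParams
    lnL: float
    converged: bool
    n_free_params: int
    model: str
    branch_lengths: np.ndarray
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "lnL": self.lnL,
            "converged": self.converged,
            "n_free_params": self.n_free_params,
            "params": self.params.to_dict(),
            "branch_lengths": [float(t) for t in self.branch_lengths],
            "message": self.message,
        }

    def to_json(self, path) -> None:
        text = json.dumps(self.to_dict(), indent=2)
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        p = d["params"]
        return cls(
            params=BranchSiteParams(
                kappa=p["kappa"],
                p0=p["p0"],
                p1=p["p1"],
                omega0=p["omega0"],
                omega2=p["omega2"],
            ),
            lnL=d["lnL"],
            converged=d["converged"],
            n_free_params=d["n_free_params"],
            model=d["model"],
            branch_lengths=np.asarray(d["branch_lengths"], dtype=float),
            message=d.get("message", ""),
        )

    @classmethod
    def from_json(cls, path) -> "FitResult":
        if hasattr(path, "read"):
            return cls.from_dict(json.load(path))
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of the alternative against the null fit."""

    statistic: float
    df: int
    p_value: float
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "warning": self.warning,
        }


def _pack(params: BranchSiteParams, alternative: bool) -> np.ndarray:
    p0, p1 = params.p0, params.p1
    rest = max(1.0 - p0 - p1, 1e-6)
    x = [
        np.log(params.kappa),
        np.log(max(p0, 1e-6) / rest),
        np.log(max(p1, 1e-6) / rest),
        logit((params.omega0 - _W0_FLOOR) / (1.0 - _W0_FLOOR)),
    ]
    if alternative:
        x.append(np.log(max(params.omega2 - 1.0, 1e-4)))
    return np.array(x, dtype=float)


def _unpack(x: np.ndarray, alternative: bool) -> BranchSiteParams:
    e0, e1 = np.exp(x[1]), np.exp(x[2])
    denom = 1.0 + e0 + e1
    p0, p1 = e0 / denom, e1 / denom
    omega0 = _W0_FLOOR + (1.0 - _W0_FLOOR) * expit(x[3])
    omega0 = min(omega0, 1.0 - 1e-9)
    omega2 = 1.0 + np.exp(x[4]) if alternative else 1.0
    return BranchSiteParams(
        kappa=float(np.exp(x[0])),
        p0=float(p0),
        p1=float(p1),
        omega0=float(omega0),
        omega2=float(min(omega2, _W2_CAP)),
    )


def _bounds(alternative: bool, n_blens: int):
    bounds = [
        (np.log(1e-3), np.log(1e3)),  # kappa
        (-15.0, 15.0),  # p0 logit
        (-15.0, 15.0),  # p1 logit
        (-15.0, 15.0),  # omega0 logistic
    ]
    if alternative:
        bounds.append((np.log(1e-6), np.log(_W2_CAP - 1.0)))
    bounds += [(np.log(_BLEN_FLOOR), np.log(_BLEN_CAP))] * n_blens
    return bounds


_DEFAULT_START = BranchSiteParams(kappa=2.0, p0=0.7, p1=0.2, omega0=0.1, omega2=2.0)


def _random_start(rng: np.random.Generator, alternative: bool) -> BranchSiteParams:
    p0, p1 = rng.dirichlet([4.0, 2.0, 1.0])[:2]
    return BranchSiteParams(
        kappa=float(np.exp(rng.uniform(np.log(0.5), np.log(8.0)))),
        p0=float(np.clip(p0, 1e-3, 0.995)),
        p1=float(np.clip(p1, 1e-3, 0.995)),
        omega0=float(rng.uniform(0.01, 0.6)),
        omega2=float(1.0 + np.exp(rng.uniform(np.log(0.2), np.log(10.0))))
        if alternative
        else 1.0,
    )


def fit_branch_site(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: str = "alternative",
    freqs: CodonFrequencies | None = None,
    optimize_branch_lengths: bool = False,
    n_restarts: int = 5,
    seed: int = DEFAULT_SEED,
    tol: float = 1e-8,
    maxiter: int = 500,
    start: BranchSiteParams | None = None,
) -> FitResult:
    """Fit the null or alternative branch-site model by maximum likelihood.

    Branch lengths are taken from the tree and held fixed unless
    ``optimize_branch_lengths`` is set, in which case they are estimated
    jointly (input lengths seed the optimizer).  Non-convergence after all
    restarts is flagged on the result, never silent.
    """
    if model not in {"null", "alternative"}:
        raise ValueError("model must be 'null' or 'alternative'")
    alternative = model == "alternative"
    check_tree_alignment(tree, aln)
    if alternative and sum(1 for n in tree.postorder() if n.foreground) == 0:
        raise ValueError("alternative model requires at least one foreground branch")
    if freqs is None:
        freqs = estimate_f3x4(aln)

    ptree = PackedTree(tree, aln.taxa)
    states = encode_alignment(aln)
    patterns, counts, _ = compress_patterns(states)
    n_variable = int(
        sum(1 for col in patterns.T if len({s for s in col if s >= 0}) > 1)
    )
    fixed_lengths = ptree.branch_lengths()
    n_blens = ptree.n_branches if optimize_branch_lengths else 0
    n_model_params = 5 if alternative else 4  # incl. kappa

    def objective(x: np.ndarray) -> float:
        try:
            params = _unpack(x, alternative)
            lengths = (
                np.exp(x[n_model_params:]) if optimize_branch_lengths else fixed_lengths
            )
            class_ll = class_site_log_likelihoods(
                ptree, patterns, params, freqs, lengths=lengths
            )
            total, _ = mixture_log_likelihood(class_ll, params.proportions, counts)
        except (ValueError, FloatingPointError):
            return 1e12
        if not np.isfinite(total):
            return 1e12
        return -total

    rng = np.random.default_rng(seed)
    starts = [start or _DEFAULT_START]
    starts += [_random_start(rng, alternative) for _ in range(n_restarts)]

    best = None
    any_success = False
    bounds = _bounds(alternative, n_blens)
    for sp in starts:
        x0 = _pack(sp, alternative)
        if optimize_branch_lengths:
            x0 = np.concatenate(
                [x0, np.log(np.clip(fixed_lengths, _BLEN_FLOOR, _BLEN_CAP))]
            )
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
            any_success = bool(res.success)
        elif res.success and res.fun <= best.fun + 1e-6:
            # a successful start reached (essentially) the same optimum
            any_success = True

    params = _unpack(best.x, alternative)
    lengths = (
        np.exp(best.x[n_model_params:]) if optimize_branch_lengths else fixed_lengths
    )
    message = str(best.message)
    if n_variable == 0:
        message = (
            "alignment has no variable sites; omega parameters are "
            "unidentifiable (flat likelihood). " + message
        )
    return FitResult(
        params=params,
        lnL=float(-best.fun),
        converged=bool(any_success),
        n_free_params=n_model_params + n_blens,
        model=model,
        branch_lengths=np.asarray(lengths, dtype=float),
        message=message,
    )


def likelihood_ratio_test(
    fit_null: FitResult, fit_alt: FitResult, tol: float = 1e-2
) -> LRTResult:
    """Chi-square(1) LRT of the alternative fit against the nested null.

    The statistic ``2 (lA - l0)`` is clipped at zero; an alternative
    log-likelihood below the null beyond ``tol`` raises a warning flag
    (optimizer failure) but still yields a valid, clipped result.
    """
    raw = 2.0 * (fit_alt.lnL - fit_null.lnL)
    warning = None
    if raw < -tol:
        warning = (
            f"alternative lnL ({fit_alt.lnL}) below null lnL ({fit_null.lnL}); "
            "likely optimizer failure, statistic clipped to 0"
        )
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    statistic = max(0.0, raw)
    p_value = float(chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    return LRTResult(statistic=statistic, df=1, p_value=p_value, warning=warning)
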