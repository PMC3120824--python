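"""Orchestration of the full study-shaped analysis.

``run_selection_scan`` fits the null and alternative branch-site models for
each configured foreground scheme, runs the LRT and the site-posterior
analysis, and writes model-summary and selected-sites tables.
``run_physchem_scan`` builds the charge/hydropathy divergence profiles and
runs the rank-sum, G, sliding-window and permutation-regression analyses.

All outputs are plain TSV/JSON; raw p-values are reported without
multiple-testing correction (the handful of tests mirrors the source
analysis).  Identical config and seed give byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import physchem as pc
from .beb import beb_site_posteriors, count_selected_sites, posterior_table
from .codonmodel import estimate_f3x4
from .fit import fit_branch_site, likelihood_ratio_test
from .seqio import (
    A1_DOMAIN_BOUNDS,
    BindingSiteSet,
    build_coordinate_map,
    check_tree_alignment,
    read_amino_alignment,
    read_binding_sites,
    read_codon_alignment,
    read_labeled_tree,
    read_taxon_groups,
)

logger = logging.getLogger("venomscan")


class ConvergenceError(RuntimeError):
    """A model fit failed to converge after all restarts."""


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    ``trees`` maps a foreground-scheme name (e.g. the schemes with and
    without the unconfirmed-resistance taxon) to a labeled Newick file.
    """

    alignment: str
    trees: dict
    groups: str
    binding: str | None = None
    amino_alignment: str | None = None
    reference_taxon: str = "Mus"
    start_pos: int = 524
    thresholds: tuple[float, float] = (0.95, 0.5)
    window: int = 5
    n_perm: int = 1000
    seed: int = 2011
    out_dir: str = "results"
    optimize_branch_lengths: bool = True
    reoptimize_alt_branch_lengths: bool = False
    n_restarts: int = 5
    region: tuple[int, int] = A1_DOMAIN_BOUNDS

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        if hasattr(path, "read"):
            raw = json.load(path)
        else:
            with open(path) as fh:
                raw = json.load(fh)
        cfg = cls(**raw)
        cfg.thresholds = tuple(cfg.thresholds)
        cfg.region = tuple(cfg.region)
        return cfg

    def validate(self, require_trees: bool = True) -> None:
        paths = [self.alignment, self.groups, *self.trees.values()]
        if self.binding:
            paths.append(self.binding)
        if self.amino_alignment:
            paths.append(self.amino_alignment)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValueError(f"missing input files: {missing}")
        if require_trees and not self.trees:
            raise ValueError("at least one foreground scheme is required")
        for thr in self.thresholds:
            if not 0 < thr <= 1:
                raise ValueError(f"threshold {thr} outside (0, 1]")
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be an odd positive integer")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_binding(config: AnalysisConfig) -> BindingSiteSet:
    if config.binding:
        return read_binding_sites(config.binding)
    return BindingSiteSet()


def run_selection_scan(config: AnalysisConfig) -> dict:
    """Branch-site fits, LRTs and site posteriors for every scheme."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    aln = read_codon_alignment(config.alignment)
    freqs = estimate_f3x4(aln)
    amino = aln.translate()
    coord = build_coordinate_map(amino, config.reference_taxon, config.start_pos)
    binding = _load_binding(config)
    thr_high, thr_low = config.thresholds

    results = {}
    model_rows = []
    for scheme, tree_path in config.trees.items():
        t0 = time.perf_counter()
        logger.info("scheme %s: fitting (seed %d)", scheme, config.seed)
        tree = read_labeled_tree(tree_path)
        check_tree_alignment(tree, aln)

        fit0 = fit_branch_site(
            aln,
            tree,
            model="null",
            freqs=freqs,
            optimize_branch_lengths=config.optimize_branch_lengths,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        tree_alt = tree.with_branch_lengths(fit0.branch_lengths)
        fit_a = fit_branch_site(
            aln,
            tree_alt,
            model="alternative",
            freqs=freqs,
            optimize_branch_lengths=config.reoptimize_alt_branch_lengths,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        for fit, tag in ((fit0, "null"), (fit_a, "alt")):
            if not fit.converged:
                raise ConvergenceError(
                    f"scheme {scheme!r}: {tag} model failed to converge: "
                    f"{fit.message}"
                )
            fit.to_json(out_dir / f"fit_{scheme}_{tag}.json")

        lrt = likelihood_ratio_test(fit0, fit_a)
        _json_dump(lrt.to_dict(), out_dir / f"lrt_{scheme}.json")

        posteriors = beb_site_posteriors(aln, tree_alt, fit_a, freqs=freqs)
        sites = posterior_table(posteriors, coord, aln, min_p=thr_low)
        sites.to_csv(out_dir / f"sites_{scheme}.tsv", sep="\t", index=False)

        counts = count_selected_sites(
            posteriors.p_selected,
            [p if p is not None else -(10**6) for p in map(
                coord.position_of_column, range(posteriors.n_sites)
            )],
            threshold=thr_high,
            binding=binding,
            region=config.region,
        )
        for fit, constraint in ((fit0, "omega2=1"), (fit_a, "omega2>1")):
            p = fit.params
            for cls, prop, bg, fg in (
                ("0", p.p0, p.omega0, p.omega0),
                ("1", p.p1, 1.0, 1.0),
                ("2a", p.p2a, p.omega0, p.omega2),
                ("2b", p.p2b, 1.0, p.omega2),
            ):
                model_rows.append(
                    {
                        "scheme": scheme,
                        "model": constraint,
                        "site_class": cls,
                        "proportion": prop,
                        "omega_background": bg,
                        "omega_foreground": fg,
                        "lnL": fit.lnL,
                        "kappa": p.kappa,
                    }
                )
        results[scheme] = {
            "fit_null": fit0,
            "fit_alt": fit_a,
            "lrt": lrt,
            "posteriors": posteriors,
            "sites_table": sites,
            "enrichment_counts": counts,
        }
        logger.info(
            "scheme %s: 2dl=%.3f p=%.3g (%.1fs)",
            scheme,
            lrt.statistic,
            lrt.p_value,
            time.perf_counter() - t0,
        )

    pd.DataFrame(model_rows).to_csv(
        out_dir / "model_summary.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return results


def run_physchem_scan(config: AnalysisConfig, selection_results: dict | None = None) -> dict:
    """Property profiles, rank-sum/G tests, sliding windows, permutations."""
    config.validate(require_trees=False)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.amino_alignment:
        amino = read_amino_alignment(config.amino_alignment)
    else:
        amino = read_codon_alignment(config.alignment).translate()
    groups = read_taxon_groups(config.groups)
    groups.check_covers(amino.taxa)
    binding = _load_binding(config)
    coord = build_coordinate_map(amino, config.reference_taxon, config.start_pos)
    lo, hi = config.region

    tests: dict = {"seed": config.seed, "n_perm": config.n_perm}
    profiles = {}
    for scale in (pc.charge_scale(), pc.hydropathy_scale()):
        t0 = time.perf_counter()
        values = pc.property_values(amino, scale)
        profile = pc.group_delta_profile(values, amino.taxa, groups, coord, binding)
        profile["smoothed_delta"] = pc.sliding_window(
            profile["delta"].to_numpy(), config.window
        )
        profile["smoothed_abs_delta"] = pc.sliding_window(
            profile["abs_delta"].to_numpy(), config.window
        )
        in_region = profile["site"].between(lo, hi)
        region = profile[in_region & profile["abs_delta"].notna()]

        bind_vals = region.loc[region["binding"], "abs_delta"].to_numpy()
        non_vals = region.loc[~region["binding"], "abs_delta"].to_numpy()
        rs_bind_first = pc.rank_sum_test(bind_vals, non_vals)
        rs_non_first = pc.rank_sum_test(non_vals, bind_vals)

        dist = pc.distance_to_binding(region["site"].to_numpy(), binding)
        perm = {}
        for include in (True, False):
            res = pc.permutation_slope_test(
                region["abs_delta"].to_numpy(),
                dist,
                n_perm=config.n_perm,
                include_binding=include,
                seed=config.seed,
                is_binding=region["binding"].to_numpy(),
            )
            tag = "with_binding" if include else "without_binding"
            perm[tag] = res.to_dict()
            pd.DataFrame({"null_slope": res.null_slopes}).to_csv(
                out_dir / f"perm_slopes_{scale.name}_{tag}.tsv",
                sep="\t",
                index=False,
                float_format="%.8g",
            )

        profile.to_csv(
            out_dir / f"profile_{scale.name}.tsv",
            sep="\t",
            index=False,
            float_format="%.6g",
        )
        profiles[scale.name] = profile
        tests[scale.name] = {
            "rank_sum_binding_first": vars(rs_bind_first),
            "rank_sum_nonbinding_first": vars(rs_non_first),
            "permutation_regression": perm,
        }
        logger.info("physchem %s done (%.1fs)", scale.name, time.perf_counter() - t0)

    if selection_results:
        thr_high, _ = config.thresholds
        gtests = {}
        for scheme, res in selection_results.items():
            counts = res["enrichment_counts"]
            table = (
                (counts["binding_selected"],
                 counts["binding_total"] - counts["binding_selected"]),
                (counts["nonbinding_selected"],
                 counts["nonbinding_total"] - counts["nonbinding_selected"]),
            )
            g = pc.g_test(table)
            gtests[scheme] = {
                "threshold": thr_high,
                "counts": counts,
                "G": g.statistic,
                "df": g.df,
                "p_value": g.p_value,
            }
        tests["g_tests"] = gtests

    _json_dump(tests, out_dir / "physchem_tests.json")
    return {"profiles": profiles, "tests": tests}


def run(config: AnalysisConfig) -> dict:
    """Full pipeline: selection scan followed by the physchem scan."""
    selection = run_selection_scan(config)
    physchem = run_physchem_scan(config, selection_results=selection)
    return {"selection": selection, "physchem": physchem}
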