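# venomscan

Tools for detecting episodic positive selection on a venom-targeted protein
and for profiling physicochemical divergence between resistant and
non-resistant taxa along its sequence.

Two analysis tracks are provided:

1. **Branch-site selection test** (`venomscan.codonmodel`, `.likelihood`,
   `.fit`, `.beb`): a GY94-style codon substitution model with F3x4
   frequencies, a four-class branch-site mixture (purifying / neutral
   background classes, with a foreground class allowed omega2 >= 1 on
   designated branches), maximum-likelihood fitting of the null
   (omega2 = 1) and alternative models, a chi-square(1) likelihood-ratio
   test, and empirical-Bayes site posteriors (full prior-grid "BEB"
   integration, plug-in "NEB" fallback) for identifying positively
   selected sites.
2. **Physicochemical divergence scan** (`venomscan.physchem`): per-residue
   charge (K/R = +1, D/E = -1, H = 0 by default) and Kyte-Doolittle
   hydropathy, per-site group-mean change |delta| between resistant and
   non-resistant taxa, Wilcoxon rank-sum comparison of binding vs
   non-binding sites, a G-test of 2x2 enrichment counts, sliding-window
   smoothing, and a permutation test for the regression of |delta| on
   distance to the nearest binding site.

Supporting modules: `venomscan.seqio` (FASTA alignments, Newick trees with
`#1` foreground branch tags, reference-coordinate maps, binding-site and
taxon-group TSVs), `venomscan.synthetic` (branch-site codon simulator with
an event-recording mode, and a resistant-vs-non-resistant amino-acid
property simulator), and `venomscan.pipeline` (study-shaped orchestration
emitting TSV/JSON reports).

## Command line

```sh
# model fits and LRT
venomscan fit --alignment aln.fasta --tree tree.nwk --model null --out fit0.json
venomscan fit --alignment aln.fasta --tree tree.nwk --model alt  --out fitA.json
venomscan lrt --null fit0.json --alt fitA.json

# site posteriors (selected-sites table)
venomscan beb --alignment aln.fasta --tree tree.nwk --fit fitA.json \
    --ref-taxon Mus --start 524 --out sites.tsv

# physicochemical scan
venomscan physchem --alignment aa.fasta --amino --groups groups.tsv \
    --ref-taxon Mus --start 524 --window 5 --n-perm 1000 --seed 2011 --out report/

# synthetic data
venomscan simulate codon    --spec codon_spec.json    --out sim/
venomscan simulate physchem --spec physchem_spec.json --out sim/

# full pipeline from a JSON config
venomscan run --config config.json [--dry-run]
```

Exit codes: 0 success, 2 validation error, 3 convergence failure.

Foreground branches are marked in Newick with the `#1` suffix, e.g.
`((A:0.1,B:0.1)#1:0.05,C:0.2);` puts the AB-stem branch in the foreground.

A pipeline config is a JSON object; minimal example:

```json
{
  "alignment": "aln.fasta",
  "trees": {"include": "tree_inc.nwk", "exclude": "tree_exc.nwk"},
  "groups": "groups.tsv",
  "reference_taxon": "Mus",
  "start_pos": 524,
  "out_dir": "results"
}
```

Optional keys: `binding` (TSV of binding positions; defaults to the 12
canonical botrocetin-binding residues 628-668 in Mus mature-peptide
numbering), `amino_alignment`, `thresholds` (default `[0.95, 0.5]`),
`window`, `n_perm`, `seed`, `optimize_branch_lengths`,
`reoptimize_alt_branch_lengths`, `n_restarts`, `region` (default the A1
domain, 478-728).

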