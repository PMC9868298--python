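# metapep

Peptide-centric quantitative metaproteomics for microbial communities:
taxonomic profiling by lowest-common-ancestor (LCA) peptide assignment,
compositional abundance rollup and diversity, nonparametric differential
abundance, co-occurrence networks with Walktrap communities, PLS-DA with
leave-one-out Q², and taxon-aware functional enrichment.

The package is aimed at analyses of DIA mass-spectrometry metaproteomes
of complex communities — the motivating case is solid-state fermentation
starters (e.g. *Baijiu* Daqu, whose white/yellow/black types reflect
under/well/over-fermentation) sampled across seasons — where peptides are
quantified against a metagenome-derived protein database and the
questions are: *who is there, how does the community differ between
sample types and seasons, which taxa co-occur, and which functions
change?*

## The methods in brief

* **Taxonomic profiling.** Peptides are matched to database proteins by
  exact equality against I/L-equalized tryptic peptides (Leu and Ile are
  isobaric and indistinguishable by MS/MS) and assigned to the lowest
  common ancestor of the matched proteins' taxa. Taxa supported by a
  single peptide are folded into their parent. The abundance of taxon *t*
  in sample *s* is cumulative,
  `A(t,s) = Σ_{peptides assigned to t or descendants} intensity`,
  reported as percent of the root total of *s*; genus diversity is the
  Shannon index `H = −Σ p ln p`.
* **Differential taxa.** Kruskal–Wallis (p < 0.01) followed by pairwise
  Mann–Whitney U (p < 0.01) on percent-of-root values, with per-pair fold
  changes and a seasonal pattern label (`Au+` = higher in autumn than at
  least one other season and never lower).
* **Differential proteins.** Fold-change gate (FC > 2 or FC < 0.5) plus
  Benjamini–Hochberg-adjusted Kruskal–Wallis and pairwise Mann–Whitney
  (adjusted p < 0.05).
* **Co-occurrence.** Genera at mean relative abundance > 0.05 % are
  linked when Spearman rho > 0.8 with Bonferroni-adjusted p < 0.05;
  modules come from the Walktrap random-walk algorithm at maximum
  modularity.
* **PLS-DA.** MetaboAnalyst-style preprocessing (≤50 % missing filter,
  1/5-minimum imputation, sum normalization, log10, auto-scaling), PLS2
  against the one-hot class matrix, and leave-one-out Q² with fold-wise
  re-scaling.
* **Enrichment.** Hypergeometric KO over-representation against explicit
  taxon-specific backgrounds; COG tallies and per-taxon breakdowns of the
  differential proteins.

A fully seeded synthetic-study generator (`metapep.simulate`) emulates a
3-type × 3-season × 10-replicate design with taxon-structured peptide
intensities, planted fold changes, planted co-abundance guilds and
intensity-dependent (MNAR) missingness, and returns the ground truth, so
the entire pipeline is testable without any external data. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a study with a fourfold autumn increase planted on a minor
genus of the black starter, run the taxonomic pipeline, and test:

```python
import metapep as mp
from metapep.profiles import (prune_singletons, rank_profile,
                              shannon_by_sample, taxon_rollup)
from metapep.stats import GroupDesign, differential_taxa

target = "d2.p2.c1.o1.f2.g1"   # a genus at ~0.4 % mean relative abundance
cfg = mp.SimulationConfig(
    seed=1,
    planted_taxon_effects=(
        mp.PlantedEffect(target, "autumn", 4.0, sample_type="black"),
    ),
)
study = mp.simulate_study(cfg)                       # 946 peptides x 90 samples
index = mp.build_index(study.proteome)
assignments = prune_singletons(
    mp.assign_all(study.peptide_matrix.index, index, study.tree), study.tree
)
profile = taxon_rollup(study.peptide_matrix, assignments, study.tree)

black = study.metadata[study.metadata["type"] == "black"]
design = GroupDesign.from_metadata(black, "season")
diff = differential_taxa(
    profile.percent_of_root[list(black.sample_id)], design, alpha=0.01
)
print(diff.loc[target, ["fc_summer_vs_autumn", "kw_p", "significant", "pattern"]])
```

Output:

```
fc_summer_vs_autumn    0.16684
kw_p                     6e-05
significant               True
pattern                    Au+
```

The planted genus is recovered: its summer/autumn abundance ratio is
≈0.17 (autumn-elevated; the realized ratio overshoots the planted 1/4
because percent-of-root abundances are compositional), the omnibus
Kruskal–Wallis p-value is 6·10⁻⁵, and the pattern label `Au+` says the
genus is significantly more abundant in autumn than in the other
seasons. Genus diversity per sample is one call away
(`shannon_by_sample(rank_profile(profile, "genus"))`, e.g. H = 2.355 for
the first black spring sample), and the black-starter co-occurrence
network (`metapep.network.build_network`) recovers the three planted
co-abundance guilds as Walktrap modules.

The same stages are available as a CLI for file-based runs, each writing
a JSON manifest with parameters and SHA-256 checksums:

```sh
metapep all --seed 1 --out-dir runs/demo
metapep network --profile runs/demo/profile.tsv --taxonomy runs/demo/taxonomy.tsv \
    --metadata runs/demo/metadata.tsv --sample-type black --out-prefix runs/demo/net
```

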