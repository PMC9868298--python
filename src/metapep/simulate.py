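"""Synthetic metaproteomic studies with known ground truth.

The generator emulates a solid-state-fermentation starter survey: three
starter types sampled over three seasons with ten replicates each.  It
produces, from one seed, a taxonomy, a protein database, a peptide
quantification matrix with intensity-dependent missingness, protein-level
quantities, functional annotations and the ground truth needed to score
every pipeline stage (true genus abundances, planted differential
features, planted co-abundance blocks).

The generative model, top-down:

* genus log-abundance = base (per genus) + type effect + planted
  season/type fold changes + co-abundance block factor + sample noise,
  all in natural-log space (log-normal abundances);
* protein abundance = genus abundance x fixed protein weight x
  protein-level noise x planted protein fold changes;
* peptide intensity = protein abundance x fixed per-peptide response
  factor, summed over proteins sharing the peptide, times a global scale;
* missingness is missing-not-at-random by default: the probability of a
  missing value falls logistically with log10 intensity, as in DIA data
  where low-abundance peptides drop below the detection limit.

One root seed feeds independent per-stage streams, so enabling one stage
never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .peptides import ProteinRecord, digest, equalize_il, write_fasta_database
from .taxonomy import TaxonNode, TaxonomyTree, write_lineage_table

# stage indices for derived random streams
_STREAMS = {
    "proteome": 1,
    "weights": 2,
    "blocks": 3,
    "abundance": 4,
    "response": 5,
    "missing": 6,
    "annotation": 7,
}


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth fold change: ``target`` (taxon or protein id) is
    multiplied by ``fold`` in group ``group`` (optionally only within one
    sample type)."""

    target: str
    group: str
    fold: float
    sample_type: str | None = None

    def __post_init__(self):
        if not self.fold > 0:
            raise ValueError("planted fold changes must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the reference study
    conditions (3 types x 3 seasons x 10 replicates, ~25% CV)."""

    seed: int = 0
    # taxonomy shape, root -> domain -> phylum -> class -> order -> family -> genus
    n_domains: int = 2
    phyla_per_domain: int = 2
    classes_per_phylum: int = 1
    orders_per_class: int = 1
    families_per_order: int = 2
    genera_per_family: int = 4
    # proteome
    proteins_per_genus: int = 6
    protein_length: tuple[int, int] = (80, 400)
    peptides_per_protein: int = 5
    # design
    types: tuple[str, ...] = ("white", "yellow", "black")
    seasons: tuple[str, ...] = ("spring", "summer", "autumn")
    replicates: int = 10
    # abundance model (natural-log space)
    base_sigma: float = 1.0
    type_sigma: float = 0.5
    noise_sigma: float = 0.25
    protein_noise_sigma: float = 0.15
    weight_sigma: float = 0.5
    response_sigma: float = 0.5
    intensity_scale: float = 1e6
    # missingness: P(missing) = 1 / (1 + exp(slope * (log10 I - midpoint)))
    missingness: str = "mnar"  # mnar | mcar | none
    missing_midpoint: float = 5.0
    missing_slope: float = 2.0
    mcar_rate: float = 0.1
    # co-abundance community structure: a block is a guild of minor genera
    # whose variation is mostly shared.  Members carry a moderate common
    # factor and small independent noise, so within-block correlation is
    # decisively above the network edge threshold after closure, peptide
    # noise and missingness, while the guild's shared swings stay small
    # relative to the per-sample total (large shared swings would induce
    # spurious closure correlations among all other genera and inflate the
    # percent-of-root denominator noise)
    n_blocks: int = 3
    block_size: int = 6
    block_sigma: float = 1.0
    block_member_noise_sigma: float = 0.1
    block_depletion: float = 1.5
    # planted effects
    planted_taxon_effects: tuple[PlantedEffect, ...] = ()
    planted_protein_effects: tuple[PlantedEffect, ...] = ()
    # annotations
    cog_pool: str = "CEGOPQJKLMT"
    n_ko: int = 30
    enriched_ko: str = "K99999"
    enriched_fg_rate: float = 0.8
    enriched_bg_rate: float = 0.05

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stage]])

    @property
    def n_genera(self) -> int:
        return (
            self.n_domains
            * self.phyla_per_domain
            * self.classes_per_phylum
            * self.orders_per_class
            * self.families_per_order
            * self.genera_per_family
        )


@dataclass
class GroundTruth:
    """What the generator actually planted, for scoring the pipeline."""

    genus_relative: pd.DataFrame  # true per-sample intensity shares
    differential_taxa: list[PlantedEffect]
    differential_proteins: list[PlantedEffect]
    blocks: dict[str, int]  # genus -> co-abundance block
    enriched_proteins: frozenset[str]  # carry the enriched KO term


@dataclass
class SimulatedStudy:
    tree: TaxonomyTree
    proteome: list[ProteinRecord]
    peptide_matrix: pd.DataFrame  # equalized peptides x samples, NaN missing
    peptide_proteins: dict[str, frozenset[str]]
    protein_matrix: pd.DataFrame  # proteins x samples, NaN missing
    metadata: pd.DataFrame  # sample_id, type, season
    annotations: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


# -- taxonomy -----------------------------------------------------------------


def simulate_taxonomy(config: SimulationConfig) -> TaxonomyTree:
    """Balanced taxonomy following the standard rank chain; deterministic."""
    if config.n_genera <= 0:
        raise ValueError("degenerate taxonomy shape: no genera")
    nodes = [TaxonNode("root", "root", "root", "root")]
    shape = [
        ("domain", config.n_domains),
        ("phylum", config.phyla_per_domain),
        ("class", config.classes_per_phylum),
        ("order", config.orders_per_class),
        ("family", config.families_per_order),
        ("genus", config.genera_per_family),
    ]
    prefix = {"domain": "d", "phylum": "p", "class": "c",
              "order": "o", "family": "f", "genus": "g"}
    level_ids = ["root"]
    for rank, count in shape:
        next_ids = []
        for parent in level_ids:
            for i in range(1, count + 1):
                stem = "" if parent == "root" else parent + "."
                tid = f"{stem}{prefix[rank]}{i}"
                nodes.append(TaxonNode(tid, parent, rank, tid))
                next_ids.append(tid)
        level_ids = next_ids
    return TaxonomyTree(nodes)


# -- proteome -----------------------------------------------------------------

# 19 residues: ambiguous letters (B, Z, J) excluded; K/R enriched so that
# tryptic fragments average ~8 residues
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_WEIGHTS = np.array(
    [
        0.07,  # A
        0.01,  # C
        0.05,  # D
        0.06,  # E
        0.04,  # F
        0.07,  # G
        0.02,  # H
        0.05,  # I
        0.06,  # K
        0.09,  # L
        0.02,  # M
        0.04,  # N
        0.03,  # P
        0.04,  # Q
        0.06,  # R
        0.07,  # S
        0.05,  # T
        0.07,  # V
        0.01,  # W
        0.09,  # Y
    ]
)
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


def simulate_proteome(
    tree: TaxonomyTree, config: SimulationConfig
) -> list[ProteinRecord]:
    """Random protein sequences, ``proteins_per_genus`` per genus."""
    rng = config.rng("proteome")
    lo, hi = config.protein_length
    records = []
    counter = 0
    for genus in tree.at_rank("genus"):
        for _ in range(config.proteins_per_genus):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(_AA, size=length, p=_AA_WEIGHTS))
            records.append(ProteinRecord(f"prot{counter:05d}", seq, genus))
            counter += 1
    return records


def assign_blocks(genera: list[str], config: SimulationConfig) -> dict[str, int]:
    """Deterministic assignment of genera to co-abundance blocks."""
    needed = config.n_blocks * config.block_size
    if needed > len(genera):
        raise ValueError(
            f"{config.n_blocks} blocks of {config.block_size} genera need "
            f"{needed} genera, taxonomy has {len(genera)}"
        )
    rng = config.rng("blocks")
    order = list(rng.permutation(genera))
    return {
        order[b * config.block_size + i]: b
        for b in range(config.n_blocks)
        for i in range(config.block_size)
    }


# -- experiment ---------------------------------------------------------------


def _select_peptides(
    record: ProteinRecord, rng: np.random.Generator, config: SimulationConfig
) -> list[str]:
    """Detectable peptides of a protein: a random subset of its fully
    tryptic, 7-30-residue, I/L-equalized digest products."""
    products = digest(equalize_il(record.sequence), missed_cleavages=0, min_length=7)
    unique = sorted({p for p in products if len(p) <= 30})
    if not unique:
        return []
    k = min(config.peptides_per_protein, len(unique))
    picked = rng.choice(len(unique), size=k, replace=False)
    return [unique[i] for i in sorted(picked)]


def simulate_experiment(
    tree: TaxonomyTree,
    proteome: list[ProteinRecord],
    config: SimulationConfig,
) -> SimulatedStudy:
    """Generate quantities, metadata, annotations and ground truth."""
    genera = tree.at_rank("genus")
    for eff in config.planted_taxon_effects:
        if eff.target not in tree:
            raise ValueError(f"planted effect on unknown taxon {eff.target!r}")
        if eff.group not in config.seasons:
            raise ValueError(f"planted effect on unknown group {eff.group!r}")
    protein_ids = {p.protein_id for p in proteome}
    for eff in config.planted_protein_effects:
        if eff.target not in protein_ids:
            raise ValueError(
                f"planted effect on unknown protein {eff.target!r}"
            )

    samples = []
    meta_rows = []
    for t in config.types:
        for s in config.seasons:
            for r in range(1, config.replicates + 1):
                sid = f"{t}_{s}_{r:02d}"
                samples.append(sid)
                meta_rows.append({"sample_id": sid, "type": t, "season": s})
    metadata = pd.DataFrame(meta_rows)
    n_samples = len(samples)

    blocks = (
        assign_blocks(genera, config) if config.n_blocks > 0 else {}
    )

    # genus log-abundances -----------------------------------------------
    rng_ab = config.rng("abundance")
    base = rng_ab.normal(0.0, config.base_sigma, size=len(genera))
    type_eff = {
        t: rng_ab.normal(0.0, config.type_sigma, size=len(genera))
        for t in config.types
    }
    block_z = rng_ab.normal(
        0.0, config.block_sigma, size=(max(config.n_blocks, 1), n_samples)
    )
    noise_unit = rng_ab.normal(0.0, 1.0, size=(len(genera), n_samples))

    log_genus = np.zeros((len(genera), n_samples))
    for gi, genus in enumerate(genera):
        noise_sd = (
            config.block_member_noise_sigma
            if genus in blocks
            else config.noise_sigma
        )
        for si, sid in enumerate(samples):
            t, season = metadata.loc[si, "type"], metadata.loc[si, "season"]
            val = base[gi] + type_eff[t][gi] + noise_sd * noise_unit[gi, si]
            if genus in blocks:
                val += block_z[blocks[genus], si] - config.block_depletion
            for eff in config.planted_taxon_effects:
                if (
                    eff.group == season
                    and (eff.sample_type is None or eff.sample_type == t)
                    and tree.is_ancestor(eff.target, genus)
                ):
                    val += np.log(eff.fold)
            log_genus[gi, si] = val
    genus_abund = np.exp(log_genus)

    # protein abundances --------------------------------------------------
    rng_w = config.rng("weights")
    weights = np.exp(
        rng_w.normal(0.0, config.weight_sigma, size=len(proteome))
    )
    prot_noise = rng_w.normal(
        0.0, config.protein_noise_sigma, size=(len(proteome), n_samples)
    )
    genus_index = {g: i for i, g in enumerate(genera)}
    season_of = metadata["season"].to_numpy()
    type_of = metadata["type"].to_numpy()
    prot_abund = np.empty((len(proteome), n_samples))
    for pi, rec in enumerate(proteome):
        row = (
            genus_abund[genus_index[rec.taxon_id]]
            * weights[pi]
            * np.exp(prot_noise[pi])
        )
        for eff in config.planted_protein_effects:
            if eff.target == rec.protein_id:
                mask = season_of == eff.group
                if eff.sample_type is not None:
                    mask &= type_of == eff.sample_type
                row = np.where(mask, row * eff.fold, row)
        prot_abund[pi] = row

    # peptide intensities -------------------------------------------------
    rng_r = config.rng("response")
    pep_rows: dict[str, np.ndarray] = {}
    pep_proteins: dict[str, set[str]] = {}
    true_genus_intensity = np.zeros((len(genera), n_samples))
    for pi, rec in enumerate(proteome):
        for pep in _select_peptides(rec, rng_r, config):
            response = np.exp(rng_r.normal(0.0, config.response_sigma))
            contrib = prot_abund[pi] * response * config.intensity_scale
            if pep in pep_rows:
                pep_rows[pep] = pep_rows[pep] + contrib
            else:
                pep_rows[pep] = contrib
            pep_proteins.setdefault(pep, set()).add(rec.protein_id)
            true_genus_intensity[genus_index[rec.taxon_id]] += contrib

    peptides = sorted(pep_rows)
    intensity = np.vstack([pep_rows[p] for p in peptides])

    # missingness ---------------------------------------------------------
    rng_m = config.rng("missing")
    if config.missingness == "mnar":
        with np.errstate(over="ignore"):
            p_missing = 1.0 / (
                1.0
                + np.exp(
                    config.missing_slope
                    * (np.log10(intensity) - config.missing_midpoint)
                )
            )
    elif config.missingness == "mcar":
        p_missing = np.full_like(intensity, config.mcar_rate)
    elif config.missingness == "none":
        p_missing = np.zeros_like(intensity)
    else:
        raise ValueError(f"unknown missingness model {config.missingness!r}")
    missing = rng_m.random(intensity.shape) < p_missing
    observed = np.where(missing, np.nan, intensity)

    peptide_matrix = pd.DataFrame(observed, index=peptides, columns=samples)

    # protein matrix: sum of observed peptide intensities per protein
    prot_rows = {}
    for pi, rec in enumerate(proteome):
        own = [
            p for p in pep_proteins if rec.protein_id in pep_proteins[p]
        ]
        if not own:
            prot_rows[rec.protein_id] = np.full(n_samples, np.nan)
            continue
        sub = peptide_matrix.loc[own]
        total = sub.sum(axis=0, skipna=True).to_numpy()
        all_missing = sub.isna().all(axis=0).to_numpy()
        prot_rows[rec.protein_id] = np.where(all_missing, np.nan, total)
    protein_matrix = pd.DataFrame.from_dict(
        prot_rows, orient="index", columns=samples
    )

    # annotations ---------------------------------------------------------
    rng_a = config.rng("annotation")
    planted_ids = {e.target for e in config.planted_protein_effects}
    ko_pool = [f"K{i:05d}" for i in range(1, config.n_ko + 1)]
    ann_rows = []
    enriched: set[str] = set()
    for rec in proteome:
        cogs = frozenset(
            rng_a.choice(
                list(config.cog_pool), size=int(rng_a.integers(1, 3)),
                replace=False,
            )
        )
        kos = {ko_pool[int(rng_a.integers(0, len(ko_pool)))]}
        rate = (
            config.enriched_fg_rate
            if rec.protein_id in planted_ids
            else config.enriched_bg_rate
        )
        if rng_a.random() < rate:
            kos.add(config.enriched_ko)
            enriched.add(rec.protein_id)
        ecs = frozenset()
        if rng_a.random() < 0.3:
            ecs = frozenset({f"3.2.1.{int(rng_a.integers(1, 99))}"})
        lineage_names = [
            tree.nodes[tid].name for _, tid in tree.lineage(rec.taxon_id)
        ]
        ann_rows.append(
            {
                "protein_id": rec.protein_id,
                "cog_categories": cogs,
                "ko_ids": frozenset(kos),
                "ec": ecs,
                "taxon_string": ";".join(lineage_names),
            }
        )
    annotations = pd.DataFrame(ann_rows).set_index("protein_id")

    shares = true_genus_intensity / true_genus_intensity.sum(axis=0)
    truth = GroundTruth(
        genus_relative=pd.DataFrame(shares, index=genera, columns=samples),
        differential_taxa=list(config.planted_taxon_effects),
        differential_proteins=list(config.planted_protein_effects),
        blocks=blocks,
        enriched_proteins=frozenset(enriched),
    )
    return SimulatedStudy(
        tree=tree,
        proteome=proteome,
        peptide_matrix=peptide_matrix,
        peptide_proteins={p: frozenset(v) for p, v in pep_proteins.items()},
        protein_matrix=protein_matrix,
        metadata=metadata,
        annotations=annotations,
        truth=truth,
        config=config,
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Taxonomy + proteome + experiment in one call."""
    tree = simulate_taxonomy(config)
    proteome = simulate_proteome(tree, config)
    return simulate_experiment(tree, proteome, config)


# -- writers ------------------------------------------------------------------


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every file the pipeline reads, plus ground-truth tables."""
    from .enrichment import write_annotations
    from .io import write_metadata, write_quant_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxonomy": outdir / "taxonomy.tsv",
        "fasta": outdir / "proteome.fasta",
        "protein_taxa": outdir / "protein_taxa.tsv",
        "peptides": outdir / "peptide_quant.tsv",
        "proteins": outdir / "protein_quant.tsv",
        "metadata": outdir / "metadata.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth_genus": outdir / "ground_truth_genus_relative.tsv",
        "truth_effects": outdir / "ground_truth_effects.tsv",
        "truth_blocks": outdir / "ground_truth_blocks.tsv",
    }
    write_lineage_table(study.tree, paths["taxonomy"])
    write_fasta_database(study.proteome, paths["fasta"], paths["protein_taxa"])
    leading = {
        pep: sorted(prots)[0] for pep, prots in study.peptide_proteins.items()
    }
    write_quant_matrix(study.peptide_matrix, paths["peptides"], proteins=leading)
    write_quant_matrix(study.protein_matrix, paths["proteins"])
    write_metadata(study.metadata, paths["metadata"])
    write_annotations(study.annotations, paths["annotations"])
    study.truth.genus_relative.rename_axis("taxon_id").to_csv(
        paths["truth_genus"], sep="\t"
    )
    with open(paths["truth_effects"], "w", encoding="utf-8") as fh:
        fh.write("kind\ttarget\tgroup\tfold\tsample_type\n")
        for kind, effects in (
            ("taxon", study.truth.differential_taxa),
            ("protein", study.truth.differential_proteins),
        ):
            for e in effects:
                fh.write(
                    f"{kind}\t{e.target}\t{e.group}\t{e.fold}\t"
                    f"{e.sample_type or ''}\n"
                )
    with open(paths["truth_blocks"], "w", encoding="utf-8") as fh:
        fh.write("taxon_id\tblock\n")
        for genus in sorted(study.truth.blocks):
            fh.write(f"{genus}\t{study.truth.blocks[genus]}\n")
    return paths
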