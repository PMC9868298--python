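"""Taxon abundance profiles: rollup of peptide quantities onto the taxonomy.

A taxon's abundance in a sample is the sum of the quantities of all
peptides assigned to it or to any of its descendants (cumulative rollup),
expressed as a percentage of the abundance of the root taxon, i.e. of all
taxonomically annotated signal in that sample.  A count mode replaces
intensities by presence (peptide observed in the sample) for a robustness
check of the intensity-based profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .peptides import PeptideAssignment
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)


def validate_quant_matrix(matrix: pd.DataFrame) -> None:
    """A peptide quantification matrix: peptides x samples, NaN = missing."""
    if (matrix.fillna(0) < 0).any().any():
        raise ValueError("peptide quantities must be non-negative")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids in quantification matrix")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate peptides in quantification matrix")


def prune_singletons(
    assignments: Sequence[PeptideAssignment], tree: TaxonomyTree
) -> list[PeptideAssignment]:
    """Reassign peptides of singleton taxa to their parents, to fixpoint.

    A taxon (other than root) supported by exactly one peptide across the
    whole dataset is considered spurious: it is removed and its peptide
    moves to the parental taxon.  The rule is applied bottom-up (deepest
    taxa first) and iterated until no singleton remains, so a peptide can
    cascade several levels.  The peptide set and total quantities are
    unchanged; only taxon labels move.
    """
    current = {i: a.taxon_id for i, a in enumerate(assignments)}
    while True:
        counts: dict[str, int] = {}
        for tid in current.values():
            if tid is not None:
                counts[tid] = counts.get(tid, 0) + 1
        singles = [
            t for t, c in counts.items() if c == 1 and t != tree.root_id
        ]
        if not singles:
            break
        max_depth = max(tree.depth(t) for t in singles)
        level = {t for t in singles if tree.depth(t) == max_depth}
        for i, tid in current.items():
            if tid in level:
                current[i] = tree.parent(tid)
    return [
        PeptideAssignment(a.peptide, a.proteins, current[i])
        for i, a in enumerate(assignments)
    ]


@dataclass
class TaxonAbundanceProfile:
    """Cumulative taxon abundance per sample plus percent-of-root.

    ``cumulative`` and ``percent_of_root`` are taxa x samples frames; the
    root row of ``percent_of_root`` is 100 for every sample that carries
    any annotated signal (NaN otherwise).
    """

    cumulative: pd.DataFrame
    percent_of_root: pd.DataFrame
    mode: str
    tree: TaxonomyTree

    @property
    def samples(self) -> list[str]:
        return list(self.cumulative.columns)


def taxon_rollup(
    matrix: pd.DataFrame,
    assignments: Sequence[PeptideAssignment],
    tree: TaxonomyTree,
    mode: str = "intensity",
) -> TaxonAbundanceProfile:
    """Accumulate peptide quantities onto the taxonomy.

    intensity mode: missing intensities contribute 0 (no imputation);
    count mode: a peptide contributes 1 to a sample iff its intensity is
    observed (non-missing and > 0) there.
    """
    if mode not in ("intensity", "count"):
        raise ValueError(f"unknown rollup mode {mode!r}")
    validate_quant_matrix(matrix)
    assigned = [a for a in assignments if a.taxon_id is not None]
    missing_peps = [a.peptide for a in assigned if a.peptide not in matrix.index]
    if missing_peps:
        raise ValueError(
            f"{len(missing_peps)} assigned peptides absent from the "
            f"quantification matrix (first: {missing_peps[0]!r})"
        )

    samples = list(matrix.columns)
    if mode == "intensity":
        values = matrix.fillna(0.0)
    else:
        values = (matrix.fillna(0.0) > 0).astype(float)

    direct = pd.DataFrame(
        0.0, index=sorted(tree.nodes), columns=samples
    )
    for a in assigned:
        direct.loc[a.taxon_id] += values.loc[a.peptide].to_numpy(dtype=float)

    cumulative = direct.copy()
    for tid in tree.postorder():
        node = tree.nodes[tid]
        if not node.is_root:
            cumulative.loc[node.parent_id] += cumulative.loc[tid]

    root_total = cumulative.loc[tree.root_id]
    percent = cumulative.divide(root_total.where(root_total > 0), axis=1) * 100
    dead = [s for s in samples if not root_total[s] > 0]
    if dead:
        logger.warning(
            "samples with no annotated signal, percent-of-root undefined: %s",
            ", ".join(map(str, dead)),
        )
    return TaxonAbundanceProfile(cumulative, percent, mode, tree)


def rank_profile(profile: TaxonAbundanceProfile, rank: str) -> pd.DataFrame:
    """Relative abundances (fractions of root, 0..1) of all taxa at a rank."""
    taxa = profile.tree.at_rank(rank)
    return profile.percent_of_root.loc[taxa] / 100.0


def shannon_index(abundances: Iterable[float]) -> float:
    """Shannon diversity H = -sum p ln p (nats) over positive entries.

    The vector is renormalized to sum to one over its positive entries;
    an all-zero vector has no defined diversity.
    """
    vec = np.asarray(list(abundances), dtype=float)
    vec = vec[~np.isnan(vec)]
    if (vec < 0).any():
        raise ValueError("abundances must be non-negative")
    pos = vec[vec > 0]
    if pos.size == 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = pos / pos.sum()
    return float(-(p * np.log(p)).sum())


def shannon_by_sample(table: pd.DataFrame) -> pd.Series:
    """Shannon index per sample (columns) of a taxa x samples table."""
    return pd.Series(
        {s: shannon_index(table[s]) for s in table.columns}, name="shannon"
    )


def group_ratio(
    profile: TaxonAbundanceProfile,
    numerator: Iterable[str],
    denominator: Iterable[str],
) -> pd.Series:
    """Per-sample ratio of summed cumulative abundances of two taxon sets
    (e.g. fungi over bacteria).  Zero denominator gives a missing value."""
    num_taxa = list(numerator)
    den_taxa = list(denominator)
    for tid in num_taxa + den_taxa:
        profile.tree._require(tid)
    num = profile.cumulative.loc[num_taxa].sum(axis=0)
    den = profile.cumulative.loc[den_taxa].sum(axis=0)
    return (num / den.where(den > 0)).rename("group_ratio")


# -- profile IO ---------------------------------------------------------------


def write_profile(profile: TaxonAbundanceProfile, path: str | Path) -> None:
    """Long-format TSV: taxon_id, rank, name, sample, cumulative,
    percent_of_root.  Missing percent encoded as empty string."""
    tree = profile.tree
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "taxon_id\trank\tname\tsample\tcumulative\tpercent_of_root\n"
        )
        for tid in sorted(tree.nodes):
            node = tree.nodes[tid]
            for s in profile.samples:
                cum = profile.cumulative.at[tid, s]
                pct = profile.percent_of_root.at[tid, s]
                pct_str = "" if math.isnan(pct) else repr(float(pct))
                fh.write(
                    f"{tid}\t{node.rank}\t{node.name}\t{s}\t"
                    f"{float(cum)!r}\t{pct_str}\n"
                )


def read_profile(path: str | Path, tree: TaxonomyTree) -> TaxonAbundanceProfile:
    long = pd.read_csv(path, sep="\t", dtype={"taxon_id": str, "sample": str})
    cumulative = long.pivot(
        index="taxon_id", columns="sample", values="cumulative"
    )
    percent = long.pivot(
        index="taxon_id", columns="sample", values="percent_of_root"
    )
    cumulative.columns.name = None
    percent.columns.name = None
    return TaxonAbundanceProfile(
        cumulative.astype(float), percent.astype(float), "intensity", tree
    )
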