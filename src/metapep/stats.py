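"""Nonparametric differential-abundance testing.

Two cascades are used, mirroring common metaproteomics practice:

* taxa: Kruskal-Wallis across groups (raw p < 0.01) followed by pairwise
  Mann-Whitney U tests (raw p < 0.01);
* proteins: a fold-change gate (FC > 2 or FC < 0.5) combined with
  Benjamini-Hochberg-adjusted Kruskal-Wallis and pairwise Mann-Whitney
  tests (adjusted p < 0.05).

Each differential feature additionally receives a seasonal pattern label
(e.g. ``Au+`` for "significantly more abundant in autumn than at least one
other season, and never significantly less abundant than any").
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# -- primitive tests ----------------------------------------------------------


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with average-rank ties.

    The exact null distribution is used when both samples have at most 8
    observations (enumerated over permutations in the presence of ties);
    larger samples use the tie-corrected normal approximation with
    continuity correction.  Returns ``(U, p)`` with U counted for the
    first sample.
    """
    a = _clean_vector(a, "a")
    b = _clean_vector(b, "b")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # complete tie: no evidence either way
        return float(len(a) * len(b) / 2), 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    if max(len(a), len(b)) <= 8:
        # exact: closed-form null without ties, full enumeration with
        method = "exact" if no_ties else sps.PermutationMethod(
            n_resamples=2_000_000
        )
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-squared (k-1 df).

    A completely tied dataset carries no rank information and returns
    ``(0, 1)`` instead of an error.
    """
    cleaned = [_clean_vector(g, f"group {i}") for i, g in enumerate(groups)]
    if len(cleaned) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    pooled = np.concatenate(cleaned)
    if pooled.size < 3:
        raise ValueError("kruskal_wallis needs at least 3 observations")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.kruskal(*cleaned)
    return float(res.statistic), float(res.pvalue)


def _clean_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"vector {name} is empty after dropping missing")
    return arr


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, position-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(a, b) -> float:
    """Ratio of group means, missing values dropped.

    Returns ``inf`` when only the denominator mean is zero and ``nan``
    when both means are zero (undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return float("nan")
    ma, mb = float(a.mean()), float(b.mean())
    if mb == 0:
        return float("inf") if ma > 0 else float("nan")
    return ma / mb


# -- experimental design ------------------------------------------------------


@dataclass
class GroupDesign:
    """Maps each sample id to a group label, with a fixed group order."""

    labels: Mapping[str, str]
    groups: Sequence[str]

    def __post_init__(self):
        self.groups = list(self.groups)
        if len(self.groups) < 2:
            raise ValueError("a design needs at least 2 groups")
        unknown = set(self.labels.values()) - set(self.groups)
        if unknown:
            raise ValueError(f"labels reference unknown groups: {unknown}")
        for g in self.groups:
            if g not in set(self.labels.values()):
                raise ValueError(f"group {g!r} has no samples")

    @classmethod
    def from_metadata(
        cls, metadata: pd.DataFrame, column: str, groups: Sequence[str] | None = None
    ) -> "GroupDesign":
        labels = dict(zip(metadata["sample_id"], metadata[column]))
        if groups is None:
            groups = list(dict.fromkeys(metadata[column]))
        return cls(labels, groups)

    def samples_of(self, group: str, universe: Iterable[str]) -> list[str]:
        return [s for s in universe if self.labels.get(s) == group]

    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.groups, 2))


_SEASON_CODES = {"spring": "Sp", "summer": "Su", "autumn": "Au", "winter": "Wi"}


def group_code(group: str) -> str:
    return _SEASON_CODES.get(group.lower(), group[:2].capitalize())


def season_pattern(
    higher: Mapping[tuple[str, str], bool], groups: Sequence[str]
) -> str:
    """Pattern label from directed pairwise significance flags.

    ``higher[(a, b)]`` is True when a is significantly more abundant than
    b.  A group earns a ``+`` when it is significantly higher than at
    least one other group and never significantly lower than any; with no
    significant pair the label is ``NS``.
    """
    for a, b in itertools.combinations(groups, 2):
        if higher.get((a, b), False) and higher.get((b, a), False):
            raise ValueError(
                f"contradictory flags: both {a}>{b} and {b}>{a} significant"
            )
    plus = []
    for g in groups:
        wins = any(higher.get((g, o), False) for o in groups if o != g)
        losses = any(higher.get((o, g), False) for o in groups if o != g)
        if wins and not losses:
            plus.append(g)
    if not plus:
        return "NS"
    return "".join(group_code(g) + "+" for g in plus)


# -- differential tables ------------------------------------------------------


def _per_feature_stats(
    matrix: pd.DataFrame, design: GroupDesign
) -> pd.DataFrame:
    """Raw KW p, pairwise FC and MWU p for every feature (row) of a
    features x samples matrix."""
    samples = [s for s in matrix.columns if s in design.labels]
    group_cols = {
        g: design.samples_of(g, samples) for g in design.groups
    }
    for g, cols in group_cols.items():
        if not cols:
            raise ValueError(f"group {g!r} absent from the matrix columns")
        if len(cols) < 3:
            logger.warning(
                "group %r has only %d samples; tests will be underpowered",
                g,
                len(cols),
            )
    rows = []
    pairs = design.pairs()
    for feature, values in matrix.iterrows():
        by_group = {g: values[cols].to_numpy(dtype=float) for g, cols in group_cols.items()}
        row: dict[str, float] = {}
        try:
            _, row["kw_p"] = kruskal_wallis(list(by_group.values()))
        except ValueError:
            row["kw_p"] = 1.0
        for a, b in pairs:
            key = f"{a}_vs_{b}"
            row[f"fc_{key}"] = fold_change(by_group[a], by_group[b])
            try:
                _, row[f"p_{key}"] = mann_whitney_u(by_group[a], by_group[b])
            except ValueError:
                row[f"p_{key}"] = 1.0
        row["min_pair_p"] = min(row[f"p_{a}_vs_{b}"] for a, b in pairs)
        rows.append(pd.Series(row, name=feature))
    return pd.DataFrame(rows)


def _patterns(
    table: pd.DataFrame,
    design: GroupDesign,
    pair_significant: Mapping[tuple[str, str], pd.Series],
) -> pd.Series:
    out = {}
    for feature in table.index:
        higher: dict[tuple[str, str], bool] = {}
        for a, b in design.pairs():
            if not bool(pair_significant[(a, b)].loc[feature]):
                continue
            fc = table.at[feature, f"fc_{a}_vs_{b}"]
            if np.isnan(fc):
                continue
            if fc > 1:
                higher[(a, b)] = True
            elif fc < 1:
                higher[(b, a)] = True
        out[feature] = season_pattern(higher, design.groups)
    return pd.Series(out, name="pattern")


def differential_taxa(
    profile_table: pd.DataFrame,
    design: GroupDesign,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Differential-taxon table on percent-of-root abundances.

    A taxon is flagged when the Kruskal-Wallis p-value and at least one
    pairwise Mann-Whitney p-value fall below ``alpha`` (both unadjusted;
    multiplicity correction is reserved for the protein-level cascade).
    ``profile_table`` is taxa x samples, typically
    ``TaxonAbundanceProfile.percent_of_root``.
    """
    table = _per_feature_stats(profile_table, design)
    kw_gate = table["kw_p"] < alpha
    pair_sig = {
        (a, b): (table[f"p_{a}_vs_{b}"] < alpha) & kw_gate
        for a, b in design.pairs()
    }
    table["significant"] = kw_gate & (table["min_pair_p"] < alpha)
    table["pattern"] = _patterns(table, design, pair_sig)
    table.index.name = "feature_id"
    return table


def differential_features(
    matrix: pd.DataFrame,
    design: GroupDesign,
    fc_lo: float = 0.5,
    fc_hi: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-feature (protein) table with BH adjustment and FC gate.

    BH is applied across features to the Kruskal-Wallis p-values and,
    separately within each group pair, to the Mann-Whitney p-values.  A
    feature is differential for a pair iff the fold change passes the gate
    (FC > fc_hi or FC < fc_lo) and both adjusted p-values are below
    ``alpha``; it is flagged overall when any pair is differential.
    """
    table = _per_feature_stats(matrix, design)
    table["kw_adj_p"] = bh_adjust(table["kw_p"])
    kw_gate = table["kw_adj_p"] < alpha
    pair_sig: dict[tuple[str, str], pd.Series] = {}
    for a, b in design.pairs():
        key = f"{a}_vs_{b}"
        table[f"adj_p_{key}"] = bh_adjust(table[f"p_{key}"])
        fc = table[f"fc_{key}"]
        gate = (fc > fc_hi) | (fc < fc_lo)
        pair_sig[(a, b)] = gate & (table[f"adj_p_{key}"] < alpha) & kw_gate
    table["significant"] = pd.DataFrame(pair_sig).any(axis=1)
    table["pattern"] = _patterns(table, design, pair_sig)
    table.index.name = "feature_id"
    return table
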