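"""Functional summaries of differential proteins and KO over-representation.

Differential proteins are tallied per COG category and per taxon, and KEGG
Orthology (KO) terms are tested for over-representation with a one-sided
hypergeometric test against an explicit, taxon-specific background (no
online KEGG queries: backgrounds are supplied as tables).
"""

from __future__ import annotations

import logging
from collections.abc import Collection, Iterable, Mapping
from pathlib import Path

import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

COG_ALPHABET = set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

UNANNOTATED = "unannotated"
UNASSIGNED = "unassigned"


def read_annotations(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read an eggNOG-mapper-style annotation TSV.

    Returns a frame indexed by protein id with columns ``cog_categories``
    (frozenset of single letters), ``ko_ids`` (frozenset), ``ec``
    (frozenset) and ``taxon_string`` (semicolon-separated lineage text).
    Column names are configurable via ``columns`` with keys ``query``,
    ``cog``, ``ko``, ``ec``, ``taxonomy``.
    """
    names = {
        "query": "query",
        "cog": "COG_category",
        "ko": "KEGG_ko",
        "ec": "EC",
        "taxonomy": "taxonomy",
    }
    names.update(columns or {})
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if names["query"] not in raw.columns:
        raise ValueError(
            f"annotation table {path}: missing column {names['query']!r}"
        )
    out = pd.DataFrame(index=raw[names["query"]])
    out.index.name = "protein_id"
    if out.index.duplicated().any():
        raise ValueError("duplicate protein ids in annotation table")

    def split_set(col: str, sep: str = ",") -> list[frozenset[str]]:
        if names[col] not in raw.columns:
            return [frozenset()] * len(raw)
        return [
            frozenset(
                t.strip()
                for t in str(v).replace("ko:", "").split(sep)
                if t.strip() and t.strip() != "-"
            )
            for v in raw[names[col]]
        ]

    out["cog_categories"] = [
        frozenset(c for c in str(v) if c in COG_ALPHABET)
        for v in (raw[names["cog"]] if names["cog"] in raw.columns else [""] * len(raw))
    ]
    out["ko_ids"] = split_set("ko")
    out["ec"] = split_set("ec")
    out["taxon_string"] = (
        raw[names["taxonomy"]].tolist()
        if names["taxonomy"] in raw.columns
        else [""] * len(raw)
    )
    return out


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("query\tCOG_category\tKEGG_ko\tEC\ttaxonomy\n")
        for pid, row in annotations.iterrows():
            cog = "".join(sorted(row["cog_categories"])) or "-"
            ko = ",".join(f"ko:{k}" for k in sorted(row["ko_ids"])) or "-"
            ec = ",".join(sorted(row["ec"])) or "-"
            fh.write(f"{pid}\t{cog}\t{ko}\t{ec}\t{row['taxon_string']}\n")


def cog_counts(
    diff: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Counts of differential proteins per (COG category, pattern label).

    A protein annotated with several categories counts once per category;
    proteins absent from the annotation table land in an ``unannotated``
    row.  Only rows of ``diff`` flagged significant are tallied.
    """
    counts: dict[tuple[str, str], int] = {}
    sig = diff[diff["significant"]] if "significant" in diff else diff
    for pid, row in sig.iterrows():
        pattern = row.get("pattern", "NS")
        if pid in annotations.index:
            cats = annotations.at[pid, "cog_categories"] or frozenset(
                [UNANNOTATED]
            )
        else:
            cats = frozenset([UNANNOTATED])
        for cat in cats:
            counts[(cat, pattern)] = counts.get((cat, pattern), 0) + 1
    if not counts:
        return pd.DataFrame(dtype=int)
    table = pd.Series(counts).unstack(fill_value=0)
    table.index.name = "cog_category"
    table.columns.name = "pattern"
    return table.sort_index()


def resolve_taxon_string(
    taxon_string: str, tree: TaxonomyTree
) -> str | None:
    """Deepest tree node whose name appears in a lineage text.

    The lineage text is split on ``;`` or ``|``; names are matched
    case-sensitively against node names.
    """
    parts = [
        p.strip()
        for p in taxon_string.replace("|", ";").split(";")
        if p.strip()
    ]
    by_name: dict[str, str] = {}
    for tid, node in tree.nodes.items():
        by_name.setdefault(node.name, tid)
    best, best_depth = None, -1
    for part in parts:
        tid = by_name.get(part)
        if tid is not None and tree.depth(tid) > best_depth:
            best, best_depth = tid, tree.depth(tid)
    return best


def taxon_breakdown(
    diff: pd.DataFrame,
    annotations: pd.DataFrame,
    tree: TaxonomyTree,
    rank: str = "class",
) -> pd.Series:
    """Percentage of differential proteins per taxon at ``rank``.

    Proportions are over the annotated differential proteins; proteins
    whose lineage text cannot be resolved to the tree fall into an
    ``unassigned`` bucket (excluded from the denominator).
    """
    sig = diff[diff["significant"]] if "significant" in diff else diff
    tallies: dict[str, int] = {}
    annotated = 0
    for pid in sig.index:
        if pid not in annotations.index:
            continue
        annotated += 1
        node = resolve_taxon_string(annotations.at[pid, "taxon_string"], tree)
        bucket = UNASSIGNED
        if node is not None:
            at_rank = tree.ancestor_at_rank(node, rank)
            if at_rank is not None:
                bucket = tree.nodes[at_rank].name
        tallies[bucket] = tallies.get(bucket, 0) + 1
    denom = annotated - tallies.get(UNASSIGNED, 0)
    if denom == 0:
        return pd.Series(dtype=float, name="percent")
    out = pd.Series(
        {
            k: 100.0 * v / denom
            for k, v in tallies.items()
            if k != UNASSIGNED
        },
        name="percent",
    )
    return out.sort_values(ascending=False)


def enrich_terms(
    fg: Iterable[str],
    background: Mapping[str, Collection[str]],
    universe: Collection[str] | None = None,
    min_size: int = 2,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of terms in ``fg``.

    ``background`` maps each term to the set of universe items carrying
    it; ``universe`` defaults to the union of all term sets.  Foreground
    items outside the universe are logged and dropped.  For each term with
    at least ``min_size`` background hits, p = P[X >= fg_hits] with X ~
    Hypergeometric(bg_size, bg_hits, fg_size); BH adjustment is across the
    tested terms.
    """
    if not background:
        raise ValueError("background is empty")
    if universe is None:
        universe = set().union(*background.values())
    universe = set(universe)
    fg_set = set(fg)
    outside = fg_set - universe
    if outside:
        logger.warning(
            "%d foreground items outside the background universe dropped",
            len(outside),
        )
        fg_set -= outside
    bg_size, fg_size = len(universe), len(fg_set)
    rows = []
    for term in sorted(background):
        members = set(background[term]) & universe
        bg_hits = len(members)
        if bg_hits < min_size:
            continue
        fg_hits = len(fg_set & members)
        p = float(sps.hypergeom.sf(fg_hits - 1, bg_size, bg_hits, fg_size))
        rows.append(
            {
                "term": term,
                "fg_hits": fg_hits,
                "fg_size": fg_size,
                "bg_hits": bg_hits,
                "bg_size": bg_size,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "fg_hits", "fg_size", "bg_hits", "bg_size", "p"]
    ).set_index("term")
    if len(result):
        result["adj_p"] = bh_adjust(result["p"])
    else:
        result["adj_p"] = pd.Series(dtype=float)
    return result


def enrich_by_taxon(
    diff: pd.DataFrame,
    annotations: pd.DataFrame,
    backgrounds: Mapping[str, Mapping[str, Collection[str]]],
    tree: TaxonomyTree,
    rank: str = "class",
    min_size: int = 2,
) -> dict[str, pd.DataFrame]:
    """KO enrichment per dominant taxon at ``rank``.

    Differential proteins are grouped by their taxon at ``rank`` (via the
    annotation lineage text); each group's KO set (set semantics: one
    contribution per protein-KO pair collapsed to unique KOs) is tested
    against that taxon's background (``backgrounds[taxon_name]``).
    """
    sig = diff[diff["significant"]] if "significant" in diff else diff
    ko_by_taxon: dict[str, set[str]] = {}
    for pid in sig.index:
        if pid not in annotations.index:
            continue
        node = resolve_taxon_string(annotations.at[pid, "taxon_string"], tree)
        if node is None:
            continue
        at_rank = tree.ancestor_at_rank(node, rank)
        if at_rank is None:
            continue
        name = tree.nodes[at_rank].name
        ko_by_taxon.setdefault(name, set()).update(
            annotations.at[pid, "ko_ids"]
        )
    out = {}
    for taxon, kos in sorted(ko_by_taxon.items()):
        if taxon not in backgrounds:
            logger.warning("no background for taxon %r; skipped", taxon)
            continue
        out[taxon] = enrich_terms(kos, backgrounds[taxon], min_size=min_size)
    return out


def read_background(path: str | Path) -> dict[str, dict[str, set[str]]]:
    """Read taxon-specific term backgrounds: TSV taxon, term, gene_id."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("taxon", "term", "gene_id"):
        if col not in raw.columns:
            raise ValueError(f"background table {path}: missing column {col!r}")
    out: dict[str, dict[str, set[str]]] = {}
    for taxon, term, gene in raw.itertuples(index=False):
        out.setdefault(taxon, {}).setdefault(term, set()).add(gene)
    return out
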