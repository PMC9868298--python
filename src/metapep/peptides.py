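"""Peptide-to-protein matching and lowest-common-ancestor taxon assignment.

Peptides observed by the mass spectrometer are matched back to the protein
database by exact equality against in-silico tryptic peptides, with leucine
and isoleucine treated as indistinguishable (they are isobaric and cannot
be separated by standard MS/MS).  A peptide shared by proteins of several
taxa is assigned to the lowest common ancestor of those taxa, so each
peptide contributes abundance at the most specific taxonomic level its
sequence supports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

_MOD_PATTERN = re.compile(r"\[[^\]]*\]|\([^)]*\)")


def equalize_il(sequence: str) -> str:
    """Replace every isoleucine (I) by leucine (L).

    Length is preserved; letters outside the amino-acid alphabet are passed
    through with a warning so that unusual database entries do not abort a
    run.
    """
    unknown = set(sequence) - AMINO_ACIDS
    if unknown:
        logger.warning(
            "non-amino-acid letters %s passed through I/L equalization",
            "".join(sorted(unknown)),
        )
    return sequence.replace("I", "L")


def strip_modifications(peptide: str) -> str:
    """Drop bracket/parenthesis modification annotations, e.g.
    ``PEPM(ox)TIDE`` -> ``PEPMTIDE``."""
    return _MOD_PATTERN.sub("", peptide)


def digest(
    sequence: str, missed_cleavages: int = 2, min_length: int = 1
) -> list[str]:
    """In-silico tryptic digestion.

    Cleaves C-terminal to K or R except when the next residue is P.  All
    fragments containing at most ``missed_cleavages`` internal uncut sites
    are returned, in order of start position then length.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    boundaries = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(sequence))
    fragments = [
        sequence[boundaries[i] : boundaries[i + 1]]
        for i in range(len(boundaries) - 1)
    ]
    peptides = []
    for start in range(len(fragments)):
        for span in range(1, missed_cleavages + 2):
            if start + span > len(fragments):
                break
            pep = "".join(fragments[start : start + span])
            if len(pep) >= min_length:
                peptides.append(pep)
    return peptides


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein with its taxon of origin."""

    protein_id: str
    sequence: str
    taxon_id: str


@dataclass
class PeptideIndex:
    """Lookup from I/L-equalized tryptic peptide to the proteins containing it.

    ``min_length`` mirrors the practice of peptide-centric taxonomic tools:
    very short peptides match half the database and carry no taxonomic
    information, so they are excluded from the index.
    """

    mapping: dict[str, frozenset[str]]
    protein_taxa: dict[str, str]
    missed_cleavages: int = 2
    min_length: int = 5
    substring: bool = False
    _sequences: dict[str, str] = field(default_factory=dict, repr=False)

    def lookup(self, peptide: str) -> frozenset[str]:
        pep = equalize_il(peptide)
        hit = self.mapping.get(pep, frozenset())
        if hit or not self.substring:
            return hit
        # substring fallback: scan equalized protein sequences
        return frozenset(
            pid for pid, seq in self._sequences.items() if pep in seq
        )


def build_index(
    db: Sequence[ProteinRecord],
    missed_cleavages: int = 2,
    min_length: int = 5,
    substring: bool = False,
) -> PeptideIndex:
    """Digest every database protein and index the equalized peptides."""
    if not db:
        raise ValueError("protein database is empty")
    seen: set[str] = set()
    mapping: dict[str, set[str]] = {}
    taxa: dict[str, str] = {}
    sequences: dict[str, str] = {}
    for rec in db:
        if rec.protein_id in seen:
            raise ValueError(f"duplicate protein_id {rec.protein_id!r}")
        seen.add(rec.protein_id)
        taxa[rec.protein_id] = rec.taxon_id
        eq = equalize_il(rec.sequence)
        if substring:
            sequences[rec.protein_id] = eq
        for pep in digest(eq, missed_cleavages, min_length):
            mapping.setdefault(pep, set()).add(rec.protein_id)
    return PeptideIndex(
        mapping={p: frozenset(s) for p, s in mapping.items()},
        protein_taxa=taxa,
        missed_cleavages=missed_cleavages,
        min_length=min_length,
        substring=substring,
        _sequences=sequences,
    )


@dataclass(frozen=True)
class PeptideAssignment:
    """A peptide, the proteins it matches and its LCA taxon (None = no match)."""

    peptide: str
    proteins: frozenset[str]
    taxon_id: str | None


def assign_lca(
    peptide: str, index: PeptideIndex, tree: TaxonomyTree
) -> PeptideAssignment:
    """Assign one peptide to the LCA of the taxa of its matching proteins."""
    proteins = index.lookup(peptide)
    if not proteins:
        return PeptideAssignment(equalize_il(peptide), frozenset(), None)
    taxa = {index.protein_taxa[p] for p in proteins}
    return PeptideAssignment(equalize_il(peptide), proteins, tree.lca(taxa))


def assign_all(
    peptides: Iterable[str], index: PeptideIndex, tree: TaxonomyTree
) -> list[PeptideAssignment]:
    return [assign_lca(p, index, tree) for p in peptides]


# -- database IO --------------------------------------------------------------


def read_fasta_database(
    fasta_path: str | Path, taxon_tsv: str | Path
) -> list[ProteinRecord]:
    """Read a protein FASTA plus a sidecar ``protein_id\\ttaxon_id`` table."""
    taxa: dict[str, str] = {}
    with open(taxon_tsv, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["protein_id", "taxon_id"]:
            raise ValueError(
                f"taxon table {taxon_tsv}: expected columns "
                f"protein_id, taxon_id; got {header}"
            )
        for line in fh:
            if not line.strip():
                continue
            pid, tid = line.rstrip("\n").split("\t")[:2]
            taxa[pid] = tid
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in taxa:
            raise ValueError(f"protein {rec.id!r} missing from taxon table")
        records.append(
            ProteinRecord(rec.id, str(rec.seq).upper(), taxa[rec.id])
        )
    return records


def write_fasta_database(
    db: Sequence[ProteinRecord],
    fasta_path: str | Path,
    taxon_tsv: str | Path,
) -> None:
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for rec in db:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
    with open(taxon_tsv, "w", encoding="utf-8") as fh:
        fh.write("protein_id\ttaxon_id\n")
        for rec in db:
            fh.write(f"{rec.protein_id}\t{rec.taxon_id}\n")
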