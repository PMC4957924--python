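"""Phosphotyrosine peptide library construction.

Builds the non-redundant library of 11-mer peptide windows (5 residues, the
central phosphotyrosine, 5 residues) from protein sequences and phosphosite
annotations, and enumerates background tyrosine windows from proteins that
carry no phosphotyrosine annotation at all.

Conventions
-----------
* Positions are 1-based in all I/O (annotation files, error messages).
* Windows that run off a protein terminus are padded with ``'-'`` (blank),
  which is also the 21st symbol of the scoring alphabet.
* Windows containing ``X`` (unknown residue) are dropped with a warning:
  there is no frequency data for X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
BLANK = "-"
PROTEIN_ALPHABET = frozenset(AA20 + "X")
WINDOW_LENGTH = 11
FLANK = 5

__all__ = [
    "AA20",
    "BLANK",
    "WINDOW_LENGTH",
    "FLANK",
    "ProteinRecord",
    "PhosphoSite",
    "PeptideWindow",
    "LibraryError",
    "SiteValidationError",
    "SiteAnnotationResult",
    "read_fasta",
    "read_site_annotations",
    "extract_windows",
    "enumerate_background_windows",
    "window_at",
    "write_windows_tsv",
]


class LibraryError(ValueError):
    """Malformed input to the library builder."""


class SiteValidationError(LibraryError):
    """A phosphosite annotation that cannot be interpreted at all."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with one primary identifier.

    When several FASTA entries share an identical sequence they are collapsed
    into a single record; ``merged_ids`` keeps every contributing identifier
    (the primary ``id`` is the first one encountered).
    """

    id: str
    sequence: str
    gene: str | None = None
    merged_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LibraryError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise LibraryError(
                f"protein {self.id!r}: non-standard residues {sorted(bad)}"
            )
        if not self.merged_ids:
            object.__setattr__(self, "merged_ids", (self.id,))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class PhosphoSite:
    """A phosphotyrosine site: protein identifier plus 1-based position."""

    protein_id: str
    position: int
    residue: str = "Y"


@dataclass(frozen=True)
class PeptideWindow:
    """An 11-mer window centred on a phosphotyrosine.

    ``sequence`` is exactly 11 characters over the 20 amino acids plus
    ``'-'`` for positions beyond a protein terminus; the centre (index 6,
    1-based) is always ``Y``.  ``sources`` records every
    ``(protein_id, position, gene)`` the window was extracted from; identical
    11-mers from different proteins collapse into one window with merged
    sources.
    """

    sequence: str
    sources: frozenset[tuple[str, int, str | None]] = frozenset()

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise LibraryError(
                f"window {self.sequence!r}: length {len(self.sequence)} != {WINDOW_LENGTH}"
            )
        if self.sequence[FLANK] != "Y":
            raise LibraryError(f"window {self.sequence!r}: centre is not Y")

    def __str__(self) -> str:
        return self.sequence


@dataclass
class SiteAnnotationResult:
    """Valid sites plus every rejected row with its reason."""

    sites: list[PhosphoSite]
    rejected: list[tuple[PhosphoSite, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into non-redundant :class:`ProteinRecord` objects.

    Sequences are uppercased.  Entries with byte-identical sequences are
    collapsed into one record whose ``merged_ids`` lists all contributing
    identifiers.  A gene symbol is taken from the second whitespace-separated
    token of the header, when present.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i for i, line in enumerate(text.splitlines(), start=1) if line.strip()
        )
        raise LibraryError(f"{path}: not FASTA (line {first_bad} does not start a record)")

    by_sequence: dict[str, dict] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        gene = rec.description.split()[1] if len(rec.description.split()) > 1 else None
        if not seq:
            raise LibraryError(f"{path}: entry {rec.id!r} has an empty sequence")
        entry = by_sequence.setdefault(seq, {"ids": [], "gene": gene})
        entry["ids"].append(rec.id)
        if entry["gene"] is None:
            entry["gene"] = gene
    return [
        ProteinRecord(
            id=entry["ids"][0],
            sequence=seq,
            gene=entry["gene"],
            merged_ids=tuple(entry["ids"]),
        )
        for seq, entry in by_sequence.items()
    ]


def _protein_index(proteins: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    index: dict[str, ProteinRecord] = {}
    for p in proteins:
        for pid in p.merged_ids:
            index[pid] = p
    return index


def read_site_annotations(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> SiteAnnotationResult:
    """Read a phosphosite annotation table (``protein_id \\t position \\t residue``).

    Duplicate rows collapse to one site.  Sites naming an unknown protein or
    whose protein sequence does not carry ``Y`` at the stated position are
    collected in ``rejected`` with a reason rather than silently dropped.
    Positions outside ``1..len(protein)`` are unrecoverable and raise
    :class:`SiteValidationError` naming the record.
    """
    frame = pd.read_csv(
        path, sep="\t", comment="#", names=["protein_id", "position", "residue"],
        dtype={"protein_id": str, "residue": str},
    )
    if len(frame) and frame.iloc[0]["protein_id"] == "protein_id":
        frame = frame.iloc[1:]
    index = _protein_index(proteins)
    seen: set[PhosphoSite] = set()
    result = SiteAnnotationResult(sites=[])
    for row in frame.itertuples(index=False):
        site = PhosphoSite(str(row.protein_id), int(row.position), str(row.residue))
        if site in seen:
            continue
        seen.add(site)
        protein = index.get(site.protein_id)
        if protein is None:
            result.rejected.append((site, "protein not found"))
            continue
        if not 1 <= site.position <= len(protein):
            raise SiteValidationError(
                f"site ({site.protein_id}, {site.position}, {site.residue}): "
                f"position out of range 1..{len(protein)}"
            )
        actual = protein.sequence[site.position - 1]
        if actual != "Y":
            result.rejected.append((site, f"residue at position is {actual}, not Y"))
            continue
        result.sites.append(site)
    result.sites.sort()
    return result


def window_at(protein: ProteinRecord, position: int) -> str:
    """The 11-mer around 1-based ``position``, blank-padded at the termini."""
    i = position - 1
    left = protein.sequence[max(0, i - FLANK) : i]
    right = protein.sequence[i + 1 : i + 1 + FLANK]
    return (
        BLANK * (FLANK - len(left))
        + left
        + protein.sequence[i]
        + right
        + BLANK * (FLANK - len(right))
    )


def _build_windows(
    entries: Iterable[tuple[ProteinRecord, int]]
) -> list[PeptideWindow]:
    """Deduplicate (protein, position) windows into PeptideWindows, merging sources."""
    sources_by_seq: dict[str, set[tuple[str, int, str | None]]] = {}
    dropped: list[str] = []
    for protein, position in entries:
        seq = window_at(protein, position)
        if "X" in seq:
            dropped.append(f"{protein.id}:{position}")
            continue
        sources_by_seq.setdefault(seq, set()).add((protein.id, position, protein.gene))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} window(s) containing X: {', '.join(dropped[:5])}"
            + ("…" if len(dropped) > 5 else ""),
            stacklevel=3,
        )
    return [
        PeptideWindow(seq, frozenset(srcs))
        for seq, srcs in sorted(sources_by_seq.items())
    ]


def extract_windows(
    sites: Iterable[PhosphoSite] | SiteAnnotationResult,
    proteins: Sequence[ProteinRecord],
) -> list[PeptideWindow]:
    """Extract the non-redundant 11-mer windows around annotated pY sites.

    One window per unique 11-mer string; identical peptides occurring in
    several proteins (or several positions) keep every source.  The output is
    sorted by peptide sequence, so extraction is deterministic and
    order-independent.
    """
    index = _protein_index(proteins)
    entries = []
    for site in sites:
        protein = index.get(site.protein_id)
        if protein is None:
            raise LibraryError(f"site references unknown protein {site.protein_id!r}")
        entries.append((protein, site.position))
    return _build_windows(entries)


def enumerate_background_windows(
    proteins: Sequence[ProteinRecord],
    annotated: Iterable[PhosphoSite],
    site_level: bool = False,
) -> list[PeptideWindow]:
    """Windows around tyrosines that carry no phosphotyrosine annotation.

    By default exclusion is protein-level: a protein with *any* annotated pY
    site contributes no background windows.  ``site_level=True`` instead
    excludes only the annotated positions themselves, for corpora with dense
    annotations.
    """
    annotated = list(annotated)
    annotated_proteins = {s.protein_id for s in annotated}
    annotated_positions = {(s.protein_id, s.position) for s in annotated}
    entries = []
    for protein in proteins:
        if not site_level and annotated_proteins & set(protein.merged_ids):
            continue
        for i, residue in enumerate(protein.sequence):
            if residue != "Y":
                continue
            position = i + 1
            if site_level and any(
                (pid, position) in annotated_positions for pid in protein.merged_ids
            ):
                continue
            entries.append((protein, position))
    return _build_windows(entries)


def write_windows_tsv(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Write windows as ``peptide \\t sources`` (sources as ``id:pos`` joined by ``,``)."""
    rows = [
        {
            "peptide": w.sequence,
            "sources": ",".join(
                f"{pid}:{pos}" for pid, pos, _ in sorted(w.sources)
            ),
        }
        for w in windows
    ]
    pd.DataFrame(rows, columns=["peptide", "sources"]).to_csv(
        path, sep="\t", index=False
    )
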