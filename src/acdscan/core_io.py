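"""Domain types and file IO for sequences, alignments and annotation tables.

Coordinates are 1-based and inclusive on both ends throughout the package,
for residue positions as well as alignment/profile columns.  The residue
alphabet is the 20 canonical amino acids plus ``X`` (unknown); ``X`` is
carried through all computations but contributes only background statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

#: Structural elements of the alpha-crystallin domain, amino- to
#: carboxy-terminal: beta strands beta2..beta9 and the loops between them.
#: The L57 loop separates the two beta-sheet zones.
ACD_ELEMENTS = (
    "b2", "L23", "b3", "L34", "b4", "L45", "b5",
    "L57",
    "b7", "L78", "b8", "L89", "b9",
)

#: Single-character code used for each element in Stockholm ``#=GC`` landmark
#: strings (one character per alignment column).
ELEMENT_CODES = {
    "b2": "2", "L23": "a", "b3": "3", "L34": "b", "b4": "4", "L45": "c",
    "b5": "5", "L57": "L", "b7": "7", "L78": "d", "b8": "8", "L89": "e",
    "b9": "9",
}
CODE_TO_ELEMENT = {v: k for k, v in ELEMENT_CODES.items()}

#: The three architectural zones of the ACD and the elements they comprise.
ZONE_OF_ELEMENT = {
    "b2": "b2b5", "L23": "b2b5", "b3": "b2b5", "L34": "b2b5",
    "b4": "b2b5", "L45": "b2b5", "b5": "b2b5",
    "L57": "l57",
    "b7": "b7b9", "L78": "b7b9", "b8": "b7b9", "L89": "b7b9", "b9": "b7b9",
}

STOCKHOLM_LANDMARK_TAG = "ACD_elements"


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SequenceRecord:
    """One databank protein with its residues and curation metadata.

    ``existence_level`` follows the UniProt protein-existence scale
    (1 = protein evidence ... 5 = unknown); records default to 5 until
    metadata is merged.
    """

    accession: str
    residues: str
    description: str = ""
    lineage: list[str] = field(default_factory=list)
    is_fragment: bool = False
    existence_level: int = 5

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.accession}: empty residue string")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue character(s) {sorted(bad)}"
            )
        if not 1 <= self.existence_level <= 5:
            raise ValueError(
                f"{self.accession}: existence_level {self.existence_level} "
                "outside [1, 5]"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A gap-aware multiple alignment: rows of (accession, gapped string)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows, lengths {sorted(lengths)}")
        for acc, s in self.rows:
            bad = set(s.upper()) - set(ALPHABET + GAP)
            if bad:
                raise ValueError(f"{acc}: illegal alignment character(s) {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, c: int) -> str:
        """Residues of 1-based column ``c`` across rows."""
        return "".join(s[c - 1] for _, s in self.rows)


@dataclass
class SeedAnnotation:
    """Structural landmark labels for seed-alignment columns.

    Maps each 1-based alignment column in the labeled range to one of
    :data:`ACD_ELEMENTS`.  Elements must appear contiguously and in
    amino-to-carboxy order, with no unlabeled column between the start of
    beta2 and the end of beta9.
    """

    element_of_column: dict[int, str]

    def __post_init__(self) -> None:
        if not self.element_of_column:
            raise ValueError("empty landmark annotation")
        cols = sorted(self.element_of_column)
        if cols != list(range(cols[0], cols[-1] + 1)):
            raise ValueError("landmark columns must be contiguous")
        order = []
        for c in cols:
            el = self.element_of_column[c]
            if el not in ACD_ELEMENTS:
                raise ValueError(f"unknown structural element {el!r}")
            if not order or order[-1] != el:
                order.append(el)
        expected = [el for el in ACD_ELEMENTS if el in set(order)]
        if order != expected:
            raise ValueError(
                f"structural elements out of order: {order} (expected subsequence "
                f"of {list(ACD_ELEMENTS)})"
            )

    @property
    def columns(self) -> list[int]:
        return sorted(self.element_of_column)

    def zone_of_column(self, c: int) -> str:
        return ZONE_OF_ELEMENT[self.element_of_column[c]]

    def element_span(self, element: str) -> tuple[int, int]:
        """First and last 1-based column carrying ``element``."""
        cols = [c for c, el in self.element_of_column.items() if el == element]
        if not cols:
            raise KeyError(element)
        return min(cols), max(cols)


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    Metadata fields are defaulted (empty lineage, not a fragment,
    existence level 5) until :func:`read_metadata` merges a sidecar table.
    """
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise ParseError(
                f"{path}: entry {entry.id!r} contains illegal residue "
                f"character(s) {sorted(bad)}"
            )
        if not seq:
            raise ParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(SequenceRecord(accession=entry.id, residues=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.accession}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_metadata(path: str | Path, records: Sequence[SequenceRecord]) -> list[str]:
    """Merge a metadata TSV into ``records`` in place.

    Expected columns: ``accession``, ``lineage`` (semicolon-joined taxon
    names, may be empty), ``fragment`` (0/1), ``existence`` (1-5).
    Returns the accessions of TSV rows that matched no record.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "lineage", "fragment", "existence"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata column(s) {sorted(missing)}")
    by_acc = {r.accession: r for r in records}
    unmatched: list[str] = []
    for row in df.itertuples(index=False):
        existence = int(row.existence)
        if not 1 <= existence <= 5:
            raise ParseError(
                f"{path}: existence level {existence} for {row.accession} outside [1, 5]"
            )
        rec = by_acc.get(row.accession)
        if rec is None:
            unmatched.append(row.accession)
            continue
        rec.lineage = [t.strip() for t in str(row.lineage).split(";") if t.strip()]
        rec.is_fragment = str(row.fragment).strip() in ("1", "true", "True")
        rec.existence_level = existence
    return unmatched


def write_metadata(records: Iterable[SequenceRecord], path: str | Path) -> None:
    rows = [
        {
            "accession": r.accession,
            "lineage": ";".join(r.lineage),
            "fragment": int(r.is_fragment),
            "existence": r.existence_level,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _annotation_from_landmark_string(landmark: str, n_columns: int) -> SeedAnnotation:
    if len(landmark) != n_columns:
        raise ParseError(
            f"landmark string length {len(landmark)} != alignment columns {n_columns}"
        )
    element_of_column: dict[int, str] = {}
    for i, code in enumerate(landmark, start=1):
        if code in (".", GAP, " "):
            continue
        if code not in CODE_TO_ELEMENT:
            raise ParseError(f"unknown landmark code {code!r} at column {i}")
        element_of_column[i] = CODE_TO_ELEMENT[code]
    return SeedAnnotation(element_of_column)


def read_seed_alignment(
    path: str | Path, annotation_path: str | Path | None = None
) -> tuple[Alignment, SeedAnnotation]:
    """Read the seed ACD alignment plus its structural landmarks.

    Two layouts are accepted:

    * Stockholm with a ``#=GC ACD_elements`` line giving one landmark code per
      column (see :data:`ELEMENT_CODES`); ``annotation_path`` is ignored.
    * Aligned FASTA plus a landmark TSV with columns ``column_index`` (1-based)
      and ``element``.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("# STOCKHOLM"):
        msa = AlignIO.read(str(path), "stockholm")
        aln = Alignment([(r.id, str(r.seq).upper()) for r in msa])
        tag = f"GC:{STOCKHOLM_LANDMARK_TAG}"
        landmark = msa.column_annotations.get(tag) or msa.column_annotations.get(
            STOCKHOLM_LANDMARK_TAG
        )
        if landmark is None:
            raise ParseError(
                f"{path}: no '#=GC {STOCKHOLM_LANDMARK_TAG}' landmark line"
            )
        ann = _annotation_from_landmark_string(landmark, aln.n_columns)
        return aln, ann
    msa = AlignIO.read(str(path), "fasta")
    aln = Alignment([(r.id, str(r.seq).upper()) for r in msa])
    if annotation_path is None:
        raise ParseError("aligned FASTA seed needs a landmark TSV")
    df = pd.read_csv(annotation_path, sep="\t")
    if not {"column_index", "element"} <= set(df.columns):
        raise ParseError(f"{annotation_path}: need columns column_index, element")
    element_of_column = {
        int(row.column_index): str(row.element) for row in df.itertuples(index=False)
    }
    for c in element_of_column:
        if not 1 <= c <= aln.n_columns:
            raise ParseError(f"landmark column {c} outside alignment (1..{aln.n_columns})")
    return aln, SeedAnnotation(element_of_column)


def write_seed_alignment(aln: Alignment, ann: SeedAnnotation, path: str | Path) -> None:
    """Write a seed alignment as Stockholm with the landmark ``#=GC`` line."""
    codes = []
    for c in range(1, aln.n_columns + 1):
        el = ann.element_of_column.get(c)
        codes.append(ELEMENT_CODES[el] if el else ".")
    name_w = max(len(acc) for acc, _ in aln.rows)
    name_w = max(name_w, len("#=GC " + STOCKHOLM_LANDMARK_TAG))
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for acc, s in aln.rows:
            fh.write(f"{acc:<{name_w}} {s}\n")
        fh.write(f"{'#=GC ' + STOCKHOLM_LANDMARK_TAG:<{name_w}} {''.join(codes)}\n")
        fh.write("//\n")


def validate_region(start: int, end: int, length: int, what: str = "region") -> None:
    """Check a 1-based inclusive region against a sequence length."""
    if not (1 <= start <= end <= length):
        raise ValueError(f"{what} [{start}, {end}] invalid for length {length}")
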