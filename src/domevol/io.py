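"""Sequence, alignment, manifest and region-map I/O plus coordinate mapping.

All user-facing coordinates are 1-based inclusive, matching the convention of
published domain tables for TRPM8-like channel proteins (e.g. "Pore region
886-954" on the human reference). Internally positions are converted to
0-based offsets as needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: residues admitted in a SequenceRecord (the 20 canonical letters plus X)
ALLOWED = set(AMINO_ACIDS) | {"X"}
#: ambiguity/rare codes folded into X on read
AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "J": "X", "O": "X"}

#: peptide recognized by the pore-loop antibody used for cross-species
#: immunodetection of TRPM8 (residues 917-929 of the human protein)
PORE_LOOP_EPITOPE = "SDVDGTTYDFAHC"


class DomevolError(ValueError):
    """Base error for malformed inputs."""


def _clean_residues(raw: str, *, allow_gap: bool, context: str) -> str:
    out = []
    warned = False
    for i, ch in enumerate(raw.upper()):
        if ch == ".":
            ch = GAP
        if ch in AMBIGUOUS:
            if not warned:
                warnings.warn(
                    f"{context}: ambiguous residue {ch!r} mapped to X", stacklevel=3
                )
                warned = True
            ch = AMBIGUOUS[ch]
        if ch in ALLOWED or (allow_gap and ch == GAP):
            out.append(ch)
        else:
            raise DomevolError(
                f"{context}: illegal character {ch!r} at position {i + 1}"
            )
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped (or, inside an Alignment, gapped) protein sequence."""

    id: str
    residues: str
    species: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise DomevolError("record id must be nonempty")
        if not self.residues:
            raise DomevolError(f"record {self.id!r}: residues must be nonempty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class Alignment:
    """An equal-length gapped collection of at least two protein sequences."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if len(records) < 2:
            raise DomevolError("alignment needs at least 2 records")
        ids = [r.id for r in records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise DomevolError(f"duplicate record id(s): {sorted(dupes)}")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            ragged = [r.id for r in records if len(r) != len(records[0])]
            raise DomevolError(f"ragged alignment rows: {ragged}")
        self.records = records
        self.ncols = lengths.pop()
        self._index = {r.id: k for k, r in enumerate(records)}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, rid: str) -> SequenceRecord:
        try:
            return self.records[self._index[rid]]
        except KeyError:
            raise DomevolError(f"record {rid!r} not in alignment") from None

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, col: int) -> str:
        """Residues of 1-based column `col`, one character per record."""
        if not 1 <= col <= self.ncols:
            raise DomevolError(f"column {col} outside 1..{self.ncols}")
        return "".join(r.residues[col - 1] for r in self.records)

    def slice_columns(self, cols: Iterable[int]) -> "Alignment":
        """New alignment restricted to the given 1-based columns (in order)."""
        cols = list(cols)
        rows = []
        for r in self.records:
            rows.append(
                SequenceRecord(
                    r.id,
                    "".join(r.residues[c - 1] for c in cols),
                    species=r.species,
                    source=r.source,
                )
            )
        return Alignment(rows)

    def drop_allgap_columns(self) -> tuple["Alignment", int]:
        keep = [
            c
            for c in range(1, self.ncols + 1)
            if any(r.residues[c - 1] != GAP for r in self.records)
        ]
        dropped = self.ncols - len(keep)
        if dropped == 0:
            return self, 0
        return self.slice_columns(keep), dropped


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read ungapped protein FASTA. Ids are the first header token, upper-cased
    residues; duplicate ids and illegal characters are hard errors."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DomevolError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _clean_residues(
            str(rec.seq), allow_gap=False, context=f"{path}:{rec.id}"
        )
        records.append(
            SequenceRecord(rec.id, residues, species=rec.description[len(rec.id):].strip())
        )
    if not records:
        raise DomevolError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = r.id if not r.species else f"{r.id} {r.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into a validated Alignment.

    All-gap columns are removed (count logged). Ragged rows raise, listing the
    offending ids.
    """
    path = Path(path)
    if format not in {"fasta", "clustal"}:
        raise DomevolError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:  # biopython raises on ragged/empty input
        # recover per-row lengths for a more useful error
        try:
            raw = list(SeqIO.parse(str(path), format))
        except Exception:
            raise DomevolError(f"cannot parse {path}: {exc}") from exc
        if not raw:
            raise DomevolError(f"no sequences in {path}") from exc
        ref_len = len(raw[0].seq)
        ragged = [r.id for r in raw if len(r.seq) != ref_len]
        raise DomevolError(f"ragged alignment rows in {path}: {ragged}") from exc
    records = [
        SequenceRecord(
            rec.id,
            _clean_residues(str(rec.seq), allow_gap=True, context=f"{path}:{rec.id}"),
            species=rec.description[len(rec.id):].strip(),
        )
        for rec in msa
    ]
    aln = Alignment(records)
    aln, dropped = aln.drop_allgap_columns()
    if dropped:
        log.info("removed %d all-gap column(s) from %s", dropped, path)
    return aln


def write_alignment(aln: Alignment, path: str | Path) -> None:
    write_fasta(aln.records, path)


# ---------------------------------------------------------------------------
# coordinate mapping


def ref_to_column(aln: Alignment, reference_id: str, pos: int) -> int:
    """Alignment column (1-based) holding the `pos`-th non-gap residue of the
    reference row."""
    row = aln[reference_id].residues
    if pos < 1:
        raise DomevolError(f"position {pos} out of range")
    seen = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            seen += 1
            if seen == pos:
                return col
    raise DomevolError(
        f"position {pos} beyond ungapped length {seen} of {reference_id!r}"
    )


def column_to_ref(aln: Alignment, reference_id: str, col: int) -> int | None:
    """Ungapped reference position at alignment column `col`, or None if the
    reference has a gap there."""
    row = aln[reference_id].residues
    if not 1 <= col <= aln.ncols:
        raise DomevolError(f"column {col} outside 1..{aln.ncols}")
    if row[col - 1] == GAP:
        return None
    return col - row[:col].count(GAP)


# ---------------------------------------------------------------------------
# epitope scanning


def scan_epitope(
    record: SequenceRecord, peptide: str, max_mismatch: int = 0
) -> tuple[int, int] | None:
    """Best exact-positional match of `peptide` within `record`.

    Returns (1-based start, n_matches) for the window with the most positional
    matches, provided mismatches <= max_mismatch; otherwise None ("no hit").
    Ties break toward the smallest start.
    """
    if not peptide:
        raise DomevolError("empty peptide")
    peptide = peptide.upper()
    seq = record.ungapped
    m = len(peptide)
    if m > len(seq):
        raise DomevolError("peptide longer than sequence")
    best_start, best_matches = 1, -1
    for start in range(len(seq) - m + 1):
        matches = sum(a == b for a, b in zip(seq[start : start + m], peptide))
        if matches > best_matches:
            best_start, best_matches = start + 1, matches
    if m - best_matches > max_mismatch:
        return None
    return best_start, best_matches


# ---------------------------------------------------------------------------
# region maps and manifests

_PKG_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise DomevolError(
                f"region {self.name!r}: invalid span {self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionMap:
    """Named 1-based inclusive intervals on an ungapped reference sequence.

    Overlaps between regions are permitted (domain tables routinely nest, e.g.
    a TRP-box inside the TRP-domain inside the C-terminus).
    """

    reference_id: str
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise DomevolError(f"duplicate region name(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise DomevolError(f"no region named {name!r}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def validate_against(self, reference_length: int) -> None:
        for r in self.regions:
            if r.end > reference_length:
                raise DomevolError(
                    f"region {r.name!r} end {r.end} beyond reference length "
                    f"{reference_length}"
                )


def load_region_map(path: str | Path, reference_id: str) -> RegionMap:
    """Load a TSV region table with columns: region, start, end."""
    df = pd.read_csv(path, sep="\t")
    required = {"region", "start", "end"}
    if not required.issubset(df.columns):
        raise DomevolError(f"region map needs columns {sorted(required)}")
    regions = [
        Region(str(row.region), int(row.start), int(row.end))
        for row in df.itertuples()
    ]
    return RegionMap(reference_id, regions)


def trpm8_region_map(reference_id: str = "NP_076985.4") -> RegionMap:
    """The shipped domain/motif table for human TRPM8 (28 named regions)."""
    return load_region_map(_PKG_DATA / "trpm8_regions.tsv", reference_id)


@dataclass
class Manifest:
    """Accession bookkeeping for a protein family: which sequences exist, how
    long they should be, and whether they are complete."""

    table: pd.DataFrame  # species, scientific_name, accession, expected_length, source, complete

    def __post_init__(self) -> None:
        if self.table["accession"].duplicated().any():
            dup = self.table.loc[self.table["accession"].duplicated(), "accession"]
            raise DomevolError(f"duplicate accession(s): {sorted(dup)}")
        lengths = self.table["expected_length"].dropna()
        if (lengths <= 0).any():
            raise DomevolError("expected_length must be positive when present")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def complete(self) -> pd.DataFrame:
        return self.table[self.table["complete"]]

    def accession_for(self, species: str) -> str:
        hit = self.table[self.table["species"].str.lower() == species.lower()]
        if hit.empty:
            raise DomevolError(f"species {species!r} not in manifest")
        return str(hit.iloc[0]["accession"])


def load_manifest(path: str | Path) -> Manifest:
    df = pd.read_csv(path, sep="\t")
    required = {"species", "scientific_name", "accession", "source", "complete"}
    if not required.issubset(df.columns):
        raise DomevolError(f"manifest needs columns {sorted(required)}")
    if "expected_length" not in df.columns:
        df["expected_length"] = pd.NA
    if df["expected_length"].isna().any():
        warnings.warn("manifest rows with missing expected_length accepted")
    df["expected_length"] = pd.to_numeric(df["expected_length"], errors="coerce")
    df["complete"] = df["complete"].astype(bool)
    return Manifest(df)


def trpm8_manifest() -> Manifest:
    """The shipped 39-accession TRPM8 manifest (24 complete + 15 fragmented)."""
    return load_manifest(_PKG_DATA / "trpm8_manifest.tsv")
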