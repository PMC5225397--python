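"""Record and merged-group I/O for the duplicate-characterization pipeline.

A *merged group* is an exemplar record together with the records a database
curator merged into it; expanding groups yields exemplar-duplicate pairs, the
unit of all downstream categorization and impact analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "NucleotideRecord",
    "MergedGroup",
    "DuplicatePair",
    "SubmitterComparison",
    "ParseError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_genbank_flat",
    "read_group_table",
    "expand_groups",
    "submitter_overlap",
    "normalize_submitter",
    "write_pair_table",
]

#: IUPAC nucleotide one-letter codes (unambiguous + ambiguity codes).
IUPAC_NT = frozenset("ACGTNRYSWKMBDHV")

GROUP_TABLE_COLUMNS = ["group_id", "exemplar_accession", "member_accession", "organism"]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into the domain model."""


class ValidationError(ValueError):
    """Raised when parsed data violates a structural invariant."""


@dataclass(frozen=True)
class NucleotideRecord:
    """One nucleotide database record.

    The sequence is stored uppercased with U mapped to T, so a single
    canonical alphabet feeds alignment and property computation.
    """

    accession: str
    sequence: str
    version: int = 0
    definition: str = ""
    organism: str = ""
    submitters: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("record accession must be non-empty")
        if not self.sequence:
            raise ValidationError(f"record {self.accession}: empty sequence")
        bad = set(self.sequence) - IUPAC_NT
        if bad:
            raise ParseError(
                f"record {self.accession}: illegal sequence character(s) "
                f"{sorted(bad)!r} (not IUPAC nucleotide codes)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MergedGroup:
    """An exemplar accession plus the member accessions merged into it."""

    group_id: str
    exemplar_accession: str
    member_accessions: tuple[str, ...]
    organism: str = ""

    def __post_init__(self) -> None:
        if not self.member_accessions:
            raise ValidationError(f"group {self.group_id}: no members")
        if self.exemplar_accession in self.member_accessions:
            raise ValidationError(
                f"group {self.group_id}: exemplar {self.exemplar_accession} "
                "appears among its own members"
            )

    @property
    def n_records(self) -> int:
        """Total records the group represents (exemplar + members)."""
        return 1 + len(self.member_accessions)


@dataclass(frozen=True)
class DuplicatePair:
    """One exemplar paired with one record it replaced."""

    exemplar: NucleotideRecord
    duplicate: NucleotideRecord
    group_id: str
    organism: str = ""

    def __post_init__(self) -> None:
        if self.exemplar.accession == self.duplicate.accession:
            raise ValidationError(
                f"group {self.group_id}: pair of a record with itself "
                f"({self.exemplar.accession})"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.exemplar.accession, self.duplicate.accession)


@dataclass(frozen=True)
class SubmitterComparison:
    shared_count: int
    union_count: int
    same_submitter: bool


_SEQ_CLEAN = str.maketrans({"u": "T", "U": "T"})


def _canonical_sequence(raw: str) -> str:
    return raw.translate(_SEQ_CLEAN).upper().replace(" ", "")


def normalize_submitter(name: str) -> str:
    """Canonicalize a submitter name to case-folded ``surname,initials`` form.

    AUTHORS lines vary only in spacing and case in practice, so comparison is
    on the case-folded, whitespace-stripped form.
    """
    name = re.sub(r"\s+", " ", name.strip()).casefold()
    # "surname , j." / "surname, j." -> "surname,j."
    name = re.sub(r"\s*,\s*", ",", name)
    return name


def read_fasta(path: str | Path) -> list[NucleotideRecord]:
    """Read FASTA records; header = accession, optional ``organism=``/``def=`` tags.

    Underscores in tag values are rendered back to spaces (FASTA headers are
    whitespace-delimited).
    """
    path = Path(path)
    records: list[NucleotideRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise ParseError(f"{path}: FASTA entry with empty header")
        organism = ""
        definition = ""
        for token in entry.description.split()[1:]:
            if token.startswith("organism="):
                organism = token[len("organism="):].replace("_", " ")
            elif token.startswith("def="):
                definition = token[len("def="):].replace("_", " ")
        seq = _canonical_sequence(str(entry.seq))
        if not seq:
            raise ParseError(f"{path}: record {entry.id} has an empty sequence")
        records.append(
            NucleotideRecord(
                accession=entry.id,
                sequence=seq,
                definition=definition,
                organism=organism,
            )
        )
    return records


def write_fasta(records: Iterable[NucleotideRecord], path: str | Path) -> None:
    """Write records to FASTA with the tagged-header convention of read_fasta."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            tags = []
            if rec.organism:
                tags.append(f"organism={rec.organism.replace(' ', '_')}")
            if rec.definition:
                tags.append(f"def={rec.definition.replace(' ', '_')}")
            header = " ".join([rec.accession, *tags])
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def _split_authors(authors: str) -> set[str]:
    """Split a GenBank AUTHORS string into individual names.

    Names are 'Surname,Initials' with no internal whitespace; separators are
    ', ' and ' and '.
    """
    parts = re.split(r",\s+|\s+and\s+", authors.strip())
    return {p.strip().rstrip(".,;") + ("." if p.strip().endswith(".") else "")
            for p in parts if p.strip()}


def read_genbank_flat(path: str | Path) -> list[NucleotideRecord]:
    """Read GenBank flat-file records.

    Submitters are the union of AUTHORS names over all REFERENCE blocks;
    DEFINITION is captured verbatim with line wraps joined by single spaces
    (Biopython's convention). A record missing its ORIGIN sequence is a parse
    error; a missing DEFINITION yields an empty definition.
    """
    path = Path(path)
    records: list[NucleotideRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed GenBank flat file: {exc}") from exc
    for entry in parsed:
        try:
            raw_seq = str(entry.seq)
        except Exception as exc:  # undefined sequence (no ORIGIN)
            raise ParseError(
                f"{path}: record {entry.id} has no ORIGIN sequence"
            ) from exc
        seq = _canonical_sequence(raw_seq)
        if not seq:
            raise ParseError(f"{path}: record {entry.id} has no ORIGIN sequence")
        submitters: set[str] = set()
        for ref in entry.annotations.get("references", []):
            if ref.authors:
                submitters |= _split_authors(ref.authors)
        accession = entry.annotations.get("accessions", [entry.id])[0]
        version = 0
        m = re.search(r"\.(\d+)$", entry.id)
        if m:
            version = int(m.group(1))
        definition = entry.description or ""
        if definition == "<unknown description>":
            definition = ""
        records.append(
            NucleotideRecord(
                accession=accession,
                version=version,
                sequence=seq,
                definition=definition,
                organism=entry.annotations.get("organism", ""),
                submitters=frozenset(submitters),
            )
        )
    return records


def read_group_table(path: str | Path) -> list[MergedGroup]:
    """Read the merged-group TSV (one row per group member).

    Header must be exactly ``group_id  exemplar_accession  member_accession
    organism``. Rows are grouped by group_id preserving file order of members.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != GROUP_TABLE_COLUMNS:
        raise ParseError(
            f"{path}: expected header {GROUP_TABLE_COLUMNS}, got {list(df.columns)}"
        )
    dup_rows = df.duplicated(subset=["group_id", "member_accession"])
    if dup_rows.any():
        offending = df.loc[dup_rows, ["group_id", "member_accession"]]
        raise ValidationError(
            f"{path}: duplicate (group_id, member) rows: "
            f"{offending.to_records(index=False).tolist()}"
        )
    groups: list[MergedGroup] = []
    for gid, sub in df.groupby("group_id", sort=False):
        exemplars = sub["exemplar_accession"].unique()
        if len(exemplars) != 1:
            raise ValidationError(
                f"{path}: group {gid} lists multiple exemplars {list(exemplars)}"
            )
        organisms = sub["organism"].unique()
        if len(organisms) != 1:
            raise ValidationError(
                f"{path}: group {gid} lists multiple organisms {list(organisms)}"
            )
        groups.append(
            MergedGroup(
                group_id=str(gid),
                exemplar_accession=exemplars[0],
                member_accessions=tuple(sub["member_accession"]),
                organism=organisms[0],
            )
        )
    return groups


def expand_groups(
    groups: Sequence[MergedGroup],
    records: Mapping[str, NucleotideRecord],
) -> list[DuplicatePair]:
    """Expand merged groups into exemplar-duplicate pairs.

    A group with k members yields exactly k pairs, so the pair count is the
    total member count over all groups. All referenced accessions must
    resolve; missing ones are reported together.
    """
    missing: list[str] = []
    for g in groups:
        for acc in (g.exemplar_accession, *g.member_accessions):
            if acc not in records:
                missing.append(acc)
    if missing:
        raise ValidationError(
            "accessions referenced by groups but absent from records: "
            + ", ".join(sorted(set(missing)))
        )
    pairs: list[DuplicatePair] = []
    for g in groups:
        exemplar = records[g.exemplar_accession]
        for acc in g.member_accessions:
            pairs.append(
                DuplicatePair(
                    exemplar=exemplar,
                    duplicate=records[acc],
                    group_id=g.group_id,
                    organism=g.organism,
                )
            )
    return pairs


def submitter_overlap(a: NucleotideRecord, b: NucleotideRecord) -> SubmitterComparison:
    """Compare two records' submitter sets after name normalization.

    ``same_submitter`` is true iff the normalized sets intersect; an empty set
    on either side never counts as shared.
    """
    sa = {normalize_submitter(s) for s in a.submitters}
    sb = {normalize_submitter(s) for s in b.submitters}
    shared = len(sa & sb)
    union = max(len(sa | sb), 1)
    return SubmitterComparison(
        shared_count=shared,
        union_count=union,
        same_submitter=shared >= 1,
    )


def write_pair_table(pairs: Sequence[DuplicatePair], path: str | Path) -> pd.DataFrame:
    """Write the expanded pair table as TSV; returns the DataFrame written."""
    rows = []
    for p in pairs:
        cmp = submitter_overlap(p.exemplar, p.duplicate)
        rows.append(
            {
                "group_id": p.group_id,
                "organism": p.organism,
                "exemplar_accession": p.exemplar.accession,
                "duplicate_accession": p.duplicate.accession,
                "same_submitter": cmp.same_submitter,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "organism",
            "exemplar_accession",
            "duplicate_accession",
            "same_submitter",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
    return df
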