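"""Duplicate-pair categorization at sequence level and annotation level.

Sequence level assigns exactly one of:

* ``ES`` exact sequences — local identity and alignment proportion both 100%;
* ``SS`` similar sequences — both statistics below 100% but at least 90%;
* ``EF`` exact fragments — identity 100%, proportion below 90%;
* ``SF`` similar fragments — identity at least 90% (below 100%), proportion
  below 90%;
* ``LI`` low identity — identity below 90%, or no significant hit
  (E-value above the cutoff or no alignment at all);
* ``LS`` long sequence — pair excluded from alignment by the length cap;
* ``UC`` unclassified — residual cells of the decision table (unreachable
  under the default thresholds; reachable only if they are reconfigured).

The boundary cell (identity 100, proportion in [90, 100)) that the category
definitions leave open is mapped to SS: such a pair is near-identical overall
but not exact.

Annotation level flags any of WD / SP / PR when either record's DEFINITION
contains "WORKING DRAFT" / "SEQUENCING IN PROGRESS" / "PREDICTED"
(case-insensitive); a pair may carry several, independent of its sequence
category.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .alignment import AlignmentResult
from .records import DuplicatePair

__all__ = [
    "SEQUENCE_CATEGORIES",
    "ANNOTATION_CATEGORIES",
    "CategoryThresholds",
    "CategoryLabel",
    "assign_sequence_category",
    "assign_annotation_categories",
    "categorize_pairs",
]

SEQUENCE_CATEGORIES = ("ES", "SS", "EF", "SF", "LI", "LS", "UC")
ANNOTATION_CATEGORIES = ("WD", "SP", "PR")

_ANNOTATION_KEYWORDS = {
    "WD": "WORKING DRAFT",
    "SP": "SEQUENCING IN PROGRESS",
    "PR": "PREDICTED",
}

SUMMARY_COLUMNS = [
    "organism",
    "total_records",
    "ES",
    "SS",
    "EF",
    "SF",
    "LI",
    "WD",
    "SP",
    "PR",
    "LS",
    "UC",
]


@dataclass(frozen=True)
class CategoryThresholds:
    """Thresholds of the sequence-level decision table."""

    high: float = 90.0
    exact: float = 100.0
    evalue_cutoff: float = 1e-3

    def __post_init__(self) -> None:
        if not (0.0 < self.high < self.exact):
            raise ValueError("require 0 < high < exact")


@dataclass(frozen=True)
class CategoryLabel:
    sequence_category: str
    annotation_categories: frozenset[str]


def assign_sequence_category(
    aln: Optional[AlignmentResult],
    thresholds: CategoryThresholds = CategoryThresholds(),
    long_flag: bool = False,
) -> str:
    """Assign the sequence-level category of one pair.

    The decision table is total and ordered: LS (length cap) takes precedence
    over everything; LI (no hit / insignificant / identity below ``high``)
    over all similarity categories; then ES / EF / SF / SS by the identity and
    proportion bands; UC catches any residual cell.
    """
    if long_flag:
        return "LS"
    if aln is None:
        raise ValueError("pair has neither an alignment nor a long-sequence flag")
    high, exact = thresholds.high, thresholds.exact
    identity, proportion = aln.local_identity, aln.alignment_proportion
    if (not aln.has_hit) or aln.evalue > thresholds.evalue_cutoff or identity < high:
        return "LI"
    if identity == exact and proportion == exact:
        return "ES"
    if identity == exact and proportion < high:
        return "EF"
    if high <= identity < exact and proportion < high:
        return "SF"
    if high <= identity <= exact and high <= proportion < exact:
        return "SS"
    return "UC"


def _normalize_definition(text: str) -> str:
    return re.sub(r"\s+", " ", text).upper()


def assign_annotation_categories(pair: DuplicatePair) -> frozenset[str]:
    """Annotation-level categories of a pair (possibly empty, possibly several).

    A category applies when *either* record's DEFINITION contains its keyword,
    matched case-insensitively on whitespace-normalized text.
    """
    texts = [
        _normalize_definition(pair.exemplar.definition),
        _normalize_definition(pair.duplicate.definition),
    ]
    return frozenset(
        cat
        for cat, keyword in _ANNOTATION_KEYWORDS.items()
        if any(keyword in t for t in texts)
    )


def categorize_pairs(
    pairs: Sequence[DuplicatePair],
    alignments: Mapping[tuple[str, str], Optional[AlignmentResult]],
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every pair and summarize counts per organism.

    ``alignments`` maps ``(exemplar_accession, duplicate_accession)`` to the
    pair's alignment result, or to ``None`` for pairs excluded by the length
    cap. Returns ``(pair_table, summary)``: the per-pair label table and a
    per-organism count matrix over all sequence and annotation categories.
    Sequence-category counts partition the pairs of an organism; annotation
    counts may overlap. ``total_records`` counts the distinct records of the
    organism appearing in the pairs.
    """
    rows = []
    for pair in pairs:
        key = pair.key
        if key not in alignments:
            raise KeyError(
                f"pair {key} has no alignment result and no long-sequence flag"
            )
        aln = alignments[key]
        seq_cat = assign_sequence_category(aln, thresholds, long_flag=aln is None)
        annot = assign_annotation_categories(pair)
        rows.append(
            {
                "group_id": pair.group_id,
                "organism": pair.organism,
                "exemplar": pair.exemplar.accession,
                "duplicate": pair.duplicate.accession,
                "identity": aln.local_identity if aln is not None else float("nan"),
                "proportion": (
                    aln.alignment_proportion if aln is not None else float("nan")
                ),
                "evalue": aln.evalue if aln is not None else float("nan"),
                "seq_category": seq_cat,
                "annot_categories": ";".join(sorted(annot)),
            }
        )
    pair_table = pd.DataFrame(
        rows,
        columns=[
            "group_id",
            "organism",
            "exemplar",
            "duplicate",
            "identity",
            "proportion",
            "evalue",
            "seq_category",
            "annot_categories",
        ],
    )

    summary_rows = []
    if not pair_table.empty:
        for organism, sub in pair_table.groupby("organism", sort=True):
            counts = {cat: int((sub["seq_category"] == cat).sum())
                      for cat in SEQUENCE_CATEGORIES}
            for cat in ANNOTATION_CATEGORIES:
                counts[cat] = int(
                    sub["annot_categories"]
                    .str.split(";")
                    .apply(lambda cats: cat in cats)
                    .sum()
                )
            accs = set(sub["exemplar"]) | set(sub["duplicate"])
            summary_rows.append(
                {"organism": organism, "total_records": len(accs), **counts}
            )
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    return pair_table, summary
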