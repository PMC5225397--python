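"""Impact of duplicates on GC content and melting temperature.

For each sequence property p the analysis reports, per organism x category
cell and per organism "ALL" row, the mean (``mdiff``) and standard deviation
(``std``) of the absolute difference between an exemplar and a comparison
set, in two settings:

* **group** — the exemplar against the mean of its original group (the
  exemplar together with its duplicates); because the group mean includes
  the exemplar, deviations shrink relative to the pair setting;
* **pair** — the exemplar against each duplicate directly.

Categories are pair-level, so in the group setting a group contributes its
difference once per member pair carrying the category; "Size" therefore
counts pairs in both settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import AlignmentResult, LongSequenceError, ScoringConfig, local_align
from .categorize import CategoryThresholds, categorize_pairs
from .records import (
    DuplicatePair,
    MergedGroup,
    NucleotideRecord,
    expand_groups,
    read_fasta,
    read_group_table,
    write_pair_table,
)
from .seqprops import SequenceProperties, TmConfig, sequence_properties

__all__ = [
    "PROPERTIES",
    "group_differences",
    "pair_differences",
    "duplicates_mean_differences",
    "aggregate",
    "redundancy_reduction",
    "PipelineConfig",
    "PipelineResult",
    "compute_alignments",
    "compute_properties",
    "run_pipeline",
]

PROPERTIES = ("gc", "tm_basic", "tm_salt", "tm_advanced")

_PROP_ATTR = {
    "gc": "gc_percent",
    "tm_basic": "tm_basic",
    "tm_salt": "tm_salt",
    "tm_advanced": "tm_advanced",
}


def _prop_vector(props: SequenceProperties) -> dict[str, float]:
    return {p: getattr(props, _PROP_ATTR[p]) for p in PROPERTIES}


def _lookup(props: Mapping[str, SequenceProperties], accession: str):
    if accession not in props:
        raise KeyError(f"no sequence properties for accession {accession}")
    return props[accession]


def group_differences(
    group: MergedGroup, props: Mapping[str, SequenceProperties]
) -> dict[str, float]:
    """|exemplar - mean of {exemplar} u members| for each property."""
    ex = _prop_vector(_lookup(props, group.exemplar_accession))
    members = [_prop_vector(_lookup(props, m)) for m in group.member_accessions]
    out = {}
    for p in PROPERTIES:
        values = [ex[p]] + [m[p] for m in members]
        # identical values must yield an exact zero, not summation dust
        if all(v == ex[p] for v in values):
            out[p] = 0.0
        else:
            out[p] = abs(ex[p] - float(np.mean(values)))
    return out


def pair_differences(
    pair: DuplicatePair, props: Mapping[str, SequenceProperties]
) -> dict[str, float]:
    """|exemplar - duplicate| for each property."""
    ex = _prop_vector(_lookup(props, pair.exemplar.accession))
    du = _prop_vector(_lookup(props, pair.duplicate.accession))
    return {p: abs(ex[p] - du[p]) for p in PROPERTIES}


def duplicates_mean_differences(
    group: MergedGroup, props: Mapping[str, SequenceProperties]
) -> dict[str, float]:
    """|exemplar - mean of members| (exemplar excluded from the mean)."""
    ex = _prop_vector(_lookup(props, group.exemplar_accession))
    members = [_prop_vector(_lookup(props, m)) for m in group.member_accessions]
    out = {}
    for p in PROPERTIES:
        values = [m[p] for m in members]
        if all(v == ex[p] for v in values):
            out[p] = 0.0
        else:
            out[p] = abs(ex[p] - float(np.mean(values)))
    return out


def aggregate(
    differences: Sequence[Mapping[str, float]],
    labels: Sequence[str],
    organisms: Sequence[str],
    setting: str,
    ddof: int = 1,
) -> pd.DataFrame:
    """Aggregate per-unit absolute differences into the report table.

    One row per (organism, category) plus an (organism, "ALL") row that
    aggregates every unit exactly once. ``std`` uses the sample (n-1)
    convention by default; a single-unit cell reports 0.0.
    """
    if not (len(differences) == len(labels) == len(organisms)):
        raise ValueError("differences, labels and organisms must align")
    if not differences:
        return pd.DataFrame(
            columns=["organism", "category", "setting", "size"]
            + [f"{stat}_{p}" for p in PROPERTIES for stat in ("mdiff", "std")]
        )
    df = pd.DataFrame(
        [
            {"organism": org, "category": lab, **{p: d[p] for p in PROPERTIES}}
            for d, lab, org in zip(differences, labels, organisms)
        ]
    )
    rows = []
    for organism, sub in df.groupby("organism", sort=True):
        cats = sorted(sub["category"].unique())
        for cat in cats + ["ALL"]:
            cell = sub if cat == "ALL" else sub[sub["category"] == cat]
            row = {
                "organism": organism,
                "category": cat,
                "setting": setting,
                "size": len(cell),
            }
            for p in PROPERTIES:
                row[f"mdiff_{p}"] = float(cell[p].mean())
                if len(cell) > ddof:
                    row[f"std_{p}"] = float(cell[p].std(ddof=ddof))
                else:
                    row[f"std_{p}"] = 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def redundancy_reduction(groups: Sequence[MergedGroup]) -> float:
    """Percentage size reduction achieved by keeping one exemplar per group.

    100 x (1 - groups / records). Since every group holds an exemplar plus at
    least one member, the reduction is structurally >= 50%.
    """
    if not groups:
        raise ValueError("no groups")
    n_groups = len(groups)
    n_records = sum(g.n_records for g in groups)
    return 100.0 * (1.0 - n_groups / n_records)


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration.

    Either ``fasta`` + ``groups`` name input files, or ``synthetic`` holds a
    generator config (see :mod:`seqdup.synthetic`); exactly one source must
    be given.
    """

    fasta: Optional[str] = None
    groups: Optional[str] = None
    synthetic: Optional[object] = None  # GeneratorConfig
    scoring: ScoringConfig = ScoringConfig()
    thresholds: CategoryThresholds = CategoryThresholds()
    tm: TmConfig = TmConfig()
    pair_mode: str = "pairwise"  # or "duplicates_mean"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.fasta is None or self.groups is None):
            raise ValueError(
                "configure either input files (fasta + groups) or a synthetic block"
            )
        if self.pair_mode not in ("pairwise", "duplicates_mean"):
            raise ValueError("pair_mode must be 'pairwise' or 'duplicates_mean'")


@dataclass
class PipelineResult:
    pair_table: pd.DataFrame
    summary: pd.DataFrame
    group_impact: pd.DataFrame
    pair_impact: pd.DataFrame
    redundancy_reduction: float
    properties: dict[str, SequenceProperties]


def compute_alignments(
    pairs: Sequence[DuplicatePair], scoring: ScoringConfig = ScoringConfig()
) -> dict[tuple[str, str], Optional[AlignmentResult]]:
    """Align every pair; length-capped pairs map to None (the LS flag)."""
    out: dict[tuple[str, str], Optional[AlignmentResult]] = {}
    for pair in pairs:
        try:
            out[pair.key] = local_align(
                pair.exemplar.sequence, pair.duplicate.sequence, scoring
            )
        except LongSequenceError:
            out[pair.key] = None
    return out


def compute_properties(
    records: Mapping[str, NucleotideRecord], tm: TmConfig = TmConfig()
) -> dict[str, SequenceProperties]:
    return {acc: sequence_properties(rec.sequence, tm) for acc, rec in records.items()}


def run_pipeline(
    config: PipelineConfig, out_dir: Optional[str | Path] = None
) -> PipelineResult:
    """Run the full analysis: expand, align, categorize, measure impact.

    With ``out_dir`` set, writes ``pairs.tsv``, ``table2_counts.tsv``,
    ``table3_group_impact.tsv``, ``table4_pair_impact.tsv`` and a run
    manifest. Deterministic for a fixed config (the only randomness is the
    synthetic generator's seed).
    """
    if config.synthetic is not None:
        from .synthetic import generate_benchmark

        bench = generate_benchmark(config.synthetic)
        records = bench.records
        groups = bench.groups
        pairs = bench.pairs
    else:
        records = {r.accession: r for r in read_fasta(config.fasta)}
        groups = read_group_table(config.groups)
        pairs = expand_groups(groups, records)

    alignments = compute_alignments(pairs, config.scoring)
    pair_table, summary = categorize_pairs(pairs, alignments, config.thresholds)
    props = compute_properties(records, config.tm)

    labels = list(pair_table["seq_category"])
    organisms = [p.organism for p in pairs]

    group_by_id = {g.group_id: g for g in groups}
    group_diffs = {
        gid: group_differences(g, props) for gid, g in group_by_id.items()
    }
    group_setting = [group_diffs[p.group_id] for p in pairs]
    group_impact = aggregate(group_setting, labels, organisms, setting="group")

    if config.pair_mode == "pairwise":
        pair_setting = [pair_differences(p, props) for p in pairs]
    else:
        dup_mean = {
            gid: duplicates_mean_differences(g, props)
            for gid, g in group_by_id.items()
        }
        pair_setting = [dup_mean[p.group_id] for p in pairs]
    pair_impact = aggregate(pair_setting, labels, organisms, setting="pair")

    reduction = redundancy_reduction(groups)

    result = PipelineResult(
        pair_table=pair_table,
        summary=summary,
        group_impact=group_impact,
        pair_impact=pair_impact,
        redundancy_reduction=reduction,
        properties=props,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pair_table(pairs, out / "pairs.tsv")
        pair_table.to_csv(out / "pair_categories.tsv", sep="\t", index=False)
        summary.to_csv(out / "table2_counts.tsv", sep="\t", index=False)
        group_impact.round(6).to_csv(
            out / "table3_group_impact.tsv", sep="\t", index=False
        )
        pair_impact.round(6).to_csv(
            out / "table4_pair_impact.tsv", sep="\t", index=False
        )
        manifest = _manifest(config, len(records), len(groups), len(pairs), reduction)
        with (out / "run_manifest.txt").open("w") as fh:
            for k, v in manifest.items():
                fh.write(f"{k}\t{v}\n")
    return result


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        try:
            return asdict(o)
        except TypeError:
            return repr(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _manifest(
    config: PipelineConfig,
    n_records: int,
    n_groups: int,
    n_pairs: int,
    reduction: float,
) -> dict[str, str]:
    seed = getattr(config.synthetic, "seed", "") if config.synthetic else ""
    return {
        "seqdup_version": __version__,
        "config_hash": _config_hash(config),
        "seed": str(seed),
        "inputs": config.fasta or "synthetic",
        "n_records": str(n_records),
        "n_groups": str(n_groups),
        "n_pairs": str(n_pairs),
        "redundancy_reduction_pct": f"{reduction:.4f}",
    }
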