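"""Seeded synthetic benchmarks emulating merged-record groups.

The generator produces records, merged groups and ground-truth labels whose
members realize each duplicate category by construction:

* ES — an exact copy of the exemplar;
* SS — a full-length copy with point substitutions placed to land the local
  identity inside ``ss_identity_range`` (no indels by default, so the
  intended identity is exactly controllable);
* EF — a contiguous substring whose length fraction is drawn from
  ``fragment_fraction_range``;
* SF — a fragment with SS-style substitutions on top;
* LI — a dinucleotide-shuffled copy (composition preserved, order destroyed,
  so LI pairs match exemplar GC and category effects on GC-impact statistics
  are isolated) or, in ``li_mode="random"``, a fresh random sequence.

Epsilon margins keep generated pairs away from the 90% / 100% category
boundaries so that truth-label recovery is a sharp test rather than a coin
flip. Annotation keywords ("WORKING DRAFT", "SEQUENCING IN PROGRESS",
"PREDICTED") are attached to duplicate definitions at configurable rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .records import DuplicatePair, MergedGroup, NucleotideRecord, write_fasta

__all__ = [
    "GeneratorConfig",
    "TruthLabel",
    "Benchmark",
    "generate_exemplar",
    "make_duplicate",
    "generate_benchmark",
    "write_benchmark",
    "dinucleotide_shuffle",
    "generate_offset_pairs",
]

_BASES = np.array(list("ACGT"))

_ANNOTATION_KEYWORDS = {
    "WD": "WORKING DRAFT",
    "SP": "SEQUENCING IN PROGRESS",
    "PR": "PREDICTED",
}

_SURNAMES = [
    "Smith", "Lee", "Chen", "Garcia", "Mueller", "Tanaka", "Singh", "Ivanov",
    "Rossi", "Kim", "Nguyen", "Brown", "Silva", "Kowalski", "Haddad",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs of the synthetic benchmark.

    Defaults describe the emulated merged-group structure: groups of 2-5
    records, a mix over the five sequence categories, sporadic annotation
    keywords, and exemplar lengths log-uniform between 500 and 20000 bases
    around a 42% mean GC typical of vertebrate genomic records.
    """

    seed: int = 0
    n_groups: int = 1000
    organisms: tuple[tuple[str, float], ...] = (
        ("Homo sapiens", 0.30),
        ("Bos taurus", 0.20),
        ("Danio rerio", 0.20),
        ("Rattus norvegicus", 0.15),
        ("Mus musculus", 0.15),
    )
    group_sizes: tuple[int, ...] = (2, 3, 4, 5)  # uniform over these
    category_mix: tuple[tuple[str, float], ...] = (
        ("ES", 0.30),
        ("SS", 0.20),
        ("EF", 0.20),
        ("SF", 0.15),
        ("LI", 0.15),
    )
    annotation_rates: tuple[tuple[str, float], ...] = (
        ("WD", 0.05),
        ("SP", 0.05),
        ("PR", 0.05),
    )
    length_range: tuple[int, int] = (500, 20000)  # log-uniform
    gc_mean: float = 0.42
    gc_spread: float = 0.05
    ss_identity_range: tuple[float, float] = (0.92, 0.98)
    # Lower bound keeps fragments long enough that a perfect fragment match is
    # an unambiguously significant alignment; a few-base "fragment" is a
    # chance word match, not an exact-fragment duplicate.
    fragment_fraction_range: tuple[float, float] = (0.20, 0.88)
    li_mode: str = "shuffled"  # or "random"
    margin_epsilon: float = 0.02
    ss_indels: bool = False  # robustness mode: allow indels in SS/SF

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.category_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1, got {total}")
        lo, hi = self.ss_identity_range
        eps = self.margin_epsilon
        if not (0.90 + eps <= lo < hi <= 1.0 - eps):
            raise ValueError("ss_identity_range must sit inside (0.90, 1.0) "
                             "with the epsilon margin")
        flo, fhi = self.fragment_fraction_range
        if not (0.0 < flo < fhi <= 0.90 - eps):
            raise ValueError("fragment_fraction_range must sit inside (0, 0.90) "
                             "with the epsilon margin")
        if self.li_mode not in ("shuffled", "random"):
            raise ValueError("li_mode must be 'shuffled' or 'random'")
        if self.length_range[0] < 100 or self.length_range[0] >= self.length_range[1]:
            raise ValueError("length_range must be increasing with minimum >= 100")
        if min(self.group_sizes) < 2:
            raise ValueError("every group needs at least 2 records")


@dataclass(frozen=True)
class TruthLabel:
    """Intended categories and generation parameters of one generated pair."""

    group_id: str
    exemplar: str
    duplicate: str
    seq_category: str
    annot_categories: frozenset[str]
    params: dict = field(default_factory=dict, compare=False)


@dataclass
class Benchmark:
    """In-memory synthetic benchmark: records, groups, pairs and truth."""

    config: GeneratorConfig
    records: dict[str, NucleotideRecord]
    groups: list[MergedGroup]
    pairs: list[DuplicatePair]
    truth: list[TruthLabel]

    @property
    def truth_by_pair(self) -> dict[tuple[str, str], TruthLabel]:
        return {(t.exemplar, t.duplicate): t for t in self.truth}


def generate_exemplar(cfg: GeneratorConfig, rng: np.random.Generator) -> str:
    """Random exemplar sequence: i.i.d. bases at a sampled GC target."""
    lo, hi = cfg.length_range
    length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if cfg.gc_spread > 0:
        gc = float(np.clip(rng.normal(cfg.gc_mean, cfg.gc_spread), 0.05, 0.95))
    else:
        gc = cfg.gc_mean
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _substitute(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply point substitutions at distinct positions (always to a new base)."""
    arr = np.array(list(seq))
    positions = rng.choice(len(arr), size=n_subs, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return "".join(arr)


def _indel(seq: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(1, len(seq) - 1))
    if rng.random() < 0.5 and len(seq) > 20:
        return seq[:pos] + seq[pos + 1 :]
    return seq[:pos] + str(_BASES[rng.integers(4)]) + seq[pos:]


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving exact dinucleotide (and base) counts.

    Altschul-Erickson Eulerian-path shuffle: the sequence is a walk on the
    4-vertex base graph; a random new walk with the same edge multiset is an
    exact dinucleotide shuffle. Last-edge choices are resampled until they
    form a tree toward the terminal vertex.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    succ: dict[str, list[str]] = {}
    for x, y in zip(seq, seq[1:]):
        succ.setdefault(x, []).append(y)
    last = seq[-1]
    vertices = [v for v in succ if v != last]
    for _ in range(1000):
        last_edge = {v: succ[v][rng.integers(len(succ[v]))] for v in vertices}
        # check every vertex reaches `last` through last-edges
        ok = True
        for v in vertices:
            cur, hops = v, 0
            while cur != last and hops <= 4:
                cur = last_edge.get(cur, last)
                hops += 1
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - 4-vertex graph converges in a few tries
        return "".join(rng.permutation(list(seq)))
    edges = {}
    for v, targets in succ.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        edges[v] = pool
    out = [seq[0]]
    counts = {v: 0 for v in succ}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = edges[cur][counts[cur]]
        counts[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_duplicate(
    exemplar: str,
    category: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    """Construct a duplicate sequence realizing one intended category.

    Returns the sequence and the generation parameters used (mutation count,
    fragment bounds), recorded in the pair's truth label.
    """
    L = len(exemplar)
    if category in ("EF", "SF") and L < 100:
        raise ValueError("fragment categories need an exemplar of >= 100 bases")
    if category == "ES":
        return exemplar, {}
    if category == "SS":
        identity = rng.uniform(*cfg.ss_identity_range)
        n_subs = max(1, round((1.0 - identity) * L))
        seq = _substitute(exemplar, n_subs, rng)
        if cfg.ss_indels:
            seq = _indel(seq, rng)
        return seq, {"target_identity": identity, "n_subs": n_subs}
    if category in ("EF", "SF"):
        frac = rng.uniform(*cfg.fragment_fraction_range)
        flen = max(40, round(frac * L))
        start = int(rng.integers(0, L - flen + 1))
        frag = exemplar[start : start + flen]
        params = {"fraction": frac, "start": start, "length": flen}
        if category == "SF":
            identity = rng.uniform(*cfg.ss_identity_range)
            n_subs = max(1, round((1.0 - identity) * flen))
            frag = _substitute(frag, n_subs, rng)
            if cfg.ss_indels:
                frag = _indel(frag, rng)
            params.update({"target_identity": identity, "n_subs": n_subs})
        return frag, params
    if category == "LI":
        if cfg.li_mode == "shuffled":
            return dinucleotide_shuffle(exemplar, rng), {"mode": "shuffled"}
        gc = (exemplar.count("G") + exemplar.count("C")) / L
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return "".join(_BASES[rng.choice(4, size=L, p=p)]), {"mode": "random"}
    raise ValueError(f"unknown category {category!r}")


def _submitters(rng: np.random.Generator) -> frozenset[str]:
    k = int(rng.integers(1, 4))
    names = rng.choice(len(_SURNAMES), size=k, replace=False)
    return frozenset(
        f"{_SURNAMES[i]},{chr(ord('A') + int(rng.integers(26)))}." for i in names
    )


def generate_benchmark(cfg: GeneratorConfig) -> Benchmark:
    """Generate a full benchmark: records, groups, pairs, truth labels.

    Deterministic for a fixed config (single seeded generator); each group
    draws an organism, an exemplar, and per-member categories from the mix.
    """
    rng = np.random.default_rng(cfg.seed)
    org_names = [name for name, _ in cfg.organisms]
    org_w = np.array([w for _, w in cfg.organisms], dtype=float)
    org_w = org_w / org_w.sum()
    cat_names = [c for c, _ in cfg.category_mix]
    cat_w = np.array([w for _, w in cfg.category_mix], dtype=float)
    cat_w = cat_w / cat_w.sum()
    annot_rates = dict(cfg.annotation_rates)

    records: dict[str, NucleotideRecord] = {}
    groups: list[MergedGroup] = []
    pairs: list[DuplicatePair] = []
    truth: list[TruthLabel] = []
    acc_counter = 0

    def next_acc() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"SYN{acc_counter:07d}.1"

    for g in range(cfg.n_groups):
        gid = f"g{g + 1:05d}"
        organism = org_names[rng.choice(len(org_names), p=org_w)]
        size = int(cfg.group_sizes[rng.integers(len(cfg.group_sizes))])
        ex_seq = generate_exemplar(cfg, rng)
        ex_acc = next_acc()
        exemplar = NucleotideRecord(
            accession=ex_acc,
            sequence=ex_seq,
            version=1,
            definition=f"{organism} clone {gid.upper()} genomic sequence, complete",
            organism=organism,
            submitters=_submitters(rng),
        )
        records[ex_acc] = exemplar
        member_accs: list[str] = []
        for _ in range(size - 1):
            category = cat_names[rng.choice(len(cat_names), p=cat_w)]
            seq, params = make_duplicate(ex_seq, category, cfg, rng)
            annots = frozenset(
                a for a, rate in annot_rates.items() if rng.random() < rate
            )
            definition = f"{organism} clone {gid.upper()} genomic sequence"
            for a in sorted(annots):
                definition += f", {_ANNOTATION_KEYWORDS[a]}"
            acc = next_acc()
            dup = NucleotideRecord(
                accession=acc,
                sequence=seq,
                version=1,
                definition=definition,
                organism=organism,
                submitters=_submitters(rng),
            )
            records[acc] = dup
            member_accs.append(acc)
            pairs.append(
                DuplicatePair(
                    exemplar=exemplar, duplicate=dup, group_id=gid,
                    organism=organism,
                )
            )
            truth.append(
                TruthLabel(
                    group_id=gid,
                    exemplar=ex_acc,
                    duplicate=acc,
                    seq_category=category,
                    annot_categories=annots,
                    params=params,
                )
            )
        groups.append(
            MergedGroup(
                group_id=gid,
                exemplar_accession=ex_acc,
                member_accessions=tuple(member_accs),
                organism=organism,
            )
        )
    return Benchmark(config=cfg, records=records, groups=groups, pairs=pairs,
                     truth=truth)


def write_benchmark(bench: Benchmark, out_dir: str | Path) -> None:
    """Write records.fasta, groups.tsv, truth.tsv and the resolved config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bench.records.values(), out / "records.fasta")
    group_rows = [
        {
            "group_id": g.group_id,
            "exemplar_accession": g.exemplar_accession,
            "member_accession": m,
            "organism": g.organism,
        }
        for g in bench.groups
        for m in g.member_accessions
    ]
    pd.DataFrame(group_rows).to_csv(out / "groups.tsv", sep="\t", index=False)
    truth_rows = [
        {
            "group_id": t.group_id,
            "exemplar": t.exemplar,
            "duplicate": t.duplicate,
            "true_seq_category": t.seq_category,
            "true_annot_categories": ";".join(sorted(t.annot_categories)),
            "params": json.dumps(t.params, sort_keys=True),
        }
        for t in bench.truth
    ]
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    with (out / "generator_config.json").open("w") as fh:
        json.dump(asdict(bench.config), fh, indent=2)


def generate_offset_pairs(
    n_pairs: int,
    gc_delta: float,
    length: int,
    seed: int,
    gc_mean: float = 0.42,
) -> tuple[list[DuplicatePair], dict]:
    """Designed-impact benchmark: duplicates with a fixed GC-target offset.

    Each pair is an exemplar at GC target ``gc_mean`` and an independent
    duplicate at target ``gc_mean + gc_delta`` of the same length. Used to
    check that the pair-setting mean absolute GC difference recovers the
    expected |difference| of the generating distribution. Returns the pairs
    and the generating-parameter dict (targets, per-sequence binomial
    variance of the empirical GC percentage).
    """
    rng = np.random.default_rng(seed)
    pairs: list[DuplicatePair] = []

    def seq_at(gc: float) -> str:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return "".join(_BASES[rng.choice(4, size=length, p=p)])

    for i in range(n_pairs):
        ex = NucleotideRecord(
            accession=f"OFFE{i:06d}", sequence=seq_at(gc_mean),
            organism="synthetic",
        )
        du = NucleotideRecord(
            accession=f"OFFD{i:06d}", sequence=seq_at(gc_mean + gc_delta),
            organism="synthetic",
        )
        pairs.append(
            DuplicatePair(exemplar=ex, duplicate=du, group_id=f"off{i:06d}",
                          organism="synthetic")
        )
    var_each = (
        (gc_mean * (1 - gc_mean) + (gc_mean + gc_delta) * (1 - gc_mean - gc_delta))
        / length
        * 100.0**2
    )
    params = {
        "gc_delta_percent": 100.0 * gc_delta,
        "diff_sigma_percent": float(np.sqrt(var_each)),
    }
    return pairs, params
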