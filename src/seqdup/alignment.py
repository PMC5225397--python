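"""Local alignment similarity statistics for duplicate pairs.

Two statistics drive the sequence-level categorization of a pair:

* **local identity** — 100 x identical bases / alignment length of the best
  local alignment;
* **alignment proportion** — 100 x identical bases / length of the *longer*
  sequence, a cheap proxy for global coverage that avoids a full global
  alignment.

The aligner is an exact affine-gap Smith-Waterman with BLASTN-like default
scoring (match +2, mismatch -3, gap open 5, gap extend 2; a gap of length L
costs open + L*extend). Significance follows Karlin-Altschul statistics,
E = K * m * n * exp(-lambda * S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numba
import numpy as np

__all__ = [
    "ScoringConfig",
    "KarlinAltschulParams",
    "AlignmentResult",
    "LongSequenceError",
    "local_align",
    "evalue",
    "read_blast_tab",
]


class LongSequenceError(ValueError):
    """Signalled when a sequence exceeds the configured alignment length cap.

    Callers map this condition to the LS (long sequence) category rather than
    aligning the pair.
    """


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Karlin-Altschul (K, lambda) constants for raw-score significance.

    Defaults are ungapped BLASTN-style constants for the +2/-3 scheme.
    """

    k: float = 0.41
    lam: float = 0.625


@dataclass(frozen=True)
class ScoringConfig:
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    evalue_cutoff: float = 1e-3
    min_score: int = 20
    max_length: int = 1_000_000
    stats: KarlinAltschulParams = KarlinAltschulParams()


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of the best local alignment of a pair.

    ``local_identity`` and ``alignment_proportion`` are percentages in
    [0, 100]; ``has_hit`` is false when the best score falls below the word-hit
    stand-in ``min_score`` or the E-value exceeds the cutoff.
    """

    raw_score: int
    identical_bases: int
    alignment_length: int
    local_identity: float
    alignment_proportion: float
    evalue: float
    has_hit: bool


def evalue(
    raw_score: int,
    len_a: int,
    len_b: int,
    stats: KarlinAltschulParams = KarlinAltschulParams(),
) -> float:
    """Expected number of chance local alignments scoring >= raw_score."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("sequence lengths must be positive")
    if raw_score < 0:
        raise ValueError("raw_score must be non-negative")
    return stats.k * len_a * len_b * math.exp(-stats.lam * raw_score)


@numba.njit(cache=True, inline="always")
def _better(s1, d1, si1, sj1, l1, s2, d2, si2, sj2, l2):
    # lexicographic preference: higher score, more identical bases, smaller
    # start on a, smaller start on b, shorter alignment
    if s1 != s2:
        return s1 > s2
    if d1 != d2:
        return d1 > d2
    if si1 != si2:
        return si1 < si2
    if sj1 != sj2:
        return sj1 < sj2
    return l1 < l2


@numba.njit(cache=True)
def _sw_affine(a, b, match, mismatch, gap_open, gap_extend):
    """Affine-gap Smith-Waterman over encoded sequences.

    Tracks, per DP state and cell, the (score, identical-base count, start
    coordinates, alignment length) of the preferred optimal path so the
    reported statistics are deterministic under the tie-break order of
    ``_better``. Rolling rows keep memory linear in len(b).

    Returns (score, identical_bases, alignment_length); all zero when no
    positive-scoring local alignment exists.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int64(-(2**40))
    go = np.int64(gap_open)
    ge = np.int64(gap_extend)

    # state M: alignment ends with a[i] paired to b[j]
    pMs = np.full(m + 1, NEG, np.int64)
    pMd = np.zeros(m + 1, np.int64)
    pMsi = np.zeros(m + 1, np.int64)
    pMsj = np.zeros(m + 1, np.int64)
    pMl = np.zeros(m + 1, np.int64)
    cMs = np.full(m + 1, NEG, np.int64)
    cMd = np.zeros(m + 1, np.int64)
    cMsi = np.zeros(m + 1, np.int64)
    cMsj = np.zeros(m + 1, np.int64)
    cMl = np.zeros(m + 1, np.int64)
    # state X: ends with a[i] paired to a gap (vertical)
    pXs = np.full(m + 1, NEG, np.int64)
    pXd = np.zeros(m + 1, np.int64)
    pXsi = np.zeros(m + 1, np.int64)
    pXsj = np.zeros(m + 1, np.int64)
    pXl = np.zeros(m + 1, np.int64)
    cXs = np.full(m + 1, NEG, np.int64)
    cXd = np.zeros(m + 1, np.int64)
    cXsi = np.zeros(m + 1, np.int64)
    cXsj = np.zeros(m + 1, np.int64)
    cXl = np.zeros(m + 1, np.int64)
    # state Y: ends with b[j] paired to a gap (horizontal); previous row is
    # still needed as a diagonal predecessor of M
    pYs = np.full(m + 1, NEG, np.int64)
    pYd = np.zeros(m + 1, np.int64)
    pYsi = np.zeros(m + 1, np.int64)
    pYsj = np.zeros(m + 1, np.int64)
    pYl = np.zeros(m + 1, np.int64)
    cYs = np.full(m + 1, NEG, np.int64)
    cYd = np.zeros(m + 1, np.int64)
    cYsi = np.zeros(m + 1, np.int64)
    cYsj = np.zeros(m + 1, np.int64)
    cYl = np.zeros(m + 1, np.int64)

    bs = np.int64(0)
    bd = np.int64(0)
    bsi = np.int64(0)
    bsj = np.int64(0)
    bl = np.int64(0)
    found = False

    for i in range(1, n + 1):
        cMs[0] = NEG
        cXs[0] = NEG
        cYs[0] = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            # X[i,j] from row i-1
            s1 = pMs[j] - go - ge
            s2 = pXs[j] - ge
            if pMs[j] > NEG and (pXs[j] <= NEG or _better(
                s1, pMd[j], pMsi[j], pMsj[j], pMl[j],
                s2, pXd[j], pXsi[j], pXsj[j], pXl[j],
            )):
                cXs[j] = s1
                cXd[j] = pMd[j]
                cXsi[j] = pMsi[j]
                cXsj[j] = pMsj[j]
                cXl[j] = pMl[j] + 1
            elif pXs[j] > NEG:
                cXs[j] = s2
                cXd[j] = pXd[j]
                cXsi[j] = pXsi[j]
                cXsj[j] = pXsj[j]
                cXl[j] = pXl[j] + 1
            else:
                cXs[j] = NEG

            # Y[i,j] from column j-1 of the current row
            s1 = cMs[j - 1] - go - ge
            s2 = cYs[j - 1] - ge
            if cMs[j - 1] > NEG and (cYs[j - 1] <= NEG or _better(
                s1, cMd[j - 1], cMsi[j - 1], cMsj[j - 1], cMl[j - 1],
                s2, cYd[j - 1], cYsi[j - 1], cYsj[j - 1], cYl[j - 1],
            )):
                cYs[j] = s1
                cYd[j] = cMd[j - 1]
                cYsi[j] = cMsi[j - 1]
                cYsj[j] = cMsj[j - 1]
                cYl[j] = cMl[j - 1] + 1
            elif cYs[j - 1] > NEG:
                cYs[j] = s2
                cYd[j] = cYd[j - 1]
                cYsi[j] = cYsi[j - 1]
                cYsj[j] = cYsj[j - 1]
                cYl[j] = cYl[j - 1] + 1
            else:
                cYs[j] = NEG

            # M[i,j]: best diagonal predecessor or a fresh start at (i,j)
            eq = np.int64(1) if ai == b[j - 1] else np.int64(0)
            sub = np.int64(match) if eq == 1 else np.int64(mismatch)
            ps = np.int64(0)
            pd_ = np.int64(0)
            psi = np.int64(i)
            psj = np.int64(j)
            pl = np.int64(0)
            if pMs[j - 1] > NEG and _better(
                pMs[j - 1], pMd[j - 1], pMsi[j - 1], pMsj[j - 1], pMl[j - 1],
                ps, pd_, psi, psj, pl,
            ):
                ps = pMs[j - 1]
                pd_ = pMd[j - 1]
                psi = pMsi[j - 1]
                psj = pMsj[j - 1]
                pl = pMl[j - 1]
            if pXs[j - 1] > NEG and _better(
                pXs[j - 1], pXd[j - 1], pXsi[j - 1], pXsj[j - 1], pXl[j - 1],
                ps, pd_, psi, psj, pl,
            ):
                ps = pXs[j - 1]
                pd_ = pXd[j - 1]
                psi = pXsi[j - 1]
                psj = pXsj[j - 1]
                pl = pXl[j - 1]
            if pYs[j - 1] > NEG and _better(
                pYs[j - 1], pYd[j - 1], pYsi[j - 1], pYsj[j - 1], pYl[j - 1],
                ps, pd_, psi, psj, pl,
            ):
                ps = pYs[j - 1]
                pd_ = pYd[j - 1]
                psi = pYsi[j - 1]
                psj = pYsj[j - 1]
                pl = pYl[j - 1]
            cMs[j] = ps + sub
            cMd[j] = pd_ + eq
            cMsi[j] = psi
            cMsj[j] = psj
            cMl[j] = pl + 1

            if cMs[j] > 0:
                if (not found) or _better(
                    cMs[j], cMd[j], cMsi[j], cMsj[j], cMl[j],
                    bs, bd, bsi, bsj, bl,
                ):
                    bs = cMs[j]
                    bd = cMd[j]
                    bsi = cMsi[j]
                    bsj = cMsj[j]
                    bl = cMl[j]
                    found = True

        # roll rows
        pMs, cMs = cMs, pMs
        pMd, cMd = cMd, pMd
        pMsi, cMsi = cMsi, pMsi
        pMsj, cMsj = cMsj, pMsj
        pMl, cMl = cMl, pMl
        pXs, cXs = cXs, pXs
        pXd, cXd = cXd, pXd
        pXsi, cXsi = cXsi, pXsi
        pXsj, cXsj = cXsj, pXsj
        pXl, cXl = cXl, pXl
        pYs, cYs = cYs, pYs
        pYd, cYd = cYd, pYd
        pYsi, cYsi = cYsi, pYsi
        pYsj, cYsj = cYsj, pYsj
        pYl, cYl = cYl, pYl

    if not found:
        return np.int64(0), np.int64(0), np.int64(0)
    return bs, bd, bl


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _result(
    score: int,
    ident: int,
    aln_len: int,
    len_a: int,
    len_b: int,
    scoring: ScoringConfig,
) -> AlignmentResult:
    e = evalue(max(score, 0), len_a, len_b, scoring.stats)
    if aln_len > 0:
        identity = 100.0 * ident / aln_len
    else:
        identity = 0.0
    proportion = 100.0 * ident / max(len_a, len_b)
    has_hit = aln_len > 0 and score >= scoring.min_score and e <= scoring.evalue_cutoff
    return AlignmentResult(
        raw_score=int(score),
        identical_bases=int(ident),
        alignment_length=int(aln_len),
        local_identity=identity,
        alignment_proportion=proportion,
        evalue=e,
        has_hit=has_hit,
    )


def local_align(
    a: str, b: str, scoring: ScoringConfig = ScoringConfig()
) -> AlignmentResult:
    """Best local alignment of two nucleotide sequences.

    Exact Smith-Waterman with affine gaps. On score ties the reported
    alignment is the one with most identical bases, then smallest start on
    ``a``, then on ``b`` (and, as a final deterministic tie-break, the
    shortest). Ambiguity codes never count as identical bases.

    Raises :class:`LongSequenceError` when either sequence exceeds
    ``scoring.max_length``; callers map this to the LS category.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if len(a) > scoring.max_length or len(b) > scoring.max_length:
        raise LongSequenceError(
            f"sequence length exceeds cap {scoring.max_length}"
        )
    # Exact-copy / exact-substring fast paths: a full-length perfect match is
    # the unique optimum (maximal score = match * len(short), maximal
    # identical-base count), so the DP can be skipped.
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if scoring.match > 0 and short in long_:
        score = scoring.match * len(short)
        return _result(score, len(short), len(short), len(a), len(b), scoring)
    score, ident, aln_len = _sw_affine(
        _encode(a),
        _encode(b),
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    return _result(int(score), int(ident), int(aln_len), len(a), len(b), scoring)


def read_blast_tab(
    path: str | Path,
    seq_lengths: Mapping[str, int],
    scoring: ScoringConfig = ScoringConfig(),
) -> dict[tuple[str, str], AlignmentResult]:
    """Read a BLAST tabular (outfmt-6 style) hit file as alignment results.

    Expected columns: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore. Identical-base counts are recovered
    from pident x length. ``seq_lengths`` supplies the full sequence lengths
    needed for the alignment-proportion denominator. Only the best hit
    (first occurrence, BLAST sorts by significance) per pair is kept.

    This is an optional substitute for the native aligner in parity runs
    against heuristic BLAST output.
    """
    results: dict[tuple[str, str], AlignmentResult] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"BLAST tabular line has <12 columns: {line!r}")
            q, s = fields[0], fields[1]
            if (q, s) in results:
                continue
            pident = float(fields[2])
            aln_len = int(fields[3])
            e = float(fields[10])
            ident = round(pident * aln_len / 100.0)
            la, lb = seq_lengths[q], seq_lengths[s]
            results[(q, s)] = AlignmentResult(
                raw_score=int(round(float(fields[11]))),
                identical_bases=ident,
                alignment_length=aln_len,
                local_identity=pident,
                alignment_proportion=100.0 * ident / max(la, lb),
                evalue=e,
                has_hit=e <= scoring.evalue_cutoff,
            )
    return results
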