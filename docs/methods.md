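# Methods

## The analysis in brief

The unit of analysis is the exemplar–duplicate pair: one record retained by
database curators and one record merged into it. A merged group with k
members yields exactly k pairs, so a dataset of G groups and R records
(R = G + Σ members) produces R − G pairs, and removing duplicates shrinks
the collection by 100 · (1 − G/R) percent — at least 50% whenever every
group merged at least one record (a structural identity, not an empirical
finding).

Each pair is classified twice: at sequence level from the best local
alignment, and at annotation level from DEFINITION keywords. The impact
stage then asks how much each duplicate category perturbs per-sequence
properties that downstream analyses consume.

## Alignment model

The aligner is an exact affine-gap Smith–Waterman. Scoring defaults are
BLASTN-like: match +2, mismatch −3, gap open 5, gap extend 2, with a gap of
length L costing open + L·extend. Heuristic seeded aligners approximate
exactly this optimum; at the problem sizes used here the exact optimum is
affordable and removes heuristic variability from the categorization. An
adapter for BLAST tabular output (`read_blast_tab`) exists for parity runs
against heuristic results on the same pairs.

Statistics reported per pair:

* raw score S of the optimal local alignment;
* identical bases d (matched columns with equal residues; ambiguity codes
  never count as identical);
* alignment length L_aln (columns including gaps);
* local identity 100·d/L_aln and alignment proportion 100·d/max(|a|,|b|);
* E-value K·m·n·e^(−λS) with ungapped BLASTN-style constants K = 0.41,
  λ = 0.625 for the +2/−3 scheme (configurable).

Determinism under ties: among score-optimal alignments the kernel prefers
most identical bases, then smallest start on the first sequence, then on
the second. These four keys still do not always pin down a unique alignment
length (e.g. interchangeable gap placements), so a final tie-break prefers
the shorter alignment. The DP carries the (score, identical, start-a,
start-b, length) tuple per cell and state, which makes the lexicographic
choice exact without a traceback matrix and keeps memory linear in the
shorter sequence.

`has_hit` is false when S falls below `min_score` (default 20 raw, a
stand-in for a seeded aligner's word-hit requirement) or the E-value
exceeds `evalue_cutoff` (default 0.001). An exact-copy / exact-substring
fast path skips the DP: a full-length perfect match is provably the unique
optimum under positive match scores.

Sequences longer than `max_length` (default 1,000,000) are not aligned;
their pairs are flagged LS. A length cap is the natural mechanism for a
"long sequence" category: quadratic alignment cost makes arbitrarily long
pairs impractical to classify by alignment.

## Categorization decision table

Decision order: LS (length cap) → LI (no hit, or E > 0.001, or identity
< 90%) → ES (identity = proportion = 100%) → EF (identity 100%, proportion
< 90%) → SF (identity in [90, 100), proportion < 90%) → SS (identity in
[90, 100], proportion in [90, 100)) → UC. The order makes the three LI
tests disjunctive and gives them precedence: a short perfect chance match
can show 100% identity yet be insignificant, and such pairs are low
identity, not exact.

Two cells deserve comment. The band rules leave (identity = 100,
proportion ∈ [90, 100)) unassigned; it is mapped to SS because such a pair
is near-identical overall but not exact. Proportion = 100 forces identity
= 100 (d = max length ⇒ alignment is a full-length perfect match), so ES
is equivalent to character identity and UC is unreachable at the default
thresholds — it exists so that reconfigured thresholds still yield a total
decision table. Thresholds (90, 100, 0.001) are exposed in
`CategoryThresholds`.

Annotation categories are substring tests for "WORKING DRAFT",
"SEQUENCING IN PROGRESS" and "PREDICTED" on case-folded,
whitespace-normalized DEFINITION text of either record; they are
independent of each other and of the sequence category.

## Sequence properties

GC content is 100·(G+C)/(A+C+G+T) over unambiguous bases; ambiguity codes
(including N) are excluded from numerator and denominator. All melting
temperatures strip ambiguity codes first, so GC and Tm see the same base
counts; at least 8 unambiguous bases are required.

* **Tm_basic**: Wallace rule 2(A+T) + 4(G+C) below 14 bases; Marmur–Doty
  64.9 + 41·(GC − 16.4)/L from 14 bases.
* **Tm_salt**: 100.5 + 41·GC/L − 820/L + 16.6·log10[Na+] from 14 bases;
  below 14 the Wallace estimate shifted by 16.6·(log10[Na+] − log10 0.05),
  so both short-oligo forms coincide at the 50 mM reference.
* **Tm_advanced**: nearest-neighbor thermodynamics,
  Tm = 1000·ΔH / (ΔS + R·ln(C_T/4)) − 273.15 + 16.6·log10[Na+], with the
  unified SantaLucia-1998 dimer stack and terminal-initiation parameters,
  R = 1.9872 cal/mol/K, C_T = 5·10⁻⁷ M (non-self-complementary convention),
  [Na+] = 0.05 M. Every constant lives in `TmConfig`/`NN_TABLES`, so
  alternative parameter sets drop in without code change.

These three forms are the canonical basic / salt-adjusted / nearest-
neighbor trio. They are oligo-calibrated; applying them to full-length
records (as the impact analysis does) is an interpretation convention, not
a thermodynamic prediction, and is consistent across all categories being
compared. Stripping an ambiguity code joins its neighbors into a stack;
given how rare ambiguity codes are in these records the effect is
negligible, and determinism matters more here than interpolating unknown
stacks.

## Impact statistics

For property p, each pair contributes |p(exemplar) − p(comparison)|:

* **group setting** — comparison is the mean of the original group
  *including* the exemplar (this choice materially shrinks deviations and
  is made explicit in `group_differences`); the group's difference is
  counted once per member pair, so "size" counts pairs in both settings;
* **pair setting** — comparison is the duplicate itself (default), or the
  mean of the group's duplicates with `pair_mode: duplicates_mean`.

mdiff is the mean and std the sample (n−1) standard deviation per
(organism × category) cell and per organism "ALL" row; a single-unit cell
reports std 0. Because |Σᵢ Δᵢ|/(k+1) ≤ (Σᵢ|Δᵢ|)/(k+1) < meanᵢ|Δᵢ| for any
group with k ≥ 1 members, the pair-setting mdiff dominates the
group-setting mdiff for any aggregate that unions whole groups — the
tests verify this ordering on matched data rather than assuming it.

## Synthetic benchmark generator

The generator emulates the statistical structure of curator-merged groups:
1000 groups by default, sizes uniform on {2..5}, five organisms with fixed
weights (cosmetic labels for grouping — there is no organism-specific
sequence model), exemplars i.i.d. at a Gaussian GC target (mean 0.42,
spread 0.05, typical of vertebrate genomic records), lengths log-uniform.
Category mix defaults: ES 0.30, SS 0.20, EF 0.20, SF 0.15, LI 0.15 —
exact copies most common, with every category well represented. Annotation
keywords are attached to duplicate definitions independently at 5% each.

Per-category construction:

* ES — exact copy;
* SS — substitutions only (no indels by default, so the intended identity
  is exactly controllable), target identity uniform in (0.92, 0.98);
* EF — contiguous substring, length fraction uniform in (0.20, 0.88);
* SF — fragment plus SS-style substitutions;
* LI — Altschul–Erickson dinucleotide shuffle (preserves composition,
  destroys order, so LI pairs match exemplar GC and the category's effect
  on GC-impact statistics is isolated), or a fresh random sequence in
  `li_mode: random`.

The ε-margins (default 0.02) keep intended identities and fractions away
from the 90%/100% decision boundaries, making truth-label recovery a sharp
test instead of a coin flip: local alignment may trim a few mismatch-dense
terminal bases of an SS pair, shifting realized identity slightly above
target and proportion slightly below, and the margins absorb exactly this
kind of edge effect. The fragment-fraction floor of 0.20 reflects what the
EF/SF categories mean: an exact-fragment duplicate is a *significant*
perfect alignment, and a few-base substring is a chance word match that no
significance test should (or does) call a duplicate. An `ss_indels` flag
exists for robustness experiments.

A separate designed-impact generator (`generate_offset_pairs`) emits pairs
whose duplicate GC target is offset by a fixed δ; the expected mean
absolute GC difference is then the folded-normal mean of N(100δ, σ²) with
σ² the summed binomial sampling variances, giving an analytic target for
signal-recovery checks.

## Problem sizes and numerical choices

Full-pipeline tests and the acceptance script run 1000 groups with
exemplar lengths log-uniform 200–2000 — a scaled problem size chosen so a
complete closed-loop run takes well under a minute while every category
still appears hundreds of times; the generator's default length range for
standalone use remains 500–20000. The GC-offset check uses 1000 pairs of
1000 bases at δ = 5 GC points. All randomness flows from a single seed per
run; reports are byte-identical across repeated runs of the same config.

Floating-point conventions: identity and proportion are exact 100.0
precisely when the underlying counts coincide (integer division is exact
there), so the ES test needs no tolerance; group means of identical
property values short-circuit to an exact 0 difference so the ES-only null
is exact, not approximate; report TSVs round to 6 decimals while
in-memory results keep full precision.

## Known limitations

* Alignment cost is quadratic; genuinely long records are classified LS
  rather than aligned (as the LS category intends).
* The generator does not emulate repeats, coding structure or
  per-organism duplicate prevalence; recovery rates on it bound what the
  decision rules do under their own assumptions, not performance on real
  database records, where near-threshold pairs and biological repeat
  structure will blur category boundaries.
* Submitter metadata is compared by normalized exact name overlap;
  consortium aliases or transliteration variants are out of scope.
* Tm formulas are applied outside their oligo calibration range on long
  records, by design (see above).
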