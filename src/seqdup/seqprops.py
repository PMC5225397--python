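"""Case-study sequence properties: GC content and melting temperatures.

Three melting-temperature estimates are computed, spanning the standard
ladder of sophistication:

* ``tm_basic`` — the Wallace 2+4 rule for short oligos (< 14 bases),
  switching to the Marmur-Doty GC/length formula for longer sequences;
* ``tm_salt`` — the salt-adjusted Marmur-Schildkraut-Doty form with a
  16.6 log10[Na+] correction (the short-oligo branch applies the same
  correction relative to the 50 mM reference);
* ``tm_advanced`` — nearest-neighbor thermodynamics with the unified
  SantaLucia 1998 stack/initiation parameters,
  Tm = dH / (dS + R ln(CT/4)) - 273.15 + 16.6 log10([Na+]).

All properties are computed on the unambiguous bases only: ambiguity codes
(including N) are excluded from the GC numerator and denominator and stripped
before any Tm computation, so GC and Tm see the same base counts. The
formulas are oligo-oriented but are applied to full-length records, matching
how the duplicate impact analysis uses them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SequenceProperties",
    "TmConfig",
    "gc_content",
    "tm_basic",
    "tm_salt",
    "tm_advanced",
    "sequence_properties",
    "NN_TABLES",
]

#: gas constant, cal / (mol K)
R_CAL = 1.9872

#: minimum unambiguous length for a melting-temperature estimate
MIN_TM_LENGTH = 8

#: reference sodium molarity at which tm_basic is calibrated (mol/L)
_NA_REFERENCE = 0.05

# Unified nearest-neighbor parameters (dH kcal/mol, dS cal/(mol K)) for DNA/DNA
# duplexes, SantaLucia 1998 unified set. Keys are 5'->3' dimers on one strand;
# reverse-complement dimers share parameters and are filled in below.
_SANTALUCIA_1998 = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _full_nn_table(core: dict[str, tuple[float, float]]) -> dict[str, tuple[float, float]]:
    table = dict(core)
    for dimer in [a + b for a in "ACGT" for b in "ACGT"]:
        if dimer not in table:
            table[dimer] = core[_revcomp(dimer)]
    return table


#: named nearest-neighbor parameter sets; each maps every 5'->3' dimer to
#: (dH kcal/mol, dS cal/(mol K)) plus per-terminal initiation entries
#: "init_AT" / "init_GC".
NN_TABLES: dict[str, dict[str, tuple[float, float]]] = {
    "santalucia1998": {
        **_full_nn_table(_SANTALUCIA_1998),
        "init_AT": (2.3, 4.1),
        "init_GC": (0.1, -2.8),
    }
}


@dataclass(frozen=True)
class TmConfig:
    """Melting-temperature parameters.

    ``sodium_molarity`` in mol/L (default 50 mM); ``oligo_molarity`` is the
    total strand concentration CT in mol/L (default 0.5 uM, non-self-
    complementary convention CT/4); ``nn_parameter_set`` names an entry of
    :data:`NN_TABLES`.
    """

    sodium_molarity: float = 0.05
    oligo_molarity: float = 5e-7
    nn_parameter_set: str = "santalucia1998"

    def __post_init__(self) -> None:
        if self.sodium_molarity <= 0 or self.oligo_molarity <= 0:
            raise ValueError("molarities must be positive")
        if self.nn_parameter_set not in NN_TABLES:
            raise ValueError(f"unknown parameter set {self.nn_parameter_set!r}")


@dataclass(frozen=True)
class SequenceProperties:
    gc_percent: float
    tm_basic: float
    tm_salt: float
    tm_advanced: float


def _unambiguous(seq: str) -> str:
    return "".join(c for c in seq if c in "ACGT")


def gc_content(seq: str) -> float:
    """GC percentage over the unambiguous bases of the sequence."""
    if not seq:
        raise ValueError("empty sequence")
    core = _unambiguous(seq)
    if not core:
        raise ValueError("sequence has no unambiguous A/C/G/T bases")
    gc = core.count("G") + core.count("C")
    return 100.0 * gc / len(core)


def _tm_core(seq: str) -> str:
    core = _unambiguous(seq)
    if len(core) < MIN_TM_LENGTH:
        raise ValueError(
            f"need >= {MIN_TM_LENGTH} unambiguous bases for a melting "
            f"temperature, got {len(core)}"
        )
    return core


def tm_basic(seq: str) -> float:
    """Wallace rule (< 14 bases) / Marmur-Doty formula (>= 14 bases), deg C."""
    core = _tm_core(seq)
    n = len(core)
    gc = core.count("G") + core.count("C")
    at = n - gc
    if n < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / n


def tm_salt(seq: str, cfg: TmConfig = TmConfig()) -> float:
    """Salt-adjusted melting temperature, deg C.

    For >= 14 bases: Tm = 100.5 + 41 GC/L - 820/L + 16.6 log10([Na+]).
    Below 14 bases the Wallace estimate is shifted by the same log-salt term
    relative to its 50 mM calibration point, so at [Na+] = 50 mM the two
    short-oligo estimates coincide.
    """
    core = _tm_core(seq)
    n = len(core)
    gc = core.count("G") + core.count("C")
    log_na = math.log10(cfg.sodium_molarity)
    if n < 14:
        return tm_basic(seq) + 16.6 * (log_na - math.log10(_NA_REFERENCE))
    return 100.5 + 41.0 * gc / n - 820.0 / n + 16.6 * log_na


def tm_advanced(seq: str, cfg: TmConfig = TmConfig()) -> float:
    """Nearest-neighbor melting temperature, deg C.

    Sums dimer stacking enthalpies/entropies plus the two terminal initiation
    terms, then Tm = 1000 dH / (dS + R ln(CT/4)) - 273.15 + 16.6 log10([Na+]).
    Ambiguous bases are stripped before stacking, so an ambiguity code splits
    no stack in two — the neighbors on either side of it become adjacent.
    """
    core = _tm_core(seq)
    table = NN_TABLES[cfg.nn_parameter_set]
    dh = 0.0  # kcal/mol
    ds = 0.0  # cal/(mol K)
    for end in (core[0], core[-1]):
        h, s = table["init_AT"] if end in "AT" else table["init_GC"]
        dh += h
        ds += s
    for i in range(len(core) - 1):
        h, s = table[core[i : i + 2]]
        dh += h
        ds += s
    tm_kelvin = 1000.0 * dh / (ds + R_CAL * math.log(cfg.oligo_molarity / 4.0))
    return tm_kelvin - 273.15 + 16.6 * math.log10(cfg.sodium_molarity)


def sequence_properties(seq: str, cfg: TmConfig = TmConfig()) -> SequenceProperties:
    """Bundle of the four case-study properties for one sequence."""
    return SequenceProperties(
        gc_percent=gc_content(seq),
        tm_basic=tm_basic(seq),
        tm_salt=tm_salt(seq, cfg),
        tm_advanced=tm_advanced(seq, cfg),
    )
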