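"""Independent reference implementations used only as test oracles.

These deliberately use the plainest possible formulations (dense tuple DP,
literal parameter tables) and stay independent of the package's optimized
code paths.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def sw_brute(a: str, b: str, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """Brute-force affine-gap local alignment.

    Returns (score, identical_bases) of the best local alignment, maximizing
    identical bases among maximum-score alignments (lexicographic tuple max).
    A gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(a), len(b)
    M = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    X = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    Y = [[(NEG, 0)] * (m + 1) for _ in range(n + 1)]
    best = (0, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eq = a[i - 1] == b[j - 1]
            sub = match if eq else mismatch
            ps, pd = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], (0, 0))
            M[i][j] = (ps + sub, pd + (1 if eq else 0))
            X[i][j] = max(
                (M[i - 1][j][0] - gap_open - gap_extend, M[i - 1][j][1]),
                (X[i - 1][j][0] - gap_extend, X[i - 1][j][1]),
            )
            Y[i][j] = max(
                (M[i][j - 1][0] - gap_open - gap_extend, M[i][j - 1][1]),
                (Y[i][j - 1][0] - gap_extend, Y[i][j - 1][1]),
            )
            if M[i][j][0] > 0:
                best = max(best, M[i][j])
    return best


# Straight-line nearest-neighbor summation: every 5'->3' dimer written out
# literally (unified DNA/DNA duplex parameters; dH kcal/mol, dS cal/mol/K).
NN_DH = {
    "AA": -7.9, "AC": -8.4, "AG": -7.8, "AT": -7.2,
    "CA": -8.5, "CC": -8.0, "CG": -10.6, "CT": -7.8,
    "GA": -8.2, "GC": -9.8, "GG": -8.0, "GT": -8.4,
    "TA": -7.2, "TC": -8.2, "TG": -8.5, "TT": -7.9,
}
NN_DS = {
    "AA": -22.2, "AC": -22.4, "AG": -21.0, "AT": -20.4,
    "CA": -22.7, "CC": -19.9, "CG": -27.2, "CT": -21.0,
    "GA": -22.2, "GC": -24.4, "GG": -19.9, "GT": -22.4,
    "TA": -21.3, "TC": -22.2, "TG": -22.7, "TT": -22.2,
}


def tm_nn_straightline(seq: str, na: float = 0.05, ct: float = 5e-7) -> float:
    """Independent nearest-neighbor Tm: literal table, explicit loop."""
    dh = 0.0
    ds = 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        dh += NN_DH[seq[i : i + 2]]
        ds += NN_DS[seq[i : i + 2]]
    return 1000.0 * dh / (ds + 1.9872 * math.log(ct / 4.0)) - 273.15 + 16.6 * math.log10(na)
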