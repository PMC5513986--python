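"""Independent brute-force reference implementations used as test oracles.

Everything here is written as a naive O(n^2 * L) loop over sample pairs
or an explicit formula transcription, deliberately sharing no code with
the package's vectorized estimators.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

MISSING = -1


def pairwise_pi_oracle(rows: np.ndarray, cds_length: int) -> float:
    """Per-site theta-pi by looping over all sample pairs at every site."""
    n, s = rows.shape
    total = 0.0
    for j in range(s):
        diffs = 0
        pairs = 0
        for a in range(n):
            for b in range(a + 1, n):
                if rows[a, j] == MISSING or rows[b, j] == MISSING:
                    continue
                pairs += 1
                if rows[a, j] != rows[b, j]:
                    diffs += 1
        if pairs > 0:
            total += diffs / pairs
    return total / cds_length


def site_pi_oracle(col: np.ndarray) -> float:
    """Single-site pairwise difference rate over non-missing calls."""
    vals = col[col != MISSING]
    n = len(vals)
    if n < 2:
        return math.nan
    diffs = sum(1 for a in range(n) for b in range(a + 1, n)
                if vals[a] != vals[b])
    return diffs / (n * (n - 1) / 2)


def tajima_constants_exact(n: int) -> dict[str, Fraction]:
    """Tajima's D constants recomputed in exact rational arithmetic."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajima_d_oracle(rows: np.ndarray) -> float:
    """Tajima's D from explicit pairwise counting and exact constants."""
    n, s_total = rows.shape
    seg = 0
    kbar = 0.0
    for j in range(s_total):
        col = rows[:, j]
        vals = col[col != MISSING]
        if len(vals) >= 2 and 0 < vals.sum() < len(vals):
            seg += 1
        pi = site_pi_oracle(col)
        if not math.isnan(pi):
            kbar += pi
    if seg == 0 or n < 4:
        return math.nan
    c = tajima_constants_exact(n)
    var = float(c["e1"]) * seg + float(c["e2"]) * seg * (seg - 1)
    return (kbar - seg / float(c["a1"])) / math.sqrt(var)


def hudson_fst_oracle(rows_a: np.ndarray, rows_b: np.ndarray) -> float:
    """Gene-level Hudson F_ST by explicit pair loops, ratio of sums."""
    s = rows_a.shape[1]
    hw_sum = 0.0
    hb_sum = 0.0
    any_site = False
    for j in range(s):
        va = rows_a[:, j][rows_a[:, j] != MISSING]
        vb = rows_b[:, j][rows_b[:, j] != MISSING]
        if len(va) < 2 or len(vb) < 2:
            continue
        any_site = True
        pw_a = sum(1 for x in range(len(va)) for y in range(x + 1, len(va))
                   if va[x] != va[y]) / (len(va) * (len(va) - 1) / 2)
        pw_b = sum(1 for x in range(len(vb)) for y in range(x + 1, len(vb))
                   if vb[x] != vb[y]) / (len(vb) * (len(vb) - 1) / 2)
        hb = sum(1 for x in va for y in vb if x != y) / (len(va) * len(vb))
        hw_sum += 0.5 * (pw_a + pw_b)
        hb_sum += hb
    if not any_site or hb_sum == 0:
        return math.nan
    return 1.0 - hw_sum / hb_sum


def chi2_oracle(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square from the textbook 2x2 shortcut formula:
    N * (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return math.nan
    return n * (a * d - b * c) ** 2 / denom


CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def classify_oracle(codon: str, offset: int, alt: str) -> str:
    """Translate-and-compare classification from a hand-coded codon table."""
    mutated = codon[:offset] + alt + codon[offset + 1:]
    return ("synonymous" if CODON_TABLE[codon] == CODON_TABLE[mutated]
            else "nonsynonymous")
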