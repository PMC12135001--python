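"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity from first principles (exhaustive
enumeration, closed forms, hand-entered parameter tables) without
sharing code paths with the package implementation it checks.
"""

from __future__ import annotations

import math
from functools import cache
from itertools import groupby, permutations

from Bio.Seq import Seq

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# Global alignment score by exhaustive recursion (affine gaps:
# a gap of length L costs open + L * extend)


def brute_align_score(a: str, b: str, match=2.0, mismatch=-3.0, open_=-5.0, extend=-2.0) -> float:
    @cache
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG_INF
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            best = max(best, sub + rec(i + 1, j + 1, "M"))
        if i < len(a):
            gap = extend + (0.0 if prev == "A" else open_)
            best = max(best, gap + rec(i + 1, j, "A"))
        if j < len(b):
            gap = extend + (0.0 if prev == "B" else open_)
            best = max(best, gap + rec(i, j + 1, "B"))
        return best

    result = rec(0, 0, "M")
    rec.cache_clear()
    return result


# ---------------------------------------------------------------------------
# NG86 divergence, codon by codon


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_sites(codon: str) -> float:
    """Synonymous site count by direct enumeration of the 9 mutants."""
    aa = _translate(codon)
    syn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant_aa = _translate(codon[:pos] + base + codon[pos + 1 :])
            if mutant_aa == aa and mutant_aa != "*":
                syn += 1 / 3
    return syn


def oracle_codon_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged differences; pathways through stops dropped
    unless all are blocked."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    clean, stopped = [], []
    for order in permutations(positions):
        cur, syn, nonsyn, blocked = ca, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _translate(nxt) == "*":
                blocked = True
            if _translate(cur) == _translate(nxt) and _translate(nxt) != "*":
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (stopped if blocked else clean).append((syn, nonsyn))
    paths = clean or stopped
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_ng86_ds(a: str, b: str) -> float:
    """Full NG86 dS with Jukes-Cantor correction; nan when saturated."""
    assert len(a) == len(b) and len(a) % 3 == 0
    s_a = s_b = sd = 0.0
    n_codons = len(a) // 3
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if "-" in ca + cb or "N" in ca + cb:
            continue
        if _translate(ca) == "*" or _translate(cb) == "*":
            if i == len(a) - 3:
                continue
            raise ValueError("premature stop")
        s_a += oracle_codon_sites(ca)
        s_b += oracle_codon_sites(cb)
        sd += oracle_codon_diffs(ca, cb)[0]
    s = (s_a + s_b) / 2
    ps = sd / s
    if ps >= 0.75:
        return math.nan
    return -0.75 * math.log(1 - (4 / 3) * ps)


# ---------------------------------------------------------------------------
# Nearest-neighbor melting temperature (unified parameter set, entered
# by hand from the published table; kcal/mol and cal/(mol K))

NN_PARAMS = {
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
# equivalent stacks read on the complementary strand
_EQUIV = {"TT": "AA", "TG": "CA", "AC": "GT", "AG": "CT", "TC": "GA", "CC": "GG"}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def oracle_tm_nn(seq: str, na_mM: float = 50.0, primer_nM: float = 250.0) -> float:
    dh = ds = 0.0
    for i in range(len(seq) - 1):
        stack = seq[i : i + 2]
        h, s = NN_PARAMS[_EQUIV.get(stack, stack)]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT[terminal]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    r = 1.987
    k = primer_nM * 1e-9
    return dh * 1000.0 / (ds + r * math.log(k)) - 273.15


# ---------------------------------------------------------------------------
# Dimer runs by direct all-offsets scan

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_dimer(s1: str, s2: str) -> tuple[int, int]:
    t = s2[::-1]
    max_run = three_prime = 0
    for d in range(-(len(t) - 1), len(s1)):
        idx = [i for i in range(max(0, d), min(len(s1), len(t) + d))]
        flags = [(i, _COMP.get(s1[i]) == t[i - d]) for i in idx]
        pos = 0
        for is_pair, grp in groupby(flags, key=lambda x: x[1]):
            grp = list(grp)
            if is_pair:
                length = len(grp)
                max_run = max(max_run, length)
                first_i, last_i = grp[0][0], grp[-1][0]
                if last_i == len(s1) - 1 or first_i - d == 0:
                    three_prime = max(three_prime, length)
            pos += len(grp)
    return max_run, three_prime


# ---------------------------------------------------------------------------
# Binding sites by naive scan


def oracle_binding_sites(primer: str, template: str, max_mm: int, exact3: int):
    """(start, strand, n_mismatch) triples by per-position comparison."""
    rc = "".join(_COMP[b] for b in reversed(primer))
    m = len(primer)
    out = []
    for start in range(len(template) - m + 1):
        window = template[start : start + m]
        mm = sum(1 for a, b in zip(primer, window) if a != b or b == "N")
        tail_mm = sum(
            1 for a, b in zip(primer[m - exact3 :], window[m - exact3 :]) if a != b or b == "N"
        )
        if mm <= max_mm and tail_mm == 0:
            out.append((start, "+", mm))
        mm = sum(1 for a, b in zip(rc, window) if a != b or b == "N")
        head_mm = sum(1 for a, b in zip(rc[:exact3], window[:exact3]) if a != b or b == "N")
        if mm <= max_mm and head_mm == 0:
            out.append((start, "-", mm))
    return sorted(out)
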