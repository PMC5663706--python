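"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths (and Biopython's
translation machinery): translation is a literal codon dictionary,
identity is a plain double loop, and the chimera oracle scores every
possible splice explicitly via prefix sums of per-position matches.
"""

from __future__ import annotations

import numpy as np

# Standard genetic code, written out literally.
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


def translate_oracle(nt: str) -> str:
    """Codon-by-codon lookup; keeps stops as '*', drops the trailing
    partial codon."""
    return "".join(
        CODON_TABLE[nt[i: i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


def pairwise_identity_oracle(seqs: list[str]) -> float:
    """Mean pairwise identity by explicit loops."""
    total, pairs = 0.0, 0
    for a in range(len(seqs)):
        for b in range(a + 1, len(seqs)):
            same = sum(1 for x, y in zip(seqs[a], seqs[b]) if x == y)
            total += same / len(seqs[a])
            pairs += 1
    return total / pairs


def sliding_identity_oracle(s1: str, s2: str, window: int) -> list[float]:
    """Windowed identity of two equal-length strings."""
    eq = [1 if a == b else 0 for a, b in zip(s1, s2)]
    return [
        sum(eq[k: k + window]) / window for k in range(len(eq) - window + 1)
    ]


def chimera_oracle(hybrid_aa: str, modules: dict[int, str]):
    """Score every single-crossover chimera assembly line against an
    observed hybrid and return the argmax set.

    For each non-sequential pair (i, j) the candidate line is modules
    1..i-1, the splice M_i[:b] + M_j[b:], then modules j+1..n; only
    candidates whose total length matches the hybrid are comparable.
    Returns (best_score, {(i, j): sorted list of argmax b}) over the
    candidates achieving the global maximum match count.
    """
    n = len(modules)
    L = len(modules[1])
    H = np.frombuffer(hybrid_aa.encode(), dtype=np.uint8)
    mod_arr = {k: np.frombuffer(v.encode(), dtype=np.uint8) for k, v in modules.items()}

    best_score = -1
    best: dict[tuple[int, int], list[int]] = {}
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if j in (i, i + 1):
                continue
            if (n + i - j) * L != H.size:
                continue
            # fixed flanks
            flank = 0
            for k in range(1, i):
                seg = H[(k - 1) * L: k * L]
                flank += int((seg == mod_arr[k]).sum())
            off = (i - 1) * L
            seg = H[off: off + L]
            for k, idx in enumerate(range(j + 1, n + 1)):
                s = off + L + k * L
                flank += int((H[s: s + L] == mod_arr[idx]).sum())
            mi = (seg == mod_arr[i]).astype(np.int64)
            mj = (seg == mod_arr[j]).astype(np.int64)
            pre = np.concatenate(([0], np.cumsum(mi)))
            suf = np.concatenate((np.cumsum(mj[::-1])[::-1], [0]))
            for b in range(1, L):
                score = flank + int(pre[b]) + int(suf[b])
                if score > best_score:
                    best_score = score
                    best = {(i, j): [b]}
                elif score == best_score:
                    best.setdefault((i, j), []).append(b)
    return best_score, best
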