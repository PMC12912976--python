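"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: chain packing by
exhaustive subset enumeration, connected components by union-find,
and NG86 by direct pathway enumeration written from the method
definition.
"""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------
# maximum chained-anchor count by exhaustive enumeration
# ---------------------------------------------------------------------

def _is_valid_chain(hits, gap_size):
    """hits: (q_chrom, t_chrom, q_rank, t_rank); one cell, strictly
    monotone both sides, rank gaps <= gap_size (skipped genes)."""
    if len({(h[0], h[1]) for h in hits}) != 1:
        return False
    hits = sorted(hits, key=lambda h: h[2])
    step = gap_size + 1
    qs = [h[2] for h in hits]
    ts = [h[3] for h in hits]
    if len(set(qs)) != len(qs) or len(set(ts)) != len(ts):
        return False
    for a, b in zip(qs, qs[1:]):
        if not (1 <= b - a <= step):
            return False
    inc = all(1 <= b - a <= step for a, b in zip(ts, ts[1:]))
    dec = all(1 <= a - b <= step for a, b in zip(ts, ts[1:]))
    return inc or dec


def max_chained_anchors(hits, block_size, gap_size):
    """Max total anchors over sets of anchor-disjoint valid chains,
    each with at least ``block_size`` anchors (exhaustive search)."""
    n = len(hits)
    chains = []
    for r in range(block_size, n + 1):
        for combo in itertools.combinations(range(n), r):
            if _is_valid_chain([hits[i] for i in combo], gap_size):
                chains.append(frozenset(combo))
    chains.sort(key=len, reverse=True)
    best = 0

    def dfs(idx, used, total):
        nonlocal best
        if total > best:
            best = total
        if idx == len(chains):
            return
        if total + (n - len(used)) <= best:
            return
        for i in range(idx, len(chains)):
            c = chains[i]
            if not (c & used):
                dfs(i + 1, used | c, total + len(c))
        # also the branch where no further chain is added is covered by
        # the running 'best' update above

    dfs(0, frozenset(), 0)
    return best


# ---------------------------------------------------------------------
# connected components by union-find
# ---------------------------------------------------------------------

def union_find_components(edges):
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in edges:
        union(a, b)
    comps = {}
    for node in parent:
        comps.setdefault(find(node), set()).add(node)
    return sorted(frozenset(c) for c in comps.values())


# ---------------------------------------------------------------------
# NG86 by direct pathway enumeration
# ---------------------------------------------------------------------

_ORACLE_CODE = {
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


def oracle_ng86(seq_a, seq_b):
    """(S, N, Sd, Nd, ks, ka); ks/ka are None when saturated."""
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    codons_a = [seq_a[i : i + 3] for i in range(0, len(seq_a), 3)]
    codons_b = [seq_b[i : i + 3] for i in range(0, len(seq_b), 3)]
    if codons_a and _ORACLE_CODE[codons_a[-1]] == "*" and _ORACLE_CODE[codons_b[-1]] == "*":
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]

    def sites(codon):
        syn = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if _ORACLE_CODE[alt] != "*" and _ORACLE_CODE[alt] == _ORACLE_CODE[codon]:
                    syn += 1 / 3
        return syn

    def diffs(c1, c2):
        pos = [i for i in range(3) if c1[i] != c2[i]]
        if not pos:
            return 0.0, 0.0
        results = []
        for order in itertools.permutations(pos):
            cur, syn, non, hit_stop = c1, 0, 0, False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if _ORACLE_CODE[nxt] == "*":
                    hit_stop = True
                if _ORACLE_CODE[nxt] == _ORACLE_CODE[cur]:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            results.append((hit_stop, syn, non))
        ok = [(s, n) for stop, s, n in results if not stop] or [
            (s, n) for _, s, n in results
        ]
        return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))

    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        sa, sb = sites(ca), sites(cb)
        S += (sa + sb) / 2
        N += (3 - sa + 3 - sb) / 2
        ds, dn = diffs(ca, cb)
        Sd += ds
        Nd += dn

    def jc(p):
        arg = 1 - 4 * p / 3
        return None if arg <= 0 else -0.75 * math.log(arg)

    return S, N, Sd, Nd, jc(Sd / S if S else 0.0), jc(Nd / N if N else 0.0)
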