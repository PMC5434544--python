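"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own algorithms: SD matches
are found by enumerating every window substring and testing
reverse-complement containment in the tail; folding optima by exhaustively
enumerating every nested structure.
"""

from __future__ import annotations

import textwrap

import pytest

ECOLI_TAIL = "GAUCACCUCCUUA"

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_sd_matches(window: str, tail: str = ECOLI_TAIL, min_len: int = 4):
    """Brute-force SD oracle: all maximal (p, L, a) triples.

    Enumerates every substring of length >= min_len, asks whether its
    reverse complement occurs in the tail, then discards matches that are
    sub-runs of a longer match on the same diagonal (same a - p).
    """
    win = window.upper().replace("T", "U")
    T = len(tail)
    cands = set()
    for p in range(1, len(win) + 1):
        for L in range(min_len, len(win) - p + 2):
            sub = win[p - 1 : p - 1 + L]
            try:
                rc = "".join(_RNA_COMP[b] for b in reversed(sub))
            except KeyError:
                continue  # ambiguity codes never pair
            start = 0
            while True:
                idx = tail.find(rc, start)
                if idx < 0:
                    break
                a = T - idx - L + 1
                cands.add((p, L, a))
                start = idx + 1
    maximal = set()
    for (p, L, a) in cands:
        contained = any(
            (p2, L2, a2) != (p, L, a)
            and a2 - p2 == a - p
            and p2 <= p
            and p2 + L2 >= p + L
            for (p2, L2, a2) in cands
        )
        if not contained:
            maximal.add((p, L, a))
    return maximal


_PAIR_W = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}


def enumerate_structures(n: int, min_loop: int = 3):
    """All nested pair sets on n positions with hairpin loops >= min_loop."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if j - i < min_loop + 1:
            return [frozenset()]
        out = list(rec(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            left = rec(i + 1, k - 1)
            right = rec(k + 1, j)
            for a in left:
                for b in right:
                    out.append(a | b | {(i, k)})
        return out

    return rec(0, n - 1)


def brute_fold_score(seq: str, min_loop: int = 3) -> float:
    """Exhaustive folding oracle: best score over every nested structure."""
    s = seq.upper().replace("T", "U")
    best = 0.0
    for struct in enumerate_structures(len(s), min_loop):
        score = 0.0
        ok = True
        for (i, k) in struct:
            w = _PAIR_W.get(frozenset({s[i], s[k]}))
            if w is None:
                ok = False
                break
            score += w
        if ok and score < best:
            best = score
    return best


@pytest.fixture(scope="session")
def sd_oracle():
    return brute_sd_matches


@pytest.fixture(scope="session")
def fold_oracle():
    return brute_fold_score


@pytest.fixture()
def toy_genbank(tmp_path):
    """Hand-written GenBank flat file: one plus-strand CDS and one
    minus-strand split CDS on a 600 bp linear replicon."""
    seq = ("ACGT" * 150)
    body = "\n".join(
        f"{i * 60 + 1:>9} " + " ".join(textwrap.wrap(seq[i * 60 : (i + 1) * 60], 10))
        for i in range(10)
    )
    text = f"""LOCUS       testrep1                 600 bp    DNA     linear   BCT 01-JAN-2000
DEFINITION  synthetic test replicon.
ACCESSION   testrep1
VERSION     testrep1.1
KEYWORDS    .
SOURCE      synthetic
  ORGANISM  synthetic
FEATURES             Location/Qualifiers
     source          1..600
     CDS             201..500
                     /locus_tag="g1"
                     /gene="abc"
                     /transl_table=11
     CDS             complement(join(10..21,30..41))
                     /locus_tag="g2"
ORIGIN
{body}
//
"""
    path = tmp_path / "toy.gb"
    path.write_text(text)
    return path, seq
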