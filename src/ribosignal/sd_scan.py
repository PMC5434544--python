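"""Shine–Dalgarno / anti-SD pairing detection and the D_toStart statistic.

The anti-SD (aSD) is the 3' tail of small-subunit rRNA; an SD is a stretch of
mRNA upstream of the start codon that base-pairs with it.  Because different
genes use different SDs at different spacings, the SD-to-start spacer is not
comparable across genes.  D_toStart is: project the rRNA 3'-terminal
nucleotide through the antiparallel SD/aSD duplex onto the mRNA and count
from that mRNA position to the first base of the start codon.  Genes with
different SDs but correctly positioned duplexes share the same D_toStart.

Tail site numbering counts from the 3' terminus: site 1 is the 3'-terminal
nucleotide, site T the 5'-most of the tail.  For the Escherichia coli 13-mer
tail 5'-GAUCACCUCCUUA-3' this puts the heavily used UCCUC run at sites 3-7.

Geometry of a match of length L: window positions p..p+L-1 (1-based, 5'->3')
pair with tail sites a..a+L-1 respectively, where a is the tail site paired
with the SD's 5'-most base.  The start codon sits at window positions
U+1..U+3, so

    spacer     = U - (p + L - 1)
    d_to_start = (U + 1) - p + (a - 1)  =  L + spacer + a - 1
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "ECOLI_TAIL",
    "AntiSDTail",
    "SdMatch",
    "SdProfile",
    "find_sd_matches",
    "d_to_start",
    "select_primary_sd",
    "profile_genome",
]

#: 13 nt at the 3' end of E. coli ssu (16S) rRNA, written 5'->3'.
ECOLI_TAIL = "GAUCACCUCCUUA"

_RNA = set("ACGU")
_IUPAC = set("ACGUNRYSWKMBDHV")
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class AntiSDTail:
    """The rRNA 3' tail, stored 5'->3' with 3'-end-first site numbering."""

    tail_seq: str = ECOLI_TAIL

    def __post_init__(self) -> None:
        seq = self.tail_seq.upper().replace("T", "U")
        if not seq or set(seq) - _RNA:
            raise ValueError(f"tail must be non-empty RNA over ACGU, got {self.tail_seq!r}")
        object.__setattr__(self, "tail_seq", seq)

    def __len__(self) -> int:
        return len(self.tail_seq)

    def site(self, i: int) -> str:
        """Nucleotide at tail site ``i`` (site 1 = 3'-terminal base)."""
        if not 1 <= i <= len(self.tail_seq):
            raise IndexError(f"tail site {i} outside 1..{len(self.tail_seq)}")
        return self.tail_seq[len(self.tail_seq) - i]


@dataclass(frozen=True)
class SdMatch:
    """One ungapped SD/aSD duplex.

    ``motif`` is the SD in mRNA sense (RNA alphabet, 5'->3'); ``p`` its
    5'-most position within the upstream window; ``a`` the tail site paired
    with that base.  ``flagged`` marks duplexes whose projected rRNA 3' end
    falls before the window start (conceptually negative mRNA coordinate).
    """

    motif: str
    p: int
    L: int
    a: int
    spacer: int
    d_to_start: int
    locus_tag: str = ""
    flagged: bool = False

    @property
    def tail_sites(self) -> range:
        """Tail sites covered by the duplex (3'-end numbering)."""
        return range(self.a, self.a + self.L)


def _pairs(mrna: str, tail: str, allow_gu: bool) -> bool:
    pair = (mrna, tail)
    return pair in _WC or (allow_gu and pair in _GU)


def find_sd_matches(
    window: str,
    tail: AntiSDTail | str = ECOLI_TAIL,
    min_len: int = 4,
    allow_gu: bool = False,
    locus_tag: str = "",
) -> list[SdMatch]:
    """All maximal ungapped SD/aSD duplexes of length >= ``min_len``.

    The window is the mRNA sense sequence immediately upstream of the start
    codon (T is read as U).  Pairing is antiparallel Watson-Crick, plus G:U
    when ``allow_gu``.  Maximality: no reported match is a sub-run of another
    at the same window/tail diagonal.  IUPAC ambiguity codes are legal input
    but never pair.
    """
    if isinstance(tail, str):
        tail = AntiSDTail(tail)
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    win = window.upper().replace("T", "U")
    bad = set(win) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in window: {sorted(bad)}")
    U = len(win)
    T = len(tail)
    matches: list[SdMatch] = []
    # diagonal k = a - p; window position p pairs tail site p + k
    for k in range(1 - U, T):
        p = max(1, 1 - k)
        p_hi = min(U, T - k)
        run_start = None
        while p <= p_hi + 1:
            paired = p <= p_hi and _pairs(win[p - 1], tail.site(p + k), allow_gu)
            if paired and run_start is None:
                run_start = p
            elif not paired and run_start is not None:
                L = p - run_start
                if L >= min_len:
                    matches.append(_make_match(win, U, run_start, L, run_start + k, locus_tag))
                run_start = None
            p += 1
    matches.sort(key=lambda m: (m.p, m.a))
    return matches


def _make_match(win: str, U: int, p: int, L: int, a: int, locus_tag: str) -> SdMatch:
    spacer = U - (p + L - 1)
    d = d_to_start(p, L, a, U)
    return SdMatch(
        motif=win[p - 1 : p - 1 + L],
        p=p,
        L=L,
        a=a,
        spacer=spacer,
        d_to_start=d,
        locus_tag=locus_tag,
        flagged=(p - (a - 1)) < 1,
    )


def d_to_start(p: int, L: int, a: int, U: int) -> int:
    """Distance from the projected rRNA 3' terminus to the start codon.

    The duplex is extended antiparallel by a-1 nt in the mRNA 5' direction to
    find the mRNA position opposite the rRNA 3'-terminal nucleotide; the
    return value is the offset from that position to window position U+1 (the
    first base of the start codon):  (U + 1) - p + (a - 1), algebraically
    L + spacer + a - 1.  May be computed even when the projected position
    falls before the window (callers see ``SdMatch.flagged``).
    """
    return (U + 1) - p + (a - 1)


def select_primary_sd(matches: Sequence[SdMatch]) -> Optional[SdMatch]:
    """Pick one SD per gene: longest duplex, then closest to the start codon
    (largest p), then smallest tail site a.  Deterministic; None if empty."""
    if not matches:
        return None
    return max(matches, key=lambda m: (m.L, m.p, -m.a))


@dataclass
class SdProfile:
    """Genome-wide SD/aSD summary over one selected SD per gene."""

    d_hist: Counter = field(default_factory=Counter)
    pos_hist: Counter = field(default_factory=Counter)
    site_involvement: Counter = field(default_factory=Counter)
    len_hist: Counter = field(default_factory=Counter)
    motif_counts: dict[str, int] = field(default_factory=dict)
    n_genes_scanned: int = 0
    n_genes_with_sd: int = 0
    per_gene: pd.DataFrame = field(default_factory=pd.DataFrame)


def profile_genome(
    records: Iterable,
    tail: AntiSDTail | str = ECOLI_TAIL,
    upstream: int = 20,
    min_len: int = 4,
    allow_gu: bool = False,
) -> SdProfile:
    """Scan every gene's upstream window and summarise the selected SDs.

    ``records`` are FlankedCds (anything with ``locus_tag`` and
    ``upstream_seq``).  The scan uses the last ``upstream`` nt of each
    upstream flank; genes whose window is shorter than ``min_len`` are
    counted as scanned but cannot match.  One SD per gene (see
    :func:`select_primary_sd`) feeds all summaries; all matches appear in the
    per-gene table.
    """
    if isinstance(tail, str):
        tail = AntiSDTail(tail)
    records = list(records)
    if not records:
        raise ValueError("no records to profile")
    prof = SdProfile()
    rows = []
    motif_order: dict[str, tuple[int, int]] = {}
    for rec in records:
        prof.n_genes_scanned += 1
        window = rec.upstream_seq[-upstream:] if upstream else rec.upstream_seq
        if len(window) < min_len:
            continue
        matches = find_sd_matches(
            window, tail, min_len=min_len, allow_gu=allow_gu, locus_tag=rec.locus_tag
        )
        for m in matches:
            rows.append(
                {
                    "locus_tag": rec.locus_tag,
                    "motif": m.motif,
                    "p": m.p,
                    "L": m.L,
                    "a": m.a,
                    "spacer": m.spacer,
                    "d_to_start": m.d_to_start,
                    "selected": False,
                }
            )
        best = select_primary_sd(matches)
        if best is None:
            continue
        prof.n_genes_with_sd += 1
        rows[-len(matches) + matches.index(best)]["selected"] = True
        prof.d_hist[best.d_to_start] += 1
        prof.pos_hist[best.p] += 1
        prof.len_hist[best.L] += 1
        for site in best.tail_sites:
            prof.site_involvement[site] += 1
        prof.motif_counts[best.motif] = prof.motif_counts.get(best.motif, 0) + 1
        motif_order[best.motif] = (best.a, best.L)
    # Table-1 convention: motifs ordered by pairing position along the tail,
    # then by length.
    prof.motif_counts = dict(
        sorted(prof.motif_counts.items(), key=lambda kv: motif_order[kv[0]])
    )
    prof.per_gene = pd.DataFrame(
        rows,
        columns=["locus_tag", "motif", "p", "L", "a", "spacer", "d_to_start", "selected"],
    )
    return prof
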