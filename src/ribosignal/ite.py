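"""Codon adaptation indices: I_TE and its CAI special case.

The index of translation elongation (I_TE) scores a gene by the geometric
mean of per-codon relative adaptedness weights, like CAI, but derives the
weights from highly-expressed-gene (HEG) codon usage *corrected for
background mutation bias*:

    r_i = (H_i + c) / (B_i + c)          within a synonymous family
    w_i = r_i / max_j r_j                (family maximum scaled to 1)

where H_i and B_i are HEG and background counts of codon i and c is a
pseudocount.  With a uniform background the ratio is proportional to
H_i + c, the weights collapse to the classic Sharp–Li CAI weights, and
I_TE equals CAI exactly.  The correction matters when mutation bias and
tRNA-mediated selection pull in opposite directions: in E. coli HEGs the
Ala codon GCG outnumbers GCA, yet GCA is *enriched* in HEGs relative to
background, so selection favours GCA — CAI gets the sign wrong, I_TE does
not.

Synonymous families can be treated four ways (``FamilyMode``); the default
splits six-fold families into their four-codon and two-codon boxes, which
are read by different tRNAs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

__all__ = [
    "ALL_CODONS",
    "CodonUsageTable",
    "FamilyMode",
    "FamilyPartition",
    "WTable",
    "GeneScore",
    "read_codon_usage_table",
    "codon_usage_from_cds",
    "partition_codon_families",
    "relative_adaptedness",
    "ite_score",
    "cai_score",
]

_BASES = "ACGT"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass
class CodonUsageTable:
    """Counts (or any non-negative weights) for the 64 codons."""

    counts: dict[str, float]
    genetic_code_id: int = 11
    label: str = ""

    def __post_init__(self) -> None:
        clean = {c: 0.0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            key = codon.upper().replace("U", "T")
            if key not in clean:
                raise ValueError(f"invalid codon {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon!r}")
            clean[key] = float(n)
        self.counts = clean

    def __getitem__(self, codon: str) -> float:
        return self.counts[codon.upper().replace("U", "T")]

    @classmethod
    def uniform(cls, genetic_code_id: int = 11) -> "CodonUsageTable":
        return cls({c: 1.0 for c in ALL_CODONS}, genetic_code_id, label="uniform")


def read_codon_usage_table(path: str | Path, genetic_code_id: int = 11) -> CodonUsageTable:
    """Read an EMBOSS ``.cut`` codon usage file.

    Data rows are ``CODON AA Fraction /1000 Count``; lines starting with
    ``#`` (and blank lines) are comments.  The codon and the trailing count
    column are used.  Duplicate codon rows are an error; codons absent from
    the file are zero-filled with a warning.
    """
    path = Path(path)
    counts: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("!"):
            continue
        fields = line.split()
        codon = fields[0].upper().replace("U", "T")
        if len(codon) != 3 or any(b not in _BASES for b in codon):
            raise ValueError(f"{path}:{lineno}: bad codon field {fields[0]!r}")
        if codon in counts:
            raise ValueError(f"{path}:{lineno}: duplicate codon {codon}")
        try:
            counts[codon] = float(fields[-1])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: bad count field") from exc
    missing = len(ALL_CODONS) - len(counts)
    if missing:
        warnings.warn(f"{path}: {missing} codons absent, counted as 0")
    return CodonUsageTable(counts, genetic_code_id, label=path.stem)


def codon_usage_from_cds(
    cds_seqs: Iterable[str], genetic_code_id: int = 11, label: str = ""
) -> CodonUsageTable:
    """Count all in-frame codons of a CDS collection (starts and stops
    included; consumers decide exclusions).  Sequences whose length is not a
    multiple of 3 are truncated with a warning."""
    counts = {c: 0.0 for c in ALL_CODONS}
    n_seqs = 0
    for seq in cds_seqs:
        n_seqs += 1
        s = seq.upper().replace("U", "T")
        if len(s) % 3:
            warnings.warn(f"CDS length {len(s)} not a multiple of 3; trailing bases dropped")
            s = s[: len(s) - len(s) % 3]
        for i in range(0, len(s), 3):
            codon = s[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    if n_seqs == 0:
        raise ValueError("empty CDS collection")
    return CodonUsageTable(counts, genetic_code_id, label=label)


class FamilyMode(str, Enum):
    """The four synonymous-family treatments."""

    RY_SPLIT = "ry"        # box families further split into R-/Y-ending halves
    BOX_SPLIT = "box"      # six-fold families split into 4+2 boxes (default)
    AA_LUMP = "lump"       # all synonyms of an amino acid in one family
    R_ONLY = "r-only"      # box families restricted to their A/G-ending codons


@dataclass
class FamilyPartition:
    """Disjoint synonymous-codon families; stop codons excluded.

    ``countable`` is the union of families with at least two codons: only
    those carry usage information, so single-codon families (ATG, TGG in the
    bacterial code) never enter a score.
    """

    mode: FamilyMode
    families: list[frozenset[str]]
    genetic_code_id: int = 11
    countable: frozenset[str] = field(init=False)
    family_of: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        self.family_of = {}
        for idx, fam in enumerate(self.families):
            if seen & fam:
                raise ValueError("families are not disjoint")
            seen |= fam
            for codon in fam:
                self.family_of[codon] = idx
        self.countable = frozenset(c for f in self.families if len(f) >= 2 for c in f)


def _is_r_ending(codon: str) -> bool:
    return codon[2] in "AG"


def partition_codon_families(
    genetic_code_id: int = 11, mode: FamilyMode | str = FamilyMode.BOX_SPLIT
) -> FamilyPartition:
    """Build the synonymous-family partition for a genetic code.

    BOX_SPLIT groups synonyms that share the first two codon bases, which
    splits six-fold families (Leu, Ser, Arg in the bacterial code) into one
    four-codon and one two-codon family and leaves smaller families intact;
    compound eight-fold families in other codes split into two four-fold
    boxes by the same rule.  RY_SPLIT further divides each box family into
    its purine-ending (R = A/G) and pyrimidine-ending (Y = C/T) halves.
    AA_LUMP keeps one family per amino acid.  R_ONLY restricts each box
    family to its R-ending codons, leaving Y-ending codons uncounted — in
    E. coli codon bias is strong among R-ending, weak among Y-ending codons.
    """
    mode = FamilyMode(mode)
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        if len(codon) != 3 or any(b not in _BASES for b in codon):
            continue
        by_aa.setdefault(aa, []).append(codon)

    families: list[frozenset[str]] = []
    if mode is FamilyMode.AA_LUMP:
        families = [frozenset(cods) for cods in by_aa.values()]
    else:
        boxes: list[frozenset[str]] = []
        for cods in by_aa.values():
            by_box: dict[str, list[str]] = {}
            for c in cods:
                by_box.setdefault(c[:2], []).append(c)
            boxes.extend(frozenset(v) for v in by_box.values())
        if mode is FamilyMode.BOX_SPLIT:
            families = boxes
        elif mode is FamilyMode.RY_SPLIT:
            for box in boxes:
                r = frozenset(c for c in box if _is_r_ending(c))
                y = box - r
                families.extend(f for f in (r, y) if f)
        else:  # R_ONLY
            families = [f for f in (frozenset(c for c in box if _is_r_ending(c)) for box in boxes) if f]
    families.sort(key=lambda f: min(f))
    return FamilyPartition(mode=mode, families=families, genetic_code_id=genetic_code_id)


@dataclass
class WTable:
    """Per-codon relative adaptedness; family maxima are exactly 1."""

    w: dict[str, float]
    partition: FamilyPartition
    pseudocount: float
    heg_label: str = ""
    background_label: str = ""


def relative_adaptedness(
    heg: CodonUsageTable,
    background: Optional[CodonUsageTable] = None,
    partition: Optional[FamilyPartition] = None,
    pseudocount: float = 0.5,
) -> WTable:
    """Relative adaptedness w from HEG usage, corrected for background.

    Within each countable family, r_i = (H_i + c)/(B_i + c) and
    w_i = r_i / max r.  ``background=None`` means uniform background (the CAI
    special case), in which case w_i = (H_i + c)/max_j (H_j + c).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if partition is None:
        partition = partition_codon_families(heg.genetic_code_id)
    c = pseudocount
    w: dict[str, float] = {}
    for fam in partition.families:
        if len(fam) < 2:
            continue
        r = {}
        for codon in fam:
            h = heg[codon] + c
            b = (background[codon] + c) if background is not None else 1.0
            if h == 0 or b == 0:
                raise ValueError(
                    f"zero count for {codon} with pseudocount 0; "
                    "use a positive pseudocount"
                )
            r[codon] = h / b
        rmax = max(r.values())
        for codon in fam:
            w[codon] = r[codon] / rmax
    return WTable(
        w=w,
        partition=partition,
        pseudocount=c,
        heg_label=heg.label,
        background_label=background.label if background is not None else "uniform",
    )


class GeneScore(NamedTuple):
    score: float
    n_codons: int


def _countable_codons(cds: str, wtable: WTable) -> list[str]:
    s = cds.upper().replace("U", "T")
    s = s[: len(s) - len(s) % 3]
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    # first codon is initiation, not elongation; stops and codons outside
    # countable families carry no elongation information
    return [c for c in codons[1:] if c in wtable.w and c in wtable.partition.countable]


def ite_score(cds: str, wtable: WTable) -> GeneScore:
    """Gene-level I_TE: geometric mean of w over the gene's countable codons.

    The first codon, stop codons, codons in single-codon families, and
    codons containing ambiguity characters are skipped.  Raises if no
    countable codon remains.
    """
    used = _countable_codons(cds, wtable)
    if not used:
        raise ValueError("no countable codons in CDS")
    log_sum = sum(math.log(wtable.w[c]) for c in used)
    return GeneScore(math.exp(log_sum / len(used)), len(used))


def cai_score(
    cds: str,
    heg: CodonUsageTable,
    partition: Optional[FamilyPartition] = None,
    pseudocount: float = 0.5,
) -> GeneScore:
    """Classic CAI: identical to :func:`ite_score` with uniform background."""
    wt = relative_adaptedness(heg, background=None, partition=partition, pseudocount=pseudocount)
    return ite_score(cds, wt)
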