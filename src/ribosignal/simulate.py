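"""Synthetic annotated genomes and CDS sets with planted ground truth.

Every downstream stage is tested against data whose answer is known by
construction: upstream windows carry exactly one planted SD motif at a
planted spacer (rejection sampling removes accidental complementary runs),
CDS codons are drawn with a planted bias ``b`` toward the family-maximal
codon, and hairpins of known stem/loop geometry are planted at known
offsets.  A single seeded generator drives everything, so regeneration with
the same seed reproduces files byte-identically.

The generator emulates the *signals* the profiling stages look for, not
genome evolution: intergenic composition is i.i.d., there is no operon
structure, and codon bias is independent across positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    CdsFeature,
    FlankedCds,
    GenomeRecord,
    revcomp,
    write_fasta_gff,
    write_genbank,
)
from .ite import CodonUsageTable, FamilyPartition, partition_codon_families
from .sd_scan import ECOLI_TAIL, AntiSDTail, find_sd_matches

logger = logging.getLogger(__name__)

__all__ = [
    "HairpinSpec",
    "motif_tail_site",
    "optimal_codons",
    "random_biased_cds",
    "generate_biased_cds_set",
    "simulate_genome",
    "generate_synthetic_genome",
    "simulate_mfe_records",
]

_B = np.array(list("ACGT"))


@dataclass(frozen=True)
class HairpinSpec:
    """A planted stem-loop: GC stem (unambiguously pairable against an A/C
    background) with an A-only loop, at ``offset`` nt past the stop codon."""

    stem: int = 10
    loop: int = 4
    offset: int = 30

    @property
    def length(self) -> int:
        return 2 * self.stem + self.loop


def motif_tail_site(motif: str, tail: AntiSDTail | str = ECOLI_TAIL) -> int:
    """Tail site ``a`` paired with the motif's 5'-most base.

    Raises if the motif is not the reverse complement of any tail substring
    (i.e. the SD spec is unsatisfiable for this tail).  If the motif pairs at
    several tail positions, the 3'-most placement (smallest a) is returned,
    matching the scanner's tie-break.
    """
    if isinstance(tail, str):
        tail = AntiSDTail(tail)
    rc = revcomp(motif.upper().replace("T", "U")).replace("T", "U")
    pos0 = tail.tail_seq.rfind(rc)
    if pos0 < 0:
        raise ValueError(
            f"motif {motif!r} is not the reverse complement of a substring "
            f"of tail {tail.tail_seq}"
        )
    return len(tail) - pos0 - len(rc) + 1


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    if n <= 0:
        return ""
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), n)])


# ---------------------------------------------------------------------------
# codon bias
# ---------------------------------------------------------------------------

def optimal_codons(
    partition: FamilyPartition, usage_target: Optional[CodonUsageTable] = None
) -> dict[int, str]:
    """One 'optimal' codon per countable family: the most-used codon of
    ``usage_target`` if given, otherwise the alphabetically first codon
    (a fixed, arbitrary convention for planted truth)."""
    out = {}
    for idx, fam in enumerate(partition.families):
        if len(fam) < 2:
            continue
        if usage_target is not None:
            out[idx] = max(sorted(fam), key=lambda c: usage_target[c])
        else:
            out[idx] = min(fam)
    return out


def random_biased_cds(
    rng: np.random.Generator,
    n_codons: int,
    b: float,
    partition: FamilyPartition,
    opt: dict[int, str],
) -> str:
    """ATG + ``n_codons`` biased sense codons + TAA.

    Each codon position draws a countable family uniformly, then the
    family-maximal codon with probability ``b`` and a uniform family member
    otherwise; b=1 gives an all-optimal gene, b=0 an unbiased one.
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError("bias b must be in [0, 1]")
    fam_ids = sorted(opt)
    members = {i: sorted(partition.families[i]) for i in fam_ids}
    picks = rng.integers(0, len(fam_ids), n_codons)
    coin = rng.random(n_codons)
    codons = []
    for fi, c in zip(picks, coin):
        idx = fam_ids[fi]
        if c < b:
            codons.append(opt[idx])
        else:
            fam = members[idx]
            codons.append(fam[rng.integers(0, len(fam))])
    return "ATG" + "".join(codons) + "TAA"


def generate_biased_cds_set(
    n_genes: int,
    b_values: Sequence[float] | float,
    seed: int,
    n_codons: int = 300,
    genetic_code_id: int = 11,
    usage_target: Optional[CodonUsageTable] = None,
    out_fasta: Optional[str | Path] = None,
) -> tuple[list[str], pd.DataFrame, CodonUsageTable]:
    """CDS set with per-gene planted bias; returns (sequences, truth,
    realized whole-set codon usage).  The realized usage is the natural
    background table for I_TE on this set."""
    from .ite import codon_usage_from_cds

    if n_genes == 0:
        logger.warning("generate_biased_cds_set: n_genes=0, empty output")
        empty = pd.DataFrame(columns=["locus_tag", "b", "n_codons"])
        return [], empty, CodonUsageTable.uniform(genetic_code_id)
    rng = np.random.default_rng(seed)
    b_arr = np.broadcast_to(np.asarray(b_values, dtype=float), (n_genes,))
    partition = partition_codon_families(genetic_code_id)
    opt = optimal_codons(partition, usage_target)
    seqs, rows = [], []
    for i, b in enumerate(b_arr):
        seq = random_biased_cds(rng, n_codons, float(b), partition, opt)
        locus = f"bias_{i+1:04d}"
        seqs.append(seq)
        rows.append({"locus_tag": locus, "b": float(b), "n_codons": n_codons})
    truth = pd.DataFrame(rows)
    usage = codon_usage_from_cds(seqs, genetic_code_id, label="realized")
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for row, seq in zip(rows, seqs):
                fh.write(f">{row['locus_tag']} b={row['b']:.4f}\n{seq}\n")
    return seqs, truth, usage


# ---------------------------------------------------------------------------
# planted-SD genomes
# ---------------------------------------------------------------------------

def _plant_sd_window(
    rng: np.random.Generator,
    upstream: int,
    motif: str,
    spacer: int,
    tail: AntiSDTail,
    min_len: int,
    max_attempts: int = 1000,
) -> str:
    """Upstream window containing the planted SD and no other match.

    Rejection sampling: redraw the random filler until the scanner reports
    exactly the planted duplex (so the planted match is neither extended nor
    accompanied by accidental complementary runs >= min_len).
    """
    L = len(motif)
    if spacer < 0 or L + spacer > upstream:
        raise ValueError(f"motif length {L} + spacer {spacer} exceeds window {upstream}")
    p_expected = upstream - spacer - L + 1
    attempts = 0
    while True:
        attempts += 1
        window = _rand_seq(rng, p_expected - 1) + motif + _rand_seq(rng, spacer)
        matches = find_sd_matches(window, tail, min_len=min_len)
        # a motif can legitimately pair at more than one tail position, so
        # accept any match set that is exactly the planted duplex (same p and
        # L, any tail site a)
        if matches and all(m.p == p_expected and m.L == L for m in matches):
            return window
        if attempts == max_attempts:
            logger.warning(
                "planted-SD rejection sampling slow (%d attempts); re-seeding draws",
                attempts,
            )
        if attempts >= 10 * max_attempts:
            raise RuntimeError("could not plant SD window without accidental matches")


def simulate_genome(
    n_genes: int,
    motif: str = "AGGA",
    spacer: int = 7,
    bias: Sequence[float] | float = 0.8,
    hairpin: Optional[HairpinSpec] = None,
    seed: int = 0,
    n_codons: int = 100,
    upstream: int = 20,
    min_gap: int = 150,
    tail: AntiSDTail | str = ECOLI_TAIL,
    min_len: int = 4,
    genetic_code_id: int = 11,
    replicon_id: str = "synth_1",
) -> tuple[GenomeRecord, pd.DataFrame]:
    """Build one synthetic replicon with planted signals; returns
    (GenomeRecord, truth table).

    Genes alternate over both strands with intergenic gaps >= ``min_gap``.
    Each gene's sense-strand layout is  [SD window(U)] [ATG body TAA]
    [optional stem-loop ``hairpin.offset`` nt past the stop].  The truth
    table records the planted motif, spacer, tail site a, expected
    D_toStart (= L + spacer + a - 1), bias b and hairpin placement.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if isinstance(tail, str):
        tail = AntiSDTail(tail)
    a_site = motif_tail_site(motif, tail)  # validates the motif up front
    rng = np.random.default_rng(seed)
    b_arr = np.broadcast_to(np.asarray(bias, dtype=float), (n_genes,))
    partition = partition_codon_families(genetic_code_id)
    opt = optimal_codons(partition)
    L = len(motif)
    motif_dna = motif.upper().replace("U", "T")

    parts: list[str] = [_rand_seq(rng, min_gap + int(rng.integers(0, 50)))]
    pos = len(parts[0])
    features: list[CdsFeature] = []
    rows = []
    for i in range(n_genes):
        locus = f"synth_{i+1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        window = _plant_sd_window(rng, upstream, motif_dna, spacer, tail, min_len)
        cds = random_biased_cds(rng, n_codons, float(b_arr[i]), partition, opt)
        cassette = window + cds
        hp_offset = None
        if hairpin is not None:
            stem = _rand_seq(rng, hairpin.stem, "GC")
            cassette += (
                _rand_seq(rng, hairpin.offset)
                + stem
                + "A" * hairpin.loop
                + revcomp(stem)
            )
            hp_offset = hairpin.offset
        m = len(cassette)
        c_lo, c_hi = upstream + 1, upstream + len(cds)  # cds within cassette
        if strand == "+":
            interval = (pos + c_lo, pos + c_hi)
            parts.append(cassette)
        else:
            interval = (pos + m - c_hi + 1, pos + m - c_lo + 1)
            parts.append(revcomp(cassette))
        features.append(
            CdsFeature(locus_tag=locus, strand=strand, intervals=[interval])
        )
        gap = _rand_seq(rng, min_gap + int(rng.integers(0, 50)))
        parts.append(gap)
        pos += m + len(gap)
        rows.append(
            {
                "locus_tag": locus,
                "strand": strand,
                "motif": motif.upper().replace("T", "U"),
                "spacer": spacer,
                "a": a_site,
                "L": L,
                "d_to_start": L + spacer + a_site - 1,
                "b": float(b_arr[i]),
                "hairpin_offset": hp_offset,
                "seed": seed,
            }
        )
    genome = GenomeRecord(
        replicon_id=replicon_id,
        sequence="".join(parts),
        features=features,
        topology="linear",
        genetic_code_id=genetic_code_id,
    )
    return genome, pd.DataFrame(rows)


def generate_synthetic_genome(
    n_genes: int,
    out_prefix: str | Path,
    motif: str = "AGGA",
    spacer: int = 7,
    bias: Sequence[float] | float = 0.8,
    hairpin: Optional[HairpinSpec] = None,
    seed: int = 0,
    **kwargs,
) -> tuple[GenomeRecord, pd.DataFrame, dict[str, Path]]:
    """Simulate a genome and write it as GenBank, FASTA+GFF3 and a truth TSV.

    Same seed -> byte-identical files.  Returns the in-memory genome, the
    truth table, and the paths written.
    """
    genome, truth = simulate_genome(
        n_genes, motif=motif, spacer=spacer, bias=bias, hairpin=hairpin, seed=seed, **kwargs
    )
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "genbank": prefix.with_suffix(".gb"),
        "fasta": prefix.with_suffix(".fna"),
        "gff": prefix.with_suffix(".gff3"),
        "truth": prefix.with_suffix(".truth.tsv"),
    }
    write_genbank(genome, paths["genbank"])
    write_fasta_gff(genome, paths["fasta"], paths["gff"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return genome, truth, paths


# ---------------------------------------------------------------------------
# folding-profile fixtures
# ---------------------------------------------------------------------------

def simulate_mfe_records(
    n_genes: int,
    seed: int = 0,
    down_hairpin: HairpinSpec = HairpinSpec(stem=12, loop=4, offset=30),
    flank_stem: int = 12,
    label: str = "all",
) -> tuple[list[FlankedCds], pd.DataFrame]:
    """Genes with structured flanks and an unstructured start neighbourhood.

    Layout (start-anchor region sites 1..200, start codon at 101-103):
    the upstream flank carries a strong stem-loop around sites 25-60 and a
    G tract at 76-90 (pairable against the A/C zone), while sites 91-139
    are drawn from {A,C} only and therefore cannot base-pair among
    themselves — the least-stable point of the mean profile lands where
    windows fit inside this zone.  A second stem-loop sits in the CDS
    interior, and ``down_hairpin`` is planted past the stop codon so the
    stop-anchor profile develops its minimum ~30 nt downstream of the stop.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    rows = []
    for i in range(n_genes):
        locus = f"mfe_{i+1:04d}"
        # upstream flank, 100 nt
        stem_u = _rand_seq(rng, flank_stem, "GC")
        hp_u = stem_u + "A" * 4 + revcomp(stem_u)  # 2*stem+4 nt
        pad = 100 - 15 - len(hp_u) - 10 - 10
        up = (
            _rand_seq(rng, 10)
            + hp_u
            + _rand_seq(rng, pad)
            + "G" * 15
            + _rand_seq(rng, 10, "AC")
        )
        assert len(up) == 100
        # CDS, 201 nt: ATG, A/C zone, internal GC hairpin, A/C tail, TAA
        stem_c = _rand_seq(rng, flank_stem, "GC")
        hp_c = stem_c + "A" * 4 + revcomp(stem_c)
        cds = (
            "ATG"
            + _rand_seq(rng, 36, "AC")          # sites 104-139 unstructured
            + hp_c                               # internal structure
            + _rand_seq(rng, 201 - 3 - 36 - len(hp_c) - 3, "AC")
            + "TAA"
        )
        assert len(cds) == 201
        # downstream flank, 100 nt, hairpin at the planted offset
        stem_d = _rand_seq(rng, down_hairpin.stem, "GC")
        hp_d = stem_d + "A" * down_hairpin.loop + revcomp(stem_d)
        tail_pad = 100 - down_hairpin.offset - len(hp_d)
        if tail_pad < 0:
            raise ValueError("hairpin does not fit in a 100 nt downstream flank")
        down = _rand_seq(rng, down_hairpin.offset, "AC") + hp_d + _rand_seq(rng, tail_pad, "AC")
        records.append(
            FlankedCds(
                locus_tag=locus,
                upstream_seq=up,
                cds_seq=cds,
                downstream_seq=down,
                intergenic_5p=1000,
                intergenic_3p=1000,
                location_label="synthetic",
            )
        )
        rows.append(
            {
                "locus_tag": locus,
                "label": label,
                "down_hairpin_start": down_hairpin.offset + 1,  # within downstream
                "down_hairpin_len": len(hp_d),
                "seed": seed,
            }
        )
    return records, pd.DataFrame(rows)
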