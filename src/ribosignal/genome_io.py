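"""Annotated-genome input/output and CDS flank extraction.

Coordinate convention throughout: 1-based, closed intervals on the forward
(plus) strand of the replicon, as in GenBank feature locations.  Flanking
sequences are always reported on the *sense* strand of the gene, so the
upstream flank of a minus-strand CDS is the reverse complement of the genomic
slice immediately to its right.

Circular replicons wrap: a flank that runs off one end of the sequence
continues from the other.  On linear replicons flanks are truncated at the
contig end and the record is flagged, not dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CdsFeature",
    "GenomeRecord",
    "FlankedCds",
    "read_genbank",
    "read_fasta_gff",
    "extract_cds_with_flanks",
    "filter_by_intergenic_distance",
    "write_flanked_fasta",
    "revcomp",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string, IUPAC codes preserved."""
    return str(Seq(seq).reverse_complement())


@dataclass
class CdsFeature:
    """One protein-coding feature on a replicon.

    ``intervals`` are 1-based closed [start, end] pairs in genome coordinates,
    ordered 5'->3' along the genome (i.e. ascending; a minus-strand feature's
    biological 5' end is the last interval's right edge).
    """

    locus_tag: str
    strand: str  # "+" or "-"
    intervals: list[tuple[int, int]]
    gene_name: str = ""
    is_pseudo: bool = False
    is_partial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"{self.locus_tag}: feature has no intervals")
        ivs = sorted((int(s), int(e)) for s, e in self.intervals)
        for (s, e) in ivs:
            if s > e:
                raise ValueError(f"{self.locus_tag}: bad interval [{s},{e}]")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.locus_tag}: overlapping intervals")
        self.intervals = ivs

    @property
    def start(self) -> int:
        """Leftmost genome coordinate."""
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        """Rightmost genome coordinate."""
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass
class GenomeRecord:
    """One replicon with its CDS annotation."""

    replicon_id: str
    sequence: str
    features: list[CdsFeature] = field(default_factory=list)
    topology: str = "linear"
    genetic_code_id: int = 11

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.replicon_id}: empty sequence")
        if self.topology not in {"linear", "circular"}:
            raise ValueError(f"unknown topology {self.topology!r}")
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        n = len(self.sequence)
        if self.topology == "linear":
            for f in self.features:
                if f.start < 1 or f.end > n:
                    raise ValueError(
                        f"{f.locus_tag}: interval outside [1,{n}] on linear replicon"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Forward-strand slice [start, end], 1-based closed.

        Coordinates outside [1, len] wrap on circular replicons and raise on
        linear ones.
        """
        n = len(self.sequence)
        if start > end:
            raise ValueError(f"slice start {start} > end {end}")
        if 1 <= start and end <= n:
            return self.sequence[start - 1 : end]
        if self.topology != "circular":
            raise ValueError(f"slice [{start},{end}] outside linear replicon")
        return "".join(self.sequence[(i - 1) % n] for i in range(start, end + 1))


@dataclass
class FlankedCds:
    """A CDS with sense-strand flanks: the unit consumed by all profiling stages.

    ``intergenic_5p`` / ``intergenic_3p`` are nucleotide distances from the
    gene's 5'/3' boundary to the nearest boundary of any other annotated
    feature on either strand; 0 for overlapping or abutting genes.
    """

    locus_tag: str
    upstream_seq: str
    cds_seq: str
    downstream_seq: str
    intergenic_5p: int
    intergenic_3p: int
    gene_name: str = ""
    location_label: str = ""
    truncated_5p: bool = False
    truncated_3p: bool = False


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _features_from_seqrecord(rec: SeqRecord) -> list[CdsFeature]:
    feats: list[CdsFeature] = []
    ordinal = 0
    for f in rec.features:
        if f.type != "CDS":
            continue
        ordinal += 1
        quals = f.qualifiers
        locus = (quals.get("locus_tag") or [""])[0]
        if not locus:
            locus = f"cds_{ordinal}"
            logger.warning("%s: CDS without locus_tag, synthesized %r", rec.id, locus)
        gene = (quals.get("gene") or [""])[0]
        strand = "-" if f.location.strand == -1 else "+"
        intervals = [(int(p.start) + 1, int(p.end)) for p in f.location.parts]
        feats.append(
            CdsFeature(
                locus_tag=locus,
                gene_name=gene,
                strand=strand,
                intervals=intervals,
                is_pseudo="pseudo" in quals or "pseudogene" in quals,
            )
        )
    return feats


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read a GenBank flat file into one GenomeRecord per LOCUS."""
    path = Path(path)
    try:
        seqrecords = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # biopython raises assorted types on bad input
        raise ValueError(f"{path}: cannot parse as GenBank: {exc}") from exc
    if not seqrecords:
        raise ValueError(f"{path}: no GenBank records found")
    genomes = []
    for rec in seqrecords:
        topology = rec.annotations.get("topology", "linear")
        code = 11
        for f in rec.features:
            tables = f.qualifiers.get("transl_table") if f.type == "CDS" else None
            if tables:
                code = int(tables[0])
                break
        genomes.append(
            GenomeRecord(
                replicon_id=rec.id,
                sequence=str(rec.seq),
                features=_features_from_seqrecord(rec),
                topology=topology if topology in {"linear", "circular"} else "linear",
                genetic_code_id=code,
            )
        )
    return genomes


def read_fasta_gff(fasta_path: str | Path, gff_path: str | Path) -> list[GenomeRecord]:
    """Read genome FASTA plus GFF3 annotation into GenomeRecords.

    CDS rows are grouped into multi-interval features by their ``ID`` (or
    ``Parent``) attribute, so a split CDS becomes one feature with several
    intervals, mirroring a GenBank ``join(...)`` location.
    """
    import gffutils

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"{fasta_path}: no FASTA records")
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    grouped: dict[tuple[str, str], dict] = {}
    ordinal = 0
    for row in db.features_of_type("CDS", order_by="start"):
        if row.seqid not in seqs:
            raise ValueError(
                f"{gff_path}: seqid {row.seqid!r} absent from {fasta_path}"
            )
        ordinal += 1
        # rows of one discontinuous CDS share an ID (or a Parent); gffutils
        # uniquifies only its db key, the ID attribute stays original
        raw_id = row.attributes.get("ID", [None])[0]
        key_id = row.attributes.get("Parent", [raw_id])[0] or raw_id
        if key_id is None:
            key_id = f"cds_{ordinal}"
            logger.warning("%s: CDS row without ID/Parent, synthesized %r", gff_path, key_id)
        key = (row.seqid, key_id)
        entry = grouped.setdefault(
            key,
            {
                "strand": row.strand,
                "intervals": [],
                "locus_tag": row.attributes.get("locus_tag", [key[1]])[0],
                "gene": row.attributes.get("gene", [""])[0],
                "pseudo": row.attributes.get("pseudo", ["false"])[0].lower() == "true",
            },
        )
        entry["intervals"].append((row.start, row.end))
    genomes = []
    for seqid, sequence in seqs.items():
        feats = [
            CdsFeature(
                locus_tag=e["locus_tag"],
                gene_name=e["gene"],
                strand="-" if e["strand"] == "-" else "+",
                intervals=e["intervals"],
                is_pseudo=e["pseudo"],
            )
            for (sid, _), e in grouped.items()
            if sid == seqid
        ]
        genomes.append(GenomeRecord(replicon_id=seqid, sequence=sequence, features=feats))
    return genomes


# ---------------------------------------------------------------------------
# flank extraction
# ---------------------------------------------------------------------------

def _intergenic_distances(genome: GenomeRecord) -> list[tuple[int, int]]:
    """(left_gap, right_gap) per feature, in genome orientation.

    The gap is measured to the nearest boundary of any *other* feature on
    either strand; overlapping or abutting features give 0.  With no neighbor
    on a side: linear replicons measure to the contig end, circular ones wrap
    around the origin.
    """
    feats = genome.features
    n = len(genome.sequence)
    spans = [(f.start, f.end) for f in feats]
    out = []
    for i, (s, e) in enumerate(spans):
        left = None
        right = None
        for j, (s2, e2) in enumerate(spans):
            if j == i:
                continue
            if e2 < s:
                gap = s - e2 - 1
                left = gap if left is None else min(left, gap)
            elif s2 > e:
                gap = s2 - e - 1
                right = gap if right is None else min(right, gap)
            else:  # overlapping or abutting features: zero distance
                left, right = 0, 0
        if genome.topology == "circular" and len(spans) > 1:
            # wrap-around gaps to the far side of the replicon
            for j, (s2, e2) in enumerate(spans):
                if j == i:
                    continue
                wrap_left = (s - 1) + (n - e2)
                wrap_right = (n - e) + (s2 - 1)
                left = wrap_left if left is None else min(left, wrap_left)
                right = wrap_right if right is None else min(right, wrap_right)
        if left is None:
            left = s - 1 if genome.topology == "linear" else (s - 1) + (n - e)
        if right is None:
            right = n - e if genome.topology == "linear" else (n - e) + (s - 1)
        out.append((max(0, left), max(0, right)))
    return out


def extract_cds_with_flanks(
    genome: GenomeRecord,
    upstream: int = 20,
    downstream: int = 0,
    include_location: bool = True,
    include_pseudo: bool = False,
) -> list[FlankedCds]:
    """Extract every CDS with sense-strand upstream/downstream flanks.

    Parameters
    ----------
    upstream, downstream
        Flank lengths in nt (U and Dn).  Flanks wrap on circular replicons;
        on linear ones they are truncated at contig ends and flagged.
    include_pseudo
        Pseudogenes are skipped by default.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("flank lengths must be non-negative")
    n = len(genome.sequence)
    gaps = _intergenic_distances(genome)
    out: list[FlankedCds] = []
    for feat, (left_gap, right_gap) in zip(genome.features, gaps):
        if feat.is_pseudo and not include_pseudo:
            continue
        cds = "".join(genome.slice(s, e) for s, e in feat.intervals)
        if feat.strand == "-":
            cds = revcomp(cds)

        def fwd_flank(lo: int, hi: int) -> tuple[str, bool]:
            """Forward-strand slice, truncated at linear contig ends."""
            if lo > hi:
                return "", False
            if genome.topology == "circular":
                return genome.slice(lo, hi), False
            lo_c, hi_c = max(1, lo), min(n, hi)
            if lo_c > hi_c:
                return "", True
            return genome.slice(lo_c, hi_c), (lo_c != lo or hi_c != hi)

        if feat.strand == "+":
            up, trunc5 = fwd_flank(feat.start - upstream, feat.start - 1)
            dn, trunc3 = fwd_flank(feat.end + 1, feat.end + downstream)
            ig5, ig3 = left_gap, right_gap
        else:
            up, trunc5 = fwd_flank(feat.end + 1, feat.end + upstream)
            dn, trunc3 = fwd_flank(feat.start - downstream, feat.start - 1)
            up, dn = revcomp(up), revcomp(dn)
            ig5, ig3 = right_gap, left_gap

        label = ""
        if include_location:
            label = f"{genome.replicon_id}:{feat.strand}:{feat.start}..{feat.end}"
        out.append(
            FlankedCds(
                locus_tag=feat.locus_tag,
                gene_name=feat.gene_name,
                upstream_seq=up,
                cds_seq=cds,
                downstream_seq=dn,
                intergenic_5p=ig5,
                intergenic_3p=ig3,
                location_label=label,
                truncated_5p=trunc5,
                truncated_3p=trunc3,
            )
        )
    return out


def filter_by_intergenic_distance(
    records: Iterable[FlankedCds], min_5p: int = 100, min_3p: int = 100
) -> list[FlankedCds]:
    """Keep records whose intergenic distances meet both minima.

    Used to avoid confounding the folding profile near a start codon with the
    profile at the upstream gene's stop codon when genes are closely spaced.
    """
    if min_5p < 0 or min_3p < 0:
        raise ValueError("minimum distances must be non-negative")
    return [
        r for r in records if r.intergenic_5p >= min_5p and r.intergenic_3p >= min_3p
    ]


def write_flanked_fasta(
    records: Sequence[FlankedCds], which: str, path: str | Path
) -> int:
    """Write one region per record to FASTA; returns the record count.

    ``which`` selects upstream, cds, downstream, or their concatenation.
    Header: ``locus_tag gene_name location_label`` (empty fields dropped).
    """
    choices = {"upstream", "cds", "downstream", "concatenated"}
    if which not in choices:
        raise ValueError(f"which must be one of {sorted(choices)}")
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    seqrecs = []
    for r in records:
        if which == "upstream":
            seq = r.upstream_seq
        elif which == "cds":
            seq = r.cds_seq
        elif which == "downstream":
            seq = r.downstream_seq
        else:
            seq = r.upstream_seq + r.cds_seq + r.downstream_seq
        desc = " ".join(x for x in (r.gene_name, r.location_label) if x)
        seqrecs.append(SeqRecord(Seq(seq.upper()), id=r.locus_tag, description=desc))
    count = SeqIO.write(seqrecs, str(path), "fasta")
    return count


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord back to a GenBank flat file."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.replicon_id,
        name=genome.replicon_id[:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.topology,
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        parts = [SimpleLocation(s - 1, e, strand=strand) for s, e in f.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        quals = {
            "locus_tag": [f.locus_tag],
            "transl_table": [str(genome.genetic_code_id)],
        }
        if f.gene_name:
            quals["gene"] = [f.gene_name]
        if f.is_pseudo:
            quals["pseudo"] = [""]
        rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def write_fasta_gff(genome: GenomeRecord, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write a GenomeRecord as genome FASTA plus GFF3 annotation."""
    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.replicon_id, description="")],
        str(fasta_path),
        "fasta",
    )
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.replicon_id} 1 {len(genome.sequence)}\n")
        for f in genome.features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.gene_name:
                attrs += f";gene={f.gene_name}"
            if f.is_pseudo:
                attrs += ";pseudo=true"
            for s, e in f.intervals:
                fh.write(
                    "\t".join(
                        [
                            genome.replicon_id,
                            "ribosignal",
                            "CDS",
                            str(s),
                            str(e),
                            ".",
                            f.strand,
                            "0",
                            attrs,
                        ]
                    )
                    + "\n"
                )
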