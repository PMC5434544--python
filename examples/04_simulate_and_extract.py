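"""Simulate an annotated genome, write it to disk, and extract flanked CDSs.

Demonstrates the file round trip: the simulator emits GenBank and
FASTA+GFF3 plus a truth table; both annotation routes parse back to the
same flanked records, which can be filtered by intergenic distance and
written to FASTA.
"""

import tempfile
from pathlib import Path

from ribosignal import (
    extract_cds_with_flanks,
    filter_by_intergenic_distance,
    generate_synthetic_genome,
    read_genbank,
    write_flanked_fasta,
)

outdir = Path(tempfile.mkdtemp())
genome, truth, paths = generate_synthetic_genome(
    20, outdir / "demo", motif="GGAG", spacer=6, bias=0.9, seed=11
)
print("wrote:", *[p.name for p in paths.values()])

parsed = read_genbank(paths["genbank"])[0]
records = extract_cds_with_flanks(parsed, upstream=20, downstream=20)
kept = filter_by_intergenic_distance(records, min_5p=100, min_3p=100)
print(f"{len(records)} CDSs extracted, {len(kept)} with >=100 nt intergenic space")

n = write_flanked_fasta(kept, "upstream", outdir / "upstream.fasta")
print(f"{n} upstream windows written to {outdir/'upstream.fasta'}")
print("first record:", kept[0].locus_tag, kept[0].location_label,
      kept[0].upstream_seq)
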