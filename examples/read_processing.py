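"""Raw small-RNA read processing: demultiplex, trim, map.

Builds a tiny multiplexed library (two barcodes, 3' adapter appended),
splits it by barcode, trims the adapter and maps the inserts back to the
locus with the exact ungapped k-mer mapper, reporting per-stage counts.
"""

import numpy as np

from dsbsirna import demultiplex, map_reads, trim_adapters
from dsbsirna.reads import RawRead

rng = np.random.default_rng(0)
reference = "".join(rng.choice(list("ACGT"), size=600))
ADAPTER = "TGGAATTCTCGGGTGCCAAGG"
BARCODES = {"libA": "ACGT", "libB": "TGCA"}

reads = []
for i in range(200):
    bc = "libA" if i % 2 == 0 else "libB"
    start = int(rng.integers(0, 579))
    insert = reference[start : start + 21]
    reads.append(RawRead(f"r{i}", BARCODES[bc] + insert + ADAPTER[:12]))

demux = demultiplex(reads, BARCODES)
print(f"input reads: {len(reads)}, unassigned: {demux.unassigned_count}")
for label, lib_reads in demux.libraries.items():
    trimmed = trim_adapters(lib_reads, ADAPTER, min_overlap=5, min_len=18)
    lib = map_reads(trimmed.kept, reference, name=label)
    print(
        f"{label}: {len(lib_reads)} demultiplexed, {trimmed.rejected} too short, "
        f"{lib.stats['mapped']} mapped of {lib.total_reads}"
    )
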