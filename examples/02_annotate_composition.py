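"""Classify demultiplexed inserts into RNA categories and summarise the
library composition, mirroring the species-composition and read-length
figures of a small-RNA sequencing report.

Non-miRNA categories (rRNA, tRNA, snRNA, snoRNA) are filtered first: a
read matching both a tRNA and a miRNA reference counts as tRNA.
"""

from circmir.annotate import annotate_library, apply_fragment_exclusion
from circmir.demux import BarcodeTable, demultiplex
from circmir.sim import SimConfig, simulate_reads, simulate_references

config = SimConfig(seed=1, n_reads={"serum": 20_000, "plasma": 20_000})
refs = simulate_references(config)
reads, _ = simulate_reads(config, refs)
results, _ = demultiplex(reads, BarcodeTable(dict(config.barcodes)),
                         min_len=15, max_len=35)

for lib in ("serum", "plasma"):
    inserts = [r.insert for r in results
               if r.status == "kept" and r.assignment == lib]
    summary = annotate_library(inserts, refs, library_id=lib)
    pct = summary.percentages
    mirna_pct = pct.get("miRNA", 0) + pct.get("miRNA*", 0)
    mode_length = max(summary.length_counts, key=summary.length_counts.get)
    counts = apply_fragment_exclusion(summary.feature_counts, refs)
    n_star = sum(1 for f in counts if f.endswith("*"))
    print(f"{lib}: miRNA {mirna_pct:.1f}%, tRNA {pct.get('tRNA', 0):.1f}%, "
          f"modal insert length {mode_length} nt, "
          f"{len(counts)} miRNA features detected "
          f"({len(counts) - n_star} miRNA + {n_star} miRNA*)")
# Serum is tRNA-dominated and plasma miRNA-dominated by construction; the
# modal insert length sits at the canonical 22-nt Dicer product, and the
# known tRNA-fragment decoy has been struck from the feature counts.
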