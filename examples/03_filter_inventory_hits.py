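"""Filter similarity-search hits for a paralog inventory.

Builds a small 12-column tabular hit file (the standard search output
format), keeps hits with E-value strictly better than 1e-30, and picks a
canonical isoform for a gene with two splice variants.
"""

import tempfile
from pathlib import Path

from cladesites import filter_significant, parse_hits, select_canonical_isoform, tally_paralogs

lines = [
    # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore
    "AtSH3P1\talga_hit\t31.0\t120\t80\t5\t1\t120\t1\t118\t0.01\t45",
    "AtSH3P1\tmoss_g1\t55.2\t360\t150\t3\t1\t358\t1\t355\t2e-95\t310",
    "AtSH3P2\tmoss_g1\t52.1\t355\t160\t4\t1\t350\t2\t352\t4e-88\t290",
    "AtSH3P2\trice_g2\t48.9\t340\t170\t6\t5\t344\t1\t338\t1e-31\t120",
]
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "hits.tsv"
    path.write_text("\n".join(lines) + "\n")
    hits = parse_hits(path)
    kept = filter_significant(hits)

print(f"{len(kept)}/{len(hits)} hits significant at E < 1e-30 "
      "(one best hit per subject):")
for _, row in kept.iterrows():
    print(f"  {row.sseqid}\tE={row.evalue:g}")
# The E=0.01 hit (the typical best score against chlorophyte algae) is
# rejected; moss_g1 is kept once, via its lowest-E-value hit.

iso = select_canonical_isoform([("moss_g1.1", "M" * 300), ("moss_g1.2", "M" * 352)])
print(f"canonical isoform of moss_g1: {iso} (longest splice variant)")

tally = tally_paralogs([("moss", "SH3P1"), ("rice", "SH3P2"),
                        ("rice", "SH3P1"), ("rice", "SH3P3")])
print("\nparalog tally (species x clade):")
print(tally.to_string())
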