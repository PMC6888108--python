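"""Summarise the published SH3P clade-specific site table.

The bundled table lists the 14 candidate clade-specific conserved sites of
the angiosperm SH3P family (BAR + SH3 domain proteins, clades
SH3P1/SH3P2/SH3P3).  The summary counts sites per clade and per domain.
"""

from cladesites import load_sh3p_sites, summarize_counts

table = load_sh3p_sites()
by_clade, by_domain = summarize_counts(table)

print(f"total clade-specific sites: {len(table)}")
print("per clade:", dict(sorted(by_clade.items())))
print("per domain:", by_domain)
# SH3P1 carries only 2 clade-specific sites versus 4 (SH3P2) and 8 (SH3P3),
# consistent with SH3P1 being the least diverged paralog; most sites fall
# in the membrane-binding BAR domain.
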