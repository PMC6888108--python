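"""Bundled example data.

``load_sh3p_sites`` returns the published table of 14 candidate
clade-specific conserved sites of the angiosperm SH3P family (BAR-SH3
domain proteins; clades SH3P1/SH3P2/SH3P3 named for their Arabidopsis
members, positions numbered per each clade's A. thaliana representative).
It serves as a worked example for the summary utilities; reproducing the
table itself requires the family's curated alignment, which is not bundled.
"""

from importlib import resources

from .classify import SiteTable, read_site_table


def load_sh3p_sites() -> SiteTable:
    """The 14-row published SH3P clade-specific site table."""
    ref = resources.files("cladesites.data") / "sh3p_clade_specific_sites.tsv"
    with resources.as_file(ref) as path:
        return read_site_table(path)
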