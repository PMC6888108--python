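"""Independent naive implementations used as oracles by the test suite.

These are written directly from the classification rules with plain loops
and an independently hard-coded category map; they deliberately share no
code with the package.
"""

from collections import Counter

NAIVE_CATEGORIES = {
    "aliphatic": set("MILV"),
    "small hydrophilic": set("STPAG"),
    "aromatic": set("FYW"),
    "cysteine": set("C"),
    "acid/amide": set("NDEQ"),
    "basic": set("HRK"),
}
_CAT_OF = {r: lab for lab, residues in NAIVE_CATEGORIES.items() for r in residues}


def naive_cat(ch):
    return _CAT_OF.get(ch.upper())  # None for gaps/ambiguity/nonstandard


def naive_classify(column, clades, min_clade_size=2):
    """Classify one column given per-sequence characters and clade labels.

    Returns (class_name, focal_clades_tuple).  ``column`` and ``clades`` are
    parallel sequences.
    """
    pairs = list(zip(column, clades))
    clade_names = sorted(set(clades))

    # Rule 1: universal — no gaps, no uncategorisable, one category overall.
    cats = set()
    clean = True
    for ch, _ in pairs:
        if ch == "-" or naive_cat(ch) is None:
            clean = False
            break
        cats.add(naive_cat(ch))
    if clean and len(cats) == 1:
        return "UNIVERSAL", ()

    def clade_fixed(c):
        chars = [ch for ch, cl in pairs if cl == c]
        if len(chars) < min_clade_size:
            return None
        cats = set()
        for ch in chars:
            if ch == "-" or naive_cat(ch) is None:
                return None
            cats.add(naive_cat(ch))
        return next(iter(cats)) if len(cats) == 1 else None

    def outside_count(c, category):
        n = 0
        for ch, cl in pairs:
            if cl != c and ch != "-" and naive_cat(ch) == category:
                n += 1
        return n

    specific, shared = [], []
    for c in clade_names:
        k = clade_fixed(c)
        if k is None:
            continue
        if outside_count(c, k) == 0:
            specific.append(c)
        else:
            shared.append(c)
    if specific:
        return "CLADE_SPECIFIC", tuple(specific)
    if shared:
        return "CLADE_SHARED", tuple(shared)
    return "VARIABLE", ()


def naive_refpos(ref_row, column):
    """1-based residue number by per-column rescan; None on a gap."""
    if ref_row[column - 1] == "-":
        return None
    return sum(1 for ch in ref_row[:column] if ch != "-")


def naive_order_by_frequency(multiset):
    counts = Counter(multiset)
    return sorted(counts, key=lambda r: (-counts[r], r))
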