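"""Column conservation classification and the clade-specific site table.

Every alignment column is assigned exactly one of four classes, evaluated
in this order of precedence:

1. ``UNIVERSAL`` — no gaps or uncategorisable residues anywhere, and all
   residues fall in one amino-acid category (conserved across the family).
2. ``CLADE_SPECIFIC`` — some clade (of at least ``min_clade_size`` members,
   internally gap-free and free of uncategorisable residues) is fixed for a
   category that occurs in *zero* residues of every other clade.  Gaps and
   uncategorisable residues outside the focal clade count as non-matching,
   so a clade fixed for E while others show G or a gap still qualifies.
   All qualifying clades are reported.
3. ``CLADE_SHARED`` — some clade (same internal requirements) is fixed for
   a category that also occurs in at least one residue outside it.
4. ``VARIABLE`` — everything else.

Clade-specific calls are collected into a :class:`SiteTable` whose rows
mirror the conventional published layout: site number, focal clade, domain,
position in the focal clade's reference numbering, conserved residues, and
residues observed in the other clades ordered by frequency.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .alignment import (
    GAP,
    DomainAnnotation,
    LabeledAlignment,
    assign_domain,
    refpos_map,
)
from .categories import UNCATEGORIZED, CategoryScheme, categorize

UNIVERSAL = "UNIVERSAL"
CLADE_SPECIFIC = "CLADE_SPECIFIC"
CLADE_SHARED = "CLADE_SHARED"
VARIABLE = "VARIABLE"

#: Single-letter class codes used in per-column call tracks and TSVs.
CLASS_CODES = {UNIVERSAL: "U", CLADE_SHARED: "S", CLADE_SPECIFIC: "C", VARIABLE: "V"}
CODE_CLASSES = {v: k for k, v in CLASS_CODES.items()}


@dataclass(frozen=True)
class Policy:
    """Classification knobs.

    min_clade_size: smallest clade for which fixation is meaningful
    (conservation over a single sequence is vacuous; default 2).
    """

    min_clade_size: int = 2


@dataclass(frozen=True)
class CladeProfile:
    """Per-clade tallies of one column."""

    residues: Counter  # non-gap residues -> counts (uncategorisable included)
    gap_count: int
    categories: frozenset[str]  # categories present (UNCATEGORIZED excluded)
    uncategorized_count: int
    size: int

    def __post_init__(self) -> None:
        assert sum(self.residues.values()) + self.gap_count == self.size


@dataclass(frozen=True)
class ColumnProfile:
    """Tallies of one 1-based alignment column, per clade.

    Carries the scheme it was tallied under so classification can test
    category membership of individual residues.
    """

    column: int
    per_clade: dict[str, CladeProfile]
    scheme: CategoryScheme


@dataclass(frozen=True)
class ColumnCall:
    """Classification of one column.

    ``focal_clades`` is empty for UNIVERSAL and VARIABLE; for the two
    clade-level classes ``focal_categories`` maps each focal clade to its
    fixed category and ``refpos`` to the residue number in that clade's
    reference (``None`` where the reference is gapped at the column).
    """

    column: int
    site_class: str
    focal_clades: tuple[str, ...] = ()
    focal_categories: dict[str, str] = field(default_factory=dict)
    refpos: dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.site_class in (CLADE_SPECIFIC, CLADE_SHARED):
            assert self.focal_clades and all(
                c in self.focal_categories for c in self.focal_clades
            )

    @property
    def conserved_category(self) -> Optional[str]:
        """The fixed category when unambiguous across focal clades, else None."""
        cats = set(self.focal_categories.values())
        return next(iter(cats)) if len(cats) == 1 else None

    @property
    def code(self) -> str:
        return CLASS_CODES[self.site_class]


def profile_column(aln: LabeledAlignment, scheme: CategoryScheme,
                   column: int) -> ColumnProfile:
    """Exact per-clade residue/gap/category tallies of a 1-based column."""
    chars = aln.column(column)
    per_clade: dict[str, CladeProfile] = {}
    for clade in aln.clades:
        residues: Counter = Counter()
        gaps = 0
        cats: set[str] = set()
        uncat = 0
        for sid, ch in zip(aln.seq_ids, chars):
            if aln.clade_of[sid] != clade:
                continue
            if ch == GAP:
                gaps += 1
                continue
            residues[ch] += 1
            cat = categorize(scheme, ch)
            if cat == UNCATEGORIZED:
                uncat += 1
            else:
                cats.add(cat)
        per_clade[clade] = CladeProfile(
            residues=residues, gap_count=gaps, categories=frozenset(cats),
            uncategorized_count=uncat, size=gaps + sum(residues.values()),
        )
    return ColumnProfile(column=column, per_clade=per_clade, scheme=scheme)


def classify_column(profile: ColumnProfile, policy: Policy = Policy()) -> ColumnCall:
    """Apply the four classification rules (see module docstring) to one column."""
    pc = profile.per_clade
    clades = sorted(pc)
    total_gaps = sum(p.gap_count for p in pc.values())
    total_uncat = sum(p.uncategorized_count for p in pc.values())
    all_cats = frozenset().union(*(p.categories for p in pc.values()))

    # Rule 1: universal conservation.
    if total_gaps == 0 and total_uncat == 0 and len(all_cats) == 1:
        return ColumnCall(column=profile.column, site_class=UNIVERSAL)

    # A clade is "fixed" when it is large enough, internally clean, and all
    # its residues share one category.
    def fixed_category(clade: str) -> Optional[str]:
        p = pc[clade]
        if (p.size >= policy.min_clade_size and p.gap_count == 0
                and p.uncategorized_count == 0 and len(p.categories) == 1):
            return next(iter(p.categories))
        return None

    def occurrences_outside(clade: str, category: str) -> int:
        members = profile.scheme.residues_of(category)
        n = 0
        for other in clades:
            if other == clade:
                continue
            for res, cnt in pc[other].residues.items():
                # Category membership only; gaps/uncategorisable never match.
                if res in members:
                    n += cnt
        return n

    specific: dict[str, str] = {}
    shared: dict[str, str] = {}
    for clade in clades:
        k = fixed_category(clade)
        if k is None:
            continue
        if occurrences_outside(clade, k) == 0:
            specific[clade] = k
        else:
            shared[clade] = k

    if specific:
        focal = tuple(sorted(specific))
        return ColumnCall(column=profile.column, site_class=CLADE_SPECIFIC,
                          focal_clades=focal, focal_categories=specific)
    if shared:
        focal = tuple(sorted(shared))
        return ColumnCall(column=profile.column, site_class=CLADE_SHARED,
                          focal_clades=focal, focal_categories=shared)
    return ColumnCall(column=profile.column, site_class=VARIABLE)


def order_by_frequency(residues: Union[Counter, dict, Sequence[str]]) -> list[str]:
    """Residues sorted by descending count, ties broken alphabetically."""
    counts = Counter(residues) if not isinstance(residues, Counter) else residues
    if not counts:
        raise ValueError("empty residue multiset")
    return sorted(counts, key=lambda r: (-counts[r], r))


@dataclass(frozen=True)
class SiteRow:
    """One clade-specific conserved site."""

    site: int
    clade: str
    domain: str
    column: int  # 1-based alignment column
    position: Optional[int]  # residue number in the focal clade's reference
    conserved_aa: str  # focal-clade residues, " or "-joined, by frequency
    other_aa: str  # other-clade residues (incl. 'gap'), by frequency


@dataclass(frozen=True)
class SiteTable:
    """Ordered table of clade-specific sites (alignment-column order)."""

    rows: tuple[SiteRow, ...]

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site": r.site, "clade": r.clade, "domain": r.domain,
                    "position": r.position, "conserved_aa": r.conserved_aa,
                    "aa_other_clades": r.other_aa, "column": r.column,
                }
                for r in self.rows
            ],
            columns=["site", "clade", "domain", "position", "conserved_aa",
                     "aa_other_clades", "column"],
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        df = self.to_dataframe()
        df["position"] = df["position"].map(lambda p: "NA" if p is None else p)
        df.to_csv(path, sep="\t", index=False)


def read_site_table(path: Union[str, Path]) -> SiteTable:
    """Read a site-table TSV (column 'column' optional, position 'NA' allowed)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    rows = []
    for _, rec in df.iterrows():
        pos = rec.get("position", "")
        rows.append(SiteRow(
            site=int(rec["site"]), clade=rec["clade"], domain=rec.get("domain", ""),
            column=int(rec["column"]) if rec.get("column", "") not in ("", "NA") else 0,
            position=None if pos in ("", "NA") else int(pos),
            conserved_aa=rec.get("conserved_aa", ""),
            other_aa=rec.get("aa_other_clades", ""),
        ))
    return SiteTable(rows=tuple(rows))


def _render_residues(counts: Counter, gap_count: int = 0) -> str:
    tokens = dict(counts)
    if gap_count:
        tokens["gap"] = gap_count
    c = Counter(tokens)
    return " or ".join(sorted(c, key=lambda r: (-c[r], "zzz" if r == "gap" else r)))


def scan_alignment(
    aln: LabeledAlignment,
    scheme: CategoryScheme,
    policy: Policy = Policy(),
    annotation: Optional[DomainAnnotation] = None,
) -> tuple[list[ColumnCall], SiteTable]:
    """Classify every column and build the clade-specific site table.

    Returns one :class:`ColumnCall` per column plus a :class:`SiteTable`
    holding exactly the clade-specific calls — one row per (column, focal
    clade), numbered consecutively in alignment-column order.  Positions are
    residue numbers in the focal clade's reference; where that reference is
    gapped at the column the position is ``None`` (printed ``NA``).  Domains
    are assigned through ``annotation`` (mapped via the annotation
    reference's own coordinates) when provided.
    """
    if annotation is not None and annotation.reference_id not in aln.seq_ids:
        from .errors import ReferenceError_

        raise ReferenceError_(
            f"annotation reference {annotation.reference_id!r} not in alignment"
        )
    ref_maps = {clade: refpos_map(aln, ref) for clade, ref in aln.reference_of.items()}
    ann_map = refpos_map(aln, annotation.reference_id) if annotation is not None else None

    calls: list[ColumnCall] = []
    rows: list[SiteRow] = []
    site_no = 0
    for col in range(1, aln.n_columns + 1):
        profile = profile_column(aln, scheme, col)
        call = classify_column(profile, policy)
        if call.focal_clades:
            refpos = {}
            for clade in call.focal_clades:
                rp = int(ref_maps[clade][col - 1])
                refpos[clade] = rp if rp > 0 else None
            call = ColumnCall(column=col, site_class=call.site_class,
                              focal_clades=call.focal_clades,
                              focal_categories=call.focal_categories,
                              refpos=refpos)
        calls.append(call)

        if call.site_class != CLADE_SPECIFIC:
            continue
        for clade in call.focal_clades:
            site_no += 1
            focal = profile.per_clade[clade]
            others: Counter = Counter()
            other_gaps = 0
            for c2, p2 in profile.per_clade.items():
                if c2 == clade:
                    continue
                others.update(p2.residues)
                other_gaps += p2.gap_count
            domain = ""
            if annotation is not None:
                # Domain from the annotation reference's coordinate at this
                # column; if that reference is gapped here, use the last
                # preceding residue (the column sits inside/after it).
                apos = int(ann_map[col - 1])
                if apos == 0:
                    prior = ann_map[: col - 1]
                    apos = int(prior.max()) if (prior > 0).any() else 1
                domain = assign_domain(annotation, apos)
            rows.append(SiteRow(
                site=site_no, clade=clade, domain=domain, column=col,
                position=call.refpos.get(clade),
                conserved_aa=_render_residues(focal.residues),
                other_aa=_render_residues(others, other_gaps),
            ))
    return calls, SiteTable(rows=tuple(rows))


def summarize_counts(table: SiteTable) -> tuple[dict[str, int], dict[str, int]]:
    """Per-clade and per-domain counts of clade-specific sites."""
    by_clade: Counter = Counter(r.clade for r in table.rows)
    by_domain: Counter = Counter(r.domain for r in table.rows)
    return dict(by_clade), dict(by_domain)


def write_calls_tsv(calls: Sequence[ColumnCall], path: Union[str, Path]) -> None:
    """Per-column calls TSV: column, class code, focal clades, category."""
    with open(path, "w") as fh:
        fh.write("column\tclass\tfocal_clades\tcategory\n")
        for call in calls:
            cat = call.conserved_category or ""
            fh.write(f"{call.column}\t{call.code}\t{','.join(call.focal_clades)}\t{cat}\n")


def read_calls_tsv(path: Union[str, Path]) -> list[ColumnCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("column\t")
        for line in fh:
            col, code, focal, cat = line.rstrip("\n").split("\t")
            focal_clades = tuple(focal.split(",")) if focal else ()
            cats = {c: cat for c in focal_clades} if cat else {}
            calls.append(ColumnCall(column=int(col), site_class=CODE_CLASSES[code],
                                    focal_clades=focal_clades, focal_categories=cats))
    return calls
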