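"""Amino-acid category schemes.

Conservation in this package is assessed at the level of physicochemical
residue categories, not residue identity: a site is "conserved" in a clade
when every member carries a residue from the same category (so a column of
V and I counts as conserved aliphatic).  A :class:`CategoryScheme` is a
named partition of the 20 standard amino acids into such categories.

The frozen default partitions the residues into six groups:

===================  ========
aliphatic            M I L V
small hydrophilic    S T P A G
aromatic             F Y W
cysteine             C
acid/amide           N D E Q
basic                H R K
===================  ========

Gap characters, ambiguity codes (B, J, Z, X) and nonstandard residues
(U, O, ``*``) fall outside every category and map to :data:`UNCATEGORIZED`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    SchemeError,
    SchemeIncompleteError,
    SchemeOverlapError,
    SchemeUnknownResidueError,
)

#: The 20 standard amino acids (1-letter IUPAC codes).
STANDARD_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Sentinel category returned for gaps, ambiguity codes and nonstandard residues.
UNCATEGORIZED = "UNCATEGORIZED"


@dataclass(frozen=True)
class CategoryScheme:
    """A named, disjoint, complete partition of the standard amino acids.

    Parameters
    ----------
    name:
        Human-readable scheme name.
    categories:
        Ordered ``(label, residues)`` pairs.  Labels must be unique, the
        residue sets pairwise disjoint, and their union must be exactly the
        20 standard residues.

    Raises
    ------
    SchemeOverlapError, SchemeIncompleteError, SchemeUnknownResidueError
        When the partition invariants are violated.
    SchemeError
        Fewer than 2 categories, an empty category, or a duplicate label.
    """

    name: str
    categories: tuple[tuple[str, frozenset[str]], ...]
    _lookup: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        cats = tuple((label, frozenset(res)) for label, res in self.categories)
        object.__setattr__(self, "categories", cats)
        if len(cats) < 2:
            raise SchemeError(f"scheme {self.name!r} needs at least 2 categories")
        labels = [label for label, _ in cats]
        if len(set(labels)) != len(labels):
            raise SchemeError(f"duplicate category label in scheme {self.name!r}")
        lookup: dict[str, str] = {}
        for label, residues in cats:
            if not residues:
                raise SchemeError(f"empty category {label!r}")
            for r in residues:
                if r not in STANDARD_RESIDUES:
                    raise SchemeUnknownResidueError(
                        f"category {label!r} lists non-standard character {r!r}"
                    )
                if r in lookup:
                    raise SchemeOverlapError(
                        f"residue {r!r} in both {lookup[r]!r} and {label!r}: overlap"
                    )
                lookup[r] = label
        missing = STANDARD_RESIDUES - set(lookup)
        if missing:
            raise SchemeIncompleteError(
                "incomplete partition: missing " + "".join(sorted(missing))
            )
        object.__setattr__(self, "_lookup", lookup)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.categories)

    def residues_of(self, label: str) -> frozenset[str]:
        """Residue set of a category label."""
        for lab, residues in self.categories:
            if lab == label:
                return residues
        raise KeyError(label)

    def __len__(self) -> int:
        return len(self.categories)


def default_scheme() -> CategoryScheme:
    """The frozen six-category default scheme (see module docstring).

    Pure: repeated calls return equal objects.
    """
    return CategoryScheme(
        name="six-category",
        categories=(
            ("aliphatic", frozenset("MILV")),
            ("small hydrophilic", frozenset("STPAG")),
            ("aromatic", frozenset("FYW")),
            ("cysteine", frozenset("C")),
            ("acid/amide", frozenset("NDEQ")),
            ("basic", frozenset("HRK")),
        ),
    )


def categorize(scheme: CategoryScheme, residue: str) -> str:
    """Category label of ``residue`` under ``scheme``.

    Case-insensitive.  Gap characters (``-``, ``.``), ambiguity codes and
    anything else outside the 20 standard residues return
    :data:`UNCATEGORIZED`.

    Raises
    ------
    ValueError
        If ``residue`` is not a single character.
    """
    if len(residue) != 1:
        raise ValueError(f"expected a single character, got {residue!r}")
    return scheme._lookup.get(residue.upper(), UNCATEGORIZED)


def load_scheme(config_text: str, name: str = "custom") -> CategoryScheme:
    """Parse a scheme from plain ``label: RESIDUES`` config text.

    One category per non-blank, non-``#`` line, e.g.::

        aliphatic: MILV
        small hydrophilic: STPAG
        ...

    ``label = RESIDUES`` and ``label<TAB>RESIDUES`` are accepted too.
    The parsed scheme must satisfy all partition invariants.
    """
    categories: list[tuple[str, frozenset[str]]] = []
    for lineno, raw in enumerate(config_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        for sep in (":", "=", "\t"):
            if sep in line:
                label, _, residues = line.partition(sep)
                break
        else:
            raise SchemeError(f"line {lineno}: expected 'label: RESIDUES', got {line!r}")
        label = label.strip()
        residues = residues.strip().replace(" ", "").upper()
        if not label:
            raise SchemeError(f"line {lineno}: empty category label")
        categories.append((label, frozenset(residues)))
    if not categories:
        raise SchemeError("empty scheme config")
    return CategoryScheme(name=name, categories=tuple(categories))
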