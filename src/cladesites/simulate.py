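"""Synthetic protein families with planted, verifiable conservation structure.

The generator emulates a paralogous family split into a few clades (the
default mimics a three-clade angiosperm family of ~8 members per clade and
~400 alignment columns).  Each column is planted in one of the four
conservation classes and sampled so that the classifier's definitions hold
by construction:

* UNIVERSAL — one category drawn for the whole family; every sequence gets
  a residue from it (within-category resampling produces "V or I"-style
  variation without breaking the call).
* CLADE_SPECIFIC — the focal clade is fixed for a category absent from all
  other clades.  With three or more clades the non-focal clades inherit a
  common ancestral residue drawn from the complement of the focal category,
  resampled within the complement at the substitution rate; this emulates
  the coherent "other clades" patterns seen in real families (e.g. focal
  D/E against H/R elsewhere) and keeps within-clade divergence realistic.
  With exactly two clades the single other clade is drawn i.i.d. from the
  complement instead (a shared ancestor there would make it clade-specific
  too).  Gaps may optionally be injected into non-focal clades, never into
  the focal clade.
* CLADE_SHARED — one clade fixed for a category that is forced to occur in
  at least one sequence outside it.
* VARIABLE — background draws with gaps at ``gap_rate``.

Every planted column is verified post hoc against the classifier and
resampled on collision (e.g. a VARIABLE column that accidentally satisfies
clade specificity), so generator truth and classifier output agree exactly.
A fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .alignment import GAP, LabeledAlignment
from .categories import CategoryScheme, default_scheme
from .classify import (
    CLADE_SHARED,
    CLADE_SPECIFIC,
    UNIVERSAL,
    VARIABLE,
    Policy,
    classify_column,
    profile_column,
)
from .errors import UnsatisfiableSpecError

_CLASSES = (UNIVERSAL, CLADE_SPECIFIC, CLADE_SHARED, VARIABLE)
_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic family.

    class_fractions gives the expected share of columns per class; the
    CLADE_SPECIFIC (and CLADE_SHARED) mass is spread uniformly over clades.
    within_category_substitution_rate is the chance a conserved residue is
    resampled within its category, producing "V or I"-style variation.
    gap_rate applies to VARIABLE columns; gap_rate_nonfocal optionally puts
    gaps into non-focal clades of specific columns (never the focal clade).
    """

    n_clades: int = 3
    seqs_per_clade: int = 8
    n_columns: int = 400
    class_fractions: dict = field(default_factory=lambda: {
        UNIVERSAL: 0.10, CLADE_SPECIFIC: 0.04, CLADE_SHARED: 0.08, VARIABLE: 0.78,
    })
    within_category_substitution_rate: float = 0.3
    gap_rate: float = 0.05
    gap_rate_nonfocal: float = 0.0
    residue_frequencies: Optional[dict] = None  # None -> uniform over the 20
    seed: int = 0
    min_clade_size: int = 2

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.get(c, 0.0) for c in _CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise UnsatisfiableSpecError(f"class fractions sum to {total}, not 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise UnsatisfiableSpecError("negative class fraction")
        for rate in (self.within_category_substitution_rate, self.gap_rate,
                     self.gap_rate_nonfocal):
            if not 0.0 <= rate <= 1.0:
                raise UnsatisfiableSpecError("rates must lie in [0, 1]")
        if self.n_clades < 2 and self.class_fractions.get(CLADE_SPECIFIC, 0) > 0:
            raise UnsatisfiableSpecError(
                "clade-specific columns need at least 2 clades"
            )
        if self.n_clades < 2:
            raise UnsatisfiableSpecError("need at least 2 clades")
        if self.seqs_per_clade < self.min_clade_size:
            raise UnsatisfiableSpecError(
                f"seqs_per_clade ({self.seqs_per_clade}) below "
                f"min_clade_size ({self.min_clade_size})"
            )
        if self.n_columns < 1:
            raise UnsatisfiableSpecError("need at least 1 column")


@dataclass(frozen=True)
class ColumnTruth:
    """Planted label of one column."""

    column: int
    site_class: str
    focal_clade: Optional[str] = None
    category: Optional[str] = None


@dataclass(frozen=True)
class SyntheticFamily:
    """A generated alignment plus its per-column ground truth."""

    alignment: LabeledAlignment
    truth: tuple[ColumnTruth, ...]
    spec: FamilySpec

    def __post_init__(self) -> None:
        assert len(self.truth) == self.alignment.n_columns

    def truth_tsv(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("column\tclass\tfocal_clade\tcategory\n")
            for t in self.truth:
                fh.write(f"{t.column}\t{t.site_class}\t{t.focal_clade or ''}"
                         f"\t{t.category or ''}\n")


def _residue_probs(spec: FamilySpec, alphabet: list[str]) -> np.ndarray:
    if spec.residue_frequencies is None:
        return np.full(len(alphabet), 1.0 / len(alphabet))
    p = np.array([spec.residue_frequencies.get(r, 0.0) for r in alphabet])
    if p.sum() <= 0:
        raise UnsatisfiableSpecError("residue_frequencies assign zero total mass")
    return p / p.sum()


def _draw_within(rng: np.random.Generator, residues: list[str], n: int,
                 rate: float) -> list[str]:
    """n residues: a common ancestral pick, each resampled within-category at `rate`."""
    anc = residues[rng.integers(len(residues))]
    out = []
    for _ in range(n):
        if rng.random() < rate:
            out.append(residues[rng.integers(len(residues))])
        else:
            out.append(anc)
    return out


def simulate_family(spec: FamilySpec,
                    scheme: Optional[CategoryScheme] = None) -> SyntheticFamily:
    """Generate a family with planted per-column conservation classes.

    Deterministic for a fixed ``spec.seed``.  Raises
    :class:`UnsatisfiableSpecError` when a planted column cannot be realised
    (pathological fractions or scheme).
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)
    clades = [f"clade{i + 1}" for i in range(spec.n_clades)]
    seq_ids = [f"{c}_seq{j + 1}" for c in clades for j in range(spec.seqs_per_clade)]
    clade_of = {sid: sid.rsplit("_", 1)[0] for sid in seq_ids}
    references = {c: f"{c}_seq1" for c in clades}
    n_seqs = len(seq_ids)
    clade_slices = {
        c: slice(i * spec.seqs_per_clade, (i + 1) * spec.seqs_per_clade)
        for i, c in enumerate(clades)
    }
    alphabet = sorted(set().union(*(res for _, res in scheme.categories)))
    bg = _residue_probs(spec, alphabet)
    cat_labels = list(scheme.labels)
    policy = Policy(min_clade_size=spec.min_clade_size)

    # Plant the class (and focal clade) of each column up front.
    fracs = np.array([spec.class_fractions.get(c, 0.0) for c in _CLASSES])
    planted_classes = rng.choice(len(_CLASSES), size=spec.n_columns, p=fracs)
    focal_cycle = {CLADE_SPECIFIC: 0, CLADE_SHARED: 0}

    columns = np.empty((n_seqs, spec.n_columns), dtype="<U1")
    truth: list[ColumnTruth] = []

    for j in range(spec.n_columns):
        site_class = _CLASSES[planted_classes[j]]
        focal = None
        if site_class in (CLADE_SPECIFIC, CLADE_SHARED):
            focal = clades[focal_cycle[site_class] % spec.n_clades]
            focal_cycle[site_class] += 1
        col, category = _sample_column(
            rng, spec, scheme, site_class, focal, clades, clade_slices,
            alphabet, bg, cat_labels, n_seqs,
        )
        # Post-hoc verification: resample on collision with another class.
        tries = 0
        while not _matches(col, site_class, focal, seq_ids, clade_of, scheme, policy):
            tries += 1
            if tries > _MAX_RESAMPLE:
                raise UnsatisfiableSpecError(
                    f"could not realise a {site_class} column after "
                    f"{_MAX_RESAMPLE} resamples"
                )
            col, category = _sample_column(
                rng, spec, scheme, site_class, focal, clades, clade_slices,
                alphabet, bg, cat_labels, n_seqs,
            )
        columns[:, j] = col
        truth.append(ColumnTruth(
            column=j + 1, site_class=site_class, focal_clade=focal,
            category=category if site_class != VARIABLE else None,
        ))

    records = tuple((sid, "".join(columns[i])) for i, sid in enumerate(seq_ids))
    aln = LabeledAlignment(records=records, clade_of=clade_of,
                           reference_of=references)
    return SyntheticFamily(alignment=aln, truth=tuple(truth), spec=spec)


def _sample_column(rng, spec, scheme, site_class, focal, clades, clade_slices,
                   alphabet, bg, cat_labels, n_seqs):
    rate = spec.within_category_substitution_rate
    col = np.empty(n_seqs, dtype="<U1")
    if site_class == UNIVERSAL:
        k = cat_labels[rng.integers(len(cat_labels))]
        residues = sorted(scheme.residues_of(k))
        col[:] = _draw_within(rng, residues, n_seqs, rate)
        return col, k

    if site_class == VARIABLE:
        draws = rng.choice(alphabet, size=n_seqs, p=bg)
        gaps = rng.random(n_seqs) < spec.gap_rate
        col[:] = np.where(gaps, GAP, draws)
        return col, None

    # Clade-level classes: fix a category in the focal clade.
    k = cat_labels[rng.integers(len(cat_labels))]
    residues = sorted(scheme.residues_of(k))
    fs = clade_slices[focal]
    col[fs] = _draw_within(rng, residues, fs.stop - fs.start, rate)
    others = [c for c in clades if c != focal]

    if site_class == CLADE_SPECIFIC:
        complement = sorted(set(alphabet) - set(residues))
        # Shared non-focal ancestor (needs a third clade to carry the same
        # category, otherwise the other clade would itself become specific).
        anc = complement[rng.integers(len(complement))] if len(others) > 1 else None
        for c in others:
            s = clade_slices[c]
            for i in range(s.start, s.stop):
                if rng.random() < spec.gap_rate_nonfocal:
                    col[i] = GAP
                elif anc is None or rng.random() < rate:
                    col[i] = complement[rng.integers(len(complement))]
                else:
                    col[i] = anc
        return col, k

    # CLADE_SHARED: others drawn from full background, then force one
    # out-of-clade occurrence of the focal category.
    other_idx = [i for c in others for i in range(clade_slices[c].start,
                                                  clade_slices[c].stop)]
    draws = rng.choice(alphabet, size=len(other_idx), p=bg)
    for pos, res in zip(other_idx, draws):
        col[pos] = res
    forced = other_idx[rng.integers(len(other_idx))]
    col[forced] = residues[rng.integers(len(residues))]
    return col, k


def _matches(col, site_class, focal, seq_ids, clade_of, scheme, policy) -> bool:
    """Does the classifier agree with the planted label (incl. focal clade)?"""
    records = tuple((sid, col[i]) for i, sid in enumerate(seq_ids))
    aln = LabeledAlignment(records=records, clade_of=dict(clade_of))
    call = classify_column(profile_column(aln, scheme, 1), policy)
    if call.site_class != site_class:
        return False
    if site_class in (CLADE_SPECIFIC, CLADE_SHARED):
        return call.focal_clades == (focal,)
    return True


def verify_truth(fam: SyntheticFamily,
                 scheme: Optional[CategoryScheme] = None,
                 policy: Optional[Policy] = None) -> tuple[bool, Optional[int]]:
    """Re-evaluate every column against its planted label.

    Returns ``(True, None)`` when every column's classification (including
    the focal clade for clade-level classes) matches the planted truth,
    else ``(False, first_violating_column)``.
    """
    scheme = scheme or default_scheme()
    policy = policy or Policy(min_clade_size=fam.spec.min_clade_size)
    aln = fam.alignment
    for t in fam.truth:
        profile = profile_column(aln, scheme, t.column)
        call = classify_column(profile, policy)
        ok = call.site_class == t.site_class
        if ok and t.site_class in (CLADE_SPECIFIC, CLADE_SHARED):
            ok = call.focal_clades == (t.focal_clade,)
        if not ok:
            return False, t.column
    return True, None
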