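"""Homolog inventory: hit filtering, canonical-isoform choice, paralog tallies.

The inventory stage of a protein-family survey starts from similarity-search
output in the standard 12-column tabular format (query, subject, % identity,
alignment length, mismatches, gap opens, query/subject start/end, E-value,
bit score).  Hits are accepted as family members only when their E-value is
strictly below a significance cutoff (default 1e-30 — "better than e-30");
borderline hits at the cutoff and weak hits (e.g. E = 0.01) are rejected.
For genes with several predicted splice isoforms, the longest isoform is
taken as canonical unless the caller supplies a custom ranking.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import EmptyGroupError, HitParseError

#: Column names of the standard 12-column tabular search output.
HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

_DTYPES = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}

PathLike = Union[str, Path]


def parse_hits(tsv_path: PathLike) -> pd.DataFrame:
    """Parse a 12-column tabular hit file into a typed DataFrame.

    Malformed lines (wrong field count, non-numeric values) raise
    :class:`HitParseError` naming the offending line number.
    """
    rows = []
    with open(tsv_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitParseError(
                    f"{tsv_path}:{lineno}: expected 12 fields, got {len(fields)}"
                )
            rec = dict(zip(HIT_COLUMNS, fields))
            try:
                for key, typ in _DTYPES.items():
                    rec[key] = typ(rec[key])
            except ValueError as exc:
                raise HitParseError(f"{tsv_path}:{lineno}: {exc}") from None
            if rec["evalue"] < 0:
                raise HitParseError(f"{tsv_path}:{lineno}: negative E-value")
            rows.append(rec)
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))


def filter_significant(hits: pd.DataFrame, e_max: float = 1e-30,
                       dedupe_subjects: bool = True) -> pd.DataFrame:
    """Retain hits with E-value strictly below ``e_max``.

    "Better than" in E-value semantics means smaller, and the boundary is
    excluded: an E-value exactly at the cutoff is rejected.  With
    ``dedupe_subjects`` (default) only the best hit per subject is kept —
    lowest E-value, ties broken by highest bit score then first occurrence —
    and the surviving rows keep their original order.  Idempotent.
    """
    kept = hits[hits["evalue"] < e_max]
    if dedupe_subjects and len(kept):
        best_idx = []
        for _, grp in kept.groupby("sseqid", sort=False):
            ranked = grp.sort_values(
                ["evalue", "bitscore"], ascending=[True, False], kind="stable"
            )
            best_idx.append(ranked.index[0])
        kept = kept.loc[sorted(best_idx)]
    return kept.reset_index(drop=True)


def select_canonical_isoform(
    members: Sequence[tuple[str, str]],
    key: Optional[Callable[[str, str], object]] = None,
) -> str:
    """Pick the canonical isoform from ``(isoform_id, sequence)`` pairs.

    Default rule: the longest sequence, ties broken by lexicographically
    smallest isoform id.  A custom ``key(isoform_id, sequence)`` (higher is
    better) replaces the length criterion; the id tie-break stays.
    """
    if not members:
        raise EmptyGroupError("isoform group has no members")
    ids = [i for i, _ in members]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate isoform ids in group")
    if key is None:
        key = lambda _id, seq: len(seq)
    ranked = sorted(members, key=lambda m: (-_as_rank(key(m[0], m[1])), m[0]))
    return ranked[0][0]


def _as_rank(value: object) -> float:
    return float(value)  # type: ignore[arg-type]


def tally_paralogs(records: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Count paralogs per species (rows) and clade (columns), plus totals.

    ``records`` are ``(species, clade)`` pairs, one per retained gene.
    Row totals equal the number of records per species; order-invariant.
    """
    df = pd.DataFrame(list(records), columns=["species", "clade"])
    if df.empty:
        return pd.DataFrame()
    tally = (
        df.groupby(["species", "clade"]).size().unstack(fill_value=0).sort_index()
    )
    tally = tally[sorted(tally.columns)]
    tally["total"] = tally.sum(axis=1)
    tally.columns.name = None
    return tally


def read_id_mapping(path: PathLike) -> pd.DataFrame:
    """Read a `seq_id<TAB>species<TAB>gene_id[<TAB>clade]` mapping TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] == 3:
        df.columns = ["seq_id", "species", "gene_id"]
        df["clade"] = ""
    elif df.shape[1] == 4:
        df.columns = ["seq_id", "species", "gene_id", "clade"]
    else:
        raise HitParseError(f"{path}: expected 3 or 4 columns, got {df.shape[1]}")
    return df
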