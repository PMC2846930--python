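"""Alignment-column conservation statistics for protein families.

Given a multiple alignment, a set of reference rows (e.g. the nine CCT
monomers) and a target row (e.g. a thermosome or BBS sequence), these
routines count, over a categorized set of contact columns, how often the
target's residue type is among the types observed in the references — the
"matched (percent)" tally — plus a per-reference global similarity range and
majority/minority residue profiles for selected columns.

Residue equivalence is strict identity by default.  An optional 6-class
chemical partition (small / aliphatic / aromatic / polar / basic / acidic)
can be selected explicitly; no grouping is ever applied silently.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from io import StringIO
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "Alignment",
    "PositionSet",
    "SimilarityGroups",
    "ConservationTally",
    "ColumnProfile",
    "AlignmentError",
    "read_alignment",
    "conservation_tally",
    "global_similarity_range",
    "position_profile",
    "synth_alignment",
    "tally_table",
    "profile_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_LEGAL = set(AMINO_ACIDS) | {GAP}


class AlignmentError(ValueError):
    """Raised on malformed alignments or invalid column/id references."""


def _round1(x: float) -> float:
    """Round to 1 decimal, halves away from zero (93.95 -> 94.0)."""
    return math.floor(abs(x) * 10 + 0.5) / 10 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class Alignment:
    """Equal-length labelled residue rows over the 20 amino acids plus '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment has no rows")
        if len(self.ids) != len(set(self.ids)):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dup}")
        width = len(self.rows[0])
        if width < 1:
            raise AlignmentError("alignment has zero columns")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentError(
                    f"ragged alignment: row {sid!r} has length {len(row)}, expected {width}"
                )
            for pos, ch in enumerate(row, start=1):
                if ch not in _LEGAL:
                    raise AlignmentError(
                        f"illegal character {ch!r} in row {sid!r} at column {pos}"
                    )

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise AlignmentError(f"unknown sequence id: {sid!r}") from None


def read_alignment(source: str | os.PathLike | IO[str]) -> Alignment:
    """Read a FASTA alignment from text, a path, or an open handle.

    A string that starts with '>' is parsed as FASTA text; any other string
    is treated as a file path.  Residues are upper-cased before validation.
    """
    if isinstance(source, str) and source.lstrip().startswith(">"):
        handle: IO[str] = StringIO(source)
        records = list(SeqIO.parse(handle, "fasta"))
    elif hasattr(source, "read"):
        records = list(SeqIO.parse(source, "fasta"))
    else:
        records = list(SeqIO.parse(os.fspath(source), "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    return Alignment(
        ids=tuple(r.id for r in records),
        rows=tuple(str(r.seq).upper() for r in records),
    )


@dataclass(frozen=True)
class PositionSet:
    """Categorized 1-based alignment columns, e.g. monomer-monomer contacts.

    Categories are free-form strings (the contact tables use MM for all
    monomer-monomer contact columns, CMM for the conserved subset, RR for
    ring-ring contacts).
    """

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for col, cat in self.entries:
            if col < 1:
                raise AlignmentError(f"columns are 1-based; got {col}")
            if not cat:
                raise AlignmentError("empty category name")
            if (col, cat) in seen:
                raise AlignmentError(f"duplicate entry: column {col}, category {cat!r}")
            seen.add((col, cat))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, str]]) -> "PositionSet":
        return cls(entries=tuple((int(c), str(k)) for c, k in pairs))

    @classmethod
    def from_tsv(cls, text: str) -> "PositionSet":
        """Parse 'column<TAB>category' lines; '#' comments and a 'column' header are skipped."""
        pairs = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentError(f"line {lineno}: expected 'column<TAB>category'")
            if parts[0].lower() == "column":
                continue
            try:
                col = int(parts[0])
            except ValueError:
                raise AlignmentError(f"line {lineno}: non-integer column {parts[0]!r}") from None
            pairs.append((col, parts[1]))
        return cls.from_pairs(pairs)

    def by_category(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for col, cat in self.entries:
            out.setdefault(cat, []).append(col)
        return out


class SimilarityGroups:
    """A partition of the 20 amino acids into named equivalence classes."""

    def __init__(self, classes: Mapping[str, Iterable[str]]):
        self.classes = {name: frozenset(res) for name, res in classes.items()}
        self._of: dict[str, str] = {}
        for name, residues in self.classes.items():
            for r in residues:
                if r in self._of:
                    raise AlignmentError(f"residue {r!r} assigned to two classes")
                self._of[r] = name
        missing = set(AMINO_ACIDS) - set(self._of)
        extra = set(self._of) - set(AMINO_ACIDS)
        if missing or extra:
            raise AlignmentError(
                f"classes must partition the 20 amino acids (missing {sorted(missing)}, "
                f"extra {sorted(extra)})"
            )

    def of(self, residue: str) -> str:
        return self._of[residue]

    @classmethod
    def identity(cls) -> "SimilarityGroups":
        """Each residue is its own class (the default, strictest convention)."""
        return cls({aa: {aa} for aa in AMINO_ACIDS})

    @classmethod
    def chemical(cls) -> "SimilarityGroups":
        """Six physico-chemical classes; opt-in only."""
        return cls(
            {
                "small": "ACGPST",
                "aliphatic": "ILMV",
                "aromatic": "FWY",
                "polar": "NQ",
                "basic": "HKR",
                "acidic": "DE",
            }
        )

    @classmethod
    def named(cls, name: str) -> "SimilarityGroups":
        if name == "identity":
            return cls.identity()
        if name == "chemical":
            return cls.chemical()
        raise AlignmentError(f"unknown similarity grouping: {name!r}")


@dataclass(frozen=True)
class ConservationTally:
    """Matched/total column count for one position category."""

    category: str
    matched: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.matched <= self.total:
            raise AlignmentError("matched count out of range")

    @property
    def percent(self) -> float:
        return _round1(100.0 * self.matched / self.total)

    @property
    def formatted(self) -> str:
        return f"{self.matched} ({self.percent:.1f})"


def conservation_tally(
    aln: Alignment,
    reference_ids: Iterable[str],
    target_id: str,
    positions: PositionSet,
    groups: SimilarityGroups | None = None,
) -> dict[str, ConservationTally]:
    """Count, per category, the columns where the target's residue type occurs
    among the reference residue types.

    Reference gaps are ignored when forming the column's type set; a target
    gap never matches (a missing residue cannot conserve a contact).
    """
    groups = groups or SimilarityGroups.identity()
    refs = list(reference_ids)
    if not refs:
        raise AlignmentError("need at least one reference id")
    ref_rows = [aln.row(r) for r in refs]
    target = aln.row(target_id)
    by_cat = positions.by_category()
    if not by_cat:
        raise AlignmentError("position set is empty")
    out: dict[str, ConservationTally] = {}
    for cat, cols in by_cat.items():
        matched = 0
        for col in cols:
            if col > aln.width:
                raise AlignmentError(f"column {col} beyond alignment width {aln.width}")
            idx = col - 1
            ref_classes = {groups.of(row[idx]) for row in ref_rows if row[idx] != GAP}
            t = target[idx]
            if t != GAP and groups.of(t) in ref_classes:
                matched += 1
        out[cat] = ConservationTally(category=cat, matched=matched, total=len(cols))
    return out


def global_similarity_range(
    aln: Alignment,
    reference_ids: Iterable[str],
    target_id: str,
    groups: SimilarityGroups | None = None,
) -> tuple[float, float]:
    """Min and max per-reference similarity percent of the target.

    For each reference row individually, the percent of mutually non-gap
    columns where target and reference share a residue class; the (min, max)
    over references is the "Global" range.
    """
    groups = groups or SimilarityGroups.identity()
    refs = list(reference_ids)
    if not refs:
        raise AlignmentError("need at least one reference id")
    target = aln.row(target_id)
    percents = []
    for rid in refs:
        row = aln.row(rid)
        shared = 0
        same = 0
        for t, r in zip(target, row):
            if t == GAP or r == GAP:
                continue
            shared += 1
            if groups.of(t) == groups.of(r):
                same += 1
        if shared == 0:
            raise AlignmentError(
                f"reference {rid!r} shares no mutually non-gap column with {target_id!r}"
            )
        percents.append(_round1(100.0 * same / shared))
    return min(percents), max(percents)


@dataclass(frozen=True)
class ColumnProfile:
    """Majority/minority residue letters observed at one column."""

    column: int
    majority: str
    minority: str

    @property
    def formatted(self) -> str:
        return f"{self.majority} ({self.minority})" if self.minority else self.majority


def position_profile(
    aln: Alignment,
    ids: Iterable[str],
    columns: Sequence[int],
    minority_threshold: float = 0.5,
) -> dict[int, ColumnProfile]:
    """Per-column residue profiles over a set of rows.

    Letters whose frequency among non-gap residues reaches
    ``minority_threshold`` form the majority string (ordered by decreasing
    frequency, ties alphabetical); the remaining observed letters are the
    parenthesized minority, in the same order.
    """
    if not 0 < minority_threshold < 1:
        raise AlignmentError("minority_threshold must be in (0, 1)")
    id_list = list(ids)
    rows = [aln.row(i) for i in id_list]
    out: dict[int, ColumnProfile] = {}
    for col in columns:
        if not 1 <= col <= aln.width:
            raise AlignmentError(f"column {col} beyond alignment width {aln.width}")
        observed = [row[col - 1] for row in rows if row[col - 1] != GAP]
        if not observed:
            raise AlignmentError(f"column {col} is all-gap over the selected rows")
        counts: dict[str, int] = {}
        for ch in observed:
            counts[ch] = counts.get(ch, 0) + 1
        n = len(observed)
        ordered = sorted(counts, key=lambda ch: (-counts[ch], ch))
        majority = "".join(ch for ch in ordered if counts[ch] / n >= minority_threshold)
        minority = "".join(ch for ch in ordered if counts[ch] / n < minority_threshold)
        out[col] = ColumnProfile(column=col, majority=majority, minority=minority)
    return out


def synth_alignment(
    width: int,
    column_pools: Sequence[Iterable[str]],
    n_refs: int,
    seed: int,
    id_prefix: str = "ref",
) -> Alignment:
    """Deterministic synthetic alignment: each row draws uniformly from the
    per-column residue pools.  Stands in for curated reference alignments in
    tests; it has none of the covariation of real protein families.
    """
    if n_refs < 1:
        raise AlignmentError("n_refs must be at least 1")
    if len(column_pools) != width:
        raise AlignmentError(f"need {width} column pools, got {len(column_pools)}")
    pools = []
    for i, pool in enumerate(column_pools, start=1):
        letters = sorted(set(pool))
        if not letters:
            raise AlignmentError(f"empty residue pool for column {i}")
        bad = set(letters) - _LEGAL
        if bad:
            raise AlignmentError(f"illegal residues {sorted(bad)} in pool for column {i}")
        pools.append(letters)
    rng = np.random.default_rng(seed)
    rows = tuple(
        "".join(pool[int(rng.integers(len(pool)))] for pool in pools) for _ in range(n_refs)
    )
    ids = tuple(f"{id_prefix}{i + 1:02d}" for i in range(n_refs))
    return Alignment(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# TSV writers


def tally_table(tallies: Mapping[str, ConservationTally]) -> str:
    lines = ["category\tmatched\ttotal\tpercent\tformatted"]
    for cat in tallies:
        t = tallies[cat]
        lines.append(f"{cat}\t{t.matched}\t{t.total}\t{t.percent:.1f}\t{t.formatted}")
    return "\n".join(lines) + "\n"


def profile_table(profiles: Mapping[int, ColumnProfile]) -> str:
    lines = ["column\tmajority\tminority\tformatted"]
    for col in sorted(profiles):
        p = profiles[col]
        lines.append(f"{col}\t{p.majority}\t{p.minority}\t{p.formatted}")
    return "\n".join(lines) + "\n"
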