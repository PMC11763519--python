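"""Multiple-sequence-alignment handling and reference coordinate mapping.

Receptor cavity residues are specified in ungapped 1-based coordinates of a
reference receptor (e.g. F178 means phenylalanine at residue 178 of the
reference protein).  The screen works on alignment columns, so this module
validates alignments and maps reference residue positions to columns and
back.  All interfaces speak 1-based coordinates.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GAP",
    "AlignmentSet",
    "PositionMap",
    "Site",
    "SitePanel",
    "ColumnProfile",
    "read_alignment",
    "write_alignment",
    "build_position_map",
    "extract_column",
    "read_site_panel",
]

GAP = "-"
_VALID = set("ACDEFGHIKLMNPQRSTVWY") | {GAP, "X"}


@dataclass
class AlignmentSet:
    """Named aligned amino-acid sequences of equal width.

    Sequences are stored upper-case over the 20 standard residues, the gap
    character '-' and (flagged) the ambiguity code 'X'.
    """

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment is empty")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in number")
        seen = set()
        for i in self.ids:
            if not i:
                raise ValueError("empty sequence id")
            if i in seen:
                raise ValueError(f"duplicate sequence id {i!r}")
            seen.add(i)
        norm = []
        width = len(self.sequences[0])
        for rid, seq in zip(self.ids, self.sequences):
            s = seq.upper().replace(".", GAP)
            if len(s) != width:
                raise ValueError(
                    f"ragged alignment: record {rid!r} has width {len(s)}, expected {width}"
                )
            bad = sorted(set(s) - _VALID)
            if bad:
                raise ValueError(f"record {rid!r} contains invalid characters: {''.join(bad)}")
            norm.append(s)
        self.sequences = norm
        # (n, width) array of single characters for fast column slicing
        self._array = np.array([list(s) for s in norm])
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    @property
    def width(self) -> int:
        return self._array.shape[1]

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def has_ambiguous(self) -> bool:
        """True if any record contains an 'X' residue."""
        return bool((self._array == "X").any())

    def sequence(self, rid: str) -> str:
        try:
            return self.sequences[self._index[rid]]
        except KeyError:
            raise KeyError(f"sequence id {rid!r} not in alignment") from None

    def row_indices(self, ids) -> np.ndarray:
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise KeyError(f"ids not in alignment: {', '.join(map(repr, missing))}")
        return np.array([self._index[i] for i in ids], dtype=int)

    def column(self, col: int) -> np.ndarray:
        """Characters of 1-based column ``col`` for all records."""
        if not 1 <= col <= self.width:
            raise ValueError(f"column {col} out of range 1..{self.width}")
        return self._array[:, col - 1]


@dataclass(frozen=True)
class PositionMap:
    """Bijection between ungapped reference residue positions and columns."""

    reference_id: str
    pairs: tuple[tuple[int, int, str], ...]  # (position, column, residue), 1-based

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_pos", {p: (c, r) for p, c, r in self.pairs})
        object.__setattr__(self, "_by_col", {c: p for p, c, _ in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)

    def column_of(self, position: int) -> int:
        try:
            return self._by_pos[position][0]
        except KeyError:
            raise ValueError(
                f"position {position} outside reference {self.reference_id!r} "
                f"(ungapped length {len(self.pairs)})"
            ) from None

    def residue_at(self, position: int) -> str:
        return self._by_pos[position][1]

    def position_of(self, column: int) -> int:
        try:
            return self._by_col[column]
        except KeyError:
            raise ValueError(f"column {column} is a gap in reference {self.reference_id!r}") from None


@dataclass(frozen=True)
class Site:
    """One cavity position in reference coordinates, e.g. (178, 'F', 'ECL2')."""

    position: int
    expected_residue: str | None = None
    label: str = ""


@dataclass
class SitePanel:
    sites: list[Site] = field(default_factory=list)

    def __post_init__(self) -> None:
        pos = [s.position for s in self.sites]
        if any(p < 1 for p in pos):
            raise ValueError("site positions must be >= 1")
        dup = [p for p, n in collections.Counter(pos).items() if n > 1]
        if dup:
            raise ValueError(f"duplicate site positions: {dup}")

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def validate_against(self, posmap: PositionMap) -> None:
        """Check stated expected residues against the mapped reference."""
        for s in self.sites:
            actual = posmap.residue_at(s.position) if s.position <= len(posmap) else None
            if actual is None:
                raise ValueError(f"site {s.position} beyond reference length {len(posmap)}")
            if s.expected_residue and actual != s.expected_residue.upper():
                raise ValueError(
                    f"site {s.position}: expected residue {s.expected_residue!r} "
                    f"but reference has {actual!r}"
                )


@dataclass(frozen=True)
class ColumnProfile:
    """Residue multiset of one column for a record subset."""

    counts: collections.Counter
    n_gaps: int
    n_ambiguous: int

    @property
    def n_usable(self) -> int:
        return sum(self.counts.values())


def read_alignment(path, fmt: str = "fasta") -> AlignmentSet:
    """Read a FASTA or Clustal alignment into an :class:`AlignmentSet`.

    Sequence case is normalized to upper and '.' gaps to '-'.  Ragged input,
    duplicate ids and empty files raise ``ValueError``.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}; use 'fasta' or 'clustal'")
    path = Path(path)
    if fmt == "fasta":
        # read records individually so ragged input gives a clear error
        from Bio import SeqIO

        recs = list(SeqIO.parse(str(path), "fasta"))
    else:
        recs = list(AlignIO.read(str(path), "clustal"))
    if not recs:
        raise ValueError(f"no sequences found in {path}")
    return AlignmentSet([r.id for r in recs], [str(r.seq) for r in recs])


def write_alignment(aln: AlignmentSet, path, fmt: str = "fasta") -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.sequences)]
    )
    AlignIO.write(msa, str(path), fmt)


def build_position_map(aln: AlignmentSet, reference_id: str) -> PositionMap:
    """Map each non-gap reference residue to its alignment column (1-based)."""
    seq = aln.sequence(reference_id)
    pairs = []
    pos = 0
    for col, ch in enumerate(seq, start=1):
        if ch != GAP:
            pos += 1
            pairs.append((pos, col, ch))
    if not pairs:
        raise ValueError(f"reference {reference_id!r} is all gaps (zero ungapped length)")
    return PositionMap(reference_id, tuple(pairs))


def extract_column(aln: AlignmentSet, column: int, ids=None) -> ColumnProfile:
    """Residue multiset at 1-based ``column`` for ``ids`` (default: all records).

    Gaps and 'X' are separated out and counted, not included in the multiset.
    """
    chars = aln.column(column)
    if ids is not None:
        chars = chars[aln.row_indices(list(ids))]
    counts = collections.Counter()
    gaps = ambig = 0
    for ch in chars:
        if ch == GAP:
            gaps += 1
        elif ch == "X":
            ambig += 1
        else:
            counts[ch] += 1
    return ColumnProfile(counts, gaps, ambig)


def read_site_panel(path) -> SitePanel:
    """Read a cavity-site panel from a 1-3 column TSV.

    Columns: position (1-based integer), optional expected residue, optional
    free-text label.  A header line is tolerated if the first field is not an
    integer.
    """
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                position = int(fields[0])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ValueError(f"{path}:{lineno}: position {fields[0]!r} is not an integer")
            residue = fields[1].strip().upper() or None if len(fields) > 1 else None
            label = fields[2].strip() if len(fields) > 2 else ""
            sites.append(Site(position, residue, label))
    if not sites:
        raise ValueError(f"no sites found in {path}")
    return SitePanel(sites)
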