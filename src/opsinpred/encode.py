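"""Alignment statistics, one-hot encoding, and reference coordinate mapping.

The regression features are indicator variables: one per (alignment column,
residue observed at that column in training).  Two rules matter downstream:

* invariant (zero-entropy) columns carry no information about phenotype
  variation and are dropped before encoding;
* a residue not seen at a column in training encodes as all-zero in that
  column's block — the model cannot distinguish between different unseen
  residues.  Gaps encode the same way by default.

Column conservation is summarised as Shannon entropy in bits (gaps excluded
from the frequencies), and "relative entropy" is each column's entropy divided
by the maximum column entropy in the alignment.

``PositionMap`` translates alignment columns into the community's
bovine-rhodopsin reference numbering, with ``<pos>+k`` insertion codes where
the reference row is gapped, and labels each column with its transmembrane
domain (TMD1..TMD7) or "loop".
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Rows of equal-length aligned amino-acid strings keyed by accession."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("row ids are not unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls(ids=[r.id for r in recs], rows=[str(r.seq).upper() for r in recs])

    @classmethod
    def from_pairs(cls, pairs) -> "Alignment":
        ids, rows = zip(*pairs) if pairs else ((), ())
        return cls(ids=list(ids), rows=list(rows))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, accession: str) -> str:
        try:
            return self.rows[self.ids.index(accession)]
        except ValueError:
            raise AlignmentError(f"no row {accession!r} in alignment") from None

    def column(self, j: int) -> str:
        """Column ``j`` (0-based) as a string, one character per row."""
        return "".join(r[j] for r in self.rows)

    def select_columns(self, cols) -> "Alignment":
        cols = list(cols)
        return Alignment(
            ids=list(self.ids),
            rows=["".join(r[j] for j in cols) for r in self.rows],
        )

    def subset_rows(self, ids) -> "Alignment":
        ids = list(ids)
        return Alignment(ids=ids, rows=[self.row(i) for i in ids])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")


def alignment_from_records(records) -> Alignment:
    """Build an Alignment from dataset records whose sequences are already in
    a common column space (equal lengths, e.g. indel-free synthetic data or
    mutants of aligned parents)."""
    ids = [r.accession for r in records]
    rows = [r.aa_seq for r in records]
    lengths = {len(s) for s in rows}
    if len(lengths) > 1:
        raise AlignmentError(
            f"records have unequal sequence lengths {sorted(lengths)}; align them first"
        )
    return Alignment(ids=ids, rows=rows)


@dataclass(frozen=True)
class ColumnProfile:
    column: int  # 0-based alignment column
    frequencies: dict  # residue -> frequency (gaps excluded)
    gap_fraction: float
    entropy_bits: float
    relative_entropy: float
    all_gap: bool = False


def column_entropy(al: Alignment) -> list[ColumnProfile]:
    """Per-column residue frequencies and Shannon entropy (bits).

    Gaps are excluded from the frequency counts.  All-gap columns have
    undefined entropy: they are flagged and excluded from the relative
    scaling, which divides each column's entropy by the alignment's maximum.
    """
    if len(al) == 0:
        raise AlignmentError("empty alignment")
    raw = []
    for j in range(al.n_columns):
        col = al.column(j)
        n_gap = col.count(GAP)
        residues = [c for c in col if c != GAP]
        if not residues:
            raw.append((j, {}, 1.0, float("nan"), True))
            continue
        counts = Counter(residues)
        total = len(residues)
        freqs = {res: c / total for res, c in sorted(counts.items())}
        h = -sum(p * math.log2(p) for p in freqs.values())
        raw.append((j, freqs, n_gap / len(col), h, False))
    finite = [h for *_, h, all_gap in raw if not all_gap]
    h_max = max(finite) if finite else 0.0
    profiles = []
    for j, freqs, gap_frac, h, all_gap in raw:
        rel = float("nan") if all_gap else (h / h_max if h_max > 0 else 0.0)
        profiles.append(
            ColumnProfile(
                column=j,
                frequencies=freqs,
                gap_fraction=gap_frac,
                entropy_bits=h,
                relative_entropy=rel,
                all_gap=all_gap,
            )
        )
    return profiles


def _variant_columns(al: Alignment) -> list[int]:
    out = []
    for j in range(al.n_columns):
        residues = {c for c in al.column(j) if c != GAP}
        if len(residues) >= 2:
            out.append(j)
    return out


def drop_invariant_columns(al: Alignment) -> tuple[Alignment, list[int]]:
    """Remove zero-entropy columns (judged on non-gap residues).

    Returns the reduced alignment and the 0-based indices of dropped columns.
    """
    keep = _variant_columns(al)
    dropped = [j for j in range(al.n_columns) if j not in set(keep)]
    if not keep:
        warnings.warn("all columns invariant; encoded alignment is empty", stacklevel=2)
    return al.select_columns(keep), dropped


def trim_columns(al: Alignment, max_gap_fraction: float) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    A deliberately simple stand-in for block-based alignment cleaning: it
    removes heavily gapped columns only, with no flank or conservation logic.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    n = len(al)
    keep, removed = [], []
    for j in range(al.n_columns):
        gap_frac = al.column(j).count(GAP) / n
        (keep if gap_frac <= max_gap_fraction else removed).append(j)
    return al.select_columns(keep), removed


@dataclass
class EncodedMatrix:
    """One-hot features: samples x (column, residue) indicators."""

    X: pd.DataFrame  # index = sample ids, columns = "<col>:<residue>" labels
    #: per 0-based source column: residues with an indicator, in label order
    vocabulary: dict[int, tuple[str, ...]]

    @property
    def feature_labels(self) -> list[str]:
        return list(self.X.columns)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)


def one_hot(al: Alignment, vocabulary: dict[int, tuple[str, ...]] | None = None) -> EncodedMatrix:
    """One-hot encode an alignment.

    Training mode (``vocabulary=None``) builds the vocabulary from the
    alignment itself, skipping columns with fewer than two distinct non-gap
    residues (zero-entropy columns contribute no features).  Prediction mode
    reuses a training vocabulary: residues absent from a column's vocabulary
    — and gaps — encode as all-zero in that column's block, so every unseen
    residue looks the same to the model.
    """
    if vocabulary is None:
        vocabulary = {}
        for j in _variant_columns(al):
            residues = sorted({c for c in al.column(j) if c != GAP})
            vocabulary[j] = tuple(residues)
    else:
        max_col = max(vocabulary, default=-1)
        if max_col >= al.n_columns:
            raise AlignmentError(
                f"vocabulary refers to column {max_col} but alignment has "
                f"{al.n_columns} columns"
            )
    labels = [f"{j + 1}:{res}" for j in sorted(vocabulary) for res in vocabulary[j]]
    data = np.zeros((len(al), len(labels)))
    pos = {lab: k for k, lab in enumerate(labels)}
    for i, row in enumerate(al.rows):
        for j in sorted(vocabulary):
            lab = f"{j + 1}:{row[j]}"
            if lab in pos:
                data[i, pos[lab]] = 1.0
    X = pd.DataFrame(data, index=list(al.ids), columns=labels)
    return EncodedMatrix(X=X, vocabulary=dict(vocabulary))


@dataclass
class PositionMap:
    """Alignment column -> (reference position or insertion code, TMD label)."""

    reference_id: str
    ref_positions: list[str]  # per column: "40" or "40+2" insertion codes
    ref_residues: list[str]  # reference row characters per column
    tmd_labels: list[str]  # per column: "TMD1".."TMD7" or "loop"

    def reference_position(self, column: int) -> str:
        """Reference coordinate of a 0-based alignment column."""
        return self.ref_positions[column]

    def column_of_reference(self, ref_pos: int) -> int:
        """0-based alignment column carrying integer reference position."""
        try:
            return self.ref_positions.index(str(ref_pos))
        except ValueError:
            raise AlignmentError(f"reference position {ref_pos} not in map") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": [i + 1 for i in range(len(self.ref_positions))],
                "ref_pos": self.ref_positions,
                "ref_residue": self.ref_residues,
                "tmd": self.tmd_labels,
            }
        )


def map_to_reference(
    al: Alignment, reference_row: str, tmd_table: dict[int, tuple[int, int]] | None = None
) -> PositionMap:
    """Assign reference numbering and TMD labels to every alignment column.

    Columns where the reference is gapped get ``"<prevPos>+k"`` insertion
    codes (``"0+k"`` before the first reference residue).  TMD labels come
    from closed 1-based intervals in reference coordinates; insertion-coded
    columns inherit no TMD ("loop").
    """
    row = al.row(reference_row)
    tmd_table = tmd_table or {}
    ref_positions: list[str] = []
    tmd_labels: list[str] = []
    pos = 0
    insert = 0
    for c in row:
        if c == GAP:
            insert += 1
            ref_positions.append(f"{pos}+{insert}")
            tmd_labels.append("loop")
        else:
            pos += 1
            insert = 0
            ref_positions.append(str(pos))
            label = "loop"
            for d, (start, end) in tmd_table.items():
                if start <= pos <= end:
                    label = f"TMD{d}"
                    break
            tmd_labels.append(label)
    return PositionMap(
        reference_id=reference_row,
        ref_positions=ref_positions,
        ref_residues=list(row),
        tmd_labels=tmd_labels,
    )
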