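"""Mutation-notation parsing and mutant/chimera sequence reconstruction.

Point mutants are written in the field's compact notation: ``D83N`` means the
wild-type residue D at position 83 is replaced by N; multiple edits are joined
with underscores (``D83N_A292S``).  Positions are 1-based indices into the
ungapped native parent sequence unless the spec is flagged as being in
reference (bovine-rhodopsin) coordinates, in which case a
:class:`~opsinpred.encode.PositionMap` translates them.

Chimeras swap whole transmembrane domains (TMD1–TMD7) from a donor sequence
into a parent, working in alignment column space.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqdata import AA_ALPHABET

_TOKEN_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class MutationError(ValueError):
    """Raised for malformed notation or edits inconsistent with a sequence."""


@dataclass(frozen=True)
class Edit:
    wt_residue: str
    position: int  # 1-based
    new_residue: str

    def __str__(self) -> str:
        return f"{self.wt_residue}{self.position}{self.new_residue}"


@dataclass(frozen=True)
class MutationSpec:
    """An ordered, position-disjoint list of point edits."""

    edits: tuple[Edit, ...]
    frame: str = "native"  # or "reference"

    def __post_init__(self) -> None:
        if self.frame not in ("native", "reference"):
            raise MutationError(f"unknown frame {self.frame!r}")
        positions = [e.position for e in self.edits]
        if len(set(positions)) != len(positions):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise MutationError(f"multiple edits at the same position(s): {dupes}")
        # normalize: ascending positions
        object.__setattr__(self, "edits", tuple(sorted(self.edits, key=lambda e: e.position)))
        for e in self.edits:
            if e.wt_residue == e.new_residue:
                raise MutationError(f"edit {e}: wild-type and new residue are identical")
            for res in (e.wt_residue, e.new_residue):
                if res not in AA_ALPHABET:
                    raise MutationError(f"edit {e}: unknown residue {res!r}")
            if e.position < 1:
                raise MutationError(f"edit {e}: positions are 1-based and positive")

    def __str__(self) -> str:
        return "_".join(str(e) for e in self.edits)


def parse_mutation_notation(s: str, frame: str = "native") -> MutationSpec:
    """Parse ``"D83N_A292S"``-style notation into a :class:`MutationSpec`."""
    if not s:
        raise MutationError("empty mutation notation")
    edits = []
    for token in s.split("_"):
        m = _TOKEN_RE.match(token)
        if not m:
            raise MutationError(f"malformed mutation token {token!r} in {s!r}")
        wt, pos, new = m.group(1), int(m.group(2)), m.group(3)
        if pos == 0:
            raise MutationError(f"malformed mutation token {token!r}: position must be >= 1")
        edits.append(Edit(wt, pos, new))
    return MutationSpec(edits=tuple(edits), frame=frame)


def apply_mutations(seq: str, spec: MutationSpec) -> str:
    """Apply point edits to an ungapped sequence, validating wild-type residues.

    A mismatch between an edit's stated wild-type residue and the sequence is
    an error: it almost always means the notation is in a different coordinate
    frame (translate reference-frame specs through a PositionMap first).
    """
    if spec.frame != "native":
        raise MutationError(
            "spec is in reference coordinates; translate to native positions first"
        )
    chars = list(seq)
    for e in spec.edits:
        if e.position > len(chars):
            raise MutationError(
                f"edit {e}: position beyond sequence length {len(chars)}"
            )
        found = chars[e.position - 1]
        if found != e.wt_residue:
            raise MutationError(
                f"edit {e}: sequence has {found!r} at position {e.position}, "
                f"expected {e.wt_residue!r}"
            )
        chars[e.position - 1] = e.new_residue
    return "".join(chars)


def diff_to_notation(wt: str, mut: str) -> str:
    """Inverse of :func:`apply_mutations`: underscore-joined tokens, ascending."""
    if len(wt) != len(mut):
        raise MutationError(
            f"cannot diff sequences of different lengths ({len(wt)} vs {len(mut)})"
        )
    tokens = [
        f"{a}{i}{b}" for i, (a, b) in enumerate(zip(wt, mut), start=1) if a != b
    ]
    return "_".join(tokens)


@dataclass(frozen=True)
class ChimeraSpec:
    """Swap the given TMDs of the parent for the donor's, in reference coords."""

    parent_accession: str
    donor_accession: str
    domains: frozenset[int]  # TMD indices 1..7
    boundary_table: dict[int, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.domains:
            raise MutationError("chimera spec selects no domains")
        bad = sorted(d for d in self.domains if not 1 <= d <= 7)
        if bad:
            raise MutationError(f"TMD indices out of range 1..7: {bad}")
        ivals = sorted(self.boundary_table.values())
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if e1 >= s2:
                raise MutationError("TMD boundaries overlap or are unordered")


def read_tmd_table(path) -> dict[int, tuple[int, int]]:
    """Read a key-value TMD boundary file (``TMD1=37-61`` per line, 1-based
    closed intervals in reference coordinates; '#' comments allowed)."""
    table: dict[int, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            m = re.match(r"^TMD(\d)$", key.strip())
            iv = re.match(r"^(\d+)\s*-\s*(\d+)$", val.strip())
            if not (m and iv):
                raise MutationError(f"malformed TMD table line: {line!r}")
            start, end = int(iv.group(1)), int(iv.group(2))
            if start > end:
                raise MutationError(f"TMD interval reversed: {line!r}")
            table[int(m.group(1))] = (start, end)
    return table


def build_chimera(parent_row: str, donor_row: str, spec: ChimeraSpec, pmap) -> str:
    """Build an ungapped chimeric sequence from two aligned rows.

    ``pmap`` is a :class:`~opsinpred.encode.PositionMap` over the same
    alignment; its TMD labels decide which columns take donor residues.
    """
    if len(parent_row) != len(donor_row):
        raise MutationError("parent and donor rows are not from the same alignment")
    wanted = {f"TMD{d}" for d in spec.domains}
    labels = pmap.tmd_labels
    if len(labels) != len(parent_row):
        raise MutationError("PositionMap does not cover this alignment")
    for d in sorted(spec.domains):
        cols = [i for i, lab in enumerate(labels) if lab == f"TMD{d}"]
        if cols and all(donor_row[i] == "-" for i in cols):
            raise MutationError(f"donor is entirely gapped in TMD{d}")
    out = [
        donor_row[i] if labels[i] in wanted else parent_row[i]
        for i in range(len(parent_row))
    ]
    return "".join(c for c in out if c != "-")
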