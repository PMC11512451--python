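"""Genotype–phenotype dataset model, I/O, deduplication and subset filters.

An opsin genotype–phenotype dataset pairs amino-acid sequences with the
wavelength of maximal absorbance (``lambda_max``, nm) measured by heterologous
expression, plus the taxonomic and experimental metadata needed to slice the
data into analysis subsets (vertebrate/invertebrate, wild-type-only, per gene
family, ...).

Sequences live in a FASTA file keyed by accession; everything else lives in a
tab-separated metadata table with one row per record.  ``load_dataset`` joins
the two on accession.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: metadata TSV columns, in canonical order ("class" maps to ``class_name``)
META_COLUMNS = [
    "accession",
    "species",
    "phylum",
    "class",
    "gene_family",
    "lambda_max",
    "record_type",
    "mutation_notation",
    "parent_accession",
    "source_ref",
]

RECORD_TYPES = ("wt", "mutant", "chimera")


class DatasetError(ValueError):
    """Raised on malformed or inconsistent genotype–phenotype data."""


@dataclass(frozen=True)
class OpsinRecord:
    """One genotype–phenotype row: a sequence and its measured lambda_max."""

    accession: str
    species: str
    phylum: str
    class_name: str
    gene_family: str
    aa_seq: str
    lambda_max: float
    record_type: str = "wt"
    mutation_notation: str | None = None
    parent_accession: str | None = None
    dna_seq: str | None = None
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise DatasetError(f"{self.accession}: empty amino-acid sequence")
        bad = set(self.aa_seq) - AA_ALPHABET
        if bad:
            raise DatasetError(
                f"{self.accession}: non-amino-acid characters {sorted(bad)} "
                "(sequences must be ungapped, 20-letter alphabet)"
            )
        if not self.lambda_max > 0:
            raise DatasetError(f"{self.accession}: lambda_max must be positive")
        if self.record_type not in RECORD_TYPES:
            raise DatasetError(
                f"{self.accession}: record_type {self.record_type!r} not in {RECORD_TYPES}"
            )
        if self.record_type == "mutant" and not (
            self.mutation_notation and self.parent_accession
        ):
            raise DatasetError(
                f"{self.accession}: mutant records need mutation_notation and parent_accession"
            )
        if self.record_type == "chimera" and not self.parent_accession:
            raise DatasetError(
                f"{self.accession}: chimera records need parent_accession"
            )


@dataclass
class Dataset:
    """An ordered, accession-unique collection of :class:`OpsinRecord`."""

    name: str = "dataset"
    version: str = "1.0"
    records: list[OpsinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.accession in seen:
                raise DatasetError(f"duplicate accession {r.accession!r}")
            seen.add(r.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, accession: str) -> OpsinRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)

    def __contains__(self, accession: str) -> bool:
        return any(r.accession == accession for r in self.records)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def lambda_vector(self) -> pd.Series:
        return pd.Series(
            [r.lambda_max for r in self.records], index=self.accessions, name="lambda_max"
        )

    def with_records(self, records: Sequence[OpsinRecord], suffix: str = "") -> "Dataset":
        name = f"{self.name}_{suffix}" if suffix else self.name
        return Dataset(name=name, version=self.version, records=list(records))


def _parse_lambda(value, row_number: int) -> float:
    try:
        lam = float(value)
    except (TypeError, ValueError):
        raise DatasetError(
            f"metadata row {row_number}: malformed lambda_max {value!r}"
        ) from None
    if not lam > 0 or lam != lam:
        raise DatasetError(f"metadata row {row_number}: lambda_max must be positive, got {value!r}")
    return lam


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and value != value):
        return None
    s = str(value).strip()
    return s or None


def load_dataset(seq_path, meta_path, name: str = "dataset", version: str = "1.0") -> Dataset:
    """Join a FASTA file and a metadata TSV into a :class:`Dataset`.

    FASTA ids must be a superset of the metadata accessions; a metadata row
    without a sequence is a hard error naming every offending accession.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(seq_path), "fasta")}
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"accession", "species", "phylum", "class", "gene_family", "lambda_max", "record_type"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise DatasetError(f"metadata missing columns: {sorted(missing_cols)}")

    missing = [a for a in meta["accession"] if a not in seqs]
    if missing:
        raise DatasetError(f"no sequence in FASTA for accessions: {missing}")

    records = []
    for i, row in enumerate(meta.to_dict("records"), start=2):  # header is line 1
        acc = row["accession"]
        records.append(
            OpsinRecord(
                accession=acc,
                species=row["species"],
                phylum=row["phylum"],
                class_name=row["class"],
                gene_family=row["gene_family"],
                aa_seq=seqs[acc],
                lambda_max=_parse_lambda(row["lambda_max"], i),
                record_type=row["record_type"],
                mutation_notation=_opt(row.get("mutation_notation")),
                parent_accession=_opt(row.get("parent_accession")),
                source_ref=str(row.get("source_ref") or "") if _opt(row.get("source_ref")) else "",
            )
        )
    return Dataset(name=name, version=version, records=records)


def write_dataset(ds: Dataset, seq_path, meta_path) -> None:
    """Write FASTA + metadata TSV; byte-stable given an identical dataset."""
    seq_records = [
        SeqRecord(Seq(r.aa_seq), id=r.accession, description="") for r in ds.records
    ]
    with open(seq_path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")
    rows = []
    for r in ds.records:
        rows.append(
            {
                "accession": r.accession,
                "species": r.species,
                "phylum": r.phylum,
                "class": r.class_name,
                "gene_family": r.gene_family,
                "lambda_max": repr(r.lambda_max),
                "record_type": r.record_type,
                "mutation_notation": r.mutation_notation or "",
                "parent_accession": r.parent_accession or "",
                "source_ref": r.source_ref,
            }
        )
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(meta_path, sep="\t", index=False)


@dataclass
class DedupResult:
    dataset: Dataset
    #: one row per retained record that absorbed duplicates
    report: pd.DataFrame


def deduplicate(ds: Dataset, tol_nm: float = 3.0) -> DedupResult:
    """Collapse records with identical amino-acid sequences.

    Duplicates whose lambda_max values span at most ``tol_nm`` are merged into
    the first-seen record with the mean lambda_max; a wider spread is a
    curation conflict and raises, listing the accessions involved.
    """
    if tol_nm < 0:
        raise ValueError("tol_nm must be >= 0")
    groups: dict[str, list[OpsinRecord]] = {}
    order: list[str] = []
    for r in ds.records:
        if r.aa_seq not in groups:
            order.append(r.aa_seq)
        groups.setdefault(r.aa_seq, []).append(r)

    kept: list[OpsinRecord] = []
    report_rows = []
    for seq in order:
        members = groups[seq]
        if len(members) == 1:
            kept.append(members[0])
            continue
        lams = [m.lambda_max for m in members]
        spread = max(lams) - min(lams)
        accs = [m.accession for m in members]
        if spread > tol_nm:
            raise DatasetError(
                f"identical sequences with lambda_max spread {spread:.3g} nm > "
                f"tolerance {tol_nm} nm: {accs}"
            )
        mean_lam = sum(lams) / len(lams)
        kept.append(replace(members[0], lambda_max=mean_lam))
        report_rows.append(
            {
                "retained": members[0].accession,
                "collapsed": ",".join(accs[1:]),
                "lambda_max": mean_lam,
                "spread_nm": spread,
            }
        )
    report = pd.DataFrame(report_rows, columns=["retained", "collapsed", "lambda_max", "spread_nm"])
    return DedupResult(dataset=ds.with_records(kept), report=report)


# ---------------------------------------------------------------------------
# subset rules

Rule = Callable[[OpsinRecord], bool]

#: the analysis convention: phylum Chordata counts as vertebrate
VERTEBRATE_PHYLUM = "Chordata"

_NAMED_RULES: dict[str, Rule] = {
    "vertebrate": lambda r: r.phylum == VERTEBRATE_PHYLUM,
    "invertebrate": lambda r: r.phylum != VERTEBRATE_PHYLUM,
    "wild_type_only": lambda r: r.record_type == "wt",
    "mutants_only": lambda r: r.record_type in ("mutant", "chimera"),
}


def gene_family(families: Iterable[str]) -> Rule:
    fams = set(families)
    return lambda r: r.gene_family in fams


def _as_rule(rule) -> Rule:
    if callable(rule):
        return rule
    if isinstance(rule, str):
        try:
            return _NAMED_RULES[rule]
        except KeyError:
            raise ValueError(
                f"unknown subset rule {rule!r}; named rules: {sorted(_NAMED_RULES)}"
            ) from None
    # iterable of rules = conjunction
    rules = [_as_rule(r) for r in rule]
    return lambda rec: all(f(rec) for f in rules)


def subset(ds: Dataset, rule, suffix: str | None = None) -> Dataset:
    """Filter a dataset by a named rule, predicate, or conjunction of both."""
    pred = _as_rule(rule)
    kept = [r for r in ds.records if pred(r)]
    if not kept:
        warnings.warn(f"subset rule {rule!r} matched no records in {ds.name}", stacklevel=2)
    if suffix is None:
        suffix = rule if isinstance(rule, str) else "subset"
    return ds.with_records(kept, suffix=suffix)
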