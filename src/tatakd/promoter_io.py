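"""Reading, validating, filtering and writing promoter cohorts.

A cohort is an ordered collection of 90 bp proximal-promoter sequences,
each labelled with the species it comes from, the gene family it belongs
to (globulin, albumin or beta-amylase — the three wheat seed-storage /
starch-metabolism families analysed here) and whether the species is a
food or a non-food plant.

Conventions
-----------
* Sequences are stored 5'->3' on the annotated strand, position 90 being
  adjacent to the transcription start site.  Coordinates are 1-based and
  inclusive.
* Input sequences are uppercased and RNA-style ``U`` is mapped to ``T``.
  IUPAC ambiguity codes (R, Y, W, S, K, M, B, D, H, V, N) are accepted at
  validation time but are removed by :func:`filter_ambiguous` before any
  affinity scoring.  Any other character is a hard validation error.
* Metadata travels alongside the FASTA as a tab-separated table with the
  header ``record_id  species  gene_family  group``; ``#``-prefixed lines
  are comments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROMOTER_LENGTH = 90

_UNAMBIGUOUS = frozenset("ACGT")
_IUPAC_DNA = frozenset("ACGTRYWSKMBDHVN")

PathLike = Union[str, Path]


class GeneFamily(str, Enum):
    """The three gene families: wheat-allergen homologue classes."""

    GLOBULIN = "globulin"
    ALBUMIN = "albumin"
    BETA_AMYLASE = "beta_amylase"


class PlantGroup(str, Enum):
    """Food vs non-food plant species."""

    FOOD = "food"
    NON_FOOD = "non_food"


class ValidationError(ValueError):
    """A sequence violates the 90 bp / IUPAC-DNA contract."""


class SchemaError(ValueError):
    """The FASTA/metadata pair violates the cohort schema."""


@dataclass(frozen=True)
class PromoterRecord:
    """One 90 bp proximal promoter with its cohort labels."""

    record_id: str
    species: str
    gene_family: GeneFamily
    group: PlantGroup
    sequence: str

    def is_unambiguous(self) -> bool:
        return set(self.sequence) <= _UNAMBIGUOUS


@dataclass
class Cohort:
    """Ordered, duplicate-free collection of promoter records."""

    records: list[PromoterRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate record_id(s) in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]


def normalize_sequence(raw: str, record_id: str) -> str:
    """Uppercase, map U->T, enforce length 90 and the IUPAC DNA alphabet."""
    seq = raw.strip().upper().replace("U", "T")
    if len(seq) != PROMOTER_LENGTH:
        raise ValidationError(
            f"record {record_id!r}: sequence length {len(seq)} != {PROMOTER_LENGTH}"
        )
    bad = set(seq) - _IUPAC_DNA
    if bad:
        raise ValidationError(
            f"record {record_id!r}: non-IUPAC character(s) {sorted(bad)}"
        )
    return seq


def _read_metadata(metadata_source: PathLike | io.TextIOBase) -> pd.DataFrame:
    df = pd.read_csv(metadata_source, sep="\t", comment="#", dtype=str)
    required = ["record_id", "species", "gene_family", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata is missing column(s): {missing}")
    return df


def read_fasta_with_metadata(
    fasta_source: PathLike | io.TextIOBase,
    metadata_source: PathLike | io.TextIOBase,
    provenance: str = "",
) -> Cohort:
    """Read a FASTA + metadata TSV pair into a validated :class:`Cohort`.

    The two sources must describe exactly the same set of record ids;
    a record present in only one of them is a schema error.  FASTA
    record order defines cohort order.
    """
    seqs: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(fasta_source, "fasta"):
        if rec.id in seqs:
            raise SchemaError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = normalize_sequence(str(rec.seq), rec.id)
        order.append(rec.id)

    meta = _read_metadata(metadata_source)
    if meta["record_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["record_id"].duplicated(), "record_id"])
        raise SchemaError(f"duplicate metadata record_id(s): {dupes}")
    meta_ids = set(meta["record_id"])
    fasta_only = sorted(set(order) - meta_ids)
    meta_only = sorted(meta_ids - set(order))
    if fasta_only or meta_only:
        raise SchemaError(
            f"FASTA/metadata mismatch: only in FASTA {fasta_only}, "
            f"only in metadata {meta_only}"
        )

    rows = meta.set_index("record_id")
    records = []
    for rid in order:
        row = rows.loc[rid]
        try:
            fam = GeneFamily(row["gene_family"])
        except ValueError:
            raise SchemaError(
                f"record {rid!r}: unknown gene_family {row['gene_family']!r}"
            ) from None
        try:
            grp = PlantGroup(row["group"])
        except ValueError:
            raise SchemaError(
                f"record {rid!r}: unknown group {row['group']!r}"
            ) from None
        records.append(
            PromoterRecord(
                record_id=rid,
                species=str(row["species"]),
                gene_family=fam,
                group=grp,
                sequence=seqs[rid],
            )
        )
    return Cohort(records=records, provenance=provenance)


def filter_ambiguous(cohort: Cohort) -> tuple[Cohort, list[str]]:
    """Partition a cohort into ACGT-only records and removed record ids.

    Promoters containing any IUPAC ambiguity code (w, s, r, y, k, m, b,
    d, h, v, n) are excluded from affinity analysis, mirroring the
    exclusion of sequences with unknown nucleotides from the study
    cohorts.  Idempotent; input order preserved.
    """
    kept, removed = [], []
    for rec in cohort:
        (kept if rec.is_unambiguous() else removed).append(rec)
    return (
        Cohort(records=kept, provenance=cohort.provenance),
        [r.record_id for r in removed],
    )


def partition(cohort: Cohort, by: str) -> dict[str, Cohort]:
    """Split a cohort by ``gene_family``, ``group`` or ``species``.

    Returns a dict keyed by label value (sorted), each sub-cohort
    preserving input order.  The sub-cohorts partition the input.
    """
    if by not in ("gene_family", "group", "species"):
        raise ValueError(f"cannot partition by {by!r}")
    buckets: dict[str, list[PromoterRecord]] = {}
    for rec in cohort:
        key = getattr(rec, by)
        key = key.value if isinstance(key, Enum) else key
        buckets.setdefault(key, []).append(rec)
    return {
        label: Cohort(records=recs, provenance=cohort.provenance)
        for label, recs in sorted(buckets.items())
    }


def write_cohort(
    cohort: Cohort,
    fasta_sink: PathLike | io.TextIOBase,
    metadata_sink: PathLike | io.TextIOBase,
) -> None:
    """Write a cohort as an unwrapped FASTA plus metadata TSV.

    ``read_fasta_with_metadata`` on the outputs reproduces the cohort
    exactly; writing twice produces byte-identical files.
    """
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in cohort
    ]
    writer = SeqIO.FastaIO.FastaWriter(fasta_sink, wrap=None)
    writer.write_file(seq_records)
    meta = pd.DataFrame(
        {
            "record_id": [r.record_id for r in cohort],
            "species": [r.species for r in cohort],
            "gene_family": [r.gene_family.value for r in cohort],
            "group": [r.group.value for r in cohort],
        }
    )
    meta.to_csv(metadata_sink, sep="\t", index=False)


def concat(cohorts: Iterable[Cohort], provenance: str = "") -> Cohort:
    """Concatenate cohorts into one (ids must stay unique)."""
    records: list[PromoterRecord] = []
    for c in cohorts:
        records.extend(c.records)
    return Cohort(records=records, provenance=provenance)


def relabel(record: PromoterRecord, **changes) -> PromoterRecord:
    """Return a copy of a record with some fields replaced."""
    return replace(record, **changes)
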