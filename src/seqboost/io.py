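"""FASTA and gene-list input/output: parsing, sanitization, deduplication.

Records are kept in a thin dataclass rather than Biopython's ``SeqRecord``
so that downstream feature code only ever sees plain A/C/G/T strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO

from .errors import AmbiguousBaseError, EmptySequenceError, FastaFormatError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

DedupMode = Literal["id", "seq"]
SanitizePolicy = Literal["strip", "reject"]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry.

    ``label`` is an optional binary class: 1 for positive, 0 for negative,
    ``None`` for unlabeled query records.
    """

    id: str
    description: str = ""
    residues: str = ""
    label: Optional[int] = None

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FastaDataset:
    """Ordered collection of records plus a provenance tag."""

    records: list[SequenceRecord] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def with_label(self, label: Optional[int]) -> "FastaDataset":
        return FastaDataset(
            records=[replace(r, label=label) for r in self.records],
            source=self.source,
        )


def read_fasta(path: str | Path) -> FastaDataset:
    """Parse a FASTA file into a dataset.

    The record id is the first whitespace-delimited header token; residues
    are concatenated across lines and uppercased.  An empty file yields an
    empty dataset; sequence data before any header is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    with open(path) as handle:
        # Reject leading non-header content explicitly: Biopython's parser
        # silently skips text before the first ">".
        pos = handle.tell()
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: sequence data before any '>' header"
                    )
                break
            pos = handle.tell()
        handle.seek(pos)
        for rec in SeqIO.parse(handle, "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(
                SequenceRecord(
                    id=rec.id, description=desc, residues=str(rec.seq).upper()
                )
            )
    return FastaDataset(records=records, source=str(path))


def write_fasta(ds: FastaDataset, path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns."""
    with open(path, "w") as handle:
        for rec in ds.records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                handle.write(rec.residues[i : i + wrap] + "\n")


def dedup_records(
    ds: FastaDataset, mode: DedupMode = "id"
) -> tuple[FastaDataset, list[tuple[str, str]]]:
    """Drop duplicate records, keeping the first occurrence.

    ``mode="id"`` deduplicates on record id (the default, mirroring
    ``seqkit rmdup``); ``mode="seq"`` on the exact residue string.
    Returns the filtered dataset and a list of ``(id, reason)`` removals.
    """
    if mode not in ("id", "seq"):
        raise ValueError(f"unknown dedup mode: {mode!r}")
    seen: set[str] = set()
    kept: list[SequenceRecord] = []
    removed: list[tuple[str, str]] = []
    for rec in ds.records:
        key = rec.id if mode == "id" else rec.residues
        if key in seen:
            removed.append((rec.id, f"duplicate-{mode}"))
        else:
            seen.add(key)
            kept.append(rec)
    if removed:
        log.info("dedup(%s): removed %d of %d records", mode, len(removed), len(ds))
    return FastaDataset(records=kept, source=ds.source), removed


def write_dedup_report(removed: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("id\treason\n")
        for rec_id, reason in removed:
            handle.write(f"{rec_id}\t{reason}\n")


def sanitize(
    rec: SequenceRecord, policy: SanitizePolicy = "strip"
) -> SequenceRecord:
    """Uppercase residues and resolve non-ACGT characters.

    ``strip`` silently removes ambiguity codes (N, R, Y, ...) and logs the
    count; ``reject`` raises on the first one.  An all-ambiguous sequence is
    an error under either policy.
    """
    if not rec.residues:
        raise EmptySequenceError(f"record {rec.id!r} has no residues")
    upper = rec.residues.upper()
    bad = [c for c in upper if c not in VALID_BASES]
    if bad and policy == "reject":
        raise AmbiguousBaseError(
            f"record {rec.id!r}: non-ACGT character {bad[0]!r}"
        )
    clean = "".join(c for c in upper if c in VALID_BASES)
    if not clean:
        raise EmptySequenceError(
            f"record {rec.id!r}: empty after removing {len(bad)} non-ACGT characters"
        )
    if bad:
        log.debug("sanitize: removed %d non-ACGT characters from %s", len(bad), rec.id)
    return replace(rec, residues=clean)


def sanitize_dataset(
    ds: FastaDataset, policy: SanitizePolicy = "strip"
) -> FastaDataset:
    return FastaDataset(
        records=[sanitize(r, policy) for r in ds.records], source=ds.source
    )


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list (one identifier per line), deduplicated
    preserving first occurrence."""
    seen: set[str] = set()
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and token not in seen:
            seen.add(token)
            out.append(token)
    return out


def check_overlap(a: FastaDataset, b: FastaDataset) -> set[str]:
    """Ids present in both datasets (off-by-default cross-file check)."""
    return set(a.ids()) & set(b.ids())
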