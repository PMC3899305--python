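"""Protein records and FASTA/TSV input-output.

A :class:`ProteinRecord` is one candidate P450 protein together with the
metadata the downstream stages need: a unique id, the species label and
(optionally) the CYP-style name used by the census.  Sequences are
normalised on construction: uppercased, with a single trailing ``*`` stop
character stripped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 standard one-letter amino-acid codes
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in an input sequence (X = unknown residue)
VALID_RESIDUES = frozenset(STANDARD_AA) | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate P450 protein.

    Parameters
    ----------
    id:
        Unique identifier within a dataset (e.g. a JGI protein id).
    species:
        Species label (e.g. ``Pchr``).
    sequence:
        Amino-acid sequence over the 20-letter alphabet plus ``X``.
        Uppercased and stripped of a trailing ``*`` on construction.
    cyp_name:
        CYP-style name (``CYP<family><subfamily><member>``), may be absent.
    """

    id: str
    species: str
    sequence: str
    cyp_name: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        """Residue count of the (normalised) sequence."""
        return len(self.sequence)


def check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    """Raise ``ValueError`` naming the first duplicated record id."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id: {rec.id!r}")
        seen.add(rec.id)


def read_protein_fasta(
    path: str | Path,
    names_tsv: str | Path | None = None,
) -> list[ProteinRecord]:
    """Read candidate P450 proteins from FASTA.

    The header convention is ``id|species|cyp_name`` (cyp_name may be
    empty).  Records whose headers carry only an id fall back to a sidecar
    TSV with columns ``id``, ``species``, ``cyp_name``.
    """
    sidecar: dict[str, tuple[str, str | None]] = {}
    if names_tsv is not None:
        for row in _read_names_tsv(names_tsv):
            sidecar[row[0]] = (row[1], row[2] or None)

    records: list[ProteinRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        parts = seqrec.description.split()[0].split("|")
        rid = parts[0]
        if len(parts) >= 2 and parts[1]:
            species = parts[1]
            cyp = parts[2] if len(parts) >= 3 and parts[2] else None
        elif rid in sidecar:
            species, cyp = sidecar[rid]
        else:
            raise ValueError(
                f"record {rid!r}: no species in header and no sidecar entry"
            )
        records.append(
            ProteinRecord(id=rid, species=species, sequence=str(seqrec.seq), cyp_name=cyp)
        )
    check_unique_ids(records)
    return records


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA with ``id|species|cyp_name`` headers."""
    seqrecs = [
        SeqRecord(
            Seq(rec.sequence),
            id=f"{rec.id}|{rec.species}|{rec.cyp_name or ''}",
            description="",
        )
        for rec in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def _read_names_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    rows: list[tuple[str, str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return rows
        if header[:2] != ["id", "species"]:
            # headerless file: treat the first line as data
            rows.append((header[0], header[1], header[2] if len(header) > 2 else ""))
        for row in reader:
            if not row:
                continue
            rows.append((row[0], row[1], row[2] if len(row) > 2 else ""))
    return rows


def write_names_tsv(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "species", "cyp_name"])
        for rec in records:
            writer.writerow([rec.id, rec.species, rec.cyp_name or ""])
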