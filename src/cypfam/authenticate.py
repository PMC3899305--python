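"""Signature-motif authentication of candidate P450 proteins.

Cytochrome P450s carry two diagnostic sequence signatures: the
heme-binding decapeptide ``FXXGXXXCXG`` (the C is the axial cysteine
ligand of the heme iron) and the ``EXXR`` salt-bridge motif of the
K-helix.  In all P450 folds the K-helix lies upstream of the heme ligand,
so a protein is called authentic only when at least one EXXR occurrence
starts strictly before at least one heme-motif occurrence.

Pattern semantics: positions marked ``X`` accept any of the 20 standard
residues but *not* the ambiguity code ``X`` — an unknown residue cannot
positively evidence a motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import STANDARD_AA, VALID_RESIDUES, ProteinRecord, check_unique_ids

_STANDARD = frozenset(STANDARD_AA)

#: anchored residues of the heme-binding decapeptide FXXGXXXCXG
HEME_ANCHORS: dict[int, str] = {0: "F", 3: "G", 7: "C", 9: "G"}
HEME_LEN = 10
#: anchored residues of the K-helix EXXR tetrapeptide
EXXR_ANCHORS: dict[int, str] = {0: "E", 3: "R"}
EXXR_LEN = 4

#: machine-readable rejection reasons
REASON_BAD_SEQUENCE = "bad-sequence"
REASON_MISSING_HEME = "missing-heme"
REASON_MISSING_EXXR = "missing-exxr"
REASON_WRONG_ORDER = "wrong-order"


@dataclass(frozen=True)
class MotifHits:
    """Motif scan result for one protein.

    ``heme_positions`` / ``exxr_positions`` are 0-based start offsets of
    all (possibly overlapping) matches, in ascending order.  ``authentic``
    is true iff both lists are non-empty and some EXXR start precedes some
    heme start.
    """

    heme_positions: tuple[int, ...]
    exxr_positions: tuple[int, ...]
    authentic: bool


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(
            f"non-amino-acid characters in sequence: {''.join(sorted(bad))!r}"
        )


def _scan_pattern(seq: str, anchors: dict[int, str], wlen: int) -> tuple[int, ...]:
    """All start offsets where the anchored pattern matches ``seq``.

    Every window position must hold a standard residue; anchored positions
    must hold the anchor residue exactly.
    """
    hits: list[int] = []
    for start in range(len(seq) - wlen + 1):
        window = seq[start : start + wlen]
        ok = True
        for off, ch in enumerate(window):
            want = anchors.get(off)
            if want is not None:
                if ch != want:
                    ok = False
                    break
            elif ch not in _STANDARD:
                ok = False
                break
        if ok:
            hits.append(start)
    return tuple(hits)


def scan_motifs(rec: ProteinRecord) -> MotifHits:
    """Scan one record for the two P450 signature motifs.

    Raises ``ValueError`` on an empty sequence or characters outside the
    20 standard residues plus ``X``.
    """
    _validate_sequence(rec.sequence)
    heme = _scan_pattern(rec.sequence, HEME_ANCHORS, HEME_LEN)
    exxr = _scan_pattern(rec.sequence, EXXR_ANCHORS, EXXR_LEN)
    authentic = bool(heme) and bool(exxr) and min(exxr) < max(heme)
    return MotifHits(heme_positions=heme, exxr_positions=exxr, authentic=authentic)


def classify(rec: ProteinRecord) -> str | None:
    """Return a rejection reason for ``rec``, or ``None`` if authentic.

    When both motifs are missing the reason reported is ``missing-heme``
    (the defining P450 signature).
    """
    try:
        hits = scan_motifs(rec)
    except ValueError:
        return REASON_BAD_SEQUENCE
    if hits.authentic:
        return None
    if not hits.heme_positions:
        return REASON_MISSING_HEME
    if not hits.exxr_positions:
        return REASON_MISSING_EXXR
    return REASON_WRONG_ORDER


def filter_authentic(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], list[tuple[str, str]]]:
    """Partition records into authentic P450s and rejects.

    Returns ``(authentic, rejected)`` where ``rejected`` holds
    ``(id, reason)`` pairs with reasons from ``bad-sequence``,
    ``missing-heme``, ``missing-exxr``, ``wrong-order``.  The partition is
    exhaustive and disjoint and the authentic list preserves input order.
    Duplicate ids raise ``ValueError``.
    """
    check_unique_ids(records)
    authentic: list[ProteinRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        reason = classify(rec)
        if reason is None:
            authentic.append(rec)
        else:
            rejected.append((rec.id, reason))
    return authentic, rejected
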