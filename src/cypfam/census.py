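"""CYP nomenclature, the species x family census and the enrichment cutoff.

P450s are named ``CYP<family><subfamily letter><member number>`` (e.g.
``CYP5035C1``); the census counts authentic P450s per species and family
and an *enriched* family is one whose summed count reaches a stated
fraction (default 2%) of all P450s in the compared genomes.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records import ProteinRecord

_CYP_RE = re.compile(r"^CYP(\d+)(?:([A-Z])(\d+)?)?$", re.IGNORECASE)


class CypNameError(ValueError):
    """A string that does not follow CYP-number[-letter[-number]] form."""


@dataclass(frozen=True)
class CypName:
    """Parsed CYP name: family (``CYP``+integer), subfamily, member."""

    family: str
    family_number: int
    subfamily: str | None = None
    member: int | None = None

    def __str__(self) -> str:
        s = self.family
        if self.subfamily is not None:
            s += self.subfamily
            if self.member is not None:
                s += str(self.member)
        return s


def parse_cyp_name(name: str) -> CypName:
    """Parse a CYP-style name; the ``CYP`` prefix is case-insensitive.

    ``CYP5035C1`` -> family CYP5035, subfamily C, member 1;
    ``CYP63B`` -> family CYP63, subfamily B, member absent;
    ``CYP63`` -> bare family.  Anything else raises :class:`CypNameError`.
    """
    m = _CYP_RE.match(name.strip())
    if not m:
        raise CypNameError(f"not a CYP name: {name!r}")
    number = int(m.group(1))
    if number < 1:
        raise CypNameError(f"family number must be >= 1: {name!r}")
    subfamily = m.group(2).upper() if m.group(2) else None
    member = int(m.group(3)) if m.group(3) else None
    return CypName(
        family=f"CYP{number}",
        family_number=number,
        subfamily=subfamily,
        member=member,
    )


def _family_sort_key(family: str) -> tuple[int, str]:
    return (parse_cyp_name(family).family_number, family)


@dataclass
class CensusTable:
    """Species x family count matrix.

    ``counts`` is a pandas DataFrame with species as rows (lexicographic)
    and families as columns (numeric family sort).  Only families counted
    at least once appear.
    """

    counts: pd.DataFrame

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def family_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def build_census(records: Sequence[ProteinRecord]) -> CensusTable:
    """Count authentic P450s per species and family.

    Every record must carry a parseable ``cyp_name``; offenders are all
    collected and reported in a single error (no silent drops).
    """
    offenders: list[str] = []
    rows: list[tuple[str, str]] = []
    for rec in records:
        if rec.cyp_name is None:
            offenders.append(f"{rec.id}: <no name>")
            continue
        try:
            cyp = parse_cyp_name(rec.cyp_name)
        except CypNameError:
            offenders.append(f"{rec.id}: {rec.cyp_name!r}")
            continue
        rows.append((rec.species, cyp.family))
    if offenders:
        raise CypNameError(
            "unparseable CYP names: " + "; ".join(offenders)
        )
    if not rows:
        return CensusTable(counts=pd.DataFrame(dtype=int))
    df = pd.DataFrame(rows, columns=["species", "family"])
    counts = pd.crosstab(df["species"], df["family"]).astype(int)
    counts = counts.reindex(
        index=sorted(counts.index),
        columns=sorted(counts.columns, key=_family_sort_key),
    )
    counts.index.name = "species"
    counts.columns.name = "family"
    return CensusTable(counts=counts)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero (x >= 0)."""
    return int(math.floor(x + 0.5))


def enrichment_cutoff(total: int, fraction: float = 0.02) -> int:
    """Member-count cutoff for an enriched family.

    ``round-half-up(fraction * total)``: a 2% cutoff on 1061 P450s gives 21.
    """
    if total < 1:
        raise ValueError("census total must be >= 1")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return round_half_up(fraction * total)


@dataclass
class EnrichmentResult:
    """Enriched families under the fractional cutoff.

    ``enriched`` is sorted by descending total count (ties by family
    number); ``species_specific`` are the enriched families present in at
    most ``k`` species; ``presence`` is a boolean species x enriched-family
    matrix (count >= 1).
    """

    fraction: float
    cutoff: int
    enriched: list[str]
    species_specific: list[str]
    presence: pd.DataFrame
    family_totals: pd.Series

    def table(self) -> pd.DataFrame:
        """Long-form summary: family, total, enriched, n_species, species-specific."""
        rows = []
        for fam in self.family_totals.index:
            n_species = int((self.presence[fam]).sum()) if fam in self.presence else 0
            rows.append(
                {
                    "family": fam,
                    "total": int(self.family_totals[fam]),
                    "enriched": fam in self.enriched,
                    "n_species": n_species,
                    "species_specific": fam in self.species_specific,
                }
            )
        return pd.DataFrame(rows)


def enrich(
    census: CensusTable,
    fraction: float = 0.02,
    k_species_specific: int = 2,
) -> EnrichmentResult:
    """Apply the fractional enrichment cutoff to a census.

    A family is enriched iff its summed count >= the cutoff
    (round-half-up of ``fraction * total``).  An empty census raises
    ``ValueError``.
    """
    total = census.total
    cutoff = enrichment_cutoff(total, fraction)
    totals = census.family_totals()
    enriched = sorted(
        (fam for fam in census.families if int(totals[fam]) >= cutoff),
        key=lambda f: (-int(totals[f]), _family_sort_key(f)),
    )
    presence_all = census.counts >= 1
    presence = presence_all.reindex(columns=enriched)
    species_specific = [
        fam for fam in enriched if int(presence[fam].sum()) <= k_species_specific
    ]
    # family_totals ordered like the census columns for stable reporting
    return EnrichmentResult(
        fraction=fraction,
        cutoff=cutoff,
        enriched=enriched,
        species_specific=species_specific,
        presence=presence,
        family_totals=totals,
    )
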