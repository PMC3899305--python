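"""Tandem-array detection and per-family scaffold distributions.

A tandem array is two or more same-family genes co-located on one
scaffold — the signature of local gene duplication.  The default rule is
pure scaffold co-location (any number of intervening genes); an optional
stricter rule caps the number of intervening non-family genes between
consecutive members.  Strand is ignored.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from .genestruct import GeneModel


@dataclass(frozen=True)
class TandemArray:
    """Same-species, same-family genes on one scaffold, size >= 2."""

    family: str
    species: str
    scaffold: str
    members: tuple[str, ...]  # gene ids ordered by start coordinate

    @property
    def size(self) -> int:
        return len(self.members)


def detect_tandem(
    genes: Sequence[GeneModel],
    families: Mapping[str, str],
    max_intervening: int | None = None,
) -> tuple[list[TandemArray], list[str]]:
    """Find tandem arrays among ``genes``.

    ``families`` maps gene id to family; genes without an entry or
    without a scaffold are skipped and reported.  With
    ``max_intervening=None`` (the scaffold-level default) each
    (species, family, scaffold) group of >= 2 members forms one array;
    a numeric limit splits groups wherever more than that many
    non-family genes (among ``genes``) lie between consecutive members.
    Returns ``(arrays, skipped_ids)``; arrays are disjoint.
    """
    skipped = [g.gene_id for g in genes if not g.scaffold or g.gene_id not in families]
    usable = [g for g in genes if g.scaffold and g.gene_id in families]

    groups: dict[tuple[str, str, str], list[GeneModel]] = defaultdict(list)
    for g in usable:
        groups[(g.species, families[g.gene_id], g.scaffold)].append(g)

    # rank of each gene along its (species, scaffold) for the strict rule
    rank: dict[str, int] = {}
    if max_intervening is not None:
        by_scaffold: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
        for g in usable:
            by_scaffold[(g.species, g.scaffold)].append(g)
        for glist in by_scaffold.values():
            for i, g in enumerate(sorted(glist, key=lambda x: (x.start, x.gene_id))):
                rank[g.gene_id] = i

    arrays: list[TandemArray] = []
    for (species, family, scaffold), members in sorted(groups.items()):
        members = sorted(members, key=lambda g: (g.start, g.gene_id))
        if max_intervening is None:
            runs = [members]
        else:
            runs = []
            current = [members[0]]
            for prev, cur in zip(members, members[1:]):
                intervening = rank[cur.gene_id] - rank[prev.gene_id] - 1
                if intervening > max_intervening:
                    runs.append(current)
                    current = [cur]
                else:
                    current.append(cur)
            runs.append(current)
        for run in runs:
            if len(run) >= 2:
                arrays.append(
                    TandemArray(
                        family=family,
                        species=species,
                        scaffold=scaffold,
                        members=tuple(g.gene_id for g in run),
                    )
                )
    return arrays, sorted(skipped)


def scaffold_distribution(
    genes: Sequence[GeneModel],
    families: Mapping[str, str],
    family: str,
    species: str | None = None,
) -> list[tuple[str, int]]:
    """Per-scaffold member counts for one family (singletons included).

    Ordered by descending count then scaffold name — the presentation
    used for scaffold rows in gene-location tables.
    """
    counts: Counter[str] = Counter()
    for g in genes:
        if families.get(g.gene_id) != family:
            continue
        if species is not None and g.species != species:
            continue
        counts[g.scaffold] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
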