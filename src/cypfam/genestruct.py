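"""Exon-intron gene structure: profiles, matching, paralog/ortholog calls.

Duplicated genes retain the exon sizes and intron positions of their
ancestor, so shared exon-intron structure is evidence of duplication
(paralogs, within a species) or of descent from a pre-speciation ancestor
(orthologs, across species).  Structures are compared by exon-count-gated
positional exon-length matching: profiles with different intron counts
never match; otherwise the score is the fraction of positionally paired
exons whose lengths agree within a nucleotide tolerance (default 3 nt,
one codon of annotation wobble).

Coordinates: GFF3 is 1-based inclusive; internally everything is 0-based
half-open.  Profiles are strand-normalised (transcript orientation), so a
minus-strand gene lists its genomically last exon first.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import gffutils


@dataclass(frozen=True)
class GeneModel:
    """Scaffold-anchored exon coordinate list for one gene/mRNA.

    ``exons`` are 0-based half-open intervals sorted by genomic start and
    non-overlapping.  ``protein_length`` (residues) links the model to its
    protein and gates the intron summaries; it may be unknown (``None``).
    """

    gene_id: str
    species: str
    scaffold: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


@dataclass(frozen=True)
class StructureProfile:
    """Strand-normalised exon-length vector (5'->3' in transcript order).

    ``intron_offsets`` are the cumulative coding offsets at which introns
    interrupt the transcript (cumulative sums of all but the last exon
    length), strictly increasing.
    """

    exon_lengths: tuple[int, ...]
    intron_offsets: tuple[int, ...]

    @property
    def n_introns(self) -> int:
        return len(self.exon_lengths) - 1


@dataclass(frozen=True)
class StructureMatch:
    """Pairwise structural comparison; symmetric, score(a,a) = 1."""

    gene_a: str
    gene_b: str
    score: float
    same_structure: bool


def structure_profile(g: GeneModel) -> StructureProfile:
    lengths = [e - s for s, e in g.exons]
    if g.strand == "-":
        lengths.reverse()
    offsets = []
    cum = 0
    for ln in lengths[:-1]:
        cum += ln
        offsets.append(cum)
    return StructureProfile(exon_lengths=tuple(lengths), intron_offsets=tuple(offsets))


def structure_similarity(
    a: StructureProfile,
    b: StructureProfile,
    tol_nt: int = 3,
    theta: float = 0.8,
    gene_a: str = "a",
    gene_b: str = "b",
) -> StructureMatch:
    """Score structural similarity of two profiles.

    Different intron counts score 0.  Otherwise the score is the fraction
    of positionally paired exons with ``|len_a - len_b| <= tol_nt``, and
    ``same_structure`` is ``score >= theta``.
    """
    if a.n_introns != b.n_introns:
        return StructureMatch(gene_a, gene_b, 0.0, False)
    k = len(a.exon_lengths)
    matched = sum(
        1 for x, y in zip(a.exon_lengths, b.exon_lengths) if abs(x - y) <= tol_nt
    )
    score = matched / k
    return StructureMatch(gene_a, gene_b, score, score >= theta)


@dataclass
class ParalogClusters:
    """Single-linkage same-structure clusters within one species+family."""

    clusters: list[tuple[str, ...]]
    singletons: list[str]

    def labels(self) -> dict[str, int]:
        """Cluster label per gene id (singletons get their own labels)."""
        out: dict[str, int] = {}
        lab = 0
        for cl in self.clusters:
            for gid in cl:
                out[gid] = lab
            lab += 1
        for gid in self.singletons:
            out[gid] = lab
            lab += 1
        return out


def cluster_paralogs(
    genes: Sequence[GeneModel],
    tol_nt: int = 3,
    theta: float = 0.8,
) -> ParalogClusters:
    """Cluster same-structure genes (expected: one species, one family).

    Single linkage on ``same_structure`` edges: components of size >= 2
    are duplicate groups, the rest singletons.  Clusters are sorted by
    descending size then smallest member id; members sorted by id.
    """
    g = nx.Graph()
    profiles = {gm.gene_id: structure_profile(gm) for gm in genes}
    g.add_nodes_from(profiles)
    ids = sorted(profiles)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            m = structure_similarity(profiles[a], profiles[b], tol_nt, theta, a, b)
            if m.same_structure:
                g.add_edge(a, b)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    clusters = sorted(
        (c for c in comps if len(c) >= 2), key=lambda c: (-len(c), c[0])
    )
    singletons = sorted(c[0] for c in comps if len(c) == 1)
    return ParalogClusters(clusters=clusters, singletons=singletons)


def ortholog_candidates(
    genes: Sequence[GeneModel],
    tol_nt: int = 3,
    theta: float = 0.8,
) -> list[StructureMatch]:
    """Cross-species same-structure gene pairs (expected: one family).

    Many-to-one mappings are allowed: a single gene in one species may
    match every member of a duplicate cluster in another.  Pairs are
    ordered (id_a < id_b) and sorted.
    """
    species = {gm.gene_id: gm.species for gm in genes}
    if len(set(species.values())) < 2:
        return []
    profiles = {gm.gene_id: structure_profile(gm) for gm in genes}
    out: list[StructureMatch] = []
    ids = sorted(profiles)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if species[a] == species[b]:
                continue
            m = structure_similarity(profiles[a], profiles[b], tol_nt, theta, a, b)
            if m.same_structure:
                out.append(m)
    return out


@dataclass
class IntronSummary:
    """Per family-and-species intron-count profile over long proteins.

    Only genes whose protein is at least ``min_len`` residues (default
    400) are counted.  ``modes`` lists every ``(P, I)`` with P = number of
    qualifying genes sharing intron count I for each I achieving the
    maximal multiplicity, ordered by descending I; ``p_over_i`` is the
    canonical mode with ties broken toward the smaller intron count.
    ``is_na`` flags the empty summary (no qualifying gene).
    """

    family: str | None
    species: str | None
    qualifying_counts: tuple[int, ...]
    min_introns: int | None
    max_introns: int | None
    modes: tuple[tuple[int, int], ...]
    p_over_i: tuple[int, int] | None
    is_na: bool

    def min_max_str(self) -> str:
        if self.is_na:
            return "NA"
        if self.min_introns == self.max_introns:
            return str(self.min_introns)
        return f"{self.min_introns}-{self.max_introns}"

    def p_over_i_str(self) -> str:
        if self.is_na:
            return "NA"
        return ";".join(f"{p}/{i}" for p, i in self.modes)


def intron_summary(
    genes: Sequence[GeneModel],
    min_len: int = 400,
    family: str | None = None,
    species: str | None = None,
) -> IntronSummary:
    counts = [
        gm.n_introns
        for gm in genes
        if gm.protein_length is not None and gm.protein_length >= min_len
    ]
    if not counts:
        return IntronSummary(
            family=family,
            species=species,
            qualifying_counts=(),
            min_introns=None,
            max_introns=None,
            modes=(),
            p_over_i=None,
            is_na=True,
        )
    tally = Counter(counts)
    best_p = max(tally.values())
    tied = sorted((i for i, p in tally.items() if p == best_p), reverse=True)
    modes = tuple((best_p, i) for i in tied)
    return IntronSummary(
        family=family,
        species=species,
        qualifying_counts=tuple(sorted(counts)),
        min_introns=min(counts),
        max_introns=max(counts),
        modes=modes,
        p_over_i=(best_p, min(tied)),
        is_na=False,
    )


# ---------------------------------------------------------------------------
# GFF3 input
# ---------------------------------------------------------------------------


def load_gene_models(
    gff3: str | Path,
    species_map: Mapping[str, str] | None = None,
    protein_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Load one :class:`GeneModel` per mRNA from a GFF3 file.

    CDS children are preferred; exon children are the fallback (never
    mixed), which removes UTR ambiguity deterministically.  The species
    comes from an mRNA ``species`` attribute or from ``species_map``.
    Malformed records (overlapping exons, missing strand, no exonic
    children, unknown species) are all collected and reported in one
    error.  When both CDS features and a protein length are available the
    coding length is checked against ``3 * protein_length + 3`` (stop
    codon included); mismatches warn rather than fail because annotated
    gene models are imperfect.
    """
    db = gffutils.create_db(
        str(gff3),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    errors: list[str] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        gene_id = mrna.id
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        feats = cds or list(db.children(mrna, featuretype="exon", order_by="start"))
        if not feats:
            errors.append(f"{gene_id}: no CDS or exon children")
            continue
        if mrna.strand not in "+-":
            errors.append(f"{gene_id}: missing strand")
            continue
        species = (mrna.attributes.get("species") or [None])[0]
        if species is None and species_map is not None:
            species = species_map.get(gene_id)
        if species is None:
            errors.append(f"{gene_id}: species unknown")
            continue
        plen = None
        if protein_lengths is not None:
            plen = protein_lengths.get(gene_id)
        if plen is None:
            attr = (mrna.attributes.get("protein_length") or [None])[0]
            plen = int(attr) if attr is not None else None
        exons = tuple((f.start - 1, f.end) for f in feats)
        try:
            model = GeneModel(
                gene_id=gene_id,
                species=species,
                scaffold=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                protein_length=plen,
            )
        except ValueError as exc:
            errors.append(str(exc))
            continue
        if cds and plen is not None:
            coding = sum(e - s for s, e in exons)
            if coding != 3 * plen + 3:
                warnings.warn(
                    f"{gene_id}: CDS length {coding} != 3*{plen}+3",
                    stacklevel=2,
                )
        models.append(model)
    if errors:
        raise ValueError("malformed gene models: " + "; ".join(errors))
    return models
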