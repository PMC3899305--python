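"""Synthetic multi-species P450 complements with planted ground truth.

The generator emulates the statistical structure the analysis assumes in
a set of sequenced fungal genomes: per-family member counts planted per
species, tandem duplicate copies that conserve exon-intron structure
exactly, cross-species orthologs seeded before the species split,
Poisson-process sequence divergence (substitution-only, no indels, so
ungapped alignments remain valid inputs to the distance stage), and
pseudogenes whose signature motifs are ablated.

Divergence model: along a branch with expected ``mu`` substitutions per
site each site is substituted with probability ``1 - exp(-mu)``, to a
uniformly chosen *different* standard residue; planted motif windows are
protected so authentic genes stay authentic.  Duplicates diverge from
their lineage founder (not chained copy-of-copy), keeping both sequence
and structural deviation bounded by the per-event parameters.

Every draw comes from one seeded generator, so identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import census as census_mod
from .authenticate import EXXR_LEN, HEME_LEN, scan_motifs
from .genestruct import GeneModel
from .phylo import Alignment
from .records import STANDARD_AA, ProteinRecord

_AA = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)
_N_AA = len(STANDARD_AA)

#: default species labels (six model basidiomycete abbreviations)
DEFAULT_SPECIES = ("Pchr", "Pcar", "Abis", "Gsp", "Ppla", "Slac")

#: default planted species x family counts: six enriched families (two of
#: them species-specific) and six rare singleton families; totals chosen so
#: the 2% cutoff splits them with a comfortable margin even after
#: pseudogene ablation
DEFAULT_FAMILY_COUNTS: dict[str, dict[str, int]] = {
    "CYP5144": {"Pchr": 20, "Pcar": 45, "Abis": 15, "Gsp": 3, "Ppla": 3, "Slac": 34},
    "CYP512": {"Pchr": 10, "Pcar": 16, "Abis": 12, "Gsp": 20, "Ppla": 8, "Slac": 14},
    "CYP5150": {"Pchr": 6, "Pcar": 8, "Abis": 7, "Gsp": 22, "Ppla": 15, "Slac": 2},
    "CYP5035": {"Pchr": 8, "Pcar": 14, "Gsp": 10, "Ppla": 2, "Slac": 6},
    "CYP5348": {"Gsp": 5, "Ppla": 20},
    "CYP5359": {"Gsp": 16},
    "CYP5801": {"Pchr": 1},
    "CYP5815": {"Pcar": 1},
    "CYP5822": {"Abis": 1},
    "CYP5830": {"Gsp": 1},
    "CYP5841": {"Ppla": 1},
    "CYP5852": {"Slac": 1},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic multi-genome dataset.

    ``family_counts`` plants the species x family census (genes emitted,
    before pseudogene ablation).  ``mu_speciation`` / ``mu_duplication``
    are expected substitutions per site on speciation and duplication
    branches; duplication divergence is kept well below speciation
    divergence so paralogs group species-specifically, as duplicates of
    recent tandem expansions do.  ``p_tandem`` is the probability a
    duplicate lands on its parent's scaffold.  ``ortholog_fraction`` is
    the probability a multi-species family is seeded before the species
    split (conserved structure, founders labelled orthologs).
    ``pseudo_fraction`` of all genes have their motifs ablated.
    ``structural_jitter_nt`` moves one exon boundary of each duplicate by
    up to that many nucleotides (0 = copy structure exactly).
    """

    species: tuple[str, ...] = DEFAULT_SPECIES
    family_counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: DEFAULT_FAMILY_COUNTS
    )
    mu_speciation: float = 0.15
    mu_duplication: float = 0.03
    p_tandem: float = 0.7
    ortholog_fraction: float = 0.5
    pseudo_fraction: float = 0.1
    structural_jitter_nt: int = 0
    exon_range: tuple[int, int] = (5, 18)
    min_exon_nt: int = 30
    intron_length_range: tuple[int, int] = (50, 400)
    protein_length_range: tuple[int, int] = (380, 520)
    intergenic_nt: int = 2000
    seed: int = 0

    def validate(self) -> None:
        for prob in (self.p_tandem, self.ortholog_fraction, self.pseudo_fraction):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mu_speciation < 0 or self.mu_duplication < 0:
            raise ValueError("divergence rates must be >= 0")
        lo, hi = self.protein_length_range
        if lo < EXXR_LEN + HEME_LEN + 40:
            raise ValueError("proteins too short to carry both motifs")
        if self.exon_range[0] < 1 or self.exon_range[1] < self.exon_range[0]:
            raise ValueError("bad exon_range")
        for fam, per_sp in self.family_counts.items():
            census_mod.parse_cyp_name(fam)
            for sp, c in per_sp.items():
                if sp not in self.species:
                    raise ValueError(f"{fam}: unknown species {sp!r}")
                if c < 0:
                    raise ValueError(f"{fam}/{sp}: negative count")
        # an exon split needs min_exon_nt per exon to be feasible
        if 3 * lo + 3 < self.exon_range[1] * self.min_exon_nt:
            raise ValueError("exon model infeasible for shortest protein")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The standard six-species, twelve-family study configuration."""
    return replace(SyntheticConfig(seed=seed), **overrides)


@dataclass(frozen=True)
class SyntheticGene:
    """One emitted gene with its full provenance labels."""

    id: str
    species: str
    family: str
    cyp_name: str
    sequence: str
    exon_lengths_tx: tuple[int, ...]  # transcript-order coding exon lengths
    scaffold: str
    strand: str
    exons_genomic: tuple[tuple[int, int], ...]  # 0-based half-open
    ancestor_id: str  # lineage founder ("" for founders themselves)
    cluster_id: str  # planted paralog cluster (species+family lineage)
    pseudogene: bool

    @property
    def protein_length(self) -> int:
        return len(self.sequence)

    def to_gene_model(self) -> GeneModel:
        return GeneModel(
            gene_id=self.id,
            species=self.species,
            scaffold=self.scaffold,
            strand=self.strand,
            exons=self.exons_genomic,
            protein_length=self.protein_length,
        )


@dataclass
class SyntheticTruth:
    """Planted labels for recovery testing.

    The census, enrichment calls, paralog clusters, ortholog pairs and
    tandem arrays all describe the *authentic* genes only (pseudogenes
    are flagged separately and fail motif authentication downstream).
    """

    census: dict[str, dict[str, int]]
    enriched: list[str]
    species_specific: list[str]
    cutoff: int
    paralog_clusters: dict[str, str]  # authentic gene id -> cluster id
    ortholog_pairs: list[tuple[str, str]]
    tandem_arrays: list[tuple[str, str, str, tuple[str, ...]]]
    pseudogenes: list[str]

    def to_json(self) -> str:
        payload = {
            "census": self.census,
            "enriched": self.enriched,
            "species_specific": self.species_specific,
            "cutoff": self.cutoff,
            "paralog_clusters": self.paralog_clusters,
            "ortholog_pairs": [list(p) for p in self.ortholog_pairs],
            "tandem_arrays": [
                {"species": s, "family": f, "scaffold": sc, "members": list(m)}
                for s, f, sc, m in self.tandem_arrays
            ],
            "pseudogenes": self.pseudogenes,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    """Generated bundle: records + gene models + truth labels."""

    config: SyntheticConfig
    genes: list[SyntheticGene]
    truth: SyntheticTruth

    @property
    def records(self) -> list[ProteinRecord]:
        return [
            ProteinRecord(
                id=g.id, species=g.species, sequence=g.sequence, cyp_name=g.cyp_name
            )
            for g in self.genes
        ]

    def gene_models(self) -> list[GeneModel]:
        return [g.to_gene_model() for g in self.genes]

    # -- serialisation ------------------------------------------------------

    def fasta_text(self) -> str:
        chunks = []
        for g in self.genes:
            chunks.append(f">{g.id}|{g.species}|{g.cyp_name}")
            seq = g.sequence
            chunks.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        return "\n".join(chunks) + "\n"

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for g in sorted(self.genes, key=lambda x: (x.species, x.scaffold, x.start_coord)):
            gid = g.id
            gene_start = g.exons_genomic[0][0] + 1
            gene_end = g.exons_genomic[-1][1]
            attrs = f"ID=gene:{gid};Name={g.cyp_name}"
            lines.append(
                "\t".join(
                    [g.scaffold, "cypfam-synth", "gene", str(gene_start),
                     str(gene_end), ".", g.strand, ".", attrs]
                )
            )
            mattrs = (
                f"ID={gid};Parent=gene:{gid};species={g.species};"
                f"protein_length={g.protein_length}"
            )
            lines.append(
                "\t".join(
                    [g.scaffold, "cypfam-synth", "mRNA", str(gene_start),
                     str(gene_end), ".", g.strand, ".", mattrs]
                )
            )
            # phase bookkeeping runs in transcript order
            genomic = list(g.exons_genomic)
            tx_order = genomic if g.strand == "+" else list(reversed(genomic))
            cum = 0
            phases = []
            for s, e in tx_order:
                phases.append((3 - cum % 3) % 3)
                cum += e - s
            phase_by_exon = dict(zip(map(tuple, tx_order), phases))
            for s, e in genomic:
                for ftype in ("exon", "CDS"):
                    ph = str(phase_by_exon[(s, e)]) if ftype == "CDS" else "."
                    lines.append(
                        "\t".join(
                            [g.scaffold, "cypfam-synth", ftype, str(s + 1),
                             str(e), ".", g.strand, ph, f"Parent={gid}"]
                        )
                    )
        return "\n".join(lines) + "\n"

    def names_text(self) -> str:
        lines = ["id\tspecies\tcyp_name"]
        lines.extend(f"{g.id}\t{g.species}\t{g.cyp_name}" for g in self.genes)
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "gff3": outdir / "genes.gff3",
            "names": outdir / "names.tsv",
            "truth": outdir / "truth.json",
        }
        paths["fasta"].write_text(self.fasta_text())
        paths["gff3"].write_text(self.gff3_text())
        paths["names"].write_text(self.names_text())
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


# SyntheticGene helper used for deterministic GFF ordering
SyntheticGene.start_coord = property(lambda self: self.exons_genomic[0][0])


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def mutate(
    seq: np.ndarray,
    mu: float,
    rng: np.random.Generator,
    protected: np.ndarray | None = None,
) -> np.ndarray:
    """Poisson-process substitution of residue-index arrays.

    Each unprotected site is substituted with probability
    ``1 - exp(-mu)`` to a uniformly chosen different residue, so the
    expected parent-child p-distance equals ``1 - exp(-mu)`` exactly.
    """
    q = -np.expm1(-mu)
    mask = rng.random(seq.size) < q
    if protected is not None:
        mask &= ~protected
    out = seq.copy()
    idx = np.flatnonzero(mask)
    if idx.size:
        shift = rng.integers(1, _N_AA, size=idx.size)
        out[idx] = (out[idx] + shift) % _N_AA
    return out


def _indices_to_str(seq: np.ndarray) -> str:
    return _AA[seq].tobytes().decode()


def _plant_motifs(seq: np.ndarray, e_pos: int, h_pos: int) -> None:
    aa = {c: STANDARD_AA.index(c) for c in "ERFGC"}
    seq[e_pos] = aa["E"]
    seq[e_pos + 3] = aa["R"]
    seq[h_pos] = aa["F"]
    seq[h_pos + 3] = aa["G"]
    seq[h_pos + 7] = aa["C"]
    seq[h_pos + 9] = aa["G"]


def _ablate_motifs(seq_str: str, rec_id: str, mode: str, rng: np.random.Generator) -> str:
    """Destroy signature motifs until the sequence fails authentication."""
    seq = list(seq_str)
    alt = {"C": "S", "E": "Q", "R": "K", "F": "L"}
    while True:
        hits = scan_motifs(ProteinRecord(id=rec_id, species="x", sequence="".join(seq)))
        if not hits.authentic:
            return "".join(seq)
        if mode in ("heme", "both") and hits.heme_positions:
            pos = hits.heme_positions[-1] + 7  # the axial cysteine
            seq[pos] = alt.get(seq[pos], "S")
        elif hits.exxr_positions:
            pos = hits.exxr_positions[0]
            seq[pos] = alt.get(seq[pos], "Q")
        else:  # pragma: no cover - authentic implies one branch fires
            raise AssertionError("authentic without motif hits")


def _apportion(total: int, weights: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` across ``weights``."""
    wsum = sum(weights)
    if wsum == 0 or total == 0:
        return [0] * len(weights)
    quotas = [total * w / wsum for w in weights]
    floors = [int(q) for q in quotas]
    short = total - sum(floors)
    order = sorted(
        range(len(weights)), key=lambda i: (-(quotas[i] - floors[i]), i)
    )
    for i in order[:short]:
        floors[i] += 1
    return [min(f, w) for f, w in zip(floors, weights)]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset (FASTA/GFF3/names/truth are views of it)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fam_order = sorted(config.family_counts, key=lambda f: census_mod.parse_cyp_name(f).family_number)

    genes: list[SyntheticGene] = []
    scaffold_counter = {sp: 0 for sp in config.species}
    scaffold_end: dict[tuple[str, str], int] = {}
    gene_counter = {sp: 0 for sp in config.species}

    def new_scaffold(sp: str) -> str:
        scaffold_counter[sp] += 1
        return f"{sp}_scaffold{scaffold_counter[sp]:03d}"

    def place(sp: str, scaffold: str, tx_lengths: tuple[int, ...], strand: str):
        """Genomic exon intervals appended at the current scaffold end."""
        start = scaffold_end.get((sp, scaffold), 0) + config.intergenic_nt
        genomic_lengths = tx_lengths if strand == "+" else tuple(reversed(tx_lengths))
        lo, hi = config.intron_length_range
        exons = []
        pos = start
        for i, ln in enumerate(genomic_lengths):
            exons.append((pos, pos + ln))
            pos += ln
            if i < len(genomic_lengths) - 1:
                pos += int(rng.integers(lo, hi + 1))
        scaffold_end[(sp, scaffold)] = pos
        return tuple(exons)

    def random_structure(length_aa: int) -> tuple[int, ...]:
        total = 3 * length_aa + 3
        k = int(rng.integers(config.exon_range[0], config.exon_range[1] + 1))
        k = min(k, total // config.min_exon_nt)
        extra = rng.multinomial(total - k * config.min_exon_nt, np.full(k, 1.0 / k))
        return tuple(int(config.min_exon_nt + e) for e in extra)

    def jitter_structure(tx_lengths: tuple[int, ...]) -> tuple[int, ...]:
        j = config.structural_jitter_nt
        if j == 0 or len(tx_lengths) < 2:
            return tx_lengths
        lengths = list(tx_lengths)
        b = int(rng.integers(0, len(lengths) - 1))  # boundary between b and b+1
        delta = int(rng.integers(-j, j + 1))
        if (
            lengths[b] + delta >= config.min_exon_nt
            and lengths[b + 1] - delta >= config.min_exon_nt
        ):
            lengths[b] += delta
            lengths[b + 1] -= delta
        return tuple(lengths)

    def random_protein(length_aa: int):
        seq = rng.integers(0, _N_AA, size=length_aa)
        seq[0] = STANDARD_AA.index("M")
        e_pos = int(0.70 * length_aa) + int(rng.integers(-5, 6))
        h_pos = int(0.90 * length_aa) + int(rng.integers(-5, 6))
        h_pos = min(h_pos, length_aa - HEME_LEN)
        e_pos = min(e_pos, h_pos - EXXR_LEN)
        _plant_motifs(seq, e_pos, h_pos)
        protected = np.zeros(length_aa, dtype=bool)
        protected[0] = True
        protected[e_pos : e_pos + EXXR_LEN] = True
        protected[h_pos : h_pos + HEME_LEN] = True
        return seq, protected

    ortholog_pairs: list[tuple[str, str]] = []
    family_gene_ids: dict[str, list[str]] = {f: [] for f in fam_order}

    for family in fam_order:
        per_sp = {
            sp: int(config.family_counts[family].get(sp, 0)) for sp in config.species
        }
        present = [sp for sp in config.species if per_sp[sp] > 0]
        if not present:
            continue
        length_aa = int(
            rng.integers(
                config.protein_length_range[0], config.protein_length_range[1] + 1
            )
        )
        anc_seq, protected = random_protein(length_aa)
        anc_structure = random_structure(length_aa)
        shared = len(present) > 1 and rng.random() < config.ortholog_fraction

        founder_ids: list[str] = []
        for sp in present:
            if shared:
                founder_seq = mutate(anc_seq, config.mu_speciation, rng, protected)
                founder_structure = anc_structure
                founder_protected = protected
            else:
                founder_seq, founder_protected = random_protein(length_aa)
                founder_structure = random_structure(length_aa)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter[sp] += 1
            fid = f"{sp}_{gene_counter[sp]:04d}"
            scaffold = new_scaffold(sp)
            exons = place(sp, scaffold, founder_structure, strand)
            cluster = f"{family}:{sp}"
            genes.append(
                SyntheticGene(
                    id=fid,
                    species=sp,
                    family=family,
                    cyp_name="",  # assigned below
                    sequence=_indices_to_str(founder_seq),
                    exon_lengths_tx=founder_structure,
                    scaffold=scaffold,
                    strand=strand,
                    exons_genomic=exons,
                    ancestor_id="",
                    cluster_id=cluster,
                    pseudogene=False,
                )
            )
            family_gene_ids[family].append(fid)
            founder_ids.append(fid)
            parent_scaffold = scaffold
            for _ in range(per_sp[sp] - 1):
                dup_seq = mutate(founder_seq, config.mu_duplication, rng, founder_protected)
                dup_structure = jitter_structure(founder_structure)
                gene_counter[sp] += 1
                did = f"{sp}_{gene_counter[sp]:04d}"
                if rng.random() < config.p_tandem:
                    dscaffold = parent_scaffold
                else:
                    dscaffold = new_scaffold(sp)
                dexons = place(sp, dscaffold, dup_structure, strand)
                genes.append(
                    SyntheticGene(
                        id=did,
                        species=sp,
                        family=family,
                        cyp_name="",
                        sequence=_indices_to_str(dup_seq),
                        exon_lengths_tx=dup_structure,
                        scaffold=dscaffold,
                        strand=strand,
                        exons_genomic=dexons,
                        ancestor_id=fid,
                        cluster_id=cluster,
                        pseudogene=False,
                    )
                )
                family_gene_ids[family].append(did)
        if shared:
            for i in range(len(founder_ids)):
                for j in range(i + 1, len(founder_ids)):
                    ortholog_pairs.append((founder_ids[i], founder_ids[j]))

    # ----- pseudogene ablation --------------------------------------------
    n_total = len(genes)
    n_pseudo = census_mod.round_half_up(config.pseudo_fraction * n_total)
    fam_sizes = [len(family_gene_ids[f]) for f in fam_order]
    per_family_pseudo = _apportion(n_pseudo, fam_sizes)
    by_id = {g.id: i for i, g in enumerate(genes)}
    pseudo_ids: list[str] = []
    for family, k in zip(fam_order, per_family_pseudo):
        if k == 0:
            continue
        chosen = rng.choice(len(family_gene_ids[family]), size=k, replace=False)
        for c in sorted(int(x) for x in chosen):
            gid = family_gene_ids[family][c]
            g = genes[by_id[gid]]
            mode = ("heme", "exxr", "both")[int(rng.integers(0, 3))]
            new_seq = _ablate_motifs(g.sequence, gid, mode, rng)
            genes[by_id[gid]] = replace(g, sequence=new_seq, pseudogene=True)
            pseudo_ids.append(gid)

    # ----- CYP names (subfamily letters cycle, members sequential) --------
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for family in fam_order:
        for i, gid in enumerate(family_gene_ids[family]):
            g = genes[by_id[gid]]
            name = f"{family}{letters[i % 26]}{i // 26 + 1}"
            genes[by_id[gid]] = replace(g, cyp_name=name)

    # ----- truth labels (authentic genes only) -----------------------------
    authentic = [g for g in genes if not g.pseudogene]
    census_counts: dict[str, dict[str, int]] = {}
    for g in authentic:
        census_counts.setdefault(g.species, {})
        census_counts[g.species][g.family] = (
            census_counts[g.species].get(g.family, 0) + 1
        )
    table = census_mod.build_census(
        [
            ProteinRecord(id=g.id, species=g.species, sequence=g.sequence, cyp_name=g.cyp_name)
            for g in authentic
        ]
    )
    enr = census_mod.enrich(table)
    pseudo_set = set(pseudo_ids)
    ortholog_pairs = [
        (a, b) for a, b in ortholog_pairs if a not in pseudo_set and b not in pseudo_set
    ]
    arrays: dict[tuple[str, str, str], list[SyntheticGene]] = {}
    for g in authentic:
        arrays.setdefault((g.species, g.family, g.scaffold), []).append(g)
    tandem_arrays = [
        (sp, fam, sc, tuple(x.id for x in sorted(members, key=lambda m: m.start_coord)))
        for (sp, fam, sc), members in sorted(arrays.items())
        if len(members) >= 2
    ]
    truth = SyntheticTruth(
        census=census_counts,
        enriched=list(enr.enriched),
        species_specific=list(enr.species_specific),
        cutoff=enr.cutoff,
        paralog_clusters={g.id: g.cluster_id for g in authentic},
        ortholog_pairs=sorted(ortholog_pairs),
        tandem_arrays=tandem_arrays,
        pseudogenes=sorted(pseudo_ids),
    )
    return SyntheticDataset(config=config, genes=genes, truth=truth)


def make_alignment(records: Sequence[ProteinRecord]) -> Alignment:
    """Ungapped alignment from equal-length family members.

    The generator never introduces indels, so the sequences themselves
    form a valid alignment; unequal lengths raise ``ValueError``.
    """
    lengths = {r.length for r in records}
    if len(lengths) > 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    return Alignment(
        taxa=tuple(r.id for r in records), rows=tuple(r.sequence for r in records)
    )
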