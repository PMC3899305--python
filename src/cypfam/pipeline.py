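"""End-to-end analysis: authenticate -> census/enrich -> trees -> structure.

:func:`run_pipeline` wires the stages together and writes a tab-separated
report bundle: the enrichment count matrix (species x enriched family),
per-family Newick trees and distance matrices, paralog clusters, ortholog
candidates, tandem arrays, intron summaries shaped like the published
duplication table, and a JSON manifest recording every parameter so the
run can be repeated identically.  Given fixed inputs the bundle is
byte-identical across reruns (the manifest carries no timestamps).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from collections import defaultdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import census as census_mod
from .authenticate import filter_authentic
from .genestruct import (
    cluster_paralogs,
    intron_summary,
    load_gene_models,
    ortholog_candidates,
    structure_profile,
)
from .phylo import Alignment, family_tree, write_distance_tsv
from .records import read_protein_fasta, write_protein_fasta
from .synth import make_alignment
from .tandem import detect_tandem, scaffold_distribution

log = logging.getLogger("cypfam")


class InputError(ValueError):
    """Bad or missing inputs (CLI exit code 2)."""


class ComputationError(RuntimeError):
    """A stage failed on valid inputs (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Inputs, parameters and output location of one pipeline run."""

    fasta: Path
    out_dir: Path
    gff3: Path | None = None
    names: Path | None = None
    alignments_dir: Path | None = None
    fraction: float = 0.02
    k_species_specific: int = 2
    tol_nt: int = 3
    theta: float = 0.8
    deletion: str = "complete"
    min_len: int = 400
    max_intervening: int | None = None
    tree_max_taxa: int | None = None
    tree_level: int = 1
    seed: int = 0

    def manifest_params(self) -> dict:
        d = asdict(self)
        # the bundle does not record its own location, so reruns into a
        # different directory stay byte-identical
        d.pop("out_dir")
        for key in ("fasta", "gff3", "names", "alignments_dir"):
            d[key] = str(d[key]) if d[key] is not None else None
        return d


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Raises :class:`InputError` for unreadable/empty inputs and
    :class:`ComputationError` when a stage fails, naming the stage.
    """
    if not Path(cfg.fasta).exists():
        raise InputError(f"input FASTA not found: {cfg.fasta}")
    try:
        records = read_protein_fasta(cfg.fasta, names_tsv=cfg.names)
    except ValueError as exc:
        raise InputError(f"reading {cfg.fasta}: {exc}") from exc
    if not records:
        raise InputError(f"no sequences in {cfg.fasta}")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "cypfam",
        "version": __version__,
        "parameters": cfg.manifest_params(),
        "n_input_records": len(records),
        "outputs": [],
    }

    def emit(relpath: str, text: str) -> None:
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(text)
        manifest["outputs"].append(relpath)

    # -- authenticate -------------------------------------------------------
    log.info("stage authenticate: %d candidates", len(records))
    authentic, rejected = filter_authentic(records)
    write_protein_fasta(authentic, out / "authentic.fasta")
    manifest["outputs"].append("authentic.fasta")
    emit(
        "rejected.tsv",
        "id\treason\n" + "".join(f"{rid}\t{reason}\n" for rid, reason in rejected),
    )
    manifest["n_authentic"] = len(authentic)
    manifest["n_rejected"] = len(rejected)
    if not authentic:
        raise ComputationError("authenticate: no authentic P450s in input")

    # -- census + enrichment ------------------------------------------------
    log.info("stage census: %d authentic P450s", len(authentic))
    try:
        table = census_mod.build_census(authentic)
        enr = census_mod.enrich(
            table, fraction=cfg.fraction, k_species_specific=cfg.k_species_specific
        )
    except ValueError as exc:
        raise ComputationError(f"census: {exc}") from exc
    emit("census.tsv", table.counts.to_csv(sep="\t"))
    emit("enrichment.tsv", enr.table().to_csv(sep="\t", index=False))
    # Figure-1-shaped matrix: species x enriched families, member counts
    emit(
        "enriched_matrix.tsv",
        table.counts.reindex(columns=enr.enriched).to_csv(sep="\t"),
    )
    manifest["census_total"] = table.total
    manifest["cutoff"] = enr.cutoff
    manifest["enriched"] = enr.enriched
    manifest["species_specific"] = enr.species_specific

    # -- per-family trees ---------------------------------------------------
    by_family: dict[str, list] = defaultdict(list)
    for rec in authentic:
        by_family[census_mod.parse_cyp_name(rec.cyp_name).family].append(rec)
    tree_notes: dict[str, str] = {}
    for fam in enr.enriched:
        members = by_family[fam]
        if len(members) < 2:
            tree_notes[fam] = "skipped: fewer than 2 members"
            continue
        if cfg.tree_max_taxa is not None and len(members) > cfg.tree_max_taxa:
            tree_notes[fam] = f"skipped: {len(members)} members > tree_max_taxa"
            continue
        aln = _family_alignment(cfg, fam, members)
        if aln is None:
            tree_notes[fam] = "skipped: no alignment (unequal lengths, none supplied)"
            continue
        log.info("stage tree: %s (%d members)", fam, len(members))
        try:
            result = family_tree(aln, deletion=cfg.deletion, level=cfg.tree_level)
        except ValueError as exc:
            raise ComputationError(f"tree {fam}: {exc}") from exc
        emit(f"trees/{fam}.nwk", result.newick + "\n")
        write_distance_tsv(result.distances, out / f"distances_{fam}.tsv")
        manifest["outputs"].append(f"distances_{fam}.tsv")
        tree_notes[fam] = (
            f"me_score={result.me_score:.6g} "
            f"trajectory={[round(x, 6) for x in result.trajectory]}"
        )
    manifest["trees"] = tree_notes

    # -- gene structure + tandem -------------------------------------------
    if cfg.gff3 is not None:
        log.info("stage structure: %s", cfg.gff3)
        lengths = {rec.id: rec.length for rec in authentic}
        auth_ids = set(lengths)
        try:
            models = [
                m
                for m in load_gene_models(cfg.gff3, protein_lengths=lengths)
                if m.gene_id in auth_ids
            ]
        except ValueError as exc:
            raise InputError(f"gene models: {exc}") from exc
        families = {
            rec.id: census_mod.parse_cyp_name(rec.cyp_name).family for rec in authentic
        }
        _structure_stage(cfg, out, emit, models, families)
        _tandem_stage(cfg, emit, models, families)

    emit("manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _family_alignment(cfg: RunConfig, fam: str, members) -> Alignment | None:
    if cfg.alignments_dir is not None:
        path = Path(cfg.alignments_dir) / f"{fam}.fasta"
        if path.exists():
            return Alignment.from_fasta(path)
    try:
        return make_alignment(members)
    except ValueError:
        return None


def _structure_stage(cfg: RunConfig, out: Path, emit, models, families) -> None:
    profile_rows = []
    for m in sorted(models, key=lambda x: x.gene_id):
        prof = structure_profile(m)
        profile_rows.append(
            {
                "gene_id": m.gene_id,
                "species": m.species,
                "family": families[m.gene_id],
                "scaffold": m.scaffold,
                "strand": m.strand,
                "n_introns": prof.n_introns,
                "exon_lengths": ",".join(map(str, prof.exon_lengths)),
                "intron_offsets": ",".join(map(str, prof.intron_offsets)),
            }
        )
    emit("structure_profiles.tsv", pd.DataFrame(profile_rows).to_csv(sep="\t", index=False))

    groups = defaultdict(list)
    for m in models:
        groups[(m.species, families[m.gene_id])].append(m)

    cluster_rows, intron_rows = [], []
    for (species, family), genes in sorted(groups.items()):
        clusters = cluster_paralogs(genes, tol_nt=cfg.tol_nt, theta=cfg.theta)
        for k, members in enumerate(clusters.clusters):
            cluster_rows.append(
                {
                    "species": species,
                    "family": family,
                    "cluster": k,
                    "size": len(members),
                    "members": ",".join(members),
                }
            )
        summary = intron_summary(
            genes, min_len=cfg.min_len, family=family, species=species
        )
        intron_rows.append(
            {
                "family": family,
                "species": species,
                "n_genes": len(genes),
                "n_qualifying": len(summary.qualifying_counts),
                "min_max_introns": summary.min_max_str(),
                "P_over_I": summary.p_over_i_str(),
            }
        )
    emit("paralog_clusters.tsv", pd.DataFrame(cluster_rows).to_csv(sep="\t", index=False))
    emit("intron_summary.tsv", pd.DataFrame(intron_rows).to_csv(sep="\t", index=False))

    by_family = defaultdict(list)
    for m in models:
        by_family[families[m.gene_id]].append(m)
    ortho_rows = []
    for family, genes in sorted(by_family.items()):
        for match in ortholog_candidates(genes, tol_nt=cfg.tol_nt, theta=cfg.theta):
            ortho_rows.append(
                {
                    "family": family,
                    "gene_a": match.gene_a,
                    "gene_b": match.gene_b,
                    "score": f"{match.score:.4f}",
                }
            )
    emit("ortholog_candidates.tsv", pd.DataFrame(ortho_rows).to_csv(sep="\t", index=False))


def _tandem_stage(cfg: RunConfig, emit, models, families) -> None:
    arrays, skipped = detect_tandem(models, families, max_intervening=cfg.max_intervening)
    rows = [
        {
            "family": a.family,
            "species": a.species,
            "scaffold": a.scaffold,
            "size": a.size,
            "members": ",".join(a.members),
        }
        for a in arrays
    ]
    emit("tandem_arrays.tsv", pd.DataFrame(rows).to_csv(sep="\t", index=False))

    dist_rows = []
    fam_species = sorted({(families[m.gene_id], m.species) for m in models})
    for family, species in fam_species:
        dist = scaffold_distribution(models, families, family, species=species)
        if dist:
            dist_rows.append(
                {
                    "family": family,
                    "species": species,
                    "scaffolds": ",".join(s for s, _ in dist),
                    "counts": ",".join(str(c) for _, c in dist),
                }
            )
    emit("scaffold_distribution.tsv", pd.DataFrame(dist_rows).to_csv(sep="\t", index=False))
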