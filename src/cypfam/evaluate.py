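"""Recovery metrics against planted synthetic truth.

These helpers run the analysis stages on a generated dataset and compare
the results with the generator's labels: precision/recall of the
enrichment calls and tandem arrays, adjusted Rand index (ARI) of the
paralog clustering, and the pseudogene rejection rate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from sklearn.metrics import adjusted_rand_score

from . import census as census_mod
from .authenticate import filter_authentic
from .genestruct import cluster_paralogs
from .synth import SyntheticDataset
from .tandem import detect_tandem


def precision_recall(predicted: set, truth: set) -> tuple[float, float]:
    """(precision, recall); empty sets are scored as perfect."""
    if not predicted and not truth:
        return 1.0, 1.0
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    return precision, recall


@dataclass
class RecoveryReport:
    enrichment_precision: float
    enrichment_recall: float
    tandem_precision: float
    tandem_recall: float
    paralog_ari: float
    pseudo_rejection_rate: float
    planted_pseudo_fraction: float
    n_genes: int


def enrichment_recovery(ds: SyntheticDataset) -> tuple[float, float]:
    """Authenticate -> census -> enrich, compared with planted calls."""
    authentic, _ = filter_authentic(ds.records)
    table = census_mod.build_census(authentic)
    result = census_mod.enrich(table)
    return precision_recall(set(result.enriched), set(ds.truth.enriched))


def tandem_recovery(
    ds: SyntheticDataset, max_intervening: int | None = None
) -> tuple[float, float]:
    """Tandem arrays on the authentic gene models vs planted arrays."""
    authentic_ids = {g.id for g in ds.genes if not g.pseudogene}
    models = [g.to_gene_model() for g in ds.genes if g.id in authentic_ids]
    families = {g.id: g.family for g in ds.genes if g.id in authentic_ids}
    arrays, _ = detect_tandem(models, families, max_intervening=max_intervening)
    predicted = {a.members for a in arrays}
    truth = {members for *_, members in ds.truth.tandem_arrays}
    return precision_recall(predicted, truth)


def paralog_recovery(ds: SyntheticDataset, tol_nt: int = 3, theta: float = 0.8) -> float:
    """ARI of structural paralog clustering against planted lineages.

    Clustering runs per species+family (the unit the analysis uses);
    labels are compared globally over all authentic genes.
    """
    groups: dict[tuple[str, str], list] = defaultdict(list)
    for g in ds.genes:
        if not g.pseudogene:
            groups[(g.species, g.family)].append(g.to_gene_model())
    predicted: dict[str, str] = {}
    for (species, family), models in sorted(groups.items()):
        labels = cluster_paralogs(models, tol_nt=tol_nt, theta=theta).labels()
        for gid, lab in labels.items():
            predicted[gid] = f"{species}|{family}|{lab}"
    ids = sorted(predicted)
    pred = [predicted[i] for i in ids]
    true = [ds.truth.paralog_clusters[i] for i in ids]
    return float(adjusted_rand_score(true, pred))


def pseudogene_rejection(ds: SyntheticDataset) -> tuple[float, float, bool]:
    """(rejected fraction, planted fraction, rejected ids == planted ids)."""
    _, rejected = filter_authentic(ds.records)
    rejected_ids = {rid for rid, _ in rejected}
    planted = set(ds.truth.pseudogenes)
    n = len(ds.genes)
    return len(rejected_ids) / n, len(planted) / n, rejected_ids == planted


def recovery_report(ds: SyntheticDataset, tol_nt: int = 3, theta: float = 0.8) -> RecoveryReport:
    ep, er = enrichment_recovery(ds)
    tp, tr = tandem_recovery(ds)
    ari = paralog_recovery(ds, tol_nt=tol_nt, theta=theta)
    rate, planted, _ = pseudogene_rejection(ds)
    return RecoveryReport(
        enrichment_precision=ep,
        enrichment_recall=er,
        tandem_precision=tp,
        tandem_recall=tr,
        paralog_ari=ari,
        pseudo_rejection_rate=rate,
        planted_pseudo_fraction=planted,
        n_genes=len(ds.genes),
    )
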