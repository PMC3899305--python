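"""Gene models, structure profiles, matching, clustering, intron summaries."""

from collections import Counter, defaultdict

import pytest
from hypothesis import given, settings, strategies as st

from cypfam.genestruct import (
    GeneModel,
    StructureProfile,
    cluster_paralogs,
    intron_summary,
    load_gene_models,
    ortholog_candidates,
    structure_profile,
    structure_similarity,
)


def gene(gid, exons, strand="+", species="Sp", scaffold="s1", plen=450):
    return GeneModel(
        gene_id=gid,
        species=species,
        scaffold=scaffold,
        strand=strand,
        exons=tuple(exons),
        protein_length=plen,
    )


def gene_from_lengths(gid, lengths, **kw):
    exons, pos = [], 0
    for ln in lengths:
        exons.append((pos, pos + ln))
        pos += ln + 100
    return gene(gid, exons, **kw)


class TestGffLoading:
    GFF = """##gff-version 3
s1\tsrc\tgene\t1\t300\t.\t+\t.\tID=gene:g1
s1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1;Parent=gene:g1;species=Sp
s1\tsrc\texon\t1\t300\t.\t+\t.\tParent=g1
s2\tsrc\tgene\t101\t600\t.\t-\t.\tID=gene:g2
s2\tsrc\tmRNA\t101\t600\t.\t-\t.\tID=g2;Parent=gene:g2;species=Sp
s2\tsrc\texon\t101\t200\t.\t-\t.\tParent=g2
s2\tsrc\texon\t401\t600\t.\t-\t.\tParent=g2
"""

    def test_coordinates_and_strand(self, tmp_path):
        path = tmp_path / "t.gff3"
        path.write_text(self.GFF)
        models = {m.gene_id: m for m in load_gene_models(path)}
        assert models["g1"].exons == ((0, 300),)
        assert structure_profile(models["g1"]).n_introns == 0
        # minus strand: genomically-last exon comes first in the profile
        assert models["g2"].exons == ((100, 200), (400, 600))
        assert structure_profile(models["g2"]).exon_lengths == (200, 100)

    def test_malformed_models_reported(self, tmp_path):
        bad = self.GFF.replace("s1\tsrc\texon\t1\t300\t.\t+\t.\tParent=g1\n", "")
        path = tmp_path / "bad.gff3"
        path.write_text(bad + "s3\tsrc\tmRNA\t1\t9\t.\t.\t.\tID=g3;species=Sp\n")
        with pytest.raises(ValueError) as exc:
            load_gene_models(path)
        assert "g1" in str(exc.value)

    def test_cds_length_consistency_warns(self, tmp_path):
        path = tmp_path / "c.gff3"
        path.write_text(
            "##gff-version 3\n"
            "s1\tsrc\tmRNA\t1\t300\t.\t+\t.\tID=g1;species=Sp;protein_length=50\n"
            "s1\tsrc\tCDS\t1\t300\t.\t+\t0\tParent=g1\n"
        )
        with pytest.warns(UserWarning, match="CDS length"):
            load_gene_models(path)

    def test_synthetic_round_trip(self, dataset_bundle, tmp_path):
        ds, paths = dataset_bundle
        lengths = {g.id: g.protein_length for g in ds.genes}
        models = {m.gene_id: m for m in load_gene_models(paths["gff3"], protein_lengths=lengths)}
        assert set(models) == {g.id for g in ds.genes}
        for g in ds.genes:
            assert structure_profile(models[g.id]).exon_lengths == g.exon_lengths_tx


class TestProfiles:
    def test_offsets_are_cumulative_exon_lengths(self):
        prof = structure_profile(gene_from_lengths("g", [100, 200, 300]))
        assert prof.n_introns == 2
        assert prof.intron_offsets == (100, 300)

    def test_single_exon(self):
        prof = structure_profile(gene_from_lengths("g", [900]))
        assert prof.n_introns == 0 and prof.intron_offsets == ()

    def test_strand_invariance_under_coordinate_mirroring(self):
        plus = gene("g", [(0, 100), (200, 450)], strand="+")
        span = 450
        mirrored = sorted((span - e, span - s) for s, e in plus.exons)
        minus = gene("g", mirrored, strand="-")
        assert structure_profile(plus) == structure_profile(minus)

    def test_planted_duplicates_have_identical_profiles(self, default_dataset):
        by_id = {g.id: g for g in default_dataset.genes}
        for g in default_dataset.genes:
            if g.ancestor_id:
                assert g.exon_lengths_tx == by_id[g.ancestor_id].exon_lengths_tx


class TestSimilarity:
    def test_identical_profiles_score_one(self):
        a = structure_profile(gene_from_lengths("a", [100, 200]))
        m = structure_similarity(a, a)
        assert m.score == 1.0 and m.same_structure

    def test_tolerance_absorbs_one_codon(self):
        a = structure_profile(gene_from_lengths("a", [100, 200, 300]))
        b = structure_profile(gene_from_lengths("b", [100, 203, 300]))
        assert structure_similarity(a, b, tol_nt=3).score == 1.0

    def test_unequal_intron_counts_score_zero(self):
        a = structure_profile(gene_from_lengths("a", [100, 200, 300]))
        b = structure_profile(gene_from_lengths("b", [100, 200, 150, 150]))
        m = structure_similarity(a, b)
        assert m.score == 0.0 and not m.same_structure

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(30, 500), min_size=1, max_size=8),
        b=st.lists(st.integers(30, 500), min_size=1, max_size=8),
    )
    def test_symmetric_reflexive_bounded(self, a, b):
        def prof(lengths):
            offs, cum = [], 0
            for ln in lengths[:-1]:
                cum += ln
                offs.append(cum)
            return StructureProfile(tuple(lengths), tuple(offs))

        pa, pb = prof(a), prof(b)
        ab = structure_similarity(pa, pb)
        ba = structure_similarity(pb, pa)
        assert ab.score == ba.score and ab.same_structure == ba.same_structure
        assert 0.0 <= ab.score <= 1.0
        assert structure_similarity(pa, pa).score == 1.0
        if ab.same_structure:
            assert pa.n_introns == pb.n_introns


class TestClustering:
    def test_single_linkage_chains(self):
        a = gene_from_lengths("a", [100, 100])
        b = gene_from_lengths("b", [103, 103])
        c = gene_from_lengths("c", [106, 106])
        result = cluster_paralogs([a, b, c], tol_nt=3, theta=0.8)
        assert result.clusters == [("a", "b", "c")]
        assert result.singletons == []

    def test_no_matches_means_no_groups(self):
        genes = [
            gene_from_lengths("a", [100]),
            gene_from_lengths("b", [100, 100]),
            gene_from_lengths("c", [100, 100, 100]),
        ]
        result = cluster_paralogs(genes)
        assert result.clusters == [] and result.singletons == ["a", "b", "c"]

    def test_eightfold_duplication_recovered(self):
        """One ancestor duplicated eight times clusters as a 9-gene group."""
        from cypfam import synth

        cfg = synth.SyntheticConfig(
            species=("SpA",),
            family_counts={"CYP9001": {"SpA": 9}},
            pseudo_fraction=0.0,
            seed=3,
        )
        ds = synth.generate(cfg)
        result = cluster_paralogs([g.to_gene_model() for g in ds.genes])
        assert len(result.clusters) == 1 and len(result.clusters[0]) == 9


class TestOrthologs:
    def test_cross_species_pairs_only(self):
        a = gene_from_lengths("a", [100, 200], species="SpA")
        b = gene_from_lengths("b", [100, 200], species="SpA")
        c = gene_from_lengths("c", [100, 200], species="SpB")
        pairs = {(m.gene_a, m.gene_b) for m in ortholog_candidates([a, b, c])}
        assert pairs == {("a", "c"), ("b", "c")}

    def test_disjoint_intron_counts_empty(self):
        a = gene_from_lengths("a", [100, 200], species="SpA")
        c = gene_from_lengths("c", [300], species="SpB")
        assert ortholog_candidates([a, c]) == []

    def test_one_gene_matching_five_gene_cluster(self):
        lone = gene_from_lengths("a1", [120, 240], species="SpA")
        cluster = [
            gene_from_lengths(f"b{i}", [120, 240], species="SpB") for i in range(5)
        ]
        pairs = ortholog_candidates([lone] + cluster)
        assert sum(1 for m in pairs if "a1" in (m.gene_a, m.gene_b)) == 5

    def test_planted_ortholog_pairs_reported(self, default_dataset):
        ds = default_dataset
        by_family = defaultdict(list)
        for g in ds.genes:
            if not g.pseudogene:
                by_family[g.family].append(g.to_gene_model())
        reported = set()
        for fam, models in by_family.items():
            for m in ortholog_candidates(models):
                reported.add((m.gene_a, m.gene_b))
                reported.add((m.gene_b, m.gene_a))
        assert ds.truth.ortholog_pairs, "default config should seed orthologs"
        for a, b in ds.truth.ortholog_pairs:
            assert (a, b) in reported


class TestIntronSummary:
    def test_modal_count(self):
        genes = [
            gene_from_lengths("a", [30] * 14),  # 13 introns
            gene_from_lengths("b", [30] * 14),
            gene_from_lengths("c", [30] * 10),  # 9 introns
        ]
        s = intron_summary(genes)
        assert (s.min_introns, s.max_introns) == (9, 13)
        assert s.p_over_i == (2, 13)
        assert s.min_max_str() == "9-13" and s.p_over_i_str() == "2/13"

    def test_short_proteins_excluded(self):
        genes = [
            gene_from_lengths("a", [30] * 11, plen=450),
            gene_from_lengths("b", [30] * 8, plen=350),
        ]
        s = intron_summary(genes)
        assert s.qualifying_counts == (10,)
        assert s.min_introns == s.max_introns == 10
        assert s.p_over_i == (1, 10)

    def test_all_short_is_na(self):
        s = intron_summary([gene_from_lengths("a", [30] * 5, plen=200)])
        assert s.is_na and s.min_max_str() == "NA" and s.p_over_i_str() == "NA"

    def test_tied_modes_all_listed_smallest_canonical(self):
        genes = [
            gene_from_lengths(f"g{i}", [30] * (k + 1))
            for i, k in enumerate([15, 15, 12, 12, 11, 11])
        ]
        s = intron_summary(genes)
        assert s.modes == ((2, 15), (2, 12), (2, 11))
        assert s.p_over_i == (2, 11)
        assert s.p_over_i_str() == "2/15;2/12;2/11"

    def test_matches_brute_force_on_synthetic_data(self, default_dataset):
        groups = defaultdict(list)
        for g in default_dataset.genes:
            if not g.pseudogene:
                groups[(g.species, g.family)].append(g)
        for (species, family), members in groups.items():
            s = intron_summary([g.to_gene_model() for g in members])
            counts = [
                len(g.exon_lengths_tx) - 1
                for g in members
                if g.protein_length >= 400
            ]
            if not counts:
                assert s.is_na
                continue
            assert s.min_introns == min(counts)
            assert s.max_introns == max(counts)
            tally = Counter(counts)
            best = max(tally.values())
            assert s.p_over_i == (best, min(i for i, p in tally.items() if p == best))
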