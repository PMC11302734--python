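"""Normalization, aggregation, richness and taxon-sharing behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gutpair.containers import AbundanceTable, AnnotationMap
from gutpair.exceptions import ValidationError
from gutpair.profiling import (
    aggregate_rank,
    gene_richness,
    normalize_relative,
    shared_exclusive_taxa,
    site_mean_abundance,
    top_n_taxa,
)

from conftest import random_table


def table_of(columns: dict, level="gene", normalized=False) -> AbundanceTable:
    frame = pd.DataFrame(columns)
    frame.index = [f"f{i}" for i in range(len(frame))]
    return AbundanceTable(frame, level=level, normalized=normalized)


class TestNormalize:
    def test_plain_column_normalization(self):
        t = normalize_relative(table_of({"s1": [2.0, 2.0, 4.0]}))
        assert np.allclose(t.data["s1"], [0.25, 0.25, 0.5])
        assert t.normalized

    def test_zero_column_preserved(self, caplog):
        with caplog.at_level("WARNING", logger="gutpair.profiling"):
            t = normalize_relative(table_of({"s1": [0.0, 0.0], "s2": [1.0, 3.0]}))
        assert (t.data["s1"] == 0).all()
        assert np.allclose(t.data["s2"], [0.25, 0.75])
        assert "all-zero" in caplog.text

    def test_single_feature_identity(self):
        t = normalize_relative(table_of({"s1": [5.0]}))
        assert t.data.iloc[0, 0] == 1.0

    def test_length_normalization(self):
        counts = table_of({"s1": [10.0, 10.0]})
        lengths = pd.Series([1000.0, 500.0], index=["f0", "f1"])
        t = normalize_relative(counts, gene_lengths=lengths)
        # per-bp rates 0.01 and 0.02 -> shares 1/3, 2/3
        assert np.allclose(t.data["s1"], [1 / 3, 2 / 3])

    def test_zero_length_rejected(self):
        counts = table_of({"s1": [1.0, 1.0]})
        lengths = pd.Series([100.0, 0.0], index=["f0", "f1"])
        with pytest.raises(ValidationError):
            normalize_relative(counts, gene_lengths=lengths)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        t = random_table(np.random.default_rng(seed), normalize=False)
        once = normalize_relative(t)
        twice = normalize_relative(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)


def toy_annotation() -> AnnotationMap:
    taxonomy = pd.DataFrame(
        {
            "phylum": ["p1", "p1", "p2", "p2"],
            "genus": ["gA", "gA", "gB", "gB"],
            "species": ["sA1", "sA1", "sB1", "unclassified"],
        },
        index=pd.Index(["f0", "f1", "f2", "f3"], name="gene"),
    )
    gene_kos = {"f0": ("K1", "K2"), "f1": ("K1",), "f2": (), "f3": ("K2",)}
    return AnnotationMap(taxonomy=taxonomy, gene_kos=gene_kos)


class TestAggregate:
    def test_genus_additivity(self):
        t = table_of({"s1": [0.3, 0.2, 0.4, 0.1]}, normalized=True)
        genus = aggregate_rank(t, toy_annotation(), "genus")
        assert genus.data.loc["gA", "s1"] == pytest.approx(0.5)
        assert genus.data.loc["gB", "s1"] == pytest.approx(0.5)

    def test_unclassified_emitted_as_row(self):
        t = table_of({"s1": [0.3, 0.2, 0.4, 0.1]}, normalized=True)
        species = aggregate_rank(t, toy_annotation(), "species")
        assert species.data.loc["unclassified", "s1"] == pytest.approx(0.1)

    def test_all_unclassified_collapses_to_one_row(self):
        ann = toy_annotation()
        tax = ann.taxonomy.copy()
        tax["species"] = "unclassified"
        ann = AnnotationMap(taxonomy=tax, gene_kos=ann.gene_kos)
        t = table_of({"s1": [0.25, 0.25, 0.25, 0.25]}, normalized=True)
        species = aggregate_rank(t, ann, "species")
        assert list(species.data.index) == ["unclassified"]
        assert species.data.iloc[0, 0] == pytest.approx(1.0)

    def test_ko_multimapping_duplicates_mass(self):
        t = table_of({"s1": [0.3, 0.2, 0.4, 0.1]}, normalized=True)
        kos = aggregate_rank(t, toy_annotation(), "KO")
        assert kos.data.loc["K1", "s1"] == pytest.approx(0.5)  # f0 + f1
        assert kos.data.loc["K2", "s1"] == pytest.approx(0.4)  # f0 + f3
        # total exceeds 1: a 2-KO gene contributes its mass to each KO
        assert kos.data["s1"].sum() > 0.8

    def test_mass_conservation_random_tables(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            t = random_table(rng, n_features=50, n_samples=8)
            genes = [f"gene{i}" for i in range(50)]
            t.data.index = genes
            taxonomy = pd.DataFrame(
                {
                    "phylum": rng.choice(["p1", "p2"], 50),
                    "genus": rng.choice(["gA", "gB", "gC"], 50),
                    "species": rng.choice(["s1", "s2", "unclassified"], 50),
                },
                index=pd.Index(genes, name="gene"),
            )
            # keep nesting consistent: derive genus from species, phylum from genus
            taxonomy["genus"] = taxonomy["species"].map(
                {"s1": "gA", "s2": "gB", "unclassified": "gC"}
            )
            taxonomy["phylum"] = taxonomy["genus"].map({"gA": "p1", "gB": "p2", "gC": "p2"})
            ann = AnnotationMap(taxonomy=taxonomy, gene_kos={})
            for rank in ("phylum", "genus", "species"):
                agg = aggregate_rank(t, ann, rank)
                assert np.allclose(
                    agg.data.sum(axis=0), t.data.sum(axis=0), atol=1e-12
                )

    def test_unknown_gene_rejected(self):
        t = table_of({"s1": [1.0, 1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValidationError, match="missing from annotation"):
            aggregate_rank(t, toy_annotation(), "genus")


class TestRichness:
    def test_counts_nonzeros(self):
        t = table_of({"s1": [0.0, 0.1, 0.9]}, normalized=True)
        assert gene_richness(t, "s1") == 2

    def test_zero_column(self):
        t = table_of({"s1": [0.0, 0.0]})
        assert gene_richness(t, "s1") == 0

    def test_unknown_sample(self):
        t = table_of({"s1": [1.0]})
        with pytest.raises(ValidationError):
            gene_richness(t, "nope")

    def test_invariant_under_rescaling(self):
        rng = np.random.default_rng(8)
        t = random_table(rng, normalize=False)
        t.data.iloc[::3, :] = 0.0
        scaled = AbundanceTable(t.data * 7.5, level=t.level)
        for s in t.sample_ids:
            assert gene_richness(t, s) == gene_richness(scaled, s)


def paired_metadata(n=3) -> pd.DataFrame:
    rows = []
    for i in range(n):
        for site in ("mucosa", "feces"):
            rows.append(
                dict(sample_id=f"sub{i}_{site}", subject_id=f"sub{i}", site=site,
                     age=50, gender="male", bmi=22.0, polyp_group=2)
            )
    return pd.DataFrame(rows).set_index("sample_id")


class TestSharedExclusive:
    def test_set_partition(self):
        md = paired_metadata(1)
        frame = pd.DataFrame(
            {"sub0_mucosa": [0.5, 0.5, 0.0], "sub0_feces": [0.4, 0.3, 0.3]},
            index=["A", "B", "C"],
        )
        t = AbundanceTable(frame, level="genus")
        shared, excl_m, excl_f = shared_exclusive_taxa(t, md)
        assert shared == {"A", "B"}
        assert excl_m == set()
        assert excl_f == {"C"}

    def test_identical_sites_all_shared(self):
        md = paired_metadata(1)
        frame = pd.DataFrame(
            {"sub0_mucosa": [0.5, 0.5], "sub0_feces": [0.5, 0.5]}, index=["A", "B"]
        )
        shared, excl_m, excl_f = shared_exclusive_taxa(AbundanceTable(frame, level="genus"), md)
        assert shared == {"A", "B"} and not excl_m and not excl_f

    def test_partition_covers_all_present(self, default_dataset):
        from gutpair.profiling import aggregate_rank

        genus = aggregate_rank(default_dataset.table, default_dataset.annotation, "genus")
        shared, excl_m, excl_f = shared_exclusive_taxa(genus, default_dataset.metadata)
        present = set(genus.data.index[(genus.data > 0).any(axis=1)])
        assert shared | excl_m | excl_f == present
        assert shared.isdisjoint(excl_m) and shared.isdisjoint(excl_f)
        assert excl_m.isdisjoint(excl_f)

    def test_planted_mucosa_exclusives_recovered(self, default_dataset):
        from gutpair.profiling import aggregate_rank

        genus = aggregate_rank(default_dataset.table, default_dataset.annotation, "genus")
        _, excl_m, _ = shared_exclusive_taxa(genus, default_dataset.metadata)
        assert excl_m == set(default_dataset.truth.exclusive_mucosa)


class TestTopN:
    def test_sorting(self):
        md = paired_metadata(1)
        frame = pd.DataFrame(
            {"sub0_mucosa": [0.5, 0.3, 0.2], "sub0_feces": [0.1, 0.2, 0.7]},
            index=["A", "B", "C"],
        )
        t = AbundanceTable(frame, level="genus")
        assert top_n_taxa(t, md, "mucosa", 2) == ["A", "B"]
        assert top_n_taxa(t, md, "feces", 1) == ["C"]

    def test_tie_breaks_lexicographic(self):
        md = paired_metadata(1)
        frame = pd.DataFrame(
            {"sub0_mucosa": [0.25, 0.25, 0.25, 0.25], "sub0_feces": [0.25] * 4},
            index=["d", "b", "c", "a"],
        )
        t = AbundanceTable(frame, level="genus")
        assert top_n_taxa(t, md, "mucosa", 4) == ["a", "b", "c", "d"]

    def test_n_larger_than_taxa_returns_all(self):
        md = paired_metadata(1)
        frame = pd.DataFrame({"sub0_mucosa": [0.6, 0.4], "sub0_feces": [0.5, 0.5]},
                             index=["A", "B"])
        assert len(top_n_taxa(AbundanceTable(frame, level="genus"), md, "mucosa", 10)) == 2

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        md = paired_metadata(4)
        t = random_table(rng, n_features=30, n_samples=8, level="genus")
        t.data.columns = md.index
        got = top_n_taxa(t, md, "feces", 10)
        means = t.data[[c for c in md.index if c.endswith("feces")]].mean(axis=1)
        expect = sorted(means.index, key=lambda f: (-means[f], f))[:10]
        assert got == expect


def test_site_mean_abundance_missing_feature_rejected(default_dataset):
    with pytest.raises(ValidationError):
        site_mean_abundance(default_dataset.table, default_dataset.metadata,
                            features=["not_a_gene"])
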