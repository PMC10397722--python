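import numpy as np
import pandas as pd
import pytest

from orthoclass.datamodel import ExpressionMatrix, GeneAnnotation
from orthoclass.orthology import (
    FeatureSpace,
    OrthologTable,
    OrthologyError,
    build_feature_space,
    filter_one_to_one,
    filter_protein_coding,
    project_to_feature_space,
    read_feature_space,
    read_ortholog_table,
    write_feature_space,
)
from orthoclass.simulate import SimulationConfig, generate_ortholog_table


def _table(rows):
    frame = pd.DataFrame(
        rows,
        columns=[
            "human_gene_id",
            "human_gene_name",
            "canine_gene_id",
            "canine_gene_name",
            "homology_type",
        ],
    )
    return OrthologTable(frame=frame)


def _row(h, c, kind="ortholog_one2one"):
    return (h, f"n_{h}", c, f"n_{c}", kind)


HEADER = "human_gene_id\thuman_gene_name\tcanine_gene_id\tcanine_gene_name\thomology_type\n"


class TestReadOrthologTable:
    def test_parse_three_rows(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text(
            HEADER
            + "ENSG1\tA\tENSCAFG1\ta\tortholog_one2one\n"
            + "ENSG2\tB\tENSCAFG2\tb\tortholog_one2one\n"
            + "ENSG3\tC\tENSCAFG3\tc\tortholog_one2many\n"
        )
        table = read_ortholog_table(path)
        assert len(table) == 3

    def test_version_suffix_stripped(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text(
            HEADER + "ENSG00000141510.17\tTP53\tENSCAFG0001.2\ttp53\tortholog_one2one\n"
        )
        table = read_ortholog_table(path)
        assert table.frame.loc[0, "human_gene_id"] == "ENSG00000141510"
        assert table.frame.loc[0, "canine_gene_id"] == "ENSCAFG0001"

    def test_missing_homology_type_column(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text(
            "human_gene_id\thuman_gene_name\tcanine_gene_id\tcanine_gene_name\n"
            "ENSG1\tA\tENSCAFG1\ta\n"
        )
        with pytest.raises(OrthologyError, match="homology_type"):
            read_ortholog_table(path)

    def test_empty_data_section_is_empty_table(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text(HEADER)
        assert len(read_ortholog_table(path)) == 0

    def test_biomart_headers_accepted(self, tmp_path):
        path = tmp_path / "orth.tsv"
        path.write_text(
            "Gene stable ID\tGene name\tDog gene stable ID\tDog gene name\t"
            "Dog homology type\nENSG1\tA\tENSCAFG1\ta\tortholog_one2one\n"
        )
        table = read_ortholog_table(path)
        assert table.frame.loc[0, "canine_gene_id"] == "ENSCAFG1"


class TestFilterOneToOne:
    def test_mislabeled_duplicate_dropped(self):
        # one human gene paired with two canine genes despite one2one labels
        table = _table([_row("h1", "c1"), _row("h1", "c2"), _row("h2", "c3")])
        kept = filter_one_to_one(table)
        assert kept.frame["human_gene_id"].tolist() == ["h2"]

    def test_disjoint_pairs_unchanged(self):
        table = _table([_row("h1", "c1"), _row("h2", "c2"), _row("h3", "c3")])
        kept = filter_one_to_one(table)
        assert len(kept) == 3

    def test_one2many_rows_dropped(self):
        table = _table([_row("h1", "c1"), _row("h2", "c2", "ortholog_one2many")])
        assert len(filter_one_to_one(table)) == 1

    def test_idempotent(self):
        table = _table(
            [_row("h1", "c1"), _row("h1", "c2"), _row("h2", "c3"), _row("h3", "c3")]
        )
        once = filter_one_to_one(table)
        twice = filter_one_to_one(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_generator_ground_truth_count(self):
        config = SimulationConfig(
            class_names=("A", "B"),
            samples_per_class_a={"A": 3, "B": 3},
            samples_per_class_b={"A": 3, "B": 3},
            n_genes_one_to_one=250,
            n_genes_one_to_many=30,
            n_signature_genes_per_class=5,
            seed=1,
        )
        table, _, _ = generate_ortholog_table(config)
        assert len(filter_one_to_one(table)) == 250


class TestFilterProteinCoding:
    def _annotation(self, mapping):
        return GeneAnnotation(
            gene_ids=list(mapping),
            length_bp=np.full(len(mapping), 1000),
            biotype=list(mapping.values()),
        )

    def test_seven_of_ten_kept(self):
        rows = [_row(f"h{i}", f"c{i}") for i in range(10)]
        ann = self._annotation(
            {f"h{i}": "protein_coding" if i < 7 else "lncRNA" for i in range(10)}
        )
        kept = filter_protein_coding(_table(rows), ann)
        assert len(kept) == 7

    def test_all_non_coding_gives_empty_then_build_error(self):
        rows = [_row("h1", "c1"), _row("h2", "c2")]
        ann = self._annotation({"h1": "lncRNA", "h2": "miRNA"})
        kept = filter_protein_coding(_table(rows), ann)
        assert len(kept) == 0
        with pytest.raises(OrthologyError):
            build_feature_space(kept)

    def test_missing_gene_dropped_with_warning(self, caplog):
        rows = [_row("h1", "c1"), _row("h2", "c2")]
        ann = self._annotation({"h1": "protein_coding"})
        import logging

        with caplog.at_level(logging.WARNING):
            kept = filter_protein_coding(_table(rows), ann)
        assert len(kept) == 1
        assert any("absent from annotation" in r.message for r in caplog.records)

    def test_annotation_authoritative_over_table_biotype(self):
        frame = pd.DataFrame(
            [
                ("h1", "n", "c1", "n", "ortholog_one2one", "protein_coding"),
            ],
            columns=[
                "human_gene_id",
                "human_gene_name",
                "canine_gene_id",
                "canine_gene_name",
                "homology_type",
                "human_biotype",
            ],
        )
        ann = self._annotation({"h1": "lncRNA"})
        assert len(filter_protein_coding(OrthologTable(frame=frame), ann)) == 0

    def test_composition_idempotent(self):
        rows = [_row(f"h{i}", f"c{i}") for i in range(6)] + [
            _row("h0", "cx"),  # breaks h0 uniqueness
        ]
        ann = self._annotation({f"h{i}": "protein_coding" for i in range(6)})
        once = filter_protein_coding(filter_one_to_one(_table(rows)), ann)
        twice = filter_protein_coding(filter_one_to_one(once), ann)
        pd.testing.assert_frame_equal(once.frame, twice.frame)


class TestFeatureSpace:
    def test_sort_rule_and_canine_map(self):
        table = _table([_row("hB", "cX"), _row("hA", "cY")])
        fs = build_feature_space(table)
        assert list(fs.human_ids) == ["hA", "hB"]
        assert fs.canine_to_index == {"cY": 0, "cX": 1}

    def test_size_equals_row_count(self):
        table = _table([_row(f"h{i}", f"c{i}") for i in range(9)])
        assert len(build_feature_space(table)) == 9

    def test_bijection_round_trip(self):
        table = _table([_row(f"h{i:02d}", f"c{i:02d}") for i in range(12)])
        fs = build_feature_space(table)
        for i, canine in enumerate(fs.canine_ids):
            assert fs.canine_to_index[canine] == i

    def test_duplicate_after_strip_rejected(self):
        table = _table([_row("h1", "c1"), _row("h1", "c2")])
        with pytest.raises(OrthologyError):
            build_feature_space(table)

    def test_fingerprint_depends_on_order_content(self):
        a = FeatureSpace(("hA", "hB"), ("c1", "c2"))
        b = FeatureSpace(("hA", "hC"), ("c1", "c2"))
        assert a.fingerprint() != b.fingerprint()

    def test_tsv_round_trip(self, tmp_path):
        fs = build_feature_space(_table([_row(f"h{i}", f"c{i}") for i in range(5)]))
        path = tmp_path / "fs.tsv"
        write_feature_space(fs, path)
        back = read_feature_space(path)
        assert back.human_ids == fs.human_ids
        assert back.canine_ids == fs.canine_ids


class TestProjection:
    def _fs(self, n=4):
        return build_feature_space(_table([_row(f"h{i}", f"c{i}") for i in range(n)]))

    def _canine_matrix(self, genes, n_samples=3, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            gene_ids=genes,
            sample_ids=[f"s{j}" for j in range(n_samples)],
            values=rng.normal(size=(len(genes), n_samples)),
            unit="log10_tpm",
            species="canine",
        )

    def test_canine_projection_drops_unmapped(self):
        fs = self._fs(4)
        genes = [f"c{i}" for i in range(4)] + [f"extra{i}" for i in range(50)]
        m = self._canine_matrix(genes)
        out = project_to_feature_space(m, fs)
        assert out.n_genes == 4
        assert out.gene_ids == list(fs.human_ids)
        assert out.species == "canine"

    def test_missing_feature_gene_named(self):
        fs = self._fs(4)
        m = ExpressionMatrix(
            ["h0", "h1", "h2"],
            ["s0"],
            np.zeros((3, 1)),
            "log10_tpm",
            "human",
        )
        with pytest.raises(OrthologyError, match="h3"):
            project_to_feature_space(m, fs)

    def test_values_and_sample_order_bit_exact(self):
        fs = self._fs(4)
        genes = ["c3", "c1", "c0", "c2", "junk"]
        m = self._canine_matrix(genes, n_samples=5, seed=9)
        out = project_to_feature_space(m, fs)
        assert out.sample_ids == m.sample_ids
        for i, h in enumerate(fs.human_ids):
            c = fs.canine_ids[i]
            src = m.gene_ids.index(c)
            assert np.array_equal(out.values[i], m.values[src])

    def test_counts_unit_rejected(self):
        fs = self._fs(2)
        m = ExpressionMatrix(
            ["c0", "c1"], ["s0"], np.ones((2, 1)), "counts", "canine"
        )
        with pytest.raises(OrthologyError, match="unit"):
            project_to_feature_space(m, fs)


class TestFeatureSpaceSizeInvariant:
    @pytest.mark.parametrize("n11,fpc", [(100, 0.9), (251, 0.73), (60, 1.0)])
    def test_size_formula(self, n11, fpc):
        config = SimulationConfig(
            class_names=("A", "B"),
            samples_per_class_a={"A": 3, "B": 3},
            samples_per_class_b={"A": 3, "B": 3},
            n_genes_one_to_one=n11,
            fraction_protein_coding=fpc,
            n_signature_genes_per_class=5,
            seed=2,
        )
        table, ann_a, _ = generate_ortholog_table(config)
        fs = build_feature_space(
            filter_protein_coding(filter_one_to_one(table), ann_a)
        )
        assert len(fs) == round(n11 * fpc)
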