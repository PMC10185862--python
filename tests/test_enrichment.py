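import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicload import (
    AnnotationError,
    PathwayAnnotation,
    ValidationError,
    bin_to_colours,
    condition_contrast,
    export_kegg_overlay,
    overlay_palette,
    rank_genes,
    score_pathways,
    top_k_annotation_fraction,
)

from conftest import random_standardized


def scores_frame(mapping, component=2):
    """Gene-score table with a single PC column, as rank/score accept."""
    cols = {f"PC{k}": np.zeros(len(mapping)) for k in range(1, component)}
    cols[f"PC{component}"] = list(mapping.values())
    df = pd.DataFrame(cols, index=pd.Index(mapping.keys(), name="gene"))
    return df


def test_rank_genes_descending_by_loading():
    ranking = rank_genes(scores_frame({"g1": 0.5, "g2": -0.1, "g3": 0.3}), 2)
    assert ranking.gene_ids == ["g1", "g3", "g2"]


def test_rank_genes_breaks_ties_lexicographically():
    ranking = rank_genes(scores_frame({"gB": 0.5, "gA": 0.5, "gC": -1.0}), 2)
    assert ranking.gene_ids == ["gA", "gB", "gC"]


def test_rank_respects_component_argument():
    df = pd.DataFrame(
        {"PC1": [1.0, 0.0], "PC2": [0.0, 1.0]},
        index=pd.Index(["g1", "g2"], name="gene"),
    )
    assert rank_genes(df, 1).gene_ids == ["g1", "g2"]
    assert rank_genes(df, 2).gene_ids == ["g2", "g1"]


def test_invalid_component_rejected(std_matrix):
    from omicload import run_pca

    pca = run_pca(std_matrix, n_components=2)
    with pytest.raises(ValidationError, match="component"):
        rank_genes(pca, 3)


def test_top_k_fraction_counts_annotated_genes():
    loadings = {f"g{i:02d}": 1.0 - i * 0.01 for i in range(20)}
    ranking = rank_genes(scores_frame(loadings), 2)
    flagellar = [f"g{i:02d}" for i in (0, 1, 2, 4, 5, 7, 9)]  # 7 of the top 10
    ann = PathwayAnnotation.from_records(
        [(g, "map02040", "flagellar assembly") for g in flagellar]
        + [("g15", "map00650", "butanoate metabolism")]
    )
    fraction, hits = top_k_annotation_fraction(ranking, ann, {"map02040"}, 10)
    assert fraction == pytest.approx(0.7)
    assert hits["annotated"].sum() == 7
    assert set(hits.columns) == {"gene_id", "loading", "annotated", "pathways"}


def test_top_k_fraction_empty_target_set_is_zero(annotation):
    ranking = rank_genes(scores_frame({f"g{i:03d}": float(-i) for i in range(6)}), 2)
    fraction, _ = top_k_annotation_fraction(ranking, annotation, set(), 5)
    assert fraction == 0.0


def test_top_k_fraction_full_coverage_is_one(annotation):
    ranking = rank_genes(scores_frame({f"g{i:03d}": float(i) for i in range(6)}), 2)
    fraction, _ = top_k_annotation_fraction(
        ranking, annotation, {"pwA", "pwB"}, 6
    )
    assert fraction == 1.0


def test_top_k_larger_than_gene_count_rejected(annotation):
    ranking = rank_genes(scores_frame({"g000": 1.0}), 2)
    with pytest.raises(ValidationError, match="exceeds"):
        top_k_annotation_fraction(ranking, annotation, {"pwA"}, 2)


def test_top_k_fraction_monotone_in_pathway_sets(annotation):
    ranking = rank_genes(
        scores_frame({f"g{i:03d}": float(6 - i) for i in range(6)}), 2
    )
    small, _ = top_k_annotation_fraction(ranking, annotation, {"pwA"}, 4)
    big, _ = top_k_annotation_fraction(ranking, annotation, {"pwA", "pwB"}, 4)
    assert big >= small


# -- pathway scoring -------------------------------------------------------


def test_pathway_score_is_member_mean():
    ann = PathwayAnnotation.from_records([("g1", "P", "p"), ("g3", "P", "p")])
    table = score_pathways(
        scores_frame({"g1": 0.5, "g2": -0.1, "g3": 0.3}), 2, ann, min_size=1
    )
    assert table.score_of("P") == pytest.approx(0.4)


def test_min_size_excludes_small_pathways():
    ann = PathwayAnnotation.from_records(
        [("g1", "big", "b"), ("g2", "big", "b"), ("g3", "tiny", "t")]
    )
    table = score_pathways(
        scores_frame({"g1": 1.0, "g2": 0.0, "g3": 5.0}), 2, ann, min_size=2
    )
    assert table.table["pathway_id"].tolist() == ["big"]
    with pytest.raises(AnnotationError):
        table.rank_of("tiny")


def test_no_pathway_meets_min_size_rejected():
    ann = PathwayAnnotation.from_records([("g1", "P", "p")])
    with pytest.raises(AnnotationError, match="at least"):
        score_pathways(scores_frame({"g1": 1.0, "g2": 0.0}), 2, ann, min_size=2)


def test_absent_genes_do_not_contribute():
    ann = PathwayAnnotation.from_records(
        [("g1", "P", "p"), ("g2", "P", "p"), ("ghost", "P", "p")]
    )
    table = score_pathways(scores_frame({"g1": 1.0, "g2": 0.0}), 2, ann, min_size=1)
    assert table.table["n_genes"].iloc[0] == 2
    assert table.score_of("P") == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(20))
def test_scores_match_brute_force_mean_oracle(seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(60)]
    loadings = dict(zip(genes, rng.normal(size=60)))
    rows = []
    for p in range(6):
        members = rng.choice(genes, size=rng.integers(3, 15), replace=False)
        rows.extend((g, f"pw{p}", f"pw{p}") for g in members)
    ann = PathwayAnnotation.from_records(rows)
    table = score_pathways(scores_frame(loadings), 2, ann, min_size=3)
    for pid, members in ann.gene_sets().items():
        expected = math.fsum(loadings[g] for g in members) / len(members)
        assert table.score_of(pid) == pytest.approx(expected, abs=1e-12)


def test_adding_gene_at_current_mean_is_a_fixed_point():
    loadings = {"g1": 0.9, "g2": 0.1, "g3": 0.5}
    ann1 = PathwayAnnotation.from_records([("g1", "P", "p"), ("g2", "P", "p")])
    ann2 = PathwayAnnotation.from_records(
        [("g1", "P", "p"), ("g2", "P", "p"), ("g3", "P", "p")]
    )
    s1 = score_pathways(scores_frame(loadings), 2, ann1, min_size=1).score_of("P")
    s2 = score_pathways(scores_frame(loadings), 2, ann2, min_size=1).score_of("P")
    assert s1 == pytest.approx(0.5) and s2 == pytest.approx(s1)


def test_abs_mode_ranks_by_magnitude_keeping_signed_scores():
    loadings = {"g1": -1.0, "g2": -1.0, "g3": 0.4, "g4": 0.4}
    ann = PathwayAnnotation.from_records(
        [("g1", "neg", "n"), ("g2", "neg", "n"), ("g3", "pos", "p"), ("g4", "pos", "p")]
    )
    signed = score_pathways(scores_frame(loadings), 2, ann, min_size=1)
    magnitude = score_pathways(scores_frame(loadings), 2, ann, min_size=1, mode="abs_mean")
    assert signed.rank_of("pos") == 1 and signed.rank_of("neg") == 2
    assert magnitude.rank_of("neg") == 1
    assert magnitude.score_of("neg") == pytest.approx(-1.0)


# -- condition contrasts ---------------------------------------------------


def test_contrast_of_condition_with_itself_is_zero(std_matrix):
    c = condition_contrast(std_matrix, "LB20", "LB20")
    np.testing.assert_allclose(c.to_numpy(), 0.0)


def test_contrast_is_column_difference(std_matrix):
    c = condition_contrast(std_matrix, "LB20", "LB60", layer="transcript")
    expect = std_matrix.values[:, 0] - std_matrix.values[:, 2]
    np.testing.assert_allclose(c.to_numpy(), expect, atol=1e-12)


def test_contrast_antisymmetry(std_matrix):
    ab = condition_contrast(std_matrix, "LB20", "LB60")
    ba = condition_contrast(std_matrix, "LB60", "LB20")
    np.testing.assert_allclose(ab.to_numpy(), -ba.to_numpy(), atol=1e-12)


def test_contrast_unknown_condition_rejected(std_matrix):
    with pytest.raises(ValidationError):
        condition_contrast(std_matrix, "LB999", "LB60")


def test_log2_ratio_mode(small_matrix):
    c = condition_contrast(small_matrix, "LB20", "LB60", mode="log2_ratio")
    a = small_matrix.values[:, 0]
    b = small_matrix.values[:, 2]
    np.testing.assert_allclose(c.to_numpy(), np.log2((a + 1) / (b + 1)), atol=1e-12)


# -- overlay binning -------------------------------------------------------


def test_zero_contrast_lands_in_centre_bin():
    ov = bin_to_colours(pd.Series({"g1": 0.0}), n_bins=11, clip=2.0)
    assert ov.table["bin"].iloc[0] == 5


@pytest.mark.parametrize("value,expected", [(2.0, 10), (5.0, 10), (-2.0, 0), (-9.0, 0)])
def test_clipped_extremes_land_in_outermost_bins(value, expected):
    ov = bin_to_colours(pd.Series({"g": value}), n_bins=11, clip=2.0)
    assert ov.table["bin"].iloc[0] == expected


@given(st.lists(st.floats(-3, 3, allow_nan=False), min_size=1, max_size=30))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_negating_contrasts_mirrors_bins(values):
    s = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
    fwd = bin_to_colours(s, n_bins=11, clip=2.0).table["bin"]
    rev = bin_to_colours(-s, n_bins=11, clip=2.0).table["bin"]
    assert ((fwd + rev) == 10).all()


def test_even_bin_count_rejected():
    with pytest.raises(ValidationError, match="odd"):
        bin_to_colours(pd.Series({"g": 0.0}), n_bins=10)


def test_palette_runs_blue_to_red_through_yellow():
    palette = overlay_palette(11)
    assert palette[0] == "#0000ff"
    assert palette[-1] == "#ff0000"
    assert palette[5].lower() == "#ffff00"


def test_overlay_export_round_trips(tmp_path):
    ov = bin_to_colours(
        pd.Series({"g1": -3.0, "g2": 0.0, "g3": 3.0}), n_bins=5, clip=1.0
    )
    path = tmp_path / "colors.txt"
    export_kegg_overlay(ov, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("#gene_id")
    parsed = dict(line.split("\t") for line in lines[1:])
    assert parsed == dict(zip(ov.table["gene_id"], ov.table["colour"]))


def test_empty_overlay_writes_header_and_warns(tmp_path):
    ov = bin_to_colours(pd.Series(dtype=float), n_bins=5, clip=1.0)
    path = tmp_path / "colors.txt"
    with pytest.warns(UserWarning, match="empty overlay"):
        export_kegg_overlay(ov, path)
    assert path.read_text().splitlines() == ["#gene_id\tcolour"]
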