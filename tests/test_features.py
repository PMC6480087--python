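"""Tests for SACF/TNF/HACF featurization and the Wilcoxon selection stage."""

import numpy as np
import pandas as pd
import pytest

from hacf import (
    DNASequence,
    FeatureRecipe,
    feature_matrix,
    hacf_features,
    sacf_features,
    tnf_features,
    wilcoxon_select,
)
from hacf.features import (
    SchemaError,
    read_feature_matrix,
    sacf_names,
    write_feature_matrix,
)
from hacf.sequence_io import reverse_complement


def _rand_seq(rng, L=1000, sid="s"):
    return DNASequence(sid, "".join("ACGT"[i] for i in rng.integers(0, 4, size=L)))


def test_sacf_window_is_17_to_500_at_1kb():
    names = sacf_names(1000)
    assert len(names) == 484
    assert names[0] == "acf_17" and names[-1] == "acf_500"


def test_sacf_features_dimension_and_names():
    fv = sacf_features(_rand_seq(np.random.default_rng(0)))
    assert len(fv.values) == 484
    assert fv.names[:2] == ("acf_17", "acf_18")


def test_sacf_homopolymer_is_all_ones():
    fv = sacf_features(DNASequence("h", "A" * 1000))
    assert np.all(fv.values == 1.0)


def test_sacf_reverse_complement_invariance():
    seq = _rand_seq(np.random.default_rng(1), sid="fwd")
    rc = DNASequence("rc", reverse_complement(seq.bases))
    assert np.array_equal(sacf_features(seq).values, sacf_features(rc).values)


def test_sacf_rejects_nonstandard_length():
    with pytest.raises(ValueError):
        sacf_features(DNASequence("s", "ACGT" * 100), seq_len=1000)


def test_tnf_single_window():
    fv = tnf_features(DNASequence("g", "GGGG"))
    assert len(fv.values) == 256
    s = fv.as_series()
    assert s["tnf_GGGG"] == 1.0 and s.drop("tnf_GGGG").sum() == 0.0


def test_tnf_homopolymer_and_normalization():
    fv = tnf_features(DNASequence("a", "AAAAA"))
    assert fv.as_series()["tnf_AAAA"] == 1.0
    rng = np.random.default_rng(2)
    fv = tnf_features(_rand_seq(rng, L=500))
    assert fv.values.sum() == pytest.approx(1.0)
    assert np.all(fv.values >= 0) and np.all(fv.values <= 1)


def test_tnf_too_short_rejected():
    with pytest.raises(ValueError):
        tnf_features(DNASequence("s", "ACG"))


def test_hacf_dimensions():
    rng = np.random.default_rng(3)
    seq = _rand_seq(rng)
    all_names = sacf_names(1000)
    kept209 = tuple(all_names[i] for i in sorted(rng.choice(484, size=209, replace=False)))
    assert len(hacf_features(seq, kept209).values) == 465
    assert len(hacf_features(seq, ()).values) == 256  # pure TNF mode
    assert len(hacf_features(seq, tuple(all_names)).values) == 740


def test_hacf_unknown_name_rejected():
    with pytest.raises(SchemaError):
        hacf_features(_rand_seq(np.random.default_rng(4)), ("acf_9999",))


def _feature_frames(rng, n_rows=100, n_feat=6, shift=0.0):
    base = rng.normal(size=(n_rows, n_feat))
    base[:, 0] += shift
    return pd.DataFrame(base, columns=[f"f{i}" for i in range(n_feat)])


def test_wilcoxon_null_keeps_nothing():
    rng = np.random.default_rng(5)
    pos = _feature_frames(rng)
    neg = _feature_frames(rng)
    res = wilcoxon_select(pos, neg, threshold=1e-20)
    assert res.kept_names == ()


def test_wilcoxon_separated_supports_kept():
    rng = np.random.default_rng(6)
    pos = _feature_frames(rng, shift=100.0)  # complete separation on f0
    neg = _feature_frames(rng)
    res = wilcoxon_select(pos, neg, threshold=1e-20)
    assert "f0" in res.kept_names
    assert res.p_values["f0"] < 1e-20


def test_wilcoxon_constant_feature_never_kept():
    pos = pd.DataFrame({"c": [1.0] * 10, "x": np.arange(10.0)})
    neg = pd.DataFrame({"c": [1.0] * 10, "x": np.arange(10.0) + 0.5})
    res = wilcoxon_select(pos, neg, threshold=0.9999)
    assert res.p_values["c"] == 1.0
    assert "c" not in res.kept_names


def test_wilcoxon_schema_and_row_count_errors():
    pos = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(SchemaError):
        wilcoxon_select(pos, pd.DataFrame({"b": [1.0, 2.0]}))
    with pytest.raises(ValueError):
        wilcoxon_select(pos, pd.DataFrame({"a": [1.0]}))


def test_wilcoxon_symmetric_and_row_order_invariant():
    rng = np.random.default_rng(7)
    pos = _feature_frames(rng, n_rows=30, shift=2.0)
    neg = _feature_frames(rng, n_rows=40)
    r1 = wilcoxon_select(pos, neg, threshold=1e-3)
    r2 = wilcoxon_select(neg, pos, threshold=1e-3)  # two-sided: swap-symmetric
    assert r1.p_values == pytest.approx(r2.p_values)
    shuffled = pos.sample(frac=1.0, random_state=8)
    r3 = wilcoxon_select(shuffled, neg, threshold=1e-3)
    assert r1.p_values == pytest.approx(r3.p_values)


def test_feature_matrix_shape_and_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    seqs = [_rand_seq(rng, L=300, sid=f"s{i}") for i in range(3)]
    recipe = FeatureRecipe(kind="hacf", seq_len=300)
    X = feature_matrix(seqs, recipe)
    assert X.shape == (3, len(recipe.feature_names()))
    path = tmp_path / "X.tsv"
    write_feature_matrix(X, path)
    back = read_feature_matrix(path)
    assert np.allclose(back.to_numpy(), X.to_numpy(), rtol=5e-12, atol=0)
    assert list(back.columns) == list(X.columns)


def test_feature_matrix_duplicate_ids_rejected():
    rng = np.random.default_rng(10)
    seqs = [_rand_seq(rng, L=300, sid="dup"), _rand_seq(rng, L=300, sid="dup")]
    with pytest.raises(ValueError, match="dup"):
        feature_matrix(seqs, FeatureRecipe(kind="tnf"))


def test_feature_matrix_excludes_ambiguous_sequences():
    rng = np.random.default_rng(11)
    good = _rand_seq(rng, L=300, sid="good")
    withn = DNASequence("hasN", "N" + good.bases[1:])
    X = feature_matrix([good, withn], FeatureRecipe(kind="hacf", seq_len=300))
    assert list(X.index) == ["good"]


def test_feature_matrix_length_violation_lists_ids():
    rng = np.random.default_rng(12)
    seqs = [_rand_seq(rng, L=300, sid="ok"), _rand_seq(rng, L=200, sid="short")]
    with pytest.raises(ValueError, match="short"):
        feature_matrix(seqs, FeatureRecipe(kind="sacf", seq_len=300))
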