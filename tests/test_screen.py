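"""Temporal gene-screen filters and the synthetic-table generator."""

import numpy as np
import pandas as pd
import pytest

from glitimer.screen import (
    TRUE_CLASSES,
    classify_biphasic,
    filter_downregulated,
    generate_synthetic_table,
    read_table,
    write_table,
)

# classes whose noiseless templates satisfy each screen; the CyC-insensitive
# decoy still drops between 3.5 and 5.5 DDC, so it passes the down-regulated
# screen (its violated rule exists only in the biphasic gate)
DOWNREG_TRUTH = {"biphasic_peak2", "biphasic_peak3p5", "monotone_down",
                 "cyc_insensitive_decoy"}
BIPHASIC_TRUTH = {"biphasic_peak2": "peak2", "biphasic_peak3p5": "peak3.5"}


@pytest.fixture(scope="module")
def noiseless_table():
    return generate_synthetic_table(700, noise_sd=0.0, seed=0)


def test_noiseless_downregulated_recovery_is_exact(noiseless_table):
    res = filter_downregulated(noiseless_table)
    expected = noiseless_table["true_class"].isin(DOWNREG_TRUTH) & (
        noiseless_table["biotype"] == "protein_coding"
    )
    assert (res["downregulated_pass"] == expected).all()


def test_noiseless_biphasic_recovery_is_exact(noiseless_table):
    res = classify_biphasic(noiseless_table)
    expected = noiseless_table["true_class"].map(BIPHASIC_TRUTH).fillna("none")
    assert (res["biphasic_label"] == expected).all()


def test_peak_labels_are_mutually_exclusive(noiseless_table):
    res = classify_biphasic(noiseless_table)
    assert not ((res["biphasic_label"] == "peak2") & (res["biphasic_label"] == "peak3.5")).any()
    both = res["biphasic_peak2"] & res["biphasic_peak3p5"]
    # any gene satisfying both rule sets still receives a single label
    assert res.loc[both, "biphasic_label"].isin(["peak2", "peak3.5"]).all()


def test_pure_flat_mix_passes_nothing():
    t = generate_synthetic_table(50, class_mix={"flat": 1.0}, seed=1)
    assert not filter_downregulated(t)["downregulated_pass"].any()
    assert (classify_biphasic(t)["biphasic_label"] == "none").all()


def test_pure_peak2_mix_fully_recovered():
    t = generate_synthetic_table(40, class_mix={"biphasic_peak2": 1.0}, seed=2)
    assert (classify_biphasic(t)["biphasic_label"] == "peak2").all()


@pytest.mark.parametrize(
    "decoy, relax",
    [
        ("non_coding_decoy", "biotype"),
        ("cyc_insensitive_decoy", "cyc_fc"),
    ],
)
def test_each_decoy_fails_exactly_its_one_rule(noiseless_table, decoy, relax):
    res = classify_biphasic(noiseless_table)
    sub = res[res["true_class"] == decoy]
    assert (sub["biphasic_label"] == "none").all()

    # re-evaluate the printed conjunction with the single violated rule relaxed;
    # the decoy must then be admitted as a peak-at-2 gene
    t = noiseless_table[noiseless_table["true_class"] == decoy]
    gate = (
        ((t["fpkm_2"] >= 2) | (t["fpkm_3p5"] >= 2))
        & (t["p_sag_vs_cyc_3p5"] <= 0.05)
    )
    if relax == "biotype":
        gate &= t["log2fc_sag_vs_cyc_3p5"] >= 0.5
    else:  # relax the CyC fold-change inequality, keep the biotype rule
        gate &= t["biotype"] == "protein_coding"
    peak2 = (
        gate
        & (t["p_2_vs_0"] <= 0.05) & (t["p_2_vs_6p5"] <= 0.05)
        & (t["log2fc_2_vs_0"] >= 0.5) & (t["log2fc_2_vs_1"] >= 0)
        & (t["log2fc_2_vs_6p5"] >= 0.5) & (t["log2fc_2_vs_5p5"] >= 0.5)
        & (t["log2fc_2_vs_4p5"] >= 0)
    )
    assert peak2.all()


def test_noncoding_decoy_rejected_by_downregulated_screen(noiseless_table):
    res = filter_downregulated(noiseless_table)
    sub = res[res["true_class"] == "non_coding_decoy"]
    assert not sub["downregulated_pass"].any()
    # it satisfies every numeric rule; only the biotype rule rejects it
    numeric = (
        (sub["fpkm_3p5"] >= 2) & (sub["p_3p5_vs_5p5"] <= 0.05)
        & (sub["log2fc_3p5_vs_5p5"] >= 0.22)
    )
    assert numeric.all()


def test_raising_fc_cutoff_never_admits_more_genes(noiseless_table):
    counts = [
        filter_downregulated(noiseless_table, fc_cutoff=c)["downregulated_pass"].sum()
        for c in (0.22, 0.5, 1.0, 2.5, 5.0)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_filters_are_idempotent(noiseless_table):
    res = filter_downregulated(noiseless_table)
    passed = res[res["downregulated_pass"]].drop(columns=["downregulated_pass"])
    again = filter_downregulated(passed)
    assert again["downregulated_pass"].all()

    lab = classify_biphasic(noiseless_table)
    peak2 = lab[lab["biphasic_label"] == "peak2"].drop(
        columns=["biphasic_peak2", "biphasic_peak3p5", "biphasic_label"]
    )
    assert (classify_biphasic(peak2)["biphasic_label"] == "peak2").all()


def test_missing_columns_reported_by_name(noiseless_table):
    broken = noiseless_table.drop(columns=["log2fc_3p5_vs_5p5"])
    with pytest.raises(ValueError, match="log2fc_3p5_vs_5p5"):
        filter_downregulated(broken)
    with pytest.raises(ValueError, match="log2fc_2_vs_4p5"):
        classify_biphasic(noiseless_table.drop(columns=["log2fc_2_vs_4p5"]))


def test_moderate_noise_recovery():
    t = generate_synthetic_table(700, noise_sd=0.1, seed=11)
    res = classify_biphasic(t)
    for cls, label in BIPHASIC_TRUTH.items():
        sub = res[res["true_class"] == cls]
        assert (sub["biphasic_label"] == label).mean() >= 0.9


def test_generator_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        generate_synthetic_table(10, class_mix={"flat": 0.5})
    with pytest.raises(ValueError, match="unknown"):
        generate_synthetic_table(10, class_mix={"nope": 1.0})
    t = generate_synthetic_table(97, seed=5)  # largest-remainder apportionment
    assert len(t) == 97
    assert set(t["true_class"]) == set(TRUE_CLASSES)


def test_table_round_trip(tmp_path, noiseless_table):
    path = tmp_path / "table.tsv"
    write_table(noiseless_table, path)
    back = read_table(path)
    pd.testing.assert_frame_equal(
        back, noiseless_table, check_exact=False, rtol=1e-12
    )
    assert (back.columns == noiseless_table.columns).all()
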