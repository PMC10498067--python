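"""DIF pipeline: flagging rules, purification, determinism, curves."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ordif.dif import (
    DIFAnalyzer,
    DIFReport,
    DIFResult,
    analyze_item,
    classify_item,
    export_dif_curves,
    run_iterative_dif,
)
from ordif.io import ResponseMatrix, RunConfig
from ordif.simulate import SyntheticSpec, default_item_bank, generate


def _matrix(df):
    return ResponseMatrix(df.drop(columns="group").astype(float), df["group"])


@pytest.mark.parametrize(
    "stats,expected",
    [
        # printed gender item-1 row: uniform significant, small R2, large CVBL
        (
            dict(p_uniform=0.0041, p_nonuniform=0.5534, deltaR1=0.0029,
                 deltaR2=0.0001, deltaBeta1=0.0137),
            dict(flag_uniform_sig=True, flag_nonuniform_sig=False,
                 flag_large_r2=False, flag_large_cvbl=True),
        ),
        # printed gender item-36 row: nonuniform significant, not large
        (
            dict(p_uniform=0.1723, p_nonuniform=0.0001, deltaR1=0.0007,
                 deltaR2=0.0054, deltaBeta1=0.0120),
            dict(flag_uniform_sig=False, flag_nonuniform_sig=True,
                 flag_large_r2=False, flag_large_cvbl=True),
        ),
        # null statistics: no flags at all
        (
            dict(p_uniform=1.0, p_nonuniform=1.0, deltaR1=0.0,
                 deltaR2=0.0, deltaBeta1=0.0),
            dict(flag_uniform_sig=False, flag_nonuniform_sig=False,
                 flag_large_r2=False, flag_large_cvbl=False),
        ),
    ],
)
def test_classify_item_criteria(stats, expected):
    assert classify_item(stats, RunConfig()) == expected


def test_classify_item_bonferroni_shrinks_flags():
    stats = dict(p_uniform=0.01, p_nonuniform=0.5, deltaR1=0.0, deltaR2=0.0,
                 deltaBeta1=0.0)
    plain = classify_item(stats, RunConfig())
    bonf = classify_item(stats, RunConfig(bonferroni=True), n_items=10)
    assert plain["flag_uniform_sig"] and not bonf["flag_uniform_sig"]


def test_deterministic_item_shows_no_group_signal():
    rng = np.random.default_rng(1)
    th = rng.normal(size=400)
    g = rng.integers(0, 2, 400)
    y = np.digitize(th, [-1.0, 0.0, 1.0]) + 1  # function of theta only
    stats = analyze_item(y, th, g)
    assert stats["chi2_uniform"] < 1e-2
    assert stats["chi2_nonuniform"] < 1e-2


def test_no_dif_run_is_single_pass_fixed_point():
    a, b = default_item_bank(10)
    spec = SyntheticSpec(n_per_group=(300, 300), discrimination=a, thresholds=b)
    df, _ = generate(spec, seed=0)  # seed chosen so no item is chance-flagged
    report = run_iterative_dif(_matrix(df))
    assert report.trace == [frozenset()]
    assert report.termination == "fixed_point"
    assert sorted(report.anchor_items) == sorted(df.columns[:-1])


def test_purification_is_deterministic(fixture_run):
    _, rm, _ = fixture_run
    cfg = RunConfig(max_purification_iters=4)
    r1 = run_iterative_dif(rm, cfg)
    r2 = run_iterative_dif(rm, cfg)
    pd.testing.assert_frame_equal(r1.to_frame(), r2.to_frame())
    assert r1.trace == r2.trace and r1.termination == r2.termination


def test_fixture_purification_converges(fixture_run):
    _, rm, truth = fixture_run
    report = run_iterative_dif(rm, RunConfig(max_purification_iters=10))
    assert report.termination in ("fixed_point", "cycle")
    if len(report.trace) > 1:
        assert report.trace[-1] == report.trace[-2] or report.trace[-1] in report.trace[:-2]
    # anchors and flags partition the usable items
    flagged = set(report.flagged_items)
    assert flagged.isdisjoint(report.anchor_items)
    assert flagged | set(report.anchor_items) == set(rm.item_ids)


def test_all_flagged_stops_with_warning():
    a3 = np.array([1.2, 1.0, 1.4])
    b3 = np.tile(np.array([-1.0, 0.0, 1.0, 2.0]), (3, 1))
    spec = SyntheticSpec(
        n_per_group=(300, 300),
        discrimination=a3,
        thresholds=b3,
        dif_spec=[(j, "uniform", 2.0) for j in range(3)],
    )
    df, _ = generate(spec, seed=6)
    with pytest.warns(UserWarning, match="every item is flagged"):
        report = run_iterative_dif(_matrix(df))
    assert report.termination == "all_flagged"
    assert report.anchor_items  # last non-empty anchor set preserved


def test_uniform_chi2_monotone_in_dif_magnitude():
    """Median uniform chi-square grows with the injected threshold shift."""
    b = np.array([[-1.2, -0.3, 0.6, 1.5]])
    medians = []
    for delta in (0.0, 0.25, 0.5, 1.0):
        chis = []
        for rep in range(40):
            spec = SyntheticSpec(
                n_per_group=(250, 250),
                discrimination=np.array([1.3]),
                thresholds=b,
                dif_spec=[(0, "uniform", delta)] if delta else [],
            )
            df, truth = generate(spec, seed=1000 + rep)
            s = analyze_item(df["item01"].to_numpy(), truth.theta, truth.group)
            chis.append(s["chi2_uniform"])
        medians.append(np.median(chis))
    assert all(m2 >= m1 for m1, m2 in zip(medians, medians[1:]))


def _forced_uniform_report(items):
    results = [
        DIFResult(item_id=i, p_uniform=0.001, p_nonuniform=0.9, deltaR1=0.01,
                  deltaR2=0.0, deltaBeta1=0.02, flag_uniform_sig=True)
        for i in items
    ]
    return DIFReport(results, [], [frozenset(items)], RunConfig(), "fixed_point")


def test_export_curves_cancel_out_pattern():
    """Opposite uniform shifts give crossing per-group test curves."""
    a2 = np.array([1.2, 1.2])
    b2 = np.tile(np.array([-1.0, 0.0, 1.0, 2.0]), (2, 1))
    spec = SyntheticSpec(
        n_per_group=(1500, 1500),
        discrimination=a2,
        thresholds=b2,
        dif_spec=[(0, "uniform", 0.8), (1, "uniform", -0.8)],
    )
    df, truth = generate(spec, seed=3)
    rm = _matrix(df)
    report = _forced_uniform_report(["item01", "item02"])
    curves = export_dif_curves(report, rm, truth.theta)
    labels = [c for c in curves.columns if c != "theta"]
    gap = curves[labels[0]].to_numpy() - curves[labels[1]].to_numpy()
    mid = slice(10, len(gap) - 10)  # interior of the grid, where data live
    assert gap[mid].min() < 0 < gap[mid].max()
    for lab in labels:
        assert np.all(curves[lab] >= 2.0 - 1e-9)
        assert np.all(curves[lab] <= 10.0 + 1e-9)


def test_export_curves_overlap_without_dif():
    a2 = np.array([1.2, 1.0])
    b2 = np.tile(np.array([-1.0, 0.0, 1.0, 2.0]), (2, 1))
    spec = SyntheticSpec(n_per_group=(2000, 2000), discrimination=a2, thresholds=b2)
    df, truth = generate(spec, seed=5)
    report = _forced_uniform_report(["item01", "item02"])
    curves = export_dif_curves(report, _matrix(df), truth.theta)
    labels = [c for c in curves.columns if c != "theta"]
    gap = np.abs(curves[labels[0]] - curves[labels[1]])
    mid = slice(10, len(gap) - 10)
    assert gap.to_numpy()[mid].max() < 0.25  # sampling noise only


def test_export_curves_empty_report():
    spec = SyntheticSpec(
        n_per_group=(50, 50),
        discrimination=np.array([1.0]),
        thresholds=np.array([[-1.0, 0.0, 1.0, 2.0]]),
    )
    df, truth = generate(spec, seed=0)
    report = DIFReport([], [], [frozenset()], RunConfig(), "fixed_point")
    curves = export_dif_curves(report, _matrix(df), truth.theta)
    assert curves.empty and "note" in curves.attrs
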