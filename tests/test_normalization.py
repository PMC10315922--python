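"""Between-sample normalization: factor recovery and invariances."""

import numpy as np
import pandas as pd
import pytest

from tracelfq import (
    IonTable,
    SampleNormalizer,
    SimulationConfig,
    normalize_samples,
    simulate_dataset,
)
from tracelfq.ion_table import COLUMNS


def _two_sample_table(scale2=1.0):
    rows = []
    rng = np.random.default_rng(3)
    for i in range(40):
        base = float(rng.uniform(10, 1000))
        rows.append(("P%d" % (i % 10), f"ion{i}", "a", base))
        rows.append(("P%d" % (i % 10), f"ion{i}", "b", base * scale2))
    return IonTable(pd.DataFrame(rows, columns=COLUMNS))


def test_pure_loading_offset_is_removed_exactly():
    t = _two_sample_table(scale2=4.0)
    res = normalize_samples(t)
    diff = res.log2_factors["a"] - res.log2_factors["b"]
    assert diff == pytest.approx(2.0, abs=1e-9)
    wide = res.normalized_table.to_wide()
    np.testing.assert_allclose(wide["a"], wide["b"], rtol=1e-12)


def test_already_normalized_input_gives_zero_factors():
    t = _two_sample_table(scale2=4.0)
    once = normalize_samples(t).normalized_table
    again = normalize_samples(once)
    np.testing.assert_allclose(again.log2_factors, 0.0, atol=1e-9)


def test_factors_are_median_centered():
    res = normalize_samples(_two_sample_table(scale2=8.0))
    assert np.median(res.log2_factors) == pytest.approx(0.0, abs=1e-12)


def test_scale_equivariance():
    """Multiplying one sample by c shifts its recovered log2 factor by
    -log2 c relative to the others and leaves the normalized output
    unchanged up to the global median-zero gauge."""
    t = _two_sample_table()
    res = normalize_samples(t)
    df = t.df.copy()
    df.loc[df["sample"] == "b", "intensity"] *= 2.0 ** 1.7
    res_scaled = normalize_samples(IonTable(df))
    rel = res.log2_factors - res.log2_factors["a"]
    rel_scaled = res_scaled.log2_factors - res_scaled.log2_factors["a"]
    assert (rel_scaled["b"] - rel["b"]) == pytest.approx(-1.7, abs=1e-9)
    wide = res.normalized_table.to_wide().to_numpy()
    wide_scaled = res_scaled.normalized_table.to_wide().to_numpy()
    gauge = wide_scaled / wide
    np.testing.assert_allclose(gauge, gauge.flat[0], rtol=1e-9)


def test_factor_recovery_with_minority_regulation():
    """Loading offsets are recovered within 0.05 log2 despite 30% of
    proteins being regulated, thanks to the median's robustness."""
    rng = np.random.default_rng(42)
    offsets = rng.uniform(-1, 1, size=6)
    cfg = SimulationConfig(
        n_proteins={"background": 140, "regulated": 60},
        species_fold_changes={"background": 1.0, "regulated": 3.0},
        sample_loading_offsets=list(offsets),
        noise_sd=0.1, missing_fraction=0.0, seed=42,
    )
    table, truth = simulate_dataset(cfg)
    res = normalize_samples(table)
    true_centered = pd.Series(offsets, index=table.samples)
    true_centered -= true_centered.median()
    # normalization factors should cancel the loading offsets
    np.testing.assert_allclose(res.log2_factors, -true_centered, atol=0.05)


def test_housekeeping_subset_restricts_trace_building():
    # sample b carries a 4x loading offset; the 'contaminant' protein is
    # hugely regulated and would corrupt a small-table median, but the
    # subset excludes it
    rows = []
    for i in range(10):
        rows.append(("HK", f"hk{i}", "a", 100.0))
        rows.append(("HK", f"hk{i}", "b", 400.0))
    for i in range(14):
        rows.append(("CONT", f"c{i}", "a", 100.0))
        rows.append(("CONT", f"c{i}", "b", 100.0 * 2 ** 5))
    t = IonTable(pd.DataFrame(rows, columns=COLUMNS))
    res = normalize_samples(t, subset={"HK"})
    assert (res.log2_factors["a"] - res.log2_factors["b"]
            ) == pytest.approx(2.0, abs=1e-9)


def test_subset_with_no_ions_raises():
    t = _two_sample_table()
    with pytest.raises(ValueError, match="no ions"):
        normalize_samples(t, subset={"NOT_A_PROTEIN"})


def test_unalignable_sample_flagged_with_zero_factor():
    rows = [("P1", "i1", "a", 8.0), ("P1", "i1", "b", 16.0),
            ("P1", "i2", "a", 8.0), ("P2", "i3", "c", 9.0)]
    t = IonTable(pd.DataFrame(rows, columns=COLUMNS))
    res = normalize_samples(t)
    assert res.flags["c"]
    # flagged sample's data passes through with factor relative to the
    # median gauge only
    assert res.log2_factors.notna().all()


def test_sklearn_estimator_contract():
    norm = SampleNormalizer(nmax=7)
    assert norm.get_params()["nmax"] == 7
    norm.set_params(nmax=9)
    t = _two_sample_table(scale2=2.0)
    out = norm.fit(t).transform(t)
    assert set(out.columns) == {"protein", "ion", "sample", "intensity"}
    assert hasattr(norm, "log2_factors_")


def test_mode_center_handles_majority_regulation():
    """With a heterogeneously regulated majority of ions, the median shift
    is dragged into the regulated mass but the kernel-density mode stays
    on the sharp peak formed by the unregulated ions."""
    rng = np.random.default_rng(21)
    rows = []
    for i in range(400):
        base = float(rng.uniform(15, 25))
        # 60% regulated, each by its own fold change: broad smear of
        # changes, while the unregulated 40% pile up at the loading offset
        reg = float(rng.uniform(1.0, 5.0)) if i < 240 else 0.0
        noise = rng.normal(0, 0.05, 2)
        rows.append(("P%d" % i, f"ion{i}", "a", 2.0 ** (base + noise[0])))
        rows.append(("P%d" % i, f"ion{i}", "b",
                     2.0 ** (base + reg + 1.0 + noise[1])))
    t = IonTable(pd.DataFrame(rows, columns=COLUMNS))
    med = normalize_samples(t, center="median")
    mod = normalize_samples(t, center="mode")
    # true loading offset of b is +1, so factor_a - factor_b should be +1
    assert (mod.log2_factors["a"] - mod.log2_factors["b"]
            ) == pytest.approx(1.0, abs=0.2)
    assert abs((med.log2_factors["a"] - med.log2_factors["b"]) - 1.0) > 0.5
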