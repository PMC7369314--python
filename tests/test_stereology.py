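"""Stereology: totals, Cavalieri volumes, densities, region assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgquant.stereology import (
    RegionEstimate,
    SectionRecord,
    SectionSeries,
    cavalieri_volume,
    classify_region,
    density,
    estimate_total,
    read_section_table,
)
from dgquant.synth import generate_section_series


def series(counts, areas=None, interval=10, thickness=30.0):
    areas = areas if areas is not None else [1.0] * len(counts)
    recs = [
        SectionRecord(bregma_mm=-2.0 - 0.3 * i, area_mm2=a, count=c)
        for i, (a, c) in enumerate(zip(areas, counts))
    ]
    return SectionSeries(recs, sampling_interval=interval, section_thickness_um=thickness)


# --- region classification --------------------------------------------------


@pytest.mark.parametrize(
    "bregma, expected",
    [
        (-3.8, "dorsal"),     # canonical dorsal example section
        (-6.8, "ventral"),    # canonical ventral example section
        (-1.0, "out_of_range"),
        (-4.52, "ventral"),   # shared boundary assigned ventral by convention
        (-1.80, "dorsal"),
        (-6.81, "out_of_range"),
    ],
)
def test_region_boundaries(bregma, expected):
    assert classify_region(bregma) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(-6.80, -1.80, allow_nan=False))
def test_region_partition_has_no_gap_or_overlap(bregma):
    assert classify_region(bregma) in ("dorsal", "ventral")


# --- totals and volumes -----------------------------------------------------


def test_total_is_summed_counts_times_interval():
    assert estimate_total(series([3, 5, 2])) == 100
    assert estimate_total(series([0, 0, 0])) == 0


def test_empty_series_rejected():
    s = series([1])
    s.records = []
    with pytest.raises(ValueError, match="empty"):
        estimate_total(s)
    with pytest.raises(ValueError, match="empty"):
        cavalieri_volume(s)


def test_cavalieri_effective_spacing_is_300_um():
    """Two 1-mm^2 sections, 30-um thickness, 1-in-10 sampling: 0.6 mm^3."""
    assert cavalieri_volume(series([0, 0], areas=[1.0, 1.0])) == pytest.approx(0.6)


def test_zero_area_section_contributes_zero_volume():
    assert cavalieri_volume(series([0], areas=[0.0])) == 0.0


def test_prism_volume_consistent_across_sampling_intervals():
    # constant-area prism: 100 sections of 30 um, 1 mm^2 -> 3 mm^3
    full = series([0] * 100, interval=1)
    sub = series([0] * 10, interval=10)
    v_full, v_sub = cavalieri_volume(full), cavalieri_volume(sub)
    assert v_full == pytest.approx(3.0)
    assert abs(v_sub - v_full) <= 1.0 * 0.3  # within one sampled slab


def test_density_reference_value_and_identity():
    s = series([5, 3, 2], areas=[0.5, 0.5, 2 / 3])  # total 100, volume 0.5
    est = density(s)
    assert est.est_total_cells == 100
    assert est.volume_mm3 == pytest.approx(0.5)
    assert est.density_cells_per_mm3 == pytest.approx(200.0)
    assert est.density_cells_per_mm3 * est.volume_mm3 == pytest.approx(
        est.est_total_cells, rel=1e-9
    )


def test_zero_counts_give_zero_density():
    assert density(series([0, 0])).density_cells_per_mm3 == 0.0


def test_all_zero_areas_give_informative_error():
    with pytest.raises(ValueError, match="area"):
        density(series([1, 1], areas=[0.0, 0.0]))


def test_linearity_in_counts_and_areas():
    s1, s2 = series([1, 2, 3]), series([2, 4, 6])
    assert estimate_total(s2) == 2 * estimate_total(s1)
    a1, a2 = series([0], areas=[1.0]), series([0], areas=[2.0])
    assert cavalieri_volume(a2) == 2 * cavalieri_volume(a1)


# --- generator conservation and unbiasedness --------------------------------


def test_interval_one_returns_counts_summing_to_true_total():
    s, true_total = generate_section_series(
        2000.0, [1.0] * 30, thickness_um=30.0, interval=1, seed=5
    )
    assert int(s.counts.sum()) == true_total


def test_zero_density_gives_all_zero_counts():
    s, true_total = generate_section_series(0.0, [1.0] * 20, interval=10, seed=1)
    assert true_total == 0
    assert np.all(s.counts == 0)


def test_estimate_total_unbiased_over_many_stacks():
    """Systematic 1-in-10 sampling of uniform cells is unbiased for the total."""
    est, truth = [], []
    for seed in range(300):
        s, t = generate_section_series(
            1000.0, [1.0] * 100, thickness_um=30.0, interval=10, seed=seed
        )
        est.append(estimate_total(s))
        truth.append(t)
    ratio = np.mean(est) / np.mean(truth)
    assert abs(ratio - 1.0) < 0.02


def test_recovered_density_close_to_truth():
    dens = []
    for seed in range(200):
        s, _ = generate_section_series(
            1000.0, [1.0] * 100, thickness_um=30.0, interval=10, seed=seed
        )
        dens.append(density(s).density_cells_per_mm3)
    assert np.mean(dens) == pytest.approx(1000.0, rel=0.03)


# --- CSV interface ----------------------------------------------------------


def test_section_table_roundtrip(tmp_path):
    import pandas as pd

    df = pd.DataFrame(
        {
            "animal_id": ["a1"] * 4,
            "bregma_mm": [-2.0, -3.0, -5.0, -6.0],
            "area_mm2": [1.0, 1.2, 0.8, 0.9],
            "count": [3, 4, 5, 6],
        }
    )
    path = tmp_path / "sections.csv"
    df.to_csv(path, index=False)
    by_region = read_section_table(path)
    assert set(by_region) == {("a1", "dorsal"), ("a1", "ventral")}
    assert estimate_total(by_region[("a1", "dorsal")]) == 70
    assert estimate_total(by_region[("a1", "ventral")]) == 110
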