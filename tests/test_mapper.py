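"""Shifted Pearson correlation and the cross-species age map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agemap.mapper import (
    AgeMap,
    MapperOptions,
    ShiftMapResult,
    best_shift,
    human_to_mouse_age,
    map_diseases,
    mouse_to_human_age,
    pearson_at_shift,
)
from agemap.synthetic import example_specs, generate_matrix_pair

RNG = np.random.default_rng(1234)


def _unimodal(n, mean, sd):
    x = np.arange(n, dtype=float)
    return np.exp(-0.5 * ((x - mean) / sd) ** 2)


def _oracle_best_shift(h, m, max_shift, min_overlap=10):
    """Independent exhaustive scan using numpy.corrcoef."""
    best = None
    for s in range(max_shift + 1):
        w = min(len(h), len(m) - s)
        if w < min_overlap:
            continue
        a, b = h[:w], m[s : s + w]
        if a.std() == 0 or b.std() == 0:
            continue
        r = np.corrcoef(a, b)[0, 1]
        if best is None or r > best[1] + 1e-15:
            best = (s, r)
    return best


def test_exact_alignment_gives_r_one():
    v = _unimodal(50, 20, 5)
    padded = np.concatenate([np.zeros(13), v])
    assert pearson_at_shift(v, padded, 13) == pytest.approx(1.0)


def test_zero_variance_window_is_undefined():
    assert pearson_at_shift(np.ones(30), np.ones(40), 0) is None


def test_anti_aligned_patterns_give_minus_one():
    h = np.array([0.0, 1.0] * 10)
    m = np.array([1.0, 0.0] * 10)
    assert pearson_at_shift(h, m, 0) == pytest.approx(-1.0)


def test_too_small_overlap_is_undefined():
    v = _unimodal(30, 10, 3)
    assert pearson_at_shift(v, v, 25, min_overlap=10) is None
    assert pearson_at_shift(v, np.concatenate([v, v]), 55) is None  # beyond mouse axis


@pytest.mark.parametrize("planted", [0, 3, 99, 264, 500])
def test_best_shift_recovers_planted_noiseless(planted):
    h = _unimodal(121, 40, 10)
    m = np.zeros(1029)
    w = min(121, 1029 - planted)
    m[planted : planted + w] = h[:w]
    s, r = best_shift(h, m)
    assert s == planted
    assert r == pytest.approx(1.0)


def test_best_shift_matches_exhaustive_oracle():
    h = RNG.random(60)
    m = RNG.random(200)
    ours = best_shift(h, m, MapperOptions(max_shift=140))
    oracle = _oracle_best_shift(h, m, 140)
    assert ours[0] == oracle[0]
    assert ours[1] == pytest.approx(oracle[1], abs=1e-12)


def test_tie_broken_toward_smaller_shift():
    # periodic pattern: every multiple of the period correlates identically
    h = np.tile([1.0, 2.0, 3.0, 2.0], 10)
    m = np.tile([1.0, 2.0, 3.0, 2.0], 40)
    s, r = best_shift(h, m, MapperOptions(max_shift=20))
    assert s == 0
    assert r == pytest.approx(1.0)


def test_default_scan_covers_every_shift():
    opts = MapperOptions()
    assert opts.max_shift == 1028
    h = _unimodal(121, 30, 8)
    m = np.zeros(1029)
    m[1028 - 120 :] = h  # pattern planted at the very end of the axis
    s, _ = best_shift(h, m, opts)
    assert s > 900  # reachable only if large shifts were evaluated


@given(
    scale=st.floats(min_value=0.1, max_value=50),
    offset=st.floats(min_value=-5, max_value=5),
)
@settings(max_examples=50, deadline=None)
def test_pearson_affine_invariance(scale, offset):
    h = _unimodal(80, 30, 7)
    m = np.concatenate([np.zeros(11), _unimodal(80, 30, 7), np.zeros(30)])
    r0 = pearson_at_shift(h, m, 11)
    r1 = pearson_at_shift(h * scale + offset, m, 11)
    r2 = pearson_at_shift(h, m * scale + offset, 11)
    assert r1 == pytest.approx(r0, abs=1e-12)
    assert r2 == pytest.approx(r0, abs=1e-12)


def test_map_diseases_accepts_planted_rejects_unrelated():
    specs = example_specs()
    human, mouse, truth = generate_matrix_pair(specs, noise_cv=0.0, seed=5)
    amap = map_diseases(human, mouse)
    related = set(truth[truth["related"]]["concept_id"])
    assert set(amap.entries) == related
    assert amap.n_compared == len(specs)
    for cid in related:
        planted = int(truth.set_index("concept_id").loc[cid, "planted_shift_days"])
        assert amap.entries[cid].shift_days == planted
        assert amap.entries[cid].r2 > 0.5


def test_map_requires_normalized_matrices():
    human, mouse, _ = generate_matrix_pair(example_specs(), seed=3)
    human.normalized = False
    with pytest.raises(ValueError, match="normalized"):
        map_diseases(human, mouse)


def test_disease_only_in_one_matrix_is_absent():
    specs = example_specs()
    human, _, _ = generate_matrix_pair(specs, seed=2)
    _, mouse, _ = generate_matrix_pair(specs[1:], seed=2)
    amap = map_diseases(human, mouse)
    assert specs[0].concept_id not in amap.entries
    assert amap.n_compared == len(specs) - 1


@pytest.fixture(scope="module")
def worked_map():
    return AgeMap(entries={
        "diabetes": ShiftMapResult("diabetes", 99, 0.9, 0.81, 100, True),
        "leukemia": ShiftMapResult("leukemia", 90, 0.9, 0.81, 100, True),
        "anemia": ShiftMapResult("anemia", 265, 0.9, 0.81, 100, True),
    })


def test_worked_age_conversions(worked_map):
    """A 99-day shift sends mouse day 120 to human year 21; the classic
    printed pairs for leukemia (30 y <-> 120 d) and anemia (30 y <-> 295 d)
    follow from shifts 90 and 265."""
    assert mouse_to_human_age(worked_map, "diabetes", 120) == 21
    assert human_to_mouse_age(worked_map, "leukemia", 30) == 120
    assert mouse_to_human_age(worked_map, "leukemia", 120) == 30
    assert human_to_mouse_age(worked_map, "anemia", 30) == 295
    assert mouse_to_human_age(worked_map, "anemia", 295) == 30


def test_conversion_boundaries_and_errors(worked_map):
    assert mouse_to_human_age(worked_map, "diabetes", 99) == 0
    assert human_to_mouse_age(worked_map, "diabetes", 0) == 99
    with pytest.raises(KeyError):
        mouse_to_human_age(worked_map, "gout", 120)
    with pytest.raises(ValueError, match="negative human age"):
        mouse_to_human_age(worked_map, "diabetes", 50)


@given(age=st.integers(min_value=0, max_value=119))
@settings(max_examples=40, deadline=None)
def test_roundtrip_identity_and_unit_slope(worked_map, age):
    there = human_to_mouse_age(worked_map, "diabetes", age)
    assert mouse_to_human_age(worked_map, "diabetes", there) == age
    assert human_to_mouse_age(worked_map, "diabetes", age + 1) - there == 1
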