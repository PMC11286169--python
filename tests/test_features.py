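"""Feature catalog: entropy profiling, band statistics, spectral descriptors."""

import numpy as np
import pytest

from szevents.features import (
    DEFAULT_BANDS,
    EntropyProfile,
    band_statistics,
    catalog_names,
    compute_features,
    default_catalog,
    entropy_profile,
    extract_table,
    feature_columns,
    profile_secondary_features,
    sample_entropy,
    spectral_features,
)
from szevents.io import ValidationError

FS = 256
T = np.arange(1280) / FS


def bruteforce_sampen(x, m, r):
    """O(N^2) reference: explicit loops, Chebyshev matching, float32 inputs."""
    x = np.asarray(x, dtype=np.float32)
    n = len(x) - m
    b = a = 0
    for i in range(n):
        for j in range(i + 1, n):
            if max(abs(float(x[i + k]) - float(x[j + k])) for k in range(m)) <= r:
                b += 1
                if max(
                    abs(float(x[i + k]) - float(x[j + k])) for k in range(m + 1)
                ) <= r:
                    a += 1
    if b == 0:
        return float("nan")
    if a == 0:
        return float("inf")
    return -np.log(a / b)


def norm(v):
    return np.nan_to_num(np.asarray(v, dtype=float), posinf=9e9, nan=-9.0)


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.full(100, 3.7), 2, 0.5) == 0.0

    def test_matches_bruteforce_small_ramp(self):
        x = np.arange(1, 9, dtype=float)
        for r in (0.5, 1.0, 1.5, 3.0):
            assert norm(sample_entropy(x, 2, r)) == norm(bruteforce_sampen(x, 2, r))

    def test_matches_bruteforce_random(self, rng):
        for _ in range(5):
            x = rng.normal(0, 10, size=60)
            r = float(rng.uniform(0.5, 15))
            assert norm(sample_entropy(x, 2, r)) == pytest.approx(
                norm(bruteforce_sampen(x, 2, r)), rel=1e-10
            )

    def test_periodic_signal_near_zero(self):
        x = np.tile([0.0, 1.0, 2.0, 1.0], 60)
        assert sample_entropy(x, 2, 0.1) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            sample_entropy(np.ones(3), 2, 0.5)


class TestEntropyProfile:
    def test_equals_per_tolerance_sampen(self, rng):
        for _ in range(8):
            x = rng.normal(0, rng.uniform(1, 40), size=120)
            p = entropy_profile(x, m=2, R=25)
            direct = [sample_entropy(x, 2, r) for r in p.tolerances]
            assert np.array_equal(norm(p.values), norm(direct))

    def test_nonincreasing_on_seeded_signals(self, rng):
        for _ in range(5):
            x = rng.normal(0, 5, size=300)
            p = entropy_profile(x)
            v = p.values[np.isfinite(p.values)]
            assert np.all(np.diff(v) <= 1e-12)

    def test_constant_signal_all_zero(self):
        p = entropy_profile(np.full(50, 2.0))
        finite = p.values[np.isfinite(p.values)]
        assert len(finite) == len(p.values)
        assert np.all(finite == 0.0)

    def test_grid_spans_dmax(self, rng):
        x = rng.normal(size=200)
        p = entropy_profile(x, R=50)
        assert len(p) == 50
        assert p.tolerances[-1] == pytest.approx(p.d_max)


class TestProfileSecondary:
    def test_hand_trapezoid(self):
        p = EntropyProfile(
            m=2, tolerances=np.array([1.0, 2.0, 3.0]),
            values=np.array([2.0, 1.0, 0.0]), d_max=3.0,
        )
        v = dict(zip(catalog_names()[18:30], profile_secondary_features(p)))
        assert v["ep_area"] == pytest.approx(2.0)
        assert v["ep_max"] == 2.0
        assert v["ep_range"] == 2.0
        assert v["ep_argmax_frac"] == pytest.approx(1 / 3)
        assert v["ep_n_finite"] == 3
        assert v["ep_terminal"] == 0.0

    def test_argmax_at_first_grid_point_for_nonincreasing(self, rng):
        x = rng.normal(0, 3, size=400)
        p = entropy_profile(x)
        vec = profile_secondary_features(p, signal_sd=float(x.std()))
        finite = np.isfinite(p.values)
        expected = p.tolerances[finite][np.argmax(p.values[finite])] / p.d_max
        assert vec[8] == pytest.approx(expected)

    def test_all_undefined_profile_gives_zeros(self):
        p = EntropyProfile(
            m=2, tolerances=np.array([1.0, 2.0]),
            values=np.array([np.nan, np.nan]), d_max=2.0,
        )
        assert np.all(profile_secondary_features(p) == 0.0)


class TestBandStatistics:
    def test_alpha_tone_concentrates_in_alpha(self):
        x = 40 * np.sin(2 * np.pi * 10 * T)
        alpha = dict(zip(range(8), band_statistics(x, DEFAULT_BANDS[2])))
        gamma = dict(zip(range(8), band_statistics(x, DEFAULT_BANDS[4])))
        assert alpha[1] > 0.9   # relative power in 8-13 Hz
        assert gamma[1] < 0.05

    def test_zero_signal_all_zero(self):
        for band in DEFAULT_BANDS:
            assert np.all(band_statistics(np.zeros(1280), band) == 0.0)

    def test_white_noise_relative_powers_track_bandwidth(self, rng):
        # flat-spectrum expectation, averaged over windows to tame MC noise
        rel = {b.name: [] for b in DEFAULT_BANDS}
        for _ in range(20):
            x = rng.normal(0, 10, size=1280)
            for b in DEFAULT_BANDS:
                rel[b.name].append(band_statistics(x, b)[1])
        means = {k: np.mean(v) for k, v in rel.items()}
        assert sum(means.values()) <= 1.1
        total_bw = 79.5
        for b in DEFAULT_BANDS[1:]:  # theta..gamma follow the bandwidth ratio
            expected = (b.f_hi - b.f_lo) / total_bw
            assert means[b.name] == pytest.approx(expected, rel=0.35), b.name
        # the 0.5 Hz delta edge leaves a long zero-phase filter transient in
        # a 5-s window, inflating delta beyond its 3.5 Hz bandwidth share
        assert 0.02 <= means["delta"] <= 4 * (3.5 / total_bw)


class TestSpectralFeatures:
    def test_white_noise_high_entropy(self, rng):
        v = dict(zip(catalog_names()[70:], spectral_features(rng.normal(0, 5, 1280))))
        assert v["spectral_entropy"] > 0.9

    def test_pure_tone_flat_edge_frequencies(self):
        x = 30 * np.sin(2 * np.pi * 10 * T)
        v = dict(zip(catalog_names()[70:], spectral_features(x)))
        assert v["spectral_flatness"] < 0.05
        assert abs(v["sef50"] - 10) <= 1.0
        assert abs(v["sef95"] - 10) <= 1.0
        assert v["peak_freq"] == pytest.approx(10, abs=0.5)

    def test_zero_signal_all_zero(self):
        assert np.all(spectral_features(np.zeros(1280)) == 0.0)


class TestCatalog:
    def test_catalog_composition(self):
        cat = default_catalog()
        assert len(cat) == 92
        groups = {}
        for f in cat:
            groups[f.group] = groups.get(f.group, 0) + 1
        assert groups == {
            "time_stat": 18, "entropy_profile": 12, "band_stat": 40, "spectral": 22,
        }
        assert len({f.name for f in cat}) == 92

    def test_compute_features_constant_signal(self):
        v = dict(zip(catalog_names(), compute_features(np.full(1280, 4.2))))
        assert v["variance"] == pytest.approx(0.0, abs=1e-15)
        assert v["zero_crossings"] == 0.0
        assert v["line_length"] == 0.0
        assert np.isfinite(list(v.values())).all()

    def test_nonfinite_input_rejected_with_key(self):
        x = np.zeros(1280)
        x[5] = np.nan
        with pytest.raises(ValidationError, match="seg-3"):
            compute_features(x, key="seg-3")

    def test_custom_callable_feature(self):
        from szevents.features import FeatureDef

        cat = default_catalog() + [
            FeatureDef("abs_sum", "time_stat", func=lambda x: np.abs(x).sum())
        ]
        x = np.sin(2 * np.pi * 3 * T)
        v = compute_features(x, cat)
        assert v[-1] == pytest.approx(np.abs(x).sum())


class TestInvariances:
    @pytest.fixture()
    def x(self, rng):
        return rng.normal(0, 12, size=1280)

    def test_amplitude_shift_invariance(self, x):
        names = catalog_names()
        a = dict(zip(names, compute_features(x)))
        b = dict(zip(names, compute_features(x + 100.0)))
        exact = ["variance", "std", "zero_crossings", "line_length",
                 "hjorth_activity", "peak_to_peak", "iqr", "mad"]
        for n in exact:
            assert a[n] == pytest.approx(b[n], rel=1e-9), n
        near = ["spectral_entropy", "alpha_power", "beta_rel_power",
                "ep_max", "ep_mean", "sef90"]
        for n in near:
            assert a[n] == pytest.approx(b[n], rel=1e-3, abs=1e-6), n

    def test_scale_equivariance(self, x):
        c = 2.5
        names = catalog_names()
        a = dict(zip(names, compute_features(x)))
        b = dict(zip(names, compute_features(c * x)))
        for n in ["variance", "energy", "alpha_power", "total_power"]:
            assert b[n] == pytest.approx(c**2 * a[n], rel=1e-4), n
        for n in ["skewness", "kurtosis", "spectral_entropy", "spectral_flatness",
                  "alpha_rel_power", "delta_rel_power", "ratio_theta_alpha",
                  "sef75", "peak_freq", "zero_crossings"]:
            assert b[n] == pytest.approx(a[n], rel=1e-3, abs=1e-8), n


@pytest.fixture(scope="module")
def table_and_timeline(tiny_dataset):
    from szevents.io import SubjectTimeline

    tl = tiny_dataset.timelines[0]
    short = SubjectTimeline(tl.subject_id, [tl.records[0]])
    return extract_table(short, entropy_stride=4), short


class TestExtractTable:
    def test_shape_and_columns(self, table_and_timeline):
        table, tl = table_and_timeline
        n_seg = int(tl.records[0].duration_s // 5)
        assert table.shape == (n_seg, 3 + 2024 + 1)
        assert list(table.columns[:3]) == ["subject", "record", "index"]
        assert table.columns[3] == "FP1-F7/mean"
        assert len(feature_columns(tl.records[0].channels.labels)) == 2024

    def test_values_match_direct_compute(self, table_and_timeline):
        table, tl = table_and_timeline
        rec = tl.records[0]
        seg_i, ch = 3, 5
        x = rec.signal[ch, seg_i * 1280 : (seg_i + 1) * 1280].astype(float)
        direct = compute_features(x, entropy_stride=4)
        lab = rec.channels.labels[ch]
        row = table[table["index"] == seg_i].iloc[0]
        got = row[[f"{lab}/{n}" for n in catalog_names()]].to_numpy(dtype=float)
        assert np.allclose(got, direct, rtol=1e-9, atol=1e-12)

    def test_labels_match_segmentation(self, table_and_timeline):
        from szevents.segment import segment_record

        table, tl = table_and_timeline
        expected = [s.label for s in segment_record(tl.records[0])]
        assert list(table["label"]) == expected

    def test_all_values_finite(self, table_and_timeline):
        table, _ = table_and_timeline
        vals = table.drop(columns=["subject", "record", "index"]).to_numpy(dtype=float)
        assert np.isfinite(vals).all()
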