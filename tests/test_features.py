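"""Feature catalogue: hand-computed examples, an independent per-formula
oracle, and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ethoclass as ec
from ethoclass.features import FULL_FEATURE_NAMES, FEATURE_GROUP_SIZES


def bout_from(x, y, z, fs=10.0):
    return ec.Bout(samples=np.column_stack([x, y, z]), fs=fs)


# ---------------------------------------------------------------------------
# independent direct-formula reference implementation (the oracle): each
# feature computed from its plain definition with explicit loops/sums,
# sharing no code with the features module.
# ---------------------------------------------------------------------------

def _moments(c):
    n = len(c)
    mean = sum(c) / n
    m2 = sum((v - mean) ** 2 for v in c) / n
    m3 = sum((v - mean) ** 3 for v in c) / n
    m4 = sum((v - mean) ** 4 for v in c) / n
    return mean, m2, m3, m4


def _quartile_type7(c, q):
    s = sorted(c)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])


def _main_freq_bruteforce(c, fs):
    n = len(c)
    mean = sum(c) / n
    x = [v - mean for v in c]
    best_k, best_amp = 1, -1.0
    for k in range(1, n // 2 + 1):
        re = sum(x[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = sum(x[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        amp = 2.0 / n * math.hypot(re, im)
        if amp > best_amp + 1e-12:
            best_k, best_amp = k, amp
    return best_k * fs / n, best_amp


def reference_features(bout):
    """Straightforward implementation of every catalogue formula."""
    raw = bout.samples
    n = len(raw)
    cols = {a: list(raw[:, i]) for i, a in enumerate("xyz")}
    out = {}
    stats = {}
    for a, c in cols.items():
        mean, m2, m3, m4 = _moments(c)
        var = m2 * n / (n - 1)
        sd = math.sqrt(var)
        stats[a] = (mean, var, sd, m2, m3, m4)
    for a in "xyz":
        out[f"mean_{a}"] = stats[a][0]
    for a in "xyz":
        out[f"var_{a}"] = stats[a][1]
    for a in "xyz":
        out[f"sd_{a}"] = stats[a][2]
    for a in "xyz":
        mean, _, sd, *_ = stats[a]
        out[f"cv_{a}"] = sd / mean if sd != 0 and mean != 0 else 0.0
    for a in "xyz":
        _, _, sd, m2, m3, m4 = stats[a]
        out[f"skew_{a}"] = m3 / m2 ** 1.5 if sd != 0 else 0.0
    for a in "xyz":
        _, _, sd, m2, m3, m4 = stats[a]
        out[f"kurt_{a}"] = m4 / m2 ** 2 - 3.0 if sd != 0 else 0.0
    for a in "xyz":
        out[f"max_{a}"] = max(cols[a])
    for a in "xyz":
        out[f"min_{a}"] = min(cols[a])
    for a in "xyz":
        out[f"range_{a}"] = max(cols[a]) - min(cols[a])
    for a in "xyz":
        out[f"norm_{a}"] = math.sqrt(sum(v * v for v in cols[a]))
    pairs = [("x", "y"), ("x", "z"), ("y", "z")]
    for a, b in pairs:
        ma, mb = stats[a][0], stats[b][0]
        cov = sum((u - ma) * (v - mb) for u, v in zip(cols[a], cols[b])) / (n - 1)
        out[f"cov_{a}{b}"] = cov
    for a, b in pairs:
        den = stats[a][2] * stats[b][2]
        out[f"corr_{a}{b}"] = out[f"cov_{a}{b}"] / den if den != 0 else 0.0
    for a, b in pairs:
        out[f"meandiff_{a}{b}"] = stats[a][0] - stats[b][0]
    for a, b in pairs:
        d = [u - v for u, v in zip(cols[a], cols[b])]
        md = sum(d) / n
        out[f"sddiff_{a}{b}"] = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    # static = per-axis mean; dynamic = raw - static
    dyn = {a: [v - stats[a][0] for v in cols[a]] for a in "xyz"}
    for a in "xyz":
        out[f"statvar_{a}"] = 0.0
    for a in "xyz":
        dm = sum(dyn[a]) / n
        out[f"dynvar_{a}"] = sum((v - dm) ** 2 for v in dyn[a]) / (n - 1)
    for a in "xyz":
        out[f"meandba_{a}"] = sum(abs(v) for v in dyn[a]) / n
    for a in "xyz":
        out[f"maxdba_{a}"] = max(abs(v) for v in dyn[a])
    out["odba"] = sum(
        abs(dyn["x"][i]) + abs(dyn["y"][i]) + abs(dyn["z"][i]) for i in range(n)
    ) / n
    mx, my, mz = stats["x"][0], stats["y"][0], stats["z"][0]
    out["pitch"] = math.degrees(math.atan2(mx, math.hypot(my, mz)))
    out["roll"] = math.degrees(math.atan2(my, mz))
    for a in "xyz":
        d = [cols[a][i + 1] - cols[a][i] for i in range(n - 1)]
        out[f"meandl_{a}"] = sum(abs(v) for v in d) / len(d)
    for a in "xyz":
        d = [cols[a][i + 1] - cols[a][i] for i in range(n - 1)]
        dm = sum(d) / len(d)
        out[f"vardl_{a}"] = (
            sum((v - dm) ** 2 for v in d) / (len(d) - 1) if len(d) > 1 else 0.0
        )
    spectra = {a: _main_freq_bruteforce(cols[a], bout.fs) for a in "xyz"}
    for a in "xyz":
        out[f"mainfreq_{a}"] = spectra[a][0]
    for a in "xyz":
        out[f"mainamp_{a}"] = spectra[a][1]
    for q in (25, 50, 75):
        for a in "xyz":
            out[f"q{q}_{a}"] = _quartile_type7(cols[a], q / 100)
    return out


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class TestDecomposition:
    def test_constant_bout_is_all_static(self):
        b = bout_from([0] * 4, [0] * 4, [1.0] * 4)
        static, dyn = ec.static_dynamic_decompose(b)
        assert np.allclose(static, b.samples)
        assert np.allclose(dyn, 0.0)

    def test_full_bout_window_hand_example(self):
        b = bout_from([1, 2, 3, 2], [0] * 4, [1] * 4)
        static, dyn = ec.static_dynamic_decompose(b)
        assert np.allclose(static[:, 0], 2.0)
        assert np.allclose(dyn[:, 0], [-1, 0, 1, 0])

    def test_sum_identity_random_bouts(self, random_bout):
        for seed in range(5):
            b = random_bout(n=37, seed=seed)
            static, dyn = ec.static_dynamic_decompose(b)
            assert np.allclose(static + dyn, b.samples, atol=1e-12)

    def test_windowed_smoothing_sums_to_raw(self, random_bout):
        b = random_bout(n=50, seed=3)
        static, dyn = ec.static_dynamic_decompose(b, window=5)
        assert np.allclose(static + dyn, b.samples, atol=1e-12)
        # a shorter window tracks the signal, leaving less dynamic energy
        assert np.abs(dyn).sum() < np.abs(ec.static_dynamic_decompose(b)[1]).sum()


class TestOdba:
    def test_constant_bout_zero(self):
        assert ec.compute_odba(bout_from([0] * 4, [0] * 4, [1] * 4)) == 0.0

    def test_alternating_axes(self):
        a = 0.25
        sig = [a, -a] * 4
        b = bout_from(sig, sig, sig)
        assert ec.compute_odba(b) == pytest.approx(3 * a)

    def test_hand_example(self):
        b = bout_from([1, 2, 3, 2], [0] * 4, [-1, 1, -1, 1])
        assert ec.compute_odba(b) == pytest.approx(0.5 + 0.0 + 1.0)


class TestPitchRoll:
    @pytest.mark.parametrize(
        "mean_vec, pitch, roll",
        [((0, 0, 1), 0.0, 0.0), ((1, 0, 0), 90.0, 0.0),
         ((0.5, 0, np.sqrt(3) / 2), 30.0, 0.0), ((0, 1, 0), 0.0, 90.0)],
    )
    def test_closed_form_angles(self, mean_vec, pitch, roll):
        b = bout_from(*([v] * 4 for v in mean_vec))
        got = ec.compute_pitch_roll(b)
        assert got == (pytest.approx(pitch, abs=1e-9), pytest.approx(roll, abs=1e-9))

    def test_zero_vector_warns_and_returns_zero(self):
        b = bout_from([1, -1], [1, -1], [1, -1])
        with pytest.warns(UserWarning):
            assert ec.compute_pitch_roll(b) == (0.0, 0.0)

    def test_rotation_moves_pitch_monotonically(self):
        angles = np.linspace(0, 90, 10)
        pitches = []
        for ang in angles:
            r = np.radians(ang)
            b = bout_from([np.sin(r)] * 4, [0] * 4, [np.cos(r)] * 4)
            pitches.append(ec.compute_pitch_roll(b)[0])
        assert np.allclose(pitches, angles, atol=1e-9)


class TestMainFrequency:
    def test_exact_bin_sinusoid(self):
        fs, n = 40.0, 40
        t = np.arange(n) / fs
        freq, amp = ec.compute_main_frequency(np.sin(2 * np.pi * 2 * t), fs)
        assert freq == pytest.approx(2.0)
        assert amp == pytest.approx(1.0)

    def test_constant_signal_zero_amplitude(self):
        freq, amp = ec.compute_main_frequency(np.ones(16), 8.0)
        assert amp == 0.0
        assert freq == pytest.approx(0.5)  # first non-DC bin

    def test_two_tone_picks_larger(self):
        fs, n = 40.0, 40
        t = np.arange(n) / fs
        sig = np.sin(2 * np.pi * 2 * t) + 2 * np.sin(2 * np.pi * 5 * t)
        freq, amp = ec.compute_main_frequency(sig, fs)
        assert freq == pytest.approx(5.0)
        assert amp == pytest.approx(2.0)

    def test_matches_bruteforce_dft(self, random_bout):
        b = random_bout(n=31, seed=7)
        for ax in range(3):
            got = ec.compute_main_frequency(b.samples[:, ax], b.fs)
            want = _main_freq_bruteforce(list(b.samples[:, ax]), b.fs)
            assert got == (pytest.approx(want[0]), pytest.approx(want[1]))


# ---------------------------------------------------------------------------
# the full catalogue
# ---------------------------------------------------------------------------

class TestFullCatalogue:
    def test_exactly_78_named_features(self, stork_bouts):
        fv = ec.compute_full_features(stork_bouts[0])
        assert len(fv) == 78
        assert fv.names == FULL_FEATURE_NAMES

    def test_group_sizes(self):
        assert FEATURE_GROUP_SIZES == (30, 12, 13, 2, 6, 6, 9)
        assert sum(FEATURE_GROUP_SIZES) == 78 == len(FULL_FEATURE_NAMES)

    def test_constant_bout_degenerate_values(self):
        fv = ec.compute_full_features(bout_from([0] * 6, [0] * 6, [1] * 6))
        for name in fv.names:
            assert np.isfinite(fv[name]), name
        for stat in ("var", "sd", "cv", "range", "dynvar", "meandba", "maxdba"):
            for a in "xyz":
                assert fv[f"{stat}_{a}"] == 0.0
        for pair in ("xy", "xz", "yz"):
            assert fv[f"corr_{pair}"] == 0.0
        assert fv["odba"] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_bouts(self, random_bout, seed):
        """Every feature matches an independent direct-formula implementation."""
        b = random_bout(n=40, seed=seed)
        fv = ec.compute_full_features(b)
        ref = reference_features(b)
        for name in FULL_FEATURE_NAMES:
            assert fv[name] == pytest.approx(ref[name], abs=1e-9), name

    def test_oracle_equivalence_odd_length(self, random_bout):
        b = random_bout(n=33, seed=99)
        fv = ec.compute_full_features(b)
        ref = reference_features(b)
        for name in FULL_FEATURE_NAMES:
            assert fv[name] == pytest.approx(ref[name], abs=1e-9), name

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariants_hold_on_random_bouts(self, seed):
        rng = np.random.default_rng(seed)
        b = ec.Bout(samples=rng.normal(0, 1, size=(24, 3)), fs=10.0)
        fv = ec.compute_full_features(b)
        assert fv["odba"] >= 0
        for a in "xyz":
            assert fv[f"var_{a}"] >= 0
            assert fv[f"range_{a}"] >= 0
        for pair in ("xy", "xz", "yz"):
            assert abs(fv[f"corr_{pair}"]) <= 1 + 1e-12
        assert np.all(np.isfinite(fv.as_array()))


class TestSimplifiedSets:
    @pytest.mark.parametrize("placement, n", [("back", 5), ("collar", 5),
                                              ("leg", 5), ("ear", 4)])
    def test_feature_counts_per_placement(self, stork_bouts, placement, n):
        fv = ec.compute_simplified_features(stork_bouts[0], placement)
        assert len(fv) == n
        assert fv.set_kind == "simplified"

    def test_unknown_placement_rejected(self, stork_bouts):
        with pytest.raises(ec.ValidationError):
            ec.compute_simplified_features(stork_bouts[0], "tail")

    def test_values_equal_full_catalogue_counterparts(self, random_bout):
        b = random_bout(n=40, seed=5)
        full = ec.compute_full_features(b)
        back = ec.compute_simplified_features(b, "back")
        # default axis map: surge=x, heave=z
        assert back["mean_surge"] == full["mean_x"]
        assert back["sd_surge"] == full["sd_x"]
        assert back["mean_heave"] == full["mean_z"]
        assert back["sd_heave"] == full["sd_z"]
        assert back["odba"] == full["odba"]
        ear = ec.compute_simplified_features(b, "ear")
        assert ear["mainfreq_heave"] == full["mainfreq_z"]

    def test_axis_map_reroutes_roles(self, random_bout):
        b = random_bout(n=20, seed=6)
        amap = ec.AxisMap(surge=2, sway=0, heave=1)
        fv = ec.compute_simplified_features(b, "back", axis_map=amap)
        full = ec.compute_full_features(b)
        assert fv["mean_surge"] == full["mean_z"]
        assert fv["mean_heave"] == full["mean_y"]


def test_feature_table_shape(stork_bouts):
    tab = ec.feature_table(stork_bouts, "full")
    assert tab.shape == (len(stork_bouts), 2 + 78)
    assert list(tab.columns[:2]) == ["bout_id", "label"]
    simp = ec.feature_table(stork_bouts, "simplified", "back")
    assert simp.shape == (len(stork_bouts), 2 + 5)
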