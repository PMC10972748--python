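"""Tracking, decay fitting, and PCNA pattern/transition detection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk

from qibcdeg.kinetics import (
    classify_pcna_pattern,
    detect_phase_transitions,
    fit_chase_table,
    fit_exponential_decay,
    link_tracks,
    normalize_track,
)
from qibcdeg.synthetic_data import ChaseTruth, simulate_chase


def _frames(trajectories, mfi=100.0):
    """trajectories: list of [(x, y) per frame or None]."""
    rows = []
    for f in range(max(len(t) for t in trajectories)):
        for i, traj in enumerate(trajectories):
            if f < len(traj) and traj[f] is not None:
                x, y = traj[f]
                rows.append(
                    {"frame": f, "cell_id": i + 1, "centroid_x": x, "centroid_y": y,
                     "cgas_gfp_mfi_corrected": mfi}
                )
    return pd.DataFrame(rows)


class TestLinkTracks:
    def test_stationary_nuclei_one_full_track_each(self):
        trajs = [[(50, 50)] * 10, [(150, 90)] * 10, [(260, 200)] * 10]
        tracks = link_tracks(_frames(trajs))
        assert len(tracks) == 3
        assert all(len(t) == 10 for t in tracks)

    def test_disappearing_nucleus_terminates_track(self):
        trajs = [[(50, 50)] * 10, [(150, 90)] * 5 + [None] * 5]
        tracks = link_tracks(_frames(trajs))
        assert sorted(len(t) for t in tracks) == [5, 10]

    def test_each_detection_in_at_most_one_track(self):
        rng = np.random.default_rng(3)
        trajs = [
            [(x0 + rng.normal(0, 2), y0 + rng.normal(0, 2)) for _ in range(8)]
            for x0, y0 in [(40, 40), (90, 40), (40, 90), (90, 90)]
        ]
        frames = _frames(trajs)
        tracks = link_tracks(frames)
        n_linked = sum(len(t) for t in tracks)
        assert n_linked == len(frames)

    def test_crossing_pair_matches_exhaustive_assignment(self):
        # two nuclei on crossing paths, < max_disp per frame; greedy matching
        # must reproduce the global minimum found by enumerating assignments
        a = [(10 + 8 * f, 50.0) for f in range(10)]
        b = [(82 - 8 * f, 54.0) for f in range(10)]
        tracks = link_tracks(_frames([a, b]), max_disp=20.0)
        assert len(tracks) == 2
        got = {tuple(tr.xy) for tr in tracks}

        # brute force: per frame pair, pick the permutation minimizing total cost
        truth_tracks = [[a[0]], [b[0]]]
        for f in range(1, 10):
            prev = [t[-1] for t in truth_tracks]
            cur = [a[f], b[f]]
            best = min(
                itertools.permutations(range(2)),
                key=lambda perm: sum(
                    math.dist(prev[i], cur[perm[i]]) for i in range(2)
                ),
            )
            for i in range(2):
                truth_tracks[i].append(cur[best[i]])
        assert got == {tuple(t) for t in truth_tracks}


class TestNormalizeTrack:
    def test_reference_frame_is_one_and_arithmetic(self):
        tracks = link_tracks(_frames([[(10, 10)] * 3]))
        tr = tracks[0]
        tr.mfi = [200.0, 100.0, 50.0]
        normalize_track(tr)
        assert tr.relative_mfi == [1.0, 0.5, 0.25]

    def test_scale_invariance(self):
        tracks = link_tracks(_frames([[(10, 10)] * 4]))
        tr = tracks[0]
        tr.mfi = [5.0, 4.0, 2.0, 1.0]
        base = list(normalize_track(tr).relative_mfi)
        tr.mfi = [v * 123.4 for v in tr.mfi]
        assert normalize_track(tr).relative_mfi == pytest.approx(base)

    def test_nonpositive_reference_raises(self):
        tracks = link_tracks(_frames([[(10, 10)] * 2]))
        tr = tracks[0]
        tr.mfi = [0.0, 1.0]
        with pytest.raises(ValueError):
            normalize_track(tr)


class TestFitExponentialDecay:
    def test_exact_exponential_recovers_half_life(self):
        t = [0.0, 2.0, 4.0, 6.0]
        v = [100.0 * 2 ** (-ti / 4.0) for ti in t]
        fit = fit_exponential_decay(t, v)
        assert fit.half_life == pytest.approx(4.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n0 == pytest.approx(100.0, rel=1e-12)

    def test_constant_series_has_infinite_half_life(self):
        fit = fit_exponential_decay([0, 2, 4], [5.0, 5.0, 5.0])
        assert fit.rate_k == 0.0
        assert math.isinf(fit.half_life)

    def test_increasing_series_clamps_to_zero_rate(self):
        with pytest.warns(UserWarning, match="clamping"):
            fit = fit_exponential_decay([0, 2, 4], [1.0, 2.0, 4.0])
        assert fit.rate_k == 0.0

    @pytest.mark.parametrize(
        "t,v", [([0, 1], [1.0, 0.5]), ([0, 1, 2], [1.0, 0.0, -1.0])]
    )
    def test_invalid_inputs_raise(self, t, v):
        with pytest.raises(ValueError):
            fit_exponential_decay(t, v)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(k=st.floats(min_value=1e-3, max_value=2.0))
    def test_half_life_identity(self, k):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        fit = fit_exponential_decay(t, 50.0 * np.exp(-k * t))
        assert fit.half_life * fit.rate_k == pytest.approx(math.log(2), rel=1e-9)

    def test_noisy_replicates_recover_rate_within_two_percent(self):
        truth = ChaseTruth(rate_k=0.2, noise_cv=0.05)
        table = simulate_chase(truth, seed=13, n_replicates=500)
        fits = fit_chase_table(table)
        assert len(fits) == 500
        assert np.median(fits["rate_k"]) == pytest.approx(0.2, rel=0.02)

    def test_fit_closure_on_noiseless_simulation(self):
        truth = ChaseTruth(rate_k=0.31, n0=77.0, noise_cv=0.0)
        table = simulate_chase(truth, seed=0)
        fit = fit_exponential_decay(table["time_h"], table["abundance"])
        assert fit.rate_k == pytest.approx(0.31, rel=1e-9)
        assert fit.n0 == pytest.approx(77.0, rel=1e-9)


class TestPcnaPattern:
    def test_uniform_crop_is_diffuse_with_zero_score(self):
        label, score = classify_pcna_pattern(np.full((25, 25), 120.0))
        assert label == "diffuse" and score == 0.0

    def test_focal_crop_is_punctate(self, rng):
        crop = np.full((41, 41), 100.0)
        for r, c in rng.integers(5, 36, (10, 2)):
            rr, cc = disk((r, c), 2, shape=crop.shape)
            crop[rr, cc] = 500.0  # 5x background replication foci
        label, score = classify_pcna_pattern(crop)
        assert label == "punctate" and score > 1.0

    def test_score_exactly_at_threshold_is_diffuse(self):
        crop = np.full((25, 25), 100.0)
        _, score = classify_pcna_pattern(crop, threshold=0.0)
        assert score == 0.0
        assert classify_pcna_pattern(crop, threshold=0.0)[0] == "diffuse"

    def test_small_crop_raises(self):
        with pytest.raises(ValueError, match="pixels"):
            classify_pcna_pattern(np.full((4, 4), 1.0))


def _oracle_transitions(pattern, min_run):
    """Independent run-length scan used to cross-check the implementation."""
    out = {}
    i = 0
    n = len(pattern)
    while i <= n - min_run and "G1_S" not in out:
        if all(p == "punctate" for p in pattern[i : i + min_run]):
            out["G1_S"] = i
        i += 1
    if "G1_S" in out:
        j = out["G1_S"] + min_run
        while j <= n - min_run and "S_G2" not in out:
            if all(p == "diffuse" for p in pattern[j : j + min_run]):
                out["S_G2"] = j
            j += 1
    return out


class TestPhaseTransitions:
    def test_clean_pulse(self):
        pat = ["diffuse"] * 3 + ["punctate"] * 4 + ["diffuse"] * 3
        assert detect_phase_transitions(pat) == {"G1_S": 3, "S_G2": 7}

    def test_all_diffuse_has_no_boundaries(self):
        assert detect_phase_transitions(["diffuse"] * 8) == {}

    def test_flicker_ignored(self):
        pat = ["diffuse", "punctate", "diffuse", "diffuse",
               "punctate", "punctate", "punctate"]
        assert detect_phase_transitions(pat) == {"G1_S": 4}

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        bits=st.lists(st.booleans(), min_size=1, max_size=24),
        min_run=st.integers(min_value=1, max_value=4),
    )
    def test_matches_brute_force_scan(self, bits, min_run):
        pat = ["punctate" if b else "diffuse" for b in bits]
        assert detect_phase_transitions(pat, min_run) == _oracle_transitions(pat, min_run)
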