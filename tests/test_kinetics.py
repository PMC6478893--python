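"""Site-contact series, smoothing, event extraction and residence statistics."""

import numpy as np
import pytest

from cglipidsite.core import AnalysisConfig
from cglipidsite.kinetics import (
    SiteDefinition,
    default_log_bins,
    extract_events,
    majority_smooth,
    raw_contact_series,
    residence_time_distribution,
    time_weighted_mean,
)

from conftest import make_topology, make_trajectory


def brute_force_scanner(series, frame_interval):
    """Independent run-length scan with end-censoring count."""
    events = []
    n_end = 0
    run = 0
    for i, v in enumerate(series):
        if v:
            run += 1
        elif run:
            events.append((i - run, run, run * frame_interval))
            run = 0
    if run:
        n_end += 1
    return events, n_end


def brute_force_vote(series, window=5, min_true=3):
    """Per-frame majority vote on the edge-replicated padded series."""
    n = len(series)
    half = window // 2
    out = []
    for i in range(n):
        votes = 0
        for k in range(i - half, i + half + 1):
            votes += series[min(max(k, 0), n - 1)]
        out.append(1 if votes >= min_true else 0)
    return out


class TestRawContactSeries:
    @staticmethod
    def _site_fixture(d1, d2, d3):
        """One head bead at given distances from three one-residue groups."""
        topo = make_topology(3, 1, prot_resids=[58, 73, 81])
        # groups placed along orthogonal axes from the origin corner region
        g = np.array([[20.0, 20, 20], [60.0, 20, 20], [20.0, 60, 20]])
        head = [20.0 + 0, 20, 20]
        frame = np.vstack([g, [head]])
        # move head so that its distance to each group is d1/d2/d3: place the
        # groups instead at the requested distances along distinct axes
        frame = np.array(
            [
                [20.0 + d1, 20, 20],
                [20.0, 20 + d2, 20],
                [20.0, 20, 20 + d3],
                [20.0, 20, 20],
            ]
        )
        traj = make_trajectory([frame], topology=topo)
        site = SiteDefinition(groups=((58,), (73,), (81,)))
        return traj, site

    @pytest.mark.parametrize(
        "dists,expected",
        [
            ((5.0, 5.0, 12.0), 1),  # 2 of 3 within 8 Å
            ((5.0, 12.0, 12.0), 0),  # only 1 group
            ((5.0, 5.0, 5.0), 1),  # all 3
        ],
    )
    def test_min_groups_rule(self, dists, expected):
        traj, site = self._site_fixture(*dists)
        series = raw_contact_series(traj, site, ligand=1, head_names=("AM1",))
        assert series.tolist() == [expected]

    def test_empty_group_raises(self):
        traj, _ = self._site_fixture(5, 5, 5)
        site = SiteDefinition(groups=((58,), (73,), (99,)))
        with pytest.raises(ValueError, match="no protein residues"):
            raw_contact_series(traj, site, ligand=1, head_names=("AM1",))

    def test_site_groups_must_be_disjoint(self):
        with pytest.raises(ValueError, match="disjoint"):
            SiteDefinition(groups=((58, 59), (59, 60), (81,)))


class TestMajoritySmooth:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([1, 1, 1, 1, 1], [1, 1, 1, 1, 1]),  # constant identity
            ([0, 0, 1, 0, 0], [0, 0, 0, 0, 0]),  # isolated spike removed
            ([1, 1, 0, 1, 1], [1, 1, 1, 1, 1]),  # brief loss bridged
        ],
    )
    def test_examples(self, series, expected):
        assert majority_smooth(series).tolist() == expected
        assert brute_force_vote(series) == expected

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            majority_smooth([1, 0, 1], window=4, min_true=2)

    def test_isolated_features_in_constant_series(self):
        # every isolated spike/gap of length <= window - min_true vanishes
        for gap in (1, 2):
            base = [1] * 10
            base[5 : 5 + gap] = [0] * gap
            assert majority_smooth(base).tolist() == [1] * 10
            base = [0] * 10
            base[5 : 5 + gap] = [1] * gap
            assert majority_smooth(base).tolist() == [0] * 10
        # length-3 features survive the 5/3 vote
        base = [0] * 10
        base[4:7] = [1, 1, 1]
        assert sum(majority_smooth(base)) == 3


class TestExtractEvents:
    def test_end_censoring_example(self):
        ev = extract_events([0, 1, 1, 1, 0, 1, 1], 600.0)
        assert len(ev.events) == 1
        assert ev.events[0].duration == pytest.approx(1800.0)
        assert ev.n_discarded_end_censored == 1

    def test_all_zero_and_fully_bound(self):
        assert extract_events([0, 0, 0], 600.0).events == []
        ev = extract_events([1, 1, 1], 600.0)
        assert ev.events == []
        assert ev.n_discarded_end_censored == 1

    def test_start_censoring_flag(self):
        ev = extract_events([1, 1, 0, 1, 0], 600.0, discard_start_censored=True)
        assert [e.start_frame for e in ev.events] == [3]
        assert ev.n_discarded_start_censored == 1

    def test_oracle_equivalence_random_series(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 200))
            series = (rng.random(n) < rng.uniform(0.05, 0.95)).astype(int)
            ev = extract_events(series, 600.0)
            expected, n_end = brute_force_scanner(series, 600.0)
            got = [(e.start_frame, e.n_frames, e.duration) for e in ev.events]
            assert got == expected
            assert ev.n_discarded_end_censored == n_end
            # events are non-overlapping and separated by >= 1 unbound frame
            for a, b in zip(ev.events, ev.events[1:]):
                assert b.start_frame > a.start_frame + a.n_frames


class TestResidenceDistribution:
    def test_caption_identity_example(self):
        # events of 2 and 3 frames in a 10-frame run -> sum(y) = 0.5
        ev = extract_events([0, 1, 1, 0, 0, 1, 1, 1, 0, 0], 600.0)
        hist = residence_time_distribution(
            ev, bins=default_log_bins(600.0, 6000.0)
        )
        assert hist.bound_fraction == pytest.approx(0.5, abs=1e-12)

    def test_conservation_random_event_sets(self, rng):
        for _ in range(300):
            n = int(rng.integers(10, 200))
            series = (rng.random(n) < 0.4).astype(int)
            ev = extract_events(series, 600.0)
            if not ev.events:
                continue
            bins = default_log_bins(600.0, ev.total_time)
            hist = residence_time_distribution(ev, bins=bins)
            retained = ev.bound_time / ev.total_time
            assert hist.bound_fraction == pytest.approx(retained, abs=1e-12)

    def test_single_event_single_bin(self):
        ev = extract_events([0, 1, 1, 1, 1, 0, 0, 0, 0, 0], 600.0)
        bins = np.array([500.0, 3000.0, 6000.0])
        hist = residence_time_distribution(ev, bins=bins)
        assert hist.y[0] == pytest.approx(2400.0 / 6000.0)
        assert hist.y[1] == 0.0

    def test_out_of_range_event_raises(self):
        ev = extract_events([0, 1, 1, 1, 1, 0], 600.0)
        with pytest.raises(ValueError, match="outside"):
            residence_time_distribution(ev, bins=np.array([100.0, 1000.0]))

    def test_no_events_all_zero(self):
        ev = extract_events([0, 0, 0, 0, 0, 0, 0, 0, 0, 0], 600.0)
        hist = residence_time_distribution(ev, bins=np.array([600.0, 6000.0]))
        assert hist.bound_fraction == 0.0


class TestTimeWeightedMean:
    @pytest.mark.parametrize(
        "durations,expected",
        [([1, 1, 1], 1.0), ([1, 3], 2.5), ([5], 5.0)],
    )
    def test_examples(self, durations, expected):
        assert time_weighted_mean(durations) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            time_weighted_mean([])

    def test_dominated_by_long_events(self, rng):
        d = rng.exponential(1.0, 100)
        assert time_weighted_mean(d) >= d.mean()
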