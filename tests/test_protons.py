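import math

import numpy as np
import pytest

from carbodyn.protons import (
    DissociationEpisode,
    HopEvent,
    HostInterval,
    analyze_protons,
    classify_transitions,
    episode_statistics,
    extract_hops,
    filter_rattling,
    mark_concerted,
    segment_episodes,
    transition_fraction_indirect,
)
from carbodyn.synth import (
    EpisodeScript,
    GeometryTemplates,
    generate_episode_stream,
    render_atomistic,
)
from carbodyn.topology import StateSequence


def intervals(*pairs, lead=1.0):
    """Build a HostInterval series from (host, duration) pairs."""
    out = []
    t = 0.0
    for host, dur in pairs:
        out.append(HostInterval(host, t, t + dur))
        t += dur
    return out


def as_pairs(series):
    return [(iv.host, round(iv.duration, 6)) for iv in series]


# ---------------------------------------------------------------------------
# brute-force oracle for the minimum-residence filter
# ---------------------------------------------------------------------------

def oracle_filter(pairs, tau):
    """Independent brute-force realization of the rattling rule.

    Works on (host, duration) tuples.  Every contiguous block of interior
    sub-threshold intervals is enumerated by exhaustive (i, j) scan; the
    largest (leftmost on ties) block whose two flanks share a host is
    deleted with its duration absorbed, and the procedure restarts until no
    deletable block remains.
    """

    def merge(s):
        out = []
        for h, d in s:
            if out and out[-1][0] == h:
                out[-1] = [h, out[-1][1] + d]
            else:
                out.append([h, d])
        return [tuple(x) for x in out]

    s = merge(list(pairs))
    while True:
        n = len(s)
        candidates = []
        for i in range(1, n - 1):
            for j in range(i, n - 1):
                if all(s[k][1] < tau - 1e-9 for k in range(i, j + 1)):
                    candidates.append((i, j))
        candidates.sort(key=lambda b: (-(b[1] - b[0]), b[0]))
        for i, j in candidates:
            if s[i - 1][0] == s[j + 1][0]:
                absorbed = sum(d for _, d in s[i - 1:j + 2])
                s = merge(s[:i - 1] + [(s[i - 1][0], absorbed)] + s[j + 2:])
                break
        else:
            return tuple(s)


class TestFilterRattling:
    def test_pure_rattle_removed(self):
        s = filter_rattling(intervals(("A", 1.0), ("B", 0.05), ("A", 1.0)), 0.2)
        assert as_pairs(s) == [("A", 2.05)]
        assert extract_hops(s) == []

    def test_mediating_run_retained_by_default(self):
        s = filter_rattling(intervals(("A", 1.0), ("B", 0.05), ("C", 1.0)), 0.2)
        assert [iv.host for iv in s] == ["A", "B", "C"]
        assert len(extract_hops(s)) == 2

    def test_mediating_run_collapsed_when_requested(self):
        s = filter_rattling(intervals(("A", 1.0), ("B", 0.05), ("C", 1.0)), 0.2,
                            collapse_mediated=True)
        assert [iv.host for iv in s] == ["A", "C"]
        assert len(extract_hops(s)) == 1

    def test_multi_interval_rattle_run(self):
        s = filter_rattling(
            intervals(("A", 1.0), ("B", 0.1), ("C", 0.1), ("A", 1.0)), 0.2
        )
        assert as_pairs(s) == [("A", 2.2)]

    def test_terminal_intervals_exempt(self):
        s = filter_rattling(intervals(("A", 0.05), ("B", 1.0), ("C", 0.05)), 0.2)
        assert [iv.host for iv in s] == ["A", "B", "C"]

    def test_zero_tau_is_identity_up_to_merging(self):
        ivs = intervals(("A", 1.0), ("B", 0.01), ("A", 0.01))
        assert as_pairs(filter_rattling(ivs, 0.0)) == as_pairs(ivs)

    def test_matches_brute_force_oracle_on_random_series(self, rng):
        hosts = list("ABCD")
        for _ in range(200):
            n = int(rng.integers(2, 12))
            pairs = []
            prev = None
            for _ in range(n):
                h = hosts[int(rng.integers(len(hosts)))]
                while h == prev:
                    h = hosts[int(rng.integers(len(hosts)))]
                prev = h
                d = float(rng.choice([0.05, 0.1, 0.15, 0.25, 0.5, 1.0]))
                pairs.append((h, d))
            expected = oracle_filter(pairs, 0.2)
            got = filter_rattling(intervals(*pairs), 0.2)
            assert as_pairs(got) == [(h, round(d, 6)) for h, d in expected]

    def test_monotone_in_tau(self, rng):
        """Increasing tau_commit never increases the accepted hop count."""
        hosts = list("ABC")
        for _ in range(100):
            n = int(rng.integers(2, 10))
            pairs = []
            prev = None
            for _ in range(n):
                h = hosts[int(rng.integers(3))]
                while h == prev:
                    h = hosts[int(rng.integers(3))]
                prev = h
                pairs.append((h, float(rng.uniform(0.02, 0.6))))
            counts = [
                len(extract_hops(filter_rattling(intervals(*pairs), tau)))
                for tau in (0.0, 0.1, 0.2, 0.4)
            ]
            assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestExtractHops:
    def test_two_hop_return(self):
        s = intervals(("acid", 1.0), ("w", 0.5), ("acid", 1.0))
        hops = extract_hops(s)
        assert len(hops) == 2
        assert (hops[0].from_o, hops[0].to_o) == ("acid", "w")
        assert (hops[1].from_o, hops[1].to_o) == ("w", "acid")

    def test_four_hop_long_range(self):
        s = intervals(("a", 1.0), ("w1", 0.3), ("w2", 0.3), ("w1", 0.3), ("a", 1.0))
        assert len(extract_hops(s)) == 4

    def test_empty(self):
        assert extract_hops([]) == []


class TestMarkConcerted:
    def hops(self, times_hosts):
        return [HopEvent(t, 0, a, b) for t, a, b in times_hosts]

    def test_shared_intermediate_within_window(self):
        marked = mark_concerted(self.hops([(5.00, "a", "b"), (5.04, "b", "c")]), 0.1)
        assert marked[0].concerted_group == marked[1].concerted_group is not None

    def test_slow_hops_stay_single(self):
        marked = mark_concerted(self.hops([(1.0, "a", "b"), (2.0, "b", "c")]), 0.1)
        assert all(h.concerted_group is None for h in marked)

    def test_transitive_chain_of_three(self):
        marked = mark_concerted(
            self.hops([(1.0, "a", "b"), (1.05, "b", "c"), (1.10, "c", "d")]), 0.1
        )
        groups = {h.concerted_group for h in marked}
        assert groups == {0}

    def test_no_shared_oxygen_not_grouped(self):
        marked = mark_concerted(self.hops([(1.0, "a", "b"), (1.01, "c", "d")]), 0.1)
        assert all(h.concerted_group is None for h in marked)


def make_seq(labels, dt=0.1, acid=(1, 2, 3)):
    return StateSequence(labels=list(labels), dihedrals=np.full((len(labels), 2), np.nan),
                         times=np.arange(len(labels)) * dt, acid_oxygens=tuple(acid),
                         carbon=0)


class TestSegmentEpisodes:
    def test_homing(self):
        seq = make_seq(["H2CO3_CT"] * 100)
        hops = [HopEvent(5.0, 0, 2, 10), HopEvent(6.0, 0, 10, 2)]
        eps = segment_episodes(hops, seq)
        assert len(eps) == 1
        e = eps[0]
        assert e.endpoint == "homing" and e.n_hops == 2 and e.range_class == "short"
        assert e.source_conformer == "CT"

    def test_exploratory_on_other_carboxyl_oxygen(self):
        seq = make_seq(["H2CO3_CC"] * 100)
        hops = [HopEvent(5.0, 0, 2, 10), HopEvent(6.0, 0, 10, 3)]
        e = segment_episodes(hops, seq)[0]
        assert e.endpoint == "exploratory"

    def test_escaped_at_trajectory_end(self):
        seq = make_seq(["H2CO3_CC"] * 100)
        hops = [HopEvent(5.0, 0, 2, 10), HopEvent(6.0, 0, 10, 11)]
        e = segment_episodes(hops, seq)[0]
        assert e.endpoint == "escaped"

    def test_endpoint_trichotomy(self, rng):
        seq = make_seq(["H2CO3_CC"] * 1000)
        waters = list(range(10, 16))
        hops = []
        t = 1.0
        cur = 2
        for _ in range(60):
            nxt = int(rng.choice(waters + [2, 3]))
            if nxt == cur:
                continue
            hops.append(HopEvent(t, 0, cur, nxt))
            cur = nxt
            t += 0.5
        eps = segment_episodes(hops, seq)
        assert all(e.endpoint in ("homing", "exploratory", "escaped") for e in eps)
        # completed episodes are disjoint in time
        done = [e for e in eps if e.endpoint != "escaped"]
        for a, b in zip(done, done[1:]):
            assert a.t_end <= b.t_start


class TestClassifyTransitions:
    def test_adjacent_is_direct(self):
        events = classify_transitions(make_seq(["H2CO3_CT"] * 3 + ["H2CO3_CC"] * 3))
        assert len(events) == 1 and events[0].kind == "direct"

    def test_bicarbonate_interval_is_indirect(self):
        events = classify_transitions(
            make_seq(["H2CO3_CT"] * 3 + ["HCO3"] * 2 + ["H2CO3_CC"] * 3)
        )
        assert events[0].kind == "indirect"

    def test_return_to_same_conformer_not_counted(self):
        events = classify_transitions(
            make_seq(["H2CO3_CT"] * 3 + ["HCO3"] * 2 + ["H2CO3_CT"] * 3)
        )
        assert events == []

    def test_fraction_over_ct_to_cc_only(self):
        seq = make_seq(
            ["H2CO3_CT"] * 2 + ["HCO3"] * 2 + ["H2CO3_CC"] * 2
            + ["H2CO3_CT"] * 2 + ["H2CO3_CC"] * 2
        )
        events = classify_transitions(seq)
        assert transition_fraction_indirect(events) == pytest.approx(50.0)


class TestEpisodeStatistics:
    def ep(self, source, endpoint, n_hops=2):
        return DissociationEpisode(
            source_conformer=source, origin_o=2, hops=[], n_hops=n_hops,
            range_class="short" if n_hops == 2 else "long",
            endpoint=endpoint, t_start=0.0, t_end=1.0,
        )

    def test_source_fraction(self):
        eps = [self.ep("CT", "homing")] * 3 + [self.ep("CC", "homing")]
        st = episode_statistics(eps)
        assert st["source_fraction_pct"]["CT"] == pytest.approx(75.0)

    def test_all_two_hop_mass(self):
        st = episode_statistics([self.ep("CC", "homing")] * 5)
        assert st["hop_histogram"] == {"CC": {2: 5}}
        assert st["short_range_pct"] == pytest.approx(100.0)

    def test_escaped_and_overlapping_excluded(self):
        bad = self.ep("CC", "escaped")
        ov = self.ep("CC", "homing")
        ov.overlapping = True
        st = episode_statistics([self.ep("CT", "homing"), bad, ov])
        assert st["n_completed"] == 1

    def test_empty_warns(self, caplog):
        with caplog.at_level("WARNING"):
            st = episode_statistics([])
        assert st["n_completed"] == 0

    def test_binomial_recovery_on_scripted_episodes(self, rng):
        p = 0.7
        n = 2000
        eps = [
            self.ep("CC", "homing" if rng.random() < p else "exploratory")
            for _ in range(n)
        ]
        st = episode_statistics(eps)
        se = math.sqrt(p * (1 - p) / n) * 100
        assert abs(st["homing_fraction_pct"]["CC"] - 100 * p) < 3 * se


class TestEndToEndOnRenderedTrajectories:
    def test_two_hop_homing_script(self):
        script = EpisodeScript(source="CC", hosts=[0], endpoint="homing")
        traj, _ = render_atomistic([script], GeometryTemplates(jitter=0.0), seed=7)
        res = analyze_protons(traj)
        assert len(res.episodes) == 1
        e = res.episodes[0]
        assert e.n_hops == 2 and e.endpoint == "homing" and e.source_conformer == "CC"

    def test_three_water_relay(self):
        script = EpisodeScript(source="CT", hosts=[0, 3, 5], endpoint="exploratory")
        traj, _ = render_atomistic([script], GeometryTemplates(jitter=0.0), seed=8)
        res = analyze_protons(traj)
        e = res.episodes[0]
        assert e.n_hops == 4 and e.range_class == "long"
        assert e.endpoint == "exploratory"

    def test_fully_associated_trajectory_has_no_episodes(self):
        labels = ["H2CO3_CC"] * 20
        seq = make_seq(labels)
        traj, _ = render_atomistic(
            StateSequence(labels=labels, dihedrals=np.full((20, 2), np.nan),
                          times=np.arange(20) * 0.1),
            GeometryTemplates(jitter=0.0), seed=9,
        )
        res = analyze_protons(traj)
        assert res.episodes == [] and res.hops == []

    def test_rattled_render_matches_rattle_free_ground_truth(self):
        """Rattle insertions raise the raw hop count but filtered episodes
        equal the clean script exactly."""
        clean = [
            EpisodeScript(source="CC", hosts=[0, 2], endpoint="homing"),
            EpisodeScript(source="CT", hosts=[4], endpoint="exploratory"),
        ]
        rattled = [
            EpisodeScript(source="CC", hosts=[0, 2], endpoint="homing",
                          rattles=[(0, 5), (1, 3)]),
            EpisodeScript(source="CT", hosts=[4], endpoint="exploratory",
                          rattles=[(0, 1)]),
        ]
        t_clean, _ = render_atomistic(clean, GeometryTemplates(jitter=0.0), seed=10)
        t_rat, _ = render_atomistic(rattled, GeometryTemplates(jitter=0.0), seed=10)
        res_clean = analyze_protons(t_clean)
        res_rat = analyze_protons(t_rat)
        raw = analyze_protons(t_rat, tau_commit=0.0)
        assert len(raw.hops) > len(res_rat.hops)
        got = [(e.source_conformer, e.n_hops, e.endpoint) for e in res_rat.episodes]
        want = [(e.source_conformer, e.n_hops, e.endpoint) for e in res_clean.episodes]
        assert got == want

    def test_statistics_recovery_against_generator(self):
        config = {
            "source_weights": {"CT": 0.6, "CC": 0.4},
            "hop_distribution": {2: 0.7, 3: 0.2, 4: 0.1},
            "endpoint_probs": {"CT": {"homing": 0.9}, "CC": {"homing": 0.5}},
            "rattle_rate": 0.4,
        }
        scripts, truth = generate_episode_stream(config, 150, seed=12)
        traj, _ = render_atomistic(scripts, seed=12)
        st = analyze_protons(traj).statistics
        assert st["n_completed"] == 150
        for s in ("CC", "CT"):
            assert st["source_fraction_pct"][s] == pytest.approx(
                truth["source_fraction_pct"][s], abs=1e-9
            )
            assert st["homing_fraction_pct"][s] == pytest.approx(
                truth["homing_fraction_pct"][s], abs=1e-9
            )
        assert st["hop_histogram"] == truth["hop_histogram"]
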