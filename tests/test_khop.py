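import numpy as np
import pandas as pd
import pytest

from devtraj.de import calls_from_table
from devtraj.khop import khop_counts, label_intervals

from .conftest import make_samples


def calls_from_flags(times, de_map, condition="c"):
    """Build a DECalls from {(t_a, t_b): {gene: direction}} (t_a < t_b)."""
    rows = []
    genes = sorted({g for d in de_map.values() for g in d})
    for i, ta in enumerate(times):
        for tb in times[i + 1 :]:
            flagged = de_map.get((ta, tb), {})
            for g in genes:
                de = g in flagged
                direction = flagged.get(g, "none")
                rows.append(
                    (g, float(ta), float(tb), 0.0 if de else 1.0,
                     0.0 if de else 1.0, de, direction, 1.0 if direction == "up" else -1.0)
                )
    tab = pd.DataFrame(
        rows,
        columns=["gene_id", "time_a", "time_b", "p", "fdr", "de", "direction", "log2fc"],
    )
    return calls_from_table(tab, condition=condition)


def brute_force_khop(times, de_map, k_max, direction):
    """Independent enumeration of the dedup rule, straight from its wording."""
    out = {}
    for i, t in enumerate(times):
        assigned = {}
        for k in range(1, k_max + 1):
            j = i - k if direction == "up" else i + k
            if not (0 <= j < len(times)):
                continue
            ta, tb = (times[j], t) if direction == "up" else (t, times[j])
            for g, d in de_map.get((ta, tb), {}).items():
                if d == direction and g not in assigned:
                    assigned[g] = k
        for k in range(1, k_max + 1):
            j = i - k if direction == "up" else i + k
            if 0 <= j < len(times):
                out[(float(t), k)] = {g for g, kk in assigned.items() if kk == k}
    return out


class TestDedup:
    def test_smallest_delta_worked_example(self):
        """DE at (4 vs 3) and (4 vs 2): counted once, in the 1-hop bin."""
        times = [2, 3, 4]
        de_map = {(3, 4): {"gX": "up"}, (2, 4): {"gX": "up"}}
        calls = calls_from_flags(times, de_map)
        table = khop_counts(calls, make_samples(times), k_max=4)
        assert table.count(4.0, 1, "up") == 1
        assert table.count(4.0, 2, "up") == 0

    def test_matches_brute_force_enumeration(self):
        """Random DE assignments over 6 time points x 20 genes reproduce an
        exhaustive per-gene enumeration of the dedup rule."""
        rng = np.random.default_rng(0)
        times = [0, 1, 2, 3, 4, 5]
        genes = [f"g{i}" for i in range(20)]
        de_map = {}
        for i, ta in enumerate(times):
            for tb in times[i + 1 :]:
                flagged = {
                    g: rng.choice(["up", "down"])
                    for g in genes
                    if rng.random() < 0.25
                }
                if flagged:
                    de_map[(ta, tb)] = flagged
        calls = calls_from_flags(times, de_map)
        table = khop_counts(calls, make_samples(times), k_max=4)
        for direction in ("up", "down"):
            oracle = brute_force_khop(times, de_map, 4, direction)
            for (t, k), expect in oracle.items():
                got = table.gene_sets.get((t, k, direction), frozenset())
                assert set(got) == expect, (t, k, direction)

    def test_partition_property(self):
        """Bins of a fixed (reference, direction) are disjoint and their
        union is the set of genes DE at any scanned hop."""
        rng = np.random.default_rng(1)
        times = [0, 1, 2, 3, 4]
        genes = [f"g{i}" for i in range(15)]
        de_map = {}
        for i, ta in enumerate(times):
            for tb in times[i + 1 :]:
                flagged = {g: "up" for g in genes if rng.random() < 0.4}
                if flagged:
                    de_map[(ta, tb)] = flagged
        calls = calls_from_flags(times, de_map)
        table = khop_counts(calls, make_samples(times), k_max=4)
        for t in map(float, times):
            bins = [
                table.gene_sets.get((t, k, "up"), frozenset()) for k in range(1, 5)
            ]
            union = set().union(*bins)
            assert sum(len(b) for b in bins) == len(union)  # disjoint
            i = times.index(t)
            scanned = set()
            for k in range(1, 5):
                if i - k >= 0:
                    scanned |= {
                        g
                        for g, d in de_map.get((times[i - k], t), {}).items()
                        if d == "up"
                    }
            assert union == scanned
            assert table.union_size(t, "up") == len(union)

    def test_no_de_all_zero(self):
        times = [0, 1, 2]
        calls = calls_from_flags(times, {(0, 1): {"gA": "none"}})
        table = khop_counts(calls, make_samples(times), k_max=2)
        assert (table.counts["n_genes"] == 0).all()

    def test_boundary_bins_absent(self):
        """First reference time has no up bins; last has no down bins."""
        times = [0, 1, 2, 3]
        calls = calls_from_flags(times, {(0, 1): {"gA": "up"}})
        table = khop_counts(calls, make_samples(times), k_max=4)
        c = table.counts
        assert c[(c.ref_time == 0.0) & (c.direction == "up")].empty
        assert c[(c.ref_time == 3.0) & (c.direction == "down")].empty

    def test_kmax_validation(self):
        calls = calls_from_flags([0, 1], {})
        with pytest.raises(ValueError, match="k_max"):
            khop_counts(calls, make_samples([0, 1]), k_max=0)

    def test_clock_mode_skips_missing_offsets(self):
        """In clock-hours mode, a hop lands only on a sampled time exactly k
        hours away: over 0,1,2,4 the 1-hop back from 4 h has no bin."""
        times = [0, 1, 2, 4]
        de_map = {(2, 4): {"gA": "up"}, (3, 4): {"gA": "up"}}
        calls = calls_from_flags(times, {(2, 4): {"gA": "up"}})
        idx = khop_counts(calls, make_samples(times), k_max=2, hop_mode="index")
        clock = khop_counts(calls, make_samples(times), k_max=2, hop_mode="clock")
        assert idx.count(4.0, 1, "up") == 1  # adjacent sampled point is 2 h
        assert (4.0, 1, "up") not in clock.gene_sets  # no sample at 3 h
        assert clock.count(4.0, 2, "up") == 1


class TestIntervals:
    def test_uniform_counts_no_rapid(self):
        times = [0, 1, 2, 3, 4]
        de_map = {
            (t, times[i + 1]): {"gA": "up", "gB": "down"}
            for i, t in enumerate(times[:-1])
        }
        calls = calls_from_flags(times, de_map)
        table = khop_counts(calls, make_samples(times))
        labels = label_intervals(table, make_samples(times))
        assert (labels["label"] == "gradual").all()

    def test_spike_is_rapid_and_scale_invariant(self):
        times = [0, 1, 2, 3, 4]
        genes = [f"g{i}" for i in range(30)]

        def build(mult):
            de_map = {}
            for i, t in enumerate(times[:-1]):
                n = (25 if t == 2 else 2) * mult
                de_map[(t, times[i + 1])] = {g: "up" for g in genes[: min(n, 30)]}
            return de_map

        for mult in (1,):
            calls = calls_from_flags(times, build(mult))
            table = khop_counts(calls, make_samples(times))
            labels = label_intervals(table, make_samples(times))
            rapid = labels.loc[labels.label == "rapid", ["t_from", "t_to"]]
            assert rapid.values.tolist() == [[2.0, 3.0]]

    def test_too_few_times_rejected(self):
        calls = calls_from_flags([0, 1], {(0, 1): {"gA": "none"}})
        table = khop_counts(calls, make_samples([0, 1]))
        with pytest.raises(ValueError, match=">= 3"):
            label_intervals(table, make_samples([0, 1]))
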