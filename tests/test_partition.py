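"""Balanced downsampling quotas, pooled rescaling, cell-wise splitting."""

import numpy as np
import pytest

from cytopipe import Dataset, downsample_balanced, rescale, split_dataset
from cytopipe.errors import DegenerateChannelError, InfeasibilityError

from conftest import make_sample


def dataset_with_sizes(rng, sizes: dict, groups: dict):
    samples = [make_sample(rng.normal(size=(n, 2)), sid, groups[sid])
               for sid, n in sizes.items()]
    return Dataset(samples, groups)


def tag_counts(ds, tag="downsampled"):
    return {s.sample_id: int(np.sum(s.tags[tag])) for s in ds.samples}


def test_quota_example(rng):
    # G1 = {S1:1000, S2:500}, G2 = {S3:2000}:
    # Q = min(2*500, 1*2000) = 1000 -> S1/S2 get 500 each, S3 gets 1000
    ds = dataset_with_sizes(
        rng, {"S1": 1000, "S2": 500, "S3": 2000},
        {"S1": "G1", "S2": "G1", "S3": "G2"})
    out = downsample_balanced(ds, seed=42)
    counts = tag_counts(out)
    assert counts == {"S1": 500, "S2": 500, "S3": 1000}
    assert sum(counts.values()) == 2000
    # non-destructive
    assert all(s.n_events == o.n_events for s, o in zip(ds.samples, out.samples))


def test_single_sample_all_tagged(rng):
    ds = dataset_with_sizes(rng, {"S1": 100}, {"S1": "G"})
    out = downsample_balanced(ds, seed=0)
    assert tag_counts(out) == {"S1": 100}


def test_downsample_deterministic_and_substream_stable(rng):
    ds = dataset_with_sizes(
        rng, {"S1": 800, "S2": 600}, {"S1": "G1", "S2": "G1"})
    a = downsample_balanced(ds, seed=7)
    b = downsample_balanced(ds, seed=7)
    for s1, s2 in zip(a.samples, b.samples):
        np.testing.assert_array_equal(s1.tags["downsampled"], s2.tags["downsampled"])
    c = downsample_balanced(ds, seed=8)
    assert any(
        not np.array_equal(x.tags["downsampled"], y.tags["downsampled"])
        for x, y in zip(a.samples, c.samples)
    )


def test_downsample_respects_base_tag(rng):
    ds = dataset_with_sizes(rng, {"S1": 500}, {"S1": "G"})
    mask = np.zeros(500, dtype=bool)
    mask[:200] = True
    ds.samples[0].set_tag("gate:live", mask)
    out = downsample_balanced(ds, base_tag="gate:live", seed=0)
    tagged = out.samples[0].tags["downsampled"]
    assert tagged.sum() == 200
    assert np.all(mask[tagged])  # only eligible events drawn


def test_downsample_group_balance_property(rng):
    sizes = {"A1": 900, "A2": 700, "B1": 650, "B2": 800, "B3": 640}
    groups = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "B3": "B"}
    out = downsample_balanced(dataset_with_sizes(rng, sizes, groups), seed=3)
    counts = tag_counts(out)
    per_group = {}
    for sid, g in groups.items():
        per_group.setdefault(g, []).append(counts[sid])
    # samples within a group contribute equally
    assert all(len(set(v)) == 1 for v in per_group.values())


def test_downsample_empty_sample_infeasible(rng):
    ds = dataset_with_sizes(rng, {"S1": 100, "S2": 50}, {"S1": "G", "S2": "G"})
    ds.samples[1].set_tag("gate:x", np.zeros(50, dtype=bool))
    ds.samples[0].set_tag("gate:x", np.ones(100, dtype=bool))
    with pytest.raises(InfeasibilityError, match="S2"):
        downsample_balanced(ds, base_tag="gate:x")


class TestRescale:
    def test_uniform_midpoint(self, rng):
        x = np.linspace(0, 10, 1001).reshape(-1, 1)
        ds = Dataset([make_sample(x)], {"S1": "g"})
        out = rescale(ds, lo_pct=0, hi_pct=100)
        mid = out.samples[0].events[500, 0]
        assert mid == pytest.approx(0.5, abs=1e-9)

    def test_clipping_below_lo(self, rng):
        x = np.concatenate([[-100.0], np.linspace(0, 10, 1000)]).reshape(-1, 1)
        ds = Dataset([make_sample(x)], {"S1": "g"})
        out = rescale(ds, lo_pct=1, hi_pct=99)
        assert out.samples[0].events[0, 0] == 0.0
        assert np.all(out.samples[0].events >= 0)
        assert np.all(out.samples[0].events <= 1)

    def test_pooled_bounds_shared_across_samples(self, rng):
        s1 = make_sample(rng.uniform(0, 1, size=(500, 1)), "A")
        s2 = make_sample(rng.uniform(0, 10, size=(500, 1)), "B")
        ds = Dataset([s1, s2], {"A": "g", "B": "g"})
        out = rescale(ds, lo_pct=0, hi_pct=100)
        p1 = out["A"].provenance[-1]["parameters"]
        p2 = out["B"].provenance[-1]["parameters"]
        assert p1["p_lo"] == p2["p_lo"] and p1["p_hi"] == p2["p_hi"]

    def test_rank_preserved_within_unclipped_range(self, rng):
        x = rng.normal(size=(1000, 1))
        ds = Dataset([make_sample(x.copy())], {"S1": "g"})
        out = rescale(ds)
        y = out.samples[0].events[:, 0]
        inner = (y > 0) & (y < 1)
        np.testing.assert_array_equal(
            np.argsort(x[inner, 0], kind="stable"),
            np.argsort(y[inner], kind="stable"),
        )

    def test_constant_channel_degenerate(self, rng):
        ds = Dataset([make_sample(np.ones((100, 1)))], {"S1": "g"})
        with pytest.raises(DegenerateChannelError):
            rescale(ds)


class TestSplit:
    def test_even_split(self, rng):
        ds = Dataset([make_sample(rng.normal(size=(1000, 1)))], {"S1": "g"})
        ds = downsample_balanced(ds, seed=0)
        out = split_dataset(ds, 0.5, seed=0)
        s = out.samples[0]
        assert int(s.tags["split:A"].sum()) == 500
        assert int(s.tags["split:B"].sum()) == 500
        assert not np.any(s.tags["split:A"] & s.tags["split:B"])

    def test_floor_rule(self, rng):
        ds = Dataset([make_sample(rng.normal(size=(10, 1)))], {"S1": "g"})
        out = split_dataset(ds, 0.3, seed=0)
        assert int(out.samples[0].tags["split:A"].sum()) == 3
        assert int(out.samples[0].tags["split:B"].sum()) == 7

    def test_split_only_downsampled(self, rng):
        ds = Dataset([make_sample(rng.normal(size=(100, 1)))], {"S1": "g"})
        mask = np.zeros(100, dtype=bool)
        mask[:40] = True
        ds.samples[0].set_tag("downsampled", mask)
        out = split_dataset(ds, 0.5, seed=1)
        s = out.samples[0]
        both = s.tags["split:A"] | s.tags["split:B"]
        np.testing.assert_array_equal(both, mask)

    def test_deterministic(self, rng):
        ds = Dataset([make_sample(rng.normal(size=(100, 1)))], {"S1": "g"})
        a = split_dataset(ds, 0.4, seed=9)
        b = split_dataset(ds, 0.4, seed=9)
        np.testing.assert_array_equal(a.samples[0].tags["split:A"],
                                      b.samples[0].tags["split:A"])

    def test_too_few_events(self, rng):
        ds = Dataset([make_sample(rng.normal(size=(1, 1)))], {"S1": "g"})
        with pytest.raises(InfeasibilityError):
            split_dataset(ds, 0.5)

    def test_invalid_fraction(self, rng):
        ds = Dataset([make_sample(rng.normal(size=(10, 1)))], {"S1": "g"})
        with pytest.raises(ValueError):
            split_dataset(ds, 1.0)
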