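import numpy as np
import pytest

from seqdsn.datasets import (DomainDataset, build_domain_dataset, make_cv_plan,
                             pair_domains, sample_negatives, upsample_to_match)
from seqdsn.sequence_io import SiteRecord, TranscriptSet


def _ts(**entries):
    ts = TranscriptSet()
    for k, v in entries.items():
        ts.add(k, v)
    return ts


class TestSampleNegatives:
    def test_capped_at_availability(self):
        ts = _ts(t1="UUUUU")
        pos = [SiteRecord("t1", 0, 1, "source")]
        negs = sample_negatives(ts, pos, ratio=10, seed=0)
        assert len(negs) == 4
        assert all(n.label == 0 for n in negs)
        assert all(n.position != 0 for n in negs)

    def test_overall_ratio_approx_ten(self):
        # mRNA-like: long transcripts, sparse positives, plenty of U
        rng = np.random.default_rng(5)
        ts = TranscriptSet()
        positives = []
        for i in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=500))
            name = f"tx{i}"
            ts.add(name, seq)
            us = [j for j, b in enumerate(seq) if b == "U"]
            positives.append(SiteRecord(name, us[0], 1, "target"))
        negs = sample_negatives(ts, positives, ratio=10, seed=1)
        ratio = len(negs) / len(positives)
        assert ratio == pytest.approx(10, abs=0.5)

    def test_negatives_are_uridines_off_positive_sites(self):
        ts = _ts(t1="UAUGUCU")
        pos = [SiteRecord("t1", 0, 1, "source")]
        negs = sample_negatives(ts, pos, ratio=10, seed=0)
        assert {n.position for n in negs} <= {2, 4, 6}

    def test_all_mode_returns_every_spare_u(self):
        ts = _ts(t1="UUUAUU")
        pos = [SiteRecord("t1", 1, 1, "source")]
        negs = sample_negatives(ts, pos, mode="all")
        assert {n.position for n in negs} == {0, 2, 4, 5}

    def test_determinism_contract(self):
        ts = _ts(t1="U" * 50)
        pos = [SiteRecord("t1", 10, 1, "source")]
        a = sample_negatives(ts, pos, ratio=5, seed=3)
        b = sample_negatives(ts, pos, ratio=5, seed=3)
        c = sample_negatives(ts, pos, ratio=5, seed=4)
        assert a == b
        assert a != c

    def test_input_order_invariance(self):
        ts = _ts(t1="U" * 30, t2="U" * 30)
        pos = [SiteRecord("t1", 0, 1, "source"), SiteRecord("t2", 5, 1, "source")]
        assert (sample_negatives(ts, pos, ratio=3, seed=7)
                == sample_negatives(ts, pos[::-1], ratio=3, seed=7))

    def test_no_spare_u_warns(self):
        ts = _ts(t1="UAAA")
        pos = [SiteRecord("t1", 0, 1, "source")]
        with pytest.warns(UserWarning, match="no spare"):
            negs = sample_negatives(ts, pos, ratio=2, seed=0)
        assert negs == []


class TestCVPlan:
    def test_six_groups_give_36_folds(self):
        pos = [("p", i) for i in range(30)]
        neg = [("n", i) for i in range(300)]
        plan = make_cv_plan(pos, neg, groups=6, seed=0)
        assert len(plan.folds) == 36

    def test_two_groups_give_4_folds(self):
        plan = make_cv_plan([("p", i) for i in range(4)],
                            [("n", i) for i in range(4)], groups=2, seed=0)
        assert len(plan.folds) == 4

    def test_coverage_and_disjointness(self):
        pos = [("p", i) for i in range(25)]
        neg = [("n", i) for i in range(26)]
        groups = 5
        plan = make_cv_plan(pos, neg, groups=groups, seed=1)
        from collections import Counter
        seen = Counter()
        for fold in plan.folds:
            test = plan.test_keys(fold)
            train = plan.train_keys(fold)
            assert not test & train
            assert test | train == set(pos) | set(neg)
            seen.update(test)
        # every record tested in exactly `groups` folds of its label
        assert all(v == groups for v in seen.values())

    def test_group_sizes_near_equal(self):
        plan = make_cv_plan([("p", i) for i in range(32)],
                            [("n", i) for i in range(33)], groups=6, seed=2)
        from collections import Counter
        for mapping in (plan.pos_groups, plan.neg_groups):
            sizes = Counter(mapping.values()).values()
            assert max(sizes) - min(sizes) <= 1

    def test_json_roundtrip(self, tmp_path):
        plan = make_cv_plan([("p", i) for i in range(6)],
                            [("n", i) for i in range(6)], groups=3, seed=0)
        plan.to_json(tmp_path / "plan.json")
        from seqdsn.datasets import CVPlan
        loaded = CVPlan.from_json(tmp_path / "plan.json")
        assert loaded.pos_groups == plan.pos_groups
        assert loaded.neg_groups == plan.neg_groups

    def test_too_few_ids(self):
        with pytest.raises(ValueError, match="at least"):
            make_cv_plan([("p", 0)], [("n", i) for i in range(6)], groups=6)


class TestUpsample:
    def test_length_and_superset(self):
        recs = list("abcde")
        out = upsample_to_match(recs, 50, seed=0)
        assert len(out) == 50
        assert set(out) == set(recs)

    def test_identity_when_equal(self):
        recs = list("abc")
        assert upsample_to_match(recs, 3, seed=0) == recs

    def test_frequency_spread_bounded(self):
        import math
        from collections import Counter
        recs = list(range(7))
        target = 24
        counts = Counter(upsample_to_match(recs, target, seed=1))
        assert max(counts.values()) - min(counts.values()) <= 1
        assert max(counts.values()) <= math.ceil(target / len(recs)) + 1

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            upsample_to_match([], 5)

    def test_shrink_errors(self):
        with pytest.raises(ValueError):
            upsample_to_match(list("abc"), 2)


def _toy_domain(n, domain, seed=0, L=5):
    rng = np.random.default_rng(seed)
    enc = np.eye(4)[rng.integers(0, 4, size=(n, L))]
    labels = rng.integers(0, 2, size=n)
    prov = [SiteRecord(f"{domain}{i}", 0, int(labels[i]), domain)
            for i in range(n)]
    return DomainDataset(enc, labels, domain, prov)


class TestPairedStream:
    def test_batch_structure(self):
        src = _toy_domain(100, "source")
        tgt = _toy_domain(30, "target", seed=1)
        stream = pair_domains(src, tgt, batch=10, seed=0)
        batches = list(stream.epoch(0))
        assert len(batches) == 10
        assert len(stream.target) == 100  # upsampled to source size
        for s, t in batches:
            assert len(s) == len(t)

    def test_epoch_covers_source_once(self):
        src = _toy_domain(50, "source")
        tgt = _toy_domain(20, "target", seed=1)
        stream = pair_domains(src, tgt, batch=16, seed=0)
        ids = [r.transcript_id for s, _ in stream.epoch(0)
               for r in s.provenance]
        assert sorted(ids) == sorted(r.transcript_id for r in src.provenance)

    def test_same_seed_same_order(self):
        src = _toy_domain(40, "source")
        tgt = _toy_domain(15, "target", seed=1)
        a = pair_domains(src, tgt, batch=8, seed=5)
        b = pair_domains(src, tgt, batch=8, seed=5)
        for (sa, ta), (sb, tb) in zip(a.epoch(0), b.epoch(0)):
            np.testing.assert_array_equal(sa.encoded, sb.encoded)
            np.testing.assert_array_equal(ta.encoded, tb.encoded)

    def test_empty_domain_rejected(self):
        src = _toy_domain(10, "source")
        empty = DomainDataset(np.zeros((0, 5, 4)), np.zeros(0, int), "target")
        with pytest.raises(ValueError, match="non-empty"):
            pair_domains(src, empty)


class TestBuildDomainDataset:
    def test_windows_and_labels(self, tiny_transcripts):
        sites = [SiteRecord("t3", 20, 1, "target"),
                 SiteRecord("t3", 7, 0, "target"),
                 SiteRecord("t1", 2, 1, "source")]
        ds = build_domain_dataset(tiny_transcripts, sites, "target", flank=3)
        assert len(ds) == 2  # source record filtered out
        assert ds.encoded.shape == (2, 7, 4)
        # canonical sort by (transcript, position): position 7 first
        assert ds.provenance[0].position == 7
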