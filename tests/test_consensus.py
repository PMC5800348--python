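"""Three-stage filter: reference-set partitioning, unanimity consensus,
cross-algorithm corroboration, codified inspection, and the funnel contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import panelcnv as p
from panelcnv.callers import CnvCall
from panelcnv.consensus import (ConsensusError, ConsensusEvent, ConsensusParams,
                                InspectionThresholds, _cluster_count,
                                cross_algorithm, inspect,
                                partition_reference_sets, run_filters,
                                triple_consensus)


def _meta(n, gender="male", panel="v2", prefix="s"):
    return [p.SampleMeta(f"{prefix}{i:03d}", gender, panel) for i in range(n)]


def _call(exon_start, exon_end, type="del", sample_id="t0", ratio=None, conf=10.0,
          panel=None):
    if ratio is None:
        ratio = 0.5 if type == "del" else 1.5
    start = 100 * exon_start
    end = 100 * exon_end
    chrom = "chr1"
    if panel is not None:
        t0, t1 = panel.targets[exon_start], panel.targets[exon_end - 1]
        chrom, start, end = t0.chrom, t0.start, t1.end
    return CnvCall(sample_id=sample_id, chrom=chrom, start=start, end=end,
                   exon_start=exon_start, exon_end=exon_end, type=type,
                   ratio=ratio, copy_number=1 if type == "del" else 3,
                   confidence=conf, algorithm="bb-hmm")


class TestPartition:
    def test_exactly_90_matched_partitions_all(self):
        cohort = _meta(91)
        triple = partition_reference_sets(cohort, "s000")
        assert sorted(triple.all_samples) == [m.sample_id for m in cohort[1:]]
        assert all(len(s) == 30 for s in triple.sets)

    def test_shortfall_reported(self):
        cohort = _meta(90)  # 89 matched candidates
        with pytest.raises(ConsensusError, match="shortfall 1"):
            partition_reference_sets(cohort, "s000")

    def test_gender_and_kit_matching(self):
        cohort = (_meta(40, "male", "v2") + _meta(40, "female", "v2", prefix="f")
                  + _meta(40, "male", "v3", prefix="k"))
        params = ConsensusParams(set_size=10)
        triple = partition_reference_sets(cohort, "f000", params)
        assert all(s.startswith("f") for s in triple.all_samples)

    def test_seed_determinism_and_seed_sensitivity(self):
        cohort = _meta(120)
        a = partition_reference_sets(cohort, "s005", ConsensusParams(seed=1))
        b = partition_reference_sets(cohort, "s005", ConsensusParams(seed=1))
        c = partition_reference_sets(cohort, "s005", ConsensusParams(seed=2))
        assert a == b
        assert a != c

    def test_other_samples_do_not_perturb_triple(self):
        """Appending a non-matching sample leaves an existing triple unchanged."""
        cohort = _meta(120)
        before = partition_reference_sets(cohort, "s007")
        after = partition_reference_sets(cohort + _meta(1, "female", prefix="x"), "s007")
        assert before == after

    @given(st.integers(0, 2**31 - 1), st.integers(91, 140))
    @settings(max_examples=25, deadline=None)
    def test_invariants_on_random_cohorts(self, seed, n):
        cohort = _meta(n)
        triple = partition_reference_sets(cohort, "s000", ConsensusParams(seed=seed))
        flat = triple.all_samples
        assert len(flat) == len(set(flat)) == 90
        assert "s000" not in flat
        assert all(len(s) == 30 for s in triple.sets)


class TestTripleConsensus:
    @pytest.fixture
    def panel(self, toy_panel):
        return toy_panel

    def test_identical_lists_identity(self, panel):
        lists = [[_call(3, 5, panel=panel)] for _ in range(3)]
        events = triple_consensus(lists, panel)
        assert len(events) == 1
        assert (events[0].call.exon_start, events[0].call.exon_end) == (3, 5)

    def test_two_of_three_dropped(self, panel):
        lists = [[_call(3, 5, panel=panel)], [_call(3, 5, panel=panel)], []]
        assert triple_consensus(lists, panel) == []

    def test_span_intersection(self, panel):
        lists = [[_call(1, 6, panel=panel)], [_call(2, 7, panel=panel)],
                 [_call(3, 8, panel=panel)]]
        events = triple_consensus(lists, panel)
        assert len(events) == 1
        assert (events[0].call.exon_start, events[0].call.exon_end) == (3, 6)

    def test_type_strict(self, panel):
        lists = [[_call(3, 5, panel=panel)], [_call(3, 5, panel=panel)],
                 [_call(3, 5, type="dup", panel=panel)]]
        assert triple_consensus(lists, panel) == []

    def test_mixed_samples_rejected(self, panel):
        lists = [[_call(3, 5, sample_id="a", panel=panel)],
                 [_call(3, 5, sample_id="b", panel=panel)], []]
        with pytest.raises(ConsensusError, match="mixed"):
            triple_consensus(lists, panel)

    def test_unanimity_dominance(self, panel):
        """Every surviving event overlaps a call in each individual run."""
        rng = np.random.default_rng(0)
        lists = []
        for _ in range(3):
            calls, pos = [], 0
            while pos < 35:
                a = pos + int(rng.integers(0, 4))
                b = a + int(rng.integers(1, 4))
                if b > 40:
                    break
                calls.append(_call(a, min(b, 40),
                                   type=("del", "dup")[int(rng.integers(2))],
                                   panel=panel))
                pos = b + int(rng.integers(1, 5))
            lists.append(calls)
        for ev in triple_consensus(lists, panel):
            for run in lists:
                assert any(c.type == ev.call.type
                           and c.exon_start < ev.call.exon_end
                           and ev.call.exon_start < c.exon_end for c in run)


class TestCrossAlgorithm:
    def _event(self, panel, **kw):
        c = _call(3, 5, panel=panel, **kw)
        return ConsensusEvent(call=c, per_set_calls=(c, c, c))

    def test_one_of_two_other_algorithms_suffices(self, toy_panel):
        ev = self._event(toy_panel)
        others = {"zscore": [_call(4, 6, panel=toy_panel)], "external": []}
        assert len(cross_algorithm([ev], others)) == 1

    def test_uncorroborated_dropped(self, toy_panel):
        ev = self._event(toy_panel)
        assert cross_algorithm([ev], {"z": []}) == []

    def test_type_mismatch_is_not_corroboration(self, toy_panel):
        ev = self._event(toy_panel)
        others = {"z": [_call(3, 5, type="dup", panel=toy_panel)]}
        assert cross_algorithm([ev], others) == []


class TestInspect:
    def _setup(self, n_samples=40, n_exons=30, seed=0):
        panel = p.make_panel("insp", n_exons, 3)
        rng = np.random.default_rng(seed)
        lam = np.full(n_exons, 2000.0)
        counts = rng.poisson(lam[:, None] * np.ones(n_samples)).astype(np.int64)
        ids = [f"s{i:02d}" for i in range(n_samples)]
        return panel, counts, ids

    def _triple(self, ids, test):
        rest = [s for s in ids if s != test]
        return p.ReferenceSetTriple(test, (tuple(rest[0:10]), tuple(rest[10:20]),
                                           tuple(rest[20:30])))

    def test_clean_het_deletion_passes(self):
        panel, counts, ids = self._setup()
        rng = np.random.default_rng(1)
        counts[5:8, 0] = rng.poisson(1000.0, 3)  # het del exons 5-7 in s00
        norm = p.normalize_coverage(counts)
        call = _call(5, 8, sample_id="s00", panel=panel)
        ev = ConsensusEvent(call=call, per_set_calls=(call, call, call))
        report = inspect(ev, norm, ids, self._triple(ids, "s00"))
        assert report.verdict == "pass"
        assert report.continuity == 1.0
        assert report.cohort_recurrence == 0.0

    def test_recurrent_noisy_region_flagged(self):
        panel, counts, ids = self._setup(seed=2)
        counts[5:8, 0:16] //= 2  # same signal in 40% of the cohort
        norm = p.normalize_coverage(counts)
        call = _call(5, 8, sample_id="s00", panel=panel)
        ev = ConsensusEvent(call=call, per_set_calls=(call, call, call))
        report = inspect(ev, norm, ids, self._triple(ids, "s00"))
        assert report.cohort_recurrence > 0.10
        assert report.verdict == "flag"

    def test_alternating_span_fails_continuity(self):
        panel, counts, ids = self._setup(seed=3)
        counts[np.array([5, 7, 9]), 0] //= 2  # alternating abnormal exons
        norm = p.normalize_coverage(counts)
        call = _call(5, 11, sample_id="s00", ratio=0.7, panel=panel)
        ev = ConsensusEvent(call=call, per_set_calls=(call, call, call))
        report = inspect(ev, norm, ids, self._triple(ids, "s00"))
        assert report.continuity == pytest.approx(1 / 6)
        assert report.verdict == "flag"


class TestRunFilters:
    def test_empty_candidates(self, toy_panel):
        norm = np.ones((len(toy_panel), 10))
        ids = [f"s{i}" for i in range(10)]
        triple = p.ReferenceSetTriple("s0", (("s1", "s2"), ("s3", "s4"), ("s5", "s6")))
        events, funnel = run_filters([[], [], []], {"z": []}, toy_panel, norm,
                                     ids, triple)
        assert events == []
        assert all(v == 0 for v in funnel.values())

    def test_funnel_monotone_nonincreasing(self):
        """End-to-end pipeline funnel on the spiked fixture is a funnel."""
        from panelcnv.pipeline import PipelineConfig, run_pipeline
        cfg = PipelineConfig(
            seed=20_240_101,
            simulate=small_cohort_spec(),
            consensus=p.ConsensusParams(set_size=8))
        result = run_pipeline(cfg)
        f = result.funnel
        assert (f["candidates"] >= f["after_triple_consensus"]
                >= f["after_cross_algorithm"] >= f["after_inspection"])

    def test_cluster_count_counts_distinct_overlapping_groups(self):
        calls = [_call(0, 3), _call(2, 5), _call(8, 9),
                 _call(2, 4, type="dup")]
        assert _cluster_count(calls) == 3


def small_cohort_spec():
    return p.SimulationSpec(
        n_samples_per_panel={"mini": 60},
        panel_shapes=(("mini", (300, 20)),),
        dispersion=0.0025,
        cnv_events=(
            p.CnvEventSpec("mini", 1, 1, 1),
            p.CnvEventSpec("mini", 1, 2, 1),
            p.CnvEventSpec("mini", 1, 4, 1),
            p.CnvEventSpec("mini", 1, 1, 0),
            p.CnvEventSpec("mini", 1, 2, 3),
            p.CnvEventSpec("mini", 1, 2, 4),
        ),
        seed=20_240_101,
    )
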