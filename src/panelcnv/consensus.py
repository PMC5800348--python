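"""Three-stage consensus filtering of candidate CNV calls.

Stage 1 — triple reference sets: each test sample is called three times by the
beta-binomial HMM caller, each run against a reference aggregated from one of
three disjoint, randomly drawn groups of samples matched to the test on gender
and panel version.  An event survives only if all three runs call it (same
type, >= 1 shared exon); the surviving span is the intersection of the three.

Stage 2 — cross-algorithm concordance: the event must also be called (same
type, >= 1 shared exon) by at least one independent algorithm.

Stage 3 — codified inspection: four features that an analyst would read off a
ratio plot (ratio consistency within the span, reference-set variability,
cohort-wide recurrence of the signal, continuity of abnormal exons) are
computed and thresholded.

Each stage returns a subset of its input; the per-stage survivor counts form
the filter funnel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .callers import CnvCall
from .io import PanelDesign, SampleMeta
from .qc import intersample_cv
from .simulate import hash_version


class ConsensusError(ValueError):
    pass


@dataclass(frozen=True)
class InspectionThresholds:
    max_ratio_sd: float = 0.15        # dispersion of per-exon ratios in the span
    max_reference_cv: float = 15.0    # percent, worst exon in the span
    max_cohort_recurrence: float = 0.10  # fraction of cohort abnormal here
    min_continuity: float = 1.0       # longest abnormal run / span length


@dataclass(frozen=True)
class ConsensusParams:
    n_sets: int = 3
    set_size: int = 30
    match_keys: tuple[str, ...] = ("gender", "panel_version")
    min_other_algorithms: int = 1
    inspection: InspectionThresholds = InspectionThresholds()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 2 or self.set_size < 2:
            raise ConsensusError("need n_sets >= 2 and set_size >= 2")


@dataclass(frozen=True)
class ReferenceSetTriple:
    test_id: str
    sets: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        flat = [s for group in self.sets for s in group]
        if len(set(flat)) != len(flat):
            raise ConsensusError("reference sets are not pairwise disjoint")
        if self.test_id in flat:
            raise ConsensusError("test sample inside its own reference sets")

    @property
    def all_samples(self) -> list[str]:
        return [s for group in self.sets for s in group]


@dataclass
class InspectionReport:
    ratio_consistency: float
    reference_variability: float
    cohort_recurrence: float
    continuity: float
    verdict: str  # pass | flag


@dataclass
class ConsensusEvent:
    call: CnvCall                       # the merged call
    per_set_calls: tuple[CnvCall, ...]  # provenance: the three stage-1 calls
    other_calls: tuple[CnvCall, ...] = ()
    inspection: InspectionReport | None = None
    filter_stage_reached: str = "triple"


# ---------------------------------------------------------------------------
# stage 0: reference-set construction
# ---------------------------------------------------------------------------

def partition_reference_sets(cohort: Sequence[SampleMeta], test_id: str,
                             params: ConsensusParams = ConsensusParams()
                             ) -> ReferenceSetTriple:
    """Draw n_sets disjoint matched reference sets of exactly set_size samples.

    Matching is on all ``match_keys`` (gender and panel version by default);
    the draw is uniform without replacement, seeded by the global seed plus a
    stable hash of the test id, so one sample's triple does not depend on which
    other samples are being tested.
    """
    by_id = {m.sample_id: m for m in cohort}
    if test_id not in by_id:
        raise ConsensusError(f"unknown test sample {test_id}")
    test = by_id[test_id]
    matched = [m.sample_id for m in cohort
               if m.sample_id != test_id
               and all(getattr(m, k) == getattr(test, k) for k in params.match_keys)]
    need = params.n_sets * params.set_size
    if len(matched) < need:
        raise ConsensusError(
            f"insufficient matched samples for {test_id}: need {need}, "
            f"have {len(matched)} (shortfall {need - len(matched)})")
    rng = np.random.default_rng((params.seed + hash_version(test_id)) % (2**31))
    perm = rng.permutation(len(matched))[:need]
    chosen = [matched[i] for i in perm]
    sets = tuple(tuple(chosen[i * params.set_size:(i + 1) * params.set_size])
                 for i in range(params.n_sets))
    return ReferenceSetTriple(test_id=test_id, sets=sets)


# ---------------------------------------------------------------------------
# stage 1: triple consensus
# ---------------------------------------------------------------------------

def _span_overlap(a: CnvCall, b: CnvCall) -> bool:
    return a.exon_start < b.exon_end and b.exon_start < a.exon_end


def triple_consensus(calls_per_set: Sequence[Sequence[CnvCall]],
                     panel: PanelDesign) -> list[ConsensusEvent]:
    """Keep events called in every reference-set run (same type, >=1 shared
    exon); merged span = intersection of spans, ratio/confidence = medians."""
    sample_ids = {c.sample_id for calls in calls_per_set for c in calls}
    if len(sample_ids) > 1:
        raise ConsensusError(f"mixed sample ids in consensus input: {sample_ids}")
    first, *others = calls_per_set
    events: list[ConsensusEvent] = []
    for call in first:
        partners = [call]
        for other in others:
            match = [c for c in other if c.type == call.type and _span_overlap(c, call)]
            if not match:
                partners = None
                break
            # closest-overlapping partner: maximal shared exons
            match.sort(key=lambda c: -(min(c.exon_end, call.exon_end)
                                       - max(c.exon_start, call.exon_start)))
            partners.append(match[0])
        if partners is None:
            continue
        a = max(c.exon_start for c in partners)
        b = min(c.exon_end for c in partners)
        if a >= b:  # pairwise overlap with the seed call guarantees a < b
            continue
        t0, t1 = panel.targets[a], panel.targets[b - 1]
        merged = replace(
            call, exon_start=a, exon_end=b,
            chrom=t0.chrom, start=t0.start, end=t1.end,
            ratio=float(np.median([c.ratio for c in partners])),
            confidence=float(np.median([c.confidence for c in partners])),
            algorithm="consensus")
        events.append(ConsensusEvent(call=merged, per_set_calls=tuple(partners)))
    return events


# ---------------------------------------------------------------------------
# stage 2: cross-algorithm concordance
# ---------------------------------------------------------------------------

def cross_algorithm(events: Sequence[ConsensusEvent],
                    other_calls: dict[str, Sequence[CnvCall]],
                    min_other_algorithms: int = 1) -> list[ConsensusEvent]:
    """Keep events corroborated by >= min_other_algorithms independent call
    lists (same type, >= 1 shared exon)."""
    kept: list[ConsensusEvent] = []
    for ev in events:
        corroborating: list[CnvCall] = []
        n_algorithms = 0
        for _, calls in sorted(other_calls.items()):
            match = [c for c in calls
                     if c.type == ev.call.type and _span_overlap(c, ev.call)]
            if match:
                n_algorithms += 1
                corroborating.extend(match)
        if n_algorithms >= min_other_algorithms:
            kept.append(replace_event(ev, other_calls=tuple(corroborating),
                                      stage="cross_algorithm"))
    return kept


def replace_event(ev: ConsensusEvent, **kw) -> ConsensusEvent:
    stage = kw.pop("stage", ev.filter_stage_reached)
    return ConsensusEvent(call=ev.call, per_set_calls=ev.per_set_calls,
                          other_calls=kw.get("other_calls", ev.other_calls),
                          inspection=kw.get("inspection", ev.inspection),
                          filter_stage_reached=stage)


# ---------------------------------------------------------------------------
# stage 3: codified inspection
# ---------------------------------------------------------------------------

def inspect(event: ConsensusEvent, normalized: np.ndarray,
            sample_ids: Sequence[str], triple: ReferenceSetTriple,
            thresholds: InspectionThresholds = InspectionThresholds()
            ) -> InspectionReport:
    """Compute the four inspection features for one surviving event.

    normalized: cohort counts-per-million matrix (exons x samples) for the
    event's panel; sample_ids gives its column order.
    """
    idx = {s: i for i, s in enumerate(sample_ids)}
    s_test = idx[event.call.sample_id]
    ref_idx = [idx[s] for s in triple.all_samples]
    a, b = event.call.exon_start, event.call.exon_end

    expected = normalized[:, ref_idx].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(expected > 0, normalized[:, s_test] / expected, np.nan)
    span_ratios = ratios[a:b]
    ratio_consistency = float(np.nanstd(span_ratios, ddof=1)) if b - a > 1 else 0.0

    cv = intersample_cv(normalized, ref_idx)
    reference_variability = float(np.nanmax(cv[a:b]))

    # cohort recurrence: fraction of other samples aberrant over this span
    median_cov = np.median(normalized, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cohort_ratio = np.where(median_cov[:, None] > 0,
                                normalized / median_cov[:, None], 1.0)
    span_mean = cohort_ratio[a:b].mean(axis=0)
    others = [i for i in range(normalized.shape[1]) if i != s_test]
    aberrant = (span_mean[others] < 0.75) | (span_mean[others] > 1.25)
    cohort_recurrence = float(np.mean(aberrant)) if others else 0.0

    # continuity: longest same-side abnormal run of the test's per-exon ratios
    if event.call.type == "del":
        abnormal = span_ratios < 0.75
    else:
        abnormal = span_ratios > 1.25
    longest = run = 0
    for flag in abnormal:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    continuity = longest / (b - a)

    verdict = "pass" if (
        ratio_consistency <= thresholds.max_ratio_sd
        and reference_variability <= thresholds.max_reference_cv
        and cohort_recurrence <= thresholds.max_cohort_recurrence
        and continuity >= thresholds.min_continuity
    ) else "flag"
    return InspectionReport(ratio_consistency, reference_variability,
                            cohort_recurrence, continuity, verdict)


# ---------------------------------------------------------------------------
# full funnel
# ---------------------------------------------------------------------------

def _cluster_count(calls: Sequence[CnvCall]) -> int:
    """Distinct candidate events = clusters of same-type overlapping calls."""
    count = 0
    by_type: dict[str, list[CnvCall]] = {}
    for c in calls:
        by_type.setdefault(c.type, []).append(c)
    for _, group in sorted(by_type.items()):
        group = sorted(group, key=lambda c: (c.exon_start, c.exon_end))
        end = -1
        for c in group:
            if c.exon_start >= end:
                count += 1
                end = c.exon_end
            else:
                end = max(end, c.exon_end)
    return count


def run_filters(calls_per_set: Sequence[Sequence[CnvCall]],
                other_calls: dict[str, Sequence[CnvCall]],
                panel: PanelDesign,
                normalized: np.ndarray,
                sample_ids: Sequence[str],
                triple: ReferenceSetTriple,
                params: ConsensusParams = ConsensusParams()
                ) -> tuple[list[ConsensusEvent], dict[str, int]]:
    """Apply the three filter stages in order for one test sample.

    Returns the surviving events (sorted by sample, chrom, start) and the
    per-stage funnel counts.
    """
    candidates = _cluster_count([c for calls in calls_per_set for c in calls])
    stage1 = triple_consensus(calls_per_set, panel)
    stage2 = cross_algorithm(stage1, other_calls, params.min_other_algorithms)
    stage3: list[ConsensusEvent] = []
    for ev in stage2:
        report = inspect(ev, normalized, sample_ids, triple, params.inspection)
        ev = replace_event(ev, inspection=report, stage="inspection")
        if report.verdict == "pass":
            stage3.append(ev)
    stage3.sort(key=lambda e: (e.call.sample_id, e.call.chrom, e.call.start))
    funnel = {
        "candidates": candidates,
        "after_triple_consensus": len(stage1),
        "after_cross_algorithm": len(stage2),
        "after_inspection": len(stage3),
    }
    return stage3, funnel
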