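"""Coverage quality assurance for panel CNV surveillance.

Read-depth CNV calling is only as good as the coverage it sees.  This module
computes the quality metrics that determine per-exon callability: normalized
coverage (counts-per-million), insufficient-coverage flags (< 50 deduplicated
reads), cohort-wide consistently-poor exons, and the intersample coefficient of
variation (CV) of normalized coverage across a reference set — the main
accuracy covariate for single-exon events.  It also estimates single-exon
deletion spike-in accuracy as a function of that CV.

Exon-level counts stand proxy for the minimum nucleotide depth within the exon;
the pipeline's inputs do not carry per-base coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .io import CountsMatrix
from .simulate import spike_cnv

NORMALIZATION_CONSTANT = 1_000_000  # counts-per-million; CV is scale-invariant


class QCError(ValueError):
    pass


class SolitaryReferenceError(QCError):
    """A reference set of one sample: CV undefined, exon routed to exclusion."""


@dataclass(frozen=True)
class QCParams:
    min_reads: int = 50
    poor_fraction: float = 0.90
    cv_bins: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, float("inf"))

    def __post_init__(self) -> None:
        if self.min_reads <= 0:
            raise QCError("min_reads must be > 0")
        if not 0 < self.poor_fraction <= 1:
            raise QCError("poor_fraction must be in (0, 1]")


@dataclass
class QCReport:
    """Per-exon coverage metrics plus exclusion accounting inputs.

    ``n_solitary_cells`` / ``n_poor_cells`` count exon-sample observations
    excluded because the caller's reference set was a solitary sample, or
    because the exon shows consistently poor coverage across the cohort.
    """

    mean_depth: np.ndarray
    median_depth: np.ndarray
    insufficient: np.ndarray          # bool, exons x samples
    poor_exons: list[int]
    reference_cv: np.ndarray | None = None   # percent, per exon (NaN where undefined)
    n_solitary_cells: int = 0
    n_poor_cells: int = 0


def normalize_coverage(counts: CountsMatrix | np.ndarray,
                       sample_ids: Sequence[str] | None = None) -> np.ndarray:
    """Counts-per-million per sample: norm(e,s) = 1e6 * count(e,s) / sum_e count(e,s)."""
    if isinstance(counts, CountsMatrix):
        matrix, sample_ids = counts.counts, counts.sample_ids
    else:
        matrix = np.asarray(counts)
    totals = matrix.sum(axis=0)
    if np.any(totals == 0):
        bad = int(np.argmax(totals == 0))
        name = sample_ids[bad] if sample_ids is not None else f"column {bad}"
        raise QCError(f"sample {name} has zero total count; cannot normalize")
    return NORMALIZATION_CONSTANT * matrix / totals


def flag_insufficient(counts: CountsMatrix | np.ndarray,
                      params: QCParams = QCParams()) -> np.ndarray:
    """Boolean exons x samples: True where count < min_reads (strict)."""
    matrix = counts.counts if isinstance(counts, CountsMatrix) else np.asarray(counts)
    return matrix < params.min_reads


def consistently_poor_exons(flags: np.ndarray,
                            params: QCParams = QCParams()) -> list[int]:
    """Exons flagged insufficient in >= poor_fraction of cohort samples."""
    frac = np.asarray(flags).mean(axis=1)
    return [int(i) for i in np.nonzero(frac >= params.poor_fraction)[0]]


def intersample_cv(normalized: np.ndarray, sample_idx: Sequence[int],
                   exon: int | None = None) -> float | np.ndarray:
    """CV (%) of normalized coverage across ``sample_idx``, per exon.

    100 * sd / mean with the sample (n-1) standard deviation.  A one-sample set
    raises :class:`SolitaryReferenceError`; a zero-mean exon yields NaN and is
    routed to exclusion by the caller.
    """
    idx = list(sample_idx)
    if len(idx) < 2:
        raise SolitaryReferenceError(
            f"reference set of size {len(idx)}: intersample CV undefined")
    sub = np.asarray(normalized)[:, idx]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    # a constant set has CV exactly 0 (np.std leaves ~1e-14 mean round-off)
    constant = np.ptp(sub, axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    cv = np.where(constant & (mean > 0), 0.0, cv)
    if exon is not None:
        return float(cv[exon])
    return cv


def exclusion_accounting(qc: QCReport, total_cells: int) -> dict[str, int]:
    """Exon-sample observation accounting: excluded-by-reason, their sum, and
    analysed = total - excluded.  Raises on internally inconsistent totals."""
    excluded = qc.n_solitary_cells + qc.n_poor_cells
    analysed = total_cells - excluded
    if qc.n_solitary_cells < 0 or qc.n_poor_cells < 0 or analysed < 0:
        raise QCError(
            f"inconsistent exclusion accounting: solitary={qc.n_solitary_cells} "
            f"poor={qc.n_poor_cells} total={total_cells}")
    return {
        "excluded_solitary": qc.n_solitary_cells,
        "excluded_poor": qc.n_poor_cells,
        "excluded_total": excluded,
        "analysed": analysed,
        "total": total_cells,
    }


def build_qc_report(counts: CountsMatrix, params: QCParams = QCParams()) -> QCReport:
    flags = flag_insufficient(counts, params)
    poor = consistently_poor_exons(flags, params)
    n_samples = len(counts.sample_ids)
    return QCReport(
        mean_depth=counts.counts.mean(axis=1),
        median_depth=np.median(counts.counts, axis=1),
        insufficient=flags,
        poor_exons=poor,
        n_poor_cells=len(poor) * n_samples,
    )


# ---------------------------------------------------------------------------
# spike-in accuracy
# ---------------------------------------------------------------------------

@dataclass
class SpikeInAccuracy:
    bin_edges: tuple[float, ...]
    detected: np.ndarray      # per bin
    attempted: np.ndarray     # per bin

    @property
    def accuracy(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempted > 0,
                            self.detected / np.maximum(self.attempted, 1), np.nan)

    @property
    def overall(self) -> float:
        total = int(self.attempted.sum())
        return float(self.detected.sum() / total) if total else float("nan")


def spike_in_accuracy(counts: CountsMatrix,
                      caller: Callable[[np.ndarray, CountsMatrix], list],
                      params: QCParams,
                      n_reps: int,
                      seed: int,
                      spike_cn: int = 1,
                      min_depth: float = 50.0) -> SpikeInAccuracy:
    """Monte-Carlo single-exon spike-in accuracy, stratified by intersample CV.

    Each replicate spikes one single-exon event at copy number ``spike_cn``
    (heterozygous deletion by default) into a random (sample, exon) cell with
    adequate coverage, re-calls that sample with ``caller(spiked_column,
    rest_of_cohort)``, and scores a detection when a call of the spiked type
    covers the spiked exon.  ``spike_cn=2`` is the null spike: its "detection"
    rate is the caller's per-replicate false-positive rate at that exon.

    Accuracy is stratified by each spiked exon's CV of normalized coverage
    across the rest of the cohort, using ``params.cv_bins``.
    """
    if n_reps < 1:
        raise QCError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    normalized = normalize_coverage(counts)
    n_exons, n_samples = counts.counts.shape
    edges = np.asarray(params.cv_bins, dtype=float)
    detected = np.zeros(len(edges) - 1, dtype=int)
    attempted = np.zeros(len(edges) - 1, dtype=int)
    eligible = np.nonzero(counts.counts.mean(axis=1) >= min_depth)[0]
    if eligible.size == 0:
        raise QCError(f"no exon with mean depth >= {min_depth}")
    spike_type = "del" if spike_cn < 2 else ("dup" if spike_cn > 2 else None)

    for _ in range(n_reps):
        e = int(rng.choice(eligible))
        s = int(rng.integers(n_samples))
        rest_idx = [i for i in range(n_samples) if i != s]
        cv = intersample_cv(normalized, rest_idx, exon=e)
        b = int(np.clip(np.searchsorted(edges, cv, side="right") - 1, 0, len(edges) - 2))
        column = spike_cnv(counts.counts[:, s].copy(), (e, e + 1), spike_cn, rng)
        pool = CountsMatrix(counts.panel,
                            [counts.sample_ids[i] for i in rest_idx],
                            counts.counts[:, rest_idx])
        calls = caller(column, pool)
        if spike_cn == 2:
            hit = any(c.exon_start <= e < c.exon_end for c in calls)
        else:
            hit = any(c.type == spike_type and c.exon_start <= e < c.exon_end
                      for c in calls)
        attempted[b] += 1
        detected[b] += int(hit)

    return SpikeInAccuracy(tuple(edges), detected, attempted)
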