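"""Two independent read-depth CNV callers over exon counts.

Caller A (``call_bb_hmm``) follows the aggregated-reference beta-binomial HMM
design used by exome/panel read-depth callers: the test sample's count at each
exon is modelled as a beta-binomial draw from the combined test+reference
count, with the expected test fraction scaled by CN/2 under each copy-number
state, a three-state (CN 1/2/3) Markov chain along the panel, Viterbi decoding,
and a log10 Bayes-factor confidence per call.

Caller B (``call_zscore``) is a control-matched ratio/z-score engine: the test
exon's normalized coverage is compared with the mean of its k best-matching
control samples, and runs of exons that are both ratio-aberrant and
z-significant are merged into calls.  It plays the "second algorithm" role in
the consensus filter and shares no statistical machinery with caller A.

Both callers are deterministic: no internal randomness.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from scipy import optimize, stats

from .io import CountsMatrix, PanelDesign
from .qc import normalize_coverage


class CallerError(ValueError):
    pass


@dataclass(frozen=True)
class CallerParams:
    transition_prob: float = 1e-4   # per-exon probability of entering a CNV state
    exit_prob: float = 0.5          # per-exon probability of leaving a CNV state
    states: tuple[int, ...] = (1, 2, 3)
    max_ref_samples: int = 30
    z_threshold: float = 3.0
    ratio_del_max: float = 0.75
    ratio_dup_min: float = 1.25
    min_confidence: float = 0.0     # minimum reported log10 Bayes factor
    k_controls: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.transition_prob < 1 or not 0 < self.exit_prob < 1:
            raise CallerError("transition probabilities must lie in (0,1)")
        if not self.ratio_del_max < 1 < self.ratio_dup_min:
            raise CallerError("require ratio_del_max < 1 < ratio_dup_min")


@dataclass(frozen=True)
class CnvCall:
    """A called deletion or duplication over a contiguous run of panel exons."""

    sample_id: str
    chrom: str
    start: int        # 0-based half-open union of implicated exons
    end: int
    exon_start: int   # half-open span of panel-order exon indices
    exon_end: int
    type: str         # del | dup
    ratio: float      # mean observed/expected over the span
    copy_number: int
    confidence: float  # log10 Bayes factor (caller A) or peak |z| (caller B)
    algorithm: str

    def __post_init__(self) -> None:
        if self.exon_start >= self.exon_end:
            raise CallerError("empty exon span")
        if self.type == "del" and not self.ratio < 1:
            raise CallerError(f"del call with ratio {self.ratio} >= 1")
        if self.type == "dup" and not self.ratio > 1:
            raise CallerError(f"dup call with ratio {self.ratio} <= 1")

    @property
    def n_exons(self) -> int:
        return self.exon_end - self.exon_start

    def overlaps(self, other: "CnvCall") -> bool:
        return (self.exon_start < other.exon_end and other.exon_start < self.exon_end)


# ---------------------------------------------------------------------------
# reference aggregation
# ---------------------------------------------------------------------------

def select_reference(test: np.ndarray, pool: CountsMatrix,
                     params: CallerParams = CallerParams(),
                     test_id: str | None = None) -> tuple[list[str], np.ndarray, bool]:
    """Choose and aggregate the reference samples for one test column.

    Candidates are ranked by Pearson correlation of normalized coverage with
    the test; prefix sets of the ranking are scored by the sample variance of
    the per-exon test fraction test/(test+ref) — a proxy for the precision of
    the expected ratio — and the best prefix (ties resolved toward more
    samples, up to ``max_ref_samples``) is aggregated by element-wise sum.

    Returns (chosen sample ids, aggregated column, solitary_flag); the flag is
    True when only a single candidate exists.
    """
    if len(pool.sample_ids) == 0:
        raise CallerError("empty reference pool")
    if test_id is not None and test_id in pool.sample_ids:
        raise CallerError(f"test sample {test_id} present in its own reference pool")
    test = np.asarray(test, dtype=float)
    if test.shape[0] != pool.counts.shape[0]:
        raise CallerError("test column length does not match pool")

    if len(pool.sample_ids) == 1:
        return list(pool.sample_ids), pool.counts[:, 0].copy(), True

    test_norm = 1e6 * test / max(test.sum(), 1)
    pool_norm = normalize_coverage(pool)
    # Pearson correlation of normalized coverage against the test column
    t = test_norm - test_norm.mean()
    p = pool_norm - pool_norm.mean(axis=0)
    denom = np.sqrt((t**2).sum()) * np.sqrt((p**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (p * t[:, None]).sum(axis=0) / denom, 0.0)
    order = np.argsort(-corr, kind="stable")

    cap = min(params.max_ref_samples, len(order))
    agg = np.cumsum(pool.counts[:, order[:cap]].astype(float), axis=1)
    totals = test + agg.T  # (prefix, exon)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, test / totals, np.nan)
    proxies = np.array([np.nanvar(row, ddof=1) for row in frac])
    best = np.nanmin(proxies)
    # largest prefix achieving the minimum (within float tolerance)
    i_star = int(np.nonzero(proxies <= best + 1e-15)[0][-1])
    chosen = [pool.sample_ids[j] for j in order[: i_star + 1]]
    return chosen, agg[:, i_star].astype(np.int64), False


# ---------------------------------------------------------------------------
# beta-binomial emission and dispersion fit
# ---------------------------------------------------------------------------

def bb_logpmf(x: np.ndarray, n: np.ndarray, p: float | np.ndarray,
              phi: float) -> np.ndarray:
    """log P(x | n, p, phi) under a beta-binomial with mean fraction p and
    intraclass correlation phi; exactly binomial at phi = 0."""
    x = np.asarray(x)
    n = np.asarray(n)
    if phi < 0:
        raise CallerError("phi must be >= 0")
    if phi < 1e-12:
        return stats.binom.logpmf(x, n, p)
    a = np.asarray(p) * (1.0 / phi - 1.0)
    b = (1.0 - np.asarray(p)) * (1.0 / phi - 1.0)
    return stats.betabinom.logpmf(x, n, a, b)


def fit_dispersion(test: np.ndarray, reference: np.ndarray,
                   mask: np.ndarray | None = None) -> float:
    """Maximum-likelihood beta-binomial overdispersion phi of the test fraction.

    x_e ~ BB(n_e = test_e + ref_e, p = total_test/(total_test+total_ref), phi)
    over non-CNV exons (``mask`` True = use; default all); phi = 0 (binomial)
    is recovered when the data carry no extra-binomial variation.
    """
    test = np.asarray(test, dtype=np.int64)
    reference = np.asarray(reference, dtype=np.int64)
    if test.shape != reference.shape:
        raise CallerError("test and reference columns differ in length")
    n = test + reference
    keep = n > 0
    if mask is not None:
        keep = keep & np.asarray(mask, dtype=bool)
    if not keep.any():
        raise CallerError("degenerate input: all usable counts zero")
    x, n = test[keep], n[keep]
    p = x.sum() / n.sum()
    if p <= 0 or p >= 1:
        raise CallerError("degenerate input: test fraction is 0 or 1")

    def nll(log_phi: float) -> float:
        return -float(bb_logpmf(x, n, p, float(np.exp(log_phi))).sum())

    res = optimize.minimize_scalar(nll, bounds=(np.log(1e-8), np.log(0.5)),
                                   method="bounded")
    phi = float(np.exp(res.x))
    if -float(bb_logpmf(x, n, p, 0.0).sum()) <= res.fun:
        return 0.0
    return phi


# ---------------------------------------------------------------------------
# caller A: beta-binomial HMM
# ---------------------------------------------------------------------------

def _transition_log(params: CallerParams) -> tuple[np.ndarray, np.ndarray]:
    """(log initial dist, log transition matrix) over states (CN1, CN2, CN3)."""
    q, e = params.transition_prob, params.exit_prob
    T = np.array([
        [1 - e, e, 0.0],
        [q, 1 - 2 * q, q],
        [0.0, e, 1 - e],
    ])
    pi = np.array([q, 1 - 2 * q, q])
    with np.errstate(divide="ignore"):
        return np.log(pi), np.log(T)


def hmm_emissions(test: np.ndarray, reference: np.ndarray, phi: float,
                  p0: float | None = None) -> tuple[np.ndarray, float]:
    """Per-exon log emission matrix (exons x states CN1/CN2/CN3) and p0."""
    test = np.asarray(test, dtype=np.int64)
    reference = np.asarray(reference, dtype=np.int64)
    n = test + reference
    if p0 is None:
        tot = n.sum()
        if tot == 0:
            raise CallerError("degenerate input: all counts zero")
        p0 = test.sum() / tot
    odds = p0 / (1.0 - p0)
    log_emis = np.empty((len(test), 3))
    for k, cn in enumerate((1, 2, 3)):
        sc = cn / 2.0
        p_c = sc * odds / (sc * odds + 1.0)
        log_emis[:, k] = bb_logpmf(test, n, p_c, phi)
    return log_emis, p0


def viterbi(log_emis: np.ndarray, log_pi: np.ndarray,
            log_T: np.ndarray) -> np.ndarray:
    """Most probable state path (indices into the state axis)."""
    n, k = log_emis.shape
    delta = log_pi + log_emis[0]
    back = np.zeros((n, k), dtype=np.int8)
    for t in range(1, n):
        scores = delta[:, None] + log_T
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(k)] + log_emis[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_loglik(states: np.ndarray, log_emis: np.ndarray, log_pi: np.ndarray,
                log_T: np.ndarray) -> float:
    """Joint log likelihood of one state path with its emissions."""
    states = np.asarray(states)
    ll = log_pi[states[0]] + log_emis[0, states[0]]
    for t in range(1, len(states)):
        ll += log_T[states[t - 1], states[t]] + log_emis[t, states[t]]
    return float(ll)


def call_bb_hmm(test: np.ndarray, reference: np.ndarray, panel: PanelDesign,
                params: CallerParams = CallerParams(),
                phi: float | None = None,
                p0: float | None = None,
                sample_id: str = "test",
                algorithm: str = "bb-hmm") -> list[CnvCall]:
    """Decode copy-number state along the panel and emit CNV calls.

    Chromosome breaks reset the chain to its initial distribution, so calls
    never span chromosomes.  Confidence is the log10 likelihood ratio of the
    decoded path (normal outside the call's span) to the all-normal path.
    """
    test = np.asarray(test, dtype=np.int64)
    reference = np.asarray(reference, dtype=np.int64)
    if len(test) != len(panel) or len(reference) != len(panel):
        raise CallerError("column length does not match panel")
    if phi is None:
        # two-pass: fit everywhere, decode, refit excluding decoded CNV spans
        # so a real event does not inflate the dispersion that judges it
        phi0 = fit_dispersion(test, reference)
        first = call_bb_hmm(test, reference, panel, params, phi=phi0, p0=p0,
                            sample_id=sample_id, algorithm=algorithm)
        if not first:
            return first
        mask = np.ones(len(panel), dtype=bool)
        for c in first:
            mask[c.exon_start:c.exon_end] = False
        phi = fit_dispersion(test, reference, mask=mask)
    log_emis, p0 = hmm_emissions(test, reference, phi, p0=p0)
    log_pi, log_T = _transition_log(params)

    n = test + reference
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_e = np.where(n > 0, test / np.maximum(n, 1) / p0, 1.0)

    calls: list[CnvCall] = []
    chroms = panel.chroms
    boundaries = [0] + [i for i in range(1, len(panel)) if chroms[i] != chroms[i - 1]] \
        + [len(panel)]
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        emis = log_emis[a:b]
        path = viterbi(emis, log_pi, log_T)
        normal = np.ones(b - a, dtype=np.int8)
        ll_normal = path_loglik(normal, emis, log_pi, log_T)
        i = 0
        while i < b - a:
            if path[i] != 1:
                j = i
                while j < b - a and path[j] == path[i]:
                    j += 1
                isolated = normal.copy()
                isolated[i:j] = path[i]
                conf = (path_loglik(isolated, emis, log_pi, log_T) - ll_normal) / np.log(10)
                cn = int((1, 2, 3)[path[i]])
                span_ratio = float(np.mean(ratio_e[a + i:a + j]))
                cnv_type = "del" if cn < 2 else "dup"
                # a decoded CNV whose mean ratio contradicts its side is noise
                if (cnv_type == "del" and span_ratio < 1) or \
                        (cnv_type == "dup" and span_ratio > 1):
                    if conf >= params.min_confidence:
                        t0, t1 = panel.targets[a + i], panel.targets[a + j - 1]
                        calls.append(CnvCall(
                            sample_id=sample_id, chrom=t0.chrom,
                            start=t0.start, end=t1.end,
                            exon_start=a + i, exon_end=a + j,
                            type=cnv_type, ratio=span_ratio, copy_number=cn,
                            confidence=float(conf), algorithm=algorithm))
                i = j
            else:
                i += 1
    return calls


# ---------------------------------------------------------------------------
# caller B: control-matched ratio/z-score
# ---------------------------------------------------------------------------

def call_zscore(test: np.ndarray, control_pool: CountsMatrix, panel: PanelDesign,
                params: CallerParams = CallerParams(),
                sample_id: str = "test",
                test_id: str | None = None,
                algorithm: str = "zscore") -> list[CnvCall]:
    """Ratio/z-score CNV calling against the k best-matching control samples.

    An exon is abnormal iff its ratio to the control mean is outside
    [ratio_del_max, ratio_dup_min] and |z| >= z_threshold; maximal runs of
    same-side abnormal exons become calls with the peak |z| as confidence.
    """
    if test_id is not None and test_id in control_pool.sample_ids:
        raise CallerError(f"test sample {test_id} present in control pool")
    if len(control_pool.sample_ids) < 5:
        raise CallerError(
            f"control pool of {len(control_pool.sample_ids)} samples; need >= 5")
    test = np.asarray(test, dtype=float)
    if test.shape[0] != len(panel):
        raise CallerError("column length does not match panel")

    test_norm = 1e6 * test / test.sum()
    pool_norm = normalize_coverage(control_pool)
    dist = np.abs(pool_norm - test_norm[:, None]).sum(axis=0)
    k = min(params.k_controls, pool_norm.shape[1])
    best = np.argsort(dist, kind="stable")[:k]
    controls = pool_norm[:, best]
    mean_k = controls.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(mean_k > 0, test_norm / mean_k, 1.0)
        control_ratios = np.where(mean_k[:, None] > 0,
                                  controls / mean_k[:, None], 1.0)
    sd = control_ratios.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (ratio - 1.0) / sd,
                     np.where(ratio == 1.0, 0.0, np.inf * np.sign(ratio - 1.0)))

    abnormal = ((ratio < params.ratio_del_max) | (ratio > params.ratio_dup_min)) \
        & (np.abs(z) >= params.z_threshold)
    side = np.where(ratio < 1, -1, 1)

    calls: list[CnvCall] = []
    chroms = panel.chroms
    i = 0
    n = len(panel)
    while i < n:
        if abnormal[i]:
            j = i
            while (j < n and abnormal[j] and side[j] == side[i]
                   and chroms[j] == chroms[i]):
                j += 1
            span_ratio = float(ratio[i:j].mean())
            cnv_type = "del" if side[i] < 0 else "dup"
            if (cnv_type == "del" and span_ratio < 1) or \
                    (cnv_type == "dup" and span_ratio > 1):
                t0, t1 = panel.targets[i], panel.targets[j - 1]
                calls.append(CnvCall(
                    sample_id=sample_id, chrom=t0.chrom, start=t0.start, end=t1.end,
                    exon_start=i, exon_end=j, type=cnv_type, ratio=span_ratio,
                    copy_number=1 if cnv_type == "del" else 3,
                    confidence=float(np.max(np.abs(z[i:j]))), algorithm=algorithm))
            i = j
        else:
            i += 1
    return calls
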