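"""Synthetic gene-panel cohorts with the statistical structure read-depth CNV
calling assumes.

Counts are negative-binomial (Gamma-Poisson): exon baselines lambda_e are
log-normal with a long right tail (median ~1579 deduplicated reads per exon,
matching a production IRD panel service), multiplied by a per-sample log-normal
size factor f_s and by CN/2 for exons inside a spiked CNV.  The generator also
emits external-style CNV call sets (the shape of a WGS comparison cohort) for
frequency-annotation testing.

Everything is driven by one `numpy` Generator seeded from the spec, so an
identical spec + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CountsMatrix, ExonTarget, PanelDesign, SampleMeta

# production panel shapes: version -> (n_exons, n_genes)
PANEL_REGISTRY: dict[str, tuple[int, int]] = {
    "v2": (1590, 105),
    "v3": (2704, 180),
}

_CHROMS = [f"chr{i}" for i in range(1, 23)]


def make_panel(version: str, n_exons: int | None = None, n_genes: int | None = None) -> PanelDesign:
    """Build a deterministic synthetic panel design.

    Gene sizes (exon counts) are drawn from a seeded distribution so the panel
    mixes single-exon and large multi-exon transcripts; the layout is a pure
    function of (version, n_exons, n_genes).
    """
    if n_exons is None or n_genes is None:
        if version not in PANEL_REGISTRY:
            raise KeyError(f"unknown panel version {version!r}; "
                           f"registered: {sorted(PANEL_REGISTRY)}")
        n_exons, n_genes = PANEL_REGISTRY[version]
    if n_genes > n_exons:
        raise ValueError("more genes than exons")
    rng = np.random.default_rng(hash_version(version) % (2**31))
    # gene sizes >= 1 summing to n_exons: 1 each plus a gamma-proportional share
    raw = rng.gamma(shape=1.2, scale=1.0, size=n_genes)
    extra = np.round(raw / raw.sum() * (n_exons - n_genes)).astype(int)
    sizes = 1 + extra
    while sizes.sum() > n_exons:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_exons:
        sizes[int(rng.integers(n_genes))] += 1
    targets: list[ExonTarget] = []
    pos = {c: 1_000_000 for c in _CHROMS}
    for g in range(n_genes):
        chrom = _CHROMS[g % len(_CHROMS)]
        gene = f"{version.upper()}G{g:03d}"
        tx = f"NM_{version}{g:04d}.1"
        start = pos[chrom]
        for e in range(int(sizes[g])):
            length = int(rng.integers(80, 300))
            targets.append(ExonTarget(chrom, start, start + length, gene, tx, e + 1, "+"))
            start += length + int(rng.integers(500, 5000))
        pos[chrom] = start + 100_000  # intergenic gap
    return PanelDesign(version=version, targets=tuple(targets))


def hash_version(version: str) -> int:
    """Stable (non-salted) hash of a version/sample tag."""
    import zlib
    return zlib.crc32(version.encode())


# ---------------------------------------------------------------------------
# simulation spec and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvEventSpec:
    """A class of CNVs to spike: ``n_carriers`` samples on ``panel`` each get
    one event of ``span_exons`` contiguous exons at copy number ``cn``."""

    panel: str
    n_carriers: int
    span_exons: int
    cn: int  # 0,1,3,4
    min_exon_depth: float = 500.0  # restrict placement to well-covered exons

    @property
    def type(self) -> str:
        return "del" if self.cn < 2 else "dup"

    def __post_init__(self) -> None:
        if self.cn not in (0, 1, 3, 4):
            raise ValueError(f"spiked copy number must be in {{0,1,3,4}}, got {self.cn}")
        if self.n_carriers < 0 or self.span_exons < 1:
            raise ValueError("invalid event spec")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic cohort."""

    n_samples_per_panel: dict[str, int] = field(
        default_factory=lambda: {"v2": 197, "v3": 353})
    exon_baseline_median: float = 1579.0
    exon_baseline_sigma: float = 0.91     # log-sd; gives mean ~2389 with long tail
    sample_sigma: float = 0.15            # log-sd of per-sample size factor
    dispersion: float = 0.0025            # mean NB alpha: Var = m + alpha m^2
    exon_dispersion_sigma: float = 1.5    # log-sd of per-exon alpha heterogeneity
    gender_ratio: float = 0.5             # fraction male
    cnv_events: tuple[CnvEventSpec, ...] = ()
    dropout_floor: float = 0.01           # residual capture fraction at CN=0
    seed: int = 0
    # ad-hoc panels not in PANEL_REGISTRY: version -> (n_exons, n_genes)
    panel_shapes: tuple[tuple[str, tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        if self.exon_baseline_median <= 0 or self.exon_baseline_sigma <= 0:
            raise ValueError("baseline parameters must be > 0")
        if self.sample_sigma < 0 or self.dispersion < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.gender_ratio <= 1:
            raise ValueError("gender_ratio must be in [0,1]")
        if not 0 <= self.dropout_floor < 1:
            raise ValueError("dropout_floor must be in [0,1)")


@dataclass(frozen=True)
class TruthEvent:
    sample_id: str
    panel: str
    exon_start: int   # panel-order index, half-open span
    exon_end: int
    cn: int
    type: str
    chrom: str
    start: int        # genomic, 0-based half-open union of implicated exons
    end: int


@dataclass
class TruthSet:
    events: list[TruthEvent]

    def __post_init__(self) -> None:
        by_sample: dict[str, list[TruthEvent]] = {}
        for ev in self.events:
            by_sample.setdefault(ev.sample_id, []).append(ev)
        for sid, evs in by_sample.items():
            evs = sorted(evs, key=lambda e: e.exon_start)
            for a, b in zip(evs, evs[1:]):
                if b.exon_start < a.exon_end:
                    raise ValueError(f"overlapping truth events for sample {sid}")

    def __len__(self) -> int:
        return len(self.events)

    def for_sample(self, sample_id: str) -> list[TruthEvent]:
        return [e for e in self.events if e.sample_id == sample_id]

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for e in sorted(self.events, key=lambda e: (e.chrom, e.start, e.sample_id)):
                fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.sample_id}\t{e.cn}\t{e.type}\n")


@dataclass
class Cohort:
    """Bundle returned by :func:`simulate_cohort` (one counts matrix per panel)."""

    counts: dict[str, CountsMatrix]
    metadata: list[SampleMeta]
    truth: TruthSet

    @property
    def total_cells(self) -> int:
        return sum(m.counts.size for m in self.counts.values())


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             alpha: float | np.ndarray) -> np.ndarray:
    """Negative-binomial draw with Var = m + alpha m^2 (Poisson when alpha=0).

    ``alpha`` may be a per-exon column vector broadcasting over samples."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.all(alpha <= 0):
        return rng.poisson(mean)
    alpha = np.maximum(alpha, 1e-12)
    r = np.broadcast_to(1.0 / alpha, mean.shape)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_cohort(spec: SimulationSpec,
                    panels: dict[str, PanelDesign] | None = None) -> Cohort:
    """Simulate per-exon deduplicated read counts for one or more panels.

    count(e, s) ~ NB(mean = lambda_e * f_s * CN(e,s)/2, dispersion alpha);
    CN comes from the spiked truth events (2 elsewhere); CN=0 retains the
    ``dropout_floor`` fraction of the expected depth.
    """
    rng = np.random.default_rng(spec.seed)
    if panels is None:
        shapes = dict(spec.panel_shapes)
        panels = {v: (make_panel(v, *shapes[v]) if v in shapes else make_panel(v))
                  for v in sorted(spec.n_samples_per_panel)}
    for v in spec.n_samples_per_panel:
        if v not in panels:
            raise KeyError(f"unknown panel version {v!r}")

    metadata: list[SampleMeta] = []
    truth_events: list[TruthEvent] = []
    counts: dict[str, CountsMatrix] = {}

    for version in sorted(spec.n_samples_per_panel):
        panel = panels[version]
        n_samples = spec.n_samples_per_panel[version]
        n_exons = len(panel)
        sample_ids = [f"S{version}_{i:04d}" for i in range(n_samples)]
        n_male = int(round(spec.gender_ratio * n_samples))
        genders = ["male"] * n_male + ["female"] * (n_samples - n_male)
        metadata.extend(SampleMeta(s, g, version)
                        for s, g in zip(sample_ids, genders))

        lam = np.exp(rng.normal(np.log(spec.exon_baseline_median),
                                spec.exon_baseline_sigma, size=n_exons))
        # per-exon dispersion heterogeneity: capture efficiency varies by
        # target, so some exons are far noisier than the panel average
        s = spec.exon_dispersion_sigma
        alpha = spec.dispersion * np.exp(rng.normal(0.0, s, size=n_exons) - s**2 / 2) \
            if s > 0 else np.full(n_exons, spec.dispersion)
        f = np.exp(rng.normal(0.0, spec.sample_sigma, size=n_samples))
        f /= np.exp(spec.sample_sigma**2 / 2)  # E[f] = 1

        cn = np.full((n_exons, n_samples), 2, dtype=float)
        occupied: dict[int, list[tuple[int, int]]] = {}
        for ev_spec in spec.cnv_events:
            if ev_spec.panel != version:
                continue
            if ev_spec.n_carriers > n_samples:
                raise ValueError(
                    f"{ev_spec.n_carriers} carriers exceed cohort size {n_samples}")
            spans = _eligible_spans(panel, lam, ev_spec.span_exons,
                                    ev_spec.min_exon_depth)
            if not spans:
                raise ValueError(
                    f"no eligible {ev_spec.span_exons}-exon span at depth "
                    f">= {ev_spec.min_exon_depth} in panel {version}")
            carriers = rng.choice(n_samples, size=ev_spec.n_carriers, replace=False)
            for s in carriers:
                s = int(s)
                placed = False
                order = rng.permutation(len(spans))
                for j in order:
                    a, b = spans[j]
                    if all(b <= a2 or a >= b2 for a2, b2 in occupied.get(s, [])):
                        placed = True
                        break
                if not placed:
                    raise ValueError(f"cannot place non-overlapping event for sample {s}")
                occupied.setdefault(s, []).append((a, b))
                cn[a:b, s] = ev_spec.cn
                t0, t1 = panel.targets[a], panel.targets[b - 1]
                truth_events.append(TruthEvent(
                    sample_id=sample_ids[s], panel=version, exon_start=a, exon_end=b,
                    cn=ev_spec.cn, type=ev_spec.type,
                    chrom=t0.chrom, start=t0.start, end=t1.end))

        scale = np.where(cn == 0, spec.dropout_floor, cn / 2.0)
        mean = lam[:, None] * f[None, :] * scale
        matrix = _nb_draw(rng, mean, alpha[:, None]).astype(np.int64)
        counts[version] = CountsMatrix(panel, sample_ids, matrix)

    return Cohort(counts=counts, metadata=metadata, truth=TruthSet(truth_events))


def _eligible_spans(panel: PanelDesign, lam: np.ndarray, span: int,
                    min_depth: float) -> list[tuple[int, int]]:
    """Contiguous ``span``-exon windows lying within one transcript with every
    exon baseline >= min_depth."""
    spans = []
    i = 0
    targets = panel.targets
    n = len(targets)
    while i < n:
        j = i
        while j < n and targets[j].transcript == targets[i].transcript:
            j += 1
        for a in range(i, j - span + 1):
            if np.all(lam[a:a + span] >= min_depth):
                spans.append((a, a + span))
        i = j
    return spans


# ---------------------------------------------------------------------------
# spiking into existing count columns
# ---------------------------------------------------------------------------

def spike_cnv(column: np.ndarray, span: tuple[int, int], cn: int,
              rng: np.random.Generator, dropout_floor: float = 0.01) -> np.ndarray:
    """Return a copy of a per-exon count column with a CNV spiked over ``span``.

    Deletions binomially thin the observed counts (keep probability cn/2, or the
    dropout floor at CN=0), duplications add a Poisson top-up with mean
    count*(cn/2 - 1); either way E[new] = E[old] * cn/2 inside the span and the
    column is untouched outside it.
    """
    a, b = span
    if not (0 <= a < b <= len(column)):
        raise IndexError(f"span {span} out of bounds for column of length {len(column)}")
    if cn not in (0, 1, 2, 3, 4):
        raise ValueError(f"copy number must be in 0..4, got {cn}")
    if cn == 2:
        return column.copy()
    out = column.copy()
    seg = column[a:b]
    if cn < 2:
        p = dropout_floor if cn == 0 else cn / 2.0
        out[a:b] = rng.binomial(seg, p) if p > 0 else 0
    else:
        out[a:b] = seg + rng.poisson(seg * (cn / 2.0 - 1.0))
    return out


# ---------------------------------------------------------------------------
# external-style call sets (WGS comparison cohort shape)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExternalEventSpec:
    """A recurrent event seeded into an external cohort: ``n_carriers`` of the
    cohort's samples carry a call at (approximately) these coordinates."""

    chrom: str
    start: int
    end: int
    type: str  # del | dup
    n_carriers: int


@dataclass(frozen=True)
class ExternalCall:
    chrom: str
    start: int
    end: int
    type: str


def simulate_external_callsets(events: Sequence[ExternalEventSpec], n_samples: int,
                               seed: int, jitter: float = 0.1) -> list[list[ExternalCall]]:
    """Per-sample call sets in which each seeded event recurs in exactly
    ``n_carriers`` samples, with endpoints jittered by up to ``jitter`` of the
    event length (so reciprocal-overlap matching is exercised, not trivial
    equality)."""
    rng = np.random.default_rng(seed)
    callsets: list[list[ExternalCall]] = [[] for _ in range(n_samples)]
    for ev in events:
        if ev.n_carriers > n_samples:
            raise ValueError(f"recurrence {ev.n_carriers} exceeds cohort size {n_samples}")
        length = ev.end - ev.start
        carriers = rng.choice(n_samples, size=ev.n_carriers, replace=False)
        for s in carriers:
            if jitter > 0:
                ds = int(rng.integers(-int(jitter * length), int(jitter * length) + 1))
                de = int(rng.integers(-int(jitter * length), int(jitter * length) + 1))
            else:
                ds = de = 0
            start, end = ev.start + ds, ev.end + de
            if start >= end:
                start, end = ev.start, ev.end
            callsets[int(s)].append(ExternalCall(ev.chrom, start, end, ev.type))
    return callsets
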