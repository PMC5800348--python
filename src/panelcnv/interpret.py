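"""Clinical-style interpretation of consensus CNV events.

Copy number and zygosity are assigned from the observed/expected read ratio
(the decoded HMM state only distinguishes CN 1/2/3; homozygous deletions and
4-copy duplications are resolved from the ratio).  Events are named in the
HGVS "uncertain breakpoint" cDNA style used in clinical CNV reporting —
c.(a+1_b-1)_(c+1_d-1)del — because exon-level read-depth calling never knows
the true breakpoints.  Cohort frequency annotation counts carriers in external
call sets whose events cover at least half of the panel event.  ACMG class
labels are carried as input annotations, never computed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd


class InterpretError(ValueError):
    pass


# ---------------------------------------------------------------------------
# copy number and zygosity from the read ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyNumberBins:
    """Ratio bin edges, symmetric around the expected CN/2 ratios
    (0, 0.5, 1, 1.5, 2)."""

    hom_del_max: float = 0.15
    het_del_max: float = 0.75
    het_dup_min: float = 1.25
    hom_dup_min: float = 1.75


def assign_copy_number(ratio: float, cnv_type: str | None = None,
                       bins: CopyNumberBins = CopyNumberBins()) -> tuple[int, str]:
    """Map an observed/expected ratio to (copy number, zygosity label).

    The bins partition [0, inf): [0,0.15) -> 0 (hom del), [0.15,0.75) -> 1
    (het del), [0.75,1.25) -> 2, [1.25,1.75) -> 3 (het dup), >=1.75 -> 4.
    If ``cnv_type`` is given it must agree with the bin's side.
    """
    if ratio < 0:
        raise InterpretError(f"negative ratio {ratio}")
    if ratio < bins.hom_del_max:
        cn, zygosity = 0, "hom"
    elif ratio < bins.het_del_max:
        cn, zygosity = 1, "het"
    elif ratio < bins.het_dup_min:
        cn, zygosity = 2, "n/a"
    elif ratio < bins.hom_dup_min:
        cn, zygosity = 3, "het"
    else:
        cn, zygosity = 4, "hom"
    if cnv_type == "del" and cn >= 2:
        raise InterpretError(f"del call with ratio {ratio} outside deletion bins")
    if cnv_type == "dup" and cn <= 2:
        raise InterpretError(f"dup call with ratio {ratio} outside duplication bins")
    return cn, zygosity


# ---------------------------------------------------------------------------
# HGVS-style CNV naming
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """cDNA coordinate map: per-exon (start, end) positions, 1-based inclusive,
    in transcription order."""

    name: str
    exon_cdna: tuple[tuple[int, int], ...]

    @classmethod
    def from_lengths(cls, name: str, lengths: Sequence[int]) -> "TranscriptModel":
        bounds, pos = [], 1
        for ln in lengths:
            bounds.append((pos, pos + ln - 1))
            pos += ln
        return cls(name, tuple(bounds))

    @property
    def n_exons(self) -> int:
        return len(self.exon_cdna)


def hgvs_cnv_name(exon_first: int, exon_last: int, cnv_type: str,
                  transcript: TranscriptModel) -> str:
    """HGVS-like cDNA name for a CNV spanning exons ``exon_first..exon_last``
    (1-based ordinals, inclusive) of one transcript.

    Whole-transcript events use the fully uncertain form c.(?_-1)_(*1_?);
    internal events flank the span with the last position of the preceding
    exon and the first of the following exon: c.(a+1_b-1)_(c+1_d-1).
    """
    if cnv_type not in ("del", "dup"):
        raise InterpretError(f"invalid CNV type {cnv_type!r}")
    n = transcript.n_exons
    if not 1 <= exon_first <= exon_last <= n:
        raise InterpretError(
            f"exon span {exon_first}..{exon_last} outside transcript "
            f"{transcript.name} with {n} exons")
    if exon_first == 1:
        left = "(?_-1)"
    else:
        a = transcript.exon_cdna[exon_first - 2][1]
        b = transcript.exon_cdna[exon_first - 1][0]
        left = f"({a}+1_{b}-1)"
    if exon_last == n:
        right = "(*1_?)"
    else:
        c = transcript.exon_cdna[exon_last - 1][1]
        d = transcript.exon_cdna[exon_last][0]
        right = f"({c}+1_{d}-1)"
    return f"{transcript.name}: c.{left}_{right}{cnv_type}"


_HGVS_RE = re.compile(
    r"^(?P<tx>\S+): c\.(?P<left>\(\?_-1\)|\((?P<a>\d+)\+1_(?P<b>\d+)-1\))"
    r"_(?P<right>\(\*1_\?\)|\((?P<c>\d+)\+1_(?P<d>\d+)-1\))(?P<type>del|dup)$")


def parse_hgvs_cnv_name(name: str, transcript: TranscriptModel) -> tuple[int, int, str]:
    """Recover (exon_first, exon_last, type) from a name emitted by
    :func:`hgvs_cnv_name` — the round-trip oracle for the naming scheme."""
    m = _HGVS_RE.match(name)
    if not m or m.group("tx") != transcript.name:
        raise InterpretError(f"unparseable CNV name {name!r}")
    starts = [s for s, _ in transcript.exon_cdna]
    ends = [e for _, e in transcript.exon_cdna]
    if m.group("left") == "(?_-1)":
        first = 1
    else:
        first = starts.index(int(m.group("b"))) + 1
    if m.group("right") == "(*1_?)":
        last = transcript.n_exons
    else:
        last = ends.index(int(m.group("c"))) + 1
    return first, last, m.group("type")


def hgvs_names_for_event(exon_spans: dict[TranscriptModel, tuple[int, int]],
                         cnv_type: str) -> list[str]:
    """Multi-gene events emit one name per implicated transcript."""
    return [hgvs_cnv_name(a, b, cnv_type, tx)
            for tx, (a, b) in exon_spans.items()]


# ---------------------------------------------------------------------------
# frequency annotation against external cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrequencyParams:
    min_overlap_fraction: float = 0.5  # of the panel event's length

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap_fraction <= 1:
            raise InterpretError("min_overlap_fraction must be in (0, 1]")


def annotate_frequency(event, callsets: dict[str, Sequence[Sequence]],
                       params: FrequencyParams = FrequencyParams()
                       ) -> dict[str, int]:
    """Carrier counts per external cohort.

    ``callsets`` maps cohort name -> list of per-sample call lists (objects
    with chrom/start/end/type).  A sample counts iff any of its same-type calls
    intersects the event over >= min_overlap_fraction of the *event's* length
    (one-directional, matching the panel-event-centric definition).
    """
    length = event.end - event.start
    if length <= 0:
        raise InterpretError("event has non-positive length")
    out: dict[str, int] = {}
    for cohort, samples in callsets.items():
        carriers = 0
        for calls in samples:
            for c in calls:
                if c.type != event.type or c.chrom != event.chrom:
                    continue
                overlap = min(c.end, event.end) - max(c.start, event.start)
                if overlap / length >= params.min_overlap_fraction:
                    carriers += 1
                    break
        out[cohort] = carriers
    return out


# ---------------------------------------------------------------------------
# confirmation records, PPV and cohort yield
# ---------------------------------------------------------------------------

CLASSIFICATIONS = ("pathogenic", "likely pathogenic", "uncertain significance",
                   "likely benign", "benign")
CONTRIBUTIONS = ("confirms", "provisional", "none")


@dataclass(frozen=True)
class ConfirmationRecord:
    sample_id: str
    event_label: str
    gene: str
    type: str                     # del | dup
    tested: bool
    confirmed: bool
    classification: str = "uncertain significance"
    diagnostic_contribution: str = "none"
    zygosity: str = ""
    group: str = "primary"        # primary | excluded_set

    def __post_init__(self) -> None:
        if self.confirmed and not self.tested:
            raise InterpretError(
                f"{self.sample_id}/{self.event_label}: confirmed but not tested")
        if self.classification not in CLASSIFICATIONS:
            raise InterpretError(f"unknown classification {self.classification!r}")
        if self.diagnostic_contribution not in CONTRIBUTIONS:
            raise InterpretError(
                f"unknown contribution {self.diagnostic_contribution!r}")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal half-up rounding at the printed precision (78.571 -> 79)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PpvResult:
    n_confirmed: int
    n_tested: int
    raw: float          # percent
    rounded: float      # percent, half-up at requested precision


def compute_ppv(records: Iterable[ConfirmationRecord],
                precision: int = 0) -> PpvResult:
    """Positive predictive value: 100 x confirmed / tested."""
    tested = [r for r in records if r.tested]
    if not tested:
        raise InterpretError("PPV undefined: no tested records")
    confirmed = sum(r.confirmed for r in tested)
    raw = 100.0 * confirmed / len(tested)
    return PpvResult(confirmed, len(tested), raw, round_half_up(raw, precision))


def summarize_cohort(records: Sequence[ConfirmationRecord],
                     n_individuals: int) -> dict:
    """Cohort-level yield summary over confirmed events.

    Individuals are de-duplicated; one with any diagnosis-contributing
    confirmed CNV counts to the diagnostic yield, one with only
    non-contributing confirmed CNVs counts to the incidental-finding rate.
    """
    confirmed = [r for r in records if r.confirmed]
    diag_ids = {r.sample_id for r in confirmed
                if r.diagnostic_contribution in ("confirms", "provisional")}
    other_ids = {r.sample_id for r in confirmed} - diag_ids
    by_type = {"del": sum(r.type == "del" for r in confirmed),
               "dup": sum(r.type == "dup" for r in confirmed)}
    # recurrence: confirmed events seen in more than one individual
    by_label: dict[tuple[str, str], set[str]] = {}
    for r in confirmed:
        by_label.setdefault((r.event_label, r.type), set()).add(r.sample_id)
    recurrence = {f"{label} ({t})": len(ids)
                  for (label, t), ids in sorted(by_label.items()) if len(ids) > 1}
    pct = lambda k: round_half_up(100.0 * k / n_individuals, 1) if n_individuals else 0.0
    return {
        "n_individuals": n_individuals,
        "n_confirmed_events": len(confirmed),
        "confirmed_by_type": by_type,
        "n_diagnostic_individuals": len(diag_ids),
        "n_other_individuals": len(other_ids),
        "pct_diagnostic": pct(len(diag_ids)),
        "pct_other": pct(len(other_ids)),
        "pct_any_cnv": pct(len(diag_ids) + len(other_ids)),
        "recurrent_events": recurrence,
    }


def load_confirmed_events() -> list[ConfirmationRecord]:
    """Load the packaged confirmed-events table (the study's wet-lab
    confirmation outcomes, a pipeline input)."""
    with resources.files("panelcnv.data").joinpath("confirmed_events.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype=str)
    records = []
    for r in df.itertuples(index=False):
        records.append(ConfirmationRecord(
            sample_id=r.sample_id, event_label=r.event_label, gene=r.gene,
            type=r.type, tested=r.tested == "yes", confirmed=r.confirmed == "yes",
            classification=r.classification,
            diagnostic_contribution=r.diagnostic_contribution,
            zygosity=r.zygosity, group=r.group))
    return records
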