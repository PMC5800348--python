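"""Readers and writers for panel designs, count matrices, metadata and call sets.

Internal coordinates are 0-based half-open (BED convention); everything written
for human consumption (calls TSV) is 1-based inclusive.  Readers validate and
reject rather than coerce: a malformed file raises :class:`PanelIOError` naming
the offending line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class PanelIOError(ValueError):
    """Raised for malformed or invariant-violating input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonTarget:
    """One captured exon: the unit of CNV resolution.

    ``start``/``end`` are 0-based half-open genomic coordinates.  ``exon_index``
    is the ordinal of the exon within its transcript in transcription order
    (1-based, contiguous).
    """

    chrom: str
    start: int
    end: int
    gene: str
    transcript: str
    exon_index: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelIOError(
                f"exon target {self.gene}/{self.transcript} exon {self.exon_index}: "
                f"start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise PanelIOError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PanelDesign:
    """An ordered set of exon targets for one enrichment-kit version."""

    version: str
    targets: tuple[ExonTarget, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.targets, key=lambda t: (t.chrom, t.start, t.end)))
        object.__setattr__(self, "targets", ordered)
        seen: set[tuple[str, int]] = set()
        per_tx: dict[str, list[int]] = {}
        for t in ordered:
            key = (t.transcript, t.exon_index)
            if key in seen:
                raise PanelIOError(
                    f"duplicate (transcript, exon_index) = {key} in panel {self.version}"
                )
            seen.add(key)
            per_tx.setdefault(t.transcript, []).append(t.exon_index)
        for tx, idxs in per_tx.items():
            idxs = sorted(idxs)
            if idxs != list(range(idxs[0], idxs[0] + len(idxs))):
                raise PanelIOError(f"transcript {tx}: exon_index not contiguous ({idxs})")

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([t.chrom for t in self.targets])

    def exon_indices_of_transcript(self, transcript: str) -> list[int]:
        return [i for i, t in enumerate(self.targets) if t.transcript == transcript]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    gender: str  # "male" | "female"
    panel_version: str

    def __post_init__(self) -> None:
        if self.gender not in ("male", "female"):
            raise PanelIOError(f"sample {self.sample_id}: invalid gender {self.gender!r}")


@dataclass
class CountsMatrix:
    """Deduplicated read counts, exons (rows, panel order) x samples (columns)."""

    panel: PanelDesign
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.panel), len(self.sample_ids)):
            raise PanelIOError(
                f"counts shape {self.counts.shape} does not match panel "
                f"({len(self.panel)} exons) x samples ({len(self.sample_ids)})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise PanelIOError("counts matrix contains non-integer cells")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise PanelIOError("counts matrix contains negative cells")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PanelIOError("duplicate sample ids in counts matrix")

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "CountsMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountsMatrix(self.panel, list(sample_ids), self.counts[:, idx].copy())


# ---------------------------------------------------------------------------
# panel design I/O
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["chrom", "start", "end", "gene", "transcript", "exon_index", "strand"]


def read_panel(path: str | Path, version: str | None = None) -> PanelDesign:
    """Read a BED-derived panel TSV with annotation columns.

    Expected columns: chrom, start, end, gene, transcript, exon_index, strand
    (tab-separated, with header).  Raises :class:`PanelIOError` naming the line
    for malformed rows.
    """
    path = Path(path)
    targets: list[ExonTarget] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PANEL_COLUMNS:
            raise PanelIOError(f"{path}: line 1: expected header {_PANEL_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_PANEL_COLUMNS):
                raise PanelIOError(f"{path}: line {lineno}: expected "
                                   f"{len(_PANEL_COLUMNS)} fields, got {len(fields)}")
            try:
                targets.append(ExonTarget(
                    chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                    gene=fields[3], transcript=fields[4],
                    exon_index=int(fields[5]), strand=fields[6],
                ))
            except PanelIOError as exc:
                raise PanelIOError(f"{path}: line {lineno}: {exc}") from exc
            except ValueError as exc:
                raise PanelIOError(f"{path}: line {lineno}: {exc}") from exc
    return PanelDesign(version=version or path.stem, targets=tuple(targets))


def write_panel(panel: PanelDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PANEL_COLUMNS) + "\n")
        for t in panel.targets:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t{t.transcript}"
                     f"\t{t.exon_index}\t{t.strand}\n")


# ---------------------------------------------------------------------------
# counts matrix I/O
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, panel: PanelDesign) -> CountsMatrix:
    """Read a counts TSV (header = sample ids, one row per panel exon in panel order)."""
    df = pd.read_csv(path, sep="\t")
    if len(df) != len(panel):
        raise PanelIOError(
            f"{path}: {len(df)} rows but panel {panel.version} has {len(panel)} exons"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise PanelIOError(f"{path}: non-numeric cell in counts matrix")
    if np.any(np.mod(values, 1) != 0):
        raise PanelIOError(f"{path}: non-integer cell in counts matrix")
    if (values < 0).any():
        raise PanelIOError(f"{path}: negative cell in counts matrix")
    return CountsMatrix(panel, list(df.columns), values.astype(np.int64))


def write_counts(matrix: CountsMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.counts, columns=matrix.sample_ids).to_csv(
        path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "gender", "panel_version"):
        if col not in df.columns:
            raise PanelIOError(f"{path}: missing metadata column {col!r}")
    metas = [SampleMeta(r.sample_id, r.gender, r.panel_version)
             for r in df.itertuples(index=False)]
    if len({m.sample_id for m in metas}) != len(metas):
        raise PanelIOError(f"{path}: duplicate sample ids in metadata")
    return metas


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgender\tpanel_version\n")
        for m in metas:
            fh.write(f"{m.sample_id}\t{m.gender}\t{m.panel_version}\n")


# ---------------------------------------------------------------------------
# call-set output
# ---------------------------------------------------------------------------

_CALL_TSV_COLUMNS = ["sample_id", "chrom", "start", "end", "type", "copy_number",
                     "ratio", "confidence", "algorithm", "gene", "exons_n"]


def write_calls(events, path: str | Path, format: str = "tsv") -> None:
    """Write called events as TSV (1-based inclusive coordinates) or VCF 4.2.

    ``events`` is an iterable of objects with sample_id, chrom, start, end
    (0-based half-open), type ("del"/"dup"), ratio, confidence, algorithm and
    optionally copy_number / gene / n_exons attributes.
    """
    events = list(events)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_CALL_TSV_COLUMNS) + "\n")
            for ev in events:
                fh.write("\t".join(str(x) for x in (
                    ev.sample_id, ev.chrom, ev.start + 1, ev.end, ev.type,
                    getattr(ev, "copy_number", ""),
                    f"{ev.ratio:.4f}", f"{ev.confidence:.3f}", ev.algorithm,
                    getattr(ev, "gene", ""), getattr(ev, "n_exons", ""),
                )) + "\n")
    elif format == "vcf":
        _write_vcf(events, path)
    else:
        raise PanelIOError(f"unknown call format {format!r}")


def _write_vcf(events, path: str | Path) -> None:
    for ev in events:
        if ev.start >= ev.end:
            raise PanelIOError(f"invalid record for VCF output: start {ev.start} >= end {ev.end}")
        if ev.type not in ("del", "dup"):
            raise PanelIOError(f"invalid SV type {ev.type!r}")
    events = sorted(events, key=lambda e: (e.chrom, e.start, e.end, e.sample_id))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of variant">\n')
        fh.write('##INFO=<ID=CONF,Number=1,Type=Float,Description='
                 '"Caller confidence (log10 Bayes factor or peak |z|)">\n')
        fh.write('##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample">\n')
        contigs = sorted({ev.chrom for ev in events})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, ev in enumerate(events):
            svtype = ev.type.upper()
            # POS is the base before the event per VCF symbolic-allele convention;
            # with 0-based half-open start, that is simply `start` in 1-based space.
            pos = max(ev.start, 1)
            info = (f"SVTYPE={svtype};END={ev.end};CONF={ev.confidence:.3f};"
                    f"SAMPLE={ev.sample_id}")
            fh.write(f"{ev.chrom}\t{pos}\t{svtype.lower()}_{i}\tN\t<{svtype}>\t.\t.\t{info}\n")
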