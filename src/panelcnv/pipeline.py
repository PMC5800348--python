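"""End-to-end orchestration: QC -> triple calling -> consensus filters ->
interpretation -> reports.

The unit of work is one panel version (counts matrices from different
enrichment kits are disjoint exon sets and never mixed).  For every test
sample the beta-binomial HMM caller runs three times, once against each of
three disjoint gender/kit-matched reference sets; the z-score caller runs once
against the full matched pool; the consensus filter reduces the candidates and
the survivors are interpreted (copy number, zygosity, HGVS-style name).

Outputs are stamped with the config hash and seed; a rerun with an identical
config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .callers import CallerParams, call_bb_hmm, call_zscore, fit_dispersion, select_reference
from .consensus import (ConsensusError, ConsensusEvent, ConsensusParams,
                        InspectionThresholds, partition_reference_sets, run_filters)
from .interpret import (FrequencyParams, InterpretError, TranscriptModel,
                        annotate_frequency, assign_copy_number, hgvs_cnv_name)
from .qc import QCParams, build_qc_report, exclusion_accounting, normalize_coverage
from .simulate import Cohort, CnvEventSpec, SimulationSpec, simulate_cohort

log = logging.getLogger("panelcnv")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    paths: dict = field(default_factory=dict)       # panel/counts/metadata/... files
    simulate: SimulationSpec | None = None
    caller: CallerParams = field(default_factory=CallerParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    qc: QCParams = field(default_factory=QCParams)
    frequency: FrequencyParams = field(default_factory=FrequencyParams)

    def hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def validate_config(source: str | Path | dict) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a config mapping (or YAML file path).

    Returns (config, errors); every violation is reported at once with its
    field path, and the config is None if any error was found.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: list[str] = []

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed: must be a non-negative integer, got {seed!r}")

    paths = raw.get("paths", {}) or {}
    sim_raw = raw.get("simulate")
    if sim_raw is None and "counts" not in paths:
        errors.append("paths.counts: required when no simulate section is given")
    for key in ("metadata", "confirmations"):
        if key in paths and not Path(paths[key]).exists():
            errors.append(f"paths.{key}: file not found: {paths[key]}")
    for key in ("counts", "panel"):
        for version, p in (paths.get(key) or {}).items():
            if not Path(p).exists():
                errors.append(f"paths.{key}.{version}: file not found: {p}")

    sim = None
    if sim_raw is not None:
        try:
            events = tuple(CnvEventSpec(**e) for e in sim_raw.pop("cnv_events", []))
            sim = SimulationSpec(seed=seed, cnv_events=events, **{
                k: (v if k != "n_samples_per_panel" else dict(v))
                for k, v in sim_raw.items()})
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")

    def build(cls, key):
        try:
            section = raw.get(key, {}) or {}
            if key == "consensus" and "inspection" in section:
                section = dict(section)
                section["inspection"] = InspectionThresholds(**section["inspection"])
            return cls(**section)
        except (TypeError, ValueError) as exc:
            errors.append(f"{key}: {exc}")
            return cls()

    caller = build(CallerParams, "caller")
    consensus = build(ConsensusParams, "consensus")
    qc = build(QCParams, "qc")
    frequency = build(FrequencyParams, "frequency")

    if sim is not None and consensus is not None:
        need = consensus.n_sets * consensus.set_size
        for version, n in sim.n_samples_per_panel.items():
            # worst-case matched pool after the gender split
            matched = min(round(sim.gender_ratio * n), n - round(sim.gender_ratio * n))
            if matched - 1 < need:
                errors.append(
                    f"consensus: insufficient matched samples for panel {version}: "
                    f"{consensus.n_sets} sets of {consensus.set_size} need {need}, "
                    f"worst gender stratum has {matched - 1} candidates")

    if errors:
        return None, errors
    cfg = PipelineConfig(seed=seed, paths=paths, simulate=sim, caller=caller,
                         consensus=consensus, qc=qc, frequency=frequency)
    return cfg, []


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------

@dataclass
class InterpretedEvent:
    event: ConsensusEvent
    copy_number: int
    zygosity: str
    hgvs: list[str]
    genes: list[str]
    frequencies: dict[str, int] = field(default_factory=dict)


@dataclass
class PipelineResult:
    events: list[InterpretedEvent]
    funnel: dict[str, int]
    accounting: dict[str, int]
    qc_summaries: dict[str, dict]
    sensitivity: float | None = None
    truth_matches: list[tuple] = field(default_factory=list)
    config_hash: str = ""
    seed: int = 0


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def _load_cohort(config: PipelineConfig) -> Cohort:
    if config.simulate is not None:
        return simulate_cohort(config.simulate)
    panels = {}
    for version, p in (config.paths.get("panel") or {}).items():
        panels[version] = pio.read_panel(p, version=version)
    counts = {}
    for version, p in (config.paths.get("counts") or {}).items():
        if version not in panels:
            raise ConfigError(f"counts given for panel {version} without a panel file")
        counts[version] = pio.read_counts(p, panels[version])
    metadata = pio.read_metadata(config.paths["metadata"])
    from .simulate import TruthSet
    return Cohort(counts=counts, metadata=metadata, truth=TruthSet([]))


def transcript_models(panel: pio.PanelDesign) -> dict[str, TranscriptModel]:
    """Build cDNA coordinate maps from the panel's exon lengths (coding
    positions approximated by captured-exon extents)."""
    lengths: dict[str, list[int]] = {}
    for t in panel.targets:
        lengths.setdefault(t.transcript, []).append(t.length)
    return {tx: TranscriptModel.from_lengths(tx, ls) for tx, ls in lengths.items()}


def _interpret_event(ev: ConsensusEvent, panel: pio.PanelDesign,
                     tx_models: dict[str, TranscriptModel],
                     external_callsets: dict | None,
                     freq_params: FrequencyParams) -> InterpretedEvent:
    call = ev.call
    try:
        cn, zygosity = assign_copy_number(call.ratio, call.type)
    except InterpretError:
        # ratio near a bin edge disagreeing with the decoded side: keep the
        # decoded copy number, flag zygosity as unresolved
        cn, zygosity = call.copy_number, "unresolved"
    spans: dict[str, tuple[int, int]] = {}
    genes: list[str] = []
    for i in range(call.exon_start, call.exon_end):
        t = panel.targets[i]
        if t.gene not in genes:
            genes.append(t.gene)
        a, b = spans.get(t.transcript, (t.exon_index, t.exon_index))
        spans[t.transcript] = (min(a, t.exon_index), max(b, t.exon_index))
    names = [hgvs_cnv_name(a, b, call.type, tx_models[tx])
             for tx, (a, b) in spans.items()]
    freqs = {}
    if external_callsets:
        freqs = annotate_frequency(call, external_callsets, freq_params)
    return InterpretedEvent(event=ev, copy_number=cn, zygosity=zygosity,
                            hgvs=names, genes=genes, frequencies=freqs)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 external_callsets: dict | None = None) -> PipelineResult:
    """Execute the full surveillance workflow on one cohort."""
    cohort = _load_cohort(config)
    total_cells = cohort.total_cells
    funnel = {"candidates": 0, "after_triple_consensus": 0,
              "after_cross_algorithm": 0, "after_inspection": 0}
    all_events: list[InterpretedEvent] = []
    qc_summaries: dict[str, dict] = {}
    n_solitary_cells = 0
    n_poor_cells = 0

    consensus_params = ConsensusParams(
        n_sets=config.consensus.n_sets, set_size=config.consensus.set_size,
        match_keys=config.consensus.match_keys,
        min_other_algorithms=config.consensus.min_other_algorithms,
        inspection=config.consensus.inspection, seed=config.seed)

    for version in sorted(cohort.counts):
        counts = cohort.counts[version]
        panel = counts.panel
        n_exons = len(panel)
        metas = [m for m in cohort.metadata if m.panel_version == version]
        qc_report = build_qc_report(counts, config.qc)
        n_poor_cells += qc_report.n_poor_cells
        normalized = normalize_coverage(counts)
        tx_models = transcript_models(panel)
        qc_summaries[version] = {
            "n_exons": n_exons,
            "n_samples": len(counts.sample_ids),
            "mean_depth": float(qc_report.mean_depth.mean()),
            "poor_exons": qc_report.poor_exons,
            "pct_cells_sufficient": float(100.0 * (~qc_report.insufficient).mean()),
        }
        ref_cvs: list[float] = []

        for meta in metas:
            sid = meta.sample_id
            test = counts.column(sid)
            try:
                triple = partition_reference_sets(metas, sid, consensus_params)
            except ConsensusError as exc:
                raise ConsensusError(f"stage reference-sets, sample {sid}: {exc}") from exc

            calls_per_set = []
            solitary = False
            for group in triple.sets:
                pool = counts.subset(list(group))
                chosen, agg, sol = select_reference(test, pool, config.caller,
                                                    test_id=sid)
                solitary |= sol
                phi = fit_dispersion(test, agg)
                calls_per_set.append(call_bb_hmm(
                    test, agg, panel, config.caller, phi=phi, sample_id=sid))
                idx = [counts.sample_ids.index(s) for s in chosen]
                if len(idx) >= 2:
                    cv = normalize_and_cv(normalized, idx)
                    ref_cvs.append(cv)
            if solitary:
                n_solitary_cells += n_exons

            matched_ids = [m.sample_id for m in metas if m.sample_id != sid
                           and all(getattr(m, k) == getattr(meta, k)
                                   for k in consensus_params.match_keys)]
            other = {"zscore": call_zscore(test, counts.subset(matched_ids), panel,
                                           config.caller, sample_id=sid, test_id=sid)}
            events, sample_funnel = run_filters(
                calls_per_set, other, panel, normalized, counts.sample_ids,
                triple, consensus_params)
            for k in funnel:
                funnel[k] += sample_funnel[k]
            log.info("sample %s funnel: %s", sid, sample_funnel)
            for ev in events:
                all_events.append(_interpret_event(
                    ev, panel, tx_models, external_callsets, config.frequency))

        qc_summaries[version]["mean_reference_cv_pct"] = (
            float(np.mean(ref_cvs)) if ref_cvs else float("nan"))

    qc_total = build_accounting(n_solitary_cells, n_poor_cells, total_cells)

    sensitivity, matches = _score_against_truth(cohort, all_events)
    result = PipelineResult(
        events=all_events, funnel=funnel, accounting=qc_total,
        qc_summaries=qc_summaries, sensitivity=sensitivity,
        truth_matches=matches, config_hash=config.hash(), seed=config.seed)
    if outdir is not None:
        _write_outputs(result, cohort, Path(outdir))
    return result


def normalize_and_cv(normalized: np.ndarray, idx: list[int]) -> float:
    """Mean per-exon intersample CV (%) over one selected reference set."""
    sub = normalized[:, idx]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    return float(np.nanmean(cv))


def build_accounting(n_solitary: int, n_poor: int, total_cells: int) -> dict[str, int]:
    from .qc import QCReport
    qc = QCReport(mean_depth=np.zeros(0), median_depth=np.zeros(0),
                  insufficient=np.zeros((0, 0), bool), poor_exons=[],
                  n_solitary_cells=n_solitary, n_poor_cells=n_poor)
    return exclusion_accounting(qc, total_cells)


def _score_against_truth(cohort: Cohort, events: list[InterpretedEvent]
                         ) -> tuple[float | None, list[tuple]]:
    if len(cohort.truth) == 0:
        return None, []
    matches = []
    hits = 0
    for t in cohort.truth.events:
        found = None
        for ie in events:
            c = ie.event.call
            if (c.sample_id == t.sample_id and c.type == t.type
                    and c.exon_start < t.exon_end and t.exon_start < c.exon_end):
                found = ie
                break
        if found is not None:
            hits += 1
        matches.append((t, found))
    return hits / len(cohort.truth), matches


def _write_outputs(result: PipelineResult, cohort: Cohort, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.config_hash, "seed": result.seed}
    pio.write_calls([ie.event.call for ie in result.events],
                    outdir / "events.tsv", format="tsv")
    pio.write_calls([ie.event.call for ie in result.events],
                    outdir / "events.vcf", format="vcf")
    with open(outdir / "funnel.json", "w") as fh:
        json.dump({**stamp, "funnel": result.funnel,
                   "accounting": result.accounting}, fh, indent=2, sort_keys=True)
    with open(outdir / "qc_summary.json", "w") as fh:
        json.dump({**stamp, "panels": result.qc_summaries,
                   **({"sensitivity_vs_truth": result.sensitivity}
                      if result.sensitivity is not None else {})},
                  fh, indent=2, sort_keys=True)
    with open(outdir / "interpretation.tsv", "w") as fh:
        fh.write("sample_id\tgenes\ttype\tcopy_number\tzygosity\tratio\t"
                 "confidence\thgvs\tfrequencies\n")
        for ie in result.events:
            c = ie.event.call
            fh.write("\t".join([
                c.sample_id, ",".join(ie.genes), c.type, str(ie.copy_number),
                ie.zygosity, f"{c.ratio:.3f}", f"{c.confidence:.2f}",
                "; ".join(ie.hgvs),
                ",".join(f"{k}={v}" for k, v in sorted(ie.frequencies.items())),
            ]) + "\n")
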