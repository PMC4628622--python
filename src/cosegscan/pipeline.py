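"""End-to-end orchestration: config loading, stage trace, pipeline runs and
the causal-variant recovery experiment.

Stage order is fixed: ingest, merge of adjacent substitutions, read-support
filter, shared-candidate scan, cohort-database filter, population-MAF
filter, brain-expression filter, consequence filter, validation override,
co-segregation test.  The annotation filters are set intersections, so
order affects only which stage a removal is attributed to in the trace.

Reports are deterministic: re-running with the same config and inputs
produces byte-identical output files (timestamps appear in logs only).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping

import numpy as np
import yaml

from . import annotation_filters as af
from .annotation_filters import FilterConfig, FilterResult
from .candidate_scan import (
    ScanConfig,
    merge_adjacent_substitutions,
    shared_candidates,
    support_filter,
)
from .pedigree_io import Pedigree, parse_ped
from .segregation import (
    InheritanceModel,
    PASS_COSEGREGATING,
    SegregationVerdict,
    apply_validation,
    cosegregation_test,
    read_validation_table,
)
from .synthetic_data import (
    SimulatedDataset,
    SimulationConfig,
    simulate_dataset,
    true_genotype,
)
from .variant_io import (
    GenotypeTable,
    HET,
    HOM_ALT,
    VariantKey,
    annotate_table,
    key_to_str,
    str_to_key,
    read_annotation_table,
    read_gene_whitelist,
    read_variant_calls,
    write_outputs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "FilterTrace",
    "StageEntry",
    "PipelineResult",
    "RecoverySummary",
    "load_config",
    "run_stages",
    "run_pipeline",
    "recovery_experiment",
]

STAGES = (
    "ingest",
    "merge_mnv",
    "support_filter",
    "shared_scan",
    "cohort_db",
    "population_maf",
    "expression",
    "consequence",
    "validation",
    "cosegregation",
)


class ConfigError(ValueError):
    pass


@dataclass
class StageEntry:
    """One trace row.  ``removed`` holds count-reducing eliminations;
    ``relabeled`` holds reason codes that do not change the variant count
    (e.g. the leading constituent of a merged substitution, which the merge
    product replaces)."""

    name: str
    n_in: int
    n_out: int
    removed: dict[VariantKey, str] = field(default_factory=dict)
    relabeled: dict[VariantKey, str] = field(default_factory=dict)
    notes: dict[str, Any] = field(default_factory=dict)

    def reason_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for reason in self.removed.values():
            base = reason.split(":", 1)[0]
            tally[base] = tally.get(base, 0) + 1
        return tally


class FilterTrace:
    """Ordered stage entries with reconciliation invariants enforced.

    ``out_count`` of each stage must equal ``in_count`` of the next, and the
    removal tally must equal ``in_count - out_count``.
    """

    def __init__(self, metadata: Mapping[str, Any] | None = None) -> None:
        self.stages: list[StageEntry] = []
        self.metadata: dict[str, Any] = dict(metadata or {})
        self._pass_keys: set[VariantKey] = set()

    def add(self, entry: StageEntry) -> None:
        if self.stages and entry.n_in != self.stages[-1].n_out:
            raise AssertionError(
                f"trace mismatch: stage {entry.name} in_count {entry.n_in} != "
                f"previous out_count {self.stages[-1].n_out}"
            )
        if entry.n_in - entry.n_out != len(entry.removed):
            raise AssertionError(
                f"trace mismatch in stage {entry.name}: "
                f"{entry.n_in} - {entry.n_out} != {len(entry.removed)} removals"
            )
        self.stages.append(entry)

    def set_pass_keys(self, keys: Iterable[VariantKey]) -> None:
        self._pass_keys = set(keys)

    def final_reasons(self) -> dict[VariantKey, str]:
        """Terminal reason per variant ever seen by the pipeline."""
        reasons: dict[VariantKey, str] = {}
        for entry in self.stages:
            reasons.update(entry.relabeled)
            reasons.update(entry.removed)
        for key in self._pass_keys:
            reasons[key] = PASS_COSEGREGATING
        return reasons

    def counts(self) -> list[tuple[str, int, int]]:
        return [(e.name, e.n_in, e.n_out) for e in self.stages]


@dataclass
class PipelineResult:
    trace: FilterTrace
    verdicts: dict[VariantKey, SegregationVerdict]
    pass_keys: set[VariantKey]
    table: GenotypeTable


# ---------------------------------------------------------------------------
# Config handling

_TOP_KEYS = {
    "name", "pedigree", "vcf", "vcfs", "samples", "annotations", "whitelist",
    "validation", "out_dir", "stages", "scan", "filters", "model", "seed",
}
_SCAN_KEYS = {
    "min_alt_reads", "carrier_genotypes", "allow_hom_alt_carrier",
    "exception_ids", "allow_missing_in_exceptions", "support_scope",
}
_FILTER_KEYS = {
    "maf_threshold", "require_absent_from_cohort_db", "cohort_db_size",
    "cohort_db_max_frequency", "keep_consequences", "require_brain_expression",
}
_MODEL_KEYS = {"mode", "max_unaffected_carriers", "carrier_genotypes", "exception_ids"}


@dataclass
class PipelineConfig:
    pedigree: Path
    vcfs: list[Path]
    annotations: Path
    out_dir: Path
    samples: list[str] | None = None
    whitelist: Path | None = None
    validation: Path | None = None
    stages: list[str] | None = None
    scan: ScanConfig = ScanConfig()
    filters: FilterConfig = FilterConfig()
    model: InheritanceModel = InheritanceModel()
    seed: int | None = None
    name: str = ""
    source_text: str = ""

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:16]


def _check_keys(section: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown {where} key(s): {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a pipeline YAML config.

    Relative paths resolve against the config file's directory.  Any unknown
    key (including unknown stage names) raises :class:`ConfigError` before
    any computation happens.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _check_keys(data, _TOP_KEYS, "config")
    base = path.parent

    def resolve(p: str) -> Path:
        candidate = Path(p)
        return candidate if candidate.is_absolute() else base / candidate

    for required in ("pedigree", "annotations", "out_dir"):
        if required not in data:
            raise ConfigError(f"{path}: missing required key {required!r}")
    if ("vcf" in data) == ("vcfs" in data):
        raise ConfigError(f"{path}: exactly one of 'vcf' or 'vcfs' is required")
    vcfs = [resolve(data["vcf"])] if "vcf" in data else [resolve(p) for p in data["vcfs"]]

    stages = data.get("stages")
    if stages is not None:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"{path}: unknown stage name(s): {sorted(unknown)}")

    scan_section = data.get("scan") or {}
    _check_keys(scan_section, _SCAN_KEYS, "scan")
    if "carrier_genotypes" in scan_section:
        scan_section["carrier_genotypes"] = frozenset(scan_section["carrier_genotypes"])
    if "exception_ids" in scan_section:
        scan_section["exception_ids"] = frozenset(scan_section["exception_ids"])
    filter_section = data.get("filters") or {}
    _check_keys(filter_section, _FILTER_KEYS, "filters")
    if "keep_consequences" in filter_section:
        filter_section["keep_consequences"] = frozenset(filter_section["keep_consequences"])
    model_section = data.get("model") or {}
    _check_keys(model_section, _MODEL_KEYS, "model")
    if "carrier_genotypes" in model_section:
        model_section["carrier_genotypes"] = frozenset(model_section["carrier_genotypes"])
    if "exception_ids" in model_section:
        model_section["exception_ids"] = frozenset(model_section["exception_ids"])

    try:
        scan = ScanConfig(**scan_section)
        filters = FilterConfig(**filter_section)
        model = InheritanceModel(**model_section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    return PipelineConfig(
        pedigree=resolve(data["pedigree"]),
        vcfs=vcfs,
        annotations=resolve(data["annotations"]),
        out_dir=resolve(str(data["out_dir"])),
        samples=list(data["samples"]) if "samples" in data else None,
        whitelist=resolve(data["whitelist"]) if "whitelist" in data else None,
        validation=resolve(data["validation"]) if "validation" in data else None,
        stages=list(stages) if stages is not None else None,
        scan=scan,
        filters=filters,
        model=model,
        seed=data.get("seed"),
        name=str(data.get("name", "")),
        source_text=text,
    )


# ---------------------------------------------------------------------------
# Stage execution


def _filter_stage(
    trace: FilterTrace,
    name: str,
    candidates: set[VariantKey],
    result: FilterResult,
) -> set[VariantKey]:
    trace.add(
        StageEntry(
            name=name,
            n_in=len(candidates),
            n_out=len(result.kept),
            removed=dict(result.reasons),
            notes={"notes": dict(result.notes)} if result.notes else {},
        )
    )
    return result.kept


def run_stages(
    ped: Pedigree,
    table: GenotypeTable,
    annotations: Mapping[VariantKey, Mapping[str, Any]],
    scan: ScanConfig,
    filters: FilterConfig,
    model: InheritanceModel,
    whitelist: set[str] | None = None,
    validation_rows: Iterable[tuple[VariantKey, str, str]] | None = None,
    validation_provider: Callable[[set[VariantKey]], list[tuple[VariantKey, str, str]]] | None = None,
    stages: Iterable[str] | None = None,
    metadata: Mapping[str, Any] | None = None,
) -> PipelineResult:
    """Run the fixed stage cascade over in-memory inputs.

    ``whitelist``, when given, overrides per-variant ``brain_expressed``
    flags by gene membership.  ``validation_provider`` may supply validation
    rows lazily once the surviving candidate set is known (used by the
    recovery experiment); otherwise ``validation_rows`` is used directly.
    ``stages`` may disable optional stages; order is always the canonical
    one.
    """
    enabled = set(STAGES if stages is None else stages)
    trace = FilterTrace(metadata=metadata)

    annotate_table(table, annotations)
    if whitelist is not None:
        for record in table.variants:
            if record.gene is not None:
                record.brain_expressed = record.gene in whitelist

    trace.add(StageEntry("ingest", len(table.variants), len(table.variants)))

    if "merge_mnv" in enabled:
        merged = merge_adjacent_substitutions(table)
        removed: dict[VariantKey, str] = {}
        relabeled: dict[VariantKey, str] = {}
        for m in merged.variants:
            constituents = m.scores.get("merged_from")
            if not constituents:
                continue
            reason = f"MERGED_INTO:{key_to_str(m.key)}"
            keys = [str_to_key(s) for s in constituents]
            relabeled[keys[0]] = reason  # replaced in place by the product
            for k in keys[1:]:
                removed[k] = reason
        trace.add(
            StageEntry(
                "merge_mnv",
                len(table.variants),
                len(merged.variants),
                removed=removed,
                relabeled=relabeled,
            )
        )
        table = merged

    if "support_filter" in enabled:
        table, downgraded = support_filter(table, scan)
        trace.add(
            StageEntry(
                "support_filter",
                len(table.variants),
                len(table.variants),
                notes={"downgraded_calls": downgraded},
            )
        )

    candidates, scan_reasons = shared_candidates(table, ped, scan)
    trace.add(
        StageEntry("shared_scan", len(table.variants), len(candidates), removed=scan_reasons)
    )

    record_map = {v.key: v for v in table.variants}
    if "cohort_db" in enabled:
        candidates = _filter_stage(
            trace, "cohort_db", candidates, af.filter_cohort_db(candidates, record_map, filters)
        )
    if "population_maf" in enabled:
        candidates = _filter_stage(
            trace, "population_maf", candidates,
            af.filter_population_maf(candidates, record_map, filters),
        )
    if "expression" in enabled:
        candidates = _filter_stage(
            trace, "expression", candidates,
            af.filter_expression(candidates, record_map, filters),
        )
    if "consequence" in enabled:
        candidates = _filter_stage(
            trace, "consequence", candidates,
            af.filter_consequence(candidates, record_map, filters),
        )

    if "validation" in enabled:
        rows = (
            validation_provider(candidates)
            if validation_provider is not None
            else list(validation_rows or [])
        )
        table = apply_validation(table, rows, ped=ped)
        trace.add(StageEntry("validation", len(candidates), len(candidates)))

    verdicts: dict[VariantKey, SegregationVerdict] = {}
    pass_keys: set[VariantKey] = set()
    failed: dict[VariantKey, str] = {}
    for key in sorted(candidates):
        verdict = cosegregation_test(key, ped, table, model)
        verdicts[key] = verdict
        if verdict.status == PASS_COSEGREGATING:
            pass_keys.add(key)
        else:
            failed[key] = verdict.status
    trace.add(
        StageEntry("cosegregation", len(candidates), len(pass_keys), removed=failed)
    )
    trace.set_pass_keys(pass_keys)

    for name, n_in, n_out in trace.counts():
        logger.info("stage %-14s %6d -> %6d", name, n_in, n_out)
    return PipelineResult(trace=trace, verdicts=verdicts, pass_keys=pass_keys, table=table)


def run_pipeline(config_path: str | Path) -> PipelineResult:
    """Load a config, run the cascade over its inputs and write outputs."""
    cfg = load_config(config_path)
    for p in [cfg.pedigree, cfg.annotations, *cfg.vcfs] + (
        [cfg.whitelist] if cfg.whitelist else []
    ) + ([cfg.validation] if cfg.validation else []):
        if not Path(p).exists():
            raise ConfigError(f"missing input file: {p}")

    ped = parse_ped(cfg.pedigree)
    table = read_variant_calls(cfg.vcfs, sample_ids=cfg.samples)
    ped = ped.mark_sequenced([s for s in table.samples if s in ped])
    annotations = read_annotation_table(cfg.annotations)
    whitelist = read_gene_whitelist(cfg.whitelist) if cfg.whitelist else None
    validation_rows = (
        read_validation_table(cfg.validation) if cfg.validation else None
    )

    result = run_stages(
        ped,
        table,
        annotations,
        scan=cfg.scan,
        filters=cfg.filters,
        model=cfg.model,
        whitelist=whitelist,
        validation_rows=validation_rows,
        stages=cfg.stages,
        metadata={"config_hash": cfg.config_hash, "seed": cfg.seed},
    )
    write_outputs(result.table, result.trace, cfg.out_dir)
    return result


# ---------------------------------------------------------------------------
# Recovery experiment


@dataclass
class RecoverySummary:
    n_reps: int
    recovery_rate: float
    pass_set_sizes: list[int]
    causal_status_counts: dict[str, int]

    def size_quantiles(self) -> dict[str, float]:
        sizes = np.asarray(self.pass_set_sizes, dtype=float)
        return {
            "min": float(sizes.min()),
            "q25": float(np.quantile(sizes, 0.25)),
            "median": float(np.quantile(sizes, 0.5)),
            "q75": float(np.quantile(sizes, 0.75)),
            "max": float(sizes.max()),
        }


def _truth_validation_provider(dataset: SimulatedDataset):
    index = {key: i for i, key in enumerate(dataset.background.keys)}

    def provider(candidates: set[VariantKey]) -> list[tuple[VariantKey, str, str]]:
        rows: list[tuple[VariantKey, str, str]] = []
        for key in sorted(candidates):
            for ind in dataset.ped:
                if key == dataset.causal_key:
                    dose = dataset.causal_dosages[ind.id]
                elif key in index:
                    dose = int(dataset.background.dosages[ind.id][index[key]])
                else:
                    continue
                rows.append((key, ind.id, true_genotype(dose)))
        return rows

    return provider


def recovery_experiment(
    sim_cfg: SimulationConfig,
    n_reps: int,
    scan: ScanConfig | None = None,
    filters: FilterConfig | None = None,
    model: InheritanceModel | None = None,
) -> RecoverySummary:
    """Simulate -> run the cascade ``n_reps`` times; report how often the
    implanted causal variant lands in the PASS set, and PASS-set sizes.

    Per-replicate seeds derive from ``numpy.random.SeedSequence(seed).spawn``
    so the experiment is reproducible from the single master seed.  The
    validation stage re-types every surviving candidate with truth genotypes
    across the whole pedigree (error-free orthogonal validation).
    Replicates in which no affected individual was sequenced cannot be
    scanned and count as non-recoveries.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    scan = scan or ScanConfig()
    filters = filters or FilterConfig()
    model = model or InheritanceModel()
    children = np.random.SeedSequence(sim_cfg.seed).spawn(n_reps)

    recovered = 0
    sizes: list[int] = []
    status_counts: dict[str, int] = {}
    for child in children:
        rng = np.random.default_rng(child)
        dataset = simulate_dataset(sim_cfg, rng=rng)
        try:
            result = run_stages(
                dataset.ped,
                dataset.table,
                dataset.annotations,
                scan=scan,
                filters=filters,
                model=model,
                whitelist=dataset.whitelist,
                validation_provider=_truth_validation_provider(dataset),
            )
        except Exception as exc:  # noqa: BLE001 - degenerate replicates recorded, not fatal
            sizes.append(0)
            status_counts["SCAN_UNDEFINED"] = status_counts.get("SCAN_UNDEFINED", 0) + 1
            logger.warning("replicate failed: %s", exc)
            continue
        sizes.append(len(result.pass_keys))
        if dataset.causal_key in result.pass_keys:
            recovered += 1
        verdict = result.verdicts.get(dataset.causal_key)
        status = verdict.status if verdict is not None else (
            result.trace.final_reasons().get(dataset.causal_key, "NOT_A_CANDIDATE")
        )
        base = status.split(":", 1)[0]
        status_counts[base] = status_counts.get(base, 0) + 1
    return RecoverySummary(
        n_reps=n_reps,
        recovery_rate=recovered / n_reps,
        pass_set_sizes=sizes,
        causal_status_counts=status_counts,
    )
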