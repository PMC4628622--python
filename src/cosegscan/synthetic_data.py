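"""Generators for pedigrees, genotypes and annotations with the statistical
structure the co-segregation analysis assumes, plus the packaged
worked-example fixture.

The generative model: a heterozygous causal variant is dropped from a
founder through the pedigree under Mendelian rules; carriers are affected
with probability ``penetrance`` and non-carriers with probability
``phenocopy_rate`` (the background population prevalence).  Background
variation is simulated per site from a minor-allele-frequency spectrum with
founder genotypes in Hardy-Weinberg proportions, so every individual's
marginal per-site genotype distribution is identical regardless of pedigree
depth.  Per-sample call-count dispersion (the platform-level spread around
the mean) is modelled as sample-specific dropout of background calls and
can be disabled for strictly Mendelian tables.

All randomness flows through a single :class:`numpy.random.Generator`;
identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .pedigree_io import Individual, Pedigree, write_ped
from .variant_io import (
    GenotypeCall,
    GenotypeTable,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    NON_REF,
    VariantKey,
    VariantRecord,
    key_to_str,
    write_vcf,
)

__all__ = [
    "MafSpectrum",
    "PedigreeSpec",
    "SimulationConfig",
    "BackgroundData",
    "SimulatedDataset",
    "Fig1aFixture",
    "make_pedigree",
    "gene_drop",
    "assign_phenotypes",
    "apply_phenotypes",
    "select_sequenced",
    "simulate_background",
    "inject_errors",
    "simulate_dataset",
    "check_mendelian",
    "make_fig1a_fixture",
    "write_fig1a_fixture",
    "write_dataset",
    "make_results_gene_panel",
    "make_candidate_panel16",
]


@dataclass(frozen=True)
class MafSpectrum:
    """Mixture of a rare and a common uniform MAF class."""

    rare_fraction: float = 0.5
    rare_range: tuple[float, float] = (0.0005, 0.01)
    common_range: tuple[float, float] = (0.05, 0.5)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rare = rng.random(n) < self.rare_fraction
        lo_r, hi_r = self.rare_range
        lo_c, hi_c = self.common_range
        maf = rng.uniform(lo_c, hi_c, size=n)
        maf[rare] = rng.uniform(lo_r, hi_r, size=int(rare.sum()))
        return maf

    def mean_nonref_prob(self) -> float:
        """E[1 - (1-p)^2] = E[2p - p^2] for the uniform mixture (closed form)."""

        def moment(lo: float, hi: float) -> float:
            mean = (lo + hi) / 2
            second = (hi**3 - lo**3) / (3 * (hi - lo))
            return 2 * mean - second

        return self.rare_fraction * moment(*self.rare_range) + (
            1 - self.rare_fraction
        ) * moment(*self.common_range)


@dataclass(frozen=True)
class PedigreeSpec:
    generations: int = 4
    children_per_couple: int = 3


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    pedigree_spec: PedigreeSpec = PedigreeSpec()
    causal_founder_id: str = "G1:1"
    penetrance: float = 1.0
    phenocopy_rate: float = 0.075
    n_background_mean: int = 50556
    n_background_sd: int = 6524
    background_maf_distribution: MafSpectrum = MafSpectrum()
    cohort_db_overlap: float = 0.95
    fp_call_rate: float = 0.0
    fn_call_rate: float = 0.0
    validation_error_free: bool = True
    n_sequenced_affected: int = 7
    n_sequenced_unaffected: int = 3
    sample_count_dispersion: bool = True
    nonsynonymous_rate: float = 0.5
    brain_expressed_rate: float = 0.5
    causal_gene: str = "GENE_CAUSAL"
    causal_key: VariantKey = ("cX", 500000, "G", "T")
    causal_pop_maf: float = 0.0001
    n_contigs: int = 4

    def __post_init__(self) -> None:
        for name in (
            "penetrance",
            "phenocopy_rate",
            "cohort_db_overlap",
            "fp_call_rate",
            "fn_call_rate",
            "nonsynonymous_rate",
            "brain_expressed_rate",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_background_mean <= 0:
            raise ValueError("n_background_mean must be positive")
        if self.n_background_sd < 0:
            raise ValueError("n_background_sd must be non-negative")


# ---------------------------------------------------------------------------
# Pedigree construction and transmission


def make_pedigree(spec: PedigreeSpec, name: str = "SIM") -> Pedigree:
    """Deterministic multi-generation pedigree.

    Generation 1 is a founding couple ``G1:1`` x ``G1:2``; every blood-line
    child below the last generation marries a married-in founder (id suffixed
    ``S``).  Phenotypes start as untested and are assigned later.
    """
    if spec.generations < 1 or spec.children_per_couple < 1:
        raise ValueError("pedigree spec must have >= 1 generation and child per couple")
    members: list[Individual] = [
        Individual(id="G1:1", sex="male"),
        Individual(id="G1:2", sex="female"),
    ]
    couples: list[tuple[str, str]] = [("G1:1", "G1:2")]
    for gen in range(2, spec.generations + 1):
        next_couples: list[tuple[str, str]] = []
        counter = 0
        for father, mother in couples:
            for _ in range(spec.children_per_couple):
                counter += 1
                child_id = f"G{gen}:{counter}"
                sex = "male" if counter % 2 == 1 else "female"
                members.append(
                    Individual(id=child_id, father_id=father, mother_id=mother, sex=sex)
                )
                if gen < spec.generations:
                    spouse_id = f"G{gen}:S{counter}"
                    spouse_sex = "female" if sex == "male" else "male"
                    members.append(Individual(id=spouse_id, sex=spouse_sex))
                    couple = (
                        (child_id, spouse_id) if sex == "male" else (spouse_id, child_id)
                    )
                    next_couples.append(couple)
        couples = next_couples
    return Pedigree(members, name=name)


def _topological_order(ped: Pedigree) -> list[Individual]:
    order: list[Individual] = []
    placed: set[str] = set()
    pending = list(ped)
    while pending:
        progressed = False
        remaining = []
        for ind in pending:
            parents_ready = all(
                p in placed for p in (ind.father_id, ind.mother_id) if p is not None
            )
            if parents_ready:
                order.append(ind)
                placed.add(ind.id)
                progressed = True
            else:
                remaining.append(ind)
        if not progressed:  # cannot happen: Pedigree construction bars cycles
            raise RuntimeError("pedigree is not topologically orderable")
        pending = remaining
    return order


def gene_drop(
    ped: Pedigree,
    causal_founder_id: str,
    rng: np.random.Generator,
    extra_carrier_ids: Iterable[str] = (),
) -> dict[str, int]:
    """Drop a heterozygous founder allele through the pedigree.

    Returns causal-allele dosage (0/1/2) per individual.  Each child
    inherits the allele from a carrier parent with probability dosage/2,
    independently per parent.  Founders other than the causal founder are
    hom_ref unless listed as explicitly configured married-in carriers.
    """
    founder = ped[causal_founder_id]
    if not founder.is_founder:
        raise ValueError(f"causal founder {causal_founder_id!r} has recorded parents")
    carriers = {causal_founder_id} | set(extra_carrier_ids)
    dosage: dict[str, int] = {}
    for ind in _topological_order(ped):
        if ind.is_founder:
            dosage[ind.id] = 1 if ind.id in carriers else 0
        else:
            d = 0
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and dosage[pid] > 0:
                    d += int(rng.random() < dosage[pid] / 2)
            dosage[ind.id] = d
    return dosage


def assign_phenotypes(
    dosages: Mapping[str, int], cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Affected/unaffected per individual: carriers with probability
    ``penetrance``, non-carriers with probability ``phenocopy_rate``."""
    phenotypes: dict[str, str] = {}
    for ind_id, dose in dosages.items():
        p = cfg.penetrance if dose > 0 else cfg.phenocopy_rate
        phenotypes[ind_id] = "affected" if rng.random() < p else "unaffected"
    return phenotypes


def apply_phenotypes(ped: Pedigree, phenotypes: Mapping[str, str]) -> Pedigree:
    return Pedigree(
        (replace(ind, phenotype=phenotypes.get(ind.id, ind.phenotype)) for ind in ped),
        name=ped.name,
    )


def select_sequenced(
    ped: Pedigree, cfg: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    """Pick the exome-sequenced subset: affected and unaffected members."""
    affected = sorted(i.id for i in ped if i.phenotype == "affected")
    unaffected = sorted(i.id for i in ped if i.phenotype == "unaffected")
    chosen: list[str] = []
    for pool, n in ((affected, cfg.n_sequenced_affected), (unaffected, cfg.n_sequenced_unaffected)):
        take = min(n, len(pool))
        if take:
            chosen.extend(str(s) for s in rng.choice(pool, size=take, replace=False))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Background variation


@dataclass
class BackgroundData:
    table: GenotypeTable
    annotations: dict[VariantKey, dict]
    manifest: dict
    dosages: dict[str, np.ndarray]
    keys: list[VariantKey]


def _background_keys(n: int, n_contigs: int) -> list[VariantKey]:
    # spacing of 10 guarantees no accidental adjacency between background sites
    return [
        (f"c{(i % n_contigs) + 1}", 1000 + (i // n_contigs) * 10, "A", "G")
        for i in range(n)
    ]


def simulate_background(
    ped: Pedigree,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sequenced_ids: Iterable[str] | None = None,
) -> BackgroundData:
    """Simulate background variants for the pedigree's sequenced samples.

    The number of sites is calibrated so expected per-sample non-reference
    counts match ``n_background_mean``; when ``sample_count_dispersion`` is
    on, per-sample targets are drawn from N(mean, sd) and realised by
    dropping randomly chosen background calls (platform-style dropout), and
    the site count is padded so targets are reachable.  The manifest records
    the exact realised per-sample counts.
    """
    sequenced = sorted(sequenced_ids) if sequenced_ids is not None else ped.sequenced_ids()
    spectrum = cfg.background_maf_distribution
    rate = spectrum.mean_nonref_prob()
    headroom = 2.5 * cfg.n_background_sd if cfg.sample_count_dispersion else 0
    n_sites = max(1, int(round((cfg.n_background_mean + headroom) / rate)))
    mafs = spectrum.draw(n_sites, rng)

    dosages: dict[str, np.ndarray] = {}
    for ind in _topological_order(ped):
        if ind.is_founder:
            dosages[ind.id] = rng.binomial(2, mafs).astype(np.int8)
        else:
            d = np.zeros(n_sites, dtype=np.int8)
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    d += (rng.random(n_sites) < dosages[pid] / 2).astype(np.int8)
            dosages[ind.id] = d

    keys = _background_keys(n_sites, cfg.n_contigs)
    consequence_draw = rng.random(n_sites)
    consequences = np.where(
        consequence_draw < cfg.nonsynonymous_rate,
        "non_synonymous",
        np.where(
            consequence_draw < cfg.nonsynonymous_rate + 0.9 * (1 - cfg.nonsynonymous_rate),
            "synonymous",
            "other",
        ),
    )
    in_db = rng.random(n_sites) < cfg.cohort_db_overlap
    brain = rng.random(n_sites) < cfg.brain_expressed_rate
    annotations = {
        keys[i]: {
            "gene": f"BG{i:06d}",
            "consequence": str(consequences[i]),
            "pop_maf": float(mafs[i]),
            "in_cohort_db": bool(in_db[i]),
            "brain_expressed": bool(brain[i]),
        }
        for i in range(n_sites)
    }

    table = GenotypeTable(samples=sequenced)
    for key in keys:
        table.add_variant(VariantRecord(chrom=key[0], pos=key[1], ref=key[2], alt=key[3]))
    counts: dict[str, int] = {}
    for sample in sequenced:
        nonref = np.flatnonzero(dosages[sample] > 0)
        if cfg.sample_count_dispersion:
            target = max(0, int(round(rng.normal(cfg.n_background_mean, cfg.n_background_sd))))
            if len(nonref) > target:
                dropped = rng.choice(nonref, size=len(nonref) - target, replace=False)
                keep_mask = np.ones(n_sites, dtype=bool)
                keep_mask[dropped] = False
                nonref = nonref[keep_mask[nonref]]
        depths = rng.poisson(45, size=len(nonref))
        for idx, depth in zip(nonref, depths):
            genotype = HET if dosages[sample][idx] == 1 else HOM_ALT
            table.set_call(
                keys[idx], sample, GenotypeCall(genotype=genotype, alt_reads=int(depth))
            )
        counts[sample] = len(nonref)

    manifest = {
        "n_sites": n_sites,
        "per_sample_counts": counts,
        "configured_mean": cfg.n_background_mean,
        "configured_sd": cfg.n_background_sd,
    }
    table.sort()
    return BackgroundData(
        table=table, annotations=annotations, manifest=manifest, dosages=dosages, keys=keys
    )


def check_mendelian(background: BackgroundData, ped: Pedigree) -> int:
    """Number of child non-reference alleles not explainable by a parent.

    Operates on the pristine transmitted dosage matrix (before per-sample
    dropout or error injection); zero for any simulation output.
    """
    violations = 0
    for ind in ped:
        if ind.is_founder:
            continue
        child = background.dosages[ind.id]
        parent_sum = np.zeros_like(child)
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                parent_sum += background.dosages[pid]
        violations += int(np.sum(child > parent_sum))
        # a hom_alt child needs both parents to carry
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                violations += int(np.sum((child == 2) & (background.dosages[pid] == 0)))
    return violations


# ---------------------------------------------------------------------------
# Error injection


def inject_errors(
    table: GenotypeTable, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[GenotypeTable, list[tuple[VariantKey, str, str]]]:
    """Apply genotyping-error processes to exome calls.

    False positives: implicit-hom_ref (absent) exome entries flip to het
    with simulated read support at rate ``fp_call_rate``.  False negatives:
    explicit non-reference exome calls drop to missing at rate
    ``fn_call_rate``.  Validation-source calls are untouched when
    ``validation_error_free``.  Returns the new table and a log of
    (variant, sample, kind) flips.
    """
    out = table.copy()
    flips: list[tuple[VariantKey, str, str]] = []
    if cfg.fp_call_rate == 0 and cfg.fn_call_rate == 0:
        return out, flips
    for record in table.variants:
        for sample in table.samples:
            call = table.get_call(record.key, sample)
            if call is None:
                if cfg.fp_call_rate and rng.random() < cfg.fp_call_rate:
                    out.set_call(
                        record.key,
                        sample,
                        GenotypeCall(genotype=HET, alt_reads=int(rng.integers(25, 80))),
                    )
                    flips.append((record.key, sample, "false_positive"))
                continue
            if call.source == "validation" and cfg.validation_error_free:
                continue
            if call.genotype in NON_REF and cfg.fn_call_rate and rng.random() < cfg.fn_call_rate:
                out.set_call(record.key, sample, GenotypeCall(genotype=MISSING, source=call.source))
                flips.append((record.key, sample, "false_negative"))
    return out, flips


# ---------------------------------------------------------------------------
# Full dataset assembly


@dataclass
class SimulatedDataset:
    ped: Pedigree
    table: GenotypeTable
    annotations: dict[VariantKey, dict]
    whitelist: set[str]
    validation_rows: list[tuple[VariantKey, str, str]]
    causal_key: VariantKey
    causal_dosages: dict[str, int]
    background: BackgroundData
    manifest: dict
    error_log: list[tuple[VariantKey, str, str]]


def true_genotype(dose: int) -> str:
    return (HOM_REF, HET, HOM_ALT)[dose]


def simulate_dataset(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate a complete analysable dataset from a simulation config.

    Pipeline-ready pieces: pedigree with phenotypes and the sequenced subset
    marked, a genotype table over sequenced samples containing background
    variation plus the implanted causal variant, annotations, a
    brain-expression whitelist, validation rows (truth genotypes for the
    causal variant across the whole pedigree), and a manifest with exact
    per-sample call counts for oracle checks.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    ped = make_pedigree(cfg.pedigree_spec)
    causal_dosages = gene_drop(ped, cfg.causal_founder_id, rng)
    phenotypes = assign_phenotypes(causal_dosages, cfg, rng)
    ped = apply_phenotypes(ped, phenotypes)
    sequenced = select_sequenced(ped, cfg, rng)
    ped = ped.mark_sequenced(sequenced)

    background = simulate_background(ped, cfg, rng, sequenced_ids=sequenced)
    table = background.table
    annotations = dict(background.annotations)

    chrom, pos, ref, alt = cfg.causal_key
    causal_record = VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt)
    table.add_variant(causal_record)
    for sample in sequenced:
        dose = causal_dosages[sample]
        if dose > 0:
            table.set_call(
                cfg.causal_key,
                sample,
                GenotypeCall(
                    genotype=true_genotype(dose), alt_reads=int(rng.integers(25, 90))
                ),
            )
    annotations[cfg.causal_key] = {
        "gene": cfg.causal_gene,
        "consequence": "non_synonymous",
        "pop_maf": cfg.causal_pop_maf,
        "in_cohort_db": False,
        "brain_expressed": True,
    }
    table.sort()

    table, error_log = inject_errors(table, cfg, rng)

    whitelist = {f["gene"] for f in annotations.values() if f.get("brain_expressed")}
    validation_rows = [
        (cfg.causal_key, ind.id, true_genotype(causal_dosages[ind.id])) for ind in ped
    ]
    manifest = {
        "seed": cfg.seed,
        "causal_key": key_to_str(cfg.causal_key),
        "causal_gene": cfg.causal_gene,
        "sequenced": sequenced,
        "n_affected_sequenced": sum(1 for s in sequenced if ped[s].phenotype == "affected"),
        "per_sample_counts": {
            s: background.manifest["per_sample_counts"][s]
            + (1 if causal_dosages[s] > 0 else 0)
            for s in sequenced
        },
        "background": background.manifest,
        "n_error_flips": len(error_log),
    }
    return SimulatedDataset(
        ped=ped,
        table=table,
        annotations=annotations,
        whitelist=whitelist,
        validation_rows=validation_rows,
        causal_key=cfg.causal_key,
        causal_dosages=causal_dosages,
        background=background,
        manifest=manifest,
        error_log=error_log,
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as PED, per-sample VCFs, annotation TSV,
    validation TSV, whitelist and JSON manifest (all deterministic text)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["pedigree"] = out_dir / "pedigree.ped"
    write_ped(dataset.ped, paths["pedigree"])

    vcf_paths = []
    for sample in dataset.table.samples:
        sub = GenotypeTable(samples=[sample])
        for record in dataset.table.variants:
            call = dataset.table.get_call(record.key, sample)
            if call is not None and call.genotype != HOM_REF:
                sub.add_variant(replace(record, scores=dict(record.scores)))
                sub.set_call(record.key, sample, call)
        vcf_path = out_dir / f"{sample.replace(':', '_')}.vcf"
        write_vcf(sub, vcf_path)
        vcf_paths.append(vcf_path)
    paths["vcfs"] = vcf_paths

    paths["annotations"] = out_dir / "annotations.tsv"
    _write_annotations(dataset.annotations, paths["annotations"])

    paths["validation"] = out_dir / "validation.tsv"
    _write_validation(dataset.validation_rows, paths["validation"])

    paths["whitelist"] = out_dir / "whitelist.txt"
    with open(paths["whitelist"], "w") as fh:
        fh.write("# brain-expressed gene whitelist\n")
        for gene in sorted(dataset.whitelist):
            fh.write(gene + "\n")

    paths["manifest"] = out_dir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(dataset.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    config = "\n".join(
        [
            "pedigree: pedigree.ped",
            "vcfs:",
            *[f"  - {p.name}" for p in vcf_paths],
            "samples:",
            *[f"  - '{s}'" for s in dataset.table.samples],
            "annotations: annotations.tsv",
            "whitelist: whitelist.txt",
            "validation: validation.tsv",
            "out_dir: out",
            "scan: {min_alt_reads: 20}",
            "model: {max_unaffected_carriers: 0}",
            "filters: {}",
            "",
        ]
    )
    paths["config"] = out_dir / "config.yaml"
    paths["config"].write_text(config)
    return paths


def _write_annotations(annotations: Mapping[VariantKey, Mapping], path: Path) -> None:
    score_cols: list[str] = []
    for fields in annotations.values():
        for name in fields.get("scores", {}):
            if name not in score_cols:
                score_cols.append(name)
    with open(path, "w") as fh:
        header = ["chrom", "pos", "ref", "alt", "gene", "consequence", "pop_maf",
                  "in_cohort_db", "brain_expressed"] + score_cols
        fh.write("\t".join(header) + "\n")
        for key in sorted(annotations):
            fields = annotations[key]
            maf = fields.get("pop_maf")
            row = [
                key[0], str(key[1]), key[2], key[3],
                fields.get("gene") or ".",
                fields.get("consequence") or ".",
                "." if maf is None else f"{maf:.6g}",
                _bool_cell(fields.get("in_cohort_db")),
                _bool_cell(fields.get("brain_expressed")),
            ]
            scores = fields.get("scores", {})
            row += [str(scores.get(c, ".")) for c in score_cols]
            fh.write("\t".join(row) + "\n")


def _bool_cell(value: bool | None) -> str:
    if value is None:
        return "."
    return "true" if value else "false"


_VALIDATION_GT_TEXT = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def _write_validation(rows: Iterable[tuple[VariantKey, str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_key\tindividual_id\tgenotype\n")
        for key, ind_id, genotype in rows:
            fh.write(f"{key_to_str(key)}\t{ind_id}\t{_VALIDATION_GT_TEXT[genotype]}\n")


# ---------------------------------------------------------------------------
# The packaged worked-example fixture

AFFECTED_SEQUENCED = ("IV:1", "IV:5", "IV:7", "IV:9", "V:6", "V:7", "V:8")
UNAFFECTED_SEQUENCED = ("III:2", "IV:6", "IV:11")
SEQUENCED = AFFECTED_SEQUENCED + UNAFFECTED_SEQUENCED

# The eight candidate genes of the worked example with their consequence
# classes; five are non-synonymous and were taken to orthogonal validation.
RESULTS_GENES = (
    ("CEP63", "non_synonymous"),
    ("DNAJC11", "synonymous"),
    ("GET4", "non_synonymous"),
    ("INTS5", "non_synonymous"),
    ("PAQR9", "synonymous"),
    ("RNF152", "non_synonymous"),
    ("TNRC18", "synonymous"),
    ("ZNF507", "non_synonymous"),
)

CEP63_SNV1: VariantKey = ("3", 134264558, "G", "T")
CEP63_SNV2: VariantKey = ("3", 134264559, "A", "T")
CEP63_MERGED: VariantKey = ("3", 134264558, "GA", "TT")
GET4_KEY: VariantKey = ("7", 926000, "T", "G")
INTS5_KEY: VariantKey = ("11", 61600000, "C", "T")
RNF152_KEY: VariantKey = ("18", 59465000, "G", "A")
ZNF507_KEY: VariantKey = ("19", 32840000, "C", "G")


@dataclass
class Fig1aFixture:
    ped: Pedigree
    table: GenotypeTable
    annotations: dict[VariantKey, dict]
    validation_rows: list[tuple[VariantKey, str, str]]
    whitelist: set[str]
    causal_key: VariantKey
    exception_ids: frozenset[str]


def _fixture_pedigree() -> Pedigree:
    """The worked-example subtree: 10 sequenced members plus the relatives
    needed for transmission reasoning (an approximation of the full family).
    """
    rows = [
        Individual("I:1", sex="male"),
        Individual("I:2", sex="female"),
        Individual("II:1", "I:1", "I:2", sex="male", phenotype="affected"),
        Individual("II:2", sex="female"),
        Individual("III:2", "II:1", "II:2", sex="female", phenotype="unaffected"),
        Individual("III:4", "II:1", "II:2", sex="female", phenotype="uncertain"),
        Individual("III:7", "II:1", "II:2", sex="male", phenotype="affected"),
        Individual("III:3", sex="male", phenotype="unaffected"),  # married in
        Individual("III:8", sex="female"),  # married in
        Individual("IV:9", "III:3", "III:4", sex="male", phenotype="affected"),
        Individual("IV:11", "III:3", "III:4", sex="male", phenotype="unaffected"),
        Individual("IV:1", "III:7", "III:8", sex="female", phenotype="affected"),
        Individual("IV:5", "III:7", "III:8", sex="male", phenotype="affected"),
        Individual("IV:6", "III:7", "III:8", sex="female", phenotype="unaffected"),
        Individual("IV:7", "III:7", "III:8", sex="male", phenotype="affected"),
        Individual("IV:2", sex="male"),  # married in
        Individual("V:6", "IV:2", "IV:1", sex="male", phenotype="affected"),
        Individual("V:7", "IV:2", "IV:1", sex="female", phenotype="affected"),
        Individual("V:8", "IV:2", "IV:1", sex="male", phenotype="affected"),
    ]
    return Pedigree(rows, name="DDFAM").mark_sequenced(SEQUENCED)


_FIXTURE_ANNOTATIONS: dict[VariantKey, dict] = {
    CEP63_SNV1: {
        "gene": "CEP63", "consequence": "non_synonymous", "pop_maf": 0.0001,
        "in_cohort_db": False, "brain_expressed": True,
        "scores": {"gerp": "5.53", "polyphen2": "1", "sift": "0"},
    },
    CEP63_SNV2: {
        "gene": "CEP63", "consequence": "non_synonymous", "pop_maf": 0.0001,
        "in_cohort_db": False, "brain_expressed": True,
    },
    GET4_KEY: {
        "gene": "GET4", "consequence": "non_synonymous", "pop_maf": None,
        "in_cohort_db": False, "brain_expressed": True,
    },
    INTS5_KEY: {
        "gene": "INTS5", "consequence": "non_synonymous", "pop_maf": None,
        "in_cohort_db": False, "brain_expressed": True,
    },
    RNF152_KEY: {
        "gene": "RNF152", "consequence": "non_synonymous", "pop_maf": 0.001,
        "in_cohort_db": False, "brain_expressed": True,
    },
    ZNF507_KEY: {
        "gene": "ZNF507", "consequence": "non_synonymous", "pop_maf": 0.002,
        "in_cohort_db": False, "brain_expressed": True,
    },
}


def make_fig1a_fixture() -> Fig1aFixture:
    """Deterministic worked-example dataset.

    Exome calls make all five candidate variants pass the shared scan on the
    sequenced subset (the causal variant is represented as two adjacent SNVs
    so the merge step has work to do).  Validation genotypes then encode the
    four exclusion outcomes and the single co-segregating variant.
    """
    ped = _fixture_pedigree()
    table = GenotypeTable(samples=list(SEQUENCED))
    raw_keys = [CEP63_SNV1, CEP63_SNV2, GET4_KEY, INTS5_KEY, RNF152_KEY, ZNF507_KEY]
    for key in raw_keys:
        table.add_variant(VariantRecord(chrom=key[0], pos=key[1], ref=key[2], alt=key[3]))
    for vi, key in enumerate(raw_keys):
        for si, sample in enumerate(AFFECTED_SEQUENCED):
            table.set_call(
                key, sample, GenotypeCall(genotype=HET, alt_reads=22 + 3 * vi + 2 * si)
            )
    table.sort()

    validation_rows: list[tuple[VariantKey, str, str]] = []
    # the exome-only candidate proved monomorphic on re-sequencing
    for ind_id in SEQUENCED + ("III:4", "III:3"):
        validation_rows.append((GET4_KEY, ind_id, HOM_REF))
    # neither parent of the exception individual carries this one
    validation_rows.append((INTS5_KEY, "III:4", HOM_REF))
    validation_rows.append((INTS5_KEY, "III:3", HOM_REF))
    # unaffected carriers revealed by re-sequencing
    validation_rows.append((ZNF507_KEY, "III:2", HET))
    validation_rows.append((ZNF507_KEY, "IV:11", HET))
    validation_rows.append((RNF152_KEY, "IV:6", HET))
    # the co-segregating variant: carrier mother of the exception individual
    validation_rows.append((CEP63_MERGED, "III:4", HET))
    validation_rows.append((CEP63_MERGED, "III:3", HOM_REF))
    validation_rows.append((CEP63_MERGED, "II:1", HET))

    annotations = {k: dict(v) for k, v in _FIXTURE_ANNOTATIONS.items()}
    whitelist = {g for g, _ in RESULTS_GENES} | {"DECOY1", "DECOY2"}
    return Fig1aFixture(
        ped=ped,
        table=table,
        annotations=annotations,
        validation_rows=validation_rows,
        whitelist=whitelist,
        causal_key=CEP63_MERGED,
        exception_ids=frozenset({"IV:9"}),
    )


def write_fig1a_fixture(out_dir: str | Path) -> dict[str, Path]:
    """Write the worked-example fixture plus a ready-to-run pipeline config."""
    fixture = make_fig1a_fixture()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["pedigree"] = out_dir / "family.ped"
    write_ped(fixture.ped, paths["pedigree"])

    vcf_names = []
    for sample in fixture.table.samples:
        sub = GenotypeTable(samples=[sample])
        for record in fixture.table.variants:
            call = fixture.table.get_call(record.key, sample)
            if call is not None and call.genotype != HOM_REF:
                sub.add_variant(replace(record, scores=dict(record.scores)))
                sub.set_call(record.key, sample, call)
        name = f"{sample.replace(':', '_')}.vcf"
        write_vcf(sub, out_dir / name)
        vcf_names.append(name)

    paths["annotations"] = out_dir / "annotations.tsv"
    _write_annotations(fixture.annotations, paths["annotations"])
    paths["validation"] = out_dir / "validation.tsv"
    _write_validation(fixture.validation_rows, paths["validation"])
    paths["whitelist"] = out_dir / "whitelist.txt"
    with open(paths["whitelist"], "w") as fh:
        for gene in sorted(fixture.whitelist):
            fh.write(gene + "\n")

    config = "\n".join(
        [
            "pedigree: family.ped",
            "vcfs:",
            *[f"  - {name}" for name in vcf_names],
            "samples:",
            *[f"  - '{sample}'" for sample in fixture.table.samples],
            "annotations: annotations.tsv",
            "whitelist: whitelist.txt",
            "validation: validation.tsv",
            "out_dir: out",
            "scan:",
            "  min_alt_reads: 20",
            "  exception_ids: ['IV:9']",
            "model:",
            "  max_unaffected_carriers: 0",
            "  exception_ids: ['IV:9']",
            "filters: {}",
            "",
        ]
    )
    paths["config"] = out_dir / "config.yaml"
    paths["config"].write_text(config)
    return paths


def make_candidate_panel16() -> tuple[set[VariantKey], dict[VariantKey, dict]]:
    """Sixteen rare shared candidates: eight in the worked-example genes
    (brain-expressed) and eight in non-brain decoy genes, mirroring the
    post-rarity candidate list used in cascade tests."""
    candidates: set[VariantKey] = set()
    annotations: dict[VariantKey, dict] = {}
    for i, (gene, consequence) in enumerate(RESULTS_GENES):
        key: VariantKey = (f"p{i + 1}", 10000 + i, "A", "C")
        candidates.add(key)
        annotations[key] = {
            "gene": gene, "consequence": consequence, "pop_maf": 0.001,
            "in_cohort_db": False, "brain_expressed": True,
        }
    for i in range(8):
        key = (f"d{i + 1}", 20000 + i, "G", "T")
        candidates.add(key)
        consequence = "non_synonymous" if i % 2 == 0 else "synonymous"
        annotations[key] = {
            "gene": f"DECOYGENE{i}", "consequence": consequence, "pop_maf": 0.002,
            "in_cohort_db": False, "brain_expressed": False,
        }
    return candidates, annotations


def make_results_gene_panel() -> tuple[set[VariantKey], dict[VariantKey, dict]]:
    """The eight-gene candidate panel (post-expression step) for the
    consequence-filter worked example."""
    candidates, annotations = make_candidate_panel16()
    kept = {k for k in candidates if annotations[k]["brain_expressed"]}
    return kept, {k: annotations[k] for k in kept}
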