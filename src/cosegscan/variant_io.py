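"""Variant, genotype-call and genotype-table types plus VCF/TSV input-output.

Reading uses :mod:`pysam` (plain or bgzipped VCF 4.x); writing emits
deterministic uncompressed VCF 4.2 so that outputs are byte-identical for a
given input.  Variant identity is the tuple ``(chrom, pos, ref, alt)``;
``pos`` is the 1-based leftmost position.

No-call policy: a variant absent from a sequenced sample's per-sample VCF is
interpreted as homozygous reference for that sample (per-sample discovery
calling emits no reference blocks).  An explicit ``./.`` genotype is
``missing`` and imposes no constraint downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "CONSEQUENCES",
    "VariantKey",
    "VariantRecord",
    "GenotypeCall",
    "GenotypeTable",
    "VariantIOError",
    "AnnotationError",
    "key_to_str",
    "str_to_key",
    "read_variant_calls",
    "read_annotation_table",
    "annotate_table",
    "read_gene_whitelist",
    "write_vcf",
    "write_outputs",
]

# genotype states
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"
GENOTYPES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})
NON_REF = frozenset({HET, HOM_ALT})

CONSEQUENCES = frozenset({"non_synonymous", "synonymous", "other", "unknown"})

ALLELE_CHARS = frozenset("ACGTN")

VariantKey = tuple[str, int, str, str]


class VariantIOError(IOError):
    """Raised for unreadable or ill-formed variant input."""


class AnnotationError(ValueError):
    """Raised for malformed annotation tables."""


def key_to_str(key: VariantKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def str_to_key(text: str) -> VariantKey:
    parts = text.rsplit(":", 3)
    if len(parts) != 4:
        raise ValueError(f"malformed variant key {text!r} (want chrom:pos:ref:alt)")
    chrom, pos, ref, alt = parts
    return chrom, int(pos), ref, alt


@dataclass
class VariantRecord:
    """A biallelic variant with optional annotations.

    ``scores`` is an open pass-through mapping for external scores
    (conservation, deleteriousness, ...) that the pipeline never interprets.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    consequence: str | None = None
    pop_maf: float | None = None
    in_cohort_db: bool | None = None
    brain_expressed: bool | None = None
    scores: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele.upper()) - ALLELE_CHARS:
                raise ValueError(f"invalid allele {allele!r} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"invalid consequence {self.consequence!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class GenotypeCall:
    """One (variant, sample) call; ``source`` is ``exome`` or ``validation``."""

    genotype: str
    alt_reads: int | None = None
    source: str = "exome"

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"invalid genotype {self.genotype!r}")
        if self.source not in ("exome", "validation"):
            raise ValueError(f"invalid source {self.source!r}")
        if self.alt_reads is not None:
            if self.alt_reads < 0:
                raise ValueError("alt_reads must be non-negative")
            if self.genotype == MISSING or self.source != "exome":
                raise ValueError("alt_reads only valid for non-missing exome calls")


class GenotypeTable:
    """Ordered variants x samples with a sparse call mapping.

    Only explicit calls are stored.  Interpretation of absent entries
    (hom_ref for sequenced exome samples, untyped otherwise) is the business
    of the consuming stage, via :meth:`observed_genotype`.
    """

    def __init__(
        self,
        variants: Iterable[VariantRecord] = (),
        samples: Iterable[str] = (),
        calls: Mapping[tuple[VariantKey, str], GenotypeCall] | None = None,
    ) -> None:
        self.variants: list[VariantRecord] = []
        self._by_key: dict[VariantKey, VariantRecord] = {}
        self.samples: list[str] = []
        self.calls: dict[tuple[VariantKey, str], GenotypeCall] = {}
        for v in variants:
            self.add_variant(v)
        for s in samples:
            self.add_sample(s)
        if calls:
            for (key, sample), call in calls.items():
                self.set_call(key, sample, call)

    def add_variant(self, record: VariantRecord) -> None:
        if record.key in self._by_key:
            raise ValueError(f"duplicate variant {key_to_str(record.key)}")
        self.variants.append(record)
        self._by_key[record.key] = record

    def add_sample(self, sample_id: str) -> None:
        if sample_id not in self.samples:
            self.samples.append(sample_id)

    def has_variant(self, key: VariantKey) -> bool:
        return key in self._by_key

    def variant(self, key: VariantKey) -> VariantRecord:
        return self._by_key[key]

    def set_call(self, key: VariantKey, sample_id: str, call: GenotypeCall) -> None:
        if key not in self._by_key:
            raise KeyError(f"unknown variant {key_to_str(key)}")
        if sample_id not in self.samples:
            raise KeyError(f"unknown sample {sample_id!r}")
        self.calls[(key, sample_id)] = call

    def get_call(self, key: VariantKey, sample_id: str) -> GenotypeCall | None:
        return self.calls.get((key, sample_id))

    def observed_genotype(
        self, key: VariantKey, sample_id: str, sequenced: bool
    ) -> str | None:
        """Genotype of ``sample_id`` at ``key``, or None if untyped.

        Explicit ``missing`` calls return None (unconstrained); an absent
        call returns ``hom_ref`` when the individual is in the sequenced
        exome subset, None otherwise.
        """
        call = self.calls.get((key, sample_id))
        if call is not None:
            return None if call.genotype == MISSING else call.genotype
        if sequenced and sample_id in self.samples:
            return HOM_REF
        return None

    def copy(self) -> "GenotypeTable":
        out = GenotypeTable(samples=self.samples)
        for v in self.variants:
            out.add_variant(replace(v, scores=dict(v.scores)))
        out.calls = dict(self.calls)
        return out

    def sort(self) -> None:
        """Order variants by (chrom, pos, ref, alt); chroms lexicographically."""
        self.variants.sort(key=lambda v: v.key)

    def sample_nonref_count(self, sample_id: str) -> int:
        return sum(
            1
            for (key, sid), call in self.calls.items()
            if sid == sample_id and call.genotype in NON_REF
        )

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# VCF reading


def _gt_to_genotype(gt: tuple | None, alt_index: int) -> str:
    if gt is None or all(a is None for a in gt):
        return MISSING
    if any(a is None for a in gt):
        return MISSING
    n_alt = sum(1 for a in gt if a == alt_index)
    if n_alt == 0:
        return HOM_REF
    if n_alt == len(gt):
        return HOM_ALT
    return HET


def _alt_depth(sample: Any, alt_index: int) -> int | None:
    ad = sample.get("AD")
    if ad is None:
        return None
    try:
        value = ad[alt_index]
    except (IndexError, TypeError):
        return None
    return None if value is None else int(value)


def read_variant_calls(
    paths: Sequence[str | Path] | str | Path,
    sample_ids: Sequence[str] | None = None,
) -> GenotypeTable:
    """Read one multi-sample VCF or a list of per-sample VCFs.

    Multi-allelic records are split into biallelic :class:`VariantRecord`
    entries sharing chrom/pos/ref.  Alt read depth is taken from the AD
    format field when present.  With per-sample files, ``sample_ids`` pairs
    with ``paths`` positionally (defaulting to each file's sample name).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]

    table = GenotypeTable()
    if len(paths) == 1:
        _read_one_vcf(table, paths[0], wanted_samples=sample_ids)
        if sample_ids:
            missing = [s for s in sample_ids if s not in table.samples]
            if missing:
                raise VariantIOError(
                    f"{paths[0]}: samples not present in VCF: {missing}"
                )
    else:
        if sample_ids is not None and len(sample_ids) != len(paths):
            raise VariantIOError(
                f"got {len(paths)} VCFs but {len(sample_ids)} sample ids"
            )
        for i, path in enumerate(paths):
            rename = None if sample_ids is None else sample_ids[i]
            _read_one_vcf(table, path, rename_single=rename)
    table.sort()
    return table


def _read_one_vcf(
    table: GenotypeTable,
    path: Path,
    wanted_samples: Sequence[str] | None = None,
    rename_single: str | None = None,
) -> None:
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VariantIOError(f"cannot read VCF {path}: {exc}") from exc
    with vcf:
        file_samples = list(vcf.header.samples)
        if rename_single is not None:
            if len(file_samples) != 1:
                raise VariantIOError(
                    f"{path}: expected a single-sample VCF, found {len(file_samples)} samples"
                )
            name_map = {file_samples[0]: rename_single}
        else:
            name_map = {s: s for s in file_samples}
        use_samples = (
            [s for s in file_samples if s in set(wanted_samples)]
            if wanted_samples is not None and rename_single is None
            else file_samples
        )
        for s in use_samples:
            table.add_sample(name_map[s])
        for lineno, rec in enumerate(vcf, start=1):
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                if set(alt.upper()) - ALLELE_CHARS:
                    logger.warning(
                        "%s: skipping symbolic/non-sequence ALT %r at %s:%s",
                        path, alt, rec.chrom, rec.pos,
                    )
                    continue
                try:
                    record = VariantRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt
                    )
                except ValueError as exc:
                    raise VariantIOError(
                        f"{path}: record {lineno} ({rec.chrom}:{rec.pos}): {exc}"
                    ) from exc
                if not table.has_variant(record.key):
                    table.add_variant(record)
                for s in use_samples:
                    sample = rec.samples[s]
                    genotype = _gt_to_genotype(sample.get("GT"), alt_index)
                    if genotype == HOM_REF:
                        continue  # sparse: hom_ref is the implicit default
                    alt_reads = (
                        None if genotype == MISSING else _alt_depth(sample, alt_index)
                    )
                    table.set_call(
                        record.key,
                        name_map[s],
                        GenotypeCall(genotype=genotype, alt_reads=alt_reads),
                    )


# ---------------------------------------------------------------------------
# Annotation tables

_ANNOTATION_FIELDS = ("gene", "consequence", "pop_maf", "in_cohort_db", "brain_expressed")
_REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt")
_TRUE_STRINGS = {"true", "t", "yes", "1"}
_FALSE_STRINGS = {"false", "f", "no", "0"}


def _parse_bool(value: Any, column: str) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("", "na", "nan", "."):
        return None
    if text in _TRUE_STRINGS:
        return True
    if text in _FALSE_STRINGS:
        return False
    raise AnnotationError(f"cannot parse boolean {value!r} in column {column!r}")


def _parse_maf(value: Any) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    if text in ("", ".", "na", "NA", "nan"):
        return None
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


def read_annotation_table(path: str | Path) -> dict[VariantKey, dict[str, Any]]:
    """Read a whitespace/tab-delimited annotation table into a key -> fields map.

    Required columns: chrom, pos, ref, alt.  Recognised optional columns:
    gene, consequence, pop_maf, in_cohort_db, brain_expressed; anything else
    is passed through under ``scores``.  ``pop_maf`` accepts a ``%`` suffix.
    Unknown consequence strings map to ``unknown`` with a logged warning.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    for col in _REQUIRED_COLUMNS:
        if col not in frame.columns:
            raise AnnotationError(f"{path}: missing column: {col}")
    score_cols = [
        c for c in frame.columns if c not in _REQUIRED_COLUMNS + _ANNOTATION_FIELDS
    ]
    result: dict[VariantKey, dict[str, Any]] = {}
    for row in frame.itertuples(index=False):
        data = row._asdict()
        key: VariantKey = (
            str(data["chrom"]),
            int(data["pos"]),
            str(data["ref"]),
            str(data["alt"]),
        )
        if key in result:
            raise AnnotationError(f"{path}: duplicate annotation row for {key_to_str(key)}")
        fields: dict[str, Any] = {}
        if "gene" in data and isinstance(data["gene"], str):
            fields["gene"] = data["gene"]
        if "consequence" in data and isinstance(data["consequence"], str):
            consequence = data["consequence"].strip()
            if consequence not in CONSEQUENCES:
                logger.warning(
                    "%s: unknown consequence %r for %s; mapping to 'unknown'",
                    path, consequence, key_to_str(key),
                )
                consequence = "unknown"
            fields["consequence"] = consequence
        if "pop_maf" in data:
            fields["pop_maf"] = _parse_maf(data["pop_maf"])
        if "in_cohort_db" in data:
            fields["in_cohort_db"] = _parse_bool(data["in_cohort_db"], "in_cohort_db")
        if "brain_expressed" in data:
            fields["brain_expressed"] = _parse_bool(data["brain_expressed"], "brain_expressed")
        scores = {
            c: data[c] for c in score_cols if isinstance(data[c], str) and data[c] != "."
        }
        if scores:
            fields["scores"] = scores
        result[key] = fields
    return result


def annotate_table(
    table: GenotypeTable, annotations: Mapping[VariantKey, Mapping[str, Any]]
) -> None:
    """Apply annotation fields in place to matching variant records."""
    for record in table.variants:
        fields = annotations.get(record.key)
        if not fields:
            continue
        for name in _ANNOTATION_FIELDS:
            if name in fields:
                setattr(record, name, fields[name])
        record.scores.update(fields.get("scores", {}))


def read_gene_whitelist(path: str | Path) -> set[str]:
    """One gene symbol per line; '#' comments and blank lines ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split()[0])
    return genes


# ---------------------------------------------------------------------------
# Output writing

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
    '##INFO=<ID=POP_MAF,Number=1,Type=Float,Description="Population minor allele frequency">',
    '##INFO=<ID=COHORT_DB,Number=1,Type=String,Description="Present in in-house cohort database">',
    '##INFO=<ID=BRAIN_EXPR,Number=1,Type=String,Description="Gene has validated brain expression">',
    '##INFO=<ID=MERGED_FROM,Number=.,Type=String,Description="Constituent records of a merged multi-base substitution">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths (ref,alt)">',
]

_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def _info_field(record: VariantRecord) -> str:
    parts = []
    if record.gene:
        parts.append(f"GENE={record.gene}")
    if record.consequence:
        parts.append(f"CSQ={record.consequence}")
    if record.pop_maf is not None:
        parts.append(f"POP_MAF={record.pop_maf:g}")
    if record.in_cohort_db is not None:
        parts.append(f"COHORT_DB={'true' if record.in_cohort_db else 'false'}")
    if record.brain_expressed is not None:
        parts.append(f"BRAIN_EXPR={'true' if record.brain_expressed else 'false'}")
    merged = record.scores.get("merged_from")
    if merged:
        parts.append("MERGED_FROM=" + ",".join(merged))
    return ";".join(parts) if parts else "."


def write_vcf(
    table: GenotypeTable,
    path: str | Path,
    keys: Iterable[VariantKey] | None = None,
) -> None:
    """Write variants (all, or the subset ``keys``) as deterministic VCF 4.2.

    Absent calls for listed samples are written as 0/0 per the no-call
    policy, so a write -> read round trip reproduces observed genotypes.
    """
    wanted = None if keys is None else set(keys)
    records = [v for v in table.variants if wanted is None or v.key in wanted]
    records.sort(key=lambda v: v.key)
    contigs = sorted({v.chrom for v in records})
    lines = list(_VCF_HEADER_LINES)
    lines += [f"##contig=<ID={c}>" for c in contigs]
    columns = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if table.samples:
        columns += ["FORMAT"] + list(table.samples)
    lines.append("\t".join(columns))
    for record in records:
        row = [
            record.chrom,
            str(record.pos),
            ".",
            record.ref,
            record.alt,
            ".",
            "PASS",
            _info_field(record),
        ]
        if table.samples:
            row.append("GT:AD")
            for sample in table.samples:
                call = table.get_call(record.key, sample)
                if call is None:
                    row.append("0/0:.")
                    continue
                gt = _GT_STRINGS[call.genotype]
                ad = f".,{call.alt_reads}" if call.alt_reads is not None else "."
                row.append(f"{gt}:{ad}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_outputs(table: GenotypeTable, trace: Any, out_dir: str | Path) -> dict[str, Path]:
    """Write surviving variants (VCF), per-variant report (TSV) and trace summary.

    ``trace`` is a :class:`cosegscan.pipeline.FilterTrace`; survivors are the
    variants whose terminal reason is ``PASS_COSEGREGATING``.  Returns the
    mapping of logical name to written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise VariantIOError(f"cannot create output directory {out_dir}: {exc}") from exc

    reasons = trace.final_reasons()
    pass_keys = [k for k, r in reasons.items() if r == "PASS_COSEGREGATING"]

    paths = {
        "vcf": out_dir / "surviving_variants.vcf",
        "report": out_dir / "variant_report.tsv",
        "trace": out_dir / "stage_trace.tsv",
    }
    write_vcf(table, paths["vcf"], keys=pass_keys)

    with open(paths["report"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\treason\n")
        for key in sorted(reasons):
            gene = table.variant(key).gene if table.has_variant(key) else None
            chrom, pos, ref, alt = key
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{gene or '.'}\t{reasons[key]}\n")

    with open(paths["trace"], "w") as fh:
        fh.write("stage\tin_count\tout_count\tnotes\n")
        for entry in trace.stages:
            tally = ",".join(
                f"{reason}:{count}" for reason, count in sorted(entry.reason_tally().items())
            )
            fh.write(f"{entry.name}\t{entry.n_in}\t{entry.n_out}\t{tally or '.'}\n")
    return paths
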