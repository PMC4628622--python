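"""Shared-candidate scan: read-support thresholding, adjacent-substitution
merging, and the affected-carrier / unaffected-non-carrier intersection."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .pedigree_io import Pedigree, phenotype_groups
from .variant_io import (
    GenotypeCall,
    GenotypeTable,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    NON_REF,
    VariantKey,
    key_to_str,
)

__all__ = ["ScanConfig", "ScanError", "merge_adjacent_substitutions", "support_filter", "shared_candidates"]


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ScanConfig:
    """Configuration for the shared-candidate scan.

    ``exception_ids`` names individuals whose carrier status is required at
    scan time but whose transmission lineage is only examined later, at the
    segregation stage.  With ``allow_missing_in_exceptions`` (off by
    default) a missing call in an exception individual does not disqualify a
    variant.  ``support_scope`` selects whether the read-support threshold
    applies to every call (``per_call``) or is satisfied by any one sample
    (``any_sample``).
    """

    min_alt_reads: int = 20
    carrier_genotypes: frozenset[str] = frozenset({HET})
    allow_hom_alt_carrier: bool = False
    exception_ids: frozenset[str] = frozenset()
    allow_missing_in_exceptions: bool = False
    support_scope: str = "per_call"

    def __post_init__(self) -> None:
        if not self.carrier_genotypes or not self.carrier_genotypes <= {HET, HOM_ALT}:
            raise ScanError(
                f"carrier_genotypes must be a non-empty subset of {{het, hom_alt}}, "
                f"got {set(self.carrier_genotypes)}"
            )
        if self.min_alt_reads < 0:
            raise ScanError("min_alt_reads must be non-negative")
        if self.support_scope not in ("per_call", "any_sample"):
            raise ScanError(f"invalid support_scope {self.support_scope!r}")

    @property
    def effective_carrier_genotypes(self) -> frozenset[str]:
        if self.allow_hom_alt_carrier:
            return self.carrier_genotypes | {HOM_ALT}
        return self.carrier_genotypes


def _genotype_vector(table: GenotypeTable, key: VariantKey) -> tuple:
    return tuple(
        (c.genotype if (c := table.get_call(key, s)) is not None else None)
        for s in table.samples
    )


def merge_adjacent_substitutions(table: GenotypeTable) -> GenotypeTable:
    """Merge runs of adjacent SNVs with identical genotype vectors into MNVs.

    A run of single-base substitutions at consecutive positions on one
    chromosome whose per-sample genotype vectors are identical (and carry at
    least one explicit non-reference call) is replaced by one multi-base
    substitution with position the leftmost constituent and ref/alt the
    concatenation in position order.  Annotations come from the first
    constituent, with the constituent keys noted under
    ``scores['merged_from']``.  Positions hosting more than one candidate
    allele are never merged across (phase ambiguity).  Idempotent: merged
    records are multi-base and cannot merge again.
    """
    variants = sorted(table.variants, key=lambda v: v.key)
    position_count: dict[tuple[str, int], int] = {}
    for v in variants:
        locus = (v.chrom, v.pos)
        position_count[locus] = position_count.get(locus, 0) + 1

    def mergeable(v) -> bool:
        if not v.is_snv or position_count[(v.chrom, v.pos)] > 1:
            return False
        vec = _genotype_vector(table, v.key)
        return any(g in NON_REF for g in vec)

    out = GenotypeTable(samples=table.samples)
    runs: list[list] = []
    current: list = []
    for v in variants:
        if (
            current
            and mergeable(v)
            and mergeable(current[-1])
            and v.chrom == current[-1].chrom
            and v.pos == current[-1].pos + 1
            and _genotype_vector(table, v.key) == _genotype_vector(table, current[-1].key)
        ):
            current.append(v)
        else:
            if current:
                runs.append(current)
            current = [v]
    if current:
        runs.append(current)

    for run in runs:
        if len(run) == 1:
            v = run[0]
            out.add_variant(replace(v, scores=dict(v.scores)))
            for s in table.samples:
                call = table.get_call(v.key, s)
                if call is not None:
                    out.set_call(v.key, s, call)
            continue
        first = run[0]
        merged = replace(
            first,
            ref="".join(v.ref for v in run),
            alt="".join(v.alt for v in run),
            scores={**first.scores, "merged_from": [key_to_str(v.key) for v in run]},
        )
        out.add_variant(merged)
        for s in table.samples:
            calls = [table.get_call(v.key, s) for v in run]
            if calls[0] is None:
                continue
            depths = [c.alt_reads for c in calls if c is not None and c.alt_reads is not None]
            alt_reads = min(depths) if depths and calls[0].genotype != MISSING else None
            out.set_call(
                merged.key,
                s,
                GenotypeCall(
                    genotype=calls[0].genotype,
                    alt_reads=alt_reads,
                    source=calls[0].source,
                ),
            )
    out.sort()
    return out


def support_filter(table: GenotypeTable, cfg: ScanConfig) -> tuple[GenotypeTable, int]:
    """Downgrade under-supported non-reference exome calls to missing.

    Returns the filtered table and the number of downgraded calls.
    Validation-source calls are never touched, nor are calls without a
    recorded alt read depth (no evidence either way).  With
    ``support_scope='any_sample'`` a variant is exempt whenever at least one
    sample meets the threshold.
    """
    if cfg.min_alt_reads == 0:
        return table.copy(), 0
    out = table.copy()
    exempt: set[VariantKey] = set()
    if cfg.support_scope == "any_sample":
        for (key, _sample), call in table.calls.items():
            if (
                call.source == "exome"
                and call.genotype in NON_REF
                and call.alt_reads is not None
                and call.alt_reads >= cfg.min_alt_reads
            ):
                exempt.add(key)
    downgraded = 0
    for (key, sample), call in table.calls.items():
        if key in exempt or call.source != "exome" or call.genotype not in NON_REF:
            continue
        if call.alt_reads is not None and call.alt_reads < cfg.min_alt_reads:
            out.calls[(key, sample)] = GenotypeCall(genotype=MISSING, source="exome")
            downgraded += 1
    return out, downgraded


def shared_candidates(
    table: GenotypeTable, ped: Pedigree, cfg: ScanConfig
) -> tuple[set[VariantKey], dict[VariantKey, str]]:
    """Variants carried by every affected sequenced individual and absent
    from every unaffected sequenced individual.

    Affected individuals must have a genotype in the carrier set; a missing
    call disqualifies the variant unless the individual is an exception id
    and ``allow_missing_in_exceptions`` is set.  Unaffected individuals must
    be hom_ref; their missing calls are treated as hom_ref at this stage
    (validation genotypes revisit them later).  Returns the candidate key
    set plus a reason code for every excluded variant.
    """
    sequenced = ped.sequenced_ids()
    missing_samples = [s for s in sequenced if s not in table.samples]
    if missing_samples:
        raise ScanError(f"sequenced individuals absent from genotype table: {missing_samples}")
    affected, unaffected, _ = phenotype_groups(ped, sequenced)
    if not affected:
        raise ScanError("no affected sequenced individuals: shared-candidate scan undefined")

    carriers = cfg.effective_carrier_genotypes
    kept: set[VariantKey] = set()
    reasons: dict[VariantKey, str] = {}
    for record in table.variants:
        key = record.key
        verdict = None
        for ind_id in sorted(affected):
            call = table.get_call(key, ind_id)
            genotype = call.genotype if call is not None else HOM_REF
            if genotype in carriers:
                continue
            if (
                genotype == MISSING
                and ind_id in cfg.exception_ids
                and cfg.allow_missing_in_exceptions
            ):
                continue
            verdict = "NOT_SHARED"
            break
        if verdict is None:
            for ind_id in sorted(unaffected):
                call = table.get_call(key, ind_id)
                genotype = call.genotype if call is not None else HOM_REF
                if genotype not in (HOM_REF, MISSING):
                    verdict = "NOT_SHARED"
                    break
        if verdict is None:
            kept.add(key)
        else:
            reasons[key] = verdict
    return kept, reasons
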