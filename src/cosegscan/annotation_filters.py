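"""Rarity / consequence / expression filter cascade over shared candidates.

Every filter has set-intersection semantics: it partitions its input into a
kept set and a removed set with per-variant reason codes, never adds
variants, and composes order-independently with the other filters.
Candidates without a population frequency or cohort-database annotation are
treated as novel: they pass the rarity filters and are tagged with a NOVEL
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

from .variant_io import CONSEQUENCES, VariantKey, VariantRecord, key_to_str

__all__ = [
    "FilterConfig",
    "FilterResult",
    "FilterError",
    "filter_cohort_db",
    "filter_population_maf",
    "filter_consequence",
    "filter_expression",
]

# reason codes
IN_COHORT_DB = "IN_COHORT_DB"
MAF_ABOVE_THRESHOLD = "MAF_ABOVE_THRESHOLD"
UNKNOWN_CONSEQUENCE = "UNKNOWN_CONSEQUENCE"
CONSEQUENCE_EXCLUDED = "CONSEQUENCE_EXCLUDED"
NOT_BRAIN_EXPRESSED = "NOT_BRAIN_EXPRESSED"
NOVEL = "NOVEL"


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and switches for the annotation filter cascade.

    ``cohort_db_size`` is descriptive metadata only (the size of the
    in-house exome collection backing the presence flags); filtering is
    presence-based, with an optional frequency-based alternative via
    ``cohort_db_max_frequency`` (off by default).
    """

    maf_threshold: float = 0.01
    require_absent_from_cohort_db: bool = True
    cohort_db_size: int = 700
    cohort_db_max_frequency: float | None = None
    keep_consequences: frozenset[str] = frozenset({"non_synonymous"})
    require_brain_expression: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.maf_threshold <= 1):
            raise FilterError(f"maf_threshold must be in (0, 1], got {self.maf_threshold}")
        if not self.keep_consequences:
            raise FilterError("keep_consequences must be non-empty")
        bad = set(self.keep_consequences) - CONSEQUENCES
        if bad:
            raise FilterError(f"unknown consequence classes: {sorted(bad)}")


@dataclass
class FilterResult:
    kept: set[VariantKey]
    reasons: dict[VariantKey, str] = field(default_factory=dict)
    notes: dict[VariantKey, str] = field(default_factory=dict)


def _annotation(annotations: Mapping[VariantKey, Any], key: VariantKey, name: str) -> Any:
    ann = annotations.get(key)
    if ann is None:
        return None
    if isinstance(ann, VariantRecord):
        return getattr(ann, name)
    return ann.get(name)


def filter_cohort_db(
    candidates: set[VariantKey],
    annotations: Mapping[VariantKey, Any],
    cfg: FilterConfig,
) -> FilterResult:
    """Remove candidates flagged present in the in-house cohort database.

    Removal is presence-based; candidates with no cohort annotation are
    retained and noted as NOVEL.  When ``cohort_db_max_frequency`` is set,
    a numeric ``cohort_db_frequency`` annotation at or above it also removes
    the candidate.
    """
    result = FilterResult(kept=set())
    for key in candidates:
        if cfg.require_absent_from_cohort_db:
            present = _annotation(annotations, key, "in_cohort_db")
            if present is True:
                result.reasons[key] = IN_COHORT_DB
                continue
            if present is None:
                result.notes[key] = NOVEL
            if cfg.cohort_db_max_frequency is not None:
                freq = _annotation(annotations, key, "cohort_db_frequency")
                if freq is not None and float(freq) >= cfg.cohort_db_max_frequency:
                    result.reasons[key] = IN_COHORT_DB
                    continue
        result.kept.add(key)
    return result


def filter_population_maf(
    candidates: set[VariantKey],
    annotations: Mapping[VariantKey, Any],
    cfg: FilterConfig,
) -> FilterResult:
    """Remove candidates with population MAF at or above the threshold
    (strictly-below-threshold survives); absent MAF is retained as NOVEL."""
    result = FilterResult(kept=set())
    for key in candidates:
        maf = _annotation(annotations, key, "pop_maf")
        if maf is None:
            result.notes[key] = NOVEL
            result.kept.add(key)
        elif maf >= cfg.maf_threshold:
            result.reasons[key] = MAF_ABOVE_THRESHOLD
        else:
            result.kept.add(key)
    return result


def filter_consequence(
    candidates: set[VariantKey],
    annotations: Mapping[VariantKey, Any],
    cfg: FilterConfig,
) -> FilterResult:
    """Keep candidates whose consequence class is configured to be kept."""
    result = FilterResult(kept=set())
    for key in candidates:
        consequence = _annotation(annotations, key, "consequence")
        if consequence in cfg.keep_consequences:
            result.kept.add(key)
        elif consequence in (None, "unknown"):
            result.reasons[key] = UNKNOWN_CONSEQUENCE
        else:
            result.reasons[key] = CONSEQUENCE_EXCLUDED
    return result


def filter_expression(
    candidates: set[VariantKey],
    annotations: Mapping[VariantKey, Any],
    cfg: FilterConfig,
) -> FilterResult:
    """Keep candidates in genes with a validated brain-expression flag.

    With ``require_brain_expression`` on, every candidate must carry a
    boolean ``brain_expressed`` annotation; missing annotations are an
    error listing the offending variants.
    """
    if not cfg.require_brain_expression:
        return FilterResult(kept=set(candidates))
    unannotated = [
        key for key in candidates
        if _annotation(annotations, key, "brain_expressed") is None
    ]
    if unannotated:
        raise FilterError(
            "brain_expressed annotation required but missing for: "
            + ", ".join(key_to_str(k) for k in sorted(unannotated))
        )
    result = FilterResult(kept=set())
    for key in candidates:
        if _annotation(annotations, key, "brain_expressed"):
            result.kept.add(key)
        else:
            result.reasons[key] = NOT_BRAIN_EXPRESSED
    return result
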