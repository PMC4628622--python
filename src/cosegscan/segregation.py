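"""Per-variant co-segregation verdicts after validation-genotype override.

The verdict is computed over every individual with a typed genotype: an
explicit non-missing call, or an implicit hom_ref for sequenced exome
samples without a call.  Uncertain- and untested-phenotype individuals
never impose a constraint; uncertain carriers in particular never count as
unaffected carriers.

Exception individuals (affected members whose transmitting parent cannot be
assumed, e.g. one parent married in with unknown phenotype) additionally
require :func:`confirm_transmission`: the variant must be connectable to
another typed carrier through a parent lineage that no typed non-carrier
contradicts.  An indeterminate lineage (all connecting relatives untyped)
does not fail the variant; it passes with a caveat in the narrative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .pedigree_io import Pedigree
from .variant_io import (
    GenotypeCall,
    GenotypeTable,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    VariantKey,
    key_to_str,
    str_to_key,
)

__all__ = [
    "InheritanceModel",
    "SegregationVerdict",
    "ValidationError",
    "read_validation_table",
    "apply_validation",
    "cosegregation_test",
    "confirm_transmission",
]

PASS_COSEGREGATING = "PASS_COSEGREGATING"
FAIL_UNAFFECTED_CARRIER = "FAIL_UNAFFECTED_CARRIER"
FAIL_MISSING_IN_AFFECTED = "FAIL_MISSING_IN_AFFECTED"
FAIL_MONOMORPHIC = "FAIL_MONOMORPHIC"
FAIL_ANCESTRY_UNCONFIRMED = "FAIL_ANCESTRY_UNCONFIRMED"

_VALIDATION_GT = {"0/0": HOM_REF, "0/1": HET, "1/0": HET, "1/1": HOM_ALT, "./.": MISSING}


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class InheritanceModel:
    """Dominant-model parameters for the co-segregation test.

    ``max_unaffected_carriers`` operationalises "high penetrance": the number
    of typed unaffected carriers tolerated before a variant fails (0 means
    complete penetrance among typed individuals).
    """

    mode: str = "autosomal_dominant"
    max_unaffected_carriers: int = 0
    carrier_genotypes: frozenset[str] = frozenset({HET})
    exception_ids: frozenset[str] = frozenset()
    exception_notes: dict[str, str] = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.mode != "autosomal_dominant":
            raise ValueError(f"unsupported inheritance mode {self.mode!r}")
        if self.max_unaffected_carriers < 0:
            raise ValueError("max_unaffected_carriers must be >= 0")
        if not self.carrier_genotypes or not self.carrier_genotypes <= {HET, HOM_ALT}:
            raise ValueError("carrier_genotypes must be a non-empty subset of {het, hom_alt}")


@dataclass(frozen=True)
class SegregationVerdict:
    variant: VariantKey
    status: str
    offending_ids: tuple[str, ...] = ()
    narrative: str = ""


def read_validation_table(path: str | Path) -> list[tuple[VariantKey, str, str]]:
    """Read a validation TSV (variant_key, individual_id, genotype) into rows.

    Genotypes use VCF-style strings 0/0, 0/1, 1/1 (and ./.).  Contradictory
    duplicate rows for the same (variant, individual) raise
    :class:`ValidationError`; exact duplicates are tolerated.
    """
    rows: list[tuple[VariantKey, str, str]] = []
    seen: dict[tuple[VariantKey, str], str] = {}
    with open(path) as fh:
        reader = csv.reader(
            (line for line in fh if line.strip() and not line.startswith("#")),
            delimiter="\t",
        )
        header = next(reader, None)
        if header is None:
            return []
        if [c.strip().lower() for c in header[:3]] != ["variant_key", "individual_id", "genotype"]:
            raise ValidationError(
                f"{path}: expected header variant_key/individual_id/genotype, got {header}"
            )
        for lineno, fields in enumerate(reader, start=2):
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 columns")
            key = str_to_key(fields[0].strip())
            ind_id = fields[1].strip()
            gt_text = fields[2].strip()
            if gt_text not in _VALIDATION_GT:
                raise ValidationError(f"{path}:{lineno}: invalid genotype {gt_text!r}")
            genotype = _VALIDATION_GT[gt_text]
            prior = seen.get((key, ind_id))
            if prior is not None and prior != genotype:
                raise ValidationError(
                    f"{path}:{lineno}: contradictory validation genotypes for "
                    f"{key_to_str(key)} / {ind_id}: {prior} vs {genotype}"
                )
            seen[(key, ind_id)] = genotype
            rows.append((key, ind_id, genotype))
    return rows


def apply_validation(
    table: GenotypeTable,
    validation: Iterable[tuple[VariantKey, str, str]] | str | Path,
    ped: Pedigree | None = None,
) -> GenotypeTable:
    """Override exome genotypes with validation genotypes.

    ``validation`` is a path to the TSV or pre-parsed rows.  Validation
    rows may introduce calls for previously unlisted individuals (the table
    gains those samples).  Rows for variants not in the table are ignored
    (they refer to candidates eliminated earlier).  Overrides are recorded
    with ``source='validation'``.
    """
    if isinstance(validation, (str, Path)):
        rows = read_validation_table(validation)
    else:
        rows = list(validation)
        seen: dict[tuple[VariantKey, str], str] = {}
        for key, ind_id, genotype in rows:
            prior = seen.get((key, ind_id))
            if prior is not None and prior != genotype:
                raise ValidationError(
                    f"contradictory validation genotypes for {key_to_str(key)} / {ind_id}"
                )
            seen[(key, ind_id)] = genotype
    out = table.copy()
    for key, ind_id, genotype in rows:
        if ped is not None and ind_id not in ped:
            raise ValidationError(f"validation row names unknown individual {ind_id!r}")
        if not out.has_variant(key):
            continue
        out.add_sample(ind_id)
        out.set_call(key, ind_id, GenotypeCall(genotype=genotype, source="validation"))
    return out


def _typed_genotype(table: GenotypeTable, ped: Pedigree, key: VariantKey, ind_id: str) -> str | None:
    ind = ped[ind_id]
    return table.observed_genotype(key, ind_id, sequenced=ind.sequenced)


def cosegregation_test(
    variant: VariantKey,
    ped: Pedigree,
    table: GenotypeTable,
    model: InheritanceModel,
) -> SegregationVerdict:
    """Co-segregation verdict for one variant on the full pedigree.

    Checks, in order: FAIL_MONOMORPHIC (no typed individual carries any
    alternate allele), FAIL_MISSING_IN_AFFECTED (a typed affected individual
    is not a carrier), FAIL_UNAFFECTED_CARRIER (typed unaffected carriers
    exceed the tolerated count), FAIL_ANCESTRY_UNCONFIRMED (an exception-id
    carrier whose transmission lineage is contradicted).  Otherwise
    PASS_COSEGREGATING, with a caveat note when an exception lineage is
    indeterminate.
    """
    if not table.has_variant(variant):
        raise KeyError(f"variant {key_to_str(variant)} not in table")
    carriers = model.carrier_genotypes
    genotypes = {ind.id: _typed_genotype(table, ped, variant, ind.id) for ind in ped}

    if not any(g in (HET, HOM_ALT) for g in genotypes.values() if g is not None):
        return SegregationVerdict(
            variant, FAIL_MONOMORPHIC, narrative="no typed individual carries the variant"
        )

    missing_in_affected = sorted(
        ind.id
        for ind in ped
        if ind.phenotype == "affected"
        and genotypes[ind.id] is not None
        and genotypes[ind.id] not in carriers
    )
    if missing_in_affected:
        return SegregationVerdict(
            variant,
            FAIL_MISSING_IN_AFFECTED,
            offending_ids=tuple(missing_in_affected),
            narrative="affected individuals without the carrier genotype: "
            + ", ".join(missing_in_affected),
        )

    unaffected_carriers = sorted(
        ind.id
        for ind in ped
        if ind.phenotype == "unaffected" and genotypes[ind.id] in carriers
    )
    if len(unaffected_carriers) > model.max_unaffected_carriers:
        return SegregationVerdict(
            variant,
            FAIL_UNAFFECTED_CARRIER,
            offending_ids=tuple(unaffected_carriers),
            narrative="unaffected carriers: " + ", ".join(unaffected_carriers),
        )

    caveats: list[str] = []
    for exc_id in sorted(model.exception_ids):
        if exc_id not in ped or genotypes.get(exc_id) not in carriers:
            continue
        outcome = confirm_transmission(variant, ped, table, exc_id, carrier_genotypes=carriers)
        if outcome == "unconfirmed":
            return SegregationVerdict(
                variant,
                FAIL_ANCESTRY_UNCONFIRMED,
                offending_ids=(exc_id,),
                narrative=f"transmission to {exc_id} from a common ancestor not confirmed",
            )
        if outcome == "indeterminate":
            caveats.append(f"transmission lineage to {exc_id} runs through untyped individuals")
    narrative = "co-segregates under the dominant model"
    if caveats:
        narrative += " (caveat: " + "; ".join(caveats) + ")"
    return SegregationVerdict(variant, PASS_COSEGREGATING, narrative=narrative)


def _up_chains(ped: Pedigree, ind_id: str) -> Iterator[list[str]]:
    """Yield every upward chain [ind, parent, ..., ancestor], including the
    trivial chain [ind]."""
    yield [ind_id]
    ind = ped[ind_id]
    for pid in (ind.father_id, ind.mother_id):
        if pid is not None:
            for chain in _up_chains(ped, pid):
                yield [ind_id] + chain


def confirm_transmission(
    variant: VariantKey,
    ped: Pedigree,
    table: GenotypeTable,
    individual_id: str,
    carrier_genotypes: frozenset[str] = frozenset({HET, HOM_ALT}),
) -> str:
    """Classify the transmission lineage of ``individual_id``'s variant.

    Considers every lineage linking the individual to another typed carrier
    through a shared ancestor (including the carrier being an ancestor or
    descendant).  Returns ``confirmed`` if some lineage contains a typed
    carrier step (or is a direct parent/child link) and no typed
    non-carrier; ``unconfirmed`` if every lineage is contradicted by a typed
    non-carrier; ``indeterminate`` if no other typed carrier exists or the
    only uncontradicted lineages run exclusively through untyped
    individuals.
    """
    if individual_id not in ped:
        raise KeyError(f"unknown individual {individual_id!r}")
    own = _typed_genotype(table, ped, variant, individual_id)
    if own not in carrier_genotypes:
        raise ValueError(f"{individual_id!r} does not carry {key_to_str(variant)}")

    def genotype(ind_id: str) -> str | None:
        return _typed_genotype(table, ped, variant, ind_id)

    other_carriers = [
        ind.id
        for ind in ped
        if ind.id != individual_id and genotype(ind.id) in carrier_genotypes
    ]
    if not other_carriers:
        return "indeterminate"

    my_chains = list(_up_chains(ped, individual_id))
    by_ancestor: dict[str, list[list[str]]] = {}
    for chain in my_chains:
        by_ancestor.setdefault(chain[-1], []).append(chain)

    saw_indeterminate = False
    for carrier_id in other_carriers:
        for chain_c in _up_chains(ped, carrier_id):
            ancestor = chain_c[-1]
            for chain_i in by_ancestor.get(ancestor, ()):
                lineage = (set(chain_i[1:]) | set(chain_c[1:])) - {individual_id, carrier_id}
                states = [genotype(x) for x in lineage]
                if any(s is not None and s not in carrier_genotypes for s in states):
                    continue  # contradicted by a typed non-carrier
                if not lineage or any(s in carrier_genotypes for s in states):
                    return "confirmed"
                saw_indeterminate = True
    return "indeterminate" if saw_indeterminate else "unconfirmed"
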