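from __future__ import annotations

import itertools

import numpy as np
import pytest

from cosegscan.candidate_scan import ScanConfig, merge_adjacent_substitutions, shared_candidates
from cosegscan.pedigree_io import Individual, Pedigree
from cosegscan.segregation import (
    FAIL_ANCESTRY_UNCONFIRMED,
    FAIL_MISSING_IN_AFFECTED,
    FAIL_MONOMORPHIC,
    FAIL_UNAFFECTED_CARRIER,
    InheritanceModel,
    PASS_COSEGREGATING,
    ValidationError,
    apply_validation,
    confirm_transmission,
    cosegregation_test,
    read_validation_table,
)
from cosegscan.synthetic_data import (
    CEP63_MERGED,
    GET4_KEY,
    INTS5_KEY,
    RNF152_KEY,
    ZNF507_KEY,
    make_fig1a_fixture,
)
from cosegscan.variant_io import (
    GenotypeCall,
    GenotypeTable,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    VariantRecord,
)

# ---------------------------------------------------------------------------
# apply_validation


def _one_variant_table(samples, calls, key=("1", 10, "A", "G")):
    table = GenotypeTable(samples=samples)
    table.add_variant(VariantRecord(*key))
    for sample, genotype in calls.items():
        table.set_call(key, sample, GenotypeCall(genotype, alt_reads=30 if genotype in (HET, HOM_ALT) else None))
    return table


def test_validation_overrides_exome_call():
    key = ("1", 10, "A", "G")
    table = _one_variant_table(["s1"], {"s1": HET})
    out = apply_validation(table, [(key, "s1", HOM_REF)])
    call = out.get_call(key, "s1")
    assert call.genotype == HOM_REF
    assert call.source == "validation"
    # input untouched
    assert table.get_call(key, "s1").genotype == HET


def test_validation_adds_unsequenced_individual():
    key = ("1", 10, "A", "G")
    table = _one_variant_table(["s1"], {"s1": HET})
    out = apply_validation(table, [(key, "granny", HET)])
    assert "granny" in out.samples
    assert out.get_call(key, "granny").genotype == HET


def test_validation_empty_is_identity():
    table = _one_variant_table(["s1"], {"s1": HET})
    out = apply_validation(table, [])
    assert out.calls == table.calls
    assert out.samples == table.samples


def test_validation_contradictory_rows_error():
    key = ("1", 10, "A", "G")
    table = _one_variant_table(["s1"], {"s1": HET})
    with pytest.raises(ValidationError, match="contradictory"):
        apply_validation(table, [(key, "s1", HOM_REF), (key, "s1", HET)])


def test_validation_tsv_round_trip(tmp_path):
    path = tmp_path / "val.tsv"
    path.write_text(
        "variant_key\tindividual_id\tgenotype\n"
        "1:10:A:G\ts1\t0/1\n"
        "1:10:A:G\ts2\t0/0\n"
    )
    rows = read_validation_table(path)
    assert rows == [(("1", 10, "A", "G"), "s1", HET), (("1", 10, "A", "G"), "s2", HOM_REF)]


def test_validation_unknown_individual_checked_against_pedigree():
    key = ("1", 10, "A", "G")
    table = _one_variant_table(["s1"], {"s1": HET})
    ped = Pedigree([Individual("s1", phenotype="affected")]).mark_sequenced(["s1"])
    with pytest.raises(ValidationError, match="stranger"):
        apply_validation(table, [(key, "stranger", HET)], ped=ped)


# ---------------------------------------------------------------------------
# worked-example verdicts


@pytest.fixture()
def validated_fixture(fig1a):
    table = merge_adjacent_substitutions(fig1a.table)
    table = apply_validation(table, fig1a.validation_rows, ped=fig1a.ped)
    model = InheritanceModel(exception_ids=fig1a.exception_ids)
    return fig1a.ped, table, model


def test_znf507_fails_on_two_unaffected_carriers(validated_fixture):
    ped, table, model = validated_fixture
    verdict = cosegregation_test(ZNF507_KEY, ped, table, model)
    assert verdict.status == FAIL_UNAFFECTED_CARRIER
    assert set(verdict.offending_ids) == {"III:2", "IV:11"}


def test_rnf152_fails_on_one_unaffected_carrier(validated_fixture):
    ped, table, model = validated_fixture
    verdict = cosegregation_test(RNF152_KEY, ped, table, model)
    assert verdict.status == FAIL_UNAFFECTED_CARRIER
    assert verdict.offending_ids == ("IV:6",)


def test_get4_monomorphic_after_validation(validated_fixture):
    ped, table, model = validated_fixture
    verdict = cosegregation_test(GET4_KEY, ped, table, model)
    assert verdict.status == FAIL_MONOMORPHIC
    assert verdict.offending_ids == ()


def test_ints5_ancestry_unconfirmed(validated_fixture):
    ped, table, model = validated_fixture
    verdict = cosegregation_test(INTS5_KEY, ped, table, model)
    assert verdict.status == FAIL_ANCESTRY_UNCONFIRMED
    assert verdict.offending_ids == ("IV:9",)


def test_cep63_passes(validated_fixture):
    ped, table, model = validated_fixture
    verdict = cosegregation_test(CEP63_MERGED, ped, table, model)
    assert verdict.status == PASS_COSEGREGATING


# ---------------------------------------------------------------------------
# confirm_transmission


def test_ints5_pattern_unconfirmed(validated_fixture):
    ped, table, _ = validated_fixture
    assert confirm_transmission(INTS5_KEY, ped, table, "IV:9") == "unconfirmed"


def test_cep63_lineage_confirmed(validated_fixture):
    ped, table, _ = validated_fixture
    assert confirm_transmission(CEP63_MERGED, ped, table, "IV:9") == "confirmed"


def test_no_other_typed_carriers_indeterminate():
    ped = Pedigree(
        [
            Individual("f", sex="male"),
            Individual("m", sex="female"),
            Individual("kid", father_id="f", mother_id="m", phenotype="affected"),
        ]
    ).mark_sequenced(["kid"])
    table = _one_variant_table(["kid"], {"kid": HET})
    assert confirm_transmission(("1", 10, "A", "G"), ped, table, "kid") == "indeterminate"


def test_sibling_carrier_with_untyped_parents_indeterminate():
    ped = Pedigree(
        [
            Individual("f", sex="male"),
            Individual("m", sex="female"),
            Individual("kid", father_id="f", mother_id="m", phenotype="affected"),
            Individual("sib", father_id="f", mother_id="m", phenotype="affected"),
        ]
    ).mark_sequenced(["kid", "sib"])
    table = _one_variant_table(["kid", "sib"], {"kid": HET, "sib": HET})
    assert confirm_transmission(("1", 10, "A", "G"), ped, table, "kid") == "indeterminate"


def test_carrier_parent_confirms():
    ped = Pedigree(
        [
            Individual("f", sex="male"),
            Individual("m", sex="female"),
            Individual("kid", father_id="f", mother_id="m", phenotype="affected"),
        ]
    ).mark_sequenced(["kid", "f"])
    table = _one_variant_table(["kid", "f"], {"kid": HET, "f": HET})
    assert confirm_transmission(("1", 10, "A", "G"), ped, table, "kid") == "confirmed"


def test_non_carrier_raises():
    ped = Pedigree([Individual("a", phenotype="affected")]).mark_sequenced(["a"])
    table = _one_variant_table(["a"], {"a": HOM_REF})
    with pytest.raises(ValueError):
        confirm_transmission(("1", 10, "A", "G"), ped, table, "a")
    with pytest.raises(KeyError):
        confirm_transmission(("1", 10, "A", "G"), ped, table, "nobody")


# ---------------------------------------------------------------------------
# exhaustive oracle equivalence


def _oracle_verdict(ped, genotypes, model):
    """Brute-force re-evaluation of the verdict definition over explicit
    typed genotypes (None = untyped), written directly from the rule text."""
    typed = {i: g for i, g in genotypes.items() if g is not None}
    if not any(g in (HET, HOM_ALT) for g in typed.values()):
        return FAIL_MONOMORPHIC
    if any(
        ped[i].phenotype == "affected" and typed[i] not in model.carrier_genotypes
        for i in typed
    ):
        return FAIL_MISSING_IN_AFFECTED
    unaffected_carriers = [
        i for i in typed
        if ped[i].phenotype == "unaffected" and typed[i] in model.carrier_genotypes
    ]
    if len(unaffected_carriers) > model.max_unaffected_carriers:
        return FAIL_UNAFFECTED_CARRIER
    for exc in model.exception_ids:
        if typed.get(exc) in model.carrier_genotypes:
            if _oracle_confirm_two_generation(ped, typed, exc, model.carrier_genotypes) == "unconfirmed":
                return FAIL_ANCESTRY_UNCONFIRMED
    return PASS_COSEGREGATING


def _oracle_confirm_two_generation(ped, typed, ind_id, carriers):
    """Transmission oracle for a parents-plus-children pedigree, enumerated
    case by case rather than by graph search."""
    ind = ped[ind_id]
    others = [i for i, g in typed.items() if i != ind_id and g in carriers]
    if not others:
        return "indeterminate"
    parents = [p for p in (ind.father_id, ind.mother_id) if p is not None]
    if any(typed.get(p) in carriers for p in parents):
        return "confirmed"
    saw_open = False
    for other in others:
        shared = set(parents) & {
            p for p in (ped[other].father_id, ped[other].mother_id) if p is not None
        }
        for parent in shared:
            if typed.get(parent) in carriers:
                return "confirmed"
            if parent not in typed:
                saw_open = True
    return "indeterminate" if saw_open else "unconfirmed"


def _five_member_pedigree(phenotypes):
    f_ph, m_ph, c1_ph, c2_ph, c3_ph = phenotypes
    return Pedigree(
        [
            Individual("F", sex="male", phenotype=f_ph),
            Individual("M", sex="female", phenotype=m_ph),
            Individual("C1", father_id="F", mother_id="M", phenotype=c1_ph),
            Individual("C2", father_id="F", mother_id="M", phenotype=c2_ph),
            Individual("C3", father_id="F", mother_id="M", phenotype=c3_ph),
        ]
    ).mark_sequenced([])  # genotypes are always explicit in the enumeration


@pytest.mark.parametrize(
    "phenotypes,model",
    [
        (("affected", "unaffected", "affected", "unaffected", "uncertain"), InheritanceModel()),
        (("untested", "untested", "affected", "affected", "unaffected"), InheritanceModel()),
        (
            ("untested", "untested", "affected", "affected", "untested"),
            InheritanceModel(exception_ids=frozenset({"C1"})),
        ),
        (
            ("affected", "uncertain", "affected", "unaffected", "untested"),
            InheritanceModel(max_unaffected_carriers=1, exception_ids=frozenset({"C1"})),
        ),
    ],
)
@pytest.mark.parametrize("states", [(HOM_REF, HET, MISSING), (HOM_REF, HET, HOM_ALT)])
def test_exhaustive_oracle_equivalence(phenotypes, model, states):
    ped = _five_member_pedigree(phenotypes)
    ids = ["F", "M", "C1", "C2", "C3"]
    key = ("1", 10, "A", "G")
    seen = set()
    for assignment in itertools.product(states, repeat=5):
        table = GenotypeTable(samples=ids)
        table.add_variant(VariantRecord(*key))
        for ind_id, genotype in zip(ids, assignment):
            table.set_call(key, ind_id, GenotypeCall(genotype))
        verdict = cosegregation_test(key, ped, table, model)
        genotypes = {
            i: (None if g == MISSING else g) for i, g in zip(ids, assignment)
        }
        assert verdict.status == _oracle_verdict(ped, genotypes, model), (
            phenotypes, assignment,
        )
        seen.add(verdict.status)
    # the enumeration must exercise more than a single status code
    assert FAIL_MONOMORPHIC in seen and PASS_COSEGREGATING in seen


def test_every_status_code_reachable():
    statuses = set()
    model = InheritanceModel(exception_ids=frozenset({"C1"}))
    ped = _five_member_pedigree(("untested", "untested", "affected", "affected", "unaffected"))
    ids = ["F", "M", "C1", "C2", "C3"]
    key = ("1", 10, "A", "G")
    for assignment in itertools.product((HOM_REF, HET, MISSING), repeat=5):
        table = GenotypeTable(samples=ids)
        table.add_variant(VariantRecord(*key))
        for ind_id, genotype in zip(ids, assignment):
            table.set_call(key, ind_id, GenotypeCall(genotype))
        statuses.add(cosegregation_test(key, ped, table, model).status)
    assert statuses == {
        PASS_COSEGREGATING,
        FAIL_MONOMORPHIC,
        FAIL_MISSING_IN_AFFECTED,
        FAIL_UNAFFECTED_CARRIER,
        FAIL_ANCESTRY_UNCONFIRMED,
    }


# ---------------------------------------------------------------------------
# invariants


def test_verdict_invariant_to_relabeling(validated_fixture):
    ped, table, model = validated_fixture
    mapping = {ind.id: f"X{i}" for i, ind in enumerate(ped)}
    renamed_ped = Pedigree(
        [
            Individual(
                mapping[ind.id],
                father_id=mapping.get(ind.father_id),
                mother_id=mapping.get(ind.mother_id),
                sex=ind.sex,
                phenotype=ind.phenotype,
                sequenced=ind.sequenced,
            )
            for ind in ped
        ],
        name=ped.name,
    )
    renamed_table = GenotypeTable(samples=[mapping[s] for s in table.samples])
    for v in table.variants:
        renamed_table.add_variant(VariantRecord(v.chrom, v.pos, v.ref, v.alt))
    for (key, sample), call in table.calls.items():
        renamed_table.set_call(key, mapping[sample], call)
    renamed_model = InheritanceModel(
        exception_ids=frozenset(mapping[i] for i in model.exception_ids)
    )
    for v in table.variants:
        original = cosegregation_test(v.key, ped, table, model)
        renamed = cosegregation_test(v.key, renamed_ped, renamed_table, renamed_model)
        assert renamed.status == original.status
        assert set(renamed.offending_ids) == {mapping[i] for i in original.offending_ids}


def test_pass_implies_shared_on_typed_subset():
    # with no exceptions and zero tolerated unaffected carriers, a PASS
    # verdict implies survival of the shared scan restricted to typed
    # individuals (het/hom_ref/missing worlds)
    rng = np.random.default_rng(31)
    model = InheritanceModel()
    key = ("1", 10, "A", "G")
    for _ in range(200):
        n = int(rng.integers(2, 7))
        ids = [f"i{k}" for k in range(n)]
        phenotypes = rng.choice(["affected", "unaffected", "uncertain"], size=n)
        ped = Pedigree(
            [Individual(i, phenotype=str(p)) for i, p in zip(ids, phenotypes)]
        )
        table = GenotypeTable(samples=ids)
        table.add_variant(VariantRecord(*key))
        typed_ids = []
        for i in ids:
            genotype = rng.choice([HET, HOM_REF, MISSING], p=[0.4, 0.4, 0.2])
            table.set_call(key, i, GenotypeCall(str(genotype)))
            if genotype != MISSING:
                typed_ids.append(i)
        ped = ped.mark_sequenced(typed_ids)
        verdict = cosegregation_test(key, ped, table, model)
        if verdict.status == PASS_COSEGREGATING and any(
            ped[i].phenotype == "affected" for i in typed_ids
        ):
            kept, _ = shared_candidates(table, ped, ScanConfig(min_alt_reads=0))
            assert key in kept
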