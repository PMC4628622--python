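from __future__ import annotations

import numpy as np
import pytest

from cosegscan.candidate_scan import (
    ScanConfig,
    ScanError,
    merge_adjacent_substitutions,
    shared_candidates,
    support_filter,
)
from cosegscan.pedigree_io import Individual, Pedigree
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
# helpers


def _table(samples, variant_calls):
    """variant_calls: {(chrom,pos,ref,alt): {sample: (genotype, alt_reads)}}"""
    table = GenotypeTable(samples=samples)
    for key, calls in variant_calls.items():
        table.add_variant(VariantRecord(*key))
        for sample, (genotype, alt_reads) in calls.items():
            table.set_call(key, sample, GenotypeCall(genotype, alt_reads=alt_reads))
    table.sort()
    return table


def _flat_pedigree(affected, unaffected, sequenced=None):
    members = [
        Individual(i, sex="male", phenotype="affected") for i in affected
    ] + [Individual(i, sex="female", phenotype="unaffected") for i in unaffected]
    ped = Pedigree(members)
    return ped.mark_sequenced(sequenced if sequenced is not None else [m.id for m in members])


def oracle_shared(table, affected, unaffected, carrier_genotypes):
    """Independent re-evaluation of the shared-candidate rule, straight from
    its definition (absent call = hom_ref; missing disqualifies affected,
    is tolerated in unaffected)."""
    out = set()
    for v in table.variants:
        ok = True
        for a in affected:
            call = table.get_call(v.key, a)
            genotype = call.genotype if call else HOM_REF
            if genotype not in carrier_genotypes:
                ok = False
        for u in unaffected:
            call = table.get_call(v.key, u)
            genotype = call.genotype if call else HOM_REF
            if genotype not in (HOM_REF, MISSING):
                ok = False
        if ok:
            out.add(v.key)
    return out


# ---------------------------------------------------------------------------
# merge_adjacent_substitutions


def test_merge_adjacent_identical_vectors():
    table = _table(
        ["a1", "a2", "u1"],
        {
            ("chr3", 134264558, "G", "T"): {"a1": (HET, 30), "a2": (HET, 31)},
            ("chr3", 134264559, "A", "T"): {"a1": (HET, 28), "a2": (HET, 35)},
        },
    )
    merged = merge_adjacent_substitutions(table)
    assert len(merged) == 1
    record = merged.variants[0]
    assert record.key == ("chr3", 134264558, "GA", "TT")
    assert record.scores["merged_from"] == [
        "chr3:134264558:G:T",
        "chr3:134264559:A:T",
    ]
    call = merged.get_call(record.key, "a1")
    assert call.genotype == HET
    assert call.alt_reads == 28  # most conservative constituent depth


def test_merge_skips_different_carrier_sets():
    table = _table(
        ["a1", "a2"],
        {
            ("1", 10, "G", "T"): {"a1": (HET, 30)},
            ("1", 11, "A", "T"): {"a2": (HET, 30)},
        },
    )
    merged = merge_adjacent_substitutions(table)
    assert len(merged) == 2


def test_merge_skips_indels_and_gaps():
    table = _table(
        ["a1"],
        {
            ("1", 10, "G", "GT"): {"a1": (HET, 30)},  # insertion, untouched
            ("1", 11, "A", "T"): {"a1": (HET, 30)},
            ("1", 13, "C", "T"): {"a1": (HET, 30)},  # gap: 11 -> 13
        },
    )
    merged = merge_adjacent_substitutions(table)
    assert {v.key for v in merged.variants} == {v.key for v in table.variants}


def _random_table(rng, n_samples=4, n_variants=8):
    samples = [f"s{i}" for i in range(n_samples)]
    table = GenotypeTable(samples=samples)
    pos = 100
    for _ in range(n_variants):
        pos += int(rng.integers(1, 3))  # often adjacent
        key = ("1", pos, "A", "G")
        if table.has_variant(key):
            continue
        table.add_variant(VariantRecord(*key))
        for s in samples:
            g = rng.choice([None, HOM_REF, HET, HOM_ALT, MISSING], p=[0.4, 0.1, 0.3, 0.1, 0.1])
            if g is not None:
                reads = None if g == MISSING else int(rng.integers(1, 60))
                table.set_call(key, s, GenotypeCall(g, alt_reads=reads))
    table.sort()
    return table


def test_merge_idempotent_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(30):
        table = _random_table(rng)
        once = merge_adjacent_substitutions(table)
        twice = merge_adjacent_substitutions(once)
        assert [v.key for v in twice.variants] == [v.key for v in once.variants]
        assert twice.calls == once.calls


def test_merge_preserves_carrier_status():
    rng = np.random.default_rng(7)
    for _ in range(30):
        table = _random_table(rng)
        merged = merge_adjacent_substitutions(table)
        for record in merged.variants:
            constituents = record.scores.get("merged_from")
            if not constituents:
                continue
            for s in table.samples:
                merged_call = merged.get_call(record.key, s)
                for text in constituents:
                    chrom, pos, ref, alt = text.rsplit(":", 3)
                    original = table.get_call((chrom, int(pos), ref, alt), s)
                    assert (original is None) == (merged_call is None)
                    if original is not None:
                        assert original.genotype == merged_call.genotype


# ---------------------------------------------------------------------------
# support_filter


@pytest.mark.parametrize(
    "alt_reads,expected", [(20, HET), (19, MISSING), (100, HET)]
)
def test_support_threshold_boundary(alt_reads, expected):
    table = _table(["s"], {("1", 5, "A", "G"): {"s": (HET, alt_reads)}})
    filtered, downgraded = support_filter(table, ScanConfig(min_alt_reads=20))
    assert filtered.get_call(("1", 5, "A", "G"), "s").genotype == expected
    assert downgraded == (0 if expected == HET else 1)


def test_support_filter_disabled():
    table = _table(["s"], {("1", 5, "A", "G"): {"s": (HET, 1)}})
    filtered, downgraded = support_filter(table, ScanConfig(min_alt_reads=0))
    assert downgraded == 0
    assert filtered.get_call(("1", 5, "A", "G"), "s").genotype == HET


def test_support_filter_any_sample_scope():
    table = _table(
        ["s1", "s2"],
        {("1", 5, "A", "G"): {"s1": (HET, 5), "s2": (HET, 30)}},
    )
    cfg = ScanConfig(min_alt_reads=20, support_scope="any_sample")
    filtered, downgraded = support_filter(table, cfg)
    assert downgraded == 0
    assert filtered.get_call(("1", 5, "A", "G"), "s1").genotype == HET


def test_support_filter_spares_validation_calls():
    table = GenotypeTable(samples=["s"])
    table.add_variant(VariantRecord("1", 5, "A", "G"))
    table.set_call(("1", 5, "A", "G"), "s", GenotypeCall(HET, source="validation"))
    filtered, downgraded = support_filter(table, ScanConfig(min_alt_reads=20))
    assert downgraded == 0
    assert filtered.get_call(("1", 5, "A", "G"), "s").genotype == HET


# ---------------------------------------------------------------------------
# shared_candidates


def test_causal_pattern_is_candidate():
    affected = [f"a{i}" for i in range(7)]
    unaffected = [f"u{i}" for i in range(3)]
    ped = _flat_pedigree(affected, unaffected)
    key = ("1", 10, "A", "G")
    table = _table(affected + unaffected, {key: {a: (HET, 40) for a in affected}})
    kept, _ = shared_candidates(table, ped, ScanConfig())
    assert kept == {key}


def test_six_of_seven_affected_excluded():
    affected = [f"a{i}" for i in range(7)]
    ped = _flat_pedigree(affected, ["u0"])
    key = ("1", 10, "A", "G")
    table = _table(affected + ["u0"], {key: {a: (HET, 40) for a in affected[:6]}})
    kept, reasons = shared_candidates(table, ped, ScanConfig())
    assert kept == set()
    assert reasons[key] == "NOT_SHARED"


def test_unaffected_carrier_excluded():
    ped = _flat_pedigree(["a0"], ["u0"])
    key = ("1", 10, "A", "G")
    table = _table(["a0", "u0"], {key: {"a0": (HET, 40), "u0": (HET, 40)}})
    kept, _ = shared_candidates(table, ped, ScanConfig())
    assert kept == set()


def test_no_affected_is_error():
    ped = _flat_pedigree([], ["u0"])
    table = _table(["u0"], {})
    with pytest.raises(ScanError, match="no affected"):
        shared_candidates(table, ped, ScanConfig())


def test_missing_in_exception_requires_leniency_flag():
    ped = _flat_pedigree(["a0", "a1"], [])
    key = ("1", 10, "A", "G")
    calls = {key: {"a0": (HET, 40), "a1": (MISSING, None)}}
    strict = ScanConfig(exception_ids=frozenset({"a1"}))
    kept, _ = shared_candidates(_table(["a0", "a1"], calls), ped, strict)
    assert kept == set()
    lenient = ScanConfig(exception_ids=frozenset({"a1"}), allow_missing_in_exceptions=True)
    kept, _ = shared_candidates(_table(["a0", "a1"], calls), ped, lenient)
    assert kept == {key}


def test_shared_candidates_matches_bruteforce_oracle():
    rng = np.random.default_rng(123)
    cfg = ScanConfig(min_alt_reads=0)
    for _ in range(60):
        n_aff = int(rng.integers(1, 6))
        n_un = int(rng.integers(0, 5))
        affected = [f"a{i}" for i in range(n_aff)]
        unaffected = [f"u{i}" for i in range(n_un)]
        ped = _flat_pedigree(affected, unaffected)
        table = _random_table(rng, n_samples=0)
        table.samples.extend(affected + unaffected)
        for v in table.variants:
            for s in table.samples:
                g = rng.choice([None, HET, HOM_ALT, MISSING], p=[0.45, 0.35, 0.1, 0.1])
                if g is not None:
                    reads = None if g == MISSING else int(rng.integers(1, 60))
                    table.set_call(v.key, s, GenotypeCall(g, alt_reads=reads))
        kept, _ = shared_candidates(table, ped, cfg)
        expected = oracle_shared(table, affected, unaffected, cfg.effective_carrier_genotypes)
        assert kept == expected


def test_anti_monotone_in_affected_set():
    rng = np.random.default_rng(5)
    for _ in range(20):
        affected = ["a0", "a1", "a2"]
        ped_small = _flat_pedigree(affected[:2], ["u0"])
        ped_large = _flat_pedigree(affected, ["u0"])
        table = _random_table(rng, n_samples=0)
        table.samples.extend(affected + ["u0"])
        for v in table.variants:
            for s in table.samples:
                if rng.random() < 0.5:
                    table.set_call(v.key, s, GenotypeCall(HET, alt_reads=40))
        small, _ = shared_candidates(table, ped_small, ScanConfig())
        large, _ = shared_candidates(table, ped_large, ScanConfig())
        assert large <= small


def test_support_then_scan_equals_scan_on_predowngraded():
    rng = np.random.default_rng(17)
    cfg = ScanConfig(min_alt_reads=20)
    for _ in range(20):
        affected = ["a0", "a1"]
        unaffected = ["u0"]
        ped = _flat_pedigree(affected, unaffected)
        table = _random_table(rng, n_samples=0)
        table.samples.extend(affected + unaffected)
        for v in table.variants:
            for s in table.samples:
                if rng.random() < 0.6:
                    table.set_call(
                        v.key, s, GenotypeCall(HET, alt_reads=int(rng.integers(1, 60)))
                    )
        filtered, _ = support_filter(table, cfg)
        via_pipeline, _ = shared_candidates(filtered, ped, cfg)
        direct, _ = shared_candidates(filtered.copy(), ped, ScanConfig(min_alt_reads=0))
        assert via_pipeline == direct
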