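"""RSCU, dRSCU, optimal-codon calling, Fop and AT3."""

import math

import numpy as np
import pytest

from codonopt import codon_metrics as cm
from codonopt.fixtures import table1_fixture
from codonopt.genetic_code import STANDARD_CODE

from conftest import make_cds


def test_rscu_equal_use_is_one():
    cds = make_cds("g", ["GCT", "GCC", "GCA", "GCG"] * 2)
    prof = cm.rscu(cds)
    for codon in ("GCT", "GCC", "GCA", "GCG"):
        assert prof.rscu[codon] == pytest.approx(1.0)


def test_rscu_hand_computed_values():
    cds = make_cds("g", ["GCT"] * 3 + ["GCC"])
    prof = cm.rscu(cds)
    assert prof.rscu["GCT"] == pytest.approx(3.0)
    assert prof.rscu["GCC"] == pytest.approx(1.0)
    assert prof.rscu["GCA"] == 0.0
    assert prof.rscu["GCG"] == 0.0


def test_rscu_empty_family_undefined():
    cds = make_cds("g", ["GCT", "GCT"])
    prof = cm.rscu(cds)
    assert "AAA" not in prof.rscu and "AAG" not in prof.rscu


def test_rscu_family_sums_equal_degeneracy(random_cds):
    for cds in random_cds(10, 200):
        prof = cm.rscu(cds)
        for aa, family in STANDARD_CODE.families.items():
            present = [c for c in family if c in prof.rscu]
            if present:
                assert sum(prof.rscu[c] for c in family) == pytest.approx(
                    len(family), abs=1e-12
                )


def test_rscu_codons_with_n_excluded():
    cds = make_cds("g", ["GCT", "GCN", "GCC"])
    prof = cm.rscu(cds)
    assert prof.counts["GCT"] == 1 and prof.counts["GCC"] == 1
    assert prof.rscu["GCT"] == pytest.approx(2.0)


def test_delta_rscu_identical_sets_zero(random_cds):
    profiles = [cm.rscu(c) for c in random_cds(6, 150)]
    for rec in cm.delta_rscu(profiles, profiles):
        assert rec.delta == pytest.approx(0.0)


def test_delta_rscu_antisymmetry(random_cds):
    genes = random_cds(12, 150)
    a = [cm.rscu(c) for c in genes[:6]]
    b = [cm.rscu(c) for c in genes[6:]]
    fwd = {r.codon: r.delta for r in cm.delta_rscu(a, b)}
    rev = {r.codon: r.delta for r in cm.delta_rscu(b, a)}
    for codon in fwd:
        assert fwd[codon] == -rev[codon]


def test_delta_rscu_family_deltas_sum_to_zero(random_cds):
    # with 150 random codons per gene every family is present in every gene
    genes = random_cds(10, 400)
    a = [cm.rscu(c) for c in genes[:5]]
    b = [cm.rscu(c) for c in genes[5:]]
    records = cm.delta_rscu(a, b)
    by_aa = {}
    for r in records:
        by_aa.setdefault(r.amino_acid, []).append(r.delta)
    for aa, deltas in by_aa.items():
        assert sum(deltas) == pytest.approx(0.0, abs=1e-9)


def test_delta_rscu_sparse_codon_flagged():
    rich = [cm.rscu(make_cds(f"a{i}", ["GCT", "GCC"] * 30)) for i in range(4)]
    poor = [cm.rscu(make_cds(f"b{i}", ["GCT", "GCC"] * 30)) for i in range(4)]
    records = cm.delta_rscu(rich, poor)
    lys = next(r for r in records if r.codon == "AAA")
    assert lys.flagged and math.isnan(lys.p_raw)


def test_call_optimal_codons_on_published_table():
    records, _ = table1_fixture()
    opt = cm.call_optimal_codons(records)
    assert opt.primary_optimal["A"] == "GCT"
    assert opt.primary_nonoptimal["A"] == "GCG"
    assert opt.primary_optimal["R"] == "AGA"  # AGG positive but ns
    assert opt.primary_nonoptimal["R"] == "CGC"
    assert opt.primary_optimal["L"] == "TTA"
    assert "ACA" in opt.secondary_optimal["T"]


def test_call_optimal_codons_all_zero():
    records, _ = table1_fixture()
    null = [
        cm.DeltaRscuRecord(
            codon=r.codon, amino_acid=r.amino_acid, delta=0.0,
            mean_high=1.0, mean_low=1.0, t_stat=0.0, p_raw=1.0, p_bonf=1.0,
            n_high=10, n_low=10,
        )
        for r in records
    ]
    opt = cm.call_optimal_codons(null)
    assert not opt.primary_optimal and not opt.primary_nonoptimal


def test_fop_all_optimal_gene():
    records, _ = table1_fixture()
    opt = cm.call_optimal_codons(records)
    cds = make_cds("g", ["GCT", "AAT", "TTA"] * 10)
    assert cm.fop(cds, opt) == 1.0


def test_fop_partial_count():
    records, _ = table1_fixture()
    opt = cm.call_optimal_codons(records)
    cds = make_cds("g", ["GCT"] * 4 + ["GCC"] * 6)
    assert cm.fop(cds, opt) == pytest.approx(0.4)


def test_fop_met_trp_only_undefined():
    records, _ = table1_fixture()
    opt = cm.call_optimal_codons(records)
    cds = make_cds("g", ["ATG", "TGG"] * 5)
    assert math.isnan(cm.fop(cds, opt))


def test_fop_invariant_under_codon_permutation(rng, random_cds):
    records, _ = table1_fixture()
    opt = cm.call_optimal_codons(records)
    cds = random_cds(1, 200)[0]
    shuffled = list(cds.codons)
    rng.shuffle(shuffled)
    cds2 = make_cds("g2", shuffled)
    assert cm.fop(cds2, opt) == pytest.approx(cm.fop(cds, opt))
    assert cm.at3(cds2) == pytest.approx(cm.at3(cds))


def test_at3_extremes_and_brute_force(random_cds):
    assert cm.at3(make_cds("g", ["GCT", "GCA"] * 3)) == 1.0
    assert cm.at3(make_cds("g", ["GCC", "GCG"] * 3)) == 0.0
    cds = random_cds(1, 300)[0]
    scored = [
        c for c in cds.codons
        if len(STANDARD_CODE.families[STANDARD_CODE.codon_to_aa[c]]) > 1
    ]
    expected = sum(c[2] in "AT" for c in scored) / len(scored)
    assert cm.at3(cds) == pytest.approx(expected, abs=1e-12)


def test_at3_excludes_met_trp_by_default():
    cds = make_cds("g", ["ATG", "GCT"])
    assert cm.at3(cds) == 1.0            # only GCT scored
    assert cm.at3(cds, all_codons=True) == pytest.approx(0.5)  # ATG ends G


def test_elevated_use_threshold_closed():
    profiles = {
        "a": cm.rscu(make_cds("a", ["GTG"] * 3 + ["GTT"] * 5)),   # rscu 1.5
        "b": cm.rscu(make_cds("b", ["GTG"] * 1 + ["GTT"] * 7)),   # rscu 0.5
        "c": cm.rscu(make_cds("c", ["GCT"] * 8)),                 # family absent
    }
    got = cm.elevated_use_genes({"a", "b", "c"}, profiles, "GTG")
    assert got == frozenset({"a"})


def test_elevated_use_rejects_single_codon_family():
    with pytest.raises(ValueError):
        cm.elevated_use_genes(set(), {}, "ATG")
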