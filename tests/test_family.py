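"""Family data model: allele-presence semantics, VCF I/O, variant union and
kinship estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fascreen.family import (
    ALT,
    NOCALL,
    REF,
    Pedigree,
    Presence,
    VariantRecord,
    estimate_relatedness,
    read_family_vcf,
    test_alleles as allele_presence,
    unify_variants,
    write_family_vcf,
)
from fascreen.simulate import QuadSimConfig, simulate_family_quad

from conftest import QUAD


# ---------------------------------------------------------------------------
# allele presence
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pair, expected",
    [
        ((ALT, REF), Presence.PRESENT),
        ((REF, ALT), Presence.PRESENT),
        ((ALT, ALT), Presence.PRESENT),
        ((ALT, NOCALL), Presence.PRESENT),
        ((NOCALL, ALT), Presence.PRESENT),
        ((REF, REF), Presence.ABSENT),
        ((NOCALL, REF), Presence.NOCALL),
        ((REF, NOCALL), Presence.NOCALL),
        ((NOCALL, NOCALL), Presence.NOCALL),
    ],
)
def test_presence_partition_is_exhaustive(pair, expected):
    """All 9 call-pair combinations map to exactly one presence verdict."""
    assert allele_presence(pair) is expected


# ---------------------------------------------------------------------------
# pedigree / variant record invariants
# ---------------------------------------------------------------------------

def test_pedigree_rejects_duplicate_labels():
    with pytest.raises(ValueError, match="distinct"):
        Pedigree(father_id="A", mother_id="A", index_id="C")


def test_variant_record_invariants():
    with pytest.raises(ValueError, match="ref == alt"):
        VariantRecord(chrom="1", pos=10, ref="A", alt="A")
    with pytest.raises(ValueError, match="50 nt"):
        VariantRecord(chrom="1", pos=10, ref="A" * 60, alt="T")
    with pytest.raises(ValueError, match="MAF"):
        VariantRecord(chrom="1", pos=10, ref="A", alt="T", panel_freqs={"p": 1.5})


# ---------------------------------------------------------------------------
# variant union
# ---------------------------------------------------------------------------

def _v(pos, alt="T", chrom="1", ref="A"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt)


def test_unify_basic_union():
    v1, v2, v3 = _v(10), _v(20), _v(30)
    out = unify_variants([[v1, v2], [v2, v3]])
    assert [v.pos for v in out] == [10, 20, 30]


def test_unify_conflicting_reference_is_fatal():
    with pytest.raises(ValueError, match="conflicting reference"):
        unify_variants([[_v(10, ref="A", alt="T")], [_v(10, ref="C", alt="T")]])


@st.composite
def variant_sets(draw):
    pool = [_v(p, alt=a) for p in range(10, 40) for a in "CGT"]
    idx = draw(st.lists(st.integers(0, len(pool) - 1), max_size=15))
    return [pool[i] for i in idx]


@given(variant_sets(), variant_sets(), variant_sets())
def test_unify_commutative_associative_idempotent(a, b, c):
    key = lambda vs: [v.key for v in vs]
    assert key(unify_variants([a, b])) == key(unify_variants([b, a]))
    assert key(unify_variants([unify_variants([a, b]), c])) == key(
        unify_variants([a, unify_variants([b, c])])
    )
    u = unify_variants([a, b, c])
    assert key(unify_variants([u, u])) == key(u)


def test_unify_matches_bruteforce_on_random_sets():
    rng = np.random.default_rng(42)
    sets = []
    for _ in range(4):
        positions = rng.choice(100_000, size=1000, replace=False)
        sets.append([_v(int(p)) for p in positions])
    out = unify_variants(sets)
    brute = sorted({v.key for s in sets for v in s})
    assert [v.key for v in out] == brute


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tF\tM\tP\tS
"""


def _write_vcf(tmp_path, body):
    path = tmp_path / "fam.vcf"
    path.write_text(VCF_HEADER + body)
    return path


def test_read_simple_quad_site(tmp_path):
    path = _write_vcf(
        tmp_path, "1\t100\t.\tA\tT\t.\tPASS\t.\tGT:GQ\t0/0:99\t0/0:99\t0/1:99\t0/0:99\n"
    )
    fg = read_family_vcf(path, QUAD)
    assert len(fg) == 1
    assert fg.sample_calls(0, "P") == (REF, ALT)
    assert all(fg.sample_calls(0, s) == (REF, REF) for s in "FMS")
    assert fg.quality.all()


def test_multiallelic_record_splits_into_biallelic(tmp_path):
    path = _write_vcf(
        tmp_path, "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT:GQ\t0/1:99\t0/2:99\t1/2:99\t0/0:99\n"
    )
    fg = read_family_vcf(path, QUAD)
    assert list(fg.variants["alt"]) == ["G", "T"]
    g = fg.variants["alt"].tolist().index("G")
    t = 1 - g
    # for the G record, allele 2 (T) reads as non-carrier of G
    assert fg.sample_calls(g, "F") == (REF, ALT)
    assert fg.sample_calls(g, "M") == (REF, REF)
    assert fg.sample_calls(g, "P") == (ALT, REF)
    assert fg.sample_calls(t, "M") == (REF, ALT)
    assert fg.sample_calls(t, "P") == (REF, ALT)


def test_half_call_maps_to_nocall_alt(tmp_path):
    path = _write_vcf(
        tmp_path, "1\t100\t.\tA\tT\t.\tPASS\t.\tGT:GQ\t0/0:99\t0/0:99\t0/1:99\t./1:99\n"
    )
    fg = read_family_vcf(path, QUAD)
    assert fg.sample_calls(0, "S") == (NOCALL, ALT)


def test_low_gq_and_fail_filter_map_to_low_quality(tmp_path):
    body = (
        "1\t100\t.\tA\tT\t.\tPASS\t.\tGT:GQ\t0/1:10\t0/0:99\t0/1:99\t0/0:99\n"
        "1\t200\t.\tA\tT\t.\tq10\t.\tGT:GQ\t0/1:99\t0/0:99\t0/1:99\t0/0:99\n"
    )
    fg = read_family_vcf(_write_vcf(tmp_path, body), QUAD)
    assert fg.quality[0].tolist() == [False, True, True, True]
    assert not fg.quality[1].any()  # record-level FILTER fail


def test_missing_pedigree_sample_is_fatal(tmp_path):
    path = _write_vcf(tmp_path, "")
    missing = Pedigree(father_id="F", mother_id="M", index_id="XX")
    with pytest.raises(ValueError, match="XX"):
        read_family_vcf(path, missing)


def test_unsorted_vcf_is_fatal(tmp_path):
    body = (
        "1\t200\t.\tA\tT\t.\tPASS\t.\tGT:GQ\t0/0:99\t0/0:99\t0/1:99\t0/0:99\n"
        "1\t100\t.\tA\tT\t.\tPASS\t.\tGT:GQ\t0/0:99\t0/0:99\t0/1:99\t0/0:99\n"
    )
    with pytest.raises(ValueError, match="unsorted"):
        read_family_vcf(_write_vcf(tmp_path, body), QUAD)


def test_vcf_round_trip_preserves_calls_and_quality(tmp_path):
    sim = simulate_family_quad(
        QuadSimConfig(seed=5, n_genes=60, nocall_rate=0.05, lowq_rate=0.1)
    )
    path = tmp_path / "rt.vcf"
    write_family_vcf(sim.fg_raw, path)
    back = read_family_vcf(path, sim.pedigree)
    assert (back.calls == sim.fg_raw.calls).all()
    assert (back.quality == sim.fg_raw.quality).all()
    assert back.variants[["chrom", "pos", "ref", "alt"]].equals(
        sim.fg_raw.variants[["chrom", "pos", "ref", "alt"]]
    )


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def _mendelian_pair_fg(n_sites, seed, related=True):
    """Dedicated two-sample Mendelian simulation used as the kinship oracle:
    sites at common MAF ~ U(0.05, 0.5), parent genotypes HWE, offspring
    receives one parental allele plus one population allele."""
    import pandas as pd

    from fascreen.family import FamilyGenotypes

    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.5, n_sites)
    parent = np.stack([rng.random(n_sites) < p, rng.random(n_sites) < p], axis=1)
    if related:
        transmitted = np.where(
            rng.random(n_sites) < 0.5, parent[:, 0], parent[:, 1]
        )
    else:
        transmitted = rng.random(n_sites) < p
    other = np.stack([transmitted, rng.random(n_sites) < p], axis=1)
    calls = np.zeros((n_sites, 4, 2), dtype=np.int8)
    calls[:, 0] = parent
    calls[:, 2] = other
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_sites + 1),
            "ref": "A",
            "alt": "T",
            "vclass": "SNV",
            "freq_panel": p,
        }
    )
    return FamilyGenotypes(QUAD, variants, calls, np.ones((n_sites, 4), bool))


def test_parent_offspring_phi_near_quarter():
    fg = _mendelian_pair_fg(10_000, seed=1, related=True)
    est = estimate_relatedness(fg, "F", "P")
    assert est.phi == pytest.approx(0.25, abs=0.02)
    assert est.degree_bin == "1st-degree"


def test_unrelated_pair_phi_near_zero():
    fg = _mendelian_pair_fg(10_000, seed=2, related=False)
    est = estimate_relatedness(fg, "F", "P")
    assert abs(est.phi) < 0.02
    assert est.degree_bin == ">=9th-degree/unrelated"


def test_identical_genomes_bin_as_duplicate():
    fg = _mendelian_pair_fg(5_000, seed=3, related=True)
    fg.calls[:, 2] = fg.calls[:, 0]
    est = estimate_relatedness(fg, "F", "P")
    assert est.phi == pytest.approx(0.5, abs=1e-9)
    assert est.degree_bin == "duplicate/MZ"


def test_too_few_informative_sites_is_fatal():
    fg = _mendelian_pair_fg(500, seed=4)
    with pytest.raises(ValueError, match="informative sites"):
        estimate_relatedness(fg, "F", "P")


def test_simulated_quads_place_parents_first_degree():
    """Across 100 clean simulated quads both parent-index pairs land in the
    1st-degree bin."""
    ok = 0
    for seed in range(100):
        sim = simulate_family_quad(QuadSimConfig(seed=seed, n_genes=500))
        ped = sim.pedigree
        bins = {
            estimate_relatedness(sim.fg, ped.father_id, ped.index_id).degree_bin,
            estimate_relatedness(sim.fg, ped.mother_id, ped.index_id).degree_bin,
        }
        ok += bins == {"1st-degree"}
    assert ok >= 99
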