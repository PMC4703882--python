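"""Inheritance models: recessive homozygous, compound heterozygous with
parental-origin assignment, de novo, and segregation labels.  The compound-het
screen is checked against a brute-force enumeration oracle over parental
assignments."""

import numpy as np
import pytest

from fascreen.inheritance import (
    AMBIGUOUS,
    BIPARENTAL,
    COMPOUND_HET,
    DENOVO,
    MATERNAL,
    PATERNAL,
    CandidateHit,
    classify_segregation,
    compound_heterozygous,
    de_novo,
    recessive_homozygous,
)
from fascreen.simulate import QuadSimConfig, simulate_family_quad

from conftest import QUAD, make_fg


def _row(pos, gt, gene="GENE1", **kw):
    base = {"chrom": "1", "pos": pos, "ref": "A", "alt": "T", "gene": gene, "gt": gt}
    base.update(kw)
    return base


# ---------------------------------------------------------------------------
# recessive homozygous
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gts, expect_hit",
    [
        ({"P": "1/1", "S": "0/1", "F": "0/1", "M": "0/1"}, True),
        ({"P": "1/1", "S": "0/0", "F": "0/1", "M": "0/1"}, True),
        ({"P": "1/1", "S": "1/1", "F": "0/1", "M": "0/1"}, False),  # affected sib
        ({"P": "./1", "S": "0/1", "F": "0/1", "M": "0/1"}, False),  # index not called
        ({"P": "1/1", "S": "0/1", "F": "1/1", "M": "0/1"}, False),  # father hom
        ({"P": "1/1", "S": "./.", "F": "0/1", "M": "0/1"}, True),   # sib no-call ok
    ],
)
def test_recessive_homozygous_rule(gts, expect_hit):
    fg = make_fg([_row(1, gts)])
    hits = recessive_homozygous(fg, QUAD)
    assert (len(hits) == 1) is expect_hit


def test_recessive_requires_high_quality_index():
    fg = make_fg([_row(1, {"P": "1/1", "F": "0/1", "M": "0/1", "S": "0/1"}, lowq=["P"])])
    assert recessive_homozygous(fg, QUAD) == []


# ---------------------------------------------------------------------------
# de novo
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gts, lowq, expect_hit",
    [
        ({"P": "0/1"}, [], True),                       # everyone else 0/0 HIGH
        ({"P": "0/1", "F": "0/1"}, [], False),          # inherited
        ({"P": "0/1", "M": "./."}, [], False),          # ambiguous parent
        ({"P": "0/1", "S": "0/1"}, [], False),          # sibling carries it
        ({"P": "0/1"}, ["F"], False),                   # father call LOW
        ({"P": "./1"}, [], False),                      # index not cleanly het
    ],
)
def test_de_novo_requires_positive_absence_everywhere(gts, lowq, expect_hit):
    fg = make_fg([_row(1, gts, lowq=lowq)])
    hits = de_novo(fg, QUAD)
    assert (len(hits) == 1) is expect_hit


def test_de_novo_sibling_requirement_is_configurable():
    fg = make_fg([_row(1, {"P": "0/1", "S": "0/1"})])
    assert de_novo(fg, QUAD) == []
    assert len(de_novo(fg, QUAD, require_sibling_absent=False)) == 1


# ---------------------------------------------------------------------------
# compound heterozygous: examples
# ---------------------------------------------------------------------------

def test_compound_het_one_variant_per_parent():
    fg = make_fg([
        _row(1, {"P": "0/1", "F": "0/1", "M": "0/0", "S": "0/0"}),
        _row(2, {"P": "0/1", "F": "0/0", "M": "0/1", "S": "0/0"}),
    ])
    hits = compound_heterozygous(fg, QUAD)
    assert len(hits) == 1
    assert hits[0].origin == (PATERNAL, MATERNAL)


def test_compound_het_rejects_same_parent_pair():
    fg = make_fg([
        _row(1, {"P": "0/1", "F": "0/1", "M": "0/0", "S": "0/0"}),
        _row(2, {"P": "0/1", "F": "0/1", "M": "0/0", "S": "0/0"}),
    ])
    assert compound_heterozygous(fg, QUAD) == []


def test_compound_het_rejects_variant_present_in_sibling():
    fg = make_fg([
        _row(1, {"P": "0/1", "F": "0/1", "M": "0/0", "S": "0/1"}),
        _row(2, {"P": "0/1", "F": "0/0", "M": "0/1", "S": "0/0"}),
    ])
    assert compound_heterozygous(fg, QUAD) == []


def test_compound_het_needs_same_gene():
    fg = make_fg([
        _row(1, {"P": "0/1", "F": "0/1", "M": "0/0", "S": "0/0"}, gene="A"),
        _row(2, {"P": "0/1", "F": "0/0", "M": "0/1", "S": "0/0"}, gene="B"),
    ])
    assert compound_heterozygous(fg, QUAD) == []


def test_parent_swap_leaves_gene_hits_invariant():
    fg = make_fg([
        _row(1, {"P": "0/1", "F": "0/1", "M": "0/0", "S": "0/0"}),
        _row(2, {"P": "0/1", "F": "0/0", "M": "0/1", "S": "0/0"}),
    ])
    from fascreen.family import Pedigree

    swapped = Pedigree(father_id="M", mother_id="F", index_id="P", sibling_id="S")
    a = compound_heterozygous(fg, QUAD)
    b = compound_heterozygous(fg, swapped)
    assert {h.gene for h in a} == {h.gene for h in b}
    assert a[0].origin == tuple(reversed(b[0].origin))


# ---------------------------------------------------------------------------
# compound heterozygous: brute-force oracle
# ---------------------------------------------------------------------------

GENOTYPES = ["0/0", "0/1", "1/1", "./.", "./0", "./1"]


def _presence(gt):
    if "1" in gt:
        return "PRESENT"
    if gt == "0/0":
        return "ABSENT"
    return "NOCALL"


def _is_het(gt):
    a, b = gt.split("/")
    return (a == "1") != (b == "1")


def oracle_compound_het(site_a, site_b):
    """Direct enumeration over the two parental assignments.

    site_*: dict sample -> genotype string for F, M, P, S.
    """
    for s in (site_a, site_b):
        if not _is_het(s["P"]):
            return False
        if _presence(s["S"]) == "PRESENT":
            return False
    for va_parent, vb_parent in (("F", "M"), ("M", "F")):
        va_ok = (
            _presence(site_a[va_parent]) in ("PRESENT", "NOCALL")
            and _presence(site_a[vb_parent]) in ("ABSENT", "NOCALL")
        )
        vb_ok = (
            _presence(site_b[vb_parent]) in ("PRESENT", "NOCALL")
            and _presence(site_b[va_parent]) in ("ABSENT", "NOCALL")
        )
        if va_ok and vb_ok:
            return True
    return False


def test_compound_het_matches_oracle_with_nocalls():
    """Seeded random sampling over the full 6-genotype state space,
    including half-calls and no-calls, against the enumeration oracle."""
    rng = np.random.default_rng(2024)
    for _ in range(400):
        site_a = {s: GENOTYPES[rng.integers(6)] for s in "FMPS"}
        site_b = {s: GENOTYPES[rng.integers(6)] for s in "FMPS"}
        fg = make_fg([_row(1, site_a), _row(2, site_b)])
        got = len(compound_heterozygous(fg, QUAD)) == 1
        assert got is oracle_compound_het(site_a, site_b), (site_a, site_b)


# ---------------------------------------------------------------------------
# model disjointness and planted recovery
# ---------------------------------------------------------------------------

def test_de_novo_and_recessive_hits_disjoint_on_fully_called_data():
    sim = simulate_family_quad(QuadSimConfig(seed=21, n_genes=300))
    dn = {h.variants[0].key for h in de_novo(sim.fg, sim.pedigree)}
    rh = {h.variants[0].key for h in recessive_homozygous(sim.fg, sim.pedigree)}
    assert dn.isdisjoint(rh)


@pytest.mark.parametrize("model", [DENOVO, "RECESSIVE_HOM", "COMPOUND_HET"])
def test_planted_configuration_is_recovered(model):
    from fascreen.inheritance import DE_NOVO, RECESSIVE_HOM

    model = {"DENOVO": DE_NOVO, "RECESSIVE_HOM": RECESSIVE_HOM,
             "COMPOUND_HET": COMPOUND_HET}[model]
    fn = {DE_NOVO: de_novo, RECESSIVE_HOM: recessive_homozygous,
          COMPOUND_HET: compound_heterozygous}[model]
    sim = simulate_family_quad(QuadSimConfig(seed=33, n_genes=300,
                                             planted=((model, "TARGET"),)))
    hits = fn(sim.fg, sim.pedigree)
    assert "TARGET" in {h.gene for h in hits}


# ---------------------------------------------------------------------------
# segregation labels
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "gts, label",
    [
        ({"P": "0/1", "F": "0/1"}, PATERNAL),
        ({"P": "0/1", "M": "0/1"}, MATERNAL),
        ({"P": "0/1", "F": "0/1", "M": "0/1"}, BIPARENTAL),
        ({"P": "0/1"}, DENOVO),
        ({"P": "0/1", "F": "./."}, AMBIGUOUS),
        ({"P": "0/1", "M": "./0"}, AMBIGUOUS),
    ],
)
def test_classify_segregation_labels(gts, label):
    fg = make_fg([_row(1, gts)])
    assert classify_segregation(fg, 0, QUAD) == label


def test_candidate_hit_invariants():
    from fascreen.family import VariantRecord

    v1 = VariantRecord(chrom="1", pos=1, ref="A", alt="T")
    with pytest.raises(ValueError, match="two distinct"):
        CandidateHit(COMPOUND_HET, "G", (v1,), (PATERNAL,))
    with pytest.raises(ValueError, match="PATERNAL, MATERNAL"):
        CandidateHit(
            COMPOUND_HET, "G",
            (v1, VariantRecord(chrom="1", pos=2, ref="A", alt="T")),
            (PATERNAL, PATERNAL),
        )
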