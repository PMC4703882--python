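"""Inheritance-model candidate selection on a quad pedigree.

Three models are screened: recessive homozygous, compound heterozygous with a
parental-origin constraint, and de novo.  No-call handling differs by model:
the compound-het screen is permissive (an uncalled allele is compatible with
any required state) while the de novo screen is strict (an uncalled parental
or sibling allele disqualifies the site — a de novo claim needs positive
evidence of absence in every other family member).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .family import ALT, NOCALL, REF, FamilyGenotypes, Pedigree, Presence, VariantRecord, test_alleles

DE_NOVO = "DE_NOVO"
RECESSIVE_HOM = "RECESSIVE_HOM"
COMPOUND_HET = "COMPOUND_HET"

PATERNAL = "PATERNAL"
MATERNAL = "MATERNAL"
DENOVO = "DENOVO"
BIPARENTAL = "BIPARENTAL"
AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class CandidateHit:
    model: str
    gene: str
    variants: tuple[VariantRecord, ...]
    origin: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.model == COMPOUND_HET:
            if len(self.variants) != 2 or self.variants[0].key == self.variants[1].key:
                raise ValueError("compound-het hit needs two distinct variants")
            if set(self.origin) != {PATERNAL, MATERNAL}:
                raise ValueError("compound-het origins must be {PATERNAL, MATERNAL}")
        elif len(self.variants) != 1:
            raise ValueError(f"{self.model} hit carries exactly one variant")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "gene": self.gene,
            "variants": [
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt}
                for v in self.variants
            ],
            "origin": list(self.origin),
        }


def _cols(fg: FamilyGenotypes, ped: Pedigree):
    sib = None if ped.sibling_id is None else fg.sample_index(ped.sibling_id)
    return (
        fg.sample_index(ped.father_id),
        fg.sample_index(ped.mother_id),
        fg.sample_index(ped.index_id),
        sib,
    )


# ---------------------------------------------------------------------------
# recessive homozygous
# ---------------------------------------------------------------------------

def recessive_homozygous(fg: FamilyGenotypes, ped: Pedigree) -> list[CandidateHit]:
    """Index hom-alt (both alleles HIGH), both parents called het, sibling not
    hom-alt (uncalled sibling alleles are compatible)."""
    jf, jm, ji, js = _cols(fg, ped)
    c = fg.calls
    idx_hom = (c[:, ji] == ALT).all(axis=1) & fg.quality[:, ji]
    fa_het = np.sort(c[:, jf], axis=1)[:, 0] == REF
    fa_het &= np.sort(c[:, jf], axis=1)[:, 1] == ALT
    mo = np.sort(c[:, jm], axis=1)
    mo_het = (mo[:, 0] == REF) & (mo[:, 1] == ALT)
    hit = idx_hom & fa_het & mo_het
    if js is not None:
        sib_hom = (c[:, js] == ALT).all(axis=1)
        hit &= ~sib_hom
    return [
        CandidateHit(RECESSIVE_HOM, fg.record(i).gene, (fg.record(i),), (BIPARENTAL,))
        for i in np.flatnonzero(hit)
    ]


# ---------------------------------------------------------------------------
# de novo
# ---------------------------------------------------------------------------

def de_novo(
    fg: FamilyGenotypes, ped: Pedigree, require_sibling_absent: bool = True
) -> list[CandidateHit]:
    """Index called het with HIGH quality; father, mother (and by default the
    sibling) called hom-ref with HIGH quality.  Any NOCALL disqualifies."""
    jf, jm, ji, js = _cols(fg, ped)
    c = fg.calls
    idx = np.sort(c[:, ji], axis=1)
    idx_het = (idx[:, 0] == REF) & (idx[:, 1] == ALT) & fg.quality[:, ji]
    hit = idx_het
    for j in [jf, jm] + ([js] if js is not None and require_sibling_absent else []):
        hom_ref = (c[:, j] == REF).all(axis=1) & fg.quality[:, j]
        hit &= hom_ref
    return [
        CandidateHit(DE_NOVO, fg.record(i).gene, (fg.record(i),), (DENOVO,))
        for i in np.flatnonzero(hit)
    ]


# ---------------------------------------------------------------------------
# compound heterozygous
# ---------------------------------------------------------------------------

def _index_het(calls) -> bool:
    # exactly one ALT slot; the partner slot (REF or NOCALL) is then
    # compatible with heterozygosity under the permissive no-call reading
    a, b = int(calls[0]), int(calls[1])
    return (a == ALT) != (b == ALT)


def _can_transmit(presence: Presence) -> bool:
    return presence in (Presence.PRESENT, Presence.NOCALL)


def _can_lack(presence: Presence) -> bool:
    return presence in (Presence.ABSENT, Presence.NOCALL)


def compound_heterozygous(fg: FamilyGenotypes, ped: Pedigree) -> list[CandidateHit]:
    """Per gene, all variant pairs heterozygous in the index for which the two
    variants can be assigned to different parental genomes.

    An assignment (vA from father, vB from mother) is consistent when the
    father is PRESENT-or-NOCALL for vA and ABSENT-or-NOCALL for vB, and the
    mother the converse; the sibling must be ABSENT-or-NOCALL for both.  When
    both assignments are consistent the one with more positive parental
    PRESENT evidence is reported (ties: first variant paternal).
    """
    jf, jm, ji, js = _cols(fg, ped)
    c = fg.calls

    idx_het = np.fromiter(
        (_index_het(c[i, ji]) for i in range(len(fg))), dtype=bool, count=len(fg)
    )
    fa = np.array([test_alleles(c[i, jf]) for i in range(len(fg))], dtype=object)
    mo = np.array([test_alleles(c[i, jm]) for i in range(len(fg))], dtype=object)
    if js is not None:
        sib_ok = np.fromiter(
            (_can_lack(test_alleles(c[i, js])) for i in range(len(fg))),
            dtype=bool,
            count=len(fg),
        )
    else:
        sib_ok = np.ones(len(fg), dtype=bool)

    genes = fg.variants["gene"].fillna("").astype(str).to_numpy()
    eligible = idx_het & sib_ok & (genes != "")

    hits: list[CandidateHit] = []
    for gene in sorted(set(genes[eligible])):
        members = np.flatnonzero(eligible & (genes == gene))
        if len(members) < 2:
            continue
        for ia, ib in combinations(members.tolist(), 2):
            va_pat = (
                _can_transmit(fa[ia]) and _can_lack(mo[ia])
                and _can_transmit(mo[ib]) and _can_lack(fa[ib])
            )
            va_mat = (
                _can_transmit(mo[ia]) and _can_lack(fa[ia])
                and _can_transmit(fa[ib]) and _can_lack(mo[ib])
            )
            if not (va_pat or va_mat):
                continue
            if va_pat and va_mat:
                # prefer the assignment backed by more called PRESENT parents
                ev_pat = (fa[ia] is Presence.PRESENT) + (mo[ib] is Presence.PRESENT)
                ev_mat = (mo[ia] is Presence.PRESENT) + (fa[ib] is Presence.PRESENT)
                choose_pat = ev_pat >= ev_mat
            else:
                choose_pat = va_pat
            origin = (PATERNAL, MATERNAL) if choose_pat else (MATERNAL, PATERNAL)
            hits.append(
                CandidateHit(
                    COMPOUND_HET, gene, (fg.record(ia), fg.record(ib)), origin
                )
            )
    return hits


# ---------------------------------------------------------------------------
# segregation labelling
# ---------------------------------------------------------------------------

def classify_segregation(fg: FamilyGenotypes, i: int, ped: Pedigree) -> str:
    """Label variant i from the parental presence pattern.

    AMBIGUOUS whenever either parental presence test returns NOCALL; DENOVO
    when the index carries the variant and both parents are called reference.
    """
    jf, jm, ji, _ = _cols(fg, ped)
    fa = test_alleles(fg.calls[i, jf])
    mo = test_alleles(fg.calls[i, jm])
    if fa is Presence.NOCALL or mo is Presence.NOCALL:
        return AMBIGUOUS
    idx = test_alleles(fg.calls[i, ji])
    if fa is Presence.PRESENT and mo is Presence.PRESENT:
        return BIPARENTAL
    if fa is Presence.PRESENT:
        return PATERNAL
    if mo is Presence.PRESENT:
        return MATERNAL
    if idx is Presence.PRESENT:
        return DENOVO
    return AMBIGUOUS
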