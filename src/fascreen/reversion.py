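"""Revertant-clone classification and LOH directionality.

MMC-resistant clones of a cell line heterozygous for a deleterious RAD51
allele are genotyped at the RAD51 site, at one informative SNP in each of the
two flanking genes (CASC5 and DNAJC17, same chromosome arm) and at an
unlinked control site (DCHS2, different chromosome).  Loss of the mutant
RAD51 allele together with homozygosity of both flanking SNPs indicates loss
of heterozygosity; retained flanking heterozygosity indicates back mutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import pandas as pd
from scipy.stats import binom

LOH_RETAIN_WT = "LOH_RETAIN_WT"
BACK_MUTATION = "BACK_MUTATION"
LOH_RETAIN_MUT = "LOH_RETAIN_MUT"
NON_REVERTED = "NON_REVERTED"
AMBIGUOUS = "AMBIGUOUS"

ALLELIC_STATES = ("HET", "WT_ONLY", "MUT_ONLY", "NOCALL")
SNP_STATES = ("HET", "HOM", "NOCALL")


@dataclass(frozen=True)
class CloneGenotype:
    clone_id: str
    rad51_site: str
    casc5_snp: str
    dnajc17_snp: str
    dchs2_site: str

    def __post_init__(self) -> None:
        if self.rad51_site not in ALLELIC_STATES:
            raise ValueError(f"bad rad51 state {self.rad51_site!r}")
        if self.casc5_snp not in SNP_STATES or self.dnajc17_snp not in SNP_STATES:
            raise ValueError("flanking SNP state must be HET, HOM or NOCALL")
        if self.dchs2_site not in ALLELIC_STATES:
            raise ValueError(f"bad dchs2 state {self.dchs2_site!r}")


@dataclass(frozen=True)
class ReversionSummary:
    n_clones: int
    n_wt_only: int
    n_mut_only: int
    n_loh_wt: int
    n_backmut: int
    fraction_reverted: int  # percent, rounded to nearest integer
    class_counts: tuple
    dchs2_retained: tuple  # (clone_id, bool) per reverted clone


def classify_clone(c: CloneGenotype) -> str:
    """Mechanism call for one clone; total and mutually exclusive.

    HET at RAD51 is non-reverted regardless of flanking state.  A single
    detected allele is assigned LOH only when both flanking SNPs have gone
    homozygous, and back mutation only when both remain heterozygous; mixed
    or uncalled flanking evidence is AMBIGUOUS.  A mutant-only clone with
    heterozygous flanking SNPs (a forward mutation of the wild-type base)
    has no class in this scheme and is likewise AMBIGUOUS.
    """
    if c.rad51_site == "HET":
        return NON_REVERTED
    if c.rad51_site == "NOCALL":
        return AMBIGUOUS
    flanking = (c.casc5_snp, c.dnajc17_snp)
    if flanking == ("HOM", "HOM"):
        return LOH_RETAIN_WT if c.rad51_site == "WT_ONLY" else LOH_RETAIN_MUT
    if flanking == ("HET", "HET") and c.rad51_site == "WT_ONLY":
        return BACK_MUTATION
    return AMBIGUOUS


def summarize_reversion(clones: list[CloneGenotype]) -> ReversionSummary:
    """Counts per mechanism class and the percent of wild-type-only clones.

    The reversion percentage is n_wt_only / n_clones rounded half-up to the
    nearest integer (7 of 58 reports 12%).
    """
    if not clones:
        raise ValueError("empty clone panel")
    classes = [classify_clone(c) for c in clones]
    counts = {k: classes.count(k) for k in
              (LOH_RETAIN_WT, BACK_MUTATION, LOH_RETAIN_MUT, NON_REVERTED, AMBIGUOUS)}
    n_wt = sum(1 for c in clones if c.rad51_site == "WT_ONLY")
    n_mut = sum(1 for c in clones if c.rad51_site == "MUT_ONLY")
    frac = int(floor(100.0 * n_wt / len(clones) + 0.5))
    retained = tuple(
        (c.clone_id, c.dchs2_site in ("HET", "MUT_ONLY"))
        for c in clones
        if c.rad51_site == "WT_ONLY"
    )
    return ReversionSummary(
        n_clones=len(clones),
        n_wt_only=n_wt,
        n_mut_only=n_mut,
        n_loh_wt=counts[LOH_RETAIN_WT],
        n_backmut=counts[BACK_MUTATION],
        fraction_reverted=frac,
        class_counts=tuple(sorted(counts.items())),
        dchs2_retained=retained,
    )


def loh_direction_test(n_wt_only: int, n_mut_only: int) -> float:
    """One-sided exact binomial sign test for LOH directionality.

    Under no selective direction each reverted clone retains either allele
    with probability 1/2; returns P(X >= n_wt_only | n, 1/2).  This is an
    added formalization of the qualitative observation that no mutant-only
    clone was recovered.
    """
    n = n_wt_only + n_mut_only
    if n < 1:
        raise ValueError("need at least one reverted clone")
    return float(binom.sf(n_wt_only - 1, n, 0.5))


_LOCUS_FIELDS = {"rad51": "rad51_site", "dchs2": "dchs2_site"}


def locus_retention(clones: list[CloneGenotype], locus: str) -> dict[str, bool]:
    """Per reverted (RAD51 wild-type-only) clone: does it still carry the
    variant at the queried allelic locus?"""
    if locus not in _LOCUS_FIELDS:
        raise ValueError(f"unknown locus {locus!r}; choose from {sorted(_LOCUS_FIELDS)}")
    f = _LOCUS_FIELDS[locus]
    return {
        c.clone_id: getattr(c, f) in ("HET", "MUT_ONLY")
        for c in clones
        if c.rad51_site == "WT_ONLY"
    }


# -- I/O --------------------------------------------------------------------

def read_clone_panel(path) -> list[CloneGenotype]:
    """Read a clone panel CSV: clone_id, rad51, casc5, dnajc17, dchs2."""
    df = pd.read_csv(path)
    return [
        CloneGenotype(
            clone_id=str(r.clone_id),
            rad51_site=str(r.rad51),
            casc5_snp=str(r.casc5),
            dnajc17_snp=str(r.dnajc17),
            dchs2_site=str(r.dchs2),
        )
        for r in df.itertuples()
    ]


def summary_to_dict(s: ReversionSummary) -> dict:
    return {
        "n_clones": s.n_clones,
        "n_wt_only": s.n_wt_only,
        "n_mut_only": s.n_mut_only,
        "n_loh_wt": s.n_loh_wt,
        "n_backmut": s.n_backmut,
        "fraction_reverted_percent": s.fraction_reverted,
        "class_counts": dict(s.class_counts),
        "dchs2_retained": {cid: ok for cid, ok in s.dchs2_retained},
        "loh_direction_note": "one-sided exact binomial sign test (added formalization)",
    }
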