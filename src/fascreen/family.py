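"""Family variant data model, VCF I/O and relatedness estimation.

The central container is :class:`FamilyGenotypes`: the union of all variants
seen in any member of a quad pedigree (father, mother, affected index,
unaffected sibling), with a per-variant, per-sample pair of allele calls and a
per-genotype quality flag.  Variants are biallelic after loading (multiallelic
VCF records are split at read time), 1-based VCF coordinates throughout.

Allele calls are coded as small integers: ``REF = 0``, ``ALT = 1``,
``NOCALL = -1``.  A genotype is HIGH quality iff its record passed FILTER and
its genotype quality (GQ) is at least 20; this emulates the high-confidence
("VQHIGH"-style) call flag of array/WGS platforms that VCF does not carry
natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REF = 0
ALT = 1
NOCALL = -1

#: per-tool pathogenicity call codes used in the ``pred_*`` variant columns
DAMAGING = 1
BENIGN = 0
MISSING = -1

PREDICTOR_TOOLS = ("sift", "polyphen", "mutationtaster", "cadd")
DEFAULT_PANELS = ("1000g_eur", "esp", "cg69")

#: GQ threshold separating HIGH from LOW genotype quality
GQ_HIGH = 20


class Presence(Enum):
    """Allele-presence verdict for one genome at one variant site."""

    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    NOCALL = "NOCALL"


@dataclass(frozen=True)
class Pedigree:
    """A quad pedigree: both parents and the affected index are mandatory."""

    father_id: str
    mother_id: str
    index_id: str
    sibling_id: str | None = None

    def __post_init__(self) -> None:
        labels = [self.father_id, self.mother_id, self.index_id]
        if self.sibling_id is not None:
            labels.append(self.sibling_id)
        if len(set(labels)) != len(labels):
            raise ValueError(f"pedigree sample labels must be distinct: {labels}")

    @property
    def samples(self) -> list[str]:
        out = [self.father_id, self.mother_id, self.index_id]
        if self.sibling_id is not None:
            out.append(self.sibling_id)
        return out

    @classmethod
    def from_ped(cls, path) -> "Pedigree":
        """Read a 4-column PED-like TSV: role<TAB>sample_id per line.

        Roles are ``father``, ``mother``, ``index``, ``sibling`` (sibling
        optional).
        """
        roles: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                role, sample = line.split("\t")[:2]
                roles[role.lower()] = sample
        try:
            return cls(
                father_id=roles["father"],
                mother_id=roles["mother"],
                index_id=roles["index"],
                sibling_id=roles.get("sibling"),
            )
        except KeyError as exc:  # pragma: no cover - trivial message path
            raise ValueError(f"pedigree file {path} missing role {exc}") from exc


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with its annotations, frequencies and predictor calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str = "SNV"
    gene: str = ""
    consequence: str = ""
    splice_offset: int | None = None
    panel_freqs: dict[str, float] = field(default_factory=dict)
    predictor_calls: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if max(len(self.ref), len(self.alt)) > 50:
            raise ValueError(f"allele longer than 50 nt at {self.chrom}:{self.pos}")
        for panel, maf in self.panel_freqs.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF {maf} for panel {panel} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def classify_vclass(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "block_substitution"


class FamilyGenotypes:
    """Variant x sample allele-call matrix for a quad pedigree.

    Parameters
    ----------
    pedigree
        The quad pedigree; columns are ordered father, mother, index, sibling.
    variants
        DataFrame with at least columns chrom, pos, ref, alt.  Annotation
        columns (gene, consequence, splice_offset, vclass), per-panel
        frequency columns (``freq_<panel>``, NaN = absent from panel) and
        predictor columns (``pred_<tool>``, coded DAMAGING/BENIGN/MISSING)
        are attached by the ``attach_*`` helpers.
    calls
        int8 array of shape (n_variants, n_samples, 2) holding REF/ALT/NOCALL.
    quality
        bool array of shape (n_variants, n_samples); True = HIGH.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        variants: pd.DataFrame,
        calls: np.ndarray,
        quality: np.ndarray,
    ) -> None:
        self.pedigree = pedigree
        self.samples = pedigree.samples
        self.variants = variants.reset_index(drop=True)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.quality = np.asarray(quality, dtype=bool)
        n = len(self.variants)
        if self.calls.shape != (n, len(self.samples), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} variants x {len(self.samples)} samples x 2"
            )
        if self.quality.shape != (n, len(self.samples)):
            raise ValueError("quality shape does not match variants x samples")

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def sample_calls(self, i: int, sample: str) -> tuple[int, int]:
        j = self.sample_index(sample)
        return tuple(int(x) for x in self.calls[i, j])

    def subset(self, mask: np.ndarray) -> "FamilyGenotypes":
        mask = np.asarray(mask)
        return FamilyGenotypes(
            self.pedigree,
            self.variants.loc[mask].reset_index(drop=True),
            self.calls[mask],
            self.quality[mask],
        )

    def record(self, i: int) -> VariantRecord:
        row = self.variants.iloc[i]
        freqs = {
            c[len("freq_"):]: float(row[c])
            for c in self.variants.columns
            if c.startswith("freq_") and pd.notna(row[c])
        }
        preds = {
            c[len("pred_"):]: int(row[c])
            for c in self.variants.columns
            if c.startswith("pred_")
        }
        return VariantRecord(
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            vclass=str(row.get("vclass", classify_vclass(row["ref"], row["alt"]))),
            gene=str(row.get("gene", "") or ""),
            consequence=str(row.get("consequence", "") or ""),
            splice_offset=None
            if "splice_offset" not in row or pd.isna(row["splice_offset"])
            else int(row["splice_offset"]),
            panel_freqs=freqs,
            predictor_calls=preds,
        )


# ---------------------------------------------------------------------------
# allele-presence semantics
# ---------------------------------------------------------------------------

def test_alleles(calls: Sequence[int]) -> Presence:
    """Allele-presence test for one genome at one biallelic site.

    PRESENT iff at least one slot carries the alternate allele; ABSENT iff
    both slots are called reference; NOCALL otherwise (any uncalled slot
    without positive evidence).
    """
    a, b = int(calls[0]), int(calls[1])
    if a == ALT or b == ALT:
        return Presence.PRESENT
    if a == REF and b == REF:
        return Presence.ABSENT
    return Presence.NOCALL


def unify_variants(
    per_sample_sets: Iterable[Iterable[VariantRecord]],
) -> list[VariantRecord]:
    """Union of per-genome variant sets keyed by (chrom, pos, ref, alt).

    Order is deterministic: sorted by chromosome (natural order), position,
    ref, alt.  Two records with the same (chrom, pos) span but different ref
    alleles indicate an inconsistent reference and are fatal.
    """
    merged: dict[tuple[str, int, str, str], VariantRecord] = {}
    ref_at: dict[tuple[str, int, int], str] = {}
    for sample_set in per_sample_sets:
        for v in sample_set:
            span = (v.chrom, v.pos, len(v.ref))
            if span in ref_at and ref_at[span] != v.ref:
                raise ValueError(
                    f"conflicting reference alleles at {v.chrom}:{v.pos}: "
                    f"{ref_at[span]!r} vs {v.ref!r}"
                )
            ref_at[span] = v.ref
            merged.setdefault(v.key, v)
    return sorted(merged.values(), key=lambda v: (_chrom_rank(v.chrom), v.pos, v.ref, v.alt))


def _chrom_rank(chrom: str) -> tuple[int, str]:
    c = chrom.removeprefix("chr")
    return (0, f"{int(c):03d}") if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_family_vcf(path, ped: Pedigree) -> FamilyGenotypes:
    """Load a multi-sample VCF into a :class:`FamilyGenotypes`.

    Multiallelic records are split into biallelic records at the same
    position; for the record carrying alternate allele k, genotype allele k
    maps to ALT, any other called allele to REF, and ``.`` to NOCALL.  A
    genotype is HIGH iff the record FILTER is PASS (or missing) and the
    sample GQ is >= 20 (absent GQ defaults to HIGH).  Output is sorted by
    (chrom, pos); unsorted input is fatal, as are missing pedigree samples
    and non-diploid genotypes.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    for s in ped.samples:
        if s not in vcf_samples:
            raise ValueError(f"pedigree sample {s!r} not in VCF header {vcf_samples}")
    cols = [vcf_samples.index(s) for s in ped.samples]

    rows: list[tuple] = []
    calls: list[list[list[int]]] = []
    qual: list[list[bool]] = []
    last: tuple[tuple[int, str], int] | None = None
    seen_chroms: set[str] = set()
    for rec in vcf:
        key = (_chrom_rank(rec.CHROM), rec.POS)
        if last is not None:
            if key[0] != last[0] and rec.CHROM in seen_chroms:
                raise ValueError(f"unsorted VCF: chromosome {rec.CHROM} re-appears")
            if key[0] == last[0] and rec.POS < last[1]:
                raise ValueError(f"unsorted VCF at {rec.CHROM}:{rec.POS}")
        last = key
        seen_chroms.add(rec.CHROM)

        gts = rec.genotypes  # [a0, a1, ..., phased]
        for j in cols:
            if len(gts[j]) != 3:  # two allele slots + phase flag
                raise ValueError(
                    f"non-diploid genotype for sample {ped.samples[cols.index(j)]} "
                    f"at {rec.CHROM}:{rec.POS}"
                )
        filter_pass = rec.FILTER is None  # cyvcf2: None == PASS/'.'
        try:
            gq = rec.format("GQ")
        except KeyError:
            gq = None
        for k, alt in enumerate(rec.ALT, start=1):
            row_calls = []
            row_qual = []
            for j in cols:
                pair = []
                for slot in gts[j][:2]:
                    if slot < 0:
                        pair.append(NOCALL)
                    elif slot == k:
                        pair.append(ALT)
                    else:
                        pair.append(REF)
                row_calls.append(pair)
                if gq is None or np.isnan(float(gq[j][0])):
                    high = filter_pass
                else:
                    high = filter_pass and float(gq[j][0]) >= GQ_HIGH
                row_qual.append(high)
            rows.append((rec.CHROM, rec.POS, rec.REF, alt, classify_vclass(rec.REF, alt)))
            calls.append(row_calls)
            qual.append(row_qual)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vclass"])
    calls_arr = (
        np.asarray(calls, dtype=np.int8)
        if calls
        else np.zeros((0, len(ped.samples), 2), dtype=np.int8)
    )
    qual_arr = (
        np.asarray(qual, dtype=bool)
        if qual
        else np.zeros((0, len(ped.samples)), dtype=bool)
    )
    order = np.lexsort(
        (
            variants["alt"].to_numpy(),
            variants["ref"].to_numpy(),
            variants["pos"].to_numpy(),
            variants["chrom"].map(lambda c: _chrom_rank(c)[1]).to_numpy(),
        )
    ) if len(variants) else np.array([], dtype=int)
    variants = variants.iloc[order].reset_index(drop=True)
    return FamilyGenotypes(ped, variants, calls_arr[order], qual_arr[order])


def write_family_vcf(fg: FamilyGenotypes, path) -> None:
    """Write a FamilyGenotypes back out as plain-text VCF 4.2.

    Quality flags are encoded as GQ (HIGH -> 99, LOW -> 5) so that a read
    round-trip restores them under the GQ >= 20 rule.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(fg.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(fg.samples)
            + "\n"
        )
        sym = {REF: "0", ALT: "1", NOCALL: "."}
        for i in range(len(fg)):
            row = fg.variants.iloc[i]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                ".",
                str(row["ref"]),
                str(row["alt"]),
                ".",
                "PASS",
                ".",
                "GT:GQ",
            ]
            for j in range(len(fg.samples)):
                gt = "/".join(sym[int(x)] for x in fg.calls[i, j])
                gq = "99" if fg.quality[i, j] else "5"
                fields.append(f"{gt}:{gq}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# annotation / score / frequency attachment
# ---------------------------------------------------------------------------

_KEY = ["chrom", "pos", "ref", "alt"]


def _normalise_key(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    return df


def attach_annotations(fg: FamilyGenotypes, ann: pd.DataFrame) -> FamilyGenotypes:
    """Attach gene / consequence / splice_offset columns by variant key."""
    ann = _normalise_key(ann)[_KEY + ["gene", "consequence", "splice_offset"]]
    merged = _normalise_key(fg.variants).merge(ann, on=_KEY, how="left")
    merged["gene"] = merged["gene"].fillna("")
    merged["consequence"] = merged["consequence"].fillna("")
    return FamilyGenotypes(fg.pedigree, merged, fg.calls, fg.quality)


#: default raw-score binarization cut-offs (overridable); the categorical
#: MutationTaster classes A and D count as damaging
SCORE_CUTOFFS = {"sift": 0.05, "polyphen": 0.446, "cadd": 20.0}


def binarize_scores(scores: pd.DataFrame, cutoffs: dict | None = None) -> pd.DataFrame:
    """Map raw predictor scores to DAMAGING/BENIGN/MISSING codes.

    SIFT is damaging at or below its cut-off; PolyPhen and CADD at or above;
    MutationTaster arrives as a class letter (A/D damaging, N/P benign).
    """
    cut = dict(SCORE_CUTOFFS)
    if cutoffs:
        cut.update(cutoffs)
    out = _normalise_key(scores)[_KEY].copy()
    for tool in PREDICTOR_TOOLS:
        col = scores[tool] if tool in scores else pd.Series(np.nan, index=scores.index)
        if tool == "mutationtaster":
            vals = col.astype("string").str.upper()
            coded = np.where(
                vals.isin(["A", "D"]), DAMAGING, np.where(vals.isna(), MISSING, BENIGN)
            )
        else:
            num = pd.to_numeric(col, errors="coerce")
            if tool == "sift":
                dam = num <= cut["sift"]
            else:
                dam = num >= cut[tool]
            coded = np.where(num.isna(), MISSING, np.where(dam, DAMAGING, BENIGN))
        out[f"pred_{tool}"] = coded.astype(np.int8)
    return out


def attach_scores(
    fg: FamilyGenotypes, scores: pd.DataFrame, cutoffs: dict | None = None
) -> FamilyGenotypes:
    """Attach per-tool pathogenicity calls; raw scores are binarized first."""
    pred_cols = [c for c in scores.columns if c.startswith("pred_")]
    if pred_cols:
        coded = _normalise_key(scores)[_KEY + pred_cols]
    else:
        coded = binarize_scores(scores, cutoffs)
    merged = _normalise_key(fg.variants).merge(coded, on=_KEY, how="left")
    for tool in PREDICTOR_TOOLS:
        col = f"pred_{tool}"
        if col not in merged:
            merged[col] = MISSING
        merged[col] = merged[col].fillna(MISSING).astype(np.int8)
    return FamilyGenotypes(fg.pedigree, merged, fg.calls, fg.quality)


def attach_frequencies(fg: FamilyGenotypes, freqs: pd.DataFrame) -> FamilyGenotypes:
    """Attach per-panel MAF columns from a long table (variant key, panel, maf)."""
    freqs = _normalise_key(freqs)
    bad = freqs[(freqs["maf"] < 0) | (freqs["maf"] > 1)]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(f"MAF {r['maf']} outside [0, 1] at {r['chrom']}:{r['pos']}")
    wide = freqs.pivot_table(index=_KEY, columns="panel", values="maf", aggfunc="first")
    wide.columns = [f"freq_{p}" for p in wide.columns]
    merged = _normalise_key(fg.variants).merge(
        wide.reset_index(), on=_KEY, how="left"
    )
    return FamilyGenotypes(fg.pedigree, merged, fg.calls, fg.quality)


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

#: kinship degree-bin labels; bin d covers phi >= 2^-(d + 3/2), d = 0 meaning
#: duplicate/monozygotic.  Below the 9th-degree boundary (2^-10.5) a pair is
#: reported unrelated.
DEGREE_LABELS = {0: "duplicate/MZ"}
MAX_DEGREE = 9


@dataclass(frozen=True)
class KinshipEstimate:
    phi: float
    degree_bin: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 0.5:
            raise ValueError(f"phi {self.phi} outside [0, 0.5]")


def degree_bin(phi: float) -> str:
    for d in range(0, MAX_DEGREE + 1):
        if phi >= 2.0 ** -(d + 1.5):
            return DEGREE_LABELS.get(d, f"{d}th-degree" if d > 3 else f"{d}{'st' if d == 1 else 'nd' if d == 2 else 'rd'}-degree")
    return ">=9th-degree/unrelated"


def estimate_relatedness(
    fg: FamilyGenotypes, a: str, b: str, min_sites: int = 1000
) -> KinshipEstimate:
    """Robust method-of-moments kinship coefficient from genotype concordance.

    Uses biallelic SNVs fully called in both genomes with a known panel
    frequency, and the within-pair concordance moments

        phi_hat = (N_hh - 2 N_opp) / (N_het_a + N_het_b)

    where N_hh counts sites heterozygous in both genomes, N_opp sites with
    opposite homozygotes and N_het the per-genome heterozygote counts.
    Parent-offspring pairs land near 0.25, duplicates near 0.5, unrelated
    pairs near 0.  Unlike the classic frequency-product estimator this ratio
    is insensitive to the carrier ascertainment inherent in a union of
    family variants (sites carried by nobody never enter the call set).
    The degree bin uses the standard log2 boundaries phi >= 2^-(d + 3/2).
    """
    ja, jb = fg.sample_index(a), fg.sample_index(b)
    freq_cols = [c for c in fg.variants.columns if c.startswith("freq_")]
    if not freq_cols:
        raise ValueError("no panel frequency columns attached")
    p = fg.variants[freq_cols].mean(axis=1).to_numpy()
    ga = fg.calls[:, ja].sum(axis=1)
    gb = fg.calls[:, jb].sum(axis=1)
    called = (fg.calls[:, ja] >= 0).all(axis=1) & (fg.calls[:, jb] >= 0).all(axis=1)
    is_snv = (fg.variants["vclass"] == "SNV").to_numpy() if "vclass" in fg.variants else np.ones(len(fg), bool)
    ok = called & is_snv & np.isfinite(p) & (p > 0) & (p < 1)
    n = int(ok.sum())
    if n < min_sites:
        raise ValueError(f"only {n} informative sites (need >= {min_sites})")
    het_a = ga[ok] == 1
    het_b = gb[ok] == 1
    n_hh = int((het_a & het_b).sum())
    n_opp = int((np.abs(ga[ok] - gb[ok]) == 2).sum())
    den = int(het_a.sum()) + int(het_b.sum())
    if den == 0:
        raise ValueError("no heterozygous sites in either genome")
    phi = min(0.5, max(0.0, (n_hh - 2.0 * n_opp) / den))
    return KinshipEstimate(phi=phi, degree_bin=degree_bin(phi))


def kinship_report(fg: FamilyGenotypes, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for a, b in pairs:
        est = estimate_relatedness(fg, a, b)
        rows.append({"sample_a": a, "sample_b": b, "phi": est.phi, "degree": est.degree_bin})
    return pd.DataFrame(rows)
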