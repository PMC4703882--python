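"""Synthetic-data generators with planted ground truth.

Every input the analysis consumes can be generated here: Mendelian quad
genotypes with annotation/score/frequency tables, revertant clone panels,
worm-like-chain filament height maps, and titration / time-course tables.
All generators are pure functions of (config, seed).

The family generator draws parental genotypes from panel allele frequencies
under Hardy-Weinberg, transmits alleles Mendelianly to the two children, and
then injects no-calls and symmetric allele-flip errors at configured rates.
Causal variants are planted on top of that background: a de novo variant
(index het, everyone else hom-ref), a recessive homozygote (index hom-alt,
parents het) or a compound-het pair (one paternal, one maternal variant in
the same gene), each rare/absent in all panels and called damaging by three
of the four predictors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .family import (
    ALT,
    NOCALL,
    REF,
    DEFAULT_PANELS,
    FamilyGenotypes,
    Pedigree,
    attach_annotations,
    attach_frequencies,
    attach_scores,
    write_family_vcf,
)
from .inheritance import COMPOUND_HET, DE_NOVO, RECESSIVE_HOM
from .morphometry import FilamentTrace, MorphometryConstants, SFMImage
from .reversion import BACK_MUTATION, LOH_RETAIN_MUT, LOH_RETAIN_WT, NON_REVERTED

DEFAULT_PED = Pedigree(father_id="FATHER", mother_id="MOTHER",
                       index_id="INDEX", sibling_id="SIBLING")

# background consequence-class frequencies, roughly whole-genome-like: the
# vast majority of small variants are non-coding, a few percent exonic
_CONSEQ_CLASSES = [
    ("intergenic", 0.48), ("intronic", 0.30), ("ncRNA", 0.02),
    ("utr3", 0.04), ("utr5", 0.03), ("synonymous", 0.10),
    ("non_synonymous", 0.0235), ("splice", 0.004),
    ("frameshift_insertion", 0.0005), ("frameshift_deletion", 0.0005),
    ("non_frameshift_insertion", 0.0003), ("non_frameshift_deletion", 0.0003),
    ("non_frameshift_substitution", 0.0002), ("stop_gain", 0.0006),
    ("stop_loss", 0.0001),
]
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class QuadSimConfig:
    """Study conditions for a simulated quad.

    Defaults give ~10,000 background variants (2,000 genes x 5 variants)
    with a Beta(0.3, 3) site-frequency spectrum (many rare, some common),
    clean calls (no-call and error rates zero) and no planted causal
    variant.
    """

    n_genes: int = 2000
    variants_per_gene: int = 5
    maf_beta: tuple[float, float] = (0.3, 3.0)
    panels: tuple[str, ...] = DEFAULT_PANELS
    panel_missing_rate: float = 0.05
    nocall_rate: float = 0.0
    genotype_error_rate: float = 0.0
    lowq_rate: float = 0.0
    damaging_rate: float = 0.05   # per-tool background DAMAGING probability
    score_missing_rate: float = 0.05
    planted: tuple[tuple[str, str | None], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.panel_missing_rate, self.nocall_rate,
                  self.genotype_error_rate, self.lowq_rate,
                  self.damaging_rate, self.score_missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class QuadGroundTruth:
    planted: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"planted": self.planted}


@dataclass
class QuadSim:
    """In-memory bundle of everything the family pipeline consumes."""

    pedigree: Pedigree
    fg: FamilyGenotypes          # fully annotated
    fg_raw: FamilyGenotypes      # calls only (what the VCF carries)
    annotations: pd.DataFrame
    scores: pd.DataFrame
    frequencies: pd.DataFrame
    truth: QuadGroundTruth

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "family.vcf",
            "annotations": outdir / "annotations.tsv",
            "scores": outdir / "scores.tsv",
            "frequencies": outdir / "frequencies.tsv",
            "pedigree": outdir / "pedigree.ped",
            "truth": outdir / "ground_truth.json",
        }
        write_family_vcf(self.fg_raw, paths["vcf"])
        self.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        self.scores.to_csv(paths["scores"], sep="\t", index=False)
        self.frequencies.to_csv(paths["frequencies"], sep="\t", index=False)
        ped = self.pedigree
        lines = [f"father\t{ped.father_id}", f"mother\t{ped.mother_id}",
                 f"index\t{ped.index_id}"]
        if ped.sibling_id:
            lines.append(f"sibling\t{ped.sibling_id}")
        paths["pedigree"].write_text("\n".join(lines) + "\n")
        paths["truth"].write_text(json.dumps(self.truth.to_dict(), indent=2))
        return paths


def _transmit(rng: np.random.Generator, dose: np.ndarray) -> np.ndarray:
    """One Mendelian allele per site from a parent with given alt dosage."""
    return np.where(rng.random(len(dose)) < dose / 2.0, ALT, REF).astype(np.int8)


def _parent_doses_conditional(
    rng: np.random.Generator, maf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (father, mother) alt dosages under HWE at each site's MAF,
    conditioned on dosage sum >= 1 (inverse-CDF over the 8 remaining
    dosage combinations)."""
    n = len(maf)
    p0 = (1 - maf) ** 2
    p1 = 2 * maf * (1 - maf)
    p2 = maf**2
    combos = np.array([(a, b) for a in (0, 1, 2) for b in (0, 1, 2) if (a, b) != (0, 0)])
    probs = np.empty((n, len(combos)))
    marg = {0: p0, 1: p1, 2: p2}
    for k, (a, b) in enumerate(combos):
        probs[:, k] = marg[a] * marg[b]
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    pick = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
    chosen = combos[pick]
    return chosen[:, 0].astype(np.int8), chosen[:, 1].astype(np.int8)


def simulate_family_quad(cfg: QuadSimConfig, ped: Pedigree = DEFAULT_PED) -> QuadSim:
    rng = np.random.default_rng(cfg.seed)
    n_bg = cfg.n_genes * cfg.variants_per_gene

    # --- background sites -------------------------------------------------
    gene_idx = np.repeat(np.arange(cfg.n_genes), cfg.variants_per_gene)
    genes = np.array([f"G{g:05d}" for g in gene_idx])
    chroms = np.array([f"{(g % 22) + 1}" for g in gene_idx])
    gene_start = 100_000 + (gene_idx // 22) * 50_000
    offsets = np.sort(
        rng.choice(np.arange(1, 40_000), size=(cfg.n_genes, cfg.variants_per_gene),
                   replace=True), axis=1,
    )
    # ensure unique positions within a gene
    offsets += np.arange(cfg.variants_per_gene)[None, :]
    pos = gene_start + offsets.reshape(-1)

    ref_b = _BASES[rng.integers(0, 4, n_bg)]
    alt_shift = rng.integers(1, 4, n_bg)
    alt_b = _BASES[(np.searchsorted(_BASES, ref_b) + alt_shift) % 4]

    maf = rng.beta(*cfg.maf_beta, n_bg).clip(1e-4, 0.5)

    conseq_labels = np.array([c for c, _ in _CONSEQ_CLASSES])
    conseq_p = np.array([p for _, p in _CONSEQ_CLASSES])
    conseq = rng.choice(conseq_labels, size=n_bg, p=conseq_p / conseq_p.sum())
    splice_off = np.full(n_bg, np.nan)
    is_splice = conseq == "splice"
    off = rng.integers(1, 9, is_splice.sum()) * rng.choice([-1, 1], is_splice.sum())
    splice_off[is_splice] = off

    # genotypes: parents HWE at maf, jointly conditioned on >= 1 parental
    # carrier (a union of family variants contains no zero-carrier site),
    # children by Mendelian transmission
    fa_dose, mo_dose = _parent_doses_conditional(rng, maf)
    calls = np.zeros((n_bg, 4, 2), dtype=np.int8)
    calls[:, 0, 0] = (fa_dose == 2).astype(np.int8)
    calls[:, 0, 1] = (fa_dose >= 1).astype(np.int8)
    calls[:, 1, 0] = (mo_dose == 2).astype(np.int8)
    calls[:, 1, 1] = (mo_dose >= 1).astype(np.int8)
    calls[:, 2, 0] = _transmit(rng, fa_dose)
    calls[:, 2, 1] = _transmit(rng, mo_dose)
    calls[:, 3, 0] = _transmit(rng, fa_dose)
    calls[:, 3, 1] = _transmit(rng, mo_dose)

    # predictor calls and panel frequencies
    n_tools = 4
    u = rng.random((n_bg, n_tools))
    pred = np.where(u < cfg.damaging_rate, 1,
                    np.where(u < cfg.damaging_rate + cfg.score_missing_rate, -1, 0))
    panel_freq = np.empty((n_bg, len(cfg.panels)))
    for k in range(len(cfg.panels)):
        jitter = rng.lognormal(0.0, 0.2, n_bg)
        panel_freq[:, k] = np.clip(maf * jitter, 0.0, 0.5)
    panel_present = rng.random((n_bg, len(cfg.panels))) >= cfg.panel_missing_rate

    rows = {
        "chrom": chroms, "pos": pos, "ref": ref_b, "alt": alt_b,
        "gene": genes, "consequence": conseq, "splice_offset": splice_off,
        "pred": list(pred), "panel_freq": list(panel_freq),
        "panel_present": list(panel_present),
        "calls": list(calls),
    }
    df = pd.DataFrame(rows)

    # --- planted causal variants ------------------------------------------
    truth = QuadGroundTruth()
    used_genes: set[str] = set()
    extra: list[dict] = []
    auto_gene = iter(f"CAUSAL{i:02d}" for i in range(1, 100))
    for model, gene in cfg.planted:
        gene = gene or next(auto_gene)
        if gene in used_genes:
            raise ValueError(f"planted gene collision: {gene}")
        used_genes.add(gene)
        chrom = "15"
        base_pos = 41_000_000 + len(extra) * 10_000
        damaging = np.array([1, 1, 1, 0], dtype=np.int8)
        absent = np.zeros(len(cfg.panels), dtype=bool)

        def planted_row(pos_, calls_, origin):
            return {
                "chrom": chrom, "pos": pos_, "ref": "G", "alt": "A",
                "gene": gene, "consequence": "non_synonymous",
                "splice_offset": np.nan, "pred": damaging,
                "panel_freq": np.zeros(len(cfg.panels)),
                "panel_present": absent, "calls": np.array(calls_, dtype=np.int8),
                "_origin": origin,
            }

        if model == DE_NOVO:
            r = planted_row(base_pos, [[0, 0], [0, 0], [0, 1], [0, 0]], "DENOVO")
            extra.append(r)
            truth.planted.append({"model": model, "gene": gene,
                                  "keys": [[chrom, r["pos"], "G", "A"]],
                                  "origins": ["DENOVO"]})
        elif model == RECESSIVE_HOM:
            sib = [0, 1] if rng.random() < 0.5 else [0, 0]
            r = planted_row(base_pos, [[0, 1], [0, 1], [1, 1], sib], "BIPARENTAL")
            extra.append(r)
            truth.planted.append({"model": model, "gene": gene,
                                  "keys": [[chrom, r["pos"], "G", "A"]],
                                  "origins": ["BIPARENTAL"]})
        elif model == COMPOUND_HET:
            ra = planted_row(base_pos, [[0, 1], [0, 0], [1, 0], [0, 0]], "PATERNAL")
            rb = planted_row(base_pos + 500, [[0, 0], [0, 1], [0, 1], [0, 0]], "MATERNAL")
            extra.extend([ra, rb])
            truth.planted.append({"model": model, "gene": gene,
                                  "keys": [[chrom, ra["pos"], "G", "A"],
                                           [chrom, rb["pos"], "G", "A"]],
                                  "origins": ["PATERNAL", "MATERNAL"]})
        else:
            raise ValueError(f"unknown planted model {model!r}")
    if extra:
        df = pd.concat([df, pd.DataFrame(extra).drop(columns=["_origin"])],
                       ignore_index=True)

    # --- noise injection ---------------------------------------------------
    n = len(df)
    calls = np.stack(df["calls"].to_numpy())
    if cfg.genotype_error_rate > 0:
        flip = rng.random((n, 4, 2)) < cfg.genotype_error_rate
        calls = np.where(flip & (calls >= 0), 1 - calls, calls).astype(np.int8)
    if cfg.nocall_rate > 0:
        nc = rng.random((n, 4, 2)) < cfg.nocall_rate
        calls = np.where(nc, NOCALL, calls).astype(np.int8)
    quality = rng.random((n, 4)) >= cfg.lowq_rate

    # --- assemble tables ---------------------------------------------------
    order = np.lexsort((df["pos"].to_numpy(),
                        df["chrom"].map(lambda c: int(c)).to_numpy()))
    df = df.iloc[order].reset_index(drop=True)
    calls, quality = calls[order], quality[order]

    key_cols = df[["chrom", "pos", "ref", "alt"]]
    ann = key_cols.copy()
    ann["gene"] = df["gene"]
    ann["consequence"] = df["consequence"]
    ann["splice_offset"] = df["splice_offset"]

    pred = np.stack(df["pred"].to_numpy())
    scores = key_cols.copy()
    scores["sift"] = _raw_score(rng, pred[:, 0], lambda r, k: r.uniform(0, 0.05, k),
                                lambda r, k: r.uniform(0.06, 1.0, k))
    scores["polyphen"] = _raw_score(rng, pred[:, 1], lambda r, k: r.uniform(0.446, 1.0, k),
                                    lambda r, k: r.uniform(0.0, 0.44, k))
    mt = np.where(pred[:, 2] == 1, "D", np.where(pred[:, 2] == -1, "", "N"))
    scores["mutationtaster"] = mt
    scores["cadd"] = _raw_score(rng, pred[:, 3], lambda r, k: r.uniform(20.0, 45.0, k),
                                lambda r, k: r.uniform(0.0, 19.9, k))

    pf = np.stack(df["panel_freq"].to_numpy())
    pp = np.stack(df["panel_present"].to_numpy())
    freq_rows = []
    for k, panel in enumerate(cfg.panels):
        sel = pp[:, k]
        sub = key_cols.loc[sel].copy()
        sub["panel"] = panel
        sub["maf"] = pf[sel, k]
        freq_rows.append(sub)
    freqs = pd.concat(freq_rows, ignore_index=True).sort_values(
        ["chrom", "pos", "panel"], kind="mergesort").reset_index(drop=True)

    variants = key_cols.copy()
    variants["vclass"] = "SNV"
    fg_raw = FamilyGenotypes(ped, variants, calls, quality)
    fg = attach_annotations(fg_raw, ann)
    fg = attach_scores(fg, scores)
    fg = attach_frequencies(fg, freqs)
    return QuadSim(pedigree=ped, fg=fg, fg_raw=fg_raw, annotations=ann,
                   scores=scores, frequencies=freqs, truth=truth)


def _raw_score(rng, calls, damaging_sampler, benign_sampler) -> np.ndarray:
    out = np.full(len(calls), np.nan)
    dam = calls == 1
    ben = calls == 0
    out[dam] = damaging_sampler(rng, int(dam.sum()))
    out[ben] = benign_sampler(rng, int(ben.sum()))
    return out


# ---------------------------------------------------------------------------
# clone panels
# ---------------------------------------------------------------------------

_MECHANISM_STATES = {
    LOH_RETAIN_WT: ("WT_ONLY", "HOM", "HOM"),
    BACK_MUTATION: ("WT_ONLY", "HET", "HET"),
    LOH_RETAIN_MUT: ("MUT_ONLY", "HOM", "HOM"),
}


def simulate_clone_panel(
    n_clones: int = 58,
    reverted_fraction: float = 7 / 58,
    mechanism_mix: dict[str, float] | None = None,
    nocall_rate: float = 0.0,
    dchs2_retained: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Clone panel with a planted reversion fraction and mechanism mix.

    Returns (panel DataFrame with columns clone_id/rad51/casc5/dnajc17/dchs2,
    ground-truth dict with the per-clone mechanism labels).  The unlinked
    DCHS2 control variant is retained in every clone by default.
    """
    if not 0.0 <= reverted_fraction <= 1.0:
        raise ValueError("reverted_fraction must lie in [0, 1]")
    mix = mechanism_mix or {LOH_RETAIN_WT: 1.0}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mechanism_mix sums to {total}, not 1")
    unknown = set(mix) - set(_MECHANISM_STATES)
    if unknown:
        raise ValueError(f"unknown mechanisms {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_rev = int(round(n_clones * reverted_fraction))
    mechanisms = list(rng.choice(list(mix), size=n_rev, p=list(mix.values())))
    labels = mechanisms + [NON_REVERTED] * (n_clones - n_rev)

    rows = []
    for i, mech in enumerate(labels):
        if mech == NON_REVERTED:
            rad51, casc5, dnajc17 = "HET", "HET", "HET"
        else:
            rad51, casc5, dnajc17 = _MECHANISM_STATES[mech]
        dchs2 = "HET" if dchs2_retained else "WT_ONLY"
        states = [rad51, casc5, dnajc17, dchs2]
        if nocall_rate > 0:
            states = [s if rng.random() >= nocall_rate else "NOCALL" for s in states]
        rows.append({"clone_id": f"clone{i + 1:03d}", "rad51": states[0],
                     "casc5": states[1], "dnajc17": states[2], "dchs2": states[3]})
    panel = pd.DataFrame(rows)
    truth = {"mechanisms": {r["clone_id"]: m for r, m in zip(rows, labels)},
             "n_reverted": n_rev}
    return panel, truth


# ---------------------------------------------------------------------------
# filament renders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilamentRenderConfig:
    """Worm-like-chain render of one filament in a square field of view.

    Geometry follows the 1.5-fold extension of protein-coated B-form DNA:
    coated stretches rise 0.51 nm/bp, bare (gap) stretches 0.34 nm/bp.
    Heights are the filament apex height for coated DNA and a lower bare-DNA
    height inside gaps; the probe is emulated by a Gaussian ridge
    cross-section of width ``blur_sigma_px`` pixels, and instrument noise is
    additive Gaussian.  Persistence lengths are generator parameters, not
    measurements.
    """

    dna_bp: int = 3901
    coverage_fraction: float = 1.0
    n_gaps: int = 0
    gap_length_bp: int = 90  # a gap must exceed ~2x the tip radius to read sub-1 nm
    mean_height_nm: float = 2.2
    bare_height_nm: float = 0.5
    noise_sd_nm: float = 0.15
    persistence_nm: float = 200.0
    bare_persistence_nm: float = 50.0
    pixel_size_nm: float = 1500.0 / 512.0
    field_px: int = 512
    blur_sigma_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dna_bp <= 0:
            raise ValueError("dna_bp must be positive")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in [0, 1]")


def _place_gaps(rng, dna_bp: int, n_gaps: int, gap_bp: int,
                margin_bp: int, sep_bp: int) -> list[tuple[int, int]]:
    """Non-overlapping gap intervals with end margins and minimum separation,
    drawn by the uniform-spacing construction (no rejection)."""
    if n_gaps == 0:
        return []
    need = 2 * margin_bp + n_gaps * gap_bp + (n_gaps - 1) * sep_bp
    free = dna_bp - need
    if free < 0:
        raise ValueError(
            f"cannot place {n_gaps} gaps of {gap_bp} bp on {dna_bp} bp "
            f"with margin {margin_bp} and separation {sep_bp}"
        )
    cuts = np.sort(rng.random(n_gaps)) * free
    starts = (margin_bp + cuts + np.arange(n_gaps) * (gap_bp + sep_bp)).astype(int)
    return [(int(s), int(s + gap_bp)) for s in starts]


def render_filament_image(
    cfg: FilamentRenderConfig,
    max_retries: int = 300,
) -> tuple[SFMImage, FilamentTrace, dict]:
    """Render one filament; returns (image, true trace, ground truth).

    The backbone is a discrete worm-like chain sampled at 2-nm arclength
    steps with Gaussian angular deflections of variance ds / Lp; paths that
    leave the field of view or approach themselves closer than ~4 pixels are
    redrawn (bounded retries, then fatal with a suggestion to enlarge the
    field).
    """
    rng = np.random.default_rng(cfg.seed)
    consts = MorphometryConstants()

    # per-bp coated state
    coated = np.ones(cfg.dna_bp, dtype=bool)
    if cfg.coverage_fraction < 1.0:
        n_gaps = max(1, cfg.n_gaps)
        gap_bp = int(round((1.0 - cfg.coverage_fraction) * cfg.dna_bp / n_gaps))
    else:
        n_gaps, gap_bp = cfg.n_gaps, cfg.gap_length_bp
    margin_bp = max(150, cfg.dna_bp // 20)
    gaps = _place_gaps(rng, cfg.dna_bp, n_gaps, gap_bp, margin_bp, sep_bp=80)
    for a, b in gaps:
        coated[a:b] = False

    rise = np.where(coated, consts.filament_rise, consts.bform_rise)
    cum_s = np.concatenate([[0.0], np.cumsum(rise)])
    total_len = float(cum_s[-1])

    ds = 2.0
    n_steps = int(np.ceil(total_len / ds))
    s_mid = (np.arange(n_steps) + 0.5) * (total_len / n_steps)
    bp_idx = np.clip(np.searchsorted(cum_s, s_mid) - 1, 0, cfg.dna_bp - 1)
    step_coated = coated[bp_idx]
    lp = np.where(step_coated, cfg.persistence_nm, cfg.bare_persistence_nm)
    step = total_len / n_steps

    field_nm = cfg.field_px * cfg.pixel_size_nm
    edge_nm = 8.0 * cfg.blur_sigma_px * cfg.pixel_size_nm / 2.0 + 20.0
    usable = field_nm - 2 * edge_nm
    # non-adjacent strands must stay resolvable: farther apart than the
    # tracer's closing footprint plus the ridge width
    min_sep_nm = 20.0
    min_arc_sep = 15 * step

    xy = None
    for _ in range(max_retries):
        theta0 = rng.uniform(0, 2 * np.pi)
        dtheta = rng.normal(0.0, np.sqrt(step / lp))
        theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta[:-1])])
        pts = np.zeros((n_steps + 1, 2))
        pts[1:, 0] = np.cumsum(step * np.cos(theta))
        pts[1:, 1] = np.cumsum(step * np.sin(theta))
        span = pts.max(axis=0) - pts.min(axis=0)
        if span.max() > usable:
            continue
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r=min_sep_nm, output_type="ndarray")
        if len(pairs) and (np.abs(pairs[:, 0] - pairs[:, 1]) * step > min_arc_sep).any():
            continue
        xy = pts - (pts.min(axis=0) + pts.max(axis=0)) / 2.0 + field_nm / 2.0
        break
    if xy is None:
        raise RuntimeError(
            f"could not fit a {total_len:.0f}-nm chain in a {field_nm:.0f}-nm field "
            f"after {max_retries} attempts; increase field_px"
        )

    # rasterize: Gaussian ridge cross-section of apex height h at each sample
    heights_at = np.where(step_coated, cfg.mean_height_nm, cfg.bare_height_nm)
    heights_at = np.append(heights_at, heights_at[-1])  # one height per point
    img = np.zeros((cfg.field_px, cfg.field_px))
    sigma_px = cfg.blur_sigma_px
    w = int(np.ceil(3.5 * sigma_px))
    offs = np.arange(-w, w + 1)
    orr, occ = np.meshgrid(offs, offs, indexing="ij")
    px = xy / cfg.pixel_size_nm  # (row, col) = (y, x): use (x->col, y->row)
    for (x, y), h in zip(px, heights_at):
        r0, c0 = int(round(y)), int(round(x))
        rr = r0 + orr
        cc = c0 + occ
        d2 = (rr - y) ** 2 + (cc - x) ** 2
        stamp = h * np.exp(-d2 / (2.0 * sigma_px**2))
        ok = (rr >= 0) & (rr < cfg.field_px) & (cc >= 0) & (cc < cfg.field_px)
        np.maximum.at(img, (rr[ok], cc[ok]), stamp[ok])
    if cfg.noise_sd_nm > 0:
        img += rng.normal(0.0, cfg.noise_sd_nm, img.shape)

    image = SFMImage(heights=img, pixel_size=cfg.pixel_size_nm)
    true_path = np.column_stack([px[:, 1], px[:, 0]])  # (row, col)
    trace = FilamentTrace(path=true_path, heights_along=heights_at)
    truth = {
        "dna_bp": cfg.dna_bp,
        "n_gaps": len(gaps),
        "gap_intervals_bp": gaps,
        "gap_length_bp": gap_bp if gaps else 0,
        "coated_bp": int(coated.sum()),
        "true_length_nm": total_len,
        "coverage_fraction": float(coated.mean()),
    }
    return image, trace, truth


# ---------------------------------------------------------------------------
# biochemical tables
# ---------------------------------------------------------------------------

def simulate_titration(
    half_sat_um: float = 0.3,
    hill: float = 4.0,
    concentrations=None,
    total_intensity: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Hill-shaped binding titration as per-lane band intensities.

    With the defaults, half of the DNA is bound at 0.3 uM and binding is
    essentially saturated by 0.8 uM.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations if concentrations is not None
                   else np.round(np.arange(0.05, 1.01, 0.05), 3), dtype=float)
    frac = c**hill / (half_sat_um**hill + c**hill)
    if noise_sd > 0:
        frac = np.clip(frac + rng.normal(0, noise_sd, len(c)), 0.0, 1.0)
    df = pd.DataFrame({
        "concentration_um": c,
        "bound_intensity": total_intensity * frac,
        "unbound_intensity": total_intensity * (1 - frac),
    })
    return df, {"half_sat_um": half_sat_um, "hill": hill}


def simulate_timecourse(
    slope: float = 2.0,
    times=None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Linear ATP-hydrolysis time course with multiplicative noise."""
    rng = np.random.default_rng(seed)
    t = np.asarray(times if times is not None else np.arange(0.0, 31.0, 3.0),
                   dtype=float)
    y = slope * t
    if noise_frac > 0:
        y = y * (1.0 + rng.normal(0, noise_frac, len(t)))
    y = np.clip(y, 0.0, None)
    df = pd.DataFrame({"time_min": t, "hydrolysed": y})
    return df, {"slope": slope}
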