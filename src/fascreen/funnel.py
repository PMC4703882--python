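"""Variant-prioritization funnel: quality, frequency, proband-carrier and
consequence filters, the 2-of-4 pathogenicity consensus, and the funnel
composition with per-stage accounting.

Stage order is fixed: quality -> frequency -> proband carrier -> consequence
-> inheritance model -> pathogenicity consensus.  Each stage keeps a subset
of its input, so stage counts are non-increasing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .family import ALT, DAMAGING, REF, DEFAULT_PANELS, PREDICTOR_TOOLS, FamilyGenotypes, Pedigree

log = logging.getLogger(__name__)

#: consequence classes kept by the consequence filter (splice handled by offset)
DEFAULT_CONSEQUENCES = frozenset(
    {
        "non_synonymous",
        "frameshift_insertion",
        "frameshift_deletion",
        "non_frameshift_insertion",
        "non_frameshift_deletion",
        "non_frameshift_substitution",
        "stop_gain",
        "stop_loss",
        "splice",
    }
)

#: the full label set the generator can emit; anything else is warned about
KNOWN_CONSEQUENCES = DEFAULT_CONSEQUENCES | {
    "synonymous",
    "intronic",
    "intergenic",
    "utr3",
    "utr5",
    "ncRNA",
}


@dataclass(frozen=True)
class FilterConfig:
    """Funnel thresholds.

    maf_max is inclusive (a variant at exactly 1% passes); the consensus rule
    is "at least k of m tools call damaging" with missing scores counting as
    non-positive; splice variants are kept up to ``splice_window`` bases into
    intron or exon.
    """

    maf_max: float = 0.01
    panels: tuple[str, ...] = DEFAULT_PANELS
    consensus_k: int = 2
    consensus_m: int = 4
    splice_window: int = 2
    consequence_whitelist: frozenset = DEFAULT_CONSEQUENCES

    def __post_init__(self) -> None:
        if not 0 < self.maf_max <= 1:
            raise ValueError("maf_max must be in (0, 1]")
        if not 1 <= self.consensus_k <= self.consensus_m:
            raise ValueError("need 1 <= consensus_k <= consensus_m")


@dataclass
class FunnelReport:
    """Per-stage survivor counts plus the final candidate hits."""

    model: str
    stage_names: list[str] = field(default_factory=list)
    stage_counts: list[int] = field(default_factory=list)
    survivors: list = field(default_factory=list)  # CandidateHit list

    def add_stage(self, name: str, count: int) -> None:
        if self.stage_counts and count > self.stage_counts[-1]:
            raise ValueError(
                f"funnel stage {name} grew the variant set "
                f"({self.stage_counts[-1]} -> {count})"
            )
        self.stage_names.append(name)
        self.stage_counts.append(count)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "model": self.model,
            "stages": dict(zip(self.stage_names, self.stage_counts)),
            "survivors": [h.to_dict() for h in self.survivors],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def quality_mask(fg: FamilyGenotypes) -> np.ndarray:
    """True where >= 1 genome carries the variant as a HIGH-quality call."""
    present = (fg.calls == ALT).any(axis=2)
    return (present & fg.quality).any(axis=1)


def filter_quality(fg: FamilyGenotypes) -> FamilyGenotypes:
    return fg.subset(quality_mask(fg))


def frequency_mask(fg: FamilyGenotypes, cfg: FilterConfig) -> np.ndarray:
    """True where MAF <= maf_max in every panel the variant appears in.

    A variant absent from every panel passes: unknown means rare (the causal
    de novo variant is by definition novel).
    """
    keep = np.ones(len(fg), dtype=bool)
    for panel in cfg.panels:
        col = f"freq_{panel}"
        if col not in fg.variants.columns:
            continue
        maf = fg.variants[col].to_numpy(dtype=float)
        bad = np.isfinite(maf) & ((maf < 0) | (maf > 1))
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(f"MAF {maf[i]} outside [0, 1] in panel {panel}")
        keep &= ~(np.isfinite(maf) & (maf > cfg.maf_max))
    return keep


def filter_frequency(fg: FamilyGenotypes, cfg: FilterConfig) -> FamilyGenotypes:
    return fg.subset(frequency_mask(fg, cfg))


def proband_carrier_mask(fg: FamilyGenotypes, ped: Pedigree) -> np.ndarray:
    """Drop variants where the index is called hom-ref on both alleles.

    Variants with any uncalled index allele are retained at this stage.
    """
    j = fg.sample_index(ped.index_id)
    hom_ref = (fg.calls[:, j] == REF).all(axis=1)
    return ~hom_ref


def filter_proband_carrier(fg: FamilyGenotypes, ped: Pedigree) -> FamilyGenotypes:
    return fg.subset(proband_carrier_mask(fg, ped))


def consequence_mask(fg: FamilyGenotypes, cfg: FilterConfig) -> np.ndarray:
    cons = fg.variants["consequence"].fillna("").astype(str).to_numpy()
    unknown = sorted(set(cons) - KNOWN_CONSEQUENCES - {""})
    if unknown:
        log.warning("dropping variants with unknown consequence labels: %s", unknown)
    keep = np.isin(cons, list(cfg.consequence_whitelist - {"splice"}))
    if "splice" in cfg.consequence_whitelist:
        off = pd.to_numeric(
            fg.variants.get("splice_offset", pd.Series(np.nan, index=fg.variants.index)),
            errors="coerce",
        ).to_numpy(dtype=float)
        splice_ok = (cons == "splice") & np.isfinite(off) & (np.abs(off) <= cfg.splice_window)
        keep |= splice_ok
    return keep


def filter_consequence(fg: FamilyGenotypes, cfg: FilterConfig) -> FamilyGenotypes:
    return fg.subset(consequence_mask(fg, cfg))


def pathogenicity_consensus(calls: Sequence[int], cfg: FilterConfig | None = None) -> bool:
    """True iff >= k of the m per-tool calls are DAMAGING (missing = not positive)."""
    cfg = cfg or FilterConfig()
    if len(calls) != cfg.consensus_m:
        raise ValueError(f"expected {cfg.consensus_m} tool calls, got {len(calls)}")
    return sum(1 for c in calls if c == DAMAGING) >= cfg.consensus_k


def consensus_mask(fg: FamilyGenotypes, cfg: FilterConfig) -> np.ndarray:
    cols = [f"pred_{t}" for t in PREDICTOR_TOOLS]
    missing = [c for c in cols if c not in fg.variants.columns]
    if missing:
        raise ValueError(f"predictor columns not attached: {missing}")
    pred = fg.variants[cols].to_numpy()
    return (pred == DAMAGING).sum(axis=1) >= cfg.consensus_k


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def apply_funnel(
    fg: FamilyGenotypes,
    ped: Pedigree,
    cfg: FilterConfig | None = None,
    model: str = "denovo",
) -> FunnelReport:
    """Run the full prioritization funnel for one inheritance model.

    ``model`` is one of ``denovo``, ``recessive``, ``compound_het``.  The
    inheritance stage reduces the variant set to those participating in a
    candidate hit; the consensus stage then keeps hits whose every variant
    scores damaging in >= k of m predictors.
    """
    from . import inheritance

    cfg = cfg or FilterConfig()
    models = {
        "denovo": inheritance.de_novo,
        "recessive": inheritance.recessive_homozygous,
        "compound_het": inheritance.compound_heterozygous,
    }
    if model not in models:
        raise ValueError(f"unknown inheritance model {model!r}; choose from {sorted(models)}")

    report = FunnelReport(model=model)
    report.add_stage("input", len(fg))
    fg = filter_quality(fg)
    report.add_stage("quality", len(fg))
    fg = filter_frequency(fg, cfg)
    report.add_stage("frequency", len(fg))
    fg = filter_proband_carrier(fg, ped)
    report.add_stage("proband_carrier", len(fg))
    fg = filter_consequence(fg, cfg)
    report.add_stage("consequence", len(fg))

    hits = models[model](fg, ped)
    n_model_variants = len({v.key for h in hits for v in h.variants})
    report.add_stage(f"model:{model}", n_model_variants)

    surviving = [
        h
        for h in hits
        if all(
            pathogenicity_consensus(
                [v.predictor_calls.get(t, -1) for t in PREDICTOR_TOOLS], cfg
            )
            for v in h.variants
        )
    ]
    n_final = len({v.key for h in surviving for v in h.variants})
    report.add_stage("consensus", n_final)
    report.survivors = surviving
    return report
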