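"""End-to-end orchestration: load inputs, run the funnel for the selected
inheritance models, prioritize candidate genes, and write a report bundle."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .family import (
    FamilyGenotypes,
    Pedigree,
    attach_annotations,
    attach_frequencies,
    attach_scores,
    read_family_vcf,
)
from .funnel import FilterConfig, apply_funnel
from .prioritize import load_gene_scores, rank_candidates

log = logging.getLogger(__name__)

ALL_MODELS = ("denovo", "recessive", "compound_het")


@dataclass
class RunConfig:
    vcf: str
    pedigree: str
    annotations: str
    scores: str
    frequencies: str
    outdir: str = "fascreen_out"
    gene_scores: str | None = None
    models: tuple[str, ...] = ALL_MODELS
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        fc = raw.pop("filter_config", {})
        if isinstance(fc, dict):
            raw["filter_config"] = FilterConfig(**fc)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("vcf", "pedigree", "annotations", "scores", "frequencies"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
        if self.gene_scores and not Path(self.gene_scores).exists():
            raise FileNotFoundError(f"gene_scores input not found: {self.gene_scores}")
        for m in self.models:
            if m not in ALL_MODELS:
                raise ValueError(f"unknown model {m!r}")


def load_inputs(cfg: RunConfig) -> tuple[FamilyGenotypes, Pedigree]:
    ped = Pedigree.from_ped(cfg.pedigree)
    fg = read_family_vcf(cfg.vcf, ped)
    fg = attach_annotations(fg, pd.read_csv(cfg.annotations, sep="\t"))
    fg = attach_scores(fg, pd.read_csv(cfg.scores, sep="\t"))
    fg = attach_frequencies(fg, pd.read_csv(cfg.frequencies, sep="\t"))
    return fg, ped


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the funnel for every selected inheritance model and prioritize.

    Writes per-model FunnelReport JSON, a candidate TSV and a ranked gene
    table to ``cfg.outdir``; returns the combined report dict.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fg, ped = load_inputs(cfg)
    log.info("loaded %d variants for %d samples", len(fg), len(fg.samples))

    combined: dict = {"version": __version__, "seed": cfg.seed, "models": {}}
    all_hits = []
    for model in cfg.models:
        report = apply_funnel(fg, ped, cfg.filter_config, model=model)
        report.to_json(outdir / f"funnel_{model}.json")
        combined["models"][model] = report.to_dict()
        all_hits.extend(report.survivors)
        pd.DataFrame([h.to_dict() for h in report.survivors]).to_csv(
            outdir / f"candidates_{model}.tsv", sep="\t", index=False
        )

    if cfg.gene_scores:
        ranked = rank_candidates(all_hits, load_gene_scores(cfg.gene_scores))
        ranked.to_csv(outdir / "ranked_genes.tsv", sep="\t", index=False)
        combined["ranked_genes"] = ranked["gene"].tolist()

    with open(outdir / "report.json", "w") as fh:
        json.dump(combined, fh, indent=2, default=str)
    return combined
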