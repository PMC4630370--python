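"""End-to-end orchestration of the chemical- and expression-proteomics arms.

The chemical arm runs target deconvolution on an identified-protein list,
derives emPAI-proportional affinities, tests the filtered profile for
term enrichment and ranks perturbed functional subnetworks.  The expression
arm fits reporter-ion ratios, filters by GOF, aggregates to proteins,
normalizes, derives population thresholds and calls differential expression
with trend clusters.  ``intersect_profiles`` joins the two arms over an
interactome.  Every run with an output directory writes its artifacts plus a
JSON manifest (parameters, seed, input hashes) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .deconvolution import DeconReport, TargetProfile, deconvolve
from .empai import DEFAULT_MASS_WINDOW, affinity_from_empai
from .enrichment import EnrichmentResult, enrich_terms
from .itraq_quant import (
    DEFAULT_MIN_GOF,
    DEThresholds,
    ReporterFit,
    TIME_POINTS,
    aggregate_peptides,
    call_differential,
    cluster_trends,
    compute_thresholds,
    filter_by_gof,
    fit_reporter_ratios,
    normalize_ratios,
    reporter_templates,
)
from .netscore import extract_subnetworks, interaction_overlap, rank_perturbed

__all__ = [
    "PipelineConfig",
    "ChemicalResults",
    "ExpressionResults",
    "run_chemical",
    "run_expression",
    "intersect_profiles",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline parameters (all defaults match the analysis protocol)."""

    min_gof: float = DEFAULT_MIN_GOF
    p_level: float = 0.1
    crapome_threshold: float = 2.0
    min_complex_members: int = 2
    alpha: float = 0.05
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW
    crapome_filter: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_gof <= 1:
            raise ValueError("min_gof must be in [0, 1]")
        if not 0 < self.p_level < 1:
            raise ValueError("p_level must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.crapome_threshold < 0:
            raise ValueError("crapome_threshold must be >= 0")
        if self.min_complex_members < 1:
            raise ValueError("min_complex_members must be >= 1")
        if not self.mass_window[0] < self.mass_window[1]:
            raise ValueError("mass_window must be (low, high) with low < high")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "mass_window" in raw:
            raw["mass_window"] = tuple(raw["mass_window"])
        return cls(**raw)


@dataclass
class ChemicalResults:
    report: DeconReport
    profile: TargetProfile
    affinities: dict[str, float]
    subnetworks: pd.DataFrame | None
    enrichment: list[EnrichmentResult]


@dataclass
class ExpressionResults:
    fits: dict[str, list[ReporterFit]]
    n_fits_total: int
    n_fits_retained: int
    quant: pd.DataFrame
    thresholds: DEThresholds
    calls: pd.DataFrame
    clusters: list[tuple[tuple[str, ...], list[str]]]
    enrichment: list[EnrichmentResult]


def _hash_params(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, params: Mapping, extra: Mapping) -> None:
    manifest = {
        "tool": "peptarget",
        "version": __version__,
        "stage": stage,
        "parameters": dict(params),
        "parameters_hash": _hash_params(dict(params)),
        **dict(extra),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_chemical(
    identified: Iterable[str],
    sticky: Iterable[str],
    central: Iterable[str],
    *,
    crapome_counts: Mapping[str, float] | None = None,
    complex_catalog: Mapping[str, Iterable[str]] | None = None,
    empai: Mapping[str, float] | None = None,
    forced_full_affinity: Iterable[str] = (),
    annotations: Mapping[str, Iterable[str]] | None = None,
    background: Iterable[str] | None = None,
    graph: nx.Graph | None = None,
    term2nodes: Mapping[str, Iterable[str]] | None = None,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | os.PathLike | None = None,
) -> ChemicalResults:
    """Deconvolution -> affinity scoring -> enrichment -> subnetwork ranking."""
    identified = list(identified)
    report, profile = deconvolve(
        identified,
        sticky,
        central,
        crapome_counts,
        complex_catalog,
        crapome_threshold=config.crapome_threshold,
        min_complex_members=config.min_complex_members,
        crapome_filter=config.crapome_filter,
    )
    affinities: dict[str, float] = {}
    if empai:
        profile_empai = {a: v for a, v in empai.items() if a in set(profile.accessions)}
        affinities = affinity_from_empai(profile_empai or dict(empai), forced_full_affinity)
        profile.affinities = affinities
    enrichment: list[EnrichmentResult] = []
    if annotations:
        bg = set(background) if background is not None else set(identified)
        enrichment = enrich_terms(
            set(profile.accessions) & bg, bg, annotations, alpha=config.alpha
        )
    subnet_table = None
    if graph is not None and term2nodes:
        subnets = extract_subnetworks(graph, term2nodes)
        scoring_affinities = affinities or {a: 1.0 for a in profile.accessions}
        subnet_table = rank_perturbed(subnets, scoring_affinities, graph)
    results = ChemicalResults(report, profile, affinities, subnet_table, enrichment)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prof = pd.DataFrame(
            {
                "accession": profile.accessions,
                "crapome_count": [profile.crapome_counts.get(a) for a in profile.accessions],
                "affinity": [affinities.get(a) for a in profile.accessions],
            }
        )
        prof.to_csv(outdir / "profile.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(report)]).drop(columns="complex_hits").to_csv(
            outdir / "report.tsv", sep="\t", index=False
        )
        pd.DataFrame(report.complex_hits, columns=["complex", "members_present", "complex_size"]).to_csv(
            outdir / "complexes.tsv", sep="\t", index=False
        )
        if subnet_table is not None:
            subnet_table.to_csv(outdir / "subnetworks.tsv", sep="\t", index=False)
        if enrichment:
            pd.DataFrame([dataclasses.asdict(r) for r in enrichment]).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
        _write_manifest(
            outdir,
            "chemical",
            dataclasses.asdict(config),
            {"counts": {k: v for k, v in dataclasses.asdict(report).items() if k != "complex_hits"}},
        )
    return results


def run_expression(
    spectra: Mapping[str, "np.ndarray"],
    peptide_map: Mapping[str, str],
    templates: Sequence | None = None,
    *,
    annotations: Mapping[str, Iterable[str]] | None = None,
    background: Iterable[str] | None = None,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | os.PathLike | None = None,
) -> ExpressionResults:
    """Fit -> GOF filter -> aggregate -> normalize -> thresholds -> calls -> clusters."""
    templates = list(templates) if templates is not None else reporter_templates()
    fits: dict[str, list[ReporterFit]] = {}
    n_total = 0
    n_kept = 0
    for pep, observed in spectra.items():
        fit = fit_reporter_ratios(observed, templates)
        n_total += 1
        kept = filter_by_gof([fit], config.min_gof)
        n_kept += len(kept)
        if kept:
            fits[pep] = kept
    if not fits:
        raise ValueError(f"no spectrum passed the GOF filter (min_gof={config.min_gof})")
    quant = aggregate_peptides(fits, peptide_map)
    normalized = normalize_ratios(quant)
    thresholds = compute_thresholds(normalized, p_level=config.p_level)
    calls = call_differential(normalized, thresholds)
    clusters = cluster_trends(calls)
    enrichment: list[EnrichmentResult] = []
    if annotations:
        significant = set(calls.index[calls["significant_any"]])
        bg = set(background) if background is not None else set(calls.index)
        enrichment = enrich_terms(significant & bg, bg, annotations, alpha=config.alpha)
    results = ExpressionResults(
        fits, n_total, n_kept, quant, thresholds, calls, clusters, enrichment
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_pep = pd.DataFrame(
            [
                {
                    "peptide": pep,
                    "protein": peptide_map[pep],
                    "gof": f.gof,
                    **{f"ratio_{c}": f.ratios[i] for i, c in enumerate((114, 115, 116, 117))},
                }
                for pep, fs in fits.items()
                for f in fs
            ]
        )
        per_pep.to_csv(outdir / "peptide_fits.tsv", sep="\t", index=False)
        calls.to_csv(outdir / "quant.tsv", sep="\t")
        pd.DataFrame([{"time_point": tp, "threshold": t} for tp, t in thresholds.tau.items()]).to_csv(
            outdir / "thresholds.tsv", sep="\t", index=False
        )
        if enrichment:
            pd.DataFrame([dataclasses.asdict(r) for r in enrichment]).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
        _write_manifest(
            outdir,
            "expression",
            dataclasses.asdict(config),
            {
                "n_spectra": n_total,
                "n_retained": n_kept,
                "n_proteins": int(len(quant)),
                "n_significant": int(calls["significant_any"].sum()),
                "thresholds": thresholds.tau,
            },
        )
    return results


def intersect_profiles(
    targets: Iterable[str],
    de_proteins: Iterable[str],
    graph: nx.Graph | None = None,
    *,
    outdir: str | os.PathLike | None = None,
) -> dict:
    """Join the chemical target profile with the differential-expression set.

    Reports the accession intersection and, given an interactome, the
    target-DE interaction pairs plus a node-attribute export for external
    visualization tools.
    """
    target_set = set(targets)
    de_set = set(de_proteins)
    shared = sorted(target_set & de_set)
    pairs = interaction_overlap(target_set, de_set, graph) if graph is not None else []
    report = {
        "n_targets": len(target_set),
        "n_differential": len(de_set),
        "shared_accessions": shared,
        "n_shared": len(shared),
        "interaction_pairs": pairs,
        "n_interaction_pairs": len(pairs),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(pairs, columns=["target", "de_protein"]).to_csv(
            outdir / "interaction_pairs.tsv", sep="\t", index=False
        )
        nodes = sorted(target_set | de_set)
        pd.DataFrame(
            {
                "node": nodes,
                "is_target": [n in target_set for n in nodes],
                "is_differential": [n in de_set for n in nodes],
            }
        ).to_csv(outdir / "node_attributes.tsv", sep="\t", index=False)
        _write_manifest(outdir, "intersect", {}, {k: v for k, v in report.items() if isinstance(v, int)})
    return report
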