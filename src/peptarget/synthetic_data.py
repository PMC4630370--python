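"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the study's data — a pull-down
inventory with sticky/central/contaminant attributes, a 4-plex reporter-ion
experiment over three treatment time points with a minority of truly
regulated proteins, and an annotated interactome — at configurable sizes,
and emit the ground truth needed to score any downstream caller.  Every
generator is a pure function of its arguments and seed (bit-identical
reruns).  Packaged transcriptions of the published result tables (55 filtered
targets with emPAI, 10 scored subnetworks, 72 differential proteins) load via
:func:`load_paper_tables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .itraq_quant import (
    CHANNELS,
    OFF,
    ON,
    TIME_POINTS,
    IsotopePattern,
    reporter_templates,
)

__all__ = [
    "PulldownFixture",
    "ItraqFixture",
    "NetworkFixture",
    "PaperFixtures",
    "TABLE3_THRESHOLDS",
    "gen_pulldown_fixture",
    "gen_reporter_spectrum",
    "gen_itraq_experiment",
    "gen_network_fixture",
    "load_paper_tables",
]

#: Significance thresholds printed with the 72-row differential table
#: (40 min, 2 h, 5 h on the signed fold-change scale).
TABLE3_THRESHOLDS = {"40min": 2.6, "2h": 2.6, "5h": 2.4}

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# Roughly human-like residue frequencies; K+R ~ 11% so tryptic peptides
# average ~9 residues.
_RESIDUE_P = np.array(
    [7.0, 2.3, 4.7, 7.1, 3.7, 6.6, 2.6, 4.3, 5.7, 10.0,
     2.1, 3.6, 6.3, 4.8, 5.3, 8.3, 5.4, 6.0, 1.2, 3.0]
)
_RESIDUE_P = _RESIDUE_P / _RESIDUE_P.sum()


def _syn_accessions(n: int) -> list[str]:
    return [f"SYN{i:05d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PulldownFixture:
    """Synthetic AP-MS inventory with contaminant attributes."""

    identified: list[str]
    sticky: set[str]
    central: set[str]
    crapome_counts: dict[str, float]
    observed_peptides: dict[str, int]
    sequences: dict[str, str]
    n_crapome_above: int
    seed: int


@dataclass(frozen=True)
class ItraqFixture:
    """Synthetic 4-plex reporter experiment with planted regulation."""

    true_ratio: dict[tuple[str, str], float]
    onoff_truth: dict[tuple[str, str], str]
    spectra: dict[str, np.ndarray]  # peptide id -> observed reporter intensities
    peptide_map: dict[str, str]
    templates: list[IsotopePattern]
    regulated: set[str]
    seed: int


@dataclass(frozen=True)
class NetworkFixture:
    """Synthetic annotated interactome with placed drug targets."""

    edges: list[tuple[str, str]]
    term2nodes: dict[str, set[str]]
    targets: dict[str, float]
    placement: dict[str, tuple[str, str]]  # target -> (direct|peripheral, term)
    seed: int

    def graph(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class PaperFixtures:
    """Transcriptions of the published result tables."""

    table1: pd.DataFrame  # 55 filtered targets: accession, gene, score, empai
    table2: pd.DataFrame  # 10 subnetworks: term, go_id, nodes, targets, s_net
    table3: pd.DataFrame  # 72 differential proteins with signed FCs / ON / OFF
    thresholds: dict[str, float] = field(default_factory=lambda: dict(TABLE3_THRESHOLDS))


def _random_protein_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RESIDUES, size=length, p=_RESIDUE_P))


def gen_pulldown_fixture(
    n_total: int,
    n_sticky: int,
    n_central_in_profile: int,
    seed: int,
    *,
    n_crapome_above: int | None = None,
) -> PulldownFixture:
    """Pull-down inventory whose deconvolution counts are known by construction.

    ``n_sticky`` identified proteins are flagged as unloaded-matrix binders and
    ``n_central_in_profile`` of the remainder as central-proteome members, so
    the filter chain yields n_total - n_sticky and then
    n_total - n_sticky - n_central_in_profile survivors.  Contaminant-repository
    counts cover the central members; ``n_crapome_above`` of them (default:
    round(n_central * 91/106), the fraction observed in the study's annotation)
    exceed the conventional threshold of 2.
    """
    if n_sticky < 0 or n_central_in_profile < 0 or n_total < 0:
        raise ValueError("cardinalities must be non-negative")
    if n_sticky + n_central_in_profile > n_total:
        raise ValueError(
            "n_sticky + n_central_in_profile must be <= n_total "
            f"({n_sticky} + {n_central_in_profile} > {n_total})"
        )
    if n_crapome_above is None:
        n_crapome_above = round(n_central_in_profile * 91 / 106)
    if n_crapome_above > n_central_in_profile:
        raise ValueError("n_crapome_above must be <= n_central_in_profile")
    rng = np.random.default_rng(seed)
    identified = _syn_accessions(n_total)
    order = rng.permutation(n_total)
    sticky = {identified[i] for i in order[:n_sticky]}
    central = {identified[i] for i in order[n_sticky : n_sticky + n_central_in_profile]}
    central_sorted = sorted(central)
    above = set(
        rng.choice(central_sorted, size=n_crapome_above, replace=False)
    ) if n_crapome_above else set()
    crapome_counts = {
        acc: float(np.round(rng.uniform(2.5, 60.0), 2)) if acc in above
        else float(np.round(rng.uniform(0.0, 2.0), 2))
        for acc in central_sorted
    }
    sequences = {
        acc: _random_protein_sequence(rng, int(rng.integers(120, 600)))
        for acc in identified
    }
    observed_peptides = {acc: int(rng.integers(1, 12)) for acc in identified}
    return PulldownFixture(
        identified=identified,
        sticky=sticky,
        central=central,
        crapome_counts=crapome_counts,
        observed_peptides=observed_peptides,
        sequences=sequences,
        n_crapome_above=n_crapome_above,
        seed=seed,
    )


def gen_reporter_spectrum(
    ratios: Sequence[float],
    templates: Sequence[IsotopePattern],
    noise_frac: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Observed reporter-region intensities: sum_c ratios[c] * template_c.

    Multiplicative Gaussian noise of relative magnitude ``noise_frac`` is
    applied per grid point and the result clipped at zero.
    """
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios < 0):
        raise ValueError("channel ratios must be non-negative")
    if len(ratios) != len(templates):
        raise ValueError("need one ratio per template")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spectrum = np.zeros_like(templates[0].intensity)
    for r, t in zip(ratios, templates):
        spectrum = spectrum + r * t.intensity
    if noise_frac:
        spectrum = spectrum * (1.0 + noise_frac * rng.standard_normal(spectrum.size))
    return np.clip(spectrum, 0.0, None)


def gen_itraq_experiment(
    n_proteins: int,
    frac_regulated: float,
    effect_fc: float,
    peptides_per_protein: int,
    noise_sd_log2: float,
    frac_on: float = 0.0,
    frac_off: float = 0.0,
    seed: int = 0,
) -> ItraqFixture:
    """4-plex reporter experiment with planted fold changes and ON/OFF proteins.

    Regulated proteins carry true ratio ``effect_fc`` or ``1/effect_fc`` at a
    random non-empty subset of the three time points (ratio 1 elsewhere);
    unregulated proteins sit at 1.  Peptide-level channel ratios are the
    protein ratio perturbed by Gaussian noise of SD ``noise_sd_log2`` in log2
    space; each peptide yields one noiseless 4-channel mixture spectrum of the
    default reporter templates (the ratio noise, not detector noise, is the
    modeled variability).  ON proteins have a silent control channel (hence ON
    wherever treated signal exists — all three time points here); OFF proteins
    have one silenced treated channel.
    """
    for name, frac in (("frac_regulated", frac_regulated), ("frac_on", frac_on), ("frac_off", frac_off)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if frac_regulated + frac_on + frac_off > 1:
        raise ValueError("regulated + ON + OFF fractions must be <= 1")
    if effect_fc <= 1:
        raise ValueError("effect_fc must be > 1")
    if peptides_per_protein < 1:
        raise ValueError("peptides_per_protein must be >= 1")
    rng = np.random.default_rng(seed)
    proteins = _syn_accessions(n_proteins)
    order = rng.permutation(n_proteins)
    n_reg = round(frac_regulated * n_proteins)
    n_on = round(frac_on * n_proteins)
    n_off = round(frac_off * n_proteins)
    regulated = {proteins[i] for i in order[:n_reg]}
    on_set = {proteins[i] for i in order[n_reg : n_reg + n_on]}
    off_set = {proteins[i] for i in order[n_reg + n_on : n_reg + n_on + n_off]}

    true_ratio: dict[tuple[str, str], float] = {}
    onoff_truth: dict[tuple[str, str], str] = {}
    off_tp: dict[str, str] = {}
    for prot in proteins:
        if prot in on_set:
            for tp in TIME_POINTS:
                onoff_truth[(prot, tp)] = ON
            continue
        if prot in off_set:
            tp_off = TIME_POINTS[rng.integers(len(TIME_POINTS))]
            off_tp[prot] = tp_off
        hit_tps: set[str] = set()
        if prot in regulated:
            mask = rng.random(len(TIME_POINTS)) < 0.5
            if not mask.any():
                mask[rng.integers(len(TIME_POINTS))] = True
            direction = effect_fc if rng.random() < 0.5 else 1.0 / effect_fc
            hit_tps = {tp for tp, m in zip(TIME_POINTS, mask) if m}
        else:
            direction = 1.0
        for tp in TIME_POINTS:
            if prot in off_set and tp == off_tp[prot]:
                onoff_truth[(prot, tp)] = OFF
            else:
                true_ratio[(prot, tp)] = direction if tp in hit_tps else 1.0
                onoff_truth[(prot, tp)] = "normal"

    templates = reporter_templates()
    spectra: dict[str, np.ndarray] = {}
    peptide_map: dict[str, str] = {}
    for prot in proteins:
        for j in range(peptides_per_protein):
            pep = f"{prot}_pep{j + 1}"
            peptide_map[pep] = prot
            channel_amounts = np.empty(len(CHANNELS))
            channel_amounts[0] = 0.0 if prot in on_set else 1.0
            for i, tp in enumerate(TIME_POINTS, start=1):
                if prot in on_set:
                    channel_amounts[i] = 1.0
                elif onoff_truth[(prot, tp)] == OFF:
                    channel_amounts[i] = 0.0
                else:
                    noisy = np.log2(true_ratio[(prot, tp)]) + noise_sd_log2 * rng.standard_normal()
                    channel_amounts[i] = 2.0**noisy
            spectra[pep] = gen_reporter_spectrum(channel_amounts, templates, 0.0, rng)
    return ItraqFixture(
        true_ratio=true_ratio,
        onoff_truth=onoff_truth,
        spectra=spectra,
        peptide_map=peptide_map,
        templates=templates,
        regulated=regulated,
        seed=seed,
    )


def gen_network_fixture(
    n_nodes: int,
    n_edges: int,
    n_terms: int,
    term_size: int,
    n_targets: int,
    seed: int,
) -> NetworkFixture:
    """Connected random interactome with connected term annotations and targets.

    Terms are grown by random neighbor expansion so each annotation induces a
    connected subgraph.  Targets alternate between direct placement (a member
    of their assigned term, round-robin over terms) and peripheral placement
    (a non-member neighbor of the term); the placement is recorded as ground
    truth.  Target affinities are Uniform(0.2, 1], with the first target
    forced to affinity 1.
    """
    if n_nodes < 1 or term_size > n_nodes or term_size < 1:
        raise ValueError("infeasible node/term sizes")
    if n_edges < n_nodes - 1 or n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError(f"cannot build a connected simple graph with {n_edges} edges on {n_nodes} nodes")
    if n_targets > n_nodes:
        raise ValueError("more targets than nodes")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:04d}" for i in range(1, n_nodes + 1)]
    # random spanning tree, then random extra edges
    perm = list(rng.permutation(nodes))
    edges: set[tuple[str, str]] = set()
    adj: dict[str, set[str]] = {v: set() for v in nodes}

    def add_edge(u: str, v: str) -> None:
        edges.add((min(u, v), max(u, v)))
        adj[u].add(v)
        adj[v].add(u)

    for i in range(1, n_nodes):
        add_edge(perm[i], perm[rng.integers(i)])
    while len(edges) < n_edges:
        u, v = rng.choice(nodes, size=2, replace=False)
        if (min(u, v), max(u, v)) not in edges:
            add_edge(u, v)

    term2nodes: dict[str, set[str]] = {}
    for t in range(n_terms):
        start = nodes[rng.integers(n_nodes)]
        members = {start}
        frontier = set(adj[start])
        while len(members) < term_size and frontier:
            nxt = sorted(frontier)[rng.integers(len(frontier))]
            members.add(nxt)
            frontier = (frontier | adj[nxt]) - members
        term2nodes[f"TERM{t + 1:03d}"] = members

    targets: dict[str, float] = {}
    placement: dict[str, tuple[str, str]] = {}
    term_ids = sorted(term2nodes)
    for i in range(n_targets):
        term = term_ids[i % len(term_ids)] if term_ids else ""
        members = term2nodes.get(term, set())
        outside_neighbors = sorted(
            {nb for m in members for nb in adj[m]} - members - set(targets)
        )
        direct_pool = sorted(members - set(targets))
        if i % 2 == 0 and direct_pool:
            node = direct_pool[rng.integers(len(direct_pool))]
            placement[node] = ("direct", term)
        elif outside_neighbors:
            node = outside_neighbors[rng.integers(len(outside_neighbors))]
            placement[node] = ("peripheral", term)
        else:
            pool = sorted(set(nodes) - set(targets))
            node = pool[rng.integers(len(pool))]
            placement[node] = ("unplaced", term)
        targets[node] = 1.0 if not targets else float(rng.uniform(0.2, 1.0))
    return NetworkFixture(
        edges=sorted(edges),
        term2nodes=term2nodes,
        targets=targets,
        placement=placement,
        seed=seed,
    )


def _load_packaged_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("peptarget.data").joinpath(name)
    try:
        with ref.open("r", encoding="utf-8") as fh:
            return pd.read_csv(fh, sep="\t")
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"packaged fixture {name!r} is missing") from exc


def load_paper_tables() -> PaperFixtures:
    """Load the packaged transcriptions of the published result tables."""
    table1 = _load_packaged_tsv("table1_targets.tsv")
    table2 = _load_packaged_tsv("table2_subnetworks.tsv")
    table3 = _load_packaged_tsv("table3_differential.tsv")
    for name, df, expected in (
        ("table1_targets.tsv", table1, 55),
        ("table2_subnetworks.tsv", table2, 10),
        ("table3_differential.tsv", table3, 72),
    ):
        if len(df) != expected:
            raise ValueError(f"malformed fixture {name}: expected {expected} rows, got {len(df)}")
    # fold-change columns hold floats or ON/OFF tokens
    for col in ("fc_40min", "fc_2h", "fc_5h"):
        table3[col] = [
            v if v in (ON, OFF) else float(v) for v in table3[col].astype(str).str.strip()
        ]
    return PaperFixtures(table1=table1, table2=table2, table3=table3)
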