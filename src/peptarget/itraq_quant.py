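"""4-plex reporter-ion quantification from overlapping isotopic envelopes.

Each labeled peptide yields one reporter-region spectrum in which the four
isobaric-tag reporter channels (nominal m/z 114-117; 114 = untreated control,
115/116/117 = the three treatment time points) appear as overlapping isotopic
envelopes.  Channel amounts are recovered by non-negative least squares
against in-silico isotope templates; fit quality is a goodness-of-fit (GOF)
coefficient in [0, 1] based on the difference between observed and fitted
distributions, and peptides with GOF below 0.8 are discarded.  Peptide ratios
(relative to channel 114) are averaged in log space per protein, median-
centered per time point, and called differentially expressed against a
population threshold |median| + z*SD of the log2 ratios (two-sided p < 0.1 by
default).  A protein detected in treated but not control channels is ON;
detected in control but not a treated channel, OFF — both significant by
definition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CHANNELS",
    "TIME_POINTS",
    "ON",
    "OFF",
    "DEFAULT_MIN_GOF",
    "IsotopePattern",
    "ReporterFit",
    "DEThresholds",
    "isotopic_pattern",
    "reporter_templates",
    "fit_reporter_ratios",
    "goodness_of_fit",
    "filter_by_gof",
    "protein_ratio",
    "aggregate_peptides",
    "normalize_ratios",
    "signed_fold_change",
    "unsigned_ratio",
    "compute_thresholds",
    "call_differential",
    "cluster_trends",
]

#: Reporter channel labels in fit order; channel 114 is the reference (control).
CHANNELS = (114, 115, 116, 117)
#: Treatment time points quantified by channels 115, 116, 117.
TIME_POINTS = ("40min", "2h", "5h")
ON = "ON"
OFF = "OFF"
DEFAULT_MIN_GOF = 0.8
#: Fitted channel coefficient below this fraction of the total is "not detected".
DETECTION_FRACTION = 1e-3

NEUTRON = 1.0033548378  # Da, mass difference of an isotope peak

#: Monoisotopic (mass, abundance) pairs for elements of reporter-ion fragments.
ISOTOPE_TABLE: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
    "N": [(14.0030740052, 0.99636), (15.0001088984, 0.00364)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "S": [(31.97207069, 0.9499), (32.97145850, 0.0075), (33.96786683, 0.0425), (35.96708088, 0.0001)],
}


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotope distribution on an m/z grid, unit total intensity."""

    grid: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "intensity", intensity)
        if grid.shape != intensity.shape:
            raise ValueError("grid and intensity must have the same length")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        if abs(float(intensity.sum()) - 1.0) > 1e-9:
            raise ValueError("intensity must sum to 1")


@dataclass
class ReporterFit:
    """Fitted channel ratios (relative to channel 114) and fit quality."""

    ratios: np.ndarray
    gof: float
    coefficients: np.ndarray
    reference_channel: int = 114
    ill_conditioned: bool = False
    detected: np.ndarray = field(default_factory=lambda: np.ones(4, dtype=bool))


@dataclass(frozen=True)
class DEThresholds:
    """Per-time-point significance thresholds on the symmetric |FC| scale."""

    tau: dict[str, float]
    z: float
    p_level: float

    def __post_init__(self) -> None:
        for tp, t in self.tau.items():
            if t < 1:
                raise ValueError(f"threshold for {tp} must be >= 1, got {t}")


def isotopic_pattern(
    composition: Mapping[str, int],
    isotope_table: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    prune: float = 1e-6,
) -> IsotopePattern:
    """Aggregated isotope distribution of a molecular composition.

    Convolves the per-atom isotope abundance vectors (indexed by neutron
    count), drops peaks below ``prune`` relative to the maximum, and
    renormalizes.  The m/z grid is the monoisotopic mass plus whole neutron
    masses (centroid/aggregated model, adequate at unit resolution).
    """
    table = ISOTOPE_TABLE if isotope_table is None else isotope_table
    if prune < 0:
        raise ValueError("prune must be >= 0")
    dist = np.array([1.0])
    mono = 0.0
    for element, count in composition.items():
        if element not in table:
            raise KeyError(f"unknown element {element!r}")
        if count < 0:
            raise ValueError(f"negative atom count for {element}")
        isotopes = sorted(table[element], key=lambda mi: mi[0])
        abund = np.array([a for _, a in isotopes], dtype=float)
        if abs(abund.sum() - 1.0) > 1e-6:
            raise ValueError(f"abundances for {element} must sum to 1")
        mono += isotopes[0][0] * count
        # offsets between consecutive isotopes in neutron units
        base = isotopes[0][0]
        atom = np.zeros(1 + round((isotopes[-1][0] - base) / NEUTRON))
        for m, a in isotopes:
            atom[round((m - base) / NEUTRON)] += a
        for _ in range(count):
            dist = np.convolve(dist, atom)
    keep = dist >= prune * dist.max()
    last = int(np.nonzero(keep)[0].max())
    dist = dist[: last + 1].copy()
    dist[dist < prune * dist.max()] = 0.0
    dist /= dist.sum()
    grid = mono + NEUTRON * np.arange(dist.size)
    return IsotopePattern(grid, dist)


#: Elemental composition used for default reporter-tag fragment envelopes.
DEFAULT_REPORTER_COMPOSITION = {"C": 6, "H": 13, "N": 2}


def reporter_templates(
    composition: Mapping[str, int] | None = None,
    n_channels: int = 4,
    first_mz: float = 114.0,
) -> list[IsotopePattern]:
    """Four reporter templates 1 Da apart on a shared m/z grid.

    Each channel is the isotopic envelope of ``composition`` shifted to its
    nominal reporter m/z, so the +1/+2 satellites of channel c overlap the
    monoisotopic peaks of channels c+1/c+2 — the overlap the envelope fit
    deconvolves.
    """
    comp = DEFAULT_REPORTER_COMPOSITION if composition is None else composition
    envelope = isotopic_pattern(comp)
    n_iso = envelope.intensity.size
    width = n_channels + n_iso - 1
    grid = first_mz + np.arange(width, dtype=float)
    templates = []
    for c in range(n_channels):
        intensity = np.zeros(width)
        intensity[c : c + n_iso] = envelope.intensity
        templates.append(IsotopePattern(grid, intensity))
    return templates


def goodness_of_fit(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Total-variation similarity of two spectra normalized to unit area.

    GOF = 1 - 0.5 * sum(|obs - fit|) after area normalization; 1 means a
    perfect fit, 0 disjoint support.  Symmetric and invariant to joint or
    separate rescaling of either spectrum.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("spectra must share a grid")
    if np.any(obs < 0) or np.any(fit < 0):
        raise ValueError("spectra must be non-negative")
    area_o, area_f = obs.sum(), fit.sum()
    if area_o == 0 or area_f == 0:
        raise ValueError("zero-area spectrum")
    return float(1.0 - 0.5 * np.abs(obs / area_o - fit / area_f).sum())


def fit_reporter_ratios(
    observed: np.ndarray, templates: Sequence[IsotopePattern]
) -> ReporterFit:
    """Non-negative least-squares mixture fit of channel templates.

    Minimizes ||observed - sum_c r_c * template_c||^2 over r_c >= 0, then
    reports ratios relative to channel 114 when its coefficient is detected
    (raw coefficients otherwise, with the channel flagged undetected).
    """
    obs = np.asarray(observed, dtype=float)
    if np.any(obs < 0):
        raise ValueError("observed intensities must be non-negative")
    if obs.sum() == 0:
        raise ValueError("all-zero observed spectrum")
    design = np.column_stack([t.intensity for t in templates])
    if obs.shape[0] != design.shape[0]:
        raise ValueError("observed spectrum and templates must share a grid")
    ill = False
    if np.linalg.matrix_rank(design) < design.shape[1]:
        ill = True
        warnings.warn("reporter templates are linearly dependent; fit is ill-conditioned")
    coeffs, _ = optimize.nnls(design, obs)
    fitted = design @ coeffs
    gof = goodness_of_fit(obs, fitted)
    detected = coeffs > DETECTION_FRACTION * coeffs.sum()
    if detected[0]:
        ratios = coeffs / coeffs[0]
    else:
        ratios = coeffs.copy()
    return ReporterFit(ratios, gof, coeffs, ill_conditioned=ill, detected=detected)


def filter_by_gof(
    fits: Iterable[ReporterFit], min_gof: float = DEFAULT_MIN_GOF
) -> list[ReporterFit]:
    """Keep fits with GOF >= min_gof ("below 0.8" excluded, boundary retained)."""
    if not 0 <= min_gof <= 1:
        raise ValueError("min_gof must be in [0, 1]")
    return [f for f in fits if f.gof >= min_gof]


def protein_ratio(peptide_ratios: Sequence[float]) -> float:
    """Geometric mean of peptide fold changes (arithmetic mean in log space)."""
    if len(peptide_ratios) == 0:
        raise ValueError("no peptide ratios to average")
    arr = np.asarray(peptide_ratios, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ratios must be > 0")
    return float(np.exp(np.log(arr).mean()))


def aggregate_peptides(
    fits: Mapping[str, Sequence[ReporterFit]],
    peptide_map: Mapping[str, str],
) -> pd.DataFrame:
    """Aggregate retained peptide fits to a protein x time-point ratio table.

    ``fits`` maps peptide id -> reporter fits (one per spectrum of that
    peptide); ``peptide_map`` maps peptide -> protein.  Per protein and time
    point the numeric ratios are averaged geometrically; a time point where
    every fit lacks control signal (but has treated signal) is ON, and one
    where every fit lacks treated signal (but has control) is OFF.  Returns a
    DataFrame indexed by protein with object columns per time point (float or
    ON/OFF token) and ``n_peptides``.
    """
    per_protein: dict[str, dict[str, list]] = {}
    pep_counts: dict[str, set[str]] = {}
    for pep, pep_fits in fits.items():
        if pep not in peptide_map:
            raise KeyError(f"peptide {pep!r} missing from peptide map")
        prot = peptide_map[pep]
        slot = per_protein.setdefault(prot, {tp: [] for tp in TIME_POINTS})
        pep_counts.setdefault(prot, set()).add(pep)
        for f in pep_fits:
            for i, tp in enumerate(TIME_POINTS, start=1):
                if not f.detected[0] and f.detected[i]:
                    slot[tp].append(ON)
                elif f.detected[0] and not f.detected[i]:
                    slot[tp].append(OFF)
                elif f.detected[0]:
                    slot[tp].append(float(f.ratios[i]))
    rows = {}
    for prot, slot in per_protein.items():
        row: dict[str, object] = {}
        for tp in TIME_POINTS:
            vals = slot[tp]
            numeric = [v for v in vals if isinstance(v, float)]
            if numeric:
                row[tp] = protein_ratio(numeric)
            elif vals and all(v == ON for v in vals):
                row[tp] = ON
            elif vals and all(v == OFF for v in vals):
                row[tp] = OFF
            else:
                row[tp] = np.nan
        row["n_peptides"] = len(pep_counts[prot])
        rows[prot] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "accession"
    return table[list(TIME_POINTS) + ["n_peptides"]]


def normalize_ratios(table: pd.DataFrame) -> pd.DataFrame:
    """Median-center each time-point column in log space (median ratio -> 1).

    ON/OFF tokens and missing values pass through untouched and are excluded
    from the median.
    """
    out = table.copy()
    for tp in TIME_POINTS:
        numeric = pd.to_numeric(out[tp], errors="coerce")
        med = np.exp(np.nanmedian(np.log(numeric.dropna().astype(float))))
        out[tp] = [
            v / med if isinstance(v, (int, float, np.floating)) and not pd.isna(v) else v
            for v in out[tp]
        ]
    return out


def signed_fold_change(ratio: float) -> float:
    """Signed-fold-change convention: r >= 1 -> r, r < 1 -> -1/r (|FC| >= 1)."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    return float(ratio) if ratio >= 1 else float(-1.0 / ratio)


def unsigned_ratio(fc: float) -> float:
    """Inverse of :func:`signed_fold_change` on the signed-FC scale."""
    if abs(fc) < 1:
        raise ValueError("|signed fold change| must be >= 1")
    return float(fc) if fc >= 1 else float(-1.0 / fc)


def compute_thresholds(
    normalized_ratios: Mapping[str, Sequence[float]] | pd.DataFrame,
    p_level: float = 0.1,
) -> DEThresholds:
    """Population-based significance thresholds per time point.

    On log2 ratios, tau_log2 = |median| + z*SD with z the two-sided Gaussian
    quantile for ``p_level`` (1.6449 at p < 0.1); reported on the symmetric
    signed-fold-change scale as tau = 2**tau_log2.
    """
    if not 0 < p_level < 1:
        raise ValueError("p_level must be in (0, 1)")
    z = float(stats.norm.ppf(1 - p_level / 2))
    tau = {}
    if isinstance(normalized_ratios, pd.DataFrame):
        cols = {
            tp: pd.to_numeric(normalized_ratios[tp], errors="coerce").dropna().astype(float)
            for tp in TIME_POINTS
            if tp in normalized_ratios
        }
    else:
        cols = {tp: np.asarray(v, dtype=float) for tp, v in normalized_ratios.items()}
    for tp, ratios in cols.items():
        arr = np.log2(np.asarray(ratios, dtype=float))
        if arr.size < 3:
            raise ValueError(f"need >= 3 ratios per time point, got {arr.size} for {tp}")
        tau[tp] = float(2.0 ** (abs(np.median(arr)) + z * arr.std(ddof=1)))
    return DEThresholds(tau=tau, z=z, p_level=p_level)


def call_differential(
    table: pd.DataFrame, thresholds: DEThresholds | Mapping[str, float]
) -> pd.DataFrame:
    """Mark per-time-point significance on a signed-fold-change table.

    A protein is significant at a time point iff its status there is ON or
    OFF, or |signed FC| >= tau for that time point (inclusive).  A fold
    change of exactly 1 (no change) is never significant, so a degenerate
    population with tau = 1 yields zero calls.  Ratio-scale columns are
    converted to signed fold changes; adds ``fc_<tp>`` (signed FC or token),
    ``sig_<tp>`` booleans and ``significant_any``.
    """
    tau = thresholds.tau if isinstance(thresholds, DEThresholds) else dict(thresholds)
    out = table.copy()
    for tp in TIME_POINTS:
        fcs, sigs = [], []
        for v in out[tp]:
            if isinstance(v, str) and v in (ON, OFF):
                fcs.append(v)
                sigs.append(True)
            elif pd.isna(v):
                fcs.append(np.nan)
                sigs.append(False)
            else:
                v = float(v)
                # accept either ratio scale (0 < v) or already-signed FC (|v| >= 1)
                fc = signed_fold_change(v) if 0 < v < 1 else v
                if abs(fc) < 1:
                    raise ValueError(f"fold change {v} is neither a ratio nor signed FC")
                fcs.append(fc)
                sigs.append(abs(fc) >= tau[tp] and abs(fc) > 1.0)
        out[f"fc_{tp}"] = fcs
        out[f"sig_{tp}"] = sigs
    out["significant_any"] = np.logical_or.reduce(
        [out[f"sig_{tp}"].to_numpy(dtype=bool) for tp in TIME_POINTS]
    )
    return out


def trend_pattern(row: pd.Series) -> tuple[str, ...]:
    """Discretized trajectory of one called protein: down/none/up/ON/OFF per time point."""
    pattern = []
    for tp in TIME_POINTS:
        fc, sig = row[f"fc_{tp}"], bool(row[f"sig_{tp}"])
        if isinstance(fc, str) and fc in (ON, OFF):
            pattern.append(fc)
        elif not sig or pd.isna(fc):
            pattern.append("none")
        else:
            pattern.append("up" if fc > 0 else "down")
    return tuple(pattern)


def cluster_trends(calls: pd.DataFrame) -> list[tuple[tuple[str, ...], list[str]]]:
    """Group proteins by identical discretized trajectories, largest group first."""
    groups: dict[tuple[str, ...], list[str]] = {}
    for acc, row in calls.iterrows():
        groups.setdefault(trend_pattern(row), []).append(str(acc))
    return sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
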