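"""Protein abundance from peptide counts: in-silico digestion, PAI/emPAI, affinity scores.

The exponentially modified Protein Abundance Index (emPAI) is a label-free
estimate of protein amount derived from peptide-level identification counts:

    PAI   = n_observed / n_observable
    emPAI = 10**PAI - 1

where ``n_observable`` is the number of distinct tryptic peptides of the
protein whose mass falls inside the instrument's detectable window, and
``n_observed`` is the number of those actually identified.  In an affinity
pull-down the amount of a protein captured on the drug matrix is taken as a
proxy for drug-target affinity, so affinities are emPAI values max-normalized
to (0, 1].
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

__all__ = [
    "STANDARD_RESIDUES",
    "DEFAULT_MASS_WINDOW",
    "Peptide",
    "AbundanceIndex",
    "tryptic_digest",
    "peptide_monoisotopic_mass",
    "count_observable",
    "compute_empai",
    "empai_for_sequence",
    "affinity_from_empai",
]

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Default observable-peptide mass window in Da.  Derived from a 400-2000 m/z
#: survey range with MS/MS triggered on 2+ and 3+ precursors:
#: (400-1.00728)*2 ~ 798 Da up to (2000-1.00728)*3 ~ 5997 Da.
DEFAULT_MASS_WINDOW = (798.0, 5997.0)

# Trypsin: cleave C-terminal to K or R unless the next residue is P.
_TRYPSIN_SITE = re.compile(r"(?<=[KR])(?!P)")


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty amino-acid sequence")
    for i, ch in enumerate(sequence):
        if ch not in STANDARD_RESIDUES:
            raise ValueError(
                f"invalid residue {ch!r} at position {i} (1-based {i + 1})"
            )


@dataclass(frozen=True)
class Peptide:
    """One tryptic cleavage product with its neutral monoisotopic mass."""

    sequence: str
    monoisotopic_mass: float
    missed_cleavages: int


@dataclass(frozen=True)
class AbundanceIndex:
    """PAI/emPAI for one protein."""

    n_observed: int
    n_observable: int
    pai: float
    empai: float


def peptide_monoisotopic_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a peptide in Da (residue masses + water)."""
    _validate_sequence(sequence)
    return float(_pmass.fast_mass(sequence))


def tryptic_digest(sequence: str, max_missed: int = 0) -> list[Peptide]:
    """Digest ``sequence`` with trypsin (cleave after K/R, not before P).

    Returns every product with 0..``max_missed`` missed cleavages, in
    N-to-C order (grouped by start position, shorter products first), each
    annotated with its missed-cleavage count and monoisotopic mass.
    """
    _validate_sequence(sequence)
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    fragments = [f for f in _TRYPSIN_SITE.split(sequence) if f]
    peptides: list[Peptide] = []
    for start in range(len(fragments)):
        for stop in range(start + 1, min(start + 2 + max_missed, len(fragments) + 1)):
            pep = "".join(fragments[start:stop])
            peptides.append(
                Peptide(pep, peptide_monoisotopic_mass(pep), stop - start - 1)
            )
    return peptides


def count_observable(
    peptides: Iterable[Peptide],
    mass_min: float = DEFAULT_MASS_WINDOW[0],
    mass_max: float = DEFAULT_MASS_WINDOW[1],
) -> int:
    """Number of distinct peptide sequences with mass in [mass_min, mass_max]."""
    if not mass_min < mass_max:
        raise ValueError("mass_min must be < mass_max")
    return len(
        {p.sequence for p in peptides if mass_min <= p.monoisotopic_mass <= mass_max}
    )


def compute_empai(n_observed: int, n_observable: int) -> AbundanceIndex:
    """PAI = n_observed/n_observable; emPAI = 10**PAI - 1."""
    if n_observable <= 0:
        raise ValueError("abundance index undefined: no observable peptides")
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    pai = n_observed / n_observable
    return AbundanceIndex(n_observed, n_observable, pai, 10.0**pai - 1.0)


def empai_for_sequence(
    sequence: str,
    n_observed: int,
    *,
    mass_window: tuple[float, float] = DEFAULT_MASS_WINDOW,
    max_missed: int = 0,
) -> AbundanceIndex:
    """Convenience: digest, count observables in the mass window, compute emPAI."""
    peptides = tryptic_digest(sequence, max_missed=max_missed)
    n_observable = count_observable(peptides, *mass_window)
    if n_observable == 0:
        raise ValueError(
            "abundance index undefined: no observable peptides in mass window"
        )
    return compute_empai(n_observed, n_observable)


def affinity_from_empai(
    empai_by_accession: Mapping[str, float],
    forced_full_affinity: Iterable[str] = (),
) -> dict[str, float]:
    """Max-normalize emPAI values to affinity scores in (0, 1].

    Members of ``forced_full_affinity`` (e.g. targets validated by orthogonal
    experiments but absent from the pull-down) get affinity exactly 1 and are
    added to the map if missing.  Scale-invariant: multiplying every emPAI by
    a positive constant leaves the result unchanged.
    """
    forced = set(forced_full_affinity)
    if not empai_by_accession and not forced:
        raise ValueError("no emPAI values and no forced accessions")
    for acc, v in empai_by_accession.items():
        if v <= 0:
            raise ValueError(f"emPAI for {acc} must be > 0, got {v}")
    affinities: dict[str, float] = {}
    if empai_by_accession:
        top = max(empai_by_accession.values())
        affinities = {a: v / top for a, v in empai_by_accession.items()}
    for acc in forced:
        affinities[acc] = 1.0
    return affinities
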