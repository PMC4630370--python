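"""Target deconvolution for affinity-purification MS hit lists.

AP-MS pull-downs carry heavy background: proteins that stick to the unloaded
matrix, ubiquitously expressed "central proteome" proteins, and frequent
contaminants catalogued by CRAPome-style repositories.  The filter chain here
is (1) subtract matrix binders identified in the no-drug control, (2) subtract
central-proteome members, (3) annotate survivors and removed members with
their average spectral count from a contaminant repository (annotation only
by default — the count is supporting evidence, not a filter), then report
known protein complexes overlapping the filtered profile.

Accessions are matched on their root: isoform suffixes ("-2") and versions
(".3") are stripped before comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TargetProfile",
    "DeconReport",
    "normalize_accession",
    "subtract_nonspecific",
    "subtract_central_proteome",
    "crapome_annotate",
    "complex_overlap",
    "deconvolve",
]


def normalize_accession(accession: str) -> str:
    """Strip isoform ("-n") and version (".n") suffixes from an accession."""
    acc = accession.strip()
    for sep in ("-", "."):
        head, _, tail = acc.partition(sep)
        if tail.isdigit():
            acc = head
    return acc


@dataclass
class TargetProfile:
    """Ordered accession set surviving the filter chain, with provenance flags."""

    accessions: list[str]
    n_removed_sticky: int = 0
    n_removed_central: int = 0
    central_flags: dict[str, bool] = field(default_factory=dict)
    crapome_counts: dict[str, float] = field(default_factory=dict)
    affinities: dict[str, float] | None = None

    def __len__(self) -> int:
        return len(self.accessions)

    def __contains__(self, accession: str) -> bool:
        return normalize_accession(accession) in set(self.accessions)


@dataclass(frozen=True)
class DeconReport:
    """Counts at every stage of the filter chain plus complex overlap."""

    n_identified: int
    n_sticky: int
    n_profile: int
    n_central: int
    n_filtered: int
    n_crapome_above: int
    complex_hits: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if self.n_profile != self.n_identified - self.n_sticky:
            raise ValueError("report identity violated: n_profile != n_identified - n_sticky")
        if self.n_filtered != self.n_profile - self.n_central:
            raise ValueError("report identity violated: n_filtered != n_profile - n_central")


def _normalized_unique(accessions: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for acc in accessions:
        seen.setdefault(normalize_accession(acc), None)
    return list(seen)


def subtract_nonspecific(
    identified: Iterable[str], sticky: Iterable[str]
) -> TargetProfile:
    """Remove proteins also retained on the unloaded control matrix."""
    ids = _normalized_unique(identified)
    sticky_set = set(_normalized_unique(sticky))
    survivors = [a for a in ids if a not in sticky_set]
    return TargetProfile(survivors, n_removed_sticky=len(ids) - len(survivors))


def subtract_central_proteome(
    profile: TargetProfile, central: Iterable[str]
) -> TargetProfile:
    """Remove central-proteome members; flag which profile members they were."""
    central_set = set(_normalized_unique(central))
    flags = {a: (a in central_set) for a in profile.accessions}
    survivors = [a for a in profile.accessions if not flags[a]]
    return TargetProfile(
        survivors,
        n_removed_sticky=profile.n_removed_sticky,
        n_removed_central=len(profile.accessions) - len(survivors),
        central_flags=flags,
        crapome_counts=dict(profile.crapome_counts),
        affinities=profile.affinities,
    )


def crapome_annotate(
    profile: TargetProfile,
    counts: Mapping[str, float],
    threshold: float = 2.0,
    *,
    accessions: Iterable[str] | None = None,
    remove: bool = False,
) -> tuple[TargetProfile, int]:
    """Annotate accessions with contaminant-repository average spectral counts.

    Returns the profile and the number of annotated accessions with count
    strictly greater than ``threshold``.  By default annotation covers the
    central-proteome members flagged during subtraction (the set whose
    contaminant status the repository corroborates); pass ``accessions`` to
    annotate a different set.  With ``remove=True`` profile members above the
    threshold are additionally dropped.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    norm_counts = {}
    for acc, c in counts.items():
        if c < 0:
            raise ValueError(f"negative spectral count for {acc}: {c}")
        norm_counts[normalize_accession(acc)] = float(c)
    if accessions is None:
        flagged_central = [a for a, f in profile.central_flags.items() if f]
        pool = flagged_central if flagged_central else list(profile.accessions)
    else:
        pool = _normalized_unique(accessions)
    annotations = {a: norm_counts[a] for a in pool if a in norm_counts}
    n_above = sum(1 for c in annotations.values() if c > threshold)
    members = profile.accessions
    if remove:
        members = [a for a in members if annotations.get(a, 0.0) <= threshold]
    out = TargetProfile(
        list(members),
        n_removed_sticky=profile.n_removed_sticky,
        n_removed_central=profile.n_removed_central,
        central_flags=dict(profile.central_flags),
        crapome_counts={**profile.crapome_counts, **annotations},
        affinities=profile.affinities,
    )
    return out, n_above


def complex_overlap(
    profile: TargetProfile | Iterable[str],
    catalog: Mapping[str, Iterable[str]],
    min_members: int = 2,
) -> list[tuple[str, int, int]]:
    """Protein complexes with >= min_members members in the profile.

    Returns (complex id, members present, complex size), sorted by members
    present descending, then complex id.
    """
    if min_members < 1:
        raise ValueError("min_members must be >= 1")
    members = set(
        profile.accessions if isinstance(profile, TargetProfile) else _normalized_unique(profile)
    )
    hits = []
    for cid, complex_members in catalog.items():
        cm = set(_normalized_unique(complex_members))
        present = len(cm & members)
        if present >= min_members:
            hits.append((cid, present, len(cm)))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def deconvolve(
    identified: Iterable[str],
    sticky: Iterable[str],
    central: Iterable[str],
    crapome_counts: Mapping[str, float] | None = None,
    complex_catalog: Mapping[str, Iterable[str]] | None = None,
    *,
    crapome_threshold: float = 2.0,
    min_complex_members: int = 2,
    crapome_filter: bool = False,
) -> tuple[DeconReport, TargetProfile]:
    """Run the full filter chain and emit a stage-by-stage report."""
    ids = _normalized_unique(identified)
    profile = subtract_nonspecific(ids, sticky)
    profile = subtract_central_proteome(profile, central)
    n_above = 0
    if crapome_counts is not None:
        profile, n_above = crapome_annotate(
            profile, crapome_counts, crapome_threshold, remove=crapome_filter
        )
    hits = (
        complex_overlap(profile, complex_catalog, min_complex_members)
        if complex_catalog
        else []
    )
    report = DeconReport(
        n_identified=len(ids),
        n_sticky=profile.n_removed_sticky,
        n_profile=len(ids) - profile.n_removed_sticky,
        n_central=profile.n_removed_central,
        n_filtered=len(ids) - profile.n_removed_sticky - profile.n_removed_central,
        n_crapome_above=n_above,
        complex_hits=hits,
    )
    return report, profile
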