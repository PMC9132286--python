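"""Flexible-region detection and designability filtering.

Turns per-residue RMSF profiles into highly flexible regions: the pooled
mean RMSF over all residues of all models is the cutoff, residues strictly
above it are flagged, consecutive flagged residues merge into regions,
configured exclusion zones (e.g. a floppy C-terminus) are dropped, regions
are ranked by mean RMSF, and positions are screened by their minimum
distance to the catalytic residues (strictly more than 15 Å by default).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import RmsfProfile
from .io import StructureModel

__all__ = [
    "FlexibleRegion",
    "DesignabilityMask",
    "flexibility_cutoff",
    "flag_flexible_residues",
    "merge_into_regions",
    "summarize_region",
    "summarize_region_replicates",
    "rank_regions",
    "active_site_distance",
    "designability_mask",
    "identify_flexible_regions",
]

#: Default designability rule: strictly more than 15 Å from any catalytic residue.
DEFAULT_MIN_ACTIVE_SITE_DISTANCE = 15.0


@dataclass(frozen=True)
class FlexibleRegion:
    """A maximal run of consecutive highly flexible residues."""

    region_id: int
    start_residue: int
    end_residue: int
    mean_rmsf: float = float("nan")
    sd_rmsf: float = float("nan")

    def __post_init__(self):
        if self.start_residue > self.end_residue:
            raise ValueError("region start must not exceed end")

    @property
    def n_residues(self) -> int:
        return self.end_residue - self.start_residue + 1

    @property
    def residues(self) -> range:
        return range(self.start_residue, self.end_residue + 1)

    def __contains__(self, residue_number: int) -> bool:
        return self.start_residue <= residue_number <= self.end_residue


@dataclass(frozen=True)
class DesignabilityMask:
    residue_number: int
    distance_to_active_site: float
    designable: bool


def flexibility_cutoff(profiles: Sequence[RmsfProfile] | RmsfProfile) -> float:
    """Arithmetic mean of the pooled per-residue RMSF over all profiles (Å)."""
    if isinstance(profiles, RmsfProfile):
        profiles = [profiles]
    if not profiles:
        raise ValueError("need at least one RMSF profile")
    return float(np.mean(np.concatenate([p.rmsf for p in profiles])))


def flag_flexible_residues(profile: RmsfProfile, cutoff: float) -> set[int]:
    """Residues with RMSF strictly above the cutoff (values exactly at it are not flagged)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return set(profile.residue_numbers[profile.rmsf > cutoff].tolist())


def _in_any(residue: int, intervals: Iterable[tuple[int, int]]) -> bool:
    return any(a <= residue <= b for a, b in intervals)


def merge_into_regions(flagged: Iterable[int],
                       exclusion: Sequence[tuple[int, int]] = (),
                       gap_tolerance: int = 0) -> list[FlexibleRegion]:
    """Merge flagged residues into maximal runs of consecutive residue numbers.

    Residues inside any ``exclusion`` interval are dropped before merging.
    ``gap_tolerance`` residues may be bridged (default 0: strict adjacency).
    Regions come back sorted by start with ids 1..n.
    """
    kept = sorted(r for r in set(flagged) if not _in_any(r, exclusion))
    regions: list[FlexibleRegion] = []
    for res in kept:
        if regions and res - regions[-1].end_residue <= gap_tolerance + 1:
            last = regions[-1]
            regions[-1] = replace(last, end_residue=res)
        else:
            regions.append(FlexibleRegion(len(regions) + 1, res, res))
    return regions


def summarize_region(region: FlexibleRegion | tuple[int, int],
                     profile: RmsfProfile,
                     region_id: int | None = None) -> FlexibleRegion:
    """Fill a region's mean and sd RMSF from a profile (population sd across residues)."""
    if isinstance(region, tuple):
        region = FlexibleRegion(region_id or 0, region[0], region[1])
    values = profile.region_values(region.start_residue, region.end_residue)
    return replace(region, mean_rmsf=float(np.mean(values)), sd_rmsf=float(np.std(values)))


def summarize_region_replicates(region: FlexibleRegion,
                                profiles: Sequence[RmsfProfile]) -> FlexibleRegion:
    """Fill a region's statistics from replicate profiles.

    The mean is the average of the replicates' region-mean RMSF; the sd is
    the sample standard deviation across replicates (0 for one replicate).
    """
    if not profiles:
        raise ValueError("need at least one replicate profile")
    means = [p.region_mean(region.start_residue, region.end_residue) for p in profiles]
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return replace(region, mean_rmsf=float(np.mean(means)), sd_rmsf=sd)


def rank_regions(regions: Sequence[FlexibleRegion], k: int) -> list[FlexibleRegion]:
    """Top-k regions by mean RMSF (descending); ties break to the smaller region id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(regions):
        raise ValueError(f"k={k} exceeds the {len(regions)} available regions")
    return sorted(regions, key=lambda r: (-r.mean_rmsf, r.region_id))[:k]


def active_site_distance(model: StructureModel, residue_number: int,
                         catalytic_residues: Sequence[int]) -> float:
    """Minimum distance (Å) from any atom of a residue to any atom of any catalytic residue."""
    res_idx = model.residue_atom_indices(residue_number)
    cat_idx = np.concatenate([model.residue_atom_indices(c) for c in catalytic_residues])
    return float(cdist(model.coords[res_idx], model.coords[cat_idx]).min())


def designability_mask(model: StructureModel,
                       regions: Sequence[FlexibleRegion],
                       catalytic_residues: Sequence[int],
                       threshold: float = DEFAULT_MIN_ACTIVE_SITE_DISTANCE
                       ) -> list[DesignabilityMask]:
    """Per-residue designability over the given regions.

    A position is designable iff its minimum active-site distance is
    strictly greater than ``threshold`` ("more than 15 Å"): a residue at
    exactly the threshold is not designable.
    """
    out = []
    for region in regions:
        for res in region.residues:
            d = active_site_distance(model, res, catalytic_residues)
            out.append(DesignabilityMask(res, d, d > threshold))
    return out


def identify_flexible_regions(profiles: Sequence[RmsfProfile] | RmsfProfile,
                              exclusion: Sequence[tuple[int, int]] = (),
                              gap_tolerance: int = 0,
                              cutoff: float | None = None) -> list[FlexibleRegion]:
    """Full detection pass: pooled cutoff → flags (union over profiles) → merged regions.

    With several (replicate) profiles a residue is flagged if its mean RMSF
    across profiles exceeds the cutoff; region statistics are then filled
    from replicate region means.
    """
    if isinstance(profiles, RmsfProfile):
        profiles = [profiles]
    if cutoff is None:
        cutoff = flexibility_cutoff(profiles)
    common = sorted(set.intersection(*(set(p.residue_numbers.tolist()) for p in profiles)))
    mean_profile = RmsfProfile(
        np.array(common),
        np.array([np.mean([p.value_at(r) for p in profiles]) for r in common]),
        profiles[0].selection, "mean-of-replicates")
    flagged = flag_flexible_residues(mean_profile, cutoff)
    regions = merge_into_regions(flagged, exclusion, gap_tolerance)
    return [summarize_region_replicates(r, profiles) for r in regions]
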