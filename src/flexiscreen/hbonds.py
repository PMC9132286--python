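"""Geometric hydrogen-bond detection and occupancy statistics.

A hydrogen bond exists in a frame iff (i) the donor-heavy-atom to acceptor
distance is ≤ 3.5 Å and (ii) the donor–H⋯acceptor angle, measured at the
hydrogen, is ≥ 120°; both criteria are inclusive at the boundary.
Occupancy is the percentage of frames in which a (donor heavy atom,
acceptor) pair satisfies the criteria — alternative hydrogens on one donor
count as one bond per frame — and is classified into four strength levels:
strong (> 75 %), medium (75–50 %), weak (50–25 %), very weak (25–10 %);
occupancies at or below 10 % go unreported.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .io import Ensemble, HBondTopology, StructureModel
from .regions import FlexibleRegion

__all__ = [
    "HBondObservation",
    "HBondStat",
    "HBondCounts",
    "detect_hbonds_frame",
    "hbond_occupancy",
    "classify_strength",
    "region_hbond_summary",
    "diff_hbond_reports",
]

DEFAULT_DISTANCE_MAX = 3.5     # donor-heavy to acceptor, Å (inclusive)
DEFAULT_ANGLE_MIN = 120.0      # D–H⋯A angle at the hydrogen, degrees (inclusive)
OCCUPANCY_REPORT_MIN = 10.0    # percent; at or below → unreported

STRENGTH_LEVELS = ("strong", "medium", "weak", "very_weak")


@dataclass(frozen=True)
class HBondObservation:
    """One geometric hydrogen bond in one frame (atom indices into the model)."""

    donor_atom: int
    hydrogen: int
    acceptor_atom: int
    frame: int = 0


@dataclass(frozen=True)
class HBondStat:
    """Ensemble occupancy of one (donor heavy atom, acceptor) pair."""

    donor_atom: int
    acceptor_atom: int
    donor_residue: int
    acceptor_residue: int
    donor_atom_name: str
    acceptor_atom_name: str
    occupancy: float
    strength: str

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 100.0:
            raise ValueError("occupancy must lie in [0, 100]")


@dataclass(frozen=True)
class HBondCounts:
    """Per-strength-class bond counts for one region (Table-5 shape)."""

    region_id: int
    strong: int = 0
    medium: int = 0
    weak: int = 0
    very_weak: int = 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.strong, self.medium, self.weak, self.very_weak)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


def detect_hbonds_frame(model: StructureModel, topology: HBondTopology,
                        d_max: float = DEFAULT_DISTANCE_MAX,
                        angle_min: float = DEFAULT_ANGLE_MIN,
                        frame: int = 0) -> list[HBondObservation]:
    """All hydrogen bonds in one conformation (intra-residue pairs excluded)."""
    if not topology.donors or not topology.acceptors:
        return []
    donors = np.array(topology.donors, dtype=int)      # (m, 2): heavy, H
    acceptors = np.array(topology.acceptors, dtype=int)
    coords = model.coords
    dist = cdist(coords[donors[:, 0]], coords[acceptors])
    # boundaries are inclusive; tiny slack absorbs floating-point round-off
    cand = np.argwhere(dist <= d_max + 1e-9)
    out = []
    for di, ai in cand:
        heavy, hyd = donors[di]
        acc = acceptors[ai]
        if acc == heavy or acc == hyd:
            continue
        if model.res_ids[heavy] == model.res_ids[acc]:
            continue
        v1 = coords[heavy] - coords[hyd]
        v2 = coords[acc] - coords[hyd]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= angle_min - 1e-9:
            out.append(HBondObservation(int(heavy), int(hyd), int(acc), frame))
    return out


def hbond_occupancy(ensemble: Ensemble, topology: HBondTopology,
                    d_max: float = DEFAULT_DISTANCE_MAX,
                    angle_min: float = DEFAULT_ANGLE_MIN,
                    window: tuple[int, int] | None = None) -> list[HBondStat]:
    """Occupancy of every observed (donor heavy atom, acceptor) pair over the ensemble.

    ``window`` restricts the statistic to a half-open frame interval.
    Several hydrogens on one donor count as a single bond per frame.
    """
    start, stop = (0, ensemble.n_frames) if window is None else window
    n_frames = stop - start
    if n_frames <= 0:
        raise ValueError("occupancy requires at least one frame")
    counts: dict[tuple[int, int], int] = {}
    for f in range(start, stop):
        obs = detect_hbonds_frame(ensemble.frame(f), topology, d_max, angle_min, frame=f)
        for pair in {(o.donor_atom, o.acceptor_atom) for o in obs}:
            counts[pair] = counts.get(pair, 0) + 1
    t = ensemble.template
    stats = []
    for (donor, acc), n in sorted(counts.items()):
        occ = 100.0 * n / n_frames
        stats.append(HBondStat(
            donor, acc, int(t.res_ids[donor]), int(t.res_ids[acc]),
            str(t.names[donor]), str(t.names[acc]), occ, classify_strength(occ)))
    return stats


def classify_strength(occupancy: float) -> str:
    """Map an occupancy percentage to its strength class.

    strong > 75 ≥ medium > 50 ≥ weak > 25 ≥ very_weak > 10 ≥ unreported.
    """
    if not 0.0 <= occupancy <= 100.0:
        raise ValueError(f"occupancy {occupancy} outside [0, 100]")
    if occupancy > 75.0:
        return "strong"
    if occupancy > 50.0:
        return "medium"
    if occupancy > 25.0:
        return "weak"
    if occupancy > OCCUPANCY_REPORT_MIN:
        return "very_weak"
    return "unreported"


def _region_min_distances(model: StructureModel, region: FlexibleRegion) -> dict[int, float]:
    in_region = np.isin(model.res_ids, list(region.residues))
    region_coords = model.coords[in_region]
    out = {}
    for res in np.unique(model.res_ids):
        idx = model.res_ids == res
        out[int(res)] = float(cdist(model.coords[idx], region_coords).min())
    return out


def region_hbond_summary(stats: Sequence[HBondStat], region: FlexibleRegion,
                         neighbor_cutoff: float | None = None,
                         model: StructureModel | None = None) -> HBondCounts:
    """Count reported bonds with at least one partner residue inside the region.

    By default the other partner may be any residue. With ``neighbor_cutoff``
    (and a reference ``model``), the outside partner must lie within that
    distance of the region. One count per unique donor/acceptor pair.
    """
    min_dist = None
    if neighbor_cutoff is not None:
        if model is None:
            raise ValueError("neighbor_cutoff requires a reference model")
        min_dist = _region_min_distances(model, region)
    tallies = dict.fromkeys(STRENGTH_LEVELS, 0)
    seen = set()
    for s in stats:
        key = (s.donor_atom, s.acceptor_atom)
        if key in seen or s.strength == "unreported":
            continue
        d_in, a_in = s.donor_residue in region, s.acceptor_residue in region
        if not (d_in or a_in):
            continue
        if min_dist is not None:
            partner = s.acceptor_residue if d_in else s.donor_residue
            if min_dist.get(partner, np.inf) > neighbor_cutoff:
                continue
        seen.add(key)
        tallies[s.strength] += 1
    return HBondCounts(region.region_id, **tallies)


def diff_hbond_reports(wildtype: HBondCounts, mutant: HBondCounts) -> dict[str, int]:
    """Signed per-class (mutant − wild type) bond-count deltas plus the total."""
    if wildtype.region_id != mutant.region_id:
        raise ValueError("summaries describe different regions")
    deltas = {level: getattr(mutant, level) - getattr(wildtype, level)
              for level in STRENGTH_LEVELS}
    deltas["total"] = mutant.total - wildtype.total
    return deltas
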