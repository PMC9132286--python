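"""Three-state secondary-structure assignment (simplified DSSP).

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (r in Å);
a bond exists iff E < −0.5 kcal/mol. Pattern rules then assign the 8-state
classes — consecutive n-turns give helices (G/H/I), bridge patterns give
strands (E/B) — which collapse to three states: {H, G, I} → helix,
{E, B} → sheet, everything else → coil. Amide hydrogens are synthesized
geometrically when the structure lacks them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Ensemble, StructureModel
from .regions import FlexibleRegion

__all__ = [
    "SecStructAssignment",
    "SecStructSummary",
    "backbone_hbond_energy",
    "assign_secstruct_frame",
    "assign_states",
    "region_secstruct_percentages",
]

KS_ENERGY_CUTOFF = -0.5   # kcal/mol
_KS_FACTOR = 0.084 * 332.0
_CHAIN_BREAK_CN = 2.5     # Å; larger C(i)–N(i+1) distance breaks the chain
STATES = ("sheet", "helix", "coil")


@dataclass(frozen=True)
class SecStructAssignment:
    residue_number: int
    state: str
    frame: int = 0


@dataclass(frozen=True)
class SecStructSummary:
    """Region-level secondary-structure percentages, mean ± sd across replicates."""

    region_id: int
    pct_sheet: float
    pct_helix: float
    pct_coil: float
    sd_sheet: float = 0.0
    sd_helix: float = 0.0
    sd_coil: float = 0.0

    def __post_init__(self):
        if abs(self.pct_sheet + self.pct_helix + self.pct_coil - 100.0) > 0.2:
            raise ValueError("percentages must sum to 100 within rounding")


def backbone_hbond_energy(donor_atoms: dict, acceptor_atoms: dict) -> float:
    """Kabsch–Sander energy of an N–H → C=O backbone hydrogen bond (kcal/mol).

    ``donor_atoms`` needs positions for N and H; ``acceptor_atoms`` for C and O.
    """
    n, h = np.asarray(donor_atoms["N"]), np.asarray(donor_atoms["H"])
    c, o = np.asarray(acceptor_atoms["C"]), np.asarray(acceptor_atoms["O"])
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return -np.inf  # overlapping atoms: treat as (unphysically) bonded
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _synthesize_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray) -> np.ndarray:
    """Place H opposite the bisector of C(prev)–N–Cα at 1.01 Å."""
    d = -((c_prev - n) / np.linalg.norm(c_prev - n) + (ca - n) / np.linalg.norm(ca - n))
    return n + 1.01 * d / np.linalg.norm(d)


class _Backbone:
    """Per-residue backbone geometry with chain-break bookkeeping."""

    def __init__(self, model: StructureModel):
        residues = list(dict.fromkeys(
            zip(model.chains.tolist(), model.res_ids.tolist())))
        atoms: list[dict] = []
        kept: list[tuple[str, int]] = []
        skipped = []
        for chain, res in residues:
            mask = (model.res_ids == res) & (model.chains == chain)
            entry = {}
            for name in ("N", "CA", "C", "O", "H"):
                idx = np.flatnonzero(mask & (model.names == name))
                if idx.size:
                    entry[name] = model.coords[idx[0]]
            if all(k in entry for k in ("N", "CA", "C", "O")):
                atoms.append(entry)
                kept.append((chain, res))
            else:
                skipped.append(res)
        if skipped:
            warnings.warn(f"residues {skipped} lack a complete backbone and "
                          "were skipped", stacklevel=3)
        self.atoms = atoms
        self.res_ids = [res for _, res in kept]
        n = len(atoms)
        # continuity: peptide bond present between i and i+1 within one chain
        self.connected = np.zeros(max(n - 1, 0), dtype=bool)
        for i in range(n - 1):
            same_chain = kept[i][0] == kept[i + 1][0]
            self.connected[i] = same_chain and (
                np.linalg.norm(atoms[i + 1]["N"] - atoms[i]["C"]) <= _CHAIN_BREAK_CN)
        # Kabsch–Sander convention: a chain-start residue has no amide proton
        # available for pattern search, so it never donates.
        self.can_donate = np.zeros(n, dtype=bool)
        for i in range(n):
            if i > 0 and self.connected[i - 1]:
                self.can_donate[i] = True
                if "H" not in atoms[i]:
                    atoms[i]["H"] = _synthesize_amide_h(atoms[i]["N"], atoms[i]["CA"],
                                                        atoms[i - 1]["C"])

    def __len__(self) -> int:
        return len(self.atoms)

    def contiguous(self, i: int, j: int) -> bool:
        lo, hi = sorted((i, j))
        return bool(self.connected[lo:hi].all())

    def hbond(self, i: int, j: int) -> bool:
        """True iff CO of residue i accepts a hydrogen bond from NH of residue j."""
        if not (0 <= i < len(self) and 0 <= j < len(self)) or abs(i - j) < 2:
            return False
        donor = self.atoms[j]
        if not self.can_donate[j] or "H" not in donor:
            return False
        return backbone_hbond_energy(donor, self.atoms[i]) < KS_ENERGY_CUTOFF


def assign_states(model: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    """3-state assignment for one conformation.

    Returns ``(residue_numbers, states)`` where states are ``sheet`` /
    ``helix`` / ``coil``. Pattern search restarts after chain breaks.
    """
    bb = _Backbone(model)
    n = len(bb)
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if abs(i - j) >= 2 and bb.hbond(i, j):
                hb[i, j] = True

    def turn(order: int, i: int) -> bool:
        return (i + order < n and bb.contiguous(i, i + order) and hb[i, i + order])

    helix = np.zeros(n, dtype=bool)
    for order, length in ((4, 4), (3, 3), (5, 5)):  # H before G before I
        for i in range(1, n - order):
            if turn(order, i - 1) and turn(order, i):
                helix[i:i + length] = True

    sheet = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 3, n):
            para = ((hb[i - 1, j] and hb[j, i + 1] if i >= 1 and i + 1 < n else False)
                    or (hb[j - 1, i] and hb[i, j + 1] if j >= 1 and j + 1 < n else False))
            anti = ((hb[i, j] and hb[j, i])
                    or (hb[i - 1, j + 1] and hb[j - 1, i + 1]
                        if i >= 1 and j + 1 < n else False))
            if para or anti:
                sheet[i] = sheet[j] = True

    states = np.where(helix, "helix", "coil")
    states = np.where(sheet & ~helix, "sheet", states)  # 4-helix outranks a bridge
    return np.array(bb.res_ids), states.astype("U5")


def assign_secstruct_frame(model: StructureModel, frame: int = 0) -> list[SecStructAssignment]:
    res_ids, states = assign_states(model)
    return [SecStructAssignment(int(r), str(s), frame) for r, s in zip(res_ids, states)]


def region_secstruct_percentages(replicates: Sequence[Ensemble] | Ensemble,
                                 region: FlexibleRegion) -> SecStructSummary:
    """Sheet/helix/coil percentages of a region, mean ± sd across replicate ensembles.

    Per frame the fraction of the region's residues in each state is taken,
    averaged over the frames of each replicate, then summarized across
    replicates (sample sd; 0 for a single replicate).
    """
    if isinstance(replicates, Ensemble):
        replicates = [replicates]
    if not replicates:
        raise ValueError("need at least one ensemble")
    per_replicate = []
    for ens in replicates:
        frame_fracs = []
        for f in range(ens.n_frames):
            res_ids, states = assign_states(ens.frame(f))
            in_region = np.isin(res_ids, list(region.residues))
            if not in_region.any():
                raise ValueError(f"region {region.region_id} has no assignable residues")
            frame_fracs.append([np.mean(states[in_region] == s) for s in STATES])
        per_replicate.append(100.0 * np.mean(frame_fracs, axis=0))
    arr = np.array(per_replicate)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(3)
    return SecStructSummary(region.region_id, *mean.tolist(),
                            sd_sheet=sd[0], sd_helix=sd[1], sd_coil=sd[2])
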