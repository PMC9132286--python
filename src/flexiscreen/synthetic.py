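"""Synthetic conformational ensembles with planted, recoverable structure.

Stands in for MD trajectories: a polyalanine backbone built from ideal
internal coordinates is perturbed by independent per-atom Gaussian
displacements whose per-residue amplitudes (σ, Å per coordinate) are
prescribed, so the expected RMSF is known in closed form (σ√3 without
superposition). Hydrogen-bond pairs can be planted at exact frame
occupancies, and "mutant" ensembles scale the amplitudes of one region so
the expected regional ΔRMSF is 100·(scale − 1) %.

The generator is a null model of the marginal conformational distribution
only — it has no dynamics, no force field and no temperature; labels such
as "500 K" map to nothing but larger amplitude profiles chosen by the
caller.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import DesignRecord, Ensemble, StructureModel
from .regions import FlexibleRegion

__all__ = [
    "EnsembleSpec",
    "build_toy_protein",
    "build_antiparallel_sheet",
    "generate_ensemble",
    "generate_mutant_pair",
    "make_design_table_fixture",
]

# Ideal backbone internal coordinates (Å / degrees, standard peptide values)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0

#: Backbone dihedrals (φ, ψ) per ideal geometry
DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "coil": (-75.0, 145.0),   # polyproline-II-like: hydrogen-bond free
}

# Planted hydrogen-bond geometry: unambiguous w.r.t. the 3.5 Å / 120° criteria
_HB_ON_DISTANCE = 2.9    # donor-heavy to acceptor, Å
_HB_ON_ANGLE = 165.0     # D–H⋯A angle, degrees
_HB_OFF_DISTANCE = 4.5   # Å, safely outside the distance criterion


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position d with |cd| = bond, ∠(b,c,d) = angle and dihedral(a,b,c,d)."""
    theta, chi = np.radians(angle), np.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(chi),
                        bond * np.sin(theta) * np.sin(chi)])
    return c + m @ d_local


def _build_backbone(phi_psi: list[tuple[float, float]], chain: str = "A",
                    first_res_id: int = 1) -> StructureModel:
    n_res = len(phi_psi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    alpha = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(alpha), np.sin(alpha), 0.0])
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_prev)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi_psi[i][0])
    names, elements, res_ids, coords = [], [], [], []
    for i in range(n_res):
        O = _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, phi_psi[i][1] + 180.0)
        if i == 0:
            d = -((CA[i] - N[i]) / np.linalg.norm(CA[i] - N[i])
                  + (C[i] - N[i]) / np.linalg.norm(C[i] - N[i]))
        else:
            d = -((C[i - 1] - N[i]) / np.linalg.norm(C[i - 1] - N[i])
                  + (CA[i] - N[i]) / np.linalg.norm(CA[i] - N[i]))
        H = N[i] + _B_N_H * d / np.linalg.norm(d)
        for name, elem, pos in (("N", "N", N[i]), ("H", "H", H), ("CA", "C", CA[i]),
                                ("C", "C", C[i]), ("O", "O", O)):
            names.append(name)
            elements.append(elem)
            res_ids.append(first_res_id + i)
            coords.append(pos)
    n_atoms = len(names)
    return StructureModel(names, elements, res_ids, ["ALA"] * n_atoms,
                          [chain] * n_atoms, np.array(coords))


def build_toy_protein(n_residues: int, base_geometry: str = "helix") -> StructureModel:
    """Polyalanine backbone (N, H, Cα, C, O per residue) with ideal dihedrals.

    ``mixed`` concatenates helix, coil and strand segments of roughly equal
    length in one chain.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if base_geometry == "mixed":
        thirds = [n_residues // 3, n_residues // 3,
                  n_residues - 2 * (n_residues // 3)]
        phi_psi = []
        for geom, length in zip(("helix", "coil", "strand"), thirds):
            phi_psi += [DIHEDRALS[geom]] * length
    elif base_geometry in DIHEDRALS:
        phi_psi = [DIHEDRALS[base_geometry]] * n_residues
    else:
        raise ValueError(f"unknown base geometry {base_geometry!r}")
    return _build_backbone(phi_psi)


def build_antiparallel_sheet(n_residues: int = 8) -> StructureModel:
    """Two-chain antiparallel β-sheet built by pairing a strand with its 180°-rotated copy.

    The second strand is rotated about the first strand's axis and slid
    (grid search) to the register that maximizes the number of inter-strand
    O···N contacts at hydrogen-bond range.
    """
    a = _build_backbone([DIHEDRALS["strand"]] * n_residues, chain="A", first_res_id=1)
    ca = a.coords[a.names == "CA"]
    centroid = ca.mean(axis=0)
    # strand axis, in-plane perpendicular and sheet normal from PCA of the Cα trace
    _, _, vt = np.linalg.svd(ca - centroid)
    axis, perp, normal = vt
    rot = 2.0 * np.outer(normal, normal) - np.eye(3)  # 2-fold dyad normal to the sheet
    b_base = (a.coords - centroid) @ rot.T + centroid
    o_a = a.coords[a.names == "O"]
    n_mask = a.names == "N"

    def score(b_coords):
        d = np.linalg.norm(o_a[:, None] - b_coords[n_mask][None], axis=-1)
        d2 = np.linalg.norm(b_coords[a.names == "O"][:, None]
                            - a.coords[n_mask][None], axis=-1)
        contacts = np.sum((d > 2.6) & (d < 3.2)) + np.sum((d2 > 2.6) & (d2 < 3.2))
        clash = np.linalg.norm(a.coords[:, None] - b_coords[None], axis=-1).min() < 2.0
        return -1 if clash else contacts

    best, best_b = -2, None
    for direction in (perp, normal):
        for sign in (1.0, -1.0):
            for shift_perp in np.arange(3.0, 6.5, 0.05):
                for shift_axis in np.arange(-7.0, 7.0, 0.05):
                    b = b_base + sign * shift_perp * direction + shift_axis * axis
                    sc = score(b)
                    if sc > best:
                        best, best_b = sc, b
    names = np.concatenate([a.names, a.names])
    elements = np.concatenate([a.elements, a.elements])
    res_ids = np.concatenate([a.res_ids, a.res_ids + n_residues])
    chains = np.array(["A"] * a.n_atoms + ["B"] * a.n_atoms)
    coords = np.vstack([a.coords, best_b])
    return StructureModel(names, elements, res_ids, ["ALA"] * len(names), chains, coords)


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for one synthetic ensemble; equal seeds give bit-identical output."""

    n_residues: int = 30
    n_frames: int = 100
    amplitude_profile: float | np.ndarray = 0.5
    region_scaling: dict = field(default_factory=dict)
    planted_hbonds: tuple = ()
    base_geometry: str = "helix"
    seed: int = 0
    exact_occupancy: bool = True

    def residue_sigmas(self) -> np.ndarray:
        sig = np.broadcast_to(np.asarray(self.amplitude_profile, float),
                              (self.n_residues,)).copy()
        if np.any(sig < 0):
            raise ValueError("amplitudes must be non-negative")
        for (start, end), factor in self.region_scaling.items():
            sig[start - 1:end] *= factor
        return sig


def _plant_hbond(coords, donor_idx, hydrogen_idx, acceptor_idx, on, rng):
    """Move the acceptor atom into / out of criterion-satisfying geometry."""
    d, h = coords[donor_idx], coords[hydrogen_idx]
    u = h - d
    dh = np.linalg.norm(u)
    u /= dh
    if not on:
        coords[acceptor_idx] = d + _HB_OFF_DISTANCE * u
        return
    # direction 15° off the D→H axis, in a deterministic perpendicular plane
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(u, ref)
    perp /= np.linalg.norm(perp)
    off = np.radians(180.0 - _HB_ON_ANGLE)
    w = np.cos(off) * u + np.sin(off) * perp
    # |HA| from the law of cosines so that |DA| is exactly the planted distance
    cos_t = np.cos(np.radians(_HB_ON_ANGLE))
    r_ha = dh * cos_t + np.sqrt(dh * dh * (cos_t * cos_t - 1.0) + _HB_ON_DISTANCE ** 2)
    coords[acceptor_idx] = h + r_ha * w


def generate_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Base structure + per-frame Gaussian displacements + planted hydrogen bonds.

    Planted pairs ``(donor_residue, acceptor_residue, occupancy %)`` use the
    donor's backbone N–H and the acceptor's backbone O; the O is restrained
    to D–A 2.9 Å at a 165° angle in exactly ``round(occupancy/100 ×
    n_frames)`` frames (per-frame Bernoulli draws with ``exact_occupancy=
    False``) and pushed to 4.5 Å otherwise.
    """
    base = build_toy_protein(spec.n_residues, spec.base_geometry)
    rng = np.random.default_rng(spec.seed)
    sigma_res = spec.residue_sigmas()
    sigma_atom = sigma_res[base.res_ids - 1]
    coords = (base.coords[None] + rng.standard_normal((spec.n_frames, base.n_atoms, 3))
              * sigma_atom[None, :, None])
    moved = set()
    plans = []
    for donor_res, acceptor_res, occ in spec.planted_hbonds:
        if not 0.0 <= occ <= 100.0:
            raise ValueError("occupancy must lie in [0, 100]")
        if donor_res == acceptor_res:
            raise ValueError("donor and acceptor residue must differ")
        d_idx = int(np.flatnonzero((base.res_ids == donor_res) & (base.names == "N"))[0])
        h_idx = int(np.flatnonzero((base.res_ids == donor_res) & (base.names == "H"))[0])
        a_idx = int(np.flatnonzero((base.res_ids == acceptor_res) & (base.names == "O"))[0])
        if a_idx in moved:
            raise ValueError(f"conflicting restraints: acceptor O of residue "
                             f"{acceptor_res} is planted twice")
        moved.add(a_idx)
        if spec.exact_occupancy:
            n_on = round(occ / 100.0 * spec.n_frames)
            on_frames = np.zeros(spec.n_frames, dtype=bool)
            on_frames[rng.permutation(spec.n_frames)[:n_on]] = True
        else:
            on_frames = rng.random(spec.n_frames) < occ / 100.0
        plans.append((d_idx, h_idx, a_idx, on_frames))
    for f in range(spec.n_frames):
        for d_idx, h_idx, a_idx, on_frames in plans:
            _plant_hbond(coords[f], d_idx, h_idx, a_idx, bool(on_frames[f]), rng)
    return Ensemble(base, coords, topology_key=f"synthetic-{spec.seed}")


def generate_mutant_pair(spec: EnsembleSpec, region: FlexibleRegion | tuple[int, int],
                         scale_factor: float) -> tuple[Ensemble, Ensemble]:
    """Wild-type ensemble plus an independent mutant with region amplitudes × scale.

    Expected regional ΔRMSF is ``100·(scale_factor − 1) %``. The mutant uses
    an independent noise stream (seed offset) so the two ensembles emulate
    separate simulations.
    """
    if not scale_factor > 0:
        raise ValueError("scale factor must be positive")
    if isinstance(region, FlexibleRegion):
        interval = (region.start_residue, region.end_residue)
    else:
        interval = tuple(region)
    if interval[0] < 1 or interval[1] > spec.n_residues:
        raise ValueError("region lies outside the protein")
    wildtype = generate_ensemble(spec)
    scaling = dict(spec.region_scaling)
    scaling[interval] = scaling.get(interval, 1.0) * scale_factor
    mutant_spec = replace(spec, region_scaling=scaling, seed=spec.seed + 2**20)
    return wildtype, generate_ensemble(mutant_spec)


_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_design_table_fixture(mode: str = "paper", seed: int = 0,
                              n_positions: int = 20) -> list[DesignRecord]:
    """Design-score records: the shipped published table, or a random analog.

    Random mode draws ΔΔG uniformly in [−8, 4] REU with random substitutions
    for funnel testing.
    """
    if mode == "paper":
        from .datasets import table2_designs
        return table2_designs()
    if mode != "random":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_positions):
        native = _AA[rng.integers(len(_AA))]
        designed = _AA[rng.integers(len(_AA))]
        has_design = designed != native and rng.random() > 0.2
        records.append(DesignRecord(
            region_id=1 + i // max(n_positions // 3, 1),
            residue_number=10 + i,
            native_aa=native,
            active_site_distance=float(rng.uniform(5.0, 60.0)),
            has_interaction_potential=bool(rng.random() > 0.1),
            designed_aa=designed if has_design else None,
            ddG=float(np.round(rng.uniform(-8.0, 4.0), 1)) if has_design else None,
        ))
    return records
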