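"""Superposition and flexibility metrics.

Rigid-body least-squares superposition (Kabsch), RMSD series against a
reference conformation, iterative alignment of an ensemble to its evolving
average structure, centroid-frame selection, and per-residue RMSF — the
flexibility measure the screening pipeline is built on.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError
from .io import Ensemble, StructureModel

__all__ = [
    "AtomSelection",
    "RmsfProfile",
    "RmsdSeries",
    "kabsch_superpose",
    "rmsd_series",
    "average_structure",
    "superpose_ensemble",
    "select_centroid",
    "compute_rmsf",
]

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class AtomSelection:
    """Which atoms enter a superposition or flexibility statistic.

    mode: ``calpha`` | ``backbone`` | ``heavy`` | ``all``;
    residue_filter: optional list of inclusive ``(start, end)`` residue intervals.
    """

    mode: str = "calpha"
    residue_filter: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if self.mode not in ("calpha", "backbone", "heavy", "all"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.residue_filter is not None:
            object.__setattr__(self, "residue_filter",
                               tuple((int(a), int(b)) for a, b in self.residue_filter))

    def indices(self, model: StructureModel) -> np.ndarray:
        if self.mode == "calpha":
            mask = model.names == "CA"
        elif self.mode == "backbone":
            mask = np.isin(model.names, _BACKBONE_NAMES)
        elif self.mode == "heavy":
            mask = model.elements != "H"
        else:
            mask = np.ones(model.n_atoms, dtype=bool)
        if self.residue_filter is not None:
            in_any = np.zeros(model.n_atoms, dtype=bool)
            for start, end in self.residue_filter:
                in_any |= (model.res_ids >= start) & (model.res_ids <= end)
            mask &= in_any
        return np.flatnonzero(mask)


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Å) for one ensemble under one atom selection."""

    residue_numbers: np.ndarray
    rmsf: np.ndarray
    selection: AtomSelection = field(default_factory=AtomSelection)
    source_label: str = ""

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.rmsf.shape != self.residue_numbers.shape:
            raise ValueError("rmsf and residue_numbers must have equal length")
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF values must be non-negative")

    def value_at(self, residue_number: int) -> float:
        idx = np.flatnonzero(self.residue_numbers == residue_number)
        if idx.size == 0:
            raise KeyError(f"residue {residue_number} not in profile")
        return float(self.rmsf[idx[0]])

    def region_values(self, start: int, end: int) -> np.ndarray:
        mask = (self.residue_numbers >= start) & (self.residue_numbers <= end)
        present = set(self.residue_numbers[mask].tolist())
        missing = [r for r in range(start, end + 1) if r not in present]
        if missing:
            raise KeyError(f"profile is missing residues {missing}")
        return self.rmsf[mask]

    def region_mean(self, start: int, end: int) -> float:
        return float(np.mean(self.region_values(start, end)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue_number": self.residue_numbers, "rmsf": self.rmsf})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, **kw) -> "RmsfProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(df["residue_number"].to_numpy(), df["rmsf"].to_numpy(), **kw)


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) against one reference conformation."""

    frame_index: np.ndarray
    rmsd: np.ndarray
    reference_label: str = ""

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        if np.any(self.rmsd < 0):
            raise ValueError("RMSD values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frame_index, "rmsd": self.rmsd})


# ---------------------------------------------------------------------------
# Kabsch superposition

def _check_superposable(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("superposition needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] < 1e-9 or s[1] / s[0] < 1e-8:
        raise DegenerateGeometryError("selected atoms are collinear or coincident")


def _fit_transform(mobile: np.ndarray, reference: np.ndarray):
    """Proper rotation + translation minimising RMSD of mobile onto reference."""
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal atom counts")
    _check_superposable(mobile)
    _check_superposable(reference)
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    return rot, mob_c, ref_c


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None):
    """Superpose ``mobile`` onto ``reference`` and return ``(transformed, rmsd)``.

    The transform (fit on ``selection`` indices when given, else on all
    atoms) is applied to every mobile atom; the returned RMSD is measured
    over the fitted atoms and is the least-squares minimum over all proper
    rotations and translations.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    rot, mob_c, ref_c = _fit_transform(mobile[sel], reference[sel])
    transformed = rot.apply(mobile - mob_c) + ref_c
    return transformed, _rmsd(transformed[sel], reference[sel])


def rmsd_series(ensemble: Ensemble, reference: StructureModel,
                selection: AtomSelection = AtomSelection("calpha"),
                superpose: bool = True) -> RmsdSeries:
    """RMSD of every frame against a reference conformation.

    Each frame is superposed onto the reference (on ``selection``) before
    the deviation is measured, so pure rigid-body motion contributes zero.
    """
    sel = selection.indices(ensemble.template)
    if sel.size < 3:
        raise DegenerateGeometryError("selection resolves to fewer than 3 atoms")
    ref = reference.coords[sel]
    out = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        frame = ensemble.coords[i][sel]
        if superpose:
            _, out[i] = kabsch_superpose(frame, ref)
        else:
            out[i] = _rmsd(frame, ref)
    return RmsdSeries(np.arange(ensemble.n_frames), out, reference_label=f"model{reference.model_id}")


def average_structure(ensemble: Ensemble) -> StructureModel:
    """Per-atom arithmetic mean over frames (frames must already be mutually superposed)."""
    return ensemble.template.with_coords(ensemble.coords.mean(axis=0), model_id=0)


def superpose_ensemble(ensemble: Ensemble,
                       selection: AtomSelection = AtomSelection("calpha"),
                       tol: float = 1e-4, max_iter: int = 10) -> Ensemble:
    """Iteratively align all frames to the evolving average structure.

    Every frame is Kabsch-aligned (on ``selection``) to the current average,
    the average is recomputed, and the cycle repeats until the average moves
    less than ``tol`` Å (RMS) or ``max_iter`` is reached. Deterministic; a
    warning is emitted on non-convergence and the last iterate is returned.
    """
    sel = selection.indices(ensemble.template)
    if sel.size < 3:
        raise DegenerateGeometryError("selection resolves to fewer than 3 atoms")
    coords = ensemble.coords.copy()
    reference = coords[0][sel]
    for _ in range(max_iter):
        for i in range(coords.shape[0]):
            rot, mob_c, ref_c = _fit_transform(coords[i][sel], reference)
            coords[i] = rot.apply(coords[i] - mob_c) + ref_c
        new_reference = coords[:, sel].mean(axis=0)
        shift = _rmsd(new_reference, reference)
        reference = new_reference
        if shift < tol:
            break
    else:
        warnings.warn(f"ensemble alignment did not converge within {max_iter} "
                      f"iterations (last average shift {shift:.2e} Å)", stacklevel=2)
    return Ensemble(ensemble.template, coords, ensemble.frame_times, ensemble.topology_key)


def select_centroid(ensemble: Ensemble,
                    window: tuple[int, int] | None = None,
                    selection: AtomSelection = AtomSelection("calpha")):
    """Pick the frame closest to the window's average structure.

    ``window`` is a half-open ``(start, stop)`` frame interval (default: all
    frames). Returns ``(frame_index, StructureModel)`` where the index is
    absolute. Ties break to the earliest frame.
    """
    start, stop = (0, ensemble.n_frames) if window is None else window
    if not (0 <= start < stop <= ensemble.n_frames):
        raise ValueError(f"empty or out-of-range window ({start}, {stop})")
    sel = selection.indices(ensemble.template)
    if sel.size < 3:
        raise DegenerateGeometryError("selection resolves to fewer than 3 atoms")
    window_coords = ensemble.coords[start:stop, sel]
    avg = window_coords.mean(axis=0)
    rmsds = np.array([kabsch_superpose(frame, avg)[1] for frame in window_coords])
    best = int(np.argmin(rmsds))  # argmin returns the first minimum: earliest frame
    return start + best, ensemble.frame(start + best)


def compute_rmsf(ensemble: Ensemble,
                 selection: AtomSelection = AtomSelection("calpha"),
                 superpose: bool = True,
                 source_label: str = "") -> RmsfProfile:
    """Per-residue RMSF over an ensemble.

    For residue *r*: ``RMSF = sqrt(mean over frames and selected atoms of the
    squared displacement from the atom's time-average position)``. Global
    rigid motion is removed first by iterative alignment to the average
    structure unless ``superpose=False`` (for pre-aligned frames).
    Residues with no atom in the selection are omitted with a warning.
    """
    if superpose:
        ensemble = superpose_ensemble(ensemble, selection)
    template = ensemble.template
    sel = selection.indices(template)
    mean_coords = ensemble.coords.mean(axis=0)
    sq_disp = np.sum((ensemble.coords - mean_coords) ** 2, axis=-1)  # (frames, atoms)
    residues, values, skipped = [], [], []
    for res in dict.fromkeys(template.res_ids.tolist()):  # preserves order
        idx = sel[template.res_ids[sel] == res]
        if idx.size == 0:
            skipped.append(res)
            continue
        residues.append(res)
        values.append(np.sqrt(np.mean(sq_disp[:, idx])))
    if skipped:
        warnings.warn(f"residues {skipped} have no atoms in selection "
                      f"{selection.mode!r} and were omitted", stacklevel=2)
    return RmsfProfile(np.array(residues), np.array(values), selection, source_label)
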