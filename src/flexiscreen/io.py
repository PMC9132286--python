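"""Structure and table I/O.

Conformational ensembles are exchanged as multi-model PDB files (one MODEL
per frame) and held in memory as array-backed :class:`Ensemble` objects.
Design scores, flexible-region summaries and ΔRMSF screens are exchanged as
TSV tables in which ``-`` marks an absent value.
"""
from __future__ import annotations

import io as _stdio
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

from .errors import PDBParseError, TableParseError, TopologyError

__all__ = [
    "Atom",
    "StructureModel",
    "Ensemble",
    "DesignRecord",
    "HBondTopology",
    "read_ensemble",
    "write_ensemble",
    "read_design_table",
    "read_region_table",
    "read_delta_rmsf_table",
    "build_hbond_topology",
]

#: Maximum covalent H-to-heavy-atom distance used to infer bonded hydrogens (Å).
HYDROGEN_BOND_LENGTH_MAX = 1.2


@dataclass(frozen=True)
class Atom:
    """One atom of one conformation (coordinates in Å)."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")
        object.__setattr__(self, "position", pos)


class StructureModel:
    """One conformation: parallel annotation arrays plus an (n_atoms, 3) coordinate array.

    Residue numbering is taken verbatim from the source (1-based); no
    renumbering is ever applied.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str],
        res_ids: Sequence[int],
        res_names: Sequence[str],
        chains: Sequence[str],
        coords: np.ndarray,
        model_id: int = 1,
        serials: Sequence[int] | None = None,
    ):
        self.names = np.asarray(names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.res_names = np.asarray(res_names, dtype="U4")
        self.chains = np.asarray(chains, dtype="U4")
        self.coords = np.asarray(coords, dtype=float)
        self.model_id = int(model_id)
        n = len(self.names)
        if n == 0:
            raise ValueError("a StructureModel needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError("coordinate array shape does not match atom count")
        if serials is None:
            serials = np.arange(1, n + 1)
        self.serials = np.asarray(serials, dtype=int)
        for chain in np.unique(self.chains):
            rid = self.res_ids[self.chains == chain]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue numbers decrease within chain {chain!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(int(self.serials[i]), str(self.names[i]), str(self.elements[i]),
                 int(self.res_ids[i]), str(self.res_names[i]), str(self.chains[i]),
                 self.coords[i])
            for i in range(self.n_atoms)
        ]

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], model_id: int = 1) -> "StructureModel":
        return cls(
            [a.name for a in atoms], [a.element for a in atoms],
            [a.residue_number for a in atoms], [a.residue_name for a in atoms],
            [a.chain for a in atoms], np.array([a.position for a in atoms]),
            model_id=model_id, serials=[a.serial for a in atoms],
        )

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        return StructureModel(self.names, self.elements, self.res_ids, self.res_names,
                              self.chains, coords,
                              self.model_id if model_id is None else model_id,
                              self.serials)

    def residue_atom_indices(self, residue_number: int) -> np.ndarray:
        idx = np.flatnonzero(self.res_ids == residue_number)
        if idx.size == 0:
            raise KeyError(f"residue {residue_number} not present")
        return idx


class Ensemble:
    """Ordered frames sharing one topology.

    All per-residue flexibility statistics and hydrogen-bond occupancies are
    computed over an Ensemble. Coordinates live in a single
    ``(n_frames, n_atoms, 3)`` array; annotations are shared across frames.
    """

    def __init__(
        self,
        template: StructureModel,
        coords: np.ndarray,
        frame_times: np.ndarray | None = None,
        topology_key: str = "",
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[0] < 1:
            raise ValueError("need a (n_frames, n_atoms, 3) coordinate array with >= 1 frame")
        if coords.shape[1:] != (template.n_atoms, 3):
            raise TopologyError(
                f"coordinate array for {coords.shape[1]} atoms does not match "
                f"template with {template.n_atoms} atoms")
        self.template = template
        self.coords = coords
        self.frame_times = None if frame_times is None else np.asarray(frame_times, float)
        if self.frame_times is not None and len(self.frame_times) != coords.shape[0]:
            raise ValueError("frame_times length does not match frame count")
        self.topology_key = topology_key or f"{template.n_atoms}atoms"

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> StructureModel:
        return self.template.with_coords(self.coords[i], model_id=i + 1)

    @property
    def frames(self) -> list[StructureModel]:
        return [self.frame(i) for i in range(self.n_frames)]

    def __iter__(self) -> Iterator[StructureModel]:
        return iter(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    @classmethod
    def from_models(cls, models: Sequence[StructureModel], **kw) -> "Ensemble":
        if not models:
            raise ValueError("an Ensemble needs at least one frame")
        first = models[0]
        key = list(zip(first.names, first.res_ids, first.chains))
        for m in models[1:]:
            if m.n_atoms != first.n_atoms or key != list(zip(m.names, m.res_ids, m.chains)):
                raise TopologyError(
                    f"model {m.model_id} does not share the topology of model "
                    f"{first.model_id}")
        return cls(first, np.stack([m.coords for m in models]), **kw)

    def slice_frames(self, start: int, stop: int) -> "Ensemble":
        times = None if self.frame_times is None else self.frame_times[start:stop]
        return Ensemble(self.template, self.coords[start:stop], times, self.topology_key)


@dataclass(frozen=True)
class DesignRecord:
    """One designed position: Rosetta ΔΔG (REU) plus the active-site distance rule inputs."""

    region_id: int
    residue_number: int
    native_aa: str
    active_site_distance: float
    has_interaction_potential: bool
    designed_aa: str | None = None
    ddG: float | None = None

    def __post_init__(self):
        if self.ddG is not None and self.designed_aa is None:
            raise ValueError(f"position {self.residue_number}: ΔΔG without a designed residue")
        if self.active_site_distance < 0:
            raise ValueError("active-site distance must be >= 0")


@dataclass
class HBondTopology:
    """Donor (heavy atom, bonded hydrogen) pairs and acceptor heavy atoms, as atom indices."""

    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# PDB ensembles

def _find_bad_pdb_line(path: Path) -> str:
    """Best-effort scan for the first unparseable ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return f"line {lineno}: {line.rstrip()}"
    return ""


def _element_from_name(name: str) -> str:
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def read_ensemble(path: str | Path, format: str = "pdb-multimodel") -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    A single-model file yields a 1-frame ensemble. Atom order is preserved
    from the file; chain-less records are assigned chain ``"A"``.
    """
    if format != "pdb-multimodel":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError/ValueError variants
        msg = str(exc)
        if "atoms" in msg or "model" in msg.lower():
            raise TopologyError(f"{path}: inconsistent models: {msg}") from exc
        bad = _find_bad_pdb_line(path)
        raise PDBParseError(f"{path}: {msg}" + (f" ({bad})" if bad else "")) from exc
    if isinstance(stack, struc.AtomArray):  # pragma: no cover - biotite always stacks here
        stack = struc.stack([stack])
    chains = np.where(stack.chain_id == "", "A", stack.chain_id)
    elements = np.array([
        e if e else _element_from_name(n)
        for e, n in zip(stack.element, stack.atom_name)
    ])
    template = StructureModel(stack.atom_name, elements, stack.res_id,
                              stack.res_name, chains, stack.coord[0])
    return Ensemble(template, np.array(stack.coord, dtype=float),
                    topology_key=path.stem)


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a standard multi-model PDB (one MODEL/ENDMDL per frame)."""
    t = ensemble.template
    stack = struc.AtomArrayStack(ensemble.n_frames, ensemble.n_atoms)
    stack.coord[:] = ensemble.coords
    stack.set_annotation("atom_name", t.names)
    stack.set_annotation("element", t.elements)
    stack.set_annotation("res_id", t.res_ids)
    stack.set_annotation("res_name", t.res_names)
    stack.set_annotation("chain_id", t.chains)
    stack.set_annotation("hetero", np.zeros(ensemble.n_atoms, dtype=bool))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Tabular fixtures

_ABSENT = "-"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import csv
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         skipinitialspace=True)
    except (pd.errors.EmptyDataError, csv.Error):
        if path.stat().st_size > 0 and path.read_text().strip():
            raise TableParseError(f"{path}: could not determine table format")
        return pd.DataFrame()
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    return df


def _opt_float(value, *, path, column) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text in (_ABSENT, "", "nan"):
        return None
    try:
        return float(text)
    except ValueError:
        raise TableParseError(f"{path}: non-numeric {column} value {text!r}") from None


def read_design_table(path: str | Path) -> list[DesignRecord]:
    """Read a per-position design-score table into :class:`DesignRecord` rows.

    Expected columns (order free, ``-`` = absent): region, residue_number,
    active_site_distance, native_aa, has_interaction_potential, designed_aa,
    ddG. A missing region column yields ``region_id = 0``.
    """
    df = _read_table(path)
    if df.empty:
        return []
    records = []
    for _, row in df.iterrows():
        designed = str(row.get("designed_aa", _ABSENT)).strip()
        designed = None if designed in (_ABSENT, "", "nan") else designed
        ddg = _opt_float(row.get("ddg"), path=path, column="ddG")
        if ddg is not None and designed is None:
            raise TableParseError(f"{path}: ΔΔG given without a designed residue "
                                  f"at position {row['residue_number']}")
        records.append(DesignRecord(
            region_id=int(row.get("region", 0) or 0),
            residue_number=int(row["residue_number"]),
            native_aa=str(row["native_aa"]).strip(),
            active_site_distance=float(row["active_site_distance"]),
            has_interaction_potential=str(row.get("has_interaction_potential", "Yes")
                                          ).strip().lower() in ("yes", "true", "1"),
            designed_aa=designed,
            ddG=ddg,
        ))
    return records


def read_region_table(path: str | Path) -> pd.DataFrame:
    """Read a flexible-region summary table (region, start/end residue, count, mean±sd RMSF)."""
    df = _read_table(path)
    for col in ("region", "start_residue", "end_residue", "n_residues"):
        df[col] = df[col].astype(int)
    for col in ("mean_rmsf", "sd_rmsf"):
        df[col] = df[col].astype(float)
    return df


def read_delta_rmsf_table(path: str | Path) -> pd.DataFrame:
    """Read a mutant ΔRMSF screen table; absent 313 K entries become NaN."""
    df = _read_table(path)
    df["region"] = df["region"].astype(int)
    for col in df.columns:
        if col.startswith(("mean_", "sem_")):
            df[col] = [
                v if v is not None else np.nan
                for v in (_opt_float(x, path=path, column=col) for x in df[col])
            ]
    return df


# ---------------------------------------------------------------------------
# Donor/acceptor topology

def build_hbond_topology(model: StructureModel) -> HBondTopology:
    """Infer hydrogen-bond donors and acceptors from one conformation.

    Every N or O with a hydrogen within 1.2 Å is a donor (one entry per
    bonded hydrogen); every N or O is an acceptor. Bonds are inferred by
    distance because MD-derived PDBs rarely carry CONECT records.
    """
    heavy_no = np.flatnonzero(np.isin(model.elements, ("N", "O")))
    hydrogens = np.flatnonzero(model.elements == "H")
    topo = HBondTopology(acceptors=[int(i) for i in heavy_no])
    if hydrogens.size == 0:
        warnings.warn("model has no hydrogens: donor list is empty and "
                      "hydrogen-bond criteria cannot be evaluated", stacklevel=2)
        return topo
    if heavy_no.size:
        tree = cKDTree(model.coords[heavy_no])
        dist, nearest = tree.query(model.coords[hydrogens],
                                   distance_upper_bound=HYDROGEN_BOND_LENGTH_MAX)
        for h, d, j in zip(hydrogens, dist, nearest):
            if np.isfinite(d):
                topo.donors.append((int(heavy_no[j]), int(h)))
    topo.donors.sort()
    return topo
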