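"""Structure and trajectory I/O.

Coordinates are stored in a lab frame in Angstrom with ``z`` along the
interface normal, pointing from the lipid monolayer into the aqueous
subphase.  File parsing and writing is delegated to :mod:`mdtraj`
(PDB/GRO topologies, XTC/DCD coordinate streams); this module wraps the
results in light-weight array containers and enforces the conventions
the spectral and selection layers rely on: Angstrom units, 1-based
residue numbering preserved from the input file, and per-frame
(trajectory id, time) bookkeeping.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import mdtraj as md
from mdtraj.core import element as _element

from .errors import ConfigurationError, FormatError, TopologyError

__all__ = [
    "StructureFrame",
    "TrajectoryEnsemble",
    "PROTEIN_RESIDUES",
    "LIPID_RESIDUES",
    "SOLVENT_RESIDUES",
    "read_structure",
    "read_trajectory",
    "split_components",
    "write_ensemble",
    "to_mdtraj",
    "frames_per_trajectory",
    "recenter_on_lipid_phosphorus",
]

#: Three-letter codes treated as protein residues by default.
PROTEIN_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residue names treated as membrane lipids by default ("DPP"/"POP"/"DOP"
#: cover the 3-character truncation classic PDB columns impose).
LIPID_RESIDUES = frozenset(
    {"DPPG", "DPPC", "POPG", "POPC", "DPPS", "DOPC", "DPP", "POP", "DOP"}
)

#: Residue names dropped as solvent/ions when splitting components.
SOLVENT_RESIDUES = frozenset(
    {"SOL", "HOH", "WAT", "TIP3", "TIP4", "SPC", "NA", "CL", "NA+", "CL-", "SOD", "CLA", "K", "POT"}
)


@dataclass
class StructureFrame:
    """One timestamped set of atomic coordinates with metadata.

    Attributes
    ----------
    xyz : (n_atoms, 3) float array, Angstrom, lab frame (z = interface normal).
    atom_names, elements, res_names : per-atom string arrays.
    res_ids : per-atom 1-based residue sequence indices (file numbering).
    chain_ids : per-atom chain identifiers.
    time_ps : frame time in picoseconds.
    traj_id : identifier of the trajectory the frame came from.
    box : optional (3, 3) box vectors in Angstrom.
    """

    xyz: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    time_ps: float = 0.0
    traj_id: str = ""
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        for name in ("atom_names", "elements", "res_names", "chain_ids"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        n = len(self.xyz)
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must have shape (n_atoms, 3)")
        for name in ("atom_names", "elements", "res_names", "res_ids", "chain_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match atom count")
        if n and not np.isfinite(self.xyz).all():
            raise ValueError("non-finite coordinates")
        if n and self.res_ids.min() < 1:
            raise ValueError("residue indices must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    def select(self, mask: np.ndarray) -> "StructureFrame":
        """Return the sub-frame of atoms where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            xyz=self.xyz[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            res_names=self.res_names[mask],
            res_ids=self.res_ids[mask],
            chain_ids=self.chain_ids[mask],
        )

    def transformed(self, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)) -> "StructureFrame":
        """Rigidly rotate (about the origin) and translate the frame."""
        xyz = self.xyz
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        xyz = xyz + np.asarray(translation, dtype=float)
        return replace(self, xyz=xyz)

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain_id, res_id) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.res_ids):
            seen.setdefault((c, int(r)), None)
        return list(seen)


@dataclass
class TrajectoryEnsemble:
    """Ordered collection of frames pooled across trajectories."""

    frames: list[StructureFrame] = field(default_factory=list)

    def __post_init__(self) -> None:
        times: dict[str, float] = {}
        for f in self.frames:
            prev = times.get(f.traj_id)
            if prev is not None and f.time_ps <= prev:
                raise ValueError(
                    f"times within trajectory {f.traj_id!r} must be strictly increasing"
                )
            times[f.traj_id] = f.time_ps

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> StructureFrame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def global_indices(self) -> np.ndarray:
        return np.arange(len(self.frames))

    def extend(self, other: "TrajectoryEnsemble") -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(self.frames + other.frames)


def _frames_from_mdtraj(traj: md.Trajectory, traj_id: str) -> list[StructureFrame]:
    top = traj.topology
    atom_names = np.array([a.name for a in top.atoms], dtype=object)
    elements = np.array(
        [a.element.symbol if a.element is not None else "" for a in top.atoms], dtype=object
    )
    res_names = np.array([a.residue.name for a in top.atoms], dtype=object)
    res_ids = np.array([a.residue.resSeq for a in top.atoms], dtype=int)
    chain_ids = np.array(
        [
            getattr(a.residue.chain, "chain_id", None) or chr(ord("A") + a.residue.chain.index % 26)
            for a in top.atoms
        ],
        dtype=object,
    )
    out = []
    times = traj.time if traj.time is not None else np.zeros(traj.n_frames)
    for k in range(traj.n_frames):
        box = None
        if traj.unitcell_vectors is not None:
            box = traj.unitcell_vectors[k] * 10.0
        out.append(
            StructureFrame(
                xyz=traj.xyz[k] * 10.0,  # nm -> Angstrom
                atom_names=atom_names,
                elements=elements,
                res_names=res_names,
                res_ids=res_ids,
                chain_ids=chain_ids,
                time_ps=float(times[k]),
                traj_id=traj_id,
                box=box,
            )
        )
    return out


def read_structure(path: str | os.PathLike, format: str | None = None, model: str = "error") -> StructureFrame:
    """Read a single-frame structure from a PDB or GRO file.

    Parameters
    ----------
    format : ``"pdb"`` or ``"gro"``; inferred from the extension when None.
    model : how to treat multi-MODEL files — ``"error"`` (default) or
        ``"first"`` to keep only the first model.
    """
    path = os.fspath(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ConfigurationError(f"unsupported structure format: {fmt!r}")
    if model not in ("error", "first"):
        raise ConfigurationError(f"model policy must be 'error' or 'first', got {model!r}")
    try:
        traj = md.load(path)
    except Exception as exc:  # mdtraj raises various parse errors
        raise FormatError(f"could not parse {fmt.upper()} file {path}: {exc}") from exc
    if traj.n_frames > 1:
        if model == "error":
            raise FormatError(
                f"{path} contains {traj.n_frames} models; pass model='first' to keep one"
            )
        traj = traj[0]
    return _frames_from_mdtraj(traj, traj_id=os.path.basename(path))[0]


def read_trajectory(
    topology: str | os.PathLike,
    coordinates: str | os.PathLike,
    stride: int = 1,
    traj_id: str | None = None,
) -> TrajectoryEnsemble:
    """Read a coordinate stream (XTC/DCD/multi-model PDB) against a topology.

    With ``n`` stored frames and stride ``s`` the result holds
    ``floor((n - 1)/s) + 1`` frames (frames 0, s, 2s, ...).
    """
    if stride < 1:
        raise ConfigurationError("stride must be a positive integer")
    topology = os.fspath(topology)
    coordinates = os.fspath(coordinates)
    try:
        traj = md.load(coordinates, top=topology, stride=stride)
    except ValueError as exc:
        raise TopologyError(f"topology/coordinate mismatch: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"could not read trajectory {coordinates}: {exc}") from exc
    tid = traj_id if traj_id is not None else os.path.splitext(os.path.basename(coordinates))[0]
    return TrajectoryEnsemble(_frames_from_mdtraj(traj, traj_id=tid))


def frames_per_trajectory(duration_ps: float, save_interval_ps: float) -> int:
    """Number of saved frames for one run, inclusive of t = 0."""
    if save_interval_ps <= 0:
        raise ConfigurationError("save interval must be positive")
    return int(math.floor(duration_ps / save_interval_ps)) + 1


def split_components(
    frame: StructureFrame,
    protein_residues: Iterable[str] = PROTEIN_RESIDUES,
    lipid_residues: Iterable[str] = LIPID_RESIDUES,
) -> tuple[StructureFrame, StructureFrame]:
    """Partition a frame into (protein, lipid) sub-frames, dropping solvent.

    The two residue-name sets must be disjoint.  Solvent and ions (and
    any residue in neither set) are discarded here, not at read time.
    """
    prot_set = frozenset(protein_residues)
    lip_set = frozenset(lipid_residues)
    if prot_set & lip_set:
        raise ConfigurationError("protein and lipid residue-name sets overlap")
    names = frame.res_names
    prot_mask = np.array([n in prot_set for n in names], dtype=bool)
    lip_mask = np.array([n in lip_set for n in names], dtype=bool)
    if not prot_mask.any():
        raise TopologyError("no protein atoms")
    return frame.select(prot_mask), frame.select(lip_mask)


def to_mdtraj(frames: StructureFrame | Sequence[StructureFrame]) -> md.Trajectory:
    """Convert one or more frames (shared atom ordering) to an mdtraj Trajectory."""
    if isinstance(frames, StructureFrame):
        frames = [frames]
    if not frames:
        raise ValueError("no frames")
    ref = frames[0]
    for f in frames[1:]:
        if f.n_atoms != ref.n_atoms or not np.array_equal(f.atom_names, ref.atom_names):
            raise TopologyError("frames do not share a common atom ordering")
    top = md.Topology()
    chain_map: dict[str, md.core.topology.Chain] = {}
    res_map: dict[tuple[str, int, str], md.core.topology.Residue] = {}
    for i in range(ref.n_atoms):
        cid = ref.chain_ids[i]
        if cid not in chain_map:
            chain_map[cid] = top.add_chain()
        rkey = (cid, int(ref.res_ids[i]), ref.res_names[i])
        if rkey not in res_map:
            res_map[rkey] = top.add_residue(ref.res_names[i], chain_map[cid], resSeq=int(ref.res_ids[i]))
        sym = ref.elements[i] or ref.atom_names[i][:1]
        try:
            el = _element.get_by_symbol(sym.capitalize())
        except KeyError:
            el = _element.virtual
        top.add_atom(ref.atom_names[i], el, res_map[rkey])
    xyz = np.stack([f.xyz for f in frames]) / 10.0  # Angstrom -> nm
    time = np.array([f.time_ps for f in frames])
    traj = md.Trajectory(xyz, top, time=time)
    if ref.box is not None:
        traj.unitcell_vectors = np.stack(
            [(f.box if f.box is not None else ref.box) / 10.0 for f in frames]
        )
    return traj


def write_ensemble(frames: Sequence[StructureFrame], path: str | os.PathLike) -> None:
    """Write frames with a shared atom ordering as a multi-model PDB."""
    if not frames:
        raise ValueError("no frames to write")
    counts = {f.n_atoms for f in frames}
    if len(counts) != 1:
        raise TopologyError(f"heterogeneous atom counts: {sorted(counts)}")
    to_mdtraj(list(frames)).save_pdb(os.fspath(path))


def recenter_on_lipid_phosphorus(
    frame: StructureFrame, lipid_residues: Iterable[str] = LIPID_RESIDUES
) -> StructureFrame:
    """Shift z so that the mean lipid phosphorus height defines z = 0.

    Implements the lab-frame convention that the monolayer phosphate
    plane is the coordinate origin along the interface normal.  Frames
    without lipid phosphorus atoms are returned unchanged.
    """
    lip_set = frozenset(lipid_residues)
    mask = np.array(
        [(rn in lip_set) and (el == "P" or an.startswith("P")) for rn, el, an in
         zip(frame.res_names, frame.elements, frame.atom_names)],
        dtype=bool,
    )
    if not mask.any():
        return frame
    z0 = float(frame.xyz[mask, 2].mean())
    return frame.transformed(translation=(0.0, 0.0, -z0))
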