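"""Synthetic structures, pseudo-membranes and noisy reference spectra.

These generators stand in for the two experimental inputs of the frame
selection workflow: MD-derived protein conformations above a lipid
monolayer, and replicate-averaged polarized VSFG spectra.  Proteins are
poly-alanine backbones built from ideal internal coordinates at chosen
(phi, psi) dihedrals; the membrane is a square grid of phosphorus-like
beads (residue name DPPG) — a purely geometric stand-in for distance
and orientation analysis, with no lipid chemistry.  Synthetic
"experiments" are weighted mixtures of calculated frame spectra with
i.i.d. Gaussian per-point noise over 2-50 replicates, matching the
replicate structure real datasets are averaged from.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.constants import Avogadro

from .errors import ConfigurationError
from .exciton_model import ExcitonParameters
from .frame_selection import ExperimentalDataset
from .geometry import principal_axis, rotation_z, tilt_twist_matrix
from .sfg_response import FrequencyGrid, FresnelWeights, calc_frame_spectra
from .structure_io import StructureFrame, TrajectoryEnsemble

__all__ = [
    "HelixSpec",
    "SyntheticExperiment",
    "LPRParams",
    "build_ideal_helix",
    "build_coil",
    "orient_structure",
    "make_lipid_slab",
    "combine_frames",
    "synth_experiment",
    "compute_lpr",
    "ScenarioLibrary",
    "flat_vs_upright_scenario",
    "scenario_experiment",
]

# ideal backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.5


@dataclass(frozen=True)
class HelixSpec:
    """Ideal helix fixture: n residues at (phi, psi), then oriented."""

    n_residues: int
    phi_deg: float = -57.0
    psi_deg: float = -47.0
    tilt_deg: float = 0.0
    twist_deg: float = 0.0
    translation: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ConfigurationError("need at least two residues")


@dataclass
class SyntheticExperiment:
    """A known-truth reference dataset generated from library frames."""

    frame_indices: list
    weights: np.ndarray
    sigma_noise: float
    n_replicates: int
    seed: int
    true_spectra: dict               # pc -> noiseless mixture intensity
    replicates: list                 # list of pc -> intensity dicts
    dataset: ExperimentalDataset


@dataclass(frozen=True)
class LPRParams:
    """Quantities fixing the interfacial lipid-to-protein molar ratio.

    concentration_M : protein concentration in the subphase (mol/L).
    volume_L : subphase volume (L).
    area_A2 : interfacial (trough) area (Angstrom^2).
    area_per_lipid_A2 : monolayer area per lipid (Angstrom^2/molecule);
        50 for a condensed phosphoglycerol monolayer at ~30 mN/m.
    """

    concentration_M: float
    volume_L: float
    area_A2: float
    area_per_lipid_A2: float = 50.0

    def __post_init__(self) -> None:
        for name in ("concentration_M", "volume_L", "area_A2", "area_per_lipid_A2"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d from atoms a-b-c."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(dihedral), np.sin(angle) * np.sin(dihedral)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi_deg: np.ndarray, psi_deg: np.ndarray) -> StructureFrame:
    """Poly-alanine N/CA/C/O/H backbone from per-residue dihedrals
    (omega fixed at 180; phi of residue 1 is unused)."""
    n = len(phi_deg)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    # a virtual predecessor fixes the (arbitrary) first phi rotation
    C = [_place_atom(np.array([0.0, -1.0, 0.0]), N[0], CA[0], _B_CA_C, _A_N_CA_C, phi_deg[0])]
    for i in range(1, n):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi_deg[i - 1]))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi_deg[i]))
    O = [
        _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi_deg[i] + 180.0) for i in range(n)
    ]
    xyz, names, elements, res_ids = [], [], [], []
    for i in range(n):
        for pos, nm, el in ((N[i], "N", "N"), (CA[i], "CA", "C"), (C[i], "C", "C"), (O[i], "O", "O")):
            xyz.append(pos)
            names.append(nm)
            elements.append(el)
            res_ids.append(i + 1)
        if i > 0:  # amide H trans to the preceding carbonyl oxygen
            d = C[i - 1] - O[i - 1]
            H = N[i] + _B_N_H * d / np.linalg.norm(d)
            xyz.append(H)
            names.append("H")
            elements.append("H")
            res_ids.append(i + 1)
    n_atoms = len(xyz)
    return StructureFrame(
        xyz=np.array(xyz),
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        res_names=np.array(["ALA"] * n_atoms, dtype=object),
        res_ids=np.array(res_ids),
        chain_ids=np.array(["A"] * n_atoms, dtype=object),
    )


def _canonical_orientation(frame: StructureFrame) -> StructureFrame:
    """Center on the CA centroid and align the CA principal axis
    (first residue -> last residue) with +z."""
    ca = frame.xyz[np.array([a == "CA" for a in frame.atom_names], dtype=bool)]
    axis = principal_axis(ca)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    centered = frame.transformed(translation=-ca.mean(axis=0))
    return centered.transformed(rotation=R)


def build_ideal_helix(spec: HelixSpec) -> StructureFrame:
    """Ideal poly-alanine helix, axis canonically along +z (N-terminus at
    the bottom), then tilted/twisted/translated per the spec."""
    n = spec.n_residues
    frame = _build_backbone(np.full(n, spec.phi_deg), np.full(n, spec.psi_deg))
    frame = _canonical_orientation(frame)
    frame = orient_structure(frame, spec.tilt_deg, spec.twist_deg, 0.0)
    return frame.transformed(translation=spec.translation)


def build_coil(n_residues: int, seed: int) -> StructureFrame:
    """Random-coil backbone: dihedrals drawn uniformly from a broad
    coil region (phi in [-180, -50]; psi in [60, 180] or [-180, -150],
    i.e. the PPII/extended basin), reproducible from the seed."""
    if n_residues < 2:
        raise ConfigurationError("need at least two residues")
    rng = np.random.default_rng(seed)
    phi = rng.uniform(-180.0, -50.0, size=n_residues)
    psi = np.where(
        rng.random(n_residues) < 0.75,
        rng.uniform(60.0, 180.0, size=n_residues),
        rng.uniform(-180.0, -150.0, size=n_residues),
    )
    frame = _build_backbone(phi, psi)
    return frame.transformed(translation=-frame.xyz.mean(axis=0))


def orient_structure(
    frame: StructureFrame, tilt_deg: float, twist_deg: float, z_offset: float = 0.0
) -> StructureFrame:
    """Rigidly reorient a structure about its centroid: twist about the
    molecular z axis, tilt about a horizontal axis, then shift along z.
    Internal geometry (all pairwise distances) is preserved."""
    centroid = frame.xyz.mean(axis=0)
    R = tilt_twist_matrix(tilt_deg, twist_deg)
    out = frame.transformed(translation=-centroid)
    out = out.transformed(rotation=R)
    return out.transformed(translation=centroid + np.array([0.0, 0.0, z_offset]))


def make_lipid_slab(nx: int, ny: int, spacing: float = 8.0, z0: float = 0.0) -> StructureFrame:
    """Square grid of pseudo-lipid phosphorus beads at height z0
    (residue name DPPG, one bead per residue, chain L)."""
    if nx < 1 or ny < 1:
        raise ConfigurationError("grid counts must be >= 1")
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    pts = np.array([[x, y, z0] for x in xs for y in ys])
    n = len(pts)
    return StructureFrame(
        xyz=pts,
        atom_names=np.array(["P"] * n, dtype=object),
        elements=np.array(["P"] * n, dtype=object),
        res_names=np.array(["DPPG"] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        chain_ids=np.array(["L"] * n, dtype=object),
    )


def combine_frames(*parts: StructureFrame, time_ps: float = 0.0, traj_id: str = "") -> StructureFrame:
    """Concatenate frames (e.g. protein + slab) into one frame."""
    return StructureFrame(
        xyz=np.concatenate([p.xyz for p in parts]),
        atom_names=np.concatenate([p.atom_names for p in parts]),
        elements=np.concatenate([p.elements for p in parts]),
        res_names=np.concatenate([p.res_names for p in parts]),
        res_ids=np.concatenate([p.res_ids for p in parts]),
        chain_ids=np.concatenate([p.chain_ids for p in parts]),
        time_ps=time_ps,
        traj_id=traj_id,
    )


def synth_experiment(
    library: TrajectoryEnsemble,
    frame_indices: Sequence[int],
    weights: Sequence[float],
    sigma_noise: float,
    n_replicates: int,
    seed: int,
    params: ExcitonParameters,
    grid: FrequencyGrid | None = None,
    fresnel: FresnelWeights | None = None,
    label: str = "synthetic",
    spectra: Sequence | None = None,
) -> SyntheticExperiment:
    """Noisy replicate dataset from a known mixture of library frames.

    The noiseless truth is the weight-averaged calculated intensity of
    the generating frames; each replicate adds i.i.d. Gaussian per-point
    noise of standard deviation ``sigma_noise`` (homoscedastic per PC).
    """
    if sigma_noise < 0:
        raise ConfigurationError("noise sigma must be non-negative")
    if n_replicates < 2:
        raise ConfigurationError("need at least two replicates")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(frame_indices) or (w < 0).any():
        raise ConfigurationError("weights must be non-negative, one per generating frame")
    if not np.isclose(w.sum(), 1.0):
        raise ConfigurationError("weights must sum to 1")
    grid = grid or FrequencyGrid.default()
    if spectra is None:
        gen = [
            calc_frame_spectra(library[i], params, grid, weights=fresnel) for i in frame_indices
        ]
    else:
        gen = [spectra[i] for i in frame_indices]
    pcs = list(gen[0].intensities)
    true = {
        pc: np.sum([wi * g.intensities[pc] for wi, g in zip(w, gen)], axis=0) for pc in pcs
    }
    rng = np.random.default_rng(seed)
    reps = [
        {pc: true[pc] + rng.normal(0.0, sigma_noise, size=len(grid)) for pc in pcs}
        for _ in range(n_replicates)
    ]
    dataset = ExperimentalDataset.from_replicates(grid, reps, label=label)
    return SyntheticExperiment(
        frame_indices=list(frame_indices),
        weights=w,
        sigma_noise=sigma_noise,
        n_replicates=n_replicates,
        seed=seed,
        true_spectra=true,
        replicates=reps,
        dataset=dataset,
    )


def compute_lpr(p: LPRParams) -> float:
    """Lipid-to-protein molar ratio: interfacial lipid moles over
    dissolved protein moles, LPR = (A / a_L) / (N_A * c * V)."""
    lipid_moles = (p.area_A2 / p.area_per_lipid_A2) / Avogadro
    protein_moles = p.concentration_M * p.volume_L
    if protein_moles <= 0:
        raise ConfigurationError("zero protein amount")
    return lipid_moles / protein_moles


@dataclass
class ScenarioLibrary:
    """Flat-vs-upright benchmark library above a pseudo-lipid slab."""

    ensemble: TrajectoryEnsemble
    labels: np.ndarray               # per-frame class: flat | upright | coil
    slab: StructureFrame
    n_residues: int
    seed: int
    manifest: dict = field(default_factory=dict)

    def indices_of(self, label: str) -> np.ndarray:
        return np.where(self.labels == label)[0]


def scenario_experiment(
    scenario: "ScenarioLibrary",
    label: str,
    params: ExcitonParameters,
    seed: int,
    spectra: Sequence | None = None,
    n_generators: int = 15,
    noise_frac: float = 0.01,
    n_replicates: int = 30,
    grid: FrequencyGrid | None = None,
) -> SyntheticExperiment:
    """Synthetic reference dataset generated from one scenario class.

    A uniform mixture of ``n_generators`` randomly chosen frames of the
    class defines the truth; replicate noise defaults to 1% of the SSP
    peak of that mixture spectrum (the signal the dataset actually
    contains), emulating high signal-to-noise replicate-averaged VSFG
    data.
    """
    idx = scenario.indices_of(label)
    if len(idx) == 0:
        raise ConfigurationError(f"scenario has no frames of class {label!r}")
    rng = np.random.default_rng(seed)
    gen = rng.choice(idx, size=min(n_generators, len(idx)), replace=False)
    gen = [int(i) for i in gen]
    w = np.full(len(gen), 1.0 / len(gen))
    grid = grid or FrequencyGrid.default()
    if spectra is not None:
        gen_specs = [spectra[i] for i in gen]
    else:
        gen_specs = [calc_frame_spectra(scenario.ensemble[i], params, grid) for i in gen]
    mixture_ssp = np.sum([wi * g.intensities["ssp"] for wi, g in zip(w, gen_specs)], axis=0)
    sigma = noise_frac * max(float(mixture_ssp.max()), 1e-12)
    return synth_experiment(
        scenario.ensemble, gen, w, sigma, n_replicates,
        int(rng.integers(2**31)), params, grid=grid, label=label, spectra=spectra,
    )


def _place_above(frame: StructureFrame, slab_z: float, clearance: float) -> StructureFrame:
    dz = (slab_z + clearance) - frame.xyz[:, 2].min()
    return frame.transformed(translation=(0.0, 0.0, dz))


def flat_vs_upright_scenario(
    n_frames: int = 200,
    n_residues: int = 30,
    seed: int = 7,
    slab_nx: int = 12,
    slab_ny: int = 12,
    slab_spacing: float = 8.0,
) -> ScenarioLibrary:
    """Benchmark library: flat-lying helices (tilt ~ 90 deg), upright
    helices (tilt 0-20 deg, N-terminus anchored at the slab) and random
    coils above one pseudo-lipid slab.

    Per-frame variation: uniform tilt jitter inside each class band,
    uniform twist, Gaussian dihedral jitter (sigma 3 deg) and 4-6 A
    clearance above the slab — a rough emulation of the conformational
    spread of MD snapshots within one orientation class.
    """
    if n_frames < 3:
        raise ConfigurationError("scenario needs at least three frames")
    rng = np.random.default_rng(seed)
    slab = make_lipid_slab(slab_nx, slab_ny, spacing=slab_spacing, z0=0.0)
    n_flat = n_upright = round(0.35 * n_frames)
    n_coil = n_frames - n_flat - n_upright
    labels = ["flat"] * n_flat + ["upright"] * n_upright + ["coil"] * n_coil
    frames = []
    for k, label in enumerate(labels):
        if label == "coil":
            prot = build_coil(n_residues, seed=int(rng.integers(2**31)))
            prot = orient_structure(prot, rng.uniform(0, 180), rng.uniform(0, 360))
        else:
            phi = -57.0 + rng.normal(0.0, 3.0, size=n_residues)
            psi = -47.0 + rng.normal(0.0, 3.0, size=n_residues)
            prot = _canonical_orientation(_build_backbone(phi, psi))
            tilt = rng.uniform(80, 100) if label == "flat" else rng.uniform(0, 20)
            prot = orient_structure(prot, tilt, rng.uniform(0, 360))
        prot = _place_above(prot, slab_z=0.0, clearance=rng.uniform(4.0, 6.0))
        frames.append(combine_frames(prot, slab, time_ps=50.0 * k, traj_id="synthetic"))
    manifest = {
        "scenario": "flat-vs-upright",
        "n_frames": n_frames,
        "n_residues": n_residues,
        "seed": seed,
        "classes": {"flat": n_flat, "upright": n_upright, "coil": n_coil},
        "slab": {"nx": slab_nx, "ny": slab_ny, "spacing_A": slab_spacing},
        "tilt_bands_deg": {"flat": [80, 100], "upright": [0, 20]},
        "dihedral_jitter_deg": 3.0,
        "clearance_A": [4.0, 6.0],
    }
    return ScenarioLibrary(
        ensemble=TrajectoryEnsemble(frames),
        labels=np.array(labels, dtype=object),
        slab=slab,
        n_residues=n_residues,
        seed=seed,
        manifest=manifest,
    )
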