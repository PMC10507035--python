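"""Amide-I one-exciton Hamiltonian.

Each peptide bond contributes one local amide-I oscillator with a
transition dipole in the O=C-N plane, an anchor point displaced along
the C=O bond, and an axially symmetric local Raman tensor.  Local modes
couple through-space by point transition-dipole coupling (TDC) and
through-bond by a constant nearest-neighbour term; diagonalizing the
resulting symmetric matrix yields delocalized eigenmodes whose
collective transition dipoles and Raman tensors drive the second-order
response.

Default parameters follow the common amide-I parameterizations: a
uniform local frequency of 1650 cm^-1 (amide-I' in a D2O subphase), a
dipole tilted 20 degrees from the C=O bond toward the nitrogen and
anchored 0.868 Angstrom from the carbonyl carbon, a TDC prefactor
giving non-neighbour couplings of a few cm^-1 at typical backbone
separations, and a nearest-neighbour coupling of -8.5 cm^-1.  All of
them are configuration-exposed; per-unit frequency shifts can be
supplied externally (e.g. from an electrostatic map computed elsewhere).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError, TopologyError
from .structure_io import StructureFrame

__all__ = [
    "ExcitonParameters",
    "AmideUnitSet",
    "ExcitonHamiltonian",
    "EigenmodeSet",
    "extract_amide_units",
    "tdc_coupling",
    "build_hamiltonian",
    "diagonalize",
]

#: Maximum C-N distance (Angstrom) regarded as an intact peptide bond.
CHAIN_BREAK_CUTOFF = 2.5


@dataclass
class ExcitonParameters:
    """Physical parameters of the amide-I exciton model.

    omega0 : base local-mode frequency (cm^-1).
    coupling_prefactor : TDC prefactor A (cm^-1 Angstrom^3) for unit dipoles.
    dipole_tilt_deg : angle of the transition dipole from the C=O bond
        toward N, in the O=C-N plane (degrees).
    anchor_offset : dipole anchor displacement from the carbonyl carbon
        along C=O (Angstrom).
    nn_coupling : constant nearest-neighbour (|i-j| = 1, same chain)
        coupling (cm^-1).  A (phi, psi)-map hook can replace it via
        ``nn_coupling_func``.
    linewidth_fwhm : homogeneous Lorentzian linewidth Gamma (cm^-1,
        FWHM of the single-mode |chi|^2 peak).
    raman_ratio : transverse/longitudinal principal value rho of the
        axially symmetric local Raman tensor (1, rho, rho).
    dipole_magnitude, raman_magnitude : overall scale factors.
    frequency_shifts : optional per-unit shifts added to omega0 (cm^-1).
    """

    omega0: float = 1650.0
    coupling_prefactor: float = 580.0
    dipole_tilt_deg: float = 20.0
    anchor_offset: float = 0.868
    nn_coupling: float = -8.5
    nn_coupling_func: object = None  # optional callable(unit_i, unit_j) -> cm^-1
    linewidth_fwhm: float = 12.0
    raman_ratio: float = 0.25
    dipole_magnitude: float = 1.0
    raman_magnitude: float = 1.0
    frequency_shifts: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.linewidth_fwhm <= 0:
            raise ConfigurationError("linewidth FWHM must be positive")
        if not np.isfinite(self.coupling_prefactor):
            raise ConfigurationError("TDC prefactor must be finite")
        if not (0.0 <= self.dipole_tilt_deg < 90.0):
            raise ConfigurationError("dipole tilt must lie in [0, 90) degrees")


@dataclass
class AmideUnitSet:
    """Per-peptide-bond chromophores of one protein frame.

    Arrays are indexed by unit; ``chain_labels``/``donor_res_ids``
    identify the donating residue, ``is_proline`` flags X-Pro bonds
    (kept with identical parameters, flagged for inspection).
    """

    anchors: np.ndarray            # (n, 3) Angstrom
    dipoles: np.ndarray            # (n, 3) unit directions
    raman: np.ndarray              # (n, 3, 3) lab-frame local Raman tensors
    frequencies: np.ndarray        # (n,) cm^-1
    donor_res_ids: np.ndarray      # (n,) int
    chain_labels: np.ndarray       # (n,) object
    is_proline: np.ndarray         # (n,) bool

    def __post_init__(self) -> None:
        n = len(self.anchors)
        norms = np.linalg.norm(self.dipoles, axis=1)
        if n and not np.allclose(norms, 1.0, atol=1e-10):
            raise ValueError("dipole directions must be unit vectors")
        if n and not np.allclose(self.raman, np.swapaxes(self.raman, 1, 2), atol=1e-12):
            raise ValueError("local Raman tensors must be symmetric")

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class ExcitonHamiltonian:
    """Symmetric exciton matrix (cm^-1) plus the units it was built from."""

    matrix: np.ndarray
    units: AmideUnitSet

    def __post_init__(self) -> None:
        H = np.asarray(self.matrix, dtype=float)
        if H.ndim != 2 or H.shape[0] != H.shape[1]:
            raise ValueError("Hamiltonian must be square")
        if not np.allclose(H, H.T, atol=1e-10):
            raise ValueError("Hamiltonian must be symmetric")
        self.matrix = H


@dataclass
class EigenmodeSet:
    """Delocalized amide-I eigenmodes of one frame."""

    frequencies: np.ndarray        # (n,) cm^-1, ascending
    dipoles: np.ndarray            # (n, 3) collective transition dipoles M_q
    raman: np.ndarray              # (n, 3, 3) collective Raman tensors A_q
    eigenvectors: np.ndarray       # (n, n), column q = mode q
    linewidth_fwhm: float = 12.0

    def __len__(self) -> int:
        return len(self.frequencies)


def _backbone_index(frame: StructureFrame) -> dict[tuple[str, int], dict[str, int]]:
    """Map (chain, res_id) -> {atom_name: atom_index} for backbone atoms."""
    idx: dict[tuple[str, int], dict[str, int]] = {}
    for i, (c, r, a) in enumerate(zip(frame.chain_ids, frame.res_ids, frame.atom_names)):
        if a in ("N", "CA", "C", "O", "H", "HN"):
            idx.setdefault((c, int(r)), {})[a] = i
    return idx


def extract_amide_units(protein: StructureFrame, params: ExcitonParameters) -> AmideUnitSet:
    """Locate every peptide bond and build its amide-I chromophore.

    A chain of n residues yields n-1 units; bonds across chain breaks
    (C-N distance above 2.5 Angstrom) are skipped.  Residues without
    backbone N/CA/C/O atoms (e.g. pseudo-lipid beads) are ignored.
    """
    bb = _backbone_index(protein)
    # group consecutive residues per chain in file order
    chains: dict[str, list[int]] = {}
    for (c, r) in protein.residue_keys():
        if (c, r) in bb:
            chains.setdefault(c, []).append(r)

    theta = np.deg2rad(params.dipole_tilt_deg)
    anchors, dipoles, ramans, donors, labels, prolines = [], [], [], [], [], []
    resname_of = {
        (c, int(r)): n for c, r, n in zip(protein.chain_ids, protein.res_ids, protein.res_names)
    }
    any_backbone = False
    for c, res_list in chains.items():
        for r1, r2 in zip(res_list[:-1], res_list[1:]):
            a1, a2 = bb[(c, r1)], bb[(c, r2)]
            if not all(k in a1 for k in ("C", "O")) or "N" not in a2:
                raise TopologyError(f"missing backbone atom at residue {r1}/{r2} chain {c}")
            any_backbone = True
            C = protein.xyz[a1["C"]]
            O = protein.xyz[a1["O"]]
            N = protein.xyz[a2["N"]]
            if np.linalg.norm(N - C) > CHAIN_BREAK_CUTOFF or r2 != r1 + 1:
                continue  # chain break: no chromophore across it
            u = O - C
            u /= np.linalg.norm(u)
            v = N - C
            v = v - (v @ u) * u
            nv = np.linalg.norm(v)
            if nv < 1e-9:
                raise GeometryError(f"degenerate O=C-N plane at residue {r1} chain {c}")
            v /= nv
            e = np.cos(theta) * u + np.sin(theta) * v
            anchors.append(C + params.anchor_offset * u)
            dipoles.append(e)
            rho = params.raman_ratio
            ramans.append(
                params.raman_magnitude * (rho * np.eye(3) + (1.0 - rho) * np.outer(e, e))
            )
            donors.append(r1)
            labels.append(c)
            prolines.append(resname_of.get((c, r2)) == "PRO")
    if not any_backbone:
        raise TopologyError("no protein backbone found in frame")
    n = len(anchors)
    freqs = np.full(n, params.omega0)
    if params.frequency_shifts is not None:
        shifts = np.asarray(params.frequency_shifts, dtype=float)
        if len(shifts) != n:
            raise ConfigurationError(
                f"{len(shifts)} frequency shifts supplied for {n} amide units"
            )
        freqs = freqs + shifts
    return AmideUnitSet(
        anchors=np.array(anchors).reshape(n, 3),
        dipoles=np.array(dipoles).reshape(n, 3),
        raman=np.array(ramans).reshape(n, 3, 3),
        frequencies=freqs,
        donor_res_ids=np.array(donors, dtype=int),
        chain_labels=np.array(labels, dtype=object),
        is_proline=np.array(prolines, dtype=bool),
    )


def tdc_coupling(
    anchor_i: np.ndarray,
    dipole_i: np.ndarray,
    anchor_j: np.ndarray,
    dipole_j: np.ndarray,
    params: ExcitonParameters,
) -> float:
    """Point transition-dipole coupling between two amide units (cm^-1).

    J = A [e_i.e_j - 3 (e_i.n)(e_j.n)] / r^3 with n the unit separation
    vector; symmetric under i <-> j.
    """
    rvec = np.asarray(anchor_j, dtype=float) - np.asarray(anchor_i, dtype=float)
    r = float(np.linalg.norm(rvec))
    if r < 0.5:
        raise GeometryError(f"chromophores {r:.3f} Angstrom apart (clash)")
    n = rvec / r
    kappa = float(dipole_i @ dipole_j) - 3.0 * float(dipole_i @ n) * float(dipole_j @ n)
    return params.coupling_prefactor * kappa / r**3


def build_hamiltonian(units: AmideUnitSet, params: ExcitonParameters) -> ExcitonHamiltonian:
    """Assemble the one-exciton matrix: local frequencies on the diagonal,
    a nearest-neighbour rule for adjacent units of one chain, TDC elsewhere."""
    n = len(units)
    if n < 1:
        raise ValueError("need at least one amide unit")
    H = np.zeros((n, n))
    H[np.diag_indices(n)] = units.frequencies
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = units.chain_labels[i] == units.chain_labels[j]
            adjacent = same_chain and abs(int(units.donor_res_ids[i]) - int(units.donor_res_ids[j])) == 1
            if adjacent:
                if params.nn_coupling_func is not None:
                    J = float(params.nn_coupling_func(i, j, units))
                else:
                    J = params.nn_coupling
            else:
                J = tdc_coupling(
                    units.anchors[i], units.dipoles[i], units.anchors[j], units.dipoles[j], params
                )
            H[i, j] = H[j, i] = J
    return ExcitonHamiltonian(matrix=H, units=units)


def diagonalize(hamiltonian: ExcitonHamiltonian, params: ExcitonParameters | None = None) -> EigenmodeSet:
    """Eigenmodes with collective transition dipoles and Raman tensors.

    M_q = sum_i c_qi mu_i and A_q = sum_i c_qi alpha_i, where c is the
    orthonormal eigenvector matrix (columns = modes, ascending
    frequency).  The orthogonal transform preserves trace and the
    dipole-strength sum rule, which downstream tests assert.
    """
    H = hamiltonian.matrix
    w, c = np.linalg.eigh(H)
    units = hamiltonian.units
    mag = params.dipole_magnitude if params is not None else 1.0
    mu = mag * units.dipoles
    M = c.T @ mu                                # (n_modes, 3)
    A = np.einsum("iq,iab->qab", c, units.raman)  # (n_modes, 3, 3)
    gamma = params.linewidth_fwhm if params is not None else 12.0
    return EigenmodeSet(frequencies=w, dipoles=M, raman=A, eigenvectors=c, linewidth_fwhm=gamma)
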