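"""Structural characterization of selected frame ensembles.

Secondary structure uses the simplified three-state DSSP scheme:
backbone hydrogen bonds are assigned with the Kabsch-Sander
electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond existing when E < -0.5 kcal/mol; n-turn patterns yield helix
states (alpha/3-10/pi collapsed to 'H'), bridge patterns yield strand
('E'), everything else is coil ('C').  Amide hydrogens missing from the
input are placed geometrically on the nitrogen, 1.01 Angstrom along the
preceding C=O direction (in the amide plane, trans to the carbonyl
oxygen).

Lipid proximity is the per-residue minimum distance over all residue
atoms to any lipid atom, averaged over ensemble members with the
standard error of the mean (member std / sqrt(N)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, TopologyError
from .structure_io import StructureFrame

__all__ = [
    "HBOND_ENERGY_CUTOFF",
    "ResidueProfile",
    "dssp_assign",
    "helicity_profile",
    "min_distance_profile",
    "segment_summary",
    "DEFAULT_SEGMENTS",
]

#: Kabsch-Sander hydrogen-bond threshold (kcal/mol).
HBOND_ENERGY_CUTOFF = -0.5
_KS_PREFACTOR = 0.084 * 332.0
_NH_BOND_LENGTH = 1.01

#: Default alpha-synuclein segments: lipid-anchoring N-terminus, the
#: amyloidogenic NAC core, and the acidic C-terminus.
DEFAULT_SEGMENTS = {"N-term": (1, 60), "NAC": (61, 95), "C-term": (96, 140)}


@dataclass
class ResidueProfile:
    """Per-residue ensemble statistics (helicity and/or lipid distance)."""

    res_ids: np.ndarray
    n_frames: int
    helicity: np.ndarray | None = None
    helicity_sem: np.ndarray | None = None
    min_dist: np.ndarray | None = None
    min_dist_sem: np.ndarray | None = None

    def to_table(self, path) -> None:
        cols = {"residue": self.res_ids}
        if self.helicity is not None:
            cols["helicity"] = self.helicity
            cols["helicity_sem"] = self.helicity_sem
        if self.min_dist is not None:
            cols["min_dist_A"] = self.min_dist
            cols["min_dist_sem"] = self.min_dist_sem
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _chain_residues(frame: StructureFrame):
    """Per chain: ordered residues with backbone atom indices and names."""
    atoms: dict[tuple[str, int], dict[str, int]] = {}
    rnames: dict[tuple[str, int], str] = {}
    for i, (c, r, a, rn) in enumerate(
        zip(frame.chain_ids, frame.res_ids, frame.atom_names, frame.res_names)
    ):
        atoms.setdefault((c, int(r)), {})[a] = i
        rnames[(c, int(r))] = rn
    chains: dict[str, list] = {}
    for (c, r) in frame.residue_keys():
        chains.setdefault(c, []).append((r, atoms[(c, r)], rnames[(c, r)]))
    return chains


def dssp_assign(frame: StructureFrame) -> dict:
    """Simplified DSSP codes {'H','E','C'} keyed by (chain_id, res_id).

    Residues lacking backbone N/CA/C/O are assigned 'C'.
    """
    chains = _chain_residues(frame)
    # flat residue list with per-residue geometry
    residues = []  # (chain, res_id, N, CA, C, O, H or None, is_pro)
    for c, res_list in chains.items():
        prev = None
        for r, amap, rname in res_list:
            if not all(k in amap for k in ("N", "CA", "C", "O")):
                residues.append((c, r, None, None, None, None, None, False))
                prev = None
                continue
            N = frame.xyz[amap["N"]]
            CA = frame.xyz[amap["CA"]]
            C = frame.xyz[amap["C"]]
            O = frame.xyz[amap["O"]]
            H = None
            for hname in ("H", "HN"):
                if hname in amap:
                    H = frame.xyz[amap[hname]]
                    break
            if H is None and prev is not None and r == prev[0] + 1:
                # geometric placement along the preceding C=O direction
                d = prev[1] - prev[2]  # C_prev - O_prev
                H = N + _NH_BOND_LENGTH * d / np.linalg.norm(d)
            if rname == "PRO":
                H = None  # proline nitrogen cannot donate
            residues.append((c, r, N, CA, C, O, H, rname == "PRO"))
            prev = (r, C, O)

    n = len(residues)
    ok = [res[2] is not None for res in residues]

    def hbond(j: int, i: int) -> bool:
        """CO of residue j accepts the NH of residue i."""
        if not (ok[i] and ok[j]):
            return False
        ci, cj = residues[i][0], residues[j][0]
        ri, rj = residues[i][1], residues[j][1]
        if ci == cj and abs(ri - rj) < 2:
            return False  # self and the amide's own neighbours
        H = residues[i][6]
        if H is None:
            return False
        N = residues[i][2]
        C, O = residues[j][4], residues[j][5]
        r_on = np.linalg.norm(O - N)
        r_ch = np.linalg.norm(C - H)
        r_oh = np.linalg.norm(O - H)
        r_cn = np.linalg.norm(C - N)
        if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
            return True  # overlapping atoms: formally E -> -inf
        E = _KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        return E < HBOND_ENERGY_CUTOFF

    # precompute all bonds between residues within 9 A CA distance
    cas = np.array([res[3] if ok[k] else [1e6, 1e6, 1e6] for k, res in enumerate(residues)])
    tree = cKDTree(cas)
    neighbor_pairs = tree.query_pairs(9.0)
    bonds = set()
    for a, b in neighbor_pairs:
        if hbond(a, b):
            bonds.add((a, b))
        if hbond(b, a):
            bonds.add((b, a))

    def consecutive(i: int, j: int) -> bool:
        """Positions i..j belong to one chain without numbering gaps."""
        if i < 0 or j >= n:
            return False
        c0, r0 = residues[i][0], residues[i][1]
        for k in range(i, j + 1):
            if residues[k][0] != c0 or residues[k][1] != r0 + (k - i):
                return False
        return True

    def turn(i: int, length: int) -> bool:
        j = i + length
        return consecutive(i, j) and (i, j) in bonds

    helix4 = np.zeros(n, dtype=bool)
    helix3 = np.zeros(n, dtype=bool)
    helix5 = np.zeros(n, dtype=bool)
    for length, flags in ((4, helix4), (3, helix3), (5, helix5)):
        for i in range(1, n):
            if turn(i - 1, length) and turn(i, length):
                flags[i : i + length] = True

    strand = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            ci, cj = residues[i][0], residues[j][0]
            ri, rj = residues[i][1], residues[j][1]
            if ci == cj and abs(ri - rj) < 3:
                continue
            parallel = ((i - 1, j) in bonds and (j, i + 1) in bonds and consecutive(i - 1, i + 1)) or (
                (j - 1, i) in bonds and (i, j + 1) in bonds and consecutive(j - 1, j + 1)
            )
            anti = ((i, j) in bonds and (j, i) in bonds) or (
                (i - 1, j + 1) in bonds and (j - 1, i + 1) in bonds
                and consecutive(i - 1, i + 1) and consecutive(j - 1, j + 1)
            )
            if parallel or anti:
                strand[i] = strand[j] = True

    codes = {}
    for k, res in enumerate(residues):
        if not ok[k]:
            code = "C"
        elif helix4[k]:
            code = "H"
        elif strand[k]:
            code = "E"
        elif helix3[k] or helix5[k]:
            code = "H"
        else:
            code = "C"
        codes[(res[0], res[1])] = code
    return codes


def _residue_keys_checked(frames: Sequence[StructureFrame]) -> list:
    keys = frames[0].residue_keys()
    for f in frames[1:]:
        if f.residue_keys() != keys:
            raise TopologyError("ensemble frames do not share residue numbering")
    return keys


def helicity_profile(ensemble: Sequence[StructureFrame]) -> ResidueProfile:
    """Fraction of ensemble members that are helical at each residue,
    with the standard error of the mean over members."""
    if not ensemble:
        raise ConfigurationError("empty ensemble")
    keys = _residue_keys_checked(ensemble)
    ind = np.zeros((len(ensemble), len(keys)))
    for fi, frame in enumerate(ensemble):
        codes = dssp_assign(frame)
        ind[fi] = [1.0 if codes.get(k) == "H" else 0.0 for k in keys]
    N = len(ensemble)
    sem = ind.std(axis=0, ddof=1) / np.sqrt(N) if N > 1 else np.zeros(len(keys))
    return ResidueProfile(
        res_ids=np.array([r for _, r in keys]),
        n_frames=N,
        helicity=ind.mean(axis=0),
        helicity_sem=sem,
    )


def min_distance_profile(
    pairs: Sequence[tuple[StructureFrame, StructureFrame]]
) -> ResidueProfile:
    """Per-residue mean minimum distance (Angstrom) from any residue atom
    to the nearest lipid atom, averaged over ensemble members."""
    if not pairs:
        raise ConfigurationError("empty ensemble")
    keys = _residue_keys_checked([p for p, _ in pairs])
    key_index = {k: i for i, k in enumerate(keys)}
    dists = np.full((len(pairs), len(keys)), np.inf)
    for fi, (protein, lipid) in enumerate(pairs):
        if lipid.n_atoms == 0:
            raise ConfigurationError("empty lipid subset in ensemble member")
        tree = cKDTree(lipid.xyz)
        d, _ = tree.query(protein.xyz)
        for ai in range(protein.n_atoms):
            k = key_index[(protein.chain_ids[ai], int(protein.res_ids[ai]))]
            dists[fi, k] = min(dists[fi, k], d[ai])
    N = len(pairs)
    sem = dists.std(axis=0, ddof=1) / np.sqrt(N) if N > 1 else np.zeros(len(keys))
    return ResidueProfile(
        res_ids=np.array([r for _, r in keys]),
        n_frames=N,
        min_dist=dists.mean(axis=0),
        min_dist_sem=sem,
    )


def segment_summary(
    profile: ResidueProfile, segments: dict | None = None
) -> pd.DataFrame:
    """Mean helicity and/or lipid distance per named residue segment."""
    segments = segments or DEFAULT_SEGMENTS
    rows = []
    rmin, rmax = profile.res_ids.min(), profile.res_ids.max()
    for name, (lo, hi) in segments.items():
        if lo < rmin or hi > rmax:
            raise ConfigurationError(
                f"segment {name} ({lo}-{hi}) outside residue range {rmin}-{rmax}"
            )
        mask = (profile.res_ids >= lo) & (profile.res_ids <= hi)
        row: dict = {"segment": name, "first": lo, "last": hi}
        if profile.helicity is not None:
            row["mean_helicity"] = float(profile.helicity[mask].mean())
        if profile.min_dist is not None:
            row["mean_min_dist_A"] = float(profile.min_dist[mask].mean())
        rows.append(row)
    return pd.DataFrame(rows)
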