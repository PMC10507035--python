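"""Frame selection against experimental polarized spectra.

Every candidate frame's calculated spectra are compared with the
experimental means by a residual sum of squares (RSS) over all included
polarization combinations and grid points inside the scoring window,
after fitting a single non-negative scale factor per frame (one joint
scale across PCs, preserving inter-PC intensity ratios).  Frames are
ranked by ascending RSS and the ensemble is grown in rank order until
the spectral spread within the ensemble first reaches the experimental
spread: the pooled per-point standard deviation of the scaled
calculated spectra must equal (first cross) the pooled experimental
standard deviation of the replicate measurements.  Pooling is the mean
of per-point sample standard deviations over the scored window and PCs.

The scoring window defaults to the amide-I band (1600-1700 cm^-1) even
though experiments extend to 1800 cm^-1, so the lipid ester carbonyl
band the model does not simulate never enters the residuals.  All four
PCs enter with unit weight, including the chiral PSP, whose inclusion
filters out frames with spurious chiral response.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GridMismatchError
from .exciton_model import ExcitonParameters
from .geometry import tilt_twist_matrix
from .sfg_response import (
    POLARIZATION_COMBINATIONS,
    FrequencyGrid,
    FresnelWeights,
    PolarizedSpectrumSet,
    calc_frame_spectra,
)
from .structure_io import StructureFrame, TrajectoryEnsemble

__all__ = [
    "DEFAULT_WINDOW",
    "ExperimentalDataset",
    "FrameScore",
    "SelectedEnsemble",
    "OrientationScanResult",
    "fit_scale",
    "rss_score",
    "compute_library_spectra",
    "rank_frames",
    "experimental_std",
    "pooled_std_from_dataset",
    "select_ensemble",
    "orientation_scan",
    "read_experimental_table",
    "write_scores_table",
]

#: Default scoring window (cm^-1): the amide-I band.
DEFAULT_WINDOW = (1600.0, 1700.0)


@dataclass
class ExperimentalDataset:
    """Replicate-averaged experimental spectra with per-point spread."""

    grid: FrequencyGrid
    means: dict                     # pc -> (n_omega,) mean intensity
    stds: dict                     # pc -> (n_omega,) per-point sample std
    n_replicates: int = 0
    normalization: str = "gold-referenced"
    label: str = ""

    def __post_init__(self) -> None:
        for pc, s in self.stds.items():
            if np.any(np.asarray(s) < 0):
                raise ValueError(f"negative standard deviation in {pc}")
            if len(np.asarray(s)) != len(self.grid):
                raise GridMismatchError(f"std of {pc} does not match the grid")
        for pc, m in self.means.items():
            if len(np.asarray(m)) != len(self.grid):
                raise GridMismatchError(f"mean of {pc} does not match the grid")

    @property
    def pcs(self) -> tuple:
        return tuple(self.means)

    @classmethod
    def from_replicates(
        cls,
        grid: FrequencyGrid,
        replicates: Sequence[dict],
        label: str = "",
        normalization: str = "synthetic",
    ) -> "ExperimentalDataset":
        """Build means and per-point stds from replicate per-PC spectra."""
        if len(replicates) < 2:
            raise ConfigurationError("need at least two replicates")
        pcs = list(replicates[0])
        means = {pc: np.mean([r[pc] for r in replicates], axis=0) for pc in pcs}
        stds = {pc: np.std([r[pc] for r in replicates], axis=0, ddof=1) for pc in pcs}
        return cls(grid=grid, means=means, stds=stds, n_replicates=len(replicates),
                   normalization=normalization, label=label)

    def to_table(self, path) -> None:
        rows = []
        for pc in self.pcs:
            for i, wn in enumerate(self.grid.points):
                rows.append(
                    {
                        "wavenumber_cm-1": wn,
                        "pc": pc,
                        "intensity": self.means[pc][i],
                        "std": self.stds[pc][i],
                        "n_replicates": self.n_replicates,
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_experimental_table(path, label: str = "") -> ExperimentalDataset:
    """Read a tabular spectrum file (wavenumber_cm-1, pc, intensity[, std,
    n_replicates])."""
    df = pd.read_csv(path, sep="\t")
    required = {"wavenumber_cm-1", "pc", "intensity"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"spectrum table needs columns {sorted(required)}")
    pcs = sorted(df["pc"].unique())
    grids = {pc: df[df["pc"] == pc]["wavenumber_cm-1"].to_numpy() for pc in pcs}
    ref = grids[pcs[0]]
    for pc in pcs[1:]:
        if len(grids[pc]) != len(ref) or not np.allclose(grids[pc], ref):
            raise GridMismatchError("PCs do not share one wavenumber grid")
    grid = FrequencyGrid(ref)
    means, stds = {}, {}
    for pc in pcs:
        sub = df[df["pc"] == pc]
        means[pc] = sub["intensity"].to_numpy(dtype=float)
        stds[pc] = (
            sub["std"].to_numpy(dtype=float) if "std" in df.columns else np.zeros(len(ref))
        )
    n_rep = int(df["n_replicates"].iloc[0]) if "n_replicates" in df.columns else 0
    return ExperimentalDataset(grid=grid, means=means, stds=stds, n_replicates=n_rep, label=label)


@dataclass(frozen=True)
class FrameScore:
    """RSS score of one frame against one experimental dataset."""

    frame_index: int
    scale: float
    rss: float
    traj_id: str = ""
    time_ps: float = 0.0


def _window_mask(grid: FrequencyGrid, window: tuple) -> np.ndarray:
    lo, hi = window
    mask = (grid.points >= lo) & (grid.points <= hi)
    if not mask.any():
        raise ConfigurationError(f"no grid points inside window {window}")
    return mask


def _common_pcs(calc: PolarizedSpectrumSet, exp: ExperimentalDataset, pcs) -> list:
    if pcs is not None and len(pcs) == 0:
        raise ConfigurationError("empty polarization-combination subset")
    chosen = [pc.lower() for pc in (exp.pcs if pcs is None else pcs)]
    missing = [pc for pc in chosen if pc not in calc.intensities or pc not in exp.means]
    if missing:
        raise ConfigurationError(f"polarization combinations not available: {missing}")
    return chosen


def fit_scale(
    calc: PolarizedSpectrumSet,
    exp: ExperimentalDataset,
    window: tuple = DEFAULT_WINDOW,
    pcs: Sequence[str] | None = None,
) -> float:
    """Single non-negative least-squares scale: s = max(0, <exp,calc>/<calc,calc>)."""
    if not calc.grid.same_as(exp.grid):
        raise GridMismatchError("calculated and experimental grids differ")
    mask = _window_mask(calc.grid, window)
    chosen = _common_pcs(calc, exp, pcs)
    num = sum(float(exp.means[pc][mask] @ calc.intensities[pc][mask]) for pc in chosen)
    den = sum(float(calc.intensities[pc][mask] @ calc.intensities[pc][mask]) for pc in chosen)
    if den == 0.0:
        warnings.warn("all-zero calculated spectrum: scale set to 0")
        return 0.0
    return max(0.0, num / den)


def rss_score(
    calc: PolarizedSpectrumSet,
    exp: ExperimentalDataset,
    window: tuple = DEFAULT_WINDOW,
    pcs: Sequence[str] | None = None,
    frame_index: int = 0,
    traj_id: str = "",
    time_ps: float = 0.0,
) -> FrameScore:
    """RSS between the scaled calculated and experimental mean spectra."""
    s = fit_scale(calc, exp, window=window, pcs=pcs)
    mask = _window_mask(calc.grid, window)
    chosen = _common_pcs(calc, exp, pcs)
    rss = 0.0
    for pc in chosen:
        resid = exp.means[pc][mask] - s * calc.intensities[pc][mask]
        rss += float(resid @ resid)
    return FrameScore(frame_index=frame_index, scale=s, rss=rss, traj_id=traj_id, time_ps=time_ps)


def _spectra_worker(args):
    frame, params, grid, weights, n_phi = args
    try:
        return calc_frame_spectra(frame, params, grid, weights=weights, n_phi=n_phi)
    except Exception as exc:
        return exc


def compute_library_spectra(
    library: TrajectoryEnsemble,
    params: ExcitonParameters,
    grid: FrequencyGrid | None = None,
    weights: FresnelWeights | None = None,
    n_phi: int = 36,
    on_error: str = "raise",
    n_workers: int = 1,
    progress: Callable | None = None,
) -> list:
    """Calculated spectra for every frame (None where a frame failed and
    ``on_error='skip'``).  Results are independent of ``n_workers``."""
    if on_error not in ("raise", "skip"):
        raise ConfigurationError("on_error must be 'raise' or 'skip'")
    grid = grid or FrequencyGrid.default()
    jobs = [(frame, params, grid, weights, n_phi) for frame in library]
    if n_workers > 1:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(_spectra_worker, jobs, chunksize=8))
    else:
        results = map(_spectra_worker, jobs)
    out = []
    for i, res in enumerate(results):
        if isinstance(res, Exception):
            if on_error == "raise":
                raise res
            warnings.warn(f"frame {i}: spectral calculation failed; skipped ({res})")
            out.append(None)
        else:
            out.append(res)
        if progress is not None:
            progress(i)
    return out


def rank_frames(
    library: TrajectoryEnsemble,
    exp: ExperimentalDataset,
    params: ExcitonParameters,
    grid: FrequencyGrid | None = None,
    window: tuple = DEFAULT_WINDOW,
    pcs: Sequence[str] | None = None,
    weights: FresnelWeights | None = None,
    spectra: Sequence[PolarizedSpectrumSet] | None = None,
    on_error: str = "raise",
) -> list:
    """Score every frame and sort ascending by RSS (ties broken by the
    global frame index, so ranking is deterministic)."""
    if len(library) == 0:
        raise ConfigurationError("empty frame library")
    if spectra is None:
        spectra = compute_library_spectra(
            library, params, grid=grid, weights=weights, on_error=on_error
        )
    scores = []
    for i, (frame, spec) in enumerate(zip(library, spectra)):
        if spec is None:
            continue
        scores.append(
            rss_score(
                spec, exp, window=window, pcs=pcs,
                frame_index=i, traj_id=frame.traj_id, time_ps=frame.time_ps,
            )
        )
    return sorted(scores, key=lambda sc: (sc.rss, sc.frame_index))


def experimental_std(
    replicates: Sequence[dict],
    grid: FrequencyGrid,
    window: tuple = DEFAULT_WINDOW,
    pcs: Sequence[str] | None = None,
) -> float:
    """Pooled experimental spread: mean over scored points and PCs of the
    per-point sample standard deviation (n-1 denominator) of replicates."""
    if len(replicates) < 2:
        raise ConfigurationError("need at least two replicates for a standard deviation")
    mask = _window_mask(grid, window)
    chosen = [pc.lower() for pc in (pcs or list(replicates[0]))]
    vals = []
    for pc in chosen:
        stack = np.stack([np.asarray(r[pc], dtype=float) for r in replicates])
        vals.append(np.std(stack, axis=0, ddof=1)[mask])
    return float(np.mean(np.concatenate(vals)))


def pooled_std_from_dataset(
    exp: ExperimentalDataset,
    window: tuple = DEFAULT_WINDOW,
    pcs: Sequence[str] | None = None,
) -> float:
    """Pool a dataset's stored per-point standard deviations the same way
    ``experimental_std`` pools replicates (mean over window and PCs)."""
    mask = _window_mask(exp.grid, window)
    chosen = [pc.lower() for pc in (pcs or exp.pcs)]
    return float(np.mean(np.concatenate([np.asarray(exp.stds[pc])[mask] for pc in chosen])))


def _pooled_calc_std(
    member_spectra: Sequence[PolarizedSpectrumSet],
    scales: Sequence[float],
    mask: np.ndarray,
    pcs: Sequence[str],
) -> float:
    """Pooled spread of scaled calculated spectra over ensemble members."""
    if len(member_spectra) < 2:
        return 0.0
    vals = []
    for pc in pcs:
        stack = np.stack(
            [s * spec.intensities[pc][mask] for spec, s in zip(member_spectra, scales)]
        )
        vals.append(np.std(stack, axis=0, ddof=1))
    return float(np.mean(np.concatenate(vals)))


@dataclass
class SelectedEnsemble:
    """Frames below the std-matched RSS cutoff, with spectral envelopes."""

    member_indices: list            # ascending RSS order
    threshold: float
    pooled_calc_std: float
    pooled_exp_std: float
    member_scores: list = field(default_factory=list)
    mean_spectra: dict = field(default_factory=dict)   # pc -> array
    min_spectra: dict = field(default_factory=dict)
    max_spectra: dict = field(default_factory=dict)
    grid: FrequencyGrid | None = None

    @property
    def size(self) -> int:
        return len(self.member_indices)

    def to_json(self, path) -> None:
        payload = {
            "members": [int(i) for i in self.member_indices],
            "threshold": self.threshold,
            "pooled_calc_std": self.pooled_calc_std,
            "pooled_exp_std": self.pooled_exp_std,
            "scores": [
                {"frame_index": sc.frame_index, "scale": sc.scale, "rss": sc.rss,
                 "traj_id": sc.traj_id, "time_ps": sc.time_ps}
                for sc in self.member_scores
            ],
            "wavenumber_cm-1": list(self.grid.points) if self.grid is not None else None,
            "mean_spectra": {pc: list(v) for pc, v in self.mean_spectra.items()},
            "min_spectra": {pc: list(v) for pc, v in self.min_spectra.items()},
            "max_spectra": {pc: list(v) for pc, v in self.max_spectra.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def select_ensemble(
    ranking: Sequence[FrameScore],
    spectra: Sequence[PolarizedSpectrumSet],
    pooled_exp_std: float,
    window: tuple = DEFAULT_WINDOW,
    pcs: Sequence[str] | None = None,
) -> SelectedEnsemble:
    """Grow the ensemble in ascending-RSS order until its pooled spectral
    spread first reaches the experimental spread.

    ``spectra`` is indexed by global frame index.  With a zero
    experimental spread the ensemble is the set of rank-1-tied frames.
    The returned threshold is the RSS of the last included frame, and
    the per-PC mean/min/max envelopes describe the scaled member spectra.
    """
    if not ranking:
        raise ConfigurationError("empty ranking")
    grid = spectra[ranking[0].frame_index].grid
    mask = _window_mask(grid, window)
    chosen = [pc.lower() for pc in (pcs or list(spectra[ranking[0].frame_index].intensities))]

    if pooled_exp_std == 0.0:
        best = ranking[0].rss
        members = [sc for sc in ranking if sc.rss == best]
    else:
        members = []
        pooled = 0.0
        for sc in ranking:
            members.append(sc)
            pooled = _pooled_calc_std(
                [spectra[m.frame_index] for m in members],
                [m.scale for m in members], mask, chosen,
            )
            if pooled >= pooled_exp_std:
                break
        else:
            warnings.warn(
                "ensemble spread never reached the experimental spread; all frames selected"
            )
    member_spectra = [spectra[m.frame_index].scaled(m.scale) for m in members]
    stacks = {
        pc: np.stack([ms.intensities[pc] for ms in member_spectra]) for pc in chosen
    }
    return SelectedEnsemble(
        member_indices=[m.frame_index for m in members],
        threshold=members[-1].rss,
        pooled_calc_std=_pooled_calc_std(
            [spectra[m.frame_index] for m in members], [m.scale for m in members], mask, chosen
        ),
        pooled_exp_std=pooled_exp_std,
        member_scores=list(members),
        mean_spectra={pc: stacks[pc].mean(axis=0) for pc in chosen},
        min_spectra={pc: stacks[pc].min(axis=0) for pc in chosen},
        max_spectra={pc: stacks[pc].max(axis=0) for pc in chosen},
        grid=grid,
    )


@dataclass
class OrientationScanResult:
    """RSS map over rigid-body (tilt, twist) orientations."""

    tilt_deg: np.ndarray            # (n_tilt,)
    twist_deg: np.ndarray           # (n_twist,)
    rss: np.ndarray                 # (n_tilt, n_twist)
    best_tilt: float
    best_twist: float
    best_rss: float


def orientation_scan(
    structure: StructureFrame,
    exp: ExperimentalDataset,
    tilt_grid_deg: Sequence[float],
    twist_grid_deg: Sequence[float],
    params: ExcitonParameters,
    grid: FrequencyGrid | None = None,
    window: tuple = DEFAULT_WINDOW,
    pcs: Sequence[str] | None = None,
    weights: FresnelWeights | None = None,
) -> OrientationScanResult:
    """Score a rigid structure against the data for every (tilt, twist).

    The structure is rotated about its centroid (twist about the
    molecular z axis, then tilt about a horizontal axis); the RSS map is
    periodic in twist with period 360 degrees.
    """
    tilts = np.asarray(tilt_grid_deg, dtype=float)
    twists = np.asarray(twist_grid_deg, dtype=float)
    if tilts.size == 0 or twists.size == 0:
        raise ConfigurationError("empty orientation grid")
    grid = grid or FrequencyGrid.default()
    centroid = structure.xyz.mean(axis=0)
    centered = structure.transformed(translation=-centroid)
    rss_map = np.empty((len(tilts), len(twists)))
    for a, th in enumerate(tilts):
        for b, tw in enumerate(twists):
            rotated = centered.transformed(rotation=tilt_twist_matrix(th, tw), translation=centroid)
            spec = calc_frame_spectra(rotated, params, grid, weights=weights)
            rss_map[a, b] = rss_score(spec, exp, window=window, pcs=pcs).rss
    a, b = np.unravel_index(np.argmin(rss_map), rss_map.shape)
    return OrientationScanResult(
        tilt_deg=tilts, twist_deg=twists, rss=rss_map,
        best_tilt=float(tilts[a]), best_twist=float(twists[b]), best_rss=float(rss_map[a, b]),
    )


def write_scores_table(scores: Sequence[FrameScore], path) -> None:
    """Write the ranking as TSV (frame_index, trajectory_id, time_ps, scale, rss)."""
    pd.DataFrame(
        [
            {
                "frame_index": sc.frame_index,
                "trajectory_id": sc.traj_id,
                "time_ps": sc.time_ps,
                "scale": sc.scale,
                "rss": sc.rss,
            }
            for sc in scores
        ]
    ).to_csv(path, sep="\t", index=False)
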