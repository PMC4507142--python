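"""Bilayer trajectory statistics and simulation-composition arithmetic.

Implements the analyses run on membrane molecular-dynamics trajectories:
counts of Na+ ions bound at the bilayer surface (minimum-image distance to
any DOPC phosphorus below a 0.8 nm cutoff), radial distribution functions,
the XY bilayer-area series with a steady-state check, percent-reduction
summaries, and the electroneutrality bookkeeping for simulated systems
(Na+ + monocationic IL = Cl-).

Trajectories are consumed either as standard GRO/XTC(TRR) files through
MDAnalysis or as the in-repo :class:`~gakit.synthetic.TrajectoryFrames`
container.  Boxes must be orthorhombic; all distances use the minimum-image
convention, so every statistic is invariant under uniform translation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .synthetic import TrajectoryFrames

__all__ = [
    "BoundIonSeries",
    "RDFResult",
    "AreaSeries",
    "SystemComposition",
    "PercentReduction",
    "count_bound_ions",
    "percent_reduction",
    "rdf",
    "xy_area_series",
    "counterions_needed",
    "ion_pairs_for_concentration",
    "molar_ratio",
    "load_trajectory",
]

#: mol of water per litre of water — the standard convention for converting
#: a molar salt concentration into an ion count per simulated water count.
WATER_MOLARITY = 55.5


def minimum_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors to their nearest periodic image."""
    return delta - box * np.round(delta / box)


# ---------------------------------------------------------------------------
# Bound-ion counting
# ---------------------------------------------------------------------------

@dataclass
class BoundIonSeries:
    """Per-frame count of Na+ within the binding cutoff of any phosphate."""

    times: np.ndarray  # ns
    counts: np.ndarray  # int per frame
    cutoff: float  # nm
    window: tuple[float, float]  # ns, analysis window
    mean: float  # over the window
    sd: float  # per-frame SD over the window (window dispersion)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "bound_na": self.counts})


def _window_slice(n_frames: int, window_fraction: float) -> slice:
    start = n_frames - max(1, int(round(window_fraction * n_frames)))
    return slice(start, n_frames)


def count_bound_ions(
    frames: TrajectoryFrames,
    cutoff: float = 0.8,
    window_fraction: float = 0.5,
    ion_group: str = "NA",
    phosphate_group: str = "P_DOPC",
) -> BoundIonSeries:
    """Count Na+ ions close to the membrane surface, per frame.

    An ion counts (once) when its minimum-image distance to *any* DOPC
    phosphorus is strictly below ``cutoff`` (default 0.8 nm).  The summary
    mean +/- SD is taken over the trailing ``window_fraction`` of frames,
    mirroring analysis over the equilibrated final half of a trajectory.
    """
    if frames.n_frames == 0:
        raise ValueError("no frames to analyse")
    for g in (ion_group, phosphate_group):
        if g not in frames.groups:
            raise ValueError(f"required group {g!r} missing from frames")
    ions = frames.groups[ion_group]
    phos = frames.groups[phosphate_group]
    if phos.shape[1] == 0:
        raise ValueError("phosphate group is empty")

    counts = np.zeros(frames.n_frames, dtype=int)
    cut2 = cutoff * cutoff
    for f in range(frames.n_frames):
        if ions.shape[1] == 0:
            continue
        d = minimum_image(ions[f][:, None, :] - phos[f][None, :, :],
                          frames.box[f])
        min_d2 = np.min(np.einsum("ijk,ijk->ij", d, d), axis=1)
        counts[f] = int(np.count_nonzero(min_d2 < cut2))

    sl = _window_slice(frames.n_frames, window_fraction)
    win = counts[sl]
    sd = float(win.std(ddof=1)) if win.size > 1 else 0.0
    return BoundIonSeries(
        times=frames.times.copy(), counts=counts, cutoff=float(cutoff),
        window=(float(frames.times[sl][0]), float(frames.times[sl][-1])),
        mean=float(win.mean()), sd=sd,
    )


@dataclass(frozen=True)
class PercentReduction:
    """Reduction of a test mean relative to a reference mean."""

    value: float  # unrounded percent
    rounded: int  # reported percent

    def __str__(self) -> str:  # pragma: no cover
        return f"{self.rounded}%"


def percent_reduction(mean_ref: float, mean_test: float) -> PercentReduction:
    """100 * (1 - mean_test / mean_ref); reported rounded to the nearest
    integer percent, with the unrounded value retained."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    value = 100.0 * (1.0 - mean_test / mean_ref)
    return PercentReduction(value=float(value), rounded=int(round(value)))


# ---------------------------------------------------------------------------
# Radial distribution function
# ---------------------------------------------------------------------------

@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, nm
    g: np.ndarray  # g(r)
    counts: np.ndarray  # raw pair counts per shell, summed over frames
    reference_group: str
    target_group: str
    dr: float  # nm
    r_max: float  # nm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.r, "g_r": self.g})


def rdf(
    frames: TrajectoryFrames,
    reference_group: str,
    target_group: str,
    r_max: float,
    dr: float,
) -> RDFResult:
    """Radial distribution function g(r) between two atom groups.

    Minimum-image pair distances (periodic KD-tree) are binned into
    spherical shells; each frame's histogram is normalized by the reference
    count, the target bulk number density N_t / V, and the exact shell
    volume (4/3)pi[(r+dr)^3 - r^3], then averaged over frames.  For a
    homogeneous (ideal-gas-like) system g(r) -> 1.  Self-pairs are excluded
    when reference and target are the same group.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    half_min_box = float(np.min(frames.box)) / 2.0
    if r_max > half_min_box + 1e-9:
        raise ValueError("r_max must not exceed half the smallest box length")
    for g in (reference_group, target_group):
        if g not in frames.groups or frames.groups[g].shape[1] == 0:
            raise ValueError(f"group {g!r} missing or empty")

    ref = frames.groups[reference_group]
    tgt = frames.groups[target_group]
    same = reference_group == target_group
    n_ref, n_tgt = ref.shape[1], tgt.shape[1]
    if same and n_ref < 2:
        raise ValueError("need at least two particles for a same-group RDF")

    nbins = int(math.ceil(r_max / dr))
    edges = np.arange(nbins + 1) * dr
    counts = np.zeros(nbins, dtype=float)
    expected = 0.0  # accumulated ideal-gas pair count per unit g(r)
    shell_vol = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    from scipy.spatial import cKDTree

    for f in range(frames.n_frames):
        box = frames.box[f]
        vol = float(np.prod(box))
        # periodic KD-tree needs wrapped coordinates
        ref_w = np.mod(ref[f], box)
        tgt_w = np.mod(tgt[f], box)
        tree_ref = cKDTree(ref_w, boxsize=box)
        tree_tgt = tree_ref if same else cKDTree(tgt_w, boxsize=box)
        # cumulative pair counts at each edge; self pairs (distance 0) fall
        # into the r <= 0 bucket and drop out of the shell differences
        cum = tree_ref.count_neighbors(tree_tgt, edges)
        counts += np.diff(cum)
        expected += n_ref * (n_tgt - (1 if same else 0)) / vol

    g_r = counts / (expected * shell_vol)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r=centers, g=g_r, counts=counts,
                     reference_group=reference_group,
                     target_group=target_group, dr=float(dr),
                     r_max=float(r_max))


# ---------------------------------------------------------------------------
# XY-area series
# ---------------------------------------------------------------------------

@dataclass
class AreaSeries:
    """Per-frame bilayer XY area (Lx * Ly) with a steady-state check."""

    times: np.ndarray  # ns
    areas: np.ndarray  # nm^2
    mean: float  # over the analysis window
    sd: float
    steady: bool  # first-quarter vs last-quarter means agree
    drift: float  # relative difference between those means

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "area_nm2": self.areas})


def xy_area_series(
    frames: TrajectoryFrames,
    window_fraction: float = 0.5,
    steady_rel_tol: float = 0.02,
) -> AreaSeries:
    """Bilayer surface area Lx * Ly per frame.

    The steady-state check compares the mean area of the first quarter of
    frames with the last quarter; a relative difference within
    ``steady_rel_tol`` counts as equilibrated.
    """
    if frames.n_frames == 0:
        raise ValueError("no frames to analyse")
    areas = frames.box[:, 0] * frames.box[:, 1]
    sl = _window_slice(frames.n_frames, window_fraction)
    win = areas[sl]
    q = max(1, frames.n_frames // 4)
    m_first, m_last = float(areas[:q].mean()), float(areas[-q:].mean())
    overall = float(areas.mean())
    drift = abs(m_last - m_first) / overall if overall else 0.0
    return AreaSeries(
        times=frames.times.copy(), areas=areas,
        mean=float(win.mean()),
        sd=float(win.std(ddof=1)) if win.size > 1 else 0.0,
        steady=bool(drift <= steady_rel_tol), drift=float(drift),
    )


# ---------------------------------------------------------------------------
# System composition (electroneutrality arithmetic)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemComposition:
    """Molecule and ion counts of one simulated bilayer system.

    The ionic liquid carries +1 per molecule, so electroneutrality requires
    n_cl = n_na + n_il.
    """

    n_dopc: int
    n_il: int
    n_na: int
    n_cl: int | None = None
    n_water: int = 0
    il_charge: int = 1

    def __post_init__(self) -> None:
        for name in ("n_dopc", "n_il", "n_na", "n_water"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cl is not None and self.n_cl < 0:
            raise ValueError("n_cl must be non-negative")

    @property
    def electroneutral(self) -> bool:
        return (self.n_cl is not None
                and self.n_cl == self.n_na + self.il_charge * self.n_il)


def counterions_needed(composition: SystemComposition) -> SystemComposition:
    """Complete a composition with the Cl- count that neutralizes it:
    n_cl = n_na + n_il (monocationic IL)."""
    n_cl = composition.n_na + composition.il_charge * composition.n_il
    completed = replace(composition, n_cl=n_cl)
    assert completed.electroneutral
    return completed


def ion_pairs_for_concentration(molar_conc: float, n_water: int) -> int:
    """NaCl ion pairs approximating a molar concentration for a given water
    count: round(c * n_water / 55.5).  A planning utility for box setup."""
    if molar_conc < 0:
        raise ValueError("concentration must be non-negative")
    if n_water <= 0:
        raise ValueError("n_water must be positive")
    return int(round(molar_conc * n_water / WATER_MOLARITY))


def molar_ratio(n_a: int, n_b: int) -> tuple[int, int]:
    """Reduce a molecule-count pair to its lowest-terms molar ratio."""
    if n_b <= 0:
        raise ValueError("second count must be positive")
    if n_a < 0:
        raise ValueError("counts must be non-negative")
    g = math.gcd(int(n_a), int(n_b))
    return int(n_a) // g, int(n_b) // g


# ---------------------------------------------------------------------------
# Standard-format input
# ---------------------------------------------------------------------------

DEFAULT_SELECTIONS = {
    "NA": "name NA",
    "CL": "name CL",
    "P_DOPC": "name P",
    "IL_HEAD": "name NIL",
}


def load_trajectory(
    topology,
    trajectory=None,
    selections: dict[str, str] | None = None,
) -> TrajectoryFrames:
    """Read a GRO/PDB topology (+ XTC/TRR frames) into TrajectoryFrames.

    ``selections`` maps group names to MDAnalysis selection strings; groups
    selecting zero atoms are kept empty.  Triclinic boxes are rejected.
    """
    import MDAnalysis as mda

    sel = dict(DEFAULT_SELECTIONS, **(selections or {}))
    u = (mda.Universe(str(topology), str(trajectory))
         if trajectory is not None else mda.Universe(str(topology)))
    atom_groups = {name: u.select_atoms(expr) for name, expr in sel.items()}

    times, boxes = [], []
    coords: dict[str, list[np.ndarray]] = {name: [] for name in atom_groups}
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None:
            raise ValueError("trajectory frames carry no box information")
        if not np.allclose(dims[3:], 90.0, atol=1e-2):
            raise ValueError("triclinic boxes are not supported; "
                             "only orthorhombic cells are handled")
        boxes.append(dims[:3] / 10.0)  # Angstrom -> nm
        times.append(ts.time / 1000.0)  # ps -> ns
        for name, ag in atom_groups.items():
            coords[name].append(ag.positions / 10.0)

    return TrajectoryFrames(
        times=np.asarray(times), box=np.asarray(boxes),
        groups={name: np.asarray(stack) if stack and stack[0].size else
                np.zeros((len(times), 0, 3))
                for name, stack in coords.items()},
        metadata={"topology": str(topology),
                  "trajectory": None if trajectory is None else str(trajectory)},
    )
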