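"""Time-series analysis of conformational ensembles.

Covers per-frame backbone RMSD and radius-of-gyration traces, per-residue
time-averaged main-chain RMSD, circular statistics on backbone dihedrals,
and single-pass leader clustering of frames in (phi, psi) space with
representative-frame selection.  Angles live in degrees in (-180, 180] and
all dispersion measures respect the wraparound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import structures
from .structures import Structure


def wrap_angles(a: np.ndarray | float) -> np.ndarray | float:
    """Map angles in degrees onto (-180, 180]."""
    w = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return w


def wrapped_diff(a, b):
    """Signed smallest angular difference a - b in degrees, in (-180, 180]."""
    return wrap_angles(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass
class DihedralSeries:
    """Backbone (phi, psi) angles per frame for an ordered residue set.

    angles has shape (n_frames, n_residues, 2) with the last axis (phi, psi);
    residues holds the matching residue sequence numbers.
    """

    angles: np.ndarray
    residues: list[int]
    frame_spacing: float | None = None  # carried metadata; unused by the math

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 3 or self.angles.shape[2] != 2:
            raise ValueError("angles must have shape (frames, residues, 2)")
        if self.angles.shape[1] != len(self.residues):
            raise ValueError("residue list does not match angle array")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("dihedral series contains missing values")
        self.angles = wrap_angles(self.angles)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def columns(self, residues: Iterable[int] | None = None) -> np.ndarray:
        """Flat (n_frames, 2k) view of the angles of the selected residues."""
        if residues is None:
            idx = list(range(len(self.residues)))
        else:
            idx = []
            for r in residues:
                if r not in self.residues:
                    raise ValueError(f"residue {r} not present in series (have {self.residues})")
                idx.append(self.residues.index(r))
        return self.angles[:, idx, :].reshape(self.n_frames, -1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in range(self.n_frames):
            for j, res in enumerate(self.residues):
                rows.append({"frame": f, "residue": res,
                             "phi": self.angles[f, j, 0], "psi": self.angles[f, j, 1]})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DihedralSeries":
        residues = sorted(df["residue"].unique())
        frames = sorted(df["frame"].unique())
        pivot = df.set_index(["frame", "residue"])
        angles = np.empty((len(frames), len(residues), 2))
        for i, f in enumerate(frames):
            for j, r in enumerate(residues):
                row = pivot.loc[(f, r)]
                angles[i, j] = (row["phi"], row["psi"])
        return cls(angles=angles, residues=[int(r) for r in residues])


def read_dihedral_tsv(path) -> DihedralSeries:
    return DihedralSeries.from_frame(pd.read_csv(path, sep="\t"))


def write_dihedral_tsv(series: DihedralSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def extract_dihedrals(
    frames: Sequence[Structure],
    residues: Iterable[int],
    chain_id: str | None = None,
) -> DihedralSeries:
    """Phi/psi time series for the given residues of every frame.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1); the
    flanking residues must therefore be present too.
    """
    residues = list(residues)
    if not frames:
        raise ValueError("extract_dihedrals: empty trajectory")
    angles = np.empty((len(frames), len(residues), 2))
    for fi, frame in enumerate(frames):
        cid = chain_id or frame.chains[0]
        by_seq = {r.seq_number: r for r in frame.residues if r.chain_id == cid}
        for ri, seq in enumerate(residues):
            try:
                prev, cur, nxt = by_seq[seq - 1], by_seq[seq], by_seq[seq + 1]
                phi = structures.dihedral(prev.atom("C").coords, cur.atom("N").coords,
                                          cur.atom("CA").coords, cur.atom("C").coords)
                psi = structures.dihedral(cur.atom("N").coords, cur.atom("CA").coords,
                                          cur.atom("C").coords, nxt.atom("N").coords)
            except KeyError as exc:
                raise ValueError(f"frame {fi}: incomplete backbone around residue {seq}: {exc}") from None
            angles[fi, ri] = (phi, psi)
    return DihedralSeries(angles=angles, residues=residues)


def circular_mean(angles_deg: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    mean = np.arctan2(np.sin(rad).mean(axis=axis), np.cos(rad).mean(axis=axis))
    return wrap_angles(np.rad2deg(mean))


def circular_sd(angles_deg: np.ndarray, axis: int | None = None, method: str = "circular"):
    """Standard deviation of angles in degrees, respecting wraparound.

    method="circular": sqrt(-2 ln R) with R the mean resultant length (the
    circular standard deviation).  method="unwrap": arithmetic SD after
    recentring every angle about the circular mean; the two agree for small
    dispersion.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.shape[axis] if axis is not None else a.size
    if n < 2:
        raise ValueError("circular_sd requires at least 2 angles")
    if method == "circular":
        rad = np.deg2rad(a)
        r = np.hypot(np.sin(rad).mean(axis=axis), np.cos(rad).mean(axis=axis))
        r = np.clip(r, 1e-300, 1.0)
        return np.rad2deg(np.sqrt(-2.0 * np.log(r)))
    if method == "unwrap":
        mean = circular_mean(a, axis=axis)
        dev = wrapped_diff(a, np.expand_dims(mean, axis) if axis is not None else mean)
        return np.sqrt(np.mean(np.square(dev), axis=axis))
    raise ValueError(f"unknown method {method!r}")


def default_threshold(series: DihedralSeries, residues: Iterable[int] | None = None,
                      method: str = "circular") -> float:
    """Average per-angle standard deviation over the selected residues.

    This is the data-derived cluster radius: the mean of the circular SDs of
    each selected phi/psi column over the whole time series.
    """
    cols = series.columns(residues)
    if cols.shape[0] < 2:
        raise ValueError("default_threshold requires at least 2 frames")
    sds = circular_sd(cols, axis=0, method=method)
    return float(np.mean(sds))


@dataclass
class ClusterResult:
    labels: np.ndarray            # per-frame cluster index, 0-based
    centres: np.ndarray           # (n_clusters, n_angles) circular-mean centres, degrees
    representatives: list[int]    # per-cluster frame index closest to the centre
    threshold: float
    occupancy: np.ndarray         # per-cluster % of trajectory

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(1, self.n_clusters + 1),
            "occupancy_percent": np.round(self.occupancy, 4),
            "representative_frame": self.representatives,
        })


def _angle_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """RMS over angle columns of the wrapped differences (degrees)."""
    d = wrapped_diff(a, b)
    return np.sqrt(np.mean(np.square(d), axis=-1))


def cluster_dihedrals(
    series: DihedralSeries,
    residues: Iterable[int] | None = None,
    threshold: float | None = None,
) -> ClusterResult:
    """Single-pass leader clustering of frames in dihedral space.

    Frames are visited in time order; a frame joins the first existing
    cluster whose founding centre lies within `threshold` (RMS of wrapped
    per-angle differences), otherwise it founds a new cluster.  Afterwards
    centres are recomputed as per-angle circular means of the members and
    each cluster's representative is the member frame closest to that centre
    (ties -> earliest frame).
    """
    cols = series.columns(residues)
    if threshold is None:
        threshold = default_threshold(series, residues)
    if threshold <= 0:
        raise ValueError("cluster threshold must be positive")
    n = cols.shape[0]
    if n == 0:
        raise ValueError("cluster_dihedrals: empty series")
    founders: list[np.ndarray] = []
    labels = np.empty(n, dtype=int)
    for f in range(n):
        assigned = -1
        for ci, centre in enumerate(founders):
            if _angle_distance(cols[f], centre) <= threshold:
                assigned = ci
                break
        if assigned < 0:
            founders.append(cols[f].copy())
            assigned = len(founders) - 1
        labels[f] = assigned
    k = len(founders)
    centres = np.empty((k, cols.shape[1]))
    representatives = []
    occupancy = np.empty(k)
    for ci in range(k):
        members = np.flatnonzero(labels == ci)
        centres[ci] = circular_mean(cols[members], axis=0)
        dists = _angle_distance(cols[members], centres[ci])
        representatives.append(int(members[int(np.argmin(dists))]))
        occupancy[ci] = 100.0 * len(members) / n
    return ClusterResult(labels=labels, centres=centres, representatives=representatives,
                         threshold=float(threshold), occupancy=occupancy)


@dataclass
class TrajectoryProfiles:
    per_frame: pd.DataFrame      # frame, backbone_rmsd, rog
    per_residue: pd.DataFrame    # seq_number, res_name, mean_rmsd, sd_rmsd


def trajectory_profiles(
    frames: Sequence[Structure],
    reference: Structure,
    chain_id: str | None = None,
    fit_residues: Iterable[int] | None = None,
) -> TrajectoryProfiles:
    """Backbone RMSD/RoG traces plus time-averaged per-residue RMSD.

    Every frame is first least-squares fitted to the reference on C-alpha
    atoms (optionally restricted to `fit_residues`); the per-residue value
    is then the main-chain RMSD of that residue without refitting, averaged
    over frames, with its standard deviation over frames.
    """
    if not frames:
        raise ValueError("trajectory_profiles: empty trajectory")
    cid = chain_id or reference.chains[0]
    fit_set = set(fit_residues) if fit_residues is not None else None

    def ca_coords(s: Structure) -> np.ndarray:
        return s.select_coords(
            atom_names={"CA"}, chain_id=cid,
            predicate=(None if fit_set is None else (lambda r, a: r.seq_number in fit_set)),
        )

    ref_ca = ca_coords(reference)
    ref_residues = [r for r in reference.residues if r.chain_id == cid]
    per_frame_rows = []
    res_rmsds = {r.seq_number: [] for r in ref_residues}
    for fi, frame in enumerate(frames):
        fit = structures.superpose(ca_coords(frame), ref_ca)
        fitted = fit.apply_structure(frame)
        bb_f = fitted.select_coords(atom_names=structures.MAINCHAIN_ATOMS, chain_id=cid)
        bb_r = reference.select_coords(atom_names=structures.MAINCHAIN_ATOMS, chain_id=cid)
        bb_rmsd = float(np.sqrt(np.mean(np.sum((bb_f - bb_r) ** 2, axis=1))))
        rog = structures.radius_of_gyration(fitted, chain_id=cid)
        per_frame_rows.append({"frame": fi, "backbone_rmsd": bb_rmsd, "rog": rog})
        for r in ref_residues:
            res_rmsds[r.seq_number].append(
                structures.per_residue_rmsd(fitted, reference, cid, r.seq_number))
    per_res_rows = [
        {
            "seq_number": r.seq_number,
            "res_name": r.res_name,
            "mean_rmsd": float(np.mean(res_rmsds[r.seq_number])),
            "sd_rmsd": float(np.std(res_rmsds[r.seq_number])),
        }
        for r in ref_residues
    ]
    return TrajectoryProfiles(per_frame=pd.DataFrame(per_frame_rows),
                              per_residue=pd.DataFrame(per_res_rows))
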