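"""Trajectory summary statistics: superposition, RMSD, RMSF, cross-correlation
and hydrogen-bond / salt-bridge occupancy.

These are the standard post-processing statistics of an MD trajectory. The
trajectory itself is an input (multi-model PDB or a plain per-frame XYZ
table); no simulation is run here. Superposition uses the Kabsch algorithm
(least-squares optimal proper rotation, reflections excluded); RMSF and the
dynamic cross-correlation map (DCCM) are computed after superposing every
frame onto an iterated mean structure, so a global rigid motion of the whole
system does not masquerade as internal fluctuation.

Definitions, for selected atoms i and frames t with deviations
dr_i(t) = r_i(t) - <r_i>:

    RMSF_i  = sqrt( <|dr_i|^2> )
    DCCM_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>)

Occupancy of a geometric interaction is the fraction of frames in which its
distance (and optionally angle) criterion holds; a salt-bridge occupancy is
simply a distance-only specification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("condiv.trajstats")


@dataclass
class Trajectory:
    """Frames (F, A, 3) in Angstrom plus per-atom metadata arrays."""

    coords: np.ndarray
    chains: np.ndarray            # (A,) str
    resnums: np.ndarray           # (A,) int
    resnames: np.ndarray          # (A,) str
    atom_names: np.ndarray        # (A,) str
    dt_ps: float = 0.0            # frame spacing, metadata only

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1 or self.coords.shape[1] < 1:
            raise ValueError("need at least one frame and one atom")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        for arr in (self.chains, self.resnums, self.resnames, self.atom_names):
            if len(arr) != self.coords.shape[1]:
                raise ValueError("metadata length must equal atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, selection: str = "name CA",
               exclude_residues: Sequence[Tuple[int, int]] = ()) -> np.ndarray:
        """Atom indices for a simple selection expression.

        Supported: ``all``, ``name <ATOM>``, ``chain <ID>``, combined with
        ``and``. ``exclude_residues`` removes inclusive resnum ranges (the
        usual way to drop flexible terminal segments).
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        tokens = selection.strip().split()
        i = 0
        while i < len(tokens):
            tok = tokens[i]
            if tok == "all":
                i += 1
            elif tok == "name":
                mask &= self.atom_names == tokens[i + 1]
                i += 2
            elif tok == "chain":
                mask &= self.chains == tokens[i + 1]
                i += 2
            elif tok == "and":
                i += 1
            else:
                raise ValueError(f"unsupported selection token {tok!r}")
        for lo, hi in exclude_residues:
            mask &= ~((self.resnums >= lo) & (self.resnums <= hi))
        return np.flatnonzero(mask)

    def atom_index(self, chain: str, resnum: int, name: str) -> int:
        hits = np.flatnonzero(
            (self.chains == chain) & (self.resnums == resnum) & (self.atom_names == name)
        )
        if len(hits) == 0:
            raise KeyError(f"atom {chain}:{resnum}:{name} not found in trajectory")
        return int(hits[0])


@dataclass
class HBondSpec:
    """Geometric criterion for one H-bond (or, distance-only, a salt bridge)."""

    donor: Tuple[str, int, str]                  # (chain, resnum, atom name)
    acceptor: Tuple[str, int, str]
    antecedent: Optional[Tuple[str, int, str]] = None
    dist_cutoff: float = 3.5
    angle_cutoff: Optional[float] = 120.0        # None -> distance-only
    label: str = ""

    def __post_init__(self):
        if self.dist_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if self.angle_cutoff is not None and self.angle_cutoff <= 0:
            raise ValueError("angle cutoff must be positive")
        if self.angle_cutoff is not None and self.antecedent is None:
            raise ValueError("angle criterion needs a donor antecedent atom")


@dataclass
class TrajectoryStats:
    rmsd_series: np.ndarray
    rmsf: np.ndarray
    dccm: np.ndarray
    hbond_occupancy: Dict[str, float] = field(default_factory=dict)
    selection_indices: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with det(rotation) = +1 (proper
    rotation only; a mirror-image input keeps a positive RMSD rather than
    being reflected away). Superposed coordinates are
    ``mobile @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"atom count mismatch: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms of shape (n, 3)")

    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    x = mobile - mob_center
    y = reference - ref_center
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ref_center - rotation @ mob_center
    moved = x @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def _superpose_frames(coords: np.ndarray, fit_idx: np.ndarray,
                      reference: np.ndarray) -> np.ndarray:
    """Superpose every frame onto ``reference`` over the fit atom subset."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, trans, _ = kabsch_superpose(coords[f, fit_idx], reference)
        out[f] = coords[f] @ rot.T + trans
    return out


def _mean_structure_superpose(coords: np.ndarray, fit_idx: np.ndarray,
                              passes: int = 2) -> np.ndarray:
    """Superpose all frames onto their iterated mean structure."""
    fitted = _superpose_frames(coords, fit_idx, coords[0, fit_idx])
    for _ in range(passes):
        mean_ref = fitted[:, fit_idx].mean(axis=0)
        fitted = _superpose_frames(fitted, fit_idx, mean_ref)
    return fitted


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, reference_frame: int = 0,
                selection: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame RMSD to a reference frame after optimal superposition."""
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    ref = traj.coords[reference_frame, idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.coords[f, idx], ref)
    return out


def rmsf(traj: Trajectory, selection: Optional[np.ndarray] = None,
         superpose: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the time-mean position."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    coords = traj.coords
    if superpose:
        coords = _mean_structure_superpose(coords, idx)
    sub = coords[:, idx]
    dev = sub - sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


def cross_correlation(traj: Trajectory, selection: Optional[np.ndarray] = None,
                      superpose: bool = True) -> np.ndarray:
    """Dynamic cross-correlation map over the selection.

    Zero-variance atoms get a zero row/column (diagonal 1) with a warning.
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least two frames")
    idx = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    coords = traj.coords
    if superpose:
        coords = _mean_structure_superpose(coords, idx)
    sub = coords[:, idx]
    dev = sub - sub.mean(axis=0)                       # (F, S, 3)
    cov = np.einsum("fik,fjk->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        logger.warning("%d zero-variance atoms in DCCM selection", int(zero.sum()))
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    dccm = cov / denom
    if zero.any():
        dccm[zero, :] = 0.0
        dccm[:, zero] = 0.0
    np.fill_diagonal(dccm, 1.0)
    dccm = np.clip(dccm, -1.0, 1.0)
    return (dccm + dccm.T) / 2.0


def hbond_occupancy(traj: Trajectory, spec: HBondSpec) -> float:
    """Fraction of frames satisfying the H-bond geometric criterion.

    Distance between donor and acceptor heavy atoms must be <= the cutoff and,
    when an angle cutoff is given, the antecedent-donor-acceptor angle must be
    >= it. Raw (unsuperposed) coordinates are used: internal distances and
    angles are rigid-motion invariant.
    """
    di = traj.atom_index(*spec.donor)
    ai = traj.atom_index(*spec.acceptor)
    d_xyz = traj.coords[:, di]
    a_xyz = traj.coords[:, ai]
    dist = np.linalg.norm(d_xyz - a_xyz, axis=1)
    ok = dist <= spec.dist_cutoff
    if spec.angle_cutoff is not None:
        ti = traj.atom_index(*spec.antecedent)
        t_xyz = traj.coords[:, ti]
        v1 = t_xyz - d_xyz
        v2 = a_xyz - d_xyz
        num = np.sum(v1 * v2, axis=1)
        den = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        with np.errstate(invalid="ignore"):
            ang = np.degrees(np.arccos(np.clip(num / np.maximum(den, 1e-12), -1, 1)))
        ok &= ang >= spec.angle_cutoff
    return float(np.mean(ok))


def compute_stats(
    traj: Trajectory,
    selection: str = "name CA",
    exclude_residues: Sequence[Tuple[int, int]] = (),
    hbond_specs: Sequence[HBondSpec] = (),
    reference_frame: int = 0,
) -> TrajectoryStats:
    """All standard summary statistics for one trajectory."""
    idx = traj.select(selection, exclude_residues)
    if len(idx) == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    stats = TrajectoryStats(
        rmsd_series=rmsd_series(traj, reference_frame, idx),
        rmsf=rmsf(traj, idx),
        dccm=cross_correlation(traj, idx),
        selection_indices=idx,
    )
    for i, spec in enumerate(hbond_specs):
        label = spec.label or f"hbond_{i + 1}"
        stats.hbond_occupancy[label] = hbond_occupancy(traj, spec)
    return stats


# ---------------------------------------------------------------------------
# trajectory input
# ---------------------------------------------------------------------------

def read_trajectory_pdb(path: str, dt_ps: float = 0.0) -> Trajectory:
    """Multi-model PDB -> Trajectory (models are frames; atom order must match)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", path)
    frames = []
    meta = None
    for model in structure:
        coords, chains, resnums, resnames, names = [], [], [], [], []
        for chain in model:
            for res in chain:
                if res.id[0].strip():
                    continue
                for atom in res:
                    coords.append(atom.get_coord())
                    chains.append(chain.id)
                    resnums.append(res.id[1])
                    resnames.append(res.get_resname().strip())
                    names.append(atom.get_name())
        frames.append(np.asarray(coords, dtype=float))
        if meta is None:
            meta = (np.asarray(chains), np.asarray(resnums, dtype=int),
                    np.asarray(resnames), np.asarray(names))
    if not frames:
        raise ValueError(f"no models in {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("models differ in atom count; cannot form a trajectory")
    return Trajectory(coords=np.stack(frames), chains=meta[0], resnums=meta[1],
                      resnames=meta[2], atom_names=meta[3], dt_ps=dt_ps)


def read_trajectory_xyz(path: str, metadata: Optional[dict] = None,
                        dt_ps: float = 0.0) -> Trajectory:
    """Plain whitespace XYZ table -> Trajectory.

    Format: blank-line-separated frames, one ``x y z`` row per atom, with an
    optional leading header per frame giving the atom count. Metadata
    (chains/resnums/names) may be supplied; defaults are CA pseudo-atoms
    numbered 1..A on chain A.
    """
    frames: List[List[List[float]]] = []
    current: List[List[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                if current:
                    frames.append(current)
                    current = []
                continue
            if len(parts) == 1:          # per-frame atom-count header
                if current:
                    frames.append(current)
                    current = []
                continue
            current.append([float(parts[-3]), float(parts[-2]), float(parts[-1])])
    if current:
        frames.append(current)
    if not frames:
        raise ValueError(f"no frames in {path}")
    coords = np.asarray(frames, dtype=float)
    n_atoms = coords.shape[1]
    meta = metadata or {}
    return Trajectory(
        coords=coords,
        chains=np.asarray(meta.get("chains", ["A"] * n_atoms)),
        resnums=np.asarray(meta.get("resnums", np.arange(1, n_atoms + 1)), dtype=int),
        resnames=np.asarray(meta.get("resnames", ["GLY"] * n_atoms)),
        atom_names=np.asarray(meta.get("atom_names", ["CA"] * n_atoms)),
        dt_ps=dt_ps,
    )
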