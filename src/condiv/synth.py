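"""Synthetic-data generators with known ground truth.

Every analysis stage in this package is exercised against data whose true
structure is planted by construction: alignments with foreground-conserved
pattern columns, nested subfamily patterns and foreground-specific inserts;
trajectories with prescribed per-atom fluctuation amplitudes, inter-atom
displacement correlations and H-bond on/off occupancy; and minimal two-residue
structures placing an interaction atom pair at an exact distance.

Alignment columns draw from per-column Dirichlet backgrounds (concentration
0.5 by default, giving realistically skewed residue usage). Trajectory
displacements follow a zero-mean multivariate normal, under which RMSF and the
cross-correlation map have closed-form expectations, so recovery is exactly
falsifiable. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import AMINO_ACIDS, GAP
from .msa_io import LabeledAlignment
from .structmap import Residue, ResidueKey, StructureModel
from .trajstats import Trajectory

N_AA = len(AMINO_ACIDS)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class PlantedPattern:
    """A foreground-conserved pattern column.

    Sequences whose group label starts with ``group`` draw a pattern-set
    residue with probability ``conservation``; all other sequences draw one
    with probability ``bg_freq``; otherwise the column's background
    distribution applies.
    """

    column: int                  # 1-based
    residues: str                # pattern set, e.g. "E" or "DE"
    conservation: float = 0.95
    bg_freq: float = 0.05
    group: Optional[str] = None  # None -> the foreground label


@dataclass
class PlantedInsert:
    """A foreground-specific insert: fg occupied, bg gapped, per sequence."""

    start: int                   # 1-based inclusive
    end: int
    fg_occupancy: float = 0.95
    bg_gap_fraction: float = 0.98


@dataclass
class SyntheticAlignmentSpec:
    n_fg: int = 200
    n_bg: int = 600
    n_columns: int = 150
    fg_label: str = "CMGC/MAPK"
    bg_label: str = "CMGC/other"
    fg_sublabels: Sequence[str] = ()          # e.g. ("CMGC/MAPK/p38", "CMGC/MAPK/JNK")
    concentration: float = 0.5
    patterns: List[PlantedPattern] = field(default_factory=list)
    inserts: List[PlantedInsert] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        insert_cols = set()
        for ins in self.inserts:
            if not (1 <= ins.start <= ins.end <= self.n_columns):
                raise ValueError(f"insert [{ins.start},{ins.end}] outside alignment")
            if not (0 <= ins.fg_occupancy <= 1 and 0 <= ins.bg_gap_fraction <= 1):
                raise ValueError("insert occupancy/gap outside [0,1]")
            insert_cols.update(range(ins.start, ins.end + 1))
        for pat in self.patterns:
            if not (1 <= pat.column <= self.n_columns):
                raise ValueError(f"pattern column {pat.column} outside alignment")
            if not (0 <= pat.conservation <= 1 and 0 <= pat.bg_freq <= 1):
                raise ValueError("pattern conservation/frequency outside [0,1]")
            if pat.column in insert_cols:
                raise ValueError(
                    f"pattern column {pat.column} lies inside a planted insert interval"
                )
            if not pat.residues or any(r not in AMINO_ACIDS for r in pat.residues):
                raise ValueError(f"invalid pattern residue set {pat.residues!r}")


def gen_alignment(spec: SyntheticAlignmentSpec) -> Tuple[LabeledAlignment, dict]:
    """Generate a labeled alignment with planted contrast structure.

    Returns the alignment and a ground-truth dict recording exactly what was
    planted (pattern columns with their residue sets and levels, insert
    intervals, group sizes).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_fg + spec.n_bg
    L = spec.n_columns

    # per-column background residue distributions
    bg_dist = rng.dirichlet([spec.concentration] * N_AA, size=L)   # (L, 20)
    cdf = np.cumsum(bg_dist, axis=1)
    u = rng.random((n_total, L))
    mat = np.empty((n_total, L), dtype=np.intp)
    for col in range(L):
        mat[:, col] = np.searchsorted(cdf[col], u[:, col])
    mat = np.minimum(mat, N_AA - 1)

    # labels: fg (optionally split into subfamilies, round-robin) then bg
    labels: List[str] = []
    for i in range(spec.n_fg):
        if spec.fg_sublabels:
            labels.append(spec.fg_sublabels[i % len(spec.fg_sublabels)])
        else:
            labels.append(spec.fg_label)
    labels.extend([spec.bg_label] * spec.n_bg)
    labels_arr = np.asarray(labels)

    def members(prefix: str) -> np.ndarray:
        return np.array([
            lab == prefix or lab.startswith(prefix + "/") for lab in labels_arr
        ])

    # plant pattern columns; the stated levels are the TOTAL pattern-set
    # frequencies, so non-hits redraw from the background distribution
    # restricted to non-pattern residues
    for pat in spec.patterns:
        col = pat.column - 1
        codes = np.array([AMINO_ACIDS.index(r) for r in pat.residues])
        in_group = members(pat.group or spec.fg_label)
        prob = np.where(in_group, pat.conservation, pat.bg_freq)
        hit = rng.random(n_total) < prob
        choice = rng.integers(0, len(codes), size=n_total)
        mat[hit, col] = codes[choice[hit]]
        if len(codes) < N_AA:
            rest = bg_dist[col].copy()
            rest[codes] = 0.0
            rest /= rest.sum()
            rest_cdf = np.cumsum(rest)
            stray = (~hit) & np.isin(mat[:, col], codes)
            if stray.any():
                redraw = np.searchsorted(rest_cdf, rng.random(int(stray.sum())))
                mat[stray, col] = np.minimum(redraw, N_AA - 1)

    gap_mask = np.zeros((n_total, L), dtype=bool)
    is_fg = members(spec.fg_label)
    for ins in spec.inserts:
        sl = slice(ins.start - 1, ins.end)
        fg_present = rng.random(n_total) < ins.fg_occupancy
        bg_gapped = rng.random(n_total) < ins.bg_gap_fraction
        gap_here = np.where(is_fg, ~fg_present, bg_gapped)
        gap_mask[:, sl] |= gap_here[:, None]

    alphabet = np.array(list(AMINO_ACIDS + GAP))
    coded = np.where(gap_mask, N_AA, mat)
    records = []
    width = len(str(n_total))
    for i in range(n_total):
        sid = f"seq{i + 1:0{width}d}"
        records.append((sid, "".join(alphabet[coded[i]])))
    label_of = {sid: lab for (sid, _), lab in zip(records, labels)}

    truth = {
        "patterns": [
            {"column": p.column, "residues": p.residues,
             "conservation": p.conservation, "bg_freq": p.bg_freq,
             "group": p.group or spec.fg_label}
            for p in spec.patterns
        ],
        "inserts": [
            {"start": i.start, "end": i.end, "fg_occupancy": i.fg_occupancy,
             "bg_gap_fraction": i.bg_gap_fraction}
            for i in spec.inserts
        ],
        "fg_ids": [records[i][0] for i in range(n_total) if is_fg[i]],
        "bg_ids": [records[i][0] for i in range(n_total) if not is_fg[i]],
        "seed": spec.seed,
    }
    aln = LabeledAlignment(records=records, label_of=label_of, n_columns=L)
    return aln, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class CorrelationBlock:
    """Pairwise displacement correlation rho planted between the listed atoms."""

    atoms: Sequence[int]         # 0-based atom indices
    rho: float


@dataclass
class PlantedHBond:
    """A donor/acceptor pair toggled inside/outside the cutoff per frame."""

    donor: int                   # 0-based atom index
    acceptor: int
    occupancy: float = 0.9
    inside: float = 3.0          # Angstrom when the bond is formed
    outside: float = 4.5         # when broken


@dataclass
class SyntheticTrajSpec:
    reference: Optional[np.ndarray] = None     # (A, 3); default: spaced pseudo-CA chain
    n_atoms: int = 20
    n_frames: int = 1000
    sigmas: Optional[np.ndarray] = None        # per-atom isotropic amplitude, Angstrom
    blocks: List[CorrelationBlock] = field(default_factory=list)
    hbonds: List[PlantedHBond] = field(default_factory=list)
    rigid_motion: bool = False                 # add a random rigid transform per frame
    dt_ps: float = 4.0
    seed: int = 0


def _correlation_matrix(n: int, blocks: Sequence[CorrelationBlock]) -> np.ndarray:
    corr = np.eye(n)
    for blk in blocks:
        atoms = list(blk.atoms)
        for i in atoms:
            for j in atoms:
                if i != j:
                    corr[i, j] = blk.rho
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError(f"planted correlation matrix is not PSD (min eigenvalue {eig.min():.3g})")
    return corr


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def gen_trajectory(spec: SyntheticTrajSpec) -> Tuple[Trajectory, dict]:
    """Generate a trajectory with known fluctuation/correlation/occupancy truth.

    Displacements are drawn per coordinate axis from N(0, S) with
    S_ij = rho_ij * sigma_i * sigma_j, so atom i's RMSF is sigma_i * sqrt(3)
    and the displacement-vector correlation of atoms i, j is exactly rho_ij.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.reference is not None:
        ref = np.asarray(spec.reference, dtype=float)
    else:
        # extended pseudo-CA chain, 3.8 A spacing with mild curvature
        t = np.arange(spec.n_atoms)
        ref = np.stack([3.8 * t, 1.5 * np.sin(t / 3.0), 1.5 * np.cos(t / 5.0)], axis=1)
    n_atoms = ref.shape[0]
    if spec.n_frames < 2:
        raise ValueError("need at least two frames")

    sigmas = (np.full(n_atoms, 0.5) if spec.sigmas is None
              else np.asarray(spec.sigmas, dtype=float))
    if (sigmas < 0).any():
        raise ValueError("fluctuation amplitudes must be >= 0")
    corr = _correlation_matrix(n_atoms, spec.blocks)
    cov = corr * np.outer(sigmas, sigmas)
    # symmetric PSD square root (tolerates zero-amplitude atoms)
    w, v = np.linalg.eigh(cov)
    sqrt_cov = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T

    z = rng.normal(size=(spec.n_frames, 3, n_atoms))
    disp = np.einsum("ab,fkb->fka", sqrt_cov, z).transpose(0, 2, 1)  # (F, A, 3)
    coords = ref[None, :, :] + disp

    # plant H-bond pairs: acceptor placed at an exact distance from the donor
    hb_truth = []
    for hb in spec.hbonds:
        formed = rng.random(spec.n_frames) < hb.occupancy
        direction = np.array([1.0, 0.0, 0.0])
        dist = np.where(formed, hb.inside, hb.outside)
        coords[:, hb.acceptor] = coords[:, hb.donor] + direction * dist[:, None]
        hb_truth.append({
            "donor": hb.donor, "acceptor": hb.acceptor,
            "target_occupancy": hb.occupancy,
            "realized_occupancy": float(formed.mean()),
        })

    if spec.rigid_motion:
        for f in range(spec.n_frames):
            rot = _random_rotation(rng)
            trans = rng.normal(scale=5.0, size=3)
            coords[f] = coords[f] @ rot.T + trans

    traj = Trajectory(
        coords=coords,
        chains=np.asarray(["A"] * n_atoms),
        resnums=np.arange(1, n_atoms + 1),
        resnames=np.asarray(["GLY"] * n_atoms),
        atom_names=np.asarray(["CA"] * n_atoms),
        dt_ps=spec.dt_ps,
    )
    truth = {
        "sigmas": sigmas.tolist(),
        "rmsf_expected": (sigmas * np.sqrt(3.0)).tolist(),
        "correlation": corr.tolist(),
        "hbonds": hb_truth,
        "seed": spec.seed,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def make_toy_structure(kind: str, distance: float) -> StructureModel:
    """Minimal two-residue structure with one interaction pair at an exact
    distance and otherwise ideal geometry.

    kinds: ``salt_bridge`` (Arg NH1 vs Glu OE1), ``hbond`` (Ser OG donor with
    CB antecedent at 180 deg vs backbone O acceptor), ``ch_pi`` (Ala CB carbon
    vs Phe ring centroid).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    far = np.array([50.0, 50.0, 50.0])   # parks scaffold atoms away from the pair

    def res(chain, num, name, atoms):
        key = ResidueKey(chain=chain, resnum=num)
        return key, Residue(key=key, name=name,
                            atoms={k: np.asarray(v, dtype=float) for k, v in atoms.items()})

    if kind == "salt_bridge":
        k1, r1 = res("A", 1, "ARG", {
            "CA": far, "CZ": [-1.3, 0.0, 0.0], "NH1": [0.0, 0.0, 0.0],
        })
        k2, r2 = res("A", 10, "GLU", {
            "CA": far + 5.0, "CD": [distance + 1.3, 0.0, 0.0],
            "OE1": [distance, 0.0, 0.0],
        })
    elif kind == "hbond":
        k1, r1 = res("A", 1, "SER", {
            "CA": far, "CB": [-1.5, 0.0, 0.0], "OG": [0.0, 0.0, 0.0],
        })
        k2, r2 = res("A", 10, "GLY", {
            "CA": far + 5.0, "C": [distance + 1.2, 0.0, 0.0],
            "O": [distance, 0.0, 0.0],
        })
    elif kind == "ch_pi":
        # regular hexagon of radius 1.39 A in the yz-plane centred at origin
        ring = {}
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        for i, name in enumerate(ring_names):
            ang = 2 * np.pi * i / 6
            ring[name] = [0.0, 1.39 * np.cos(ang), 1.39 * np.sin(ang)]
        ring["CA"] = list(far)
        k2, r2 = res("A", 10, "PHE", ring)
        k1, r1 = res("A", 1, "ALA", {
            "CA": far + 5.0, "CB": [distance, 0.0, 0.0],
        })
    else:
        raise ValueError(f"unknown toy-structure kind {kind!r}")
    return StructureModel(residues={k1: r1, k2: r2}, name=f"toy_{kind}")


def write_pdb(model: StructureModel, path: str) -> None:
    """Write a StructureModel as a minimal single-model PDB file."""
    with open(path, "w") as fh:
        serial = 1
        for key in sorted(model.residues):
            r = model.residues[key]
            for aname, xyz in r.atoms.items():
                element = aname[0] if aname[0].isalpha() else aname[1]
                name4 = aname if len(aname) == 4 else f" {aname:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name4} {r.name:>3s} {key.chain}"
                    f"{key.resnum:4d}{key.icode or ' ':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")
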