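"""Structure reading, column-to-residue mapping, interaction detection and
region coupling.

Family-distinguishing alignment columns are mapped onto crystal-structure
residues through the reference row, then typed residue-residue interactions
(salt bridges, hydrogen bonds, van der Waals contacts, CH-pi) are detected by
standard geometric criteria and assembled into an undirected contact graph on
which connectivity between named structural regions (docking groove, C-tail,
alphaC helix, ...) can be tested.

All thresholds are geometric literature defaults and live in
:class:`condiv.config.RunConfig`; crystal structures rarely resolve hydrogens,
so the hydrogen-bond criterion uses heavy atoms only (donor-acceptor distance
plus the antecedent-donor-acceptor angle).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import DEFAULT_REGIONS, GAP
from .msa_io import LabeledAlignment, ReferenceNumbering

logger = logging.getLogger("condiv.structmap")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# positively charged side-chain nitrogens vs carboxylate oxygens
BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

# heavy-atom H-bond donors: atom -> antecedent (for the geometric angle)
DONORS = {
    ("*", "N"): "CA",
    ("ARG", "NE"): "CD", ("ARG", "NH1"): "CZ", ("ARG", "NH2"): "CZ",
    ("LYS", "NZ"): "CE",
    ("HIS", "ND1"): "CG", ("HIS", "NE2"): "CD2",
    ("ASN", "ND2"): "CG", ("GLN", "NE2"): "CD",
    ("SER", "OG"): "CB", ("THR", "OG1"): "CB",
    ("TYR", "OH"): "CZ", ("TRP", "NE1"): "CD1",
    ("CYS", "SG"): "CB",
}
ACCEPTORS = {
    ("*", "O"), ("*", "OXT"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}

AROMATIC_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class ResidueKey:
    chain: str
    resnum: int
    icode: str = ""

    def __str__(self):
        return f"{self.chain}:{self.resnum}{self.icode}"

    def __lt__(self, other):
        return (self.chain, self.resnum, self.icode) < (other.chain, other.resnum, other.icode)


@dataclass
class Residue:
    key: ResidueKey
    name: str                                  # three-letter code
    atoms: Dict[str, np.ndarray]               # atom name -> xyz (Angstrom)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureModel:
    """One model, one altloc, protein residues of a structure file."""

    residues: Dict[ResidueKey, Residue]
    name: str = ""

    def chain_residues(self, chain: str) -> List[Residue]:
        out = [r for k, r in self.residues.items() if k.chain == chain]
        out.sort(key=lambda r: (r.key.resnum, r.key.icode))
        return out

    def chain_sequence(self, chain: str) -> str:
        return "".join(r.one_letter for r in self.chain_residues(chain))

    def chains(self) -> List[str]:
        return sorted({k.chain for k in self.residues})


@dataclass
class InteractionRecord:
    """A typed residue-residue interaction with its defining geometry."""

    type: str                                   # salt_bridge | hbond | vdw | ch_pi
    res1: Tuple[str, int, str]                  # (chain, resnum, resname)
    res2: Tuple[str, int, str]
    atom1: str
    atom2: str
    distance: float
    geometry: Optional[float] = None            # hbond angle (deg) or ring-centroid distance

    def residue_pair(self):
        return frozenset((self.res1, self.res2))


class PDBFormatError(ValueError):
    pass


def read_structure(path: str, keep_ligands: bool = False, name: str = "") -> StructureModel:
    """Read a PDB file into a StructureModel.

    Only the first MODEL is kept; for alternate locations only blank or 'A'
    altlocs are retained (with a warning when others are dropped); HETATM
    records are excluded unless ``keep_ligands``. Parse failures report the
    offending line number.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(name or "model", path)
    except PDBConstructionException as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    except ValueError as exc:
        raise PDBFormatError(f"{path}: unparseable record: {exc}") from exc

    try:
        model = next(iter(structure))
    except StopIteration:
        raise PDBFormatError(f"{path}: no models found") from None

    residues: Dict[ResidueKey, Residue] = {}
    dropped_altloc = False
    for chain in model:
        for res in chain:
            hetflag, resnum, icode = res.id
            if hetflag.strip() and not keep_ligands:
                continue
            key = ResidueKey(chain=chain.id, resnum=resnum, icode=icode.strip())
            atoms: Dict[str, np.ndarray] = {}
            for atom in res:
                if atom.is_disordered():
                    selected = None
                    for alt in atom.disordered_get_list():
                        if alt.get_altloc() in (" ", "A"):
                            selected = alt
                            break
                    if selected is None:
                        dropped_altloc = True
                        continue
                    dropped_altloc = True
                    atom = selected
                coord = np.asarray(atom.get_coord(), dtype=float)
                if not np.isfinite(coord).all():
                    raise PDBFormatError(f"{path}: non-finite coordinates at atom {atom.get_full_id()}")
                atoms[atom.get_name()] = coord
            if atoms:
                residues[key] = Residue(key=key, name=res.get_resname().strip(), atoms=atoms)
    if dropped_altloc:
        logger.warning("%s: alternate locations other than 'A' discarded", path)
    if not residues:
        raise PDBFormatError(f"{path}: no residues parsed")
    return StructureModel(residues=residues, name=name or path)


# ---------------------------------------------------------------------------
# column -> structure mapping
# ---------------------------------------------------------------------------

def map_columns_to_structure(
    aln: LabeledAlignment,
    numbering: ReferenceNumbering,
    model: StructureModel,
    chain: str,
    min_identity: float = 0.30,
) -> Dict[int, Tuple[str, int]]:
    """Map master alignment columns to structure residues of one chain.

    The reference row (gaps removed) is globally aligned against the chain
    sequence (match +2, mismatch -1, gap open -5, extend -1); master columns
    then map through the reference numbering and this pairwise alignment.
    Unresolved chain residues simply stay unmapped. An alignment identity
    below ``min_identity`` (over aligned pairs) is rejected.
    """
    from Bio import Align

    ref_row = aln.sequence(numbering.ref_id)
    ref_seq = ref_row.replace(GAP, "")
    chain_res = model.chain_residues(chain)
    if not chain_res:
        raise KeyError(f"chain {chain!r} not in structure")
    chain_seq = "".join(r.one_letter for r in chain_res)

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    alignment = aligner.align(ref_seq, chain_seq)[0]

    # identity over aligned (non-gap vs non-gap) pairs
    aligned_ref, aligned_chain = alignment.aligned
    n_pairs = n_id = 0
    for (rs, re_), (cs, ce) in zip(aligned_ref, aligned_chain):
        for k in range(re_ - rs):
            n_pairs += 1
            if ref_seq[rs + k] == chain_seq[cs + k]:
                n_id += 1
    if n_pairs == 0 or n_id / n_pairs < min_identity:
        raise ValueError(
            f"reference does not match chain {chain!r}: identity "
            f"{(n_id / n_pairs if n_pairs else 0.0):.2f} below {min_identity:.2f}"
        )

    # reference residue index (0-based along ref_seq) -> chain residue index
    ref_to_chain: Dict[int, int] = {}
    for (rs, re_), (cs, ce) in zip(aligned_ref, aligned_chain):
        for k in range(re_ - rs):
            ref_to_chain[rs + k] = cs + k

    # master column -> ref residue ordinal (0-based) via the numbering map
    mapped_cols = sorted(numbering.col_to_refnum)
    out: Dict[int, Tuple[str, int]] = {}
    for ordinal, col in enumerate(mapped_cols):
        ci = ref_to_chain.get(ordinal)
        if ci is not None:
            out[col] = (chain, chain_res[ci].key.resnum)
    return out


# ---------------------------------------------------------------------------
# interaction detection
# ---------------------------------------------------------------------------

def _atom_table(model: StructureModel):
    """Flat arrays over all heavy atoms: coords + residue/atom metadata."""
    coords, keys, resnames, atomnames = [], [], [], []
    for key in sorted(model.residues):
        res = model.residues[key]
        for aname, xyz in res.atoms.items():
            if aname.startswith("H") or (len(aname) > 1 and aname[0].isdigit() and "H" in aname):
                continue
            coords.append(xyz)
            keys.append(key)
            resnames.append(res.name)
            atomnames.append(aname)
    return np.asarray(coords), keys, resnames, atomnames


def _seq_separated(k1: ResidueKey, k2: ResidueKey, min_sep: int) -> bool:
    if k1.chain != k2.chain:
        return True
    return abs(k1.resnum - k2.resnum) >= min_sep


def detect_interactions(
    model: StructureModel,
    types: Sequence[str] = ("salt_bridge", "hbond", "vdw", "ch_pi"),
    salt_bridge_cutoff: float = 4.0,
    hbond_dist_cutoff: float = 3.5,
    hbond_angle_cutoff: float = 120.0,
    vdw_cutoff: float = 4.5,
    ch_pi_cutoff: float = 4.5,
    min_seq_separation: int = 2,
) -> List[InteractionRecord]:
    """Detect typed residue-residue interactions by geometric criteria.

    salt_bridge: closest basic-N / carboxylate-O pair <= 4.0 A (one record per
    residue pair, at the minimum distance). hbond: donor-acceptor heavy atoms
    <= 3.5 A with antecedent-donor-acceptor angle >= 120 deg. vdw: any
    heavy-atom pair <= 4.5 A between residues >= 2 apart in sequence (one
    record per pair at minimum distance). ch_pi: carbon to aromatic ring
    centroid <= 4.5 A.
    """
    records: List[InteractionRecord] = []
    residues = [model.residues[k] for k in sorted(model.residues)]

    def restuple(res: Residue):
        return (res.key.chain, res.key.resnum, res.name)

    if "salt_bridge" in types:
        for r1 in residues:
            if r1.name not in BASIC_ATOMS:
                continue
            for r2 in residues:
                if r2.name not in ACIDIC_ATOMS or r1.key == r2.key:
                    continue
                best = None
                for a1 in BASIC_ATOMS[r1.name]:
                    if a1 not in r1.atoms:
                        continue
                    for a2 in ACIDIC_ATOMS[r2.name]:
                        if a2 not in r2.atoms:
                            continue
                        d = float(np.linalg.norm(r1.atoms[a1] - r2.atoms[a2]))
                        if best is None or d < best[0]:
                            best = (d, a1, a2)
                if best is not None and best[0] <= salt_bridge_cutoff:
                    records.append(InteractionRecord(
                        type="salt_bridge", res1=restuple(r1), res2=restuple(r2),
                        atom1=best[1], atom2=best[2], distance=best[0],
                    ))

    if "hbond" in types:
        for r1 in residues:          # donor residue
            donors = []
            for (rn, an), ante in DONORS.items():
                if rn in ("*", r1.name) and an in r1.atoms and ante in r1.atoms:
                    donors.append((an, ante))
            for r2 in residues:      # acceptor residue
                if r1.key == r2.key:
                    continue
                acceptors = [an for (rn, an) in ACCEPTORS
                             if rn in ("*", r2.name) and an in r2.atoms]
                for d_name, ante_name in donors:
                    for a_name in acceptors:
                        d_xyz, ante_xyz = r1.atoms[d_name], r1.atoms[ante_name]
                        a_xyz = r2.atoms[a_name]
                        dist = float(np.linalg.norm(d_xyz - a_xyz))
                        if dist > hbond_dist_cutoff or dist < 1e-6:
                            continue
                        v1 = ante_xyz - d_xyz
                        v2 = a_xyz - d_xyz
                        cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                        angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                        if angle >= hbond_angle_cutoff:
                            records.append(InteractionRecord(
                                type="hbond", res1=restuple(r1), res2=restuple(r2),
                                atom1=d_name, atom2=a_name,
                                distance=dist, geometry=angle,
                            ))

    if "vdw" in types:
        coords, keys, resnames, atomnames = _atom_table(model)
        if len(coords):
            tree = cKDTree(coords)
            best: Dict[frozenset, Tuple[float, int, int]] = {}
            for i, j in tree.query_pairs(vdw_cutoff):
                if keys[i] == keys[j] or not _seq_separated(keys[i], keys[j], min_seq_separation):
                    continue
                pair = frozenset((keys[i], keys[j]))
                d = float(np.linalg.norm(coords[i] - coords[j]))
                if pair not in best or d < best[pair][0]:
                    best[pair] = (d, i, j)
            for pair, (d, i, j) in sorted(best.items(), key=lambda kv: tuple(sorted(kv[0]))):
                ri, rj = model.residues[keys[i]], model.residues[keys[j]]
                records.append(InteractionRecord(
                    type="vdw", res1=restuple(ri), res2=restuple(rj),
                    atom1=atomnames[i], atom2=atomnames[j], distance=d,
                ))

    if "ch_pi" in types:
        for r2 in residues:          # ring residue
            ring = AROMATIC_RINGS.get(r2.name)
            if ring is None or not all(a in r2.atoms for a in ring):
                continue
            centroid = np.mean([r2.atoms[a] for a in ring], axis=0)
            for r1 in residues:
                if r1.key == r2.key:
                    continue
                best = None
                for aname, xyz in r1.atoms.items():
                    if not aname.startswith("C"):
                        continue
                    d = float(np.linalg.norm(xyz - centroid))
                    if best is None or d < best[0]:
                        best = (d, aname)
                if best is not None and best[0] <= ch_pi_cutoff:
                    records.append(InteractionRecord(
                        type="ch_pi", res1=restuple(r1), res2=restuple(r2),
                        atom1=best[1], atom2="ring_centroid",
                        distance=best[0], geometry=best[0],
                    ))
    return records


# ---------------------------------------------------------------------------
# contact graph and region coupling
# ---------------------------------------------------------------------------

@dataclass
class ContactGraph:
    """Undirected residue graph with named region node sets."""

    graph: nx.Graph
    regions: Dict[str, List] = field(default_factory=dict)


def build_contact_graph(
    records: List[InteractionRecord],
    regions: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    chain: Optional[str] = None,
    restrict_to: Optional[Sequence[int]] = None,
) -> ContactGraph:
    """Assemble interactions into a contact graph.

    ``regions`` maps a region name to residue-number intervals (inclusive,
    reference numbering); nodes are (chain, resnum) pairs. ``restrict_to``
    keeps only the listed residue numbers (e.g. family-specific pattern
    residues plus a segment of interest).
    """
    g = nx.Graph()
    for rec in records:
        n1 = (rec.res1[0], rec.res1[1])
        n2 = (rec.res2[0], rec.res2[1])
        if restrict_to is not None and (n1[1] not in restrict_to or n2[1] not in restrict_to):
            continue
        if n1 == n2:
            continue
        g.add_edge(n1, n2, type=rec.type, distance=rec.distance)

    named: Dict[str, List] = {}
    if regions:
        for name, intervals in regions.items():
            members = []
            for node in g.nodes:
                ch, num = node
                if chain is not None and ch != chain:
                    continue
                if any(lo <= num <= hi for lo, hi in intervals):
                    members.append(node)
            named[name] = sorted(members)
    return ContactGraph(graph=g, regions=named)


def coupling_path(
    cg: ContactGraph, source_region: str, target_region: str
) -> Optional[List]:
    """Shortest path (fewest edges) between two named regions, or None.

    Ties are broken lexicographically over residue identifiers so the result
    is deterministic; returns None when the regions are disconnected.
    """
    for name in (source_region, target_region):
        if name not in cg.regions:
            raise KeyError(f"unknown region {name!r}")
    sources = [n for n in cg.regions[source_region] if n in cg.graph]
    targets = {n for n in cg.regions[target_region] if n in cg.graph}
    if not sources or not targets:
        return None

    # multi-source BFS with sorted expansion for deterministic tie-breaks
    from collections import deque

    parent = {}
    queue = deque()
    for s in sorted(sources):
        parent[s] = None
        queue.append(s)
    while queue:
        node = queue.popleft()
        if node in targets:
            path = []
            while node is not None:
                path.append(node)
                node = parent[node]
            return list(reversed(path))
        for nb in sorted(cg.graph.neighbors(node)):
            if nb not in parent:
                parent[nb] = node
                queue.append(nb)
    return None


def default_regions() -> Dict[str, List[Tuple[int, int]]]:
    """The shipped named-region map (reference numbering, p38-alpha convention)."""
    return {k: list(v) for k, v in DEFAULT_REGIONS.items()}
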