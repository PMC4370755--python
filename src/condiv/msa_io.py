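"""Alignment I/O, reference numbering and the hierarchical group tree.

The master multiple sequence alignment is read from aligned FASTA; group
membership (e.g. ``CMGC/MAPK/p38``) comes from a two-column TSV. All column
and residue numbering is 1-based with inclusive intervals, matching the
p38-alpha residue citation convention used throughout the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import AMINO_ACIDS, GAP, GAP_CODE, NONSTANDARD, UNKNOWN, UNKNOWN_CODE

logger = logging.getLogger("condiv.msa_io")

ROOT_LABEL = ""

_CODE_OF = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE_OF[GAP] = GAP_CODE
_CODE_OF[UNKNOWN] = UNKNOWN_CODE


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments or malformed label tables."""


@dataclass
class LabeledAlignment:
    """An aligned sequence set with hierarchical group labels.

    records hold ``(seq_id, aligned_seq)`` pairs over the 20 standard residues
    plus ``-`` (gap) and ``X`` (unknown); ``label_of`` maps each seq_id to a
    slash-separated group path. Unlabeled sequences carry the root label ``""``.
    """

    records: List[Tuple[str, str]]
    label_of: Dict[str, str]
    n_columns: int
    _matrix: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        seen = set()
        for seq_id, seq in self.records:
            if seq_id in seen:
                raise AlignmentFormatError(f"duplicate sequence id: {seq_id}")
            seen.add(seq_id)
            if len(seq) != self.n_columns:
                raise AlignmentFormatError(
                    f"sequence {seq_id!r} has length {len(seq)}, expected {self.n_columns}"
                )
            bad = set(seq) - set(_CODE_OF)
            if bad:
                raise AlignmentFormatError(
                    f"sequence {seq_id!r} contains invalid characters {sorted(bad)}"
                )
        if self.n_columns < 1:
            raise AlignmentFormatError("alignment must have at least one column")
        for seq_id in seen:
            self.label_of.setdefault(seq_id, ROOT_LABEL)

    @property
    def seq_ids(self) -> List[str]:
        return [sid for sid, _ in self.records]

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def sequence(self, seq_id: str) -> str:
        for sid, seq in self.records:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def matrix(self) -> np.ndarray:
        """Integer-coded (n_sequences, n_columns) view; cached."""
        if self._matrix is None:
            mat = np.empty((len(self.records), self.n_columns), dtype=np.uint8)
            for i, (_, seq) in enumerate(self.records):
                mat[i] = [_CODE_OF[c] for c in seq]
            self._matrix = mat
        return self._matrix

    def index_of(self, seq_ids) -> np.ndarray:
        pos = {sid: i for i, (sid, _) in enumerate(self.records)}
        return np.array([pos[s] for s in seq_ids], dtype=np.intp)

    def members_of(self, label_prefix: str) -> List[str]:
        """Sequence ids whose label path starts with the given prefix."""
        if label_prefix == ROOT_LABEL:
            return self.seq_ids
        out = []
        for sid in self.seq_ids:
            lab = self.label_of[sid]
            if lab == label_prefix or lab.startswith(label_prefix + "/"):
                out.append(sid)
        return out


@dataclass
class ReferenceNumbering:
    """Master-column to reference-residue-number map.

    Exactly the non-gap columns of the reference row are mapped; numbers run
    consecutively from ``first_residue``. Columns and numbers are 1-based.
    """

    ref_id: str
    col_to_refnum: Dict[int, int]

    def refnum(self, column: int) -> Optional[int]:
        return self.col_to_refnum.get(column)

    def column_of(self, refnum: int) -> Optional[int]:
        for col, num in self.col_to_refnum.items():
            if num == refnum:
                return col
        return None


@dataclass
class TreeNode:
    name: str                      # group path prefix; "" at the root
    members: List[str]
    children: List["TreeNode"] = field(default_factory=list)


@dataclass
class HyperpartitionTree:
    """Rooted tree of group-path prefixes; each node's member set is the
    sequences whose label has that prefix. Children partition subsets of the
    parent."""

    root: TreeNode

    def nodes(self) -> List[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def node(self, name: str) -> TreeNode:
        for n in self.nodes():
            if n.name == name:
                return n
        raise KeyError(name)


def _normalize_seq(seq: str, seq_id: str) -> str:
    out = []
    warned = False
    for c in seq.upper().replace(".", GAP):
        if c in _CODE_OF:
            out.append(c)
        elif c in NONSTANDARD:
            if not warned:
                logger.warning("non-standard residue %r in %s mapped to X", c, seq_id)
                warned = True
            out.append(UNKNOWN)
        else:
            raise AlignmentFormatError(f"invalid character {c!r} in sequence {seq_id!r}")
    return "".join(out)


def read_labels(path: str) -> Dict[str, str]:
    """Two-column TSV ``seq_id<TAB>group/path``."""
    labels: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentFormatError(
                    f"{path}:{lineno}: expected 'seq_id<TAB>group/path', got {line!r}"
                )
            labels[parts[0]] = parts[1].strip("/")
    return labels


def read_alignment(path: str, label_path: Optional[str] = None) -> LabeledAlignment:
    """Read an aligned FASTA plus optional label TSV into a LabeledAlignment.

    ``.`` gaps and lowercase are normalised; non-standard residues map to X.
    Ragged records and labels naming unknown sequences are errors; unlabeled
    sequences fall to the root group with a warning.
    """
    records: List[Tuple[str, str]] = []
    n_columns = None
    for rec in SeqIO.parse(path, "fasta"):
        seq = _normalize_seq(str(rec.seq), rec.id)
        if n_columns is None:
            n_columns = len(seq)
        elif len(seq) != n_columns:
            raise AlignmentFormatError(
                f"ragged alignment: sequence {rec.id!r} has length {len(seq)}, "
                f"expected {n_columns}"
            )
        records.append((rec.id, seq))
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")

    labels: Dict[str, str] = {}
    if label_path is not None:
        labels = read_labels(label_path)
        ids = {sid for sid, _ in records}
        unknown = set(labels) - ids
        if unknown:
            raise AlignmentFormatError(
                f"label table names unknown sequence ids: {sorted(unknown)[:5]}"
            )
        unlabeled = ids - set(labels)
        if unlabeled:
            logger.warning("%d sequences unlabeled; assigned to root group", len(unlabeled))
    return LabeledAlignment(records=records, label_of=labels, n_columns=n_columns)


def write_alignment(aln: LabeledAlignment, path: str, label_path: Optional[str] = None) -> None:
    """Write aligned FASTA (and labels TSV if requested); inverse of read_alignment."""
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records]
    SeqIO.write(recs, path, "fasta")
    if label_path is not None:
        with open(label_path, "w") as fh:
            for sid, _ in aln.records:
                fh.write(f"{sid}\t{aln.label_of[sid]}\n")


def make_reference_numbering(
    aln: LabeledAlignment, ref_id: str, first_residue: int = 1
) -> ReferenceNumbering:
    """Number the non-gap columns of the reference row consecutively.

    ``first_residue`` sets the number of the reference's first residue, so the
    map can match any published construct numbering.
    """
    try:
        ref_seq = aln.sequence(ref_id)
    except KeyError:
        raise KeyError(f"reference id {ref_id!r} not in alignment") from None
    col_to_refnum: Dict[int, int] = {}
    num = first_residue
    for col, c in enumerate(ref_seq, start=1):
        if c != GAP:
            col_to_refnum[col] = num
            num += 1
    if not col_to_refnum:
        raise ValueError("reference has no residues (all-gap row)")
    return ReferenceNumbering(ref_id=ref_id, col_to_refnum=col_to_refnum)


def write_reference_numbering(numbering: ReferenceNumbering, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("column\trefnum\n")
        for col in sorted(numbering.col_to_refnum):
            fh.write(f"{col}\t{numbering.col_to_refnum[col]}\n")


def build_hyperpartition(aln: LabeledAlignment) -> HyperpartitionTree:
    """Build the rooted tree of all distinct label-path prefixes.

    A degenerate single-label input yields a root-only tree (a node is only
    created for prefixes that actually split the data below the root).
    """
    prefixes = set()
    for sid in aln.seq_ids:
        label = aln.label_of[sid]
        if label == ROOT_LABEL:
            continue
        parts = label.split("/")
        for i in range(1, len(parts) + 1):
            prefixes.add("/".join(parts[:i]))

    root = TreeNode(name=ROOT_LABEL, members=list(aln.seq_ids))
    by_name = {ROOT_LABEL: root}
    for prefix in sorted(prefixes, key=lambda p: (p.count("/"), p)):
        members = aln.members_of(prefix)
        parent_name = "/".join(prefix.split("/")[:-1])
        while parent_name and parent_name not in by_name:
            parent_name = "/".join(parent_name.split("/")[:-1])
        parent = by_name[parent_name]
        # a prefix that does not split its parent adds no contrast; collapse it
        if set(members) == set(parent.members):
            by_name[prefix] = parent
            continue
        node = TreeNode(name=prefix, members=members)
        parent.children.append(node)
        by_name[prefix] = node
    return HyperpartitionTree(root=root)
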