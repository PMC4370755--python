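"""Scanner for the MAPK D-domain docking consensus motif.

MAPK substrates and effectors dock via a linear motif of the form
psi(1-3) X(3-7) phi-X-phi: a short run of positively charged residues, an
intervening spacer of any residues, then a hydrophobic-X-hydrophobic triplet.
Residue classes default to psi = {K, R} and phi = {L, I, V, F, M} and are
configurable, since the consensus defines the classes chemically rather than
as fixed residue sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List

from .config import PHI_RESIDUES, PSI_RESIDUES


@dataclass
class DMotifMatch:
    """One docking-motif occurrence (1-based inclusive coordinates)."""

    start: int
    end: int
    basic_run: int            # psi run length b, 1..3
    spacer: int               # spacer length x, 3..7
    phi_positions: tuple      # 1-based positions of the three triplet residues

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def scan_d_motif(
    seq: str,
    psi: str = PSI_RESIDUES,
    phi: str = PHI_RESIDUES,
    min_basic: int = 1,
    max_basic: int = 3,
    min_spacer: int = 3,
    max_spacer: int = 7,
) -> List[DMotifMatch]:
    """Find all docking-motif matches in an unaligned protein sequence.

    Overlapping start positions are reported, but each start contributes only
    its leftmost-longest parse (longest total span; ties resolved toward the
    longer basic run), and a parse whose hydrophobic triplet is already
    claimed by an earlier, longer match is folded into it — so a run of two
    arginines yields one match, not two, while distinct motif occurrences
    that overlap are all kept.
    """
    seq = seq.upper()
    psi_set, phi_set = set(psi), set(phi)
    n = len(seq)
    matches: List[DMotifMatch] = []
    for start in range(n):
        if seq[start] not in psi_set:
            continue
        best = None
        for b in range(min_basic, max_basic + 1):
            if start + b > n or any(seq[start + i] not in psi_set for i in range(b)):
                break
            for x in range(min_spacer, max_spacer + 1):
                t = start + b + x       # 0-based index of first triplet residue
                if t + 2 >= n:
                    break
                if seq[t] in phi_set and seq[t + 2] in phi_set:
                    key = (b + x + 3, b)
                    if best is None or key > best[0]:
                        best = (key, b, x, t)
        if best is not None:
            _, b, x, t = best
            matches.append(DMotifMatch(
                start=start + 1,
                end=t + 3,
                basic_run=b,
                spacer=x,
                phi_positions=(t + 1, t + 2, t + 3),
            ))
    # fold sub-parses of one occurrence (same triplet, later start) into the
    # earlier, longer match
    kept: List[DMotifMatch] = []
    claimed = set()
    for m in matches:
        if m.phi_positions in claimed:
            continue
        claimed.add(m.phi_positions)
        kept.append(m)
    return kept


def d_motif_regex(
    psi: str = PSI_RESIDUES,
    phi: str = PHI_RESIDUES,
    min_basic: int = 1,
    max_basic: int = 3,
    min_spacer: int = 3,
    max_spacer: int = 7,
) -> re.Pattern:
    """Equivalent regular expression for the consensus (validation helper)."""
    return re.compile(
        f"[{psi}]{{{min_basic},{max_basic}}}"
        f".{{{min_spacer},{max_spacer}}}"
        f"[{phi}].[{phi}]"
    )
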