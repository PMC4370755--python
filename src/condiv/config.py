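"""Run configuration and numeric defaults.

Every threshold used anywhere in the pipeline lives here, so a manifest that
records a ``RunConfig`` suffices to reproduce a run. Distance cutoffs are in
Angstrom, angles in degrees.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

logger = logging.getLogger("condiv")

#: Canonical residue order used for all index-coded alignments and profiles.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
#: Integer codes: 0..19 residues, 20 gap, 21 unknown.
GAP_CODE = 20
UNKNOWN_CODE = 21

# Non-standard one-letter codes normalised to 'X' on input.
NONSTANDARD = set("BZUOJ*")

#: Default residue classes for the docking (D-) motif consensus psi(1-3) X(3-7) phi-X-phi.
#: psi = positively charged (His excluded: often uncharged at physiological pH),
#: phi = hydrophobic. Both are configurable in scan_d_motif.
PSI_RESIDUES = "KR"
PHI_RESIDUES = "LIVFM"

#: Named structural regions of the MAPK kinase domain in p38-alpha numbering.
#: docking_groove = alphaD-alphaE linker; CD = common docking site in the C-tail.
DEFAULT_REGIONS = {
    "docking_groove": [(119, 134)],
    "alphaE": [(124, 144)],
    "beta7_beta8": [(159, 163)],
    "CD_site": [(313, 316)],
    "alphaC": [(59, 78)],
    "C_tail": [(310, 356)],
}


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults are the package's standard operating values; any YAML config or
    CLI flag simply overrides fields here.
    """

    # inputs
    alignment: Optional[str] = None
    labels: Optional[str] = None
    ref_id: Optional[str] = None
    first_residue: int = 1
    pdb: Optional[str] = None
    chain: Optional[str] = None
    trajectory: Optional[str] = None
    out_dir: str = "condiv_out"

    # contrast scoring
    alpha: float = 0.05                 # Bonferroni family-wise level
    top_k: Optional[int] = None         # overrides alpha-based cut when set
    min_fg_coverage: float = 0.5        # fraction non-gap fg weight needed to score a column

    # insert detection
    insert_min_len: int = 2
    insert_occ_min: float = 0.5         # fg non-gap occupancy
    insert_gap_min: float = 0.9         # bg gap fraction
    insert_merge_gap: int = 2           # runs closer than this many columns are merged

    # structural interaction thresholds (Angstrom / degrees)
    salt_bridge_cutoff: float = 4.0
    hbond_dist_cutoff: float = 3.5
    hbond_angle_cutoff: float = 120.0
    vdw_cutoff: float = 4.5
    ch_pi_cutoff: float = 4.5
    min_seq_separation: int = 2         # residue separation for vdw contacts
    keep_ligands: bool = False

    # trajectory analysis
    selection: str = "name CA"
    exclude_residues: list = field(default_factory=list)  # [(start, end)] ranges

    # randomness
    seed: int = 0

    def rng(self) -> np.random.Generator:
        """The single seeded RNG behind all stochastic operations."""
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        for name in ("salt_bridge_cutoff", "hbond_dist_cutoff", "vdw_cutoff",
                     "ch_pi_cutoff", "hbond_angle_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.insert_occ_min <= 1 and 0 <= self.insert_gap_min <= 1):
            raise ValueError("insert occupancy/gap thresholds must be in [0,1]")
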