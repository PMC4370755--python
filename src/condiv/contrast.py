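"""Foreground/background contrast scoring of alignment columns.

The divergence of a family (foreground) from its relatives (background) is
quantified per alignment column with a ball-in-urn law: pool the weighted
residue counts of both sets into one urn, draw the foreground-sized sample
without replacement, and ask how surprising the observed count of
pattern-matching residues is. Formally, with T = N_F + N_B pooled residues of
which K = k_F + k_B match the pattern set R, the column p-value is

    p = P(X >= k_F),  X ~ Hypergeometric(T, K, N_F)

computed in log space. Sequence redundancy is corrected by Henikoff
position-based weights before counting, so weighted frequencies reflect
diversity rather than database sampling. Pattern sets are grown greedily per
column; significant columns ("pattern positions") are ranked by p-value.

Foreground-specific insert segments — column runs occupied in the foreground
but gapped in the background — are detected separately, with the same
ball-in-urn score applied to gap-vs-residue counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .config import AMINO_ACIDS, GAP_CODE, UNKNOWN_CODE
from .msa_io import HyperpartitionTree, LabeledAlignment

logger = logging.getLogger("condiv.contrast")

N_AA = len(AMINO_ACIDS)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# sequence weighting
# ---------------------------------------------------------------------------

@dataclass
class SequenceWeights:
    """Positive per-sequence weights, rescaled so the mean weight is 1."""

    weight_of: Dict[str, float]

    def vector(self, seq_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.weight_of[s] for s in seq_ids], dtype=float)


def henikoff_weights(aln: LabeledAlignment) -> SequenceWeights:
    """Position-based sequence weights (Henikoff & Henikoff 1994).

    In a column with r distinct residue types, a sequence showing residue a
    (which occurs s_a times) contributes 1/(r * s_a); gaps and X contribute
    nothing. A sequence's raw weight is the mean contribution over its own
    non-gap columns; weights are rescaled to mean 1 over the alignment.

    Weights are computed on the unique rows of the alignment, then each unique
    row's weight is split equally among its identical copies. This makes the
    scheme exactly invariant under sequence duplication: adding copies of a
    sequence redistributes its mass but leaves every weighted column frequency
    unchanged.
    """
    full = aln.matrix()
    n_seq = full.shape[0]
    mat, inverse, mult = np.unique(full, axis=0, return_inverse=True, return_counts=True)
    n_col = mat.shape[1]
    contrib = np.zeros_like(mat, dtype=float)
    for col in range(n_col):
        codes = mat[:, col]
        counts = np.bincount(codes, minlength=UNKNOWN_CODE + 1)[:N_AA]
        present = counts > 0
        r = int(present.sum())
        if r == 0:
            continue
        weight_per_code = np.zeros(UNKNOWN_CODE + 1)
        weight_per_code[:N_AA][present] = 1.0 / (r * counts[present])
        contrib[:, col] = weight_per_code[codes]

    residue_mask = mat < N_AA
    n_residues = residue_mask.sum(axis=1)
    if not n_residues.any():
        raise ValueError("all-gap alignment: cannot weight")
    with np.errstate(invalid="ignore"):
        raw = np.where(n_residues > 0, contrib.sum(axis=1) / np.maximum(n_residues, 1), 0.0)
    # an all-gap row carries no information; give it the minimum positive weight
    if (raw <= 0).any():
        floor = raw[raw > 0].min() if (raw > 0).any() else 1.0
        raw = np.where(raw > 0, raw, floor)
    per_seq = raw[inverse] / mult[inverse]     # split mass among identical copies
    weights = per_seq * (n_seq / per_seq.sum())
    return SequenceWeights(weight_of=dict(zip(aln.seq_ids, weights)))


# ---------------------------------------------------------------------------
# weighted column profiles
# ---------------------------------------------------------------------------

@dataclass
class ColumnProfile:
    """Weighted residue/gap counts per column over a sequence subset.

    counts: (n_columns, 20); gap_count: (n_columns,); effective total
    N = counts.sum(axis=1) excludes both gaps and X.
    """

    counts: np.ndarray
    gap_count: np.ndarray
    unknown_count: np.ndarray
    total_weight: float

    @property
    def n_columns(self) -> int:
        return self.counts.shape[0]

    @property
    def effective_n(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def frequencies(self) -> np.ndarray:
        n = self.effective_n[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.counts / n, 0.0)


def weighted_profile(
    aln: LabeledAlignment, w: SequenceWeights, subset: Sequence[str]
) -> ColumnProfile:
    """Weighted per-column residue and gap counts over a sequence subset."""
    subset = list(subset)
    if not subset:
        raise ValueError("empty sequence subset")
    idx = aln.index_of(subset)
    mat = aln.matrix()[idx]
    wv = w.vector(subset)
    n_col = aln.n_columns
    counts = np.zeros((n_col, N_AA))
    for code in range(N_AA):
        counts[:, code] = wv @ (mat == code)
    gap_count = wv @ (mat == GAP_CODE)
    unknown_count = wv @ (mat == UNKNOWN_CODE)
    return ColumnProfile(
        counts=counts, gap_count=gap_count, unknown_count=unknown_count,
        total_weight=float(wv.sum()),
    )


def freq_to_tenths(freq: float) -> int:
    """Display a frequency as a single integer tenth digit.

    floor(freq*10) clamped to 9, so 0.65 -> 6 (60-70%) and 1.0 -> 9.
    """
    if not (0.0 <= freq <= 1.0):
        raise ValueError(f"frequency {freq} outside [0, 1]")
    return min(int(freq * 10), 9)


# ---------------------------------------------------------------------------
# ball-in-urn column score
# ---------------------------------------------------------------------------

def ball_in_urn_pvalue(k_F: float, N_F: float, k_B: float, N_B: float) -> float:
    """Upper-tail hypergeometric probability of the foreground match count.

    Weighted counts are rounded to the nearest integers (preserving k <= N);
    with T = N_F + N_B balls, K = k_F + k_B of them red, and N_F drawn without
    replacement, returns P(X >= k_F). Computed via log-gamma and logsumexp for
    numerical stability at large counts.
    """
    if min(k_F, N_F, k_B, N_B) < 0:
        raise ValueError("negative counts")
    if k_F > N_F or k_B > N_B:
        raise ValueError("k exceeds N")
    if N_F + N_B <= 0:
        raise ValueError("empty urn")
    kf = int(round(k_F))
    nf = int(round(N_F))
    kb = int(round(k_B))
    nb = int(round(N_B))
    kf = min(kf, nf)
    kb = min(kb, nb)
    T = nf + nb
    K = kf + kb
    if T == 0:
        raise ValueError("empty urn after rounding")
    if kf <= max(0, K - nb):
        return 1.0  # the observed count is the guaranteed minimum (or below)
    hi = min(K, nf)
    x = np.arange(kf, hi + 1)
    log_pmf = (
        _log_comb(K, x)
        + _log_comb(T - K, nf - x)
        - _log_comb(T, nf)
    )
    return float(min(1.0, math.exp(logsumexp(log_pmf))))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# pattern selection
# ---------------------------------------------------------------------------

@dataclass
class PatternColumn:
    """One scored alignment column: its pattern residue set and contrast.

    ``p_value`` is selection-adjusted: the raw ball-in-urn tail probability of
    the chosen set, Bonferroni-multiplied by the number of nonempty residue
    sets of size up to |R|, sum_j<=|R| C(20, j). The raw tail probability
    refers to one fixed, pre-specified set; the search picks the best set
    among those it could reach, so the adjusted value is what admits a valid
    significance cut, and the size-dependent penalty prefers compact conserved
    patterns over sprawling complement sets. ``p_raw`` keeps the unadjusted
    tail.
    """

    column: int                       # 1-based master column
    pattern_set: FrozenSet[str]
    k_F: float
    N_F: float
    k_B: float
    N_B: float
    p_value: float
    p_raw: float = 1.0

    @property
    def height(self) -> float:
        """Histogram height: -log10 of the adjusted p."""
        return -math.log10(self.p_value) if self.p_value > 0 else math.inf


def select_pattern(
    column: int,
    fg: ColumnProfile,
    bg: ColumnProfile,
    min_fg_coverage: float = 0.5,
) -> Optional[PatternColumn]:
    """Greedy pattern-set search for one column.

    Seeds the set with the foreground-majority residue, then repeatedly adds
    the residue (among those more frequent in the foreground than the
    background) whose inclusion most decreases the selection-adjusted
    p-value — the ball-in-urn tail multiplied by the number of pattern sets
    of size up to |R| — stopping when no addition helps. The adjustment
    charges the search for every set it could have picked, which keeps the
    reported significance honest under the null and stops the set from
    absorbing weakly-enriched residues. Ties break alphabetically,
    making the search deterministic. Columns whose foreground effective
    coverage is below ``min_fg_coverage`` are not scored (returns None).
    """
    i = column - 1
    fg_counts = fg.counts[i]
    bg_counts = bg.counts[i]
    n_f = float(fg_counts.sum())
    n_b = float(bg_counts.sum())
    fg_total = n_f + float(fg.gap_count[i]) + float(fg.unknown_count[i])
    if fg_total <= 0 or n_f / fg_total < min_fg_coverage or n_f == 0:
        return None

    fg_freq = fg_counts / n_f
    bg_freq = bg_counts / n_b if n_b > 0 else np.zeros(N_AA)

    # seed: foreground-majority residue, alphabetical tie-break
    seed = int(np.lexsort((np.arange(N_AA), -fg_freq))[0])
    chosen = [seed]
    candidates = [
        a for a in range(N_AA)
        if a != seed and fg_freq[a] > bg_freq[a] and fg_counts[a] > 0
    ]

    def raw_pval(residues: List[int]) -> float:
        kf = float(fg_counts[residues].sum())
        kb = float(bg_counts[residues].sum())
        return ball_in_urn_pvalue(kf, n_f, kb, n_b)

    def adjusted(p: float, size: int) -> float:
        return p * sum(math.comb(N_AA, j) for j in range(1, size + 1))

    best_raw = raw_pval(chosen)
    best_adj = adjusted(best_raw, len(chosen))
    while candidates:
        trial = [(raw_pval(chosen + [a]), a) for a in candidates]
        trial.sort()
        p_new, a_new = trial[0]
        adj_new = adjusted(p_new, len(chosen) + 1)
        if adj_new < best_adj:
            chosen.append(a_new)
            candidates.remove(a_new)
            best_raw, best_adj = p_new, adj_new
        else:
            break

    kf = float(fg_counts[chosen].sum())
    kb = float(bg_counts[chosen].sum())
    return PatternColumn(
        column=column,
        pattern_set=frozenset(AMINO_ACIDS[a] for a in chosen),
        k_F=kf, N_F=n_f, k_B=kb, N_B=n_b,
        p_value=min(1.0, best_adj),
        p_raw=best_raw,
    )


@dataclass
class ContrastResult:
    """Scored columns for one foreground/background contrast."""

    node_name: str
    columns: List[PatternColumn]
    ranked_positions: List[int]       # the display "black dots", best first
    threshold: float                  # per-column p cut actually applied
    alpha: float
    n_eligible: int

    def column_result(self, column: int) -> Optional[PatternColumn]:
        for pc in self.columns:
            if pc.column == column:
                return pc
        return None


def score_contrast(
    aln: LabeledAlignment,
    w: SequenceWeights,
    foreground: Sequence[str],
    background: Sequence[str],
    alpha: float = 0.05,
    top_k: Optional[int] = None,
    min_fg_coverage: float = 0.5,
    node_name: str = "",
) -> ContrastResult:
    """Score every eligible column of a foreground/background partition.

    Ranked pattern positions are the columns surviving a Bonferroni cut at
    family-wise level ``alpha`` over the eligible columns (or, with ``top_k``,
    simply the best k columns), sorted by ascending p-value with column-index
    tie-break.
    """
    fg_set, bg_set = set(foreground), set(background)
    if not fg_set or not bg_set:
        raise ValueError("foreground and background must be nonempty")
    if fg_set & bg_set:
        raise ValueError(f"foreground and background overlap: {sorted(fg_set & bg_set)[:5]}")

    fg_prof = weighted_profile(aln, w, sorted(fg_set))
    bg_prof = weighted_profile(aln, w, sorted(bg_set))

    columns: List[PatternColumn] = []
    for col in range(1, aln.n_columns + 1):
        pc = select_pattern(col, fg_prof, bg_prof, min_fg_coverage=min_fg_coverage)
        if pc is not None:
            columns.append(pc)

    n_eligible = len(columns)
    order = sorted(columns, key=lambda pc: (pc.p_value, pc.column))
    if top_k is not None:
        ranked = [pc.column for pc in order[:top_k]]
        threshold = order[min(top_k, len(order)) - 1].p_value if order else 0.0
    else:
        threshold = alpha / n_eligible if n_eligible else 0.0
        ranked = [pc.column for pc in order if pc.p_value <= threshold]
    return ContrastResult(
        node_name=node_name, columns=columns, ranked_positions=ranked,
        threshold=threshold, alpha=alpha, n_eligible=n_eligible,
    )


def subfamily_contrasts(
    aln: LabeledAlignment,
    w: SequenceWeights,
    tree: HyperpartitionTree,
    alpha: float = 0.05,
    top_k: Optional[int] = None,
    min_fg_coverage: float = 0.5,
    exclusive: bool = True,
    min_pattern_conservation: float = 0.7,
    max_pattern_bg_frequency: float = 0.3,
) -> Dict[str, ContrastResult]:
    """Contrast every non-root tree node against its within-parent complement.

    For each node, foreground = node members and background = parent members
    minus node members (a subfamily versus its sibling subfamilies). Nodes
    whose complement is empty are skipped with a warning.

    With ``exclusive`` (the default), a column significant at several nodes is
    assigned to the single node that explains it most parsimoniously: a
    pattern conserved in one subfamily also shows a contrast at the family
    level (partial conservation) and at its sibling (as a large complement
    "anti-pattern" via depletion), so without exclusive assignment the same
    planted column would be reported at several nodes. The assignment prefers
    nodes where the column is a genuine pattern — conserved in the foreground
    (pattern frequency >= ``min_pattern_conservation``) and divergent in the
    background (pattern frequency <= ``max_pattern_bg_frequency``); a
    subfamily pattern sits near 50% at the family level and the family-level
    anti-pattern keeps ~50% background frequency, so both are disqualified —
    and among those the smallest size-adjusted p. The sprawling complement
    set at a sibling pays a far larger selection penalty than a compact
    conserved pattern, so the column lands at the node where it is a
    parsimonious conserved-and-divergent pattern.
    """
    results: Dict[str, ContrastResult] = {}
    stack = [(tree.root, None)]
    pairs = []
    while stack:
        node, parent = stack.pop()
        if parent is not None:
            pairs.append((node, parent))
        stack.extend((child, node) for child in node.children)
    for node, parent in sorted(pairs, key=lambda p: p[0].name):
        background = [s for s in parent.members if s not in set(node.members)]
        if not background:
            logger.warning("node %r skipped: empty complement background", node.name)
            continue
        results[node.name] = score_contrast(
            aln, w, node.members, background,
            alpha=alpha, top_k=top_k, min_fg_coverage=min_fg_coverage,
            node_name=node.name,
        )
    if exclusive and results:
        best_node: Dict[int, tuple] = {}
        for name, res in sorted(results.items()):
            significant = set(res.ranked_positions)
            for pc in res.columns:
                if pc.column not in significant:
                    continue
                fg_freq = pc.k_F / pc.N_F if pc.N_F > 0 else 0.0
                bg_freq = pc.k_B / pc.N_B if pc.N_B > 0 else 0.0
                genuine = 0 if (fg_freq >= min_pattern_conservation
                                and bg_freq <= max_pattern_bg_frequency) else 1
                key = (genuine, pc.p_value, name.count("/"), name)
                if pc.column not in best_node or key < best_node[pc.column]:
                    best_node[pc.column] = key
        for name, res in results.items():
            res.ranked_positions = [
                col for col in res.ranked_positions if best_node[col][3] == name
            ]
    return results


# ---------------------------------------------------------------------------
# insert detection
# ---------------------------------------------------------------------------

@dataclass
class InsertCall:
    """A maximal column run occupied in the foreground but gapped in the
    background — a candidate family-specific insert segment."""

    start: int                        # 1-based inclusive
    end: int
    fg_occupancy: float               # mean fraction non-gap fg weight over the run
    bg_gap_fraction: float            # mean fraction gapped bg weight over the run
    p_value: float                    # gap-contrast ball-in-urn p at the best column


def detect_inserts(
    aln: LabeledAlignment,
    w: SequenceWeights,
    foreground: Sequence[str],
    background: Sequence[str],
    min_len: int = 2,
    occ_min: float = 0.5,
    gap_min: float = 0.9,
    merge_gap: int = 2,
) -> List[InsertCall]:
    """Call foreground-specific insert segments.

    A column qualifies when the weighted foreground non-gap occupancy is at
    least ``occ_min`` and the weighted background gap fraction is at least
    ``gap_min``. Maximal qualifying runs of length >= ``min_len`` are reported;
    runs separated by fewer than ``merge_gap`` columns are merged first. Each
    run is scored by the ball-in-urn law on gap-versus-residue counts at its
    most contrasted column.
    """
    fg_set, bg_set = set(foreground), set(background)
    if not fg_set or not bg_set:
        raise ValueError("foreground and background must be nonempty")
    if fg_set & bg_set:
        raise ValueError("foreground and background overlap")

    fg_prof = weighted_profile(aln, w, sorted(fg_set))
    bg_prof = weighted_profile(aln, w, sorted(bg_set))

    fg_total = fg_prof.total_weight
    bg_total = bg_prof.total_weight
    fg_occ = 1.0 - fg_prof.gap_count / fg_total
    bg_gap = bg_prof.gap_count / bg_total
    qualifying = (fg_occ >= occ_min) & (bg_gap >= gap_min)

    # maximal runs over qualifying columns
    runs: List[Tuple[int, int]] = []
    start = None
    for i, q in enumerate(qualifying):
        if q and start is None:
            start = i
        elif not q and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(qualifying) - 1))

    # merge runs separated by < merge_gap columns
    merged: List[Tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    calls: List[InsertCall] = []
    for s, e in merged:
        if e - s + 1 < min_len:
            continue
        best_p = 1.0
        for i in range(s, e + 1):
            kf = fg_total - float(fg_prof.gap_count[i])     # fg residues present
            kb = bg_total - float(bg_prof.gap_count[i])     # bg residues present
            p = ball_in_urn_pvalue(kf, fg_total, kb, bg_total)
            best_p = min(best_p, p)
        calls.append(InsertCall(
            start=s + 1, end=e + 1,
            fg_occupancy=float(fg_occ[s:e + 1].mean()),
            bg_gap_fraction=float(bg_gap[s:e + 1].mean()),
            p_value=best_p,
        ))
    return calls
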