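"""Global alignment of two compressed-shift profiles.

Two proteins are aligned by dynamic programming over their per-residue
profile values (each in [0, 1]); the match cost for residues i, j is the
absolute difference |v_a(i) - v_b(j)| and every gap column costs a fixed
penalty (default 0.4).  The DP minimizes the TOTAL cost of the global
alignment; the reported score is total cost divided by the number of
alignment columns, so it reads as a mean per-column distance — lower is
better.  This is the gapped one-to-one variant of dynamic time warping:
every residue of both proteins appears in exactly one column.

Optionally ("hybrid" mode) an amino-acid identity term is mixed in: the
BLOSUM62 log-odds scores are mapped monotonically onto [0, 1] by their
empirical quantile over the 210 unordered residue pairs (midpoint ranks
for ties) and inverted, so similar residue pairs cost little.  The match
cost is then a convex combination of the profile term and this
substitution cost.

A residue whose profile value is missing contributes the gap penalty when
matched — neutral: matching it is never better or worse than gapping it.
Tie-breaking in the traceback is deterministic: diagonal (match), then
consuming from the first profile, then from the second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.stats import rankdata

from .shift_io import ProfileRecord

GAP = None            # gap marker inside alignment columns
DEFAULT_GAP_PENALTY = 0.4
MODES = ("shiftcrypt", "hybrid")

_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SubstitutionCost:
    """Symmetric 20x20 matrix of amino-acid match costs in [0, 1]."""

    matrix: np.ndarray                       # indexed by _AA_ORDER
    alphabet: str = _AA_ORDER

    def cost(self, aa1: str, aa2: str) -> float:
        return float(self.matrix[self.alphabet.index(aa1),
                                 self.alphabet.index(aa2)])


def rescale_blosum62() -> SubstitutionCost:
    """Quantile-rescale BLOSUM62 into costs: high similarity -> low cost.

    Each of the 210 unordered-pair scores s is mapped to its empirical
    quantile (fraction of entries <= s, ties sharing the midpoint rank)
    and the cost is 1 - quantile.  W/W, the unique maximum score, gets
    cost exactly 0; the map is strictly decreasing in the raw score.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ORDER)
    pairs = [(i, j) for i in range(n) for j in range(i, n)]
    scores = np.array([blosum[_AA_ORDER[i], _AA_ORDER[j]] for i, j in pairs])
    quantiles = rankdata(scores, method="average") / len(scores)
    costs = 1.0 - quantiles
    matrix = np.zeros((n, n))
    for (i, j), c in zip(pairs, costs):
        matrix[i, j] = matrix[j, i] = c
    return SubstitutionCost(matrix)


@dataclass
class AlignmentResult:
    """A global alignment of two profiles and its cost breakdown.

    ``columns`` pairs positional indices (0-based) of the two profiles;
    None marks a gap.  ``score`` is total cost / number of columns.
    """

    columns: list[tuple[Optional[int], Optional[int]]]
    column_costs: list[float]
    total_cost: float
    score: float
    aligned_a: str
    aligned_b: str
    entry_a: str
    entry_b: str
    mode: str
    gap_penalty: float
    mix_weight: float


def _match_cost_matrix(a: ProfileRecord, b: ProfileRecord, mode: str,
                       gap_penalty: float, mix_weight: float,
                       sub: Optional[SubstitutionCost]) -> np.ndarray:
    va = np.array([np.nan if v is None else v for v in a.values])
    vb = np.array([np.nan if v is None else v for v in b.values])
    bio = np.abs(va[:, None] - vb[None, :])
    bio[np.isnan(bio)] = gap_penalty      # missing value: neutral cost
    if mode == "shiftcrypt":
        return bio
    if sub is None:
        sub = rescale_blosum62()
    ia = [sub.alphabet.index(c) for c in a.sequence]
    ib = [sub.alphabet.index(c) for c in b.sequence]
    aa = sub.matrix[np.ix_(ia, ib)]
    return (1.0 - mix_weight) * bio + mix_weight * aa


def align(a: ProfileRecord, b: ProfileRecord,
          gap_penalty: float = DEFAULT_GAP_PENALTY,
          mode: str = "shiftcrypt", mix_weight: float = 0.5,
          sub: Optional[SubstitutionCost] = None) -> AlignmentResult:
    """Globally align two profiles, minimizing total cost.

    Needleman-Wunsch over the match-cost matrix with constant gap penalty
    (end gaps included).  Deterministic traceback: on cost ties, prefer
    the diagonal move, then consuming a residue of ``a``, then of ``b``.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty profile")
    if mode not in MODES:
        raise ValueError(f"unknown alignment mode {mode!r}; "
                         f"choose one of {', '.join(MODES)}")
    if not (0.0 <= mix_weight <= 1.0):
        raise ValueError("mix_weight must be in [0, 1]")

    C = _match_cost_matrix(a, b, mode, gap_penalty, mix_weight, sub)
    n, m = C.shape
    # Boundaries are accumulated additively (not arange * penalty) so every
    # cell is a left-to-right float sum over its path, exactly comparable
    # with an enumeration oracle that sums the same way.
    D = np.empty((n + 1, m + 1))
    D[0, 0] = 0.0
    for j in range(1, m + 1):
        D[0, j] = D[0, j - 1] + gap_penalty
    for i in range(1, n + 1):
        D[i, 0] = D[i - 1, 0] + gap_penalty
    for i in range(1, n + 1):
        Di, Dp, Ci = D[i], D[i - 1], C[i - 1]
        for j in range(1, m + 1):
            Di[j] = min(Dp[j - 1] + Ci[j - 1],
                        Dp[j] + gap_penalty,
                        Di[j - 1] + gap_penalty)

    columns: list[tuple[Optional[int], Optional[int]]] = []
    costs: list[float] = []
    i, j = n, m
    inf = float("inf")
    while i > 0 or j > 0:
        diag = D[i - 1, j - 1] + C[i - 1, j - 1] if i > 0 and j > 0 else inf
        up = D[i - 1, j] + gap_penalty if i > 0 else inf
        left = D[i, j - 1] + gap_penalty if j > 0 else inf
        best = min(diag, up, left)
        if diag == best:
            columns.append((i - 1, j - 1))
            costs.append(float(C[i - 1, j - 1]))
            i, j = i - 1, j - 1
        elif up == best:
            columns.append((i - 1, GAP))
            costs.append(gap_penalty)
            i -= 1
        else:
            columns.append((GAP, j - 1))
            costs.append(gap_penalty)
            j -= 1
    columns.reverse()
    costs.reverse()

    total = float(D[n, m])
    aligned_a = "".join("-" if ci is None else a.sequence[ci] for ci, _ in columns)
    aligned_b = "".join("-" if cj is None else b.sequence[cj] for _, cj in columns)
    return AlignmentResult(
        columns=columns, column_costs=costs, total_cost=total,
        score=total / len(columns), aligned_a=aligned_a, aligned_b=aligned_b,
        entry_a=a.entry_id, entry_b=b.entry_id, mode=mode,
        gap_penalty=gap_penalty, mix_weight=mix_weight,
    )


def alignment_to_fasta(result: AlignmentResult) -> str:
    """Two-record gapped FASTA; stripping '-' recovers the input sequences."""
    return (f">{result.entry_a}\n{result.aligned_a}\n"
            f">{result.entry_b}\n{result.aligned_b}\n")


def alignment_report(result: AlignmentResult) -> dict:
    """JSON-ready report: score, settings, and per-column pairing costs."""
    return {
        "entry_a": result.entry_a,
        "entry_b": result.entry_b,
        "mode": result.mode,
        "gap_penalty": result.gap_penalty,
        "mix_weight": result.mix_weight,
        "score": result.score,
        "total_cost": result.total_cost,
        "columns": [
            {"i": ci, "j": cj, "cost": cost}
            for (ci, cj), cost in zip(result.columns, result.column_costs)
        ],
    }


def score_matrix(profiles: Sequence[ProfileRecord],
                 gap_penalty: float = DEFAULT_GAP_PENALTY,
                 mode: str = "shiftcrypt",
                 mix_weight: float = 0.5) -> np.ndarray:
    """All-against-all alignment scores (symmetric; diagonal included).

    The upper triangle is computed and mirrored; the minimal total cost is
    symmetric in its arguments, so this loses nothing.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    sub = rescale_blosum62() if mode == "hybrid" else None
    k = len(profiles)
    S = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            s = align(profiles[i], profiles[j], gap_penalty, mode,
                      mix_weight, sub).score
            S[i, j] = S[j, i] = s
    return S
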