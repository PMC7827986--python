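"""Subfamily adjudication and ensemble annotation confidence.

A genomic sequence ``t`` is scored against every subfamily consensus
``q_i`` in a library; the conventional annotation is the single
highest-scoring candidate. Because integer alignment scores are scaled
log-odds, ``score(t, q_i) = lambda * log2(P(t|q_i) / P(t|R))``, the
ensemble of competing scores also supports a posterior-style confidence

    Conf(q_i | t) = 2^(s_i / lambda) / sum_j 2^(s_j / lambda),

in which the null-model term ``P(t|R)`` cancels. ``lambda`` is the
scale factor of the scoring matrix, recovered here as the unique
positive root of ``sum_ab p_a p_b 2^(s_ab / lambda) = 1`` under the
background letter frequencies (the standard consistency condition for
log-odds matrices). Gap penalties contribute to scores but carry no
probabilistic interpretation, and all candidates are treated as covering
the same genomic range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats import GenomeInterval, ScoringMatrix, TEAnnotation


class NoValidLambdaError(ValueError):
    """The scoring matrix admits no positive lambda (expected score must
    be negative and at least one score positive)."""


@dataclass
class AlignmentCandidate:
    """Score of one competing subfamily annotation for a sequence."""

    subfamily: str
    score: float
    aligned_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"{self.subfamily}: score must be finite")


@dataclass
class ConfidenceSet:
    """Normalized ensemble confidences for one sequence's candidates."""

    confidences: dict[str, float]
    lambda_used: float
    best: str
    tie: bool


def positional_score(seq: str, consensus: str, matrix: ScoringMatrix) -> int:
    """Gapless sum of pair scores at corresponding positions."""
    if len(seq) != len(consensus):
        raise ValueError(
            f"positional scoring requires equal lengths ({len(seq)} vs {len(consensus)})"
        )
    return sum(matrix.score(a, b) for a, b in zip(seq, consensus))


def _make_aligner(matrix: ScoringMatrix) -> Align.PairwiseAligner:
    sub = substitution_matrices.Array(alphabet="".join(matrix.alphabet), dims=2)
    for (a, b), s in matrix.scores.items():
        sub[a, b] = s
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -float(matrix.gap_open)
    aligner.extend_gap_score = -float(matrix.gap_extend)
    return aligner


def score_candidates(
    instance: str,
    library,
    matrix: ScoringMatrix,
    mode: str = "positional",
) -> list[AlignmentCandidate]:
    """Score ``instance`` against every subfamily consensus.

    ``positional`` mode sums pair scores at corresponding positions
    (valid for the gapless simulated data); ``local`` mode runs an
    affine-gap local alignment, whose score can only exceed the
    positional score since it may trim poorly matching ends.
    """
    if not instance:
        raise ValueError("instance sequence must be non-empty")
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    extra = set(instance) - set(matrix.alphabet)
    if extra:
        raise ValueError(f"instance letters outside matrix alphabet: {sorted(extra)}")
    if mode not in {"positional", "local"}:
        raise ValueError(f"unknown scoring mode {mode!r}")

    candidates = []
    aligner = _make_aligner(matrix) if mode == "local" else None
    for record in library.records:
        if mode == "positional":
            score = positional_score(instance, record.consensus, matrix)
            rng_on_t: tuple[int, int] | None = (0, len(instance))
        else:
            score = float(aligner.score(instance, record.consensus))
            rng_on_t = None
        candidates.append(AlignmentCandidate(record.name, float(score), rng_on_t))
    return candidates


def infer_lambda(
    matrix: ScoringMatrix,
    background: Mapping[str, float] | None = None,
    rel_tol: float = 1e-10,
) -> float:
    """Solve for the scale factor lambda of a log-odds scoring matrix.

    Returns the unique ``lambda > 0`` with
    ``sum_ab p_a p_b 2^(s_ab / lambda) = 1``, located by bisection on
    ``u = 1/lambda``. Requires a negative expected score and at least
    one positive score under the background frequencies.
    """
    if background is None:
        background = {a: 1.0 / len(matrix.alphabet) for a in matrix.alphabet}
    total = sum(background.values())
    bg = {a: background[a] / total for a in matrix.alphabet}

    p = np.array([bg[a] * bg[b] for a in matrix.alphabet for b in matrix.alphabet])
    s = np.array(
        [matrix.scores[(a, b)] for a in matrix.alphabet for b in matrix.alphabet],
        dtype=float,
    )
    if float(np.sum(p * s)) >= 0:
        raise NoValidLambdaError("expected score under background must be negative")
    if s.max() <= 0:
        raise NoValidLambdaError("at least one positive score is required")

    def g(u: float) -> float:
        return float(np.sum(p * np.exp2(s * u))) - 1.0

    # g(0) = 0, g decreases initially (negative expected score) and
    # diverges for large u, so the positive root is bracketed by growth.
    hi = 1.0
    for _ in range(200):
        if g(hi) > 0:
            break
        hi *= 2.0
    else:  # pragma: no cover - unreachable given preconditions
        raise NoValidLambdaError("failed to bracket lambda")
    lo = hi / 2.0
    while g(lo) > 0:
        hi = lo
        lo /= 2.0
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 2.0 / (lo + hi)


def matrix_with_lambda(
    lambda0: float,
    seed: int = 0,
    alphabet: Sequence[str] = ("A", "C", "G", "T"),
) -> tuple[ScoringMatrix, dict[str, float]]:
    """Construct a random scoring matrix whose true scale factor is
    exactly ``lambda0``, plus its background frequencies.

    A random symmetric integer matrix (positive matches, negative
    mismatches) is drawn, then the background is tuned along a line in
    the frequency simplex until ``sum_ab p_a p_b 2^(s_ab/lambda0) = 1``
    holds exactly. The implied joint ``P(a,b) = p_a p_b 2^(s_ab/lambda0)``
    is then a valid distribution whose lambda0-scaled log-odds are
    integral, so the integer matrix is its own rounded log-odds matrix.
    Used to calibrate and test lambda inference.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    n = len(alphabet)
    uniform = np.full(n, 1.0 / n)
    for _ in range(500):
        diag = rng.integers(1, 4, n)
        tri = -rng.integers(3, 9, (n, n))
        off = np.triu(tri, 1)
        s = np.diag(diag).astype(float) + off + off.T

        def f(p: np.ndarray) -> float:
            return float(np.sum(np.outer(p, p) * np.exp2(s / lambda0)))

        if f(uniform) >= 1.0:
            continue  # redraw: need room to tune upward toward a vertex
        vertex = np.eye(n)[int(np.argmax(diag))]
        t = brentq(lambda t: f((1 - t) * uniform + t * vertex) - 1.0, 0.0, 1.0)
        p = (1 - t) * uniform + t * vertex
        scores = {
            (alphabet[i], alphabet[j]): int(s[i, j]) for i in range(n) for j in range(n)
        }
        return ScoringMatrix(tuple(alphabet), scores), dict(zip(alphabet, p))
    raise RuntimeError("failed to draw a tunable score matrix")  # pragma: no cover


def confidence(candidates: Sequence[AlignmentCandidate], lam: float) -> ConfidenceSet:
    """Ensemble confidence over competing annotations.

    Computed with the maximum score subtracted first, so the result is
    numerically stable and invariant to adding a constant to all scores.
    ``tie`` is set when the two top scores are equal; ``best`` is the
    lexicographically smallest subfamily among the maximal scores.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    scores = np.array([c.score for c in candidates], dtype=float)
    names = [c.subfamily for c in candidates]
    weights = np.exp2((scores - scores.max()) / lam)
    conf = weights / weights.sum()
    top = scores.max()
    winners = [n for n, s in zip(names, scores) if s == top]
    return ConfidenceSet(
        confidences=dict(zip(names, conf.tolist())),
        lambda_used=float(lam),
        best=min(winners),
        tie=len(winners) > 1,
    )


def annotate_instance(
    candidates: Sequence[AlignmentCandidate],
    family: str = "",
    interval: GenomeInterval | None = None,
    source_id: str = "",
) -> TEAnnotation:
    """Adjudicate by highest score; ties go to the lexicographically
    smallest subfamily name and are recorded on the annotation."""
    if not candidates:
        raise ValueError("need at least one candidate")
    top = max(c.score for c in candidates)
    winners = sorted(c.subfamily for c in candidates if c.score == top)
    if interval is None:
        best = next(c for c in candidates if c.subfamily == winners[0])
        length = (best.aligned_range[1] - best.aligned_range[0]) if best.aligned_range else 1
        interval = GenomeInterval("query", 0, max(1, length))
    return TEAnnotation(
        interval=interval,
        family=family,
        subfamily=winners[0],
        score=top,
        source_id=source_id,
        tie=len(winners) > 1,
    )
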