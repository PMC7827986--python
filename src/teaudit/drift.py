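"""Point-mutation model of subfamily annotation drift.

Two subfamilies ``i`` and ``j`` are separated by ``n`` diagnostic sites
— consensus positions where their nucleotides differ. An instance of
``i`` inserted agreeing with its consensus at all ``n`` sites can
accumulate enough point mutations at those sites that it looks more
like ``j``. With per-site identity ``p_a = P(A_i)`` (probability a site
is unmutated since insertion) and mutations uniform over the three
alternative nucleotides:

* ``P(B_ij) = (1 - p_a) / 3`` — the site flips to j's diagnostic value;
* ``P(O_ij) = 2 (1 - p_a) / 3`` — the site mutates to a third value,
  informative for neither subfamily;
* ``P(c) = p_a / (1 - P(O)) = 3 p_a / (1 + 2 p_a)`` — the site keeps
  i's value given it did not go to a third value.

The probability that an instance of ``i`` is recognized as ``j`` sums
over the number ``k`` of sites lost to third values; among the
remaining ``n - k`` informative sites, strictly more must agree with
``j`` than with ``i``:

    P(S: i -> j) = sum_{k=0}^{n-1} C(n,k) (1-P(O))^(n-k) P(O)^k
                   * B(floor((n-k-1)/2), n-k, P(c))

where ``B`` is the binomial CDF. The prose reading "at least half the
sites" is available via ``majority='half'`` for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom

_VALID = set("ACGT")


@dataclass
class DiagnosticSiteSet:
    """Substitution columns distinguishing two subfamily consensuses."""

    subfamily_i: str
    subfamily_j: str
    sites: list[tuple[int, str, str]]  # (position on consensus i, nt_i, nt_j)

    def __post_init__(self) -> None:
        for pos, a, b in self.sites:
            if a == b:
                raise ValueError(f"site {pos}: diagnostic nucleotides must differ")

    @property
    def n(self) -> int:
        return len(self.sites)


@dataclass
class DriftParams:
    """Per-site outcome probabilities at identity ``p_a``."""

    p_a: float
    p_b: float
    p_o: float
    p_c: float


@dataclass
class DriftMatrix:
    """Pairwise subfamily-conversion probabilities and type aggregation."""

    pairwise: pd.DataFrame  # rows: source subfamily i, cols: target j
    site_counts: pd.DataFrame
    type_table: pd.DataFrame | None = None


def diagnostic_sites(
    consensus_i: str,
    consensus_j: str,
    name_i: str = "i",
    name_j: str = "j",
) -> DiagnosticSiteSet:
    """Find the substitution columns between two consensuses.

    Equal-length sequences are compared column by column; otherwise a
    global pairwise alignment is computed first. Indel columns and
    columns involving non-ACGT letters are excluded — the drift model is
    substitution-only. Positions index consensus ``i``.
    """
    if not consensus_i or not consensus_j:
        raise ValueError("consensus sequences must be non-empty")
    sites: list[tuple[int, str, str]] = []
    if len(consensus_i) == len(consensus_j):
        for pos, (a, b) in enumerate(zip(consensus_i, consensus_j)):
            if a != b and a in _VALID and b in _VALID:
                sites.append((pos, a, b))
    else:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
        alignment = aligner.align(consensus_i, consensus_j)[0]
        row_i, row_j = str(alignment[0]), str(alignment[1])
        pos = 0
        for a, b in zip(row_i, row_j):
            if a != "-" and b != "-" and a != b and a in _VALID and b in _VALID:
                sites.append((pos, a, b))
            if a != "-":
                pos += 1
    return DiagnosticSiteSet(name_i, name_j, sites)


def site_change_probs(p_a: float) -> DriftParams:
    """Closed-form per-site probabilities from the identity fraction."""
    if not 0.0 <= p_a <= 1.0:
        raise ValueError(f"identity must be in [0,1], got {p_a}")
    p_b = (1.0 - p_a) / 3.0
    p_o = 2.0 * (1.0 - p_a) / 3.0
    p_c = 3.0 * p_a / (1.0 + 2.0 * p_a) if p_a > 0 else 0.0
    return DriftParams(p_a=p_a, p_b=p_b, p_o=p_o, p_c=p_c)


def binom_cdf(x: float, n: int, p: float) -> float:
    """Binomial CDF ``P(X <= floor(x))`` with saturated tails."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    if x < 0:
        return 0.0
    if x >= n:
        return 1.0
    return float(_binom.cdf(math.floor(x), n, p))


def _drift_sum(n: int, p_c: float, p_o: float, majority: str = "strict") -> float:
    """Sum over k third-value sites of the flip probability (see module
    docstring). ``p_o`` may be forced (e.g. to 0) for model analysis."""
    if majority not in {"strict", "half"}:
        raise ValueError("majority must be 'strict' or 'half'")
    total = 0.0
    for k in range(n):
        m = n - k
        bound = (m - 1) // 2 if majority == "strict" else m // 2
        total += (
            math.comb(n, k)
            * (1.0 - p_o) ** m
            * p_o**k
            * binom_cdf(bound, m, p_c)
        )
    return total


def conversion_prob(n: int, p_a: float, majority: str = "strict") -> float:
    """Probability that an instance of ``i`` drifts to look like ``j``
    across ``n`` diagnostic sites at identity ``p_a``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 0.0
    params = site_change_probs(p_a)
    return _drift_sum(n, params.p_c, params.p_o, majority)


def conversion_matrix(
    library,
    identities: Mapping[str, float] | None = None,
    majority: str = "strict",
) -> DriftMatrix:
    """Pairwise conversion probabilities for every ordered subfamily pair.

    ``pairwise[i][j] = conversion_prob(n_ij, identities[i])`` where
    ``n_ij`` counts the diagnostic sites between the two consensuses.
    The diagonal is zero. ``identities`` defaults to the per-subfamily
    identities stored in the library.
    """
    names = library.names
    if identities is None:
        identities = library.identity_map()
    missing = [n for n in names if n not in identities]
    if missing:
        raise KeyError(f"missing identity for subfamilies: {missing}")

    n_sites = pd.DataFrame(0, index=names, columns=names, dtype=int)
    probs = pd.DataFrame(0.0, index=names, columns=names, dtype=float)
    for i in names:
        for j in names:
            if i == j:
                continue
            n_ij = diagnostic_sites(library[i].consensus, library[j].consensus, i, j).n
            n_sites.loc[i, j] = n_ij
            probs.loc[i, j] = conversion_prob(n_ij, identities[i], majority)
    return DriftMatrix(pairwise=probs, site_counts=n_sites)


def aggregate_by_type(
    matrix: DriftMatrix,
    frequencies: Mapping[str, float],
    type_map: Mapping[str, str],
    types: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Frequency-weighted type-level aggregation of the pairwise matrix.

    ``cell(T1, T2)`` is the weighted mean over sources ``i`` in ``T1``
    of the summed probability of converting to any ``j != i`` in ``T2``;
    the ``combined_mismatch`` column sums over all targets regardless of
    type, and therefore equals the row sum when the type columns cover
    every subfamily.
    """
    names = list(matrix.pairwise.index)
    for name in names:
        if name not in frequencies:
            raise KeyError(f"missing frequency for subfamily {name!r}")
        if name not in type_map:
            raise KeyError(f"missing type for subfamily {name!r}")
    if types is None:
        types = sorted({type_map[n] for n in names})

    members = {t: [n for n in names if type_map[n] == t] for t in types}
    rows = []
    for t1 in types:
        wsum = sum(frequencies[i] for i in members[t1])
        if wsum <= 0:
            raise ValueError(f"type {t1!r} has zero total frequency weight")
        row: dict[str, object] = {"type": t1}
        for t2 in types:
            row[t2] = (
                sum(
                    frequencies[i]
                    * sum(matrix.pairwise.loc[i, j] for j in members[t2] if j != i)
                    for i in members[t1]
                )
                / wsum
            )
        row["combined_mismatch"] = (
            sum(
                frequencies[i] * sum(matrix.pairwise.loc[i, j] for j in names if j != i)
                for i in members[t1]
            )
            / wsum
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    matrix.type_table = table
    return table
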