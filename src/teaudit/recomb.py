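"""Windowed binomial scan for recombination signatures.

A gene conversion that imported a tract from a divergent donor leaves a
local dip in identity inside an otherwise uniformly diverged segmental
duplication. The scan splits a TE pair's alignment into non-overlapping
windows of 100 non-gap columns (trailing ``n mod 100`` columns unused),
counts identical columns per window, and asks how surprising the worst
window is: ``raw_p`` is the binomial CDF of the smallest count at the
segment-wide background identity, Bonferroni-corrected by the number of
windows. Pairs with corrected ``P < alpha`` (default 0.001) are flagged.

Columns with a gap in either row count neither toward a window's 100
columns nor toward identity; columns containing ``N`` count as non-gap
but never as identical. The background identity always comes from the
full containing segment alignment, not from the TE sub-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GAP, SegmentAlignment
from .drift import binom_cdf
from .pairing import TEPair


@dataclass
class WindowScan:
    """Result of scanning one TE pair alignment."""

    window_counts: list[int]
    background_identity: float
    min_count: int | None
    n_windows: int
    raw_p: float
    corrected_p: float
    flagged: bool


@dataclass
class RecombSummary:
    table: pd.DataFrame


def _rows_to_arrays(row_a: str, row_b: str) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.frombuffer(row_a.encode(), dtype=np.uint8),
        np.frombuffer(row_b.encode(), dtype=np.uint8),
    )


def segment_identity(seg: SegmentAlignment) -> float:
    """Identical columns / non-gap columns over the whole segment."""
    a, b = _rows_to_arrays(seg.row_a, seg.row_b)
    nongap = (a != ord(GAP)) & (b != ord(GAP))
    n = int(nongap.sum())
    if n == 0:
        raise ValueError(f"segment {seg.id}: no non-gap columns")
    identical = (a == b) & nongap & (a != ord("N"))
    return float(identical.sum()) / n


def window_scan(
    row_a: str,
    row_b: str,
    background_identity: float,
    window: int = 100,
    alpha: float = 0.001,
) -> WindowScan:
    """Scan a two-row (possibly gapped) TE pair alignment for a
    significantly low-identity window. See module docstring."""
    if not 0.0 <= background_identity <= 1.0:
        raise ValueError("background_identity must be in [0,1]")
    if len(row_a) != len(row_b):
        raise ValueError("pair alignment rows differ in length")
    a, b = _rows_to_arrays(row_a, row_b)
    keep = (a != ord(GAP)) & (b != ord(GAP))
    a, b = a[keep], b[keep]
    n_windows = len(a) // window
    if n_windows == 0:
        return WindowScan([], background_identity, None, 0, 1.0, 1.0, False)
    identical = ((a == b) & (a != ord("N"))).astype(np.int64)[: n_windows * window]
    counts = identical.reshape(n_windows, window).sum(axis=1)
    min_count = int(counts.min())
    raw_p = binom_cdf(min_count, window, background_identity)
    corrected_p = min(1.0, raw_p * n_windows)
    return WindowScan(
        window_counts=[int(c) for c in counts],
        background_identity=background_identity,
        min_count=min_count,
        n_windows=n_windows,
        raw_p=raw_p,
        corrected_p=corrected_p,
        flagged=corrected_p < alpha,
    )


def scan_pair(
    seg: SegmentAlignment,
    pair: TEPair,
    window: int = 100,
    alpha: float = 0.001,
    background_identity: float | None = None,
) -> WindowScan:
    """Scan the sub-alignment spanned by a TE pair within its segment."""
    if pair.pair_columns is None:
        raise ValueError("pair has no alignment column range")
    start, end = pair.pair_columns
    if background_identity is None:
        background_identity = segment_identity(seg)
    return window_scan(
        seg.row_a[start:end], seg.row_b[start:end], background_identity, window, alpha
    )


def summarize_recombination(
    items: Sequence[tuple[TEPair, WindowScan]],
    type_map: Mapping[str, str],
) -> RecombSummary:
    """Percent of flagged pairs per subfamily type, split by concordance.

    A pair contributes to the type group of each member (once if both
    members share a type). The optional mean identity to consensus is
    the element-level mean of ``100 * (1 - divergence)`` over members
    whose annotations carry a divergence.
    """
    groups: dict[str, dict[str, list]] = {}
    for pair, scan in items:
        if pair.concordant is None:
            raise ValueError("pairs must be concordance-labeled before summarizing")
        types = set()
        for anno in (pair.anno_a, pair.anno_b):
            try:
                types.add(type_map[anno.subfamily])
            except KeyError:
                raise KeyError(f"subfamily {anno.subfamily!r} missing from type_map") from None
        for t in types:
            g = groups.setdefault(t, {"conc": [], "disc": [], "ids": []})
            (g["conc"] if pair.concordant else g["disc"]).append(scan.flagged)
            for anno in (pair.anno_a, pair.anno_b):
                if anno.divergence is not None:
                    g["ids"].append(100.0 * (1.0 - anno.divergence))

    rows = []
    for t in sorted(groups):
        g = groups[t]
        if not g["conc"] and not g["disc"]:
            continue
        rows.append(
            {
                "type": t,
                "n_concordant": len(g["conc"]),
                "n_discordant": len(g["disc"]),
                "percent_flagged_concordant": (
                    100.0 * sum(g["conc"]) / len(g["conc"]) if g["conc"] else float("nan")
                ),
                "percent_flagged_discordant": (
                    100.0 * sum(g["disc"]) / len(g["disc"]) if g["disc"] else float("nan")
                ),
                "mean_percent_id_to_consensus": (
                    float(np.mean(g["ids"])) if g["ids"] else float("nan")
                ),
            }
        )
    return RecombSummary(table=pd.DataFrame(rows))
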