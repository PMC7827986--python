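"""Replicate TE pair extraction and discordance tabulation.

TEs annotated on the two copies of a segmental duplication are matched
through the columns of the segment alignment. A matched pair survives
only if it passes all of the reliability filters (evaluated
conjunctively, so order never matters):

* ``multiplicity`` — a TE overlapping multiple TEs in the other copy is
  dropped, along with everything it touches;
* ``min_length`` — both copies must be longer than ``min_len`` bp;
* ``coverage`` — the reciprocal projected coverage must reach
  ``min_cov`` for both copies;
* ``contiguity`` — the projected overlap must form one contiguous
  alignment, i.e. contain no unaligned/indel block longer than
  ``max_indel_block`` columns;
* ``ambiguity`` — neither member may carry a family-only call.

A retained pair is *concordant* when both members name the same
subfamily, *discordant* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GAP, GenomeInterval, SegmentAlignment, TEAnnotation

FILTER_RULES = ("multiplicity", "min_length", "coverage", "contiguity", "ambiguity")


@dataclass
class TEPair:
    """A pair of homologous TE annotations from a duplicated segment."""

    anno_a: TEAnnotation
    anno_b: TEAnnotation
    pair_columns: tuple[int, int] | None = None
    concordant: bool | None = None
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def passed_all(self) -> bool:
        return all(ok for _, ok in self.filter_trace)

    def failed_rules(self) -> list[str]:
        return [rule for rule, ok in self.filter_trace if not ok]


@dataclass
class DiscordanceSummary:
    """Per-family discordance rates plus the type-level cross table."""

    by_family: pd.DataFrame
    cross_table: pd.DataFrame


def _column_positions(row: str, interval: GenomeInterval) -> np.ndarray:
    """Genomic position of each alignment column (-1 at gap columns)."""
    arr = np.frombuffer(row.encode(), dtype=np.uint8)
    nongap = arr != ord(GAP)
    pos = np.where(nongap, interval.start + np.cumsum(nongap) - 1, -1)
    return pos


def _anno_columns(pos: np.ndarray, anno: TEAnnotation) -> np.ndarray:
    return (pos >= anno.interval.start) & (pos < anno.interval.end)


def _max_gap_run(either_gap: np.ndarray) -> int:
    """Longest run of True in a boolean array."""
    if not either_gap.any():
        return 0
    padded = np.concatenate([[False], either_gap, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return int((ends - starts).max())


def extract_te_pairs(
    seg: SegmentAlignment,
    annos_a: Sequence[TEAnnotation],
    annos_b: Sequence[TEAnnotation],
    min_len: int = 50,
    min_cov: float = 0.8,
    max_indel_block: int = 30,
    dropped: list[TEPair] | None = None,
) -> list[TEPair]:
    """Match TEs across the two copies of one segmental duplication.

    Every annotation must lie inside its copy's interval. Returns the
    retained pairs; if ``dropped`` is a list, candidate pairs that fail
    any filter are appended to it with their full ``filter_trace``.
    """
    for label, annos, iv in (("a", annos_a, seg.interval_a), ("b", annos_b, seg.interval_b)):
        for anno in annos:
            if (
                anno.interval.chrom != iv.chrom
                or anno.interval.start < iv.start
                or anno.interval.end > iv.end
            ):
                raise ValueError(
                    f"segment {seg.id}: annotation {anno.source_id or anno.subfamily} "
                    f"outside copy-{label} interval"
                )

    pos_a = _column_positions(seg.row_a, seg.interval_a)
    pos_b = _column_positions(seg.row_b, seg.interval_b)
    cols_a = [_anno_columns(pos_a, anno) for anno in annos_a]
    cols_b = [_anno_columns(pos_b, anno) for anno in annos_b]
    gap_a = np.frombuffer(seg.row_a.encode(), dtype=np.uint8) == ord(GAP)
    gap_b = np.frombuffer(seg.row_b.encode(), dtype=np.uint8) == ord(GAP)
    either_gap = gap_a | gap_b

    overlaps = {
        (i, j): ca & cb
        for i, ca in enumerate(cols_a)
        for j, cb in enumerate(cols_b)
        if (ca & cb).any()
    }
    partners_a = np.zeros(len(annos_a), dtype=int)
    partners_b = np.zeros(len(annos_b), dtype=int)
    for i, j in overlaps:
        partners_a[i] += 1
        partners_b[j] += 1

    kept: list[TEPair] = []
    for (i, j), inter in sorted(overlaps.items()):
        anno_a, anno_b = annos_a[i], annos_b[j]
        n_inter = int(inter.sum())
        n_a = int(cols_a[i].sum())
        n_b = int(cols_b[j].sum())
        span = np.nonzero(inter)[0]
        gap_run = _max_gap_run(either_gap[span[0] : span[-1] + 1])
        trace = [
            ("multiplicity", partners_a[i] == 1 and partners_b[j] == 1),
            ("min_length", len(anno_a.interval) > min_len and len(anno_b.interval) > min_len),
            ("coverage", n_inter / n_a >= min_cov and n_inter / n_b >= min_cov),
            ("contiguity", gap_run <= max_indel_block),
            ("ambiguity", not anno_a.is_ambiguous and not anno_b.is_ambiguous),
        ]
        union = np.nonzero(cols_a[i] | cols_b[j])[0]
        pair = TEPair(
            anno_a=anno_a,
            anno_b=anno_b,
            pair_columns=(int(union[0]), int(union[-1]) + 1),
            filter_trace=trace,
        )
        if pair.passed_all:
            kept.append(pair)
        elif dropped is not None:
            dropped.append(pair)
    return kept


def pair_by_overlap(
    annos_mapped: Sequence[TEAnnotation],
    annos_target: Sequence[TEAnnotation],
    min_len: int = 50,
    min_cov: float = 0.8,
    dropped: list[TEPair] | None = None,
) -> list[TEPair]:
    """Pair two pre-mapped annotation sets by genomic overlap.

    ``annos_mapped`` must already be in the target genome's coordinate
    system. Candidate pairs are taken greedily by descending overlap and
    subjected to the same multiplicity / length / coverage / ambiguity
    filters as segment-based pairing (coverage here is bp overlap over
    each member's length).
    """
    overlaps: dict[tuple[int, int], int] = {}
    for i, ma in enumerate(annos_mapped):
        for j, ta in enumerate(annos_target):
            ov = ma.interval.overlap(ta.interval)
            if ov > 0:
                overlaps[(i, j)] = ov
    partners_m = np.zeros(len(annos_mapped), dtype=int)
    partners_t = np.zeros(len(annos_target), dtype=int)
    for i, j in overlaps:
        partners_m[i] += 1
        partners_t[j] += 1

    kept: list[TEPair] = []
    for (i, j), ov in sorted(overlaps.items(), key=lambda kv: (-kv[1], kv[0])):
        anno_a, anno_b = annos_mapped[i], annos_target[j]
        trace = [
            ("multiplicity", partners_m[i] == 1 and partners_t[j] == 1),
            ("min_length", len(anno_a.interval) > min_len and len(anno_b.interval) > min_len),
            (
                "coverage",
                ov / len(anno_a.interval) >= min_cov and ov / len(anno_b.interval) >= min_cov,
            ),
            ("contiguity", True),  # no alignment available; cannot be interrupted
            ("ambiguity", not anno_a.is_ambiguous and not anno_b.is_ambiguous),
        ]
        pair = TEPair(anno_a=anno_a, anno_b=anno_b, filter_trace=trace)
        if pair.passed_all:
            kept.append(pair)
        elif dropped is not None:
            dropped.append(pair)
    return kept


def label_concordance(pair: TEPair) -> TEPair:
    """Set the concordance flag by exact subfamily-name equality."""
    if pair.anno_a.is_ambiguous or pair.anno_b.is_ambiguous:
        raise ValueError(
            "cannot label concordance for an AMBIGUOUS member "
            "(should have been filtered upstream)"
        )
    pair.concordant = pair.anno_a.subfamily == pair.anno_b.subfamily
    return pair


def _lookup(mapping: Mapping[str, str], subfamily: str, what: str) -> str:
    try:
        return mapping[subfamily]
    except KeyError:
        raise KeyError(f"subfamily {subfamily!r} missing from {what}") from None


def summarize_discordance(
    pairs: Iterable[TEPair],
    family_map: Mapping[str, str],
    type_map: Mapping[str, str],
    types: Sequence[str] | None = None,
) -> DiscordanceSummary:
    """Tabulate discordance per family and per subfamily type.

    The per-family table counts each pair once (per family touched) and
    reports ``percent_discordant = 100 * n_discordant / n_pairs``. The
    cross table has one row per type in ``types`` (default: every type
    seen): concordant pairs count once in their type's row; a discordant
    pair whose members fall in two different rows is listed in both
    (this is the double counting that makes row mismatch percents exceed
    the family-level rate); partners outside the tracked types fall in
    the ``other`` column. Rows with no pairs are omitted.
    """
    pairs = [p if p.concordant is not None else label_concordance(p) for p in pairs]

    fam_counts: dict[str, list[int]] = {}
    for pair in pairs:
        fams = {
            _lookup(family_map, pair.anno_a.subfamily, "family_map"),
            _lookup(family_map, pair.anno_b.subfamily, "family_map"),
        }
        for fam in fams:
            n = fam_counts.setdefault(fam, [0, 0])
            n[0] += 1
            n[1] += 0 if pair.concordant else 1
    by_family = pd.DataFrame(
        [
            {
                "family": fam,
                "n_pairs": n,
                "n_discordant": d,
                "percent_discordant": 100.0 * d / n,
            }
            for fam, (n, d) in sorted(fam_counts.items())
            if n > 0
        ]
    )

    pair_types = [
        (
            _lookup(type_map, p.anno_a.subfamily, "type_map"),
            _lookup(type_map, p.anno_b.subfamily, "type_map"),
        )
        for p in pairs
    ]
    if types is None:
        types = sorted({t for ta_tb in pair_types for t in ta_tb})
    tracked = set(types)

    concordant = {t: 0 for t in types}
    cells = {t: {c: 0 for c in [*types, "other"]} for t in types}
    for pair, (ta, tb) in zip(pairs, pair_types):
        if pair.concordant:
            if ta in tracked:
                concordant[ta] += 1
            continue
        if ta == tb:
            if ta in tracked:
                cells[ta][ta] += 1
            continue
        if ta in tracked:
            cells[ta][tb if tb in tracked else "other"] += 1
        if tb in tracked:
            cells[tb][ta if ta in tracked else "other"] += 1

    rows = []
    for t in types:
        n_non = sum(cells[t].values())
        total = concordant[t] + n_non
        if total == 0:
            continue
        row = {"type": t, "concordant": concordant[t]}
        row.update({f"nonmatch_{c}": cells[t][c] for c in types})
        row["other"] = cells[t]["other"]
        row["mismatch_percent"] = 100.0 * n_non / total
        rows.append(row)
    cross_table = pd.DataFrame(rows)
    return DiscordanceSummary(by_family=by_family, cross_table=cross_table)
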