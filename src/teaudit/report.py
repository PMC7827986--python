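"""Whole-pipeline orchestration and confidence-distribution reporting.

``run_pipeline`` wires the stages together: simulate (or load) segment
pairs and annotations, annotate every TE copy against the library,
extract filtered replicate pairs, tabulate discordance, evaluate the
point-mutation drift model, scan pairs for recombination signatures,
and compare annotation-confidence distributions between concordant and
discordant pairs. Every number in the resulting bundle comes from a
stage output; the reporter recomputes nothing.

For each retained pair the *smallest-best-confidence* — the lower of
the two members' best-candidate confidences — serves as a proxy for the
confidence that both copies are correctly annotated. The concordant and
discordant distributions of this value are binned for display and
compared with an exact two-sample Kolmogorov–Smirnov statistic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from . import __version__
from .annotate import annotate_instance, confidence, infer_lambda, score_candidates
from .drift import aggregate_by_type, conversion_matrix
from .formats import (
    ScoringMatrix,
    SegmentAlignment,
    TEAnnotation,
    read_bed,
    read_scoring_matrix,
    read_segment_alignment,
)
from .pairing import DiscordanceSummary, TEPair, extract_te_pairs, label_concordance, summarize_discordance
from .recomb import RecombSummary, WindowScan, scan_pair, segment_identity, summarize_recombination
from .simgen import (
    SubfamilyLibrary,
    apply_gene_conversion,
    duplicate_with_divergence,
    make_subfamily_library,
    read_subfamily_fasta,
    simulate_instances,
)

logger = logging.getLogger("teaudit")


@dataclass
class PairConfidence:
    """Best-candidate confidences for the two members of a pair."""

    pair_id: str
    conf_a: float
    conf_b: float
    concordant: bool

    def __post_init__(self) -> None:
        for value in (self.conf_a, self.conf_b):
            if not 0.0 < value <= 1.0:
                raise ValueError(f"confidences must be in (0,1], got {value}")

    @property
    def smallest_best(self) -> float:
        return min(self.conf_a, self.conf_b)


def smallest_best_confidence(conf_a: float, conf_b: float) -> float:
    """The lower of the two members' best-candidate confidences."""
    return min(conf_a, conf_b)


@dataclass
class ConfidenceDistributions:
    bin_edges: np.ndarray
    concordant_fraction: np.ndarray
    discordant_fraction: np.ndarray
    ks_statistic: float | None
    ks_pvalue: float | None
    concordant_values: np.ndarray
    discordant_values: np.ndarray


def confidence_distributions(
    pairs: Sequence[PairConfidence], bin_width: float = 0.05
) -> ConfidenceDistributions:
    """Binned smallest-best-confidence distributions plus exact KS test.

    Histograms are normalized to sum to 1 within each group (binning is
    presentation-only); the KS statistic ``D = sup |F_disc - F_conc|``
    and its asymptotic p-value are computed on the raw values. If either
    group is empty the distributions are still produced and the KS
    comparison is skipped with a warning.
    """
    conc = np.array([p.smallest_best for p in pairs if p.concordant], dtype=float)
    disc = np.array([p.smallest_best for p in pairs if not p.concordant], dtype=float)
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)

    def _frac(values: np.ndarray) -> np.ndarray:
        if len(values) == 0:
            return np.zeros(len(edges) - 1)
        hist, _ = np.histogram(values, bins=edges)
        return hist / hist.sum()

    if len(conc) and len(disc):
        result = ks_2samp(disc, conc, method="asymp")
        ks_stat, ks_p = float(result.statistic), float(result.pvalue)
    else:
        warnings.warn("one confidence group is empty; KS comparison skipped")
        ks_stat = ks_p = None
    return ConfidenceDistributions(
        bin_edges=edges,
        concordant_fraction=_frac(conc),
        discordant_fraction=_frac(disc),
        ks_statistic=ks_stat,
        ks_pvalue=ks_p,
        concordant_values=conc,
        discordant_values=disc,
    )


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""

    discordance: DiscordanceSummary
    drift_types: pd.DataFrame
    drift_pairwise: pd.DataFrame
    recombination: RecombSummary
    confidences: ConfidenceDistributions
    pair_confidences: list[PairConfidence]
    pairs: list[TEPair]
    scans: list[WindowScan]
    filter_counts: dict[str, int]
    lambda_used: float
    metadata: dict


_DEFAULTS: dict = {
    "seed": 0,
    "simulate": {
        "ancestral_length": 300,
        "n_subfamilies": 6,
        "diagnostic_per_split": 4,
        "type_partition": 2,
        "identity": 0.95,
        "frequency": 1.0,
        "n_instances": 200,
        "post_dup_identity": 0.975,
        "flank_length": 500,
        "conversion": {"rate": 0.0, "tract_min": 50, "tract_max": 300},
    },
    "scoring": {"match": 2, "mismatch": -3, "mode": "positional"},
    "pairing": {"min_len": 50, "min_cov": 0.8, "max_indel_block": 30},
    "recomb": {"window": 100, "alpha": 0.001},
    "report": {"bin_width": 0.05},
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _ungapped_te_sequence(seg: SegmentAlignment, anno: TEAnnotation, copy: str) -> str:
    iv, row = (
        (seg.interval_a, seg.row_a) if copy == "a" else (seg.interval_b, seg.row_b)
    )
    ungapped = row.replace("-", "")
    start = anno.interval.start - iv.start
    return ungapped[start : start + len(anno.interval)]


def _load_inputs(config: dict):
    """Load segments, annotations, library and matrix from files."""
    inputs = config["inputs"]
    paths = {key: Path(inputs[key]) for key in ("library", "matrix", "segments_dir", "annotations")}
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input path(s): {missing}")
    library = read_subfamily_fasta(paths["library"], family=inputs.get("family", "TEfam"))
    matrix = read_scoring_matrix(paths["matrix"])
    segments = [
        read_segment_alignment(p)
        for p in sorted(paths["segments_dir"].glob("*.afa"))
        + sorted(paths["segments_dir"].glob("*.fa"))
    ]
    annotations = read_bed(paths["annotations"], family_map={r.name: library.family for r in library.records})
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for anno in annotations:
        by_chrom.setdefault(anno.interval.chrom, []).append(anno)
    seg_annos = [
        (seg, by_chrom.get(seg.interval_a.chrom, []), by_chrom.get(seg.interval_b.chrom, []))
        for seg in segments
    ]
    return library, matrix, seg_annos


def _simulate_inputs(config: dict):
    sim = config["simulate"]
    seed = int(config["seed"])
    library = make_subfamily_library(
        ancestral_length=sim["ancestral_length"],
        n_subfamilies=sim["n_subfamilies"],
        diagnostic_per_split=sim["diagnostic_per_split"],
        type_partition=sim["type_partition"],
        seed=seed,
        identity=sim["identity"],
        frequency=sim["frequency"],
    )
    instances, truths = simulate_instances(library, sim["n_instances"], seed=seed + 1)
    seg_pairs = duplicate_with_divergence(
        instances,
        post_dup_identity=sim["post_dup_identity"],
        flank_length=sim["flank_length"],
        seed=seed + 2,
    )
    conv = sim["conversion"]
    if conv["rate"] > 0:
        donor_pool = [(seq, anno.subfamily) for seq, anno in instances]
        rng = np.random.default_rng(seed + 3)
        sub_seeds = rng.integers(0, 2**31 - 1, size=len(seg_pairs))
        seg_pairs = [
            apply_gene_conversion(
                pair,
                donor_pool,
                tract_range=(conv["tract_min"], conv["tract_max"]),
                rate=conv["rate"],
                seed=int(sub_seed),
                truth=truth,
            )[0]
            for pair, truth, sub_seed in zip(seg_pairs, truths, sub_seeds)
        ]
    seg_annos = [(seg, [annos[0]], [annos[1]]) for seg, annos in seg_pairs]
    return library, seg_annos, truths


def run_pipeline(config: Mapping | None = None) -> ReportBundle:
    """Execute the full audit. Bit-reproducible given (config, seed)."""
    config = _merge(_DEFAULTS, config or {})
    truths = None
    if "inputs" in config:
        library, matrix, seg_annos = _load_inputs(config)
    else:
        library, seg_annos, truths = _simulate_inputs(config)
        matrix = ScoringMatrix.from_match_mismatch(
            config["scoring"]["match"], config["scoring"]["mismatch"]
        )
    lam = infer_lambda(matrix)
    mode = config["scoring"]["mode"]
    logger.info("lambda inferred from scoring matrix: %.6f", lam)

    # --- annotate every TE copy against the library -----------------------
    conf_by_source: dict[str, float] = {}
    observed: list[tuple[SegmentAlignment, list[TEAnnotation], list[TEAnnotation]]] = []
    for seg, annos_a, annos_b in seg_annos:
        obs_a, obs_b = [], []
        for copy, annos, out in (("a", annos_a, obs_a), ("b", annos_b, obs_b)):
            for anno in annos:
                seq = _ungapped_te_sequence(seg, anno, copy)
                candidates = score_candidates(seq, library, matrix, mode=mode)
                obs = annotate_instance(
                    candidates,
                    family=library.family,
                    interval=anno.interval,
                    source_id=anno.source_id or f"{seg.id}{copy}",
                )
                cset = confidence(candidates, lam)
                conf_by_source[obs.source_id] = cset.confidences[cset.best]
                divergence = 1.0 - (
                    sum(x == y for x, y in zip(seq, library[obs.subfamily].consensus))
                    / len(seq)
                    if len(seq) == len(library[obs.subfamily].consensus)
                    else 0.0
                )
                obs.divergence = max(0.0, min(1.0, divergence))
                out.append(obs)
        observed.append((seg, obs_a, obs_b))

    # --- pair extraction and discordance ----------------------------------
    pairing_cfg = config["pairing"]
    kept: list[TEPair] = []
    kept_segments: list[SegmentAlignment] = []
    dropped: list[TEPair] = []
    for seg, obs_a, obs_b in observed:
        seg_kept = extract_te_pairs(
            seg,
            obs_a,
            obs_b,
            min_len=pairing_cfg["min_len"],
            min_cov=pairing_cfg["min_cov"],
            max_indel_block=pairing_cfg["max_indel_block"],
            dropped=dropped,
        )
        kept.extend(label_concordance(p) for p in seg_kept)
        kept_segments.extend([seg] * len(seg_kept))
    filter_counts = {rule: 0 for rule in ("multiplicity", "min_length", "coverage", "contiguity", "ambiguity")}
    for pair in dropped:
        for rule in pair.failed_rules():
            filter_counts[rule] += 1
    logger.info("pairs kept: %d, dropped: %d (%s)", len(kept), len(dropped), filter_counts)

    family_map = {name: library.family for name in library.names}
    type_map = library.type_map()
    discordance = summarize_discordance(kept, family_map, type_map)

    # --- drift model -------------------------------------------------------
    drift_matrix = conversion_matrix(library)
    drift_types = aggregate_by_type(drift_matrix, library.frequency_map(), type_map)

    # --- recombination scan ------------------------------------------------
    recomb_cfg = config["recomb"]
    scans = [
        scan_pair(seg, pair, window=recomb_cfg["window"], alpha=recomb_cfg["alpha"])
        for seg, pair in zip(kept_segments, kept)
    ]
    recombination = summarize_recombination(list(zip(kept, scans)), type_map)

    # --- confidence comparison --------------------------------------------
    pair_confidences = [
        PairConfidence(
            pair_id=f"{pair.anno_a.source_id}|{pair.anno_b.source_id}",
            conf_a=conf_by_source[pair.anno_a.source_id],
            conf_b=conf_by_source[pair.anno_b.source_id],
            concordant=bool(pair.concordant),
        )
        for pair in kept
    ]
    conf_dists = confidence_distributions(
        pair_confidences, bin_width=config["report"]["bin_width"]
    )

    metadata = {
        "config": json.loads(json.dumps(config, default=str)),
        "seed": config["seed"],
        "version": __version__,
        "n_segments": len(seg_annos),
        "n_pairs_kept": len(kept),
        "n_pairs_dropped": len(dropped),
    }
    return ReportBundle(
        discordance=discordance,
        drift_types=drift_types,
        drift_pairwise=drift_matrix.pairwise,
        recombination=recombination,
        confidences=conf_dists,
        pair_confidences=pair_confidences,
        pairs=kept,
        scans=scans,
        filter_counts=filter_counts,
        lambda_used=lam,
        metadata=metadata,
    )


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write the bundle as TSV tables plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.discordance.by_family.to_csv(outdir / "discordance.tsv", sep="\t", index=False)
    bundle.discordance.cross_table.to_csv(outdir / "cross_table.tsv", sep="\t", index=False)
    bundle.drift_pairwise.to_csv(outdir / "drift_pairwise.tsv", sep="\t")
    bundle.drift_types.to_csv(outdir / "drift_types.tsv", sep="\t", index=False)
    bundle.recombination.table.to_csv(outdir / "recomb.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "pair_id": pc.pair_id,
                "conf_a": pc.conf_a,
                "conf_b": pc.conf_b,
                "smallest_best": pc.smallest_best,
                "concordant": pc.concordant,
            }
            for pc in bundle.pair_confidences
        ]
    ).to_csv(outdir / "confidence.tsv", sep="\t", index=False)

    conc, disc = bundle.confidences.concordant_values, bundle.confidences.discordant_values
    summary = {
        "metadata": bundle.metadata,
        "lambda": bundle.lambda_used,
        "filter_counts": bundle.filter_counts,
        "n_flagged_recombination": int(sum(s.flagged for s in bundle.scans)),
        "ks_statistic": bundle.confidences.ks_statistic,
        "ks_pvalue": bundle.confidences.ks_pvalue,
        "median_smallest_best_concordant": float(np.median(conc)) if len(conc) else None,
        "median_smallest_best_discordant": float(np.median(disc)) if len(disc) else None,
        "discordance": bundle.discordance.by_family.to_dict(orient="records"),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
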