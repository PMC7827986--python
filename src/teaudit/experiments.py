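"""Calibration experiments for the audit's statistical machinery.

Each function runs one self-contained simulation-based check at a
stated problem size and returns the measured quantities, so both the
test suite and reporting scripts can execute the same procedures:

* false-positive rate of the recombination scan under the null
  (duplicated pairs with uniform divergence, no gene conversion);
* power of the scan against injected gene-conversion tracts;
* agreement of the empirical subfamily flip rate with the closed-form
  drift model when instances are annotated by diagnostic-site majority;
* lambda recovery error for scoring matrices with a known scale factor.
"""

from __future__ import annotations

import numpy as np

from .annotate import infer_lambda, matrix_with_lambda
from .drift import conversion_prob
from .pairing import extract_te_pairs
from .recomb import scan_pair, segment_identity
from .simgen import (
    apply_gene_conversion,
    duplicate_with_divergence,
    make_subfamily_library,
    mutate,
    seq_to_ints,
    ints_to_seq,
    simulate_instances,
)


def _simulated_pairs(
    n_pairs: int,
    te_length: int,
    flank_length: int,
    instance_identity: float,
    post_dup_identity: float,
    seed: int,
):
    library = make_subfamily_library(
        ancestral_length=te_length,
        n_subfamilies=1,
        identity=instance_identity,
        seed=seed,
    )
    instances, _ = simulate_instances(library, n_pairs, seed=seed + 1)
    pairs = duplicate_with_divergence(
        instances,
        post_dup_identity=post_dup_identity,
        flank_length=flank_length,
        seed=seed + 2,
    )
    return instances, pairs


def _flag_fraction(seg_pairs, window: int, alpha: float) -> float:
    flagged = 0
    for seg, (anno_a, anno_b) in seg_pairs:
        (pair,) = extract_te_pairs(seg, [anno_a], [anno_b])
        scan = scan_pair(seg, pair, window=window, alpha=alpha)
        flagged += scan.flagged
    return flagged / len(seg_pairs)


def recomb_null_rate(
    n_pairs: int = 2000,
    te_length: int = 400,
    flank_length: int = 2000,
    instance_identity: float = 0.95,
    post_dup_identity: float = 0.975,
    window: int = 100,
    alpha: float = 0.001,
    seed: int = 0,
) -> float:
    """Fraction of uniformly diverged pairs (no gene conversion) flagged
    by the windowed scan; Bonferroni bounds the expectation by alpha."""
    _, pairs = _simulated_pairs(
        n_pairs, te_length, flank_length, instance_identity, post_dup_identity, seed
    )
    return _flag_fraction(pairs, window, alpha)


def recomb_power_rate(
    n_pairs: int = 500,
    te_length: int = 400,
    flank_length: int = 2000,
    instance_identity: float = 0.95,
    post_dup_identity: float = 0.975,
    tract_length: int = 200,
    donor_divergence: float = 0.2,
    window: int = 100,
    alpha: float = 0.001,
    seed: int = 0,
) -> float:
    """Fraction of pairs flagged after a gene-conversion tract from a
    donor diverged by ``donor_divergence`` is injected into one copy.

    With the tract at least twice the window length, some full window
    always lies inside the converted region, where expected identity is
    depressed far below the segment background.
    """
    instances, pairs = _simulated_pairs(
        n_pairs, te_length, flank_length, instance_identity, post_dup_identity, seed
    )
    rng = np.random.default_rng(seed + 3)
    converted = []
    for (seq, _anno), pair in zip(instances, pairs):
        donor = ints_to_seq(mutate(rng, seq_to_ints(seq), donor_divergence))
        new_pair, _ = apply_gene_conversion(
            pair,
            [(donor, "donor")],
            tract_range=(tract_length, tract_length),
            rate=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        converted.append(new_pair)
    return _flag_fraction(converted, window, alpha)


def drift_flip_rate(
    n_instances: int = 100_000,
    n_sites: int = 10,
    p_a: float = 0.85,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Empirical vs modeled subfamily flip rate.

    Simulates instances of one subfamily whose sibling differs at
    ``n_sites`` diagnostic positions, annotates each instance by
    strict diagnostic-site majority (ties keep the original label), and
    compares the flip frequency with the closed-form conversion
    probability. Returns ``(empirical, expected, binomial_se)``.
    """
    library = make_subfamily_library(
        ancestral_length=max(50, 6 * n_sites),
        n_subfamilies=2,
        diagnostic_per_split=n_sites,
        identity=p_a,
        frequency=[1.0, 0.0],
        seed=seed,
    )
    cons_i = seq_to_ints(library["SF01"].consensus)
    cons_j = seq_to_ints(library["SF02"].consensus)
    sites = np.nonzero(cons_i != cons_j)[0]
    instances, _ = simulate_instances(library, n_instances, seed=seed + 1)
    observed = np.stack([seq_to_ints(seq)[sites] for seq, _ in instances])
    n_match_j = (observed == cons_j[sites]).sum(axis=1)
    n_match_i = (observed == cons_i[sites]).sum(axis=1)
    empirical = float((n_match_j > n_match_i).mean())
    expected = conversion_prob(n_sites, p_a)
    se = float(np.sqrt(expected * (1 - expected) / n_instances))
    return empirical, expected, se


def lambda_recovery_max_error(
    lambda0s=(1.0, 5.0, 10.0),
    n_draws: int = 5,
    seed: int = 0,
) -> float:
    """Worst relative error recovering a known scale factor from
    randomly constructed log-odds matrices (see
    :func:`teaudit.annotate.matrix_with_lambda`)."""
    worst = 0.0
    for lambda0 in lambda0s:
        for draw in range(n_draws):
            matrix, background = matrix_with_lambda(lambda0, seed=seed + draw)
            lam = infer_lambda(matrix, background)
            worst = max(worst, abs(lam - lambda0) / lambda0)
    return worst
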