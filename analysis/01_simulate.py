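#!/usr/bin/env python
"""Materialize the synthetic study dataset.

Generates the subfamily library, the diverged TE instances, the
duplicated segments (with gene conversion applied at the study rate),
and full ground truth, and writes them under results/sim/ for
inspection. The downstream scripts regenerate the same dataset
deterministically from the shared config.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study_config import RESULTS, STUDY

from teaudit.simgen import (
    apply_gene_conversion,
    duplicate_with_divergence,
    make_subfamily_library,
    simulate_instances,
    write_simulation,
)


def main() -> None:
    sim = STUDY["simulate"]
    seed = STUDY["seed"]
    library = make_subfamily_library(
        ancestral_length=sim["ancestral_length"],
        n_subfamilies=sim["n_subfamilies"],
        diagnostic_per_split=sim["diagnostic_per_split"],
        type_partition=sim["type_partition"],
        identity=sim["identity"],
        seed=seed,
    )
    instances, truths = simulate_instances(library, sim["n_instances"], seed=seed + 1)
    pairs = duplicate_with_divergence(
        instances,
        post_dup_identity=sim["post_dup_identity"],
        flank_length=sim["flank_length"],
        seed=seed + 2,
    )
    conv = sim["conversion"]
    donors = [(seq, anno.subfamily) for seq, anno in instances]
    rng = np.random.default_rng(seed + 3)
    sub_seeds = rng.integers(0, 2**31 - 1, size=len(pairs))
    pairs = [
        apply_gene_conversion(
            pair,
            donors,
            tract_range=(conv["tract_min"], conv["tract_max"]),
            rate=conv["rate"],
            seed=int(s),
            truth=truth,
        )[0]
        for pair, truth, s in zip(pairs, truths, sub_seeds)
    ]
    outdir = RESULTS / "sim"
    write_simulation(outdir, library, pairs, truths)

    n_converted = sum(bool(t.conversion_events) for t in truths)
    print(f"library: {len(library)} subfamilies "
          f"({dict((r.name, r.type_label) for r in library.records)})")
    print(f"instances: {len(instances)} at identity {sim['identity']}")
    print(f"segments: {len(pairs)} two-copy duplications, "
          f"{n_converted} with a gene-conversion tract")
    print(f"written to {outdir}")


if __name__ == "__main__":
    main()
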