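"""Shared study conditions for the numbered analysis scripts.

One synthetic "genome": a family of 4 subfamilies in 2 types, with a
clique structure (only 2 diagnostic sites per split) so that point
mutation and gene conversion can realistically flip subfamily calls.
Instances are 15% diverged from their consensus (an old-ish family);
each is duplicated once inside a 1.3 kb segment and the copies diverge
a further ~2% each; 5% of pairs receive a gene-conversion tract from a
random cousin instance.
"""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = {
    "seed": 20260930,
    "simulate": {
        "ancestral_length": 300,
        "n_subfamilies": 4,
        "diagnostic_per_split": 2,
        "type_partition": 2,
        "identity": 0.85,
        "n_instances": 1000,
        "post_dup_identity": 0.98,
        "flank_length": 500,
        "conversion": {"rate": 0.05, "tract_min": 100, "tract_max": 250},
    },
    "scoring": {"match": 2, "mismatch": -3, "mode": "positional"},
}
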