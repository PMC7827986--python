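"""Synthetic TE data with full ground truth.

The generator emulates the processes that create replicate TE pairs in a
real genome: a subfamily library diverges along a tree with a fixed
number of diagnostic substitutions per split; TE instances accumulate
independent point mutations after insertion; a segment around an
instance is duplicated once and both copies diverge further; and a gene
conversion event may overwrite a tract of one copy with the homologous
region of a donor element.

The default mutation model is substitution-only, i.i.d. across sites and
uniform over the three alternative nucleotides, so duplicated copies
stay positionally aligned and can be emitted as gapless two-row
alignments. Everything is reproducible bit-exactly from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .formats import (
    GenomeInterval,
    SegmentAlignment,
    TEAnnotation,
    write_bed,
    write_segment_alignment,
)

_NUC_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BYTE_TO_INT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BYTE_TO_INT[_b] = _i


def seq_to_ints(seq: str) -> np.ndarray:
    arr = _BYTE_TO_INT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted(set(seq) - set("ACGT"))
        raise ValueError(f"sequence contains non-ACGT letters: {bad}")
    return arr.astype(np.int64)

def ints_to_seq(arr: np.ndarray) -> str:
    return _NUC_BYTES[arr].tobytes().decode()


@dataclass
class SubfamilyRecord:
    """One subfamily: consensus, coarse type, genome weight, identity.

    ``identity`` is the target mean identity of instances to the
    consensus (the per-site probability that a site is unmutated since
    insertion); ``frequency`` is a nonnegative genome-frequency weight.
    """

    name: str
    type_label: str
    consensus: str
    frequency: float = 1.0
    identity: float = 0.95

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.name}: consensus must be non-empty")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.name}: identity must be in [0,1]")
        if self.frequency < 0:
            raise ValueError(f"{self.name}: frequency must be nonnegative")


@dataclass
class SubfamilyLibrary:
    """Named subfamily consensuses plus their ancestry tree."""

    records: list[SubfamilyRecord]
    ancestry: dict[str, str | None]
    family: str = "TEfam"

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("subfamily names must be unique")
        if self.records and sum(r.frequency for r in self.records) <= 0:
            raise ValueError("subfamily frequencies must sum to > 0")
        self._by_name = {r.name: r for r in self.records}

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def __getitem__(self, name: str) -> SubfamilyRecord:
        return self._by_name[name]

    def __len__(self) -> int:
        return len(self.records)

    def type_map(self) -> dict[str, str]:
        return {r.name: r.type_label for r in self.records}

    def frequency_map(self) -> dict[str, float]:
        return {r.name: r.frequency for r in self.records}

    def identity_map(self) -> dict[str, float]:
        return {r.name: r.identity for r in self.records}

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                parent = self.ancestry.get(r.name)
                fh.write(
                    f">{r.name} type={r.type_label} frequency={r.frequency:g} "
                    f"identity={r.identity:g} parent={parent or '.'}\n{r.consensus}\n"
                )


def read_subfamily_fasta(path: str | Path, family: str = "TEfam") -> SubfamilyLibrary:
    """Read a library written by :meth:`SubfamilyLibrary.write_fasta`."""
    records: list[SubfamilyRecord] = []
    ancestry: dict[str, str | None] = {}
    name, meta, seq_parts = None, {}, []

    def _flush() -> None:
        if name is None:
            return
        records.append(
            SubfamilyRecord(
                name=name,
                type_label=meta.get("type", "T1"),
                consensus="".join(seq_parts),
                frequency=float(meta.get("frequency", 1.0)),
                identity=float(meta.get("identity", 0.95)),
            )
        )
        parent = meta.get("parent", ".")
        ancestry[name] = None if parent == "." else parent

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            _flush()
            head = line[1:].split()
            name = head[0]
            meta = dict(part.split("=", 1) for part in head[1:] if "=" in part)
            seq_parts = []
        elif line.strip():
            seq_parts.append(line.strip().upper())
    _flush()
    return SubfamilyLibrary(records, ancestry, family=family)


@dataclass
class TruthRecord:
    """Ground truth for one simulated TE instance."""

    instance_id: str
    true_subfamily: str
    realized_divergence: float
    conversion_events: list[tuple[str, tuple[int, int]]] = field(default_factory=list)


def _resolve_types(type_partition, n: int) -> list[str]:
    """Expand a type-partition spec into one label per subfamily.

    ``None`` puts everything in one type; an integer ``k`` cuts the
    subfamilies (in creation order) into ``k`` contiguous blocks named
    ``T1..Tk``; a sequence of labels is used verbatim.
    """
    if type_partition is None:
        return ["T1"] * n
    if isinstance(type_partition, int):
        if type_partition < 1:
            raise ValueError("type_partition must be >= 1")
        block = -(-n // type_partition)  # ceil
        return [f"T{i // block + 1}" for i in range(n)]
    labels = list(type_partition)
    if len(labels) != n:
        raise ValueError(f"type_partition lists {len(labels)} labels for {n} subfamilies")
    return labels


def mutate(rng: np.random.Generator, ints: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly to one
    of the 3 other nucleotides. Returns a new array."""
    out = ints.copy()
    mask = rng.random(len(ints)) < rate
    n_hit = int(mask.sum())
    if n_hit:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n_hit)) % 4
    return out


def make_subfamily_library(
    ancestral_length: int = 300,
    n_subfamilies: int = 6,
    diagnostic_per_split: int = 4,
    type_partition=None,
    seed: int = 0,
    identity: float | Sequence[float] = 0.95,
    frequency: float | Sequence[float] = 1.0,
    family: str = "TEfam",
) -> SubfamilyLibrary:
    """Grow a subfamily library along a random tree.

    Starting from a random ancestral consensus, each of the
    ``n_subfamilies - 1`` splits copies a randomly chosen existing
    subfamily and substitutes exactly ``diagnostic_per_split`` positions.
    Splits use disjoint position sets, so any two subfamilies differ at
    >= ``diagnostic_per_split`` sites and no diagnostic site is ever
    overwritten by a later split.
    """
    if ancestral_length < 50:
        raise ValueError("ancestral_length must be >= 50")
    if n_subfamilies < 1:
        raise ValueError("n_subfamilies must be >= 1")
    n_splits = n_subfamilies - 1
    if diagnostic_per_split * n_splits > ancestral_length:
        raise ValueError(
            f"infeasible: {n_splits} splits x {diagnostic_per_split} diagnostic "
            f"sites exceed ancestral length {ancestral_length}"
        )
    rng = np.random.default_rng(seed)
    identities = np.broadcast_to(np.asarray(identity, dtype=float), (n_subfamilies,))
    frequencies = np.broadcast_to(np.asarray(frequency, dtype=float), (n_subfamilies,))
    types = _resolve_types(type_partition, n_subfamilies)

    ancestral = rng.integers(0, 4, size=ancestral_length)
    site_pool = rng.permutation(ancestral_length)
    consensuses = [ancestral]
    names = [f"SF{1:02d}"]
    ancestry: dict[str, str | None] = {names[0]: None}
    for split in range(n_splits):
        parent_idx = int(rng.integers(0, len(consensuses)))
        sites = site_pool[split * diagnostic_per_split : (split + 1) * diagnostic_per_split]
        child = consensuses[parent_idx].copy()
        child[sites] = (child[sites] + rng.integers(1, 4, size=len(sites))) % 4
        child_name = f"SF{len(consensuses) + 1:02d}"
        ancestry[child_name] = names[parent_idx]
        names.append(child_name)
        consensuses.append(child)

    records = [
        SubfamilyRecord(
            name=names[i],
            type_label=types[i],
            consensus=ints_to_seq(consensuses[i]),
            frequency=float(frequencies[i]),
            identity=float(identities[i]),
        )
        for i in range(n_subfamilies)
    ]
    return SubfamilyLibrary(records, ancestry, family=family)


def simulate_instances(
    library: SubfamilyLibrary,
    n_instances: int,
    seed: int = 0,
) -> tuple[list[tuple[str, TEAnnotation]], list[TruthRecord]]:
    """Draw diverged TE instances from the library.

    Each instance picks a subfamily with probability proportional to its
    frequency, then substitutes every site independently with
    probability ``1 - identity`` (uniform over the 3 alternatives). No
    indels are introduced. Returns ``(instances, truth)`` where each
    instance is ``(sequence, annotation)`` carrying the true subfamily.
    """
    if n_instances < 0:
        raise ValueError("n_instances must be >= 0")
    rng = np.random.default_rng(seed)
    freqs = np.array([r.frequency for r in library.records], dtype=float)
    probs = freqs / freqs.sum()
    choices = rng.choice(len(library.records), size=n_instances, p=probs)

    instances: list[tuple[str, TEAnnotation]] = []
    truths: list[TruthRecord] = []
    consensus_ints = [seq_to_ints(r.consensus) for r in library.records]
    for i, idx in enumerate(choices):
        record = library.records[idx]
        seq_ints = mutate(rng, consensus_ints[idx], 1.0 - record.identity)
        divergence = float((seq_ints != consensus_ints[idx]).mean())
        instance_id = f"inst{i:06d}"
        anno = TEAnnotation(
            interval=GenomeInterval(instance_id, 0, len(seq_ints)),
            family=library.family,
            subfamily=record.name,
            divergence=divergence,
            source_id=instance_id,
        )
        instances.append((ints_to_seq(seq_ints), anno))
        truths.append(TruthRecord(instance_id, record.name, divergence))
    return instances, truths


def duplicate_with_divergence(
    instances: Sequence[tuple[str, TEAnnotation]],
    post_dup_identity: float = 0.95,
    flank_length: int = 500,
    seed: int = 0,
    family: str | None = None,
) -> list[tuple[SegmentAlignment, tuple[TEAnnotation, TEAnnotation]]]:
    """Duplicate each instance (plus random flanks) and diverge the copies.

    The TE plus uniform-random flanks forms a segment that is duplicated
    once; both copies are then substituted independently at rate
    ``1 - post_dup_identity`` across the whole segment (flanks included,
    so identity is consistent along the segment). Output is a gapless
    two-row alignment per instance with truth-labeled annotations for
    both copies at ``[flank_length, flank_length + te_length)``.
    """
    if not 0.0 <= post_dup_identity <= 1.0:
        raise ValueError("post_dup_identity must be in [0,1]")
    rng = np.random.default_rng(seed)
    rate = 1.0 - post_dup_identity
    pairs: list[tuple[SegmentAlignment, tuple[TEAnnotation, TEAnnotation]]] = []
    for i, (seq, anno) in enumerate(instances):
        te = seq_to_ints(seq)
        left = rng.integers(0, 4, size=flank_length)
        right = rng.integers(0, 4, size=flank_length)
        template = np.concatenate([left, te, right])
        copy_a = mutate(rng, template, rate)
        copy_b = mutate(rng, template, rate)
        seg_id = f"seg{i:06d}"
        seg = SegmentAlignment(
            id=seg_id,
            interval_a=GenomeInterval(f"{seg_id}a", 0, len(template)),
            interval_b=GenomeInterval(f"{seg_id}b", 0, len(template)),
            row_a=ints_to_seq(copy_a),
            row_b=ints_to_seq(copy_b),
        )
        te_annos = tuple(
            TEAnnotation(
                interval=GenomeInterval(f"{seg_id}{copy}", flank_length, flank_length + len(te)),
                family=family if family is not None else anno.family,
                subfamily=anno.subfamily,
                source_id=f"{anno.source_id}/{copy}",
            )
            for copy in ("a", "b")
        )
        pairs.append((seg, te_annos))
    return pairs


def apply_gene_conversion(
    pair: tuple[SegmentAlignment, tuple[TEAnnotation, TEAnnotation]],
    donor_pool: Sequence[tuple[str, str]],
    tract_range: tuple[int, int] = (50, 300),
    rate: float = 1.0,
    seed: int = 0,
    truth: TruthRecord | None = None,
) -> tuple[tuple[SegmentAlignment, tuple[TEAnnotation, TEAnnotation]], TruthRecord | None]:
    """Maybe overwrite a tract of one TE copy with a donor's homologous region.

    With probability ``rate``, a tract of uniform length in
    ``tract_range`` is placed uniformly inside one randomly chosen TE
    copy and replaced by the same TE-relative coordinates of a donor
    drawn from ``donor_pool`` (a list of ``(sequence, subfamily)``).
    The event is appended to ``truth.conversion_events``.
    """
    if tract_range[0] < 1:
        raise ValueError("tract_range minimum must be >= 1")
    if not donor_pool:
        raise ValueError("donor_pool must be non-empty")
    seg, (anno_a, anno_b) = pair
    rng = np.random.default_rng(seed)
    if rng.random() >= rate:
        return pair, truth
    if "-" in seg.row_a or "-" in seg.row_b:
        raise NotImplementedError("gene conversion requires gapless segment alignments")
    te_len = len(anno_a.interval)
    tmin, tmax = tract_range
    if tmin > te_len:
        raise ValueError(f"infeasible: minimum tract {tmin} exceeds TE length {te_len}")
    tract_len = int(rng.integers(tmin, min(tmax, te_len) + 1))
    start = int(rng.integers(0, te_len - tract_len + 1))
    which = int(rng.integers(0, 2))
    donor_seq, donor_subfamily = donor_pool[int(rng.integers(0, len(donor_pool)))]
    if len(donor_seq) < start + tract_len:
        raise ValueError("donor shorter than required tract coordinates")

    anno = (anno_a, anno_b)[which]
    iv = (seg.interval_a, seg.interval_b)[which]
    row = (seg.row_a, seg.row_b)[which]
    offset = anno.interval.start - iv.start
    new_row = (
        row[: offset + start]
        + donor_seq[start : start + tract_len]
        + row[offset + start + tract_len :]
    )
    new_seg = SegmentAlignment(
        id=seg.id,
        interval_a=seg.interval_a,
        interval_b=seg.interval_b,
        row_a=new_row if which == 0 else seg.row_a,
        row_b=new_row if which == 1 else seg.row_b,
    )
    if truth is not None:
        truth.conversion_events.append((donor_subfamily, (start, start + tract_len)))
    return (new_seg, (anno_a, anno_b)), truth


def write_truth_table(truths: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("instance_id\ttrue_subfamily\trealized_divergence\tconversion_events\n")
        for t in truths:
            events = ";".join(
                f"{donor}:{start}-{end}" for donor, (start, end) in t.conversion_events
            )
            fh.write(
                f"{t.instance_id}\t{t.true_subfamily}\t{t.realized_divergence:.6f}\t{events or '.'}\n"
            )


def write_simulation(
    outdir: str | Path,
    library: SubfamilyLibrary,
    pairs: Sequence[tuple[SegmentAlignment, tuple[TEAnnotation, TEAnnotation]]],
    truths: Sequence[TruthRecord],
) -> None:
    """Write library FASTA, per-segment aligned FASTA, truth BED and TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    segdir = outdir / "segments"
    segdir.mkdir(exist_ok=True)
    library.write_fasta(outdir / "library.fa")
    annos: list[TEAnnotation] = []
    for seg, (anno_a, anno_b) in pairs:
        write_segment_alignment(seg, segdir / f"{seg.id}.afa")
        annos.extend([anno_a, anno_b])
    write_bed(annos, outdir / "truth_annotations.bed")
    write_truth_table(truths, outdir / "truth.tsv")
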