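"""Core genomic types and readers/writers for external file formats.

Every coordinate held inside the package is 0-based half-open on the
forward strand. Conversions to and from each format's native convention
(e.g. RepeatMasker's 1-based inclusive columns) happen only in the
readers and writers defined here, so the rest of the package never needs
to think about off-by-one issues.

Supported formats:

* RepeatMasker ``.out`` annotation tables (read)
* BED6 annotation intervals (read/write)
* pairwise aligned FASTA for segmental duplications (read/write)
* square integer scoring matrices with an alphabet header (read/write)
* flat YAML config files (read)
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Marker used for annotations that name a family but no specific subfamily.
AMBIGUOUS = "AMBIGUOUS"

#: Repeat names that denote a bare family with no subfamily resolution.
DEFAULT_AMBIGUOUS_NAMES = frozenset({"Alu", "L1"})

GAP = "-"
_COORD_RE = re.compile(r"(?P<chrom>[^\s:]+):(?P<start>\d+)-(?P<end>\d+)\((?P<strand>[+-])\)")


class FormatError(ValueError):
    """An input file violates its format contract."""


@dataclass(frozen=True)
class GenomeInterval:
    """Half-open genomic interval: ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Length of the bp overlap with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TEAnnotation:
    """A transposable-element interval with its subfamily call.

    ``subfamily`` is either a concrete subfamily name (e.g. ``AluSx``) or
    the :data:`AMBIGUOUS` marker when the source record named only a
    family. ``divergence`` is the mismatch fraction to the assigned
    consensus, in [0, 1]. ``tie`` records whether adjudication between
    equal-scoring candidates was required to produce this call.
    """

    interval: GenomeInterval
    family: str
    subfamily: str
    score: float | None = None
    divergence: float | None = None
    source_id: str = ""
    tie: bool = False

    def __post_init__(self) -> None:
        if self.divergence is not None and not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"divergence must be in [0,1], got {self.divergence}")

    @property
    def is_ambiguous(self) -> bool:
        return self.subfamily == AMBIGUOUS


def _ungapped_len(row: str) -> int:
    return len(row) - row.count(GAP)


@dataclass
class SegmentAlignment:
    """A two-copy segmental duplication as a gapped pairwise alignment.

    ``row_a``/``row_b`` are equal-length gapped sequences over
    ``{A,C,G,T,N,-}``; ``interval_a``/``interval_b`` give the genomic
    span of each copy, whose length must equal the ungapped row length.
    No column may be a gap in both rows.
    """

    id: str
    interval_a: GenomeInterval
    interval_b: GenomeInterval
    row_a: str
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise FormatError(
                f"segment {self.id}: rows differ in length "
                f"({len(self.row_a)} vs {len(self.row_b)})"
            )
        for label, row, iv in (("a", self.row_a, self.interval_a), ("b", self.row_b, self.interval_b)):
            if _ungapped_len(row) != len(iv):
                raise FormatError(
                    f"segment {self.id}: ungapped length of row {label} "
                    f"({_ungapped_len(row)}) does not match its interval ({len(iv)})"
                )
        for col, (x, y) in enumerate(zip(self.row_a, self.row_b)):
            if x == GAP and y == GAP:
                raise FormatError(f"segment {self.id}: column {col} is gap in both rows")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)


@dataclass
class ScoringMatrix:
    """Integer substitution scores over an ordered nucleotide alphabet.

    ``scores`` maps every ordered letter pair to an integer. Gap
    penalties are nonnegative magnitudes (a gap *costs* ``gap_open`` to
    start and ``gap_extend`` per additional position).
    """

    alphabet: tuple[str, ...]
    scores: dict[tuple[str, str], int]
    gap_open: int = 12
    gap_extend: int = 2

    def __post_init__(self) -> None:
        for a in self.alphabet:
            for b in self.alphabet:
                if (a, b) not in self.scores:
                    raise ValueError(f"score undefined for pair ({a},{b})")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be nonnegative")

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise ValueError(f"letter pair ({a},{b}) outside matrix alphabet") from None

    @property
    def max_score(self) -> int:
        return max(self.scores.values())

    def expected_score(self, background: Mapping[str, float]) -> float:
        """Expected pair score under independent background letters."""
        return sum(
            background[a] * background[b] * self.scores[(a, b)]
            for a in self.alphabet
            for b in self.alphabet
        )

    @classmethod
    def from_match_mismatch(
        cls,
        match: int,
        mismatch: int,
        alphabet: Sequence[str] = ("A", "C", "G", "T"),
        gap_open: int = 12,
        gap_extend: int = 2,
    ) -> "ScoringMatrix":
        scores = {
            (a, b): (match if a == b else mismatch) for a in alphabet for b in alphabet
        }
        return cls(tuple(alphabet), scores, gap_open, gap_extend)


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def _resolve_subfamily(name: str, family: str, ambiguous_names: Iterable[str]) -> str:
    if name == family or name in ambiguous_names:
        return AMBIGUOUS
    return name


def read_repeatmasker_out(
    path: str | Path,
    ambiguous_names: Iterable[str] = DEFAULT_AMBIGUOUS_NAMES,
) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` table into annotations.

    The three header lines are skipped. 1-based inclusive coordinates
    become 0-based half-open; a ``C`` strand becomes ``-``; ``%div`` is
    converted to a fraction. Records whose repeat name equals the family
    (or is listed in ``ambiguous_names``) are flagged :data:`AMBIGUOUS`.
    The family is the part of the class/family column after the slash.
    """
    lines = Path(path).read_text().splitlines()
    annotations: list[TEAnnotation] = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 14:
            raise FormatError(
                f"{path}: line {lineno}: expected >= 14 columns, got {len(fields)}"
            )
        try:
            score = float(fields[0])
            divergence = float(fields[1]) / 100.0
            chrom = fields[4]
            begin = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
        strand_sym = fields[8]
        if strand_sym == "+":
            strand = "+"
        elif strand_sym in {"C", "-"}:
            strand = "-"
        else:
            raise FormatError(
                f"{path}: line {lineno}: unknown strand symbol {strand_sym!r}"
            )
        name = fields[9]
        class_family = fields[10]
        family = class_family.split("/")[-1] if class_family else name
        source_id = fields[14] if len(fields) > 14 else ""
        annotations.append(
            TEAnnotation(
                interval=GenomeInterval(chrom, begin - 1, end, strand),
                family=family,
                subfamily=_resolve_subfamily(name, family, ambiguous_names),
                score=score,
                divergence=divergence,
                source_id=source_id,
            )
        )
    return annotations


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    family_map: Mapping[str, str] | None = None,
    ambiguous_names: Iterable[str] = DEFAULT_AMBIGUOUS_NAMES,
) -> list[TEAnnotation]:
    """Read BED6 annotations (coordinates taken as-is, already half-open).

    The name column is either ``family/subfamily`` or a bare name. A bare
    name is resolved through ``family_map`` (subfamily -> family) when
    possible; otherwise it is treated as a family-only, AMBIGUOUS record.
    """
    annotations: list[TEAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(
                f"{path}: line {lineno}: BED6 requires >= 6 columns, got {len(fields)}"
            )
        chrom, start, end, name, score, strand = fields[:6]
        if "/" in name:
            family, sub = name.split("/", 1)
            subfamily = _resolve_subfamily(sub, family, ambiguous_names)
        elif family_map is not None and name in family_map:
            family = family_map[name]
            subfamily = _resolve_subfamily(name, family, ambiguous_names)
        else:
            family, subfamily = name, AMBIGUOUS
        annotations.append(
            TEAnnotation(
                interval=GenomeInterval(chrom, int(start), int(end), strand),
                family=family,
                subfamily=subfamily,
                score=None if score == "." else float(score),
                source_id=f"{Path(path).name}:{lineno}",
            )
        )
    return annotations


def write_bed(annotations: Iterable[TEAnnotation], path: str | Path) -> None:
    """Write annotations as BED6; name column is ``family/subfamily``."""
    with open(path, "w") as fh:
        for anno in annotations:
            name = anno.family if anno.is_ambiguous else f"{anno.family}/{anno.subfamily}"
            score = 0 if anno.score is None else anno.score
            score_str = str(int(score)) if float(score).is_integer() else str(score)
            iv = anno.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score_str}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Aligned FASTA segment pairs
# ---------------------------------------------------------------------------

def _parse_coord_header(text: str, path: str | Path) -> GenomeInterval:
    match = _COORD_RE.search(text)
    if match is None:
        raise FormatError(f"{path}: header {text!r} lacks 'chrom:start-end(strand)'")
    return GenomeInterval(
        match["chrom"], int(match["start"]), int(match["end"]), match["strand"]
    )


def read_segment_alignment(path: str | Path, seg_id: str | None = None) -> SegmentAlignment:
    """Read a two-record aligned FASTA describing one segmental duplication."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise FormatError(f"{path}: expected exactly 2 aligned records, got {len(records)}")
    iv_a = _parse_coord_header(records[0].description, path)
    iv_b = _parse_coord_header(records[1].description, path)
    return SegmentAlignment(
        id=seg_id if seg_id is not None else Path(path).stem,
        interval_a=iv_a,
        interval_b=iv_b,
        row_a=str(records[0].seq).upper(),
        row_b=str(records[1].seq).upper(),
    )


def write_segment_alignment(seg: SegmentAlignment, path: str | Path) -> None:
    records = []
    for iv, row in ((seg.interval_a, seg.row_a), (seg.interval_b, seg.row_b)):
        header = f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
        records.append(SeqRecord(Seq(row), id=header, description=seg.id))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Scoring matrix text format
# ---------------------------------------------------------------------------

def read_scoring_matrix(
    path: str | Path, gap_open: int = 12, gap_extend: int = 2
) -> ScoringMatrix:
    """Read a square integer scoring matrix.

    First non-comment row lists the alphabet; each following row is a
    letter label plus one integer per alphabet letter.
    """
    lines = [
        line for line in Path(path).read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty scoring matrix")
    alphabet = tuple(lines[0].split())
    rows = lines[1:]
    if len(rows) != len(alphabet):
        raise FormatError(
            f"{path}: non-square matrix ({len(rows)} rows for {len(alphabet)} letters)"
        )
    scores: dict[tuple[str, str], int] = {}
    seen: set[str] = set()
    for row in rows:
        fields = row.split()
        label = fields[0]
        if label not in alphabet:
            raise FormatError(f"{path}: row label {label!r} not in header alphabet")
        if label in seen:
            raise FormatError(f"{path}: duplicate row label {label!r}")
        seen.add(label)
        if len(fields) - 1 != len(alphabet):
            raise FormatError(
                f"{path}: row {label!r} has {len(fields) - 1} cells, expected {len(alphabet)}"
            )
        for letter, cell in zip(alphabet, fields[1:]):
            try:
                scores[(label, letter)] = int(cell)
            except ValueError:
                raise FormatError(f"{path}: non-integer cell {cell!r} in row {label!r}") from None
    return ScoringMatrix(alphabet, scores, gap_open, gap_extend)


def write_scoring_matrix(matrix: ScoringMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.alphabet) + "\n")
        for a in matrix.alphabet:
            cells = "\t".join(str(matrix.scores[(a, b)]) for b in matrix.alphabet)
            fh.write(f"{a}\t{cells}\n")


def load_config(path: str | Path) -> dict:
    """Load a (possibly nested) YAML key-value config file."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if config is None:
        return {}
    if not isinstance(config, dict):
        raise FormatError(f"{path}: config must be a key-value mapping")
    return config
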