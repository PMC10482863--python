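"""Time-ordered stitching of loop sequences into growing molecular intermediates.

A protein chain is annotated with loop structures, each labeled by the
N-terminal residue index of the loop in the reference chain (e.g. loop 34)
and carrying the age (nd) of its prototype.  Stitching concatenates, at
each time event, the sequences of all loops whose age does not exceed the
event, in positional (N -> C) order — yielding a series of growing
intermediates written ``34 | 34|213 | 34|80|213 | ...``.  Replacement
variants substitute one slot of an intermediate by alternative loops that
preserve the ascending positional order (the reshuffling experiment design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from efnet.io_formats import PrototypeId

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class LoopAnnotation:
    """One loop of the reference chain with its span, sequence, prototype and age."""

    label: int  # N-terminal residue index of the loop
    span: tuple[int, int]  # 1-based inclusive residue interval
    sequence: str
    prototype: PrototypeId | None
    age: float

    def __post_init__(self) -> None:
        lo, hi = self.span
        if lo < 1 or hi < lo:
            raise ValueError(f"loop {self.label}: invalid span {self.span}")
        if len(self.sequence) != hi - lo + 1:
            raise ValueError(
                f"loop {self.label}: sequence length {len(self.sequence)} != span length {hi - lo + 1}"
            )
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"loop {self.label}: non-amino characters {sorted(bad)}")
        if not 0.0 <= self.age <= 1.0:
            raise ValueError(f"loop {self.label}: age {self.age} outside [0, 1]")


@dataclass
class Intermediate:
    """A growing molecule: loops present at a time event, in positional order."""

    members: tuple[LoopAnnotation, ...]
    age: float

    @property
    def loop_sequence(self) -> str:
        return "|".join(str(m.label) for m in self.members)

    @property
    def amino_sequence(self) -> str:
        return "".join(m.sequence for m in self.members)

    def __str__(self) -> str:
        return f"{self.loop_sequence} (nd = {self.age:g})"


def _validate_annotations(annotations: list[LoopAnnotation]) -> list[LoopAnnotation]:
    if not annotations:
        raise ValueError("build_intermediates: empty annotation list")
    labels = [a.label for a in annotations]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate loop labels")
    by_pos = sorted(annotations, key=lambda a: a.span[0])
    for a, b in zip(by_pos, by_pos[1:]):
        if b.span[0] <= a.span[1]:
            raise ValueError(f"overlapping spans: loop {a.label} {a.span} and loop {b.label} {b.span}")
    return by_pos


def build_intermediates(annotations: list[LoopAnnotation]) -> list[Intermediate]:
    """Cumulative time-ordered intermediates, one per distinct loop age.

    The first intermediate holds the most primordial loop(s); each later one
    adds every loop whose age equals that event, keeping members in
    positional order; the last contains all loops.
    """
    by_pos = _validate_annotations(annotations)
    events = sorted({a.age for a in annotations})
    series = []
    for t in events:
        members = tuple(a for a in by_pos if a.age <= t)
        series.append(Intermediate(members=members, age=t))
    return series


def reshuffle_variants(
    base: Intermediate, slot: int, candidates: list[LoopAnnotation]
) -> list[Intermediate]:
    """Replace one slot of an intermediate by each admissible candidate loop.

    ``slot`` is 1-based over the members of ``base``.  A candidate is
    admissible when substituting it keeps the positional labels strictly
    ascending; inadmissible candidates are rejected (with the reason logged
    in the returned warning when none survive).
    """
    if not 1 <= slot <= len(base.members):
        raise ValueError(f"slot {slot} out of range 1..{len(base.members)}")
    variants = []
    for cand in candidates:
        members = list(base.members)
        members[slot - 1] = cand
        labels = [m.label for m in members]
        positions = [m.span[0] for m in members]
        if all(a < b for a, b in zip(labels, labels[1:])) and all(
            a < b for a, b in zip(positions, positions[1:])
        ):
            variants.append(Intermediate(members=tuple(members), age=base.age))
    if not variants:
        warnings.warn(f"reshuffle_variants: no admissible candidate for slot {slot}")
    return variants


def write_fasta_series(intermediates: list[Intermediate], path: str | Path) -> Path:
    """Write one FASTA record per intermediate (header: loop sequence and nd age)."""
    if not intermediates:
        raise ValueError("write_fasta_series: empty series")
    records = []
    for i, inter in enumerate(intermediates):
        seq = inter.amino_sequence.upper()
        bad = set(seq) - AMINO_ACIDS
        if bad:
            raise ValueError(f"intermediate {inter.loop_sequence}: non-amino characters {sorted(bad)}")
        records.append(
            SeqRecord(
                Seq(seq),
                id=f"intermediate_{i + 1}",
                description=f"loops={inter.loop_sequence} nd={inter.age:g}",
            )
        )
    path = Path(path)
    SeqIO.write(records, path, "fasta")
    return path


def read_annotations(path: str | Path) -> list[LoopAnnotation]:
    """Read a loop-annotation TSV (label, start, end, sequence, prototype, nd)."""
    import pandas as pd

    from efnet.io_formats import parse_prototype_id

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"label", "start", "end", "sequence", "nd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table {path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        proto = None
        if "prototype" in df.columns and not pd.isna(row["prototype"]):
            proto = parse_prototype_id(row["prototype"])
        out.append(
            LoopAnnotation(
                label=int(row["label"]),
                span=(int(row["start"]), int(row["end"])),
                sequence=row["sequence"],
                prototype=proto,
                age=float(row["nd"]),
            )
        )
    return out
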