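"""Identifier grammars, tabular input readers, and the nd<->Gy molecular clock.

Two identifier grammars are used throughout:

* loop prototypes, named ``METHOD.BRACING.LEN.CLASS.SUBCLASS`` (e.g.
  ``DS.HE.3.1.1``): a clustering-method token, the bracing secondary
  structures flanking the aperiodic loop region, the loop length in residues,
  and the conformational class / geometry subclass ranks;
* domains, named by SCOP concise classification strings (ccs) of the form
  ``class.fold.superfamily.family`` (e.g. ``c.2.1.2``).

Domain ages live on the relative *nd* scale in [0, 1] (0 = origin of
proteins, 1 = present) and convert to geological time in billions of years
(Gy) through a linear molecular clock of folds, anchored by default at
nd = 0 -> 3.8 Gy and nd = 1 -> 0 Gy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

logger = logging.getLogger(__name__)

#: the ten admissible bracing codes: H = alpha helix, E = beta strand,
#: G = 3-10 helix, BN/BK = beta-linked variants.
BRACING_CODES = frozenset({"HH", "HE", "EH", "HG", "GH", "GG", "EG", "GE", "BN", "BK"})


class ParseError(ValueError):
    """Malformed identifier or table field."""


@dataclass(frozen=True, order=True)
class PrototypeId:
    """Structured loop-prototype identifier (``DS.HE.3.1.1`` style)."""

    method: str
    bracing: str
    loop_length: int
    class_rank: int
    subclass_rank: int

    def __post_init__(self) -> None:
        if not self.method:
            raise ParseError("prototype id: empty method token")
        if self.bracing not in BRACING_CODES:
            raise ParseError(
                f"prototype id: unknown bracing code {self.bracing!r} "
                f"(expected one of {sorted(BRACING_CODES)})"
            )
        if self.loop_length < 0:
            raise ParseError("prototype id: loop_length must be >= 0")
        if self.class_rank < 1 or self.subclass_rank < 1:
            raise ParseError("prototype id: class/subclass ranks must be >= 1")

    def __str__(self) -> str:
        return (
            f"{self.method}.{self.bracing}.{self.loop_length}"
            f".{self.class_rank}.{self.subclass_rank}"
        )


@dataclass(frozen=True, order=True)
class DomainCcs:
    """SCOP concise classification string (``c.2.1.2`` style)."""

    scop_class: str
    fold: int
    superfamily: int
    family: int

    def __post_init__(self) -> None:
        if len(self.scop_class) != 1 or not self.scop_class.isalpha():
            raise ParseError(f"ccs: class must be a single letter, got {self.scop_class!r}")
        if min(self.fold, self.superfamily, self.family) < 1:
            raise ParseError("ccs: fold/superfamily/family must be positive integers")

    def __str__(self) -> str:
        return f"{self.scop_class}.{self.fold}.{self.superfamily}.{self.family}"


def _int_field(token: str, what: str, minimum: int) -> int:
    try:
        value = int(token)
    except ValueError:
        raise ParseError(f"{what}: non-integer component {token!r}") from None
    if value < minimum:
        raise ParseError(f"{what}: component {value} below minimum {minimum}")
    return value


def parse_prototype_id(s: str) -> PrototypeId:
    """Parse a dotted loop-prototype id; serializing the result round-trips."""
    if not s:
        raise ParseError("prototype id: empty string")
    parts = s.split(".")
    if len(parts) != 5:
        raise ParseError(f"prototype id {s!r}: expected 5 dot-separated fields, got {len(parts)}")
    method, bracing, length, cls, sub = parts
    return PrototypeId(
        method=method,
        bracing=bracing,
        loop_length=_int_field(length, f"prototype id {s!r} loop_length", 0),
        class_rank=_int_field(cls, f"prototype id {s!r} class_rank", 1),
        subclass_rank=_int_field(sub, f"prototype id {s!r} subclass_rank", 1),
    )


def parse_scop_ccs(s: str) -> DomainCcs:
    """Parse a SCOP concise classification string; round-trip identity holds."""
    if not s:
        raise ParseError("ccs: empty string")
    parts = s.split(".")
    if len(parts) != 4:
        raise ParseError(f"ccs {s!r}: expected class.fold.superfamily.family (4 fields)")
    cls, fold, sf, fam = parts
    return DomainCcs(
        scop_class=cls,
        fold=_int_field(fold, f"ccs {s!r} fold", 1),
        superfamily=_int_field(sf, f"ccs {s!r} superfamily", 1),
        family=_int_field(fam, f"ccs {s!r} family", 1),
    )


@dataclass
class MappingRecord:
    loop: PrototypeId
    domain: DomainCcs
    evalue: float | None = None


@dataclass
class MappingTable:
    """Deduplicated loop<->domain association records, optionally e-value filtered."""

    records: list[MappingRecord]
    n_read: int = 0
    n_dropped_evalue: int = 0
    n_duplicates: int = 0

    @property
    def loops(self) -> list[PrototypeId]:
        return sorted({r.loop for r in self.records})

    @property
    def domains(self) -> list[DomainCcs]:
        return sorted({r.domain for r in self.records})

    def by_loop(self) -> dict[PrototypeId, list[DomainCcs]]:
        out: dict[PrototypeId, list[DomainCcs]] = {}
        for r in self.records:
            out.setdefault(r.loop, []).append(r.domain)
        return out

    def by_domain(self) -> dict[DomainCcs, list[PrototypeId]]:
        out: dict[DomainCcs, list[PrototypeId]] = {}
        for r in self.records:
            out.setdefault(r.domain, []).append(r.loop)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loop": [str(r.loop) for r in self.records],
                "domain": [str(r.domain) for r in self.records],
                "evalue": [r.evalue for r in self.records],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Chronology:
    """Domain ages on the relative nd scale, with the sorted unique time events."""

    ages: dict[DomainCcs, float]
    events: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        for d, nd in self.ages.items():
            if not 0.0 <= nd <= 1.0:
                raise ValueError(f"chronology: nd={nd} for {d} outside [0, 1]")
        self.events = sorted(set(self.ages.values()))

    @property
    def min_age(self) -> float:
        return self.events[0]

    def to_frame(self) -> pd.DataFrame:
        items = sorted(self.ages.items(), key=lambda kv: (kv[1], str(kv[0])))
        return pd.DataFrame(
            {"domain": [str(d) for d, _ in items], "nd": [a for _, a in items]}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # tab-separated, mandatory header, '#' comment lines
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_mapping_table(path: str | Path, evalue_max: float | None = None) -> MappingTable:
    """Read a loop<->domain mapping TSV (columns ``loop``, ``domain``, optional ``evalue``).

    Rows whose e-value fails the strict ``evalue < evalue_max`` filter are
    dropped; duplicated (loop, domain) pairs collapse to one record keeping
    the minimum e-value (conservative with respect to the filter).
    """
    df = _read_tsv(path)
    for col in ("loop", "domain"):
        if col not in df.columns:
            raise ParseError(f"mapping table {path}: missing required column {col!r}")
    has_evalue = "evalue" in df.columns
    n_read = len(df)
    best: dict[tuple[PrototypeId, DomainCcs], float | None] = {}
    n_dup = 0
    n_dropped = 0
    for _, row in df.iterrows():
        loop = parse_prototype_id(row["loop"])
        domain = parse_scop_ccs(row["domain"])
        ev: float | None = None
        if has_evalue and not pd.isna(row["evalue"]):
            ev = float(row["evalue"])
            if ev <= 0:
                raise ParseError(f"mapping table {path}: non-positive e-value {ev}")
        key = (loop, domain)
        if key in best:
            n_dup += 1
            old = best[key]
            if ev is not None and (old is None or ev < old):
                if old is not None:
                    logger.warning("duplicate pair %s/%s with conflicting e-values; keeping minimum", loop, domain)
                best[key] = ev
        else:
            best[key] = ev
    records = []
    for (loop, domain), ev in best.items():
        if evalue_max is not None and ev is not None and not ev < evalue_max:
            n_dropped += 1
            continue
        records.append(MappingRecord(loop, domain, ev))
    if n_dup:
        logger.info("mapping table %s: collapsed %d duplicate pairs", path, n_dup)
    logger.info(
        "mapping table %s: read %d rows, kept %d, dropped %d by e-value",
        path, n_read, len(records), n_dropped,
    )
    return MappingTable(records=records, n_read=n_read, n_dropped_evalue=n_dropped, n_duplicates=n_dup)


def read_chronology(path: str | Path) -> Chronology:
    """Read a domain chronology TSV (columns ``domain``, ``nd``)."""
    df = _read_tsv(path)
    for col in ("domain", "nd"):
        if col not in df.columns:
            raise ParseError(f"chronology {path}: missing required column {col!r}")
    ages: dict[DomainCcs, float] = {}
    for _, row in df.iterrows():
        d = parse_scop_ccs(row["domain"])
        nd = float(row["nd"])
        if not 0.0 <= nd <= 1.0:
            raise ParseError(f"chronology {path}: nd={nd} for {d} outside [0, 1]")
        if d in ages and ages[d] != nd:
            raise ParseError(f"chronology {path}: domain {d} repeated with conflicting nd")
        ages[d] = nd
    return Chronology(ages=ages)


@dataclass
class Clock:
    """Linear nd -> Gy molecular clock: Gy = intercept + slope * nd."""

    intercept: float = 3.8
    slope: float = -3.8
    pearson_r: float | None = None
    spearman_rho: float | None = None


DEFAULT_CLOCK = Clock()


def fit_clock(calibration: Sequence[tuple[float, float]]) -> Clock:
    """Least-squares linear clock from (nd, Gy) calibration points.

    Attaches Pearson r and Spearman rho of the calibration set.  Requires at
    least two points with distinct nd.
    """
    if len(calibration) < 2:
        raise ValueError("fit_clock: need >= 2 calibration points")
    nd = np.asarray([p[0] for p in calibration], dtype=float)
    gy = np.asarray([p[1] for p in calibration], dtype=float)
    if np.allclose(nd, nd[0]):
        raise ValueError("fit_clock: all nd values identical")
    res = _sps.linregress(nd, gy)
    if np.allclose(gy, gy[0]):
        rho = 0.0
    else:
        rho = float(_sps.spearmanr(nd, gy).statistic)
    return Clock(
        intercept=float(res.intercept),
        slope=float(res.slope),
        pearson_r=float(res.rvalue),
        spearman_rho=rho,
    )


def nd_to_gy(nd: float | np.ndarray, clock: Clock | None = None) -> float | np.ndarray:
    """Convert relative nd age(s) to geological time in Gy (before present)."""
    clock = clock or DEFAULT_CLOCK
    arr = np.asarray(nd, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValueError("nd_to_gy: nd outside [0, 1]")
    out = clock.intercept + clock.slope * arr
    return float(out) if np.isscalar(nd) or arr.ndim == 0 else out


def validate_inputs(mapping: MappingTable, chronology: Chronology) -> dict[str, int]:
    """Cross-check a mapping table against a chronology; returns summary counts."""
    mapped_domains = set(mapping.domains)
    aged = set(chronology.ages)
    missing = sorted(str(d) for d in mapped_domains - aged)
    if missing:
        raise ValueError(
            f"{len(missing)} mapped domains missing from chronology: {', '.join(missing[:10])}"
        )
    return {
        "n_records": len(mapping.records),
        "n_loops": len(mapping.loops),
        "n_domains": len(mapped_domains),
        "n_chronology_domains": len(aged),
        "n_events": len(chronology.events),
        "n_unmapped_domains": len(aged - mapped_domains),
    }
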