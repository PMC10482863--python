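"""Synthetic datasets with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a loop-prototype /
domain-family mapping grown along a timeline: domains appear at discrete
time events (ages are event ranks normalized to [0, 1], mirroring nd); each
new domain births one loop that is non-modular (NM, 1:1) with probability
``nm_fraction``, contemporaneous-modular (M', shared with a second domain of
the same event) at rate ``mprime_rate``, and modular (M) otherwise; modular
loops are subsequently reused by younger domains with preferential
attachment (probability proportional to current degree raised to
``attach_exponent``), biased toward the loop's planted community block.
Reuse only ever targets domains younger than the loop's earliest partner,
so the donor/acceptor age ordering holds by construction.  Every planted-M
loop is guaranteed to map to at least two domains of distinct ages, so the
M/M'/NM classifier should recover the planted labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from efnet.io_formats import (
    BRACING_CODES,
    Chronology,
    DomainCcs,
    MappingRecord,
    MappingTable,
    PrototypeId,
)
from efnet.loopstitch import LoopAnnotation
from efnet.netstats import sample_discrete_power_law

_SCOP_CLASSES = "abcdefg"
_BRACINGS = sorted(BRACING_CODES)


@dataclass
class SynthConfig:
    """Generator parameters; defaults give a mid-sized, clearly modular dataset."""

    n_domains: int = 300
    n_events: int = 50
    nm_fraction: float = 0.55
    mprime_rate: float = 0.01
    attach_exponent: float = 1.0
    n_blocks: int = 4
    p_in: float = 0.9
    p_out: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nm_fraction", "mprime_rate", "p_in", "p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.nm_fraction + self.mprime_rate > 1.0:
            raise ValueError("nm_fraction + mprime_rate must be <= 1")
        if self.attach_exponent < 0:
            raise ValueError("attach_exponent must be >= 0")
        if self.n_events > self.n_domains:
            raise ValueError("infeasible config: n_events > n_domains")
        if self.n_events < 1 or self.n_domains < 1 or self.n_blocks < 1:
            raise ValueError("n_domains, n_events and n_blocks must be >= 1")


@dataclass
class GroundTruth:
    """Planted labels and parameters consistent with the emitted tables."""

    loop_labels: dict[PrototypeId, str]
    loop_blocks: dict[PrototypeId, int]
    domain_blocks: dict[DomainCcs, int]
    ages: dict[DomainCcs, float]
    config: SynthConfig = field(repr=False, default=None)

    @property
    def nm_fraction(self) -> float:
        labels = list(self.loop_labels.values())
        return labels.count("NM") / len(labels)


def _domain_id(i: int) -> DomainCcs:
    return DomainCcs(
        scop_class=_SCOP_CLASSES[i % len(_SCOP_CLASSES)],
        fold=i // len(_SCOP_CLASSES) + 1,
        superfamily=1,
        family=1,
    )


def _loop_id(i: int, rng: np.random.Generator) -> PrototypeId:
    return PrototypeId(
        method="DS",
        bracing=_BRACINGS[int(rng.integers(len(_BRACINGS)))],
        loop_length=int(rng.integers(0, 12)),
        class_rank=i + 1,
        subclass_rank=1,
    )


def generate_dataset(cfg: SynthConfig) -> tuple[MappingTable, Chronology, GroundTruth]:
    """Grow a synthetic mapping table and chronology with planted M/M'/NM labels."""
    rng = np.random.default_rng(cfg.seed)
    n, ne = cfg.n_domains, cfg.n_events

    domains = [_domain_id(i) for i in range(n)]
    event_of = [i * ne // n for i in range(n)]  # non-decreasing, all events hit
    ages = {
        d: (event_of[i] / (ne - 1) if ne > 1 else 0.0) for i, d in enumerate(domains)
    }
    domain_block = {d: int(rng.integers(cfg.n_blocks)) for d in domains}

    by_event: dict[int, list[DomainCcs]] = {}
    for i, d in enumerate(domains):
        by_event.setdefault(event_of[i], []).append(d)

    records: list[MappingRecord] = []
    pairs: set[tuple[PrototypeId, DomainCcs]] = set()

    def add(loop: PrototypeId, dom: DomainCcs) -> None:
        if (loop, dom) not in pairs:
            pairs.add((loop, dom))
            records.append(MappingRecord(loop, dom))

    loop_labels: dict[PrototypeId, str] = {}
    loop_blocks: dict[PrototypeId, int] = {}
    loop_partners: dict[PrototypeId, list[DomainCcs]] = {}
    m_pool: list[PrototypeId] = []  # modular loops eligible for reuse
    m_degree: dict[PrototypeId, int] = {}
    m_birth_event: dict[PrototypeId, int] = {}

    p_same = cfg.p_in / (cfg.p_in + cfg.p_out) if cfg.p_in + cfg.p_out > 0 else 0.5
    counter = 0
    for i, dom in enumerate(domains):
        ev = event_of[i]
        loop = _loop_id(counter, rng)
        counter += 1
        u = rng.random()
        if u < cfg.nm_fraction:
            label = "NM"
        elif u < cfg.nm_fraction + cfg.mprime_rate:
            label = "M'"
        else:
            label = "M"
        if label == "M'":
            others = [d for d in by_event[ev] if d != dom]
            if others:
                partner = others[int(rng.integers(len(others)))]
                add(loop, dom)
                add(loop, partner)
                loop_partners[loop] = [dom, partner]
            else:  # lone domain in its event: no contemporaneous partner exists
                label = "NM"
        if label in ("NM", "M"):
            add(loop, dom)
            loop_partners[loop] = [dom]
        if label == "M":
            m_pool.append(loop)
            m_degree[loop] = 1
            m_birth_event[loop] = ev
        loop_labels[loop] = label
        loop_blocks[loop] = domain_block[dom]

        # preferential-attachment reuse of an older modular loop by this domain
        if ev > 0 and rng.random() < (1.0 - cfg.nm_fraction):
            eligible = [l for l in m_pool if m_birth_event[l] < ev]
            if eligible:
                same = [l for l in eligible if loop_blocks[l] == domain_block[dom]]
                pool = same if (same and rng.random() < p_same) else eligible
                w = np.array([m_degree[l] for l in pool], dtype=float) ** cfg.attach_exponent
                if w.sum() <= 0:
                    w = np.ones(len(pool))
                chosen = pool[int(rng.choice(len(pool), p=w / w.sum()))]
                if (chosen, dom) not in pairs:
                    add(chosen, dom)
                    m_degree[chosen] += 1
                    loop_partners[chosen].append(dom)

    # guarantee: every planted-M loop spans >= 2 distinct ages
    for loop in m_pool:
        partner_ages = {ages[d] for d in loop_partners[loop]}
        if len(partner_ages) >= 2:
            continue
        birth_age = next(iter(partner_ages))
        younger = [d for d in domains if ages[d] > birth_age and (loop, d) not in pairs]
        older = [d for d in domains if ages[d] < birth_age and (loop, d) not in pairs]
        candidates = younger or older
        if candidates:
            extra = candidates[int(rng.integers(len(candidates)))]
            add(loop, extra)
            m_degree[loop] += 1
            loop_partners[loop].append(extra)
        else:  # single-event chronology: modularity across ages is impossible
            loop_labels[loop] = "NM" if len(loop_partners[loop]) == 1 else "M'"

    mapping = MappingTable(records=records, n_read=len(records))
    chronology = Chronology(ages=ages)
    truth = GroundTruth(
        loop_labels=loop_labels,
        loop_blocks=loop_blocks,
        domain_blocks=domain_block,
        ages=ages,
        config=cfg,
    )
    return mapping, chronology, truth


def generate_power_law_sample(
    alpha: float, n: int, seed: int | None = None, xmin: int = 1
) -> np.ndarray:
    """i.i.d. draws from the discrete power law P(x) ∝ x^-alpha (zeta normalization)."""
    return sample_discrete_power_law(alpha, n, xmin=xmin, seed=seed)


def generate_planted_partition(
    n_blocks: int, block_size: int, p_in: float, p_out: float, seed: int | None = None
) -> tuple[nx.Graph, dict]:
    """Planted-partition benchmark graph and its ground-truth block labels."""
    g = nx.planted_partition_graph(n_blocks, block_size, p_in, p_out, seed=seed)
    labels = {n: d["block"] for n, d in g.nodes(data=True)}
    nx.set_edge_attributes(g, 1, "weight")
    return g, labels


def generate_toy_annotations(n_loops: int, seed: int | None = None) -> list[LoopAnnotation]:
    """Random non-overlapping loop annotations for stitching fixtures.

    Spans ascend along a synthetic chain with random loop lengths and
    linkers; the oldest loop always has age 0 and ages are distinct event
    values so the intermediate series has one step per loop.
    """
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    rng = np.random.default_rng(seed)
    aa = sorted(set("ACDEFGHIKLMNPQRSTVWY"))
    pos = 1 + int(rng.integers(0, 10))
    out = []
    ages = np.sort(rng.random(n_loops))
    ages[0] = 0.0
    order = rng.permutation(n_loops)  # age order decoupled from chain position
    for i in range(n_loops):
        length = int(rng.integers(3, 9))
        seq = "".join(aa[int(j)] for j in rng.integers(0, len(aa), size=length))
        out.append(
            LoopAnnotation(
                label=pos,
                span=(pos, pos + length - 1),
                sequence=seq,
                prototype=_loop_id(i, rng),
                age=float(ages[order[i]]),
            )
        )
        pos += length + int(rng.integers(1, 6))
    return out
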