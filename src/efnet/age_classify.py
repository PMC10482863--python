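"""Age transfer from domains to loop prototypes and M/M'/NM classification.

A loop prototype inherits its time of origin from the domains it maps to.
Two transfer schemes are supported:

* scheme 1 — the loop is as old as its most ancient associated domain (the
  age of the first structural scaffold);
* scheme 2 — the loop is as old as the more recent of the pair of most
  ancient associated domains (the age at which the loop function is first
  transferred between scaffolds), i.e. the second-smallest age in the
  multiset of linked-domain ages.

Because a donor loop must be at least as old as its acceptor domain, any
loop whose oldest partner sits at the global minimum of the chronology has
no possible older donor; such loops receive their scheme-1 age under scheme
2 as well (the *lex continui* exception).

Prototypes are partitioned into:

* NM (non-modular) — mapped to exactly one domain;
* M' (contemporaneous modular) — mapped to >= 2 domains, all of the same age;
* M (modular) — mapped to domains of >= 2 distinct ages.
"""

from __future__ import annotations

from dataclasses import dataclass

from efnet.io_formats import Chronology, DomainCcs, MappingTable, PrototypeId


@dataclass
class LoopAgeAssignment:
    loop: PrototypeId
    scheme1_age: float
    scheme2_age: float
    n_domains: int
    n_distinct_ages: int


@dataclass
class PrototypeClassification:
    """Partition of loop prototypes into the labels M, M' and NM."""

    partition: dict[PrototypeId, str]

    def counts(self) -> dict[str, int]:
        out = {"M": 0, "M'": 0, "NM": 0}
        for label in self.partition.values():
            out[label] += 1
        return out

    def loops_with_label(self, label: str) -> set[PrototypeId]:
        return {l for l, lab in self.partition.items() if lab == label}


@dataclass
class DomainVenn:
    """Venn grouping of domains by the kind of loops they map to."""

    m_only: set[DomainCcs]
    nm_only: set[DomainCcs]
    both: set[DomainCcs]
    unmapped: set[DomainCcs]


def _linked_ages(mapping: MappingTable, chronology: Chronology) -> dict[PrototypeId, list[float]]:
    missing = sorted({str(r.domain) for r in mapping.records if r.domain not in chronology.ages})
    if missing:
        raise ValueError(
            f"assign_loop_ages: {len(missing)} mapped domains missing from chronology: "
            + ", ".join(missing[:10])
        )
    ages: dict[PrototypeId, list[float]] = {}
    for loop, domains in mapping.by_loop().items():
        ages[loop] = sorted(chronology.ages[d] for d in domains)
    return ages


def assign_loop_ages(
    mapping: MappingTable, chronology: Chronology, scheme: int = 2
) -> list[LoopAgeAssignment]:
    """Transfer domain ages to loops under both schemes (see module docstring).

    ``scheme`` selects which age downstream consumers should read but both
    are always computed; it must be 1 or 2.
    """
    if scheme not in (1, 2):
        raise ValueError("scheme must be 1 or 2")
    linked = _linked_ages(mapping, chronology)
    global_min = chronology.min_age
    out = []
    for loop in sorted(linked):
        ages = linked[loop]
        s1 = ages[0]
        # second smallest with multiplicity; single-domain loops keep s1
        s2 = ages[1] if len(ages) >= 2 else s1
        if s1 == global_min:
            # no older donor domain exists: scheme 2 falls back to scheme 1
            s2 = s1
        out.append(
            LoopAgeAssignment(
                loop=loop,
                scheme1_age=s1,
                scheme2_age=s2,
                n_domains=len(ages),
                n_distinct_ages=len(set(ages)),
            )
        )
    return out


def loop_age_map(assignments: list[LoopAgeAssignment], scheme: int = 2) -> dict[PrototypeId, float]:
    """Convenience: loop -> age under the chosen scheme."""
    attr = "scheme1_age" if scheme == 1 else "scheme2_age"
    return {a.loop: getattr(a, attr) for a in assignments}


def classify_prototypes(mapping: MappingTable, chronology: Chronology) -> PrototypeClassification:
    """Label every loop prototype M, M' or NM from its linked-domain ages."""
    linked = _linked_ages(mapping, chronology)
    partition: dict[PrototypeId, str] = {}
    for loop, ages in linked.items():
        if len(ages) == 1:
            partition[loop] = "NM"
        elif len(set(ages)) == 1:
            partition[loop] = "M'"
        else:
            partition[loop] = "M"
    return PrototypeClassification(partition=partition)


def venn_domains(
    mapping: MappingTable,
    classification: PrototypeClassification,
    chronology: Chronology,
) -> DomainVenn:
    """Group domains by whether they map to modular (M/M'), non-modular, or no loops."""
    missing = {r.loop for r in mapping.records} - set(classification.partition)
    if missing:
        raise ValueError(f"venn_domains: {len(missing)} loops missing from classification")
    m_only: set[DomainCcs] = set()
    nm_only: set[DomainCcs] = set()
    both: set[DomainCcs] = set()
    mapped = mapping.by_domain()
    for domain, loops in mapped.items():
        labels = {classification.partition[l] for l in loops}
        modular = bool(labels & {"M", "M'"})
        nonmod = "NM" in labels
        if modular and nonmod:
            both.add(domain)
        elif modular:
            m_only.add(domain)
        else:
            nm_only.add(domain)
    unmapped = set(chronology.ages) - set(mapped)
    return DomainVenn(m_only=m_only, nm_only=nm_only, both=both, unmapped=unmapped)
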