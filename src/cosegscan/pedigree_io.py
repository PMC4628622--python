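"""Parsing, validation and phenotype queries for multi-generation pedigrees.

The on-disk format is a PED-like whitespace-delimited table with six columns
(family, id, father, mother, sex, phenotype).  Lines starting with ``#`` are
comments.  The phenotype column uses the standard codes 1 (unaffected),
2 (affected) and 0 (untested), extended with code 9 for individuals whose
affection status was assessed but remained uncertain.  Untested and uncertain
individuals are distinguishable in reports but both impose no constraint
during co-segregation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "parse_ped",
    "write_ped",
    "phenotype_groups",
    "validate_pedigree",
]

SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
SEX_TO_CODE = {v: k for k, v in SEX_CODES.items()}
PHENOTYPE_CODES = {"1": "unaffected", "2": "affected", "0": "untested", "9": "uncertain"}
PHENOTYPE_TO_CODE = {v: k for k, v in PHENOTYPE_CODES.items()}

PHENOTYPES = frozenset(PHENOTYPE_CODES.values())
SEXES = frozenset(SEX_CODES.values())


class PedigreeError(ValueError):
    """Raised for malformed or structurally inconsistent pedigree input."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders (or for a parent
    recorded as unknown).  ``sequenced`` marks membership in the
    exome-sequenced subset; it is not part of the PED text format and is set
    programmatically (e.g. from the sample list of the genotype data).
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    phenotype: str = "untested"
    sequenced: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(f"invalid sex {self.sex!r} for individual {self.id!r}")
        if self.phenotype not in PHENOTYPES:
            raise PedigreeError(
                f"invalid phenotype {self.phenotype!r} for individual {self.id!r}"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """An ordered collection of :class:`Individual` with referential checks.

    Construction verifies id uniqueness, that parent references resolve
    within the pedigree and that the parent graph is acyclic.
    """

    def __init__(self, individuals: Iterable[Individual], name: str = "") -> None:
        self.name = name
        self._members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._members:
                raise PedigreeError(f"duplicate individual id: {ind.id!r}")
            self._members[ind.id] = ind
        for ind in self._members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._members:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown parent {pid!r}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # colour: 0 unseen, 1 on stack, 2 done
        colour = {i: 0 for i in self._members}
        for start in self._members:
            if colour[start]:
                continue
            stack: list[tuple[str, Iterator[str]]] = [(start, self._parent_iter(start))]
            colour[start] = 1
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if colour[p] == 1:
                        raise PedigreeError(
                            f"pedigree contains an ancestry cycle through {p!r}"
                        )
                    if colour[p] == 0:
                        colour[p] = 1
                        stack.append((p, self._parent_iter(p)))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = 2
                    stack.pop()

    def _parent_iter(self, ind_id: str) -> Iterator[str]:
        ind = self._members[ind_id]
        return iter([p for p in (ind.father_id, ind.mother_id) if p is not None])

    def __getitem__(self, ind_id: str) -> Individual:
        try:
            return self._members[ind_id]
        except KeyError:
            raise KeyError(f"unknown individual id: {ind_id!r}") from None

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._members

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self.name == other.name and self._members == other._members

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def parents_of(self, ind_id: str) -> list[Individual]:
        ind = self[ind_id]
        return [self[p] for p in (ind.father_id, ind.mother_id) if p is not None]

    def children_of(self, ind_id: str) -> list[Individual]:
        return [i for i in self if ind_id in (i.father_id, i.mother_id)]

    def mark_sequenced(self, ids: Iterable[str]) -> "Pedigree":
        """Return a copy with ``sequenced=True`` exactly for ``ids``."""
        wanted = set(ids)
        unknown = wanted - set(self._members)
        if unknown:
            raise PedigreeError(f"unknown individual ids: {sorted(unknown)}")
        return Pedigree(
            (replace(i, sequenced=i.id in wanted) for i in self), name=self.name
        )

    def sequenced_ids(self) -> list[str]:
        return [i.id for i in self if i.sequenced]


def parse_ped(path: str | Path) -> Pedigree:
    """Parse a PED-like file into a :class:`Pedigree`.

    Raises :class:`PedigreeError` for duplicate ids, dangling parent
    references or ancestry cycles, naming the offending id.
    """
    path = Path(path)
    rows: list[Individual] = []
    family = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            fam, ind_id, father, mother, sex, phen = fields
            family = family or fam
            if sex not in SEX_CODES:
                raise PedigreeError(f"{path}:{lineno}: invalid sex code {sex!r}")
            if phen not in PHENOTYPE_CODES:
                raise PedigreeError(f"{path}:{lineno}: invalid phenotype code {phen!r}")
            rows.append(
                Individual(
                    id=ind_id,
                    father_id=None if father == "0" else father,
                    mother_id=None if mother == "0" else mother,
                    sex=SEX_CODES[sex],
                    phenotype=PHENOTYPE_CODES[phen],
                )
            )
    if not rows:
        raise PedigreeError(f"{path}: no data rows")
    return Pedigree(rows, name=family)


def write_ped(ped: Pedigree, path: str | Path) -> None:
    """Serialize a pedigree back to the 6-column PED dialect."""
    with open(path, "w") as fh:
        fh.write("# family id father mother sex phenotype\n")
        for ind in ped:
            fh.write(
                "\t".join(
                    [
                        ped.name or "FAM",
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        SEX_TO_CODE[ind.sex],
                        PHENOTYPE_TO_CODE[ind.phenotype],
                    ]
                )
                + "\n"
            )


def phenotype_groups(
    ped: Pedigree, subset: Iterable[str] | str = "all"
) -> tuple[set[str], set[str], set[str]]:
    """Partition ``subset`` into (affected, unaffected, unconstrained) id sets.

    Uncertain and untested individuals both land in the unconstrained set.
    ``subset`` may be ``"all"`` or an iterable of ids (all must exist).
    """
    ids = ped.ids if subset == "all" else list(subset)
    affected: set[str] = set()
    unaffected: set[str] = set()
    unconstrained: set[str] = set()
    for ind_id in ids:
        phen = ped[ind_id].phenotype  # raises KeyError for unknown ids
        if phen == "affected":
            affected.add(ind_id)
        elif phen == "unaffected":
            unaffected.add(ind_id)
        else:
            unconstrained.add(ind_id)
    return affected, unaffected, unconstrained


def validate_pedigree(ped: Pedigree) -> list[str]:
    """Return non-fatal structural warnings; never mutates the pedigree.

    Flags single-known-parent individuals, parent roles inconsistent with
    recorded sex, and disconnected family components.
    """
    warnings: list[str] = []
    for ind in ped:
        if (ind.father_id is None) != (ind.mother_id is None):
            known = ind.father_id or ind.mother_id
            warnings.append(
                f"individual {ind.id!r} has a single known parent ({known!r})"
            )
        if ind.father_id is not None and ped[ind.father_id].sex == "female":
            warnings.append(
                f"father {ind.father_id!r} of {ind.id!r} is recorded as female"
            )
        if ind.mother_id is not None and ped[ind.mother_id].sex == "male":
            warnings.append(
                f"mother {ind.mother_id!r} of {ind.id!r} is recorded as male"
            )
    if len(ped) > 1:
        components = _connected_components(ped)
        if len(components) > 1:
            warnings.append(f"pedigree has {len(components)} disconnected components")
    return warnings


def _connected_components(ped: Pedigree) -> list[set[str]]:
    adjacency: dict[str, set[str]] = {i.id: set() for i in ped}
    for ind in ped:
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                adjacency[ind.id].add(pid)
                adjacency[pid].add(ind.id)
    seen: set[str] = set()
    components: list[set[str]] = []
    for start in adjacency:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            node = queue.pop()
            for other in adjacency[node]:
                if other not in comp:
                    comp.add(other)
                    queue.append(other)
        seen |= comp
        components.append(comp)
    return components
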