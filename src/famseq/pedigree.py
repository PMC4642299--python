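"""Pedigree structures, PED parsing, and pedigree-based kinship.

A pedigree here is a forest of family graphs read from a 6-column PED file.
Individual ids must be unique across the whole cohort (multi-sample VCFs have
a single sample namespace), so simulated and real ids are written as
``<family>-<member>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "PedigreeMember",
    "Pedigree",
    "KinshipResult",
    "read_ped",
    "parse_ped_text",
]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown",
              "male": "male", "female": "female", "unknown": "unknown"}
_AFF_CODES = {"2": "yes", "1": "no", "0": "unknown", "-9": "unknown",
              "yes": "yes", "no": "no", "unknown": "unknown"}
_MISSING_PARENT = {"0", "", ".", "NA"}


@dataclass(frozen=True)
class PedigreeMember:
    """One row of a PED file."""

    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: str = "unknown"          # male | female | unknown
    affected: str = "unknown"     # yes | no | unknown

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class KinshipResult:
    """Kinship coefficient phi and relationship degree for a pair.

    degree follows the genetic-relationship convention
    ``round(-log2(2 * phi))``: 0 for self/duplicate, 1 for parent-offspring
    and full sibs (phi = 1/4), 3 for first cousins (phi = 1/16), 4 for
    first cousins once removed (phi = 1/32).  ``degree`` is None for
    unrelated pairs (phi = 0).
    """

    pair: tuple[str, str]
    phi: float
    degree: int | None

    @property
    def related(self) -> bool:
        return self.phi > 0.0


class Pedigree:
    """Validated forest of family pedigrees."""

    def __init__(self, members: Iterable[PedigreeMember]):
        self.members: dict[str, PedigreeMember] = {}
        self.families: dict[str, list[str]] = {}
        for m in members:
            if m.individual_id in self.members:
                raise ValueError(f"duplicate individual id {m.individual_id!r}")
            self.members[m.individual_id] = m
            self.families.setdefault(m.family_id, []).append(m.individual_id)
        self._depth: dict[str, int] = {}
        self._phi_memo: dict[tuple[str, str], float] = {}
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        for m in self.members.values():
            for pid, role, want_sex in ((m.father_id, "father", "male"),
                                        (m.mother_id, "mother", "female")):
                if pid is None:
                    continue
                if pid == m.individual_id:
                    raise ValueError(
                        f"{m.individual_id!r} lists itself as its own {role}")
                if pid not in self.members:
                    raise ValueError(
                        f"unknown {role} id {pid!r} for {m.individual_id!r}")
                parent = self.members[pid]
                if parent.family_id != m.family_id:
                    raise ValueError(
                        f"{role} {pid!r} of {m.individual_id!r} belongs to "
                        f"family {parent.family_id!r}, not {m.family_id!r}")
                if parent.sex not in ("unknown", want_sex):
                    raise ValueError(
                        f"{role} {pid!r} of {m.individual_id!r} has sex "
                        f"{parent.sex!r}")
        # depth computation doubles as cycle / self-ancestry detection
        for iid in self.members:
            self.depth(iid)

    def depth(self, iid: str) -> int:
        """Generation depth (founders are 0); raises on ancestry cycles."""
        if iid in self._depth:
            return self._depth[iid]
        seen: set[str] = set()

        def rec(x: str) -> int:
            if x in self._depth:
                return self._depth[x]
            if x in seen:
                raise ValueError(f"ancestry cycle involving {x!r}")
            seen.add(x)
            m = self.members[x]
            d = 0
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    d = max(d, rec(pid) + 1)
            self._depth[x] = d
            return d

        return rec(iid)

    # -- accessors ----------------------------------------------------------

    def member(self, iid: str) -> PedigreeMember:
        try:
            return self.members[iid]
        except KeyError:
            raise KeyError(f"unknown individual id {iid!r}") from None

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        m = self.member(iid)
        return m.father_id, m.mother_id

    def founders(self, family_id: str) -> list[str]:
        return [i for i in self.families[family_id] if self.members[i].is_founder]

    def nonfounders(self, family_id: str) -> list[str]:
        return [i for i in self.families[family_id] if not self.members[i].is_founder]

    def affected(self, family_id: str) -> list[str]:
        return [i for i in self.families[family_id]
                if self.members[i].affected == "yes"]

    def unaffected(self, family_id: str) -> list[str]:
        return [i for i in self.families[family_id]
                if self.members[i].affected == "no"]

    def family_of(self, iid: str) -> str:
        return self.member(iid).family_id

    def topological(self, family_id: str) -> list[str]:
        """Family members ordered parents-before-children."""
        return sorted(self.families[family_id], key=lambda i: (self.depth(i), i))

    # -- kinship ------------------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi by the standard recursion.

        Founders are assumed unrelated and non-inbred.
        """
        self.member(a), self.member(b)
        return self._phi(a, b)

    def _phi(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key in self._phi_memo:
            return self._phi_memo[key]
        if a == b:
            f, m = self.parents(a)
            val = 0.5 * (1.0 + (self._phi(f, m) if f and m else 0.0))
        else:
            # recurse on the deeper individual; at equal depth neither is an
            # ancestor of the other so recursing on either is valid
            if self.depth(a) < self.depth(b):
                a, b = b, a
            f, m = self.parents(a)
            if f is None and m is None:
                val = 0.0
            else:
                val = 0.5 * ((self._phi(f, b) if f else 0.0)
                             + (self._phi(m, b) if m else 0.0))
        self._phi_memo[key] = val
        return val

    def kinship_result(self, a: str, b: str) -> KinshipResult:
        phi = self.kinship(a, b)
        degree = round(-math.log2(2.0 * phi)) if phi > 0 else None
        return KinshipResult(pair=(a, b), phi=phi, degree=degree)

    # -- serialization ------------------------------------------------------

    def to_ped_text(self) -> str:
        sex_out = {"male": "1", "female": "2", "unknown": "0"}
        aff_out = {"yes": "2", "no": "1", "unknown": "0"}
        lines = []
        for fam in self.families:
            for iid in self.families[fam]:
                m = self.members[iid]
                lines.append("\t".join([
                    fam, iid, m.father_id or "0", m.mother_id or "0",
                    sex_out[m.sex], aff_out[m.affected]]))
        return "\n".join(lines) + "\n"


def parse_ped_text(text: str) -> Pedigree:
    members = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line {ln}: expected 6 columns, got {len(fields)}")
        fam, iid, fid, mid, sex, aff = fields[:6]
        members.append(PedigreeMember(
            family_id=fam,
            individual_id=iid,
            father_id=None if fid in _MISSING_PARENT else fid,
            mother_id=None if mid in _MISSING_PARENT else mid,
            sex=_SEX_CODES.get(sex.lower(), "unknown"),
            affected=_AFF_CODES.get(aff.lower(), "unknown"),
        ))
    return Pedigree(members)


def read_ped(path) -> Pedigree:
    """Read a 6-column whitespace-delimited PED file."""
    with open(path) as fh:
        return parse_ped_text(fh.read())
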