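"""Pedigree representation, PED file I/O, relationship matrices, pattern enumeration.

A :class:`Pedigree` is an ordered collection of individuals with parent
links; the *index individual* (consultand) — the person whose disease risk
is being predicted — always occupies position 0. The additive genetic
relationship matrix A (twice the kinship coefficient; 0.5 for
parent-offspring and full-sibling pairs) is built by the standard tabular
recursion and drives the liability covariance of the whole family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np

#: Largest pedigree for which all 2^n disease-status patterns are enumerated.
DEFAULT_PATTERN_CAP = 16


class PedigreeError(Exception):
    """Base class for pedigree construction and parsing failures."""


class PedParseError(PedigreeError):
    """A PED file row could not be parsed or referenced an unknown individual."""


class PedigreeStructureError(PedigreeError):
    """The pedigree violates a structural invariant (cycle, bad index, ...)."""


class Sex(Enum):
    UNKNOWN = 0
    MALE = 1
    FEMALE = 2

    @classmethod
    def from_code(cls, code: str) -> "Sex":
        try:
            return cls(int(code))
        except (ValueError, KeyError):
            raise PedParseError(f"invalid sex code {code!r} (expected 0, 1, or 2)")


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids are ``None`` for founders."""

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    is_index: bool = False


class Pedigree:
    """Ordered family with the index individual first.

    Parameters
    ----------
    individuals:
        Members of a single family. Exactly one must have ``is_index=True``.
        The index individual is moved to position 0; the relative order of
        the remaining members is preserved.
    family_id:
        Label used when writing PED files.
    """

    def __init__(
        self,
        individuals,
        family_id: str = "FAM1",
        *,
        _relationship: np.ndarray | None = None,
        _validate_links: bool = True,
    ):
        individuals = list(individuals)
        if not individuals:
            raise PedigreeStructureError("a pedigree needs at least one individual")
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            raise PedigreeStructureError("duplicate individual ids in pedigree")
        index_members = [ind for ind in individuals if ind.is_index]
        if len(index_members) != 1:
            raise PedigreeStructureError(
                f"exactly one index individual required, found {len(index_members)}"
            )
        ordered = index_members + [ind for ind in individuals if not ind.is_index]
        self.individuals: list[Individual] = ordered
        self.family_id = family_id
        self._pos = {ind.id: i for i, ind in enumerate(ordered)}
        self._A = _relationship
        if _validate_links:
            self._check_links()
            self._check_acyclic()

    # -- structure ---------------------------------------------------------

    def _check_links(self) -> None:
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self._pos:
                    raise PedParseError(
                        f"individual {ind.id!r} names parent {pid!r}, "
                        "who is not in the pedigree"
                    )

    def _check_acyclic(self) -> None:
        # iterative DFS over parent links; an individual may never be its own ancestor
        state: dict[str, int] = {}  # 0 visiting, 1 done
        for start in self._pos:
            if start in state:
                continue
            stack = [(start, iter(self._parent_ids(start)))]
            state[start] = 0
            while stack:
                node, parents = stack[-1]
                advanced = False
                for pid in parents:
                    if pid is None or pid not in self._pos:
                        continue
                    if state.get(pid) == 0:
                        raise PedigreeStructureError(
                            f"cyclic ancestry involving individual {pid!r}"
                        )
                    if pid not in state:
                        state[pid] = 0
                        stack.append((pid, iter(self._parent_ids(pid))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    def _parent_ids(self, iid: str):
        ind = self.individuals[self._pos[iid]]
        return (ind.father_id, ind.mother_id)

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.individuals)

    def __len__(self) -> int:
        return self.n

    @property
    def index(self) -> Individual:
        return self.individuals[0]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def position(self, iid: str) -> int:
        return self._pos[iid]

    # -- relationship matrix ----------------------------------------------

    def relationship_matrix(self) -> np.ndarray:
        """Additive relationship matrix A in pedigree order (index row/col 0).

        Tabular recursion: processing individuals parents-first,
        ``A[i, j] = 0.5 * (A[fa, j] + A[mo, j])`` for previously processed
        ``j`` (a missing parent contributes 0) and
        ``A[i, i] = 1 + 0.5 * A[fa, mo]`` when both parents are known.
        Supports inbred pedigrees (diagonal > 1) with a warning.
        """
        if self._A is not None:
            return self._A.copy()
        n = self.n
        A = np.zeros((n, n))
        order = self._topological_order()
        processed: list[int] = []
        for i in order:
            ind = self.individuals[i]
            fa = self._pos.get(ind.father_id) if ind.father_id else None
            mo = self._pos.get(ind.mother_id) if ind.mother_id else None
            for j in processed:
                a = 0.0
                if fa is not None:
                    a += 0.5 * A[fa, j]
                if mo is not None:
                    a += 0.5 * A[mo, j]
                A[i, j] = A[j, i] = a
            if fa is not None and mo is not None:
                A[i, i] = 1.0 + 0.5 * A[fa, mo]
            else:
                A[i, i] = 1.0
            processed.append(i)
        if np.any(np.diag(A) > 1.0 + 1e-12):
            warnings.warn(
                "pedigree contains inbreeding loops (diagonal of A exceeds 1); "
                "the outbred-family assumptions of the model may not hold",
                stacklevel=2,
            )
        self._A = A
        return A.copy()

    def _topological_order(self) -> list[int]:
        # parents before children
        order: list[int] = []
        seen: set[int] = set()

        def visit(i: int) -> None:
            if i in seen:
                return
            seen.add(i)
            ind = self.individuals[i]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in self._pos:
                    visit(self._pos[pid])
            order.append(i)

        for i in range(self.n):
            visit(i)
        return order

    # -- sex marginalization ----------------------------------------------

    def marginalize_sex(self, applicable_sex: Sex) -> "Pedigree":
        """Drop relatives whose sex cannot express the disease.

        For a sex-limited disease the phenotype of the non-applicable sex is
        unobserved; by Gaussian marginalization this equals removing those
        individuals from the model. Unknown-sex individuals are retained.
        The reduced pedigree keeps the corresponding sub-block of the
        relationship matrix (links through removed parents stay encoded in
        A even though the parent rows are gone).
        """
        if applicable_sex == Sex.UNKNOWN:
            return self
        idx = self.index
        if idx.sex not in (applicable_sex, Sex.UNKNOWN):
            raise PedigreeStructureError(
                "index individual's sex is not applicable for this disease; "
                "flip the sexes of all pedigree members first"
            )
        keep = [
            i
            for i, ind in enumerate(self.individuals)
            if ind.sex in (applicable_sex, Sex.UNKNOWN)
        ]
        if len(keep) == self.n:
            return self
        A = self.relationship_matrix()[np.ix_(keep, keep)]
        members = [self.individuals[i] for i in keep]
        return Pedigree(
            members,
            family_id=self.family_id,
            _relationship=A,
            _validate_links=False,
        )

    def flip_sexes(self) -> "Pedigree":
        """Return a pedigree with all male/female labels swapped."""
        swap = {Sex.MALE: Sex.FEMALE, Sex.FEMALE: Sex.MALE, Sex.UNKNOWN: Sex.UNKNOWN}
        members = [replace(ind, sex=swap[ind.sex]) for ind in self.individuals]
        return Pedigree(
            members,
            family_id=self.family_id,
            _relationship=self._A,
            _validate_links=False,
        )

    # -- pattern enumeration ----------------------------------------------

    def enumerate_patterns(self, cap: int = DEFAULT_PATTERN_CAP) -> np.ndarray:
        """All 2^n disease-status vectors, shape ``(2**n, n)``.

        Binary-counting order with the index individual as the lowest-order
        bit: row k has individual i affected iff bit i of k is set.
        """
        if self.n > cap:
            raise PedigreeStructureError(
                f"pedigree of size {self.n} exceeds the pattern cap of {cap}; "
                "use a restricted model or a smaller pedigree"
            )
        k = np.arange(2**self.n, dtype=np.int64)
        bits = (k[:, None] >> np.arange(self.n)) & 1
        return bits.astype(np.uint8)

    # -- first-degree relatives -------------------------------------------

    def first_degree_positions(self) -> list[int]:
        """Positions (pedigree order) of the index's parents, full siblings, and children."""
        idx = self.index
        out = []
        for i, ind in enumerate(self.individuals[1:], start=1):
            is_parent = ind.id in (idx.father_id, idx.mother_id)
            is_child = idx.id in (ind.father_id, ind.mother_id)
            is_full_sib = (
                idx.father_id is not None
                and idx.mother_id is not None
                and ind.father_id == idx.father_id
                and ind.mother_id == idx.mother_id
            )
            if is_parent or is_child or is_full_sib:
                out.append(i)
        return out

    # -- I/O ----------------------------------------------------------------

    def write_ped(self, path, statuses=None) -> None:
        """Write PED text: FID IID PAT MAT SEX PROBAND [STATUS ...].

        ``statuses`` may be a 1-D vector (one row per individual, extra
        column of 1=unaffected / 2=affected) or a 2-D array of simulated
        replicates (one status column per replicate).
        """
        lines = []
        status_arr = None
        if statuses is not None:
            status_arr = np.atleast_2d(np.asarray(statuses))
            if status_arr.shape[-1] != self.n and status_arr.shape[0] == self.n:
                status_arr = status_arr.T
        for i, ind in enumerate(self.individuals):
            row = [
                self.family_id,
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                str(ind.sex.value),
                "1" if ind.is_index else "0",
            ]
            if status_arr is not None:
                row.extend(str(1 + int(s)) for s in status_arr[:, i])
            lines.append("\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")

    def __repr__(self) -> str:
        return f"Pedigree(n={self.n}, index={self.index.id!r})"


def read_ped(path, index_id: str | None = None) -> Pedigree:
    """Parse a whitespace-delimited PED/FAM-style file into a :class:`Pedigree`.

    Columns: FID IID PAT MAT SEX [PROBAND], with ``0`` for a missing parent
    and SEX coded 1=male, 2=female, 0=unknown. The index individual is
    marked by a nonzero sixth column, or supplied via ``index_id``
    (which overrides any proband column).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 5:
            raise PedParseError(f"line {lineno}: expected at least 5 columns, got {len(fields)}")
        rows.append((lineno, fields))
    if not rows:
        raise PedParseError(f"no pedigree rows found in {path}")
    fids = {f[1][0] for f in rows}
    if len(fids) > 1:
        raise PedParseError(f"multiple family ids in one file: {sorted(fids)}")
    iids = {f[1][1] for f in rows}
    individuals = []
    proband_count = 0
    for lineno, f in rows:
        fid, iid, pat, mat, sex = f[:5]
        for pid in (pat, mat):
            if pid != "0" and pid not in iids:
                raise PedParseError(
                    f"line {lineno}: individual {iid!r} names absent parent {pid!r}"
                )
        if index_id is not None:
            is_index = iid == index_id
        else:
            is_index = len(f) >= 6 and f[5] not in ("0", "-9")
        proband_count += is_index
        individuals.append(
            Individual(
                id=iid,
                father_id=None if pat == "0" else pat,
                mother_id=None if mat == "0" else mat,
                sex=Sex.from_code(sex),
                is_index=is_index,
            )
        )
    if index_id is not None and proband_count == 0:
        raise PedParseError(f"index id {index_id!r} not found in {path}")
    if proband_count != 1:
        raise PedigreeStructureError(
            f"{proband_count} proband flags in {path}; mark exactly one index "
            "individual or pass an explicit index id"
        )
    return Pedigree(individuals, family_id=next(iter(fids)))
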