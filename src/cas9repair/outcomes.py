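"""Domain model of Cas9 target sites and mutational outcomes.

A Cas9/NGG nuclease cuts bluntly between the 4th and 3rd base upstream of
the PAM.  Repair of the break produces indels, which we represent as a
replaced half-open interval on the construct plus an inserted string.  Many
coordinate representations produce the same mutated molecule (deletions
between microhomologies, insertions next to repeats); all public functions
work on a canonical, maximally 5'-shifted representative.

The classifier stratifies outcomes into the ten groups used throughout the
package: 1bp and 2bp deletions, medium (3-9bp) and long (10bp+) deletions
split by microhomology, 1-2bp cut-site insertions matching the PAM-distal
or PAM-proximal flank, and other insertions (including insertion-deletions)
split by whether the insert is templated from flanking sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "TargetSite",
    "Indel",
    "OutcomeCategory",
    "FlankMatch",
    "ClassifiedOutcome",
    "CoordinateError",
    "apply_indel",
    "canonicalize",
    "mh_length",
    "insertion_at_cut",
    "insertion_flank_match",
    "templated_insertion",
    "classify",
    "directionality",
]

_DNA = frozenset("ACGT")


class CoordinateError(ValueError):
    """An edit interval falls outside the target sequence."""


def _check_dna(seq: str, what: str) -> None:
    if not set(seq) <= _DNA:
        bad = sorted(set(seq) - _DNA)
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class TargetSite:
    """A construct sequence with protospacer/PAM coordinates.

    The cut index ``c`` is derived as ``pam_start - 3``; the blunt cut lies
    between ``sequence[c-1]`` (the PAM-distal flank) and ``sequence[c]``
    (the PAM-proximal flank).
    """

    target_id: str
    sequence: str
    protospacer_start: int
    pam_start: int

    def __post_init__(self) -> None:
        _check_dna(self.sequence, f"target {self.target_id!r} sequence")
        if self.sequence[self.pam_start + 1 : self.pam_start + 3] != "GG":
            raise ValueError(
                f"target {self.target_id!r}: no NGG PAM at position {self.pam_start}"
            )
        c = self.cut_index
        if not 0 < c < len(self.sequence):
            raise ValueError(f"target {self.target_id!r}: cut index {c} out of range")
        if not self.protospacer_start < c:
            raise ValueError(
                f"target {self.target_id!r}: protospacer must start 5' of the cut"
            )

    @property
    def cut_index(self) -> int:
        return self.pam_start - 3

    @property
    def distal_flank(self) -> str:
        """Base immediately 5' of the cut (PAM-distal)."""
        return self.sequence[self.cut_index - 1]

    @property
    def proximal_flank(self) -> str:
        """Base immediately 3' of the cut (PAM-proximal)."""
        return self.sequence[self.cut_index]


_KEY_RE = re.compile(
    r"^(?:DEL:(?P<da>\d+)-(?P<db>\d+)"
    r"|INS:(?P<ip>\d+):(?P<iseq>[ACGT]+)"
    r"|IND:(?P<ca>\d+)-(?P<cb>\d+):(?P<cseq>[ACGT]+))$"
)


@dataclass(frozen=True, order=True)
class Indel:
    """An edit: the half-open interval [start, end) is replaced by ``insert``."""

    start: int
    end: int
    insert: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"inverted interval [{self.start},{self.end})")
        if self.start == self.end and not self.insert:
            raise ValueError("the identity edit is not an outcome")
        if self.insert:
            _check_dna(self.insert, "inserted sequence")

    @property
    def deletion_size(self) -> int:
        return self.end - self.start

    @property
    def insertion_size(self) -> int:
        return len(self.insert)

    @property
    def net_change(self) -> int:
        return self.insertion_size - self.deletion_size

    @property
    def is_deletion(self) -> bool:
        return self.deletion_size > 0 and not self.insert

    @property
    def is_insertion(self) -> bool:
        return self.deletion_size == 0 and bool(self.insert)

    @property
    def is_compound(self) -> bool:
        return self.deletion_size > 0 and bool(self.insert)

    def key(self) -> str:
        if self.is_deletion:
            return f"DEL:{self.start}-{self.end}"
        if self.is_insertion:
            return f"INS:{self.start}:{self.insert}"
        return f"IND:{self.start}-{self.end}:{self.insert}"

    @classmethod
    def from_key(cls, key: str) -> "Indel":
        m = _KEY_RE.match(key)
        if m is None:
            raise ValueError(f"malformed outcome string {key!r}")
        g = m.groupdict()
        if g["da"] is not None:
            return cls(int(g["da"]), int(g["db"]))
        if g["ip"] is not None:
            p = int(g["ip"])
            return cls(p, p, g["iseq"])
        return cls(int(g["ca"]), int(g["cb"]), g["cseq"])


class OutcomeCategory(Enum):
    """The ten outcome groups used for all composition and fold-change tables."""

    D1 = "1bp deletion"
    D2 = "2bp deletion"
    D3_9_MH = "3-9bp deletion, MH"
    D3_9 = "3-9bp deletion"
    D10P_MH = "10bp+ deletion, MH"
    D10P = "10bp+ deletion"
    I12_PROX = "1-2bp insertion, PAM-proximal"
    I12_DIST = "1-2bp insertion, PAM-distal"
    OTHER_I_MH = "other insertion, templated"
    OTHER_I = "other insertion"


class FlankMatch(Enum):
    DISTAL_ONLY = "distal only"
    PROXIMAL_ONLY = "proximal only"
    BOTH = "both"
    NEITHER = "neither"
    NA = "not applicable"


@dataclass(frozen=True)
class ClassifiedOutcome:
    """An indel together with every derived annotation the analyses use.

    ``mh_len`` is capped at the deletion size so that the inter-homology
    distance ``deletion_size - mh_len`` is never negative (relevant only
    for deletions inside homopolymer runs longer than twice the deletion;
    :func:`mh_length` itself is uncapped).
    """

    indel: Indel
    category: OutcomeCategory
    mh_len: int
    flank_match: FlankMatch
    directionality: float | None
    in_frame: bool


def apply_indel(sequence: str, indel: Indel) -> str:
    """Return the mutated sequence produced by ``indel`` on ``sequence``."""
    if indel.start < 0 or indel.end > len(sequence):
        raise CoordinateError(
            f"edit [{indel.start},{indel.end}) outside sequence of length {len(sequence)}"
        )
    return sequence[: indel.start] + indel.insert + sequence[indel.end :]


def canonicalize(target: TargetSite, raw: Indel) -> Indel:
    """Return the canonical representative of ``raw``'s equivalence class.

    Among all edits producing the identical mutated sequence, the canonical
    one is minimal: insert bases that merely re-create deleted reference
    bases are trimmed away, and the remaining edit is shifted maximally 5'
    (minimal start coordinate).  Idempotent.
    """
    seq = target.sequence
    if raw.start < 0 or raw.end > len(seq):
        raise CoordinateError(
            f"edit [{raw.start},{raw.end}) outside target {target.target_id!r}"
        )
    a, b, ins = raw.start, raw.end, raw.insert
    # Reduce: trim insert prefix/suffix that matches the deleted interval.
    while a < b and ins and ins[0] == seq[a]:
        a += 1
        ins = ins[1:]
    while a < b and ins and ins[-1] == seq[b - 1]:
        b -= 1
        ins = ins[:-1]
    if a == b and not ins:
        raise ValueError("edit reproduces the reference sequence")
    if not ins:  # pure deletion: left-align through microhomology
        while a > 0 and seq[a - 1] == seq[b - 1]:
            a -= 1
            b -= 1
    elif a == b:  # pure insertion: left-align through repeats
        while a > 0 and ins[-1] == seq[a - 1]:
            ins = seq[a - 1] + ins[:-1]
            a -= 1
            b -= 1
    # Compound edits are immobile once reduced: a 1bp shift would require
    # ins[-1] == seq[b-1], which reduction has already excluded.
    return Indel(a, b, ins)


def mh_length(target: TargetSite, d: Indel) -> int:
    """Microhomology length of a pure deletion.

    For the canonical (left-aligned) deletion [a, b) this is the largest k
    with ``seq[a:a+k] == seq[b:b+k]``, which equals the number of distinct
    deletion windows producing the identical mutated sequence, minus one.
    """
    if d.insert:
        raise ValueError("mh_length is defined for pure deletions only")
    can = canonicalize(target, d)
    seq = target.sequence
    a, b = can.start, can.end
    k = 0
    while b + k < len(seq) and seq[a + k] == seq[b + k]:
        k += 1
    return k


def insertion_at_cut(target: TargetSite, i: Indel) -> str | None:
    """Insert content as placed at the cut, or None if the insertion's
    equivalence class does not include the cut position."""
    if not i.is_insertion:
        return None
    seq = target.sequence
    c = target.cut_index
    mutated = apply_indel(seq, i)
    cand = mutated[c : c + len(i.insert)]
    if len(cand) == len(i.insert) and seq[:c] + cand + seq[c:] == mutated:
        return cand
    return None


def insertion_flank_match(target: TargetSite, i: Indel) -> FlankMatch:
    """Compare a 1-2bp cut-site insertion to the sequences flanking the cut.

    A length-L insert is compared to the L bases 5' of the cut (PAM-distal)
    and the L bases 3' of it (PAM-proximal).  Insertions that cannot be
    placed at the cut, or longer than 2bp, return NA.
    """
    if not i.is_insertion or i.insertion_size > 2:
        return FlankMatch.NA
    placed = insertion_at_cut(target, i)
    if placed is None:
        return FlankMatch.NA
    c = target.cut_index
    L = len(placed)
    if c - L < 0 or c + L > len(target.sequence):
        return FlankMatch.NA
    distal = target.sequence[c - L : c]
    proximal = target.sequence[c : c + L]
    m_d, m_p = placed == distal, placed == proximal
    if m_d and m_p:
        return FlankMatch.BOTH
    if m_d:
        return FlankMatch.DISTAL_ONLY
    if m_p:
        return FlankMatch.PROXIMAL_ONLY
    return FlankMatch.NEITHER


def templated_insertion(
    target: TargetSite, i: Indel, window: int = 10, min_len: int = 2
) -> bool:
    """Whether an insert is copied from sequence flanking the edit.

    True iff the insert (length >= ``min_len``) occurs as an exact substring
    of the ``window`` bp immediately 5' or 3' of the edit after removal of
    the deleted interval.  Single-base inserts are never called templated
    here (1bp cut-site insertions have their own flank-match categories).
    """
    if not i.insert or i.insertion_size < min_len:
        return False
    seq = target.sequence
    left = seq[max(0, i.start - window) : i.start]
    right = seq[i.end : i.end + window]
    return i.insert in left or i.insert in right


def directionality(target: TargetSite, d: Indel) -> float:
    """max(L, R) / (L + R) for a pure deletion losing L bases PAM-distal and
    R bases PAM-proximal of the cut; 1 means fully one-sided."""
    if d.insert or d.deletion_size == 0:
        raise ValueError("directionality is defined for pure deletions only")
    can = canonicalize(target, d)
    c = target.cut_index
    L = max(0, c - can.start)
    R = max(0, can.end - c)
    return max(L, R) / (L + R)


def classify(
    target: TargetSite,
    o: Indel,
    mh_threshold: int = 1,
    both_flank_to_distal: bool = True,
    templated_window: int = 10,
    templated_min_len: int = 2,
) -> ClassifiedOutcome:
    """Assign an outcome to exactly one of the ten categories.

    ``mh_threshold`` controls the "with microhomology" split of medium/long
    deletions.  BOTH-flank-matching 1-2bp insertions are binned with the
    PAM-distal category by default (the flank_match field preserves the
    distinction for insertion-specific analyses).
    """
    o = canonicalize(target, o)
    size = o.deletion_size
    in_frame = o.net_change % 3 == 0

    if o.is_deletion:
        raw_mh = mh_length(target, o)
        mh = min(raw_mh, size)
        dirn = directionality(target, o)
        if size == 1:
            cat = OutcomeCategory.D1
        elif size == 2:
            cat = OutcomeCategory.D2
        elif size <= 9:
            cat = OutcomeCategory.D3_9_MH if mh >= mh_threshold else OutcomeCategory.D3_9
        else:
            cat = OutcomeCategory.D10P_MH if mh >= mh_threshold else OutcomeCategory.D10P
        return ClassifiedOutcome(o, cat, mh, FlankMatch.NA, dirn, in_frame)

    fm = insertion_flank_match(target, o)
    if o.is_insertion and o.insertion_size <= 2 and fm is not FlankMatch.NA:
        if fm is FlankMatch.PROXIMAL_ONLY:
            return ClassifiedOutcome(o, OutcomeCategory.I12_PROX, 0, fm, None, in_frame)
        if fm is FlankMatch.DISTAL_ONLY or (fm is FlankMatch.BOTH and both_flank_to_distal):
            return ClassifiedOutcome(o, OutcomeCategory.I12_DIST, 0, fm, None, in_frame)
        # NEITHER (or BOTH routed here by configuration): fall through.
    templ = templated_insertion(target, o, templated_window, templated_min_len)
    cat = OutcomeCategory.OTHER_I_MH if templ else OutcomeCategory.OTHER_I
    return ClassifiedOutcome(o, cat, 0, fm, None, in_frame)
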