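"""Roster-based confirmation of noisy OCR ear-tag readings.

A farm roster holds the 4-digit "work numbers" printed on the yellow ear
tags.  The digit recognizer emits raw strings of variable length (missing,
spurious or substituted digits are all common), and this module decides,
per reading, whether the string can be attributed to a roster tag.

Three lookup structures are derived from the roster:

* the *four-digit list* — the roster itself, for exact matches;
* the *three-digit list* — every delete-one-digit subsequence of every
  tag, so a reading with one dropped digit still resolves ("124_",
  "12_9", "1_49" and "_249" all point at "1249");
* the *one-digit list* — per digit position, which tags carry which digit
  there; intersecting any three of the four position indices recovers all
  tags that agree with a 4-character cut on at least three positions,
  i.e. all roster tags within Hamming distance 1.

A reading is saved or discarded by one of ten rules.  Save rules:
S1 exact three-digit-list hit (unique), S2 multiple three-digit hits
resolved by position history, S3 a length-4 cut found verbatim in the
roster, S4 a unique Hamming<=1 candidate, S5 multiple Hamming<=1
candidates resolved by history.  Discard rules D1-D5 mirror these
(too short / no match / ambiguous without history, for the three-digit
and cut paths respectively).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional

__all__ = [
    "Roster",
    "CheckLists",
    "TagHistory",
    "ConfirmationResult",
    "build_checklists",
    "cut_windows",
    "hamming1_candidates",
    "confirm_tag",
    "update_final_list",
    "WORKED_EXAMPLE_ROSTER",
    "WORKED_EXAMPLE_STREAM",
]

_TAG_RE = re.compile(r"^[0-9]{4}$")

SAVE_RULES = ("S1", "S2", "S3", "S4", "S5")
DISCARD_RULES = ("D1", "D2", "D3", "D4", "D5")


@dataclass(frozen=True)
class Roster:
    """Set of distinct 4-digit ear-tag work numbers."""

    tags: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tags:
            raise ValueError("roster is empty")
        for t in self.tags:
            if not _TAG_RE.match(t):
                raise ValueError(f"malformed roster tag {t!r}: expected 4 digits")

    @classmethod
    def from_iterable(cls, tags: Iterable[str]) -> "Roster":
        return cls(frozenset(str(t).strip() for t in tags if str(t).strip()))

    @classmethod
    def from_file(cls, path: str | Path) -> "Roster":
        """Read a plain-text roster, one 4-digit ID per line."""
        lines = Path(path).read_text().splitlines()
        return cls.from_iterable(lines)

    def __contains__(self, tag: str) -> bool:
        return tag in self.tags

    def __iter__(self):
        return iter(sorted(self.tags))

    def __len__(self) -> int:
        return len(self.tags)


@dataclass(frozen=True)
class CheckLists:
    """Lookup structures derived from a :class:`Roster`.

    ``three_digit`` maps each delete-one-digit subsequence to the roster
    tags producing it.  ``one_digit`` holds one map per digit position
    (0-based): digit character -> tags carrying that digit there.
    """

    four_digit: frozenset[str]
    three_digit: Mapping[str, frozenset[str]]
    one_digit: tuple[Mapping[str, frozenset[str]], ...]


def build_checklists(roster: Roster) -> CheckLists:
    three: dict[str, set[str]] = {}
    one: tuple[dict[str, set[str]], ...] = tuple({} for _ in range(4))
    for tag in roster.tags:
        for drop in range(4):
            key = tag[:drop] + tag[drop + 1 :]
            three.setdefault(key, set()).add(tag)
        for pos, ch in enumerate(tag):
            one[pos].setdefault(ch, set()).add(tag)
    return CheckLists(
        four_digit=frozenset(roster.tags),
        three_digit={k: frozenset(v) for k, v in three.items()},
        one_digit=tuple({k: frozenset(v) for k, v in m.items()} for m in one),
    )


def cut_windows(s: str) -> list[str]:
    """All contiguous length-4 windows of ``s``, left to right."""
    return [s[i : i + 4] for i in range(len(s) - 3)]


def hamming1_candidates(cut: str, lists: CheckLists) -> set[str]:
    """Roster tags agreeing with ``cut`` on at least three positions.

    Implemented as the union, over the four position triples, of the
    intersection of the three per-position one-digit index sets —
    equivalent to brute-force Hamming distance <= 1 matching.
    """
    if len(cut) != 4:
        raise ValueError(f"cut must have length 4, got {cut!r}")
    out: set[str] = set()
    for triple in combinations(range(4), 3):
        sets = [lists.one_digit[p].get(cut[p]) for p in triple]
        if any(s is None for s in sets):
            continue
        inter = sets[0] & sets[1] & sets[2]
        out |= inter
    return out


@dataclass(frozen=True)
class ConfirmationResult:
    """Outcome of confirming one raw reading: saved (S1-S5) or discarded
    (D1-D5); ``tag`` is the confirmed roster tag when saved."""

    status: str  # "saved" | "discarded"
    rule: str
    tag: Optional[str] = None

    def __post_init__(self) -> None:
        saved = self.status == "saved"
        if saved != (self.rule in SAVE_RULES) or saved != (self.tag is not None):
            raise ValueError("inconsistent ConfirmationResult")


def _saved(rule: str, tag: str) -> ConfirmationResult:
    return ConfirmationResult("saved", rule, tag)


def _discarded(rule: str) -> ConfirmationResult:
    return ConfirmationResult("discarded", rule)


def confirm_tag(
    s: Optional[str],
    lists: CheckLists,
    history: Optional[str] = None,
) -> ConfirmationResult:
    """Run the ten-rule save/discard decision tree on a raw reading.

    ``history`` is the tag most recently confirmed at the same camera
    position, if any; it arbitrates the ambiguous rules S2/S5.  Absent
    readings (``None``) and non-digit sentinel characters are tolerated:
    non-digits are stripped before the length is evaluated.
    """
    if s is None:
        s = ""
    if not isinstance(s, str):
        raise TypeError("reading must be a string or None")
    s = re.sub(r"[^0-9]", "", s)

    if len(s) < 3:
        return _discarded("D1")

    if len(s) == 3:
        matches = lists.three_digit.get(s, frozenset())
        if not matches:
            return _discarded("D2")
        if len(matches) == 1:
            return _saved("S1", next(iter(matches)))
        if history in matches:
            return _saved("S2", history)
        return _discarded("D3")

    cuts = cut_windows(s)
    for cut in cuts:  # first verbatim roster hit wins, left to right
        if cut in lists.four_digit:
            return _saved("S3", cut)
    candidates: set[str] = set()
    for cut in cuts:
        candidates |= hamming1_candidates(cut, lists)
    if not candidates:
        return _discarded("D4")
    if len(candidates) == 1:
        return _saved("S4", next(iter(candidates)))
    if history in candidates:
        return _saved("S5", history)
    return _discarded("D5")


def update_final_list(initial_entries: Iterable[str]) -> Optional[str]:
    """Collapse one position's confirmed tags over a window to one tag.

    Returns the modal tag; ties break toward the most recently confirmed;
    ``None`` when the window produced no confirmations.
    """
    entries = list(initial_entries)
    if not entries:
        return None
    counts = Counter(entries)
    best = max(counts.values())
    tied = {t for t, c in counts.items() if c == best}
    for tag in reversed(entries):
        if tag in tied:
            return tag
    raise AssertionError("unreachable")


@dataclass
class TagHistory:
    """Most recent confirmed tag and rolling final-list entry per
    (camera, position)."""

    _recent: dict[tuple[int, int], str] = field(default_factory=dict)
    _final: dict[tuple[int, int], str] = field(default_factory=dict)

    def get(self, camera: int, position: int) -> Optional[str]:
        key = (camera, position)
        return self._recent.get(key, self._final.get(key))

    def record(self, camera: int, position: int, tag: str) -> None:
        self._recent[(camera, position)] = tag

    def set_final(self, camera: int, position: int, tag: str) -> None:
        self._final[(camera, position)] = tag

    def final_entries(self) -> dict[tuple[int, int], str]:
        return dict(self._final)


# Worked example: a ten-cow roster and three frames of raw readings for
# four cows (left and right ear each).  ``None`` marks a frame where no
# string was recognized for that ear.
WORKED_EXAMPLE_ROSTER: tuple[str, ...] = (
    "0004", "0647", "1127", "1246", "1249",
    "1733", "3140", "5202", "5208", "9230",
)

# stream[frame][cow] = (left reading, right reading); cows hold tags
# 1127, 0647, 5208, 9230.
WORKED_EXAMPLE_STREAM: tuple[tuple[tuple[Optional[str], Optional[str]], ...], ...] = (
    (("112", None), ("069", "064"), ("5208", "52087"), ("99231", "7231")),
    (("11", "1127"), ("11641", "064"), ("520", "15203"), ("9230", "9230")),
    (("124", "1247"), ("0647", "11647"), ("5208", "5202"), ("7280", "9230")),
)


def run_worked_example() -> list[list[tuple[ConfirmationResult, ConfirmationResult]]]:
    """Replay the bundled worked-example stream against its roster.

    History evolves as in live operation: each saved result immediately
    becomes the history entry for its cow position (both ears share one
    position).  Returns per-frame, per-cow (left, right) outcomes.
    """
    lists = build_checklists(Roster.from_iterable(WORKED_EXAMPLE_ROSTER))
    history = TagHistory()
    out: list[list[tuple[ConfirmationResult, ConfirmationResult]]] = []
    for frame in WORKED_EXAMPLE_STREAM:
        row: list[tuple[ConfirmationResult, ConfirmationResult]] = []
        for cow, (left, right) in enumerate(frame, start=1):
            results = []
            for reading in (left, right):
                res = confirm_tag(reading, lists, history.get(0, cow))
                if res.status == "saved":
                    history.record(0, cow, res.tag)
                results.append(res)
            row.append((results[0], results[1]))
        out.append(row)
    return out
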