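"""Mismatch-tolerant inverted-repeat (palindrome) discovery.

A repeat is two same-length arms separated by a short spacer where the
reverse complement of arm2 matches arm1 within a mismatch budget
(substitutions only; N mismatches everything, including N). Reported
repeats are maximal: neither arm can be symmetrically extended without
exceeding the budget or the sequence bounds. Repeats wholly contained
(both arms) in a longer reported repeat with equal spacer are suppressed —
for equal spacers containment forces an equal arm1 end, so suppression is
equivalent to reporting only the maximal extension per (arm1_end, spacer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .genome import reverse_complement

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class IRParams:
    """Scan parameters.

    ``min_arm`` is an arm length under ``per_arm`` semantics and a total
    repeat length (arm + spacer + arm) under ``total`` semantics.
    """

    min_arm: int = 20
    max_gap: int = 7
    max_mismatch: int = 2
    length_semantics: str = "per_arm"

    def __post_init__(self) -> None:
        if self.min_arm < 2:
            raise ValueError("min_arm must be >= 2")
        if self.max_gap < 0 or self.max_mismatch < 0:
            raise ValueError("max_gap and max_mismatch must be >= 0")
        if self.length_semantics not in ("per_arm", "total"):
            raise ValueError("length_semantics must be 'per_arm' or 'total'")

    def accepts(self, arm_len: int, spacer_len: int) -> bool:
        if self.length_semantics == "per_arm":
            return arm_len >= self.min_arm
        return 2 * arm_len + spacer_len >= self.min_arm


@dataclass
class InvertedRepeat:
    seq_id: str
    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    arm_len: int
    spacer_len: int
    mismatches: int
    arm1_seq: str = ""
    arm2_seq: str = ""

    def __post_init__(self) -> None:
        if self.arm1_end > self.arm2_start:
            raise ValueError("arm1 must precede arm2")
        if self.arm2_start - self.arm1_end != self.spacer_len:
            raise ValueError("spacer_len inconsistent with arm coordinates")
        if (self.arm1_end - self.arm1_start != self.arm_len
                or self.arm2_end - self.arm2_start != self.arm_len):
            raise ValueError("arm coordinates inconsistent with arm_len")

    def revalidate(self) -> bool:
        """True iff the stored mismatch count equals the recomputed Hamming
        distance between arm1 and revcomp(arm2)."""
        if not self.arm1_seq or not self.arm2_seq:
            return True
        rc = reverse_complement(self.arm2_seq)
        mm = sum(1 for a, b in zip(self.arm1_seq, rc)
                 if a != b or a == "N" or b == "N")
        return mm == self.mismatches


def _pair_mismatch(left: str, right: str) -> bool:
    # N is a mismatch to everything, itself included
    if left == "N" or right == "N":
        return True
    return _COMPLEMENT[left] != right


def find_inverted_repeats(seq: str, params: Optional[IRParams] = None,
                          seq_id: str = "") -> list[InvertedRepeat]:
    """All maximal inverted repeats of ``seq`` satisfying ``params``,
    sorted by (arm1_start, -arm_len)."""
    params = params or IRParams()
    s = seq.upper()
    n = len(s)
    min_needed = (2 * params.min_arm if params.length_semantics == "per_arm"
                  else params.min_arm)
    if n < min_needed:
        log.debug("sequence of length %d below minimum %d; no scan", n, min_needed)
        return []
    out: list[InvertedRepeat] = []
    for e in range(1, n):  # arm1_end (exclusive)
        for g in range(0, params.max_gap + 1):
            if e + g >= n:
                break
            mm = 0
            arm = 0
            # extend symmetrically: pair k is (e-1-k, e+g+k)
            while e - 1 - arm >= 0 and e + g + arm < n:
                if _pair_mismatch(s[e - 1 - arm], s[e + g + arm]):
                    if mm + 1 > params.max_mismatch:
                        break
                    mm += 1
                arm += 1
            if arm >= 1 and params.accepts(arm, g):
                a1s, a2s = e - arm, e + g
                arm1, arm2 = s[a1s:e], s[a2s:a2s + arm]
                true_mm = sum(
                    1 for k in range(arm)
                    if _pair_mismatch(s[e - 1 - k], s[e + g + k])
                )
                out.append(InvertedRepeat(
                    seq_id=seq_id,
                    arm1_start=a1s, arm1_end=e,
                    arm2_start=a2s, arm2_end=a2s + arm,
                    arm_len=arm, spacer_len=g, mismatches=true_mm,
                    arm1_seq=arm1, arm2_seq=arm2,
                ))
    out.sort(key=lambda r: (r.arm1_start, -r.arm_len, r.spacer_len))
    return out


def scan_upstream_all(loci, params: Optional[IRParams] = None):
    """Scan the upstream sequence of each regulator locus.

    Returns ``(per_locus, summary)`` where ``per_locus`` maps locus_id to
    its list of repeats and ``summary`` holds total IR and IR-bearing locus
    counts.
    """
    params = params or IRParams()
    per_locus: dict[str, list[InvertedRepeat]] = {}
    for locus in loci:
        reps = find_inverted_repeats(locus.upstream_seq, params,
                                     seq_id=locus.locus_id)
        per_locus[locus.locus_id] = reps
    total = sum(len(v) for v in per_locus.values())
    with_ir = sum(1 for v in per_locus.values() if v)
    summary = {"n_loci": len(per_locus), "n_irs": total,
               "n_loci_with_ir": with_ir}
    return per_locus, summary


@dataclass
class RepeatBox:
    """An inverted-repeat operator written out as arm1 + spacer + arm2."""

    arm1: str
    spacer: str
    arm2: str

    @classmethod
    def from_repeat(cls, seq: str, rep: InvertedRepeat) -> "RepeatBox":
        s = seq.upper()
        return cls(arm1=s[rep.arm1_start:rep.arm1_end],
                   spacer=s[rep.arm1_end:rep.arm2_start],
                   arm2=s[rep.arm2_start:rep.arm2_end])


def score_rbox_pair(box_a: RepeatBox, box_b: RepeatBox) -> dict:
    """Positional comparison of two operator boxes of identical geometry.

    Returns per-component match vectors and difference counts for the
    first arms, the spacers, and the second arms.
    """
    if len(box_a.arm1) != len(box_b.arm1) or len(box_a.arm2) != len(box_b.arm2):
        raise ValueError("arm lengths differ between boxes")
    if len(box_a.spacer) != len(box_b.spacer):
        raise ValueError("spacer lengths differ between boxes")
    report = {}
    for name, x, y in (("arm1", box_a.arm1, box_b.arm1),
                       ("spacer", box_a.spacer, box_b.spacer),
                       ("arm2", box_a.arm2, box_b.arm2)):
        matches = [a == b for a, b in zip(x.upper(), y.upper())]
        report[f"{name}_matches"] = matches
        report[f"{name}_differences"] = sum(1 for m in matches if not m)
    return report


IR_TSV_COLUMNS = ["seq_id", "arm1_start", "arm1_end", "arm2_start", "arm2_end",
                  "arm_len", "spacer_len", "mismatches", "arm1_seq", "arm2_seq"]


def write_ir_tsv(repeats: Iterable[InvertedRepeat], path: str | Path,
                 coords: str = "one_based") -> None:
    """Write repeats as TSV; 1-based inclusive coordinates by default,
    BED-like 0-based half-open with ``coords='bed'``."""
    off = 1 if coords == "one_based" else 0
    with open(path, "w") as fh:
        fh.write("\t".join(IR_TSV_COLUMNS) + "\n")
        for r in repeats:
            a1s, a2s = r.arm1_start + off, r.arm2_start + off
            fh.write("\t".join(map(str, [
                r.seq_id, a1s, r.arm1_end, a2s, r.arm2_end,
                r.arm_len, r.spacer_len, r.mismatches, r.arm1_seq, r.arm2_seq,
            ])) + "\n")
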