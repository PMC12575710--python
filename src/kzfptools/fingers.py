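"""C2H2 zinc-finger detection and fingerprint extraction.

A canonical C2H2 zinc finger is matched as ``C-x(2,4)-C-x(10,14)-H-x(3,5)-H``.
The *fingerprint* of a finger is the four residues at helix positions
-1, +2, +3 and +6 — the positions that contact DNA and determine binding
specificity.  Helical numbering is anchored from the first coordinating
histidine (h1): -1 = h1-7, +2 = h1-5, +3 = h1-4, +6 = h1-1.  On the
canonical 12-residue spacer this is equivalent to indexing the spacer at
positions 6, 8, 9, 12 (1-based), and reproduces the classic Zif268
finger-1 fingerprint ``RDER``.

Fingers whose spacer carries a mutation in one of the conserved structural
residues (-12 F/Y, -3 F, +4 L) are flagged ``structural``; fingers rescued
with a single C/H anchor substitution are flagged ``ch_mutation``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KRAB_A_CONSENSUS",
    "ZincFinger",
    "FingerprintArray",
    "scan_c2h2",
    "extract_fingerprint",
    "detect_krab",
]

#: 42-residue KRAB-A box consensus shipped with the package. Synthetic genes
#: embed it verbatim; detection scores window identity against it.
KRAB_A_CONSENSUS = "RTLVTFKDVFVDFTREEWKLLDTAQQIVYRNVMLENYKNLVS"

# Spacer characters: any residue letter (X tolerated) but never a stop '*',
# so translated frames cannot chain fingers across stop codons.
_X = "[A-Z]"
_CANONICAL = re.compile(f"C{_X}{{2,4}}?C{_X}{{10,14}}?H{_X}{{3,5}}?H")

# Relaxed variants: exactly one of the four coordinating residues replaced.
# The substituted anchor must not itself be the canonical residue.
_RELAXED = [
    re.compile(f"[^C*]{_X}{{2,4}}?C{_X}{{10,14}}?H{_X}{{3,5}}?H"),
    re.compile(f"C{_X}{{2,4}}?[^C*]{_X}{{10,14}}?H{_X}{{3,5}}?H"),
    re.compile(f"C{_X}{{2,4}}?C{_X}{{10,14}}?[^H*]{_X}{{3,5}}?H"),
    re.compile(f"C{_X}{{2,4}}?C{_X}{{10,14}}?H{_X}{{3,5}}?[^H*]"),
]

#: minimum unmatched gap (residues) between two canonical fingers that is
#: searched for a degenerate finger in the rescue pass.
_RESCUE_MIN_GAP = 28


@dataclass
class ZincFinger:
    """One detected zinc finger, all offsets 0-based on the scanned protein."""

    protein_start: int
    protein_end: int  # exclusive
    c1: int
    c2: int
    h1: int
    h2: int
    spacer: str
    fingerprint: str = ""
    flag_ch_mutation: bool = False
    flag_structural_mutation: bool = False


@dataclass
class FingerprintArray:
    """Ordered fingerprints of one zinc-finger array.

    Identity between arrays is exact ordered string identity of the
    concatenated 4-mers (:attr:`key`); the mutation flags are carried for
    display but never enter the identity comparison.
    """

    entries: list[tuple[str, bool, bool]] = field(default_factory=list)

    @classmethod
    def from_fingers(cls, fingers: list[ZincFinger]) -> "FingerprintArray":
        return cls(
            [
                (f.fingerprint, f.flag_ch_mutation, f.flag_structural_mutation)
                for f in fingers
            ]
        )

    @property
    def key(self) -> str:
        return "".join(e[0] for e in self.entries)

    @property
    def display(self) -> str:
        out = []
        for fp, ch, st in self.entries:
            mark = "!" if ch else ("~" if st else "")
            out.append(fp + mark)
        return "-".join(out)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, FingerprintArray):
            return self.key == other.key
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.key)


def _finger_from_match(protein: str, start: int, end: int, *, ch_flag: bool) -> ZincFinger:
    """Build a ZincFinger from a regex match span.

    Anchor offsets are positional: the first and last residues are the C
    anchors' slots, the histidines are located from the right end.  For
    relaxed matches the substituted slot keeps its positional assignment.
    """
    seq = protein[start:end]
    # h2 is the last residue; h1 is found by matching the tail H-x(3,5)-H
    h2 = end - 1
    # search h1: positions end-1-4-1 .. end-1-6-1 relative; pick the residue
    # such that spacer length lands in [10, 14] from c2.
    # c1 is the first residue; c2 is 3..5 after c1.
    c1 = start
    # Locate c2 and h1 by enumerating slot widths (c2-c1 in 3..5, h2-h1 in
    # 4..6) under the spacer-length constraint; prefer assignments that put
    # actual C/H residues in the anchor slots, then spacers closest to 12.
    best = None
    for c2_off in range(3, 6):
        for h_gap in range(4, 7):
            c2 = start + c2_off
            h1 = h2 - h_gap
            spacer_len = h1 - c2 - 1
            if 10 <= spacer_len <= 14:
                score = (
                    (protein[c1] == "C")
                    + (protein[c2] == "C")
                    + (protein[h1] == "H")
                    + (protein[h2] == "H")
                )
                cand = (score, -abs(spacer_len - 12), c2, h1)
                if best is None or cand > best:
                    best = cand
    assert best is not None
    _, _, c2, h1 = best
    spacer = protein[c2 + 1 : h1]
    zf = ZincFinger(
        protein_start=start,
        protein_end=end,
        c1=c1,
        c2=c2,
        h1=h1,
        h2=h2,
        spacer=spacer,
        flag_ch_mutation=ch_flag,
    )
    zf.fingerprint, zf.flag_structural_mutation = extract_fingerprint(protein, zf)
    return zf


def scan_c2h2(protein: str) -> list[ZincFinger]:
    """Scan a protein left-to-right for C2H2 zinc fingers.

    Canonical fingers are matched non-overlapping with leftmost-shortest
    preference.  A second pass over unmatched gaps of at least
    28 residues *between* two canonical fingers admits fingers carrying
    exactly one C/H anchor substitution (``flag_ch_mutation``); this mirrors
    degenerate fingers occurring inside annotated arrays.

    An empty sequence yields an empty list.
    """
    protein = protein.upper()
    fingers = [
        _finger_from_match(protein, m.start(), m.end(), ch_flag=False)
        for m in _CANONICAL.finditer(protein)
    ]
    # rescue pass over inter-finger gaps
    rescued: list[ZincFinger] = []
    for left, right in zip(fingers, fingers[1:]):
        gap_start, gap_end = left.protein_end, right.protein_start
        if gap_end - gap_start < _RESCUE_MIN_GAP:
            continue
        pos = gap_start
        while pos < gap_end:
            best = None
            for pat in _RELAXED:
                m = pat.match(protein, pos, gap_end)
                if m and (best is None or m.end() < best.end()):
                    best = m
            if best is not None:
                rescued.append(
                    _finger_from_match(protein, best.start(), best.end(), ch_flag=True)
                )
                pos = best.end()
            else:
                pos += 1
    out = sorted(fingers + rescued, key=lambda f: f.protein_start)
    return out


def extract_fingerprint(protein: str, finger: ZincFinger) -> tuple[str, bool]:
    """Extract the 4-residue fingerprint and the structural-mutation flag.

    Positions are anchored from the first histidine: -1 = h1-7, +2 = h1-5,
    +3 = h1-4, +6 = h1-1.  Positions that would fall at or before c2 (a
    spacer shorter than 7) are padded with ``-`` and force the structural
    flag.  The structural flag is also set when -3 (h1-9) is not F, +4
    (h1-3) is not L, or -12 (two residues before c1) is not F/Y.
    """
    h1, c1, c2 = finger.h1, finger.c1, finger.c2
    fp = []
    padded = False
    for off in (7, 5, 4, 1):
        idx = h1 - off
        if idx <= c2 or idx < 0:
            fp.append("-")
            padded = True
        else:
            fp.append(protein[idx])
    structural = padded
    for idx, allowed in ((h1 - 9, "F"), (h1 - 3, "L"), (c1 - 2, "FY")):
        if idx < 0 or (idx <= c2 and idx > c1) or protein[idx] not in allowed:
            structural = True
    return "".join(fp), structural


def detect_krab(
    protein: str,
    consensus: str = KRAB_A_CONSENSUS,
    threshold: float = 0.6,
) -> tuple[bool, float, int]:
    """Slide the KRAB-A consensus over the protein and score window identity.

    Returns ``(found, score, offset)`` where *score* is the best fraction of
    consensus positions matched (partial overlaps at the protein ends are
    scored against the full consensus length) and *offset* is the protein
    position where the best window starts (may be negative for a partial
    left overlap).  ``found`` is ``score >= threshold``.
    """
    if not protein:
        return False, 0.0, 0
    p = np.frombuffer(protein.upper().encode("ascii"), dtype=np.uint8)
    c = np.frombuffer(consensus.upper().encode("ascii"), dtype=np.uint8)
    L = len(c)
    if len(p) >= L:
        windows = np.lib.stride_tricks.sliding_window_view(p, L)
        scores = (windows == c).mean(axis=1)
        best = int(np.argmax(scores))
        score = float(scores[best])
    else:
        # protein shorter than the consensus: best partial overlap
        best, score = 0, 0.0
        for off in range(-(L - 1), len(p)):
            lo, hi = max(0, off), min(len(p), off + L)
            if hi <= lo:
                continue
            m = int((p[lo:hi] == c[lo - off : hi - off]).sum())
            s = m / L
            if s > score:
                best, score = off, s
    return score >= threshold, score, best
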