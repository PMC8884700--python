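"""CDR localisation on VHH amino-acid sequences.

Anchor-motif heuristic (conserved Cys pair, FR2 Trp, FR4 WGxG motif) in the
spirit of structure-based CDR boundaries, plus a manual-span escape hatch.
Spans are 0-based half-open internally; reports also print 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["AnchorNotFoundError", "CdrRules", "AntibodyAnnotation", "annotate_cdrs"]


class AnchorNotFoundError(ValueError):
    """A required framework anchor motif could not be located."""


@dataclass(frozen=True)
class CdrRules:
    """Tunable anchor windows and offsets for motif-mode annotation.

    All indices are 0-based on the amino-acid sequence.
    """

    cys1_window: tuple[int, int] = (14, 30)   # search window for first conserved Cys
    cdr1_offset: int = 4                      # CDR1 starts this many residues after Cys1
    trp_search: tuple[int, int] = (7, 26)     # FR2 Trp window, relative to Cys1
    trp_gap: int = 2                          # CDR1 ends this many residues before the Trp
    cdr2_offset: int = 15                     # CDR2 starts this many residues after the Trp
    cdr2_len_range: tuple[int, int] = (4, 10)
    fr3_motif: str = r"[RK].{5}T[AV]Y"        # framework-3 start motif ending CDR2
    cdr2_fallback_len: int = 7
    cys2_window: tuple[int, int] = (84, 104)  # search window for second conserved Cys
    cdr3_offset: int = 3                      # CDR3 starts this many residues after Cys2
    fr4_motif: str = r"WG.G"                  # J-region motif; CDR3 ends at its Trp
    min_len: int = 80
    max_len: int = 160


@dataclass
class AntibodyAnnotation:
    """CDR1/2/3 spans (0-based half-open) and the framework anchors found."""

    aa_seq: str
    cdr1: tuple[int, int]
    cdr2: tuple[int, int]
    cdr3: tuple[int, int]
    anchors: dict = field(default_factory=dict)
    source: str = "motif"

    def __post_init__(self) -> None:
        spans = [self.cdr1, self.cdr2, self.cdr3]
        n = len(self.aa_seq)
        prev_end = 0
        for name, (s, e) in zip(("cdr1", "cdr2", "cdr3"), spans):
            if not (0 <= s < e <= n):
                raise ValueError(f"{name} span [{s},{e}) invalid for length {n}")
            if s < prev_end:
                raise ValueError("CDR spans must be disjoint and ordered")
            prev_end = e
        if self.source == "motif":
            cys2 = self.anchors.get("cys2")
            fr4 = self.anchors.get("fr4_trp")
            if cys2 is not None and cys2 >= self.cdr3[0]:
                raise ValueError("second Cys must precede cdr3 start")
            if fr4 is not None and fr4 < self.cdr3[1]:
                raise ValueError("WGxG motif must begin at or after cdr3 end")

    @property
    def spans(self) -> tuple[tuple[int, int], ...]:
        return (self.cdr1, self.cdr2, self.cdr3)

    def cdr_lengths(self) -> tuple[int, int, int]:
        return tuple(e - s for s, e in self.spans)  # type: ignore[return-value]

    def cdr_index_set(self) -> set[int]:
        """All 0-based sequence positions inside any CDR span."""
        out: set[int] = set()
        for s, e in self.spans:
            out.update(range(s, e))
        return out

    def to_report(self) -> dict:
        """JSON-friendly report with both 0-based half-open and 1-based inclusive."""
        rep = {"source": self.source, "anchors": dict(self.anchors)}
        for name, (s, e) in zip(("cdr1", "cdr2", "cdr3"), self.spans):
            rep[name] = {
                "zero_based_half_open": [s, e],
                "one_based_inclusive": [s + 1, e],
                "length": e - s,
                "sequence": self.aa_seq[s:e],
            }
        return rep


def annotate_cdrs(
    aa_seq: str,
    mode: str = "motif",
    manual_spans: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None,
    rules: CdrRules | None = None,
) -> AntibodyAnnotation:
    """Locate CDR1/2/3 either by framework anchor motifs or from manual spans.

    Motif mode raises :class:`AnchorNotFoundError` naming the first missing
    anchor; it never guesses.
    """
    aa_seq = aa_seq.strip().upper()
    if mode == "manual":
        if manual_spans is None or len(manual_spans) != 3:
            raise ValueError("manual mode requires exactly three spans")
        c1, c2, c3 = (tuple(s) for s in manual_spans)
        return AntibodyAnnotation(aa_seq, c1, c2, c3, anchors={}, source="manual")
    if mode != "motif":
        raise ValueError(f"unknown mode {mode!r}")

    rules = rules or CdrRules()
    n = len(aa_seq)
    if not (rules.min_len <= n <= rules.max_len):
        raise ValueError(
            f"sequence length {n} outside VHH-like range "
            f"[{rules.min_len}, {rules.max_len}] required for motif mode")

    lo, hi = rules.cys1_window
    cys1 = aa_seq.find("C", lo, hi)
    if cys1 < 0:
        raise AnchorNotFoundError("first conserved Cys not found")

    wlo, whi = rules.trp_search
    trp = aa_seq.find("W", cys1 + wlo, cys1 + whi)
    if trp < 0:
        raise AnchorNotFoundError("conserved FR2 Trp not found")

    cdr1 = (cys1 + rules.cdr1_offset, trp - rules.trp_gap)
    if cdr1[1] <= cdr1[0]:
        raise AnchorNotFoundError("CDR1 window collapsed (anchors too close)")

    cdr2_start = trp + rules.cdr2_offset
    lmin, lmax = rules.cdr2_len_range
    window = aa_seq[cdr2_start + lmin: cdr2_start + lmax + 1 + 8]
    m = re.search(rules.fr3_motif, window)
    if m is not None and m.start() <= lmax - lmin:
        cdr2_end = cdr2_start + lmin + m.start()
    else:
        cdr2_end = cdr2_start + rules.cdr2_fallback_len
    cdr2 = (cdr2_start, cdr2_end)

    clo, chi = rules.cys2_window
    cys2 = aa_seq.find("C", clo, chi)
    if cys2 < 0:
        raise AnchorNotFoundError("second conserved Cys not found")

    m4 = re.search(rules.fr4_motif, aa_seq[cys2:])
    if m4 is None:
        raise AnchorNotFoundError("WGxG motif (FR4) not found")
    fr4_trp = cys2 + m4.start()

    cdr3 = (cys2 + rules.cdr3_offset, fr4_trp)
    if cdr3[1] <= cdr3[0]:
        raise AnchorNotFoundError("CDR3 window collapsed (anchors too close)")

    anchors = {"cys1": cys1, "fr2_trp": trp, "cys2": cys2, "fr4_trp": fr4_trp}
    return AntibodyAnnotation(aa_seq, cdr1, cdr2, cdr3, anchors=anchors, source="motif")
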