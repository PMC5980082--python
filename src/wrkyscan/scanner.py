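"""WRKY-domain detection by grammar scanning.

A WRKY domain is an N-terminal heptapeptide anchor (canonically ``WRKYGQK``)
followed, within a bounded window, by a zinc-finger arrangement of
metal-coordinating residues:

* C2H2 finger (Groups I and II): ``C-X(4,5)-C-X(22,23)-H-X(1)-H``
* C2HC finger (Group III):       ``C-X(7)-C-X(23)-H-X(1)-C``

The scanner matches the heptapeptide against an enumerated variant list
(exact strings, not fuzzy), then searches downstream for the earliest
zinc-finger arrangement satisfying the spacer ranges.  All coordinates are
0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .seq_io import ProteinRecord

#: Heptapeptide variants actually observed in Taxus chinensis.
CANONICAL_VARIANTS = ("WRKYGQK", "WRKYGKK")

#: Additional variants reported from angiosperms (e.g. soybean); opt-in.
EXTENDED_VARIANTS = CANONICAL_VARIANTS + (
    "WRKYGEK", "WRKYGKR", "WRKYEDK", "WKKYGQK", "WHQYGLK",
)

#: Default zinc-finger search window (residues downstream of the
#: heptapeptide end).  Covers the ~60-aa canonical domain with margin.
DEFAULT_WINDOW = 80


@dataclass(frozen=True)
class ZincFingerGrammar:
    """Anchor residues plus inclusive spacer-length ranges between them."""

    name: str
    anchors: tuple[str, ...]
    spacers: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.spacers) != len(self.anchors) - 1:
            raise ValueError("need one spacer range per consecutive anchor pair")
        for lo, hi in self.spacers:
            if lo < 0 or lo > hi:
                raise ValueError(f"bad spacer range ({lo}, {hi})")

    def validate(self, sequence: str, positions: Sequence[int]) -> bool:
        """Re-check that ``positions`` satisfy this grammar on ``sequence``."""
        if len(positions) != len(self.anchors):
            return False
        for pos, aa in zip(positions, self.anchors):
            if pos < 0 or pos >= len(sequence) or sequence[pos] != aa:
                return False
        for (a, b), (lo, hi) in zip(zip(positions, positions[1:]), self.spacers):
            gap = b - a - 1
            if not (lo <= gap <= hi):
                return False
        return True


C2H2 = ZincFingerGrammar("C2H2", ("C", "C", "H", "H"), ((4, 5), (22, 23), (1, 1)))
C2HC = ZincFingerGrammar("C2HC", ("C", "C", "H", "C"), ((7, 7), (23, 23), (1, 1)))

DEFAULT_GRAMMARS = (C2H2, C2HC)


@dataclass(frozen=True)
class Anchor:
    """A heptapeptide occurrence."""

    start: int
    end: int          # start + 7
    heptapeptide: str
    variant: str      # "canonical" or the matched variant string


@dataclass(frozen=True)
class WrkyDomain:
    """A detected WRKY domain on one protein.

    ``zf_type`` is ``"C2H2"``, ``"C2HC"`` or ``"incomplete"`` (no valid
    zinc-finger arrangement within the window).  ``zf_positions`` are the
    absolute indices of the coordinating residues, empty when incomplete.
    ``terminal`` is ``"N"``/``"C"`` on multi-domain proteins, else
    ``"single"``.  ``ambiguous`` marks domains whose downstream region
    satisfies both grammars (typed C2H2 by tie-break).
    """

    protein_id: str
    heptapeptide: str
    hept_start: int
    hept_end: int
    variant: str
    zf_type: str
    zf_positions: tuple[int, ...]
    start: int
    end: int
    terminal: str = "single"
    ambiguous: bool = False


def find_heptapeptides(
    record: ProteinRecord,
    variants: Sequence[str] = CANONICAL_VARIANTS,
) -> list[Anchor]:
    """All occurrences of any listed heptapeptide variant, left to right.

    Occurrences are reported at every distinct start position (starts are
    necessarily distinct; patterns are all 7-mers).  The canonical
    ``WRKYGQK`` is tagged ``"canonical"``; others carry the variant string.
    """
    if not variants:
        raise ValueError("variant list must be non-empty")
    bad = [v for v in variants if len(v) != 7]
    if bad:
        raise ValueError(f"variants must be 7-letter patterns, got {bad}")
    seq = record.sequence
    hits: list[Anchor] = []
    for i in range(len(seq) - 6):
        word = seq[i:i + 7]
        if word in variants:
            tag = "canonical" if word == "WRKYGQK" else word
            hits.append(Anchor(start=i, end=i + 7, heptapeptide=word, variant=tag))
    return hits


def match_zinc_finger(
    record: ProteinRecord,
    anchor: Anchor,
    grammar: ZincFingerGrammar,
    window: int = DEFAULT_WINDOW,
) -> tuple[int, ...] | None:
    """Earliest zinc-finger arrangement downstream of ``anchor``.

    Scans at most ``window`` residues past the heptapeptide end.  Among
    arrangements sharing the leftmost first anchor residue, the
    lexicographically smallest position vector wins.  Returns absolute
    positions of the coordinating residues, or None.
    """
    seq = record.sequence
    lo = anchor.end
    hi = min(len(seq), anchor.end + window)

    def extend(prefix: tuple[int, ...], level: int) -> tuple[int, ...] | None:
        if level == len(grammar.anchors):
            return prefix
        aa = grammar.anchors[level]
        if level == 0:
            candidates = range(lo, hi)
        else:
            smin, smax = grammar.spacers[level - 1]
            base = prefix[-1]
            candidates = range(base + 1 + smin, min(base + 1 + smax, hi - 1) + 1)
        for pos in candidates:
            if pos < hi and seq[pos] == aa:
                found = extend(prefix + (pos,), level + 1)
                if found is not None:
                    return found
        return None

    return extend((), 0)


def scan_protein(
    record: ProteinRecord,
    grammars: Sequence[ZincFingerGrammar] = DEFAULT_GRAMMARS,
    variants: Sequence[str] = CANONICAL_VARIANTS,
    window: int = DEFAULT_WINDOW,
) -> list[WrkyDomain]:
    """Detect all WRKY domains on one protein.

    One domain per heptapeptide anchor.  Zinc-finger typing tries C2H2 first,
    then C2HC; an anchor matching both is flagged ambiguous and typed C2H2
    (the majority class).  Domains whose residue intervals overlap are
    resolved by keeping the earlier anchor.  Terminal tags are assigned
    N/.../C when two or more domains survive, else "single".
    """
    if len(grammars) < 2:
        raise ValueError("both zinc-finger grammars must be supplied")
    c2h2 = next(g for g in grammars if g.name == "C2H2")
    c2hc = next(g for g in grammars if g.name == "C2HC")

    domains: list[WrkyDomain] = []
    for anchor in find_heptapeptides(record, variants):
        pos_h2 = match_zinc_finger(record, anchor, c2h2, window)
        pos_hc = match_zinc_finger(record, anchor, c2hc, window)
        if pos_h2 is not None:
            zf_type, zf_pos = "C2H2", pos_h2
        elif pos_hc is not None:
            zf_type, zf_pos = "C2HC", pos_hc
        else:
            zf_type, zf_pos = "incomplete", ()
        end = (zf_pos[-1] + 1) if zf_pos else anchor.end
        domains.append(
            WrkyDomain(
                protein_id=record.id,
                heptapeptide=anchor.heptapeptide,
                hept_start=anchor.start,
                hept_end=anchor.end,
                variant=anchor.variant,
                zf_type=zf_type,
                zf_positions=zf_pos,
                start=anchor.start,
                end=end,
                ambiguous=(pos_h2 is not None and pos_hc is not None),
            )
        )

    # overlap resolution: keep the earlier anchor
    kept: list[WrkyDomain] = []
    for dom in domains:
        if kept and dom.start < kept[-1].end:
            continue
        kept.append(dom)

    if len(kept) >= 2:
        tags = ["N"] + [f"M{i}" for i in range(1, len(kept) - 1)] + ["C"]
        kept = [replace(d, terminal=t) for d, t in zip(kept, tags)]
    return kept


def scan_all(
    records: Iterable[ProteinRecord],
    grammars: Sequence[ZincFingerGrammar] = DEFAULT_GRAMMARS,
    variants: Sequence[str] = CANONICAL_VARIANTS,
    window: int = DEFAULT_WINDOW,
) -> dict[str, list[WrkyDomain]]:
    """Scan a collection; returns protein id -> domain list (possibly empty)."""
    return {
        r.id: scan_protein(r, grammars=grammars, variants=variants, window=window)
        for r in records
    }


def extract_domain_sequences(
    records: dict[str, ProteinRecord] | Iterable[ProteinRecord],
    domains: Iterable[WrkyDomain],
    flank: int = 0,
) -> list[ProteinRecord]:
    """Cut detected domains out of their proteins (plus ``flank`` residues
    per side, clipped at the sequence bounds).

    Domains from multi-domain proteins get ids suffixed ``-N``/``-C`` after
    their terminal tag; single domains keep the bare protein id.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not isinstance(records, dict):
        records = {r.id: r for r in records}
    out: list[ProteinRecord] = []
    for dom in domains:
        rec = records[dom.protein_id]
        lo = max(0, dom.start - flank)
        hi = min(len(rec.sequence), dom.end + flank)
        suffix = "" if dom.terminal == "single" else f"-{dom.terminal}"
        out.append(
            ProteinRecord(
                id=f"{dom.protein_id}{suffix}",
                description=f"WRKY domain {lo}-{hi}",
                sequence=rec.sequence[lo:hi],
            )
        )
    return out


def domains_to_rows(domains: Iterable[WrkyDomain]) -> list[dict]:
    """Flatten domains for TSV reporting."""
    return [
        {
            "protein_id": d.protein_id,
            "start": d.start,
            "end": d.end,
            "heptapeptide": d.heptapeptide,
            "variant": d.variant,
            "zf_type": d.zf_type,
            "zf_positions": ",".join(map(str, d.zf_positions)),
            "terminal": d.terminal,
            "ambiguous": int(d.ambiguous),
        }
        for d in domains
    ]
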