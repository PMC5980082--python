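"""Accessory regulatory-motif annotation.

Short linear motifs reported for WRKY proteins are matched by pattern
class, not by an enumerated subtype list:

* ``EAR_LxLxL``  — the L-x-L-x-L repression core (reported with one residue
  of trailing context when available, so 6-letter subtype names such as
  LKLDLY come out literally);
* ``EAR_DLNxxP`` — the DLNxxP repression core;
* ``LxxLL``      — the nuclear-receptor-style interaction helix;
* ``HARF``       — the RTGHARFRR(A/G)P peptide of Group IId WRKYs;
* ``LeucineZipper`` — a heuristic: >= ``min_repeats`` leucines at exact
  7-residue spacing (I/V tolerated internally behind a flag).

Overlapping hits of the same class are all reported.  Profile-HMM domains
(Plant_zf_clust, CaMBD, HSF) are not computed; pre-computed annotations can
be merged from a TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .seq_io import ProteinRecord

MOTIF_CLASSES = ("EAR_LxLxL", "EAR_DLNxxP", "LxxLL", "HARF", "LeucineZipper")

_LXXLL = re.compile(r"(?=(L..LL))")
_LXLXL = re.compile(r"(?=(L.L.L))")
_DLNXXP = re.compile(r"(?=(DLN..P))")
_HARF = re.compile(r"(?=(RTGHARFRR[AG]P))")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``subtype`` is the literal matched core."""

    protein_id: str
    motif_class: str
    subtype: str
    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if self.motif_class == "LeucineZipper":
            return  # subtype is a descriptive tag (e.g. L7x4), not a core
        if self.matched != self.subtype and not self.subtype.startswith(self.matched):
            # subtype may extend matched by context, never the reverse
            raise ValueError("subtype must equal or extend the matched core")


def _regex_hits(
    record: ProteinRecord, pattern: re.Pattern, motif_class: str
) -> list[MotifHit]:
    hits = []
    for m in pattern.finditer(record.sequence):
        core = m.group(1)
        start = m.start()
        hits.append(
            MotifHit(
                protein_id=record.id,
                motif_class=motif_class,
                subtype=core,
                start=start,
                end=start + len(core),
                matched=core,
            )
        )
    return hits


def find_lxxll(record: ProteinRecord) -> list[MotifHit]:
    """All (possibly overlapping) L-x-x-L-L occurrences; subtype = the 5-mer."""
    return _regex_hits(record, _LXXLL, "LxxLL")


def find_harf(record: ProteinRecord) -> list[MotifHit]:
    """Occurrences of RTGHARFRR(A/G)P."""
    return _regex_hits(record, _HARF, "HARF")


def find_ear(record: ProteinRecord) -> list[MotifHit]:
    """EAR repression motifs of both structural classes.

    LxLxL cores are reported with one residue of trailing context when the
    sequence extends past the core, reproducing conventional 6-letter
    subtype names (LKLDLY, LKLALS, ...); the hit interval covers the core
    only.
    """
    hits: list[MotifHit] = []
    seq = record.sequence
    for m in _LXLXL.finditer(seq):
        core = m.group(1)
        start = m.start()
        end = start + 5
        subtype = seq[start:end + 1] if end < len(seq) else core
        hits.append(
            MotifHit(record.id, "EAR_LxLxL", subtype, start, end, core)
        )
    hits.extend(_regex_hits(record, _DLNXXP, "EAR_DLNxxP"))
    return hits


def find_leucine_zipper(
    record: ProteinRecord,
    period: int = 7,
    min_repeats: int = 4,
    allow_iv: bool = False,
) -> list[MotifHit]:
    """Heuristic leucine-zipper call: maximal runs of leucines at exact
    ``period`` spacing with at least ``min_repeats`` positions.

    With ``allow_iv=True``, isoleucine/valine are tolerated at internal
    repeat positions (the first and last must still be L).
    """
    if period <= 0 or min_repeats <= 0:
        raise ValueError("period and min_repeats must be positive")
    seq = record.sequence
    internal_ok = set("LIV") if allow_iv else {"L"}
    hits: list[MotifHit] = []
    for start in range(len(seq)):
        if seq[start] != "L":
            continue
        if start - period >= 0 and seq[start - period] in internal_ok:
            continue  # suffix of a longer run; only maximal runs reported
        positions = [start]
        nxt = start + period
        while nxt < len(seq) and seq[nxt] in internal_ok:
            positions.append(nxt)
            nxt += period
        while positions and seq[positions[-1]] != "L":
            positions.pop()  # runs must end on a leucine
        if len(positions) < min_repeats:
            continue
        lo, hi = positions[0], positions[-1] + 1
        heptads = len(positions)
        hits.append(
            MotifHit(
                protein_id=record.id,
                motif_class="LeucineZipper",
                subtype=f"L7x{heptads}",
                start=lo,
                end=hi,
                matched=seq[lo:hi],
            )
        )
    return hits


def annotate_all(
    records: Iterable[ProteinRecord],
    classes: Sequence[str] = MOTIF_CLASSES,
    *,
    zipper_period: int = 7,
    zipper_min_repeats: int = 4,
    zipper_allow_iv: bool = False,
) -> tuple[list[MotifHit], dict[str, int]]:
    """Annotate all requested motif classes on every record.

    Returns coordinate-sorted hits (by protein id, then start, then class)
    plus per-class counts.  Records never interact: hits are strictly
    per-sequence.
    """
    bad = set(classes) - set(MOTIF_CLASSES)
    if bad:
        raise ValueError(f"unknown motif class(es) {sorted(bad)}")
    hits: list[MotifHit] = []
    for rec in records:
        if "EAR_LxLxL" in classes or "EAR_DLNxxP" in classes:
            for h in find_ear(rec):
                if h.motif_class in classes:
                    hits.append(h)
        if "LxxLL" in classes:
            hits.extend(find_lxxll(rec))
        if "HARF" in classes:
            hits.extend(find_harf(rec))
        if "LeucineZipper" in classes:
            hits.extend(
                find_leucine_zipper(
                    rec, period=zipper_period, min_repeats=zipper_min_repeats,
                    allow_iv=zipper_allow_iv,
                )
            )
    hits.sort(key=lambda h: (h.protein_id, h.start, h.motif_class, h.end))
    counts = {c: 0 for c in classes}
    for h in hits:
        counts[h.motif_class] += 1
    return hits, counts


def hits_to_rows(hits: Iterable[MotifHit]) -> list[dict]:
    return [
        {
            "protein_id": h.protein_id,
            "class": h.motif_class,
            "subtype": h.subtype,
            "start": h.start,
            "end": h.end,
        }
        for h in hits
    ]


def merge_external_annotations(
    hits: Iterable[MotifHit], tsv_path, *, sep: str = "\t"
) -> pd.DataFrame:
    """Merge regex hits with pre-computed external domain annotations.

    The TSV must have columns protein_id, domain_name, start, end, source
    (e.g. Pfam profile hits computed elsewhere).  Returns one combined
    DataFrame with a ``source`` column ('scan' for in-repo hits).
    """
    own = pd.DataFrame(hits_to_rows(hits))
    if own.empty:
        own = pd.DataFrame(columns=["protein_id", "class", "subtype", "start", "end"])
    own = own.rename(columns={"class": "domain_name"})
    own["source"] = "scan"
    own = own.drop(columns=["subtype"])
    ext = pd.read_csv(tsv_path, sep=sep)
    need = {"protein_id", "domain_name", "start", "end", "source"}
    if not need <= set(ext.columns):
        raise ValueError(f"external annotation TSV needs columns {sorted(need)}")
    merged = pd.concat([own, ext[sorted(own.columns)]], ignore_index=True)
    return merged.sort_values(["protein_id", "start"]).reset_index(drop=True)
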