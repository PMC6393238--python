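"""Editing quantification from Sanger chromatogram peak heights.

A-to-I editing reads as an A/G mixed peak in the sequencing trace of the
RT-PCR product; the editing level at a site is 100 * G / (A + G) computed
from the two peak heights. This module locates the edited site from an
anchor subsequence (e.g. the RT-PCR primer), computes the editing percent,
and scans flanking adenosines for off-target editing.

Input is either an AB1 trace file (read with Biopython) or a plain CSV of
per-call peak heights (``sample,position,base,A,C,G,T``) so the whole
module is testable without binary fixtures. Peak height, not area, is
used; no baseline subtraction is applied by default, which can diverge
slightly from commercial chromatogram viewers that background-correct.
Coordinates are 0-based internally and 1-based in written reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["position", "base", "A", "C", "G", "T"]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TraceSite:
    """The four channel peak heights at one base-call position."""

    position: int
    a: float
    c: float
    g: float
    t: float

    def __post_init__(self) -> None:
        heights = (self.a, self.c, self.g, self.t)
        if any(h < 0 for h in heights):
            raise ValueError("peak heights must be >= 0")
        if not any(h > 0 for h in heights):
            raise ValueError("at least one peak height must be > 0")


@dataclass(frozen=True)
class EditingCall:
    """An editing percentage at a site, with its offset from the anchor site."""

    site: TraceSite
    editing_pct: float
    anchor_offset: int = 0


def editing_pct(site: TraceSite) -> float:
    """Editing percent 100 * G / (A + G) from the site's peak heights.

    C and T heights are ignored; the statistic is invariant under common
    rescaling of all four peaks, so raw fluorescence units never matter.
    """
    total = site.a + site.g
    if not total > 0:
        raise ValueError(
            f"position {site.position}: A + G peak heights are zero; not an A/G site"
        )
    return 100.0 * site.g / total


def locate_site(basecalls: str, anchor: str, offset: int) -> int:
    """Locate the editing site as ``anchor start + offset`` in the base calls.

    The anchor (>= 10 nt, e.g. the RT-PCR primer) must match exactly once,
    on either strand. For a reverse-complement match the returned index is
    counted in the anchor's own orientation, i.e. walking ``offset`` bases
    from the anchor's 5' end toward its 3' end and flipping back to
    base-call coordinates.
    """
    if len(anchor) < 10:
        raise ValueError("anchor must be at least 10 nt")
    seq = basecalls.upper()
    fwd = anchor.upper()
    rev = reverse_complement(fwd)

    def find_all(pattern: str) -> list[int]:
        hits, start = [], 0
        while (i := seq.find(pattern, start)) != -1:
            hits.append(i)
            start = i + 1
        return hits

    fwd_hits = find_all(fwd)
    rev_hits = find_all(rev)
    n = len(fwd_hits) + len(rev_hits)
    if n != 1:
        raise ValueError(f"anchor matches {n} times in base calls; need exactly 1")
    if fwd_hits:
        pos = fwd_hits[0] + offset
    else:
        pos = rev_hits[0] + len(anchor) - 1 - offset
    if not 0 <= pos < len(seq):
        raise ValueError(f"anchor + offset points outside the trace ({pos})")
    return pos


def trace_site(trace: pd.DataFrame, position: int) -> TraceSite:
    row = trace.loc[trace["position"] == position]
    if row.empty:
        raise ValueError(f"position {position} not in trace")
    r = row.iloc[0]
    return TraceSite(int(r["position"]), float(r["A"]), float(r["C"]), float(r["G"]), float(r["T"]))


@dataclass
class OfftargetReport:
    """Flanking-adenosine scan: calls passing ``min_pct`` plus scan counts."""

    calls: list[EditingCall]
    n_scanned: int
    n_suppressed: int


def offtarget_scan(
    trace: pd.DataFrame,
    center: int,
    window: int,
    min_pct: float = 5.0,
) -> OfftargetReport:
    """Editing percent at every reference adenosine within ±``window`` nt.

    The window is truncated silently at the trace ends. Sites below
    ``min_pct`` are suppressed from the call list but counted in the
    summary; ``window = 0`` reports only the center site.
    """
    positions = set(trace["position"].astype(int))
    if center not in positions:
        raise ValueError(f"center position {center} outside trace")
    lo, hi = center - window, center + window
    calls: list[EditingCall] = []
    n_scanned = n_suppressed = 0
    for pos in sorted(p for p in positions if lo <= p <= hi):
        site = trace_site(trace, pos)
        base = str(trace.loc[trace["position"] == pos, "base"].iloc[0]).upper()
        if base != "A":
            continue
        n_scanned += 1
        pct = editing_pct(site)
        if pct >= min_pct:
            calls.append(EditingCall(site, pct, anchor_offset=pos - center))
        else:
            n_suppressed += 1
    return OfftargetReport(calls, n_scanned, n_suppressed)


# ---------------------------------------------------------------------------
# Input readers


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    """Per-call peak-height CSV with columns position,base,A,C,G,T."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV lacks column(s) {missing}")
    return df[TRACE_COLUMNS].copy()


def read_ab1(path: str | Path) -> pd.DataFrame:
    """Peak heights at each base call from an AB1 trace file.

    Uses Biopython's ``abi`` parser: raw channel data (``DATA9``-``DATA12``,
    in the ``FWO_`` filter-wheel order) sampled at the per-call peak
    locations (``PLOC2``/``PLOC1``), which is the per-call trace maximum a
    chromatogram viewer displays.
    """
    from Bio import SeqIO

    record = SeqIO.read(str(path), "abi")
    raw = record.annotations["abif_raw"]
    order_raw = raw["FWO_1"]
    order = order_raw.decode() if isinstance(order_raw, bytes) else str(order_raw)
    channels = {
        base: np.asarray(raw[f"DATA{9 + i}"], dtype=float) for i, base in enumerate(order)
    }
    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    if ploc is None:
        raise ValueError(f"{path}: AB1 file has no peak-location (PLOC) tag")
    calls = str(record.seq)
    rows = []
    for i, loc in enumerate(ploc):
        rows.append(
            {
                "position": i,
                "base": calls[i] if i < len(calls) else "N",
                **{b: float(channels[b][loc]) for b in "ACGT"},
            }
        )
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def quantify_editing(
    trace: pd.DataFrame,
    anchor: str,
    offset: int,
    window: int = 0,
    min_pct: float = 5.0,
) -> tuple[EditingCall, OfftargetReport]:
    """Locate the edited site from an anchor and quantify it (plus flanks)."""
    basecalls = "".join(trace.sort_values("position")["base"].astype(str))
    pos = locate_site(basecalls, anchor, offset)
    site = trace_site(trace, pos)
    call = EditingCall(site, editing_pct(site), anchor_offset=0)
    report = offtarget_scan(trace, pos, window, min_pct=min_pct) if window else OfftargetReport(
        [call], 1, 0
    )
    return call, report
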