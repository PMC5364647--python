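"""Interaction prediction: local antisense alignment and table import.

The built-in predictor looks for stretches of an sRNA that can base-pair
with a target 5'UTR.  Following the classical trick of antisense searching
with a homology aligner, the UTR is reverse-complemented and a
Smith–Waterman local alignment (linear gap penalty) is run against the
sRNA; a match in that space is a Watson–Crick pair (A-U or G-C) in the
duplex, and G·U wobble pairs receive their own (lower) reward.  Hit
coordinates on the UTR are mapped back through the reverse-complement
transform.  IUPAC ambiguity codes never pair and score as mismatches.

Suboptimal hits are produced greedily: after reporting a hit, the sRNA
and UTR positions it used are masked and the alignment is recomputed,
until the best score falls below ``min_score`` or ``max_hits`` is
reached.  Reported hits therefore never overlap on either sequence and
their scores are non-increasing.

Energy-based predictions are not recomputed here: tables in the common
semicolon/comma-separated convention (columns id1,start1,end1,
id2,start2,end2,E) are imported as interactions with the free energy E
(kcal/mol, more negative = more stable duplex) as score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, RegionError, ValidationError
from .model import (
    MRNA,
    SRNA,
    Interaction,
    Region,
    RegulatoryNetwork,
    RnaNode,
)
from .sequence_io import RNA_ALPHABET, reverse_complement

logger = logging.getLogger(__name__)

_NEG = -1e18  # effectively -inf for masked DP cells


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for the antisense aligner.

    Defaults (+2 match / +1 wobble / -1 mismatch / -2 per gap position,
    report threshold 8) require at least four consecutive Watson–Crick
    pairs before a hit is reported.
    """

    match: float = 2.0
    wobble: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    min_score: float = 8.0
    max_hits: int = 3

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValidationError("match reward must be positive")
        if self.gap >= 0:
            raise ValidationError("gap penalty must be negative")
        if self.min_score <= 0:
            raise ValidationError("min_score must be positive")
        if self.max_hits < 1:
            raise ValidationError("max_hits must be >= 1")


@dataclass(frozen=True)
class AlignmentHit:
    """One local antisense alignment above threshold.

    ``mrna_region`` is on the original 5'UTR in 5'->3' coordinates.
    ``paired_string`` is a three-line trace: sRNA 5'->3', pairing symbols
    ('|' Watson–Crick, ':' wobble, '.' mismatch, ' ' gap), UTR 3'->5'.
    """

    score: float
    srna_region: Region
    mrna_region: Region
    paired_string: str


def _pair_score(a: str, b: str, p: AlignParams) -> float:
    """Score of aligning sRNA char *a* to reverse-complement-space char *b*.

    Equality of unambiguous bases means a Watson–Crick duplex pair; (G,A)
    and (U,C) in rc-space are the two G·U wobble orientations.
    """
    if a == b and a in "ACGU":
        return p.match
    if (a == "G" and b == "A") or (a == "U" and b == "C"):
        return p.wobble
    return p.mismatch


def _sw_matrix(
    srna: str, rcu: str, p: AlignParams,
    row_mask: np.ndarray, col_mask: np.ndarray,
) -> np.ndarray:
    n, m = len(srna), len(rcu)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        if row_mask[i - 1]:
            continue  # row stays 0: no alignment crosses a masked base
        a = srna[i - 1]
        for j in range(1, m + 1):
            if col_mask[j - 1]:
                continue
            diag = H[i - 1, j - 1] + _pair_score(a, rcu[j - 1], p)
            up = H[i - 1, j] + p.gap
            left = H[i, j - 1] + p.gap
            H[i, j] = max(0.0, diag, up, left)
    return H


def _traceback(
    H: np.ndarray, srna: str, rcu: str, p: AlignParams, i: int, j: int
) -> tuple[int, int, str, str, str]:
    """Walk back from cell (i, j) to the start of the local alignment.

    Ties resolve diagonal > up > left for determinism.  Returns the
    1-based start row/col and the three trace lines (top = sRNA, mid =
    symbols, bottom = rc-space chars, later complemented for display).
    """
    top: list[str] = []
    mid: list[str] = []
    bot: list[str] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        a, b = srna[i - 1], rcu[j - 1]
        s = _pair_score(a, b, p)
        if H[i, j] == H[i - 1, j - 1] + s:
            top.append(a)
            bot.append(b)
            if s == p.match and a == b and a in "ACGU":
                mid.append("|")
            elif s == p.wobble:
                mid.append(":")
            else:
                mid.append(".")
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + p.gap:
            top.append(a)
            mid.append(" ")
            bot.append("-")
            i -= 1
        else:
            top.append("-")
            mid.append(" ")
            bot.append(b)
            j -= 1
    return i + 1, j + 1, "".join(reversed(top)), "".join(reversed(mid)), "".join(reversed(bot))


def rescore_trace(paired_string: str, p: AlignParams) -> float:
    """Recompute an alignment score from its display trace.

    Works in duplex space (sRNA char vs original UTR char), independently
    of the reverse-complement machinery: A-U/G-C score match, G·U scores
    wobble, gaps score gap, anything else mismatch.
    """
    top, _mid, bottom = paired_string.split("\n")
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wobble = {("G", "U"), ("U", "G")}
    total = 0.0
    for a, b in zip(top, bottom):
        if a == "-" or b == "-":
            total += p.gap
        elif (a, b) in wc:
            total += p.match
        elif (a, b) in wobble:
            total += p.wobble
        else:
            total += p.mismatch
    return total


def antisense_align(
    srna: str, utr: str, p: AlignParams = AlignParams()
) -> list[AlignmentHit]:
    """Local antisense alignment of an sRNA against a 5'UTR.

    Returns hits best-first; greedy non-overlapping suboptimals up to
    ``p.max_hits``, each with score >= ``p.min_score``.
    """
    srna = srna.upper().replace("T", "U")
    utr = utr.upper().replace("T", "U")
    if not srna or not utr:
        raise ValidationError("sequences must be non-empty")
    for name, s in (("sRNA", srna), ("UTR", utr)):
        bad = set(s) - RNA_ALPHABET
        if bad:
            raise ParseError(f"{name} sequence: non-IUPAC characters {sorted(bad)}")
    rcu = reverse_complement(utr)
    L = len(utr)
    row_mask = np.zeros(len(srna), dtype=bool)
    col_mask = np.zeros(L, dtype=bool)
    hits: list[AlignmentHit] = []
    while len(hits) < p.max_hits:
        H = _sw_matrix(srna, rcu, p, row_mask, col_mask)
        best = float(H.max())
        if best < p.min_score:
            break
        i2, j2 = np.unravel_index(int(np.argmax(H)), H.shape)
        i1, j1, top, mid, bot = _traceback(H, srna, rcu, p, int(i2), int(j2))
        # rc-space cols [j1, j2] map back to UTR positions [L-j2+1, L-j1+1]
        srna_region = Region(i1, int(i2))
        mrna_region = Region(L - int(j2) + 1, L - j1 + 1)
        # display bottom line as the original UTR read 3'->5'
        utr_line = "".join(
            "-" if c == "-" else reverse_complement(c) for c in bot
        )
        hits.append(
            AlignmentHit(
                score=best,
                srna_region=srna_region,
                mrna_region=mrna_region,
                paired_string=f"{top}\n{mid}\n{utr_line}",
            )
        )
        row_mask[i1 - 1 : int(i2)] = True
        col_mask[j1 - 1 : int(j2)] = True
    return hits


def predict_network(
    srnas: list[tuple[str, str]],
    utrs: list[tuple[str, str]],
    p: AlignParams = AlignParams(),
) -> RegulatoryNetwork:
    """Build a bipartite network from all-against-all antisense alignment.

    One sRNA node per input sRNA, one mRNA node per UTR, one interaction
    per reported hit (method ``antisense_align``).
    """
    srna_ids = [sid for sid, _ in srnas]
    gene_ids = [gid for gid, _ in utrs]
    if len(set(srna_ids)) != len(srna_ids) or len(set(gene_ids)) != len(gene_ids):
        raise ValidationError("duplicate ids within the sRNA or UTR list")
    collisions = set(srna_ids) & set(gene_ids)
    if collisions:
        raise ValidationError(f"id collision between sRNAs and genes: {sorted(collisions)}")
    logger.info(
        "antisense prediction: %d sRNAs x %d UTRs, params %s", len(srnas), len(utrs), p
    )
    net = RegulatoryNetwork(meta={"created_by": "predict_network"})
    for sid, seq in srnas:
        net.add_node(RnaNode(id=sid, role=SRNA, gene_name=sid, sequence=seq))
    for gid, seq in utrs:
        net.add_node(RnaNode(id=gid, role=MRNA, gene_name=gid, sequence=seq))
    for sid, sseq in srnas:
        for gid, useq in utrs:
            for hit in antisense_align(sseq, useq, p):
                net.interactions.append(
                    Interaction(
                        srna_id=sid,
                        mrna_id=gid,
                        srna_region=hit.srna_region,
                        mrna_region=hit.mrna_region,
                        score=hit.score,
                        method="antisense_align",
                    )
                )
    return net


_MANDATORY = ("id1", "start1", "end1", "id2", "start2", "end2", "E")


def parse_intarna_table(
    path: str | Path,
    sep: str | None = None,
    mrna_side: str = "1",
    column_map: dict[str, str] | None = None,
) -> list[Interaction]:
    """Import an energy-based prediction table as interactions.

    The table must carry columns id1,start1,end1,id2,start2,end2,E
    (renameable through ``column_map``); by convention side 1 is the
    mRNA/target and side 2 the sRNA/query (swap with ``mrna_side='2'``).
    The separator is sniffed (';' vs ',') unless given.
    """
    path = Path(path)
    if sep is None:
        header = path.read_text().splitlines()[0] if path.read_text() else ""
        sep = ";" if header.count(";") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing mandatory column(s) {missing}")
    if mrna_side == "1":
        m, s = "1", "2"
    else:
        m, s = "2", "1"
    out: list[Interaction] = []
    for idx, row in df.iterrows():
        try:
            energy = float(row["E"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {idx}: non-numeric E {row['E']!r}") from exc
        try:
            srna_region = Region(int(row[f"start{s}"]), int(row[f"end{s}"]))
            mrna_region = Region(int(row[f"start{m}"]), int(row[f"end{m}"]))
        except RegionError as exc:
            raise RegionError(f"{path}: row {idx}: {exc}") from exc
        out.append(
            Interaction(
                srna_id=str(row[f"id{s}"]),
                mrna_id=str(row[f"id{m}"]),
                srna_region=srna_region,
                mrna_region=mrna_region,
                score=energy,
                method="intarna",
            )
        )
    return out


def network_from_interactions(
    interactions: list[Interaction],
    srna_lengths: dict[str, int] | None = None,
    mrna_lengths: dict[str, int] | None = None,
) -> RegulatoryNetwork:
    """Assemble a network from imported interactions, creating nodes on
    the fly (lengths optional)."""
    net = RegulatoryNetwork(meta={"created_by": "network_from_interactions"})
    for it in interactions:
        if it.srna_id not in net.nodes:
            net.add_node(
                RnaNode(
                    id=it.srna_id, role=SRNA, gene_name=it.srna_id,
                    length=(srna_lengths or {}).get(it.srna_id),
                )
            )
        if it.mrna_id not in net.nodes:
            net.add_node(
                RnaNode(
                    id=it.mrna_id, role=MRNA, gene_name=it.mrna_id,
                    length=(mrna_lengths or {}).get(it.mrna_id),
                )
            )
        net.interactions.append(it.copy())
    from .model import validate_network

    validate_network(net)
    return net
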