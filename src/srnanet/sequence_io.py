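"""Sequence and feature input, 5'UTR extraction, nucleotide utilities.

Input pairing is genome FASTA + a GFF3 subset for gene features.  The
5'UTR of a gene is taken as a fixed window around its annotated start:
``upstream_len`` bases strictly before the first base of the gene plus
``downstream_len`` bases inside the gene starting at its first base (on
the coding strand).  Windows falling off a contig edge are clamped and
the clamping is recorded in the returned provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

# IUPAC nucleotide alphabet (RNA form), including ambiguity codes.
RNA_ALPHABET = set("ACGUNRYSWKMBDHV")

# Involutive complement map over the full IUPAC alphabet:
# A<->U, G<->C, R(AG)<->Y(CU), K(GU)<->M(AC), B<->V, D<->H, S/W/N fixed.
_COMPLEMENT = str.maketrans("ACGUNRYSWKMBDHV", "UGCANYRSWMKVHDB")


@dataclass(frozen=True)
class GeneFeature:
    """One gene row of a feature table (1-based inclusive genomic coords)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id!r}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be + or -")


@dataclass(frozen=True)
class UtrSpec:
    """Window sizes for 5'UTR extraction, in nucleotides."""

    upstream_len: int = 150
    downstream_len: int = 60

    def __post_init__(self) -> None:
        if self.upstream_len < 0 or self.downstream_len < 0:
            raise ValidationError("UTR window lengths must be non-negative")
        if self.upstream_len + self.downstream_len < 1:
            raise ValidationError("UTR window must span at least one base")


def _check_alphabet(seq: str, name: str) -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ParseError(f"sequence {name!r}: non-IUPAC characters {sorted(bad)}")


def read_fasta(path: str | Path, rna: bool = True) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(id, sequence), ...]``.

    Ids are the first whitespace-delimited header token.  Sequences are
    uppercased; in RNA mode (default) T is normalized to U.  Empty files,
    duplicate ids and non-IUPAC characters raise explicit errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: empty or non-FASTA file")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        seq = str(rec.seq).upper()
        if rna:
            seq = seq.replace("T", "U")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        _check_alphabet(seq, rec.id)
        out.append((rec.id, seq))
    return out


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC RNA string (an involution)."""
    _check_alphabet(seq.upper(), "reverse_complement input")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def read_features(
    path: str | Path, feature_type: str = "gene"
) -> list[GeneFeature]:
    """Parse a GFF3 subset into gene features.

    Only rows whose type column matches ``feature_type`` are kept.  The
    gene id comes from the ``ID=`` attribute, falling back to
    ``locus_tag=``; rows lacking both are skipped with a warning.
    """
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig, _source, ftype, start, end, _score, strand, _frame, attrs = cols
            if ftype != feature_type:
                continue
            attr_map = {}
            for part in attrs.split(";"):
                part = part.strip()
                if "=" in part:
                    k, v = part.split("=", 1)
                    attr_map[k] = v
            gene_id = attr_map.get("ID") or attr_map.get("locus_tag")
            if not gene_id:
                logger.warning("%s:%d: row has no ID or locus_tag attribute; skipped", path, lineno)
                continue
            try:
                feat = GeneFeature(gene_id, contig, int(start), int(end), strand)
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            features.append(feat)
    return features


def extract_utrs(
    genome: dict[str, str],
    features: list[GeneFeature],
    spec: UtrSpec = UtrSpec(),
) -> list[tuple[str, str, dict]]:
    """Extract a 5'UTR window for each gene.

    For a + strand gene the genomic window is
    ``[start - upstream_len, start - 1 + downstream_len]``; for a - strand
    gene it is ``[end + 1 - downstream_len, end + upstream_len]`` and the
    slice is reverse-complemented so the returned sequence reads 5'->3'
    on the mRNA.  Windows are clamped to ``[1, contig length]``; genes
    whose window lies entirely outside the contig are skipped with a
    warning record (provenance dict with ``skipped=True``).

    Returns ``[(gene_id, utr_sequence, provenance), ...]`` where
    provenance records the contig, strand, genomic window and whether
    clamping occurred.
    """
    out: list[tuple[str, str, dict]] = []
    for feat in features:
        if feat.contig not in genome:
            raise ParseError(f"gene {feat.gene_id!r}: contig {feat.contig!r} not in genome")
        contig_seq = genome[feat.contig].upper().replace("T", "U")
        clen = len(contig_seq)
        if feat.strand == "+":
            lo = feat.start - spec.upstream_len
            hi = feat.start - 1 + spec.downstream_len
        else:
            lo = feat.end + 1 - spec.downstream_len
            hi = feat.end + spec.upstream_len
        clo, chi = max(1, lo), min(clen, hi)
        prov = {
            "contig": feat.contig,
            "strand": feat.strand,
            "genomic_start": clo,
            "genomic_end": chi,
            "clamped": (clo != lo) or (chi != hi),
        }
        if chi < 1 or clo > clen or clo > chi:
            prov["skipped"] = True
            logger.warning(
                "gene %s: UTR window [%d,%d] outside contig %s; skipped",
                feat.gene_id, lo, hi, feat.contig,
            )
            out.append((feat.gene_id, "", prov))
            continue
        seq = contig_seq[clo - 1 : chi]
        if feat.strand == "-":
            seq = reverse_complement(seq)
        out.append((feat.gene_id, seq, prov))
    return out
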