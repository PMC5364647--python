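"""Deterministic synthetic networks with planted ground truth.

The generator emulates the structures a target-mining analysis looks
for, so every algorithm can be tested against a known truth:

* a planted SIM (single-input module): one sRNA regulating a chosen
  number of distinct targets;
* a planted DOR (dense overlapping regulon): a block of sRNAs all
  regulating a shared block of mRNAs;
* planted region clusters: groups of the focal sRNA's interactions
  whose regions on the sRNA are drawn inside disjoint windows
  (center ± width), emulating distinct binding seeds;
* planted annotation enrichment: one term over-represented among the
  focal sRNA's targets against the mRNA background, plus decoy terms;
* noise interactions among the remaining, non-planted nodes.

The noise model deliberately keeps the planted truth uniquely
identifiable: noise edges never touch planted nodes and each noise mRNA
receives at most one noise edge, so no spurious SIM hub or
multiply-regulated mRNA can arise from noise alone.  Scores are drawn
from a normal model truncated to negative values, mimicking duplex free
energies.  All draws come from one seeded generator, so output is a
pure function of the spec.

Defaults are sized after well-studied enterobacterial sRNAs: sRNA
length 90 nt, extracted 5'UTR windows of 210 nt.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np

from .enrichment import AnnotationCatalog
from .errors import ValidationError
from .model import (
    MRNA,
    SRNA,
    Interaction,
    Region,
    RegulatoryNetwork,
    RnaNode,
    validate_network,
)

DEFAULT_SRNA_LEN = 90
DEFAULT_MRNA_LEN = 210


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic network draw."""

    n_srna: int = 10
    n_mrna: int = 200
    srna_len: int = DEFAULT_SRNA_LEN
    mrna_len: int = DEFAULT_MRNA_LEN
    noise_edges: int = 0
    sim: tuple[int, int] | None = None  # (srna_index, n_targets)
    dor: tuple[int, int] | None = None  # (n_srnas, n_mrnas)
    region_clusters: tuple[tuple[int, int, int], ...] = ()  # (center, width, n)
    annotation: tuple[str, int, int, int] | None = None
    # (term_id, K_background, k_in_targets, n_terms_decoy)
    score_model: tuple[float, float] = (-10.0, 3.0)
    seed: int = 0


@dataclass
class SynthTruth:
    """Planted ground truth accompanying a generated network."""

    sim_srna: str | None = None
    sim_edges: set[str] = field(default_factory=set)
    dor_srnas: set[str] = field(default_factory=set)
    dor_mrnas: set[str] = field(default_factory=set)
    dor_edges: set[str] = field(default_factory=set)
    region_labels: dict[str, int] = field(default_factory=dict)  # edge key -> cluster
    enriched_term: str | None = None


def _draw_score(rng: np.random.Generator, model: tuple[float, float]) -> float:
    """Normal draw truncated to negative values (free-energy-like)."""
    mean, sd = model
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x < 0:
            return round(float(x), 2)
    return -abs(float(rng.normal(mean, sd))) or -0.01


def _random_region(rng: np.random.Generator, length: int, span: int = 12) -> Region:
    span = min(span, length)
    start = int(rng.integers(1, length - span + 2))
    return Region(start, start + span - 1)


def generate(
    spec: SynthSpec,
) -> tuple[RegulatoryNetwork, AnnotationCatalog, SynthTruth]:
    """Generate (network, catalog, truth) deterministically from the spec."""
    if spec.n_srna < 1 or spec.n_mrna < 1:
        raise ValidationError("node counts must be positive")
    for center, width, _n in spec.region_clusters:
        if center + width > spec.srna_len:
            raise ValidationError(
                f"region cluster ({center},{width}) exceeds sRNA length {spec.srna_len}"
            )
    windows = [(c - w, c + w) for c, w, _ in spec.region_clusters]
    for i in range(len(windows)):
        for j in range(i + 1, len(windows)):
            a, b = windows[i], windows[j]
            if a[0] <= b[1] and b[0] <= a[1]:
                raise ValidationError(
                    f"region cluster windows {a} and {b} overlap; planted clusters "
                    "must be separable"
                )
    rng = np.random.default_rng(spec.seed)
    net = RegulatoryNetwork(meta={"created_by": "synthgen", "seed": spec.seed})
    srna_ids = [f"s{i:03d}" for i in range(spec.n_srna)]
    mrna_ids = [f"m{i:03d}" for i in range(spec.n_mrna)]
    for sid in srna_ids:
        net.add_node(RnaNode(id=sid, role=SRNA, gene_name=sid, length=spec.srna_len))
    for mid in mrna_ids:
        net.add_node(RnaNode(id=mid, role=MRNA, gene_name=mid, length=spec.mrna_len))
    truth = SynthTruth()
    planted_srnas: set[str] = set()
    planted_mrnas: set[str] = set()
    next_mrna = 0

    def take_mrnas(count: int) -> list[str]:
        nonlocal next_mrna
        if next_mrna + count > spec.n_mrna:
            raise ValidationError(
                f"spec needs {next_mrna + count} planted mRNAs but only "
                f"{spec.n_mrna} exist"
            )
        out = mrna_ids[next_mrna : next_mrna + count]
        next_mrna += count
        return out

    def add_edge(sid: str, mid: str, srna_region: Region | None = None) -> Interaction:
        it = Interaction(
            srna_id=sid,
            mrna_id=mid,
            srna_region=srna_region or _random_region(rng, spec.srna_len),
            mrna_region=_random_region(rng, spec.mrna_len),
            score=_draw_score(rng, spec.score_model),
            method="intarna",
        )
        net.interactions.append(it)
        return it

    focal = srna_ids[spec.sim[0]] if spec.sim else srna_ids[0]

    # planted SIM
    sim_targets: list[str] = []
    if spec.sim is not None:
        srna_index, n_targets = spec.sim
        truth.sim_srna = srna_ids[srna_index]
        planted_srnas.add(truth.sim_srna)
        sim_targets = take_mrnas(n_targets)
        planted_mrnas.update(sim_targets)
        for mid in sim_targets:
            it = add_edge(truth.sim_srna, mid)
            truth.sim_edges.add(it.key)

    # planted region clusters on the focal sRNA
    if spec.region_clusters:
        planted_srnas.add(focal)
        for label, (center, width, n_inter) in enumerate(spec.region_clusters):
            for mid in take_mrnas(n_inter):
                planted_mrnas.add(mid)
                a = int(rng.integers(0, width + 1))
                b = int(rng.integers(0, width + 1))
                start = max(1, center - a)
                end = min(spec.srna_len, center + b)
                it = add_edge(focal, mid, srna_region=Region(start, end))
                truth.region_labels[it.key] = label

    # planted DOR: a block of sRNAs sharing a block of targets
    if spec.dor is not None:
        n_s, n_m = spec.dor
        if n_s > spec.n_srna - 1:
            raise ValidationError("not enough sRNAs for the planted DOR")
        dor_srnas = [s for s in reversed(srna_ids) if s not in planted_srnas][:n_s]
        if len(dor_srnas) < n_s:
            raise ValidationError("not enough free sRNAs for the planted DOR")
        dor_mrnas = take_mrnas(n_m)
        truth.dor_srnas = set(dor_srnas)
        truth.dor_mrnas = set(dor_mrnas)
        planted_srnas.update(dor_srnas)
        planted_mrnas.update(dor_mrnas)
        for sid in sorted(dor_srnas):
            for mid in dor_mrnas:
                it = add_edge(sid, mid)
                truth.dor_edges.add(it.key)

    # noise among non-planted nodes; one noise edge per mRNA keeps the
    # planted motifs the only SIM hubs / multiply-regulated targets
    free_srnas = [s for s in srna_ids if s not in planted_srnas]
    free_mrnas = [m for m in mrna_ids[next_mrna:] if m not in planted_mrnas]
    if spec.noise_edges:
        if not free_srnas:
            raise ValidationError("no free sRNAs left for noise edges")
        if spec.noise_edges > len(free_mrnas):
            raise ValidationError(
                f"{spec.noise_edges} noise edges need as many free mRNAs, "
                f"only {len(free_mrnas)} available"
            )
        chosen = rng.choice(len(free_mrnas), size=spec.noise_edges, replace=False)
        for idx in sorted(int(i) for i in chosen):
            sid = free_srnas[int(rng.integers(0, len(free_srnas)))]
            add_edge(sid, free_mrnas[idx])

    # annotation catalog with one planted enriched term plus decoys
    catalog = AnnotationCatalog()
    if spec.annotation is not None:
        term, K_bg, k_in, n_decoy = spec.annotation
        carriers = sim_targets[:k_in] if sim_targets else mrna_ids[:k_in]
        if k_in > len(carriers):
            raise ValidationError("k_in_targets exceeds the planted target count")
        carriers = list(carriers)
        # extra carriers come from outside the focal sRNA's target set so
        # the planted selection overlap is exactly k_in_targets
        focal_targets = {it.mrna_id for it in net.interactions if it.srna_id == focal}
        others = [m for m in mrna_ids if m not in set(carriers) and m not in focal_targets]
        extra = K_bg - len(carriers)
        if extra < 0 or extra > len(others):
            raise ValidationError("K_background incompatible with planted targets")
        pick = rng.choice(len(others), size=extra, replace=False)
        carriers += [others[int(i)] for i in pick]
        truth.enriched_term = term
        catalog.term_defs[term] = "iron storage and transport"
        for g in carriers:
            catalog.gene_terms.setdefault(g, set()).add(term)
            net.nodes[g].terms.add(term)
        for d in range(n_decoy):
            decoy = f"T{d:03d}"
            catalog.term_defs[decoy] = f"decoy process {d}"
            size = int(rng.integers(max(1, K_bg // 2), K_bg + 1))
            pick = rng.choice(spec.n_mrna, size=min(size, spec.n_mrna), replace=False)
            for i in pick:
                g = mrna_ids[int(i)]
                catalog.gene_terms.setdefault(g, set()).add(decoy)
                net.nodes[g].terms.add(decoy)
    validate_network(net)
    return net, catalog, truth


# -- planted antisense sequences ---------------------------------------

_BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def generate_antisense_case(
    seed: int,
    n_utrs: int = 10,
    k_with_seed: int = 4,
    srna_len: int = DEFAULT_SRNA_LEN,
    utr_len: int = DEFAULT_MRNA_LEN,
    seed_len: int = 18,
) -> tuple[tuple[str, str], list[tuple[str, str]], set[str]]:
    """One random sRNA and UTRs, k of which carry a planted perfect
    antisense seed of the sRNA; returns (srna, utrs, utr_ids_with_seed).

    The planted seed is the exact reverse complement of a ``seed_len``
    window of the sRNA, spliced into the UTR.  Detection is meant to run
    with a stringent scoring scheme (heavy mismatch and gap penalties):
    there a perfect 18-mer seed scores 36 while random 210-nt UTRs stay
    around the mid-20s, so planted and background hits are separable by
    threshold.
    """
    rng = np.random.default_rng(seed)
    srna_seq = "".join(rng.choice(_BASES, size=srna_len))
    s0 = int(rng.integers(0, srna_len - seed_len + 1))
    window = srna_seq[s0 : s0 + seed_len]
    antisense = "".join(_COMP[c] for c in reversed(window))
    utrs = []
    with_seed: set[str] = set()
    for i in range(n_utrs):
        gid = f"g{i:03d}"
        seq = "".join(rng.choice(_BASES, size=utr_len))
        if i < k_with_seed:
            pos = int(rng.integers(0, utr_len - seed_len + 1))
            seq = seq[:pos] + antisense + seq[pos + seed_len :]
            with_seed.add(gid)
        utrs.append((gid, seq))
    return ("sRNA1", srna_seq), utrs, with_seed


# -- packaged validated-target compendium -------------------------------


def validated_targets() -> dict[str, list[dict]]:
    """The packaged compendium of experimentally validated RyhB and FnrS
    targets (E. coli), as curated from public target databases.

    Returns a mapping sRNA name -> list of records with keys ``gene``,
    ``n_sources`` and optional ``shared``/``alias`` flags.  The
    per-source support flags are best-effort; analyses should rely on
    the gene lists.
    """
    ref = importlib.resources.files("srnanet.data").joinpath("validated_targets.json")
    doc = json.loads(ref.read_text())
    return {k: v for k, v in doc.items() if k in ("RyhB", "FnrS")}


def validated_target_genes(srna: str) -> list[str]:
    """Gene names of the validated targets of one sRNA ('RyhB' or 'FnrS')."""
    table = validated_targets()
    if srna not in table:
        raise KeyError(f"no validated-target list for {srna!r}")
    return [rec["gene"] for rec in table[srna]]
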