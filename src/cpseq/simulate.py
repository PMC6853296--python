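"""Ground-truthed simulator for cyclic-phosphate small-RNA libraries.

The generative model mirrors the biogenesis assumptions the downstream
analysis is built to detect: substrate fragments whose boundaries fall at
C|A dinucleotide junctions with tunable probability, fragment lengths
confined to a 20-45 nt window, a doped synthetic spike-in of known sequence,
3'-adapter-ligated reads, and a paired-condition mode in which substrate
read abundance is scaled down while spike-in and substrate-mRNA levels are
held constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cpseq._util import DNA_BASES, ConfigurationError
from cpseq.iolib import FastqRead, SeqRecordTuple, write_fasta, write_fastq
from cpseq.trna import TRNARecord, write_annotation

# 37-nt synthetic spike-in (DNA alphabet).
SPIKE_IN_SEQUENCE = "CAGTGGTGGGCCAGATGTAAACATTAGATTGTTCTTG"
SPIKE_IN_ID = "spike_in_cP"

# Shared default 3' adapter (20 nt); the trimmer uses the same default so the
# simulator and the preprocessing stage round-trip bit-exactly.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAG"

CATEGORY_ORDER = ("spike_in", "cyto_tRNA", "rRNA", "mito", "mRNA", "genome")
SUBSTRATE_CATEGORIES = ("cyto_tRNA", "rRNA", "mito", "mRNA", "genome")

DEFAULT_CATEGORY_WEIGHTS = {
    "cyto_tRNA": 0.45,
    "rRNA": 0.20,
    "mito": 0.05,
    "mRNA": 0.18,
    "genome": 0.12,
}

# tRNA fragment-class mix used by the "halves" tRNA model.
_TRNA_CLASS_WEIGHTS = {
    "FIVE_HALF": 0.60,
    "THREE_HALF": 0.30,
    "FIVE_TRF": 0.04,
    "THREE_TRF": 0.03,
    "I_TRF": 0.03,
}
# Within 3'-halves: terminal np 75 (CC) dominates, np 76 (CCA) minor.
_THREE_HALF_CC_FRACTION = 0.95
# Within His 5'-anchored reads: G-1 vs G1 starts.
_HIS_G_MINUS1_FRACTION = 0.7

_ISOACCEPTOR_POOL = [
    "ValCAC",
    "GlyGCC",
    "LysCUU",
    "GluCUC",
    "AspGUC",
    "GlyCCC",
    "LeuCAG",
    "ArgCCG",
    "SerGCU",
    "AlaAGC",
]

TRUTH_COLUMNS = [
    "read_id",
    "source_category",
    "source_reference_id",
    "start",
    "end",
    "upstream_base",
    "downstream_base",
    "intended_fragment_class",
    "is_spike_in",
]


@dataclass
class SimulatorConfig:
    """Knobs of the library generator; validated on construction."""

    seed: int = 0
    n_reads: int = 10_000
    p_ca_cleavage: float = 0.9
    fragment_len_range: tuple[int, int] = (20, 45)
    error_rate: float = 0.0
    spike_in_fraction: float = 0.02
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    reduction_factor: float = 4.0
    adapter: str = DEFAULT_ADAPTER
    # "dinucleotide": boundaries from the C|A-biased junction model;
    # "uniform": boundaries uniform over all junctions (null model).
    cleavage_model: str = "dinucleotide"
    # Optional per-category reference weights, e.g. {"cyto_tRNA": {"tRNA1": 0.4, ...}}.
    reference_weights: dict[str, dict[str, float]] | None = None
    # "halves": tRNA reads drawn from the fragment-taxonomy model anchored at
    # the planted anticodon-loop C|A site; "dinucleotide": tRNAs treated like
    # any other substrate.
    trna_mode: str = "halves"
    resample_cap: int = 1000

    def __post_init__(self):
        for name in ("p_ca_cleavage", "error_rate", "spike_in_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.fragment_len_range
        if lo < 1 or lo > hi:
            raise ConfigurationError(f"invalid fragment_len_range {self.fragment_len_range}")
        if self.n_reads < 0:
            raise ConfigurationError("n_reads must be >= 0")
        if self.reduction_factor <= 0:
            raise ConfigurationError("reduction_factor must be > 0")
        if self.cleavage_model not in ("dinucleotide", "uniform"):
            raise ConfigurationError(f"unknown cleavage_model {self.cleavage_model!r}")
        if self.trna_mode not in ("halves", "dinucleotide"):
            raise ConfigurationError(f"unknown trna_mode {self.trna_mode!r}")
        total = sum(self.category_weights.values())
        if total <= 0:
            raise ConfigurationError("category_weights must have positive mass")
        self.category_weights = {k: v / total for k, v in self.category_weights.items()}
        unknown = set(self.category_weights) - set(SUBSTRATE_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown substrate categories: {sorted(unknown)}")


@dataclass
class ReferenceBundle:
    """Per-category reference sequences plus tRNA annotations and the adapter."""

    spike_in: list[SeqRecordTuple]
    cyto_tRNA: list[SeqRecordTuple]
    rRNA: list[SeqRecordTuple]
    mito: list[SeqRecordTuple]
    mRNA: list[SeqRecordTuple]
    genome: list[SeqRecordTuple]
    trna_records: list[TRNARecord]
    adapter: str = DEFAULT_ADAPTER

    def by_category(self, category: str) -> list[SeqRecordTuple]:
        if category not in CATEGORY_ORDER:
            raise KeyError(category)
        return getattr(self, category)

    def sequences(self, category: str) -> dict[str, str]:
        return {rec.id: rec.seq for rec in self.by_category(category)}

    def all_sequences(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for cat in CATEGORY_ORDER:
            out.update(self.sequences(cat))
        return out

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cat in CATEGORY_ORDER:
            write_fasta(outdir / f"{cat}.fasta", self.by_category(cat))
        write_annotation(outdir / "trna_annotation.tsv", self.trna_records)
        (outdir / "adapter.txt").write_text(self.adapter + "\n")

    @classmethod
    def load(cls, refdir) -> "ReferenceBundle":
        from cpseq.iolib import read_fasta
        from cpseq.trna import read_annotation

        refdir = Path(refdir)
        cats = {cat: read_fasta(refdir / f"{cat}.fasta") for cat in CATEGORY_ORDER}
        seqs = {rec.id: rec.seq for rec in cats["cyto_tRNA"]}
        trna_records = read_annotation(refdir / "trna_annotation.tsv", seqs)
        adapter = (refdir / "adapter.txt").read_text().strip()
        return cls(
            spike_in=cats["spike_in"],
            cyto_tRNA=cats["cyto_tRNA"],
            rRNA=cats["rRNA"],
            mito=cats["mito"],
            mRNA=cats["mRNA"],
            genome=cats["genome"],
            trna_records=trna_records,
            adapter=adapter,
        )


# ---------------------------------------------------------------------------
# Toy reference construction


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=length))


def _has_window_compatible_ca_pair(seq: str, lo: int, hi: int) -> bool:
    sites = [j for j in range(1, len(seq)) if seq[j - 1] == "C" and seq[j] == "A"]
    return any(
        lo <= b - a <= hi for i, a in enumerate(sites) for b in sites[i + 1 :]
    )


def _make_substrate(rng, length_range, frag_range, adapter, forbid) -> str:
    """Random substrate guaranteed to support C|A fragments in the size window."""
    lo, hi = frag_range
    for _ in range(200):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_seq(rng, length)
        if adapter in seq or any(f in seq for f in forbid):
            continue
        if _has_window_compatible_ca_pair(seq, lo, hi):
            return seq
    raise RuntimeError("failed to draw a substrate with a usable C|A junction pair")


def loop_ca_site(trna: TRNARecord) -> int:
    """Cut position j of the planted anticodon-loop C|A (cut between j-1 and j)."""
    seq = trna.sequence
    for j in range(trna.loop_start + 1, trna.loop_end + 1):
        if seq[j - 1] == "C" and seq[j] == "A":
            return j
    raise ValueError(f"{trna.ref_id}: no C|A junction inside the anticodon loop")


def _make_trna(rng, ref_id, isoacceptor, has_minus1, minus1_base) -> TRNARecord:
    """76-nt canonical body + CCA; loop np 32-38 carries one planted C|A site."""
    body = list(_random_seq(rng, 73))
    # np numbering: body index i (0-based) holds np i+1.
    anticodon = isoacceptor[-3:].replace("U", "T")
    body[31] = "C"  # np 32
    body[32] = "A"  # np 33 -> planted C|A cut between np 32 and np 33
    body[33:36] = list(anticodon)  # np 34-36
    body[72] = "T" if body[72] == "A" else body[72]  # keep discriminator != A after CC
    seq = "".join(body) + "CCA"
    # avoid a second C|A inside the loop so the planted site is unambiguous
    for j in range(33, 38):
        if seq[j] == "C" and seq[j + 1] == "A":
            seq = seq[: j + 1] + "G" + seq[j + 2 :]
    if has_minus1:
        seq = minus1_base + seq
    offset = 1 if has_minus1 else 0
    rec = TRNARecord(
        ref_id=ref_id,
        isoacceptor=isoacceptor,
        sequence=seq,
        loop_start=31 + offset,
        loop_end=37 + offset,
        has_minus1=has_minus1,
        minus1_base=minus1_base,
    )
    rec.validate()
    return rec


def build_toy_references(
    seed: int,
    n_trna: int = 6,
    n_mrna: int = 6,
    n_rrna: int = 3,
    n_mito: int = 1,
    adapter: str = DEFAULT_ADAPTER,
    fragment_len_range: tuple[int, int] = (20, 45),
) -> ReferenceBundle:
    """Generate a deterministic toy reference bundle for every mapping category.

    tRNAs are 76-nt canonical bodies with appended CCA and an anticodon loop
    at np 32-38 containing exactly one C|A junction; the last tRNA is a
    His-like record with a -1 G. Other substrates are 300-2000 nt random
    sequences guaranteed to contain C|A junction pairs spaced within the
    fragment window.
    """
    if min(n_trna, n_mrna, n_rrna, n_mito) < 1:
        raise ConfigurationError("all reference counts must be >= 1")
    rng = np.random.default_rng(seed)

    trna_records = []
    for i in range(n_trna):
        iso = _ISOACCEPTOR_POOL[i % len(_ISOACCEPTOR_POOL)]
        if i >= len(_ISOACCEPTOR_POOL):
            iso = f"{iso}{i // len(_ISOACCEPTOR_POOL) + 1}"
        is_his = i == n_trna - 1
        if is_his:
            iso = "HisGUG"
        trna_records.append(
            _make_trna(
                rng,
                ref_id=f"tRNA_{iso}",
                isoacceptor=iso,
                has_minus1=is_his,
                minus1_base="G" if is_his else None,
            )
        )
    trna_fa = [SeqRecordTuple(r.ref_id, r.sequence) for r in trna_records]

    forbid = [SPIKE_IN_SEQUENCE]
    mrna = [
        SeqRecordTuple(
            f"mRNA_{i + 1:02d}", _make_substrate(rng, (300, 2000), fragment_len_range, adapter, forbid)
        )
        for i in range(n_mrna)
    ]
    rrna_names = ["rRNA_28S", "rRNA_18S", "rRNA_5.8S", "rRNA_5S"]
    rrna = [
        SeqRecordTuple(
            rrna_names[i] if i < len(rrna_names) else f"rRNA_{i + 1}",
            _make_substrate(rng, (300, 2000), fragment_len_range, adapter, forbid),
        )
        for i in range(n_rrna)
    ]
    mito = [
        SeqRecordTuple(
            f"mito_{i + 1}", _make_substrate(rng, (1000, 2000), fragment_len_range, adapter, forbid)
        )
        for i in range(n_mito)
    ]
    genome = [
        SeqRecordTuple("chr_toy", _make_substrate(rng, (3000, 5000), fragment_len_range, adapter, forbid))
    ]
    return ReferenceBundle(
        spike_in=[SeqRecordTuple(SPIKE_IN_ID, SPIKE_IN_SEQUENCE)],
        cyto_tRNA=trna_fa,
        rRNA=rrna,
        mito=mito,
        mRNA=mrna,
        genome=genome,
        trna_records=trna_records,
        adapter=adapter,
    )


# ---------------------------------------------------------------------------
# Library simulation


class _JunctionModel:
    """Precomputed C|A and other inter-nucleotide junctions per reference."""

    def __init__(self, seq: str):
        n = len(seq)
        is_ca = np.zeros(n, dtype=bool)
        for j in range(1, n):
            if seq[j - 1] == "C" and seq[j] == "A":
                is_ca[j] = True
        all_j = np.arange(1, n)
        self.ca = all_j[is_ca[1:]]
        self.other = all_j[~is_ca[1:]]
        self.all = all_j

    def draw(self, rng, p_ca: float, uniform: bool) -> int:
        if uniform:
            return int(rng.choice(self.all))
        if self.ca.size and rng.random() < p_ca:
            return int(rng.choice(self.ca))
        pool = self.other if self.other.size else self.ca
        return int(rng.choice(pool))


def _draw_fragment(rng, model: _JunctionModel, cfg: SimulatorConfig) -> tuple[int, int] | None:
    lo, hi = cfg.fragment_len_range
    uniform = cfg.cleavage_model == "uniform"
    for _ in range(cfg.resample_cap):
        b1 = model.draw(rng, cfg.p_ca_cleavage, uniform)
        b2 = model.draw(rng, cfg.p_ca_cleavage, uniform)
        if b1 == b2:
            continue
        start, end = (b1, b2) if b1 < b2 else (b2, b1)
        if lo <= end - start <= hi:
            return start, end
    return None


def _draw_trna_fragment(rng, trna: TRNARecord, cfg: SimulatorConfig) -> tuple[int, int, str]:
    """(start, end, intended class) under the taxonomy-anchored tRNA model."""
    cut = loop_ca_site(trna)
    seq_len = len(trna.sequence)
    np1 = trna.np1_index
    classes = list(_TRNA_CLASS_WEIGHTS)
    weights = np.array([_TRNA_CLASS_WEIGHTS[c] for c in classes])
    cls = classes[rng.choice(len(classes), p=weights / weights.sum())]
    if cls == "FIVE_HALF":
        start = np1
        if trna.has_minus1 and rng.random() < _HIS_G_MINUS1_FRACTION:
            start = 0
        return start, cut, cls
    if cls == "THREE_HALF":
        # terminal np 75 (cut between C75 and A76) dominates; np 76 otherwise
        end = seq_len - 1 if rng.random() < _THREE_HALF_CC_FRACTION else seq_len
        return cut, end, cls
    if cls == "FIVE_TRF":
        end = int(rng.integers(np1 + cfg.fragment_len_range[0], trna.loop_start))
        return np1, end, cls
    if cls == "THREE_TRF":
        start = int(rng.integers(trna.loop_end + 1, seq_len - cfg.fragment_len_range[0] + 1))
        return start, seq_len, cls
    # I_TRF: internal, ends well before the discriminator
    start = int(rng.integers(np1 + 2, np1 + 10))
    length = int(rng.integers(cfg.fragment_len_range[0], 31))
    return start, start + length, "I_TRF"


def _inject_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        choices = [b for b in DNA_BASES if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_library(
    refs: ReferenceBundle, cfg: SimulatorConfig
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Emit an adapter-ligated FASTQ library and its per-read truth table."""
    rng = np.random.default_rng(cfg.seed)
    lo, _hi = cfg.fragment_len_range

    cat_names = [c for c in SUBSTRATE_CATEGORIES if cfg.category_weights.get(c, 0) > 0]
    cat_p = np.array([cfg.category_weights[c] for c in cat_names])
    cat_p = cat_p / cat_p.sum()

    # per-category reference ids, sampling weights and junction models
    cat_refs: dict[str, list[SeqRecordTuple]] = {}
    cat_ref_p: dict[str, np.ndarray] = {}
    models: dict[str, _JunctionModel] = {}
    trna_by_ref = {r.ref_id: r for r in refs.trna_records}
    for cat in cat_names:
        usable = [rec for rec in refs.by_category(cat) if len(rec.seq) >= lo + 1]
        skipped = [rec.id for rec in refs.by_category(cat) if len(rec.seq) < lo + 1]
        for rid in skipped:
            warnings.warn(f"substrate {rid} shorter than min fragment; skipped")
        if not usable:
            raise ConfigurationError(f"category {cat} has no usable substrate")
        cat_refs[cat] = usable
        w = np.ones(len(usable))
        if cfg.reference_weights and cat in cfg.reference_weights:
            given = cfg.reference_weights[cat]
            w = np.array([given.get(rec.id, 0.0) for rec in usable])
            if w.sum() <= 0:
                raise ConfigurationError(f"reference_weights for {cat} have no mass")
        cat_ref_p[cat] = w / w.sum()
        for rec in usable:
            models.setdefault(rec.id, _JunctionModel(rec.seq))

    reads: list[FastqRead] = []
    truth_rows: list[dict] = []
    spike_seq = refs.spike_in[0].seq

    for i in range(cfg.n_reads):
        read_id = f"read{i:07d}"
        if rng.random() < cfg.spike_in_fraction:
            insert = spike_seq
            row = dict(
                read_id=read_id,
                source_category="spike_in",
                source_reference_id=refs.spike_in[0].id,
                start=0,
                end=len(spike_seq),
                upstream_base=".",
                downstream_base=".",
                intended_fragment_class=".",
                is_spike_in=1,
            )
        else:
            cat = cat_names[rng.choice(len(cat_names), p=cat_p)]
            intended = "."
            for _attempt in range(20):
                rec = cat_refs[cat][rng.choice(len(cat_refs[cat]), p=cat_ref_p[cat])]
                if cat == "cyto_tRNA" and cfg.trna_mode == "halves":
                    start, end, intended = _draw_trna_fragment(
                        rng, trna_by_ref[rec.id], cfg
                    )
                    break
                frag = _draw_fragment(rng, models[rec.id], cfg)
                if frag is not None:
                    start, end = frag
                    break
            else:
                warnings.warn(f"could not place a fragment in category {cat}; read skipped")
                continue
            seq = rec.seq
            insert = seq[start:end]
            row = dict(
                read_id=read_id,
                source_category=cat,
                source_reference_id=rec.id,
                start=start,
                end=end,
                upstream_base=seq[start - 1] if start > 0 else ".",
                downstream_base=seq[end] if end < len(seq) else ".",
                intended_fragment_class=intended,
                is_spike_in=0,
            )
        read_seq = _inject_errors(rng, insert + cfg.adapter, cfg.error_rate)
        reads.append(FastqRead(read_id, read_seq, "I" * len(read_seq)))
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth.attrs["seed"] = cfg.seed
    return reads, truth


def write_truth_table(path, truth: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        seed = truth.attrs.get("seed")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        truth.to_csv(fh, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"upstream_base": str, "downstream_base": str}
    )
    return df


def simulate_aging_pair(
    refs: ReferenceBundle, cfg: SimulatorConfig
) -> tuple[
    tuple[list[FastqRead], pd.DataFrame],
    tuple[list[FastqRead], pd.DataFrame],
    pd.DataFrame,
]:
    """Two-condition libraries plus a condition-invariant substrate mRNA table.

    Condition 2 keeps the spike-in read expectation of condition 1 but scales
    every substrate category down by 1/reduction_factor. The returned mRNA
    table mimics an externally produced mRNA-seq RPKM table whose per-mRNA
    values are statistically unchanged between conditions.
    """
    r = cfg.reduction_factor
    if r <= 0:
        raise ConfigurationError("reduction_factor must be > 0")
    f = cfg.spike_in_fraction
    lib1 = simulate_library(refs, replace(cfg, seed=cfg.seed))

    shrink = f + (1 - f) / r
    n2 = int(round(cfg.n_reads * shrink))
    f2 = f / shrink if shrink > 0 else 0.0
    cfg2 = replace(cfg, seed=cfg.seed + 1, n_reads=n2, spike_in_fraction=f2)
    lib2 = simulate_library(refs, cfg2)

    rng = np.random.default_rng(cfg.seed + 2)
    rows = []
    for rec in refs.mRNA:
        base = float(rng.uniform(50.0, 500.0))
        rows.append(
            {
                "substrate_id": rec.id,
                "length_nt": len(rec.seq),
                "rpkm_cond1": base * float(1 + rng.normal(0, 0.02)),
                "rpkm_cond2": base * float(1 + rng.normal(0, 0.02)),
            }
        )
    mrna_table = pd.DataFrame(rows)
    return lib1, lib2, mrna_table


__all__ = [
    "SPIKE_IN_SEQUENCE",
    "SPIKE_IN_ID",
    "DEFAULT_ADAPTER",
    "CATEGORY_ORDER",
    "SUBSTRATE_CATEGORIES",
    "SimulatorConfig",
    "ReferenceBundle",
    "build_toy_references",
    "loop_ca_site",
    "simulate_library",
    "simulate_aging_pair",
    "write_truth_table",
    "read_truth_table",
    "write_fastq",
    "write_fasta",
]
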