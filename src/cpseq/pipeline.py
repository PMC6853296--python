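"""End-to-end pipeline: trim -> select -> map -> classify -> signature -> quantify.

Every run writes its TSV/SAM/BED/bedGraph products plus a JSON manifest
(config snapshot, input checksums, per-stage read counts, version) from
which a rerun reproduces all outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

import cpseq
from cpseq._util import ConfigurationError, sha256_file
from cpseq.iolib import read_fastq, write_bed6, write_bedgraph, write_fastq, write_sam
from cpseq.mapping import (
    MappingConfig,
    PRIORITY_ORDER,
    category_counts,
    category_proportions,
    map_sequential,
    write_alignments,
)
from cpseq.preprocess import PipelineConfig, preprocess_reads
from cpseq.quantify import count_spike_in, normalized_rpkm, substrate_counts
from cpseq.signature import (
    alignment_profile,
    ca_boundary_fraction,
    end_composition,
    flanking_context,
    fragment_sequence,
    infer_cleavage_sites,
    length_distribution,
    write_cleavage_profile,
    write_composition,
)
from cpseq.simulate import ReferenceBundle
from cpseq.trna import classify_fragment, write_fragment_calls

log = logging.getLogger("cpseq")


@dataclass
class RunConfig:
    input_fastq: str
    reference_dir: str
    output_dir: str
    min_len: int = 20
    max_len: int = 45
    max_mismatch: int = 1
    min_adapter_overlap: int = 5
    keep_untrimmed: bool = False
    sample_id: str = "sample"
    n_profile_refs: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest dictionary."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    refs = ReferenceBundle.load(cfg.reference_dir)
    for cat in PRIORITY_ORDER:
        if not refs.by_category(cat):
            raise ConfigurationError(f"reference category {cat} is empty")

    reads = read_fastq(cfg.input_fastq)
    log.info("input reads: %d", len(reads))

    pre_cfg = PipelineConfig(
        adapter_seq=refs.adapter,
        min_len=cfg.min_len,
        max_len=cfg.max_len,
        min_adapter_overlap=cfg.min_adapter_overlap,
        keep_untrimmed=cfg.keep_untrimmed,
    )
    selected, summary = preprocess_reads(reads, pre_cfg)
    write_fastq(outdir / "trimmed.fastq", selected)
    summary.to_frame().to_csv(outdir / "trim_summary.tsv", sep="\t", index=False)
    log.info("adapter-found: %d, length-selected: %d", summary.n_adapter_found, len(selected))

    category_refs = {cat: refs.by_category(cat) for cat in PRIORITY_ORDER}
    assignments = map_sequential(
        selected, category_refs, MappingConfig(max_mismatch=cfg.max_mismatch)
    )
    write_alignments(outdir / "alignments.tsv", assignments)
    reads_by_id = {r.id: r.seq for r in selected}
    ref_lengths = {rid: len(s) for rid, s in refs.all_sequences().items()}
    write_sam(outdir / "alignments.sam", assignments, reads_by_id, ref_lengths)
    write_bed6(outdir / "alignments.bed", assignments)
    counts = category_counts(assignments)
    counts.rename_axis("category").rename("n_reads").to_csv(
        outdir / "category_counts.tsv", sep="\t"
    )
    props = category_proportions(assignments)
    props.rename_axis("category").rename("fraction").to_csv(
        outdir / "category_proportions.tsv", sep="\t"
    )

    # tRNA taxonomy
    trna_by_ref = {t.ref_id: t for t in refs.trna_records}
    trna_alns = [a for a in assignments if a.category == "cyto_tRNA"]
    calls = [classify_fragment(a, trna_by_ref[a.ref_id]) for a in trna_alns]
    write_fragment_calls(outdir / "fragment_calls.tsv", calls)
    if calls:
        cls_counts = pd.Series([c.fragment_class.value for c in calls]).value_counts()
        (cls_counts / cls_counts.sum()).rename_axis("fragment_class").rename("fraction").to_csv(
            outdir / "fragment_class_proportions.tsv", sep="\t"
        )

    # signature analyses over uniquely assigned, mapped, non-spike fragments
    refseqs = refs.all_sequences()
    frags = [a for a in assignments if a.category not in ("unmapped", "spike_in")]
    frag_seqs = [fragment_sequence(a, refseqs) for a in frags]
    write_composition(outdir / "end_composition_5p.tsv", end_composition(frag_seqs, 5))
    write_composition(outdir / "end_composition_3p.tsv", end_composition(frag_seqs, 3))
    write_composition(outdir / "flanking_composition.tsv", flanking_context(frags, refseqs))
    ca5, ca3, caboth = ca_boundary_fraction(frags, refseqs)
    pd.DataFrame(
        [{"ca_5prime": ca5, "ca_3prime": ca3, "ca_both": caboth}]
    ).to_csv(outdir / "ca_boundary_fraction.tsv", sep="\t", index=False)
    profiles = [infer_cleavage_sites(calls, t) for t in refs.trna_records]
    write_cleavage_profile(outdir / "cleavage_profiles.tsv", profiles)
    length_distribution(
        [len(s) for s in frag_seqs], cfg.min_len, cfg.max_len
    ).rename_axis("length_nt").rename("n_reads").to_csv(
        outdir / "length_distribution.tsv", sep="\t"
    )

    # alignment profiles for the most read-rich non-tRNA substrates
    by_ref = pd.Series(
        [a.ref_id for a in frags if a.category in ("mRNA", "rRNA")], dtype=object
    ).value_counts()
    for rid in sorted(by_ref.head(cfg.n_profile_refs).index):
        prof = alignment_profile(frags, rid, len(refseqs[rid]))
        write_bedgraph(outdir / f"profile_{rid}.bedgraph", rid, prof.coverage)
        with open(outdir / f"profile_{rid}_top.bed", "w") as fh:
            for (s, e), n in prof.top_intervals:
                fh.write(f"{rid}\t{s}\t{e}\tinterval\t{n}\t+\n")

    # quantification
    spike = count_spike_in(assignments)
    if spike > 0:
        mrna_counts = substrate_counts(assignments, "mRNA")
        norm = normalized_rpkm(
            mrna_counts,
            {rid: len(s) for rid, s in refs.sequences("mRNA").items()},
            spike,
            sample_id=cfg.sample_id,
        )
        norm.to_csv(outdir / "normalized_rpkm.tsv", sep="\t", index=False)

    manifest = {
        "tool": "cpseq",
        "version": cpseq.__version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {
            "fastq_sha256": sha256_file(cfg.input_fastq),
            "reference_dir": str(cfg.reference_dir),
        },
        "stage_counts": {
            "input": summary.n_input,
            "adapter_found": summary.n_adapter_found,
            "length_selected": summary.n_length_selected,
            "spike_in": int(spike),
            **{cat: int(counts.get(cat, 0)) for cat in PRIORITY_ORDER},
            "unmapped": int(counts.get("unmapped", 0)),
        },
    }
    tmp = outdir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, outdir / "manifest.json")
    return manifest
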