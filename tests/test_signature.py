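import numpy as np
import pytest

from cpseq._util import revcomp
from cpseq.mapping import CategoryAlignment, MappingConfig, map_sequential
from cpseq.preprocess import PipelineConfig, preprocess_reads
from cpseq.signature import (
    alignment_profile,
    ca_boundary_fraction,
    end_composition,
    flanking_context,
    fragment_sequence,
    infer_cleavage_sites,
    length_distribution,
)
from cpseq.simulate import SimulatorConfig, loop_ca_site, simulate_library
from cpseq.trna import classify_fragment


def frag(ref_id, start, end, strand="+", read_id="r"):
    return CategoryAlignment(read_id, "mRNA", ref_id, start, end, strand, 0)


def run_sim(toy_refs, category_refs, **cfg_kwargs):
    cfg = SimulatorConfig(error_rate=0.0, trna_mode="dinucleotide", **cfg_kwargs)
    reads, truth = simulate_library(toy_refs, cfg)
    selected, _ = preprocess_reads(reads, PipelineConfig(adapter_seq=toy_refs.adapter))
    assignments = map_sequential(selected, category_refs, MappingConfig())
    return [a for a in assignments if a.category not in ("unmapped", "spike_in")]


class TestEndComposition:
    def test_five_prime_position_one(self):
        m = end_composition(["ACG", "AAT"], 5)
        assert m.fraction(1, "A") == 1.0

    def test_three_prime_position_one_reports_u(self):
        m = end_composition(["ACG", "AAT"], 3)
        assert m.fraction(1, "G") == 0.5
        assert m.fraction(1, "U") == 0.5  # T reported in RNA alphabet

    def test_short_reads_contribute_partial_positions(self):
        m = end_composition(["ACG", "ACGTACGTACGT"], 5, n_positions=10)
        assert m.counts.loc[3].sum() == 2
        assert m.counts.loc[4].sum() == 1

    def test_columns_are_probability_vectors(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 46)))) for _ in range(50)]
        m = end_composition(seqs, 3)
        sums = m.fractions.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_empty_input(self):
        m = end_composition([], 5)
        assert m.n_reads == 0
        assert (m.fractions.to_numpy() == 0).all()

    def test_invalid_end(self):
        with pytest.raises(ValueError):
            end_composition(["ACGT"], 4)


class TestFlankingContext:
    REF = {"m1": "GGCAGTCCAG"}

    def test_direct_indexing_example(self):
        m = flanking_context([frag("m1", 3, 8)], self.REF)
        assert m.fraction(-1, "C") == 1.0  # reference index 2
        assert m.fraction(1, "A") == 1.0  # reference index 8

    def test_edge_fragment_contributes_nothing_upstream(self):
        m = flanking_context([frag("m1", 0, 8)], self.REF)
        assert m.counts.loc[-1].sum() == 0
        assert m.counts.loc[1].sum() == 1

    def test_minus_strand_revcomp(self):
        # read orientation: -1 flank is the complement of the base after end
        m = flanking_context([frag("m1", 3, 8, strand="-")], self.REF)
        assert m.fraction(-1, revcomp(self.REF["m1"][8]).replace("T", "U")) == 1.0
        assert m.fraction(1, revcomp(self.REF["m1"][2]).replace("T", "U")) == 1.0

    def test_matches_bruteforce_reextraction(self, toy_refs, category_refs):
        frags = run_sim(toy_refs, category_refs, seed=51, n_reads=800, p_ca_cleavage=0.3)
        seqs = toy_refs.all_sequences()
        m = flanking_context(frags, seqs, k=4)
        counts = {lab: dict.fromkeys("ACGU", 0) for lab in list(range(-4, 0)) + list(range(1, 5))}
        for a in frags:
            ref = seqs[a.ref_id]
            for off in range(1, 5):
                if a.start - off >= 0:
                    b = ref[a.start - off].replace("T", "U")
                    counts[-off][b] += 1
                if a.end + off - 1 < len(ref):
                    b = ref[a.end + off - 1].replace("T", "U")
                    counts[off][b] += 1
        for lab, row in counts.items():
            total = sum(row.values())
            for b, c in row.items():
                expected = c / total if total else 0.0
                assert m.fraction(lab, b) == pytest.approx(expected)


class TestCABoundaryFraction:
    def test_pure_ca_simulator(self, toy_refs, category_refs):
        frags = run_sim(toy_refs, category_refs, seed=52, n_reads=1500, p_ca_cleavage=1.0)
        assert ca_boundary_fraction(frags, toy_refs.all_sequences()) == (1.0, 1.0, 1.0)

    def test_empty_input_not_available(self):
        assert ca_boundary_fraction([], {}) == (None, None, None)

    def test_monotone_in_p(self, toy_refs, category_refs):
        seqs = toy_refs.all_sequences()
        values = []
        for p in (0.0, 0.5, 1.0):
            frags = run_sim(
                toy_refs, category_refs, seed=53, n_reads=2500, p_ca_cleavage=p
            )
            values.append(ca_boundary_fraction(frags, seqs)[2])
        assert values[0] < values[1] < values[2]
        assert values[0] == 0.0 and values[2] == 1.0

    def test_uniform_model_matches_junction_frequency(self, toy_refs, category_refs):
        cfg = SimulatorConfig(
            seed=54,
            n_reads=4000,
            cleavage_model="uniform",
            error_rate=0.0,
            trna_mode="dinucleotide",
            spike_in_fraction=0.0,
        )
        reads, truth = simulate_library(toy_refs, cfg)
        selected, _ = preprocess_reads(
            reads, PipelineConfig(adapter_seq=toy_refs.adapter)
        )
        frags = [
            a
            for a in map_sequential(selected, category_refs, MappingConfig())
            if a.category not in ("unmapped", "spike_in")
        ]
        seqs = toy_refs.all_sequences()
        ca5, ca3, _ = ca_boundary_fraction(frags, seqs)
        # analytic expectation: frequency of C|A among all junctions,
        # approximately P(C)*P(A) of the toy base composition (~1/16)
        pooled = "".join(seqs.values())
        expected = sum(
            1 for i in range(1, len(pooled)) if pooled[i - 1] == "C" and pooled[i] == "A"
        ) / (len(pooled) - 1)
        assert ca5 == pytest.approx(expected, abs=0.05)
        assert ca3 == pytest.approx(expected, abs=0.05)


class TestInferCleavageSites:
    def test_concordant_boundary(self, toy_refs):
        t = toy_refs.trna_records[0]
        a5 = CategoryAlignment("r1", "cyto_tRNA", t.ref_id, 0, 34, "+", 0)
        a3 = CategoryAlignment("r2", "cyto_tRNA", t.ref_id, 34, 75, "+", 0)
        calls = [classify_fragment(a5, t), classify_fragment(a3, t)]
        prof = infer_cleavage_sites(calls, t)
        assert prof.from_five_ends[34] == 1  # 5'-half ends at index 33
        assert prof.from_three_starts[34] == 1
        assert prof.concordant_boundaries() == [34]
        assert prof.modal_boundary() == 34

    def test_only_five_halves_no_concordance(self, toy_refs):
        t = toy_refs.trna_records[0]
        a5 = CategoryAlignment("r1", "cyto_tRNA", t.ref_id, 0, 34, "+", 0)
        prof = infer_cleavage_sites([classify_fragment(a5, t)], t)
        assert prof.concordant_boundaries() == []

    def test_modal_boundary_recovers_planted_site(self, toy_refs, category_refs):
        cfg = SimulatorConfig(seed=55, n_reads=6000, error_rate=0.0)
        reads, _ = simulate_library(toy_refs, cfg)
        selected, _ = preprocess_reads(
            reads, PipelineConfig(adapter_seq=toy_refs.adapter)
        )
        assignments = map_sequential(selected, category_refs, MappingConfig())
        by_ref = {t.ref_id: t for t in toy_refs.trna_records}
        calls = [
            classify_fragment(a, by_ref[a.ref_id])
            for a in assignments
            if a.category == "cyto_tRNA"
        ]
        for t in toy_refs.trna_records:
            prof = infer_cleavage_sites(calls, t)
            expected = loop_ca_site(t)
            assert prof.modal_boundary() == expected
            assert expected in prof.concordant_boundaries()


class TestAlignmentProfile:
    def test_two_identical_fragments(self):
        frags = [frag("m1", 5, 25, read_id="a"), frag("m1", 5, 25, read_id="b")]
        prof = alignment_profile(frags, "m1", 40)
        assert (prof.coverage[5:25] == 2).all()
        assert prof.coverage[:5].sum() == 0 and prof.coverage[25:].sum() == 0
        assert prof.top_intervals == [((5, 25), 2)]

    def test_empty(self):
        prof = alignment_profile([], "m1", 40)
        assert prof.coverage.sum() == 0
        assert prof.top_intervals == []

    def test_coverage_conservation(self, toy_refs, category_refs):
        frags = run_sim(toy_refs, category_refs, seed=56, n_reads=1200, p_ca_cleavage=0.5)
        seqs = toy_refs.all_sequences()
        rid = toy_refs.mRNA[0].id
        mine = [a for a in frags if a.ref_id == rid]
        prof = alignment_profile(mine, rid, len(seqs[rid]))
        assert prof.coverage.sum() == sum(a.end - a.start for a in mine)
        assert prof.starts.sum() == len(mine) == prof.ends.sum()

    def test_dominant_site_recovered(self, toy_refs, category_refs):
        rid = toy_refs.mRNA[0].id
        weights = {rec.id: (0.9 if rec.id == rid else 0.1 / (len(toy_refs.mRNA) - 1)) for rec in toy_refs.mRNA}
        cfg = SimulatorConfig(
            seed=57,
            n_reads=2000,
            p_ca_cleavage=1.0,
            error_rate=0.0,
            spike_in_fraction=0.0,
            category_weights={"mRNA": 1.0},
            reference_weights={"mRNA": weights},
        )
        reads, truth = simulate_library(toy_refs, cfg)
        selected, _ = preprocess_reads(
            reads, PipelineConfig(adapter_seq=toy_refs.adapter)
        )
        frags = [
            a
            for a in map_sequential(selected, category_refs, MappingConfig())
            if a.category == "mRNA"
        ]
        counts = truth[truth.source_reference_id == rid].groupby(["start", "end"]).size()
        true_top = counts.idxmax()
        prof = alignment_profile(frags, rid, len(toy_refs.all_sequences()[rid]))
        assert prof.top_intervals[0][0] == true_top


class TestLengthDistribution:
    def test_simple(self):
        hist = length_distribution([20, 20, 45])
        assert hist[20] == 2 and hist[45] == 1
        assert hist.sum() == 3

    def test_empty(self):
        assert length_distribution([]).sum() == 0

    def test_simulated_lengths_fill_window(self, toy_refs, category_refs):
        frags = run_sim(toy_refs, category_refs, seed=58, n_reads=3000, p_ca_cleavage=0.0)
        hist = length_distribution([a.end - a.start for a in frags])
        assert hist.sum() == len(frags)
        assert (hist.index >= 20).all() and (hist.index <= 45).all()
        assert (hist > 0).mean() > 0.9  # broad coverage of the window

    def test_end_composition_of_simulated_internal_fragments(
        self, toy_refs, category_refs
    ):
        frags = run_sim(toy_refs, category_refs, seed=59, n_reads=1500, p_ca_cleavage=1.0)
        seqs = toy_refs.all_sequences()
        fseqs = [fragment_sequence(a, seqs) for a in frags]
        assert end_composition(fseqs, 5).fraction(1, "A") == 1.0
        assert end_composition(fseqs, 3).fraction(1, "C") == 1.0
        m = flanking_context(frags, seqs)
        assert m.fraction(-1, "C") == 1.0
        assert m.fraction(1, "A") == 1.0
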