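"""Genotype-to-phenotype map: planted-gene ground truth, phenotype algebra,
fitness, coding annotation, purity/symmetry invariants."""

import numpy as np
import pytest

from bitevol.chemistry import (
    PROMOTER_CONSENSUS,
    PROMOTER_MAX_MISMATCH,
    W_MAX,
    build_target,
    FitnessParams,
)
from bitevol.decoder import (
    GridMismatchError,
    annotate_coding,
    compute_phenotype,
    decode,
    decode_structure,
    find_promoters,
    find_terminator,
    fitness,
    metabolic_error,
    transcribe,
    translate,
)
from bitevol.genome import Genome
from bitevol.synthetic import (
    PlantedGene,
    PlantedGenomeSpec,
    cassette_self_consistent,
    gray_decode_mwh,
    make_planted_genome,
    motif_free_filler,
)

RNG = np.random.default_rng(20240917)


def planted(length=400, codons="011101110011", strand=0, mismatches=0, seed=0):
    gene = PlantedGene(codons=codons, strand=strand, mismatches=mismatches)
    assert cassette_self_consistent(gene)
    return make_planted_genome(
        PlantedGenomeSpec(length=length, genes=(gene,)), np.random.default_rng(seed)
    )


def clean_gene(n_codons, rng, **kw):
    """Random self-consistent gene that decodes to a functional protein."""
    from bitevol.synthetic import random_functional_gene

    return random_functional_gene(n_codons, rng, **kw)


class TestPromoters:
    def test_planted_promoters_found_with_full_expression(self):
        genes = tuple(clean_gene(4, RNG) for _ in range(3))
        g, truth = make_planted_genome(
            PlantedGenomeSpec(length=700, genes=genes), np.random.default_rng(1)
        )
        proms = find_promoters(g)
        assert len(proms) == 3
        assert all(p.expression == 1.0 and p.mismatches == 0 for p in proms)
        assert [(p.strand, p.position) for p in proms] == [
            (s, pos) for s, pos, _, _ in truth.promoters
        ]

    def test_filler_has_no_promoters(self):
        g = Genome(bits=motif_free_filler(500, RNG, circular=True))
        assert find_promoters(g) == ()

    def test_d_max_boundary_not_detected(self):
        g, truth = planted(mismatches=PROMOTER_MAX_MISMATCH + 1, seed=3)
        assert truth.promoters == ()
        assert find_promoters(g) == ()

    def test_d_max_detected_with_reduced_expression(self):
        g, _ = planted(mismatches=PROMOTER_MAX_MISMATCH, seed=4)
        (p,) = find_promoters(g)
        assert p.mismatches == PROMOTER_MAX_MISMATCH
        assert p.expression == pytest.approx(
            1 - PROMOTER_MAX_MISMATCH / (PROMOTER_MAX_MISMATCH + 1)
        )


class TestTerminators:
    def test_planted_hairpin_found(self):
        g, truth = planted(seed=5)
        strand, start, tlen, term = truth.rnas[0]
        assert find_terminator(g, start, strand) == term

    def test_all_zero_genome_has_none(self):
        assert find_terminator(Genome.from_string("0" * 64), 0, 0) is None

    def test_scan_wraps_origin(self):
        g, truth = planted(seed=6)
        strand, start, tlen, term = truth.rnas[0]
        rot = g.rotated(len(g) - start + 5)  # move transcript across origin
        # terminator position after rotation, in strand-local coordinates
        shift = len(g) - start + 5 if strand == 0 else -(len(g) - start + 5)
        expect = (term + shift) % len(g)
        assert find_terminator(rot, (start + shift) % len(g), strand) == expect


class TestTranscription:
    def test_single_gene_single_rna(self):
        g, truth = planted(seed=7)
        rnas = transcribe(g)
        assert len(rnas) == 1
        assert (rnas[0].strand, rnas[0].start, rnas[0].length, rnas[0].terminator) == truth.rnas[0]

    def test_no_promoter_no_rna(self):
        g = Genome(bits=motif_free_filler(300, RNG, circular=True))
        assert transcribe(g) == ()

    def test_two_promoters_share_one_terminator(self):
        # tandem promoters: copy B carries 3 mismatches (positions 4, 5, 11)
        # that break the hairpin patterns the consensus itself contains, so
        # both transcripts run to the single planted terminator.
        second = list(PROMOTER_CONSENSUS)
        for f in (4, 5, 11):
            second[f] = "1" if second[f] == "0" else "0"
        pad = "000000"
        hairpin = "0110" + "000" + "1001"
        bits = PROMOTER_CONSENSUS + "".join(second) + pad + hairpin + "0" * 40
        g = Genome.from_string(bits)
        rnas = [r for r in transcribe(g) if r.strand == 0]
        assert sorted(r.start for r in rnas) == [22, 44]
        assert {r.terminator for r in rnas} == {50}


class TestTranslation:
    def test_planted_codons_decode_to_oracle_values(self):
        rng = np.random.default_rng(11)
        for strand in (0, 1):
            gene = clean_gene(8, rng, strand=strand)
            g, truth = make_planted_genome(
                PlantedGenomeSpec(length=400, genes=(gene,)), np.random.default_rng(8)
            )
            (rna,) = transcribe(g)
            (prot,) = translate(rna, g)
            m, w, h = gray_decode_mwh(gene.codon_values)
            assert (prot.m, prot.w, prot.h) == (m, w, h)
            assert prot.e == 1.0
            assert prot.cds_length == 3 * 8 + 6

    def test_transcript_without_rbs_yields_no_protein(self):
        cons = PROMOTER_CONSENSUS
        hairpin = "0110" + "000" + "1001"
        g = Genome.from_string(cons + "000000" + hairpin + "0" * 60)
        rnas = transcribe(g)
        assert any(r.strand == 0 and r.start == 22 for r in rnas)
        assert decode_structure(g).proteins == ()

    def test_start_immediately_stop_discarded(self):
        # gene head then STOP with no functional codon in between
        cons = PROMOTER_CONSENSUS
        head = "011011" + "0000" + "000"
        stop = "001"
        hairpin = "0110" + "000" + "1001"
        g = Genome.from_string(cons + head + stop + hairpin + "0" * 60)
        assert decode_structure(g).proteins == ()

    def test_gray_decoding_small_cases(self):
        # one M1 codon -> m = 1; M0 -> 0; W1 W0 (gray "10" -> binary "11") -> w_max
        assert gray_decode_mwh([0b101])[0] == 1.0
        assert gray_decode_mwh([0b100])[0] == 0.0
        assert gray_decode_mwh([0b011, 0b010])[1] == pytest.approx(W_MAX)
        # H codons: gray "11" -> binary "10" -> 2/3 -> h = 1/3
        assert gray_decode_mwh([0b111, 0b111])[2] == pytest.approx(2 / 3 * 2 - 1)


class TestPhenotype:
    def test_no_proteins_zero_phenotype(self):
        assert (compute_phenotype([]) == 0).all()

    def test_single_triangle(self):
        y = compute_phenotype([(0.5, 0.1, 1.0, 1.0)])
        x = np.linspace(0, 1, y.size)
        inside = np.abs(x - 0.5) < 0.1
        assert np.allclose(y[inside], 1 - np.abs(x[inside] - 0.5) / 0.1)
        assert (y[~inside] == 0).all()
        assert y.max() == pytest.approx(1.0, abs=1e-2)

    def test_two_triangles_clip_at_one(self):
        y = compute_phenotype([(0.5, 0.1, 0.6, 1.0)] * 2)
        assert y.max() == 1.0  # 1.2 clipped
        assert (y <= 1.0).all() and (y >= 0.0).all()

    def test_negative_height_clips_at_zero(self):
        y = compute_phenotype([(0.5, 0.1, -0.8, 1.0)])
        assert (y == 0).all()


class TestFitness:
    def test_error_zero_on_identical(self, default_target):
        assert metabolic_error(default_target.values.copy(), default_target) == 0.0

    def test_constant_gap(self):
        t = build_target(grid=513)
        p = np.zeros(513)
        gap = metabolic_error(p, np.full(513, 0.5))
        assert gap == pytest.approx(0.5)

    def test_grid_mismatch(self, default_target):
        with pytest.raises(GridMismatchError):
            metabolic_error(np.zeros(100), default_target)

    def test_refinement_oracle(self):
        rng = np.random.default_rng(2)
        prots = [
            (rng.uniform(), rng.uniform(0.005, W_MAX), rng.uniform(-1, 1), 1.0)
            for _ in range(12)
        ]
        e1 = metabolic_error(compute_phenotype(prots, 1024), build_target(1024))
        e2 = metabolic_error(compute_phenotype(prots, 10231), build_target(10231))
        assert abs(e1 - e2) < 1e-3

    def test_fitness_examples(self):
        assert fitness(0.0) == 1.0
        assert fitness(0.001, FitnessParams(k=1000)) == pytest.approx(np.exp(-1))
        assert fitness(0.01) < fitness(0.005) < fitness(0.0)
        with pytest.raises(ValueError):
            fitness(-1e-9)


class TestCodingAnnotation:
    def test_planted_cds_size(self):
        # 38 codons -> CDS = 3*38 + 6 = 120 bp in a 1000 bp genome
        gene = clean_gene(38, np.random.default_rng(3))
        g, truth = make_planted_genome(
            PlantedGenomeSpec(length=1000, genes=(gene,)), np.random.default_rng(9)
        )
        mask, coding, noncoding, frac = annotate_coding(g)
        assert coding == 120 == truth.coding_size
        assert frac == pytest.approx(0.12)
        assert coding + noncoding == len(g)

    def test_no_proteins_zero_fraction(self):
        g = Genome(bits=motif_free_filler(250, RNG, circular=True))
        _, coding, noncoding, frac = annotate_coding(g)
        assert coding == 0 and frac == 0.0 and noncoding == 250

    def test_essential_mode_counts_signals_too(self):
        g, _ = planted(seed=13)
        _, cds_only, _, _ = annotate_coding(g, coding="cds")
        _, essential, _, _ = annotate_coding(g, coding="essential")
        # promoter (22) + RBS/spacer (10) + terminator (11) on top of the CDS
        assert essential == cds_only + 43


class TestDecodePurity:
    def test_decode_is_deterministic(self):
        g, _ = planted(seed=14)
        a = decode(g)
        b = decode(g)
        assert a.metabolic_error == b.metabolic_error
        assert a.fitness == b.fitness
        assert [p.mwhe for p in a.proteins] == [p.mwhe for p in b.proteins]

    def test_strand_symmetry_and_rotation_invariance(self):
        rng = np.random.default_rng(15)
        genes = (clean_gene(5, rng, strand=0), clean_gene(7, rng, strand=1))
        g, _ = make_planted_genome(
            PlantedGenomeSpec(length=500, genes=genes), np.random.default_rng(10)
        )
        dec = decode(g)
        assert len(dec.proteins) == 2
        rc = decode(g.reverse_complement())
        assert sorted(p.mwhe for p in rc.proteins) == sorted(p.mwhe for p in dec.proteins)
        assert rc.metabolic_error == dec.metabolic_error
        rot = decode(g.rotated(137))
        assert rot.metabolic_error == dec.metabolic_error
        assert rot.coding_size == dec.coding_size

    def test_phenotype_and_fitness_bounds(self):
        g, _ = planted(seed=16)
        dec = decode(g)
        assert (dec.phenotype >= 0).all() and (dec.phenotype <= 1).all()
        assert 0 < dec.fitness <= 1
        assert dec.coding_size + dec.noncoding_size == dec.length
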