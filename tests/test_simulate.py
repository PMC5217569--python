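"""Methylome realization, bisulfite conversion, read chemistry, errors,
artifacts and FASTQ round-trips."""

import numpy as np
import pytest

from bsartifact.genome import CPG, ReferenceGenome, index_cytosines, revcomp
from bsartifact.simulate import (
    ArtifactModel,
    BisulfiteRead,
    MethylomeSpec,
    R2Collapse,
    SSSI_CLONE_LEVEL,
    SimulationConfig,
    _convert_fragment,
    apply_artifact,
    apply_errors,
    read_fastq,
    read_fastq_paired,
    reads_from_fragment,
    realize_methylome,
    simulate_library,
    write_fastq,
    write_fastq_paired,
)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    g = ReferenceGenome([("t", seq)])
    return g, index_cytosines(g)


class TestRealizeMethylome:
    def test_uniform_zero(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec.uniform(0.0))
        assert np.all(m.expected_levels() == 0.0)

    def test_sssi_default_level(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec.sssi())
        cpg = idx.context == CPG
        assert np.all(m.expected_levels()[cpg] == SSSI_CLONE_LEVEL)
        assert np.all(m.expected_levels()[~cpg] == 0.0)

    def test_mixture_expected_level_is_symmetric(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec.mixture(0.5))
        cpg = idx.context == CPG
        assert np.allclose(m.expected_levels()[cpg], 0.5)

    def test_mixture_requires_components(self):
        with pytest.raises(ValueError):
            MethylomeSpec(mode="mixture")

    def test_rejects_out_of_range_probability(self):
        with pytest.raises(ValueError):
            MethylomeSpec.uniform(1.5)


class TestSimulateFragment:
    def test_fully_methylated_fragment_equals_genomic_strand(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec(mode="uniform", cpg_level=1.0,
                                                 noncpg_level=1.0))
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(read_len=50)
        frag = _convert_fragment(g, m, cfg, rng, "t", 100, 200, "+")
        assert frag.text == g.sequence("t")[100:300]

    def test_fully_unmethylated_fragment_has_no_c(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec.uniform(0.0))
        rng = np.random.default_rng(0)
        for strand in "+-":
            frag = _convert_fragment(g, m, SimulationConfig(read_len=50), rng,
                                     "t", 50, 300, strand)
            assert "C" not in frag.text

    def test_partial_conversion_leaves_binomial_residue(self):
        # 10,000 genomic Cs, conversion 0.99 -> ~100 residual Cs (4 sd band)
        g = ReferenceGenome([("c", "C" * 10_000)])
        idx = index_cytosines(g)
        m = realize_methylome(idx, MethylomeSpec.uniform(0.0))
        cfg = SimulationConfig(read_len=50, conversion_rate=0.99)
        rng = np.random.default_rng(42)
        frag = _convert_fragment(g, m, cfg, rng, "c", 0, 10_000, "+")
        residual = frag.text.count("C")
        sd = np.sqrt(10_000 * 0.01 * 0.99)
        assert abs(residual - 100) < 4 * sd

    def test_fragment_longer_than_record_rejected(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec.uniform(0.0))
        cfg = SimulationConfig(read_len=50, fragment_mean=5000, fragment_sd=0)
        with pytest.raises(ValueError):
            _convert_fragment(g, m, cfg, np.random.default_rng(0), "t", 0, 5000, "+")


class TestReadChemistry:
    """5mC strand coding: PBAT reads 5mC as G in R1 / C in R2; MethylC-seq
    reads 5mC as C in R1 / G in R2."""

    @pytest.fixture()
    def methylated_fragment(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec(mode="uniform", cpg_level=1.0))
        rng = np.random.default_rng(1)
        return _convert_fragment(g, m, SimulationConfig(read_len=80), rng,
                                 "t", 0, 120, "+"), idx

    def _cpg_offsets(self, idx, start, flen, rl):
        pos, flat = idx.strand_positions("t", "+")
        sel = (pos >= start) & (pos < start + flen) & (idx.context[flat] == CPG)
        return pos[sel] - start

    def test_pbat_coding(self, methylated_fragment):
        frag, idx = methylated_fragment
        r1, r2 = reads_from_fragment(frag, SimulationConfig(read_len=80), "r")
        offs = self._cpg_offsets(idx, 0, 120, 80)
        for o in offs:
            if o < 80:
                assert r2.bases[o] == "C"  # 5mC as C in R2
            r1_off = 119 - o  # R1 reads the reverse complement from the 3' end
            if r1_off < 80:
                assert r1.bases[r1_off] == "G"  # 5mC as G in R1

    def test_methylc_coding_is_mirror(self, methylated_fragment):
        frag, idx = methylated_fragment
        r1, r2 = reads_from_fragment(
            frag, SimulationConfig(protocol="MethylC", read_len=80), "r"
        )
        offs = self._cpg_offsets(idx, 0, 120, 80)
        for o in offs:
            if o < 80:
                assert r1.bases[o] == "C"  # 5mC as C in R1
            r2_off = 119 - o
            if r2_off < 80:
                assert r2.bases[r2_off] == "G"  # 5mC as G in R2

    def test_unmethylated_pbat_r1_has_no_g(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec.uniform(0.0))
        cfg = SimulationConfig(read_len=60, fragment_mean=150, fragment_sd=10,
                               n_fragments=50, seed=3)
        reads = simulate_library(g, m, cfg)
        r1s = [r for r in reads if r.mate == "R1"]
        assert r1s and all("G" not in r.bases for r in r1s)

    def test_mates_are_reverse_complements_at_full_fragment_length(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec.uniform(0.5))
        cfg = SimulationConfig(read_len=100, fragment_mean=100, fragment_sd=0,
                               n_fragments=10, seed=4)
        reads = simulate_library(g, m, cfg)
        by_id = {}
        for r in reads:
            by_id.setdefault(r.id, {})[r.mate] = r
        for pair in by_id.values():
            assert pair["R1"].bases == revcomp(pair["R2"].bases)

    def test_read_longer_than_fragment_rejected(self, toy):
        g, idx = toy
        m = realize_methylome(idx, MethylomeSpec.uniform(0.0))
        frag = _convert_fragment(g, m, SimulationConfig(read_len=50),
                                 np.random.default_rng(0), "t", 0, 60, "+")
        with pytest.raises(ValueError):
            reads_from_fragment(frag, SimulationConfig(read_len=80), "r")


def _mkread(bases, quals=None, mate="R1"):
    if quals is None:
        quals = np.full(len(bases), 38, np.uint8)
    return BisulfiteRead("r", mate, "PBAT", bases, np.asarray(quals, np.uint8))


class TestApplyErrors:
    def test_zero_rate_is_identity(self):
        r = _mkread("ACGTACGT")
        out = apply_errors(r, SimulationConfig(error_rate=0.0), np.random.default_rng(0))
        assert out.bases == r.bases

    def test_rate_one_changes_every_base(self):
        r = _mkread("ACGTACGTACGT")
        out = apply_errors(r, SimulationConfig(error_rate=1.0), np.random.default_rng(0))
        assert all(a != b for a, b in zip(r.bases, out.bases))

    def test_error_count_is_binomial(self):
        n, rate = 1_000_000, 0.001
        r = _mkread("A" * n)
        out = apply_errors(r, SimulationConfig(error_rate=rate), np.random.default_rng(7))
        n_sub = sum(1 for a, b in zip(r.bases, out.bases) if a != b)
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(n_sub - n * rate) < 4 * sd


class TestApplyArtifact:
    def test_null_model_is_identity(self):
        r = _mkread("GGGGAACC")
        out = apply_artifact(r, ArtifactModel(), np.random.default_rng(0))
        assert out.bases == r.bases and np.array_equal(out.quals, r.quals)

    def test_full_undercall_removes_every_g(self):
        r = _mkread("GAGCGTGG")
        out = apply_artifact(r, ArtifactModel(g_to_a_rate=1.0), np.random.default_rng(0))
        assert "G" not in out.bases
        assert out.bases == "AAACATAA"  # G -> A specifically

    def test_untargeted_mate_unchanged(self):
        r = _mkread("GGGG", mate="R2")
        out = apply_artifact(r, ArtifactModel(g_to_a_rate=1.0), np.random.default_rng(0))
        assert out.bases == "GGGG"

    def test_quality_penalty_floors_at_two(self):
        r = _mkread("GGGG", quals=[10, 10, 10, 10])
        model = ArtifactModel(g_to_a_rate=1.0, g_quality_penalty=20)
        out = apply_artifact(r, model, np.random.default_rng(0))
        assert np.all(out.quals == 2)

    def test_density_collapse_caps_qualities(self):
        r = _mkread("ACGT", mate="R2")
        model = ArtifactModel(target_mate="R2",
                              r2_collapse=R2Collapse(density=650.0, quality_floor=5))
        out = apply_artifact(r, model, np.random.default_rng(0))
        assert np.all(out.quals == 5)
        low = ArtifactModel(target_mate="R2",
                            r2_collapse=R2Collapse(density=200.0, quality_floor=5))
        out = apply_artifact(r, low, np.random.default_rng(0))
        assert np.array_equal(out.quals, r.quals)

    def test_observed_level_shrinks_to_m_times_one_minus_q(self):
        # E[obs] = m(1-q): at m=1 every CpG reads G on R1; undercall q leaves
        # a G fraction of (1-q) among 5mC-coding bases
        q = 0.08
        rng = np.random.default_rng(9)
        r = _mkread("G" * 100_000)
        out = apply_artifact(r, ArtifactModel(g_to_a_rate=q), rng)
        frac_g = out.bases.count("G") / len(out.bases)
        sd = np.sqrt(q * (1 - q) / len(out.bases))
        assert abs(frac_g - (1 - q)) < 4 * sd


class TestFastqIO:
    def test_round_trip_identity(self, tmp_path):
        reads = [_mkread("ACGTN", [2, 20, 30, 41, 38])]
        p = tmp_path / "x.fastq"
        write_fastq(reads, p)
        back = read_fastq(p)
        assert back[0].bases == "ACGTN"
        assert np.array_equal(back[0].quals, reads[0].quals)

    def test_quality_41_encodes_as_J(self, tmp_path):
        p = tmp_path / "x.fastq"
        write_fastq([_mkread("A", [41])], p)
        assert p.read_text().splitlines()[3] == "J"  # chr(41+33)

    def test_empty_read_set(self, tmp_path):
        p = tmp_path / "x.fastq"
        write_fastq([], p)
        assert p.read_text() == ""
        assert read_fastq(p) == []

    def test_paired_writer_rejects_id_mismatch(self, tmp_path):
        r1 = _mkread("ACGT")
        r2 = BisulfiteRead("other", "R2", "PBAT", "ACGT", np.full(4, 38, np.uint8))
        with pytest.raises(ValueError):
            write_fastq_paired([(r1, r2)], tmp_path / "a.fq", tmp_path / "b.fq")

    def test_paired_reader_rejects_id_mismatch(self, tmp_path):
        write_fastq([_mkread("ACGT")], tmp_path / "a.fq")
        write_fastq([BisulfiteRead("z", "R2", "PBAT", "ACGT",
                                   np.full(4, 38, np.uint8))], tmp_path / "b.fq")
        with pytest.raises(ValueError):
            read_fastq_paired(tmp_path / "a.fq", tmp_path / "b.fq")


def test_same_seed_gives_byte_identical_fastq(toy, tmp_path):
    g, idx = toy
    m = realize_methylome(idx, MethylomeSpec.uniform(0.6))
    cfg = SimulationConfig(read_len=60, fragment_mean=150, fragment_sd=15,
                           n_fragments=200, error_rate=0.01, seed=77)
    art = ArtifactModel(g_to_a_rate=0.1, g_quality_penalty=15)
    paths = []
    for i in range(2):
        reads = simulate_library(g, m, cfg, artifact=art)
        p = tmp_path / f"run{i}.fastq"
        write_fastq(reads, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]
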