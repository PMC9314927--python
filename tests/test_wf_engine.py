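"""Wright-Fisher engine: fitness, meiosis, generations, splits, VCF."""

import numpy as np
import pysam
import pytest

from chromdiv.sim_config import (
    build_chromosome,
    default_parameters,
    diffusion_rescale,
    scale_parameters,
)
from chromdiv.wf_engine import (
    DemographySchedule,
    Population,
    advance_generation,
    fitness,
    gametogenesis,
    run_generations,
    run_scenario,
    sample_snapshot,
    split_population,
    write_vcf,
)


def _tiny_params(**overrides):
    defaults = dict(
        ancestral_Ne_diploids=10,
        selection_mode="neutral",
        mutation_rate_per_bp_per_gen=0.0,
        mean_recombination_rate_per_bp_per_gen=0.0,
    )
    defaults.update(overrides)
    return scale_parameters(default_parameters(**defaults), 1)


def _pop_with_site(n_diploids, carriers, position=500, s=0.0):
    pop = Population("t", n_diploids, capacity=64)
    pop.positions[0] = position
    pop.sel_coeffs[0] = s
    pop.mut_ids[0] = 0
    pop.next_mutation_id = 1
    pop.n_sites = 1
    for h in carriers:
        pop.H[h, 0] = 1
    return pop


class TestFitness:
    def test_no_selected_mutations(self):
        pop = _pop_with_site(2, carriers=[0], s=0.0)
        assert fitness(pop).tolist() == [1.0, 1.0]

    def test_heterozygote_codominant(self):
        pop = _pop_with_site(2, carriers=[0], s=-0.01)
        assert fitness(pop)[0] == pytest.approx(0.995)

    def test_homozygote(self):
        pop = _pop_with_site(2, carriers=[0, 1], s=-0.01)
        assert fitness(pop)[0] == pytest.approx(0.99)

    def test_multiplicative_across_loci(self):
        pop = _pop_with_site(1, carriers=[0], s=-0.01)
        pop.positions[1] = 700
        pop.sel_coeffs[1] = 0.02
        pop.mut_ids[1] = 1
        pop.n_sites = 2
        pop.H[0, 1] = 1
        pop.H[1, 1] = 1
        assert fitness(pop)[0] == pytest.approx(0.995 * 1.02)

    def test_lethal_floor(self):
        pop = _pop_with_site(1, carriers=[0, 1], s=-1.5)
        assert fitness(pop)[0] == 0.0


class TestGametogenesis:
    def test_no_recombination_no_mutation_copies_parent(self):
        sp = _tiny_params()
        chrom = build_chromosome(100_000, 1.0, sp)
        pop = _pop_with_site(1, carriers=[0])
        rng = np.random.default_rng(0)
        for _ in range(20):
            gamete, new = gametogenesis(pop, 0, chrom, sp, rng)
            assert not new
            assert gamete.tolist() in ([1], [0])  # one of the two parental haplotypes

    def test_crossover_rate_phenotype(self):
        """Realised switch count between 100 phase-informative markers
        matches the Poisson crossover intensity r*L."""
        sp = scale_parameters(
            default_parameters(ancestral_Ne_diploids=10_000, mutation_rate_per_bp_per_gen=0.0),
            25,
        )
        chrom = build_chromosome(1_000_000, 1.0, sp)
        pop = Population("x", 1, capacity=128)
        for k in range(100):
            pop.positions[k] = k * 10_000 + 5_000
            pop.mut_ids[k] = k
        pop.n_sites = 100
        pop.H[0, :100] = 1
        rng = np.random.default_rng(3)
        n = 30_000
        switches = np.array(
            [int(np.sum(np.diff(gametogenesis(pop, 0, chrom, sp, rng)[0]) != 0)) for _ in range(n)]
        )
        expected = 2.5e-7 * 1_000_000 * 0.99  # markers span 99% of the chromosome
        se = switches.std(ddof=1) / np.sqrt(n)
        assert abs(switches.mean() - expected) < 3 * se

    def test_multiplier_scales_crossovers(self):
        sp = scale_parameters(
            default_parameters(ancestral_Ne_diploids=10_000, mutation_rate_per_bp_per_gen=0.0),
            25,
        )
        pop = Population("x", 1, capacity=128)
        for k in range(100):
            pop.positions[k] = k * 10_000 + 5_000
            pop.mut_ids[k] = k
        pop.n_sites = 100
        pop.H[0, :100] = 1
        rng = np.random.default_rng(4)
        means = {}
        for mult in (0.33, 3.0):
            chrom = build_chromosome(1_000_000, mult, sp)
            switches = [
                int(np.sum(np.diff(gametogenesis(pop, 0, chrom, sp, rng)[0]) != 0))
                for _ in range(30_000)
            ]
            means[mult] = np.mean(switches)
        assert means[3.0] / means[0.33] == pytest.approx(3.0 / 0.33, rel=0.15)

    def test_gene_conversion_transfers_tracts(self):
        """With crossovers off, conversion tracts copy homologous markers
        at the Poisson initiation rate times the per-tract marker yield."""
        from chromdiv.sim_config import ChromosomeMap

        sp = _tiny_params(ancestral_Ne_diploids=1)
        L = 1_000_000
        chrom = ChromosomeMap(
            length_bp=L,
            coding_starts=np.array([0]),
            coding_ends=np.array([10]),
            per_bp_recombination_rate=0.0,
            per_bp_gene_conversion_initiation_rate=2e-6,  # 2 tracts/meiosis
            gene_conversion_tract_len_bp=440.0,
        )
        pop = Population("x", 1, capacity=512)
        k = 200
        pop.positions[:k] = np.arange(k) * 5_000 + 2_500
        pop.mut_ids[:k] = np.arange(k)
        pop.n_sites = k
        pop.H[0, :k] = 1  # hap0 carries every marker, hap1 none
        rng = np.random.default_rng(0)
        n = 20_000
        transferred = np.empty(n)
        for i in range(n):
            g, _ = gametogenesis(pop, 0, chrom, sp, rng)
            s = g.sum()
            transferred[i] = min(s, k - s)
        # 2 tracts/meiosis x (200 markers / 1 Mb) x 440 bp = 0.176 markers
        expected = 2 * (k / L) * 440.0
        se = transferred.std(ddof=1) / np.sqrt(n)
        assert abs(transferred.mean() - expected) < 3 * se

    def test_mutation_influx(self):
        sp = _tiny_params(mutation_rate_per_bp_per_gen=1e-5)
        chrom = build_chromosome(100_000, 1.0, sp)
        pop = Population("x", 1, capacity=64)
        rng = np.random.default_rng(5)
        counts = [len(gametogenesis(pop, 0, chrom, sp, rng)[1]) for _ in range(5_000)]
        assert np.mean(counts) == pytest.approx(1.0, abs=3 * np.std(counts) / np.sqrt(5_000))


class TestAdvanceGeneration:
    def test_heterozygosity_decay_one_generation(self):
        """E[H'] = H0 * (1 - 1/2N) for drift-only updates."""
        sp = _tiny_params()
        chrom = build_chromosome(100_000, 1.0, sp)
        rng = np.random.default_rng(7)
        hets = []
        for _ in range(3_000):
            pop = _pop_with_site(10, carriers=range(10))
            advance_generation(pop, chrom, sp, rng)
            p = pop.H[:, 0].sum() / 20 if pop.n_sites else float(pop.n_subs > 0)
            hets.append(2 * p * (1 - p))
        hets = np.asarray(hets)
        expected = 0.5 * (1 - 1 / 20)
        se = hets.std(ddof=1) / np.sqrt(hets.size)
        assert abs(hets.mean() - expected) < 3 * se

    def test_selection_pushes_frequency_up(self):
        """Deterministic expectation: delta-p = s*h*p(1-p)/w-bar > 0."""
        sp = _tiny_params(ancestral_Ne_diploids=200, selection_mode="with_selection")
        chrom = build_chromosome(100_000, 1.0, sp)
        rng = np.random.default_rng(8)
        freqs = []
        for _ in range(200):
            pop = _pop_with_site(200, carriers=range(200), s=0.1)
            advance_generation(pop, chrom, sp, rng)
            n = pop.H[:, 0].sum() if pop.n_sites else 400 * (pop.n_subs > 0)
            freqs.append(n / 400)
        assert np.mean(freqs) > 0.5

    def test_extinction_raises(self):
        sp = _tiny_params(selection_mode="with_selection")
        chrom = build_chromosome(100_000, 1.0, sp)
        pop = _pop_with_site(2, carriers=[0, 1, 2, 3], s=-2.0)  # homozygous lethal in all
        with pytest.raises(RuntimeError, match="extinct"):
            advance_generation(pop, chrom, sp, np.random.default_rng(9))

    def test_allele_lineage_audit(self):
        """Every offspring allele traces to a parental haplotype or is a
        fresh single-carrier mutation column."""
        sp = _tiny_params(mutation_rate_per_bp_per_gen=5e-6)
        chrom = build_chromosome(100_000, 1.0, sp)
        rng = np.random.default_rng(10)
        pop = Population("x", 5, capacity=256)
        for k in range(8):
            pop.positions[k] = 1000 * (k + 1)
            pop.mut_ids[k] = k
        pop.next_mutation_id = 8
        pop.n_sites = 8
        pop.H[: 2 * 5, :8] = rng.integers(0, 2, size=(10, 8))
        for _ in range(10):
            pre_H = pop.genotype_matrix().copy()
            pre_ids = pop.site_ids().copy()
            pre_subs = set(pop.substitution_ids())
            parents = advance_generation(pop, chrom, sp, rng, return_parents=True)
            id_to_pre_col = {int(m): c for c, m in enumerate(pre_ids)}
            post_subs = set(pop.substitution_ids())
            for j in range(pop.n_haplotypes):
                carried = set(int(i) for i in pop.haplotype_mutation_ids(j)) | post_subs
                parent = int(parents[j])
                parental = set(
                    int(pre_ids[c])
                    for c in range(pre_ids.size)
                    if pre_H[2 * parent, c] or pre_H[2 * parent + 1, c]
                ) | pre_subs
                new_ids = carried - parental
                for mid in new_ids:
                    assert mid not in id_to_pre_col  # must be a de novo mutation
            # columns never present before must have been created this generation
            assert pop.next_mutation_id >= pre_ids.size


class TestSplit:
    def _burned_pop(self):
        sp = _tiny_params(ancestral_Ne_diploids=400)
        pop = Population("pop_A", 400, capacity=32)
        return pop

    def test_equal_split(self):
        pop = self._burned_pop()
        p1, p2 = split_population(pop, 0.5, np.random.default_rng(0))
        assert p1.N == p2.N == 200
        assert p1.label == "pop_1" and p2.label == "pop_2"

    def test_severe_bottleneck(self):
        pop = self._burned_pop()
        p1, p2 = split_population(pop, 0.1, np.random.default_rng(0))
        assert p1.N == p2.N == 40

    def test_overlapping_fraction_rejected(self):
        pop = self._burned_pop()
        with pytest.raises(ValueError):
            split_population(pop, 0.6, np.random.default_rng(0))

    def test_daughters_partition_founders(self):
        """Daughter allele counts at a marker sum to the ancestral count
        when the split fraction is exactly one half."""
        pop = _pop_with_site(10, carriers=[0, 3, 5, 8, 13])
        p1, p2 = split_population(pop, 0.5, np.random.default_rng(1))
        total = p1.genotype_matrix().sum() + p2.genotype_matrix().sum()
        assert total == 5


@pytest.fixture(scope="module")
def small_scenario():
    raw = default_parameters(
        ancestral_Ne_diploids=100,
        selection_mode="neutral",
        mutation_rate_per_bp_per_gen=5e-7,
        mean_recombination_rate_per_bp_per_gen=2.5e-7,
        output_interval_generations=250,
    )
    sp = scale_parameters(raw, 1)
    chrom = build_chromosome(1_000_000, 1.0, sp)
    sched = DemographySchedule.from_parameters(sp, max_generations=500)
    return sp, chrom, sched


class TestRunScenario:
    def test_schedule_from_parameters(self, small_scenario):
        sp, _, sched = small_scenario
        assert sched.burn_in_generations == 20 * 100
        assert sched.sampling_generations == (1, 250, 500)

    def test_deterministic_given_seed(self, small_scenario):
        sp, chrom, sched = small_scenario
        r1 = run_scenario(sp, chrom, sched, seed=42, sample_size=10)
        r2 = run_scenario(sp, chrom, sched, seed=42, sample_size=10)
        assert np.array_equal(r1.ancestral_snapshot.genotypes, r2.ancestral_snapshot.genotypes)
        assert np.array_equal(r1.ancestral_snapshot.positions, r2.ancestral_snapshot.positions)
        for a, b in zip(r1.divergence_samples, r2.divergence_samples):
            assert np.array_equal(a.haploid_1.ids, b.haploid_1.ids)
            assert np.array_equal(a.haploid_2.ids, b.haploid_2.ids)

    def test_neutral_mode_effects_all_zero(self, small_scenario):
        sp, chrom, sched = small_scenario
        res = run_scenario(sp, chrom, sched, seed=11, sample_size=10)
        assert np.all(res.ancestral_snapshot.sel_coeffs == 0.0)

    def test_fast_path_matches_reference_heterozygosity(self):
        """Kernel and reference paths agree on drift-only decay."""
        sp = _tiny_params(ancestral_Ne_diploids=20)
        chrom = build_chromosome(100_000, 1.0, sp)
        decayed = []
        for rep in range(400):
            pop = _pop_with_site(20, carriers=range(20))
            run_generations(pop, chrom, sp, 10, seed=rep)
            p = pop.H[:, 0].sum() / 40 if pop.n_sites else float(pop.n_subs > 0)
            decayed.append(2 * p * (1 - p))
        decayed = np.asarray(decayed)
        expected = 0.5 * (1 - 1 / 40) ** 10
        se = decayed.std(ddof=1) / np.sqrt(decayed.size)
        assert abs(decayed.mean() - expected) < 3 * se


class TestVcf:
    def _snapshot(self, rng):
        sp = _tiny_params(ancestral_Ne_diploids=5, mutation_rate_per_bp_per_gen=1e-5)
        chrom = build_chromosome(100_000, 1.0, sp)
        pop = Population("pop_A", 5, capacity=128)
        run_generations(pop, chrom, sp, 50, seed=77)
        return sample_snapshot(pop, 4, chrom, rng), chrom

    def test_round_trip_genotype_matrix(self, tmp_path, small_rng):
        snap, _ = self._snapshot(small_rng)
        assert snap.positions.size > 0
        path = tmp_path / "sample.vcf"
        write_vcf(snap, path)
        vcf = pysam.VariantFile(str(path))
        recs = list(vcf)
        assert len(recs) == snap.positions.size
        for j, rec in enumerate(recs):
            assert rec.pos == snap.positions[j] + 1  # 1-based
            for i in range(snap.n_individuals):
                gt = rec.samples[f"ind{i}"]["GT"]
                assert gt == (snap.genotypes[2 * i, j], snap.genotypes[2 * i + 1, j])
                assert rec.samples[f"ind{i}"].phased

    def test_header_only_when_no_segregating_sites(self, tmp_path):
        sp = _tiny_params(ancestral_Ne_diploids=5)
        chrom = build_chromosome(100_000, 1.0, sp)
        pop = Population("pop_A", 5, capacity=16)
        snap = sample_snapshot(pop, 3, chrom, np.random.default_rng(0))
        path = tmp_path / "empty.vcf"
        write_vcf(snap, path)
        assert len(list(pysam.VariantFile(str(path)))) == 0

    def test_single_heterozygote_record(self, tmp_path):
        sp = _tiny_params(ancestral_Ne_diploids=2)
        chrom = build_chromosome(100_000, 1.0, sp)
        pop = _pop_with_site(2, carriers=[1], position=999)
        rng = np.random.default_rng(1)
        snap = sample_snapshot(pop, 2, chrom, rng)
        path = tmp_path / "het.vcf"
        write_vcf(snap, path)
        text = path.read_text()
        lines = [l for l in text.splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        fields = lines[0].split("\t")
        assert fields[1] == "1000"
        assert "0|1" in fields[9:] or "1|0" in fields[9:]
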