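"""Construction contracts and statistical calibration of the ALE simulator."""

import numpy as np
import pytest

from alemut.io_formats import write_reference
from alemut.simulate import (SimulationConfig, ArmSpec, generate_reference,
                             preexisting_variants, simulate_arm,
                             simulate_mic_trajectory, simulate_pileup)

STOPS = {"TAA", "TAG", "TGA"}


class TestGenerateReference:
    def test_construction_contract(self):
        cfg = SimulationConfig(genome_length=30_000, gc_content=0.464,
                               cds_fraction=0.8, seed=1)
        ref = generate_reference(cfg)
        assert len(ref.sequence) == 30_000
        assert 0.454 <= ref.gc_content <= 0.474
        assert 0.75 <= ref.cds_fraction <= 0.85

    def test_cds_are_valid_orfs(self, small_genome):
        for f in small_genome.features:
            seq = small_genome.sequence[f.start - 1:f.end]
            if f.strand == "-":
                comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
                seq = "".join(comp[b] for b in reversed(seq))
            assert len(seq) % 3 == 0
            assert seq.startswith("ATG")
            assert seq[-3:] in STOPS
            internal = {seq[i:i + 3] for i in range(3, len(seq) - 3, 3)}
            assert not internal & STOPS

    def test_infeasible_sizing_raises(self):
        cfg = SimulationConfig(genome_length=300, cds_fraction=0.99)
        with pytest.raises(ValueError, match="infeasible"):
            generate_reference(cfg)

    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        cfg = SimulationConfig(genome_length=5_000, cds_fraction=0.6, seed=7)
        for i in (1, 2):
            ref = generate_reference(cfg)
            write_reference(ref, tmp_path / f"r{i}.fasta", tmp_path / f"r{i}.gff3")
        assert (tmp_path / "r1.fasta").read_bytes() == (tmp_path / "r2.fasta").read_bytes()
        assert (tmp_path / "r1.gff3").read_bytes() == (tmp_path / "r2.gff3").read_bytes()


class TestSimulateArm:
    def test_poisson_mean_of_fixed_events(self):
        """Mean de novo count over many lineages matches rate x generations
        within 2 SE (independent Poisson-sampling oracle)."""
        cfg = SimulationConfig(genome_length=50_000, n_lineages=50, seed=5,
                               generations_total=2000, sampling_interval=200,
                               arms=(ArmSpec("A", 0.01, True), ArmSpec("C", 0.0)))
        ref = generate_reference(cfg)
        truth = simulate_arm(ref, cfg, "A")
        counts = [sum(not t.is_preexisting for t in recs) for recs in truth.values()]
        expected = 0.01 * 2000
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 2 * se
        # oracle: direct Poisson sampling at the same mean has matching spread
        oracle = np.random.default_rng(0).poisson(expected, size=5000)
        assert abs(np.mean(counts) - oracle.mean()) < 3 * se

    def test_zero_rate_arm_has_only_preexisting(self, small_genome, desk_config):
        cfg = _replace(desk_config, arms=(ArmSpec("A", 0.01, True),
                                          ArmSpec("C", 0.0)))
        truth = simulate_arm(small_genome, cfg, "C")
        for recs in truth.values():
            assert all(t.is_preexisting for t in recs)
            assert len(recs) == cfg.n_preexisting_snvs

    def test_preexisting_shared_identically_and_fixed_everywhere(
            self, small_genome, desk_config):
        pre = {v for v in preexisting_variants(small_genome, desk_config)}
        for arm in ("A", "G", "C"):
            truth = simulate_arm(small_genome, desk_config, arm)
            for recs in truth.values():
                planted = {t.key for t in recs if t.is_preexisting}
                assert planted == pre
                for t in recs:
                    if t.is_preexisting:
                        assert all(f == 1.0 for f in t.frequency_by_sample.values())

    def test_preexisting_is_intersection_of_generation0_fixed(
            self, small_genome, desk_config):
        """Pre-existing SNVs = exactly the variants fixed at generation 0 in
        every lineage of every arm."""
        gen0_sets = []
        for arm in ("A", "G", "C"):
            for recs in simulate_arm(small_genome, desk_config, arm).values():
                gen0_sets.append({t.key for t in recs
                                  if t.frequency_by_sample.get(0, 0.0) == 1.0})
        inter = set.intersection(*gen0_sets)
        pre = set(preexisting_variants(small_genome, desk_config))
        assert inter == pre

    def test_origin_before_first_presence(self, small_genome, desk_config):
        truth = simulate_arm(small_genome, desk_config, "A")
        for recs in truth.values():
            for t in recs:
                seen = [g for g, f in t.frequency_by_sample.items() if f > 0]
                if seen:
                    assert t.origin_generation <= min(seen)

    def test_undefined_arm_rejected(self, small_genome, desk_config):
        with pytest.raises(KeyError):
            simulate_arm(small_genome, desk_config, "X")


class TestSimulatePileup:
    def test_noise_free_fixed_site(self, small_genome, desk_config, rng):
        cfg = _replace(desk_config, sequencing_error_rate=0.0, background_sites=0)
        truth = simulate_arm(small_genome, cfg, "A")
        recs = next(iter(truth.values()))
        pile = simulate_pileup(small_genome, recs, 0, cfg, rng=rng)
        for _, row in pile.iterrows():
            cov = row[list("ACGT")].sum()
            rec = next(t for t in recs if t.position == row["pos"])
            if rec.variant_type == "SNV" and rec.frequency_by_sample[0] == 1.0:
                assert row[rec.alt_allele] == cov
                assert row[rec.ref_allele] == 0

    def test_variant_free_sites_clean_without_error(self, small_genome, desk_config, rng):
        cfg = _replace(desk_config, sequencing_error_rate=0.0, background_sites=50)
        pile = simulate_pileup(small_genome, [], 0, cfg, rng=rng)
        for _, row in pile.iterrows():
            assert row[row["ref"]] == row[list("ACGT")].sum()

    def test_allele_fraction_matches_truth_frequency(self, small_genome, rng):
        """Binomial oracle: mean alt fraction over replicate draws sits
        within 2 SE of the planted frequency 0.5."""
        from alemut.simulate import TruthRecord
        cfg = SimulationConfig(genome_length=30_000, seed=11, coverage_mean=200,
                               sequencing_error_rate=0.001, background_sites=0)
        rec = TruthRecord(lineage_id="A1", position=10, ref_allele=small_genome.base_at(10),
                          alt_allele="A" if small_genome.base_at(10) != "A" else "C",
                          origin_generation=100,
                          frequency_by_sample={g: 0.5 for g in cfg.sampled_generations})
        fracs = []
        for _ in range(1000):
            pile = simulate_pileup(small_genome, [rec], 200, cfg, rng=rng)
            row = pile.iloc[0]
            fracs.append(row[rec.alt_allele] / row[list("ACGT")].sum())
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) < 2 * se + 1e-3

    def test_high_coverage_converges_to_truth(self, small_genome):
        """Pileup allele fractions converge to truth frequencies as coverage
        grows (3 SE at coverage 1e4)."""
        from alemut.simulate import TruthRecord
        cfg = SimulationConfig(genome_length=30_000, seed=11, coverage_mean=1e4,
                               sequencing_error_rate=0.003, background_sites=0)
        e = cfg.sequencing_error_rate
        draws = 10
        for f in (0.1, 0.5, 0.9):
            rec = TruthRecord(lineage_id="A1", position=50,
                              ref_allele=small_genome.base_at(50),
                              alt_allele="G" if small_genome.base_at(50) != "G" else "T",
                              origin_generation=0,
                              frequency_by_sample={g: f for g in cfg.sampled_generations})
            rng = np.random.default_rng(4)
            fracs = []
            for _ in range(draws):
                pile = simulate_pileup(small_genome, [rec], 0, cfg, rng=rng)
                row = pile.iloc[0]
                fracs.append(row[rec.alt_allele] / row[list("ACGT")].sum())
            expected = f * (1 - e) + (1 - f) * (e / 3)  # binomial oracle
            se = np.sqrt(f * (1 - f) / cfg.coverage_mean / draws)
            assert abs(np.mean(fracs) - expected) < 3 * se
            assert abs(np.mean(fracs) - f) < 3 * se + e  # converges to truth

    def test_unsampled_generation_rejected(self, small_genome, desk_config):
        with pytest.raises(KeyError):
            simulate_pileup(small_genome, [], 123, desk_config)

    def test_deterministic_under_seed(self, small_genome, desk_config):
        truth = simulate_arm(small_genome, desk_config, "G")
        recs = next(iter(truth.values()))
        p1 = simulate_pileup(small_genome, recs, 400, desk_config)
        p2 = simulate_pileup(small_genome, recs, 400, desk_config)
        assert p1.equals(p2)


class TestMicTrajectory:
    def _records(self, lineage, fixed_gens, cfg):
        from alemut.simulate import TruthRecord
        return [TruthRecord(lineage_id=lineage, position=100 + i, ref_allele="A",
                            alt_allele="C", origin_generation=max(g - 1, 1),
                            frequency_by_sample={}, confers_resistance=True,
                            fixed_generation=g)
                for i, g in enumerate(fixed_gens)]

    def test_doubling_rule(self):
        cfg = SimulationConfig(genome_length=10_000, mic_initial=2.0,
                               mic_plateau_cap=512.0, generations_total=1000,
                               sampling_interval=200)
        truth = {"A1": self._records("A1", [150, 350], cfg)}
        mic = simulate_mic_trajectory(truth, cfg, "A")
        assert mic.values[:, 0].tolist() == [2, 4, 8, 8, 8, 8]

    def test_no_resistance_constant(self, small_genome, desk_config):
        truth = simulate_arm(small_genome, desk_config, "C")
        mic = simulate_mic_trajectory(truth, desk_config, "C")
        assert np.all(mic.values == desk_config.mic_initial)

    def test_plateau_cap(self):
        cfg = SimulationConfig(genome_length=10_000, mic_initial=2.0,
                               mic_plateau_cap=32.0, generations_total=1000,
                               sampling_interval=200)
        truth = {"A1": self._records("A1", [100, 200, 300, 400, 500], cfg)}
        mic = simulate_mic_trajectory(truth, cfg, "A")
        assert mic.values[-1, 0] == 32.0


def test_config_yaml_round_trip(desk_config):
    again = SimulationConfig.from_yaml(desk_config.to_yaml())
    assert again == desk_config


def test_sampling_interval_must_divide_total():
    with pytest.raises(ValueError, match="divide"):
        SimulationConfig(generations_total=2000, sampling_interval=300)


def _replace(cfg, **kw):
    import dataclasses
    return dataclasses.replace(cfg, **kw)
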