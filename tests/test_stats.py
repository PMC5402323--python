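"""Rates, spectrum, Nei-Gojobori site counting, Ka/Ks, z-test and COG tallies."""

import numpy as np
import pytest

from alemut.denovo import DeNovoMutation
from alemut.stats import (cog_tally, count_sites, ka_ks, mutation_rate,
                          spectrum_proportions, summarize_arm,
                          two_proportion_z, _per_codon_sites)

BASES = "ACGT"


def snv(pos, ref, alt, consequence=None, lineage="A1"):
    return DeNovoMutation(lineage_id=lineage, position=pos, ref_allele=ref,
                          alt_allele=alt, variant_type="SNV", first_seen=200,
                          last_seen=2000, fixed_at=200, consequence=consequence)


class TestMutationRate:
    def test_antibiotic_regime_values(self):
        per_gen, per_bp = mutation_rate(20, 2000, 2_861_848)
        assert per_gen == pytest.approx(0.01)
        assert per_bp == pytest.approx(3.494e-9, rel=1e-3)

    def test_control_regime_values(self):
        per_gen, per_bp = mutation_rate(5.5, 2000, 2_861_848)
        assert per_gen == pytest.approx(0.00275)
        assert per_bp == pytest.approx(9.61e-10, rel=1e-3)

    def test_zero_count(self):
        assert mutation_rate(0, 2000, 100) == (0.0, 0.0)

    def test_invalid_denominators(self):
        with pytest.raises(ValueError):
            mutation_rate(1, 0, 100)
        with pytest.raises(ValueError):
            mutation_rate(1, 100, 0)


class TestSpectrumProportions:
    def test_hand_counted_classes(self):
        props, ti_tv = spectrum_proportions([("G", "A"), ("C", "A"), ("A", "C")])
        assert props["CG→TA"] == pytest.approx(1 / 3)
        assert props["CG→AT"] == pytest.approx(1 / 3)
        assert props["AT→CG"] == pytest.approx(1 / 3)
        assert ti_tv == pytest.approx(0.5)  # 1 transition / 2 transversions

    def test_single_transition_undefined_titv(self):
        props, ti_tv = spectrum_proportions([("G", "A")])
        assert props["CG→TA"] == 1.0 and ti_tv is None

    def test_empty_input(self):
        assert spectrum_proportions([]) == ({}, None)

    def test_proportions_sum_to_one(self, rng):
        pairs = []
        for _ in range(500):
            r, a = rng.choice(list(BASES), size=2, replace=False)
            pairs.append((str(r), str(a)))
        props, _ = spectrum_proportions(pairs)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_classes_recovered(self, rng):
        """Multinomial oracle: 1e4 SNVs drawn uniformly over the six classes
        give per-class proportions within 3 SE of 1/6."""
        from alemut.annotate import SPECTRUM_LABELS
        by_class = {"AT→CG": ("A", "C"), "AT→GC": ("A", "G"), "AT→TA": ("A", "T"),
                    "CG→AT": ("C", "A"), "CG→GC": ("C", "G"), "CG→TA": ("C", "T")}
        n = 10_000
        draws = rng.choice(list(SPECTRUM_LABELS), size=n)
        props, _ = spectrum_proportions([by_class[d] for d in draws])
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for lab in SPECTRUM_LABELS:
            assert abs(props[lab] - 1 / 6) < 3 * se

    def test_indels_rejected(self):
        bad = DeNovoMutation(lineage_id="A1", position=1, ref_allele="AT",
                             alt_allele="A", variant_type="deletion",
                             first_seen=0, last_seen=0, fixed_at=0)
        with pytest.raises(ValueError, match="SNV"):
            spectrum_proportions([bad])


class TestCountSites:
    def test_ttt_enumeration(self):
        syn, nonsyn = _per_codon_sites()["TTT"]
        assert syn == pytest.approx(1 / 3)  # only TTT->TTC preserves Phe
        assert nonsyn == pytest.approx(8 / 3)

    def test_atg_has_no_synonymous_site(self):
        assert _per_codon_sites()["ATG"] == (0.0, 3.0)

    def test_brute_force_oracle_all_64_codons(self):
        """Independent enumeration of all 9 single-base changes per codon."""
        from tests.test_annotate import ORACLE_CODE
        per_codon = _per_codon_sites()
        for codon, aa in ORACLE_CODE.items():
            syn = 0.0
            for i in range(3):
                f = sum(1 for b in BASES if b != codon[i]
                        and ORACLE_CODE[codon[:i] + b + codon[i + 1:]] == aa)
                syn += f / 3
            assert per_codon[codon][0] == pytest.approx(syn)
            assert sum(per_codon[codon]) == pytest.approx(3.0)

    def test_conservation_on_generated_genome(self, small_genome):
        syn, nonsyn = count_sites(small_genome)
        n_codons = sum(f.length // 3 for f in small_genome.features)
        assert syn + nonsyn == pytest.approx(3 * n_codons, abs=1e-6)

    def test_codon_usage_weighting(self, small_genome):
        # weighting everything onto ATG leaves zero synonymous sites
        syn, nonsyn = count_sites(small_genome, codon_usage={"ATG": 1000.0})
        n_codons = sum(f.length // 3 for f in small_genome.features)
        assert syn == 0.0 and nonsyn == pytest.approx(3 * n_codons)


class TestKaKs:
    def test_no_synonymous_flagged_undefined(self):
        res = ka_ks([snv(1, "A", "C", "non-synonymous")], (100.0, 300.0))
        assert res.ratio is None and not res.defined

    def test_neutrality_identity(self):
        muts = ([snv(i, "A", "C", "non-synonymous") for i in range(30)]
                + [snv(i + 100, "A", "C", "synonymous") for i in range(10)])
        res = ka_ks(muts, (100.0, 300.0))  # equal per-site densities
        assert res.ratio == pytest.approx(1.0)

    def test_zero_sites_error(self):
        with pytest.raises(ValueError):
            ka_ks([], (0.0, 10.0))

    def test_neutral_simulation_ratio_near_one(self, small_genome, rng):
        """1e5 SNVs placed uniformly over CDS positions with uniform alt
        bases give Ka/Ks within 3 SE of 1 (neutral oracle)."""
        from alemut.annotate import classify_consequence
        cds_positions = np.concatenate([np.arange(f.start, f.end + 1)
                                        for f in small_genome.features])
        n = 100_000
        pos = rng.choice(cds_positions, size=n)
        muts = []
        for p in pos:
            ref_base = small_genome.base_at(int(p))
            alt = str(rng.choice([b for b in BASES if b != ref_base]))
            cons, _ = classify_consequence((int(p), ref_base, alt), small_genome)
            muts.append(snv(int(p), ref_base, alt, cons))
        sites = count_sites(small_genome)
        res = ka_ks(muts, sites)
        p_syn = sites[0] / sum(sites)
        se_ratio = np.sqrt(1 / (n * p_syn * (1 - p_syn)))  # delta-method scale
        assert abs(res.ratio - 1.0) < 3 * se_ratio


class TestTwoProportionZ:
    def test_null_identity(self):
        res = two_proportion_z(10, 20, 5, 10)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_one_tailed == pytest.approx(0.5)

    def test_closed_form_oracle(self):
        """Pooled-variance closed form plus high-precision normal CDF."""
        from scipy.stats import norm
        x1, n1, x2, n2 = 15, 20, 5, 10
        p_hat = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / np.sqrt(p_hat * (1 - p_hat) * (1 / n1 + 1 / n2))
        res = two_proportion_z(x1, n1, x2, n2)
        assert res.z == pytest.approx(z)
        assert res.z == pytest.approx(1.369, abs=1e-3)
        assert res.p_one_tailed == pytest.approx(float(norm.sf(z)))
        assert res.p_one_tailed == pytest.approx(0.086, abs=1e-3)

    def test_extreme_but_valid_proportions(self):
        res = two_proportion_z(20, 20, 0, 10)
        assert res.z > 0 and res.p_one_tailed < 0.01

    def test_antisymmetry(self):
        a = two_proportion_z(15, 20, 5, 10)
        b = two_proportion_z(5, 10, 15, 20)
        assert a.z == pytest.approx(-b.z)

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(ValueError, match="degenerate"):
            two_proportion_z(0, 20, 0, 10)


class TestCogTally:
    def test_replicate_accumulation(self):
        genes = [("G", "G1", "geneX"), ("G", "G2", "geneX")]
        tally = cog_tally(genes, {"geneX": "K"})
        assert tally["G"]["K"] == 2

    def test_empty_map_unassigned(self):
        tally = cog_tally([("A", "A1", "geneY")], {})
        assert tally["A"]["unassigned"] == 1

    def test_multi_letter_assignment(self):
        tally = cog_tally([("A", "A1", "geneZ")], {"geneZ": "KM"})
        assert tally["A"]["K"] == 1 and tally["A"]["M"] == 1


class TestSummarizeArm:
    def test_pooled_summary(self, small_genome):
        from alemut.annotate import annotate_denovo
        muts = [snv(f.start + 4, small_genome.base_at(f.start + 4),
                    "A" if small_genome.base_at(f.start + 4) != "A" else "G",
                    lineage=f"A{i % 2 + 1}")
                for i, f in enumerate(small_genome.features[:6])]
        annotate_denovo(muts, small_genome)
        s = summarize_arm("A", muts, n_lineages=2, generations_total=1000,
                          ref=small_genome)
        assert s.mean_denovo_count == 3.0
        assert s.rate_per_generation == pytest.approx(0.003)
        assert sum(s.spectrum_proportions.values()) == pytest.approx(1.0)
        assert s.n_synonymous + s.n_nonsynonymous == len(muts)
        assert s.nonsyn_fraction == pytest.approx(
            s.n_nonsynonymous / len(muts))
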