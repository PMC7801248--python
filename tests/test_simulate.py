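"""The synthetic-evolution generator: planted divergences, events, truth."""

import math

import numpy as np
import pytest

from skullcap.simulate import (ConfigurationError, EvolutionScenario,
                               PlaidConfig, TandemEvent,
                               jc_p, mutate_sequence, simulate_cds_pairs,
                               simulate_contact_matrix, simulate_genome_pair,
                               simulate_ltr_set)


# ------------------------------------------------------------ mutate_sequence


def test_mutate_zero_probability_is_identity():
    cds = "ATGGCTAAAGATTGG" * 20
    assert mutate_sequence(cds, 0.0, 0.0, 1) == cds


def test_mutate_internal_stop_rejected():
    with pytest.raises(ValueError, match="stop"):
        mutate_sequence("ATGTAAGCT", 0.1, 0.1, 1)


def test_mutate_saturating_probability_rejected():
    with pytest.raises(ValueError):
        mutate_sequence("ATGGCT", 0.75, 0.0, 1)


def test_mutate_synonymous_rate_matches_binomial_expectation():
    """1e5 fully synonymous sites: observed fraction within 0.1441 +- 0.004."""
    rng = np.random.default_rng(3)
    fourfold = ["GCT", "GGA", "CCG", "ACC", "GTA", "TCT"]
    cds = "".join(fourfold[i] for i in rng.integers(0, 6, 100_000))
    out = mutate_sequence(cds, 0.1441, 0.0, 4)
    diffs = sum(a != b for a, b in zip(cds[2::3], out[2::3]))
    assert abs(diffs / 100_000 - 0.1441) < 0.004
    # nonsynonymous positions untouched
    assert cds[0::3] == out[0::3] and cds[1::3] == out[1::3]


def test_mutate_never_creates_stop_codons():
    from skullcap._codons import STOP_CODONS, codons_of

    pairs = simulate_cds_pairs(50, 200, 0.5, 0.5, seed=9)
    for _, b in pairs:
        assert not any(c in STOP_CODONS for c in codons_of(b))


# ------------------------------------------------------------ scenario checks


def test_shared_wgd_must_precede_speciation():
    with pytest.raises(ConfigurationError, match="WGD"):
        EvolutionScenario(wgd_age=3e6, speciation_age=6e6)


def test_tandem_event_must_postdate_speciation():
    with pytest.raises(ConfigurationError, match="tandem"):
        EvolutionScenario(wgd_age=None, speciation_age=6e6, tandem_events=[
            TandemEvent("A", 8e6, 0)])


def test_omega_and_loss_bounds():
    with pytest.raises(ConfigurationError):
        EvolutionScenario(omega=1.5)
    with pytest.raises(ConfigurationError):
        EvolutionScenario(gene_loss_fraction_post_wgd=1.0)


# ------------------------------------------------------------ genome pair


def test_zero_speciation_age_gives_identical_genomes():
    sc = EvolutionScenario(n_chromosomes=1, genes_per_chromosome=10,
                           wgd_age=None, speciation_age=0.0, seed=1)
    ga, gb, truth = simulate_genome_pair(sc)
    for a_id, b_id, div in truth.ortholog_pairs:
        assert div == 0.0
        assert ga.gene(a_id).cds == gb.gene(b_id).cds


def test_truth_table_divergences_and_completeness():
    sc = EvolutionScenario(n_chromosomes=1, genes_per_chromosome=15,
                           wgd_age=33.46e6, speciation_age=6.15e6, seed=2,
                           tandem_events=[TandemEvent("A", 2e6, 3, copies=1)])
    ga, gb, truth = simulate_genome_pair(sc)
    mu = sc.syn_rate_mu
    for _, _, div in truth.ortholog_pairs:
        assert div == pytest.approx(2 * mu * sc.speciation_age)
    for _, _, _, event, age, div in truth.paralog_pairs:
        assert div == pytest.approx(2 * mu * age)
        assert event in ("wgd", "tandem")
    for g in list(ga.genes) + list(gb.genes):
        assert g.gene_id in truth.gene_history


def test_post_wgd_retained_count_exact():
    n = 30
    for loss in (0.0, 0.25, 0.4):
        sc = EvolutionScenario(n_chromosomes=1, genes_per_chromosome=n,
                               wgd_age=33.46e6, speciation_age=6.15e6,
                               gene_loss_fraction_post_wgd=loss, seed=3)
        ga, _, _ = simulate_genome_pair(sc)
        assert len(ga) == math.ceil((1 - loss) * 2 * n)


def test_simulation_reproducible_byte_identical():
    sc = dict(n_chromosomes=1, genes_per_chromosome=12, wgd_age=20e6,
              speciation_age=5e6, seed=42,
              tandem_events=[TandemEvent("B", 1e6, 2, copies=2)])
    ga1, gb1, t1 = simulate_genome_pair(EvolutionScenario(**sc))
    sc["tandem_events"] = [TandemEvent("B", 1e6, 2, copies=2)]
    ga2, gb2, t2 = simulate_genome_pair(EvolutionScenario(**sc))
    assert ga1.cds_map() == ga2.cds_map() and gb1.cds_map() == gb2.cds_map()
    assert t1.ortholog_pairs == t2.ortholog_pairs
    assert t1.paralog_pairs == t2.paralog_pairs


def test_ortholog_divergence_matches_jc_expectation():
    """Observed synonymous-site difference within 3 binomial SE of JC."""
    sc = EvolutionScenario(n_chromosomes=1, genes_per_chromosome=60,
                           cds_length_codons=(300, 300), wgd_age=None,
                           speciation_age=6.15e6, omega=0.0, seed=6)
    ga, gb, truth = simulate_genome_pair(sc)
    p_expected = jc_p(sc.syn_rate_mu, sc.speciation_age)
    diffs = total = 0
    for a_id, b_id, _ in truth.ortholog_pairs:
        a, b = ga.gene(a_id).cds, gb.gene(b_id).cds
        # omega=0: only synonymous changes happen; count third positions of
        # fourfold-degenerate ancestral codons via the whole-sequence rate
        diffs += sum(x != y for x, y in zip(a, b))
        total += len(a)
    # expected diff count = p * (number of effectively synonymous sites);
    # measure instead through the estimator-facing rate: per-site fraction
    # at synonymous capacity ~ S/3 of sites
    from skullcap.kaks import kaks_pair

    ks = np.array([kaks_pair(ga.gene(a).cds, gb.gene(b).cds).Ks
                   for a, b, _ in truth.ortholog_pairs])
    k_true = 2 * sc.syn_rate_mu * sc.speciation_age
    se = ks.std(ddof=1) / np.sqrt(len(ks))
    assert abs(ks.mean() - k_true) <= max(3 * se, 0.02 * k_true)
    assert diffs / total < p_expected  # nonsynonymous sites are frozen


# ------------------------------------------------------------ LTR elements


def test_ltr_age_zero_identical_repeats():
    for e in simulate_ltr_set(5, 200, 0.0, 1.3e-8, seed=1):
        assert e.ltr5_seq == e.ltr3_seq
        assert e.true_age == 0.0


@pytest.mark.parametrize("age,p_expected", [
    (1.41e6, 0.0358), (0.88e6, 0.0225),
])
def test_ltr_divergence_matches_jc_forward_formula(age, p_expected):
    elements = simulate_ltr_set(300, 2000, age, 1.3e-8, seed=2)
    p_obs = np.mean([sum(a != b for a, b in zip(e.ltr5_seq, e.ltr3_seq)) / 2000
                     for e in elements])
    se = math.sqrt(p_expected * (1 - p_expected) / (300 * 2000))
    assert abs(p_obs - jc_p(1.3e-8, age)) < 3 * se
    assert jc_p(1.3e-8, age) == pytest.approx(p_expected, abs=3e-4)


def test_ltr_argument_validation():
    with pytest.raises(ValueError):
        simulate_ltr_set(0, 2000, 1e6, 1.3e-8, 1)
    with pytest.raises(ValueError):
        simulate_ltr_set(5, 50, 1e6, 1.3e-8, 1)


# ------------------------------------------------------------ Hi-C plaid


def test_plaid_label_rounding():
    cfg = PlaidConfig(n_bins=500, fraction_A=0.532, seed=1)
    _, labels, _, _ = simulate_contact_matrix(cfg)
    assert (labels == "A").sum() == 266


def test_plaid_matrix_symmetric_and_nonnegative():
    cfg = PlaidConfig(n_bins=100, seed=2)
    m, _, _, _ = simulate_contact_matrix(cfg)
    assert np.allclose(m.counts, m.counts.T)
    assert (m.counts >= 0).all()


def test_noiseless_matrix_equals_expected_formula():
    cfg = PlaidConfig(n_bins=50, plaid_strength=0.3, noise=False, seed=3)
    m, labels, _, _ = simulate_contact_matrix(cfg)
    c = np.where(labels == "A", 1.0, -1.0)
    i = np.arange(50)
    dist = np.abs(i[:, None] - i[None, :])
    expected = cfg.noise_scale * (1 + dist) ** -cfg.decay_exponent \
        * (1 + 0.3 * np.outer(c, c))
    assert np.allclose(m.counts, expected)


def test_zero_plaid_strength_has_no_compartment_signal():
    from skullcap.compartments import oe_normalize

    cfg = PlaidConfig(n_bins=120, plaid_strength=0.0, noise_scale=5000.0, seed=4)
    m, _, _, _ = simulate_contact_matrix(cfg)
    oe = oe_normalize(m.counts)
    corr = np.corrcoef(oe)
    off = corr[~np.eye(120, dtype=bool)]
    assert abs(off.mean()) < 0.05


def test_plaid_config_validation():
    with pytest.raises(ValueError):
        PlaidConfig(plaid_strength=1.0)
    with pytest.raises(ValueError):
        PlaidConfig(fraction_A=0.0)
    with pytest.raises(ValueError):
        PlaidConfig(gene_density_A=3.0, gene_density_B=5.0)
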