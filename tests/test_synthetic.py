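"""The generators reproduce the experimental designs and their ground truth."""

import numpy as np
import pandas as pd
import pytest

import psfdilution as psf
from psfdilution import synthetic
from psfdilution.synthetic import fam_key


@pytest.mark.parametrize(
    "n_families,n_per_family,n_species",
    [(3, 6, 18), (1, 2, 2), (2, 3, 6)],
)
def test_species_pool_counts(n_families, n_per_family, n_species):
    pool = psf.make_species_pool(n_families, n_per_family)
    assert len(pool.species) == n_species
    sizes = pd.Series(pool.family).value_counts()
    assert set(sizes) == {n_per_family}
    assert pool.species[0] == "F1_S1"


@pytest.mark.parametrize("bad", [(0, 6), (3, 1), (-1, -1)])
def test_species_pool_invalid(bad):
    with pytest.raises(ValueError):
        psf.make_species_pool(*bad)


def test_pairing_design_counts(pool, pairs):
    assert len(pairs) == 81
    by_combo = {}
    for a, b in pairs:
        by_combo.setdefault(fam_key(pool.family[a], pool.family[b]), []).append((a, b))
    for fam in pool.families:
        assert len(by_combo[fam_key(fam, fam)]) == 9
    for key, grp in by_combo.items():
        fa, fb = key.split("|")
        if fa != fb:
            assert len(grp) == 18
    # each species meets exactly 3 partners per family (including its own)
    partner_fams = {sp: [] for sp in pool.species}
    for a, b in pairs:
        partner_fams[a].append(pool.family[b])
        partner_fams[b].append(pool.family[a])
    for sp, fams in partner_fams.items():
        counts = pd.Series(fams).value_counts()
        assert set(counts) == {3} and len(counts) == 3


def test_pairing_design_small_family_rejected():
    small = psf.make_species_pool(2, 3)
    with pytest.raises(ValueError, match="need >= 4"):
        psf.make_pairing_design(small)


def test_dissimilarity_structure(pool, config, dissims):
    dm = dissims["soil_fungal_pathogen"]
    m = dm.d.to_numpy()
    assert np.allclose(np.diag(m), 0)
    assert np.allclose(m, m.T)
    assert m.min() >= 0 and m.max() <= 1
    again = psf.simulate_dissimilarities(pool, config, "soil_fungal_pathogen")
    pd.testing.assert_frame_equal(dm.d, again.d)


def test_dissimilarity_unknown_group(pool, config):
    with pytest.raises(ValueError, match="unknown"):
        psf.simulate_dissimilarities(pool, config, "mystery_group")


def test_dissimilarity_exact_blocks(pool):
    means = {
        g: {k: (0.3 if k == "F2|F2" else 0.7) for k in
            ["F1|F1", "F2|F2", "F3|F3", "F1|F2", "F1|F3", "F2|F3"]}
        for g in synthetic.ALL_GROUPS
    }
    cfg = psf.SimulationConfig(seed=0, dissimilarity_means=means, dissimilarity_sd=0.0)
    dm = psf.simulate_dissimilarities(pool, cfg, "soil_oomycete")
    legumes = pool.members("F2")
    assert dm.value(legumes[0], legumes[1]) == 0.3
    assert dm.value(legumes[0], pool.members("F1")[0]) == 0.7


def _flat_dissims(pool, value):
    combos = ["F1|F1", "F2|F2", "F3|F3", "F1|F2", "F1|F3", "F2|F3"]
    means = {g: {k: value for k in combos} for g in synthetic.ALL_GROUPS}
    cfg = psf.SimulationConfig(
        seed=0, dissimilarity_means=means, dissimilarity_sd=0.0, psf_noise_sd=0.0
    )
    return psf.simulate_all_dissimilarities(pool, cfg), cfg


def test_true_psf_at_zero_dissimilarity_is_intercept(pool):
    dis, cfg = _flat_dissims(pool, 0.0)
    truth = psf.simulate_true_psf(dis, cfg)
    assert np.allclose(truth["true_psf"], 1.589)


def test_true_psf_at_full_dissimilarity(pool):
    dis, cfg = _flat_dissims(pool, 1.0)
    truth = psf.simulate_true_psf(dis, cfg)
    assert np.allclose(truth["true_psf"], -3.471)


def test_true_psf_requires_pathogen_groups(dissims, config):
    partial = {"soil_fungal_pathogen": dissims["soil_fungal_pathogen"]}
    with pytest.raises(ValueError, match="missing predictor group"):
        psf.simulate_true_psf(partial, config)


def test_true_psf_deterministic(dissims, config, truth):
    again = psf.simulate_true_psf(dissims, config)
    pd.testing.assert_frame_equal(truth, again)


def test_greenhouse_design_counts(pool, pairs, truth, config):
    pots = psf.simulate_greenhouse(pool, pairs, truth, config)
    assert len(pots) == 702
    per_species = pots.groupby("plant").size()
    assert set(per_species) == {39}  # 9 conspecific + 27 heterospecific + 3 sterile
    reps = pots.groupby(["plant", "inoculum"]).size()
    for sp in pool.species:
        assert reps[(sp, sp)] == 9
        assert reps[(sp, "sterile")] == 3


def test_greenhouse_noiseless_cell_means_return_truth(pool, pairs, noiseless_truth,
                                                      noiseless_config):
    pots = psf.simulate_greenhouse(pool, pairs, noiseless_truth, noiseless_config)
    live = pots[pots["inoculum"] != "sterile"]
    logmass = np.log(live["shoot_mass_g"] + live["root_mass_g"])
    cells = logmass.groupby([live["plant"], live["inoculum"]]).mean()
    tm = synthetic.psf_truth_matrix(noiseless_truth, pool.species)
    for a, b in pairs:
        est = cells[(a, a)] + cells[(b, b)] - cells[(a, b)] - cells[(b, a)]
        assert est == pytest.approx(tm.loc[a, b], abs=1e-10)


def test_field_design_counts(pool, config):
    design = psf.make_field_design(pool, config)
    assert len(design) == 240
    assert (design["richness"] >= 2).sum() == 168
    richness_counts = design["richness"].value_counts()
    assert richness_counts[1] == 72 and richness_counts[2] == 72
    assert richness_counts[3] == 48 and richness_counts[6] == 48
    mono = design[design["richness"] == 1]
    per_species = mono["composition"].value_counts()
    assert set(per_species) == {4}
    for _, row in design.iterrows():
        members = row["composition"].split("|")
        fams = {pool.family[s] for s in members}
        assert len(members) == row["richness"]
        if row["dispersion"] == "under" and row["richness"] > 1:
            assert len(fams) == 1
        if row["dispersion"] == "over":
            assert len(fams) > 1


def test_field_design_requires_default_shape(config):
    small = psf.make_species_pool(2, 6)
    with pytest.raises(ValueError, match="3 families"):
        psf.make_field_design(small, config)


def test_field_biomass_null_model(pool, noiseless_truth):
    cfg = psf.SimulationConfig(seed=0, dilution_gain=0.0, biomass_cv=0.0,
                               cover_noise_sd=0.0)
    design = psf.make_field_design(pool, cfg)
    bio = psf.simulate_field_biomass(design, noiseless_truth, cfg)
    ref = psf.MonocultureReference.from_biomass(bio, design)
    for plot_id, grp in bio.groupby("plot_id"):
        if len(grp) < 2:
            continue
        eff = psf.biodiversity_effects(grp.set_index("species")["biomass_g"], ref)
        assert eff["CE"] == pytest.approx(0.0, abs=1e-9)
        assert eff["SE"] == pytest.approx(0.0, abs=1e-9)
        assert eff["RYT"] == pytest.approx(1.0, abs=1e-12)


def test_field_biomass_dilution_creates_complementarity(pool, noiseless_truth):
    cfg = psf.SimulationConfig(seed=0, dilution_gain=1.0, biomass_cv=0.0,
                               cover_noise_sd=0.0)
    design = psf.make_field_design(pool, cfg)
    bio = psf.simulate_field_biomass(design, noiseless_truth, cfg)
    ref = psf.MonocultureReference.from_biomass(bio, design)
    tm = synthetic.psf_truth_matrix(noiseless_truth, pool.species)
    scores = synthetic.plot_dilution_scores(design, tm).set_index("plot_id")
    checked = 0
    for plot_id, grp in bio.groupby("plot_id"):
        if len(grp) < 2 or scores.loc[plot_id, "predicted_psf"] >= 0:
            continue
        eff = psf.biodiversity_effects(grp.set_index("species")["biomass_g"], ref)
        assert eff["CE"] > 0
        checked += 1
    assert checked > 50


def test_field_biomass_deterministic(pool, truth, config):
    design = psf.make_field_design(pool, config)
    a = psf.simulate_field_biomass(design, truth, config)
    b = psf.simulate_field_biomass(design, truth, config)
    pd.testing.assert_frame_equal(a, b)


def test_asv_tables_deterministic_and_in_depth_range(pool, config):
    t1 = psf.simulate_asv_tables(pool, config, "soil_fungal_pathogen")
    t2 = psf.simulate_asv_tables(pool, config, "soil_fungal_pathogen")
    pd.testing.assert_frame_equal(t1.counts, t2.counts)
    lo, hi = config.read_depth_range
    assert t1.totals.between(lo, hi).all()
    assert t1.samples.groupby("species").size().eq(2).all()


def test_asv_overlap_extremes():
    pool = psf.make_species_pool(1, 6)
    for overlap, expected in [(1.0, 0.0), (0.0, 1.0)]:
        cfg = psf.SimulationConfig(
            seed=0, n_families=1, asv_count_noise=False,
            read_depth_range=(2000, 2000),
            asv_overlap={"soil_fungal_pathogen": {"F1|F1": overlap}},
        )
        table = psf.simulate_asv_tables(pool, cfg, "soil_fungal_pathogen")
        dm = psf.species_pair_dissimilarity(psf.rarefy(table, "min", seed=0))
        off = dm.d.to_numpy()[np.triu_indices(len(dm.species), 1)]
        assert np.allclose(off, expected, atol=0.02)


def test_asv_overlap_monotonicity():
    pool = psf.make_species_pool(1, 6)
    means = []
    for overlap in (0.2, 0.5, 0.8):
        cfg = psf.SimulationConfig(
            seed=7, n_families=1,
            asv_overlap={"soil_fungal_pathogen": {"F1|F1": overlap}},
        )
        table = psf.simulate_asv_tables(pool, cfg, "soil_fungal_pathogen")
        dm = psf.species_pair_dissimilarity(psf.rarefy(table, "min", seed=0))
        means.append(dm.d.to_numpy()[np.triu_indices(6, 1)].mean())
    assert means[0] > means[1] > means[2]
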