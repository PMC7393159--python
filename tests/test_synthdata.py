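"""Generator tests: contour model, study design, haplotype simulator."""

import numpy as np
import pytest

from otomorph.efd import compute_efd, normalize_efd
from otomorph.popgen import amova_phi_st, pairwise_distance_matrix
from otomorph.synthdata import (
    ContourParams,
    HaplotypeSimConfig,
    StudyDesignConfig,
    calibrate_divergence,
    generate_contour,
    generate_otolith_dataset,
    simulate_haplotype_populations,
)


def _phi(pops) -> float:
    seqs, labels = [], []
    for pop, aln in pops.items():
        seqs.extend(aln.sequences)
        labels.extend([pop] * len(aln))
    return amova_phi_st(pairwise_distance_matrix(seqs), labels).phi_st


# ---------------------------------------------------------------------------
# contour model
# ---------------------------------------------------------------------------


def test_contour_closed_forms():
    c = generate_contour(ContourParams(s=1.0, h=1.0, d=0.0, K=256))
    r = np.hypot(c.points[:, 0], c.points[:, 1])
    assert np.abs(r - 1.0).max() < 1e-12

    c = generate_contour(ContourParams(s=2.0, h=0.5, d=0.0, K=256))
    e = compute_efd(c, 1, parametrization="uniform")
    assert e.coeffs[0, 0] == pytest.approx(2.0, abs=1e-3)
    assert e.coeffs[0, 3] == pytest.approx(1.0, abs=1e-3)

    # notch: minimum radius within w of t0, equal to s * (1 - d) there
    t = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    c = generate_contour(ContourParams(s=1.0, h=1.0, d=0.3, t0=np.pi, w=0.3, K=4096))
    r = np.hypot(c.points[:, 0], c.points[:, 1])
    tmin = t[np.argmin(r)]
    assert abs(tmin - np.pi) < 0.3
    assert r.min() == pytest.approx(0.7, rel=0.01)
    assert c.signed_area() > 0  # counterclockwise


def test_contour_param_validation():
    with pytest.raises(ValueError, match="notch depth"):
        ContourParams(s=1.0, d=1.0)
    with pytest.raises(ValueError, match="K"):
        ContourParams(s=1.0, K=16)
    with pytest.raises(ValueError, match="> 0"):
        ContourParams(s=-1.0)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


def test_dataset_determinism_and_shape():
    cfg = StudyDesignConfig(fish_per_cell=2, seed=11)
    c1, m1, t1 = generate_otolith_dataset(cfg)
    c2, m2, t2 = generate_otolith_dataset(cfg)
    assert m1.equals(m2)
    assert t1["otolith_truth"].equals(t2["otolith_truth"])
    assert all(np.array_equal(a.points, b.points) for a, b in zip(c1, c2))
    assert len(m1) == 4 * 3 * 2 * 2 * 2
    # both otoliths of a fish share covariates and the fish-level h draw
    truth = t1["otolith_truth"]
    per_fish = truth.groupby("fish_id")[["u_fish_h", "z_size"]].nunique()
    assert (per_fish == 1).all().all()
    assert set(m1["side"]) == {"left", "right"}


def test_zero_variation_gives_identical_shapes():
    cfg = StudyDesignConfig(
        fish_per_cell=2,
        beta_size_h=0.0,
        beta_size_d=0.0,
        site_effects_h={},
        sex_site_effects_h={},
        fish_sd=0.0,
        residual_sd=0.0,
        seed=5,
    )
    contours, meta, _ = generate_otolith_dataset(cfg)
    # identical up to size scaling (and mirroring): normalized EFDs all equal
    efds = []
    for c in contours[:10]:
        if c.side == "right":
            from otomorph.efd import mirror_contour

            c = mirror_contour(c)
        efds.append(normalize_efd(compute_efd(c, 6)).coeffs)
    for e in efds[1:]:
        assert np.abs(e - efds[0]).max() < 1e-9


def test_planted_site_effect_appears_in_truth():
    cfg = StudyDesignConfig(
        fish_per_cell=40,
        site_effects_h={"Mutondwe": 0.0, "Kalambo": 0.05, "Katukula": 0.0},
        sex_site_effects_h={},
        seed=3,
    )
    _, _, truth = generate_otolith_dataset(cfg)
    t = truth["otolith_truth"]
    means = t.groupby("site")["h_true"].mean()
    mc_err = 3.0 * t["h_true"].std() / np.sqrt(len(t) / 3)
    assert means["Kalambo"] - means["Mutondwe"] == pytest.approx(0.05, abs=mc_err)
    assert means["Kalambo"] - means["Katukula"] == pytest.approx(0.05, abs=mc_err)


def test_zero_fish_per_cell_rejected():
    with pytest.raises(ValueError, match="fish_per_cell"):
        StudyDesignConfig(fish_per_cell=0)


# ---------------------------------------------------------------------------
# haplotype simulator
# ---------------------------------------------------------------------------


def test_panmixia_gives_near_zero_phi_st():
    vals = [
        _phi(
            simulate_haplotype_populations(
                HaplotypeSimConfig(populations=("A", "B"), n_per_pop=(30, 30), m=1.0, seed=s)
            )
        )
        for s in range(20)
    ]
    assert -0.05 < np.mean(vals) < 0.05


def test_full_isolation_without_mutation_gives_phi_one():
    cfg = HaplotypeSimConfig(
        populations=("A", "B"),
        n_per_pop=(30, 30),
        m=0.0,
        n_private_sites=10,
        within_cluster_mut_mean=0.0,
        shared_pool_mut_mean=0.0,
        seed=2,
    )
    assert _phi(simulate_haplotype_populations(cfg)) == pytest.approx(1.0)


def test_phi_st_monotone_in_isolation():
    for seed in range(5):
        phis = [
            _phi(
                simulate_haplotype_populations(
                    HaplotypeSimConfig(
                        populations=("A", "B"), n_per_pop=(28, 28), m=m, seed=seed
                    )
                )
            )
            for m in (0.0, 0.5, 1.0)
        ]
        assert phis[0] > phis[1] > phis[2]


def test_sequences_are_valid_and_deterministic():
    cfg = HaplotypeSimConfig(seed=9)
    pops1 = simulate_haplotype_populations(cfg)
    pops2 = simulate_haplotype_populations(cfg)
    for pop in pops1:
        assert pops1[pop].sequences == pops2[pop].sequences
        assert all(set(s) <= set("ACGT") for s in pops1[pop].sequences)
        assert 24 <= len(pops1[pop]) <= 33


def test_haplotype_config_validation():
    with pytest.raises(ValueError, match="populations"):
        HaplotypeSimConfig(populations=("only",))
    with pytest.raises(ValueError, match="L"):
        HaplotypeSimConfig(L=10)
    with pytest.raises(ValueError, match=">= 2 samples"):
        HaplotypeSimConfig(populations=("A", "B"), n_per_pop=(1, 30))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def test_calibration_to_midrange_target():
    cfg = HaplotypeSimConfig(populations=("A", "B"), seed=11)
    tuned = calibrate_divergence(0.5, cfg, n_seeds=3)
    realized = np.mean(
        [
            _phi(simulate_haplotype_populations(
                HaplotypeSimConfig(populations=("A", "B"), m=tuned.m, seed=100 + s)
            ))
            for s in range(6)
        ]
    )
    assert 0.40 <= realized <= 0.60


def test_calibration_to_zero_returns_high_admixture():
    tuned = calibrate_divergence(0.0, HaplotypeSimConfig(populations=("A", "B"), seed=4), n_seeds=3)
    assert tuned.m > 0.8


def test_calibration_unreachable_target_reports_closest():
    # a nearly undifferentiated simulator cannot reach strong divergence
    cfg = HaplotypeSimConfig(
        populations=("A", "B"),
        n_private_sites=1,
        within_cluster_mut_mean=4.0,
        shared_pool_mut_mean=4.0,
        seed=6,
    )
    with pytest.raises(ValueError, match="closest"):
        calibrate_divergence(0.85, cfg, n_seeds=3)
    with pytest.raises(ValueError, match="target_phi"):
        calibrate_divergence(0.95, cfg)
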