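"""Shared test utilities: an in-memory analysis chain and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from otomorph.efd import (
    compute_efd,
    mirror_contour,
    normalize_efd,
    power_spectrum,
    resample_contour,
    select_harmonics,
)
from otomorph.shapepca import coefficient_matrix, fit_shape_pca
from otomorph.shapestats import assemble_records
from otomorph.synthdata import StudyDesignConfig, generate_otolith_dataset


def run_shape_chain(
    config: StudyDesignConfig,
    max_harmonics: int = 12,
    resample: int = 256,
    threshold: float = 0.99999,
):
    """contours -> mirror -> resample -> EFD -> per-species PCA -> records.

    Returns (records, truth, pcas): the per-otolith analysis table joined to
    metadata, the generator ground truth, and the per-species ShapePCA fits.
    """
    contours, metadata, truth = generate_otolith_dataset(config)
    by_species: dict[str, list] = {}
    for c in contours:
        if c.side == "right":
            c = mirror_contour(c)
        c = resample_contour(c, resample)
        e = normalize_efd(compute_efd(c, max_harmonics))
        by_species.setdefault(c.metadata["species"], []).append(e)

    pcas = {}
    score_frames = []
    for species, efds in sorted(by_species.items()):
        mat = coefficient_matrix(efds)
        from otomorph.efd import EFDCoefficients

        mean_shape = EFDCoefficients(
            coeffs=mat.to_numpy().mean(axis=0).reshape(-1, 4), normalized=False
        )
        n_sel = select_harmonics(power_spectrum(mean_shape), threshold)
        truncated = [
            EFDCoefficients(
                coeffs=e.coeffs[:n_sel].copy(),
                normalized=True,
                specimen_id=e.specimen_id,
            )
            for e in efds
        ]
        pca = fit_shape_pca(coefficient_matrix(truncated))
        pcas[species] = pca
        score_frames.append(pca.scores)
    scores = pd.concat(score_frames)
    records = assemble_records(scores, metadata)
    return records, truth, pcas


def lmm_records(
    seed: int,
    fish_per_cell: int = 15,
    species=("caudopunctatus", "pulcher", "savoryi", "moorii"),
    sites=("Mutondwe", "Kalambo", "Katukula"),
    sexes=("F", "M"),
    site_effects: dict | None = None,
    sex_site_effects: dict | None = None,
    beta_size: float = 0.010,
    site_beta_size: dict | None = None,
    fish_sd: float = float(np.sqrt(4.227e-4)),
    resid_sd: float = float(np.sqrt(8.038e-5)),
) -> pd.DataFrame:
    """Per-otolith analysis records drawn directly from the mixed-model
    structure (PC scores instead of contours), for statistics-level tests.

    PC1 carries the planted size, site, sex-by-site and fish effects; PC2 is
    an independent axis with the same variance components.  area_um2 is
    linear in the latent standardized size so area_z equals it exactly.
    """
    rng = np.random.default_rng(seed)
    site_effects = site_effects or {}
    sex_site_effects = sex_site_effects or {}
    site_beta_size = site_beta_size or {}
    rows = []
    for sp in species:
        for site in sites:
            for sex in sexes:
                for i in range(fish_per_cell):
                    fish_id = f"{sp}_{site}_{sex}_{i:03d}"
                    z = rng.standard_normal()
                    u1 = rng.standard_normal() * fish_sd
                    u2 = rng.standard_normal() * fish_sd
                    mu1 = (
                        (beta_size + site_beta_size.get(site, 0.0)) * z
                        + site_effects.get(site, 0.0)
                        + (sex_site_effects.get(site, 0.0) if sex == "F" else 0.0)
                        + u1
                    )
                    mu2 = 0.005 * z + u2
                    for j, side in enumerate(("left", "right")):
                        rows.append(
                            {
                                "specimen_id": f"{fish_id}_{side[0].upper()}",
                                "fish_id": fish_id,
                                "species": sp,
                                "site": site,
                                "sex": sex,
                                "side": side,
                                "area_um2": 1e6 * (1.0 + 0.15 * z),
                                "PC1": mu1 + rng.standard_normal() * resid_sd,
                                "PC2": mu2 + rng.standard_normal() * resid_sd,
                            }
                        )
    from otomorph.shapestats import standardize_area

    return standardize_area(pd.DataFrame(rows))


def amova_oracle(distmat: np.ndarray, labels: list) -> tuple[float, float, float]:
    """Textbook two-level AMOVA written with explicit loops.

    Returns (sigma2_among, sigma2_within, phi_st) from the standard
    sums-of-squared-distances identities with the unequal-sample-size
    coefficient n'.
    """
    d = np.asarray(distmat, dtype=float)
    n = d.shape[0]
    pops = []
    for lab in labels:
        if lab not in pops:
            pops.append(lab)
    ss_total = 0.0
    for i in range(n):
        for j in range(n):
            ss_total += d[i, j] ** 2
    ss_total /= 2.0 * n
    ss_within = 0.0
    sizes = []
    for pop in pops:
        idx = [i for i, lab in enumerate(labels) if lab == pop]
        sizes.append(len(idx))
        s = 0.0
        for i in idx:
            for j in idx:
                s += d[i, j] ** 2
        ss_within += s / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    P = len(pops)
    ms_among = ss_among / (P - 1)
    ms_within = ss_within / (n - P)
    n_prime = (n - sum(s**2 for s in sizes) / n) / (P - 1)
    sigma2_b = ms_within
    sigma2_a = (ms_among - ms_within) / n_prime
    return sigma2_a, sigma2_b, sigma2_a / (sigma2_a + sigma2_b)


def random_sequences(rng: np.random.Generator, n: int, L: int, mut_mean: float = 2.0):
    """Haplotype sample from one panmictic pool (ancestral + Poisson mutations)."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    anc = rng.integers(0, 4, size=L)
    seqs = []
    for _ in range(n):
        s = anc.copy()
        k = rng.poisson(mut_mean)
        if k:
            pos = rng.integers(0, L, size=k)
            s[pos] = (s[pos] + rng.integers(1, 4, size=k)) % 4
        seqs.append(bases[s].tobytes().decode())
    return seqs


def square_contour(K_per_side: int = 100):
    """Unit square traversed counterclockwise, K_per_side points per side."""
    from otomorph.efd import Contour

    t = np.linspace(0.0, 1.0, K_per_side, endpoint=False)
    bottom = np.column_stack([t, np.zeros_like(t)])
    right = np.column_stack([np.ones_like(t), t])
    top = np.column_stack([1.0 - t, np.ones_like(t)])
    left = np.column_stack([np.zeros_like(t), 1.0 - t])
    return Contour(points=np.vstack([bottom, right, top, left]))
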