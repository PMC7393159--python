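"""Synthetic otolith contours and haplotype samples with known ground truth.

Two generators back the test surface of the whole pipeline:

* an otolith-outline generator producing ellipse-plus-notch contours whose
  two free shape parameters — relative height ``h`` and anterior-notch depth
  ``d`` — map one-to-one onto the two dominant axes of real saccular-otolith
  shape variation (height along the dorsoventral axis; prominence of the
  anterior notch), embedded in a crossed species x site x sex sampling
  design with fish-level random effects, allometric size effects and
  plantable site / site-specific sex effects;
* a cluster-admixture haplotype simulator whose single mixing parameter
  ``m`` tunes realized pairwise Phi_ST continuously between panmixia
  (m = 1) and strong differentiation (m = 0).

Every planted coefficient and every latent draw is returned in a
ground-truth record so that downstream estimates can be checked against
what was actually simulated.

Seeding: one master seed; independent per-stage streams are derived with
fixed ``numpy.random.SeedSequence`` spawn keys (0 = otolith dataset,
1 = haplotypes, 2 = calibration).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .efd import Contour
from .popgen import HaplotypeAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "ContourParams",
    "StudyDesignConfig",
    "HaplotypeSimConfig",
    "generate_contour",
    "generate_otolith_dataset",
    "simulate_haplotype_populations",
    "calibrate_divergence",
]

_SPECIES = ("caudopunctatus", "pulcher", "savoryi", "moorii")
_SITES = ("Mutondwe", "Kalambo", "Katukula")

# Default variance components for the fish random intercept and the
# within-fish residual, on the shape-axis scale (variances 4.227e-4 and
# 8.038e-5 — the within-fish correlation structure typical of paired
# otolith measurements).
_FISH_SD = float(np.sqrt(4.227e-4))
_RESIDUAL_SD = float(np.sqrt(8.038e-5))


@dataclass
class ContourParams:
    """Parameters of the ellipse-plus-Gaussian-notch outline model.

    The outline is x(t) = s cos(t) m(t), y(t) = s h sin(t) m(t) for
    t in [0, 2 pi), with radial notch factor
    m(t) = 1 - d exp(-wrap(t - t0)^2 / (2 w^2)).

    s      otolith size (µm, > 0): semi-axis along x.
    h      height multiplier (> 0): dorsoventral / anteroposterior ratio.
    d      notch depth in [0, 1): fraction of radius removed at the notch.
    t0     notch angular position (radians).
    w      notch angular width (radians, > 0).
    K      number of sample points (>= 32), equally spaced in t.

    d < 1 keeps the radial factor positive, so the curve is simple.
    """

    s: float
    h: float = 1.0
    d: float = 0.0
    t0: float = np.pi
    w: float = 0.35
    K: int = 256

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("size s must be > 0")
        if self.h <= 0:
            raise ValueError("height multiplier h must be > 0")
        if not (0.0 <= self.d < 1.0):
            raise ValueError("notch depth d must satisfy 0 <= d < 1")
        if self.w <= 0:
            raise ValueError("notch width w must be > 0")
        if self.K < 32:
            raise ValueError("K must be >= 32")


def generate_contour(params: ContourParams, specimen_id: str = "",
                     metadata: dict | None = None) -> Contour:
    """Evaluate the outline model on K equally spaced parameter values.

    The curve is closed and counterclockwise by construction.
    """
    t = np.linspace(0.0, 2.0 * np.pi, params.K, endpoint=False)
    delta = np.arctan2(np.sin(t - params.t0), np.cos(t - params.t0))
    m = 1.0 - params.d * np.exp(-(delta**2) / (2.0 * params.w**2))
    x = params.s * np.cos(t) * m
    y = params.s * params.h * np.sin(t) * m
    return Contour(
        points=np.column_stack([x, y]),
        specimen_id=specimen_id,
        side="left",
        metadata=metadata or {},
    )


def _mirror_points(points: np.ndarray) -> np.ndarray:
    """Reflect about the vertical centroid axis, preserving orientation."""
    cx = points[:, 0].mean()
    pts = points.copy()
    pts[:, 0] = 2.0 * cx - pts[:, 0]
    return np.roll(pts[::-1], 1, axis=0)


@dataclass
class StudyDesignConfig:
    """Crossed species x site x sex design with paired otoliths per fish.

    Shape effects act additively on the height axis ``h`` and the notch
    axis ``d``:

        h_otolith = base_height + beta_size_h * z + site_effect_h[site]
                    + 1[female] * sex_site_effect_h[site] + u_fish + eps

    where z is the fish's latent standardized size, u_fish ~ N(0, fish_sd^2)
    is shared by both otoliths of a fish and eps ~ N(0, residual_sd^2) is
    otolith-specific.  The notch axis gets the analogous linear predictor
    (with independent fish and residual draws of the same SDs).
    """

    species: Sequence[str] = _SPECIES
    sites: Sequence[str] = _SITES
    sexes: Sequence[str] = ("F", "M")
    fish_per_cell: int = 25
    otoliths_per_fish: int = 2
    base_height: float = 0.75
    base_notch: float = 0.12
    beta_size_h: float = 0.010
    beta_size_d: float = 0.005
    site_beta_size_h: dict = field(default_factory=dict)  # site-specific extra slope
    site_effects_h: dict = field(
        default_factory=lambda: {"Mutondwe": 0.0, "Kalambo": 0.04, "Katukula": 0.02}
    )
    site_effects_d: dict = field(default_factory=dict)
    sex_site_effects_h: dict = field(
        default_factory=lambda: {"Mutondwe": 0.03, "Kalambo": 0.0, "Katukula": 0.0}
    )
    fish_sd: float = _FISH_SD
    residual_sd: float = _RESIDUAL_SD
    base_size_um: float = 900.0
    size_log_sd: float = 0.15
    notch_t0: float = np.pi
    notch_w: float = 0.35
    points_per_contour: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fish_per_cell < 1:
            raise ValueError("fish_per_cell must be >= 1")
        if self.otoliths_per_fish < 1:
            raise ValueError("otoliths_per_fish must be >= 1")
        for name in ("fish_sd", "residual_sd", "size_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.species) < 1 or len(self.sites) < 2:
            raise ValueError("need >= 1 species and >= 2 sites")


def generate_otolith_dataset(
    config: StudyDesignConfig,
) -> tuple[list[Contour], pd.DataFrame, dict]:
    """Generate the full design and its ground truth, deterministically.

    Returns ``(contours, metadata, truth)`` where ``metadata`` has one row
    per otolith (specimen_id, fish_id, species, site, sex, side, area_um2)
    and ``truth`` records the planted coefficients plus per-otolith latent
    values (standardized size z, fish intercepts, realized h and d).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    sides = ("left", "right")
    contours: list[Contour] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []

    for species in config.species:
        for site in config.sites:
            for sex in config.sexes:
                for i in range(config.fish_per_cell):
                    fish_id = f"{species}_{site}_{sex}_{i:03d}"
                    z = rng.standard_normal()
                    size = config.base_size_um * np.exp(config.size_log_sd * z)
                    u_h = rng.standard_normal() * config.fish_sd
                    u_d = rng.standard_normal() * config.fish_sd
                    h_fish = (
                        config.base_height
                        + (config.beta_size_h + config.site_beta_size_h.get(site, 0.0)) * z
                        + config.site_effects_h.get(site, 0.0)
                        + (config.sex_site_effects_h.get(site, 0.0) if sex == "F" else 0.0)
                        + u_h
                    )
                    d_fish = (
                        config.base_notch
                        + config.beta_size_d * z
                        + config.site_effects_d.get(site, 0.0)
                        + u_d
                    )
                    for j in range(config.otoliths_per_fish):
                        h = h_fish + rng.standard_normal() * config.residual_sd
                        d = d_fish + rng.standard_normal() * config.residual_sd
                        d = float(np.clip(d, 0.0, 0.95))
                        side = sides[j % 2]
                        specimen_id = f"{fish_id}_{side[0].upper()}"
                        params = ContourParams(
                            s=size,
                            h=max(h, 1e-3),
                            d=d,
                            t0=config.notch_t0,
                            w=config.notch_w,
                            K=config.points_per_contour,
                        )
                        contour = generate_contour(params, specimen_id=specimen_id)
                        if side == "right":
                            contour = replace(
                                contour,
                                points=_mirror_points(contour.points),
                                side="right",
                            )
                        area = abs(contour.signed_area())
                        meta = {
                            "specimen_id": specimen_id,
                            "fish_id": fish_id,
                            "species": species,
                            "site": site,
                            "sex": sex,
                            "side": side,
                            "area_um2": area,
                        }
                        contour.metadata.update(meta)
                        contours.append(contour)
                        meta_rows.append(meta)
                        truth_rows.append(
                            {
                                "specimen_id": specimen_id,
                                "fish_id": fish_id,
                                "species": species,
                                "site": site,
                                "sex": sex,
                                "z_size": z,
                                "u_fish_h": u_h,
                                "u_fish_d": u_d,
                                "h_true": h,
                                "d_true": d,
                            }
                        )

    metadata = pd.DataFrame(meta_rows)
    truth = {
        "config": _jsonable_config(config),
        "otolith_truth": pd.DataFrame(truth_rows),
    }
    logger.info(
        "generated %d contours (%d fish) for %d species x %d sites x %d sexes",
        len(contours),
        len(contours) // config.otoliths_per_fish,
        len(config.species),
        len(config.sites),
        len(config.sexes),
    )
    return contours, metadata, truth


def _jsonable_config(config) -> dict:
    out = {}
    for k, v in asdict(config).items():
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


# ---------------------------------------------------------------------------
# Haplotype simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class HaplotypeSimConfig:
    """Cluster-admixture model for mitochondrial haplotype samples.

    Each population owns a private haplotype cluster: an ancestral sequence
    carrying ``n_private_sites`` population-specific fixed substitutions.
    An individual draws from the shared ancestral pool with probability
    ``m`` and from its private cluster with probability 1 - m, then
    accumulates a Poisson number of individual mutations.  m = 1 gives
    panmixia (Phi_ST ~ 0); m = 0 with mutation-free clusters gives
    Phi_ST = 1.
    """

    L: int = 400
    populations: Sequence[str] = _SITES
    n_per_pop: Sequence[int] | None = None
    n_range: tuple[int, int] = (24, 33)
    n_private_sites: int = 8
    within_cluster_mut_mean: float = 1.5
    shared_pool_mut_mean: float = 1.5
    m: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 50:
            raise ValueError("sequence length L must be >= 50")
        if len(self.populations) < 2:
            raise ValueError("need >= 2 populations")
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("admixture parameter m must lie in [0, 1]")
        if self.n_per_pop is not None:
            if len(self.n_per_pop) != len(self.populations):
                raise ValueError("n_per_pop length must match populations")
            if any(n < 2 for n in self.n_per_pop):
                raise ValueError("each population needs >= 2 samples")
        if self.n_private_sites * len(self.populations) > self.L:
            raise ValueError("too many private sites for sequence length")


def simulate_haplotype_populations(
    config: HaplotypeSimConfig,
) -> dict[str, HaplotypeAlignment]:
    """Simulate per-population aligned haplotype samples (A/C/G/T only)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    P = len(config.populations)
    ancestral = rng.integers(0, 4, size=config.L)

    all_sites = rng.permutation(config.L)
    private_sites = [
        all_sites[p * config.n_private_sites : (p + 1) * config.n_private_sites]
        for p in range(P)
    ]
    cores = []
    for p in range(P):
        core = ancestral.copy()
        core[private_sites[p]] = (core[private_sites[p]] + rng.integers(1, 4, size=config.n_private_sites)) % 4
        cores.append(core)

    if config.n_per_pop is not None:
        sizes = list(config.n_per_pop)
    else:
        lo, hi = config.n_range
        sizes = rng.integers(lo, hi + 1, size=P).tolist()

    out: dict[str, HaplotypeAlignment] = {}
    for p, pop in enumerate(config.populations):
        seqs = []
        ids = []
        for i in range(sizes[p]):
            if rng.random() < config.m:
                seq = ancestral.copy()
                n_mut = rng.poisson(config.shared_pool_mut_mean)
            else:
                seq = cores[p].copy()
                n_mut = rng.poisson(config.within_cluster_mut_mean)
            if n_mut > 0:
                pos = rng.integers(0, config.L, size=n_mut)
                seq[pos] = (seq[pos] + rng.integers(1, 4, size=n_mut)) % 4
            seqs.append(_BASES[seq].tobytes().decode("ascii"))
            ids.append(f"{pop}_{i:03d}")
        out[pop] = HaplotypeAlignment(population=pop, ids=ids, sequences=seqs)
    return out


def calibrate_divergence(
    target_phi: float,
    config: HaplotypeSimConfig,
    n_seeds: int = 5,
    tol: float = 0.05,
    max_iter: int = 25,
) -> HaplotypeSimConfig:
    """Tune the admixture parameter m by bisection to a target mean Phi_ST.

    The realized Phi_ST (averaged over ``n_seeds`` seeds derived from the
    config seed) decreases monotonically in m, so bisection on m converges.
    If the target exceeds what the simulator can reach (e.g. ~1 with
    within-cluster mutation on), an error reports the closest achieved
    value.
    """
    if not (0.0 <= target_phi <= 0.9):
        raise ValueError("target_phi must lie in [0, 0.9]")
    from .popgen import amova_phi_st, pairwise_distance_matrix

    base = np.random.SeedSequence(config.seed, spawn_key=(2,))
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in base.spawn(n_seeds)]

    def realized(m: float) -> float:
        vals = []
        for s in seeds:
            sim = replace(config, m=m, seed=s)
            pops = simulate_haplotype_populations(sim)
            seqs, labels = [], []
            for pop, aln in pops.items():
                seqs.extend(aln.sequences)
                labels.extend([pop] * len(aln.sequences))
            dist = pairwise_distance_matrix(seqs)
            try:
                vals.append(amova_phi_st(dist, labels).phi_st)
            except ValueError:
                vals.append(0.0)  # no molecular variance: treat as undifferentiated
        return float(np.mean(vals))

    lo, hi = 0.0, 1.0
    phi_lo = realized(lo)  # maximal differentiation
    phi_hi = realized(hi)  # panmixia
    best_m, best_phi = (lo, phi_lo) if abs(phi_lo - target_phi) < abs(phi_hi - target_phi) else (hi, phi_hi)
    if target_phi > phi_lo + tol:
        raise ValueError(
            f"target Phi_ST {target_phi:.3f} unreachable: closest achieved "
            f"{phi_lo:.3f} at m=0"
        )
    for _ in range(max_iter):
        if abs(best_phi - target_phi) <= tol:
            break
        mid = 0.5 * (lo + hi)
        phi_mid = realized(mid)
        if abs(phi_mid - target_phi) < abs(best_phi - target_phi):
            best_m, best_phi = mid, phi_mid
        if phi_mid > target_phi:
            lo = mid  # too differentiated: raise m
        else:
            hi = mid
    if abs(best_phi - target_phi) > tol:
        raise ValueError(
            f"calibration failed after {max_iter} iterations: closest "
            f"Phi_ST {best_phi:.3f} at m={best_m:.4f} (target {target_phi:.3f})"
        )
    logger.info(
        "calibrated m=%.4f for target Phi_ST %.3f (realized %.3f over %d seeds)",
        best_m, target_phi, best_phi, n_seeds,
    )
    return replace(config, m=best_m)
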