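"""Mixed-model tests on otolith-shape PC scores.

Two analyses, both with a fish-level random intercept because each fish
contributes two otoliths:

* per-(species, site, PC) sex-difference tests — PC ~ scaled area + sex,
  with the area x sex interaction kept only when significant — under a
  Bonferroni-corrected alpha for the full planned grid (24 tests for the
  default 2 PCs x 4 species x 3 sites, i.e. alpha = 0.002);
* cross-site marginal-mean contrasts per sex — PC ~ scaled area +
  species x site — with all within-species site pairs compared at the
  covariate mean (standardized area = 0) and Tukey multiplicity adjustment
  over the pairs of each species.

Otolith surface area is standardized (z-scored) within species before
modelling, so species of different absolute size share one allometry scale.
The reported sex effect is the female - male marginal difference at
standardized area 0, stated explicitly to avoid contrast-coding ambiguity.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import patsy

from .lmm import LmmFit, fit_lmm, tukey_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "standardize_area",
    "assemble_records",
    "fit_lmm",
    "sex_difference_tests",
    "site_contrasts",
]

_INTERACTION_ALPHA = 0.05  # drop the area x sex interaction at p >= this


def standardize_area(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``area_z``: otolith surface area z-scored within species."""
    if "area_um2" not in records:
        raise ValueError("records need an 'area_um2' column")
    out = records.copy()
    grp = out.groupby("species")["area_um2"]
    out["area_z"] = (out["area_um2"] - grp.transform("mean")) / grp.transform(
        "std", ddof=1
    )
    return out


def assemble_records(scores: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join per-otolith PC scores to specimen metadata and standardize area.

    ``scores`` is indexed by specimen_id with PC1..PCn columns (per-species
    PCAs are concatenated upstream); ``metadata`` carries fish_id, species,
    site, sex, side and area_um2.
    """
    merged = metadata.merge(
        scores.reset_index(), on="specimen_id", how="inner", validate="one_to_one"
    )
    if merged.empty:
        raise ValueError("no overlap between scores and metadata specimen ids")
    return standardize_area(merged)


def _marginal_mean_row(design_info, setting: dict) -> np.ndarray:
    """Model-matrix row for one covariate setting (marginal-mean L vector)."""
    frame = pd.DataFrame([setting])
    (mat,) = patsy.build_design_matrices([design_info], frame)
    return np.asarray(mat)[0]


def _sex_effect(fit: LmmFit, setting_base: dict) -> dict:
    """Female - male marginal difference at standardized area 0."""
    row_f = _marginal_mean_row(fit.design_info, {**setting_base, "sex": "F"})
    row_m = _marginal_mean_row(fit.design_info, {**setting_base, "sex": "M"})
    return fit.contrast(row_f - row_m)


def sex_difference_tests(
    dataset: pd.DataFrame,
    pcs: tuple[str, ...] = ("PC1", "PC2"),
) -> tuple[pd.DataFrame, float]:
    """One sex test per (species, site, PC) cell of the planned grid.

    Each test fits PC ~ area_z * sex with a fish random intercept, drops the
    interaction when its Wald p >= 0.05 (logged), and reports the
    female - male marginal difference at area_z = 0.  The per-test alpha is
    0.05 divided by the number of planned tests (0.002 for the default
    grid); cells missing a sex are marked untestable and do not shrink the
    family.  Returns (records, alpha).
    """
    species_levels = sorted(dataset["species"].unique())
    site_levels = sorted(dataset["site"].unique())
    n_tests = len(species_levels) * len(site_levels) * len(pcs)
    alpha = 0.05 / n_tests
    rows = []
    for species, site, pc in itertools.product(species_levels, site_levels, pcs):
        cell = dataset[(dataset["species"] == species) & (dataset["site"] == site)]
        row = {"species": species, "site": site, "pc": pc}
        if cell["sex"].nunique() < 2 or pc not in cell:
            rows.append(
                {**row, "testable": False, "estimate": np.nan, "se": np.nan,
                 "t": np.nan, "df": np.nan, "p": np.nan,
                 "interaction_kept": False, "significant": False}
            )
            logger.warning("cell %s/%s/%s untestable (missing a sex)", species, site, pc)
            continue
        full = fit_lmm(cell, f"{pc} ~ area_z * sex", "fish_id")
        inter_p = float(full.pvalues.loc["area_z:sex[T.M]"])
        if inter_p < _INTERACTION_ALPHA:
            fit, kept = full, True
        else:
            fit, kept = fit_lmm(cell, f"{pc} ~ area_z + sex", "fish_id"), False
            logger.info(
                "cell %s/%s/%s: area x sex interaction dropped (p=%.3f)",
                species, site, pc, inter_p,
            )
        eff = _sex_effect(fit, {"area_z": 0.0})
        rows.append(
            {**row, "testable": True, "estimate": eff["estimate"], "se": eff["se"],
             "t": eff["t"], "df": eff["df"], "p": eff["p"],
             "interaction_kept": kept, "significant": eff["p"] < alpha}
        )
    return pd.DataFrame(rows), alpha


def site_contrasts(
    dataset: pd.DataFrame,
    sex: str,
    pcs: tuple[str, ...] = ("PC1", "PC2"),
) -> pd.DataFrame:
    """Within-species pairwise site contrasts of marginal means, per sex.

    Fits PC ~ area_z + species x site with a fish random intercept on the
    chosen sex, evaluates marginal means at area_z = 0, contrasts every site
    pair within each species, and Tukey-adjusts over the pairs of each
    species (3 pairs for 3 sites).  Contrasts are antisymmetric:
    estimate(A vs B) = -estimate(B vs A).
    """
    sub = dataset[dataset["sex"] == sex]
    if sub.empty:
        raise ValueError(f"no records for sex {sex!r}")
    site_levels = sorted(sub["site"].unique())
    if len(site_levels) < 2:
        raise ValueError("need >= 2 sites for contrasts")
    rows = []
    for pc in pcs:
        multi_species = sub["species"].nunique() > 1
        formula = (
            f"{pc} ~ area_z + C(species) * C(site)" if multi_species
            else f"{pc} ~ area_z + C(site)"
        )
        fit = fit_lmm(sub, formula, "fish_id")
        for species, spdata in sub.groupby("species", observed=True):
            present = sorted(spdata["site"].unique())
            missing = set(site_levels) - set(present)
            if missing:
                logger.warning(
                    "species %s: site(s) %s absent; pairs involving them skipped",
                    species, sorted(missing),
                )
            k = len(present)
            for site_a, site_b in itertools.combinations(present, 2):
                row_a = _marginal_mean_row(
                    fit.design_info, {"area_z": 0.0, "species": species, "site": site_a}
                )
                row_b = _marginal_mean_row(
                    fit.design_info, {"area_z": 0.0, "species": species, "site": site_b}
                )
                res = fit.contrast(row_a - row_b)
                p_adj = tukey_adjust(res["t"], k, res["df"])
                rows.append(
                    {
                        "species": species, "sex": sex, "pc": pc,
                        "site_a": site_a, "site_b": site_b,
                        "estimate": res["estimate"], "se": res["se"],
                        "t": res["t"], "df": res["df"],
                        "p_raw": res["p"], "p_adj": max(p_adj, res["p"]),
                    }
                )
    return pd.DataFrame(rows)
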