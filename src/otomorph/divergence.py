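"""Do between-population shape differences track neutral genetic divergence?

Stage one extracts eight "difference measures" describing how divergent
otolith shape is between each pair of populations.  For every sex, species
and PC (2 x 4 x 2 = 16 model pairs) the PC score is z-scaled and regressed
on standardized otolith area and site with a fish random intercept; the
three pairwise site differences of the marginal means are the *intercept*
differences.  Refitting with the area x site interaction yields the three
pairwise *slope* (allometry) differences.  Crossing {PC1, PC2} x
{intercept, slope} x {female, male} gives the eight measures; with four
species and three site pairs the table has 96 rows.

Stage two stacks all measures into one hierarchical regression on Phi_ST:
each measure gets its own intercept and its own Phi_ST slope beta_m, with
random intercepts for species, measure-within-species, population pair and
measure-within-pair.  Variance components are regularized by a
boundary-avoiding Gamma(2.5) prior on each random-effect SD (penalized
REML — the maximum-a-posteriori analogue of weakly-informative covariance
priors), which keeps the small design (12 observations per measure)
estimable.  A measure's shape divergence is declared related to neutral
divergence only when its 95% confidence interval for beta_m excludes zero.

Responses are z-scaled within measure before fitting; Phi_ST enters on its
natural 0-1 scale.  Stage-one standard errors are not propagated into stage
two (two-stage convention); an inverse-variance-weighted sensitivity mode
is available via ``weights="ivw"``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import fit_lmm, fit_reml
from .shapestats import _marginal_mean_row

logger = logging.getLogger(__name__)

__all__ = [
    "DivergenceFit",
    "extract_difference_measures",
    "fit_divergence_model",
]


@dataclass
class DivergenceFit:
    """Per-measure Phi_ST effects with 95% CIs and variance components."""

    table: pd.DataFrame
    vcomp: dict
    converged: bool
    nobs: int


def _pair_key(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def extract_difference_measures(
    dataset: pd.DataFrame,
    pcs: tuple[str, ...] = ("PC1", "PC2"),
) -> pd.DataFrame:
    """Between-site intercept and slope differences per sex, species and PC.

    Returns a long table keyed by (species, pair, sex, pc, measure_type)
    with the estimated difference and its SE; 96 rows for the default
    2 sexes x 4 species x 2 PCs x 3 site pairs x {intercept, slope} design.
    """
    rows = []
    sexes = sorted(dataset["sex"].unique())
    species_levels = sorted(dataset["species"].unique())
    n_models = 0
    for sex, species, pc in itertools.product(sexes, species_levels, pcs):
        sub = dataset[(dataset["sex"] == sex) & (dataset["species"] == species)].copy()
        if sub.empty:
            logger.warning("no data for %s/%s/%s; skipped", sex, species, pc)
            continue
        sd = sub[pc].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"{sex}/{species}/{pc}: PC scores have zero variance")
        sub["pc_scaled"] = (sub[pc] - sub[pc].mean()) / sd
        sites = sorted(sub["site"].unique())
        if len(sites) < 2:
            logger.warning("species %s has < 2 sites for sex %s; skipped", species, sex)
            continue

        fit_int = fit_lmm(sub, "pc_scaled ~ area_z + C(site)", "fish_id")
        fit_slp = fit_lmm(sub, "pc_scaled ~ area_z * C(site)", "fish_id")
        n_models += 1  # one model pair (with and without interaction)

        for site_a, site_b in itertools.combinations(sites, 2):
            base = {
                "species": species,
                "pair": _pair_key(site_a, site_b),
                "site_a": site_a,
                "site_b": site_b,
                "sex": sex,
                "pc": pc,
            }
            ra = _marginal_mean_row(fit_int.design_info, {"area_z": 0.0, "site": site_a})
            rb = _marginal_mean_row(fit_int.design_info, {"area_z": 0.0, "site": site_b})
            res = fit_int.contrast(ra - rb)
            rows.append(
                {**base, "measure_type": "intercept",
                 "value": res["estimate"], "se": res["se"]}
            )
            # allometric slope at a site = d(marginal mean)/d(area_z)
            sa1 = _marginal_mean_row(fit_slp.design_info, {"area_z": 1.0, "site": site_a})
            sa0 = _marginal_mean_row(fit_slp.design_info, {"area_z": 0.0, "site": site_a})
            sb1 = _marginal_mean_row(fit_slp.design_info, {"area_z": 1.0, "site": site_b})
            sb0 = _marginal_mean_row(fit_slp.design_info, {"area_z": 0.0, "site": site_b})
            res = fit_slp.contrast((sa1 - sa0) - (sb1 - sb0))
            rows.append(
                {**base, "measure_type": "slope",
                 "value": res["estimate"], "se": res["se"]}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no difference measures could be extracted")
    out["measure"] = out["pc"] + "_" + out["measure_type"] + "_" + out["sex"]
    logger.info(
        "extracted %d difference-measure rows from %d model pairs "
        "(%d measures)", len(out), n_models, out["measure"].nunique(),
    )
    return out


def fit_divergence_model(
    diffs: pd.DataFrame,
    phi: pd.DataFrame,
    weights: str | None = None,
    penalty_shape: float = 2.5,
) -> DivergenceFit:
    """Hierarchical regression of scaled difference measures on Phi_ST.

    ``phi`` is a long table with columns (species, pop1, pop2, phi_st); each
    (species, pair) row of ``diffs`` must join to one Phi_ST value.  Fits
    the stacked model with measure-specific intercepts and Phi_ST slopes and
    the four random-intercept groupings described in the module docstring,
    then reports each measure's slope with a Satterthwaite-t 95% CI.
    """
    phi = phi.copy()
    phi["pair"] = [_pair_key(a, b) for a, b in zip(phi["pop1"], phi["pop2"])]
    data = diffs.merge(
        phi[["species", "pair", "phi_st"]], on=["species", "pair"], how="left",
        validate="many_to_one",
    )
    if data["phi_st"].isna().any():
        missing = data.loc[data["phi_st"].isna(), ["species", "pair"]].drop_duplicates()
        raise ValueError(
            f"no Phi_ST value for {len(missing)} (species, pair) combination(s): "
            f"{missing.to_records(index=False).tolist()}"
        )
    if np.ptp(data["phi_st"].to_numpy()) == 0.0:
        raise ValueError(
            "all Phi_ST values are equal: measure slopes are inestimable "
            "(no differentiation contrast in the predictor)"
        )

    data = data.sort_values(["measure", "species", "pair"]).reset_index(drop=True)
    grp = data.groupby("measure")["value"]
    data["y"] = (data["value"] - grp.transform("mean")) / grp.transform("std", ddof=1)
    if weights == "ivw":
        w = 1.0 / data["se"] ** 2
        data["y"] = data["y"] * np.sqrt(w / w.mean())
        logger.info("inverse-variance sensitivity weighting applied")
    elif weights is not None:
        raise ValueError(f"unknown weights mode {weights!r}")

    measures = sorted(data["measure"].unique())
    M = pd.get_dummies(data["measure"], dtype=float)[measures].to_numpy()
    X = np.hstack([M, M * data["phi_st"].to_numpy()[:, None]])
    param_names = [f"intercept[{m}]" for m in measures] + [f"beta[{m}]" for m in measures]

    def dummies(col: pd.Series) -> np.ndarray:
        return pd.get_dummies(col.astype(str), dtype=float).to_numpy()

    Z_list = [
        dummies(data["species"]),
        dummies(data["species"] + ":" + data["measure"]),
        dummies(data["pair"]),
        dummies(data["pair"] + ":" + data["measure"]),
    ]
    comp_names = ["species", "measure:species", "pair", "measure:pair"]
    fit = fit_reml(
        data["y"].to_numpy(), X, Z_list,
        component_names=comp_names, param_names=param_names,
        penalty_shape=penalty_shape,
    )

    rows = []
    p_fixed = X.shape[1]
    for i, m in enumerate(measures):
        L = np.zeros(p_fixed)
        L[len(measures) + i] = 1.0
        res = fit.contrast(L)
        tcrit = stats.t.ppf(0.975, res["df"])
        lo, hi = res["estimate"] - tcrit * res["se"], res["estimate"] + tcrit * res["se"]
        rows.append(
            {"measure": m, "beta": res["estimate"], "se": res["se"],
             "df": res["df"], "ci_low": lo, "ci_high": hi,
             "excludes_zero": bool(lo > 0.0 or hi < 0.0)}
        )
    table = pd.DataFrame(rows)
    logger.info(
        "divergence model: %d/%d measure CIs exclude zero",
        int(table["excludes_zero"].sum()), len(table),
    )
    return DivergenceFit(
        table=table, vcomp=fit.vcomp, converged=fit.converged, nobs=fit.nobs
    )
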