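"""Cross-validation and prediction-quality metrics.

Two masking schemes mirror the two prediction problems a line-breeding
programme cares about:

* **CV1** (leave-one-year-location-out): every fold masks all
  phenotypes of one environment; a line's records in other
  environments stay in training.  This is prediction for tested lines
  in an untested environment.
* **CV2** (leave-one-breeding-cycle-out): every fold masks all
  phenotypes of one breeding cycle's lines; prediction for genuinely
  new lines from historical records.

Under *trait-assisted* prediction (TA) only the target trait is masked
in the validation fold; the correlated secondary trait stays observed
and informs the masked trait through the bivariate model.

Predictive ability (PA) is the Pearson correlation between
fixed-effect-corrected line means per year-location and the predicted
genetic values (``g`` alone, or ``g + gw`` for reaction-norm models),
pooled over all masked cells.  Dispersion bias is measured by the
inflation slope ``b_wp = cov(u_w, u_p) / var(u_p)`` of whole-information
on partial-information predictions (1 = no inflation, < 1 =
over-dispersed predictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import MODEL_EFFECTS, MODEL_TRAITS, ModelDesign, ReactionNormModel

__all__ = [
    "CVPlan",
    "CVReport",
    "make_folds",
    "fold_mask",
    "corrected_line_means",
    "predictive_ability",
    "bootstrap_se",
    "paired_model_test",
    "max_pa",
    "family_heritability",
    "inflation_slope",
    "run_cross_validation",
    "compare_reports",
]


@dataclass
class CVPlan:
    scheme: str
    folds: list[tuple[str, np.ndarray]]  # (fold id, masked obs ids)


def make_folds(
    phenos: pd.DataFrame,
    scheme: str,
    env_col: str = "env_id",
    cycle_col: str = "cycle",
    obs_col: str = "obs_id",
) -> CVPlan:
    """One fold per year-location (CV1) or per breeding cycle (CV2).

    Check plots (``is_check`` column, if present) are never masked:
    they play the role of repeated reference varieties that are always
    phenotyped.
    """
    universe = phenos
    if "is_check" in phenos.columns:
        universe = phenos[~phenos["is_check"].astype(bool)]
    if scheme.lower() == "cv1":
        key = env_col
    elif scheme.lower() == "cv2":
        key = cycle_col
    else:
        raise ValueError("scheme must be 'cv1' or 'cv2'")
    if key not in universe.columns:
        raise ValueError(f"phenotype table lacks column {key!r}")
    folds = [
        (str(level), grp[obs_col].to_numpy())
        for level, grp in universe.groupby(key, sort=True)
    ]
    if len(folds) < 2:
        raise ValueError(f"fewer than 2 folds under scheme {scheme!r}")
    return CVPlan(scheme=scheme.lower(), folds=folds)


def fold_mask(
    design: ModelDesign, obs_ids: np.ndarray, ta_trait: str | None = None
) -> np.ndarray:
    """Boolean (n, T) mask for one fold.

    All traits are masked for the fold's observations, or only
    ``ta_trait`` under trait-assisted masking.
    """
    n, T = design.Y.shape
    rows = design.obs_ids.isin(set(obs_ids))
    mask = np.zeros((n, T), dtype=bool)
    if ta_trait is None:
        mask[rows, :] = True
    else:
        if ta_trait not in design.trait_cols:
            raise ValueError(f"trait {ta_trait!r} not in design traits {design.trait_cols}")
        mask[rows, design.trait_cols.index(ta_trait)] = True
    return mask


def corrected_line_means(
    phenos: pd.DataFrame,
    fixed_fitted: pd.DataFrame,
    trait_cols,
    line_col: str = "line_id",
    env_col: str = "env_id",
    obs_col: str = "obs_id",
) -> pd.DataFrame:
    """Per (line, environment, trait) mean of fixed-effect-corrected plots.

    ``fixed_fitted`` holds the estimated fixed-effect value per
    observation (posterior mean of ``X b``, normally from a fit on the
    full data).  Returns a frame indexed by (line, env) with one column
    per trait plus ``n_reps``.
    """
    if isinstance(trait_cols, str):
        trait_cols = [trait_cols]
    df = phenos.set_index(obs_col)
    missing = df.index.difference(fixed_fitted.index)
    if len(missing):
        raise ValueError(f"observations without fixed-effect estimates: {list(missing)[:5]}")
    corrected = df[list(trait_cols)].sub(fixed_fitted.loc[df.index, list(trait_cols)])
    corrected[line_col] = df[line_col].values
    corrected[env_col] = df[env_col].values
    grouped = corrected.groupby([line_col, env_col])
    out = grouped[list(trait_cols)].mean()
    out["n_reps"] = grouped[trait_cols[0]].count()
    return out


def predictive_ability(y_corrected: np.ndarray, predictions: np.ndarray) -> float:
    """Pearson correlation over masked (line, environment) cells."""
    y = np.asarray(y_corrected, dtype=float)
    p = np.asarray(predictions, dtype=float)
    ok = np.isfinite(y) & np.isfinite(p)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 aligned cells for predictive ability")
    return float(stats.pearsonr(y[ok], p[ok])[0])


def bootstrap_se(
    y: np.ndarray,
    p: np.ndarray,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
    ci: float = 0.95,
) -> dict:
    """Nonparametric bootstrap SE and percentile CI of the correlation.

    Resamples (cell) pairs with replacement at full sample size.
    Degenerate resamples (zero variance in either vector) are redrawn
    and counted.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap replicates")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    n = len(y)
    draws = np.empty(n_boot)
    degenerate = 0
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, n, n)
            ys, ps = y[idx], p[idx]
            if ys.std() > 0 and ps.std() > 0:
                break
            degenerate += 1
        draws[b] = np.corrcoef(ys, ps)[0, 1]
    alpha = (1 - ci) / 2
    return {
        "se": float(draws.std(ddof=1)),
        "ci": (float(np.quantile(draws, alpha)), float(np.quantile(draws, 1 - alpha))),
        "n_degenerate": degenerate,
    }


def paired_model_test(errors_a: np.ndarray, errors_b: np.ndarray) -> dict:
    """Two-tailed paired t-test on per-cell prediction errors of two models.

    The paired unit is the squared prediction error per masked
    (line, environment) cell; both models must be evaluated on the same
    cells.  Zero-variance differences yield p = 1 with a flag.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("the two models must share the same masked cells")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):  # identical models
            return {"statistic": 0.0, "pvalue": 1.0, "degenerate": True}
        # constant nonzero shift: infinitely significant
        return {"statistic": float(np.sign(diff.mean()) * np.inf),
                "pvalue": 0.0, "degenerate": True}
    t, pval = stats.ttest_rel(a, b)
    return {"statistic": float(t), "pvalue": float(pval), "degenerate": False}


def max_pa(n_reps: float, h2f: float) -> float:
    """Upper bound on predictive ability: ``n h2f / (1 + (n - 1) h2f)``.

    ``n_reps`` is the average number of repetitions of a line within a
    year-location; ``h2f`` the family-mean heritability (or, for
    reaction-norm models, the proportion of variance explained by the
    genomic plus genomic-by-EC effects).  Monotone increasing in both.
    """
    if not (0.0 <= h2f <= 1.0):
        raise ValueError("h2f must lie in [0, 1]")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return n_reps * h2f / (1.0 + (n_reps - 1.0) * h2f)


def family_heritability(
    vc: dict[str, float],
    dG: float,
    n_reps: float,
    include_gw: bool = False,
    gw_scale: float = 1.0,
) -> float:
    """Family-mean heritability from plot-level variance components.

    Variance of a line's within-environment mean over ``n_reps`` plots:
    line and genomic terms are fully shared, the line-by-environment
    term is shared within the environment, spatial and residual terms
    average down by ``n_reps``.  With ``include_gw`` the genomic-by-EC
    variance (scaled by the mean diagonal of its kernel) joins the
    heritable numerator, giving the proportion of variance explained by
    the genomic additive plus interaction effects.
    """
    num = dG * vc["g"]
    if include_gw:
        num += gw_scale * vc.get("gw", 0.0)
    den = vc["l"] + dG * vc["g"] + vc["f"] + (vc["s"] + vc["e"]) / n_reps
    if include_gw:
        den += gw_scale * vc.get("gw", 0.0)
    return float(num / den)


def inflation_slope(u_whole: np.ndarray, u_partial: np.ndarray) -> float:
    """Regression slope of whole- on partial-information predictions."""
    w = np.asarray(u_whole, dtype=float)
    p = np.asarray(u_partial, dtype=float)
    if len(w) != len(p) or len(w) < 3:
        raise ValueError("aligned vectors of length >= 3 required")
    var_p = np.var(p, ddof=1)
    if var_p == 0:
        raise ValueError("partial-information predictions have zero variance")
    cov = np.cov(w, p, ddof=1)[0, 1]
    return float(cov / var_p)


# ----------------------------------------------------------------------
@dataclass
class CVReport:
    """Cross-validation outcome for one model under one scheme."""

    model: str
    scheme: str
    target_trait: str
    trait_assisted: bool
    seed: int
    cells: pd.DataFrame
    pa: dict = field(default_factory=dict)
    pa_se: dict = field(default_factory=dict)
    pa_ci: dict = field(default_factory=dict)
    pa_per_fold: pd.DataFrame | None = None
    b_wp: dict = field(default_factory=dict)
    max_pa: dict = field(default_factory=dict)
    n_reps_mean: float = float("nan")
    vc: pd.DataFrame | None = None

    def summary(self) -> dict:
        out = {
            "model": self.model, "scheme": self.scheme,
            "target_trait": self.target_trait, "trait_assisted": self.trait_assisted,
            "n_cells": int(len(self.cells)), "n_reps_mean": self.n_reps_mean,
        }
        for k, v in self.pa.items():
            out[f"pa_{k}"] = v
        for k, v in self.pa_se.items():
            out[f"pa_se_{k}"] = v
        for k, v in self.b_wp.items():
            out[f"b_wp_{k}"] = v
        for k, v in self.max_pa.items():
            out[f"max_pa_{k}"] = v
        return out


def run_cross_validation(
    design: ModelDesign,
    model: str,
    scheme: str,
    *,
    target_trait: str | None = None,
    trait_assisted: bool = False,
    n_iter: int = 1500,
    burn_in: int = 500,
    thin: int = 5,
    r2: float = 0.90,
    df0: float = 1e-4,
    random_state: int = 0,
    boot_reps: int = 1000,
) -> CVReport:
    """Full CV protocol for one model: whole-information fit, per-fold
    masked refits, predictive ability, bootstrap SEs, inflation slopes
    and the maximum-PA bound.

    Fixed effects for the corrected line means come from the
    whole-information fit, matching the protocol of estimating fixed
    effects once on the full data.
    """
    n_traits = MODEL_TRAITS[model]
    if trait_assisted and n_traits != 2:
        raise ValueError("trait-assisted prediction needs a bivariate model")
    if target_trait is None:
        target_trait = design.trait_cols[0]
    if n_traits == 1:
        fit_design = design.with_traits([target_trait])
    else:
        if len(design.trait_cols) != 2:
            raise ValueError("bivariate models need a two-trait design")
        fit_design = design
    has_gw = "gw" in MODEL_EFFECTS[model]

    chain = dict(n_iter=n_iter, burn_in=burn_in, thin=thin, r2=r2, df0=df0)
    seeds = np.random.SeedSequence(random_state).spawn(64)
    whole = ReactionNormModel(
        model, random_state=np.random.default_rng(seeds[0]), **chain
    ).fit(fit_design)

    corrected = corrected_line_means(
        fit_design.phenos, whole.fixed_fitted_, [target_trait]
    )
    plan = make_folds(fit_design.phenos, scheme)

    ph = fit_design.phenos
    obs_line = pd.Series(ph["line_id"].values, index=ph[fit_design.obs_col].values)
    obs_env = pd.Series(ph["env_id"].values, index=ph[fit_design.obs_col].values)

    def per_cell(fit, obs_ids):
        """ghat and (mean) gw-hat per masked (line, env) cell."""
        ghat = fit.genetic_values_[target_trait]
        sub = pd.DataFrame(
            {"line_id": obs_line.loc[obs_ids].values,
             "env_id": obs_env.loc[obs_ids].values},
            index=obs_ids,
        )
        if has_gw:
            sub["gw"] = fit.gw_values_.loc[obs_ids, target_trait].values
            cells = sub.groupby(["line_id", "env_id"])["gw"].mean().to_frame("gw")
        else:
            cells = sub.groupby(["line_id", "env_id"]).size().to_frame("n")
            cells["gw"] = 0.0
        cells["g"] = ghat.loc[cells.index.get_level_values("line_id")].values
        return cells[["g", "gw"]]

    rows = []
    for i, (fold_id, obs_ids) in enumerate(plan.folds):
        mask = fold_mask(fit_design, obs_ids, ta_trait=target_trait if trait_assisted else None)
        fit = ReactionNormModel(
            model, random_state=np.random.default_rng(seeds[i + 1]), **chain
        ).fit(fit_design, mask=mask)
        part = per_cell(fit, obs_ids)
        wcells = per_cell(whole, obs_ids)
        cell = part.join(wcells, rsuffix="_w").join(
            corrected[[target_trait, "n_reps"]], how="left"
        )
        cell = cell.rename(columns={target_trait: "y_corrected"})
        cell["fold"] = fold_id
        rows.append(cell.reset_index())
    cells = pd.concat(rows, ignore_index=True)
    cells = cells.dropna(subset=["y_corrected"])

    report = CVReport(
        model=model, scheme=plan.scheme, target_trait=target_trait,
        trait_assisted=trait_assisted, seed=random_state, cells=cells,
        vc=whole.vc_summary_,
    )
    report.n_reps_mean = float(cells["n_reps"].mean())

    pred_types = {"g": cells["g"].to_numpy()}
    whole_types = {"g": cells["g_w"].to_numpy()}
    if has_gw:
        pred_types["g_plus_gw"] = (cells["g"] + cells["gw"]).to_numpy()
        whole_types["g_plus_gw"] = (cells["g_w"] + cells["gw_w"]).to_numpy()

    y = cells["y_corrected"].to_numpy()
    boot_rng = np.random.default_rng(seeds[len(plan.folds) + 1])
    per_fold_rows = []
    for key, pred in pred_types.items():
        report.pa[key] = predictive_ability(y, pred)
        boot = bootstrap_se(y, pred, n_boot=boot_reps, seed=boot_rng)
        report.pa_se[key] = boot["se"]
        report.pa_ci[key] = boot["ci"]
        for fold_id, grp in cells.assign(pred=pred).groupby("fold"):
            if len(grp) >= 3:
                per_fold_rows.append(
                    {"fold": fold_id, "type": key,
                     "pa": predictive_ability(grp["y_corrected"], grp["pred"]),
                     "n_cells": len(grp)}
                )
    report.pa_per_fold = pd.DataFrame(per_fold_rows)

    # inflation slopes per predicted effect (g; and gw for RN models)
    report.b_wp["g"] = inflation_slope(cells["g_w"], cells["g"])
    if has_gw:
        report.b_wp["gw"] = inflation_slope(cells["gw_w"], cells["gw"])

    # maximum-PA bound from whole-information variance components
    t_idx = fit_design.trait_cols.index(target_trait)
    vcd = {e: whole.vc_mean_[e][t_idx, t_idx] for e in whole.vc_mean_}
    dG = fit_design.dG if fit_design.dG is not None else 1.0
    nbar = report.n_reps_mean
    h2f = family_heritability(vcd, dG, nbar, include_gw=False)
    report.max_pa["g"] = max_pa(nbar, h2f)
    if has_gw:
        gw_scale = 1.0
        blk = fit_design.blocks.get("gw")
        if blk is not None:
            gw_scale = float(blk.lam.sum() / len(fit_design.obs_ids))  # mean kernel diagonal
        h2f_gw = family_heritability(vcd, dG, nbar, include_gw=True, gw_scale=gw_scale)
        report.max_pa["g_plus_gw"] = max_pa(nbar, min(h2f_gw, 1.0))
    return report


def compare_reports(a: CVReport, b: CVReport, pred_type: str = "g") -> dict:
    """Paired t-test between two models' per-cell squared errors."""
    key = ["line_id", "env_id"]
    ca = a.cells.set_index(key)
    cb = b.cells.set_index(key)
    common = ca.index.intersection(cb.index)

    def pred(c):
        if pred_type == "g":
            return c.loc[common, "g"]
        return c.loc[common, "g"] + c.loc[common, "gw"]

    err_a = (ca.loc[common, "y_corrected"] - pred(ca)) ** 2
    err_b = (cb.loc[common, "y_corrected"] - pred(cb)) ** 2
    return paired_model_test(err_a.to_numpy(), err_b.to_numpy())
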