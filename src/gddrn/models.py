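"""Bayesian mixed models for multi-environment trials (M1-M5).

The model family, in increasing order of structure:

* **M1** (baseline): fixed trial effects (trial nested within
  year-location-cycle) plus random line ``l``, line-by-environment
  ``f`` and spatial ``s`` effects.
* **M2** adds a genomic additive effect ``g`` with the GRM ``G`` as
  covariance (G-BLUP).
* **M3** adds the reaction-norm interaction ``gw`` with covariance
  ``(Zg G Zg') o Omega``: genotype-by-environment signal expressed as
  marker-by-environmental-covariate covariance.
* **M4/M5** are the bivariate versions of M2/M3; each random effect
  gets a 2x2 between-trait covariance matrix (Kronecker structure,
  e.g. ``G (x) K`` for the genomic effect).

Fitting is by Gibbs sampling.  Every kernel-structured effect is
reparameterized in the eigenbasis of its covariance: if
``Z K Z'`` enters the model, write ``K = U D U'``, set
``W0 = Z U D^{1/2}`` and a second orthogonal rotation ``V`` such that
``(W0 V)'(W0 V)`` is diagonal; the coefficients on ``W0 V`` are then a
priori i.i.d. and their full conditional is diagonal, so each effect is
block-updated in one vectorized draw per iteration.  Variances get
scaled-inverse-chi-square full conditionals (single trait) or 2x2
inverse-Wishart full conditionals (bivariate); fixed effects carry flat
priors.  Missing phenotypes (including deliberately masked validation
records) are handled by residual data augmentation, which is what makes
trait-assisted prediction work: a masked target trait still borrows
through the residual and effect-level between-trait covariances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator

__all__ = [
    "MODEL_EFFECTS",
    "MODEL_TRAITS",
    "ModelDesign",
    "ReactionNormModel",
    "fit_gibbs",
    "plugin_heritability",
    "mcmc_diagnostics",
]

#: Random-effect sets per named model.
MODEL_EFFECTS: dict[str, tuple[str, ...]] = {
    "M1": ("l", "f", "s"),
    "M2": ("l", "f", "s", "g"),
    "M3": ("l", "f", "s", "g", "gw"),
    "M4": ("l", "f", "s", "g"),
    "M5": ("l", "f", "s", "g", "gw"),
}

#: Number of traits per named model (M4/M5 are bivariate).
MODEL_TRAITS = {"M1": 1, "M2": 1, "M3": 1, "M4": 2, "M5": 2}


class _EffectBlock:
    """Pre-orthogonalized design for one random effect.

    ``W`` (n x r) is the working design whose cross-product is the
    diagonal ``lam``; coefficients on ``W`` are a priori i.i.d. with
    the effect's (co)variance.  ``P`` maps coefficients back to effect
    values on the original levels (``None`` means identity: levels and
    coefficients coincide, as for i.i.d. line effects).
    """

    def __init__(self, name, W, lam, P, levels):
        self.name = name
        self.W = W
        self.lam = np.asarray(lam, dtype=float)
        self.P = P
        self.levels = levels
        self.r = len(self.lam)

    def coef_cross(self, E):
        return np.asarray(self.W.T @ E)

    def fitted(self, C):
        return np.asarray(self.W @ C)

    def effect_values(self, C):
        return C if self.P is None else self.P @ C


def _eigh_psd(K: np.ndarray, label: str, eig_tol: float, psd_tol: float = 1e-8):
    d, U = np.linalg.eigh(K)
    if d[-1] <= 0:
        raise ValueError(f"kernel {label} has no positive eigenvalue")
    if d[0] < -psd_tol * d[-1]:
        raise ValueError(
            f"kernel {label} is not positive semidefinite "
            f"(min eigenvalue {d[0]:.3e} vs max {d[-1]:.3e})"
        )
    keep = d > eig_tol * d[-1]
    return d[keep], U[:, keep]


def _onehot(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


class ModelDesign:
    """Assembled design: phenotypes, fixed effects, and effect blocks.

    Observations are canonically sorted by ``obs_id`` and factor levels
    lexicographically, so the fitted posterior is invariant to the
    input row order (bit-for-bit, given a seed).  Building a design is
    the expensive step (kernel eigendecompositions); it can be shared
    across models, traits subsets and cross-validation folds because
    masking is applied at fit time, not here.

    Parameters
    ----------
    phenos : DataFrame with columns ``obs_id``, ``line_id``, ``env_id``,
        the fixed factor (default ``trial``) and the trait columns.
    trait_cols : one or two phenotype column names.
    G : optional line x line GRM (enables ``g`` and, with ``omega``,
        ``gw``).
    S : optional observation-level spatial kernel (enables ``s``).
    omega : optional observation-level EC kernel.
    """

    def __init__(
        self,
        phenos: pd.DataFrame,
        trait_cols,
        *,
        G: pd.DataFrame | None = None,
        S: pd.DataFrame | None = None,
        omega: pd.DataFrame | None = None,
        fixed_col: str = "trial",
        line_col: str = "line_id",
        env_col: str = "env_id",
        obs_col: str = "obs_id",
        eig_tol: float = 1e-10,
    ):
        if isinstance(trait_cols, str):
            trait_cols = (trait_cols,)
        self.trait_cols = tuple(trait_cols)
        for col in (obs_col, line_col, env_col, fixed_col, *self.trait_cols):
            if col not in phenos.columns:
                raise ValueError(f"phenotype table lacks column {col!r}")
        self.phenos = phenos.sort_values(obs_col).reset_index(drop=True)
        self.obs_col, self.line_col, self.env_col, self.fixed_col = (
            obs_col, line_col, env_col, fixed_col,
        )
        self.obs_ids = pd.Index(self.phenos[obs_col])
        self.n = len(self.phenos)
        self.Y = self.phenos[list(self.trait_cols)].to_numpy(dtype=float)

        # --- fixed effects: intercept + dummies, reference level dropped
        # deterministically (lexicographically first)
        trial = self.phenos[fixed_col].astype(str)
        levels = sorted(trial.unique())
        dummies = pd.get_dummies(
            pd.Categorical(trial, categories=levels), drop_first=True
        ).to_numpy(dtype=float)
        X = np.column_stack([np.ones(self.n), dummies])
        self.fixed_names = ["(intercept)"] + [str(c) for c in levels[1:]]
        Q, Rtri = np.linalg.qr(X)
        diag = np.abs(np.diag(Rtri))
        if diag.min() < 1e-8 * max(diag.max(), 1.0):
            raise ValueError("fixed-effect design is rank deficient after reference dropping")
        self.Q, self.Rtri = Q, Rtri

        # --- random-effect blocks
        self.blocks: dict[str, _EffectBlock] = {}
        lines = pd.Index(sorted(self.phenos[line_col].astype(str).unique()))
        self.line_ids = lines
        line_codes = lines.get_indexer(self.phenos[line_col].astype(str))
        Zl = _onehot(line_codes, len(lines))
        counts_l = np.asarray(Zl.sum(axis=0)).ravel()
        self.blocks["l"] = _EffectBlock("l", Zl, counts_l, None, lines)

        pairs = self.phenos[line_col].astype(str) + "|" + self.phenos[env_col].astype(str)
        pair_levels = pd.Index(sorted(pairs.unique()))
        pair_codes = pair_levels.get_indexer(pairs)
        Zf = _onehot(pair_codes, len(pair_levels))
        counts_f = np.asarray(Zf.sum(axis=0)).ravel()
        self.blocks["f"] = _EffectBlock("f", Zf, counts_f, None, pair_levels)

        if S is not None:
            Smat = S.loc[self.obs_ids, self.obs_ids].to_numpy(dtype=float)
            d, U = _eigh_psd(Smat, "S", eig_tol)
            W = U * np.sqrt(d)
            self.blocks["s"] = _EffectBlock("s", W, d, W, self.obs_ids)

        self.dG = None
        if G is not None:
            missing = sorted(set(lines) - set(G.index.astype(str)))
            if missing:
                raise ValueError(f"lines absent from G: {missing[:5]}")
            Gsub = G.copy()
            Gsub.index = Gsub.index.astype(str)
            Gsub.columns = Gsub.columns.astype(str)
            Gsub = Gsub.loc[lines, lines].to_numpy(dtype=float)
            self.dG = float(np.mean(np.diag(Gsub)))
            dg, Ug = _eigh_psd(Gsub, "G", eig_tol)
            B = Ug * np.sqrt(dg)
            M = (B * counts_l[:, None]).T @ B
            lam, V = np.linalg.eigh(M)
            keep = lam > eig_tol * max(lam[-1], 1.0)
            lam, V = lam[keep], V[:, keep]
            W = np.asarray(Zl @ B) @ V
            self.blocks["g"] = _EffectBlock("g", W, lam, B @ V, lines)

            if omega is not None:
                from .kernels import build_gw_kernel

                obs_line = pd.Series(
                    self.phenos[line_col].astype(str).values, index=self.obs_ids
                )
                GW = build_gw_kernel(
                    pd.DataFrame(Gsub, index=lines, columns=lines), obs_line, omega
                ).to_numpy(dtype=float)
                dgw, Ugw = _eigh_psd(GW, "GW", eig_tol)
                Wgw = Ugw * np.sqrt(dgw)
                self.blocks["gw"] = _EffectBlock("gw", Wgw, dgw, Wgw, self.obs_ids)

    def with_traits(self, trait_cols) -> "ModelDesign":
        """Shallow copy restricted to a subset of traits (blocks shared)."""
        if isinstance(trait_cols, str):
            trait_cols = (trait_cols,)
        for t in trait_cols:
            if t not in self.trait_cols and t not in self.phenos.columns:
                raise ValueError(f"unknown trait {t!r}")
        clone = object.__new__(ModelDesign)
        clone.__dict__.update(self.__dict__)
        clone.trait_cols = tuple(trait_cols)
        clone.Y = clone.phenos[list(trait_cols)].to_numpy(dtype=float)
        return clone


def _draw_invwishart(rng: np.random.Generator, nu: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition."""
    T = scale.shape[0]
    if T == 1:
        return scale / rng.chisquare(nu)
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((T, T))
    for i in range(T):
        A[i, i] = np.sqrt(rng.chisquare(nu - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    LA = L @ A
    return np.linalg.inv(LA @ LA.T)


def _sample_coeff_block(rng, lam, B, Rinv, Siginv):
    """Vectorized block draw of coefficients with diagonal cross-product.

    Row j of the returned matrix has full-conditional precision
    ``lam_j R^-1 + Sigma^-1`` and mean ``prec^-1 R^-1 b_j``.
    """
    T = B.shape[1]
    r = len(lam)
    if T == 1:
        prec = lam * Rinv[0, 0] + Siginv[0, 0]
        mean = B[:, 0] * Rinv[0, 0] / prec
        return (mean + rng.standard_normal(r) / np.sqrt(prec))[:, None]
    a = lam * Rinv[0, 0] + Siginv[0, 0]
    b = lam * Rinv[0, 1] + Siginv[0, 1]
    d = lam * Rinv[1, 1] + Siginv[1, 1]
    det = a * d - b * b
    rhs = B @ Rinv  # Rinv symmetric
    m1 = (d * rhs[:, 0] - b * rhs[:, 1]) / det
    m2 = (-b * rhs[:, 0] + a * rhs[:, 1]) / det
    c11, c12, c22 = d / det, -b / det, a / det
    L11 = np.sqrt(c11)
    L21 = c12 / L11
    L22 = np.sqrt(np.maximum(c22 - L21 * L21, 0.0))
    z1 = rng.standard_normal(r)
    z2 = rng.standard_normal(r)
    C = np.empty((r, 2))
    C[:, 0] = m1 + L11 * z1
    C[:, 1] = m2 + L21 * z1 + L22 * z2
    return C


def _augment_missing(rng, Yaug, fitted, miss, R):
    T = Yaug.shape[1]
    if T == 1:
        idx = miss[:, 0]
        if idx.any():
            Yaug[idx, 0] = fitted[idx, 0] + rng.standard_normal(idx.sum()) * np.sqrt(R[0, 0])
        return
    both = miss[:, 0] & miss[:, 1]
    if both.any():
        L = np.linalg.cholesky(R)
        Z = rng.standard_normal((int(both.sum()), 2))
        Yaug[both] = fitted[both] + Z @ L.T
    for t, o in ((0, 1), (1, 0)):
        only = miss[:, t] & ~miss[:, o]
        if only.any():
            e_obs = Yaug[only, o] - fitted[only, o]
            mu = R[t, o] / R[o, o] * e_obs
            var = R[t, t] - R[t, o] ** 2 / R[o, o]
            Yaug[only, t] = (
                fitted[only, t] + mu + rng.standard_normal(int(only.sum())) * np.sqrt(max(var, 0.0))
            )


class ReactionNormModel(BaseEstimator):
    """Gibbs-sampled mixed model for one of M1-M5 (or a custom effect set).

    Parameters
    ----------
    model : name in ``MODEL_EFFECTS`` selecting effects and trait count;
        ignored when ``effects`` is given explicitly.
    effects : optional explicit tuple of effect names among
        ``{"l", "f", "s", "g", "gw"}``.
    n_iter, burn_in, thin : chain settings.  Retained draws are
        ``(n_iter - burn_in) / thin``.
    r2 : prior proportion of phenotypic variance attributed to the
        random terms jointly; each random effect's prior scale is set so
        its prior mode implies an equal share of ``r2 * var(y)``, and
        the residual gets ``(1 - r2) * var(y)``.
    df0 : prior degrees of freedom added to the (inverse-chi-square /
        inverse-Wishart) variance priors; near zero is uninformative.
    random_state : int seed or ``numpy.random.Generator``.

    Fitted attributes (trailing underscore) include posterior summaries
    (``variance_draws_``, ``vc_mean_``, ``vc_psd_``), posterior-mean
    effect values (``genetic_values_``, ``gw_values_``, ``line_values_``,
    ``fixed_fitted_``) and chain metadata.
    """

    def __init__(
        self,
        model: str = "M2",
        effects=None,
        n_iter: int = 5000,
        burn_in: int = 1000,
        thin: int = 5,
        r2: float = 0.90,
        df0: float = 1e-4,
        random_state=None,
    ):
        self.model = model
        self.effects = effects
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.r2 = r2
        self.df0 = df0
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, design: ModelDesign, mask: np.ndarray | None = None):
        """Run the chain on ``design``.

        ``mask`` is an optional boolean (n, T) array marking phenotype
        cells to treat as missing in addition to NaN entries in the
        data (used for cross-validation and trait-assisted masking).
        """
        if self.effects is not None:
            effects = tuple(self.effects)
        else:
            if self.model not in MODEL_EFFECTS:
                raise ValueError(f"unknown model {self.model!r}")
            effects = MODEL_EFFECTS[self.model]
            if len(design.trait_cols) != MODEL_TRAITS[self.model]:
                raise ValueError(
                    f"{self.model} expects {MODEL_TRAITS[self.model]} trait(s), "
                    f"design has {len(design.trait_cols)}; use design.with_traits(...)"
                )
        missing_blocks = [e for e in effects if e not in design.blocks]
        if missing_blocks:
            raise ValueError(f"design lacks kernels for effects: {missing_blocks}")

        n, T = design.Y.shape
        Y = design.Y
        miss = np.isnan(Y)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (n, T):
                raise ValueError(f"mask must have shape {(n, T)}")
            miss = miss | mask
        self.mask_ = miss.copy()

        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )

        # prior scales from the observed-data variance partition
        var_y = np.array(
            [np.nanvar(np.where(miss[:, t], np.nan, Y[:, t]), ddof=1) for t in range(T)]
        )
        var_y = np.where(np.isfinite(var_y) & (var_y > 0), var_y, 1.0)
        share = self.r2 * var_y / len(effects)
        if T == 1:
            nu0 = self.df0
            S0 = {e: np.array([[share[0] * (self.df0 + 2.0)]]) for e in effects}
            nu0_R = self.df0
            S0_R = np.array([[(1.0 - self.r2) * var_y[0] * (self.df0 + 2.0)]])
        else:
            nu0 = T + self.df0
            S0 = {e: np.diag(share) * (nu0 + T + 1.0) for e in effects}
            nu0_R = T + self.df0
            S0_R = np.diag((1.0 - self.r2) * var_y) * (nu0_R + T + 1.0)

        blocks = {e: design.blocks[e] for e in effects}
        Sigma = {e: np.diag(share).reshape(T, T).copy() for e in effects}
        Siginv = {e: np.linalg.inv(Sigma[e]) for e in effects}
        R = np.diag((1.0 - self.r2) * var_y).reshape(T, T)
        Rinv = np.linalg.inv(R)

        C = {e: np.zeros((blocks[e].r, T)) for e in effects}
        F = {e: np.zeros((n, T)) for e in effects}
        beta = np.zeros((design.Q.shape[1], T))
        Ffix = np.zeros((n, T))
        Yaug = np.where(miss, 0.0, Y)
        col_mean = np.array(
            [np.nanmean(np.where(miss[:, t], np.nan, Y[:, t])) for t in range(T)]
        )
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        Yaug = np.where(miss, col_mean, Y)

        n_keep = (self.n_iter - self.burn_in) // self.thin
        if n_keep < 1:
            raise ValueError("chain settings leave no retained draws")
        sig_draws = {e: np.zeros((n_keep, T, T)) for e in effects}
        res_draws = np.zeros((n_keep, T, T))
        beta_draws = np.zeros((n_keep, beta.shape[0], T))
        u_sum = {e: np.zeros((len(blocks[e].levels), T)) for e in effects}
        fit_sum = np.zeros((n, T))
        fix_sum = np.zeros((n, T))
        kept = 0

        ones = np.ones(design.Q.shape[1])
        zero_prec = np.zeros((T, T))
        for it in range(self.n_iter):
            fitted = Ffix.copy()
            for e in effects:
                fitted += F[e]
            _augment_missing(rng, Yaug, fitted, miss, R)
            E = Yaug - fitted

            # fixed effects (flat prior, orthonormal working design Q)
            Ep = E + Ffix
            Bq = design.Q.T @ Ep
            beta = _sample_coeff_block(rng, ones, Bq, Rinv, zero_prec)
            Ffix = design.Q @ beta
            E = Ep - Ffix

            for e in effects:
                blk = blocks[e]
                Ep = E + F[e]
                Bk = blk.coef_cross(Ep)
                C[e] = _sample_coeff_block(rng, blk.lam, Bk, Rinv, Siginv[e])
                SS = C[e].T @ C[e]
                Sigma[e] = _draw_invwishart(rng, nu0 + blk.r, S0[e] + SS)
                if not np.all(np.isfinite(Sigma[e])):
                    raise RuntimeError(f"divergent chain at iteration {it} (effect {e})")
                Siginv[e] = np.linalg.inv(Sigma[e])
                F[e] = blk.fitted(C[e])
                E = Ep - F[e]

            R = _draw_invwishart(rng, nu0_R + n, S0_R + E.T @ E)
            if not np.all(np.isfinite(R)):
                raise RuntimeError(f"divergent chain at iteration {it} (residual)")
            Rinv = np.linalg.inv(R)

            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0 and kept < n_keep:
                for e in effects:
                    sig_draws[e][kept] = Sigma[e]
                    u_sum[e] += blocks[e].effect_values(C[e])
                res_draws[kept] = R
                beta_draws[kept] = solve_triangular(design.Rtri, beta)
                fix_sum += Ffix
                fit_sum += Ffix + sum(F[e] for e in effects)
                kept += 1

        # ----- posterior summaries -------------------------------------
        self.design_ = design
        self.effects_ = effects
        self.n_draws_ = kept
        self.trait_cols_ = design.trait_cols
        self.variance_draws_ = {**sig_draws, "e": res_draws}
        self.beta_draws_ = beta_draws
        self.fixed_names_ = design.fixed_names
        self.fixed_effects_ = pd.DataFrame(
            beta_draws.mean(axis=0), index=design.fixed_names, columns=design.trait_cols
        )
        self.fixed_fitted_ = pd.DataFrame(
            fix_sum / kept, index=design.obs_ids, columns=design.trait_cols
        )
        self.fitted_values_ = pd.DataFrame(
            fit_sum / kept, index=design.obs_ids, columns=design.trait_cols
        )
        self.effect_means_ = {
            e: pd.DataFrame(
                u_sum[e] / kept, index=blocks[e].levels, columns=design.trait_cols
            )
            for e in effects
        }
        if "g" in effects:
            self.genetic_values_ = self.effect_means_["g"]
        if "gw" in effects:
            self.gw_values_ = self.effect_means_["gw"]
        if "l" in effects:
            self.line_values_ = self.effect_means_["l"]
        mean = {e: d.mean(axis=0) for e, d in self.variance_draws_.items()}
        psd = {e: d.std(axis=0, ddof=1) for e, d in self.variance_draws_.items()}
        rows = []
        for e in list(effects) + ["e"]:
            for t, trait in enumerate(design.trait_cols):
                rows.append(
                    {"effect": e, "param": f"var[{trait}]",
                     "mean": mean[e][t, t], "psd": psd[e][t, t]}
                )
            if T == 2:
                rows.append(
                    {"effect": e, "param": "cov", "mean": mean[e][0, 1], "psd": psd[e][0, 1]}
                )
        self.vc_summary_ = pd.DataFrame(rows)
        self.vc_mean_ = {e: mean[e] for e in mean}
        self.vc_psd_ = {e: psd[e] for e in psd}
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "variance_draws_"):
            raise RuntimeError("model is not fitted")

    def predict(self, X=None) -> pd.DataFrame:
        """Posterior-mean fitted values per observation and trait."""
        self._check_fitted()
        return self.fitted_values_

    def variance_components(self) -> pd.DataFrame:
        self._check_fitted()
        return self.vc_summary_

    def heritability(self, dG: float | None = None) -> pd.DataFrame:
        """Plot-level narrow (h2) and broad (H2) heritability per trait.

        ``h2 = d(G) s2_g / s2_P`` and ``H2 = (s2_l + d(G) s2_g) / s2_P``
        with ``s2_P = s2_l + d(G) s2_g + s2_f + s2_s + s2_e``, computed
        per retained draw and then summarized.
        """
        self._check_fitted()
        needed = ("l", "g", "f", "s")
        missing = [e for e in needed if e not in self.variance_draws_]
        if missing:
            raise ValueError(f"heritability needs effects {missing} in the model")
        if dG is None:
            dG = self.design_.dG
        if dG is None:
            raise ValueError("mean GRM diagonal d(G) unavailable; pass dG explicitly")
        rows = []
        for t, trait in enumerate(self.trait_cols_):
            d = {e: self.variance_draws_[e][:, t, t] for e in ("l", "g", "f", "s", "e")}
            sP = d["l"] + dG * d["g"] + d["f"] + d["s"] + d["e"]
            h2 = dG * d["g"] / sP
            H2 = (d["l"] + dG * d["g"]) / sP
            rows.append(
                {"trait": trait,
                 "h2": h2.mean(), "h2_psd": h2.std(ddof=1),
                 "H2": H2.mean(), "H2_psd": H2.std(ddof=1),
                 "sigma2_P": sP.mean(), "sigma2_P_psd": sP.std(ddof=1)}
            )
        return pd.DataFrame(rows).set_index("trait")

    def trait_correlations(self) -> pd.DataFrame:
        """Between-trait correlation per effect: ``cov12 / sqrt(v1 v2)``
        summarized over retained draws; zero-variance draws are skipped
        and counted."""
        self._check_fitted()
        if len(self.trait_cols_) != 2:
            raise ValueError("trait correlations require a bivariate fit")
        rows = []
        for e, draws in self.variance_draws_.items():
            v1, v2, c = draws[:, 0, 0], draws[:, 1, 1], draws[:, 0, 1]
            ok = (v1 > 0) & (v2 > 0)
            corr = c[ok] / np.sqrt(v1[ok] * v2[ok])
            rows.append(
                {"effect": e, "corr": corr.mean(), "psd": corr.std(ddof=1),
                 "n_skipped": int((~ok).sum())}
            )
        return pd.DataFrame(rows).set_index("effect")

    def diagnostics(self, mcse_threshold: float = 0.05) -> pd.DataFrame:
        """Convergence diagnostics for the variance-parameter chains."""
        self._check_fitted()
        chains = {}
        for e, draws in self.variance_draws_.items():
            for t, trait in enumerate(self.trait_cols_):
                chains[f"var_{e}[{trait}]"] = draws[:, t, t]
            if draws.shape[1] == 2:
                chains[f"cov_{e}"] = draws[:, 0, 1]
        return mcmc_diagnostics(chains, mcse_threshold=mcse_threshold)


def fit_gibbs(design: ModelDesign, model: str = "M2", **kwargs) -> ReactionNormModel:
    """Thin functional wrapper over :class:`ReactionNormModel`."""
    return ReactionNormModel(model=model, **kwargs).fit(design)


def plugin_heritability(vc: dict[str, float], dG: float) -> tuple[float, float, float]:
    """Point heritabilities from plug-in variance components.

    Returns ``(h2, H2, sigma2_P)`` using the plot-level formulas.
    """
    sP = vc["l"] + dG * vc["g"] + vc["f"] + vc["s"] + vc["e"]
    h2 = dG * vc["g"] / sP
    H2 = (vc["l"] + dG * vc["g"]) / sP
    return h2, H2, sP


def mcmc_diagnostics(
    chains: dict[str, np.ndarray], mcse_threshold: float = 0.05
) -> pd.DataFrame:
    """Effective sample size and Monte Carlo standard error per chain.

    ``MCSE = sd / sqrt(ESS)`` with autocorrelation-adjusted ESS.
    Chains shorter than 50 draws raise; degenerate (constant) chains
    are flagged rather than failing.
    """
    import arviz as az

    rows = []
    for name, chain in chains.items():
        chain = np.asarray(chain, dtype=float)
        if chain.ndim != 1:
            raise ValueError(f"chain {name!r} must be 1-D")
        if len(chain) < 50:
            raise ValueError(f"chain {name!r} has fewer than 50 draws")
        sd = chain.std(ddof=1)
        if sd == 0:
            ess, mcse, flag = np.nan, np.nan, True
        else:
            with np.errstate(all="ignore"):
                ess = float(az.ess(chain))
            mcse = sd / np.sqrt(ess) if np.isfinite(ess) and ess > 0 else np.nan
            flag = not np.isfinite(mcse) or mcse > mcse_threshold
        rows.append(
            {"param": name, "mean": chain.mean(), "sd": sd,
             "ess": ess, "mcse": mcse, "flagged": bool(flag)}
        )
    return pd.DataFrame(rows).set_index("param")
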