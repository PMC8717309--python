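"""Bayesian linear mixed model with a phylogenetic random effect.

Model, for n species with response y (log(SGS + 1)) and design matrix X
(intercept plus log-transformed seed traits):

    y = X b + a + e,   a ~ N(0, s2p * R),   e ~ N(0, s2e * I)

where R is the phylogenetic correlation matrix (shared root-path lengths,
standardized to unit diagonal). Lynch's phylogenetic heritability,
h2 = s2p / (s2p + s2e), measures the proportion of between-species variance
attributable to phylogeny.

Inference is blocked Gibbs sampling with conjugate updates, performed in the
eigenbasis of R (R = U L U'), which makes every conditional diagonal:

* b | s2p, s2e  — the random effect is integrated out analytically, so b is
  drawn from the exact marginal conditional N(bhat, (X' V^-1 X)^-1) with
  V = s2p R + s2e I (a flat prior on b);
* a | b, s2p, s2e — independent normals in the eigenbasis;
* s2p, s2e — inverse-gamma (default IG(0.001, 0.001) on both), optionally
  held fixed for validation against the closed-form conjugate posterior.

Model comparison uses the deviance information criterion with the *marginal*
Gaussian deviance, y ~ N(Xb, s2p R + s2e I) (random effects integrated out):
Dbar = mean deviance over draws, pD = Dbar - D(posterior means),
DIC = Dbar + pD. Models within 2 DIC units of the best are competing.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TransformError, ValidationError
from .phylo import PhyloCovariance

__all__ = [
    "ModelSpec",
    "PmmPosterior",
    "ModelRanking",
    "design_matrix",
    "gibbs_sample",
    "heritability",
    "hpd_interval",
    "dic",
    "enumerate_models",
]

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ModelSpec:
    """Chain and model configuration.

    Defaults are desk scale (tens of seconds per fit); production-scale chains
    are configured by raising ``iterations``/``burn_in``/``thin``.
    """

    response: str = "sgs"
    predictors: tuple[str, ...] = ("density", "ei", "area")
    include_phylogeny: bool = True
    iterations: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    prior_shape: float = 0.001
    prior_rate: float = 0.001
    variance_prior: str = "ig"  # "ig" | "px" (parameter expansion for s2p)
    px_alpha_var: float = 1.0
    px_nu: float = 1.0
    fixed_variances: tuple[float, float] | None = None  # (s2p, s2e); validation only

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValidationError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")
        if self.variance_prior not in ("ig", "px"):
            raise ValidationError("variance_prior must be 'ig' or 'px'")


@dataclass
class PmmPosterior:
    """Retained MCMC draws and derived summaries."""

    beta: np.ndarray          # (m, p)
    sigma2_p: np.ndarray      # (m,); all zero for the no-phylogeny model
    sigma2_e: np.ndarray      # (m,)
    h2: np.ndarray            # (m,)
    predictor_names: list[str]
    spec: ModelSpec
    diagnostics: dict = field(default_factory=dict)
    dic: float | None = None
    pd_eff: float | None = None
    skipped_draws: int = 0

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.predictor_names):
            lo, hi = hpd_interval(self.beta[:, j])
            rows.append({"parameter": name, "mean": self.beta[:, j].mean(),
                         "hpd_low": lo, "hpd_high": hi})
        for name, draws in (("sigma2_p", self.sigma2_p),
                            ("sigma2_e", self.sigma2_e), ("h2", self.h2)):
            lo, hi = hpd_interval(draws)
            rows.append({"parameter": name, "mean": draws.mean(),
                         "hpd_low": lo, "hpd_high": hi})
        return pd.DataFrame(rows)


def design_matrix(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Response and design matrix on the model scale.

    y = log(SGS + 1); X = [1 | log(predictors)] in the spec's column order.
    Rows must already be restricted to modelled species (zero-capacity species
    excluded upstream); any missing or non-positive value is an error naming
    the offending species.
    """
    cols = [spec.response, *spec.predictors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"columns absent from table: {missing}")
    sub = table.loc[:, ["species", *cols]]
    bad = sub[sub[cols].isna().any(axis=1)]
    if len(bad):
        raise ValidationError(
            f"missing values for species: {list(bad['species'])}; "
            "exclude them before modelling"
        )
    y = np.log1p(sub[spec.response].to_numpy(dtype=float))
    if np.isnan(y).any():
        raise TransformError("response contains values below -1")
    columns = [np.ones(len(sub))]
    names = ["intercept"]
    for p in spec.predictors:
        v = sub[p].to_numpy(dtype=float)
        if (v <= 0).any():
            rows = list(sub.loc[v <= 0, "species"])
            raise TransformError(f"non-positive {p!r} for species {rows}")
        columns.append(np.log(v))
        names.append(p)
    X = np.column_stack(columns)
    return y, X, names


def _as_matrix(R: PhyloCovariance | np.ndarray | None) -> np.ndarray | None:
    if R is None:
        return None
    if isinstance(R, PhyloCovariance):
        return R.matrix
    return np.asarray(R, dtype=float)


def _sample_inverse_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def gibbs_sample(
    y: np.ndarray,
    X: np.ndarray,
    R: PhyloCovariance | np.ndarray | None,
    spec: ModelSpec,
) -> PmmPosterior:
    """Draw from the posterior of the phylogenetic mixed model.

    ``R`` is the phylogenetic correlation (or covariance) matrix; ``None``
    fits the independent-residuals model (h2 reported as 0 by construction).
    Deterministic for a given seed and spec. Split-chain R-hat and effective
    sample sizes (via arviz) are stored in ``diagnostics``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError("y and X have inconsistent shapes")
    Rm = _as_matrix(R)
    rng = np.random.default_rng(spec.seed)

    use_phylo = Rm is not None
    if use_phylo:
        if Rm.shape != (n, n):
            raise ValidationError("R has wrong shape")
        lam, U = np.linalg.eigh(Rm)
        if lam.min() <= 1e-10:
            raise ValidationError(
                "phylogenetic matrix is not positive definite "
                f"(min eigenvalue {lam.min():.3e})"
            )
        yt = U.T @ y
        Xt = U.T @ X
    else:
        lam = np.ones(n)
        yt, Xt = y, X

    a0, b0 = spec.prior_shape, spec.prior_rate
    fixed = spec.fixed_variances
    if fixed is not None:
        s2p, s2e = float(fixed[0]), float(fixed[1])
        if s2e <= 0 or (use_phylo and s2p <= 0) or s2p < 0:
            raise ValidationError("fixed variances must be positive")
        if not use_phylo:
            s2p = 0.0
    else:
        # Initialize from OLS residual variance.
        beta_ols, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = yt - Xt @ beta_ols
        s2e = max(float(resid @ resid) / max(n - p, 1), 1e-6)
        s2p = s2e if use_phylo else 0.0

    # Parameter expansion: a = alpha * a_tilde, s2p = alpha^2 * s2t. The
    # implied prior on sigma_p (half-Cauchy-like for nu = 1) keeps mass away
    # from zero, where the inverse-gamma shape piles up.
    px = spec.variance_prior == "px" and use_phylo and fixed is None
    alpha = 1.0
    s2t = s2p if s2p > 0 else s2e

    n_keep = math.ceil((spec.iterations - spec.burn_in) / spec.thin)
    beta_draws = np.empty((n_keep, p))
    s2p_draws = np.empty(n_keep)
    s2e_draws = np.empty(n_keep)

    XtT = Xt.T
    keep = 0
    for it in range(spec.iterations):
        d = 1.0 / (s2p * lam + s2e)  # diagonal of V^-1 in eigenbasis
        # --- b | s2p, s2e (random effect integrated out; flat prior) ---
        A = XtT @ (d[:, None] * Xt)
        bvec = XtT @ (d * yt)
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"singular precision at iteration {it}") from exc
        mean = np.linalg.solve(A, bvec)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        resid = yt - Xt @ beta

        if use_phylo:
            if px:
                # --- a_tilde | rest (working scale), then alpha | a_tilde ---
                prec = 1.0 / (s2t * lam) + alpha * alpha / s2e
                v = 1.0 / prec
                a_t = v * alpha * resid / s2e + np.sqrt(v) * rng.standard_normal(n)
                denom = float(a_t @ a_t) / s2e + 1.0 / spec.px_alpha_var
                num = float(a_t @ resid) / s2e
                alpha = num / denom + math.sqrt(1.0 / denom) * rng.standard_normal()
                s2t = _sample_inverse_gamma(
                    rng,
                    0.5 * spec.px_nu + 0.5 * n,
                    0.5 * spec.px_nu + 0.5 * float(np.sum(a_t * a_t / lam)),
                )
                err = resid - alpha * a_t
                s2e = _sample_inverse_gamma(
                    rng, a0 + 0.5 * n, b0 + 0.5 * float(err @ err)
                )
                s2p = alpha * alpha * s2t
            else:
                # --- a | b, variances: diagonal normal in eigenbasis ---
                prec = 1.0 / (s2p * lam) + 1.0 / s2e
                v = 1.0 / prec
                a_mean = v * resid / s2e
                a_t = a_mean + np.sqrt(v) * rng.standard_normal(n)
                if fixed is None:
                    s2p = _sample_inverse_gamma(
                        rng, a0 + 0.5 * n, b0 + 0.5 * float(np.sum(a_t * a_t / lam))
                    )
                    err = resid - a_t
                    s2e = _sample_inverse_gamma(
                        rng, a0 + 0.5 * n, b0 + 0.5 * float(err @ err)
                    )
        else:
            if fixed is None:
                s2e = _sample_inverse_gamma(
                    rng, a0 + 0.5 * n, b0 + 0.5 * float(resid @ resid)
                )
        if not np.isfinite(s2e) or (use_phylo and not np.isfinite(s2p)):
            raise ValidationError(f"variance overflow at iteration {it}")

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            beta_draws[keep] = beta
            s2p_draws[keep] = s2p
            s2e_draws[keep] = s2e
            keep += 1

    beta_draws = beta_draws[:keep]
    s2p_draws = s2p_draws[:keep]
    s2e_draws = s2e_draws[:keep]
    h2 = np.where(
        s2p_draws + s2e_draws > 0, s2p_draws / (s2p_draws + s2e_draws), 0.0
    )
    if not use_phylo:
        h2 = np.zeros_like(s2e_draws)

    post = PmmPosterior(
        beta=beta_draws,
        sigma2_p=s2p_draws if use_phylo else np.zeros(keep),
        sigma2_e=s2e_draws,
        h2=h2,
        predictor_names=[f"b{j}" for j in range(p)],
        spec=spec,
        diagnostics=_chain_diagnostics(beta_draws, s2e_draws, h2, use_phylo),
    )
    d, pd_eff, skipped = dic(post, y, X, R)
    post.dic, post.pd_eff, post.skipped_draws = d, pd_eff, skipped
    return post


def _chain_diagnostics(
    beta: np.ndarray, s2e: np.ndarray, h2: np.ndarray, use_phylo: bool
) -> dict:
    """Split-half R-hat and ESS via arviz on the retained draws."""
    m = beta.shape[0]
    if m < 8:
        return {}
    import arviz as az

    half = m // 2
    out: dict[str, float] = {}
    series = {"sigma2_e": s2e}
    for j in range(beta.shape[1]):
        series[f"b{j}"] = beta[:, j]
    if use_phylo:
        series["h2"] = h2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, draws in series.items():
            split = np.stack([draws[:half], draws[half: 2 * half]])
            out[f"rhat_{name}"] = float(az.rhat(split))
            out[f"ess_{name}"] = float(az.ess(np.asarray(draws)[None, :]))
    return out


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    m = len(x)
    if m == 0:
        raise ValidationError("no draws")
    k = max(int(math.ceil(prob * m)), 1)
    if k >= m:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def heritability(posterior: PmmPosterior, prob: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Posterior mean h2 and its highest-posterior-density interval."""
    if posterior.n_draws < 100:
        warnings.warn(
            f"only {posterior.n_draws} retained draws; heritability summary is noisy",
            UserWarning,
            stacklevel=2,
        )
    h2 = posterior.h2
    return float(h2.mean()), hpd_interval(h2, prob)


def _marginal_deviance(
    yt: np.ndarray, Xt: np.ndarray, lam: np.ndarray,
    beta: np.ndarray, s2p: np.ndarray, s2e: np.ndarray,
) -> np.ndarray:
    """-2 log N(y; Xb, s2p R + s2e I) per draw, in the eigenbasis of R."""
    n = len(yt)
    denom = s2p[:, None] * lam[None, :] + s2e[:, None]
    resid = yt[None, :] - beta @ Xt.T
    ll = -0.5 * (n * LOG_2PI + np.log(denom).sum(axis=1) + (resid**2 / denom).sum(axis=1))
    return -2.0 * ll


def dic(
    posterior: PmmPosterior,
    y: np.ndarray,
    X: np.ndarray,
    R: PhyloCovariance | np.ndarray | None,
) -> tuple[float, float, int]:
    """Deviance information criterion with the marginal Gaussian deviance.

    Returns (DIC, pD, n_skipped_draws). Draws with a numerically singular
    marginal covariance are skipped and counted.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Rm = _as_matrix(R)
    if Rm is not None:
        lam, U = np.linalg.eigh(Rm)
        yt, Xt = U.T @ y, U.T @ X
    else:
        lam = np.zeros(len(y))  # s2p is zero anyway for the no-phylogeny model
        yt, Xt = y, X

    denom = posterior.sigma2_p[:, None] * lam[None, :] + posterior.sigma2_e[:, None]
    ok = (denom > 0).all(axis=1) & np.isfinite(denom).all(axis=1)
    skipped = int((~ok).sum())
    if not ok.any():
        raise ValidationError("all draws yield singular marginal covariance")
    D = _marginal_deviance(
        yt, Xt, lam,
        posterior.beta[ok], posterior.sigma2_p[ok], posterior.sigma2_e[ok],
    )
    dbar = float(D.mean())
    d_at_mean = float(
        _marginal_deviance(
            yt, Xt, lam,
            posterior.beta[ok].mean(axis=0, keepdims=True),
            np.array([posterior.sigma2_p[ok].mean()]),
            np.array([posterior.sigma2_e[ok].mean()]),
        )[0]
    )
    pd_eff = dbar - d_at_mean
    return dbar + pd_eff, pd_eff, skipped


@dataclass
class ModelRanking:
    """All-subsets DIC ranking; models within 2 units of the best compete."""

    table: pd.DataFrame  # columns: model, predictors, k, dic, pd, delta_dic, competing, failed
    posteriors: dict[str, PmmPosterior]

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])

    @property
    def competing(self) -> list[str]:
        return list(self.table.loc[self.table["competing"], "model"])


def enumerate_models(
    table: pd.DataFrame,
    predictors: Sequence[str],
    R: PhyloCovariance | np.ndarray | None,
    spec: ModelSpec,
    keep_posteriors: bool = False,
) -> ModelRanking:
    """Fit every predictor subset (including intercept-only) and rank by DIC.

    Ties are broken by parameter count, then lexicographic predictor order.
    Subsets that fail to sample are recorded as failed, never silently dropped.
    """
    predictors = list(predictors)
    if len(predictors) > 12:
        raise ValidationError("refusing to enumerate more than 2^12 subsets")
    rows = []
    posteriors: dict[str, PmmPosterior] = {}
    for idx, k in enumerate(
        itertools.chain.from_iterable(
            itertools.combinations(predictors, r) for r in range(len(predictors) + 1)
        )
    ):
        label = "+".join(k) if k else "intercept"
        sub_spec = replace(spec, predictors=tuple(k), seed=spec.seed + idx + 1)
        try:
            y, X, _ = design_matrix(table, sub_spec)
            post = gibbs_sample(y, X, R, sub_spec)
        except ValidationError as exc:
            rows.append({"model": label, "predictors": list(k), "k": len(k) + 1,
                         "dic": np.nan, "pd": np.nan, "failed": str(exc)})
            continue
        rows.append({"model": label, "predictors": list(k), "k": len(k) + 1,
                     "dic": post.dic, "pd": post.pd_eff, "failed": ""})
        if keep_posteriors:
            posteriors[label] = post

    df = pd.DataFrame(rows)
    df["_lex"] = df["predictors"].map(lambda ps: tuple(sorted(ps)))
    df = df.sort_values(
        by=["dic", "k", "_lex"], na_position="last", kind="mergesort"
    ).drop(columns="_lex").reset_index(drop=True)
    fitted = df["dic"].notna()
    best = df.loc[fitted, "dic"].min()
    df["delta_dic"] = df["dic"] - best
    df["competing"] = fitted & (df["delta_dic"] <= 2.0)
    return ModelRanking(table=df, posteriors=posteriors)
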