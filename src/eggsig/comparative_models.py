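"""Comparative statistics relating egg-signature defences to brood parasitism.

Species are classified as parasitized from clutch-level parasitism records
(any non-zero local rate counts), with a restrictive alternative that also
promotes species with parasitism records from elsewhere in their range. The
three defence measures are then modelled with ordinary least squares
(parasitism status + family + sample size as fixed effects), with
interaction models for group-specific consistency–distinctiveness slopes, and
a battery of robustness variants: rank-transformed responses, sample-size
weighting, Cook's-distance outlier exclusion, resampling every species to a
minimum clutch count, and phylogenetic generalized least squares (PGLS) with
Pagel's λ estimated by maximum likelihood over a set of candidate trees.

Statuses are coded with *unparasitized* as the reference level, so the
interaction coefficient equals the parasitized-group slope minus the
unparasitized-group slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .schema import RESULT_COLUMNS

logger = logging.getLogger(__name__)

STATUS_LEVELS = ["unparasitized", "parasitized"]  # reference level first


# ---------------------------------------------------------------------------
# parasitism classification
# ---------------------------------------------------------------------------


def classify_parasitism(eggs: pd.DataFrame) -> pd.DataFrame:
    """Per-species parasitism status from clutch-level records.

    The local rate is (parasitized clutches) / (scored clutches);
    ``status_local`` is parasitized iff the rate is non-zero, and
    ``status_restrictive`` additionally promotes species with parasitism
    records from elsewhere in their range.
    """
    rows = []
    for species, grp in eggs.groupby("species", sort=False):
        clutches = grp.drop_duplicates("clutch_id")
        n = len(clutches)
        if n == 0:
            raise ValueError(f"species {species!r} has no scored clutches")
        n_par = int(clutches["parasitized"].sum())
        rate = n_par / n
        elsewhere = bool(clutches["parasitized_elsewhere"].iloc[0]) if "parasitized_elsewhere" in clutches else False
        local = "parasitized" if rate > 0 else "unparasitized"
        restrictive = "parasitized" if (rate > 0 or elsewhere) else "unparasitized"
        rows.append(
            {
                "species": species,
                "n_scored_clutches": n,
                "n_parasitized_clutches": n_par,
                "parasitism_rate_local": rate,
                "parasitized_elsewhere": elsewhere,
                "status_local": local,
                "status_restrictive": restrictive,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear model machinery
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Coefficients and diagnostics of one (possibly weighted / phylogenetic) fit."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    nobs: int
    residuals: np.ndarray
    fittedvalues: np.ndarray
    loglik: float
    weights: np.ndarray | None = None
    lam: float | None = None
    design: pd.DataFrame | None = None
    response: np.ndarray | None = None

    def summary_rows(self) -> list[dict]:
        return [
            {
                "term": term,
                "estimate": float(self.params[term]),
                "se": float(self.bse[term]),
                "t": float(self.tvalues[term]),
                "df": int(self.df_resid),
                "p": float(self.pvalues[term]),
                "lambda": self.lam,
                "n": int(self.nobs),
            }
            for term in self.params.index
        ]


def _check_full_rank(X: pd.DataFrame) -> None:
    x = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name columns whose removal restores full column rank
        bad = [
            col
            for i, col in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def build_design(
    df: pd.DataFrame,
    predictors: list[str],
    status_column: str = "status_local",
    interaction_with_status: str | None = None,
) -> pd.DataFrame:
    """Build a design matrix with intercept, dummy-coded factors and covariates.

    ``status`` is coded 0/1 with unparasitized as reference; ``family`` with
    the first family (alphabetically) as reference. ``interaction_with_status``
    adds a (predictor × parasitized) column, whose coefficient is the
    parasitized-minus-unparasitized slope difference.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(df))}
    for term in predictors:
        if term == "status":
            cols["status[parasitized]"] = (df[status_column] == "parasitized").to_numpy(float)
        elif term == "family":
            levels = sorted(df["family"].unique())
            for lvl in levels[1:]:
                cols[f"family[{lvl}]"] = (df["family"] == lvl).to_numpy(float)
        else:
            cols[term] = df[term].to_numpy(float)
    if interaction_with_status is not None:
        cols[f"{interaction_with_status}:status[parasitized]"] = (
            df[interaction_with_status].to_numpy(float)
            * (df[status_column] == "parasitized").to_numpy(float)
        )
    return pd.DataFrame(cols, index=df.index)


def fit_ols(
    response: np.ndarray | pd.Series,
    design: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> ModelFit:
    """(Weighted) least squares with classical standard errors and t-tests."""
    y = np.asarray(response, dtype=float)
    if len(y) <= design.shape[1]:
        raise ValueError("more parameters than observations")
    _check_full_rank(design)
    if weights is None:
        res = sm.OLS(y, design).fit()
    else:
        res = sm.WLS(y, design, weights=np.asarray(weights, float)).fit()
    return ModelFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        residuals=np.asarray(res.resid),
        fittedvalues=np.asarray(res.fittedvalues),
        loglik=float(res.llf),
        weights=None if weights is None else np.asarray(weights, float),
        design=design,
        response=y,
    )


def fit_interaction_model(
    table: pd.DataFrame,
    predictor: str,
    status_column: str = "status_local",
    covariates: list[str] | None = None,
    response: str = "consistency",
) -> dict:
    """Interaction model plus within-group simple-slope fits.

    Returns ``{"interaction": ModelFit, "additive": ModelFit,
    "groups": {status: ModelFit}}``. Both parasitism groups must contain at
    least 3 species for the group-wise fits to be estimable.
    """
    covariates = ["family", "n_clutches_used"] if covariates is None else covariates
    counts = table[status_column].value_counts()
    if len(counts) < 2 or counts.min() < 3:
        raise ValueError("both parasitism groups must be present with >= 3 species")

    terms = [predictor, "status"] + covariates
    additive = fit_ols(table[response], build_design(table, terms, status_column))
    inter = fit_ols(
        table[response],
        build_design(table, terms, status_column, interaction_with_status=predictor),
    )
    groups = {}
    for status, grp in table.groupby(status_column):
        gterms = [predictor] + [c for c in covariates if c != "family" or grp["family"].nunique() > 1]
        groups[status] = fit_ols(grp[response], build_design(grp, gterms, status_column))
    return {"interaction": inter, "additive": additive, "groups": groups}


def cooks_distance(fit: ModelFit, flag_threshold: float | None = None) -> pd.DataFrame:
    """Classical Cook's D per observation from the hat matrix.

    ``D_i = r_i² h_ii / (p s² (1 − h_ii)²)``; for weighted fits the formula is
    applied to the whitened (√w-scaled) problem. Observations with
    ``D > 4/n`` (configurable) are flagged.
    """
    X = fit.design.to_numpy(dtype=float)
    r = fit.residuals.copy()
    if fit.weights is not None:
        sw = np.sqrt(fit.weights)
        X = X * sw[:, None]
        r = r * sw
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    scale = max(1.0, float(np.abs(fit.fittedvalues).max()))
    if np.abs(r).max() <= 1e-12 * scale:  # perfect fit: no influence to measure
        d = np.zeros(n)
    else:
        s2 = float(r @ r) / (n - p)
        d = r**2 * h / (p * s2 * (1.0 - h) ** 2)
    threshold = 4.0 / n if flag_threshold is None else flag_threshold
    return pd.DataFrame(
        {"cooks_d": d, "leverage": h, "flagged": d > threshold}, index=fit.design.index
    )


def rank_transform(values) -> np.ndarray:
    """Ascending ranks with ties given average ranks."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to rank")
    return stats.rankdata(v, method="average")


# ---------------------------------------------------------------------------
# phylogenetic machinery
# ---------------------------------------------------------------------------


def phylo_covariance(tree: dendropy.Tree, lam: float = 1.0) -> tuple[list[str], np.ndarray]:
    """λ-scaled Brownian covariance among the tips of ``tree``.

    Entry (i, j) is the shared root-to-tip branch length of tips i and j (the
    root depth of their most recent common ancestor); λ multiplies the
    off-diagonal entries only. Returns tip labels and the matrix in that order.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    vcv = np.zeros((n, n))

    # postorder: each node knows its root depth and its descendant tip set;
    # tips first meeting at a node share that node's depth.
    depths: dict = {}
    for node in tree.preorder_node_iter():
        parent_depth = depths.get(node.parent_node, 0.0)
        depths[node] = parent_depth + (node.edge.length or 0.0)
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tipsets[node] = [i]
            vcv[i, i] = depths[node]
        else:
            children = [tipsets[c] for c in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        vcv[i, children[b]] = depths[node]
                        vcv[children[b], i] = depths[node]
            tipsets[node] = [i for sub in children for i in sub]
    if lam != 1.0:
        off = vcv - np.diag(np.diag(vcv))
        vcv = lam * off + np.diag(np.diag(vcv))
    return labels, vcv


def _gls_profile_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> tuple[float, np.ndarray]:
    """ML log-likelihood of a GLS model with variance profiled out."""
    n = len(y)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance") from exc
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    r = yi - Xi @ beta
    rss = float(r @ r)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta


@dataclass
class LambdaFit:
    lam: float
    loglik: float
    loglik_zero: float
    lr_statistic: float
    p_value: float
    unidentifiable: bool = False


def estimate_lambda(
    trait: pd.Series,
    tree: dendropy.Tree,
    design: pd.DataFrame | None = None,
) -> LambdaFit:
    """Profile-ML Pagel's λ on [0, 1] with a likelihood-ratio test against λ = 0.

    The likelihood is the Gaussian GLS likelihood with mean given by ``design``
    (default: intercept only) and covariance λV + (1−λ)diag(V). λ is found by
    a coarse grid followed by bounded refinement (tolerance 1e-8); the p-value
    compares 2·ΔlogL against χ²₁ (at the λ̂ = 0 boundary this is conservative).
    On a star tree the likelihood is constant in λ and the fit is flagged
    unidentifiable.
    """
    if len(trait) < 4:
        raise ValueError("need at least 4 species")
    labels, V = phylo_covariance(tree, 1.0)
    missing = [lab for lab in trait.index if lab not in set(labels)]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    order = [lab for lab in labels if lab in set(trait.index)]
    idx = [labels.index(lab) for lab in order]
    V = V[np.ix_(idx, idx)]
    y = trait.loc[order].to_numpy(dtype=float)
    X = np.ones((len(y), 1)) if design is None else design.loc[order].to_numpy(dtype=float)
    diag = np.diag(np.diag(V))
    off = V - diag

    def nll(lam: float) -> float:
        return -_gls_profile_loglik(y, X, lam * off + diag)[0]

    grid = np.linspace(0.0, 1.0, 21)
    vals = np.array([nll(g) for g in grid])
    if vals.max() - vals.min() < 1e-10:
        ll = -float(vals[0])
        return LambdaFit(0.0, ll, ll, 0.0, 1.0, unidentifiable=True)
    i = int(np.argmin(vals))
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8})
    lam_hat, ll_hat = float(res.x), -float(res.fun)
    # the optimum may sit exactly on a boundary
    for cand in (0.0, 1.0):
        if -nll(cand) >= ll_hat:
            lam_hat, ll_hat = cand, -nll(cand)
    ll0 = -nll(0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return LambdaFit(lam_hat, ll_hat, ll0, lr, p)


def fit_pgls(
    response: pd.Series,
    design: pd.DataFrame,
    tree: dendropy.Tree,
    lam: float | str = "ML",
) -> ModelFit:
    """GLS with λ-scaled phylogenetic error covariance.

    λ is estimated by profile ML jointly with the coefficients unless a fixed
    value is given. Standard errors use the unbiased variance estimate
    (df = n − p); family membership is conventionally excluded from
    phylogenetic runs since the phylogeny already separates the families.
    Response and design rows are aligned to tree tips by index label.
    """
    labels, V = phylo_covariance(tree, 1.0)
    present = set(response.index)
    missing = [lab for lab in present if lab not in set(labels)]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    order = [lab for lab in labels if lab in present]
    y = response.loc[order].to_numpy(dtype=float)
    X = design.loc[order]
    _check_full_rank(X)
    x = X.to_numpy(dtype=float)
    idx = [labels.index(lab) for lab in order]
    V = V[np.ix_(idx, idx)]
    diag = np.diag(np.diag(V))
    off = V - diag

    if lam == "ML":
        grid = np.linspace(0.0, 1.0, 21)
        vals = [-_gls_profile_loglik(y, x, g * off + diag)[0] for g in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
        res = optimize.minimize_scalar(
            lambda g: -_gls_profile_loglik(y, x, g * off + diag)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        for cand in (0.0, 1.0):
            if _gls_profile_loglik(y, x, cand * off + diag)[0] >= -res.fun:
                lam_hat = cand
    else:
        lam_hat = float(lam)

    Vl = lam_hat * off + diag
    ll, _ = _gls_profile_loglik(y, x, Vl)
    Vinv = np.linalg.inv(Vl)
    xtvx_inv = np.linalg.inv(x.T @ Vinv @ x)
    beta = xtvx_inv @ (x.T @ Vinv @ y)
    r = y - x @ beta
    n, p = x.shape
    s2 = float(r @ Vinv @ r) / (n - p)
    bse = np.sqrt(np.diag(s2 * xtvx_inv))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    terms = list(X.columns)
    return ModelFit(
        params=pd.Series(beta, index=terms),
        bse=pd.Series(bse, index=terms),
        tvalues=pd.Series(tvals, index=terms),
        pvalues=pd.Series(pvals, index=terms),
        df_resid=n - p,
        nobs=n,
        residuals=r,
        fittedvalues=x @ beta,
        loglik=ll,
        lam=lam_hat,
        design=X,
        response=y,
    )


@dataclass
class LambdaSummary:
    per_tree: pd.DataFrame  # columns: tree, lambda, p, note
    lam_mean: float
    lam_sd: float
    p_min: float
    p_max: float
    n_failed: int


def lambda_over_trees(
    trait: pd.Series, trees: list[dendropy.Tree], design: pd.DataFrame | None = None
) -> LambdaSummary:
    """Estimate λ on each candidate tree; summarize as mean ± s.d. and p range."""
    if not trees:
        raise ValueError("need at least one tree")
    rows = []
    for i, tree in enumerate(trees):
        try:
            fit = estimate_lambda(trait, tree, design)
            rows.append({"tree": i, "lambda": fit.lam, "p": fit.p_value, "note": ""})
        except Exception as exc:  # per-tree failures recorded, not fatal
            logger.warning("lambda estimation failed on tree %d: %s", i, exc)
            rows.append({"tree": i, "lambda": np.nan, "p": np.nan, "note": str(exc)})
    per = pd.DataFrame(rows)
    ok = per.dropna(subset=["lambda"])
    return LambdaSummary(
        per_tree=per,
        lam_mean=float(ok["lambda"].mean()),
        lam_sd=float(ok["lambda"].std(ddof=1)) if len(ok) > 1 else 0.0,
        p_min=float(ok["p"].min()),
        p_max=float(ok["p"].max()),
        n_failed=int(per["note"].astype(bool).sum()),
    )


# ---------------------------------------------------------------------------
# the full model battery
# ---------------------------------------------------------------------------

RESPONSES = ["consistency", "absolute_distinctiveness", "combinatorial_distinctiveness"]
PREDICTORS = ["absolute_distinctiveness", "combinatorial_distinctiveness"]


def _rows(model_id: str, variant: str, response: str, fit: ModelFit, note: str = "") -> list[dict]:
    rows = []
    for row in fit.summary_rows():
        row.update({"model_id": model_id, "variant": variant, "response": response, "note": note})
        rows.append(row)
    return rows


def run_full_battery(
    signatures: pd.DataFrame,
    statuses: pd.DataFrame,
    trees: list[dendropy.Tree] | None = None,
    eggs: pd.DataFrame | None = None,
    seed: int = 0,
    variants: list[str] | None = None,
    resample_to: int = 5,
    cooks_top_k: int = 2,
) -> pd.DataFrame:
    """Run the full grid of defence models and robustness variants.

    The grid is (i) each defence measure ~ status + family + sample size,
    (ii) consistency ~ each distinctiveness component, additive and with a
    status interaction plus group-wise simple slopes; variants re-run the grid
    with the restrictive status, rank-transformed responses, sample-size
    weights (covariate dropped), species resampled to ``resample_to`` clutches
    (needs per-egg data), Cook's-distance outliers excluded, and PGLS on the
    first supplied tree (family dropped). One tidy row per model term; any
    variant failure is recorded in ``note`` and the run continues.
    """
    variants = (
        ["baseline", "restrictive", "rank", "weighted", "resampled", "outliers_excluded", "pgls"]
        if variants is None
        else variants
    )
    table = signatures.merge(statuses, on="species", how="left")
    table = table.set_index("species", drop=False)
    defined = table[~table["undefined_entropy"].astype(bool)]

    out: list[dict] = []

    def grid(tab: pd.DataFrame, variant: str, status_col: str, *, rank: bool = False,
             weighted: bool = False, pgls_tree=None, exclude_outliers: bool = False) -> None:
        covs = ["status"] + (["family"] if pgls_tree is None else []) + (
            [] if (weighted or variant == "resampled") else ["n_clutches_used"]
        )
        for response in RESPONSES:
            sub = tab if response == "consistency" else tab[~tab["undefined_entropy"].astype(bool)]
            sub = sub.dropna(subset=[response])
            model_id = f"{response}~status"
            try:
                y = rank_transform(sub[response]) if rank else sub[response]
                y = pd.Series(np.asarray(y, float), index=sub.index)
                X = build_design(sub, covs, status_col)
                w = sub["n_clutches_used"].to_numpy(float) if weighted else None
                if exclude_outliers:
                    base = fit_ols(y, X, weights=w)
                    flags = cooks_distance(base)
                    drop = flags.sort_values("cooks_d", ascending=False)
                    drop = drop[drop["flagged"]].head(cooks_top_k).index
                    keep = ~sub.index.isin(drop)
                    sub, y, X = sub[keep], y[keep], X[keep]
                    w = w[keep] if w is not None else None
                if pgls_tree is not None:
                    fit = fit_pgls(y, X, pgls_tree)
                else:
                    fit = fit_ols(y, X, weights=w)
                out.extend(_rows(model_id, variant, response, fit))
            except Exception as exc:
                logger.warning("model %s (%s) failed: %s", model_id, variant, exc)
                out.append({"model_id": model_id, "variant": variant, "response": response,
                            "term": "", "note": f"failed: {exc}"})
        for predictor in PREDICTORS:
            sub = tab[~tab["undefined_entropy"].astype(bool)].dropna(
                subset=["consistency", predictor]
            )
            model_id = f"consistency~{predictor}"
            try:
                y = rank_transform(sub["consistency"]) if rank else sub["consistency"]
                y = pd.Series(np.asarray(y, float), index=sub.index)
                terms = [predictor] + covs
                X_add = build_design(sub, terms, status_col)
                X_int = build_design(sub, terms, status_col, interaction_with_status=predictor)
                w = sub["n_clutches_used"].to_numpy(float) if weighted else None
                if exclude_outliers:
                    base = fit_ols(y, X_int, weights=w)
                    flags = cooks_distance(base)
                    drop = flags.sort_values("cooks_d", ascending=False)
                    drop = drop[drop["flagged"]].head(cooks_top_k).index
                    keep = ~sub.index.isin(drop)
                    sub, y = sub[keep], y[keep]
                    X_add, X_int = X_add[keep], X_int[keep]
                    w = w[keep] if w is not None else None
                if pgls_tree is not None:
                    fit_add = fit_pgls(y, X_add, pgls_tree)
                    fit_int = fit_pgls(y, X_int, pgls_tree)
                else:
                    fit_add = fit_ols(y, X_add, weights=w)
                    fit_int = fit_ols(y, X_int, weights=w)
                out.extend(_rows(model_id + "+additive", variant, "consistency", fit_add))
                out.extend(_rows(model_id + "+interaction", variant, "consistency", fit_int))
                # group-wise simple slopes; a sparse group must not sink its sibling
                for status, grp in sub.groupby(status_col):
                    gid = model_id + f"+group[{status}]"
                    try:
                        gcovs = [c for c in covs if c != "status"]
                        gcovs = [c for c in gcovs if c != "family" or grp["family"].nunique() > 1]
                        yg = y.loc[grp.index]
                        Xg = build_design(grp, [predictor] + gcovs, status_col)
                        wg = grp["n_clutches_used"].to_numpy(float) if weighted else None
                        if pgls_tree is not None:
                            fit_g = fit_pgls(yg, Xg, pgls_tree)
                        else:
                            fit_g = fit_ols(yg, Xg, weights=wg)
                        out.extend(_rows(gid, variant, "consistency", fit_g))
                    except Exception as exc:
                        logger.warning("model %s (%s) failed: %s", gid, variant, exc)
                        out.append({"model_id": gid, "variant": variant,
                                    "response": "consistency", "term": "",
                                    "note": f"failed: {exc}"})
            except Exception as exc:
                logger.warning("model %s (%s) failed: %s", model_id, variant, exc)
                out.append({"model_id": model_id, "variant": variant, "response": "consistency",
                            "term": "", "note": f"failed: {exc}"})

    if "baseline" in variants:
        grid(table, "baseline", "status_local")
    if "restrictive" in variants:
        grid(table, "restrictive", "status_restrictive")
    if "rank" in variants:
        grid(table, "rank", "status_local", rank=True)
    if "weighted" in variants:
        grid(table, "weighted", "status_local", weighted=True)
    if "resampled" in variants:
        if eggs is None:
            out.append({"model_id": "resampled", "variant": "resampled", "term": "",
                        "note": "failed: per-egg data required for resampling"})
        else:
            from .signature_metrics import species_signatures

            try:
                # only consistency is recomputed at the reduced sample size: a
                # handful of clutches cannot support a 10-metric covariance, so
                # distinctiveness keeps its full-sample values
                enough = eggs.groupby("species")["clutch_id"].nunique() >= resample_to
                keep = enough[enough].index
                resig = species_signatures(
                    eggs[eggs["species"].isin(keep)], seed=seed, resample_to=resample_to
                )
                retab = signatures[signatures["species"].isin(keep)].copy()
                retab = retab.merge(
                    resig[["species", "consistency"]].rename(
                        columns={"consistency": "consistency_resampled"}
                    ),
                    on="species",
                )
                retab["consistency"] = retab["consistency_resampled"]
                retab = retab.drop(columns=["consistency_resampled"])
                retab = retab.merge(statuses, on="species", how="left").set_index(
                    "species", drop=False
                )
                grid(retab, "resampled", "status_local")
            except Exception as exc:
                logger.warning("resampled variant failed: %s", exc)
                out.append({"model_id": "resampled", "variant": "resampled", "term": "",
                            "note": f"failed: {exc}"})
    if "outliers_excluded" in variants:
        grid(table, "outliers_excluded", "status_local", exclude_outliers=True)
    if "pgls" in variants:
        if trees:
            grid(table, "pgls", "status_local", pgls_tree=trees[0])
        else:
            out.append({"model_id": "pgls", "variant": "pgls", "term": "",
                        "note": "failed: no trees supplied"})

    result = pd.DataFrame(out)
    for col in RESULT_COLUMNS:
        if col not in result.columns:
            result[col] = np.nan
    result["note"] = result["note"].fillna("")
    return result[RESULT_COLUMNS]
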