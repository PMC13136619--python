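"""Per-gene sparse linear regulatory models with a copy-number covariate.

Each gene's expression over the training cells is modeled as a linear
combination of (a) the expression of all other genes outside a local
exclusion zone of +/-50 positions on the gene's own chromosome (so windowed
copy-number leakage cannot masquerade as regulation) and (b) the gene's own
copy-number estimate.  Predictors are selected along the lasso regularization
path; each predictor entering the path receives a p-value from the covariance
test for lasso (an Exp(1) reference on the drop of the covariance statistic
at its entry knot, noise scale taken from the residuals at the
cross-validation-selected penalty).  Predictors with BH-adjusted q <= 0.01
are retained and their coefficients come from an ordinary least-squares refit.

All path computations run on precomputed inner-product (Gram) matrices shared
across the per-gene subtasks, which makes a few hundred gene models tractable
on a single CPU.  Memory grows with the square of the gene count; the
intended scale is the simulation study and comparable problem sizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lars_path_gram

from codelnet.diffexp import bh_fdr
from codelnet.genomics_io import ExpressionMatrix, GeneAnnotation, PipelineConfig

logger = logging.getLogger(__name__)

EXPRESSION = "expression"
COPY_NUMBER = "copy_number"

PREDICTOR_COLUMNS = ["predictor_id", "kind", "coefficient", "p", "q"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Sparse linear model of one target gene.

    ``predictors`` columns: predictor_id, kind (expression/copy_number),
    coefficient, p, q.  Coefficients are in target-expression units per one
    train-set standard deviation of the predictor; the intercept completes an
    OLS refit on the retained predictors over the training cells.
    """

    target: str
    intercept: float
    predictors: pd.DataFrame
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.predictors):
            expr = self.predictors["kind"] == EXPRESSION
            if (self.predictors.loc[expr, "predictor_id"] == self.target).any():
                raise ValueError(f"model of {self.target} lists itself as predictor")

    @property
    def expression_predictors(self) -> pd.DataFrame:
        return self.predictors[self.predictors["kind"] == EXPRESSION]

    @property
    def has_cn_predictor(self) -> bool:
        return bool((self.predictors["kind"] == COPY_NUMBER).any())


@dataclass
class RegulatoryNetwork:
    """One learned network instance: gene models plus the train/test split and
    the standardization statistics needed to reproduce predictions."""

    instance_id: int
    seed: int
    train_cells: list[str]
    test_cells: list[str]
    models: dict[str, GeneModel]
    train_mean: pd.Series
    train_sd: pd.Series
    cn_mean: pd.Series | None
    cn_sd: pd.Series | None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_cells) & set(self.test_cells):
            raise ValueError("train and test cells overlap")

    @property
    def genes(self) -> list[str]:
        return list(self.models)

    def expression_edges(self) -> pd.DataFrame:
        """Long edge table: source (predictor), target, coefficient, p, q."""
        rows = []
        for target, model in self.models.items():
            for _, r in model.expression_predictors.iterrows():
                rows.append(
                    {
                        "source": r["predictor_id"],
                        "target": target,
                        "coefficient": r["coefficient"],
                        "p": r["p"],
                        "q": r["q"],
                    }
                )
        return pd.DataFrame(rows, columns=["source", "target", "coefficient", "p", "q"])


# ---------------------------------------------------------------------------
# Gene / cell selection
# ---------------------------------------------------------------------------


def filter_variable_genes(X: ExpressionMatrix, cutoff: float = 0.5) -> ExpressionMatrix:
    """Keep genes with sample variance across the analysis cells >= cutoff."""
    var = X.data.var(axis=1, ddof=1)
    keep = var >= cutoff
    if not keep.any():
        raise ValueError(f"no gene reaches the variance cutoff {cutoff}")
    return ExpressionMatrix(X.data.loc[keep], X.transform_scale_factor)


def split_train_test(cell_ids, fraction: float = 2.0 / 3.0, seed: int = 0):
    """Uniformly random train/test split, ``round(fraction * n)`` train cells."""
    cell_ids = list(cell_ids)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if len(cell_ids) < 9:
        raise ValueError("need at least 9 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cell_ids))
    n_train = int(round(fraction * len(cell_ids)))
    train = [cell_ids[i] for i in sorted(perm[:n_train])]
    test = [cell_ids[i] for i in sorted(perm[n_train:])]
    return train, test


def candidate_predictor_set(
    target: str,
    ann: GeneAnnotation,
    analysis_genes=None,
    exclusion: int = 50,
) -> list[str]:
    """All analysis genes except the target and any gene within ``exclusion``
    order positions of it on the same chromosome.

    The local exclusion zone keeps predictors from merely tracking the
    target's chromosomal copy-number neighborhood.
    """
    t = ann.table
    if analysis_genes is not None:
        t = t[t["gene_id"].isin(set(analysis_genes))]
    row = t[t["gene_id"] == target]
    if len(row) == 0:
        raise KeyError(f"target {target!r} not in annotation")
    chrom = row["chromosome"].iloc[0]
    oi = int(row["order_index"].iloc[0])
    local = (t["chromosome"] == chrom) & ((t["order_index"] - oi).abs() <= exclusion)
    return list(t.loc[~local, "gene_id"])


# ---------------------------------------------------------------------------
# Lasso path + covariance test on Gram products
# ---------------------------------------------------------------------------


def _lars_lasso_gram(Xy, Gram, n_samples, max_iter, alpha_min=0.0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alphas, _, coefs = lars_path_gram(
            Xy=Xy, Gram=Gram, n_samples=n_samples, max_iter=max_iter,
            method="lasso", alpha_min=alpha_min,
        )
    return alphas, coefs


def _interp_path(alphas, coefs, alpha):
    """Lasso coefficients at an arbitrary penalty: the LARS path is piecewise
    linear in alpha; above the first knot the solution is 0, below the last
    computed knot it is clamped to the last solution (truncated path)."""
    if alpha >= alphas[0]:
        return np.zeros(coefs.shape[0])
    if alpha <= alphas[-1]:
        return coefs[:, -1]
    j = int(np.searchsorted(-alphas, -alpha, side="left"))
    a_hi, a_lo = alphas[j - 1], alphas[j]
    w = (a_hi - alpha) / (a_hi - a_lo)
    return coefs[:, j - 1] * (1 - w) + coefs[:, j] * w


def _cv_sigma2(Xy, Gram, fold_products, yty, n_samples, max_iter):
    """Noise variance from residuals at the cross-validation-selected penalty.

    ``fold_products``: list of (Xy_t, Gram_t, n_t, Xy_v, Gram_v, yty_v).
    Validation error is evaluated on the knot-alpha grid of the full-train
    path; all quantities are inner products, no data matrices.
    Returns (sigma2, alpha_cv, df_cv).
    """
    alphas, coefs = _lars_lasso_gram(Xy, Gram, n_samples, max_iter)
    grid = alphas
    cv_err = np.zeros(len(grid))
    for Xy_t, Gram_t, n_t, Xy_v, Gram_v, yty_v in fold_products:
        f_alphas, f_coefs = _lars_lasso_gram(Xy_t, Gram_t, n_t, max_iter)
        # knot alphas are already per-sample normalized, hence comparable
        # between the full path and the fold paths
        for i, a in enumerate(grid):
            beta = _interp_path(f_alphas, f_coefs, a)
            nz = np.flatnonzero(beta)
            if len(nz) == 0:
                cv_err[i] += yty_v
                continue
            b = beta[nz]
            cv_err[i] += (
                yty_v - 2.0 * Xy_v[nz] @ b + b @ Gram_v[np.ix_(nz, nz)] @ b
            )
    best = int(np.argmin(cv_err))
    alpha_cv = grid[best]
    beta = coefs[:, best]
    nz = np.flatnonzero(beta)
    rss = yty - 2.0 * Xy[nz] @ beta[nz] + beta[nz] @ Gram[np.ix_(nz, nz)] @ beta[nz]
    df = len(nz)
    sigma2 = max(rss, 0.0) / max(n_samples - df - 1, 1)
    return float(sigma2), float(alpha_cv), df


def _reduced_lasso_coefs(Xy, Gram, n_samples, alpha, s_init, max_rounds=100):
    """Lasso solution restricted to a small predictor set at a fixed penalty,
    via active-set iteration on the KKT conditions (Gram form).

    ``s_init`` are warm-start signs (0 = initially excluded).  Stationarity on
    the support S reads ``beta_S = (G_SS)^-1 (Xy_S - n*alpha*sign_S)``; the
    iteration drops sign-inconsistent variables and admits excluded variables
    whose correlation exceeds the penalty.  Returns the coefficient vector or
    None if it fails to settle (caller falls back to a full path solve).
    """
    m = len(Xy)
    s = np.asarray(s_init, dtype=float).copy()
    lam = n_samples * alpha
    for _ in range(max_rounds):
        S = np.flatnonzero(s)
        beta = np.zeros(m)
        if len(S):
            try:
                b = np.linalg.solve(
                    Gram[np.ix_(S, S)], Xy[S] - lam * s[S]
                )
            except np.linalg.LinAlgError:
                b, *_ = np.linalg.lstsq(
                    Gram[np.ix_(S, S)], Xy[S] - lam * s[S], rcond=None
                )
            beta[S] = b
            mism = S[np.sign(beta[S]) != s[S]]
            if len(mism):
                s[mism] = 0.0
                continue
        resid_cor = Xy - Gram @ beta
        viol = np.flatnonzero((np.abs(resid_cor) > lam * (1 + 1e-9)) & (s == 0))
        if len(viol):
            j = viol[np.argmax(np.abs(resid_cor[viol]))]
            s[j] = np.sign(resid_cor[j])
            continue
        return beta
    return None


def covariance_test_pvalues(Xy, Gram, n_samples, max_iter, sigma2):
    """Covariance-test p-values for every predictor entering the lasso path.

    For a predictor first active at knot ``k`` the statistic is the drop in
    covariance ``(<y, X b(a_{k+1})> - <y, X_A b_A(a_{k+1})>) / sigma2`` with
    ``A`` the active set just before entry; under the null it follows Exp(1),
    so ``p = exp(-T)``.  Entries with no later knot to evaluate against are
    reported at p = 1 (cannot be assessed on a truncated path).

    Returns dict predictor_index -> p.
    """
    alphas, coefs = _lars_lasso_gram(Xy, Gram, n_samples, max_iter)
    nz = coefs != 0.0
    first_knot = {}
    for j in np.flatnonzero(nz.any(axis=1)):
        first_knot[int(j)] = int(np.argmax(nz[j]))
    pvals: dict[int, float] = {}
    for j, k0 in first_knot.items():
        # the stored knot where the coefficient first turns nonzero is the
        # knot immediately AFTER the entry knot, i.e. Lockhart's lambda_{k+1}
        k1 = k0
        beta_full = coefs[:, k1]
        cov_full = float(Xy @ beta_full)
        prev = np.flatnonzero(coefs[:, k0 - 1]) if k0 >= 1 else np.array([], int)
        if len(prev):
            s_init = np.sign(coefs[prev, k1])
            zero = s_init == 0
            if zero.any():
                s_init[zero] = np.sign(coefs[prev, k0 - 1])[zero]
            beta_red = _reduced_lasso_coefs(
                Xy[prev], Gram[np.ix_(prev, prev)], n_samples, alphas[k1], s_init
            )
            if beta_red is None:  # rare: fall back to an explicit path solve
                a_red, c_red = _lars_lasso_gram(
                    Xy[prev], Gram[np.ix_(prev, prev)], n_samples, max_iter,
                    alpha_min=alphas[k1],
                )
                beta_red = _interp_path(a_red, c_red, alphas[k1])
            cov_red = float(Xy[prev] @ beta_red)
        else:
            cov_red = 0.0
        drop = cov_full - cov_red
        if sigma2 <= 0:
            pvals[j] = 1.0 if drop <= 0 else 0.0
        else:
            pvals[j] = float(np.exp(-max(drop, 0.0) / sigma2))
    return pvals


@dataclass
class _InstanceProducts:
    """Shared inner products of one training set (standardized scale)."""

    genes: list[str]
    n_train: int
    S: np.ndarray            # Zs.T @ Zs, genes x genes
    C: np.ndarray | None     # CNs.T @ Zs, genes x genes (row g: gene g's CN)
    cn_cn: np.ndarray | None  # per-gene CN self inner product
    folds: list[dict]        # per-fold product blocks


def _standardize(block: np.ndarray):
    mean = block.mean(axis=0)
    sd = block.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(block)
    z[:, ok] = (block[:, ok] - mean[ok]) / sd[ok]
    return z, mean, sd, ok


def _build_products(Ztr, CNtr, n_folds=5):
    n = Ztr.shape[0]
    S = Ztr.T @ Ztr
    if CNtr is not None:
        C = CNtr.T @ Ztr
        cn_cn = (CNtr**2).sum(axis=0)
    else:
        C, cn_cn = None, None
    folds = []
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    for f in range(n_folds):
        val = np.arange(bounds[f], bounds[f + 1])
        trn = np.setdiff1d(np.arange(n), val)
        d = {
            "S_t": Ztr[trn].T @ Ztr[trn],
            "S_v": Ztr[val].T @ Ztr[val],
            "n_t": len(trn),
        }
        if CNtr is not None:
            d["C_t"] = CNtr[trn].T @ Ztr[trn]
            d["C_v"] = CNtr[val].T @ Ztr[val]
            d["cn_cn_t"] = (CNtr[trn] ** 2).sum(axis=0)
            d["cn_cn_v"] = (CNtr[val] ** 2).sum(axis=0)
        folds.append(d)
    return S, C, cn_cn, folds


def _fit_one_gene(
    g: int,
    pred_idx: np.ndarray,
    use_cn: bool,
    prod: _InstanceProducts,
    sd_y: float,
    config: PipelineConfig,
) -> GeneModel:
    """Fit the model of gene index ``g`` from shared inner products."""
    genes = prod.genes
    target = genes[g]
    n = prod.n_train
    p_expr = len(pred_idx)
    if p_expr + int(use_cn) == 0 or sd_y == 0:
        flags = ("zero_variance_target",) if sd_y == 0 else ("no_predictors",)
        return GeneModel(target, 0.0, pd.DataFrame(columns=PREDICTOR_COLUMNS), flags)

    dim = p_expr + int(use_cn)
    Gram = np.empty((dim, dim))
    Gram[:p_expr, :p_expr] = prod.S[np.ix_(pred_idx, pred_idx)]
    Xy = np.empty(dim)
    Xy[:p_expr] = prod.S[pred_idx, g]
    if use_cn:
        Gram[p_expr, :p_expr] = prod.C[g, pred_idx]
        Gram[:p_expr, p_expr] = prod.C[g, pred_idx]
        Gram[p_expr, p_expr] = prod.cn_cn[g]
        Xy[p_expr] = prod.C[g, g]
    yty = prod.S[g, g]

    fold_products = []
    for d in prod.folds:
        Xy_t = np.empty(dim)
        Xy_t[:p_expr] = d["S_t"][pred_idx, g]
        Gram_t = np.empty((dim, dim))
        Gram_t[:p_expr, :p_expr] = d["S_t"][np.ix_(pred_idx, pred_idx)]
        Xy_v = np.empty(dim)
        Xy_v[:p_expr] = d["S_v"][pred_idx, g]
        Gram_v = np.empty((dim, dim))
        Gram_v[:p_expr, :p_expr] = d["S_v"][np.ix_(pred_idx, pred_idx)]
        if use_cn:
            for G_, C_, key in ((Gram_t, d["C_t"], "cn_cn_t"), (Gram_v, d["C_v"], "cn_cn_v")):
                G_[p_expr, :p_expr] = C_[g, pred_idx]
                G_[:p_expr, p_expr] = C_[g, pred_idx]
                G_[p_expr, p_expr] = d[key][g]
            Xy_t[p_expr] = d["C_t"][g, g]
            Xy_v[p_expr] = d["C_v"][g, g]
        yty_v = d["S_v"][g, g]
        fold_products.append((Xy_t, Gram_t, d["n_t"], Xy_v, Gram_v, yty_v))

    cap = min(n - 2, config.lasso_path_cap)
    sigma2, _, _ = _cv_sigma2(Xy, Gram, fold_products, yty, n, cap)
    pvals = covariance_test_pvalues(Xy, Gram, n, cap, sigma2)

    if not pvals:
        return GeneModel(target, 0.0, pd.DataFrame(columns=PREDICTOR_COLUMNS))
    idx = np.array(sorted(pvals), dtype=int)
    p_raw = np.array([pvals[int(j)] for j in idx])
    q = bh_fdr(np.clip(p_raw, 0.0, 1.0))
    keep = idx[q <= config.predictor_q]
    if len(keep) == 0:
        return GeneModel(target, 0.0, pd.DataFrame(columns=PREDICTOR_COLUMNS))

    # OLS refit on the retained standardized predictors (Gram form):
    # beta = (Z_K^T Z_K)^-1 Z_K^T y; intercept = mean(y) in original units.
    G_K = Gram[np.ix_(keep, keep)]
    b, *_ = np.linalg.lstsq(G_K, Xy[keep], rcond=None)
    rows = []
    qmap = dict(zip(idx.tolist(), q.tolist()))
    for j, coef in zip(keep.tolist(), b):
        kind = COPY_NUMBER if (use_cn and j == p_expr) else EXPRESSION
        pid = target if kind == COPY_NUMBER else genes[pred_idx[j]]
        rows.append(
            {
                "predictor_id": pid,
                "kind": kind,
                "coefficient": coef * sd_y,  # back to target units per predictor sd
                "p": pvals[int(j)],
                "q": qmap[j],
            }
        )
    return GeneModel(target, 0.0, pd.DataFrame(rows, columns=PREDICTOR_COLUMNS))


def fit_gene_model(
    y: np.ndarray,
    Z: pd.DataFrame,
    kinds: pd.Series,
    config: PipelineConfig | None = None,
    target: str = "target",
) -> GeneModel:
    """Standalone single-model fit (cells x predictors), used directly in
    tests and small problems; ``learn_network`` uses the shared-product path.

    ``kinds`` maps predictor column -> expression/copy_number.
    """
    config = config or PipelineConfig()
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError("need at least 20 training cells")
    sd_y = y.std()
    block = Z.to_numpy(dtype=float)
    z, mean, sd, ok = _standardize(block)
    cols = [c for c, keep in zip(Z.columns, ok) if keep]
    z = z[:, ok]
    if sd_y == 0 or z.shape[1] == 0:
        flags = ("zero_variance_target",) if sd_y == 0 else ("no_predictors",)
        return GeneModel(target, float(y.mean()), pd.DataFrame(columns=PREDICTOR_COLUMNS), flags)
    ys = (y - y.mean()) / sd_y
    Gram = z.T @ z
    Xy = z.T @ ys
    bounds = np.linspace(0, n, 6).astype(int)
    fold_products = []
    for f in range(5):
        val = np.arange(bounds[f], bounds[f + 1])
        trn = np.setdiff1d(np.arange(n), val)
        fold_products.append(
            (
                z[trn].T @ ys[trn], z[trn].T @ z[trn], len(trn),
                z[val].T @ ys[val], z[val].T @ z[val], float(ys[val] @ ys[val]),
            )
        )
    cap = min(n - 2, config.lasso_path_cap)
    sigma2, _, _ = _cv_sigma2(Xy, Gram, fold_products, float(ys @ ys), n, cap)
    pvals = covariance_test_pvalues(Xy, Gram, n, cap, sigma2)
    if not pvals:
        return GeneModel(target, float(y.mean()), pd.DataFrame(columns=PREDICTOR_COLUMNS))
    idx = np.array(sorted(pvals), dtype=int)
    q = bh_fdr(np.array([pvals[int(j)] for j in idx]))
    keep = idx[q <= config.predictor_q]
    if len(keep) == 0:
        return GeneModel(target, float(y.mean()), pd.DataFrame(columns=PREDICTOR_COLUMNS))
    b, *_ = np.linalg.lstsq(Gram[np.ix_(keep, keep)], Xy[keep], rcond=None)
    qmap = dict(zip(idx.tolist(), q.tolist()))
    rows = [
        {
            "predictor_id": cols[j],
            "kind": kinds[cols[j]],
            "coefficient": coef * sd_y,
            "p": pvals[int(j)],
            "q": qmap[j],
        }
        for j, coef in zip(keep.tolist(), b)
    ]
    return GeneModel(target, float(y.mean()), pd.DataFrame(rows, columns=PREDICTOR_COLUMNS))


# ---------------------------------------------------------------------------
# Network learning / prediction / validation
# ---------------------------------------------------------------------------


def learn_network(
    X: ExpressionMatrix,
    CN: pd.DataFrame | None,
    ann: GeneAnnotation,
    config: PipelineConfig | None = None,
    seed: int = 0,
    instance_id: int = 0,
    exclusion: int = 50,
) -> RegulatoryNetwork:
    """Learn one network instance: split cells, fit every gene's model.

    ``X`` is the analysis matrix (variance-filtered, genomically ordered);
    ``CN`` aligns gene x cell copy-number estimates (None disables the
    covariate).  Per-gene failures are recorded as model flags, never abort
    the instance.  Deterministic given the seed.
    """
    from codelnet.genomics_io import restrict_annotation

    config = config or PipelineConfig()
    ann = restrict_annotation(ann, X.gene_ids)
    genes = list(X.gene_ids)
    train, test = split_train_test(list(X.cell_ids), config.train_fraction, seed)
    if len(train) < 20:
        raise ValueError("need at least 20 training cells")

    Ztr = X.data[train].to_numpy(dtype=float).T  # cells x genes
    Zs, mean, sd, ok = _standardize(Ztr)
    if CN is not None:
        CNtr = CN.loc[genes, train].to_numpy(dtype=float).T
        CNs, cn_mean, cn_sd, cn_ok = _standardize(CNtr)
    else:
        CNs = cn_mean = cn_sd = cn_ok = None

    S, C, cn_cn, folds = _build_products(Zs, CNs)
    prod = _InstanceProducts(genes, len(train), S, C, cn_cn, folds)

    gene_pos = {g: i for i, g in enumerate(genes)}
    t = ann.table.set_index("gene_id")
    chrom = t.loc[genes, "chromosome"].to_numpy()
    oi = t.loc[genes, "order_index"].to_numpy()

    models: dict[str, GeneModel] = {}
    for g, gene in enumerate(genes):
        same = chrom == chrom[g]
        local = same & (np.abs(oi - oi[g]) <= exclusion)
        pred_idx = np.flatnonzero(~local & ok)
        use_cn = CNs is not None and bool(cn_ok[g])
        if sd[g] == 0:
            models[gene] = GeneModel(
                gene, float(mean[g]), pd.DataFrame(columns=PREDICTOR_COLUMNS),
                ("zero_variance_target",),
            )
            continue
        try:
            model = _fit_one_gene(g, pred_idx, use_cn, prod, sd[g], config)
            model.intercept = float(mean[g])
            models[gene] = model
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("model for %s failed: %s", gene, exc)
            models[gene] = GeneModel(
                gene, float(mean[g]), pd.DataFrame(columns=PREDICTOR_COLUMNS),
                ("fit_failed",),
            )

    return RegulatoryNetwork(
        instance_id=instance_id,
        seed=seed,
        train_cells=train,
        test_cells=test,
        models=models,
        train_mean=pd.Series(mean, index=genes),
        train_sd=pd.Series(sd, index=genes),
        cn_mean=pd.Series(cn_mean, index=genes) if cn_mean is not None else None,
        cn_sd=pd.Series(cn_sd, index=genes) if cn_sd is not None else None,
        config=config.as_dict() | {"exclusion": exclusion},
    )


def predict_expression(
    net: RegulatoryNetwork,
    X_test: pd.DataFrame | ExpressionMatrix,
    CN_test: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Model-based expression prediction for new cells.

    Predictor values are standardized with the training-set parameters; the
    copy-number covariate of a gene reads from ``CN_test``.  Missing predictor
    rows are an error naming the predictor.
    """
    data = X_test.data if isinstance(X_test, ExpressionMatrix) else X_test
    cells = data.columns
    out = np.zeros((len(net.models), len(cells)))
    for i, (gene, model) in enumerate(net.models.items()):
        yhat = np.full(len(cells), model.intercept)
        for _, r in model.predictors.iterrows():
            pid = r["predictor_id"]
            if r["kind"] == EXPRESSION:
                if pid not in data.index:
                    raise KeyError(f"predictor {pid!r} missing from test matrix")
                v = data.loc[pid].to_numpy(dtype=float)
                m, s = net.train_mean[pid], net.train_sd[pid]
            else:
                if CN_test is None or pid not in CN_test.index:
                    raise KeyError(f"copy-number predictor {pid!r} missing")
                v = CN_test.loc[pid, cells].to_numpy(dtype=float)
                m, s = net.cn_mean[pid], net.cn_sd[pid]
            if s > 0:
                yhat = yhat + r["coefficient"] * (v - m) / s
        out[i] = yhat
    return pd.DataFrame(out, index=list(net.models), columns=cells)


def prediction_quality(pred: pd.DataFrame, obs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Pearson correlation between predicted and observed expression.

    Constant predictions (or observations) make r undefined; they are flagged
    and excluded from downstream medians.
    """
    if pred.shape != obs.shape:
        raise ValueError("prediction and observation shapes differ")
    if pred.shape[1] < 3:
        raise ValueError("need at least 3 test cells for correlations")
    P = pred.to_numpy(dtype=float)
    O = obs.loc[pred.index, pred.columns].to_numpy(dtype=float)
    Pc = P - P.mean(axis=1, keepdims=True)
    Oc = O - O.mean(axis=1, keepdims=True)
    denom = np.sqrt((Pc**2).sum(axis=1) * (Oc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Pc * Oc).sum(axis=1) / denom
    defined = denom > 0
    return pd.DataFrame(
        {"r": np.where(defined, r, np.nan), "defined": defined,
         "n_test": pred.shape[1]},
        index=pred.index,
    )


def compare_median_correlations(r_orig: pd.Series, r_random: pd.Series):
    """One-sided paired rank test (Wilcoxon signed-rank): original > random.

    Pairs with an undefined correlation on either side are dropped; the
    all-ties degenerate case yields p = 1 by convention with a flag.
    Returns (median_orig, median_random, p, flag).
    """
    paired = pd.DataFrame({"orig": r_orig, "rand": r_random}).dropna()
    if len(paired) == 0:
        raise ValueError("no paired defined correlations")
    d = paired["orig"] - paired["rand"]
    med_o = float(paired["orig"].median())
    med_r = float(paired["rand"].median())
    if (d == 0).all():
        return med_o, med_r, 1.0, "all_ties"
    stat = stats.wilcoxon(paired["orig"], paired["rand"],
                          alternative="greater", zero_method="wilcox")
    return med_o, med_r, float(stat.pvalue), ""


# ---------------------------------------------------------------------------
# Degree-preserving permutation
# ---------------------------------------------------------------------------


def permute_network_degree_preserving(
    net: RegulatoryNetwork,
    ann: GeneAnnotation,
    seed: int = 0,
    n_swaps_factor: int = 10,
    exclusion: int = 50,
    n_swaps: int | None = None,
) -> RegulatoryNetwork:
    """Random network of identical complexity via directed double-edge swaps.

    Two expression edges (a->b), (c->d) are rewired to (a->d), (c->b) when the
    result creates no self-loop, no duplicate edge, and no edge inside the
    local +/-50 exclusion zone; each edge's coefficient stays attached to its
    moving source.  ``10 * n_edges`` successful swaps are performed (bounded
    attempts); ``n_swaps`` overrides the count for diagnostic use.
    Copy-number covariates are reassigned uniformly among genes, preserving
    their count.  Intercepts, split, and standardization stats are unchanged.
    """
    from codelnet.genomics_io import restrict_annotation

    rng = np.random.default_rng(seed)
    genes = net.genes
    ann = restrict_annotation(ann, genes)
    t = ann.table.set_index("gene_id")
    chrom = {g: t.loc[g, "chromosome"] for g in genes}
    oi = {g: int(t.loc[g, "order_index"]) for g in genes}

    def is_local(u, v):
        return chrom[u] == chrom[v] and abs(oi[u] - oi[v]) <= exclusion

    edges = []  # (source, target, coefficient, p, q)
    cn_records = []
    for target, model in net.models.items():
        for _, r in model.predictors.iterrows():
            if r["kind"] == EXPRESSION:
                edges.append([r["predictor_id"], target, r["coefficient"], r["p"], r["q"]])
            else:
                cn_records.append((r["coefficient"], r["p"], r["q"]))
    warn_flag = ""
    if len(edges) >= 2:
        edge_set = {(e[0], e[1]) for e in edges}
        target_swaps = n_swaps if n_swaps is not None else n_swaps_factor * len(edges)
        max_attempts = 100 * target_swaps
        done = attempts = 0
        while done < target_swaps and attempts < max_attempts:
            attempts += 1
            i, j = rng.integers(0, len(edges), size=2)
            if i == j:
                continue
            a, b = edges[i][0], edges[i][1]
            c, d = edges[j][0], edges[j][1]
            if a == d or c == b:
                continue
            if (a, d) in edge_set or (c, b) in edge_set:
                continue
            if is_local(a, d) or is_local(c, b):
                continue
            edge_set.discard((a, b))
            edge_set.discard((c, d))
            edge_set.add((a, d))
            edge_set.add((c, b))
            edges[i][1], edges[j][1] = d, b
            done += 1
        if done == 0:
            warn_flag = "no_legal_swap"
            logger.warning("degree-preserving permutation found no legal swap")
    else:
        warn_flag = "too_few_edges"

    cn_targets = list(rng.choice(genes, size=len(cn_records), replace=False)) \
        if cn_records else []

    new_models: dict[str, GeneModel] = {}
    rows_by_target: dict[str, list] = {g: [] for g in genes}
    for source, target, coef, p, q in edges:
        rows_by_target[target].append(
            {"predictor_id": source, "kind": EXPRESSION,
             "coefficient": coef, "p": p, "q": q}
        )
    for (coef, p, q), target in zip(cn_records, cn_targets):
        rows_by_target[target].append(
            {"predictor_id": target, "kind": COPY_NUMBER,
             "coefficient": coef, "p": p, "q": q}
        )
    for gene in genes:
        old = net.models[gene]
        flags = old.flags + ((warn_flag,) if warn_flag else ())
        new_models[gene] = GeneModel(
            gene, old.intercept,
            pd.DataFrame(rows_by_target[gene], columns=PREDICTOR_COLUMNS),
            flags,
        )
    return RegulatoryNetwork(
        instance_id=net.instance_id,
        seed=seed,
        train_cells=net.train_cells,
        test_cells=net.test_cells,
        models=new_models,
        train_mean=net.train_mean,
        train_sd=net.train_sd,
        cn_mean=net.cn_mean,
        cn_sd=net.cn_sd,
        config=dict(net.config) | {"permuted": True},
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_network(net: RegulatoryNetwork, prefix) -> None:
    """TSV edge table plus a JSON header with split and config snapshot."""
    import json

    rows = []
    for target, model in net.models.items():
        for _, r in model.predictors.iterrows():
            rows.append(
                {
                    "instance_id": net.instance_id,
                    "target_gene": target,
                    "predictor_id": r["predictor_id"],
                    "kind": r["kind"],
                    "coefficient": r["coefficient"],
                    "p": r["p"],
                    "q": r["q"],
                }
            )
    pd.DataFrame(
        rows,
        columns=["instance_id", "target_gene", "predictor_id", "kind",
                 "coefficient", "p", "q"],
    ).to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)
    header = {
        "instance_id": net.instance_id,
        "seed": net.seed,
        "train_cells": net.train_cells,
        "test_cells": net.test_cells,
        "config": net.config,
        "genes": net.genes,
        "intercepts": {g: net.models[g].intercept for g in net.genes},
        "train_mean": net.train_mean.to_dict(),
        "train_sd": net.train_sd.to_dict(),
        "cn_mean": net.cn_mean.to_dict() if net.cn_mean is not None else None,
        "cn_sd": net.cn_sd.to_dict() if net.cn_sd is not None else None,
    }
    with open(f"{prefix}.header.json", "w") as fh:
        json.dump(header, fh, indent=1)


def read_network(prefix) -> RegulatoryNetwork:
    """Reload a network instance written by :func:`write_network`."""
    import json

    with open(f"{prefix}.header.json") as fh:
        header = json.load(fh)
    edges = pd.read_csv(f"{prefix}.edges.tsv", sep="\t")
    genes = header["genes"]
    models: dict[str, GeneModel] = {}
    for gene in genes:
        sub = edges[edges["target_gene"] == gene]
        rows = sub.rename(columns={"predictor_id": "predictor_id"})[
            ["predictor_id", "kind", "coefficient", "p", "q"]
        ].reset_index(drop=True)
        models[gene] = GeneModel(gene, header["intercepts"][gene], rows)
    return RegulatoryNetwork(
        instance_id=header["instance_id"],
        seed=header["seed"],
        train_cells=header["train_cells"],
        test_cells=header["test_cells"],
        models=models,
        train_mean=pd.Series(header["train_mean"]),
        train_sd=pd.Series(header["train_sd"]),
        cn_mean=pd.Series(header["cn_mean"]) if header["cn_mean"] else None,
        cn_sd=pd.Series(header["cn_sd"]) if header["cn_sd"] else None,
        config=header["config"],
    )
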