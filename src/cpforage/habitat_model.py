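"""Binomial habitat-selection GAMs with shrinkage splines and CV-driven selection.

The model is a penalized logistic regression of presence vs pseudo-absence on
smooth functions of standardized covariates. Each smooth uses a natural cubic
regression spline basis on quantile knots (default k = 3) with the exact
integrated-squared-second-derivative penalty; the penalty's null space
(the linear trend left unpenalized by a conventional smoother) is given a
small positive eigenvalue, so a large enough smoothing parameter shrinks a
term's effective degrees of freedom all the way to zero and uninformative
covariates can drop out of the fit ("shrinkage smoothers"). Smoothing
parameters are chosen per term by GCV inside a penalized IRLS loop.

Covariates enter by forward stepwise selection ordered and validated by
cross-validated ROC AUC, with leave-one-colony-out folds (or random splits
for single-colony groups), a tie rule for near-equal starting covariates, an
optional distance x bathymetry tensor smooth trial, and knot escalation
(3 -> 4 -> 5) when a kept term's deviance residuals fail a runs test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.linalg import null_space
from scipy.special import expit
from scipy.stats import rankdata

log = logging.getLogger(__name__)

LOG_LAMBDA_GRID = np.linspace(-4.0, 8.0, 13)
SHRINK_EPS = 0.1  # null-space eigenvalue as a fraction of the largest penalty eigenvalue
MAX_COVARIATES = 7


class GamConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SmoothTerm:
    """One smooth: a covariate name, or a pair for a tensor-product smooth."""

    covariate: str | tuple[str, str]
    k: int = 3

    def __post_init__(self) -> None:
        if self.k < 3:
            raise ValueError("at least 3 knots are required")

    @property
    def name(self) -> str:
        if isinstance(self.covariate, tuple):
            return "x".join(self.covariate)
        return self.covariate

    @property
    def is_tensor(self) -> bool:
        return isinstance(self.covariate, tuple)


class _MarginalBasis:
    """Cardinal natural cubic splines on quantile knots, with exact curvature penalty."""

    def __init__(self, x: np.ndarray, k: int, knots: np.ndarray | None = None):
        if knots is None:
            qs = np.linspace(0, 1, k)
            knots = np.unique(np.quantile(x, qs))
            if len(knots) < 3:
                lo, hi = float(np.min(x)), float(np.max(x))
                if hi <= lo:
                    hi = lo + 1.0
                knots = np.linspace(lo, hi, k)
        self.knots = np.asarray(knots, dtype=float)
        knots = self.knots
        m = len(knots)
        self.splines = []
        for j in range(m):
            e = np.zeros(m)
            e[j] = 1.0
            self.splines.append(CubicSpline(knots, e, bc_type="natural"))
        # exact penalty: second derivatives are piecewise linear between knots
        s2 = np.array([sp(knots, 2) for sp in self.splines])  # (m, m)
        h = np.diff(knots)
        S = np.zeros((m, m))
        for l in range(m - 1):
            a = s2[:, l]
            b = s2[:, l + 1]
            S += h[l] / 6.0 * (2 * np.outer(a, a) + np.outer(a, b) + np.outer(b, a) + 2 * np.outer(b, b))
        self.S = S

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        xc = np.clip(x, lo, hi)
        B = np.column_stack([sp(xc) for sp in self.splines])
        # linear extrapolation beyond the boundary knots
        below, above = x < lo, x > hi
        if below.any():
            d = np.array([sp(lo, 1) for sp in self.splines])
            B[below] += np.outer(x[below] - lo, d)
        if above.any():
            d = np.array([sp(hi, 1) for sp in self.splines])
            B[above] += np.outer(x[above] - hi, d)
        return B


class _TermBlock:
    """Constrained (sum-to-zero) design block and shrinkage penalty for one term."""

    def __init__(self, term: SmoothTerm, data: pd.DataFrame):
        self.term = term
        if term.is_tensor:
            a, b = term.covariate
            self.marginals = (_MarginalBasis(data[a].to_numpy(), term.k),
                              _MarginalBasis(data[b].to_numpy(), term.k))
            Ba = self.marginals[0].evaluate(data[a].to_numpy())
            Bb = self.marginals[1].evaluate(data[b].to_numpy())
            B = _row_kron(Ba, Bb)
            Sa, Sb = self.marginals[0].S, self.marginals[1].S
            ka, kb = Sa.shape[0], Sb.shape[0]
            S = np.kron(Sa, np.eye(kb)) + np.kron(np.eye(ka), Sb)
        else:
            self.marginals = (_MarginalBasis(data[term.covariate].to_numpy(), term.k),)
            B = self.marginals[0].evaluate(data[term.covariate].to_numpy())
            S = self.marginals[0].S
        C = B.mean(axis=0, keepdims=True)
        Z = null_space(C)
        self.Z = Z
        Sc = Z.T @ S @ Z
        # shrinkage: lift the penalty's null space so lambda -> inf zeroes the term
        evals, evecs = np.linalg.eigh(Sc)
        evals = np.maximum(evals, 0.0)
        top = evals.max() if evals.max() > 0 else 1.0
        evals[evals < 1e-10 * top] = SHRINK_EPS * top
        self.S = (evecs * evals) @ evecs.T
        self.X = B @ Z

    def design(self, data: pd.DataFrame | dict) -> np.ndarray:
        term = self.term
        if term.is_tensor:
            a, b = term.covariate
            Ba = self.marginals[0].evaluate(np.asarray(data[a], dtype=float).ravel())
            Bb = self.marginals[1].evaluate(np.asarray(data[b], dtype=float).ravel())
            B = _row_kron(Ba, Bb)
        else:
            B = self.marginals[0].evaluate(np.asarray(data[term.covariate], dtype=float).ravel())
        return B @ self.Z


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def _block_to_dict(blk: _TermBlock) -> dict:
    cov = list(blk.term.covariate) if blk.term.is_tensor else blk.term.covariate
    return {
        "covariate": cov,
        "k": blk.term.k,
        "knots": [m.knots.tolist() for m in blk.marginals],
        "Z": blk.Z.tolist(),
    }


def _block_from_dict(d: dict) -> _TermBlock:
    cov = tuple(d["covariate"]) if isinstance(d["covariate"], list) else d["covariate"]
    term = SmoothTerm(cov, d["k"])
    blk = _TermBlock.__new__(_TermBlock)
    blk.term = term
    blk.marginals = tuple(
        _MarginalBasis(np.zeros(1), term.k, knots=np.asarray(kn)) for kn in d["knots"]
    )
    blk.Z = np.asarray(d["Z"], dtype=float)
    blk.S = None
    blk.X = None
    return blk


@dataclass
class FittedGAM:
    """Penalized binomial GAM: intercept + smooth terms with per-term lambdas."""

    terms: list[SmoothTerm]
    blocks: list[_TermBlock] = field(repr=False, default_factory=list)
    beta: np.ndarray | None = None
    lambdas: np.ndarray | None = None
    edf_by_term: dict[str, float] = field(default_factory=dict)
    edf_total: float = 0.0
    deviance: float = 0.0
    converged: bool = False
    separation_flag: bool = False

    @property
    def intercept(self) -> float:
        return float(self.beta[0])

    def _design(self, data) -> np.ndarray:
        n = len(next(iter(data.values()))) if isinstance(data, dict) else len(data)
        cols = [np.ones((n, 1))]
        cols += [blk.design(data) for blk in self.blocks]
        return np.hstack(cols)

    def predict_eta(self, data) -> np.ndarray:
        """Linear predictor on new data (columns named as the fitted covariates)."""
        return self._design(data) @ self.beta

    def predict_mu(self, data) -> np.ndarray:
        return expit(self.predict_eta(data))

    def partial_effect(self, term_name: str, data) -> np.ndarray:
        """Centered contribution of one smooth term evaluated on new data."""
        off = 1
        for blk in self.blocks:
            w = blk.Z.shape[1]
            if blk.term.name == term_name:
                return blk.design(data) @ self.beta[off : off + w]
            off += w
        raise KeyError(term_name)

    def to_dict(self) -> dict:
        return {
            "blocks": [_block_to_dict(b) for b in self.blocks],
            "beta": self.beta.tolist(),
            "lambdas": self.lambdas.tolist() if self.lambdas is not None else None,
            "edf_by_term": self.edf_by_term,
            "edf_total": self.edf_total,
            "deviance": self.deviance,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedGAM":
        blocks = [_block_from_dict(b) for b in d["blocks"]]
        gam = cls(terms=[b.term for b in blocks], blocks=blocks)
        gam.beta = np.asarray(d["beta"], dtype=float)
        gam.lambdas = np.asarray(d["lambdas"], dtype=float) if d.get("lambdas") else None
        gam.edf_by_term = d.get("edf_by_term", {})
        gam.edf_total = d.get("edf_total", 0.0)
        gam.deviance = d.get("deviance", 0.0)
        gam.converged = d.get("converged", True)
        return gam


def _pirls(X, y, S_blocks, col_slices, lambdas, beta0=None, max_iter=60, tol=1e-8):
    """Penalized IRLS for binomial y given per-term penalties; returns fit stats."""
    n, p = X.shape
    S = np.zeros((p, p))
    for sl, Sb, lam in zip(col_slices, S_blocks, lambdas):
        S[sl, sl] += lam * Sb
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    dev_old = np.inf
    ok = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X
        try:
            beta_new = np.linalg.solve(H + S, XtW @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(H + S, XtW @ z, rcond=None)[0]
        dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))
        if np.max(np.abs(beta_new - beta)) < tol * (1 + np.max(np.abs(beta))):
            beta = beta_new
            ok = True
            break
        if not np.isfinite(dev):
            break
        beta = beta_new
        dev_old = dev
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    w = mu * (1 - mu)
    XtW = X.T * w
    H = XtW @ X
    A = np.linalg.solve(H + S, H)
    edf_diag = np.diag(A)
    dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))
    return beta, dev, edf_diag, ok


def fit_binomial_gam(
    table: pd.DataFrame,
    terms: list[SmoothTerm],
    label_col: str = "label",
    select_lambda: bool = True,
    n_sweeps: int = 2,
) -> FittedGAM:
    """Fit a penalized binomial GAM with per-term GCV smoothing selection.

    ``table`` must hold the (standardized) covariate columns the terms name
    and a 0/1 ``label`` column. Smoothing parameters are optimized one term
    at a time on a log grid by the GCV score n*deviance/(n - edf)^2.
    """
    y = table[label_col].to_numpy().astype(float)
    if y.min() == y.max():
        raise ValueError("labels are all one class")
    if not terms:
        raise ValueError("no terms supplied")
    model = FittedGAM(terms=list(terms))
    model.blocks = [_TermBlock(t, table) for t in terms]
    n = len(table)
    X = np.hstack([np.ones((n, 1))] + [blk.X for blk in model.blocks])
    S_blocks, col_slices = [], []
    off = 1
    for blk in model.blocks:
        w = blk.X.shape[1]
        S_blocks.append(blk.S)
        col_slices.append(slice(off, off + w))
        off += w

    lambdas = np.ones(len(terms))
    beta = None

    def gcv(lams, beta0):
        b, dev, edf_diag, ok = _pirls(X, y, S_blocks, col_slices, lams, beta0)
        edf = edf_diag.sum()
        denom = max(n - edf, 1e-3)
        return n * dev / denom**2, b, dev, edf_diag, ok

    if select_lambda:
        for _ in range(n_sweeps):
            for j in range(len(terms)):
                best = (np.inf, None, None)
                for ll in LOG_LAMBDA_GRID:
                    trial = lambdas.copy()
                    trial[j] = 10.0**ll
                    score, b, *_ = gcv(trial, beta)
                    if score < best[0]:
                        best = (score, 10.0**ll, b)
                lambdas[j] = best[1]
                beta = best[2]
    score, beta, dev, edf_diag, ok = gcv(lambdas, beta)
    if not ok:
        log.warning("fit_binomial_gam: IRLS did not fully converge (deviance %.3f)", dev)
    mu = expit(X @ beta)
    model.separation_flag = bool((np.minimum(mu, 1 - mu) < 1e-8).mean() > 0.5)
    if model.separation_flag:
        log.warning("fit_binomial_gam: possible complete separation detected")
    model.beta = beta
    model.lambdas = lambdas
    model.edf_by_term = {
        t.name: float(edf_diag[sl].sum()) for t, sl in zip(terms, col_slices)
    }
    model.edf_total = float(edf_diag.sum())
    model.deviance = float(dev)
    model.converged = ok
    return model


def fit_intercept_only(table: pd.DataFrame, label_col: str = "label") -> float:
    """Constant fitted probability of the intercept-only binomial model."""
    return float(table[label_col].mean())


def roc_metrics(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """AUC (rank / Mann-Whitney form, ties 1/2) and Youden-optimal sens/spec.

    Sensitivity and specificity are reported at the threshold maximizing
    Youden's J = sensitivity + specificity - 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # Youden threshold scan over the sorted unique scores
    order = np.argsort(scores)[::-1]
    y_sorted = labels[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, len(s_sorted) - 1]
    sens = tps[idx] / n_pos
    spec = 1.0 - fps[idx] / n_neg
    best = int(np.argmax(sens + spec))
    return float(auc), float(sens[best]), float(spec[best])


@dataclass
class FoldScheme:
    """Cross-validation folds: leave-one-colony-out or a random split."""

    mode: str  # "colony" | "random"
    assignments: pd.Series  # fold label per row

    @classmethod
    def by_colony(cls, table: pd.DataFrame) -> "FoldScheme":
        return cls("colony", table["colony_id"].astype(str))

    @classmethod
    def random_split(cls, table: pd.DataFrame, test_fraction: float = 0.25, seed: int = 0) -> "FoldScheme":
        rng = np.random.default_rng(seed)
        lab = np.where(rng.random(len(table)) < test_fraction, "test", "train")
        return cls("random", pd.Series(lab, index=table.index))

    def folds(self):
        if self.mode == "colony":
            for colony in sorted(self.assignments.unique()):
                test = self.assignments == colony
                yield ~test.to_numpy(), test.to_numpy()
        else:
            test = (self.assignments == "test").to_numpy()
            yield ~test, test


def cv_evaluate(
    table: pd.DataFrame,
    terms: list[SmoothTerm],
    scheme: FoldScheme,
    label_col: str = "label",
) -> dict:
    """Fit on each training fold, score the held-out fold, report mean +- SD metrics."""
    aucs, sens, specs = [], [], []
    skipped = 0
    for train, test in scheme.folds():
        y_test = table.loc[test, label_col]
        y_train = table.loc[train, label_col]
        if y_test.nunique() < 2 or y_train.nunique() < 2:
            skipped += 1
            log.warning("cv_evaluate: fold skipped (single class)")
            continue
        gam = fit_binomial_gam(table[train], terms, label_col=label_col)
        score = gam.predict_eta(table[test])
        a, sn, sp = roc_metrics(score, y_test.to_numpy())
        aucs.append(a)
        sens.append(sn)
        specs.append(sp)
    if not aucs:
        raise ValueError("no usable folds")
    return {
        "auc": float(np.mean(aucs)),
        "auc_sd": float(np.std(aucs, ddof=0)),
        "sensitivity": float(np.mean(sens)),
        "sensitivity_sd": float(np.std(sens, ddof=0)),
        "specificity": float(np.mean(specs)),
        "specificity_sd": float(np.std(specs, ddof=0)),
        "n_folds": len(aucs),
        "n_skipped": skipped,
    }


def _runs_test_poor_fit(residuals: np.ndarray, order_by: np.ndarray, alpha: float = 0.05) -> bool:
    """Wald-Wolfowitz runs test on residual signs ordered by a covariate."""
    signs = np.sign(residuals[np.argsort(order_by, kind="stable")])
    signs = signs[signs != 0]
    n1 = int((signs > 0).sum())
    n2 = int((signs < 0).sum())
    if n1 == 0 or n2 == 0 or n1 + n2 < 20:
        return False
    runs = 1 + int((np.diff(signs) != 0).sum())
    mu = 2 * n1 * n2 / (n1 + n2) + 1
    var = 2 * n1 * n2 * (2 * n1 * n2 - n1 - n2) / ((n1 + n2) ** 2 * (n1 + n2 - 1))
    z = (runs - mu) / np.sqrt(var)
    from scipy.stats import norm

    return 2 * norm.sf(abs(z)) < alpha


def _deviance_residuals(gam: FittedGAM, table: pd.DataFrame, label_col: str) -> np.ndarray:
    y = table[label_col].to_numpy().astype(float)
    mu = np.clip(gam.predict_mu(table), 1e-10, 1 - 1e-10)
    d = -2 * (y * np.log(mu) + (1 - y) * np.log1p(-mu))
    return np.sign(y - mu) * np.sqrt(d)


@dataclass
class HabitatModel:
    """Final selected model for one group: terms, fit, design proportions, CV metrics."""

    group: str
    terms: list[SmoothTerm]
    gam: FittedGAM
    p_absence: float
    p_presence: float
    standardization: dict[str, tuple[float, float]]
    cv_metrics: dict
    single_covariate_auc: dict[str, float] = field(default_factory=dict)

    @property
    def offset(self) -> float:
        """Case-control intercept correction log[(1 - P_a) P_u / P_a]."""
        return float(np.log((1 - self.p_absence) * self.p_presence / self.p_absence))


def forward_stepwise(
    table: pd.DataFrame,
    candidates: list[str],
    scheme: FoldScheme,
    group: str = "group",
    k: int = 3,
    tie_epsilon: float = 0.01,
    try_tensor: tuple[str, str] | None = ("distance", "bathymetry"),
    max_covariates: int = MAX_COVARIATES,
    standardization: dict[str, tuple[float, float]] | None = None,
    max_knots: int = 5,
    label_col: str = "label",
) -> HabitatModel:
    """Forward stepwise GAM selection ordered and validated by CV AUC.

    Each candidate is first scored alone; candidates are added in descending
    single-covariate AUC order and kept only when the mean CV AUC improves by
    at least ``tie_epsilon``. When the top two single-covariate AUCs are
    within ``tie_epsilon``, the whole procedure is rerun from each starting
    covariate and the higher-AUC final model wins. A distance x bathymetry
    tensor smooth replaces the marginal smooths if it improves CV AUC, and a
    kept term's knots are raised (to at most ``max_knots``) when its deviance
    residuals fail a runs test against the covariate.
    """
    if not candidates:
        raise ValueError("no candidate covariates")
    singles: dict[str, float] = {}
    for name in candidates:
        try:
            m = cv_evaluate(table, [SmoothTerm(name, k)], scheme, label_col)
            singles[name] = m["auc"]
        except ValueError:
            singles[name] = np.nan
    ranked = sorted((n for n in candidates if np.isfinite(singles[n])), key=lambda n: -singles[n])
    if not ranked:
        raise ValueError("no candidate could be evaluated")

    def run(order: list[str]):
        kept: list[SmoothTerm] = []
        best_metrics = None
        best_auc = 0.5  # intercept-only AUC
        for name in order:
            if len(kept) >= max_covariates:
                break
            trial = kept + [SmoothTerm(name, k)]
            try:
                m = cv_evaluate(table, trial, scheme, label_col)
            except ValueError:
                continue
            if m["auc"] >= best_auc + tie_epsilon:
                kept = trial
                best_auc = m["auc"]
                best_metrics = m
        return kept, best_auc, best_metrics

    starts = [ranked]
    if len(ranked) >= 2 and singles[ranked[0]] - singles[ranked[1]] < tie_epsilon:
        alt = [ranked[1], ranked[0]] + ranked[2:]
        starts.append(alt)
    results = [run(order) for order in starts]
    kept, best_auc, best_metrics = max(results, key=lambda r: r[1])

    if best_metrics is None:
        log.warning("forward_stepwise: no covariate beat the intercept-only model")
        gam = None
        kept = []
        best_metrics = {"auc": 0.5, "auc_sd": 0.0, "sensitivity": np.nan, "sensitivity_sd": np.nan,
                        "specificity": np.nan, "specificity_sd": np.nan, "n_folds": 0, "n_skipped": 0}
    else:
        # tensor trial: replace the two marginal smooths if CV AUC improves
        if try_tensor is not None:
            names = [t.name for t in kept]
            if try_tensor[0] in names and try_tensor[1] in names:
                tens = [t for t in kept if t.name not in try_tensor] + [SmoothTerm(try_tensor, k)]
                try:
                    m = cv_evaluate(table, tens, scheme, label_col)
                    if m["auc"] > best_auc:
                        kept, best_auc, best_metrics = tens, m["auc"], m
                except ValueError:
                    pass
        # knot escalation on poor residual fit
        improved = True
        while improved:
            improved = False
            gam_full = fit_binomial_gam(table, kept, label_col=label_col)
            resid = _deviance_residuals(gam_full, table, label_col)
            for i, t in enumerate(kept):
                if t.is_tensor or t.k >= max_knots:
                    continue
                if _runs_test_poor_fit(resid, table[t.covariate].to_numpy()):
                    kept[i] = SmoothTerm(t.covariate, t.k + 1)
                    log.info("forward_stepwise: raised knots for %s to %d", t.name, t.k + 1)
                    improved = True
            if improved:
                m = cv_evaluate(table, kept, scheme, label_col)
                best_metrics = m
                best_auc = m["auc"]
        gam = fit_binomial_gam(table, kept, label_col=label_col)

    p_u = float((table[label_col] == 1).mean())
    return HabitatModel(
        group=group,
        terms=kept,
        gam=gam,
        p_absence=1.0 - p_u,
        p_presence=p_u,
        standardization=standardization or {},
        cv_metrics=best_metrics,
        single_covariate_auc={k_: float(v) for k_, v in singles.items()},
    )
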